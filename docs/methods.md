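# Methods

This note documents the models, numerical choices and limitations behind
`rbskit`. It is written for a reader who wants to know exactly what each
stage computes and what the synthetic benchmarks do and do not show.

## Motif model and scanning

The RCD1-binding SLiM (RBS) consensus is

    [ED].{1,2}[^RK][YF].{1,4}[^RK][DE]L

with three single-position variants — V1 drops the leading acidic anchor
(`.{1,2}[^RK][YF].{1,4}[^RK][DE]L`), V2 substitutes the C-terminal
leucine (`...[DE][FIMV]`), V3 inserts one residue before it
(`...[DE].L`) — and an expanded union pattern `...[DE]([LIVMF]|.L)`.
Concrete spans range from 7 residues (V1 minimum) to 13 (V3 and the `.L`
alternative at maximal spacer lengths).

Scanning semantics were a genuinely open design point because a pattern
with two variable-length wildcard runs admits several expansions over
the same residues. The scanner reports every **distinct residue span**
(start, end) for which at least one wildcard assignment matches, and
collapses multiple internal assignments of the same span into one match.
This matches how motif positions are marked on alignments (residues, not
parses). Implementation: for each start position and each candidate span
length within the class's span range, an anchored regex full-match is
tested; an exhaustive wildcard-expansion oracle in the test suite checks
span-for-span equality on random sequences.

Reverse-orientation scanning matches the pattern against the reversed
residue string (proteins: reversal only, no complementation) and reports
spans in forward coordinates; a locus matching both ways yields two
match records.

`X` is accepted as an unknown residue. It never satisfies any pattern
element — including wildcards and negated classes — because an unknown
residue cannot be asserted to meet a constraint. In composition-based
scores it is neutral (mid-scale hydropathy, zero charge, unit helix
weight with a warning).

Per-protein classification assigns `RBS` whenever a consensus match
exists; variants are counted only in consensus-negative proteins, with
fixed precedence V1 > V2 > V3 on ties. Group count tables report
"consensus/total" plus per-variant counts, so variant counts can never
exceed total minus consensus.

## Isoelectric point filter

Candidate peptides are filtered on pI < 4.5 (strict: a peptide at
exactly 4.5 fails). The pI is the root of the Henderson–Hasselbalch net
charge over N-terminus, C-terminus and K/R/H/D/E/C/Y side chains, found
by bisection on pH ∈ [0, 14] until both |charge| < 1e-4 and the bracket
is below 1e-6 pH units (the second criterion matters for very basic
peptides whose charge curve is nearly flat at the crossing). The pKa set
is the EMBOSS table — N-term 8.6, C-term 3.6, K 10.8, R 12.5, H 6.5,
D 3.9, E 4.1, C 8.5, Y 10.1 — chosen as a widely used, fully published
default; it is a function argument, so alternative tables drop in
without code changes. A dense-grid oracle (step 1e-4) bounds the
bisection error below 2e-4 pH in tests.

## Conservation

Column identity is the modal-residue fraction over non-gap rows
(percentage-identity style, no substitution-matrix weighting); columns
with fewer than two residues are flagged undefined. Conserved regions
are maximal runs of columns at or above a threshold, tolerating up to
`max_gap` consecutive sub-threshold columns, discarding runs shorter
than `min_len`, labelled left-to-right with a group prefix (A1…An
style). Defaults — threshold 0.8, min_len 5, max_gap 2 — are declared
choices, not inferred from any published segmentation, and are exposed
in the run configuration.

The motif-conservation filter clusters matches whose alignment-column
spans lie within `window_slack` (default 3) columns of one another into
loci. The conserved fraction is (rows with a match in the locus window)
/ (rows whose degapped sequence spans the window); fragment homologs
that do not reach the window are excluded from the denominator,
mirroring the completeness rule used when curating ortholog sets. A
locus is conserved at fraction ≥ 0.5 (boundary inclusive). A motif
present in one homolog at a non-conserved position — the signature of a
non-binding match — scores 1/n and fails.

## Disorder profiles and MoRFs

Per-residue disorder scores are pluggable: external predictor output is
ingested from (position, residue, score) tables with strict
position/residue validation, and a built-in stand-in makes the pipeline
self-contained. The stand-in is a FoldIndex-inspired charge/hydropathy
rule over a centred window (default 11 residues):

    d = clamp01(0.5 − (2.785·⟨H⟩ − |⟨q⟩| − 1.151) / 2)

with ⟨H⟩ the mean Kyte–Doolittle hydropathy rescaled to [0, 1] and ⟨q⟩
the mean net charge (K, R = +1; D, E = −1; H = +0.5). It reproduces the
coarse order/disorder contrast of composition-biased segments; it does
**not** reproduce any specific predictor's numbers, and no acceptance
check compares it to one.

Scores are projected onto alignment columns through each row's
coordinate map; per column, the rows that are not gapped there
contribute, and min / Q1 / median / Q3 / max are computed with the
linear-interpolation quantile rule (the default of mainstream numeric
stacks). Columns with fewer than three contributing rows are flagged
undefined rather than extrapolated — a deliberate choice over the
alternative of imputing from neighbours. The disorder threshold 0.5
separates order-like from disorder-like medians.

A motif region "dips" when the median of its column medians is at least
`delta` (default 0.05) below the median of medians over flanking windows
(default 15 columns each side, truncated at profile edges); the reported
depth is the difference. With `delta = 0`, any strict decrease counts.

MoRF flags are boolean per-residue tracks; runs shorter than 4 residues
are removed before aggregation, and a column is MoRF-conserved only when
flagged rows exceed 50% of its non-gap rows (strict inequality).

## Helix–coil model

Per-residue helicity uses a Lifson–Roig helix–coil model: each residue
is helix (h) or coil (c); an h residue flanked by h on both sides
carries its propagation weight `w`, any other h residue the nucleation
weight `v` (default 0.05), coil residues weight 1. A residue counts as
helical when it sits in an h-run of length ≥ 3 (one helical turn), so
peptides shorter than three residues have identically zero profiles.

Probabilities are computed exactly by a dynamic program over coil
positions: the partition function factorises over maximal h-runs (run
weight v²·∏ interior w, or v for a singleton), and P(run = [a, b]) is
prefix × run weight × suffix over the total. This is algebraically the
transfer-matrix partition function, organised to yield P(residue in run
≥ 3) directly; the test suite verifies it against exhaustive 2^n state
enumeration to 1e-10 relative error for n ≤ 10.

The shipped `w` table orders residues by intrinsic helix propensity
(Ala 1.70 highest; Gly 0.30 and Pro 0.01 lowest) following host-guest
propensity scales. The model is a documented stand-in for full
helix-propensity predictors: it reproduces ordering and monotone trends
(e.g. a TFE-like global boost of `w` increases mean helicity
monotonically), not any published percentage. Published per-peptide
helicity percentages are therefore never test targets.

The hydrophobic-staple annotation takes a helix start (N-cap) index and
checks N′ = N-cap − 1 and N4 = N-cap + 4: a staple is present when both
are in {L, I, F, V, M}; the N-cap is capping-competent when in
{D, E, N, S, T}. Indexing matches the F/D…L spacing of the canonical
staple geometry.

CD helix fractions at 222 nm use the two-state estimate
fH = (θ222 − θC) / (θH(n) − θC) with θH(n) = −39500·(1 − 2.57/n) and
θC = 2220 − 53·T (°C), clamped to [0, 1]. Only the 222 nm two-state
estimate is supported; full spectrum deconvolution is out of scope.

## ITC model and fitting

The one-set-of-sites forward model uses the standard instrument-software
conventions. With cumulative injected volume Vi into cell volume V0:

    Mt_i = Mt0·(1 − Vi/2V0)        (cell species)
    Xt_i = Xt0·(Vi/V0)·(1 − Vi/2V0)  (titrant)

bound complex [MX] is the physical root of
x² − x(N·Mt + Xt + Kd) + N·Mt·Xt = 0, cumulative heat
Q_i = ΔH·V0·[MX]_i, and the differential heat carries the
displaced-volume correction
dQ_i = Q_i − Q_{i−1} + (dV_i/V0)(Q_i + Q_{i−1})/2, normalised per mole
of injectant (kJ/mol). Other dilution dialects exist; this one is
isolated in `simulate_isotherm` so an alternative is a one-function
change. Defaults mirror the experimental setup the package emulates:
200 µl cell, 18 × 2 µl injections 180 s apart, 25 °C.

Fitting is trust-region least squares over (N, log10 Kd, ΔH), default
start N = 1, c = 10, ΔH from the first injection, with a log-spaced
Kd multi-start (1 nM–100 µM) when the single start fails or leaves a
poor optimum. Standard errors come from the Gauss–Newton covariance
s²(JᵀJ)⁻¹ with the delta method for Kd. "No detectable binding" is
raised for: fewer than 6 injections, a flat isotherm (range < 2% of
scale), an isotherm without curvature (max second difference < 0.0035 ×
range — dilution-only declines measure near 0.002, the gentlest
fit-worthy transitions above 0.005), or a fitted Kd pinned at the upper
bound. c-values outside [1, 1000] warn but do not fail.

Derived quantities: ΔG = RT·ln(Kd·10⁻⁹) in kJ/mol at T = 298.15 K
default, −TΔS = ΔG − ΔH (an identity by construction, asserted on every
fit). Kd is stored in nM to match tabulation convention. Fold changes
are reported raw and rounded to the nearest integer.

## Synthetic data

The family generator emulates the architecture the pipeline targets: an
ordered, hydrophobic-biased DNA-binding-domain-like segment (first 40%
of the sequence) followed by a disordered tail biased to D/E/P/S/K/G
composition, two conserved tail blocks, and the motif planted at one
homologous tail position in round(prevalence·n_rows) rows. Rows derive
from a random ancestor by column-wise substitution at rate
1 − conservation_level (default 0.9) in conserved segments and 0.8
elsewhere; alignments are produced by construction (no aligner), with an
optional insertion block present in half the rows to exercise gap
mapping. Defaults (12 rows, 120 residues) are sized like a compact
ortholog family.

Palette construction gives the generator analytically known properties:
the tail palette contains no Y/F and no terminal hydrophobics
(L/I/M/V/F), the ordered palette no D/E, so chance motifs cannot arise
outside the planted block and planted classes cannot shadow one
another; the motif-free palette (no D/E/Y/F/L/I/M/V and no K/R
conflicts) supports exact false-positive-rate-zero checks. Planted
wildcard positions draw from an acid-enriched alphabet (D/E/A/S/G, no
K/R), so planted peptides always pass the pI filter. Every fixture
carries its ground truth (spans, classes, orientation, segment
boundaries, seed) and regenerates byte-identically from its seed.

What the generator does **not** emulate: tree-structured evolution
(rows are exchangeable, not phylogenetically correlated), indel
processes beyond the single optional block, compositional drift within
segments, and alignment error. Passing benchmarks therefore demonstrate
correctness of the scanning/aggregation machinery under known ground
truth, not recovery performance on real, phylogenetically structured
families.

Titration fixtures add seeded Gaussian noise to the forward model;
the benchmark noise level is 2% of the maximum heat, and the recovery
study uses 100 seeded replicates (median Kd error well inside 15%,
median N error inside 5%). CD series invert the two-state 222 nm formula
at requested helix fractions.

## Problem sizes

The shipped verification suite runs the scanner oracle on 10⁴ random
sequences of length ≤ 60, the profile oracle on 10³ random alignments,
the pI grid oracle on 10³ random peptides, the helix enumeration oracle
on peptides of length ≤ 10, and the ITC recovery study on 100
replicates; these sizes give stable medians and exhaustive coverage of
the span/quantile edge cases while keeping a full run in well under a
minute.

## Known limitations

- The built-in disorder scorer and the Lifson–Roig stand-in are
  composition/propensity models; they are not substitutes for trained
  predictors and are labelled as such wherever they appear.
- Conservation segmentation thresholds are declared defaults; region
  boundaries on real families are sensitive to them.
- The ITC model covers a single class of independent sites; competitive
  and two-site schemes, and baseline integration of raw power traces,
  are out of scope.
- No alignment construction: alignments are inputs (or generated by
  construction); nucleotide sequences are not supported.
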