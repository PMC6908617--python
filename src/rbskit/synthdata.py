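"""Seeded generators for every input the pipeline consumes.

Families emulate the architecture of the transcription-factor homolog
groups the pipeline is built for: an ordered, hydrophobic-biased
DNA-binding-domain-like segment followed by a disordered tail biased to
D/E/P/S/K composition, with conserved blocks and a binding motif planted
at a homologous tail location in a controllable fraction of rows.
Titration fixtures add seeded Gaussian noise to the one-set-of-sites
forward model; CD series invert the 222 nm two-state formula.  Every
fixture records its ground truth and its seed, and regeneration from the
same seed is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence as TSeq

import numpy as np

from .seqcore import Alignment, GappedRow, Sequence
from .motifscan import MotifPattern, compile_pattern, compute_pI
from .helix import CdReading, theta_coil, theta_helix
from .thermo import TitrationExperiment, simulate_isotherm

#: Residue palettes for the two composition regimes.
ORDERED_PALETTE = "LIVFAMWYTGC"
DISORDERED_PALETTE = "DEPSKGQNAST"

#: Palette free of every mandatory motif class ([ED]/[DE] anchors, [YF]
#: aromatic, terminal L/hydrophobics): sequences drawn from it can never
#: contain a motif of any class.
MOTIF_FREE_PALETTE = "GSTNQAHWC"

#: Wildcard fill used when planting motifs: acid-enriched so planted
#: peptides pass the pI < 4.5 filter, and free of K/R.
ACIDIC_WILDCARD = "DDEEAASG"


@dataclass
class FamilyFixture:
    """A synthetic ortholog family with full ground truth."""

    sequences: list[Sequence]
    alignment: Alignment
    planted: dict[str, tuple[int, int]]  # row id -> 1-based residue span
    motif_class: str
    orientation: str
    ordered_span: tuple[int, int]  # residue coords (gap-free fixture columns coincide)
    tail_span: tuple[int, int]
    conserved_blocks: list[tuple[int, int]]  # alignment column spans
    seed: int

    def ground_truth_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "motif_class": self.motif_class,
                "orientation": self.orientation,
                "planted": {k: list(v) for k, v in self.planted.items()},
                "ordered_span": list(self.ordered_span),
                "tail_span": list(self.tail_span),
                "conserved_blocks": [list(b) for b in self.conserved_blocks],
            },
            indent=2,
            sort_keys=True,
        )


def sample_motif_instance(pattern: MotifPattern, rng: np.random.Generator) -> str:
    """Draw one concrete expansion of a motif class.

    Wildcard runs get a uniformly drawn length and acid-enriched fills,
    so sampled peptides are guaranteed to pass the pI filter; fixed
    residue sets are sampled uniformly (basic residues are excluded from
    wildcards by construction).
    """
    alt = pattern.alternatives[int(rng.integers(len(pattern.alternatives)))]
    out = []
    for el in alt:
        k = int(rng.integers(el.min_repeat, el.max_repeat + 1))
        full_wildcard = len(el.residues) >= 18  # '.' or [^RK]
        for _ in range(k):
            if full_wildcard:
                out.append(ACIDIC_WILDCARD[int(rng.integers(len(ACIDIC_WILDCARD)))])
            else:
                choices = sorted(el.residues)
                out.append(choices[int(rng.integers(len(choices)))])
    peptide = "".join(out)
    assert compute_pI(peptide) < 4.5
    return peptide


def make_family(
    n_rows: int = 12,
    length: int = 120,
    motif_class: str = "RBS",
    prevalence: float = 1.0,
    conservation_level: float = 0.9,
    seed: int = 0,
    orientation: str = "forward",
    motif_free: bool = False,
    gap_block: bool = False,
) -> FamilyFixture:
    """Generate a synthetic ortholog family with a planted motif.

    Rows derive from a random ancestor by column-wise substitution: the
    ordered segment (first 40% of columns, hydrophobic palette) and two
    conserved tail blocks substitute at rate ``1 - conservation_level``;
    the rest of the disordered tail substitutes at a high background rate.
    The motif is planted at one homologous tail location in
    ``round(prevalence * n_rows)`` rows.  With ``motif_free`` the whole
    family is drawn from a palette lacking every mandatory motif residue
    class and nothing is planted.  ``gap_block`` inserts an insertion
    block present in half the rows to exercise coordinate mapping.
    """
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must be in [0, 1]")
    rng = np.random.default_rng(seed)
    pattern = compile_pattern(motif_class)

    ordered_len = int(round(0.4 * length))
    tail_len = length - ordered_len
    if pattern.max_span + 10 > tail_len:
        raise ValueError("motif (plus margin) longer than disordered tail")

    if motif_free:
        ordered_palette = tail_palette = MOTIF_FREE_PALETTE
    else:
        ordered_palette, tail_palette = ORDERED_PALETTE, DISORDERED_PALETTE

    def draw(palette: str, k: int) -> str:
        return "".join(palette[i] for i in rng.integers(len(palette), size=k))

    ancestor = draw(ordered_palette, ordered_len) + draw(tail_palette, tail_len)

    # Two conserved blocks inside the tail; the motif goes into the first.
    block_len = max(8, pattern.max_span + 2)
    b1_start = ordered_len + 5
    b2_start = length - block_len - 3
    conserved_blocks_res = [(b1_start + 1, b1_start + block_len),
                            (b2_start + 1, b2_start + block_len)]

    motif_instance = None if motif_free else sample_motif_instance(pattern, rng)
    motif_start = b1_start  # 0-based; homologous location for every carrier
    n_planted = 0 if motif_free else int(round(prevalence * n_rows))

    sub_rate_cons = 1.0 - conservation_level
    sub_rate_bg = 0.8

    rows: list[str] = []
    planted: dict[str, tuple[int, int]] = {}
    for r in range(n_rows):
        chars = list(ancestor)
        for i in range(length):
            in_ordered = i < ordered_len
            in_block = any(s - 1 <= i <= e - 1 for s, e in conserved_blocks_res)
            rate = sub_rate_cons if (in_ordered or in_block) else sub_rate_bg
            if rng.random() < rate:
                palette = ordered_palette if in_ordered else tail_palette
                chars[i] = palette[int(rng.integers(len(palette)))]
        row_id = f"SYN{r + 1:02d}"
        if r < n_planted:
            insert = motif_instance if orientation == "forward" else motif_instance[::-1]
            chars[motif_start : motif_start + len(insert)] = list(insert)
            planted[row_id] = (motif_start + 1, motif_start + len(insert))
        rows.append("".join(chars))

    # Optional insertion block: half the rows gain extra residues, the rest
    # a gap block, placed between the ordered segment and the first
    # conserved tail block.
    if gap_block:
        ins_len = 6
        ins_col = ordered_len + 2
        gapped_rows = []
        for r, row in enumerate(rows):
            if r % 2 == 0:
                piece = draw(tail_palette, ins_len)
            else:
                piece = "-" * ins_len
            gapped_rows.append(row[:ins_col] + piece + row[ins_col:])
        aligned = gapped_rows
        shift = ins_len
    else:
        aligned = rows
        shift = 0

    gapped = [GappedRow(f"SYN{r + 1:02d}", aligned[r]) for r in range(n_rows)]
    alignment = Alignment(gapped)
    sequences = [g.degap() for g in gapped]

    def res_to_col(span: tuple[int, int]) -> tuple[int, int]:
        lo, hi = span
        if lo - 1 >= ins_threshold():
            return lo + shift, hi + shift
        return lo, hi

    def ins_threshold() -> int:
        return ordered_len + 2

    conserved_blocks_cols = [res_to_col(b) for b in conserved_blocks_res]

    # Planted spans are residue coordinates; with a gap block, rows carrying
    # the insertion have their tail residues shifted by its length.
    if gap_block:
        shifted: dict[str, tuple[int, int]] = {}
        for rid, (lo, hi) in planted.items():
            r = int(rid[3:]) - 1
            d = ins_len if r % 2 == 0 else 0
            shifted[rid] = (lo + d, hi + d)
        planted = shifted

    return FamilyFixture(
        sequences=sequences,
        alignment=alignment,
        planted=planted,
        motif_class=motif_class,
        orientation=orientation,
        ordered_span=(1, ordered_len),
        tail_span=(ordered_len + 1, length),
        conserved_blocks=conserved_blocks_cols,
        seed=seed,
    )


@dataclass
class TitrationFixture:
    """A simulated titration with its generating parameters."""

    experiment: TitrationExperiment
    true_n: float
    true_kd_nM: float
    true_dH_kJ_per_mol: float
    noise_sigma: float
    seed: int


def make_titration(
    true_n: float = 0.95,
    true_kd_nM: float = 400.0,
    true_dH_kJ_per_mol: float = -40.0,
    experiment_template: TitrationExperiment | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> TitrationFixture:
    """Simulate a noisy one-set-of-sites titration.

    ``noise_sigma`` is the absolute Gaussian noise level on the normalized
    heats (kJ/mol of injectant); 0 reproduces the forward model exactly.
    """
    if noise_sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    template = experiment_template or TitrationExperiment()
    heats = simulate_isotherm(true_n, true_kd_nM, true_dH_kJ_per_mol, template)
    rng = np.random.default_rng(seed)
    noisy = heats + rng.normal(0.0, noise_sigma, size=heats.shape) if noise_sigma else heats
    experiment = TitrationExperiment(
        cell_volume_ul=template.cell_volume_ul,
        injection_volumes_ul=template.injection_volumes_ul,
        spacing_s=template.spacing_s,
        cell_concentration_uM=template.cell_concentration_uM,
        syringe_concentration_uM=template.syringe_concentration_uM,
        temperature_K=template.temperature_K,
        syringe_species=template.syringe_species,
        normalized_heats_kJ_per_mol=noisy,
    )
    return TitrationFixture(experiment, true_n, true_kd_nM, true_dH_kJ_per_mol, noise_sigma, seed)


def make_cd_series(
    helix_fractions: TSeq[float],
    tfe_levels: TSeq[float] | None = None,
    n: int = 29,
    temperature: float = 25.0,
    noise: float = 0.0,
    seed: int = 0,
) -> list[CdReading]:
    """CD 222 nm readings for a TFE co-solvent series.

    Ellipticities are obtained by inverting the two-state helix-fraction
    formula at each requested fraction, plus optional Gaussian noise.
    """
    fracs = np.asarray(helix_fractions, dtype=float)
    if ((fracs < 0) | (fracs > 1)).any():
        raise ValueError("helix fractions must be in [0, 1]")
    if tfe_levels is None:
        tfe_levels = np.linspace(0.0, 40.0, len(fracs))
    rng = np.random.default_rng(seed)
    tc = theta_coil(temperature)
    th = theta_helix(n)
    out = []
    for f, tfe in zip(fracs, tfe_levels):
        theta = f * (th - tc) + tc
        if noise:
            theta += rng.normal(0.0, noise)
        out.append(CdReading(theta222=theta, temperature=temperature, n=n, tfe=float(tfe)))
    return out
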