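"""RCD1-binding SLiM (RBS) pattern family, bidirectional scanning and filters.

The consensus RCD1-binding motif is ``[ED].{1,2}[^RK][YF].{1,4}[^RK][DE]L``:
an acidic anchor, a short spacer free of basic residues, a central aromatic,
a second basic-free spacer and an acidic-hydrophobic terminus.  Three
single-position variants and one expanded union pattern complete the family:

=========  ===========================================================
class      pattern
=========  ===========================================================
RBS        ``[ED].{1,2}[^RK][YF].{1,4}[^RK][DE]L``
RBS-V1     ``.{1,2}[^RK][YF].{1,4}[^RK][DE]L``       (acidic anchor lost)
RBS-V2     ``[ED].{1,2}[^RK][YF].{1,4}[^RK][DE][FIMV]``
RBS-V3     ``[ED].{1,2}[^RK][YF].{1,4}[^RK][DE].L``  (inserted residue)
EXPANDED   ``[ED].{1,2}[^RK][YF].{1,4}[^RK][DE]([LIVMF]|.L)``
=========  ===========================================================

Scanning reports every distinct residue span (start, end) admitting at
least one assignment of the variable-length wildcard runs; multiple
internal expansions of the same span collapse to a single match.  Reverse
scanning matches the pattern against the reversed residue string (no
complementation — these are proteins) and reports spans in original
coordinates, so a locus conserved in both directions yields two matches.

The discriminatory filters are a central aromatic residue (guaranteed by
the ``[YF]`` element) and an isoelectric point strictly below 4.5,
computed from a Henderson-Hasselbalch charge sum by bisection.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence as TSeq

from .seqcore import Sequence

CLASS_IDS = ("RBS", "RBS-V1", "RBS-V2", "RBS-V3", "EXPANDED")

# 'X' never matches any character class, including negated ones and wildcards:
# an unknown residue cannot be asserted to satisfy a constraint.
_ANY = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class Element:
    """One pattern element: a residue set with a (min, max) repeat count."""

    residues: frozenset[str]
    min_repeat: int = 1
    max_repeat: int = 1

    def regex(self) -> str:
        if self.residues == frozenset(_ANY):
            core = "[^X]"
        else:
            core = "[" + "".join(sorted(self.residues)) + "]"
        if (self.min_repeat, self.max_repeat) == (1, 1):
            return core
        return f"{core}{{{self.min_repeat},{self.max_repeat}}}"


def _set(chars: str) -> frozenset[str]:
    return frozenset(chars)


def _not(chars: str) -> frozenset[str]:
    return frozenset(_ANY - set(chars))


_CORE = (
    Element(_not("RK")),                  # no basic residue before the aromatic
    Element(_set("YF")),                  # central aromatic
    Element(frozenset(_ANY), 1, 4),       # spacer
    Element(_not("RK")),
    Element(_set("DE")),                  # acidic penultimate anchor
)

_DEFINITIONS: dict[str, tuple[Element, ...]] = {
    "RBS": (Element(_set("ED")), Element(frozenset(_ANY), 1, 2)) + _CORE + (Element(_set("L")),),
    "RBS-V1": (Element(frozenset(_ANY), 1, 2),) + _CORE + (Element(_set("L")),),
    "RBS-V2": (Element(_set("ED")), Element(frozenset(_ANY), 1, 2)) + _CORE + (Element(_set("FIMV")),),
    "RBS-V3": (Element(_set("ED")), Element(frozenset(_ANY), 1, 2)) + _CORE
    + (Element(frozenset(_ANY)), Element(_set("L"))),
}


@dataclass(frozen=True)
class MotifPattern:
    """A compiled SLiM pattern: ordered elements, or a union of alternatives."""

    class_id: str
    alternatives: tuple[tuple[Element, ...], ...]

    @property
    def elements(self) -> tuple[Element, ...]:
        if len(self.alternatives) != 1:
            raise ValueError(f"{self.class_id} is a union pattern; use .alternatives")
        return self.alternatives[0]

    @property
    def min_span(self) -> int:
        return min(sum(e.min_repeat for e in alt) for alt in self.alternatives)

    @property
    def max_span(self) -> int:
        return max(sum(e.max_repeat for e in alt) for alt in self.alternatives)

    def regex(self) -> str:
        alts = ["".join(e.regex() for e in alt) for alt in self.alternatives]
        if len(alts) == 1:
            return alts[0]
        return "|".join(f"(?:{a})" for a in alts)


def compile_pattern(class_id: str) -> MotifPattern:
    """Compile one of the five motif classes into a :class:`MotifPattern`."""
    if class_id in _DEFINITIONS:
        return MotifPattern(class_id, (_DEFINITIONS[class_id],))
    if class_id == "EXPANDED":
        head = (Element(_set("ED")), Element(frozenset(_ANY), 1, 2)) + _CORE
        return MotifPattern(
            "EXPANDED",
            (
                head + (Element(_set("FILMV")),),
                head + (Element(frozenset(_ANY)), Element(_set("L"))),
            ),
        )
    raise ValueError(f"unknown motif class {class_id!r}; expected one of {CLASS_IDS}")


@dataclass
class MotifMatch:
    """A located SLiM hit with its filter verdicts.

    ``span`` is 1-based inclusive in the original (forward) residue
    coordinates regardless of orientation; ``matched_peptide`` is the
    orientation-adjusted string the pattern actually matched (reversed
    relative to the forward subsequence for reverse-orientation hits).
    Filter verdicts are tri-state: None until the corresponding stage runs.
    """

    seq_id: str
    span: tuple[int, int]
    orientation: str  # "forward" | "reverse"
    class_id: str
    matched_peptide: str
    aromatic_ok: bool | None = None
    pI_value: float | None = None
    pI_ok: bool | None = None
    conserved_ok: bool | None = None


def scan(
    sequence: Sequence,
    pattern: MotifPattern,
    orientations: Iterable[str] = ("forward",),
) -> list[MotifMatch]:
    """Find every distinct residue span matching the pattern.

    For each start position and candidate span length within the pattern's
    span range, the substring is tested for a full match; this enumerates
    all wildcard-run assignments while collapsing internal expansions of
    the same span into one reported match.
    """
    orientations = tuple(orientations)
    bad = set(orientations) - {"forward", "reverse"}
    if bad:
        raise ValueError(f"unknown orientation(s) {sorted(bad)}")
    rx = re.compile(pattern.regex())
    n = len(sequence)
    out: list[MotifMatch] = []
    for orientation in orientations:
        text = sequence.residues if orientation == "forward" else sequence.residues[::-1]
        for start in range(n):
            for span_len in range(pattern.min_span, pattern.max_span + 1):
                end = start + span_len
                if end > n:
                    break
                if rx.fullmatch(text, start, end):
                    if orientation == "forward":
                        span = (start + 1, end)
                    else:
                        span = (n - end + 1, n - start)
                    out.append(
                        MotifMatch(
                            seq_id=sequence.id,
                            span=span,
                            orientation=orientation,
                            class_id=pattern.class_id,
                            matched_peptide=text[start:end],
                        )
                    )
    out.sort(key=lambda m: (m.span, m.orientation != "forward"))
    return out


# Classification precedence among variants, applied only to proteins
# without a consensus match.
_PRECEDENCE = ("RBS-V1", "RBS-V2", "RBS-V3")


def classify_protein(matches: TSeq[MotifMatch]) -> str:
    """Assign one variant label per protein.

    A protein with any consensus (RBS) match is labelled ``RBS``; variants
    are counted only in proteins without the consensus, with fixed
    precedence V1 > V2 > V3 on ties; otherwise ``none``.
    """
    ids = {m.seq_id for m in matches}
    if len(ids) > 1:
        raise ValueError(f"matches from multiple proteins: {sorted(ids)}")
    classes = {m.class_id for m in matches}
    if "RBS" in classes:
        return "RBS"
    for cls in _PRECEDENCE:
        if cls in classes:
            return cls
    return "none"


# ---------------------------------------------------------------------------
# Isoelectric point
# ---------------------------------------------------------------------------

#: EMBOSS pKa values for the ionizable groups considered.
EMBOSS_PKA: Mapping[str, float] = {
    "Nterm": 8.6,
    "Cterm": 3.6,
    "K": 10.8,
    "R": 12.5,
    "H": 6.5,
    "D": 3.9,
    "E": 4.1,
    "C": 8.5,
    "Y": 10.1,
}

_POSITIVE = ("Nterm", "K", "R", "H")
_NEGATIVE = ("Cterm", "D", "E", "C", "Y")


def net_charge(peptide: str, pH: float, pka: Mapping[str, float] = EMBOSS_PKA) -> float:
    """Henderson-Hasselbalch net charge of a free peptide at ``pH``."""
    if not peptide:
        raise ValueError("empty peptide")
    counts = {aa: peptide.count(aa) for aa in "KRHDECY"}
    charge = 0.0
    for group in _POSITIVE:
        n = 1 if group == "Nterm" else counts[group]
        if n:
            charge += n / (1.0 + 10.0 ** (pH - pka[group]))
    for group in _NEGATIVE:
        n = 1 if group == "Cterm" else counts[group]
        if n:
            charge -= n / (1.0 + 10.0 ** (pka[group] - pH))
    return charge


def compute_pI(peptide: str, pka: Mapping[str, float] = EMBOSS_PKA, tol: float = 1e-4) -> float:
    """Isoelectric point: the pH in [0, 14] where the net charge crosses zero.

    Found by bisection until ``|charge| < tol``; a peptide whose charge never
    changes sign on [0, 14] is clamped to the relevant boundary.
    """
    lo, hi = 0.0, 14.0
    if net_charge(peptide, lo, pka) <= 0:
        return lo
    if net_charge(peptide, hi, pka) >= 0:
        return hi
    pH = 7.0
    for _ in range(200):
        pH = 0.5 * (lo + hi)
        q = net_charge(peptide, pH, pka)
        # converge in both charge and pH so flat charge curves (e.g. very
        # basic peptides) still pin the crossing point precisely
        if abs(q) < tol and hi - lo < 1e-6:
            break
        if q > 0:
            lo = pH
        else:
            hi = pH
    return pH


PI_THRESHOLD = 4.5


def apply_filters(
    match: MotifMatch,
    pka: Mapping[str, float] = EMBOSS_PKA,
    pi_threshold: float = PI_THRESHOLD,
) -> MotifMatch:
    """Fill in the aromatic and pI filter verdicts of a match.

    The pI criterion is strict: a matched peptide at exactly the threshold
    fails. The central-aromatic check is re-verified on the matched peptide
    even though the ``[YF]`` element guarantees it for genuine matches.
    """
    pi = compute_pI(match.matched_peptide, pka)
    return replace(
        match,
        aromatic_ok=bool(set(match.matched_peptide) & {"Y", "F"}),
        pI_value=pi,
        pI_ok=pi < pi_threshold,
    )


# ---------------------------------------------------------------------------
# Per-group counting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupCounts:
    """Counts for one TF homology group, formatted ``with-motif/total``."""

    group: str
    consensus: int
    total: int
    variants: Mapping[str, int]

    @property
    def formatted(self) -> str:
        return f"{self.consensus}/{self.total}"


def count_table(families: Mapping[str, Mapping[str, str]]) -> list[GroupCounts]:
    """Tabulate per-group motif prevalence.

    Parameters
    ----------
    families : mapping
        ``{group name: {protein id: classification label}}`` with labels as
        produced by :func:`classify_protein`.

    Returns per group the consensus count out of the group size plus counts
    of each variant among consensus-negative proteins (so the sum of variant
    counts never exceeds total minus consensus).
    """
    out = []
    for group, labels in families.items():
        values = list(labels.values())
        consensus = sum(1 for v in values if v == "RBS")
        variants = {cls: sum(1 for v in values if v == cls) for cls in _PRECEDENCE}
        out.append(GroupCounts(group, consensus, len(values), variants))
    return out
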