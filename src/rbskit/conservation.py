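"""Alignment-column conservation, conserved-region segmentation and the
conservation filter separating binding-competent from non-binding motifs.

Identity scoring is the modal-residue fraction over non-gap rows per
column (percentage-identity style, no substitution-matrix weighting).
Conserved regions are maximal above-threshold runs, tolerant of short
sub-threshold interruptions, labelled left-to-right with a group prefix
in the style of the lettered blocks (A1..A9, B1..B6, ...) seen in family
architecture maps.  A motif locus is kept only when it is present at the
homologous alignment position in at least half of the family — a motif
occurring in a single homolog at a non-conserved position is the
signature of a non-binding match.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence as TSeq

from .seqcore import GAP, Alignment, map_region
from .motifscan import MotifMatch

#: Defaults for region segmentation and the conservation filter.
DEFAULT_THRESHOLD = 0.8
DEFAULT_MIN_LEN = 5
DEFAULT_MAX_GAP = 2
DEFAULT_WINDOW_SLACK = 3
DEFAULT_CONSERVED_FRACTION = 0.5


@dataclass
class ConservationTrack:
    """Per-column identity score in [0, 1] plus effective depth.

    ``score[i]`` is NaN (flagged undefined) where fewer than two rows have
    a residue in column ``i``.
    """

    scores: list[float]
    depths: list[int]

    def __len__(self) -> int:
        return len(self.scores)

    def defined(self, i: int) -> bool:
        return not math.isnan(self.scores[i])


@dataclass(frozen=True)
class ConservedRegion:
    label: str
    span: tuple[int, int]  # 1-based inclusive columns
    mean_score: float


def column_identity(alignment: Alignment) -> ConservationTrack:
    """Modal-residue fraction per column over non-gap rows."""
    scores: list[float] = []
    depths: list[int] = []
    for col in range(alignment.ncol):
        residues = [r.gapped[col] for r in alignment.rows if r.gapped[col] != GAP]
        depth = len(residues)
        depths.append(depth)
        if depth < 2:
            scores.append(float("nan"))
        else:
            modal = Counter(residues).most_common(1)[0][1]
            scores.append(modal / depth)
    return ConservationTrack(scores, depths)


def find_conserved_regions(
    track: ConservationTrack,
    threshold: float = DEFAULT_THRESHOLD,
    min_len: int = DEFAULT_MIN_LEN,
    max_gap: int = DEFAULT_MAX_GAP,
    prefix: str = "A",
) -> list[ConservedRegion]:
    """Segment a conservation track into labelled conserved regions.

    A region is a maximal run of above-threshold columns in which up to
    ``max_gap`` consecutive sub-threshold (or undefined) columns are
    tolerated; runs shorter than ``min_len`` columns are discarded.
    Regions always start and end on above-threshold columns.
    """
    above = [track.defined(i) and track.scores[i] >= threshold for i in range(len(track))]
    regions: list[tuple[int, int]] = []
    i = 0
    n = len(above)
    while i < n:
        if not above[i]:
            i += 1
            continue
        start = i
        end = i
        j = i + 1
        gap_run = 0
        while j < n:
            if above[j]:
                end = j
                gap_run = 0
            else:
                gap_run += 1
                if gap_run > max_gap:
                    break
            j += 1
        regions.append((start, end))
        i = end + 1
    out = []
    k = 0
    for start, end in regions:
        if end - start + 1 < min_len:
            continue
        k += 1
        span_scores = [track.scores[i] for i in range(start, end + 1) if track.defined(i)]
        out.append(
            ConservedRegion(
                label=f"{prefix}{k}",
                span=(start + 1, end + 1),
                mean_score=sum(span_scores) / len(span_scores),
            )
        )
    return out


@dataclass
class MotifLocus:
    """A cluster of motif matches at a homologous alignment location."""

    column_span: tuple[int, int]
    matches: list[MotifMatch]
    fraction: float
    conserved: bool


def motif_conservation(
    alignment: Alignment,
    matches: TSeq[MotifMatch],
    window_slack: int = DEFAULT_WINDOW_SLACK,
    conserved_fraction: float = DEFAULT_CONSERVED_FRACTION,
) -> list[MotifLocus]:
    """Cluster matches into loci and apply the conservation filter.

    Matches whose column spans overlap within ``window_slack`` columns form
    one locus.  The conserved fraction is the number of rows with a match
    in the locus window over the number of rows whose degapped sequence
    spans the window (fragment homologs that do not reach the window are
    excluded from the denominator).  A locus is conserved when the
    fraction is at least ``conserved_fraction``; each member match has its
    ``conserved_ok`` verdict filled in.
    """
    if not matches:
        return []
    spans = []
    for m in matches:
        cs = map_region(alignment, m.seq_id, m.span)
        spans.append((cs, m))
    spans.sort(key=lambda t: t[0])

    clusters: list[list[tuple[tuple[int, int], MotifMatch]]] = []
    for cs, m in spans:
        if clusters:
            prev_span = _cluster_span(clusters[-1])
            if cs[0] <= prev_span[1] + window_slack:
                clusters[-1].append((cs, m))
                continue
        clusters.append([(cs, m)])

    loci = []
    for cluster in clusters:
        lo, hi = _cluster_span(cluster)
        rows_with = {m.seq_id for _, m in cluster}
        covering = [r.id for r in alignment.rows if _covers(alignment, r.id, lo, hi)]
        denom = len(covering) if covering else len(alignment.rows)
        fraction = sum(1 for rid in covering if rid in rows_with) / denom
        verdict = fraction >= conserved_fraction
        members = []
        for _, m in cluster:
            m.conserved_ok = verdict
            members.append(m)
        loci.append(MotifLocus((lo, hi), members, fraction, verdict))
    return loci


def _cluster_span(cluster) -> tuple[int, int]:
    return min(cs[0] for cs, _ in cluster), max(cs[1] for cs, _ in cluster)


def _covers(alignment: Alignment, row_id: str, lo: int, hi: int) -> bool:
    """True when the row's degapped sequence extends across columns lo..hi."""
    cmap = alignment.coordinate_map(row_id)
    if cmap.nres == 0:
        return False
    first = cmap.to_column(1)
    last = cmap.to_column(cmap.nres)
    return first <= lo and last >= hi
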