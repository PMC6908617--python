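"""Lifson-Roig helix-coil model, hydrophobic-staple annotation and CD
helix-fraction estimation.

The helix-coil model assigns each residue a helix (h) or coil (c) state.
A conformation's statistical weight is the product of per-residue
weights: a residue in the interior of an h-run (h neighbours on both
sides) contributes its propagation weight ``w``; any other h residue
contributes the nucleation weight ``v``; coil residues contribute 1.
A residue counts as *helical* when it belongs to an h-run of length at
least three (the shortest run able to form one alpha-helical turn), so
dipeptides have identically zero helicity.

Per-residue helix probabilities are computed exactly by a dynamic
program over coil positions: the partition function factorises over
maximal h-runs (weight v^2 * prod(interior w), or v for a singleton),
and the probability that a given run is realised is the product of the
prefix partition function ending in coil before it, the run weight, and
the suffix partition function starting in coil after it, over the total
partition function.  This is algebraically the transfer-matrix partition
function, organised so that P(residue in run >= 3) comes out directly.

The shipped propagation weights order residues by intrinsic helix
propensity (Ala highest, Gly and Pro lowest); they parameterise a
documented stand-in for full helix-propensity predictors, not a
reproduction of any of them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .seqcore import Sequence

#: Lifson-Roig propagation weights (relative equilibrium constants for
#: extending a helix by one residue). Ordering follows host-guest helix
#: propensity scales: A > E,L,M > Q,R,K > I,F,D,W > S,H,T,V > N,C,Y > G >> P.
DEFAULT_W: Mapping[str, float] = {
    "A": 1.70, "E": 1.25, "L": 1.25, "M": 1.20, "Q": 1.10, "R": 1.05,
    "K": 1.00, "I": 0.95, "F": 0.90, "D": 0.85, "W": 0.85, "S": 0.75,
    "H": 0.75, "T": 0.70, "V": 0.70, "N": 0.65, "C": 0.60, "Y": 0.60,
    "G": 0.30, "P": 0.01,
}

#: Global nucleation weight (cost of starting a helix).
DEFAULT_V = 0.05

#: Weight assigned to unknown residues ('X'), with a warning.
NEUTRAL_W = 1.0


@dataclass
class HelixProfile:
    """Per-residue helix probability plus mean percent helicity."""

    peptide_id: str
    probabilities: np.ndarray

    @property
    def mean_helicity(self) -> float:
        """Mean per-residue helix probability, as a percentage."""
        return float(self.probabilities.mean() * 100.0)


def _weights(residues: str, w_table: Mapping[str, float]) -> np.ndarray:
    w = np.empty(len(residues))
    for i, aa in enumerate(residues):
        if aa in w_table:
            w[i] = w_table[aa]
        else:
            warnings.warn(f"no helix weight for residue {aa!r}; using neutral 1.0", stacklevel=3)
            w[i] = NEUTRAL_W
    if (w <= 0).any():
        raise ValueError("helix propagation weights must be positive")
    return w


def lr_helicity(
    peptide: Sequence,
    w_table: Mapping[str, float] = DEFAULT_W,
    v: float = DEFAULT_V,
) -> HelixProfile:
    """Exact per-residue helix probabilities under the Lifson-Roig model.

    Returns P(residue i is in an h-run of length >= 3) for every residue,
    computed from the exact partition function (no sampling, no
    truncation).  Peptides shorter than 3 residues get an all-zero
    profile.
    """
    if v <= 0:
        raise ValueError("nucleation weight v must be positive")
    n = len(peptide)
    if n < 3:
        return HelixProfile(peptide.id, np.zeros(n))
    w = _weights(peptide.residues, w_table)

    # run_weight[a, b] (0-based, a <= b): statistical weight of an exact
    # h-run a..b — boundary h residues carry v, interior residues carry w.
    run_weight = np.zeros((n, n))
    for a in range(n):
        run_weight[a, a] = v
        interior = 1.0
        for b in range(a + 1, n):
            run_weight[a, b] = v * v * interior
            interior *= w[b]

    # F[i] (stored at Fa[i + 1], i = -1..n): partition function of residues
    # 0..i with residue i coil; positions -1 and n are virtual coils.
    Fa = np.zeros(n + 2)
    Fa[0] = 1.0
    for j in range(n + 1):  # coil at position j (j == n virtual)
        total = Fa[j]  # previous coil at j-1, empty run between
        for k in range(-1, j - 1):  # previous coil at k, h-run k+1..j-1
            total += Fa[k + 1] * run_weight[k + 1, j - 1]
        Fa[j + 1] = total
    Z = Fa[n + 1]

    # B[j] (j = 0..n): partition function of residues j..n-1 with residue j
    # coil (j == n: empty suffix).
    Ba = np.zeros(n + 1)
    Ba[n] = 1.0
    for j in range(n - 1, -1, -1):
        total = Ba[j + 1]
        for m in range(j + 2, n + 1):  # next coil at m, h-run j+1..m-1
            total += Ba[m] * run_weight[j + 1, m - 1]
        Ba[j] = total

    prob = np.zeros(n)
    for a in range(n):
        for b in range(a + 2, n):  # h-runs of length >= 3
            tail = Ba[b + 1] if b + 1 <= n else 1.0
            p = Fa[a] * run_weight[a, b] * tail / Z
            prob[a : b + 1] += p
    return HelixProfile(peptide.id, prob)


# ---------------------------------------------------------------------------
# Hydrophobic staple / N-cap annotation
# ---------------------------------------------------------------------------

#: Hydrophobic residues able to form the N'/N4 staple pair.
STAPLE_HYDROPHOBIC = frozenset("LIFVM")

#: Capping-competent residues at the N-cap position.
NCAP_POLAR = frozenset("DENST")


@dataclass(frozen=True)
class StapleAnnotation:
    """N-cap geometry of a helix start.

    ``ncap_index`` is the first helical position (1-based); N' is the
    residue immediately before it and N4 the fourth helical residue
    (ncap + 4).  A hydrophobic staple is present when N' and N4 are both
    hydrophobic (L/I/F/V/M), stabilising the helix start by packing
    against each other and strengthening capping.
    """

    ncap_index: int
    nprime_index: int
    n4_index: int
    ncap_is_acidic: bool
    staple_present: bool


def annotate_staple(peptide: Sequence, helix_start: int) -> StapleAnnotation:
    """Annotate the N-cap / N' / N4 geometry at ``helix_start`` (1-based)."""
    n = len(peptide)
    if helix_start < 2 or helix_start + 4 > n:
        raise IndexError(
            f"helix_start {helix_start} leaves no room for N' and N4 in peptide of length {n}"
        )
    res = peptide.residues
    nprime = res[helix_start - 2]  # ncap - 1
    ncap = res[helix_start - 1]
    n4 = res[helix_start + 3]  # ncap + 4
    return StapleAnnotation(
        ncap_index=helix_start,
        nprime_index=helix_start - 1,
        n4_index=helix_start + 4,
        ncap_is_acidic=ncap in NCAP_POLAR,
        staple_present=nprime in STAPLE_HYDROPHOBIC and n4 in STAPLE_HYDROPHOBIC,
    )


# ---------------------------------------------------------------------------
# CD helix fraction at 222 nm
# ---------------------------------------------------------------------------

THETA_HELIX_INF = -39500.0  # deg cm^2 dmol^-1, infinite-length helix at 222 nm
CHAIN_LENGTH_CORRECTION = 2.57


@dataclass(frozen=True)
class CdReading:
    """One far-UV CD observation at 222 nm.

    theta222 is the mean residue ellipticity (deg cm^2 dmol^-1),
    temperature in deg C, n the peptide chain length, tfe the
    trifluoroethanol percentage (v/v) of the co-solvent series.
    """

    theta222: float
    temperature: float
    n: int
    tfe: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("chain length must be >= 2")
        if not 0.0 <= self.tfe <= 100.0:
            raise ValueError("TFE percentage must be in [0, 100]")


def theta_coil(temperature: float) -> float:
    """Random-coil 222 nm baseline (deg cm^2 dmol^-1) at ``temperature`` degC."""
    return 2220.0 - 53.0 * temperature


def theta_helix(n: int) -> float:
    """Full-helix 222 nm limit for a chain of ``n`` residues."""
    return THETA_HELIX_INF * (1.0 - CHAIN_LENGTH_CORRECTION / n)


def cd_fraction_helix(reading: CdReading) -> float:
    """Two-state helix fraction from the 222 nm mean residue ellipticity.

    fH = (theta222 - thetaC) / (thetaH(n) - thetaC), clamped to [0, 1],
    with thetaH(n) = -39500 * (1 - 2.57/n) and thetaC = 2220 - 53*T.
    """
    if reading.n < 3:
        raise ValueError("helix fraction needs chain length >= 3")
    tc = theta_coil(reading.temperature)
    th = theta_helix(reading.n)
    f = (reading.theta222 - tc) / (th - tc)
    return float(min(1.0, max(0.0, f)))
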