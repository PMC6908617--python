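"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a result by exhaustive enumeration or dense-grid
search, sharing no code path with the implementation it checks.
"""

from __future__ import annotations

import itertools
import re

import numpy as np

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_NOT_RK = "".join(sorted(set(STANDARD_AA) - set("RK")))

# Fixed (non-variable) regex pieces per motif class; wildcard runs are
# expanded explicitly by the oracle, so only fixed-width classes appear.
_PIECES = {
    "RBS": (["[ED]"], "L"),
    "RBS-V1": ([], "L"),
    "RBS-V2": (["[ED]"], "[FIMV]"),
    "RBS-V3": (["[ED]"], f"[{STANDARD_AA}][L]"),
}


def _expansions(class_id: str):
    """All fixed-length regexes for one motif class (wildcards expanded)."""
    any_aa = f"[{STANDARD_AA}]"
    not_rk = f"[{_NOT_RK}]"
    if class_id == "EXPANDED":
        for rx in _expansions("RBS-V2"):
            yield rx.replace("[FIMV]", "[FILMV]")
        yield from _expansions("RBS-V3")
        return
    head, tail = _PIECES[class_id]
    for a in (1, 2):
        for b in (1, 2, 3, 4):
            yield "".join(head) + any_aa * a + not_rk + "[YF]" + any_aa * b + not_rk + "[DE]" + tail


def scan_spans(residues: str, class_id: str) -> set[tuple[int, int]]:
    """All distinct 1-based spans matched by any wildcard expansion."""
    spans = set()
    for rx in _expansions(class_id):
        compiled = re.compile(f"(?=({rx}))")
        for m in compiled.finditer(residues):
            spans.add((m.start() + 1, m.start() + len(m.group(1))))
    return spans


def pi_grid(peptide: str, pka: dict, step: float = 1e-4) -> float:
    """Dense-grid isoelectric point under a Henderson-Hasselbalch sum."""
    counts = {aa: peptide.count(aa) for aa in "KRHDECY"}
    grid = np.arange(0.0, 14.0 + step, step)
    charge = np.zeros_like(grid)
    charge += 1.0 / (1.0 + 10.0 ** (grid - pka["Nterm"]))
    for aa in "KRH":
        if counts[aa]:
            charge += counts[aa] / (1.0 + 10.0 ** (grid - pka[aa]))
    charge -= 1.0 / (1.0 + 10.0 ** (pka["Cterm"] - grid))
    for aa in "DECY":
        if counts[aa]:
            charge -= counts[aa] / (1.0 + 10.0 ** (pka[aa] - grid))
    return float(grid[np.argmin(np.abs(charge))])


def quantile_sorted(values, q: float) -> float:
    """Linear-interpolation quantile from explicit order statistics."""
    xs = sorted(values)
    n = len(xs)
    h = (n - 1) * q
    lo = int(np.floor(h))
    hi = int(np.ceil(h))
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def lr_enumeration(residues: str, w_table, v: float) -> np.ndarray:
    """Exhaustive helix-coil state sum: P(residue in h-run >= 3)."""
    n = len(residues)
    w = [w_table[a] for a in residues]
    Z = 0.0
    num = np.zeros(n)
    for states in itertools.product((0, 1), repeat=n):
        weight = 1.0
        for i, s in enumerate(states):
            if s:
                left = states[i - 1] if i > 0 else 0
                right = states[i + 1] if i < n - 1 else 0
                weight *= w[i] if (left and right) else v
        Z += weight
        i = 0
        while i < n:
            if states[i]:
                j = i
                while j < n and states[j]:
                    j += 1
                if j - i >= 3:
                    num[i:j] += weight
                i = j
            else:
                i += 1
    return num / Z
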