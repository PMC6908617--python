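"""One-set-of-sites ITC forward model, dilution handling, nonlinear
fitting and derived binding thermodynamics.

The forward model is the standard single-class independent-sites
isotherm used by instrument fitting software.  After injection i the
displaced-volume-corrected totals in the cell are::

    Mt_i = Mt0 * (1 - Vi / (2 V0))
    Xt_i = Xt0 * (Vi / V0) * (1 - Vi / (2 V0))

with Vi the cumulative injected volume.  The bound-complex
concentration is the physical root of the binding quadratic with total
site concentration N*Mt, the cumulative heat is Q_i = dH * V0 * [MX]_i,
and the differential heat of injection i carries the displaced-volume
correction::

    dQ_i = Q_i - Q_{i-1} + (dV_i / V0) * (Q_i + Q_{i-1}) / 2

normalised per mole of injectant.  Fitting is trust-region least squares
on (N, log10 Kd, dH) with multi-start over log-spaced Kd; a flat
isotherm raises :class:`NoBindingError`, mirroring the "no detectable
binding" verdict of failed titrations.  Derived quantities follow
dG = R T ln(Kd [M]) and -T dS = dG - dH.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence as TSeq

import numpy as np
from scipy.optimize import least_squares

R_GAS = 8.314  # J mol^-1 K^-1

#: Default experiment geometry: 200 ul cell, 18 x 2 ul injections, 180 s apart.
DEFAULT_CELL_VOLUME_UL = 200.0
DEFAULT_SCHEDULE = (2.0,) * 18
DEFAULT_SPACING_S = 180.0
DEFAULT_TEMPERATURE_K = 298.15


class NoBindingError(RuntimeError):
    """Raised when an isotherm carries no recoverable binding signal (NB)."""


@dataclass
class TitrationExperiment:
    """An ITC titration: geometry, schedule, concentrations and heats.

    Volumes in ul, concentrations in uM, temperature in K.  Normalized
    heats are in kJ per mole of injectant.
    """

    cell_volume_ul: float = DEFAULT_CELL_VOLUME_UL
    injection_volumes_ul: tuple[float, ...] = DEFAULT_SCHEDULE
    spacing_s: float = DEFAULT_SPACING_S
    cell_concentration_uM: float = 20.0
    syringe_concentration_uM: float = 250.0
    temperature_K: float = DEFAULT_TEMPERATURE_K
    syringe_species: str = "RST"
    normalized_heats_kJ_per_mol: np.ndarray | None = None

    def __post_init__(self) -> None:
        dv = np.asarray(self.injection_volumes_ul, dtype=float)
        if (dv <= 0).any():
            raise ValueError("injection volumes must be positive")
        if dv.sum() >= self.cell_volume_ul:
            raise ValueError("total injected volume must stay below the cell volume")
        self.injection_volumes_ul = tuple(dv)
        if self.normalized_heats_kJ_per_mol is not None:
            self.normalized_heats_kJ_per_mol = np.asarray(
                self.normalized_heats_kJ_per_mol, dtype=float
            )
            if len(self.normalized_heats_kJ_per_mol) != len(dv):
                raise ValueError("one normalized heat per injection required")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes_ul)

    def molar_ratios(self) -> np.ndarray:
        """Syringe-species : cell-species molar ratio after each injection."""
        v0 = self.cell_volume_ul
        vi = np.cumsum(self.injection_volumes_ul)
        mt = self.cell_concentration_uM * (1 - vi / (2 * v0))
        xt = self.syringe_concentration_uM * (vi / v0) * (1 - vi / (2 * v0))
        return xt / mt


def _bound_complex(mt_uM: np.ndarray, xt_uM: np.ndarray, n_sites: float, kd_uM: float) -> np.ndarray:
    """Physical root of the single-site quadratic, in uM."""
    sites = n_sites * mt_uM
    b = sites + xt_uM + kd_uM
    disc = np.maximum(b * b - 4.0 * sites * xt_uM, 0.0)
    return 0.5 * (b - np.sqrt(disc))


def simulate_isotherm(
    n_sites: float,
    kd_nM: float,
    dH_kJ_per_mol: float,
    experiment: TitrationExperiment,
) -> np.ndarray:
    """Per-injection normalized heats (kJ/mol of injectant) for one set of sites."""
    if n_sites <= 0 or kd_nM <= 0:
        raise ValueError("N and Kd must be positive")
    v0 = experiment.cell_volume_ul
    dv = np.asarray(experiment.injection_volumes_ul)
    vi = np.cumsum(dv)
    mt = experiment.cell_concentration_uM * (1 - vi / (2 * v0))
    xt = experiment.syringe_concentration_uM * (vi / v0) * (1 - vi / (2 * v0))
    mx = _bound_complex(mt, xt, n_sites, kd_nM * 1e-3)  # uM

    # Cumulative heat in joules: dH [J/mol] * V0 [l] * [MX] [mol/l].
    q = dH_kJ_per_mol * 1e3 * (v0 * 1e-6) * (mx * 1e-6)
    q_prev = np.concatenate([[0.0], q[:-1]])
    dq = q - q_prev + (dv / v0) * (q + q_prev) / 2.0
    moles_injected = (dv * 1e-6) * (experiment.syringe_concentration_uM * 1e-6)
    return dq / moles_injected / 1e3  # kJ per mol of injectant


def subtract_dilution(
    raw_heats: TSeq[float],
    blank_heats: TSeq[float] | None = None,
    tail_k: int | None = None,
) -> np.ndarray:
    """Heat-of-dilution correction.

    Either subtract a blank titration of the same schedule element-wise,
    or subtract the mean of the last ``tail_k`` injections — the constant
    level the enthalpy change settles to once the cell is saturated.
    """
    raw = np.asarray(raw_heats, dtype=float)
    if (blank_heats is None) == (tail_k is None):
        raise ValueError("provide exactly one of blank_heats or tail_k")
    if blank_heats is not None:
        blank = np.asarray(blank_heats, dtype=float)
        if blank.shape != raw.shape:
            raise ValueError(
                f"blank schedule mismatch: {len(blank)} injections vs {len(raw)}"
            )
        return raw - blank
    if not 1 <= tail_k <= len(raw):
        raise ValueError("tail_k out of range")
    return raw - raw[-tail_k:].mean()


@dataclass
class BindingFit:
    """Fitted one-set-of-sites parameters with derived thermodynamics.

    Kd in nM to match the field's tabulation convention; energies in
    kJ/mol; dG = R T ln(Kd * 1e-9) and -T dS = dG - dH hold by
    construction.
    """

    n_sites: float
    kd_nM: float
    dH_kJ_per_mol: float
    temperature_K: float
    se_n: float = float("nan")
    se_kd_nM: float = float("nan")
    se_dH: float = float("nan")
    dG_kJ_per_mol: float = field(init=False)
    minus_TdS_kJ_per_mol: float = field(init=False)

    def __post_init__(self) -> None:
        if self.kd_nM <= 0:
            raise ValueError("Kd must be positive")
        self.dG_kJ_per_mol, self.minus_TdS_kJ_per_mol = derive_thermo(
            self.kd_nM, self.dH_kJ_per_mol, self.temperature_K
        )

    def c_value(self, cell_concentration_uM: float) -> float:
        return self.n_sites * cell_concentration_uM / (self.kd_nM * 1e-3)

    def as_dict(self) -> dict:
        return {
            "N": self.n_sites,
            "Kd_nM": self.kd_nM,
            "dH_kJ_per_mol": self.dH_kJ_per_mol,
            "dG_kJ_per_mol": self.dG_kJ_per_mol,
            "minus_TdS_kJ_per_mol": self.minus_TdS_kJ_per_mol,
            "se_N": self.se_n,
            "se_Kd_nM": self.se_kd_nM,
            "se_dH_kJ_per_mol": self.se_dH,
            "temperature_K": self.temperature_K,
        }


def derive_thermo(kd_nM: float, dH_kJ_per_mol: float, temperature_K: float = DEFAULT_TEMPERATURE_K) -> tuple[float, float]:
    """(dG, -T dS) in kJ/mol from Kd (nM) and dH (kJ/mol) at ``temperature_K``."""
    if kd_nM <= 0:
        raise ValueError("Kd must be positive")
    dG = R_GAS * temperature_K * np.log(kd_nM * 1e-9) / 1e3
    return float(dG), float(dG - dH_kJ_per_mol)


def fold_change(kd_a_nM: float, kd_b_nM: float) -> tuple[float, int]:
    """Affinity ratio Kd_a / Kd_b, raw and rounded to the nearest fold."""
    if kd_a_nM <= 0 or kd_b_nM <= 0:
        raise ValueError("Kd values must be positive")
    ratio = kd_a_nM / kd_b_nM
    return ratio, int(round(ratio))


def fit_one_set_of_sites(
    experiment: TitrationExperiment,
    c_range: tuple[float, float] = (1.0, 1000.0),
    min_informative: int = 6,
) -> BindingFit:
    """Least-squares fit of (N, Kd, dH) to an isotherm.

    Standard errors come from the Jacobian at the optimum.  When the
    single default start fails, a multi-start over log-spaced Kd values
    is attempted.  A flat isotherm (no curvature, no recoverable Kd)
    raises :class:`NoBindingError`.
    """
    heats = experiment.normalized_heats_kJ_per_mol
    if heats is None:
        raise ValueError("experiment carries no measured heats")
    if len(heats) < min_informative:
        raise NoBindingError(f"only {len(heats)} injections; need >= {min_informative}")

    span = float(np.max(heats) - np.min(heats))
    scale = float(np.max(np.abs(heats)))
    if scale == 0.0 or span < 0.02 * scale:
        raise NoBindingError("flat isotherm: no detectable binding")
    # A dilution-only signal declines essentially linearly; a binding
    # transition leaves second-difference structure.  Without it N, Kd and
    # dH are not separately identifiable.
    # Relative curvature sits near 0.002 for dilution-only declines and above
    # 0.005 even for weak (c ~ 0.5) binding transitions.
    curvature = float(np.max(np.abs(np.diff(heats, 2))))
    if curvature < 0.0035 * span:
        raise NoBindingError("isotherm carries no curvature: no detectable binding")

    def residuals(theta: np.ndarray) -> np.ndarray:
        n_sites, log10_kd, dh = theta
        model = simulate_isotherm(n_sites, 10.0 ** log10_kd, dh, experiment)
        return model - heats

    dh0 = float(heats[0])
    # Default start: stoichiometry 1, c-value 10 (Kd = Mt0 / 10), dH from the
    # first (near-saturating-excess) injection.
    kd0_nM = experiment.cell_concentration_uM * 1e3 / 10.0
    bounds = ([1e-3, -3.0, -1e4], [1e3, 9.0, 1e4])

    def solve(x0):
        return least_squares(
            residuals, x0, bounds=bounds, method="trf",
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )

    best = None
    try:
        res = solve(np.array([1.0, np.log10(kd0_nM), dh0]))
        if res.success:
            best = res
    except Exception:
        pass
    # Multi-start over log-spaced Kd when the single start fails or lands on
    # a clearly poor optimum.
    rms_floor = 0.05 * scale
    if best is None or np.sqrt(2 * best.cost / len(heats)) > rms_floor:
        for lk in np.linspace(0.0, 5.0, 6):  # 1 nM .. 100 uM
            try:
                res = solve(np.array([1.0, lk, dh0]))
            except Exception:
                continue
            if res.success and (best is None or res.cost < best.cost):
                best = res
    if best is None:
        raise NoBindingError("optimizer failed to converge from all starts")

    n_sites, log10_kd, dh = best.x
    kd_nM = 10.0 ** log10_kd
    if log10_kd > 8.5:
        raise NoBindingError("fitted Kd at upper bound: isotherm carries no curvature")

    c_val = n_sites * experiment.cell_concentration_uM / (kd_nM * 1e-3)
    if not c_range[0] <= c_val <= c_range[1]:
        warnings.warn(
            f"c-value {c_val:.3g} outside fittable range {c_range}; "
            "estimates may be unreliable",
            stacklevel=2,
        )

    # Covariance from J^T J at the optimum (Gauss-Newton approximation).
    m, p = best.jac.shape
    dof = max(m - p, 1)
    s2 = 2.0 * best.cost / dof
    try:
        cov = s2 * np.linalg.inv(best.jac.T @ best.jac)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        se_n, se_logkd, se_dh = se
        se_kd = kd_nM * np.log(10.0) * se_logkd  # delta method
    except np.linalg.LinAlgError:
        se_n = se_kd = se_dh = float("nan")

    return BindingFit(
        n_sites=float(n_sites),
        kd_nM=float(kd_nM),
        dH_kJ_per_mol=float(dh),
        temperature_K=experiment.temperature_K,
        se_n=float(se_n),
        se_kd_nM=float(se_kd),
        se_dH=float(se_dh),
    )
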