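"""One-site isothermal-titration-calorimetry isotherm: forward model and fit.

Each injection of titrant displaces an equal volume from the cell, so cell
concentrations follow the proportional-dilution recursion

    P_i = P_{i-1} (1 - v_i/V0)
    L_i = L_{i-1} (1 - v_i/V0) + L_syr v_i/V0

and the integrated heat of injection i is the change in moles of complex
in the cell (corrected for the complex carried out with the displaced
volume) times the molar binding enthalpy:

    q_i = V0 dH ( [PL]_i - [PL]_{i-1} (1 - v_i/V0) )

with [PL] from the exact 1:1 quadratic using n-scaled binding sites.  The
fit floats (n, Kd, dH); the shape parameter c = n P0 / Kd controls how
well the isotherm constrains Kd (reliable roughly for c in 1-1000).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .binding_core import fraction_bound
from .errors import DomainError, ValidationError

__all__ = [
    "R_GAS",
    "ITCExperiment",
    "ITCFitResult",
    "itc_heats",
    "itc_fit",
    "c_value",
    "derive_thermo",
]

R_GAS = 8.314  # J mol^-1 K^-1
J_PER_UCAL = 4.184e-6  # exactly, by definition of the calorie

# heat bookkeeping: V0 [uL] * conc [uM] * dH [kJ/mol]
#   = 1e-6 L * 1e-6 mol/L * 1e3 J/mol = 1e-9 J  ->  / 4.184e-6 J/ucal
_UCAL_FACTOR = 1e-9 / J_PER_UCAL  # ucal per (uL * uM * kJ/mol)

C_RELIABLE_LOW = 1.0
C_RELIABLE_HIGH = 1000.0
C_UNRELIABLE = 0.1


@dataclass
class ITCExperiment:
    """An ITC titration design, optionally with observed injection heats."""

    cell_volume: float  # uL
    cell_protein: float  # uM, before the first injection
    syringe_ligand: float  # uM
    injection_volumes: list[float]  # uL per injection
    heats: list[float] | None = None  # ucal per injection
    temperature: float = 303.15  # K

    def __post_init__(self) -> None:
        if self.cell_volume <= 0:
            raise ValidationError("cell_volume must be > 0")
        if self.cell_protein <= 0:
            raise ValidationError("cell_protein must be > 0")
        if any(v <= 0 for v in self.injection_volumes):
            raise ValidationError("all injection volumes must be > 0")
        if self.syringe_ligand <= self.cell_protein:
            raise ValidationError(
                "syringe_ligand must exceed cell_protein (titrant-excess design)"
            )
        if self.heats is not None and len(self.heats) != len(self.injection_volumes):
            raise ValidationError(
                f"{len(self.heats)} heats for {len(self.injection_volumes)} injections"
            )

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)


@dataclass
class ITCFitResult:
    """Fitted one-site parameters with derived thermodynamics."""

    n: float
    kd: float  # uM
    dh: float  # kJ/mol
    dg: float  # kJ/mol
    minus_tds: float  # kJ/mol
    n_stderr: float
    kd_stderr: float
    dh_stderr: float
    c_value: float
    first_injection_excluded: bool
    converged: bool
    reliable: bool
    warnings: list[str] = field(default_factory=list)


def itc_heats(experiment: ITCExperiment, n: float, kd: float, dh: float) -> np.ndarray:
    """Model integrated heats (ucal) for every injection of the design."""
    if not all(map(math.isfinite, (n, kd, dh))):
        raise DomainError("model parameters must be finite")
    if kd <= 0:
        raise DomainError(f"kd must be > 0, got {kd}")
    v0 = experiment.cell_volume
    p = experiment.cell_protein
    l = 0.0
    pl_prev = 0.0
    heats = np.empty(experiment.n_injections)
    for i, vi in enumerate(experiment.injection_volumes):
        d = vi / v0
        p *= 1.0 - d
        l = l * (1.0 - d) + experiment.syringe_ligand * d
        if p < 0 or l < 0:
            raise ValidationError("concentrations went negative during displacement")
        sites = n * p
        pl = fraction_bound(sites, l, kd) * sites if sites > 0 else 0.0
        heats[i] = v0 * dh * (pl - pl_prev * (1.0 - d)) * _UCAL_FACTOR
        pl_prev = pl
    return heats


def c_value(n: float, protein: float, kd: float) -> float:
    """Wiseman shape parameter c = n [P]0 / Kd (dimensionless)."""
    if kd <= 0:
        raise DomainError(f"kd must be > 0, got {kd}")
    return n * protein / kd


def derive_thermo(kd: float, dh: float, temperature: float) -> tuple[float, float]:
    """(dG, -TdS) in kJ/mol from Kd (uM) and dH (kJ/mol) at T (K).

    dG = RT ln(Kd / 1 M);  -TdS = dG - dH.
    """
    if kd <= 0:
        raise DomainError(f"kd must be > 0, got {kd}")
    if temperature <= 0:
        raise DomainError(f"temperature must be > 0, got {temperature}")
    dg = R_GAS * temperature * math.log(kd * 1e-6) / 1000.0
    return dg, dg - dh


def _init_guesses(experiment: ITCExperiment, heats: np.ndarray,
                  volumes: list[float]) -> tuple[float, float, float]:
    """Coarse initialisation: dH from the total heat assuming n = 1 and full
    saturation, Kd from a small log-spaced grid at those fixed (n, dH)."""
    v0 = experiment.cell_volume
    p0 = experiment.cell_protein
    total = float(np.sum(heats))
    dh0 = total / (v0 * p0 * _UCAL_FACTOR)
    if dh0 == 0:
        dh0 = -1.0
    best_kd, best_sse = p0, np.inf
    for kd in np.geomspace(1e-3, 1e4, 36):
        model = _model_subset(experiment, 1.0, kd, dh0)
        sse = float(np.sum((model - _observed(experiment)) ** 2))
        if sse < best_sse:
            best_sse, best_kd = sse, kd
    return 1.0, best_kd, dh0


def _observed(experiment: ITCExperiment) -> np.ndarray:
    return np.asarray(experiment.heats, dtype=float)


def _model_subset(experiment, n, kd, dh):
    return itc_heats(experiment, n, kd, dh)


def itc_fit(
    experiment: ITCExperiment,
    exclude_first: bool = True,
    fit_dilution_offset: bool = False,
) -> ITCFitResult:
    """Least-squares fit of (n, Kd, dH) to observed injection heats.

    The first injection (the small priming shot, diluted by diffusion
    across the syringe tip during equilibration) is excluded from the
    residual by default.  ``fit_dilution_offset`` adds a constant
    per-injection heat of dilution as a fourth parameter.
    """
    if experiment.heats is None:
        raise ValidationError("experiment has no observed heats to fit")
    if experiment.n_injections < 8:
        raise ValidationError("need >= 8 injections for a one-site fit")
    obs = _observed(experiment)
    mask = np.ones(experiment.n_injections, dtype=bool)
    if exclude_first:
        mask[0] = False

    n0, kd0, dh0 = _init_guesses(experiment, obs[mask], experiment.injection_volumes)
    params = lmfit.Parameters()
    params.add("n", value=n0, min=0.05, max=10.0)
    params.add("log_kd", value=math.log10(kd0), min=-4.0, max=6.0)
    params.add("dh", value=dh0)
    if fit_dilution_offset:
        params.add("q_dil", value=0.0)

    def residual(p):
        model = itc_heats(experiment, p["n"].value, 10.0 ** p["log_kd"].value,
                          p["dh"].value)
        if fit_dilution_offset:
            model = model + p["q_dil"].value * np.asarray(
                experiment.injection_volumes
            ) / experiment.injection_volumes[-1]
        return (model - obs)[mask]

    out = lmfit.minimize(residual, params, method="least_squares", max_nfev=5000)

    n = float(out.params["n"].value)
    kd = float(10.0 ** out.params["log_kd"].value)
    dh = float(out.params["dh"].value)
    log_kd_err = out.params["log_kd"].stderr
    kd_err = kd * math.log(10.0) * log_kd_err if log_kd_err is not None else float("nan")
    c = c_value(n, experiment.cell_protein, kd)
    dg, mtds = derive_thermo(kd, dh, experiment.temperature)

    warnings: list[str] = []
    reliable = True
    if not (C_RELIABLE_LOW <= c <= C_RELIABLE_HIGH):
        warnings.append(
            f"c = {c:.3g} outside the reliable window "
            f"[{C_RELIABLE_LOW:g}, {C_RELIABLE_HIGH:g}]; Kd poorly constrained"
        )
        reliable = False
    if c < C_UNRELIABLE:
        warnings.append("c < 0.1: isotherm is featureless, fit unreliable")
    if not out.success:
        warnings.append("optimizer did not report convergence")

    return ITCFitResult(
        n=n,
        kd=kd,
        dh=dh,
        dg=dg,
        minus_tds=mtds,
        n_stderr=float(out.params["n"].stderr or np.nan),
        kd_stderr=float(kd_err),
        dh_stderr=float(out.params["dh"].stderr or np.nan),
        c_value=c,
        first_injection_excluded=exclude_first,
        converged=bool(out.success),
        reliable=reliable,
        warnings=warnings,
    )
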