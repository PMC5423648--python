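"""Single-site binding with ligand depletion and the global shared-Kd fit.

At the protein concentrations used in protein-observed NMR titrations
(hundreds of micromolar) the bound ligand is a substantial fraction of the
total, so the hyperbolic isotherm is wrong and the exact 1:1 mass-balance
quadratic must be used:

    [PL] = (( [P]t + [L]t + Kd ) - sqrt(( [P]t + [L]t + Kd )^2
            - 4 [P]t [L]t)) / 2

The observed chemical-shift change of a residue in fast exchange is the
population-weighted average of its free and bound shifts,

    ddelta_obs = ddelta_max * [PL] / [P]t,

so a titration followed for many residues shares a single Kd while each
residue carries its own saturation response ddelta_max.  The global fit
minimises the summed squared residuals over (Kd, {ddelta_max,r}).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .errors import DegenerateDataError, DomainError, ValidationError

__all__ = [
    "ExchangeRegime",
    "PeakAssignment",
    "TitrationPoint",
    "TitrationSeries",
    "BindingFitResult",
    "fraction_bound",
    "predict_csp",
    "fit_global",
    "fit_single",
    "saturation_percent",
]

KD_MIN_UM = 1e-3
KD_MAX_UM = 1e5


class ExchangeRegime(str, enum.Enum):
    FAST = "fast"
    SLOW = "slow"
    UNKNOWN = "unknown"


@dataclass
class PeakAssignment:
    """One assigned amide cross-peak of a 2D 1H-15N correlation spectrum.

    ``state`` distinguishes the free- and bound-state peaks of a residue in
    slow exchange; fast-exchange spectra have a single ("free"-labelled)
    peak per residue that drifts with saturation.
    """

    residue_id: int
    residue_name: str
    delta_h: float  # 1H shift, ppm
    delta_n: float  # 15N shift, ppm
    intensity: float | None = None
    state: str = "free"

    def __post_init__(self) -> None:
        if self.intensity is not None and self.intensity < 0:
            raise ValidationError(
                f"peak {self.residue_name}{self.residue_id}: intensity must be >= 0"
            )


@dataclass
class TitrationPoint:
    """One point of a titration: the totals in the tube plus its peak list."""

    protein_total: float  # uM
    ligand_total: float  # uM
    peaks: list[PeakAssignment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.protein_total > 0):
            raise ValidationError("protein_total must be > 0")
        if self.ligand_total < 0:
            raise ValidationError("ligand_total must be >= 0")


@dataclass
class TitrationSeries:
    """An ordered ligand-into-protein titration.

    The first point is the ligand-free reference; ligand totals are
    non-decreasing from there.
    """

    points: list[TitrationPoint]
    temperature: float = 303.15  # K
    ligand_name: str = ""
    exchange_regime: ExchangeRegime = ExchangeRegime.UNKNOWN

    def __post_init__(self) -> None:
        if isinstance(self.exchange_regime, str):
            self.exchange_regime = ExchangeRegime(self.exchange_regime)
        self.validate()

    def validate(self) -> None:
        if not self.points:
            raise ValidationError("titration series has no points")
        ligand = [p.ligand_total for p in self.points]
        if ligand[0] != 0:
            raise ValidationError(
                f"first titration point must be ligand-free, got {ligand[0]} uM"
            )
        if any(b < a for a, b in zip(ligand, ligand[1:])):
            raise ValidationError(f"ligand schedule must be non-decreasing: {ligand}")

    @property
    def ligand_totals(self) -> np.ndarray:
        return np.array([p.ligand_total for p in self.points], dtype=float)

    @property
    def protein_totals(self) -> np.ndarray:
        return np.array([p.protein_total for p in self.points], dtype=float)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class BindingFitResult:
    """Shared Kd plus per-residue saturation responses from a global fit."""

    kd: float  # uM
    dmax_per_residue: dict[int, float]  # residue_id -> ppm
    kd_stderr: float
    dmax_stderr: dict[int, float]
    residuals_rms: float
    n_points_used: int
    converged: bool

    def __post_init__(self) -> None:
        if not (self.kd > 0):
            raise ValidationError("fitted kd must be > 0")


def _check_finite_nonneg(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DomainError(f"{name} must be finite, got {value!r}")
    if np.any(arr < 0):
        raise DomainError(f"{name} must be >= 0, got {value!r}")
    return arr


def fraction_bound(protein_total, ligand_total, kd):
    """Fraction of protein in complex, [PL]/[P]t, from the exact quadratic.

    Parameters are totals in uM; ``kd`` in uM.  Accepts scalars or arrays
    (broadcast).  Uses the quadratic root that keeps
    [PL] <= min([P]t, [L]t), written in the cancellation-free form
    2ab / (s + sqrt(s^2 - 4ab)) so weak-binding corners stay accurate.
    """
    p = _check_finite_nonneg("protein_total", protein_total)
    l = _check_finite_nonneg("ligand_total", ligand_total)
    k = _check_finite_nonneg("kd", kd)
    if np.any(p <= 0):
        raise DomainError(f"protein_total must be > 0, got {protein_total!r}")
    s = p + l + k
    disc = s * s - 4.0 * p * l
    disc = np.maximum(disc, 0.0)  # guard tiny negative round-off
    pl = np.where(l > 0, 2.0 * p * l / (s + np.sqrt(disc)), 0.0)
    f = pl / p
    out = np.clip(f, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def predict_csp(dmax, protein_total, ligand_total, kd):
    """Model CSP at a titration point: ddelta_max x fraction bound (ppm)."""
    d = _check_finite_nonneg("dmax", dmax)
    return d * fraction_bound(protein_total, ligand_total, kd)


def saturation_percent(protein_total, ligand_total, kd) -> float:
    """Percent of protein in the bound state: 100 x fraction_bound."""
    return 100.0 * fraction_bound(protein_total, ligand_total, kd)


def _kd_initial_guess(
    trajectories: dict[int, np.ndarray], series: TitrationSeries
) -> float:
    """Midpoint heuristic: the ligand total at which the largest trajectory
    reaches half of its final value, corrected for depletion (at half
    saturation roughly Kd ~ L_half - P/2).  Falls back to the protein total.
    """
    ligand = series.ligand_totals
    p0 = float(series.protein_totals[0])
    best = None
    best_span = 0.0
    for traj in trajectories.values():
        t = np.asarray(traj, dtype=float)
        ok = np.isfinite(t)
        if ok.sum() < 2:
            continue
        final = t[ok][-1]
        if final > best_span:
            best_span = final
            best = t
    if best is None or best_span <= 0:
        return p0
    half = 0.5 * best_span
    ok = np.isfinite(best)
    above = np.nonzero(ok & (best >= half))[0]
    if above.size == 0:
        return p0
    l_half = float(ligand[above[0]])
    guess = l_half - 0.5 * p0
    if not (KD_MIN_UM < guess < KD_MAX_UM):
        return p0
    return guess


def _prepare_trajectories(
    trajectories: dict[int, "np.typing.ArrayLike"],
    series: TitrationSeries,
    residue_subset=None,
) -> dict[int, np.ndarray]:
    series.validate()
    if residue_subset is not None:
        subset = set(residue_subset)
        trajectories = {r: t for r, t in trajectories.items() if r in subset}
    n_pts = len(series)
    prepared: dict[int, np.ndarray] = {}
    for rid, traj in trajectories.items():
        arr = np.asarray(traj, dtype=float)
        if arr.shape != (n_pts,):
            raise ValidationError(
                f"residue {rid}: trajectory has {arr.size} values for "
                f"{n_pts} titration points"
            )
        prepared[rid] = arr
    usable = np.concatenate([t[np.isfinite(t)] for t in prepared.values()]) if prepared else np.array([])
    if usable.size == 0 or np.all(usable == 0):
        raise DegenerateDataError(
            "trajectories are empty or all zero; no binding signal to fit"
        )
    return prepared


def fit_global(
    trajectories: dict[int, "np.typing.ArrayLike"],
    series: TitrationSeries,
    residue_subset=None,
    weights: dict[int, float] | None = None,
) -> BindingFitResult:
    """Fit one shared Kd and one ddelta_max per residue to CSP trajectories.

    Parameters
    ----------
    trajectories
        Map residue_id -> per-point combined CSP (ppm), aligned with
        ``series.points``; NaN marks broadened/missing points, which are
        dropped from the residual (never imputed).
    series
        The titration design providing [P]t and [L]t at each point.
    residue_subset
        Optional iterable of residue_ids to restrict the fit to.
    weights
        Optional per-residue residual weights (default: unweighted).

    Returns
    -------
    BindingFitResult with curvature-based standard errors.
    """
    prepared = _prepare_trajectories(trajectories, series, residue_subset)
    if len(prepared) < 1:
        raise ValidationError("no residues to fit")
    n_usable = int(sum(np.isfinite(t).sum() for t in prepared.values()))
    if len(series) < 4:
        raise ValidationError("need >= 4 titration points for a Kd fit")

    p_tot = series.protein_totals
    l_tot = series.ligand_totals
    rids = sorted(prepared)

    params = lmfit.Parameters()
    params.add("kd", value=_kd_initial_guess(prepared, series),
               min=KD_MIN_UM, max=KD_MAX_UM)
    for rid in rids:
        t = prepared[rid]
        start = float(np.nanmax(t)) if np.isfinite(t).any() else 0.0
        params.add(f"dmax_{rid}", value=max(start, 1e-6), min=0.0)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        f = fraction_bound(p_tot, l_tot, p["kd"].value)
        chunks = []
        for rid in rids:
            t = prepared[rid]
            ok = np.isfinite(t)
            w = 1.0 if weights is None else float(weights.get(rid, 1.0))
            chunks.append(w * (p[f"dmax_{rid}"].value * f[ok] - t[ok]))
        return np.concatenate(chunks)

    out = lmfit.minimize(residual, params, method="least_squares",
                         max_nfev=2000 * (len(rids) + 1))

    kd = float(out.params["kd"].value)
    kd_err = out.params["kd"].stderr
    dmax = {rid: float(out.params[f"dmax_{rid}"].value) for rid in rids}
    dmax_err = {
        rid: float(out.params[f"dmax_{rid}"].stderr or np.nan) for rid in rids
    }
    res = residual(out.params)
    at_bounds = kd <= KD_MIN_UM * 1.001 or kd >= KD_MAX_UM * 0.999
    return BindingFitResult(
        kd=kd,
        dmax_per_residue=dmax,
        kd_stderr=float(kd_err) if kd_err is not None else float("nan"),
        dmax_stderr=dmax_err,
        residuals_rms=float(np.sqrt(np.mean(res**2))),
        n_points_used=n_usable,
        converged=bool(out.success) and not at_bounds,
    )


def fit_single(trajectory, series: TitrationSeries) -> BindingFitResult:
    """One-residue Kd fit: the QC companion to :func:`fit_global`.

    A residue whose lone-fit Kd deviates more than ~3x from the global value
    usually reports a second event (secondary site, exchange contribution)
    and should be excluded from the global pool.
    """
    arr = np.asarray(trajectory, dtype=float)
    if np.isfinite(arr).sum() < 4:
        raise ValidationError("need >= 4 usable points for a single-residue fit")
    return fit_global({0: arr}, series)


def bootstrap_kd_stderr(
    trajectories: dict[int, "np.typing.ArrayLike"],
    series: TitrationSeries,
    n_boot: int = 200,
    seed: int = 0,
) -> float:
    """Residual-bootstrap standard error of the global Kd.

    Refits after resampling (with replacement) the residuals of the point
    estimate and adding them back onto the fitted model.  A seeded
    alternative to the curvature-based error for ill-conditioned fits.
    """
    base = fit_global(trajectories, series)
    prepared = _prepare_trajectories(trajectories, series)
    f = fraction_bound(series.protein_totals, series.ligand_totals, base.kd)
    model = {rid: base.dmax_per_residue[rid] * f for rid in prepared}
    resid = np.concatenate([
        (prepared[rid] - model[rid])[np.isfinite(prepared[rid])]
        for rid in prepared
    ])
    rng = np.random.default_rng(seed)
    kds = []
    for _ in range(n_boot):
        fake = {}
        for rid in prepared:
            t = prepared[rid].copy()
            ok = np.isfinite(t)
            t[ok] = model[rid][ok] + rng.choice(resid, size=int(ok.sum()))
            fake[rid] = t
        kds.append(fit_global(fake, series).kd)
    return float(np.std(kds, ddof=1))


def kd_deviates(single: BindingFitResult, global_fit: BindingFitResult,
                fold: float = 3.0) -> bool:
    """Flag a residue whose lone-fit Kd is > ``fold`` away from the global Kd."""
    ratio = single.kd / global_fit.kd
    return bool(max(ratio, 1.0 / ratio) > fold)
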