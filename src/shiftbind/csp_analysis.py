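"""Per-residue chemical-shift-perturbation profiles from titration peak lists.

The combined amide CSP uses the standard 15N-downweighted Euclidean norm

    ddelta = sqrt( ddelta_H^2 + (ddelta_N / 5)^2 )

(the factor 5 compensates the larger 15N shift range).  Profiles are
classified against the mean and mean + SD of the quantified residues, the
convention used to mark significant perturbations along the sequence.
Residues whose signals broaden beyond detection during the titration carry
no quantifiable endpoint CSP and are reported separately.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .binding_core import ExchangeRegime, TitrationSeries
from .errors import CapabilityError, DomainError, ValidationError

__all__ = [
    "N15_SCALE",
    "CSPClass",
    "CSPProfile",
    "HetNOERecord",
    "Trajectory",
    "SlowTrajectory",
    "combined_csp",
    "build_trajectories",
    "profile_from_trajectories",
    "classify_csp",
    "detect_broadened",
    "het_noe",
]

N15_SCALE = 5.0


class CSPClass(str, enum.Enum):
    BELOW_MEAN = "below_mean"
    ABOVE_MEAN = "above_mean"
    ABOVE_MEAN_PLUS_SD = "above_mean_plus_sd"


def combined_csp(delta_h_change, delta_n_change, *, n_scale: float = N15_SCALE):
    """Combined 1H/15N shift change in ppm (weighted Euclidean norm).

    ``n_scale`` overrides the 15N downweighting constant; the default of 5
    is the convention and should not normally be changed.
    """
    dh = np.asarray(delta_h_change, dtype=float)
    dn = np.asarray(delta_n_change, dtype=float)
    if not (np.all(np.isfinite(dh)) and np.all(np.isfinite(dn))):
        raise DomainError("shift changes must be finite")
    out = np.hypot(dh, dn / n_scale)
    return float(out) if out.ndim == 0 else out


@dataclass
class Trajectory:
    """Per-point (1H, 15N, intensity) track of one residue in fast exchange.

    NaN marks points where the peak could not be found within the matching
    gate (overlap, broadening, or genuine disappearance).
    """

    residue_id: int
    delta_h: np.ndarray
    delta_n: np.ndarray
    intensity: np.ndarray

    @property
    def csp(self) -> np.ndarray:
        """Combined CSP relative to the first (free-state) point; NaN at
        missing points."""
        return np.hypot(self.delta_h - self.delta_h[0],
                        (self.delta_n - self.delta_n[0]) / N15_SCALE)

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.delta_h)


@dataclass
class SlowTrajectory:
    """Free/bound peak intensities of one residue in slow exchange."""

    residue_id: int
    free_intensity: np.ndarray
    bound_intensity: np.ndarray
    free_position: tuple[float, float]  # (1H, 15N) ppm
    bound_position: tuple[float, float] | None

    @property
    def csp(self) -> float:
        """Endpoint CSP between the bound and free peak positions."""
        if self.bound_position is None:
            return float("nan")
        return combined_csp(self.bound_position[0] - self.free_position[0],
                            self.bound_position[1] - self.free_position[1])


@dataclass
class CSPProfile:
    """Endpoint CSPs with classification flags.

    ``per_residue`` holds quantified residues only; residues lost to
    exchange broadening are listed in ``broadened`` and excluded from the
    mean/SD, residues missing for other reasons in ``unassigned``.
    """

    per_residue: dict[int, float]
    mean: float = float("nan")
    sd: float = float("nan")
    class_map: dict[int, CSPClass] = field(default_factory=dict)
    broadened: set[int] = field(default_factory=set)
    unassigned: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.per_residue.values()):
            raise ValidationError("CSP values must be >= 0")
        overlap = self.broadened & set(self.per_residue)
        if overlap:
            raise ValidationError(
                f"residues {sorted(overlap)} are both quantified and broadened"
            )


def _match_peaks(prev_pos: dict[int, tuple[float, float]], peaks, max_jump: float):
    """Assign current peaks to tracked residues by minimum total combined-shift
    displacement (optimal assignment), gated at ``max_jump`` per residue."""
    rids = list(prev_pos)
    if not rids or not peaks:
        return {}
    cost = np.empty((len(rids), len(peaks)))
    for i, rid in enumerate(rids):
        h0, n0 = prev_pos[rid]
        for j, pk in enumerate(peaks):
            cost[i, j] = combined_csp(pk.delta_h - h0, pk.delta_n - n0)
    # forbid over-gate matches but keep the matrix feasible
    big = 1e6
    gated = np.where(cost <= max_jump, cost, big)
    rows, cols = linear_sum_assignment(gated)
    return {rids[i]: peaks[j] for i, j in zip(rows, cols) if gated[i, j] < big}


def _check_duplicates(peaks) -> None:
    seen = set()
    for pk in peaks:
        key = (pk.residue_id, pk.state)
        if key in seen:
            raise ValidationError(
                f"duplicate residue {pk.residue_id} (state {pk.state!r}) in peak list"
            )
        seen.add(key)


def build_trajectories(series: TitrationSeries, max_jump: float = 0.05):
    """Track each residue's peak through the titration.

    Fast exchange: assignments are carried point-to-point by optimal
    nearest-neighbour matching in combined-shift distance, gated by
    ``max_jump`` (ppm); an unmatched residue is marked missing at that
    point (NaN) and matching resumes from its last known position.
    Returns ``dict residue_id -> Trajectory``.

    Slow exchange: each residue keeps fixed free/bound positions and the
    two peaks exchange intensity; per-state intensities are reported
    instead of drifting shifts.  Returns ``dict residue_id ->
    SlowTrajectory``.
    """
    for point in series.points:
        _check_duplicates(point.peaks)
    if series.exchange_regime is ExchangeRegime.SLOW:
        return _build_slow(series)
    return _build_fast(series, max_jump)


def _build_fast(series: TitrationSeries, max_jump: float):
    first = series.points[0].peaks
    n_pts = len(series)
    trajs = {
        pk.residue_id: Trajectory(
            residue_id=pk.residue_id,
            delta_h=np.full(n_pts, np.nan),
            delta_n=np.full(n_pts, np.nan),
            intensity=np.full(n_pts, np.nan),
        )
        for pk in first
    }
    pos = {}
    for pk in first:
        t = trajs[pk.residue_id]
        t.delta_h[0], t.delta_n[0] = pk.delta_h, pk.delta_n
        t.intensity[0] = np.nan if pk.intensity is None else pk.intensity
        pos[pk.residue_id] = (pk.delta_h, pk.delta_n)
    for i, point in enumerate(series.points[1:], start=1):
        matched = _match_peaks(pos, point.peaks, max_jump)
        for rid, pk in matched.items():
            t = trajs[rid]
            t.delta_h[i], t.delta_n[i] = pk.delta_h, pk.delta_n
            t.intensity[i] = np.nan if pk.intensity is None else pk.intensity
            pos[rid] = (pk.delta_h, pk.delta_n)
    return trajs


def _build_slow(series: TitrationSeries):
    n_pts = len(series)
    first = {pk.residue_id: pk for pk in series.points[0].peaks}
    last_bound = {
        pk.residue_id: pk
        for pk in series.points[-1].peaks
        if pk.state == "bound"
    }
    out = {}
    for rid, pk0 in first.items():
        free_i = np.zeros(n_pts)
        bound_i = np.zeros(n_pts)
        for i, point in enumerate(series.points):
            for pk in point.peaks:
                if pk.residue_id != rid:
                    continue
                val = 0.0 if pk.intensity is None else pk.intensity
                if pk.state == "bound":
                    bound_i[i] += val
                else:
                    free_i[i] += val
        bpk = last_bound.get(rid)
        out[rid] = SlowTrajectory(
            residue_id=rid,
            free_intensity=free_i,
            bound_intensity=bound_i,
            free_position=(pk0.delta_h, pk0.delta_n),
            bound_position=None if bpk is None else (bpk.delta_h, bpk.delta_n),
        )
    return out


def profile_from_trajectories(
    trajectories: dict[int, Trajectory],
    broadened: set[int] | None = None,
) -> CSPProfile:
    """Endpoint CSP profile (last vs first titration point) from fast-exchange
    trajectories.  Residues in ``broadened`` (or with no usable endpoint) are
    excluded from the quantified map."""
    broadened = set(broadened or ())
    per_residue: dict[int, float] = {}
    unassigned: set[int] = set()
    for rid, traj in trajectories.items():
        if rid in broadened:
            continue
        csp = traj.csp
        ok = np.isfinite(csp)
        if not ok.any() or not np.isfinite(csp[-1]):
            # fall back to the last observable point
            if ok.any():
                per_residue[rid] = float(csp[ok][-1])
            else:
                unassigned.add(rid)
            continue
        per_residue[rid] = float(csp[-1])
    return CSPProfile(per_residue=per_residue, broadened=broadened,
                      unassigned=unassigned)


def classify_csp(profile: CSPProfile) -> CSPProfile:
    """Set mean, SD and per-residue classes on a profile.

    Mean and sample SD are computed over quantified residues only (the
    broadened set never contributes).  Classes use inclusive thresholds:
    ddelta >= mean is "above mean", ddelta >= mean + SD additionally
    "above mean + SD"; the classes are nested by construction.
    """
    if not profile.per_residue:
        raise ValidationError("cannot classify an empty CSP profile")
    values = np.array(list(profile.per_residue.values()))
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    if sd < 1e-12 * max(mean, 1.0):  # identical values up to round-off
        sd = 0.0
    class_map = {}
    for rid, v in profile.per_residue.items():
        if v >= mean + sd:
            class_map[rid] = CSPClass.ABOVE_MEAN_PLUS_SD
        elif v >= mean:
            class_map[rid] = CSPClass.ABOVE_MEAN
        else:
            class_map[rid] = CSPClass.BELOW_MEAN
    profile.mean = mean
    profile.sd = sd
    profile.class_map = class_map
    return profile


def detect_broadened(
    series: TitrationSeries,
    alpha: float = 0.1,
    max_jump: float = 0.05,
) -> dict[int, int]:
    """Residues whose signals broaden beyond detection during the titration.

    Intensities are first normalised to the median intensity trend over all
    residues at each point, which absorbs global effects (dilution,
    receiver-gain changes).  A residue is flagged once its normalised
    intensity drops below ``alpha`` times its own first-point value — or its
    peak disappears outright — and the earliest such point index is
    recorded.  Returns ``dict residue_id -> point index``.
    """
    trajs = build_trajectories(series, max_jump=max_jump)
    if not trajs:
        return {}
    some = next(iter(trajs.values()))
    if isinstance(some, SlowTrajectory):
        raise CapabilityError(
            "broadening detection expects fast-exchange trajectories"
        )
    if all(not np.isfinite(t.intensity).any() for t in trajs.values()):
        raise CapabilityError(
            "peak lists carry no intensities; use shift-only analysis "
            "(build_trajectories / profile_from_trajectories)"
        )
    n_pts = len(series)
    rel = {}
    for rid, t in trajs.items():
        i0 = t.intensity[0]
        if not np.isfinite(i0) or i0 <= 0:
            continue
        r = t.intensity / i0
        r[~np.isfinite(r)] = 0.0  # vanished peak = zero intensity
        rel[rid] = r
    flagged: dict[int, int] = {}
    stack = np.array(list(rel.values()))
    trend = np.nanmedian(np.where(stack > 0, stack, np.nan), axis=0)
    trend = np.where(np.isfinite(trend) & (trend > 0), trend, 1.0)
    for rid, r in rel.items():
        norm = r / trend
        below = np.nonzero(norm < alpha)[0]
        below = below[below > 0]
        if below.size:
            flagged[rid] = int(below[0])
    return flagged


@dataclass
class HetNOERecord:
    """Steady-state {1H}-15N NOE of one residue: I_sat / I_ref."""

    residue_id: int
    i_sat: float
    i_ref: float
    noe: float
    noe_err: float


def het_noe(
    sat: dict[int, float],
    ref: dict[int, float],
    noise_sd: float,
) -> list[HetNOERecord]:
    """Heteronuclear NOE ratios with propagated spectral-noise errors.

    noe = I_sat/I_ref;  sigma_noe = |noe| sqrt((s/I_sat)^2 + (s/I_ref)^2)
    where ``noise_sd`` is the spectral noise standard deviation shared by
    the interleaved saturated/reference pair.
    """
    if set(sat) != set(ref):
        raise ValidationError(
            f"saturated/reference residue sets differ: "
            f"{sorted(set(sat) ^ set(ref))}"
        )
    records = []
    for rid in sorted(sat):
        i_sat, i_ref = float(sat[rid]), float(ref[rid])
        if i_ref <= 0:
            raise DomainError(f"residue {rid}: reference intensity must be > 0")
        noe = i_sat / i_ref
        if i_sat == 0:
            err = noise_sd / i_ref
        else:
            err = abs(noe) * math.sqrt(
                (noise_sd / i_sat) ** 2 + (noise_sd / i_ref) ** 2
            )
        records.append(HetNOERecord(rid, i_sat, i_ref, noe, err))
    return records
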