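import numpy as np
import pytest
from hypothesis import settings

from shiftbind.binding_core import (
    ExchangeRegime,
    PeakAssignment,
    TitrationPoint,
    TitrationSeries,
)
from shiftbind.synthetic_data import SimulationConfig, simulate_fast_exchange

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")


def mass_balance_fraction_bound(p_t: float, l_t: float, kd: float) -> float:
    """Independent oracle: solve the two mass-balance equations iteratively
    for the free-ligand concentration, then form [PL]/[P]t.  Never uses the
    closed-form quadratic."""
    from scipy.optimize import brentq

    if l_t == 0:
        return 0.0
    if kd == 0:
        return min(p_t, l_t) / p_t

    def excess_ligand(l_free):
        return l_free + p_t * l_free / (kd + l_free) - l_t

    l_free = brentq(excess_ligand, 0.0, l_t, xtol=1e-16, rtol=1e-15)
    return (p_t * l_free / (kd + l_free)) / p_t


def series_from_schedule(protein_total, schedule, **kwargs) -> TitrationSeries:
    """Bare titration series (no peaks) for trajectory-level fitting tests."""
    points = [TitrationPoint(protein_total, float(l)) for l in schedule]
    return TitrationSeries(points, **kwargs)


def make_peak_series(positions, protein_total=250.0, schedule=None,
                     intensities=None) -> TitrationSeries:
    """Series built from explicit per-point peak positions.

    ``positions``: list over points of dict residue_id -> (dH ppm, dN ppm).
    Only the first point's residue ids are used as assignments; later points
    keep the ids purely as bookkeeping (tracking must not rely on them).
    """
    schedule = schedule if schedule is not None else list(range(len(positions)))
    points = []
    for i, (lig, pos) in enumerate(zip(schedule, positions)):
        peaks = []
        for rid, (h, n) in pos.items():
            inten = None if intensities is None else intensities[i].get(rid)
            peaks.append(PeakAssignment(rid, "X", h, n, inten))
        points.append(TitrationPoint(protein_total, float(lig), peaks))
    return TitrationSeries(points, exchange_regime=ExchangeRegime.FAST)


@pytest.fixture
def noiseless_coa_series() -> TitrationSeries:
    """Noiseless fast-exchange titration at the cofactor design (Kd 28 uM,
    250 uM protein, schedule to 1.75 mM)."""
    cfg = SimulationConfig(seed=11, shift_noise_sd=(0.0, 0.0),
                           intensity_noise_cv=0.0)
    return simulate_fast_exchange(cfg)


@pytest.fixture
def toy_pdb(tmp_path):
    """Three-residue poly-ALA PDB written from scratch."""
    lines = []
    serial = 1
    for resseq in (25, 26, 27):
        for name, elem in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
            x, y, z = resseq * 1.0, serial * 0.1, 0.0
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s} ALA A{resseq:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {elem:>2s}"
            )
            serial += 1
    lines.append("END")
    path = tmp_path / "toy.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path
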