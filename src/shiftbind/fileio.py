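"""Readers and writers for the text formats the pipeline touches.

* Sparky-style peak lists (.list): whitespace-delimited ``Assignment w1 w2
  [Height]`` with w1 = 15N and w2 = 1H (ppm).  Assignments look like
  ``D26N-H``; bound-state peaks of a slow-exchange pair are written with a
  ``b`` suffix (``D26N-Hb``), a package convention since the Sparky label
  itself cannot carry the state.
* Titration manifest CSV: one row per point with totals and the path of
  that point's peak list.
* ITC CSV: a ``# key=value`` metadata block followed by
  ``injection_index,volume_uL,heat_ucal`` rows (empty heats = design-only).
* PDB annotation: per-residue values written into the B-factor column.

All units at these boundaries are uM, ppm, uL, ucal and kelvin.
"""

from __future__ import annotations

import csv
import json
import re
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser, PDBIO

from .binding_core import (
    BindingFitResult,
    ExchangeRegime,
    PeakAssignment,
    TitrationPoint,
    TitrationSeries,
)
from .csp_analysis import CSPProfile
from .errors import DomainError, ValidationError
from .itc_model import ITCExperiment, ITCFitResult

__all__ = [
    "read_sparky_peaklist",
    "write_sparky_peaklist",
    "read_titration",
    "write_titration",
    "read_itc_csv",
    "write_itc_csv",
    "annotate_pdb",
    "write_fit_json",
    "write_csp_csv",
]

_ASSIGNMENT_RE = re.compile(r"^([A-Za-z])(\d+)N-H(b?)$")

BROADENED_SENTINEL = -1.00  # B-factor value marking broadened residues


def _parse_assignment(token: str, lineno: int) -> tuple[str, int, str]:
    m = _ASSIGNMENT_RE.match(token)
    if not m:
        raise ValidationError(
            f"line {lineno}: unparseable assignment {token!r} "
            f"(expected e.g. D26N-H)"
        )
    name, rid, bound = m.groups()
    return name.upper(), int(rid), "bound" if bound else "free"


def read_sparky_peaklist(path) -> list[PeakAssignment]:
    """Parse a Sparky peak list into assigned peaks.

    Comment lines (#) and the conventional ``Assignment w1 w2`` header are
    skipped.  If the w1/w2 columns look swapped (w1 in the amide 1H window
    5-12 ppm and w2 in the 15N window 100-135 ppm) a warning is emitted and
    the axes are corrected.
    """
    peaks: list[PeakAssignment] = []
    seen: set[tuple[int, str]] = set()
    w1s, w2s = [], []
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        txt = line.strip()
        if not txt or txt.startswith("#"):
            continue
        cols = txt.split()
        if cols[0].lower() == "assignment":
            continue
        if len(cols) not in (3, 4):
            raise ValidationError(f"line {lineno}: expected 3 or 4 columns, got {len(cols)}")
        name, rid, state = _parse_assignment(cols[0], lineno)
        try:
            w1, w2 = float(cols[1]), float(cols[2])
            height = float(cols[3]) if len(cols) == 4 else None
        except ValueError as exc:
            raise ValidationError(f"line {lineno}: bad numeric field ({exc})") from None
        key = (rid, state)
        if key in seen:
            raise ValidationError(
                f"line {lineno}: duplicate residue {rid} (state {state!r})"
            )
        seen.add(key)
        w1s.append(w1)
        w2s.append(w2)
        rows.append((name, rid, state, w1, w2, height))
    if rows:
        w1a, w2a = np.array(w1s), np.array(w2s)
        w1_looks_h = np.median(w1a) < 20
        w2_looks_n = np.median(w2a) > 50
        if w1_looks_h and w2_looks_n:
            warnings.warn(
                f"{path}: w1/w2 axis order looks swapped "
                f"(w1 median {np.median(w1a):.1f} ppm in the 1H window); "
                f"swapping axes", stacklevel=2)
            rows = [(n, r, s, w2, w1, h) for (n, r, s, w1, w2, h) in rows]
    for name, rid, state, w1, w2, height in rows:
        peaks.append(PeakAssignment(rid, name, delta_h=w2, delta_n=w1,
                                    intensity=height, state=state))
    return peaks


def write_sparky_peaklist(peaks: list[PeakAssignment], path) -> None:
    lines = [f"{'Assignment':>14} {'w1':>10} {'w2':>10} {'Height':>14}"]
    for pk in peaks:
        suffix = "b" if pk.state == "bound" else ""
        label = f"{pk.residue_name}{pk.residue_id}N-H{suffix}"
        height = "" if pk.intensity is None else f"{pk.intensity:14.1f}"
        lines.append(f"{label:>14} {pk.delta_n:10.3f} {pk.delta_h:10.4f} {height}")
    Path(path).write_text("\n".join(lines) + "\n")


_MANIFEST_FIELDS = ["point_index", "ligand_total_uM", "protein_total_uM",
                    "peaklist_path", "temperature_K"]


def write_titration(series: TitrationSeries, outdir) -> Path:
    """Write one peak list per titration point plus a manifest CSV.
    Returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.csv"
    with manifest.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_MANIFEST_FIELDS)
        writer.writeheader()
        for i, point in enumerate(series.points):
            name = f"point_{i:02d}.list"
            write_sparky_peaklist(point.peaks, outdir / name)
            writer.writerow({
                "point_index": i,
                "ligand_total_uM": point.ligand_total,
                "protein_total_uM": point.protein_total,
                "peaklist_path": name,
                "temperature_K": series.temperature,
            })
    return manifest


def read_titration(manifest_path, exchange_regime="unknown",
                   ligand_name: str = "") -> TitrationSeries:
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    points = []
    temperature = 303.15
    with manifest_path.open() as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        raise ValidationError(f"{manifest_path}: empty manifest")
    for expected, row in enumerate(rows):
        missing = [k for k in _MANIFEST_FIELDS if row.get(k) in (None, "")]
        if missing:
            raise ValidationError(f"{manifest_path}: missing fields {missing}")
        if int(row["point_index"]) != expected:
            raise ValidationError(
                f"{manifest_path}: point_index must be contiguous from 0"
            )
        peak_path = base / row["peaklist_path"]
        if not peak_path.exists():
            raise ValidationError(f"{manifest_path}: peak list {peak_path} not found")
        points.append(TitrationPoint(
            protein_total=float(row["protein_total_uM"]),
            ligand_total=float(row["ligand_total_uM"]),
            peaks=read_sparky_peaklist(peak_path),
        ))
        temperature = float(row["temperature_K"])
    return TitrationSeries(points, temperature=temperature,
                           ligand_name=ligand_name,
                           exchange_regime=ExchangeRegime(exchange_regime))


_ITC_META_KEYS = ["cell_volume_uL", "cell_protein_uM", "syringe_ligand_uM",
                  "temperature_K"]


def write_itc_csv(experiment: ITCExperiment, path) -> None:
    lines = [
        f"# cell_volume_uL={experiment.cell_volume}",
        f"# cell_protein_uM={experiment.cell_protein}",
        f"# syringe_ligand_uM={experiment.syringe_ligand}",
        f"# temperature_K={experiment.temperature}",
        "injection_index,volume_uL,heat_ucal",
    ]
    for i, v in enumerate(experiment.injection_volumes):
        q = "" if experiment.heats is None else repr(experiment.heats[i])
        lines.append(f"{i},{v},{q}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_itc_csv(path) -> ITCExperiment:
    """Load an ITC table; empty heat cells give a design-only experiment
    usable as a simulation template."""
    meta: dict[str, float] = {}
    volumes: list[float] = []
    heats: list[float] = []
    any_heat = False
    header_seen = False
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        txt = line.strip()
        if not txt:
            continue
        if txt.startswith("#"):
            if "=" in txt:
                key, val = txt.lstrip("#").split("=", 1)
                meta[key.strip()] = float(val)
            continue
        if not header_seen:
            cols = [c.strip() for c in txt.split(",")]
            if cols != ["injection_index", "volume_uL", "heat_ucal"]:
                raise ValidationError(
                    f"{path}:{lineno}: expected header "
                    f"injection_index,volume_uL,heat_ucal, got {txt!r}"
                )
            header_seen = True
            continue
        cols = txt.split(",")
        vol = float(cols[1])
        if vol <= 0:
            raise ValidationError(f"{path}:{lineno}: injection volume must be > 0")
        volumes.append(vol)
        if len(cols) > 2 and cols[2].strip() != "":
            heats.append(float(cols[2]))
            any_heat = True
        else:
            heats.append(float("nan"))
    missing = [k for k in _ITC_META_KEYS if k not in meta]
    if missing:
        raise ValidationError(f"{path}: missing metadata keys {missing}")
    if any_heat and any(np.isnan(q) for q in heats):
        raise ValidationError(f"{path}: heats column is partially filled")
    return ITCExperiment(
        cell_volume=meta["cell_volume_uL"],
        cell_protein=meta["cell_protein_uM"],
        syringe_ligand=meta["syringe_ligand_uM"],
        injection_volumes=volumes,
        heats=heats if any_heat else None,
        temperature=meta["temperature_K"],
    )


def annotate_pdb(pdb_path, profile: CSPProfile, field: str, out_path,
                 chain_id: str | None = None) -> None:
    """Write a per-residue profile quantity into the B-factor column.

    ``field`` selects what is encoded: ``csp`` (ppm value), ``class``
    (0/1/2 for below mean / above mean / above mean + SD) or ``broadened``
    (1 for broadened residues).  Broadened residues are always marked with
    the sentinel -1.00 in ``csp`` mode; unmatched residues are set to 0.
    A REMARK header documents the encoding.
    """
    if field not in ("csp", "class", "broadened"):
        raise DomainError(f"unknown annotation field {field!r}")
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("annotated", str(pdb_path))
    model = next(structure.get_models())
    chains = list(model.get_chains())
    chain = chains[0] if chain_id is None else model[chain_id]

    class_codes = {"below_mean": 0.0, "above_mean": 1.0, "above_mean_plus_sd": 2.0}
    values: dict[int, float] = {}
    if field == "csp":
        values.update({rid: v for rid, v in profile.per_residue.items()})
        values.update({rid: BROADENED_SENTINEL for rid in profile.broadened})
    elif field == "class":
        values.update({rid: class_codes[c.value] for rid, c in profile.class_map.items()})
    else:
        values.update({rid: 1.0 for rid in profile.broadened})

    struct_ids = [res.id[1] for res in chain.get_residues() if res.id[0] == " "]
    overlap = set(struct_ids) & set(values)
    if not overlap:
        raise ValidationError(
            f"no residue overlap between profile "
            f"(ids {min(values, default='-')}-{max(values, default='-')}) and "
            f"structure chain {chain.id!r} "
            f"(ids {min(struct_ids, default='-')}-{max(struct_ids, default='-')}); "
            f"check the numbering offset"
        )
    for res in chain.get_residues():
        value = values.get(res.id[1], 0.0)
        for atom in res.get_atoms():
            atom.set_bfactor(value)

    io = PDBIO()
    io.set_structure(structure)
    io.save(str(out_path))
    remarks = (
        f"REMARK   3 B-FACTOR COLUMN ENCODES PER-RESIDUE {field.upper()}\n"
        f"REMARK   3 BROADENED RESIDUES MARKED WITH SENTINEL {BROADENED_SENTINEL:.2f}\n"
    )
    out = Path(out_path)
    out.write_text(remarks + out.read_text())


def write_fit_json(result: BindingFitResult | ITCFitResult, path) -> None:
    data = asdict(result)
    Path(path).write_text(json.dumps(data, indent=2, default=str) + "\n")


def write_csp_csv(profile: CSPProfile, path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["residue_id", "csp_ppm", "class", "broadened"])
        for rid in sorted(set(profile.per_residue) | profile.broadened):
            if rid in profile.broadened:
                writer.writerow([rid, "", "", 1])
            else:
                cls = profile.class_map.get(rid)
                writer.writerow([rid, repr(profile.per_residue[rid]),
                                 "" if cls is None else cls.value, 0])
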