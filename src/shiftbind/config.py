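"""Flat key=value run configuration, echoed into every output directory."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

from .errors import ValidationError


@dataclass
class RunConfig:
    """Defaults for every tunable threshold of the pipeline."""

    seed: int = 0
    alpha: float = 0.1  # broadening detection threshold (fraction of start)
    max_jump: float = 0.05  # peak-tracking gate, ppm (combined shift)
    n15_scale: float = 5.0  # 15N downweighting in the combined CSP
    kd_min: float = 1e-3  # uM, fit bound
    kd_max: float = 1e5  # uM, fit bound
    shift_noise_h: float = 0.005  # ppm, generator default
    shift_noise_n: float = 0.025  # ppm
    intensity_noise_cv: float = 0.05
    detection_floor: float = 0.05
    verbosity: int = 1

    def save(self, path) -> None:
        lines = [f"{k} = {v}" for k, v in asdict(self).items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path) -> "RunConfig":
        known = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            txt = line.strip()
            if not txt or txt.startswith(("#", ";", "[")):
                continue
            if "=" not in txt:
                raise ValidationError(f"{path}:{lineno}: expected key = value")
            key, val = (s.strip() for s in txt.split("=", 1))
            if key not in known:
                raise ValidationError(f"{path}:{lineno}: unknown key {key!r}")
            caster = int if known[key] in ("int", int) else float
            kwargs[key] = caster(val)
        return cls(**kwargs)
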