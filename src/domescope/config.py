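"""Run configuration: flat dotted-key text files with validated defaults.

The config format is one ``key = value`` per line, ``#`` comments,
nesting expressed by dotted keys (``scene.n_planes = 20``). Unknown keys
are rejected so typos fail fast; a round trip through
:func:`save_config` / :func:`load_config` is the identity on normalized
configs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, fields
from pathlib import Path

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]


def _bool(s: str) -> bool:
    if s.lower() in ("true", "1", "yes"):
        return True
    if s.lower() in ("false", "0", "no"):
        return False
    raise ValueError(f"not a boolean: {s!r}")


@dataclass
class RunConfig:
    """All pipeline knobs; field names map to dotted keys via ``__``."""

    scene__field_size_um: float = 540.0
    scene__pixel_size_um: float = 1.0
    scene__z_step_um: float = 5.0
    scene__n_planes: int = 20
    scene__n_nuclei: int = 120
    scene__n_domes: int = 3
    scene__dome_radius_min_um: float = 25.0
    scene__dome_radius_max_um: float = 45.0
    scene__dome_apex_ratio: float = 0.8
    scene__mito_density: float = 0.0
    scene__enlarged_fraction: float = 0.0
    scene__n_autophagosomes: int = 0
    scene__blur_rate_px_per_um: float = 0.3
    scene__noise_gaussian_sd: float = 3.0
    scene__noise_poisson_scale: float = 1.0
    grid__rows: int = 2
    grid__cols: int = 2
    grid__overlap_fraction: float = 0.125
    recon__focus_method: str = "variance"
    recon__window_px: int = 7
    recon__smooth_radius_px: int = 2
    recon__search_radius_px: int = 8
    recon__blend: str = "feather"
    quant__min_height_um: float = -1.0  # -1 -> use one z-step
    quant__min_dome_area_um2: float = 500.0
    quant__nuclei_min_area_um2: float = 12.0
    quant__enlarged_threshold_um2: float = 2.0
    quant__puncta_min_area_um2: float = 4.0
    quant__puncta_quantile: float = 0.99
    assay__ocr_selector: str = "vendor"
    mz__ppm_tolerance: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.grid__overlap_fraction < 0.5):
            raise ValueError("grid.overlap_fraction must be in [0, 0.5)")
        if self.recon__focus_method not in ("variance", "tenengrad"):
            raise ValueError("recon.focus_method must be variance or tenengrad")
        if self.recon__blend not in ("feather", "nearest"):
            raise ValueError("recon.blend must be feather or nearest")
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, float) and not (v == v and abs(v) < 1e12):
                raise ValueError(f"{_dotted(f.name)} must be finite")

    @property
    def min_height_um(self) -> float:
        """Dome detection threshold; defaults to one z-step above base."""
        if self.quant__min_height_um < 0:
            return self.scene__z_step_um
        return self.quant__min_height_um


def _dotted(field_name: str) -> str:
    return field_name.replace("__", ".")


def _field_name(dotted: str) -> str:
    return dotted.replace(".", "__")


def load_config(path) -> RunConfig:
    """Parse a flat key-value config file; unknown keys raise ValueError."""
    text = Path(path).read_text()
    known = {f.name: f for f in fields(RunConfig)}
    defaults = RunConfig()
    kwargs = {}
    unknown = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        name = _field_name(key)
        if name not in known:
            unknown.append(key)
            continue
        current = getattr(defaults, name)
        if isinstance(current, bool):
            kwargs[name] = _bool(val)
        elif isinstance(current, int):
            kwargs[name] = int(val)
        elif isinstance(current, float):
            kwargs[name] = float(val)
        else:
            kwargs[name] = val
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**kwargs)


def save_config(cfg: RunConfig, path) -> None:
    """Write the config in canonical (sorted dotted-key) form."""
    Path(path).write_text(_canonical_text(cfg))


def _canonical_text(cfg: RunConfig) -> str:
    lines = []
    for f in sorted(fields(cfg), key=lambda f: _dotted(f.name)):
        v = getattr(cfg, f.name)
        lines.append(f"{_dotted(f.name)} = {v}")
    return "\n".join(lines) + "\n"


def config_hash(cfg: RunConfig) -> str:
    """Stable hash of the normalized config, for provenance records."""
    return hashlib.sha256(_canonical_text(cfg).encode()).hexdigest()[:16]
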