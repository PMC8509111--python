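"""Frame and scenario configuration.

External files are YAML with millimetres for every length and degrees
for every angle; internal computation uses radians.  The experiments
behind the published accuracy figures ship as named presets
(``fig3`` ... ``fig7``) loadable with :func:`load_preset`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml

from .errors import ConfigError

__all__ = [
    "FrameConfig",
    "ScenarioConfig",
    "DEFAULT_TARGETS",
    "load_config",
    "load_preset",
    "preset_names",
]

#: The six printed target points, image (u, v) mm relative to image centre.
DEFAULT_TARGETS = {
    "center": (0.0, 0.0),
    "right": (50.0, 0.0),
    "left": (-50.0, 0.0),
    "anterior": (0.0, 50.0),
    "posterior": (0.0, -50.0),
    "anterolateral": (50.0, 50.0),
}

_SP_ASPECTS_3 = ("anterior", "left", "right")
_SP_ASPECTS_4 = ("anterior", "left", "right", "posterior")


@dataclass(frozen=True)
class FrameConfig:
    """Localizer layout on the frame.

    Parameters
    ----------
    kind : 'sp' or 'n'
    aspects : tuple of aspect names
        Subset of anterior/posterior/left/right; localizer planes are
        vertical and tangent to the placement circle at each aspect.
    radius : float
        Placement radius in mm.
    tan_alpha : float
        SP half-angle tangent (V slope).
    extent : float
        SP vertical rod span in mm.
    n_width, n_height : float
        N-localizer vertical-rod spacing and height in mm.
    """

    kind: str = "sp"
    aspects: tuple = _SP_ASPECTS_3
    radius: float = 100.0
    tan_alpha: float = 0.4
    extent: float = 180.0
    n_width: float = 120.0
    n_height: float = 150.0

    def __post_init__(self):
        if self.kind not in ("sp", "n"):
            raise ConfigError(f"kind must be 'sp' or 'n', got {self.kind!r}")
        object.__setattr__(self, "aspects", tuple(self.aspects))
        if not self.aspects:
            raise ConfigError("at least one aspect required")
        if len(set(self.aspects)) != len(self.aspects):
            raise ConfigError("duplicate aspects")
        for val, name in (
            (self.radius, "radius"),
            (self.tan_alpha, "tan_alpha"),
            (self.extent, "extent"),
            (self.n_width, "n_width"),
            (self.n_height, "n_height"),
        ):
            if not val > 0:
                raise ConfigError(f"{name} must be positive, got {val}")

    @property
    def alpha(self) -> float:
        return math.atan(self.tan_alpha)

    @classmethod
    def sp3(cls, **kw):
        """Three SP localizers: anterior, left, right (no posterior)."""
        return cls(kind="sp", aspects=_SP_ASPECTS_3, **kw)

    @classmethod
    def sp4(cls, **kw):
        """Four SP localizers at 90 degree intervals."""
        return cls(kind="sp", aspects=_SP_ASPECTS_4, **kw)

    @classmethod
    def n4(cls, **kw):
        """Four N-localizers at 90 degree intervals."""
        return cls(kind="n", aspects=_SP_ASPECTS_4, **kw)


@dataclass(frozen=True)
class ScenarioConfig:
    """One Monte Carlo sweep arm: frame + solver mode + plane schedule."""

    scenario_id: str
    frame: FrameConfig
    mode: str  # classic | three_point | n_localizer
    theta_deg: float = 0.0
    z_start: float = 5.0
    z_stop: float = 155.0
    z_step: float = 2.0
    n_iterations: int = 2**21
    noise_mm: float = 1.0
    noise_distribution: str = "disk"
    targets: dict = field(default_factory=lambda: dict(DEFAULT_TARGETS))

    def __post_init__(self):
        modes = ("classic", "three_point", "n_localizer")
        if self.mode not in modes:
            raise ConfigError(f"mode must be one of {modes}, got {self.mode!r}")
        if self.mode == "n_localizer" and self.frame.kind != "n":
            raise ConfigError("n_localizer mode requires an 'n' frame")
        if self.mode != "n_localizer" and self.frame.kind != "sp":
            raise ConfigError(f"{self.mode} mode requires an 'sp' frame")
        if self.z_step <= 0 or self.z_stop < self.z_start:
            raise ConfigError("invalid height schedule")
        if self.n_iterations < 1:
            raise ConfigError("n_iterations must be >= 1")
        if self.noise_mm < 0:
            raise ConfigError("noise_mm must be >= 0")

    @property
    def theta(self) -> float:
        return math.radians(self.theta_deg)

    def heights(self) -> np.ndarray:
        n = int(round((self.z_stop - self.z_start) / self.z_step)) + 1
        return self.z_start + self.z_step * np.arange(n)

    def with_iterations(self, n):
        return replace(self, n_iterations=int(n))

    def target_array(self):
        labels = list(self.targets)
        uv = np.array([self.targets[k] for k in labels], dtype=float)
        return labels, uv


def _frame_from_dict(d):
    d = dict(d)
    kind = d.pop("kind", "sp")
    kw = {
        "radius": float(d.pop("radius_mm", 100.0)),
        "tan_alpha": float(d.pop("tan_alpha", 0.4)),
        "extent": float(d.pop("extent_mm", 180.0)),
        "n_width": float(d.pop("n_width_mm", 120.0)),
        "n_height": float(d.pop("n_height_mm", 150.0)),
    }
    aspects = d.pop("aspects", None)
    if d:
        raise ConfigError(f"unknown frame keys: {sorted(d)}")
    if aspects is None:
        aspects = _SP_ASPECTS_4 if kind == "n" else _SP_ASPECTS_3
    return FrameConfig(kind=kind, aspects=tuple(aspects), **kw)


def _scenario_from_dict(d, default_frame, defaults):
    d = dict(d)
    frame = _frame_from_dict(d.pop("frame")) if "frame" in d else default_frame
    if frame is None:
        raise ConfigError("scenario has no frame and no top-level frame given")
    targets = d.pop("targets", None)
    if targets in (None, "default"):
        targets = dict(DEFAULT_TARGETS)
    else:
        targets = {str(k): (float(v[0]), float(v[1])) for k, v in targets.items()}
    kw = dict(
        scenario_id=str(d.pop("id")),
        frame=frame,
        mode=str(d.pop("mode")),
        theta_deg=float(d.pop("theta_deg", 0.0)),
        z_start=float(d.pop("z_start_mm", defaults.get("z_start_mm", 5.0))),
        z_stop=float(d.pop("z_stop_mm", defaults.get("z_stop_mm", 155.0))),
        z_step=float(d.pop("z_step_mm", defaults.get("z_step_mm", 2.0))),
        n_iterations=int(d.pop("iterations", defaults.get("iterations", 2**21))),
        noise_mm=float(d.pop("noise_mm", defaults.get("noise_mm", 1.0))),
        noise_distribution=str(
            d.pop("noise_distribution", defaults.get("noise_distribution", "disk"))
        ),
        targets=targets,
    )
    if d:
        raise ConfigError(f"unknown scenario keys: {sorted(d)}")
    return ScenarioConfig(**kw)


def parse_config(doc):
    """Scenario list from a parsed YAML document."""
    if not isinstance(doc, dict) or "scenarios" not in doc:
        raise ConfigError("config must be a mapping with a 'scenarios' list")
    default_frame = _frame_from_dict(doc["frame"]) if "frame" in doc else None
    defaults = doc.get("defaults", {})
    return [
        _scenario_from_dict(s, default_frame, defaults) for s in doc["scenarios"]
    ]


def load_config(path):
    """Scenario list from a YAML file."""
    try:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    except FileNotFoundError as exc:
        raise ConfigError(f"config file not found: {path}") from exc
    return parse_config(doc)


def preset_names():
    files = resources.files("spframe") / "scenarios"
    return sorted(p.name[:-5] for p in files.iterdir() if p.name.endswith(".yaml"))


def load_preset(name):
    """Bundled experiment preset (fig3 ... fig7) as a scenario list."""
    res = resources.files("spframe") / "scenarios" / f"{name}.yaml"
    if not res.is_file():
        raise ConfigError(
            f"unknown preset {name!r}; available: {preset_names()}"
        )
    return parse_config(yaml.safe_load(res.read_text()))
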