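"""Detection configuration.

All published tool parameters are exposed under their exact names
(``CILIA_GAUSS_SIGMA`` etc.), alongside implementation extras such as the
CLAHE settings and the component connectivity, which the published
parameter table does not pin down.  Configurations load from a flat
``env.txt``-style ``KEY=value`` file with optional override mappings.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Mapping

from .errors import ConfigurationError

#: Default per-cilium feature columns, in output order.
DEFAULT_CILIA_FEATURES = (
    "area",
    "perimeter",
    "eccentricity",
    "form_factor",
    "axis_minor_length",
    "axis_major_length",
    "skeleton_length",
)

_VALID_FEATURES = set(DEFAULT_CILIA_FEATURES)


@dataclass(frozen=True)
class DetectionConfig:
    """All tunable parameters of the two-branch pipeline.

    The upper-case keys carry the published defaults; lower-case keys are
    implementation extras.
    """

    # cilia branch
    CILIA_GAUSS_SIGMA: float = 8.0
    CILIA_TOPHAT_RADIUS: int = 13
    CILIA_MIN_LENGTH: float = 14.0
    CILIA_MIN_AREA: float = 256.0
    CILIA_MIN_ECCENTRICITY: float = 0.46
    CILIA_MIN_PERIMETER: float = 67.0
    EXCLUDE_EDGE_CILIA: bool = False
    CILIA_COLOR: str = "red+green"
    CILIA_FEATURES: tuple[str, ...] = DEFAULT_CILIA_FEATURES
    # nuclei branch
    CELLPOSE_FLOW_THRESHOLD: float = 0.4
    CELLPOSE_MIN_SIZE: int = 15
    EXCLUDE_EDGE_NUCLEI: bool = False
    # implementation extras
    clahe_clip_limit: float = 0.01
    clahe_tile_grid: int = 8
    connectivity: int = 8
    pixel_size: float | None = None  # micrometres per pixel; None = report px only
    within_cell_radius: float | None = None  # None = median nucleus diameter
    length_measure: str = "skeleton"  # or "major_axis"
    nuclei_channel: str = "blue"

    def __post_init__(self) -> None:
        if self.CILIA_GAUSS_SIGMA <= 0:
            raise ConfigurationError("CILIA_GAUSS_SIGMA must be > 0")
        if self.CILIA_TOPHAT_RADIUS < 1:
            raise ConfigurationError("CILIA_TOPHAT_RADIUS must be >= 1")
        if not 0.0 <= self.CILIA_MIN_ECCENTRICITY <= 1.0:
            raise ConfigurationError("CILIA_MIN_ECCENTRICITY must lie in [0, 1]")
        for key in ("CILIA_MIN_LENGTH", "CILIA_MIN_AREA", "CILIA_MIN_PERIMETER"):
            if getattr(self, key) < 0:
                raise ConfigurationError(f"{key} must be >= 0")
        if self.CILIA_COLOR not in ("red", "green", "blue", "red+green"):
            raise ConfigurationError(f"invalid CILIA_COLOR {self.CILIA_COLOR!r}")
        unknown = set(self.CILIA_FEATURES) - _VALID_FEATURES
        if unknown:
            raise ConfigurationError(f"unknown CILIA_FEATURES entries: {sorted(unknown)}")
        if self.connectivity not in (4, 8):
            raise ConfigurationError("connectivity must be 4 or 8")
        if self.length_measure not in ("skeleton", "major_axis"):
            raise ConfigurationError("length_measure must be 'skeleton' or 'major_axis'")
        if self.clahe_clip_limit <= 0:
            raise ConfigurationError("clahe_clip_limit must be > 0")

    def to_dict(self) -> dict[str, Any]:
        out = {}
        for f in fields(self):
            value = getattr(self, f.name)
            out[f.name] = list(value) if isinstance(value, tuple) else value
        return out


_FIELD_TYPES = {f.name: f.type for f in fields(DetectionConfig)}


def _parse_value(key: str, text: str) -> Any:
    """Parse one textual config value according to its field type."""
    text = text.strip()
    # normalize curly quotes that appear in the published parameter table
    text = (
        text.replace("“", '"').replace("”", '"')
        .replace("‘", "'").replace("’", "'")
    )
    if key == "CILIA_FEATURES":
        inner = text.strip()
        if inner.startswith("'") and inner.endswith("'"):
            inner = inner[1:-1]
        try:
            value = ast.literal_eval(inner)
        except (ValueError, SyntaxError) as exc:
            raise ConfigurationError(f"cannot parse CILIA_FEATURES: {text!r}") from exc
        if not isinstance(value, (list, tuple)):
            raise ConfigurationError(f"CILIA_FEATURES must be a list, got {text!r}")
        return tuple(str(v) for v in value)
    default = getattr(DetectionConfig(), key)
    if isinstance(default, bool):
        if text in ("True", "true", "TRUE", "1"):
            return True
        if text in ("False", "false", "FALSE", "0"):
            return False
        raise ConfigurationError(f"cannot parse boolean for {key}: {text!r}")
    if text in ("None", "none", ""):
        return None
    if isinstance(default, int) and not isinstance(default, bool):
        try:
            return int(text)
        except ValueError as exc:
            raise ConfigurationError(f"cannot parse integer for {key}: {text!r}") from exc
    if isinstance(default, float) or default is None:
        try:
            return float(text)
        except ValueError as exc:
            raise ConfigurationError(f"cannot parse number for {key}: {text!r}") from exc
    return text.strip("'\"")


def load_config(
    path: str | Path | None = None,
    overrides: Mapping[str, Any] | None = None,
) -> DetectionConfig:
    """Build a configuration: defaults <- file <- overrides.

    The file is flat ``KEY=value`` text; blank lines and ``#`` comments
    are ignored.  Unknown keys raise :class:`ConfigurationError` naming
    the key.
    """
    values: dict[str, Any] = {}
    if path is not None:
        for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigurationError(f"line {lineno} is not KEY=value: {line!r}")
            key, _, raw = line.partition("=")
            key = key.strip()
            if key == "DIR_NAME":  # input-folder key of the published tool; handled by the CLI
                continue
            if key not in _FIELD_TYPES:
                raise ConfigurationError(f"unknown configuration key {key!r}")
            values[key] = _parse_value(key, raw)
    if overrides:
        for key, value in overrides.items():
            if key not in _FIELD_TYPES:
                raise ConfigurationError(f"unknown configuration key {key!r}")
            values[key] = _parse_value(key, value) if isinstance(value, str) else value
    return DetectionConfig(**values)
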