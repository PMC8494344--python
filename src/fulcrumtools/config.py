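"""Processing configuration.

All tunables of the cleaning/flagging stages live in one dataclass so a
whole run is reproducible from a single config object (or YAML file).
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field


@dataclass(frozen=True)
class ProcessingConfig:
    """Tunable parameters for processing, flagging, and photo handling.

    Parameters
    ----------
    fahrenheit_threshold:
        Raw temperature readings strictly greater than this value are
        assumed to have been recorded in Fahrenheit and are converted to
        Celsius. Readings at or below the threshold are left untouched.
    run_length_min:
        Minimum number of identical consecutive readings (collections
        ordered by date+time) for a stuck-probe run flag.
    ambient_temp_range, substrate_temp_range:
        Plausible post-conversion ranges in degrees Celsius; values outside
        are flagged extreme, never dropped.
    altitude_range:
        Plausible elevation range in meters.
    c_label_pattern, s_label_pattern:
        Grammars for collection and specimen labels after trim+uppercase
        normalization.
    thumbnail_max_dim:
        Longest side of generated photo thumbnails, in pixels.
    """

    fahrenheit_threshold: float = 40.0
    run_length_min: int = 3
    ambient_temp_range: tuple[float, float] = (-10.0, 50.0)
    substrate_temp_range: tuple[float, float] = (-10.0, 50.0)
    altitude_range: tuple[float, float] = (-100.0, 5500.0)
    c_label_pattern: str = r"^C-[0-9]+$"
    s_label_pattern: str = r"^S-[0-9]+$"
    thumbnail_max_dim: int = 300

    def __post_init__(self) -> None:
        if self.fahrenheit_threshold <= 0:
            raise ValueError("fahrenheit_threshold must be positive")
        if self.run_length_min < 2:
            raise ValueError("run_length_min must be at least 2")
        for name in ("ambient_temp_range", "substrate_temp_range", "altitude_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be an ordered (low, high) pair")
        re.compile(self.c_label_pattern)
        re.compile(self.s_label_pattern)

    def replace(self, **kwargs) -> "ProcessingConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "ProcessingConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        d = dict(d)
        for name in ("ambient_temp_range", "substrate_temp_range", "altitude_range"):
            if name in d:
                d[name] = tuple(d[name])
        return cls(**d)
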