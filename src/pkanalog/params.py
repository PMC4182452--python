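"""Analog configuration: the user-facing knobs of the disposition analog.

The analog is relationally grounded: amounts, times and concentrations are in
internal units, and two scale factors (``x_scale``, ``y_scale``) plus the
referent dose map them to hours and nmol/l.  Every parameter here is constant
for the duration of one simulation run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterator

import yaml

__all__ = ["AnalogParameters", "TransferChannel", "ParameterError"]


class ParameterError(ValueError):
    """Raised when a parameter value violates its declared range."""


@dataclass(frozen=True)
class TransferChannel:
    """One stochastic inter-grid transfer channel.

    Each simulation cycle, every site of ``source`` independently moves
    ``fract`` of its amount to the matching site of ``destination`` with
    probability ``prob``, once the global clock has reached ``delay``.
    """

    delay: int
    fract: float
    prob: float
    source: str
    destination: str

    def active(self, clock: int) -> bool:
        return clock >= self.delay


# field name -> (kind, lo, hi); kind "int" values must be integral
_RANGES: dict[str, tuple[str, float, float | None]] = {
    "grid_width": ("int", 1, None),
    "grid_height": ("int", 1, None),
    "x_scale": ("float", 0.0, None),  # strictly positive, checked below
    "y_scale": ("float", 0.0, None),
    "init_dose": ("float", 0.0, None),
    "disperse_count": ("int", 0, None),
}
_STRICT_POSITIVE = {"x_scale", "y_scale", "init_dose"}


@dataclass(frozen=True)
class AnalogParameters:
    """All tunable analog parameters, defaulting to the stock one-peak profile.

    Fractions and probabilities are dimensionless in [0, 1]; delays and counts
    are non-negative integers in simulation time steps; ``init_dose`` is the
    total drug amount seeded into the dissolution grid; ``x_scale`` is hours
    per time step and ``y_scale`` divides the plasma dose fraction when mapping
    to concentration units.
    """

    grid_width: int = 100
    grid_height: int = 100
    x_scale: float = 1.0
    y_scale: float = 120.0
    init_dose: float = 10000.0
    d_to_g_delay: int = 1
    d_to_g_fract: float = 0.1
    d_to_g_prob: float = 0.8
    diff_g_ratio: float = 1.0
    g_to_c_delay: int = 0
    g_to_c_fract: float = 0.0
    g_to_c_prob: float = 0.0
    ga_to_p_delay: int = 0
    ga_to_p_fract: float = 0.1
    ga_to_p_prob: float = 0.8
    gb_to_p_delay: int = 0
    gb_to_p_fract: float = 0.1
    gb_to_p_prob: float = 0.8
    gc_to_p_delay: int = 0
    gc_to_p_fract: float = 0.1
    gc_to_p_prob: float = 0.8
    p_to_e_delay: int = 0
    p_to_e_fract: float = 0.1
    p_to_e_prob: float = 0.8
    disperse_rate: float = 0.1
    evap_rate: float = 0.0
    disperse_count: int = 2

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            name = f.name
            if name in _RANGES:
                kind, lo, hi = _RANGES[name]
                if kind == "int":
                    if value != int(value):
                        raise ParameterError(f"{name} must be an integer, got {value!r}")
                    object.__setattr__(self, name, int(value))
                    value = int(value)
                if value < lo or (hi is not None and value > hi):
                    raise ParameterError(f"{name}={value!r} out of range")
                if name in _STRICT_POSITIVE and value <= 0:
                    raise ParameterError(f"{name} must be positive, got {value!r}")
            elif name.endswith(("_delay",)):
                if value != int(value) or value < 0:
                    raise ParameterError(
                        f"{name} must be a non-negative integer, got {value!r}"
                    )
                object.__setattr__(self, name, int(value))
            else:  # fractions, probabilities, ratios, rates
                if not 0.0 <= value <= 1.0:
                    raise ParameterError(f"{name}={value!r} not in [0, 1]")
                object.__setattr__(self, name, float(value))
        if self.init_dose <= 0:
            raise ParameterError(f"init_dose must be positive, got {self.init_dose!r}")

    # -- transfer channels -------------------------------------------------

    def channel(self, name: str) -> TransferChannel:
        """Build the named channel (``d_to_g``, ``g_to_c``, ``ga_to_p``,
        ``gb_to_p``, ``gc_to_p`` or ``p_to_e``)."""
        src_dst = {
            "d_to_g": ("dissolution", "gi"),
            "g_to_c": ("gi_ab", "gi_c"),
            "ga_to_p": ("gi_a", "plasma"),
            "gb_to_p": ("gi_b", "plasma"),
            "gc_to_p": ("gi_c", "plasma"),
            "p_to_e": ("plasma", "eliminated"),
        }
        if name not in src_dst:
            raise KeyError(name)
        src, dst = src_dst[name]
        return TransferChannel(
            delay=getattr(self, f"{name}_delay"),
            fract=getattr(self, f"{name}_fract"),
            prob=getattr(self, f"{name}_prob"),
            source=src,
            destination=dst,
        )

    def replace(self, **changes) -> "AnalogParameters":
        return dataclasses.replace(self, **changes)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, mapping: dict) -> "AnalogParameters":
        """Build from a flat mapping; keys may use either the published
        CamelCase names (``DtoGFract``) or snake_case (``d_to_g_fract``),
        case-insensitively.  Unknown keys are rejected."""
        kwargs: dict[str, float] = {}
        for key, value in mapping.items():
            name = _canonical_name(key)
            if name is None:
                raise ParameterError(f"unknown parameter {key!r}")
            if name in kwargs:
                raise ParameterError(f"duplicate parameter {key!r}")
            kwargs[name] = value
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        """Write a flat key/value parameter file using the published names."""
        out = {_PUBLISHED[name]: value for name, value in self.to_dict().items()}
        Path(path).write_text(yaml.safe_dump(out, sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalogParameters":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ParameterError(f"{path}: expected a flat key/value mapping")
        return cls.from_dict(data)

    def iter_channels(self) -> Iterator[TransferChannel]:
        for name in ("d_to_g", "g_to_c", "ga_to_p", "gb_to_p", "gc_to_p", "p_to_e"):
            yield self.channel(name)


# published (CamelCase) spelling of every field
_PUBLISHED: dict[str, str] = {
    "grid_width": "GridWidth",
    "grid_height": "GridHeight",
    "x_scale": "XScale",
    "y_scale": "YScale",
    "init_dose": "InitDose",
    "d_to_g_delay": "DtoGDelay",
    "d_to_g_fract": "DtoGFract",
    "d_to_g_prob": "DtoGProb",
    "diff_g_ratio": "DiffGRatio",
    "g_to_c_delay": "GtoCDelay",
    "g_to_c_fract": "GtoCFract",
    "g_to_c_prob": "GtoCProb",
    "ga_to_p_delay": "GAtoPDelay",
    "ga_to_p_fract": "GAtoPFract",
    "ga_to_p_prob": "GAtoPProb",
    "gb_to_p_delay": "GBtoPDelay",
    "gb_to_p_fract": "GBtoPFract",
    "gb_to_p_prob": "GBtoPProb",
    "gc_to_p_delay": "GCtoPDelay",
    "gc_to_p_fract": "GCtoPFract",
    "gc_to_p_prob": "GCtoPProb",
    "p_to_e_delay": "PtoEDelay",
    "p_to_e_fract": "PtoEFract",
    "p_to_e_prob": "PtoEProb",
    "disperse_rate": "DisperseRate",
    "evap_rate": "EvapRate",
    "disperse_count": "DisperseCount",
}

# normalized (lowercase, no underscores) -> field name
_NORMALIZED: dict[str, str] = {}
for _field, _pub in _PUBLISHED.items():
    _NORMALIZED[_pub.lower()] = _field
    _NORMALIZED[_field.replace("_", "")] = _field


def _canonical_name(key: str) -> str | None:
    return _NORMALIZED.get(str(key).strip().replace("_", "").lower())
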