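"""Rate-parameter sets for the nine-state Nav gating model.

A model variant is defined by 24 positive rate parameters (two per
voltage-dependent rate law, or a single multiplier for rates tied to the
activation/deactivation backbone), a Q10 and a simulation temperature.
The two variants shipped with the package are the optimized wild-type and
Scn4b-/- (Navbeta4-null) parameter sets for mouse cerebellar Purkinje
neurons; custom variants are loaded from flat key-value text files.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

__all__ = [
    "PARAMETER_NAMES",
    "RateParameterSet",
    "load_parameters",
    "save_parameters",
    "wild_type",
    "scn4b_null",
]

#: The 24 free rate parameters, in the conventional input-vector order.
PARAMETER_NAMES: tuple[str, ...] = (
    "a11_variable1", "a11_variable2",
    "a12", "a13",
    "b11_variable1", "b11_variable2",
    "b12", "b13",
    "a3_variable1", "a3_variable2",
    "b3_variable1", "b3_variable2",
    "a2_variable1", "a2_variable2",
    "a6_variable1", "a6_variable2",
    "b6_variable1", "b6_variable2",
    "a2s_variable1", "a2s_variable2",
    "b2s_variable1", "b2s_variable2",
    "a3s_variable1", "a3s_variable2",
)


@dataclass(frozen=True)
class RateParameterSet:
    """The 24 free rate parameters of one model variant.

    All rate parameters are strictly positive.  ``q10`` and
    ``temperature_K`` control the temperature scaling of the rates
    (see :func:`navresurge.kinetics.temperature_factor`); the shipped
    sets use Q10 = 3 at 295 K (22 degC, room temperature).
    """

    a11_variable1: float
    a11_variable2: float
    a12: float
    a13: float
    b11_variable1: float
    b11_variable2: float
    b12: float
    b13: float
    a3_variable1: float
    a3_variable2: float
    b3_variable1: float
    b3_variable2: float
    a2_variable1: float
    a2_variable2: float
    a6_variable1: float
    a6_variable2: float
    b6_variable1: float
    b6_variable2: float
    a2s_variable1: float
    a2s_variable2: float
    b2s_variable1: float
    b2s_variable2: float
    a3s_variable1: float
    a3s_variable2: float
    q10: float = 3.0
    temperature_K: float = 295.0
    label: str = field(default="custom", compare=False)

    def __post_init__(self) -> None:
        for name in PARAMETER_NAMES:
            value = getattr(self, name)
            if not (value > 0.0):
                raise ValueError(
                    f"rate parameter {name!r} must be strictly positive, got {value!r}"
                )
        if not (self.q10 > 0.0):
            raise ValueError(f"q10 must be positive, got {self.q10!r}")
        if not (self.temperature_K > 0.0):
            raise ValueError(
                f"temperature_K must be positive, got {self.temperature_K!r}"
            )

    # -- conversions ----------------------------------------------------

    def values(self) -> tuple[float, ...]:
        """The 24 free parameters in :data:`PARAMETER_NAMES` order."""
        return tuple(getattr(self, name) for name in PARAMETER_NAMES)

    def to_dict(self) -> dict[str, float | str]:
        out: dict[str, float | str] = {name: getattr(self, name) for name in PARAMETER_NAMES}
        out["q10"] = self.q10
        out["temperature_K"] = self.temperature_K
        out["label"] = self.label
        return out

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float | str]) -> "RateParameterSet":
        known = {f.name for f in fields(cls)}
        missing = [n for n in PARAMETER_NAMES if n not in mapping]
        if missing:
            raise KeyError(f"missing rate parameter(s): {', '.join(missing)}")
        unknown = sorted(set(mapping) - known)
        if unknown:
            raise KeyError(f"unknown parameter key(s): {', '.join(unknown)}")
        kwargs: dict[str, float | str] = {}
        for key, value in mapping.items():
            kwargs[key] = str(value) if key == "label" else float(value)
        return cls(**kwargs)  # type: ignore[arg-type]

    def with_values(self, **updates: float) -> "RateParameterSet":
        """A copy with some of the free parameters replaced."""
        bad = sorted(set(updates) - set(PARAMETER_NAMES))
        if bad:
            raise KeyError(f"unknown rate parameter(s): {', '.join(bad)}")
        return replace(self, **updates)

    def content_hash(self) -> str:
        """Short stable hash of the numeric content, for output provenance."""
        text = ",".join(f"{v!r}" for v in self.values())
        text += f",{self.q10!r},{self.temperature_K!r}"
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def _iter_kv_lines(text: str) -> Iterator[tuple[str, str]]:
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed parameter line (expected 'key = value'): {raw!r}")
        key, value = line.split("=", 1)
        yield key.strip(), value.strip()


def load_parameters(path: str | Path) -> RateParameterSet:
    """Load a :class:`RateParameterSet` from a flat key-value text file.

    The file holds one ``key = value`` pair per line (``#`` starts a
    comment); all 24 rate-parameter keys are required, ``q10``,
    ``temperature_K`` and ``label`` are optional.  Duplicate, missing,
    unknown or non-positive keys raise with the offending key named.
    """
    path = Path(path)
    mapping: dict[str, float | str] = {}
    for key, value in _iter_kv_lines(path.read_text()):
        if key in mapping:
            raise ValueError(f"duplicate parameter key {key!r} in {path}")
        mapping[key] = value
    return RateParameterSet.from_dict(mapping)


def save_parameters(params: RateParameterSet, path: str | Path) -> None:
    """Write a parameter set in the flat key-value format of :func:`load_parameters`."""
    lines = [f"label = {params.label}",
             f"q10 = {params.q10!r}",
             f"temperature_K = {params.temperature_K!r}"]
    lines += [f"{name} = {getattr(params, name)!r}" for name in PARAMETER_NAMES]
    Path(path).write_text("\n".join(lines) + "\n")


def _load_shipped(filename: str) -> RateParameterSet:
    text = resources.files("navresurge.data").joinpath(filename).read_text()
    mapping: dict[str, float | str] = dict(_iter_kv_lines(text))
    return RateParameterSet.from_dict(mapping)


def wild_type() -> RateParameterSet:
    """The optimized wild-type Purkinje-neuron parameter set."""
    return _load_shipped("wt.params")


def scn4b_null() -> RateParameterSet:
    """The optimized Scn4b-/- (Navbeta4-null) parameter set."""
    return _load_shipped("scn4b_ko.params")
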