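"""Open-channel-block (OB) gating topology for mechanism comparison.

The competing account of the resurgent current posits an endogenous
blocking particle that occludes open channels, producing an open-blocked
(OB) state that connects *only* to the open state: blocked channels must
re-open (conducting briefly) to unblock, which generates the resurgent
current on repolarization.  The scheme has five closed states (C1-C5),
one open state (O), the OB state and six inactivated states (I1-I6): the
closed/open backbone C1-...-C5-O, vertical inactivation edges C1-I1 ...
C5-I5 and O-I6, the inactivated row I1-...-I6, and O-OB.

The published numeric rate constants for this scheme are not reproduced
here; the module ships the topology, its structural invariants and a
loader for user-supplied rate tables, plus a synthetic placeholder rate
set (qualitatively reasonable, not the published values) for
demonstrating the discriminating protocols.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping

import numpy as np

from .analysis import fit_single_exponential
from .kinetics import KineticScheme, MarkovModel
from . import protocols as proto
from .propagation import CurrentModel

__all__ = [
    "OB_STATES",
    "OB_EDGES",
    "OBModel",
    "build_ob_scheme",
    "load_ob_rates",
    "synthetic_ob_rates",
    "discriminate_mechanism",
]

OB_STATES: tuple[str, ...] = (
    "C1", "C2", "C3", "C4", "C5", "O", "OB",
    "I1", "I2", "I3", "I4", "I5", "I6",
)

_backbone = ["C1", "C2", "C3", "C4", "C5", "O"]
_inactivated = ["I1", "I2", "I3", "I4", "I5", "I6"]

OB_EDGES: tuple[tuple[str, str], ...] = tuple(
    [(a, b) for a, b in zip(_backbone, _backbone[1:])]
    + [(b, a) for a, b in zip(_backbone, _backbone[1:])]
    + [(a, b) for a, b in zip(_inactivated, _inactivated[1:])]
    + [(b, a) for a, b in zip(_inactivated, _inactivated[1:])]
    + [(c, i) for c, i in zip(_backbone, _inactivated)]
    + [(i, c) for c, i in zip(_backbone, _inactivated)]
    + [("O", "OB"), ("OB", "O")]
)

RateFunction = Callable[[float], float]


def build_ob_scheme(rate_table: Mapping[tuple[str, str], RateFunction]) -> "OBModel":
    """Build the 13-state OB model from a complete edge -> rate-function table.

    Every edge of the topology must have a rate function (voltage in mV ->
    rate in ms^-1); missing edges are reported together.  The structural
    invariant that OB touches only the open state is enforced: extra edges
    into or out of OB are rejected.
    """
    missing = [edge for edge in OB_EDGES if edge not in rate_table]
    if missing:
        raise ValueError(
            "rate table is missing edge rate(s): "
            + ", ".join(f"{a}->{b}" for a, b in missing)
        )
    extra = [edge for edge in rate_table if edge not in OB_EDGES]
    if extra:
        bad_ob = [e for e in extra if "OB" in e]
        if bad_ob:
            raise ValueError(
                "the OB state may connect only to O; illegal edge(s): "
                + ", ".join(f"{a}->{b}" for a, b in bad_ob)
            )
        raise ValueError(
            "unknown edge(s) in rate table: " + ", ".join(f"{a}->{b}" for a, b in extra)
        )
    return OBModel(dict(rate_table))


class OBModel(MarkovModel):
    """The 13-state open-channel-block model with user-supplied rates."""

    def __init__(self, rate_table: Mapping[tuple[str, str], RateFunction],
                 label: str = "open-channel-block"):
        scheme = KineticScheme(
            states=OB_STATES,
            edges=tuple((a, b, "a11") for a, b in OB_EDGES),  # rate names unused
            rate_names=("a11",),
        )
        super().__init__(scheme, label=label)
        self.rate_table = dict(rate_table)
        self._index = {s: i for i, s in enumerate(OB_STATES)}

    def generator(self, voltage_mV: float) -> np.ndarray:
        n = len(OB_STATES)
        q = np.zeros((n, n))
        for (frm, to), fn in self.rate_table.items():
            rate = float(fn(voltage_mV))
            if rate < 0 or not np.isfinite(rate):
                raise ValueError(f"rate for edge {frm}->{to} is invalid at V={voltage_mV}: {rate}")
            q[self._index[frm], self._index[to]] = rate
        np.fill_diagonal(q, q.diagonal() - q.sum(axis=1))
        return q


def _exp_rate(amplitude: float, vslope: float) -> RateFunction:
    """Rate law A * exp(V / k); a zero slope key means voltage-independent."""
    if vslope == 0.0:
        return lambda v: amplitude
    return lambda v: amplitude * np.exp(v / vslope)


def load_ob_rates(path: str | Path) -> dict[tuple[str, str], RateFunction]:
    """Load an OB rate table from flat key-value text.

    Keys are ``FROM.TO.amp`` and ``FROM.TO.vslope`` (mV per e-fold;
    0 means constant), one pair per directed edge, e.g.::

        O.OB.amp = 1.5
        O.OB.vslope = 100.0
    """
    entries: dict[tuple[str, str], dict[str, float]] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, value = line.partition("=")
        parts = key.strip().split(".")
        if len(parts) != 3 or parts[2] not in ("amp", "vslope"):
            raise ValueError(f"malformed OB rate key {key.strip()!r} (expected FROM.TO.amp|vslope)")
        frm, to, which = parts
        entries.setdefault((frm, to), {})[which] = float(value)
    table: dict[tuple[str, str], RateFunction] = {}
    for edge, kv in entries.items():
        if "amp" not in kv:
            raise ValueError(f"edge {edge[0]}->{edge[1]} is missing its 'amp' key")
        table[edge] = _exp_rate(kv["amp"], kv.get("vslope", 0.0))
    return table


def synthetic_ob_rates() -> dict[tuple[str, str], RateFunction]:
    """A synthetic placeholder rate table for the OB topology.

    These values are NOT the published rate constants; they are a
    qualitatively reasonable parameterization (activation favored by
    depolarization, open-channel block favored at positive potentials,
    unblock and deactivation favored by hyperpolarization, no slowly
    absorbing state) used only to demonstrate the structural difference
    between the two mechanisms.
    """
    table: dict[tuple[str, str], RateFunction] = {}
    # activation backbone: forward rates grow, backward shrink, with V
    for a, b in zip(_backbone, _backbone[1:]):
        table[(a, b)] = _exp_rate(8.0, 45.0)
        table[(b, a)] = _exp_rate(0.6, -35.0)
    # inactivated row mirrors the backbone
    for a, b in zip(_inactivated, _inactivated[1:]):
        table[(a, b)] = _exp_rate(8.0, 45.0)
        table[(b, a)] = _exp_rate(0.6, -35.0)
    # vertical inactivation: faster for states further along the backbone;
    # recovery is fast enough that the block/inactivation balance
    # equilibrates within a few ms (no slowly absorbing state)
    for k, (c, i) in enumerate(zip(_backbone, _inactivated)):
        table[(c, i)] = _exp_rate(0.05 * (k + 1), 80.0)
        table[(i, c)] = _exp_rate(0.5, -40.0)
    # open-state fast inactivation, reversible on the ms scale
    table[("O", "I6")] = _exp_rate(1.2, 200.0)
    table[("I6", "O")] = _exp_rate(0.25, -60.0)
    # open-channel block: favored at depolarized V; unblock on
    # hyperpolarization (the blocker is expelled by inward flux)
    table[("O", "OB")] = _exp_rate(4.0, 60.0)
    table[("OB", "O")] = _exp_rate(0.4, -25.0)
    return table


@dataclass(frozen=True)
class MechanismReport:
    """Duration-attenuation and envelope metrics for one gating scheme."""

    label: str
    duration_tau_ms: float
    attenuation_fraction: float  # 1 - (peak at longest prepulse / peak at 2 ms)
    envelope_deviation: float


def _report(model: MarkovModel, current: CurrentModel) -> MechanismReport:
    curve = proto.duration_dependence(model, current)
    try:
        tau = fit_single_exponential(curve.x, curve.y, with_offset=True).tau_ms
    except (ValueError, RuntimeError):
        tau = float("inf")  # no measurable attenuation
    _, _, deviation = proto.envelope_comparison(model, current)
    return MechanismReport(
        label=model.label,
        duration_tau_ms=tau,
        attenuation_fraction=float(1.0 - curve.y[-1]),
        envelope_deviation=deviation,
    )


def discriminate_mechanism(
    model_a: MarkovModel,
    model_b: MarkovModel,
    current: CurrentModel | None = None,
) -> tuple[MechanismReport, MechanismReport]:
    """Run the discriminating protocols against two gating schemes.

    The duration-dependence protocol separates the mechanisms: a slowly
    absorbing inactivated state produces strong attenuation of the
    resurgent peak with prepulse duration, whereas an open-channel-block
    scheme without one shows little.
    """
    current = current or CurrentModel()
    return _report(model_a, current), _report(model_b, current)
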