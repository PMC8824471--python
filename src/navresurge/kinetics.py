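"""Nine-state Markov scheme, rate laws and generator assembly.

The gating model has three closed states (C1, C2, C3), one open state (O),
two closed-inactivated states (IC1, IC2), two fast-inactivated states
(IF1, IF2) and one slowly populated inactivated state (IS).  The fast
(O -> IF1 -> IF2) and slow (O -> IS) inactivation pathways are parallel:
fast inactivation terminates the transient current, while re-opening from
IF1 on repolarization produces the resurgent current, whose decay reflects
slow accumulation into IS.

Rates are in ms^-1 with membrane potential in mV.  Two rates are not free:
``b2`` (IF1 -> O) and ``b3s`` (C3 -> IS) are fixed by microscopic
reversibility of the C3-O-IF1 and C3-O-IS cycles, so that the product of
rates around each closed loop is the same in both directions at every
voltage.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .parameters import RateParameterSet

__all__ = [
    "RATE_NAMES",
    "NINE_STATES",
    "TransitionRates",
    "KineticScheme",
    "NINE_STATE_SCHEME",
    "temperature_factor",
    "evaluate_rates",
    "build_generator",
    "cycle_balance_residuals",
    "MarkovModel",
    "NavModel",
]

#: Recommended voltage range; rates remain well behaved here.
VOLTAGE_RANGE_MV = (-150.0, 60.0)

#: Hard guard against overflow in the exponential rate laws.
VOLTAGE_LIMIT_MV = 500.0

RATE_NAMES: tuple[str, ...] = (
    "a11", "a12", "a13", "b11", "b12", "b13",
    "a2", "b2", "a3", "b3", "a6", "b6",
    "a2s", "b2s", "a3s", "b3s",
)

NINE_STATES: tuple[str, ...] = ("C1", "C2", "C3", "O", "IC1", "IC2", "IF1", "IF2", "IS")


def temperature_factor(q10: float, temperature_K: float) -> float:
    """Temperature scaling applied to every rate: 1 / q10**((37 - T_C) / 10).

    Equals 1 at 37 degC; below that every rate slows by the same factor.
    """
    if not (q10 > 0.0):
        raise ValueError(f"q10 must be positive, got {q10!r}")
    if not (temperature_K > 0.0):
        raise ValueError(f"temperature_K must be positive, got {temperature_K!r}")
    t_celsius = temperature_K - 273.0
    return 1.0 / q10 ** ((37.0 - t_celsius) / 10.0)


@dataclass(frozen=True)
class TransitionRates:
    """All 16 transition rates (ms^-1) evaluated at one membrane potential."""

    a11: float
    a12: float
    a13: float
    b11: float
    b12: float
    b13: float
    a2: float
    b2: float
    a3: float
    b3: float
    a6: float
    b6: float
    a2s: float
    b2s: float
    a3s: float
    b3s: float
    voltage_mV: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self) if f.name != "voltage_mV"}


def evaluate_rates(params: RateParameterSet, voltage_mV: float) -> TransitionRates:
    """Evaluate the 16 transition rates at a membrane potential.

    ``b2`` and ``b3s`` are derived from the microscopic-reversibility
    constraints of the two triangular loops through the open state; they
    are never free parameters.
    """
    v = float(voltage_mV)
    if not np.isfinite(v):
        raise ValueError(f"voltage must be finite, got {voltage_mV!r}")
    if abs(v) > VOLTAGE_LIMIT_MV:
        raise ValueError(
            f"voltage {v} mV out of range (|V| <= {VOLTAGE_LIMIT_MV} mV); "
            "the exponential rate laws overflow far outside the physiological range"
        )
    p = params
    tf = temperature_factor(p.q10, p.temperature_K)

    a11 = tf / (p.a11_variable1 * np.exp(-v / p.a11_variable2))
    a12 = p.a12 * a11
    a13 = p.a13 * a11
    b11 = tf / (p.b11_variable1 * np.exp(v / p.b11_variable2))
    b12 = p.b12 * b11
    b13 = p.b13 * b11
    a3 = tf * p.a3_variable1 * np.exp(-v / p.a3_variable2)
    b3 = tf * p.b3_variable1 * np.exp(v / p.b3_variable2)
    a2 = tf * p.a2_variable1 * np.exp(v / p.a2_variable2)
    b2 = (a13 * a2 * a3) / (b13 * b3)
    a6 = tf * p.a6_variable1 * np.exp(v / p.a6_variable2)
    b6 = tf * p.b6_variable1 * np.exp(-v / p.b6_variable2)
    a2s = tf * p.a2s_variable1 * np.exp(v / p.a2s_variable2)
    b2s = tf * p.b2s_variable1 * np.exp(-v / p.b2s_variable2)
    a3s = tf * p.a3s_variable1 * np.exp(-v / p.a3s_variable2)
    b3s = (a2s * a3s * a13) / (b2s * b13)

    values = dict(a11=a11, a12=a12, a13=a13, b11=b11, b12=b12, b13=b13,
                  a2=a2, b2=b2, a3=a3, b3=b3, a6=a6, b6=b6,
                  a2s=a2s, b2s=b2s, a3s=a3s, b3s=b3s)
    for name, value in values.items():
        if not np.isfinite(value):
            raise FloatingPointError(f"rate {name} is not finite at V = {v} mV")
    return TransitionRates(voltage_mV=v, **{k: float(val) for k, val in values.items()})


@dataclass(frozen=True)
class KineticScheme:
    """States and rate-labelled directed edges of a Markov gating scheme."""

    states: tuple[str, ...]
    edges: tuple[tuple[str, str, str], ...]
    rate_names: tuple[str, ...] = RATE_NAMES

    def __post_init__(self) -> None:
        if len(set(self.states)) != len(self.states):
            raise ValueError("duplicate state names")
        index = {s: i for i, s in enumerate(self.states)}
        for frm, to, rate in self.edges:
            if frm not in index or to not in index:
                raise ValueError(f"edge ({frm}, {to}, {rate}) references unknown state")
            if rate not in self.rate_names:
                raise ValueError(f"edge ({frm}, {to}, {rate}): unknown rate name {rate!r}")
        # connectivity (undirected reachability from the first state)
        adjacency: dict[str, set[str]] = {s: set() for s in self.states}
        for frm, to, _ in self.edges:
            adjacency[frm].add(to)
            adjacency[to].add(frm)
        seen = {self.states[0]}
        stack = [self.states[0]]
        while stack:
            for nxt in adjacency[stack.pop()]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        if seen != set(self.states):
            raise ValueError(f"scheme is not connected; unreachable: {set(self.states) - seen}")

    def state_index(self, state: str) -> int:
        return self.states.index(state)


#: The nine-state scheme.  The activation backbone is C1-C2-C3-O; the
#: closed-inactivated row IC1-IC2-IF1 reuses the backbone rates a11/a12
#: (forward) and b11/b12 (reverse); vertical transitions between the rows
#: use a3 (toward the non-inactivated row) and b3 (toward the inactivated
#: row); fast open-state inactivation is O-IF1 (a2/b2), the deeper fast
#: state IF1-IF2 (a6/b6), and the slow pathway O-IS (a2s/b2s) with IS-C3
#: recovery (a3s/b3s).  b2 and b3s close the two triangles reversibly.
NINE_STATE_SCHEME = KineticScheme(
    states=NINE_STATES,
    edges=(
        ("C1", "C2", "a11"), ("C2", "C1", "b11"),
        ("C2", "C3", "a12"), ("C3", "C2", "b12"),
        ("C3", "O", "a13"), ("O", "C3", "b13"),
        ("IC1", "IC2", "a11"), ("IC2", "IC1", "b11"),
        ("IC2", "IF1", "a12"), ("IF1", "IC2", "b12"),
        ("IC1", "C1", "a3"), ("C1", "IC1", "b3"),
        ("IC2", "C2", "a3"), ("C2", "IC2", "b3"),
        ("IF1", "C3", "a3"), ("C3", "IF1", "b3"),
        ("O", "IF1", "a2"), ("IF1", "O", "b2"),
        ("IF1", "IF2", "a6"), ("IF2", "IF1", "b6"),
        ("O", "IS", "a2s"), ("IS", "O", "b2s"),
        ("IS", "C3", "a3s"), ("C3", "IS", "b3s"),
    ),
)


def build_generator(
    params: RateParameterSet,
    scheme: KineticScheme = NINE_STATE_SCHEME,
    voltage_mV: float = 0.0,
) -> np.ndarray:
    """Assemble the generator matrix Q at a fixed voltage.

    ``Q[i, j]`` for i != j is the transition rate from state i to state j;
    the diagonal makes every row sum to zero, so occupancy evolves as
    ``p(t + dt) = p(t) @ expm(Q dt)``.
    """
    rates = evaluate_rates(params, voltage_mV).as_dict()
    n = len(scheme.states)
    index = {s: i for i, s in enumerate(scheme.states)}
    q = np.zeros((n, n))
    for frm, to, rate in scheme.edges:
        try:
            q[index[frm], index[to]] = rates[rate]
        except KeyError:
            raise KeyError(f"edge ({frm}, {to}): rate {rate!r} not provided") from None
    np.fill_diagonal(q, q.diagonal() - q.sum(axis=1))
    return q


def cycle_balance_residuals(
    params: RateParameterSet, voltage_mV: float
) -> tuple[float, float]:
    """Microscopic-reversibility residuals of the two constrained cycles.

    Returns ``(a13*a2*a3 - b13*b2*b3, a13*a2s*a3s - b13*b2s*b3s)`` for the
    fast (C3-O-IF1) and slow (C3-O-IS) loops; both vanish (to rounding)
    when b2 and b3s come from :func:`evaluate_rates`.
    """
    r = evaluate_rates(params, voltage_mV)
    fast = r.a13 * r.a2 * r.a3 - r.b13 * r.b2 * r.b3
    slow = r.a13 * r.a2s * r.a3s - r.b13 * r.b2s * r.b3s
    return float(fast), float(slow)


class MarkovModel:
    """A kinetic scheme together with a way of evaluating its generator.

    The propagation engine only needs ``states`` and ``generator(V)``, so
    alternative topologies (e.g. the open-channel-block scheme) plug in
    unchanged.
    """

    def __init__(self, scheme: KineticScheme, label: str = "custom"):
        self.scheme = scheme
        self.label = label

    @property
    def states(self) -> tuple[str, ...]:
        return self.scheme.states

    def generator(self, voltage_mV: float) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    @property
    def open_states(self) -> tuple[str, ...]:
        return ("O",)

    def open_index(self) -> list[int]:
        return [self.scheme.state_index(s) for s in self.open_states]


class NavModel(MarkovModel):
    """The nine-state Purkinje Nav gating model for one parameter set."""

    def __init__(self, params: RateParameterSet, scheme: KineticScheme = NINE_STATE_SCHEME):
        super().__init__(scheme, label=params.label)
        self.params = params

    def generator(self, voltage_mV: float) -> np.ndarray:
        return build_generator(self.params, self.scheme, voltage_mV)

    def rates(self, voltage_mV: float) -> TransitionRates:
        return evaluate_rates(self.params, voltage_mV)
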