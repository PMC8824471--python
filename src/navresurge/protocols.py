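"""Voltage-clamp protocol battery.

Each function builds a protocol, simulates it and applies the measurement
conventions of :mod:`navresurge.analysis`, returning a
:class:`SummaryCurve` (or scalars for the single-valued paradigms).  The
nine numbered optimization protocols (availability, activation,
inactivation tau, recovery, persistent fraction, resurgent/transient
ratio, duration dependence, resurgent decay tau, prepulse independence)
start from the steady state at a -90 mV holding potential unless the
protocol definition says otherwise; the figure-level paradigms (resurgent
voltage dependence from -80 mV, sequential recovery, envelope test, slow
ramps) are also provided.

All curves are deterministic functions of the model and the grid/step
options, so repeated runs are bit-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .analysis import (
    fit_single_exponential,
    measure_peak,
    subtract_persistent,
    tau_one_over_e,
)
from .kinetics import MarkovModel
from .propagation import (
    CurrentModel,
    Ramp,
    SimulationTrace,
    StateVector,
    Step,
    VoltageProtocol,
    simulate,
    steady_state,
)

__all__ = [
    "SummaryCurve",
    "availability_curve",
    "activation_curve",
    "inactivation_tau_curve",
    "recovery_curve",
    "persistent_fraction",
    "resurgent_ratio_curve",
    "duration_dependence",
    "resurgent_decay_taus",
    "prepulse_peak_spread",
    "sequential_recovery",
    "envelope_comparison",
    "ramp_current",
    "three_component_trace",
]

#: Default repolarization window for resurgent-current measurements (ms);
#: long enough to capture the peak and most of the decay at every tested
#: voltage.
DEFAULT_REPOL_MS = 100.0

#: Default sampling for depolarizing segments (I_NaT peaks ~0.03 ms after
#: a strong step) and for slower repolarization segments.
DT_FAST = 0.001
DT_SLOW = 0.005


@dataclass(frozen=True)
class SummaryCurve:
    """Protocol output: an (x, y) curve with protocol metadata."""

    protocol_id: str
    x: np.ndarray
    y: np.ndarray
    x_label: str = "x"
    y_label: str = "y"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("x and y must have the same length")
        dx = np.diff(x)
        if len(dx) and not (np.all(dx > 0) or np.all(dx < 0)):
            raise ValueError("x must be strictly monotone")
        if not np.all(np.isfinite(y)):
            raise ValueError("y contains non-finite values")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)


# ---------------------------------------------------------------------------
# shared measurement helpers


def _two_step_trace(
    model: MarkovModel,
    current: CurrentModel,
    hold: float,
    v1: float,
    d1: float,
    v2: float,
    d2: float,
    dt1: float,
    dt2: float,
    initial_state: StateVector | None = None,
) -> SimulationTrace:
    """Depolarize (v1, d1) then repolarize (v2, d2) from the holding steady state."""
    # two sampling rates: simulate the two steps as separate protocols to
    # keep the depolarization finely sampled without oversampling the long
    # repolarization
    proto1 = VoltageProtocol(hold, (Step(v1, d1),), sample_interval_ms=dt1)
    tr1 = simulate(model, proto1, current, initial_state=initial_state)
    end_state = StateVector(tr1.occupancies[-1], model.states, tr1.time_ms[-1])
    proto2 = VoltageProtocol(hold, (Step(v2, d2),), sample_interval_ms=dt2)
    tr2 = simulate(model, proto2, current, initial_state=end_state)
    # stitch into a single trace with contiguous time
    t = np.concatenate([tr1.time_ms, tr2.time_ms[1:] + d1])
    v = np.concatenate([tr1.voltage_mV, tr2.voltage_mV[1:]])
    occ = np.vstack([tr1.occupancies, tr2.occupancies[1:]])
    p_open = np.concatenate([tr1.open_probability, tr2.open_probability[1:]])
    i = np.concatenate([tr1.current, tr2.current[1:]])
    return SimulationTrace(
        time_ms=t, voltage_mV=v, occupancies=occ, states=model.states,
        current=i, open_probability=p_open,
        segment_bounds=((0.0, d1), (d1, d1 + d2)),
        model_label=model.label, e_rev_mV=current.e_rev_mV,
    )


def _segment_peak(
    trace: SimulationTrace, segment: int, subtract: bool = True
) -> tuple[float, float, float]:
    """(|peak|, peak time, persistent level) of one protocol segment."""
    window = trace.segment_window(segment)
    if subtract:
        t, i_adj, level = subtract_persistent(trace, window)
        k = int(np.argmax(np.abs(i_adj)))
        return float(abs(i_adj[k])), float(t[k]), float(level)
    amp, t_peak = measure_peak(trace, window)
    return abs(amp), t_peak, 0.0


def _resurgent_peak(
    model: MarkovModel,
    current: CurrentModel,
    hold: float,
    dep_v: float,
    dep_ms: float,
    repol_v: float,
    repol_ms: float,
    dt_dep: float = DT_FAST,
    dt_repol: float = DT_SLOW,
    initial_state: StateVector | None = None,
    subtract: bool = True,
) -> tuple[float, float, SimulationTrace]:
    trace = _two_step_trace(
        model, current, hold, dep_v, dep_ms, repol_v, repol_ms, dt_dep, dt_repol,
        initial_state=initial_state,
    )
    amp, t_peak, _ = _segment_peak(trace, 1, subtract=subtract)
    return amp, t_peak, trace


# ---------------------------------------------------------------------------
# the nine optimization protocols


def availability_curve(
    model: MarkovModel,
    current: CurrentModel | None = None,
    conditioning_mV: Sequence[float] = tuple(np.arange(-120.0, -9.0, 5.0)),
    test_ms: float = 10.0,
    dt_ms: float = 0.002,
) -> SummaryCurve:
    """Steady-state availability (inactivation) curve.

    For each conditioning voltage the channel is equilibrated, then
    depolarized to 0 mV; the peak open probability is normalized to the
    value after conditioning at the most hyperpolarized voltage.
    """
    current = current or CurrentModel()
    peaks = []
    for v_cond in conditioning_mV:
        p0 = steady_state(model, v_cond)
        proto = VoltageProtocol(v_cond, (Step(0.0, test_ms),), sample_interval_ms=dt_ms)
        tr = simulate(model, proto, current, initial_state=p0)
        peaks.append(tr.open_probability.max())
    y = np.asarray(peaks) / peaks[0]
    return SummaryCurve(
        "availability", np.asarray(conditioning_mV), y,
        x_label="conditioning voltage (mV)", y_label="normalized peak P_open",
        metadata={"model": model.label, "test_ms": test_ms},
    )


def activation_curve(
    model: MarkovModel,
    current: CurrentModel | None = None,
    test_mV: Sequence[float] = tuple(np.arange(-77.0, 0.1, 3.0)) + (0.0,),
    test_ms: float = 10.0,
    dt_ms: float = 0.002,
    holding_mV: float = -80.0,
) -> SummaryCurve:
    """Conductance-voltage (activation) curve, normalized at 0 mV.

    With the ohmic current model the conductance G = I / (V - E_rev)
    equals g_max * P_open, so the normalized curve is the normalized peak
    open probability.
    """
    current = current or CurrentModel()
    p0 = steady_state(model, holding_mV)
    peaks = []
    for v in test_mV:
        proto = VoltageProtocol(holding_mV, (Step(v, test_ms),), sample_interval_ms=dt_ms)
        tr = simulate(model, proto, current, initial_state=p0)
        peaks.append(tr.open_probability.max())
    y = np.asarray(peaks) / peaks[-1]
    return SummaryCurve(
        "activation", np.asarray(test_mV), y,
        x_label="test voltage (mV)", y_label="normalized conductance",
        metadata={"model": model.label, "holding_mV": holding_mV},
    )


def inactivation_tau_curve(
    model: MarkovModel,
    current: CurrentModel | None = None,
    test_mV: Sequence[float] = tuple(np.arange(-50.0, 0.1, 5.0)),
    test_ms: float = 30.0,
    dt_ms: float = DT_FAST,
    holding_mV: float = -90.0,
) -> SummaryCurve:
    """Decay time constant (1/e) of the transient current per test voltage."""
    current = current or CurrentModel()
    p0 = steady_state(model, holding_mV)
    xs, taus = [], []
    for v in test_mV:
        proto = VoltageProtocol(holding_mV, (Step(v, test_ms),), sample_interval_ms=dt_ms)
        tr = simulate(model, proto, current, initial_state=p0)
        t, i_adj, _ = subtract_persistent(tr, tr.segment_window(0))
        try:
            taus.append(tau_one_over_e(t, i_adj))
            xs.append(v)
        except ValueError as err:
            warnings.warn(f"tau-inact: excluding V={v} mV ({err})", stacklevel=2)
    return SummaryCurve(
        "tau-inact", np.asarray(xs), np.asarray(taus),
        x_label="test voltage (mV)", y_label="tau (ms)",
        metadata={"model": model.label},
    )


def recovery_curve(
    model: MarkovModel,
    current: CurrentModel | None = None,
    intervals_ms: Sequence[float] = (1, 2, 3, 5, 7, 10, 15, 20, 30, 50, 75, 100, 150, 200, 300, 500),
    pulse_ms: float = 20.0,
    test_pulse_ms: float = 5.0,
    dt_ms: float = 0.002,
    holding_mV: float = -90.0,
) -> SummaryCurve:
    """Recovery of the transient current from inactivation at -90 mV.

    A conditioning pulse to 0 mV inactivates the channels; after a variable
    interval at the holding potential a second pulse measures the
    recovered fraction (second/first peak ratio).
    """
    current = current or CurrentModel()
    p0 = steady_state(model, holding_mV)
    proto1 = VoltageProtocol(holding_mV, (Step(0.0, pulse_ms),), sample_interval_ms=dt_ms)
    tr1 = simulate(model, proto1, current, initial_state=p0)
    peak1, _, _ = _segment_peak(tr1, 0, subtract=False)
    end1 = StateVector(tr1.occupancies[-1], model.states)
    ratios = []
    for interval in intervals_ms:
        proto = VoltageProtocol(
            holding_mV,
            (Step(holding_mV, float(interval)), Step(0.0, test_pulse_ms)),
            sample_interval_ms=dt_ms,
        )
        tr = simulate(model, proto, current, initial_state=end1)
        peak2, _, _ = _segment_peak(tr, 1, subtract=False)
        ratios.append(peak2 / peak1)
    return SummaryCurve(
        "recovery", np.asarray(intervals_ms, dtype=float), np.asarray(ratios),
        x_label="recovery interval (ms)", y_label="fractional recovery",
        metadata={"model": model.label, "pulse_ms": pulse_ms},
    )


def persistent_fraction(
    model: MarkovModel,
    current: CurrentModel | None = None,
    dep_ms: float = 5.0,
    repol_mV: float = -45.0,
    repol_ms: float = 100.0,
) -> float:
    """Persistent current at the end of a 100 ms step to -45 mV, as a
    fraction of the initial transient peak at 0 mV."""
    current = current or CurrentModel()
    trace = _two_step_trace(model, current, -90.0, 0.0, dep_ms, repol_mV, repol_ms,
                            DT_FAST, DT_SLOW)
    peak_t, _, _ = _segment_peak(trace, 0, subtract=False)
    _, _, level = subtract_persistent(trace, trace.segment_window(1))
    return float(abs(level) / peak_t)


def resurgent_ratio_curve(
    model: MarkovModel,
    current: CurrentModel | None = None,
    repol_mV: Sequence[float] = tuple(np.arange(-80.0, -4.0, 5.0)),
    holding_mV: float = -90.0,
    dep_mV: float = 0.0,
    dep_ms: float = 5.0,
    repol_ms: float = DEFAULT_REPOL_MS,
    dt_dep: float = DT_FAST,
    dt_repol: float = DT_SLOW,
    normalize: bool = True,
) -> SummaryCurve:
    """Peak resurgent current per repolarization voltage.

    With ``normalize`` the peaks are expressed relative to the peak
    transient current of the depolarizing step (the I_NaR : I_NaT ratio);
    without it, absolute persistent-subtracted peak amplitudes are
    returned (the raw voltage-dependence paradigm).
    """
    current = current or CurrentModel()
    p0 = steady_state(model, holding_mV)
    peaks = []
    inat = None
    for v in repol_mV:
        amp, _, trace = _resurgent_peak(
            model, current, holding_mV, dep_mV, dep_ms, v, repol_ms,
            dt_dep, dt_repol, initial_state=p0,
        )
        if inat is None:
            # brief depolarizing step: measure the transient peak raw (the
            # persistent level is tiny relative to the transient peak, so
            # subtracted and raw peaks are indistinguishable)
            inat, _, _ = _segment_peak(trace, 0, subtract=False)
        peaks.append(amp)
    y = np.asarray(peaks) / (inat if normalize else 1.0)
    return SummaryCurve(
        "inar-ratio" if normalize else "inar-voltage",
        np.asarray(repol_mV), y,
        x_label="repolarization voltage (mV)",
        y_label="I_NaR / I_NaT" if normalize else "peak I_NaR (norm. units)",
        metadata={"model": model.label, "holding_mV": holding_mV, "dep_mV": dep_mV},
    )


def duration_dependence(
    model: MarkovModel,
    current: CurrentModel | None = None,
    durations_ms: Sequence[float] = tuple(np.arange(2.0, 37.0, 2.0)),
    dep_mV: float = 20.0,
    repol_mV: float = -45.0,
    repol_ms: float = DEFAULT_REPOL_MS,
    holding_mV: float = -90.0,
    dt_dep: float = 0.002,
    dt_repol: float = DT_SLOW,
) -> SummaryCurve:
    """Attenuation of the peak resurgent current with prepulse duration.

    Depolarizations to +20 mV of increasing duration drive progressively
    more channels into the slow-inactivated state, attenuating the
    resurgent current revealed at -45 mV; peaks are normalized to the
    shortest (2 ms) prepulse.
    """
    current = current or CurrentModel()
    p0 = steady_state(model, holding_mV)
    peaks = []
    for dur in durations_ms:
        amp, _, _ = _resurgent_peak(
            model, current, holding_mV, dep_mV, float(dur), repol_mV, repol_ms,
            dt_dep, dt_repol, initial_state=p0,
        )
        peaks.append(amp)
    y = np.asarray(peaks) / peaks[0]
    return SummaryCurve(
        "duration", np.asarray(durations_ms, dtype=float), y,
        x_label="prepulse duration (ms)", y_label="normalized peak I_NaR",
        metadata={"model": model.label, "dep_mV": dep_mV, "repol_mV": repol_mV},
    )


def resurgent_decay_taus(
    model: MarkovModel,
    current: CurrentModel | None = None,
    repol_mV: Sequence[float] = tuple(np.arange(-45.0, -4.0, 5.0)),
    holding_mV: float = -90.0,
    dep_ms: float = 5.0,
    repol_ms: float = DEFAULT_REPOL_MS,
    dt_repol: float = DT_SLOW,
) -> SummaryCurve:
    """Decay time constant (1/e) of the resurgent current per voltage."""
    current = current or CurrentModel()
    p0 = steady_state(model, holding_mV)
    xs, taus = [], []
    for v in repol_mV:
        _, _, trace = _resurgent_peak(
            model, current, holding_mV, 0.0, dep_ms, v, repol_ms,
            DT_FAST, dt_repol, initial_state=p0,
        )
        t, i_adj, _ = subtract_persistent(trace, trace.segment_window(1))
        try:
            taus.append(tau_one_over_e(t, i_adj))
            xs.append(v)
        except ValueError as err:
            warnings.warn(f"inar-tau: excluding V={v} mV ({err})", stacklevel=2)
    return SummaryCurve(
        "inar-tau", np.asarray(xs), np.asarray(taus),
        x_label="repolarization voltage (mV)", y_label="tau (ms)",
        metadata={"model": model.label},
    )


def prepulse_peak_spread(
    model: MarkovModel,
    current: CurrentModel | None = None,
    prepulse_mV: Sequence[float] = tuple(np.arange(-35.0, -4.0, 5.0)),
    prepulse_ms: float = 5.0,
    repol_mV: float = -45.0,
    repol_ms: float = DEFAULT_REPOL_MS,
    holding_mV: float = -90.0,
) -> tuple[SummaryCurve, float]:
    """Peak resurgent current per prepulse voltage and its coefficient of
    variation.

    The resurgent current's independence of the prepulse potential is the
    model's hallmark; the CV quantifies it.
    """
    current = current or CurrentModel()
    p0 = steady_state(model, holding_mV)
    peaks = []
    for v in prepulse_mV:
        amp, _, _ = _resurgent_peak(
            model, current, holding_mV, float(v), prepulse_ms, repol_mV, repol_ms,
            DT_FAST, DT_SLOW, initial_state=p0,
        )
        peaks.append(amp)
    peaks_arr = np.asarray(peaks)
    cv = float(peaks_arr.std() / peaks_arr.mean())
    curve = SummaryCurve(
        "prepulse", np.asarray(prepulse_mV), peaks_arr,
        x_label="prepulse voltage (mV)", y_label="peak I_NaR (norm. units)",
        metadata={"model": model.label, "cv": cv},
    )
    return curve, cv


# ---------------------------------------------------------------------------
# figure-level paradigms


def sequential_recovery(
    model: MarkovModel,
    current: CurrentModel | None = None,
    gap_ms: float = 20.0,
) -> tuple[float, float]:
    """Two identical (0 mV / -45 mV) protocols separated by a brief gap.

    Returns ``(relative_I_NaT, relative_I_NaR)``: the ratios of the second
    protocol's transient and resurgent peaks to the first's.  The
    single-population model recovers both components together over the
    20 ms gap at -90 mV, so the two ratios come out nearly equal (it does
    not reproduce the differential recovery seen experimentally).
    """
    current = current or CurrentModel()
    hold = -90.0
    p0 = steady_state(model, hold)
    tr1 = _two_step_trace(model, current, hold, 0.0, 5.0, -45.0, 100.0, DT_FAST, DT_SLOW,
                          initial_state=p0)
    inat1, _, _ = _segment_peak(tr1, 0, subtract=False)
    inar1, _, _ = _segment_peak(tr1, 1)
    gap_proto = VoltageProtocol(hold, (Step(hold, gap_ms),), sample_interval_ms=DT_SLOW)
    end1 = StateVector(tr1.occupancies[-1], model.states)
    gap_tr = simulate(model, gap_proto, current, initial_state=end1)
    end_gap = StateVector(gap_tr.occupancies[-1], model.states)
    tr2 = _two_step_trace(model, current, hold, 0.0, 5.0, -45.0, 100.0, DT_FAST, DT_SLOW,
                          initial_state=end_gap)
    inat2, _, _ = _segment_peak(tr2, 0, subtract=False)
    inar2, _, _ = _segment_peak(tr2, 1)
    return inat2 / inat1, inar2 / inar1


def envelope_comparison(
    model: MarkovModel,
    current: CurrentModel | None = None,
    sustained_ms: float = 80.0,
    brief_repol_ms: float = 2.0,
    brief_dep_ms: float = 5.0,
) -> tuple[SimulationTrace, SimulationTrace, float]:
    """Envelope test: sustained vs repetitive brief repolarizations.

    The sustained protocol is 5 ms at 0 mV then ``sustained_ms`` at
    -45 mV; the repetitive protocol interleaves 2 ms steps to -45 mV with
    5 ms depolarizations to 0 mV over the same span.  Each repetition's
    peak current is compared with the sustained current at the same
    absolute time after the first repolarization onset;
    ``envelope_deviation`` is the largest mismatch relative to the peak
    sustained current.
    """
    current = current or CurrentModel()
    hold = -90.0
    p0 = steady_state(model, hold)
    sustained = _two_step_trace(
        model, current, hold, 0.0, 5.0, -45.0, sustained_ms, DT_FAST, DT_SLOW,
        initial_state=p0,
    )
    cycle_ms = brief_repol_ms + brief_dep_ms
    n_cycles = int(np.floor((sustained_ms - brief_repol_ms) / cycle_ms)) + 1
    segments: list[Step] = [Step(0.0, brief_dep_ms)]
    for k in range(n_cycles):
        segments.append(Step(-45.0, brief_repol_ms))
        if k < n_cycles - 1:
            segments.append(Step(0.0, brief_dep_ms))
    proto = VoltageProtocol(hold, tuple(segments), sample_interval_ms=DT_SLOW)
    repetitive = simulate(model, proto, current, initial_state=p0)

    # sustained reference: |I| at -45 mV vs time since repolarization onset
    sus_window = sustained.segment_window(1)
    sus_mask = sustained.window_mask(*sus_window)
    sus_t = sustained.time_ms[sus_mask] - sus_window[0]
    sus_i = np.abs(sustained.current[sus_mask])
    peak_sus = sus_i.max()

    deviations = []
    for seg_idx in range(1, len(repetitive.segment_bounds), 2):
        window = repetitive.segment_window(seg_idx)
        amp, t_peak = measure_peak(repetitive, window)
        t_abs = t_peak - repetitive.segment_window(1)[0]  # since first repol onset
        if t_abs > sus_t[-1]:
            continue
        ref = float(np.interp(t_abs, sus_t, sus_i))
        deviations.append(abs(abs(amp) - ref) / peak_sus)
    return sustained, repetitive, float(max(deviations))


def ramp_current(
    model: MarkovModel,
    current: CurrentModel | None = None,
    direction: str = "up",
    slope_mV_per_ms: float = 0.12,
    v_low: float = -100.0,
    v_high: float = 0.0,
    sample_ms: float = 2.0,
    ramp_delta_v: float = 0.25,
) -> SummaryCurve:
    """Current-voltage relation during a slow voltage ramp.

    The depolarizing ("up") ramp from -100 to 0 mV carries only the
    persistent component; the hyperpolarizing ("down") ramp from 0 to
    -100 mV (starting from the steady state at 0 mV) additionally carries
    any resurgent component.  At 0.12 mV/ms the two relations nearly
    overlap.
    """
    current = current or CurrentModel()
    if direction == "up":
        hold, ramp = v_low, Ramp(v_low, v_high, slope_mV_per_ms)
    elif direction == "down":
        hold, ramp = v_high, Ramp(v_high, v_low, slope_mV_per_ms)
    else:
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    proto = VoltageProtocol(hold, (ramp,), sample_interval_ms=sample_ms,
                            ramp_delta_v_mV=ramp_delta_v)
    trace = simulate(model, proto, current)
    # one sample per <= sample_ms, skipping the duplicate t=0 holding point
    v, i = trace.voltage_mV[1:], trace.current[1:]
    # voltage is piecewise constant over sub-steps; average samples per sub-step
    uniq_v = np.unique(v)
    xs, ys = [], []
    for vv in uniq_v:
        mask = v == vv
        xs.append(vv)
        ys.append(i[mask].mean())
    xs = np.asarray(xs)
    ys = np.asarray(ys)
    if direction == "down":
        xs, ys = xs[::-1], ys[::-1]
    return SummaryCurve(
        f"ramp-{direction}", xs, ys,
        x_label="voltage (mV)", y_label="current (norm. units)",
        metadata={"model": model.label, "slope_mV_per_ms": slope_mV_per_ms},
    )


def three_component_trace(
    model: MarkovModel,
    current: CurrentModel | None = None,
    holding_mV: float = -80.0,
    dep_ms: float = 5.0,
    repol_mV: float = -45.0,
    repol_ms: float = 100.0,
) -> SimulationTrace:
    """The classic paradigm revealing all three current components.

    A brief step to 0 mV evokes the fast transient current decaying to the
    persistent plateau; the subsequent repolarization reveals the slower
    resurgent current.
    """
    current = current or CurrentModel()
    return _two_step_trace(model, current, holding_mV, 0.0, dep_ms,
                           repol_mV, repol_ms, DT_FAST, DT_SLOW)
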