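"""Serialization of traces, summary curves and fit results.

Everything is plain delimited text (comma-separated, '.' decimal, UTF-8)
with a commented header carrying provenance: model label, parameter hash
and run settings.  Times are in ms, voltages in mV, currents in
normalized units (g_max = 1).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .optimize import FitResult
from .parameters import RateParameterSet, load_parameters, save_parameters
from .propagation import SimulationTrace
from .protocols import SummaryCurve

__all__ = [
    "write_trace_csv",
    "write_summary_csv",
    "read_summary_csv",
    "write_fit_result",
    "load_parameters",
    "save_parameters",
]


def _header_lines(meta: dict) -> str:
    return "".join(f"# {key} = {value}\n" for key, value in meta.items())


def write_trace_csv(trace: SimulationTrace, path: str | Path,
                    params: RateParameterSet | None = None) -> None:
    """Write a simulation trace: time, voltage, occupancies, P_open, current."""
    frame = pd.DataFrame({"time_ms": trace.time_ms, "voltage_mV": trace.voltage_mV})
    for i, state in enumerate(trace.states):
        frame[f"p_{state}"] = trace.occupancies[:, i]
    frame["open_probability"] = trace.open_probability
    frame["current"] = trace.current
    meta = {"model": trace.model_label, "e_rev_mV": trace.e_rev_mV}
    if params is not None:
        meta["parameter_hash"] = params.content_hash()
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_header_lines(meta))
        frame.to_csv(fh, index=False, float_format="%.10g")


def write_summary_csv(curve: SummaryCurve, path: str | Path,
                      params: RateParameterSet | None = None) -> None:
    """Write a protocol summary curve as (x, y) rows with a provenance header."""
    meta = {"protocol": curve.protocol_id, **curve.metadata}
    if params is not None:
        meta["parameter_hash"] = params.content_hash()
    frame = pd.DataFrame({curve.x_label: curve.x, curve.y_label: curve.y})
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_header_lines(meta))
        frame.to_csv(fh, index=False, float_format="%.10g")


def read_summary_csv(path: str | Path) -> SummaryCurve:
    """Read a summary curve written by :func:`write_summary_csv`."""
    path = Path(path)
    meta: dict[str, str] = {}
    rows = []
    header: list[str] | None = None
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            meta[key.strip()] = value.strip()
        elif header is None:
            header = line.split(",")
        elif line.strip():
            rows.append([float(v) for v in line.split(",")])
    if header is None or not rows:
        raise ValueError(f"no data rows in {path}")
    data = np.asarray(rows)
    return SummaryCurve(
        protocol_id=meta.get("protocol", path.stem),
        x=data[:, 0], y=data[:, 1],
        x_label=header[0], y_label=header[1],
        metadata={k: v for k, v in meta.items() if k != "protocol"},
    )


def write_fit_result(result: FitResult, directory: str | Path, stem: str = "fit") -> None:
    """Serialize a fit: fitted parameter file plus a cost-trace CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_parameters(result.params, directory / f"{stem}.params")
    trace = pd.DataFrame({
        "evaluation": np.arange(1, len(result.cost_trace) + 1),
        "best_cost": result.cost_trace,
    })
    with (directory / f"{stem}_cost_trace.csv").open("w") as fh:
        fh.write(_header_lines({
            "final_cost": result.cost,
            "initial_cost": result.initial_cost,
            "n_evaluations": result.n_evaluations,
            "converged": result.converged,
            "parameter_hash": result.params.content_hash(),
        }))
        trace.to_csv(fh, index=False)
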