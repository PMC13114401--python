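"""Persistence: chains and traces to HDF5, traces to delimited text."""

from __future__ import annotations

import json

import h5py
import numpy as np

from .samplers import ChainRecord
from .wave_forward import ObservationGrid, TraceMatrix

__all__ = [
    "save_chain",
    "load_chain",
    "save_traces",
    "load_traces",
    "save_traces_text",
    "load_traces_text",
]


def save_chain(path: str, chain: ChainRecord) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=chain.samples, compression="gzip")
        f.create_dataset("log_posts", data=chain.log_posts, compression="gzip")
        f.create_dataset("accepted", data=chain.accepted.astype(np.uint8), compression="gzip")
        f.attrs["seed"] = -1 if chain.seed is None else int(chain.seed)
        f.attrs["burn_in_fraction"] = chain.burn_in_fraction
        f.attrs["meta"] = json.dumps(chain.meta, default=str)


def load_chain(path: str) -> ChainRecord:
    with h5py.File(path, "r") as f:
        seed = int(f.attrs["seed"])
        return ChainRecord(
            samples=f["samples"][...],
            log_posts=f["log_posts"][...],
            accepted=f["accepted"][...].astype(bool),
            seed=None if seed < 0 else seed,
            burn_in_fraction=float(f.attrs["burn_in_fraction"]),
            meta=json.loads(f.attrs["meta"]),
        )


def save_traces(path: str, traces: TraceMatrix, extra: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=traces.values)
        f.create_dataset("receivers", data=traces.grid.receivers)
        f.create_dataset("times", data=traces.grid.times)
        for k, v in (extra or {}).items():
            if isinstance(v, np.ndarray):
                f.create_dataset(k, data=v)
            else:
                f.attrs[k] = v


def load_traces(path: str) -> TraceMatrix:
    with h5py.File(path, "r") as f:
        grid = ObservationGrid(f["receivers"][...], f["times"][...])
        return TraceMatrix(f["values"][...], grid)


def save_traces_text(path: str, traces: TraceMatrix, delimiter: str = "\t") -> None:
    """One row per receiver, columns = observation times, header of t_m."""
    header = delimiter.join(f"{t:.12g}" for t in traces.grid.times)
    np.savetxt(path, traces.values, delimiter=delimiter, header=header)


def load_traces_text(path: str, receivers: np.ndarray, delimiter: str = "\t") -> TraceMatrix:
    with open(path) as f:
        header = f.readline().lstrip("# ").strip()
    times = np.array([float(t) for t in header.split(delimiter)])
    values = np.atleast_2d(np.loadtxt(path, delimiter=delimiter, skiprows=1))
    return TraceMatrix(values, ObservationGrid(receivers, times))
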