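"""Domain containers and plain-text I/O for single-cell fluorescence trajectories.

The experiment layout this package targets is a live-imaging time course of a
population of cells carrying fluorescent-protein reporters (primary channel
``PPARG``, optional ``FABP4``), sampled on a regular grid (nominally one frame
every 0.2 h over 0-96 h). Intensities are arbitrary units (AU), already
background-corrected. Endpoint snapshots (fixed-cell intensities at one time)
and cycloheximide-chase mean-intensity series get their own small containers.

File formats are deliberately boring: long-format CSV for trajectories
(``cell_id,condition,time_h,channel,intensity``), CSV for endpoint snapshots
(``cell_id,condition,intensity``) and decay tables (``time_h,replicate,
intensity``), and a JSON sidecar for simulator ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TimeGrid",
    "CellTrace",
    "CellTruth",
    "TrajectorySet",
    "EndpointSnapshot",
    "DecayTable",
    "SchemaError",
    "ParseError",
    "IntegrityError",
    "read_traces",
    "write_traces",
    "read_endpoint",
    "write_endpoint",
    "read_decay",
    "write_decay",
    "validate",
]

DEFAULT_SCHEMA = {
    "cell_id": "cell_id",
    "condition": "condition",
    "time_h": "time_h",
    "channel": "channel",
    "intensity": "intensity",
}

_TIME_ATOL = 1e-6


class SchemaError(ValueError):
    """A required column is missing or the schema map is unusable."""


class ParseError(ValueError):
    """A cell of the table could not be parsed as the expected type."""


class IntegrityError(ValueError):
    """Duplicate keys or structurally inconsistent rows."""


@dataclass(frozen=True)
class TimeGrid:
    """Regular acquisition grid: ``start + step * i`` for ``i in range(n_frames)``."""

    start: float = 0.0
    step: float = 0.2
    n_frames: int = 481

    @property
    def end(self) -> float:
        return self.start + self.step * (self.n_frames - 1)

    def times(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n_frames)

    def index_of(self, t: float) -> int:
        """Grid index of time ``t``; raises if ``t`` is off-grid."""
        idx = round((t - self.start) / self.step)
        if idx < 0 or idx >= self.n_frames or abs(self.start + self.step * idx - t) > _TIME_ATOL:
            raise ValueError(f"time {t} is not on grid {self}")
        return int(idx)


@dataclass
class CellTrace:
    """One cell's aligned intensity time series across one or more channels."""

    cell_id: str
    condition: str
    times: np.ndarray
    channels: dict[str, np.ndarray]

    def values(self, channel: str) -> np.ndarray:
        if channel not in self.channels:
            raise KeyError(f"cell {self.cell_id}: channel {channel!r} not present")
        return self.channels[channel]

    def value_at(self, t: float) -> dict[str, float]:
        i = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[i] - t) > _TIME_ATOL:
            raise ValueError(f"cell {self.cell_id} has no frame at t={t}")
        return {ch: float(v[i]) for ch, v in self.channels.items()}


@dataclass
class CellTruth:
    """Simulator ground truth for one cell (absent for real data)."""

    fate: str  # "differentiated" | "undifferentiated"
    hit_time_h: float | None = None
    tau_A_h: float | None = None
    tau_F_h: float | None = None


@dataclass
class TrajectorySet:
    """A population of traces aligned to a shared regular time grid.

    Traces may cover a contiguous sub-window of the grid (head/tail truncation
    encodes tracking gaps); interior gaps are not representable.
    """

    grid: TimeGrid
    traces: list[CellTrace] = field(default_factory=list)
    truth: dict[str, CellTruth] | None = None

    @property
    def conditions(self) -> set[str]:
        return {tr.condition for tr in self.traces}

    @property
    def n_cells(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)

    def subset(self, cell_ids) -> "TrajectorySet":
        keep = set(cell_ids)
        traces = [tr for tr in self.traces if tr.cell_id in keep]
        truth = None
        if self.truth is not None:
            truth = {cid: t for cid, t in self.truth.items() if cid in keep}
        return TrajectorySet(self.grid, traces, truth)

    def matrix(self, channel: str) -> tuple[np.ndarray, list[str]]:
        """(n_cells, n_frames) matrix of ``channel`` values, NaN where a trace
        does not cover a frame, plus the row order of cell ids."""
        out = np.full((len(self.traces), self.grid.n_frames), np.nan)
        ids = []
        for i, tr in enumerate(self.traces):
            if channel not in tr.channels:
                continue
            i0 = self.grid.index_of(float(tr.times[0]))
            out[i, i0 : i0 + len(tr.times)] = tr.channels[channel]
            ids.append(tr.cell_id)
        return out, [tr.cell_id for tr in self.traces]

    def values_at(self, t: float, channel: str) -> tuple[np.ndarray, list[str]]:
        """Per-cell values of ``channel`` at grid time ``t`` for cells covering it."""
        j = self.grid.index_of(t)
        vals, ids = [], []
        for tr in self.traces:
            if channel not in tr.channels:
                continue
            i0 = self.grid.index_of(float(tr.times[0]))
            k = j - i0
            if 0 <= k < len(tr.times):
                vals.append(tr.channels[channel][k])
                ids.append(tr.cell_id)
        return np.asarray(vals, dtype=float), ids

    def endpoint_values(self, channel: str) -> "EndpointSnapshot":
        """Each cell's value at its own last frame (the experiment endpoint for
        full traces; QC guarantees the last frame is near the grid end)."""
        vals, ids, conds = [], [], []
        for tr in self.traces:
            if channel not in tr.channels:
                continue
            vals.append(float(tr.channels[channel][-1]))
            ids.append(tr.cell_id)
            conds.append(tr.condition)
        return EndpointSnapshot(
            values=np.asarray(vals, dtype=float),
            cell_ids=ids,
            conditions=conds,
            channel=channel,
        )


@dataclass
class EndpointSnapshot:
    """Per-cell intensities for one channel at one fixed time."""

    values: np.ndarray
    cell_ids: list[str] | None = None
    conditions: list[str] | None = None
    channel: str = "PPARG"
    time_h: float | None = None


@dataclass
class DecayTable:
    """Cycloheximide-chase series: mean intensity vs hours post-block."""

    times: np.ndarray
    values: np.ndarray
    replicates: np.ndarray | None = None


# ---------------------------------------------------------------------------
# trajectory CSV I/O


def _resolve_schema(columns, schema) -> dict[str, str]:
    sch = dict(DEFAULT_SCHEMA)
    if schema:
        sch.update(schema)
    missing = [v for v in sch.values() if v not in columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}; found {list(columns)}")
    return sch


def _truth_sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".truth.json")


def read_traces(path, schema: dict[str, str] | None = None) -> TrajectorySet:
    """Load a long-format trajectory CSV into a :class:`TrajectorySet`.

    The grid is inferred as the union of observed times; every trace must
    occupy a contiguous sub-window of it. A ground-truth sidecar
    (``<path>.truth.json``) is loaded if present.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)  # parse numerics explicitly for row-level errors
    sch = _resolve_schema(df.columns, schema)
    df = df.rename(columns={v: k for k, v in sch.items()})

    grid_default = TimeGrid(0.0, 0.2, 1)
    if df.empty:
        return TrajectorySet(grid_default, [])

    for col in ("time_h", "intensity"):
        num = pd.to_numeric(df[col], errors="coerce")
        bad = num.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # +1 header, +1 zero-base
            raise ParseError(f"non-numeric {col} at file row {row}: {df[col][bad.idxmax()]!r}")
        if num.isna().any():
            row = int(num.isna().idxmax()) + 2
            raise ParseError(f"empty {col} at file row {row}")
        df[col] = num

    dup = df.duplicated(subset=["cell_id", "time_h", "channel"], keep=False)
    if dup.any():
        key = df.loc[dup, ["cell_id", "time_h", "channel"]].iloc[0].tolist()
        raise IntegrityError(f"duplicate (cell, time, channel) rows, first: {key}")

    all_times = np.sort(df["time_h"].unique())
    if len(all_times) == 1:
        grid = TimeGrid(float(all_times[0]), 0.2, 1)
    else:
        step = float(np.min(np.diff(all_times)))
        n = int(round((all_times[-1] - all_times[0]) / step)) + 1
        grid = TimeGrid(float(all_times[0]), step, n)
        on_grid = np.abs((all_times - grid.start) / step - np.round((all_times - grid.start) / step))
        if np.any(on_grid * step > _TIME_ATOL):
            raise IntegrityError("observed times do not lie on a single regular grid")

    traces: list[CellTrace] = []
    for cell_id, sub in df.groupby("cell_id", sort=True):
        conds = sub["condition"].unique()
        if len(conds) != 1:
            raise IntegrityError(f"cell {cell_id} has multiple condition labels: {list(conds)}")
        piv = sub.pivot(index="time_h", columns="channel", values="intensity").sort_index()
        times = piv.index.to_numpy(dtype=float)
        channels = {str(ch): piv[ch].to_numpy(dtype=float) for ch in piv.columns}
        traces.append(CellTrace(str(cell_id), str(conds[0]), times, channels))

    truth = None
    sidecar = _truth_sidecar(path)
    if sidecar.exists():
        raw = json.loads(sidecar.read_text())
        truth = {
            cid: CellTruth(
                fate=rec["fate"],
                hit_time_h=rec.get("hit_time_h"),
                tau_A_h=rec.get("tau_A_h"),
                tau_F_h=rec.get("tau_F_h"),
            )
            for cid, rec in raw.items()
        }

    ts = TrajectorySet(grid, traces, truth)
    problems = validate(ts)
    if problems:
        raise IntegrityError("invalid trajectory file: " + "; ".join(problems[:5]))
    return ts


def write_traces(ts: TrajectorySet, path, truth_path=None) -> None:
    """Write a long-format trajectory CSV (9 significant digits, lossless for
    the simulator's float32-free values); truth goes to a JSON sidecar."""
    path = Path(path)
    rows = []
    for tr in ts.traces:
        for ch, vals in tr.channels.items():
            for t, v in zip(tr.times, vals):
                rows.append((tr.cell_id, tr.condition, t, ch, v))
    df = pd.DataFrame(rows, columns=["cell_id", "condition", "time_h", "channel", "intensity"])
    df.to_csv(path, index=False, float_format="%.12g")
    if ts.truth is not None:
        tp = Path(truth_path) if truth_path is not None else _truth_sidecar(path)
        payload = {
            cid: {
                "fate": t.fate,
                "hit_time_h": t.hit_time_h,
                "tau_A_h": t.tau_A_h,
                "tau_F_h": t.tau_F_h,
            }
            for cid, t in ts.truth.items()
        }
        tp.write_text(json.dumps(payload, indent=0, sort_keys=True))


def read_endpoint(path) -> EndpointSnapshot:
    df = pd.read_csv(path)
    for col in ("cell_id", "condition", "intensity"):
        if col not in df.columns:
            raise SchemaError(f"endpoint file missing column {col!r}")
    values = pd.to_numeric(df["intensity"], errors="raise").to_numpy(dtype=float)
    return EndpointSnapshot(
        values=values,
        cell_ids=df["cell_id"].astype(str).tolist(),
        conditions=df["condition"].astype(str).tolist(),
    )


def write_endpoint(snap: EndpointSnapshot, path) -> None:
    n = len(snap.values)
    df = pd.DataFrame(
        {
            "cell_id": snap.cell_ids if snap.cell_ids is not None else [str(i) for i in range(n)],
            "condition": snap.conditions if snap.conditions is not None else ["?"] * n,
            "intensity": snap.values,
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_decay(path) -> DecayTable:
    df = pd.read_csv(path)
    if "time_h" not in df.columns or "intensity" not in df.columns:
        raise SchemaError("decay file needs columns time_h, intensity (replicate optional)")
    rep = df["replicate"].to_numpy() if "replicate" in df.columns else None
    return DecayTable(
        times=df["time_h"].to_numpy(dtype=float),
        values=df["intensity"].to_numpy(dtype=float),
        replicates=rep,
    )


def write_decay(table: DecayTable, path) -> None:
    df = pd.DataFrame({"time_h": table.times, "intensity": table.values})
    if table.replicates is not None:
        df.insert(1, "replicate", table.replicates)
    df.to_csv(path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# validation


def validate(ts: TrajectorySet) -> list[str]:
    """Report (not raise) every invariant violation in ``ts``.

    An empty list means the set is valid: strictly increasing times, channel
    series matching the time axis, finite non-negative intensities, traces
    contiguous on the grid, truth (if present) covering exactly the cells.
    """
    problems: list[str] = []
    g = ts.grid
    for tr in ts.traces:
        cid = tr.cell_id
        t = np.asarray(tr.times, dtype=float)
        if t.ndim != 1 or len(t) == 0:
            problems.append(f"{cid}: empty or non-1D time axis")
            continue
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            problems.append(f"{cid}: times not strictly increasing")
        try:
            i0 = g.index_of(float(t[0]))
            expected = g.start + g.step * (i0 + np.arange(len(t)))
            if np.max(np.abs(expected - t)) > _TIME_ATOL:
                problems.append(f"{cid}: times not a contiguous grid sub-window")
        except ValueError:
            problems.append(f"{cid}: start time off the grid")
        if not tr.channels:
            problems.append(f"{cid}: no channels")
        for ch, v in tr.channels.items():
            v = np.asarray(v, dtype=float)
            if len(v) != len(t):
                problems.append(f"{cid}: channel {ch} length {len(v)} != {len(t)} frames")
                continue
            if not np.all(np.isfinite(v)):
                problems.append(f"{cid}: channel {ch} has non-finite intensities")
            elif np.any(v < 0):
                problems.append(f"{cid}: channel {ch} has negative intensities")
    ids = [tr.cell_id for tr in ts.traces]
    if len(set(ids)) != len(ids):
        problems.append("duplicate cell_id in trace list")
    if ts.truth is not None:
        missing = set(ids) - set(ts.truth)
        extra = set(ts.truth) - set(ids)
        if missing:
            problems.append(f"truth missing for {len(missing)} cell(s), e.g. {sorted(missing)[:3]}")
        if extra:
            problems.append(f"truth has {len(extra)} unknown cell id(s), e.g. {sorted(extra)[:3]}")
    return problems
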