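"""Slope analysis, feedback-engagement detection, and path geometry.

The feedback-engagement points are visible as abrupt increases in the slope
of the PPARG trajectory. Slopes are estimated by ordinary least squares over
a sliding +/-4 h window; engagement is detected when the slope exceeds a
multiple of its early-baseline value and stays there. Two further views of
the two-reporter geometry are provided: per-cell min-max normalization of the
(PPARG, FABP4) plane onto the unit square — differentiating cells run below
the diagonal because PPARG rises first — and averaging of traces binned by
their PPARG level at a reference time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .traces import CellTrace, TrajectorySet

__all__ = [
    "SlopeSeries",
    "NormalizedPathSet",
    "BinnedTraces",
    "sliding_window_slope",
    "population_mean_slope",
    "detect_engagement",
    "unit_square_normalize",
    "bin_and_average",
    "fold_change",
]


@dataclass
class SlopeSeries:
    """Windowed OLS slope (AU/h or normalized/h) at each frame of a trace."""

    times: np.ndarray
    slopes: np.ndarray
    valid: np.ndarray
    half_window_h: float


@dataclass
class NormalizedPathSet:
    """Per-cell unit-square (PPARG, FABP4) paths plus the ensemble mean path.

    ``asymmetry`` is the signed area between the mean path and the diagonal,
    positive when the path runs below the diagonal (x rises before y).
    """

    paths: dict[str, np.ndarray]
    mean_path: np.ndarray
    asymmetry: float
    skipped: list[str]


@dataclass
class BinnedTraces:
    """Quantile-binned population: per-bin mean trace for every channel."""

    bin_of: dict[str, int]
    mean_traces: dict[str, np.ndarray]  # channel -> (n_bins, n_frames)
    times: np.ndarray
    bin_time_h: float


def sliding_window_slope(
    trace: CellTrace,
    channel: str = "PPARG",
    half_window_h: float = 4.0,
    min_frames: int = 5,
) -> SlopeSeries:
    """OLS slope of ``channel`` vs time over the frames within +/-``half_window_h``
    of each frame; masked where fewer than ``min_frames`` frames fall in the
    window."""
    if channel not in trace.channels:
        raise KeyError(f"channel {channel!r} not present in cell {trace.cell_id}")
    t = np.asarray(trace.times, dtype=float)
    y = np.asarray(trace.channels[channel], dtype=float)
    if len(t) < min_frames:
        raise ValueError(f"trace has {len(t)} frames; need >= {min_frames}")
    lo = np.searchsorted(t, t - half_window_h, side="left")
    hi = np.searchsorted(t, t + half_window_h, side="right")
    # windowed first/second moments via prefix sums
    c1 = np.concatenate([[0.0], np.cumsum(t)])
    c2 = np.concatenate([[0.0], np.cumsum(t * t)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cty = np.concatenate([[0.0], np.cumsum(t * y)])
    n = (hi - lo).astype(float)
    st = c1[hi] - c1[lo]
    stt = c2[hi] - c2[lo]
    sy = cy[hi] - cy[lo]
    sty = cty[hi] - cty[lo]
    denom = n * stt - st * st
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = (n * sty - st * sy) / denom
    valid = (n >= min_frames) & (denom > 0)
    slopes = np.where(valid, slopes, np.nan)
    return SlopeSeries(times=t, slopes=slopes, valid=valid, half_window_h=half_window_h)


def population_mean_slope(
    ts: TrajectorySet,
    channel: str = "PPARG",
    fates: dict[str, str] | None = None,
    half_window_h: float = 4.0,
    min_coverage: float = 0.5,
) -> dict[str, SlopeSeries]:
    """Pointwise mean slope per fate group, masked at frames where fewer than
    ``min_coverage`` of the group's cells contribute. With ``fates=None`` all
    cells form a single group ``"all"``."""
    groups: dict[str, list[CellTrace]] = {}
    for tr in ts.traces:
        g = fates.get(tr.cell_id, None) if fates is not None else "all"
        if g is None:
            continue
        groups.setdefault(g, []).append(tr)
    out: dict[str, SlopeSeries] = {}
    grid_t = ts.grid.times()
    for g, members in groups.items():
        if not members:
            warnings.warn(f"fate group {g!r} is empty; omitted")
            continue
        acc = np.zeros(ts.grid.n_frames)
        cnt = np.zeros(ts.grid.n_frames)
        for tr in members:
            ss = sliding_window_slope(tr, channel, half_window_h)
            i0 = ts.grid.index_of(float(tr.times[0]))
            sl = np.where(ss.valid, ss.slopes, 0.0)
            acc[i0 : i0 + len(sl)] += sl
            cnt[i0 : i0 + len(sl)] += ss.valid.astype(float)
        valid = cnt >= min_coverage * len(members)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(valid, acc / cnt, np.nan)
        out[g] = SlopeSeries(times=grid_t, slopes=mean, valid=valid,
                             half_window_h=half_window_h)
    return out


def detect_engagement(
    slopes: SlopeSeries,
    baseline_window: tuple[float, float] = (8.0, 16.0),
    factor: float = 2.0,
    persistence_h: float = 2.0,
    baseline_floor: float | None = None,
) -> float | None:
    """First hour at which the slope exceeds ``factor`` times its baseline and
    stays there for ``persistence_h``.

    The baseline is the median slope over ``baseline_window`` (chosen inside
    the stimulus-driven Phase 1, after the CEBPB onset transient). The rule is
    a simple formalization of reading the engagement point off a slope plot;
    all three knobs are deliberately exposed. Returns ``None`` when the slope
    never sustains the required increase (e.g. arrested knockdown cells).
    """
    t, s, ok = slopes.times, slopes.slopes, slopes.valid
    in_base = ok & (t >= baseline_window[0]) & (t <= baseline_window[1])
    if not in_base.any():
        raise ValueError("no valid slopes in the baseline window")
    baseline = float(np.median(s[in_base]))
    if baseline <= 0:
        if baseline_floor is None:
            raise ValueError(
                "non-positive baseline slope; pass baseline_floor to use an "
                "absolute minimum slope instead"
            )
        warnings.warn("non-positive baseline slope; using absolute floor")
        baseline = baseline_floor
    level = factor * baseline
    above = ok & (s >= level)
    start_idx = np.searchsorted(t, baseline_window[1], side="left")
    for i in range(start_idx, len(t)):
        if not above[i]:
            continue
        j = np.searchsorted(t, t[i] + persistence_h, side="left")
        if j > len(t) - 1 and t[-1] - t[i] < persistence_h:
            return None  # not enough trace left to confirm persistence
        if above[i:j + 1 if j < len(t) else j].all():
            return float(t[i])
    return None


def _resample_arclength(x: np.ndarray, y: np.ndarray, n_points: int) -> np.ndarray:
    d = np.hypot(np.diff(x), np.diff(y))
    s = np.concatenate([[0.0], np.cumsum(d)])
    if s[-1] == 0:
        return np.column_stack([np.full(n_points, x[0]), np.full(n_points, y[0])])
    frac = s / s[-1]
    # collapse zero-length steps so xp is strictly increasing
    keep = np.concatenate([[True], np.diff(frac) > 0])
    frac, x, y = frac[keep], x[keep], y[keep]
    u = np.linspace(0.0, 1.0, n_points)
    return np.column_stack([np.interp(u, frac, x), np.interp(u, frac, y)])


def _signed_area_vs_diagonal(path: np.ndarray) -> float:
    """Shoelace area of the closed polygon path + straight return to its start.

    For paths from (0,0) to (1,1), positive when the path runs below the
    diagonal (counterclockwise circulation), e.g. (0,0)->(1,0)->(1,1) -> +0.5.
    """
    x, y = path[:, 0], path[:, 1]
    x2, y2 = np.roll(x, -1), np.roll(y, -1)
    return float(0.5 * np.sum(x * y2 - x2 * y))


def unit_square_normalize(
    ts: TrajectorySet,
    x_channel: str = "PPARG",
    y_channel: str = "FABP4",
    cells=None,
    n_points: int = 101,
) -> NormalizedPathSet:
    """Min-max-normalize each cell's (x, y) trajectory onto the unit square.

    Every path starts at its per-cell minima and ends at its maxima, so the
    geometry — not the absolute scale — is compared across cells. The ensemble
    mean path averages cells at equal arc-length fractions (cells traverse the
    square at different speeds); the asymmetry score is the signed area
    between the mean path and the diagonal. Cells with a constant channel are
    skipped with a warning.
    """
    wanted = set(cells) if cells is not None else None
    paths: dict[str, np.ndarray] = {}
    resampled = []
    skipped: list[str] = []
    for tr in ts.traces:
        if wanted is not None and tr.cell_id not in wanted:
            continue
        x = tr.values(x_channel).astype(float)
        y = tr.values(y_channel).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            skipped.append(tr.cell_id)
            continue
        xn = (x - x.min()) / np.ptp(x)
        yn = (y - y.min()) / np.ptp(y)
        paths[tr.cell_id] = np.column_stack([xn, yn])
        resampled.append(_resample_arclength(xn, yn, n_points))
    if skipped:
        warnings.warn(f"skipped {len(skipped)} cell(s) with a constant channel")
    if not resampled:
        raise ValueError("no usable cells for path normalization")
    mean_path = np.mean(resampled, axis=0)
    return NormalizedPathSet(
        paths=paths,
        mean_path=mean_path,
        asymmetry=_signed_area_vs_diagonal(mean_path),
        skipped=skipped,
    )


def bin_and_average(
    ts: TrajectorySet,
    channel: str = "PPARG",
    bin_time_h: float = 48.0,
    n_bins: int = 4,
) -> BinnedTraces:
    """Split cells into ``n_bins`` equal-count bins of their ``channel`` level
    at ``bin_time_h`` and average the traces of every channel within each bin.

    Quantile (equal-count) bins are robust to the long right tail of the 48-h
    PPARG distribution; ties at a bin edge are broken by cell-id order. All
    traces must cover both ``bin_time_h`` and the full grid (bin means are
    only defined where every member contributes).
    """
    if n_bins < 1 or n_bins > ts.n_cells:
        raise ValueError(f"n_bins={n_bins} incompatible with {ts.n_cells} cells")
    j = ts.grid.index_of(bin_time_h)
    traces = sorted(ts.traces, key=lambda tr: tr.cell_id)
    vals = []
    for tr in traces:
        if len(tr.times) != ts.grid.n_frames:
            raise ValueError(f"cell {tr.cell_id} does not cover the full grid")
        vals.append(tr.values(channel)[j])
    order = np.argsort(np.asarray(vals), kind="stable")  # stable => cell-id tie-break
    chunks = np.array_split(order, n_bins)
    bin_of = {}
    for b, chunk in enumerate(chunks):
        for i in chunk:
            bin_of[traces[i].cell_id] = b
    channels = sorted({ch for tr in traces for ch in tr.channels})
    mean_traces = {}
    for ch in channels:
        out = np.empty((n_bins, ts.grid.n_frames))
        for b, chunk in enumerate(chunks):
            out[b] = np.mean([traces[i].values(ch) for i in chunk], axis=0)
        mean_traces[ch] = out
    return BinnedTraces(bin_of=bin_of, mean_traces=mean_traces,
                        times=ts.grid.times(), bin_time_h=bin_time_h)


def fold_change(trace: CellTrace, channel: str = "PPARG") -> float:
    """Max/min intensity ratio over the trace; requires a positive minimum."""
    v = trace.values(channel)
    vmin = float(np.min(v))
    if vmin <= 0:
        raise ValueError(f"cell {trace.cell_id}: non-positive minimum on {channel}")
    return float(np.max(v) / vmin)
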