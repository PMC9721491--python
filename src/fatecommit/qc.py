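"""Trace-exclusion rules for live-imaging populations.

Three filters remove incomplete or mistracked traces before analysis:

* ``absent near endpoint`` — the trace's last frame is more than
  ``endpoint_window_h`` (default 6 h) before the end of the grid;
* ``late start`` — the first frame is more than ``late_start_h`` (default 4 h)
  after the start of the grid;
* ``intensity jump`` — any frame-to-frame relative change on the PPARG channel
  exceeds ``jump_ratio_max`` (default 1.0, i.e. a doubling or halving between
  12-min frames, implausible for a fluorescent-protein reporter and therefore
  read as a segmentation/tracking error).

A trace can match several rules; it is removed once with all reasons recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .traces import TrajectorySet

__all__ = ["QCParams", "QCReport", "apply_qc"]


@dataclass(frozen=True)
class QCParams:
    endpoint_window_h: float = 6.0
    late_start_h: float = 4.0
    jump_ratio_max: float = 1.0
    jump_epsilon: float = 1e-6
    jump_channels: tuple[str, ...] = ("PPARG",)

    def validate(self) -> None:
        if min(self.endpoint_window_h, self.late_start_h, self.jump_ratio_max) <= 0:
            raise ValueError("all QC parameters must be positive")


@dataclass
class QCReport:
    n_input: int = 0
    n_kept: int = 0
    removed_by_rule: dict[str, int] = field(default_factory=dict)
    reasons: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return len(self.reasons)


def apply_qc(ts: TrajectorySet, qc: QCParams | None = None) -> tuple[TrajectorySet, QCReport]:
    """Filter ``ts`` by the three exclusion rules; order of survivors is kept.

    Returns the filtered set and a report with kept/removed counts per rule and
    per-cell removal reasons. Empty input yields empty output, not an error.
    """
    qc = qc if qc is not None else QCParams()
    qc.validate()
    g = ts.grid
    report = QCReport(n_input=ts.n_cells,
                      removed_by_rule={"absent near endpoint": 0,
                                       "late start": 0,
                                       "intensity jump": 0})
    kept = []
    for tr in ts.traces:
        reasons = []
        if len(tr.times) == 0 or tr.times[-1] < g.end - qc.endpoint_window_h:
            reasons.append("absent near endpoint")
        if len(tr.times) == 0 or tr.times[0] > g.start + qc.late_start_h:
            reasons.append("late start")
        for ch in qc.jump_channels:
            if ch not in tr.channels:
                raise ValueError(f"QC jump rule needs channel {ch!r}; "
                                 f"cell {tr.cell_id} lacks it")
            v = tr.channels[ch]
            if len(v) >= 2:
                ratio = np.abs(np.diff(v)) / np.maximum(v[:-1], qc.jump_epsilon)
                if np.any(ratio > qc.jump_ratio_max):
                    reasons.append("intensity jump")
                    break
        if reasons:
            report.reasons[tr.cell_id] = reasons
            for r in reasons:
                report.removed_by_rule[r] += 1
        else:
            kept.append(tr)
    truth = None
    if ts.truth is not None:
        keep_ids = {tr.cell_id for tr in kept}
        truth = {cid: t for cid, t in ts.truth.items() if cid in keep_ids}
    report.n_kept = len(kept)
    return TrajectorySet(g, kept, truth), report
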