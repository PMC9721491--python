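"""Machine-readable run summaries and convenience plots.

``build_report`` assembles stage outputs (QC report, threshold model, hit
times, dynamics summaries, divergence profiles, decay fits) into one JSON
payload with provenance (seed, config hash, input-file hashes, package
version). The payload is byte-identical for identical inputs — no timestamps.
Plotting helpers are side effects only and carry no determinism guarantee.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np

from . import __version__

__all__ = ["build_report", "report_to_json", "file_sha256", "hash_config"]


def _jsonable(obj):
    if obj is None or isinstance(obj, (bool, int, str)):
        return obj
    if isinstance(obj, float):
        return None if not np.isfinite(obj) else obj
    if isinstance(obj, (np.floating, np.integer)):
        return _jsonable(obj.item())
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        items = sorted(obj) if isinstance(obj, set) else obj
        return [_jsonable(v) for v in items]
    return str(obj)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def hash_config(config) -> str:
    payload = json.dumps(_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def build_report(
    sections: dict,
    seed: int | None = None,
    config=None,
    input_files: dict[str, str] | None = None,
) -> dict:
    """Assemble stage outputs into one deterministic report payload.

    ``sections`` maps stage name -> stage output (dataclasses, dicts and
    numpy containers are all converted). At least one section is required.
    ``input_files`` maps logical name -> path; each file is hashed.
    """
    if not sections:
        raise ValueError("at least one stage output is required")
    grids = {
        str(s.get("grid")) for s in sections.values()
        if isinstance(s, dict) and "grid" in s
    }
    if len(grids) > 1:
        raise ValueError(f"conflicting grids across inputs: {sorted(grids)}")
    provenance: dict = {"package": "fatecommit", "version": __version__}
    if seed is not None:
        provenance["seed"] = int(seed)
    if config is not None:
        provenance["config_sha256"] = hash_config(config)
    if input_files:
        provenance["inputs"] = {
            name: {"path": str(p), "sha256": file_sha256(p)}
            for name, p in sorted(input_files.items())
        }
    return {"provenance": provenance, "sections": _jsonable(sections)}


def report_to_json(report: dict) -> str:
    return json.dumps(report, sort_keys=True, indent=2, separators=(",", ": "))


# ---------------------------------------------------------------------------
# plots (smoke-tested conveniences only)


def _get_axes(ax):
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    return ax


def plot_traces(ts, channel="PPARG", fates=None, max_cells=60, ax=None):
    """Overlay single-cell traces, colored by fate when labels are given."""
    ax = _get_axes(ax)
    colors = {"differentiated": "tab:red", "undifferentiated": "0.6"}
    for tr in ts.traces[:max_cells]:
        fate = fates.get(tr.cell_id) if fates else None
        ax.plot(tr.times, tr.values(channel), lw=0.6,
                color=colors.get(fate, "tab:blue"), alpha=0.5)
    ax.set_xlabel("time (h)")
    ax.set_ylabel(f"{channel} (AU)")
    return ax


def plot_hit_histogram(hits, bin_width_h=2.0, ax=None):
    ax = _get_axes(ax)
    counts, edges = hits.histogram(bin_width_h)
    ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge",
           color="tab:red", alpha=0.7, edgecolor="white")
    ax.axvline(hits.mean, color="k", ls="--", lw=1,
               label=f"mean {hits.mean:.1f} h")
    ax.set_xlabel("threshold hit time (h)")
    ax.set_ylabel("cells")
    ax.legend()
    return ax


def plot_slope_series(series_by_group, ax=None):
    ax = _get_axes(ax)
    for name, ss in series_by_group.items():
        ax.plot(ss.times, ss.slopes, label=str(name))
    ax.set_xlabel("time (h)")
    ax.set_ylabel("slope (AU/h)")
    ax.legend()
    return ax


def plot_paths(path_set, max_cells=40, ax=None):
    ax = _get_axes(ax)
    for i, (cid, p) in enumerate(path_set.paths.items()):
        if i >= max_cells:
            break
        ax.plot(p[:, 0], p[:, 1], lw=0.5, color="0.7", alpha=0.6)
    mp = path_set.mean_path
    ax.plot(mp[:, 0], mp[:, 1], lw=2, color="tab:red", label="mean path")
    ax.plot([0, 1], [0, 1], ls="--", color="k", lw=1)
    ax.set_xlabel("normalized PPARG")
    ax.set_ylabel("normalized FABP4")
    ax.legend()
    return ax
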