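"""Fate classification and commitment-threshold estimation.

Differentiation is a binary outcome: endpoint PPARG levels are bimodal, with
an undifferentiated low mode and a differentiated high mode roughly 8-fold
apart. This module implements the three estimators built on that bimodality:

* a 2-component Gaussian mixture on log10 endpoint intensities, classifying
  each cell to the component with the larger posterior (``fit_endpoint_mixture``
  / ``classify_fate``), with a BIC-based degeneracy check;
* an ROC scan over candidate thresholds at the decision time (default 48 h,
  just before stimulus removal) constrained to a false-positive rate below 5%
  (``select_threshold``), plus the control-fit transfer rule for multi-condition
  experiments (``transfer_threshold``);
* the fixed-cell convention of taking the midpoint between the two histogram
  peaks (``histogram_midpoint_threshold``), implemented as the midpoint of the
  mixture-component means in log space for bin-width robustness.

Hit times — the first time each differentiated cell's PPARG trace reaches the
threshold — are extracted with linear interpolation between frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.mixture import GaussianMixture

from .traces import EndpointSnapshot, TrajectorySet

__all__ = [
    "MixtureFit",
    "ThresholdModel",
    "HitTimes",
    "InsufficientDataError",
    "DegenerateInputError",
    "fit_endpoint_mixture",
    "classify_fate",
    "select_threshold",
    "transfer_threshold",
    "histogram_midpoint_threshold",
    "percent_differentiated",
    "threshold_hit_times",
]

DIFF = "differentiated"
UNDIFF = "undifferentiated"


class InsufficientDataError(ValueError):
    pass


class DegenerateInputError(ValueError):
    pass


@dataclass
class MixtureFit:
    """Two-component Gaussian mixture fit, ordered low mean < high mean.

    ``means``/``variances``/``weights`` live in the fitted space (log10 AU by
    default); ``responsibilities[:, 1]`` is the posterior of the high
    component for each input value.
    """

    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    responsibilities: np.ndarray
    log_space: bool
    bic_one: float
    bic_two: float

    @property
    def degenerate(self) -> bool:
        """True when one component explains the data at least as well (BIC)."""
        return self.bic_one <= self.bic_two

    @property
    def bic_difference(self) -> float:
        return self.bic_one - self.bic_two

    def transform(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        return np.log10(v) if self.log_space else v

    def posterior_high(self, values) -> np.ndarray:
        x = self.transform(values)
        log_like = np.stack(
            [
                np.log(self.weights[k])
                + stats.norm.logpdf(x, self.means[k], np.sqrt(self.variances[k]))
                for k in (0, 1)
            ],
            axis=-1,
        )
        log_norm = np.logaddexp(log_like[..., 0], log_like[..., 1])
        return np.exp(log_like[..., 1] - log_norm)


@dataclass
class ThresholdModel:
    """Commitment threshold (AU) at the decision time with achieved ROC point."""

    threshold: float
    t_dec: float
    fpr: float
    tpr: float
    labels: list[str]
    candidates: np.ndarray
    fpr_max: float
    constraint_met: bool = True


@dataclass
class HitTimes:
    """First threshold-crossing hour per differentiated cell."""

    hit_times: dict[str, float]
    n_never: int
    threshold: float

    @property
    def times(self) -> np.ndarray:
        return np.asarray(sorted(self.hit_times.values()), dtype=float)

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.hit_times.values())))

    @property
    def sd(self) -> float:
        return float(np.std(list(self.hit_times.values()), ddof=1))

    def histogram(self, bin_width_h: float = 2.0):
        t = self.times
        edges = np.arange(np.floor(t.min()), np.ceil(t.max()) + bin_width_h, bin_width_h)
        counts, edges = np.histogram(t, bins=edges)
        return counts, edges


def _as_values(values) -> np.ndarray:
    if isinstance(values, EndpointSnapshot):
        return np.asarray(values.values, dtype=float)
    return np.asarray(values, dtype=float)


def fit_endpoint_mixture(
    values,
    log_transform: bool = True,
    n_init: int = 10,
    random_state: int = 0,
) -> MixtureFit:
    """Fit a 2-component Gaussian mixture to endpoint intensities.

    Fitted on log10 values by default (the two modes span ~8-fold and are
    close to log-symmetric). Deterministic: k-means initialization with
    ``n_init`` restarts and a fixed random state, best likelihood kept.
    """
    v = _as_values(values)
    if len(v) < 10:
        raise InsufficientDataError(f"need >= 10 values for a mixture fit, got {len(v)}")
    if not np.all(np.isfinite(v)):
        raise ValueError("endpoint values must be finite")
    if log_transform and np.any(v <= 0):
        raise ValueError("log-space mixture requires strictly positive intensities")
    x = (np.log10(v) if log_transform else v).reshape(-1, 1)
    if np.ptp(x) == 0:
        raise DegenerateInputError("zero-variance endpoint values")
    fits = {}
    for k in (1, 2):
        gm = GaussianMixture(
            n_components=k, covariance_type="full", n_init=n_init,
            init_params="k-means++", random_state=random_state, reg_covar=1e-10,
        ).fit(x)
        fits[k] = gm
    gm = fits[2]
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    variances = gm.covariances_.ravel()[order]
    weights = gm.weights_[order]
    resp = gm.predict_proba(x)[:, order]
    return MixtureFit(
        means=means, variances=variances, weights=weights,
        responsibilities=resp, log_space=log_transform,
        bic_one=float(fits[1].bic(x)), bic_two=float(fits[2].bic(x)),
    )


def classify_fate(fit: MixtureFit, values) -> list[str]:
    """Label each value by its mixture component: high -> differentiated.

    Exact posterior ties go to undifferentiated (the conservative call).
    Refuses degenerate (effectively unimodal) fits.
    """
    if fit.degenerate:
        raise DegenerateInputError(
            "mixture fit is degenerate (one component suffices by BIC); "
            "fate classification from it would be arbitrary"
        )
    post_high = fit.posterior_high(_as_values(values))
    return [DIFF if p > 0.5 else UNDIFF for p in post_high]


def _roc_counts(values, fates):
    v = _as_values(values)
    f = np.asarray(fates)
    pos = v[f == DIFF]
    neg = v[f == UNDIFF]
    return v, pos, neg


def select_threshold(
    values_at_tdec,
    fates,
    fpr_max: float = 0.05,
    t_dec: float = 48.0,
    rule: str = "max_margin",
) -> ThresholdModel:
    """FPR-constrained ROC scan for the commitment threshold.

    Candidates are the midpoints between consecutive sorted distinct values
    plus both extremes; a cell is predicted positive iff ``value >= threshold``.
    Two selection rules are offered:

    * ``"max_margin"`` (default): among candidates with FPR < ``fpr_max``,
      maximize TPR, break ties by the lowest FPR, and break remaining ties at
      the middle candidate — the ROC point maximizing TPR - FPR under the
      constraint, placed mid-gap when the classes separate cleanly;
    * ``"min_feasible"``: the smallest candidate with FPR < ``fpr_max``
      (maximum sensitivity; hugs the upper tail of the negative class).

    If no candidate meets the constraint the largest candidate is returned
    flagged (``constraint_met=False``).
    """
    if rule not in ("max_margin", "min_feasible"):
        raise ValueError("rule must be 'max_margin' or 'min_feasible'")
    v, pos, neg = _roc_counts(values_at_tdec, fates)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError(
            "both fate classes are required to scan a threshold; fit the "
            "mixture on a bimodal (e.g. non-stimulated control) condition and "
            "transfer its threshold instead"
        )
    sv = np.unique(v)
    if len(sv) == 1:
        candidates = sv.astype(float)
    else:
        candidates = np.concatenate([[sv[0]], (sv[:-1] + sv[1:]) / 2.0, [sv[-1]]])
    fpr = np.array([(neg >= c).mean() for c in candidates])
    tpr = np.array([(pos >= c).mean() for c in candidates])
    feasible = fpr < fpr_max
    if not feasible.any():
        i = len(candidates) - 1
        warnings.warn("no candidate threshold satisfies the FPR constraint; "
                      "returning the largest candidate")
        met = False
    else:
        idx = np.where(feasible)[0]
        if rule == "min_feasible":
            i = int(idx[0])
        else:
            best_tpr = tpr[idx].max()
            idx = idx[tpr[idx] == best_tpr]
            best_fpr = fpr[idx].min()
            idx = idx[fpr[idx] == best_fpr]
            i = int(idx[len(idx) // 2])
        met = True
    thr = float(candidates[i])
    labels = [DIFF if x >= thr else UNDIFF for x in v]
    return ThresholdModel(
        threshold=thr, t_dec=t_dec, fpr=float(fpr[i]), tpr=float(tpr[i]),
        labels=labels, candidates=candidates, fpr_max=fpr_max, constraint_met=met,
    )


def transfer_threshold(
    control_fit: MixtureFit,
    control_threshold: ThresholdModel,
    other_values,
) -> list[str]:
    """Call another condition's cells with the control-derived threshold.

    The mixture is fitted (and the threshold selected) on the bimodal control
    condition only; other conditions — which may lack one mode entirely — are
    called by straight comparison to that threshold, no refitting.
    """
    v = _as_values(other_values)
    thr = control_threshold.threshold
    return [DIFF if x >= thr else UNDIFF for x in v]


def histogram_midpoint_threshold(values, log_transform: bool = True) -> float:
    """Fixed-cell threshold: the center between the two peaks of the endpoint
    histogram, estimated as the midpoint of the mixture-component means (in
    log space when fitted there) and returned in AU."""
    fit = fit_endpoint_mixture(values, log_transform=log_transform)
    if fit.degenerate:
        raise DegenerateInputError("endpoint distribution is not bimodal")
    mid = float(np.mean(fit.means))
    return float(10 ** mid) if fit.log_space else mid


def percent_differentiated(values, threshold: float) -> float:
    """Fraction of cells at or above the threshold (ties count as above)."""
    v = _as_values(values)
    if len(v) == 0:
        raise InsufficientDataError("no values")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return float(np.mean(v >= threshold))


def threshold_hit_times(
    ts: TrajectorySet,
    threshold: float,
    fates: dict[str, str],
    channel: str = "PPARG",
    interpolate: bool = True,
) -> HitTimes:
    """First threshold crossing per differentiated cell.

    The crossing hour is linearly interpolated between the bracketing frames
    (``interpolate=False`` reverts to the first frame at or above threshold).
    Differentiated cells that never reach the threshold are counted in
    ``n_never``; a trace already above threshold at its first frame hits at
    that frame's time.
    """
    diff_ids = [cid for cid, f in fates.items() if f == DIFF]
    if not diff_ids:
        raise ValueError("no differentiated cells: hit times undefined")
    wanted = set(diff_ids)
    hits: dict[str, float] = {}
    n_never = 0
    for tr in ts.traces:
        if tr.cell_id not in wanted:
            continue
        v = tr.values(channel)
        above = v >= threshold
        if not above.any():
            n_never += 1
            continue
        i = int(np.argmax(above))
        if i == 0 or not interpolate:
            hits[tr.cell_id] = float(tr.times[i])
        else:
            t0, t1 = tr.times[i - 1], tr.times[i]
            v0, v1 = v[i - 1], v[i]
            hits[tr.cell_id] = float(t0 + (threshold - v0) / (v1 - v0) * (t1 - t0))
    if not hits:
        raise ValueError("no differentiated cell ever crosses the threshold")
    return HitTimes(hit_times=hits, n_never=n_never, threshold=float(threshold))
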