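"""Synthetic trajectory populations from a three-phase positive-feedback model.

The generative model encodes the sequential-feedback picture of adipogenic
commitment. Normalized PPARG ``n(t)`` of a differentiating cell is piecewise
linear with slope steps at each feedback engagement:

* Phase 1 — stimulus-driven slow rise: slope ``s1`` from CEBPB onset ``t_B``
  (default 4 h) to the CEBPA engagement point ``tau_A`` (default 17 h).
* Phase 2 — sequential feedback engagement: slope ``s2`` on ``[tau_A, tau_F)``
  and ``s3`` after FABP4 engages at ``tau_F`` (default 27 h), until ``n``
  crosses the commitment threshold ``theta_n`` (default 0.253, crossed at
  32.1 h for the canonical cell).
* Phase 3 — self-sustained rise: slope ``s4`` to 44 h, then saturation
  ``n(t) = 1 - (1 - n(44)) * exp(-(t - 44)/tau_sat)``.

Absolute PPARG is ``P(t) = P_basal * (1 + (fold_P - 1) * n(t))`` (roughly
8-fold dynamic range). Normalized FABP4 ``m(t)`` leaks slowly from ``t_B``,
rises moderately after its own engagement at ``tau_F``, and surges
exponentially after 44 h, capped at 1; its absolute fold range is drawn
log-uniformly in 100-2,000, reproducing the strongly delayed, high-dynamic-
range FABP4 response seen in differentiating cells.

Cells that do not differentiate rise at a fraction of ``s1`` with no
engagements and relax back toward basal once the stimulus is removed at 48 h.
Perturbation scenarios (CEBPB/CEBPA/FABP4 knockdown, rosiglitazone rescue)
arrest or modify the slope program of would-be differentiating cells while
leaving the population identically distributed before the targeted
engagement point, so divergence-time analyses recover the engagement hours.

Randomness is split into three independent substreams (structure, noise,
artifacts) spawned from one seed: the same seed with noise and artifact rates
zeroed reproduces the same cells' clean trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .traces import CellTrace, CellTruth, DecayTable, TimeGrid, TrajectorySet

__all__ = [
    "CanonicalParams",
    "SimConfig",
    "SCENARIOS",
    "canonical_trace",
    "simulate_population",
    "simulate_decay_series",
]

SCENARIOS = (
    "control",
    "nonstimulated",
    "siCEBPB",
    "siCEBPA",
    "siFABP4",
    "siFABP4_rosi",
    "rosi",
)


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class CanonicalParams:
    """Deterministic skeleton of the differentiating trajectory (times in h,
    slopes in normalized units per hour)."""

    t_B: float = 4.0
    tau_A: float = 17.0
    tau_F: float = 27.0
    s1: float = 0.0035
    s2: float = 0.0080
    s3: float = 0.0250
    theta_n: float = 0.253
    s4: float = 0.0208
    t_sat: float = 44.0
    tau_sat: float = 12.0
    fold_P: float = 8.0
    fabp4_leak: float = 0.0008
    fabp4_mid: float = 0.0048
    fabp4_surge_rate: float = math.log(10.0) / 35.0
    stim_end: float = 48.0

    def validate(self) -> None:
        if not (0 < self.t_B < self.tau_A < self.tau_F < self.stim_end):
            raise ParameterError("need 0 < t_B < tau_A < tau_F < stim_end")
        for name in ("s1", "s2", "s3", "s4", "fabp4_leak", "fabp4_mid", "fabp4_surge_rate"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"slope {name} must be > 0")
        if not (0 < self.theta_n < 1):
            raise ParameterError("theta_n must be in (0, 1)")
        if self.fold_P <= 1:
            raise ParameterError("fold_P must exceed 1")

    def hit_time(self) -> float:
        """Commitment-threshold crossing hour of the canonical cell."""
        n_A = self.s1 * (self.tau_A - self.t_B)
        n_F = n_A + self.s2 * (self.tau_F - self.tau_A)
        if self.theta_n <= n_A:
            return self.t_B + self.theta_n / self.s1
        if self.theta_n <= n_F:
            return self.tau_A + (self.theta_n - n_A) / self.s2
        t_hit = self.tau_F + (self.theta_n - n_F) / self.s3
        if t_hit >= self.stim_end:
            raise ParameterError(
                f"theta_n={self.theta_n} not reachable on the s3 segment before "
                f"stimulus removal at {self.stim_end} h (crossing at {t_hit:.1f} h)"
            )
        return t_hit


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of one simulated population."""

    canonical: CanonicalParams = field(default_factory=CanonicalParams)
    n_cells: int = 1000
    p_diff: float = 0.6
    sigma_t: float = 3.0
    jitter_max_h: float = 8.0
    slope_cv: float = 0.15
    slope_factor_bounds: tuple[float, float] = (0.5, 2.0)
    fold_F_range: tuple[float, float] = (100.0, 2000.0)
    undiff_slope_factor: float = 0.7
    undiff_relax_h: float = 24.0
    P_basal: float = 100.0
    F_basal: float = 10.0
    sigma_m: float = 0.05
    p_dropout: float = 0.05
    dropout_keep_frac: tuple[float, float] = (0.50, 0.94)
    p_late_start: float = 0.03
    late_start_range_h: tuple[float, float] = (4.0, 12.0)
    p_spike: float = 0.02
    spike_factor_range: tuple[float, float] = (2.0, 4.0)
    scenario: str = "control"
    rho_B: float = 0.25
    p_escape_siCEBPA: float = 0.05
    p_escape_siFABP4: float = 0.10
    kappa_rosi: float = 1.8
    rosi_rescue_s3_factor: float = 0.7
    grid: TimeGrid = field(default_factory=TimeGrid)
    seed: int = 0

    def validate(self) -> None:
        self.canonical.validate()
        if self.n_cells < 0:
            raise ParameterError("n_cells must be >= 0")
        for name in ("p_diff", "p_dropout", "p_late_start", "p_spike",
                     "p_escape_siCEBPA", "p_escape_siFABP4"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        if self.fold_F_range[0] < 1 or self.fold_F_range[1] < self.fold_F_range[0]:
            raise ParameterError("fold_F_range must satisfy 1 <= lo <= hi")
        if self.scenario not in SCENARIOS:
            raise ParameterError(f"unknown scenario {self.scenario!r}; one of {SCENARIOS}")
        if self.scenario == "siCEBPA" and self.p_escape_siCEBPA > self.p_diff:
            raise ParameterError("p_escape_siCEBPA cannot exceed p_diff")
        if self.scenario == "siFABP4" and self.p_escape_siFABP4 > self.p_diff:
            raise ParameterError("p_escape_siFABP4 cannot exceed p_diff")
        if self.sigma_m < 0 or self.sigma_t < 0 or self.slope_cv < 0:
            raise ParameterError("sigma_m, sigma_t, slope_cv must be >= 0")


# ---------------------------------------------------------------------------
# trajectory kernels (vectorized over cells)


def _overlap(t, lo, hi):
    """Per-cell length of [lo, hi] covered by time <= t; lo/hi broadcast (cells, 1)."""
    return np.clip(np.minimum(t, hi) - lo, 0.0, None)


def _pparg_full(t, t_B, tau_A, tau_F, s1, s2, s3, s4, theta, t_sat, tau_sat, stim_end):
    """Normalized PPARG of fully differentiating cells. Per-cell parameter
    arrays have shape (cells, 1); ``t`` has shape (frames,). Returns the
    (cells, frames) matrix and the per-cell threshold-crossing hours."""
    n_A = s1 * (tau_A - t_B)
    n_F = n_A + s2 * (tau_F - tau_A)
    # crossing segment (almost always s3; s1/s2 possible for extreme draws)
    with np.errstate(divide="ignore"):
        t_hit = np.where(
            theta <= n_A,
            t_B + theta / s1,
            np.where(theta <= n_F, tau_A + (theta - n_A) / s2, tau_F + (theta - n_F) / s3),
        )
    t_sat_eff = np.maximum(t_sat, t_hit)
    n = (
        s1 * _overlap(t, t_B, np.minimum(tau_A, t_hit))
        + s2 * _overlap(t, tau_A, np.minimum(tau_F, t_hit))
        + s3 * _overlap(t, tau_F, t_hit)
        + s4 * _overlap(t, t_hit, t_sat_eff)
    )
    n_sat = (
        s1 * (np.minimum(tau_A, t_hit) - t_B).clip(0)
        + s2 * (np.minimum(tau_F, t_hit) - tau_A).clip(0)
        + s3 * (t_hit - tau_F).clip(0)
        + s4 * (t_sat_eff - t_hit)
    )
    sat = 1.0 - (1.0 - n_sat) * np.exp(-(t - t_sat_eff) / tau_sat)
    n = np.where(t > t_sat_eff, sat, n)
    return n, t_hit.ravel()


def _pparg_ramp(t, t_B, slope, stim_end, relax_h):
    """Ramp-and-relax PPARG: constant slope from t_B to stimulus removal, then
    exponential relaxation toward basal (undiff cells, arrested knockdowns)."""
    n = slope * _overlap(t, t_B, stim_end)
    n_end = slope * (stim_end - t_B)
    n = np.where(t > stim_end, n_end * np.exp(-(t - stim_end) / relax_h), n)
    return n


def _pparg_two_slope(t, t_B, tau_A, s1, s2, stim_end, relax_h):
    """siFABP4 arrest: canonical s1 then s2 from tau_A until stimulus removal."""
    n = s1 * _overlap(t, t_B, tau_A) + s2 * _overlap(t, tau_A, stim_end)
    n_end = s1 * (tau_A - t_B) + s2 * (stim_end - tau_A)
    n = np.where(t > stim_end, n_end * np.exp(-(t - stim_end) / relax_h), n)
    return n


def _fabp4_full(t, t_B, tau_F, leak, mid, g, t_sat):
    """Normalized FABP4 of differentiating cells: leak, mid rise, capped surge."""
    m = leak * _overlap(t, t_B, tau_F) + mid * _overlap(t, tau_F, t_sat)
    m_sat = leak * (tau_F - t_B) + mid * (t_sat - tau_F)
    surge = m_sat * np.exp(g * (t - t_sat))
    m = np.where(t > t_sat, surge, m)
    return np.minimum(m, 1.0)


def _fabp4_leak(t, t_B, leak, stim_end, relax_h):
    m = leak * _overlap(t, t_B, stim_end)
    m_end = leak * (stim_end - t_B)
    m = np.where(t > stim_end, m_end * np.exp(-(t - stim_end) / relax_h), m)
    return m


def _geomean(lo, hi):
    return math.sqrt(lo * hi)


def canonical_trace(
    params: CanonicalParams | None = None,
    fate: str = "differentiating",
    *,
    grid: TimeGrid | None = None,
    P_basal: float = 100.0,
    F_basal: float = 10.0,
    fold_F: float | None = None,
    undiff_slope_factor: float = 0.7,
    undiff_relax_h: float = 24.0,
    cell_id: str = "canonical",
    condition: str = "control",
) -> CellTrace:
    """Noise-free trajectory of the canonical cell over the full grid.

    ``fate`` is ``"differentiating"`` or ``"undifferentiated"``. The returned
    trace carries PPARG and FABP4 in absolute AU; ground truth is attached as
    ``trace.truth`` (fate, threshold hit time, engagement hours).
    """
    p = params if params is not None else CanonicalParams()
    p.validate()
    g = grid if grid is not None else TimeGrid()
    t = g.times()[None, :]
    if fold_F is None:
        fold_F = _geomean(100.0, 2000.0)

    one = np.ones((1, 1))
    if fate == "differentiating":
        p.hit_time()  # raises if theta unreachable
        n, t_hit = _pparg_full(
            t, p.t_B * one, p.tau_A * one, p.tau_F * one,
            p.s1 * one, p.s2 * one, p.s3 * one, p.s4 * one,
            p.theta_n * one, p.t_sat * one, p.tau_sat * one, p.stim_end,
        )
        m = _fabp4_full(t, p.t_B * one, p.tau_F * one, p.fabp4_leak * one,
                        p.fabp4_mid * one, p.fabp4_surge_rate * one, p.t_sat * one)
        truth = CellTruth("differentiated", float(t_hit[0]), p.tau_A, p.tau_F)
    elif fate == "undifferentiated":
        n = _pparg_ramp(t, p.t_B * one, undiff_slope_factor * p.s1 * one,
                        p.stim_end, undiff_relax_h)
        m = _fabp4_leak(t, p.t_B * one, p.fabp4_leak * one, p.stim_end, undiff_relax_h)
        truth = CellTruth("undifferentiated")
    else:
        raise ValueError(f"fate must be 'differentiating' or 'undifferentiated', got {fate!r}")

    P = P_basal * (1.0 + (p.fold_P - 1.0) * n[0])
    F = F_basal * (1.0 + (fold_F - 1.0) * m[0])
    tr = CellTrace(cell_id, condition, g.times(), {"PPARG": P, "FABP4": F})
    tr.truth = truth  # informal attribute; populations carry truth on the set
    return tr


# ---------------------------------------------------------------------------
# population simulation


def _lognormal_factors(rng, cv, size, bounds):
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    f = rng.lognormal(mean=0.0, sigma=sigma, size=size)
    return np.clip(f, bounds[0], bounds[1])


def simulate_population(config: SimConfig) -> TrajectorySet:
    """Simulate ``config.n_cells`` cells under ``config.scenario``.

    Ground truth (fate, clean hit time, jittered engagement hours) is recorded
    per cell before measurement noise and tracking artifacts are applied.
    Identical configs (including seed) produce bit-identical output.
    """
    config.validate()
    p = config.canonical
    g = config.grid
    t = g.times()[None, :]
    n_cells = config.n_cells
    if n_cells == 0:
        return TrajectorySet(g, [], truth={})

    ss = np.random.SeedSequence(config.seed)
    rng_struct, rng_noise, rng_art = (np.random.default_rng(s) for s in ss.spawn(3))

    # structural draws (same order regardless of scenario, for substream stability)
    base_fate_diff = rng_struct.random(n_cells) < config.p_diff
    escape_u = rng_struct.random(n_cells)
    delta = np.clip(rng_struct.normal(0.0, config.sigma_t, n_cells),
                    -config.jitter_max_h, config.jitter_max_h)
    f = _lognormal_factors(rng_struct, config.slope_cv, (4, n_cells),
                           config.slope_factor_bounds)
    log_lo, log_hi = math.log(config.fold_F_range[0]), math.log(config.fold_F_range[1])
    fold_F = np.exp(rng_struct.uniform(log_lo, log_hi, n_cells))

    tau_A = p.tau_A + delta
    tau_F = p.tau_F + delta
    s1 = p.s1 * f[0]
    s2 = p.s2 * f[1]
    s3 = p.s3 * f[2]
    s4 = p.s4 * f[3]

    scen = config.scenario
    if scen == "rosi":
        s2, s3 = s2 * config.kappa_rosi, s3 * config.kappa_rosi
    elif scen == "siFABP4_rosi":
        s3 = s3 * config.rosi_rescue_s3_factor

    # per-cell trajectory class
    # full: complete differentiation program; ramp: constant-slope arrest;
    # two_slope: siFABP4 arrest (s2 persists); flat: nonstimulated
    if scen in ("control", "rosi", "siFABP4_rosi"):
        is_full = base_fate_diff
        ramp_slope = config.undiff_slope_factor * s1
        is_two_slope = np.zeros(n_cells, bool)
    elif scen == "nonstimulated":
        is_full = np.zeros(n_cells, bool)
        ramp_slope = np.zeros(n_cells)
        is_two_slope = np.zeros(n_cells, bool)
    elif scen == "siCEBPB":
        is_full = np.zeros(n_cells, bool)
        ramp_slope = np.where(base_fate_diff, config.rho_B * s1,
                              config.undiff_slope_factor * s1)
        is_two_slope = np.zeros(n_cells, bool)
    elif scen == "siCEBPA":
        p_esc = config.p_escape_siCEBPA / config.p_diff if config.p_diff > 0 else 0.0
        is_full = base_fate_diff & (escape_u < p_esc)
        arrested = base_fate_diff & ~is_full
        ramp_slope = np.where(arrested, s1, config.undiff_slope_factor * s1)
        is_two_slope = np.zeros(n_cells, bool)
    elif scen == "siFABP4":
        p_esc = config.p_escape_siFABP4 / config.p_diff if config.p_diff > 0 else 0.0
        is_full = base_fate_diff & (escape_u < p_esc)
        is_two_slope = base_fate_diff & ~is_full
        ramp_slope = config.undiff_slope_factor * s1
    else:  # pragma: no cover
        raise AssertionError(scen)

    col = lambda x: np.asarray(x, dtype=float).reshape(-1, 1)
    n = np.empty((n_cells, g.n_frames))
    m = np.empty((n_cells, g.n_frames))
    hit = np.full(n_cells, np.nan)

    full_idx = np.where(is_full)[0]
    if len(full_idx):
        nf, t_hit = _pparg_full(
            t, p.t_B, col(tau_A[full_idx]), col(tau_F[full_idx]),
            col(s1[full_idx]), col(s2[full_idx]), col(s3[full_idx]), col(s4[full_idx]),
            p.theta_n, p.t_sat, p.tau_sat, p.stim_end,
        )
        n[full_idx] = nf
        hit[full_idx] = t_hit
        m[full_idx] = _fabp4_full(
            t, p.t_B, col(tau_F[full_idx]), p.fabp4_leak, p.fabp4_mid,
            p.fabp4_surge_rate, p.t_sat,
        )

    two_idx = np.where(is_two_slope)[0]
    if len(two_idx):
        n[two_idx] = _pparg_two_slope(
            t, p.t_B, col(tau_A[two_idx]), col(s1[two_idx]), col(s2[two_idx]),
            p.stim_end, config.undiff_relax_h,
        )
        m[two_idx] = _fabp4_leak(t, p.t_B, p.fabp4_leak, p.stim_end,
                                 config.undiff_relax_h) * np.ones((len(two_idx), 1))

    ramp_idx = np.where(~is_full & ~is_two_slope)[0]
    if len(ramp_idx):
        n[ramp_idx] = _pparg_ramp(t, p.t_B, col(ramp_slope[ramp_idx]),
                                  p.stim_end, config.undiff_relax_h)
        leak = 0.0 if scen == "nonstimulated" else p.fabp4_leak
        m[ramp_idx] = _fabp4_leak(t, p.t_B, leak, p.stim_end,
                                  config.undiff_relax_h) * np.ones((len(ramp_idx), 1))

    P = config.P_basal * (1.0 + (p.fold_P - 1.0) * n)
    F = config.F_basal * (1.0 + (fold_F[:, None] - 1.0) * m)

    # measurement noise: multiplicative lognormal, iid per frame and channel
    if config.sigma_m > 0:
        P = P * np.exp(rng_noise.normal(0.0, config.sigma_m, P.shape))
        F = F * np.exp(rng_noise.normal(0.0, config.sigma_m, F.shape))
    else:
        rng_noise.normal(size=0)

    # tracking artifacts
    u_drop = rng_art.random(n_cells)
    keep_frac = rng_art.uniform(*config.dropout_keep_frac, n_cells)
    u_late = rng_art.random(n_cells)
    late_start = rng_art.uniform(*config.late_start_range_h, n_cells)
    u_spike = rng_art.random(n_cells)
    spike_pos = rng_art.random(n_cells)
    spike_gain = rng_art.uniform(*config.spike_factor_range, n_cells)

    times = g.times()
    width = max(3, len(str(n_cells - 1)))
    traces: list[CellTrace] = []
    truth: dict[str, CellTruth] = {}
    for i in range(n_cells):
        lo_idx = 0
        hi_idx = g.n_frames
        if u_late[i] < config.p_late_start:
            lo_idx = int(np.searchsorted(times, late_start[i], side="right"))
        if u_drop[i] < config.p_dropout:
            hi_idx = max(lo_idx + 1, int(round(keep_frac[i] * g.n_frames)))
        Pi = P[i, lo_idx:hi_idx].copy()
        Fi = F[i, lo_idx:hi_idx].copy()
        if u_spike[i] < config.p_spike and len(Pi) > 0:
            j = int(spike_pos[i] * len(Pi))
            Pi[j] *= spike_gain[i]
            Fi[j] *= spike_gain[i]
        cid = f"c{i:0{width}d}"
        traces.append(
            CellTrace(cid, scen, times[lo_idx:hi_idx], {"PPARG": Pi, "FABP4": Fi})
        )
        if is_full[i]:
            truth[cid] = CellTruth("differentiated", float(hit[i]),
                                   float(tau_A[i]), float(tau_F[i]))
        elif is_two_slope[i]:
            truth[cid] = CellTruth("undifferentiated", None, float(tau_A[i]), None)
        else:
            truth[cid] = CellTruth("undifferentiated")
    return TrajectorySet(g, traces, truth)


def noise_free(config: SimConfig) -> SimConfig:
    """The same population without measurement noise or tracking artifacts
    (identical structural draws thanks to substream separation)."""
    return replace(config, sigma_m=0.0, p_dropout=0.0, p_late_start=0.0, p_spike=0.0)


# ---------------------------------------------------------------------------
# cycloheximide-chase series


def simulate_decay_series(
    half_life: float,
    I0: float = 100.0,
    times=None,
    sigma: float = 0.05,
    n_replicates: int = 3,
    seed: int = 0,
) -> DecayTable:
    """First-order decay measurements: ``I0 * exp(-ln2 * t / half_life)`` with
    multiplicative Gaussian noise of relative SD ``sigma``, floored at a small
    positive value. Default grid 0..24 h every 2 h, 3 replicates."""
    if half_life <= 0:
        raise ParameterError("half_life must be > 0")
    if times is None:
        times = np.arange(0.0, 25.0, 2.0)
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ParameterError("times must be >= 0")
    rng = np.random.default_rng(seed)
    t_all = np.tile(times, n_replicates)
    rep = np.repeat(np.arange(n_replicates), len(times))
    clean = I0 * np.exp(-math.log(2.0) * t_all / half_life)
    vals = clean * (1.0 + rng.normal(0.0, sigma, clean.shape))
    vals = np.maximum(vals, 1e-9 * I0)
    return DecayTable(times=t_all, values=vals, replicates=rep)
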