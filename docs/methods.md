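# Methods

## The generative model

The simulator encodes the sequential positive-feedback picture of adipogenic
commitment as a minimal piecewise-linear kinetic skeleton. Normalized PPARG
`n(t) ∈ [0, 1]` of a differentiating cell is 0 until CEBPB onset `t_B = 4 h`,
then rises with slope `s1 = 0.0035 /h` (stimulus-driven Phase 1), steps to
`s2 = 0.0080 /h` at CEBPA engagement `τ_A = 17 h` and to `s3 = 0.0250 /h` at
FABP4 engagement `τ_F = 27 h` (Phase 2), crosses the commitment threshold
`θ = 0.253` at

    t_hit = τ_F + (θ − n(τ_F)) / s3 = 27 + (0.253 − 0.1255)/0.025 = 32.1 h,

continues with `s4 = 0.0208 /h` until 44 h (Phase 3), and saturates as
`n(t) = 1 − (1 − n(44))·exp(−(t − 44)/12)`. Absolute intensity is
`P(t) = P_basal·(1 + (fold_P − 1)·n(t))` with `P_basal = 100 AU` and
`fold_P = 8`. Normalized FABP4 leaks at `0.0008 /h` from `t_B`, rises at
`0.0048 /h` from `τ_F`, and surges exponentially (rate `ln(10)/35 /h`) from
44 h, capped at 1; the absolute fold range is drawn log-uniformly from
[100, 2000] per cell. These slopes and breakpoints were calibrated once so
that the canonical cell reproduces the anchor set ~10% of maximal PPARG at
24 h, ~50% at 44 h, 10% of maximal FABP4 at 44 h, ~8-fold PPARG range, and a
32.1-h threshold crossing; the calibration is frozen and asserted by tests.

A piecewise-linear skeleton (rather than a mechanistic ODE) was a deliberate
choice: every statistic the package computes — windowed slopes, engagement
steps, fraction-of-maximal anchors, threshold crossings — is a direct
geometric property of the trajectory, so the minimal model that exhibits the
right geometry keeps calibration transparent and analytically checkable.

Undifferentiated cells rise at `0.7·s1` with no engagements, never approach
θ, and relax exponentially toward basal (time constant 24 h) after stimulus
removal at 48 h; their FABP4 stays on the leak slope and relaxes likewise.

### Heterogeneity, noise, artifacts

Per cell: one timing jitter δ ~ Normal(0, 3 h), clipped at ±8 h, shifts τ_A
and τ_F together (the feedback order is preserved across cells, so a single
shared δ); independent lognormal factors with CV 0.15 scale `s1..s4`, clipped
to [0.5, 2] to exclude physically meaningless draws (the clip bites with
probability ~2×10⁻⁶). FABP4's leak/mid slopes are left deterministic so the
early-suppression property (below 3% of maximal before τ_F) holds for every
cell. Measurement noise is multiplicative lognormal (σ = 0.05) per frame and
channel. Tracking artifacts exist solely to exercise QC: 5% of traces are
truncated to 50–94% of their duration, 3% start between 4 and 12 h, 2% carry
a single 2–4× intensity spike. Randomness is drawn from three substreams
(structure / noise / artifacts) spawned from one seed, so zeroing the noise
and artifact rates reproduces the same cells' clean trajectories.

### Perturbation scenarios

The fate coin (p_diff = 0.6) is flipped identically in every scenario;
scenarios modify what would-be differentiating cells do, so a knockdown
population is statistically identical to control *before* the targeted
engagement point — the property the divergence-time analysis measures.

* `siCEBPB`: differentiating-fate cells ramp at `0.25·s1`, no engagements.
* `siCEBPA`: canonical until τ_A, then the slope stays `s1`; a residual
  fraction (5% of the population) escapes and differentiates fully.
* `siFABP4`: canonical until τ_F, then the slope stays `s2` (10% escape).
  Arrested cells relax after stimulus removal and end undifferentiated.
* `rosi`: `s2, s3` multiplied by 1.8 (ligand bypass accelerates Phase 2).
* `siFABP4_rosi`: τ_F engagement restored at `0.7·s3` (partial rescue).
* `nonstimulated`: flat basal on both channels.

`p_escape` is the *population* fraction that still differentiates; the escape
probability within the differentiating-fate pool is `p_escape / p_diff`.

### What the generator does not emulate

No cell division, movement or spatial context; no interior tracking gaps
(only head/tail truncation); no post-threshold PPARG dip after stimulus
removal in committed cells (monotone saturation instead — none of the
implemented statistics depend on it); no FABP5 compensation kinetics beyond
the escape fractions; noise is stationary and uncorrelated across frames,
unlike slow focus or illumination drifts in real microscopes. Passing
recovery tests on this generator therefore shows the analysis is correct and
calibrated for trajectory geometry plus iid multiplicative noise, not that it
is robust to every real-world imaging pathology.

## Analysis procedures and numerical choices

**QC.** Three rules: last frame more than 6 h before the grid end; first
frame more than 4 h after the grid start; any frame-to-frame relative PPARG
change above 1.0 (a doubling/halving in 12 min is implausible for a
fluorescent protein; the cutoff is configurable, and the rule is evaluated on
PPARG only). Idempotent, and loosening any parameter never removes a
previously kept trace.

**Fate calls.** 2-component Gaussian mixture on log₁₀ endpoint PPARG (the
modes are ~8-fold apart and closer to log-symmetric; linear space is a flag
away), k-means++ initialization, 10 restarts, fixed random state for
determinism. A BIC comparison against the 1-component fit flags effectively
unimodal inputs, which the classifier refuses. Posterior ties go to
undifferentiated.

**Commitment threshold.** Candidates are midpoints between consecutive
sorted distinct 48-h values plus both extremes; predicted-positive means
value ≥ threshold. Among candidates with FPR < 5% the default rule maximizes
TPR, then minimizes FPR, then takes the middle candidate — the maximum-margin
threshold, which on cleanly separated fates is the single candidate in the
gap between the classes and maximizes TPR − FPR subject to the constraint.
`rule="min_feasible"` gives the alternative maximum-sensitivity reading (the
smallest constraint-satisfying candidate, which hugs the undifferentiated
upper tail). When several conditions share an experiment, the mixture and
threshold come from the bimodal control and are transferred to the other
conditions without refitting. For fixed-cell endpoint data the threshold is
the midpoint between the two mixture-component means in log space —
equivalent to the center between the histogram peaks but insensitive to bin
width. A value exactly at threshold counts as differentiated (determinism).

**Hit times.** First crossing of the threshold by each differentiated cell's
PPARG trace, linearly interpolated between the bracketing frames (removes the
~+0.1 h discretization bias of first-frame-at-or-above at 12-min sampling;
configurable). Cells already above threshold hit at their first frame; cells
never crossing are counted separately.

**Engagement detection.** The slope series is a ±4 h windowed OLS fit
(masked where fewer than 5 frames fall in the window). Baseline = median
slope over 8–16 h (inside Phase 1, past the onset transient); engagement =
first time the slope reaches 2× baseline and stays there for 2 h. The rule
formalizes what is otherwise read off a slope plot; all three knobs are
exposed, and a non-positive baseline requires an explicit absolute floor.
On the canonical cell it fires at 18.6 h, ~1.6 h after τ_A, because the
windowed slope needs part of the window past the breakpoint before it clears
2× baseline — a known, documented lag of the detector, not of the model.

**Path geometry.** Per-cell min-max normalization of (PPARG, FABP4) onto the
unit square; the ensemble mean path averages cells at 101 equal arc-length
fractions (cells traverse at different speeds; time-averaging would smear the
corner). The asymmetry score is the shoelace area of the path closed along
the diagonal: +0.5 for a path along the bottom-right boundary, 0 on the
diagonal, positive whenever the x-channel leads.

**Binned averages.** Equal-count (quantile) bins of the 48-h PPARG level —
robust to the long right tail — with ties broken by cell-id order; per-bin
pointwise mean traces for every channel.

**Divergence timing.** Per-frame Kruskal–Wallis (2 groups, tie-corrected,
χ² approximation; log p computed from the χ² log-survival function so it
stays finite far below floating-point underflow of p). Frames with fewer
than 5 cells in either group are masked. The divergence time is the first
frame with log p below −20; natural log is the default (e⁻²⁰ ≈ 2×10⁻⁹) with
base-10 selectable, and no multiple-testing correction is applied across
frames — the extreme cutoff plays that role. The detector is a changepoint
heuristic: it fires only after enough evidence accumulates, so its estimate
lags the true engagement by an amount that grows with the within-population
spread (~1.5 h at the CEBPB onset, ~2 h at τ_A, ~3 h at τ_F under default
conditions; see limitations).

**Decay fits.** Nonlinear least squares of `I0·e^(−kt)`, initialized from
the log-linear regression, residuals weighted by the observed intensities
(chase noise is multiplicative, and unweighted fits undercover: measured 95%
CI coverage ~84% unweighted vs ~93% weighted at σ = 0.05); 95% CI on k from
the asymptotic covariance with a t quantile (n − 2 df), half-life bounds by
inverting the k interval (respects positivity, unlike the delta method).
A plateau term is available behind a flag; `k` effectively zero over the
observed span is reported as non-decaying rather than an error.

**Determinism.** Every stochastic routine takes a seed; the pipeline spawns
per-stage substreams from one global seed, and reports contain no timestamps,
so identical inputs give byte-identical JSON.

## Problem sizes

Default analyses use 1,000-cell populations (700 per arm for divergence
comparisons, matching the ~700-trace cohorts typical of a live-imaging
experiment) on a 481-frame grid; recovery statistics aggregate 10 replicate
simulations, and coverage/calibration checks use 100 replicates. A full
pipeline run is a few seconds on one CPU.

## Known limitations

* The 48-h commitment threshold is only identified up to the gap between the
  two fate populations at the decision time. Under default conditions the
  undifferentiated population tops out near 0.18 (normalized) while the
  slowest differentiators are near 0.48, so any data-driven scan places the
  threshold somewhere in that wide gap — the max-margin rule at ~0.33, the
  max-sensitivity rule at ~0.15 — rather than at the generating θ = 0.253.
  Pinning θ itself requires stimulus-removal (irreversibility) information
  that a single-snapshot ROC scan does not see. Mean recovered hit times
  shift accordingly (~+2.8 h for max-margin, ~−5 h for max-sensitivity
  relative to the generating 32.1 h).
* The divergence-time estimator inherits the detection lag described above;
  its estimates are upper bounds on the true engagement times, tightest when
  within-population heterogeneity is small. The engagement *ordering* is
  nevertheless recovered in every replicate under default conditions.
* The engagement detector's baseline window assumes Phase 1 spans roughly
  8–16 h; shifting `t_B` or `τ_A` materially requires re-choosing the window.
* Mixture-based fate calling needs both modes present; unimodal conditions
  must use a transferred control threshold.
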