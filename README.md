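# fatecommit

Single-cell trajectory analysis of adipogenic fate commitment.

During adipogenesis, preadipocytes decide between two terminal states, and
the master regulator PPARG carries the decision: cells whose PPARG level
crosses a threshold just before the differentiation stimulus is removed
commit irreversibly and differentiate; cells below it return to the basal
state. Live-cell imaging of citrine-PPARG (and FABP4-mKate2) reporters
produces per-cell intensity time courses — one frame every 12 min over 96 h —
whose analysis raises a recurring set of questions: which traces are
trustworthy, where is the commitment threshold, when does each cell cross it,
and when do the positive feedbacks that drive the rise (PPARG–CEBPA, then
PPARG–FABP4) become engaged?

`fatecommit` packages that analysis for anyone working with two-reporter
differentiation time courses, together with a calibrated synthetic trajectory
generator so every stage can be exercised, tested and benchmarked without
microscopy data.

## What's inside

* **Trajectory containers and I/O** (`fatecommit.traces`) — long-format CSV
  traces on a regular time grid, endpoint snapshots, decay tables, validation.
* **Synthetic generator** (`fatecommit.simulate`) — a three-phase piecewise
  model of normalized PPARG *n(t)*: slope *s₁* from CEBPB onset (4 h), *s₂*
  after CEBPA engagement (τ_A = 17 h), *s₃* after FABP4 engagement
  (τ_F = 27 h) until the commitment threshold θ = 0.253 is crossed at 32.1 h,
  then *s₄* and saturation; FABP4 stays near basal until late and then surges
  100–2,000-fold. Cell-to-cell timing jitter, slope heterogeneity,
  measurement noise, tracking artifacts, and knockdown/rescue scenarios
  (siCEBPB, siCEBPA, siFABP4, rosiglitazone) are all parameterized, with
  per-cell ground truth recorded.
* **Trace QC** (`fatecommit.qc`) — the three exclusion rules: absent near the
  endpoint (6 h), late start (4 h), implausible frame-to-frame PPARG jumps.
* **Fate and threshold** (`fatecommit.commitment`) — 2-component Gaussian
  mixture on log₁₀ endpoint PPARG; FPR-constrained ROC scan for the 48-h
  commitment threshold; control-to-condition threshold transfer;
  histogram-midpoint threshold for fixed-cell data; percent differentiated;
  interpolated threshold hit times.
* **Feedback dynamics** (`fatecommit.dynamics`) — ±4 h sliding-window OLS
  slopes, engagement-point detection, unit-square (PPARG, FABP4) path
  normalization with a diagonal-asymmetry score, quantile-binned trace
  averaging, fold changes.
* **Divergence timing** (`fatecommit.divergence`) — per-frame Kruskal–Wallis
  comparison of two populations and the first log *p* < −20 crossing.
* **Decay kinetics** (`fatecommit.decay`) — first-order cycloheximide-chase
  fits, half-life with 95% confidence bounds.
* **Pipeline, reports, CLI** (`fatecommit.pipeline`, `fatecommit.report`,
  `fatecommit` command) — one-seed deterministic orchestration and
  machine-readable run summaries.

## Worked example

`examples/02_commitment_threshold.py` simulates 1,000 DMI-stimulated cells,
applies QC, calls fates from the bimodal 96-h endpoint and scans for the 48-h
commitment threshold:

```text
mixture modes at 110 and 795 AU (weights 0.38/0.62)
fate calls match simulator ground truth for 100.0% of cells
48-h commitment threshold: 338 AU (FPR 0.000, TPR 1.000)
hit times: mean 35.3 h, SD 2.8 h over 557 differentiated cells (0 never crossed)
```

The two mixture modes are the undifferentiated (~110 AU, basal-like) and
differentiated (~795 AU, ~8-fold up) populations; the scan places the
threshold inside the gap separating the two fates at 48 h with zero false
positives, and the hit-time distribution is unimodal with a mean a few hours
after the FABP4 feedback engages. The other example scripts cover simulation
and QC, engagement detection and path geometry, knockdown divergence timing
(`siCEBPB < siCEBPA < siFABP4` in every run), and half-life fitting; each
prints one short annotated block like the above.

The same stages are available as a thin CLI:

```sh
fatecommit simulate --seed 1 --n-cells 500 --out traces.csv
fatecommit qc --in traces.csv --out kept.csv --report qc.json
fatecommit threshold --in kept.csv --out threshold.json
fatecommit hits --in kept.csv --threshold threshold.json --out hits.csv
```

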