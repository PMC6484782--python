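# Methods

This note documents the models and procedures implemented in `synclamp`,
the parameter choices behind them, and what the synthetic-data experiments
do and do not establish.

## The plant: a stochastic budding-yeast population

Each cell carries a total fluorescence content `G` (the α-synuclein-GFP
pool) and a volume proxy `V`; the *measured* normalized fluorescence is the
concentration `G / V`. Content follows a linear induction/decay law,

    dG/dt = (p_gal · u + p_basal) · φ · V  −  δ · G,

integrated with the exact exponential update of the linear ODE at 1-min
internal steps, where `u ∈ [0, 1]` is the galactose fraction of the medium
(zero-order hold over each 5-min sampling period), `φ` is a static per-cell
lognormal production factor (mean 1, CV = `extrinsic_noise_cv`), and `δ` is
a first-order loss rate. Production scales with volume, as ribosome content
does. A small multiplicative lognormal jitter (CV 0.02) is applied to the
state once per sampling period; cell-to-cell variability is dominated by
`φ`, which is the standard extrinsic-noise picture and what sets the
steady-state population CV of ≈0.25 seen in the traces.

**Division and dilution.** The cell cycle alternates an unbudded (G1) phase
and a budded (S–G2–M) phase (`budded_fraction` = 0.6 of a sampled
normal-distributed cycle length). During the budded phase `V` grows from 1
to `1/(1−s)` where `s` is the shed fraction; at division the mother keeps
`(1−s)·G` and volume 1, the daughter receives `s·G` and volume `s/(1−s)`.
With the default `s = 0.38` — derived from the newborn/mother size ratio
0.61 via `s = 0.61/1.61` — the daughter volume is exactly 0.61 and
concentration is continuous through division for both cells. Two
consequences follow without further assumptions:

* under active production, measured per-cell fluorescence is smooth through
  divisions (only a small dip from G1 regrowth of the daughter), matching
  the small inter-cycle drops seen in controlled single-cell experiments;
* with production off (clearance), content is frozen, so concentration
  falls by exactly `s` across each budded phase — the 38% drop at division,
  realized as dilution by bud growth.

Total fluorescence content is conserved exactly at division
(`mother + daughter = parent`, by construction `daughter = s·G`,
`mother = G − s·G`).

**Aggregation.** Each cell samples a personal aggregation threshold from a
lognormal with strain-specific mean and CV (WT 13.1 n.u., CV 0.18; A53T
7.4 n.u., CV 0.28) — lognormal guarantees positivity. A cell aggregates
once its concentration has stayed at or above its threshold continuously
for an exponentially distributed delay (mean 12 min WT, 20 min A53T).
Aggregation switches the cycle-length mean from the pre- to the
post-aggregation value (110→145 min WT, 96→140 min A53T) and permanently
arrests a small fraction of cells (6% WT, 11% A53T).

**Chamber.** Cells live in a monolayer of finite capacity (default 120).
Mothers are trapped; daughters join the population while capacity allows
and are otherwise recorded as births that immediately leave the field of
view. Newborns are placed adjacent to the mother at the angle with the most
clearance, which keeps nearest-neighbour lineage assignment well posed.
Centroids wobble by 0.5 px per sampling period.

**Clearance experiments.** Cells start with inclusions and
clearance-normalized fluorescence ≈1. Production is off; the time to first
bud (TFB) is lognormal with mean `tfb_base_mean · m(treatment)` and CV
0.35. The treatment multipliers (rapamycin 0.5, untreated 1.0, MG132 1.5,
PMSF 2.5) are **not measured values** — only their ordering is constrained
by the study; the magnitudes are package defaults. MG132 additionally
multiplies the cycle length by 1.4 (its reported cell-cycle impairment).
Inclusions are scored as dissolved when normalized fluorescence falls below
0.35, which ties the disappearance time to TFB plus a few division times
and reproduces the strong TFB–clearance correlation mechanistically.

**Free parameters.** The induction kinetics of the GAL1 promoter in these
strains are not reported, so `p_gal = 0.3` n.u./min, `p_basal = 0`, and
`δ = 0.01`/min are package calibrations chosen once so that (a) the
open-loop step response settles on the timescale of a few hundred minutes
and (b) the closed loop can reach and hold the full 2–18 n.u. range used by
the stepwise experiments with `u ≤ 1` despite division dilution.

## The controller

The prediction model is the study's 3-state linear difference system: two
dynamic states in observable canonical form plus a constant disturbance
state `x3` entering the output (`y = c1·x1 + c2·x2 + x3`). `x3` receives
nonzero process noise in the Kalman filter — the standard offset-free MPC
construction — so model/plant mismatch (including average division
dilution) is absorbed as an estimated output disturbance and the
steady-state tracking error vanishes.

* **Identification.** No numeric model parameters ship with the package:
  `run_closed_loop` identifies the model at run time by ARX(2) least
  squares on a noise-free, non-dividing simulator step response (free-run
  RMSE ≈ 1e-12 on that data). The fit degrades gracefully and is flagged
  `low_quality` when the output is noise-dominated.
* **Kalman filter.** Joseph-form covariance update (keeps P symmetric
  PSD); `q = 1e-3`, `r = 0.1` on the normalized-unit scale. These are
  design choices, not measured values.
* **MPC.** One scalar `u` held over the 120-min prediction horizon,
  minimizing the sum of squared predicted errors with bounded Brent search
  (the cost is quadratic in a scalar on an interval; an SQP solver adds
  nothing). Only the first period is applied (receding horizon); the pulse
  duration is `d = u·T`. A full input-sequence mode exists behind
  `optimize_sequence`. The reference is held at its current value over the
  horizon by default: previewing future set-point steps makes the
  controller ramp up before each step, whereas the platform's recorded
  traces rise only after a step; `reference_preview=True` enables
  anticipatory tracking.
* **Calibration.** The first 15 min of every experiment run under glucose
  (`u = 0`); in single-cell mode the controlled cell is chosen uniformly at
  random at the end of calibration and the shared medium actuates the whole
  chamber.

## Imaging, tracking, statistics

**Segmentation** Gaussian low-pass (σ=1) → linear stretch of the 1st–99th
percentiles (falling back to the full range when cells cover <1% of pixels,
and declaring the scene blank when the stretch range sits within 8× the
robust noise scale) → Canny edges → circular Hough transform over radii
4–15 px. `sensitivity` (default 0.5) is the minimum fraction of a circle's
perimeter that must be supported by edge votes; overlapping detections
closer than `0.8·(r1+r2)` keep only the stronger peak. These settings were
chosen on rendered fixtures — the original platform's values are not
published. On 100 random 5-cell frames the round trip achieves recall 1.0,
centroid RMSE ≈ 0.4 px, and ≤0.1% quantification error.

**Quantification and normalization.** Per-cell mean over the mask disk
minus the mean of a background rectangle outside the chamber; values may go
slightly negative and are not clipped. Control experiments normalize GFP by
the calibration-phase mCherry mean (15 min, 3 frames); clearance
experiments normalize by the 5-min calibration GFP so traces start at ≈1.
In the imaged closed-loop path the same-frame mCherry is used as the
calibration estimate (it is constitutive and temporally constant in the
simulator), which avoids having to track cells inside the control loop.

**Tracking and lineage.** Frame-to-frame identity is the
minimum-total-displacement assignment (Hungarian algorithm on a padded cost
matrix whose pad cost `max_disp` acts as the gate: a link forms only when
it is cheaper than a loss plus a birth). Births take the nearest
already-tracked cell as mother (ties to the lower id). Nearest-neighbour
mothering is exact for well-separated lineages and degrades in crowded
neighbourhoods where siblings and grandmothers tie; the tests assert exact
recovery in the separated regime and ≥80% in crowded simulator movies.

**Threshold classifier.** Samples are labeled by the ground-truth
aggregation time (`t ≥ tA` → aggregation; cells without `tA` contribute
only negatives). The scan set is {−∞} ∪ {midpoints of consecutive sorted
unique x} ∪ {+∞}, which contains a global maximizer of the empirical
accuracy; ties break to the smallest candidate. This replaces the original
genetic-algorithm search — on a one-dimensional threshold the exhaustive
scan is exact and deterministic. The bootstrap null permutes labels
uniformly and scores each resample with the *fixed* fitted threshold (no
re-fit); because the count of positive labels landing on flagged points is
hypergeometric under permutation, the implementation samples that count
directly — one draw per resample, identical in distribution to
materializing each permuted dataset.

A systematic feature worth knowing: the accuracy-optimal single threshold
sits a few percent *below* the planted per-cell threshold mean, because
cells with low personal thresholds aggregate earlier in the ramp and
contribute disproportionately many aggregation-labeled samples. The
recovered WT threshold is typically 8–10% below 13.1 n.u.; the A53T
threshold 3–5% below 7.4 n.u. The same asymmetry is inherent in the
original experimental design.

**Clearance statistics.** Drop at division uses boundary samples — the last
sample at/before the bud event and the first at/after the division. The
dilution model predicts `f0·(1−s)^i` at the i-th division; its error is the
elementwise percentage difference. The population mean uses only cells
present for the whole experiment; `t_1/2` is linearly interpolated between
5-min samples. The Conover–Iman statistic uses shared Kruskal–Wallis ranks,
`S² = (Σr² − N(N+1)²/4)/(N−1)`, and Student's t with `N−k` degrees of
freedom, unadjusted by default (Bonferroni behind a flag). Censored TFBs
(no bud within the experiment) are reported at the experiment length and
excluded from the TFB–clearance correlation.

## Problem sizes and determinism

The acceptance script uses 20 seeds × {53 WT, 64 A53T} cells for the ramp
cohorts (nine 500-min levels), 10 seeds × 4 treatments × 25 cells for
clearance, and one 1,500-min single-cell run; population experiments start
from 20–25 mothers with chamber capacity equal to the cohort size so that
the tracked mothers persist for the full experiment. These sizes mirror the
study's cohort sizes. Every random quantity flows from a single seed
argument through `numpy.random.default_rng`; repeated runs are
byte-identical.

## What the synthetic experiments show — and what they do not

The generator plants the published quantities (thresholds and their CVs,
cycle means, delays, the 38% shed fraction) and the pipeline recovers them
through the full measurement chain; this validates the *computations* —
controller, segmentation, tracking, classifier, clearance statistics — not
the biology. Real data differ in ways the plant does not emulate: inclusion
visibility is a manual call on images rather than a threshold crossing with
an exponential delay; phase-contrast texture, focus drift and cell crowding
are absent; budding detection is taken from ground truth rather than
morphology; and the clearance treatment multipliers are ordinal stand-ins.
Quantities that depend only on planted values (e.g. the recovered threshold
ratio) are parameter-recovery checks, not independent measurements.

## Known limitations

* No mechanistic autophagy/proteasome model — treatments act only through
  TFB and cycle-length multipliers.
* No amyloid nucleation/elongation kinetics; aggregation is a phenotype
  switch with a sampled threshold and delay.
* No cell pushing/crowding mechanics; the chamber is a capacity cap with
  immediate loss of surplus newborns.
* The Hough segmenter is tuned for the synthetic renderer's ring contrast;
  real phase-contrast images would need re-tuned enhancement and
  sensitivity.
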