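# synclamp

Closed-loop control and single-cell analysis of α-synuclein aggregation in
budding yeast — as a fully in-silico, tested pipeline.

α-Synuclein dosage drives inclusion formation in the yeast Parkinson's-disease
model: cells expressing the protein (as a GFP fusion, from the
galactose-inducible *GAL1* promoter) form cytoplasmic inclusions only once the
per-cell concentration crosses a threshold. Measuring that threshold requires
holding protein expression at prescribed levels over hours — which is what
automated microfluidics feedback control does: measure per-cell fluorescence
every 5 min, estimate the state of a small linear model with a Kalman filter,
and compute the galactose pulse duration by model predictive control (MPC).

`synclamp` reimplements that platform around a stochastic cell-population
simulator that stands in for cells + microfluidics + microscope, so the whole
loop — and all downstream single-cell statistics — runs on a laptop:

* **`synclamp.plant`** — budding cells with inducible expression, extrinsic
  cell-to-cell noise, sampled per-cell aggregation thresholds, aggregation
  delay, post-aggregation cell-cycle slowdown, asymmetric division (the mother
  sheds 38% of its fluorescence content, from the 0.61 daughter/mother size
  ratio), and treatment-dependent clearance kinetics.
* **`synclamp.control`** — the 3-state linear prediction model with a constant
  disturbance state, Kalman filtering, and receding-horizon minimization of
  the predicted squared tracking error with the pulse duration `d = u·T ∈ [0, 5]`
  min; model parameters are identified from simulator step responses.
* **`synclamp.imaging`** / **`synclamp.render`** — synthetic phase-contrast /
  GFP / RFP frames, circular-Hough segmentation, background-subtracted
  per-cell quantification, mCherry normalization.
* **`synclamp.tracking`** — optimal-assignment frame linking (Hungarian
  algorithm), lineage reconstruction, and the single-cell trace filters
  (span > 500 min; peak ≥ 16 n.u. WT / 10 n.u. A53T).
* **`synclamp.aggregation`** — the aggregation threshold classifier
  `f(x) = aggregation iff x ≥ l`, fitted by exhaustively maximizing
  `ACC = (TP + TN)/N`; bootstrap permutation null; aggregation delay;
  cell-cycle statistics; Student's t test; boxplot outlier rule.
* **`synclamp.clearance`** — time to first bud (TFB), drop at division, the
  38%-per-division dilution model and its prediction error, population
  half-time, Conover–Iman rank-sum comparisons, TFB–clearance correlation.
* **`synclamp.experiment`** / **`synclamp.cli`** — the closed-loop harness
  (population or single-cell control, ground-truth or imaged measurement
  path) and the `synclamp` command-line interface.

## Worked example

Recover the wild-type aggregation threshold from a simulated nine-level
stepwise induction experiment (500 min per level, population-mode MPC):

```python
from synclamp.experiment import generate_aggregation_cohort
from synclamp.aggregation import bootstrap_random_accuracy, aggregation_cv

cohort = generate_aggregation_cohort("WT", n_cells=53, seed=1001)
fit = cohort.fit
print(f"threshold l = {fit.l:.2f} n.u., ACC = {fit.acc:.4f} "
      f"(TP={fit.tp}, TN={fit.tn}, N={fit.n})")
print(f"random ACC  = {bootstrap_random_accuracy(cohort.dataset, fit, 10_000, seed=1001):.4f}")
print(f"CV at aggregation = {aggregation_cv(cohort.fluor_at_aggregation):.3f}")
```

prints

```
threshold l = 11.71 n.u., ACC = 0.9114 (TP=17929, TN=25592, N=47753)
random ACC  = 0.5128
CV at aggregation = 0.187
```

The fitted threshold sits near the planted per-cell threshold mean of
13.1 n.u. (slightly below it, because cells with low personal thresholds
aggregate earlier in the ramp and contribute more aggregation-labeled
samples); the classifier's 91% accuracy against a 51% permutation null shows
the label structure is genuinely concentration-driven, and the CV across
cells at their aggregation time recovers the planted dispersion of 0.18.

The same machinery is available from the shell:

```
synclamp control --mode population --ref 4:2000 --seed 0 --out-dir runs/demo
synclamp analyze-aggregation --traces runs/demo/traces.csv --out runs/demo/report.json
```

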