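# blankqc

Blank-injection conditioning analysis for untargeted LC-MS metabolomics
batches.

## The problem

Untargeted UPLC-MS batches interleave extraction blanks with samples: the
blanks are needed to identify background features (plasticizers, solvent
impurities, carry-over), but injecting them *deconditions* the analytical
system — the column and source lose the steady state built up by repeated
matrix injections, and the next several samples show shifted intensities,
retention times and peak widths until the system reconditions. How many
post-blank injections must be discarded, and which features are background
rather than biology, are batch-design questions every metabolomics lab
faces and for which there is no standard assessment.

`blankqc` implements a post-acquisition answer for batches designed as
repeated deconditioning/conditioning cycles (a group of 1 or 3 blanks
followed by 8 replicate sample injections, after a leading block of
conditioning QCs). It takes an already-built peak table (features ×
injections matrices of peak area, RT and peak width, e.g. exported from
XCMS) and provides:

* **QC-SVRC drift correction** — per-feature ε-insensitive support vector
  regression (RBF kernel) of intensity over run order, trained on
  reference injections (leading QCs plus the pre-blank samples), with
  C = median(reference), ε searched over 3–10 % of the median and γ over
  [1, 1e5] by leave-one-out RMSECV; corrected = area · median/trend.
* **Blank-based feature screening** — a feature is *informative* iff
  min(sample)/max(blank) > 9, more than 90 % of replicates exceed 9 × the
  blank maximum, and RSD(QCs) < 20 % after correction; *column carry-over
  +k* features follow the sequential detection pattern (present in blanks
  1..k and samples k+1..8, absent in between) across the 3-blank cycles;
  the rest shared with blanks are *contaminants*.
* **Guided-PCA conditioning assessment** — for each post-blank position
  n = 1..7 versus the position-8 reference set, the δ statistic
  δ = var(X v_g)/var(X v_1) ∈ (0, 1], where v_g is the first right
  singular vector of YᵀX (Y the unit-column group indicator) and v_1 that
  of centered X, with a label-permutation p-value
  p = #{δ̂ < δ̂_p}/m — plus per-feature Welch t-tests on area, RT and
  width with Benjamini–Hochberg FDR, counting affected features per
  position.
* **Profile clustering** — hierarchical clustering (1 − Pearson distance,
  average linkage) of cycle-averaged post-blank intensity profiles, to
  separate response families such as the late-eluting lipophilic fraction
  that reconditions slowly.
* **A synthetic-batch generator** with planted ground truth (drift,
  deconditioning kinetics, contaminants, carry-over patterns) for
  validating every stage end-to-end.

See `docs/methods.md` for the models, assumptions and defaults.

## Worked example

```python
from blankqc import BatchConditioning, plasma_like

model = BatchConditioning.from_simulation(plasma_like(seed=1))
model.config.svrc.n_eps, model.config.svrc.n_gamma = 4, 9  # fast grid
res = model.fit(m=200, seed=1, cluster_curves=False)
print(res.summary())
```

prints

```
             Blank-injection conditioning analysis
================================================================
Injections: 170   Features: 260   Permutations m: 200   Seed: 1
Feature classification:
  informative       150
  contaminant        80
  carryover+1        10
  carryover+2         5
  carryover+3        15
  excluded            0
Median QC RSD: 9.00% raw -> 4.56% corrected
----------------------------------------------------------------
Conditioning curve (intense deconditioning), reference position 8:
   n   delta       p  #area    #RT #width
   1   0.993  0.000*    132     66     64
   2   1.000  0.000*    106     67     65
   3   1.000  0.000*     73     67     67
   4   1.000  0.000*     66     66     65
   5   0.997  0.000*     67     70     66
   6   0.325  0.745       0      0      0
   7   0.249  0.795       0      0      0
  recovery (area count at false-positive level): position 6
----------------------------------------------------------------
Conditioning curve (mild deconditioning), reference position 8:
   n   delta       p  #area    #RT #width
   1   0.937  0.005*     66     33     21
   2   0.999  0.000*     71     65     64
   3   0.999  0.000*     67     67     72
   4   0.996  0.000*     67     66     68
   5   0.976  0.000*     44     22     16
   6   0.656  0.200       0      0      0
   7   0.294  0.955       0      0      0
  recovery (area count at false-positive level): position 6
----------------------------------------------------------------
Profile clusters (HCA, 1 - Pearson, average linkage):
  cluster 1: 85 features (56.7%), median RT 2.40 min
  cluster 2: 65 features (43.3%), median RT 5.39 min
================================================================
```

Reading it: all 150 planted informative features survive screening and the
background classes are recovered exactly. After an intense (3-blank)
deconditioning, the sets of samples injected 1–5 positions after the blank
differ significantly from the position-8 reference (δ ≈ 1, permutation
p ≤ 0.005; 132 of 150 features affected at position 1), and the system is
statistically indistinguishable from conditioned at position 6 — exactly
the recovery position planted in the simulation. The two profile clusters
split the early-eluting mildly-affected features (cluster 1) from the
late-eluting strongly-affected ones (cluster 2, median RT 5.4 min).

The same analysis runs from the shell on real exported tables:

```sh
blankqc run --table peaks.tsv --sequence sequence.tsv \
    --detection detection.tsv --out results/ -m 1000 --seed 7
blankqc simulate --preset plasma --seed 1 --out simdir/   # synthetic data
```

`simulate`, `correct`, `screen`, `assess`, `cluster` and `run` subcommands
accept a YAML config (`PipelineConfig.to_yaml`) for thresholds, grids and
simulation parameters.

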