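# Methods

## Scope and data model

The package mirrors the measurement chain of a longitudinal mouse MRI
monitoring study. Four measurement channels feed one long-format cohort
table (animal, sex, genotype, timepoint, measurement, value, exclusion
flag):

1. relaxometry — T1 from Look-Locker inversion recovery, T2 from
   multi-echo spin echo, both per ROI mean signal;
2. volumetry — organ/tumor volumes from integer label masks;
3. histomorphometry — percent iron-positive area from stained sections;
4. cohort statistics — per-timepoint two-group comparisons.

All inputs can be generated synthetically from explicit ground truth, which
is what the tests and the acceptance script use.

## Relaxation models and fitting

**Inversion recovery.** `S(TI) = a − b·exp(−TI/T1*)` with the Look-Locker
correction `T1 = T1*·(b/a − 1)` applied to the fitted parameters; ideal
inversion corresponds to `b = 2a`, in which case `T1 = T1*`. The generator
is parameterized directly by `(a, b, T1*)` (or `T1`, converted through the
correction) rather than an inversion-efficiency parameter, matching the
fitted parameterization.

**Polarity restoration.** Magnitude reconstruction discards the sign of the
inverted early samples. The fitter enumerates flip hypotheses j = 0 … (index
of the signal minimum + 1), negates the first j samples, fits each
hypothesis and keeps the lowest residual sum of squares. The set is small,
so the search is exhaustive and deterministic. Series that already contain
negative values are treated as signed data and fitted directly.

**Echo decay.** `S(TE) = M0·exp(−TE/T2) + c` with `c ≥ 0` (the offset
exists to absorb the magnitude-noise floor, so a negative value has no
physical reading; the bound is enforced in the solver). The first echo of
the train is excluded unconditionally — in a multi-echo spin echo sequence
it is biased by stimulated-echo/slice-profile effects — which makes T2
estimates provably invariant to any corruption of echo 1.

**IRLS.** Both fits run through one routine: weighted nonlinear least
squares (SciPy trust-region-reflective, tolerances 1e-14) alternating with
Huber reweighting, `w = min(1, 1.345·s/|r|)` with scale `s = 1.4826·MAD` of
the current residuals. The weights for the *first* solve are seeded from
the residuals at the starting point rather than set to one: a gross outlier
is then down-weighted before it can steer the initial solve into the wrong
basin. Convergence is declared when the relative parameter step falls below
1e-8; the iteration cap is 200 because the fixed-point iteration contracts
at a rate of roughly 0.86 per step on noisy decay data, needing ~90 steps
to reach that tolerance. `weights_rule="ols"` short-circuits to a single
unit-weight solve (used for oracle comparisons).

**Initialization** is deterministic and derivative-free. IR: `a₀ = max S`,
`b₀ = a₀ + |min S|`, `T1*₀ = t_null/ln 2` from the zero crossing (schedule
midpoint if none). Decay: `c₀ = min S`, and `(M0₀, T2₀)` from a Theil–Sen
(median-of-pairwise-slopes) regression of `log(S − c₀ + ε)` on TE — the
median slope keeps the start sane when one echo is corrupted, which an
ordinary log-linear regression does not.

**Degenerate fits** with `b/a ≤ 1` (implying `T1 ≤ 0`) are returned with
`converged=False` and parameters intact, never clamped.

**Exclusions** are input data, mirroring a manual review workflow. An
optional automated flagger (`auto_exclude_motion`: residual > 4 robust sd
after an initial fit, one refit) is provided but off by default.

**Stability metrics.** For an internal-reference tissue, per-timepoint
percent deviation `100·(x − mean)/mean` and CoV `100·sd/mean` (sample sd,
ddof 1) quantify longitudinal measurement stability per animal.

## Volumetry

Volume is voxel count × voxel volume — the convention of semi-automatic
segmentation tools — with no partial-volume weighting; this makes volumes
exact, additive under label splits, and directly testable against the
phantom generator's analytic shape volumes. World coordinates use the
voxel-center convention `world = origin + (index + 0.5)·spacing`, and
phantom membership is decided at the voxel center with half-open boundaries
on the max side, so a box aligned to the grid rasterizes to an exactly
predictable count. A label touching the grid boundary sets a truncation
flag: the organ may exceed the field of view and the volume is a lower
bound. Onset detection reports the first timepoint a trajectory reaches a
user threshold (the minimum detectable lesion volume is protocol-dependent,
so it is a parameter, default 0.4 mm³); percent change from a zero volume
is undefined and flagged as onset instead.

## Iron histomorphometry

Features per pixel: RGB, two stain-density channels from color
deconvolution with fixed Prussian-blue/nuclear-red absorbance vectors
(configurable), and Gaussian-smoothed copies of all five at scales (1, 2)
px. The classifier is a seeded random forest (50 trees, min leaf 2), with a
linear-discriminant fallback below 64 labeled pixels where an ensemble has
nothing to average over. Training pixels are canonically sorted by flat
image index before fitting, so annotation order cannot change the model.
Tissue is defined as luminance < 0.95 by default (background glass is
near-white); iron load is `100·n_positive/n_tissue` over tissue pixels
only. The synthetic slide generator draws an exact pixel count positive
(optionally clustered through a smoothed random field) around two class
colors with Gaussian jitter — it emulates class colors and granule
clustering but not out-of-focus blur, stain gradients, or annotation error,
so passing tests demonstrate the estimator, not slide-quality robustness.

## Cohort statistics

Per measurement and timepoint: genotype comparisons within each sex and sex
comparisons within each genotype (per-group gating; a pooled switch
exists). The normality gate is Kolmogorov–Smirnov with Lilliefors
correction — the naive KS with plugged-in estimated mean/sd is
anticonservative — toggleable to the uncorrected form; the Lilliefors table
needs n ≥ 4, so n = 3 falls back to the uncorrected test. Zero-variance
groups are non-normal (point mass) and route to Mann–Whitney, where t is
undefined. The Mann–Whitney two-tailed p is exact by full enumeration of
C(n1+n2, n1) rank assignments (midranks under ties) when both n ≤ 8 —
cached for the tie-free case — otherwise the tie- and continuity-corrected
normal approximation. Stars: *, **, *** at p ≤ 0.05/0.01/0.001. No
multiple-testing correction by default; Benjamini–Hochberg is an explicit
opt-in flag.

Under the null (Gaussian, n = 7/group) the gated procedure's measured
type-I rate is slightly below nominal (the exact MW branch is discrete),
comfortably inside [0.03, 0.07] at α = 0.05.

## Synthetic cohort generator

Defaults are the study design the package targets: 7 animals per sex ×
genotype, visits at 2, 4, 6, 8, 10, 12 months. Measurement values are
`baseline(t) + genotype_effect·[mutant] + sex_effect·[male] + N(0, sd)`
with effects scalar or per-timepoint. Default measurements and scatter are
chosen as typical adult-mouse abdominal MRI values: body weight rising
22→30 g (males +6 g, sd 1.5 g), vertebral marrow T1 ≈ 700 ms (sd 20 ms),
splenic T2 ≈ 15–16 ms (males +2.5 ms — females carry more splenic iron,
which shortens T2; sd 1.2 ms), splenic volume 70–100 mm³ (sd 8 mm³). The
tumor model samples a per-animal onset from per-visit hazards (defaults:
mutant females 0.08/visit, mutant males 0.015, controls 0 — lesions are
overwhelmingly a mutant-female event), then grows volume geometrically
(×4/visit from 0.5 mm³). The generator emulates group structure, effect
sizes and onset patterns; it does not emulate within-animal correlation
across visits, dropout, or measurement-protocol failures.

## Signal noise model

Magnitude-mode noise is Rician: independent Gaussian components of sd σ on
the real and imaginary parts of the noiseless signal, then the magnitude.
This yields the nonzero noise floor at long TE (absorbed by `c`) and the
rectification of negative IR samples (undone by polarity restoration).
Gaussian mode adds signed noise directly. Default schedules: 50 inversion
times from 7 ms in uniform 140 ms steps (sampling schedules vary by
protocol, so the schedule is always explicit input; this is only the
packaged default), and 14 echoes at 6 ms spacing (TE 6–84 ms).

## Pipeline and determinism

One `RunConfig` (YAML-loadable) drives all stages; all child seeds derive
from the master seed via `numpy.random.SeedSequence` (kept below 2³¹).
Outputs are plain CSV/Markdown/JSON with no timestamps; the manifest lists
every written file with its SHA-256, per-stage counts, and warnings
(non-converged fits, truncated labels, exclusions), so identical config +
seed reproduces byte-identical runs. In synthetic mode the per-animal
relaxation series are generated with ground-truth T1/T2 equal to the
cohort's drawn values (ideal inversion, SNR 50, magnitude noise, a 15%
first-echo bias), so fitted values can be audited against the cohort truth.

## Problem sizes

Tests and the acceptance script run the chain at desk scale, chosen so the
statistical checks retain power: 125-point noiseless parameter grids; 200
noise realizations for stability and robustness rates; 20 slides at
150×150 px for iron recovery; 2000 simulated null cohorts for type-I
calibration; pipeline determinism at 3 animals/group × 3 visits with
120-px slides. Library defaults remain the full design (7/group, 6 visits,
200-px slides).

## Known limitations

- ROI-mean fitting only; voxelwise mapping is a convenience, not a goal.
  No B1/inversion-efficiency correction, no multi-exponential T2.
- Volumetry trusts the input mask; no segmentation, no partial-volume
  model, no wall-thickness measurement.
- The pixel classifier is trained per staining batch; no stain
  normalization across batches is attempted.
- The statistics are per-cell two-group tests, as in standard phenotyping
  reports — no mixed-effects longitudinal modeling, and no correction for
  the many tests unless BH is enabled.
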