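# mrimon

Quantitative analysis for longitudinal small-animal MRI tumor-monitoring
studies: MR relaxometry, organ volumetry, stain-based iron quantification
and cohort-level statistics — plus a synthetic-data generator that emulates
every input, so the full chain runs and is testable without any scanner
data.

## Who this is for

Preclinical imaging groups that follow mouse cohorts (e.g. 2 sexes x 2
genotypes, repeated abdominal MRI over months) and need the downstream
numbers: tissue T1/T2 per visit, spleen/cecum/tumor volumes from
segmentation masks, percent iron-positive area from stained sections, and
the per-timepoint two-group comparisons that tie it together.

## The models at the core

**T1 (Look-Locker inversion recovery).** The sampled recovery follows

```
S(TI) = a − b·exp(−TI/T1*),     T1 = T1*·(b/a − 1)
```

where `T1*` is the apparent relaxation time under the repeated low-flip
readout and the correction recovers the true T1. Magnitude data is
polarity-restored (every candidate flip index up to one past the signal
minimum is fitted; best residual wins).

**T2 (multi-echo spin echo).** Echo decays follow

```
S(TE) = M0·exp(−TE/T2) + c
```

with `c ≥ 0` absorbing the magnitude-noise floor; the first echo is always
excluded from fitting. Both models are fitted by iteratively reweighted
least squares (Huber weights, MAD scale), so isolated motion-corrupted
frames are down-weighted instead of dragging the estimate.

**Volumetry** is exact voxel counting (`volume = n_voxels × voxel volume`),
with percent-change trajectories and threshold-based tumor-onset detection.
**Iron load** is a supervised per-pixel classifier (color + stain-unmixed +
multiscale features) reporting percent positive area over tissue.
**Statistics** follow the standard phenotyping policy: Kolmogorov–Smirnov
(Lilliefors) normality gate, then unpaired two-tailed t test or two-tailed
Mann–Whitney (exact by enumeration for n ≤ 8), starred at 0.05/0.01/0.001.

## Worked example

```
$ python examples/01_t1_relaxometry.py
true T1        : 700.0 ms (b = 2a, so T1* = T1)
fitted a, b    :   1003.7,   2004.1  (signal units)
fitted T1*     :    704.9 ms  (apparent, Look-Locker)
corrected T1   :    702.6 ms  = T1* x (b/a - 1)
polarity flips : 4 early samples restored to negative
converged      : True, residual rms 14.8
```

A magnitude recovery curve generated at SNR 50 (true T1 = 700 ms) is
polarity-restored (4 rectified pre-null samples flipped back negative) and
fitted; the Look-Locker-corrected T1 lands within 0.4% of truth. The other
examples cover robust T2 with a corrupted echo (`02`), phantom volumetry
and tumor trajectories (`03`), iron quantification (`04`), cohort
statistics (`05`) and the end-to-end pipeline with its checksummed run
manifest (`06`).

The `mrimon` CLI wraps the shell-facing pieces:

```
mrimon run --seed 1 --out-dir runs/demo      # full synthetic pipeline
mrimon fit-t1 series.csv --out t1_fits.csv   # fits from a long-format CSV
mrimon volumes image.nii mask.nii --labels spleen=1,cecum=2,tumor=3
mrimon cohort-report cohort.csv --mtc bh
```

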