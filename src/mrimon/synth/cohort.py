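"""Longitudinal synthetic cohorts: 2 sexes x 2 genotypes x repeated MRI visits.

The generator emulates a monitoring study design of n animals per sex and
genotype followed over a schedule of ages.  Each measurement is drawn as

    value = baseline(timepoint) + genotype_effect·[mutant] + sex_effect·[male]
            + Normal(0, residual_sd)

with effects either constant or specified per timepoint, so configured
group differences are known exactly and group-level statistics can be
checked against them.  An optional tumor model samples a per-animal onset
timepoint from per-visit hazards (by genotype and sex) and grows the lesion
geometrically from an initial volume; before onset the tumor is simply not
visible and produces no record, matching how lesions enter a monitoring
table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEXES = ("f", "m")
GENOTYPES = ("mutant", "control")

#: default visit schedule: ages in months
DEFAULT_TIMEPOINTS = (2.0, 4.0, 6.0, 8.0, 10.0, 12.0)


def _per_timepoint(value, n_tp: int) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(n_tp, float(arr))
    if arr.size != n_tp:
        raise ValueError("per-timepoint effect length must match timepoints")
    return arr.astype(float)


@dataclass
class MeasurementEffect:
    """Ground-truth structure of one measurement across the study.

    ``baseline`` is the control-female mean per timepoint (scalar or one
    value per timepoint); ``genotype_effect`` and ``sex_effect`` shift
    mutants and males respectively (scalar or per timepoint);
    ``residual_sd`` is the within-group Gaussian scatter.
    """

    baseline: float | tuple | list | np.ndarray
    genotype_effect: float | tuple | list | np.ndarray = 0.0
    sex_effect: float | tuple | list | np.ndarray = 0.0
    residual_sd: float = 1.0


@dataclass
class TumorModel:
    """Per-visit onset hazards and geometric growth of detected tumors.

    ``onset_hazard`` maps (genotype, sex) to the probability that a
    tumor-free animal develops a detectable lesion at each visit (scalar or
    per timepoint).  After onset the volume grows by ``growth_factor`` per
    visit interval starting from ``initial_volume_mm3``.
    """

    onset_hazard: dict = field(
        default_factory=lambda: {
            ("mutant", "f"): 0.08,
            ("mutant", "m"): 0.015,
            ("control", "f"): 0.0,
            ("control", "m"): 0.0,
        }
    )
    initial_volume_mm3: float = 0.5
    growth_factor: float = 4.0


def default_effects() -> dict[str, MeasurementEffect]:
    """Study-like defaults: body weight, marrow T1, spleen T2, spleen volume.

    Baselines and scatter are chosen to look like an adult-mouse abdominal
    MRI study: body weight rising with age, males ~6 g heavier; vertebral
    marrow T1 near 700 ms; splenic T2 near 16 ms, shorter in females
    (higher iron); splenic volume near 80-100 mm^3.
    """
    return {
        "body_weight_g": MeasurementEffect(
            baseline=(22.0, 25.0, 27.0, 28.5, 29.5, 30.0),
            genotype_effect=-1.0, sex_effect=6.0, residual_sd=1.5,
        ),
        "marrow_t1_ms": MeasurementEffect(
            baseline=(700.0, 700.0, 695.0, 690.0, 690.0, 685.0),
            genotype_effect=-60.0, sex_effect=10.0, residual_sd=20.0,
        ),
        "spleen_t2_ms": MeasurementEffect(
            baseline=(15.0, 15.0, 15.5, 15.5, 16.0, 16.0),
            genotype_effect=0.0, sex_effect=2.5, residual_sd=1.2,
        ),
        "spleen_volume_mm3": MeasurementEffect(
            baseline=(70.0, 80.0, 88.0, 92.0, 96.0, 100.0),
            genotype_effect=4.0, sex_effect=-12.0, residual_sd=8.0,
        ),
    }


@dataclass
class CohortGenConfig:
    n_per_group: int = 7
    timepoints: tuple = DEFAULT_TIMEPOINTS
    effects: dict[str, MeasurementEffect] = field(default_factory=default_effects)
    tumor_model: TumorModel | None = field(default_factory=TumorModel)
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        tps = np.asarray(self.timepoints, float)
        if tps.size < 1 or np.any(np.diff(tps) <= 0):
            raise ValueError("timepoints must be increasing")
        for name, eff in self.effects.items():
            if not isinstance(eff, MeasurementEffect):
                raise ValueError(f"effects[{name!r}] must be a MeasurementEffect")
            if eff.residual_sd < 0:
                raise ValueError(f"effects[{name!r}].residual_sd must be >= 0")
            _per_timepoint(eff.baseline, tps.size)
        if self.tumor_model is not None and self.tumor_model.growth_factor <= 0:
            raise ValueError("tumor growth factor must be > 0")


def generate_cohort(config: CohortGenConfig) -> pd.DataFrame:
    """Draw a long-format cohort table.

    Columns: animal, sex, genotype, timepoint, measurement, value, excluded,
    exclusion_reason.  One row per animal x timepoint x measurement, plus
    ``tumor_volume_mm3`` rows from each sampled onset onward.  Deterministic
    given config and seed.
    """
    config.validate()
    tps = np.asarray(config.timepoints, float)
    rng = np.random.default_rng(config.seed)
    rows: list[dict] = []

    animals = [
        (f"{sex}_{geno[:3]}_{i + 1:02d}", sex, geno)
        for geno in GENOTYPES
        for sex in SEXES
        for i in range(config.n_per_group)
    ]

    for name, eff in config.effects.items():
        base = _per_timepoint(eff.baseline, tps.size)
        g_eff = _per_timepoint(eff.genotype_effect, tps.size)
        s_eff = _per_timepoint(eff.sex_effect, tps.size)
        for animal, sex, geno in animals:
            noise = rng.normal(0.0, eff.residual_sd, tps.size) if eff.residual_sd > 0 else np.zeros(tps.size)
            values = (
                base
                + g_eff * (geno == "mutant")
                + s_eff * (sex == "m")
                + noise
            )
            for tp, v in zip(tps, values):
                rows.append(
                    {"animal": animal, "sex": sex, "genotype": geno,
                     "timepoint": tp, "measurement": name, "value": float(v),
                     "excluded": False, "exclusion_reason": ""}
                )

    if config.tumor_model is not None:
        tm = config.tumor_model
        for animal, sex, geno in animals:
            hazard = _per_timepoint(tm.onset_hazard.get((geno, sex), 0.0), tps.size)
            onset_idx = None
            for k in range(tps.size):
                if rng.uniform() < hazard[k]:
                    onset_idx = k
                    break
            if onset_idx is None:
                continue
            vol = tm.initial_volume_mm3
            for k in range(onset_idx, tps.size):
                rows.append(
                    {"animal": animal, "sex": sex, "genotype": geno,
                     "timepoint": tps[k], "measurement": "tumor_volume_mm3",
                     "value": float(vol), "excluded": False,
                     "exclusion_reason": ""}
                )
                vol *= tm.growth_factor

    return pd.DataFrame(
        rows,
        columns=["animal", "sex", "genotype", "timepoint", "measurement",
                 "value", "excluded", "exclusion_reason"],
    )
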