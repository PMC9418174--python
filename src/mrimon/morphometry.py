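"""Organ and tumor volumetry from integer label masks.

Volumes are voxel counts times the voxel volume — the convention of
semi-automatic segmentation tools — with no partial-volume weighting, so
results are exact and additive.  Trajectories report per-interval percent
change and onset detection flags the first timepoint a lesion reaches a
visibility threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class VolumeImage:
    """3-D scalar voxel grid with mm spacing (voxel-center world convention:
    world = origin + (index + 0.5) * spacing)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("VolumeImage data must be 3-D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive per axis")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class LabelMask:
    """Integer organ labels on the same grid as a paired image."""

    labels: np.ndarray
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("LabelMask labels must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("LabelMask labels must be integer")


@dataclass
class VolumeRecord:
    organ: str
    volume_mm3: float
    n_voxels: int
    truncated: bool = False
    animal: str | None = None
    timepoint: float | None = None


def mask_volume(
    mask: LabelMask,
    spacing: tuple[float, float, float],
    label_id: int,
    *,
    organ: str | None = None,
    animal: str | None = None,
    timepoint: float | None = None,
) -> VolumeRecord:
    """Volume of one label: voxel count x voxel volume (mm^3).

    A label absent from the mask yields a zero-volume record.  ``truncated``
    is set when the label touches the grid boundary — the segmented organ may
    exceed the field of view, so the reported volume is a lower bound.
    """
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing must be positive per axis")
    hit = mask.labels == label_id
    n = int(hit.sum())
    truncated = False
    if n:
        truncated = bool(
            hit[0].any() or hit[-1].any()
            or hit[:, 0].any() or hit[:, -1].any()
            or hit[:, :, 0].any() or hit[:, :, -1].any()
        )
    name = organ or mask.label_names.get(label_id, f"label_{label_id}")
    return VolumeRecord(
        organ=name,
        volume_mm3=n * float(np.prod(spacing)),
        n_voxels=n,
        truncated=truncated,
        animal=animal,
        timepoint=timepoint,
    )


def volume_trajectory(records: list[VolumeRecord] | pd.DataFrame) -> pd.DataFrame:
    """Order one animal+organ's volumes by timepoint and add percent change.

    ``pct_change`` between consecutive timepoints is 100*(V_t − V_{t−1})/V_{t−1};
    it is NaN (with ``onset=True``) when the previous volume is zero and the
    current one is not, because a relative change from nothing is undefined.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(
            {
                "animal": [r.animal for r in records],
                "organ": [r.organ for r in records],
                "timepoint": [r.timepoint for r in records],
                "volume_mm3": [r.volume_mm3 for r in records],
            }
        )
    if df["timepoint"].isna().any():
        raise ValueError("every record needs a timepoint")
    if df["timepoint"].duplicated().any():
        raise ValueError("duplicate timepoints in trajectory")
    df = df.sort_values("timepoint").reset_index(drop=True)
    prev = df["volume_mm3"].shift(1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (df["volume_mm3"] - prev) / prev
    pct[prev == 0] = np.nan
    df["pct_change"] = pct
    df["onset"] = (prev == 0) & (df["volume_mm3"] > 0)
    return df


def detect_onset(
    trajectories: pd.DataFrame, threshold_mm3: float
) -> pd.DataFrame:
    """First timepoint each (animal, organ) reaches ``threshold_mm3``.

    Expects long-format columns animal, organ, timepoint, volume_mm3.
    Trajectories never reaching the threshold are omitted — the lesion stays
    "not visible" throughout the monitoring window.
    """
    if threshold_mm3 <= 0:
        raise ValueError("threshold must be > 0")
    rows = []
    for (animal, organ), grp in trajectories.groupby(["animal", "organ"], sort=True):
        grp = grp.sort_values("timepoint")
        hit = grp[grp["volume_mm3"] >= threshold_mm3]
        if len(hit):
            first = hit.iloc[0]
            rows.append(
                {
                    "animal": animal,
                    "organ": organ,
                    "onset_timepoint": first["timepoint"],
                    "volume_mm3": first["volume_mm3"],
                }
            )
    return pd.DataFrame(rows, columns=["animal", "organ", "onset_timepoint", "volume_mm3"])


def load_nifti_pair(image_path: str | Path, mask_path: str | Path) -> tuple[VolumeImage, LabelMask]:
    """Read a NIfTI image + integer mask pair sharing one grid."""
    import nibabel as nib

    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    if img.shape != msk.shape:
        raise ValueError("image and mask grids differ")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    data = np.asarray(img.dataobj, dtype=float)
    labels = np.asarray(msk.dataobj).astype(np.int32)
    return VolumeImage(data=data, spacing=spacing), LabelMask(labels=labels)


def save_nifti(volume: np.ndarray, spacing: tuple[float, float, float], path: str | Path) -> None:
    import nibabel as nib

    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume), affine), str(path))
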