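"""Reading parcellated PET volumes and extracting per-region voxel samples.

Subject volumes are assumed to already live in a common template space on the
same voxel grid as an integer-label atlas (labels 1..R, background 0). This
module extracts per-region intensity samples, applies global-mean intensity
normalization (the brain mask being the atlas support), and computes region
and meta-ROI mean uptakes. Grids that do not match are an error — nothing is
resampled silently.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ParcellatedSubject",
    "AtlasMap",
    "load_parcellation",
    "global_normalize",
    "region_mean_uptake",
    "meta_roi_uptake",
    "load_lobe_map",
    "aal90_lobe_map",
]

MIN_VOXELS_PER_REGION = 10

LOBES = ("frontal", "parietal", "occipital", "temporal", "other")


@dataclass
class ParcellatedSubject:
    """Per-region voxel-intensity samples for one subject.

    ``samples`` maps region id (1..R) to a 1-D array of voxel intensities in
    normalized-uptake units. Regions are kept in sorted-id order everywhere.
    """

    subject_id: str
    samples: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        clean: dict[int, np.ndarray] = {}
        for rid in sorted(self.samples):
            x = np.asarray(self.samples[rid], dtype=np.float64).ravel()
            if not np.all(np.isfinite(x)):
                raise ValueError(f"region {rid}: non-finite intensities")
            if x.size < MIN_VOXELS_PER_REGION:
                raise ValueError(
                    f"region {rid}: only {x.size} voxels (need >= {MIN_VOXELS_PER_REGION})"
                )
            clean[rid] = x
        self.samples = clean

    @property
    def region_ids(self) -> list[int]:
        return list(self.samples)

    @property
    def n_regions(self) -> int:
        return len(self.samples)

    @property
    def mean_uptake(self) -> np.ndarray:
        return np.array([self.samples[i].mean() for i in self.samples])

    def pooled_mean(self) -> float:
        """Mean over all in-atlas voxels, pooled across regions."""
        total = sum(x.sum() for x in self.samples.values())
        n = sum(x.size for x in self.samples.values())
        return total / n


@dataclass
class AtlasMap:
    """Integer-label atlas volume plus region names and lobe membership."""

    label_volume: np.ndarray
    region_names: dict[int, str] = field(default_factory=dict)
    lobe_of: dict[int, str] = field(default_factory=dict)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.label_volume = np.asarray(self.label_volume)
        if not np.issubdtype(self.label_volume.dtype, np.integer):
            lab = np.rint(self.label_volume)
            if not np.allclose(lab, self.label_volume):
                raise ValueError("atlas labels must be integers")
            self.label_volume = lab.astype(np.int32)
        labels = self.labels
        if labels and min(labels) < 1:
            raise ValueError("atlas labels must be >= 1 (0 is background)")
        if not self.region_names:
            self.region_names = {i: f"region_{i:02d}" for i in labels}
        if not self.lobe_of:
            self.lobe_of = {i: "other" for i in labels}
        missing = set(labels) - set(self.lobe_of)
        if missing:
            raise ValueError(f"lobe_of missing labels: {sorted(missing)}")

    @property
    def labels(self) -> list[int]:
        u = np.unique(self.label_volume)
        return [int(v) for v in u if v > 0]


def _load_volume(vol):
    """Accept a NIfTI path, a nibabel image, or a bare array (identity affine)."""
    import nibabel as nib

    if isinstance(vol, (str,)) or hasattr(vol, "__fspath__"):
        img = nib.load(str(vol))
        return np.asarray(img.get_fdata(), dtype=np.float64), img.affine
    if hasattr(vol, "get_fdata"):
        return np.asarray(vol.get_fdata(), dtype=np.float64), vol.affine
    arr = np.asarray(vol, dtype=np.float64)
    return arr, np.eye(4)


def load_parcellation(subject_volume, atlas: AtlasMap | object, subject_id: str = "subject") -> ParcellatedSubject:
    """Extract per-region voxel samples from a subject volume.

    ``atlas`` may be an :class:`AtlasMap` or anything ``nibabel`` can load.
    Non-finite and non-positive voxels are dropped (positive support is
    required downstream by the log in the divergence); a region left with
    fewer than 10 usable voxels is an error naming that region.
    """
    data, aff_s = _load_volume(subject_volume)
    if isinstance(atlas, AtlasMap):
        labels_vol = atlas.label_volume
        # an AtlasMap without an explicit affine is compared by shape only
        aff_a = atlas.affine if atlas.affine is not None else aff_s
        amap = atlas
    else:
        lab, aff_a = _load_volume(atlas)
        amap = AtlasMap(label_volume=lab)
        labels_vol = amap.label_volume
    if data.shape != labels_vol.shape:
        raise ValueError(f"grid mismatch: subject {data.shape} vs atlas {labels_vol.shape}")
    if not np.allclose(aff_s, aff_a, atol=1e-4):
        raise ValueError("affine mismatch between subject and atlas (tolerance 1e-4)")

    samples: dict[int, np.ndarray] = {}
    for rid in amap.labels:
        x = data[labels_vol == rid]
        x = x[np.isfinite(x) & (x > 0)]
        if x.size < MIN_VOXELS_PER_REGION:
            raise ValueError(
                f"region {rid} ({amap.region_names.get(rid, '?')}): "
                f"only {x.size} usable voxels after exclusion"
            )
        samples[rid] = x
    return ParcellatedSubject(subject_id=subject_id, samples=samples)


def global_normalize(subject: ParcellatedSubject) -> ParcellatedSubject:
    """Divide every intensity by the pooled in-atlas mean (global mean uptake).

    After normalization the pooled mean is 1 to floating-point accuracy, and
    the operation is idempotent.
    """
    g = subject.pooled_mean()
    if not np.isfinite(g) or g <= 0:
        raise ValueError(f"non-positive global mean uptake: {g}")
    return ParcellatedSubject(
        subject_id=subject.subject_id,
        samples={rid: x / g for rid, x in subject.samples.items()},
    )


def region_mean_uptake(subject: ParcellatedSubject) -> np.ndarray:
    """Arithmetic mean intensity per region, in sorted region-id order."""
    return subject.mean_uptake


def meta_roi_uptake(subject: ParcellatedSubject, roi_labels: Iterable[int]) -> float:
    """Voxel-count-weighted mean uptake over a union of regions.

    Used for composite signature regions (e.g. an AD-meta-ROI); the label
    set is configurable, not hard-coded.
    """
    roi = sorted(set(int(r) for r in roi_labels))
    if not roi:
        raise ValueError("roi_labels is empty")
    unknown = [r for r in roi if r not in subject.samples]
    if unknown:
        raise KeyError(f"roi labels not in subject: {unknown}")
    total = sum(subject.samples[r].sum() for r in roi)
    n = sum(subject.samples[r].size for r in roi)
    return float(total / n)


def load_lobe_map(path) -> pd.DataFrame:
    """Read a lobe map CSV with columns label,name,lobe."""
    df = pd.read_csv(path)
    required = {"label", "name", "lobe"}
    if not required.issubset(df.columns):
        raise ValueError(f"lobe map needs columns {sorted(required)}")
    bad = set(df["lobe"]) - set(LOBES)
    if bad:
        raise ValueError(f"unknown lobes {sorted(bad)}; allowed: {LOBES}")
    return df


def aal90_lobe_map() -> pd.DataFrame:
    """The shipped 90-region AAL lobe map (label, name, lobe)."""
    ref = importlib.resources.files("klse").joinpath("data/aal90_lobes.csv")
    with importlib.resources.as_file(ref) as p:
        return load_lobe_map(p)


def lobe_dict(df: pd.DataFrame) -> dict[int, str]:
    """Lobe map DataFrame -> {label: lobe}."""
    return dict(zip(df["label"].astype(int), df["lobe"]))
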