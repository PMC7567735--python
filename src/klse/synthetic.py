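"""Synthetic PET-like cohorts with known distributional structure.

Generates parcellated subjects whose per-region voxel intensities follow a
known law (Gaussian by default, lognormal optionally), cohorts with injected
group differences in chosen regions, proportional-hazards conversion times
driven by known features, and small NIfTI fixtures for exercising the I/O
layer. Every operation is deterministic given its seed: a cohort-level seed
spawns independent per-subject substreams via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io import ParcellatedSubject

__all__ = [
    "RegionSpec",
    "CohortSpec",
    "HazardSpec",
    "simulate_subject",
    "simulate_cohort",
    "simulate_conversion",
    "block_atlas_layout",
    "write_nifti_fixture",
]


@dataclass(frozen=True)
class RegionSpec:
    """Distribution of voxel intensities in one atlas region.

    ``mu`` and ``sigma`` are the location and scale of the per-voxel
    intensity law in normalized-uptake units (global mean = 1).
    """

    region_id: int
    mu: float
    sigma: float
    n_voxels: int = 500

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"region {self.region_id}: sigma must be > 0, got {self.sigma}")
        if self.n_voxels < 10:
            raise ValueError(f"region {self.region_id}: n_voxels must be >= 10, got {self.n_voxels}")
        if self.region_id < 1:
            raise ValueError(f"region_id must be >= 1, got {self.region_id}")


@dataclass(frozen=True)
class CohortSpec:
    """Two-or-more-group cohort layout.

    ``groups`` maps a group label to ``(n_subjects, overrides)`` where
    ``overrides`` replaces the base RegionSpec for the listed region ids —
    the only place group differences enter the generator.
    """

    base_regions: tuple[RegionSpec, ...]
    groups: tuple[tuple[str, int, tuple[RegionSpec, ...]], ...]
    subject_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [r.region_id for r in self.base_regions]
        if len(set(ids)) != len(ids):
            raise ValueError("region_ids must be unique")
        if not self.groups:
            raise ValueError("at least one group required")
        for label, n, _ in self.groups:
            if n < 2:
                raise ValueError(f"group {label!r}: n_subjects must be >= 2, got {n}")
        if self.subject_noise_sd < 0:
            raise ValueError("subject_noise_sd must be >= 0")

    def regions_for(self, label: str) -> tuple[RegionSpec, ...]:
        """Base regions with this group's overrides applied."""
        for glabel, _, overrides in self.groups:
            if glabel == label:
                by_id = {r.region_id: r for r in self.base_regions}
                for r in overrides:
                    if r.region_id not in by_id:
                        raise ValueError(f"override for unknown region {r.region_id}")
                    by_id[r.region_id] = r
                return tuple(by_id[i] for i in sorted(by_id))
        raise KeyError(label)


@dataclass(frozen=True)
class HazardSpec:
    """Exponential proportional-hazards generator for conversion times.

    ``beta`` is the log-hazard per standard deviation of each named feature;
    ``baseline_rate`` is the exponential baseline hazard in 1/months and
    ``censor_time`` the administrative censoring horizon in months.
    """

    beta: Mapping[str, float]
    baseline_rate: float = 0.02
    censor_time: float = 36.0

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be > 0")
        if self.censor_time <= 0:
            raise ValueError("censor_time must be > 0")

    def to_json(self) -> str:
        return json.dumps(
            {
                "beta": dict(self.beta),
                "baseline_rate": self.baseline_rate,
                "censor_time": self.censor_time,
            },
            sort_keys=True,
        )


def simulate_subject(
    spec: Sequence[RegionSpec],
    jitter_sd: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
    subject_id: str = "synthetic",
    law: str = "gaussian",
) -> ParcellatedSubject:
    """Draw one parcellated subject from per-region intensity laws.

    A single between-subject jitter is drawn per region and added to that
    region's location ``mu`` before sampling voxels, emulating biological
    variability of regional uptake around the group mean. ``law`` selects
    ``"gaussian"`` (default) or ``"lognormal"`` (mu/sigma interpreted on the
    log scale).

    Deterministic given ``seed``.
    """
    if law not in ("gaussian", "lognormal"):
        raise ValueError(f"unknown law {law!r}")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    samples: dict[int, np.ndarray] = {}
    for r in spec:
        mu = r.mu + (rng.normal(0.0, jitter_sd) if jitter_sd > 0 else 0.0)
        if law == "gaussian":
            x = rng.normal(mu, r.sigma, size=r.n_voxels)
        else:
            x = rng.lognormal(mu, r.sigma, size=r.n_voxels)
        samples[r.region_id] = x
    return ParcellatedSubject(subject_id=subject_id, samples=samples)


def _cohort_streams(cohort: CohortSpec) -> list[np.random.SeedSequence]:
    total = sum(n for _, n, _ in cohort.groups)
    return np.random.SeedSequence(cohort.seed).spawn(total)


def simulate_cohort(cohort: CohortSpec, law: str = "gaussian") -> list[tuple[ParcellatedSubject, str]]:
    """Draw all subjects of a cohort; group differences enter only via overrides.

    Subject substreams are spawned up front from the single cohort seed, so
    identical seeds yield byte-identical cohorts.
    """
    streams = _cohort_streams(cohort)
    out: list[tuple[ParcellatedSubject, str]] = []
    i = 0
    for label, n, _ in cohort.groups:
        regions = cohort.regions_for(label)
        for k in range(n):
            subj = simulate_subject(
                regions,
                jitter_sd=cohort.subject_noise_sd,
                seed=streams[i],
                subject_id=f"{label}_{k:03d}",
                law=law,
            )
            out.append((subj, label))
            i += 1
    return out


def simulate_conversion(
    features,
    hazard: HazardSpec,
    seed: int | np.random.SeedSequence = 0,
):
    """Draw conversion times from an exponential proportional-hazards model.

    ``features`` is a pandas DataFrame (subjects x named features). Each
    named coefficient in ``hazard.beta`` acts on the column standardized to
    zero mean and unit SD across the table, so coefficients are log-hazards
    per SD. Event times are exponential with rate
    ``baseline_rate * exp(beta . z)``; times beyond ``censor_time`` are
    administratively censored. Returns a DataFrame with columns
    ``subject_id, time_months, event``.
    """
    import pandas as pd

    unknown = set(hazard.beta) - set(features.columns)
    if unknown:
        raise KeyError(f"beta names not in features: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    lp = np.zeros(len(features))
    for name, b in hazard.beta.items():
        col = features[name].to_numpy(dtype=float)
        sd = col.std()
        z = (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)
        lp += b * z
    rate = hazard.baseline_rate * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    event = t_event <= hazard.censor_time
    time = np.where(event, t_event, hazard.censor_time)
    return pd.DataFrame(
        {
            "subject_id": list(features.index.astype(str)),
            "time_months": time,
            "event": event.astype(int),
        }
    )


def block_atlas_layout(n_regions: int, n_voxels: int, shape: tuple[int, int, int]):
    """Assign each region a contiguous voxel block in a small 3-D grid.

    Returns an integer label volume of ``shape`` with labels 1..n_regions,
    background 0, filling the grid in C order.
    """
    total = int(np.prod(shape))
    if n_regions * n_voxels > total:
        raise ValueError(
            f"grid {shape} has {total} voxels; need {n_regions * n_voxels}"
        )
    flat = np.zeros(total, dtype=np.int16)
    for r in range(n_regions):
        flat[r * n_voxels : (r + 1) * n_voxels] = r + 1
    return flat.reshape(shape)


def write_nifti_fixture(
    subject: ParcellatedSubject,
    atlas_layout: np.ndarray,
    pet_path,
    atlas_path,
):
    """Write a subject volume and matching atlas label volume (identity affine).

    Voxels outside every region (label 0) are filled with zeros and are
    therefore excluded on re-extraction. Round-trip through
    :func:`klse.io.load_parcellation` recovers each region's sample multiset.
    """
    import nibabel as nib

    atlas_layout = np.asarray(atlas_layout)
    vol = np.zeros(atlas_layout.shape, dtype=np.float64)
    for rid, x in subject.samples.items():
        idx = np.nonzero(atlas_layout == rid)
        if len(idx[0]) != len(x):
            raise ValueError(
                f"region {rid}: atlas block has {len(idx[0])} voxels, subject has {len(x)} samples"
            )
        vol[idx] = x
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(vol, affine), str(pet_path))
    nib.save(nib.Nifti1Image(atlas_layout.astype(np.int16), affine), str(atlas_path))
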