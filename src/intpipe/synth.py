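"""Seeded synthetic case-control rsfMRI cohorts.

Voxel time series are stationary AR(1) Gaussian processes with spatially
varying lag-1 coefficients.  Case-control timescale effects are planted in
compact voxel regions by giving the two diagnostic groups different phi
there.  Per-subject mean framewise displacement is drawn lognormal with a
group-specific location, and a symptom score is linearly coupled to the
subject's true mean timescale over the first planted region.

Under AR(1) the theoretical ACF is ``phi**k``, so the true INT has the
closed form ``tr * phi / (1 - phi)`` (sum of the positive lags), which is
what the ground-truth maps report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

__all__ = [
    "PlantedRegion",
    "CohortSpec",
    "SyntheticCohort",
    "simulate_series",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
    "box_region",
    "true_int",
]

GROUPS = ("HC", "SZ")


def true_int(phi: np.ndarray | float, tr: float) -> np.ndarray | float:
    """Closed-form INT of a stationary AR(1) process: ``tr * phi / (1 - phi)``."""
    return tr * phi / (1.0 - phi)


@dataclass(frozen=True)
class PlantedRegion:
    """A voxel set where the two groups have different lag-1 coefficients."""

    name: str
    voxels: np.ndarray  # 3-D boolean grid
    phi_control: float
    phi_patient: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "voxels", np.asarray(self.voxels, dtype=bool))
        for label, phi in (("phi_control", self.phi_control), ("phi_patient", self.phi_patient)):
            if not 0.0 <= phi < 1.0:
                raise ValueError(f"{label}={phi} outside [0, 1) for region {self.name!r}")
        if not self.voxels.any():
            raise ValueError(f"planted region {self.name!r} is empty")


def box_region(
    grid_shape: tuple[int, int, int],
    center: Sequence[int],
    size: Sequence[int],
    name: str,
    phi_control: float,
    phi_patient: float,
) -> PlantedRegion:
    """Axis-aligned box region helper (clipped to the grid)."""
    vox = np.zeros(grid_shape, dtype=bool)
    sl = tuple(
        slice(max(0, c - s // 2), min(dim, c - s // 2 + s))
        for c, s, dim in zip(center, size, grid_shape)
    )
    vox[sl] = True
    return PlantedRegion(name, vox, phi_control, phi_patient)


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort; all randomness flows from ``seed``."""

    n_per_group: int
    grid_shape: tuple[int, int, int]
    tr: float
    n_frames: int
    seed: int
    n_sessions: int = 1
    mask: np.ndarray | None = None
    base_phi: float = 0.3
    planted_regions: list[PlantedRegion] = field(default_factory=list)
    noise_sd: float = 0.0
    phi_jitter_sd: float = 0.05
    fd_params: dict = field(
        default_factory=lambda: {"HC": (-2.0, 0.4), "SZ": (-1.6, 0.4)}
    )
    symptom_model: tuple[float, float, float] = (50.0, -5.0, 3.0)
    smoothing_fwhm_vox: float = 0.0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(v) for v in self.grid_shape)
        if self.mask is None:
            self.mask = np.ones(self.grid_shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.validate()

    def validate(self) -> None:
        if self.mask.shape != self.grid_shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != grid shape {self.grid_shape}"
            )
        if not self.mask.any():
            raise ValueError("mask selects zero voxels")
        if not 0.0 <= self.base_phi < 1.0:
            raise ValueError(f"base_phi={self.base_phi} outside [0, 1)")
        if self.n_frames < 50:
            raise ValueError(f"n_frames must be >= 50, got {self.n_frames}")
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if self.n_per_group < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.n_sessions < 1:
            raise ValueError("need at least 1 session")
        claimed = np.zeros(self.grid_shape, dtype=bool)
        for region in self.planted_regions:
            if region.voxels.shape != self.grid_shape:
                raise ValueError(f"region {region.name!r} shape mismatch")
            if (region.voxels & ~self.mask).any():
                raise ValueError(f"region {region.name!r} leaves the mask")
            if (region.voxels & claimed).any():
                raise ValueError(f"region {region.name!r} overlaps another region")
            claimed |= region.voxels

    @property
    def session_lengths(self) -> list[int]:
        return [self.n_frames] * self.n_sessions

    def phi_map(self, group: str) -> np.ndarray:
        """Group-level (pre-jitter) phi grid; NaN outside the mask."""
        phi = np.full(self.grid_shape, np.nan)
        phi[self.mask] = self.base_phi
        for region in self.planted_regions:
            phi[region.voxels] = (
                region.phi_control if group == "HC" else region.phi_patient
            )
        return phi


@dataclass
class SyntheticCohort:
    """Simulated volumes plus subject records and generative ground truth."""

    spec: CohortSpec
    volumes: list[np.ndarray]
    records: pd.DataFrame
    truth_phi: list[np.ndarray]
    truth_int: list[np.ndarray]
    affine: np.ndarray = field(default_factory=lambda: np.diag([3.0, 3.0, 3.0, 1.0]))

    def __post_init__(self) -> None:
        if len(self.volumes) != len(self.records):
            raise ValueError("one record per volume required")


def simulate_series(
    phi: float,
    n_frames: int,
    innovation_sd: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """One stationary AR(1) draw: ``x_t = phi x_{t-1} + eps_t``.

    The initial state comes from the stationary distribution
    ``N(0, innovation_sd^2 / (1 - phi^2))``, so the whole series is
    stationary; an identical seed gives a bit-identical series.
    """
    if not 0.0 <= phi < 1.0:
        raise ValueError(f"phi={phi} outside [0, 1); process would be nonstationary")
    if n_frames < 2:
        raise ValueError(f"need n_frames >= 2, got {n_frames}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x0 = rng.normal(0.0, innovation_sd / np.sqrt(1.0 - phi**2))
    eps = rng.normal(0.0, innovation_sd, size=n_frames)
    out, _ = lfilter([1.0], [1.0, -phi], eps, zi=np.array([phi * x0]))
    return out


def _simulate_block(
    phis: np.ndarray, n_frames: int, rng: np.random.Generator
) -> np.ndarray:
    """Stationary AR(1) series for many voxels at once; rows share nothing.

    ``phis`` is (V,) and may differ per voxel, so the recursion is stepped
    through time with vectorised updates across voxels.
    """
    n_vox = phis.size
    x0 = rng.normal(0.0, 1.0, size=n_vox) / np.sqrt(1.0 - phis**2)
    eps = rng.normal(0.0, 1.0, size=(n_vox, n_frames))
    out = np.empty((n_vox, n_frames))
    prev = x0
    for t in range(n_frames):
        prev = phis * prev + eps[:, t]
        out[:, t] = prev
    return out


def simulate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Simulate a full seeded cohort from a :class:`CohortSpec`.

    Subject order is all controls (HC) then all patients (SZ).  Per-subject
    phi jitter is an independent Gaussian field added to the phi map and
    clipped to [0, 0.95], giving nonzero between-subject variance at every
    voxel while keeping voxels statistically independent.  Symptom
    scores couple linearly to the subject's true mean INT over the first
    planted region (plus noise); they are recorded for patients, as are CPZ
    doses.
    """
    spec.validate()
    root = np.random.default_rng(spec.seed)
    n_total = 2 * spec.n_per_group
    subject_rngs = root.spawn(n_total)

    volumes: list[np.ndarray] = []
    truth_phi: list[np.ndarray] = []
    truth_int: list[np.ndarray] = []
    rows = []
    mask = spec.mask
    first_region = spec.planted_regions[0] if spec.planted_regions else None

    for idx in range(n_total):
        group = "HC" if idx < spec.n_per_group else "SZ"
        subject_id = f"sub-{group.lower()}{idx % spec.n_per_group + 1:03d}"
        rng = subject_rngs[idx]

        phi = spec.phi_map(group)
        if spec.phi_jitter_sd > 0:
            jitter = rng.normal(0.0, spec.phi_jitter_sd, size=phi.shape)
        else:
            jitter = 0.0
        phi_subj = np.clip(phi + jitter, 0.0, 0.95)

        phis = phi_subj[mask]
        sessions = [
            _simulate_block(phis, spec.n_frames, rng) for _ in range(spec.n_sessions)
        ]
        data = np.concatenate(sessions, axis=1)
        if spec.noise_sd > 0:
            data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)

        vol = np.zeros(spec.grid_shape + (spec.n_frames * spec.n_sessions,))
        vol[mask] = data
        if spec.smoothing_fwhm_vox > 0:
            from scipy.ndimage import gaussian_filter

            sigma = spec.smoothing_fwhm_vox / np.sqrt(8.0 * np.log(2.0))
            vol = gaussian_filter(vol, sigma=(sigma, sigma, sigma, 0.0))

        int_subj = np.full(spec.grid_shape, np.nan)
        int_subj[mask] = true_int(phi_subj[mask], spec.tr)

        mu, sigma = spec.fd_params[group]
        mean_fd = float(rng.lognormal(mu, sigma))
        age = float(np.clip(rng.normal(35.0, 10.0), 18.0, 65.0))
        sex = "M" if rng.random() < 0.5 else "F"

        symptom = np.nan
        cpz = np.nan
        if group == "SZ":
            intercept, slope, noise = spec.symptom_model
            regional = (
                float(int_subj[first_region.voxels].mean())
                if first_region is not None
                else float(int_subj[mask].mean())
            )
            symptom = intercept + slope * regional + rng.normal(0.0, noise)
            cpz = float(rng.lognormal(5.5, 0.5))

        volumes.append(vol)
        truth_phi.append(phi_subj)
        truth_int.append(int_subj)
        rows.append(
            {
                "subject_id": subject_id,
                "group": group,
                "sex": sex,
                "age": age,
                "mean_fd": mean_fd,
                "cpz": cpz,
                "symptom": symptom,
            }
        )

    records = pd.DataFrame(rows)
    return SyntheticCohort(
        spec=spec,
        volumes=volumes,
        records=records,
        truth_phi=truth_phi,
        truth_int=truth_int,
    )


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict:
    """Write a cohort to disk: per-subject NIfTI, mask NIfTI, records/truth TSV.

    Returns a manifest dict (also written as ``manifest.json``) listing every
    path; all files round-trip through :func:`read_cohort`.
    """
    import nibabel as nib

    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {directory}: {exc}") from exc

    spec = cohort.spec
    manifest: dict = {
        "tr": spec.tr,
        "session_lengths": spec.session_lengths,
        "mask": str(directory / "mask.nii.gz"),
        "records": str(directory / "participants.tsv"),
        "truth": str(directory / "truth.tsv"),
        "volumes": {},
    }
    nib.save(
        nib.Nifti1Image(spec.mask.astype(np.uint8), cohort.affine),
        manifest["mask"],
    )
    truth_rows = []
    for i, row in cohort.records.iterrows():
        path = directory / f"{row.subject_id}_bold.nii.gz"
        nib.save(nib.Nifti1Image(cohort.volumes[i].astype(np.float32), cohort.affine), path)
        manifest["volumes"][row.subject_id] = str(path)
        truth_rows.append(
            {
                "subject_id": row.subject_id,
                "mean_true_int": float(np.nanmean(cohort.truth_int[i])),
                "mean_true_phi": float(np.nanmean(cohort.truth_phi[i])),
            }
        )
    cohort.records.to_csv(manifest["records"], sep="\t", index=False)
    pd.DataFrame(truth_rows).to_csv(manifest["truth"], sep="\t", index=False)
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    manifest["manifest"] = str(directory / "manifest.json")
    return manifest


def read_cohort(manifest: dict | str | Path) -> tuple[list[np.ndarray], np.ndarray, pd.DataFrame]:
    """Load ``(volumes, mask, records)`` back from a :func:`write_cohort` manifest."""
    import nibabel as nib

    if not isinstance(manifest, dict):
        with open(manifest) as fh:
            manifest = json.load(fh)
    mask = np.asarray(nib.load(manifest["mask"]).get_fdata()) > 0
    records = pd.read_csv(manifest["records"], sep="\t")
    volumes = [
        np.asarray(nib.load(manifest["volumes"][sid]).get_fdata())
        for sid in records.subject_id
    ]
    return volumes, mask, records
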