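"""Synthetic cohorts and skeleton-space DTI data with planted effects.

Two generators make the full analysis chain testable without any imaging
download:

* clinical trajectories — per-patient (D50, dx) pairs drawn from a lognormal
  D50 distribution with dx tied to D50 through a noisy ratio, visit schedules
  with integer ALSFRS-R scores (curve value + Gaussian noise, rounded and
  clamped to [0, 48]), and an MRI time point placed so the cohort spans the
  early disease phases;
* diffusion-tensor eigenvalue maps on a toy white-matter skeleton — tubular
  "tracts" with literature-typical eigenvalues, voxel noise, and effects
  planted in named regions by shifting the eigenvalue combination that moves
  the targeted scalar metric (FA via the radial eigenvalues, AD via L1, MD
  via all three), scaled by a per-subject driver (group membership or a
  standardised clinical variable).

The generator emulates the statistical structure of a TBSS study (skeleton
geometry, group/covariate-linked metric shifts, independent voxel noise); it
does not model MR physics, registration error or spatially correlated noise.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .progression import (
    FULL_HEALTH_SCORE,
    AlsfrsObservation,
    PatientRecord,
    cfs_curve,
)
from .voxelwise import SkeletonDataset

__all__ = [
    "CohortSpec",
    "EffectSpec",
    "SkeletonGeometry",
    "DTIEigenMaps",
    "simulate_trajectories",
    "make_skeleton_mask",
    "simulate_eigen_maps",
    "derive_metrics",
    "simulate_metric_datasets",
    "default_benchmark_effects",
    "export_fixture",
    "load_fixture",
]

#: Mean-FA threshold defining the skeleton mask.
SKELETON_FA_THRESHOLD = 0.2

#: Baseline tract eigenvalues (L1, L2, L3) in mm^2/s — typical WM literature values.
BASELINE_TRACT_EIGENVALUES = (1.7e-3, 0.4e-3, 0.3e-3)

#: Baseline eigenvalues outside tracts (near-isotropic tissue).
BASELINE_BACKGROUND_EIGENVALUES = (1.0e-3, 0.85e-3, 0.75e-3)

#: Per-eigenvalue Gaussian voxel noise SD (mm^2/s).
EIGEN_NOISE_SD = 0.08e-3


@dataclass(frozen=True)
class CohortSpec:
    """Generating distribution of a synthetic ALS cohort.

    Defaults reproduce the clinical structure of a mid-size single-centre
    cohort: D50 lognormal with median 28.8 months, dx tied to D50 by a mean
    ratio of 2.54, integer scores with 1.5-point assessment noise, and an
    MRI time point distributed so roughly 40%/55%/5% of patients sit in
    Phases I/II/III+ at scan time.
    """

    n_patients: int = 145
    n_controls: int = 69
    d50_log_median: float = math.log(28.8)
    d50_log_sd: float = 0.52
    dx_ratio: float = 2.54
    dx_log_noise_sd: float = 0.25
    first_visit_window: tuple[float, float] = (2.0, 8.0)
    visit_interval: tuple[float, float] = (1.0, 4.0)
    n_visits: tuple[int, int] = (4, 10)
    score_noise_sd: float = 1.5
    rd50_mri: tuple[float, float] = (0.28, 0.13)
    rd50_mri_range: tuple[float, float] = (0.05, 0.7)
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0 or self.n_controls < 0:
            raise ValueError("counts must be >= 0")
        if self.score_noise_sd < 0 or self.dx_log_noise_sd < 0 or self.d50_log_sd < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass(frozen=True)
class EffectSpec:
    """One planted effect: a metric shift in a named skeleton region.

    ``magnitude`` is expressed in units of the per-eigenvalue voxel noise SD;
    ``driver`` chooses what scales the shift per subject — ``group`` (patient
    indicator) or a standardised clinical variable (``d50``, ``rd50``,
    ``cfs``, ``cfl``); ``direction`` is the sign of the metric change per
    unit driver.
    """

    region: str
    metric: str
    direction: str
    driver: str
    magnitude: float

    def __post_init__(self) -> None:
        if self.metric not in ("FA", "MD", "AD", "RD"):
            raise ValueError(f"unknown metric {self.metric}")
        if self.direction not in ("increase", "decrease"):
            raise ValueError("direction must be 'increase' or 'decrease'")
        if self.driver not in ("group", "d50", "rd50", "cfs", "cfl"):
            raise ValueError(f"unknown driver {self.driver}")
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")


@dataclass
class SkeletonGeometry:
    """Toy skeleton: mask, named tract regions and the synthetic mean-FA map."""

    mask: np.ndarray
    regions: dict[str, np.ndarray]
    mean_fa: np.ndarray

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def region_mask_vector(self, name: str) -> np.ndarray:
        """Region membership over the masked voxels (1-D boolean)."""
        return self.regions[name][self.mask]


@dataclass
class DTIEigenMaps:
    """Sorted diffusion-tensor eigenvalue maps (L1 >= L2 >= L3 >= 0)."""

    L1: np.ndarray
    L2: np.ndarray
    L3: np.ndarray

    def __post_init__(self) -> None:
        for a, b in ((self.L1, self.L2), (self.L2, self.L3)):
            if np.any(a < b - 1e-15):
                raise ValueError("eigenvalue ordering violated")
        if np.any(self.L3 < 0):
            raise ValueError("eigenvalues must be >= 0")


# ---------------------------------------------------------------------------
# clinical trajectories
# ---------------------------------------------------------------------------


def _draw_ages(rng: np.random.Generator, n: int, center: float, sd: float,
               lo: float, hi: float) -> np.ndarray:
    return np.clip(rng.normal(center, sd, n), lo, hi)


def simulate_trajectories(
    spec: CohortSpec | None = None,
) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Generate patient and control records with known true (D50, dx).

    Returns the records (patients first, then controls without ALSFRS-R
    observations) and a ground-truth table with the generating parameters of
    each patient.  Deterministic given ``spec.seed``.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    records: list[PatientRecord] = []
    truth_rows: list[dict] = []

    ages = _draw_ages(rng, spec.n_patients, 64.0, 10.0, 31.0, 82.0)
    for i in range(spec.n_patients):
        pid = f"als{i:03d}"
        d50 = float(np.exp(rng.normal(spec.d50_log_median, spec.d50_log_sd)))
        dx = float(d50 / spec.dx_ratio * np.exp(rng.normal(0.0, spec.dx_log_noise_sd)))
        dx = max(dx, 0.5)
        n_visits = int(rng.integers(spec.n_visits[0], spec.n_visits[1] + 1))
        t0 = rng.uniform(*spec.first_visit_window)
        gaps = rng.uniform(*spec.visit_interval, size=n_visits - 1)
        times = t0 + np.concatenate([[0.0], np.cumsum(gaps)])
        noise = rng.normal(0.0, spec.score_noise_sd, n_visits)
        scores = np.clip(
            np.rint(cfs_curve(times, d50, dx) + noise), 0, FULL_HEALTH_SCORE
        ).astype(int)
        lo, hi = spec.rd50_mri_range
        rd50_mri = float(np.clip(rng.normal(*spec.rd50_mri), lo, hi))
        mri_t = 2.0 * d50 * rd50_mri
        records.append(
            PatientRecord(
                id=pid,
                age_at_mri=float(ages[i]),
                sex="male" if rng.random() < 0.552 else "female",
                onset_type="limb" if rng.random() < 0.69 else "bulbar",
                handedness=str(rng.choice(["right", "left", "unknown"],
                                          p=[0.869, 0.083, 0.048])),
                mri_t_months=mri_t,
                observations=[
                    AlsfrsObservation(t_months=float(t), score=int(s))
                    for t, s in zip(times, scores)
                ],
                group="patient",
            )
        )
        truth_rows.append(
            {"patient_id": pid, "true_d50": d50, "true_dx": dx,
             "true_rd50_at_mri": rd50_mri, "mri_t_months": mri_t}
        )

    ctrl_ages = _draw_ages(rng, spec.n_controls, 54.0, 10.0, 25.0, 80.0)
    for i in range(spec.n_controls):
        records.append(
            PatientRecord(
                id=f"ctl{i:03d}",
                age_at_mri=float(ctrl_ages[i]),
                sex="male" if rng.random() < 0.493 else "female",
                onset_type="none",
                handedness=str(rng.choice(["right", "left", "unknown"],
                                          p=[0.869, 0.083, 0.048])),
                mri_t_months=0.0,
                observations=[],
                group="control",
            )
        )
    return records, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# skeleton geometry
# ---------------------------------------------------------------------------


def make_skeleton_mask(
    grid_shape: tuple[int, int, int] = (32, 32, 12),
    tract_fa: float = 0.55,
    background_fa: float = 0.12,
) -> SkeletonGeometry:
    """Build a toy tract layout and its mean-FA skeleton mask.

    Four disjoint named regions emulate recognisable tract families:
    ``cst_like`` (two through-plane columns), ``callosal_like`` (a
    commissural bar), ``frontal_assoc`` (two anterior association bundles)
    and ``cerebellar_like`` (an inferior blob).  The skeleton mask is every
    voxel whose synthetic mean FA exceeds 0.2.
    """
    nx, ny, nz = grid_shape
    if nx < 16 or ny < 16 or nz < 8:
        raise ValueError("grid must be at least 16 x 16 x 8")
    mean_fa = np.full(grid_shape, background_fa, dtype=float)
    regions: dict[str, np.ndarray] = {}

    def carve(name: str, sl: tuple[slice, slice, slice]) -> None:
        block = np.zeros(grid_shape, dtype=bool)
        block[sl] = True
        for other in regions.values():  # keep regions disjoint
            block &= ~other
        mean_fa[block] = tract_fa
        regions[name] = block

    cx1, cx2 = nx // 3, 2 * nx // 3
    cy = ny // 2
    carve("cst_like", (slice(cx1, cx1 + 2), slice(cy, cy + 2), slice(1, nz - 1)))
    cst2 = np.zeros(grid_shape, dtype=bool)
    cst2[cx2:cx2 + 2, cy:cy + 2, 1:nz - 1] = True
    mean_fa[cst2] = tract_fa
    regions["cst_like"] = regions["cst_like"] | cst2

    zc = 2 * nz // 3
    carve("callosal_like", (slice(cx1 + 3, cx2 - 1), slice(cy, cy + 2), slice(zc, zc + 2)))
    carve(
        "frontal_assoc",
        (slice(nx // 4, nx // 4 + 2), slice(2, cy - 2), slice(nz // 2, nz // 2 + 2)),
    )
    fa2 = np.zeros(grid_shape, dtype=bool)
    fa2[3 * nx // 4:3 * nx // 4 + 2, 2:cy - 2, nz // 2:nz // 2 + 2] = True
    fa2 &= ~regions["cst_like"] & ~regions["callosal_like"] & ~regions["frontal_assoc"]
    mean_fa[fa2] = tract_fa
    regions["frontal_assoc"] = regions["frontal_assoc"] | fa2

    carve("cerebellar_like", (slice(nx // 2 - 2, nx // 2 + 2), slice(ny - 8, ny - 4), slice(0, 2)))

    mask = mean_fa > SKELETON_FA_THRESHOLD
    return SkeletonGeometry(mask=mask, regions=regions, mean_fa=mean_fa)


# ---------------------------------------------------------------------------
# eigenvalue maps and scalar metrics
# ---------------------------------------------------------------------------


def _driver_values(subjects: pd.DataFrame, driver: str) -> np.ndarray:
    """Per-subject effect scaling: group indicator or standardised covariate."""
    if driver == "group":
        return (subjects["group"].astype(str) == "patient").to_numpy(dtype=float)
    vals = subjects[driver].to_numpy(dtype=float)
    is_pat = (subjects["group"].astype(str) == "patient").to_numpy()
    z = np.zeros(len(subjects))
    if is_pat.sum() > 1 and np.nanstd(vals[is_pat]) > 0:
        mu, sd = np.nanmean(vals[is_pat]), np.nanstd(vals[is_pat])
        z[is_pat] = (vals[is_pat] - mu) / sd
    return np.nan_to_num(z)


def simulate_eigen_maps(
    subjects: pd.DataFrame,
    effects: list[EffectSpec],
    geometry: SkeletonGeometry,
    noise_sd: float = EIGEN_NOISE_SD,
    seed: int | None = 0,
) -> list[DTIEigenMaps]:
    """Eigenvalue maps over the skeleton voxels for every subject.

    ``subjects`` must carry a ``group`` column plus any clinical driver
    columns referenced by the effects.  Effect shifts move the eigenvalue
    combination that drives the target metric (FA/RD via L2+L3, AD via L1,
    MD via all three) by ``magnitude * noise_sd * driver``; ordering
    violations introduced by shifts are clipped.
    """
    for eff in effects:
        if eff.region not in geometry.regions:
            raise ValueError(f"effect references unknown region '{eff.region}'")
    rng = np.random.default_rng(seed)
    n_vox = geometry.n_voxels
    base = np.array(BASELINE_TRACT_EIGENVALUES)
    ordering_clips = 0

    shifts = []  # (region_vector, per-subject shift per eigenvalue)
    for eff in effects:
        region = geometry.region_mask_vector(eff.region)
        sign = 1.0 if eff.direction == "increase" else -1.0
        drive = sign * eff.magnitude * noise_sd * _driver_values(subjects, eff.driver)
        if eff.metric == "AD":
            per_eig = np.array([1.0, 0.0, 0.0])
        elif eff.metric == "MD":
            per_eig = np.array([1.0, 1.0, 1.0])
        elif eff.metric == "RD":
            per_eig = np.array([0.0, 1.0, 1.0])
        else:  # FA: raising the radial eigenvalues lowers FA
            per_eig = np.array([0.0, -1.0, -1.0])
        shifts.append((region, np.outer(drive, per_eig)))

    out: list[DTIEigenMaps] = []
    for s in range(len(subjects)):
        eig = np.tile(base, (n_vox, 1)) + rng.normal(0.0, noise_sd, (n_vox, 3))
        for region, subj_shift in shifts:
            eig[region] += subj_shift[s]
        # restore L1 >= L2 >= L3 >= 0 after shifts and noise
        clipped = eig.copy()
        clipped[:, 1] = np.minimum(clipped[:, 1], clipped[:, 0])
        clipped[:, 2] = np.minimum(clipped[:, 2], clipped[:, 1])
        clipped = np.maximum(clipped, 0.0)
        ordering_clips += int(np.sum(clipped != eig))
        out.append(DTIEigenMaps(L1=clipped[:, 0], L2=clipped[:, 1], L3=clipped[:, 2]))
    if ordering_clips:
        import logging

        logging.getLogger(__name__).info(
            "clipped %d eigenvalue entries to restore ordering", ordering_clips
        )
    return out


def derive_metrics(eigen: DTIEigenMaps) -> dict[str, np.ndarray]:
    """Scalar DTI metrics from sorted eigenvalues.

    AD = L1; RD = (L2 + L3)/2; MD = (L1 + L2 + L3)/3;
    FA = sqrt(3/2) * ||L - MD|| / ||L||, defined as 0 for all-zero tensors.
    """
    L = np.stack([eigen.L1, eigen.L2, eigen.L3], axis=-1).astype(float)
    md = L.mean(axis=-1)
    norm = np.sqrt((L**2).sum(axis=-1))
    dev = np.sqrt(((L - md[..., None]) ** 2).sum(axis=-1))
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.sqrt(1.5) * np.where(norm > 0, dev / np.where(norm > 0, norm, 1.0), 0.0)
    return {
        "FA": fa,
        "MD": md,
        "AD": L[..., 0],
        "RD": (L[..., 1] + L[..., 2]) / 2.0,
    }


def simulate_metric_datasets(
    subjects: pd.DataFrame,
    effects: list[EffectSpec],
    geometry: SkeletonGeometry,
    noise_sd: float = EIGEN_NOISE_SD,
    seed: int | None = 0,
) -> dict[str, SkeletonDataset]:
    """Subjects x voxels datasets for FA/MD/AD/RD with the planted effects."""
    eigen_maps = simulate_eigen_maps(subjects, effects, geometry, noise_sd, seed)
    ids = subjects["patient_id"].astype(str).tolist() if "patient_id" in subjects else None
    stacks: dict[str, list[np.ndarray]] = {m: [] for m in ("FA", "MD", "AD", "RD")}
    for eig in eigen_maps:
        metrics = derive_metrics(eig)
        for m in stacks:
            stacks[m].append(metrics[m])
    return {
        m: SkeletonDataset(
            mask=geometry.mask, values=np.vstack(v), metric_tag=m, subject_ids=ids
        )
        for m, v in stacks.items()
    }


def default_benchmark_effects() -> list[EffectSpec]:
    """Planted effects of the seeded benchmark.

    A group-driven FA decrease in the corticospinal-like region and an AD
    elevation that grows as D50 falls (aggressive disease) in the frontal
    association region — the qualitative pattern a TBSS study of disease
    aggressiveness reports.  Magnitudes are benchmark parameters, not
    estimates of any real cohort's effects.
    """
    return [
        EffectSpec(region="cst_like", metric="FA", direction="decrease",
                   driver="group", magnitude=1.5),
        EffectSpec(region="frontal_assoc", metric="AD", direction="decrease",
                   driver="d50", magnitude=1.2),
    ]


# ---------------------------------------------------------------------------
# fixture export / reload
# ---------------------------------------------------------------------------


def _records_to_tables(records: list[PatientRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    clin_rows, demo_rows = [], []
    for rec in records:
        for obs in rec.observations:
            clin_rows.append(
                {"patient_id": rec.id, "t_months": obs.t_months, "alsfrs_r": obs.score}
            )
        demo_rows.append(
            {
                "patient_id": rec.id,
                "age_at_mri": rec.age_at_mri,
                "sex": rec.sex,
                "onset_type": rec.onset_type,
                "handedness": rec.handedness,
                "mri_t_months": rec.mri_t_months,
                "group": rec.group,
            }
        )
    return pd.DataFrame(clin_rows), pd.DataFrame(demo_rows)


def export_fixture(
    out_dir: str | Path,
    records: list[PatientRecord],
    truth: pd.DataFrame,
    geometry: SkeletonGeometry,
    datasets: dict[str, SkeletonDataset],
    effects: list[EffectSpec],
    seed: int | None = None,
    force: bool = False,
) -> dict:
    """Write the synthetic study to disk (CSV + NIfTI + JSON); returns the manifest."""
    import nibabel as nib

    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty (pass force=True to overwrite)")
    out.mkdir(parents=True, exist_ok=True)

    clinical, demographics = _records_to_tables(records)
    clinical.to_csv(out / "clinical.csv", index=False)
    demographics.to_csv(out / "demographics.csv", index=False)
    truth.to_csv(out / "ground_truth_params.csv", index=False)

    affine = np.eye(4)
    nib.save(nib.Nifti1Image(geometry.mask.astype(np.uint8), affine), out / "mask.nii")
    nib.save(nib.Nifti1Image(geometry.mean_fa.astype(np.float32), affine),
             out / "mean_fa.nii")
    labels = np.zeros(geometry.mask.shape, dtype=np.int16)
    region_ids = {}
    for i, (name, region) in enumerate(sorted(geometry.regions.items()), start=1):
        labels[region] = i
        region_ids[name] = i
    nib.save(nib.Nifti1Image(labels, affine), out / "regions.nii")

    hasher = hashlib.sha256()
    for metric, ds in sorted(datasets.items()):
        vol = np.zeros((*geometry.mask.shape, ds.n_subjects), dtype=np.float32)
        vol[geometry.mask] = ds.values.T.astype(np.float32)
        nib.save(nib.Nifti1Image(vol, affine), out / f"{metric}.nii")
        hasher.update(np.ascontiguousarray(vol).tobytes())

    manifest = {
        "seed": seed,
        "n_subjects": len(records),
        "grid_shape": list(geometry.mask.shape),
        "n_skeleton_voxels": geometry.n_voxels,
        "region_ids": region_ids,
        "metrics": sorted(datasets.keys()),
        "effects": [asdict(e) for e in effects],
        "data_sha256": hasher.hexdigest(),
    }
    (out / "ground_truth.json").write_text(
        json.dumps({"effects": [asdict(e) for e in effects]}, indent=2)
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def load_fixture(fixture_dir: str | Path):
    """Reload an exported fixture; inverse of :func:`export_fixture`."""
    import nibabel as nib

    d = Path(fixture_dir)
    clinical = pd.read_csv(d / "clinical.csv")
    demographics = pd.read_csv(d / "demographics.csv")
    manifest = json.loads((d / "manifest.json").read_text())
    mask = np.asarray(nib.load(d / "mask.nii").dataobj).astype(bool)
    mean_fa = np.asarray(nib.load(d / "mean_fa.nii").dataobj).astype(float)
    labels = np.asarray(nib.load(d / "regions.nii").dataobj).astype(int)
    regions = {
        name: labels == rid for name, rid in manifest["region_ids"].items()
    }
    geometry = SkeletonGeometry(mask=mask, regions=regions, mean_fa=mean_fa)
    ids = demographics["patient_id"].astype(str).tolist()
    datasets = {}
    for metric in manifest["metrics"]:
        vol = np.asarray(nib.load(d / f"{metric}.nii").dataobj).astype(float)
        datasets[metric] = SkeletonDataset(
            mask=mask, values=vol[mask].T, metric_tag=metric, subject_ids=ids
        )
    effects = [EffectSpec(**e) for e in manifest["effects"]]
    return clinical, demographics, geometry, datasets, effects, manifest
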