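"""Synthetic memory-clinic cohorts with paired 3D volumes.

Generates cohorts of subjects with subjective cognitive decline or mild
cognitive impairment, a fraction of whom progress to Alzheimer's dementia
("early AD") within four years.  Group-conditional marginals (demographics,
cognition, APOE ε4 allele count, hippocampal and intracranial volume) default
to the published BioFINDER-1 characteristics of such a cohort, so downstream
models face realistically overlapping class distributions.

Each subject can additionally carry a pair of 3D volumes:

* an "MRI" — smooth random texture plus a bright spherical structure whose
  voxel count scales linearly with the subject's hippocampal volume
  (native-space convention, larger grid, cropped downstream);
* a "Jacobian-determinant" (JD) surrogate — 1.0 background with a spherical
  atrophy region whose value equals the subject's hippocampal volume divided
  by the non-progressor group mean, so values < 1 encode local contraction
  (template-space convention, smaller grid, zero-padded downstream).

Everything is deterministic given the config seed; per-subject volume streams
are derived from (seed, subject index) so volumes can be produced lazily and
in any order.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError

N_REGIONS = 68
#: indices of "AD-signature" cortical regions whose volumes shrink in early AD
SIGNATURE_REGIONS = tuple(range(10, 26))

GROUPS = ("non_ad", "early_ad")


@dataclass(frozen=True)
class GroupParams:
    """Per-group Gaussian marginals (mean, SD) and a female fraction."""

    age: tuple[float, float]
    education: tuple[float, float]
    mmse: tuple[float, float]
    adas: tuple[float, float]
    apoe_p: float          # per-allele probability; count ~ Binomial(2, p)
    hippocampus: tuple[float, float]   # mm^3, hemispheric average
    icv: tuple[float, float]           # cm^3
    female_fraction: float
    mmse_slope: tuple[float, float]    # points/year, between-subject


#: BioFINDER-1-like defaults: 223 stable vs 109 progressors out of 332.
DEFAULT_GROUP_PARAMS: dict[str, GroupParams] = {
    "non_ad": GroupParams(
        age=(70.2, 5.5), education=(12.0, 3.7), mmse=(28.2, 1.7),
        adas=(4.2, 2.4), apoe_p=0.2, hippocampus=(3339.0, 480.0),
        icv=(1136.0, 153.0), female_fraction=0.475,
        mmse_slope=(-0.2, 0.4),
    ),
    "early_ad": GroupParams(
        age=(72.1, 4.7), education=(11.8, 3.5), mmse=(27.1, 1.7),
        adas=(6.7, 2.1), apoe_p=0.5, hippocampus=(2927.0, 415.0),
        icv=(1114.0, 107.0), female_fraction=0.468,
        mmse_slope=(-1.5, 0.8),
    ),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the published cohort composition (n = 332 with 32.8%
    four-year progressors) and group marginals.  ``mri_hippo_signal=False``
    removes the hippocampal structure from the MRI texture so the JD volume is
    the only imaging modality carrying outcome signal.
    """

    n_subjects: int = 332
    prevalence_early_ad: float = 0.328
    group_params: dict[str, GroupParams] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PARAMS))
    followup_schedule: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0)
    visit_noise_sd: float = 1.0        # MMSE points, test-retest
    mri_shape: tuple[int, int, int] = (40, 40, 40)
    jd_shape: tuple[int, int, int] = (32, 32, 32)
    atrophy_center: tuple[int, int, int] = (16, 16, 16)
    atrophy_radius: int = 6
    jd_background_noise_sd: float = 0.02   # registration-noise surrogate
    voxel_size_mm: float = 4.0
    mri_hippo_signal: bool = True
    exact_counts: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ConfigurationError("n_subjects must be positive")
        if not 0.0 < self.prevalence_early_ad < 1.0:
            raise ConfigurationError(
                "prevalence_early_ad must lie strictly between 0 and 1")
        for g in GROUPS:
            if g not in self.group_params:
                raise ConfigurationError(f"group_params missing group {g!r}")
            p = self.group_params[g]
            for name in ("age", "education", "mmse", "adas",
                         "hippocampus", "icv", "mmse_slope"):
                _, sd = getattr(p, name)
                if sd <= 0:
                    raise ConfigurationError(
                        f"group_params[{g!r}].{name} SD must be > 0")
            if not 0.0 <= p.apoe_p <= 1.0:
                raise ConfigurationError(
                    f"group_params[{g!r}].apoe_p must lie in [0, 1]")
            if not 0.0 <= p.female_fraction <= 1.0:
                raise ConfigurationError(
                    f"group_params[{g!r}].female_fraction must lie in [0, 1]")
        if len(self.followup_schedule) == 0:
            raise ConfigurationError("followup_schedule is empty")
        times = np.asarray(self.followup_schedule, float)
        if times.min() != 0.0 or times.max() > 4.0 or (times < 0).any():
            raise ConfigurationError(
                "followup_schedule must lie in [0, 4] years and include 0")
        if self.visit_noise_sd < 0:
            raise ConfigurationError("visit_noise_sd must be >= 0")
        for name in ("mri_shape", "jd_shape"):
            shp = getattr(self, name)
            if len(shp) != 3 or any(s <= 0 for s in shp):
                raise ConfigurationError(f"{name} must be three positive ints")
        c, r = self.atrophy_center, self.atrophy_radius
        if r <= 0:
            raise ConfigurationError("atrophy_radius must be positive")
        for axis in range(3):
            if c[axis] - r < 0 or c[axis] + r >= self.jd_shape[axis]:
                raise ConfigurationError(
                    "atrophy_region must lie fully inside the JD grid "
                    f"(axis {axis})")
        if self.jd_background_noise_sd < 0:
            raise ConfigurationError(
                "jd_background_noise_sd must be >= 0")
        if self.voxel_size_mm <= 0:
            raise ConfigurationError("voxel_size_mm must be positive")


@dataclass
class SubjectRecord:
    """One subject's clinical features, follow-ups and outcome labels."""

    subject_id: str
    group: str                         # "non_ad" | "early_ad"
    age: float
    sex: str                           # "F" | "M"
    education: float
    baseline_mmse: float
    adas_delayed_recall: float
    apoe_e4_count: int
    hippocampal_volume_mm3: float      # hemispheric average
    icv_cm3: float
    regional_volumes: np.ndarray       # 68 gray-matter region volumes, mm^3
    followups: list[tuple[float, float]] = field(default_factory=list)
    true_slope: float | None = None    # hidden ground truth, points/year

    @property
    def progressed_4y(self) -> bool:
        return self.group == "early_ad"


@dataclass
class VolumePair:
    """A subject's 3D intensity volume and JD (local volume change) volume."""

    mri: np.ndarray
    jd: np.ndarray


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float = -np.inf, hi: float = np.inf,
                      size: int | None = None) -> np.ndarray | float:
    """Gaussian draw with resample-on-violation truncation."""
    n = 1 if size is None else size
    out = rng.normal(mean, sd, n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return float(out[0]) if size is None else out


def _region_base_means() -> np.ndarray:
    # deterministic per-region baseline volumes, 1.5-12 cm^3 range
    idx = np.arange(N_REGIONS)
    return 1500.0 + 155.0 * idx


def generate_followups(subject: SubjectRecord, config: GeneratorConfig,
                       rng: np.random.Generator) -> SubjectRecord:
    """Attach longitudinal MMSE visits to a subject.

    A true slope is drawn from the subject's group slope distribution and
    kept as hidden truth; observed MMSE at time t is
    baseline + slope*t + N(0, visit_noise_sd), clipped to [0, 30].
    """
    if len(config.followup_schedule) == 0:
        raise ConfigurationError("followup_schedule is empty")
    params = config.group_params[subject.group]
    slope = float(rng.normal(*params.mmse_slope))
    subject.true_slope = slope
    times = np.asarray(config.followup_schedule, float)
    noise = (rng.normal(0.0, config.visit_noise_sd, times.size)
             if config.visit_noise_sd > 0 else np.zeros(times.size))
    observed = np.clip(subject.baseline_mmse + slope * times + noise, 0.0, 30.0)
    order = np.argsort(times, kind="stable")
    subject.followups = [(float(times[i]), float(observed[i])) for i in order]
    return subject


def generate_cohort(config: GeneratorConfig) -> list[SubjectRecord]:
    """Draw a full cohort, deterministic given ``config.seed``.

    Group labels follow the configured prevalence (Bernoulli per subject, or
    the exact rounded split when ``exact_counts``); each continuous feature is
    a truncated Gaussian from its group's marginal.  Plausibility bounds:
    age in [60, 80], baseline MMSE in [24, 30], ADAS >= 0, volumes > 0.
    """
    config.validate()
    # distinct nonzero stream tag: default_rng([s, 0]) would collide with
    # default_rng(s) because trailing zero entropy words are absorbed
    rng = np.random.default_rng([config.seed, 11])
    n = config.n_subjects
    if config.exact_counts:
        n_early = int(round(n * config.prevalence_early_ad))
        labels = np.zeros(n, dtype=bool)
        labels[rng.choice(n, n_early, replace=False)] = True
    else:
        labels = rng.random(n) < config.prevalence_early_ad

    base_means = _region_base_means()
    cohort: list[SubjectRecord] = []
    for i in range(n):
        group = "early_ad" if labels[i] else "non_ad"
        p = config.group_params[group]
        region_means = base_means.copy()
        region_sds = 0.12 * base_means
        if group == "early_ad":
            region_means = region_means.copy()
            region_means[list(SIGNATURE_REGIONS)] -= (
                0.4 * region_sds[list(SIGNATURE_REGIONS)])
        subject = SubjectRecord(
            subject_id=f"sub-{i + 1:04d}",
            group=group,
            age=_truncated_normal(rng, *p.age, lo=60.0, hi=80.0),
            sex="F" if rng.random() < p.female_fraction else "M",
            education=_truncated_normal(rng, *p.education, lo=0.0),
            baseline_mmse=_truncated_normal(rng, *p.mmse, lo=24.0, hi=30.0),
            adas_delayed_recall=_truncated_normal(rng, *p.adas, lo=0.0),
            apoe_e4_count=int(rng.binomial(2, p.apoe_p)),
            hippocampal_volume_mm3=_truncated_normal(
                rng, *p.hippocampus, lo=1e-9),
            icv_cm3=_truncated_normal(rng, *p.icv, lo=1e-9),
            regional_volumes=np.maximum(
                rng.normal(region_means, region_sds), 1.0),
        )
        generate_followups(subject, config, rng)
        cohort.append(subject)
    return cohort


def _subject_index(subject_id: str) -> int:
    m = re.search(r"(\d+)$", subject_id)
    if m is None:
        raise ConfigurationError(
            f"subject_id {subject_id!r} carries no numeric suffix")
    return int(m.group(1))


def generate_volume_pair(subject: SubjectRecord,
                         config: GeneratorConfig) -> VolumePair:
    """Synthesize the paired MRI / JD volumes for one subject.

    Deterministic given (config.seed, subject_id).  The atrophy sphere must
    fit inside the JD grid (validated by the config).
    """
    config.validate()
    rng = np.random.default_rng(
        [config.seed, 23, 1 + _subject_index(subject.subject_id)])
    non_ad_mean = config.group_params["non_ad"].hippocampus[0]

    # --- MRI: smoothed white noise background, optional bright "hippocampus"
    mri = rng.normal(0.0, 1.0, config.mri_shape)
    mri = ndimage.gaussian_filter(mri, sigma=2.0)
    mri = (mri - mri.min()) / (mri.max() - mri.min())  # [0, 1] texture
    mri = 20.0 + 60.0 * mri
    if config.mri_hippo_signal:
        center = tuple(s // 2 for s in config.mri_shape)
        grid = np.indices(config.mri_shape)
        dist2 = sum((grid[a] - center[a]) ** 2 for a in range(3))
        # voxel count proportional to hippocampal volume; ~500 voxels at the
        # non-AD group mean
        count = max(1, int(round(500.0 * subject.hippocampal_volume_mm3
                                 / non_ad_mean)))
        if count > mri.size:
            raise ConfigurationError(
                "mri_shape too small for the hippocampal structure")
        flat_order = np.argsort(dist2, axis=None, kind="stable")
        mask = np.zeros(mri.size, dtype=bool)
        mask[flat_order[:count]] = True
        mri[mask.reshape(config.mri_shape)] += 60.0

    # --- JD: near-unit background (registration noise), spherical
    # contraction scaled by hippocampus; the contraction region itself is
    # noise-free so its value encodes the planted signal exactly
    jd = np.ones(config.jd_shape)
    if config.jd_background_noise_sd > 0:
        jd += rng.normal(0.0, config.jd_background_noise_sd,
                         config.jd_shape)
        jd = np.maximum(jd, 0.05)          # JD values stay positive
    grid = np.indices(config.jd_shape)
    c = config.atrophy_center
    dist2 = sum((grid[a] - c[a]) ** 2 for a in range(3))
    sphere = dist2 <= config.atrophy_radius ** 2
    jd[sphere] = subject.hippocampal_volume_mm3 / non_ad_mean
    return VolumePair(mri=mri.astype(np.float32), jd=jd.astype(np.float32))


def generate_volumes(cohort: Sequence[SubjectRecord],
                     config: GeneratorConfig) -> dict[str, VolumePair]:
    return {s.subject_id: generate_volume_pair(s, config) for s in cohort}


def atrophy_mask(config: GeneratorConfig) -> np.ndarray:
    """Boolean mask of the planted atrophy sphere on the JD grid."""
    grid = np.indices(config.jd_shape)
    c = config.atrophy_center
    dist2 = sum((grid[a] - c[a]) ** 2 for a in range(3))
    return dist2 <= config.atrophy_radius ** 2


# ---------------------------------------------------------------------------
# tabular views and on-disk layout

SUBJECT_COLUMNS = [
    "subject_id", "group", "age", "sex", "education_years", "mmse_baseline",
    "adas_delayed", "apoe_e4", "hippocampus_mm3", "icv_cm3",
] + [f"region_{i + 1:03d}" for i in range(N_REGIONS)] + ["true_slope"]


def cohort_to_frame(cohort: Sequence[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for s in cohort:
        row = {
            "subject_id": s.subject_id, "group": s.group, "age": s.age,
            "sex": s.sex, "education_years": s.education,
            "mmse_baseline": s.baseline_mmse,
            "adas_delayed": s.adas_delayed_recall, "apoe_e4": s.apoe_e4_count,
            "hippocampus_mm3": s.hippocampal_volume_mm3, "icv_cm3": s.icv_cm3,
            "true_slope": s.true_slope,
        }
        for i, v in enumerate(s.regional_volumes):
            row[f"region_{i + 1:03d}"] = float(v)
        rows.append(row)
    return pd.DataFrame(rows, columns=SUBJECT_COLUMNS)


def followups_to_frame(cohort: Sequence[SubjectRecord]) -> pd.DataFrame:
    rows = [
        {"subject_id": s.subject_id, "time_years": t, "mmse": y}
        for s in cohort for (t, y) in s.followups
    ]
    return pd.DataFrame(rows, columns=["subject_id", "time_years", "mmse"])


def write_cohort(cohort: Sequence[SubjectRecord],
                 volumes: dict[str, VolumePair] | None,
                 directory: str | Path,
                 config: GeneratorConfig | None = None) -> None:
    """Persist a cohort as CSVs plus per-subject NIfTI volumes.

    Layout: subjects.csv, followups.csv, volumes/<id>_mri.nii.gz and
    volumes/<id>_jd.nii.gz.  Round-trips losslessly through ``read_cohort``.
    """
    import nibabel as nib

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cohort_to_frame(cohort).to_csv(directory / "subjects.csv", index=False,
                                   float_format="%.17g")
    followups_to_frame(cohort).to_csv(directory / "followups.csv",
                                      index=False, float_format="%.17g")
    if volumes is None:
        return
    voxel = config.voxel_size_mm if config is not None else 1.0
    affine = np.diag([voxel, voxel, voxel, 1.0])
    vdir = directory / "volumes"
    vdir.mkdir(exist_ok=True)
    for s in cohort:
        if s.subject_id not in volumes:
            raise KeyError(
                f"missing volume pair for subject {s.subject_id!r}")
        pair = volumes[s.subject_id]
        nib.save(nib.Nifti1Image(np.asarray(pair.mri, np.float32), affine),
                 vdir / f"{s.subject_id}_mri.nii.gz")
        nib.save(nib.Nifti1Image(np.asarray(pair.jd, np.float32), affine),
                 vdir / f"{s.subject_id}_jd.nii.gz")


def read_cohort(directory: str | Path,
                load_volumes: bool = True,
                ) -> tuple[list[SubjectRecord], dict[str, VolumePair]]:
    """Read a cohort written by :func:`write_cohort` (or real-data layout)."""
    import nibabel as nib

    directory = Path(directory)
    subjects = pd.read_csv(directory / "subjects.csv",
                           float_precision="round_trip")
    followups = pd.read_csv(directory / "followups.csv",
                            float_precision="round_trip")
    fu_by_id: dict[str, list[tuple[float, float]]] = {}
    for _, r in followups.iterrows():
        fu_by_id.setdefault(str(r["subject_id"]), []).append(
            (float(r["time_years"]), float(r["mmse"])))
    cohort = []
    for _, r in subjects.iterrows():
        sid = str(r["subject_id"])
        ts = r.get("true_slope", np.nan)
        cohort.append(SubjectRecord(
            subject_id=sid, group=str(r["group"]), age=float(r["age"]),
            sex=str(r["sex"]), education=float(r["education_years"]),
            baseline_mmse=float(r["mmse_baseline"]),
            adas_delayed_recall=float(r["adas_delayed"]),
            apoe_e4_count=int(r["apoe_e4"]),
            hippocampal_volume_mm3=float(r["hippocampus_mm3"]),
            icv_cm3=float(r["icv_cm3"]),
            regional_volumes=np.array(
                [r[f"region_{i + 1:03d}"] for i in range(N_REGIONS)], float),
            followups=sorted(fu_by_id.get(sid, [])),
            true_slope=None if pd.isna(ts) else float(ts),
        ))
    volumes: dict[str, VolumePair] = {}
    if load_volumes and (directory / "volumes").is_dir():
        for s in cohort:
            mri_path = directory / "volumes" / f"{s.subject_id}_mri.nii.gz"
            jd_path = directory / "volumes" / f"{s.subject_id}_jd.nii.gz"
            if not mri_path.exists() or not jd_path.exists():
                raise FileNotFoundError(
                    f"missing volume file for subject {s.subject_id!r}")
            volumes[s.subject_id] = VolumePair(
                mri=np.asanyarray(nib.load(mri_path).dataobj, np.float32),
                jd=np.asanyarray(nib.load(jd_path).dataobj, np.float32))
    return cohort, volumes
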