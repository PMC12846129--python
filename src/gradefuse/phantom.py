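"""Synthetic multimodal phantom cohorts.

The generator emulates the statistical structure of a solid-tumor cohort with
two pathological grade strata (GI–II vs GIII) and two planted treatment-
response subtypes nested within grade:

* tumor geometry is a randomly placed ellipsoid with a smooth boundary
  perturbation and a concentric necrotic core whose volume fraction rises
  with grade (and with the planted high-risk subtype);
* three co-registered modality surrogates differ in contrast and noise: a
  CT-like texture channel, a smoother MRI-like channel with a bright core,
  and a PET-like channel with grade- and subtype-scaled focal hotspots;
* clinical features carry grade-correlated biomarkers (a PD-L1-like level,
  an EGFR-like mutation flag, an AFP-like level) plus demographics, with
  configurable missingness and record-time jitter;
* response labels follow a logistic model on (grade, subtype, biomarker,
  texture) latents with recorded coefficients, and progression-free survival
  follows subtype-dependent exponential hazards with independent exponential
  censoring.

Every random draw flows from a single ``numpy`` Generator seeded from the
config, so regeneration with the same config is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .datatypes import ClinicalRecord, VolumeImage
from .exceptions import ConfigurationError
from .metrics import auc as _auc

__all__ = ["PhantomConfig", "SyntheticCohort", "generate_cohort", "bayes_optimal_auc"]

MODALITIES = ("CT", "MRI", "PET")

# Cohort-level composition constants (grade mix, responder fraction, tumor
# types, demographics, subtype PFS medians) follow the reference cohort
# description; effect sizes of the planted subtype on images and biomarkers
# are generator choices documented in docs/methods.md.
_TUMOR_TYPES = ("NSCLC", "HCC")


@dataclass
class PhantomConfig:
    n_patients: int = 200
    volume_shape: tuple[int, int, int] = (16, 16, 16)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    grade_prevalence: tuple[float, ...] = (0.42, 0.58)
    subtype_effect: float = 2.0               # log-odds of response per planted subtype
    necrosis_mean_by_grade: tuple[float, ...] = (0.05, 0.30)
    heterogeneity_sd_by_grade: tuple[float, ...] = (0.20, 0.50)
    missing_rate: float = 0.05
    temporal_jitter_sd: float = 10.0          # days
    seed: int = 0
    # subtype structure
    subtype_prevalence_by_grade: tuple[float, ...] = (0.35, 0.55)
    # the high-risk subtype is planted as a dominant within-grade mode of
    # variation (comparable in size to the grade effect itself): extensive
    # necrosis, hypermetabolic PET foci and high PD-L1 — the regime in which
    # "different responses within the same grade" is imaging-visible
    necrosis_shift_subtype: float = 0.30      # extra necrotic fraction, high-risk
    texture_shift_subtype: float = 1.00       # relative texture-SD increase, high-risk
    hotspot_gain_subtype: float = 1.50        # extra PET hotspot amplitude, high-risk
    biomarker_shift_subtype: float = 3.00     # PD-L1-like shift, high-risk
    biomarker_noise_sd: float = 0.45          # within-class PD-L1 spread (bimodal marker)
    response_base_rate: float = 0.49
    pfs_median_by_subtype: tuple[float, float] = (14.2, 5.8)   # months: low-, high-risk
    censoring_rate: float = 0.25
    tumor_type_prevalence: tuple[float, float] = (0.53, 0.47)

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be positive")
        if len(self.volume_shape) != 3 or any(int(s) < 4 for s in self.volume_shape):
            raise ConfigurationError("volume_shape must be a positive integer triple (>= 4 voxels)")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ConfigurationError("voxel spacing must be positive")
        if not np.isclose(sum(self.grade_prevalence), 1.0):
            raise ConfigurationError("grade_prevalence must sum to 1")
        for name in ("missing_rate", "censoring_rate", "response_base_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        for f in (*self.necrosis_mean_by_grade, *self.subtype_prevalence_by_grade):
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError("fractions must lie in [0, 1]")
        n_g = len(self.grade_prevalence)
        if not (len(self.necrosis_mean_by_grade) == len(self.heterogeneity_sd_by_grade)
                == len(self.subtype_prevalence_by_grade) == n_g):
            raise ConfigurationError("per-grade parameter tuples must match grade_prevalence")


@dataclass
class SyntheticCohort:
    config: PhantomConfig
    volumes: dict            # pid -> {modality -> VolumeImage}
    masks: dict              # pid -> VolumeImage (binary)
    clinical: list           # list[ClinicalRecord]
    truth_manifest: pd.DataFrame
    coefficients: dict = field(default_factory=dict)

    @property
    def patient_ids(self) -> list[str]:
        return [r.patient_id for r in self.clinical]

    def clinical_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.clinical:
            row = {"patient_id": r.patient_id, **r.features,
                   "grade": r.grade, "response": r.response,
                   "pfs_time": r.pfs_time, "pfs_event": r.pfs_event,
                   "record_time": r.timestamp}
            rows.append(row)
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        (out / "volumes").mkdir(parents=True, exist_ok=True)
        for pid, mods in self.volumes.items():
            for mod, vol in mods.items():
                vol.to_nifti(out / "volumes" / f"{pid}_{mod}.nii.gz")
            self.masks[pid].to_nifti(out / "volumes" / f"{pid}_mask.nii.gz")
        self.clinical_frame().to_csv(out / "clinical.csv", index=False)
        self.truth_manifest.to_csv(out / "truth_manifest.csv", index=False)
        echo = asdict(self.config)
        echo["_coefficients"] = {k: float(v) for k, v in self.coefficients.items()}
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(echo, fh)
        return out


def load_cohort(in_dir: str | Path) -> SyntheticCohort:
    """Read a cohort previously written with :meth:`SyntheticCohort.write`."""
    src = Path(in_dir)
    with open(src / "config.yaml") as fh:
        echo = yaml.safe_load(fh)
    coeffs = echo.pop("_coefficients", {})
    for key in ("volume_shape", "voxel_spacing", "grade_prevalence",
                "necrosis_mean_by_grade", "heterogeneity_sd_by_grade",
                "subtype_prevalence_by_grade", "pfs_median_by_subtype",
                "tumor_type_prevalence"):
        if key in echo:
            echo[key] = tuple(echo[key])
    config = PhantomConfig(**echo)
    clinical_df = pd.read_csv(src / "clinical.csv")
    truth = pd.read_csv(src / "truth_manifest.csv")
    volumes, masks, clinical = {}, {}, []
    for _, row in clinical_df.iterrows():
        pid = row["patient_id"]
        volumes[pid] = {mod: VolumeImage.from_nifti(src / "volumes" / f"{pid}_{mod}.nii.gz",
                                                    modality=mod)
                        for mod in MODALITIES}
        masks[pid] = VolumeImage.from_nifti(src / "volumes" / f"{pid}_mask.nii.gz",
                                            modality="mask")
        feats = {k: row[k] for k in ("age", "sex", "tumor_type", "pdl1", "egfr", "afp")}
        clinical.append(ClinicalRecord(
            patient_id=pid, features=feats, grade=int(row["grade"]),
            response=int(row["response"]), pfs_time=float(row["pfs_time"]),
            pfs_event=int(row["pfs_event"]), timestamp=float(row["record_time"])))
    return SyntheticCohort(config=config, volumes=volumes, masks=masks,
                           clinical=clinical, truth_manifest=truth,
                           coefficients=coeffs)


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal(shape), sigma)
    sd = f.std()
    return f / sd if sd > 0 else f


def _tumor_geometry(rng: np.random.Generator, shape, necrosis_target: float):
    """Perturbed ellipsoid mask plus a concentric necrotic core."""
    dims = np.asarray(shape, dtype=float)
    center = dims / 2.0 + rng.uniform(-0.06, 0.06, size=3) * dims
    semi = rng.uniform(0.24, 0.34, size=3) * dims
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    r = np.sqrt(sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi)))
    pert = 0.10 * _smooth_field(rng, shape, sigma=max(2.0, min(shape) / 8.0))
    mask = (r + pert) < 1.0
    if mask.sum() < 8:  # degenerate draw; fall back to the unperturbed ellipsoid
        mask = r < 1.0
    core = (r + pert) < float(np.cbrt(max(necrosis_target, 0.0)))
    core &= mask
    return mask, core, r


def generate_cohort(config: PhantomConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort (volumes, masks, clinical, truth)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_g = len(config.grade_prevalence)

    base_logit = float(np.log(config.response_base_rate / (1 - config.response_base_rate)))
    mean_subtype = float(np.dot(config.grade_prevalence, config.subtype_prevalence_by_grade))
    mean_grade = float(np.dot(config.grade_prevalence, np.arange(n_g)))
    # expected product of the centred subtype/grade terms, used to keep the
    # marginal responder rate at the configured base rate
    e_prod = float(sum(
        config.grade_prevalence[g]
        * ((g - mean_grade)
           * (config.subtype_prevalence_by_grade[g] - mean_subtype))
        for g in range(n_g)))
    coeffs = {
        "intercept": base_logit,
        "beta_subtype": -float(config.subtype_effect),   # high-risk responds less
        "beta_grade": 1.20,
        # grade-interaction scales with the main subtype effect, so a null
        # subtype effect implies no subtype-dependent response at all
        "beta_interaction": -0.5 * float(config.subtype_effect),
        "beta_texture": -0.40,
        "beta_biomarker": 0.30,
        "subtype_centering": mean_subtype,
        "grade_centering": mean_grade,
        "interaction_centering": e_prod,
    }

    volumes, masks, clinical, truth_rows = {}, {}, [], []
    for idx in range(config.n_patients):
        pid = f"P{idx:04d}"
        g = int(rng.choice(n_g, p=config.grade_prevalence))
        s = int(rng.random() < config.subtype_prevalence_by_grade[g])

        nec_target = float(np.clip(
            config.necrosis_mean_by_grade[g] + config.necrosis_shift_subtype * s
            + rng.normal(0.0, 0.03), 0.0, 0.85))
        u_tex = float(rng.standard_normal())
        tex_sd = max(0.02, config.heterogeneity_sd_by_grade[g]
                     * (1.0 + config.texture_shift_subtype * s) * (1.0 + 0.15 * u_tex))

        mask, core, r = _tumor_geometry(rng, config.volume_shape, nec_target)
        rim = mask & ~core
        shape = tuple(int(v) for v in config.volume_shape)

        # CT-like: textured rim, dark necrotic core
        ct = rng.normal(0.20, 0.05, size=shape)
        ct[rim] = rng.normal(0.60, tex_sd, size=int(rim.sum()))
        ct[core] = rng.normal(0.12, 0.05, size=int(core.sum()))
        # MRI-like: smoother contrast, bright fluid core
        mri = rng.normal(0.30, 0.05, size=shape)
        mri[rim] = rng.normal(0.55, 0.6 * tex_sd, size=int(rim.sum()))
        mri[core] = rng.normal(0.80, 0.06, size=int(core.sum()))
        mri = gaussian_filter(mri, 0.6)
        # PET-like: low background plus focal hotspots scaled by grade/subtype
        pet = rng.normal(0.10, 0.03, size=shape)
        pet[mask] += 0.20
        amp = 0.40 + 0.45 * g + config.hotspot_gain_subtype * s
        in_mask = np.argwhere(mask)
        n_hot = 1 + g + 2 * s
        grids = np.meshgrid(*[np.arange(d, dtype=float) for d in shape], indexing="ij")
        for _ in range(n_hot):
            cx = in_mask[rng.integers(len(in_mask))]
            sig = 0.10 * min(shape)
            blob = np.exp(-sum((gr - c) ** 2 for gr, c in zip(grids, cx)) / (2 * sig ** 2))
            pet += amp * blob

        volumes[pid] = {
            "CT": VolumeImage(ct, config.voxel_spacing, "CT", 0.0),
            "MRI": VolumeImage(mri, config.voxel_spacing, "MRI", 0.0),
            "PET": VolumeImage(pet, config.voxel_spacing, "PET", 0.0),
        }
        masks[pid] = VolumeImage(mask.astype(np.float64), config.voxel_spacing, "mask", 0.0)

        # clinical phenotypes
        u_bio = float(rng.standard_normal())
        pdl1 = 0.5 * g + config.biomarker_shift_subtype * s + config.biomarker_noise_sd * u_bio
        egfr = int(rng.random() < 1.0 / (1.0 + np.exp(-(-1.2 + 0.8 * g + 0.8 * s))))
        afp = 0.8 * (1 - s) + 0.2 * g + float(rng.standard_normal())
        age = float(rng.normal(62.4, 11.5))
        sex = "M" if rng.random() < 0.624 else "F"
        tumor_type = _TUMOR_TYPES[int(rng.random() >= config.tumor_type_prevalence[0])]
        record_time = float(rng.normal(0.0, config.temporal_jitter_sd))

        logit = (coeffs["intercept"]
                 + coeffs["beta_subtype"] * (s - mean_subtype)
                 + coeffs["beta_grade"] * (g - mean_grade)
                 + coeffs["beta_interaction"]
                 * ((s - mean_subtype) * (g - mean_grade) - e_prod)
                 + coeffs["beta_texture"] * u_tex
                 + coeffs["beta_biomarker"] * u_bio)
        p_resp = float(1.0 / (1.0 + np.exp(-logit)))
        response = int(rng.random() < p_resp)

        lam = np.log(2.0) / config.pfs_median_by_subtype[s]
        t_event = float(rng.exponential(1.0 / lam))
        r_c = config.censoring_rate
        if r_c > 0:
            mu = lam * r_c / (1.0 - r_c)
            t_cens = float(rng.exponential(1.0 / mu))
        else:
            t_cens = np.inf
        pfs_time = min(t_event, t_cens)
        pfs_event = int(t_event <= t_cens)

        features = {"age": age, "sex": sex, "tumor_type": tumor_type,
                    "pdl1": pdl1, "egfr": egfr, "afp": afp}
        if config.missing_rate > 0:
            for key in ("age", "pdl1", "afp", "sex", "tumor_type"):
                if rng.random() < config.missing_rate:
                    features[key] = np.nan
        clinical.append(ClinicalRecord(
            patient_id=pid, features=features, grade=g, response=response,
            pfs_time=pfs_time, pfs_event=pfs_event, timestamp=record_time))

        mask_n = int(mask.sum())
        truth_rows.append({
            "patient_id": pid, "grade": g, "subtype": s,
            "p_response": p_resp, "response": response,
            "necrotic_fraction": float(core.sum()) / mask_n if mask_n else 0.0,
            "texture_sd": tex_sd, "u_texture": u_tex, "u_biomarker": u_bio,
            "pfs_time": pfs_time, "pfs_event": pfs_event,
        })

    truth = pd.DataFrame(truth_rows)
    return SyntheticCohort(config=config, volumes=volumes, masks=masks,
                           clinical=clinical, truth_manifest=truth,
                           coefficients=coeffs)


def bayes_optimal_auc(cohort: SyntheticCohort) -> float:
    """AUC of the true generative response probability against realised labels.

    Upper-bounds (in expectation) the AUC any model can reach on this cohort,
    since the generative probability is the Bayes-optimal score.
    """
    t = cohort.truth_manifest
    return _auc(t["p_response"].to_numpy(), t["response"].to_numpy())
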