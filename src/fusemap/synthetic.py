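"""Synthetic multimodal cohorts with planted latent structure.

Each subject carries a latent maturation score z that increases with age
(with a sex-specific intercept). Regional brain features load on z — linearly
in one modality, through a saturating link in the other — plus a sex
gradient, site location/scale effects and Gaussian noise. PDS items are
ordinalized monotone functions of z with logistic reporter noise; diagnosis
counts follow a Poisson whose rate grows with the deviation of z from its
age/sex expectation (females only, by default). This mirrors the statistical
assumptions of the fusion/embedding/transfer pipeline so that every stage is
testable without access-restricted cohort data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ModalityMatrix

__all__ = ["GeneratorConfig", "SyntheticCohort", "generate_cohort", "generate_longitudinal_pair"]

Z_AGE_SLOPE = 0.35  # latent maturation per year
Z_FEMALE_INTERCEPT = 0.5  # earlier maturation in females
PDS_ITEM_QUANTILES = (0.25, 0.5, 0.75)  # fixed thresholds on the z scale
MENARCHE_QUANTILE = 0.6
DIAGNOSIS_LOG_BASE = np.log(2.2)  # clinical cohorts span roughly 1-10 diagnoses


@dataclass
class GeneratorConfig:
    n_subjects: int
    n_features_per_modality: int = 34
    n_modalities: int = 2
    n_sites: int = 1
    sex_ratio: float = 0.5  # fraction female
    age_range: tuple = (8.0, 21.0)
    latent_loading_scale: float = 1.0
    noise_sd: float = 1.0
    site_offset_sd: float = 0.0
    site_scale_sd: float = 0.0
    sex_gradient_strength: float = 0.3
    pds_coupling: float = 1.5
    diagnosis_coupling: float = 0.5
    seed: int = 0
    clinical: bool = False  # truncate diagnosis counts to >= 1
    # Cohorts sharing a structure_seed share feature loadings and sex
    # gradients (the same biology measured in different samples), while
    # demographics, sites and noise still follow `seed`.
    structure_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 4:
            raise ValueError("n_subjects must be >= 4")
        if self.n_modalities < 1:
            raise ValueError("n_modalities must be >= 1")
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise ValueError("sex_ratio must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.age_range[1] <= self.age_range[0]:
            raise ValueError("age_range must be increasing")
        if self.latent_loading_scale == 0 and (self.pds_coupling != 0 or self.diagnosis_coupling != 0):
            raise ValueError(
                "latent_loading_scale = 0 with nonzero phenotype coupling leaves the "
                "planted signal unidentifiable from features"
            )


@dataclass
class SyntheticCohort:
    """Generated cohort: per-modality feature tables, a long-format phenotype
    table (one row per subject x timepoint) and the planted latent truth."""

    modalities: list  # baseline / single-visit ModalityMatrix per modality
    phenotypes: pd.DataFrame
    latent_truth: pd.DataFrame
    config: GeneratorConfig
    followup_modalities: list | None = None

    @property
    def subject_ids(self) -> list[str]:
        return list(self.modalities[0].subject_ids)

    def write(self, outdir) -> None:
        """One wide CSV per modality (+ per timepoint), one phenotype CSV,
        and a JSON sidecar with the config and latent truth."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for mod in self.modalities:
            mod.to_frame().to_csv(outdir / f"features_{mod.modality}_baseline.csv", index=False)
        if self.followup_modalities:
            for mod in self.followup_modalities:
                mod.to_frame().to_csv(outdir / f"features_{mod.modality}_followup.csv", index=False)
        self.phenotypes.to_csv(outdir / "phenotypes.csv", index=False)
        sidecar = {
            "config": asdict(self.config),
            "latent_truth": self.latent_truth.to_dict(orient="list"),
        }
        (outdir / "cohort.json").write_text(json.dumps(sidecar, indent=2))


def _substreams(cfg: "GeneratorConfig", names) -> dict:
    children = np.random.SeedSequence(cfg.seed).spawn(len(names))
    rng = {name: np.random.default_rng(child) for name, child in zip(names, children)}
    structure_seed = cfg.seed if cfg.structure_seed is None else cfg.structure_seed
    rng["loadings"] = np.random.default_rng(
        np.random.SeedSequence(entropy=structure_seed, spawn_key=(10_001,))
    )
    return rng


_BLOCKS = (
    "demographics", "latent", "loadings", "sites", "noise",
    "pds", "diagnosis", "longitudinal", "noise_followup", "pds_followup",
)


def _z_thresholds(cfg: GeneratorConfig) -> np.ndarray:
    lo, hi = cfg.age_range
    return np.array([Z_AGE_SLOPE * q * (hi - lo) for q in PDS_ITEM_QUANTILES])


def _expected_z(age: np.ndarray, female: np.ndarray, cfg: GeneratorConfig) -> np.ndarray:
    return Z_AGE_SLOPE * (age - cfg.age_range[0]) + Z_FEMALE_INTERCEPT * female


SAT_MID = 2.5  # z midpoint of the developmental range the links model
SAT_HALFWIDTH = 4.5


def _saturating(z: np.ndarray) -> np.ndarray:
    """Mildly saturating link for the second modality: shared monotone signal
    with complementary compressive curvature. Fixed constants — a property
    of the modelled biology, identical across cohorts."""
    return SAT_HALFWIDTH * np.tanh((z - SAT_MID) / SAT_HALFWIDTH) + SAT_MID


_LINKS = [lambda z: z, _saturating]


def _links_for(cfg: GeneratorConfig):
    return _LINKS


def _draw_structure(cfg: GeneratorConfig, rng: dict):
    """Cohort-level fixed effects: loadings, sex gradients, site parameters."""
    p, m = cfg.n_features_per_modality, cfg.n_modalities
    loadings, sexgrad = [], []
    for _ in range(m):
        mag = rng["loadings"].uniform(0.5, 1.5, size=p) * cfg.latent_loading_scale
        sign = rng["loadings"].choice([-1.0, 1.0], size=p)
        loadings.append(mag * sign)
        sexgrad.append(rng["loadings"].normal(0.0, 1.0, size=p) * cfg.sex_gradient_strength)
    site_offsets = rng["sites"].normal(0.0, cfg.site_offset_sd, size=(m, cfg.n_sites, p)) \
        if cfg.site_offset_sd > 0 else np.zeros((m, cfg.n_sites, p))
    site_scales = np.exp(rng["sites"].normal(0.0, cfg.site_scale_sd, size=cfg.n_sites)) \
        if cfg.site_scale_sd > 0 else np.ones(cfg.n_sites)
    return loadings, sexgrad, site_offsets, site_scales


def _features(cfg, z, female, site_idx, structure, rng_noise):
    loadings, sexgrad, site_offsets, site_scales = structure
    n = len(z)
    mods = []
    ids = [f"S{i + 1:05d}" for i in range(n)]
    links = _links_for(cfg)
    for m in range(cfg.n_modalities):
        g = links[m % len(links)](z)
        X = np.outer(g, loadings[m])
        X += np.outer(female, sexgrad[m])
        X += site_offsets[m][site_idx]
        noise = rng_noise.normal(0.0, 1.0, size=(n, cfg.n_features_per_modality))
        X += cfg.noise_sd * site_scales[site_idx][:, None] * noise
        mods.append(ModalityMatrix(ids, X, modality=f"mod{m + 1}"))
    return ids, mods


def _pds_items(cfg, z, female, rng) -> pd.DataFrame:
    """Ordinal 1-4 items from fixed thresholds on pds_coupling*z plus
    logistic reporter noise; binary menarche for females."""
    from .phenotypes import FEMALE_ITEMS, MALE_ITEMS

    n = len(z)
    thr = cfg.pds_coupling * _z_thresholds(cfg)
    lo, hi = cfg.age_range
    men_thr = cfg.pds_coupling * Z_AGE_SLOPE * MENARCHE_QUANTILE * (hi - lo)
    cols = {}
    all_items = sorted(set(MALE_ITEMS) | set(FEMALE_ITEMS))
    for item in all_items:
        u = cfg.pds_coupling * z + rng.logistic(0.0, 1.0, size=n)
        score = 1 + (u[:, None] > thr[None, :]).sum(axis=1)
        applicable = np.where(
            [(item in MALE_ITEMS, item in FEMALE_ITEMS)[int(f)] for f in female], True, False
        )
        cols[f"pds_{item}"] = np.where(applicable, score.astype(float), np.nan)
    u_men = cfg.pds_coupling * z + rng.logistic(0.0, 1.0, size=n)
    cols["menarche"] = np.where(female.astype(bool), (u_men > men_thr).astype(float), np.nan)
    return pd.DataFrame(cols)


def _diagnoses(cfg, z, age, female, rng) -> np.ndarray:
    dev = np.abs(z - _expected_z(age, female, cfg))
    lam = np.exp(DIAGNOSIS_LOG_BASE + cfg.diagnosis_coupling * dev * female)
    counts = rng.poisson(lam)
    if cfg.clinical:
        # truncated Poisson(lambda) >= 1 by redrawing zeros
        zero = counts == 0
        while np.any(zero):
            counts[zero] = rng.poisson(lam[zero])
            zero = counts == 0
    return counts


def _phenotype_frame(cfg, ids, age, female, site_idx, z, items, diag, cbcl, timepoint, reporter="caregiver"):
    df = pd.DataFrame(
        {
            "subject_id": ids,
            "sex": np.where(female.astype(bool), "female", "male"),
            "age": age,
            "site": [f"site{j + 1}" for j in site_idx],
            "timepoint": timepoint,
            "reporter": reporter,
            "diagnosis_count": diag,
            "cbcl_total": cbcl,
        }
    )
    return pd.concat([df, items], axis=1)


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Single-visit cohort with planted latent maturation structure."""
    cfg = config
    rng = _substreams(cfg, _BLOCKS)
    n = cfg.n_subjects

    female = (rng["demographics"].random(n) < cfg.sex_ratio).astype(float)
    age = rng["demographics"].uniform(*cfg.age_range, size=n)
    site_idx = rng["demographics"].integers(0, cfg.n_sites, size=n)
    z = _expected_z(age, female, cfg) + rng["latent"].normal(0.0, 1.0, size=n)

    structure = _draw_structure(cfg, rng)
    ids, mods = _features(cfg, z, female, site_idx, structure, rng["noise"])
    items = _pds_items(cfg, z, female, rng["pds"])
    diag = _diagnoses(cfg, z, age, female, rng["diagnosis"])
    cbcl = 5.0 * diag + np.abs(rng["diagnosis"].normal(0.0, 8.0, size=n))
    pheno = _phenotype_frame(cfg, ids, age, female, site_idx, z, items, diag, cbcl, "single")
    truth = pd.DataFrame(
        {
            "subject_id": ids,
            "timepoint": "single",
            "z": z,
            "sex_offset": Z_FEMALE_INTERCEPT * female,
        }
    )
    return SyntheticCohort(modalities=mods, phenotypes=pheno, latent_truth=truth, config=cfg)


def generate_longitudinal_pair(config: GeneratorConfig, delta_z_by_sex: dict) -> SyntheticCohort:
    """Two-visit cohort: same subjects, loadings and sites at both visits;
    the latent score increments by a sex-specific mean (plus noise scaled by
    noise_sd) so that delta-z and delta-PDS are coupled by construction."""
    cfg = config
    rng = _substreams(cfg, _BLOCKS)
    n = cfg.n_subjects

    female = (rng["demographics"].random(n) < cfg.sex_ratio).astype(float)
    age = rng["demographics"].uniform(*cfg.age_range, size=n)
    site_idx = rng["demographics"].integers(0, cfg.n_sites, size=n)
    z1 = _expected_z(age, female, cfg) + rng["latent"].normal(0.0, 1.0, size=n)

    delta = np.array([delta_z_by_sex["female"] if f else delta_z_by_sex["male"] for f in female])
    dz_noise = rng["longitudinal"].normal(0.0, 1.0, size=n) * 0.2 * cfg.noise_sd
    z2 = z1 + delta + dz_noise
    dage = 2.0 + rng["longitudinal"].normal(0.0, 1.0, size=n) * 0.1 * cfg.noise_sd
    age2 = age + np.abs(dage)

    structure = _draw_structure(cfg, rng)
    ids, mods1 = _features(cfg, z1, female, site_idx, structure, rng["noise"])
    _, mods2 = _features(cfg, z2, female, site_idx, structure, rng["noise_followup"])

    items1 = _pds_items(cfg, z1, female, rng["pds"])
    items2 = _pds_items(cfg, z2, female, rng["pds_followup"])
    diag = _diagnoses(cfg, z1, age, female, rng["diagnosis"])
    cbcl = 5.0 * diag + np.abs(rng["diagnosis"].normal(0.0, 8.0, size=n))
    ph1 = _phenotype_frame(cfg, ids, age, female, site_idx, z1, items1, diag, cbcl, "baseline")
    ph2 = _phenotype_frame(cfg, ids, age2, female, site_idx, z2, items2, diag, cbcl, "followup")
    pheno = pd.concat([ph1, ph2], ignore_index=True)
    truth = pd.DataFrame(
        {
            "subject_id": ids * 2,
            "timepoint": ["baseline"] * n + ["followup"] * n,
            "z": np.concatenate([z1, z2]),
            "sex_offset": np.tile(Z_FEMALE_INTERCEPT * female, 2),
        }
    )
    return SyntheticCohort(
        modalities=mods1,
        phenotypes=pheno,
        latent_truth=truth,
        config=cfg,
        followup_modalities=mods2,
    )
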