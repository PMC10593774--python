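"""Parametric empirical-Bayes batch harmonization (ComBat) for feature tables.

Site/scanner location and scale effects are estimated per feature, shrunk
across features with a normal prior on locations and an inverse-gamma prior
on scales, and removed. Applied independently per modality (and, in the
pipeline, per timepoint and per train/test partition).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .datatypes import ModalityMatrix

__all__ = ["CombatModel", "combat_fit", "combat_apply", "combat_fit_apply"]


@dataclass
class CombatModel:
    """Frozen harmonization parameters for one modality.

    gamma_star : EB-shrunk batch locations (batch x feature), standardized units.
    delta_star : EB-shrunk batch variance multipliers (batch x feature), > 0.
    """

    batches: list[str]
    grand_mean: np.ndarray
    pooled_var: np.ndarray
    gamma_star: np.ndarray
    delta_star: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "batches": self.batches,
                "grand_mean": self.grand_mean.tolist(),
                "pooled_var": self.pooled_var.tolist(),
                "gamma_star": self.gamma_star.tolist(),
                "delta_star": self.delta_star.tolist(),
                "feature_names": self.feature_names,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CombatModel":
        d = json.loads(text)
        return cls(
            batches=d["batches"],
            grand_mean=np.asarray(d["grand_mean"], dtype=float),
            pooled_var=np.asarray(d["pooled_var"], dtype=float),
            gamma_star=np.asarray(d["gamma_star"], dtype=float),
            delta_star=np.asarray(d["delta_star"], dtype=float),
            feature_names=d.get("feature_names", []),
        )


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _eb_iterate(Z_b, gamma_hat, delta_hat, gamma_bar, tau2, a, b, tol=1e-6, max_iter=500):
    """Iterative conditional posterior-mode updates for one batch."""
    n = Z_b.shape[0]
    g_old, d_old = gamma_hat.copy(), delta_hat.copy()
    for _ in range(max_iter):
        g_new = (n * tau2 * gamma_hat + d_old * gamma_bar) / (n * tau2 + d_old)
        ss = ((Z_b - g_new[None, :]) ** 2).sum(axis=0)
        d_new = (b + 0.5 * ss) / (n / 2.0 + a - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < tol:
            break
    return g_old, d_old


def combat_fit(modality: ModalityMatrix, batches) -> CombatModel:
    """Estimate EB-shrunk batch location/scale effects.

    Requires >= 2 batches with >= 2 subjects each and no zero-variance
    feature.
    """
    labels = [str(b) for b in batches]
    if len(labels) != modality.n_subjects:
        raise ValueError("one batch label per subject required")
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("at least 2 batches required for harmonization")
    lab_arr = np.asarray(labels)
    idx = {u: np.where(lab_arr == u)[0] for u in uniq}
    for u, ii in idx.items():
        if len(ii) < 2:
            raise ValueError(f"batch '{u}' has fewer than 2 subjects")

    X = modality.values
    n, p = X.shape
    var0 = X.var(axis=0)
    if np.any(var0 == 0):
        bad = [modality.feature_names[j] for j in np.where(var0 == 0)[0]]
        raise ValueError(f"zero-variance features: {bad[:5]}")

    batch_means = np.vstack([X[idx[u]].mean(axis=0) for u in uniq])
    weights = np.array([len(idx[u]) / n for u in uniq])
    grand_mean = weights @ batch_means
    # residual variance after removing batch means, pooled over subjects
    resid = X - batch_means[[uniq.index(l) for l in labels]]
    pooled_var = (resid**2).mean(axis=0)
    if np.any(pooled_var == 0):
        bad = [modality.feature_names[j] for j in np.where(pooled_var == 0)[0]]
        raise ValueError(f"zero within-batch variance features: {bad[:5]}")

    Z = (X - grand_mean) / np.sqrt(pooled_var)

    gamma_star = np.zeros((len(uniq), p))
    delta_star = np.zeros((len(uniq), p))
    for bi, u in enumerate(uniq):
        Zb = Z[idx[u]]
        gamma_hat = Zb.mean(axis=0)
        delta_hat = Zb.var(axis=0, ddof=1)
        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=1)
        a, b = _aprior(delta_hat), _bprior(delta_hat)
        g, d = _eb_iterate(Zb, gamma_hat, delta_hat, gamma_bar, tau2, a, b)
        gamma_star[bi] = g
        delta_star[bi] = d
    if np.any(delta_star <= 0):
        raise RuntimeError("non-positive shrunk scale estimate")

    return CombatModel(
        batches=uniq,
        grand_mean=grand_mean,
        pooled_var=pooled_var,
        gamma_star=gamma_star,
        delta_star=delta_star,
        feature_names=list(modality.feature_names),
    )


def combat_apply(modality: ModalityMatrix, model: CombatModel, batches) -> ModalityMatrix:
    """Remove the fitted batch effects from a feature table."""
    labels = [str(b) for b in batches]
    if len(labels) != modality.n_subjects:
        raise ValueError("one batch label per subject required")
    unseen = sorted(set(labels) - set(model.batches))
    if unseen:
        raise ValueError(f"unseen batch labels: {unseen}")
    lut = {u: i for i, u in enumerate(model.batches)}
    bi = np.array([lut[l] for l in labels])

    Z = (modality.values - model.grand_mean) / np.sqrt(model.pooled_var)
    adj = (Z - model.gamma_star[bi]) / np.sqrt(model.delta_star[bi])
    out = adj * np.sqrt(model.pooled_var) + model.grand_mean
    return ModalityMatrix(
        subject_ids=list(modality.subject_ids),
        values=out,
        modality=modality.modality,
        feature_names=list(modality.feature_names),
    )


def combat_fit_apply(modality: ModalityMatrix, batches) -> ModalityMatrix:
    return combat_apply(modality, combat_fit(modality, batches), batches)
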