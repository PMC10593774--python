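"""Model/Results objects for the fused-network reference space.

`ReferenceSpaceModel` holds the data (source cohort modalities, optional
target-adaptation modalities) and hyperparameters; `fit()` runs fusion,
embedding and transfer boosting and returns a `ReferenceSpaceResults` that
predicts embedding scores for new subjects, evaluates against a ground-truth
fusion of held-out data, and prints a summary table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import EmbeddingComparison, EmbeddingResult, FusedNetwork, ModalityMatrix
from .embedding import (
    EmbeddingParams,
    compare_embeddings,
    diffusion_map_embed,
    procrustes_align,
)
from .fusion import SNFParams, affinity_from_modality, snf_fuse
from .transfer import (
    DomainAdaptedModel,
    ElasticNetParams,
    TransferParams,
    fit_elastic_net,
    tradaboost_fit,
    tradaboost_predict,
)

__all__ = ["ReferenceSpaceModel", "ReferenceSpaceResults", "fuse_and_embed", "concat_features"]


def concat_features(modalities: list[ModalityMatrix]):
    """Column-concatenate modality tables (same subjects, same order)."""
    ids = modalities[0].subject_ids
    for mod in modalities[1:]:
        if mod.subject_ids != ids:
            raise ValueError("modalities have mismatched subject ids/order")
    X = np.hstack([m.values for m in modalities])
    names = [f"{m.modality}:{f}" for m in modalities for f in m.feature_names]
    return X, names, list(ids)


def fuse_and_embed(
    modalities: list[ModalityMatrix],
    snf: SNFParams,
    embed: EmbeddingParams,
) -> tuple[FusedNetwork, EmbeddingResult]:
    """Affinities -> fused network -> diffusion map for one cohort."""
    affs = [affinity_from_modality(m, snf) for m in modalities]
    net = snf_fuse(affs, snf)
    return net, diffusion_map_embed(net, embed)


class ReferenceSpaceModel:
    """Learn a transferable mapping from raw regional brain features to the
    first brain embedding of a fused similarity network.

    Parameters
    ----------
    source_modalities : feature tables of the reference (source) cohort.
    target_adapt_modalities : optional held-out target-cohort subset used for
        instance-weighted domain adaptation; omitting it falls back to a
        plain elastic net fitted on the source alone.
    """

    def __init__(
        self,
        source_modalities: list[ModalityMatrix],
        target_adapt_modalities: list[ModalityMatrix] | None = None,
        snf: SNFParams | None = None,
        embed: EmbeddingParams | None = None,
        elastic_net: ElasticNetParams | None = None,
        transfer: TransferParams | None = None,
        align_scaling: bool = True,
    ) -> None:
        self.source_modalities = source_modalities
        self.target_adapt_modalities = target_adapt_modalities
        self.snf = snf or SNFParams()
        self.embed = embed or EmbeddingParams()
        self.elastic_net = elastic_net or ElasticNetParams()
        self.transfer = transfer or TransferParams()
        self.align_scaling = align_scaling

    @classmethod
    def from_dataframes(cls, source_frames: list[pd.DataFrame], adapt_frames=None, **kwargs):
        mods = [ModalityMatrix.from_frame(df, modality=f"mod{i + 1}") for i, df in enumerate(source_frames)]
        adapt = (
            [ModalityMatrix.from_frame(df, modality=f"mod{i + 1}") for i, df in enumerate(adapt_frames)]
            if adapt_frames is not None
            else None
        )
        return cls(mods, adapt, **kwargs)

    def fit(self) -> "ReferenceSpaceResults":
        src_net, src_emb = fuse_and_embed(self.source_modalities, self.snf, self.embed)
        X_src, names, _ = concat_features(self.source_modalities)
        y_src = src_emb.first

        adapt_emb = None
        if self.target_adapt_modalities is not None:
            _, adapt_emb_raw = fuse_and_embed(self.target_adapt_modalities, self.snf, self.embed)
            X_adapt, names_a, _ = concat_features(self.target_adapt_modalities)
            if names_a != names:
                raise ValueError("adaptation features do not match source feature columns")
            # Bridge: a source-only elastic net supplies the correspondence
            # needed to orient (and scale) the target-adapt embedding into
            # the source space.
            mu, sd = X_src.mean(axis=0), X_src.std(axis=0, ddof=0)
            sd = np.where(sd == 0, 1.0, sd)
            bridge = fit_elastic_net((X_src - mu) / sd, y_src, None, self.elastic_net)
            y_bridge = bridge.predict((X_adapt - mu) / sd)
            y_adapt = procrustes_align(adapt_emb_raw.first, y_bridge, scaling=self.align_scaling)
            adapt_emb = EmbeddingResult(
                adapt_emb_raw.subject_ids, y_adapt[:, None], adapt_emb_raw.eigenvalues[:1]
            )
            model = tradaboost_fit(
                X_src, y_src, X_adapt, y_adapt,
                feature_names=names, en=self.elastic_net, tp=self.transfer,
            )
        else:
            warnings.warn("no target-adaptation data: falling back to a source-only elastic net")
            model = tradaboost_fit(
                np.empty((0, X_src.shape[1])), np.empty(0), X_src, y_src,
                feature_names=names, en=self.elastic_net, tp=self.transfer,
            )
        return ReferenceSpaceResults(
            spec=self,
            adapted_model=model,
            source_network=src_net,
            source_embedding=src_emb,
            adapt_embedding=adapt_emb,
        )


@dataclass
class ReferenceSpaceResults:
    """Fitted reference space: the frozen transfer ensemble plus the source
    fusion artefacts it was trained on."""

    spec: ReferenceSpaceModel
    adapted_model: DomainAdaptedModel
    source_network: FusedNetwork
    source_embedding: EmbeddingResult
    adapt_embedding: EmbeddingResult | None = None
    evaluations: dict = field(default_factory=dict)

    def predict(self, modalities: list[ModalityMatrix]) -> pd.DataFrame:
        """Predicted first-embedding score per subject."""
        X, names, ids = concat_features(modalities)
        yhat = tradaboost_predict(self.adapted_model, X, feature_names=names)
        return pd.DataFrame({"subject_id": ids, "embedding_pred": yhat})

    def evaluate(
        self, test_modalities: list[ModalityMatrix], label: str = "test"
    ) -> EmbeddingComparison:
        """Predict held-out subjects and compare with the 'ground truth'
        first embedding obtained by fusing and embedding the held-out data
        themselves, after Procrustes alignment."""
        pred = self.predict(test_modalities)["embedding_pred"].to_numpy()
        _, truth_emb = fuse_and_embed(test_modalities, self.spec.snf, self.spec.embed)
        aligned = procrustes_align(pred, truth_emb.first, scaling=self.spec.align_scaling)
        cmp = compare_embeddings(aligned, truth_emb.first)
        self.evaluations[label] = cmp
        return cmp

    def summary(self) -> str:
        lines = [
            "Reference-space transfer model",
            "=" * 46,
            f"source subjects:        {self.source_network.n_subjects}",
            f"feature columns:        {len(self.adapted_model.feature_names)}",
            f"embedding components:   {self.source_embedding.scores.shape[1]}",
            f"leading eigenvalues:    "
            + ", ".join(f"{v:.3f}" for v in self.source_embedding.eigenvalues[:3]),
            f"SNF K={self.spec.snf.K}, mu={self.spec.snf.mu}, T={self.spec.snf.T}; "
            f"diffusion t={self.spec.embed.t}, alpha={self.spec.embed.alpha}",
            f"boosting rounds kept:   {len(self.adapted_model.estimators)}",
            f"adapted:                {self.adapt_embedding is not None}",
        ]
        for label, cmp in self.evaluations.items():
            lines.append(
                f"[{label}] RMSE={cmp.rmse:.3f} MAE={cmp.mae:.3f} "
                f"R2={cmp.r2:.3f} r={cmp.pearson_r:.3f}"
            )
        return "\n".join(lines)
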