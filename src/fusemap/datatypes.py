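"""Core containers shared across the fusion / embedding / transfer pipeline.

Subject tables are plain pandas objects at the I/O boundary; internally the
pipeline passes these light wrappers so that subject ordering and identity
travel with every matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ModalityMatrix",
    "AffinityMatrix",
    "FusedNetwork",
    "EmbeddingResult",
    "EmbeddingComparison",
]


def _check_ids(subject_ids) -> list[str]:
    ids = [str(s) for s in subject_ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ValueError(f"duplicate subject ids: {dupes}")
    return ids


@dataclass
class ModalityMatrix:
    """One modality's subjects x features values (e.g. 34 bilaterally
    averaged Desikan-Killiany regional volumes)."""

    subject_ids: list[str]
    values: np.ndarray
    modality: str = "modality"
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.subject_ids = _check_ids(self.subject_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D subjects x features matrix")
        if self.values.shape[0] != len(self.subject_ids):
            raise ValueError("row count does not match number of subject ids")
        if not np.all(np.isfinite(self.values)):
            bad = np.where(~np.isfinite(self.values).all(axis=1))[0]
            names = [self.subject_ids[i] for i in bad[:5]]
            raise ValueError(f"non-finite values for subjects {names}")
        if self.feature_names is None:
            p = self.values.shape[1]
            self.feature_names = [f"{self.modality}_{j + 1:02d}" for j in range(p)]
        elif len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length does not match columns")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "subject_id", self.subject_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, modality: str = "modality") -> "ModalityMatrix":
        if "subject_id" not in df.columns:
            raise ValueError("feature table must contain a 'subject_id' column")
        feats = [c for c in df.columns if c != "subject_id"]
        if not feats:
            raise ValueError("feature table has no feature columns")
        vals = df[feats].to_numpy(dtype=float)
        return cls(
            subject_ids=list(df["subject_id"].astype(str)),
            values=vals,
            modality=modality,
            feature_names=feats,
        )

    def subset(self, idx) -> "ModalityMatrix":
        ids = [self.subject_ids[i] for i in idx]
        return ModalityMatrix(ids, self.values[idx], self.modality, list(self.feature_names))


def _square_checks(subject_ids, M, sym_tol=1e-10):
    M = np.asarray(M, dtype=float)
    n = len(subject_ids)
    if M.shape != (n, n):
        raise ValueError("matrix shape does not match number of subject ids")
    if np.max(np.abs(M - M.T)) > sym_tol:
        raise ValueError("matrix is not symmetric within tolerance")
    if np.min(M) < 0:
        raise ValueError("matrix has negative entries")
    return M


@dataclass
class AffinityMatrix:
    """Nonnegative symmetric subject x subject similarity from the scaled
    exponential kernel."""

    subject_ids: list[str]
    W: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = _check_ids(self.subject_ids)
        self.W = _square_checks(self.subject_ids, self.W)

    @property
    def n_subjects(self) -> int:
        return self.W.shape[0]


@dataclass
class FusedNetwork:
    """Symmetric nonnegative similarity network after cross-modal fusion."""

    subject_ids: list[str]
    S_fused: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = _check_ids(self.subject_ids)
        self.S_fused = _square_checks(self.subject_ids, self.S_fused)
        if np.any(self.S_fused.sum(axis=1) == 0):
            raise ValueError("fused network has an all-zero row")

    @property
    def n_subjects(self) -> int:
        return self.S_fused.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.S_fused, index=self.subject_ids, columns=self.subject_ids)


@dataclass
class EmbeddingResult:
    """Diffusion-map scores; column 0 is the first brain embedding."""

    subject_ids: list[str]
    scores: np.ndarray
    eigenvalues: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = _check_ids(self.subject_ids)
        self.scores = np.asarray(self.scores, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.scores.shape[0] != len(self.subject_ids):
            raise ValueError("score rows do not match subject ids")
        if self.scores.shape[1] != self.eigenvalues.shape[0]:
            raise ValueError("one eigenvalue per component required")

    @property
    def first(self) -> np.ndarray:
        return self.scores[:, 0]

    def to_frame(self) -> pd.DataFrame:
        k = self.scores.shape[1]
        df = pd.DataFrame(self.scores, columns=[f"embedding_{i + 1}" for i in range(k)])
        df.insert(0, "subject_id", self.subject_ids)
        return df


@dataclass
class EmbeddingComparison:
    rmse: float
    mae: float
    r2: float
    pearson_r: float

    def as_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "mae": self.mae,
            "r2": self.r2,
            "pearson_r": self.pearson_r,
        }
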