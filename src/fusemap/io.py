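"""Tabular readers/writers for feature tables, networks and scores."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import EmbeddingResult, FusedNetwork, ModalityMatrix

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "write_network",
    "read_network",
    "write_scores",
    "read_scores",
]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_feature_table(path, modality: str | None = None) -> ModalityMatrix:
    """Read a wide subject x feature CSV/TSV (column `subject_id` + numeric
    feature columns). Duplicate ids, non-numeric cells and empty tables are
    rejected with specific errors."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.empty:
        raise ValueError(f"{path}: empty feature table")
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: missing 'subject_id' column")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"{path}: duplicate subject ids {dupes[:5]}")
    feats = [c for c in df.columns if c != "subject_id"]
    bad = [c for c in feats if not np.issubdtype(df[c].dtype, np.number)]
    if bad:
        raise ValueError(f"{path}: non-numeric feature columns {bad[:5]}")
    if df[feats].isna().any().any():
        raise ValueError(f"{path}: missing values in feature columns")
    return ModalityMatrix.from_frame(df, modality=modality or path.stem)


def write_feature_table(mod: ModalityMatrix, path) -> None:
    path = Path(path)
    mod.to_frame().to_csv(path, sep=_sep_for(path), index=False)


def write_network(net: FusedNetwork, path) -> None:
    net.to_frame().to_csv(path)


def read_network(path) -> FusedNetwork:
    df = pd.read_csv(path, index_col=0)
    return FusedNetwork(subject_ids=list(df.index.astype(str)), S_fused=df.to_numpy(float))


def write_scores(emb: EmbeddingResult, path) -> None:
    path = Path(path)
    emb.to_frame().to_csv(path, index=False)
    side = pd.DataFrame(
        {"component": np.arange(1, len(emb.eigenvalues) + 1), "eigenvalue": emb.eigenvalues}
    )
    side.to_csv(path.with_suffix(".eigenvalues.csv"), index=False)


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path)
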