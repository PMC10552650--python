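"""Tissue-identity embedding of expression profiles.

Tissue-specific expression signatures are conserved across related species,
so a degraded library of unknown or uncertain origin can be placed by
embedding a reference tissue atlas from extant species and projecting the
query onto it.  The workflow is:

1. normalize counts to CPM against the total of genome-wide mapped
   deduplicated reads (not the feature-set sum);
2. restrict all species to one-to-one shared homologous features;
3. log2(x + 1) for mRNA profiles (miRNA profiles stay on the CPM scale);
4. fit a 2-D UMAP embedding on the reference atlas only
   (n_neighbors=5, metric="correlation" i.e. Pearson distance 1 - r,
   spread=10, random_state=30) and project queries onto it;
5. read out tissue identity as the tissue of the nearest reference sample
   in embedding space (top-3 neighbors reported).

Matrices are pandas DataFrames with features as rows and samples as
columns; sample metadata carries ``species`` and ``tissue`` columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd


def cpm_transform(matrix: pd.DataFrame, library_sizes: Mapping[str, float] | pd.Series) -> pd.DataFrame:
    """Counts-per-million against externally supplied library sizes.

    The denominator is the total number of genome-wide mapped deduplicated
    reads per sample, so columns only sum to 1e6 when the features happen to
    cover the whole library.
    """
    sizes = pd.Series(library_sizes, dtype=float).reindex(matrix.columns)
    if sizes.isna().any():
        missing = list(matrix.columns[sizes.isna()])
        raise ValueError(f"missing library sizes for samples: {missing}")
    if (sizes <= 0).any():
        raise ValueError("library sizes must be > 0")
    return matrix * 1e6 / sizes


def log2_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2(x + 1); monotone, so within-sample rankings are preserved."""
    return np.log2(matrix + 1.0)


def select_shared_features(
    matrices: Mapping[str, pd.DataFrame],
    homolog_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Restrict per-species matrices to shared homologs and join samples.

    ``homolog_map`` has columns (species, feature_id, homolog_id); homolog
    groups kept are those mapped one-to-one in every species.  When it is
    None, feature ids are treated as directly comparable and the row-index
    intersection is used.  Rows are returned in sorted canonical order.
    """
    if homolog_map is None:
        common: set[str] | None = None
        for df in matrices.values():
            ids = set(df.index)
            common = ids if common is None else common & ids
        if not common:
            raise ValueError("no shared features across species")
        rows = sorted(common)
        return pd.concat([df.loc[rows] for df in matrices.values()], axis=1)

    keep: set[str] | None = None
    per_species: dict[str, dict[str, str]] = {}
    for species in matrices:
        sub = homolog_map[homolog_map["species"] == species]
        dup = sub["homolog_id"].duplicated(keep=False)
        if dup.any():
            warnings.warn(
                f"{species}: dropped {sub.loc[dup, 'homolog_id'].nunique()} "
                "one-to-many homolog groups"
            )
            sub = sub[~dup]
        mapping = dict(zip(sub["homolog_id"], sub["feature_id"]))
        mapping = {
            h: f for h, f in mapping.items() if f in matrices[species].index
        }
        per_species[species] = mapping
        ids = set(mapping)
        keep = ids if keep is None else keep & ids
    if not keep:
        raise ValueError("no shared homologous features across species")
    rows = sorted(keep)
    parts = []
    for species, df in matrices.items():
        feats = [per_species[species][h] for h in rows]
        part = df.loc[feats]
        part.index = rows
        parts.append(part)
    return pd.concat(parts, axis=1)


@dataclass
class EmbeddingModel:
    reducer: object  # fitted umap.UMAP
    coordinates: pd.DataFrame  # samples x (umap1, umap2)
    metadata: pd.DataFrame  # samples x (species, tissue)
    features: pd.Index

    @property
    def tissues(self) -> pd.Series:
        return self.metadata["tissue"]


def fit_embedding(
    reference_matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    n_neighbors: int = 5,
    metric: str = "correlation",
    spread: float = 10.0,
    random_state: int = 30,
    min_dist: float = 0.1,
) -> EmbeddingModel:
    """Fit a 2-D UMAP on the reference atlas (samples = matrix columns).

    The Pearson metric is correlation distance 1 - r.  Query samples must
    never be part of the fit; use :func:`project` for them.
    """
    import umap

    n_samples = reference_matrix.shape[1]
    if n_samples < n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors+1={n_neighbors + 1} reference samples, got {n_samples}"
        )
    missing = [s for s in reference_matrix.columns if s not in metadata.index]
    if missing:
        raise ValueError(f"metadata missing for samples: {missing}")
    reducer = umap.UMAP(
        n_neighbors=n_neighbors,
        metric=metric,
        spread=spread,
        min_dist=min_dist,
        random_state=random_state,
        n_components=2,
    )
    coords = reducer.fit_transform(reference_matrix.T.to_numpy(dtype=float))
    coordinates = pd.DataFrame(
        coords, index=reference_matrix.columns, columns=["umap1", "umap2"]
    )
    return EmbeddingModel(
        reducer=reducer,
        coordinates=coordinates,
        metadata=metadata.loc[reference_matrix.columns],
        features=reference_matrix.index,
    )


def project(model: EmbeddingModel, query_matrix: pd.DataFrame, top_k: int = 3) -> pd.DataFrame:
    """Project query samples and label them by nearest reference tissue.

    Returns one row per query sample: umap coordinates, the tissue of the
    nearest reference sample (Euclidean distance in embedding space), and
    the ``top_k`` nearest reference samples.
    """
    missing = [f for f in model.features if f not in query_matrix.index]
    if missing:
        raise ValueError(
            f"query lacks {len(missing)} reference features, e.g. {missing[:5]}"
        )
    aligned = query_matrix.loc[model.features]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns on small transforms
        coords = model.reducer.transform(aligned.T.to_numpy(dtype=float))
    ref = model.coordinates.to_numpy()
    rows = []
    for sample, (x, y) in zip(aligned.columns, coords):
        d = np.sqrt(((ref - [x, y]) ** 2).sum(axis=1))
        order = np.argsort(d, kind="stable")
        nearest = [model.coordinates.index[i] for i in order[:top_k]]
        rows.append(
            {
                "sample": sample,
                "umap1": float(x),
                "umap2": float(y),
                "tissue": model.tissues.loc[nearest[0]],
                "neighbors": nearest,
            }
        )
    return pd.DataFrame(rows).set_index("sample")


__all__ = [
    "cpm_transform",
    "log2_transform",
    "select_shared_features",
    "EmbeddingModel",
    "fit_embedding",
    "project",
]
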