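"""Gene-set signature scores, distance-from-normal grading, embeddings and
cross-modality integration with RNA-seq.

The prognostic signature is the mean gene-span RNAPII signal over the 64
replication-dependent histone genes (the ribosomal-protein set is carried
as a comparator). Sample-level structure is summarized by UMAP embeddings
of log-transformed feature matrices, by Euclidean distance from the normal
centroid, and by a ridge-regularized canonical correlation analysis that
places CUTAC and RNA-seq samples in a shared space for nearest-neighbor
label transfer (treating the shared genes as observations, as is standard
when the two modalities profile different samples).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.stats import spearmanr

from .coverage import SignalMatrix

LOG_EPS = 1e-3


@dataclass
class EmbeddingResult:
    feature_kind: str
    coords: pd.DataFrame          # index: sample ids; columns: UMAP1, UMAP2
    seed: int
    neighbor_graph: object        # sparse fuzzy simplicial set from UMAP


@dataclass
class IntegrationMap:
    cutac_coords: pd.DataFrame
    rnaseq_coords: pd.DataFrame
    neighbors: pd.DataFrame       # cutac_sample, rank, rnaseq_sample, distance
    transferred: pd.DataFrame     # per CUTAC sample: neighbor-averaged labels
    canonical_correlations: np.ndarray


def signature_score(matrix: SignalMatrix, set_name: str,
                    gene_sets: dict[str, list[str]]) -> pd.DataFrame:
    """Per-sample mean gene-span signal over a gene set.

    Returns a frame (sample, set, score) with the per-gene sub-matrix in
    ``attrs['per_gene']``.
    """
    if matrix.interval_kind != "gene_span":
        raise ValueError("signature_score requires a gene_span matrix")
    members = gene_sets[set_name]
    missing = [g for g in members if g not in matrix.values.columns]
    if missing:
        raise KeyError(f"genes missing from matrix: {missing[:5]}")
    sub = matrix.values[members]
    out = pd.DataFrame({"sample": sub.index, "set": set_name,
                        "score": sub.mean(axis=1).to_numpy()})
    out.attrs["per_gene"] = sub
    return out


def distance_from_normal(matrix: SignalMatrix, normal_ids: list[str],
                         query_ids: list[str],
                         transform: str = "log10") -> pd.DataFrame:
    """Euclidean distance of each query sample from the normal centroid.

    Features are log10(x + eps)-transformed by default (identity with
    ``transform=None``); distances are ranked descending (rank 1 = farthest
    from normal).
    """
    if len(normal_ids) < 2:
        raise ValueError("need at least two normal samples")
    X = matrix.values
    if X.shape[1] == 0:
        raise ValueError("empty feature set")
    vals = X.to_numpy(float)
    if transform == "log10":
        vals = np.log10(vals + LOG_EPS)
    elif transform is not None:
        raise ValueError("transform must be 'log10' or None")
    frame = pd.DataFrame(vals, index=X.index, columns=X.columns)
    centroid = frame.loc[normal_ids].mean(axis=0).to_numpy()
    dists = np.linalg.norm(frame.loc[query_ids].to_numpy() - centroid, axis=1)
    out = pd.DataFrame({"sample": query_ids, "distance": dists})
    out["rank"] = out["distance"].rank(ascending=False,
                                       method="first").astype(int)
    return out


def grade_correlation(distances: np.ndarray,
                      grades: np.ndarray) -> tuple[float, float]:
    """Spearman correlation of distance-from-normal with (ordinal) grade."""
    distances = np.asarray(distances, float)
    grades = np.asarray(grades, float)
    if distances.size != grades.size or distances.size < 5:
        raise ValueError("need >= 5 paired observations")
    if np.unique(distances).size == 1 or np.unique(grades).size == 1:
        warnings.warn("constant input; correlation undefined")
        return float("nan"), float("nan")
    r, p = spearmanr(distances, grades)
    return float(r), float(p)


def embed(matrix: SignalMatrix, feature_kind: str, seed: int,
          n_neighbors: int = 15, top_features: int = 5_000) -> EmbeddingResult:
    """2-D UMAP of log-transformed features, deterministic given seed.

    For bin/cCRE matrices only the ``top_features`` highest-variance
    features are used; gene-set matrices use all features.
    """
    import umap  # deferred: numba compilation is expensive at import

    X = np.log10(matrix.values.to_numpy(float) + LOG_EPS)
    n_samples = X.shape[0]
    if n_samples < 3:
        raise ValueError("need at least 3 samples to embed")
    if feature_kind in ("bin500", "bin1000", "ccre") and X.shape[1] > top_features:
        keep = np.argsort(X.var(axis=0))[::-1][:top_features]
        X = X[:, np.sort(keep)]
    if n_neighbors >= n_samples:
        warnings.warn(f"n_neighbors reduced to {n_samples - 1}")
        n_neighbors = n_samples - 1
    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                        random_state=seed)
    coords = reducer.fit_transform(X)
    frame = pd.DataFrame(coords, index=matrix.values.index,
                         columns=["UMAP1", "UMAP2"])
    return EmbeddingResult(feature_kind=feature_kind, coords=frame,
                           seed=seed, neighbor_graph=reducer.graph_)


def _standardize_genes(frame: pd.DataFrame) -> np.ndarray:
    """log-transform then z-score each gene (column) across samples."""
    X = np.log10(frame.to_numpy(float) + LOG_EPS)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def integrate_cca(cutac_matrix: SignalMatrix, rnaseq: pd.DataFrame,
                  n_components: int = 10, k: int = 20,
                  ridge: float = 1e-3) -> IntegrationMap:
    """Ridge-regularized CCA between CUTAC gene-span signal and RNA-seq.

    ``rnaseq`` is a genes x samples count table. Shared genes are
    intersected; each modality is log-transformed and gene-standardized.
    Treating genes as observations and samples as variables, canonical
    sample-loading vectors a, b maximize corr(Xa, Yb) under ridge-shrunk
    within-modality covariances; each sample's coordinates in the shared
    space are its loadings on the first ``n_components`` canonical vectors
    (L2-normalized per sample). For every CUTAC sample the k nearest RNA-seq
    samples by Euclidean distance are reported and any numeric metadata
    later joined on them can be neighbor-averaged.
    """
    if cutac_matrix.interval_kind != "gene_span":
        raise ValueError("integration requires a gene_span CUTAC matrix")
    shared = [g for g in cutac_matrix.values.columns if g in rnaseq.index]
    if len(shared) < 2:
        raise ValueError("fewer than 2 shared genes between modalities")
    X = _standardize_genes(cutac_matrix.values[shared])          # n1 x p
    Y = _standardize_genes(rnaseq.loc[shared].T)                 # n2 x p
    n1, n2, p = X.shape[0], Y.shape[0], len(shared)

    Cxx = X @ X.T / p + ridge * np.eye(n1)
    Cyy = Y @ Y.T / p + ridge * np.eye(n2)
    Cxy = X @ Y.T / p
    Wx = scipy.linalg.fractional_matrix_power(Cxx, -0.5).real
    Wy = scipy.linalg.fractional_matrix_power(Cyy, -0.5).real
    U, s, Vt = np.linalg.svd(Wx @ Cxy @ Wy)
    n_components = int(min(n_components, s.size))
    A = Wx @ U[:, :n_components]   # sample loadings, CUTAC
    B = Wy @ Vt.T[:, :n_components]

    def norm_rows(M: np.ndarray) -> np.ndarray:
        nrm = np.linalg.norm(M, axis=1, keepdims=True)
        nrm[nrm == 0] = 1.0
        return M / nrm

    A, B = norm_rows(A), norm_rows(B)
    cutac_ids = list(cutac_matrix.values.index)
    rna_ids = list(rnaseq.columns)
    if k > n2:
        warnings.warn(f"k clipped from {k} to {n2}")
        k = n2

    rows = []
    for i, sid in enumerate(cutac_ids):
        d = np.linalg.norm(B - A[i], axis=1)
        order = np.argsort(d, kind="stable")[:k]
        for rank, j in enumerate(order, start=1):
            rows.append({"cutac_sample": sid, "rank": rank,
                         "rnaseq_sample": rna_ids[j],
                         "distance": float(d[j])})
    neighbors = pd.DataFrame(rows)
    transferred = (neighbors.groupby("cutac_sample", sort=False)
                   .agg(nearest=("rnaseq_sample", "first"),
                        mean_distance=("distance", "mean")).reset_index())
    return IntegrationMap(
        cutac_coords=pd.DataFrame(A, index=cutac_ids),
        rnaseq_coords=pd.DataFrame(B, index=rna_ids),
        neighbors=neighbors, transferred=transferred,
        canonical_correlations=s[:n_components])


def transfer_labels(integration: IntegrationMap, labels: pd.Series,
                    how: str = "mean") -> pd.Series:
    """Neighbor-vote/average a per-RNA-seq-sample label onto CUTAC samples."""
    nb = integration.neighbors
    vals = nb.assign(value=nb["rnaseq_sample"].map(labels))
    grouped = vals.groupby("cutac_sample", sort=False)["value"]
    if how == "mean":
        return grouped.mean()
    if how == "vote":
        return grouped.agg(lambda s: s.mode().iloc[0])
    raise ValueError("how must be 'mean' or 'vote'")
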