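"""Clone partitioning, longitudinal tracking, clustering and embedding.

A *clone* is the set of cells sharing an identical called-genotype vector
over a chosen list of marker variants.  Cells with a NOCALL at any marker
are excluded from the partition denominator and reported separately, so
clone percentages are reproducible over the reliably genotyped cells.

Cell clustering uses a Hamming distance over called genotype states with
pairwise-complete normalization (NOCALL entries are excluded pair by pair),
followed by agglomerative linkage — the construction used to separate cell
populations of donor vs recipient origin by germline-marker zygosity.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.decomposition import PCA

from .containers import (
    NOCALL,
    ClonePartition,
    GenotypeMatrix,
    TimepointSeries,
    clone_key,
)


class CloneAssigner(BaseEstimator):
    """Partition cells into genotype-vector clones over marker variants.

    After ``fit``, ``partition_`` holds the :class:`ClonePartition`; clones
    are enumerated in descending cell count (ties broken by clone key).
    """

    def __init__(self, marker_variants: Optional[Sequence[str]] = None):
        self.marker_variants = marker_variants

    def fit(self, X: GenotypeMatrix, y=None) -> "CloneAssigner":
        markers = list(self.marker_variants or [])
        if not markers:
            raise ValueError("marker_variants must be a non-empty list")
        missing = [m for m in markers if m not in X.states.columns]
        if missing:
            raise ValueError(f"marker variants absent from genotype matrix: {missing}")
        dropped = [m for m in markers if not bool(X.retained[m])]
        if dropped:
            raise ValueError(f"marker variants failed variant QC: {dropped}")

        sub = X.states[markers]
        complete = (sub != NOCALL).all(axis=1)
        assigned = sub.loc[complete]
        keys = pd.Series(
            [clone_key(row) for row in assigned.to_numpy()],
            index=assigned.index,
            name="clone_key",
        )
        counts = keys.value_counts()
        table = pd.DataFrame({"count": counts})
        table["fraction"] = (
            table["count"] / table["count"].sum() if len(table) else np.nan
        )
        table["label"] = ""
        table = table.sort_values(
            by=["count"], ascending=False, kind="mergesort"
        )  # value_counts pre-sorts ties by first occurrence; mergesort keeps it stable
        table = (
            table.reset_index()
            .sort_values(["count", "clone_key"], ascending=[False, True], kind="mergesort")
            .set_index("clone_key")
        )
        self.partition_ = ClonePartition(
            marker_variants=markers,
            table=table,
            assignments=keys,
            unassigned=int((~complete).sum()),
        )
        return self

    def predict(self, X: GenotypeMatrix) -> pd.Series:
        """Clone key per cell (NaN where any marker is NOCALL)."""
        markers = self.partition_.marker_variants
        sub = X.states[markers]
        complete = (sub != NOCALL).all(axis=1)
        out = pd.Series(np.nan, index=X.cells, dtype=object, name="clone_key")
        out.loc[complete] = [clone_key(row) for row in sub.loc[complete].to_numpy()]
        return out


def assign_clones(
    genotypes: GenotypeMatrix, marker_variants: Sequence[str]
) -> ClonePartition:
    """Assign cells to genotype-defined clones; wrapper over CloneAssigner."""
    return CloneAssigner(marker_variants=list(marker_variants)).fit(genotypes).partition_


def track_clones(
    partitions: Sequence[tuple[str, ClonePartition]]
) -> TimepointSeries:
    """Match clones across timepoints by genotype vector.

    Every genotype key present in any partition appears exactly once in the
    series, with fraction 0 where absent.  Clones absent at the first
    timepoint but present later are flagged emergent.
    """
    if not partitions:
        raise ValueError("at least one timepoint required")
    labels = [tp for tp, _ in partitions]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate timepoint labels")
    markers0 = partitions[0][1].marker_variants
    for tp, part in partitions[1:]:
        if part.marker_variants != markers0:
            raise ValueError(
                f"timepoint {tp!r} uses different marker variants than {labels[0]!r}"
            )
    frac = pd.DataFrame(
        {tp: part.table["fraction"] for tp, part in partitions}
    ).fillna(0.0)
    frac.index.name = "clone_key"
    # stable order: descending fraction at the first timepoint, then key
    frac = frac.sort_values(
        by=[labels[0]], ascending=False, kind="mergesort"
    )
    frac = frac.loc[
        sorted(frac.index, key=lambda k: (-frac.loc[k, labels[0]], k))
    ]
    emergent = (frac[labels[0]] == 0.0) & (frac[labels[1:]].sum(axis=1) > 0.0) if len(
        labels
    ) > 1 else pd.Series(False, index=frac.index)
    return TimepointSeries(timepoints=labels, fractions=frac, emergent=emergent)


def genotype_distance_matrix(
    states: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Hamming distance over called states, pairwise-complete.

    Returns (distance matrix, boolean mask of cells with >= 1 call).  Pairs
    of cells with no mutually called variant get the maximal distance 1.
    """
    valid = states != NOCALL
    has_call = valid.any(axis=1)
    X = states[has_call]
    M = valid[has_call].astype(np.float64)
    agree = np.zeros((X.shape[0], X.shape[0]))
    for s in np.unique(X[X != NOCALL]):
        A = ((X == s) & (M > 0)).astype(np.float64)
        agree += A @ A.T
    pairs = M @ M.T
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(pairs > 0, (pairs - agree) / np.maximum(pairs, 1.0), 1.0)
    np.fill_diagonal(D, 0.0)
    # numerical guard: symmetrize and clip
    D = np.clip((D + D.T) / 2.0, 0.0, 1.0)
    return D, has_call


class HammingClusterer(BaseEstimator, ClusterMixin):
    """Agglomerative clustering of cells on pairwise-complete Hamming distance.

    ``fit`` computes ``linkage_`` (scipy linkage matrix over included cells),
    ``labels_`` (flat clusters at ``n_clusters``) and ``included_cells_``.
    Cells with no called genotype at any retained variant are excluded with
    a warning.  Deterministic for a fixed input order.
    """

    def __init__(self, n_clusters: int = 2, linkage: str = "average", distance: str = "hamming"):
        self.n_clusters = n_clusters
        self.linkage = linkage
        self.distance = distance

    def fit(self, X: GenotypeMatrix, y=None) -> "HammingClusterer":
        if self.distance != "hamming":
            raise ValueError("only the pairwise-complete 'hamming' distance is supported")
        variants = X.retained_ids()
        if not variants:
            raise ValueError("no retained variants to cluster on")
        states = X.states[variants].to_numpy()
        if states.shape[0] < 2:
            raise ValueError("clustering requires at least 2 cells")
        D, has_call = genotype_distance_matrix(states)
        if not has_call.all():
            warnings.warn(
                f"excluded {int((~has_call).sum())} all-NOCALL cell(s) from clustering"
            )
        self.included_cells_ = X.cells[has_call]
        self.distance_matrix_ = D
        self.linkage_ = scipy_linkage(squareform(D, checks=False), method=self.linkage)
        self.labels_ = fcluster(self.linkage_, t=self.n_clusters, criterion="maxclust")
        return self

    def fit_predict(self, X: GenotypeMatrix, y=None) -> pd.Series:
        self.fit(X)
        return pd.Series(self.labels_, index=self.included_cells_, name="cluster")


def cluster_cells(
    genotypes: GenotypeMatrix,
    n_clusters: int = 2,
    linkage: str = "average",
    distance: str = "hamming",
) -> tuple[np.ndarray, pd.Series]:
    """Hierarchical tree + flat labels; wrapper over :class:`HammingClusterer`."""
    est = HammingClusterer(n_clusters=n_clusters, linkage=linkage, distance=distance)
    labels = est.fit_predict(genotypes)
    return est.linkage_, labels


class GenotypeEmbedder(BaseEstimator, TransformerMixin):
    """PCA-then-UMAP 2-D embedding of the genotype matrix (a reporting aid).

    Genotype states are encoded numerically (WT=0, HET=1, HOM=2) with NOCALL
    imputed to the variant mean over called cells; PCA reduces to
    ``n_components`` (default 5) and UMAP maps to 2-D.  Deterministic given
    ``random_state``.  Zero-variance input yields all-zero coordinates with
    a warning.
    """

    def __init__(self, n_components: int = 5, random_state: int = 0):
        self.n_components = n_components
        self.random_state = random_state

    def fit_transform(self, X: GenotypeMatrix, y=None) -> pd.DataFrame:
        variants = X.retained_ids()
        if not variants:
            raise ValueError("no retained variants to embed")
        if X.states.shape[0] < 3:
            raise ValueError("embedding requires at least 3 cells")
        states = X.states[variants].to_numpy(dtype=np.float64)
        states[states == NOCALL] = np.nan
        col_mean = np.nanmean(
            np.where(np.isnan(states), np.nan, states), axis=0
        )
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        filled = np.where(np.isnan(states), col_mean[None, :], states)

        if np.allclose(filled.std(axis=0), 0.0):
            warnings.warn("zero-variance genotype matrix; returning zero embedding")
            coords = np.zeros((filled.shape[0], 2))
        else:
            k = min(self.n_components, filled.shape[1], filled.shape[0] - 1)
            reduced = PCA(n_components=k, random_state=self.random_state).fit_transform(
                filled
            )
            import umap  # deferred: numba compilation is expensive at import

            n_neighbors = min(15, filled.shape[0] - 1)
            coords = umap.UMAP(
                n_components=2,
                n_neighbors=n_neighbors,
                random_state=self.random_state,
            ).fit_transform(reduced)
        self.embedding_ = pd.DataFrame(
            np.asarray(coords, dtype=np.float64),
            index=X.cells,
            columns=["umap1", "umap2"],
        )
        return self.embedding_

    def fit(self, X: GenotypeMatrix, y=None) -> "GenotypeEmbedder":
        self.fit_transform(X)
        return self


def embed_cells(
    genotypes: GenotypeMatrix, n_components: int = 5, seed: int = 0
) -> pd.DataFrame:
    """2-D cell embedding; wrapper over :class:`GenotypeEmbedder`."""
    return GenotypeEmbedder(n_components=n_components, random_state=seed).fit_transform(
        genotypes
    )
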