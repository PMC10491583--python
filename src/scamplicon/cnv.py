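"""Read-depth normalization and relative-ploidy (CNV) estimation.

Per-amplicon read depth in targeted single-cell panels carries two large
systematic factors: per-cell library size and per-amplicon capture
efficiency.  Both are removed by a two-factor normalization (each cell's
counts divided by that cell's total, then each amplicon divided by its
median over a reference cell set).  Ploidy of a cell group is then
estimated per amplicon relative to a reference group assumed diploid —
in the transplant setting, donor cells:

    ploidy(g, amplicon) = 2 * mean_norm(g, amplicon) / mean_norm(ref, amplicon)

Gene-level ploidy is the unweighted mean over the gene's amplicons, and a
copy loss (e.g. monosomy 7 seen at BRAF/EZH2 amplicons) is flagged when it
falls below ``loss_threshold`` (default 1.5, the midpoint of 1 and 2).
Only depth-based copy loss is reported; allele-ratio LOH is out of scope.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import AlleleCountMatrix, PloidyProfile


class DepthNormalizer(BaseEstimator, TransformerMixin):
    """Two-factor depth normalization: library size, then amplicon efficiency.

    ``fit`` learns per-amplicon median factors from the reference cells
    (default: all cells of the fitted matrix); amplicons with zero reference
    median are masked (NaN) with a warning.
    """

    def __init__(self, reference_cells: Optional[Sequence[str]] = None):
        self.reference_cells = reference_cells

    @staticmethod
    def _library_normalize(depth: pd.DataFrame) -> pd.DataFrame:
        totals = depth.sum(axis=1)
        zero = totals == 0
        if zero.any():
            warnings.warn(f"{int(zero.sum())} cell(s) with zero total depth")
        return depth.div(totals.replace(0, np.nan), axis=0)

    def fit(self, X: AlleleCountMatrix, y=None) -> "DepthNormalizer":
        depth = X.depth()
        if depth.shape[0] < 2 or depth.shape[1] < 2:
            raise ValueError("normalization requires >= 2 cells and >= 2 amplicons")
        lib = self._library_normalize(depth)
        ref = lib if self.reference_cells is None else lib.loc[list(self.reference_cells)]
        med = ref.median(axis=0)
        dead = med == 0
        if dead.any():
            warnings.warn(
                f"masking {int(dead.sum())} amplicon(s) with zero reference median: "
                f"{list(med.index[dead])}"
            )
        self.amplicon_factor_ = med.replace(0, np.nan)
        return self

    def transform(self, X: AlleleCountMatrix) -> pd.DataFrame:
        lib = self._library_normalize(X.depth())
        return lib.div(self.amplicon_factor_, axis=1)


def normalize_counts(
    counts: AlleleCountMatrix, reference_cells: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Normalized per-cell per-amplicon depth; wrapper over DepthNormalizer."""
    return DepthNormalizer(reference_cells=reference_cells).fit_transform(counts)


class PloidyEstimator(BaseEstimator):
    """Per-group relative ploidy against a diploid reference group.

    ``fit`` takes the normalized depth matrix and a per-cell group Series;
    empty groups are skipped with a warning.  The reference group's own
    ploidy is identically 2 by construction.  Fitted attribute:
    ``profile_`` (:class:`PloidyProfile`).
    """

    def __init__(
        self,
        reference_group: str = "donor",
        loss_threshold: float = 1.5,
        manifest: Optional[pd.DataFrame] = None,
    ):
        self.reference_group = reference_group
        self.loss_threshold = loss_threshold
        self.manifest = manifest

    def fit(self, X: pd.DataFrame, groups: pd.Series) -> "PloidyEstimator":
        groups = groups.reindex(X.index)
        names = [g for g in pd.unique(groups.dropna())]
        if self.reference_group not in names:
            raise ValueError(f"reference group {self.reference_group!r} is empty")
        kept = []
        for g in names:
            if (groups == g).sum() == 0:
                warnings.warn(f"skipping empty group {g!r}")
            else:
                kept.append(g)
        # reference first, then the others in input order
        kept = [self.reference_group] + [g for g in kept if g != self.reference_group]

        ref_mean = X.loc[groups == self.reference_group].mean(axis=0)
        rows = {}
        for g in kept:
            grp_mean = X.loc[groups == g].mean(axis=0)
            rows[g] = 2.0 * grp_mean / ref_mean
        amp = pd.DataFrame(rows).T
        amp.index.name = "group"

        if self.manifest is not None:
            genes = self.manifest.loc[amp.columns, "gene"]
            gene_ploidy = amp.T.groupby(genes).mean().T
        else:
            gene_ploidy = amp.copy()
        loss = {
            (g, gene)
            for g in gene_ploidy.index
            for gene in gene_ploidy.columns
            if g != self.reference_group
            and np.isfinite(gene_ploidy.loc[g, gene])
            and gene_ploidy.loc[g, gene] < self.loss_threshold
        }
        self.profile_ = PloidyProfile(
            amplicon_ploidy=amp,
            gene_ploidy=gene_ploidy,
            reference_group=self.reference_group,
            loss_threshold=self.loss_threshold,
            loss_calls=loss,
        )
        return self


def estimate_ploidy(
    normalized: pd.DataFrame,
    groups: pd.Series,
    reference_group: str,
    manifest: Optional[pd.DataFrame] = None,
    loss_threshold: float = 1.5,
) -> PloidyProfile:
    """Relative ploidy per (group, amplicon/gene); wrapper over PloidyEstimator."""
    est = PloidyEstimator(
        reference_group=reference_group,
        loss_threshold=loss_threshold,
        manifest=manifest,
    ).fit(normalized, groups)
    return est.profile_
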