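"""Per-cell genotype calling from allele counts with VAF-band thresholds.

A call at one (cell, variant) follows amplicon-platform convention: with
read depth d = ref + alt and VAF = alt/d,

* d < ``min_depth``                        -> NOCALL
* VAF*100 <  ``vaf_wt``                    -> WT
* ``vaf_wt``  <= VAF*100 < ``vaf_het``     -> NOCALL (ambiguous band)
* ``vaf_het`` <= VAF*100 < ``vaf_hom``     -> HET
* VAF*100 >= ``vaf_hom``                   -> HOM

and any call whose genotype quality falls below ``min_gq`` is demoted to
NOCALL.  Genotype quality is phred-scaled: 10 * (log10 L_best - log10
L_second) for binomial read likelihoods with expected alt fractions
(eps, 0.5, 1 - eps) for WT/HET/HOM, eps = 0.01.  Quality is therefore
monotone in depth and independent of which VAF band the call landed in.

Variant-level QC masks out variants genotyped in fewer than
``min_genotyped_fraction`` of cells (boundary inclusive).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import (
    HET,
    HOM,
    NOCALL,
    WT,
    AlleleCountMatrix,
    GenotypeMatrix,
)

PHRED = 10.0 / np.log(10.0)


def genotype_quality(
    alt: np.ndarray, depth: np.ndarray, hom_error: float = 0.01
) -> np.ndarray:
    """Phred-scaled gap between best and second-best genotype likelihood.

    Likelihoods are binomial in the alt-read count with expected alt
    fractions ``hom_error`` (WT), 0.5 (HET) and ``1 - hom_error`` (HOM).
    At depth 0 all three likelihoods coincide and the quality is 0.
    """
    alt = np.asarray(alt)
    depth = np.asarray(depth)
    ll = np.stack(
        [
            stats.binom.logpmf(alt, depth, p)
            for p in (hom_error, 0.5, 1.0 - hom_error)
        ],
        axis=-1,
    )
    ll_sorted = np.sort(ll, axis=-1)
    return PHRED * (ll_sorted[..., -1] - ll_sorted[..., -2])


class GenotypeCaller(BaseEstimator, TransformerMixin):
    """Stateless transformer: AlleleCountMatrix -> GenotypeMatrix.

    Parameters
    ----------
    min_depth : int, default 10
        Minimum read depth for a call.
    min_gq : float, default 30
        Minimum phred genotype quality.
    vaf_wt, vaf_het, vaf_hom : float, defaults 5 / 35 / 95
        VAF thresholds in percent; must satisfy 0 <= wt < het < hom <= 100.
    hom_error : float, default 0.01
        Expected alt fraction in a homozygous-ref cell for the quality model.
    """

    def __init__(
        self,
        min_depth: int = 10,
        min_gq: float = 30.0,
        vaf_wt: float = 5.0,
        vaf_het: float = 35.0,
        vaf_hom: float = 95.0,
        hom_error: float = 0.01,
    ):
        self.min_depth = min_depth
        self.min_gq = min_gq
        self.vaf_wt = vaf_wt
        self.vaf_het = vaf_het
        self.vaf_hom = vaf_hom
        self.hom_error = hom_error

    def _validate_params(self) -> None:
        if self.min_depth < 0 or self.min_gq < 0:
            raise ValueError("min_depth and min_gq must be non-negative")
        if not (0.0 <= self.vaf_wt < self.vaf_het < self.vaf_hom <= 100.0):
            raise ValueError(
                "VAF thresholds must satisfy 0 <= vaf_wt < vaf_het <= vaf_hom <= 100"
            )
        if not (0.0 < self.hom_error < 0.5):
            raise ValueError("hom_error must lie in (0, 0.5)")

    def fit(self, X: AlleleCountMatrix, y=None) -> "GenotypeCaller":
        self._validate_params()
        self.n_cells_ = X.n_cells
        self.n_variants_ = len(X.variant_ids)
        return self

    def transform(self, X: AlleleCountMatrix) -> GenotypeMatrix:
        self._validate_params()
        ref = X.ref.to_numpy(dtype=np.int64)
        alt = X.alt.to_numpy(dtype=np.int64)
        depth = ref + alt

        with np.errstate(invalid="ignore", divide="ignore"):
            vaf = np.where(depth > 0, alt / np.maximum(depth, 1), np.nan)
        gq = genotype_quality(alt, depth, self.hom_error)

        vaf_pct = vaf * 100.0
        states = np.full(depth.shape, NOCALL, dtype=np.int8)
        callable_ = depth >= self.min_depth
        with np.errstate(invalid="ignore"):
            states[callable_ & (vaf_pct < self.vaf_wt)] = WT
            states[callable_ & (vaf_pct >= self.vaf_het) & (vaf_pct < self.vaf_hom)] = HET
            states[callable_ & (vaf_pct >= self.vaf_hom)] = HOM
        # 5-35% band stays NOCALL; low-quality calls are demoted
        states[gq < self.min_gq] = NOCALL

        idx, cols = X.cells, X.ref.columns
        states_df = pd.DataFrame(states, index=idx, columns=cols)
        frac = (states_df != NOCALL).mean(axis=0)
        return GenotypeMatrix(
            states=states_df,
            vaf=pd.DataFrame(vaf, index=idx, columns=cols),
            depth=pd.DataFrame(depth, index=idx, columns=cols),
            gq=pd.DataFrame(gq, index=idx, columns=cols),
            manifest=X.manifest,
            genotyped_fraction=frac,
            retained=pd.Series(True, index=cols),
        )


class VariantQC(BaseEstimator, TransformerMixin):
    """Mask variants genotyped in fewer than ``min_genotyped_fraction`` of cells.

    The cell set and call matrices are unchanged; only the ``retained`` mask
    is updated.  The boundary is inclusive: exactly the threshold fraction is
    retained.
    """

    def __init__(self, min_genotyped_fraction: float = 0.5):
        self.min_genotyped_fraction = min_genotyped_fraction

    def fit(self, X: GenotypeMatrix, y=None) -> "VariantQC":
        if not (0.0 <= self.min_genotyped_fraction <= 1.0):
            raise ValueError("min_genotyped_fraction must lie in [0, 1]")
        self.retained_ = X.genotyped_fraction >= self.min_genotyped_fraction
        return self

    def transform(self, X: GenotypeMatrix) -> GenotypeMatrix:
        self.fit(X)
        return GenotypeMatrix(
            states=X.states,
            vaf=X.vaf,
            depth=X.depth,
            gq=X.gq,
            manifest=X.manifest,
            genotyped_fraction=X.genotyped_fraction,
            retained=self.retained_,
        )


def call_genotypes(
    counts: AlleleCountMatrix,
    min_depth: int = 10,
    min_gq: float = 30.0,
    vaf_wt: float = 5.0,
    vaf_het: float = 35.0,
    vaf_hom: float = 95.0,
) -> GenotypeMatrix:
    """Call per-cell genotypes; thin wrapper over :class:`GenotypeCaller`."""
    return GenotypeCaller(
        min_depth=min_depth,
        min_gq=min_gq,
        vaf_wt=vaf_wt,
        vaf_het=vaf_het,
        vaf_hom=vaf_hom,
    ).fit_transform(counts)


def apply_variant_qc(
    matrix: GenotypeMatrix, min_genotyped_fraction: float = 0.5
) -> GenotypeMatrix:
    """Apply the genotyped-cell-fraction variant filter; wrapper over VariantQC."""
    return VariantQC(min_genotyped_fraction=min_genotyped_fraction).fit_transform(matrix)
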