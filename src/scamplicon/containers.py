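"""Core data containers shared across the pipeline.

The pipeline's interchange objects are thin dataclasses around pandas
structures: an :class:`AlleleCountMatrix` of per-cell ref/alt read counts,
a :class:`GenotypeMatrix` of per-cell calls, a :class:`ClonePartition`
mapping cells to genotype-defined clones, and result objects for chimerism
and ploidy analyses.  Cells index rows, variant sites index columns,
throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

# Genotype state codes.  NOCALL is -1 so that {0, 1, 2} count alt-allele copies.
WT: int = 0
HET: int = 1
HOM: int = 2
NOCALL: int = -1

STATE_LABELS: dict[int, str] = {WT: "WT", HET: "HET", HOM: "HOM", NOCALL: "NOCALL"}
LABEL_STATES: dict[str, int] = {v: k for k, v in STATE_LABELS.items()}

VARIANT_ROLES = ("somatic_marker", "germline_marker", "amplicon_only")

_ID_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<pos>\d+):(?P<ref>[ACGTN]+)/(?P<alt>[ACGTN]+)$")


@dataclass(frozen=True)
class VariantSite:
    """A targeted variant site, named ``chr:pos:ref/alt`` (1-based position).

    Parameters
    ----------
    id : str
        Site identifier, e.g. ``"chr12:25398281:C/T"``.
    gene : str
        Gene label used for reporting and gene-level ploidy aggregation.
    role : str
        One of ``somatic_marker`` (tumour-defining mutation),
        ``germline_marker`` (donor/recipient polymorphism) or
        ``amplicon_only`` (read-depth-only target used for CNV).
    """

    id: str
    gene: str
    role: str = "somatic_marker"

    def __post_init__(self) -> None:
        m = _ID_RE.match(self.id)
        if m is None:
            raise ValueError(
                f"malformed variant id {self.id!r}; expected 'chr:pos:ref/alt'"
            )
        if int(m.group("pos")) <= 0:
            raise ValueError(f"variant position must be positive: {self.id!r}")
        if m.group("ref") == m.group("alt"):
            raise ValueError(f"ref and alt alleles identical in {self.id!r}")
        if self.role not in VARIANT_ROLES:
            raise ValueError(f"unknown variant role {self.role!r}")

    @property
    def chrom(self) -> str:
        return self.id.split(":", 2)[0]

    @property
    def pos(self) -> int:
        return int(self.id.split(":", 2)[1])

    @property
    def ref(self) -> str:
        return self.id.split(":", 2)[2].split("/")[0]

    @property
    def alt(self) -> str:
        return self.id.split(":", 2)[2].split("/")[1]


def manifest_frame(sites: Iterable[VariantSite]) -> pd.DataFrame:
    """Build a manifest DataFrame (index: id; columns: gene, role) from sites."""
    rows = list(sites)
    ids = [s.id for s in rows]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate variant ids in manifest")
    return pd.DataFrame(
        {"gene": [s.gene for s in rows], "role": [s.role for s in rows]},
        index=pd.Index(ids, name="id"),
    )


def manifest_sites(manifest: pd.DataFrame) -> list[VariantSite]:
    """Inverse of :func:`manifest_frame`."""
    return [
        VariantSite(id=i, gene=str(r["gene"]), role=str(r["role"]))
        for i, r in manifest.iterrows()
    ]


@dataclass
class AlleleCountMatrix:
    """Per-cell, per-variant ref/alt read counts plus the variant manifest.

    ``ref`` and ``alt`` are integer DataFrames with identical cell index and
    variant-id columns.  Each variant site doubles as its amplicon: the
    per-amplicon total read depth is ``ref + alt``.
    """

    ref: pd.DataFrame
    alt: pd.DataFrame
    manifest: pd.DataFrame

    def __post_init__(self) -> None:
        if self.ref.shape != self.alt.shape:
            raise ValueError("ref and alt count matrices differ in shape")
        if self.ref.shape[0] == 0 or self.ref.shape[1] == 0:
            raise ValueError("empty allele-count matrix")
        if not self.ref.index.equals(self.alt.index) or not self.ref.columns.equals(
            self.alt.columns
        ):
            raise ValueError("ref and alt matrices are not aligned")
        if self.ref.index.has_duplicates:
            raise ValueError("duplicate cell identifiers")
        missing = [v for v in self.manifest.index if v not in self.ref.columns]
        if missing:
            raise ValueError(f"manifest variants absent from count matrix: {missing}")
        extra = [v for v in self.ref.columns if v not in self.manifest.index]
        if extra:
            raise ValueError(f"count-matrix variants absent from manifest: {extra}")
        for name, df in (("ref", self.ref), ("alt", self.alt)):
            arr = df.to_numpy()
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.allclose(arr, np.round(arr)):
                    raise ValueError(f"{name} counts are not integers")
            if (arr < 0).any():
                raise ValueError(f"negative {name} counts")
        # align column order to manifest order
        order = list(self.manifest.index)
        self.ref = self.ref[order].astype(np.int64)
        self.alt = self.alt[order].astype(np.int64)

    @property
    def cells(self) -> pd.Index:
        return self.ref.index

    @property
    def variant_ids(self) -> list[str]:
        return list(self.ref.columns)

    @property
    def n_cells(self) -> int:
        return self.ref.shape[0]

    def depth(self) -> pd.DataFrame:
        """Total read depth per (cell, variant) — the per-amplicon totals."""
        return self.ref + self.alt


@dataclass
class GenotypeMatrix:
    """Per-cell, per-variant genotype calls with VAF, depth and quality.

    ``states`` holds integer codes (WT=0, HET=1, HOM=2, NOCALL=-1).
    ``genotyped_fraction`` is the per-variant fraction of non-NOCALL cells,
    and ``retained`` the per-variant QC mask (all True until
    ``apply_variant_qc`` runs).
    """

    states: pd.DataFrame
    vaf: pd.DataFrame
    depth: pd.DataFrame
    gq: pd.DataFrame
    manifest: pd.DataFrame
    genotyped_fraction: pd.Series
    retained: pd.Series

    @property
    def cells(self) -> pd.Index:
        return self.states.index

    @property
    def variant_ids(self) -> list[str]:
        return list(self.states.columns)

    def retained_ids(self) -> list[str]:
        return [v for v in self.states.columns if bool(self.retained[v])]

    def state_labels(self) -> pd.DataFrame:
        """States as human-readable strings (WT/HET/HOM/NOCALL)."""
        return self.states.replace(STATE_LABELS)

    def called(self) -> pd.DataFrame:
        """Boolean mask of non-NOCALL entries."""
        return self.states != NOCALL


def clone_key(states: Sequence[int]) -> str:
    """Canonical clone key for a genotype vector, e.g. ``"HET/WT"``."""
    return "/".join(STATE_LABELS[int(s)] for s in states)


@dataclass
class ClonePartition:
    """Cells partitioned into genotype-vector-defined clones.

    ``table`` is indexed by clone key (descending cell count) with columns
    ``count``, ``fraction`` and ``label`` (user-supplied alias, empty by
    default).  ``assignments`` maps each assigned cell to its clone key;
    cells with any NOCALL among the marker variants are excluded and counted
    in ``unassigned``.
    """

    marker_variants: list[str]
    table: pd.DataFrame
    assignments: pd.Series
    unassigned: int

    @property
    def n_assigned(self) -> int:
        return int(self.table["count"].sum())

    def fraction(self, key: str) -> float:
        return float(self.table.loc[key, "fraction"]) if key in self.table.index else 0.0

    def relabel(self, aliases: Mapping[str, str]) -> "ClonePartition":
        """Attach human labels (e.g. sAML, JMML, Donor) to clone keys."""
        table = self.table.copy()
        for key, label in aliases.items():
            if key in table.index:
                table.loc[key, "label"] = label
        return ClonePartition(self.marker_variants, table, self.assignments, self.unassigned)


@dataclass
class TimepointSeries:
    """Clone fractions tracked across ordered timepoints.

    ``fractions`` is indexed by clone key with one column per timepoint
    (0.0 where absent).  ``emergent`` flags clones absent at the first
    timepoint but present later.
    """

    timepoints: list[str]
    fractions: pd.DataFrame
    emergent: pd.Series

    def to_long(self) -> pd.DataFrame:
        """Fishplot-ready long format: (timepoint, clone_key, fraction)."""
        long = (
            self.fractions.reset_index()
            .melt(id_vars="clone_key", var_name="timepoint", value_name="fraction")
        )
        long["timepoint"] = pd.Categorical(
            long["timepoint"], categories=self.timepoints, ordered=True
        )
        return long.sort_values(["timepoint", "clone_key"]).reset_index(drop=True)


@dataclass(frozen=True)
class ADOEstimate:
    """A directional allelic-dropout rate for one variant.

    ``direction`` is ``het_to_hom_alt`` (ref allele lost, cell appears
    HOM-alt), ``het_to_hom_ref`` (alt allele lost, cell appears WT) or
    ``total`` (either).  ``ci95`` is a Wilson 95% interval.
    """

    variant: str
    direction: str
    rate: float
    n_informative: int
    ci95: tuple[float, float]

    def __post_init__(self) -> None:
        if not (0.0 <= self.rate <= 1.0):
            raise ValueError("ADO rate outside [0, 1]")
        if self.n_informative <= 0:
            raise ValueError("ADO estimate requires informative cells")
        lo, hi = self.ci95
        if not (lo - 1e-12 <= self.rate <= hi + 1e-12):
            raise ValueError("confidence interval does not cover the rate")


@dataclass(frozen=True)
class MarkerPair:
    """Two germline polymorphisms heterozygous in donor, homozygous in recipient."""

    v1: str
    v2: str

    def __post_init__(self) -> None:
        if self.v1 == self.v2:
            raise ValueError("marker pair must use two distinct variants")


#: classify_origin categories, in reporting order
ORIGIN_CATEGORIES = ("donor", "recipient", "ado_ref_ref", "mixed_zygosity", "nocall")


@dataclass
class ChimerismResult:
    """ADO-corrected dual-marker chimerism quantification.

    ``counts`` are the classify_origin category counts; ``expected_false_recipient``
    the estimated number of donor cells masquerading as recipient through
    combined dropout; ``corrected_fraction`` is over cells genotyped at both
    markers (the ``n_genotyped`` denominator).
    """

    counts: dict[str, int]
    ado1: Optional[ADOEstimate]
    ado2: Optional[ADOEstimate]
    estimator: str
    expected_false_recipient: float
    corrected_recipient_count: float
    corrected_fraction: float
    ci95: tuple[float, float]
    n_genotyped: int
    over_corrected: bool = False

    def __post_init__(self) -> None:
        if self.corrected_recipient_count < 0:
            raise ValueError("corrected recipient count must be non-negative")
        if self.corrected_recipient_count > self.counts.get("recipient", 0) + 1e-9:
            raise ValueError("correction cannot exceed the observed recipient count")


@dataclass
class PloidyProfile:
    """Per-amplicon and per-gene ploidy of cell groups relative to a diploid reference.

    ``amplicon_ploidy`` and ``gene_ploidy`` are group × amplicon / group × gene
    DataFrames; the reference group row is identically 2 by construction.
    ``loss_calls`` holds (group, gene) pairs whose gene ploidy fell below
    ``loss_threshold``.
    """

    amplicon_ploidy: pd.DataFrame
    gene_ploidy: pd.DataFrame
    reference_group: str
    loss_threshold: float
    loss_calls: set[tuple[str, str]] = field(default_factory=set)
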