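"""Synthetic single-cell amplicon dataset generator with known ground truth.

Emulates targeted single-cell DNA data of the Tapestri kind: a few thousand
cells drawn from discrete clones, each clone defined by a genotype vector
over the panel's variant sites; negative-binomial per-amplicon read depth;
independent per-allele-copy dropout (ADO); and a small per-read miscall
probability.  Germline markers with donor-heterozygous / recipient-homozygous
zygosity and copy-number lesions (e.g. monosomy of a chromosome-7 amplicon
set) are expressed through the clone genotype vectors and an optional
copy-number map.

The allelic-dropout model: every physical allele copy of a cell at a site is
lost independently with probability ``ado[v]``.  A heterozygous cell thus
keeps both copies with probability (1-a)^2, loses exactly one with
probability 2a(1-a) (appearing homozygous for the survivor), and loses both
with probability a^2, in which case only error reads are emitted and the
genotype caller sees near-zero depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .containers import (
    HET,
    HOM,
    LABEL_STATES,
    NOCALL,
    STATE_LABELS,
    WT,
    AlleleCountMatrix,
    VariantSite,
    manifest_frame,
)

CLONE_ORIGINS = ("recipient", "donor")

GenotypeLike = Union[int, str]


def _state_code(g: GenotypeLike) -> int:
    code = LABEL_STATES[g] if isinstance(g, str) else int(g)
    if code not in (WT, HET, HOM):
        raise ValueError(f"clone genotype must be WT/HET/HOM, got {g!r}")
    return code


@dataclass
class CloneSpec:
    """One clone: a label, a genotype vector, a population fraction, an origin."""

    label: str
    genotype: Mapping[str, GenotypeLike]
    fraction: float
    origin: str = "recipient"

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError(f"clone fraction outside [0, 1]: {self.fraction}")
        if self.origin not in CLONE_ORIGINS:
            raise ValueError(f"unknown clone origin {self.origin!r}")
        self.genotype = {v: _state_code(g) for v, g in self.genotype.items()}


@dataclass
class SimConfig:
    """Full specification of a synthetic dataset.

    Parameters
    ----------
    sites : sequence of VariantSite
        The panel.  ``amplicon_only`` sites carry no alternate allele and are
        simulated WT in every clone (depth-only targets for CNV).
    clones : sequence of CloneSpec
        Clone fractions must sum to 1; every somatic/germline marker needs a
        genotype entry in every clone.
    n_cells : int
    ado : mapping variant id -> per-allele-copy dropout probability in [0, 0.5]
        Sites absent from the map get 0.
    mean_depth : float
        Mean reads per cell per amplicon for a diploid locus.
    depth_dispersion : float
        Negative-binomial size parameter; variance = m + m^2/dispersion.
    error_rate : float
        Per-read allele miscall probability, in [0, 0.01].
    cnv : mapping (clone label, variant id or gene) -> copy number in {0,1,2,3}
        Scales depth by cn/2 and sets the number of allele copies.
    seed : int
    """

    sites: Sequence[VariantSite]
    clones: Sequence[CloneSpec]
    n_cells: int
    ado: Mapping[str, float] = field(default_factory=dict)
    mean_depth: float = 60.0
    depth_dispersion: float = 10.0
    error_rate: float = 0.002
    cnv: Mapping[tuple[str, str], int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.mean_depth <= 0 or self.depth_dispersion <= 0:
            raise ValueError("mean_depth and depth_dispersion must be positive")
        if not (0.0 <= self.error_rate <= 0.01):
            raise ValueError("error_rate outside [0, 0.01]")
        if not self.clones:
            raise ValueError("at least one clone required")
        total = float(sum(c.fraction for c in self.clones))
        if total <= 0.0:
            raise ValueError("all clone fractions are zero")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"clone fractions sum to {total}, expected 1")
        ids = [s.id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant ids in panel")
        id_set = set(ids)
        for v, a in self.ado.items():
            if v not in id_set:
                raise ValueError(f"ado map references unknown variant {v!r}")
            if not (0.0 <= a <= 0.5):
                raise ValueError(f"ado[{v!r}] outside [0, 0.5]")
        markers = [s for s in self.sites if s.role != "amplicon_only"]
        for clone in self.clones:
            for s in markers:
                if s.id not in clone.genotype:
                    raise ValueError(
                        f"clone {clone.label!r} lacks a genotype for marker {s.id!r}"
                    )
            for v in clone.genotype:
                if v not in id_set:
                    raise ValueError(
                        f"clone {clone.label!r} genotype references unknown variant {v!r}"
                    )
        labels = [c.label for c in self.clones]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate clone labels")
        genes = {s.gene for s in self.sites}
        for (label, key), cn in self.cnv.items():
            if label not in labels:
                raise ValueError(f"cnv map references unknown clone {label!r}")
            if key not in id_set and key not in genes:
                raise ValueError(f"cnv map references unknown amplicon/gene {key!r}")
            if cn not in (0, 1, 2, 3):
                raise ValueError(f"copy number must be in {{0,1,2,3}}, got {cn}")
        # a heterozygous genotype needs at least two allele copies
        for clone in self.clones:
            for s in self.sites:
                g = clone.genotype.get(s.id, WT)
                if g == HET and self._copy_number(clone.label, s) < 2:
                    raise ValueError(
                        f"clone {clone.label!r} is HET at {s.id} but has copy "
                        "number < 2 there — contradictory specification"
                    )

    def _copy_number(self, clone_label: str, site: VariantSite) -> int:
        if (clone_label, site.id) in self.cnv:
            return int(self.cnv[(clone_label, site.id)])
        if (clone_label, site.gene) in self.cnv:
            return int(self.cnv[(clone_label, site.gene)])
        return 2


@dataclass
class SimTruth:
    """Ground truth for a simulated dataset.

    Per cell: clone label, origin, true genotype label per variant, and the
    number of ref/alt allele copies lost to dropout at each variant.
    """

    clone: pd.Series
    origin: pd.Series
    genotype: pd.DataFrame
    ref_dropped: pd.DataFrame
    alt_dropped: pd.DataFrame

    @property
    def n_cells(self) -> int:
        return len(self.clone)

    def clone_counts(self) -> pd.Series:
        return self.clone.value_counts()


def simulate_dataset(config: SimConfig) -> tuple[AlleleCountMatrix, SimTruth]:
    """Draw a synthetic dataset; deterministic given ``config`` (incl. seed).

    For each cell a clone is drawn from the clone fractions; for each variant
    each allele copy survives dropout independently; total read depth is
    negative-binomial with mean scaled by copy number / 2; read allele
    identities are drawn from the surviving copies with per-read error.
    Cells that lose every copy at a site emit only error reads.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    clones = list(config.clones)
    fractions = np.array([c.fraction for c in clones], dtype=float)
    fractions = fractions / fractions.sum()
    clone_idx = rng.choice(len(clones), size=n, p=fractions)

    width = max(4, len(str(n)))
    cells = pd.Index([f"cell_{i:0{width}d}" for i in range(n)], name="cell_id")

    ref_counts: dict[str, np.ndarray] = {}
    alt_counts: dict[str, np.ndarray] = {}
    truth_geno: dict[str, np.ndarray] = {}
    ref_drop: dict[str, np.ndarray] = {}
    alt_drop: dict[str, np.ndarray] = {}

    e = config.error_rate
    r = config.depth_dispersion

    for site in config.sites:
        a = float(config.ado.get(site.id, 0.0))
        geno_by_clone = np.array(
            [c.genotype.get(site.id, WT) for c in clones], dtype=np.int64
        )
        cn_by_clone = np.array(
            [config._copy_number(c.label, site) for c in clones], dtype=np.int64
        )
        g = geno_by_clone[clone_idx]
        cn = cn_by_clone[clone_idx]

        n_alt = np.where(g == HOM, cn, np.where(g == HET, 1, 0))
        n_ref = cn - n_alt

        surv_ref = rng.binomial(n_ref, 1.0 - a)
        surv_alt = rng.binomial(n_alt, 1.0 - a)

        mean = config.mean_depth * cn / 2.0
        p_nb = r / (r + mean)
        depth = rng.negative_binomial(r, p_nb)

        s = surv_ref + surv_alt
        with np.errstate(invalid="ignore", divide="ignore"):
            p_alt = np.where(s > 0, (surv_alt * (1.0 - e) + surv_ref * e) / np.maximum(s, 1), 0.0)
        alt_reads = rng.binomial(depth, p_alt)
        ref_reads = depth - alt_reads
        # total amplification failure: only stray error reads survive
        failed = s == 0
        if failed.any():
            emitted = rng.binomial(depth[failed], e)
            alt_f = rng.binomial(emitted, 0.5)
            alt_reads[failed] = alt_f
            ref_reads[failed] = emitted - alt_f

        ref_counts[site.id] = ref_reads
        alt_counts[site.id] = alt_reads
        truth_geno[site.id] = g
        ref_drop[site.id] = n_ref - surv_ref
        alt_drop[site.id] = n_alt - surv_alt

    manifest = manifest_frame(config.sites)
    acm = AlleleCountMatrix(
        ref=pd.DataFrame(ref_counts, index=cells),
        alt=pd.DataFrame(alt_counts, index=cells),
        manifest=manifest,
    )
    labels = np.array([c.label for c in clones])
    origins = np.array([c.origin for c in clones])
    truth = SimTruth(
        clone=pd.Series(labels[clone_idx], index=cells, name="clone"),
        origin=pd.Series(origins[clone_idx], index=cells, name="origin"),
        genotype=pd.DataFrame(truth_geno, index=cells).replace(STATE_LABELS),
        ref_dropped=pd.DataFrame(ref_drop, index=cells),
        alt_dropped=pd.DataFrame(alt_drop, index=cells),
    )
    return acm, truth
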