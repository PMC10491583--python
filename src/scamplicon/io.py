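"""File formats: wide TSV count matrices, variant manifests, VCF export.

The native interchange format is TSV.  The count matrix is wide — one row
per cell, a ``cell_id`` column, and two columns per variant named
``<variant id>.ref`` and ``<variant id>.alt``.  The manifest is a TSV with
columns ``id``, ``gene``, ``role``.  Ground-truth tables and fishplot
long-format tables are plain TSV as well.  VCF export (one record per
manifest variant, 1-based positions as in the variant ids) goes through
pysam and yields standards-conformant VCF 4.2.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
import pysam
import yaml

from .containers import (
    AlleleCountMatrix,
    TimepointSeries,
    VariantSite,
    manifest_frame,
    manifest_sites,
)
from .sim import SimTruth

PathLike = Union[str, Path]


def write_manifest(manifest: pd.DataFrame, path: PathLike) -> None:
    manifest.reset_index().to_csv(path, sep="\t", index=False)


def read_manifest(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "gene", "role"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"manifest {path} lacks required columns {sorted(required - set(df.columns))}"
        )
    manifest = manifest_frame(
        VariantSite(id=r["id"], gene=r["gene"], role=r["role"]) for _, r in df.iterrows()
    )
    return manifest


def write_allele_counts(
    counts: AlleleCountMatrix, path: PathLike, manifest_path: Optional[PathLike] = None
) -> None:
    """Write the wide count TSV (and optionally the manifest TSV)."""
    wide = pd.DataFrame(index=counts.cells)
    for v in counts.variant_ids:
        wide[f"{v}.ref"] = counts.ref[v]
        wide[f"{v}.alt"] = counts.alt[v]
    wide.reset_index().to_csv(path, sep="\t", index=False)
    if manifest_path is not None:
        write_manifest(counts.manifest, manifest_path)


def read_allele_counts(path: PathLike, manifest_path: PathLike) -> AlleleCountMatrix:
    """Read and validate the wide count TSV against its manifest.

    Rejects a missing ``<id>.ref``/``<id>.alt`` column pair, negative counts
    and duplicate cell ids, reporting the offending file line (1-based,
    counting the header as line 1).
    """
    manifest = read_manifest(manifest_path)
    df = pd.read_csv(path, sep="\t")
    if "cell_id" not in df.columns:
        raise ValueError(f"{path}: missing 'cell_id' column")
    dup = df["cell_id"].duplicated()
    if dup.any():
        line = int(np.flatnonzero(dup)[0]) + 2
        raise ValueError(f"{path}: duplicate cell id {df['cell_id'][dup].iloc[0]!r} at line {line}")
    df = df.set_index("cell_id")

    missing = [
        v
        for v in manifest.index
        if f"{v}.ref" not in df.columns or f"{v}.alt" not in df.columns
    ]
    if missing:
        raise ValueError(f"{path}: missing .ref/.alt column pair for variant(s) {missing}")

    ref = pd.DataFrame({v: df[f"{v}.ref"] for v in manifest.index})
    alt = pd.DataFrame({v: df[f"{v}.alt"] for v in manifest.index})
    for name, mat in (("ref", ref), ("alt", alt)):
        neg = mat.lt(0)
        if neg.to_numpy().any():
            row = int(np.flatnonzero(neg.any(axis=1))[0])
            raise ValueError(
                f"{path}: negative {name} count at line {row + 2} "
                f"(cell {mat.index[row]!r})"
            )
    return AlleleCountMatrix(ref=ref, alt=alt, manifest=manifest)


def write_truth(truth: SimTruth, path: PathLike) -> None:
    """Ground-truth table: one row per cell with clone, origin, genotypes and dropouts."""
    out = pd.DataFrame({"clone": truth.clone, "origin": truth.origin})
    for v in truth.genotype.columns:
        out[f"{v}.genotype"] = truth.genotype[v]
        out[f"{v}.ref_dropped"] = truth.ref_dropped[v]
        out[f"{v}.alt_dropped"] = truth.alt_dropped[v]
    out.reset_index().to_csv(path, sep="\t", index=False)


def write_fishplot(series: TimepointSeries, path: PathLike) -> None:
    """Fishplot-ready long table: timepoint, clone_key, fraction."""
    series.to_long().to_csv(path, sep="\t", index=False)


def load_yaml(path: PathLike) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(obj: Mapping, path: PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(obj), fh, sort_keys=True)


def export_variants_vcf(
    manifest: pd.DataFrame,
    path: PathLike,
    clone_genotypes: Optional[Mapping[str, Mapping[str, str]]] = None,
) -> None:
    """One VCF 4.2 record per manifest variant, via pysam.

    ``clone_genotypes`` optionally maps clone label -> {variant id -> genotype
    label}; it is carried in the per-record ``CLONES`` INFO field as
    ``label=GENOTYPE`` entries.  Positions are 1-based as in the variant ids.
    """
    sites = manifest_sites(manifest)  # re-validates every id
    header = pysam.VariantHeader()
    header.add_meta(
        "INFO", items=[("ID", "GENE"), ("Number", "1"), ("Type", "String"), ("Description", "Gene label")]
    )
    header.add_meta(
        "INFO", items=[("ID", "ROLE"), ("Number", "1"), ("Type", "String"), ("Description", "Variant role in the panel")]
    )
    header.add_meta(
        "INFO",
        items=[
            ("ID", "CLONES"),
            ("Number", "."),
            ("Type", "String"),
            ("Description", "Per-clone genotype summary, label=GT"),
        ],
    )
    for chrom in dict.fromkeys(s.chrom for s in sites):
        header.contigs.add(chrom)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for s in sorted(sites, key=lambda s: (s.chrom, s.pos, s.id)):
            rec = vcf.new_record(
                contig=s.chrom, start=s.pos - 1, alleles=(s.ref, s.alt)
            )
            rec.info["GENE"] = s.gene
            rec.info["ROLE"] = s.role
            if clone_genotypes:
                entries = tuple(
                    f"{label}={geno[s.id]}"
                    for label, geno in clone_genotypes.items()
                    if s.id in geno
                )
                if entries:
                    rec.info["CLONES"] = entries
            vcf.write(rec)


def validate_vcf(path: PathLike) -> int:
    """Parse a VCF with pysam; return the record count (raises if malformed)."""
    with pysam.VariantFile(str(path)) as vcf:
        return sum(1 for _ in vcf)
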