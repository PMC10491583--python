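"""Shared fixtures: small panels, clone mixtures, and direct matrix builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import scamplicon as sc
from scamplicon.containers import LABEL_STATES, manifest_frame

# Variant panel used across tests (patient-1 / patient-2 style markers)
PTPN11 = sc.VariantSite("chr12:112888165:G/T", "PTPN11", "somatic_marker")
SETBP1 = sc.VariantSite("chr18:42531907:G/A", "SETBP1", "somatic_marker")
TP53 = sc.VariantSite("chr17:7579472:G/C", "TP53", "germline_marker")
KRAS = sc.VariantSite("chr12:25398281:C/T", "KRAS", "somatic_marker")
FLT3_V1 = sc.VariantSite("chr13:28592546:T/C", "FLT3", "germline_marker")
FLT3_V2 = sc.VariantSite("chr13:28602226:AAGAG/A", "FLT3", "germline_marker")


def make_counts(rows: dict[str, tuple[int, int]], variant: sc.VariantSite = KRAS):
    """Single-variant AlleleCountMatrix from {cell: (ref, alt)}."""
    cells = pd.Index(list(rows), name="cell_id")
    ref = pd.DataFrame({variant.id: [rows[c][0] for c in cells]}, index=cells)
    alt = pd.DataFrame({variant.id: [rows[c][1] for c in cells]}, index=cells)
    return sc.AlleleCountMatrix(ref=ref, alt=alt, manifest=manifest_frame([variant]))


def gm_from_states(states: dict[str, list[str]], sites: list[sc.VariantSite]):
    """GenotypeMatrix built directly from state labels {variant id: per-cell labels}."""
    n = len(next(iter(states.values())))
    cells = pd.Index([f"c{i}" for i in range(n)], name="cell_id")
    codes = pd.DataFrame(
        {v: [LABEL_STATES[s] for s in labels] for v, labels in states.items()},
        index=cells,
        dtype=np.int8,
    )
    depth = pd.DataFrame(40, index=cells, columns=codes.columns)
    vaf = codes.replace({0: 0.0, 1: 0.5, 2: 1.0, -1: np.nan}).astype(float)
    gq = pd.DataFrame(99.0, index=cells, columns=codes.columns)
    frac = (codes != sc.NOCALL).mean(axis=0)
    return sc.GenotypeMatrix(
        states=codes,
        vaf=vaf,
        depth=depth,
        gq=gq,
        manifest=manifest_frame(sites),
        genotyped_fraction=frac,
        retained=pd.Series(True, index=codes.columns),
    )


@pytest.fixture
def patient1_clones():
    """Table-1-style clones: sAML (PTPN11 het, SETBP1 het), WT, JMML."""
    return [
        sc.CloneSpec("sAML", {PTPN11.id: "HET", SETBP1.id: "HET"}, 0.883),
        sc.CloneSpec("WT", {PTPN11.id: "WT", SETBP1.id: "WT"}, 0.06),
        sc.CloneSpec("JMML", {PTPN11.id: "HET", SETBP1.id: "WT"}, 0.057),
    ]


@pytest.fixture
def patient2_sites():
    return [KRAS, FLT3_V1, FLT3_V2]


def transplant_mixture(
    recipient_fraction: float,
    n_cells: int,
    ado: float,
    seed: int,
    mean_depth: float = 60.0,
    error_rate: float = 0.002,
):
    """Donor (HET/HET germline pair) + recipient (HOM/HOM) mixture config."""
    clones = [
        sc.CloneSpec(
            "donor",
            {FLT3_V1.id: "HET", FLT3_V2.id: "HET"},
            1.0 - recipient_fraction,
            origin="donor",
        ),
        sc.CloneSpec(
            "recipient",
            {FLT3_V1.id: "HOM", FLT3_V2.id: "HOM"},
            recipient_fraction,
            origin="recipient",
        ),
    ]
    return sc.SimConfig(
        sites=[FLT3_V1, FLT3_V2],
        clones=clones,
        n_cells=n_cells,
        ado={FLT3_V1.id: ado, FLT3_V2.id: ado},
        mean_depth=mean_depth,
        error_rate=error_rate,
        seed=seed,
    )
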