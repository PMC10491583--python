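"""Clone partitioning, tracking across timepoints, clustering, embedding."""

import numpy as np
import pandas as pd
import pytest

import scamplicon as sc
from conftest import KRAS, PTPN11, SETBP1, TP53, gm_from_states, patient1_clones


def _patient1_gm(n_saml=10, n_wt=3, n_jmml=2):
    """Cells with the three Table-1-style genotype vectors."""
    p = ["HET"] * n_saml + ["WT"] * n_wt + ["HET"] * n_jmml
    s = ["HET"] * n_saml + ["WT"] * n_wt + ["WT"] * n_jmml
    return gm_from_states({PTPN11.id: p, SETBP1.id: s}, [PTPN11, SETBP1])


class TestAssignClones:
    def test_three_clone_vectors_recovered(self):
        part = sc.assign_clones(_patient1_gm(), [PTPN11.id, SETBP1.id])
        assert list(part.table.index) == ["HET/HET", "WT/WT", "HET/WT"]
        assert part.table["count"].tolist() == [10, 3, 2]
        assert part.unassigned == 0

    def test_single_genotype_vector_single_clone(self):
        gm = gm_from_states({KRAS.id: ["HET"] * 5}, [KRAS])
        part = sc.assign_clones(gm, [KRAS.id])
        assert len(part.table) == 1
        assert part.fraction("HET") == 1.0

    def test_nocall_cells_counted_unassigned(self):
        gm = gm_from_states({KRAS.id: ["HET", "NOCALL", "WT"]}, [KRAS])
        part = sc.assign_clones(gm, [KRAS.id])
        assert part.unassigned == 1
        assert part.n_assigned == 2

    def test_fractions_recovered_within_multinomial_error(self, patient1_clones):
        cfg = sc.SimConfig(
            sites=[PTPN11, SETBP1], clones=patient1_clones, n_cells=1000,
            error_rate=0.0, mean_depth=200.0, depth_dispersion=50.0, seed=5,
        )
        acm, _ = sc.simulate_dataset(cfg)
        part = sc.assign_clones(
            sc.apply_variant_qc(sc.call_genotypes(acm)), [PTPN11.id, SETBP1.id]
        )
        for key, p in [("HET/HET", 0.883), ("WT/WT", 0.06), ("HET/WT", 0.057)]:
            sigma = np.sqrt(p * (1 - p) / part.n_assigned)
            assert abs(part.fraction(key) - p) <= 3 * sigma

    def test_permutation_invariance(self):
        gm = _patient1_gm()
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(gm.cells))
        shuffled = sc.GenotypeMatrix(
            states=gm.states.iloc[perm],
            vaf=gm.vaf.iloc[perm],
            depth=gm.depth.iloc[perm],
            gq=gm.gq.iloc[perm],
            manifest=gm.manifest,
            genotyped_fraction=gm.genotyped_fraction,
            retained=gm.retained,
        )
        a = sc.assign_clones(gm, [PTPN11.id, SETBP1.id]).table
        b = sc.assign_clones(shuffled, [PTPN11.id, SETBP1.id]).table
        pd.testing.assert_frame_equal(a, b)

    def test_fractions_sum_to_one(self):
        part = sc.assign_clones(_patient1_gm(), [PTPN11.id, SETBP1.id])
        assert abs(part.table["fraction"].sum() - 1.0) < 1e-9

    def test_empty_marker_set_rejected(self):
        with pytest.raises(ValueError):
            sc.assign_clones(_patient1_gm(), [])

    def test_qc_failed_marker_rejected(self):
        gm = _patient1_gm()
        gm.retained[PTPN11.id] = False
        with pytest.raises(ValueError, match="QC"):
            sc.assign_clones(gm, [PTPN11.id])


class TestTrackClones:
    def _partition(self, labels):
        gm = gm_from_states({KRAS.id: labels}, [KRAS])
        return sc.assign_clones(gm, [KRAS.id])

    def test_patient2_style_series_has_three_tracked_clones(self):
        before = self._partition(["HET"] * 87 + ["WT"] * 8 + ["HOM"] * 5)
        after = self._partition(["WT"] * 998 + ["HET"] * 2)
        series = sc.track_clones([("before HSCT", before), ("after HSCT", after)])
        assert len(series.fractions) == 3
        assert series.fractions.loc["HOM", "after HSCT"] == 0.0

    def test_identical_partitions_give_constant_series(self):
        p = self._partition(["HET"] * 6 + ["WT"] * 4)
        series = sc.track_clones([("t0", p), ("t1", p)])
        assert (series.fractions["t0"] == series.fractions["t1"]).all()

    def test_emergent_clone_flagged_with_zero_initial_fraction(self):
        before = self._partition(["WT"] * 10)
        after = self._partition(["WT"] * 9 + ["HOM"] * 1)
        series = sc.track_clones([("t0", before), ("t1", after)])
        assert series.fractions.loc["HOM", "t0"] == 0.0
        assert bool(series.emergent["HOM"])
        assert not bool(series.emergent["WT"])

    def test_every_clone_key_appears_exactly_once(self):
        before = self._partition(["HET"] * 5 + ["WT"] * 5)
        after = self._partition(["HOM"] * 5 + ["WT"] * 5)
        series = sc.track_clones([("t0", before), ("t1", after)])
        assert sorted(series.fractions.index) == ["HET", "HOM", "WT"]
        assert not series.fractions.index.has_duplicates

    def test_mismatched_marker_sets_rejected(self):
        p1 = self._partition(["WT"] * 3)
        gm2 = gm_from_states({TP53.id: ["HET"] * 3}, [TP53])
        p2 = sc.assign_clones(gm2, [TP53.id])
        with pytest.raises(ValueError, match="marker"):
            sc.track_clones([("t0", p1), ("t1", p2)])


class TestClusterCells:
    def test_zygosity_split_separates_origins_exactly_without_ado(self):
        # donor cells HET at the TP53 polymorphism, recipient cells HOM
        labels = ["HET"] * 30 + ["HOM"] * 20
        gm = gm_from_states({TP53.id: labels}, [TP53])
        _, flat = sc.cluster_cells(gm, n_clusters=2)
        truth = pd.Series([0] * 30 + [1] * 20, index=gm.cells)
        table = pd.crosstab(flat, truth)
        # each flat cluster maps to exactly one origin
        assert (table.gt(0).sum(axis=1) == 1).all()
        assert table.to_numpy().sum() == 50

    def test_identical_cells_collapse_to_one_cluster(self):
        gm = gm_from_states({TP53.id: ["HET"] * 12}, [TP53])
        est = sc.HammingClusterer(n_clusters=1).fit(gm)
        from scipy.cluster.hierarchy import fcluster

        labels = fcluster(est.linkage_, t=0.5, criterion="distance")
        assert len(set(labels)) == 1

    def test_cluster_origin_agreement_with_dropout(self):
        from conftest import transplant_mixture

        cfg = transplant_mixture(0.5, n_cells=1000, ado=0.05, seed=13)
        acm, truth = sc.simulate_dataset(cfg)
        gm = sc.apply_variant_qc(sc.call_genotypes(acm))
        est = sc.HammingClusterer(n_clusters=2).fit(gm)
        flat = pd.Series(est.labels_, index=est.included_cells_)
        origin = truth.origin.loc[flat.index]
        table = pd.crosstab(flat, origin)
        agreement = table.max(axis=1).sum() / table.to_numpy().sum()
        assert agreement >= 0.95

    def test_all_nocall_cells_excluded_with_warning(self):
        gm = gm_from_states({TP53.id: ["HET", "HOM", "NOCALL"]}, [TP53])
        with pytest.warns(UserWarning, match="NOCALL"):
            est = sc.HammingClusterer(n_clusters=2).fit(gm)
        assert len(est.included_cells_) == 2


class TestEmbedCells:
    def test_separated_clones_and_positive_silhouette(self):
        sites = [PTPN11, SETBP1, TP53]
        labels = (["HET"] * 60 + ["WT"] * 60, ["HET"] * 60 + ["WT"] * 60,
                  ["HOM"] * 60 + ["HET"] * 60)
        gm = gm_from_states(dict(zip([s.id for s in sites], labels)), sites)
        coords = sc.embed_cells(gm, seed=0)
        truth = np.array([0] * 60 + [1] * 60)
        from scipy.spatial.distance import cdist
        from sklearn.metrics import silhouette_score

        a, b = coords.to_numpy()[truth == 0], coords.to_numpy()[truth == 1]
        intra = (cdist(a, a).mean() + cdist(b, b).mean()) / 2
        inter = cdist(a, b).mean()
        assert inter > intra
        assert silhouette_score(coords.to_numpy(), truth) > 0

    def test_duplicated_cell_embeds_to_coincident_points(self):
        gm = gm_from_states({TP53.id: ["HET"] * 25}, [TP53])
        with pytest.warns(UserWarning, match="zero-variance"):
            coords = sc.embed_cells(gm, seed=1)
        assert np.allclose(coords.to_numpy(), coords.to_numpy()[0], atol=1e-12)

    def test_requires_three_cells(self):
        gm = gm_from_states({TP53.id: ["HET", "HOM"]}, [TP53])
        with pytest.raises(ValueError):
            sc.embed_cells(gm)
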