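import numpy as np
import pandas as pd
import pytest

import proxistate as px
from proxistate.association import (aggregation_curve, build_pair_table,
                                    compartment_split, interval_profile,
                                    shuffle_gene_signals)
from proxistate.core import make_binning
from proxistate.hic import make_proximity_bins, external_matrix
from proxistate.signals import gene_density


class TestBuildPairTable:
    def test_toy_row_count_and_order(self, toy):
        table = build_pair_table(toy.proximity)
        assert len(table) == toy.binning.n_interchromosomal_pairs()
        assert (table["i"] < table["j"]).all()
        keys = list(zip(table["i"], table["j"]))
        assert keys == sorted(keys)

    def test_deterministic_recompute(self, toy):
        t1 = build_pair_table(toy.proximity, tracks=toy.tracks,
                              genes=toy.genes, links=toy.links)
        t2 = build_pair_table(toy.proximity, tracks=toy.tracks,
                              genes=toy.genes, links=toy.links)
        pd.testing.assert_frame_equal(t1, t2)

    def test_masked_proximity_rows_excluded(self):
        b = make_binning({"c1": 2_000_000, "c2": 2_000_000})
        vals = np.zeros((4, 4))
        mask = b.interchromosomal_mask().copy()
        mask[0, 2] = mask[2, 0] = False
        C = external_matrix(vals, b, mask)
        table = build_pair_table(C)
        assert len(table) == 3
        assert (0, 2) not in set(zip(table["i"], table["j"]))

    def test_compartment_groups(self, toy):
        table = build_pair_table(toy.proximity)
        comp = np.array(toy.binning.compartments)
        for row in table.itertuples():
            a, c = comp[row.i], comp[row.j]
            expected = "AA" if a == c == "A" else (
                "BB" if a == c == "B" else "AB")
            assert row.compartment_group == expected

    def test_full_feature_set_columns(self, pair_table):
        for col in ["proximity", "D_expression", "A_expression", "jaccard",
                    "go_CC", "coexpression", "gene_content",
                    "compartment_group"]:
            assert col in pair_table.columns


class TestIntervalProfile:
    def test_negated_proximity_gives_rho_minus_one(self, pair_table,
                                                   prox_bins):
        t = pair_table.copy()
        t["neg"] = -t["proximity"]
        prof = interval_profile(t, "neg", prox_bins)
        assert prof.rho_medians == pytest.approx(-1.0)
        assert prof.rho_pairs == pytest.approx(-1.0)

    def test_permuted_feature_uncorrelated(self):
        rng = np.random.default_rng(42)
        n = 10_000
        prox = rng.normal(0, 1, n)
        t = pd.DataFrame({"proximity": prox,
                          "feat": rng.permutation(prox)})
        pb = make_proximity_bins(prox)
        prof = interval_profile(t, "feat", pb)
        assert abs(prof.rho_medians) < 0.5
        assert prof.p_medians > 0.05

    def test_single_interval_is_an_error(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame({"proximity": rng.normal(size=100),
                          "feat": rng.normal(size=100)})
        pb = make_proximity_bins(t["proximity"].to_numpy(), n_bins=29,
                                 kept_range=(14, 14))
        with pytest.raises(ValueError):
            interval_profile(t, "feat", pb)

    def test_constant_feature_rho_undefined(self, prox_bins, pair_table):
        t = pair_table.copy()
        t["const"] = 1.0
        prof = interval_profile(t, "const", prox_bins)
        assert np.isnan(prof.rho_medians)

    def test_counts_cover_unmasked_rows(self, pair_table, prox_bins):
        prof = interval_profile(pair_table, "D_expression", prox_bins)
        assert prof.table["count"].sum() == len(pair_table)


class TestCompartmentSplit:
    def test_partition_is_exhaustive(self, pair_table):
        subs = compartment_split(pair_table)
        total = sum(len(s) for s in subs.values())
        dropped = (pair_table["compartment_group"] == "NA").sum()
        assert total + dropped == len(pair_table)
        assert set(subs) == {"AA", "BB", "AB"}

    def test_all_one_compartment(self):
        b = make_binning({"c1": 2_000_000, "c2": 2_000_000})
        b.set_compartments(["A"] * 4)
        C = external_matrix(np.zeros((4, 4)), b)
        table = build_pair_table(C)
        with pytest.warns(UserWarning):
            subs = compartment_split(table)
        assert len(subs["AA"]) == len(table)
        assert len(subs["BB"]) == 0


class TestShuffle:
    def test_per_compartment_payload_multiset_preserved(self, bundle):
        shuffled = shuffle_gene_signals(bundle.genes, seed=3)
        for comp in ("A", "B"):
            before = sorted(bundle.genes.loc[
                bundle.genes["compartment"] == comp, "expression"])
            after = sorted(shuffled.loc[
                shuffled["compartment"] == comp, "expression"])
            assert np.allclose(before, after)

    def test_positions_and_gene_content_untouched(self, bundle):
        shuffled = shuffle_gene_signals(bundle.genes, seed=3)
        assert (shuffled["start"] == bundle.genes["start"]).all()
        assert (shuffled["chrom"] == bundle.genes["chrom"]).all()
        before = gene_density(bundle.genes, bundle.binning)
        after = gene_density(shuffled, bundle.binning)
        assert (before == after).all()

    def test_single_gene_compartment_unchanged(self):
        genes = pd.DataFrame({
            "gene_id": ["g1", "g2", "g3"], "chrom": ["c1"] * 3,
            "start": [0, 100, 200], "end": [50, 150, 250],
            "expression": [1.0, 2.0, 3.0],
            "compartment": ["A", "B", "B"]})
        shuffled = shuffle_gene_signals(genes, seed=0)
        assert shuffled.loc[0, "gene_id"] == "g1"
        assert shuffled.loc[0, "expression"] == 1.0

    def test_seeded_reproducible(self, bundle):
        a = shuffle_gene_signals(bundle.genes, seed=9)
        b = shuffle_gene_signals(bundle.genes, seed=9)
        pd.testing.assert_frame_equal(a, b)
        c = shuffle_gene_signals(bundle.genes, seed=10)
        assert not (c["gene_id"] == a["gene_id"]).all()


class TestAggregationCurve:
    def test_group_count_floor(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame({"feat": rng.normal(size=1_700),
                          "proximity": rng.normal(size=1_700)})
        curve = aggregation_curve(t, "feat", group_size=500)
        assert len(curve) == 3
        kept = aggregation_curve(t, "feat", group_size=500, remainder="keep")
        assert len(kept) == 4

    def test_feature_means_are_sorted(self):
        rng = np.random.default_rng(1)
        t = pd.DataFrame({"feat": rng.normal(size=900),
                          "proximity": rng.normal(size=900)})
        curve = aggregation_curve(t, "feat", group_size=100)
        assert (np.diff(curve["mean_feat"]) >= 0).all()

    def test_group_size_one_is_identity_scatter(self):
        t = pd.DataFrame({"feat": [3.0, 1.0, 2.0],
                          "proximity": [30.0, 10.0, 20.0]})
        curve = aggregation_curve(t, "feat", group_size=1)
        assert list(curve["mean_feat"]) == [1.0, 2.0, 3.0]
        assert list(curve["mean_proximity"]) == [10.0, 20.0, 30.0]

    def test_fewer_rows_than_group_warns_single_group(self):
        t = pd.DataFrame({"feat": [1.0, 2.0], "proximity": [1.0, 2.0]})
        with pytest.warns(UserWarning):
            curve = aggregation_curve(t, "feat", group_size=50_000)
        assert len(curve) == 1

    def test_invalid_group_size(self):
        t = pd.DataFrame({"feat": [1.0], "proximity": [1.0]})
        with pytest.raises(ValueError):
            aggregation_curve(t, "feat", group_size=0)


class TestPlantedAssociations:
    def test_difference_features_anticorrelate_with_proximity(
            self, pair_table, prox_bins):
        for feat in ("D_expression", "D_DNAse", "D_methylation"):
            prof = interval_profile(pair_table, feat, prox_bins)
            assert prof.rho_medians < -0.5

    def test_jaccard_and_go_similarity_increase_with_proximity(
            self, pair_table, prox_bins):
        assert interval_profile(pair_table, "jaccard",
                                prox_bins).rho_medians > 0.5
        assert interval_profile(pair_table, "go_CC",
                                prox_bins).rho_medians > 0.5

    def test_shuffle_flattens_planted_coupling(self):
        """Interval-median correlation of the expression difference with
        proximity is strong before, and near zero after, the
        compartment-constrained shuffle (aggregated over 5 seeds)."""
        cfg = px.compartment_decoupled_config()
        orig, shuf = [], []
        for seed in (1, 2, 3, 4, 5):
            b = px.simulate(cfg, seed=seed)
            table = build_pair_table(
                b.proximity, tracks={"expression": b.tracks["expression"]})
            pb = make_proximity_bins(table["proximity"].to_numpy())
            orig.append(interval_profile(table, "D_expression",
                                         pb).rho_medians)
            genes2 = shuffle_gene_signals(b.genes, seed=seed + 100)
            track2 = px.SignalTrack(
                "expression",
                genes2[["chrom", "start", "end", "expression"]].rename(
                    columns={"expression": "height"}).reset_index(drop=True))
            t2 = build_pair_table(b.proximity,
                                  tracks={"expression": track2})
            shuf.append(interval_profile(t2, "D_expression", pb).rho_medians)
        assert np.mean(orig) < -0.7
        assert abs(np.mean(shuf)) < 0.3
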