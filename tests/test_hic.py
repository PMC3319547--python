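import numpy as np
import pandas as pd
import pytest

from proxistate.core import make_binning
from proxistate.hic import (ProximityBinning, coverage_fractions,
                            correlation_matrix, enrichment_matrix,
                            identity_level, identity_qc_profile,
                            make_proximity_bins, raw_matrix)
from proxistate.simulate import SimulationConfig, simulate


def _three_fragment_counts():
    """3 fragments on 3 chromosomes with O12=10, O13=10, O23=20."""
    b = make_binning({f"c{k}": 1_000_000 for k in (1, 2, 3)})
    O = np.array([[0, 10, 10], [10, 0, 20], [10, 20, 0]], dtype=float)
    return raw_matrix(O, b)


class TestCoverageFractions:
    def test_single_pair_genome(self):
        b = make_binning({"c1": 1_000_000, "c2": 1_000_000})
        O = raw_matrix(np.array([[0.0, 8.0], [8.0, 0.0]]), b)
        assert np.allclose(coverage_fractions(O), [1.0, 1.0])

    def test_three_fragment_example(self):
        f = coverage_fractions(_three_fragment_counts())
        assert np.allclose(f, [0.5, 0.75, 0.75])

    def test_fractions_sum_to_two(self):
        rng = np.random.default_rng(0)
        b = make_binning({"c1": 3_000_000, "c2": 2_000_000, "c3": 2_000_000})
        O = rng.poisson(20, (7, 7)).astype(float)
        O = np.triu(O, 1) + np.triu(O, 1).T
        f = coverage_fractions(raw_matrix(O, b))
        assert np.isclose(f.sum(), 2.0)

    def test_zero_total_is_an_error(self):
        b = make_binning({"c1": 1_000_000, "c2": 1_000_000})
        with pytest.raises(ValueError):
            coverage_fractions(raw_matrix(np.zeros((2, 2)), b))

    def test_uncovered_fragment_gets_zero(self):
        b = make_binning({"c1": 2_000_000, "c2": 1_000_000})
        O = np.zeros((3, 3))
        O[0, 2] = O[2, 0] = 5
        f = coverage_fractions(raw_matrix(O, b))
        assert f[1] == 0.0


class TestEnrichment:
    def test_single_pair_is_unity(self):
        b = make_binning({"c1": 1_000_000, "c2": 1_000_000})
        O = raw_matrix(np.array([[0.0, 7.0], [7.0, 0.0]]), b)
        C = enrichment_matrix(O)
        assert np.isclose(C.values[0, 1], 1.0)

    def test_three_fragment_hand_value(self):
        # C*(1,2) = O12 / (f1 f2 T) = 10 / (0.5 * 0.75 * 40) = 2/3
        C = enrichment_matrix(_three_fragment_counts())
        assert np.isclose(C.values[0, 1], 2.0 / 3.0)

    def test_scale_invariance(self):
        O = _three_fragment_counts()
        doubled = raw_matrix(O.values * 2, O.binning)
        assert np.allclose(enrichment_matrix(O).values,
                           enrichment_matrix(doubled).values)

    def test_zero_expected_entries_masked(self):
        b = make_binning({"c1": 2_000_000, "c2": 1_000_000})
        O = np.zeros((3, 3))
        O[0, 2] = O[2, 0] = 5
        C = enrichment_matrix(raw_matrix(O, b))
        assert not C.mask[1, 2]  # fragment 1 has zero coverage


def brute_force_pair_pearson(V, M, i, j):
    """Independent Pearson oracle over the common usable index set."""
    common = [k for k in range(len(V)) if M[i, k] and M[j, k]
              and k not in (i, j)]
    x = np.array([V[i, k] for k in common])
    y = np.array([V[j, k] for k in common])
    if len(common) < 3 or x.std() == 0 or y.std() == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


class TestCorrelationMatrix:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        b = make_binning({f"c{k}": 2_000_000 for k in (1, 2, 3)})
        O = rng.poisson(30, (6, 6)).astype(float)
        O = np.triu(O, 1) + np.triu(O, 1).T
        Cstar = enrichment_matrix(raw_matrix(O, b))
        C = correlation_matrix(Cstar)
        for i in range(6):
            for j in range(i + 1, 6):
                if not Cstar.mask[i, j]:
                    continue
                expected = brute_force_pair_pearson(Cstar.values, Cstar.mask,
                                                    i, j)
                if expected is None:
                    assert not C.mask[i, j]
                else:
                    assert C.mask[i, j]
                    assert abs(C.values[i, j] - expected) < 1e-10

    def test_symmetric_and_bounded(self, bundle):
        C = bundle.proximity
        assert np.allclose(C.values, C.values.T)
        vals = C.values[C.mask]
        assert vals.min() >= -1.0 and vals.max() <= 1.0

    def test_too_few_common_entries_masked(self):
        b = make_binning({"c1": 1_000_000, "c2": 1_000_000})
        O = raw_matrix(np.array([[0.0, 4.0], [4.0, 0.0]]), b)
        C = correlation_matrix(enrichment_matrix(O))
        assert not C.mask.any()


class TestIdentityLevel:
    @pytest.fixture
    def binning(self):
        return make_binning({"c1": 2_000_000, "c2": 2_000_000})

    def test_no_hits_is_zero(self, binning):
        hits = pd.DataFrame(columns=["frag_i", "frag_j", "start_i", "end_i",
                                     "start_j", "end_j", "percent_identity"])
        assert identity_level(0, 2, hits, binning) == 0.0

    def test_hand_value(self, binning):
        hits = pd.DataFrame([{"frag_i": 0, "frag_j": 2, "start_i": 0,
                              "end_i": 100, "start_j": 500, "end_j": 600,
                              "percent_identity": 95.0}])
        assert identity_level(0, 2, hits, binning) == pytest.approx(
            200 / 2_000_000)

    def test_overlapping_hits_merged(self, binning):
        hits = pd.DataFrame([
            {"frag_i": 0, "frag_j": 2, "start_i": 0, "end_i": 100,
             "start_j": 0, "end_j": 100, "percent_identity": 95.0},
            {"frag_i": 0, "frag_j": 2, "start_i": 50, "end_i": 150,
             "start_j": 200, "end_j": 300, "percent_identity": 95.0}])
        # merged on i: [0,150) = 150 bp; on j: 100 + 100 = 200 bp
        assert identity_level(0, 2, hits, binning) == pytest.approx(
            350 / 2_000_000)
        unmerged = identity_level(0, 2, hits, binning, merge_hits=False)
        assert unmerged == pytest.approx(400 / 2_000_000)

    def test_symmetry_and_threshold(self, binning):
        hits = pd.DataFrame([
            {"frag_i": 2, "frag_j": 0, "start_i": 0, "end_i": 1000,
             "start_j": 0, "end_j": 1000, "percent_identity": 93.0},
            {"frag_i": 0, "frag_j": 2, "start_i": 0, "end_i": 5000,
             "start_j": 0, "end_j": 5000, "percent_identity": 80.0}])
        a = identity_level(0, 2, hits, binning)
        assert a == identity_level(2, 0, hits, binning)
        assert a == pytest.approx(2000 / 2_000_000)  # low-identity hit ignored

    def test_per_fragment_denominator_mode(self, binning):
        hits = pd.DataFrame([{"frag_i": 0, "frag_j": 2, "start_i": 0,
                              "end_i": 200, "start_j": 0, "end_j": 100,
                              "percent_identity": 95.0}])
        v = identity_level(0, 2, hits, binning, denominator="per_fragment")
        assert v == pytest.approx(0.5 * (200 / 1e6 + 100 / 1e6))

    def test_out_of_fragment_hit_clipped(self, binning):
        hits = pd.DataFrame([{"frag_i": 0, "frag_j": 2, "start_i": 999_900,
                              "end_i": 1_000_200, "start_j": 0, "end_j": 100,
                              "percent_identity": 95.0}])
        with pytest.warns(UserWarning):
            v = identity_level(0, 2, hits, binning)
        assert v == pytest.approx(200 / 2_000_000)


class TestProximityBinning:
    def test_uniform_values_equal_counts(self):
        values = np.arange(29 * 10) / 10.0  # uniform over [0, 29)
        pb = make_proximity_bins(values, n_bins=29)
        counts = np.bincount(pb.assign(values), minlength=29)
        assert counts.min() == counts.max() == 10

    def test_max_value_in_last_bin(self):
        pb = make_proximity_bins(np.linspace(0, 1, 40), n_bins=4)
        assert pb.assign(np.array([1.0]))[0] == 3

    def test_single_bin(self):
        pb = make_proximity_bins(np.linspace(0, 1, 40), n_bins=1, n_kept=1)
        assert (pb.assign(np.linspace(0, 1, 40)) == 0).all()

    def test_default_kept_range_is_central_18_of_29(self):
        pb = make_proximity_bins(np.linspace(0, 1, 100))
        assert pb.kept_range == (5, 22)
        assert len(pb.kept_bins) == 18

    def test_degenerate_and_sparse_inputs(self):
        with pytest.raises(ValueError):
            make_proximity_bins(np.ones(100))
        with pytest.raises(ValueError):
            make_proximity_bins(np.arange(5), n_bins=29)


class TestIdentityQC:
    def test_planted_artifacts_flag_top_bins(self):
        cfg = SimulationConfig(n_artifact_pairs=40)
        b = simulate(cfg, seed=5)
        pb = make_proximity_bins(b.proximity.pair_series()["value"].to_numpy())
        prof = identity_qc_profile(b.proximity, b.hits, pb)
        flagged = prof[prof["flagged"]]["bin"].to_numpy()
        assert len(flagged) > 0
        # artifacts were attached to the highest-proximity pairs
        assert flagged.min() >= pb.n_bins - 10

    def test_no_hits_gives_flat_zero_profile(self, bundle):
        pb = make_proximity_bins(
            bundle.proximity.pair_series()["value"].to_numpy())
        prof = identity_qc_profile(bundle.proximity, bundle.hits, pb)
        nonempty = prof[prof["count"] > 0]
        assert (nonempty["median"] == 0).all()
        assert not prof["flagged"].any()
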