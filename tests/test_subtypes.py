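import numpy as np
import pandas as pd
import pytest

from conftest import run_pipeline, truth_for
from dmscape.constants import AA_ORDER
from dmscape.landscape import fit_pca
from dmscape.subtypes import (
    LABEL_RE,
    ClusteringParams,
    assign_subtypes,
    cluster_amino_acid,
    correlate_subtypes,
    cosine_distance,
    count_numbered_subtypes,
    label_subtypes,
    most_selective_subtype,
    saturation_analysis,
    split_permissive,
    subtype_mean_profiles,
)
from test_landscape import make_profileset


class TestSplitPermissive:
    def test_all_entries_below_threshold(self):
        v = [0.39, -0.39] * 10
        v[AA_ORDER.index("A")] = 0.0
        ps = make_profileset([("s", "g", 1, "A", v)])
        perm, clus = split_permissive(ps, 0.4)
        assert len(perm) == 1 and len(clus) == 0

    def test_boundary_is_strict(self):
        v = [0.0] * 20
        v[AA_ORDER.index("C")] = -0.4  # exactly the threshold -> clusterable
        ps = make_profileset([("s", "g", 1, "A", v)])
        perm, clus = split_permissive(ps, 0.4)
        assert len(perm) == 0 and len(clus) == 1

    def test_zero_profile_is_permissive(self):
        ps = make_profileset([("s", "g", 1, "A", [0.0] * 20)])
        perm, clus = split_permissive(ps, 0.4)
        assert len(perm) == 1

    def test_partition_exhaustive_disjoint(self, small_landscape):
        _, profiles, _ = small_landscape
        perm, clus = split_permissive(profiles)
        assert len(perm) + len(clus) == len(profiles)
        assert len(perm.intersection(clus)) == 0


class TestCosineDistance:
    def test_identical_orthogonal_opposite(self):
        u = np.array([1.0, 0.0, 2.0])
        assert cosine_distance(u, u) == pytest.approx(0.0)
        assert cosine_distance([1, 0], [0, 1]) == pytest.approx(1.0)
        assert cosine_distance(u, -u) == pytest.approx(2.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero vector"):
            cosine_distance([0.0, 0.0], [1.0, 0.0])

    def test_magnitude_invariant(self):
        u, v = np.array([1.0, -2.0, 0.5]), np.array([0.3, 1.0, -1.0])
        assert cosine_distance(u, v) == pytest.approx(cosine_distance(5 * u, 0.1 * v))


class TestClusterAminoAcid:
    def test_two_planted_archetypes(self, rng):
        a = rng.normal([3, 0, 0, 0], 0.1, size=(50, 4))
        b = rng.normal([0, 3, 0, 0], 0.1, size=(50, 4))
        ids = cluster_amino_acid(np.vstack([a, b]), ClusteringParams())
        assert set(ids) == {1, 2}
        assert len(set(ids[:50])) == 1 and len(set(ids[50:])) == 1

    def test_identical_directions_single_cluster(self, rng):
        base = np.array([1.0, 2.0, -1.0])
        X = base * rng.uniform(0.5, 2.0, size=(30, 1))  # same direction, varied length
        ids = cluster_amino_acid(X, ClusteringParams(min_cluster_size=10))
        assert set(ids) == {1}

    def test_too_few_positions_all_outliers(self):
        with pytest.warns(UserWarning, match="fewer than 2"):
            ids = cluster_amino_acid(np.ones((1, 3)), ClusteringParams())
        assert (ids == 0).all()

    def test_min_size_forces_outliers(self, rng):
        X = rng.normal(size=(5, 3))
        ids = cluster_amino_acid(X, ClusteringParams(min_cluster_size=20))
        assert (ids == 0).all()


class TestLabelSubtypes:
    def test_frequency_ordering_and_outliers(self):
        ids = np.array([1] * 50 + [2] * 80 + [0] * 5)
        labels = label_subtypes("C", ids)
        assert labels[:50] == ["C2"] * 50  # smaller cluster -> higher number
        assert labels[50:130] == ["C1"] * 80
        assert labels[130:] == ["CO"] * 5

    def test_no_outliers_no_o_label(self):
        labels = label_subtypes("Q", np.array([1] * 30))
        assert set(labels) == {"Q1"}

    def test_equal_size_tie_broken_by_tightness(self, rng):
        tight = rng.normal([4, 0, 0], 0.01, size=(20, 3))
        loose = rng.normal([0, 4, 0], 0.8, size=(20, 3))
        pcs = np.vstack([loose, tight])
        ids = np.array([1] * 20 + [2] * 20)
        labels = label_subtypes("A", ids, pcs)
        assert labels[20] == "A1"  # tight cluster wins the tie
        assert labels[0] == "A2"

    def test_label_grammar(self, small_landscape):
        _, profiles, _ = small_landscape
        assignments = assign_subtypes(profiles)
        assert assignments["label"].str.match(LABEL_RE).all()
        wt = assignments["wt_aa"]
        assert (assignments["label"].str[0] == wt).all()


class TestSubtypeMeanProfiles:
    def test_singleton_and_pair_means(self):
        v0 = [0.0] * 20
        v1 = [-1.0] * 20
        v1[AA_ORDER.index("A")] = 0.0
        ps = make_profileset(
            [("s", "g", 1, "A", v0), ("s", "g", 2, "A", v1), ("s", "g", 3, "C", v0)]
        )
        assignments = pd.DataFrame(
            {
                "study": ["s"] * 3, "gene": ["g"] * 3,
                "position": [1, 2, 3], "wt_aa": ["A", "A", "C"],
                "label": ["A1", "A1", "CP"],
            }
        )
        out = subtype_mean_profiles(assignments, ps)
        expected = (np.array(v0) + np.array(v1)) / 2
        np.testing.assert_allclose(out.loc["A1", list(AA_ORDER)], expected)
        assert out.loc["A1", "size"] == 2
        assert out.loc["A1", "frequency"] == 1.0

    def test_frequencies_sum_to_one_per_amino_acid(self, small_landscape):
        _, profiles, _ = small_landscape
        assignments = assign_subtypes(profiles)
        out = subtype_mean_profiles(assignments, profiles)
        sums = out.groupby(out.index.str[0])["frequency"].sum()
        np.testing.assert_allclose(sums, 1.0)

    def test_numbered_sizes_non_increasing(self, small_landscape):
        _, profiles, _ = small_landscape
        assignments = assign_subtypes(profiles)
        out = subtype_mean_profiles(assignments, profiles)
        numbered = out[out.index.str[1:].str.isdigit()]
        for aa, group in numbered.groupby(numbered.index.str[0]):
            ordered = group.sort_index(key=lambda s: s.str[1:].astype(int))
            assert (np.diff(ordered["size"]) <= 0).all()


class TestCorrelateSubtypes:
    def test_matrix_matches_direct_pearson(self):
        rng = np.random.default_rng(3)
        rows = rng.normal(size=(3, 20))
        df = pd.DataFrame(rows, index=["A1", "A2", "C1"], columns=list(AA_ORDER))
        corr, order = correlate_subtypes(df)
        for i, a in enumerate(df.index):
            for j, b in enumerate(df.index):
                expected = np.corrcoef(rows[i], rows[j])[0, 1]
                assert corr.loc[a, b] == pytest.approx(expected)
        assert sorted(order) == sorted(df.index)

    def test_identical_and_negated_profiles(self):
        base = np.linspace(-1, 1, 20)
        df = pd.DataFrame([base, base, -base], index=["A1", "A2", "C1"],
                          columns=list(AA_ORDER))
        corr, _ = correlate_subtypes(df)
        assert corr.loc["A1", "A2"] == pytest.approx(1.0)
        assert corr.loc["A1", "C1"] == pytest.approx(-1.0)

    def test_constant_profile_rejected_by_name(self):
        df = pd.DataFrame(
            [np.zeros(20), np.linspace(-1, 1, 20)],
            index=["A1", "C1"], columns=list(AA_ORDER),
        )
        with pytest.raises(ValueError, match="A1"):
            correlate_subtypes(df)


class TestMostSelective:
    def test_picks_most_negative_by_default(self):
        df = pd.DataFrame(
            [[-0.9] * 20, [-0.2] * 20],
            index=["A1", "A2"], columns=list(AA_ORDER),
        )
        out = most_selective_subtype(df)
        assert out["A"] == "A1"
        assert most_selective_subtype(df, highest=True)["A"] == "A2"

    def test_amino_acid_without_numbered_subtype_missing(self):
        df = pd.DataFrame([[-0.5] * 20], index=["AP"], columns=list(AA_ORDER))
        out = most_selective_subtype(df)
        assert out.isna().all()


class TestPlantedRecovery:
    def test_recovered_subtypes_match_planted_archetypes(self, planted_landscape):
        """On a 2,000-position landscape with archetype separation far above
        the noise scale, clustering recovers the planted per-amino-acid
        subtypes (ARI >= 0.8, permissive/outlier positions excluded)."""
        from sklearn.metrics import adjusted_rand_score

        _, profiles, truth = planted_landscape
        assignments = assign_subtypes(profiles)
        labels = pd.Series(assignments["label"].to_numpy(), index=profiles.index)
        planted = (
            profiles.index.get_level_values("wt_aa")
            + ":" + truth_for(profiles, truth)["archetype"]
        )
        numbered = labels.str[1:].str.isdigit()
        ari = adjusted_rand_score(planted[numbered.to_numpy()], labels[numbered])
        assert ari >= 0.8


@pytest.fixture(scope="module")
def saturation_table(small_landscape):
    _, profiles, _ = small_landscape
    return saturation_analysis(profiles, start=200, step=200, n_shuffles=2, seed=7)


class TestSaturation:
    def test_deterministic_under_seed(self, small_landscape, saturation_table):
        _, profiles, _ = small_landscape
        again = saturation_analysis(profiles, start=200, step=200, n_shuffles=2, seed=7)
        pd.testing.assert_frame_equal(saturation_table, again)

    def test_full_subset_equals_full_pipeline_count(self, small_landscape, saturation_table):
        _, profiles, _ = small_landscape
        full = count_numbered_subtypes(assign_subtypes(profiles)["label"])
        at_n = saturation_table[saturation_table["size"] == len(profiles)]
        assert (at_n["n_subtypes"] == full).all()

    def test_start_beyond_data_errors(self, small_landscape):
        _, profiles, _ = small_landscape
        with pytest.raises(ValueError, match="start"):
            saturation_analysis(profiles, start=10_000)
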