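import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dmscape.constants import AA_ORDER
from dmscape.ingest import (
    IngestError,
    StudyConfig,
    average_replicates,
    collapse_multimutants,
    filter_positions,
    impute_missing,
    normalize_study,
    transform_scores,
)


def variants(rows):
    return pd.DataFrame(
        rows, columns=["study", "gene", "substitutions", "score", "replicate", "condition"]
    )


def singles(rows):
    return pd.DataFrame(
        rows, columns=["study", "gene", "position", "wt_aa", "mut_aa", "score"]
    )


def normalized(rows):
    df = pd.DataFrame(
        rows, columns=["study", "gene", "position", "wt_aa", "mut_aa", "er"]
    )
    df["measured"] = True
    return df


class TestTransformScores:
    def test_log2_ratio_maps_wild_type_to_zero(self):
        df = variants([("s", "g", "A1C", 1.0, "", ""), ("s", "g", "A1D", 0.5, "", "")])
        out = transform_scores(df, StudyConfig(study_id="s", gene="g", transform="log2_ratio"))
        assert out["score"].tolist() == [0.0, -1.0]

    def test_identity_leaves_scores_unchanged(self):
        df = variants([("s", "g", "A1C", -0.7, "", "")])
        out = transform_scores(df, StudyConfig(study_id="s", gene="g"))
        assert out["score"].tolist() == [-0.7]

    def test_negate_and_affine(self):
        df = variants([("s", "g", "A1C", 2.0, "", "")])
        neg = transform_scores(df, StudyConfig(study_id="s", gene="g", transform="negate"))
        assert neg["score"].tolist() == [-2.0]
        aff = transform_scores(
            df, StudyConfig(study_id="s", gene="g", transform="affine", affine=(0.5, -1.0))
        )
        assert aff["score"].tolist() == [0.0]

    def test_log2_ratio_rejects_nonpositive_naming_record(self):
        df = variants([("s", "g", "A1C", -0.5, "", "")])
        with pytest.raises(IngestError, match="A1C"):
            transform_scores(df, StudyConfig(study_id="s", gene="g", transform="log2_ratio"))


class TestAverageReplicates:
    def test_mean_over_replicates(self):
        df = variants(
            [("s", "g", "A1C", -1.0, "r1", ""), ("s", "g", "A1C", -2.0, "r2", "")]
        )
        out = average_replicates(df, StudyConfig(study_id="s", gene="g"))
        assert out["score"].tolist() == [-1.5]

    def test_single_replicate_identity(self):
        df = variants([("s", "g", "A1C", -0.7, "r1", "")])
        out = average_replicates(df, StudyConfig(study_id="s", gene="g"))
        assert out["score"].tolist() == [-0.7]

    def test_condition_policy_drop(self):
        df = variants(
            [("s", "g", "A1C", -1.0, "r1", "c1"), ("s", "g", "A1C", 5.0, "r1", "c2")]
        )
        cfg = StudyConfig(
            study_id="s", gene="g", condition_policy={"c1": "average", "c2": "drop"}
        )
        assert average_replicates(df, cfg)["score"].tolist() == [-1.0]

    def test_condition_policy_prefer_keeps_only_preferred(self):
        df = variants(
            [("s", "g", "A1C", -1.0, "r1", "broad"), ("s", "g", "A1C", 3.0, "r1", "narrow")]
        )
        cfg = StudyConfig(
            study_id="s", gene="g",
            condition_policy={"broad": "prefer", "narrow": "average"},
        )
        assert average_replicates(df, cfg)["score"].tolist() == [-1.0]

    def test_zero_retained_conditions_errors(self):
        df = variants([("s", "g", "A1C", -1.0, "r1", "c1")])
        cfg = StudyConfig(study_id="s", gene="g", condition_policy={"c1": "drop"})
        with pytest.raises(IngestError, match="retains no"):
            average_replicates(df, cfg)


class TestCollapseMultimutants:
    def test_unmeasured_single_gets_mean_of_containing_sequences(self):
        df = variants(
            [("s", "g", "A1C;D2E", -1.0, "", ""), ("s", "g", "A1C;F3G", -0.4, "", "")]
        )
        out = collapse_multimutants(df, cap=2)
        a1c = out[(out["position"] == 1) & (out["mut_aa"] == "C")]
        assert a1c["score"].tolist() == [pytest.approx(-0.7)]

    def test_direct_measurement_wins(self):
        df = variants(
            [
                ("s", "g", "A1C", -0.3, "", ""),
                ("s", "g", "A1C;D2E", -1.0, "", ""),
            ]
        )
        out = collapse_multimutants(df, cap=2)
        a1c = out[(out["position"] == 1) & (out["mut_aa"] == "C")]
        assert a1c["score"].tolist() == [-0.3]

    def test_cap_excludes_long_sequences(self):
        df = variants([("s", "g", "A1C;D2E;F3G", -1.0, "", "")])
        out = collapse_multimutants(df, cap=2)
        assert out.empty

    def test_cap_below_one_errors(self):
        with pytest.raises(IngestError):
            collapse_multimutants(variants([]), cap=0)


class TestNormalizeStudy:
    def test_bottom_decile_median_by_hand(self):
        # 20 scores, two smallest {-10, -9}: ceil(0.1*20)=2, median -9.5
        scores = [-10.0, -9.0] + [float(x) for x in range(-8, 10)]
        rows = [
            ("s", "g", i + 1, "A", "C", sc) for i, sc in enumerate(scores)
        ]
        out = normalize_study(singles(rows))
        assert out["er"].min() == pytest.approx(-10 / 9.5)
        assert sorted(out["er"])[:2] == [pytest.approx(-10 / 9.5), pytest.approx(-9 / 9.5)]
        assert np.median(sorted(out["er"])[:2]) == pytest.approx(-1.0)

    def test_all_minus_one_self_normalizing(self):
        rows = [("s", "g", i + 1, "A", "C", -1.0) for i in range(12)]
        out = normalize_study(singles(rows))
        assert (out["er"] == -1.0).all()

    @given(
        scale=st.floats(min_value=0.01, max_value=100.0),
        seed=st.integers(min_value=0, max_value=50),
    )
    def test_scale_invariance_and_sign_preservation(self, scale, seed):
        r = np.random.default_rng(seed)
        base = np.concatenate([r.normal(-3, 0.5, 5), r.normal(0, 0.5, 25)])
        rows = lambda v: [("s", "g", i + 1, "A", "C", s) for i, s in enumerate(v)]
        out1 = normalize_study(singles(rows(base)))
        out2 = normalize_study(singles(rows(base * scale)))
        np.testing.assert_allclose(out1["er"], out2["er"], rtol=1e-9)
        assert (np.sign(out1["er"]) == np.sign(base)).all()

    def test_bottom_decile_pool_excludes_synonymous(self):
        # nonsynonymous tail {-4,-4}, synonymous -100 must not enter the pool
        rows = [("s", "g", i + 1, "A", "C", s) for i, s in enumerate([-4.0] * 2 + [0.0] * 18)]
        rows.append(("s", "g", 30, "A", "=", -100.0))
        out = normalize_study(singles(rows))
        nonsyn = out[out["mut_aa"] != "="]
        assert nonsyn["er"].min() == pytest.approx(-1.0)

    def test_degenerate_and_small_studies_error(self):
        zeros = [("s", "g", i + 1, "A", "C", 0.0) for i in range(20)]
        with pytest.raises(IngestError, match="degenerate"):
            normalize_study(singles(zeros))
        with pytest.raises(IngestError, match=">= 10"):
            normalize_study(singles(zeros[:5]))


def position_with_n_measured(position, wt, n, study="s", gene="g"):
    targets = [aa for aa in AA_ORDER if aa != wt][: n - 1] + ["*"]
    return [(study, gene, position, wt, mut, -0.5) for mut in targets[:n]]


class TestFilterPositions:
    @pytest.mark.parametrize("n,kept", [(14, False), (15, True), (20, True)])
    def test_threshold_boundary(self, n, kept):
        table = normalized(position_with_n_measured(1, "A", n))
        out = filter_positions(table)
        assert (len(out) > 0) is kept

    def test_synonymous_does_not_count(self):
        rows = position_with_n_measured(1, "A", 14)
        rows.append(("s", "g", 1, "A", "=", 0.0))
        assert filter_positions(normalized(rows)).empty

    def test_never_alters_scores(self):
        table = normalized(
            position_with_n_measured(1, "A", 20) + position_with_n_measured(2, "C", 10)
        )
        out = filter_positions(table)
        assert len(out) <= len(table)
        merged = out.merge(table, on=["study", "gene", "position", "wt_aa", "mut_aa"])
        assert (merged["er_x"] == merged["er_y"]).all()


class TestImputeMissing:
    def test_median_of_substitution_type(self):
        rows = []
        # three positions with measured A->C at {-1.0, -0.5, 0.1}
        for pos, val in [(1, -1.0), (2, -0.5), (3, 0.1)]:
            rows.extend(
                ("s", "g", pos, "A", mut, val if mut == "C" else -0.2)
                for mut in [aa for aa in AA_ORDER if aa != "A"] + ["*"]
            )
        # position 4 misses A->C
        rows.extend(
            ("s", "g", 4, "A", mut, -0.2)
            for mut in [aa for aa in AA_ORDER if aa not in ("A", "C")] + ["*"]
        )
        profiles = impute_missing(normalized(rows))
        pos4 = profiles.er.xs(4, level="position")
        assert pos4["C"].iloc[0] == pytest.approx(-0.5)
        assert profiles.imputed.xs(4, level="position")["C"].iloc[0]

    def test_missing_synonymous_becomes_zero(self):
        rows = position_with_n_measured(1, "A", 20)
        profiles = impute_missing(normalized(rows))
        assert profiles.er.iloc[0]["A"] == 0.0
        assert profiles.imputed.iloc[0]["A"]

    def test_fully_measured_position_untouched(self):
        rows = [
            ("s", "g", 1, "A", mut, -0.3)
            for mut in [aa for aa in AA_ORDER if aa != "A"] + ["*"]
        ]
        rows.append(("s", "g", 1, "A", "=", 0.05))
        profiles = impute_missing(normalized(rows))
        assert not profiles.imputed.iloc[0].any()
        assert profiles.er.iloc[0]["A"] == pytest.approx(0.05)
        assert profiles.n_measured.iloc[0] == 20

    def test_unseen_type_errors_listing_it(self):
        rows = position_with_n_measured(1, "W", 19)  # misses exactly one type
        missing_mut = [aa for aa in AA_ORDER if aa != "W"][18]
        with pytest.raises(IngestError, match=f"W->{missing_mut}"):
            impute_missing(normalized(rows))

    def test_no_missing_values_after_imputation(self, small_landscape):
        _, profiles, _ = small_landscape
        assert np.isfinite(profiles.er.to_numpy()).all()
        measured_frac = 1 - profiles.imputed.to_numpy().mean()
        assert 0.9 < measured_frac <= 1.0


def test_pipeline_normalizes_before_filtering():
    """A sparse position's scores still shape the normalization tail before
    the position itself is dropped (normalize precedes filter)."""
    # deleterious tail lives entirely on a sparse (to-be-filtered) position
    sparse = [("s", "g", 1, "A", mut, -8.0) for mut in ["C", "D"]]
    dense = [
        ("s", "g", 2, "C", mut, -0.5)
        for mut in [aa for aa in AA_ORDER if aa != "C"] + ["*"]
    ]
    table = singles(sparse + dense)
    norm = normalize_study(table)
    filtered = filter_positions(norm)
    assert set(filtered["position"]) == {2}
    # ceil(0.1*22)=3 smallest: {-8, -8, -0.5} -> median -8
    assert filtered["er"].iloc[0] == pytest.approx(-0.5 / 8.0)
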