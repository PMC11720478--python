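import numpy as np
import pandas as pd
import pytest

import freeassoc as fa
from freeassoc.errors import SchemaError, UsageError


@pytest.fixture
def grouped_study():
    """Two groups x two hand-assigned clusters with countable tokens."""
    rows = [
        # group A: 3 tokens in cluster-1 words, 1 token in cluster-2 words
        ("a1", "A", "top", "alpha"),
        ("a1", "A", "top", "alpha"),
        ("a2", "A", "top", "beta"),
        ("a2", "A", "top", "gamma"),
        # group B: 1 and 3
        ("b1", "B", "top", "alpha"),
        ("b1", "B", "top", "gamma"),
        ("b2", "B", "top", "gamma"),
        ("b2", "B", "top", "delta"),
    ]
    frame = pd.DataFrame(
        rows, columns=["participant_id", "grp", "cue", "response"]
    )
    study = fa.import_study(frame, participant_vars=["grp"])
    study = fa.set_targets(study, "responses")
    study.targets["cluster"] = [1, 1, 2, 2]  # alpha,beta -> 1; gamma,delta -> 2
    study.targets["valence"] = [6.0, 6.0, 9.0, np.nan]
    return study


class TestCrossTargets:
    def test_manual_enumeration(self, grouped_study):
        table = fa.cross_targets(grouped_study, "grp", "cluster")
        assert table.loc["A"].tolist() == [3, 1]
        assert table.loc["B"].tolist() == [1, 3]

    def test_normalized_rows_sum_to_one(self, grouped_study):
        table = fa.cross_targets(grouped_study, "grp", "cluster", normalize=True)
        assert table.sum(axis=1).tolist() == pytest.approx([1.0, 1.0])

    def test_cell_total_conservation(self, grouped_study):
        table = fa.cross_targets(grouped_study, "grp", "cluster")
        assert table.to_numpy().sum() == len(grouped_study.responses)

    def test_group_without_tokens_gets_zero_then_nan_row(self, grouped_study):
        extra = grouped_study.copy()
        extra.participants = pd.concat(
            [extra.participants, pd.DataFrame([{"participant_id": "c1", "grp": "C"}])],
            ignore_index=True,
        )
        counts = fa.cross_targets(extra, "grp", "cluster")
        assert counts.loc["C"].tolist() == [0, 0]
        props = fa.cross_targets(extra, "grp", "cluster", normalize=True)
        assert props.loc["C"].isna().all()

    def test_continuous_target_variable_redirected(self, grouped_study):
        grouped_study.targets["score"] = np.linspace(0, 1, 4) + np.arange(4) * 0.123
        grouped_study.targets["score"] = grouped_study.targets["score"].astype(float)
        many = grouped_study.copy()
        many.targets = pd.DataFrame(
            {
                "target": [f"t{i}" for i in range(30)],
                "score": np.random.default_rng(0).random(30),
            }
        )
        with pytest.raises(UsageError, match="compare_targets"):
            fa.cross_targets(many, "grp", "score")

    def test_unknown_variable_rejected(self, grouped_study):
        with pytest.raises(SchemaError):
            fa.cross_targets(grouped_study, "nope", "cluster")


class TestCompareTargets:
    def test_frequency_weighted_mean(self, grouped_study):
        # group A tokens with valence: alpha(6) x2, beta(6), gamma(9) -> 6.75
        out = fa.compare_targets(grouped_study, "grp", "valence", "mean")
        row = out.set_index("grp").loc["A"]
        assert row["valence"] == pytest.approx((6 + 6 + 6 + 9) / 4)

    def test_tokens_without_norm_value_counted_as_missing(self, grouped_study):
        out = fa.compare_targets(grouped_study, "grp", "valence", "mean")
        row = out.set_index("grp").loc["B"]
        assert row["n_missing"] == 1  # the delta token
        assert row["n_tokens"] == 3
        assert row["valence"] == pytest.approx((6 + 9 + 9) / 3)

    def test_identical_distributions_give_identical_summaries(self):
        rows = []
        for g, p in (("A", "a1"), ("B", "b1")):
            rows += [(p, g, "top", "x"), (p, g, "top", "y")]
        frame = pd.DataFrame(
            rows, columns=["participant_id", "grp", "cue", "response"]
        )
        study = fa.set_targets(
            fa.import_study(frame, participant_vars=["grp"]), "responses"
        )
        study.targets["valence"] = [2.0, 8.0]
        out = fa.compare_targets(study, "grp", "valence", "mean")
        assert out["valence"].nunique() == 1

    def test_constant_characteristic_returns_constant(self, grouped_study):
        grouped_study.targets["constant"] = 4.2
        out = fa.compare_targets(grouped_study, "grp", "constant", "mean")
        assert out["constant"].tolist() == pytest.approx([4.2, 4.2])

    def test_non_numeric_characteristic_rejected(self, grouped_study):
        grouped_study.targets["label"] = list("wxyz")
        with pytest.raises(UsageError):
            fa.compare_targets(grouped_study, "grp", "label")


def random_two_group_study(seed, n_cues=40, vocab=200, tokens_per_cue=30):
    """Null model: both groups answer every cue with independent uniform
    draws from a shared vocabulary — no shared structure."""
    rng = np.random.default_rng(seed)
    words = [f"w{i:03d}" for i in range(vocab)]
    rows = []
    for g, pid in (("A", "a1"), ("B", "b1")):
        for c in range(n_cues):
            for _ in range(tokens_per_cue):
                rows.append((pid, g, f"cue{c:02d}", words[rng.integers(vocab)]))
    frame = pd.DataFrame(
        rows, columns=["participant_id", "grp", "cue", "response"]
    )
    return fa.set_targets(
        fa.import_study(frame, participant_vars=["grp"]), "cues"
    )


class TestRSA:
    def test_group_against_itself_is_unity(self, small_study):
        result = fa.rsa_self(small_study, "gender", "male", n_dim=15)
        assert result.rho == pytest.approx(1.0)

    def test_duplicated_groups_give_unity(self):
        rows = []
        for g, pid in (("A", "a1"), ("B", "b1")):
            rows += [
                (pid, g, "top", "x"),
                (pid, g, "top", "y"),
                (pid, g, "x", "u"),
                (pid, g, "x", "v"),
                (pid, g, "x", "u"),
                (pid, g, "y", "v"),
                (pid, g, "y", "w"),
                (pid, g, "y", "w"),
            ]
        frame = pd.DataFrame(
            rows, columns=["participant_id", "grp", "cue", "response"]
        )
        study = fa.set_targets(
            fa.import_study(frame, participant_vars=["grp"]), "cues"
        )
        results = fa.compare_embeddings(study, "grp", n_dim=3)
        assert len(results) == 1
        assert results[0].rho == pytest.approx(1.0)
        assert results[0].shared_target_count == 3

    @pytest.mark.parametrize("rsa_type", ["lower_triangle", "row_wise"])
    def test_independent_groups_near_zero(self, rsa_type):
        study = random_two_group_study(seed=21)
        results = fa.compare_embeddings(study, "grp", type=rsa_type, n_dim=30)
        assert abs(results[0].rho) < 0.1

    def test_lower_triangle_invariant_to_shared_target_permutation(self):
        study = random_two_group_study(seed=22, n_cues=12, vocab=60)
        base = fa.compare_embeddings(study, "grp", n_dim=10)[0]
        permuted = study.copy()
        rng = np.random.default_rng(0)
        order = rng.permutation(len(permuted.targets))
        permuted.targets = permuted.targets.iloc[order].reset_index(drop=True)
        again = fa.compare_embeddings(permuted, "grp", n_dim=10)[0]
        assert again.rho == pytest.approx(base.rho, abs=1e-12)

    def test_too_few_shared_targets_rejected(self):
        rows = [
            ("a1", "A", "top", "x"),
            ("a1", "A", "top", "y"),
            ("b1", "B", "top", "x"),
            ("b1", "B", "top", "z"),
        ]
        frame = pd.DataFrame(
            rows, columns=["participant_id", "grp", "cue", "response"]
        )
        study = fa.set_targets(
            fa.import_study(frame, participant_vars=["grp"]), "cues"
        )
        with pytest.raises(UsageError, match="shared"):
            fa.compare_embeddings(study, "grp")

    def test_multi_variable_call_adds_interaction_grouping(self, small_study):
        results = fa.compare_embeddings(
            small_study, ["gender", "education"], n_dim=10
        )
        variables = {r.variable for r in results}
        assert variables == {"gender", "education", "gender x education"}
        frame = fa.rsa_frame(results)
        # 1 gender pair + 1 education pair + C(4,2) interaction pairs
        assert len(frame) == 1 + 1 + 6
        assert ((frame["rho"] <= 1) & (frame["rho"] >= -1)).all()

    def test_response_targets_rejected(self, toy_study):
        study = fa.set_targets(toy_study, "both")
        with pytest.raises(UsageError):
            fa.compare_embeddings(study, "gender")
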