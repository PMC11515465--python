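import numpy as np
import pandas as pd
import pytest

from balmet import (
    ConfusionMatrix,
    MrmcModel,
    MrmcTable,
    RateQuartet,
    ScoreSet,
    UndefinedMetricError,
    auroc,
    bootstrap_difference_ci,
    bootstrap_metric_ci,
    generate_synthetic_mrmc,
    prevalence_bias,
    rates,
    reader_average_cm,
    reconstruct_counts,
)
from conftest import random_matrices


def make_table(rows, cut=4.0):
    return MrmcTable(
        data=pd.DataFrame(rows, columns=["modality", "reader", "case", "truth", "rating"]),
        positivity_cut=cut,
    )


def perfect_table(n_pos=3, n_neg=5, readers=2):
    rows = []
    for r in range(readers):
        for c in range(n_pos + n_neg):
            truth = int(c < n_pos)
            rows.append((1, r, c, truth, 6 if truth else 1))
    return make_table(rows)


class TestReaderAverage:
    def test_identical_readers_equal_single_reader(self):
        t = perfect_table(readers=4)
        cm = reader_average_cm(t, 1)
        assert cm.as_tuple() == (3, 0, 0, 5)

    def test_two_reader_cellwise_mean(self):
        rows = [
            # reader 0 perfect, reader 1 exactly wrong, on the same two cases
            (1, 0, 0, 1, 6), (1, 0, 1, 0, 1),
            (1, 1, 0, 1, 1), (1, 1, 1, 0, 6),
        ]
        cm = reader_average_cm(make_table(rows), 1)
        assert cm.as_tuple() == (0.5, 0.5, 0.5, 0.5)

    def test_prevalence_survives_averaging(self):
        t = generate_synthetic_mrmc(n_cases=663, prevalence=0.074, n_readers=3, seed=0)
        prev, _ = prevalence_bias(reader_average_cm(t, 1))
        assert prev == pytest.approx(49 / 663, abs=1e-12)

    def test_missing_ratings_rejected(self):
        rows = [(1, 0, 0, 1, 6), (1, 0, 1, 0, 1), (1, 1, 0, 1, 6)]  # reader 1 skips case 1
        with pytest.raises(ValueError, match="missing"):
            reader_average_cm(make_table(rows), 1)

    def test_unknown_modality(self):
        with pytest.raises(KeyError):
            reader_average_cm(perfect_table(), 99)


class TestTableValidation:
    def test_truth_must_be_case_constant(self):
        rows = [(1, 0, 0, 1, 6), (1, 1, 0, 0, 6)]
        with pytest.raises(ValueError, match="truth differs"):
            make_table(rows)

    def test_missing_columns(self):
        with pytest.raises(ValueError, match="missing columns"):
            MrmcTable(data=pd.DataFrame({"modality": [1], "reader": [1]}))

    def test_csv_round_trip(self, tmp_path):
        t = generate_synthetic_mrmc(n_cases=40, prevalence=0.25, n_readers=2, seed=3)
        path = tmp_path / "ratings.csv"
        t.to_csv(path)
        back = MrmcTable.from_csv(path, positivity_cut=t.positivity_cut)
        pd.testing.assert_frame_equal(
            back.data, t.data[list(back.data.columns)], check_dtype=False
        )


class TestReconstructCounts:
    def test_breast_cancer_matrices(self):
        got = reconstruct_counts(663, 0.074, RateQuartet(0.918, 0.883, 0.385, 0.993))
        assert got.as_tuple() == (45, 72, 4, 542)
        got = reconstruct_counts(663, 0.074, RateQuartet(0.901, 0.807, 0.271, 0.991))
        assert got.as_tuple() == (44, 117, 5, 497)

    def test_round_trip_identity(self, rng):
        for cm in random_matrices(rng, 25, max_cell=120):
            prev, _ = prevalence_bias(cm)
            got = reconstruct_counts(int(cm.n), prev, rates(cm))
            assert got.as_tuple() == cm.as_tuple()

    def test_perfect_quartet(self):
        assert reconstruct_counts(10, 0.5, RateQuartet(1, 1, 1, 1)).as_tuple() == (5, 0, 0, 5)

    def test_infeasible(self):
        with pytest.raises(ValueError, match="infeasible"):
            reconstruct_counts(10, 0.01, RateQuartet(0.9, 0.9, 0.5, 0.99))


class TestBootstrapStandalone:
    def test_degenerate_perfect_table(self):
        r = bootstrap_metric_ci(perfect_table(), 1, "g4", B=200, seed=0)
        assert r.estimate == 1.0
        assert (r.ci_lower, r.ci_upper) == (1.0, 1.0)

    def test_single_case_per_stratum_zero_width(self):
        rows = [(1, 0, 0, 1, 6), (1, 0, 1, 0, 1)]
        r = bootstrap_metric_ci(make_table(rows), 1, "g4", B=100, seed=0)
        assert r.ci_lower == r.ci_upper == r.estimate

    def test_every_replicate_preserves_prevalence(self):
        t = generate_synthetic_mrmc(n_cases=80, prevalence=0.2, n_readers=3, seed=5)
        prev = t.prevalence

        def replicate_prevalence(cm):
            return (cm.tp + cm.fn) / cm.n

        r = bootstrap_metric_ci(
            t, 1, replicate_prevalence, B=300, seed=1, keep_replicates=True
        )
        assert np.all(r.replicates == prev)

    def test_redraw_budget_abort(self):
        # two positive cases, one called positive: ~25% of stratified
        # resamples contain no true-positive calls, far beyond the 1% budget
        rows = [(1, 0, 0, 1, 6), (1, 0, 1, 1, 1), (1, 0, 2, 0, 1), (1, 0, 3, 0, 1)]
        t = make_table(rows)

        def undefined_without_tp(cm):
            if cm.tp == 0:
                raise UndefinedMetricError("no true positives in replicate")
            return cm.tp

        assert undefined_without_tp(reader_average_cm(t, 1)) == 1  # plug-in is defined
        with pytest.raises(RuntimeError, match="undefined"):
            bootstrap_metric_ci(t, 1, undefined_without_tp, B=200, seed=0)

    def test_ci_ordering_and_metadata(self):
        t = generate_synthetic_mrmc(n_cases=120, prevalence=0.25, n_readers=3, seed=9)
        r = bootstrap_metric_ci(t, 2, "p4", B=400, level=0.9, seed=21)
        assert r.ci_lower <= r.ci_upper
        assert r.level == 0.9 and r.B == 400 and r.metric == "p4" and r.seed == 21


class TestBootstrapDifference:
    def test_identical_modalities_crossed_is_degenerate_zero(self):
        t = generate_synthetic_mrmc(
            n_cases=60, prevalence=0.25, n_readers=2, modality_delta=0.0, seed=2
        )
        # duplicate modality 1's ratings as modality 2 so both arms are identical
        d1 = t.data[t.data["modality"] == 1]
        d2 = d1.assign(modality=2)
        tt = MrmcTable(pd.concat([d1, d2]), positivity_cut=t.positivity_cut)
        r = bootstrap_difference_ci(tt, 1, 2, "g4", B=200, seed=0, mode="crossed")
        assert r.estimate == 0.0
        assert (r.ci_lower, r.ci_upper) == (0.0, 0.0)

    def test_crossed_no_wider_than_nested_under_positive_correlation(self):
        t = generate_synthetic_mrmc(
            n_cases=300, prevalence=0.25, n_readers=4, modality_delta=0.02,
            case_effect_var=0.6, seed=13,
        )
        crossed = bootstrap_difference_ci(t, 2, 1, "g4", B=800, seed=3, mode="crossed")
        nested = bootstrap_difference_ci(t, 2, 1, "g4", B=800, seed=3, mode="nested")
        w_crossed = crossed.ci_upper - crossed.ci_lower
        w_nested = nested.ci_upper - nested.ci_lower
        assert w_crossed <= w_nested * 1.05  # up to Monte-Carlo noise

    def test_bad_mode(self):
        t = perfect_table()
        with pytest.raises(ValueError, match="mode"):
            bootstrap_difference_ci(t, 1, 1, "g4", mode="paired")


class TestGenerator:
    def test_null_modality_effect_pooled_auroc(self):
        t = generate_synthetic_mrmc(
            n_cases=400, prevalence=0.3, n_readers=5, modality_delta=0.0, seed=17
        )
        diffs = []
        truth = t.case_truth()
        for r in t.readers:
            per_mod = []
            for m in (1, 2):
                sub = t.data[(t.data["modality"] == m) & (t.data["reader"] == r)]
                sub = sub.set_index("case").loc[truth.index]
                per_mod.append(
                    auroc(ScoreSet(scores=sub["rating"].to_numpy(float),
                                   truth=truth.to_numpy()))
                )
            diffs.append(per_mod[0] - per_mod[1])
        assert abs(np.mean(diffs)) < 0.02

    def test_single_reader_two_levels_is_binary_classifier(self):
        t = generate_synthetic_mrmc(
            n_cases=50, prevalence=0.3, n_readers=1, rating_levels=2, seed=4
        )
        assert set(t.data["rating"].unique()) <= {1, 2}
        assert t.positivity_cut == 2
        cm = reader_average_cm(t, 1)
        assert all(float(c).is_integer() for c in cm.as_tuple())

    def test_breast_cancer_regime_band(self):
        """At the published study's design the reader-average rates sit within
        +/-0.05 of the published quartet (sanity band, not a point target)."""
        target_tpr, target_tnr = 0.918, 0.883  # better modality
        tprs, tnrs = [], []
        for seed in range(5):
            t = generate_synthetic_mrmc(
                n_cases=663, prevalence=0.074, n_readers=10,
                reader_auroc_mean=0.93, reader_auroc_sd=0.02,
                modality_delta=0.03, rating_levels=6, seed=seed,
            )
            q = rates(reader_average_cm(t, 2))
            tprs.append(q.tpr)
            tnrs.append(q.tnr)
        assert np.mean(tprs) == pytest.approx(target_tpr, abs=0.05)
        assert np.mean(tnrs) == pytest.approx(target_tnr, abs=0.05)

    def test_parameter_domains(self):
        with pytest.raises(ValueError):
            generate_synthetic_mrmc(rating_levels=1)
        with pytest.raises(ValueError):
            generate_synthetic_mrmc(n_cases=10, prevalence=0.01)


@pytest.fixture(scope="module")
def fitted():
    t = generate_synthetic_mrmc(
        n_cases=150, prevalence=0.25, n_readers=3, modality_delta=0.05, seed=31
    )
    return MrmcModel(t).fit(B=300, seed=8, mode="nested")


class TestModel:
    def test_frame_covers_modalities_and_contrast(self, fitted):
        df = fitted.frame()
        assert set(df["modality_or_contrast"]) == {"1", "2", "1 - 2"}
        assert set(df["metric"]) == {"g4", "p4", "mcc_scaled"}
        assert len(df) == 9

    def test_get_and_effect_direction(self, fitted):
        d = fitted.get("1 - 2", "g4")
        assert d.estimate < 0  # modality 2 carries the +0.05 AUROC shift

    def test_summary_mentions_design(self, fitted):
        s = fitted.summary()
        assert "prevalence" in s and "B = 300" in s and "nested" in s

    def test_from_dataframe_equivalent(self, fitted):
        t = fitted.model.table
        m2 = MrmcModel.from_dataframe(t.data, positivity_cut=t.positivity_cut)
        assert reader_average_cm(m2.table, 1) == reader_average_cm(t, 1)
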