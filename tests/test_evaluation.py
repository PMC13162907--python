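"""Leakage-aware splits, macro metrics, OOF confusion, session statistics,
noise sweep plumbing, Wilcoxon exactness, and the background probe."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from pigvoc.audio import LogMelSpectrogram
from pigvoc.errors import (
    CoverageError, InvalidInputError, LeakageError, SplitInfeasibleError,
)
from pigvoc.evaluation import (
    CLASSES, SplitAssignment, assign_groups, background_probe,
    compute_metrics, delta_noon, grouped_holdout_split, grouped_kfold,
    loso_by_session, noise_robustness_sweep, oof_confusion, session_summary,
    verify_no_leakage, wilcoxon_fold_test,
)
from pigvoc.synthetic import (
    DatasetManifest, SynthConfig, generate_dataset, synthesize_noise_pool,
)


def manifest_from_rows(rows):
    df = pd.DataFrame(rows)
    df["sample_id"] = np.arange(len(df))
    if "pig_id" not in df:
        df["pig_id"] = None
    df["pig_id"] = df["pig_id"].where(df["pig_id"].notna(), None)
    if "close_range" not in df:
        df["close_range"] = False
    df["close_range"] = df["close_range"].map(lambda v: bool(v) if v == v else False)
    df["mode"] = np.where(df["close_range"], "close", "routine")
    return DatasetManifest(records=df, seed=0, config=SynthConfig())


class TestAssignGroups:
    def test_same_pen_date_session_share_token(self):
        m = manifest_from_rows([
            dict(label="normal", pen_id="pen1", date="d1", session="morning"),
            dict(label="normal", pen_id="pen1", date="d1", session="morning"),
            dict(label="normal", pen_id="pen2", date="d1", session="morning"),
        ])
        tok = assign_groups(m)
        assert tok[0] == tok[1]
        assert tok[0] != tok[2]

    def test_one_pig_one_token_across_dates(self):
        m = manifest_from_rows([
            dict(label="cough", pen_id="obs", date="d1", session="morning",
                 pig_id="pigA", close_range=True),
            dict(label="cough", pen_id="obs", date="d2", session="noon",
                 pig_id="pigA", close_range=True),
            dict(label="cough", pen_id="pen1", date="d1", session="morning"),
        ])
        tok = assign_groups(m)
        assert tok[0] == tok[1]  # same pig, different dates
        assert tok[0] != tok[2]  # routine cough uses pen x date x session


class TestGroupedHoldout:
    def test_singleton_groups_hit_exact_ratios(self):
        rows = [
            dict(label=CLASSES[i % 5], pen_id=f"p{i}", date="d", session="morning")
            for i in range(100)
        ]
        split = grouped_holdout_split(manifest_from_rows(rows), seed=0)
        counts = split.assignment.value_counts()
        assert counts["train"] == 80
        assert counts["val"] == 10
        assert counts["test"] == 10

    def test_no_group_spans_partitions(self, small_manifest):
        split = grouped_holdout_split(small_manifest, seed=1)
        tokens = assign_groups(small_manifest)
        for tok in np.unique(tokens):
            parts = split.assignment[tokens == tok].unique()
            assert len(parts) == 1

    def test_equal_group_allocation_within_one_group_size(self):
        rows = []
        for g in range(10):
            for _ in range(10):
                rows.append(dict(label="normal", pen_id=f"p{g}",
                                 date="d", session="morning"))
        split = grouped_holdout_split(manifest_from_rows(rows), seed=3)
        counts = split.assignment.value_counts()
        assert abs(counts["train"] - 80) <= 10
        assert abs(counts.get("val", 0) - 10) <= 10
        assert abs(counts.get("test", 0) - 10) <= 10

    def test_too_few_groups_rejected(self):
        rows = [
            dict(label="cough", pen_id="p1", date="d", session="morning"),
            dict(label="cough", pen_id="p2", date="d", session="morning"),
        ]
        with pytest.raises(SplitInfeasibleError):
            grouped_holdout_split(manifest_from_rows(rows))


class TestGroupedKfold:
    def test_five_equal_groups_one_per_fold(self):
        rows = []
        for g in range(5):
            for _ in range(4):
                rows.append(dict(label="normal", pen_id=f"p{g}", date="d",
                                 session="morning"))
        split = grouped_kfold(manifest_from_rows(rows), k=5, seed=0)
        sizes = split.assignment.value_counts()
        assert (sizes == 4).all()

    def test_folds_partition_all_samples(self, small_manifest):
        split = grouped_kfold(small_manifest, k=5, seed=2)
        assert len(split.assignment) == len(small_manifest)
        assert set(split.assignment.unique()) == set(range(5))

    def test_fold_spread_bounded_by_max_group(self, small_manifest):
        split = grouped_kfold(small_manifest, k=5, seed=2)
        tokens = assign_groups(small_manifest)
        max_group = max(np.sum(tokens == t) for t in np.unique(tokens))
        sizes = split.assignment.value_counts()
        assert sizes.max() - sizes.min() <= max_group

    def test_fewer_groups_than_k_rejected(self):
        rows = [dict(label="normal", pen_id="p1", date="d", session="morning")] * 3
        with pytest.raises(SplitInfeasibleError):
            grouped_kfold(manifest_from_rows(rows), k=5)


class TestLoso:
    def test_three_sessions_three_splits(self, small_manifest):
        splits = loso_by_session(small_manifest)
        assert [s for s, _ in splits] == ["morning", "noon", "evening"]

    def test_test_session_never_in_train_or_val(self, small_manifest):
        for session, split in loso_by_session(small_manifest):
            sessions = small_manifest.records["session"].to_numpy()
            for part in ("train", "val"):
                assert not np.any(sessions[split.indices(part)] == session)
            assert np.all(sessions[split.indices("test")] == session)

    def test_val_fraction_respected(self):
        rows = []
        for g in range(30):
            for _ in range(5):
                rows.append(dict(
                    label=CLASSES[g % 5], pen_id=f"p{g}", date="d",
                    session=["morning", "noon", "evening"][g % 3],
                ))
        m = manifest_from_rows(rows)
        for _, split in loso_by_session(m, val_fraction=0.2):
            n_dev = len(split.indices("train")) + len(split.indices("val"))
            frac = len(split.indices("val")) / n_dev
            assert 0.1 <= frac <= 0.3  # group-level allocation is approximate

    def test_missing_session_rejected(self):
        rows = [dict(label="normal", pen_id="p1", date="d", session="morning")]
        with pytest.raises(SplitInfeasibleError):
            loso_by_session(manifest_from_rows(rows))


class TestLeakageVerification:
    def test_pig_spanning_partitions_detected(self):
        m = manifest_from_rows([
            dict(label="cough", pen_id="a", date="d1", session="morning",
                 pig_id="pigZ", close_range=True),
            dict(label="cough", pen_id="a", date="d2", session="noon",
                 pig_id="pigZ", close_range=True),
        ])
        bad = SplitAssignment(pd.Series(["train", "val"]), kind="holdout")
        with pytest.raises(LeakageError):
            verify_no_leakage(m, bad)

    def test_group_spanning_partitions_detected(self):
        m = manifest_from_rows([
            dict(label="normal", pen_id="p", date="d", session="noon"),
            dict(label="normal", pen_id="p", date="d", session="noon"),
        ])
        bad = SplitAssignment(pd.Series(["train", "test"]), kind="holdout")
        with pytest.raises(LeakageError):
            verify_no_leakage(m, bad)


class TestComputeMetrics:
    def test_perfect_predictions(self):
        y = np.array(list(CLASSES) * 4)
        score = np.zeros((len(y), 5))
        for i, lab in enumerate(y):
            score[i, CLASSES.index(lab)] = 1.0
        rep = compute_metrics(y, y, score)
        assert rep.accuracy == 100.0
        assert rep.macro_f1 == 100.0
        assert rep.macro_auroc == 1.0

    def test_toy_confusion_matches_hand_tally(self):
        # printed counts [[5,1,0],[0,4,2],[1,0,7]] over three classes
        labels = ("cough", "scream", "estrus")
        counts = np.array([[5, 1, 0], [0, 4, 2], [1, 0, 7]])
        y_true, y_pred = [], []
        for i in range(3):
            for j in range(3):
                y_true += [labels[i]] * counts[i, j]
                y_pred += [labels[j]] * counts[i, j]
        rep = compute_metrics(np.array(y_true), np.array(y_pred), labels=labels)
        # brute-force oracle
        tp = np.diag(counts)
        fp = counts.sum(axis=0) - tp
        fn = counts.sum(axis=1) - tp
        prec = tp / (tp + fp)
        rec = tp / (tp + fn)
        f1 = 2 * prec * rec / (prec + rec)
        assert np.isclose(rep.accuracy, 100 * tp.sum() / counts.sum())
        assert np.isclose(rep.macro_precision, 100 * prec.mean())
        assert np.isclose(rep.macro_recall, 100 * rec.mean())
        assert np.isclose(rep.macro_f1, 100 * f1.mean())

    def test_auroc_extremes(self):
        y = np.array(["cough"] * 3 + ["scream"] * 3)
        perfect = np.zeros((6, 5))
        perfect[:3, 0] = [0.9, 0.8, 0.7]
        perfect[3:, 0] = [0.2, 0.1, 0.0]
        perfect[:, 1] = 1 - perfect[:, 0]
        rep = compute_metrics(y, y, perfect, labels=("cough", "scream"))
        assert rep.macro_auroc == 1.0
        interleaved = perfect.copy()
        interleaved[:, 0] = [0.9, 0.5, 0.1, 0.9, 0.5, 0.1]
        interleaved[:, 1] = [0.1, 0.5, 0.9, 0.1, 0.5, 0.9]
        rep2 = compute_metrics(y, y, interleaved, labels=("cough", "scream"))
        assert np.isclose(rep2.macro_auroc, 0.5)

    def test_absent_class_excluded_with_warning(self):
        y_true = np.array(["cough", "scream", "cough"])
        y_pred = np.array(["cough", "scream", "estrus"])
        with pytest.warns(UserWarning, match="absent"):
            rep = compute_metrics(y_true, y_pred)
        present = [pc for pc in rep.per_class if not np.isnan(pc.precision)]
        assert {pc.label for pc in present} == {"cough", "scream"}

    @given(st.lists(st.tuples(st.integers(0, 4), st.integers(0, 4)),
                    min_size=1, max_size=50))
    def test_matches_brute_force_tally_on_random_vectors(self, pairs):
        y_true = np.array([CLASSES[a] for a, _ in pairs])
        y_pred = np.array([CLASSES[b] for _, b in pairs])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = compute_metrics(y_true, y_pred)
        # independent tally
        precs, recs, f1s = [], [], []
        for lab in CLASSES:
            tp = int(np.sum((y_true == lab) & (y_pred == lab)))
            fp = int(np.sum((y_true != lab) & (y_pred == lab)))
            fn = int(np.sum((y_true == lab) & (y_pred != lab)))
            if tp + fn == 0:
                continue
            p = tp / (tp + fp) if tp + fp else 0.0
            r = tp / (tp + fn)
            precs.append(p)
            recs.append(r)
            f1s.append(2 * p * r / (p + r) if p + r else 0.0)
        assert np.isclose(rep.accuracy, 100 * np.mean(y_true == y_pred))
        assert np.isclose(rep.macro_precision, 100 * np.mean(precs))
        assert np.isclose(rep.macro_recall, 100 * np.mean(recs))
        assert np.isclose(rep.macro_f1, 100 * np.mean(f1s))

    def test_auroc_invariant_to_monotone_transform(self, rng):
        y = np.array(["cough"] * 10 + ["scream"] * 10)
        rng.shuffle(y)
        score = np.zeros((20, 5))
        score[:, 0] = rng.random(20)
        score[:, 1] = 1 - score[:, 0]
        a = compute_metrics(y, y, score, labels=("cough", "scream")).macro_auroc
        transformed = score.copy()
        transformed[:, 0] = np.exp(5 * score[:, 0])  # strictly monotone
        transformed[:, 1] = np.log1p(score[:, 1])
        b = compute_metrics(y, y, transformed,
                            labels=("cough", "scream")).macro_auroc
        assert np.isclose(a, b)


class TestOofConfusion:
    def _folds(self, n=100, k=5, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.choice(CLASSES, n)
        p = rng.choice(CLASSES, n)
        idx = np.arange(n)
        return [(idx[f::k], y[f::k], p[f::k]) for f in range(k)], y, p

    def test_total_equals_sample_count(self):
        folds, _, _ = self._folds()
        cm = oof_confusion(folds, n_samples=100)
        assert cm.counts.sum() == 100

    def test_row_percentages_sum_to_100(self):
        folds, _, _ = self._folds()
        cm = oof_confusion(folds)
        pct = cm.row_normalized()
        sums = pct.sum(axis=1)[cm.counts.sum(axis=1) > 0]
        assert np.all(np.abs(sums - 100.0) < 0.5)  # rounding to one decimal

    def test_fold_order_irrelevant(self):
        folds, _, _ = self._folds()
        a = oof_confusion(folds).counts
        b = oof_confusion(folds[::-1]).counts
        assert np.array_equal(a, b)

    def test_duplicate_sample_rejected(self):
        folds, y, p = self._folds()
        dup = folds + [folds[0]]
        with pytest.raises(CoverageError):
            oof_confusion(dup)

    def test_missing_sample_rejected(self):
        folds, _, _ = self._folds()
        with pytest.raises(CoverageError):
            oof_confusion(folds[:-1], n_samples=100)


class TestSessionStatistics:
    # (morning, noon, evening) -> published noon-shift values
    PUBLISHED = [
        ((96.52, 96.03, 96.79), 0.62),
        ((95.63, 94.58, 95.87), 1.17),
        ((95.02, 94.23, 95.47), 1.02),
        ((94.18, 93.41, 94.57), 0.97),
        ((92.83, 91.79, 93.07), 1.16),
        ((91.37, 90.63, 91.88), 1.00),
    ]

    @pytest.mark.parametrize("vals,expected", PUBLISHED)
    def test_delta_noon_reproduces_published_values(self, vals, expected):
        per = dict(zip(("morning", "noon", "evening"), vals))
        assert round(delta_noon(per), 2) == expected

    def test_equal_sessions_give_zero(self):
        per = dict(morning=90.0, noon=90.0, evening=90.0)
        assert delta_noon(per) == 0.0
        assert session_summary(per).sd == 0.0

    def test_summary_mean_sd_match_published_row(self):
        rep = session_summary(dict(morning=96.52, noon=96.03, evening=96.79))
        assert round(rep.mean, 2) == 96.45
        assert round(rep.sd, 2) == 0.39
        assert round(rep.delta_noon, 2) == 0.62

    def test_mean_sd_match_two_pass_oracle(self, rng):
        vals = rng.uniform(80, 100, 3)
        per = dict(zip(("morning", "noon", "evening"), vals))
        rep = session_summary(per)
        mean = sum(vals) / 3
        sd = np.sqrt(sum((v - mean) ** 2 for v in vals) / 2)
        assert abs(rep.mean - mean) < 1e-12
        assert abs(rep.sd - sd) < 1e-12

    def test_missing_session_rejected(self):
        with pytest.raises(InvalidInputError):
            delta_noon(dict(morning=90.0, evening=91.0))


class TestWilcoxon:
    def test_identical_lists_give_p_one(self):
        with pytest.warns(UserWarning):
            assert wilcoxon_fold_test([1, 2, 3], [1, 2, 3]) == 1.0

    def test_five_positive_differences_exact_p(self):
        a = [96.0, 95.5, 97.0, 96.2, 95.9]
        b = [95.0, 94.5, 96.0, 95.2, 94.9]
        p = wilcoxon_fold_test(a, b)
        # exhaustive sign-assignment oracle: all 2^5 assignments, two-sided
        n = 5
        ranks = np.arange(1, n + 1)
        w_obs = ranks.sum()  # all differences positive
        stats = []
        for signs in range(2 ** n):
            s = np.array([(signs >> i) & 1 for i in range(n)])
            stats.append((ranks * s).sum())
        stats = np.array(stats)
        w_min = min(w_obs, ranks.sum() - w_obs)
        p_exact = np.mean(np.minimum(stats, ranks.sum() - stats) <= w_min)
        assert np.isclose(p, p_exact)
        assert np.isclose(p, 0.0625)

    def test_antisymmetric(self, rng):
        a = rng.normal(95, 1, 5)
        b = a + rng.normal(0, 1, 5)
        assert np.isclose(wilcoxon_fold_test(a, b), wilcoxon_fold_test(b, a))


class TestNoiseSweepPlumbing:
    def _samples_and_pool(self):
        m = generate_dataset(n_per_class=2, seed=5)
        tokens = assign_groups(m)
        samples = [
            (m.waveform(i), m.records.iloc[i]["label"], tokens[i])
            for i in range(len(m))
        ]
        return samples, synthesize_noise_pool(8, seed=5)

    def test_curve_length_and_exclusivity(self):
        samples, pool = self._samples_and_pool()
        chosen = []

        def classify(w):
            chosen.append(w)
            return "normal"

        curve = noise_robustness_sweep(
            classify, samples, pool, snr_bins=(10.0, 0.0), seed=0
        )
        assert len(curve.points) == 2
        assert [p[0] for p in curve.points] == [10.0, 0.0]
        # every test clip was mixed once per bin
        assert len(chosen) == 2 * len(samples)

    def test_exclusivity_error_when_no_admissible_noise(self):
        from pigvoc.synthetic import GroupKey

        samples, pool = self._samples_and_pool()
        routine = next(s for s in samples if s[2].count("|") == 2)
        pen, date, session = routine[2].split("|")
        same = GroupKey(pen_id=pen, date=date, session=session)
        with pytest.raises(LeakageError):
            noise_robustness_sweep(
                lambda w: "normal", [routine], [(pool[0][0], same)],
                snr_bins=(0.0,),
            )


class TestBackgroundProbe:
    def _specs(self, rng, n, shift=0.0):
        return [
            LogMelSpectrogram(
                rng.normal(shift, 1.0, (16, 10)), n_mels=16
            )
            for _ in range(n)
        ]

    def test_null_calibration_near_chance(self):
        """Identically distributed regions: balanced accuracy ~ 0.5."""
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            specs = self._specs(rng, 40)
            labels = np.array(["pen", "stall"] * 20)
            groups = np.repeat(np.arange(10), 4)
            acc, _ = background_probe(specs, labels, groups, seed=seed)
            accs.append(acc)
        assert 0.40 <= np.mean(accs) <= 0.60

    def test_separable_regions_near_perfect(self, rng):
        specs = self._specs(rng, 20) + self._specs(rng, 20, shift=5.0)
        labels = np.array(["pen"] * 20 + ["stall"] * 20)
        groups = np.arange(40) % 8
        acc, auroc = background_probe(specs, labels, groups)
        assert acc > 0.95
        assert auroc > 0.95

    def test_single_class_rejected(self, rng):
        specs = self._specs(rng, 4)
        with pytest.raises(InvalidInputError):
            background_probe(specs, ["pen"] * 4, [0, 1, 2, 3])
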