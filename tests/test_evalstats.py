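"""Agreement/fragmentation statistics against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import f1_score

from minisleep import evalstats as ev
from minisleep.types import ART, STAGES, MiniEpochHypnogram, SubjectMeta

from conftest import random_hypnogram

STAGE_LIST = list(STAGES)


def hyp_from(labels, period=5.0, char=None):
    labels = np.asarray(labels, dtype="<U3")
    if char is None:
        char = np.ones(len(labels), bool)
    return MiniEpochHypnogram(labels=labels, char_flag=np.asarray(char, bool),
                              period=period)


# ---------------------------------------------------------------------------
# epoch expansion
# ---------------------------------------------------------------------------

class TestExpandEpochs:
    def test_30s_epoch_becomes_six_mini_epochs(self):
        h = hyp_from(["N2", "REM"], period=30.0)
        out = ev.expand_epochs(h)
        assert len(out) == 12
        assert (out.labels[:6] == "N2").all() and (out.labels[6:] == "REM").all()
        assert out.period == 5.0 and out.char_flag.all()

    def test_empty_input_gives_empty_output(self):
        out = ev.expand_epochs(hyp_from([], period=30.0))
        assert len(out) == 0

    def test_non_divisible_period_rejected(self):
        with pytest.raises(ValueError):
            ev.expand_epochs(hyp_from(["N2"], period=7.0), target_period=5.0)

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.sampled_from(STAGE_LIST + [ART]), min_size=1, max_size=50))
    def test_expand_collapse_roundtrip_identity(self, labels):
        h = hyp_from(labels, period=30.0)
        back = ev.collapse_to_epochs(ev.expand_epochs(h), 30.0)
        assert (back.labels == h.labels).all()


# ---------------------------------------------------------------------------
# confusion matrices
# ---------------------------------------------------------------------------

class TestBuildConfusion:
    def test_identical_sequences_yield_diagonal(self):
        rng = np.random.default_rng(0)
        h = random_hypnogram(rng, 100)
        cm = ev.build_confusion(h, h)
        assert cm.total == 100
        assert (cm.counts == np.diag(np.diag(cm.counts))).all()

    def test_artifact_exclusion(self):
        r = hyp_from(["W", "ART", "N2"])
        c = hyp_from(["W", "N2", "N3"])
        cm = ev.build_confusion(r, c)
        assert cm.total == 2
        assert cm.n_excluded_artifacts == 1

    def test_counts_match_brute_force_tally(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            r = random_hypnogram(rng, 480, p_art=0.02)
            c = random_hypnogram(rng, 480, p_art=0.02)
            cm = ev.build_confusion(r, c)
            # independent double-loop tally
            expect = np.zeros((5, 5), int)
            excl = 0
            for a, b in zip(r.labels, c.labels):
                if a == ART or b == ART:
                    excl += 1
                    continue
                expect[STAGE_LIST.index(a), STAGE_LIST.index(b)] += 1
            assert (cm.counts == expect).all()
            assert cm.n_excluded_artifacts == excl
            assert cm.total + excl == 480

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ev.build_confusion(hyp_from(["W"]), hyp_from(["W", "N1"]))


class TestF1Report:
    def test_perfect_diagonal_gives_unit_f1(self):
        cm = ev.ConfusionMatrix(np.diag([10, 5, 30, 8, 7]))
        rep = ev.f1_report(cm)
        assert all(rep.f1[s] == 1.0 for s in STAGES)
        assert rep.overall_weighted_f1 == 1.0

    def test_direct_formula(self):
        # one stage with TP=8, FP=2, FN=2 -> precision = recall = F1 = 0.8
        counts = np.zeros((5, 5), int)
        counts[2, 2] = 8
        counts[2, 0] = 2  # FN for N2
        counts[0, 2] = 2  # FP for N2
        rep = ev.f1_report(ev.ConfusionMatrix(counts))
        assert rep.precision["N2"] == pytest.approx(0.8)
        assert rep.recall["N2"] == pytest.approx(0.8)
        assert rep.f1["N2"] == pytest.approx(0.8)

    def test_absent_stage_undefined_not_zero(self):
        counts = np.zeros((5, 5), int)
        counts[0, 0] = 10
        rep = ev.f1_report(ev.ConfusionMatrix(counts))
        assert rep.f1["REM"] is None
        assert rep.support["REM"] == 0

    def test_all_zero_matrix_everything_undefined(self):
        rep = ev.f1_report(ev.ConfusionMatrix(np.zeros((5, 5), int)))
        assert all(rep.f1[s] is None for s in STAGES)
        assert rep.overall_weighted_f1 is None

    def test_weighted_overall_matches_sklearn(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            k = rng.integers(2, 6)
            used = rng.choice(5, size=k, replace=False)
            n = int(rng.integers(20, 300))
            ref = rng.choice(used, n)
            cmp = rng.choice(used, n)
            rep = ev.f1_report(ev.confusion_from_indices(ref, cmp))
            sk = f1_score(ref, cmp, average="weighted",
                          labels=list(range(5)), zero_division=0)
            assert abs(rep.overall_weighted_f1 - sk) < 1e-12

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(0, 2**31 - 1))
    def test_overall_invariant_to_stage_permutation(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 30, size=(5, 5))
        perm = rng.permutation(5)
        a = ev.f1_report(ev.ConfusionMatrix(counts)).overall_weighted_f1
        b = ev.f1_report(ev.ConfusionMatrix(counts[np.ix_(perm, perm)])
                         ).overall_weighted_f1
        assert a == pytest.approx(b, abs=1e-12)


class TestAggregateF1:
    def _reports(self, values):
        reps = []
        for v in values:
            cm = ev.ConfusionMatrix(np.diag([10, 10, 10, 10, 10]))
            rep = ev.f1_report(cm)
            rep.f1 = {s: v for s in STAGES}
            rep.overall_weighted_f1 = v
            reps.append(rep)
        return reps

    def test_zero_variance_ci_is_degenerate(self):
        agg = ev.aggregate_f1(self._reports([0.7] * 8))
        assert agg["overall"]["mean"] == pytest.approx(0.7)
        assert agg["overall"]["ci"] == (pytest.approx(0.7), pytest.approx(0.7))

    def test_stage_absent_in_one_recording_reduces_n(self):
        reps = self._reports([0.6] * 5)
        reps[0].f1["REM"] = None
        agg = ev.aggregate_f1(reps)
        assert agg["per_stage"]["REM"]["n"] == 4
        assert agg["per_stage"]["N2"]["n"] == 5

    def test_bootstrap_reproducible(self):
        vals = list(np.random.default_rng(3).uniform(0.4, 0.9, 12))
        a = ev.aggregate_f1(self._reports(vals), rng_seed=5)
        b = ev.aggregate_f1(self._reports(vals), rng_seed=5)
        assert a == b


class TestNormalizeConfusion:
    def test_diagonal_matrix_identity_fractions(self):
        cm = ev.ConfusionMatrix(np.diag([3, 4, 5, 6, 7]))
        for mode in ("row", "column"):
            out = ev.normalize_confusion(cm, mode)
            assert np.allclose(out, np.eye(5))

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(4)
        cm = ev.ConfusionMatrix(rng.integers(1, 20, (5, 5)))
        out = ev.normalize_confusion(cm, "row")
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_sum_lines_are_nan_not_zero(self):
        counts = np.zeros((5, 5), int)
        counts[0, 0] = 5
        out = ev.normalize_confusion(ev.ConfusionMatrix(counts), "row")
        assert np.isnan(out[1]).all()

    def test_hand_computed_two_stage_example(self):
        # W row: 8 scored W, 2 scored N2; N2 row: 4 scored W, 6 scored N2
        counts = np.zeros((5, 5), int)
        counts[0, 0], counts[0, 2] = 8, 2
        counts[2, 0], counts[2, 2] = 4, 6
        col = ev.normalize_confusion(ev.ConfusionMatrix(counts), "column")
        assert col[0, 0] == pytest.approx(8 / 12)
        assert col[2, 0] == pytest.approx(4 / 12)
        assert col[0, 2] == pytest.approx(2 / 8)
        row = ev.normalize_confusion(ev.ConfusionMatrix(counts), "row")
        assert row[0, 0] == pytest.approx(0.8)
        assert row[2, 2] == pytest.approx(0.6)


# ---------------------------------------------------------------------------
# transitions and fractions
# ---------------------------------------------------------------------------

class TestTransitionStats:
    def test_constant_hypnogram_zero_rates(self):
        ts = ev.transition_stats(hyp_from(["N2"] * 24))
        assert ts.any_transitions_per_min == 0.0
        assert ts.sleep_wake_transitions_per_min == 0.0

    def test_strict_alternation_eleven_per_minute(self):
        ts = ev.transition_stats(hyp_from(["W", "N1"] * 6))
        assert ts.any_transitions_per_min == pytest.approx(11.0)
        assert ts.sleep_wake_transitions_per_min == pytest.approx(11.0)

    def test_art_breaks_adjacency_without_shrinking_denominator(self):
        ts = ev.transition_stats(hyp_from(["N2", "ART", "W", "W"]))
        # N2->(gap)->W is not a transition; duration stays 4 epochs
        assert ts.any_transitions_per_min == 0.0

    def test_counts_match_brute_force_scan(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            segs = [random_hypnogram(rng, int(rng.integers(5, 200)), p_art=0.05)
                    for _ in range(2)]
            ts = ev.transition_stats(segs)
            any_n = sw_n = 0
            minutes = 0.0
            for s in segs:
                minutes += len(s) * s.period / 60
                for i in range(len(s) - 1):
                    a, b = s.labels[i], s.labels[i + 1]
                    if a == ART or b == ART:
                        continue
                    if a != b:
                        any_n += 1
                    if (a == "W") != (b == "W"):
                        sw_n += 1
            assert ts.any_transitions_per_min == pytest.approx(any_n / minutes)
            assert ts.sleep_wake_transitions_per_min == pytest.approx(sw_n / minutes)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_any_rate_invariant_under_stage_relabeling(self, seed):
        rng = np.random.default_rng(seed)
        h = random_hypnogram(rng, 120)
        perm = dict(zip(STAGE_LIST, rng.permutation(STAGE_LIST)))
        relabeled = hyp_from([perm[x] for x in h.labels])
        a = ev.transition_stats(h).any_transitions_per_min
        b = ev.transition_stats(relabeled).any_transitions_per_min
        assert a == pytest.approx(b)

    def test_single_label_segment_counts_duration(self):
        ts = ev.transition_stats([hyp_from(["N2"]), hyp_from(["W"] * 12)])
        assert ts.any_transitions_per_min == 0.0


class TestStageFractions:
    def test_pure_n2(self):
        fr = ev.stage_fractions(hyp_from(["N2"] * 10))
        assert fr["N2"] == 1.0 and sum(fr.values()) == 1.0

    def test_half_n2(self):
        labels = ["N2"] * 120 + ["REM"] * 120
        assert ev.stage_fractions(hyp_from(labels))["N2"] == pytest.approx(0.5)

    def test_fractions_match_tally(self):
        rng = np.random.default_rng(6)
        h = random_hypnogram(rng, 480, p_art=0.05)
        fr = ev.stage_fractions(h)
        non_art = (h.labels != ART).sum()
        for s in STAGES:
            assert fr[s] * non_art == pytest.approx((h.labels == s).sum())

    def test_all_art_undefined(self):
        with pytest.raises(ValueError):
            ev.stage_fractions(hyp_from(["ART"] * 5))


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

class TestPairedCompare:
    def test_identical_vectors_null_convention(self):
        a = np.arange(10.0)
        res = ev.paired_compare(a, a)
        assert res.p_value == 1.0 and res.effect_size == 0.0

    def test_one_sided_shift_gives_closed_form_effect(self):
        n = 12
        a = np.arange(n, dtype=float)
        # distinct, all-positive differences (no rank ties):
        res = ev.paired_compare(a, a + np.arange(1, n + 1))
        # every difference negative: W = min(W+, W-) = 0 and
        # Z = (0 - n(n+1)/4) / sqrt(n(n+1)(2n+1)/24)
        mu = n * (n + 1) / 4
        sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24)
        assert res.statistic == 0.0
        assert abs(res.effect_size) == pytest.approx(mu / sd / np.sqrt(n))

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            ev.paired_compare([1, 2], [2, 3])


class TestGroupCompareLMM:
    def _metas(self, n, rng, paired=True):
        metas = []
        for i in range(n):
            fam = f"f{i % (n // 2)}" if paired else f"f{i}"
            metas.append(SubjectMeta(
                f"r{i}", "NT1" if i % 2 == 0 else "SIB",
                float(rng.uniform(15, 45)), "F" if rng.random() < 0.5 else "M",
                fam))
        return metas

    def test_null_groups_give_small_effect(self):
        rng = np.random.default_rng(7)
        metas = self._metas(60, rng)
        y = rng.uniform(0.5, 1.5, 60)  # independent of group
        res = ev.group_compare_lmm(y, metas)
        assert abs(res.effect_size) < 0.5
        assert res.p_value > 0.01

    def test_no_clustering_limit_equals_ols(self):
        import statsmodels.formula.api as smf
        import pandas as pd

        rng = np.random.default_rng(8)
        metas = self._metas(40, rng, paired=False)  # every family singleton
        y = rng.uniform(0.2, 2.0, 40)
        res = ev.group_compare_lmm(y, metas)
        assert res.model == "ols"
        df = pd.DataFrame({
            "y": np.sqrt(y),
            "is_nt1": [1.0 if m.group == "NT1" else 0.0 for m in metas],
            "age": [m.age for m in metas],
            "is_male": [1.0 if m.sex == "M" else 0.0 for m in metas],
        })
        ols = smf.ols("y ~ is_nt1 + age + is_male", df).fit()
        assert res.coefficient == pytest.approx(float(ols.params["is_nt1"]),
                                                abs=1e-6)

    def test_negative_outcome_rejected(self):
        rng = np.random.default_rng(9)
        metas = self._metas(10, rng)
        with pytest.raises(ValueError):
            ev.group_compare_lmm([-1.0] + [1.0] * 9, metas)


class TestStratifyByCharacteristics:
    def test_all_flags_true_empty_without_stratum(self):
        rng = np.random.default_rng(10)
        r = random_hypnogram(rng, 100)
        r.char_flag[:] = True
        c = random_hypnogram(rng, 100)
        out = ev.stratify_by_characteristics(r, c)
        assert out["without"] is None
        assert out["with"].cm.total <= 100

    def test_strata_confusions_sum_to_pooled(self):
        rng = np.random.default_rng(11)
        r = random_hypnogram(rng, 480, p_art=0.02)
        c = random_hypnogram(rng, 480, p_art=0.02)
        out = ev.stratify_by_characteristics(r, c)
        pooled = ev.build_confusion(r, c)
        total = np.zeros((5, 5), int)
        for key in ("with", "without"):
            if out[key] is not None:
                total += out[key].cm.counts
        assert (total == pooled.counts).all()

    def test_without_stratum_holds_context_stages_only(self):
        rng = np.random.default_rng(12)
        r = random_hypnogram(rng, 300)
        c = random_hypnogram(rng, 300)
        out = ev.stratify_by_characteristics(r, c)
        if out["without"] is not None:
            assert out["without"].support["W"] == 0
            assert out["without"].support["N3"] == 0
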