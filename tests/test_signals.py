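"""Signal-vs-abruptness regressions, ROC/AUC machinery, Youden thresholds."""

import numpy as np
import pandas as pd
import pytest

from microdyn.signals import (
    RocError,
    build_signal_series,
    pooled_threshold,
    regress_signal,
    roc_analysis,
)


def pair_auc_oracle(scores, labels):
    """Exhaustive pairwise P(score+ > score-) + 0.5 P(tie)."""
    pos = np.asarray(scores)[np.asarray(labels, bool)]
    neg = np.asarray(scores)[~np.asarray(labels, bool)]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation_gives_auc_one(self):
        curve = roc_analysis([3, 4, 5, 0, 1, 2], [1, 1, 1, 0, 0, 0])
        assert curve.auc == 1.0

    def test_random_scores_give_auc_near_half(self, rng):
        scores = rng.normal(size=4000)
        labels = rng.random(4000) < 0.5
        assert abs(roc_analysis(scores, labels).auc - 0.5) < 0.05

    def test_auc_equals_pairwise_oracle(self, rng):
        for _ in range(30):
            n = rng.integers(10, 200)
            scores = rng.integers(0, 10, n).astype(float)  # force ties
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            curve = roc_analysis(scores, labels)
            assert curve.auc == pytest.approx(pair_auc_oracle(scores, labels))

    def test_single_class_fails_with_counts(self):
        with pytest.raises(RocError, match="positives=0"):
            roc_analysis([1.0, 2.0], [0, 0])

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=100)
        labels = rng.random(100) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        a1 = roc_analysis(scores, labels).auc
        a2 = roc_analysis(np.exp(scores * 2), labels).auc
        assert a1 == pytest.approx(a2)

    def test_label_flip_maps_auc_to_complement(self, rng):
        scores = rng.normal(size=150)
        labels = scores + rng.normal(0, 1, 150) > 0
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        a = roc_analysis(scores, labels).auc
        b = roc_analysis(scores, ~labels).auc
        assert a + b == pytest.approx(1.0)

    def test_matches_sklearn_cross_check(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=80)
        labels = rng.random(80) < 0.3
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        assert roc_analysis(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores)
        )


class TestYouden:
    def test_perfect_separation_returns_gap_midpoint(self):
        curve = roc_analysis([10, 11, 12, 0, 1, 2], [1, 1, 1, 0, 0, 0])
        assert curve.youden_j == pytest.approx(1.0)
        assert curve.youden_threshold == pytest.approx((10 + 2) / 2)

    def test_binary_scores_threshold_between_zero_and_one(self):
        curve = roc_analysis([0, 0, 1, 1], [0, 0, 1, 1])
        assert 0 < curve.youden_threshold < 1

    def test_beats_every_alternative_threshold(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 200))
            scores = rng.normal(size=n)
            labels = scores * 0.8 + rng.normal(size=n) > 0
            if labels.all() or not labels.any():
                continue
            curve = roc_analysis(scores, labels)
            n_pos, n_neg = labels.sum(), (~labels).sum()

            def j_at(c):
                pred = scores >= c
                return (pred & labels).sum() / n_pos - (pred & ~labels).sum() / n_neg

            best = max(j_at(c) for c in np.unique(scores))
            assert j_at(curve.youden_threshold) == pytest.approx(best)


class TestRegressions:
    def _series(self, rows):
        return pd.DataFrame(
            rows, columns=["treatment", "replicate", "energy_gap", "abruptness"]
        )

    def test_bh_adjustment_hand_example(self):
        # p = (.01, .02, .03, .04), m = 4 -> all adjusted to 0.04
        rng = np.random.default_rng(0)
        rows = []
        targets = [0.01, 0.02, 0.03, 0.04]
        # craft per-replicate regressions with exactly these p-values is
        # impractical; instead check the BH step itself through statsmodels
        from statsmodels.stats.multitest import multipletests

        _, q, _, _ = multipletests(targets, method="fdr_bh")
        assert np.allclose(q, 0.04)

    def test_no_significance_when_all_p_one(self, rng):
        rows = []
        for rep in range(1, 5):
            x = rng.normal(size=10)
            rows += [("T", rep, v, 0.5) for v in x]  # constant response
        out = regress_signal(self._series(rows), index_columns=["energy_gap"])
        assert not out["significant"].fillna(False).any()

    def test_perfect_linear_signal_recovers_unit_slope(self):
        rows = []
        for rep in (1, 2):
            for v in np.linspace(0, 1, 12):
                rows.append(("T", rep, v, v))  # index == abruptness
        out = regress_signal(self._series(rows), index_columns=["energy_gap"])
        assert np.allclose(out["slope"], 1.0)
        assert (out["pvalue"] < 1e-10).all()
        assert out["significant"].all()

    def test_zero_variance_index_reported_na(self):
        rows = [("T", 1, 1.0, v) for v in np.linspace(0, 1, 8)]
        out = regress_signal(self._series(rows), index_columns=["energy_gap"])
        assert out["slope"].isna().all()


class TestBuildSeries:
    def _inputs(self):
        idx = pd.DataFrame(
            {"treatment": "T", "replicate": 1, "day": [5, 6, 7, 8],
             "energy_gap": [0.1, 0.2, 0.3, 0.4]}
        )
        ab = pd.DataFrame(
            {"treatment": "T", "replicate": 1, "t": [6, 7, 9], "p": 7,
             "abruptness": [0.2, 0.8, 0.4]}
        )
        return idx, ab

    def test_join_cardinality_is_shared_day_grid(self):
        idx, ab = self._inputs()
        out = build_signal_series(idx, ab, p=7)
        assert sorted(out["day"]) == [6, 7]

    def test_labels_follow_strict_half_threshold(self):
        idx, ab = self._inputs()
        out = build_signal_series(idx, ab, p=7).set_index("day")
        assert not out.loc[6, "is_abrupt"]
        assert out.loc[7, "is_abrupt"]

    def test_empty_join_fails(self):
        idx, ab = self._inputs()
        ab["t"] += 100
        with pytest.raises(ValueError):
            build_signal_series(idx, ab, p=7)


class TestPooling:
    def _treatment(self, rng, shift, n=200):
        scores = np.concatenate([rng.normal(0, 1, n), rng.normal(shift, 1, n)])
        labels = np.concatenate([np.zeros(n, bool), np.ones(n, bool)])
        return pd.DataFrame({"energy_gap": scores, "is_abrupt": labels})

    def test_identical_distributions_reproduce_single_threshold(self, rng):
        a = self._treatment(rng, 2.0)
        out_single = pooled_threshold({"A": a}, index_columns=["energy_gap"])
        out_pooled = pooled_threshold(
            {"A": a, "B": a.copy()}, index_columns=["energy_gap"]
        )
        assert out_pooled["threshold"].iloc[0] == pytest.approx(
            out_single["threshold"].iloc[0]
        )

    def test_pooled_auc_between_per_treatment_aucs(self, rng):
        a = self._treatment(rng, 2.5)
        b = self._treatment(rng, 1.0)
        auc_a = roc_analysis(a["energy_gap"], a["is_abrupt"]).auc
        auc_b = roc_analysis(b["energy_gap"], b["is_abrupt"]).auc
        pooled = pooled_threshold({"A": a, "B": b}, index_columns=["energy_gap"])
        lo, hi = sorted([auc_a, auc_b])
        assert lo - 0.05 <= pooled["auc"].iloc[0] <= hi + 0.05

    def test_pooled_threshold_consistent_when_applied_back(self, rng):
        a = self._treatment(rng, 2.0)
        b = self._treatment(rng, 2.0)
        pooled = pooled_threshold({"A": a, "B": b}, index_columns=["energy_gap"])
        thr = pooled["threshold"].iloc[0]
        both = pd.concat([a, b])
        pred = both["energy_gap"] >= thr
        sens = (pred & both["is_abrupt"]).sum() / both["is_abrupt"].sum()
        spec = (~pred & ~both["is_abrupt"]).sum() / (~both["is_abrupt"]).sum()
        assert sens + spec - 1 == pytest.approx(pooled["youden_j"].iloc[0])


def test_bistable_indices_higher_before_shift_than_after_relaxation(
    bistable_small, bistable_calibrated
):
    """Directional sanity: energy gap and stable-state entropy, computed on
    the detection-limited (calibrated) presence states, are elevated in the
    run-up to the endogenous community flip relative to the relaxed
    post-shift state."""
    from microdyn.landscape import PairwiseMaxEnt, binarize, energy_gap, stable_state_entropy
    from tests.conftest import flip_day

    reps = bistable_calibrated.replicates("bistable")
    target = 1
    shift = flip_day(bistable_small, replicate=target)
    others = [r for r in reps if r != target]
    bcm = binarize(bistable_calibrated, treatment="bistable", replicates=others)
    model = PairwiseMaxEnt(tol=1e-3).fit(bcm)
    wide = bistable_calibrated.wide("bistable", target)
    pres = (wide[bcm.taxon_ids] > 0).astype(int)
    rng = np.random.default_rng(0)
    gaps, ents = {}, {}
    days_before = [d for d in range(1, shift - 4) if d in pres.index]
    days_after = [d for d in range(shift + 10, shift + 31) if d in pres.index]
    for day in days_before + days_after:
        state = pres.loc[day].to_numpy()
        gaps[day] = energy_gap(state, model)
        ents[day] = stable_state_entropy(state, model, n_walks=300, seed=rng)
    assert np.mean([gaps[d] for d in days_before]) > np.mean([gaps[d] for d in days_after])
    assert np.mean([ents[d] for d in days_before]) >= np.mean([ents[d] for d in days_after])
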