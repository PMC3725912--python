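import itertools

import numpy as np
import pandas as pd
import pytest

import votefuse as vf
from votefuse.integration import BalancedSubset, PredictionSummary
from votefuse.io_model import ValidationError

from conftest import toy_labels


def _cohort(n_case=42, n_control=42):
    labels = toy_labels(
        [f"c{i}" for i in range(n_case)], [f"u{i}" for i in range(n_control)]
    )
    return vf.LabeledCohort(list(labels.index), labels)


def _features(cohort, d=4, sep=3.0, seed=0, prefix="f"):
    rng = np.random.default_rng(seed)
    rows = []
    for sid in cohort.sample_ids:
        mu = sep if cohort.labels[sid] == vf.CASE else 0.0
        rows.append(rng.normal(mu, 1.0, d))
    return pd.DataFrame(rows, index=cohort.sample_ids,
                        columns=[f"{prefix}{i}" for i in range(d)])


def test_balanced_subset_even_split_without_replacement(rng):
    cohort = _cohort()
    sub = vf.draw_balanced_subset(cohort, 40, rng)
    assert len(sub.case_ids) == len(sub.control_ids) == 20
    assert len(set(sub.ids)) == 40
    assert set(sub.case_ids) <= set(cohort.case_ids)
    assert set(sub.control_ids) <= set(cohort.control_ids)


def test_balanced_subset_exhaustive_draw(rng):
    cohort = _cohort()
    sub = vf.draw_balanced_subset(cohort, 84, rng)
    assert sorted(sub.ids) == sorted(cohort.sample_ids)


def test_balanced_subset_size_exceeding_class_errors(rng):
    with pytest.raises(ValidationError, match="exceeds"):
        vf.draw_balanced_subset(_cohort(), 86, rng)
    with pytest.raises(ValidationError, match="even"):
        vf.draw_balanced_subset(_cohort(), 41, rng)


def test_subset_draws_deterministic_under_seed():
    cohort = _cohort()
    draws1 = [vf.draw_balanced_subset(cohort, 40, np.random.default_rng(5))
              for _ in range(1)]
    draws2 = [vf.draw_balanced_subset(cohort, 40, np.random.default_rng(5))
              for _ in range(1)]
    assert draws1[0].ids == draws2[0].ids


@pytest.mark.parametrize("n,expected_total", [(1, 3), (25, 51), (1500, 3001)])
def test_pool_sizes_k_equals_n_plus_one(n, expected_total):
    cohort = _cohort(6, 6)
    geno = _features(cohort, seed=1)
    cyto = _features(cohort, seed=2, prefix="c")
    config = vf.RunConfig(sampling_size=8, sampling_time=n, classifier="lda", seed=0)
    if n > 50:  # structural check only; avoid fitting thousands of models
        with pytest.raises(ValidationError):
            vf.IntegrationModel([], [object()] * n, config)
        assert n + 1 + n == expected_total
        return
    model = vf.fit_integration(cohort, geno, cyto, config)
    assert model.k == n + 1
    assert model.k + model.n == expected_total
    assert len(model.subset_log) == expected_total


def test_fit_is_deterministic_under_seed():
    cohort = _cohort(10, 10)
    geno = _features(cohort, seed=1)
    cyto = _features(cohort, seed=2, prefix="c")
    config = vf.RunConfig(sampling_size=10, sampling_time=5, classifier="svm_rbf", seed=3)
    m1 = vf.fit_integration(cohort, geno, cyto, config)
    m2 = vf.fit_integration(cohort, geno, cyto, config)
    log1 = [s.ids for s in m1.subset_log]
    log2 = [s.ids for s in m2.subset_log]
    assert log1 == log2
    test = _cohort(5, 5)
    gte, cte = _features(test, seed=7), _features(test, seed=8, prefix="c")
    pd.testing.assert_frame_equal(
        vf.predict_integration(m1, gte, cte).table,
        vf.predict_integration(m2, gte, cte).table,
    )


def _summary(k, n, votes):
    table = pd.DataFrame(
        {
            "geno_votes": [g for g, _ in votes],
            "cyto_votes": [c for _, c in votes],
            "r_g": [g / k for g, _ in votes],
            "r_c": [c / n for _, c in votes],
            "final_call": [
                vf.CASE if (g + c) * 2 > k + n else vf.CONTROL for g, c in votes
            ],
        },
        index=[f"t{i}" for i in range(len(votes))],
    )
    return PredictionSummary(table, k, n)


def test_majority_vote_examples():
    s = _summary(26, 25, [(26, 25), (0, 25), (13, 12), (0, 0)])
    assert list(s.final_calls) == [vf.CASE, vf.CONTROL, vf.CONTROL, vf.CONTROL]
    # 25 of 51 votes is not a majority
    assert s.table.loc["t1", "geno_votes"] + s.table.loc["t1", "cyto_votes"] == 25


def test_fig_style_point_is_positive():
    # 60 of K=100 and 80 of N=100 -> plotted at (0.6, 0.8), 140 > 100 votes
    s = _summary(101, 100, [(61, 80)])
    assert s.table.loc["t0", "r_c"] == pytest.approx(0.8)
    assert s.final_calls.iloc[0] == vf.CASE


def test_tie_impossibility_k_n_plus_one():
    """With K = N+1 the total vote count is odd, so every call is defined."""
    for n in (1, 2, 5):
        k = n + 1
        for g, c in itertools.product(range(k + 1), range(n + 1)):
            total = g + c
            assert total * 2 != k + n  # no exact tie reachable


def test_vote_oracle_equivalence_enumerated_pools():
    """final_call matches exhaustive truth-table majority for tiny pools."""
    k, n = 3, 2
    for votes in itertools.product([0, 1], repeat=k + n):
        g, c = sum(votes[:k]), sum(votes[k:])
        s = _summary(k, n, [(g, c)])
        brute = vf.CASE if sum(votes) > (k + n) / 2 else vf.CONTROL
        assert s.final_calls.iloc[0] == brute


def test_attribute_separation():
    """Permuting test cytokine columns leaves genotype votes unchanged."""
    cohort = _cohort(10, 10)
    geno = _features(cohort, seed=1)
    cyto = _features(cohort, d=3, seed=2, prefix="c")
    config = vf.RunConfig(sampling_size=12, sampling_time=4, classifier="lda", seed=0)
    model = vf.fit_integration(cohort, geno, cyto, config)
    test = _cohort(8, 8)
    gte = _features(test, seed=5)
    cte = _features(test, d=3, seed=6, prefix="c")
    base = vf.predict_integration(model, gte, cte)
    # scrambling cytokine values across samples can only change cyto votes
    scrambled = cte.copy()
    scrambled[:] = cte.sample(frac=1.0, random_state=1).to_numpy()
    scr = vf.predict_integration(model, gte, scrambled)
    pd.testing.assert_series_equal(base.table["geno_votes"], scr.table["geno_votes"])
    # and vice versa
    gscr = gte.copy()
    gscr[:] = gte.sample(frac=1.0, random_state=2).to_numpy()
    scr2 = vf.predict_integration(model, gscr, cte)
    pd.testing.assert_series_equal(base.table["cyto_votes"], scr2.table["cyto_votes"])


def test_pool_exchangeability():
    """Relabeling predictor indices within a pool leaves the summary unchanged."""
    cohort = _cohort(10, 10)
    geno = _features(cohort, seed=1)
    cyto = _features(cohort, seed=2, prefix="c")
    config = vf.RunConfig(sampling_size=10, sampling_time=4, classifier="nbc", seed=9)
    model = vf.fit_integration(cohort, geno, cyto, config)
    reversed_model = vf.IntegrationModel(
        model.genotype_pool[::-1], model.cytokine_pool[::-1], config
    )
    test = _cohort(6, 6)
    gte, cte = _features(test, seed=3), _features(test, seed=4, prefix="c")
    pd.testing.assert_frame_equal(
        vf.predict_integration(model, gte, cte).table,
        vf.predict_integration(reversed_model, gte, cte).table,
    )


def test_subset_log_order_genotype_pool_first():
    cohort = _cohort(10, 10)
    geno = _features(cohort, seed=1)
    cyto = _features(cohort, seed=2, prefix="c")
    config = vf.RunConfig(sampling_size=10, sampling_time=3, classifier="lda", seed=4)
    model = vf.fit_integration(cohort, geno, cyto, config)
    # the first K subsets belong to the genotype pool: replaying the RNG
    # stream reproduces them in that order
    rng = np.random.default_rng(4)
    replay = [vf.draw_balanced_subset(cohort, 10, rng) for _ in range(model.k + model.n)]
    assert [s.ids for s in model.subset_log] == [s.ids for s in replay]


def test_unequal_subset_invariant():
    with pytest.raises(ValidationError, match="unequal"):
        BalancedSubset(["a"], [])
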