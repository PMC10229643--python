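"""Round summaries, timepoint analytics, composition comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import medopt as m
from medopt.dataset import CultureObservation, Dataset
from medopt.reporting import exact_rank_sum_p


def _dataset_from_means(space, means_by_round, timepoints=(96.0, 168.0)):
    """Dataset with prescribed per-medium means (single noiseless replicate)."""
    ds = Dataset(space)
    base = space.baseline_combination().folds
    i = 0
    for label, means in means_by_round.items():
        for value in means:
            cid = f"{label}_{i}"
            i += 1
            if isinstance(value, dict):
                per_t = value
            else:
                per_t = {t: value for t in timepoints}
            obs = CultureObservation(
                combination_id=cid,
                raw={t: np.array([v]) for t, v in per_t.items()},
                blanked={t: np.array([v]) for t, v in per_t.items()},
                mean={t: float(v) for t, v in per_t.items()},
                n_replicates=1,
            )
            ds.add(m.MediumCombination(folds=base, id=cid), obs, round_label=label)
    return ds


def test_fraction_above_reference_strict(toy_space):
    ds = _dataset_from_means(toy_space, {"r1": [1.0, 2.0, 3.0, 2.5]})
    assert m.fraction_above_reference(ds, "r1", 168.0, 2.0) == pytest.approx(0.5)
    ds_eq = _dataset_from_means(toy_space, {"r1": [2.0, 2.0]})
    assert m.fraction_above_reference(ds_eq, "r1", 168.0, 2.0) == 0.0
    ds34 = _dataset_from_means(toy_space, {"r1": [3.0, 3.0, 3.0, 1.0]})
    assert m.fraction_above_reference(ds34, "r1", 168.0, 2.0) == pytest.approx(0.75)
    with pytest.raises(ValueError):
        m.fraction_above_reference(ds, "missing", 168.0, 2.0)


def test_round_summary_quartiles_and_fraction(toy_space, oracle):
    config = m.CampaignConfig(
        n_rounds=3, batch_size=4, candidate_cap=400, max_changes=None, seed=1,
        grid=m.HyperParamGrid.reduced(n_estimators=50),
        evaluate_cv=False, compute_importance=False,
    )
    toy_oracle = m.make_default_oracle(toy_space, rng_seed=1, n_active=2)
    result = m.run_campaign(toy_space, toy_oracle, config)
    reference = 0.9
    summaries = m.round_summary(result, reference)
    assert [s.round_label for s in summaries] == ["initial", "round1", "round2", "round3"]
    ds = result.dataset
    for s in summaries:
        vals = ds.mean_a450(168.0, ds.ids_in_round(s.round_label)).to_numpy()
        assert s.n_media == len(vals)
        # brute-force quantile oracle (inclusive linear interpolation)
        srt = np.sort(vals)
        for q, got in [(0.25, s.q1), (0.5, s.median), (0.75, s.q3)]:
            h = (len(srt) - 1) * q
            lo, hi = int(np.floor(h)), int(np.ceil(h))
            expect = srt[lo] + (h - lo) * (srt[hi] - srt[lo])
            assert got == pytest.approx(expect)
        assert s.minimum == srt[0] and s.maximum == srt[-1]
        assert s.minimum <= s.q1 <= s.median <= s.q3 <= s.maximum
        assert s.fraction_above_reference == pytest.approx(np.mean(vals > reference))


def test_round_summary_singleton_round(toy_space):
    ds = _dataset_from_means(toy_space, {"initial": [1.0, 2.0], "round1": [1.5]})

    class FakeRound:
        round_index = 1
        cv_report = None

    class FakeResult:
        dataset = ds
        rounds = [FakeRound()]

        class config:
            objective_timepoint = 168.0

    s = m.round_summary(FakeResult(), 1.0)[-1]
    assert s.minimum == s.median == s.maximum == 1.5


def test_spearman_correlation_known_cases(toy_space):
    up = _dataset_from_means(
        toy_space, {"r": [{96.0: x, 168.0: x**2} for x in (1, 2, 3, 4, 5)]}
    )
    rho, _ = m.timepoint_correlation(up, 96.0, 168.0)
    assert rho == pytest.approx(1.0)
    down = _dataset_from_means(
        toy_space, {"r": [{96.0: x, 168.0: -x} for x in (1, 2, 3, 4, 5)]}
    )
    rho, _ = m.timepoint_correlation(down, 96.0, 168.0)
    assert rho == pytest.approx(-1.0)


def test_spearman_matches_rank_formula_no_ties(toy_space):
    a = [0.3, 0.1, 0.5, 0.2, 0.9, 0.6]
    b = [0.4, 0.2, 0.3, 0.1, 0.8, 0.9]
    ds = _dataset_from_means(
        toy_space, {"r": [{96.0: x, 168.0: y} for x, y in zip(a, b)]}
    )
    rho, _ = m.timepoint_correlation(ds, 96.0, 168.0)
    ra, rb = stats.rankdata(a), stats.rankdata(b)
    d2 = np.sum((ra - rb) ** 2)
    n = len(a)
    assert rho == pytest.approx(1 - 6 * d2 / (n * (n**2 - 1)))


def test_spearman_invariant_under_monotone_transform(toy_space):
    rng = np.random.default_rng(0)
    a = rng.uniform(0.1, 2.0, size=12)
    b = a + rng.normal(0, 0.3, size=12)
    ds1 = _dataset_from_means(
        toy_space, {"r": [{96.0: x, 168.0: y} for x, y in zip(a, b)]}
    )
    ds2 = _dataset_from_means(
        toy_space, {"r": [{96.0: np.exp(x), 168.0: y**3} for x, y in zip(a, b)]}
    )
    rho1, _ = m.timepoint_correlation(ds1, 96.0, 168.0)
    rho2, _ = m.timepoint_correlation(ds2, 96.0, 168.0)
    assert -1.0 <= rho1 <= 1.0
    assert rho1 == pytest.approx(rho2)


def test_changing_ratio(toy_space):
    ds = _dataset_from_means(
        toy_space,
        {"r": [{96.0: 0.2, 168.0: 0.4}, {96.0: 0.5, 168.0: 0.25}, {96.0: 0.0, 168.0: 0.3},
               {96.0: -0.01, 168.0: 0.2}]},
    )
    out = m.changing_ratio(ds, 96.0, 168.0)
    assert out["ratio"].iloc[0] == pytest.approx(2.0)
    assert out["ratio"].iloc[1] == pytest.approx(0.5)
    assert np.isnan(out["ratio"].iloc[2]) and bool(out["flagged"].iloc[2])
    assert np.isnan(out["ratio"].iloc[3]) and bool(out["flagged"].iloc[3])
    expected = ds.mean_a450(168.0).to_numpy()[:2] / ds.mean_a450(96.0).to_numpy()[:2]
    assert out["ratio"].to_numpy()[:2] == pytest.approx(expected)


def _media(space, folds_by_component_lists):
    out = []
    for i, folds in enumerate(folds_by_component_lists):
        out.append(m.MediumCombination(folds=tuple(folds), id=f"m{i}"))
    return out


def test_compare_compositions_identical_sets_not_significant(toy_space):
    media = _media(toy_space, [(0.1, 1, 10, 1), (1, 10, 0.1, 1), (10, 0.1, 1, 1)])
    cmp = m.compare_compositions(media, media, toy_space)
    assert cmp.significant_components() == []
    assert np.all(cmp.p_value > 0.05)
    assert np.all((cmp.p_value > 0) & (cmp.p_value <= 1))


def test_compare_compositions_exact_small_sample_p():
    """n=3 vs n=3 fully separated -> exact two-sided p = 2/20 = 0.1."""
    table = pd.DataFrame(
        [{"name": "X", "baseline": 1.0, "unit": "mM", "levels": "0;0.1;1;10", "fixed": False}]
    )
    sp = m.build_design_space(table)
    a = [m.MediumCombination(folds=(10.0,), id=f"a{i}") for i in range(3)]
    b = [m.MediumCombination(folds=(0.1,), id=f"b{i}") for i in range(3)]
    cmp = m.compare_compositions(a, b, sp, alpha=0.05)
    assert cmp.p_value[0] == pytest.approx(0.1)
    assert not cmp.significant[0]


@pytest.mark.parametrize("n1,n2", [(3, 3), (4, 5), (6, 6)])
def test_exact_rank_sum_matches_enumeration(n1, n2):
    rng = np.random.default_rng(n1 * 10 + n2)
    x = rng.choice([0.0, 0.1, 1.0, 10.0], size=n1)
    y = rng.choice([0.0, 0.1, 1.0, 10.0], size=n2)
    u, p = exact_rank_sum_p(x, y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    s_obs = ranks[:n1].sum()
    sums = [sum(ranks[list(c)]) for c in itertools.combinations(range(n1 + n2), n1)]
    sums = np.array(sums)
    p_le = np.mean(sums <= s_obs + 1e-9)
    p_ge = np.mean(sums >= s_obs - 1e-9)
    expect = min(1.0, 2 * min(p_le, p_ge))
    assert p == pytest.approx(expect)
    assert u == pytest.approx(s_obs - n1 * (n1 + 1) / 2)


def test_exact_rank_sum_matches_scipy_without_ties():
    rng = np.random.default_rng(4)
    x = rng.normal(size=6)
    y = rng.normal(loc=1.0, size=6)
    u, p = exact_rank_sum_p(x, y)
    ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    assert u == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue)


def test_compare_compositions_detects_shifted_component(toy_space):
    a = _media(toy_space, [(10, 1, 1, 1)] * 6 + [(100, 1, 1, 1)] * 2)
    b = _media(toy_space, [(0.1, 1, 1, 1)] * 6 + [(0, 1, 1, 1)] * 2)
    cmp = m.compare_compositions(a, b, toy_space, alpha=0.05)
    assert cmp.significant_components() == ["A"]
    with pytest.raises(ValueError):
        m.compare_compositions([], a, toy_space)
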