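import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ripetime.qpcr import (
    anova_lsd,
    compute_nrq,
    efficiency_window_of_linearity,
    genorm,
    mean_center_combine,
    plate_mean_efficiency,
    wells_to_frame,
)
from ripetime.simulate import simulate_qpcr_dataset


# -- efficiency ------------------------------------------------------------

def test_pure_doubling_curve_gives_efficiency_two():
    cyc = np.arange(1, 41.0)
    eff = efficiency_window_of_linearity(np.column_stack([cyc, 0.001 * 2.0**cyc]))
    assert eff == pytest.approx(2.0, abs=1e-3)


def test_recovers_simulated_base_with_mild_noise():
    wells = simulate_qpcr_dataset(
        8, ["a", "b"], ["a"], np.zeros((8, 2)), 1.9, 0.1, seed=5, curve_noise_sd=0.002
    )
    effs = [efficiency_window_of_linearity(w.curve) for w in wells]
    assert plate_mean_efficiency(effs) == pytest.approx(1.90, abs=0.02)


def test_flat_curve_is_an_error():
    cyc = np.arange(1, 41.0)
    with pytest.raises(ValueError, match="no exponential phase"):
        efficiency_window_of_linearity(np.column_stack([cyc, np.full(40, 7.0)]))


def test_plate_mean_efficiency():
    assert plate_mean_efficiency([2.0, 2.0, 2.0]) == 2.0
    assert plate_mean_efficiency([1.8, 2.0]) == pytest.approx(1.9)
    with pytest.raises(ValueError):
        plate_mean_efficiency([])


# -- NRQ -------------------------------------------------------------------

def _wells_from_cq(cq_table: dict, samples) -> pd.DataFrame:
    rows = [
        {"sample": s, "gene": g, "replicate": 1, "cq": cq_table[g][i]}
        for g in cq_table
        for i, s in enumerate(samples)
    ]
    return pd.DataFrame(rows)


def test_nrq_all_equal_cq_gives_unity():
    df = _wells_from_cq({"ref": [24, 24], "t": [24, 24]}, ["s1", "s2"])
    tab = compute_nrq(df, ["ref"], 2.0)
    assert np.allclose(tab.nrq.to_numpy(), 1.0)


def test_nrq_one_cycle_is_one_doubling():
    df = _wells_from_cq({"ref": [24, 24], "t": [23, 24]}, ["A", "B"])
    tab = compute_nrq(df, ["ref"], 2.0)
    assert tab.nrq.loc["A", "t"] / tab.nrq.loc["B", "t"] == pytest.approx(2.0, rel=1e-12)


def test_nrq_fold_change_exact_without_noise():
    genes = ["r1", "r2", "t"]
    x = np.zeros((4, 3))
    x[2:, 2] = np.log2(18.0)
    wells = simulate_qpcr_dataset(4, genes, ["r1", "r2"], x, 2.0, 0.0, seed=0, with_curves=False)
    tab = compute_nrq(wells_to_frame(wells), ["r1", "r2"], 2.0)
    fold = tab.nrq["t"].iloc[2:].mean() / tab.nrq["t"].iloc[:2].mean()
    assert fold == pytest.approx(18.0, rel=1e-10)


def test_nrq_scale_invariance_of_sample_ratios():
    # the calibrator choice cancels in between-sample NRQ ratios
    df = _wells_from_cq({"ref": [24.0, 25.0, 23.5], "t": [22.0, 26.0, 24.0]}, ["a", "b", "c"])
    tab1 = compute_nrq(df, ["ref"], 1.9)
    shifted = df.copy()
    shifted["cq"] = shifted["cq"] + 3.0  # uniform shift: same ratios
    tab2 = compute_nrq(shifted, ["ref"], 1.9)
    r1 = tab1.nrq["t"] / tab1.nrq["t"].iloc[0]
    r2 = tab2.nrq["t"] / tab2.nrq["t"].iloc[0]
    assert np.allclose(r1, r2)


def test_nrq_missing_reference_rejected():
    df = _wells_from_cq({"ref": [24, np.nan], "t": [24, 24]}, ["s1", "s2"])
    with pytest.raises(ValueError, match="missing Cq"):
        compute_nrq(df, ["ref"], 2.0)


# -- geNORM ----------------------------------------------------------------

def _genorm_oracle(q: pd.DataFrame):
    """Direct spreadsheet-style evaluation of the stability definitions."""
    logq = np.log2(q)
    genes = list(q.columns)
    m = {}
    for g in genes:
        m[g] = np.mean([
            np.std(logq[g] - logq[h], ddof=1) for h in genes if h != g
        ])
    return pd.Series(m)


def test_proportional_genes_have_zero_m():
    base = np.array([1.0, 5.0, 2.5, 8.0])
    q = pd.DataFrame({"a": base, "b": 2 * base, "c": 0.25 * base})
    res = genorm(q)
    assert np.allclose(res.M.to_numpy(), 0.0, atol=1e-12)


def test_destabilized_gene_ranked_least_stable():
    rng = np.random.default_rng(1)
    base = rng.uniform(1, 10, 10)
    q = pd.DataFrame({f"g{i}": base * 2 ** rng.normal(0, 0.1, 10) for i in range(5)})
    q["noisy"] = base * 2 ** rng.normal(0, 1.5, 10)
    res = genorm(q)
    assert res.M.idxmax() == "noisy"
    assert res.ranking[-1] == "noisy"


def test_m_values_match_direct_formula_oracle():
    rng = np.random.default_rng(2)
    q = pd.DataFrame(rng.lognormal(0, 0.5, (6, 5)), columns=list("abcde"))
    res = genorm(q)
    oracle = _genorm_oracle(q)
    pd.testing.assert_series_equal(res.M.sort_index(), oracle.sort_index(), atol=1e-12)


def test_v_ladder_matches_direct_formula_oracle():
    rng = np.random.default_rng(3)
    q = pd.DataFrame(rng.lognormal(0, 0.4, (8, 5)), columns=list("abcde"))
    res = genorm(q)
    logq = np.log2(q)
    for k in range(2, 5):
        nf_k = logq[res.ranking[:k]].mean(axis=1)
        nf_k1 = logq[res.ranking[: k + 1]].mean(axis=1)
        expected = np.std(nf_k - nf_k1, ddof=1)
        assert res.V[f"V{k}/{k + 1}"] == pytest.approx(expected, abs=1e-12)


def test_genorm_invariances():
    rng = np.random.default_rng(4)
    q = pd.DataFrame(rng.lognormal(0, 0.5, (7, 4)), columns=list("wxyz"))
    res = genorm(q)
    shuffled = q.sample(frac=1.0, random_state=0)  # permute samples
    res_p = genorm(shuffled)
    pd.testing.assert_series_equal(res.M, res_p.M, atol=1e-12)
    relabeled = q.rename(columns={"w": "ww"})
    res_r = genorm(relabeled)
    assert res_r.M["ww"] == pytest.approx(res.M["w"], abs=1e-14)


def test_genorm_input_validation():
    with pytest.raises(ValueError, match="positive"):
        genorm(pd.DataFrame({"a": [1, -1], "b": [1, 1], "c": [1, 1]}))
    with pytest.raises(ValueError, match="at least 3"):
        genorm(pd.DataFrame({"a": [1, 2], "b": [1, 2]}))


# -- mean centering --------------------------------------------------------

def test_single_dataset_centered_on_itself():
    rng = np.random.default_rng(5)
    d = pd.DataFrame(rng.lognormal(0, 1, (4, 2)), columns=["g1", "g2"])
    out = mean_center_combine([d])
    expected = np.log2(d) - np.log2(d).mean(axis=0)
    assert np.allclose(out.to_numpy(), expected.to_numpy())
    assert np.allclose(out.mean(axis=0), 0.0)


def test_constant_offset_between_runs_removed():
    rng = np.random.default_rng(6)
    d1 = pd.DataFrame(rng.lognormal(0, 1, (5, 3)), columns=list("abc"),
                      index=[f"s{i}" for i in range(5)])
    d2 = (d1 * 2.0**4.2).set_axis([f"t{i}" for i in range(5)])
    out = mean_center_combine([d1, d2])
    assert np.allclose(out.iloc[:5].to_numpy(), out.iloc[5:].to_numpy())


def test_group_effects_survive_combination():
    # two runs with different batch offsets but the same group effect
    rng = np.random.default_rng(7)
    effect = 1.5  # log2 units between group A and B
    frames = []
    for run, offset in enumerate([0.0, 3.0]):
        log2q = rng.normal(0, 0.1, (6, 1)) + offset
        log2q[3:] += effect
        frames.append(pd.DataFrame(
            2.0**log2q, columns=["t"], index=[f"r{run}s{i}" for i in range(6)]
        ))
    combined = mean_center_combine(frames)
    groups = np.tile([0, 0, 0, 1, 1, 1], 2)
    est = combined["t"][groups == 1].mean() - combined["t"][groups == 0].mean()
    assert est == pytest.approx(effect, abs=0.15)


def test_mismatched_gene_sets_rejected():
    d1 = pd.DataFrame({"a": [1.0, 2.0]})
    d2 = pd.DataFrame({"b": [1.0, 2.0]})
    with pytest.raises(ValueError, match="gene set"):
        mean_center_combine([d1, d2])


# -- ANOVA / LSD -----------------------------------------------------------

def test_two_group_lsd_equals_pooled_t_test():
    rng = np.random.default_rng(8)
    a = rng.normal(0, 1, 8)
    b = rng.normal(2, 1, 8)
    res = anova_lsd(np.concatenate([a, b]), np.array(["A"] * 8 + ["B"] * 8))
    t, p = stats.ttest_ind(a, b)
    assert res.pairwise["p"].iloc[0] == pytest.approx(p, rel=1e-10)
    assert res.p_omnibus == pytest.approx(p, rel=1e-10)  # F = t^2 for k = 2
    assert res.letters["A"] != res.letters["B"]


def test_three_group_anova_matches_formula_oracle():
    values = np.array([3.0, 4.0, 5.0, 7.0, 8.0, 9.0, 4.0, 5.0, 6.0])
    groups = np.array(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
    res = anova_lsd(values, groups)
    # brute-force ANOVA identities
    grand = values.mean()
    ss_between = sum(3 * (values[groups == g].mean() - grand) ** 2 for g in "abc")
    ss_within = sum(((values[groups == g] - values[groups == g].mean()) ** 2).sum() for g in "abc")
    f = (ss_between / 2) / (ss_within / 6)
    assert res.f_statistic == pytest.approx(f, rel=1e-12)
    assert res.p_omnibus == pytest.approx(stats.f.sf(f, 2, 6), rel=1e-12)
    mse = ss_within / 6
    for _, row in res.pairwise.iterrows():
        g1, g2 = row.group1, row.group2
        tstat = (values[groups == g1].mean() - values[groups == g2].mean()) / np.sqrt(mse * 2 / 3)
        assert row.p == pytest.approx(2 * stats.t.sf(abs(tstat), 6), rel=1e-12)


def test_protection_null_simulation():
    rng = np.random.default_rng(9)
    same_letter = 0
    n_rep = 100
    for _ in range(n_rep):
        v = rng.normal(0, 1, 15)
        g = np.repeat(["a", "b", "c"], 5)
        res = anova_lsd(v, g)
        if len(set(res.letters.values())) == 1:
            same_letter += 1
        # protection invariant: no declared pair without a significant omnibus
        if res.p_omnibus >= 0.05:
            assert not res.pairwise["different"].any()
    assert same_letter >= 85  # ~95% expected under the null


def test_small_group_rejected():
    with pytest.raises(ValueError, match="fewer than 2"):
        anova_lsd(np.array([1.0, 2.0, 3.0]), np.array(["a", "a", "b"]))
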