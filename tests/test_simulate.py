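import numpy as np
import pandas as pd
import pytest

from ripetime.likelihood import RipeningModelParams
from ripetime.qpcr import wells_to_frame
from ripetime.simulate import (
    ExperimentDesign,
    default_design,
    default_params,
    simulate_ethylene_trace,
    simulate_qpcr_dataset,
    simulate_ripening_experiment,
)
from ripetime.stages import STAGE_RANK, derive_censoring_intervals


def _design(**kw):
    base = dict(
        genotypes=("WT",), reference="WT", plants_per_genotype=3,
        trusses_per_plant=1, fruits_per_truss=2,
        observation_days=(30, 33, 37, 40, 44, 47, 51, 54, 58),
    )
    base.update(kw)
    return ExperimentDesign(**base)


def test_seeded_determinism(two_genotype_params):
    d = _design(genotypes=("WT", "mut"), plants_per_genotype=2)
    s1, t1 = simulate_ripening_experiment(d, two_genotype_params, seed=11)
    s2, t2 = simulate_ripening_experiment(d, two_genotype_params, seed=11)
    assert [f.observations for f in s1] == [f.observations for f in s2]
    pd.testing.assert_frame_equal(t1.latent_times, t2.latent_times)
    s3, _ = simulate_ripening_experiment(d, two_genotype_params, seed=12)
    assert [f.observations for f in s1] != [f.observations for f in s3]


def test_zero_noise_latents_equal_linear_predictor():
    params = RipeningModelParams(
        mu=[41.0, 51.0], alpha={"WT": [0, 0]},
        sigma0=np.zeros((2, 2)), sigma=np.zeros((2, 2)),
    )
    _, truth = simulate_ripening_experiment(_design(), params, seed=0)
    assert (truth.latent_times["Y1"] == 41.0).all()
    assert (truth.latent_times["Y2"] == 51.0).all()


def test_empirical_covariance_matches_generative_law():
    params = RipeningModelParams(
        mu=[40, 50], alpha={"WT": [0, 0]},
        sigma0=[[4, 1], [1, 4]], sigma=[[2, 0.5], [0.5, 2]],
    )
    d = _design(plants_per_genotype=200, fruits_per_truss=1,
                observation_days=tuple(np.arange(20.0, 80.0)))
    _, truth = simulate_ripening_experiment(d, params, seed=5)
    y = truth.latent_times[["Y1", "Y2"]].to_numpy()
    total = np.array([[6.0, 1.5], [1.5, 6.0]])  # sigma0 + sigma
    emp = np.cov(y.T)
    n = len(y)
    # 3 SE on a normal covariance entry: ~3 * sqrt(2/n) * var
    assert np.all(np.abs(emp - total) < 3 * np.sqrt(2 / n) * 6.5)
    assert np.all(np.abs(y.mean(0) - [40, 50]) < 3 * np.sqrt(6.0 / n) * 1.5)


def test_daily_schedule_bounds_interval_width():
    params = default_params()
    d = ExperimentDesign(
        genotypes=("WT", "rin-2"), reference="WT", plants_per_genotype=5,
        trusses_per_plant=1, fruits_per_truss=2,
        observation_days=tuple(np.arange(20.0, 90.0)),
    )
    series, _ = simulate_ripening_experiment(d, params, seed=1)
    for s in series:
        c = derive_censoring_intervals(s)
        for lo, hi in zip(c.lower, c.upper):
            if np.isfinite(hi):
                assert hi - lo <= 1.0 + 1e-9


def test_stage_sequences_are_valid_and_ordered():
    series, truth = simulate_ripening_experiment(default_design(), default_params(), seed=2)
    assert truth.n_clamped >= 0
    for s in series:  # FruitStageSeries already validates monotonicity
        ranks = [STAGE_RANK[st] for _, st in s.observations]
        assert ranks == sorted(ranks)


def test_order_inversions_are_clamped_not_dropped():
    # mean phase length near zero forces frequent Y2 < Y1 draws
    params = RipeningModelParams(
        mu=[40.0, 40.2], alpha={"WT": [0, 0]},
        sigma0=np.zeros((2, 2)), sigma=[[2, -1], [-1, 2]],
    )
    d = _design(plants_per_genotype=50)
    series, truth = simulate_ripening_experiment(d, params, seed=3)
    assert truth.n_clamped > 0
    assert len(series) == 100
    assert (truth.latent_times["Y2"] >= truth.latent_times["Y1"]).all()


def test_non_psd_covariance_rejected():
    with pytest.raises(ValueError, match="sigma0"):
        RipeningModelParams(
            mu=[40, 50], alpha={"WT": [0, 0]},
            sigma0=[[1, 3], [3, 1]], sigma=np.eye(2),
        )


# -- qPCR simulator --------------------------------------------------------

def test_cq_difference_is_one_cycle_per_doubling():
    x = np.array([[0.0], [1.0]])
    wells = simulate_qpcr_dataset(2, ["g"], [], x, 2.0, 0.0, seed=0,
                                  replicates=1, with_curves=False)
    df = wells_to_frame(wells)
    assert df.loc[df["sample"] =="s1", "cq"].iloc[0] - df.loc[df["sample"] =="s2", "cq"].iloc[0] == pytest.approx(1.0, abs=1e-12)


def test_fold_change_inverts_exactly_without_noise():
    x = np.array([[0.0], [np.log2(18.0)]])
    wells = simulate_qpcr_dataset(2, ["g"], [], x, 2.0, 0.0, seed=0,
                                  replicates=1, with_curves=False)
    df = wells_to_frame(wells)
    dcq = df.loc[df["sample"] =="s1", "cq"].iloc[0] - df.loc[df["sample"] =="s2", "cq"].iloc[0]
    assert 2.0 ** dcq == pytest.approx(18.0, rel=1e-12)


def test_replicate_cq_noise_has_requested_scale():
    wells = simulate_qpcr_dataset(1, ["g"], [], np.zeros((1, 1)), 2.0, 0.2,
                                  seed=4, replicates=200, with_curves=False)
    cqs = np.array([w.cq for w in wells])
    sd = cqs.std(ddof=1)
    assert abs(sd - 0.2) < 3 * 0.2 / np.sqrt(2 * 199)


def test_reference_genes_constant_across_samples():
    x = np.column_stack([np.arange(4.0), np.arange(4.0)])
    wells = simulate_qpcr_dataset(4, ["ref", "t"], ["ref"], x, 2.0, 0.0,
                                  seed=0, replicates=1, with_curves=False)
    ref_cq = [w.cq for w in wells if w.gene == "ref"]
    assert np.ptp(ref_cq) == pytest.approx(0.0, abs=1e-12)


def test_bad_efficiency_rejected():
    with pytest.raises(ValueError, match="efficiency"):
        simulate_qpcr_dataset(1, ["g"], [], np.zeros((1, 1)), 0.9, 0.0, seed=0)


# -- ethylene simulator ----------------------------------------------------

def test_zero_emission_trace_sits_at_background():
    m = simulate_ethylene_trace(0.0, 50.0, 4.0, background=5.0, noise_sd=0.0,
                                duration=10, seed=0)
    assert np.allclose(m.trace[:, 1], 5.0)


def test_steady_state_excess_concentration():
    m = simulate_ethylene_trace(8.0, 50.0, 4.0, background=5.0, noise_sd=0.0,
                                duration=10, seed=0)
    assert np.allclose(m.trace[:, 1] - 5.0, 100.0)  # rate*weight/flow


def test_invalid_cuvette_settings_rejected():
    with pytest.raises(ValueError, match="flow"):
        simulate_ethylene_trace(1.0, 50.0, 0.0, 5.0, 0.0, 10, 0)
    with pytest.raises(ValueError, match="weight"):
        simulate_ethylene_trace(1.0, -1.0, 4.0, 5.0, 0.0, 10, 0)
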