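"""Baseline correction, mass-univariate regression, cluster permutation, PDR."""

import numpy as np
import pytest

from tacit.physio import (
    EpochSet, baseline_correct, chain_channel_graph, cluster_permutation_test,
    epoch_regression, grid_channel_graph, pdr_slope_test,
    regression_by_message_type,
)
from tacit.synthetic import simulate_eeg, simulate_pdr


def _epochs(n_sub=6, n_epochs=30, amplitude=0.0, noise_sd=1.0, seed=0,
            n_channels=8, n_timepoints=20):
    rng = np.random.default_rng(seed)
    data, surprises, times = [], [], None
    for _ in range(n_sub):
        h = rng.exponential(1.0, n_epochs)
        ep, times = simulate_eeg(h, channel_pattern=[1, 2],
                                 time_window=(300.0, 700.0),
                                 amplitude=amplitude, noise_sd=noise_sd,
                                 n_channels=n_channels,
                                 n_timepoints=n_timepoints, rng=rng)
        data.append(ep)
        surprises.append(h)
    return EpochSet(data=data, step_surprise=surprises, times_ms=times,
                    channel_graph=chain_channel_graph(n_channels))


def test_baseline_correct_constant_epoch_becomes_zero():
    times = np.linspace(0, 1200, 24, endpoint=False)
    data = [np.full((3, 2, 24), 7.5)]
    eps = EpochSet(data=data, step_surprise=[np.arange(3.0)], times_ms=times)
    corrected = baseline_correct(eps, (0.0, 100.0))
    assert np.allclose(corrected.data[0], 0.0)
    # idempotent
    again = baseline_correct(corrected, (0.0, 100.0))
    assert np.allclose(again.data[0], corrected.data[0])
    assert corrected.baseline_window == (0.0, 100.0)


def test_baseline_correct_linear_trend_shifts_by_window_mean():
    times = np.linspace(0, 1200, 120, endpoint=False)
    trend = 0.01 * times
    eps = EpochSet(data=[np.tile(trend, (4, 3, 1))],
                   step_surprise=[np.arange(4.0)], times_ms=times)
    corrected = baseline_correct(eps, (0.0, 100.0))
    window_mean = trend[(times >= 0) & (times < 100)].mean()
    assert np.allclose(corrected.data[0][0, 0], trend - window_mean)
    with pytest.raises(ValueError):
        baseline_correct(eps, (1300.0, 1400.0))


def test_epoch_regression_scale_equivariance():
    eps = _epochs(amplitude=0.5, noise_sd=0.3, seed=1)
    betas = epoch_regression(eps)
    doubled = EpochSet(data=eps.data,
                       step_surprise=[2 * h for h in eps.step_surprise],
                       times_ms=eps.times_ms, channel_graph=eps.channel_graph)
    assert np.allclose(epoch_regression(doubled), betas / 2.0)


def test_epoch_regression_rejects_constant_surprise():
    times = np.linspace(0, 1200, 10, endpoint=False)
    eps = EpochSet(data=[np.zeros((5, 2, 10))],
                   step_surprise=[np.ones(5)], times_ms=times)
    with pytest.raises(ValueError):
        epoch_regression(eps)


def test_cluster_test_recovers_injected_cluster():
    eps = _epochs(n_sub=10, amplitude=0.8, noise_sd=1.0, seed=2)
    betas = epoch_regression(eps)
    result = cluster_permutation_test(betas, eps.channel_graph, n_perm=300,
                                      rng=0)
    sig = result.significant(0.05)
    assert sig, "expected the injected channel/time cluster to be detected"
    cells = {pt for c in sig for pt in c.points}
    channels = {ch for ch, _ in cells}
    assert channels & {1, 2}
    in_window = [(eps.times_ms[t] >= 300) and (eps.times_ms[t] < 700)
                 for _, t in cells]
    assert np.mean(in_window) > 0.8


def test_cluster_test_null_usually_empty():
    eps = _epochs(n_sub=8, amplitude=0.0, seed=3)
    betas = epoch_regression(eps)
    result = cluster_permutation_test(betas, eps.channel_graph, n_perm=200,
                                      rng=1)
    assert not result.significant(0.05)


def test_cluster_test_identity_flip_reproduces_observed_mass():
    """With all sign flips equal to +1 the permuted max mass must equal the
    observed max supra-threshold cluster mass."""

    class IdentityRng:
        def choice(self, options, size):
            return np.ones(size)

    eps = _epochs(n_sub=6, amplitude=1.0, noise_sd=0.5, seed=4)
    betas = epoch_regression(eps)
    result = cluster_permutation_test(betas, eps.channel_graph, n_perm=1,
                                      rng=IdentityRng())
    observed_max = max(abs(c.mass) for c in result.clusters)
    assert result.null_max_mass[0] == pytest.approx(observed_max, rel=1e-9)


def test_cluster_test_requires_subjects():
    with pytest.raises(ValueError):
        cluster_permutation_test(np.zeros((3, 4, 5)), chain_channel_graph(4))


def test_channel_graphs():
    assert chain_channel_graph(4) == [(0, 1), (1, 2), (2, 3)]
    edges = grid_channel_graph(2, 3)
    assert (0, 1) in edges and (0, 3) in edges and len(edges) == 7


def test_pdr_slope_test_noiseless_is_exact():
    rng = np.random.default_rng(5)
    surprises = [rng.exponential(1.0, 40) for _ in range(6)]
    pdr = [simulate_pdr(h, slope=0.02, noise_sd=0.0) for h in surprises]
    res = pdr_slope_test(pdr, surprises)
    assert res.slope == pytest.approx(0.02, abs=1e-12)
    assert res.ci95[0] <= 0.02 <= res.ci95[1]


def test_pdr_slope_test_recovers_generating_slope_with_noise():
    rng = np.random.default_rng(6)
    surprises = [rng.exponential(1.0, 120) for _ in range(21)]
    pdr = [simulate_pdr(h, slope=0.02, noise_sd=0.05,
                        subject_effects=(0.01 * rng.standard_normal(),
                                         0.005 * rng.standard_normal()),
                        rng=rng) for h in surprises]
    res = pdr_slope_test(pdr, surprises)
    assert res.ci95[0] <= 0.02 <= res.ci95[1]
    assert res.p_value < 0.05


def test_pdr_slope_test_drops_degenerate_subjects():
    rng = np.random.default_rng(7)
    surprises = [rng.exponential(1.0, 40) for _ in range(4)] + [np.ones(40)]
    pdr = [simulate_pdr(h, slope=0.02, noise_sd=0.01, rng=rng)
           for h in surprises]
    with pytest.warns(UserWarning):
        res = pdr_slope_test(pdr, surprises)
    assert len(res.subject_slopes) == 4


def test_regression_by_message_type_orders_injected_amplitudes():
    """Types carrying larger injected amplitude show larger masked betas."""
    rng = np.random.default_rng(8)
    data, surprises, types, times = [], [], [], None
    for _ in range(6):
        h = rng.exponential(1.0, 40)
        labels = ["enter_exit"] * 20 + ["pass_by"] * 20
        big, times = simulate_eeg(h[:20], [1, 2], (300.0, 700.0),
                                  amplitude=1.0, noise_sd=0.2,
                                  n_channels=8, n_timepoints=20, rng=rng)
        small, _ = simulate_eeg(h[20:], [1, 2], (300.0, 700.0),
                                amplitude=0.2, noise_sd=0.2,
                                n_channels=8, n_timepoints=20, rng=rng)
        data.append(np.concatenate([big, small]))
        surprises.append(h)
        types.append(labels)
    eps = EpochSet(data=data, step_surprise=surprises, times_ms=times,
                   channel_graph=chain_channel_graph(8))
    mask = np.zeros(8, dtype=bool)
    mask[[1, 2]] = True
    out = regression_by_message_type(eps, types, mask)
    window = (times >= 300) & (times < 700)
    assert out["enter_exit"][0][window].mean() > out["pass_by"][0][window].mean()
    # single-type reduces to the masked epoch regression average
    single = regression_by_message_type(eps, [["x"] * 40] * 6, mask)
    betas = epoch_regression(eps)
    assert np.allclose(single["x"][0], betas[:, mask, :].mean(axis=(0, 1)))
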