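"""Stage-1 channel log-ratio fits and normalization-factor inference."""

import numpy as np
import pandas as pd
import pytest

from plexdiff import (
    ConfigError,
    McmcConfig,
    NormalizationFactors,
    SimulationConfig,
    fit_stage1_protein,
    infer_normalization,
    simulate_study,
)
from plexdiff.benchmarks import effective_n, one_spectrum_study
from plexdiff.quantdata import CHANNELS
from plexdiff.stage1 import Stage1ProteinPosterior, protein_seed


def _degenerate_posterior(counts, seed=5):
    table, design = one_spectrum_study(counts)
    return fit_stage1_protein(
        table,
        design,
        "P1",
        McmcConfig(n_chains=4, n_iterations=3000, burn_in=400, seed=seed),
        check_convergence=False,
        fix_residual_sd=0.0,
        fix_digest_sd=0.0,
    )


def test_doubled_channel_recovers_log_two():
    counts = {c: 100 for c in CHANNELS}
    counts[114] = 200
    post = _degenerate_posterior(counts)
    g = post.gamma_stacked()
    for j, (_, c) in enumerate(post.rc_labels):
        target = np.log(2.0) if c == 114 else 0.0
        se = g[:, j].std() / np.sqrt(max(effective_n(g[:, j]), 50))
        assert abs(g[:, j].mean() - target) < 3 * se + 0.015, f"channel {c}"


def test_protein_seed_is_order_independent_and_stage_distinct():
    assert protein_seed(3, "P1", 1) == protein_seed(3, "P1", 1)
    assert protein_seed(3, "P1", 1) != protein_seed(3, "P1", 2)
    assert protein_seed(3, "P1", 1) != protein_seed(3, "P2", 1)
    assert protein_seed(3, "P1", 1) != protein_seed(4, "P1", 1)


def test_unknown_protein_is_lookup_error(small_study):
    table, design, _ = small_study
    with pytest.raises(KeyError):
        fit_stage1_protein(table, design, "NOPE", McmcConfig.desk())


def _fake_posterior(pid, rc_labels, values):
    """Posterior with degenerate draws at given per-channel values."""
    n = len(rc_labels)
    gamma = np.tile(np.asarray(values, float), (1, 100, 1))
    return Stage1ProteinPosterior(
        protein_id=pid,
        rc_labels=rc_labels,
        gamma=gamma,
        sigma2=np.zeros((1, 100, 8)),
        tau2_digest=np.zeros((1, 100)),
        converged=True,
    )


@pytest.fixture()
def one_run_design():
    _, design = one_spectrum_study({c: 10 for c in CHANNELS})
    return design


class TestInferNormalization:
    def test_degenerate_median_arithmetic(self, one_run_design):
        rc = [("plex1", c) for c in CHANNELS if c != 113]
        posts = [
            _fake_posterior("A", rc, [0.1] * 7),
            _fake_posterior("B", rc, [0.2] * 7),
            _fake_posterior("C", rc, [0.3] * 7),
        ]
        norm = infer_normalization(posts, one_run_design)
        m, s = norm.mean_sd("plex1", 114)
        assert m == pytest.approx(0.2)
        assert s == pytest.approx(0.0)

    def test_identical_zero_draws_give_zero_factor(self, one_run_design):
        rc = [("plex1", c) for c in CHANNELS if c != 113]
        posts = [_fake_posterior(p, rc, [0.0] * 7) for p in "ABC"]
        norm = infer_normalization(posts, one_run_design)
        assert norm.mean_sd("plex1", 118) == (0.0, 0.0)

    def test_reference_channel_pinned_to_zero(self, one_run_design):
        rc = [("plex1", c) for c in CHANNELS if c != 113]
        posts = [_fake_posterior(p, rc, [0.5] * 7) for p in "ABC"]
        norm = infer_normalization(posts, one_run_design)
        assert norm.mean_sd("plex1", 113) == (0.0, 0.0)

    def test_median_robust_to_minority_outliers(self, one_run_design):
        rc = [("plex1", c) for c in CHANNELS if c != 113]
        posts = [_fake_posterior(p, rc, [0.1] * 7) for p in "ABCDE"]
        posts += [_fake_posterior(p, rc, [5.0] * 7) for p in "XY"]  # 2 of 7
        norm = infer_normalization(posts, one_run_design)
        m, _ = norm.mean_sd("plex1", 115)
        assert m == pytest.approx(0.1)

    def test_fewer_than_three_proteins_is_error(self, one_run_design):
        rc = [("plex1", c) for c in CHANNELS if c != 113]
        posts = [_fake_posterior(p, rc, [0.0] * 7) for p in "AB"]
        with pytest.raises(ConfigError):
            infer_normalization(posts, one_run_design)

    def test_nonconverged_proteins_excluded(self, one_run_design):
        rc = [("plex1", c) for c in CHANNELS if c != 113]
        posts = [_fake_posterior(p, rc, [0.1] * 7) for p in "ABCD"]
        bad = _fake_posterior("Z", rc, [9.0] * 7)
        bad.converged = False
        norm = infer_normalization(posts + [bad], one_run_design)
        m, _ = norm.mean_sd("plex1", 116)
        assert m == pytest.approx(0.1)
        row = norm.frame[(norm.frame["channel"] == 116)].iloc[0]
        assert row["n_proteins_used"] == 4

    def test_point_mode_matches_drawwise_for_degenerate_draws(self, one_run_design):
        rc = [("plex1", c) for c in CHANNELS if c != 113]
        posts = [
            _fake_posterior("A", rc, [0.1] * 7),
            _fake_posterior("B", rc, [0.4] * 7),
            _fake_posterior("C", rc, [0.2] * 7),
        ]
        a = infer_normalization(posts, one_run_design, mode="drawwise")
        b = infer_normalization(posts, one_run_design, mode="point")
        assert a.mean_sd("plex1", 117) == b.mean_sd("plex1", 117)


class TestNormalizationFactors:
    def test_json_round_trip(self, tmp_path, one_run_design):
        rc = [("plex1", c) for c in CHANNELS if c != 113]
        posts = [_fake_posterior(p, rc, [0.25] * 7) for p in "ABC"]
        norm = infer_normalization(posts, one_run_design)
        path = tmp_path / "norm.json"
        norm.to_json(path)
        again = NormalizationFactors.from_json(path)
        pd.testing.assert_frame_equal(
            norm.frame, again.frame, check_dtype=False, check_exact=False
        )

    def test_missing_pair_raises(self, one_run_design):
        rc = [("plex1", c) for c in CHANNELS if c != 113]
        posts = [_fake_posterior(p, rc, [0.0] * 7) for p in "ABC"]
        norm = infer_normalization(posts, one_run_design)
        with pytest.raises(ConfigError):
            norm.mean_sd("plex9", 114)

    def test_from_truth_reproduces_biases(self):
        _, _, truth = simulate_study(SimulationConfig(seed=2, n_proteins=3))
        norm = NormalizationFactors.from_truth(truth)
        for run, per in truth.loading_bias_log.items():
            for c_str, v in per.items():
                m, s = norm.mean_sd(run, int(c_str))
                assert m == pytest.approx(v)
                assert s == 0.0


def test_spectrum_scaling_shifts_only_the_baseline(small_study):
    """Multiplying every channel of one spectrum by a constant is absorbed
    by that spectrum's baseline; channel log ratios barely move."""
    table, design, _ = small_study
    pid = max(table.spectra_per_protein(), key=table.spectra_per_protein().get)
    cfg = McmcConfig(n_chains=2, n_iterations=1200, burn_in=300, seed=6)
    base = fit_stage1_protein(table, design, pid, cfg, check_convergence=False)

    frame = table.frame.copy()
    cols = [f"ch{c}" for c in CHANNELS]
    i = frame[frame["protein"] == pid].index[0]
    frame.loc[i, cols] = (frame.loc[i, cols] * 4).astype(np.int64)
    from plexdiff.quantdata import SpectrumTable

    scaled = fit_stage1_protein(
        SpectrumTable(frame), design, pid, cfg, check_convergence=False
    )
    g0, g1 = base.gamma_stacked(), scaled.gamma_stacked()
    for j in range(g0.shape[1]):
        se = np.sqrt(
            g0[:, j].var() / max(effective_n(g0[:, j]), 50)
            + g1[:, j].var() / max(effective_n(g1[:, j]), 50)
        )
        assert abs(g0[:, j].mean() - g1[:, j].mean()) < 4 * se + 0.05
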