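"""Stage-2 differential fits, fold-change test and global-FDR selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plexdiff import (
    ConfigError,
    DifferentialCall,
    McmcConfig,
    NormalizationFactors,
    SimulationConfig,
    fit_stage2_protein,
    fold_change_call,
    select_global_fdr,
    simulate_study,
)
from plexdiff.benchmarks import effective_n
from plexdiff.quantdata import CHANNELS, SpectrumTable


class TestFoldChangeCall:
    def test_all_draws_above_threshold(self):
        call = fold_change_call(np.full(2000, np.log(1.10)), "P1")
        assert call.p_fc == 1.0
        assert call.lfdr == 0.0
        assert call.direction == "up"

    def test_all_draws_at_zero(self):
        call = fold_change_call(np.zeros(2000), "P1")
        assert call.p_fc == 0.0
        assert call.lfdr == 1.0

    def test_counting_with_tie_broken_up(self):
        call = fold_change_call(np.array([-0.2, -0.2, 0.2, 0.2]), "P1")
        assert call.p_fc == 0.5
        assert call.lfdr == 0.5
        assert call.direction == "up"

    def test_down_direction(self):
        call = fold_change_call(np.full(1000, -0.3), "P1")
        assert call.direction == "down"
        assert call.p_fc == 1.0

    def test_threshold_must_exceed_one(self):
        with pytest.raises(ConfigError):
            fold_change_call(np.zeros(10), "P1", threshold=1.0)

    @given(
        draws=st.lists(
            st.floats(min_value=-1.0, max_value=1.0), min_size=1, max_size=60
        ),
        threshold=st.floats(min_value=1.01, max_value=2.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_counting_oracle_and_lfdr_identity(self, draws, threshold):
        theta = np.array(draws)
        call = fold_change_call(theta, "P", threshold)
        t = np.log(threshold)
        p_up = np.mean(theta > t)
        p_down = np.mean(theta < -t)
        assert call.p_fc == pytest.approx(max(p_up, p_down))
        assert call.lfdr == pytest.approx(1.0 - call.p_fc)
        assert call.direction == ("up" if p_up >= p_down else "down")


def _calls(lfdrs):
    return [
        DifferentialCall(protein_id=f"P{i:03d}", p_fc=1.0 - l, lfdr=l, direction="up")
        for i, l in enumerate(lfdrs)
    ]


def _brute_force_select(lfdrs, alpha):
    """Largest prefix of the lfdr-sorted list whose mean is <= alpha."""
    order = sorted(range(len(lfdrs)), key=lambda i: (lfdrs[i], f"P{i:03d}"))
    best = 0
    for k in range(1, len(order) + 1):
        if np.mean([lfdrs[i] for i in order[:k]]) <= alpha + 1e-12:
            best = k
    return {f"P{i:03d}" for i in order[:best]}


class TestSelectGlobalFdr:
    def test_prefix_mean_worked_example(self):
        calls = _calls([0.01, 0.08, 0.20])
        sig = select_global_fdr(calls, alpha=0.05)
        assert sig == {"P000", "P001"}
        assert [c.significant for c in calls] == [True, True, False]

    def test_empty_input(self):
        assert select_global_fdr([], alpha=0.05) == set()

    def test_all_zero_lfdr_all_significant(self):
        calls = _calls([0.0] * 5)
        assert len(select_global_fdr(calls)) == 5

    def test_alpha_validation(self):
        with pytest.raises(ConfigError):
            select_global_fdr(_calls([0.1]), alpha=0.0)

    @given(
        lfdrs=st.lists(
            st.floats(min_value=0.0, max_value=1.0), min_size=0, max_size=50
        ),
        alpha=st.floats(min_value=0.01, max_value=0.5),
    )
    @settings(max_examples=80, deadline=None)
    def test_matches_exhaustive_prefix_search(self, lfdrs, alpha):
        calls = _calls(lfdrs)
        sig = select_global_fdr(calls, alpha)
        assert sig == _brute_force_select(lfdrs, alpha)
        # significance flags agree with the returned set
        assert {c.protein_id for c in calls if c.significant} == sig

    @given(
        lfdrs=st.lists(
            st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_monotone_in_alpha(self, lfdrs):
        calls = _calls(lfdrs)
        small = select_global_fdr(calls, 0.02)
        large = select_global_fdr(calls, 0.10)
        assert small <= large


@pytest.fixture(scope="module")
def fitted():
    cfg = SimulationConfig(
        seed=31,
        n_proteins=6,
        peptides_per_protein=(2, 3),
        spectra_per_peptide=(2, 3),
        fraction_differential=0.5,
        effect_size_log={"kind": "fixed", "value": float(np.log(1.6))},
    )
    table, design, truth = simulate_study(cfg)
    norm = NormalizationFactors.from_truth(truth)
    mcmc = McmcConfig(n_chains=2, n_iterations=1500, burn_in=400, seed=8)
    fits = {
        p: fit_stage2_protein(table, design, norm, p, mcmc, check_convergence=False)
        for p in table.proteins
    }
    return fits, truth, design


class TestFitStage2:
    def test_recovers_large_effects_and_nulls(self, fitted):
        fits, truth, _ = fitted
        for pid, fit in fits.items():
            true = truth.true_effect_log[pid]
            se = fit.theta.std() / np.sqrt(max(effective_n(fit.theta), 50))
            # posterior concentrates near the truth (biological noise allowed)
            assert abs(fit.mean_log_ratio - true) < 0.35
            if true != 0.0:
                assert np.sign(fit.mean_log_ratio) == np.sign(true)

    def test_hpd_brackets_mean_and_sample_quants_complete(self, fitted):
        fits, _, design = fitted
        n_samples = len(design.frame)
        for fit in fits.values():
            assert fit.hpd_low <= fit.mean_log_ratio <= fit.hpd_high
            assert len(fit.sample_quant) == n_samples
            assert fit.sample_draws.shape[1] == n_samples

    def test_missing_normalization_entry_is_config_error(self, fitted):
        fits, truth, design = fitted
        import pandas as pd

        cfg = SimulationConfig(seed=31, n_proteins=6, fraction_differential=0.5)
        table, design2, _ = simulate_study(cfg)
        partial = NormalizationFactors.from_truth(truth)
        partial.frame = partial.frame[partial.frame["run"] != "plex2"]
        partial._index = {
            k: v for k, v in partial._index.items() if k[0] != "plex2"
        }
        with pytest.raises(ConfigError):
            fit_stage2_protein(
                table, design2, partial, table.proteins[0], McmcConfig.desk()
            )


def test_symmetric_counts_give_null_condition_effect():
    """Identical counts in every channel of every spectrum cannot support a
    condition effect."""
    import pandas as pd
    from plexdiff.benchmarks import one_spectrum_study

    rows = []
    for s in range(4):
        row = {
            "protein": "P1",
            "peptide": "P1_pep1",
            "run": "plex1",
            "spectrum": f"s{s}",
        }
        row.update({f"ch{c}": 300 for c in CHANNELS})
        rows.append(row)
    table = SpectrumTable(pd.DataFrame(rows))
    _, design = one_spectrum_study({c: 1 for c in CHANNELS})
    norm = NormalizationFactors(
        pd.DataFrame(
            [
                ("plex1", c, 0.0, 0.0 if c == 113 else 0.05, 3)
                for c in CHANNELS
            ],
            columns=["run", "channel", "mean", "sd", "n_proteins_used"],
        )
    )
    fit = fit_stage2_protein(
        table,
        design,
        norm,
        "P1",
        McmcConfig(n_chains=2, n_iterations=2000, burn_in=500, seed=12),
        check_convergence=False,
    )
    se = fit.theta.std() / np.sqrt(max(effective_n(fit.theta), 50))
    assert abs(fit.theta.mean()) < 3 * se + 0.01
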