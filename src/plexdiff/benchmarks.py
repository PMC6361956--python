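"""Self-contained calibration studies on synthetic data.

Each function simulates data with known truth, runs the relevant pipeline
stage(s) from scratch, and reports summary metrics: agreement with exact
conjugate posteriors on degenerate models, recovery of injected loading
biases, coverage of the condition-effect credible intervals, and realized
false-discovery proportions of the global-FDR selection.  The studies are
sized to run on a single CPU in minutes; the problem sizes used are the
package's reference benchmark conditions and are documented in the
methods note.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .glmm import (
    BatchedPoissonGLMM,
    FIXED_EFFECT_RATE,
    FIXED_EFFECT_SHAPE,
    build_protein_data,
)
from .mcmc import GenericMHModel, McmcConfig, sample_posterior
from .quantdata import CHANNELS, SpectrumTable, StudyDesign, filter_min_spectra
from .simulate import SimulationConfig, simulate_study
from .stage1 import (
    Stage1ProteinPosterior,
    fit_stage1_protein,
    infer_normalization,
    protein_seed,
)
from .stage2 import assemble_fit, select_global_fdr, test_fold_change

#: chain regime for the replicated studies (coverage, FDR calibration);
#: lighter than the desk preset but still >= 1000 kept draws per fit
LIGHT_MCMC = dict(n_chains=2, n_iterations=500, burn_in=200)


def _light(seed: int) -> McmcConfig:
    return McmcConfig(seed=seed, **LIGHT_MCMC)


# ---------------------------------------------------------------------------
# degenerate single-spectrum fixtures


def one_spectrum_study(counts: dict[int, int]) -> tuple[SpectrumTable, StudyDesign]:
    """A one-run, one-spectrum study for conjugate-oracle checks."""
    row = {"protein": "P1", "peptide": "P1_pep1", "run": "plex1", "spectrum": "s1"}
    row.update({f"ch{c}": counts[c] for c in CHANNELS})
    table = SpectrumTable(pd.DataFrame([row]))
    rows = []
    for c in CHANNELS:
        if c == 113:
            rows.append(("plex1", c, f"plex1.{c}", "pool", "reference", "pool-a"))
        elif c == 119:
            rows.append(("plex1", c, f"plex1.{c}", "pool", "reference", "pool-b"))
        elif c in (114, 115, 116):
            rows.append(("plex1", c, f"plex1.{c}", f"ctrl{c}", "control", f"d{c}"))
        else:
            rows.append(("plex1", c, f"plex1.{c}", f"case{c}", "case", f"d{c}"))
    design = StudyDesign(
        pd.DataFrame(
            rows, columns=["run", "channel", "sample", "subject", "group", "digest"]
        )
    )
    return table, design


def exact_degenerate_gamma_draws(
    counts: dict[int, int], n_draws: int = 400_000, seed: int = 0
) -> dict[int, np.ndarray]:
    """Direct (non-MCMC) sampler for the degenerate single-spectrum model.

    With residual and digest variances pinned to zero the model reduces to
    independent Poisson counts with rates exp(beta) and exp(beta + gamma_c);
    under the package's Gamma(shape, rate) prior on the exponential scale
    the posterior factorizes as a one-dimensional marginal for a = e^beta
    (sampled here by inverse-CDF on a dense grid) times independent
    Gamma(y_c + shape, a + rate) conditionals for b_c = e^{gamma_c}.
    Returns draws of gamma_c = ln b_c per non-reference channel.
    """
    g0, r0 = FIXED_EFFECT_SHAPE, FIXED_EFFECT_RATE
    y0 = counts[113]
    others = [c for c in CHANNELS if c != 113]
    ys = np.array([counts[c] for c in others], float)
    total = y0 + ys.sum()
    centre = max(total / 8.0, 1.0)
    grid = np.linspace(max(centre * 0.2, 1e-3), centre * 5.0, 200_001)
    logp = (
        (total + g0 - 1.0) * np.log(grid)
        - grid * (1.0 + r0)
        - (ys + g0).sum() * np.log(grid + r0)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xDECA]))
    a = rng.choice(grid, p=p, size=n_draws)
    out = {}
    for c, yc in zip(others, ys):
        b = rng.standard_gamma(yc + g0, n_draws) / (a + r0)
        out[c] = np.log(b)
    return out


def conjugate_checks(seed: int = 0) -> dict:
    """Criterion-style conjugate-oracle comparison, in Monte-Carlo SEs.

    Three checks: (a) the degenerate stage-1 model against the exact direct
    sampler above; (b) a Normal-mean model with known variance against its
    closed-form posterior; (c) a Poisson-rate model with Gamma prior against
    its closed form.  Each reports the largest |z| observed, where z is the
    discrepancy of the posterior-mean estimate divided by its MC standard
    error (3 is the conventional agreement bound).
    """
    counts = {c: 100 for c in CHANNELS}
    counts[114] = 200
    table, design = one_spectrum_study(counts)
    post = fit_stage1_protein(
        table,
        design,
        "P1",
        McmcConfig(n_chains=4, n_iterations=4000, burn_in=500, seed=seed),
        check_convergence=False,
        fix_residual_sd=0.0,
        fix_digest_sd=0.0,
    )
    exact = exact_degenerate_gamma_draws(counts, seed=seed)
    zs = []
    g = post.gamma_stacked()
    for j, (_, c) in enumerate(post.rc_labels):
        draws = g[:, j]
        ess = max(effective_n(draws), 50.0)
        se = np.sqrt(draws.var() / ess + exact[c].var() / exact[c].size)
        zs.append(abs(draws.mean() - exact[c].mean()) / se)
    z_stage1 = float(max(zs))

    # Normal mean, known variance 2^2, prior N(0, 3^2), one observation y=1.5
    y, s2, t2 = 1.5, 4.0, 9.0
    post_var = 1.0 / (1.0 / t2 + 1.0 / s2)
    post_mean = post_var * (y / s2)
    model = GenericMHModel(
        lambda x: -0.5 * ((y - x[:, 0]) ** 2 / s2 + x[:, 0] ** 2 / t2),
        dim=1,
        init_scale=2.0,
    )
    draws = sample_posterior(model, 4, 4000, 500, seed=seed + 1).stacked("x")[:, 0]
    se = np.sqrt(post_var / max(effective_n(draws), 50.0))
    z_normal = float(abs(draws.mean() - post_mean) / se)

    # Poisson rate, Gamma(a, b) prior, observed count y
    a0, b0, yy = 3.0, 1.0, 7
    model = GenericMHModel(
        lambda x: yy * x[:, 0] - np.exp(x[:, 0]) + a0 * x[:, 0] - b0 * np.exp(x[:, 0]),
        dim=1,
        init_mean=np.log((a0 + yy) / (b0 + 1.0)),
        init_scale=0.5,
    )
    ldraws = sample_posterior(model, 4, 4000, 500, seed=seed + 2).stacked("x")[:, 0]
    rate = np.exp(ldraws)
    exact_mean = (a0 + yy) / (b0 + 1.0)
    exact_var = (a0 + yy) / (b0 + 1.0) ** 2
    se = np.sqrt(exact_var / max(effective_n(rate), 50.0))
    z_poisson = float(abs(rate.mean() - exact_mean) / se)

    return {
        "stage1_degenerate_max_z": z_stage1,
        "normal_conjugate_z": z_normal,
        "poisson_gamma_z": z_poisson,
        "n_draws": int(g.shape[0]),
    }


def effective_n(x: np.ndarray) -> float:
    """Initial-positive-sequence autocorrelation ESS for a single chain."""
    x = np.asarray(x, float).ravel()
    n = x.size
    if n < 10 or x.var() == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 :] / (xc @ xc)
    s = 1.0
    for k in range(1, min(n // 2, 2000)):
        if acf[k] + (acf[k + 1] if k + 1 < n else 0.0) < 0:
            break
        s += 2.0 * acf[k]
    return float(n / max(s, 1.0))


# ---------------------------------------------------------------------------
# normalization recovery


def normalization_recovery_study(
    seed: int = 0,
    config: SimulationConfig | None = None,
    mcmc: McmcConfig | None = None,
) -> dict:
    """Recover injected loading biases on the default synthetic study.

    Fits stage 1 for every filtered protein at the desk chain regime and
    checks, per assigned non-reference (run, channel), whether the inferred
    median log ratio lies within max(0.05, 3 * posterior SD) of the true
    bias.  Differential proteins and subject effects are present, so this
    also exercises the median's robustness.
    """
    config = config or SimulationConfig(seed=seed)
    mcmc = mcmc or McmcConfig.desk(seed=seed)
    table, design, truth = simulate_study(config)
    filtered, _ = filter_min_spectra(table)
    posteriors = [
        fit_stage1_protein(filtered, design, p, mcmc) for p in filtered.proteins
    ]
    norm = infer_normalization(posteriors, design)
    rows = []
    for _, r in norm.frame.iterrows():
        if r["channel"] == 113:
            continue
        true = truth.bias(r["run"], int(r["channel"]))
        tol = max(0.05, 3.0 * r["sd"])
        rows.append(
            {
                "run": r["run"],
                "channel": int(r["channel"]),
                "true_bias": true,
                "estimate": r["mean"],
                "sd": r["sd"],
                "error": r["mean"] - true,
                "within": bool(abs(r["mean"] - true) <= tol),
            }
        )
    per = pd.DataFrame(rows)
    n_conv = sum(p.converged for p in posteriors)
    return {
        "recovery_rate": float(per["within"].mean()),
        "n_pairs": int(len(per)),
        "mean_abs_error": float(per["error"].abs().mean()),
        "max_abs_error": float(per["error"].abs().max()),
        "n_proteins": len(posteriors),
        "n_converged": int(n_conv),
        "table": per,
    }


# ---------------------------------------------------------------------------
# batched fitting of structurally identical proteins (uniform synthetic
# regions); used by the replicated studies so that hundreds of fits cost
# little more than one


def fit_stage1_batch(table, design, pids, mcmc: McmcConfig):
    datas = [build_protein_data(table.for_protein(p), design, p) for p in pids]
    model = BatchedPoissonGLMM(
        datas, stage=1, chains_per_protein=mcmc.n_chains
    )
    seed = protein_seed(mcmc.seed, "|".join(pids), stage=1)
    draws = sample_posterior(
        model, model.total_chains, mcmc.n_iterations, mcmc.burn_in, seed
    )
    out = []
    for i, d in enumerate(datas):
        out.append(
            Stage1ProteinPosterior(
                protein_id=d.protein_id,
                rc_labels=d.rc_labels,
                gamma=model.slice_protein(draws.params["gamma"], i),
                sigma2=model.slice_protein(draws.params["sigma2"], i),
                tau2_digest=model.slice_protein(draws.params["tau2_digest"], i),
                converged=True,
            )
        )
    return out


def fit_stage2_batch(table, design, norm, pids, mcmc: McmcConfig):
    datas = [build_protein_data(table.for_protein(p), design, p) for p in pids]
    m, sd = norm.aligned(datas[0].rc_labels)
    model = BatchedPoissonGLMM(
        datas,
        stage=2,
        chains_per_protein=mcmc.n_chains,
        rc_prior_mean=m,
        rc_prior_sd=sd,
    )
    seed = protein_seed(mcmc.seed, "|".join(pids), stage=2)
    draws = sample_posterior(
        model, model.total_chains, mcmc.n_iterations, mcmc.burn_in, seed
    )

    def stacked(name, i):
        a = model.slice_protein(draws.params[name], i)
        return a.reshape(-1, *a.shape[2:])

    return [
        assemble_fit(
            d,
            theta=stacked("theta", i),
            nu=stacked("nu", i),
            u=stacked("u", i),
            tau2_case=stacked("tau2_case", i),
            tau2_ctrl=stacked("tau2_ctrl", i),
        )
        for i, d in enumerate(datas)
    ]


# ---------------------------------------------------------------------------
# condition-effect recovery and coverage


def coverage_study(
    seed: int = 0,
    n_proteins: int = 100,
    n_stage1_proteins: int = 40,
    mcmc: McmcConfig | None = None,
) -> dict:
    """HPD coverage and bias of the condition effect over many proteins.

    One synthetic study with ``n_proteins`` under the default study
    conditions (20% truly differential at |log fc| = ln 1.5), with uniform
    compact proteins (2 peptides x 2 spectra per run) so the whole cohort
    fits in one batched sampler.  Normalization comes from a stage-1 fit
    of a protein subset, exactly as the pipeline would obtain it.  Reports
    95% HPD coverage of the true effect and the mean signed error of the
    posterior means.
    """
    mcmc = mcmc or _light(seed)
    config = SimulationConfig(
        seed=seed,
        n_proteins=n_proteins,
        peptides_per_protein=(2, 2),
        spectra_per_peptide=(2, 2),
    )
    table, design, truth = simulate_study(config)
    filtered, _ = filter_min_spectra(table)
    proteins = filtered.proteins
    stage1_set = proteins[: min(n_stage1_proteins, len(proteins))]
    posteriors = fit_stage1_batch(filtered, design, stage1_set, mcmc)
    norm = infer_normalization(posteriors, design)
    rows = []
    for fit in fit_stage2_batch(filtered, design, norm, proteins, mcmc):
        true = truth.true_effect_log[fit.protein_id]
        rows.append(
            {
                "protein": fit.protein_id,
                "true": true,
                "mean": fit.mean_log_ratio,
                "low": fit.hpd_low,
                "high": fit.hpd_high,
                "covered": bool(fit.hpd_low <= true <= fit.hpd_high),
            }
        )
    per = pd.DataFrame(rows)
    bias = per["mean"] - per["true"]
    return {
        "coverage": float(per["covered"].mean()),
        "n_proteins": int(len(per)),
        "mean_bias": float(bias.mean()),
        "bias_se": float(bias.std(ddof=1) / np.sqrt(len(per))),
        "mean_abs_error": float(bias.abs().mean()),
        "table": per,
    }


# ---------------------------------------------------------------------------
# FDR calibration


def _region_config(seed: int, fraction: float, n_proteins: int) -> SimulationConfig:
    return SimulationConfig(
        seed=seed,
        n_proteins=n_proteins,
        peptides_per_protein=(2, 2),
        spectra_per_peptide=(2, 2),
        fraction_differential=fraction,
    )


def analyze_synthetic_region(
    config: SimulationConfig,
    mcmc: McmcConfig,
    alpha: float = 0.05,
    fc_threshold: float = 1.05,
):
    """Simulate one region and run both stages; returns (calls, truth, table)."""
    table, design, truth = simulate_study(config)
    filtered, _ = filter_min_spectra(table)
    posteriors = fit_stage1_batch(filtered, design, filtered.proteins, mcmc)
    norm = infer_normalization(posteriors, design)
    fits = fit_stage2_batch(filtered, design, norm, filtered.proteins, mcmc)
    calls = [test_fold_change(f, fc_threshold) for f in fits]
    select_global_fdr(calls, alpha)
    return calls, truth, filtered


def fdr_calibration_study(
    seed: int = 0,
    n_regions: int = 50,
    n_null_regions: int = 10,
    n_proteins: int = 24,
    alpha: float = 0.05,
) -> dict:
    """Realized FDP of the global-FDR set across replicated regions.

    ``n_regions`` synthetic regions with 20% truly differential proteins
    (effects +/- ln 1.5) are analysed end to end; the realized
    false-discovery proportion is averaged across regions and compared to
    the nominal level.  ``n_null_regions`` pure-null regions count spurious
    discoveries.  Also reports the recovery power for well-measured
    differential proteins (>= 6 spectra).
    """
    root = np.random.SeedSequence([int(seed), 0xFD5])
    region_seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in root.spawn(n_regions + n_null_regions)]
    fdps, n_disc = [], []
    power_hits, power_total = 0, 0
    for i in range(n_regions):
        rs = region_seeds[i]
        calls, truth, table = analyze_synthetic_region(
            _region_config(rs, 0.2, n_proteins), _light(rs), alpha=alpha
        )
        sig = {c.protein_id for c in calls if c.significant}
        false = {p for p in sig if truth.true_effect_log[p] == 0.0}
        fdps.append(len(false) / len(sig) if sig else 0.0)
        n_disc.append(len(sig))
        spectra = table.spectra_per_protein()
        for p, eff in truth.true_effect_log.items():
            if abs(eff) >= np.log(1.5) - 1e-9 and spectra.get(p, 0) >= 6:
                power_total += 1
                power_hits += p in sig
    null_disc = []
    for i in range(n_null_regions):
        rs = region_seeds[n_regions + i]
        calls, truth, _ = analyze_synthetic_region(
            _region_config(rs, 0.0, n_proteins), _light(rs), alpha=alpha
        )
        null_disc.append(sum(c.significant for c in calls))
    fdps = np.array(fdps)
    return {
        "mean_fdp": float(fdps.mean()),
        "fdp_mc_se": float(fdps.std(ddof=1) / np.sqrt(len(fdps))),
        "n_regions": int(n_regions),
        "mean_discoveries": float(np.mean(n_disc)),
        "power": float(power_hits / power_total) if power_total else float("nan"),
        "n_power_proteins": int(power_total),
        "null_mean_discoveries": float(np.mean(null_disc)) if null_disc else 0.0,
        "n_null_regions": int(n_null_regions),
    }
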