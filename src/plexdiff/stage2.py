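"""Stage 2: full-design differential fits, fold-change test, FDR selection.

The stage-2 model fits, per protein, the complete experimental design:
sample fixed effects with priors set to the stage-1 normalization
posterior (mean and SD of the median log ratio), a case-versus-control
condition effect with control as baseline, and subject random effects
split into separate case and control variance components, because
biological variance differs between the groups.  Reference-pool samples
carry condition status 0 and no subject deviation: they anchor the
normalization structure without inflating control biological variance.

Significance uses the posterior directly: P(1.05 fc) is the posterior
probability that the fold change exceeds the threshold in its dominant
direction, the local FDR is its complement, and the global-FDR set is the
largest lFDR-ordered prefix whose average lFDR stays at or below the
chosen level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd

from .errors import ConfigError
from .glmm import PoissonGLMM, build_protein_data
from .mcmc import ConvergenceReport, McmcConfig, assess_convergence, sample_posterior
from .quantdata import SpectrumTable, StudyDesign
from .stage1 import NormalizationFactors, protein_seed

logger = logging.getLogger(__name__)


@dataclass
class ProteinFit:
    """Posterior for one protein's condition effect and sample levels."""

    protein_id: str
    theta: np.ndarray  # (n_draws,) natural-log fold change, case vs control
    mean_log_ratio: float
    hpd_low: float
    hpd_high: float
    sample_quant: pd.DataFrame  # sample, mean, sd of latent sample log level
    sample_draws: np.ndarray  # (n_draws, n_samples)
    tau2_case: np.ndarray
    tau2_ctrl: np.ndarray
    converged: bool
    convergence: ConvergenceReport | None = None

    def __post_init__(self):
        if not (self.hpd_low <= self.mean_log_ratio <= self.hpd_high):
            raise ValueError("posterior mean must lie inside the HPD interval")


def fit_stage2_protein(
    table: SpectrumTable,
    design: StudyDesign,
    norm: NormalizationFactors,
    protein_id: str,
    mcmc: McmcConfig,
    *,
    check_convergence: bool = True,
    hdi_prob: float = 0.95,
    cauchy_scale: float = 1.0,
    ig_shape: float = 1e-3,
    ig_rate: float = 1e-3,
    fix_residual_sd: float | None = None,
    fix_digest_sd: float | None = None,
) -> ProteinFit:
    """Fit the full-design GLMM for one protein.

    Raises :class:`ConfigError` if the normalization factors do not cover
    every (run, channel) the protein was observed in.  Non-convergence
    flags the fit; it is not dropped.
    """
    frame = table.for_protein(protein_id)
    data = build_protein_data(frame, design, protein_id)
    m, s = norm.aligned(data.rc_labels)
    model = PoissonGLMM(
        data,
        stage=2,
        rc_prior_mean=m,
        rc_prior_sd=s,
        cauchy_scale=cauchy_scale,
        ig_shape=ig_shape,
        ig_rate=ig_rate,
        fix_residual_sd=fix_residual_sd,
        fix_digest_sd=fix_digest_sd,
    )
    draws = sample_posterior(
        model,
        n_chains=mcmc.n_chains,
        n_iterations=mcmc.n_iterations,
        burn_in=mcmc.burn_in,
        seed=protein_seed(mcmc.seed, protein_id, stage=2),
    )
    report = None
    converged = True
    if check_convergence and mcmc.n_chains >= 2:
        report = assess_convergence(
            type(draws)(
                params={"theta": draws.params["theta"]},
                n_chains=draws.n_chains,
                n_iterations=draws.n_iterations,
                burn_in=draws.burn_in,
                seed=draws.seed,
            )
        )
        converged = report.converged
        if not converged:
            logger.warning(
                "stage-2 fit for %s not converged (R-hat %.3f, ESS %.0f)",
                protein_id,
                report.max_r_hat,
                report.min_ess,
            )
    return assemble_fit(
        data,
        theta=draws.stacked("theta"),
        nu=draws.stacked("nu"),
        u=draws.stacked("u"),
        tau2_case=draws.stacked("tau2_case"),
        tau2_ctrl=draws.stacked("tau2_ctrl"),
        hdi_prob=hdi_prob,
        converged=converged,
        convergence=report,
    )


def assemble_fit(
    data,
    *,
    theta: np.ndarray,
    nu: np.ndarray,
    u: np.ndarray,
    tau2_case: np.ndarray,
    tau2_ctrl: np.ndarray,
    hdi_prob: float = 0.95,
    converged: bool = True,
    convergence: ConvergenceReport | None = None,
) -> ProteinFit:
    """Build a :class:`ProteinFit` from chain-concatenated draw arrays."""
    hdi = az.hdi(theta, hdi_prob=hdi_prob)
    mean = float(theta.mean())
    n_draws = theta.shape[0]
    zero = np.zeros((n_draws, 1))
    nu_ext = np.concatenate([nu, zero], axis=1)
    u_ext = np.concatenate([u, zero], axis=1) if u.size else np.zeros((n_draws, 1))
    samples = data.samples
    q = (
        nu_ext[:, samples["rc_i"].to_numpy()]
        + u_ext[:, samples["subj_i"].to_numpy()]
        + theta[:, None] * samples["is_case"].to_numpy()[None, :]
    )
    quant = pd.DataFrame(
        {
            "sample": samples["sample"].to_numpy(),
            "run": samples["run"].to_numpy(),
            "channel": samples["channel"].to_numpy(),
            "mean": q.mean(axis=0),
            "sd": q.std(axis=0, ddof=1),
        }
    )
    return ProteinFit(
        protein_id=data.protein_id,
        theta=theta,
        mean_log_ratio=mean,
        hpd_low=float(min(hdi[0], mean)),
        hpd_high=float(max(hdi[1], mean)),
        sample_quant=quant,
        sample_draws=q,
        tau2_case=tau2_case,
        tau2_ctrl=tau2_ctrl,
        converged=converged,
        convergence=convergence,
    )


@dataclass
class DifferentialCall:
    """Fold-change-threshold test result for one protein."""

    protein_id: str
    p_fc: float
    lfdr: float
    direction: str  # "up" | "down"
    significant: bool = False
    mean_log_ratio: float = float("nan")
    converged: bool = True

    def __post_init__(self):
        if not np.isclose(self.lfdr, 1.0 - self.p_fc):
            raise ValueError("lfdr must equal 1 - p_fc")


def fold_change_call(
    theta_draws: np.ndarray,
    protein_id: str,
    threshold: float = 1.05,
    mean_log_ratio: float | None = None,
    converged: bool = True,
) -> DifferentialCall:
    """P(fold change beyond +/-threshold) from raw condition-effect draws.

    ``p_up`` is the fraction of draws above ln(threshold), ``p_down`` the
    fraction below -ln(threshold); the call takes the larger with its
    direction (ties go up), and lFDR = 1 - P exactly.
    """
    if threshold <= 1.0:
        raise ConfigError("fold-change threshold must exceed 1")
    theta = np.asarray(theta_draws, float).ravel()
    if theta.size == 0:
        raise ConfigError("no posterior draws")
    t = np.log(threshold)
    p_up = float((theta > t).mean())
    p_down = float((theta < -t).mean())
    p_fc = max(p_up, p_down)
    direction = "up" if p_up >= p_down else "down"
    return DifferentialCall(
        protein_id=protein_id,
        p_fc=p_fc,
        lfdr=1.0 - p_fc,
        direction=direction,
        mean_log_ratio=(
            float(theta.mean()) if mean_log_ratio is None else float(mean_log_ratio)
        ),
        converged=converged,
    )


def test_fold_change(fit: ProteinFit, threshold: float = 1.05) -> DifferentialCall:
    return fold_change_call(
        fit.theta,
        fit.protein_id,
        threshold,
        mean_log_ratio=fit.mean_log_ratio,
        converged=fit.converged,
    )


def select_global_fdr(
    calls: list[DifferentialCall], alpha: float = 0.05
) -> set[str]:
    """Largest lFDR-ordered prefix with average lFDR <= alpha.

    Calls are sorted by lFDR ascending with ties broken by protein id;
    the selected calls are marked ``significant`` in place and their ids
    returned.  An empty input yields an empty set.
    """
    if not 0.0 < alpha < 1.0:
        raise ConfigError("alpha must lie in (0, 1)")
    for c in calls:
        c.significant = False
    if not calls:
        return set()
    order = sorted(calls, key=lambda c: (c.lfdr, c.protein_id))
    means = np.cumsum([c.lfdr for c in order]) / np.arange(1, len(order) + 1)
    ok = np.nonzero(means <= alpha)[0]
    if ok.size == 0:
        return set()
    k = int(ok[-1]) + 1
    chosen = order[:k]
    for c in chosen:
        c.significant = True
    return {c.protein_id for c in chosen}


def results_table(calls: list[DifferentialCall], fits=None) -> pd.DataFrame:
    """Per-protein results in the column layout the pipeline publishes."""
    by_id = {f.protein_id: f for f in fits} if fits else {}
    rows = []
    for c in sorted(calls, key=lambda c: c.protein_id):
        f = by_id.get(c.protein_id)
        rows.append(
            {
                "protein": c.protein_id,
                "mean_log_ratio": c.mean_log_ratio,
                "hpd_low": f.hpd_low if f else float("nan"),
                "hpd_high": f.hpd_high if f else float("nan"),
                "p_fc": c.p_fc,
                "lfdr": c.lfdr,
                "direction": c.direction,
                "significant": c.significant,
                "converged": c.converged,
            }
        )
    return pd.DataFrame(rows)
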