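"""Stage 1: per-protein run-by-channel fits and sample normalization.

Within each run the model infers, per protein, the log ratio of every
channel against channel 113.  Because most proteins do not change between
samples, the across-protein *median* of these log ratios reflects only how
much material each channel received (loading/labelling bias).  Taking the
median draw-wise over the proteins' posterior samples yields a posterior
distribution for each normalization factor; its mean and SD become the
prior for the corresponding sample fixed effect in stage 2, so
normalization uncertainty propagates instead of being frozen into a point
estimate.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .glmm import PoissonGLMM, build_protein_data
from .mcmc import ConvergenceReport, McmcConfig, assess_convergence, sample_posterior
from .quantdata import CHANNELS, REFERENCE_CHANNEL, SpectrumTable, StudyDesign

logger = logging.getLogger(__name__)


def protein_seed(base_seed: int, protein_id: str, stage: int) -> int:
    """Order-independent per-protein seed (stable across runs and platforms)."""
    h = zlib.crc32(f"stage{stage}:{protein_id}".encode())
    return int((h ^ (int(base_seed) * 2654435761)) & 0x7FFFFFFF)


@dataclass
class Stage1ProteinPosterior:
    """Posterior for one protein's within-run channel log ratios."""

    protein_id: str
    rc_labels: list[tuple[str, int]]
    gamma: np.ndarray  # (chains, iterations, n_rc) log ratio vs channel 113
    sigma2: np.ndarray  # (chains, iterations, 8) per-channel residual variances
    tau2_digest: np.ndarray  # (chains, iterations) digest variance
    converged: bool
    convergence: ConvergenceReport | None = None

    def gamma_stacked(self) -> np.ndarray:
        return self.gamma.reshape(-1, self.gamma.shape[-1])


def fit_stage1_protein(
    table: SpectrumTable,
    design: StudyDesign,
    protein_id: str,
    mcmc: McmcConfig,
    *,
    check_convergence: bool = True,
    cauchy_scale: float = 1.0,
    ig_shape: float = 1e-3,
    ig_rate: float = 1e-3,
    fix_residual_sd: float | None = None,
    fix_digest_sd: float | None = None,
) -> Stage1ProteinPosterior:
    """Fit the stage-1 GLMM for one protein.

    A non-converged fit is returned flagged, never dropped; exclusion is
    the normalization step's decision.
    """
    frame = table.for_protein(protein_id)
    data = build_protein_data(frame, design, protein_id)
    model = PoissonGLMM(
        data,
        stage=1,
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
        seed=protein_seed(mcmc.seed, protein_id, stage=1),
    )
    report = None
    converged = True
    if check_convergence and mcmc.n_chains >= 2:
        report = assess_convergence(
            type(draws)(
                params={"gamma": draws.params["gamma"]},
                n_chains=draws.n_chains,
                n_iterations=draws.n_iterations,
                burn_in=draws.burn_in,
                seed=draws.seed,
            )
        )
        converged = report.converged
        if not converged:
            logger.warning(
                "stage-1 fit for %s not converged (max R-hat %.3f, min ESS %.0f)",
                protein_id,
                report.max_r_hat,
                report.min_ess,
            )
    return Stage1ProteinPosterior(
        protein_id=protein_id,
        rc_labels=data.rc_labels,
        gamma=draws.params["gamma"],
        sigma2=draws.params["sigma2"],
        tau2_digest=draws.params["tau2_digest"],
        converged=converged,
        convergence=report,
    )


class NormalizationFactors:
    """Per-(run, channel) posterior mean/SD of the median log ratio.

    Backed by a DataFrame with columns run, channel, mean, sd,
    n_proteins_used.  The reference channel carries (0, 0) by convention.
    """

    def __init__(self, frame: pd.DataFrame):
        required = ("run", "channel", "mean", "sd", "n_proteins_used")
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ConfigError(f"normalization table missing {missing}")
        frame = frame.loc[:, list(required)].copy()
        frame["channel"] = frame["channel"].astype(int)
        frame["mean"] = frame["mean"].astype(float)
        frame["sd"] = frame["sd"].astype(float)
        ref = frame[frame["channel"] == REFERENCE_CHANNEL]
        if not (np.allclose(ref["mean"], 0.0) and np.allclose(ref["sd"], 0.0)):
            raise ConfigError("reference-channel factors must be (0, 0)")
        if not np.isfinite(frame[["mean", "sd"]].to_numpy()).all():
            raise ConfigError("normalization factors must be finite")
        self.frame = frame.sort_values(["run", "channel"]).reset_index(drop=True)
        self._index = {
            (r, c): (m, s)
            for r, c, m, s in zip(
                frame["run"], frame["channel"], frame["mean"], frame["sd"]
            )
        }

    def mean_sd(self, run: str, channel: int) -> tuple[float, float]:
        try:
            return self._index[(run, int(channel))]
        except KeyError:
            raise ConfigError(f"no normalization factor for ({run}, {channel})")

    def aligned(self, rc_labels: list[tuple[str, int]]) -> tuple[np.ndarray, np.ndarray]:
        m = np.array([self.mean_sd(r, c)[0] for r, c in rc_labels])
        s = np.array([self.mean_sd(r, c)[1] for r, c in rc_labels])
        return m, s

    def to_json(self, path) -> None:
        self.frame.to_json(path, orient="records", indent=1)

    @classmethod
    def from_json(cls, path) -> "NormalizationFactors":
        return cls(pd.read_json(path, orient="records"))

    @classmethod
    def from_truth(cls, truth, runs=None) -> "NormalizationFactors":
        """Factors taken directly from a simulation's loading biases
        (zero SD) — handy for oracle checks that isolate stage 2."""
        rows = []
        for run, per in truth.loading_bias_log.items():
            if runs is not None and run not in runs:
                continue
            for c_str, v in per.items():
                rows.append((run, int(c_str), float(v), 0.0, 0))
        return cls(
            pd.DataFrame(rows, columns=["run", "channel", "mean", "sd", "n_proteins_used"])
        )


def infer_normalization(
    posteriors: list[Stage1ProteinPosterior],
    design: StudyDesign,
    *,
    mode: str = "drawwise",
    min_proteins: int = 3,
) -> NormalizationFactors:
    """Combine per-protein channel log ratios into normalization factors.

    For each (run, channel) the draw-wise median across proteins is formed
    (chains concatenated, draws paired by iteration index, subsampled
    evenly to the shortest protein's draw count), and its posterior mean
    and SD reported.  ``mode='point'`` instead takes the median of the
    per-protein posterior means (the SD still comes from the draw-wise
    median, so stage 2 always receives a usable prior scale).
    Non-converged proteins are excluded with a logged warning.
    """
    if mode not in ("drawwise", "point"):
        raise ConfigError(f"unknown normalization mode {mode!r}")
    usable = [p for p in posteriors if p.converged]
    dropped = [p.protein_id for p in posteriors if not p.converged]
    if dropped:
        logger.warning(
            "excluding %d non-converged protein(s) from normalization: %s",
            len(dropped),
            ", ".join(sorted(dropped)[:10]),
        )
    by_rc: dict[tuple[str, int], list[np.ndarray]] = {}
    for p in usable:
        stacked = p.gamma_stacked()
        for j, lab in enumerate(p.rc_labels):
            by_rc.setdefault(lab, []).append(stacked[:, j])

    rows = []
    for run in design.runs:
        for c in CHANNELS:
            if c == REFERENCE_CHANNEL:
                rows.append((run, c, 0.0, 0.0, len(usable)))
                continue
            series = by_rc.get((run, c), [])
            if len(series) < min_proteins:
                raise ConfigError(
                    f"need >= {min_proteins} converged proteins for ({run}, {c}); "
                    f"got {len(series)}"
                )
            L = min(s.size for s in series)
            idx = np.linspace(0, L - 1, L).astype(int)
            mat = np.stack(
                [s[np.linspace(0, s.size - 1, L).astype(int)] for s in series]
            )
            med = np.median(mat, axis=0)
            del idx
            m = float(np.median([s.mean() for s in series])) if mode == "point" else float(
                med.mean()
            )
            s_ = float(med.std(ddof=1)) if L > 1 else 0.0
            rows.append((run, c, m, s_, len(series)))
    return NormalizationFactors(
        pd.DataFrame(rows, columns=["run", "channel", "mean", "sd", "n_proteins_used"])
    )
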