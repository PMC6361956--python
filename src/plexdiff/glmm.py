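"""Per-protein Poisson log-link mixed model and its block sampler.

One protein's reporter-ion counts are modelled, per observation
(spectrum s, channel c):

    y[s, c] ~ Poisson(exp(eta[s, c]))
    eta[s, c] = beta_s                 per-spectrum baseline (fixed)
              + g[run(s), c]           run-by-channel or sample effect
              + theta * x_c            condition effect (stage 2 only)
              + u[subject(c)]          group-specific subject effect (stage 2)
              + d[peptide(s), digest(c)]  peptide-by-digest random effect
              + eps[s, c]              log-normal over-dispersion residual

with the reference channel's run effect pinned to 0 so g is the
protein-level log ratio versus channel 113 within each run.  Residual
variances sigma_c^2 carry inverse-Gamma priors; random-effect standard
deviations carry half-Cauchy priors implemented by parameter expansion
(the Huang-Wand inverse-Gamma mixture), which keeps every variance update
an exact Gibbs draw.  Fixed effects use a vague conjugate log-gamma prior
(Gamma with small shape and near-zero rate on the exponential scale):
indistinguishable from flat whenever a group has observed ions, proper for
all-zero groups, scale-free over any realistic count magnitude, and it
makes the baseline, run-by-channel (stage 1) and condition updates exact
Gamma-Gibbs draws instead of Metropolis steps.

Sampling is Metropolis-within-Gibbs.  Every update is vectorized across
chains and across the units of a block; only the residuals, the
normal-prior sample effects (stage 2) and the random effects need
Metropolis steps, each with per-unit adaptive step sizes tuned during
burn-in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .quantdata import CHANNELS, REFERENCE_CHANNEL, StudyDesign

#: vague conjugate prior on exp-scale fixed effects: Gamma(shape, rate) with a
#: tiny rate so the prior is scale-free over any realistic count magnitude
#: (a rate comparable to the shape would penalize large baselines noticeably)
FIXED_EFFECT_SHAPE = 0.01
FIXED_EFFECT_RATE = 1e-8
#: numerical guard for exp-scale Gibbs draws from zero-count groups
_EFFECT_CLAMP = 30.0

_LOG_STEP_MIN, _LOG_STEP_MAX = -6.0, 2.0
_ADAPT_RATE = 0.08
_TARGET = 0.44


@dataclass
class ProteinData:
    """Index structure for one protein's observations."""

    protein_id: str
    y: np.ndarray  # (N,) float (counts)
    spec_idx: np.ndarray  # (N,) -> spectrum
    chan_pos: np.ndarray  # (N,) -> 0..7 position in CHANNELS
    rc_idx: np.ndarray  # (N,) -> run-channel effect, G = pinned reference slot
    dig_idx: np.ndarray  # (N,) -> peptide-by-digest effect
    subj_idx: np.ndarray  # (N,) -> subject effect, U = pinned slot
    case_cols: np.ndarray  # indices of case observations
    case_mask: np.ndarray  # (N,) bool
    rc_labels: list[tuple[str, int]]
    dig_labels: list[tuple[str, str]]
    subj_labels: list[str]
    subj_is_case: np.ndarray  # (U,) bool
    samples: pd.DataFrame  # sample, run, channel, rc_i, subj_i, is_case
    n_spectra: int

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def n_rc(self) -> int:
        return len(self.rc_labels)

    @property
    def n_dig(self) -> int:
        return len(self.dig_labels)

    @property
    def n_subj(self) -> int:
        return len(self.subj_labels)


def build_protein_data(
    frame: pd.DataFrame, design: StudyDesign, protein_id: str
) -> ProteinData:
    """Flatten one protein's spectrum rows into indexed observations."""
    sub = frame.sort_values(["run", "spectrum"]).reset_index(drop=True)
    S = len(sub)
    n_chan = len(CHANNELS)
    y = sub[[f"ch{c}" for c in CHANNELS]].to_numpy(float).ravel()
    spec_idx = np.repeat(np.arange(S), n_chan)
    chan_pos = np.tile(np.arange(n_chan), S)
    obs = pd.DataFrame(
        {
            "run": np.repeat(sub["run"].to_numpy(), n_chan),
            "peptide": np.repeat(sub["peptide"].to_numpy(), n_chan),
            "channel": np.tile(np.array(CHANNELS), S),
        }
    )
    obs = obs.merge(design.frame, on=["run", "channel"], how="left", sort=False)
    if obs["sample"].isna().any():
        run = obs.loc[obs["sample"].isna().idxmax(), "run"]
        raise ConfigError(f"design does not cover run {run!r}")

    runs = sorted(sub["run"].unique())
    rc_labels = [(r, c) for r in runs for c in CHANNELS if c != REFERENCE_CHANNEL]
    rc_pos = {lab: i for i, lab in enumerate(rc_labels)}
    G = len(rc_labels)
    rc_idx = np.array(
        [
            G if c == REFERENCE_CHANNEL else rc_pos[(r, c)]
            for r, c in zip(obs["run"], obs["channel"])
        ]
    )

    dig_pairs = list(zip(obs["peptide"], obs["digest"]))
    dig_labels = sorted(set(dig_pairs))
    dig_pos = {lab: i for i, lab in enumerate(dig_labels)}
    dig_idx = np.array([dig_pos[p] for p in dig_pairs])

    nonref = obs["group"] != "reference"
    subj_labels = sorted(obs.loc[nonref, "subject"].unique())
    subj_pos = {sbj: i for i, sbj in enumerate(subj_labels)}
    U = len(subj_labels)
    subj_idx = np.array(
        [
            U if g == "reference" else subj_pos[sbj]
            for g, sbj in zip(obs["group"], obs["subject"])
        ]
    )
    subj_group = obs.drop_duplicates("subject").set_index("subject")["group"]
    subj_is_case = np.array([subj_group[sbj] == "case" for sbj in subj_labels])

    case_mask = (obs["group"] == "case").to_numpy()

    samp = design.frame[design.frame["run"].isin(runs)].copy()
    samp["rc_i"] = [
        G if c == REFERENCE_CHANNEL else rc_pos[(r, c)]
        for r, c in zip(samp["run"], samp["channel"])
    ]
    samp["subj_i"] = [
        U if g == "reference" else subj_pos[sbj]
        for g, sbj in zip(samp["group"], samp["subject"])
    ]
    samp["is_case"] = samp["group"] == "case"
    samp = samp.sort_values(["run", "channel"]).reset_index(drop=True)

    return ProteinData(
        protein_id=protein_id,
        y=y,
        spec_idx=spec_idx,
        chan_pos=chan_pos,
        rc_idx=rc_idx,
        dig_idx=dig_idx,
        subj_idx=subj_idx,
        case_cols=np.nonzero(case_mask)[0],
        case_mask=case_mask,
        rc_labels=rc_labels,
        dig_labels=dig_labels,
        subj_labels=subj_labels,
        subj_is_case=subj_is_case,
        samples=samp[["sample", "run", "channel", "rc_i", "subj_i", "is_case"]],
        n_spectra=S,
    )


def _group_matrix(idx: np.ndarray, n_groups: int, n_obs: int) -> np.ndarray:
    """Dense indicator matrix (n_groups, n_obs) summing observations into
    groups; indices >= n_groups (pinned slots) contribute to no group.
    Dense because the per-protein problems are small and BLAS beats sparse
    dispatch overhead at this size."""
    M = np.zeros((n_groups, n_obs))
    keep = idx < n_groups
    M[idx[keep], np.nonzero(keep)[0]] = 1.0
    return M


def _invgamma(rng, shape, rate, size):
    # tiny shapes underflow to exactly 0; floor keeps the quotient finite
    return rate / np.maximum(rng.standard_gamma(shape, size=size), 1e-290)


class PoissonGLMM:
    """Block sampler for one protein, stage 1 or stage 2.

    Stage 1 fits run-by-channel fixed effects with the vague conjugate
    prior; stage 2 gives those effects Normal(m, s^2) priors taken from
    the stage-1 normalization posterior and adds the condition effect and
    group-specific subject random effects.  Variance components can be
    pinned (``fix_* = value``; 0 removes the component exactly), which is
    how the degenerate conjugate-oracle configurations are expressed.
    """

    def __init__(
        self,
        data: ProteinData,
        *,
        stage: int,
        rc_prior_mean: np.ndarray | None = None,
        rc_prior_sd: np.ndarray | None = None,
        cauchy_scale: float = 1.0,
        ig_shape: float = 1e-3,
        ig_rate: float = 1e-3,
        fix_residual_sd: float | None = None,
        fix_digest_sd: float | None = None,
    ):
        if stage not in (1, 2):
            raise ConfigError("stage must be 1 or 2")
        if stage == 2:
            if rc_prior_mean is None or rc_prior_sd is None:
                raise ConfigError("stage 2 requires rc prior means and SDs")
            rc_prior_mean = np.asarray(rc_prior_mean, float)
            rc_prior_sd = np.asarray(rc_prior_sd, float)
            if rc_prior_mean.shape != (data.n_rc,) or rc_prior_sd.shape != (data.n_rc,):
                raise ConfigError("rc prior arrays must match the run-channel layout")
        self.data = data
        self.stage = stage
        self.rc_m = rc_prior_mean
        self.rc_s = rc_prior_sd
        self.A = float(cauchy_scale)
        self.ig_shape = float(ig_shape)
        self.ig_rate = float(ig_rate)
        self.fix_res = fix_residual_sd
        self.fix_dig = fix_digest_sd

        d = data
        N = d.n_obs
        self.M_spec = _group_matrix(d.spec_idx, d.n_spectra, N)
        self.M_rc = _group_matrix(d.rc_idx, d.n_rc, N)
        self.M_dig = _group_matrix(d.dig_idx, d.n_dig, N)
        self.M_subj = _group_matrix(d.subj_idx, d.n_subj, N)
        self.M_chan = _group_matrix(d.chan_pos, len(CHANNELS), N)
        self.Y_spec = np.asarray(self.M_spec @ d.y)
        self.Y_rc = np.asarray(self.M_rc @ d.y)
        self.Y_dig = np.asarray(self.M_dig @ d.y)
        self.Y_subj = np.asarray(self.M_subj @ d.y)
        self.Y_case = float(d.y[d.case_cols].sum())
        self.n_chan_obs = np.asarray(self.M_chan @ np.ones(N))
        if self.stage == 2:
            self.rc_free = self.rc_s > 0  # zero-SD priors pin the effect

        # --- structure for translation (recentering) moves ---------------
        # each digest group lives entirely inside one run-channel group
        # (a digest belongs to one sample); map it there (G = pinned slot)
        dig_rc = np.empty(d.n_dig, dtype=int)
        seen = np.full(d.n_dig, False)
        for obs_i, g in enumerate(d.dig_idx):
            if not seen[g]:
                dig_rc[g] = d.rc_idx[obs_i]
                seen[g] = True
        self.dig_rc = dig_rc
        self.n_dig_per_rc = np.bincount(
            dig_rc[dig_rc < d.n_rc], minlength=d.n_rc
        ).astype(float)
        self.M_digrc = _group_matrix(dig_rc, d.n_rc, d.n_dig)
        self.n_obs_per_rc = np.asarray(self.M_rc @ np.ones(N))
        self.rc_chan = np.array(
            [CHANNELS.index(c) for _, c in d.rc_labels], dtype=int
        )
        # rc group -> subject slot / case status of its sample (stage 2)
        rc_subj = np.full(d.n_rc, d.n_subj, dtype=int)
        rc_case = np.zeros(d.n_rc, dtype=bool)
        for _, row in d.samples.iterrows():
            if row["rc_i"] < d.n_rc:
                rc_subj[row["rc_i"]] = row["subj_i"]
                rc_case[row["rc_i"]] = bool(row["is_case"])
        self.rc_subj = rc_subj
        self.rc_case = rc_case
        self.case_subjects = np.nonzero(d.subj_is_case)[0]
        self.M_subj_rc = _group_matrix(rc_subj, max(d.n_subj, 1), d.n_rc)
        # digest and subject cross-links for translation moves
        dig_subj = np.full(d.n_dig, d.n_subj, dtype=int)
        seen = np.full(d.n_dig, False)
        for obs_i, g in enumerate(d.dig_idx):
            if not seen[g]:
                dig_subj[g] = d.subj_idx[obs_i]
                seen[g] = True
        self.M_subj_dig = _group_matrix(dig_subj, max(d.n_subj, 1), d.n_dig)
        self.dig_subj = dig_subj
        self.n_dig_per_subj = np.bincount(
            dig_subj[dig_subj < d.n_subj], minlength=max(d.n_subj, 1)
        ).astype(float)
        self.n_obs_per_subj = np.asarray(self.M_subj @ np.ones(N))
        # each digest group sits in one channel; needed for digest-residual moves
        dig_chan = np.empty(d.n_dig, dtype=int)
        seen = np.full(d.n_dig, False)
        for obs_i, g in enumerate(d.dig_idx):
            if not seen[g]:
                dig_chan[g] = d.chan_pos[obs_i]
                seen[g] = True
        self.dig_chan = dig_chan
        self.n_obs_per_dig = np.asarray(self.M_dig @ np.ones(N))
        # run-level structure: spectra, free rc effects and reference-channel
        # observations of each run
        run_labels = sorted({r for r, _ in d.rc_labels}) if d.rc_labels else []
        run_pos = {r: i for i, r in enumerate(run_labels)}
        self.run_labels = run_labels
        R = len(run_labels)
        # run of each spectrum, via its observations' free rc effects
        spec_run = np.empty(d.n_spectra, dtype=int)
        rc_run = np.array([run_pos[r] for r, _ in d.rc_labels], dtype=int)
        rc_run_ext = np.concatenate([rc_run, [-1]]) if R else np.array([-1])
        obs_run_from_rc = rc_run_ext[d.rc_idx]
        for s in range(d.n_spectra):
            block = obs_run_from_rc[s * len(CHANNELS) : (s + 1) * len(CHANNELS)]
            spec_run[s] = block[block >= 0][0]
        self.spec_run = spec_run
        self.M_run_spec = _group_matrix(spec_run, max(R, 1), d.n_spectra)
        self.M_run_rc = _group_matrix(rc_run, max(R, 1), d.n_rc)
        ref_obs = np.nonzero(d.rc_idx == d.n_rc)[0]
        self.ref_obs = ref_obs
        self.ref_obs_run = spec_run[d.spec_idx[ref_obs]]
        self.M_run_ref = _group_matrix(self.ref_obs_run, max(R, 1), ref_obs.size)
        self.n_ref_per_run = np.asarray(self.M_run_ref @ np.ones(ref_obs.size))
        self.ref_chan = int(CHANNELS.index(113))
        # reference-channel digest groups of each run (for the d-compensated
        # run move); a pinned digest group's run is read off its first obs
        ref_dig = np.nonzero(dig_rc == d.n_rc)[0]
        self.ref_dig = ref_dig
        dig_run = np.full(d.n_dig, -1, dtype=int)
        seen = np.full(d.n_dig, False)
        for obs_i, g in enumerate(d.dig_idx):
            if not seen[g]:
                dig_run[g] = spec_run[d.spec_idx[obs_i]]
                seen[g] = True
        self.ref_dig_run = dig_run[ref_dig]
        self.M_run_refdig = _group_matrix(self.ref_dig_run, max(R, 1), ref_dig.size)
        self.n_refdig_per_run = np.asarray(self.M_run_refdig @ np.ones(ref_dig.size))
        self.rc_run_of = rc_run
        self.n_spec_run = np.asarray(self.M_run_spec @ np.ones(d.n_spectra))
        self.n_rc_run = np.asarray(self.M_run_rc @ np.ones(d.n_rc))
        if self.stage == 2:
            s2f = np.where(self.rc_free, self.rc_s**2, np.inf)
            self.rc_inv_s2 = 1.0 / s2f
            self.run_prec_rc = np.asarray(self.M_run_rc @ self.rc_inv_s2)
            self.run_m_over_s2 = np.asarray(self.M_run_rc @ (self.rc_m * self.rc_inv_s2))
            self.run_pinned = np.asarray(self.M_run_rc @ (~self.rc_free).astype(float)) > 0
        self.n_ref_safe = np.maximum(self.n_ref_per_run, 1.0)
        self.n_refdig_safe = np.maximum(self.n_refdig_per_run, 1.0)

        # Marginalized variance updates for stage 1.  The likelihood is flat
        # along every group-mean direction of eps (per run-channel group, and
        # per run on the reference channel) and of d (same groups), because a
        # flat fixed effect absorbs the shift.  In the identifiable
        # parametrization those mean coordinates belong to the fixed effects,
        # so the residual/digest variance updates must see only the centred
        # within-group residuals, with correspondingly fewer degrees of
        # freedom; feeding the free coordinates into the variance Gibbs
        # update would couple them into a divergent feedback loop.
        chan_of_rc = _group_matrix(self.rc_chan, len(CHANNELS), d.n_rc)
        self.M_chan_rc = chan_of_rc  # (8, G): channel of each free rc group
        # count of free-mean groups per channel (reference channel: per run)
        k_chan = np.asarray(chan_of_rc @ (self.n_obs_per_rc > 0).astype(float))
        k_chan[self.ref_chan] += float(np.sum(self.n_ref_per_run > 0))
        self.k_chan = k_chan
        n_dgroups = float(np.sum(self.n_dig_per_rc > 0)) + float(
            np.sum(self.n_refdig_per_run > 0)
        )
        self.dig_dof = max(d.n_dig - n_dgroups, 0.0)

        # per-"chain" data rows; the batched subclass overrides these so the
        # same update code serves many structurally identical proteins at once
        self.y_row = d.y[None, :]
        self.Y_spec_row = self.Y_spec[None, :]
        self.Y_rc_row = self.Y_rc[None, :]
        self.Y_dig_row = self.Y_dig[None, :]
        self.Y_subj_row = self.Y_subj[None, :]
        self.Y_case_arr = self.Y_case
        self.beta_init_row = np.log(
            np.maximum(np.asarray(self.M_spec @ d.y) / 8.0, 0.5)
        )[None, :]
        self.rc_m_row = None if self.rc_m is None else self.rc_m[None, :]

    # -- state ------------------------------------------------------------

    def init_state(self, n_chains: int, rng: np.random.Generator) -> dict:
        d = self.data
        C = n_chains
        st: dict = {}
        st["beta"] = self.beta_init_row + 0.3 * rng.standard_normal((C, d.n_spectra))
        rc = np.zeros((C, d.n_rc + 1))
        if self.stage == 1:
            rc[:, : d.n_rc] = 0.3 * rng.standard_normal((C, d.n_rc))
        else:
            jitter = (self.rc_s + 0.05) * rng.standard_normal((C, d.n_rc))
            rc[:, : d.n_rc] = self.rc_m_row + np.where(
                self.rc_free[None, :], jitter, 0.0
            )
        st["rc"] = rc
        st["theta"] = 0.3 * rng.standard_normal(C)
        u = np.zeros((C, d.n_subj + 1))
        u[:, : d.n_subj] = 0.1 * rng.standard_normal((C, d.n_subj))
        st["u"] = u
        st["d"] = 0.05 * rng.standard_normal((C, d.n_dig))
        if self.fix_dig == 0.0:
            st["d"][:] = 0.0
        st["eps"] = 0.05 * rng.standard_normal((C, d.n_obs))
        if self.fix_res == 0.0:
            st["eps"][:] = 0.0
        if self.fix_res is not None:
            st["sig2"] = np.full((C, len(CHANNELS)), float(self.fix_res) ** 2)
        else:
            st["sig2"] = 0.04 * np.exp(0.5 * rng.standard_normal((C, len(CHANNELS))))
        if self.fix_dig is not None:
            st["tau2_d"] = np.full(C, float(self.fix_dig) ** 2)
        else:
            st["tau2_d"] = 0.04 * np.exp(0.5 * rng.standard_normal(C))
        st["a_d"] = np.ones(C)
        for grp in ("case", "ctrl"):
            st[f"tau2_{grp}"] = 0.04 * np.exp(0.5 * rng.standard_normal(C))
            st[f"a_{grp}"] = np.ones(C)
        st["lam"] = np.exp(self._eta(st))
        st["ls_eps"] = np.full((C, len(CHANNELS)), np.log(0.5))
        st["ls_rc"] = np.full((C, d.n_rc), np.log(0.3))
        st["ls_u"] = np.full((C, d.n_subj), np.log(0.3))
        st["ls_d"] = np.full((C, d.n_dig), np.log(0.3))
        return st

    def _eta(self, st: dict) -> np.ndarray:
        d = self.data
        eta = (
            st["beta"][:, d.spec_idx]
            + st["rc"][:, d.rc_idx]
            + st["d"][:, d.dig_idx]
            + st["eps"]
        )
        if self.stage == 2:
            eta = eta + st["u"][:, d.subj_idx]
            eta[:, d.case_cols] += st["theta"][:, None]
        return eta

    def log_density(self, st: dict) -> np.ndarray:
        """Poisson log-likelihood per chain (up to a constant); used for
        sanity checks, not by the sampler itself."""
        lam = np.exp(self._eta(st))
        return (self.data.y[None, :] * np.log(lam) - lam).sum(axis=1)

    # -- block updates -----------------------------------------------------

    def _gsum(self, M, arr):
        return arr @ M.T

    def _update_eps(self, st, rng, adapt):
        if self.fix_res == 0.0:
            return
        d = self.data
        lam = st["lam"]
        C, N = lam.shape
        step = np.exp(st["ls_eps"])[:, d.chan_pos]
        delta = step * rng.standard_normal((C, N))
        lam_new = lam * np.exp(delta)
        sig2 = st["sig2"][:, d.chan_pos]
        logr = self.y_row * delta - (lam_new - lam) - delta * (
            2.0 * st["eps"] + delta
        ) / (2.0 * sig2)
        acc = np.log(rng.random((C, N))) < logr
        st["eps"] = np.where(acc, st["eps"] + delta, st["eps"])
        st["lam"] = np.where(acc, lam_new, lam)
        if adapt:
            rate = self._gsum(self.M_chan, acc.astype(float)) / self.n_chan_obs
            st["ls_eps"] = np.clip(
                st["ls_eps"] + _ADAPT_RATE * (rate - _TARGET),
                _LOG_STEP_MIN,
                _LOG_STEP_MAX,
            )

    def _update_sig2(self, st, rng):
        if self.fix_res is not None:
            return
        ss = self._gsum(self.M_chan, st["eps"] ** 2)
        dof = self.n_chan_obs[None, :]
        if self.stage == 1:
            # subtract the free group-mean coordinates (see __init__)
            n_rc = np.maximum(self.n_obs_per_rc, 1.0)
            s_rc = self._gsum(self.M_rc, st["eps"])
            contrib = (s_rc**2 / n_rc[None, :]) @ self.M_chan_rc.T
            if self.ref_obs.size:
                s_ref = self._gsum(self.M_run_ref, st["eps"][:, self.ref_obs])
                contrib[:, self.ref_chan] += (
                    s_ref**2 / np.maximum(self.n_ref_per_run, 1.0)[None, :]
                ).sum(axis=1)
            ss = np.maximum(ss - contrib, 0.0)
            dof = dof - self.k_chan[None, :]
        shape = self.ig_shape + 0.5 * np.maximum(dof, 0.0)
        rate = self.ig_rate + 0.5 * ss
        st["sig2"] = np.minimum(
            _invgamma(rng, np.broadcast_to(shape, ss.shape), rate, ss.shape), 100.0
        )

    def _update_beta(self, st, rng):
        g0, r0 = FIXED_EFFECT_SHAPE, FIXED_EFFECT_RATE
        lam = st["lam"]
        gs = self._gsum(self.M_spec, lam)
        T = gs / np.exp(st["beta"])
        draw = rng.standard_gamma(self.Y_spec_row + g0, size=gs.shape)
        new = np.clip(np.log(draw / (T + r0)), -_EFFECT_CLAMP, _EFFECT_CLAMP)
        st["lam"] = lam * np.exp((new - st["beta"])[:, self.data.spec_idx])
        st["beta"] = new

    def _update_rc(self, st, rng, adapt):
        d = self.data
        if d.n_rc == 0:
            return
        lam = st["lam"]
        v = st["rc"][:, : d.n_rc]
        Lam = self._gsum(self.M_rc, lam)
        if self.stage == 1:
            g0, r0 = FIXED_EFFECT_SHAPE, FIXED_EFFECT_RATE
            T = Lam / np.exp(v)
            draw = rng.standard_gamma(self.Y_rc_row + g0, size=Lam.shape)
            new = np.clip(np.log(draw / (T + r0)), -_EFFECT_CLAMP, _EFFECT_CLAMP)
            delta = new - v
            st["rc"][:, : d.n_rc] = new
        else:
            step = np.exp(st["ls_rc"])
            prop = step * rng.standard_normal(Lam.shape)
            prop = np.where(self.rc_free[None, :], prop, 0.0)
            s2 = np.where(self.rc_free, self.rc_s**2, 1.0)
            logr = (
                prop * self.Y_rc_row
                - Lam * np.expm1(prop)
                - prop * (2.0 * (v - self.rc_m_row) + prop) / (2.0 * s2[None, :])
            )
            acc = np.log(rng.random(Lam.shape)) < logr
            delta = np.where(acc, prop, 0.0)
            st["rc"][:, : d.n_rc] = v + delta
            if adapt:
                st["ls_rc"] = np.clip(
                    st["ls_rc"] + _ADAPT_RATE * (acc.astype(float) - _TARGET),
                    _LOG_STEP_MIN,
                    _LOG_STEP_MAX,
                )
        ext = np.concatenate([delta, np.zeros((delta.shape[0], 1))], axis=1)
        st["lam"] = lam * np.exp(ext[:, d.rc_idx])

    def _update_theta(self, st, rng):
        d = self.data
        if self.stage != 2 or d.case_cols.size == 0:
            return
        g0, r0 = FIXED_EFFECT_SHAPE, FIXED_EFFECT_RATE
        lam = st["lam"]
        Lam = lam[:, d.case_cols].sum(axis=1)
        T = Lam / np.exp(st["theta"])
        draw = rng.standard_gamma(self.Y_case_arr + g0, size=Lam.shape)
        new = np.clip(np.log(draw / (T + r0)), -_EFFECT_CLAMP, _EFFECT_CLAMP)
        lam[:, d.case_cols] *= np.exp(new - st["theta"])[:, None]
        st["theta"] = new

    def _update_u(self, st, rng, adapt):
        d = self.data
        if self.stage != 2 or d.n_subj == 0:
            return
        lam = st["lam"]
        v = st["u"][:, : d.n_subj]
        Lam = self._gsum(self.M_subj, lam)
        tau2 = np.where(
            d.subj_is_case[None, :], st["tau2_case"][:, None], st["tau2_ctrl"][:, None]
        )
        step = np.exp(st["ls_u"])
        prop = step * rng.standard_normal(Lam.shape)
        logr = (
            prop * self.Y_subj_row
            - Lam * np.expm1(prop)
            - prop * (2.0 * v + prop) / (2.0 * tau2)
        )
        acc = np.log(rng.random(Lam.shape)) < logr
        delta = np.where(acc, prop, 0.0)
        st["u"][:, : d.n_subj] = v + delta
        ext = np.concatenate([delta, np.zeros((delta.shape[0], 1))], axis=1)
        st["lam"] = lam * np.exp(ext[:, d.subj_idx])
        if adapt:
            st["ls_u"] = np.clip(
                st["ls_u"] + _ADAPT_RATE * (acc.astype(float) - _TARGET),
                _LOG_STEP_MIN,
                _LOG_STEP_MAX,
            )

    def _update_d(self, st, rng, adapt):
        d = self.data
        if self.fix_dig == 0.0 or d.n_dig == 0:
            return
        lam = st["lam"]
        v = st["d"]
        Lam = self._gsum(self.M_dig, lam)
        step = np.exp(st["ls_d"])
        prop = step * rng.standard_normal(Lam.shape)
        tau2 = st["tau2_d"][:, None]
        logr = (
            prop * self.Y_dig_row
            - Lam * np.expm1(prop)
            - prop * (2.0 * v + prop) / (2.0 * tau2)
        )
        acc = np.log(rng.random(Lam.shape)) < logr
        delta = np.where(acc, prop, 0.0)
        st["d"] = v + delta
        st["lam"] = lam * np.exp(delta[:, d.dig_idx])
        if adapt:
            st["ls_d"] = np.clip(
                st["ls_d"] + _ADAPT_RATE * (acc.astype(float) - _TARGET),
                _LOG_STEP_MIN,
                _LOG_STEP_MAX,
            )

    def _update_variances(self, st, rng):
        C = st["theta"].shape[0]
        A2 = self.A**2
        if self.fix_dig is None and self.data.n_dig > 0:
            ss = (st["d"] ** 2).sum(axis=1)
            n = float(self.data.n_dig)
            if self.stage == 1:
                n_g = np.maximum(self.n_dig_per_rc, 1.0)
                s_g = self._gsum(self.M_digrc, st["d"])
                contrib = (s_g**2 / n_g[None, :]).sum(axis=1)
                if self.ref_dig.size:
                    s_r = self._gsum(self.M_run_refdig, st["d"][:, self.ref_dig])
                    contrib += (
                        s_r**2 / np.maximum(self.n_refdig_per_run, 1.0)[None, :]
                    ).sum(axis=1)
                ss = np.maximum(ss - contrib, 0.0)
                n = self.dig_dof
            st["tau2_d"] = np.minimum(
                _invgamma(rng, 0.5 * (n + 1), 1.0 / st["a_d"] + 0.5 * ss, C), 100.0
            )
            st["a_d"] = _invgamma(rng, 1.0, 1.0 / A2 + 1.0 / st["tau2_d"], C)
        if self.stage == 2 and self.data.n_subj > 0:
            for grp, mask in (
                ("case", self.data.subj_is_case),
                ("ctrl", ~self.data.subj_is_case),
            ):
                n = int(mask.sum())
                ss = (st["u"][:, : self.data.n_subj][:, mask] ** 2).sum(axis=1)
                st[f"tau2_{grp}"] = _invgamma(
                    rng, 0.5 * (n + 1), 1.0 / st[f"a_{grp}"] + 0.5 * ss, C
                )
                st[f"a_{grp}"] = _invgamma(
                    rng, 1.0, 1.0 / A2 + 1.0 / st[f"tau2_{grp}"], C
                )

    # -- translation (recentering) moves ----------------------------------
    # The likelihood is flat along several directions: a run-channel effect
    # can absorb the mean of its digest effects, its residuals, or (stage 2)
    # its sample's subject effect; the baseline can absorb a spectrum's
    # residual mean; the condition effect can absorb the mean case-subject
    # effect.  Each move below translates along one such direction with the
    # shift drawn from the exact Gaussian implied by the Normal priors
    # (a Metropolis correction covers the vague log-gamma prior of the
    # parent, whose acceptance is essentially 1).  The linear predictor is
    # unchanged, so the cached Poisson rates need no update.

    def _vague_accept(self, st, rng, parent, delta):
        """Accept/reject against the Gamma(g0, g0) prior of an exp-scale
        fixed effect; returns the accepted shifts (zero where rejected)."""
        g0, r0 = FIXED_EFFECT_SHAPE, FIXED_EFFECT_RATE
        logr = g0 * delta - r0 * np.exp(parent) * np.expm1(delta)
        acc = np.log(rng.random(delta.shape)) < logr
        return np.where(acc, delta, 0.0)

    def _recenter_rc_d(self, st, rng):
        d = self.data
        ok = self.n_dig_per_rc > 0
        if self.fix_dig == 0.0 or d.n_rc == 0 or not ok.any():
            return
        dbar = self._gsum(self.M_digrc, st["d"]) / np.maximum(self.n_dig_per_rc, 1.0)
        tau2 = st["tau2_d"][:, None] if self.fix_dig is None else float(self.fix_dig) ** 2
        v = st["rc"][:, : d.n_rc]
        if self.stage == 1:
            sd = np.sqrt(tau2 / np.maximum(self.n_dig_per_rc, 1.0))
            delta = dbar + sd * rng.standard_normal(dbar.shape)
            delta = self._vague_accept(st, rng, v, delta)
        else:
            prec = self.n_dig_per_rc[None, :] / tau2 + 1.0 / np.where(
                self.rc_free, self.rc_s**2, np.inf
            )
            mean = (
                self.n_dig_per_rc[None, :] * dbar / tau2
                + (self.rc_m_row - v) / np.where(self.rc_free, self.rc_s**2, np.inf)
            ) / prec
            delta = mean + rng.standard_normal(dbar.shape) / np.sqrt(prec)
            delta = np.where(self.rc_free[None, :], delta, 0.0)
        delta = np.where(ok[None, :], delta, 0.0)
        st["rc"][:, : d.n_rc] = v + delta
        ext = np.concatenate([delta, np.zeros((delta.shape[0], 1))], axis=1)
        st["d"] = st["d"] - ext[:, self.dig_rc]

    def _recenter_rc_eps(self, st, rng):
        d = self.data
        if self.fix_res == 0.0 or d.n_rc == 0:
            return
        n = np.maximum(self.n_obs_per_rc, 1.0)
        ebar = self._gsum(self.M_rc, st["eps"]) / n
        sig2 = st["sig2"][:, self.rc_chan]
        v = st["rc"][:, : d.n_rc]
        if self.stage == 1:
            delta = ebar + np.sqrt(sig2 / n[None, :]) * rng.standard_normal(ebar.shape)
            delta = self._vague_accept(st, rng, v, delta)
        else:
            prec = n[None, :] / sig2 + 1.0 / np.where(self.rc_free, self.rc_s**2, np.inf)
            mean = (
                n[None, :] * ebar / sig2
                + (self.rc_m_row - v)
                / np.where(self.rc_free, self.rc_s**2, np.inf)
            ) / prec
            delta = mean + rng.standard_normal(ebar.shape) / np.sqrt(prec)
            delta = np.where(self.rc_free[None, :], delta, 0.0)
        st["rc"][:, : d.n_rc] = v + delta
        ext = np.concatenate([delta, np.zeros((delta.shape[0], 1))], axis=1)
        st["eps"] = st["eps"] - ext[:, d.rc_idx]

    def _recenter_beta_eps(self, st, rng):
        d = self.data
        if self.fix_res == 0.0:
            return
        w = 1.0 / st["sig2"]  # (C, 8)
        lam_prec = w.sum(axis=1, keepdims=True)  # every spectrum sees all 8 channels
        wsum = self._gsum(self.M_spec, st["eps"] * w[:, d.chan_pos])
        mean = wsum / lam_prec
        delta = mean + rng.standard_normal(mean.shape) / np.sqrt(lam_prec)
        delta = self._vague_accept(st, rng, st["beta"], delta)
        st["beta"] = st["beta"] + delta
        st["eps"] = st["eps"] - delta[:, d.spec_idx]

    def _recenter_rc_u(self, st, rng):
        d = self.data
        if self.stage != 2 or d.n_rc == 0 or d.n_subj == 0:
            return
        has_u = self.rc_subj < d.n_subj
        free = self.rc_free & has_u
        if not free.any():
            return
        u_ext = np.concatenate(
            [st["u"][:, : d.n_subj], np.zeros((st["u"].shape[0], 1))], axis=1
        )
        u_of_rc = u_ext[:, self.rc_subj]
        tau2 = np.where(
            self.rc_case[None, :], st["tau2_case"][:, None], st["tau2_ctrl"][:, None]
        )
        v = st["rc"][:, : d.n_rc]
        s2 = np.where(free, self.rc_s**2, np.inf)
        prec = 1.0 / tau2 + 1.0 / s2[None, :]
        mean = (u_of_rc / tau2 + (self.rc_m_row - v) / s2[None, :]) / prec
        delta = mean + rng.standard_normal(v.shape) / np.sqrt(prec)
        delta = np.where(free[None, :], delta, 0.0)
        st["rc"][:, : d.n_rc] = v + delta
        # subtract each rc shift from its sample's subject effect
        st["u"][:, : d.n_subj] -= self._gsum(self.M_subj_rc, delta)

    def _recenter_d_eps(self, st, rng):
        d = self.data
        if self.fix_dig == 0.0 or self.fix_res == 0.0 or d.n_dig == 0:
            return
        tau2 = (
            st["tau2_d"][:, None]
            if self.fix_dig is None
            else float(self.fix_dig) ** 2
        )
        sig2 = st["sig2"][:, self.dig_chan]
        n = self.n_obs_per_dig[None, :]
        ebar = self._gsum(self.M_dig, st["eps"]) / np.maximum(n, 1.0)
        prec = 1.0 / tau2 + n / sig2
        mean = (-st["d"] / tau2 + n * ebar / sig2) / prec
        delta = mean + rng.standard_normal(st["d"].shape) / np.sqrt(prec)
        st["d"] = st["d"] + delta
        st["eps"] = st["eps"] - delta[:, d.dig_idx]

    def _recenter_run(self, st, rng, compensate: str = "eps"):
        """Whole-run mode: shift every free channel effect of a run against
        the run's spectrum baselines, compensating on the reference channel's
        residuals (``eps``) or digest effects (``d``); resolves the reference
        channel's anchoring of the within-run common mode."""
        d = self.data
        R = len(self.run_labels)
        if R == 0:
            return
        if compensate == "eps":
            if self.fix_res == 0.0 or self.ref_obs.size == 0:
                return
            child = st["eps"][:, self.ref_obs]
            cbar = self._gsum(self.M_run_ref, child) / self.n_ref_safe
            cvar = st["sig2"][:, self.ref_chan][:, None]
            n_child = self.n_ref_safe
        else:
            if self.fix_dig == 0.0 or self.ref_dig.size == 0:
                return
            child = st["d"][:, self.ref_dig]
            cbar = self._gsum(self.M_run_refdig, child) / self.n_refdig_safe
            cvar = (
                st["tau2_d"][:, None]
                if self.fix_dig is None
                else np.full((child.shape[0], 1), float(self.fix_dig) ** 2)
            )
            n_child = self.n_refdig_safe
        sig2 = cvar
        # delta enters the compensating children positively: target mean -cbar
        delta = -cbar + np.sqrt(sig2 / n_child) * rng.standard_normal(cbar.shape)
        # Metropolis correction for the vague priors of beta (shift -delta)
        # and of the run's free rc effects (shift +delta); stage 2 rc
        # effects have Normal priors handled exactly instead.
        g0, r0 = FIXED_EFFECT_SHAPE, FIXED_EFFECT_RATE
        exp_beta_run = self._gsum(self.M_run_spec, np.exp(st["beta"]))
        v = st["rc"][:, : d.n_rc]
        if self.stage == 1:
            exp_rc_run = self._gsum(self.M_run_rc, np.exp(v))
            logr = (
                g0 * (-delta) * self.n_spec_run[None, :]
                - r0 * exp_beta_run * np.expm1(-delta)
                + g0 * delta * self.n_rc_run[None, :]
                - r0 * exp_rc_run * np.expm1(delta)
            )
        else:
            # Normal rc priors enter the delta density exactly via a
            # Gaussian factor; fold them into the proposal instead
            mean_rc_num = self.run_m_over_s2[None, :] - self._gsum(
                self.M_run_rc, v * self.rc_inv_s2[None, :]
            )
            prec = n_child[None, :] / sig2 + self.run_prec_rc[None, :]
            mean = (n_child[None, :] * (-cbar) / sig2 + mean_rc_num) / prec
            delta = mean + rng.standard_normal(cbar.shape) / np.sqrt(prec)
            # a pinned effect cannot shift, so its whole run must sit still
            delta = np.where(self.run_pinned[None, :], 0.0, delta)
            logr = g0 * (-delta) * self.n_spec_run[None, :] - r0 * exp_beta_run * np.expm1(
                -delta
            )
        acc = np.log(rng.random(delta.shape)) < logr
        delta = np.where(acc, delta, 0.0)
        st["beta"] = st["beta"] - delta[:, self.spec_run]
        st["rc"][:, : d.n_rc] = st["rc"][:, : d.n_rc] + delta[:, self.rc_run_of]
        if compensate == "eps":
            st["eps"][:, self.ref_obs] = child + delta[:, self.ref_obs_run]
        else:
            st["d"][:, self.ref_dig] = child + delta[:, self.ref_dig_run]

    def _subject_tau2(self, st):
        d = self.data
        return np.where(
            d.subj_is_case[None, :], st["tau2_case"][:, None], st["tau2_ctrl"][:, None]
        )

    def _recenter_u_eps(self, st, rng):
        d = self.data
        if self.stage != 2 or d.n_subj == 0 or self.fix_res == 0.0:
            return
        w = 1.0 / st["sig2"]  # (C, 8)
        prec_e = self._gsum(self.M_subj, np.broadcast_to(w[:, d.chan_pos], st["eps"].shape))
        wsum = self._gsum(self.M_subj, st["eps"] * w[:, d.chan_pos])
        v = st["u"][:, : d.n_subj]
        tau2 = self._subject_tau2(st)
        prec = 1.0 / tau2 + prec_e
        mean = (-v / tau2 + wsum) / prec
        delta = mean + rng.standard_normal(v.shape) / np.sqrt(prec)
        st["u"][:, : d.n_subj] = v + delta
        ext = np.concatenate([delta, np.zeros((delta.shape[0], 1))], axis=1)
        st["eps"] = st["eps"] - ext[:, d.subj_idx]

    def _recenter_u_d(self, st, rng):
        d = self.data
        if self.stage != 2 or d.n_subj == 0 or self.fix_dig == 0.0:
            return
        n = self.n_dig_per_subj[None, :]
        if not (n > 0).any():
            return
        tau2_d = (
            st["tau2_d"][:, None]
            if self.fix_dig is None
            else float(self.fix_dig) ** 2
        )
        dbar = self._gsum(self.M_subj_dig, st["d"]) / np.maximum(n, 1.0)
        v = st["u"][:, : d.n_subj]
        tau2 = self._subject_tau2(st)
        prec = 1.0 / tau2 + n / tau2_d
        mean = (-v / tau2 + n * dbar / tau2_d) / prec
        delta = mean + rng.standard_normal(v.shape) / np.sqrt(prec)
        delta = np.where(n > 0, delta, 0.0)
        st["u"][:, : d.n_subj] = v + delta
        ext = np.concatenate([delta, np.zeros((delta.shape[0], 1))], axis=1)
        st["d"] = st["d"] - ext[:, self.dig_subj]

    def _recenter_theta_u(self, st, rng):
        d = self.data
        cs = self.case_subjects
        if self.stage != 2 or cs.size == 0:
            return
        ubar = st["u"][:, cs].mean(axis=1)
        sd = np.sqrt(st["tau2_case"] / cs.size)
        delta = ubar + sd * rng.standard_normal(ubar.shape)
        delta = self._vague_accept(st, rng, st["theta"], delta)
        st["theta"] = st["theta"] + delta
        st["u"][:, cs] -= delta[:, None]

    def step(self, st: dict, rng: np.random.Generator, adapt: bool) -> None:
        # mean structure first (exact Gibbs absorbs misfit), residuals after:
        # letting eps move before beta/gamma would dump any startup misfit
        # into the residuals and inflate the channel variances
        self._update_beta(st, rng)
        self._update_rc(st, rng, adapt)
        self._update_theta(st, rng)
        self._update_u(st, rng, adapt)
        self._update_d(st, rng, adapt)
        self._update_eps(st, rng, adapt)
        self._update_sig2(st, rng)
        self._update_variances(st, rng)
        self._recenter_beta_eps(st, rng)
        self._recenter_rc_eps(st, rng)
        self._recenter_rc_d(st, rng)
        self._recenter_d_eps(st, rng)
        self._recenter_run(st, rng, "eps")
        self._recenter_run(st, rng, "d")
        self._recenter_rc_u(st, rng)
        self._recenter_u_eps(st, rng)
        self._recenter_u_d(st, rng)
        self._recenter_theta_u(st, rng)

    def tracked(self, st: dict) -> dict[str, np.ndarray]:
        d = self.data
        out = {
            "gamma" if self.stage == 1 else "nu": st["rc"][:, : d.n_rc].copy(),
            "sigma2": st["sig2"].copy(),
            "tau2_digest": st["tau2_d"].copy(),
        }
        if self.stage == 2:
            out["theta"] = st["theta"].copy()
            out["u"] = st["u"][:, : d.n_subj].copy()
            out["tau2_case"] = st["tau2_case"].copy()
            out["tau2_ctrl"] = st["tau2_ctrl"].copy()
        return out


class BatchedPoissonGLMM(PoissonGLMM):
    """Fit many structurally identical proteins in one vectorized sampler.

    All proteins must share the same observation index structure (same
    spectra/peptide/digest/subject layout against the same design); only
    the counts differ.  Proteins are stacked along the chain axis, so a
    batch of P proteins with k chains each runs as one sampler with P*k
    chains — the update rules are exactly those of the per-protein model.
    Used by the replicated calibration studies, where regions are
    simulated with uniform protein sizes precisely to enable this.
    """

    def __init__(
        self,
        datas: list[ProteinData],
        *,
        stage: int,
        chains_per_protein: int,
        rc_prior_mean: np.ndarray | None = None,
        rc_prior_sd: np.ndarray | None = None,
        **kwargs,
    ):
        if not datas:
            raise ConfigError("empty protein batch")
        base = datas[0]
        for d in datas[1:]:
            same = (
                d.n_spectra == base.n_spectra
                and np.array_equal(d.spec_idx, base.spec_idx)
                and np.array_equal(d.rc_idx, base.rc_idx)
                and np.array_equal(d.dig_idx, base.dig_idx)
                and np.array_equal(d.subj_idx, base.subj_idx)
                and np.array_equal(d.case_cols, base.case_cols)
            )
            if not same:
                raise ConfigError(
                    f"protein {d.protein_id!r} does not share the batch structure"
                )
        super().__init__(
            base,
            stage=stage,
            rc_prior_mean=rc_prior_mean,
            rc_prior_sd=rc_prior_sd,
            **kwargs,
        )
        self.protein_ids = [d.protein_id for d in datas]
        self.datas = datas
        self.n_proteins = len(datas)
        self.chains_per_protein = int(chains_per_protein)
        k = self.chains_per_protein
        ys = np.stack([d.y for d in datas])  # (P, N)
        self.y_row = np.repeat(ys, k, axis=0)
        self.Y_spec_row = np.repeat(ys @ self.M_spec.T, k, axis=0)
        self.Y_rc_row = np.repeat(ys @ self.M_rc.T, k, axis=0)
        self.Y_dig_row = np.repeat(ys @ self.M_dig.T, k, axis=0)
        self.Y_subj_row = np.repeat(ys @ self.M_subj.T, k, axis=0)
        self.Y_case_arr = np.repeat(ys[:, base.case_cols].sum(axis=1), k)
        self.beta_init_row = np.repeat(
            np.log(np.maximum((ys @ self.M_spec.T) / 8.0, 0.5)), k, axis=0
        )

    @property
    def total_chains(self) -> int:
        return self.n_proteins * self.chains_per_protein

    def init_state(self, n_chains: int, rng) -> dict:
        if n_chains != self.total_chains:
            raise ConfigError(
                f"batched model needs n_chains == proteins x chains "
                f"({self.total_chains}), got {n_chains}"
            )
        return super().init_state(n_chains, rng)

    def slice_protein(self, arr: np.ndarray, i: int) -> np.ndarray:
        """Rows of a (total_chains, ...) draw array belonging to protein i."""
        k = self.chains_per_protein
        return arr[i * k : (i + 1) * k]
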