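"""Synthetic iTRAQ 8-plex spectrum-count generator with known truth.

Generates spectrum-level reporter-ion counts with exactly the statistical
structure the inference model assumes: for spectrum *s* (peptide *p* of
protein *i*, run *r*) and channel *c*,

    y[s, c] ~ Poisson( exp( beta_s + lambda[r, c] + theta_i * x_c
                            + u[subject(r, c)] + d[p, digest(r, c)]
                            + eps[s, c] ) )

where ``beta_s`` is a per-spectrum baseline (selection/ionisation/
fragmentation efficiency), ``lambda`` the per-(run, channel) loading bias
(the true normalization factor, 0 for the reference channel), ``theta_i``
the condition effect on natural-log scale (x=1 for case channels),
``u`` group-specific subject effects, ``d`` peptide-by-digest effects and
``eps`` per-channel log-normal over-dispersion.  Each plex carries two
reference-pool digests plus three case and three control samples, the
layout used when a pooled reference links plexes.

The generator returns a truth table so normalization recovery, parameter
recovery, interval coverage and FDR calibration are all testable offline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError
from .quantdata import CHANNELS, REFERENCE_CHANNEL, SpectrumTable, StudyDesign

#: Channels holding the two reference-pool digests in the synthetic layout.
#: The inference is channel-symmetric given the design table; the pools'
#: placement (one on the reference channel, one mid-mass) is a convention.
REFERENCE_POOL_CHANNELS = (113, 119)

_NONREF = [c for c in CHANNELS if c not in REFERENCE_POOL_CHANNELS]


def draw_from_spec(spec, rng: np.random.Generator, size=None):
    """Draw from a small distribution-spec dictionary.

    Supported kinds: ``fixed`` (value), ``uniform`` (low, high),
    ``normal`` (mean, sd), ``discrete_uniform`` (low, high inclusive).
    A bare number is shorthand for ``fixed``; a 2-tuple of ints for
    ``discrete_uniform``.
    """
    if isinstance(spec, (int, float)):
        return np.full(size, float(spec)) if size is not None else float(spec)
    if isinstance(spec, (tuple, list)):
        spec = {"kind": "discrete_uniform", "low": spec[0], "high": spec[1]}
    kind = spec["kind"]
    if kind == "fixed":
        v = spec["value"]
        return np.full(size, v) if size is not None else v
    if kind == "uniform":
        return rng.uniform(spec["low"], spec["high"], size=size)
    if kind == "normal":
        return rng.normal(spec["mean"], spec["sd"], size=size)
    if kind == "discrete_uniform":
        return rng.integers(spec["low"], spec["high"] + 1, size=size)
    raise ConfigError(f"unknown distribution kind {kind!r}")


@dataclass
class SimulationConfig:
    """Generative settings; the defaults are the package's study conditions.

    Sizes follow a desk-scale rendering of a three-plex region: 60
    proteins, 1-4 peptides each, 1-5 spectra per peptide per run.  Baseline
    counts centre near 150 ions (typical QqTOF reporter magnitudes), 20% of
    proteins are truly differential with |log fold change| = ln 1.5, cases
    are biologically more variable than controls, and per-(run, channel)
    loading biases are drawn with SD 0.2 on the log scale.
    """

    n_proteins: int = 60
    peptides_per_protein: object = (1, 4)
    spectra_per_peptide: object = (1, 5)
    baseline_log_mean: float = float(np.log(150.0))
    baseline_log_sd: float = 1.0
    n_plexes: int = 3
    fraction_differential: float = 0.2
    effect_size_log: object = field(
        default_factory=lambda: {"kind": "fixed", "value": float(np.log(1.5))}
    )
    subject_sd_case: float = 0.20
    subject_sd_control: float = 0.10
    digest_sd: float = 0.10
    channel_overdispersion_sd: Mapping[int, float] | float = 0.20
    loading_bias_log: Mapping[tuple[str, int], float] | None = None
    loading_bias_sd: float = 0.20
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.fraction_differential <= 1.0:
            raise ConfigError("fraction_differential must lie in [0, 1]")
        sds = [
            self.subject_sd_case,
            self.subject_sd_control,
            self.digest_sd,
            self.baseline_log_sd,
            self.loading_bias_sd,
        ]
        if isinstance(self.channel_overdispersion_sd, Mapping):
            sds += list(self.channel_overdispersion_sd.values())
        else:
            sds.append(float(self.channel_overdispersion_sd))
        if any(s < 0 for s in sds):
            raise ConfigError("standard deviations must be >= 0")
        if self.n_proteins < 1 or self.n_plexes < 1:
            raise ConfigError("n_proteins and n_plexes must be >= 1")
        if self.loading_bias_log is not None:
            for (run, c), v in self.loading_bias_log.items():
                if c == REFERENCE_CHANNEL and v != 0.0:
                    raise ConfigError("loading bias for channel 113 must be 0")

    def overdispersion_sd(self, channel: int) -> float:
        if isinstance(self.channel_overdispersion_sd, Mapping):
            return float(self.channel_overdispersion_sd[channel])
        return float(self.channel_overdispersion_sd)


@dataclass
class SimulationTruth:
    """Ground truth behind one simulated study."""

    true_effect_log: dict[str, float]
    differential_flags: set[str]
    sample_log_abundance: dict[str, dict[str, float]]  # protein -> sample -> log level
    loading_bias_log: dict[str, dict[str, float]]  # run -> str(channel) -> bias

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "true_effect_log": dict(sorted(self.true_effect_log.items())),
                    "differential_flags": sorted(self.differential_flags),
                    "sample_log_abundance": {
                        p: dict(sorted(v.items()))
                        for p, v in sorted(self.sample_log_abundance.items())
                    },
                    "loading_bias_log": {
                        r: dict(sorted(v.items()))
                        for r, v in sorted(self.loading_bias_log.items())
                    },
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            true_effect_log=d["true_effect_log"],
            differential_flags=set(d["differential_flags"]),
            sample_log_abundance=d["sample_log_abundance"],
            loading_bias_log=d["loading_bias_log"],
        )

    def bias(self, run: str, channel: int) -> float:
        return self.loading_bias_log[run][str(channel)]


def _make_design(config: SimulationConfig, rng: np.random.Generator) -> StudyDesign:
    rows = []
    for r in range(config.n_plexes):
        run = f"plex{r + 1}"
        # randomize case/control placement among non-pool channels per plex,
        # so channel label is not confounded with condition
        order = rng.permutation(len(_NONREF))
        case_channels = {_NONREF[i] for i in order[:3]}
        k_case = k_ctrl = 0
        for c in CHANNELS:
            sample = f"{run}.{c}"
            if c in REFERENCE_POOL_CHANNELS:
                tag = "a" if c == REFERENCE_POOL_CHANNELS[0] else "b"
                rows.append(
                    (run, c, sample, "pool", "reference", f"pool-{run}-{tag}")
                )
            elif c in case_channels:
                k_case += 1
                subject = f"case-{run}-{k_case}"
                rows.append((run, c, sample, subject, "case", f"dig-{subject}"))
            else:
                k_ctrl += 1
                subject = f"ctrl-{run}-{k_ctrl}"
                rows.append((run, c, sample, subject, "control", f"dig-{subject}"))
    frame = pd.DataFrame(
        rows, columns=["run", "channel", "sample", "subject", "group", "digest"]
    )
    return StudyDesign(frame)


def simulate_study(
    config: SimulationConfig,
) -> tuple[SpectrumTable, StudyDesign, SimulationTruth]:
    """Generate one synthetic region: spectrum table, design, and truth.

    Deterministic given the config (including its seed).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0x51AB]))
    design = _make_design(config, rng)
    runs = design.runs

    # true loading biases (per run x channel, reference channel pinned at 0)
    bias: dict[str, dict[str, float]] = {}
    for run in runs:
        bias[run] = {}
        for c in CHANNELS:
            if config.loading_bias_log is not None:
                v = float(config.loading_bias_log.get((run, c), 0.0))
            else:
                v = 0.0 if c == REFERENCE_CHANNEL else float(
                    rng.normal(0.0, config.loading_bias_sd)
                )
            bias[run][str(c)] = 0.0 if c == REFERENCE_CHANNEL else v

    proteins = [f"P{i + 1:04d}" for i in range(config.n_proteins)]
    n_diff = int(round(config.fraction_differential * config.n_proteins))
    diff_idx = rng.choice(config.n_proteins, size=n_diff, replace=False)
    flags = {proteins[i] for i in diff_idx}

    true_effect: dict[str, float] = {}
    for p in proteins:
        if p in flags:
            mag = float(draw_from_spec(config.effect_size_log, rng))
            true_effect[p] = mag * (1.0 if rng.random() < 0.5 else -1.0)
        else:
            true_effect[p] = 0.0

    samples = design.samples()
    sample_meta = {
        row["sample"]: row for _, row in samples.iterrows()
    }

    sd_over = np.array([config.overdispersion_sd(c) for c in CHANNELS])

    rows = []
    sample_abund: dict[str, dict[str, float]] = {}
    for p in proteins:
        theta = true_effect[p]
        # protein-specific biological deviations per subject
        subj_eff: dict[str, float] = {"pool": 0.0}
        for _, s in samples.iterrows():
            subj = s["subject"]
            if subj in subj_eff:
                continue
            sd = (
                config.subject_sd_case
                if s["group"] == "case"
                else config.subject_sd_control
            )
            subj_eff[subj] = float(rng.normal(0.0, sd))
        abund = {}
        for _, s in samples.iterrows():
            x = 1.0 if s["group"] == "case" else 0.0
            abund[s["sample"]] = theta * x + subj_eff[s["subject"]]
        sample_abund[p] = abund

        n_pep = int(draw_from_spec(config.peptides_per_protein, rng))
        for j in range(n_pep):
            pep = f"{p}_pep{j + 1}"
            # peptide-by-digest effects, one per digest in the design
            dig_eff = {
                dg: float(rng.normal(0.0, config.digest_sd))
                for dg in samples["digest"].unique()
            }
            for run in runs:
                n_spec = int(draw_from_spec(config.spectra_per_peptide, rng))
                run_samples = samples[samples["run"] == run]
                eta_sample = np.array(
                    [
                        bias[run][str(c)]
                        + abund[f"{run}.{c}"]
                        + dig_eff[sample_meta[f"{run}.{c}"]["digest"]]
                        for c in CHANNELS
                    ]
                )
                del run_samples
                for k in range(n_spec):
                    beta = rng.normal(config.baseline_log_mean, config.baseline_log_sd)
                    for _attempt in range(20):
                        eps = rng.normal(0.0, sd_over)
                        y = rng.poisson(np.exp(beta + eta_sample + eps))
                        if y.sum() > 0:
                            break
                    else:  # pathological low-count config: force one ion
                        y[0] = 1
                    rows.append((p, pep, run, f"{run}.{pep}.s{k + 1}", *y))

    frame = pd.DataFrame(
        rows,
        columns=["protein", "peptide", "run", "spectrum", *(f"ch{c}" for c in CHANNELS)],
    )
    table = SpectrumTable(frame)
    truth = SimulationTruth(
        true_effect_log=true_effect,
        differential_flags=flags,
        sample_log_abundance=sample_abund,
        loading_bias_log=bias,
    )
    return table, design, truth


def corrupt_spectra(
    table: SpectrumTable, fraction: float, magnitude_sd: float, seed: int
) -> SpectrumTable:
    """Perturb a random fraction of spectra with heavy log-normal noise.

    Emulates background contamination / misidentified spectra that the
    per-channel residual variance is meant to absorb.  Each selected
    spectrum's counts are multiplied channel-wise by exp(N(0, magnitude_sd));
    results are rounded back to integers.  The selection is exactly
    reproducible under the same seed.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ConfigError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0FF]))
    frame = table.frame.copy()
    n = len(frame)
    n_hit = int(round(fraction * n))
    if n_hit == 0 or magnitude_sd == 0.0:
        if n_hit > 0:  # draw anyway so selection is seed-stable across magnitudes
            rng.choice(n, size=n_hit, replace=False)
        return SpectrumTable(frame)
    hit = np.sort(rng.choice(n, size=n_hit, replace=False))
    cols = [f"ch{c}" for c in CHANNELS]
    counts = frame.loc[:, cols].to_numpy().astype(float)
    z = rng.normal(0.0, magnitude_sd, size=(n_hit, len(CHANNELS)))
    counts[hit] = np.rint(counts[hit] * np.exp(z))
    # keep every spectrum observable: a spectrum zeroed out entirely keeps one ion
    dead = counts.sum(axis=1) == 0
    counts[dead, 0] = 1
    frame[cols] = counts.astype(np.int64)
    return SpectrumTable(frame)
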