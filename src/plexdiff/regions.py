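"""Cross-region summarization of differential calls.

Each region is analysed in isolation upstream; this module only combines
the per-region call sets: proportions of quantified proteins changing,
overlap partitions (which subset of regions each change appears in,
restricted to proteins quantified everywhere), selection of proteins
changed in at least k regions, and assembly of the normalized and scaled
protein-by-sample matrix handed to ordination (the ordination itself is
out of scope here).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .errors import ConfigError
from .stage1 import NormalizationFactors


@dataclass
class RegionCallSet:
    """One region's quantified universe and significant calls."""

    region: str
    quantified: set[str]
    significant: set[str]
    directions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.significant <= self.quantified:
            raise ConfigError(
                f"region {self.region!r}: significant set not within quantified set"
            )


def _check_regions(call_sets: list[RegionCallSet]) -> None:
    labels = [cs.region for cs in call_sets]
    if len(set(labels)) != len(labels):
        raise ConfigError("duplicate region labels")


def summarize_regions(call_sets: list[RegionCallSet]) -> dict:
    """Per-region counts/proportions plus cross-region quantification depth.

    Returns a dict with ``per_region`` rows (region, n_quantified,
    n_significant, proportion) and ``quantified_in_exactly_k`` /
    ``quantified_in_at_least_k`` counts for k = 1..n_regions.
    """
    if not call_sets:
        raise ConfigError("need at least one region")
    _check_regions(call_sets)
    per_region = [
        {
            "region": cs.region,
            "n_quantified": len(cs.quantified),
            "n_significant": len(cs.significant),
            "proportion": (len(cs.significant) / len(cs.quantified))
            if cs.quantified
            else 0.0,
        }
        for cs in call_sets
    ]
    all_proteins = set().union(*(cs.quantified for cs in call_sets))
    depth = {
        p: sum(p in cs.quantified for cs in call_sets) for p in all_proteins
    }
    n = len(call_sets)
    exactly = {k: sum(1 for v in depth.values() if v == k) for k in range(1, n + 1)}
    at_least = {k: sum(1 for v in depth.values() if v >= k) for k in range(1, n + 1)}
    return {
        "per_region": per_region,
        "quantified_in_exactly_k": exactly,
        "quantified_in_at_least_k": at_least,
    }


@dataclass
class OverlapPartition:
    """Counts of proteins significant in exactly each non-empty region subset."""

    regions: list[str]
    counts: dict[frozenset, int]
    restricted_to_universal: bool

    def count(self, *regions: str) -> int:
        return self.counts.get(frozenset(regions), 0)

    def exclusive(self, region: str) -> int:
        return self.count(region)

    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region_subset": "+".join(sorted(k)), "count": v}
            for k, v in sorted(self.counts.items(), key=lambda kv: sorted(kv[0]))
            if v > 0
        ]
        return pd.DataFrame(rows, columns=["region_subset", "count"])


def overlap_partition(
    call_sets: list[RegionCallSet], *, restrict_to_universal: bool = True
) -> OverlapPartition:
    """Membership-pattern counts over significant proteins.

    By default only proteins quantified in *all* regions enter, matching
    the convention for overlap diagrams; ``restrict_to_universal=False``
    counts every protein significant somewhere.
    """
    if len(call_sets) < 2:
        raise ConfigError("need at least two regions for an overlap partition")
    _check_regions(call_sets)
    universe = set.intersection(*(cs.quantified for cs in call_sets))
    counts: dict[frozenset, int] = {}
    candidates = set().union(*(cs.significant for cs in call_sets))
    if restrict_to_universal:
        candidates &= universe
    for p in candidates:
        pattern = frozenset(cs.region for cs in call_sets if p in cs.significant)
        if pattern:
            counts[pattern] = counts.get(pattern, 0) + 1
    return OverlapPartition(
        regions=[cs.region for cs in call_sets],
        counts=counts,
        restricted_to_universal=restrict_to_universal,
    )


def count_regions_changed(
    call_sets: list[RegionCallSet], k: int
) -> set[str]:
    """Proteins significant in at least k regions (and quantified in >= k)."""
    n = len(call_sets)
    if not 1 <= k <= n:
        raise ConfigError(f"k must lie in 1..{n}")
    _check_regions(call_sets)
    out = set()
    for p in set().union(*(cs.significant for cs in call_sets)):
        n_sig = sum(p in cs.significant for cs in call_sets)
        n_quant = sum(p in cs.quantified for cs in call_sets)
        if n_sig >= k and n_quant >= k:
            out.add(p)
    return out


def prepare_pca_matrix(
    sample_quant: pd.DataFrame,
    norm: NormalizationFactors,
    *,
    min_sd: float = 1e-12,
) -> pd.DataFrame:
    """Samples-by-proteins matrix for ordination.

    ``sample_quant`` holds one row per (protein, sample) with columns
    protein, sample, run, channel, mean, sd (posterior summaries of the
    latent sample-level log ratios).  Each value has its sample's
    normalization factor subtracted, is centred across samples within the
    protein, and divided by the protein's mean posterior SD.  Proteins
    missing any run covered by the table are excluded, as are proteins
    with a degenerate (zero) mean posterior SD.
    """
    required = {"protein", "sample", "run", "channel", "mean", "sd"}
    if not required <= set(sample_quant.columns):
        raise ConfigError(f"sample_quant needs columns {sorted(required)}")
    all_runs = set(sample_quant["run"].unique())
    all_samples = sorted(sample_quant["sample"].unique())
    cols = {}
    for protein, sub in sample_quant.groupby("protein"):
        if set(sub["run"].unique()) != all_runs or len(sub) < len(all_samples):
            continue  # protein not measured across all plexes
        sub = sub.set_index("sample").loc[all_samples]
        factors = np.array(
            [norm.mean_sd(r, c)[0] for r, c in zip(sub["run"], sub["channel"])]
        )
        v = sub["mean"].to_numpy() - factors
        scale = float(sub["sd"].mean())
        if scale <= min_sd:
            continue
        cols[protein] = (v - v.mean()) / scale
    return pd.DataFrame(cols, index=pd.Index(all_samples, name="sample"))
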