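"""Cross-region summaries, overlap partitions and the ordination matrix."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plexdiff import (
    ConfigError,
    NormalizationFactors,
    RegionCallSet,
    count_regions_changed,
    overlap_partition,
    prepare_pca_matrix,
    summarize_regions,
)

REGIONS6 = ["HP", "ENT", "CG", "MCx", "SCx", "CB"]


def _brute_force_patterns(call_sets, restrict=True):
    """Literal enumeration over all 2^n - 1 membership patterns."""
    labels = [cs.region for cs in call_sets]
    universe = set.intersection(*(cs.quantified for cs in call_sets))
    pool = set().union(*(cs.significant for cs in call_sets))
    if restrict:
        pool &= universe
    counts = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            pattern = frozenset(combo)
            n = sum(
                1
                for p in pool
                if frozenset(
                    cs.region for cs in call_sets if p in cs.significant
                )
                == pattern
            )
            if n:
                counts[pattern] = n
    return counts


class TestSummarizeRegions:
    def test_single_region_proportion(self):
        cs = RegionCallSet("HP", set(map(str, range(10))), {"0", "1", "2"})
        out = summarize_regions([cs])
        assert out["per_region"][0]["proportion"] == pytest.approx(0.3)

    def test_cross_region_depth_counts(self):
        sets = [
            RegionCallSet("R1", {"A", "B"}, set()),
            RegionCallSet("R2", {"B", "C"}, set()),
            RegionCallSet("R3", {"B"}, set()),
        ]
        out = summarize_regions(sets)
        assert out["quantified_in_at_least_k"][3] == 1  # only B everywhere
        assert out["quantified_in_at_least_k"][2] == 1  # still only B
        assert out["quantified_in_exactly_k"][1] == 2  # A and C once each
        assert out["quantified_in_at_least_k"][1] == 3

    def test_empty_significant_sets_zero_proportions(self):
        sets = [RegionCallSet(r, {"A", "B"}, set()) for r in REGIONS6]
        out = summarize_regions(sets)
        assert all(row["proportion"] == 0.0 for row in out["per_region"])

    def test_duplicate_labels_rejected(self):
        sets = [RegionCallSet("R", {"A"}, set()), RegionCallSet("R", {"A"}, set())]
        with pytest.raises(ConfigError):
            summarize_regions(sets)


class TestOverlapPartition:
    def test_identical_sets_fill_only_full_cell(self):
        sets = [RegionCallSet(r, {"A", "B", "C"}, {"A", "B"}) for r in REGIONS6]
        part = overlap_partition(sets)
        assert part.counts == {frozenset(REGIONS6): 2}

    def test_region_exclusive_change(self):
        sets = [
            RegionCallSet(r, {"X", "Y"}, {"X"} if r == "CB" else set())
            for r in REGIONS6
        ]
        part = overlap_partition(sets)
        assert part.exclusive("CB") == 1
        assert part.total() == 1

    def test_restriction_to_universally_quantified(self):
        sets = [
            RegionCallSet("R1", {"A", "B"}, {"A", "B"}),
            RegionCallSet("R2", {"B"}, {"B"}),
        ]
        restricted = overlap_partition(sets)
        assert restricted.total() == 1  # only B is quantified everywhere
        free = overlap_partition(sets, restrict_to_universal=False)
        assert free.total() == 2

    @given(data=st.data())
    @settings(max_examples=40, deadline=None)
    def test_matches_brute_force_enumeration(self, data):
        proteins = [f"p{i}" for i in range(20)]
        sets = []
        for r in REGIONS6:
            quant = set(
                data.draw(
                    st.lists(st.sampled_from(proteins), unique=True, max_size=20),
                    label=f"quant-{r}",
                )
            )
            sig = set(
                data.draw(
                    st.lists(st.sampled_from(sorted(quant) or proteins[:1]),
                             unique=True, max_size=len(quant)),
                    label=f"sig-{r}",
                )
            ) & quant
            sets.append(RegionCallSet(r, quant, sig))
        part = overlap_partition(sets)
        assert part.counts == _brute_force_patterns(sets)
        # cell sums reconcile with the union of significant proteins
        universe = set.intersection(*(s.quantified for s in sets))
        expected_total = len(
            set().union(*(s.significant for s in sets)) & universe
        )
        assert part.total() == expected_total


class TestCountRegionsChanged:
    def _sets(self):
        return [
            RegionCallSet("R1", {"A", "B", "C"}, {"A", "B"}),
            RegionCallSet("R2", {"A", "B"}, {"A"}),
            RegionCallSet("R3", {"A", "C"}, {"A", "C"}),
        ]

    def test_k_one_is_union(self):
        assert count_regions_changed(self._sets(), 1) == {"A", "B", "C"}

    def test_k_n_is_intersection_of_significance(self):
        assert count_regions_changed(self._sets(), 3) == {"A"}

    def test_intermediate_k(self):
        assert count_regions_changed(self._sets(), 2) == {"A"}

    def test_non_increasing_in_k(self):
        sets = self._sets()
        prev = count_regions_changed(sets, 1)
        for k in (2, 3):
            cur = count_regions_changed(sets, k)
            assert cur <= prev
            prev = cur

    def test_k_out_of_range(self):
        with pytest.raises(ConfigError):
            count_regions_changed(self._sets(), 0)
        with pytest.raises(ConfigError):
            count_regions_changed(self._sets(), 4)


def _norm(factors, runs=("plex1", "plex2")):
    rows = []
    from plexdiff.quantdata import CHANNELS

    for run in runs:
        for c in CHANNELS:
            rows.append((run, c, factors.get((run, c), 0.0), 0.0, 3))
    return NormalizationFactors(
        pd.DataFrame(rows, columns=["run", "channel", "mean", "sd", "n_proteins_used"])
    )


def _quant_frame(proteins, samples, means, sds=1.0):
    rows = []
    for p in proteins:
        for (s, run, chan) in samples:
            rows.append(
                {
                    "protein": p,
                    "sample": s,
                    "run": run,
                    "channel": chan,
                    "mean": means[(p, s)],
                    "sd": sds,
                }
            )
    return pd.DataFrame(rows)


class TestPreparePcaMatrix:
    SAMPLES = [("s1", "plex1", 113), ("s2", "plex1", 114), ("s3", "plex1", 115)]

    def test_zero_factors_unit_sds_row_centred_means(self):
        means = {("P1", "s1"): 1.0, ("P1", "s2"): 2.0, ("P1", "s3"): 3.0}
        mat = prepare_pca_matrix(_quant_frame(["P1"], self.SAMPLES, means), _norm({}))
        np.testing.assert_allclose(mat["P1"].to_numpy(), [-1.0, 0.0, 1.0])
        assert mat["P1"].mean() == pytest.approx(0.0)

    def test_injected_factor_shifts_column_before_centring(self):
        means = {("P1", "s1"): 1.0, ("P1", "s2"): 2.0, ("P1", "s3"): 3.0}
        plain = prepare_pca_matrix(
            _quant_frame(["P1"], self.SAMPLES, means), _norm({})
        )
        shifted = prepare_pca_matrix(
            _quant_frame(["P1"], self.SAMPLES, means),
            _norm({("plex1", 114): 0.3}),
        )
        delta = shifted["P1"] - plain["P1"]
        # sample s2 moves down by 0.3 minus the new centring constant
        assert (delta["s2"] - delta["s1"]) == pytest.approx(-0.3)

    def test_protein_missing_a_run_is_excluded(self):
        samples = self.SAMPLES + [("s4", "plex2", 113)]
        means = {("P1", s): 1.0 for s, _, _ in samples}
        means.update({("P2", s): 1.0 for s, _, _ in self.SAMPLES})
        frame = pd.concat(
            [
                _quant_frame(["P1"], samples, means),
                _quant_frame(["P2"], self.SAMPLES, means),
            ]
        )
        mat = prepare_pca_matrix(frame, _norm({}))
        assert list(mat.columns) == ["P1"]

    def test_zero_posterior_sd_protein_excluded(self):
        means = {("P1", "s1"): 1.0, ("P1", "s2"): 2.0, ("P1", "s3"): 3.0}
        mat = prepare_pca_matrix(
            _quant_frame(["P1"], self.SAMPLES, means, sds=0.0), _norm({})
        )
        assert mat.empty

    def test_scaling_by_mean_posterior_sd(self):
        means = {("P1", "s1"): 0.0, ("P1", "s2"): 4.0, ("P1", "s3"): 2.0}
        mat = prepare_pca_matrix(
            _quant_frame(["P1"], self.SAMPLES, means, sds=2.0), _norm({})
        )
        np.testing.assert_allclose(mat["P1"].to_numpy(), [-1.0, 1.0, 0.0])
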