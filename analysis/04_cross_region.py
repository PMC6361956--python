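#!/usr/bin/env python
"""Cross-region summarization of the three synthetic regions.

Reports per-region change proportions, the overlap partition of changes
among proteins quantified in all regions, proteins changed in at least
two regions, and the normalized, centred and SD-scaled protein-by-sample
matrix that would feed ordination.
"""

import json
from pathlib import Path

import pandas as pd

from plexdiff import (
    NormalizationFactors,
    RegionCallSet,
    count_regions_changed,
    overlap_partition,
    prepare_pca_matrix,
    summarize_regions,
)

ROOT = Path(__file__).resolve().parents[1]
STAGE2 = ROOT / "results" / "stage2"
STAGE1 = ROOT / "results" / "stage1"
OUT = ROOT / "results" / "summary"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    call_sets = []
    for path in sorted(STAGE2.glob("*.results.tsv")):
        region = path.name.split(".")[0]
        df = pd.read_csv(path, sep="\t")
        sig = df[df["significant"]]
        call_sets.append(
            RegionCallSet(
                region=region,
                quantified=set(df["protein"]),
                significant=set(sig["protein"]),
                directions=dict(zip(sig["protein"], sig["direction"])),
            )
        )
    summary = summarize_regions(call_sets)
    with open(OUT / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    for row in summary["per_region"]:
        print(
            f"{row['region']}: {row['n_significant']}/{row['n_quantified']} "
            f"changed ({100 * row['proportion']:.0f}%)"
        )

    part = overlap_partition(call_sets)
    part.to_frame().to_csv(OUT / "overlap.tsv", sep="\t", index=False)
    for region in [cs.region for cs in call_sets]:
        print(f"changes exclusive to {region}: {part.exclusive(region)}")
    shared = count_regions_changed(call_sets, 2)
    print(f"proteins changed in >= 2 regions: {len(shared)}")
    with open(OUT / "changed_in_2plus.json", "w") as fh:
        json.dump(sorted(shared), fh, indent=1)

    # ordination input from one region's per-sample posteriors
    region = call_sets[0].region
    quant = pd.read_csv(STAGE2 / f"{region}.sample_quant.tsv", sep="\t")
    norm = NormalizationFactors.from_json(STAGE1 / f"{region}.normalization.json")
    matrix = prepare_pca_matrix(quant, norm)
    matrix.to_csv(OUT / f"{region}.pca_matrix.tsv", sep="\t")
    print(
        f"ordination matrix for {region}: {matrix.shape[0]} samples x "
        f"{matrix.shape[1]} proteins -> {region}.pca_matrix.tsv"
    )


if __name__ == "__main__":
    main()
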