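#!/usr/bin/env python
"""Gene-family enrichment and two-SD expansion flags on simulated families.

Builds a small panel of simulated genome family-count profiles with one
focal genome carrying deliberately expanded families, then applies the
Fisher + Benjamini-Hochberg test and the mean +- 2 SD outlier rule.
Writes results/family_enrichment.tsv and results/family_sd_flags.tsv.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ploidyscope.enrichment import (
    enrichment_frame,
    fisher_family_test,
    flags_frame,
    sd_outlier_flags,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rng = np.random.default_rng(SEED)
    families = [f"FAM{i:03d}" for i in range(40)]
    genomes = ["focal"] + [f"relative_{i}" for i in range(1, 8)]
    counts = pd.DataFrame(rng.poisson(12, (len(genomes), len(families))),
                          index=genomes, columns=families)
    # plant three expanded families in the focal genome
    for fam in ("FAM000", "FAM001", "FAM002"):
        counts.loc["focal", fam] = int(counts[fam].mean() + 6 * counts[fam].std() + 5)

    labels = {g: ("focal" if g == "focal" else "relatives") for g in genomes}
    results = fisher_family_test(counts, labels, "focal", "relatives")
    enrichment = enrichment_frame(results).sort_values("q_value")
    enrichment.to_csv(RESULTS / "family_enrichment.tsv", sep="\t", index=False)

    flags = flags_frame(sd_outlier_flags(counts, "focal",
                                         [g for g in genomes if g != "focal"]))
    flags.to_csv(RESULTS / "family_sd_flags.tsv", sep="\t", index=False)

    print(enrichment.head(6))
    print(flags[flags.flag != "none"])


if __name__ == "__main__":
    main()
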