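#!/usr/bin/env python
"""Classify the protein-level outcome of splicing each called exitron.

Writes results/consequences.tsv and prints the category partition: internal
deletions (EIx3), altered C-termini, and NMD candidates under the 50-nt
rule.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, load_study

from exitron_scan import consequence, discovery


def main():
    genome, models, junctions, coverage, _ = load_study()
    exitrons, _ = discovery.discover(genome, models, junctions, coverage)
    records = consequence.classify_all(exitrons, models, genome)
    df = pd.DataFrame([r.as_dict() for r in records])
    df.to_csv(RESULTS / "consequences.tsv", sep="\t", index=False)

    counts = df["category"].value_counts()
    print(f"classified {len(df)} exitrons -> {RESULTS / 'consequences.tsv'}")
    for cat, n in counts.items():
        print(f"  {cat}: {n}")
    il = [r for x, r in zip(exitrons, records)
          if x.intronless_host and x.frame_class == "frameshift"]
    print(f"frameshift exitrons in intronless genes: {len(il)}; "
          f"NMD candidates among them: "
          f"{sum(r.category == 'ptc_nmd_candidate' for r in il)} "
          "(no downstream junction, so always 0)")


if __name__ == "__main__":
    main()
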