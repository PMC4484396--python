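#!/usr/bin/env python
"""Call exitrons from the simulated junction/coverage evidence.

Reads the study back through the standard file formats, runs discovery, and
writes the catalog (results/catalog.tsv + .gff3) and the per-junction
exclusion reasons.  Prints recovery against the generator truth.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, load_study

from exitron_scan import discovery, gio


def main():
    genome, models, junctions, coverage, paths = load_study()
    exitrons, excluded = discovery.discover(genome, models, junctions,
                                            coverage)
    out = gio.write_catalog(exitrons, RESULTS / "catalog")
    excluded.to_csv(RESULTS / "excluded_junctions.tsv", sep="\t", index=False)

    truth = pd.read_csv(paths["truth"], sep="\t")
    planted = {(r.contig, r.start, r.end) for r in truth.itertuples()}
    called = {x.interval for x in exitrons}
    tp = len(called & planted)
    print(f"called {len(exitrons)} exitrons -> {out['tsv']}")
    print(f"recall {tp / len(planted):.3f}, precision {tp / len(called):.3f} "
          f"vs {len(planted)} planted events")
    print("exclusion reasons:")
    for reason, n in excluded["reason"].value_counts().items():
        print(f"  {reason}: {n}")
    n3 = sum(x.frame_class == "EIx3" for x in exitrons)
    print(f"EIx3: {n3}/{len(exitrons)} ({100 * n3 / len(exitrons):.1f}%), "
          f"intronless hosts: "
          f"{sum(x.intronless_host for x in exitrons)}")


if __name__ == "__main__":
    main()
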