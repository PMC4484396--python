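#!/usr/bin/env python
"""Quantify exitron inclusion (PSI) per sample and call differential events.

Writes the long-format PSI table and the cross-sample differential calls
(delta PSI >= 15; detection = PSI <= 90 in a sample) and prints recovery of
the true PSI values.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, load_study

from exitron_scan import discovery, quant


def main():
    genome, models, junctions, coverage, paths = load_study()
    exitrons, _ = discovery.discover(genome, models, junctions, coverage)
    long = quant.psi_matrix(exitrons, junctions, coverage)
    long.to_csv(RESULTS / "psi_long.tsv", sep="\t", index=False)
    diff = quant.differential_table(long, threshold=15.0, detect_max=90.0)
    diff.to_csv(RESULTS / "differential.tsv", sep="\t", index=False)

    truth = pd.read_csv(paths["truth"], sep="\t")
    tmap = {(r.contig, r.start, r.end): r for r in truth.itertuples()}
    by_id = {x.id: tmap[x.interval] for x in exitrons
             if x.interval in tmap}
    errors = [abs(r.psi - getattr(by_id[r.exitron_id], f"psi_{r.sample}"))
              for r in long.itertuples()
              if r.exitron_id in by_id and pd.notna(r.psi)]
    print(f"PSI table: {len(long)} records -> {RESULTS / 'psi_long.tsv'}")
    print(f"mean |PSI_hat - PSI_true| = {np.mean(errors):.2f} pp "
          f"over {len(errors)} measurements at depth 150")
    n_diff = int(diff['differential'].sum())
    print(f"differential events (delta PSI >= 15): {n_diff}/{len(diff)}")
    det = long[long['psi'] <= 90].groupby('sample')['exitron_id'].nunique()
    print("events detected (PSI <= 90) per sample:")
    for s, n in det.items():
        print(f"  {s}: {n}")


if __name__ == "__main__":
    main()
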