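#!/usr/bin/env python
"""Compare sequence features of exitrons, introns and exons.

GC content, lengths, 3n fractions, and splice-site PWM strength, with
Mann-Whitney-Wilcoxon tests per comparison.  Writes a tidy statistics table
to results/sequence_features.tsv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, load_study

from exitron_scan import discovery, seqstats


def main():
    genome, models, junctions, coverage, _ = load_study()
    exitrons, _ = discovery.discover(genome, models, junctions, coverage)
    intron_coords = [(m.contig, s, e, m.strand) for m in models
                     for s, e in m.introns]

    x_seqs = [genome.fetch(x.contig, x.start, x.end, x.strand)
              for x in exitrons]
    i_seqs = [genome.fetch(c, s, e, st) for c, s, e, st in intron_coords]
    x_set = {x.interval for x in exitrons}
    e_seqs = [genome.fetch(m.contig, s, e, m.strand)
              for m in models for s, e in m.exons_genomic
              if not any(s <= xs and xe <= e for c, xs, xe in x_set
                         if c == m.contig)]

    rows = []
    for name, seqs in (("exitron", x_seqs), ("intron", i_seqs),
                       ("exon", e_seqs)):
        gc = [seqstats.gc_content(s) for s in seqs]
        frac3, n3, n = seqstats.fraction_3n([len(s) for s in seqs])
        rows.append(dict(group=name, n=n, median_len=np.median([len(s) for s in seqs]),
                         mean_gc=np.mean(gc), fraction_3n=frac3))
    summary = pd.DataFrame(rows)

    tests = []
    gc_x = [seqstats.gc_content(s) for s in x_seqs]
    for other, seqs in (("intron", i_seqs), ("exon", e_seqs)):
        gc_o = [seqstats.gc_content(s) for s in seqs]
        r = seqstats.mww_test(gc_x, gc_o)
        tests.append(("gc_exitron_vs_" + other, r.statistic, r.p_value,
                      r.n_a, r.n_b))
        r = seqstats.mww_test([len(s) for s in x_seqs],
                              [len(s) for s in seqs])
        tests.append(("len_exitron_vs_" + other, r.statistic, r.p_value,
                      r.n_a, r.n_b))
    tests_df = pd.DataFrame(tests, columns=["comparison", "U", "p",
                                            "n_exitron", "n_other"])
    tests_df["q"] = seqstats.bh_adjust(tests_df["p"])

    # splice-site strength: exitrons vs constitutive introns
    strength = []
    for kind in ("donor", "acceptor"):
        pwm = seqstats.build_pwm(intron_coords, genome, kind)
        x_scores = [seqstats.score_site(pwm, genome, x.contig, x.start,
                                        x.end, x.strand) for x in exitrons]
        i_scores = [seqstats.score_site(pwm, genome, c, s, e, st)
                    for c, s, e, st in intron_coords]
        r = seqstats.mww_test(x_scores, i_scores, alternative="less")
        strength.append((kind, np.mean(x_scores), np.mean(i_scores),
                         r.p_value))

    out = RESULTS / "sequence_features.tsv"
    pd.concat([summary.assign(table="groups"),
               tests_df.assign(table="mww")], axis=0).to_csv(
        out, sep="\t", index=False)
    print(f"summary -> {out}")
    print(summary.to_string(index=False,
                            float_format=lambda v: f"{v:.3f}"))
    print("\nMann-Whitney tests:")
    print(tests_df.to_string(index=False,
                             float_format=lambda v: f"{v:.3g}"))
    print("\nsplice-site strength (mean bits, exitron vs intron, one-sided p):")
    for kind, mx, mi, p in strength:
        print(f"  {kind}: {mx:.2f} vs {mi:.2f} bits, p = {p:.3g}")


if __name__ == "__main__":
    main()
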