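"""Shared study definition for the numbered analysis scripts.

One synthetic study underlies the whole analysis: 200 protein-coding genes,
half carrying a planted exitron, three samples (two tissues at high
inclusion plus a stress condition with a broader PSI range), evidence depth
150.  Scripts regenerate it on demand — the generator is fully seeded, so
every run sees byte-identical inputs.
"""

from pathlib import Path

from exitron_scan import gio, synthio

ROOT = Path(__file__).resolve().parent.parent
STUDY_DIR = ROOT / "results" / "synth_study"
RESULTS = ROOT / "results"

STUDY_CONFIG = synthio.SynthConfig(
    n_genes=200,
    exitron_fraction=0.5,
    depth=150,
    psi_map={"flowers": (60.0, 95.0), "seedlings": (60.0, 95.0),
             "stress": (30.0, 90.0)},
    seed=17,
)


def ensure_study() -> dict:
    """Write the study to disk if absent; return the artefact paths."""
    if not (STUDY_DIR / "config.json").exists():
        return synthio.write_study(STUDY_CONFIG, STUDY_DIR)
    paths = {
        "genome": STUDY_DIR / "genome.fa",
        "annotation": STUDY_DIR / "annotation.gff3",
        "variants": STUDY_DIR / "variants.vcf",
        "truth": STUDY_DIR / "truth.tsv",
        "config": STUDY_DIR / "config.json",
    }
    for s in sorted(STUDY_CONFIG.psi_map):
        paths[f"junctions.{s}"] = STUDY_DIR / f"junctions.{s}.bed"
        paths[f"coverage.{s}"] = STUDY_DIR / f"coverage.{s}.bedgraph"
    return paths


def load_study():
    """Read the study back through the file-format layer (round trip)."""
    paths = ensure_study()
    genome = gio.read_genome(paths["genome"])
    models = gio.select_transcripts(gio.read_annotation(paths["annotation"]))
    junctions, coverage = {}, {}
    for s in sorted(STUDY_CONFIG.psi_map):
        junctions[s] = gio.read_junctions(paths[f"junctions.{s}"], s)
        coverage[s] = gio.read_coverage(paths[f"coverage.{s}"], s,
                                        genome.lengths)
    return genome, models, junctions, coverage, paths
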