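"""Synthetic genomes with planted exitrons and per-sample evidence.

The generator emulates the statistical structure the downstream analysis
assumes: multi-exon and intronless protein-coding genes with valid ORFs,
exitrons planted strictly inside CDS exons with canonical GT..AG boundaries,
no in-frame stop codons and a controlled EIx3 (length multiple of 3)
fraction, junction/coverage evidence drawn binomially at a specified true
PSI per sample, and SNPs with controlled codon-position distribution and
splice-signal overlap.  Every draw flows from ``SynthConfig.seed``, and
re-running with the same seed yields byte-identical output files.

Defaults mirror the study conditions reported for the Arabidopsis exitron
catalog: 45.8% of exitrons with length a multiple of 3, 18.9% of exitrons
hosted in annotated intronless genes, exitron GC below exon GC but above
intron GC, and high inclusion (the exitron-containing isoform is the major
transcript).
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gio import (
    CoverageTrack,
    GenomeSequence,
    TranscriptModel,
    Variant,
    JUNCTION_COLUMNS,
    reverse_complement,
    write_annotation,
    write_coverage,
    write_genome,
    write_junctions,
    write_variants,
)

STOP_CODONS = ("TAA", "TAG", "TGA")
_BASES = np.array(list("ACGT"))

# margin (nt) between a planted exitron and its host CDS-exon boundaries;
# keeps planted events strictly internal with room for the inclusion window
PLANT_MARGIN = 12


@dataclass
class SynthConfig:
    """Parameters of one synthetic study.

    ``psi_map`` maps sample name to either a fixed true PSI in [0, 100] or a
    ``(lo, hi)`` range from which each event's PSI is drawn uniformly.
    ``depth`` is the expected read evidence per event; ``snp_rate`` is
    variants per kb of exitron sequence.
    """

    n_genes: int = 200
    intronless_fraction: float = 0.189
    exitron_fraction: float = 0.5
    eix3_fraction: float = 0.458
    exitron_length_range: tuple[int, int] = (24, 150)
    exon_length_range: tuple[int, int] = (120, 300)
    intron_length_range: tuple[int, int] = (80, 200)
    exons_per_gene_range: tuple[int, int] = (2, 6)
    gc_exitron: float = 0.38
    gc_exon: float = 0.44
    gc_intron: float = 0.32
    psi_map: dict = field(default_factory=lambda: {"flowers": (60.0, 95.0),
                                                   "seedlings": (60.0, 95.0)})
    depth: int = 100
    snp_rate: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("intronless_fraction", "exitron_fraction", "eix3_fraction",
                     "gc_exitron", "gc_exon", "gc_intron"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("exitron_length_range", "exon_length_range",
                     "intron_length_range", "exons_per_gene_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name}=({lo}, {hi}) invalid")
        if self.exitron_length_range[0] < 9:
            raise ValueError("exitrons shorter than 9 nt are not supported")
        if self.exitron_length_range[1] + 2 * PLANT_MARGIN > self.exon_length_range[1]:
            raise ValueError(
                "max exitron length does not fit inside max exon length "
                f"with {PLANT_MARGIN} nt margins"
            )
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")


@dataclass(frozen=True)
class PlantedExitron:
    exitron_id: str
    gene_id: str
    contig: str
    start: int          # genomic, 0-based half-open
    end: int
    strand: str
    cds_offset: int     # 5' offset in the spliced CDS (codon-aligned)
    frame_class: str    # "EIx3" | "frameshift"
    intronless_host: bool
    psi: dict           # sample -> true PSI in [0, 100]

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.contig, self.start, self.end)


@dataclass(frozen=True)
class PlantedSnp:
    contig: str
    pos: int            # genomic, 0-based
    ref: str
    alt: str
    exitron_id: str
    codon_position: int  # 1 | 2 | 3 in the host reading frame
    in_splice_signal: bool


@dataclass
class TruthSet:
    planted_exitrons: list[PlantedExitron] = field(default_factory=list)
    planted_snps: list[PlantedSnp] = field(default_factory=list)

    def exitron_intervals(self) -> set[tuple[str, int, int]]:
        return {x.interval for x in self.planted_exitrons}

    def by_id(self) -> dict[str, PlantedExitron]:
        return {x.exitron_id: x for x in self.planted_exitrons}


# ---------------------------------------------------------------------------
# sequence construction helpers
# ---------------------------------------------------------------------------

def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def _random_coding(rng: np.random.Generator, n_nt: int, gc: float) -> np.ndarray:
    """Random stop-free coding bases (length multiple of 3, no ATG/stop ends)."""
    assert n_nt % 3 == 0
    out = _random_bases(rng, n_nt, gc)
    for i in range(0, n_nt, 3):
        while "".join(out[i:i + 3]) in STOP_CODONS:
            out[i:i + 3] = _random_bases(rng, 3, gc)
    return out


def _patch_stops(cds: np.ndarray, fixed: set[int]) -> None:
    """Remove in-frame stop codons by setting one free base per codon to C.

    No stop codon contains C, and edits stay within the codon, so a single
    pass terminates.  ``fixed`` marks positions that must not change (ATG,
    terminal stop, planted GT/AG dinucleotides).
    """
    for i in range(3, len(cds) - 3, 3):
        if "".join(cds[i:i + 3]) in STOP_CODONS:
            free = [j for j in range(i, i + 3) if j not in fixed]
            if not free:
                raise RuntimeError("stop codon with no patchable base")
            cds[free[0]] = "C"


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def _exitron_lengths(rng, n_exitrons: int, eix3_fraction: float,
                     lo: int, hi: int) -> list[int]:
    """Exitron lengths hitting the EIx3 fraction exactly (after rounding)."""
    n_3n = int(round(n_exitrons * eix3_fraction))
    multiples = [l for l in range(lo, hi + 1) if l % 3 == 0]
    others = [l for l in range(lo, hi + 1) if l % 3 != 0]
    lengths = [int(rng.choice(multiples)) for _ in range(n_3n)]
    lengths += [int(rng.choice(others)) for _ in range(n_exitrons - n_3n)]
    rng.shuffle(lengths)
    return lengths


def generate_genome(config: SynthConfig):
    """Build (genome, annotation, truth) for one synthetic study.

    Genes are laid out on a single contig separated by intergenic spacers,
    with alternating strands.  Planted exitrons are codon-aligned, start GT,
    end AG, carry no in-frame stop codon, and hit ``eix3_fraction`` and
    ``intronless_fraction`` exactly after rounding.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = config.n_genes
    n_intronless = int(round(n * config.intronless_fraction))
    n_exitron = int(round(n * config.exitron_fraction))
    # stratify exitron hosts so the intronless-host share matches exactly
    n_x_intronless = min(int(round(n_exitron * config.intronless_fraction)),
                         n_intronless)
    n_x_multi = n_exitron - n_x_intronless
    if n_x_multi > n - n_intronless:
        raise ValueError("not enough multi-exon genes to host requested exitrons")

    gene_plan = []  # (intronless, has_exitron)
    gene_plan += [(True, True)] * n_x_intronless
    gene_plan += [(True, False)] * (n_intronless - n_x_intronless)
    gene_plan += [(False, True)] * n_x_multi
    gene_plan += [(False, False)] * (n - n_intronless - n_x_multi)
    rng.shuffle(gene_plan)

    n_planted = sum(1 for _, x in gene_plan if x)
    xlens = _exitron_lengths(rng, n_planted, config.eix3_fraction,
                             *config.exitron_length_range)

    samples = sorted(config.psi_map)

    contig = "chr1"
    pieces: list[str] = []
    cursor = 0
    models: list[TranscriptModel] = []
    truth = TruthSet()
    xi = 0

    for gi, (intronless, has_exitron) in enumerate(gene_plan):
        gene_id = f"SYNG{gi + 1:05d}"
        tx_id = f"{gene_id}.1"
        strand = "+" if gi % 2 == 0 else "-"
        n_exons = 1 if intronless else int(rng.integers(*config.exons_per_gene_range,
                                                        endpoint=True))
        exon_lens = [int(rng.integers(*config.exon_length_range, endpoint=True))
                     for _ in range(n_exons)]
        xlen = xlens[xi] if has_exitron else 0
        host_exon = int(rng.integers(0, n_exons)) if has_exitron else -1
        if has_exitron and exon_lens[host_exon] < xlen + 2 * PLANT_MARGIN + 3:
            # +3 guarantees a codon-aligned start inside the margins
            exon_lens[host_exon] = xlen + 2 * PLANT_MARGIN + 3 + int(rng.integers(0, 30))
        total = sum(exon_lens)
        # trim the last exon so the CDS is a whole number of codons
        trim = total % 3
        if trim:
            if n_exons - 1 == host_exon:
                exon_lens[host_exon] += 3 - trim
            else:
                exon_lens[-1] -= trim
        total = sum(exon_lens)
        assert total % 3 == 0 and total >= 9

        cds = np.concatenate([np.array(list("ATG")),
                              _random_coding(rng, total - 6, config.gc_exon),
                              np.array(list(rng.choice(STOP_CODONS)))])
        fixed = {0, 1, 2, total - 3, total - 2, total - 1}

        xoff = -1
        if has_exitron:
            # codon-aligned start, >= PLANT_MARGIN from both exon edges
            exon_cds_start = sum(exon_lens[:host_exon])
            lo = exon_cds_start + PLANT_MARGIN
            hi = exon_cds_start + exon_lens[host_exon] - PLANT_MARGIN - xlen
            lo_c = -(-lo // 3) * 3
            choices = np.arange(lo_c, hi + 1, 3)
            # keep clear of the translation start / terminal stop codons
            choices = choices[(choices >= 3) & (choices + xlen <= total - 3)]
            assert len(choices) > 0, "exitron does not fit in host exon"
            xoff = int(rng.choice(choices))
            body = _random_bases(rng, xlen, config.gc_exitron)
            cds[xoff:xoff + xlen] = body
            cds[xoff:xoff + 2] = list("GT")
            cds[xoff + xlen - 2:xoff + xlen] = list("AG")
            fixed |= {xoff, xoff + 1, xoff + xlen - 2, xoff + xlen - 1}
            # keep a TAG from forming when the base before the acceptor AG
            # sits at codon position 1
            _patch_stops(cds, fixed)
        else:
            _patch_stops(cds, fixed)

        # assemble the gene in sense orientation: exons + introns
        sense_parts = []
        intron_ivs_sense = []  # (start, end) in sense-gene coordinates
        exon_ivs_sense = []
        pos = 0
        cpos = 0
        for k, elen in enumerate(exon_lens):
            exon_ivs_sense.append((pos, pos + elen))
            sense_parts.append("".join(cds[cpos:cpos + elen]))
            pos += elen
            cpos += elen
            if k < n_exons - 1:
                ilen = int(rng.integers(*config.intron_length_range, endpoint=True))
                iseq = "".join(_random_bases(rng, ilen, config.gc_intron))
                iseq = "GT" + iseq[2:-2] + "AG"
                intron_ivs_sense.append((pos, pos + ilen))
                sense_parts.append(iseq)
                pos += ilen
        gene_sense = "".join(sense_parts)
        glen = len(gene_sense)

        spacer = "".join(_random_bases(rng, int(rng.integers(100, 300)), 0.35))
        pieces.append(spacer)
        cursor += len(spacer)
        g0 = cursor
        pieces.append(gene_sense if strand == "+" else
                      reverse_complement(gene_sense))
        cursor += glen

        def to_genomic(a: int, b: int) -> tuple[int, int]:
            if strand == "+":
                return g0 + a, g0 + b
            return g0 + glen - b, g0 + glen - a

        exons_gen = [to_genomic(a, b) for a, b in exon_ivs_sense]
        if strand == "-":
            exons_gen = exons_gen  # already in transcription order via mapping
        model = TranscriptModel(
            gene_id=gene_id, transcript_id=tx_id, contig=contig, strand=strand,
            exons=tuple(exons_gen), cds=tuple(exons_gen),
        )
        models.append(model)

        if has_exitron:
            # exitron sense-gene coordinates: host exon start + offset in exon
            exon_cds_start = sum(exon_lens[:host_exon])
            in_exon = xoff - exon_cds_start
            ex_s_sense = exon_ivs_sense[host_exon][0] + in_exon
            xs, xe = to_genomic(ex_s_sense, ex_s_sense + xlen)
            psi = {}
            for s in samples:
                spec = config.psi_map[s]
                if isinstance(spec, (tuple, list)):
                    psi[s] = float(np.round(rng.uniform(*spec), 3))
                else:
                    psi[s] = float(spec)
            truth.planted_exitrons.append(PlantedExitron(
                exitron_id=f"PX{xi + 1:05d}", gene_id=gene_id, contig=contig,
                start=xs, end=xe, strand=strand, cds_offset=xoff,
                frame_class="EIx3" if xlen % 3 == 0 else "frameshift",
                intronless_host=intronless, psi=psi,
            ))
            xi += 1

    pieces.append("".join(_random_bases(rng, 150, 0.35)))
    genome = GenomeSequence({contig: "".join(pieces)})
    return genome, models, truth


# ---------------------------------------------------------------------------
# evidence simulation
# ---------------------------------------------------------------------------

def sample_seed(base_seed: int, sample: str) -> int:
    """Deterministic per-sample seed derived from the study seed (< 2^31)."""
    return (base_seed * 1_000_003 + zlib.crc32(sample.encode())) % (2 ** 31 - 1)


def simulate_evidence(truth: TruthSet, annotation: Sequence[TranscriptModel],
                      genome: GenomeSequence, depth: int, sample: str,
                      base_seed: int = 0):
    """Per-sample junction table and coverage track for the planted study.

    For each planted exitron the exclusion junction count is drawn
    ``Binomial(depth, 1 - PSI/100)``; per-base coverage inside the exitron
    reflects only inclusion reads while exonic coverage outside reflects both
    isoforms.  Annotated introns of multi-exon genes receive full junction
    support so the caller can train splice-site PWMs on them.
    """
    known = truth.planted_exitrons
    if known and any(sample not in x.psi for x in known):
        raise KeyError(f"sample {sample!r} has no true PSI in the truth set")
    rng = np.random.default_rng(sample_seed(base_seed, sample))

    track = CoverageTrack.zeros(genome.lengths, sample)
    rows = []
    by_gene = {x.gene_id: x for x in known}
    for m in annotation:
        for s, e in m.exons_genomic:
            track.add(m.contig, s, e, depth)
        for s, e in m.introns:
            rows.append((m.contig, s, e, m.strand, depth, sample))
        x = by_gene.get(m.gene_id)
        if x is not None:
            p_excl = 1.0 - x.psi[sample] / 100.0
            excl = int(rng.binomial(depth, p_excl))
            incl = depth - excl
            track.set(x.contig, x.start, x.end, incl)
            if excl > 0:
                rows.append((x.contig, x.start, x.end, x.strand, excl, sample))
    junctions = pd.DataFrame(rows, columns=JUNCTION_COLUMNS)
    junctions = junctions.sort_values(["contig", "start", "end"]).reset_index(drop=True)
    return junctions, track


# ---------------------------------------------------------------------------
# SNP injection
# ---------------------------------------------------------------------------

DONOR_SIGNAL_SPAN = 6    # first bases of the exitron (GT + extension)
ACCEPTOR_SIGNAL_SPAN = 6  # last bases of the exitron (extension + AG)


def inject_snps(truth: TruthSet, annotation: Sequence[TranscriptModel],
                genome: GenomeSequence, snp_rate: float,
                codon_bias: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
                signal_fraction: float = 0.1,
                base_seed: int = 0) -> list[Variant]:
    """Plant SNPs inside exitrons with an exact codon-position distribution.

    ``codon_bias`` gives the proportions of SNPs at codon positions 1/2/3 of
    the host reading frame (must sum to 1); counts are exact after rounding.
    ``signal_fraction`` of the SNPs are placed inside the donor/acceptor
    signal spans at the exitron ends.  Colliding positions are deduplicated
    deterministically with a warning.
    """
    if abs(sum(codon_bias) - 1.0) > 1e-9:
        raise ValueError("codon_bias must sum to 1")
    rng = np.random.default_rng(sample_seed(base_seed, "__snps__"))
    exitrons = truth.planted_exitrons
    if not exitrons:
        return []
    total_kb = sum(x.length for x in exitrons) / 1000.0
    n_snps = int(round(snp_rate * total_kb))
    n1 = int(round(n_snps * codon_bias[0]))
    n2 = int(round(n_snps * codon_bias[1]))
    n2 = min(n2, n_snps - n1)
    n3 = n_snps - n1 - n2
    wanted = [1] * n1 + [2] * n2 + [3] * n3
    rng.shuffle(wanted)
    n_signal = int(round(n_snps * signal_fraction))

    used: set[tuple[str, int]] = set()
    variants: list[Variant] = []
    for i, cpos in enumerate(wanted):
        in_signal = i < n_signal
        placed = False
        for _ in range(200):
            x = exitrons[int(rng.integers(len(exitrons)))]
            # sense offsets within the exitron at the requested codon position;
            # exitrons are codon-aligned so offset % 3 == cpos - 1
            if in_signal:
                cand = [o for o in range(x.length)
                        if o % 3 == cpos - 1 and
                        (o < DONOR_SIGNAL_SPAN or
                         o >= x.length - ACCEPTOR_SIGNAL_SPAN)]
            else:
                cand = [o for o in range(DONOR_SIGNAL_SPAN,
                                         x.length - ACCEPTOR_SIGNAL_SPAN)
                        if o % 3 == cpos - 1]
            if not cand:
                continue
            off = int(rng.choice(cand))
            gpos = (x.start + off if x.strand == "+" else x.end - 1 - off)
            if (x.contig, gpos) in used:
                continue
            used.add((x.contig, gpos))
            ref = genome.fetch(x.contig, gpos, gpos + 1)
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            variants.append(Variant(x.contig, gpos, ref, alt,
                                    label=f"snp{len(variants) + 1:05d}"))
            truth.planted_snps.append(PlantedSnp(
                contig=x.contig, pos=gpos, ref=ref, alt=alt,
                exitron_id=x.exitron_id, codon_position=cpos,
                in_splice_signal=in_signal,
            ))
            placed = True
            break
        if not placed:
            warnings.warn("SNP position collision could not be resolved; "
                          "fewer SNPs planted than requested")
    return variants


# ---------------------------------------------------------------------------
# protein-feature planting (for the protein-overlap statistics)
# ---------------------------------------------------------------------------

def simulate_protein_features(truth: TruthSet,
                              annotation: Sequence[TranscriptModel],
                              kind: str = "ptm",
                              density_exitron: float = 0.06,
                              density_background: float = 0.02,
                              base_seed: int = 0) -> pd.DataFrame:
    """Point/short features planted at different densities inside vs outside
    exitron-coded protein regions.

    Returns a tidy feature table (protein_id, kind, label, start_aa, end_aa,
    ptm_type) suitable for :mod:`exitron_scan.protmap`.
    """
    rng = np.random.default_rng(sample_seed(base_seed, "__features__"))
    by_gene = {x.gene_id: x for x in truth.planted_exitrons}
    rows = []
    for m in annotation:
        n_aa = m.cds_length // 3 - 1  # exclude the stop codon
        x = by_gene.get(m.gene_id)
        xa = xb = -1
        if x is not None:
            xa = x.cds_offset // 3 + 1          # 1-based aa interval
            xb = (x.cds_offset + x.length - 1) // 3 + 1
        for aa in range(1, n_aa + 1):
            dens = density_exitron if (x is not None and xa <= aa <= xb) \
                else density_background
            if rng.random() < dens:
                rows.append((m.transcript_id, kind, f"{kind}_site", aa, aa,
                             "phospho" if kind == "ptm" else ""))
    return pd.DataFrame(rows, columns=["protein_id", "kind", "label",
                                       "start_aa", "end_aa", "ptm_type"])


# ---------------------------------------------------------------------------
# study writer
# ---------------------------------------------------------------------------

def truth_table(truth: TruthSet) -> pd.DataFrame:
    rows = []
    for x in truth.planted_exitrons:
        row = dict(exitron_id=x.exitron_id, gene_id=x.gene_id, contig=x.contig,
                   start=x.start, end=x.end, strand=x.strand, length=x.length,
                   cds_offset=x.cds_offset, frame_class=x.frame_class,
                   intronless_host=x.intronless_host)
        for s, v in sorted(x.psi.items()):
            row[f"psi_{s}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def write_study(config: SynthConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate a full study and write all artefacts under ``outdir``.

    Emits genome FASTA, GFF3 annotation, per-sample junction BED and
    bedGraph coverage, a VCF of planted SNPs, the truth TSV, and a JSON
    sidecar echoing the configuration and derived per-sample seeds.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, models, truth = generate_genome(config)
    paths = {
        "genome": outdir / "genome.fa",
        "annotation": outdir / "annotation.gff3",
        "variants": outdir / "variants.vcf",
        "truth": outdir / "truth.tsv",
        "config": outdir / "config.json",
    }
    write_genome(genome, paths["genome"])
    write_annotation(models, paths["annotation"])
    sample_seeds = {}
    for sample in sorted(config.psi_map):
        junctions, track = simulate_evidence(truth, models, genome,
                                             config.depth, sample, config.seed)
        jpath = outdir / f"junctions.{sample}.bed"
        cpath = outdir / f"coverage.{sample}.bedgraph"
        write_junctions(junctions, jpath)
        write_coverage(track, cpath)
        paths[f"junctions.{sample}"] = jpath
        paths[f"coverage.{sample}"] = cpath
        sample_seeds[sample] = sample_seed(config.seed, sample)
    variants = inject_snps(truth, models, genome, config.snp_rate,
                           base_seed=config.seed)
    write_variants(variants, genome, paths["variants"])
    tt = truth_table(truth)
    tt.to_csv(paths["truth"], sep="\t", index=False)
    sidecar = {"config": {k: list(v) if isinstance(v, tuple) else v
                          for k, v in asdict(config).items()},
               "sample_seeds": sample_seeds}
    paths["config"].write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return paths
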