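"""Genomic I/O and the internal coordinate model.

Everything inside the package uses 0-based half-open coordinates on the
forward genomic strand; conversion to the 1-based closed conventions of
GFF3/VCF happens only at file boundaries.  A splice-junction interval spans
exactly the intronic bases: the donor GT occupies ``[start, start+2)`` and
the acceptor AG occupies ``[end-2, end)`` on the coding strand.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeSequence",
    "TranscriptModel",
    "CoverageTrack",
    "Variant",
    "read_genome",
    "write_genome",
    "read_annotation",
    "write_annotation",
    "read_junctions",
    "write_junctions",
    "read_coverage",
    "write_coverage",
    "read_variants",
    "write_variants",
    "spliced_cds",
    "translate",
    "write_catalog",
    "read_catalog",
    "select_transcripts",
]

_IUPAC = set("ACGTRYSWKMBDHVN")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

JUNCTION_COLUMNS = ["contig", "start", "end", "strand", "read_count", "sample"]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSequence:
    """In-memory genome with strand-aware subsequence access."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            if name in self._seqs:
                raise ValueError(f"duplicate contig name: {name!r}")
            seq = seq.upper()
            bad = set(seq) - _IUPAC
            if bad:
                raise ValueError(f"non-IUPAC characters in {name!r}: {sorted(bad)}")
            self._seqs[name] = seq

    @property
    def contigs(self) -> list[str]:
        return list(self._seqs)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._seqs.items()}

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        """Subsequence ``[start, end)``; minus strand returns the reverse complement."""
        seq = self._seqs[contig]
        if start < 0 or end > len(seq) or end < start:
            raise IndexError(
                f"range [{start}, {end}) out of bounds for {contig} (len {len(seq)})"
            )
        sub = seq[start:end]
        return reverse_complement(sub) if strand == "-" else sub


@dataclass(frozen=True)
class TranscriptModel:
    """A protein-coding transcript: the coordinate backbone of the analysis.

    ``exons`` and ``cds`` are tuples of genomic ``(start, end)`` intervals in
    transcription order (descending genomic coordinate on the minus strand).
    ``flags`` records annotation-level problems (e.g. a spliced CDS whose
    length is not a multiple of 3) without dropping the transcript.
    """

    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        for ivs in (self.exons, self.cds):
            for s, e in ivs:
                if e <= s:
                    raise ValueError(f"empty interval ({s}, {e})")
        gen = self.exons_genomic
        for (s1, e1), (s2, e2) in zip(gen, gen[1:]):
            if s2 < e1:
                raise ValueError("overlapping exons")

    # -- derived geometry ---------------------------------------------------

    @property
    def exons_genomic(self) -> list[tuple[int, int]]:
        return sorted(self.exons)

    @property
    def cds_genomic(self) -> list[tuple[int, int]]:
        return sorted(self.cds)

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Genomic intron intervals (ascending), derived from exon gaps."""
        gen = self.exons_genomic
        return [(e1, s2) for (_, e1), (s2, _) in zip(gen, gen[1:])]

    @property
    def is_intronless(self) -> bool:
        return len(self.exons) == 1

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def span(self) -> tuple[int, int]:
        gen = self.exons_genomic
        return gen[0][0], gen[-1][1]

    @property
    def frame_anchor(self) -> int:
        """Genomic coordinate (0-based) of the first coding base."""
        s, e = self.cds[0]
        return s if self.strand == "+" else e - 1

    def cds_offset_of(self, pos: int) -> int:
        """Offset of genomic position ``pos`` in the spliced CDS (0-based).

        Raises ``ValueError`` when ``pos`` is not a coding base.
        """
        off = 0
        for s, e in self.cds:  # transcription order
            if s <= pos < e:
                return off + (pos - s if self.strand == "+" else e - 1 - pos)
            off += e - s
        raise ValueError(f"position {pos} not in CDS of {self.transcript_id}")

    def cds_interval_of(self, start: int, end: int) -> tuple[int, int]:
        """Map a genomic interval contained in one CDS piece to (cds_offset, length).

        The offset is the 5'-most coding offset of the interval in
        transcription orientation.
        """
        for s, e in self.cds:
            if s <= start and end <= e:
                off5 = self.cds_offset_of(start if self.strand == "+" else end - 1)
                return off5, end - start
        raise ValueError(
            f"[{start}, {end}) not contained in a single CDS interval of "
            f"{self.transcript_id}"
        )

    def cds_junction_offsets(self) -> list[int]:
        """Exon-exon junction positions in spliced-CDS coordinates."""
        offs, acc = [], 0
        for s, e in self.cds[:-1]:
            acc += e - s
            offs.append(acc)
        return offs


@dataclass(frozen=True)
class Variant:
    """A single-nucleotide variant; ``pos`` is internal 0-based."""

    contig: str
    pos: int
    ref: str
    alt: str
    label: str = "."

    def __post_init__(self):
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("only single-nucleotide variants are supported")


class CoverageTrack:
    """Per-base read depth for one sample, stored as dense per-contig arrays."""

    def __init__(self, depths: Mapping[str, np.ndarray], sample: str):
        self.sample = sample
        self._depths = {c: np.asarray(a, dtype=float) for c, a in depths.items()}
        for c, a in self._depths.items():
            if (a < 0).any():
                raise ValueError(f"negative depth on {c}")

    @classmethod
    def zeros(cls, contig_lengths: Mapping[str, int], sample: str) -> "CoverageTrack":
        return cls({c: np.zeros(n) for c, n in contig_lengths.items()}, sample)

    @property
    def contigs(self) -> list[str]:
        return list(self._depths)

    def array(self, contig: str) -> np.ndarray:
        return self._depths[contig]

    def add(self, contig: str, start: int, end: int, value: float) -> None:
        self._depths[contig][start:end] += value

    def set(self, contig: str, start: int, end: int, value: float) -> None:
        self._depths[contig][start:end] = value

    def mean(self, contig: str, start: int, end: int) -> float:
        if end <= start:
            raise ValueError("empty interval")
        return float(self._depths[contig][start:end].mean())


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_genome(path: str | Path) -> GenomeSequence:
    """Read a FASTA into a :class:`GenomeSequence` (names = first token)."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA record {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    return GenomeSequence(seqs)


def write_genome(genome: GenomeSequence, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(genome[c]), id=c, description="") for c in genome.contigs
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 / GTF annotation
# ---------------------------------------------------------------------------

def _models_from_db(db) -> list[TranscriptModel]:
    import gffutils  # local import keeps module import cheap

    models = []
    tx_types = [t for t in ("mRNA", "transcript") if t in set(db.featuretypes())]
    seen = set()
    for ttype in tx_types:
        for tx in db.features_of_type(ttype, order_by=("seqid", "start")):
            if tx.id in seen:
                continue
            seen.add(tx.id)
            exons = [(f.start - 1, f.end) for f in db.children(tx, featuretype="exon")]
            cds = [
                (f.start - 1, f.end, f.frame)
                for f in db.children(tx, featuretype="CDS")
            ]
            if not cds:
                continue
            if not exons:
                exons = [(s, e) for s, e, _ in cds]
            strand = tx.strand
            exons = sorted(exons, reverse=strand == "-")
            cds_sorted = sorted(cds, key=lambda t: t[0], reverse=strand == "-")
            gene_id = tx.attributes.get("gene_id", [None])[0]
            if gene_id is None:
                parents = tx.attributes.get("Parent", [tx.id])
                gene_id = parents[0]
            flags = []
            cds_ivs = tuple((s, e) for s, e, _ in cds_sorted)
            total = sum(e - s for s, e in cds_ivs)
            if total % 3 != 0:
                flags.append("cds_length_not_multiple_of_3")
            # reconcile annotated phase with the cumulative frame
            acc = 0
            for s, e, frame in cds_sorted:
                if frame not in (".", None):
                    if int(frame) != (3 - acc % 3) % 3:
                        flags.append("cds_phase_mismatch")
                        break
                acc += e - s
            exon_set = sorted((s, e) for s, e in exons)
            for s, e in cds_ivs:
                if not any(xs <= s and e <= xe for xs, xe in exon_set):
                    raise ValueError(
                        f"CDS [{s}, {e}) outside exon bounds in {tx.id}"
                    )
            models.append(
                TranscriptModel(
                    gene_id=gene_id,
                    transcript_id=tx.id,
                    contig=tx.seqid,
                    strand=strand,
                    exons=tuple(exons),
                    cds=cds_ivs,
                    flags=tuple(flags),
                )
            )
    return models


def read_annotation(path: str | Path, dialect: str = "gff3") -> list[TranscriptModel]:
    """Parse a GFF3 or GTF annotation into transcript models.

    Coordinates are converted from 1-based closed to internal 0-based
    half-open.  Transcripts whose spliced CDS length is not a multiple of 3,
    or whose CDS phase disagrees with the cumulative frame, are flagged (see
    ``TranscriptModel.flags``) rather than dropped.
    """
    import gffutils

    if dialect not in ("gff3", "gtf"):
        raise ValueError(f"unknown dialect {dialect!r}")
    db = gffutils.create_db(
        str(path), dbfn=":memory:", merge_strategy="create_unique",
        keep_order=True, disable_infer_genes=True,
    )
    return _models_from_db(db)


def write_annotation(models: Sequence[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as GFF3 (gene/mRNA/exon/CDS, 1-based closed)."""
    lines = ["##gff-version 3"]
    for m in sorted(models, key=lambda m: (m.contig, m.span[0], m.transcript_id)):
        g0, g1 = m.span
        lines.append(
            "\t".join([m.contig, "exitron_scan", "gene", str(g0 + 1), str(g1),
                       ".", m.strand, ".", f"ID={m.gene_id}"])
        )
        lines.append(
            "\t".join([m.contig, "exitron_scan", "mRNA", str(g0 + 1), str(g1),
                       ".", m.strand, ".",
                       f"ID={m.transcript_id};Parent={m.gene_id}"])
        )
        for s, e in m.exons_genomic:
            lines.append(
                "\t".join([m.contig, "exitron_scan", "exon", str(s + 1), str(e),
                           ".", m.strand, ".", f"Parent={m.transcript_id}"])
            )
        acc = 0
        phased = []
        for s, e in m.cds:  # transcription order for phase computation
            phased.append(((s, e), (3 - acc % 3) % 3))
            acc += e - s
        for (s, e), phase in sorted(phased):
            lines.append(
                "\t".join([m.contig, "exitron_scan", "CDS", str(s + 1), str(e),
                           ".", m.strand, str(phase),
                           f"Parent={m.transcript_id}"])
            )
    Path(path).write_text("\n".join(lines) + "\n")


def select_transcripts(models: Iterable[TranscriptModel]) -> list[TranscriptModel]:
    """One analysis transcript per gene: the longest CDS, ties by id."""
    best: dict[str, TranscriptModel] = {}
    for m in models:
        cur = best.get(m.gene_id)
        if cur is None or (m.cds_length, m.transcript_id) > (cur.cds_length,
                                                             cur.transcript_id):
            best[m.gene_id] = m
    return [best[g] for g in sorted(best)]


# ---------------------------------------------------------------------------
# BED junctions / bedGraph coverage / VCF variants
# ---------------------------------------------------------------------------

def read_junctions(path: str | Path, sample: str) -> pd.DataFrame:
    """Read a BED6 junction table (interval = intronic bases, score = reads)."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{i}: expected 6 BED columns")
            try:
                start, end, count = int(parts[1]), int(parts[2]), int(float(parts[4]))
            except ValueError as exc:
                raise ValueError(f"{path}:{i}: malformed line") from exc
            if end <= start or count < 0:
                raise ValueError(f"{path}:{i}: invalid junction")
            rows.append((parts[0], start, end, parts[5], count, sample))
    return pd.DataFrame(rows, columns=JUNCTION_COLUMNS)


def write_junctions(table: pd.DataFrame, path: str | Path) -> None:
    table = table.sort_values(["contig", "start", "end"]).reset_index(drop=True)
    with open(path, "w") as fh:
        for i, r in table.iterrows():
            fh.write(
                f"{r.contig}\t{r.start}\t{r.end}\tJ{i:06d}\t{r.read_count}\t{r.strand}\n"
            )


def read_coverage(path: str | Path, sample: str,
                  contig_lengths: Mapping[str, int]) -> CoverageTrack:
    """Expand a bedGraph into a dense per-base coverage track."""
    track = CoverageTrack.zeros(contig_lengths, sample)
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{i}: expected 4 bedGraph columns")
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{i}: malformed line") from exc
            track.set(parts[0], start, end, value)
    return track


def write_coverage(track: CoverageTrack, path: str | Path) -> None:
    """Run-length encode the track as bedGraph (zero runs omitted)."""
    with open(path, "w") as fh:
        for contig in track.contigs:
            a = track.array(contig)
            if not len(a):
                continue
            breaks = np.flatnonzero(np.diff(a)) + 1
            starts = np.concatenate([[0], breaks])
            ends = np.concatenate([breaks, [len(a)]])
            for s, e in zip(starts, ends):
                v = a[s]
                if v != 0:
                    fh.write(f"{contig}\t{s}\t{e}\t{v:g}\n")


def read_variants(path: str | Path,
                  genome: GenomeSequence | None = None) -> list[Variant]:
    """Read SNVs from a VCF; checks REF against the genome when provided."""
    import pysam

    variants = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                if len(rec.ref) != 1 or len(alt) != 1:
                    continue  # indels out of scope
                v = Variant(rec.chrom, rec.pos - 1, rec.ref, alt,
                            rec.id or ".")
                if genome is not None:
                    actual = genome.fetch(v.contig, v.pos, v.pos + 1)
                    if actual != v.ref:
                        raise ValueError(
                            f"VCF REF mismatch at {v.contig}:{rec.pos}: "
                            f"file says {v.ref}, genome has {actual}"
                        )
                variants.append(v)
    return variants


def write_variants(variants: Sequence[Variant], genome: GenomeSequence,
                   path: str | Path) -> None:
    lines = ["##fileformat=VCFv4.2"]
    for contig, length in genome.lengths.items():
        lines.append(f"##contig=<ID={contig},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for v in sorted(variants, key=lambda v: (v.contig, v.pos, v.alt)):
        lines.append(
            f"{v.contig}\t{v.pos + 1}\t{v.label}\t{v.ref}\t{v.alt}\t.\tPASS\t."
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Sequence helpers
# ---------------------------------------------------------------------------

def spliced_cds(model: TranscriptModel, genome: GenomeSequence) -> str:
    """Strand-correct concatenation of the CDS in translation order."""
    return "".join(
        genome.fetch(model.contig, s, e, model.strand) for s, e in model.cds
    )


def translate(cds_seq: str) -> str:
    """Standard-table translation; trailing partial codon ignored."""
    usable = len(cds_seq) - len(cds_seq) % 3
    return str(Seq(cds_seq[:usable]).translate())


# ---------------------------------------------------------------------------
# Exitron catalog output
# ---------------------------------------------------------------------------

CATALOG_COLUMNS = [
    "exitron_id", "contig", "start", "end", "strand", "gene_id",
    "transcript_id", "host_exon_index", "length", "frame_class",
    "donor_dinucleotide", "acceptor_dinucleotide", "gc", "intronless_host",
]


def write_catalog(exitrons, path_prefix: str | Path,
                  consequences=None, psi_records=None) -> dict[str, Path]:
    """Write the exitron catalog as a flat TSV plus a GFF3 companion.

    Rows are deterministically ordered by (contig, start, end, id).
    ``consequences`` / ``psi_records`` are joined onto the TSV when given.
    """
    prefix = Path(path_prefix)
    rows = [
        dict(
            exitron_id=x.id, contig=x.contig, start=x.start, end=x.end,
            strand=x.strand, gene_id=x.gene_id, transcript_id=x.transcript_id,
            host_exon_index=x.host_exon_index, length=x.length,
            frame_class=x.frame_class, donor_dinucleotide=x.donor_dinucleotide,
            acceptor_dinucleotide=x.acceptor_dinucleotide,
            gc=round(x.gc, 6), intronless_host=x.intronless_host,
        )
        for x in exitrons
    ]
    df = pd.DataFrame(rows, columns=CATALOG_COLUMNS)
    df = df.sort_values(["contig", "start", "end", "exitron_id"]).reset_index(drop=True)
    if consequences is not None:
        cdf = pd.DataFrame([c.as_dict() for c in consequences])
        df = df.merge(cdf, on="exitron_id", how="left")
    if psi_records is not None:
        pdf = pd.DataFrame(
            [(p.exitron_id, p.sample, p.psi) for p in psi_records],
            columns=["exitron_id", "sample", "psi"],
        )
        wide = pdf.pivot(index="exitron_id", columns="sample", values="psi")
        wide.columns = [f"psi_{c}" for c in wide.columns]
        df = df.merge(wide.reset_index(), on="exitron_id", how="left")
    tsv = prefix.with_suffix(".tsv")
    df.to_csv(tsv, sep="\t", index=False)
    gff = prefix.with_suffix(".gff3")
    lines = ["##gff-version 3"]
    for r in df.itertuples():
        lines.append("\t".join([
            r.contig, "exitron_scan", "exitron", str(r.start + 1), str(r.end),
            ".", r.strand, ".",
            f"ID={r.exitron_id};Parent={r.transcript_id};frame_class={r.frame_class}",
        ]))
    gff.write_text("\n".join(lines) + "\n")
    return {"tsv": tsv, "gff3": gff}


def read_catalog(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
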