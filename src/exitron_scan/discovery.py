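"""Exitron calling from splice-junction and coverage evidence.

An exitron is an alternatively spliced internal region of a protein-coding
exon: its intronic interval lies strictly inside the CDS portion of exactly
one annotated exon, it carries canonical GT..AG boundaries on the coding
strand, contains no stop codon in the host reading frame, and shows both
exclusion (junction reads) and inclusion (exonic coverage) evidence — so the
unspliced exon and the spliced form are both observed.  Junctions that
coincide with annotated introns are intron-retention evidence, junctions
that share an end with an exon boundary are alternative 5'/3' splice sites,
and junctions with exclusion but no inclusion evidence are unannotated
constitutive introns; all are excluded with a reason code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import quant
from .gio import GenomeSequence, TranscriptModel, CoverageTrack
from .seqstats import gc_content

STOP_CODONS = {"TAA", "TAG", "TGA"}

EXCLUSION_REASONS = (
    "annotated_intron",
    "shares_boundary",
    "multi_exon_span",
    "outside_cds",
    "strand_conflict",
    "noncanonical_signal",
    "in_frame_stop",
    "ambiguous_base",
    "low_junction_support",
    "no_inclusion_evidence",
)


@dataclass(frozen=True)
class ExitronCandidate:
    contig: str
    start: int
    end: int
    strand: str
    host_transcript: TranscriptModel
    host_exon_index: int
    margin5: int
    margin3: int

    def __post_init__(self):
        if self.margin5 < 1 or self.margin3 < 1:
            raise ValueError("candidate not strictly internal (margin < 1)")

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.contig, self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SignalCheck:
    passed: bool
    donor_dinucleotide: str
    acceptor_dinucleotide: str
    stop_free: bool
    reason: str = ""


@dataclass
class Exitron:
    """A called exitron with per-sample support."""

    id: str
    contig: str
    start: int
    end: int
    strand: str
    gene_id: str
    transcript_id: str
    host_exon_index: int
    length: int
    frame_class: str               # "EIx3" | "frameshift"
    donor_dinucleotide: str
    acceptor_dinucleotide: str
    gc: float
    intronless_host: bool
    support: dict = field(default_factory=dict)  # sample -> (junction, inclusion)
    donor_score: float | None = None
    acceptor_score: float | None = None
    branch_point_score: float | None = None

    def __post_init__(self):
        if self.length != self.end - self.start:
            raise ValueError("length inconsistent with interval")
        expected = "EIx3" if self.length % 3 == 0 else "frameshift"
        if self.frame_class != expected:
            raise ValueError("frame_class inconsistent with length")

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.contig, self.start, self.end)


def _cds_exon_of(model: TranscriptModel, start: int, end: int):
    """CDS piece of ``model`` strictly containing [start, end), or None."""
    for idx, (s, e) in enumerate(model.cds_genomic):
        if s < start and end < e:
            return idx, (s, e)
    return None


def candidate_junctions(junctions: pd.DataFrame,
                        models: Sequence[TranscriptModel]):
    """Filter junctions down to exitron candidates.

    Returns ``(candidates, excluded)`` where ``excluded`` is a DataFrame with
    a ``reason`` column (one of :data:`EXCLUSION_REASONS`).  A junction
    qualifies when its intronic interval lies strictly inside the CDS portion
    of exactly one exon of a selected transcript, does not coincide with an
    annotated intron, does not share an end with any exon/CDS boundary, and
    matches the host gene strand.
    """
    by_contig: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_contig.setdefault(m.contig, []).append(m)
    annotated_introns = {
        (m.contig, s, e) for m in models for s, e in m.introns
    }
    boundaries: dict[str, set[int]] = {}
    for m in models:
        bset = boundaries.setdefault(m.contig, set())
        for s, e in m.exons_genomic:
            bset.update((s, e))
        for s, e in m.cds_genomic:
            bset.update((s, e))

    candidates: list[ExitronCandidate] = []
    excluded_rows = []

    def exclude(row, reason):
        excluded_rows.append(dict(contig=row.contig, start=row.start,
                                  end=row.end, strand=row.strand,
                                  read_count=row.read_count,
                                  sample=row.sample, reason=reason))

    for row in junctions.itertuples(index=False):
        if (row.contig, row.start, row.end) in annotated_introns:
            exclude(row, "annotated_intron")
            continue
        if row.start in boundaries.get(row.contig, ()) or \
                row.end in boundaries.get(row.contig, ()):
            exclude(row, "shares_boundary")
            continue
        hit = None
        reason = "outside_cds"
        for m in by_contig.get(row.contig, ()):
            g0, g1 = m.span
            if not (g0 <= row.start and row.end <= g1):
                continue
            found = _cds_exon_of(m, row.start, row.end)
            if found is None:
                # inside the gene body but not inside a single CDS exon
                for s, e in m.cds_genomic:
                    if (s < row.start < e) != (s < row.end < e):
                        reason = "multi_exon_span"
                continue
            if row.strand != m.strand:
                reason = "strand_conflict"
                continue
            hit = (m, found[0])
            break
        if hit is None:
            exclude(row, reason)
            continue
        m, exon_idx = hit
        s, e = m.cds_genomic[exon_idx]
        if m.strand == "+":
            margin5, margin3 = row.start - s, e - row.end
        else:
            margin5, margin3 = e - row.end, row.start - s
        candidates.append(ExitronCandidate(
            contig=row.contig, start=int(row.start), end=int(row.end),
            strand=m.strand, host_transcript=m, host_exon_index=exon_idx,
            margin5=margin5, margin3=margin3,
        ))

    # merge duplicate intervals arising from multiple samples
    uniq: dict[tuple, ExitronCandidate] = {}
    for c in candidates:
        uniq.setdefault(c.interval, c)
    candidates = [uniq[k] for k in sorted(uniq)]
    excluded = pd.DataFrame(
        excluded_rows,
        columns=["contig", "start", "end", "strand", "read_count", "sample",
                 "reason"],
    )
    return candidates, excluded


def validate_signals(candidate: ExitronCandidate, genome: GenomeSequence,
                     allowed_donors: frozenset[str] = frozenset({"GT"})
                     ) -> SignalCheck:
    """Check canonical splice signals and stop-freedom in the host frame.

    The donor/acceptor dinucleotides are the first/last two intronic bases in
    transcription orientation; the stop-free check scans host-frame codons
    lying wholly inside the candidate interval.
    """
    seq = genome.fetch(candidate.contig, candidate.start, candidate.end,
                       candidate.strand)
    donor, acceptor = seq[:2], seq[-2:]
    if "N" in donor or "N" in acceptor:
        return SignalCheck(False, donor, acceptor, False, "ambiguous_base")
    m = candidate.host_transcript
    five_prime = candidate.start if m.strand == "+" else candidate.end - 1
    cds_off = m.cds_offset_of(five_prime)
    phase = (3 - cds_off % 3) % 3  # sense offset of the first in-frame codon
    stop_free = True
    for i in range(phase, len(seq) - 2, 3):
        if seq[i:i + 3] in STOP_CODONS:
            stop_free = False
            break
    if donor not in allowed_donors or acceptor != "AG":
        return SignalCheck(False, donor, acceptor, stop_free,
                           "noncanonical_signal")
    if not stop_free:
        return SignalCheck(False, donor, acceptor, False, "in_frame_stop")
    return SignalCheck(True, donor, acceptor, True)


def call_exitrons(candidates: Sequence[ExitronCandidate],
                  genome: GenomeSequence,
                  junction_tables: Mapping[str, pd.DataFrame],
                  coverage_tracks: Mapping[str, CoverageTrack],
                  min_junction: int = 3,
                  min_inclusion: float = 3.0,
                  window: int = 10,
                  allowed_donors: Iterable[str] = ("GT",)):
    """Validate signals, apply evidence thresholds, and emit the catalog.

    A candidate is called when some sample shows >= ``min_junction`` junction
    reads and some sample shows inclusion coverage >= ``min_inclusion``
    (estimated over the first/last ``window`` intronic bases).  Candidates
    with junction support but no inclusion anywhere are reported separately
    as unannotated constitutive introns.  Returns
    ``(exitrons, rejected_df)``.
    """
    allowed = frozenset(allowed_donors)
    samples = sorted(junction_tables)
    exitrons: list[Exitron] = []
    rejected = []

    for c in sorted(candidates, key=lambda c: c.interval):
        check = validate_signals(c, genome, allowed)
        if not check.passed:
            rejected.append(dict(contig=c.contig, start=c.start, end=c.end,
                                 reason=check.reason))
            continue
        support = {}
        for s in samples:
            counts = quant.count_evidence(
                c.interval, junction_tables[s], coverage_tracks[s],
                sample=s, window=window)
            support[s] = (counts.exclusion, counts.inclusion)
        has_junction = any(j >= min_junction for j, _ in support.values())
        has_inclusion = any(i >= min_inclusion for _, i in support.values())
        if not has_junction:
            rejected.append(dict(contig=c.contig, start=c.start, end=c.end,
                                 reason="low_junction_support"))
            continue
        if not has_inclusion:
            rejected.append(dict(contig=c.contig, start=c.start, end=c.end,
                                 reason="no_inclusion_evidence"))
            continue
        m = c.host_transcript
        seq = genome.fetch(c.contig, c.start, c.end, c.strand)
        exitrons.append(Exitron(
            id="",  # assigned below, deterministically
            contig=c.contig, start=c.start, end=c.end, strand=c.strand,
            gene_id=m.gene_id, transcript_id=m.transcript_id,
            host_exon_index=c.host_exon_index, length=c.length,
            frame_class="EIx3" if c.length % 3 == 0 else "frameshift",
            donor_dinucleotide=check.donor_dinucleotide,
            acceptor_dinucleotide=check.acceptor_dinucleotide,
            gc=gc_content(seq), intronless_host=m.is_intronless,
            support=support,
        ))

    exitrons.sort(key=lambda x: x.interval)
    for i, x in enumerate(exitrons, 1):
        x.id = f"EI{i:05d}"
    rejected_df = pd.DataFrame(rejected,
                               columns=["contig", "start", "end", "reason"])
    return exitrons, rejected_df


def flag_intronless(exitrons: Sequence[Exitron],
                    models: Sequence[TranscriptModel]) -> None:
    """Re-derive the intronless-host flag from the annotation (in place)."""
    single = {m.transcript_id: m.is_intronless for m in models}
    for x in exitrons:
        x.intronless_host = single[x.transcript_id]


def discover(genome: GenomeSequence, models: Sequence[TranscriptModel],
             junction_tables: Mapping[str, pd.DataFrame],
             coverage_tracks: Mapping[str, CoverageTrack],
             min_junction: int = 3, min_inclusion: float = 3.0,
             window: int = 10, allowed_donors: Iterable[str] = ("GT",)):
    """End-to-end exitron discovery over a multi-sample study.

    Pools junctions across samples for candidate generation, then applies
    signal validation and per-sample evidence thresholds.  Returns
    ``(exitrons, excluded_df)`` with exclusion reasons for every junction or
    candidate that did not make the catalog.
    """
    pooled = pd.concat(list(junction_tables.values()), ignore_index=True)
    candidates, excluded = candidate_junctions(pooled, models)
    exitrons, rejected = call_exitrons(
        candidates, genome, junction_tables, coverage_tracks,
        min_junction=min_junction, min_inclusion=min_inclusion,
        window=window, allowed_donors=allowed_donors)
    all_excluded = pd.concat(
        [excluded[["contig", "start", "end", "reason"]], rejected],
        ignore_index=True,
    ).drop_duplicates().sort_values(["contig", "start", "end"]).reset_index(drop=True)
    return exitrons, all_excluded
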