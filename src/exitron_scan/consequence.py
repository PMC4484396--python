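"""Protein-level consequences of exitron splicing.

Retaining an exitron yields the full-length annotated protein; splicing it
out yields one of three fates.  An EIx3 exitron (length a multiple of 3)
deletes internal amino acids without a frameshift.  A frameshift exitron
shifts the reading frame downstream of the new junction, which either alters
the protein C-terminus or creates a premature termination codon (PTC); PTCs
lying more than 50 nt upstream of the final exon-exon junction of the
spliced transcript mark the transcript as a nonsense-mediated decay (NMD)
candidate (the 50-nt rule).  The junction created by exitron splicing itself
counts as an exon-exon junction, so frameshift exitrons in single-exon genes
can never be NMD candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .discovery import Exitron
from .gio import GenomeSequence, TranscriptModel, spliced_cds, translate

NMD_RULE_NT = 50

CATEGORIES = ("internal_deletion", "altered_cterm", "ptc_nmd_candidate")


@dataclass(frozen=True)
class ConsequenceRecord:
    exitron_id: str
    category: str
    deleted_aa_start: int | None = None   # 1-based, internal_deletion only
    deleted_aa_end: int | None = None
    partial_codons: bool = False          # exitron boundaries split codons
    new_stop_cds_position: int | None = None  # nt offset in the spliced CDS
    nmd_rule_distance: int | None = None  # nt from new stop to last junction
    stop_loss: bool = False               # no stop found in the new frame

    def as_dict(self) -> dict:
        return dict(exitron_id=self.exitron_id, category=self.category,
                    deleted_aa_start=self.deleted_aa_start,
                    deleted_aa_end=self.deleted_aa_end,
                    partial_codons=self.partial_codons,
                    new_stop_cds_position=self.new_stop_cds_position,
                    nmd_rule_distance=self.nmd_rule_distance,
                    stop_loss=self.stop_loss)


def splice_out(cds_seq: str, cds_offset: int, length: int) -> str:
    """Remove ``length`` nt starting at ``cds_offset`` from a CDS sequence."""
    if length < 1:
        raise ValueError("exitron length must be >= 1")
    if cds_offset < 0 or cds_offset + length > len(cds_seq):
        raise ValueError("exitron does not lie within the CDS")
    return cds_seq[:cds_offset] + cds_seq[cds_offset + length:]


def nmd_candidate(new_stop_end: int, junction_offsets: Sequence[int],
                  rule_nt: int = NMD_RULE_NT) -> tuple[bool, int]:
    """Apply the 50-nt rule on spliced-transcript coordinates.

    ``new_stop_end`` is the coordinate just past the stop codon;
    ``junction_offsets`` are all exon-exon junction positions of the spliced
    transcript, including the junction created by exitron splicing.  The
    flag is True iff the stop lies strictly more than ``rule_nt`` nt upstream
    of the final junction.
    """
    if not junction_offsets:
        return False, 0
    distance = max(junction_offsets) - new_stop_end
    return distance > rule_nt, distance


def spliced_junction_offsets(model: TranscriptModel, exitron_cds_offset: int,
                             exitron_length: int) -> list[int]:
    """Exon-exon junctions of the exitron-spliced transcript, in spliced-CDS
    coordinates (annotated junctions shifted past the exitron, plus the new
    junction)."""
    offs = []
    for j in model.cds_junction_offsets():
        if j <= exitron_cds_offset:
            offs.append(j)
        else:
            offs.append(j - exitron_length)
    offs.append(exitron_cds_offset)
    return sorted(set(offs))


def classify_consequence(exitron: Exitron, model: TranscriptModel,
                         genome: GenomeSequence) -> ConsequenceRecord:
    """Classify the protein-level outcome of splicing one exitron."""
    cds = spliced_cds(model, genome)
    five_prime = exitron.start if model.strand == "+" else exitron.end - 1
    offset = model.cds_offset_of(five_prime)
    length = exitron.length
    spliced = splice_out(cds, offset, length)

    if exitron.frame_class == "EIx3":
        partial = offset % 3 != 0
        aa_start = offset // 3 + 1
        aa_end = (offset + length - 1) // 3 + 1
        return ConsequenceRecord(
            exitron_id=exitron.id, category="internal_deletion",
            deleted_aa_start=aa_start, deleted_aa_end=aa_end,
            partial_codons=partial,
        )

    protein = translate(spliced)
    junctions = spliced_junction_offsets(model, offset, length)
    # first stop at/after the new splice junction
    first_codon = offset // 3
    stop_aa = protein.find("*", first_codon)
    if stop_aa == -1:
        return ConsequenceRecord(exitron_id=exitron.id,
                                 category="altered_cterm", stop_loss=True)
    stop_start = stop_aa * 3
    flag, distance = nmd_candidate(stop_start + 3, junctions)
    category = "ptc_nmd_candidate" if flag else "altered_cterm"
    return ConsequenceRecord(
        exitron_id=exitron.id, category=category,
        new_stop_cds_position=stop_start, nmd_rule_distance=distance,
    )


def classify_all(exitrons: Sequence[Exitron],
                 models: Sequence[TranscriptModel],
                 genome: GenomeSequence) -> list[ConsequenceRecord]:
    by_tx = {m.transcript_id: m for m in models}
    return [classify_consequence(x, by_tx[x.transcript_id], genome)
            for x in exitrons]


def isoform_proteins(exitron: Exitron, model: TranscriptModel,
                     genome: GenomeSequence) -> tuple[str, str]:
    """(full-length, exitron-spliced) protein sequences, stops trimmed."""
    cds = spliced_cds(model, genome)
    five_prime = exitron.start if model.strand == "+" else exitron.end - 1
    offset = model.cds_offset_of(five_prime)
    spliced = splice_out(cds, offset, exitron.length)

    def clean(p: str) -> str:
        i = p.find("*")
        return p if i == -1 else p[:i]

    return clean(translate(cds)), clean(translate(spliced))
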