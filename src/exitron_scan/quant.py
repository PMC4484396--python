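"""PSI quantification and differential exitron splicing.

PSI (percent spliced in) here measures exitron *inclusion* — the share of
transcripts retaining the exitron — so a high PSI means the full-length,
exitron-containing isoform dominates.  Inclusion evidence is the mean
per-base coverage over the first and last ``window`` intronic bases (reads
there can only come from the unspliced isoform, because exclusion reads jump
the interval); exclusion evidence is the junction read count of the exact
exitron interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .gio import CoverageTrack


@dataclass(frozen=True)
class EvidenceCounts:
    exitron_id: str
    sample: str
    inclusion: float
    exclusion: int

    def __post_init__(self):
        if self.inclusion < 0 or self.exclusion < 0:
            raise ValueError("evidence counts must be non-negative")


@dataclass(frozen=True)
class PsiRecord:
    exitron_id: str
    sample: str
    psi: float | None
    informative: bool


@dataclass(frozen=True)
class DifferentialResult:
    exitron_id: str
    psi_by_sample: dict
    delta_psi: float
    differential: bool
    detected_in: tuple[str, ...]


def count_evidence(exitron_interval: tuple[str, int, int],
                   junctions: pd.DataFrame, coverage: CoverageTrack,
                   sample: str, window: int = 10) -> EvidenceCounts:
    """Inclusion/exclusion evidence for one exitron in one sample.

    ``exitron_interval`` may be a 3-tuple ``(contig, start, end)`` or any
    object with an ``interval`` attribute and an ``id``.
    """
    if hasattr(exitron_interval, "interval"):
        xid = getattr(exitron_interval, "id", "")
        contig, start, end = exitron_interval.interval
    else:
        contig, start, end = exitron_interval
        xid = f"{contig}:{start}-{end}"
    length = end - start
    if window > length // 2:
        warnings.warn(f"window {window} > half exitron length {length}; shrunk")
        window = max(1, length // 2)
    hit = junctions[(junctions["contig"] == contig) &
                    (junctions["start"] == start) &
                    (junctions["end"] == end)]
    exclusion = int(hit["read_count"].sum()) if len(hit) else 0
    incl5 = coverage.mean(contig, start, start + window)
    incl3 = coverage.mean(contig, end - window, end)
    return EvidenceCounts(exitron_id=xid, sample=sample,
                          inclusion=(incl5 + incl3) / 2.0, exclusion=exclusion)


def psi(counts: EvidenceCounts, min_total: float = 10.0) -> PsiRecord:
    """PSI = 100 * inclusion / (inclusion + exclusion).

    The record is non-informative (psi ``None``) when total evidence falls
    below ``min_total``.
    """
    total = counts.inclusion + counts.exclusion
    if total <= 0:
        return PsiRecord(counts.exitron_id, counts.sample, None, False)
    value = 100.0 * counts.inclusion / total
    return PsiRecord(counts.exitron_id, counts.sample, value,
                     informative=total >= min_total)


def differential(records: Sequence[PsiRecord], threshold: float = 15.0,
                 detect_max: float = 90.0) -> DifferentialResult:
    """Cross-sample differential call for one exitron.

    ``delta_psi`` is max - min PSI over informative samples; the event is
    differential when that reaches ``threshold`` with at least two
    informative samples.  ``detected_in`` lists samples with PSI <=
    ``detect_max`` (the spliced isoform is visibly used there).
    """
    if not records:
        raise ValueError("no PSI records")
    xid = records[0].exitron_id
    if any(r.exitron_id != xid for r in records):
        raise ValueError("records belong to different exitrons")
    informative = {r.sample: r.psi for r in records if r.informative}
    psi_by_sample = {r.sample: r.psi for r in records}
    if len(informative) >= 2:
        values = list(informative.values())
        delta = max(values) - min(values)
    else:
        delta = 0.0
    detected = tuple(sorted(s for s, v in informative.items()
                            if v is not None and v <= detect_max))
    return DifferentialResult(
        exitron_id=xid, psi_by_sample=psi_by_sample, delta_psi=delta,
        differential=delta >= threshold and len(informative) >= 2,
        detected_in=detected,
    )


def psi_matrix(exitrons, junction_tables: Mapping[str, pd.DataFrame],
               coverage_tracks: Mapping[str, CoverageTrack],
               window: int = 10, min_total: float = 10.0) -> pd.DataFrame:
    """Tidy exitron x sample PSI table (long format)."""
    rows = []
    for x in exitrons:
        for s in sorted(junction_tables):
            c = count_evidence(x, junction_tables[s], coverage_tracks[s],
                               sample=s, window=window)
            r = psi(c, min_total=min_total)
            rows.append((r.exitron_id, s, r.psi, r.informative,
                         c.inclusion, c.exclusion))
    return pd.DataFrame(rows, columns=["exitron_id", "sample", "psi",
                                       "informative", "inclusion",
                                       "exclusion"])


def differential_table(psi_long: pd.DataFrame, threshold: float = 15.0,
                       detect_max: float = 90.0) -> pd.DataFrame:
    """Apply :func:`differential` per exitron over a long-format PSI table."""
    rows = []
    for xid, grp in psi_long.groupby("exitron_id", sort=True):
        records = [PsiRecord(xid, r.sample, r.psi if pd.notna(r.psi) else None,
                             bool(r.informative))
                   for r in grp.itertuples()]
        d = differential(records, threshold=threshold, detect_max=detect_max)
        rows.append((xid, d.delta_psi, d.differential,
                     ",".join(d.detected_in)))
    return pd.DataFrame(rows, columns=["exitron_id", "delta_psi",
                                       "differential", "detected_in"])
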