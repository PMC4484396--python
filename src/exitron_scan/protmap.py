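"""Protein-coordinate mapping and protein-feature overlap statistics.

Exitrons are mapped to 1-based inclusive amino-acid intervals of their host
protein and intersected with precomputed feature tables (PFAM-style domains,
disordered regions, short linear motifs, PTM sites — the predictors that
produce such tables run upstream of this package).  Enrichment between
exitron-coded and exon-coded residues uses per-residue rates (feature-covered
aa / total aa), which is the length-corrected unit, with an exact binomial
tail p-value and BH correction across feature kinds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gio import TranscriptModel
from .seqstats import bh_adjust

FEATURE_KINDS = ("domain", "disorder", "slim", "ptm")

FEATURE_COLUMNS = ["protein_id", "kind", "label", "start_aa", "end_aa",
                   "ptm_type"]


@dataclass(frozen=True)
class ProteinInterval:
    protein_id: str
    start_aa: int   # 1-based inclusive
    end_aa: int
    source_id: str = ""
    partial_start: bool = False   # 5' exitron boundary splits a codon
    partial_end: bool = False

    def __post_init__(self):
        if not 1 <= self.start_aa <= self.end_aa:
            raise ValueError("need 1 <= start_aa <= end_aa")

    @property
    def length_aa(self) -> int:
        return self.end_aa - self.start_aa + 1


@dataclass(frozen=True)
class FeatureRecord:
    protein_id: str
    kind: str
    label: str
    start_aa: int
    end_aa: int
    ptm_type: str = ""

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not 1 <= self.start_aa <= self.end_aa:
            raise ValueError("bad feature coordinates")


@dataclass(frozen=True)
class OverlapRow:
    interval: ProteinInterval
    feature: FeatureRecord
    overlap_aa: int
    boundary_coincident: bool = False


@dataclass(frozen=True)
class EnrichmentResult:
    kind: str
    target_rate: float
    background_rate: float
    fold: float
    p_value: float
    target_aa: int
    background_aa: int
    rate_floored: bool = False


def genomic_to_protein(exitron, model: TranscriptModel) -> ProteinInterval:
    """Amino-acid interval covering every codon with >= 1 exitron nucleotide.

    Partial-codon flags mark boundaries that split codons; both are False
    for frame-aligned EIx3 exitrons.
    """
    five_prime = exitron.start if model.strand == "+" else exitron.end - 1
    offset = model.cds_offset_of(five_prime)
    length = exitron.end - exitron.start
    start_aa = offset // 3 + 1
    end_aa = (offset + length - 1) // 3 + 1
    return ProteinInterval(
        protein_id=model.transcript_id, start_aa=start_aa, end_aa=end_aa,
        source_id=getattr(exitron, "id", ""),
        partial_start=offset % 3 != 0, partial_end=(offset + length) % 3 != 0,
    )


def overlap_features(interval: ProteinInterval,
                     features: Sequence[FeatureRecord]) -> list[OverlapRow]:
    """Every feature of the same protein sharing >= 1 aa with the interval."""
    rows = []
    for f in features:
        if f.protein_id != interval.protein_id:
            continue
        lo = max(interval.start_aa, f.start_aa)
        hi = min(interval.end_aa, f.end_aa)
        if lo <= hi:
            rows.append(OverlapRow(interval=interval, feature=f,
                                   overlap_aa=hi - lo + 1))
    return rows


def boundary_coincidence(interval: ProteinInterval,
                         domains: Sequence[FeatureRecord],
                         tol_aa: int = 5) -> tuple[bool, bool]:
    """Whether each exitron boundary lies within ``tol_aa`` of a domain border.

    Only ``domain`` features of the host protein are considered.
    """
    borders = [b for f in domains
               if f.protein_id == interval.protein_id and f.kind == "domain"
               for b in (f.start_aa, f.end_aa)]
    start_hit = any(abs(interval.start_aa - b) <= tol_aa for b in borders)
    end_hit = any(abs(interval.end_aa - b) <= tol_aa for b in borders)
    return start_hit, end_hit


def _covered_aa(intervals: Sequence[ProteinInterval],
                features: Sequence[FeatureRecord], kind: str) -> tuple[int, int]:
    """(feature-covered aa, total aa) over a set of protein intervals."""
    by_protein: dict[str, list[FeatureRecord]] = {}
    for f in features:
        if f.kind == kind:
            by_protein.setdefault(f.protein_id, []).append(f)
    covered = total = 0
    for iv in intervals:
        total += iv.length_aa
        feats = by_protein.get(iv.protein_id, ())
        if not feats:
            continue
        mask = np.zeros(iv.length_aa, dtype=bool)
        for f in feats:
            lo = max(iv.start_aa, f.start_aa) - iv.start_aa
            hi = min(iv.end_aa, f.end_aa) - iv.start_aa
            if lo <= hi:
                mask[lo:hi + 1] = True
        covered += int(mask.sum())
    return covered, total


def feature_enrichment(target: Sequence[ProteinInterval],
                       background: Sequence[ProteinInterval],
                       features: Sequence[FeatureRecord],
                       kind: str) -> EnrichmentResult:
    """Per-residue enrichment of one feature kind in target vs background.

    The null rate is the background per-residue coverage; the target covered
    residue count is tested with an exact binomial (upper tail when the
    target rate exceeds the background, lower tail otherwise would be read
    off the fold < 1).
    """
    if not target or not background:
        raise ValueError("target and background must be non-empty")
    t_cov, t_tot = _covered_aa(target, features, kind)
    b_cov, b_tot = _covered_aa(background, features, kind)
    floored = False
    q = b_cov / b_tot
    if q == 0:
        q = 1.0 / (2 * b_tot)
        floored = True
    p = stats.binomtest(t_cov, t_tot, min(q, 1.0),
                        alternative="greater").pvalue
    t_rate = t_cov / t_tot
    return EnrichmentResult(kind=kind, target_rate=t_rate,
                            background_rate=b_cov / b_tot, fold=t_rate / q,
                            p_value=float(p), target_aa=t_tot,
                            background_aa=b_tot, rate_floored=floored)


def enrichment_table(target: Sequence[ProteinInterval],
                     background: Sequence[ProteinInterval],
                     features: Sequence[FeatureRecord],
                     kinds: Sequence[str] = FEATURE_KINDS) -> pd.DataFrame:
    """Run :func:`feature_enrichment` per kind and BH-adjust across kinds."""
    present = [k for k in kinds
               if any(f.kind == k for f in features)]
    results = [feature_enrichment(target, background, features, k)
               for k in present]
    df = pd.DataFrame([{
        "kind": r.kind, "target_rate": r.target_rate,
        "background_rate": r.background_rate, "fold": r.fold,
        "p_value": r.p_value, "target_aa": r.target_aa,
        "background_aa": r.background_aa,
    } for r in results])
    if len(df):
        df["q_value"] = bh_adjust(df["p_value"].tolist())
    return df


def exon_background_intervals(models: Sequence[TranscriptModel],
                              exclude: Mapping[str, ProteinInterval] | Sequence[ProteinInterval] = (),
                              ) -> list[ProteinInterval]:
    """Whole-protein intervals (minus nothing) as a simple exon-derived
    background; exitron-coded spans can be excluded by splitting around them."""
    excl_by_protein: dict[str, list[ProteinInterval]] = {}
    seq = exclude.values() if isinstance(exclude, Mapping) else exclude
    for iv in seq:
        excl_by_protein.setdefault(iv.protein_id, []).append(iv)
    out = []
    for m in models:
        n_aa = m.cds_length // 3 - 1  # exclude the stop codon
        if n_aa < 1:
            continue
        pieces = [(1, n_aa)]
        for iv in sorted(excl_by_protein.get(m.transcript_id, []),
                         key=lambda iv: iv.start_aa):
            new = []
            for lo, hi in pieces:
                if iv.end_aa < lo or iv.start_aa > hi:
                    new.append((lo, hi))
                    continue
                if lo < iv.start_aa:
                    new.append((lo, iv.start_aa - 1))
                if iv.end_aa < hi:
                    new.append((iv.end_aa + 1, hi))
            pieces = new
        for lo, hi in pieces:
            out.append(ProteinInterval(protein_id=m.transcript_id,
                                       start_aa=lo, end_aa=hi,
                                       source_id="exon_background"))
    return out


def read_features(path: str | Path) -> list[FeatureRecord]:
    """Read a feature TSV (protein_id, kind, label, start_aa, end_aa, ptm_type)."""
    df = pd.read_csv(path, sep="\t", dtype={"ptm_type": str},
                     keep_default_na=False)
    missing = set(FEATURE_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    if "ptm_type" not in df.columns:
        df["ptm_type"] = ""
    return [FeatureRecord(r.protein_id, r.kind, r.label, int(r.start_aa),
                          int(r.end_aa), r.ptm_type)
            for r in df.itertuples()]


def features_from_frame(df: pd.DataFrame) -> list[FeatureRecord]:
    return [FeatureRecord(r.protein_id, r.kind, r.label, int(r.start_aa),
                          int(r.end_aa), str(r.ptm_type))
            for r in df.itertuples()]
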