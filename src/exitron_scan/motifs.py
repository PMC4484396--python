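"""Motif scanning and enrichment in exitron vs background sequence sets.

Motifs are user-supplied (e.g. experimentally derived RBM5/SUA binding
sites) as IUPAC consensus strings or position weight matrices with a score
threshold.  Scanning is sense-strand only by default: exitrons are
transcribed, mRNA-resident elements.  Enrichment uses a per-position
Bernoulli null — the background hit rate per scannable position — and an
exact binomial upper-tail p-value for the target hit count; a per-sequence
(>= 1 hit) mode is available as an alternative unit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


@dataclass(frozen=True)
class MotifModel:
    """IUPAC consensus or PWM motif; PWM hits require score >= threshold*max."""

    name: str
    iupac: str | None = None
    pwm: np.ndarray | None = None   # (W, 4) additive scores
    threshold: float = 0.8

    def __post_init__(self):
        if (self.iupac is None) == (self.pwm is None):
            raise ValueError("provide exactly one of iupac or pwm")
        if self.iupac is not None:
            if not self.iupac:
                raise ValueError("empty motif")
            bad = set(self.iupac.upper()) - set(IUPAC)
            if bad:
                raise ValueError(f"invalid IUPAC characters: {sorted(bad)}")
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")

    @property
    def width(self) -> int:
        return len(self.iupac) if self.iupac is not None else len(self.pwm)

    def matches(self, window: str) -> bool:
        window = window.upper()
        if self.iupac is not None:
            return all(b in IUPAC[c]
                       for b, c in zip(window, self.iupac.upper()))
        if any(b not in _BASE_INDEX for b in window):
            return False
        score = sum(self.pwm[i, _BASE_INDEX[b]] for i, b in enumerate(window))
        max_score = self.pwm.max(axis=1).sum()
        return score >= self.threshold * max_score


@dataclass(frozen=True)
class MotifEnrichmentResult:
    motif: str
    target_hits: int
    target_positions: int
    background_hits: int
    background_positions: int
    fold_enrichment: float
    p_value: float
    background_rate_floored: bool = False


def scan(sequences: Mapping[str, str], motif: MotifModel) -> pd.DataFrame:
    """All match start offsets of ``motif`` on the sense strand.

    Returns a table (sequence_id, offset, strand, match); every distinct
    start position that matches is reported.
    """
    if not sequences:
        raise ValueError("no sequences to scan")
    w = motif.width
    rows = []
    for sid in sorted(sequences):
        seq = sequences[sid].upper()
        for i in range(0, len(seq) - w + 1):
            window = seq[i:i + w]
            if motif.matches(window):
                rows.append((sid, i, "+", window))
    return pd.DataFrame(rows, columns=["sequence_id", "offset", "strand",
                                       "match"])


def scannable_positions(sequences: Mapping[str, str], width: int) -> int:
    return sum(max(0, len(s) - width + 1) for s in sequences.values())


def enrichment(target: Mapping[str, str], background: Mapping[str, str],
               motif: MotifModel, unit: str = "position"
               ) -> MotifEnrichmentResult:
    """Binomial enrichment of motif hits in target vs background sequences.

    ``unit="position"``: the null hit probability per scannable position is
    estimated from the background, and the target hit count is tested
    against Binomial(target positions, q) (upper tail).  ``unit="sequence"``
    tests the count of sequences with >= 1 hit instead.
    """
    if not target or not background:
        raise ValueError("target and background must be non-empty")
    w = motif.width
    t_hits_df = scan(target, motif)
    b_hits_df = scan(background, motif)
    if unit == "position":
        t_hits = len(t_hits_df)
        b_hits = len(b_hits_df)
        t_n = scannable_positions(target, w)
        b_n = scannable_positions(background, w)
    elif unit == "sequence":
        t_hits = t_hits_df["sequence_id"].nunique()
        b_hits = b_hits_df["sequence_id"].nunique()
        t_n = len(target)
        b_n = len(background)
    else:
        raise ValueError(f"unknown unit {unit!r}")
    if t_n == 0 or b_n == 0:
        raise ValueError("no scannable positions (motif longer than sequences?)")
    floored = False
    q = b_hits / b_n
    if q == 0:
        q = 1.0 / (2 * b_n)
        floored = True
    p = stats.binomtest(t_hits, t_n, min(q, 1.0), alternative="greater").pvalue
    t_rate = t_hits / t_n
    fold = t_rate / q if q > 0 else np.inf
    return MotifEnrichmentResult(
        motif=motif.name, target_hits=t_hits, target_positions=t_n,
        background_hits=b_hits, background_positions=b_n,
        fold_enrichment=fold, p_value=float(p),
        background_rate_floored=floored,
    )


def read_motifs(path: str | Path) -> list[MotifModel]:
    """Read motifs from a simple text format.

    Each motif is either one line ``name<TAB>IUPAC`` or a PWM block::

        >name threshold=0.8
        A C G T      (one row of 4 scores per position)
        ...
    """
    motifs: list[MotifModel] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line or line.startswith("#"):
            i += 1
            continue
        if line.startswith(">"):
            header = line[1:].split()
            name = header[0]
            threshold = 0.8
            for tok in header[1:]:
                if tok.startswith("threshold="):
                    threshold = float(tok.split("=", 1)[1])
            i += 1
            rows = []
            while i < len(lines):
                parts = lines[i].split()
                if len(parts) != 4 or lines[i].startswith(">"):
                    break
                try:
                    rows.append([float(x) for x in parts])
                except ValueError:
                    break
                i += 1
            if not rows:
                raise ValueError(f"PWM block for {name} has no rows")
            motifs.append(MotifModel(name=name, pwm=np.array(rows),
                                     threshold=threshold))
        else:
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ValueError(f"bad motif line: {line!r}")
            motifs.append(MotifModel(name=parts[0], iupac=parts[1]))
            i += 1
    return motifs
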