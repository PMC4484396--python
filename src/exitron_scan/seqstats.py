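"""Sequence-feature statistics and splice-site models.

Covers the descriptive statistics that separate exitrons from introns and
exons (GC content, lengths, the fraction of 3n events), additive log-odds
position weight matrices (PWMs) for donor and acceptor splice sites trained
on annotated constitutive introns, SNP impact on splice-signal strength,
codon-position tallies of coding variants, and the two workhorse tests
(Mann-Whitney-Wilcoxon for distribution shifts, exact binomial for
enrichment counts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gio import GenomeSequence, TranscriptModel, Variant

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# window geometry relative to the splice site, in transcription orientation:
# donor covers 3 exonic + 10 intronic bases, acceptor 14 intronic + 3 exonic
DONOR_WINDOW = (-3, 10)
ACCEPTOR_WINDOW = (-14, 3)


# ---------------------------------------------------------------------------
# elementary sequence statistics
# ---------------------------------------------------------------------------

def gc_content(sequence: str) -> float:
    """(G+C) / unambiguous length; ambiguous bases excluded from both sides."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    counts = {b: seq.count(b) for b in BASES}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("sequence has no unambiguous bases")
    return (counts["G"] + counts["C"]) / denom


STOP_CODONS = {"TAA", "TAG", "TGA"}


def _has_stop(seq: str, frame: int) -> bool:
    return any(seq[i:i + 3] in STOP_CODONS
               for i in range(frame, len(seq) - 2, 3))


def fraction_3n(lengths: Sequence[int],
                sequences: Sequence[str] | None = None,
                require_stop_free: bool = False,
                frame: str | int = "any") -> tuple[float, int, int]:
    """Fraction of intervals whose length is a multiple of 3.

    When ``require_stop_free`` is set (and sequences are supplied), a 3n
    member only counts if it lacks in-frame stop codons: ``frame`` may be a
    fixed frame offset (0/1/2) or ``"any"`` (stop-free in at least one of
    the three frames — the convention used when comparing against introns,
    whose reading frame is undefined).

    Returns ``(fraction, n_3n, n_total)``.
    """
    lengths = list(lengths)
    if not lengths or any(l < 1 for l in lengths):
        raise ValueError("lengths must be a non-empty list of positive ints")
    n_total = len(lengths)
    n_3n = 0
    for i, l in enumerate(lengths):
        if l % 3 != 0:
            continue
        if require_stop_free:
            if sequences is None:
                raise ValueError("sequences required for the stop-free rule")
            seq = sequences[i].upper()
            if frame == "any":
                ok = any(not _has_stop(seq, f) for f in range(3))
            else:
                ok = not _has_stop(seq, int(frame))
            if not ok:
                continue
        n_3n += 1
    return n_3n / n_total, n_3n, n_total


# ---------------------------------------------------------------------------
# splice-site PWMs
# ---------------------------------------------------------------------------

@dataclass
class Pwm:
    """Additive log2-odds splice-site model over a fixed window.

    ``offsets`` label the window positions relative to the splice site
    (negative = exonic side for donors, intronic side for acceptors, see
    :data:`DONOR_WINDOW` / :data:`ACCEPTOR_WINDOW`).  ``log_odds`` is a
    (window x 4) matrix in bits against ``background`` base frequencies.
    """

    site_kind: str                  # "donor" | "acceptor"
    offsets: tuple[int, ...]
    counts: np.ndarray              # (W, 4) training counts
    log_odds: np.ndarray            # (W, 4) bits
    background: np.ndarray          # (4,)
    pseudocount: float

    @property
    def width(self) -> int:
        return len(self.offsets)

    @property
    def probabilities(self) -> np.ndarray:
        p = self.counts + self.pseudocount
        return p / p.sum(axis=1, keepdims=True)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.log_odds.argmax(axis=1))

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=1).sum())

    def score(self, window_seq: str) -> float:
        """Summed per-position log-odds of a window sequence, in bits."""
        if len(window_seq) != self.width:
            raise ValueError(
                f"window length {len(window_seq)} != PWM width {self.width}")
        s = 0.0
        for i, b in enumerate(window_seq.upper()):
            if b not in _BASE_INDEX:
                raise ValueError(f"ambiguous base {b!r} in window")
            s += self.log_odds[i, _BASE_INDEX[b]]
        return float(s)

    def relative(self, score: float) -> float:
        """Min-max normalised score in [0, 1] (1 = best attainable window)."""
        rng = self.max_score - self.min_score
        if rng == 0:
            return 1.0
        return (score - self.min_score) / rng

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.log_odds, columns=list(BASES))
        df.insert(0, "offset", self.offsets)
        return df


@dataclass(frozen=True)
class SpliceSiteScore:
    exitron_id: str
    donor_score: float
    acceptor_score: float
    donor_relative: float
    acceptor_relative: float
    branch_point_score: float | None = None


@dataclass(frozen=True)
class SnpImpactRecord:
    variant: Variant
    site_kind: str
    offset: int | None
    score_ref: float
    score_alt: float
    delta: float
    direction: str    # strengthen | weaken | neutral | outside_signal


@dataclass(frozen=True)
class CodonPositionTally:
    n1: int
    n2: int
    n3: int
    statistic: float
    p_value: float

    @property
    def total(self) -> int:
        return self.n1 + self.n2 + self.n3


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    method: str


def _site_window_coords(site_kind: str, intron_start: int, intron_end: int,
                        strand: str) -> tuple[int, int]:
    """Genomic window of a donor/acceptor site of the intron ``[start, end)``."""
    d_lo, d_hi = DONOR_WINDOW
    a_lo, a_hi = ACCEPTOR_WINDOW
    if strand == "+":
        if site_kind == "donor":
            return intron_start + d_lo, intron_start + d_hi
        return intron_end + a_lo, intron_end + a_hi
    if site_kind == "donor":
        return intron_end - d_hi, intron_end - d_lo
    return intron_start - a_hi, intron_start - a_lo


def site_window_seq(genome: GenomeSequence, contig: str, intron_start: int,
                    intron_end: int, strand: str, site_kind: str) -> str:
    s, e = _site_window_coords(site_kind, intron_start, intron_end, strand)
    return genome.fetch(contig, s, e, strand)


def build_pwm(introns: Sequence[tuple[str, int, int, str]],
              genome: GenomeSequence, site_kind: str,
              pseudocount: float = 1.0,
              background: str | np.ndarray = "training") -> Pwm:
    """Train a donor or acceptor PWM on annotated intron coordinates.

    ``introns`` are ``(contig, start, end, strand)`` tuples; windows falling
    outside contig bounds or containing ambiguous bases are skipped with a
    warning.  ``background`` is either ``"training"`` (marginal base
    frequencies of the training windows), ``"uniform"``, or an explicit
    length-4 frequency vector.
    """
    if site_kind not in ("donor", "acceptor"):
        raise ValueError(f"unknown site kind {site_kind!r}")
    lo, hi = DONOR_WINDOW if site_kind == "donor" else ACCEPTOR_WINDOW
    width = hi - lo
    counts = np.zeros((width, 4))
    used = 0
    for contig, s, e, strand in introns:
        try:
            seq = site_window_seq(genome, contig, s, e, strand, site_kind)
        except (IndexError, KeyError):
            warnings.warn(f"site window out of bounds for {contig}:{s}-{e}; skipped")
            continue
        if any(b not in _BASE_INDEX for b in seq):
            warnings.warn(f"ambiguous base in training window {contig}:{s}-{e}")
            continue
        for i, b in enumerate(seq):
            counts[i, _BASE_INDEX[b]] += 1
        used += 1
    if used == 0:
        raise ValueError("no usable training sites")
    if used < 10:
        warnings.warn(f"only {used} training sites; PWM will be noisy")
    if isinstance(background, str):
        if background == "training":
            bg = counts.sum(axis=0)
            bg = bg / bg.sum()
        elif background == "uniform":
            bg = np.full(4, 0.25)
        else:
            raise ValueError(f"unknown background {background!r}")
    else:
        bg = np.asarray(background, dtype=float)
        bg = bg / bg.sum()
    probs = (counts + pseudocount) / (counts + pseudocount).sum(axis=1,
                                                                keepdims=True)
    log_odds = np.log2(probs / bg)
    offsets = tuple(o if o < 0 else o + 1 for o in range(lo, hi))
    return Pwm(site_kind=site_kind, offsets=offsets, counts=counts,
               log_odds=log_odds, background=bg, pseudocount=pseudocount)


def score_site(pwm: Pwm, genome: GenomeSequence, contig: str,
               intron_start: int, intron_end: int, strand: str) -> float:
    """Score one splice site of the intron interval with a trained PWM."""
    seq = site_window_seq(genome, contig, intron_start, intron_end, strand,
                          pwm.site_kind)
    return pwm.score(seq)


BRANCH_CONSENSUS = "CTRAY"
_IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT", "S": "CG",
    "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT", "H": "ACT",
    "V": "ACG", "N": "ACGT",
}


def branch_point_score(genome: GenomeSequence, contig: str, intron_start: int,
                       intron_end: int, strand: str,
                       search_window: tuple[int, int] = (-50, -10)
                       ) -> tuple[float, int]:
    """Best CTRAY consensus match upstream of the acceptor (descriptive only).

    Returns ``(fraction of consensus positions matched, offset of the match
    relative to the acceptor site)``; never used as a hard filter.
    """
    lo, hi = search_window
    if strand == "+":
        s, e = intron_end + lo, intron_end + hi
    else:
        s, e = intron_start - hi, intron_start - lo
    s = max(s, 0)
    seq = genome.fetch(contig, s, e, strand)
    best, best_off = 0.0, lo
    w = len(BRANCH_CONSENSUS)
    for i in range(0, len(seq) - w + 1):
        m = sum(seq[i + j] in _IUPAC_SETS[c]
                for j, c in enumerate(BRANCH_CONSENSUS)) / w
        if m > best:
            best, best_off = m, lo + i
    return best, best_off


def score_exitron_sites(exitron, pwm_donor: Pwm, pwm_acceptor: Pwm,
                        genome: GenomeSequence,
                        with_branch_point: bool = True) -> SpliceSiteScore:
    d = score_site(pwm_donor, genome, exitron.contig, exitron.start,
                   exitron.end, exitron.strand)
    a = score_site(pwm_acceptor, genome, exitron.contig, exitron.start,
                   exitron.end, exitron.strand)
    bp = None
    if with_branch_point:
        bp, _ = branch_point_score(genome, exitron.contig, exitron.start,
                                   exitron.end, exitron.strand)
    return SpliceSiteScore(
        exitron_id=getattr(exitron, "id", ""), donor_score=d,
        acceptor_score=a, donor_relative=pwm_donor.relative(d),
        acceptor_relative=pwm_acceptor.relative(a), branch_point_score=bp)


# ---------------------------------------------------------------------------
# SNP impact on splice signals
# ---------------------------------------------------------------------------

def snp_splice_impact(pwm: Pwm, variant: Variant, intron_start: int,
                      intron_end: int, strand: str,
                      tol: float = 0.1) -> SnpImpactRecord:
    """Delta PWM score of a SNP inside a splice-signal window.

    The delta equals the column log-odds difference alt - ref at the
    variant's window offset, which is exactly the full-rescore difference
    because the model is additive.  Variants outside the window are recorded
    with direction ``outside_signal``.
    """
    w_s, w_e = _site_window_coords(pwm.site_kind, intron_start, intron_end,
                                   strand)
    if not (w_s <= variant.pos < w_e):
        return SnpImpactRecord(variant, pwm.site_kind, None, 0.0, 0.0, 0.0,
                               "outside_signal")
    if strand == "+":
        idx = variant.pos - w_s
        ref, alt = variant.ref, variant.alt
    else:
        idx = w_e - 1 - variant.pos
        ref, alt = _COMPLEMENT[variant.ref], _COMPLEMENT[variant.alt]
    col = pwm.log_odds[idx]
    score_ref = float(col[_BASE_INDEX[ref]])
    score_alt = float(col[_BASE_INDEX[alt]])
    delta = score_alt - score_ref
    if abs(delta) < tol:
        direction = "neutral"
    else:
        direction = "strengthen" if delta > 0 else "weaken"
    return SnpImpactRecord(variant, pwm.site_kind, pwm.offsets[idx],
                           score_ref, score_alt, delta, direction)


# ---------------------------------------------------------------------------
# codon positions of coding SNPs
# ---------------------------------------------------------------------------

def snp_codon_positions(variants: Sequence[Variant],
                        host_models: Mapping[str, TranscriptModel] | Sequence,
                        variant_hosts: Sequence[str] | None = None
                        ) -> CodonPositionTally:
    """Tally codon positions (1/2/3) of SNPs inside coding sequence.

    ``host_models`` maps transcript_id -> model and ``variant_hosts`` gives
    the host transcript per variant; alternatively pass a sequence of models
    and hosts are resolved by coordinate containment.  Codon position is
    strand-aware: position = (CDS offset mod 3) + 1.  The tally is tested
    against the uniform (1/3, 1/3, 1/3) null with a chi-square
    goodness-of-fit test.
    """
    if variant_hosts is None:
        models = list(host_models.values()) if isinstance(host_models, Mapping) \
            else list(host_models)

        def find(v: Variant) -> TranscriptModel | None:
            for m in models:
                if m.contig != v.contig:
                    continue
                for s, e in m.cds_genomic:
                    if s <= v.pos < e:
                        return m
            return None

        resolved = [(v, find(v)) for v in variants]
    else:
        resolved = [(v, host_models[h]) for v, h in zip(variants, variant_hosts)]

    counts = [0, 0, 0]
    for v, m in resolved:
        if m is None:
            raise ValueError(f"variant at {v.contig}:{v.pos + 1} not in any CDS")
        off = m.cds_offset_of(v.pos)
        counts[off % 3] += 1
    total = sum(counts)
    if total == 0:
        raise ValueError("no variants to tally")
    chi = stats.chisquare(counts)
    return CodonPositionTally(n1=counts[0], n2=counts[1], n3=counts[2],
                              statistic=float(chi.statistic),
                              p_value=float(chi.pvalue))


# ---------------------------------------------------------------------------
# workhorse tests
# ---------------------------------------------------------------------------

def mww_test(sample_a: Sequence[float], sample_b: Sequence[float],
             alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney-Wilcoxon rank-sum test."""
    a, b = list(sample_a), list(sample_b)
    if not a or not b:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative=alternative)
    return TestResult(statistic=float(res.statistic),
                      p_value=float(res.pvalue), n_a=len(a), n_b=len(b),
                      method="mann-whitney-wilcoxon")


def binomial_test(k: int, n: int, p0: float,
                  alternative: str = "two-sided") -> TestResult:
    """Exact binomial test by tail summation."""
    if not 0 <= k <= n or n < 1:
        raise ValueError("need 0 <= k <= n, n >= 1")
    res = stats.binomtest(k, n, p0, alternative=alternative)
    return TestResult(statistic=float(k), p_value=float(res.pvalue),
                      n_a=n, n_b=0, method="binomial")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg FDR adjustment."""
    from statsmodels.stats.multitest import multipletests

    if len(p_values) == 0:
        return np.array([])
    return multipletests(list(p_values), method="fdr_bh")[1]
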