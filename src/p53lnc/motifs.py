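"""PWM and p53 response-element scanning, and motif enrichment.

The canonical p53RE is a dimer of two RRRCWWGYYY half-sites separated by
a 0–13 nt spacer (R = A/G, Y = C/T, W = A/T). The dimeric pattern is
palindromic under reverse complement (R↔Y, C↔G, W↔W with the site
reversed), so a forward-strand scan already covers both strands; hits
are therefore reported once, on '+'.

PWM scanning uses log-odds scores in bits against a background
distribution (uniform unless supplied); N bases contribute zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import IO, Callable, Iterable, Sequence

import numpy as np
from scipy import stats

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

HALF_SITE = "RRRCWWGYYY"
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "W": "AT", "S": "CG", "K": "GT", "M": "AC",
    "N": "ACGT",
}


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    offset: int  # 0-based start of the full match
    strand: str
    score: float  # log-odds in bits (PWM mode); match span for consensus mode
    mismatches: int | None = None  # consensus mode only
    spacer: int | None = None  # p53RE mode only


@dataclass
class Pwm:
    """Position weight matrix (probabilities) with a background model."""

    matrix: np.ndarray  # shape (width, 4), rows sum to 1, entries > 0
    background: np.ndarray | None = None  # shape (4,), sums to 1

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (width, 4)")
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM columns must each sum to 1")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-6):
            raise ValueError("background must sum to 1")
        if (self.matrix <= 0).any() or (self.background <= 0).any():
            raise ValueError("PWM entries must be strictly positive (use a pseudocount)")

    @property
    def width(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def log_odds(self) -> np.ndarray:
        """Per-position log2(p/background), shape (width, 4)."""
        return np.log2(self.matrix / self.background[None, :])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        pseudocount: float = 0.5,
        background: np.ndarray | None = None,
    ) -> "Pwm":
        counts = np.asarray(counts, dtype=float) + pseudocount
        return cls(counts / counts.sum(axis=1, keepdims=True), background)

    @classmethod
    def from_consensus(cls, consensus: str, match_prob: float = 0.997) -> "Pwm":
        """Degenerate-consensus PWM: matching bases share ``match_prob``."""
        rows = []
        for ch in consensus.upper():
            allowed = _IUPAC[ch]
            row = np.full(4, (1 - match_prob) / (4 - len(allowed)) if len(allowed) < 4 else 0.25)
            for b in allowed:
                row[_BASE_INDEX[b]] = match_prob / len(allowed)
            rows.append(row / row.sum())
        return cls(np.array(rows))

    @classmethod
    def from_meme_text(cls, handle: IO[str]) -> "Pwm":
        """Read the first motif from MEME minimal text format."""
        from Bio import motifs as bio_motifs

        records = bio_motifs.parse(handle, "minimal")
        motif = next(iter(records))
        counts = np.array(
            [[motif.counts[b][i] for b in "ACGT"] for i in range(motif.length)]
        )
        bg = None
        if motif.background:
            bg = np.array([motif.background[b] for b in "ACGT"])
        return cls.from_counts(counts, pseudocount=0.5, background=bg)


def _encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else -> -1."""
    s = seq.upper().replace("U", "T")
    return np.array([_BASE_INDEX.get(ch, -1) for ch in s], dtype=np.int64)


def scan_pwm(
    seq: str,
    pwm: Pwm,
    threshold: float,
    sequence_id: str = "",
) -> list[MotifHit]:
    """All windows on both strands scoring ≥ ``threshold`` bits.

    N positions contribute 0 to the log-odds sum. Reverse-strand hits
    are reported at the forward-coordinate offset of the window. Results
    are sorted by offset (then strand).
    """
    w = pwm.width
    if len(seq) < w:
        return []
    lo = pwm.log_odds
    hits: list[MotifHit] = []
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        codes = _encode(s)
        n = len(codes)
        # windowed sum of per-position log-odds; N (-1) scores 0
        contrib = np.zeros((n, w))
        for j in range(w):
            valid = codes[j : n - w + 1 + j] >= 0
            col = np.where(valid, lo[j, np.clip(codes[j : n - w + 1 + j], 0, 3)], 0.0)
            contrib[: n - w + 1, j] = col
        scores = contrib[: n - w + 1].sum(axis=1)
        for i in np.flatnonzero(scores >= threshold):
            offset = int(i) if strand == "+" else n - w - int(i)
            hits.append(MotifHit(sequence_id, offset, strand, float(scores[i])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def _mismatch_profile(seq_codes: np.ndarray, pattern: str) -> np.ndarray:
    """Mismatch counts of ``pattern`` (IUPAC) at every start offset."""
    n, w = len(seq_codes), len(pattern)
    if n < w:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n - w + 1, dtype=np.int64)
    for j, ch in enumerate(pattern):
        allowed = {_BASE_INDEX[b] for b in _IUPAC[ch]}
        window = seq_codes[j : n - w + 1 + j]
        match = np.isin(window, list(allowed))
        out += ~match
    return out


def p53re_scan(
    seq: str,
    max_mismatch: int = 2,
    spacer_range: Iterable[int] = range(0, 14),
    sequence_id: str = "",
) -> list[MotifHit]:
    """Dimeric p53RE matches: RRRCWWGYYY-N(s)-RRRCWWGYYY, total
    mismatches ≤ ``max_mismatch`` over the 20 informative positions.

    The pattern is strand-symmetric, so each genomic site is reported
    exactly once (strand '+'). Every qualifying (offset, spacer)
    combination is returned, sorted by offset then spacer; the hit score
    is the matched span in bp.
    """
    codes = _encode(seq)
    half = _mismatch_profile(codes, HALF_SITE)
    w = len(HALF_SITE)
    hits: list[MotifHit] = []
    for s in spacer_range:
        span = 2 * w + s
        if len(codes) < span:
            continue
        total = half[: len(codes) - span + 1] + half[w + s : len(codes) - w + 1]
        for i in np.flatnonzero(total <= max_mismatch):
            hits.append(
                MotifHit(
                    sequence_id,
                    int(i),
                    "+",
                    float(span),
                    mismatches=int(total[i]),
                    spacer=s,
                )
            )
    hits.sort(key=lambda h: (h.offset, h.spacer))
    return hits


@dataclass(frozen=True)
class EnrichmentResult:
    foreground_fraction: float
    background_fraction: float
    fold: float  # inf when background fraction is 0 and foreground > 0
    p_value: float  # one-sided Fisher exact
    n_foreground: int
    n_background: int


def motif_enrichment(
    foreground_seqs: Sequence[str],
    background_seqs: Sequence[str],
    scanner: Callable[..., list[MotifHit]],
    **scanner_params,
) -> EnrichmentResult:
    """Per-sequence hit indicator in each set; fold change of hit
    fractions and a one-sided Fisher exact p-value on the 2×2 table."""
    if not foreground_seqs or not background_seqs:
        raise ValueError("both sequence sets must be non-empty")
    f_hit = sum(1 for s in foreground_seqs if scanner(s, **scanner_params))
    b_hit = sum(1 for s in background_seqs if scanner(s, **scanner_params))
    nf, nb = len(foreground_seqs), len(background_seqs)
    ff, bf = f_hit / nf, b_hit / nb
    if bf == 0:
        fold = math.inf if ff > 0 else 1.0
    else:
        fold = ff / bf
    table = [[f_hit, nf - f_hit], [b_hit, nb - b_hit]]
    p = float(stats.fisher_exact(table, alternative="greater")[1])
    return EnrichmentResult(ff, bf, fold, p, nf, nb)
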