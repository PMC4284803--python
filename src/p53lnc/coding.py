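"""Coding-potential scoring for transcripts (CPAT-style).

Four sequence features — longest sense-strand ORF length and coverage,
the Fickett TESTCODE statistic, and a hexamer-usage log-likelihood
ratio — are combined by logistic regression into a coding probability.
Transcripts scoring at or above the decision cutoff (default 0.364, the
published human cutoff for this feature family) are flagged as likely
coding.

The Fickett statistic uses the classic published lookup tables: for each
base, a position parameter (asymmetry of occurrence across the three
codon positions) and a content parameter (overall fraction) are
discretised through 10-bin probability tables and combined in a weighted
sum. Scores above ~0.95 indicate coding, below ~0.74 noncoding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np

DEFAULT_CUTOFF = 0.364
DEFAULT_PSEUDOCOUNT = 1.0 / 4096.0
MIN_LNCRNA_LENGTH = 200  # nt; the lncRNA definition (> 200 nt)

_STOPS = {"TAA", "TAG", "TGA"}
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


# --- longest ORF -------------------------------------------------------


@dataclass(frozen=True)
class OrfResult:
    start: int  # 0-based nt offset of the ATG; -1 when no ORF
    length: int  # nt including the stop codon; multiple of 3
    coverage: float  # length / transcript length

    @property
    def frame(self) -> int:
        return self.start % 3 if self.start >= 0 else 0


def longest_orf(seq: str) -> OrfResult:
    """Longest ATG→stop reading frame on the sense strand.

    All three frames are scanned; the ORF length includes the stop
    codon. Codons containing N never match either ATG or a stop. Ties
    are broken toward the smallest start. Returns a zero result when no
    complete ORF exists.
    """
    s = _normalize(seq)
    n = len(s)
    best_start, best_len = -1, 0
    for frame in range(3):
        open_start = -1
        for i in range(frame, n - 2, 3):
            codon = s[i : i + 3]
            if open_start < 0:
                if codon == "ATG":
                    open_start = i
            elif codon in _STOPS:
                length = i + 3 - open_start
                if length > best_len or (length == best_len and open_start < best_start):
                    best_start, best_len = open_start, length
                open_start = -1
    if best_len == 0:
        return OrfResult(-1, 0, 0.0)
    return OrfResult(best_start, best_len, best_len / n)


# --- Fickett TESTCODE --------------------------------------------------

# 10-bin probability tables: row order A, C, G, T; bins indexed by the
# first threshold the parameter value reaches (descending thresholds).
_FICKETT_POSITION_PROB = {
    "A": (0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22),
    "C": (0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23),
    "G": (0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08),
    "T": (0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09),
}
_FICKETT_CONTENT_PROB = {
    "A": (0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21),
    "C": (0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31),
    "G": (0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29),
    "T": (0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58),
}
_FICKETT_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_FICKETT_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_POSITION_THRESHOLDS = (1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0)
_CONTENT_THRESHOLDS = (0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0)


def _lookup(value: float, thresholds: Sequence[float], probs: Sequence[float]) -> float:
    for t, p in zip(thresholds, probs):
        if value >= t:
            return p
    return probs[-1]


def fickett_score(seq: str, min_length: int = MIN_LNCRNA_LENGTH) -> float:
    """Fickett TESTCODE statistic from the published lookup tables.

    Deterministic weighted sum over the four bases of a position-bias
    term (max/min occupancy across codon positions) and a content term
    (base fraction). Sequences shorter than ``min_length`` are still
    scored; callers should treat those scores as low-confidence.
    Non-ACGT characters are ignored in the counts.
    """
    s = _normalize(seq)
    pos_counts = {b: [0, 0, 0] for b in "ACGT"}
    totals = {b: 0 for b in "ACGT"}
    for i, ch in enumerate(s):
        if ch in pos_counts:
            pos_counts[ch][i % 3] += 1
            totals[ch] += 1
    n_counted = sum(totals.values())
    score = 0.0
    for base in "ACGT":
        c = pos_counts[base]
        position_param = max(c) / (min(c) + 1)
        content_param = totals[base] / n_counted if n_counted else 0.0
        score += (
            _lookup(position_param, _POSITION_THRESHOLDS, _FICKETT_POSITION_PROB[base])
            * _FICKETT_POSITION_WEIGHT[base]
        )
        score += (
            _lookup(content_param, _CONTENT_THRESHOLDS, _FICKETT_CONTENT_PROB[base])
            * _FICKETT_CONTENT_WEIGHT[base]
        )
    return score


# --- hexamer usage bias ------------------------------------------------


def _hexamer_indices(seq: str, step: int, frame: int = 0) -> np.ndarray:
    """Indices (base-4 codes) of clean ACGT hexamers at the given step."""
    s = _normalize(seq)
    codes = np.array([_BASE_INDEX.get(ch, -1) for ch in s], dtype=np.int64)
    out = []
    for i in range(frame, len(s) - 5, step):
        window = codes[i : i + 6]
        if (window >= 0).all():
            out.append(int(window @ (4 ** np.arange(5, -1, -1))))
    return np.asarray(out, dtype=np.int64)


@dataclass
class HexamerTable:
    """Hexamer probabilities under coding and noncoding training sets."""

    coding: np.ndarray  # shape (4096,), sums to 1, all > 0
    noncoding: np.ndarray
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        assert self.coding.shape == (4096,) and self.noncoding.shape == (4096,)
        assert (self.coding > 0).all() and (self.noncoding > 0).all()


def train_hexamer_table(
    coding_seqs: Iterable[str],
    noncoding_seqs: Iterable[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> HexamerTable:
    """Count hexamers in-frame (step 3) for coding sequences and at every
    offset (step 1) for noncoding ones; add the pseudocount and
    normalise each table to a probability distribution."""

    def count(seqs: Iterable[str], step: int) -> np.ndarray:
        counts = np.zeros(4096, dtype=float)
        n_seqs = 0
        for seq in seqs:
            n_seqs += 1
            idx = _hexamer_indices(seq, step)
            if len(idx):
                np.add.at(counts, idx, 1.0)
        if n_seqs == 0:
            raise ValueError("hexamer training requires a non-empty sequence set")
        counts += pseudocount
        return counts / counts.sum()

    return HexamerTable(count(coding_seqs, 3), count(noncoding_seqs, 1), pseudocount)


def hexamer_llr(seq: str, table: HexamerTable) -> float:
    """Mean log(coding/noncoding) over step-3 hexamers in the longest-ORF
    frame (frame 0 when the sequence has no ORF). Sequences shorter than
    6 nt, or without a single clean hexamer, score 0."""
    if len(seq) < 6:
        return 0.0
    frame = longest_orf(seq).frame
    idx = _hexamer_indices(seq, step=3, frame=frame)
    if len(idx) == 0:
        return 0.0
    return float(np.mean(np.log(table.coding[idx] / table.noncoding[idx])))


# --- logistic combination ----------------------------------------------

FEATURE_NAMES = ("orf_length", "orf_coverage", "fickett", "hexamer_llr")


@dataclass
class CodingModel:
    """Logistic model over the four coding-potential features."""

    weights: dict[str, float]
    intercept: float
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        if not (0.0 < self.cutoff < 1.0):
            raise ValueError("cutoff must lie strictly between 0 and 1")

    def to_text(self, handle: IO[str]) -> None:
        handle.write(f"intercept\t{self.intercept!r}\n")
        handle.write(f"cutoff\t{self.cutoff!r}\n")
        for k in FEATURE_NAMES:
            handle.write(f"{k}\t{self.weights[k]!r}\n")

    @classmethod
    def from_text(cls, handle: IO[str]) -> "CodingModel":
        kv = dict(line.split("\t") for line in handle.read().strip().splitlines())
        return cls(
            weights={k: float(kv[k]) for k in FEATURE_NAMES},
            intercept=float(kv["intercept"]),
            cutoff=float(kv["cutoff"]),
        )


def compute_features(seq: str, table: HexamerTable) -> dict[str, float]:
    orf = longest_orf(seq)
    return {
        "orf_length": float(orf.length),
        "orf_coverage": orf.coverage,
        "fickett": fickett_score(seq),
        "hexamer_llr": hexamer_llr(seq, table),
    }


def coding_probability(features: Mapping[str, float], model: CodingModel) -> float:
    """Coding probability via the logistic transform of the weighted
    feature sum; raises on a missing feature, naming it."""
    z = model.intercept
    for name, w in model.weights.items():
        if name not in features:
            raise KeyError(f"missing coding-potential feature: {name}")
        z += w * features[name]
    return 1.0 / (1.0 + math.exp(-z))


def train_coding_model(
    coding_seqs: Sequence[str],
    noncoding_seqs: Sequence[str],
    table: HexamerTable | None = None,
    cutoff: float = DEFAULT_CUTOFF,
) -> tuple[CodingModel, HexamerTable]:
    """Fit the logistic feature combination on labelled training sets.

    The hexamer table is trained on the same sets unless supplied. Raw
    (unstandardised) features are passed to the IRLS fit, which is
    well-conditioned at these feature scales.
    """
    from .signature import fit_logistic

    if table is None:
        table = train_hexamer_table(coding_seqs, noncoding_seqs)
    rows = [compute_features(s, table) for s in list(coding_seqs) + list(noncoding_seqs)]
    x = np.array([[r[k] for k in FEATURE_NAMES] for r in rows])
    y = np.array([1.0] * len(coding_seqs) + [0.0] * len(noncoding_seqs))
    fit = fit_logistic(x, y)
    weights = dict(zip(FEATURE_NAMES, fit.coef))
    return CodingModel(weights, fit.intercept, cutoff), table


def score_transcripts(
    seqs: Mapping[str, str], model: CodingModel, table: HexamerTable
):
    """Score a set of transcript sequences; returns a DataFrame with the
    four features, probability and coding/noncoding label."""
    import pandas as pd

    rows = []
    for tid, seq in seqs.items():
        feats = compute_features(seq, table)
        p = coding_probability(feats, model)
        rows.append(
            {
                "transcript_id": tid,
                **feats,
                "coding_prob": p,
                "label": "coding" if p >= model.cutoff else "noncoding",
            }
        )
    return pd.DataFrame(rows)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Transcript sequences keyed by record id."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
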