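"""Amino-acid PWM scanning with exact p-values and BH q-values.

A FIMO-equivalent scanner: each window of a protein is scored as the sum
of per-position log2 odds of a position probability matrix against a
background model. P-values are exact under the background model, computed
by dynamic programming over integer-quantized scores (the standard
construction for PWM score distributions); q-values are Benjamini-Hochberg
over all windows of a scan.

Scores are reported on the same 1/1000-bit quantization grid the p-value
table uses, so a reported score and its p-value are always consistent.
Users scanning with real FIMO output can bypass this scanner entirely and
feed FIMO TSV straight into the classifier; the printed thresholds
(60/85/0.01) are plain parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .model import AA_ALPHABET, MotifHit, ProteinRecord

__all__ = [
    "PWM",
    "ScoredWindow",
    "score_sequence",
    "score_pvalue_table",
    "bh_qvalues",
    "scan_records",
    "filter_motif_hits",
    "MOTIF_NAMES",
    "STRICT_MOTIFS",
    "DEFAULT_SCORE_MIN",
    "DEFAULT_QVALUE_MAX",
    "DEFAULT_STRICT_SCORE_MIN",
]

#: NB-ARC-diagnostic motif indices and their conventional names.
MOTIF_NAMES = {2: "RNBS-D", 7: "MHD", 8: "linker"}

#: Motifs under the stricter score cutoff when used as extraction evidence.
STRICT_MOTIFS = frozenset({7, 8, "MHD", "linker"})

DEFAULT_SCORE_MIN = 60.0
DEFAULT_QVALUE_MAX = 0.01
DEFAULT_STRICT_SCORE_MIN = 85.0

#: Score quantization granularity: 1/1000 of a bit.
DEFAULT_GRANULARITY = 1e-3


@dataclass
class PWM:
    """A position probability matrix over a protein alphabet.

    ``matrix`` has shape (L, len(alphabet)) with rows summing to 1;
    ``background`` is a strictly positive per-letter distribution.
    A small pseudocount is added to matrix probabilities before taking
    log2 odds so zero cells stay finite.
    """

    motif_id: int | str
    matrix: np.ndarray
    alphabet: str = AA_ALPHABET
    background: Optional[np.ndarray] = None
    pseudocount: float = 1e-4

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] < 1:
            raise ValueError("PWM matrix must be 2-D with at least one row")
        if self.matrix.shape[1] != len(self.alphabet):
            raise ValueError(
                f"matrix has {self.matrix.shape[1]} columns for a "
                f"{len(self.alphabet)}-letter alphabet"
            )
        sums = self.matrix.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-3):
            row = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(
                f"motif {self.motif_id}: probability row {row + 1} sums to "
                f"{sums[row]:.4g}"
            )
        if self.background is None:
            self.background = np.full(len(self.alphabet), 1.0 / len(self.alphabet))
        self.background = np.asarray(self.background, dtype=float)
        if np.any(self.background <= 0):
            raise ValueError("background probabilities must be strictly positive")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def name(self) -> str:
        if isinstance(self.motif_id, int) and self.motif_id in MOTIF_NAMES:
            return MOTIF_NAMES[self.motif_id]
        return str(self.motif_id)

    def log_odds(self) -> np.ndarray:
        """Per-position log2 odds, pseudocount-adjusted."""
        return np.log2((self.matrix + self.pseudocount) / self.background)

    def quantized_scores(self, granularity: float = DEFAULT_GRANULARITY) -> np.ndarray:
        """Integer log-odds on the quantization grid (units of ``granularity`` bits)."""
        return np.rint(self.log_odds() / granularity).astype(np.int64)


@dataclass
class ScoredWindow:
    """One scored start position of a PWM along a sequence."""

    position: int  # 1-based start
    score: float
    pvalue: float = 1.0


@dataclass
class ScoreDistribution:
    """Exact distribution of the window score under the background model.

    ``sf[k]`` is P(score >= (k + min_score) * granularity) for integer
    offsets k; built by per-position convolution of the quantized score
    probability mass functions.
    """

    min_score: int
    sf: np.ndarray
    granularity: float

    def pvalue(self, score: float) -> float:
        k = int(round(score / self.granularity)) - self.min_score
        if k <= 0:
            return 1.0
        if k >= len(self.sf):
            return float(self.sf[-1]) if len(self.sf) else 1.0
        return float(self.sf[k])


def score_pvalue_table(pwm: PWM, granularity: float = DEFAULT_GRANULARITY) -> ScoreDistribution:
    """Exact p-values for every attainable quantized window score.

    The p-value of a threshold s is the probability, under the background
    model over random L-mers, that the window score is >= s. Computed by
    convolving per-position pmfs over the integer score grid; p is
    monotone non-increasing in s and p(min score) = 1.
    """
    q = pwm.quantized_scores(granularity)
    bg = pwm.background
    mins = q.min(axis=1)
    maxs = q.max(axis=1)
    total_min = int(mins.sum())
    total_max = int(maxs.sum())
    pmf = np.array([1.0])
    offset = 0
    for i in range(q.shape[0]):
        row_pmf = np.zeros(int(maxs[i] - mins[i]) + 1)
        for letter_idx, s in enumerate(q[i]):
            row_pmf[int(s - mins[i])] += bg[letter_idx]
        pmf = np.convolve(pmf, row_pmf)
    # pmf[k] = P(sum == total_min + k); suffix-sum for the survival function
    sf = np.cumsum(pmf[::-1])[::-1]
    sf = np.minimum(sf, 1.0)  # guard against float drift
    assert len(sf) == total_max - total_min + 1
    return ScoreDistribution(min_score=total_min, sf=sf, granularity=granularity)


def score_sequence(pwm: PWM, record: ProteinRecord,
                   granularity: float = DEFAULT_GRANULARITY,
                   table: Optional[ScoreDistribution] = None) -> list[ScoredWindow]:
    """Score every window of ``record`` against ``pwm``.

    One window per start position 1..len-L+1; letters outside the PWM
    alphabet (e.g. X) contribute log-odds 0, i.e. they score as background.
    A sequence shorter than the motif yields an empty list.
    """
    L = len(pwm)
    seq = record.sequence
    n = len(seq)
    if n < L:
        return []
    if table is None:
        table = score_pvalue_table(pwm, granularity)
    q = pwm.quantized_scores(granularity)
    index = {a: i for i, a in enumerate(pwm.alphabet)}
    idx = np.array([index.get(c, -1) for c in seq], dtype=np.int64)
    known = idx >= 0
    # per-position score rows padded with a zero column for unknown letters
    padded = np.hstack([q, np.zeros((L, 1), dtype=np.int64)])
    totals = np.zeros(n - L + 1, dtype=np.int64)
    for j in range(L):
        col = idx[j:j + n - L + 1].copy()
        col[~known[j:j + n - L + 1]] = -1
        totals += padded[j][col]
    windows = []
    for i, t in enumerate(totals):
        score = float(t) * granularity
        windows.append(ScoredWindow(position=i + 1, score=score, pvalue=table.pvalue(score)))
    return windows


def bh_qvalues(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values.

    q_i = min over j with p_j >= p_i of (p_j * n / rank_j); q >= p
    elementwise and q is monotone non-decreasing in p.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def scan_records(pwms: Sequence[PWM], records: Sequence[ProteinRecord],
                 report_pvalue_max: float = 1e-3,
                 granularity: float = DEFAULT_GRANULARITY) -> list[MotifHit]:
    """Scan a set of sequences with a set of PWMs, FIMO-style.

    All windows of the whole scan form a single testing family for the BH
    q-values; hits with p-value <= ``report_pvalue_max`` are reported as
    :class:`MotifHit` rows (scores on the FIMO-like log2-odds scale).
    """
    raw: list[tuple[PWM, ProteinRecord, ScoredWindow]] = []
    pvals: list[float] = []
    for pwm in pwms:
        table = score_pvalue_table(pwm, granularity)
        for rec in records:
            for win in score_sequence(pwm, rec, granularity, table=table):
                raw.append((pwm, rec, win))
                pvals.append(win.pvalue)
    if not raw:
        return []
    qvals = bh_qvalues(pvals)
    hits: list[MotifHit] = []
    for (pwm, rec, win), qv in zip(raw, qvals):
        if win.pvalue > report_pvalue_max:
            continue
        L = len(pwm)
        hits.append(MotifHit(
            seq_id=rec.id,
            motif_id=pwm.motif_id,
            start=win.position,
            end=win.position + L - 1,
            score=win.score,
            pvalue=win.pvalue,
            qvalue=float(qv),
            matched_seq=rec.sequence[win.position - 1:win.position + L - 1],
        ))
    hits.sort(key=lambda h: (h.seq_id, h.start, str(h.motif_id)))
    return hits


def is_strict_motif(motif_id: int | str) -> bool:
    """True for the linker and MHD motifs (stricter extraction cutoff)."""
    if motif_id in STRICT_MOTIFS:
        return True
    return str(motif_id) in {"7", "8", "MHD", "linker"}


def filter_motif_hits(hits: Iterable[MotifHit],
                      score_min: float = DEFAULT_SCORE_MIN,
                      q_max: float = DEFAULT_QVALUE_MAX,
                      strict_motifs: Optional[frozenset] = None,
                      strict_score_min: float = DEFAULT_STRICT_SCORE_MIN) -> list[MotifHit]:
    """Apply the score >= 60 / q <= 0.01 motif filter.

    Kept hits whose motif is linker or MHD additionally need
    score >= 85 to count as NB-ARC extraction evidence; below that they
    are kept for annotation but flagged ``extraction_ok=False``.
    Output is a subset of the input and filtering is idempotent.
    """
    def strict(h: MotifHit) -> bool:
        if strict_motifs is not None:
            return h.motif_id in strict_motifs or str(h.motif_id) in {
                str(m) for m in strict_motifs}
        return is_strict_motif(h.motif_id)

    out = []
    for h in hits:
        if h.score >= score_min and h.qvalue <= q_max:
            ok = (not strict(h)) or h.score >= strict_score_min
            out.append(replace(h, extraction_ok=ok))
    return out
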