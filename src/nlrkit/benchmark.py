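"""Benchmarking metrics for NLR annotation tools.

Retrieval sensitivity (percent of reference NLRs retrieved), specificity
(percent of retrieved sequences that are genuine NLRs), and
domain-architecture annotation accuracy under the canonical-domain
comparison rules: only the TIR, Rx-type CC, RPW8-type CC, NB-ARC and LRR
domains are considered and sequentially duplicated domains are compressed,
so e.g. a predicted "CONL" (integrated domain between CC and NB-ARC)
compares as "CNL". Percentages are printed to one decimal, round-half-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "MetricReport",
    "round_pct",
    "canonicalize_architecture",
    "sensitivity",
    "specificity",
    "architecture_accuracy",
    "intersection_counts",
]

#: Letters considered in architecture comparisons (canonical NLR domains).
CANONICAL_LETTERS = frozenset("TCRNL")


def round_pct(value: float, digits: int = 1) -> float:
    """Round-half-up to ``digits`` decimals (printed-percentage style)."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def canonicalize_architecture(arch: str) -> str:
    """Reduce an architecture string to the canonical comparison form.

    Letters outside {T, C, R, N, L} are dropped (integrated domains, the
    late-blight R1 domain, C-JID), then adjacent duplicates collapse.
    Idempotent.
    """
    kept = [c for c in arch if c in CANONICAL_LETTERS]
    out: list[str] = []
    for c in kept:
        if not out or out[-1] != c:
            out.append(c)
    return "".join(out)


def sensitivity(retrieved: int, total: int) -> float:
    """Percent of the reference dataset retrieved, one decimal."""
    if total <= 0:
        raise ValueError("reference total must be positive")
    if not (0 <= retrieved <= total):
        raise ValueError("retrieved count must lie in [0, total]")
    return round_pct(100.0 * retrieved / total)


def specificity(true_positives: int, false_positives: int) -> float:
    """Percent of retrieved sequences that are genuine NLRs, one decimal."""
    if true_positives + false_positives <= 0:
        raise ValueError("specificity undefined with no retrieved sequences")
    return round_pct(100.0 * true_positives / (true_positives + false_positives))


@dataclass
class MetricReport:
    """Per-tool architecture-annotation tally.

    ``verdicts`` maps each reference ID to ``correct``, ``incorrect``,
    ``other`` (retrieved but not reliably classified as NLR) or
    ``missing``; counts over the first three plus missing equal the
    reference size.
    """

    tool: str = ""
    reference_size: int = 0
    correct: int = 0
    incorrect: int = 0
    other: int = 0
    missing: int = 0
    accuracy_pct: float = 0.0
    verdicts: dict[str, str] = field(default_factory=dict)
    per_subclass: dict[str, dict[str, int]] = field(default_factory=dict)


def architecture_accuracy(predictions: Mapping[str, tuple[str, bool]],
                          reference: Mapping[str, str],
                          subclasses: Optional[Mapping[str, str]] = None,
                          tool: str = "") -> MetricReport:
    """Compare predicted architectures against the reference annotation.

    ``predictions`` maps retrieved IDs to (architecture string,
    reliable-NLR flag); ``reference`` maps every reference ID to its
    architecture. Both sides are canonicalized before comparison. A
    retrieved ID is ``correct`` iff the canonical strings are equal,
    ``other`` if the tool did not reliably classify it as an NLR, else
    ``incorrect``; accuracy = 100 * correct / reference size.
    """
    report = MetricReport(tool=tool, reference_size=len(reference))
    for rid, ref_arch in reference.items():
        if rid not in predictions:
            verdict = "missing"
        else:
            pred_arch, reliable = predictions[rid]
            if not reliable:
                verdict = "other"
            elif canonicalize_architecture(pred_arch) == canonicalize_architecture(ref_arch):
                verdict = "correct"
            else:
                verdict = "incorrect"
        report.verdicts[rid] = verdict
        setattr(report, verdict, getattr(report, verdict) + 1)
        if subclasses:
            sub = subclasses.get(rid, "other")
            bucket = report.per_subclass.setdefault(
                sub, {"correct": 0, "incorrect": 0, "other": 0, "missing": 0})
            bucket[verdict] += 1
    if report.reference_size:
        report.accuracy_pct = round_pct(100.0 * report.correct / report.reference_size)
    return report


def intersection_counts(tool_outputs: Mapping[str, Iterable[str]]
                        ) -> dict[frozenset, int]:
    """Exact-subset intersection tally (UpSet-style).

    One entry per non-empty tool combination: the number of IDs retrieved
    by exactly that set of tools. Counts sum to the size of the union.
    """
    if not tool_outputs:
        raise ValueError("at least one tool output is required")
    sets = {tool: set(ids) for tool, ids in tool_outputs.items()}
    union = set().union(*sets.values())
    counts: dict[frozenset, int] = {}
    for rid in union:
        combo = frozenset(t for t, s in sets.items() if rid in s)
        counts[combo] = counts.get(combo, 0) + 1
    return counts
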