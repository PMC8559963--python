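"""Alignment trimming and descriptive dataset statistics ahead of
phylogenetics.

Columns of a multiple sequence alignment are removed when their site
coverage (fraction of non-gap rows) falls below a threshold; the
convention here keeps a column at exactly the threshold (a 95% rule
removes columns with coverage < 0.95). ``X`` counts as coverage, ``-``
and ``.`` as gaps. Length statistics use the sample (n-1) standard
deviation and flag sequences beyond two standard deviations of the mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import ProteinRecord

PathLike = Union[str, Path]

GAP_CHARS = frozenset("-.")

__all__ = [
    "Alignment",
    "LengthStats",
    "trim_columns",
    "length_stats",
    "group_counts",
    "read_phylip",
    "write_phylip",
    "read_fasta_alignment",
]


@dataclass
class Alignment:
    """Rows of (ID, gapped sequence), all the same length, unique IDs."""

    rows: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [rid for rid, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("alignment row IDs must be unique")
        lengths = {len(seq) for _, seq in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"alignment rows differ in length: {sorted(lengths)}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0


def trim_columns(aln: Alignment, min_coverage: float = 0.95) -> Alignment:
    """Keep columns whose site coverage is >= ``min_coverage``.

    Row order is preserved and the operation is idempotent; a gap-free
    column is never removed. An all-columns-removed result returns an
    empty alignment with a warning.
    """
    if not aln.rows:
        return Alignment(rows=[])
    mat = np.array([list(seq) for _, seq in aln.rows])
    is_gap = np.isin(mat, list(GAP_CHARS))
    coverage = 1.0 - is_gap.mean(axis=0)
    keep = coverage >= min_coverage - 1e-12  # float-safe at the boundary
    if not keep.any():
        warnings.warn("column trimming removed every alignment position",
                      stacklevel=2)
        return Alignment(rows=[(rid, "") for rid, _ in aln.rows])
    trimmed = ["".join(row) for row in mat[:, keep]]
    return Alignment(rows=[(rid, seq) for (rid, _), seq in zip(aln.rows, trimmed)])


@dataclass
class LengthStats:
    n: int
    mean: float
    stdev: float
    min: int
    max: int
    outlier_ids: list[str] = field(default_factory=list)


def length_stats(records: Sequence[ProteinRecord]) -> LengthStats:
    """Sequence-length distribution with 2-standard-deviation outliers.

    Standard deviation uses the n-1 denominator (0 for a single record);
    outliers satisfy |length - mean| > 2 * stdev strictly.
    """
    if not records:
        raise ValueError("length_stats requires at least one record")
    lengths = np.array([len(r) for r in records], dtype=float)
    mean = float(lengths.mean())
    stdev = float(lengths.std(ddof=1)) if len(lengths) > 1 else 0.0
    outliers = [r.id for r, ln in zip(records, lengths)
                if abs(ln - mean) > 2 * stdev]
    if stdev == 0.0:
        outliers = []
    return LengthStats(n=len(records), mean=mean, stdev=stdev,
                       min=int(lengths.min()), max=int(lengths.max()),
                       outlier_ids=outliers)


def group_counts(records: Sequence[ProteinRecord],
                 key: str = "genus") -> dict[str, int]:
    """Per-genus (or per-subclass) tallies, ordered by descending count
    then name; records without metadata fall into ``unknown``."""
    if key not in ("genus", "subclass"):
        raise ValueError("key must be 'genus' or 'subclass'")
    counts: dict[str, int] = {}
    for r in records:
        value = getattr(r, key) or "unknown"
        counts[value] = counts.get(value, 0) + 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return dict(ordered)


# ------------------------------------------------------------- PHYLIP

def _to_biopython(aln: Alignment) -> MultipleSeqAlignment:
    return MultipleSeqAlignment(
        [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in aln.rows]
    )


def write_phylip(aln: Alignment, path: PathLike) -> None:
    """Write relaxed PHYLIP (full IDs, header "n m")."""
    AlignIO.write(_to_biopython(aln), str(path), "phylip-relaxed")


def read_phylip(path: PathLike) -> Alignment:
    """Read relaxed PHYLIP; header/row mismatches raise."""
    try:
        bio = AlignIO.read(str(path), "phylip-relaxed")
    except ValueError as exc:
        raise ValueError(f"{path}: malformed PHYLIP alignment: {exc}") from exc
    return Alignment(rows=[(rec.id, str(rec.seq)) for rec in bio])


def read_fasta_alignment(path: PathLike) -> Alignment:
    bio = AlignIO.read(str(path), "fasta")
    return Alignment(rows=[(rec.id, str(rec.seq)) for rec in bio])
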