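"""Core value types shared across the pipeline.

Coordinates are 1-based inclusive everywhere (the convention shared by
InterProScan TSV, FIMO TSV and GFF3); no conversion happens internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

#: The 20 canonical amino acids, in MEME/alphabetical order.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Letters tolerated in input sequences beyond the canonical 20.
EXTRA_LETTERS = "XBZJUO*"

SUBCLASSES = ("TIR-NLR", "CC-NLR", "CCR-NLR", "CCG10-NLR", "other")


@dataclass
class ProteinRecord:
    """An identified amino-acid sequence with optional metadata.

    ``genus`` and ``subclass`` are used by the redundancy-reduction and
    benchmarking steps; they may be absent for plain annotation runs.
    """

    id: str
    sequence: str
    genus: Optional[str] = None
    subclass: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record id must be non-empty")
        self.sequence = "".join(self.sequence.split()).upper()
        if len(self.sequence) < 1:
            raise ValueError(f"sequence of {self.id!r} is empty")
        allowed = set(AA_ALPHABET + EXTRA_LETTERS)
        bad = set(self.sequence) - allowed
        if bad:
            raise ValueError(
                f"sequence of {self.id!r} contains letters outside the "
                f"amino-acid alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SignatureHit:
    """One interval of evidence from a domain-signature database.

    ``analysis`` names the member database (Pfam, Gene3D, SUPERFAMILY,
    PROSITE profiles, SMART, CDD, PRINTS); ``accession`` is the signature
    identifier (e.g. PF00931). ``extra`` keeps any InterProScan TSV columns
    beyond the ninth as opaque text.
    """

    seq_id: str
    analysis: str
    accession: str
    start: int
    end: int
    score: Optional[float] = None
    evalue: Optional[float] = None
    description: str = ""
    extra: str = ""

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("signature accession must be non-empty")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval {self.start}-{self.end} for {self.seq_id}"
                f"/{self.accession} (need 1 <= start <= end)"
            )

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class MotifHit:
    """One PWM motif match on a protein (FIMO-style).

    ``extraction_ok`` records whether the hit may serve as NB-ARC
    extraction evidence: the linker and MHD motifs require score >= 85
    while all motifs require score >= 60 and q <= 0.01. Sub-threshold
    hits are kept for annotation output but flagged ineligible.
    """

    seq_id: str
    motif_id: int | str
    start: int
    end: int
    score: float
    pvalue: float
    qvalue: float
    matched_seq: str = ""
    extraction_ok: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid motif interval {self.start}-{self.end} on {self.seq_id}"
            )
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"p-value {self.pvalue} outside (0, 1]")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


#: Domain-call categories and their one-letter architecture codes.
CATEGORY_LETTERS = {
    "R1": "1",
    "CC": "C",
    "RPW8": "R",
    "TIR": "T",
    "NBARC": "N",
    "LRR": "L",
    "CJID": "J",
    "OTHER": "O",
}


@dataclass
class DomainCall:
    """A merged, categorized domain interval with its supporting evidence."""

    seq_id: str
    category: str
    start: int
    end: int
    evidence: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category not in CATEGORY_LETTERS:
            raise ValueError(f"unknown domain category {self.category!r}")
        if not self.evidence:
            raise ValueError("domain call must carry at least one evidence hit")

    @property
    def letter(self) -> str:
        return CATEGORY_LETTERS[self.category]

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class Architecture:
    """Ordered, repeat-compressed letter summary of a protein's domain calls."""

    letters: str
    calls: list = field(default_factory=list)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.letters


CATEGORIES = (
    "NLR",
    "NLR-degenerate",
    "TX",
    "CCX",
    "RPW8",
    "MLKL",
    "non-NLR",
)


@dataclass
class ClassifiedSequence:
    """A protein with its category, architecture and extracted NB-ARC regions.

    ``rule`` names the classification clause that fired, e.g.
    ``nbarc-signature``, ``nbarc-motif``, ``degenerate-ploop``,
    ``degenerate-motif``, ``helo``, ``tir-only`` ...
    """

    record: ProteinRecord
    category: str
    architecture: Architecture
    nbarc_regions: list[tuple[int, int]] = field(default_factory=list)
    rule: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    """True if two 1-based inclusive intervals share at least one residue."""
    return a[0] <= b[1] and b[0] <= a[1]


def interval_gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Residues strictly between two intervals (0 if they touch or overlap)."""
    if overlaps(a, b):
        return 0
    return max(a[0], b[0]) - min(a[1], b[1]) - 1
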