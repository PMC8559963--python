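"""Synthetic evidence generator for pipeline testing.

Emits proteins with planted domain architectures plus matching mock
InterProScan TSV and FIMO TSV evidence, so classification, extraction,
benchmarking and clustering are testable with no external searches.
Fixture sequences are uniform-random residues: domain content is carried
entirely by the planted evidence, since the classifier never re-derives
signatures from sequence. Planted motifs default to score 90 / q 1e-4
(clearing both the 60 and 85 thresholds); boundary fixtures probe the
filter edges. Fixed seeds give byte-identical emitted files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .benchmark import canonicalize_architecture
from .model import AA_ALPHABET, MotifHit, ProteinRecord, SignatureHit
from . import io as nio

PathLike = Union[str, Path]

__all__ = [
    "FixtureSpec",
    "MotifPlan",
    "generate_protein",
    "generate_family",
    "emit_mock_files",
    "read_truth_tsv",
    "DEFAULT_MOTIF_PLAN",
]

ARCH_LETTERS = set("1CRTNLJO")

#: (database, accession) planted for each architecture letter.
LETTER_EVIDENCE = {
    "1": ("Pfam", "PF12061"),
    "C": ("Pfam", "PF18052"),
    "R": ("Pfam", "PF05659"),
    "T": ("Pfam", "PF01582"),
    "L": ("Gene3D", "G3DSA:3.80.10.10"),
    "O": ("ProSiteProfiles", "PS50808"),  # zf-BED integrated domain
}

EXTRA_EVIDENCE = {
    "ploop": ("SUPERFAMILY", "SSF52540"),
    "helo": ("Pfam", "PF06760"),
}

#: Typical planted segment lengths (aa) per letter.
SEGMENT_LENGTHS = {
    "1": (140, 170), "C": (120, 160), "R": (130, 170), "T": (160, 190),
    "N": (280, 330), "L": (200, 320), "J": (100, 130), "O": (80, 120),
    "ploop": (170, 210), "helo": (130, 160),
}

MOTIF_LENGTH = 15


@dataclass(frozen=True)
class MotifPlan:
    """One motif to plant: index (2 = RNBS-D, 7 = MHD, 8 = linker), FIMO
    score and q-value."""

    motif_id: int
    score: float = 90.0
    qvalue: float = 1e-4

    @property
    def passes_filter(self) -> bool:
        return self.score >= 60.0 and self.qvalue <= 0.01

    @property
    def extraction_eligible(self) -> bool:
        if not self.passes_filter:
            return False
        if self.motif_id in (7, 8):  # MHD / linker need the stricter cutoff
            return self.score >= 85.0
        return True


DEFAULT_MOTIF_PLAN = (MotifPlan(2), MotifPlan(7), MotifPlan(8))


@dataclass(frozen=True)
class FixtureSpec:
    """Blueprint for one synthetic protein.

    ``architecture`` is the target letter string over {1,C,R,T,N,L,J,O};
    ``nbarc_mode`` decides whether an N segment carries the Pfam NB-ARC
    signature ("signature") or only a P-loop NTPase signature relying on
    planted motifs ("motif"). ``extra_domains`` appends stand-alone
    "ploop" or "helo" segments (lettered O in the truth architecture) for
    the degenerate and MLKL categories.
    """

    architecture: str
    genus: str = "Oryza"
    subclass: Optional[str] = None
    nbarc_mode: str = "signature"
    motif_plan: Optional[tuple[MotifPlan, ...]] = None
    extra_domains: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        bad = set(self.architecture) - ARCH_LETTERS
        if bad:
            raise ValueError(f"architecture letters outside {{1CRTNLJO}}: {sorted(bad)}")
        if self.nbarc_mode not in ("signature", "motif"):
            raise ValueError("nbarc_mode must be 'signature' or 'motif'")
        for x in self.extra_domains:
            if x not in EXTRA_EVIDENCE:
                raise ValueError(f"unknown extra domain {x!r}")

    @property
    def motifs(self) -> tuple[MotifPlan, ...]:
        if self.motif_plan is not None:
            return self.motif_plan
        if "N" in self.architecture:
            return DEFAULT_MOTIF_PLAN
        return ()

    # -- intended truth (independent of the classifier implementation) --

    def _eligible_motifs(self) -> list[MotifPlan]:
        return [m for m in self.motifs if m.extraction_eligible]

    @property
    def expected_architecture(self) -> str:
        letters = []
        for c in self.architecture:
            if c == "N" and self.nbarc_mode == "motif" and not self._eligible_motifs():
                letters.append("O")  # bare P-loop segment, no NB-ARC call
            else:
                letters.append(c)
        letters.extend("O" for _ in self.extra_domains)
        out = []
        for c in letters:
            if not out or out[-1] != c:
                out.append(c)
        return "".join(out)

    @property
    def expected_category(self) -> str:
        arch = self.architecture
        eligible = self._eligible_motifs()
        has_nbarc = "N" in arch and (self.nbarc_mode == "signature" or eligible)
        sensor = bool(set(arch) & set("1CRT"))
        bare_ploop = ("ploop" in self.extra_domains
                      or ("N" in arch and self.nbarc_mode == "motif" and not eligible))
        if has_nbarc:
            return "NLR"
        if sensor and bare_ploop:
            return "NLR-degenerate"
        if (sensor or "L" in arch) and eligible:
            return "NLR-degenerate"
        if "helo" in self.extra_domains:
            return "MLKL"
        if "T" in arch:
            return "TX"
        if "C" in arch or "1" in arch:
            return "CCX"
        if "R" in arch:
            return "RPW8"
        return "non-NLR"


def _random_peptide(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(AA_ALPHABET))[rng.integers(0, 20, n)])


def generate_protein(spec: FixtureSpec, seq_id: str,
                     rng: Optional[np.random.Generator] = None, seed: int = 0,
                     ) -> tuple[ProteinRecord, list[SignatureHit],
                                list[MotifHit], list[SignatureHit]]:
    """Build one synthetic protein and its planted evidence.

    Returns (record, signature hits, motif hits, C-JID hits). Segments
    are concatenated in architecture order with 5-30 aa linkers; each
    segment gets one signature hit from its letter's vocabulary and the
    N segment (or, absent one, the first segment) hosts the planted
    motifs.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    segments = list(spec.architecture) + list(spec.extra_domains)
    seq_parts: list[str] = []
    sig_hits: list[SignatureHit] = []
    cjid_hits: list[SignatureHit] = []
    seg_bounds: dict[int, tuple[int, int]] = {}
    pos = 0
    for i, seg in enumerate(segments):
        if i > 0:
            linker = int(rng.integers(5, 31))
            seq_parts.append(_random_peptide(rng, linker))
            pos += linker
        lo, hi = SEGMENT_LENGTHS[seg]
        length = int(rng.integers(lo, hi + 1))
        start, end = pos + 1, pos + length
        seg_bounds[i] = (start, end)
        seq_parts.append(_random_peptide(rng, length))
        pos += length
        if seg == "N":
            if spec.nbarc_mode == "signature":
                sig_hits.append(SignatureHit(seq_id, "Pfam", "PF00931", start, end,
                                             score=1e-50, description="NB-ARC"))
                sig_hits.append(SignatureHit(
                    seq_id, "SUPERFAMILY", "SSF52540",
                    max(1, start - 5), min(end + 5, end), score=1e-40,
                    description="P-loop containing NTPase"))
            else:
                sig_hits.append(SignatureHit(seq_id, "SUPERFAMILY", "SSF52540",
                                             start, end, score=1e-40,
                                             description="P-loop containing NTPase"))
        elif seg == "J":
            cjid_hits.append(SignatureHit(seq_id, "HMMER", "C-JID", start, end,
                                          score=50.0, evalue=1e-20))
        elif seg in EXTRA_EVIDENCE and seg not in LETTER_EVIDENCE:
            db, acc = EXTRA_EVIDENCE[seg]
            sig_hits.append(SignatureHit(seq_id, db, acc, start, end, score=1e-30))
        else:
            db, acc = LETTER_EVIDENCE[seg]
            sig_hits.append(SignatureHit(seq_id, db, acc, start, end, score=1e-30))

    sequence = "".join(seq_parts)
    record = ProteinRecord(id=seq_id, sequence=sequence, genus=spec.genus,
                           subclass=spec.subclass)

    motif_hits: list[MotifHit] = []
    if spec.motifs:
        if "N" in spec.architecture:
            host = seg_bounds[spec.architecture.index("N")]
        else:
            host = seg_bounds[0]
        span = host[1] - host[0] + 1 - MOTIF_LENGTH
        offsets = np.linspace(5, max(6, span - 5), num=len(spec.motifs)).astype(int)
        for plan, off in zip(spec.motifs, offsets):
            start = host[0] + int(off)
            end = start + MOTIF_LENGTH - 1
            motif_hits.append(MotifHit(
                seq_id=seq_id, motif_id=plan.motif_id, start=start, end=end,
                score=plan.score, pvalue=min(plan.qvalue, 1.0) / 2,
                qvalue=plan.qvalue,
                matched_seq=sequence[start - 1:end]))
    return record, sig_hits, motif_hits, cjid_hits


def generate_family(seed_record: ProteinRecord, n: int, identity: float,
                    rng: Optional[np.random.Generator] = None, seed: int = 0,
                    ) -> list[ProteinRecord]:
    """``n`` mutated copies of a sequence at a target identity.

    Substitution-only mutants: each copy differs from the seed at
    round((1 - identity) * L) distinct positions, so realized pairwise
    identity to the seed equals the target up to rounding.
    """
    if not (0.0 < identity <= 1.0):
        raise ValueError("identity must lie in (0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    L = len(seed_record)
    k = int(round((1.0 - identity) * L))
    out = []
    letters = np.array(list(AA_ALPHABET))
    for i in range(n):
        seq = list(seed_record.sequence)
        positions = rng.choice(L, size=k, replace=False)
        for p in positions:
            choices = [a for a in AA_ALPHABET if a != seq[p]]
            seq[p] = choices[int(rng.integers(0, len(choices)))]
        out.append(ProteinRecord(id=f"{seed_record.id}_m{i + 1}",
                                 sequence="".join(seq),
                                 genus=seed_record.genus))
    return out


def _write_domtbl(hits: Sequence[SignatureHit], path: PathLike) -> None:
    """Minimal HMMER domtblout emitter for planted C-JID hits."""
    with open(path, "w") as fh:
        fh.write("# target name - tlen query name accession qlen ... (mock)\n")
        for h in hits:
            cols = [h.seq_id, "-", "0", h.accession, "-", "120", repr(h.evalue or 1e-20),
                    repr(h.score or 0.0), "1.0", "1", "1", repr(h.evalue or 1e-20),
                    repr(h.evalue or 1e-20), repr(h.score or 0.0), "1.0", "1", "120",
                    str(h.start), str(h.end), str(h.start), str(h.end), "0.99"]
            fh.write(" ".join(cols) + "\n")


def emit_mock_files(specs: Sequence[FixtureSpec], outdir: PathLike,
                    seed: int = 42) -> dict[str, Path]:
    """Emit FASTA + mock InterProScan TSV + mock FIMO TSV (+ C-JID
    domtblout when J segments exist) and a truth table for a fixture set.

    Deterministic: identical seeds give byte-identical files. The truth
    TSV columns are id, genus, category, architecture, canonical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, sig_hits, motif_hits, cjid_hits, truth = [], [], [], [], []
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(specs))
    for i, (spec, ss) in enumerate(zip(specs, children)):
        rng = np.random.default_rng(ss)
        rec, sigs, mots, cjid = generate_protein(spec, f"FX{i + 1:04d}", rng)
        records.append(rec)
        sig_hits.extend(sigs)
        motif_hits.extend(mots)
        cjid_hits.extend(cjid)
        truth.append((rec.id, spec.genus, spec.expected_category,
                      spec.expected_architecture,
                      canonicalize_architecture(spec.expected_architecture)))

    paths = {
        "fasta": outdir / "proteins.fasta",
        "ipr": outdir / "interproscan.tsv",
        "fimo": outdir / "fimo.tsv",
        "truth": outdir / "truth.tsv",
    }
    nio.write_fasta(records, paths["fasta"])
    nio.write_interproscan_tsv(sig_hits, paths["ipr"],
                               seq_lengths={r.id: len(r) for r in records})
    nio.write_fimo_tsv(motif_hits, paths["fimo"])
    with open(paths["truth"], "w") as fh:
        fh.write("id\tgenus\tcategory\tarchitecture\tcanonical\n")
        for row in truth:
            fh.write("\t".join(row) + "\n")
    if cjid_hits:
        paths["cjid"] = outdir / "cjid.domtbl"
        _write_domtbl(cjid_hits, paths["cjid"])
    return paths


def read_truth_tsv(path: PathLike) -> dict[str, dict[str, str]]:
    """Read an emitted truth table back as {id: {column: value}}."""
    out: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            out[cols[0]] = dict(zip(header, cols))
    return out
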