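"""Evidence-based NLR domain calling, classification and NB-ARC extraction.

This is the pipeline's core. Signature hits from the InterProScan member
databases are mapped to domain categories through a fixed accession
vocabulary, merged into domain calls, and each protein is assigned one of
seven categories:

* ``NLR`` - carries an NB-ARC domain (signature evidence, or a P-loop
  NTPase signature chain supported by the NB-ARC motifs RNBS-D / MHD /
  linker);
* ``NLR-degenerate`` - an N-terminal NLR domain (Rx-type CC, R1, RPW8-type
  CC, TIR) with a stand-alone P-loop NTPase hit, or any of those domains
  (or an LRR) together with an extraction-eligible NB-ARC motif;
* ``TX`` / ``CCX`` / ``RPW8`` - TIR-only, CC/R1-only or RPW8-only proteins
  lacking P-loop and motif evidence;
* ``MLKL`` - plant MLKL-like proteins carrying the HeLo domain (PF06760);
* ``non-NLR`` - everything else.

Precedence is NLR > NLR-degenerate > MLKL > TX > CCX > RPW8 > non-NLR, so
stronger evidence always wins and the partition is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .model import (
    Architecture,
    ClassifiedSequence,
    DomainCall,
    MotifHit,
    ProteinRecord,
    SignatureHit,
    overlaps,
    interval_gap,
)

__all__ = [
    "DEFAULT_VOCABULARY",
    "DomainVocabulary",
    "merge_category_intervals",
    "detect_nbarc",
    "build_domain_calls",
    "build_architecture",
    "classify",
    "extract_nbarc_fasta",
    "dedupe_sequences",
    "annotate_proteome",
]

#: Gap (aa) tolerated when merging same-category signature intervals.
DEFAULT_MERGE_GAP = 20


@dataclass(frozen=True)
class DomainVocabulary:
    """Accession sets defining each domain category.

    The sets mirror the InterProScan member-database signatures that are
    diagnostic for each canonical NLR domain; ``nbarc_extract`` is the
    wider P-loop/helical signature set whose mutual overlap delimits the
    NB-ARC region used for phylogenetics.
    """

    r1: frozenset = frozenset({"PF12061"})
    cc: frozenset = frozenset({"PF18052", "cd14798", "G3DSA:1.20.5.4130"})
    rpw8: frozenset = frozenset({"PF05659", "PS51153"})
    tir: frozenset = frozenset({
        "PF01582", "PF13676", "G3DSA:3.40.50.10140", "SSF52200", "PS50104",
        "SM00255",
    })
    nbarc: frozenset = frozenset({"PF00931", "G3DSA:1.10.8.430"})
    nbarc_extract: frozenset = frozenset({
        "G3DSA:3.40.50.300", "SSF52540", "G3DSA:1.10.8.430", "SSF46785",
        "G3DSA:1.10.10.10", "PF00931",
    })
    ploop: frozenset = frozenset({"SSF52540", "G3DSA:3.40.50.300"})
    lrr: frozenset = frozenset({
        "G3DSA:3.80.10.10", "PF08263", "PF07723", "PF07725", "PF12799",
        "PF13306", "PF00560", "PF13516", "PF13855", "SSF52047", "SSF52058",
        "SM00367", "SM00368", "SM00369", "PF18837", "PF01463", "SM00082",
        "SM00013", "PF01462", "PF18831", "PF18805",
    })
    mlkl_helo: frozenset = frozenset({"PF06760"})
    id_extra: frozenset = frozenset({"PS51697", "PS50808", "SM00614"})
    #: NB-ARC-diagnostic motif indices (RNBS-D, MHD, linker).
    nbarc_motifs: frozenset = frozenset({2, 7, 8})

    def category_of(self, accession: str) -> str:
        """Architecture category of a signature accession (OTHER if none)."""
        for cat, accs in (
            ("R1", self.r1), ("CC", self.cc), ("RPW8", self.rpw8),
            ("TIR", self.tir), ("NBARC", self.nbarc), ("LRR", self.lrr),
        ):
            if accession in accs:
                return cat
        return "OTHER"

    def is_nbarc_motif(self, motif_id) -> bool:
        if motif_id in self.nbarc_motifs:
            return True
        return str(motif_id) in {str(m) for m in self.nbarc_motifs} | {
            "RNBS-D", "MHD", "linker"}


DEFAULT_VOCABULARY = DomainVocabulary()


# ------------------------------------------------------ interval merging

def merge_category_intervals(hits: Sequence[SignatureHit],
                             vocabulary: DomainVocabulary = DEFAULT_VOCABULARY,
                             category: str = "OTHER",
                             gap: int = DEFAULT_MERGE_GAP) -> list[DomainCall]:
    """Merge overlapping or near-adjacent (gap <= ``gap``) hits of one
    category into domain calls, sorted by start and pairwise disjoint
    beyond the gap after merging."""
    if not hits:
        return []
    ordered = sorted(hits, key=lambda h: (h.start, -(h.end - h.start)))
    calls: list[DomainCall] = []
    cur = [ordered[0]]
    cur_start, cur_end = ordered[0].start, ordered[0].end
    for h in ordered[1:]:
        if interval_gap((cur_start, cur_end), h.interval) <= gap:
            cur.append(h)
            cur_end = max(cur_end, h.end)
        else:
            calls.append(DomainCall(cur[0].seq_id, category, cur_start, cur_end, cur))
            cur = [h]
            cur_start, cur_end = h.start, h.end
    calls.append(DomainCall(cur[0].seq_id, category, cur_start, cur_end, cur))
    return calls


# ------------------------------------------------------ NB-ARC detection

def detect_nbarc(sig_hits: Sequence[SignatureHit],
                 motif_hits: Sequence[MotifHit],
                 vocabulary: DomainVocabulary = DEFAULT_VOCABULARY,
                 ) -> list[tuple[int, int]]:
    """Locate NB-ARC regions from signature/motif evidence.

    Chains of mutually overlapping NB-ARC-extraction signatures
    (P-loop NTPase, winged-helix and helical Gene3D/SUPERFAMILY folds,
    Pfam NB-ARC) are merged; a chain is an NB-ARC region iff it overlaps
    at least one NB-ARC accession hit (PF00931 / G3DSA:1.10.8.430) or at
    least one extraction-eligible RNBS-D/MHD/linker motif. Region
    boundaries are the union of the chained signature intervals, extended
    to cover any overlapping diagnostic motif. Regions are returned in
    order of start (their 1..k order is the NB-ARC numbering).

    ``motif_hits`` must already be threshold-filtered; only hits with
    ``extraction_ok`` count as support.
    """
    extract_hits = [h for h in sig_hits if h.accession in vocabulary.nbarc_extract]
    if not extract_hits:
        return []
    motifs = [m for m in motif_hits
              if m.extraction_ok and vocabulary.is_nbarc_motif(m.motif_id)]
    # chain strictly by overlap (no gap tolerance): split signatures of one
    # NB-ARC always overlap, while tandem NB-ARCs are separated by linkers
    chains = merge_category_intervals(extract_hits, vocabulary, "NBARC", gap=0)
    regions: list[tuple[int, int]] = []
    for chain in chains:
        anchored = any(h.accession in vocabulary.nbarc for h in chain.evidence)
        support = [m for m in motifs if overlaps(chain.interval, m.interval)]
        if not anchored and not support:
            continue
        start, end = chain.start, chain.end
        for m in support:
            start = min(start, m.start)
            end = max(end, m.end)
        regions.append((start, end))
    regions.sort()
    return regions


# ------------------------------------------------------ domain calls

def build_domain_calls(seq_id: str,
                       sig_hits: Sequence[SignatureHit],
                       motif_hits: Sequence[MotifHit],
                       nbarc_regions: Optional[Sequence[tuple[int, int]]] = None,
                       cjid_hits: Sequence[SignatureHit] = (),
                       vocabulary: DomainVocabulary = DEFAULT_VOCABULARY,
                       gap: int = DEFAULT_MERGE_GAP) -> list[DomainCall]:
    """Turn one protein's evidence into ordered, merged domain calls.

    NB-ARC regions become N calls carrying their supporting signatures.
    NB-ARC-extraction signatures consumed by a region are excluded from
    the OTHER bucket; remaining signatures are merged per category, and
    accessions outside the vocabulary (including stand-alone P-loop hits,
    the HeLo domain and integrated-domain signatures) are lettered O.
    """
    if nbarc_regions is None:
        nbarc_regions = detect_nbarc(sig_hits, motif_hits, vocabulary)
    calls: list[DomainCall] = []
    by_cat: dict[str, list[SignatureHit]] = {}
    for h in sig_hits:
        cat = vocabulary.category_of(h.accession)
        if h.accession in vocabulary.nbarc_extract | vocabulary.nbarc:
            if any(overlaps(h.interval, r) for r in nbarc_regions):
                continue  # consumed by an NB-ARC region
            if cat == "NBARC":
                cat = "OTHER"  # unanchored NB-ARC-fold signature
        if cat == "NBARC":
            continue
        by_cat.setdefault(cat, []).append(h)
    for region in nbarc_regions:
        evidence = [h for h in sig_hits
                    if h.accession in vocabulary.nbarc_extract | vocabulary.nbarc
                    and overlaps(h.interval, region)]
        evidence = evidence or [SignatureHit(seq_id, "nlrkit", "NB-ARC-region",
                                             region[0], region[1])]
        calls.append(DomainCall(seq_id, "NBARC", region[0], region[1], evidence))
    for cat, hits in by_cat.items():
        calls.extend(merge_category_intervals(hits, vocabulary, cat, gap=gap))
    if cjid_hits:
        calls.extend(merge_category_intervals(list(cjid_hits), vocabulary, "CJID", gap=gap))
    calls.sort(key=lambda c: (c.start, -(c.end - c.start)))
    return calls


def build_architecture(domain_calls: Sequence[DomainCall]) -> Architecture:
    """Compressed architecture string over ordered domain calls.

    One letter per call in start order (overlapping calls of different
    categories are both kept, ordered by start then longer-first);
    adjacent identical letters collapse to one.
    """
    ordered = sorted(domain_calls, key=lambda c: (c.start, -(c.end - c.start)))
    letters = []
    for call in ordered:
        if not letters or letters[-1] != call.letter:
            letters.append(call.letter)
    return Architecture(letters="".join(letters), calls=list(ordered))


# ------------------------------------------------------ classification

def _standalone_ploop(sig_hits: Sequence[SignatureHit],
                      vocabulary: DomainVocabulary) -> bool:
    """A P-loop NTPase hit whose interval overlaps no non-P-loop signature.

    This excludes kinases/transporters whose P-loop co-annotates with
    their own domain (ABC transporter cassettes, AAA ATPases, ...).
    """
    ploops = [h for h in sig_hits if h.accession in vocabulary.ploop]
    others = [h for h in sig_hits if h.accession not in vocabulary.ploop]
    for p in ploops:
        if not any(overlaps(p.interval, o.interval) for o in others):
            return True
    return False


def classify(record: ProteinRecord,
             domain_calls: Sequence[DomainCall],
             motif_hits: Sequence[MotifHit],
             nbarc_regions: Sequence[tuple[int, int]],
             sig_hits: Sequence[SignatureHit] = (),
             vocabulary: DomainVocabulary = DEFAULT_VOCABULARY) -> ClassifiedSequence:
    """Assign exactly one of the seven categories to a protein.

    ``motif_hits`` must already be threshold-filtered; extraction-eligible
    NB-ARC motifs (RNBS-D at >= 60, MHD/linker at >= 85) count as
    degeneracy evidence.
    """
    arch = build_architecture(domain_calls)
    cats = {c.category for c in domain_calls}
    sensor = cats & {"CC", "R1", "RPW8", "TIR"}
    eligible_motifs = [m for m in motif_hits
                       if m.extraction_ok and vocabulary.is_nbarc_motif(m.motif_id)]

    if nbarc_regions:
        anchored = any(
            h.accession in vocabulary.nbarc
            for c in domain_calls if c.category == "NBARC"
            for h in c.evidence if isinstance(h, SignatureHit)
        )
        rule = "nbarc-signature" if anchored else "nbarc-motif"
        return ClassifiedSequence(record, "NLR", arch, list(nbarc_regions), rule)

    if sensor and _standalone_ploop(sig_hits, vocabulary):
        return ClassifiedSequence(record, "NLR-degenerate", arch, [], "degenerate-ploop")
    if (sensor or "LRR" in cats) and eligible_motifs:
        return ClassifiedSequence(record, "NLR-degenerate", arch, [], "degenerate-motif")
    if any(isinstance(h, SignatureHit) and h.accession in vocabulary.mlkl_helo
           for h in sig_hits):
        return ClassifiedSequence(record, "MLKL", arch, [], "helo")
    if "TIR" in cats:
        return ClassifiedSequence(record, "TX", arch, [], "tir-only")
    if cats & {"CC", "R1"}:
        return ClassifiedSequence(record, "CCX", arch, [], "cc-only")
    if "RPW8" in cats:
        return ClassifiedSequence(record, "RPW8", arch, [], "rpw8-only")
    return ClassifiedSequence(record, "non-NLR", arch, [], "no-nlr-evidence")


# ------------------------------------------------------ extraction

def extract_nbarc_fasta(record: ProteinRecord,
                        nbarc_regions: Sequence[tuple[int, int]]) -> list[ProteinRecord]:
    """Extract NB-ARC subsequences, numbered by order in the protein.

    A single region keeps the parent ID; multiple regions get ``id_1``,
    ``id_2``, ... in start order.
    """
    out = []
    multiple = len(nbarc_regions) > 1
    for k, (start, end) in enumerate(sorted(nbarc_regions), start=1):
        if start < 1 or end > len(record):
            raise ValueError(
                f"NB-ARC region {start}-{end} outside sequence {record.id} "
                f"(length {len(record)})"
            )
        rid = f"{record.id}_{k}" if multiple else record.id
        out.append(ProteinRecord(id=rid, sequence=record.sequence[start - 1:end],
                                 genus=record.genus, subclass=record.subclass))
    return out


def dedupe_sequences(records: Sequence[ProteinRecord]
                     ) -> tuple[list[ProteinRecord], dict[str, list[str]]]:
    """Exact-string deduplication on sequence.

    The first-seen ID represents each distinct sequence; the multiplicity
    map lists every member ID per representative.
    """
    unique: list[ProteinRecord] = []
    members: dict[str, list[str]] = {}
    by_seq: dict[str, str] = {}
    for r in records:
        rep = by_seq.get(r.sequence)
        if rep is None:
            by_seq[r.sequence] = r.id
            unique.append(r)
            members[r.id] = [r.id]
        else:
            members[rep].append(r.id)
    return unique, members


# ------------------------------------------------------ whole-proteome run

def annotate_proteome(records: Sequence[ProteinRecord],
                      sig_hits: Sequence[SignatureHit],
                      motif_hits: Sequence[MotifHit],
                      cjid_hits: Sequence[SignatureHit] = (),
                      vocabulary: DomainVocabulary = DEFAULT_VOCABULARY,
                      score_min: float = 60.0,
                      q_max: float = 0.01,
                      strict_score_min: float = 85.0,
                      merge_gap: int = DEFAULT_MERGE_GAP,
                      ) -> list[ClassifiedSequence]:
    """Filter motif evidence and classify every input sequence.

    Returns one :class:`ClassifiedSequence` per record, in input order;
    every sequence receives exactly one category.
    """
    from .motifs import filter_motif_hits

    kept = filter_motif_hits(motif_hits, score_min=score_min, q_max=q_max,
                             strict_score_min=strict_score_min)
    sig_by_seq: dict[str, list[SignatureHit]] = {}
    for h in sig_hits:
        sig_by_seq.setdefault(h.seq_id, []).append(h)
    motif_by_seq: dict[str, list[MotifHit]] = {}
    for m in kept:
        motif_by_seq.setdefault(m.seq_id, []).append(m)
    cjid_by_seq: dict[str, list[SignatureHit]] = {}
    for h in cjid_hits:
        cjid_by_seq.setdefault(h.seq_id, []).append(h)

    out = []
    for rec in records:
        sigs = sig_by_seq.get(rec.id, [])
        mots = motif_by_seq.get(rec.id, [])
        regions = detect_nbarc(sigs, mots, vocabulary)
        calls = build_domain_calls(rec.id, sigs, mots, regions,
                                   cjid_by_seq.get(rec.id, ()), vocabulary,
                                   gap=merge_gap)
        out.append(classify(rec, calls, mots, regions, sigs, vocabulary))
    return out
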