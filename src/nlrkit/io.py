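"""Readers and writers for the external formats the pipeline touches.

FASTA, InterProScan-format TSV, FIMO-format TSV, MEME minimal motif files,
GFF3 feature output and plain TSV reports. All coordinates stay 1-based
inclusive; parsers are strict on their dialect and never silently drop
lines (malformed lines raise with a line number).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import MotifHit, ProteinRecord, SignatureHit

PathLike = Union[str, Path]

__all__ = [
    "read_fasta",
    "write_fasta",
    "parse_interproscan_tsv",
    "write_interproscan_tsv",
    "parse_fimo_tsv",
    "write_fimo_tsv",
    "read_meme_motifs",
    "write_meme_motifs",
    "write_gff3",
    "parse_gff3",
    "parse_cjid_domtbl",
]


# ---------------------------------------------------------------- FASTA

def read_fasta(path: PathLike, genus: Optional[str] = None) -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    Folded sequence lines are joined, whitespace stripped and letters
    uppercased. Duplicate IDs raise; an empty file returns an empty list
    with a warning.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence ID in {path}: {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq), genus=genus))
    if not records:
        warnings.warn(f"no FASTA records found in {path}", stacklevel=2)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: PathLike, width: int = 60) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


# ------------------------------------------------- InterProScan TSV

def _parse_float(field: str) -> Optional[float]:
    field = field.strip()
    if field in ("", "-"):
        return None
    return float(field)


def parse_interproscan_tsv(path: PathLike) -> list[SignatureHit]:
    """Parse the InterProScan v5 TSV dialect into :class:`SignatureHit` rows.

    Expected column order: id, md5, length, analysis, accession,
    description, start, stop, score, [status, date, InterPro accession,
    GO terms, ...]. Columns beyond the ninth are preserved as opaque text.
    """
    hits: list[SignatureHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise ValueError(
                    f"{path}:{lineno}: malformed InterProScan line "
                    f"({len(cols)} columns, need >= 9)"
                )
            try:
                start, stop = int(cols[6]), int(cols[7])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer start/stop "
                    f"({cols[6]!r}, {cols[7]!r})"
                ) from exc
            try:
                hit = SignatureHit(
                    seq_id=cols[0],
                    analysis=cols[3],
                    accession=cols[4],
                    start=start,
                    end=stop,
                    score=_parse_float(cols[8]),
                    description=cols[5],
                    extra="\t".join(cols[9:]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_interproscan_tsv(hits: Iterable[SignatureHit], path: PathLike,
                           seq_lengths: Optional[dict[str, int]] = None) -> None:
    """Emit hits in the InterProScan TSV column order (round-trips with
    :func:`parse_interproscan_tsv`)."""
    seq_lengths = seq_lengths or {}
    with open(path, "w") as fh:
        for h in hits:
            score = "-" if h.score is None else repr(h.score)
            cols = [
                h.seq_id, "-", str(seq_lengths.get(h.seq_id, 0)), h.analysis,
                h.accession, h.description, str(h.start), str(h.end), score,
            ]
            if h.extra:
                cols.append(h.extra)
            fh.write("\t".join(cols) + "\n")


# ------------------------------------------------------- FIMO TSV

_FIMO_HEADER = (
    "motif_id\tmotif_alt_id\tsequence_name\tstart\tstop\tstrand\t"
    "score\tp-value\tq-value\tmatched_sequence"
)


def _coerce_motif_id(text: str) -> int | str:
    try:
        return int(text)
    except ValueError:
        return text


def parse_fimo_tsv(path: PathLike) -> list[MotifHit]:
    """Parse the FIMO TSV dialect (header line tolerated, ``#`` comments
    skipped). The q-value column is mandatory: the downstream filter is
    defined on q-values."""
    hits: list[MotifHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if cols[0] == "motif_id":  # header
                if "q-value" not in cols and "qvalue" not in cols:
                    raise ValueError(
                        f"{path}:{lineno}: FIMO table lacks a q-value column; "
                        "q-values are required by the score/q-value filter "
                        "(rerun FIMO without --text)"
                    )
                continue
            if len(cols) < 10:
                raise ValueError(
                    f"{path}:{lineno}: malformed FIMO line ({len(cols)} columns, "
                    "need 10 incl. q-value; q-values are required by the filter)"
                )
            hits.append(MotifHit(
                seq_id=cols[2],
                motif_id=_coerce_motif_id(cols[0]),
                start=int(cols[3]),
                end=int(cols[4]),
                score=float(cols[6]),
                pvalue=float(cols[7]),
                qvalue=float(cols[8]),
                matched_seq=cols[9],
            ))
    return hits


def write_fimo_tsv(hits: Iterable[MotifHit], path: PathLike) -> None:
    """Emit motif hits in FIMO's TSV column layout (drop-in replacement for
    a real FIMO run; round-trips with :func:`parse_fimo_tsv`)."""
    with open(path, "w") as fh:
        fh.write(_FIMO_HEADER + "\n")
        for h in hits:
            fh.write("\t".join([
                str(h.motif_id), ".", h.seq_id, str(h.start), str(h.end), "+",
                repr(h.score), repr(h.pvalue), repr(h.qvalue), h.matched_seq,
            ]) + "\n")


# ------------------------------------------- MEME minimal motif format

def read_meme_motifs(path: PathLike):
    """Read position probability matrices from a MEME minimal-format file.

    Returns a list of :class:`nlrkit.motifs.PWM`. Each matrix row must sum
    to 1 within 1e-3, otherwise a validation error names the motif and row.

    The Biopython minimal-MEME reader renormalizes probabilities through a
    pseudo-count round trip, which would mask exactly the row-sum defects
    this reader must reject, so the (tiny) format is read directly.
    """
    from .motifs import PWM  # deferred to avoid a cycle

    alphabet = None
    background = None
    pwms = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    current_id: Optional[str] = None
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("ALPHABET="):
            alphabet = line.split("=", 1)[1].strip()
        elif line.startswith("Background letter frequencies"):
            freq_tokens: list[str] = []
            i += 1
            while i < len(lines) and lines[i].strip() and not lines[i].startswith("MOTIF"):
                freq_tokens.extend(lines[i].split())
                i += 1
            pairs = dict(zip(freq_tokens[::2], [float(x) for x in freq_tokens[1::2]]))
            if alphabet is None:
                alphabet = "".join(pairs)
            background = np.array([pairs[a] for a in alphabet])
            continue
        elif line.startswith("MOTIF"):
            current_id = line.split()[1]
        elif line.startswith("letter-probability matrix"):
            if alphabet is None:
                raise ValueError(f"{path}: letter-probability matrix before ALPHABET")
            # key=value parse of "alength= 20 w= 2 nsites= ..."
            tokens = line.split(":", 1)[1].split()
            kv = {}
            for j in range(0, len(tokens) - 1):
                if tokens[j].endswith("="):
                    kv[tokens[j][:-1]] = tokens[j + 1]
            width = int(kv.get("w", 0))
            rows = []
            i += 1
            while i < len(lines) and lines[i].strip() and not lines[i].startswith("MOTIF"):
                rows.append([float(x) for x in lines[i].split()])
                i += 1
            matrix = np.array(rows, dtype=float)
            if width and matrix.shape[0] != width:
                raise ValueError(
                    f"{path}: motif {current_id}: expected w={width} rows, "
                    f"got {matrix.shape[0]}"
                )
            if matrix.shape[1] != len(alphabet):
                raise ValueError(
                    f"{path}: motif {current_id}: {matrix.shape[1]} columns for "
                    f"a {len(alphabet)}-letter alphabet"
                )
            sums = matrix.sum(axis=1)
            bad = np.where(np.abs(sums - 1.0) > 1e-3)[0]
            if bad.size:
                raise ValueError(
                    f"{path}: motif {current_id}: probability row {bad[0] + 1} "
                    f"sums to {sums[bad[0]]:.4g}, not 1"
                )
            bg = background if background is not None else np.full(len(alphabet), 1.0 / len(alphabet))
            pwms.append(PWM(
                motif_id=_coerce_motif_id(current_id or str(len(pwms) + 1)),
                matrix=matrix,
                alphabet=alphabet,
                background=bg,
            ))
            continue
        i += 1
    return pwms


def write_meme_motifs(pwms, path: PathLike) -> None:
    """Write PWMs in MEME minimal format (round-trips with
    :func:`read_meme_motifs`)."""
    with open(path, "w") as fh:
        fh.write("MEME version 5\n\n")
        if pwms:
            fh.write(f"ALPHABET= {pwms[0].alphabet}\n\n")
            fh.write("Background letter frequencies\n")
            fh.write(" ".join(
                f"{a} {p:.6f}" for a, p in zip(pwms[0].alphabet, pwms[0].background)
            ) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= {pwm.matrix.shape[1]} "
                f"w= {pwm.matrix.shape[0]} nsites= 20 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


# ------------------------------------------------------------ GFF3

def write_gff3(records: Sequence[ProteinRecord], calls, path: PathLike,
               motif_hits: Sequence[MotifHit] = ()) -> None:
    """Write domain calls and retained motif hits as protein-space GFF3.

    One feature line per :class:`DomainCall` (type ``protein_match``,
    source = the first evidence database) and per motif hit (type
    ``sequence_motif``, source ``FIMO``), sorted by sequence then start.
    """
    known = {r.id for r in records}
    features = []
    for call in calls:
        if call.seq_id not in known:
            raise ValueError(f"domain call references unknown sequence {call.seq_id!r}")
        source = getattr(call.evidence[0], "analysis", "nlrkit")
        accs = ",".join(sorted({
            str(getattr(e, "accession", getattr(e, "motif_id", "?"))) for e in call.evidence
        }))
        attrs = f"category={call.category};accession={accs}"
        features.append((call.seq_id, call.start, call.end, source, "protein_match", attrs))
    for mh in motif_hits:
        if mh.seq_id not in known:
            raise ValueError(f"motif hit references unknown sequence {mh.seq_id!r}")
        attrs = (
            f"motif={mh.motif_id};score={mh.score:g};qvalue={mh.qvalue:g};"
            f"extraction_ok={'true' if mh.extraction_ok else 'false'}"
        )
        features.append((mh.seq_id, mh.start, mh.end, "FIMO", "sequence_motif", attrs))
    features.sort(key=lambda f: (f[0], f[1], -(f[2] - f[1])))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seq_id, start, end, source, ftype, attrs in features:
            fh.write(
                f"{seq_id}\t{source}\t{ftype}\t{start}\t{end}\t.\t.\t.\t{attrs}\n"
            )


def parse_gff3(path: PathLike) -> list[tuple[str, str, str, int, int, str]]:
    """Minimal GFF3 reader used for round-trip checks: returns
    (seqid, source, type, start, end, attributes) tuples."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: GFF3 line has {len(cols)} columns")
            out.append((cols[0], cols[1], cols[2], int(cols[3]), int(cols[4]), cols[8]))
    return out


# --------------------------------------------- HMMER domtblout (C-JID)

def parse_cjid_domtbl(path: PathLike) -> list[SignatureHit]:
    """Read C-JID domain hits from a HMMER ``--domtblout`` table.

    Only the envelope coordinates (columns 20-21) and the target name are
    used; the hits are lettered J in the architecture.
    """
    hits: list[SignatureHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 22:
                raise ValueError(
                    f"{path}:{lineno}: malformed domtblout line ({len(cols)} columns)"
                )
            hits.append(SignatureHit(
                seq_id=cols[0],
                analysis="HMMER",
                accession=cols[3] if cols[3] != "-" else "C-JID",
                start=int(cols[19]),
                end=int(cols[20]),
                score=float(cols[13]),
                evalue=float(cols[12]),
            ))
    return hits
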