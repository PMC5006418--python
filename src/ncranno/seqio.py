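"""Readers/writers and coordinate conventions shared by the whole pipeline.

All sequences are handled as uppercase DNA over ``{A,C,G,T,N}``; RNA input
(``U``) is mapped to ``T`` at read time so a single alphabet flows through the
scoring code.  Internal coordinates are 0-based half-open on the forward
strand; minus-strand features keep forward-strand coordinates plus a strand
flag.  Conversion to the 1-based inclusive GFF3 convention happens only in
:func:`write_annotations`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "RNA_CLASSES",
    "Contig",
    "QueryRecord",
    "SeedAlignment",
    "GenomicInterval",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_stockholm",
    "write_stockholm",
    "write_annotations",
    "reverse_complement",
    "normalize_wuss",
]

#: Fixed vocabulary of RNA classes used throughout the pipeline.
RNA_CLASSES = frozenset(
    {"miRNA", "rRNA", "snRNA", "snoRNA", "tRNA", "misc_RNA", "lncRNA"}
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_SEQ = re.compile(r"^[ACGTNU]*$")


class FormatError(ValueError):
    """Raised for malformed FASTA/Stockholm input; carries a line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


@dataclass(frozen=True)
class Contig:
    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class QueryRecord:
    """A query sequence tagged with its family, RNA class and source species.

    Headers follow the artifact convention ``>family|class|species``,
    e.g. ``>mir-124|miRNA|CIN``.
    """

    family_id: str
    rna_class: str
    species_tag: str
    sequence: str

    def __post_init__(self):
        if self.rna_class not in RNA_CLASSES:
            raise ValueError(
                f"unknown RNA class {self.rna_class!r}; expected one of "
                f"{sorted(RNA_CLASSES)}"
            )
        if not self.sequence:
            raise ValueError(f"empty sequence for query {self.family_id!r}")

    @property
    def id(self) -> str:
        return f"{self.family_id}|{self.rna_class}|{self.species_tag}"


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on the forward strand of one contig."""

    contig_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start},{self.end}) on {self.contig_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.contig_id != other.contig_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class SeedAlignment:
    """A family seed alignment with consensus secondary structure.

    ``rows`` maps sequence name to the aligned string (gap characters ``-``
    or ``.``); ``ss_cons`` is normalized to ``{'(', ')', '.'}``.
    """

    family_id: str
    rows: dict[str, str] = field(default_factory=dict)
    ss_cons: str = ""
    rna_class: str = "misc_RNA"

    @property
    def columns(self) -> int:
        return len(self.ss_cons)

    def validate(self) -> None:
        ncol = self.columns
        for name, aligned in self.rows.items():
            if len(aligned) != ncol:
                raise FormatError(
                    f"row {name!r} has {len(aligned)} columns, expected {ncol}"
                )
        _check_balanced(self.ss_cons)

    def pair_table(self) -> dict[int, int]:
        """Column pairing from ss_cons, both directions included."""
        stack: list[int] = []
        pairs: dict[int, int] = {}
        for i, c in enumerate(self.ss_cons):
            if c == "(":
                stack.append(i)
            elif c == ")":
                if not stack:
                    raise FormatError("unbalanced SS_cons: unmatched ')'")
                j = stack.pop()
                pairs[i] = j
                pairs[j] = i
        if stack:
            raise FormatError("unbalanced SS_cons: unmatched '('")
        return pairs


def _check_balanced(ss: str) -> None:
    depth = 0
    for c in ss:
        if c == "(":
            depth += 1
        elif c == ")":
            depth -= 1
            if depth < 0:
                raise FormatError("unbalanced SS_cons: unmatched ')'")
    if depth != 0:
        raise FormatError("unbalanced SS_cons: unmatched '('")


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; an involution, N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


def _normalize_sequence(raw: str, line: int) -> str:
    seq = raw.upper()
    if not _VALID_SEQ.match(seq):
        bad = sorted(set(seq) - set("ACGTNU"))
        raise FormatError(f"invalid sequence characters {bad}", line)
    return seq.replace("U", "T")


def read_fasta(path) -> list:
    """Read FASTA into :class:`Contig` or :class:`QueryRecord` objects.

    Headers of the form ``family|class|species`` (three ``|``-separated
    fields with a known RNA class) produce :class:`QueryRecord`; any other
    header produces :class:`Contig`.  Sequences are uppercased, U→T mapped,
    and characters outside ``{A,C,G,T,N,U}`` rejected with the offending
    line number.
    """
    records = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def _flush():
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"empty record {header!r}", header_line)
        parts = header.split("|")
        if len(parts) == 3 and parts[1] in RNA_CLASSES:
            records.append(QueryRecord(parts[0], parts[1], parts[2], seq))
        else:
            records.append(Contig(header, seq))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            stripped = raw.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                _flush()
                header = stripped[1:].split()[0] if stripped[1:].strip() else ""
                if not header:
                    raise FormatError("malformed FASTA header", lineno)
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FormatError("sequence before first header", lineno)
                chunks.append(_normalize_sequence(stripped, lineno))
    _flush()
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"duplicate record ids {dup}")
    return records


def write_fasta(records, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# WUSS pair symbols mapped onto plain brackets; everything else unpaired.
_WUSS_OPEN = set("(<[{")
_WUSS_CLOSE = set(")>]}")


def normalize_wuss(ss: str) -> str:
    """Map WUSS structure annotation to ``{'(', ')', '.'}`` and check balance."""
    out = []
    for c in ss:
        if c in _WUSS_OPEN:
            out.append("(")
        elif c in _WUSS_CLOSE:
            out.append(")")
        else:
            out.append(".")
    norm = "".join(out)
    _check_balanced(norm)
    return norm


def read_stockholm(path, family_id: str | None = None,
                   rna_class: str = "misc_RNA") -> SeedAlignment:
    """Parse a Stockholm 1.0 alignment with a ``#=GC SS_cons`` line.

    Interleaved blocks are concatenated.  The consensus structure is
    normalized from WUSS to plain brackets.  Missing SS_cons or unbalanced
    brackets raise :class:`FormatError` (covariance-model construction is
    impossible without a structure line).
    """
    rows: dict[str, list[str]] = {}
    ss_parts: list[str] = []
    saw_header = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if lineno == 1:
                if not line.startswith("# STOCKHOLM"):
                    raise FormatError("missing '# STOCKHOLM 1.0' header", lineno)
                saw_header = True
                continue
            if not line.strip() or line.startswith("//"):
                continue
            if line.startswith("#=GC"):
                parts = line.split()
                if len(parts) >= 3 and parts[1] == "SS_cons":
                    ss_parts.append(parts[2])
                continue
            if line.startswith("#=GF"):
                parts = line.split()
                if len(parts) >= 3 and parts[1] == "ID" and family_id is None:
                    family_id = parts[2]
                continue
            if line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError("malformed alignment line", lineno)
            name, chunk = parts
            rows.setdefault(name, []).append(chunk)
    if not saw_header:
        raise FormatError("empty Stockholm file")
    if not ss_parts:
        raise FormatError("no '#=GC SS_cons' line: cannot build structure models")
    if not rows:
        raise FormatError("Stockholm file contains no sequence rows")
    aln = SeedAlignment(
        family_id=family_id or "family",
        rows={name: "".join(chunks).upper().replace("U", "T")
              for name, chunks in rows.items()},
        ss_cons=normalize_wuss("".join(ss_parts)),
        rna_class=rna_class,
    )
    aln.validate()
    return aln


def write_stockholm(aln: SeedAlignment, path) -> None:
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        fh.write(f"#=GF ID {aln.family_id}\n")
        width = max([len(n) for n in aln.rows] + [len("#=GC SS_cons")]) + 2
        for name, aligned in aln.rows.items():
            fh.write(f"{name:<{width}}{aligned}\n")
        fh.write(f"{'#=GC SS_cons':<{width}}{aln.ss_cons}\n")
        fh.write("//\n")


def write_annotations(loci, genome, path_gff, path_tsv) -> None:
    """Write annotated loci as GFF3 (1-based inclusive) and a mirror TSV.

    Output is deterministic: sorted by contig id, start coordinate and
    family.  Intervals are validated against contig bounds.
    """
    lengths = {c.id: c.length for c in genome}
    ordered = sorted(
        loci, key=lambda l: (l.interval.contig_id, l.interval.start, l.family_id)
    )
    for locus in ordered:
        iv = locus.interval
        clen = lengths.get(iv.contig_id)
        if clen is None:
            raise ValueError(f"locus on unknown contig {iv.contig_id!r}")
        if iv.end > clen:
            raise ValueError(
                f"interval [{iv.start},{iv.end}) out of bounds for contig "
                f"{iv.contig_id} (length {clen})"
            )
    with open(path_gff, "w") as gff, open(path_tsv, "w") as tsv:
        gff.write("##gff-version 3\n")
        tsv.write(
            "contig\tstart\tend\tstrand\tfamily_id\trna_class\t"
            "evidence\tbitscore\tevalue\n"
        )
        for idx, locus in enumerate(ordered, start=1):
            iv = locus.interval
            evidence = ",".join(sorted(locus.evidence))
            attrs = (
                f"ID=ncrna{idx};family_id={locus.family_id};"
                f"evidence={evidence};bitscore={locus.bitscore:.2f};"
                f"evalue={locus.evalue:.3g}"
            )
            gff.write(
                f"{iv.contig_id}\tncranno\t{locus.rna_class}\t"
                f"{iv.start + 1}\t{iv.end}\t{locus.bitscore:.2f}\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )
            tsv.write(
                f"{iv.contig_id}\t{iv.start}\t{iv.end}\t{iv.strand}\t"
                f"{locus.family_id}\t{locus.rna_class}\t{evidence}\t"
                f"{locus.bitscore:.4f}\t{locus.evalue:.6g}\n"
            )
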