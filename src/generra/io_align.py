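"""Reading/writing standard formats and demultiplexing aligned reads.

Amplicon references come in as FASTA, alignments as SAM (one file per
library, gDNA or cDNA), and tabular outputs leave as TSV.  SAM's 1-based
reference starts are converted to 0-based half-open coordinates at the
parse boundary; everything downstream speaks 0-based half-open.

Reverse-strand alignments need no special handling: SAM stores SEQ in
reference-forward orientation, so CIGAR walking is always left-to-right
on the reference.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from Bio import SeqIO

logger = logging.getLogger("generra")

VALID_ALPHABET = frozenset("ACGTN")

#: CIGAR operation codes used internally.  '=' and 'X' are normalized to
#: 'M' at parse time; mismatch positions are recovered later by comparing
#: query bases against the reference, so no information is lost.
QUERY_CONSUMING = frozenset("MIS=X")
REF_CONSUMING = frozenset("MDN=X")


class FastaError(ValueError):
    """Malformed or invalid FASTA input."""


class SamError(ValueError):
    """Invalid SAM input (e.g. unknown reference name)."""


@dataclass(frozen=True)
class AmpliconRef:
    """One amplicon reference sequence.

    For a miRNA-response-element network experiment this is typically a
    ~200 bp window centred on the MRE seed (100 bp of flank either side).
    """

    name: str
    sequence: str
    source_window: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 10:
            raise FastaError(
                f"reference {self.name!r}: sequence shorter than 10 nt"
            )
        bad = set(self.sequence.upper()) - VALID_ALPHABET
        if bad:
            raise FastaError(
                f"reference {self.name!r}: invalid characters {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AlignedReadRecord:
    """One aligned sequencing read in reference-forward orientation.

    ``pos`` is the 0-based reference start.  ``cigar`` is a list of
    (length, op) tuples with op in {M, I, D, S, H}; '=' / 'X' have been
    folded into M.
    """

    ref_name: str
    pos: int
    cigar: list[tuple[int, str]]
    query: str
    library: str  # "gDNA" | "cDNA"
    mapped: bool = True
    name: str = ""

    def query_consumed(self) -> int:
        return sum(n for n, op in self.cigar if op in "MIS")

    def ref_span(self) -> tuple[int, int]:
        """0-based half-open reference interval covered by the alignment."""
        end = self.pos + sum(n for n, op in self.cigar if op in "MD")
        return self.pos, end


# ---------------------------------------------------------------------------
# FASTA references
# ---------------------------------------------------------------------------

def read_reference_set(fasta_source: str | Path) -> list[AmpliconRef]:
    """Parse an amplicon reference FASTA into a list of :class:`AmpliconRef`.

    Record order is preserved; duplicate identifiers are rejected.
    """
    path = Path(fasta_source)
    refs: list[AmpliconRef] = []
    seen: set[str] = set()
    with open(path) as fh:
        stripped = fh.read().strip()
    if stripped and not stripped.startswith(">"):
        first = stripped.splitlines()[0]
        raise FastaError(f"malformed FASTA {path}: line 1 ({first!r}) is not a header")
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # Bio raises assorted ValueError subclasses
        raise FastaError(f"malformed FASTA {path}: {exc}") from exc
    for rec in records:
        if rec.id in seen:
            raise FastaError(f"duplicate reference identifier {rec.id!r}")
        seen.add(rec.id)
        refs.append(AmpliconRef(name=rec.id, sequence=str(rec.seq),
                                source_window=rec.description if rec.description != rec.id else None))
    return refs


def write_reference_set(refs: Iterable[AmpliconRef], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ref in refs:
            fh.write(f">{ref.name}\n{ref.sequence}\n")


# ---------------------------------------------------------------------------
# SAM alignments
# ---------------------------------------------------------------------------

_OP_CODE = "MIDNSHP=X"


def _normalize_cigar(cigartuples: Sequence[tuple[int, int]]) -> list[tuple[int, str]]:
    """pysam (op, len) tuples -> internal (len, op) with =/X folded into M."""
    out: list[tuple[int, str]] = []
    for op_i, length in cigartuples:
        op = _OP_CODE[op_i]
        if op in "=X":
            op = "M"
        if out and out[-1][1] == op:
            out[-1] = (out[-1][0] + length, op)
        else:
            out.append((length, op))
    return out


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def _prescreen_sam_text(path: Path) -> Path | None:
    """Drop SAM text records whose CIGAR/query lengths disagree.

    htslib refuses to parse such records at all (aborting the whole
    file), so the arithmetic check runs on the raw text first; offending
    lines are removed with a warning and the remainder parsed normally.
    Returns a filtered temp file path, or None when nothing was dropped.
    """
    import tempfile

    with open(path, "rb") as fh:
        if fh.read(2) == b"\x1f\x8b":  # BAM/bgzf: htslib-validated upstream
            return None
    kept, dropped = [], 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("@") or not line.strip():
                kept.append(line)
                continue
            fields = line.rstrip("\n").split("\t")
            cigar, seq = fields[5], fields[9]
            if cigar != "*" and seq != "*":
                consumed = sum(
                    int(n) for n, op in _CIGAR_RE.findall(cigar) if op in "MIS=X"
                )
                if consumed != len(seq):
                    logger.warning(
                        "rejecting read %s: CIGAR consumes %d query bases "
                        "but query is %d nt", fields[0], consumed, len(seq),
                    )
                    dropped += 1
                    continue
            kept.append(line)
    if not dropped:
        return None
    tmp = tempfile.NamedTemporaryFile(
        "w", suffix=".sam", delete=False, dir=path.parent
    )
    tmp.writelines(kept)
    tmp.close()
    return Path(tmp.name)


def read_alignments(
    sam_source: str | Path,
    reference_set: Sequence[AmpliconRef],
    library_label: str,
) -> dict[str, list[AlignedReadRecord]]:
    """Read a SAM/BAM file and demultiplex mapped reads per amplicon.

    Unmapped records are dropped.  Records whose query-consuming CIGAR
    length disagrees with the query length are rejected with a warning.
    A record referencing a reference name absent from ``reference_set``
    raises :class:`SamError`.
    """
    if library_label not in ("gDNA", "cDNA"):
        raise ValueError(f"library_label must be 'gDNA' or 'cDNA', got {library_label!r}")
    known = {r.name for r in reference_set}
    out: dict[str, list[AlignedReadRecord]] = {}
    filtered = _prescreen_sam_text(Path(sam_source))
    source = filtered if filtered is not None else Path(sam_source)
    try:
        out = _parse_sam(source, known, library_label)
    finally:
        if filtered is not None:
            filtered.unlink(missing_ok=True)
    return out


def _parse_sam(
    sam_source: Path, known: set[str], library_label: str
) -> dict[str, list[AlignedReadRecord]]:
    out: dict[str, list[AlignedReadRecord]] = {}
    with pysam.AlignmentFile(str(sam_source), check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            ref_name = aln.reference_name
            if ref_name not in known:
                raise SamError(f"SAM record references unknown reference {ref_name!r}")
            cigar = _normalize_cigar(aln.cigartuples or [])
            query = aln.query_sequence or ""
            consumed = sum(n for n, op in cigar if op in "MIS")
            if consumed != len(query):
                logger.warning(
                    "rejecting read %s: CIGAR consumes %d query bases but query is %d nt",
                    aln.query_name, consumed, len(query),
                )
                continue
            out.setdefault(ref_name, []).append(
                AlignedReadRecord(
                    ref_name=ref_name,
                    pos=aln.reference_start,  # pysam is already 0-based
                    cigar=cigar,
                    query=query.upper(),
                    library=library_label,
                    mapped=True,
                    name=aln.query_name or "",
                )
            )
    return out


# ---------------------------------------------------------------------------
# Annotation tables and generic TSV output
# ---------------------------------------------------------------------------

def write_table(
    records: Iterable[Mapping] | pd.DataFrame,
    path: str | Path,
    schema: Sequence[str] | None = None,
) -> None:
    """Write records as a TSV with a header, sorted by the first column.

    Deterministic: column order follows ``schema`` (or the DataFrame's
    columns) and rows are sorted by the primary (first) column.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    if schema is not None:
        if df.empty:
            df = pd.DataFrame(columns=list(schema))
        else:
            missing = set(schema) - set(df.columns)
            if missing:
                raise ValueError(f"records missing schema columns {sorted(missing)}")
            df = df[list(schema)]
    if not df.empty:
        df = df.sort_values(by=df.columns[0], kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    # footprint codes are binary strings; keep pandas from reading them as ints
    dtype = {c: str for c in header if c in ("code", "barcode")}
    return pd.read_csv(path, sep="\t", dtype=dtype)


def read_seed_list(path: str | Path) -> list[str]:
    """Read a plain-text list of 7-mer miRNA seed-match sequences."""
    seeds = []
    with open(path) as fh:
        for line in fh:
            s = line.strip().upper()
            if not s or s.startswith("#"):
                continue
            if len(s) != 7 or set(s) - VALID_ALPHABET:
                raise ValueError(f"seed list entry {s!r} is not a 7-mer")
            seeds.append(s)
    return seeds
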