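"""Unique deletion patterns (UDPs) and UDP-normalized scores (UNS).

The core of the pipeline: each read's alignment is cropped to the ROI so
that polymorphisms outside the window cannot split otherwise-identical
deletion alleles; reads truncated inside the ROI, carrying insertions, or
with too many substitutions are discarded; survivors are encoded as binary
deletion footprints (1 = reference base deleted) and clustered into UDPs
with paired gDNA/cDNA read counts.  The effect of each UDP on transcript
abundance is its cDNA/gDNA count ratio normalized by the wild-type ratio:

    UNS = (cDNA_udp / gDNA_udp) / (cDNA_WT / gDNA_WT)

UNS > 1 means removing the deleted bases de-repressed the transcript (a
destabilizing element was ablated); UNS < 1 means a stabilizing element
was removed; UNS = 0 marks complete transcript loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .io_align import AlignedReadRecord
from .roi_profile import ROI

DEFAULT_MAX_MISMATCH_FRAC = 0.10
DEFAULT_MIN_UDP_READS = 10
DEFAULT_MIN_WT_READS = 100


class UnpairedUDPError(ValueError):
    """UDP lacks the gDNA reads (or WT counts) needed to compute a UNS."""


@dataclass(frozen=True)
class DeletionFootprint:
    """Binary deletion code over the ROI; '1' = reference base deleted."""

    code: str
    roi: ROI

    def __post_init__(self) -> None:
        if len(self.code) != len(self.roi):
            raise ValueError(
                f"footprint length {len(self.code)} != ROI length {len(self.roi)}"
            )
        if set(self.code) - {"0", "1"}:
            raise ValueError("footprint code must be binary")

    @property
    def is_wildtype(self) -> bool:
        return "1" not in self.code

    @property
    def n_deleted(self) -> int:
        return self.code.count("1")

    def deleted_positions(self) -> list[int]:
        """Absolute (reference) coordinates of deleted bases."""
        return [self.roi.start + i for i, c in enumerate(self.code) if c == "1"]


@dataclass
class UDP:
    """A unique deletion pattern with paired per-library read counts."""

    footprint: DeletionFootprint
    gdna_count: int
    cdna_count: int
    mutant_sequence: str

    @property
    def paired(self) -> bool:
        return self.gdna_count > 0 and self.cdna_count > 0


@dataclass
class WTRecord:
    """Wild-type (all-zero footprint) read counts and their ratio."""

    gdna_wt_count: int
    cdna_wt_count: int

    @property
    def wt_score(self) -> float:
        if self.gdna_wt_count <= 0:
            raise UnpairedUDPError("WT score undefined with zero gDNA WT reads")
        return self.cdna_wt_count / self.gdna_wt_count


@dataclass
class UNSRecord:
    udp: UDP
    uns: float
    weight: float = 0.0


@dataclass
class CroppedRead:
    """A read's alignment restricted to ROI columns.

    ``states[i]`` is 'M' (aligned), 'D' (deleted) or '.' (not covered);
    ``bases[i]`` holds the query base at aligned columns.
    """

    roi: ROI
    states: str
    bases: str
    truncated: bool
    has_insertion: bool

    def footprint_code(self) -> str:
        return "".join("1" if s == "D" else "0" for s in self.states)


# ---------------------------------------------------------------------------
# Cropping, filtering, footprints
# ---------------------------------------------------------------------------

def crop_to_roi(read: AlignedReadRecord, roi: ROI) -> CroppedRead:
    """Restrict a read's alignment to the ROI columns.

    A read is flagged truncated when its aligned span does not cover the
    whole ROI — it starts after roi.start, ends before roi.end, or is
    clipped inside the ROI (clips shorten the aligned span, so the span
    test covers them).  Insertions are only recorded when their junction
    falls strictly inside the ROI.
    """
    states = ["."] * len(roi)
    bases = [" "] * len(roi)
    has_insertion = False
    ref_pos = read.pos
    query_pos = 0
    for n, op in read.cigar:
        if op == "M":
            for k in range(n):
                p = ref_pos + k
                if roi.start <= p < roi.end:
                    states[p - roi.start] = "M"
                    bases[p - roi.start] = read.query[query_pos + k]
            ref_pos += n
            query_pos += n
        elif op == "D":
            for k in range(n):
                p = ref_pos + k
                if roi.start <= p < roi.end:
                    states[p - roi.start] = "D"
            ref_pos += n
        elif op == "I":
            if roi.start < ref_pos < roi.end:
                has_insertion = True
            query_pos += n
        elif op == "S":
            query_pos += n
        # H consumes neither
    span_start, span_end = read.ref_span()
    truncated = span_start > roi.start or span_end < roi.end
    return CroppedRead(
        roi=roi,
        states="".join(states),
        bases="".join(bases),
        truncated=truncated,
        has_insertion=has_insertion,
    )


def filter_read(
    cropped: CroppedRead,
    roi_wt_sequence: str,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> tuple[bool, str | None]:
    """Classify a cropped read as (keep, None) or (discard, reason).

    Reads truncated within the ROI and reads carrying insertions inside it
    are discarded outright; remaining reads are discarded when the fraction
    of mismatched bases among aligned (non-deleted) ROI positions exceeds
    ``max_mismatch_frac``.
    """
    if len(roi_wt_sequence) != len(cropped.roi):
        raise ValueError("ROI wild-type sequence length does not match ROI")
    if cropped.truncated:
        return False, "truncated"
    if cropped.has_insertion:
        return False, "insertion"
    aligned = mismatches = 0
    for state, base, wt in zip(cropped.states, cropped.bases, roi_wt_sequence):
        if state == "M":
            aligned += 1
            if base != wt:
                mismatches += 1
    if aligned > 0 and mismatches / aligned > max_mismatch_frac:
        return False, "mismatch"
    return True, None


def footprint(cropped: CroppedRead, roi: ROI) -> DeletionFootprint:
    """Binary deletion footprint of a filtered read over the ROI."""
    if cropped.roi != roi:
        raise ValueError("cropped read and ROI disagree")
    return DeletionFootprint(code=cropped.footprint_code(), roi=roi)


def mutant_sequence(code: str, roi_wt_sequence: str) -> str:
    """ROI sequence with the deleted bases removed."""
    return "".join(b for b, c in zip(roi_wt_sequence, code) if c == "0")


# ---------------------------------------------------------------------------
# Minimal single-deletion aligner (worked-example / desk checks)
# ---------------------------------------------------------------------------

def align_single_deletion(read: str, reference: str) -> list[tuple[int, str]]:
    """Align a read to a reference allowing substitutions and one internal
    deletion, minimizing mismatches; returns the CIGAR.

    Brute force over every placement of the single deletion — intended for
    short desk examples and as an entry point independent of upstream
    aligners, not for production alignment (BWA or similar is upstream).
    """
    read, reference = read.upper(), reference.upper()
    d = len(reference) - len(read)
    if d < 0:
        raise ValueError("read longer than reference: no pure-deletion alignment")
    if d == 0:
        return [(len(read), "M")]
    best: tuple[int, int] | None = None  # (mismatches, split point)
    for p in range(1, len(read)):  # internal: at least 1 matched base each side
        mm = sum(a != b for a, b in zip(read[:p], reference[:p]))
        mm += sum(a != b for a, b in zip(read[p:], reference[p + d:]))
        if best is None or mm < best[0]:
            best = (mm, p)
    assert best is not None
    p = best[1]
    return [(p, "M"), (d, "D"), (len(read) - p, "M")]


# ---------------------------------------------------------------------------
# Clustering and UNS
# ---------------------------------------------------------------------------

def _footprint_sort_key(code: str) -> tuple[int, int, str]:
    first = code.find("1")
    return (first if first >= 0 else len(code), code.count("1"), code)


def cluster_udps(
    gdna_footprints: Iterable[DeletionFootprint],
    cdna_footprints: Iterable[DeletionFootprint],
    roi_wt_sequence: str,
) -> tuple[list[UDP], WTRecord]:
    """Cluster per-read footprints into UDPs paired across libraries.

    The all-zero footprint populates the WT record rather than the UDP
    table.  UDPs are ordered by (first deleted position, deletion length,
    code) for deterministic output.  Count conservation holds:
    sum of UDP counts + WT count = kept reads, per library.
    """
    counts: dict[str, list[int]] = {}
    roi: ROI | None = None
    for lib_idx, fps in enumerate((gdna_footprints, cdna_footprints)):
        for fp in fps:
            roi = roi or fp.roi
            if fp.roi != roi:
                raise ValueError("footprints span different ROIs")
            counts.setdefault(fp.code, [0, 0])[lib_idx] += 1
    wt_code = "0" * len(roi_wt_sequence)
    wt_counts = counts.pop(wt_code, [0, 0])
    wt = WTRecord(gdna_wt_count=wt_counts[0], cdna_wt_count=wt_counts[1])
    udps = [
        UDP(
            footprint=DeletionFootprint(code=code, roi=roi),
            gdna_count=c[0],
            cdna_count=c[1],
            mutant_sequence=mutant_sequence(code, roi_wt_sequence),
        )
        for code, c in sorted(counts.items(), key=lambda kv: _footprint_sort_key(kv[0]))
    ]
    return udps, wt


def uns(udp: UDP, wt: WTRecord) -> UNSRecord:
    """UDP-normalized score: (cDNA/gDNA of the UDP) over the WT ratio.

    A UDP with gDNA reads but no cDNA reads scores 0 (complete transcript
    loss, as seen when a polyA signal is ablated).  UDPs without gDNA
    reads, or WT records with a zero count, cannot be scored.
    """
    if udp.gdna_count <= 0:
        raise UnpairedUDPError("UDP has no gDNA reads")
    if wt.gdna_wt_count <= 0 or wt.cdna_wt_count <= 0:
        raise UnpairedUDPError("WT counts must both be positive")
    ratio = udp.cdna_count / udp.gdna_count
    return UNSRecord(udp=udp, uns=ratio / wt.wt_score)


def uns_records(
    udps: Sequence[UDP], wt: WTRecord
) -> tuple[list[UNSRecord], list[dict]]:
    """Score every UDP that can be scored; collect the rest as exclusions."""
    records, exclusions = [], []
    for udp in udps:
        try:
            records.append(uns(udp, wt))
        except UnpairedUDPError as exc:
            exclusions.append(
                {"code": udp.footprint.code, "reason": str(exc),
                 "gdna_count": udp.gdna_count, "cdna_count": udp.cdna_count}
            )
    return records, exclusions


def apply_count_filters(
    records: Sequence[UNSRecord],
    wt: WTRecord,
    min_udp_reads: int = DEFAULT_MIN_UDP_READS,
    min_wt_reads: int = DEFAULT_MIN_WT_READS,
) -> tuple[list[UNSRecord], list[dict]]:
    """Depth filters: drop the amplicon when either WT count is below
    ``min_wt_reads``; drop UDPs with either count below ``min_udp_reads``.

    Thresholds are exclusive ("< 100", "< 10"): counts equal to the
    threshold are kept.  Returns (kept records, structured exclusions).
    """
    exclusions: list[dict] = []
    if wt.gdna_wt_count < min_wt_reads or wt.cdna_wt_count < min_wt_reads:
        exclusions.append(
            {"code": "*", "reason": "low_wt_reads",
             "gdna_count": wt.gdna_wt_count, "cdna_count": wt.cdna_wt_count}
        )
        return [], exclusions
    kept = []
    for rec in records:
        if rec.udp.gdna_count < min_udp_reads or rec.udp.cdna_count < min_udp_reads:
            exclusions.append(
                {"code": rec.udp.footprint.code, "reason": "low_udp_reads",
                 "gdna_count": rec.udp.gdna_count, "cdna_count": rec.udp.cdna_count}
            )
        else:
            kept.append(rec)
    return kept, exclusions


def replicate_concordance(
    records_rep1: Sequence[UNSRecord], records_rep2: Sequence[UNSRecord]
) -> tuple[float, float] | None:
    """OLS fit of replicate-2 UNS on replicate-1 UNS over shared UDPs.

    Returns (slope, R^2), or None when fewer than 3 UDPs are shared.
    Join is on footprint code, so both replicates must be computed over
    consensus ROI coordinates.
    """
    u1 = {r.udp.footprint.code: r.uns for r in records_rep1}
    shared = [
        (u1[r.udp.footprint.code], r.uns)
        for r in records_rep2
        if r.udp.footprint.code in u1
    ]
    if len(shared) < 3:
        return None
    x, y = zip(*shared)
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.rvalue**2)


# ---------------------------------------------------------------------------
# Read-level driver
# ---------------------------------------------------------------------------

def reads_to_footprints(
    reads: Iterable[AlignedReadRecord],
    roi: ROI,
    roi_wt_sequence: str,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> tuple[list[DeletionFootprint], list[dict]]:
    """Crop, filter and encode a read set; returns (footprints, discards)."""
    fps, discards = [], []
    for read in reads:
        cropped = crop_to_roi(read, roi)
        keep, reason = filter_read(cropped, roi_wt_sequence, max_mismatch_frac)
        if keep:
            fps.append(footprint(cropped, roi))
        else:
            discards.append({"name": read.name, "library": read.library, "reason": reason})
    return fps, discards
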