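"""Cumulative deletion profiles and region-of-interest (ROI) calling.

For each amplicon the fraction of reads carrying a deletion at every
reference nucleotide is computed from CIGAR strings, smoothed with a
normalized box kernel, and segmented into deletion peaks.  The ROI is the
union of the widest gDNA and cDNA peaks — the window expected to contain
the bulk of Cas9/NHEJ deletions.  Amplicons where neither library shows a
peak (inefficient mutagenesis) are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_align import AlignedReadRecord


class ROINotFoundError(ValueError):
    """Neither library yielded a deletion peak for this amplicon."""


@dataclass
class DeletionProfile:
    """Per-nucleotide percentage of reads with a deletion (0-100)."""

    ref_name: str
    values: np.ndarray
    n_reads: int


@dataclass(frozen=True)
class ROI:
    """0-based half-open region of interest on one amplicon."""

    ref_name: str
    start: int
    end: int
    source: str = "auto"  # auto | manual

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid ROI [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


def deletion_coverage(read: AlignedReadRecord) -> list[tuple[int, int]]:
    """Reference intervals (0-based half-open) covered by D ops."""
    intervals = []
    pos = read.pos
    for n, op in read.cigar:
        if op == "D":
            intervals.append((pos, pos + n))
        if op in "MD":
            pos += n
    return intervals


def deletion_profile(reads: list[AlignedReadRecord], ref_length: int) -> DeletionProfile:
    """Percentage of reads whose CIGAR places a deletion at each position."""
    if not reads:
        raise ValueError("no reads")
    counts = np.zeros(ref_length, dtype=float)
    for read in reads:
        for start, end in deletion_coverage(read):
            counts[max(start, 0):min(end, ref_length)] += 1
    values = 100.0 * counts / len(reads)
    return DeletionProfile(ref_name=reads[0].ref_name, values=values, n_reads=len(reads))


def smooth_profile(profile: DeletionProfile, kernel_width: int = 5) -> DeletionProfile:
    """Moving average with a normalized box kernel.

    Edges renormalize over the truncated window so a constant profile is a
    fixed point right up to the boundaries.
    """
    if kernel_width < 1 or kernel_width % 2 == 0:
        raise ValueError(f"kernel_width must be odd and positive, got {kernel_width}")
    if kernel_width == 1:
        return DeletionProfile(profile.ref_name, profile.values.copy(), profile.n_reads)
    kernel = np.ones(kernel_width)
    num = np.convolve(profile.values, kernel, mode="same")
    den = np.convolve(np.ones_like(profile.values), kernel, mode="same")
    return DeletionProfile(profile.ref_name, num / den, profile.n_reads)


def segment_deletion_regions(
    smoothed: DeletionProfile, min_signal: float = 0.5
) -> list[tuple[int, int]]:
    """Maximal intervals where the smoothed signal exceeds ``min_signal``.

    Interval boundaries are refined outward to the nearest sign change of
    the discrete first derivative, so each reported interval spans the
    full support of its peak rather than just the supra-threshold core.
    """
    s = smoothed.values
    above = s > min_signal
    if not above.any():
        return []
    # runs of consecutive True
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = [idx[0]] + [idx[b + 1] for b in breaks]
    ends = [idx[b] + 1 for b in breaks] + [idx[-1] + 1]

    refined: list[tuple[int, int]] = []
    for start, end in zip(starts, ends):
        # walk left while signal keeps rising into the run
        while start > 0 and s[start - 1] < s[start] and s[start - 1] > 0:
            start -= 1
        # walk right while signal keeps falling out of the run
        while end < len(s) and s[end] < s[end - 1] and s[end] > 0:
            end += 1
        refined.append((int(start), int(end)))
    # refinement can make neighbours touch; merge overlaps
    merged: list[tuple[int, int]] = []
    for start, end in refined:
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def _widest(intervals: list[tuple[int, int]], signal: np.ndarray) -> tuple[int, int] | None:
    """Widest interval; ties broken by larger total area, then leftmost."""
    if not intervals:
        return None
    return max(
        intervals,
        key=lambda iv: (iv[1] - iv[0], float(signal[iv[0]:iv[1]].sum()), -iv[0]),
    )


def call_roi(
    gdna_profile: DeletionProfile,
    cdna_profile: DeletionProfile,
    kernel_width: int = 5,
    min_signal: float = 0.5,
) -> ROI:
    """Call the ROI as the union of the widest gDNA and cDNA deletion peaks.

    If only one library shows a peak its widest interval is returned; if
    neither does, the amplicon is excluded via :class:`ROINotFoundError`.
    """
    picks = []
    for prof in (gdna_profile, cdna_profile):
        sm = smooth_profile(prof, kernel_width)
        iv = _widest(segment_deletion_regions(sm, min_signal), sm.values)
        if iv is not None:
            picks.append(iv)
    if not picks:
        raise ROINotFoundError(f"ROI not found for {gdna_profile.ref_name}")
    start = min(iv[0] for iv in picks)
    end = max(iv[1] for iv in picks)
    return ROI(ref_name=gdna_profile.ref_name, start=start, end=end, source="auto")
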