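"""MRE-scores: consensus activity of a miRNA response element.

UDPs are classified against the MRE annotation (seed-deleting when at
least one deleted base falls in the extended seed, positions 1-8 of the
site), UDPs that create de-novo seed matches for abundant miRNAs are
excluded, and the surviving seed-deleting UNS values are averaged with
weights proportional to gDNA sequencing depth:

    MRE-score = sum_i w_i * UNS_i,   w_i = gDNA_count_i / sum_j gDNA_count_j

Scores partition into low (< 2), medium (2-4) and high (> 4) groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .roi_profile import ROI
from .udp_uns import UDP, DeletionFootprint, UNSRecord

SEED_DELETING = "seed_deleting"
SEED_INTACT = "seed_intact"

GROUP_LOW_BELOW = 2.0
GROUP_HIGH_ABOVE = 4.0


@dataclass(frozen=True)
class MREAnnotation:
    """A miRNA response element on one amplicon.

    Intervals are 0-based half-open reference coordinates.  The extended
    seed (site positions 1-8, complementary to miRNA nucleotides 1-8) is 8
    nt and lies within the 22-nt binding region (site positions 1-22).
    ``D`` is the distance from the STOP codon to the seed and ``L`` the
    total 3'UTR length, both in nt.
    """

    gene: str
    mre_id: str
    seed_start: int
    seed_end: int
    binding_start: int
    binding_end: int
    site_type: str = "7mer-m8"
    D: int | None = None
    L: int | None = None

    def __post_init__(self) -> None:
        if self.seed_end - self.seed_start != 8:
            raise ValueError(f"{self.mre_id}: extended seed must be 8 nt")
        if self.binding_end - self.binding_start != 22:
            raise ValueError(f"{self.mre_id}: binding region must be 22 nt")
        if not (self.binding_start <= self.seed_start and self.seed_end <= self.binding_end):
            raise ValueError(f"{self.mre_id}: seed not inside binding region")
        if self.D is not None and self.L is not None and self.D > self.L:
            raise ValueError(f"{self.mre_id}: D > L")


@dataclass
class MREScoreResult:
    mre_id: str
    score: float
    n_udps: int
    group: str


def classify_seed_overlap(udp: UDP, mre: MREAnnotation) -> str:
    """'seed_deleting' iff the footprint removes >= 1 extended-seed base."""
    fp = udp.footprint
    if mre.seed_start < fp.roi.start or mre.seed_end > fp.roi.end:
        raise ValueError(
            f"{mre.mre_id}: seed interval [{mre.seed_start}, {mre.seed_end}) "
            f"outside ROI [{fp.roi.start}, {fp.roi.end})"
        )
    for pos in fp.deleted_positions():
        if mre.seed_start <= pos < mre.seed_end:
            return SEED_DELETING
    return SEED_INTACT


def is_distal_only(udp: UDP, mre: MREAnnotation) -> bool:
    """True for seed-deleting UDPs touching only the seed-distal
    nucleotides (site positions 1 and 8), sparing the core seed (2-7)."""
    hits = [
        p for p in udp.footprint.deleted_positions()
        if mre.seed_start <= p < mre.seed_end
    ]
    core = range(mre.seed_start + 1, mre.seed_end - 1)
    return bool(hits) and not any(p in core for p in hits)


def scan_de_novo_mres(
    mutant_sequence: str, wt_sequence: str, seed7mer_list: Sequence[str]
) -> list[str]:
    """Seed-match 7-mers present in the mutant ROI sequence but absent from
    the wild-type ROI sequence — deletions can juxtapose flanking bases
    into an ectopic miRNA site, which would distort the UNS.
    """
    mutant, wt = mutant_sequence.upper(), wt_sequence.upper()
    created = []
    for seed in seed7mer_list:
        if len(seed) != 7:
            raise ValueError(f"seed-match {seed!r} is not a 7-mer")
        s = seed.upper()
        if s in mutant and s not in wt:
            created.append(s)
    return created


def check_coincidental_rres(
    uns_with: Sequence[float], uns_without: Sequence[float]
) -> float | None:
    """Two-sided Wilcoxon rank-sum p-value comparing UNS distributions of
    UDPs with vs without a coincidental RRE deletion; None below n=3."""
    if len(uns_with) < 3 or len(uns_without) < 3:
        return None
    return float(stats.ranksums(uns_with, uns_without).pvalue)


def coincidental_rre_report(
    records: Sequence[UNSRecord],
    rre_intervals: Mapping[str, tuple[int, int]],
    alpha: float = 0.05,
) -> list[dict]:
    """Per-RRE rank-sum comparison of UNS for UDPs deleting vs sparing it.

    ``rre_intervals`` maps RRE name -> 0-based half-open reference
    interval (polyA signals, Pumilio elements, ARE/HuR motifs...).
    """
    out = []
    for name, (start, end) in rre_intervals.items():
        with_rre, without = [], []
        for rec in records:
            hit = any(start <= p < end for p in rec.udp.footprint.deleted_positions())
            (with_rre if hit else without).append(rec.uns)
        p = check_coincidental_rres(with_rre, without)
        out.append(
            {"rre": name, "n_with": len(with_rre), "n_without": len(without),
             "p_value": p, "flagged": bool(p is not None and p < alpha)}
        )
    return out


def assign_group(score: float) -> str:
    """low < 2, medium in [2, 4], high > 4 (boundaries go to medium)."""
    if score <= 0:
        raise ValueError(f"MRE-score must be positive, got {score}")
    if score < GROUP_LOW_BELOW:
        return "low"
    if score <= GROUP_HIGH_ABOVE:
        return "medium"
    return "high"


def _weights(records: Sequence[UNSRecord]) -> np.ndarray:
    counts = np.array([r.udp.gdna_count for r in records], dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("total gDNA count is zero")
    return counts / total


def mre_score(uns_records: Sequence[UNSRecord], mre_id: str = "") -> MREScoreResult:
    """gDNA-depth-weighted mean UNS over (filtered, seed-deleting,
    de-novo-clean) UDPs, with its group assignment.

    Raises ValueError on an empty record set — an MRE with no detectable
    seed deletions has no score and is excluded upstream.
    """
    if not uns_records:
        raise ValueError("no seed-deleting UDPs: MRE cannot be scored")
    w = _weights(uns_records)
    score = float(np.dot(w, [r.uns for r in uns_records]))
    for rec, wi in zip(uns_records, w):
        rec.weight = float(wi)
    return MREScoreResult(
        mre_id=mre_id, score=score, n_udps=len(uns_records), group=assign_group(score)
    )


def weighted_group_mean(
    uns_records: Sequence[UNSRecord],
    mre: MREAnnotation | None = None,
    restriction: str = "full_roi",
) -> float:
    """gDNA-count-weighted mean UNS over a restricted UDP set.

    ``restriction`` is 'full_roi' (all records) or 'binding_region_only',
    which keeps UDPs whose deletions all fall inside the 22-nt binding
    region (site positions 1-22).
    """
    if restriction not in ("full_roi", "binding_region_only"):
        raise ValueError(f"unknown restriction {restriction!r}")
    records = list(uns_records)
    if restriction == "binding_region_only":
        if mre is None:
            raise ValueError("binding_region_only restriction needs the MRE annotation")
        records = [
            r for r in records
            if all(mre.binding_start <= p < mre.binding_end
                   for p in r.udp.footprint.deleted_positions())
        ]
    if not records:
        raise ValueError("no records after restriction")
    w = _weights(records)
    return float(np.dot(w, [r.uns for r in records]))


def score_mre(
    records: Sequence[UNSRecord],
    mre: MREAnnotation,
    seed7mer_list: Sequence[str],
    wt_roi_sequence: str,
) -> tuple[MREScoreResult | None, list[dict]]:
    """Full per-MRE scoring: classify, exclude de-novo-site UDPs, score.

    Every input record lands exactly once in {scored, excluded-with-reason};
    the exclusion list carries seed-intact and de-novo-creating UDPs.
    """
    scored, exclusions = [], []
    for rec in records:
        cls = classify_seed_overlap(rec.udp, mre)
        if cls == SEED_INTACT:
            exclusions.append({"code": rec.udp.footprint.code, "reason": "seed_intact"})
            continue
        created = scan_de_novo_mres(rec.udp.mutant_sequence, wt_roi_sequence, seed7mer_list)
        if created:
            exclusions.append(
                {"code": rec.udp.footprint.code,
                 "reason": "de_novo_mre:" + ",".join(created)}
            )
            continue
        scored.append(rec)
    if not scored:
        exclusions.append({"code": "*", "reason": "no_seed_deleting_udps"})
        return None, exclusions
    return mre_score(scored, mre_id=mre.mre_id), exclusions
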