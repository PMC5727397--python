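"""Combinatorial editing patterns (CEPs) and MRE cooperativity.

When several MREs on one UTR are mutagenized together, each UDP is
summarized as a barcode with one character per annotated MRE in UTR
order: '-' when the deletion removes at least one base of that MRE's
interval, 'x' when the MRE is intact.  Complementary CEP triples
(disjoint deletion sets whose union is a third observed CEP) let the
observed combinatorial derepression be compared with the multiplicative
expectation from the two source CEPs — values above it indicate
cooperative MRE interactions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
from scipy import stats

from .udp_uns import DeletionFootprint, UNSRecord

DEFAULT_MIN_UDPS_PER_CEP = 10

DELETED = "-"
INTACT = "x"


@dataclass(frozen=True)
class CEP:
    barcode: str

    def __post_init__(self) -> None:
        if set(self.barcode) - {DELETED, INTACT}:
            raise ValueError(f"barcode {self.barcode!r} must be over {{'-','x'}}")

    @property
    def n_deleted(self) -> int:
        return self.barcode.count(DELETED)

    def deleted_set(self) -> frozenset[int]:
        return frozenset(i for i, c in enumerate(self.barcode) if c == DELETED)


@dataclass
class CEPGroup:
    cep: CEP
    uns_values: list[float]

    @property
    def n_udps(self) -> int:
        return len(self.uns_values)

    @property
    def mean_uns(self) -> float:
        return float(np.mean(self.uns_values))


def cep_barcode(
    footprint: DeletionFootprint, mre_intervals: Sequence[tuple[int, int]]
) -> CEP:
    """Barcode a footprint against MRE intervals given in UTR order.

    Character i is '-' iff the footprint deletes >= 1 base inside MRE i's
    interval (partial overlap counts), else 'x'.  Intervals are 0-based
    half-open in the same reference frame as the footprint.
    """
    deleted = footprint.deleted_positions()
    chars = []
    for start, end in mre_intervals:
        if start < footprint.roi.start or end > footprint.roi.end:
            raise ValueError(
                f"MRE interval [{start}, {end}) outside ROI "
                f"[{footprint.roi.start}, {footprint.roi.end})"
            )
        hit = any(start <= p < end for p in deleted)
        chars.append(DELETED if hit else INTACT)
    return CEP(barcode="".join(chars))


def group_by_cep(
    uns_records: Sequence[UNSRecord],
    mre_intervals: Sequence[tuple[int, int]],
    min_udps: int = DEFAULT_MIN_UDPS_PER_CEP,
) -> list[CEPGroup]:
    """Group UDPs by barcode; keep groups with more than ``min_udps``
    members (strict, per the '> 10 UDPs' filter)."""
    buckets: dict[str, list[float]] = {}
    for rec in uns_records:
        bc = cep_barcode(rec.udp.footprint, mre_intervals).barcode
        buckets.setdefault(bc, []).append(rec.uns)
    return [
        CEPGroup(cep=CEP(bc), uns_values=vals)
        for bc, vals in sorted(buckets.items())
        if len(vals) > min_udps
    ]


def mean_uns_by_n_deleted(groups: Sequence[CEPGroup]) -> dict[int, float]:
    """Aggregate mean UNS per number of deleted MREs (CEP complexity)."""
    buckets: dict[int, list[float]] = {}
    for g in groups:
        buckets.setdefault(g.cep.n_deleted, []).extend(g.uns_values)
    return {k: float(np.mean(v)) for k, v in sorted(buckets.items())}


def combine_barcodes(a: str, b: str) -> str | None:
    """CEP1 + CEP2 -> combinatorial barcode, or None when their deleted
    sets overlap (e.g. '--xxxxx' + 'xxxxx-x' = '--xxx-x')."""
    if len(a) != len(b):
        raise ValueError("barcodes differ in length")
    out = []
    for ca, cb in zip(a, b):
        if ca == DELETED and cb == DELETED:
            return None
        out.append(DELETED if DELETED in (ca, cb) else INTACT)
    return "".join(out)


def find_complementary_triples(
    groups: Sequence[CEPGroup],
) -> list[tuple[CEPGroup, CEPGroup, CEPGroup]]:
    """All (sourceA, sourceB, combinatorial) triples among retained groups.

    Sources have disjoint deleted-MRE sets and the combinatorial group's
    deleted set is exactly their union; all three groups must have passed
    the UDP-count filter.  Each unordered source pair appears once.
    """
    by_barcode = {g.cep.barcode: g for g in groups}
    triples = []
    ordered = sorted(by_barcode)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            if by_barcode[a].cep.n_deleted == 0 or by_barcode[b].cep.n_deleted == 0:
                continue
            combo = combine_barcodes(a, b)
            if combo is not None and combo in by_barcode:
                triples.append((by_barcode[a], by_barcode[b], by_barcode[combo]))
    return triples


def theoretical_combinatorial_uns(mean_a: float, mean_b: float) -> float:
    """Multiplicative (no-interaction) expectation: UNS values are fold
    derepressions, so independent effects multiply."""
    if mean_a <= 0 or mean_b <= 0:
        raise ValueError("source mean UNS values must be positive")
    return mean_a * mean_b


def cooperativity_test(
    combinatorial_uns_values: Sequence[float],
    source_a_values: Sequence[float],
    source_b_values: Sequence[float],
    alpha: float = 0.05,
) -> dict:
    """Test whether a combinatorial CEP exceeds the multiplicative
    expectation from its source CEPs.

    Primary statistic: two-sided Mann-Whitney U between the observed
    combinatorial UNS values and the pairwise product set {a_i * b_j} of
    source values.  Direction is 'cooperative' when the test is
    significant with observed median above the predicted point value,
    'additive' otherwise.  A one-sample Wilcoxon signed-rank against the
    predicted constant is reported as a secondary check.
    """
    obs = np.asarray(combinatorial_uns_values, dtype=float)
    a = np.asarray(source_a_values, dtype=float)
    b = np.asarray(source_b_values, dtype=float)
    predicted = theoretical_combinatorial_uns(float(a.mean()), float(b.mean()))
    if obs.size < 3 or a.size < 1 or b.size < 1:
        return {"predicted": predicted, "p_value": None,
                "p_wilcoxon": None, "direction": None,
                "observed_median": float(np.median(obs)) if obs.size else None}
    products = np.array([x * y for x, y in product(a, b)])
    p_mw = float(stats.mannwhitneyu(obs, products, alternative="two-sided").pvalue)
    diffs = obs - predicted
    p_w = (float(stats.wilcoxon(diffs).pvalue)
           if np.any(diffs != 0) else 1.0)
    direction = (
        "cooperative"
        if p_mw < alpha and float(np.median(obs)) > float(np.median(products))
        else "additive"
    )
    return {
        "predicted": predicted,
        "observed_median": float(np.median(obs)),
        "p_value": p_mw,
        "p_wilcoxon": p_w,
        "direction": direction,
    }
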