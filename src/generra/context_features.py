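"""Contextual features of miRNA response elements.

Sequence-context covariates expected to modulate MRE potency: local AU
content around the seed (distance-weighted sliding windows), seed
position within the UTR, GC content of the non-seed portion of the
binding region, RNA accessibility z-scores against a shuffled-sequence
baseline (folding backend injected; a toy AU-based backend ships so no
external folding tool is required), and the prevalence of co-targeting
miRNAs.  Feature trends across MRE-score groups are assessed with
pairwise rank-sum tests.

Externally computed features (pairing free energy, conservation, Pol-II
occupancy) are merged as precomputed per-MRE numeric columns.
"""

from __future__ import annotations

from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

AU = frozenset("ATU")
GC = frozenset("GC")


# ---------------------------------------------------------------------------
# Local AU content
# ---------------------------------------------------------------------------

def weighted_au_mean(window_values: Sequence[float], distances: Sequence[float]) -> float:
    """Distance-weighted mean of per-window AU fractions, w_i = 1/d_i.

    AU = sum_i (w_i / sum_j w_j) * AU_i
    """
    if len(window_values) != len(distances) or not window_values:
        raise ValueError("need matching, non-empty window values and distances")
    w = 1.0 / np.asarray(distances, dtype=float)
    return float(np.dot(w / w.sum(), np.asarray(window_values, dtype=float)))


def local_au_content(
    sequence: str, seed_start: int, seed_end: int, window: int = 5
) -> float:
    """Weighted AU fraction of the seed's flanking sequence.

    Sliding ``window``-nt windows (step 1) are taken over the sequence
    (nominally 200 bp centred on the seed); windows overlapping the seed
    are skipped.  Each window's AU fraction is weighted by 1/d where d is
    the distance from the window centre to the nearest seed boundary
    (floored at 1 nt).  Result is a fraction in [0, 1].
    """
    seq = sequence.upper()
    if seed_start < window or len(seq) - seed_end < window:
        raise ValueError("sequence too short: need >= one full window per flank")
    values, dists = [], []
    for a in range(0, len(seq) - window + 1):
        b = a + window
        if a < seed_end and b > seed_start:  # overlaps seed
            continue
        centre = a + window // 2
        if centre < seed_start:
            d = seed_start - centre
        else:
            d = centre - seed_end + 1
        values.append(sum(c in AU for c in seq[a:b]) / window)
        dists.append(max(d, 1))
    return weighted_au_mean(values, dists)


# ---------------------------------------------------------------------------
# Positional and compositional features
# ---------------------------------------------------------------------------

def seed_position_index(D: float, L: float) -> float:
    """| (D/L * 100) - 50 |: 0 for a UTR-centred seed, 50 at either end.

    D = distance from STOP codon to seed, L = total UTR length (nt).
    """
    if L <= 0 or D < 0 or D > L:
        raise ValueError(f"need 0 <= D <= L with L > 0, got D={D}, L={L}")
    return abs(D / L * 100.0 - 50.0)


def gc_content_9_22(mre_sequence_22nt: str) -> float:
    """Percent G+C over binding-site positions 9-22 (outside the extended
    seed), given the 22-nt site sequence oriented position 1 -> 22."""
    seq = mre_sequence_22nt.upper()
    if len(seq) != 22:
        raise ValueError(f"binding-region sequence must be 22 nt, got {len(seq)}")
    tail = seq[8:]
    return 100.0 * sum(c in GC for c in tail) / len(tail)


# ---------------------------------------------------------------------------
# Accessibility z-scores (pluggable folding backend)
# ---------------------------------------------------------------------------

def au_accessibility(sequence: str, window: int = 7) -> np.ndarray:
    """Toy accessibility backend: per-nucleotide AU fraction of itself and
    neighbouring bases within a centred window.  AU-rich stretches tend to
    be unstructured, so this mimics the shape (not the physics) of an
    unpaired-probability profile from an RNA folding tool."""
    seq = sequence.upper()
    flags = np.array([1.0 if c in AU else 0.0 for c in seq])
    half = window // 2
    out = np.empty(len(seq))
    for i in range(len(seq)):
        lo, hi = max(0, i - half), min(len(seq), i + half + 1)
        out[i] = flags[lo:hi].mean()
    return out


def accessibility_zscore(
    sequence: str,
    accessibility_fn: Callable[[str], np.ndarray],
    n_shuffles: int = 10_000,
    rng_seed: int = 0,
    seed_start: int | None = None,
    upstream_window: int = 25,
) -> tuple[np.ndarray, float | None]:
    """Per-position accessibility z-scores against a shuffled baseline.

    The whole sequence is shuffled ``n_shuffles`` times; the baseline mean
    and SD of accessibility at every position give
    z_p = (target_p - mean_p) / sd_p.  Positions with zero baseline SD get
    NaN.  When ``seed_start`` is given, the mean z over the
    ``upstream_window`` nt immediately upstream of the extended seed is
    returned as the aggregate (the stretch found most informative for MRE
    activity); otherwise the aggregate is None.
    """
    rng = np.random.default_rng(rng_seed)
    target = np.asarray(accessibility_fn(sequence), dtype=float)
    if target.shape != (len(sequence),):
        raise ValueError("accessibility_fn must return one value per nucleotide")
    chars = np.array(list(sequence))
    acc = np.empty((n_shuffles, len(sequence)))
    for i in range(n_shuffles):
        acc[i] = accessibility_fn("".join(rng.permutation(chars)))
    mean = acc.mean(axis=0)
    sd = acc.std(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (target - mean) / sd, np.nan)
    aggregate = None
    if seed_start is not None:
        lo = max(0, seed_start - upstream_window)
        win = z[lo:seed_start]
        finite = win[np.isfinite(win)]
        aggregate = float(finite.mean()) if finite.size else None
    return z, aggregate


# ---------------------------------------------------------------------------
# Co-targeting miRNAs
# ---------------------------------------------------------------------------

def cotargeting_prevalence(
    utr_sequence: str, seed7mer_lists_by_mirna: Mapping[str, Sequence[str]]
) -> int:
    """Number of distinct miRNAs with >= 1 seed-match 7-mer in the UTR.

    Multiple sites for one miRNA count once.
    """
    utr = utr_sequence.upper()
    count = 0
    for seeds in seed7mer_lists_by_mirna.values():
        if any(s.upper() in utr for s in seeds):
            count += 1
    return count


def cotargeting_percentage_by_group(
    counts: Sequence[int], group_labels: Sequence[str]
) -> dict[str, float]:
    """Per MRE-score group, the percentage of genes co-targeted by at
    least one other miRNA."""
    if len(counts) != len(group_labels):
        raise ValueError("counts and group labels must align")
    buckets: dict[str, list[int]] = {}
    for c, g in zip(counts, group_labels):
        buckets.setdefault(g, []).append(c)
    return {
        g: 100.0 * sum(1 for c in v if c >= 1) / len(v)
        for g, v in sorted(buckets.items())
    }


# ---------------------------------------------------------------------------
# Group trends
# ---------------------------------------------------------------------------

def feature_group_trend(
    feature_values: Sequence[float],
    group_labels: Sequence[str],
    group_order: Sequence[str] = ("low", "medium", "high"),
) -> dict:
    """Group medians, pairwise two-sided rank-sum p-values, and a flag for
    a monotonic median trend across the ordered groups.

    Groups with fewer than 3 members have their comparisons reported as
    None.  Raises when fewer than 2 groups are non-empty.
    """
    if len(feature_values) != len(group_labels):
        raise ValueError("feature values and group labels must align")
    buckets: dict[str, list[float]] = {g: [] for g in group_order}
    for v, g in zip(feature_values, group_labels):
        if g not in buckets:
            raise ValueError(f"unknown group label {g!r}")
        buckets[g].append(v)
    nonempty = [g for g in group_order if buckets[g]]
    if len(nonempty) < 2:
        raise ValueError("need at least 2 non-empty groups")
    medians = {g: float(np.median(buckets[g])) for g in nonempty}
    pvalues: dict[tuple[str, str], float | None] = {}
    for i, g1 in enumerate(group_order):
        for g2 in group_order[i + 1:]:
            if len(buckets[g1]) >= 3 and len(buckets[g2]) >= 3:
                pvalues[(g1, g2)] = float(stats.ranksums(buckets[g1], buckets[g2]).pvalue)
            else:
                pvalues[(g1, g2)] = None
    med_seq = [medians[g] for g in group_order if g in medians]
    increasing = all(a <= b for a, b in zip(med_seq, med_seq[1:]))
    decreasing = all(a >= b for a, b in zip(med_seq, med_seq[1:]))
    distinct = len(set(med_seq)) > 1
    return {
        "medians": medians,
        "p_values": pvalues,
        "monotonic": distinct and (increasing or decreasing),
    }


def merge_external_features(
    features: Mapping[str, Mapping[str, float]],
    external: Mapping[str, Mapping[str, float]],
) -> dict[str, dict[str, float]]:
    """Merge precomputed per-MRE numeric columns (e.g. pairing free
    energy, conservation, Pol-II occupancy) into a feature table keyed by
    mre_id."""
    out = {k: dict(v) for k, v in features.items()}
    for mre_id, cols in external.items():
        out.setdefault(mre_id, {}).update(cols)
    return out
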