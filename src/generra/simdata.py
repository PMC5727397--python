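"""Synthetic amplicon-sequencing data with known ground truth.

Emulates a Cas9/NHEJ mutagenesis experiment read out by paired gDNA and
cDNA amplicon sequencing: deletions are anchored at Cas9 cut sites and
extend away from the PAM, with lengths drawn from a geometric
distribution calibrated to the ~19-nt median observed for NHEJ deletions
in S2R+ cells; gDNA reads are a multinomial sample over the allele
frequencies; cDNA frequencies are the gDNA frequencies re-weighted by
each allele's fold-derepression effect E, so the expected UNS of every
simulated UDP equals its E by construction.  Uniform substitution errors
and wild-type read majorities are included.

Everything is deterministic under a fixed seed, so the generator doubles
as the ground-truth oracle for pipeline round-trip and parameter-recovery
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_align import AmpliconRef
from .mre_score import MREAnnotation

BASES = np.array(list("ACGT"))


def _default_mres() -> list[MREAnnotation]:
    # one MRE centred on a 200-nt amplicon: extended seed [96,104),
    # 22-nt binding region [96,118)
    return [MREAnnotation(gene="simgene", mre_id="sim-mre-1",
                          seed_start=96, seed_end=104,
                          binding_start=96, binding_end=118,
                          D=96, L=200)]


def _default_cuts() -> list[tuple[int, str]]:
    # two seed-adjacent cuts (deletions extend into the seed) and one
    # distal control cut producing seed-intact alleles
    return [(104, "right"), (96, "left"), (140, "left")]


@dataclass
class SimConfig:
    """Study conditions for one simulated amplicon.

    ``cut_sites`` are (position, pam_side) pairs; deletions start at the
    cut and extend away from the PAM ('left' PAM -> rightward deletion).
    ``true_effects`` maps the footprint class ('seed_deleting' /
    'seed_intact') to the fold-derepression E; with several MREs hit, the
    per-MRE effects multiply, scaled by cooperativity_factor**(k-1).
    """

    rng_seed: int = 0
    amplicon_length: int = 200
    mre_layout: list[MREAnnotation] = field(default_factory=_default_mres)
    cut_sites: list[tuple[int, str]] = field(default_factory=_default_cuts)
    median_deletion_length: int = 19
    editing_rate: float = 0.5
    true_effects: dict[str, float] = field(
        default_factory=lambda: {"seed_deleting": 1.0, "seed_intact": 1.0}
    )
    # per-UDP biological heterogeneity: each allele's effect is its class
    # mean times a mean-preserving lognormal factor exp(sigma*Z - sigma^2/2);
    # 0 gives every allele exactly its class effect
    effect_sigma: float = 0.0
    cooperativity_factor: float = 1.0
    depth: int = 10_000
    mismatch_rate: float = 0.002
    n_udps: int = 40
    dirichlet_alpha: float = 1.0
    # amplicon named after the gene: in an MRE-network experiment each
    # amplicon is the window around one gene's MRE, so annotation rows
    # join to amplicons on this name
    combinatorial_fraction: float = 0.0  # fraction of UDPs pairing two cuts
    ref_name: str = "simgene"

    def __post_init__(self) -> None:
        if not (0 <= self.editing_rate < 1):
            raise ValueError("editing_rate must be in [0, 1)")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        for pos, side in self.cut_sites:
            if not (0 < pos < self.amplicon_length):
                raise ValueError(f"cut site {pos} outside amplicon")
            if side not in ("left", "right"):
                raise ValueError(f"pam_side must be 'left' or 'right', got {side!r}")
        for e in self.true_effects.values():
            if e < 0:
                raise ValueError("effects must be >= 0")


@dataclass
class UdpTruth:
    """One simulated deletion allele with its generative parameters."""

    intervals: tuple[tuple[int, int], ...]  # 0-based half-open deletions
    frequency: float
    effect: float
    gdna_count: int = 0
    cdna_count: int = 0

    def code(self, length: int) -> str:
        chars = ["0"] * length
        for start, end in self.intervals:
            for p in range(start, end):
                chars[p] = "1"
        return "".join(chars)


@dataclass
class SimBundle:
    config: SimConfig
    reference: AmpliconRef
    repertoire: list[UdpTruth]
    wt_gdna: int
    wt_cdna: int
    gdna_sam: str
    cdna_sam: str


def geometric_deletion_lengths(
    median: int, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Geometric deletion lengths (minimum 1) hitting the target median."""
    if median < 1:
        raise ValueError("median must be >= 1")
    if median == 1:
        p = 0.6
    else:
        p = 1.0 - 0.5 ** (1.0 / (median - 0.5))
    return rng.geometric(p, size=size)


def _deletion_interval(
    cut: int, pam_side: str, length: int, amplicon_length: int
) -> tuple[int, int]:
    """Deletion extending away from the PAM, clipped to the amplicon
    interior (at least one flanking matched base on each side)."""
    if pam_side == "left":
        start, end = cut, cut + length
    else:
        start, end = cut - length, cut
    start = max(start, 1)
    end = min(end, amplicon_length - 1)
    if end <= start:  # degenerate after clipping; keep 1 nt at the cut
        start, end = (cut, cut + 1) if pam_side == "left" else (cut - 1, cut)
    return start, end


def effect_for_intervals(
    intervals: tuple[tuple[int, int], ...], config: SimConfig
) -> float:
    """Fold-derepression of an allele: per-MRE effects multiply over the
    MREs whose extended seed it hits, times cooperativity_factor**(k-1)."""
    e_seed = config.true_effects.get("seed_deleting", 1.0)
    e_other = config.true_effects.get("seed_intact", 1.0)
    k = 0
    for mre in config.mre_layout:
        hit = any(s < mre.seed_end and e > mre.seed_start for s, e in intervals)
        if hit:
            k += 1
    if k == 0:
        return e_other
    return (e_seed**k) * (config.cooperativity_factor ** (k - 1))


def simulate_udp_repertoire(
    config: SimConfig, rng: np.random.Generator | None = None
) -> list[UdpTruth]:
    """Draw a repertoire of distinct deletion alleles with frequencies.

    Cut sites are cycled; lengths are geometric around the configured
    median; Dirichlet-distributed frequencies carry total mass
    ``editing_rate`` (wild type keeps the rest).  With
    ``combinatorial_fraction`` > 0, that fraction of alleles combines
    deletions at two distinct cut sites (multiplexed sgRNA pools).
    """
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    if config.editing_rate == 0 or config.n_udps == 0:
        return []
    seen: set[tuple[tuple[int, int], ...]] = set()
    alleles: list[tuple[tuple[int, int], ...]] = []
    n_cuts = len(config.cut_sites)
    attempts = 0
    while len(alleles) < config.n_udps and attempts < config.n_udps * 50:
        attempts += 1
        if n_cuts >= 2 and rng.random() < config.combinatorial_fraction:
            i, j = rng.choice(n_cuts, size=2, replace=False)
            picks = [int(i), int(j)]
        else:
            picks = [int(rng.integers(n_cuts))]
        ivs = []
        for idx in picks:
            cut, side = config.cut_sites[idx]
            length = int(geometric_deletion_lengths(
                config.median_deletion_length, 1, rng)[0])
            ivs.append(_deletion_interval(cut, side, length, config.amplicon_length))
        ivs.sort()
        merged: list[tuple[int, int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        key = tuple(merged)
        if key not in seen:
            seen.add(key)
            alleles.append(key)
    freqs = rng.dirichlet(np.full(len(alleles), config.dirichlet_alpha))
    freqs = freqs * config.editing_rate
    s = config.effect_sigma
    scatter = (np.exp(s * rng.standard_normal(len(alleles)) - s**2 / 2)
               if s > 0 else np.ones(len(alleles)))
    return [
        UdpTruth(intervals=iv, frequency=float(f),
                 effect=effect_for_intervals(iv, config) * float(sc))
        for iv, f, sc in zip(alleles, freqs, scatter)
    ]


def simulate_counts(
    repertoire: list[UdpTruth],
    wt_frequency: float,
    depth: int,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Multinomial gDNA and effect-weighted multinomial cDNA counts.

    Fills each UdpTruth's counts in place and returns the WT pair.  cDNA
    probabilities are frequency * E renormalized (WT has E = 1), so the
    expected UNS of every allele equals its E — the normalization cancels
    in the UNS ratio.
    """
    freqs = np.array([wt_frequency] + [u.frequency for u in repertoire])
    freqs = freqs / freqs.sum()
    effects = np.array([1.0] + [u.effect for u in repertoire])
    gdna = rng.multinomial(depth, freqs)
    cdna_p = freqs * effects
    cdna_p = cdna_p / cdna_p.sum()
    cdna = rng.multinomial(depth, cdna_p)
    for u, g, c in zip(repertoire, gdna[1:], cdna[1:]):
        u.gdna_count = int(g)
        u.cdna_count = int(c)
    return int(gdna[0]), int(cdna[0])


def _random_reference(length: int, rng: np.random.Generator, name: str) -> AmpliconRef:
    seq = "".join(rng.choice(BASES, size=length))
    return AmpliconRef(name=name, sequence=seq, source_window="synthetic")


def _cigar_string(intervals: tuple[tuple[int, int], ...], length: int) -> str:
    if not intervals:
        return f"{length}M"
    parts = []
    pos = 0
    for start, end in intervals:
        if start > pos:
            parts.append(f"{start - pos}M")
        parts.append(f"{end - start}D")
        pos = end
    if pos < length:
        parts.append(f"{length - pos}M")
    return "".join(parts)


def _read_sequence(
    reference: str,
    intervals: tuple[tuple[int, int], ...],
    mismatch_rate: float,
    rng: np.random.Generator,
) -> str:
    kept = []
    deleted = set()
    for s, e in intervals:
        deleted.update(range(s, e))
    for i, base in enumerate(reference):
        if i in deleted:
            continue
        kept.append(base)
    seq = np.array(kept)
    if mismatch_rate > 0:
        hits = np.flatnonzero(rng.random(len(seq)) < mismatch_rate)
        for h in hits:
            others = [b for b in "ACGT" if b != seq[h]]
            seq[h] = others[int(rng.integers(3))]
    return "".join(seq)


def emit_sam(
    repertoire: list[UdpTruth],
    wt_count: int,
    reference: AmpliconRef,
    library: str,
    mismatch_rate: float,
    rng: np.random.Generator,
) -> str:
    """Render one library's reads as SAM text (reads span the amplicon)."""
    length = len(reference)
    lines = [
        "@HD\tVN:1.6\tSO:unsorted",
        f"@SQ\tSN:{reference.name}\tLN:{length}",
    ]
    def add(intervals: tuple[tuple[int, int], ...], count: int, tag: str) -> None:
        cigar = _cigar_string(intervals, length)
        for i in range(count):
            seq = _read_sequence(reference.sequence, intervals, mismatch_rate, rng)
            lines.append(
                f"{library}_{tag}_{i}\t0\t{reference.name}\t1\t60\t{cigar}"
                f"\t*\t0\t0\t{seq}\t*"
            )
    add((), wt_count, "wt")
    for u_idx, u in enumerate(repertoire):
        count = u.gdna_count if library == "gDNA" else u.cdna_count
        add(u.intervals, count, f"udp{u_idx}")
    return "\n".join(lines) + "\n"


def simulate_experiment(config: SimConfig) -> SimBundle:
    """Run the full generative model for one amplicon.

    Deterministic under ``config.rng_seed``: identical configs give
    byte-identical SAM text.
    """
    rng = np.random.default_rng(config.rng_seed)
    reference = _random_reference(config.amplicon_length, rng, config.ref_name)
    repertoire = simulate_udp_repertoire(config, rng)
    wt_gdna, wt_cdna = simulate_counts(
        repertoire, 1.0 - config.editing_rate, config.depth, rng
    )
    gdna_sam = emit_sam(repertoire, wt_gdna, reference, "gDNA",
                        config.mismatch_rate, rng)
    cdna_sam = emit_sam(repertoire, wt_cdna, reference, "cDNA",
                        config.mismatch_rate, rng)
    return SimBundle(config=config, reference=reference, repertoire=repertoire,
                     wt_gdna=wt_gdna, wt_cdna=wt_cdna,
                     gdna_sam=gdna_sam, cdna_sam=cdna_sam)


def simulate_replicates(config: SimConfig, n: int = 2) -> list[SimBundle]:
    """Independent count draws from one generative truth (shared
    reference, repertoire and effects; fresh sampling noise per
    replicate)."""
    base_rng = np.random.default_rng(config.rng_seed)
    reference = _random_reference(config.amplicon_length, base_rng, config.ref_name)
    repertoire = simulate_udp_repertoire(config, base_rng)
    bundles = []
    for rep in range(n):
        rep_rng = np.random.default_rng((config.rng_seed, rep))
        rep_repertoire = [
            UdpTruth(intervals=u.intervals, frequency=u.frequency, effect=u.effect)
            for u in repertoire
        ]
        wt_g, wt_c = simulate_counts(
            rep_repertoire, 1.0 - config.editing_rate, config.depth, rep_rng
        )
        bundles.append(SimBundle(
            config=config, reference=reference, repertoire=rep_repertoire,
            wt_gdna=wt_g, wt_cdna=wt_c,
            gdna_sam=emit_sam(rep_repertoire, wt_g, reference, "gDNA",
                              config.mismatch_rate, rep_rng),
            cdna_sam=emit_sam(rep_repertoire, wt_c, reference, "cDNA",
                              config.mismatch_rate, rep_rng),
        ))
    return bundles


def simulate_cooperativity_dataset(
    effect_a: float,
    effect_b: float,
    cooperativity: float,
    n_source: int = 30,
    n_combinatorial: int = 30,
    sigma: float = 0.25,
    rng: np.random.Generator | int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-UDP UNS draws for two source CEPs and their combinatorial CEP.

    Each UNS is its true effect under multiplicative lognormal noise
    (sigma on the log scale).  A combinatorial value is
    cooperativity * E_a * E_b times the product of two independent noise
    terms, so under cooperativity = 1 it is distributed exactly like a
    product of one source-A and one source-B draw — the additive null of
    the cooperativity test.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    a = effect_a * np.exp(sigma * rng.standard_normal(n_source))
    b = effect_b * np.exp(sigma * rng.standard_normal(n_source))
    comb = (cooperativity * effect_a * effect_b
            * np.exp(sigma * rng.standard_normal(n_combinatorial))
            * np.exp(sigma * rng.standard_normal(n_combinatorial)))
    return a, b, comb


def write_bundle(bundle: SimBundle, outdir: str | Path) -> dict[str, Path]:
    """Write ref.fa, gdna.sam, cdna.sam, mres.tsv and truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ref": outdir / "ref.fa",
        "gdna": outdir / "gdna.sam",
        "cdna": outdir / "cdna.sam",
        "mres": outdir / "mres.tsv",
        "truth": outdir / "truth.tsv",
    }
    ref = bundle.reference
    paths["ref"].write_text(f">{ref.name}\n{ref.sequence}\n")
    paths["gdna"].write_text(bundle.gdna_sam)
    paths["cdna"].write_text(bundle.cdna_sam)
    mre_rows = ["gene\tmre_id\tseed_start\tseed_end\tbinding_start\tbinding_end\tsite_type\tD\tL"]
    for m in bundle.config.mre_layout:
        mre_rows.append(f"{m.gene}\t{m.mre_id}\t{m.seed_start}\t{m.seed_end}"
                        f"\t{m.binding_start}\t{m.binding_end}\t{m.site_type}\t{m.D}\t{m.L}")
    paths["mres"].write_text("\n".join(mre_rows) + "\n")
    truth_rows = ["code\tfrequency\teffect\tgdna_count\tcdna_count"]
    for u in bundle.repertoire:
        truth_rows.append(
            f"{u.code(len(ref))}\t{u.frequency:.6g}\t{u.effect:.6g}"
            f"\t{u.gdna_count}\t{u.cdna_count}"
        )
    paths["truth"].write_text("\n".join(truth_rows) + "\n")
    return paths
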