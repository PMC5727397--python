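"""End-to-end pipeline driver: ingest -> ROI -> UDP/UNS -> MRE-scores.

Per-amplicon failures (no deletion peak, low wild-type depth) become
structured exclusion records; the run only fails when every amplicon
does.  A manifest recording thresholds and seeds accompanies the outputs
so a run can be reproduced exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import io_align, roi_profile, udp_uns
from .io_align import AmpliconRef
from .mre_score import MREAnnotation, score_mre
from .roi_profile import ROI, ROINotFoundError
from .udp_uns import UNSRecord, WTRecord

logger = logging.getLogger("generra")


@dataclass
class RunConfig:
    ref_fasta: str
    gdna_sam: str
    cdna_sam: str
    outdir: str
    mre_table: str | None = None
    seed_list: str | None = None
    min_udp_reads: int = udp_uns.DEFAULT_MIN_UDP_READS
    min_wt_reads: int = udp_uns.DEFAULT_MIN_WT_READS
    max_mismatch_frac: float = udp_uns.DEFAULT_MAX_MISMATCH_FRAC
    kernel_width: int = 5
    min_signal: float = 0.5
    roi_overrides: dict[str, tuple[int, int]] = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.min_udp_reads <= 0 or self.min_wt_reads <= 0:
            raise ValueError("count thresholds must be positive")


@dataclass
class AmpliconResult:
    ref: AmpliconRef
    roi: ROI
    records: list[UNSRecord]
    wt: WTRecord
    exclusions: list[dict]


def read_mre_table(path: str | Path) -> list[MREAnnotation]:
    df = pd.read_csv(path, sep="\t")
    return [
        MREAnnotation(
            gene=str(r.gene), mre_id=str(r.mre_id),
            seed_start=int(r.seed_start), seed_end=int(r.seed_end),
            binding_start=int(r.binding_start), binding_end=int(r.binding_end),
            site_type=str(getattr(r, "site_type", "7mer-m8")),
            D=int(r.D) if "D" in df.columns else None,
            L=int(r.L) if "L" in df.columns else None,
        )
        for r in df.itertuples()
    ]


def process_amplicon(
    ref: AmpliconRef,
    gdna_reads: list,
    cdna_reads: list,
    config: RunConfig,
) -> AmpliconResult:
    """ROI calling, footprint encoding, clustering and UNS for one amplicon."""
    if ref.name in config.roi_overrides:
        start, end = config.roi_overrides[ref.name]
        roi = ROI(ref_name=ref.name, start=start, end=end, source="manual")
    else:
        gprof = roi_profile.deletion_profile(gdna_reads, len(ref))
        cprof = roi_profile.deletion_profile(cdna_reads, len(ref))
        roi = roi_profile.call_roi(gprof, cprof, config.kernel_width, config.min_signal)
    roi_seq = ref.sequence[roi.start:roi.end]
    g_fps, g_disc = udp_uns.reads_to_footprints(
        gdna_reads, roi, roi_seq, config.max_mismatch_frac)
    c_fps, c_disc = udp_uns.reads_to_footprints(
        cdna_reads, roi, roi_seq, config.max_mismatch_frac)
    udps, wt = udp_uns.cluster_udps(g_fps, c_fps, roi_seq)
    records, unpaired = udp_uns.uns_records(udps, wt)
    kept, excluded = udp_uns.apply_count_filters(
        records, wt, config.min_udp_reads, config.min_wt_reads)
    total_gdna = sum(r.udp.gdna_count for r in kept)
    for r in kept:
        r.weight = r.udp.gdna_count / total_gdna if total_gdna else 0.0
    exclusions = unpaired + excluded
    for d in exclusions:
        d["ref_name"] = ref.name
    return AmpliconResult(ref=ref, roi=roi, records=kept, wt=wt,
                          exclusions=exclusions)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write the result tables.

    Returns a summary dict; raises RuntimeError only when every amplicon
    fails.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    refs = io_align.read_reference_set(config.ref_fasta)
    gdna = io_align.read_alignments(config.gdna_sam, refs, "gDNA")
    cdna = io_align.read_alignments(config.cdna_sam, refs, "cDNA")

    results: dict[str, AmpliconResult] = {}
    all_exclusions: list[dict] = []
    udp_rows: list[dict] = []
    roi_rows: list[str] = []
    for ref in refs:
        g_reads = gdna.get(ref.name, [])
        c_reads = cdna.get(ref.name, [])
        try:
            res = process_amplicon(ref, g_reads, c_reads, config)
        except (ROINotFoundError, ValueError) as exc:
            all_exclusions.append(
                {"ref_name": ref.name, "code": "*", "reason": str(exc),
                 "gdna_count": len(g_reads), "cdna_count": len(c_reads)}
            )
            logger.warning("amplicon %s excluded: %s", ref.name, exc)
            continue
        all_exclusions.extend(res.exclusions)
        if any(d["reason"] == "low_wt_reads" for d in res.exclusions):
            logger.warning("amplicon %s excluded: wild-type depth below %d",
                           ref.name, config.min_wt_reads)
            continue
        results[ref.name] = res
        roi_rows.append(f"{ref.name}\t{res.roi.start}\t{res.roi.end}\t{res.roi.source}")
        for rec in res.records:
            udp_rows.append({
                "ref_name": ref.name,
                "roi": f"{res.roi.start}-{res.roi.end}",
                "code": rec.udp.footprint.code,
                "gdna_count": rec.udp.gdna_count,
                "cdna_count": rec.udp.cdna_count,
                "uns": rec.uns,
                "weight": rec.weight,
            })
    if refs and not results:
        raise RuntimeError("all amplicons failed or were excluded")

    io_align.write_table(
        udp_rows, outdir / "udp_table.tsv",
        schema=["ref_name", "roi", "code", "gdna_count", "cdna_count", "uns", "weight"],
    )
    io_align.write_table(
        all_exclusions, outdir / "exclusions.tsv",
        schema=["ref_name", "code", "reason", "gdna_count", "cdna_count"],
    )
    (outdir / "rois.bed").write_text("\n".join(roi_rows) + ("\n" if roi_rows else ""))

    score_rows: list[dict] = []
    if config.mre_table:
        mres = read_mre_table(config.mre_table)
        seeds = io_align.read_seed_list(config.seed_list) if config.seed_list else []
        by_ref: dict[str, list[MREAnnotation]] = {}
        for m in mres:
            by_ref.setdefault(m.gene, []).append(m)
        for ref_name, res in results.items():
            for mre in by_ref.get(ref_name, []):
                roi_seq = res.ref.sequence[res.roi.start:res.roi.end]
                try:
                    result, excl = score_mre(res.records, mre, seeds, roi_seq)
                except ValueError as exc:
                    logger.warning("MRE %s not scored: %s", mre.mre_id, exc)
                    continue
                if result is not None:
                    score_rows.append({
                        "mre_id": result.mre_id, "score": result.score,
                        "n_udps": result.n_udps, "group": result.group,
                    })
        io_align.write_table(
            score_rows, outdir / "mre_scores.tsv",
            schema=["mre_id", "score", "n_udps", "group"],
        )

    manifest = {
        "config": {k: v for k, v in asdict(config).items()},
        "n_amplicons": len(refs),
        "n_amplicons_scored": len(results),
        "n_udps": len(udp_rows),
        "n_exclusions": len(all_exclusions),
        "n_mre_scores": len(score_rows),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
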