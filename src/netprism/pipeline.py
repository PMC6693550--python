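"""End-to-end pipeline: filters -> tracks -> metrics/profiles/enhancers.

A :class:`RunConfig` collects every path and parameter; :func:`run_pipeline`
executes the stages in order and writes a manifest with a SHA-256 checksum
for every output, so two runs with the same config and inputs can be
compared byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass

import pandas as pd

from . import annotation, enhancers as enh_mod, metrics, profiles, reads, tracks

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, reason: str):
        super().__init__(f"stage {stage!r} failed: {reason}")
        self.stage = stage
        self.reason = reason


@dataclass
class RunConfig:
    bam: str = ""
    gtf: str = ""
    chrom_sizes: str = ""
    enhancers_bed: str = ""
    super_enhancers_bed: str = ""
    reference_fasta: str = ""
    outdir: str = "netprism_out"
    # read filtering
    umi_tag: str = "RX"
    mapq_min: int = 10
    polarity: str = "antisense"
    primer: str = ""
    primer_k: int = 6
    # tracks
    normalize: bool = True
    smooth_window: int = 10
    # metrics
    promoter_window: tuple[int, int] = (-30, 250)
    body_start: int = 300
    body_end_offset: int = 200
    tr_mode: str = "density"
    upstream_clash_bp: int = 2500
    rpkm_threshold: float = 1.0
    # profiles
    tss_half_width: int = 1000
    artifact_span: int = 100
    artifact_frac: float = 0.8
    artifact_mode: str = "heuristic"
    ci: str = "normal95"
    # enhancers
    distal_window_bp: int = 2000

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest dict (also written to disk)."""
    cfg = config
    for stage, path in [("inputs", cfg.bam), ("inputs", cfg.gtf),
                        ("inputs", cfg.chrom_sizes)]:
        if not path or not os.path.exists(path):
            raise PipelineError(stage, f"missing required input file: {path!r}")
    os.makedirs(cfg.outdir, exist_ok=True)
    outputs: list[str] = []

    def out(name: str) -> str:
        path = os.path.join(cfg.outdir, name)
        outputs.append(path)
        return path

    with open(out("config.json"), "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=2, sort_keys=True)

    # annotation
    try:
        genes = annotation.read_gtf(cfg.gtf)
        chrom_sizes = annotation.read_chrom_sizes(cfg.chrom_sizes)
        model = annotation.GenomeModel(chrom_sizes, genes)
        model.validate()
    except Exception as exc:
        raise PipelineError("annotation", str(exc)) from exc
    terminals = annotation.terminal_nucleotides(genes)

    # read filters
    try:
        positions, report = reads.process_alignments(
            cfg.bam,
            terminals,
            reference_path=cfg.reference_fasta or None,
            primer_prefix=cfg.primer,
            k=cfg.primer_k,
            polarity=cfg.polarity,
            umi_tag=cfg.umi_tag,
            mapq_min=cfg.mapq_min,
        )
    except Exception as exc:
        raise PipelineError("reads", str(exc)) from exc
    with open(out("filter_report.json"), "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    _write_tsv(
        pd.DataFrame(positions, columns=["chrom", "pos", "strand"]),
        out("positions.tsv"),
    )

    # tracks
    raw = tracks.build_track(positions, chrom_sizes)
    if cfg.normalize and raw.n_positions > 0:
        track = tracks.normalize_1x(raw)
    else:
        if cfg.normalize:
            logger.warning("empty library: 1x normalization skipped")
        track = raw
    tracks.write_bedgraph(track, out("coverage.plus.bedgraph"),
                          out("coverage.minus.bedgraph"))

    # gene-level metrics on the promoter-clash-free set
    clean_genes = annotation.promoter_clash_filter(
        genes, cfg.upstream_clash_bp, chrom_sizes
    )
    tr_records = [
        metrics.travelling_ratio(
            g, track, cfg.promoter_window, cfg.body_start, cfg.body_end_offset,
            mode=cfg.tr_mode,
        )
        for g in clean_genes
    ]
    _write_tsv(
        pd.DataFrame(
            [
                {
                    "gene_id": r.gene_id,
                    "promoter_density": r.promoter_density,
                    "body_density": r.body_density,
                    "tr": r.tr,
                    "reason": r.reason,
                }
                for r in tr_records
            ]
        ),
        out("tr.tsv"),
    )
    defined = [r for r in tr_records if r.defined]
    if defined:
        _write_tsv(metrics.tr_cumulative(tr_records), out("tr_ecdf.tsv"))

    # exon / intron densities (internal exons only)
    exon_feats = [r for g in genes for r in annotation.internal_exons(g)]
    intron_feats = [r for g in genes for r in annotation.derive_introns(g)]
    dens = metrics.feature_density(exon_feats, track, "exon") + metrics.feature_density(
        intron_feats, track, "intron"
    )
    _write_tsv(
        pd.DataFrame(
            [
                {"feature_id": d.feature_id, "kind": d.kind, "length": d.length,
                 "density": d.density}
                for d in dens
            ]
        ),
        out("density.tsv"),
    )

    # sense / antisense directionality
    _write_tsv(
        metrics.sense_antisense_split(positions, clean_genes),
        out("directionality.tsv"),
    )

    # TSS metaplot with artifact-row filtering
    anchors = profiles.tss_anchors(clean_genes)
    meta_written = False
    if anchors:
        for channel in ("sense", "antisense"):
            mat = profiles.build_matrix(track, anchors, cfg.tss_half_width, channel)
            mat, removed = profiles.artifact_row_filter(
                mat, cfg.artifact_span, cfg.artifact_frac, cfg.artifact_mode
            )
            mp = profiles.metaplot(mat, cfg.smooth_window, cfg.ci)
            _write_tsv(mp, out(f"metaplot_tss.{channel}.tsv"))
            if removed:
                logger.info("TSS %s matrix: removed artifact rows %s", channel, removed)
        meta_written = True
    if not meta_written:
        logger.warning("no genes for metaplots")

    # enhancers (optional inputs)
    if cfg.enhancers_bed or cfg.super_enhancers_bed:
        typical = (
            annotation.read_bed(cfg.enhancers_bed, "typical")
            if cfg.enhancers_bed and os.path.exists(cfg.enhancers_bed)
            else []
        )
        super_ = (
            annotation.read_bed(cfg.super_enhancers_bed, "super")
            if cfg.super_enhancers_bed and os.path.exists(cfg.super_enhancers_bed)
            else []
        )
        merged = enh_mod.resolve_enhancer_classes(typical, super_)
        distal = annotation.select_distal_enhancers(merged, genes, cfg.distal_window_bp)
        if raw.n_positions > 0:
            gated = metrics.filter_by_rpkm(
                distal, raw, raw.n_positions, cfg.rpkm_threshold
            )
        else:
            gated = []
        table = enh_mod.enhancer_density(track, gated) if gated else pd.DataFrame(
            columns=["enhancer_id", "class", "density"]
        )
        _write_tsv(table, out("enhancer_density.tsv"))
        if gated and {"distal", "super"} <= set(table["class"]):
            res = enh_mod.class_comparison(table, "density")
            with open(out("enhancer_test.json"), "w") as fh:
                json.dump(res, fh, indent=2, sort_keys=True)

    manifest = {
        "outputs": {
            os.path.basename(p): _sha256(p) for p in outputs if os.path.exists(p)
        },
        "n_retained_positions": len(positions),
    }
    with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
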