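"""End-to-end pipeline: genotyping maps -> coverage -> blocks -> BLUP ->
QTL scan -> WAF, with a JSON manifest of inputs, parameters and outputs."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import genome_stats, io, marker_map, pheno_stats, qtl_blocks
from .bin_map import BinCallingParams, infer_segments
from .genome import segments_to_frame
from .qtl_blocks import QtlScanParams

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; earlier outputs are preserved on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths and parameters of a full run.  Any of snp/marker/phenotype
    inputs may be omitted; downstream stages that need them are skipped."""

    genome: str
    outdir: str
    snp_input: str | None = None
    marker_input: str | None = None
    phenotype_input: str | None = None
    donor_id: str = "donor"
    recipient_id: str = "recipient"
    bin_params: BinCallingParams = field(default_factory=BinCallingParams)
    qtl_params: QtlScanParams = field(default_factory=QtlScanParams)
    waf_anchor_trait: str | None = None
    waf_traits: list[str] | None = None
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "bin_params" in raw:
            raw["bin_params"] = BinCallingParams(**raw["bin_params"])
        if "qtl_params" in raw:
            raw["qtl_params"] = QtlScanParams(**raw["qtl_params"])
        return cls(**raw)

    def params_dict(self) -> dict:
        d = asdict(self)
        return d


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Execute all configured stages; returns {artifact name: path}.

    Stage order: mm-map (markers), gr-map (SNPs), coverage, blocks, blup,
    qtl, waf.  A stage failure raises :class:`PipelineError` naming the
    stage; artifacts already written stay on disk.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    inputs: dict[str, str] = {"genome": config.genome}

    def _write(name: str, fname: str, writer) -> None:
        path = outdir / fname
        writer(path)
        outputs[name] = str(path)

    genome = io.read_genome_table(config.genome)

    mm_segments = None
    if config.marker_input:
        try:
            marker_table = io.read_marker_tsv(config.marker_input)
            inputs["markers"] = config.marker_input
            mm_segments = marker_map.call_marker_segments(marker_table, genome)
            _write("mm_segments", "mm_segments.tsv",
                   lambda p: marker_map.marker_segments_to_frame(mm_segments).to_csv(p, sep="\t", index=False))
            _write("mm_summary", "mm_summary.tsv",
                   lambda p: marker_map.mm_summary(mm_segments, genome).to_csv(p, sep="\t", index=False))
            if genome.cm is not None:
                cov = genome_stats.union_coverage(mm_segments, genome, unit="cm")
                _write("mm_coverage", "mm_coverage.tsv", lambda p: cov.to_csv(p, sep="\t", index=False))
        except Exception as e:  # noqa: BLE001
            raise PipelineError("mm-map", e) from e

    gr_segments = None
    if config.snp_input:
        try:
            snp_table = io.read_snp_input(config.snp_input, config.donor_id, config.recipient_id)
            inputs["snps"] = config.snp_input
            bins, gr_segments = infer_segments(snp_table, genome, config.bin_params)
            _write("bins", "bins.tsv", lambda p: io.write_bed_like(io.bins_to_frame(bins), p))
            _write("gr_segments", "gr_segments.tsv",
                   lambda p: io.write_bed_like(segments_to_frame(gr_segments), p))
        except Exception as e:  # noqa: BLE001
            raise PipelineError("gr-map", e) from e

        try:
            cov = genome_stats.union_coverage(gr_segments, genome, unit="bp")
            cov["fold_coverage"] = genome_stats.fold_coverage(gr_segments, genome)
            counts = {c: len(snp_table.positions[c]) for c in snp_table.chroms}
            dens = genome_stats.density_stats(counts, genome, mode="snp")
            _write("gr_coverage", "gr_coverage.tsv", lambda p: cov.to_csv(p, sep="\t", index=False))
            _write("snp_density", "snp_density.tsv", lambda p: dens.to_csv(p, sep="\t", index=False))
        except Exception as e:  # noqa: BLE001
            raise PipelineError("coverage", e) from e

    blocks = None
    if gr_segments is not None:
        try:
            blocks = qtl_blocks.partition_blocks(gr_segments, genome)
            lines = sorted({s.line for s in gr_segments}) or list(snp_table.lines)
            _write("blocks", "blocks.tsv",
                   lambda p: io.write_bed_like(qtl_blocks.blocks_to_frame(blocks), p))
            _write("carriers", "carriers.tsv",
                   lambda p: qtl_blocks.carrier_matrix(blocks, snp_table.lines).to_csv(p, sep="\t"))
        except Exception as e:  # noqa: BLE001
            raise PipelineError("blocks", e) from e

    if config.phenotype_input:
        try:
            pheno = io.read_phenotypes(config.phenotype_input)
            inputs["phenotypes"] = config.phenotype_input
            blup = pheno_stats.fit_blup(pheno)
            _write("blups", "blups.csv", lambda p: blup.blups.to_csv(p, index_label="line"))
            _write("heritability", "heritability.csv", lambda p: blup.h2_frame().to_csv(p, index=False))
            r, pv, flags = pheno_stats.trait_correlations(blup.blups)
            _write("correlations", "correlations.csv", lambda p: r.to_csv(p))
            _write("correlation_flags", "correlation_flags.csv", lambda p: flags.to_csv(p))
        except Exception as e:  # noqa: BLE001
            raise PipelineError("blup", e) from e

        if blocks is not None:
            try:
                blups_g = blup.blups.reindex(snp_table.lines).dropna()
                qtl = qtl_blocks.scan_qtl(blocks, blups_g, config.qtl_params)
                _write("qtl", "qtl.tsv", lambda p: qtl.to_csv(p, sep="\t", index=False))
            except Exception as e:  # noqa: BLE001
                raise PipelineError("qtl", e) from e

            try:
                waf_out = _waf_stage(blocks, blups_g, blup, config)
                if waf_out is not None:
                    _write("waf", "waf.tsv", lambda p: io.write_bed_like(waf_out, p))
            except Exception as e:  # noqa: BLE001
                raise PipelineError("waf", e) from e
        else:
            logger.info("no SNP-based blocks available; QTL and WAF stages skipped")
    else:
        logger.info("no phenotypes configured; BLUP/QTL/WAF stages skipped")

    manifest_path = outdir / "manifest.json"
    io.write_manifest(manifest_path, inputs, config.params_dict(), outputs)
    outputs["manifest"] = str(manifest_path)
    return outputs


def _waf_stage(blocks, blups_g: pd.DataFrame, blup, config: PipelineConfig) -> pd.DataFrame | None:
    """Per-block WAF over the traits positively correlated with the anchor
    trait (default: the first trait)."""
    anchor = config.waf_anchor_trait or blups_g.columns[0]
    if anchor not in blups_g.columns:
        raise KeyError(f"WAF anchor trait {anchor!r} not among traits")
    r, _, _ = pheno_stats.trait_correlations(blups_g)
    traits = config.waf_traits or [
        t for t in blups_g.columns if r.loc[anchor, t] > 0 and pd.notna(blup.h2.get(t))
    ]
    if not traits:
        return None
    # full per-block additive-effect matrix: scan with no LOD threshold
    params = QtlScanParams(
        p_in=config.qtl_params.p_in,
        p_out=config.qtl_params.p_out,
        lod_threshold=0.0,
        lod_cap=config.qtl_params.lod_cap,
        donor_positive=config.qtl_params.donor_positive,
    )
    full = qtl_blocks.scan_qtl(blocks, blups_g[traits], params)
    additive = full.pivot_table(index="block", columns="trait", values="additive_effect")
    waf = pheno_stats.compute_waf(
        additive, r.loc[anchor, traits], {t: blup.h2[t] for t in traits}
    )
    return pheno_stats.waf_track(waf, blocks)
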