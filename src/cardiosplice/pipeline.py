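"""End-to-end orchestration: filter -> count -> RPKM -> DEG -> splice ->
enrich -> motif, with one JSON config, TSV outputs and a run manifest.

Each stage is a pure function of (inputs, config) that reads its
upstream tables from the run directory and writes its own, so any stage
can be re-run standalone on cached outputs; re-running with the same
config reproduces every file byte for byte (the run manifest records
seed and config but no timestamps — timings go to the log only).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import read_exon_bed
from .diffexpr import (call_degs, classify_opposite, classify_turned_on,
                       flag_degs)
from .enrichment import PathwayDB, enrich_categories, heat_matrix
from .motifscan import extract_upstream, motif_enrichment
from .quantify import (CONTRASTS, compute_rpkm, expressed_genes,
                       load_experiment)
from .splicing import detect_exon_variants, summarize_variant_types

log = logging.getLogger("cardiosplice")

STAGES = ("quantify", "deg", "splice", "enrich", "motif")


@dataclass
class PipelineConfig:
    """Paths, thresholds and flags for a pipeline run.

    Threshold defaults are the study's stated values: 2 RPKM expression
    floor, 10 RPKM exon floor, alpha 0.05, |log1.5 FC| >= 1, Bayes error
    <= 0.1, >= 5 query genes per reported pathway.
    """

    annotation: str
    manifest: str
    genome: str | None = None
    gmt: str | None = None

    rpkm_floor: float = 2.0
    exon_rpkm_min: float = 10.0
    alpha: float = 0.05
    min_abs_log15fc: float = 1.0
    bayes_e_max: float = 0.1
    min_pathway_k: int = 5

    drop_chrm: bool = True
    chrm_name: str = "chrM"
    bh_correction: bool = False
    expressed_mode: str = "any_replicate"
    fc_pseudocount: float = 0.25
    log_rpkb_pseudocount: float = 1.0
    equal_var: bool = True
    bayes_method: str = "quad"

    motifs: tuple[str, ...] = ("GGGAGGG", "CCCTCCC")
    motif_foreground: str = "opposite"   # or "turned_on"
    upstream_length: int = 1000

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rpkm_floor", "exon_rpkm_min", "min_abs_log15fc",
                     "bayes_e_max", "min_pathway_k"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "motifs" in data:
            data["motifs"] = tuple(data["motifs"])
        base = Path(path).parent
        for key in ("annotation", "manifest", "genome", "gmt"):
            if data.get(key) and not Path(data[key]).is_absolute():
                data[key] = str(base / data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["motifs"] = list(d["motifs"])
        return d


def _samples_of(samples: pd.DataFrame, condition: str) -> list[str]:
    return samples.loc[samples["condition"] == condition, "sample_id"].tolist()


def _read_tsv(path: Path, index_col: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


# -- stages -----------------------------------------------------------------

def stage_quantify(config: PipelineConfig, outdir: Path) -> dict:
    """Filter reads, count exons/genes, normalize to RPKM, find the
    expressed-gene universe."""
    annotation = read_exon_bed(config.annotation)
    exon_counts, gene_counts, samples = load_experiment(
        config.manifest, annotation,
        drop_chrm=config.drop_chrm, chrm_name=config.chrm_name)
    mapped = samples.set_index("sample_id")["mapped_reads_total"]
    rpkm_gene = compute_rpkm(gene_counts, annotation.gene_lengths(), mapped)
    rpkm_exon = compute_rpkm(exon_counts, annotation.exon_lengths(), mapped)
    expressed = expressed_genes(rpkm_gene, samples, floor=config.rpkm_floor,
                                mode=config.expressed_mode)
    exon_counts.to_csv(outdir / "counts_exon.tsv", sep="\t", index_label="exon_id")
    gene_counts.to_csv(outdir / "counts_gene.tsv", sep="\t", index_label="gene_id")
    rpkm_gene.to_csv(outdir / "rpkm_gene.tsv", sep="\t",
                     index_label="gene_id", float_format="%.8g")
    rpkm_exon.to_csv(outdir / "rpkm_exon.tsv", sep="\t",
                     index_label="exon_id", float_format="%.8g")
    samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    with open(outdir / "expressed_genes.tsv", "w") as fh:
        fh.write("condition\tgene_id\n")
        for cond in sorted(expressed):
            for g in sorted(expressed[cond]):
                fh.write(f"{cond}\t{g}\n")
    return {"n_samples": len(samples), "n_genes": len(gene_counts),
            "n_exons": len(exon_counts),
            "expressed_per_condition": {c: len(s)
                                        for c, s in sorted(expressed.items())}}


def stage_deg(config: PipelineConfig, outdir: Path) -> dict:
    """Call DEGs for both contrasts and classify turned-on/opposite genes."""
    rpkm_gene = _read_tsv(outdir / "rpkm_gene.tsv", "gene_id")
    samples = pd.read_csv(outdir / "samples.tsv", sep="\t")
    degs = {}
    for name, (ctrl_cond, trt_cond) in CONTRASTS.items():
        degs[name] = call_degs(
            rpkm_gene, _samples_of(samples, ctrl_cond),
            _samples_of(samples, trt_cond), alpha=config.alpha,
            min_abs_log15fc=config.min_abs_log15fc, floor=config.rpkm_floor,
            pseudocount=config.fc_pseudocount, equal_var=config.equal_var,
            bh_correction=config.bh_correction)
    exercise = _samples_of(samples, "exercise")
    turned_on = classify_turned_on(
        degs["PAH"], rpkm_gene, _samples_of(samples, "sham"),
        _samples_of(samples, "TAC"), exercise or None,
        floor=config.rpkm_floor)
    opposite = classify_opposite(degs["PAH"], degs["PHH"])
    for name, df in degs.items():
        flag_degs(df, turned_on if name == "PAH" else set(), opposite) \
            .to_csv(outdir / f"degs_{name}.tsv", sep="\t", index=False,
                    float_format="%.6g")
    pd.Series(sorted(turned_on), name="gene_id").to_csv(
        outdir / "turned_on.tsv", sep="\t", index=False)
    pd.Series(sorted(opposite), name="gene_id").to_csv(
        outdir / "opposite.tsv", sep="\t", index=False)
    info = {name: {"tested": int(df["tested"].sum()),
                   "up": int((df["call"] == "up").sum()),
                   "down": int((df["call"] == "down").sum())}
            for name, df in degs.items()}
    info["turned_on"] = len(turned_on)
    info["opposite"] = len(opposite)
    return info


def stage_splice(config: PipelineConfig, outdir: Path) -> dict:
    """Exon inclusion/exclusion cascade for both contrasts."""
    annotation = read_exon_bed(config.annotation)
    exon_counts = _read_tsv(outdir / "counts_exon.tsv", "exon_id")
    gene_counts = _read_tsv(outdir / "counts_gene.tsv", "gene_id")
    rpkm_exon = _read_tsv(outdir / "rpkm_exon.tsv", "exon_id")
    samples = pd.read_csv(outdir / "samples.tsv", sep="\t")
    variants = detect_exon_variants(
        exon_counts, gene_counts, rpkm_exon, annotation, samples,
        rpkm_threshold=config.exon_rpkm_min, alpha=config.alpha,
        e_max=config.bayes_e_max, bayes_method=config.bayes_method,
        rng=config.seed)
    variants.to_csv(outdir / "exon_variants.tsv", sep="\t", index=False,
                    float_format="%.6g")
    summarize_variant_types(variants).to_csv(
        outdir / "as_summary.tsv", sep="\t", index=False, float_format="%.6g")
    return {name: {"calls": int((variants["contrast"] == name).sum())}
            for name in CONTRASTS}


def stage_enrich(config: PipelineConfig, outdir: Path) -> dict:
    """Pathway enrichment of the six DEG/AS gene-list categories."""
    db = PathwayDB.from_gmt(config.gmt)
    variants = pd.read_csv(outdir / "exon_variants.tsv", sep="\t")
    queries = {}
    for name in CONTRASTS:
        df = pd.read_csv(outdir / f"degs_{name}.tsv", sep="\t")
        queries[f"{name}_up"] = set(df.loc[df["call"] == "up", "gene_id"])
        queries[f"{name}_down"] = set(df.loc[df["call"] == "down", "gene_id"])
        queries[f"{name}_AS"] = set(
            variants.loc[variants["contrast"] == name, "gene_id"])
    records = enrich_categories(queries, db, alpha=config.alpha,
                                min_k=config.min_pathway_k)
    records.to_csv(outdir / "enrichment.tsv", sep="\t", index=False,
                   float_format="%.6g")
    heat_matrix(records).to_csv(outdir / "heat_matrix.tsv", sep="\t",
                                index_label="pathway_id", float_format="%.6g")
    return {"n_pathways": len(db),
            "significant": int(records["significant"].sum())}


def stage_motif(config: PipelineConfig, outdir: Path) -> dict:
    """Consensus-motif occurrence enrichment in the configured foreground
    gene set (turned-on or opposite) versus all other genes."""
    annotation = read_exon_bed(config.annotation)
    upstream = extract_upstream(annotation, config.genome,
                                length=config.upstream_length)
    fg_file = "opposite.tsv" if config.motif_foreground == "opposite" \
        else "turned_on.tsv"
    fg_tab = pd.read_csv(outdir / fg_file, sep="\t")
    fg = sorted(set(fg_tab["gene_id"]) & set(upstream)) if len(fg_tab) else []
    bg = sorted(set(upstream) - set(fg))
    rows = []
    if fg:
        for motif in config.motifs:
            r = motif_enrichment(fg, bg, upstream, motif)
            rows.append(dataclasses.asdict(r))
    pd.DataFrame(rows, columns=["motif", "fg_hit", "fg_total", "bg_hit",
                                "bg_total", "p"]) \
        .to_csv(outdir / "motif_enrichment.tsv", sep="\t", index=False,
                float_format="%.6g")
    return {"n_motifs": len(rows), "foreground_size": len(fg)}


def run_stage(name: str, config: PipelineConfig, outdir: str | Path) -> dict:
    """Run one stage standalone against an existing run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fn = {"quantify": stage_quantify, "deg": stage_deg,
          "splice": stage_splice, "enrich": stage_enrich,
          "motif": stage_motif}[name]
    t = time.monotonic()
    log.info("stage %s ...", name)
    info = fn(config, outdir)
    log.info("stage %s done in %.1fs", name, time.monotonic() - t)
    return info


def run_all(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every applicable stage in dependency order.

    The enrichment stage runs only when a GMT is configured, the motif
    stage only when a genome is.  Writes ``run_manifest.json`` and
    returns it.
    """
    t0 = time.monotonic()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config": config.to_dict(), "stages": {}}
    for name in STAGES:
        if name == "enrich" and not config.gmt:
            continue
        if name == "motif" and not (config.genome and config.motifs):
            continue
        manifest["stages"][name] = run_stage(name, config, outdir)
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("run-all finished in %.1fs", time.monotonic() - t0)
    return manifest
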