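"""Shared fixtures: simulated studies at the default desk scale and a
small emitted fixture directory for pipeline-level tests."""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd
import pytest

import cardiosplice as cs


def condition_samples(samples: pd.DataFrame, condition: str) -> list[str]:
    return samples.loc[samples["condition"] == condition, "sample_id"].tolist()


def tree_digest(root: Path) -> str:
    """SHA-256 over all files under root (skipping FASTA .fai indexes,
    which readers create as a side effect)."""
    h = hashlib.sha256()
    for p in sorted(Path(root).rglob("*")):
        if p.is_file() and p.suffix != ".fai":
            h.update(str(p.relative_to(root)).encode())
            h.update(p.read_bytes())
    return h.hexdigest()


@pytest.fixture(scope="session")
def study() -> cs.StudyFixture:
    """Default spiked study (300 genes, 4x3 samples), counts only."""
    return cs.simulate_study(seed=1, materialize_reads=False)


@pytest.fixture(scope="session")
def null_study() -> cs.StudyFixture:
    """Zero-effect study at the same scale."""
    return cs.simulate_study(cs.SimulationConfig.null(), seed=1,
                             materialize_reads=False)


@pytest.fixture(scope="session")
def study_rpkm(study):
    mapped = study.samples.set_index("sample_id")["mapped_reads_total"]
    rpkm_gene = cs.compute_rpkm(study.gene_counts,
                                study.annotation.gene_lengths(), mapped)
    rpkm_exon = cs.compute_rpkm(study.exon_counts,
                                study.annotation.exon_lengths(), mapped)
    return rpkm_gene, rpkm_exon


@pytest.fixture(scope="session")
def study_degs(study, study_rpkm):
    rpkm_gene, _ = study_rpkm
    sam = study.samples
    degs = {}
    for name, (ctrl, trt) in cs.CONTRASTS.items():
        degs[name] = cs.call_degs(rpkm_gene, condition_samples(sam, ctrl),
                                  condition_samples(sam, trt))
    return degs


@pytest.fixture(scope="session")
def study_variants(study, study_rpkm):
    _, rpkm_exon = study_rpkm
    return cs.detect_exon_variants(study.exon_counts, study.gene_counts,
                                   rpkm_exon, study.annotation, study.samples)


@pytest.fixture(scope="session")
def small_fixture_dir(tmp_path_factory) -> Path:
    """A small study with materialized reads, emitted to disk."""
    cfg = cs.SimulationConfig(n_genes=100, library_size=50_000,
                              n_as_events=10, n_deg_pah_up=4,
                              n_deg_pah_down=2, n_deg_phh_up=1,
                              n_deg_phh_down=2, n_turned_on=2, n_opposite=2,
                              n_pathways=10)
    fixture = cs.simulate_study(cfg, seed=7)
    out = tmp_path_factory.mktemp("fixture")
    cs.emit_fixture(fixture, out)
    return out


@pytest.fixture()
def small_config(small_fixture_dir) -> cs.PipelineConfig:
    d = small_fixture_dir
    return cs.PipelineConfig(annotation=str(d / "annotation.bed"),
                             manifest=str(d / "manifest.tsv"),
                             genome=str(d / "genome.fa"),
                             gmt=str(d / "pathways.gmt"), seed=7)
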