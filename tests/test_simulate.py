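"""The synthetic-study generator: determinism, truth invariants and the
effect-size dial."""

import numpy as np
import pandas as pd
import pytest

import cardiosplice as cs
from tests.conftest import condition_samples, tree_digest


SMALL = dict(n_genes=80, library_size=30_000, n_deg_pah_up=3,
             n_deg_pah_down=2, n_deg_phh_up=1, n_deg_phh_down=1,
             n_turned_on=2, n_opposite=2, n_as_events=8, n_pathways=8)


def test_emission_is_byte_identical_under_a_seed(tmp_path):
    cfg = cs.SimulationConfig(**SMALL)
    for d in ("a", "b"):
        cs.emit_fixture(cs.simulate_study(cfg, seed=5), tmp_path / d)
    assert tree_digest(tmp_path / "a") == tree_digest(tmp_path / "b")
    cs.emit_fixture(cs.simulate_study(cfg, seed=6), tmp_path / "c")
    assert tree_digest(tmp_path / "a") != tree_digest(tmp_path / "c")


def test_annotation_round_trips_through_the_loader(tmp_path):
    ann, genome = cs.build_toy_annotation(n_genes=60, seed=2)
    path = tmp_path / "ann.bed"
    cs.write_exon_bed(ann, path)
    back = cs.read_exon_bed(path)
    assert back.to_dataframe().equals(ann.to_dataframe())
    # genes do not overlap each other on a contig
    for chrom in {e.chrom for e in ann.exons}:
        spans = sorted(g.span for g in ann.genes.values() if g.chrom == chrom)
        assert all(s2 >= e1 for (_, e1), (s2, _) in zip(spans, spans[1:]))


def test_truth_invariants(study, study_rpkm):
    rpkm_gene, _ = study_rpkm
    truth = study.truth
    sham = condition_samples(study.samples, "sham")
    # turned-on genes are below the expression floor at baseline
    ton = truth.genes.index[truth.genes["is_turned_on"]]
    assert (rpkm_gene.loc[ton, sham].mean(axis=1) < 2.0).all()
    # spiked AS exons sit on labelled exons of multi-exon genes
    alt = study.annotation.alt_types_map()
    for exon_id in truth.exons.index[truth.exons["is_as_event"]]:
        assert len(alt[exon_id]) > 0
        gene = study.annotation.gene(truth.exons.loc[exon_id, "gene_id"])
        assert len(gene) >= 2
    # opposite genes have discordant true fold changes
    opp = truth.genes[truth.genes["is_opposite"]]
    assert ((opp["true_fc_pah"] - 1) * (opp["true_fc_phh"] - 1) < 0).all()


def test_library_size_bookkeeping(study):
    lib = study.config.library_size
    totals = study.samples["mapped_reads_total"].to_numpy()
    # totals track the configured size; per-gene NB noise leaves a
    # few-percent spread (dominated by the largest genes' bcv^2 term)
    assert np.all(np.abs(totals - lib) < 0.05 * lib)


def test_materialized_reads_contain_decoys_that_filters_remove():
    cfg = cs.SimulationConfig(**SMALL)
    fx = cs.simulate_study(cfg, seed=3)
    sid = fx.samples["sample_id"].iloc[0]
    reads = fx.reads[sid]
    assert (~reads["is_unique"]).any()
    assert (reads["mismatches"] == 2).any()
    assert (reads["chrom"] == cfg.chrm_name).any()
    kept = cs.filter_alignments(reads)
    assert kept["is_unique"].all()
    assert (kept["mismatches"] < 2).all()
    assert (kept["chrom"] != cfg.chrm_name).all()
    assert len(kept) == fx.samples.set_index("sample_id") \
        .loc[sid, "mapped_reads_total"]


def test_pipeline_counts_match_simulated_counts():
    """Counting the materialized reads reproduces the drawn counts."""
    cfg = cs.SimulationConfig(**SMALL)
    fx = cs.simulate_study(cfg, seed=4)
    sid = fx.samples["sample_id"].iloc[0]
    kept = cs.filter_alignments(fx.reads[sid])
    ec, gc = cs.count_exon_reads(kept, fx.annotation)
    assert ec.equals(fx.exon_counts[sid].rename("count"))


def test_spike_requests_beyond_eligible_features_fail():
    with pytest.raises(ValueError):
        cs.simulate_study(cs.SimulationConfig(**{**SMALL, "n_as_events": 500}),
                          seed=0, materialize_reads=False)
    with pytest.raises(ValueError):   # no labelled exons at all
        cs.simulate_study(cs.SimulationConfig(
            **{**SMALL, "alt_fraction": 0.0, "n_as_events": 1}),
            seed=0, materialize_reads=False)
    with pytest.raises(ValueError):   # more DEG spikes than genes
        cs.simulate_study(cs.SimulationConfig(n_genes=20), seed=0,
                          materialize_reads=False)


def _deg_sensitivity(fx):
    mapped = fx.samples.set_index("sample_id")["mapped_reads_total"]
    rpkm = cs.compute_rpkm(fx.gene_counts, fx.annotation.gene_lengths(),
                           mapped)
    hits = total = 0
    for name, (ctrl, trt) in cs.CONTRASTS.items():
        degs = cs.call_degs(rpkm, condition_samples(fx.samples, ctrl),
                            condition_samples(fx.samples, trt))
        col = f"direction_{name.lower()}"
        spiked = fx.truth.genes[fx.truth.genes[f"is_deg_{name.lower()}"]]
        hits += (degs.loc[spiked.index, "call"] == spiked[col]).sum()
        total += len(spiked)
    return hits / total


def _as_sensitivity(fx):
    mapped = fx.samples.set_index("sample_id")["mapped_reads_total"]
    rpkm_e = cs.compute_rpkm(fx.exon_counts, fx.annotation.exon_lengths(),
                             mapped)
    calls = cs.detect_exon_variants(fx.exon_counts, fx.gene_counts, rpkm_e,
                                    fx.annotation, fx.samples)
    keyed = set(zip(calls["exon_id"], calls["contrast"]))
    spiked = fx.truth.exons[fx.truth.exons["is_as_event"]]
    hits = sum((e, c) in keyed
               for e, c in zip(spiked["exon_id"], spiked["contrast"]))
    return hits / len(spiked)


def test_effect_size_dial_is_monotone():
    """Caller sensitivity rises with spiked effect size."""
    deg_sens = []
    for fc in (1.3, 3.0, 8.0):
        cfg = cs.SimulationConfig(**{**SMALL, "deg_fc_range": (fc, fc),
                                     "n_as_events": 0})
        fx = cs.simulate_study(cfg, seed=9, materialize_reads=False)
        deg_sens.append(_deg_sensitivity(fx))
    assert deg_sens == sorted(deg_sens)
    as_sens = []
    for delta in (0.03, 0.15, 0.3):
        cfg = cs.SimulationConfig(**{**SMALL, "as_delta": delta})
        fx = cs.simulate_study(cfg, seed=9, materialize_reads=False)
        as_sens.append(_as_sensitivity(fx))
    assert as_sens == sorted(as_sens)


def test_gmt_emission_round_trip(tmp_path, study):
    db = study.pathways
    db.to_gmt(tmp_path / "p.gmt")
    back = cs.PathwayDB.from_gmt(tmp_path / "p.gmt")
    assert back.pathways == db.pathways
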