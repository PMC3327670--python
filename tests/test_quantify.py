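"""Read filtering, the largest-overlap counting rule and RPKM."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cardiosplice as cs
from cardiosplice.quantify import count_exon_reads


def reads_frame(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "read_id",
                                     "mismatches", "is_unique"])
    df["strand"] = "+"
    return df


# -- filtering -------------------------------------------------------------

@pytest.mark.parametrize("unique,mism,chrom,kept", [
    (False, 0, "chr1", False),   # multi-mapped
    (True, 2, "chr1", False),    # two mismatches
    (True, 1, "chr1", True),     # fewer than two mismatches
    (True, 0, "chr1", True),
    (True, 0, "chrM", False),    # mitochondrial, dropped by default
])
def test_filter_alignment_rules(unique, mism, chrom, kept):
    df = reads_frame([(chrom, 10, 46, "r1", mism, unique)])
    out = cs.filter_alignments(df)
    assert (len(out) == 1) == kept


def test_filter_chrm_optional_and_empty_input():
    df = reads_frame([("chrM", 10, 46, "r1", 0, True)])
    assert len(cs.filter_alignments(df, drop_chrm=False)) == 1
    empty = reads_frame([])
    assert len(cs.filter_alignments(empty)) == 0


def test_read_bed_flags_multimappers(tmp_path):
    p = tmp_path / "reads.bed"
    p.write_text("chr1\t10\t46\tr1\t0\t+\n"
                 "chr1\t90\t126\tr1\t0\t+\n"
                 "chr1\t50\t86\tr2\t1\t+\n")
    df = cs.read_alignment_bed(p)
    assert df["is_unique"].tolist() == [False, False, True]


# -- counting ---------------------------------------------------------------

def annotation_two_genes():
    E = cs.ExonRecord
    return cs.Annotation([
        E("g1.e1", "g1", "chr1", 50, 200, "+"),
        E("g1.e2", "g1", "chr1", 300, 400, "+"),
        E("g2.e1", "g2", "chr1", 1000, 1100, "-"),
    ])


def test_count_basic_assignment():
    ann = annotation_two_genes()
    reads = reads_frame([
        ("chr1", 100, 136, "r1", 0, True),   # inside g1.e1
        ("chr1", 10, 46, "r2", 0, True),     # overlaps nothing
        ("chr1", 1050, 1086, "r3", 0, True),  # inside g2.e1
    ])
    ec, gc = count_exon_reads(reads, ann)
    assert ec["g1.e1"] == 1 and ec["g1.e2"] == 0 and ec["g2.e1"] == 1
    assert gc["g1"] == 1 and gc["g2"] == 1


def test_count_largest_overlap_and_tie_break():
    E = cs.ExonRecord
    # adjacent exons of one gene: a read spanning the junction goes to
    # the larger overlap; on an exact tie, to the smaller start
    ann = cs.Annotation([E("e1", "g1", "chr1", 100, 200, "+"),
                        E("e2", "g1", "chr1", 200, 300, "+")])
    reads = reads_frame([
        ("chr1", 170, 206, "rA", 0, True),   # 30 bp in e1, 6 bp in e2
        ("chr1", 182, 218, "rB", 0, True),   # exact 18/18 tie -> e1
    ])
    ec, gc = count_exon_reads(reads, ann)
    assert ec["e1"] == 2 and ec["e2"] == 0
    assert gc["g1"] == 2   # one increment per gene per read


def test_count_interleaved_genes_count_once_each():
    E = cs.ExonRecord
    # exons of different genes overlapping: read counts once per gene
    ann = cs.Annotation([E("a", "g1", "chr1", 100, 200, "+"),
                        E("b", "g2", "chr1", 150, 250, "+")])
    reads = reads_frame([("chr1", 160, 196, "r1", 0, True)])
    ec, gc = count_exon_reads(reads, ann)
    assert ec["a"] == 1 and ec["b"] == 1
    assert gc["g1"] == 1 and gc["g2"] == 1


def _oracle_counts(reads, ann):
    """Independent per-read scan over every exon."""
    counts = {e.exon_id: 0 for e in ann.exons}
    for r in reads.itertuples(index=False):
        best = {}
        for e in ann.exons:
            if e.chrom != r.chrom:
                continue
            ov = min(r.end, e.end) - max(r.start, e.start)
            if ov <= 0:
                continue
            key = (-ov, e.start, e.exon_id)
            if e.gene_id not in best or key < best[e.gene_id]:
                best[e.gene_id] = key
        for key in best.values():
            counts[key[2]] += 1
    return counts


@pytest.mark.parametrize("overlapping", [False, True])
def test_count_matches_bruteforce_oracle(overlapping):
    rng = np.random.default_rng(42 + overlapping)
    exons, pos = [], 100
    for g in range(8):
        for e in range(int(rng.integers(1, 5))):
            length = int(rng.integers(40, 200))
            exons.append(cs.ExonRecord(f"g{g}.e{e}", f"g{g}", "chr1",
                                       pos, pos + length, "+"))
            if overlapping:   # next exon may start inside this one
                pos += int(rng.integers(10, length))
            else:
                pos = exons[-1].end + int(rng.integers(40, 300))
    ann = cs.Annotation(exons)
    n = 300
    starts = rng.integers(0, pos + 200, size=n)
    reads = reads_frame([("chr1", int(s), int(s) + 36, f"r{i}", 0, True)
                         for i, s in enumerate(starts)])
    ec, gc = count_exon_reads(reads, ann)
    oracle = _oracle_counts(reads, ann)
    assert ec.to_dict() == oracle
    if not overlapping:
        # without inter-gene overlap each read counts at most once overall
        assert gc.sum() <= n
    assert gc.equals(ec.groupby(ann.exon_gene_map()).sum().reindex(gc.index))


# -- RPKM -------------------------------------------------------------------

def test_rpkm_worked_example_and_zero():
    counts = pd.DataFrame({"s1": [1000, 0]}, index=["g1", "g2"])
    lengths = pd.Series({"g1": 2000, "g2": 500})
    mapped = pd.Series({"s1": 10_000_000})
    rpkm = cs.compute_rpkm(counts, lengths, mapped)
    assert rpkm.loc["g1", "s1"] == 50.0
    assert rpkm.loc["g2", "s1"] == 0.0


def test_rpkm_rejects_empty_library_and_bad_lengths():
    counts = pd.DataFrame({"s1": [5]}, index=["g1"])
    with pytest.raises(ValueError):
        cs.compute_rpkm(counts, pd.Series({"g1": 100}), pd.Series({"s1": 0}))
    with pytest.raises(ValueError):
        cs.compute_rpkm(counts, pd.Series({"g1": 0}), pd.Series({"s1": 10}))


@settings(deadline=None, derandomize=True)
@given(count=st.integers(0, 10**6), length=st.integers(1, 10**5),
       mapped=st.integers(1, 10**8), scale=st.integers(1, 1000))
def test_rpkm_scale_invariance(count, length, mapped, scale):
    one = cs.compute_rpkm(pd.DataFrame({"s": [count]}, index=["g"]),
                          pd.Series({"g": length}), pd.Series({"s": mapped}))
    two = cs.compute_rpkm(pd.DataFrame({"s": [count * scale]}, index=["g"]),
                          pd.Series({"g": length}),
                          pd.Series({"s": mapped * scale}))
    assert one.loc["g", "s"] == pytest.approx(two.loc["g", "s"], rel=1e-12)


def test_log_rpkb_values_and_monotonicity():
    rpkm = pd.DataFrame({"s": [0.0, 1.0, 2.0]}, index=["a", "b", "c"])
    log = cs.to_log_rpkb(rpkm)
    assert log.loc["a", "s"] == 0.0
    assert log.loc["b", "s"] == pytest.approx(np.log2(1001), abs=1e-12)
    assert log.loc["b", "s"] < log.loc["c", "s"]
    with pytest.raises(ValueError):
        cs.to_log_rpkb(rpkm - 1.0)


# -- expressed-gene universe ------------------------------------------------

def test_expressed_genes_modes():
    rpkm = pd.DataFrame({"s1": [0.1, 1.9, 5.0], "s2": [0.3, 1.9, 0.0],
                         "s3": [2.4, 1.9, 0.0]},
                        index=["g1", "g2", "g3"])
    samples = pd.DataFrame({"sample_id": ["s1", "s2", "s3"],
                            "condition": ["sham"] * 3, "replicate": [1, 2, 3]})
    by_any = cs.expressed_genes(rpkm, samples)
    assert by_any["sham"] == {"g1", "g3"}      # one replicate >= 2 suffices
    by_mean = cs.expressed_genes(rpkm, samples, mode="group_mean")
    assert by_mean["sham"] == set()            # no mean reaches 2
    assert cs.expressed_genes(rpkm, samples, floor=0.0)["sham"] == \
        {"g1", "g2", "g3"}
    with pytest.raises(ValueError):
        cs.expressed_genes(rpkm, samples, mode="sometimes")
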