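"""Read filtering, exon/gene counting and RPKM normalization.

The pipeline starts from alignment *intervals* (6-column BED-like TSV),
not from raw sequence: chrom, start, end, read_id, mismatches, strand.
Only uniquely mapped reads with fewer than two mismatches are used; a
read is considered multi-mapped when its read_id occurs on more than one
line of the file.  Mitochondrial reads are dropped by default.

Counting rule: a read increments exactly one exon per gene — the exon it
overlaps by the most base pairs (ties broken toward the smaller exon
start).  The gene count is the sum of its exon counts, so each read adds
at most 1 per gene.  Where exons of *different* genes overlap, a read
may legitimately count once in each gene.

RPKM = count / (feature length in kb x mapped reads in millions), with
the exon length for exons and the exon-model (merged union) length for
genes.  RPKB = 1000 x RPKM; the log view is log2(RPKB + pseudocount).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .annotation import Annotation

READ_COLUMNS = ["chrom", "start", "end", "read_id", "mismatches", "strand"]

#: Conditions of the two-model hypertrophy design.
CONDITIONS = ("sham", "TAC", "sedentary", "exercise")

#: The two contrasts: pathological (TAC surgery) and physiological
#: (exercise training) hypertrophy, each against its own control.
CONTRASTS = {"PAH": ("sham", "TAC"), "PHH": ("sedentary", "exercise")}


@dataclass(frozen=True)
class SampleInfo:
    """Per-sample metadata, including the post-filter library size."""

    sample_id: str
    condition: str
    replicate: int
    mapped_reads_total: int = 0


# -- reads I/O and filtering ----------------------------------------------

def read_alignment_bed(path: str | Path) -> pd.DataFrame:
    """Load a 6-column read BED; flags multi-mappers by duplicated read_id."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=READ_COLUMNS,
                     dtype={"chrom": str, "start": np.int64, "end": np.int64,
                            "read_id": str, "mismatches": np.int64, "strand": str})
    df["is_unique"] = ~df["read_id"].duplicated(keep=False)
    return df


def filter_alignments(reads: pd.DataFrame, drop_chrm: bool = True,
                      chrm_name: str = "chrM") -> pd.DataFrame:
    """Keep uniquely mapped reads with fewer than two mismatches.

    With ``drop_chrm`` (the default) mitochondrial reads are removed as
    well.  The returned frame's length is the sample's
    ``mapped_reads_total``.
    """
    if (reads["end"] <= reads["start"]).any():
        raise ValueError("malformed read interval (end <= start)")
    keep = reads["is_unique"].to_numpy() & (reads["mismatches"].to_numpy() < 2)
    if drop_chrm:
        keep &= (reads["chrom"] != chrm_name).to_numpy()
    return reads.loc[keep].reset_index(drop=True)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Per-sample manifest TSV: sample_id, condition, replicate, path."""
    df = pd.read_csv(path, sep="\t",
                     dtype={"sample_id": str, "condition": str, "path": str})
    missing = {"sample_id", "condition", "replicate", "path"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


# -- counting --------------------------------------------------------------

class _ExonIndex:
    """Fast interval lookup over the annotation.

    When the exons of a chromosome are mutually non-overlapping (the
    common case for an exon model) overlap queries reduce to two
    searchsorted calls on the sorted start/end arrays; otherwise an
    interval tree is used.
    """

    def __init__(self, annotation: Annotation):
        self.annotation = annotation
        df = annotation.to_dataframe()
        df = df.reset_index().rename(columns={"index": "exon_idx"})
        self.by_chrom: dict[str, dict] = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values(["start", "end"], kind="mergesort")
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            disjoint = bool(np.all(starts[1:] >= ends[:-1])) if len(sub) > 1 else True
            self.by_chrom[str(chrom)] = {
                "starts": starts, "ends": ends,
                "idx": sub["exon_idx"].to_numpy(), "disjoint": disjoint,
            }
        self._trees = None

    def trees(self):
        if self._trees is None:
            self._trees = self.annotation.interval_trees()
        return self._trees


def _assign_candidates(read_start: int, read_end: int,
                       cand: list[int], annotation: Annotation) -> list[int]:
    """Pick, per gene, the candidate exon with the largest overlap.

    Ties go to the exon with the smaller start.  Returns chosen exon
    indices (one per gene overlapped).
    """
    best: dict[str, tuple[int, int, int]] = {}  # gene -> (-overlap, start, idx)
    for i in cand:
        ex = annotation.exons[i]
        ov = min(read_end, ex.end) - max(read_start, ex.start)
        if ov <= 0:
            continue
        key = (-ov, ex.start, i)
        prev = best.get(ex.gene_id)
        if prev is None or key < prev:
            best[ex.gene_id] = key
    return [k[2] for k in best.values()]


def count_exon_reads(reads: pd.DataFrame, annotation: Annotation,
                     index: _ExonIndex | None = None) -> tuple[pd.Series, pd.Series]:
    """Count filtered reads per exon and per gene for one sample.

    Returns ``(exon_counts, gene_counts)`` Series covering every
    annotated exon/gene (zeros included).  Gene counts are the sums of
    their exon counts, so each read contributes at most one per gene.
    """
    if index is None:
        index = _ExonIndex(annotation)
    n_exons = len(annotation.exons)
    counts = np.zeros(n_exons, dtype=np.int64)

    for chrom, sub in reads.groupby("chrom", sort=False):
        info = index.by_chrom.get(str(chrom))
        if info is None:
            continue
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        if info["disjoint"]:
            lo = np.searchsorted(info["ends"], s, side="right")
            hi = np.searchsorted(info["starts"], e, side="left")
            width = hi - lo
            single = width == 1
            counts += np.bincount(info["idx"][lo[single]], minlength=n_exons)
            for rs, re_, l, h in zip(s[width > 1], e[width > 1],
                                     lo[width > 1], hi[width > 1]):
                cand = list(info["idx"][l:h])
                for i in _assign_candidates(int(rs), int(re_), cand, annotation):
                    counts[i] += 1
        else:
            tree = index.trees()[str(chrom)]
            for rs, re_ in zip(s, e):
                cand = [iv.data for iv in tree.overlap(int(rs), int(re_))]
                if not cand:
                    continue
                for i in _assign_candidates(int(rs), int(re_), cand, annotation):
                    counts[i] += 1

    exon_counts = pd.Series(counts, index=annotation.exon_ids, name="count")
    gene_counts = exon_counts.groupby(annotation.exon_gene_map()).sum()
    gene_counts = gene_counts.reindex(annotation.gene_ids, fill_value=0)
    return exon_counts, gene_counts


def build_count_matrices(
    sample_reads: Mapping[str, pd.DataFrame], annotation: Annotation,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exon- and gene-level count matrices (rows = features, columns = samples).

    ``sample_reads`` maps sample_id to an already *filtered* read frame.
    """
    index = _ExonIndex(annotation)
    exon_cols, gene_cols = {}, {}
    for sample_id, reads in sample_reads.items():
        ec, gc = count_exon_reads(reads, annotation, index=index)
        exon_cols[sample_id] = ec
        gene_cols[sample_id] = gc
    return pd.DataFrame(exon_cols), pd.DataFrame(gene_cols)


def load_experiment(manifest_path: str | Path, annotation: Annotation,
                    drop_chrm: bool = True, chrm_name: str = "chrM"):
    """Load, filter and count every sample listed in a manifest.

    Returns ``(exon_counts, gene_counts, samples)`` where ``samples`` is
    the manifest frame with a ``mapped_reads_total`` column recomputed
    from the filtered reads.
    """
    manifest = read_manifest(manifest_path)
    base = Path(manifest_path).parent
    filtered: dict[str, pd.DataFrame] = {}
    totals = []
    for r in manifest.itertuples(index=False):
        p = Path(r.path)
        if not p.is_absolute():
            p = base / p
        reads = filter_alignments(read_alignment_bed(p),
                                  drop_chrm=drop_chrm, chrm_name=chrm_name)
        filtered[r.sample_id] = reads
        totals.append(len(reads))
    exon_counts, gene_counts = build_count_matrices(filtered, annotation)
    samples = manifest.copy()
    samples["mapped_reads_total"] = totals
    return exon_counts, gene_counts, samples


# -- normalization ---------------------------------------------------------

def compute_rpkm(counts: pd.DataFrame, lengths: pd.Series,
                 mapped_totals: pd.Series) -> pd.DataFrame:
    """Reads per kilobase of feature per million mapped reads.

    ``RPKM[i, s] = counts[i, s] / (length_kb[i] * mapped_totals[s] / 1e6)``
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every feature needs a positive length")
    mapped_totals = mapped_totals.reindex(counts.columns)
    if mapped_totals.isna().any() or (mapped_totals <= 0).any():
        raise ValueError("empty library: mapped_reads_total must be positive")
    denom = np.outer(lengths.to_numpy() / 1e3,
                     mapped_totals.to_numpy() / 1e6)
    return pd.DataFrame(counts.to_numpy() / denom,
                        index=counts.index, columns=counts.columns)


def to_log_rpkb(rpkm: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(1000 * RPKM + pseudocount); the default pseudocount of 1 maps
    zero counts to exactly 0."""
    if (np.asarray(rpkm) < 0).any():
        raise ValueError("negative RPKM")
    return np.log2(1000.0 * rpkm + pseudocount)


def expressed_genes(rpkm: pd.DataFrame, samples: pd.DataFrame,
                    floor: float = 2.0,
                    mode: str = "any_replicate") -> dict[str, set[str]]:
    """Per-condition sets of expressed genes at an RPKM floor.

    ``any_replicate``: expressed if >= floor in at least one replicate of
    the condition; ``group_mean``: condition mean >= floor.
    """
    if mode not in ("any_replicate", "group_mean"):
        raise ValueError(f"unknown mode {mode!r}")
    out: dict[str, set[str]] = {}
    for condition, sub in samples.groupby("condition", sort=False):
        cols = [c for c in sub["sample_id"] if c in rpkm.columns]
        block = rpkm[cols]
        if mode == "any_replicate":
            mask = (block >= floor).any(axis=1)
        else:
            mask = block.mean(axis=1) >= floor
        out[str(condition)] = set(block.index[mask])
    return out
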