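"""Exon-model annotation: records, gene models and flat-file readers.

Every coordinate in this package is 0-based half-open (BED convention).
The GTF-like reader converts 1-based closed coordinates on input, so no
other module ever needs to think about the off-by-one.

A gene is represented by its *exon model*: the union of its exon
intervals.  The length of that union is the RPKM denominator, and the
strand-aware outermost coordinate is the transcription start site used
for upstream-sequence extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from intervaltree import IntervalTree

#: UCSC knownAlt vocabulary of alternative-splicing feature types.
ALT_TYPES = frozenset({
    "altPromoter", "cassetteExon", "altFinish", "altThreePrime",
    "altFivePrime", "bleedingExon", "retainedIntron", "strangeSplice",
})


@dataclass(frozen=True)
class ExonRecord:
    """One exon interval with gene membership and knownAlt labels.

    ``alt_types`` is empty for a constitutive exon; a non-empty set marks
    the exon as a known alternative-splicing feature (the splicing module
    only reports events on such exons).
    """

    exon_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    alt_types: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"exon {self.exon_id}: end ({self.end}) must exceed start ({self.start})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"exon {self.exon_id}: strand must be '+' or '-'")
        object.__setattr__(self, "alt_types", frozenset(self.alt_types))
        unknown = self.alt_types - ALT_TYPES
        if unknown:
            raise ValueError(
                f"exon {self.exon_id}: unknown alt types {sorted(unknown)}")

    @property
    def length(self) -> int:
        return self.end - self.start


def merged_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total length of the union of half-open intervals."""
    ivs = sorted(intervals)
    total = 0
    cur_start, cur_end = None, None
    for s, e in ivs:
        if cur_end is None or s > cur_end:
            if cur_end is not None:
                total += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        total += cur_end - cur_start
    return total


@dataclass
class GeneModel:
    """A gene as the ordered collection of its exons."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[ExonRecord] = field(default_factory=list)

    @property
    def exon_model_length(self) -> int:
        """Length of the merged exon union (the RPKM denominator)."""
        return merged_length((e.start, e.end) for e in self.exons)

    @property
    def tss(self) -> int:
        """Strand-aware transcription start coordinate.

        For a ``+`` gene this is the smallest exon start; for a ``-``
        gene the largest exon end (both 0-based; for ``-`` the TSS is the
        coordinate just past the last transcribed base).
        """
        if self.strand == "+":
            return min(e.start for e in self.exons)
        return max(e.end for e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return (min(e.start for e in self.exons), max(e.end for e in self.exons))

    def __len__(self) -> int:
        return len(self.exons)


class Annotation:
    """The annotation universe: exons indexed by id and grouped into genes."""

    def __init__(self, exons: Iterable[ExonRecord]):
        self.exons: list[ExonRecord] = list(exons)
        self._by_id: dict[str, ExonRecord] = {}
        genes: dict[str, GeneModel] = {}
        for ex in self.exons:
            if ex.exon_id in self._by_id:
                raise ValueError(f"duplicate exon_id {ex.exon_id!r}")
            self._by_id[ex.exon_id] = ex
            gm = genes.get(ex.gene_id)
            if gm is None:
                genes[ex.gene_id] = GeneModel(ex.gene_id, ex.chrom, ex.strand, [ex])
            else:
                if gm.chrom != ex.chrom or gm.strand != ex.strand:
                    raise ValueError(
                        f"gene {ex.gene_id}: exons disagree on chrom/strand")
                gm.exons.append(ex)
        for gm in genes.values():
            gm.exons.sort(key=lambda e: (e.start, e.end))
        self.genes: dict[str, GeneModel] = genes
        self._trees: dict[str, IntervalTree] | None = None

    # -- lookups ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.exons)

    def __iter__(self) -> Iterator[ExonRecord]:
        return iter(self.exons)

    def exon(self, exon_id: str) -> ExonRecord:
        return self._by_id[exon_id]

    def gene(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    @property
    def exon_ids(self) -> list[str]:
        return [e.exon_id for e in self.exons]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes)

    # -- derived tables --------------------------------------------------
    def exon_lengths(self) -> pd.Series:
        return pd.Series({e.exon_id: e.length for e in self.exons}, name="length")

    def gene_lengths(self) -> pd.Series:
        """Exon-model (merged union) length per gene."""
        return pd.Series(
            {g: gm.exon_model_length for g, gm in self.genes.items()}, name="length")

    def exon_gene_map(self) -> pd.Series:
        return pd.Series({e.exon_id: e.gene_id for e in self.exons}, name="gene_id")

    def alt_types_map(self) -> dict[str, frozenset[str]]:
        return {e.exon_id: e.alt_types for e in self.exons}

    def interval_trees(self) -> dict[str, IntervalTree]:
        """Per-chromosome interval trees of exon indices (built lazily)."""
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for i, ex in enumerate(self.exons):
                trees.setdefault(ex.chrom, IntervalTree()).addi(ex.start, ex.end, i)
            self._trees = trees
        return self._trees

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": [e.chrom for e in self.exons],
            "start": [e.start for e in self.exons],
            "end": [e.end for e in self.exons],
            "exon_id": [e.exon_id for e in self.exons],
            "gene_id": [e.gene_id for e in self.exons],
            "strand": [e.strand for e in self.exons],
            "alt_types": [",".join(sorted(e.alt_types)) or "." for e in self.exons],
        })

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Annotation":
        exons = [
            ExonRecord(
                exon_id=str(r.exon_id), gene_id=str(r.gene_id), chrom=str(r.chrom),
                start=int(r.start), end=int(r.end), strand=str(r.strand),
                alt_types=frozenset() if r.alt_types in (".", "", None)
                else frozenset(str(r.alt_types).split(",")),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(exons)


# -- flat-file I/O -------------------------------------------------------

def read_exon_bed(path: str | Path) -> Annotation:
    """Read the 7-column exon BED-like TSV.

    Columns: chrom, start, end, exon_id, gene_id, strand, alt_types
    (comma-separated knownAlt labels, ``.`` for none).
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "exon_id", "gene_id", "strand", "alt_types"],
        dtype={"chrom": str, "exon_id": str, "gene_id": str,
               "strand": str, "alt_types": str},
        keep_default_na=False,
    )
    return Annotation.from_dataframe(df)


def write_exon_bed(annotation: Annotation, path: str | Path) -> None:
    annotation.to_dataframe().to_csv(path, sep="\t", header=False, index=False)


def read_gtf(path: str | Path) -> Annotation:
    """Read exon features from a GTF-like file.

    Uses 1-based closed coordinates on disk (converted to 0-based
    half-open).  ``gene_id`` is required in the attribute column;
    ``exon_id`` is used when present, otherwise ids are generated as
    ``<gene_id>.e<k>`` in file order.
    """
    import re

    attr_re = re.compile(r'(\w+)\s+"([^"]*)"')
    exons: list[ExonRecord] = []
    counters: dict[str, int] = {}
    used_ids: set[str] = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "exon":
                continue
            chrom, _, _, start, end, _, strand, _, attrs = fields[:9]
            d = dict(attr_re.findall(attrs))
            if "gene_id" not in d:
                raise ValueError(f"GTF exon line without gene_id: {line!r}")
            gene_id = d["gene_id"]
            exon_id = d.get("exon_id")
            if exon_id is None:
                while True:
                    counters[gene_id] = counters.get(gene_id, 0) + 1
                    exon_id = f"{gene_id}.e{counters[gene_id]}"
                    if exon_id not in used_ids:
                        break
            used_ids.add(exon_id)
            alt = frozenset(d["alt_types"].split(",")) if d.get("alt_types") else frozenset()
            exons.append(ExonRecord(
                exon_id=exon_id, gene_id=gene_id, chrom=chrom,
                start=int(start) - 1, end=int(end), strand=strand, alt_types=alt))
    return Annotation(exons)


def apply_knownalt_bed(annotation: Annotation, path: str | Path) -> Annotation:
    """Label exons with knownAlt types from a second BED by coordinate overlap.

    The BED carries the AS type in its name (4th) column; every exon
    overlapping an interval receives that type (labels accumulate).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2, 3],
                     names=["chrom", "start", "end", "name"],
                     dtype={"chrom": str, "name": str})
    trees = annotation.interval_trees()
    extra: dict[int, set[str]] = {}
    for r in df.itertuples(index=False):
        if r.name not in ALT_TYPES:
            raise ValueError(f"unknown knownAlt type {r.name!r}")
        tree = trees.get(r.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(int(r.start), int(r.end)):
            extra.setdefault(iv.data, set()).add(r.name)
    new_exons = []
    for i, ex in enumerate(annotation.exons):
        if i in extra:
            ex = ExonRecord(ex.exon_id, ex.gene_id, ex.chrom, ex.start, ex.end,
                            ex.strand, ex.alt_types | frozenset(extra[i]))
        new_exons.append(ex)
    return Annotation(new_exons)
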