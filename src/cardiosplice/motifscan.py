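"""Promoter consensus-motif occurrence and enrichment.

Extracts the 1,000 bp immediately upstream of each gene's TSS
(strand-aware, clipped at contig ends) and scans it for an exact IUPAC
consensus match under the study's occurrence rules: a motif counts at
most once per upstream sequence and the reverse complement is *not*
considered — the scan runs on the given strand only.  Enrichment of a
motif in a foreground gene set versus an explicit background is a
one-sided Fisher exact test on presence/absence counts.

De novo motif discovery and motif-database matching are deliberately
out of scope; the module tests user-supplied consensus motifs such as
the MAZ sites GGGAGGG / CCCTCCC.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .annotation import Annotation
from .splicing import fisher_exact_upper

#: IUPAC nucleotide codes.  A sequence ``N`` is only matched by a motif
#: ``N`` (an ambiguous base is never evidence for a concrete motif letter).
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGTN",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def compile_iupac(motif: str) -> re.Pattern:
    """Compile an IUPAC consensus into a regular expression."""
    if not motif:
        raise ValueError("empty motif")
    motif = motif.upper()
    bad = set(motif) - set(IUPAC)
    if bad:
        raise ValueError(f"invalid IUPAC letters: {sorted(bad)}")
    return re.compile("".join(
        c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in motif))


def extract_upstream(annotation: Annotation, genome,
                     length: int = 1000) -> dict[str, str]:
    """Upstream sequence per gene, strand-corrected to read toward the TSS.

    ``genome`` may be a FASTA path, a ``pyfaidx.Fasta`` or a plain
    mapping of contig name to sequence.  A ``+`` gene at TSS t yields
    ``[t-length, t)``; a ``-`` gene the reverse complement of
    ``[t, t+length)``.  Sequences are clipped at contig edges; genes at
    the very edge (empty upstream) are omitted.
    """
    if isinstance(genome, (str, Path)):
        from pyfaidx import Fasta
        genome = Fasta(str(genome))
    out: dict[str, str] = {}
    for gene_id, gm in annotation.genes.items():
        try:
            contig = genome[gm.chrom]
        except KeyError:
            raise KeyError(f"gene {gene_id}: contig {gm.chrom!r} not in genome")
        contig_len = len(contig)
        if gm.strand == "+":
            start = max(0, gm.tss - length)
            seq = str(contig[start:gm.tss])
        else:
            end = min(contig_len, gm.tss + length)
            seq = reverse_complement(str(contig[gm.tss:end]))
        seq = seq.upper()
        if seq:
            out[gene_id] = seq
    return out


def scan_presence(seqs: Mapping[str, str], motif: str) -> dict[str, bool]:
    """Presence/absence of the motif per sequence, given strand only.

    Multiple occurrences in one sequence still count once; the reverse
    complement is not searched.
    """
    pat = compile_iupac(motif)
    return {name: pat.search(seq.upper()) is not None
            for name, seq in seqs.items()}


@dataclass(frozen=True)
class MotifEnrichment:
    motif: str
    fg_hit: int
    fg_total: int
    bg_hit: int
    bg_total: int
    p: float


def motif_enrichment(foreground: Iterable[str], background: Iterable[str],
                     seqs: Mapping[str, str], motif: str) -> MotifEnrichment:
    """One-sided Fisher test for motif over-representation in the
    foreground gene set versus a disjoint background."""
    fg = [g for g in foreground if g in seqs]
    bg = [g for g in background if g in seqs]
    if not fg:
        raise ValueError("empty foreground")
    if set(fg) & set(bg):
        raise ValueError("foreground and background overlap")
    present = scan_presence({g: seqs[g] for g in fg + bg}, motif)
    fg_hit = sum(present[g] for g in fg)
    bg_hit = sum(present[g] for g in bg)
    p = fisher_exact_upper(((fg_hit, len(fg) - fg_hit),
                            (bg_hit, len(bg) - bg_hit)))
    return MotifEnrichment(motif, fg_hit, len(fg), bg_hit, len(bg), p)
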