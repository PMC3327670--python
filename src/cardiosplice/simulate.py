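"""Synthetic study generator with known ground truth.

Emulates the count structure of the two-model cardiac-hypertrophy
design: four conditions (sham, TAC, sedentary, exercise) x 3 biological
replicates, single-end 36 bp reads, overdispersed per-exon counts.  The
generator produces a toy annotation (non-overlapping genes, 1-12 exons,
a knownAlt-labelled fraction), a random genome, per-sample read
intervals (plus decoy multi-mapped / 2-mismatch / mitochondrial reads to
exercise the filters), GMT pathway sets, and a truth table recording
every spiked signal:

* ordinary DEG spikes per contrast, fold changes log-uniform in the
  configured range (default 5-9x, the magnitude of the study's headline
  induced genes);
* *turned-on* genes with a near-zero baseline that activate under TAC;
* *opposite* genes spiked up in one contrast and down in the other;
* exon inclusion/exclusion events that shift one labelled exon's
  inclusion proportion by a configured delta in one contrast;
* a spiked pathway built mostly from spiked DEGs and a motif planted in
  the upstream of the turned-on and opposite genes.

Counts are negative-binomial: ``var = mu + (bcv * mu)^2`` where ``bcv``
is the biological coefficient of variation between replicates (default
0.1, the canonical value for genetically identical model organisms).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import ALT_TYPES, Annotation, ExonRecord
from .enrichment import PathwayDB
from .motifscan import reverse_complement
from .quantify import CONDITIONS

#: knownAlt label frequencies, weighted toward the types the study found
#: most abundant (alternative promoters, then cassette and bleeding exons).
ALT_TYPE_WEIGHTS = {
    "altPromoter": 0.35, "cassetteExon": 0.25, "bleedingExon": 0.12,
    "altFinish": 0.08, "altThreePrime": 0.06, "altFivePrime": 0.06,
    "retainedIntron": 0.05, "strangeSplice": 0.03,
}


@dataclass
class SimulationConfig:
    """All generator knobs; defaults are the desk-scale study conditions."""

    n_genes: int = 300
    exon_range: tuple[int, int] = (1, 12)
    exon_length_range: tuple[int, int] = (80, 300)
    intron_length_range: tuple[int, int] = (60, 400)
    intergenic_range: tuple[int, int] = (1200, 2000)
    alt_fraction: float = 0.3
    n_contigs: int = 2
    chrm_name: str = "chrM"
    chrm_length: int = 3000

    n_replicates: int = 3
    library_size: int = 200_000
    bcv: float = 0.1                      # replicate-to-replicate CV
    read_length: int = 36
    decoy_fraction: float = 0.06          # multi-mapped / 2-mismatch / chrM

    # spiked differential expression (counts per category)
    n_deg_pah_up: int = 10
    n_deg_pah_down: int = 4
    n_deg_phh_up: int = 2
    n_deg_phh_down: int = 4
    n_turned_on: int = 6
    n_opposite: int = 4
    deg_fc_range: tuple[float, float] = (5.0, 9.0)
    turned_on_base_theta: tuple[float, float] = (1e-5, 5e-5)
    turned_on_induced_theta: tuple[float, float] = (0.05, 0.15)
    min_spiked_theta: float = 0.3         # floor on baseline expression of spiked genes

    # spiked alternative splicing
    n_as_events: int = 30
    as_delta: float = 0.3
    as_baseline_inclusion: float = 0.25
    min_as_theta: float = 0.5

    # pathways
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (15, 40)
    spiked_pathway_size: int = 20
    spiked_pathway_n_deg: int = 15

    motif: str = "GGGAGGG"

    @classmethod
    def null(cls, **overrides) -> "SimulationConfig":
        """A zero-effect configuration (no spikes of any kind)."""
        return cls(n_deg_pah_up=0, n_deg_pah_down=0, n_deg_phh_up=0,
                   n_deg_phh_down=0, n_turned_on=0, n_opposite=0,
                   n_as_events=0, **overrides)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class TruthTable:
    """Ground truth for every spiked signal (test-only; the pipeline
    never reads it)."""

    genes: pd.DataFrame      # per-gene spike status and true fold changes
    exons: pd.DataFrame      # per-exon AS spike status
    pathways: pd.DataFrame   # per-pathway is_spiked
    motif_genes: list[str]   # genes whose upstream carries the planted motif


@dataclass
class StudyFixture:
    """Everything one simulated study produces."""

    config: SimulationConfig
    seed: int
    annotation: Annotation
    genome: dict[str, str]
    samples: pd.DataFrame            # sample_id, condition, replicate, mapped_reads_total
    exon_counts: pd.DataFrame
    gene_counts: pd.DataFrame
    reads: dict[str, pd.DataFrame] | None
    pathways: PathwayDB
    truth: TruthTable


# -- annotation / genome ----------------------------------------------------

def build_toy_annotation(n_genes: int = 300, exon_range: tuple[int, int] = (1, 12),
                         alt_fraction: float = 0.3, seed: int = 0,
                         config: SimulationConfig | None = None,
                         rng: np.random.Generator | None = None,
                         ) -> tuple[Annotation, dict[str, str]]:
    """Random non-overlapping gene models on 1-2 contigs plus a genome.

    Deterministic under ``seed``; ``alt_fraction`` of exons receive one
    knownAlt label drawn from the weighted 8-type vocabulary.
    """
    if n_genes < 10:
        raise ValueError("need at least 10 genes")
    cfg = config or SimulationConfig(n_genes=n_genes, exon_range=exon_range,
                                     alt_fraction=alt_fraction)
    if rng is None:
        rng = np.random.default_rng(seed)
    types = sorted(ALT_TYPE_WEIGHTS)
    weights = np.array([ALT_TYPE_WEIGHTS[t] for t in types])
    weights = weights / weights.sum()

    contig_names = [f"chrS{i + 1}" for i in range(cfg.n_contigs)]
    cursors = {c: 1500 for c in contig_names}
    exons: list[ExonRecord] = []
    width = len(str(n_genes))
    for gi in range(n_genes):
        chrom = contig_names[gi % cfg.n_contigs]
        gene_id = f"G{gi + 1:0{width}d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(cfg.exon_range[0], cfg.exon_range[1] + 1))
        pos = cursors[chrom] + int(rng.integers(*cfg.intergenic_range))
        for ei in range(n_ex):
            length = int(rng.integers(*cfg.exon_length_range))
            alt = frozenset()
            if rng.random() < cfg.alt_fraction:
                alt = frozenset([str(rng.choice(types, p=weights))])
            exons.append(ExonRecord(
                exon_id=f"{gene_id}.e{ei + 1}", gene_id=gene_id, chrom=chrom,
                start=pos, end=pos + length, strand=strand, alt_types=alt))
            pos += length + int(rng.integers(*cfg.intron_length_range))
        cursors[chrom] = pos + 1500   # room for the next gene's upstream

    genome = {}
    bases = np.frombuffer(b"ACGT", dtype="S1")
    for chrom in contig_names:
        n = cursors[chrom] + 2000
        genome[chrom] = rng.choice(bases, size=n).tobytes().decode("ascii")
    genome[cfg.chrm_name] = rng.choice(
        bases, size=cfg.chrm_length).tobytes().decode("ascii")
    return Annotation(exons), genome


def _plant_motif(genome: dict[str, str], annotation: Annotation,
                 genes: list[str], motif: str, rng: np.random.Generator) -> None:
    """Write the motif into each gene's upstream so a strand-aware
    extraction contains it verbatim."""
    for gene_id in genes:
        gm = annotation.gene(gene_id)
        off = int(rng.integers(50, 950 - len(motif)))
        if gm.strand == "+":
            start = gm.tss - 1000 + off
            insert = motif
        else:
            # upstream read as RC of [tss, tss+1000): plant RC of the motif
            start = gm.tss + 1000 - off - len(motif)
            insert = reverse_complement(motif)
        seq = genome[gm.chrom]
        genome[gm.chrom] = seq[:start] + insert + seq[start + len(insert):]


# -- the experiment ---------------------------------------------------------

def _nb_counts(mu: np.ndarray, bcv: float, rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial draws with var = mu + (bcv*mu)^2 (gamma-Poisson)."""
    mu = np.asarray(mu, dtype=float)
    if bcv <= 0:
        return rng.poisson(mu)
    shape = 1.0 / bcv ** 2
    lam = rng.gamma(shape, 1.0, size=mu.shape) * (bcv ** 2) * mu
    return rng.poisson(lam)


def simulate_experiment(annotation: Annotation, genome: dict[str, str],
                        config: SimulationConfig, seed: int = 0,
                        rng: np.random.Generator | None = None,
                        materialize_reads: bool = True) -> StudyFixture:
    """Draw the full 4-condition x R-replicate experiment with spikes.

    Spike assignments, expression draws, counts and (optionally) read
    intervals all flow from one RNG, so a fixed seed reproduces the
    fixture exactly.
    """
    cfg = config
    if rng is None:
        rng = np.random.default_rng(seed)
    gene_ids = annotation.gene_ids
    n_genes = len(gene_ids)
    lengths = annotation.gene_lengths().loc[gene_ids].to_numpy(dtype=float)

    # -- choose spiked genes (disjoint categories) ----------------------
    n_spike = (cfg.n_deg_pah_up + cfg.n_deg_pah_down + cfg.n_deg_phh_up
               + cfg.n_deg_phh_down + cfg.n_turned_on + cfg.n_opposite)
    if n_spike > n_genes:
        raise ValueError("more DEG spikes requested than genes available")
    perm = rng.permutation(n_genes)
    cut = np.cumsum([cfg.n_deg_pah_up, cfg.n_deg_pah_down, cfg.n_deg_phh_up,
                     cfg.n_deg_phh_down, cfg.n_turned_on, cfg.n_opposite])
    pah_up, pah_down, phh_up, phh_down, turned_on, opposite = (
        np.split(perm[:cut[-1]], cut[:-1]))

    # -- baseline expression and per-condition fold changes -------------
    theta = rng.lognormal(0.0, 1.0, size=n_genes)
    spiked_idx = perm[:cut[-1]]
    theta[spiked_idx] = np.maximum(theta[spiked_idx], cfg.min_spiked_theta)
    theta[turned_on] = rng.uniform(*cfg.turned_on_base_theta, size=len(turned_on))

    def draw_fc(k):
        lo, hi = np.log(cfg.deg_fc_range)
        return np.exp(rng.uniform(lo, hi, size=k))

    fc_pah = np.ones(n_genes)
    fc_phh = np.ones(n_genes)
    fc_pah[pah_up] = draw_fc(len(pah_up))
    fc_pah[pah_down] = 1.0 / draw_fc(len(pah_down))
    fc_phh[phh_up] = draw_fc(len(phh_up))
    fc_phh[phh_down] = 1.0 / draw_fc(len(phh_down))
    # turned-on: near-zero baseline, activated under TAC only
    induced = rng.uniform(*cfg.turned_on_induced_theta, size=len(turned_on))
    fc_pah[turned_on] = induced / theta[turned_on]
    # opposite: discordant directions across the two contrasts
    opp_fc = draw_fc(len(opposite))
    opp_up_in_pah = rng.random(len(opposite)) < 0.5
    fc_pah[opposite] = np.where(opp_up_in_pah, opp_fc, 1.0 / opp_fc)
    fc_phh[opposite] = np.where(opp_up_in_pah, 1.0 / opp_fc, opp_fc)

    theta_cond = {
        "sham": theta.copy(), "TAC": theta * fc_pah,
        "sedentary": theta.copy(), "exercise": theta * fc_phh,
    }

    # -- choose spiked AS exons -----------------------------------------
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    spiked_gene_set = {gene_ids[i] for i in spiked_idx}
    eligible = [e for e in annotation.exons
                if e.alt_types and len(annotation.gene(e.gene_id)) >= 2
                and e.gene_id not in spiked_gene_set
                and theta[gene_index[e.gene_id]] >= 0]
    # at most one spiked exon per gene keeps events independent
    seen_genes: set[str] = set()
    pool = []
    for e in eligible:
        if e.gene_id not in seen_genes:
            pool.append(e)
            seen_genes.add(e.gene_id)
    if cfg.n_as_events > len(pool):
        raise ValueError("more AS spikes requested than eligible labelled exons")
    as_pick = rng.choice(len(pool), size=cfg.n_as_events, replace=False)
    as_exons = [pool[i] for i in as_pick]
    for e in as_exons:   # guarantee the host gene is well expressed
        theta_idx = gene_index[e.gene_id]
        boost = max(theta[theta_idx], cfg.min_as_theta)
        for cond in theta_cond:
            theta_cond[cond][theta_idx] *= boost / theta[theta_idx]
        theta[theta_idx] = boost
    as_contrast = np.array(["PAH", "PHH"])[
        rng.integers(0, 2, size=len(as_exons))] if as_exons else np.array([])
    as_direction = np.array(["inclusion", "exclusion"])[
        rng.integers(0, 2, size=len(as_exons))] if as_exons else np.array([])

    # -- exon inclusion proportions per condition -----------------------
    exon_ids = annotation.exon_ids
    exon_index = {e: i for i, e in enumerate(exon_ids)}
    base_incl = np.ones(len(exon_ids))
    for i, ex in enumerate(annotation.exons):
        if ex.alt_types and len(annotation.gene(ex.gene_id)) >= 2:
            base_incl[i] = rng.uniform(0.4, 0.9)
    incl_cond = {c: base_incl.copy() for c in CONDITIONS}
    truth_baseline = {}
    for e, contrast, direction in zip(as_exons, as_contrast, as_direction):
        i = exon_index[e.exon_id]
        if direction == "inclusion":
            base = cfg.as_baseline_inclusion
            shifted = base + cfg.as_delta
        else:
            base = cfg.as_baseline_inclusion + cfg.as_delta
            shifted = base - cfg.as_delta
        truth_baseline[e.exon_id] = base
        for c in CONDITIONS:
            incl_cond[c][i] = base
        treated = "TAC" if contrast == "PAH" else "exercise"
        incl_cond[treated][i] = shifted

    # -- per-sample counts: gene-level NB, multinomial split over exons --
    # Biological replicate noise acts on whole-gene expression (shared by
    # the gene's exons); conditional on the gene total, reads fall on
    # exons multinomially by length x inclusion.  Exon usage is thus
    # binomial under the null, which is what Fisher's exact test assumes.
    exon_gene_idx = np.array([gene_index[e.gene_id] for e in annotation.exons])
    exon_len = np.array([e.length for e in annotation.exons], dtype=float)
    order = np.argsort(exon_gene_idx, kind="stable")
    samples = []
    exon_cols = {}
    for cond in CONDITIONS:
        w_gene = theta_cond[cond] * lengths
        mu_gene = cfg.library_size * w_gene / w_gene.sum()
        w_exon = exon_len * incl_cond[cond]
        denom = np.bincount(exon_gene_idx, weights=w_exon, minlength=n_genes)
        probs = w_exon / denom[exon_gene_idx]
        for rep in range(1, cfg.n_replicates + 1):
            sid = f"{cond}_{rep}"
            samples.append({"sample_id": sid, "condition": cond, "replicate": rep})
            gene_n = _nb_counts(mu_gene, cfg.bcv, rng)
            counts = np.zeros(len(exon_gene_idx), dtype=np.int64)
            for g in np.flatnonzero(gene_n):
                idx = order[np.searchsorted(exon_gene_idx[order], g, "left"):
                            np.searchsorted(exon_gene_idx[order], g, "right")]
                p = probs[idx]
                counts[idx] = rng.multinomial(gene_n[g], p / p.sum())
            exon_cols[sid] = counts

    exon_counts = pd.DataFrame(exon_cols, index=exon_ids)
    gene_counts = exon_counts.groupby(annotation.exon_gene_map()).sum()
    gene_counts = gene_counts.reindex(gene_ids)
    samples = pd.DataFrame(samples)
    samples["mapped_reads_total"] = gene_counts.sum(axis=0).loc[
        samples["sample_id"]].to_numpy()

    # -- plant the promoter motif ---------------------------------------
    motif_genes = sorted(gene_ids[i] for i in np.concatenate([turned_on, opposite]))
    genome = dict(genome)
    if motif_genes:
        _plant_motif(genome, annotation, motif_genes, cfg.motif, rng)

    # -- materialize read intervals -------------------------------------
    reads = None
    if materialize_reads:
        reads = {}
        for sid in samples["sample_id"]:
            reads[sid] = _materialize_reads(
                annotation, genome, exon_counts[sid], cfg, sid, rng)

    # -- pathways --------------------------------------------------------
    pathways, pathway_truth = _build_pathways(gene_ids, spiked_gene_set, cfg, rng)

    # -- truth tables ----------------------------------------------------
    direction_pah = np.array(["none"] * n_genes, dtype=object)
    direction_pah[fc_pah > 1] = "up"
    direction_pah[fc_pah < 1] = "down"
    direction_phh = np.array(["none"] * n_genes, dtype=object)
    direction_phh[fc_phh > 1] = "up"
    direction_phh[fc_phh < 1] = "down"
    genes_truth = pd.DataFrame({
        "gene_id": gene_ids,
        "is_deg_pah": fc_pah != 1.0,
        "is_deg_phh": fc_phh != 1.0,
        "direction_pah": direction_pah,
        "direction_phh": direction_phh,
        "true_fc_pah": fc_pah,
        "true_fc_phh": fc_phh,
        "is_turned_on": np.isin(np.arange(n_genes), turned_on),
        "is_opposite": np.isin(np.arange(n_genes), opposite),
    }).set_index("gene_id", drop=False)
    as_by_exon = {e.exon_id: (c, d) for e, c, d in
                  zip(as_exons, as_contrast, as_direction)}
    exons_truth = pd.DataFrame({
        "exon_id": exon_ids,
        "gene_id": [e.gene_id for e in annotation.exons],
        "is_as_event": [e.exon_id in as_by_exon for e in annotation.exons],
        "contrast": [as_by_exon.get(e.exon_id, ("none",))[0]
                     for e in annotation.exons],
        "direction": [as_by_exon[e.exon_id][1] if e.exon_id in as_by_exon
                      else "none" for e in annotation.exons],
        "baseline_inclusion": [truth_baseline.get(e.exon_id, np.nan)
                               for e in annotation.exons],
        "delta_inclusion": [cfg.as_delta if e.exon_id in as_by_exon else 0.0
                            for e in annotation.exons],
    }).set_index("exon_id", drop=False)

    return StudyFixture(
        config=cfg, seed=seed, annotation=annotation, genome=genome,
        samples=samples, exon_counts=exon_counts, gene_counts=gene_counts,
        reads=reads, pathways=pathways,
        truth=TruthTable(genes_truth, exons_truth, pathway_truth, motif_genes))


def _materialize_reads(annotation: Annotation, genome: dict[str, str],
                       exon_counts: pd.Series, cfg: SimulationConfig,
                       sample_id: str, rng: np.random.Generator) -> pd.DataFrame:
    """Turn per-exon counts into 36 bp read intervals plus decoy reads."""
    rl = cfg.read_length
    chroms, starts, ends, ids, mms = [], [], [], [], []
    serial = 0
    for ex, k in zip(annotation.exons, exon_counts.to_numpy()):
        if k == 0:
            continue
        span = max(1, ex.length - rl + 1)
        s = ex.start + rng.integers(0, span, size=k)
        e = np.minimum(s + rl, ex.end)
        mm = rng.integers(0, 2, size=k)
        for j in range(k):
            serial += 1
            ids.append(f"{sample_id}:r{serial}")
        chroms.extend([ex.chrom] * int(k))
        starts.extend(s.tolist())
        ends.extend(e.tolist())
        mms.extend(mm.tolist())

    # decoys: excluded by the alignment filters, present to exercise them
    n_decoy = int(round(cfg.library_size * cfg.decoy_fraction))
    n_multi = n_decoy // 3
    n_mm2 = n_decoy // 3
    n_chrm = n_decoy - n_multi - n_mm2
    contigs = [c for c in genome if c != cfg.chrm_name]
    for i in range(n_multi):   # one read id, two loci
        serial += 1
        rid = f"{sample_id}:d{serial}"
        for _ in range(2):
            chrom = contigs[int(rng.integers(0, len(contigs)))]
            s = int(rng.integers(0, len(genome[chrom]) - rl))
            chroms.append(chrom); starts.append(s); ends.append(s + rl)
            ids.append(rid); mms.append(0)
    exon_list = annotation.exons
    for i in range(n_mm2):     # unique but 2 mismatches, placed inside exons
        serial += 1
        ex = exon_list[int(rng.integers(0, len(exon_list)))]
        s = ex.start + int(rng.integers(0, max(1, ex.length - rl + 1)))
        chroms.append(ex.chrom); starts.append(s)
        ends.append(min(s + rl, ex.end))
        ids.append(f"{sample_id}:d{serial}"); mms.append(2)
    for i in range(n_chrm):    # clean reads on the mitochondrial contig
        serial += 1
        s = int(rng.integers(0, cfg.chrm_length - rl))
        chroms.append(cfg.chrm_name); starts.append(s); ends.append(s + rl)
        ids.append(f"{sample_id}:d{serial}"); mms.append(0)

    df = pd.DataFrame({
        "chrom": chroms, "start": starts, "end": ends,
        "read_id": ids, "mismatches": mms, "strand": "+",
    })
    df["is_unique"] = ~df["read_id"].duplicated(keep=False)
    return df


def _build_pathways(gene_ids: list[str], spiked_genes: set[str],
                    cfg: SimulationConfig, rng: np.random.Generator,
                    ) -> tuple[PathwayDB, pd.DataFrame]:
    """Random gene sets plus one pathway packed with spiked DEGs."""
    all_genes = np.array(gene_ids)
    spiked = sorted(spiked_genes)
    sets: dict[str, list[str]] = {}
    truth_rows = []
    if cfg.n_pathways > 0 and spiked:
        n_deg = min(cfg.spiked_pathway_n_deg, len(spiked))
        members = list(rng.choice(spiked, size=n_deg, replace=False))
        others = [g for g in gene_ids if g not in set(members)]
        n_fill = max(0, cfg.spiked_pathway_size - n_deg)
        members += list(rng.choice(others, size=n_fill, replace=False))
        sets["PW_spiked"] = sorted(members)
        truth_rows.append({"pathway_id": "PW_spiked", "is_spiked": True})
    n_rand = cfg.n_pathways - len(sets)
    for i in range(n_rand):
        size = int(rng.integers(*cfg.pathway_size_range))
        pid = f"PW{i + 1:03d}"
        sets[pid] = sorted(rng.choice(all_genes, size=size, replace=False))
        truth_rows.append({"pathway_id": pid, "is_spiked": False})
    db = PathwayDB(sets)
    return db, pd.DataFrame(truth_rows).set_index("pathway_id", drop=False)


def simulate_study(config: SimulationConfig | None = None, seed: int = 0,
                   materialize_reads: bool = True) -> StudyFixture:
    """Convenience: annotation + genome + experiment in one call."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    annotation, genome = build_toy_annotation(
        cfg.n_genes, cfg.exon_range, cfg.alt_fraction, config=cfg, rng=rng)
    return simulate_experiment(annotation, genome, cfg, seed=seed, rng=rng,
                               materialize_reads=materialize_reads)


# -- fixture emission -------------------------------------------------------

def emit_fixture(fixture: StudyFixture, outdir: str | Path) -> dict[str, Path]:
    """Write the fixture as the flat files the pipeline consumes.

    Re-emission under the same seed is byte-identical.  Truth files live
    under ``truth/`` and are never read by the pipeline itself.
    """
    out = Path(outdir)
    (out / "reads").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    paths: dict[str, Path] = {}

    from .annotation import write_exon_bed
    paths["annotation"] = out / "annotation.bed"
    write_exon_bed(fixture.annotation, paths["annotation"])

    paths["genome"] = out / "genome.fa"
    with open(paths["genome"], "w") as fh:
        for chrom in sorted(fixture.genome):
            fh.write(f">{chrom}\n")
            seq = fixture.genome[chrom]
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")

    if fixture.reads is None:
        raise ValueError("fixture was simulated without materialized reads")
    manifest_rows = []
    for r in fixture.samples.itertuples(index=False):
        rel = Path("reads") / f"{r.sample_id}.bed"
        fixture.reads[r.sample_id][
            ["chrom", "start", "end", "read_id", "mismatches", "strand"]
        ].to_csv(out / rel, sep="\t", header=False, index=False)
        manifest_rows.append({"sample_id": r.sample_id, "condition": r.condition,
                              "replicate": r.replicate, "path": str(rel)})
    paths["manifest"] = out / "manifest.tsv"
    pd.DataFrame(manifest_rows).to_csv(paths["manifest"], sep="\t", index=False)

    paths["pathways"] = out / "pathways.gmt"
    fixture.pathways.to_gmt(paths["pathways"])

    t = fixture.truth
    t.genes.to_csv(out / "truth" / "genes.tsv", sep="\t", index=False)
    t.exons.to_csv(out / "truth" / "exons.tsv", sep="\t", index=False)
    t.pathways.to_csv(out / "truth" / "pathways.tsv", sep="\t", index=False)
    (out / "truth" / "motif_genes.txt").write_text(
        "".join(g + "\n" for g in t.motif_genes))

    paths["config"] = out / "fixture.json"
    with open(paths["config"], "w") as fh:
        json.dump({"seed": fixture.seed, "config": fixture.config.to_dict()},
                  fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
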