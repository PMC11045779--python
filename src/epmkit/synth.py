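"""Synthetic genomes with planted expression-predictive motifs.

The generator builds fully specified toy datasets in which short planted
motifs *causally* determine the expression class, so that every stage of the
pipeline (labelling, fold assembly, training, attribution, motif discovery,
scanning, conservation) can be scored against recorded ground truth:

* multi-chromosome genomes of i.i.d. background sequence at a configurable
  GC content, with non-overlapping genes on random strands;
* exact quartile class design (25% low / 50% medium / 25% high);
* class-associated motifs inserted at seeded offsets relative to the TSS (or
  TTS) of genes of their class, recorded in a truth table;
* sequence-identical gene duplications across chromosomes with a matching
  12-column homology hit table;
* expression (TPM) tables whose quartile labelling reproduces the designed
  classes;
* genotype panels in which a deletion disrupts the planted motif in a seeded
  subset of genes and non-reference genotypes, with a complete edit ledger.

All randomness flows from a single seed; identical configs give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .regions import GeneAnnotation, RegionConfig

__all__ = ["MotifSpec", "EditSpec", "SyntheticConfig", "SyntheticDataset",
           "generate_genome", "generate_expression", "generate_genotypes"]


@dataclass(frozen=True)
class MotifSpec:
    pattern: str
    class_assoc: str  # high | low
    anchor: str = "TSS"  # TSS | TTS
    offset_range: tuple = (20, 200)
    insertion_prob: float = 0.9

    def __post_init__(self):
        if set(self.pattern) - set("ACGT"):
            raise ValueError("motif pattern must be over ACGT")
        if not 0 <= self.insertion_prob <= 1:
            raise ValueError("insertion_prob must be in [0, 1]")


@dataclass(frozen=True)
class EditSpec:
    target_motif: str
    indel_len: int = 12
    fraction_of_genotypes: float = 0.4
    edited_gene_fraction: float = 0.5


def default_motif_specs():
    return (
        MotifSpec(pattern="CACCTGTC", class_assoc="high", anchor="TSS",
                  offset_range=(20, 200), insertion_prob=0.9),
        MotifSpec(pattern="AGATCCGA", class_assoc="low", anchor="TSS",
                  offset_range=(20, 200), insertion_prob=0.9),
    )


@dataclass
class SyntheticConfig:
    n_chroms: int = 4
    genes_per_chrom: int = 500
    gene_len: int = 2000
    intergenic_len: int = 4000
    motif_specs: tuple = field(default_factory=default_motif_specs)
    background_gc: float = 0.4
    duplicate_fraction: float = 0.05
    n_genotypes: int = 15
    edit_spec: EditSpec | None = None
    seed: int = 0

    def __post_init__(self):
        if self.edit_spec is None:
            self.edit_spec = EditSpec(target_motif=self.motif_specs[0].pattern)
        if self.gene_len <= 0 or self.intergenic_len < 0:
            raise ValueError("invalid geometry")


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genome: dict  # chrom -> sequence
    annotations: list  # GeneAnnotation
    truth: pd.DataFrame  # one row per planted motif instance
    classes: pd.Series  # gene -> designed class
    homology: pd.DataFrame  # 12-column hit table (may be empty)

    def write(self, outdir):
        import os

        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "genome.fa"), "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        with open(os.path.join(outdir, "genes.gff3"), "w") as fh:
            fh.write("##gff-version 3\n")
            for a in self.annotations:
                fh.write(f"{a.chrom}\tsynth\tgene\t{a.start}\t{a.end}\t.\t{a.strand}\t.\t"
                         f"ID={a.gene_id}\n")
        self.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
        self.classes.rename("designed_class").to_csv(
            os.path.join(outdir, "classes.tsv"), sep="\t")
        self.homology.to_csv(os.path.join(outdir, "homology.tsv"), sep="\t",
                             index=False, header=False)


def _random_seq(rng, n, gc):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def generate_genome(cfg: SyntheticConfig) -> SyntheticDataset:
    """Genome + annotation + planted-motif truth + homology table."""
    rng = np.random.default_rng(cfg.seed)
    chrom_len = cfg.intergenic_len + cfg.genes_per_chrom * (cfg.gene_len + cfg.intergenic_len)
    genome, annotations = {}, []
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        seq = list(_random_seq(rng, chrom_len, cfg.background_gc))
        genome[chrom] = seq
        for gi in range(cfg.genes_per_chrom):
            start0 = cfg.intergenic_len + gi * (cfg.gene_len + cfg.intergenic_len)
            strand = "+" if rng.random() < 0.5 else "-"
            annotations.append(GeneAnnotation(
                gene_id=f"g{ci + 1:02d}_{gi + 1:04d}", chrom=chrom,
                start=start0 + 1, end=start0 + cfg.gene_len, strand=strand,
            ))

    n = len(annotations)
    n_low = n_high = n // 4
    klasses = np.array(["low"] * n_low + ["high"] * n_high + ["medium"] * (n - n_low - n_high))
    rng.shuffle(klasses)
    classes = pd.Series(klasses, index=[a.gene_id for a in annotations], name="designed_class")

    ann_by_id = {a.gene_id: a for a in annotations}
    truth_rows = []
    for a in annotations:
        for spec in cfg.motif_specs:
            if classes[a.gene_id] != spec.class_assoc:
                continue
            if rng.random() >= spec.insertion_prob:
                continue
            off = int(rng.integers(spec.offset_range[0], spec.offset_range[1] + 1))
            truth_rows.append(_plant(genome[a.chrom], a, spec, off))
    truth = pd.DataFrame(truth_rows, columns=[
        "gene_id", "chrom", "strand", "class_assoc", "pattern", "anchor",
        "offset", "genome_start0"])

    # Cross-chromosome sequence-identical duplications.  Targets come from
    # the *same designed class* as the source (so quartile counts are
    # preserved) and must be motif-free and unused; each gene takes part in
    # at most one duplication.
    hom_rows = []
    n_dup = int(round(cfg.duplicate_fraction * n))
    if n_dup and cfg.n_chroms > 1:
        carrier_ids = set(truth["gene_id"])
        used: set = set()
        sources = rng.choice(n, size=min(2 * n_dup, n), replace=False)
        done = 0
        for si in sources:
            if done >= n_dup:
                break
            src = annotations[si]
            if src.gene_id in used:
                continue
            pool = [a for a in annotations
                    if a.chrom != src.chrom and a.gene_id not in used
                    and a.gene_id not in carrier_ids
                    and a.gene_id != src.gene_id
                    and classes[a.gene_id] == classes[src.gene_id]]
            if not pool:
                continue
            tgt = pool[int(rng.integers(len(pool)))]
            # margin covers the extracted flanks without touching neighbours
            _copy_gene(genome, ann_by_id, src, tgt,
                       margin=min(1500, cfg.intergenic_len // 2))
            used.update({src.gene_id, tgt.gene_id})
            done += 1
            src_truth = truth[truth["gene_id"] == src.gene_id]
            for _, row in src_truth.iterrows():
                spec = MotifSpec(pattern=row["pattern"], class_assoc=row["class_assoc"],
                                 anchor=row["anchor"])
                truth = pd.concat([truth, pd.DataFrame([_plant(
                    genome[tgt.chrom], tgt, spec, int(row["offset"]))])],
                    ignore_index=True)
            hom_rows.append([tgt.gene_id, src.gene_id, 100.0, cfg.gene_len // 3, 0, 0,
                             1, cfg.gene_len // 3, 1, cfg.gene_len // 3, 1e-30, 200.0])
    homology = pd.DataFrame(hom_rows, columns=list(range(12)))

    genome = {c: "".join(s) for c, s in genome.items()}
    return SyntheticDataset(config=cfg, genome=genome, annotations=annotations,
                            truth=truth, classes=classes, homology=homology)


def _plant(seq_list, a: GeneAnnotation, spec: MotifSpec, off: int) -> dict:
    """Overwrite the motif into the (list-of-chars) chromosome, in gene
    orientation at ``off`` downstream of the anchor; returns the truth row."""
    start0, end0 = a.start - 1, a.end - 1
    w = len(spec.pattern)
    if spec.anchor == "TSS":
        if a.strand == "+":
            g0 = start0 + off
            seq_list[g0 : g0 + w] = list(spec.pattern)
        else:
            g0 = end0 - off - w + 1
            seq_list[g0 : g0 + w] = list(reverse_complement(spec.pattern))
    else:  # TTS anchor: off upstream of the gene end, in gene orientation
        if a.strand == "+":
            g0 = end0 - off - w + 1
            seq_list[g0 : g0 + w] = list(spec.pattern)
        else:
            g0 = start0 + off
            seq_list[g0 : g0 + w] = list(reverse_complement(spec.pattern))
    return {"gene_id": a.gene_id, "chrom": a.chrom, "strand": a.strand,
            "class_assoc": spec.class_assoc, "pattern": spec.pattern,
            "anchor": spec.anchor, "offset": off, "genome_start0": g0}


def _copy_gene(genome: dict, ann_by_id: dict, src: GeneAnnotation, tgt: GeneAnnotation,
               margin: int = 1500):
    """Copy the gene body plus ``margin`` nt of both flanks, respecting
    strand (the copy reads identically in gene orientation)."""
    s_seq, t_seq = genome[src.chrom], genome[tgt.chrom]
    s_lo, s_hi = src.start - 1 - margin, src.end + margin
    block = "".join(s_seq[s_lo:s_hi])
    if src.strand != tgt.strand:
        block = reverse_complement(block)
    t_lo = tgt.start - 1 - margin
    t_seq[t_lo : t_lo + len(block)] = list(block)


def generate_expression(dataset: SyntheticDataset, n_samples: int = 3,
                        noise_sd: float = 0.05, seed: int | None = None) -> pd.DataFrame:
    """Gene x sample TPM table realising the designed classes.

    Low genes are a mixture of a point mass at zero TPM and a weak
    lognormal component; medium and high genes draw from well separated
    lognormal components; samples add multiplicative noise.  Quartile
    labelling of the result reproduces the designed classes for >= 95% of
    genes (100% at zero noise).
    """
    cfg = dataset.config
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    mu = {"low": 0.15, "medium": 1.0, "high": 2.2}
    sd = {"low": 0.05, "medium": 0.1, "high": 0.2}
    rows = {}
    for gene, klass in dataset.classes.items():
        if klass == "low" and rng.random() < 0.5:
            base = 0.0
        else:
            base = 10.0 ** rng.normal(mu[klass], sd[klass]) - 1.0
        base = max(base, 0.0)
        noise = 10.0 ** rng.normal(0.0, noise_sd, size=n_samples) if noise_sd > 0 else np.ones(n_samples)
        rows[gene] = np.maximum(base * noise, 0.0)
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[f"sample{i + 1}" for i in range(n_samples)])


def generate_genotypes(dataset: SyntheticDataset, region_cfg: RegionConfig | None = None,
                       gene_ids=None):
    """Per-genotype fused flanking sequences plus an edit ledger.

    Genotype 0 is the reference ('ref'); a seeded subset of the other
    genotypes carries a deletion of ``edit_spec.indel_len`` nt that starts
    2 nt before the planted target-motif instance of a seeded subset of the
    motif-carrying genes.  Deleted flanks are refilled from the genomic
    sequence beyond the window, so every fused sequence keeps its length.

    Returns ``(flanks, ledger)``: ``flanks[genotype][gene] = fused string``;
    the ledger is a DataFrame (genotype, gene_id, fused_del_start, indel_len).
    """
    from .regions import extract_flanks

    cfg = dataset.config
    region_cfg = region_cfg or RegionConfig()
    edit = cfg.edit_spec
    rng = np.random.default_rng(cfg.seed + 2)

    genotype_ids = ["ref"] + [f"gt{i:02d}" for i in range(1, cfg.n_genotypes)]
    n_edited_gt = int(round(edit.fraction_of_genotypes * (cfg.n_genotypes - 1)))
    edited_gts = sorted(rng.choice(genotype_ids[1:], size=n_edited_gt, replace=False))

    carriers = dataset.truth[dataset.truth["pattern"] == edit.target_motif]
    carrier_genes = sorted(carriers["gene_id"].unique())
    n_edit_genes = int(round(edit.edited_gene_fraction * len(carrier_genes)))
    edited_genes = set(rng.choice(carrier_genes, size=n_edit_genes, replace=False))

    ann_by_id = {a.gene_id: a for a in dataset.annotations}
    if gene_ids is None:
        gene_ids = [a.gene_id for a in dataset.annotations]

    ref_flanks = {}
    edited_flanks = {}
    ledger_rows = []
    for g in gene_ids:
        a = ann_by_id[g]
        ref_flanks[g] = extract_flanks(a, dataset.genome[a.chrom], region_cfg).fused
        if g in edited_genes:
            row = carriers[carriers["gene_id"] == g].iloc[0]
            edited_flanks[g], fused_del = _delete_in_flank(
                a, dataset.genome[a.chrom], region_cfg, int(row["offset"]),
                str(row["anchor"]), edit.indel_len)
            for gt in edited_gts:
                ledger_rows.append({"genotype": gt, "gene_id": g,
                                    "fused_del_start": fused_del,
                                    "indel_len": edit.indel_len})

    flanks = {}
    for gt in genotype_ids:
        if gt in edited_gts:
            flanks[gt] = {g: edited_flanks.get(g, ref_flanks[g]) for g in gene_ids}
        else:
            flanks[gt] = dict(ref_flanks)
    ledger = pd.DataFrame(ledger_rows,
                          columns=["genotype", "gene_id", "fused_del_start", "indel_len"])
    return flanks, ledger


def _delete_in_flank(a: GeneAnnotation, chrom_seq: str, rc: RegionConfig,
                     motif_offset: int, anchor: str, indel_len: int):
    """Apply a deletion starting 2 nt before the motif (gene orientation)
    and refill the window from the genome interior so lengths are kept."""
    from .regions import _window, extract_flanks
    from Bio.Seq import reverse_complement as rcomp

    if anchor != "TSS":
        raise NotImplementedError("edits are defined relative to the TSS anchor")
    del_off = max(0, motif_offset - 2)  # offset of deletion start from TSS
    start0, end0 = a.start - 1, a.end - 1
    ext = indel_len
    if a.strand == "+":
        up_ext = _window(chrom_seq, start0 - rc.promoter_len, start0 + rc.utr5_len + ext)
    else:
        up_ext = rcomp(_window(chrom_seq, end0 + 1 - rc.utr5_len - ext,
                               end0 + 1 + rc.promoter_len))
    i = rc.promoter_len + del_off
    up = (up_ext[:i] + up_ext[i + indel_len :])[: rc.upstream_len]
    base = extract_flanks(a, chrom_seq, rc)
    fused = up + "N" * rc.spacer_len + base.downstream
    return fused, i
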