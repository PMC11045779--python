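"""End-to-end orchestration of expression-model experiments.

Stages: flank extraction -> quartile labelling -> fold assembly -> CNN
training -> evaluation -> attribution -> motif discovery -> scanning /
enrichment -> genotype conservation analysis.  The same machinery backs the
command-line interface (file inputs) and the synthetic-data experiments used
throughout the test-suite; all interchange is via plain artifacts and every
written file is recorded in a manifest.
"""

from __future__ import annotations

import time

import numpy as np
import pandas as pd

from . import io as eio
from .analysis import ScanConfig, enrichment, presence_scan
from .attribution import average_saliency, compute_contributions
from .classifier import ModelConfig, evaluate_predictions, train_fold
from .datasets import load_homology, make_folds, shuffle_control
from .discovery import discover_motifs, trim_epm
from .expression import label_table
from .genotypes import (AnalysisConfig, annotate_conservation,
                        bootstrap_percentages, classify_heterogeneity,
                        cluster_genotype_profiles)
from .regions import RegionConfig, encode_genome, one_hot
from .synth import SyntheticConfig, generate_expression, generate_genome, generate_genotypes

__all__ = ["run_synthetic_experiment", "run_experiment"]


def _encode_binary_genes(genes, genome, labels, region_cfg):
    binary = labels[labels["binary"].notna()]
    keep = [g for g in genes if g.gene_id in binary.index]
    ids, mats, flanks = encode_genome(keep, genome, region_cfg)
    encoded = dict(zip(ids, mats))
    fused = {f.gene_id: f.fused for f in flanks}
    lab = {g: int(binary.loc[g, "binary"]) for g in ids}
    return keep, encoded, fused, lab


def _train_folds(folds, encoded, lab, model_cfg, verbose=False, log=None):
    results = {}
    for fold in folds:
        t0 = time.time()
        res = train_fold(fold, encoded, lab, model_cfg, verbose=verbose)
        results[fold.fold_id] = res
        if log is not None:
            log(f"{fold.fold_id}: acc={res.metrics.get('accuracy'):.3f} "
                f"({time.time() - t0:.0f}s, {len(res.history['train_loss'])} epochs)")
    return results


def run_synthetic_experiment(
    synth_cfg: SyntheticConfig | None = None,
    model_cfg: ModelConfig | None = None,
    region_cfg: RegionConfig | None = None,
    analysis_cfg: AnalysisConfig | None = None,
    seed: int = 0,
    train_ssc: bool = True,
    attribution_reference_k: int = 5,
    max_attribution_genes_per_fold: int = 150,
    discovery_kwargs: dict | None = None,
    presence_evalue: float = 0.01,
    run_genotypes: bool = True,
    genotype_max_genes: int = 150,
    output_dir=None,
    verbose: bool = False,
) -> dict:
    """Generate a synthetic dataset and run the full pipeline on it.

    Returns a dictionary with the dataset, labels, folds, per-fold fitted
    results, the shuffled-sequence control metrics, importance tracks,
    discovered EPMs, per-EPM enrichment, and the genotype-conservation
    block.  When ``output_dir`` is given, artifacts and a manifest are
    written there.
    """
    log = print if verbose else (lambda *_: None)
    synth_cfg = synth_cfg or SyntheticConfig(seed=seed)
    region_cfg = region_cfg or RegionConfig()
    if model_cfg is None:
        # default architecture/optimiser with a schedule scaled to the
        # experiment's problem size; min_epochs rides out the pre-ignition
        # plateau before early stopping may trigger (see docs/methods.md)
        model_cfg = ModelConfig(seed=seed, max_epochs=34, min_epochs=18,
                                early_stop_patience=5, lr_reduce_patience=3,
                                plateau_restart_epoch=16, max_restarts=3)
    analysis_cfg = analysis_cfg or AnalysisConfig(seed=seed)
    discovery_kwargs = dict(discovery_kwargs or {})

    # --- data -----------------------------------------------------------
    t0 = time.time()
    dataset = generate_genome(synth_cfg)
    tpm = generate_expression(dataset)
    labels = label_table(tpm)
    log(f"synthetic genome + labels: {time.time() - t0:.0f}s")

    genes, encoded, fused, lab = _encode_binary_genes(
        dataset.annotations, dataset.genome, labels, region_cfg)
    homology = load_homology(dataset.homology) if len(dataset.homology) else []
    folds = make_folds(lab, genes, homology, scheme="SSR", seed=seed)

    # --- training -------------------------------------------------------
    fold_results = _train_folds(folds, encoded, lab, model_cfg, log=log)

    ssc_metrics = None
    if train_ssc:
        from dataclasses import replace

        ssc_folds = make_folds(lab, genes, homology, scheme="SSC", seed=seed)[:1]
        shuffled_strings = shuffle_control([fused[g] for g in sorted(fused)], seed=seed)
        shuffled = {g: one_hot(s) for g, s in zip(sorted(fused), shuffled_strings)}
        # shuffled inputs carry no signal: short schedule, no plateau restarts
        ssc_cfg = replace(model_cfg, max_epochs=min(20, model_cfg.max_epochs),
                          min_epochs=0, plateau_restart_epoch=0, max_restarts=0)
        ssc_res = _train_folds(ssc_folds, shuffled, lab, ssc_cfg, log=log)
        ssc_metrics = {fid: r.metrics for fid, r in ssc_res.items()}

    # --- attribution ----------------------------------------------------
    tracks = []
    rng = np.random.default_rng(seed + 17)
    for fold in folds:
        res = fold_results[fold.fold_id]
        val = list(fold.val_ids)
        if len(val) > max_attribution_genes_per_fold:
            val = list(rng.choice(val, size=max_attribution_genes_per_fold, replace=False))
        import zlib

        for g in val:
            tracks.append(compute_contributions(
                res.network, encoded[g], gene_id=g, reference="shuffled",
                k=attribution_reference_k,
                seed=(seed + zlib.crc32(g.encode())) % (2**31)))
    saliency = average_saliency(tracks) if tracks else None
    log(f"attribution: {len(tracks)} tracks")

    # --- motif discovery ------------------------------------------------
    epms, seqlets = discover_motifs(tracks, encoded, region_cfg, seed=seed,
                                    **discovery_kwargs)
    fwd_epms = [e for e in epms if not e.name.endswith("R")]
    log(f"discovery: {len(seqlets)} seqlets, {len(fwd_epms)} forward EPMs")

    # --- enrichment -----------------------------------------------------
    trimmed = [trim_epm(e) for e in fwd_epms]
    _, presence = presence_scan(trimmed, fused, region_cfg,
                                per_gene_evalue=presence_evalue)
    enrich = []
    high = {g for g, v in lab.items() if v == 1}
    low = {g for g, v in lab.items() if v == 0}
    for epm in trimmed:
        own, opp = (high, low) if epm.metacluster == "p0" else (low, high)
        a = sum(1 for g in own if (g, epm.name) in presence)
        b = sum(1 for g in opp if (g, epm.name) in presence)
        if a + b:
            enrich.append(enrichment(epm.name, a, len(own), b, len(opp)))

    results = {
        "dataset": dataset, "tpm": tpm, "labels": labels, "folds": folds,
        "fold_results": fold_results, "ssc_metrics": ssc_metrics,
        "tracks": tracks, "saliency": saliency, "seqlets": seqlets,
        "epms": epms, "trimmed_epms": trimmed, "presence": presence,
        "enrichment": enrich, "encoded": encoded, "fused": fused,
        "binary_labels": lab, "region_cfg": region_cfg,
    }

    # --- genotype conservation -----------------------------------------
    if run_genotypes and folds:
        # apply the best-performing fold model (lowest validation loss) to
        # the genotype panel, on its own held-out genes
        best_fold = min(folds,
                        key=lambda f: min(fold_results[f.fold_id].history["val_loss"]))
        results["genotype_fold_id"] = best_fold.fold_id
        results["genotypes"] = _genotype_block(
            dataset, best_fold, fold_results[best_fold.fold_id], trimmed,
            region_cfg, analysis_cfg, presence_evalue, log,
            max_genes=genotype_max_genes)

    if output_dir is not None:
        _write_artifacts(output_dir, results, seed, region_cfg)
    return results


def _genotype_block(dataset, fold, fold_res, trimmed_epms, region_cfg,
                    analysis_cfg, presence_evalue, log, max_genes=None):
    gene_ids = list(fold.val_ids)
    if max_genes is not None and len(gene_ids) > max_genes:
        keep = np.random.default_rng(analysis_cfg.seed + 3).choice(
            len(gene_ids), size=max_genes, replace=False)
        gene_ids = [gene_ids[i] for i in sorted(keep)]
    flanks, ledger = generate_genotypes(dataset, region_cfg, gene_ids=gene_ids)
    genotype_ids = sorted(flanks, key=lambda g: (g != "ref", g))

    probs = {}
    for gt in genotype_ids:
        mats = np.stack([one_hot(flanks[gt][g]) for g in gene_ids])
        probs[gt] = fold_res.predict_proba(mats)
    prob_df = pd.DataFrame({gt: probs[gt] for gt in genotype_ids}, index=gene_ids)

    records = [classify_heterogeneity(g, dict(prob_df.loc[g]), analysis_cfg)
               for g in gene_ids]

    matches = []
    for gt in genotype_ids:
        m, _ = presence_scan(trimmed_epms, flanks[gt], region_cfg,
                             per_gene_evalue=presence_evalue, genotype_id=gt)
        matches.extend(m)
    annotate_conservation(records, matches, genotype_ids, "ref",
                          epm_names=[e.name for e in trimmed_epms])

    # bootstrap % conserved / mutated by heterogeneity group, pooled over EPMs
    statuses = {"homogeneous": [], "differential": []}
    for rec in records:
        for name, status in rec.epm_status.items():
            if status in ("conserved", "mutated"):
                statuses[rec.heterogeneity].append(status)
    boots = {grp: (bootstrap_percentages(st, analysis_cfg) if st else None)
             for grp, st in statuses.items()}

    newick, Z = cluster_genotype_profiles(prob_df)
    log(f"genotypes: {len(records)} genes x {len(genotype_ids)} genotypes, "
        f"{len(ledger)} ledger edits")
    return {"flanks": flanks, "ledger": ledger, "prob_df": prob_df,
            "records": records, "matches": matches, "statuses": statuses,
            "bootstrap": boots, "newick": newick, "genotype_ids": genotype_ids}


def _write_artifacts(output_dir, results, seed, region_cfg):
    man = eio.Manifest(output_dir, seed)
    results["dataset"].write(man.path("synthetic"))
    for name in ("genome.fa", "genes.gff3", "truth.tsv", "classes.tsv", "homology.tsv"):
        man.path("synthetic", name)
    eio.write_labels(man.path("labels.tsv"), results["labels"])
    import json

    with open(man.path("folds.json"), "w") as fh:
        json.dump([f.to_manifest() for f in results["folds"]], fh, indent=2)
    metrics = {fid: r.metrics for fid, r in results["fold_results"].items()}
    man.data["metrics"]["folds"] = metrics
    man.data["metrics"]["ssc"] = results.get("ssc_metrics")
    if results.get("saliency") is not None:
        pd.DataFrame({"position": np.arange(results["saliency"].mean_per_position.size),
                      "mean_score": results["saliency"].mean_per_position}).to_csv(
            man.path("saliency.tsv"), sep="\t", index=False)
    eio.write_epm_table(man.path("epms.tsv"), results["epms"])
    eio.write_meme(man.path("epms.meme"), [e for e in results["epms"]
                                           if not e.name.endswith("R")])
    eio.write_enrichment(man.path("enrichment.tsv"), results["enrichment"])
    if "genotypes" in results:
        gt = results["genotypes"]
        gt["ledger"].to_csv(man.path("genotype_edits.tsv"), sep="\t", index=False)
        gt["prob_df"].to_csv(man.path("genotype_probs.tsv"), sep="\t")
        rows = [{"gene_id": r.gene_id, "variance": r.variance,
                 "heterogeneity": r.heterogeneity, **r.epm_status}
                for r in gt["records"]]
        pd.DataFrame(rows).to_csv(man.path("conservation.tsv"), sep="\t", index=False)
        with open(man.path("genotype_tree.nwk"), "w") as fh:
            fh.write(gt["newick"] + "\n")
    man.save()
    return man


def run_experiment(config: dict) -> dict:
    """File-based experiment runner (CLI back end).

    ``config`` keys: fasta, gff, tpm (gene x sample TSV), homology
    (12-column hit table, optional), scheme, output_dir, seed, plus optional
    region/model sub-dicts.  Executes extract -> label -> folds -> train ->
    evaluate -> attribute -> discover and writes artifacts under
    ``output_dir``.
    """
    import os

    from .regions import read_annotation, read_genome

    for key in ("fasta", "gff", "tpm", "output_dir"):
        if key not in config:
            raise ValueError(f"config missing required key {key!r}")
    for key in ("fasta", "gff", "tpm"):
        if not os.path.exists(config[key]):
            raise FileNotFoundError(f"{key} path does not exist: {config[key]}")

    seed = int(config.get("seed", 0))
    region_cfg = RegionConfig(**config.get("region", {}))
    model_cfg = ModelConfig(**{"seed": seed, **config.get("model", {})})
    scheme = config.get("scheme", "SSR").upper()

    genome = read_genome(config["fasta"])
    genes = read_annotation(config["gff"])
    tpm = pd.read_csv(config["tpm"], sep="\t", index_col=0)
    labels = label_table(tpm)
    man = eio.Manifest(config["output_dir"], seed, settings={"scheme": scheme})
    eio.write_labels(man.path("labels.tsv"), labels)

    genes = [g for g in genes if g.gene_id in labels.index]
    keep, encoded, fused, lab = _encode_binary_genes(genes, genome, labels, region_cfg)
    homology = load_homology(config["homology"]) if config.get("homology") else []
    folds = make_folds(lab, keep, homology, scheme=scheme, seed=seed,
                       species_of=config.get("species_of"))
    import json

    with open(man.path("folds.json"), "w") as fh:
        json.dump([f.to_manifest() for f in folds], fh, indent=2)

    if scheme == "SSC":
        shuffled_strings = shuffle_control([fused[g] for g in sorted(fused)], seed=seed)
        encoded = {g: one_hot(s) for g, s in zip(sorted(fused), shuffled_strings)}

    fold_results = _train_folds(folds, encoded, lab, model_cfg)
    man.data["metrics"]["folds"] = {fid: r.metrics for fid, r in fold_results.items()}

    if config.get("attribute", True) and folds:
        tracks = []
        for fold in folds:
            res = fold_results[fold.fold_id]
            for g in fold.val_ids[: config.get("max_attribution_genes", 200)]:
                tracks.append(compute_contributions(
                    res.network, encoded[g], gene_id=g, seed=seed,
                    k=config.get("attribution_k", 5)))
        if tracks:
            sal = average_saliency(tracks)
            pd.DataFrame({"position": np.arange(sal.mean_per_position.size),
                          "mean_score": sal.mean_per_position}).to_csv(
                man.path("saliency.tsv"), sep="\t", index=False)
            epms, _ = discover_motifs(tracks, encoded, region_cfg, seed=seed)
            eio.write_epm_table(man.path("epms.tsv"), epms)
            eio.write_meme(man.path("epms.meme"),
                           [e for e in epms if not e.name.endswith("R")])
    man.save()
    return {"manifest": man.data, "folds": folds, "fold_results": fold_results}
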