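"""Cross-genotype application of a trained model and motif conservation.

Given per-genotype flanking sequences of the same gene set, the trained
classifier yields one high-expression probability per gene and genotype.
Genes are called *differential* when the (population) variance of these
probabilities exceeds a threshold (default 0.005), else *homogeneous*; a
probability <= 0.5 means the low class.  Each EPM is *conserved* for a gene
when it has at least one in-range match in every genotype, and *mutated*
when it is present in the reference genotype but absent from at least one
other; EPMs absent everywhere are *absent* and excluded from the two-way
statistics.  Bootstrap summaries (pool size 100, 1000 replicates by
default), a Fisher intersection test, hierarchical genotype clustering and a
category-level observed-versus-predicted comparison complete the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AnalysisConfig", "ConservationRecord", "CategoryComparison",
           "classify_heterogeneity", "epm_conservation", "bootstrap_percentages",
           "fisher_intersection", "cluster_genotype_profiles", "category_comparison"]


@dataclass
class AnalysisConfig:
    variance_threshold: float = 0.005
    prob_low_cutoff: float = 0.5
    bootstrap_pool: int = 100
    bootstrap_reps: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.prob_low_cutoff < 1:
            raise ValueError("prob_low_cutoff must be in (0, 1)")
        if self.bootstrap_pool <= 0 or self.bootstrap_reps <= 0:
            raise ValueError("bootstrap pool and reps must be > 0")


@dataclass
class ConservationRecord:
    gene_id: str
    probs_by_genotype: dict
    variance: float
    heterogeneity: str  # homogeneous | differential
    class_by_genotype: dict = field(default_factory=dict)
    epm_status: dict = field(default_factory=dict)  # epm -> conserved|mutated|absent


@dataclass
class CategoryComparison:
    category_id: str
    n: int
    scaled_obs_diff: float
    scaled_pred_diff: float
    obs_p: float
    pred_p: float
    obs_fdr: float = float("nan")
    pred_fdr: float = float("nan")


def classify_heterogeneity(gene_id: str, probs_by_genotype: dict,
                           cfg: AnalysisConfig | None = None) -> ConservationRecord:
    """Population-variance heterogeneity call plus per-genotype class."""
    cfg = cfg or AnalysisConfig()
    probs = np.asarray(list(probs_by_genotype.values()), dtype=float)
    var = float(probs.var()) if probs.size else 0.0  # population variance
    het = "differential" if var > cfg.variance_threshold else "homogeneous"
    classes = {g: ("low" if p <= cfg.prob_low_cutoff else "high")
               for g, p in probs_by_genotype.items()}
    return ConservationRecord(
        gene_id=gene_id, probs_by_genotype=dict(probs_by_genotype),
        variance=var, heterogeneity=het, class_by_genotype=classes,
    )


def epm_conservation(presence: dict, reference_genotype: str) -> str:
    """Conserved / mutated / absent status of one EPM for one gene.

    ``presence`` maps genotype -> bool (>= 1 in-range match in that
    genotype's flanks).  Conserved: present in every genotype.  Mutated:
    present in the reference genotype but absent from at least one other.
    Absent everywhere (or missing from the reference): 'absent'.
    """
    if reference_genotype not in presence:
        raise KeyError(f"reference genotype {reference_genotype!r} not scanned")
    if all(presence.values()):
        return "conserved"
    if presence[reference_genotype]:
        return "mutated"
    return "absent"


def annotate_conservation(records, matches, genotype_ids, reference_genotype,
                          epm_names=None, in_range_only: bool = True):
    """Fill ``epm_status`` for every record from per-genotype scan matches.

    ``matches`` is an iterable of MotifMatch with ``genotype_id`` set.
    """
    present: dict = {}
    names = set(epm_names) if epm_names is not None else set()
    for m in matches:
        if in_range_only and not m.within_preferred:
            continue
        present.setdefault((m.gene_id, m.epm_name), set()).add(m.genotype_id)
        if epm_names is None:
            names.add(m.epm_name)
    for rec in records:
        for name in sorted(names):
            found = present.get((rec.gene_id, name), set())
            presence = {g: g in found for g in genotype_ids}
            rec.epm_status[name] = epm_conservation(presence, reference_genotype)
    return records


def bootstrap_percentages(statuses, cfg: AnalysisConfig | None = None) -> dict:
    """Bootstrap distribution of % conserved and % mutated in one gene group.

    ``statuses`` is a sequence of 'conserved'/'mutated' (absent entries should
    already be excluded).  Pools of ``bootstrap_pool`` genes are drawn with
    replacement ``bootstrap_reps`` times.
    """
    cfg = cfg or AnalysisConfig()
    statuses = np.asarray(list(statuses))
    if statuses.size == 0:
        raise ValueError("empty group")
    rng = np.random.default_rng(cfg.seed)
    conserved = (statuses == "conserved").astype(float)
    idx = rng.integers(0, statuses.size, size=(cfg.bootstrap_reps, cfg.bootstrap_pool))
    pc = conserved[idx].mean(axis=1) * 100.0
    return {"pct_conserved": pc, "pct_mutated": 100.0 - pc}


def fisher_intersection(set_a, set_b, universe):
    """Two-sided Fisher exact test on the 2x2 membership table of two gene
    sets within a universe."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a, b = set(set_a) & universe, set(set_b) & universe
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = len(universe) - n11 - n10 - n01
    odds, p = stats.fisher_exact([[n11, n10], [n01, n00]], alternative="two-sided")
    return {"odds_ratio": float(odds), "p": float(p),
            "table": ((n11, n10), (n01, n00))}


def cluster_genotype_profiles(prob_df: pd.DataFrame):
    """Hierarchical clustering of genotypes from a genes x genotypes
    probability matrix (Euclidean distance, average linkage).

    Returns ``(newick_string, linkage_matrix)``; genes with missing values
    are dropped first.
    """
    from scipy.cluster.hierarchy import linkage
    from skbio import TreeNode

    df = prob_df.dropna(axis=0)
    if df.shape[1] < 2:
        raise ValueError("need at least two genotypes")
    Z = linkage(df.T.values, method="average", metric="euclidean")
    tree = TreeNode.from_linkage_matrix(Z, list(df.columns))
    newick = str(tree).strip()
    return newick, Z


def category_comparison(categories: dict, values_a: dict, values_b: dict,
                        ortholog_pairs=None, min_n: int = 5):
    """Category-level comparison of per-gene values between species A and B.

    ``categories`` maps gene (species A id) -> category.  ``values_a`` /
    ``values_b`` map gene ids to values in [0, 1] (observed binary labels or
    predicted probabilities).  ``ortholog_pairs`` is an iterable of
    (gene_a, gene_b); identity mapping when None.  Per category the scaled
    difference mean(B) - mean(A) lies in [-1, 1] (-1 = expressed only in A),
    tested with a two-sided Wilcoxon rank-sum test and BH-corrected across
    categories.  Returns the list of comparisons; each carries the FDR for
    its own axis in ``obs_fdr``/``pred_fdr`` when called via
    :func:`compare_observed_predicted`.
    """
    if ortholog_pairs is None:
        ortholog_pairs = [(g, g) for g in values_a if g in values_b]
    per_cat: dict = {}
    for ga, gb in ortholog_pairs:
        if ga not in values_a or gb not in values_b or ga not in categories:
            continue
        per_cat.setdefault(categories[ga], []).append((values_a[ga], values_b[gb]))
    out = []
    for cat in sorted(per_cat, key=str):
        pairs = per_cat[cat]
        if len(pairs) < min_n:
            continue
        va = np.array([p[0] for p in pairs], dtype=float)
        vb = np.array([p[1] for p in pairs], dtype=float)
        stat = stats.ranksums(vb, va)
        out.append(CategoryComparison(
            category_id=str(cat), n=len(pairs),
            scaled_obs_diff=float(vb.mean() - va.mean()),
            scaled_pred_diff=float("nan"),
            obs_p=float(stat.pvalue), pred_p=float("nan"),
        ))
    _apply_bh(out, "obs_p", "obs_fdr")
    return out


def compare_observed_predicted(categories, obs_a, obs_b, pred_a, pred_b,
                               ortholog_pairs=None, min_n: int = 5):
    """Observed (labels) and predicted (probabilities) category comparisons,
    merged, with BH FDR per axis and the cross-category rank correlation."""
    obs = category_comparison(categories, obs_a, obs_b, ortholog_pairs, min_n)
    pred = category_comparison(categories, pred_a, pred_b, ortholog_pairs, min_n)
    pred_by_cat = {c.category_id: c for c in pred}
    merged = []
    for c in obs:
        pc = pred_by_cat.get(c.category_id)
        if pc is None:
            continue
        c.scaled_pred_diff = pc.scaled_obs_diff
        c.pred_p = pc.obs_p
        c.pred_fdr = pc.obs_fdr
        merged.append(c)
    if len(merged) >= 3:
        rho = stats.spearmanr([c.scaled_obs_diff for c in merged],
                              [c.scaled_pred_diff for c in merged])
        corr = float(rho.statistic)
    else:
        corr = float("nan")
    return merged, corr


def _apply_bh(comparisons, p_attr: str, fdr_attr: str):
    if not comparisons:
        return
    from statsmodels.stats.multitest import multipletests

    ps = [getattr(c, p_attr) for c in comparisons]
    _, fdr, _, _ = multipletests(ps, method="fdr_bh")
    for c, q in zip(comparisons, fdr):
        setattr(c, fdr_attr, float(q))
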