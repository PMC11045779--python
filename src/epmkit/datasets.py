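"""Homology-filtered, class-balanced cross-validation fold assembly.

Training schemes:

* ``SSR``  — single-species reference: leave one chromosome out, drop
  validation genes with a qualifying homolog on the training chromosomes.
* ``SSRU`` — as SSR but homologous validation genes are kept.
* ``MSR``  — multi-species reference: leave one species out, train on all
  chromosomes of the remaining species.
* ``SSC``  — shuffled-sequence control: SSR folds evaluated on per-sequence
  mononucleotide-shuffled inputs.

Two genes are homologous when their protein-level hit has e-value < 0.001 and
bit score > 50.  Only the training set is class-balanced (majority class
down-sampled without replacement); validation sets stay unbalanced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HomologyPair",
    "CVFold",
    "load_homology",
    "is_homologous",
    "make_folds",
    "shuffle_control",
    "HOMOLOGY_EVALUE",
    "HOMOLOGY_BITSCORE",
]

HOMOLOGY_EVALUE = 0.001
HOMOLOGY_BITSCORE = 50.0

#: column names of the standard 12-column tabular protein hit format
HIT_COLUMNS = [
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class HomologyPair:
    query_gene: str
    subject_gene: str
    e_value: float
    bit_score: float


@dataclass
class CVFold:
    fold_id: str
    validation_chrom: str
    train_ids: list
    val_ids: list
    scheme: str = "SSR"
    seed: int = 0

    def to_manifest(self) -> dict:
        return {
            "fold_id": self.fold_id,
            "validation_chrom": self.validation_chrom,
            "scheme": self.scheme,
            "seed": self.seed,
            "n_train": len(self.train_ids),
            "n_val": len(self.val_ids),
            "train_ids": list(self.train_ids),
            "val_ids": list(self.val_ids),
        }


def is_homologous(pair: HomologyPair) -> bool:
    """e-value < 0.001 and bit score > 50, both strict."""
    return pair.e_value < HOMOLOGY_EVALUE and pair.bit_score > HOMOLOGY_BITSCORE


def load_homology(hits_path_or_df) -> list:
    """Load a 12-column tab-separated hit table into a symmetrised pair list.

    Self-hits are dropped; every surviving hit is stored in both directions.
    """
    if isinstance(hits_path_or_df, pd.DataFrame):
        df = hits_path_or_df.copy()
        if list(df.columns[:12]) != HIT_COLUMNS[:12] and df.shape[1] >= 12:
            df.columns = HIT_COLUMNS[: df.shape[1]]
    else:
        df = pd.read_csv(hits_path_or_df, sep="\t", header=None, comment="#")
        if df.shape[1] < 12:
            raise ValueError(f"expected 12-column hit table, got {df.shape[1]} columns")
        df.columns = HIT_COLUMNS[: df.shape[1]]
    pairs = []
    for row in df.itertuples(index=False):
        q, s = str(row.query), str(row.subject)
        if q == s:
            continue
        e, b = float(row.evalue), float(row.bitscore)
        pairs.append(HomologyPair(q, s, e, b))
        pairs.append(HomologyPair(s, q, e, b))
    return pairs


def _homolog_map(pairs) -> dict:
    """gene -> set of genes with a *qualifying* homologous hit."""
    out: dict = {}
    for p in pairs:
        if is_homologous(p):
            out.setdefault(p.query_gene, set()).add(p.subject_gene)
            out.setdefault(p.subject_gene, set()).add(p.query_gene)
    return out


def _balance(ids, labels: dict, rng: np.random.Generator):
    zeros = [g for g in ids if labels[g] == 0]
    ones = [g for g in ids if labels[g] == 1]
    n = min(len(zeros), len(ones))
    zeros = list(rng.choice(zeros, size=n, replace=False)) if len(zeros) > n else zeros
    ones = list(rng.choice(ones, size=n, replace=False)) if len(ones) > n else ones
    merged = sorted(zeros + ones)
    return merged


def make_folds(labels, annotations, homology, scheme: str = "SSR", seed: int = 0,
               species_of: dict | None = None) -> list:
    """Build leave-one-chromosome-out (or leave-one-species-out) folds.

    Parameters
    ----------
    labels : mapping gene_id -> binary label (0 low / 1 high); medium genes
        must already be excluded.
    annotations : iterable of GeneAnnotation (chrom assignment).
    homology : HomologyPair list (as from :func:`load_homology`).
    scheme : SSR | SSRU | MSR | SSC.  SSC shares SSR's fold geometry.
    species_of : for MSR, mapping chrom -> species id.
    """
    scheme = scheme.upper()
    if scheme not in {"SSR", "SSRU", "MSR", "SSC"}:
        raise ValueError(f"unknown scheme {scheme}")
    labels = dict(labels)
    chrom_of = {a.gene_id: a.chrom for a in annotations}
    genes = [g for g in sorted(labels) if g in chrom_of]
    hmap = _homolog_map(homology)

    if scheme == "MSR":
        if species_of is None:
            raise ValueError("MSR folds need a chrom -> species map")
        group_of = {g: species_of[chrom_of[g]] for g in genes}
    else:
        group_of = {g: chrom_of[g] for g in genes}

    rng = np.random.default_rng(seed)
    folds = []
    for group in sorted(set(group_of.values())):
        val = [g for g in genes if group_of[g] == group]
        train = [g for g in genes if group_of[g] != group]
        if not any(labels[g] == 0 for g in val) and not any(labels[g] == 1 for g in val):
            import warnings

            warnings.warn(f"fold {group}: no binary-labelled validation genes; skipped")
            continue
        if scheme in ("SSR", "MSR", "SSC"):
            train_set = set(train)
            val = [g for g in val if not (hmap.get(g, set()) & train_set)]
        train = _balance(train, labels, rng)
        folds.append(
            CVFold(
                fold_id=f"{scheme}-{group}",
                validation_chrom=str(group),
                train_ids=train,
                val_ids=val,
                scheme=scheme,
                seed=seed,
            )
        )
    return folds


def shuffle_control(inputs, seed: int = 0, order: int = 1):
    """Per-sequence mononucleotide shuffle preserving composition.

    ``inputs`` may be DNA strings or one-hot matrices (L x 4).  All-zero rows
    (the N spacer and N padding) stay in place, so the fused-input geometry is
    preserved.  ``order=2`` gives a dinucleotide-preserving shuffle (altschul-
    erikson style walk) for strings.
    """
    rng = np.random.default_rng(seed)
    out = []
    for x in inputs:
        if isinstance(x, str):
            out.append(_shuffle_string(x, rng, order))
        else:
            x = np.asarray(x)
            keep = x.sum(axis=1) > 0
            idx = np.flatnonzero(keep)
            perm = rng.permutation(idx.size)
            y = x.copy()
            y[idx] = x[idx[perm]]
            out.append(y)
    return out


def _shuffle_string(s: str, rng: np.random.Generator, order: int) -> str:
    idx = [i for i, c in enumerate(s) if c != "N"]
    chars = [s[i] for i in idx]
    if order == 1:
        perm = rng.permutation(len(chars))
        shuffled = [chars[p] for p in perm]
    elif order == 2:
        shuffled = _dinucleotide_shuffle(chars, rng)
    else:
        raise ValueError("order must be 1 or 2")
    out = list(s)
    for i, c in zip(idx, shuffled):
        out[i] = c
    return "".join(out)


def _dinucleotide_shuffle(chars, rng):
    # Random Eulerian-walk shuffle preserving dinucleotide counts.
    if len(chars) < 3:
        return list(chars)
    edges: dict = {}
    for a, b in zip(chars[:-1], chars[1:]):
        edges.setdefault(a, []).append(b)
    for a in edges:
        tail = edges[a]
        # keep the last exit of the terminal vertex fixed to guarantee a walk
        rng.shuffle(tail)
    walk = [chars[0]]
    pos = {a: 0 for a in edges}
    cur = chars[0]
    for _ in range(len(chars) - 1):
        nxt = edges[cur][pos[cur]]
        pos[cur] += 1
        walk.append(nxt)
        cur = nxt
        if pos.get(cur, 0) >= len(edges.get(cur, [])):
            if len(walk) < len(chars):
                # dead end before consuming all edges: retry deterministically
                return _dinucleotide_shuffle(chars, rng)
    return walk
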