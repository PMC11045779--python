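"""Per-nucleotide contribution scores for trained classifiers.

Contribution scores are computed by backpropagating DeepLIFT *rescale*
multipliers through the network relative to a reference input (all-zeros, or
the average over several per-sequence mononucleotide shuffles).  For every
gene this yields

* ``actual``     — L x 4 scores, nonzero only at the observed base;
* ``hypothetical`` — L x 4 what-if scores obtained by projecting the
  multipliers onto each possible base at each position (difference-from-
  reference convention, as required by seqlet aggregation);
* ``per_position`` — the channel sum of ``actual``.

The scores satisfy summation-to-delta: the total actual score of a sequence
equals f(x) - mean_ref f(ref) up to float precision.  Saliency profiles are
plain positionwise means of per-position scores across sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Network

__all__ = ["ImportanceTrack", "SaliencyProfile", "compute_contributions",
           "sum_gene_score", "average_saliency", "shuffled_references"]


@dataclass
class ImportanceTrack:
    gene_id: str
    actual: np.ndarray  # (L, 4)
    hypothetical: np.ndarray  # (L, 4)

    @property
    def per_position(self) -> np.ndarray:
        return self.actual.sum(axis=1)


@dataclass
class SaliencyProfile:
    mean_per_position: np.ndarray
    n_sequences: int


def shuffled_references(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k mononucleotide shuffles of a one-hot input; all-zero rows (spacer,
    N padding) stay in place."""
    refs = np.empty((k,) + x.shape, dtype=x.dtype)
    idx = np.flatnonzero(x.sum(axis=1) > 0)
    for j in range(k):
        r = x.copy()
        r[idx] = x[idx[rng.permutation(idx.size)]]
        refs[j] = r
    return refs


def compute_contributions(network: Network, x: np.ndarray, gene_id: str = "",
                          reference: str = "shuffled", k: int = 10,
                          seed: int = 0) -> ImportanceTrack:
    """Contribution scores of one encoded input against a reference policy.

    ``reference`` is ``"zeros"`` or ``"shuffled"`` (k seeded per-sequence
    shuffles, scores averaged).  Attribution runs in float64.
    """
    x = np.asarray(x, dtype=np.float64)
    net = network.astype(np.float64)
    if reference == "zeros":
        refs = np.zeros((1,) + x.shape)
    elif reference == "shuffled":
        refs = shuffled_references(x, k, np.random.default_rng(seed))
    else:
        raise ValueError(f"unknown reference policy {reference!r}")
    if refs.shape[-2] != x.shape[-2]:
        raise ValueError("reference length mismatch")

    xb = np.repeat(x[None], len(refs), axis=0)
    m, _, _ = net.multipliers(xb, refs)
    # hypothetical: per reference, score of base b = m . (onehot(b) - ref);
    # averaged over references.
    hyp = (m - (m * refs).sum(axis=2, keepdims=True)).mean(axis=0)
    actual = hyp * x  # mask to the observed base
    return ImportanceTrack(gene_id=gene_id, actual=actual, hypothetical=hyp)


def sum_gene_score(track: ImportanceTrack) -> float:
    """Total contribution of a gene's flanking input (= f(x) - f(ref))."""
    return float(track.per_position.sum())


def average_saliency(tracks) -> SaliencyProfile:
    tracks = list(tracks)
    if not tracks:
        raise ValueError("no tracks")
    lengths = {t.per_position.shape[0] for t in tracks}
    if len(lengths) != 1:
        raise ValueError("tracks have mixed lengths")
    mean = np.mean([t.per_position for t in tracks], axis=0)
    return SaliencyProfile(mean_per_position=mean, n_sequences=len(tracks))
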