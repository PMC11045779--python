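"""Expression quantification labels: logMaxTPM, quartile thresholds, classes.

Gene expression is summarised per gene as ``logMaxTPM = log10(max TPM across
samples + 1)``, and genes are classified *low* / *medium* / *high* against the
lower and upper quartiles of the genome-wide logMaxTPM distribution.  Only the
low (binary 0) and high (binary 1) classes enter classifier training; ties at
either threshold fall into *medium*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ClassThresholds",
    "aggregate_isoforms",
    "compute_log_max_tpm",
    "compute_thresholds",
    "assign_classes",
    "label_table",
]


@dataclass(frozen=True)
class ClassThresholds:
    q_low: float
    q_high: float

    def __post_init__(self):
        if self.q_low > self.q_high:
            raise ValueError("q_low > q_high")


def aggregate_isoforms(transcript_tpm: pd.DataFrame, transcript_to_gene: dict) -> pd.DataFrame:
    """Sum isoform TPMs per gene and sample.

    ``transcript_tpm`` is transcripts x samples with transcript ids as index.
    """
    missing = [t for t in transcript_tpm.index if t not in transcript_to_gene]
    if missing:
        raise KeyError(f"transcripts without gene mapping: {missing[:5]}")
    genes = transcript_tpm.index.map(transcript_to_gene.get)
    return transcript_tpm.groupby(genes).sum()


def compute_log_max_tpm(tpms) -> float:
    """log10(max(TPM) + 1) over the samples of one gene."""
    arr = np.asarray(tpms, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one sample")
    if (arr < 0).any():
        raise ValueError("negative TPM")
    return float(np.log10(arr.max() + 1.0))


def compute_thresholds(log_max_tpms) -> ClassThresholds:
    """Empirical 25th/75th percentiles (linear-interpolation definition)."""
    arr = np.asarray(log_max_tpms, dtype=float)
    if arr.size == 0:
        raise ValueError("empty input")
    q_low, q_high = np.percentile(arr, [25, 75])
    return ClassThresholds(q_low=float(q_low), q_high=float(q_high))


def assign_classes(values: pd.Series, thresholds: ClassThresholds) -> pd.DataFrame:
    """Three-way class per gene plus binary training label (low=0, high=1).

    Strict inequalities: values equal to either threshold are *medium* and
    carry no binary label (NaN).
    """
    values = pd.Series(values, dtype=float)
    klass = pd.Series("medium", index=values.index, dtype=object)
    klass[values < thresholds.q_low] = "low"
    klass[values > thresholds.q_high] = "high"
    binary = pd.Series(np.nan, index=values.index, dtype=float)
    binary[klass == "low"] = 0.0
    binary[klass == "high"] = 1.0
    return pd.DataFrame({"log_max_tpm": values, "klass": klass, "binary": binary})


def label_table(gene_tpm: pd.DataFrame) -> pd.DataFrame:
    """Full labelling of a gene x sample TPM table.

    Returns a DataFrame indexed by gene with columns
    ``log_max_tpm``, ``klass``, ``binary``.
    """
    lmt = gene_tpm.apply(lambda row: compute_log_max_tpm(row.values), axis=1)
    thr = compute_thresholds(lmt.values)
    out = assign_classes(lmt, thr)
    out.attrs["thresholds"] = thr
    return out
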