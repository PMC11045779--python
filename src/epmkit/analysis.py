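"""Scanning and statistics for expression-predictive motifs.

* PWM scanning with log-odds scores against a 0-order background, *exact*
  p-values from a dynamic program over a discretised score lattice, and
  e-values over the scanned search space (both strands by default).
* Positional filtering of matches against each EPM's preferred range.
* Class enrichment: log2 fold change of the odds that an EPM (with in-range
  matches) occurs in genes of its own expression class versus the opposite
  class, plus an equal-split chi-square occurrence test.
* Similarity of EPMs to reference motif databases (JASPAR-style PFMs) by
  best-offset Pearson correlation with a column-shuffling null.
* Cross-model EPM clustering from IUPAC consensus strings with a local
  (Smith-Waterman) alignment distance, reverse-complement aware.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .discovery import EPM, IUPAC_BASES, _best_alignment, _rc_matrix
from .regions import BASES, RegionConfig

__all__ = ["ScanConfig", "MotifMatch", "EnrichmentResult", "SimilarityHit",
           "scan", "presence_scan", "flag_preferred", "enrichment",
           "occurrence_chi2", "compare_to_reference", "cluster_epms",
           "ScoreTable", "score_pvalue_table", "consensus_distance",
           "rc_consensus"]


@dataclass
class ScanConfig:
    evalue_threshold: float = 0.0001
    background: tuple | None = None  # None -> composition of scanned sequences
    both_strands: bool = True
    pseudocount: float = 0.01
    lattice_bin: float = 1e-4

    def __post_init__(self):
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be > 0")
        if self.background is not None:
            bg = np.asarray(self.background, dtype=float)
            if bg.min() < 0 or abs(bg.sum() - 1) > 1e-9:
                raise ValueError("background must be nonnegative and sum to 1")


@dataclass
class MotifMatch:
    epm_name: str
    gene_id: str
    start: int
    strand: str
    score: float
    p_value: float
    e_value: float
    genotype_id: str | None = None
    offset: int | None = None  # relative to TSS/TTS anchor when cfg known
    half: str | None = None
    within_preferred: bool = False


@dataclass
class EnrichmentResult:
    epm_name: str
    a: int
    A: int
    b: int
    B: int
    fraction_own: float
    fraction_opp: float
    enrichment: float
    chi2: float
    p: float


@dataclass
class SimilarityHit:
    epm_name: str
    reference_id: str
    offset: int
    orientation: str
    pcc: float
    p_value: float
    e_value: float
    significant: bool


def _seq_to_ints(seq: str) -> np.ndarray:
    lut = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _log_odds(pwm: np.ndarray, bg: np.ndarray, pseudocount: float) -> np.ndarray:
    if (bg <= 0).any():
        raise ValueError("degenerate background with a zero component")
    q = (pwm + pseudocount * bg[None, :]) / (1.0 + pseudocount)
    return np.log2(q / bg[None, :])


class ScoreTable:
    """Exact null distribution of the integer-lattice log-odds score.

    Per-column log-odds scores are discretised to an integer lattice
    (``bin_width`` units); the distribution of the window total under the
    0-order background model is computed by dynamic programming (convolution
    of the per-column score distributions), giving exact p-values
    P(score >= s).
    """

    def __init__(self, pwm: np.ndarray, bg, pseudocount: float = 0.01,
                 bin_width: float = 1e-4):
        bg = np.asarray(bg, dtype=float)
        lods = _log_odds(pwm, bg, pseudocount)
        self.bin_width = bin_width
        self.s_int = np.rint(lods / bin_width).astype(np.int64)
        self.lo = int(self.s_int.min(axis=1).sum())
        cur = np.array([1.0])
        for i in range(self.s_int.shape[0]):
            col_lo, col_hi = int(self.s_int[i].min()), int(self.s_int[i].max())
            new = np.zeros(cur.size + (col_hi - col_lo))
            for b in range(4):
                off = int(self.s_int[i, b]) - col_lo
                new[off : off + cur.size] += cur * bg[b]
            cur = new
        self.sf = np.cumsum(cur[::-1])[::-1]  # sf[k] = P(score_int >= lo + k)

    def pvalue(self, total_int) -> np.ndarray:
        """Vectorised p-value of integer total scores."""
        k = np.asarray(total_int, dtype=np.int64) - self.lo
        out = np.ones(k.shape, dtype=float)
        out[k >= self.sf.size] = 0.0
        inside = (k >= 0) & (k < self.sf.size)
        out[inside] = self.sf[k[inside]]
        return out

    def min_score_for_pvalue(self, p_threshold: float) -> int:
        """Smallest integer score whose p-value is < p_threshold."""
        ks = np.flatnonzero(self.sf < p_threshold)
        if ks.size == 0:
            return self.lo + self.sf.size  # unreachable
        return self.lo + int(ks[0])


def score_pvalue_table(pwm: np.ndarray, bg, pseudocount: float = 0.01,
                       bin_width: float = 1e-4):
    """Back-compat helper: returns (s_int, pvalue_of) from :class:`ScoreTable`."""
    table = ScoreTable(pwm, bg, pseudocount, bin_width)
    return table.s_int, lambda t: float(table.pvalue(np.array([t]))[0])


def _scan_one_strand(ints: np.ndarray, s_int: np.ndarray):
    """Integer window scores at each valid start; windows containing N are
    flagged invalid."""
    W = s_int.shape[0]
    if ints.size < W:
        return np.empty(0, dtype=np.int64), np.zeros(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(ints, W)
    valid = (windows >= 0).all(axis=1)
    safe = np.where(windows >= 0, windows, 0)
    scores = s_int[np.arange(W)[None, :], safe].sum(axis=1)
    return scores, valid


def scan(epms, sequences: dict, cfg: ScanConfig | None = None,
         region_cfg: RegionConfig | None = None, genotype_id: str | None = None):
    """Scan sequences for EPM occurrences.

    Parameters
    ----------
    epms : iterable of EPM (forward orientation; the minus strand is scanned
        with the reverse-complement PWM).
    sequences : mapping gene_id -> DNA string (e.g. fused flanking
        sequences).
    cfg : scan settings; background defaults to the overall composition of
        the scanned sequences.
    region_cfg : when given, sequences are interpreted as fused flanking
        inputs and matches get TSS/TTS-anchored offsets and halves.

    Matches with e-value < ``cfg.evalue_threshold`` are returned; the
    e-value is p-value x total scanned positions x strands.
    """
    cfg = cfg or ScanConfig()
    seq_ints = {g: _seq_to_ints(s.upper()) for g, s in sequences.items()}
    if cfg.background is not None:
        bg = np.asarray(cfg.background, dtype=float)
    else:
        counts = np.zeros(4)
        for ints in seq_ints.values():
            counts += np.bincount(ints[ints >= 0], minlength=4)
        bg = counts / counts.sum() if counts.sum() else np.full(4, 0.25)
        bg = np.clip(bg, 1e-6, None)
        bg = bg / bg.sum()

    n_strands = 2 if cfg.both_strands else 1
    matches = []
    for epm in epms:
        if epm.pwm.shape[0] > max(len(s) for s in sequences.values()):
            raise ValueError(f"{epm.name}: motif wider than every sequence")
        W = epm.pwm.shape[0]
        search_space = sum(max(0, ints.size - W + 1) for ints in seq_ints.values()) * n_strands
        strands = [("+", epm.pwm)]
        if cfg.both_strands:
            strands.append(("-", _rc_matrix(epm.pwm)))
        for strand, pwm in strands:
            table = ScoreTable(pwm, bg, cfg.pseudocount, cfg.lattice_bin)
            s_min = table.min_score_for_pvalue(cfg.evalue_threshold / max(search_space, 1))
            for g, ints in seq_ints.items():
                scores, valid = _scan_one_strand(ints, table.s_int)
                hits = np.flatnonzero(valid & (scores >= s_min))
                if hits.size == 0:
                    continue
                ps = table.pvalue(scores[hits])
                for pos, p in zip(hits, ps):
                    m = MotifMatch(
                        epm_name=epm.name, gene_id=g, start=int(pos), strand=strand,
                        score=float(scores[pos] * cfg.lattice_bin),
                        p_value=float(p), e_value=float(p * search_space),
                        genotype_id=genotype_id,
                    )
                    if region_cfg is not None:
                        _anchor_match(m, region_cfg)
                    matches.append(m)
    return matches


def preferred_windows(epm, region_cfg: RegionConfig, width: int):
    """Fused-coordinate [lo, hi) windows of allowed match *starts* for an
    EPM's preferred ranges (clipped to the half the range belongs to)."""
    windows = []
    for half, (q1, q3) in epm.preferred_ranges.items():
        if half == "upstream":
            lo = region_cfg.tss_index() + int(np.floor(q1))
            hi = region_cfg.tss_index() + int(np.ceil(q3)) + 1
            lo, hi = max(lo, 0), min(hi, region_cfg.upstream_len - width + 1)
        else:
            lo = region_cfg.tts_index() + int(np.floor(q1))
            hi = region_cfg.tts_index() + int(np.ceil(q3)) + 1
            lo = max(lo, region_cfg.upstream_len + region_cfg.spacer_len)
            hi = min(hi, region_cfg.total_input_len - width + 1)
        if hi > lo:
            windows.append((lo, hi))
    return windows


def presence_scan(epms, sequences: dict, region_cfg: RegionConfig,
                  cfg: ScanConfig | None = None, per_gene_evalue: float = 0.01,
                  genotype_id: str | None = None):
    """In-preferred-range presence calls with per-gene e-values.

    For each EPM only the positions inside its preferred ranges are scanned
    (both strands unless configured otherwise) and the e-value of a match is
    its exact p-value times the number of in-range positions scanned *in
    that gene* — the right search space for the per-gene question "does this
    motif occur here", as opposed to :func:`scan`'s corpus-wide e-value.

    Returns ``(matches, presence)`` where presence is a set of
    ``(gene_id, epm_name)`` with at least one in-range match.
    """
    cfg = cfg or ScanConfig(evalue_threshold=per_gene_evalue)
    seq_ints = {g: _seq_to_ints(s.upper()) for g, s in sequences.items()}
    if cfg.background is not None:
        bg = np.asarray(cfg.background, dtype=float)
    else:
        counts = np.zeros(4)
        for ints in seq_ints.values():
            counts += np.bincount(ints[ints >= 0], minlength=4)
        bg = counts / counts.sum() if counts.sum() else np.full(4, 0.25)
        bg = np.clip(bg, 1e-6, None)
        bg = bg / bg.sum()
    n_strands = 2 if cfg.both_strands else 1

    matches, presence = [], set()
    for epm in epms:
        W = epm.pwm.shape[0]
        windows = preferred_windows(epm, region_cfg, W)
        if not windows:
            continue
        n_pos = sum(hi - lo for lo, hi in windows) * n_strands
        strands = [("+", epm.pwm)]
        if cfg.both_strands:
            strands.append(("-", _rc_matrix(epm.pwm)))
        for strand, pwm in strands:
            table = ScoreTable(pwm, bg, cfg.pseudocount, cfg.lattice_bin)
            s_min = table.min_score_for_pvalue(per_gene_evalue / n_pos)
            for g, ints in seq_ints.items():
                for lo, hi in windows:
                    # score only the in-range slice of the sequence
                    seg, valid = _scan_one_strand(ints[lo : hi + W - 1], table.s_int)
                    ok = valid & (seg >= s_min)
                    for k in np.flatnonzero(ok):
                        p = float(table.pvalue(np.array([seg[k]]))[0])
                        m = MotifMatch(
                            epm_name=epm.name, gene_id=g, start=int(lo + k),
                            strand=strand, score=float(seg[k] * cfg.lattice_bin),
                            p_value=p, e_value=p * n_pos, genotype_id=genotype_id,
                            within_preferred=True,
                        )
                        _anchor_match(m, region_cfg)
                        matches.append(m)
                        presence.add((g, epm.name))
    return matches, presence


def _anchor_match(m: MotifMatch, rc: RegionConfig):
    if m.start < rc.upstream_len:
        m.half = "upstream"
        m.offset = m.start - rc.tss_index()
    elif m.start >= rc.upstream_len + rc.spacer_len:
        m.half = "downstream"
        m.offset = m.start - rc.tts_index()
    else:
        m.half, m.offset = None, None


def flag_preferred(matches, epms) -> list:
    """Set ``within_preferred`` per match from its EPM's [Q1, Q3] range
    (closed interval); halves without a range contribute no in-range matches."""
    by_name = {e.name: e for e in epms}
    for m in matches:
        epm = by_name.get(m.epm_name)
        m.within_preferred = False
        if epm is None or m.half is None or m.offset is None:
            continue
        rng = epm.preferred_ranges.get(m.half)
        if rng is not None and rng[0] <= m.offset <= rng[1]:
            m.within_preferred = True
    return matches


def enrichment(epm_name: str, a: int, A: int, b: int, B: int,
               eps: float = 0.5) -> EnrichmentResult:
    """log2 fold change in the odds of in-range EPM presence in own-class
    genes (a of A) versus opposite-class genes (b of B).

    ``eps`` is a continuity correction for zero cells (0 recovers the plain
    odds-ratio arithmetic).
    """
    if A <= 0 or B <= 0:
        raise ValueError("class sizes must be positive")
    if not (0 <= a <= A and 0 <= b <= B):
        raise ValueError("counts out of range")
    f_own = (a + eps) / (A + 2 * eps)
    f_opp = (b + eps) / (B + 2 * eps)
    enr = float(np.log2((f_own / (1 - f_own)) / (f_opp / (1 - f_opp))))
    chi2, p = occurrence_chi2(a, A, b, B)
    return EnrichmentResult(
        epm_name=epm_name, a=a, A=A, b=b, B=B,
        fraction_own=a / A, fraction_opp=b / B,
        enrichment=enr, chi2=chi2, p=p,
    )


def occurrence_chi2(a: int, A: int, b: int, B: int):
    """Goodness of fit of occurrence counts (a, b) against an equal split,
    1 degree of freedom."""
    if A <= 0 or B <= 0:
        raise ValueError("class sizes must be positive")
    if a + b == 0:
        raise ValueError("no occurrences to test")
    res = stats.chisquare([a, b])
    return float(res.statistic), float(res.pvalue)


def compare_to_reference(epm: EPM, references: dict, n_shuffles: int = 1000,
                         seed: int = 0, min_overlap: int = 4) -> list:
    """Best-alignment PCC of an EPM against each reference PFM.

    p-value = fraction of column(position)-shuffled versions of the reference
    scoring >= the observed PCC; e-value = p x number of references;
    significant when e-value < 0.05.
    """
    rng = np.random.default_rng(seed)
    hits = []
    n_refs = len(references)
    for ref_id, pfm in references.items():
        pfm = np.asarray(pfm, dtype=float)
        if pfm.shape[0] < min_overlap:
            raise ValueError(f"{ref_id}: reference width < {min_overlap}")
        pfm = pfm / pfm.sum(axis=1, keepdims=True)
        pcc, off, orient = _best_alignment(epm.pwm, pfm, min_overlap)
        exceed = 1  # include the observed in the null (conservative)
        for _ in range(n_shuffles):
            shuf = pfm[rng.permutation(pfm.shape[0])]
            null_pcc, _, _ = _best_alignment(epm.pwm, shuf, min_overlap)
            if null_pcc >= pcc:
                exceed += 1
        p = exceed / (n_shuffles + 1)
        e = p * n_refs
        hits.append(SimilarityHit(
            epm_name=epm.name, reference_id=ref_id, offset=off, orientation=orient,
            pcc=pcc, p_value=p, e_value=e, significant=e < 0.05,
        ))
    hits.sort(key=lambda h: -h.pcc)
    return hits


_IUPAC_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R",
                     "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
                     "D": "H", "H": "D", "N": "N"}


def rc_consensus(consensus: str) -> str:
    return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(consensus))


def _iupac_aligner(gap_open: float, gap_extend: float):
    from Bio.Align import PairwiseAligner, substitution_matrices

    letters = "".join(sorted(IUPAC_BASES))
    mat = np.zeros((len(letters), len(letters)))
    for i, x in enumerate(letters):
        for j, y in enumerate(letters):
            sx, sy = IUPAC_BASES[x], IUPAC_BASES[y]
            mat[i, j] = len(sx & sy) / len(sx | sy)
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.Array(letters, 2, mat)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def consensus_distance(c1: str, c2: str, gap_open: float = -1.0,
                       gap_extend: float = -0.5, aligner=None) -> float:
    """1 - normalised local-alignment score of two IUPAC consensus strings
    (reverse-complement orientation also searched)."""
    if not c1 or not c2:
        raise ValueError("empty consensus")
    aligner = aligner or _iupac_aligner(gap_open, gap_extend)
    score = max(aligner.score(c1, c2), aligner.score(c1, rc_consensus(c2)))
    norm = score / min(len(c1), len(c2))
    return float(max(0.0, 1.0 - norm))


def cluster_epms(epms, gap_open: float = -1.0, gap_extend: float = -0.5,
                 cut_height: float = 0.5):
    """Average-linkage hierarchical clustering of EPMs by consensus-string
    local-alignment distance.

    Returns ``(labels, linkage_matrix, distance_matrix)``; singleton clusters
    are allowed.
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    epms = list(epms)
    if len(epms) < 2:
        return np.ones(len(epms), dtype=int), None, np.zeros((len(epms), len(epms)))
    aligner = _iupac_aligner(gap_open, gap_extend)
    n = len(epms)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = consensus_distance(epms[i].consensus, epms[j].consensus, aligner=aligner)
            dmat[i, j] = dmat[j, i] = d
    Z = linkage(squareform(dmat, checks=False), method="average")
    labels = fcluster(Z, t=cut_height, criterion="distance")
    return labels, Z, dmat
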