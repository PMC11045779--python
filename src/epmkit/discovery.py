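"""Aggregation of importance tracks into expression-predictive motifs (EPMs).

The procedure mirrors the standard seqlet-aggregation approach: high-|score|
windows (*seqlets*) are excised from per-nucleotide importance tracks against
a permutation null, split by sign into two metaclusters (p0 = high-expression
associated, p1 = low), greedily clustered by patch cross-correlation with
reverse-complement awareness, and each cluster is aggregated into a
contribution weight matrix (CWM, mean hypothetical scores) plus a position
frequency matrix (PWM, aligned observed bases).  Each EPM carries positional
preferred ranges ([Q1, Q3] of seqlet offsets relative to its anchor, kept
only when >10% of seqlets fall in that half), information content, an IUPAC
consensus and a nomenclature name.

Position anchors: seqlets in the upstream half are reported relative to the
TSS (negative = promoter), seqlets in the downstream half relative to the
TTS.  The N spacer is excluded from seqlet calling.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .regions import RegionConfig, BASES

__all__ = ["Seqlet", "EPM", "extract_seqlets", "split_metaclusters",
           "cluster_and_aggregate", "positional_preference", "motif_properties",
           "name_epm", "parse_epm_name", "reverse_complement_epm", "discover_motifs"]

IUPAC_CODES = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M", frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V", frozenset("ACGT"): "N",
}
IUPAC_BASES = {v: set(k) for k, v in IUPAC_CODES.items()}


@dataclass(eq=False)
class Seqlet:
    gene_id: str
    start: int
    end: int  # 0-based half-open within the fused input
    orientation: str  # fwd | rev
    patch: np.ndarray  # (end-start, 4) hypothetical scores
    onehot: np.ndarray  # (end-start, 4) observed bases
    total_score: float
    half: str  # upstream | downstream
    anchor_offset: int


@dataclass(eq=False)
class EPM:
    name: str
    metacluster: str  # p0 | p1
    cwm: np.ndarray
    pwm: np.ndarray
    n_seqlets: int
    info_content: float = 0.0
    consensus: str = ""
    preferred_ranges: dict = field(default_factory=dict)
    seqlet_indices: list = field(default_factory=list)
    reverse_complement: "EPM | None" = None

    @property
    def width(self) -> int:
        return self.pwm.shape[0]


def _rc_matrix(mat: np.ndarray) -> np.ndarray:
    """Reverse complement of an (L, 4) matrix in A,C,G,T channel order."""
    return mat[::-1, ::-1].copy()


def _window_sums(values: np.ndarray, w: int) -> np.ndarray:
    c = np.concatenate([[0.0], np.cumsum(values)])
    return c[w:] - c[:-w]


def extract_seqlets(tracks, encoded: dict, cfg: RegionConfig | None = None,
                    window_len: int = 21, null_reps: int = 20,
                    fdr_level: float = 0.01, seed: int = 0) -> list:
    """Call seqlets from importance tracks against a positionwise-permutation null.

    ``encoded`` maps gene_id -> one-hot matrix (for the PWM of each seqlet).
    Windows are confined to one half (never cross the spacer); the |sum|
    threshold is the (1 - fdr_level) quantile of window sums pooled over
    ``null_reps`` seeded permutations of every track.
    """
    cfg = cfg or RegionConfig()
    tracks = list(tracks)
    if tracks and window_len > tracks[0].per_position.shape[0]:
        raise ValueError("window_len exceeds track length")
    up_lo, up_hi = 0, cfg.upstream_len
    dn_lo, dn_hi = cfg.upstream_len + cfg.spacer_len, cfg.total_input_len
    halves = [(up_lo, up_hi, "upstream"), (dn_lo, dn_hi, "downstream")]

    rng = np.random.default_rng(seed)
    null_samples = []
    for t in tracks:
        pp = t.per_position
        active = np.concatenate([pp[lo:hi] for lo, hi, _ in halves])
        for _ in range(null_reps):
            perm = active[rng.permutation(active.size)]
            null_samples.append(np.abs(_window_sums(perm, window_len)).astype(np.float32))
    if not null_samples:
        return []
    pooled = np.concatenate(null_samples)
    threshold = float(np.quantile(pooled, 1.0 - fdr_level))
    del pooled, null_samples

    seqlets = []
    for t in tracks:
        pp = t.per_position
        candidates = []
        for lo, hi, half in halves:
            if hi - lo < window_len:
                continue
            sums = _window_sums(pp[lo:hi], window_len)
            for i in np.flatnonzero(np.abs(sums) > threshold):
                candidates.append((lo + int(i), float(sums[i]), half))
        candidates.sort(key=lambda c: -abs(c[1]))
        taken = np.zeros(pp.shape[0], dtype=bool)
        for start, s, half in candidates:
            if taken[start : start + window_len].any():
                continue
            taken[start : start + window_len] = True
            anchor = cfg.tss_index() if half == "upstream" else cfg.tts_index()
            seqlets.append(Seqlet(
                gene_id=t.gene_id, start=start, end=start + window_len,
                orientation="fwd",
                patch=t.hypothetical[start : start + window_len].copy(),
                onehot=np.asarray(encoded[t.gene_id])[start : start + window_len].copy(),
                total_score=s, half=half, anchor_offset=start - anchor,
            ))
    return seqlets


def split_metaclusters(seqlets) -> dict:
    """p0 = positive total score (high-expression associated), p1 = negative."""
    out = {"p0": [], "p1": []}
    for s in seqlets:
        if s.total_score > 0:
            out["p0"].append(s)
        elif s.total_score < 0:
            out["p1"].append(s)
    return out


def _pearson(va: np.ndarray, vb: np.ndarray) -> float:
    va = va - va.mean()
    vb = vb - vb.mean()
    den = np.sqrt((va * va).sum() * (vb * vb).sum())
    return float((va * vb).sum() / den) if den > 0 else -2.0


def _best_alignment(a: np.ndarray, b: np.ndarray, min_overlap: int = 8):
    """Max Pearson correlation of two patches over offsets and orientations.

    Returns (pcc, offset, orientation) placing ``b`` at ``offset`` relative
    to ``a`` (orientation applied to b first).
    """
    best = (-2.0, 0, "fwd")
    for orient, bb in (("fwd", b), ("rev", _rc_matrix(b))):
        for off in range(-(bb.shape[0] - min_overlap), a.shape[0] - min_overlap + 1):
            lo_a, hi_a = max(0, off), min(a.shape[0], off + bb.shape[0])
            if hi_a - lo_a < min_overlap:
                continue
            pcc = _pearson(a[lo_a:hi_a].ravel(), bb[lo_a - off : hi_a - off].ravel())
            if pcc > best[0]:
                best = (pcc, off, orient)
    return best


def _best_alignment_to_seeds(seeds: np.ndarray, b: np.ndarray, min_overlap: int = 8):
    """Best (pcc, seed_index, offset, orientation) of patch ``b`` against a
    stack of equal-width seed patches, vectorised over seeds per offset."""
    C, W, _ = seeds.shape
    best = (-2.0, -1, 0, "fwd")
    for orient, bb in (("fwd", b), ("rev", _rc_matrix(b))):
        for off in range(-(bb.shape[0] - min_overlap), W - min_overlap + 1):
            lo, hi = max(0, off), min(W, off + bb.shape[0])
            if hi - lo < min_overlap:
                continue
            sa = seeds[:, lo:hi, :].reshape(C, -1)
            vb = bb[lo - off : hi - off].ravel()
            sa = sa - sa.mean(axis=1, keepdims=True)
            vb = vb - vb.mean()
            den = np.sqrt((sa * sa).sum(axis=1) * (vb * vb).sum())
            with np.errstate(divide="ignore", invalid="ignore"):
                pcc = np.where(den > 0, sa @ vb / np.where(den > 0, den, 1), -2.0)
            k = int(np.argmax(pcc))
            if pcc[k] > best[0]:
                best = (float(pcc[k]), k, off, orient)
    return best


def cluster_and_aggregate(seqlets, metacluster: str, max_per_metacluster: int = 20000,
                          similarity_threshold: float = 0.7, min_seqlets: int = 10,
                          min_overlap: int = 8) -> list:
    """Greedy seed-based agglomeration of one metacluster's seqlets into EPMs."""
    order = sorted(range(len(seqlets)), key=lambda i: -abs(seqlets[i].total_score))
    order = order[:max_per_metacluster]
    clusters = []  # each: {"seed": patch, "members": [(idx, off, orient)]}
    seed_stack = None
    for i in order:
        s = seqlets[i]
        joined = False
        if clusters:
            pcc, k, off, orient = _best_alignment_to_seeds(seed_stack, s.patch, min_overlap)
            if pcc >= similarity_threshold:
                clusters[k]["members"].append((i, off, orient))
                joined = True
        if not joined:
            clusters.append({"seed": s.patch, "members": [(i, 0, "fwd")]})
            seed_stack = (s.patch[None] if seed_stack is None
                          else np.concatenate([seed_stack, s.patch[None]]))

    epms = []
    for c in clusters:
        if len(c["members"]) < min_seqlets:
            continue
        W = c["seed"].shape[0]
        cwm_acc = np.zeros((W, 4))
        pwm_acc = np.zeros((W, 4))
        cover = np.zeros(W)
        for i, off, orient in c["members"]:
            patch, onehot = seqlets[i].patch, seqlets[i].onehot
            if orient == "rev":
                patch, onehot = _rc_matrix(patch), _rc_matrix(onehot)
            lo, hi = max(0, off), min(W, off + patch.shape[0])
            cwm_acc[lo:hi] += patch[lo - off : hi - off]
            pwm_acc[lo:hi] += onehot[lo - off : hi - off]
            cover[lo:hi] += 1
        covered = cover > 0
        cwm = np.where(covered[:, None], cwm_acc / np.maximum(cover, 1)[:, None], 0.0)
        rowsum = pwm_acc.sum(axis=1, keepdims=True)
        pwm = np.where(rowsum > 0, pwm_acc / np.maximum(rowsum, 1e-12), 0.25)
        epm = EPM(
            name="", metacluster=metacluster, cwm=cwm, pwm=pwm,
            n_seqlets=len(c["members"]),
            seqlet_indices=[i for i, _, _ in c["members"]],
        )
        epm.info_content, epm.consensus = motif_properties(epm)
        epms.append(epm)
    epms.sort(key=lambda e: -e.n_seqlets)
    return epms


def positional_preference(epm: EPM, seqlets) -> dict:
    """[Q1, Q3] of anchor offsets per half, kept when >10% of seqlets land there."""
    members = [seqlets[i] for i in epm.seqlet_indices]
    n = len(members)
    ranges = {}
    for half in ("upstream", "downstream"):
        offs = [s.anchor_offset for s in members if s.half == half]
        if n and len(offs) > 0.1 * n:
            q1, q3 = np.percentile(offs, [25, 75])
            ranges[half] = (float(q1), float(q3))
    epm.preferred_ranges = ranges
    return ranges


def motif_properties(epm: EPM):
    """Information content (bits) and IUPAC consensus of the PWM."""
    pwm = epm.pwm
    if not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("PWM rows must sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(pwm > 0, pwm * np.log2(np.where(pwm > 0, pwm, 1)), 0.0)
    ic = float((2.0 + plogp.sum(axis=1)).sum())
    consensus = "".join(
        IUPAC_CODES[frozenset(b for b, p in zip(BASES, row) if p >= 0.25)] for row in pwm
    )
    return ic, consensus


def trim_epm(epm: EPM, min_ic: float = 0.3) -> EPM:
    """Trim to the contiguous run of columns with per-column IC >= ``min_ic``
    around the maximum-IC column.

    Expanding outward from the information peak (rather than keeping the
    span between the outermost above-threshold columns) is robust to single
    noisy flanking columns, which would otherwise keep the whole window and
    let near-miss words score competitively in scans.  Preferred ranges
    (defined on seqlet-window starts) are shifted by the number of trimmed
    leading columns so that scan offsets stay comparable.
    """
    pwm = epm.pwm
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(pwm > 0, pwm * np.log2(np.where(pwm > 0, pwm, 1)), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    if not (ic >= min_ic).any():
        return epm
    peak = int(np.argmax(ic))
    lo, hi = peak, peak + 1
    while lo > 0 and ic[lo - 1] >= min_ic:
        lo -= 1
    while hi < ic.size and ic[hi] >= min_ic:
        hi += 1
    trimmed = EPM(
        name=epm.name, metacluster=epm.metacluster,
        cwm=epm.cwm[lo:hi].copy(), pwm=epm.pwm[lo:hi].copy(),
        n_seqlets=epm.n_seqlets,
        preferred_ranges={h: (r[0] + lo, r[1] + lo)
                          for h, r in epm.preferred_ranges.items()},
        seqlet_indices=list(epm.seqlet_indices),
    )
    trimmed.info_content, trimmed.consensus = motif_properties(trimmed)
    return trimmed


def reverse_complement_epm(epm: EPM) -> EPM:
    rc = EPM(
        name=epm.name + "R" if epm.name else "",
        metacluster=epm.metacluster,
        cwm=_rc_matrix(epm.cwm), pwm=_rc_matrix(epm.pwm),
        n_seqlets=epm.n_seqlets, preferred_ranges=dict(epm.preferred_ranges),
        seqlet_indices=list(epm.seqlet_indices),
    )
    rc.info_content, rc.consensus = motif_properties(rc)
    rc.reverse_complement = epm
    epm.reverse_complement = rc
    return rc


def name_epm(species_code: str, model_type: str, condition: int, run_idx,
             metacluster: str, motif_idx: int, orientation: str = "fwd") -> str:
    """Build an EPM name like ``epmArth-S019-p0m06`` (R suffix = reverse).

    ``run_idx`` may be None, giving the short dialect ``epmArth-S0-p0m03``.
    """
    if not re.fullmatch(r"[A-Z][a-z][a-z]{2}", species_code):
        raise ValueError("species_code must be 4 letters, capitalised (genus 2 + epithet 2)")
    if model_type not in ("S", "M"):
        raise ValueError("model_type must be 'S' (SSR) or 'M' (MSR)")
    if metacluster not in ("p0", "p1"):
        raise ValueError("metacluster must be p0 or p1")
    run = "" if run_idx is None else f"{int(run_idx):02d}"
    suffix = "R" if orientation == "rev" else ""
    return f"epm{species_code}-{model_type}{condition}{run}-{metacluster}m{motif_idx:02d}{suffix}"


def parse_epm_name(name: str) -> dict:
    m = re.fullmatch(
        r"epm([A-Z][a-z]{3})-([SM])(\d)(\d{2})?-p([01])m(\d{2})(R?)", name)
    if not m:
        raise ValueError(f"not a valid EPM name: {name!r}")
    return {
        "species_code": m.group(1),
        "model_type": m.group(2),
        "condition": int(m.group(3)),
        "run_idx": None if m.group(4) is None else int(m.group(4)),
        "metacluster": f"p{m.group(5)}",
        "motif_idx": int(m.group(6)),
        "orientation": "rev" if m.group(7) else "fwd",
    }


def discover_motifs(tracks, encoded: dict, cfg: RegionConfig | None = None,
                    species_code: str = "Synt", model_type: str = "S",
                    condition: int = 0, run_idx=None,
                    window_len: int = 21, null_reps: int = 20, fdr_level: float = 0.01,
                    similarity_threshold: float = 0.7, min_seqlets: int = 10,
                    max_per_metacluster: int = 20000, seed: int = 0):
    """End-to-end motif discovery; returns (epms, seqlets).

    The returned list contains forward EPMs each linked to an emitted
    reverse-complement partner (also in the list, name suffixed ``R``).
    """
    seqlets = extract_seqlets(tracks, encoded, cfg, window_len=window_len,
                              null_reps=null_reps, fdr_level=fdr_level, seed=seed)
    meta = split_metaclusters(seqlets)
    global_index = {id(s): i for i, s in enumerate(seqlets)}
    all_epms = []
    for mc in ("p0", "p1"):
        subset = meta[mc]
        idx_map = {j: global_index[id(s)] for j, s in enumerate(subset)}
        epms = cluster_and_aggregate(subset, mc,
                                     max_per_metacluster=max_per_metacluster,
                                     similarity_threshold=similarity_threshold,
                                     min_seqlets=min_seqlets)
        for k, epm in enumerate(epms):
            epm.seqlet_indices = [idx_map[j] for j in epm.seqlet_indices]
            epm.name = name_epm(species_code, model_type, condition, run_idx, mc, k)
            positional_preference(epm, seqlets)
            all_epms.append(epm)
            all_epms.append(reverse_complement_epm(epm))
    return all_epms, seqlets
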