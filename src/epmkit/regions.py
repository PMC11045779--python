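"""Extraction and one-hot encoding of proximal gene-flanking regions.

For every annotated gene two proximal windows are taken: an *upstream* block
(promoter + 5'UTR, anchored at the annotated gene start) and a *downstream*
block (3'UTR + terminator, anchored at the annotated gene end).  The two
blocks are fused into one sequence separated by a short spacer of ``N``
characters, oriented 5'->3' with respect to the gene (minus-strand genes are
reverse complemented), and one-hot encoded with channel order A, C, G, T.
``N`` and spacer positions encode as all-zero rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import reverse_complement

__all__ = [
    "GeneAnnotation",
    "RegionConfig",
    "FlankingSequence",
    "EncodedInput",
    "read_genome",
    "read_annotation",
    "extract_flanks",
    "encode",
    "decode",
    "one_hot",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
# IUPAC ambiguity codes (and U) collapsed to N on input.
_AMBIGUOUS = set("RYSWKMBDHVUN")


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene locus in 1-based inclusive (GFF3) coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class RegionConfig:
    """Lengths (nt) of the extracted segments and the fused-input spacer."""

    promoter_len: int = 1000
    utr5_len: int = 500
    utr3_len: int = 500
    terminator_len: int = 1000
    spacer_len: int = 20

    def __post_init__(self):
        for name in ("promoter_len", "utr5_len", "utr3_len", "terminator_len", "spacer_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def upstream_len(self) -> int:
        return self.promoter_len + self.utr5_len

    @property
    def downstream_len(self) -> int:
        return self.utr3_len + self.terminator_len

    @property
    def total_input_len(self) -> int:
        return self.upstream_len + self.spacer_len + self.downstream_len

    @property
    def spacer_start(self) -> int:
        """0-based index of the first spacer position in the fused sequence."""
        return self.upstream_len

    def tss_index(self) -> int:
        """Fused-sequence index of the gene start (first base of the 5'UTR block)."""
        return self.promoter_len

    def tts_index(self) -> int:
        """Fused-sequence index of the gene end (last base of the 3'UTR block)."""
        return self.upstream_len + self.spacer_len + self.utr3_len - 1


@dataclass
class FlankingSequence:
    gene_id: str
    upstream: str
    downstream: str
    spacer_len: int = 20
    windows_overlap: bool = False

    @property
    def fused(self) -> str:
        return self.upstream + "N" * self.spacer_len + self.downstream


@dataclass
class EncodedInput:
    gene_id: str
    matrix: np.ndarray  # (total_input_len, 4), float32 in {0, 1}


def _clean_sequence(seq: str, name: str, on_ambiguous: str = "mask") -> str:
    seq = seq.upper()
    bad = set(seq) - set(BASES) - {"N"}
    if bad:
        if on_ambiguous == "error":
            raise ValueError(f"{name}: unexpected characters {sorted(bad)}")
        unknown = bad - _AMBIGUOUS
        if unknown:
            raise ValueError(f"{name}: non-nucleotide characters {sorted(unknown)}")
        warnings.warn(f"{name}: ambiguity codes {sorted(bad)} mapped to N")
        seq = "".join(c if c in _BASE_INDEX or c == "N" else "N" for c in seq)
    return seq


def read_genome(fasta_path, on_ambiguous: str = "mask") -> dict:
    """Read a (multi-)FASTA into a map chromosome -> uppercase sequence.

    ``on_ambiguous`` is ``"mask"`` (IUPAC codes other than ACGT become N, with
    a warning) or ``"error"``.
    """
    from pyfaidx import Fasta

    fa = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True, rebuild=True)
    genome = {name: _clean_sequence(str(fa[name][:]), name, on_ambiguous) for name in fa.keys()}
    if not genome:
        raise ValueError(f"{fasta_path}: no FASTA records")
    return genome


def read_annotation(gff3_path) -> list:
    """Read gene records from a GFF3 file (1-based inclusive coordinates)."""
    import gffutils

    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for feat in db.features_of_type("gene"):
        ids = feat.attributes.get("ID")
        if not ids:
            raise ValueError(f"gene at {feat.seqid}:{feat.start}-{feat.end} has no ID attribute")
        genes.append(
            GeneAnnotation(
                gene_id=ids[0], chrom=feat.seqid, start=feat.start, end=feat.end, strand=feat.strand
            )
        )
    return genes


def _window(seq: str, lo: int, hi: int) -> str:
    """Extract seq[lo:hi] in 0-based half-open coordinates, N-padded beyond the ends."""
    n = len(seq)
    left_pad = max(0, -lo)
    right_pad = max(0, hi - n)
    return "N" * left_pad + seq[max(lo, 0) : min(hi, n)] + "N" * right_pad


def extract_flanks(gene: GeneAnnotation, chrom_seq: str, cfg: RegionConfig | None = None) -> FlankingSequence:
    """Extract the fused flanking sequence of one gene, 5'->3' in gene orientation.

    Windows anchored at the annotated gene start/end; windows that run off the
    chromosome are N-padded so every gene yields the same fused length.
    """
    cfg = cfg or RegionConfig()
    start0 = gene.start - 1  # 0-based index of first gene base
    end0 = gene.end - 1  # 0-based index of last gene base
    if gene.strand == "+":
        up = _window(chrom_seq, start0 - cfg.promoter_len, start0 + cfg.utr5_len)
        down = _window(chrom_seq, end0 + 1 - cfg.utr3_len, end0 + 1 + cfg.terminator_len)
    else:
        # mirrored windows on the + strand, then reverse complemented
        up = reverse_complement(_window(chrom_seq, end0 + 1 - cfg.utr5_len, end0 + 1 + cfg.promoter_len))
        down = reverse_complement(_window(chrom_seq, start0 - cfg.terminator_len, start0 + cfg.utr3_len))
    gene_len = gene.end - gene.start + 1
    overlap = gene_len < cfg.utr5_len + cfg.utr3_len
    return FlankingSequence(
        gene_id=gene.gene_id,
        upstream=up,
        downstream=down,
        spacer_len=cfg.spacer_len,
        windows_overlap=overlap,
    )


def one_hot(seq: str) -> np.ndarray:
    """One-hot encode a DNA string (A,C,G,T channels; N -> all-zero row)."""
    mat = np.zeros((len(seq), 4), dtype=np.float32)
    for i, c in enumerate(seq):
        j = _BASE_INDEX.get(c)
        if j is not None:
            mat[i, j] = 1.0
        elif c != "N":
            raise ValueError(f"unexpected character {c!r} at position {i}")
    return mat


def encode(flank: FlankingSequence, cfg: RegionConfig | None = None) -> EncodedInput:
    cfg = cfg or RegionConfig()
    fused = flank.fused
    if len(fused) != cfg.total_input_len:
        raise ValueError(
            f"{flank.gene_id}: fused length {len(fused)} != configured {cfg.total_input_len}"
        )
    return EncodedInput(gene_id=flank.gene_id, matrix=one_hot(fused))


def decode(encoded: EncodedInput | np.ndarray) -> str:
    """Inverse of :func:`encode`; all-zero rows decode to N."""
    mat = encoded.matrix if isinstance(encoded, EncodedInput) else encoded
    out = []
    for row in np.asarray(mat):
        nz = np.flatnonzero(row)
        out.append(BASES[nz[0]] if nz.size else "N")
    return "".join(out)


def encode_genome(genes, genome: dict, cfg: RegionConfig | None = None):
    """Extract + encode all genes; returns (gene_ids, matrix stack, flank list)."""
    cfg = cfg or RegionConfig()
    flanks = [extract_flanks(g, genome[g.chrom], cfg) for g in genes]
    mats = np.stack([encode(f, cfg).matrix for f in flanks])
    return [g.gene_id for g in genes], mats, flanks
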