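"""File interchange: FASTA/TSV/JSON artifacts, MEME and JASPAR motif formats."""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

__all__ = ["write_fasta", "read_fasta", "write_flanks_fasta", "write_encodings",
           "read_encodings", "write_labels", "read_labels", "write_meme",
           "read_meme", "read_jaspar", "Manifest", "write_epm_table",
           "write_matches", "write_enrichment"]


def write_fasta(path, records: dict, width: int = 80):
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict:
    out, name, chunks = {}, None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line.upper())
    if name is not None:
        out[name] = "".join(chunks)
    return out


def write_flanks_fasta(path, flanks, cfg):
    """One record per gene; the description carries the segment boundaries."""
    with open(path, "w") as fh:
        for f in flanks:
            desc = (f"promoter=0-{cfg.promoter_len} utr5={cfg.promoter_len}-{cfg.upstream_len} "
                    f"spacer={cfg.upstream_len}-{cfg.upstream_len + cfg.spacer_len} "
                    f"utr3_terminator={cfg.upstream_len + cfg.spacer_len}-{cfg.total_input_len} "
                    f"overlap={f.windows_overlap}")
            fh.write(f">{f.gene_id} {desc}\n")
            seq = f.fused
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_encodings(path, encoded: dict):
    np.savez_compressed(path, **{g: m for g, m in encoded.items()})


def read_encodings(path) -> dict:
    with np.load(path) as z:
        return {g: z[g] for g in z.files}


def write_labels(path, labels: pd.DataFrame):
    labels.to_csv(path, sep="\t", index_label="gene_id")


def read_labels(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_meme(path, epms, background=(0.25, 0.25, 0.25, 0.25)):
    """Minimal MEME motif format (version 4) for EPM PWMs."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A {:.5f} C {:.5f} G {:.5f} T {:.5f}\n\n".format(*background))
        for e in epms:
            fh.write(f"MOTIF {e.name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {e.width} "
                     f"nsites= {e.n_seqlets} E= 0\n")
            for row in e.pwm:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_meme(path) -> dict:
    """Read a MEME motif file into a map name -> (W, 4) probability matrix."""
    from Bio import motifs

    with open(path) as fh:
        records = motifs.parse(fh, "minimal")
    out = {}
    for m in records:
        pwm = np.array([[m.pwm[b][i] for b in "ACGT"] for i in range(m.length)])
        out[m.name] = pwm
    return out


def read_jaspar(path) -> dict:
    """Read JASPAR-format PFMs into a map matrix_id -> (W, 4) count matrix."""
    from Bio import motifs

    with open(path) as fh:
        records = motifs.parse(fh, "jaspar")
    out = {}
    for m in records:
        counts = np.array([[m.counts[b][i] for b in "ACGT"] for i in range(m.length)],
                          dtype=float)
        out[m.matrix_id or m.name] = counts
    return out


def write_epm_table(path, epms):
    rows = []
    for e in epms:
        rows.append({
            "name": e.name, "metacluster": e.metacluster, "width": e.width,
            "n_seqlets": e.n_seqlets, "info_content": e.info_content,
            "consensus": e.consensus,
            "upstream_range": _fmt_range(e.preferred_ranges.get("upstream")),
            "downstream_range": _fmt_range(e.preferred_ranges.get("downstream")),
            "cwm_sum": float(e.cwm.sum()),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _fmt_range(rng):
    return "" if rng is None else f"{rng[0]:.1f}:{rng[1]:.1f}"


def write_matches(path, matches):
    rows = [{
        "gene_id": m.gene_id, "start": m.start, "strand": m.strand,
        "epm_name": m.epm_name, "score": m.score, "p_value": m.p_value,
        "e_value": m.e_value, "genotype_id": m.genotype_id or "",
        "half": m.half or "", "offset": "" if m.offset is None else m.offset,
        "within_preferred": m.within_preferred,
    } for m in matches]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_enrichment(path, results):
    rows = [{
        "epm_name": r.epm_name, "a": r.a, "A": r.A, "b": r.b, "B": r.B,
        "fraction_own": r.fraction_own, "fraction_opp": r.fraction_opp,
        "enrichment": r.enrichment, "chi2": r.chi2, "p": r.p,
    } for r in results]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


class Manifest:
    """Records every artifact a pipeline run writes, with seeds and settings."""

    def __init__(self, output_dir, seed: int, settings: dict | None = None):
        self.output_dir = str(output_dir)
        os.makedirs(self.output_dir, exist_ok=True)
        self.data = {"seed": seed, "settings": settings or {}, "files": [],
                     "metrics": {}}

    def path(self, *parts) -> str:
        p = os.path.join(self.output_dir, *parts)
        os.makedirs(os.path.dirname(p), exist_ok=True)
        rel = os.path.relpath(p, self.output_dir)
        if rel not in self.data["files"]:
            self.data["files"].append(rel)
        return p

    def record_metric(self, key: str, value):
        self.data["metrics"][key] = value

    def save(self) -> str:
        p = os.path.join(self.output_dir, "manifest.json")
        with open(p, "w") as fh:
            json.dump(self.data, fh, indent=2, default=_json_default)
        return p


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
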