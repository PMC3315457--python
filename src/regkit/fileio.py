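"""Readers and writers for the text formats the pipeline consumes.

FASTA via Biopython; BED6 (0-based half-open), GFF3 gene models, TSV
matrices, DE tables, and motif manifests with validation that reports line
numbers. write(read(x)) is record-equivalent to x.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genelists import DE_COLUMNS, GeneListError
from .intervals import Gene, Interval
from .motifs import Motif, MotifSite, build_pwm, iupac_to_pwm


class FormatError(ValueError):
    """Malformed input file; message carries the offending line number."""


def _open(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> dict[str, str]:
    with _open(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(path, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    with _open(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_bed(path) -> list[dict]:
    """BED3/BED6 records as dicts; start >= end is rejected with line number."""
    rows = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if start < 0 or start >= end:
                raise FormatError(f"{path}:{lineno}: invalid interval {start}-{end}")
            row = {"chrom": parts[0], "start": start, "end": end,
                   "name": parts[3] if len(parts) > 3 else ".",
                   "score": parts[4] if len(parts) > 4 else ".",
                   "strand": parts[5] if len(parts) > 5 else "."}
            rows.append(row)
    return rows


def write_bed(path, rows: Iterable[Mapping]) -> None:
    with _open(path, "wt") as fh:
        for r in rows:
            fh.write("\t".join(str(r.get(k, ".")) for k in
                               ("chrom", "start", "end", "name", "score", "strand"))
                     + "\n")


def read_bed_intervals(path) -> list[Interval]:
    return [Interval(r["chrom"], r["start"], r["end"], r["name"])
            for r in read_bed(path)]


def sites_to_bed(sites: Iterable[MotifSite], widths: Mapping[str, int]) -> list[dict]:
    """MotifSites as BED6 rows; score column carries the log-odds."""
    return [{"chrom": s.seq_id, "start": s.start,
             "end": s.start + widths[s.motif_name], "name": s.motif_name,
             "score": f"{s.score:.4f}", "strand": s.strand}
            for s in sites]


def read_gff3_genes(path) -> list[Gene]:
    """Gene features from GFF3 as 0-based half-open Gene records."""
    genes = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            if parts[2] != "gene":
                continue
            try:
                start1, end1 = int(parts[3]), int(parts[4])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if start1 > end1:
                raise FormatError(f"{path}:{lineno}: start > end")
            attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
            gene_id = attrs.get("ID") or attrs.get("gene_id")
            if not gene_id:
                raise FormatError(f"{path}:{lineno}: gene feature without ID")
            genes.append(Gene(gene_id, parts[0], start1 - 1, end1, parts[6]))
    return genes


def read_tsv_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise FormatError(f"{path}: empty matrix")
    return df


def write_tsv_matrix(path, matrix: pd.DataFrame) -> None:
    matrix.to_csv(path, sep="\t")


def read_de_table(path) -> pd.DataFrame:
    """DE table TSV with required header gene_id, log2fc, pvalue, fdr."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: DE table missing column(s) {missing}")
    if "direction" not in df.columns:
        df["direction"] = np.where(df["log2fc"] > 0, "up", "down")
    return df


def write_de_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> list[str]:
    with _open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_motif_manifest(path, pseudocount: float = 0.01,
                        background=None) -> list[Motif]:
    """TSV manifest: name <TAB> IUPAC-consensus-or-matrix-path.

    A matrix path points to a MEME-minimal-style whitespace matrix with one
    line per position (A C G T probabilities or counts).
    """
    base = Path(path).parent
    motifs = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected name<TAB>spec")
            name, spec = parts[0], parts[1]
            if set(spec.upper()) <= set("ACGTRYSWKMBDHVN") and not Path(spec).suffix:
                motifs.append(iupac_to_pwm(spec, pseudocount, background, name=name))
            else:
                mat = np.loadtxt(base / spec)
                motifs.append(build_pwm(mat.T, pseudocount, background, name=name))
    return motifs
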