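"""Readers and writers for the standard file formats the pipeline consumes.

Coordinate conventions: BED and everything internal are 0-based half-open;
RepeatMasker ``.out`` tables and GFF3 are 1-based inclusive and converted on
read. BLAST tabular hits with ``sstart > send`` (minus strand) are normalised
to forward half-open intervals.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .masking import RepeatAnnotation

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_repeatmasker_out",
    "write_repeatmasker_out",
    "read_repeats_bed",
    "write_repeats_bed",
    "read_bed",
    "write_bed",
    "read_blast_tabular",
    "read_qc_sidecar",
    "write_qc_sidecar",
    "read_gff3_genes",
    "write_gff3_genes",
    "read_interproscan_tsv",
]

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_repeatmasker_out(path) -> list[RepeatAnnotation]:
    """Parse a RepeatMasker ``.out``-style table into repeat annotations.

    Columns used: divergence (col 2), query name (col 5), begin/end
    (cols 6-7, 1-based inclusive), repeat name (col 10), class/family
    (col 11). Class/family values containing ``Simple_repeat``,
    ``Satellite`` or ``Tandem`` are treated as tandem repeats.
    """
    repeats = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or not parts[0].replace(".", "").isdigit():
                continue  # header or blank
            div = float(parts[1])
            chrom = parts[4]
            start = int(parts[5]) - 1
            end = int(parts[6])
            family = parts[9]
            rclass = parts[10] if len(parts) > 10 else ""
            tandem = any(t in rclass for t in ("Simple_repeat", "Satellite", "Tandem"))
            repeats.append(
                RepeatAnnotation(
                    chrom=chrom, start=start, end=end,
                    kind="tandem" if tandem else "interspersed",
                    family=family,
                    divergence=None if tandem else div,
                )
            )
    return repeats


def write_repeatmasker_out(repeats: list[RepeatAnnotation], path) -> None:
    header = (
        "   SW   perc perc perc  query     position in query    matching  repeat\n"
        "score   div. del. ins.  sequence  begin end (left)     repeat    class/family\n\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for r in repeats:
            div = r.divergence if r.divergence is not None else 0.0
            rclass = "Tandem" if r.kind == "tandem" else "Unknown"
            fh.write(
                f"  225 {div:6.1f}  0.0  0.0  {r.chrom}  {r.start + 1} {r.end} (0)  + "
                f"{r.family or 'rep'}  {rclass}\n"
            )


def read_repeats_bed(path) -> list[RepeatAnnotation]:
    """BED with columns chrom, start, end, family, kind, divergence ('.' = none)."""
    repeats = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, family, kind, div = line.split("\t")[:6]
            div = div.strip()
            repeats.append(
                RepeatAnnotation(
                    chrom=chrom, start=int(start), end=int(end), family=family,
                    kind=kind, divergence=None if div == "." else float(div),
                )
            )
    return repeats


def write_repeats_bed(repeats: list[RepeatAnnotation], path) -> None:
    with open(path, "w") as fh:
        for r in repeats:
            div = "." if r.divergence is None else f"{r.divergence:.2f}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.family}\t{r.kind}\t{div}\n")


def read_bed(path) -> dict[str, np.ndarray]:
    """Read a plain BED3+ into per-chromosome (n, 2) interval arrays."""
    by_chrom: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            by_chrom.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
    return {c: np.array(v, dtype=np.int64) for c, v in by_chrom.items()}


def write_bed(by_chrom: dict[str, np.ndarray], path, names: bool = False) -> None:
    with open(path, "w") as fh:
        for chrom, iv in by_chrom.items():
            for i, (s, e) in enumerate(np.asarray(iv).reshape(-1, 2)):
                if names:
                    fh.write(f"{chrom}\t{s}\t{e}\t{chrom}_{i}\n")
                else:
                    fh.write(f"{chrom}\t{s}\t{e}\n")


def read_blast_tabular(path) -> pd.DataFrame:
    """Read BLAST outfmt-6 read-vs-genome hits into the match table.

    Returns columns read_id, chrom, start, end, length, identity, strand with
    genomic coordinates normalised to forward 0-based half-open.
    """
    df = pd.read_csv(path, sep="\t", names=BLAST6_COLUMNS, comment="#")
    minus = df["sstart"] > df["send"]
    start = np.where(minus, df["send"], df["sstart"]) - 1
    end = np.where(minus, df["sstart"], df["send"])
    return pd.DataFrame(
        {
            "read_id": df["qseqid"],
            "chrom": df["sseqid"],
            "start": start.astype(np.int64),
            "end": end.astype(np.int64),
            "length": (end - start).astype(np.int64),
            "identity": df["pident"].astype(float),
            "strand": np.where(minus, "-", "+"),
        }
    )


def read_qc_sidecar(path) -> pd.DataFrame:
    """Per-read QC table: id, percent_error, hq_start, hq_end, flagged."""
    df = pd.read_csv(path, sep="\t")
    required = {"id", "percent_error", "hq_start", "hq_end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"QC sidecar missing columns: {sorted(missing)}")
    if "flagged" not in df.columns:
        df["flagged"] = False
    return df


def write_qc_sidecar(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gff3_genes(path) -> pd.DataFrame:
    """Extract gene features from GFF3 (1-based inclusive -> half-open).

    Returns columns id, chrom, start, end, strand.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID") or attrs.get("Name") or f"{parts[0]}:{parts[3]}"
            rows.append(
                (gene_id, parts[0], int(parts[3]) - 1, int(parts[4]), parts[6])
            )
    return pd.DataFrame(rows, columns=["id", "chrom", "start", "end", "strand"])


def write_gff3_genes(genes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples():
            strand = getattr(row, "strand", "+")
            fh.write(
                f"{row.chrom}\twssd\tgene\t{row.start + 1}\t{row.end}\t.\t{strand}\t.\t"
                f"ID={row.id}\n"
            )


def read_interproscan_tsv(path) -> pd.DataFrame:
    """Read an InterProScan-style TSV of protein-domain matches.

    Expected tab columns: protein_id, source_db, signature, status (T/F),
    interpro_id (may be 'NULL'). Extra columns are ignored.
    """
    rows = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for parts in reader:
            if not parts or parts[0].startswith("#"):
                continue
            rows.append(parts[:5])
    df = pd.DataFrame(
        rows, columns=["protein_id", "source_db", "signature", "status", "interpro_id"]
    )
    return df
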