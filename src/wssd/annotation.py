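"""Gene, protein-domain and organelle-DNA overlays on called duplications.

Genes are *fully duplicated* when their interval lies entirely within the
union of merged duplication intervals, *partially* when they properly
overlap, *unique* otherwise. Gene density is genes per 100 kb. The domain
enrichment factor compares a domain's fractional abundance among retained
InterPro assignments of duplicated versus unique peptides. NUMT/NUPT
content is the union of organelle-alignment hit intervals (each nucleotide
counted once), reported genome-wide and inside duplications.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import intervals as ivl
from .masking import MaskedGenome
from .sd_calling import chromosome_class

__all__ = [
    "classify_genes",
    "gene_density_table",
    "retain_domain_assignments",
    "enrichment_factor",
    "numt_content",
    "top_duplicated_genes",
    "interval_composition",
]

EVALUE_CUTOFF = 1e-4


def _union_by_chrom(intervals: pd.DataFrame) -> dict[str, np.ndarray]:
    return {
        chrom: ivl.merge(grp[["start", "end"]].to_numpy())
        for chrom, grp in intervals.groupby("chrom", sort=False)
    }


def classify_genes(genes: pd.DataFrame, intervals: pd.DataFrame) -> pd.DataFrame:
    """Attach duplication_status (unique/partial/full) to each gene.

    Containment is evaluated against the union of merged intervals, so a
    gene spanning two abutting called intervals is still *full*.
    """
    union = _union_by_chrom(intervals)
    status = np.full(len(genes), "unique", dtype=object)
    genes = genes.reset_index(drop=True)
    for chrom, grp in genes.groupby("chrom", sort=False):
        iv = union.get(chrom)
        if iv is None or len(iv) == 0:
            continue
        gs = grp["start"].to_numpy()
        ge = grp["end"].to_numpy()
        # candidate union interval: the last one starting at or before gene start
        pos = np.searchsorted(iv[:, 0], gs, side="right") - 1
        pos_ok = pos >= 0
        full = np.zeros(len(grp), dtype=bool)
        full[pos_ok] = ge[pos_ok] <= iv[np.maximum(pos[pos_ok], 0), 1]
        overlap = np.zeros(len(grp), dtype=bool)
        for i, (s, e) in enumerate(zip(gs, ge)):
            j = np.searchsorted(iv[:, 1], s, side="right")
            overlap[i] = j < len(iv) and iv[j, 0] < e
        status[grp.index.to_numpy()[full]] = "full"
        status[grp.index.to_numpy()[overlap & ~full]] = "partial"
    out = genes.copy()
    out["duplication_status"] = status
    return out


def gene_density_table(
    genes: pd.DataFrame, intervals: pd.DataFrame, mg: MaskedGenome
) -> pd.DataFrame:
    """Per-chromosome gene counts and densities with stratum totals.

    Density is genes per 100 kb: chromosome density over chromosome bp and
    fully-duplicated gene density over duplicated bp. The ratio of densities
    divides the duplication density by the chromosome density.
    """
    genes = classify_genes(genes, intervals)
    union = _union_by_chrom(intervals)
    rows = []
    acc: dict[str, list] = {"nonrandom": [], "random": [], "unknown": []}
    for chrom in mg.chroms:
        size = mg.chrom_size(chrom)
        if size == 0:
            raise ValueError(f"zero-length chromosome {chrom!r}")
        sub = genes[genes["chrom"] == chrom]
        n_total = len(sub)
        n_full = int((sub["duplication_status"] == "full").sum())
        n_partial = int((sub["duplication_status"] == "partial").sum())
        iv = union.get(chrom)
        dup_bp = int((iv[:, 1] - iv[:, 0]).sum()) if iv is not None and len(iv) else 0
        rows.append((chrom, n_total, n_full, n_partial, size, dup_bp))
        acc[chromosome_class(chrom)].append(rows[-1][1:])

    def tot(name, entries):
        sums = [sum(e[i] for e in entries) for i in range(5)]
        return (name, *sums)

    rows.append(tot("Tot_nonrandom", acc["nonrandom"]))
    rows.append(tot("Tot_random", acc["random"]))
    rows.append(tot("Tot_placed", acc["nonrandom"] + acc["random"]))
    rows.append(tot("Tot_whole", acc["nonrandom"] + acc["random"] + acc["unknown"]))
    df = pd.DataFrame(
        rows,
        columns=["chr", "total_genes", "full_dup_genes", "partial_dup_genes",
                 "chr_size", "dup_size"],
    )
    df["chr_gene_density"] = 1e5 * df["total_genes"] / df["chr_size"]
    with np.errstate(divide="ignore", invalid="ignore"):
        df["full_dup_gene_density"] = np.where(
            df["dup_size"] > 0, 1e5 * df["full_dup_genes"] / df["dup_size"], np.nan
        )
    df["ratio_of_densities"] = df["full_dup_gene_density"] / df["chr_gene_density"]
    return df


def retain_domain_assignments(assignments: pd.DataFrame) -> pd.DataFrame:
    """Keep true-positive matches (status T) with an InterPro id assigned."""
    keep = (assignments["status"] == "T") & (
        ~assignments["interpro_id"].isin(["NULL", "", "-"])
    ) & assignments["interpro_id"].notna()
    return assignments[keep].reset_index(drop=True)


def enrichment_factor(
    domain_counts_dup: dict[str, int], domain_counts_unique: dict[str, int]
) -> tuple[dict[str, float], list[str]]:
    """Domain enrichment in duplicated vs unique peptides.

    EF(d) = (c_dup(d) / sum c_dup) / (c_uniq(d) / sum c_uniq). Domains absent
    from unique peptides are returned in a separate duplicated-only list
    without a numeric EF. Counts are occurrences of retained assignments
    (one per match).
    """
    tot_dup = sum(domain_counts_dup.values())
    tot_uniq = sum(domain_counts_unique.values())
    if tot_dup == 0 or tot_uniq == 0:
        raise ValueError("empty duplicated or unique domain universe")
    ef = {}
    dup_only = []
    for d, c in domain_counts_dup.items():
        cu = domain_counts_unique.get(d, 0)
        if cu == 0:
            dup_only.append(d)
        else:
            ef[d] = (c / tot_dup) / (cu / tot_uniq)
    return ef, sorted(dup_only)


def numt_content(
    hits: pd.DataFrame,
    intervals: pd.DataFrame,
    mg: MaskedGenome,
    evalue_cutoff: float = EVALUE_CUTOFF,
) -> pd.DataFrame:
    """NUMT/NUPT bp and percentages per chromosome and inside duplications.

    ``hits`` columns: organelle ('mito'/'plastid'), chrom, start, end,
    evalue. Hit intervals are unioned per organelle class so each nucleotide
    counts once; inside-duplication content is the intersection with the
    union of called intervals, with duplication bp as its denominator.
    """
    hits = hits[hits["evalue"] <= evalue_cutoff]
    sd_union = _union_by_chrom(intervals)
    rows = []
    acc: dict[str, list] = {"nonrandom": [], "random": [], "unknown": []}
    for chrom in mg.chroms:
        size = mg.chrom_size(chrom)
        sd_iv = sd_union.get(chrom, np.empty((0, 2), dtype=np.int64))
        sd_bp = int((sd_iv[:, 1] - sd_iv[:, 0]).sum()) if len(sd_iv) else 0
        vals = [chrom, size, sd_bp]
        for organelle in ("mito", "plastid"):
            sub = hits[(hits["chrom"] == chrom) & (hits["organelle"] == organelle)]
            union = ivl.merge(sub[["start", "end"]].to_numpy())
            bp = int((union[:, 1] - union[:, 0]).sum()) if len(union) else 0
            in_sd = ivl.union_length(ivl.intersect(union, sd_iv)) if len(union) else 0
            vals.extend([bp, in_sd])
        rows.append(tuple(vals))
        acc[chromosome_class(chrom)].append(vals[1:])

    def tot(name, entries):
        sums = [sum(e[i] for e in entries) for i in range(6)]
        return (name, *sums)

    rows.append(tot("Tot_nonrandom", acc["nonrandom"]))
    rows.append(tot("Tot_random", acc["random"]))
    rows.append(tot("Tot_placed", acc["nonrandom"] + acc["random"]))
    rows.append(tot("Tot_whole", acc["nonrandom"] + acc["random"] + acc["unknown"]))
    df = pd.DataFrame(
        rows,
        columns=["chr", "chr_size", "sd_size", "numt_bp", "numt_sd_bp",
                 "nupt_bp", "nupt_sd_bp"],
    )
    df["numt_pct"] = 100.0 * df["numt_bp"] / df["chr_size"]
    df["nupt_pct"] = 100.0 * df["nupt_bp"] / df["chr_size"]
    with np.errstate(divide="ignore", invalid="ignore"):
        df["numt_sd_pct"] = np.where(
            df["sd_size"] > 0, 100.0 * df["numt_sd_bp"] / df["sd_size"], np.nan
        )
        df["nupt_sd_pct"] = np.where(
            df["sd_size"] > 0, 100.0 * df["nupt_sd_bp"] / df["sd_size"], np.nan
        )
    return df


def top_duplicated_genes(
    genes: pd.DataFrame,
    intervals: pd.DataFrame,
    n: int = 100,
    domains: pd.DataFrame | None = None,
    organelle_homolog_ids: set | None = None,
) -> pd.DataFrame:
    """Rank fully duplicated genes by their interval's mean 5-kub coverage.

    Ties break by (chrom, start). If fewer than ``n`` genes are eligible all
    are returned (with a warning via the return size). Each row carries the
    containing interval's mean coverage, an organelle-homolog flag, and the
    gene's InterPro domains when an assignment table is given.
    """
    classified = classify_genes(genes, intervals)
    full = classified[classified["duplication_status"] == "full"].copy()
    if len(full) == 0:
        return pd.DataFrame(
            columns=list(genes.columns) + ["mean_coverage", "organelle_homolog", "domains"]
        )
    cov = np.zeros(len(full))
    for i, row in enumerate(full.itertuples()):
        sub = intervals[intervals["chrom"] == row.chrom]
        if len(sub) == 0:
            continue
        ov = np.minimum(sub["end"], row.end) - np.maximum(sub["start"], row.start)
        j = int(np.argmax(ov.to_numpy()))
        cov[i] = sub["mean_coverage"].iloc[j] if ov.iloc[j] > 0 else 0.0
    full["mean_coverage"] = cov
    homologs = organelle_homolog_ids or set()
    full["organelle_homolog"] = full["id"].isin(homologs)
    if domains is not None and len(domains):
        dmap = domains.groupby("protein_id")["interpro_id"].apply(
            lambda s: ",".join(sorted(set(s)))
        )
        full["domains"] = full["id"].map(dmap).fillna("")
    else:
        full["domains"] = ""
    full = full.sort_values(
        ["mean_coverage", "chrom", "start"], ascending=[False, True, True],
        ignore_index=True,
    )
    return full.head(n)


def interval_composition(
    intervals: pd.DataFrame,
    mg: MaskedGenome,
    repeats=None,
) -> pd.DataFrame:
    """GC percent and per-repeat-family bp inside duplications vs genome-wide.

    GC is computed over non-gap bases. A repeat partially covered by a
    duplication contributes only the covered bp to the inside column.
    """
    sd_union = _union_by_chrom(intervals)
    gc_in = at_in = gc_all = at_all = 0
    for chrom in mg.chroms:
        seq = np.frombuffer(mg.sequences[chrom].upper().encode(), dtype=np.uint8)
        is_gc = (seq == ord("G")) | (seq == ord("C"))
        is_at = (seq == ord("A")) | (seq == ord("T"))
        gc_all += int(is_gc.sum())
        at_all += int(is_at.sum())
        for s, e in sd_union.get(chrom, []):
            gc_in += int(is_gc[s:e].sum())
            at_in += int(is_at[s:e].sum())
    rows = [
        (
            "GC_percent",
            100.0 * gc_in / max(gc_in + at_in, 1),
            100.0 * gc_all / max(gc_all + at_all, 1),
        )
    ]
    if repeats:
        by_family: dict[str, dict[str, list]] = {}
        for r in repeats:
            by_family.setdefault(r.family or r.kind, {}).setdefault(r.chrom, []).append(
                (r.start, r.end)
            )
        for family, per_chrom in sorted(by_family.items()):
            inside = total = 0
            for chrom, iv in per_chrom.items():
                merged = ivl.merge(iv)
                total += int((merged[:, 1] - merged[:, 0]).sum())
                inside += ivl.union_length(
                    ivl.intersect(merged, sd_union.get(chrom, np.empty((0, 2))))
                )
            rows.append((f"repeat_bp:{family}", float(inside), float(total)))
    return pd.DataFrame(rows, columns=["metric", "in_duplications", "whole_genome"])
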