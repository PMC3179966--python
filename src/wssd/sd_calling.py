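"""Window classification, 6-of-7 duplication calling and genome summaries.

A 5-kub window is *negative* when its depth is at or below ``avg + 2 sd``,
*borderline* in ``(avg + 2 sd, avg + 3 sd)``, and *positive* at or above
``avg + 3 sd`` (the boundary point is positive; a switch restores the
strict-inequality reading). Every run of seven consecutive sliding windows
containing at least six positives marks all seven as duplicated; clusters of
index-consecutive marked windows, merged, are the called intervals.
Borderline windows neither count toward 6-of-7 nor break intervals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import intervals as ivl
from .calibration import Thresholds
from .masking import MaskedGenome
from .windowing import MASKED_BINS, masked_percentage_bin

__all__ = [
    "classify_windows",
    "call_intervals",
    "summarize_genome",
    "window_class_distribution",
    "interval_size_distribution",
    "chromosome_class",
    "write_intervals_bed",
]

LABELS = ("negative", "borderline", "positive")

INTERVAL_COLUMNS = ["chrom", "start", "end", "n_windows5", "mean_coverage"]


def classify_windows(
    w5: pd.DataFrame, thresholds: Thresholds, positive_inclusive: bool = True
) -> pd.DataFrame:
    """Label each 5-kub window negative/borderline/positive."""
    if thresholds is None:
        raise ValueError("thresholds are unset")
    w5 = w5.copy()
    depth = w5["depth"].to_numpy(dtype=float)
    if positive_inclusive:
        positive = depth >= thresholds.positive_cut
    else:
        positive = depth > thresholds.positive_cut
    borderline = (depth > thresholds.borderline_cut) & ~positive
    w5["label"] = np.select(
        [positive, borderline], ["positive", "borderline"], default="negative"
    )
    return w5


def _mark_m_of_n(positive: np.ndarray, m: int, n: int) -> np.ndarray:
    """Mark every window that belongs to some n-block with >= m positives."""
    L = len(positive)
    marked = np.zeros(L, dtype=bool)
    if L < n:
        return marked
    counts = np.convolve(positive.astype(int), np.ones(n, dtype=int), mode="valid")
    qual = counts >= m
    if not qual.any():
        return marked
    delta = np.zeros(L + 1, dtype=int)
    starts = np.flatnonzero(qual)
    np.add.at(delta, starts, 1)
    np.add.at(delta, starts + n, -1)
    marked = np.cumsum(delta[:-1]) > 0
    return marked


def call_intervals(
    w5: pd.DataFrame, m_of_n: tuple[int, int] = (6, 7)
) -> pd.DataFrame:
    """Call duplicated intervals from labelled sliding windows.

    Windows are processed per gap-delimited run; each cluster of
    index-consecutive marked windows becomes one interval whose span is the
    union of member spans, with ``mean_coverage`` the mean member depth.
    Clusters separated by at least one non-marked window stay separate.
    """
    m, n = m_of_n
    rows = []
    if len(w5) == 0:
        return pd.DataFrame(columns=INTERVAL_COLUMNS)
    for (chrom, run), grp in w5.groupby(["chrom", "run"], sort=False):
        grp = grp.sort_values("first")
        positive = (grp["label"] == "positive").to_numpy()
        marked = _mark_m_of_n(positive, m, n)
        if not marked.any():
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        depths = grp["depth"].to_numpy(dtype=float)
        idx = np.flatnonzero(marked)
        breaks = np.flatnonzero(np.diff(idx) > 1) + 1
        for cluster in np.split(idx, breaks):
            rows.append(
                (
                    chrom,
                    int(starts[cluster[0]]),
                    int(ends[cluster[-1]]),
                    len(cluster),
                    float(depths[cluster].mean()),
                )
            )
    df = pd.DataFrame(rows, columns=INTERVAL_COLUMNS)
    if len(df):
        df = df.sort_values(["chrom", "start"], ignore_index=True)
    return df


def chromosome_class(name: str) -> str:
    """Assembly stratum from the sequence name suffix."""
    if "_random" in name:
        return "random"
    if name.startswith(("chrUn", "Un")):
        return "unknown"
    return "nonrandom"


def summarize_genome(
    intervals: pd.DataFrame, mg: MaskedGenome
) -> pd.DataFrame:
    """Per-chromosome duplication summary with stratum totals.

    Columns: chr, chr_size, dup_size (union bp of intervals), perc_dup,
    n_intervals; followed by Tot_nonrandom / Tot_random / Tot_placed /
    Tot_whole rows (sums, not averages).
    """
    unknown = set(intervals["chrom"].unique()) - set(mg.chroms)
    if unknown:
        raise ValueError(f"intervals on unknown chromosomes: {sorted(unknown)}")
    rows = []
    per_class: dict[str, list] = {"nonrandom": [], "random": [], "unknown": []}
    for chrom in mg.chroms:
        sub = intervals[intervals["chrom"] == chrom]
        dup = ivl.union_length(sub[["start", "end"]].to_numpy())
        size = mg.chrom_size(chrom)
        rows.append((chrom, size, dup, 100.0 * dup / size, len(sub)))
        per_class[chromosome_class(chrom)].append((size, dup, len(sub)))

    def total(name, entries):
        size = sum(e[0] for e in entries)
        dup = sum(e[1] for e in entries)
        cnt = sum(e[2] for e in entries)
        pct = 100.0 * dup / size if size else 0.0
        return (name, size, dup, pct, cnt)

    rows.append(total("Tot_nonrandom", per_class["nonrandom"]))
    rows.append(total("Tot_random", per_class["random"]))
    rows.append(total("Tot_placed", per_class["nonrandom"] + per_class["random"]))
    rows.append(
        total("Tot_whole", per_class["nonrandom"] + per_class["random"] + per_class["unknown"])
    )
    return pd.DataFrame(
        rows, columns=["chr", "chr_size", "dup_size", "perc_dup", "n_intervals"]
    )


def window_class_distribution(w5: pd.DataFrame) -> pd.DataFrame:
    """Percent of negative/borderline/positive windows, overall and per
    masked-percentage bin."""
    w5 = w5.copy()
    w5["bin"] = masked_percentage_bin(w5["masked_pct"].to_numpy())
    rows = []

    def shares(sub, name):
        total = len(sub)
        if total == 0:
            return (name, 0, 0.0, 0.0, 0.0)
        counts = sub["label"].value_counts()
        return (
            name,
            total,
            100.0 * counts.get("negative", 0) / total,
            100.0 * counts.get("borderline", 0) / total,
            100.0 * counts.get("positive", 0) / total,
        )

    rows.append(shares(w5, "all"))
    for b in MASKED_BINS:
        rows.append(shares(w5[w5["bin"] == b], b))
    return pd.DataFrame(
        rows, columns=["subset", "n_windows", "negative", "borderline", "positive"]
    )


def interval_size_distribution(
    intervals: pd.DataFrame, bin_width: int = 5000
) -> dict:
    """Histogram of interval sizes plus mode (densest bin midpoint) and max."""
    if len(intervals) == 0:
        return {"counts": np.array([]), "edges": np.array([]), "mode": None, "max": None}
    sizes = (intervals["end"] - intervals["start"]).to_numpy()
    top = int(np.ceil(sizes.max() / bin_width)) * bin_width
    edges = np.arange(0, top + bin_width, bin_width)
    counts, edges = np.histogram(sizes, bins=edges)
    i = int(np.argmax(counts))
    return {
        "counts": counts,
        "edges": edges,
        "mode": float(0.5 * (edges[i] + edges[i + 1])),
        "max": int(sizes.max()),
    }


def write_intervals_bed(intervals: pd.DataFrame, path) -> None:
    """BED5: name = interval ordinal id, score = mean 5-kub coverage."""
    with open(path, "w") as fh:
        for i, row in enumerate(intervals.itertuples()):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\tSD{i + 1:05d}\t"
                f"{row.mean_coverage:.2f}\n"
            )
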