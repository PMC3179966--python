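"""Read QC, alignment filtering and midpoint depth counting.

The duplication signal in this method is *multi-mapping read depth*: every
qualifying local alignment of every read counts, so a genomic segment whose
copies were collapsed in the assembly accumulates the reads of all its
copies. Reads are therefore never uniquified to a best hit.

A built-in naive mapper (exact 32-mer seeding on a sorted k-mer index,
ungapped X-drop extension) makes the pipeline self-contained; external
BLAST tabular alignments are accepted through :func:`wssd.io.read_blast_tabular`
for users who want to reproduce the original aligner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .masking import MaskedGenome

__all__ = [
    "ReadRecord",
    "clip_reads",
    "GenomeIndex",
    "map_reads_naive",
    "compute_masked_overlap",
    "filter_matches",
    "count_depth",
    "match_midpoints",
]

log = logging.getLogger(__name__)

MATCH_COLUMNS = ["read_id", "chrom", "start", "end", "length", "identity", "strand"]

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
    _CODE[b + 32] = i  # lowercase masking stays alignable
_COMP = np.array([3, 2, 1, 0], dtype=np.uint8)


@dataclass
class ReadRecord:
    """One WGS read with its trace-quality metadata.

    ``hq_start``/``hq_end`` delimit the high-quality portion (half-open on
    the read); ``percent_error`` is the per-trace error estimate; ``flagged``
    marks reads failing the upstream low-quality/contamination screen.
    Reads lacking QC metadata pass with defaults.
    """

    id: str
    sequence: str
    hq_start: int = 0
    hq_end: int | None = None
    percent_error: float = 0.0
    flagged: bool = False

    def __post_init__(self):
        if self.hq_end is None:
            self.hq_end = len(self.sequence)
        if not (0 <= self.hq_start <= self.hq_end <= len(self.sequence)):
            raise ValueError(f"read {self.id}: hq interval outside sequence")
        if self.percent_error < 0:
            raise ValueError(f"read {self.id}: negative percent_error")


def clip_reads(
    reads: list[ReadRecord],
    max_percent_error: float = 6.0,
    min_hq_len: int = 300,
) -> tuple[list[ReadRecord], dict[str, int]]:
    """Apply trace QC: discard flagged reads, reads with percent error above
    the cutoff, and reads whose high-quality portion is shorter than
    ``min_hq_len``; truncate survivors to the high-quality interval.

    Returns the retained (clipped) reads and a per-rule discard tally.
    """
    kept = []
    counts = {"flagged": 0, "percent_error": 0, "short_hq": 0, "kept": 0}
    for r in reads:
        hq_len = r.hq_end - r.hq_start
        if r.flagged:
            counts["flagged"] += 1
        elif r.percent_error > max_percent_error:
            counts["percent_error"] += 1
        elif hq_len < min_hq_len:
            counts["short_hq"] += 1
        else:
            counts["kept"] += 1
            kept.append(
                ReadRecord(
                    id=r.id,
                    sequence=r.sequence[r.hq_start:r.hq_end],
                    percent_error=r.percent_error,
                )
            )
    return kept, counts


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


class GenomeIndex:
    """Sorted exact k-mer index over the policy-applied assembly.

    Chromosomes are concatenated with an invalid sentinel between them;
    positions where the policy forbids alignment (N-masked repeats, assembly
    gaps, ambiguous bases) are invalid and neither seed nor extend.
    """

    def __init__(self, mg: MaskedGenome, seed_len: int = 32):
        if not 1 <= seed_len <= 32:
            raise ValueError("seed_len must be in [1, 32]")
        self.seed_len = seed_len
        self.chroms = mg.chroms
        codes = []
        offsets = [0]
        for chrom in self.chroms:
            c = _encode(mg.sequences[chrom])
            if mg.mask_char_policy == "N":
                c[mg.mask_bool(chrom)] = 255
            codes.append(c)
            codes.append(np.array([255], dtype=np.uint8))  # sentinel
            offsets.append(offsets[-1] + len(c) + 1)
        self.code = np.concatenate(codes)
        self.offsets = np.array(offsets[:-1], dtype=np.int64)
        self.sizes = np.array([mg.chrom_size(c) for c in self.chroms], dtype=np.int64)
        kmers, pos = self._build_kmers(self.code, seed_len)
        order = np.argsort(kmers, kind="stable")
        self.sorted_kmers = kmers[order]
        self.sorted_pos = pos[order]

    @staticmethod
    def _build_kmers(code: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
        n = len(code)
        if n < k:
            return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
        m = n - k + 1
        kmers = np.zeros(m, dtype=np.uint64)
        invalid = (code >= 4).astype(np.int32)
        inv_cum = np.concatenate(([0], np.cumsum(invalid)))
        ok = (inv_cum[k:] - inv_cum[:-k]) == 0
        safe = np.where(code < 4, code, 0).astype(np.uint64)
        for j in range(k):
            kmers = (kmers << np.uint64(2)) | safe[j:m + j]
        pos = np.flatnonzero(ok)
        return kmers[ok], pos

    def kmer_codes(self, code: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """All valid k-mer codes of an encoded query and their offsets."""
        kmers, pos = self._build_kmers(code, self.seed_len)
        return kmers, pos

    def lookup(self, kmer: np.uint64) -> np.ndarray:
        lo = np.searchsorted(self.sorted_kmers, kmer, side="left")
        hi = np.searchsorted(self.sorted_kmers, kmer, side="right")
        return self.sorted_pos[lo:hi]

    def to_chrom(self, gstart: int, gend: int) -> tuple[str, int, int]:
        ci = int(np.searchsorted(self.offsets, gstart, side="right") - 1)
        off = int(self.offsets[ci])
        return self.chroms[ci], gstart - off, gend - off


def _xdrop_extend(
    vals: np.ndarray, eq: np.ndarray, anchor: int, anchor_end: int, xdrop: float
) -> tuple[int, int, int]:
    """Extend ungapped from a seeded anchor in both directions.

    ``vals`` holds per-position scores (+1 match, -penalty mismatch, large
    negative at unalignable bases). Returns (start, end, n_matches) in query
    coordinates (half-open).
    """
    # rightward from anchor_end
    right = vals[anchor_end:]
    if len(right):
        cs = np.cumsum(right)
        drop = np.maximum.accumulate(cs) - cs
        bad = (drop > xdrop) | (right < -1e8)
        stop = int(np.argmax(bad)) if bad.any() else len(right)
        end = anchor_end + (int(np.argmax(cs[:stop])) + 1 if stop else 0)
        if stop and cs[:stop].max() <= 0:
            end = anchor_end
    else:
        end = anchor_end
    # leftward from anchor
    left = vals[:anchor][::-1]
    if len(left):
        cs = np.cumsum(left)
        drop = np.maximum.accumulate(cs) - cs
        bad = (drop > xdrop) | (left < -1e8)
        stop = int(np.argmax(bad)) if bad.any() else len(left)
        start = anchor - (int(np.argmax(cs[:stop])) + 1 if stop else 0)
        if stop and cs[:stop].max() <= 0:
            start = anchor
    else:
        start = anchor
    return start, end, int(eq[start:end].sum())


def map_reads_naive(
    reads: list[ReadRecord],
    mg: MaskedGenome,
    seed_len: int = 32,
    min_len: int = 301,
    min_identity: float = 93.0,
    stride: int = 16,
    xdrop: float = 20.0,
    mismatch_penalty: float = 3.0,
    max_seed_hits: int = 500,
    index: GenomeIndex | None = None,
) -> pd.DataFrame:
    """Map reads with exact-seed + ungapped X-drop extension.

    All qualifying matches are reported (multi-mapping kept); extension never
    crosses N characters, so N-masking truncates matches. Reads shorter than
    ``seed_len`` yield no matches.
    """
    idx = index if index is not None else GenomeIndex(mg, seed_len=seed_len)
    G = idx.code
    gn = len(G)
    rows = []
    for read in reads:
        fwd = _encode(read.sequence)
        if len(fwd) < idx.seed_len:
            continue
        rc = _COMP[np.where(fwd < 4, fwd, 0)][::-1]
        rc[fwd[::-1] >= 4] = 255
        for strand, rcode in (("+", fwd), ("-", rc)):
            kmers, kpos = idx.kmer_codes(rcode)
            if len(kmers) == 0:
                continue
            take = np.arange(0, len(kmers), stride)
            if take[-1] != len(kmers) - 1:
                take = np.append(take, len(kmers) - 1)
            seen_diag: dict[int, int] = {}
            sel_kmers = kmers[take]
            sel_offs = kpos[take]
            for km, off in zip(sel_kmers, sel_offs):
                hits = idx.lookup(km)
                if len(hits) > max_seed_hits:
                    continue
                for g in hits:
                    d = int(g) - int(off)
                    if d not in seen_diag:
                        seen_diag[d] = int(off)
            L = len(rcode)
            reported = set()
            for diag, anchor_off in seen_diag.items():
                rs = max(0, -diag)
                re_ = min(L, gn - diag)
                if re_ - rs < min_len:
                    continue
                gseg = G[diag + rs:diag + re_]
                rseg = rcode[rs:re_]
                valid = (gseg < 4) & (rseg < 4)
                eq = (gseg == rseg) & valid
                vals = np.where(valid, np.where(eq, 1.0, -mismatch_penalty), -1e9)
                a0 = anchor_off - rs
                a1 = min(a0 + idx.seed_len, re_ - rs)
                s, e, nm = _xdrop_extend(vals, eq, a0, a1, xdrop)
                length = e - s
                if length < min_len:
                    continue
                identity = 100.0 * nm / length
                if identity < min_identity:
                    continue
                gstart = diag + rs + s
                gend = diag + rs + e
                chrom, cs_, ce_ = idx.to_chrom(gstart, gend)
                key = (chrom, cs_, ce_)
                if key in reported:
                    continue
                reported.add(key)
                rows.append((read.id, chrom, cs_, ce_, length, identity, strand))
    df = pd.DataFrame(rows, columns=MATCH_COLUMNS)
    if len(df):
        df = df.sort_values(["chrom", "start", "end", "read_id"], ignore_index=True)
    return df


def compute_masked_overlap(matches: pd.DataFrame, mg: MaskedGenome) -> pd.DataFrame:
    """Add a ``masked_overlap`` column: bp of each match inside the mask track."""
    matches = matches.reset_index(drop=True).copy()
    overlap = np.zeros(len(matches), dtype=np.int64)
    for chrom, grp in matches.groupby("chrom", sort=False):
        cum = np.concatenate(
            ([0], np.cumsum(mg.mask_bool(chrom).astype(np.int64)))
        )
        overlap[grp.index] = cum[grp["end"].to_numpy()] - cum[grp["start"].to_numpy()]
    matches["masked_overlap"] = overlap
    return matches


def filter_matches(
    matches: pd.DataFrame,
    mg: MaskedGenome,
    min_len: int = 301,
    max_masked_overlap: int = 200,
) -> pd.DataFrame:
    """Apply the alignment length and masked-overlap filters.

    Matches shorter than ``min_len`` bp on the genome are removed. Under a
    lowercase policy, matches with ``masked_overlap >= max_masked_overlap``
    are also removed; under the N policy alignments cannot enter masked
    sequence, so that filter is inapplicable and skipped. Idempotent.
    """
    out = matches[matches["length"] >= min_len]
    if mg.mask_char_policy == "lowercase":
        if "masked_overlap" not in out.columns:
            out = compute_masked_overlap(out, mg)
        out = out[out["masked_overlap"] < max_masked_overlap]
    return out.reset_index(drop=True)


def match_midpoints(matches: pd.DataFrame) -> np.ndarray:
    """Middle nucleotide of each match: start + floor((end-start-1)/2).

    Even-length matches take the left-of-center base (fixed convention).
    """
    start = matches["start"].to_numpy()
    end = matches["end"].to_numpy()
    return start + (end - start - 1) // 2


def count_depth(
    matches: pd.DataFrame,
    w1: pd.DataFrame,
    w5: pd.DataFrame,
    mg: MaskedGenome,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill per-window depth from match midpoints.

    Each match increments the unique 1-kub window whose span contains its
    middle nucleotide; midpoints in gaps or discarded regions are dropped.
    A 5-kub window's depth is the sum over its members.
    """
    w1 = w1.copy()
    w5 = w5.copy()
    w1["depth1"] = 0
    known = set(w1["chrom"].unique()) | set(mg.chroms)
    unknown = set(matches["chrom"].unique()) - known
    if unknown:
        log.warning("dropping matches on unknown chromosomes: %s", sorted(unknown))
        matches = matches[~matches["chrom"].isin(unknown)]
    matches = matches.reset_index(drop=True)
    mid = match_midpoints(matches)
    depth1 = np.zeros(len(w1), dtype=np.int64)
    for chrom, grp in matches.groupby("chrom", sort=False):
        rows = w1.index[w1["chrom"] == chrom]
        if len(rows) == 0:
            continue
        sub = w1.loc[rows]
        size = mg.chrom_size(chrom)
        lut = np.full(size, -1, dtype=np.int64)
        for r, s, e in zip(rows, sub["start"], sub["end"]):
            lut[s:e] = r
        mids = mid[grp.index.to_numpy()]
        mids = mids[(mids >= 0) & (mids < size)]
        tgt = lut[mids]
        tgt = tgt[tgt >= 0]
        if len(tgt):
            np.add.at(depth1, tgt, 1)
    w1["depth1"] = depth1
    # 5-kub depth: sum of member depth1 via per-chromosome cumulative sums
    k = w5.attrs.get("k", 5)
    depth5 = np.zeros(len(w5), dtype=np.int64)
    for chrom, grp in w5.groupby("chrom", sort=False):
        sub1 = w1[w1["chrom"] == chrom]
        d1 = sub1.set_index("index")["depth1"]
        arr = np.zeros(int(d1.index.max()) + 1, dtype=np.int64)
        arr[d1.index.to_numpy()] = d1.to_numpy()
        cum = np.concatenate(([0], np.cumsum(arr)))
        first = grp["first"].to_numpy()
        depth5[grp.index] = cum[first + k] - cum[first]
    w5["depth"] = depth5
    return w1, w5
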