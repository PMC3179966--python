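"""Read QC, naive mapping, match filtering and midpoint depth counting."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_masked_genome
from wssd import intervals as ivl
from wssd.depth import (
    ReadRecord,
    clip_reads,
    count_depth,
    filter_matches,
    map_reads_naive,
    match_midpoints,
)
from wssd.io import read_blast_tabular
from wssd.masking import RepeatAnnotation, apply_masking
from wssd.windowing import build_1kub_windows, build_5kub_windows


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


# ---------------------------------------------------------------- read QC

def test_clip_rules():
    reads = [
        ReadRecord("high_err", "A" * 400, percent_error=7.0),
        ReadRecord("short_hq", "A" * 400, hq_start=0, hq_end=250),
        ReadRecord("flagged", "A" * 400, flagged=True),
        ReadRecord("good", "A" * 735, percent_error=2.0),
        ReadRecord("clipme", "C" * 100 + "A" * 400 + "C" * 50, hq_start=100, hq_end=500),
    ]
    kept, counts = clip_reads(reads)
    assert counts == {"flagged": 1, "percent_error": 1, "short_hq": 1, "kept": 2}
    assert [r.id for r in kept] == ["good", "clipme"]
    assert len(kept[0].sequence) == 735
    assert kept[1].sequence == "A" * 400  # truncated to the hq interval


# ------------------------------------------------------------ naive mapper

def test_unique_read_maps_once_at_full_identity():
    rng = np.random.default_rng(0)
    genome = {"chr1": _random_seq(rng, 5000)}
    mg = apply_masking(genome, [], "nodiv_N")
    read = ReadRecord("r1", genome["chr1"][1000:1500])
    m = map_reads_naive([read], mg)
    assert len(m) == 1
    assert m.loc[0, ["chrom", "start", "end"]].tolist() == ["chr1", 1000, 1500]
    assert m.loc[0, "identity"] == 100.0


def test_reverse_complement_read_maps_to_forward_coordinates():
    rng = np.random.default_rng(1)
    genome = {"chr1": _random_seq(rng, 4000)}
    mg = apply_masking(genome, [], "nodiv_N")
    seg = genome["chr1"][500:1100]
    rc = seg.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    m = map_reads_naive([ReadRecord("r1", rc)], mg)
    assert len(m) == 1
    assert m.loc[0, ["start", "end", "strand"]].tolist() == [500, 1100, "-"]


def test_two_copy_read_maps_twice():
    rng = np.random.default_rng(2)
    seg = _random_seq(rng, 2000)
    # second copy at 99% identity
    arr = np.frombuffer(seg.encode(), dtype=np.uint8).copy()
    hit = rng.choice(2000, size=20, replace=False)
    lut = {65: "C", 67: "G", 71: "T", 84: "A"}
    copy = "".join(lut[arr[i]] if i in set(hit) else chr(arr[i]) for i in range(2000))
    genome = {"chr1": _random_seq(rng, 1000) + seg + _random_seq(rng, 1000) + copy
              + _random_seq(rng, 500)}
    mg = apply_masking(genome, [], "nodiv_N")
    read = ReadRecord("r1", seg[500:1100])
    m = map_reads_naive([read], mg)
    assert len(m) == 2
    assert (m["identity"] >= 97.0).all()
    assert m["identity"].max() == 100.0


def test_heavily_mutated_read_finds_no_match():
    rng = np.random.default_rng(3)
    genome = {"chr1": _random_seq(rng, 6000)}
    mg = apply_masking(genome, [], "nodiv_N")
    src = np.frombuffer(genome["chr1"][2000:2700].encode(), dtype=np.uint8).copy()
    hit = rng.random(700) < 0.10  # expected identity ~90% < the 93% cutoff
    subs = rng.integers(1, 4, size=700)
    code = np.zeros(700, dtype=np.uint8)
    for j, b in enumerate(b"ACGT"):
        code[src == b] = j
    code[hit] = (code[hit] + subs[hit]) % 4
    read = ReadRecord("r1", np.frombuffer(b"ACGT", dtype=np.uint8)[code].tobytes().decode())
    m = map_reads_naive([read], mg)
    assert len(m) == 0


def test_n_masking_truncates_matches():
    """With the N policy a match cannot extend through a masked repeat."""
    rng = np.random.default_rng(4)
    genome = {"chr1": _random_seq(rng, 3000)}
    rep = [RepeatAnnotation("chr1", 1400, 1600, "interspersed", "r", 5.0)]
    mg_n = apply_masking(genome, rep, "nodiv_N")
    mg_low = apply_masking(genome, rep, "nodiv_low")
    read = ReadRecord("r1", genome["chr1"][1000:2000])
    m_n = map_reads_naive([read], mg_n)
    m_low = map_reads_naive([read], mg_low)
    # lowercase masking: one full-length match through the repeat
    assert len(m_low) == 1 and m_low.loc[0, "length"] == 1000
    # N masking: the repeat splits the alignment into two flanking matches
    assert (m_n["length"] <= 600).all()
    assert len(ivl.intersect(m_n[["start", "end"]].to_numpy(), [[1400, 1600]])) == 0


def test_short_read_yields_nothing():
    mg = apply_masking({"c": "ACGTACGTACGTACGT" * 10}, [], "nodiv_N")
    assert len(map_reads_naive([ReadRecord("r", "ACGTACG")], mg)) == 0


# ---------------------------------------------------------------- filters

def _matches(rows):
    return pd.DataFrame(
        rows, columns=["read_id", "chrom", "start", "end", "length", "identity", "strand"]
    )


def test_filter_length_and_masked_overlap():
    seq = {"c": "A" * 1000}
    rep = [RepeatAnnotation("c", 0, 500, "interspersed", "r", 5.0)]
    mg_low = apply_masking(seq, rep, "nodiv_low")
    mg_n = apply_masking(seq, rep, "nodiv_N")
    m = _matches([
        ("a", "c", 600, 900, 300, 100.0, "+"),   # length 300: removed
        ("b", "c", 300, 700, 400, 100.0, "+"),   # masked overlap 200
        ("d", "c", 450, 850, 400, 100.0, "+"),   # masked overlap 50
    ])
    out_low = filter_matches(m, mg_low)
    assert out_low["read_id"].tolist() == ["d"]
    # N policy: the masked-overlap filter is inapplicable
    out_n = filter_matches(m, mg_n)
    assert out_n["read_id"].tolist() == ["b", "d"]
    # idempotence
    pd.testing.assert_frame_equal(filter_matches(out_low, mg_low), out_low)


def test_blast_tabular_reader_normalises_strand(tmp_path):
    path = tmp_path / "hits.tsv"
    path.write_text(
        "r1\tchr1\t98.5\t400\t6\t0\t1\t400\t1001\t1400\t1e-50\t500\n"
        "r2\tchr1\t97.0\t350\t10\t0\t1\t350\t2350\t2001\t1e-40\t400\n"
    )
    df = read_blast_tabular(path)
    assert df.loc[0, ["start", "end", "strand"]].tolist() == [1000, 1400, "+"]
    assert df.loc[1, ["start", "end", "strand"]].tolist() == [2000, 2350, "-"]
    assert (df["length"] == df["end"] - df["start"]).all()


# ------------------------------------------------------------ depth counts

def test_midpoint_convention():
    m = _matches([
        ("a", "c", 0, 4, 4, 100.0, "+"),    # even length: left of centre
        ("b", "c", 0, 5, 5, 100.0, "+"),
        ("d", "c", 10, 11, 1, 100.0, "+"),
    ])
    assert match_midpoints(m).tolist() == [1, 2, 10]


def test_count_depth_midpoint_assignment():
    masked = np.zeros(50, dtype=bool)
    gap = np.zeros(50, dtype=bool)
    mg = make_masked_genome(masked, gap)
    w1 = build_1kub_windows(mg, unit=10)
    w5 = build_5kub_windows(w1, k=2)
    m = _matches([
        ("a", "chr1", 0, 30, 30, 100.0, "+"),    # midpoint 14 -> window 1
        ("b", "chr1", 12, 16, 4, 100.0, "+"),    # midpoint 13 -> window 1
        ("d", "chr1", 45, 49, 4, 100.0, "+"),    # midpoint 46 -> window 4
        ("e", "other", 0, 20, 20, 100.0, "+"),   # unknown chromosome: dropped
    ])
    w1f, w5f = count_depth(m, w1, w5, mg)
    assert w1f["depth1"].tolist() == [0, 2, 0, 0, 1]
    # sliding window depth = sum of members
    assert w5f["depth"].tolist() == [2, 2, 0, 1]
    assert w1f["depth1"].sum() <= len(m)


def test_uniform_matches_conserve_total_depth():
    masked = np.zeros(200, dtype=bool)
    gap = np.zeros(200, dtype=bool)
    mg = make_masked_genome(masked, gap)
    w1 = build_1kub_windows(mg, unit=100)
    w5 = build_5kub_windows(w1, k=1)
    rows = [("r%d" % i, "chr1", i, i + 10, 10, 100.0, "+") for i in range(0, 190, 2)]
    w1f, _ = count_depth(_matches(rows), w1, w5, mg)
    assert w1f["depth1"].sum() == len(rows)
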