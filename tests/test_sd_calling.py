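"""Window classification, 6-of-7 calling vs a brute-force oracle, summaries."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_masked_genome
from wssd.calibration import Thresholds
from wssd.sd_calling import (
    call_intervals,
    chromosome_class,
    classify_windows,
    interval_size_distribution,
    summarize_genome,
    window_class_distribution,
)

THR = Thresholds(borderline_cut=95.2, positive_cut=103.2)  # avg 79.2, sd 8


def w5_from_depths(depths, chrom="chr1", run=0, start0=0, unit=1000, k=5):
    n = len(depths)
    starts = start0 + np.arange(n) * unit
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + k * unit,
            "first": np.arange(n),
            "run": run,
            "masked_pct": 0.0,
            "depth": depths,
        }
    )


def w5_from_labels(labels, **kw):
    depth = {"N": 79.2, "B": 100.0, "P": 150.0}
    return classify_windows(w5_from_depths([depth[c] for c in labels], **kw), THR)


# ------------------------------------------------------------- classification

@pytest.mark.parametrize(
    "depth,label",
    [(79.2, "negative"), (95.2, "negative"), (99.2, "borderline"),
     (103.19, "borderline"), (103.2, "positive"), (150.0, "positive")],
)
def test_classification_boundaries(depth, label):
    w5 = classify_windows(w5_from_depths([depth]), THR)
    assert w5.loc[0, "label"] == label


def test_boundary_convention_switch():
    w5 = classify_windows(w5_from_depths([103.2]), THR, positive_inclusive=False)
    assert w5.loc[0, "label"] == "borderline"


def test_unset_thresholds_error():
    with pytest.raises(ValueError):
        classify_windows(w5_from_depths([80.0]), None)


# ---------------------------------------------------------------- 6-of-7 rule

def oracle_call(labels, m=6, n=7):
    """Enumerate every window-of-n; mark qualifying members; cluster."""
    L = len(labels)
    marked = [False] * L
    for i in range(L - n + 1):
        if sum(labels[j] == "P" for j in range(i, i + n)) >= m:
            for j in range(i, i + n):
                marked[j] = True
    clusters = []
    i = 0
    while i < L:
        if marked[i]:
            j = i
            while j + 1 < L and marked[j + 1]:
                j += 1
            clusters.append((i, j))
            i = j + 1
        else:
            i += 1
    return clusters


@pytest.mark.parametrize(
    "labels,n_intervals",
    [("PPPPPPP", 1), ("PPPNPPP", 1), ("PPNNPPP", 0), ("PPPPPP", 0),
     ("NNNNNNN", 0), ("PPPBPPP", 1)],
)
def test_call_examples(labels, n_intervals):
    out = call_intervals(w5_from_labels(labels))
    assert len(out) == n_intervals
    if n_intervals == 1:
        # all 7 windows marked: span covers first start to last end
        assert out.loc[0, "start"] == 0
        assert out.loc[0, "end"] == (len(labels) - 1 + 5) * 1000
        assert out.loc[0, "n_windows5"] == len(labels)


def test_call_equals_bruteforce_oracle_on_random_labels():
    rng = np.random.default_rng(7)
    for _ in range(300):
        L = int(rng.integers(1, 200))
        labels = "".join(rng.choice(["N", "B", "P"], p=[0.55, 0.1, 0.35], size=L))
        got = call_intervals(w5_from_labels(labels))
        want = oracle_call(labels)
        assert len(got) == len(want)
        for row, (i, j) in zip(got.itertuples(), want):
            assert row.start == i * 1000
            assert row.end == (j + 5) * 1000
            assert row.n_windows5 == j - i + 1


def test_adding_a_positive_never_removes_an_interval():
    rng = np.random.default_rng(13)
    for _ in range(50):
        L = int(rng.integers(10, 80))
        labels = list(rng.choice(["N", "P"], p=[0.5, 0.5], size=L))
        base = call_intervals(w5_from_labels("".join(labels)))
        flip = int(rng.integers(L))
        labels[flip] = "P"
        more = call_intervals(w5_from_labels("".join(labels)))
        base_marked = set()
        for row in base.itertuples():
            base_marked.update(range(row.start, row.end))
        more_marked = set()
        for row in more.itertuples():
            more_marked.update(range(row.start, row.end))
        assert base_marked <= more_marked


def test_raising_positive_cut_never_increases_called_bases():
    rng = np.random.default_rng(29)
    depths = rng.normal(85, 15, size=120).clip(0)
    depths[30:45] += 60
    w5 = w5_from_depths(depths)
    lo = call_intervals(classify_windows(w5, Thresholds(95.0, 105.0)))
    hi = call_intervals(classify_windows(w5, Thresholds(95.0, 120.0)))
    total = lambda df: (df["end"] - df["start"]).sum() if len(df) else 0
    assert total(hi) <= total(lo)


def test_runs_are_not_joined_across_gaps():
    a = w5_from_labels("PPPPPPP", run=0, start0=0)
    b = w5_from_labels("PPPPPPP", run=1, start0=50_000)
    out = call_intervals(pd.concat([a, b], ignore_index=True))
    assert len(out) == 2


# ------------------------------------------------------------------ summaries

def test_chromosome_classes():
    assert chromosome_class("chr7") == "nonrandom"
    assert chromosome_class("chr7_random") == "random"
    assert chromosome_class("chrUn") == "unknown"


def test_summarize_genome_totals_and_union():
    mg = make_masked_genome(np.zeros(100_000, bool), np.zeros(100_000, bool))
    intervals = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1"],
            "start": [10_000, 30_000],
            "end": [30_000, 40_000],  # abutting: union counted once
            "n_windows5": [10, 5],
            "mean_coverage": [150.0, 140.0],
        }
    )
    out = summarize_genome(intervals, mg)
    row = out[out["chr"] == "chr1"].iloc[0]
    assert row["dup_size"] == 30_000
    assert row["perc_dup"] == pytest.approx(30.0)
    whole = out[out["chr"] == "Tot_whole"].iloc[0]
    assert whole["dup_size"] == 30_000
    assert whole["n_intervals"] == 2
    with pytest.raises(ValueError):
        summarize_genome(intervals.assign(chrom="nope"), mg)


def test_table_fraction_arithmetic_on_published_totals():
    """The percent-duplicated formula on a whole-genome total."""
    from wssd.reports import duplicated_fraction_percent

    assert duplicated_fraction_percent(84_947_589, 486_198_630) == 17.47


def test_window_class_distribution_shares():
    w5 = w5_from_labels("N" * 75 + "P" * 25)
    dist = window_class_distribution(w5)
    overall = dist[dist["subset"] == "all"].iloc[0]
    assert overall["positive"] == pytest.approx(25.0)
    assert overall["negative"] + overall["borderline"] + overall["positive"] == \
        pytest.approx(100.0)
    all_neg = window_class_distribution(w5_from_labels("N" * 40))
    assert all_neg.loc[0, ["negative", "borderline", "positive"]].tolist() == \
        [100.0, 0.0, 0.0]


def test_interval_size_distribution():
    iv = pd.DataFrame(
        {"chrom": "c", "start": [0, 100_000, 200_000],
         "end": [20_000, 120_000, 230_000], "n_windows5": 1, "mean_coverage": 1.0}
    )
    out = interval_size_distribution(iv)
    assert out["mode"] == pytest.approx(22_500)  # densest 5-kb bin is [20, 25) kb
    assert out["max"] == 30_000
    single = interval_size_distribution(iv.iloc[:1])
    assert single["max"] == 20_000
    empty = interval_size_distribution(iv.iloc[:0])
    assert empty["mode"] is None
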