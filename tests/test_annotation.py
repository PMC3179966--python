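"""Gene overlay, domain enrichment, organelle-DNA content, composition."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_masked_genome
from wssd.annotation import (
    classify_genes,
    enrichment_factor,
    gene_density_table,
    interval_composition,
    numt_content,
    retain_domain_assignments,
    top_duplicated_genes,
)


def _intervals(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_windows5", "mean_coverage"]
    )


def _genes(rows):
    return pd.DataFrame(rows, columns=["id", "chrom", "start", "end"])


def test_gene_status_partition():
    intervals = _intervals([("chr1", 0, 100, 5, 150.0)])
    genes = _genes([
        ("inside", "chr1", 10, 20),
        ("crossing", "chr1", 90, 150),
        ("outside", "chr1", 200, 260),
        ("elsewhere", "chr2", 0, 50),
    ])
    out = classify_genes(genes, intervals)
    by = dict(zip(out["id"], out["duplication_status"]))
    assert by == {"inside": "full", "crossing": "partial",
                  "outside": "unique", "elsewhere": "unique"}
    counts = out["duplication_status"].value_counts()
    assert counts.sum() == len(genes)


def test_gene_spanning_two_abutting_intervals_is_full():
    intervals = _intervals([("chr1", 0, 100, 5, 150.0), ("chr1", 100, 200, 5, 120.0)])
    out = classify_genes(_genes([("g", "chr1", 50, 150)]), intervals)
    assert out.loc[0, "duplication_status"] == "full"


def test_gene_density_definition():
    mg = make_masked_genome(np.zeros(100_000, bool), np.zeros(100_000, bool))
    genes = _genes([(f"g{i}", "chr1", i * 1000, i * 1000 + 500) for i in range(5)])
    tbl = gene_density_table(genes, _intervals([]), mg)
    row = tbl[tbl["chr"] == "chr1"].iloc[0]
    assert row["chr_gene_density"] == pytest.approx(5.0)  # 5 genes / 100 kb


def test_density_ratio_uses_duplicated_bp():
    mg = make_masked_genome(np.zeros(200_000, bool), np.zeros(200_000, bool))
    intervals = _intervals([("chr1", 0, 50_000, 10, 160.0)])
    genes = _genes(
        [(f"g{i}", "chr1", 1000 * i, 1000 * i + 400) for i in range(10)]  # all in dup
        + [(f"u{i}", "chr1", 100_000 + 2000 * i, 100_000 + 2000 * i + 400)
           for i in range(10)]
    )
    tbl = gene_density_table(genes, intervals, mg)
    row = tbl[tbl["chr"] == "chr1"].iloc[0]
    assert row["total_genes"] == 20
    assert row["full_dup_genes"] == 10
    assert row["chr_gene_density"] == pytest.approx(10.0)
    assert row["full_dup_gene_density"] == pytest.approx(20.0)
    assert row["ratio_of_densities"] == pytest.approx(2.0)


def test_enrichment_factor_examples():
    ef, dup_only = enrichment_factor(
        {"IPR1": 2, "IPR2": 2}, {"IPR1": 1, "IPR2": 1}
    )
    assert ef["IPR1"] == pytest.approx(1.0)
    ef, dup_only = enrichment_factor(
        {"IPR1": 10, "rest": 90}, {"IPR1": 4, "rest": 196}
    )
    assert ef["IPR1"] == pytest.approx(5.0)
    ef, dup_only = enrichment_factor({"IPRx": 3, "IPR1": 1}, {"IPR1": 5})
    assert dup_only == ["IPRx"]
    assert "IPRx" not in ef
    with pytest.raises(ValueError):
        enrichment_factor({}, {"IPR1": 1})


def test_enrichment_factor_scale_invariance():
    a = {"IPR1": 10, "IPR2": 30, "IPR3": 60}
    b = {"IPR1": 5, "IPR2": 45, "IPR3": 50}
    ef1, _ = enrichment_factor(a, b)
    ef2, _ = enrichment_factor({k: 7 * v for k, v in a.items()}, b)
    for k in ef1:
        assert ef1[k] == pytest.approx(ef2[k])


def test_retain_domain_assignments_rules():
    df = pd.DataFrame(
        {
            "protein_id": ["p1", "p1", "p2", "p3"],
            "source_db": ["Pfam"] * 4,
            "signature": ["s1", "s2", "s3", "s4"],
            "status": ["T", "F", "T", "T"],
            "interpro_id": ["IPR1", "IPR2", "NULL", "IPR3"],
        }
    )
    kept = retain_domain_assignments(df)
    assert kept["interpro_id"].tolist() == ["IPR1", "IPR3"]


def _hits(rows):
    return pd.DataFrame(rows, columns=["organelle", "chrom", "start", "end", "evalue"])


def test_numt_union_and_intersection():
    mg = make_masked_genome(np.zeros(100_000, bool), np.zeros(100_000, bool))
    hits = _hits([
        ("mito", "chr1", 0, 100, 1e-10),
        ("mito", "chr1", 50, 150, 1e-10),     # union with previous: 150 bp
        ("plastid", "chr1", 80, 120, 1e-10),
        ("mito", "chr1", 500, 600, 1e-3),     # above the e-value cutoff
    ])
    intervals = _intervals([("chr1", 100, 200, 5, 150.0)])
    tbl = numt_content(hits, intervals, mg)
    row = tbl[tbl["chr"] == "chr1"].iloc[0]
    assert row["numt_bp"] == 150
    assert row["numt_sd_bp"] == 50
    assert row["nupt_bp"] == 40
    assert row["nupt_sd_bp"] == 20
    whole = tbl[tbl["chr"] == "Tot_whole"].iloc[0]
    assert whole["numt_bp"] == 150
    assert whole["numt_pct"] == pytest.approx(100.0 * 150 / 100_000)
    # per-duplication percentage uses duplicated bp as denominator
    assert row["nupt_sd_pct"] == pytest.approx(100.0 * 20 / 100)


def test_numt_matches_per_base_marking_on_random_fixtures():
    rng = np.random.default_rng(77)
    mg = make_masked_genome(np.zeros(10_000, bool), np.zeros(10_000, bool))
    for _ in range(25):
        rows = []
        for _ in range(int(rng.integers(0, 20))):
            s = int(rng.integers(0, 9_900))
            e = min(s + int(rng.integers(1, 300)), 10_000)
            rows.append(("mito", "chr1", s, e, 1e-9))
        sd_s = int(rng.integers(0, 8000))
        intervals = _intervals([("chr1", sd_s, sd_s + 1500, 3, 130.0)])
        tbl = numt_content(_hits(rows), intervals, mg)
        row = tbl[tbl["chr"] == "chr1"].iloc[0]
        base = np.zeros(10_000, bool)
        for _, _, s, e, _ in rows:
            base[s:min(e, 10_000)] = True
        assert row["numt_bp"] == int(base.sum())
        assert row["numt_sd_bp"] == int(base[sd_s:sd_s + 1500].sum())


def test_top_genes_ranking_and_ties():
    intervals = _intervals([
        ("chr1", 0, 10_000, 5, 300.0),
        ("chr1", 50_000, 60_000, 5, 200.0),
        ("chr2", 0, 10_000, 5, 100.0),
    ])
    genes = _genes([
        ("low", "chr2", 100, 600),
        ("mid", "chr1", 51_000, 51_500),
        ("hi_b", "chr1", 5_000, 5_400),
        ("hi_a", "chr1", 1_000, 1_400),
        ("not_dup", "chr1", 20_000, 21_000),
    ])
    top = top_duplicated_genes(genes, intervals, n=2)
    assert top["id"].tolist() == ["hi_a", "hi_b"]  # same score, coordinate order
    top3 = top_duplicated_genes(genes, intervals, n=3,
                                organelle_homolog_ids={"mid"})
    assert top3["id"].tolist() == ["hi_a", "hi_b", "mid"]
    assert top3["organelle_homolog"].tolist() == [False, False, True]
    # fewer eligible genes than requested: all returned
    assert len(top_duplicated_genes(genes, intervals, n=100)) == 4


def test_interval_composition_gc():
    mg = make_masked_genome(np.zeros(1000, bool), np.zeros(1000, bool))
    mg.sequences["chr1"] = "G" * 500 + "A" * 500
    comp = interval_composition(_intervals([("chr1", 0, 400, 2, 120.0)]), mg)
    gc = comp[comp["metric"] == "GC_percent"].iloc[0]
    assert gc["in_duplications"] == pytest.approx(100.0)
    assert gc["whole_genome"] == pytest.approx(50.0)
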