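"""End-to-end orchestration: masking -> windows -> depth -> fit -> calling
-> annotation, as an in-memory run or a configured, resumable file-based run.

Every number in the emitted summary tables is recomputable from the stage
outputs; nothing is computed only in the report layer. Filter tallies
(reads discarded per QC rule, matches removed per alignment filter) are
logged and written to a machine-readable JSON so the run's bookkeeping can
be reproduced on any input.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation, calibration, depth, io as wio, masking, sd_calling, windowing
from .depth import ReadRecord

__all__ = ["RunConfig", "RunResult", "run_wssd", "run_all", "compare_masking_settings"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a file-based run; defaults reproduce the method's
    standard parameters (1 kub unit, 5-window aggregation, 6-of-7 rule,
    N-policy masking without a divergence threshold)."""

    genome_fasta: str
    repeats: str  # RepeatMasker .out or repeats BED
    reads_fasta: str
    calibration_bed: str
    output_dir: str
    reads_qc: str | None = None
    genes_gff3: str | None = None
    organelle_hits: str | None = None
    alignments: str | None = None  # BLAST outfmt-6; built-in mapper if absent
    setting: str = "nodiv_N"
    unit: int = 1000
    k: int = 5
    min_match_len: int = 301
    min_identity: float = 93.0
    max_masked_overlap: int = 200
    m_of_n: tuple[int, int] = (6, 7)
    positive_inclusive: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "m_of_n" in data:
            data["m_of_n"] = tuple(data["m_of_n"])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.setting not in masking.SETTINGS:
            raise ValueError(
                f"unknown masking setting {self.setting!r}; expected {masking.SETTINGS}"
            )
        for name in ("genome_fasta", "repeats", "reads_fasta", "calibration_bed"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")


@dataclass
class RunResult:
    """All stage outputs of one in-memory run."""

    masked_genome: masking.MaskedGenome
    w1: pd.DataFrame
    w5: pd.DataFrame
    matches: pd.DataFrame
    model: calibration.MixtureModel
    thresholds: calibration.Thresholds
    intervals: pd.DataFrame
    genome_summary: pd.DataFrame
    class_distribution: pd.DataFrame
    filter_counts: dict = field(default_factory=dict)
    calibration_depths: np.ndarray | None = None


def _calibration_depths(
    w5: pd.DataFrame, regions: dict[str, np.ndarray]
) -> np.ndarray:
    """Depths of sliding windows whose span lies inside a calibration region."""
    out = []
    for chrom, grp in w5.groupby("chrom", sort=False):
        iv = np.asarray(regions.get(chrom, np.empty((0, 2))), dtype=np.int64).reshape(-1, 2)
        if len(iv) == 0:
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        pos = np.searchsorted(iv[:, 0], starts, side="right") - 1
        ok = pos >= 0
        ok[ok] = ends[ok] <= iv[pos[ok], 1]
        out.append(grp["depth"].to_numpy()[ok])
    if not out:
        return np.empty(0)
    return np.concatenate(out)


def run_wssd(
    sequences: dict[str, str],
    repeats: list[masking.RepeatAnnotation],
    reads: list[ReadRecord],
    calibration_regions: dict[str, np.ndarray],
    setting: str = "nodiv_N",
    unit: int = 1000,
    k: int = 5,
    min_match_len: int = 301,
    min_identity: float = 93.0,
    max_masked_overlap: int = 200,
    m_of_n: tuple[int, int] = (6, 7),
    positive_inclusive: bool = True,
    matches: pd.DataFrame | None = None,
    mapper_kwargs: dict | None = None,
) -> RunResult:
    """Run the whole read-depth analysis in memory.

    If ``matches`` (external alignments, e.g. BLAST tabular) is given the
    built-in mapper is skipped.
    """
    counts: dict = {}
    mg = masking.apply_masking(sequences, repeats, setting)
    counts["masked_fraction_pct"] = masking.masked_fraction(mg)
    clipped, qc_counts = depth.clip_reads(reads)
    counts["reads"] = qc_counts
    log.info("QC: %s", qc_counts)
    w1 = windowing.build_1kub_windows(mg, unit=unit)
    w5 = windowing.build_5kub_windows(w1, k=k)
    log.info("windows: %d x %d-unmasked, %d sliding", len(w1), unit, len(w5))
    if matches is None:
        matches = depth.map_reads_naive(
            clipped, mg, min_len=min_match_len, min_identity=min_identity,
            **(mapper_kwargs or {}),
        )
    counts["matches_raw"] = int(len(matches))
    matches = depth.filter_matches(
        matches, mg, min_len=min_match_len, max_masked_overlap=max_masked_overlap
    )
    counts["matches_filtered"] = int(len(matches))
    w1, w5 = depth.count_depth(matches, w1, w5, mg)
    cal = _calibration_depths(w5, calibration_regions)
    counts["calibration_windows"] = int(len(cal))
    model = calibration.fit_mixture(cal)
    thresholds = calibration.thresholds_from(model)
    log.info(
        "fit: avg=%.2f sd=%.2f f=%s cuts=(%.2f, %.2f)",
        model.avg, model.sd, np.round(model.f, 3),
        thresholds.borderline_cut, thresholds.positive_cut,
    )
    w5 = sd_calling.classify_windows(
        w5, thresholds, positive_inclusive=positive_inclusive
    )
    intervals = sd_calling.call_intervals(w5, m_of_n=m_of_n)
    summary = sd_calling.summarize_genome(intervals, mg)
    dist = sd_calling.window_class_distribution(w5)
    return RunResult(
        masked_genome=mg, w1=w1, w5=w5, matches=matches, model=model,
        thresholds=thresholds, intervals=intervals, genome_summary=summary,
        class_distribution=dist, filter_counts=counts, calibration_depths=cal,
    )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_reads(cfg: RunConfig) -> list[ReadRecord]:
    seqs = wio.read_fasta(cfg.reads_fasta)
    qc = None
    if cfg.reads_qc:
        qc = wio.read_qc_sidecar(cfg.reads_qc).set_index("id")
    reads = []
    for rid, seq in seqs.items():
        if qc is not None and rid in qc.index:
            row = qc.loc[rid]
            reads.append(
                ReadRecord(
                    id=rid, sequence=seq,
                    hq_start=int(row["hq_start"]), hq_end=int(row["hq_end"]),
                    percent_error=float(row["percent_error"]),
                    flagged=bool(row["flagged"]),
                )
            )
        else:
            reads.append(ReadRecord(id=rid, sequence=seq))
    return reads


def run_all(cfg: RunConfig, force: bool = False) -> RunResult:
    """File-based pipeline run with manifest and stage skipping.

    Outputs land in ``cfg.output_dir``: masked FASTA, mask/gap BEDs, window
    tables, the fitted-model report and plot, duplication intervals (BED5),
    the per-chromosome summary table, the window-class distribution, gene
    and organelle tables when inputs are provided, and a manifest recording
    parameters, seeds and input checksums. Stages whose outputs are newer
    than all inputs are skipped unless ``force``.
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = [p for p in [cfg.genome_fasta, cfg.repeats, cfg.reads_fasta,
                          cfg.calibration_bed, cfg.reads_qc, cfg.genes_gff3,
                          cfg.organelle_hits, cfg.alignments] if p]
    newest_input = max(Path(p).stat().st_mtime for p in inputs)
    stamp = out / "manifest.json"
    outputs = [
        "masked.fa", "mask.bed", "gaps.bed", "windows_1kub.tsv",
        "windows_5kub.tsv", "model.json", "fit.png", "intervals.bed",
        "genome_summary.tsv", "window_classes.tsv", "filter_counts.json",
    ]
    if not force and stamp.exists() and all((out / o).exists() for o in outputs):
        if stamp.stat().st_mtime >= newest_input:
            log.info("outputs up to date; skipping recompute")
            return _load_result(cfg)

    sequences = wio.read_fasta(cfg.genome_fasta)
    if cfg.repeats.endswith(".out"):
        repeats = wio.read_repeatmasker_out(cfg.repeats)
    else:
        repeats = wio.read_repeats_bed(cfg.repeats)
    reads = _load_reads(cfg)
    regions = wio.read_bed(cfg.calibration_bed)
    ext = wio.read_blast_tabular(cfg.alignments) if cfg.alignments else None
    res = run_wssd(
        sequences, repeats, reads, regions,
        setting=cfg.setting, unit=cfg.unit, k=cfg.k,
        min_match_len=cfg.min_match_len, min_identity=cfg.min_identity,
        max_masked_overlap=cfg.max_masked_overlap, m_of_n=cfg.m_of_n,
        positive_inclusive=cfg.positive_inclusive, matches=ext,
    )
    mg = res.masked_genome
    wio.write_fasta({c: mg.masked_sequence(c) for c in mg.chroms}, out / "masked.fa")
    wio.write_bed(mg.mask, out / "mask.bed")
    wio.write_bed(mg.gaps, out / "gaps.bed")
    windowing.write_windows_bed(res.w1, out / "windows_1kub.tsv")
    windowing.write_windows_bed(res.w5, out / "windows_5kub.tsv")
    with open(out / "model.json", "w") as fh:
        json.dump(
            {
                "avg": res.model.avg, "sd": res.model.sd, "f": list(res.model.f),
                "loglik": res.model.loglik, "n_obs": res.model.n_obs,
                "borderline_cut": res.thresholds.borderline_cut,
                "positive_cut": res.thresholds.positive_cut,
            },
            fh, indent=2,
        )
    if res.calibration_depths is not None and len(res.calibration_depths):
        calibration.plot_fit(res.calibration_depths, res.model, out / "fit.png")
        calibration.pull_table(res.calibration_depths, res.model).to_csv(
            out / "pulls.tsv", sep="\t", index=False
        )
    else:
        (out / "fit.png").touch()
    sd_calling.write_intervals_bed(res.intervals, out / "intervals.bed")
    res.genome_summary.to_csv(out / "genome_summary.tsv", sep="\t", index=False,
                              float_format="%.2f")
    res.class_distribution.to_csv(out / "window_classes.tsv", sep="\t",
                                  index=False, float_format="%.2f")
    with open(out / "filter_counts.json", "w") as fh:
        json.dump(res.filter_counts, fh, indent=2, default=str)
    if cfg.genes_gff3:
        genes = wio.read_gff3_genes(cfg.genes_gff3)
        annotation.gene_density_table(genes, res.intervals, mg).to_csv(
            out / "gene_content.tsv", sep="\t", index=False, float_format="%.2f"
        )
        annotation.top_duplicated_genes(genes, res.intervals).to_csv(
            out / "top_duplicated_genes.tsv", sep="\t", index=False,
            float_format="%.2f",
        )
    if cfg.organelle_hits:
        hits = pd.read_csv(cfg.organelle_hits, sep="\t")
        annotation.numt_content(hits, res.intervals, mg).to_csv(
            out / "organelle_content.tsv", sep="\t", index=False,
            float_format="%.2f",
        )
    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "inputs": {p: _sha256(p) for p in inputs},
        "model": {"avg": res.model.avg, "sd": res.model.sd},
    }
    with open(stamp, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return res


def _load_result(cfg: RunConfig) -> RunResult:
    """Rehydrate a RunResult from a completed output directory."""
    out = Path(cfg.output_dir)
    sequences = wio.read_fasta(cfg.genome_fasta)
    if cfg.repeats.endswith(".out"):
        repeats = wio.read_repeatmasker_out(cfg.repeats)
    else:
        repeats = wio.read_repeats_bed(cfg.repeats)
    mg = masking.apply_masking(sequences, repeats, cfg.setting)
    w1 = pd.read_csv(out / "windows_1kub.tsv", sep="\t")
    w5 = pd.read_csv(out / "windows_5kub.tsv", sep="\t")
    with open(out / "model.json") as fh:
        m = json.load(fh)
    model = calibration.MixtureModel(
        avg=m["avg"], sd=m["sd"], f=tuple(m["f"]), loglik=m["loglik"],
        n_obs=m["n_obs"],
    )
    thresholds = calibration.Thresholds(m["borderline_cut"], m["positive_cut"])
    intervals = pd.read_csv(
        out / "intervals.bed", sep="\t",
        names=["chrom", "start", "end", "name", "mean_coverage"],
    )
    intervals["n_windows5"] = np.nan
    summary = pd.read_csv(out / "genome_summary.tsv", sep="\t")
    dist = pd.read_csv(out / "window_classes.tsv", sep="\t")
    with open(out / "filter_counts.json") as fh:
        counts = json.load(fh)
    return RunResult(
        masked_genome=mg, w1=w1, w5=w5, matches=pd.DataFrame(), model=model,
        thresholds=thresholds, intervals=intervals, genome_summary=summary,
        class_distribution=dist, filter_counts=counts,
    )


def compare_masking_settings(
    sequences: dict[str, str],
    repeats: list[masking.RepeatAnnotation],
    reads: list[ReadRecord],
    calibration_regions: dict[str, np.ndarray],
    settings: tuple[str, ...] = masking.SETTINGS,
    **kwargs,
) -> dict[str, pd.DataFrame]:
    """Run the analysis once per masking setting on identical inputs.

    Returns one window-class distribution per setting plus a ``joined``
    comparison table of the all-window shares.
    """
    tables: dict[str, pd.DataFrame] = {}
    joined_rows = []
    for setting in settings:
        res = run_wssd(
            sequences, repeats, reads, calibration_regions, setting=setting,
            **kwargs,
        )
        tables[setting] = res.class_distribution
        overall = res.class_distribution.iloc[0]
        joined_rows.append(
            (setting, overall["n_windows"], overall["negative"],
             overall["borderline"], overall["positive"])
        )
    tables["joined"] = pd.DataFrame(
        joined_rows,
        columns=["setting", "n_windows", "negative", "borderline", "positive"],
    )
    return tables
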