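"""Synthetic genomes, annotations and reads with known ground truth.

The generator emulates the statistical structure the read-depth analysis
assumes: a multi-chromosome assembly carrying implanted high-identity
duplications (copy number 2-4, pairwise identity 94-100%, sizes >= 10 kb),
interspersed repeat families (including old subfamilies whose annotated
divergence exceeds 10% while copies stay mutually similar), tandem-repeat
blocks, assembly gaps, organelle-derived insertions, gene models, and
~12-13x shotgun reads with mean length ~735 bp (range 300-1447). Every
implanted feature is recorded in a truth table, one row per placed copy, and
large repeat-free single-copy stretches are reserved and emitted as
calibration regions.

The mutation model is substitution-only: each duplication copy is mutated
independently from its master at half the target divergence, so the
*pairwise* identity between copies matches the requested identity. All
randomness flows from a single spec-level seed through named substreams.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import intervals as ivl
from .calibration import MixtureModel
from .depth import ReadRecord
from .masking import RepeatAnnotation

__all__ = [
    "DuplicationSpec",
    "RepeatFamilySpec",
    "OrganelleInsertionSpec",
    "SyntheticGenomeSpec",
    "SyntheticGenome",
    "generate_genome",
    "simulate_reads",
    "simulate_mixture_sample",
    "evaluate_duplication_calls",
    "write_genome_files",
    "write_reads_files",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class DuplicationSpec:
    """One implanted duplication: ``copy_number`` placed copies of a master
    segment with the given pairwise identity between copies."""

    length: int
    copy_number: int
    identity: float
    repeat_fraction: float = 0.15  # repeat content implanted inside the master

    def __post_init__(self):
        if self.copy_number < 2:
            raise ValueError("duplications need copy_number >= 2")
        if not 80.0 <= self.identity <= 100.0:
            raise ValueError("identity must be in [80, 100]")
        if self.length < 1000:
            raise ValueError("duplication length must be >= 1 kb")


@dataclass(frozen=True)
class RepeatFamilySpec:
    """A repeat family: copies of a family master that itself diverged from
    the library consensus.

    ``divergence`` is the master-to-consensus percent divergence (what a
    repeat annotator reports, up to the intra-family spread);
    ``intra_divergence`` is the pairwise percent divergence between copies.
    An old subfamily (divergence > 10, small intra_divergence) escapes
    divergence-thresholded masking while its copies still cross-align.
    """

    name: str
    consensus_len: int
    n_copies: int
    divergence: float
    intra_divergence: float = 2.0


@dataclass(frozen=True)
class OrganelleInsertionSpec:
    source: str  # "mito" or "plastid"
    length: int


@dataclass
class SyntheticGenomeSpec:
    """Full recipe for a synthetic assembly; deterministic given ``seed``."""

    chrom_sizes: dict[str, int]
    duplications: list[DuplicationSpec] = field(default_factory=list)
    repeat_families: list[RepeatFamilySpec] = field(default_factory=list)
    organelle_insertions: list[OrganelleInsertionSpec] = field(default_factory=list)
    gc: float = 0.365
    n_tandem_blocks: int = 30
    tandem_len_range: tuple[int, int] = (300, 2000)
    tandem_period_range: tuple[int, int] = (2, 200)
    gap_runs: tuple[int, ...] = (50_000, 30_000, 20_000)
    n_genes: int = 500
    gene_len_range: tuple[int, int] = (800, 5000)
    n_calibration_regions: int = 12
    calibration_region_len: int = 40_000
    calibration_margin: int = 2_000
    placement_pad: int = 1_000
    seed: int = 0

    @classmethod
    def default(cls, seed: int = 0) -> "SyntheticGenomeSpec":
        """Desk-scale study conditions: a 5 Mb assembly, 20 duplications of
        10-100 kb at copy number 2-4 and identity 94-99.5%, ~15% repeat
        content, 3 assembly gaps, 500 genes and 10 organelle insertions."""
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD5]))
        # the 5 Mb layout fits ~3.1 Mb of placed duplication copies alongside
        # calibration regions, repeats and gaps; redraw heavier draws so
        # generation is feasible for every seed
        for _ in range(100):
            dups = [
                DuplicationSpec(
                    length=int(rng.integers(10_000, 100_001)),
                    copy_number=int(rng.choice([2, 3, 4], p=[0.6, 0.3, 0.1])),
                    identity=float(rng.uniform(94.0, 99.5)),
                )
                for _ in range(20)
            ]
            if sum(d.length * d.copy_number for d in dups) <= 3_100_000:
                break
        families = [
            RepeatFamilySpec("RF_young1", 3000, 28, divergence=float(rng.uniform(2, 6))),
            RepeatFamilySpec("RF_young2", 1500, 40, divergence=float(rng.uniform(3, 8))),
            RepeatFamilySpec("RF_old1", 2500, 30, divergence=float(rng.uniform(12, 18)),
                             intra_divergence=2.0),
            RepeatFamilySpec("RF_old2", 1200, 35, divergence=float(rng.uniform(20, 28)),
                             intra_divergence=3.0),
        ]
        organelles = [
            OrganelleInsertionSpec("mito", int(rng.integers(500, 6000)))
            for _ in range(6)
        ] + [
            OrganelleInsertionSpec("plastid", int(rng.integers(500, 6000)))
            for _ in range(4)
        ]
        return cls(
            chrom_sizes={
                "chr1": 2_000_000,
                "chr2": 1_600_000,
                "chr2_random": 400_000,
                "chrUn": 1_000_000,
            },
            duplications=dups,
            repeat_families=families,
            organelle_insertions=organelles,
            seed=seed,
        )


@dataclass
class SyntheticGenome:
    """Generator output: sequences, annotations and the truth table."""

    sequences: dict[str, str]
    repeats: list[RepeatAnnotation]
    genes: pd.DataFrame
    organelles: dict[str, str]
    organelle_hits: pd.DataFrame
    truth: pd.DataFrame
    calibration_regions: dict[str, np.ndarray]
    spec: SyntheticGenomeSpec

    def truth_duplications(self, min_identity: float | None = None) -> pd.DataFrame:
        dup = self.truth[self.truth["type"] == "duplication"]
        if min_identity is not None:
            dup = dup[dup["identity"] >= min_identity]
        return dup.reset_index(drop=True)


class _Allocator:
    """Non-overlapping placement of feature intervals into free genome space.

    Free segments are chosen with probability proportional to how much slack
    they have for the request, which keeps dense layouts feasible; a pad
    separates neighbouring features.
    """

    def __init__(self, chrom_sizes: dict[str, int], pad: int, rng):
        self.free = {c: [(0, n)] for c, n in chrom_sizes.items()}
        self.pad = pad
        self.rng = rng

    def place(self, length: int, chrom: str | None = None) -> tuple[str, int]:
        for pad in (self.pad, 0):
            need = length + 2 * pad
            candidates = [
                (c, i, e - s - need)
                for c, segs in self.free.items()
                if chrom is None or c == chrom
                for i, (s, e) in enumerate(segs)
                if e - s >= need
            ]
            if candidates:
                slack = np.array([max(c[2], 0) + 1 for c in candidates], dtype=float)
                pick = self.rng.choice(len(candidates), p=slack / slack.sum())
                c, i, _ = candidates[pick]
                s, e = self.free[c][i]
                start = int(self.rng.integers(s + pad, e - pad - length + 1))
                del self.free[c][i]
                if start - pad > s:
                    self.free[c].append((s, start - pad))
                if start + length + pad < e:
                    self.free[c].append((start + length + pad, e))
                return c, start
        raise ValueError(f"cannot place a feature of {length} bp: genome too full")


def _random_seq(rng, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def _mutate(rng, seq: np.ndarray, rate: float) -> np.ndarray:
    """Independent substitutions at the given per-base rate (no indels)."""
    out = seq.copy()
    if rate <= 0:
        return out
    hit = np.flatnonzero(rng.random(len(seq)) < rate)
    if len(hit):
        out[hit] = (out[hit] + rng.integers(1, 4, size=len(hit))) % 4
    return out


def generate_genome(spec: SyntheticGenomeSpec) -> SyntheticGenome:
    """Build the synthetic assembly with its annotations and truth table."""
    ss = np.random.SeedSequence([spec.seed, 0x5E9])
    rng_bg, rng_place, rng_feat, rng_gene = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    chrom_arrays = {
        c: _random_seq(rng_bg, n, spec.gc) for c, n in spec.chrom_sizes.items()
    }
    alloc = _Allocator(spec.chrom_sizes, spec.placement_pad, rng_place)
    truth_rows = []
    repeats: list[RepeatAnnotation] = []

    def record(type_, chrom, start, end, copy_number=0, identity=np.nan,
               family="", feature_id=""):
        truth_rows.append(
            (type_, chrom, int(start), int(end), int(copy_number),
             float(identity), family, feature_id)
        )

    # 1. reserve repeat-free single-copy calibration stretches first so
    #    fragmentation by later features cannot erase them
    calibration: dict[str, list] = {}
    for i in range(spec.n_calibration_regions):
        chrom, start = alloc.place(spec.calibration_region_len)
        end = start + spec.calibration_region_len
        m = spec.calibration_margin
        calibration.setdefault(chrom, []).append((start + m, end - m))
        record("single_region", chrom, start, end, feature_id=f"single{i:02d}")

    # 2. assembly gaps
    gap_by_chrom: dict[str, list] = {}
    for i, glen in enumerate(spec.gap_runs):
        chrom, start = alloc.place(int(glen))
        chrom_arrays[chrom][start:start + glen] = 4  # N
        gap_by_chrom.setdefault(chrom, []).append((start, start + glen))
        record("gap", chrom, start, start + glen, feature_id=f"gap{i:02d}")

    # 3. family masters (shared by background copies and master-embedded ones)
    fam_master: dict[str, np.ndarray] = {}
    for fam in spec.repeat_families:
        consensus = _random_seq(rng_feat, fam.consensus_len, spec.gc)
        fam_master[fam.name] = _mutate(rng_feat, consensus, fam.divergence / 100.0)

    def new_repeat_copy(fam: RepeatFamilySpec) -> tuple[np.ndarray, float]:
        copy = _mutate(rng_feat, fam_master[fam.name], fam.intra_divergence / 200.0)
        annotated_div = fam.divergence + fam.intra_divergence / 2.0
        return copy, annotated_div

    # 4. duplications, largest first for packing; each master may embed
    #    repeat copies that are then carried (and annotated) at every placement
    order = sorted(
        range(len(spec.duplications)),
        key=lambda i: -spec.duplications[i].length,
    )
    for di in order:
        dup = spec.duplications[di]
        master = _random_seq(rng_feat, dup.length, spec.gc)
        embedded: list[tuple[int, int, str, float]] = []
        if spec.repeat_families and dup.repeat_fraction > 0:
            target = dup.repeat_fraction * dup.length
            occupied: list[tuple[int, int]] = []
            got = 0
            attempts = 0
            while got < target and attempts < 200:
                attempts += 1
                fam = spec.repeat_families[
                    int(rng_feat.integers(len(spec.repeat_families)))
                ]
                copy, adiv = new_repeat_copy(fam)
                if len(copy) >= dup.length:
                    continue
                off = int(rng_feat.integers(0, dup.length - len(copy)))
                if any(off < e and off + len(copy) > s for s, e in occupied):
                    continue
                master[off:off + len(copy)] = copy
                occupied.append((off, off + len(copy)))
                embedded.append((off, off + len(copy), fam.name, adiv))
                got += len(copy)
        half_rate = (100.0 - dup.identity) / 200.0
        for ci in range(dup.copy_number):
            chrom, start = alloc.place(dup.length)
            placed = _mutate(rng_feat, master, half_rate)
            chrom_arrays[chrom][start:start + dup.length] = placed
            record(
                "duplication", chrom, start, start + dup.length,
                copy_number=dup.copy_number, identity=dup.identity,
                feature_id=f"dup{di:02d}_c{ci}",
            )
            for off_s, off_e, fname, adiv in embedded:
                repeats.append(
                    RepeatAnnotation(
                        chrom=chrom, start=start + off_s, end=start + off_e,
                        kind="interspersed", family=fname, divergence=adiv,
                    )
                )

    # 5. background repeat-family copies
    for fam in spec.repeat_families:
        for ci in range(fam.n_copies):
            copy, adiv = new_repeat_copy(fam)
            chrom, start = alloc.place(len(copy))
            chrom_arrays[chrom][start:start + len(copy)] = copy
            repeats.append(
                RepeatAnnotation(
                    chrom=chrom, start=start, end=start + len(copy),
                    kind="interspersed", family=fam.name, divergence=adiv,
                )
            )
            record("repeat", chrom, start, start + len(copy),
                   identity=100 - adiv, family=fam.name,
                   feature_id=f"{fam.name}_c{ci}")

    # 6. tandem-repeat blocks
    for ti in range(spec.n_tandem_blocks):
        period = int(rng_feat.integers(*spec.tandem_period_range))
        total = int(rng_feat.integers(*spec.tandem_len_range))
        unit = _random_seq(rng_feat, period, spec.gc)
        block = np.tile(unit, total // period + 1)[:total]
        block = _mutate(rng_feat, block, 0.01)
        chrom, start = alloc.place(total)
        chrom_arrays[chrom][start:start + total] = block
        repeats.append(
            RepeatAnnotation(
                chrom=chrom, start=start, end=start + total,
                kind="tandem", family=f"TR{ti:02d}", divergence=None,
            )
        )
        record("tandem", chrom, start, start + total, feature_id=f"TR{ti:02d}")

    # 7. organelle genomes and nuclear insertions
    organelles = {
        "mito": _random_seq(rng_feat, 80_000, 0.44),
        "plastid": _random_seq(rng_feat, 40_000, 0.37),
    }
    hit_rows = []
    used_src: dict[str, list] = {"mito": [], "plastid": []}
    for oi, ins in enumerate(spec.organelle_insertions):
        src = organelles[ins.source]
        if ins.length >= len(src):
            raise ValueError("organelle insertion longer than organelle genome")
        # disjoint source slices: each insertion is a unique single-copy
        # segment, so insertions never cross-align with one another
        for _ in range(200):
            off = int(rng_feat.integers(0, len(src) - ins.length))
            if all(off >= e or off + ins.length <= s for s, e in used_src[ins.source]):
                break
        else:
            raise ValueError("cannot draw disjoint organelle source slices")
        used_src[ins.source].append((off, off + ins.length))
        seg = src[off:off + ins.length]
        chrom, start = alloc.place(ins.length)
        chrom_arrays[chrom][start:start + ins.length] = seg
        hit_rows.append(
            (ins.source, chrom, start, start + ins.length, 1e-20)
        )
        record(f"organelle_{ins.source}", chrom, start, start + ins.length,
               feature_id=f"org{oi:02d}")
    organelle_hits = pd.DataFrame(
        hit_rows, columns=["organelle", "chrom", "start", "end", "evalue"]
    )

    # 8. genes: uniform over non-gap sequence, overlap with features allowed
    chrom_names = list(spec.chrom_sizes)
    sizes = np.array([spec.chrom_sizes[c] for c in chrom_names], dtype=float)
    gene_rows = []
    gi = 0
    while gi < spec.n_genes:
        c = chrom_names[int(rng_gene.choice(len(chrom_names), p=sizes / sizes.sum()))]
        glen = int(rng_gene.integers(*spec.gene_len_range))
        if spec.chrom_sizes[c] <= glen:
            continue
        start = int(rng_gene.integers(0, spec.chrom_sizes[c] - glen))
        if any(start < e and start + glen > s for s, e in gap_by_chrom.get(c, [])):
            continue
        gene_rows.append(
            (f"gene{gi:04d}", c, start, start + glen,
             "+" if rng_gene.random() < 0.5 else "-")
        )
        gi += 1
    genes = pd.DataFrame(gene_rows, columns=["id", "chrom", "start", "end", "strand"])
    for row in genes.itertuples():
        record("gene", row.chrom, row.start, row.end, feature_id=row.id)

    truth = pd.DataFrame(
        truth_rows,
        columns=["type", "chrom", "start", "end", "copy_number", "identity",
                 "family", "feature_id"],
    )
    base_map = np.frombuffer(b"ACGTN", dtype=np.uint8)
    sequences = {
        c: base_map[arr].tobytes().decode() for c, arr in chrom_arrays.items()
    }
    calibration_iv = {
        c: ivl.merge(v) for c, v in calibration.items()
    }
    return SyntheticGenome(
        sequences=sequences,
        repeats=repeats,
        genes=genes,
        organelles={
            k: base_map[v].tobytes().decode() for k, v in organelles.items()
        },
        organelle_hits=organelle_hits,
        truth=truth,
        calibration_regions=calibration_iv,
        spec=spec,
    )


def simulate_reads(
    sequences: dict[str, str],
    coverage: float = 12.0,
    len_mean: float = 735.0,
    len_sd: float = 130.0,
    len_min: int = 300,
    len_max: int = 1447,
    error_rate: float = 0.005,
    qc_fail_fraction: float = 0.0126,
    seed: int = 0,
) -> list[ReadRecord]:
    """Simulate shotgun reads with trace-QC metadata.

    Read count is coverage * genome bp / mean length; start positions are
    uniform per chromosome (reads overlapping N runs are resampled, as real
    reads come from sequenced DNA, not gaps); lengths follow a truncated
    normal; substitution errors occur at ``error_rate``. A ``qc_fail_fraction``
    of reads is emitted with percent_error > 6 or a high-quality portion
    shorter than 300 bp so the QC clipping stage has work to do.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EAD]))
    chroms = list(sequences)
    arrays = {
        c: np.frombuffer(sequences[c].encode(), dtype=np.uint8) for c in chroms
    }
    is_n = {c: arrays[c] == ord("N") for c in chroms}
    ncum = {c: np.concatenate(([0], np.cumsum(is_n[c].astype(np.int64)))) for c in chroms}
    sizes = np.array([len(arrays[c]) for c in chroms], dtype=float)
    total = sizes.sum()
    n_reads = int(round(coverage * total / len_mean))
    a = (len_min - len_mean) / len_sd
    b = (len_max - len_mean) / len_sd
    lengths = stats.truncnorm.rvs(
        a, b, loc=len_mean, scale=len_sd, size=n_reads, random_state=rng
    ).astype(int)
    comp = bytes.maketrans(b"ACGT", b"TGCA")
    p_chrom = sizes / total
    reads: list[ReadRecord] = []
    for i in range(n_reads):
        L = int(lengths[i])
        for _ in range(100):
            c = chroms[int(rng.choice(len(chroms), p=p_chrom))]
            if len(arrays[c]) <= L:
                continue
            start = int(rng.integers(0, len(arrays[c]) - L))
            if ncum[c][start + L] - ncum[c][start] == 0:
                break
        else:
            continue
        seq = arrays[c][start:start + L].copy()
        if error_rate > 0:
            hit = np.flatnonzero(rng.random(L) < error_rate)
            if len(hit):
                code = np.zeros(L, dtype=np.uint8)
                for j, bch in enumerate(b"ACGT"):
                    code[seq == bch] = j
                code[hit] = (code[hit] + rng.integers(1, 4, size=len(hit))) % 4
                seq = _BASES[code]
        s = seq.tobytes().decode()
        if rng.random() < 0.5:
            s = s.translate(comp)[::-1]
        if rng.random() < qc_fail_fraction:
            if rng.random() < 0.5:
                pe = float(rng.uniform(6.01, 12.0))
                hq_start, hq_end = 0, L
            else:
                pe = float(rng.uniform(0.5, 4.0))
                hq_start = 0
                hq_end = int(rng.integers(50, 300)) if L >= 300 else L - 1
        else:
            pe = float(rng.uniform(0.2, 4.0))
            hq_start, hq_end = 0, L
        reads.append(
            ReadRecord(
                id=f"read{i:07d}", sequence=s, hq_start=hq_start, hq_end=hq_end,
                percent_error=pe,
            )
        )
    return reads


def simulate_mixture_sample(model: MixtureModel, n: int, seed: int = 0) -> np.ndarray:
    """Draw ``n`` depth values from a constrained 4-Gaussian mixture model.

    Negative draws are truncated at 0; a warning is issued if more than 0.1%
    of the sample needed truncation.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x317]))
    comps = rng.choice(4, size=n, p=np.asarray(model.f))
    means, sds = model.component_params()
    x = rng.normal(means[comps], sds[comps])
    n_neg = int((x < 0).sum())
    if n_neg > 0.001 * n:
        warnings.warn(
            f"{n_neg}/{n} mixture draws truncated at zero", stacklevel=2
        )
    return np.maximum(x, 0.0)


def evaluate_duplication_calls(
    intervals: pd.DataFrame,
    truth: pd.DataFrame,
    min_identity: float = 96.0,
) -> dict:
    """Base-level recovery of implanted duplications by called intervals.

    Sensitivity is measured against truth copies with pairwise identity at
    or above ``min_identity`` (lower-identity duplications are below the
    method's stated detection range); precision counts a called base as a
    true positive when it overlaps *any* implanted duplication copy.
    """
    dup_all = truth[truth["type"] == "duplication"]
    dup_hi = dup_all[dup_all["identity"] >= min_identity]
    chroms = set(dup_all["chrom"]) | set(intervals["chrom"])
    tp_hi = fn_hi = called_bp = fp_bp = 0
    for chrom in chroms:
        called = ivl.merge(
            intervals[intervals["chrom"] == chrom][["start", "end"]].to_numpy()
        )
        truth_all_iv = ivl.merge(
            dup_all[dup_all["chrom"] == chrom][["start", "end"]].to_numpy()
        )
        truth_hi_iv = ivl.merge(
            dup_hi[dup_hi["chrom"] == chrom][["start", "end"]].to_numpy()
        )
        cb = ivl.union_length(called)
        called_bp += cb
        fp_bp += cb - ivl.union_length(ivl.intersect(called, truth_all_iv))
        hit = ivl.union_length(ivl.intersect(called, truth_hi_iv))
        tp_hi += hit
        fn_hi += ivl.union_length(truth_hi_iv) - hit
    sensitivity = tp_hi / (tp_hi + fn_hi) if tp_hi + fn_hi else float("nan")
    precision = (called_bp - fp_bp) / called_bp if called_bp else float("nan")
    return {
        "sensitivity": sensitivity,
        "precision": precision,
        "called_bp": called_bp,
        "truth_bp_high_identity": tp_hi + fn_hi,
        "false_positive_bp": fp_bp,
    }


def write_genome_files(sg: SyntheticGenome, outdir) -> None:
    """Emit FASTA, repeat tables, gene GFF3, truth and calibration BEDs."""
    from pathlib import Path

    from . import io as wio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    wio.write_fasta(sg.sequences, out / "genome.fa")
    wio.write_fasta(sg.organelles, out / "organelles.fa")
    wio.write_repeatmasker_out(sg.repeats, out / "repeats.out")
    wio.write_repeats_bed(sg.repeats, out / "repeats.bed")
    wio.write_gff3_genes(sg.genes, out / "genes.gff3")
    sg.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    dup = sg.truth_duplications()
    with open(out / "truth_duplications.bed", "w") as fh:
        for row in dup.itertuples():
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.feature_id}\t"
                f"{row.identity:.2f}\n"
            )
    wio.write_bed(sg.calibration_regions, out / "calibration.bed")
    sg.organelle_hits.to_csv(out / "organelle_hits.tsv", sep="\t", index=False)


def write_reads_files(reads: list[ReadRecord], outdir) -> None:
    from pathlib import Path

    from . import io as wio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "reads.fa", "w") as fh:
        for r in reads:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.sequence), 60):
                fh.write(r.sequence[i:i + 60] + "\n")
    qc = pd.DataFrame(
        {
            "id": [r.id for r in reads],
            "percent_error": [r.percent_error for r in reads],
            "hq_start": [r.hq_start for r in reads],
            "hq_end": [r.hq_end for r in reads],
            "flagged": [r.flagged for r in reads],
        }
    )
    wio.write_qc_sidecar(qc, out / "reads_qc.tsv")
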