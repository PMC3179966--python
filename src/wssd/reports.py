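"""Report-layer arithmetic shared by the summary tables.

These are the small formulas behind the bookkeeping lines of a run report:
read retention after QC, estimated sequencing coverage, and percentage
fractions of genome, genes or intervals.
"""

from __future__ import annotations

__all__ = [
    "percent",
    "read_retention_percent",
    "estimated_genome_coverage",
    "duplicated_fraction_percent",
]


def percent(part: float, whole: float, ndigits: int = 2) -> float:
    """100 * part / whole, rounded."""
    if whole == 0:
        raise ValueError("zero denominator")
    return round(100.0 * part / whole, ndigits)


def read_retention_percent(total_reads: int, discarded_reads: int, ndigits: int = 1) -> float:
    """Percent of reads surviving trace QC."""
    return percent(total_reads - discarded_reads, total_reads, ndigits)


def estimated_genome_coverage(n_reads: int, mean_read_len: float, genome_bp: int) -> int:
    """Fold coverage implied by a read set, rounded to the nearest integer."""
    if genome_bp <= 0:
        raise ValueError("genome size must be positive")
    return round(n_reads * mean_read_len / genome_bp)


def duplicated_fraction_percent(dup_bp: int, genome_bp: int, ndigits: int = 2) -> float:
    """Percent of the genome covered by called duplication intervals."""
    return percent(dup_bp, genome_bp, ndigits)
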