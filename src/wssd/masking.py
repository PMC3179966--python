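"""Repeat-masking semantics for read-depth duplication analysis.

An assembly is represented as uppercase sequence plus two separate interval
tracks: *masked repeats* and *assembly gaps* (runs of N in the input). The
distinction matters downstream: unmasked-base windows extend through masked
repeats but are discarded at assembly gaps.

Three masking settings are supported, differing in stringency and policy:

``div10_low``
    interspersed repeats with divergence < 10% from consensus, plus all
    tandem repeats, masked to lowercase;
``nodiv_low``
    all repeats masked to lowercase;
``nodiv_N``
    all repeats masked to N (alignments cannot extend through them).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import intervals as ivl

__all__ = [
    "RepeatAnnotation",
    "MaskedGenome",
    "SETTINGS",
    "detect_assembly_gaps",
    "apply_masking",
    "masked_fraction",
]

SETTINGS = ("div10_low", "nodiv_low", "nodiv_N")

#: policy implied by each setting
_POLICY = {"div10_low": "lowercase", "nodiv_low": "lowercase", "nodiv_N": "N"}


@dataclass(frozen=True)
class RepeatAnnotation:
    """One repeat interval on the assembly (0-based, half-open).

    ``kind`` is ``"interspersed"`` or ``"tandem"``; ``divergence`` is percent
    divergence from the family consensus and may be ``None`` for tandem
    repeats, which carry no consensus.
    """

    chrom: str
    start: int
    end: int
    kind: str = "interspersed"
    family: str = ""
    divergence: float | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"repeat {self.chrom}:{self.start}-{self.end} empty")
        if self.divergence is not None and self.divergence < 0:
            raise ValueError("divergence must be >= 0")
        if self.kind not in ("interspersed", "tandem"):
            raise ValueError(f"unknown repeat kind {self.kind!r}")


@dataclass
class MaskedGenome:
    """Assembly sequences with mask and assembly-gap interval tracks."""

    sequences: dict[str, str]
    mask: dict[str, np.ndarray]
    gaps: dict[str, np.ndarray]
    setting: str
    mask_char_policy: str
    _mask_bool: dict = field(default_factory=dict, repr=False)

    def chrom_size(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    @property
    def chroms(self) -> list[str]:
        return list(self.sequences)

    def mask_intervals(self, chrom: str) -> np.ndarray:
        return self.mask.get(chrom, np.empty((0, 2), dtype=np.int64))

    def gap_intervals(self, chrom: str) -> np.ndarray:
        return self.gaps.get(chrom, np.empty((0, 2), dtype=np.int64))

    def mask_bool(self, chrom: str) -> np.ndarray:
        """Per-base boolean mask track (cached)."""
        if chrom not in self._mask_bool:
            self._mask_bool[chrom] = ivl.coverage_mask(
                self.mask_intervals(chrom), self.chrom_size(chrom)
            )
        return self._mask_bool[chrom]

    def masked_sequence(self, chrom: str) -> str:
        """Sequence with the mask policy applied character-wise."""
        seq = np.frombuffer(self.sequences[chrom].encode(), dtype=np.uint8).copy()
        m = self.mask_bool(chrom)
        if self.mask_char_policy == "N":
            seq[m] = ord("N")
        else:
            sel = seq[m]
            # ASCII uppercase -> lowercase
            is_upper = (sel >= ord("A")) & (sel <= ord("Z"))
            sel[is_upper] += 32
            seq[m] = sel
        return seq.tobytes().decode()

    def total_bp(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def gap_bp(self) -> int:
        return sum(ivl.union_length(g) for g in self.gaps.values())

    def masked_bp(self) -> int:
        return sum(ivl.union_length(m) for m in self.mask.values())


def detect_assembly_gaps(
    sequences: dict[str, str], min_gap_run: int = 10
) -> dict[str, np.ndarray]:
    """Find maximal runs of N of length >= ``min_gap_run`` per chromosome.

    Shorter N runs are treated as ordinary ambiguous bases, not gaps.
    """
    gaps: dict[str, np.ndarray] = {}
    for chrom, seq in sequences.items():
        arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        is_n = arr == ord("N")
        if not is_n.any():
            gaps[chrom] = np.empty((0, 2), dtype=np.int64)
            continue
        edges = np.diff(np.concatenate(([0], is_n.view(np.int8), [0])))
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
        keep = (ends - starts) >= min_gap_run
        gaps[chrom] = np.stack([starts[keep], ends[keep]], axis=1).astype(np.int64)
    return gaps


def _select_repeats(
    repeats: list[RepeatAnnotation], setting: str, divergence_cutoff: float
) -> list[RepeatAnnotation]:
    if setting == "div10_low":
        return [
            r
            for r in repeats
            if r.kind == "tandem"
            or (r.divergence is not None and r.divergence < divergence_cutoff)
        ]
    return list(repeats)


def apply_masking(
    sequences: dict[str, str],
    repeats: list[RepeatAnnotation],
    setting: str,
    min_gap_run: int = 10,
    divergence_cutoff: float = 10.0,
) -> MaskedGenome:
    """Build a :class:`MaskedGenome` under one of the three settings.

    The divergence filter is strict (< cutoff); an interspersed repeat at
    exactly the cutoff is *not* masked under ``div10_low``. Overlapping
    annotations are unioned; repeats overlapping an assembly gap are clipped
    to their non-gap portion. Assembly gaps never enter the mask track.
    """
    if setting not in SETTINGS:
        raise ValueError(f"unknown masking setting {setting!r}; expected one of {SETTINGS}")
    gaps = detect_assembly_gaps(sequences, min_gap_run=min_gap_run)
    selected = _select_repeats(repeats, setting, divergence_cutoff)
    mask: dict[str, np.ndarray] = {}
    by_chrom: dict[str, list] = {}
    for r in selected:
        if r.chrom not in sequences:
            raise ValueError(f"repeat on unknown chromosome {r.chrom!r}")
        if r.end > len(sequences[r.chrom]):
            raise ValueError(
                f"repeat {r.chrom}:{r.start}-{r.end} outside sequence bounds"
            )
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    for chrom in sequences:
        iv = ivl.merge(by_chrom.get(chrom, []))
        iv = ivl.subtract(iv, gaps[chrom])
        mask[chrom] = iv
    return MaskedGenome(
        sequences=dict(sequences),
        mask=mask,
        gaps=gaps,
        setting=setting,
        mask_char_policy=_POLICY[setting],
    )


def masked_fraction(mg: MaskedGenome) -> float:
    """Percent of non-gap bases masked (masked bp counted once under overlap)."""
    non_gap = mg.total_bp() - mg.gap_bp()
    if non_gap == 0:
        raise ValueError("genome consists only of assembly gaps")
    return 100.0 * mg.masked_bp() / non_gap
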