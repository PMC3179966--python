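"""Shared fixtures: small hand-built genomes and one full desk-scale run."""

from __future__ import annotations

import numpy as np
import pytest

from wssd import synthetic_data as synth
from wssd.masking import MaskedGenome, RepeatAnnotation, apply_masking
from wssd.pipeline import run_wssd


@pytest.fixture
def plain_genome():
    """A 10 kb single-chromosome assembly with no repeats or gaps."""
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=10_000))
    return {"chr1": seq}


def make_masked_genome(masked: np.ndarray, gap: np.ndarray, policy: str = "N"):
    """Build a MaskedGenome directly from per-base boolean tracks."""
    from wssd import intervals as ivl

    n = len(masked)
    seq = np.full(n, ord("A"), dtype=np.uint8)
    seq[gap] = ord("N")
    masked = masked & ~gap

    def runs(b):
        edges = np.diff(np.concatenate(([0], b.view(np.int8), [0])))
        return np.stack(
            [np.flatnonzero(edges == 1), np.flatnonzero(edges == -1)], axis=1
        ).astype(np.int64)

    return MaskedGenome(
        sequences={"chr1": seq.tobytes().decode()},
        mask={"chr1": runs(masked)},
        gaps={"chr1": runs(gap)},
        setting="nodiv_N" if policy == "N" else "nodiv_low",
        mask_char_policy=policy,
    )


@pytest.fixture(scope="session")
def desk_scale_run():
    """Full pipeline run at the desk-scale study conditions.

    5 Mb synthetic assembly, 20 implanted duplications (10-100 kb, copy
    number 2-4, identity 94-99.5%), ~15% repeats, 3 gaps, 12x reads of mean
    length 735 bp, N-policy masking without divergence threshold. Shared by
    the end-to-end acceptance checks.
    """
    spec = synth.SyntheticGenomeSpec.default(1)
    sg = synth.generate_genome(spec)
    reads = synth.simulate_reads(sg.sequences, coverage=12.0, seed=1)
    res = run_wssd(sg.sequences, sg.repeats, reads, sg.calibration_regions)
    return sg, reads, res
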