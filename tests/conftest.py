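"""Shared fixtures: tiny references, hand-built pileups, one small clean experiment."""
from __future__ import annotations

import numpy as np
import pytest

from adarcall.alignio import Transcript
from adarcall.consensus import BASES, ConsensusResult, PileupTable
from adarcall.edcall import CallerConfig, call_sites
from adarcall.evaluate import run_in_memory
from adarcall.simdata import SimConfig


def make_reference(seqs: dict[str, str]) -> dict[str, Transcript]:
    return {tid: Transcript(tid, seq) for tid, seq in seqs.items()}


def make_consensus(
    reference: dict[str, Transcript],
    masked_positions: dict[str, list[int]] | None = None,
    depth: int = 1000,
) -> ConsensusResult:
    """A consensus equal to the reference, unmasked except where requested."""
    variant_freq, dna_depth, masked = {}, {}, {}
    for tid, t in reference.items():
        variant_freq[tid] = np.zeros(t.length)
        dna_depth[tid] = np.full(t.length, depth, dtype=np.int64)
        m = np.zeros(t.length, dtype=bool)
        for pos in (masked_positions or {}).get(tid, []):
            m[pos] = True
        masked[tid] = m
    return ConsensusResult(dict(reference), variant_freq, dna_depth, masked)


def make_pileup(
    reference: dict[str, Transcript],
    counts: dict[str, dict[int, dict[str, int]]],
) -> PileupTable:
    """Pileup with explicit per-position base counts (support = count)."""
    table = PileupTable(reference)
    for tid, per_pos in counts.items():
        mat = table.count_matrix(tid)
        for pos, base_counts in per_pos.items():
            for base, n in base_counts.items():
                mat[pos, BASES.index(base)] += n
    return table


@pytest.fixture(scope="session")
def clean_cfg() -> SimConfig:
    """Small, error-free design with frequencies high enough to be detectable."""
    return SimConfig(
        n_transcripts=8,
        length_range=(800, 1000),
        n_edit_sites=16,
        control_freq_range=(0.25, 0.60),
        kd_reduction=1.0,
        coverage_rna=60,
        coverage_dna=40,
        error_rate=0.0,
        antisense_fraction=0.25,
        seed=42,
    )


@pytest.fixture(scope="session")
def clean_experiment(clean_cfg):
    return run_in_memory(clean_cfg, conditions=("adar2",), collect_read_ids=True)


@pytest.fixture(scope="session")
def clean_calls(clean_experiment):
    return call_sites(
        clean_experiment.pileups,
        clean_experiment.sheet,
        "adar2",
        clean_experiment.consensus,
        CallerConfig(),
    )
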