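"""Benchmarking the caller against simulated ground truth.

Runs the simulate -> filter -> consensus -> call chain fully in memory (no
files) and scores the resulting call set against the planted truth. Also
exposes the analytic recall prediction from the per-site detection power,
which quantifies how coverage and the support/frequency floors bound what
any threshold caller can recover.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .alignio import ReadFilterConfig, Transcript, filter_reads
from .consensus import ConsensusConfig, ConsensusResult, PileupTable, call_consensus, pileup
from .edcall import CallerConfig, SampleSheet, SiteCall, call_sites, detection_power
from .simdata import SimConfig, SimTruth, generate_transcriptome, plant_sites, simulate_reads


@dataclass
class ExperimentData:
    """Everything one in-memory simulated experiment produced."""

    transcripts: list[Transcript]
    reference: dict[str, Transcript]
    truth: SimTruth
    sheet: SampleSheet
    pileups: dict[str, PileupTable]
    consensus: ConsensusResult


def run_in_memory(
    cfg: SimConfig,
    conditions: Sequence[str] = ("adar2",),
    read_filter: ReadFilterConfig = ReadFilterConfig(),
    consensus_cfg: ConsensusConfig = ConsensusConfig(),
    collect_read_ids: bool = False,
) -> ExperimentData:
    """Simulate an experiment and build filtered pileups + consensus, no I/O."""
    transcripts = generate_transcriptome(cfg)
    reference = {t.id: t for t in transcripts}
    truth = plant_sites(transcripts, cfg)

    def sample_pileup(role: str, rep: int) -> PileupTable:
        readset = simulate_reads(transcripts, truth, role, rep, cfg)
        kept, _ = filter_reads(readset.to_records(reference), read_filter)
        return pileup(kept, reference, collect_read_ids=collect_read_ids)

    dna_table = sample_pileup("dna", 0)
    consensus = call_consensus(dna_table, reference, consensus_cfg)

    pileups: dict[str, PileupTable] = {}
    controls = []
    for i in range(cfg.n_control):
        sid = f"control_{i + 1}"
        controls.append(sid)
        pileups[sid] = sample_pileup("control", i)
    knockdowns: dict[str, list[str]] = {}
    for cond in conditions:
        knockdowns[cond] = []
        for i in range(cfg.n_kd):
            sid = f"kd_{cond}_{i + 1}"
            knockdowns[cond].append(sid)
            pileups[sid] = sample_pileup(f"kd_{cond}", i)
    sheet = SampleSheet(controls=controls, knockdowns=knockdowns, dna=["dna"])
    return ExperimentData(transcripts, reference, truth, sheet, pileups, consensus)


@dataclass
class RecoveryStats:
    """Called vs planted site/alt triples for one knockdown condition."""

    true_positives: set = field(default_factory=set)
    false_positives: set = field(default_factory=set)
    false_negatives: set = field(default_factory=set)

    @property
    def precision(self) -> float:
        called = len(self.true_positives) + len(self.false_positives)
        return len(self.true_positives) / called if called else 1.0

    @property
    def recall(self) -> float:
        planted = len(self.true_positives) + len(self.false_negatives)
        return len(self.true_positives) / planted if planted else 1.0


def evaluate_recovery(
    truth: SimTruth,
    calls: Sequence[SiteCall],
    condition: str = "adar2",
) -> RecoveryStats:
    """Score calls against the planted sites of one dependency class."""
    planted = {
        (s.transcript_id, s.pos, s.alt)
        for s in truth.edit_sites
        if s.dependency == condition
    }
    called = {(c.transcript_id, c.pos, c.alt) for c in calls}
    return RecoveryStats(
        true_positives=called & planted,
        false_positives=called - planted,
        false_negatives=planted - called,
    )


def contrast_experiment(
    cfg: SimConfig,
    condition: str = "adar2",
    caller_cfg: CallerConfig = CallerConfig(),
    conditions: Sequence[str] | None = None,
) -> tuple[ExperimentData, list[SiteCall], RecoveryStats]:
    """One full simulated contrast: returns data, calls, and recovery stats."""
    data = run_in_memory(cfg, conditions=conditions or (condition,))
    calls = call_sites(data.pileups, data.sheet, condition, data.consensus, caller_cfg)
    return data, calls, evaluate_recovery(data.truth, calls, condition)


def predicted_recall(
    truth: SimTruth,
    depth: float,
    caller_cfg: CallerConfig = CallerConfig(),
    n_controls: int = 4,
    condition: str = "adar2",
) -> float:
    """Mean analytic detection power over the planted sites of one class."""
    powers = [
        detection_power(s.control_freq, depth, caller_cfg, n_controls)
        for s in truth.edit_sites
        if s.dependency == condition
    ]
    return float(np.mean(powers)) if powers else 1.0
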