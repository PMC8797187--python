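"""End-to-end orchestration: simulate -> filter -> consensus -> call -> annotate -> structure.

Each stage reads its inputs from, and writes its outputs to, a fixed layout
under the run directory, so stages can be re-run individually and a missing
prerequisite produces an error naming the stage to run first. Every written
table carries the run-config hash in a ``#`` header comment; reruns with
identical inputs and seed are byte-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .alignio import (
    ReadFilterConfig,
    filter_reads,
    load_fasta,
    read_alignments,
    write_filter_report,
)
from .annotate import (
    annotate_sites,
    context_matrix,
    write_annotations_tsv,
    write_orfs_bed,
    write_orfs_gff3,
)
from .consensus import ConsensusConfig, ConsensusResult, PileupTable, call_consensus, pileup
from .edcall import (
    CallerConfig,
    SampleSheet,
    call_sites,
    mismatch_frequencies,
    read_calls_tsv,
    spectrum,
    write_calls_tsv,
    write_calls_vcf,
    write_spectrum_tsv,
)
from .simdata import SimConfig, simulate_experiment
from .structure import StructureConfig, annotate_structure, write_structure_tsv

log = logging.getLogger("adarcall")

STAGES = ("simulate", "filter", "consensus", "call", "annotate", "structure")


class PipelineError(RuntimeError):
    pass


@dataclass
class AnnotationConfig:
    min_orf_length: int = 150
    flank: int = 5


@dataclass
class RunConfig:
    """Everything one run needs; serialized verbatim into the manifest."""

    out_dir: str = "run"
    reference: str | None = None  # external reference FASTA (else simulated)
    sample_sheet: str | None = None  # external sample sheet (else simulated)
    sim: SimConfig = field(default_factory=SimConfig)
    read_filter: ReadFilterConfig = field(default_factory=ReadFilterConfig)
    consensus: ConsensusConfig = field(default_factory=ConsensusConfig)
    caller: CallerConfig = field(default_factory=CallerConfig)
    structure: StructureConfig = field(default_factory=StructureConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    seed: int | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.seed is not None:
            self.sim.seed = int(self.seed)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (run location and logging excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        d.pop("log_level", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        kwargs = dict(data)
        for key, sub in (
            ("sim", SimConfig),
            ("read_filter", ReadFilterConfig),
            ("consensus", ConsensusConfig),
            ("caller", CallerConfig),
            ("structure", StructureConfig),
            ("annotation", AnnotationConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                sect = kwargs[key]
                for tup_key in ("length_range", "control_freq_range", "dna_variant_freq_range"):
                    if tup_key in sect and isinstance(sect[tup_key], list):
                        sect[tup_key] = tuple(sect[tup_key])
                kwargs[key] = sub(**sect)
        return cls(**kwargs)


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"missing required input {path}; run the '{producer}' stage first"
        )
    return path


class PipelineRun:
    """One run directory with stage methods; see module docstring for layout."""

    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self.out = Path(cfg.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.header = [f"adarcall {__version__}", f"config_hash={cfg.config_hash()}"]

    # -- shared inputs -----------------------------------------------------

    def _reference_path(self) -> Path:
        if self.cfg.reference:
            return Path(self.cfg.reference)
        return _require(self.out / "simulate" / "reference.fasta", "simulate")

    def _sheet_path(self) -> Path:
        if self.cfg.sample_sheet:
            return Path(self.cfg.sample_sheet)
        return _require(self.out / "simulate" / "sample_sheet.yaml", "simulate")

    def _load_inputs(self):
        reference = load_fasta(self._reference_path())
        sheet = SampleSheet.from_yaml(self._sheet_path())
        return reference, sheet

    def _filtered_pileup(self, reference, sam_path, collect_read_ids=False):
        records = read_alignments(sam_path, reference)
        kept, report = filter_reads(records, self.cfg.read_filter)
        table = pileup(kept, reference, collect_read_ids=collect_read_ids)
        return table, report

    def _call_consensus(self, reference, sheet) -> ConsensusResult:
        table = PileupTable(reference)
        for sample in sheet.dna:
            records = read_alignments(sheet.paths[sample], reference)
            kept, _ = filter_reads(records, self.cfg.read_filter)
            table.add_all(kept)
        return call_consensus(table, reference, self.cfg.consensus)

    # -- stages ------------------------------------------------------------

    def stage_simulate(self) -> None:
        sim_dir = self.out / "simulate"
        transcripts, truth, paths = simulate_experiment(self.cfg.sim, sim_dir)
        sheet = SampleSheet(
            controls=[f"control_{i + 1}" for i in range(self.cfg.sim.n_control)],
            knockdowns={
                "adar1": [f"kd_adar1_{i + 1}" for i in range(self.cfg.sim.n_kd)],
                "adar2": [f"kd_adar2_{i + 1}" for i in range(self.cfg.sim.n_kd)],
            },
            dna=["dna"],
            paths={k: str(v) for k, v in paths.items()},
        )
        sheet.to_yaml(sim_dir / "sample_sheet.yaml")
        log.info("simulated %d transcripts, %d edit sites, %d samples",
                 len(transcripts), len(truth.edit_sites), len(paths))

    def stage_filter(self) -> None:
        reference, sheet = self._load_inputs()
        out = self.out / "filter"
        out.mkdir(exist_ok=True)
        for sample in sheet.all_samples():
            records = read_alignments(sheet.paths[sample], reference)
            _, report = filter_reads(records, self.cfg.read_filter)
            write_filter_report(report, out / f"{sample}.filter.tsv", self.header)
        log.info("filter reports written for %d samples", len(sheet.all_samples()))

    def stage_consensus(self) -> None:
        reference, sheet = self._load_inputs()
        if not sheet.dna:
            raise PipelineError("sample sheet lists no DNA samples; consensus needs them")
        cons = self._call_consensus(reference, sheet)
        out = self.out / "consensus"
        out.mkdir(exist_ok=True)
        cons.write_fasta(out / "consensus.fasta")
        cons.write_mask_bed(out / "mask.bed")
        cons.write_mask_tsv(out / "mask.tsv", self.header)
        n_masked = sum(int(m.sum()) for m in cons.masked.values())
        log.info("consensus called; %d positions masked", n_masked)

    def stage_call(self) -> None:
        reference, sheet = self._load_inputs()
        _require(self.out / "consensus" / "consensus.fasta", "consensus")
        cons = self._call_consensus(reference, sheet)
        pileups = {}
        rna_samples = [s for s in sheet.all_samples() if s not in sheet.dna]
        for sample in rna_samples:
            pileups[sample], _ = self._filtered_pileup(reference, sheet.paths[sample])
        out = self.out / "calls"
        out.mkdir(exist_ok=True)
        freqs = mismatch_frequencies(pileups, cons)
        with open(out / "mismatch_frequencies.tsv", "w") as fh:
            for line in self.header:
                fh.write(f"# {line}\n")
            export = freqs.copy()
            export["pos_1based"] = export.pop("pos") + 1
            export.to_csv(fh, sep="\t", index=False)
        for condition in sheet.knockdowns:
            calls = call_sites(pileups, sheet, condition, cons, self.cfg.caller)
            write_calls_tsv(calls, out / f"calls_{condition}.tsv", self.header)
            write_calls_vcf(
                calls, {t.id: t.length for t in reference.values()},
                out / f"calls_{condition}.vcf",
            )
            write_spectrum_tsv(spectrum(calls), out / f"spectrum_{condition}.tsv", self.header)
            log.info("%s: %d sites called", condition, len(calls))

    def _load_calls(self, condition: str):
        path = _require(self.out / "calls" / f"calls_{condition}.tsv", "call")
        return read_calls_tsv(path)

    def stage_annotate(self) -> None:
        reference, sheet = self._load_inputs()
        cons = self._call_consensus(reference, sheet)
        out = self.out / "annotate"
        out.mkdir(exist_ok=True)
        for condition in sheet.knockdowns:
            calls = self._load_calls(condition)
            annotations, orfs = annotate_sites(calls, cons, self.cfg.annotation.min_orf_length)
            write_annotations_tsv(annotations, out / f"annotations_{condition}.tsv", self.header)
            write_orfs_bed(orfs, out / f"orfs_{condition}.bed")
            write_orfs_gff3(orfs, out / f"orfs_{condition}.gff3")
            seqs = {tid: cons.sequence(tid) for tid in {c.transcript_id for c in calls}}
            cm = context_matrix(calls, seqs, self.cfg.annotation.flank)
            cm.write_tsv(out / f"context_{condition}.tsv", self.header)
            cm.write_pfm(out / f"context_{condition}.pfm.txt")
            log.info("%s: %d sites annotated", condition, len(annotations))

    def stage_structure(self) -> None:
        reference, sheet = self._load_inputs()
        cons = self._call_consensus(reference, sheet)
        out = self.out / "structure"
        out.mkdir(exist_ok=True)
        for condition in sheet.knockdowns:
            calls = self._load_calls(condition)
            seqs = {tid: cons.sequence(tid) for tid in {c.transcript_id for c in calls}}
            annotations = annotate_structure(calls, seqs, self.cfg.structure)
            write_structure_tsv(annotations, out / f"structure_{condition}.tsv", self.header)
            log.info("%s: structure annotated for %d sites", condition, len(annotations))

    def write_manifest(self, stages: list[str]) -> None:
        checksums = {}
        for role_path in ("simulate/reference.fasta", "simulate/sample_sheet.yaml"):
            p = self.out / role_path
            if p.exists():
                checksums[role_path] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
        manifest = {
            "tool": "adarcall",
            "version": __version__,
            "config_hash": self.cfg.config_hash(),
            "config": self.cfg.to_dict(),
            "stages": stages,
            "input_checksums": checksums,
        }
        with open(self.out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
            fh.write("\n")


def run_pipeline(cfg: RunConfig, stages: list[str] | tuple[str, ...] = ("all",)) -> Path:
    """Run the requested stages (in pipeline order); returns the run directory."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
    wanted = list(STAGES) if "all" in stages else [s for s in STAGES if s in stages]
    unknown = [s for s in stages if s not in STAGES + ("all",)]
    if unknown:
        raise PipelineError(f"unknown stages: {unknown}; valid: {', '.join(STAGES + ('all',))}")
    if "all" in stages and (cfg.reference or cfg.sample_sheet):
        wanted = [s for s in wanted if s != "simulate"]
    run = PipelineRun(cfg)
    for stage in wanted:
        log.info("running stage %s", stage)
        getattr(run, f"stage_{stage}")()
    run.write_manifest(wanted)
    return run.out
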