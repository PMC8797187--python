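"""Synthetic transcriptome, planted editing sites, and read simulation.

The generator emulates the experimental design the caller assumes: a small
multi-transcript reference carrying one ORF each, low-frequency genomic DNA
variants (including a band straddling the 0.5% mask cutoff), A-to-I editing
sites planted at control frequencies that drop by a fixed factor in one
knockdown condition, a 4 control / 4 adar1 / 4 adar2 replicate structure,
uniform substitution sequencing error, and fixed-length single-end reads
drawn uniformly along each transcript.

Everything is deterministic under ``SimConfig.seed``: the same config yields
byte-identical FASTA/FASTQ/SAM/TSV outputs.

Editing is planted per-read Bernoulli: each RNA read overlapping a site
carries the alternative base independently with the site's frequency (the
control frequency in control replicates and in non-matching knockdowns, the
reduced frequency in the matching knockdown). A configurable fraction of
transcripts is treated as antisense-assembled, so their sites appear as T>C
instead of A>G — mirroring the mixed A-to-G / T-to-C spectrum seen when
transcripts are unstranded.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .alignio import AlignmentRecord, Transcript, write_alignments, write_fasta
from .consensus import BASES, encode

ROLES = ("dna", "control", "kd_adar1", "kd_adar2")
_STOPS = ("TAA", "TAG", "TGA")


class SimConfigError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic experiment.

    Defaults describe the regime the caller's filters assume: ~1 kb
    transcripts at AT-rich (planarian-like) base composition, 40 sites at
    control frequencies 5-60% fully lost in the adar2 knockdown, 4/4/4
    replicates, 30x DNA and RNA coverage, 100 nt reads, Illumina-like 1e-3
    substitution error, and rare DNA variants in a 0.3-1% frequency band
    around the 0.5% mask cutoff.
    """

    n_transcripts: int = 30
    length_range: tuple[int, int] = (800, 1200)
    gc_content: float = 0.38
    n_edit_sites: int = 40
    control_freq_range: tuple[float, float] = (0.05, 0.60)
    kd_reduction: float = 1.0
    dependency_mix: dict[str, float] = field(default_factory=lambda: {"adar1": 0.0, "adar2": 1.0})
    dna_variant_rate: float = 1e-3
    dna_variant_freq_range: tuple[float, float] = (0.003, 0.01)
    antisense_fraction: float = 0.25
    read_length: int = 100
    coverage_dna: float = 30.0
    coverage_rna: float = 30.0
    error_rate: float = 1e-3
    n_control: int = 4
    n_kd: int = 4
    seed: int = 0

    def validate(self) -> None:
        fracs = {
            "gc_content": self.gc_content,
            "kd_reduction": self.kd_reduction,
            "dna_variant_rate": self.dna_variant_rate,
            "antisense_fraction": self.antisense_fraction,
            "error_rate": self.error_rate,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("control_freq_range", "dna_variant_freq_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise SimConfigError(f"{name} must be an ordered interval in [0, 1], got {(lo, hi)}")
        for name, v in {"adar_mix": sum(self.dependency_mix.values())}.items():
            if self.dependency_mix and not 0.0 < v <= 1.0 + 1e-9:
                raise SimConfigError(f"dependency_mix fractions must sum into (0, 1], got {v}")
        if set(self.dependency_mix) - {"adar1", "adar2"}:
            raise SimConfigError(f"dependency_mix keys must be adar1/adar2, got {sorted(self.dependency_mix)}")
        for name in ("n_transcripts", "n_edit_sites", "read_length", "n_control", "n_kd"):
            v = getattr(self, name)
            if v < 0 or (name in ("n_transcripts", "read_length") and v < 1):
                raise SimConfigError(f"{name} must be non-negative (positive for counts), got {v}")
        if self.n_control < 1 or self.n_kd < 1:
            raise SimConfigError("n_control and n_kd must each be >= 1")
        lo, hi = self.length_range
        if lo > hi:
            raise SimConfigError(f"length_range must be ordered, got {self.length_range}")
        if lo < 3 * self.read_length:
            raise SimConfigError(
                f"length_range minimum {lo} must be >= 3 x read_length ({3 * self.read_length})"
            )
        if self.coverage_dna <= 0 or self.coverage_rna <= 0:
            raise SimConfigError("coverage_dna and coverage_rna must be positive")


@dataclass(frozen=True)
class EditSite:
    transcript_id: str
    pos: int  # 0-based
    ref: str
    alt: str
    dependency: str  # "adar1" | "adar2"
    control_freq: float
    kd_freq: float


@dataclass(frozen=True)
class DnaVariant:
    transcript_id: str
    pos: int  # 0-based
    alt: str
    freq: float


@dataclass
class SimTruth:
    """Ground truth: planted edits, DNA variants, per-read origins."""

    edit_sites: list[EditSite]
    dna_variants: list[DnaVariant]
    antisense: set[str]
    read_origins: dict[str, tuple[str, int, str, tuple[int, ...]]] = field(default_factory=dict)

    def sites_by_transcript(self) -> dict[str, list[EditSite]]:
        out: dict[str, list[EditSite]] = {}
        for s in self.edit_sites:
            out.setdefault(s.transcript_id, []).append(s)
        return out

    def variants_by_transcript(self) -> dict[str, list[DnaVariant]]:
        out: dict[str, list[DnaVariant]] = {}
        for v in self.dna_variants:
            out.setdefault(v.transcript_id, []).append(v)
        return out

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("transcript_id\tpos_1based\tref\talt\tdependency\tcontrol_freq\tkd_freq\n")
            for s in self.edit_sites:
                fh.write(
                    f"{s.transcript_id}\t{s.pos + 1}\t{s.ref}\t{s.alt}\t{s.dependency}"
                    f"\t{s.control_freq:.6g}\t{s.kd_freq:.6g}\n"
                )

    def write_variants_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("transcript_id\tpos_1based\talt\tfreq\n")
            for v in self.dna_variants:
                fh.write(f"{v.transcript_id}\t{v.pos + 1}\t{v.alt}\t{v.freq:.6g}\n")


def _rng(cfg: SimConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed) & 0x7FFFFFFF, *key])


def _random_codons(rng: np.random.Generator, n: int) -> str:
    """n random codons, none of them stop codons."""
    out = []
    bases = np.array(list("ACGT"))
    while len(out) < n:
        cod = "".join(rng.choice(bases, 3))
        if cod not in _STOPS:
            out.append(cod)
    return "".join(out)


def generate_transcriptome(cfg: SimConfig) -> list[Transcript]:
    """Random transcripts at the configured GC content, one planted ORF each.

    Each transcript carries an ATG...stop ORF of at least 300 nt so that the
    ORF/codon annotation stages always have something to work on.
    """
    cfg.validate()
    rng = _rng(cfg, 1)
    p = np.array(
        [(1 - cfg.gc_content) / 2, cfg.gc_content / 2, cfg.gc_content / 2, (1 - cfg.gc_content) / 2]
    )
    bases = np.array(list("ACGT"))
    transcripts: list[Transcript] = []
    width = max(4, len(str(cfg.n_transcripts)))
    for i in range(cfg.n_transcripts):
        L = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        seq = rng.choice(bases, size=L, p=p)
        # plant one ORF: ATG + non-stop codons + stop, >= 300 nt where L allows
        max_orf = (L - 6) // 3 * 3
        if max_orf >= 300:
            hi_codons = min(200, max_orf // 3)
            orf_len = int(rng.integers(100, hi_codons + 1)) * 3
        else:
            orf_len = (L // 3) * 3
        start = int(rng.integers(0, L - orf_len + 1))
        body = "ATG" + _random_codons(rng, orf_len // 3 - 2) + _STOPS[int(rng.integers(3))]
        seq[start : start + orf_len] = list(body)
        transcripts.append(Transcript(f"t{i + 1:0{width}d}", "".join(seq)))
    return transcripts


def plant_sites(
    transcriptome: Iterable[Transcript],
    cfg: SimConfig,
) -> SimTruth:
    """Plant DNA variants and editing sites; return the ground truth.

    Editing sites sit on editable bases (A on sense transcripts, T on
    antisense ones), within the read-length interior of the transcript so
    realized coverage at the site matches the nominal fold-coverage, and
    never on a DNA-variant position. ``kd_freq = control_freq * (1 -
    kd_reduction)``.
    """
    cfg.validate()
    transcripts = list(transcriptome)
    if not transcripts:
        raise SimConfigError("transcriptome must be non-empty")
    rng = _rng(cfg, 2)

    n_anti = int(round(cfg.antisense_fraction * len(transcripts)))
    anti_idx = rng.choice(len(transcripts), size=n_anti, replace=False) if n_anti else []
    antisense = {transcripts[int(i)].id for i in anti_idx}

    variants: list[DnaVariant] = []
    variant_pos: dict[str, set[int]] = {}
    for t in transcripts:
        hits = np.nonzero(rng.random(t.length) < cfg.dna_variant_rate)[0]
        variant_pos[t.id] = set(int(h) for h in hits)
        for pos in hits:
            ref = t.sequence[pos]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            lo, hi = cfg.dna_variant_freq_range
            freq = float(rng.uniform(lo, hi))
            variants.append(DnaVariant(t.id, int(pos), alt, freq))

    eligible: list[tuple[str, int, str, str]] = []
    for t in transcripts:
        target, alt = ("T", "C") if t.id in antisense else ("A", "G")
        codes = encode(t.sequence)
        lo = cfg.read_length
        hi = t.length - cfg.read_length
        for pos in np.nonzero(codes[lo:hi] == "ACGT".index(target))[0] + lo:
            if int(pos) not in variant_pos[t.id]:
                eligible.append((t.id, int(pos), target, alt))
    if cfg.n_edit_sites > len(eligible):
        raise SimConfigError(
            f"n_edit_sites={cfg.n_edit_sites} exceeds the {len(eligible)} eligible positions"
        )
    chosen = rng.choice(len(eligible), size=cfg.n_edit_sites, replace=False)

    labels: list[str] = []
    mix = cfg.dependency_mix or {"adar2": 1.0}
    total = sum(mix.values())
    n1 = int(round(cfg.n_edit_sites * mix.get("adar1", 0.0) / total)) if total else 0
    labels = ["adar1"] * n1 + ["adar2"] * (cfg.n_edit_sites - n1)
    rng.shuffle(labels)

    sites: list[EditSite] = []
    for k, idx in enumerate(sorted(int(c) for c in chosen)):
        tid, pos, ref, alt = eligible[idx]
        cf = float(rng.uniform(*cfg.control_freq_range))
        sites.append(
            EditSite(tid, pos, ref, alt, labels[k], cf, cf * (1.0 - cfg.kd_reduction))
        )
    sites.sort(key=lambda s: (s.transcript_id, s.pos))
    return SimTruth(edit_sites=sites, dna_variants=variants, antisense=antisense)


@dataclass
class ReadSet:
    """In-memory simulated sample: one matrix of encoded reads per transcript."""

    sample_id: str
    role: str
    reads: dict[str, tuple[np.ndarray, np.ndarray]]  # tid -> (starts, codes matrix)
    read_ids: dict[str, list[str]]
    planted: dict[str, list[tuple[int, ...]]]  # per-read planted site positions

    def n_reads(self) -> int:
        return sum(len(s) for s, _ in self.reads.values())

    def to_records(self, transcripts: Mapping[str, Transcript]) -> list[AlignmentRecord]:
        recs: list[AlignmentRecord] = []
        for tid, (starts, mat) in self.reads.items():
            ref_codes = encode(transcripts[tid].sequence)
            rl = mat.shape[1]
            for i, start in enumerate(starts):
                codes = mat[i]
                nm = int(np.sum(codes != ref_codes[start : start + rl]))
                recs.append(
                    AlignmentRecord(
                        read_id=self.read_ids[tid][i],
                        transcript_id=tid,
                        start=int(start),
                        cigar=[("M", rl)],
                        edit_distance=nm,
                        read_length=rl,
                        is_mapped=True,
                        seq="".join(BASES[c] for c in codes),
                    )
                )
        return recs


def _site_freq(site: EditSite, role: str) -> float:
    """Frequency at which reads of ``role`` carry the alternative base."""
    if role == "dna":
        return 0.0
    if role == f"kd_{site.dependency}":
        return site.kd_freq
    return site.control_freq


def simulate_reads(
    transcriptome: Iterable[Transcript],
    truth: SimTruth,
    role: str,
    replicate_index: int,
    cfg: SimConfig,
) -> ReadSet:
    """Draw one sample's reads (uniform starts, planted alts, uniform error)."""
    cfg.validate()
    if role not in ROLES:
        raise SimConfigError(f"role must be one of {ROLES}, got {role!r}")
    transcripts = list(transcriptome)
    coverage = cfg.coverage_dna if role == "dna" else cfg.coverage_rna
    sample_id = role if role == "dna" else f"{role}_{replicate_index + 1}"
    rng = _rng(cfg, 3, ROLES.index(role), replicate_index)
    rl = cfg.read_length
    sites_by_t = truth.sites_by_transcript()
    vars_by_t = truth.variants_by_transcript()

    reads: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    read_ids: dict[str, list[str]] = {}
    planted: dict[str, list[tuple[int, ...]]] = {}
    for t in transcripts:
        n = max(1, int(round(coverage * t.length / rl)))
        starts = np.sort(rng.integers(0, t.length - rl + 1, size=n))
        ref_codes = encode(t.sequence)
        mat = ref_codes[starts[:, None] + np.arange(rl)[None, :]].copy()
        flags: list[set[int]] = [set() for _ in range(n)]

        if role == "dna":
            for v in vars_by_t.get(t.id, []):
                rows = np.nonzero((starts <= v.pos) & (v.pos < starts + rl))[0]
                if rows.size:
                    hit = rows[rng.random(rows.size) < v.freq]
                    mat[hit, v.pos - starts[hit]] = "ACGT".index(v.alt)
        else:
            for s in sites_by_t.get(t.id, []):
                freq = _site_freq(s, role)
                rows = np.nonzero((starts <= s.pos) & (s.pos < starts + rl))[0]
                if rows.size and freq > 0:
                    hit = rows[rng.random(rows.size) < freq]
                    mat[hit, s.pos - starts[hit]] = "ACGT".index(s.alt)
                    for r in hit:
                        flags[int(r)].add(s.pos)

        if cfg.error_rate > 0:
            err = rng.random(mat.shape) < cfg.error_rate
            n_err = int(err.sum())
            if n_err:
                mat[err] = (mat[err] + rng.integers(1, 4, size=n_err)) % 4

        ids = [f"{sample_id}:{t.id}:{i:06d}" for i in range(n)]
        reads[t.id] = (starts, mat)
        read_ids[t.id] = ids
        planted[t.id] = [tuple(sorted(f)) for f in flags]
    return ReadSet(sample_id, role, reads, read_ids, planted)


def write_sample(
    readset: ReadSet,
    transcripts: Mapping[str, Transcript],
    fastq_path: str | Path,
    sam_path: str | Path,
    truth: SimTruth | None = None,
) -> None:
    """Write a ReadSet as Phred+33 FASTQ plus a true-alignment SAM.

    When ``truth`` is given, per-read origins (transcript, start, strand,
    planted-site positions) are recorded in ``truth.read_origins``.
    """
    records = readset.to_records(transcripts)
    with open(fastq_path, "w") as fq:
        for rec in records:
            fq.write(f"@{rec.read_id}\n{rec.seq}\n+\n{'I' * len(rec.seq)}\n")
    write_alignments(records, transcripts, sam_path)
    if truth is not None:
        for tid in readset.reads:
            starts, _ = readset.reads[tid]
            for i, rid in enumerate(readset.read_ids[tid]):
                truth.read_origins[rid] = (tid, int(starts[i]), "+", readset.planted[tid][i])


def simulate_sample(
    transcriptome: Iterable[Transcript],
    truth: SimTruth,
    role: str,
    replicate_index: int,
    cfg: SimConfig,
    out_dir: str | Path,
) -> tuple[Path, Path]:
    """Simulate one sample and write its FASTQ + SAM under ``out_dir``."""
    transcripts = {t.id: t for t in transcriptome}
    readset = simulate_reads(transcripts.values(), truth, role, replicate_index, cfg)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fq = out_dir / f"{readset.sample_id}.fastq"
    sam = out_dir / f"{readset.sample_id}.sam"
    write_sample(readset, transcripts, fq, sam, truth)
    return fq, sam


def simulate_experiment(cfg: SimConfig, out_dir: str | Path):
    """Full experiment: reference, truth, DNA sample, all RNA replicates.

    Returns ``(transcripts, truth, sample_paths)`` where ``sample_paths``
    maps sample id -> SAM path, grouped by role via the sample-id prefix.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    transcripts = generate_transcriptome(cfg)
    truth = plant_sites(transcripts, cfg)
    write_fasta(transcripts, out_dir / "reference.fasta")
    truth.write_tsv(out_dir / "truth_sites.tsv")
    truth.write_variants_tsv(out_dir / "truth_dna_variants.tsv")
    reads_dir = out_dir / "reads"
    paths: dict[str, Path] = {}
    _, sam = simulate_sample(transcripts, truth, "dna", 0, cfg, reads_dir)
    paths["dna"] = sam
    for role, n in (("control", cfg.n_control), ("kd_adar1", cfg.n_kd), ("kd_adar2", cfg.n_kd)):
        for rep in range(n):
            _, sam = simulate_sample(transcripts, truth, role, rep, cfg, reads_dir)
            paths[f"{role}_{rep + 1}"] = sam
    return transcripts, truth, paths
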