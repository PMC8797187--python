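"""ADAR-dependent editing-site calling via the control/knockdown contrast.

A candidate site is a transcript position with a non-consensus base in the
RNA. The caller is a deterministic filter cascade, applied per site/alt pair:

F1  the position is not masked by the DNA consensus (variant frequency or
    depth mask);
F2  every control replicate shows the mismatch at frequency >= 2%, with
    coverage >= 10 and >= 4 unique supporting reads (defaults);
F3  every replicate of the contrasted knockdown has coverage >= 4 and a
    mismatch frequency reduced by at least 50% relative to the mean control
    frequency (zero alternative reads trivially satisfy this).

No significance test or multiple-testing correction is involved; the
procedure stands or falls with its thresholds, which is why the module also
exposes an analytic detection-power calculation (`detection_power`).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import binom

from .consensus import BASES, ConsensusResult, PileupTable, encode

MISMATCH_CLASSES = tuple(
    f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a
)
SIGNATURE_CLASSES = ("A>G", "T>C")


class CallerError(ValueError):
    pass


@dataclass
class SampleSheet:
    """Sample roles mapped to alignment paths.

    ``controls`` and each knockdown condition are ordered replicate lists of
    sample ids; ``dna`` lists the genomic DNA libraries pooled for the
    consensus; ``paths`` maps every sample id to its SAM/BAM file.
    """

    controls: list[str]
    knockdowns: dict[str, list[str]]
    dna: list[str] = field(default_factory=list)
    paths: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.controls:
            raise CallerError("sample sheet needs at least one control replicate")
        if not self.knockdowns or not any(self.knockdowns.values()):
            raise CallerError("sample sheet needs at least one knockdown replicate")
        for cond, reps in self.knockdowns.items():
            if cond not in ("adar1", "adar2"):
                raise CallerError(f"unknown knockdown condition {cond!r}")
            if not reps:
                raise CallerError(f"knockdown condition {cond!r} has no replicates")
        missing = [
            s
            for s in self.all_samples()
            if self.paths and s not in self.paths
        ]
        if missing:
            raise CallerError(f"sample ids without paths: {missing}")

    def all_samples(self) -> list[str]:
        out = list(self.dna) + list(self.controls)
        for reps in self.knockdowns.values():
            out.extend(reps)
        return out

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SampleSheet":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        paths: dict[str, str] = {}

        def ids(entries) -> list[str]:
            out = []
            for e in entries or []:
                out.append(e["id"])
                if "path" in e:
                    paths[e["id"]] = e["path"]
            return out

        sheet = cls(
            controls=ids(data.get("controls")),
            knockdowns={c: ids(v) for c, v in (data.get("knockdowns") or {}).items()},
            dna=ids(data.get("dna")),
            paths=paths,
        )
        sheet.validate()
        return sheet

    def to_yaml(self, path: str | Path) -> None:
        def entries(ids: list[str]):
            return [
                {"id": s, **({"path": str(self.paths[s])} if s in self.paths else {})}
                for s in ids
            ]

        data = {
            "dna": entries(self.dna),
            "controls": entries(self.controls),
            "knockdowns": {c: entries(v) for c, v in self.knockdowns.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass(frozen=True)
class CallerConfig:
    """Thresholds of the filter cascade (paper defaults).

    ``per_replicate_control=False`` pools control evidence (frequency and
    unique support computed over all control reads; each control must still
    show at least one alternative read). ``per_replicate_reduction=False``
    compares mean knockdown frequency, instead of every replicate, to the
    reduced control mean.
    """

    control_min_freq: float = 0.02
    control_min_cov: int = 10
    min_support_reads: int = 4
    kd_min_cov: int = 4
    max_kd_to_control_ratio: float = 0.5
    dna_variant_max: float = 0.005
    min_dna_coverage: int = 4
    per_replicate_control: bool = True
    per_replicate_reduction: bool = True

    def __post_init__(self) -> None:
        for name in ("control_min_freq", "max_kd_to_control_ratio"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise CallerError(f"{name} must be in (0, 1], got {v}")
        for name in ("control_min_cov", "min_support_reads", "kd_min_cov", "min_dna_coverage"):
            v = getattr(self, name)
            if v < 1:
                raise CallerError(f"{name} must be >= 1, got {v}")
        if self.dna_variant_max < 0:
            raise CallerError(f"dna_variant_max must be >= 0, got {self.dna_variant_max}")


@dataclass(frozen=True)
class RepStat:
    """One replicate's evidence at one site."""

    sample_id: str
    depth: int
    alt_count: int
    support: int

    @property
    def freq(self) -> float:
        return self.alt_count / self.depth if self.depth else 0.0


@dataclass
class SiteCall:
    """A called ADAR-dependent site with its per-replicate evidence."""

    transcript_id: str
    pos: int  # 0-based internally; 1-based only in written tables
    ref: str
    alt: str
    dependency: str
    control_reps: list[RepStat]
    kd_reps: list[RepStat]

    @property
    def mismatch_class(self) -> str:
        return f"{self.ref}>{self.alt}"

    @property
    def mean_control_freq(self) -> float:
        return float(np.mean([r.freq for r in self.control_reps]))

    @property
    def mean_kd_freq(self) -> float:
        return float(np.mean([r.freq for r in self.kd_reps]))

    @property
    def reduction(self) -> float:
        mc = self.mean_control_freq
        return 1.0 - self.mean_kd_freq / mc if mc > 0 else 0.0


def mismatch_frequencies(
    pileups: Mapping[str, PileupTable],
    consensus: ConsensusResult,
) -> pd.DataFrame:
    """Per-sample, per-site mismatch table against the DNA consensus.

    One row per (sample, transcript, position, alternative base) with at
    least one supporting read at an unmasked position. Frequencies use the
    A/C/G/T depth; ``unique_support`` counts distinct read ids where they
    were collected and equals ``alt_count`` otherwise.
    """
    rows = []
    for sample_id, table in pileups.items():
        for tid, cons_t in consensus.transcripts.items():
            counts = table.count_matrix(tid)[:, :4]
            depth = counts.sum(axis=1)
            cons_codes = encode(cons_t.sequence).astype(np.int64)
            mask = consensus.masked[tid]
            alt = counts.copy()
            in_range = cons_codes < 4
            alt[np.arange(len(cons_codes))[in_range], cons_codes[in_range]] = 0
            pos_idx, base_idx = np.nonzero(alt > 0)
            for p, b in zip(pos_idx, base_idx):
                if mask[p]:
                    continue
                base = BASES[b]
                rows.append(
                    {
                        "sample_id": sample_id,
                        "transcript_id": tid,
                        "pos": int(p),
                        "ref": cons_t.sequence[p],
                        "alt": base,
                        "alt_count": int(alt[p, b]),
                        "depth": int(depth[p]),
                        "freq": float(alt[p, b] / depth[p]),
                        "unique_support": table.unique_support(tid, int(p), base),
                    }
                )
    cols = [
        "sample_id", "transcript_id", "pos", "ref", "alt",
        "alt_count", "depth", "freq", "unique_support",
    ]
    return pd.DataFrame(rows, columns=cols)


def _rep_stat(table: PileupTable, sample_id: str, tid: str, pos: int, alt: str) -> RepStat:
    counts = table.count_matrix(tid)
    depth = int(counts[pos, :4].sum())
    alt_count = int(counts[pos, "ACGT".index(alt)])
    return RepStat(sample_id, depth, alt_count, table.unique_support(tid, pos, alt))


def call_sites(
    pileups: Mapping[str, PileupTable],
    sheet: SampleSheet,
    condition: str,
    consensus: ConsensusResult,
    cfg: CallerConfig = CallerConfig(),
) -> list[SiteCall]:
    """Apply the F1-F3 cascade for one knockdown condition.

    Multiple alternative bases at one position are evaluated independently.
    Output is sorted by (transcript, position, alt) and fully deterministic.
    """
    sheet.validate()
    if condition not in sheet.knockdowns:
        raise CallerError(f"condition {condition!r} not in sample sheet")
    controls = sheet.controls
    kds = sheet.knockdowns[condition]
    missing = [s for s in controls + kds if s not in pileups]
    if missing:
        raise CallerError(f"no pileup provided for samples: {missing}")

    calls: list[SiteCall] = []
    for tid, cons_t in consensus.transcripts.items():
        cons_codes = encode(cons_t.sequence).astype(np.int64)
        mask = consensus.masked[tid]
        L = cons_t.length
        idx = np.arange(L)
        # candidate (pos, alt): alt present in every control, position unmasked
        present = np.ones((L, 4), dtype=bool)
        for s in controls:
            counts = pileups[s].count_matrix(tid)[:, :4]
            present &= counts > 0
        in_range = cons_codes < 4
        present[idx[in_range], cons_codes[in_range]] = False
        present[mask] = False
        for pos, b in zip(*np.nonzero(present)):
            pos = int(pos)
            alt = "ACGT"[b]
            ctrl = [_rep_stat(pileups[s], s, tid, pos, alt) for s in controls]
            if cfg.per_replicate_control:
                ok = all(
                    r.depth >= cfg.control_min_cov
                    and r.freq >= cfg.control_min_freq
                    and r.support >= cfg.min_support_reads
                    for r in ctrl
                )
            else:
                pooled_depth = sum(r.depth for r in ctrl)
                pooled_alt = sum(r.alt_count for r in ctrl)
                pooled_support = sum(r.support for r in ctrl)
                ok = (
                    all(r.depth >= cfg.control_min_cov and r.alt_count > 0 for r in ctrl)
                    and pooled_depth > 0
                    and pooled_alt / pooled_depth >= cfg.control_min_freq
                    and pooled_support >= cfg.min_support_reads
                )
            if not ok:
                continue
            kd = [_rep_stat(pileups[s], s, tid, pos, alt) for s in kds]
            mean_ctrl = float(np.mean([r.freq for r in ctrl]))
            ceiling = cfg.max_kd_to_control_ratio * mean_ctrl
            if not all(r.depth >= cfg.kd_min_cov for r in kd):
                continue
            if cfg.per_replicate_reduction:
                if not all(r.freq <= ceiling for r in kd):
                    continue
            else:
                if float(np.mean([r.freq for r in kd])) > ceiling:
                    continue
            calls.append(
                SiteCall(tid, pos, cons_t.sequence[pos], alt, condition, ctrl, kd)
            )
    calls.sort(key=lambda c: (c.transcript_id, c.pos, c.alt))
    return calls


@dataclass
class Spectrum:
    """Counts over the 12 mismatch classes plus the A-to-I signature share."""

    counts: dict[str, int]
    total: int

    @property
    def signature_count(self) -> int:
        return sum(self.counts[c] for c in SIGNATURE_CLASSES)

    @property
    def signature_fraction(self) -> float:
        return self.signature_count / self.total if self.total else 0.0


def spectrum(calls: Sequence[SiteCall]) -> Spectrum:
    counts = {c: 0 for c in MISMATCH_CLASSES}
    for call in calls:
        counts[call.mismatch_class] += 1
    return Spectrum(counts, len(calls))


def detection_power(
    freq: float,
    depth: float,
    cfg: CallerConfig = CallerConfig(),
    n_controls: int = 4,
) -> float:
    """P(a true site passes the control filters) under binomial sampling.

    At fixed per-replicate depth ``d`` and true editing frequency ``f``, a
    control replicate passes iff its alternative-read count reaches both the
    support floor and the frequency floor, so the per-replicate pass chance
    is ``P(X >= max(min_support, ceil(min_freq * d)))`` with
    ``X ~ Binomial(d, f)``; all controls must pass independently. Depth below
    ``control_min_cov`` gives zero power. This is the quantitative limit on
    recall at low coverage.
    """
    d = int(round(depth))
    if d < cfg.control_min_cov:
        return 0.0
    k_min = max(cfg.min_support_reads, int(np.ceil(cfg.control_min_freq * d)))
    p_rep = float(binom.sf(k_min - 1, d, freq))
    return p_rep ** n_controls


# -- output writers --------------------------------------------------------


def calls_to_frame(calls: Sequence[SiteCall]) -> pd.DataFrame:
    """Flat S4-style table, 1-based positions, per-replicate freq/depth columns."""
    rows = []
    for c in calls:
        row: dict[str, object] = {
            "transcript_id": c.transcript_id,
            "pos_1based": c.pos + 1,
            "ref": c.ref,
            "alt": c.alt,
            "mismatch_class": c.mismatch_class,
            "dependency": c.dependency,
        }
        for i, r in enumerate(c.control_reps, 1):
            row[f"control{i}_freq"] = round(r.freq, 6)
            row[f"control{i}_depth"] = r.depth
        for i, r in enumerate(c.kd_reps, 1):
            row[f"kd{i}_freq"] = round(r.freq, 6)
            row[f"kd{i}_depth"] = r.depth
        row["mean_control_freq"] = round(c.mean_control_freq, 6)
        row["mean_kd_freq"] = round(c.mean_kd_freq, 6)
        row["reduction"] = round(c.reduction, 6)
        rows.append(row)
    if not rows:
        return pd.DataFrame(
            columns=[
                "transcript_id", "pos_1based", "ref", "alt", "mismatch_class",
                "dependency", "mean_control_freq", "mean_kd_freq", "reduction",
            ]
        )
    return pd.DataFrame(rows)


def write_calls_tsv(
    calls: Sequence[SiteCall], path: str | Path, header_lines: list[str] | None = None
) -> None:
    df = calls_to_frame(calls)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_calls_vcf(
    calls: Sequence[SiteCall],
    reference_lengths: Mapping[str, int],
    path: str | Path,
) -> None:
    """Minimal VCF 4.2 rendering of the calls (one record per site/alt)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DEP,Number=1,Type=String,Description="ADAR dependency">\n')
        fh.write('##INFO=<ID=CF,Number=1,Type=Float,Description="Mean control editing frequency">\n')
        fh.write('##INFO=<ID=KF,Number=1,Type=Float,Description="Mean knockdown editing frequency">\n')
        fh.write('##INFO=<ID=RED,Number=1,Type=Float,Description="Fractional reduction in knockdown">\n')
        for tid, ln in reference_lengths.items():
            fh.write(f"##contig=<ID={tid},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            info = (
                f"DEP={c.dependency};CF={c.mean_control_freq:.4f};"
                f"KF={c.mean_kd_freq:.4f};RED={c.reduction:.4f}"
            )
            fh.write(f"{c.transcript_id}\t{c.pos + 1}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t{info}\n")


def write_spectrum_tsv(
    spec: Spectrum, path: str | Path, header_lines: list[str] | None = None
) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write("mismatch_class\tcount\n")
        for cls in MISMATCH_CLASSES:
            fh.write(f"{cls}\t{spec.counts[cls]}\n")
        fh.write(f"total\t{spec.total}\n")
        fh.write(f"signature_count\t{spec.signature_count}\n")
        fh.write(f"signature_fraction\t{spec.signature_fraction:.6g}\n")


def read_calls_tsv(path: str | Path) -> list[SiteCall]:
    """Rebuild SiteCalls from a written calls table (support set to alt count)."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError:
        return []
    calls: list[SiteCall] = []
    for _, row in df.iterrows():
        ctrl, kd = [], []
        for prefix, out in (("control", ctrl), ("kd", kd)):
            i = 1
            while f"{prefix}{i}_freq" in row.index and not pd.isna(row[f"{prefix}{i}_freq"]):
                depth = int(row[f"{prefix}{i}_depth"])
                alt_count = int(round(row[f"{prefix}{i}_freq"] * depth))
                out.append(RepStat(f"{prefix}{i}", depth, alt_count, alt_count))
                i += 1
        calls.append(
            SiteCall(
                transcript_id=str(row["transcript_id"]),
                pos=int(row["pos_1based"]) - 1,
                ref=str(row["ref"]),
                alt=str(row["alt"]),
                dependency=str(row["dependency"]),
                control_reps=ctrl,
                kd_reps=kd,
            )
        )
    return calls
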