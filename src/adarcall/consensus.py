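"""Pileups and the genomic-DNA consensus / variant mask.

The caller never trusts the assembled reference directly: a consensus is
re-called from genomic DNA reads so that germline variants are not mistaken
for RNA editing. Positions where the DNA shows a variant frequency above
``dna_variant_max`` (default 0.5%, strict >) or where DNA depth is below
``min_dna_coverage`` (default 4) are masked and never considered by the
editing caller. Uncovered positions are masked.

The pileup is count-based (one (L, 5) array per transcript, bases A/C/G/T/N).
A read contributes at most one base per reference position, so the base count
at a position equals the number of distinct supporting reads unless the same
read id occurs in several records; pass ``collect_read_ids=True`` to track
identities explicitly (used by small-scale oracles and the unique-support
filter on deduplicated data).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

from .alignio import AlignmentRecord, Transcript, write_fasta

BASES = "ACGTN"
BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}
_LUT = np.full(256, 4, dtype=np.uint8)
for _b, _i in BASE_TO_CODE.items():
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """ASCII sequence -> uint8 codes (A=0 C=1 G=2 T=3, anything else=4)."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class ConsensusError(ValueError):
    pass


@dataclass
class PileupColumn:
    """Per-position base tally; ``depth`` sums all five base classes."""

    transcript_id: str
    pos: int
    counts: dict[str, int]
    supporting_reads: dict[str, set[str]] | None = None

    @property
    def depth(self) -> int:
        return sum(self.counts.values())

    @property
    def acgt_depth(self) -> int:
        """Depth used for frequencies: N bases excluded."""
        return sum(self.counts[b] for b in "ACGT")


class PileupTable:
    """Count matrices per transcript plus optional supporting-read identities."""

    def __init__(
        self,
        reference: Mapping[str, Transcript],
        collect_read_ids: bool = False,
    ) -> None:
        self.reference = reference
        self.counts: dict[str, np.ndarray] = {}
        self.support: dict[str, dict[tuple[int, int], set[str]]] | None = (
            {} if collect_read_ids else None
        )
        self._chunks: dict[str, list[np.ndarray]] = {}

    # -- building ---------------------------------------------------------

    def add(self, rec: AlignmentRecord) -> None:
        if rec.transcript_id not in self.reference:
            raise ConsensusError(
                f"read {rec.read_id!r} maps to unknown transcript {rec.transcript_id!r}"
            )
        tid = rec.transcript_id
        L = self.reference[tid].length
        codes = encode(rec.seq)
        qpos, rpos = 0, rec.start
        for op, n in rec.cigar:
            if op in "M=X":
                block = codes[qpos : qpos + n].astype(np.int64)
                flat = (np.arange(rpos, rpos + n, dtype=np.int64) * 5) + block
                self._chunks.setdefault(tid, []).append(flat)
                if self.support is not None:
                    sup = self.support.setdefault(tid, {})
                    for k in range(n):
                        sup.setdefault((rpos + k, int(block[k])), set()).add(rec.read_id)
                qpos += n
                rpos += n
            elif op in "IS":
                qpos += n
            elif op in "DN":
                rpos += n
            # H, P consume nothing
        if rpos > L:
            raise ConsensusError(
                f"read {rec.read_id!r} overhangs transcript {tid} ({rpos} > {L})"
            )

    def add_all(self, records: Iterable[AlignmentRecord]) -> "PileupTable":
        for rec in records:
            self.add(rec)
        return self

    def _materialize(self) -> None:
        for tid, chunks in self._chunks.items():
            L = self.reference[tid].length
            flat = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.int64)
            add = np.bincount(flat, minlength=L * 5).reshape(L, 5)
            if tid in self.counts:
                self.counts[tid] += add.astype(np.int64)
            else:
                self.counts[tid] = add.astype(np.int64)
        self._chunks.clear()

    # -- access -----------------------------------------------------------

    def count_matrix(self, tid: str) -> np.ndarray:
        """(L, 5) base-count matrix for one transcript (zeros if uncovered)."""
        self._materialize()
        if tid not in self.counts:
            self.counts[tid] = np.zeros((self.reference[tid].length, 5), dtype=np.int64)
        return self.counts[tid]

    def acgt_depth(self, tid: str) -> np.ndarray:
        return self.count_matrix(tid)[:, :4].sum(axis=1)

    def unique_support(self, tid: str, pos: int, base: str) -> int:
        """Distinct reads carrying ``base`` at ``pos``.

        Falls back to the raw count when read ids were not collected (exact
        whenever each read id occurs in a single alignment record).
        """
        if self.support is not None:
            return len(self.support.get(tid, {}).get((pos, BASE_TO_CODE[base]), ()))
        return int(self.count_matrix(tid)[pos, BASE_TO_CODE[base]])

    def column(self, tid: str, pos: int) -> PileupColumn:
        row = self.count_matrix(tid)[pos]
        counts = {b: int(row[i]) for i, b in enumerate(BASES)}
        sup = None
        if self.support is not None:
            sup = {
                b: set(self.support.get(tid, {}).get((pos, i), set()))
                for i, b in enumerate(BASES)
            }
        return PileupColumn(tid, pos, counts, sup)

    def iter_columns(self, tid: str | None = None) -> Iterator[PileupColumn]:
        """Yield columns for covered positions only."""
        self._materialize()
        tids = [tid] if tid is not None else list(self.counts)
        for t in tids:
            covered = np.nonzero(self.count_matrix(t).sum(axis=1))[0]
            for pos in covered:
                yield self.column(t, int(pos))


def pileup(
    records: Iterable[AlignmentRecord],
    reference: Mapping[str, Transcript],
    region: tuple[str, int, int] | None = None,
    collect_read_ids: bool = False,
) -> PileupTable:
    """Build a pileup from (already filtered) alignment records.

    ``region=(tid, start, end)`` restricts to reads overlapping the interval.
    """
    table = PileupTable(reference, collect_read_ids=collect_read_ids)
    for rec in records:
        if not rec.is_mapped:
            continue
        if region is not None:
            tid, start, end = region
            if rec.transcript_id != tid or rec.end <= start or rec.start >= end:
                continue
        table.add(rec)
    return table


@dataclass(frozen=True)
class ConsensusConfig:
    """DNA mask thresholds: variant frequency cutoff (strict >) and depth floor."""

    dna_variant_max: float = 0.005
    min_dna_coverage: int = 4

    def __post_init__(self) -> None:
        if not 0.0 <= self.dna_variant_max < 1.0:
            raise ConsensusError(f"dna_variant_max must be in [0, 1), got {self.dna_variant_max}")
        if self.min_dna_coverage < 1:
            raise ConsensusError(f"min_dna_coverage must be >= 1, got {self.min_dna_coverage}")


@dataclass
class ConsensusResult:
    """DNA-based consensus sequences plus the per-position exclusion mask."""

    transcripts: dict[str, Transcript]
    variant_freq: dict[str, np.ndarray]
    dna_depth: dict[str, np.ndarray]
    masked: dict[str, np.ndarray]

    def sequence(self, tid: str) -> str:
        return self.transcripts[tid].sequence

    def base(self, tid: str, pos: int) -> str:
        return self.transcripts[tid].sequence[pos]

    def is_masked(self, tid: str, pos: int) -> bool:
        return bool(self.masked[tid][pos])

    def write_fasta(self, path: str | Path) -> None:
        write_fasta(self.transcripts.values(), path)

    def write_mask_bed(self, path: str | Path) -> None:
        """Masked positions as 0-based half-open BED intervals (merged runs)."""
        with open(path, "w") as fh:
            for tid, mask in self.masked.items():
                padded = np.concatenate([[False], mask, [False]])
                diff = np.diff(padded.astype(np.int8))
                starts = np.nonzero(diff == 1)[0]
                ends = np.nonzero(diff == -1)[0]
                for s, e in zip(starts, ends):
                    fh.write(f"{tid}\t{s}\t{e}\n")

    def write_mask_tsv(self, path: str | Path, header_lines: list[str] | None = None) -> None:
        """Masked positions, 1-based, with variant frequency and DNA depth."""
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            fh.write("transcript_id\tpos_1based\tvariant_freq\tdna_depth\n")
            for tid, mask in self.masked.items():
                for pos in np.nonzero(mask)[0]:
                    fh.write(
                        f"{tid}\t{pos + 1}\t{self.variant_freq[tid][pos]:.6g}"
                        f"\t{self.dna_depth[tid][pos]}\n"
                    )


def call_consensus(
    dna_pileup: PileupTable,
    reference: Mapping[str, Transcript],
    cfg: ConsensusConfig = ConsensusConfig(),
) -> ConsensusResult:
    """Call the per-transcript DNA consensus and the variant/depth mask.

    Consensus base is the plurality base over A/C/G/T (ties and uncovered
    positions resolve to the reference base). Variant frequency pools all
    non-consensus A/C/G/T bases. A position is masked iff its variant
    frequency exceeds ``dna_variant_max`` or its A/C/G/T depth is below
    ``min_dna_coverage``.
    """
    transcripts: dict[str, Transcript] = {}
    variant_freq: dict[str, np.ndarray] = {}
    dna_depth: dict[str, np.ndarray] = {}
    masked: dict[str, np.ndarray] = {}
    for tid, ref_t in reference.items():
        counts = dna_pileup.count_matrix(tid)[:, :4]
        depth = counts.sum(axis=1)
        ref_codes = encode(ref_t.sequence).astype(np.int64)
        best = counts.argmax(axis=1)
        best_count = counts.max(axis=1)
        # plurality with tie -> reference: accept argmax only if it strictly
        # beats the reference-base count, else keep the reference base
        ref_count = counts[np.arange(len(ref_codes)), np.minimum(ref_codes, 3)]
        n_best = (counts == best_count[:, None]).sum(axis=1)
        unique_winner = (best_count > ref_count) & (n_best == 1)
        cons_codes = np.where(unique_winner, best, ref_codes)
        cons_codes = np.where(depth == 0, ref_codes, cons_codes)
        cons_count = counts[np.arange(len(cons_codes)), np.minimum(cons_codes, 3)]
        with np.errstate(invalid="ignore", divide="ignore"):
            vf = np.where(depth > 0, (depth - cons_count) / np.maximum(depth, 1), 0.0)
        mask = (vf > cfg.dna_variant_max) | (depth < cfg.min_dna_coverage)
        seq = "".join(BASES[c] for c in cons_codes)
        transcripts[tid] = Transcript(tid, seq)
        variant_freq[tid] = vf
        dna_depth[tid] = depth
        masked[tid] = mask
    return ConsensusResult(transcripts, variant_freq, dna_depth, masked)
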