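"""Alignment I/O and per-read quality filters.

Reads mapped to a transcriptome reference are screened with two per-read
criteria before any pileup is built: gapped alignment identity and the
fraction of the read's length that is aligned. Both thresholds default to
0.80 and are inclusive (a read sitting exactly on a threshold passes).

Coordinates are 0-based half-open everywhere inside the package; conversion
to 1-based happens only when tables are written.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class AlignioError(ValueError):
    """Malformed alignment input or reference/header mismatch."""


@dataclass(frozen=True)
class Transcript:
    """A reference (or consensus) transcript sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise AlignioError(f"transcript {self.id!r} has empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


def load_fasta(path: str | Path) -> dict[str, Transcript]:
    """Load a FASTA reference into an ordered id -> Transcript mapping."""
    out: dict[str, Transcript] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise AlignioError(f"duplicate transcript id {rec.id!r} in {path}")
        out[rec.id] = Transcript(rec.id, str(rec.seq).upper())
    if not out:
        raise AlignioError(f"no sequences found in {path}")
    return out


def write_fasta(transcripts: Iterable[Transcript], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.id, description="") for t in transcripts
    ]
    SeqIO.write(records, str(path), "fasta")


# CIGAR op classes (SAM semantics). Soft clips consume the query and count
# toward read_length; hard clips consume nothing.
_QUERY_OPS = frozenset("MIS=X")
_REF_OPS = frozenset("MDN=X")
_ALIGN_QUERY_OPS = frozenset("MI=X")  # query bases inside the alignment
_MATCHLIKE_OPS = frozenset("M=X")
_CIGAR_OPS = "MIDNSHP=X"


@dataclass
class AlignmentRecord:
    """One mapped (or unmapped) read against a transcript.

    ``edit_distance`` is NM-style: substitutions plus inserted plus deleted
    bases. ``seq`` carries the query sequence when available; pileups need it.
    """

    read_id: str
    transcript_id: str | None
    start: int  # 0-based leftmost reference position
    cigar: list[tuple[str, int]]
    edit_distance: int
    read_length: int
    is_mapped: bool
    seq: str | None = None

    def op_total(self, ops: frozenset[str] | str) -> int:
        return sum(n for op, n in self.cigar if op in ops)

    @property
    def query_consumed(self) -> int:
        return self.op_total(_QUERY_OPS)

    @property
    def ref_consumed(self) -> int:
        return self.op_total(_REF_OPS)

    @property
    def end(self) -> int:
        """0-based exclusive rightmost reference position."""
        return self.start + self.ref_consumed

    def validate(self) -> None:
        if not self.is_mapped:
            return
        bad = [op for op, _ in self.cigar if op not in _CIGAR_OPS]
        if bad:
            raise AlignioError(f"read {self.read_id!r}: unknown CIGAR ops {bad}")
        if self.query_consumed != self.read_length:
            raise AlignioError(
                f"read {self.read_id!r}: CIGAR consumes {self.query_consumed} "
                f"query bases but read_length is {self.read_length}"
            )
        if self.edit_distance < 0:
            raise AlignioError(f"read {self.read_id!r}: negative edit distance")


@dataclass(frozen=True)
class ReadFilterConfig:
    """Inclusive minimum identity and aligned-length fraction thresholds."""

    min_identity: float = 0.80
    min_aligned_fraction: float = 0.80

    def __post_init__(self) -> None:
        for name in ("min_identity", "min_aligned_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise AlignioError(f"{name} must be in (0, 1], got {v}")


def _cigartuples_to_pairs(cigartuples) -> list[tuple[str, int]]:
    return [(_CIGAR_OPS[op], length) for op, length in cigartuples]


def _pairs_to_cigartuples(pairs: list[tuple[str, int]]) -> list[tuple[int, int]]:
    return [(_CIGAR_OPS.index(op), length) for op, length in pairs]


def _count_substitutions(rec: AlignmentRecord, ref_seq: str) -> int:
    """Substitutions by direct comparison against the reference (no NM tag)."""
    subs = 0
    qpos, rpos = 0, rec.start
    for op, n in rec.cigar:
        if op in _MATCHLIKE_OPS:
            for k in range(n):
                if rec.seq[qpos + k] != ref_seq[rpos + k]:
                    subs += 1
            qpos += n
            rpos += n
        elif op in "IS":
            qpos += n
        elif op in "DN":
            rpos += n
    return subs


def read_alignments(
    path: str | Path,
    reference: Mapping[str, Transcript],
) -> Iterator[AlignmentRecord]:
    """Stream AlignmentRecords from a SAM/BAM file.

    The file header's @SQ names must all be present in ``reference`` (with
    matching lengths); otherwise an error listing the offending ids is raised.
    Records lacking an NM tag get their edit distance recomputed against the
    reference.
    """
    path = str(path)
    with pysam.AlignmentFile(path, check_sq=False) as af:
        offending = [
            name
            for name, ln in zip(af.references, af.lengths)
            if name not in reference or reference[name].length != ln
        ]
        if offending:
            raise AlignioError(
                f"{path}: header @SQ entries not matching the reference: "
                + ", ".join(offending)
            )
        for seg in af:
            if seg.is_unmapped:
                yield AlignmentRecord(
                    read_id=seg.query_name,
                    transcript_id=None,
                    start=-1,
                    cigar=[],
                    edit_distance=0,
                    read_length=len(seg.query_sequence or ""),
                    is_mapped=False,
                    seq=seg.query_sequence,
                )
                continue
            if seg.cigartuples is None:
                raise AlignioError(f"read {seg.query_name!r}: mapped but no CIGAR")
            rec = AlignmentRecord(
                read_id=seg.query_name,
                transcript_id=seg.reference_name,
                start=seg.reference_start,
                cigar=_cigartuples_to_pairs(seg.cigartuples),
                edit_distance=0,
                read_length=seg.infer_read_length(),
                is_mapped=True,
                seq=seg.query_sequence,
            )
            if seg.has_tag("NM"):
                rec.edit_distance = int(seg.get_tag("NM"))
            elif rec.seq is not None:
                indel = rec.op_total("I") + rec.op_total("D")
                rec.edit_distance = indel + _count_substitutions(
                    rec, reference[rec.transcript_id].sequence
                )
            rec.validate()
            yield rec


def write_alignments(
    records: Iterable[AlignmentRecord],
    reference: Mapping[str, Transcript],
    path: str | Path,
) -> None:
    """Write records to SAM (text) with @SQ lines taken from the reference."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": t.id, "LN": t.length} for t in reference.values()],
    }
    tid_index = {t.id: i for i, t in enumerate(reference.values())}
    with pysam.AlignmentFile(str(path), "w", header=header) as af:
        for rec in records:
            seg = pysam.AlignedSegment(af.header)
            seg.query_name = rec.read_id
            seg.query_sequence = rec.seq
            if rec.seq is not None:
                seg.query_qualities = pysam.qualitystring_to_array("I" * len(rec.seq))
            if rec.is_mapped:
                seg.flag = 0
                seg.reference_id = tid_index[rec.transcript_id]
                seg.reference_start = rec.start
                seg.mapping_quality = 60
                seg.cigartuples = _pairs_to_cigartuples(rec.cigar)
                seg.set_tag("NM", rec.edit_distance)
            else:
                seg.flag = 4
                seg.reference_id = -1
                seg.reference_start = -1
            af.write(seg)


def alignment_identity(rec: AlignmentRecord) -> float:
    """Gapped identity: matched columns / alignment columns.

    Alignment columns are match-like plus inserted plus deleted columns;
    substitutions are inferred from the NM-style edit distance.
    """
    if not rec.is_mapped:
        raise AlignioError(f"read {rec.read_id!r}: identity undefined for unmapped read")
    matchlike = rec.op_total(_MATCHLIKE_OPS)
    ins = rec.op_total("I")
    dels = rec.op_total("D")
    columns = matchlike + ins + dels
    if columns == 0:
        raise AlignioError(f"read {rec.read_id!r}: zero-length alignment")
    subs = rec.edit_distance - ins - dels
    if subs < 0:
        raise AlignioError(
            f"read {rec.read_id!r}: NM={rec.edit_distance} inconsistent with "
            f"{ins} inserted + {dels} deleted bases"
        )
    return (matchlike - subs) / columns


def aligned_fraction(rec: AlignmentRecord) -> float:
    """Fraction of the read's bases that lie inside the alignment."""
    if not rec.is_mapped:
        raise AlignioError(f"read {rec.read_id!r}: aligned fraction undefined for unmapped read")
    if rec.read_length == 0:
        raise AlignioError(f"read {rec.read_id!r}: zero read length")
    return rec.op_total(_ALIGN_QUERY_OPS) / rec.read_length


@dataclass
class FilterReport:
    """Per-reason rejection counts; kept + rejected always equals total."""

    total: int = 0
    kept: int = 0
    unmapped: int = 0
    low_identity: int = 0
    low_aligned_fraction: int = 0

    @property
    def rejected(self) -> int:
        return self.unmapped + self.low_identity + self.low_aligned_fraction

    def as_dict(self) -> dict[str, int]:
        return dataclasses.asdict(self)


def filter_reads(
    records: Iterable[AlignmentRecord],
    cfg: ReadFilterConfig = ReadFilterConfig(),
) -> tuple[list[AlignmentRecord], FilterReport]:
    """Keep mapped reads meeting both thresholds (inclusive).

    A read failing both criteria is counted once, under identity, so the
    report's reason counts partition the rejected set.
    """
    kept: list[AlignmentRecord] = []
    report = FilterReport()
    for rec in records:
        report.total += 1
        if not rec.is_mapped:
            report.unmapped += 1
        elif alignment_identity(rec) < cfg.min_identity:
            report.low_identity += 1
        elif aligned_fraction(rec) < cfg.min_aligned_fraction:
            report.low_aligned_fraction += 1
        else:
            report.kept += 1
            kept.append(rec)
    return kept, report


def write_filter_report(report: FilterReport, path: str | Path, header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write("category\tcount\n")
        for key, val in report.as_dict().items():
            fh.write(f"{key}\t{val}\n")
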