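"""Site annotation: ORF-relative region, codon effect, sequence context.

ORFs are predicted as the longest forward-strand ATG...stop frame on the
DNA-corrected consensus sequence (ties broken 5'-most; default minimum 150
nt including the stop codon). Sites are classified into 5'UTR / CDS / 3'UTR
relative to that ORF; CDS sites get a codon-effect annotation (standard
genetic code); and the +/-5 nt context of all calls is tallied into a
position-count matrix suitable for sequence-logo drawing.

T>C sites are annotated on the transcript as assembled (no strand flip), so
their codon effects refer to the assembled transcript's frame.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .consensus import ConsensusResult
from .edcall import SiteCall

REGIONS = ("5'UTR", "CDS", "3'UTR", "no-ORF")
_STOPS = {"TAA", "TAG", "TGA"}


class AnnotateError(ValueError):
    pass


@dataclass(frozen=True)
class OrfAnnotation:
    """Longest predicted ORF, 0-based half-open, stop codon included."""

    transcript_id: str
    start: int
    end: int
    has_orf: bool

    @property
    def length(self) -> int:
        return self.end - self.start if self.has_orf else 0


def predict_orf(
    transcript_id: str,
    sequence: str,
    min_orf_length: int = 150,
) -> OrfAnnotation:
    """Longest forward-strand ATG->stop ORF (incl. stop); ties break 5'-most.

    Only ATG starts are considered; an ORF must terminate in an in-frame
    stop codon within the sequence to count.
    """
    seq = sequence.upper()
    L = len(seq)
    best_len, best_start, best_end = 0, -1, -1
    for frame in range(3):
        stops = [i for i in range(frame, L - 2, 3) if seq[i : i + 3] in _STOPS]
        starts = [i for i in range(frame, L - 2, 3) if seq[i : i + 3] == "ATG"]
        si = 0
        for a in starts:
            # first in-frame stop at or after this start (both lists ascend)
            while si < len(stops) and stops[si] < a:
                si += 1
            if si >= len(stops):
                break
            end = stops[si] + 3
            length = end - a
            if length > best_len or (length == best_len and a < best_start):
                best_len, best_start, best_end = length, a, end
    if best_len >= min_orf_length:
        return OrfAnnotation(transcript_id, best_start, best_end, True)
    return OrfAnnotation(transcript_id, -1, -1, False)


def classify_region(pos: int, orf: OrfAnnotation) -> str:
    """5'UTR / CDS / 3'UTR relative to the ORF; boundaries: start is CDS, end is 3'UTR."""
    if not orf.has_orf:
        return "no-ORF"
    if pos < orf.start:
        return "5'UTR"
    if pos < orf.end:
        return "CDS"
    return "3'UTR"


@dataclass(frozen=True)
class CodonEffect:
    codon_ref: str
    codon_alt: str
    aa_ref: str
    aa_alt: str
    effect: str  # "synonymous" | "nonsynonymous" | "NA"


def codon_effect(
    pos: int,
    ref: str,
    alt: str,
    orf: OrfAnnotation,
    sequence: str,
) -> CodonEffect:
    """Amino-acid consequence of substituting ``alt`` at ``pos`` within the CDS."""
    if classify_region(pos, orf) != "CDS":
        return CodonEffect("", "", "", "", "NA")
    if sequence[pos].upper() != ref.upper():
        raise AnnotateError(
            f"reference base mismatch at {orf.transcript_id}:{pos}: "
            f"sequence has {sequence[pos]!r}, site says {ref!r}"
        )
    offset = (pos - orf.start) % 3
    cstart = pos - offset
    codon_ref = sequence[cstart : cstart + 3].upper()
    codon_alt = codon_ref[:offset] + alt.upper() + codon_ref[offset + 1 :]
    aa_ref = str(Seq(codon_ref).translate())
    aa_alt = str(Seq(codon_alt).translate())
    effect = "synonymous" if aa_ref == aa_alt else "nonsynonymous"
    return CodonEffect(codon_ref, codon_alt, aa_ref, aa_alt, effect)


@dataclass
class ContextMatrix:
    """Base counts at positions -flank..+flank around the called sites.

    ``counts`` has shape (4, 2*flank+1), rows A/C/G/T. Sites whose window
    runs off the transcript are skipped only for the truncated columns, so
    each column sum is at most ``n_sites``.
    """

    counts: np.ndarray
    n_sites: int
    flank: int = 5

    @property
    def positions(self) -> list[int]:
        return list(range(-self.flank, self.flank + 1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list("ACGT"), columns=self.positions)

    def write_tsv(self, path: str | Path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            self.to_frame().rename_axis("base").to_csv(fh, sep="\t")

    def write_pfm(self, path: str | Path) -> None:
        """Plain position-frequency-matrix text (rows A/C/G/T), logo-ready."""
        with open(path, "w") as fh:
            for i, base in enumerate("ACGT"):
                fh.write(base + "  [ " + " ".join(str(int(c)) for c in self.counts[i]) + " ]\n")


def context_matrix(
    calls: Sequence[SiteCall],
    sequences: Mapping[str, str],
    flank: int = 5,
) -> ContextMatrix:
    """Tally the (2*flank+1)-mer around each call per position."""
    w = 2 * flank + 1
    counts = np.zeros((4, w), dtype=np.int64)
    for c in calls:
        seq = sequences[c.transcript_id]
        for col, pos in enumerate(range(c.pos - flank, c.pos + flank + 1)):
            if 0 <= pos < len(seq):
                b = seq[pos].upper()
                if b in "ACGT":
                    counts["ACGT".index(b), col] += 1
    return ContextMatrix(counts, len(calls), flank)


@dataclass
class SiteAnnotation:
    site: SiteCall
    region: str
    codon: CodonEffect


def annotate_sites(
    calls: Sequence[SiteCall],
    consensus: ConsensusResult,
    min_orf_length: int = 150,
) -> tuple[list[SiteAnnotation], dict[str, OrfAnnotation]]:
    """ORF-classify every call and compute codon effects for CDS sites."""
    orfs: dict[str, OrfAnnotation] = {}
    annotations: list[SiteAnnotation] = []
    for c in calls:
        if c.transcript_id not in orfs:
            orfs[c.transcript_id] = predict_orf(
                c.transcript_id, consensus.sequence(c.transcript_id), min_orf_length
            )
        orf = orfs[c.transcript_id]
        region = classify_region(c.pos, orf)
        if region == "CDS":
            eff = codon_effect(c.pos, c.ref, c.alt, orf, consensus.sequence(c.transcript_id))
        else:
            eff = CodonEffect("", "", "", "", "NA")
        annotations.append(SiteAnnotation(c, region, eff))
    return annotations, orfs


def annotations_to_frame(annotations: Sequence[SiteAnnotation]) -> pd.DataFrame:
    rows = []
    for a in annotations:
        rows.append(
            {
                "transcript_id": a.site.transcript_id,
                "pos_1based": a.site.pos + 1,
                "ref": a.site.ref,
                "alt": a.site.alt,
                "region": a.region,
                "codon_ref": a.codon.codon_ref,
                "codon_alt": a.codon.codon_alt,
                "aa_ref": a.codon.aa_ref,
                "aa_alt": a.codon.aa_alt,
                "effect": a.codon.effect,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "pos_1based", "ref", "alt", "region",
            "codon_ref", "codon_alt", "aa_ref", "aa_alt", "effect",
        ],
    )


def write_annotations_tsv(
    annotations: Sequence[SiteAnnotation],
    path: str | Path,
    header_lines: list[str] | None = None,
) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        annotations_to_frame(annotations).to_csv(fh, sep="\t", index=False)


def write_orfs_bed(orfs: Mapping[str, OrfAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tid, orf in sorted(orfs.items()):
            if orf.has_orf:
                fh.write(f"{tid}\t{orf.start}\t{orf.end}\tORF\t0\t+\n")


def write_orfs_gff3(orfs: Mapping[str, OrfAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tid, orf in sorted(orfs.items()):
            if orf.has_orf:
                fh.write(
                    f"{tid}\tadarcall\tCDS\t{orf.start + 1}\t{orf.end}\t.\t+\t0\t"
                    f"ID=orf_{tid}\n"
                )
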