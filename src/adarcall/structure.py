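"""Secondary-structure pairing state and dsRNA-stretch length at edit sites.

ADARs act on double-stranded RNA, so a called site's structural context is
summarized by two quantities: whether the site is base-paired in the
predicted secondary structure, and the length of the dsRNA stretch that
contains it — the longest sequence interval around the site whose endpoint
positions are paired and in which at least ``min_paired_frac`` (default
80%) of positions are paired; "long" means more than 3 nt by default.

The built-in folding engine is a deterministic base-pair-maximization
dynamic program (Watson-Crick plus G.U wobble pairs, hairpin loops of at
least ``min_loop`` unpaired bases). Structures produced by a thermodynamic
folder such as RNAfold can be supplied instead as dot-bracket files; the
pairing and stretch logic is engine-agnostic.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

try:  # JIT keeps whole-transcript folding tractable; plain Python works too
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]

from .edcall import SiteCall


class StructureError(ValueError):
    pass


_RNA_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}


def _pair_matrix(allow_gu: bool = True) -> np.ndarray:
    m = np.zeros((4, 4), dtype=np.bool_)
    for a, b in (("A", "U"), ("G", "C")):
        m[_RNA_CODE[a], _RNA_CODE[b]] = m[_RNA_CODE[b], _RNA_CODE[a]] = True
    if allow_gu:
        m[_RNA_CODE["G"], _RNA_CODE["U"]] = m[_RNA_CODE["U"], _RNA_CODE["G"]] = True
    return m


@dataclass(frozen=True)
class StructureConfig:
    """Folding and stretch parameters.

    ``min_paired_frac``: minimum paired fraction inside a dsRNA stretch.
    ``long_stretch_threshold``: a stretch is "long" if strictly longer.
    ``min_loop``: minimum unpaired bases in a hairpin loop.
    ``window_cap``: if set, fold only a window of this length centred on
    each site instead of the whole transcript.
    ``stretch_window``: stretch search is confined to this many nt on each
    side of the site.
    """

    engine: str = "builtin"
    min_paired_frac: float = 0.8
    long_stretch_threshold: int = 3
    min_loop: int = 3
    window_cap: int | None = None
    stretch_window: int = 500
    allow_gu: bool = True

    def __post_init__(self) -> None:
        if self.engine not in ("builtin", "external-file"):
            raise StructureError(f"engine must be builtin or external-file, got {self.engine!r}")
        if not 0.0 < self.min_paired_frac <= 1.0:
            raise StructureError(f"min_paired_frac must be in (0, 1], got {self.min_paired_frac}")
        for name in ("long_stretch_threshold", "min_loop", "stretch_window"):
            if getattr(self, name) < 0:
                raise StructureError(f"{name} must be non-negative")


@dataclass
class SecondaryStructure:
    """Pairing map over a transcript window (0-based half-open coordinates).

    ``partner[i]`` is the window-relative partner index, or -1 if unpaired.
    """

    transcript_id: str | None
    window: tuple[int, int]
    partner: np.ndarray
    sequence: str | None = None

    def __post_init__(self) -> None:
        start, end = self.window
        if end - start != len(self.partner):
            raise StructureError("window length does not match pairing map")
        self.validate()

    def validate(self) -> None:
        p = self.partner
        paired = np.nonzero(p >= 0)[0]
        if not np.all(p[p[paired]] == paired):
            raise StructureError("pairing map is not an involution")

    @property
    def dot_bracket(self) -> str:
        out = []
        for i, j in enumerate(self.partner):
            out.append("." if j < 0 else ("(" if j > i else ")"))
        return "".join(out)

    @property
    def n_pairs(self) -> int:
        return int(np.count_nonzero(self.partner >= 0) // 2)


def _encode_rna(sequence: str) -> np.ndarray:
    codes = np.empty(len(sequence), dtype=np.int8)
    for i, ch in enumerate(sequence.upper()):
        if ch not in _RNA_CODE:
            raise StructureError(f"non-nucleotide character {ch!r} at position {i}")
        codes[i] = _RNA_CODE[ch]
    return codes


@njit(cache=False)
def _nussinov_table(codes, pairmat, min_loop):  # pragma: no cover - jitted
    n = codes.size
    N = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = N[i, j - 1]
            for k in range(i, j - min_loop):
                if pairmat[codes[k], codes[j]]:
                    v = 1
                    if k > i:
                        v += N[i, k - 1]
                    if k + 1 <= j - 1:
                        v += N[k + 1, j - 1]
                    if v > best:
                        best = v
            N[i, j] = best
    return N


def _traceback(N: np.ndarray, codes: np.ndarray, pairmat: np.ndarray, min_loop: int) -> np.ndarray:
    """Deterministic traceback: pairing j (smallest partner k) beats leaving it unpaired."""
    n = len(codes)
    partner = np.full(n, -1, dtype=np.int64)
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop or N[i, j] == 0:
            continue
        paired = False
        for k in range(i, j - min_loop):
            if not pairmat[codes[k], codes[j]]:
                continue
            v = 1
            if k > i:
                v += N[i, k - 1]
            if k + 1 <= j - 1:
                v += N[k + 1, j - 1]
            if v == N[i, j]:
                partner[k], partner[j] = j, k
                if k > i:
                    stack.append((i, k - 1))
                if k + 1 <= j - 1:
                    stack.append((k + 1, j - 1))
                paired = True
                break
        if not paired:
            stack.append((i, j - 1))
    return partner


def fold_builtin(
    sequence: str,
    cfg: StructureConfig = StructureConfig(),
    transcript_id: str | None = None,
    window: tuple[int, int] | None = None,
) -> SecondaryStructure:
    """Fold by base-pair maximization (Watson-Crick + optional G.U wobble)."""
    codes = _encode_rna(sequence)
    pairmat = _pair_matrix(cfg.allow_gu)
    if len(codes) == 0:
        raise StructureError("cannot fold an empty sequence")
    if len(codes) <= cfg.min_loop:
        partner = np.full(len(codes), -1, dtype=np.int64)
    else:
        N = _nussinov_table(codes, pairmat, cfg.min_loop)
        partner = _traceback(N, codes, pairmat, cfg.min_loop)
    win = window if window is not None else (0, len(codes))
    return SecondaryStructure(transcript_id, win, partner, sequence)


def parse_dot_bracket(notation: str) -> np.ndarray:
    """Partner map from dot-bracket text; rejects pseudoknot notation."""
    partner = np.full(len(notation), -1, dtype=np.int64)
    stack: list[int] = []
    for i, ch in enumerate(notation):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            partner[i], partner[j] = j, i
        elif ch != ".":
            raise StructureError(
                f"unsupported character {ch!r} at position {i} "
                "(pseudoknot brackets are not supported)"
            )
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[-1]}")
    return partner


def load_external_structure(
    path: str | Path,
    transcript_id: str | None = None,
    window: tuple[int, int] | None = None,
) -> SecondaryStructure:
    """Load a Vienna-style dot-bracket file.

    Accepts an optional ``>`` header line, an optional sequence line, and a
    structure line (a trailing energy annotation like ``(-12.30)`` after
    whitespace is ignored).
    """
    name, sequence, notation = transcript_id, None, None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is None:
                name = line[1:].split()[0] if line[1:].split() else None
            continue
        token = line.split()[0]
        if set(token) <= set("().") and notation is None:
            notation = token
        elif sequence is None and notation is None:
            sequence = token.upper()
    if notation is None:
        raise StructureError(f"no dot-bracket line found in {path}")
    if sequence is not None and len(sequence) != len(notation):
        raise StructureError(
            f"{path}: sequence length {len(sequence)} != structure length {len(notation)}"
        )
    partner = parse_dot_bracket(notation)
    win = window if window is not None else (0, len(notation))
    return SecondaryStructure(name, win, partner, sequence)


def site_pairing(structure: SecondaryStructure, pos: int) -> tuple[bool, int | None]:
    """Pairing state of an absolute transcript position; partner is absolute too."""
    start, end = structure.window
    if not start <= pos < end:
        raise StructureError(f"position {pos} outside structure window [{start}, {end})")
    j = int(structure.partner[pos - start])
    if j < 0:
        return False, None
    return True, j + start


def helix_stretch(
    structure: SecondaryStructure,
    pos: int,
    cfg: StructureConfig = StructureConfig(),
) -> int:
    """Length of the dsRNA stretch containing ``pos`` (0 if unpaired).

    The stretch is the longest interval [a, b] containing the site whose
    endpoints are paired and whose paired fraction is at least
    ``min_paired_frac``; the search is confined to ``stretch_window`` nt on
    each side of the site.
    """
    paired_here, _ = site_pairing(structure, pos)
    if not paired_here:
        return 0
    start, _ = structure.window
    rel = pos - start
    n = len(structure.partner)
    lo = max(0, rel - cfg.stretch_window)
    hi = min(n, rel + cfg.stretch_window + 1)
    paired = (structure.partner[lo:hi] >= 0).astype(np.int64)
    p = rel - lo
    csum = np.concatenate([[0], np.cumsum(paired)])
    b_idx = np.nonzero(paired[p:])[0] + p  # candidate right endpoints (paired)
    best = 1
    for a in range(p + 1):
        if not paired[a]:
            continue
        lens = b_idx - a + 1
        fracs = (csum[b_idx + 1] - csum[a]) / lens
        ok = fracs >= cfg.min_paired_frac
        if ok.any():
            best = max(best, int(lens[ok].max()))
    return best


@dataclass
class StructureAnnotation:
    site: SiteCall
    paired: bool
    partner: int | None
    stretch_len: int
    in_long_stretch: bool


def annotate_structure(
    calls: Sequence[SiteCall],
    sequences: Mapping[str, str],
    cfg: StructureConfig = StructureConfig(),
    structures: Mapping[str, SecondaryStructure] | None = None,
) -> list[StructureAnnotation]:
    """Fold each called transcript (or use supplied structures) and annotate sites.

    With ``window_cap`` set, a window of that length centred on each site is
    folded instead of the full transcript — a tractability knob for long
    transcripts.
    """
    out: list[StructureAnnotation] = []
    folded: dict[str, SecondaryStructure] = dict(structures or {})
    for c in calls:
        seq = sequences[c.transcript_id]
        if c.transcript_id in folded:
            st = folded[c.transcript_id]
        elif cfg.window_cap is not None and cfg.window_cap < len(seq):
            half = cfg.window_cap // 2
            lo = max(0, min(c.pos - half, len(seq) - cfg.window_cap))
            st = fold_builtin(
                seq[lo : lo + cfg.window_cap], cfg, c.transcript_id,
                window=(lo, lo + cfg.window_cap),
            )
        else:
            st = fold_builtin(seq, cfg, c.transcript_id)
            folded[c.transcript_id] = st
        paired, partner = site_pairing(st, c.pos)
        stretch = helix_stretch(st, c.pos, cfg) if paired else 0
        out.append(
            StructureAnnotation(
                c, paired, partner, stretch, stretch > cfg.long_stretch_threshold
            )
        )
    return out


def structure_to_frame(annotations: Sequence[StructureAnnotation]):
    import pandas as pd

    rows = [
        {
            "transcript_id": a.site.transcript_id,
            "pos_1based": a.site.pos + 1,
            "paired": a.paired,
            "partner_1based": (a.partner + 1) if a.partner is not None else 0,
            "stretch_len": a.stretch_len,
            "in_long_stretch": a.in_long_stretch,
        }
        for a in annotations
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "pos_1based", "paired",
            "partner_1based", "stretch_len", "in_long_stretch",
        ],
    )


def write_structure_tsv(
    annotations: Sequence[StructureAnnotation],
    path: str | Path,
    header_lines: list[str] | None = None,
) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        structure_to_frame(annotations).to_csv(fh, sep="\t", index=False)


def write_dot_bracket(structure: SecondaryStructure, path: str | Path) -> None:
    with open(path, "w") as fh:
        if structure.transcript_id:
            fh.write(f">{structure.transcript_id}\n")
        if structure.sequence is not None:
            fh.write(structure.sequence + "\n")
        fh.write(structure.dot_bracket + "\n")
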