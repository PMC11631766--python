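"""Position matrices, exact p-value scanning, and composite off-target search.

A position probability matrix (PPM) built from aligned target sites is
turned into a log-odds position weight matrix (PWM) against a background
model; sequences are scanned on both strands for windows whose score has a
background-model p-value P(S >= s) at or below a threshold. The p-value is
exact for the bin-discretized matrix, computed by dynamic-programming
convolution of the per-position score distributions (the classic
matrix-scan approach).

The off-target search is a composite scan: a lox-like core (two half-site
matrices joined by a fixed-length unscored spacer, or one full-width
matrix) plus a flank constraint — ZF motifs within a set distance of the
lox boundaries, upstream on the reverse strand and downstream on the
forward strand, matching the geometry of a ZFD-recombinase fusion's
designed landing pads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._seq import DNA, encode, revcomp

__all__ = [
    "Ppm",
    "Pwm",
    "MotifHit",
    "LoxHit",
    "LoxFlankHit",
    "FlankSides",
    "CloneMutationTable",
    "build_ppm",
    "ppm_to_pwm",
    "pwm_pvalue",
    "scan_sequence",
    "scan_lox_candidates",
    "flank_constrained_scan",
    "tally_clone_mutations",
    "write_meme",
    "read_meme",
]

UNIFORM = np.full(4, 0.25)


@dataclass
class Ppm:
    """Per-position base probabilities over A,C,G,T (columns sum to 1)."""

    matrix: np.ndarray  # shape (width, 4)
    pseudocount: float = 0.0
    n_sequences: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PPM matrix must have shape (width, 4)")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("PPM columns must each sum to 1")
        if self.pseudocount > 0 and (self.matrix <= 0).any():
            raise ValueError("PPM with pseudocount > 0 must be strictly positive")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(DNA[i] for i in self.matrix.argmax(axis=1))


def build_ppm(aligned_sequences: Sequence[str], pseudocount: float = 0.1) -> Ppm:
    """PPM from equal-length aligned sites: (count + c) / (n + 4c)."""
    if not aligned_sequences:
        raise ValueError("no sequences")
    w = len(aligned_sequences[0])
    if any(len(s) != w for s in aligned_sequences):
        raise ValueError("aligned sequences must be equal length")
    counts = np.zeros((w, 4))
    for s in aligned_sequences:
        codes = encode(s)
        if (codes > 3).any():
            raise ValueError(f"non-ACGT character in {s}")
        counts[np.arange(w), codes] += 1
    n = len(aligned_sequences)
    return Ppm(
        matrix=(counts + pseudocount) / (n + 4 * pseudocount),
        pseudocount=pseudocount,
        n_sequences=n,
    )


@dataclass
class Pwm:
    """Log2-odds weight matrix against a background base distribution."""

    matrix: np.ndarray  # shape (width, 4), log2(p/bg)
    background: np.ndarray = field(default_factory=lambda: UNIFORM.copy())
    _dist_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (width, 4)")
        if not np.isclose(self.background.sum(), 1.0) or (self.background <= 0).any():
            raise ValueError("background must be strictly positive and sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def min_score(self) -> float:
        return float(self.matrix.min(axis=1).sum())

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())

    def score(self, word: str) -> float:
        codes = encode(word)
        if codes.size != self.width or (codes > 3).any():
            raise ValueError("word must be ACGT of matrix width")
        return float(self.matrix[np.arange(self.width), codes].sum())


def ppm_to_pwm(ppm: Ppm, background: Sequence[float] = UNIFORM) -> Pwm:
    """Standard log-odds transform value = log2(p / bg)."""
    bg = np.asarray(background, dtype=float)
    if (ppm.matrix <= 0).any():
        raise ValueError("PPM has zero probabilities; build it with a pseudocount")
    return Pwm(matrix=np.log2(ppm.matrix / bg[None, :]), background=bg)


def _score_distribution(pwm: Pwm, bin_width: float) -> tuple[np.ndarray, int, np.ndarray]:
    """(survival function, integer offset, integer matrix) for binned scores.

    Index i of the survival array corresponds to integer score offset + i;
    sf[i] = P(sum of binned per-position scores >= offset + i) under the
    background model.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    key = bin_width
    if key in pwm._dist_cache:
        return pwm._dist_cache[key]
    imat = np.rint(pwm.matrix / bin_width).astype(np.int64)
    mins = imat.min(axis=1)
    maxs = imat.max(axis=1)
    offset = int(mins.sum())
    span = int((maxs - mins).sum()) + 1
    pmf = np.zeros(span)
    pmf[0] = 1.0
    cur_len = 1
    base = 0  # running sum of per-position minima already folded in
    for j in range(pwm.width):
        new_len = cur_len + int(maxs[j] - mins[j])
        new = np.zeros(new_len)
        for b in range(4):
            off = int(imat[j, b] - mins[j])
            new[off : off + cur_len] += pmf[:cur_len] * pwm.background[b]
        pmf[:new_len] = new
        cur_len = new_len
    sf = np.cumsum(pmf[:cur_len][::-1])[::-1]
    result = (sf, offset, imat)
    pwm._dist_cache[key] = result
    return result


def pwm_pvalue(pwm: Pwm, score: float, bin_width: float = 0.001) -> float:
    """Exact p-value P(S >= score) under the background model.

    Computed on the bin-discretized matrix; a conservative half-width slack
    (ceil(width/2) bins) absorbs the rounding difference between binning the
    summed score and summing the binned matrix, so the result is monotone
    non-increasing in score, equals 1 at the minimum score, and matches
    exhaustive enumeration within the discretization error.
    """
    sf, offset, _ = _score_distribution(pwm, bin_width)
    slack = math.ceil(pwm.width / 2)
    idx = int(np.rint(score / bin_width)) - slack - offset
    if idx <= 0:
        return 1.0
    if idx >= sf.size:
        idx = sf.size - 1
    return float(max(sf[idx], 0.0))


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    start: int  # 0-based on the forward strand
    strand: str
    score: float
    p_value: float
    width: int

    @property
    def end(self) -> int:
        return self.start + self.width


def _window_scores(matrix: np.ndarray, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores of all windows and a validity mask (no non-ACGT base)."""
    w = matrix.shape[0]
    n = codes.size - w + 1
    if n <= 0:
        return np.empty(0), np.empty(0, dtype=bool)
    wins = np.lib.stride_tricks.sliding_window_view(codes, w)
    valid = (wins <= 3).all(axis=1)
    safe = np.where(wins > 3, 0, wins)
    scores = matrix[np.arange(w)[None, :], safe].sum(axis=1)
    return scores, valid


def scan_sequence(
    pwm: Pwm,
    sequence: str,
    p_threshold: float = 0.001,
    strand_mode: str = "both",
    seq_id: str = "seq",
    bin_width: float = 0.001,
) -> list[MotifHit]:
    """All windows (both strands by default) with p-value <= threshold.

    Coordinates are 0-based forward-strand starts; windows containing
    non-ACGT bases are skipped.
    """
    if strand_mode not in ("both", "forward", "reverse"):
        raise ValueError("strand_mode must be 'both', 'forward' or 'reverse'")
    if len(sequence) < pwm.width:
        return []
    sf, offset, _ = _score_distribution(pwm, bin_width)
    slack = math.ceil(pwm.width / 2)

    def pvals(scores: np.ndarray) -> np.ndarray:
        idx = np.rint(scores / bin_width).astype(np.int64) - slack - offset
        idx = np.clip(idx, 0, sf.size - 1)
        p = sf[idx]
        p[idx <= 0] = 1.0
        return p

    hits: list[MotifHit] = []
    strands = {"both": ("+", "-"), "forward": ("+",), "reverse": ("-",)}[strand_mode]
    L = len(sequence)
    for strand in strands:
        seq = sequence if strand == "+" else revcomp(sequence)
        scores, valid = _window_scores(pwm.matrix, encode(seq))
        if scores.size == 0:
            continue
        p = pvals(scores)
        for i in np.flatnonzero(valid & (p <= p_threshold)):
            start = int(i) if strand == "+" else L - pwm.width - int(i)
            hits.append(
                MotifHit(seq_id, start, strand, float(scores[i]), float(p[i]), pwm.width)
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


@dataclass(frozen=True)
class LoxHit:
    """A composite lox-like match: left half + fixed-length spacer + right half."""

    seq_id: str
    start: int  # forward-strand start of the whole composite
    strand: str
    score: float  # sum of the two half scores
    p_left: float
    p_right: float
    width: int  # left width + spacer + right width

    @property
    def end(self) -> int:
        return self.start + self.width


def scan_lox_candidates(
    left_half_ppm: Ppm,
    right_half_ppm: Ppm,
    spacer_length: int,
    sequence: str,
    p_threshold: float = 0.001,
    background: Sequence[float] = UNIFORM,
    seq_id: str = "seq",
    bin_width: float = 0.001,
) -> list[LoxHit]:
    """Composite scan with two half-site matrices around an unscored spacer.

    Each half must independently pass the p-value threshold (conservative
    AND combination); the composite score is the sum of half scores. For a
    full-width single-matrix search use :func:`scan_sequence` directly.
    """
    if spacer_length < 0:
        raise ValueError("spacer_length must be >= 0")
    lw = left_half_ppm.width
    rw = right_half_ppm.width
    width = lw + spacer_length + rw
    if len(sequence) < width:
        raise ValueError("sequence shorter than composite width")
    left_pwm = ppm_to_pwm(left_half_ppm, background)
    right_pwm = ppm_to_pwm(right_half_ppm, background)
    hits: list[LoxHit] = []
    L = len(sequence)
    for strand in ("+", "-"):
        seq = sequence if strand == "+" else revcomp(sequence)
        lhits = {
            h.start: h
            for h in scan_sequence(
                left_pwm, seq, p_threshold, "forward", seq_id, bin_width
            )
        }
        rhits = {
            h.start: h
            for h in scan_sequence(
                right_pwm, seq, p_threshold, "forward", seq_id, bin_width
            )
        }
        for s, lh in lhits.items():
            rh = rhits.get(s + lw + spacer_length)
            if rh is None:
                continue
            start = s if strand == "+" else L - width - s
            hits.append(
                LoxHit(
                    seq_id,
                    start,
                    strand,
                    lh.score + rh.score,
                    lh.p_value,
                    rh.p_value,
                    width,
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


class FlankSides(str, Enum):
    BOTH = "both"
    LEFT = "left"
    RIGHT = "right"


@dataclass(frozen=True)
class LoxFlankHit:
    """A lox hit with ZF-motif matches at the constrained flank distances."""

    lox: LoxHit
    left_flank: Optional[MotifHit]
    right_flank: Optional[MotifHit]
    left_distance: Optional[int]
    right_distance: Optional[int]
    sides: FlankSides


def _best_flank(cands: list[tuple[int, MotifHit]]) -> Optional[tuple[int, MotifHit]]:
    if not cands:
        return None
    return min(cands, key=lambda c: (c[1].p_value, c[1].start))


def flank_constrained_scan(
    lox_hits: Sequence[LoxHit],
    zf_pwm_upstream: Pwm,
    zf_pwm_downstream: Pwm,
    sequence: str,
    distance_range: tuple[int, int] = (4, 6),
    p_threshold: float = 0.001,
    seq_id: str = "seq",
    bin_width: float = 0.001,
) -> list[LoxFlankHit]:
    """Filter lox hits for ZF motifs at 4-6 bp (inclusive) from the half sites.

    In the lox site's own frame the upstream ("left") motif is expected on
    the reverse strand and the downstream ("right") motif on the forward
    strand; the distance is the bp gap between the outer edge of the lox
    half site and the near edge of the motif. Hits on the minus strand are
    handled by mirroring. Only lox hits with at least one conforming flank
    are returned.
    """
    lo, hi = distance_range
    if lo > hi or lo < 0:
        raise ValueError("distance_range must be (low, high) with 0 <= low <= high")
    up_hits = scan_sequence(zf_pwm_upstream, sequence, p_threshold, "both", seq_id, bin_width)
    down_hits = scan_sequence(
        zf_pwm_downstream, sequence, p_threshold, "both", seq_id, bin_width
    )
    out: list[LoxFlankHit] = []
    for lox in lox_hits:
        if lox.strand == "+":
            left_cands = [
                (lox.start - h.end, h)
                for h in up_hits
                if h.strand == "-" and lo <= lox.start - h.end <= hi
            ]
            right_cands = [
                (h.start - lox.end, h)
                for h in down_hits
                if h.strand == "+" and lo <= h.start - lox.end <= hi
            ]
        else:
            # site frame mirrored: its upstream side is to the right on the
            # forward strand, with strands flipped
            left_cands = [
                (h.start - lox.end, h)
                for h in up_hits
                if h.strand == "+" and lo <= h.start - lox.end <= hi
            ]
            right_cands = [
                (lox.start - h.end, h)
                for h in down_hits
                if h.strand == "-" and lo <= lox.start - h.end <= hi
            ]
        left = _best_flank(left_cands)
        right = _best_flank(right_cands)
        if left is None and right is None:
            continue
        if left and right:
            sides = FlankSides.BOTH
        elif left:
            sides = FlankSides.LEFT
        else:
            sides = FlankSides.RIGHT
        out.append(
            LoxFlankHit(
                lox=lox,
                left_flank=left[1] if left else None,
                right_flank=right[1] if right else None,
                left_distance=left[0] if left else None,
                right_distance=right[0] if right else None,
                sides=sides,
            )
        )
    return out


# ---------------------------------------------------------------------------
# evolved-clone mutation tally


@dataclass
class CloneMutationTable:
    """Per-position mutation statistics of evolved clones vs their parent."""

    reference: str
    mutated_counts: np.ndarray  # clones differing from reference, per position
    distinct_residues: list[set[str]]  # non-reference residues seen, per position
    n_clones: int

    @property
    def frequencies(self) -> np.ndarray:
        return self.mutated_counts / self.n_clones

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(1, len(self.reference) + 1),
                "reference": list(self.reference),
                "n_mutated": self.mutated_counts,
                "frequency": self.frequencies,
                "n_distinct": [len(s) for s in self.distinct_residues],
                "residues": ["".join(sorted(s)) for s in self.distinct_residues],
            }
        )


def tally_clone_mutations(
    clone_protein_sequences: Sequence[str], reference_protein_sequence: str
) -> CloneMutationTable:
    """Count, per position, clones whose residue differs from the parent.

    Clones must align to the parent without indels (equal length); a clone
    of different length is rejected.
    """
    ref = reference_protein_sequence
    if not clone_protein_sequences:
        raise ValueError("no clones")
    for i, c in enumerate(clone_protein_sequences):
        if len(c) != len(ref):
            raise ValueError(f"clone {i} length {len(c)} != reference length {len(ref)}")
    counts = np.zeros(len(ref), dtype=int)
    distinct: list[set[str]] = [set() for _ in ref]
    for c in clone_protein_sequences:
        for i, (a, b) in enumerate(zip(c, ref)):
            if a != b:
                counts[i] += 1
                distinct[i].add(a)
    return CloneMutationTable(
        reference=ref,
        mutated_counts=counts,
        distinct_residues=distinct,
        n_clones=len(clone_protein_sequences),
    )


# ---------------------------------------------------------------------------
# MEME minimal text format


def write_meme(
    path,
    motifs: Mapping[str, Ppm],
    background: Sequence[float] = UNIFORM,
) -> None:
    """Write PPMs in MEME minimal text format."""
    bg = np.asarray(background, dtype=float)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {p:.6f}" for b, p in zip(DNA, bg)) + "\n\n")
        for name, ppm in motifs.items():
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {ppm.width} "
                f"nsites= {max(ppm.n_sequences, 1)} E= 0\n"
            )
            for row in ppm.matrix:
                fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_meme(path) -> dict[str, Ppm]:
    """Read PPMs from MEME minimal text format."""
    motifs: dict[str, Ppm] = {}
    name = None
    rows: list[list[float]] = []
    expect = 0
    nsites = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                name = line.split()[1]
            elif line.startswith("letter-probability matrix"):
                toks = line.replace("=", "= ").split()
                for i, t in enumerate(toks):
                    if t == "w=":
                        expect = int(toks[i + 1])
                    if t == "nsites=":
                        nsites = int(toks[i + 1])
                rows = []
            elif name is not None and expect > 0 and line and line[0] in "0123456789.":
                rows.append([float(x) for x in line.split()])
                if len(rows) == expect:
                    mat = np.asarray(rows)
                    mat = mat / mat.sum(axis=1, keepdims=True)  # renormalize rounding
                    motifs[name] = Ppm(matrix=mat, n_sequences=nsites)
                    name, rows, expect = None, [], 0
    return motifs
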