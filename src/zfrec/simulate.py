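"""Synthetic data with known ground truth.

Everything downstream of the wet lab is exercisable on data made here:
noisy long reads drawn from REC/UNREC reference mixtures at set
recombination rates, pentapeptide-insertion read libraries over an ORF, and
random genomes with planted lox-like sites carrying flanking ZF motifs at
controlled distances.

Determinism contract: every public generator takes an integer ``seed``;
per-read RNG substreams are derived with ``numpy.random.SeedSequence``
spawn keys indexed by read number, so results do not depend on the order in
which reads are drawn.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._seq import DNA, check_dna, revcomp
from .design import RecombinationState, ReferenceAmplicon
from .screen import Read

__all__ = [
    "ErrorModel",
    "ScreenTruth",
    "GenomePlant",
    "random_sequence",
    "random_cds",
    "mutate_sequence",
    "simulate_screen_reads",
    "simulate_insertion_reads",
    "plant_genome",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_SENSE_CODONS = tuple(
    a + b + c
    for a in DNA
    for b in DNA
    for c in DNA
    if a + b + c not in ("TAA", "TAG", "TGA")
)


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """Uniform random ACGT sequence."""
    return "".join(DNA[i] for i in rng.integers(0, 4, size=length))


def random_cds(n_codons: int, rng: np.random.Generator, stop: bool = True) -> str:
    """Random ORF: ATG start, stop-free body, optional terminal stop codon."""
    if n_codons < 2:
        raise ValueError("need at least start + one codon")
    body = n_codons - 1 - (1 if stop else 0)
    idx = rng.integers(0, len(_SENSE_CODONS), size=body)
    return "ATG" + "".join(_SENSE_CODONS[i] for i in idx) + ("TAA" if stop else "")


@dataclass(frozen=True)
class ErrorModel:
    """Per-base i.i.d. substitution/indel model for long-read-like noise.

    Indels are single-base events (adequate to stress classification without
    modeling homopolymer behavior). Rates are per reference base.
    """

    substitution_rate: float = 0.0
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0

    def __post_init__(self) -> None:
        for r in (self.substitution_rate, self.insertion_rate, self.deletion_rate):
            if not 0.0 <= r < 1.0:
                raise ValueError("error rates must be in [0, 1)")

    @property
    def total(self) -> float:
        return self.substitution_rate + self.insertion_rate + self.deletion_rate


def _substream(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def mutate_sequence(sequence: str, model: ErrorModel, rng: np.random.Generator) -> str:
    """Apply i.i.d. substitutions and single-base indels to a sequence."""
    if model.total == 0.0:
        return sequence
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    n = arr.size
    u = rng.random(n)
    # substitution: replace with one of the three other bases
    sub_mask = u < model.substitution_rate
    if sub_mask.any():
        idx = np.flatnonzero(sub_mask)
        shift = rng.integers(1, 4, size=idx.size)
        base_idx = np.searchsorted(_BASES, arr[idx])
        arr[idx] = _BASES[(base_idx + shift) % 4]
    del_mask = (u >= model.substitution_rate) & (
        u < model.substitution_rate + model.deletion_rate
    )
    ins_mask = (u >= model.substitution_rate + model.deletion_rate) & (
        u < model.total
    )
    if not del_mask.any() and not ins_mask.any():
        return arr.tobytes().decode("ascii")
    out = bytearray()
    ins_bases = rng.integers(0, 4, size=int(ins_mask.sum()))
    k = 0
    for i in range(n):
        if ins_mask[i]:
            out.append(_BASES[ins_bases[k]])
            k += 1
        if not del_mask[i]:
            out.append(arr[i])
    return bytes(out).decode("ascii")


@dataclass(frozen=True)
class ScreenTruth:
    """Planted per-variant recombination rates and read depth."""

    rates: Mapping[str, float]
    reads_per_variant: int

    def __post_init__(self) -> None:
        for v, r in self.rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate for {v} outside [0,1]")
        if self.reads_per_variant <= 0:
            raise ValueError("reads_per_variant must be > 0")


def simulate_screen_reads(
    reference_pairs: Mapping[str, tuple[ReferenceAmplicon, ReferenceAmplicon]],
    truth: ScreenTruth,
    error_model: ErrorModel,
    seed: int,
    mean_q: float = 12.0,
    sd_q: float = 3.0,
    both_strands: bool = True,
) -> tuple[list[Read], pd.DataFrame]:
    """Draw noisy amplicon reads from a REC/UNREC mixture per variant.

    Each read picks the REC template with probability equal to the variant's
    true rate, is optionally reverse-complemented (fair coin), then mutated.
    A constant per-read Phred value drawn from N(mean_q, sd_q) (clipped to
    [2, 40]) is attached so the quality filter has both outcomes.

    Returns the reads and a truth table (read_id, variant_id, state, strand,
    phred).
    """
    for v in truth.rates:
        if v not in reference_pairs:
            raise ValueError(f"truth variant {v} has no reference pair")
        unrec, rec = reference_pairs[v]
        if unrec.state is not RecombinationState.UNREC or rec.state is not RecombinationState.REC:
            raise ValueError(f"reference pair for {v} must be (UNREC, REC)")
    reads: list[Read] = []
    rows = []
    read_no = 0
    for v in sorted(truth.rates):
        unrec, rec = reference_pairs[v]
        rate = truth.rates[v]
        for i in range(truth.reads_per_variant):
            rng = _substream(seed, read_no)
            is_rec = rng.random() < rate
            template = rec.sequence if is_rec else unrec.sequence
            strand = "+"
            if both_strands and rng.random() < 0.5:
                template = revcomp(template)
                strand = "-"
            seq = mutate_sequence(template, error_model, rng)
            q = float(np.clip(rng.normal(mean_q, sd_q), 2.0, 40.0))
            rid = f"read{read_no:07d}"
            reads.append(
                Read(
                    id=rid,
                    sequence=seq,
                    qualities=np.full(len(seq), q),
                )
            )
            rows.append(
                {
                    "read_id": rid,
                    "variant_id": v,
                    "state": "REC" if is_rec else "UNREC",
                    "strand": strand,
                    "phred": q,
                }
            )
            read_no += 1
    return reads, pd.DataFrame(rows)


def simulate_insertion_reads(
    wild_type_orf: str,
    junction_distribution: Mapping[int, float],
    n_reads: int,
    error_model: ErrorModel = ErrorModel(),
    seed: int = 0,
    duplication: bool = False,
    insert_length: int = 15,
    orf_start: int = 0,
) -> tuple[list[Read], pd.DataFrame]:
    """Reads carrying one in-frame fixed-length insertion at a sampled junction.

    ``junction_distribution`` maps residue-junction index (0 = before the
    first codon) to probability. With ``duplication`` the insert emulates
    Mu-transposition chemistry: a 5-bp direct repeat of the bases immediately
    5' of the insertion point followed by ``insert_length - 5`` random bases,
    so the insertion carries a target-site duplication. Otherwise the insert
    is uniform random, resampled so that the planted placement is already
    left-normalized (placement within repeats is not identifiable from the
    read, so the planted event is made canonical by construction).

    The truth table records both the sampled ``junction`` and the
    ``junction_canonical`` a left-normalizing profiler should report; they
    differ only in duplication mode, where the direct repeat makes the
    leftmost equivalent placement sit 5 nt upstream.
    """
    orf = check_dna(wild_type_orf, "wild_type_orf")
    n_codons = (len(orf) - orf_start) // 3
    junctions = sorted(junction_distribution)
    probs = np.array([junction_distribution[j] for j in junctions], dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("junction distribution must sum to 1")
    for j in junctions:
        if not 0 <= j <= n_codons:
            raise ValueError(f"junction {j} outside ORF (0..{n_codons})")
    cum = np.cumsum(probs)
    reads: list[Read] = []
    rows = []
    from .pentascan import InsertionEvent, left_align_insertion, position_to_junction

    for i in range(n_reads):
        rng = _substream(seed, i)
        j = junctions[int(np.searchsorted(cum, rng.random(), side="right"))]
        pos = orf_start + 3 * j
        if duplication and pos >= 5:
            dup = orf[pos - 5 : pos]
            core = "".join(DNA[b] for b in rng.integers(0, 4, size=insert_length - 5))
            insert = core + dup
        else:
            # resample until the planted placement is its own left-normal form
            for _ in range(64):
                insert = "".join(DNA[b] for b in rng.integers(0, 4, size=insert_length))
                if pos == 0 or insert[-1] != orf[pos - 1]:
                    break
        canonical = left_align_insertion(InsertionEvent(pos, insert), orf)
        j_canon = position_to_junction(canonical.ref_pos, orf_start)
        template = orf[:pos] + insert + orf[pos:]
        seq = mutate_sequence(template, error_model, rng)
        rid = f"ins{i:06d}"
        reads.append(Read(id=rid, sequence=seq, qualities=None))
        rows.append(
            {"read_id": rid, "junction": j, "junction_canonical": j_canon, "insert": insert}
        )
    return reads, pd.DataFrame(rows)


@dataclass(frozen=True)
class GenomePlant:
    """One composite site to plant: a lox-like core with optional flanking motifs.

    ``upstream_gap``/``downstream_gap`` count the bases between the lox
    boundary and the near edge of the motif. By the screen's convention the
    upstream motif sits on the reverse strand and the downstream motif on the
    forward strand; flags allow flipping either for negative controls.
    """

    lox_sequence: str
    upstream_motif: Optional[str] = None
    downstream_motif: Optional[str] = None
    upstream_gap: int = 5
    downstream_gap: int = 4
    upstream_strand: str = "-"
    downstream_strand: str = "+"
    position: Optional[int] = None


def plant_genome(
    length: int,
    plants: Sequence[GenomePlant],
    seed: int,
    background_composition: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> tuple[str, pd.DataFrame]:
    """Random background genome with planted composite sites.

    Returns the genome sequence and a truth table with one row per plant:
    lox start/end, and (when present) motif start/end/strand for each flank,
    all 0-based half-open on the forward strand.
    """
    comp = np.asarray(background_composition, dtype=float)
    if comp.shape != (4,) or not np.isclose(comp.sum(), 1.0) or (comp < 0).any():
        raise ValueError("background_composition must be 4 non-negative probs summing to 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    genome = list(rng.choice(list(DNA), size=length, p=comp))

    # build each composite block (upstream motif + gap + lox + gap + downstream motif)
    blocks = []
    for p in plants:
        lox = check_dna(p.lox_sequence, "lox_sequence")
        up = down = ""
        if p.upstream_motif is not None:
            m = check_dna(p.upstream_motif, "upstream_motif")
            up = (revcomp(m) if p.upstream_strand == "-" else m) + "".join(
                rng.choice(list(DNA), size=p.upstream_gap, p=comp)
            )
        if p.downstream_motif is not None:
            m = check_dna(p.downstream_motif, "downstream_motif")
            down = "".join(rng.choice(list(DNA), size=p.downstream_gap, p=comp)) + (
                revcomp(m) if p.downstream_strand == "-" else m
            )
        blocks.append((p, up + lox + down, len(up), len(up) + len(lox)))

    # choose non-overlapping placements
    occupied: list[tuple[int, int]] = []
    rows = []
    for p, block, lox_off, lox_end_off in blocks:
        if p.position is not None:
            start = p.position
            if start + len(block) > length:
                raise ValueError("plant does not fit in genome")
            if any(s < start + len(block) and start < e for s, e in occupied):
                raise ValueError("plants overlap")
        else:
            for _ in range(1000):
                start = int(rng.integers(0, length - len(block) + 1))
                if not any(s < start + len(block) and start < e for s, e in occupied):
                    break
            else:
                raise ValueError("could not place plant without overlap")
        occupied.append((start, start + len(block)))
        genome[start : start + len(block)] = list(block)
        row = {
            "lox_start": start + lox_off,
            "lox_end": start + lox_end_off,
            "block_start": start,
            "block_end": start + len(block),
        }
        if p.upstream_motif is not None:
            row["up_start"] = start
            row["up_end"] = start + len(p.upstream_motif)
            row["up_strand"] = p.upstream_strand
            row["up_gap"] = p.upstream_gap
        if p.downstream_motif is not None:
            row["down_start"] = start + len(block) - len(p.downstream_motif)
            row["down_end"] = start + len(block)
            row["down_strand"] = p.downstream_strand
            row["down_gap"] = p.downstream_gap
        rows.append(row)
    return "".join(genome), pd.DataFrame(rows)
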