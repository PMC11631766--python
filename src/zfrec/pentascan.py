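"""Pentapeptide-insertion position profiling.

Transposon scanning mutagenesis introduces five-codon (15-nt) in-frame
insertions throughout a recombinase ORF; selecting for activity and
long-read sequencing the survivors yields a map of insertion-tolerant
positions. This module aligns each read globally to the wild-type ORF
reference with affine gap scoring, extracts insertion runs of the target
length, left-normalizes their placement (placement within repeats is
alignment-ambiguous), converts reference coordinates to residue junctions
(junction j = between residues j and j+1), and accumulates per-junction
counts and frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np

from ._seq import revcomp
from .align import AffineAlignment, AlignParams, OP_DEL, OP_INS, OP_MATCH, global_align_affine
from .screen import Read

__all__ = [
    "PENTAPEPTIDE_INSERT_NT",
    "InsertionEvent",
    "InsertionProfile",
    "extract_insertions",
    "left_align_insertion",
    "position_to_junction",
    "build_insertion_profile",
    "merge_profiles",
    "top_positions",
    "profile_reads",
]

#: five residues, three nt each — the footprint the profiler looks for
PENTAPEPTIDE_INSERT_NT = 15


@dataclass(frozen=True)
class InsertionEvent:
    """An insertion sitting immediately before reference position ``ref_pos``."""

    ref_pos: int
    inserted_seq: str

    @property
    def length(self) -> int:
        return len(self.inserted_seq)


def extract_insertions(
    alignment: AffineAlignment,
    query: str,
    target_length: int = PENTAPEPTIDE_INSERT_NT,
    length_tolerance: int = 0,
) -> list[InsertionEvent]:
    """Insertion runs within ``length_tolerance`` of the target length."""
    events = []
    ref_pos = 0
    query_pos = 0
    for op, n in alignment.cigar:
        if op == OP_MATCH:
            ref_pos += n
            query_pos += n
        elif op == OP_DEL:
            ref_pos += n
        elif op == OP_INS:
            if abs(n - target_length) <= length_tolerance:
                events.append(
                    InsertionEvent(ref_pos=ref_pos, inserted_seq=query[query_pos : query_pos + n])
                )
            query_pos += n
        else:
            raise ValueError(f"unknown cigar op {op}")
    return events


def left_align_insertion(event: InsertionEvent, reference: str) -> InsertionEvent:
    """Shift an insertion to its leftmost equivalent placement (idempotent).

    While the reference base immediately left of the insertion equals the
    last base of the insert, the insert can be rotated right and the event
    shifted one base left without changing the aligned sequence.
    """
    pos, seq = event.ref_pos, event.inserted_seq
    if not 0 <= pos <= len(reference):
        raise ValueError("event outside reference")
    while pos > 0 and seq and reference[pos - 1] == seq[-1]:
        seq = seq[-1] + seq[:-1]
        pos -= 1
    return InsertionEvent(ref_pos=pos, inserted_seq=seq)


def position_to_junction(ref_pos: int, orf_start: int = 0, strict: bool = False) -> int:
    """Residue junction index for an insertion at a reference coordinate.

    Junction j means "after codon j" (0 = before the first residue; an
    insertion at nt 834 of an ORF starting at 0 sits at junction 278, i.e.
    between residues 278 and 279). Off-frame apparent positions — sequencing
    errors shift placement — are rounded to the nearest codon boundary unless
    ``strict``, which rejects them.
    """
    if ref_pos < orf_start:
        raise ValueError("ref_pos before ORF start")
    offset = ref_pos - orf_start
    if strict:
        if offset % 3 != 0:
            raise ValueError(f"insertion at nt offset {offset} is off-frame")
        return offset // 3
    return int(np.floor(offset / 3 + 0.5))


@dataclass
class InsertionProfile:
    """Per-junction counts of accepted fixed-length insertions."""

    counts: dict[int, int]
    orf_length_codons: int
    total_reads: int = 0

    @property
    def n_events(self) -> int:
        return sum(self.counts.values())

    @property
    def frequencies(self) -> dict[int, float]:
        """Counts normalized by the number of accepted events (NA-free: empty
        dict when no event exists)."""
        n = self.n_events
        if n == 0:
            return {}
        return {j: c / n for j, c in sorted(self.counts.items())}


def build_insertion_profile(
    events_per_read: Sequence[Sequence[InsertionEvent]],
    orf_length_codons: int,
    orf_start: int = 0,
    per_read: str = "all",
    strict_frame: bool = False,
) -> InsertionProfile:
    """Accumulate junction counts over reads.

    ``per_read='all'`` counts every accepted event of a read (default);
    ``'first'`` counts at most one (the leftmost) per read.
    """
    if per_read not in ("all", "first"):
        raise ValueError("per_read must be 'all' or 'first'")
    counts: dict[int, int] = {}
    for events in events_per_read:
        use = sorted(events, key=lambda e: e.ref_pos)
        if per_read == "first":
            use = use[:1]
        for e in use:
            j = position_to_junction(e.ref_pos, orf_start, strict=strict_frame)
            if not 0 <= j <= orf_length_codons:
                raise ValueError(f"junction {j} out of ORF range")
            counts[j] = counts.get(j, 0) + 1
    return InsertionProfile(
        counts=counts, orf_length_codons=orf_length_codons, total_reads=len(events_per_read)
    )


def merge_profiles(profiles: Iterable[InsertionProfile]) -> InsertionProfile:
    """Pool profiles across libraries (cumulative-frequency view)."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to merge")
    length = max(p.orf_length_codons for p in profiles)
    counts: dict[int, int] = {}
    total = 0
    for p in profiles:
        total += p.total_reads
        for j, c in p.counts.items():
            counts[j] = counts.get(j, 0) + c
    return InsertionProfile(counts=counts, orf_length_codons=length, total_reads=total)


def top_positions(profile: InsertionProfile, n: int = 5) -> list[int]:
    """The ``n`` junctions with the highest counts; ties favor the lower index."""
    ranked = sorted(profile.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [j for j, _ in ranked[:n]]


def _orient(read_seq: str, reference: str) -> str:
    """Return the read in the orientation closer to the reference."""
    fwd = edlib.align(read_seq, reference, mode="NW", task="distance")["editDistance"]
    rc = revcomp(read_seq)
    rev = edlib.align(rc, reference, mode="NW", task="distance")["editDistance"]
    return read_seq if fwd <= rev else rc


def profile_reads(
    reads: Sequence[Read],
    reference: str,
    orf_start: int = 0,
    orf_length_codons: Optional[int] = None,
    target_length: int = PENTAPEPTIDE_INSERT_NT,
    length_tolerance: int = 0,
    params: AlignParams = AlignParams(),
    per_read: str = "all",
) -> InsertionProfile:
    """End-to-end profiling: orient, align, extract, left-align, count."""
    if orf_length_codons is None:
        orf_length_codons = (len(reference) - orf_start) // 3
    events_per_read = []
    for r in reads:
        seq = _orient(r.sequence, reference)
        aln = global_align_affine(seq, reference, params)
        events = extract_insertions(aln, seq, target_length, length_tolerance)
        events_per_read.append([left_align_insertion(e, reference) for e in events])
    return build_insertion_profile(
        events_per_read, orf_length_codons, orf_start=orf_start, per_read=per_read
    )
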