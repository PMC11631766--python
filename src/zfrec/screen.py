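"""Long-read classification against combinatorial references and
recombination-rate estimation.

Each amplicon read is assigned to the single best-matching reference among
all design-variant × recombination-state combinations (both read
orientations are tried), with an assignment margin guarding against
near-identical neighbors (references differing by one 9-nt GGS repeat).
Assigned reads are filtered for coverage of the target site and the fusion
diagnostic region, then counted into per-variant recombination rates
``rate = n_rec / (n_rec + n_unrec)``.

Scoring uses unit-cost edit distance (edlib's banded bit-vector aligner in
infix mode) after a shared-k-mer prefilter; the reported ``score`` is the
negated edit distance so that larger is better, and ``margin`` is the
distance gap to the second-best reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import edlib
import numpy as np
import pandas as pd

from ._seq import revcomp
from .design import Interval, RecombinationState, ReferenceAmplicon

__all__ = [
    "Read",
    "Assignment",
    "RateRecord",
    "HeatMap",
    "ReferenceIndex",
    "mean_phred",
    "filter_reads_by_quality",
    "classify_read",
    "coverage_filter",
    "classify_reads",
    "compute_rates",
    "rates_to_frame",
    "band_intensity_rate",
    "build_heatmap",
    "two_phase_demultiplex",
]


@dataclass
class Read:
    id: str
    sequence: str
    qualities: Optional[np.ndarray] = None  # per-base Phred scores

    def __post_init__(self) -> None:
        if self.qualities is not None:
            self.qualities = np.asarray(self.qualities, dtype=float)
            if self.qualities.size != len(self.sequence):
                raise ValueError(f"read {self.id}: qualities/sequence length mismatch")


def mean_phred(qualities: np.ndarray, stat: str = "mean") -> float:
    """Summary Phred score of a read.

    ``mean`` converts per-base Phred to error probabilities, averages them and
    converts back (the standard mean-quality convention); ``median`` takes the
    per-base median directly.
    """
    q = np.asarray(qualities, dtype=float)
    if q.size == 0:
        return 0.0
    if stat == "median":
        return float(np.median(q))
    if stat != "mean":
        raise ValueError("stat must be 'mean' or 'median'")
    p = np.power(10.0, -q / 10.0)
    return float(-10.0 * np.log10(p.mean()))


def filter_reads_by_quality(
    reads: Iterable[Read], min_phred: float = 10.0, stat: str = "mean"
) -> list[Read]:
    """Retain reads whose summary Phred is >= ``min_phred`` (inclusive bound).

    Reads without quality values pass (a warning case upstream of us —
    quality was already consumed or never recorded). Order is preserved.
    """
    if min_phred < 0:
        raise ValueError("min_phred must be non-negative")
    out = []
    for r in reads:
        if r.qualities is None or mean_phred(r.qualities, stat) >= min_phred:
            out.append(r)
    return out


@dataclass
class Assignment:
    read_id: str
    variant_id: Optional[str]  # None == UNASSIGNED
    state: Optional[RecombinationState]  # None == UNDETERMINED
    score: float = 0.0
    margin: float = 0.0
    strand: str = "+"
    ref_span: Optional[Interval] = None  # aligned span on the reference
    flags: set[str] = field(default_factory=set)

    @property
    def assigned(self) -> bool:
        return self.variant_id is not None

    def __post_init__(self) -> None:
        if self.variant_id is None and not self.flags:
            raise ValueError("UNASSIGNED requires at least one flag")
        if self.margin < 0:
            raise ValueError("margin must be >= 0")


@dataclass(frozen=True)
class _RefEntry:
    ref_id: str
    variant_id: str
    state: Optional[RecombinationState]
    sequence: str
    annotations: Mapping[str, Sequence[Interval]]


class ReferenceIndex:
    """All candidate references plus a shared-k-mer prefilter.

    The prefilter ranks (reference, strand) pairs by the number of read
    k-mers they share and only the top candidates are aligned; references
    within a screen share most of their sequence, so the candidate list is
    kept generous by default.
    """

    def __init__(self, entries: Sequence[_RefEntry], k: int = 13, sample_stride: int = 4):
        if not entries:
            raise ValueError("reference index is empty")
        ids = [e.ref_id for e in entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate reference ids")
        self.entries = sorted(entries, key=lambda e: e.ref_id)
        self.k = k
        self.sample_stride = sample_stride
        self._kmers: list[dict[str, frozenset[str]]] = []
        for e in self.entries:
            per_strand = {}
            for strand, seq in (("+", e.sequence), ("-", revcomp(e.sequence))):
                per_strand[strand] = frozenset(
                    seq[i : i + k] for i in range(0, max(len(seq) - k + 1, 0))
                )
            self._kmers.append(per_strand)

    @classmethod
    def from_amplicons(cls, amplicons: Sequence[ReferenceAmplicon], **kw) -> "ReferenceIndex":
        return cls(
            [
                _RefEntry(a.fasta_id, a.variant_id, a.state, a.sequence, a.annotations)
                for a in amplicons
            ],
            **kw,
        )

    @classmethod
    def from_sequences(cls, sequences: Mapping[str, str], **kw) -> "ReferenceIndex":
        """Index plain (id -> sequence) references (no recombination state)."""
        return cls(
            [_RefEntry(rid, rid, None, seq, {}) for rid, seq in sequences.items()], **kw
        )

    def __len__(self) -> int:
        return len(self.entries)

    def candidates(self, read_seq: str, top_n: Optional[int]) -> list[tuple[int, str]]:
        """(entry index, strand) pairs to align, ranked by shared k-mers."""
        pairs = [(i, s) for i in range(len(self.entries)) for s in ("+", "-")]
        if top_n is None or top_n >= len(pairs):
            return pairs
        kmers = [
            read_seq[i : i + self.k]
            for i in range(0, max(len(read_seq) - self.k + 1, 1), self.sample_stride)
        ]
        scored = []
        for i, s in pairs:
            ks = self._kmers[i][s]
            scored.append((-sum(km in ks for km in kmers), self.entries[i].ref_id, s, i))
        scored.sort()
        return [(i, s) for _, _, s, i in scored[:top_n]]


def _align(query: str, target: str, task: str = "distance"):
    return edlib.align(query, target, mode="HW", task=task)


def classify_read(
    read: Read,
    index: ReferenceIndex,
    min_margin: float = 2.0,
    top_n: Optional[int] = 32,
) -> Assignment:
    """Assign a read to its single best (variant, state) reference.

    The read and its reverse complement are scored against the candidate
    references by edit distance; the best reference wins only if it beats
    the runner-up by at least ``min_margin`` (ties and close calls are
    flagged ``ambiguous`` and left unassigned). Deterministic: candidate
    order is fixed by reference id.
    """
    if not read.sequence:
        raise ValueError("empty read")
    rc = revcomp(read.sequence)
    best: tuple[float, int, str] | None = None
    second_dist = math.inf
    for i, strand in index.candidates(read.sequence, top_n):
        q = read.sequence if strand == "+" else rc
        d = _align(q, index.entries[i].sequence)["editDistance"]
        if best is None or d < best[0]:
            if best is not None:
                second_dist = min(second_dist, best[0])
            best = (d, i, strand)
        elif d < second_dist:
            second_dist = d
    assert best is not None
    dist, i, strand = best
    margin = (second_dist - dist) if math.isfinite(second_dist) else math.inf
    entry = index.entries[i]
    if margin < min_margin:
        return Assignment(
            read_id=read.id,
            variant_id=None,
            state=None,
            score=-dist,
            margin=max(margin, 0.0),
            strand=strand,
            flags={"ambiguous"},
        )
    q = read.sequence if strand == "+" else rc
    res = _align(q, entry.sequence, task="locations")
    loc = res["locations"][0]
    span = (loc[0], loc[1] + 1)  # edlib end is inclusive
    return Assignment(
        read_id=read.id,
        variant_id=entry.variant_id,
        state=entry.state,
        score=-float(dist),
        margin=float(margin) if math.isfinite(margin) else float(len(read.sequence)),
        strand=strand,
        ref_span=span,
    )


def coverage_filter(
    assignment: Assignment,
    annotations: Mapping[str, Sequence[Interval]],
    required: Sequence[str] = ("target_site", "fusion_diagnostic"),
    mode: str = "containment",
    min_overlap_fraction: float = 0.9,
) -> bool:
    """Check that the aligned span covers the required reference regions.

    ``containment`` (default) demands full containment of every required
    interval; ``overlap`` accepts ``min_overlap_fraction`` of each interval.
    """
    if not assignment.assigned:
        raise ValueError("coverage_filter needs an assigned read")
    if assignment.ref_span is None:
        return False
    s, e = assignment.ref_span
    for name in required:
        for a, b in annotations.get(name, []):
            if mode == "containment":
                ok = s <= a and b <= e
            elif mode == "overlap":
                ov = max(0, min(e, b) - max(s, a))
                ok = ov >= min_overlap_fraction * (b - a)
            else:
                raise ValueError("mode must be 'containment' or 'overlap'")
            if not ok:
                return False
    return True


@dataclass
class RunStats:
    """Per-stage read accounting; conserves the total input count."""

    n_input: int = 0
    n_low_quality: int = 0
    n_ambiguous: int = 0
    n_no_coverage: int = 0
    n_assigned: int = 0

    def check_conservation(self) -> None:
        total = self.n_low_quality + self.n_ambiguous + self.n_no_coverage + self.n_assigned
        if total != self.n_input:
            raise AssertionError(f"read accounting leak: {total} != {self.n_input}")


def classify_reads(
    reads: Sequence[Read],
    index: ReferenceIndex,
    min_phred: float = 10.0,
    min_margin: float = 2.0,
    top_n: Optional[int] = 32,
    coverage_mode: str = "containment",
) -> tuple[list[Assignment], RunStats]:
    """Quality-filter, classify and coverage-filter a read set.

    Returns the assignments of reads surviving every filter, plus stage
    counts that reconcile exactly with the input.
    """
    stats = RunStats(n_input=len(reads))
    kept = filter_reads_by_quality(reads, min_phred)
    stats.n_low_quality = len(reads) - len(kept)
    ann_by_ref = {e.ref_id: e.annotations for e in index.entries}
    out = []
    for r in kept:
        a = classify_read(r, index, min_margin=min_margin, top_n=top_n)
        if not a.assigned:
            stats.n_ambiguous += 1
            continue
        ref_id = a.variant_id if a.state is None else f"{a.variant_id}|{a.state.value}"
        if not coverage_filter(a, ann_by_ref.get(ref_id, {}), mode=coverage_mode):
            stats.n_no_coverage += 1
            continue
        stats.n_assigned += 1
        out.append(a)
    stats.check_conservation()
    return out, stats


@dataclass
class RateRecord:
    """Recombined/unrecombined read counts for one design variant."""

    variant_id: str
    n_rec: int
    n_unrec: int
    key: dict = field(default_factory=dict)

    @property
    def rate(self) -> Optional[float]:
        denom = self.n_rec + self.n_unrec
        if denom == 0:
            return None
        return self.n_rec / denom

    @property
    def odds(self) -> Optional[float]:
        """Raw recombined/unrecombined odds (NA when n_unrec == 0)."""
        if self.n_unrec == 0:
            return None
        return self.n_rec / self.n_unrec


def compute_rates(
    assignments: Iterable[Assignment],
    manifest: Optional[pd.DataFrame] = None,
) -> list[RateRecord]:
    """One RateRecord per variant; state-undetermined reads are excluded
    from both numerator and denominator.

    ``manifest`` (optional) is the design table with a ``variant_id`` column;
    its remaining columns become the record's key fields.
    """
    counts: dict[str, list[int]] = {}
    for a in assignments:
        if not a.assigned or a.state is None:
            continue
        c = counts.setdefault(a.variant_id, [0, 0])
        if a.state is RecombinationState.REC:
            c[0] += 1
        else:
            c[1] += 1
    keys: dict[str, dict] = {}
    if manifest is not None:
        for _, row in manifest.iterrows():
            d = row.to_dict()
            keys[d.pop("variant_id")] = d
    return [
        RateRecord(v, n_rec, n_unrec, key=keys.get(v, {}))
        for v, (n_rec, n_unrec) in sorted(counts.items())
    ]


def rates_to_frame(records: Sequence[RateRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"variant_id": r.variant_id, **r.key, "n_rec": r.n_rec, "n_unrec": r.n_unrec,
               "rate": r.rate}
        rows.append(row)
    return pd.DataFrame(rows)


def band_intensity_rate(rec_intensity: float, unrec_intensity: float) -> Optional[float]:
    """Recombination efficiency from gel band intensities: rec/(rec+unrec).

    Intensities are taken as already-quantified numbers; both-zero input has
    no defined efficiency and returns None.
    """
    if rec_intensity < 0 or unrec_intensity < 0:
        raise ValueError("band intensities must be non-negative")
    total = rec_intensity + unrec_intensity
    if total == 0:
        return None
    return rec_intensity / total


@dataclass
class HeatMap:
    """Rate matrix (linker axis × spacing axis) for one motif orientation."""

    orientation: str
    rates: pd.DataFrame
    n_rec: pd.DataFrame
    n_unrec: pd.DataFrame

    @property
    def total_counts(self) -> int:
        return int(self.n_rec.to_numpy(na_value=0).sum() + self.n_unrec.to_numpy(na_value=0).sum())


def build_heatmap(
    records: Sequence[RateRecord],
    aggregation: str = "per_linker",
) -> list[HeatMap]:
    """Heat maps per orientation from keyed rate records.

    ``per_linker`` keeps the terminal-screen linker axis (rows =
    linker_left); ``summed_left_right`` pools all (L, R) linker pairs with
    equal L+R into one row and recomputes the rate from the pooled counts.
    Records lacking a motif (no orientation) are skipped: they have no
    spacing axis.
    """
    if aggregation not in ("per_linker", "summed_left_right"):
        raise ValueError("aggregation must be 'per_linker' or 'summed_left_right'")
    rows = []
    modes = set()
    for r in records:
        k = r.key
        if not k or pd.isna(k.get("orientation")) or k.get("orientation") in ("", None):
            continue
        modes.add(k.get("mode"))
        if aggregation == "summed_left_right":
            linker = int(k["linker_left"]) + int(k.get("linker_right") or 0)
        else:
            linker = int(k["linker_left"])
        rows.append(
            {
                "orientation": k["orientation"],
                "linker": linker,
                "spacing": int(k["spacing"]),
                "n_rec": r.n_rec,
                "n_unrec": r.n_unrec,
            }
        )
    if len(modes) > 1:
        raise ValueError(f"records mix screen modes: {sorted(map(str, modes))}")
    if not rows:
        return []
    df = pd.DataFrame(rows)
    out = []
    for orient, grp in df.groupby("orientation"):
        pooled = grp.groupby(["linker", "spacing"])[["n_rec", "n_unrec"]].sum()
        n_rec = pooled["n_rec"].unstack("spacing")
        n_unrec = pooled["n_unrec"].unstack("spacing")
        denom = n_rec + n_unrec
        rates = n_rec / denom.where(denom > 0)
        out.append(HeatMap(str(orient), rates, n_rec, n_unrec))
    return out


def two_phase_demultiplex(
    reads: Sequence[Read],
    backbone_index: ReferenceIndex,
    variant_libraries: Mapping[str, ReferenceIndex],
    min_phred: float = 10.0,
    min_margin: float = 2.0,
    top_n: Optional[int] = 32,
) -> list[RateRecord]:
    """Two-phase demultiplexing of a mixed pool to per-variant rates.

    Phase 1 assigns each read to one backbone (recombinase × recombination
    state; e.g. 3 recombinases × 2 states = 6 references); reads without a
    unique margin-passing best hit are dropped. Phase 2 maps each subset to
    its recombinase's library of insertion variants; the recombination state
    carries over from phase 1. Rates follow rate = n_rec/(n_rec+n_unrec).
    """
    backbones = {}
    for e in backbone_index.entries:
        backbones.setdefault(e.variant_id, set()).add(e.state)
    for b, states in backbones.items():
        if states != {RecombinationState.REC, RecombinationState.UNREC}:
            raise ValueError(f"backbone {b} lacks one recombination state")
        if b not in variant_libraries:
            raise ValueError(f"no variant library for backbone {b}")

    kept = filter_reads_by_quality(reads, min_phred)
    counts: dict[str, list[int]] = {}
    for r in kept:
        a1 = classify_read(r, backbone_index, min_margin=min_margin, top_n=top_n)
        if not a1.assigned or a1.state is None:
            continue
        a2 = classify_read(r, variant_libraries[a1.variant_id], min_margin=min_margin, top_n=top_n)
        if not a2.assigned:
            continue
        key = f"{a1.variant_id}::{a2.variant_id}"
        c = counts.setdefault(key, [0, 0])
        if a1.state is RecombinationState.REC:
            c[0] += 1
        else:
            c[1] += 1
    return [
        RateRecord(v, n_rec, n_unrec, key={"backbone": v.split("::")[0]})
        for v, (n_rec, n_unrec) in sorted(counts.items())
    ]
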