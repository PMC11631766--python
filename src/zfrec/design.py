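"""Combinatorial design of lox-zif target sites, ZF-recombinase fusions and
reference amplicons.

The screen explored here varies four axes: where a zinc-finger DNA-binding
domain (ZFD) is fused to a Cre-type recombinase (N-terminus, C-terminus, or
inserted into the ORF after residue 278), the length of the flexible
Gly-Gly-Ser (GGS) linker(s), the spacing in bp between the 34-bp lox site and
the ZF binding motif, and the orientation of that motif. This module builds
the corresponding nucleotide sequences — composite target sites, fusion
coding sequences, and paired recombined (REC) / unrecombined (UNREC)
reference amplicons — and enumerates the design space.

Coordinates are 0-based half-open throughout. Residue numbering is 1-based:
an insertion junction of 278 means "after codon 278".
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from ._seq import check_dna, pad_fill, revcomp

__all__ = [
    "LoxSite",
    "ZfMotif",
    "Orientation",
    "FlankedSides",
    "TargetSiteDesign",
    "FusionMode",
    "FusionDesign",
    "AnnotatedSequence",
    "ReferenceAmplicon",
    "GGS_CODONS",
    "TERMINAL_LINKER_REPEATS",
    "INSERTIONAL_LINKER_REPEATS",
    "build_target_site",
    "bound_site_length",
    "enumerate_target_library",
    "build_fusion_cds",
    "enumerate_fusion_library",
    "build_reference_pair",
    "count_design_space",
    "design_from_annotations",
]

#: one GGS repeat, fixed codon choice (Gly-Gly-Ser); recorded so designs are
#: reproducible at the nucleotide level.
GGS_CODONS = "GGTGGTAGC"

#: linker grids used by the two published screen modes
TERMINAL_LINKER_REPEATS = (2, 4, 6, 8, 10, 12)
INSERTIONAL_LINKER_REPEATS = tuple(range(1, 9))

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class LoxSite:
    """A lox-type recombinase target site: two half sites around a spacer.

    Default Cre-family geometry is 13 + 8 + 13 = 34 nt. Each 13-nt half site
    is bound by one recombinase monomer; the 8-nt asymmetric spacer sets the
    site's orientation and is where strand exchange resolves.
    """

    name: str
    left_half: str
    spacer: str
    right_half: str

    def __post_init__(self) -> None:
        for part, what in [
            (self.left_half, "left_half"),
            (self.spacer, "spacer"),
            (self.right_half, "right_half"),
        ]:
            object.__setattr__(self, what, check_dna(part, f"{self.name} {what}"))

    @property
    def sequence(self) -> str:
        return self.left_half + self.spacer + self.right_half

    def __len__(self) -> int:
        return len(self.left_half) + len(self.spacer) + len(self.right_half)


@dataclass(frozen=True)
class ZfMotif:
    """DNA motif bound by a ZFD; 3 nt per finger (9 nt = three fingers)."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", check_dna(self.sequence, f"motif {self.name}"))
        if len(self.sequence) % 3 != 0:
            raise ValueError(
                f"motif {self.name}: length {len(self.sequence)} not divisible by 3 "
                "(one finger reads 3 nt)"
            )

    @property
    def n_fingers(self) -> int:
        return len(self.sequence) // 3

    def __len__(self) -> int:
        return len(self.sequence)


class Orientation(str, Enum):
    """Orientation of the ZF motif relative to the lox site.

    ``A``: the motif's given sequence sits on the top strand reading toward
    the lox site (given sequence on the left flank, reverse complement on the
    right flank — mirror-symmetric). ``B``: the reverse-complement layout.
    These labels are an internal convention for a geometry the screen only
    defines graphically.
    """

    A = "A"
    B = "B"


class FlankedSides(str, Enum):
    BOTH = "both"
    LEFT = "left"
    RIGHT = "right"
    NONE = "none"


@dataclass(frozen=True)
class TargetSiteDesign:
    """One point of the target-site library: lox × motif × spacing × orientation."""

    lox: LoxSite
    motif: Optional[ZfMotif] = None
    spacing_bp: int = 0
    orientation: Orientation = Orientation.A
    flanked_sides: FlankedSides = FlankedSides.BOTH

    def __post_init__(self) -> None:
        if self.motif is None and self.flanked_sides is not FlankedSides.NONE:
            object.__setattr__(self, "flanked_sides", FlankedSides.NONE)
        if self.motif is not None and self.flanked_sides is FlankedSides.NONE:
            raise ValueError("motif given but flanked_sides is 'none'")
        if self.spacing_bp < 0:
            raise ValueError("spacing_bp must be >= 0")

    @property
    def key(self) -> str:
        if self.motif is None:
            return self.lox.name
        return (
            f"{self.lox.name}-{self.spacing_bp}-{self.motif.name}"
            f"({self.orientation.value})"
            + ("" if self.flanked_sides is FlankedSides.BOTH else f"-{self.flanked_sides.value}")
        )


class FusionMode(str, Enum):
    N_TERMINAL = "N"
    C_TERMINAL = "C"
    INSERTIONAL = "ins"


@dataclass(frozen=True)
class FusionDesign:
    """A ZF-recombinase fusion: where the ZFD goes and how long the linker(s) are.

    Terminal modes use a single linker (``linker_left_repeats``); the
    insertional mode places the ZFD inside the recombinase ORF after
    ``insertion_junction`` residues, between a left and a right GGS linker.
    """

    recombinase_id: str
    mode: FusionMode
    linker_left_repeats: int
    linker_right_repeats: int = 0
    insertion_junction: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mode is FusionMode.INSERTIONAL:
            if self.insertion_junction is None:
                raise ValueError("insertional fusion requires insertion_junction")
            for r, side in [(self.linker_left_repeats, "left"), (self.linker_right_repeats, "right")]:
                if r not in INSERTIONAL_LINKER_REPEATS and r != 0:
                    raise ValueError(
                        f"insertional {side} linker repeats must be in 1..8, got {r}"
                    )
        else:
            if self.linker_left_repeats not in TERMINAL_LINKER_REPEATS:
                raise ValueError(
                    f"terminal linker repeats must be one of {TERMINAL_LINKER_REPEATS}, "
                    f"got {self.linker_left_repeats}"
                )
            if self.linker_right_repeats:
                raise ValueError("terminal fusions use a single linker")

    @property
    def key(self) -> str:
        if self.mode is FusionMode.INSERTIONAL:
            return (
                f"{self.recombinase_id}-ins{self.insertion_junction}"
                f"-L{self.linker_left_repeats}R{self.linker_right_repeats}"
            )
        return f"{self.recombinase_id}-{self.mode.value}-L{self.linker_left_repeats}"


Interval = tuple[int, int]


@dataclass
class AnnotatedSequence:
    """A nucleotide sequence plus named 0-based half-open intervals."""

    sequence: str
    intervals: dict[str, list[Interval]] = field(default_factory=dict)

    def add(self, name: str, start: int, end: int) -> None:
        if not (0 <= start <= end <= len(self.sequence)):
            raise ValueError(f"interval {name} [{start},{end}) outside sequence bounds")
        self.intervals.setdefault(name, []).append((start, end))

    def slice(self, name: str, index: int = 0) -> str:
        start, end = self.intervals[name][index]
        return self.sequence[start:end]


class RecombinationState(str, Enum):
    REC = "REC"
    UNREC = "UNREC"


@dataclass
class ReferenceAmplicon:
    """A synthesized reference in one recombination state with annotations.

    UNREC carries two composite target sites around an intersite segment (the
    excisable cassette); REC carries the single site left after excision.
    """

    variant_id: str
    state: RecombinationState
    sequence: str
    annotations: dict[str, list[Interval]]

    def __post_init__(self) -> None:
        n_sites = len(self.annotations.get("target_site", []))
        if self.state is RecombinationState.UNREC:
            if n_sites != 2 or len(self.annotations.get("intersite", [])) != 1:
                raise ValueError("UNREC amplicon needs 2 target_site and 1 intersite interval")
        else:
            if n_sites != 1 or "intersite" in self.annotations:
                raise ValueError("REC amplicon needs exactly 1 target_site and no intersite")
        for name, ivs in self.annotations.items():
            for s, e in ivs:
                if not (0 <= s <= e <= len(self.sequence)):
                    raise ValueError(f"annotation {name} [{s},{e}) outside bounds")

    @property
    def fasta_id(self) -> str:
        return f"{self.variant_id}|{self.state.value}"


# ---------------------------------------------------------------------------
# target sites


def build_target_site(
    design: TargetSiteDesign,
    *,
    pad_cycle: str = "TCGA",
) -> AnnotatedSequence:
    """Assemble one composite lox-zif target site.

    Layout (flanked both, orientation A)::

        [motif][pad(spacing)][lox][pad(spacing)][revcomp(motif)]

    The left and right motif copies are mirror-symmetric so that each of the
    two recombinase monomers straddling a half site has a ZFD landing pad at
    the same geometry. Pads are deterministic filler (the screen constrains
    only their length).
    """
    lox_seq = design.lox.sequence
    if design.motif is None:
        out = AnnotatedSequence(lox_seq)
        out.add("lox", 0, len(lox_seq))
        return out

    motif = design.motif.sequence
    if design.orientation is Orientation.A:
        left_m, right_m = motif, revcomp(motif)
    else:
        left_m, right_m = revcomp(motif), motif

    parts: list[tuple[str, str]] = []
    if design.flanked_sides in (FlankedSides.BOTH, FlankedSides.LEFT):
        parts.append(("motif_left", left_m))
        parts.append(("spacer_left", pad_fill(design.spacing_bp, pad_cycle)))
    parts.append(("lox", lox_seq))
    if design.flanked_sides in (FlankedSides.BOTH, FlankedSides.RIGHT):
        parts.append(("spacer_right", pad_fill(design.spacing_bp, pad_cycle)))
        parts.append(("motif_right", right_m))

    seq = "".join(p for _, p in parts)
    out = AnnotatedSequence(seq)
    pos = 0
    for name, p in parts:
        if p or name == "lox":
            out.add(name, pos, pos + len(p))
        pos += len(p)
    return out


def bound_site_length(design: TargetSiteDesign) -> int:
    """Total protein-bound bases: lox site plus each placed ZF motif.

    Spacer/pad bases are contacted by neither the recombinase nor the ZFD and
    are excluded. A 34-bp lox flanked on both sides by a three-finger (9-bp)
    motif gives 34 + 2*9 = 52 bound bases.
    """
    n = len(design.lox)
    if design.motif is not None:
        per_side = {
            FlankedSides.BOTH: 2,
            FlankedSides.LEFT: 1,
            FlankedSides.RIGHT: 1,
            FlankedSides.NONE: 0,
        }[design.flanked_sides]
        n += per_side * len(design.motif)
    return n


def design_from_annotations(
    annotated: AnnotatedSequence, lox: LoxSite, motif: ZfMotif
) -> TargetSiteDesign:
    """Recover the design parameters from a built, annotated site (round-trip)."""
    iv = annotated.intervals
    has_left = "motif_left" in iv
    has_right = "motif_right" in iv
    if not has_left and not has_right:
        return TargetSiteDesign(lox=lox)
    if has_left and has_right:
        sides = FlankedSides.BOTH
    elif has_left:
        sides = FlankedSides.LEFT
    else:
        sides = FlankedSides.RIGHT
    spacer_key = "spacer_left" if has_left else "spacer_right"
    s, e = iv.get(spacer_key, [(0, 0)])[0]
    spacing = e - s
    probe = annotated.slice("motif_left" if has_left else "motif_right")
    if has_left:
        orientation = Orientation.A if probe == motif.sequence else Orientation.B
    else:
        orientation = Orientation.B if probe == motif.sequence else Orientation.A
    return TargetSiteDesign(
        lox=lox, motif=motif, spacing_bp=spacing, orientation=orientation, flanked_sides=sides
    )


def enumerate_target_library(
    lox: LoxSite,
    motif: ZfMotif,
    spacings: Sequence[int],
    orientations: Iterable[Orientation] = (Orientation.A, Orientation.B),
    include_unflanked: bool = True,
    flanked_sides: FlankedSides = FlankedSides.BOTH,
) -> list[TargetSiteDesign]:
    """Cartesian product spacings × orientations, optionally plus the bare lox."""
    spacings = list(spacings)
    if not spacings:
        raise ValueError("spacings must be non-empty")
    if len(set(spacings)) != len(spacings):
        raise ValueError("duplicate spacing values")
    designs = [
        TargetSiteDesign(
            lox=lox, motif=motif, spacing_bp=s, orientation=o, flanked_sides=flanked_sides
        )
        for s, o in itertools.product(spacings, orientations)
    ]
    if include_unflanked:
        designs.append(TargetSiteDesign(lox=lox))
    keys = [d.key for d in designs]
    if len(set(keys)) != len(keys):
        raise ValueError("variant keys not unique")
    return designs


# ---------------------------------------------------------------------------
# fusion coding sequences


def _check_cds(cds: str, what: str, allow_empty: bool = False) -> str:
    cds = check_dna(cds, what) if cds else ""
    if not cds:
        if allow_empty:
            return cds
        raise ValueError(f"{what} is empty")
    if len(cds) % 3 != 0:
        raise ValueError(f"{what} length {len(cds)} not divisible by 3")
    for i in range(0, len(cds) - 3, 3):
        if cds[i : i + 3] in STOP_CODONS:
            raise ValueError(f"{what} has internal stop codon at nt {i}")
    return cds


def _strip_stop(cds: str) -> str:
    if cds and cds[-3:] in STOP_CODONS:
        return cds[:-3]
    return cds


def _linker(repeats: int) -> str:
    return GGS_CODONS * repeats


def build_fusion_cds(
    recombinase_cds: str, zf_cds: str, design: FusionDesign
) -> str:
    """Assemble the fusion coding sequence for one design.

    N-terminal: ZFD (stop removed) + linker + recombinase.
    C-terminal: recombinase (stop removed) + linker + ZFD.
    Insertional: recombinase codons 1..j + left linker + ZFD (start/stop
    removed) + right linker + recombinase codons j+1..end, with j the
    insertion junction (1-based residue count).
    """
    rec = _check_cds(recombinase_cds, "recombinase_cds")
    zf = _check_cds(zf_cds, "zf_cds", allow_empty=True)
    if design.mode is FusionMode.N_TERMINAL:
        out = _strip_stop(zf) + _linker(design.linker_left_repeats) + rec
    elif design.mode is FusionMode.C_TERMINAL:
        out = _strip_stop(rec) + _linker(design.linker_left_repeats) + zf
    else:
        j = design.insertion_junction
        assert j is not None
        if j * 3 >= len(rec):
            raise ValueError(f"insertion junction {j} beyond recombinase CDS")
        insert = _strip_stop(zf)
        if insert.startswith("ATG"):
            insert = insert[3:]
        out = (
            rec[: j * 3]
            + _linker(design.linker_left_repeats)
            + insert
            + _linker(design.linker_right_repeats)
            + rec[j * 3 :]
        )
    assert len(out) % 3 == 0
    return out


def enumerate_fusion_library(
    recombinase_id: str,
    modes: Iterable[FusionMode],
    linker_grid: Sequence[int] | None = None,
    left_grid: Sequence[int] | None = None,
    right_grid: Sequence[int] | None = None,
    insertion_junction: int = 278,
) -> list[FusionDesign]:
    """Enumerate fusion designs for terminal and/or insertional screens."""
    designs: list[FusionDesign] = []
    modes = list(modes)
    if not modes:
        raise ValueError("mode set must be non-empty")
    for mode in modes:
        if mode is FusionMode.INSERTIONAL:
            lg = list(left_grid if left_grid is not None else INSERTIONAL_LINKER_REPEATS)
            rg = list(right_grid if right_grid is not None else INSERTIONAL_LINKER_REPEATS)
            if not lg or not rg:
                raise ValueError("insertional linker grids must be non-empty")
            for l, r in itertools.product(lg, rg):
                designs.append(
                    FusionDesign(
                        recombinase_id=recombinase_id,
                        mode=mode,
                        linker_left_repeats=l,
                        linker_right_repeats=r,
                        insertion_junction=insertion_junction,
                    )
                )
        else:
            grid = list(linker_grid if linker_grid is not None else TERMINAL_LINKER_REPEATS)
            if not grid:
                raise ValueError("terminal linker grid must be non-empty")
            for l in grid:
                designs.append(
                    FusionDesign(
                        recombinase_id=recombinase_id, mode=mode, linker_left_repeats=l
                    )
                )
    keys = [d.key for d in designs]
    if len(set(keys)) != len(keys):
        raise ValueError("fusion design keys not unique")
    return designs


# ---------------------------------------------------------------------------
# reference amplicons

SITE1_ANCHOR = "<SITE1>"
SITE2_ANCHOR = "<SITE2>"
INTERSITE_ANCHOR = "<INTERSITE>"
CDS_ANCHOR = "<CDS>"


def build_reference_pair(
    backbone: str,
    site: AnnotatedSequence,
    fusion_cds: str,
    intersite_segment: str,
    variant_id: str,
) -> tuple[ReferenceAmplicon, ReferenceAmplicon]:
    """Build the UNREC/REC reference pair for one fusion × site combination.

    ``backbone`` is a plasmid-like template containing the literal anchors
    ``<SITE1>``, ``<INTERSITE>``, ``<SITE2>`` and ``<CDS>`` (in that order
    for the site/intersite trio). UNREC substitutes the composite site at
    both site anchors and the excisable segment between them. REC models the
    excision product: recombination resolves within the lox spacer of the two
    directly repeated sites, deleting one full composite site plus the
    intersite segment and leaving a single intact composite site (with the
    outermost flanking motifs retained).
    """
    for anchor in (SITE1_ANCHOR, INTERSITE_ANCHOR, SITE2_ANCHOR, CDS_ANCHOR):
        if backbone.count(anchor) != 1:
            raise ValueError(f"backbone must contain anchor {anchor} exactly once")
    if not intersite_segment:
        raise ValueError("intersite_segment must be non-empty")
    order = sorted(
        (SITE1_ANCHOR, INTERSITE_ANCHOR, SITE2_ANCHOR), key=backbone.index
    )
    if order != [SITE1_ANCHOR, INTERSITE_ANCHOR, SITE2_ANCHOR]:
        raise ValueError("anchors must appear in order SITE1, INTERSITE, SITE2")

    check_dna(intersite_segment, "intersite_segment")
    check_dna(fusion_cds, "fusion_cds")
    site_seq = site.sequence

    # tokenize the backbone into plain-sequence and anchor tokens
    tokens = [
        t
        for t in re.split(r"(<SITE1>|<INTERSITE>|<SITE2>|<CDS>)", backbone)
        if t != ""
    ]

    def assemble(fill: Mapping[str, Optional[str]]) -> tuple[str, dict[str, Interval]]:
        """Substitute anchors (None = drop token) tracking each anchor's span."""
        parts: list[str] = []
        spans: dict[str, Interval] = {}
        pos = 0
        for tok in tokens:
            if tok in fill:
                sub = fill[tok]
                if sub is None:
                    continue
                spans[tok] = (pos, pos + len(sub))
                parts.append(sub)
                pos += len(sub)
            else:
                parts.append(tok)
                pos += len(tok)
        return "".join(parts), spans

    unrec_seq, u = assemble(
        {
            SITE1_ANCHOR: site_seq,
            INTERSITE_ANCHOR: intersite_segment,
            SITE2_ANCHOR: site_seq,
            CDS_ANCHOR: fusion_cds,
        }
    )
    rec_seq, r = assemble(
        {
            SITE1_ANCHOR: site_seq,
            INTERSITE_ANCHOR: None,
            SITE2_ANCHOR: None,
            CDS_ANCHOR: fusion_cds,
        }
    )
    if site_seq not in unrec_seq or site_seq not in rec_seq:
        raise AssertionError("assembled reference lost the target site")

    unrec_ann: dict[str, list[Interval]] = {
        "target_site": [u[SITE1_ANCHOR], u[SITE2_ANCHOR]],
        "intersite": [u[INTERSITE_ANCHOR]],
        "fusion_diagnostic": [u[CDS_ANCHOR]],
    }
    rec_ann: dict[str, list[Interval]] = {
        "target_site": [r[SITE1_ANCHOR]],
        "fusion_diagnostic": [r[CDS_ANCHOR]],
    }
    unrec = ReferenceAmplicon(variant_id, RecombinationState.UNREC, unrec_seq, unrec_ann)
    rec = ReferenceAmplicon(variant_id, RecombinationState.REC, rec_seq, rec_ann)
    return unrec, rec


def count_design_space(
    fusion_designs: Sequence[FusionDesign], site_designs: Sequence[TargetSiteDesign]
) -> int:
    """Size of the screen: |fusion designs| × |target-site designs|."""
    return len(fusion_designs) * len(site_designs)
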