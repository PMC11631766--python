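"""Structured screen configuration: parsing, whole-file validation, and
design enumeration.

A screen config describes the combinatorial grammar of one screen — the lox
site parts, the ZF motif, the spacing and orientation lists, the fusion
mode and linker grid(s) — plus pipeline thresholds and the RNG seed.
Validation reports *all* problems at once rather than failing on the first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import yaml

from .design import (
    INSERTIONAL_LINKER_REPEATS,
    TERMINAL_LINKER_REPEATS,
    FusionDesign,
    FusionMode,
    LoxSite,
    Orientation,
    TargetSiteDesign,
    ZfMotif,
    count_design_space,
    enumerate_fusion_library,
    enumerate_target_library,
)

__all__ = [
    "ConfigError",
    "Thresholds",
    "ScreenConfig",
    "parse_and_validate_config",
    "enumerate_designs",
    "design_space_size",
]


class ConfigError(ValueError):
    """Aggregated validation failure; ``errors`` lists every problem found."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("invalid config:\n" + "\n".join(f"  - {e}" for e in errors))


@dataclass(frozen=True)
class Thresholds:
    min_phred: float = 10.0
    min_margin: float = 2.0
    p_threshold: float = 0.001
    distance_range: tuple[int, int] = (4, 6)


@dataclass
class ScreenConfig:
    lox: LoxSite
    motif: Optional[ZfMotif]
    spacings: list[int]
    orientations: list[Orientation]
    include_unflanked: bool
    mode: str  # "terminal" (expands to N+C), "N", "C", or "insertional"
    recombinase_id: str
    linker_repeats: list[int]  # terminal grid, or insertional left grid
    linker_right_repeats: list[int]  # insertional right grid
    insertion_junction: int = 278
    max_spacing: int = 10
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0


_KNOWN_KEYS = {
    "lox",
    "motif",
    "spacings",
    "orientations",
    "include_unflanked",
    "mode",
    "recombinase_id",
    "linker_repeats",
    "linker_left_repeats",
    "linker_right_repeats",
    "insertion_junction",
    "max_spacing",
    "thresholds",
    "seed",
}
_KNOWN_THRESHOLDS = {"min_phred", "min_margin", "p_threshold", "distance_range"}


def _validate(raw: dict[str, Any]) -> ScreenConfig:
    errors: list[str] = []

    for key in raw:
        if key not in _KNOWN_KEYS:
            errors.append(f"unknown key '{key}'")

    lox = None
    lox_raw = raw.get("lox")
    if not isinstance(lox_raw, dict):
        errors.append("'lox' section (name/left_half/spacer/right_half) is required")
    else:
        try:
            lox = LoxSite(
                name=str(lox_raw.get("name", "lox")),
                left_half=lox_raw.get("left_half", ""),
                spacer=lox_raw.get("spacer", ""),
                right_half=lox_raw.get("right_half", ""),
            )
        except ValueError as e:
            errors.append(f"lox: {e}")

    motif = None
    if raw.get("motif") is not None:
        m = raw["motif"]
        try:
            motif = ZfMotif(name=str(m.get("name", "zf")), sequence=m.get("sequence", ""))
        except (AttributeError, ValueError) as e:
            errors.append(f"motif: {e}")

    max_spacing = int(raw.get("max_spacing", 10))
    spacings = list(raw.get("spacings", []))
    if motif is not None and not spacings:
        errors.append("'spacings' must be non-empty when a motif is configured")
    if len(set(spacings)) != len(spacings):
        errors.append("spacings: duplicate values")
    for s in spacings:
        if not isinstance(s, int) or s < 0 or s > max_spacing:
            errors.append(f"spacings: value {s} outside 0..{max_spacing}")

    orientations = []
    for o in raw.get("orientations", ["A", "B"]):
        try:
            orientations.append(Orientation(str(o)))
        except ValueError:
            errors.append(f"orientations: unknown orientation '{o}'")

    mode_raw = str(raw.get("mode", "terminal"))
    if mode_raw == "ins":
        mode_raw = "insertional"
    if mode_raw not in ("terminal", "N", "C", "insertional"):
        errors.append(f"mode: '{mode_raw}' not one of terminal/N/C/insertional")
        mode_raw = "terminal"
    is_insertional = mode_raw == "insertional"

    left_key = "linker_left_repeats" if "linker_left_repeats" in raw else "linker_repeats"
    linker_left = list(raw.get(left_key, []))
    linker_right = list(raw.get("linker_right_repeats", []))
    if not linker_left:
        errors.append(f"'{left_key}' must be non-empty")
    allowed = INSERTIONAL_LINKER_REPEATS if is_insertional else TERMINAL_LINKER_REPEATS
    for r in linker_left:
        if r not in allowed:
            errors.append(f"linker repeats: {r} not in allowed set {allowed}")
    if is_insertional:
        if not linker_right:
            errors.append("'linker_right_repeats' must be non-empty for insertional mode")
        for r in linker_right:
            if r not in allowed:
                errors.append(f"linker_right_repeats: {r} not in allowed set {allowed}")
    elif linker_right:
        errors.append("'linker_right_repeats' only applies to insertional mode")

    thresholds = Thresholds()
    t = raw.get("thresholds", {})
    if t:
        for k in t:
            if k not in _KNOWN_THRESHOLDS:
                errors.append(f"thresholds: unknown key '{k}'")
        try:
            dr = t.get("distance_range", (4, 6))
            thresholds = Thresholds(
                min_phred=float(t.get("min_phred", 10.0)),
                min_margin=float(t.get("min_margin", 2.0)),
                p_threshold=float(t.get("p_threshold", 0.001)),
                distance_range=(int(dr[0]), int(dr[1])),
            )
            if thresholds.min_phred < 0:
                errors.append("thresholds: min_phred must be non-negative")
            if not 0 < thresholds.p_threshold <= 1:
                errors.append("thresholds: p_threshold must be in (0, 1]")
            if thresholds.distance_range[0] > thresholds.distance_range[1]:
                errors.append("thresholds: distance_range inverted")
        except (TypeError, ValueError, IndexError) as e:
            errors.append(f"thresholds: {e}")

    if errors:
        raise ConfigError(errors)
    assert lox is not None
    return ScreenConfig(
        lox=lox,
        motif=motif,
        spacings=spacings,
        orientations=orientations,
        include_unflanked=bool(raw.get("include_unflanked", True)),
        mode=mode_raw,
        recombinase_id=str(raw.get("recombinase_id", "rec")),
        linker_repeats=linker_left,
        linker_right_repeats=linker_right,
        insertion_junction=int(raw.get("insertion_junction", 278)),
        max_spacing=max_spacing,
        thresholds=thresholds,
        seed=int(raw.get("seed", 0)),
    )


def parse_and_validate_config(path) -> ScreenConfig:
    """Load a YAML screen config; raise ConfigError listing every problem."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(["config file is not a mapping"])
    return _validate(raw)


def enumerate_designs(
    cfg: ScreenConfig,
) -> tuple[list[FusionDesign], list[TargetSiteDesign]]:
    """Expand a config to its fusion-design and target-site-design lists."""
    if cfg.mode == "terminal":
        modes = [FusionMode.N_TERMINAL, FusionMode.C_TERMINAL]
    elif cfg.mode == "insertional":
        modes = [FusionMode.INSERTIONAL]
    else:
        modes = [FusionMode(cfg.mode)]
    fusions = enumerate_fusion_library(
        cfg.recombinase_id,
        modes,
        linker_grid=cfg.linker_repeats,
        left_grid=cfg.linker_repeats,
        right_grid=cfg.linker_right_repeats or cfg.linker_repeats,
        insertion_junction=cfg.insertion_junction,
    )
    if cfg.motif is not None:
        sites = enumerate_target_library(
            cfg.lox,
            cfg.motif,
            cfg.spacings,
            cfg.orientations,
            include_unflanked=cfg.include_unflanked,
        )
    else:
        sites = [TargetSiteDesign(lox=cfg.lox)]
    return fusions, sites


def design_space_size(cfg: ScreenConfig) -> int:
    fusions, sites = enumerate_designs(cfg)
    return count_design_space(fusions, sites)
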