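"""Tunable parameters for the insulated-site screen, with YAML round-trip.

All thresholds used anywhere in the pipeline live here so a single config
file pins a run. Coordinates are 0-based half-open throughout the package;
conversion to 1-based closed happens only at the GFF3/GenBank boundaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

logger = logging.getLogger("insite")


@dataclass
class ConvergentParams:
    """Geometry filter for convergent ("3'-end face-to-face") gene pairs."""

    gap_min: int = 40
    gap_max: int = 500
    flank_w: int = 150  # nt of each gene's 3' end used as the "flank" window

    def __post_init__(self) -> None:
        if not (0 <= self.gap_min <= self.gap_max):
            raise ValueError("require 0 <= gap_min <= gap_max")
        if self.flank_w < 1:
            raise ValueError("flank_w must be >= 1")


@dataclass
class TerminatorParams:
    """Intrinsic (rho-independent) terminator scan parameters.

    A hit is a gap-free, exactly paired stem-loop (G:U wobble allowed)
    followed by an 8-nt T-tract window. Pair weights GC/CG=3, AT/TA=2,
    GT/TG=1; loop penalty lambda per nt beyond loop_min; positional tract
    weights favour Ts immediately after the stem.
    """

    stem_min: int = 4
    stem_max: int = 20
    loop_min: int = 3
    loop_max: int = 9
    loop_lambda: float = 1.0
    hairpin_min_score: float = 8.0  # H_min
    tail_min_score: float = 3.0  # T_min
    tract_len: int = 8
    search_up: int = 200  # nt of each gene 3' end searched, in addition to the gap

    def __post_init__(self) -> None:
        if not (1 <= self.stem_min <= self.stem_max):
            raise ValueError("bad stem bounds")
        if not (0 <= self.loop_min <= self.loop_max):
            raise ValueError("bad loop bounds")


@dataclass
class InsulationParams:
    """Coverage-insulation scoring across conditions.

    index_c = log2((f_c + p) / (gap_c + p)) with f_c the weaker flank mean;
    the site index is the minimum over conditions (insulation is required in
    every condition, not just one).
    """

    pseudocount: float = 1.0  # p, reads/base
    expressed_min: float = 20.0  # E_min, reads/base: flanks must exceed this
    index_min: float = 3.0  # I_min: >= 8-fold flank/gap ratio
    gap_max_cov: float = 5.0  # G_max, reads/base: hard cap on gap coverage


@dataclass
class RankParams:
    """Ranking of passing sites: insulation dominates, terminator strength breaks ties."""

    alpha: float = 0.1  # weight of summed terminator scores in rank_score


@dataclass
class CassetteParams:
    promoter_spacer: int = 6  # nt between promoter and fusion CDS start
    drop_payload_start: bool = True  # drop payload's native ATG in the fusion
    arm_len: int = 500  # homology arm length


@dataclass
class PipelineConfig:
    """Everything a scan/design run depends on, serialisable to YAML."""

    convergent: ConvergentParams = field(default_factory=ConvergentParams)
    terminator: TerminatorParams = field(default_factory=TerminatorParams)
    insulation: InsulationParams = field(default_factory=InsulationParams)
    rank: RankParams = field(default_factory=RankParams)
    cassette: CassetteParams = field(default_factory=CassetteParams)
    use_cds_rows: bool = False  # GFF3 fallback: use CDS rows instead of gene rows
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            v = d[f.name]
            if dataclasses.is_dataclass(f.type) or f.name in (
                "convergent",
                "terminator",
                "insulation",
                "rank",
                "cassette",
            ):
                sub = {
                    "convergent": ConvergentParams,
                    "terminator": TerminatorParams,
                    "insulation": InsulationParams,
                    "rank": RankParams,
                    "cassette": CassetteParams,
                }[f.name]
                kwargs[f.name] = sub(**v) if isinstance(v, dict) else v
            else:
                kwargs[f.name] = v
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        """Stable short hash of the full parameter set, logged per run."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
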