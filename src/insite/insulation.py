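"""Coverage-based insulation scoring of convergent gaps across conditions.

The verbal criterion — gap reads extremely low while both flanking 3' ends
are highly transcribed — is quantified per condition as

    index_c = log2((f_c + p) / (gap_c + p)),   f_c = min(flank+_c, flank-_c)

with p a pseudocount in reads/base. A site's index is the *minimum* over
conditions: insulation must hold in every condition, not just one. Tracks
are assumed comparably scaled by the caller (no library-size normalisation
here).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import ConvergentParams, InsulationParams
from .convergent import ConvergentPair, flank_windows
from .formats_io import CoverageTrack


@dataclass(frozen=True)
class ConditionScore:
    condition_id: str
    flank_plus: float
    flank_minus: float
    gap: float
    index: float


@dataclass(frozen=True)
class InsulationScore:
    """Per-condition flank/gap means and the combined (min) insulation index."""

    per_condition: tuple[ConditionScore, ...]
    index: float
    expressed_all: bool

    @property
    def max_gap(self) -> float:
        return max(c.gap for c in self.per_condition)


def window_mean(track: CoverageTrack, contig: str, interval: tuple[int, int]) -> float:
    """Arithmetic mean of per-base coverage over a nonempty interval."""
    s, e = interval
    if e <= s:
        raise ValueError(f"empty interval [{s},{e})")
    v = track.values[contig]
    if not (0 <= s and e <= len(v)):
        raise ValueError(f"interval [{s},{e}) outside contig {contig!r}")
    return float(np.mean(v[s:e]))


def insulation_index(
    pair: ConvergentPair,
    tracks: list[CoverageTrack],
    params: InsulationParams | None = None,
    flank_w: int | None = None,
) -> InsulationScore:
    """Score one convergent gap against every coverage track."""
    params = params or InsulationParams()
    w = flank_w if flank_w is not None else ConvergentParams().flank_w
    if not tracks:
        raise ValueError("at least one coverage track is required")
    iv_plus, iv_minus = flank_windows(pair, w)
    gap = pair.gap
    p = params.pseudocount
    per = []
    expressed_all = True
    for track in tracks:
        fp = window_mean(track, pair.contig_id, iv_plus)
        fm = window_mean(track, pair.contig_id, iv_minus)
        g = window_mean(track, pair.contig_id, gap)
        f = min(fp, fm)
        idx = math.log2((f + p) / (g + p))
        per.append(ConditionScore(track.condition_id, fp, fm, g, idx))
        if f < params.expressed_min:
            expressed_all = False
    return InsulationScore(
        per_condition=tuple(per),
        index=min(c.index for c in per),
        expressed_all=expressed_all,
    )


def passes_insulation(score: InsulationScore, params: InsulationParams | None = None) -> bool:
    """True iff flanks are expressed in every condition, the combined index
    clears the fold-change floor, and no condition's gap coverage exceeds
    the absolute cap (read-through guard)."""
    params = params or InsulationParams()
    return (
        score.expressed_all
        and score.index >= params.index_min
        and score.max_gap <= params.gap_max_cov
    )
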