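"""End-to-end insulated-site screen: geometry -> insulation -> dual terminators.

scan_genome composes the three filters and ranks survivors by

    rank_score = insulation_index + alpha * (T1.total_score + T2.total_score)

so insulation dominates and terminator strength breaks ties. The pipeline is
a pure function of its inputs and config; each run logs the config hash.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .config import PipelineConfig
from .convergent import ConvergentPair, find_convergent_pairs
from .formats_io import CoverageTrack, GenomeAnnotation, GenomeRecord, write_bed6
from .insulation import InsulationScore, insulation_index, passes_insulation
from .terminators import TerminatorHit, find_opposing_pair, hits_to_gff3

logger = logging.getLogger("insite")


@dataclass(frozen=True)
class CandidateSite:
    """A gap that passed every filter, with its ranking evidence."""

    pair: ConvergentPair
    score: InsulationScore
    t1: TerminatorHit
    t2: TerminatorHit
    insertion_point: int
    rank_score: float


def _check_consistency(
    genomes: dict[str, GenomeRecord],
    annotation: GenomeAnnotation,
    tracks: list[CoverageTrack],
) -> None:
    problems = []
    for contig, length in annotation.contig_lengths.items():
        if contig not in genomes:
            problems.append(f"annotation contig {contig!r} missing from genome")
        elif len(genomes[contig]) != length:
            problems.append(
                f"contig {contig!r}: annotation length {length} != sequence "
                f"length {len(genomes[contig])}"
            )
    for t in tracks:
        for contig, length in annotation.contig_lengths.items():
            v = t.values.get(contig)
            if v is None:
                problems.append(f"track {t.condition_id!r} missing contig {contig!r}")
            elif len(v) != length:
                problems.append(
                    f"track {t.condition_id!r} contig {contig!r}: length "
                    f"{len(v)} != {length}"
                )
    if problems:
        raise ValueError("inconsistent inputs: " + "; ".join(problems))


def scan_genome(
    genomes: list[GenomeRecord],
    annotation: GenomeAnnotation,
    tracks: list[CoverageTrack],
    config: Optional[PipelineConfig] = None,
) -> list[CandidateSite]:
    """Return every convergent gap that is insulated in all conditions and
    bounded by an opposing terminator pair with a valid insertion point,
    ranked by rank_score descending (ties -> leftmost coordinate)."""
    config = config or PipelineConfig()
    logger.info("scan start, config hash %s", config.config_hash())
    by_id = {g.contig_id: g for g in genomes}
    _check_consistency(by_id, annotation, tracks)

    pairs = find_convergent_pairs(
        annotation, config.convergent.gap_min, config.convergent.gap_max
    )
    logger.info("convergent pairs in gap range: %d", len(pairs))
    sites: list[CandidateSite] = []
    for pair in pairs:
        score = insulation_index(
            pair, tracks, config.insulation, flank_w=config.convergent.flank_w
        )
        if not passes_insulation(score, config.insulation):
            continue
        opp = find_opposing_pair(by_id[pair.contig_id], pair, config.terminator)
        if opp is None or opp.insertion_point is None:
            continue
        rank = score.index + config.rank.alpha * (
            opp.t1.total_score + opp.t2.total_score
        )
        sites.append(
            CandidateSite(
                pair=pair,
                score=score,
                t1=opp.t1,
                t2=opp.t2,
                insertion_point=opp.insertion_point,
                rank_score=rank,
            )
        )
    sites.sort(key=lambda s: (-s.rank_score, s.pair.contig_id, s.pair.gap[0]))
    logger.info("candidate insulated sites: %d", len(sites))
    return sites


TSV_COLUMNS = [
    "contig",
    "gene_plus",
    "gene_minus",
    "gap_start",
    "gap_end",
    "insertion_point",
    "insulation_index",
    "expressed_all",
    "max_gap_cov",
    "t1_start",
    "t1_end",
    "t1_score",
    "t2_start",
    "t2_end",
    "t2_score",
    "rank_score",
]


def sites_to_frame(sites: list[CandidateSite]) -> pd.DataFrame:
    rows = []
    for s in sites:
        rows.append(
            {
                "contig": s.pair.contig_id,
                "gene_plus": s.pair.gene_plus.gene_id,
                "gene_minus": s.pair.gene_minus.gene_id,
                "gap_start": s.pair.gap[0],
                "gap_end": s.pair.gap[1],
                "insertion_point": s.insertion_point,
                "insulation_index": round(s.score.index, 6),
                "expressed_all": s.score.expressed_all,
                "max_gap_cov": round(s.score.max_gap, 6),
                "t1_start": s.t1.footprint[0],
                "t1_end": s.t1.footprint[1],
                "t1_score": s.t1.total_score,
                "t2_start": s.t2.footprint[0],
                "t2_end": s.t2.footprint[1],
                "t2_score": s.t2.total_score,
                "rank_score": round(s.rank_score, 6),
            }
        )
    return pd.DataFrame(rows, columns=TSV_COLUMNS)


def report(sites: list[CandidateSite], out_prefix: str | Path) -> dict[str, Path]:
    """Write the site table (TSV), the gaps (BED6, score scaled to 0-1000)
    and the bounding terminators (GFF3). Returns the written paths."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv = out_prefix.with_suffix(".sites.tsv")
    bed = out_prefix.with_suffix(".gaps.bed")
    gff = out_prefix.with_suffix(".terminators.gff3")

    sites_to_frame(sites).to_csv(tsv, sep="\t", index=False)

    max_rank = max((s.rank_score for s in sites), default=0.0)
    bed_rows = []
    for s in sites:
        score = 0 if max_rank <= 0 else round(1000 * max(0.0, s.rank_score) / max_rank)
        bed_rows.append(
            (s.pair.contig_id, s.pair.gap[0], s.pair.gap[1], s.pair.name, score, ".")
        )
    write_bed6(bed_rows, bed)

    hits = [h for s in sites for h in (s.t1, s.t2)]
    hits_to_gff3(hits, gff)
    return {"tsv": tsv, "bed": bed, "gff3": gff}
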