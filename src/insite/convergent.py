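"""Convergent ("3'-end face-to-face") gene pairs and their intergenic gaps.

A convergent pair is two adjacent genes — no annotated gene of any strand
between them — with the left gene on + and the right gene on -, so both 3'
ends point into the shared gap. The gap is the geometric precondition of an
insulated site: it can host two opposing intrinsic terminators and an
insertion point.
"""

from __future__ import annotations

from dataclasses import dataclass

from .formats_io import GeneFeature, GenomeAnnotation


@dataclass(frozen=True)
class ConvergentPair:
    """A + gene followed by a - gene with a clean intergenic gap between them."""

    gene_plus: GeneFeature
    gene_minus: GeneFeature

    def __post_init__(self) -> None:
        if self.gene_plus.strand != "+" or self.gene_minus.strand != "-":
            raise ValueError("convergent pair requires (+, -) strand order")
        if self.gene_plus.contig_id != self.gene_minus.contig_id:
            raise ValueError("pair genes must share a contig")
        if self.gene_plus.end > self.gene_minus.start:
            raise ValueError("pair genes overlap")

    @property
    def contig_id(self) -> str:
        return self.gene_plus.contig_id

    @property
    def gap(self) -> tuple[int, int]:
        """[gene_plus.end, gene_minus.start), 0-based half-open."""
        return (self.gene_plus.end, self.gene_minus.start)

    @property
    def gap_len(self) -> int:
        return self.gene_minus.start - self.gene_plus.end

    @property
    def name(self) -> str:
        return f"{self.gene_plus.gene_id}|{self.gene_minus.gene_id}"


def find_convergent_pairs(
    annotation: GenomeAnnotation, gap_min: int, gap_max: int
) -> list[ConvergentPair]:
    """All adjacent (+, -) gene pairs whose gap length is within [gap_min, gap_max].

    "Adjacent" means no annotated gene of any strand intersects the gap;
    genes that overlap each other (gap length < 0) are discarded. Output is
    ordered by (contig, gap start) and is deterministic.
    """
    if not (0 <= gap_min <= gap_max):
        raise ValueError("require 0 <= gap_min <= gap_max")
    pairs: list[ConvergentPair] = []
    by_contig: dict[str, list[GeneFeature]] = {}
    for g in annotation.genes:
        by_contig.setdefault(g.contig_id, []).append(g)
    for contig in sorted(by_contig):
        genes = by_contig[contig]  # already sorted by start
        for left, right in zip(genes, genes[1:]):
            if left.strand != "+" or right.strand != "-":
                continue
            gap_s, gap_e = left.end, right.start
            if gap_e - gap_s < 0:
                continue
            if not (gap_min <= gap_e - gap_s <= gap_max):
                continue
            # adjacency: no gene of any strand may intersect the gap
            if any(
                g.start < gap_e and g.end > gap_s
                for g in genes
                if g is not left and g is not right
            ):
                continue
            pairs.append(ConvergentPair(gene_plus=left, gene_minus=right))
    return pairs


def flank_windows(pair: ConvergentPair, w: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """3'-end windows of both genes, clamped to gene bounds.

    Returns (interval_plus, interval_minus): the last min(w, len) bases of
    the + gene, and the first-in-coordinates min(w, len) bases of the - gene
    (its 3' end is its left edge).
    """
    if w < 1:
        raise ValueError("w must be >= 1")
    gp, gm = pair.gene_plus, pair.gene_minus
    wa = min(w, len(gp))
    wb = min(w, len(gm))
    return (gp.end - wa, gp.end), (gm.start, gm.start + wb)
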