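"""Intrinsic (rho-independent) terminator prediction.

A terminator is modelled as a gap-free, exactly base-paired stem-loop
followed by an 8-nt T-tract window (the poly-U run of the transcript,
written in DNA letters). Scoring is additive and deliberately simple so an
exhaustive brute-force oracle can verify the scanner bit-for-bit:

* pair weights: G:C / C:G = 3, A:T / T:A = 2, G:T / T:G (wobble) = 1
* loop penalty: lambda * (loop_len - loop_min), lambda = 1
* tract: positional weights (2.0, 1.5, 1.5, 1.0, 1.0, 0.5, 0.5, 0.5) summed
  over positions holding a T; N (padding past the sequence end) scores 0.

All work is done on the DNA alphabet; minus-strand logic is handled by
scanning the reverse complement and mirroring coordinates back.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .config import TerminatorParams
from .convergent import ConvergentPair
from .formats_io import GenomeRecord

PAIR_WEIGHTS: dict[tuple[str, str], float] = {
    ("G", "C"): 3.0,
    ("C", "G"): 3.0,
    ("A", "T"): 2.0,
    ("T", "A"): 2.0,
    ("G", "T"): 1.0,
    ("T", "G"): 1.0,
}

TAIL_WEIGHTS = (2.0, 1.5, 1.5, 1.0, 1.0, 0.5, 0.5, 0.5)

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class HairpinCandidate:
    """A stem-loop within a scanned sequence (coordinates in scan orientation)."""

    stem_len: int
    loop_len: int
    start: int  # 0-based offset of the 5' stem arm within the scanned sequence
    hairpin_score: float


@dataclass(frozen=True)
class TerminatorHit:
    """A scored terminator in genome-forward coordinates.

    ``hairpin_iv`` and ``tract_iv`` are 0-based half-open genome intervals;
    on the minus strand the tract lies to the *left* of the hairpin in genome
    coordinates (it is 3' on the transcript). The footprint is their union.
    """

    contig_id: str
    strand: str
    stem_len: int
    loop_len: int
    hairpin_iv: tuple[int, int]
    tract_iv: tuple[int, int]
    hairpin_score: float
    tail_score: float

    @property
    def total_score(self) -> float:
        return self.hairpin_score + self.tail_score

    @property
    def footprint(self) -> tuple[int, int]:
        return (
            min(self.hairpin_iv[0], self.tract_iv[0]),
            max(self.hairpin_iv[1], self.tract_iv[1]),
        )


def hairpin_score(
    stem_pairs: list[tuple[str, str]], loop_len: int, params: TerminatorParams | None = None
) -> float:
    """Sum of pair weights minus the linear loop penalty."""
    params = params or TerminatorParams()
    total = 0.0
    for pair in stem_pairs:
        if pair not in PAIR_WEIGHTS:
            raise ValueError(f"disallowed base pair {pair!r}")
        total += PAIR_WEIGHTS[pair]
    return total - params.loop_lambda * (loop_len - params.loop_min)


def tail_score(tail: str) -> float:
    """Positionally weighted T-content of the 8-nt window after the stem.

    Shorter input is padded with N (scores 0), mirroring a hairpin that sits
    at the very end of the scanned sequence.
    """
    tail = (tail + "N" * 8)[:8]
    return sum(w for w, base in zip(TAIL_WEIGHTS, tail) if base == "T")


def _scan_plus(seq: str, params: TerminatorParams) -> list[tuple]:
    """Enumerate all qualifying hairpin+tract hits in scan orientation.

    Returns raw tuples (start, stem_len, loop_len, hp_score, t_score,
    tract_start, tract_end) before overlap resolution. Stems are grown
    outward from each loop window so the enumeration is incremental yet
    exactly equivalent to trying every (start, stem_len, loop_len) triple.
    """
    n = len(seq)
    hits = []
    lam, lmin = params.loop_lambda, params.loop_min
    for loop_len in range(params.loop_min, params.loop_max + 1):
        penalty = lam * (loop_len - lmin)
        for loop_start in range(1, n):
            right0 = loop_start + loop_len
            if right0 >= n:
                break
            # grow the stem outward while bases pair
            score = 0.0
            k = 0
            while k < params.stem_max:
                li = loop_start - 1 - k
                ri = right0 + k
                if li < 0 or ri >= n:
                    break
                w = PAIR_WEIGHTS.get((seq[li], seq[ri]))
                if w is None:
                    break
                score += w
                k += 1
                if k < params.stem_min:
                    continue
                hp = score - penalty
                if hp < params.hairpin_min_score:
                    continue
                tract_start = right0 + k
                t = tail_score(seq[tract_start : tract_start + params.tract_len])
                if t < params.tail_min_score:
                    continue
                hits.append(
                    (
                        loop_start - k,
                        k,
                        loop_len,
                        hp,
                        t,
                        tract_start,
                        min(n, tract_start + params.tract_len),
                    )
                )
    return hits


def find_terminators(
    seq: str,
    strand_label: str = "+",
    params: TerminatorParams | None = None,
    offset: int = 0,
    contig_id: str = "",
) -> list[TerminatorHit]:
    """Scan a sequence for intrinsic terminators on one strand.

    For ``strand_label == "-"`` the caller passes the reverse complement of
    the genome window and coordinates are mirrored back to the forward
    frame, so ``offset`` is always the forward-genome start of the window.
    Overlapping hits are resolved greedily by total score (ties: leftmost in
    scan orientation, then longest stem); output is sorted by genome
    position.
    """
    params = params or TerminatorParams()
    if strand_label not in ("+", "-"):
        raise ValueError("strand_label must be + or -")
    n = len(seq)
    raw = _scan_plus(seq, params)
    # overlap resolution in scan orientation
    raw.sort(key=lambda h: (-(h[3] + h[4]), h[0], -h[1]))
    taken: list[tuple[int, int]] = []
    kept = []
    for h in raw:
        s, e = h[0], h[6]
        if any(s < te and e > ts for ts, te in taken):
            continue
        taken.append((s, e))
        kept.append(h)

    out = []
    for start, k, loop_len, hp, t, ts, te in kept:
        hp_iv_scan = (start, start + 2 * k + loop_len)
        tract_iv_scan = (ts, te)
        if strand_label == "+":
            hp_iv = (offset + hp_iv_scan[0], offset + hp_iv_scan[1])
            tract_iv = (offset + tract_iv_scan[0], offset + tract_iv_scan[1])
        else:
            hp_iv = (offset + n - hp_iv_scan[1], offset + n - hp_iv_scan[0])
            tract_iv = (offset + n - tract_iv_scan[1], offset + n - tract_iv_scan[0])
        out.append(
            TerminatorHit(
                contig_id=contig_id,
                strand=strand_label,
                stem_len=k,
                loop_len=loop_len,
                hairpin_iv=hp_iv,
                tract_iv=tract_iv,
                hairpin_score=hp,
                tail_score=t,
            )
        )
    out.sort(key=lambda h: h.footprint)
    return out


@dataclass(frozen=True)
class OpposingPair:
    """T1 (+ strand, ends gene_plus) and T2 (- strand, ends gene_minus).

    ``insertion_point`` is the midpoint of the interval strictly between the
    two footprints, or None when the footprints touch or overlap.
    """

    t1: TerminatorHit
    t2: TerminatorHit
    insertion_point: Optional[int]


def find_opposing_pair(
    genome: GenomeRecord,
    pair: ConvergentPair,
    params: TerminatorParams | None = None,
) -> Optional[OpposingPair]:
    """Find the best opposing terminator pair around a convergent gap.

    The search region is the last ``search_up`` nt of each gene plus the
    entire gap. Returns None unless a + strand hit and a - strand hit both
    exist; the best hit per strand is the one maximising total score (ties:
    leftmost, then longest stem).
    """
    params = params or TerminatorParams()
    gp, gm = pair.gene_plus, pair.gene_minus
    lo = max(gp.start, gp.end - params.search_up)
    hi = min(gm.end, gm.start + params.search_up)
    window = genome.sequence[lo:hi]
    plus_hits = find_terminators(window, "+", params, offset=lo, contig_id=genome.contig_id)
    minus_hits = find_terminators(
        revcomp(window), "-", params, offset=lo, contig_id=genome.contig_id
    )
    if not plus_hits or not minus_hits:
        return None

    def best(hits: list[TerminatorHit]) -> TerminatorHit:
        return min(hits, key=lambda h: (-h.total_score, h.footprint[0], -h.stem_len))

    t1, t2 = best(plus_hits), best(minus_hits)
    a = t1.footprint[1]  # T1 tract end on the genome
    b = t2.footprint[0]  # T2 tract end is its leftmost genome coordinate
    insertion = (a + b) // 2 if a < b else None
    return OpposingPair(t1=t1, t2=t2, insertion_point=insertion)


def hits_to_gff3(hits: list[TerminatorHit], path) -> None:
    """Export terminator hits as GFF3 rows (type=terminator)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, h in enumerate(hits):
            s, e = h.footprint
            attrs = (
                f"ID=term{i};stem_len={h.stem_len};loop_len={h.loop_len};"
                f"tract_start={h.tract_iv[0] + 1};tract_end={h.tract_iv[1]}"
            )
            fh.write(
                f"{h.contig_id}\tinsite\tterminator\t{s + 1}\t{e}\t"
                f"{h.total_score:g}\t{h.strand}\t.\t{attrs}\n"
            )
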