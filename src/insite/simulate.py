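"""Synthetic genomes, annotations and multi-condition coverage with ground truth.

The generator emulates the statistical structure the insulated-site screen
assumes: heterogeneous gene expression across conditions (log-normal gene
means), overdispersed per-base counts (negative binomial), sharp coverage
drop-off after intrinsic terminators, and decoy loci of four classes:

* ``no_terminator`` — convergent pair, silent gap, but no hairpin on either
  strand (passes insulation, must be rejected at the terminator filter)
* ``read_through``  — convergent pair with planted terminators but high gap
  coverage (must be rejected at the insulation filter)
* ``tandem`` / ``divergent`` — wrong gene geometry

Planted terminators use the same hairpin+U-tract grammar the predictor
searches, with jittered GC-rich arms so no single sequence is hard-coded.
Read-through past a planted terminator adds a constant ``rho * gene_mean``
to the gap on top of the intergenic background, so at ``rho = 0`` a true
gap sits exactly at background. Per-condition flank means of true-site and
read-through loci are redrawn until the locus satisfies its own class
definition with margin (a planted "true site" must actually be insulated
in expectation, or the truth labels would be wrong).

Everything is a pure function of the spec's seed: the same spec produces
byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import TerminatorParams
from .convergent import ConvergentPair
from .formats_io import (
    CoverageTrack,
    GeneFeature,
    GenomeAnnotation,
    GenomeRecord,
    write_bedgraph,
    write_fasta,
    write_gff3,
)
from .terminators import PAIR_WEIGHTS, find_opposing_pair, find_terminators, revcomp

PAIR_CLASSES = ("true_site", "no_terminator", "read_through", "tandem", "divergent")


class PackingError(RuntimeError):
    """Loci do not fit in the requested genome length."""


@dataclass
class SimulationSpec:
    """All knobs of the generator; defaults are the pinned benchmark.

    ``expr_mu``/``expr_sigma`` parameterise the log-normal of per-gene,
    per-condition means (reads/base); ``nb_dispersion`` is the shared NB
    dispersion k (variance m + k*m^2); ``rho`` is the terminator
    read-through fraction and ``background`` the intergenic mean b.
    ``spacing_range`` starts above the screen's default gap_max so adjacent
    loci never form accidental candidate pairs.
    """

    genome_len: int = 200_000
    n_genes: int = 60
    n_true_sites: int = 5
    n_decoys: dict[str, int] = field(
        default_factory=lambda: {
            "no_terminator": 5,
            "read_through": 5,
            "tandem": 5,
            "divergent": 5,
        }
    )
    n_conditions: int = 3
    expr_mu: float = math.log(100.0)
    expr_sigma: float = 0.8
    nb_dispersion: float = 0.3
    rho: float = 0.02
    rho_weak: float = 0.1
    background: float = 0.5
    seed: int = 17
    contig_id: str = "synth1"
    gene_len_range: tuple[int, int] = (800, 1600)
    gap_len_range: tuple[int, int] = (180, 320)
    spacing_range: tuple[int, int] = (600, 900)
    # class-conditioning of flank means: a planted site must satisfy its own
    # definition in expectation (see module docstring)
    flank_floor: float = 60.0
    gap_budget: float = 4.0
    index_floor: float = 3.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must be in [0, 1]")
        if self.n_true_sites < 0 or any(v < 0 for v in self.n_decoys.values()):
            raise ValueError("locus counts must be >= 0")
        if self.n_conditions < 1:
            raise ValueError("need at least one condition")
        unknown = set(self.n_decoys) - set(PAIR_CLASSES)
        if unknown:
            raise ValueError(f"unknown decoy classes {sorted(unknown)}")

    @property
    def n_pair_loci(self) -> int:
        return self.n_true_sites + sum(self.n_decoys.values())

    @property
    def n_fillers(self) -> int:
        n = self.n_genes - 2 * self.n_pair_loci
        if n < 0:
            raise ValueError("n_genes too small for the requested pair loci")
        return n


@dataclass
class LocusTruth:
    """One planted locus: geometry, terminators and per-condition means."""

    locus_id: str
    locus_class: str  # true_site, no_terminator, read_through, tandem, divergent, filler
    gene_ids: tuple[str, ...]
    gene_intervals: tuple[tuple[int, int], ...]
    strands: tuple[str, ...]
    gap: Optional[tuple[int, int]]
    terminators: tuple[tuple[str, int, int], ...]  # (strand, footprint start, end)
    gene_means: dict[str, tuple[float, ...]]  # condition_id -> per-gene mean


@dataclass
class TruthManifest:
    contig_id: str
    genome_len: int
    condition_ids: tuple[str, ...]
    loci: list[LocusTruth]

    def loci_of(self, locus_class: str) -> list[LocusTruth]:
        return [l for l in self.loci if l.locus_class == locus_class]

    @property
    def true_gaps(self) -> list[tuple[int, int]]:
        return [l.gap for l in self.loci_of("true_site")]

    def to_json(self, path: str | Path) -> None:
        d = {
            "contig_id": self.contig_id,
            "genome_len": self.genome_len,
            "condition_ids": list(self.condition_ids),
            "loci": [
                {
                    "locus_id": l.locus_id,
                    "locus_class": l.locus_class,
                    "gene_ids": list(l.gene_ids),
                    "gene_intervals": [list(iv) for iv in l.gene_intervals],
                    "strands": list(l.strands),
                    "gap": list(l.gap) if l.gap else None,
                    "terminators": [list(t) for t in l.terminators],
                    "gene_means": {c: list(m) for c, m in l.gene_means.items()},
                }
                for l in self.loci
            ],
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            contig_id=d["contig_id"],
            genome_len=d["genome_len"],
            condition_ids=tuple(d["condition_ids"]),
            loci=[
                LocusTruth(
                    locus_id=l["locus_id"],
                    locus_class=l["locus_class"],
                    gene_ids=tuple(l["gene_ids"]),
                    gene_intervals=tuple(tuple(iv) for iv in l["gene_intervals"]),
                    strands=tuple(l["strands"]),
                    gap=tuple(l["gap"]) if l["gap"] else None,
                    terminators=tuple(tuple(t) for t in l["terminators"]),
                    gene_means={c: tuple(m) for c, m in l["gene_means"].items()},
                )
                for l in d["loci"]
            ],
        )

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for l in self.loci:
            rows.append(
                {
                    "locus_id": l.locus_id,
                    "locus_class": l.locus_class,
                    "genes": ",".join(l.gene_ids),
                    "gap_start": l.gap[0] if l.gap else "",
                    "gap_end": l.gap[1] if l.gap else "",
                    "terminators": ";".join(f"{s}:{a}-{b}" for s, a, b in l.terminators),
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sequence pieces
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _rand_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _terminator_motif(rng: np.random.Generator, min_score: float = 16.0) -> str:
    """A jittered intrinsic-terminator motif: GC-rich perfect stem, short
    loop whose ends do not pair (no alternative register), full T-tract."""
    while True:
        k = int(rng.integers(8, 13))
        arm1 = "".join(rng.choice(list("GCAT"), size=k, p=[0.4, 0.4, 0.1, 0.1]))
        loop_len = int(rng.integers(3, 6))
        loop = _rand_dna(rng, loop_len)
        if (loop[0], loop[-1]) in PAIR_WEIGHTS:
            continue
        arm2 = revcomp(arm1)
        score = sum(
            PAIR_WEIGHTS[(a, b)] for a, b in zip(arm1, arm2[::-1])
        ) - (loop_len - 3)
        if score >= min_score:
            return arm1 + loop + arm2 + "TTTTTTTT"


def _draw_mean(rng: np.random.Generator, spec: SimulationSpec) -> float:
    return float(np.exp(rng.normal(spec.expr_mu, spec.expr_sigma)))


def _draw_pair_means(
    rng: np.random.Generator, spec: SimulationSpec, conditioned: bool
) -> tuple[float, float]:
    """Flank means for a pair locus; conditioned classes redraw until the
    locus satisfies its definition in expectation with margin.

    When the read-through fraction is so large that no flank level can keep
    the expected gap within budget (e.g. rho near 1), only the expression
    floor is enforced — such a site cannot be insulated by construction.
    """
    insulable = (
        spec.background + spec.rho * 2.0 * spec.flank_floor <= spec.gap_budget
    )
    for _ in range(10_000):
        m1, m2 = _draw_mean(rng, spec), _draw_mean(rng, spec)
        if not conditioned:
            return m1, m2
        f = min(m1, m2)
        if f < spec.flank_floor:
            continue
        if insulable:
            exp_gap = spec.background + spec.rho * (m1 + m2)
            if exp_gap > spec.gap_budget:
                continue
            if math.log2((f + 1.0) / (exp_gap + 1.0)) < spec.index_floor:
                continue
        return m1, m2
    raise RuntimeError("could not draw conditioned flank means; widen the model")


# ---------------------------------------------------------------------------
# locus construction
# ---------------------------------------------------------------------------


# Substitutes x (given partner y) such that (x, y) pairs on neither strand:
# (x, y) not in PAIR_WEIGHTS and (comp(y), comp(x)) not in PAIR_WEIGHTS.
# G:U wobble is not complement-symmetric, so both checks are needed.
_NONPAIRING_BOTH = {"A": "AG", "C": "CT", "G": "AG", "T": "CT", "N": "ACGT"}


def _strip_terminators(
    seq: str, lo: int, hi: int, rng: np.random.Generator, params: TerminatorParams
) -> str:
    """Mutate single stem bases until [lo, hi) holds no qualifying hit on
    either strand. Random sequence at the default thresholds almost always
    contains weak hits, so no_terminator loci are built by disruption rather
    than whole-region rejection."""
    s = list(seq)
    for _ in range(400):
        window = "".join(s[lo:hi])
        hits = find_terminators(window, "+", params, offset=lo) + find_terminators(
            revcomp(window), "-", params, offset=lo
        )
        if not hits:
            return "".join(s)
        h = hits[0]
        a, b = h.hairpin_iv
        # pick a pair of the stem (in genome frame) and break it
        j = int(rng.integers(0, h.stem_len))
        left, right = a + j, b - 1 - j
        y = s[right]
        choices = [c for c in _NONPAIRING_BOTH[y] if c != s[left]]
        s[left] = choices[int(rng.integers(0, len(choices)))]
    raise RuntimeError("could not strip terminators from decoy region")


@dataclass
class _Locus:
    locus_class: str
    seq: str
    gene_local: list[tuple[int, int, str]]  # (start, end, strand) within seq
    term_local: list[tuple[str, int, int]]  # (strand, footprint start, end) within seq


def _build_pair_locus(
    rng: np.random.Generator, spec: SimulationSpec, cls: str, tparams: TerminatorParams
) -> _Locus:
    """One two-gene locus, rejection-sampled so the planted terminator truth
    is exactly what the scanner recovers (or, for no_terminator, absent)."""
    with_terms = cls in ("true_site", "read_through")
    for _ in range(500):
        la = int(rng.integers(*spec.gene_len_range))
        lb = int(rng.integers(*spec.gene_len_range))
        gap = int(rng.integers(*spec.gap_len_range))
        if cls == "tandem":
            strands = ("+", "+")
        elif cls == "divergent":
            strands = ("-", "+")
        else:
            strands = ("+", "-")
        terms: list[tuple[str, int, int]] = []
        if with_terms:
            ta = _terminator_motif(rng)
            tb = _terminator_motif(rng)
            # 'C' guard before a plus-strand stem (and its mirror) blocks
            # outward stem extension into the T-tract
            gene_a = _rand_dna(rng, la - len(ta) - 1) + "C" + ta
            gene_b = revcomp(tb) + "G" + _rand_dna(rng, lb - len(tb) - 1)
            terms = [("+", la - len(ta), la), ("-", la + gap, la + gap + len(tb))]
        else:
            gene_a = _rand_dna(rng, la)
            gene_b = _rand_dna(rng, lb)
        seq = gene_a + _rand_dna(rng, gap) + gene_b
        if cls == "no_terminator":
            lo = max(0, la - tparams.search_up)
            hi = min(len(seq), la + gap + tparams.search_up)
            seq = _strip_terminators(seq, lo, hi, rng, tparams)
        locus = _Locus(
            locus_class=cls,
            seq=seq,
            gene_local=[(0, la, strands[0]), (la + gap, la + gap + lb, strands[1])],
            term_local=terms,
        )
        if strands != ("+", "-"):
            return locus  # wrong geometry by construction; nothing to verify
        if _pair_locus_ok(locus, tparams, with_terms):
            return locus
    raise RuntimeError(f"could not realise a {cls!r} locus in 500 attempts")


def _pair_locus_ok(locus: _Locus, tparams: TerminatorParams, with_terms: bool) -> bool:
    """Scan the locus with the real predictor: planted terminators must be
    the best recovered hits; no_terminator loci must yield no opposing pair."""
    record = GenomeRecord("locus", locus.seq)
    (a0, a1, _), (b0, b1, _) = locus.gene_local
    pair = ConvergentPair(
        gene_plus=GeneFeature("A", "locus", a0, a1, "+"),
        gene_minus=GeneFeature("B", "locus", b0, b1, "-"),
    )
    opp = find_opposing_pair(record, pair, tparams)
    if not with_terms:
        return opp is None
    if opp is None or opp.insertion_point is None:
        return False
    want_t1 = tuple(locus.term_local[0][1:])
    want_t2 = tuple(locus.term_local[1][1:])
    return opp.t1.footprint == want_t1 and opp.t2.footprint == want_t2


def _build_filler(rng: np.random.Generator, spec: SimulationSpec) -> _Locus:
    n = int(rng.integers(*spec.gene_len_range))
    strand = "+" if rng.random() < 0.5 else "-"
    return _Locus("filler", _rand_dna(rng, n), [(0, n, strand)], [])


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def simulate_genome(
    spec: SimulationSpec,
) -> tuple[GenomeRecord, GenomeAnnotation, TruthManifest]:
    """Emit a genome, its annotation, and the ground-truth manifest."""
    rng = np.random.default_rng(spec.seed)
    tparams = TerminatorParams()
    plan = (
        ["true_site"] * spec.n_true_sites
        + [c for c in ("no_terminator", "read_through", "tandem", "divergent")
           for _ in range(spec.n_decoys.get(c, 0))]
        + ["filler"] * spec.n_fillers
    )
    order = rng.permutation(len(plan))
    plan = [plan[i] for i in order]

    pieces: list[str] = []
    loci: list[LocusTruth] = []
    conditions = tuple(f"cond{i + 1}" for i in range(spec.n_conditions))
    pos = 0
    gene_counter = 0
    genes: list[GeneFeature] = []
    for idx, cls in enumerate(plan):
        spacing = int(rng.integers(*spec.spacing_range))
        if cls == "filler":
            locus = _build_filler(rng, spec)
        else:
            locus = _build_pair_locus(rng, spec, cls, tparams)
        if pos + spacing + len(locus.seq) > spec.genome_len:
            raise PackingError(
                "loci do not fit: increase genome_len or reduce locus counts"
            )
        pieces.append(_rand_dna(rng, spacing))
        pos += spacing
        offset = pos
        pieces.append(locus.seq)
        pos += len(locus.seq)

        ids = []
        ivs = []
        strands = []
        for s, e, st in locus.gene_local:
            gene_counter += 1
            gid = f"g{gene_counter:03d}"
            ids.append(gid)
            ivs.append((offset + s, offset + e))
            strands.append(st)
            genes.append(GeneFeature(gid, spec.contig_id, offset + s, offset + e, st))

        conditioned = cls in ("true_site", "read_through", "no_terminator")
        means: dict[str, tuple[float, ...]] = {}
        for c in conditions:
            if len(ids) == 2:
                means[c] = _draw_pair_means(rng, spec, conditioned)
            else:
                means[c] = (_draw_mean(rng, spec),)

        gap = (ivs[0][1], ivs[1][0]) if len(ivs) == 2 else None
        loci.append(
            LocusTruth(
                locus_id=f"L{idx:03d}",
                locus_class=cls,
                gene_ids=tuple(ids),
                gene_intervals=tuple(ivs),
                strands=tuple(strands),
                gap=gap,
                terminators=tuple(
                    (st, offset + a, offset + b) for st, a, b in locus.term_local
                ),
                gene_means=means,
            )
        )

    if pos < spec.genome_len:
        pieces.append(_rand_dna(rng, spec.genome_len - pos))
    genome = GenomeRecord(spec.contig_id, "".join(pieces))
    annotation = GenomeAnnotation(
        genes=genes, contig_lengths={spec.contig_id: spec.genome_len}
    )
    manifest = TruthManifest(
        contig_id=spec.contig_id,
        genome_len=spec.genome_len,
        condition_ids=conditions,
        loci=loci,
    )
    return genome, annotation, manifest


def expected_coverage(
    manifest: TruthManifest, spec: SimulationSpec, condition_id: str
) -> np.ndarray:
    """Closed-form per-base expected coverage for one condition.

    Gene bodies sit at their drawn mean; gaps at true sites carry background
    plus rho read-through from both flanks; read_through-decoy gaps carry
    (1 - rho_weak) of the weaker flank mean; everything else intergenic is
    background.
    """
    mean = np.full(spec.genome_len, spec.background, dtype=float)
    for locus in manifest.loci:
        ms = locus.gene_means[condition_id]
        for (s, e), m in zip(locus.gene_intervals, ms):
            mean[s:e] = m
        if locus.gap is None:
            continue
        gs, ge = locus.gap
        if locus.locus_class == "true_site":
            mean[gs:ge] = spec.background + spec.rho * (ms[0] + ms[1])
        elif locus.locus_class == "read_through":
            mean[gs:ge] = (1.0 - spec.rho_weak) * min(ms)
        # no_terminator / tandem / divergent gaps stay at background
    return mean


def simulate_coverage(
    manifest: TruthManifest, spec: SimulationSpec
) -> list[CoverageTrack]:
    """Negative-binomial per-base counts around the closed-form expectation.

    Variance is mean + k * mean^2 with the spec's shared dispersion k; the
    RNG stream is derived from the spec seed, independent of the genome
    stream, so coverage is reproducible on its own.
    """
    k = spec.nb_dispersion
    tracks = []
    for ci, cond in enumerate(manifest.condition_ids):
        rng = np.random.default_rng([spec.seed, 1000 + ci])
        mean = expected_coverage(manifest, spec, cond)
        if k > 0:
            n = 1.0 / k
            p = n / (n + mean)
            counts = rng.negative_binomial(n, p).astype(float)
        else:
            counts = rng.poisson(mean).astype(float)
        tracks.append(
            CoverageTrack(condition_id=cond, values={manifest.contig_id: counts})
        )
    return tracks


def write_simulation(
    outdir: str | Path,
    genome: GenomeRecord,
    annotation: GenomeAnnotation,
    tracks: list[CoverageTrack],
    manifest: TruthManifest,
) -> dict[str, Path]:
    """Write FASTA, GFF3, one BedGraph per condition and the truth manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["fasta"] = outdir / "genome.fasta"
    write_fasta([genome], paths["fasta"])
    paths["gff3"] = outdir / "genes.gff3"
    write_gff3(annotation, paths["gff3"])
    for t in tracks:
        p = outdir / f"{t.condition_id}.bedgraph"
        write_bedgraph(t, p)
        paths[t.condition_id] = p
    paths["truth_json"] = outdir / "truth.json"
    manifest.to_json(paths["truth_json"])
    paths["truth_tsv"] = outdir / "truth.tsv"
    manifest.to_tsv(paths["truth_tsv"])
    return paths


def default_benchmark_spec(seed: int = 17) -> SimulationSpec:
    """The pinned benchmark: 200 kb, 60 genes, 5 true sites, 20 decoys,
    3 conditions, log-normal(log 100, 0.8) means, NB dispersion 0.3,
    rho = 0.02, background 0.5."""
    return SimulationSpec(seed=seed)
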