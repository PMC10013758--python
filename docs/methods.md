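# Methods

## Problem statement

An *insulated site* is a chromosomal location suitable for knocking in a
heterologous expression cassette: an intergenic gap between two convergently
transcribed genes, transcriptionally silent under all assayed conditions,
whose flanking genes are constitutively well expressed, and which is bounded
on both sides by intrinsic (Rho-independent) terminators pointing into the
gap. The two terminators insulate the insert from transcriptional
read-through in both directions; the active flanks indicate an open region of
the nucleoid where an insert is unlikely to be silenced.

`insite` implements (a) a screen that ranks candidate sites from a genome,
its annotation, and per-condition coverage; (b) a cassette/knock-in designer;
and (c) a synthetic benchmark generator with a ground-truth manifest.

## Coordinate conventions

All internal coordinates are 0-based, half-open `[start, end)` on the forward
strand. Conversion to 1-based inclusive coordinates happens only at the GFF3
and GenBank boundaries. Minus-strand scans are performed on the reverse
complement of the window and mirrored back, so all reported intervals are in
forward-genome coordinates.

## Convergent-pair geometry

Genes are sorted by `(contig, start)`. A candidate pair is two *adjacent*
genes `g⁺` (strand `+`) followed by `g⁻` (strand `-`); the gap is
`[end(g⁺), start(g⁻))`. Filters: `gap_min ≤ |gap| ≤ gap_max`
(defaults 40 and 500 bp) and no annotated gene overlapping the gap. Adjacency
means consecutive in sorted order, so tandem (`+ +`, `- -`) and divergent
(`- +`) neighbours never form candidates.

Parameter rationale: below ~40 bp there is no room for an insert between two
terminator footprints; above ~500 bp the "gap" is likely to contain
unannotated features and the silence signal becomes diluted.

## Intrinsic-terminator model

A terminator is a hairpin followed by a U-rich tract, scored on the coding
strand of the gene it ends.

**Hairpin.** Gap-free exact pairing of two stem arms around a loop. Allowed
pairs and weights: `G:C`/`C:G` = 3, `A:T`/`T:A` = 2, `G:T`/`T:G` = 1 (wobble).
Stem length 4–20 bp, loop length 3–9 nt. Score =
`Σ pair weights − λ·(loop − loop_min)` with `λ = 1`, `loop_min = 3`.
The scan grows stems outward from every loop window, which is exactly
equivalent to enumerating every `(start, stem, loop)` triple (this equivalence
is asserted against a brute-force oracle in the tests).

**Tract.** The 8 nt immediately downstream of the hairpin, with positional
weights `(2.0, 1.5, 1.5, 1.0, 1.0, 0.5, 0.5, 0.5)` summed over positions that
are `T`. Sequences shorter than 8 nt are padded conceptually with
non-matching bases.

A hit qualifies when hairpin score ≥ `H_min = 8` and tract score ≥
`T_min = 3`. Overlapping hits are resolved greedily by total score (ties:
leftmost in scan orientation, then longest stem). These thresholds admit weak
but recognisable terminators while rejecting chance hairpins in random
sequence; the benchmark plants much stronger motifs (score ≥ 16) so recovery
does not ride the threshold.

**Opposing pair.** For a convergent pair, T1 must lie on `+` within the last
`search_up = 200` nt of `g⁺` plus the gap, and T2 on `-` within the mirror
window. The best hit per strand is kept (highest total score; ties broken by
footprint position, then stem length). The insertion point is
`(end(T1 footprint) + start(T2 footprint)) // 2` when the footprints are
disjoint in the right order, else the site has no valid insertion point and
is dropped.

## Insulation index

For condition `c`, flank value
`f_c = min(mean cov over 3′-terminal w nt of g⁺, same for g⁻)` with
`w = 150`, gap value `gap_c` = mean coverage over the gap, pseudocount
`p = 1`:

    index_c = log2((f_c + p) / (gap_c + p)),      index = min_c index_c.

A site passes when every `f_c ≥ E_min = 20` (flanks expressed in *all*
conditions), `index ≥ I_min = 3` (≥ 8-fold contrast), and
`max_c gap_c ≤ G_max = 5` (absolutely silent, not just relatively). The
pseudocount keeps the statistic finite on empty gaps and damps shot noise at
low coverage; `w = 150` is of the order of an RNA-seq library insert so the
window reflects local 3′ coverage rather than whole-gene averages.

## Ranking

    rank = index + 0.1 · (total_score(T1) + total_score(T2))

The index dominates (it is the biological quantity of interest); the small
terminator term breaks ties in favour of strongly insulated sites. Output is
sorted by descending rank, then position, and is invariant to the input order
of genes.

## Cassette and knock-in design

The cassette is `promoter — spacer — fusion CDS — terminator`:

- default promoter: σ70 consensus `TTGACA`-N17-`TATAAT` followed by a strong
  Shine–Dalgarno (`AGGAGG`) 7 nt upstream of the start codon — a stand-in,
  replaceable by any sequence;
- the fusion CDS is `ATG + tag + payload body`: the secretion-tag segment is
  taken from a donor protein by a registry recipe and back-translated with a
  fixed E. coli-biased codon table; the payload's own start codon is dropped
  (configurable). Registry recipes: `ftsP` 30 aa, `ompA` 27 aa, `tamA` 27 aa,
  `lpp-ompA` 29 aa Lpp + OmpA residues 46–159, `yebF` full 118 aa carrier,
  `inpNC` 211 aa N-domain + 99 aa C-domain;
- default terminator: a synthetic strong hairpin with a GC-clamped 10 bp stem
  and U8 tract, labelled synthetic.

A knock-in construct adds homology arms copied from the genome on either side
of the site's insertion point. `validate_design` runs five checks (frame, no
internal stops, element order, arm/genome identity, arms clear of the
terminator footprints) and the GenBank writer refuses unvalidated constructs.
`recombine` and `excise` are exact inverses.

Translation uses the bacterial codon table (NCBI table 11) for validation
only; back-translation uses one fixed codon per amino acid, so
`translate(back_translate(aa)) == aa` exactly.

## Synthetic benchmark generator

The generator emulates a bacterial chromosome with planted ground truth; it
does **not** emulate realistic sequence composition, operonic structure,
RNA-polymerase kinetics, or mapping artefacts.

**Layout.** Loci (gene pairs or single fillers) are placed sequentially with
inter-locus spacing drawn from 600–900 bp — deliberately above `gap_max` so
no accidental cross-locus candidate pairs arise. Gene lengths 800–1600 bp,
pair gaps 180–320 bp. Each gene's annotated interval extends through its
planted terminator (tract end = gene end), so the annotated gap is exactly
the inter-footprint region and the gap coverage statistic is meaningful.

**Locus classes.** `true_site` (convergent, two strong planted terminators,
silent gap), and decoys: `no_terminator` (convergent and silent but with all
qualifying terminator hits ablated), `read_through` (convergent with
terminators but leaky coverage), `tandem` and `divergent` (wrong geometry).
Planted terminator motifs use GC-rich stems (8–12 bp, loop 3–5 nt,
hairpin score ≥ 16) with a `C`/`G` guard base between hairpin and tract to
stop wobble pairing from extending the stem into the U-tract; the builder
verifies that the scanner recovers each planted footprint exactly.
`no_terminator` loci are created by iterative targeted single-base stem
disruption using substitutions that cannot pair on either strand (G·U wobble
is not complement-symmetric, so the safe sets are `A→{A,G}`-complements
etc.); whole-locus rejection sampling is infeasible because random
~700 nt windows almost always contain weak qualifying hits at the
production thresholds.

**Coverage.** Per-base means: gene bodies at their drawn lognormal mean
(`exp(N(log 100, 0.8))` per condition), background `b = 0.5`, true-site gaps
`b + ρ·(m⁺ + m⁻)` with read-through fraction `ρ = 0.02`, `read_through` gaps
`(1 − ρ_weak)·min(m⁺, m⁻)` with `ρ_weak = 0.1` (i.e. only 10 % attenuation —
clearly leaky). Counts are negative-binomial with `var = m + k·m²`,
`k = 0.3`, seeded per condition from the spec seed; `simulate_coverage` is
byte-deterministic. The read-through model is a strandless step function —
a simplification; at `ρ = 1` the gap carries the *sum* of both flank means,
which the tests treat simply as "no insulation".

**A-priori conditioning.** So that planted classes realise their definitions
under the noise model, conditioned classes redraw flank means until
`min ≥ 60`, expected gap mean ≤ 4.0, and expected index ≥ 3.5 — chosen from
the model in advance of any pipeline run, with margins inside the filter
thresholds (`E_min = 20`, `G_max = 5`, `I_min = 3`). When `ρ` makes
insulation unsatisfiable in expectation (e.g. `ρ = 1`), only the flank floor
is enforced.

## Numerical choices

- Coverage tracks are dense float64 per-base vectors; at benchmark scale
  (200 kb × 3 conditions) this is ~5 MB.
- Means over windows use `numpy.mean`; the index is computed in float64 and
  reported to 6 decimals in the TSV.
- All randomness flows from explicit seeds through
  `numpy.random.default_rng`; per-condition streams use `[seed, 1000+i]`
  seed sequences.

## Limitations

- The terminator model is gap-free (no bulges or internal loops) and uses
  additive pair weights, not a thermodynamic nearest-neighbour energy; it is
  a screen, not a folding algorithm.
- The insulation statistic assumes strand-agnostic coverage; with
  strand-specific RNA-seq the two gap strands could be scored separately.
- The read-through model in the generator is a step function and does not
  decay with distance from the gene 3′ end.
- The σ70 promoter and synthetic terminator defaults are stand-ins for
  experimentally validated parts; designs should substitute characterised
  sequences before synthesis.
- Condition coverage is treated as given; no normalisation between
  libraries is performed.
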