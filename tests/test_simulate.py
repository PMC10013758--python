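"""Generator truth-consistency: determinism, planted structure, noise model."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from insite import (
    ConvergentPair,
    SimulationSpec,
    find_terminators,
    insulation_index,
    passes_insulation,
    simulate_coverage,
    simulate_genome,
)
from insite.simulate import PackingError, expected_coverage
from insite.terminators import revcomp


def _gene_lookup(annotation):
    return {g.gene_id: g for g in annotation.genes}


def _pair_of(locus, genes):
    a, b = (genes[i] for i in locus.gene_ids)
    return ConvergentPair(gene_plus=a, gene_minus=b)


class TestDeterminism:
    def test_same_seed_identical_outputs(self, small_spec):
        g1, a1, m1 = simulate_genome(small_spec)
        g2, a2, m2 = simulate_genome(small_spec)
        assert g1.sequence == g2.sequence
        assert a1.genes == a2.genes
        assert [l.gene_means for l in m1.loci] == [l.gene_means for l in m2.loci]
        t1 = simulate_coverage(m1, small_spec)
        t2 = simulate_coverage(m2, small_spec)
        for x, y in zip(t1, t2):
            assert np.array_equal(x.values[g1.contig_id], y.values[g1.contig_id])

    def test_different_seed_differs(self, small_spec):
        g1, _, _ = simulate_genome(small_spec)
        g2, _, _ = simulate_genome(dataclasses.replace(small_spec, seed=99))
        assert g1.sequence != g2.sequence


class TestBookkeeping:
    def test_manifest_counts(self, small_sim, small_spec):
        _, annotation, manifest, _ = small_sim
        assert len(manifest.loci_of("true_site")) == small_spec.n_true_sites
        for cls, n in small_spec.n_decoys.items():
            assert len(manifest.loci_of(cls)) == n
        assert len(annotation.genes) == small_spec.n_genes
        n_pairs = small_spec.n_pair_loci
        assert len(manifest.loci) == n_pairs + small_spec.n_fillers

    def test_manifest_consistent_with_annotation(self, small_sim):
        _, annotation, manifest, _ = small_sim
        genes = _gene_lookup(annotation)
        for locus in manifest.loci:
            for gid, iv, strand in zip(locus.gene_ids, locus.gene_intervals, locus.strands):
                assert (genes[gid].start, genes[gid].end) == iv
                assert genes[gid].strand == strand
            if locus.gap is not None:
                assert locus.gap == (locus.gene_intervals[0][1], locus.gene_intervals[1][0])

    def test_manifest_json_round_trip(self, small_sim, tmp_path):
        _, _, manifest, _ = small_sim
        p = tmp_path / "truth.json"
        manifest.to_json(p)
        back = type(manifest).from_json(p)
        assert back == manifest

    def test_infeasible_packing_raises(self, small_spec):
        tiny = dataclasses.replace(small_spec, genome_len=5_000)
        with pytest.raises(PackingError, match="increase genome_len"):
            simulate_genome(tiny)


class TestPlantedTerminators:
    def test_recovered_at_planted_coordinates(self, small_sim):
        genome, _, manifest, _ = small_sim
        for locus in manifest.loci_of("true_site") + manifest.loci_of("read_through"):
            for strand, s, e in locus.terminators:
                window = genome.sequence[s - 5 : e + 5]
                if strand == "-":
                    window = revcomp(window)
                hits = find_terminators(window, strand, offset=s - 5)
                assert any(h.footprint == (s, e) for h in hits), (locus.locus_id, strand)

    def test_no_terminator_decoys_lack_opposing_pair(self, small_sim):
        from insite import find_opposing_pair

        genome, annotation, manifest, _ = small_sim
        genes = _gene_lookup(annotation)
        for locus in manifest.loci_of("no_terminator"):
            assert find_opposing_pair(genome, _pair_of(locus, genes)) is None


class TestCoverageModel:
    def test_rho_zero_true_gap_at_background(self, small_spec):
        spec = dataclasses.replace(small_spec, rho=0.0)
        _, _, manifest = simulate_genome(spec)
        for cond in manifest.condition_ids:
            mean = expected_coverage(manifest, spec, cond)
            for gs, ge in manifest.true_gaps:
                assert np.all(mean[gs:ge] == spec.background)

    def test_rho_one_gives_no_insulation(self):
        """Full read-through: true-site gaps carry flank-level coverage and
        the insulation index collapses (~0 or below)."""
        spec = SimulationSpec(
            genome_len=40_000,
            n_genes=4,
            n_true_sites=2,
            n_decoys={},
            n_conditions=1,
            rho=1.0,
            gap_len_range=(1000, 1200),  # long gaps shrink sampling error
            seed=5,
        )
        genome, annotation, manifest = simulate_genome(spec)
        tracks = simulate_coverage(manifest, spec)
        genes = _gene_lookup(annotation)
        for locus in manifest.loci_of("true_site"):
            score = insulation_index(_pair_of(locus, genes), tracks)
            assert score.index <= 0.5
            assert not passes_insulation(score)

    def test_empirical_gene_mean_matches_truth(self, small_sim):
        """Law of large numbers: per-base NB noise averages to the drawn
        gene mean over a gene body (within 5%) for well-expressed genes."""
        genome, annotation, manifest, tracks = small_sim
        genes = _gene_lookup(annotation)
        by_cond = {t.condition_id: t for t in tracks}
        checked = 0
        for locus in manifest.loci:
            for cond, means in locus.gene_means.items():
                v = by_cond[cond].values[genome.contig_id]
                for gid, m in zip(locus.gene_ids, means):
                    if m < 50:
                        continue
                    g = genes[gid]
                    emp = float(v[g.start : g.end].mean())
                    assert emp == pytest.approx(m, rel=0.05)
                    checked += 1
        assert checked >= 10

    def test_nb_variance_overdispersed(self, small_sim, small_spec):
        """Per-base counts over a constant-mean region show variance near
        m + k*m^2, far above Poisson."""
        genome, annotation, manifest, tracks = small_sim
        genes = _gene_lookup(annotation)
        locus = manifest.loci_of("true_site")[0]
        cond = manifest.condition_ids[0]
        g = genes[locus.gene_ids[0]]
        m = locus.gene_means[cond][0]
        v = tracks[0].values[genome.contig_id][g.start : g.end]
        expect_var = m + small_spec.nb_dispersion * m**2
        assert v.var() == pytest.approx(expect_var, rel=0.35)
        assert v.var() > 3 * m  # clearly super-Poisson


class TestSeparation:
    def test_true_sites_beat_read_through_decoys(self, small_sim):
        genome, annotation, manifest, tracks = small_sim
        genes = _gene_lookup(annotation)
        true_idx = [
            insulation_index(_pair_of(l, genes), tracks).index
            for l in manifest.loci_of("true_site")
        ]
        rt_idx = [
            insulation_index(_pair_of(l, genes), tracks).index
            for l in manifest.loci_of("read_through")
        ]
        assert min(true_idx) > max(rt_idx)

    def test_no_terminator_decoys_pass_insulation_only(self, small_sim):
        """The silent-gap decoys are indistinguishable by coverage and must
        be rejected by the terminator filter alone."""
        from insite import find_opposing_pair

        genome, annotation, manifest, tracks = small_sim
        genes = _gene_lookup(annotation)
        for l in manifest.loci_of("no_terminator"):
            pair = _pair_of(l, genes)
            assert passes_insulation(insulation_index(pair, tracks))
            assert find_opposing_pair(genome, pair) is None
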