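"""Fusion construction, cassette assembly, knock-in round trips."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from conftest import random_payload, random_protein
from insite import (
    GenomeRecord,
    SP_REGISTRY,
    assemble_cassette,
    build_fusion,
    excise,
    make_knockin,
    recombine,
    spec_from_registry,
    validate_design,
    write_genbank,
)
from insite.cassette import (
    DEFAULT_SIGMA70_PROMOTER,
    SignalPeptideSpec,
    back_translate,
    synthetic_rrnb_like_terminator,
    translate,
)
from insite.formats_io import read_genbank_features


class TestSignalPeptides:
    def test_registry_segment_lengths(self):
        """Registry recipes reproduce the published segment lengths."""
        rng = np.random.default_rng(1)
        donor = random_protein(rng, 300)
        for name, want in [("ftsP", 30), ("ompA", 27), ("tamA", 27), ("yebF", 118)]:
            assert len(spec_from_registry(name, donor).segment) == want
        assert len(spec_from_registry("inpNC", random_protein(rng, 400)).segment) == 211 + 99
        lpp, ompa = random_protein(rng, 78), random_protein(rng, 325)
        assert len(spec_from_registry("lpp-ompA", lpp, ompa).segment) == 29 + (159 - 46 + 1)

    def test_unknown_name(self):
        with pytest.raises(KeyError):
            spec_from_registry("nope", "M" * 50)

    def test_segment_longer_than_donor(self):
        with pytest.raises(ValueError, match="exceed donor"):
            SignalPeptideSpec("x", 40, "M" * 20)


class TestFusion:
    def test_ftsp_fusion_segment_is_30_aa(self):
        rng = np.random.default_rng(4)
        donor = random_protein(rng, 300)
        sp = spec_from_registry("ftsP", donor)
        payload = random_payload(rng, 98)  # ATG + 98 codons + stop
        fusion = build_fusion(sp, payload)
        aa = translate(fusion)
        assert aa[1:31] == donor[:30]
        assert len(aa) == 1 + 30 + 98 + 1  # M + SP + payload body + '*'

    def test_none_signal_peptide_is_identity(self):
        rng = np.random.default_rng(5)
        payload = random_payload(rng, 40)
        assert build_fusion(None, payload) == payload

    def test_translation_oracle_random_payloads(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            donor = random_protein(rng, int(rng.integers(40, 200)))
            sp = SignalPeptideSpec("t", int(rng.integers(1, len(donor))), donor)
            payload = random_payload(rng, int(rng.integers(10, 120)))
            fusion = build_fusion(sp, payload)
            want = "M" + sp.segment + translate(payload)[1:]
            assert translate(fusion) == want

    def test_native_start_kept_when_configured(self):
        rng = np.random.default_rng(7)
        donor = random_protein(rng, 50)
        sp = SignalPeptideSpec("t", 10, donor)
        payload = random_payload(rng, 20)
        fusion = build_fusion(sp, payload, drop_payload_start=False)
        assert translate(fusion) == "M" + sp.segment + translate(payload)

    def test_internal_stop_payload_rejected(self):
        bad = "ATG" + "TAA" + "GGC" + "TAA"
        with pytest.raises(ValueError, match="internal stop"):
            build_fusion(None, bad)

    def test_unframed_payload_rejected(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            build_fusion(None, "ATGG")


class TestCassette:
    def _cassette(self, rng=None, n_codons=50):
        rng = rng or np.random.default_rng(8)
        donor = random_protein(rng, 60)
        sp = spec_from_registry("ftsP", random_protein(rng, 100))
        fusion = build_fusion(sp, random_payload(rng, n_codons))
        return assemble_cassette(
            DEFAULT_SIGMA70_PROMOTER,
            fusion,
            synthetic_rrnb_like_terminator(),
            sp_segment_nt=back_translate(sp.segment),
        )

    def test_element_order_and_length(self):
        cas = self._cassette()
        assert cas.promoter_offset < cas.fusion_offset < cas.terminator_offset
        assert len(cas) == (
            len(cas.promoter) + len(cas.spacer) + len(cas.fusion_cds) + len(cas.terminator)
        )
        assert cas.sequence.startswith(cas.promoter)
        assert cas.sequence.endswith(cas.terminator)

    def test_spacer_configurable(self):
        rng = np.random.default_rng(9)
        fusion = build_fusion(None, random_payload(rng, 30))
        cas = assemble_cassette("TTGACA", fusion, "TTTTTTTT", spacer_len=10)
        assert len(cas.spacer) == 10

    def test_genbank_round_trip(self, tmp_path):
        cas = self._cassette()
        genome = _genome_with_site(2000)
        construct = make_knockin(_FakeSite(1000), cas, genome, arm_len=300)
        p = tmp_path / "c.gb"
        write_genbank(construct, p)
        feats = read_genbank_features(p)
        assert len(feats) == 6
        by_type = {t: (s, e) for t, s, e, _ in feats}
        off = 300  # left arm length
        assert by_type["promoter"] == (off, off + len(cas.promoter))
        assert by_type["CDS"] == (
            off + cas.fusion_offset,
            off + cas.fusion_offset + len(cas.fusion_cds),
        )
        assert by_type["terminator"] == (
            off + cas.terminator_offset,
            off + cas.terminator_offset + len(cas.terminator),
        )
        cds_len = by_type["CDS"][1] - by_type["CDS"][0]
        assert cds_len % 3 == 0


class _FakeSite:
    def __init__(self, insertion_point, t1=None, t2=None):
        self.insertion_point = insertion_point
        self.t1 = t1
        self.t2 = t2


def _genome_with_site(n=3000, seed=12):
    rng = np.random.default_rng(seed)
    return GenomeRecord("c", "".join("ACGT"[i] for i in rng.integers(0, 4, n)))


class TestKnockin:
    def _construct(self, arm_len=500):
        rng = np.random.default_rng(13)
        fusion = build_fusion(None, random_payload(rng, 40))
        cas = assemble_cassette(
            DEFAULT_SIGMA70_PROMOTER, fusion, synthetic_rrnb_like_terminator()
        )
        genome = _genome_with_site(4000)
        return genome, cas, make_knockin(_FakeSite(2000), cas, genome, arm_len=arm_len)

    def test_arm_lengths_and_recombined_length(self):
        genome, cas, construct = self._construct(arm_len=500)
        assert len(construct.left_arm) == len(construct.right_arm) == 500
        rec = recombine(genome, construct)
        assert len(rec) == len(genome) + len(cas)

    def test_flanking_sequence_preserved(self):
        genome, cas, construct = self._construct()
        rec = recombine(genome, construct)
        ip = construct.insertion_point
        assert rec.sequence[:ip] == genome.sequence[:ip]
        assert rec.sequence[ip + len(cas) :] == genome.sequence[ip:]

    def test_knockin_reversible(self):
        genome, _, construct = self._construct()
        assert excise(recombine(genome, construct), construct).sequence == genome.sequence

    def test_missing_insertion_point_rejected(self):
        genome, cas, _ = self._construct()
        with pytest.raises(ValueError, match="another candidate site"):
            make_knockin(_FakeSite(None), cas, genome)

    def test_arms_outside_contig_rejected(self):
        genome, cas, _ = self._construct()
        with pytest.raises(ValueError, match="beyond the contig"):
            make_knockin(_FakeSite(100), cas, genome, arm_len=500)


class TestValidation:
    def test_good_construct_passes_all(self):
        _, _, construct = TestKnockin()._construct()
        report = validate_design(construct)
        assert report.valid
        assert len(report.checks) == 5

    def test_forced_internal_stop_fails_stop_check_only(self):
        genome, cas, construct = TestKnockin()._construct()
        bad_fusion = cas.fusion_cds[:3] + "TAA" + cas.fusion_cds[6:]
        bad_cas = object.__new__(type(cas))
        for f in dataclasses.fields(cas):
            object.__setattr__(bad_cas, f.name, getattr(cas, f.name))
        object.__setattr__(bad_cas, "fusion_cds", bad_fusion)
        bad = dataclasses.replace(construct, cassette=bad_cas)
        report = validate_design(bad)
        failed = {name for name, ok, _ in report.checks if not ok}
        assert failed == {"stops"}

    def test_shifted_arms_fail_consistency(self):
        genome, _, construct = TestKnockin()._construct()
        ip = construct.insertion_point
        shifted = dataclasses.replace(
            construct,
            left_arm=genome.sequence[ip - 501 : ip - 1],
            right_arm=genome.sequence[ip - 1 : ip + 499],
        )
        report = validate_design(shifted)
        failed = {name for name, ok, _ in report.checks if not ok}
        assert failed == {"arm_consistency"}

    def test_unvalidated_construct_refused_by_writer(self, tmp_path):
        genome, cas, construct = TestKnockin()._construct()
        shifted = dataclasses.replace(construct, left_arm=construct.left_arm[:-1] + "N")
        with pytest.raises(ValueError, match="refusing"):
            write_genbank(shifted, tmp_path / "x.gb")
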