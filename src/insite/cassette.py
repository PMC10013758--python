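"""Knock-in cassette design: sigma70 promoter + signal-peptide fusion + terminator.

The cassette a chassis strain carries at an insulated site has a fixed
element order — promoter, fusion CDS (signal peptide fused in frame to the
payload), intrinsic terminator — and is flanked by homology arms taken from
the genome around the insertion point for recombination-mediated knock-in.

The signal-peptide registry stores segment recipes (lengths and donor
accessions); donor protein sequences are supplied by the caller, so nothing
needs to be downloaded. Translation uses the bacterial genetic code
(NCBI table 11).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio.Seq import Seq

from .formats_io import GenomeRecord

# --- translation -----------------------------------------------------------

#: One representative codon per amino acid (frequent E. coli codons); used
#: only to back-translate signal-peptide segments. None is a stop codon.
CODON_FOR_AA = {
    "A": "GCG", "R": "CGT", "N": "AAC", "D": "GAT", "C": "TGC",
    "Q": "CAG", "E": "GAA", "G": "GGC", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCG",
    "S": "AGC", "T": "ACC", "W": "TGG", "Y": "TAT", "V": "GTG",
}


def translate(cds: str) -> str:
    """Translate DNA with the bacterial code (table 11), stops as ``*``."""
    return str(Seq(cds).translate(table=11))


def back_translate(protein: str) -> str:
    try:
        return "".join(CODON_FOR_AA[aa] for aa in protein)
    except KeyError as exc:
        raise ValueError(f"cannot back-translate residue {exc.args[0]!r}") from exc


def validate_cds(cds: str, what: str = "CDS") -> None:
    """A valid CDS starts with ATG, is a whole number of codons, and has
    exactly one stop codon, at its 3' end."""
    if len(cds) % 3 != 0:
        raise ValueError(f"{what}: length {len(cds)} not divisible by 3")
    if not cds.startswith("ATG"):
        raise ValueError(f"{what}: does not begin with ATG")
    aa = translate(cds)
    if not aa.endswith("*"):
        raise ValueError(f"{what}: missing terminal stop codon")
    if "*" in aa[:-1]:
        raise ValueError(f"{what}: internal stop codon at aa {aa.index('*') + 1}")


# --- signal peptides -------------------------------------------------------


@dataclass(frozen=True)
class SignalPeptideSpec:
    """A signal-peptide (or anchor) segment cut from a donor protein.

    ``n_term_len`` residues are taken from the donor's N-terminus and,
    for ice-nucleation-protein-style anchors, ``c_term_len`` residues from
    its C-terminus. ``donor_protein`` is the resolved donor amino-acid
    sequence (for composite recipes, the already-concatenated segment).
    """

    name: str
    n_term_len: int
    donor_protein: str
    c_term_len: int = 0

    def __post_init__(self) -> None:
        if self.n_term_len < 1:
            raise ValueError("n_term_len must be >= 1")
        if self.n_term_len + self.c_term_len > len(self.donor_protein):
            raise ValueError(
                f"signal peptide {self.name!r}: segment lengths exceed donor "
                f"length {len(self.donor_protein)}"
            )
        if "*" in self.segment:
            raise ValueError(f"signal peptide {self.name!r}: segment contains a stop")

    @property
    def segment(self) -> str:
        """The amino-acid segment fused after the start methionine."""
        seg = self.donor_protein[: self.n_term_len]
        if self.c_term_len:
            seg += self.donor_protein[-self.c_term_len :]
        return seg


@dataclass(frozen=True)
class RegistryEntry:
    n_term_len: int
    c_term_len: int
    accessions: tuple[str, ...]
    note: str = ""


#: Built-in segment recipes. Lengths are in amino acids of the donor protein.
SP_REGISTRY: dict[str, RegistryEntry] = {
    "ftsP": RegistryEntry(30, 0, ("NP_417489.1",), "TAT signal peptide (SufI)"),
    "ompA": RegistryEntry(27, 0, ("NP_415477.1",), "Sec signal peptide"),
    "tamA": RegistryEntry(27, 0, ("NP_418641.1",), "Sec signal peptide"),
    "lpp-ompA": RegistryEntry(
        29, 0, ("NP_310411.1", "NP_415477.1"),
        "29 aa of Lpp followed by OmpA residues 46-159 (surface display)",
    ),
    "yebF": RegistryEntry(118, 0, ("NP_416361.2",), "secreted carrier protein"),
    "inpNC": RegistryEntry(
        211, 99, ("AF013159",), "ice nucleation protein N- and C-terminal domains"
    ),
}

#: Residues OmpA contributes to the lpp-ompA display anchor (1-based 46..159).
_LPP_OMPA_RANGE = (46, 159)


def spec_from_registry(
    name: str, donor_protein: str, second_donor: Optional[str] = None
) -> SignalPeptideSpec:
    """Resolve a registry recipe against caller-supplied donor sequence(s).

    ``lpp-ompA`` needs two donors (Lpp then OmpA); every other entry needs
    one. Donor proteins are given without their stop.
    """
    if name not in SP_REGISTRY:
        raise KeyError(f"unknown signal peptide {name!r}; known: {sorted(SP_REGISTRY)}")
    entry = SP_REGISTRY[name]
    if name == "lpp-ompA":
        if second_donor is None:
            raise ValueError("lpp-ompA needs donor_protein=Lpp and second_donor=OmpA")
        lo, hi = _LPP_OMPA_RANGE
        if len(second_donor) < hi:
            raise ValueError(f"OmpA donor shorter than residue {hi}")
        segment = donor_protein[: entry.n_term_len] + second_donor[lo - 1 : hi]
        return SignalPeptideSpec(name=name, n_term_len=len(segment), donor_protein=segment)
    return SignalPeptideSpec(
        name=name,
        n_term_len=entry.n_term_len,
        c_term_len=entry.c_term_len,
        donor_protein=donor_protein,
    )


# --- fusion + cassette -----------------------------------------------------


def build_fusion(
    sp: Optional[SignalPeptideSpec], payload_cds: str, drop_payload_start: bool = True
) -> str:
    """Fuse a signal-peptide segment in frame ahead of a payload CDS.

    The output is ATG + back-translated segment codons + the payload's own
    codons (native ATG dropped by default) + the payload's stop, so
    translate(output) == "M" + segment + payload protein (sans leading M).
    A None/zero-length segment returns the payload unchanged.
    """
    payload_cds = payload_cds.upper()
    validate_cds(payload_cds, "payload")
    if sp is None:
        return payload_cds
    sp_nt = back_translate(sp.segment)
    body = payload_cds[3:] if drop_payload_start else payload_cds
    fusion = "ATG" + sp_nt + body
    validate_cds(fusion, "fusion")
    return fusion


#: Default synthesized sigma70-dependent promoter: -35 TTGACA, 17-nt spacer,
#: -10 TATAAT, then a ribosome binding site (AGGAGG) 6 nt downstream with a
#: 7-nt spacer to the start codon. User-overridable everywhere it is used.
DEFAULT_SIGMA70_PROMOTER = (
    "TTGACA" + "TGCTATCCTACGCAATG" + "TATAAT" + "CGATCC" + "AGGAGG" + "ACATACC"
)


def synthetic_rrnb_like_terminator() -> str:
    """A synthetic stand-in for an rrnB-class intrinsic terminator.

    Built from the same grammar the predictor searches (10-bp G:C stem,
    4-nt loop, 8-nt T-tract); it is NOT the natural rrnB T1 sequence, which
    callers should supply themselves when exact wet-lab fidelity matters.
    """
    arm = "GGCCGGCCGG"
    loop = "TTCG"
    arm2 = str(Seq(arm).reverse_complement())
    return "CGCA" + arm + loop + arm2 + "TTTTTTTT"


@dataclass(frozen=True)
class CassetteDesign:
    """promoter -> (spacer) -> fusion CDS -> terminator, in that fixed order."""

    promoter: str
    fusion_cds: str
    terminator: str
    spacer: str = "AACAAT"
    sp_segment_nt: str = ""  # codons of the signal-peptide segment (after ATG)

    def __post_init__(self) -> None:
        validate_cds(self.fusion_cds, "fusion_cds")
        if self.sp_segment_nt and not self.fusion_cds[3:].startswith(self.sp_segment_nt):
            raise ValueError("sp_segment_nt is not the leading segment of the fusion")

    @property
    def promoter_offset(self) -> int:
        return 0

    @property
    def fusion_offset(self) -> int:
        return len(self.promoter) + len(self.spacer)

    @property
    def terminator_offset(self) -> int:
        return self.fusion_offset + len(self.fusion_cds)

    @property
    def sequence(self) -> str:
        return self.promoter + self.spacer + self.fusion_cds + self.terminator

    def __len__(self) -> int:
        return len(self.sequence)


def assemble_cassette(
    promoter: str,
    fusion: str,
    terminator: str,
    spacer_len: int = 6,
    sp_segment_nt: str = "",
) -> CassetteDesign:
    """Concatenate the three elements with a short neutral spacer between
    promoter and CDS. Element invariants are re-checked on construction."""
    if spacer_len < 0:
        raise ValueError("spacer_len must be >= 0")
    spacer = ("AACAAT" * (spacer_len // 6 + 1))[:spacer_len]
    for name, seq in (("promoter", promoter), ("terminator", terminator)):
        if not seq or set(seq) - set("ACGTN"):
            raise ValueError(f"{name}: empty or non-DNA sequence")
    return CassetteDesign(
        promoter=promoter.upper(),
        fusion_cds=fusion.upper(),
        terminator=terminator.upper(),
        spacer=spacer,
        sp_segment_nt=sp_segment_nt.upper(),
    )


# --- knock-in construct ----------------------------------------------------


@dataclass(frozen=True)
class KnockinConstruct:
    """Cassette plus homology arms around an insertion point.

    ``left_arm`` ends at, and ``right_arm`` starts at, ``insertion_point``
    on the source contig. Terminator footprints of the host site, when
    known, are kept for the untouched-footprint validation check.
    """

    contig_id: str
    insertion_point: int
    left_arm: str
    right_arm: str
    cassette: CassetteDesign
    genome: Optional[GenomeRecord] = field(default=None, repr=False)
    t1_footprint_end: Optional[int] = None
    t2_footprint_start: Optional[int] = None


def make_knockin(
    site, cassette: CassetteDesign, genome: GenomeRecord, arm_len: int = 500
) -> KnockinConstruct:
    """Cut homology arms around a candidate site's insertion point.

    ``site`` is a CandidateSite (or anything exposing ``insertion_point``,
    ``t1``/``t2`` footprints optional). Sites whose opposing terminators
    overlap carry no insertion point and are rejected with a pointer to
    choose another site.
    """
    if arm_len < 1:
        raise ValueError("arm_len must be >= 1")
    ip = getattr(site, "insertion_point", None)
    if ip is None:
        raise ValueError(
            "site has no insertion point (opposing terminator footprints "
            "overlap); choose another candidate site"
        )
    if ip - arm_len < 0 or ip + arm_len > len(genome):
        raise ValueError("homology arms extend beyond the contig")
    t1 = getattr(site, "t1", None)
    t2 = getattr(site, "t2", None)
    return KnockinConstruct(
        contig_id=genome.contig_id,
        insertion_point=ip,
        left_arm=genome.sequence[ip - arm_len : ip],
        right_arm=genome.sequence[ip : ip + arm_len],
        cassette=cassette,
        genome=genome,
        t1_footprint_end=t1.footprint[1] if t1 is not None else None,
        t2_footprint_start=t2.footprint[0] if t2 is not None else None,
    )


def recombine(genome: GenomeRecord, construct: KnockinConstruct) -> GenomeRecord:
    """The in-silico recombined genome: cassette inserted at the insertion point."""
    ip = construct.insertion_point
    seq = genome.sequence[:ip] + construct.cassette.sequence + genome.sequence[ip:]
    return GenomeRecord(genome.contig_id, seq)


def excise(recombined: GenomeRecord, construct: KnockinConstruct) -> GenomeRecord:
    """Delete the cassette interval again — the exact inverse of recombine."""
    ip = construct.insertion_point
    n = len(construct.cassette)
    return GenomeRecord(
        recombined.contig_id, recombined.sequence[:ip] + recombined.sequence[ip + n :]
    )


# --- validation ------------------------------------------------------------


@dataclass
class ValidationReport:
    checks: list[tuple[str, bool, str]]

    @property
    def valid(self) -> bool:
        return all(ok for _, ok, _ in self.checks)


def validate_design(construct: KnockinConstruct) -> ValidationReport:
    """Pass/fail report: reading frame, internal stops, element order,
    arm/insertion consistency, terminator footprints untouched."""
    checks: list[tuple[str, bool, str]] = []
    cas = construct.cassette

    ok = len(cas.fusion_cds) % 3 == 0 and cas.fusion_cds.startswith("ATG")
    checks.append(("frame", ok, "fusion is whole codons and starts with ATG"))

    aa = translate(cas.fusion_cds) if len(cas.fusion_cds) % 3 == 0 else ""
    ok = bool(aa) and aa.endswith("*") and "*" not in aa[:-1]
    checks.append(("stops", ok, "exactly one stop codon, at the 3' end"))

    ok = cas.promoter_offset < cas.fusion_offset < cas.terminator_offset
    checks.append(("element_order", ok, "promoter -> fusion -> terminator"))

    if construct.genome is not None:
        ip = construct.insertion_point
        g = construct.genome.sequence
        ok = (
            g[ip - len(construct.left_arm) : ip] == construct.left_arm
            and g[ip : ip + len(construct.right_arm)] == construct.right_arm
        )
        checks.append(("arm_consistency", ok, "arms flank the insertion point"))
    else:
        checks.append(("arm_consistency", True, "no genome attached; skipped"))

    t1e, t2s = construct.t1_footprint_end, construct.t2_footprint_start
    if t1e is not None and t2s is not None:
        ok = t1e <= construct.insertion_point <= t2s
        checks.append(("terminator_footprints", ok, "insertion between footprints"))
    else:
        checks.append(("terminator_footprints", True, "no footprints recorded; skipped"))
    return ValidationReport(checks=checks)
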