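"""Readers/writers for the formats the screen touches, with one coordinate rule.

Internally every interval is 0-based half-open. GFF3 and GenBank use 1-based
closed coordinates on disk; the conversion happens here and nowhere else.
BedGraph is already 0-based half-open. FASTA and GenBank I/O go through
Biopython; GFF3 rows are parsed with gffutils' line parser so malformed rows
raise with their line number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

_DNA_ALPHABET = set("ACGTN")


class FormatError(ValueError):
    """Malformed input file (the message names the offending line)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeRecord:
    """A contig: uppercase DNA over {A,C,G,T,N}."""

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"contig {self.contig_id!r}: empty sequence")
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            raise ValueError(
                f"contig {self.contig_id!r}: non-DNA characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneFeature:
    """A gene interval, 0-based half-open, stranded."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -")
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id!r}: require 0 <= start < end")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAnnotation:
    """Genes sorted by (contig_id, start) plus contig lengths."""

    genes: list[GeneFeature]
    contig_lengths: dict[str, int]

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.contig_id, g.start, g.end))
        for g in self.genes:
            if g.contig_id not in self.contig_lengths:
                raise ValueError(f"gene {g.gene_id!r}: unknown contig {g.contig_id!r}")
            if g.end > self.contig_lengths[g.contig_id]:
                raise ValueError(
                    f"gene {g.gene_id!r} extends past contig "
                    f"{g.contig_id!r} (len {self.contig_lengths[g.contig_id]})"
                )

    def genes_on(self, contig_id: str) -> list[GeneFeature]:
        return [g for g in self.genes if g.contig_id == contig_id]


@dataclass
class CoverageTrack:
    """Strandless per-base coverage for one condition."""

    condition_id: str
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for contig, v in self.values.items():
            v = np.asarray(v, dtype=float)
            if (v < 0).any():
                raise ValueError(f"track {self.condition_id!r}: negative coverage on {contig!r}")
            self.values[contig] = v


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a FASTA file into GenomeRecords (sequences uppercased).

    The contig_id is the header token before the first whitespace. Empty
    files and duplicate ids are errors.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate contig id {rec.id!r}")
        seen.add(rec.id)
        records.append(GenomeRecord(rec.id, str(rec.seq).upper()))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> None:
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.contig_id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def read_gff3(
    path: str | Path,
    contig_lengths: Mapping[str, int],
    feature_types: tuple[str, ...] = ("gene",),
) -> GenomeAnnotation:
    """Read gene rows from a GFF3 file into a sorted GenomeAnnotation.

    GFF3's 1-based closed coordinates are converted to 0-based half-open.
    Only rows whose type is in ``feature_types`` are used ("gene" by default,
    CDS behind the config flag). Malformed rows raise FormatError naming the
    line; genes outside their contig raise ValueError.
    """
    genes: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises bare exceptions on bad rows
                raise FormatError(f"{path}:{lineno}: malformed GFF3 row ({exc})") from exc
            if feat.featuretype not in feature_types:
                continue
            if feat.strand not in ("+", "-"):
                raise FormatError(
                    f"{path}:{lineno}: gene rows need explicit strand, got {feat.strand!r}"
                )
            gene_id = (feat.attributes.get("ID") or [f"line{lineno}"])[0]
            name = (feat.attributes.get("Name") or [""])[0]
            genes.append(
                GeneFeature(
                    gene_id=gene_id,
                    contig_id=feat.seqid,
                    start=feat.start - 1,  # 1-closed -> 0-half-open
                    end=feat.end,
                    strand=feat.strand,
                    name=name,
                )
            )
    return GenomeAnnotation(genes=genes, contig_lengths=dict(contig_lengths))


def write_gff3(
    annotation: GenomeAnnotation, path: str | Path, feature_type: str = "gene"
) -> None:
    """Write an annotation back to GFF3 (1-based closed on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig, length in sorted(annotation.contig_lengths.items()):
            fh.write(f"##sequence-region {contig} 1 {length}\n")
        for g in annotation.genes:
            attrs = f"ID={g.gene_id}"
            if g.name:
                attrs += f";Name={g.name}"
            fh.write(
                f"{g.contig_id}\tinsite\t{feature_type}\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# BedGraph
# ---------------------------------------------------------------------------


def read_bedgraph(
    path: str | Path, contig_lengths: Mapping[str, int], condition_id: str
) -> CoverageTrack:
    """Expand a BedGraph (0-based half-open, non-overlapping) to per-base vectors.

    Uncovered bases are 0. Intervals beyond the contig end or with negative
    values are errors.
    """
    values = {c: np.zeros(n, dtype=float) for c, n in contig_lengths.items()}
    covered = {c: np.zeros(n, dtype=bool) for c, n in contig_lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            contig, s, e, v = parts[0], parts[1], parts[2], parts[3]
            try:
                s, e, v = int(s), int(e), float(v)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field") from exc
            if contig not in values:
                raise FormatError(f"{path}:{lineno}: unknown contig {contig!r}")
            if not (0 <= s < e <= contig_lengths[contig]):
                raise FormatError(
                    f"{path}:{lineno}: interval [{s},{e}) outside contig "
                    f"{contig!r} (len {contig_lengths[contig]})"
                )
            if v < 0:
                raise FormatError(f"{path}:{lineno}: negative coverage value {v}")
            if covered[contig][s:e].any():
                raise FormatError(f"{path}:{lineno}: overlapping interval [{s},{e})")
            covered[contig][s:e] = True
            values[contig][s:e] = v
    return CoverageTrack(condition_id=condition_id, values=values)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Run-length compress per-base vectors back to BedGraph (zero runs omitted)."""
    with open(path, "w") as fh:
        for contig in sorted(track.values):
            v = track.values[contig]
            if len(v) == 0:
                continue
            # boundaries where the value changes
            change = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(v)]])
            for s, e in zip(starts, ends):
                val = v[s]
                if val != 0:
                    fh.write(f"{contig}\t{s}\t{e}\t{val:g}\n")


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------


def write_bed6(rows: Iterable[tuple[str, int, int, str, int, str]], path: str | Path) -> None:
    """Write (contig, start, end, name, score 0-1000, strand) rows as BED6."""
    with open(path, "w") as fh:
        for contig, start, end, name, score, strand in rows:
            fh.write(f"{contig}\t{start}\t{end}\t{name}\t{int(score)}\t{strand}\n")


# ---------------------------------------------------------------------------
# GenBank (knock-in construct)
# ---------------------------------------------------------------------------


def write_genbank(construct, path: str | Path) -> None:
    """Write a validated KnockinConstruct as a GenBank flat file.

    One feature per element: left/right homology arms (misc_feature),
    promoter, sig_peptide, CDS (the full fusion), terminator — 6 features,
    1-based closed on disk via Biopython's GenBank writer.
    """
    from .cassette import validate_design  # local import to avoid a cycle

    report = validate_design(construct)
    if not report.valid:
        failed = [name for name, ok, _ in report.checks if not ok]
        raise ValueError(f"refusing to write unvalidated construct; failed: {failed}")

    cas = construct.cassette
    seq = construct.left_arm + cas.sequence + construct.right_arm
    rec = SeqRecord(Seq(seq), id="knockin", name="knockin", description="knock-in construct")
    rec.annotations["molecule_type"] = "DNA"

    def feat(start: int, end: int, ftype: str, label: str, strand: int = 1) -> SeqFeature:
        return SeqFeature(
            FeatureLocation(start, end, strand=strand),
            type=ftype,
            qualifiers={"label": [label]},
        )

    off = len(construct.left_arm)
    rec.features.append(feat(0, off, "misc_feature", "left_homology_arm"))
    p0 = off + cas.promoter_offset
    rec.features.append(feat(p0, p0 + len(cas.promoter), "promoter", "promoter"))
    f0 = off + cas.fusion_offset
    rec.features.append(feat(f0, f0 + len(cas.fusion_cds), "CDS", "fusion_cds"))
    rec.features.append(feat(f0, f0 + len(cas.sp_segment_nt) + 3, "sig_peptide", "signal_peptide"))
    t0 = off + cas.terminator_offset
    rec.features.append(feat(t0, t0 + len(cas.terminator), "terminator", "terminator"))
    rec.features.append(
        feat(off + len(cas.sequence), len(seq), "misc_feature", "right_homology_arm")
    )
    SeqIO.write([rec], str(path), "genbank")


def read_genbank_features(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Re-read (type, start, end, label) with internal 0-based half-open coords."""
    rec = SeqIO.read(str(path), "genbank")
    out = []
    for f in rec.features:
        label = (f.qualifiers.get("label") or [""])[0]
        out.append((f.type, int(f.location.start), int(f.location.end), label))
    return out
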