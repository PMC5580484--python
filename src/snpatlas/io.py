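"""Reading and writing the standard formats the pipeline touches.

Conventions
-----------
Internal coordinates are 0-based half-open throughout the package; every
emitted file (GenBank-derived features, GFF3, VCF) uses 1-based inclusive
coordinates.  Conversion happens only through :func:`to_one_based` /
:func:`from_one_based` so the off-by-one surface is a single, tested spot.

Sequences are stored upper-case over the IUPAC nucleotide alphabet
(A, C, G, T plus the ambiguity codes R, Y, S, W, M, K, B, D, H, V, N).
Gap characters are never part of a :class:`Genome`; gapped rows live in
:class:`snpatlas.align.MultiAlignment` only.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field

import dendropy
import pandas as pd
from Bio import SeqIO

IUPAC_CODES = "ACGTRYSWMKBDHVN"
IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"G", "C"}, "W": {"A", "T"},
    "M": {"A", "C"}, "K": {"G", "T"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}
COMPLEMENT = str.maketrans("ACGTRYSWMKBDHVN", "TGCAYRSWKMVHDBN")

FEATURE_KINDS = (
    "ORF",
    "dispersed_repeat",
    "repeat_region",
    "major_repeat_region",
    "transposable_element",
)


class FormatError(ValueError):
    """Malformed or out-of-contract input file."""


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive (GenBank/GFF3/VCF convention)."""
    return start + 1, end


def from_one_based(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start1 - 1, end1


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class Genome:
    """An isolate's nucleotide sequence.

    The sequence is validated on construction: non-empty, IUPAC nucleotide
    codes only (case-insensitive input is upper-cased), no gaps, no U.
    """

    id: str
    sequence: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("genome id must be non-empty")
        seq = self.sequence.upper()
        if not seq:
            raise FormatError(f"genome {self.id!r}: empty sequence")
        allowed = set(IUPAC_CODES)
        for offset, char in enumerate(seq):
            if char not in allowed:
                raise FormatError(
                    f"genome {self.id!r}: illegal character {char!r} at offset {offset}"
                )
        self.sequence = seq

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc_percent(self) -> float:
        """GC% over unambiguous bases only, rounded to 2 decimals."""
        seq = self.sequence
        gc = seq.count("G") + seq.count("C")
        acgt = gc + seq.count("A") + seq.count("T")
        if acgt == 0:
            raise ValueError(f"genome {self.id!r}: no unambiguous bases")
        return round(100.0 * gc / acgt, 2)


@dataclass
class FeatureRecord:
    """An annotated interval on a genome (internal 0-based half-open)."""

    name: str
    start: int
    end: int
    strand: str  # "+" or "-"
    kind: str
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"feature {self.name!r}: bad interval [{self.start}, {self.end})"
            )
        if self.strand not in "+-":
            raise FormatError(f"feature {self.name!r}: bad strand {self.strand!r}")
        if self.kind not in FEATURE_KINDS:
            raise FormatError(f"feature {self.name!r}: unknown kind {self.kind!r}")

    def __len__(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[Genome]:
    """Read a (multi-)FASTA file into validated genomes.

    Ids are the header token before the first whitespace; duplicates are an
    error, as are gap characters or anything outside the IUPAC alphabet.
    """
    genomes: list[Genome] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise FormatError(f"duplicate FASTA id {record.id!r}")
        seen.add(record.id)
        genomes.append(Genome(record.id, str(record.seq), source=str(path)))
    if not genomes:
        raise FormatError(f"no FASTA records in {path}")
    return genomes


def write_fasta(path, genomes: list[Genome], width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, len(g.sequence), width):
                fh.write(g.sequence[i : i + width] + "\n")


def write_aligned_fasta(path, rows: dict[str, str], width: int = 70) -> None:
    """Write gapped rows (e.g. an MSA) as aligned FASTA."""
    with open(path, "w") as fh:
        for name, row in rows.items():
            fh.write(f">{name}\n")
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")


def read_aligned_fasta(path) -> dict[str, str]:
    rows: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in rows:
            raise FormatError(f"duplicate aligned-FASTA id {record.id!r}")
        rows[record.id] = str(record.seq).upper()
    if not rows:
        raise FormatError(f"no records in {path}")
    lengths = {len(r) for r in rows.values()}
    if len(lengths) != 1:
        raise FormatError(f"aligned-FASTA rows differ in length: {sorted(lengths)}")
    return rows


# ---------------------------------------------------------------------------
# GenBank


def _check_monotone_parts(feature, name: str) -> None:
    parts = list(feature.location.parts)
    last_end = None
    for part in parts:
        if last_end is not None and int(part.start) < last_end:
            raise FormatError(
                f"feature {name!r}: wrap-around features unsupported"
            )
        last_end = int(part.end)


def read_genbank(path) -> tuple[Genome, list[FeatureRecord]]:
    """Read a GenBank flat file: sequence plus CDS/gene features as ORFs.

    Only linear coordinates are supported; a join(...) spanning the origin
    raises, matching the package-wide linear treatment of the genome.
    """
    try:
        record = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise FormatError(f"cannot parse GenBank file {path}: {exc}") from exc
    try:
        seq = str(record.seq)
    except Exception as exc:  # undefined sequence => no ORIGIN block
        raise FormatError(f"{path}: missing ORIGIN block") from exc
    if not seq:
        raise FormatError(f"{path}: missing or empty ORIGIN block")
    genome = Genome(record.id, seq, source=str(path))
    features: list[FeatureRecord] = []
    counter = 0
    for feat in record.features:
        if feat.type not in ("CDS", "gene"):
            continue
        quals = feat.qualifiers
        name = (
            quals.get("gene", quals.get("locus_tag", quals.get("label", [None])))[0]
        )
        if name is None:
            counter += 1
            name = f"orf{counter:03d}"
        _check_monotone_parts(feat, name)
        start, end = int(feat.location.start), int(feat.location.end)
        if end > len(seq):
            raise FormatError(f"feature {name!r}: coordinate {end} outside sequence")
        strand = "-" if feat.location.strand == -1 else "+"
        features.append(FeatureRecord(name, start, end, strand, "ORF"))
    # the same locus often appears as both gene and CDS; keep one per interval
    uniq: dict[tuple, FeatureRecord] = {}
    for f in features:
        uniq.setdefault((f.start, f.end, f.strand), f)
    return genome, sorted(uniq.values(), key=lambda f: f.start)


# ---------------------------------------------------------------------------
# GFF3


def write_gff3(path, seqid: str, features: list[FeatureRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, f in enumerate(features):
            start1, end1 = to_one_based(f.start, f.end)
            attrs = [f"ID=feat{i};Name={f.name}"]
            for key, value in sorted(f.attributes.items()):
                attrs.append(f"{key}={value}")
            fh.write(
                "\t".join(
                    [
                        seqid,
                        "snpatlas",
                        f.kind,
                        str(start1),
                        str(end1),
                        ".",
                        f.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_gff3(path) -> tuple[str, list[FeatureRecord]]:
    seqid = None
    features: list[FeatureRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"bad GFF3 line: {line!r}")
            seqid = cols[0]
            start, end = from_one_based(int(cols[3]), int(cols[4]))
            attrs = {}
            name = ""
            for pair in cols[8].split(";"):
                if not pair:
                    continue
                key, _, value = pair.partition("=")
                if key == "Name":
                    name = value
                elif key != "ID":
                    attrs[key] = value
            features.append(
                FeatureRecord(name, start, end, cols[6], cols[2], attrs)
            )
    if seqid is None:
        raise FormatError(f"no features in {path}")
    return seqid, features


# ---------------------------------------------------------------------------
# VCF (minimal, sites-only + GT columns)


def write_vcf(path, reference_id: str, contig_length: int, isolates: list[str],
              snps) -> None:
    """Write SNP records as a minimal VCF 4.2.

    ``snps`` is an iterable of :class:`snpatlas.snps.SnpRecord`.  Ambiguity
    codes cannot be VCF alleles; isolates carrying one get a missing
    genotype.  An empty SNP list yields a valid header-only file.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={reference_id},length={contig_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(isolates)
            + "\n"
        )
        for snp in snps:
            ref_allele = snp.alleles.get(reference_id, "N")
            if ref_allele not in "ACGT":
                ref_allele = "N"
            alts = sorted(
                {a for a in snp.alleles.values() if a in "ACGT" and a != ref_allele}
            )
            allele_index = {ref_allele: 0}
            for j, alt in enumerate(alts, start=1):
                allele_index[alt] = j
            gts = []
            for iso in isolates:
                allele = snp.alleles.get(iso, ".")
                gts.append(str(allele_index.get(allele, ".")))
            pos1 = snp.ref_position + 1
            info = f"CAT={snp.category_label()};REGION={snp.region}"
            fh.write(
                "\t".join(
                    [
                        reference_id,
                        str(pos1),
                        ".",
                        ref_allele,
                        ",".join(alts) if alts else ".",
                        ".",
                        "PASS",
                        info,
                        "GT",
                    ]
                    + gts
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Newick


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string (validated by dendropy)."""
    try:
        return dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several error types
        raise FormatError(f"bad Newick: {exc}") from exc


def read_newick(path) -> dendropy.Tree:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(path, newick: str) -> None:
    with open(path, "w") as fh:
        fh.write(newick.rstrip("\n;") + ";\n")


# ---------------------------------------------------------------------------
# TSV / PHYLIP


def write_tsv(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_phylip_matrix(path, taxa: list[str], matrix) -> None:
    """Square PHYLIP-style distance matrix."""
    with open(path, "w") as fh:
        fh.write(f"{len(taxa)}\n")
        for i, taxon in enumerate(taxa):
            row = " ".join(f"{matrix[i][j]:.8f}" for j in range(len(taxa)))
            fh.write(f"{taxon:<12s}{row}\n")


def fasta_string(genomes: list[Genome]) -> str:
    buf = _stdio.StringIO()
    for g in genomes:
        buf.write(f">{g.id}\n{g.sequence}\n")
    return buf.getvalue()
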