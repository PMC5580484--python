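"""SNP calling from the multiple alignment and pattern classification.

A SNP position is an alignment column covered (non-gap) by every named
isolate and carrying at least two distinct characters.  Columns containing
any IUPAC ambiguity code are recorded but flagged ``ambiguous`` and are
excluded from pattern classification and density statistics, since they
reflect consensus heterogeneity of an isolate rather than a fixed
difference.

Each unambiguous pattern is classified against a rooted reference
topology: a 1|(n-1) split is specific to the singleton isolate; a 2|3
split is labeled by whichever side forms a rooted clade (else by the
2-isolate side); a triallelic column with two singleton private alleles
carries both singleton annotations; anything else is unspecific.  The
clade-preference rule is the only rule consistent with labeling the
{M,I12} pattern by the pair, the {S,I07} pattern by its clade complement
M/I12/E2, and the {E2,S} pattern by the pair.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import MultiAlignment
from .orfs import OrfRecord
from .io import FeatureRecord, parse_newick

_UNAMBIG = frozenset(b"ACGT")
_GAP = ord("-")


@dataclass
class SnpRecord:
    """One variant column.

    ``ref_position`` is 0-based on the reference genome internally (1-based
    only in emitted files); ``category`` is ("specific", (taxa...)),
    ("shared", (taxa...)), ("unspecific", ()) or ("ambiguous", ()).
    """

    ref_position: int
    column: int
    alleles: dict[str, str]
    category: tuple[str, tuple[str, ...]] = ("unspecific", ())
    region: str = "noncoding_or_repeat"
    in_repeat: bool = False

    def category_label(self) -> str:
        kind, taxa = self.category
        if kind == "specific":
            return "specific:" + "+".join(taxa)
        if kind == "shared":
            return "shared:" + "/".join(taxa)
        return kind


def rooted_clades(topology) -> set[frozenset[str]]:
    """Non-trivial clades (leaf-label sets of internal nodes) of a rooted
    tree given as Newick or a dendropy Tree."""
    tree = parse_newick(topology) if isinstance(topology, str) else topology
    clades: set[frozenset[str]] = set()
    n_leaves = len(tree.leaf_nodes())
    for node in tree.preorder_internal_node_iter():
        labels = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if 1 < len(labels) < n_leaves:
            clades.add(labels)
    return clades


def call_snps(
    msa: MultiAlignment,
    isolates: list[str],
    topology=None,
    repeat_features: list[FeatureRecord] | None = None,
) -> list[SnpRecord]:
    """Call and classify SNPs over the columns covered by all ``isolates``.

    The reference must be one of the isolates (its row provides the
    coordinate).  If ``topology`` is given, each unambiguous record is
    pattern-classified against it.
    """
    for iso in isolates:
        if iso not in msa.rows:
            raise ValueError(f"isolate {iso!r} absent from alignment")
    if msa.reference_id not in isolates:
        raise ValueError("the reference isolate must be among the called isolates")

    clades = rooted_clades(topology) if topology is not None else None
    matrix = msa.char_matrix(isolates)
    ref_positions = msa.col_to_pos(msa.reference_id)

    covered = (matrix != _GAP).all(axis=0)
    varying = (matrix != matrix[0]).any(axis=0)
    candidate_cols = np.flatnonzero(covered & varying)

    repeat_mask = None
    if repeat_features:
        repeat_mask = np.zeros(int(ref_positions.max()) + 1, dtype=bool)
        for f in repeat_features:
            repeat_mask[f.start : f.end] = True

    records: list[SnpRecord] = []
    for col in candidate_cols:
        chars = matrix[:, col]
        alleles = {iso: chr(c) for iso, c in zip(isolates, chars)}
        rec = SnpRecord(
            ref_position=int(ref_positions[col]), column=int(col), alleles=alleles
        )
        if any(c not in _UNAMBIG for c in chars):
            rec.category = ("ambiguous", ())
        elif clades is not None:
            rec.category = classify_pattern(alleles, clades)
        if repeat_mask is not None and 0 <= rec.ref_position < len(repeat_mask):
            rec.in_repeat = bool(repeat_mask[rec.ref_position])
        records.append(rec)
    return records


def classify_pattern(
    alleles: dict[str, str], clades: set[frozenset[str]]
) -> tuple[str, tuple[str, ...]]:
    """Classify one unambiguous allele pattern against the rooted topology.

    Total and deterministic over every possible pattern; invariant to the
    ordering of the isolates.
    """
    groups: dict[str, list[str]] = defaultdict(list)
    for taxon, allele in alleles.items():
        groups[allele].append(taxon)
    sizes = sorted(len(g) for g in groups.values())
    n = len(alleles)

    if len(groups) == 2:
        small, large = sorted(groups.values(), key=len)
        if len(small) == 1:
            return ("specific", tuple(small))
        if n == 5 and sizes == [2, 3]:
            side2, side3 = frozenset(small), frozenset(large)
            in2, in3 = side2 in clades, side3 in clades
            if in3 and not in2:
                return ("shared", tuple(sorted(side3)))
            return ("shared", tuple(sorted(side2)))
        # even splits or n != 5: label the smaller (or clade) side
        side_small, side_large = frozenset(small), frozenset(large)
        if side_large in clades and side_small not in clades:
            return ("shared", tuple(sorted(side_large)))
        return ("shared", tuple(sorted(side_small)))

    if len(groups) == 3 and sizes == [1, 1, n - 2]:
        singletons = sorted(t for g in groups.values() if len(g) == 1 for t in g)
        return ("specific", tuple(singletons))

    return ("unspecific", ())


def category_counts(records: list[SnpRecord]) -> pd.DataFrame:
    """Per-category tally (mirrors a branch-annotated SNP summary)."""
    counts = Counter(r.category_label() for r in records)
    frame = pd.DataFrame(
        sorted(counts.items()), columns=["category", "count"]
    )
    return frame


def snp_density(
    records: list[SnpRecord],
    orfs: list[OrfRecord],
    genome_length: int,
) -> tuple[float, float]:
    """(coding, noncoding) SNPs per bp on the reference genome.

    Coding space is the union of ORF spans; ambiguous positions are
    excluded from both numerators.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    coding_mask = np.zeros(genome_length, dtype=bool)
    for orf in orfs:
        coding_mask[orf.start : orf.end] = True
    coding_bp = int(coding_mask.sum())
    noncoding_bp = genome_length - coding_bp

    coding_snps = noncoding_snps = 0
    for rec in records:
        if rec.category[0] == "ambiguous":
            continue
        if 0 <= rec.ref_position < genome_length and coding_mask[rec.ref_position]:
            coding_snps += 1
        else:
            noncoding_snps += 1
    if coding_bp == 0 and coding_snps:
        raise ZeroDivisionError("coding SNPs with zero coding bp")
    if noncoding_bp == 0 and noncoding_snps:
        raise ZeroDivisionError("noncoding SNPs with zero noncoding bp")
    coding = coding_snps / coding_bp if coding_bp else 0.0
    noncoding = noncoding_snps / noncoding_bp if noncoding_bp else 0.0
    return coding, noncoding


def annotate_regions(records: list[SnpRecord], orfs: list[OrfRecord],
                     genome_length: int) -> None:
    """Set each record's region flag from the ORF union."""
    coding_mask = np.zeros(genome_length, dtype=bool)
    for orf in orfs:
        coding_mask[orf.start : orf.end] = True
    for rec in records:
        inside = 0 <= rec.ref_position < genome_length and coding_mask[rec.ref_position]
        rec.region = "coding" if inside and not rec.in_repeat else "noncoding_or_repeat"


def insertion_variants(msa: MultiAlignment, isolates: list[str]) -> pd.DataFrame:
    """Columns where the reference is gapped but all isolates are covered:
    insertion variants relative to the reference, reported separately from
    SNPs because they carry no reference coordinate."""
    others = [iso for iso in isolates if iso != msa.reference_id]
    matrix = msa.char_matrix(others)
    ref_row = np.frombuffer(msa.rows[msa.reference_id].encode(), dtype=np.uint8)
    ref_positions = msa.col_to_pos(msa.reference_id)
    covered = (matrix != _GAP).all(axis=0)
    cols = np.flatnonzero(covered & (ref_row == _GAP))
    rows = []
    for col in cols:
        # anchor to the last reference base before the insertion block
        before = ref_positions[:col]
        anchor = int(before[before >= 0][-1]) if (before >= 0).any() else -1
        rows.append(
            {
                "column": int(col),
                "ref_position_before": anchor,
                **{iso: chr(c) for iso, c in zip(others, matrix[:, col])},
            }
        )
    return pd.DataFrame(rows)


def snps_frame(records: list[SnpRecord], isolates: list[str]) -> pd.DataFrame:
    """One row per SNP: 1-based position, alleles, category, region, repeat flag."""
    rows = []
    for rec in records:
        row = {
            "position": rec.ref_position + 1,
            "category": rec.category_label(),
            "region": rec.region,
            "in_repeat": rec.in_repeat,
        }
        for iso in isolates:
            row[iso] = rec.alleles.get(iso, ".")
        rows.append(row)
    columns = ["position"] + isolates + ["category", "region", "in_repeat"]
    return pd.DataFrame(rows, columns=columns)
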