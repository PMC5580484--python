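"""ORF prediction, filtering and reference-guided naming.

ORFs are maximal ATG-to-stop frames on either strand of at least 150 nt
(start through stop codon inclusive).  Annotation follows the isolate
comparison rules used for small DNA virus genomes: ORFs fully inside a
repeat region are dropped, pairs overlapping by more than 100 nt keep the
longer member, and query ORFs are named for the reference ORF they cover
through the whole-genome alignment — detecting fusion (one query ORF
covering two adjacent reference ORFs, e.g. after a frameshifting
deletion) and fission (one reference ORF split across two query ORFs).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .align import MultiAlignment
from .io import FeatureRecord, Genome, revcomp

STOP_CODONS = {"TAA", "TAG", "TGA"}
START_CODON = "ATG"


@dataclass(frozen=True)
class OrfRecord:
    """An ORF interval, internal 0-based half-open, start < end on the
    forward frame regardless of strand."""

    name: str
    start: int
    end: int
    strand: str
    status: str = "intact"  # intact | fused | split | absent_in_isolate
    attributes: dict = field(default_factory=dict, compare=False, hash=False)

    @property
    def length(self) -> int:
        """nt including the stop codon."""
        return self.end - self.start

    def overlap(self, other: "OrfRecord") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def _scan_strand(seq: str, min_length: int):
    """Maximal ORFs on one (forward-oriented) strand: for each stop-bounded
    frame segment, the 5'-most ATG through the stop."""
    n = len(seq)
    out = []
    for frame in range(3):
        first_atg = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                if first_atg is not None:
                    length = pos + 3 - first_atg
                    if length >= min_length:
                        out.append((first_atg, pos + 3))
                    first_atg = None
            elif codon == START_CODON and first_atg is None:
                first_atg = pos
    return out


def find_orfs(genome: Genome | str, min_length: int = 150) -> list[OrfRecord]:
    """All maximal ATG-to-stop ORFs >= min_length on both strands."""
    seq = genome.sequence if isinstance(genome, Genome) else genome
    n = len(seq)
    records = []
    for start, end in _scan_strand(seq, min_length):
        records.append(OrfRecord(f"orf_p_{start}", start, end, "+"))
    for start, end in _scan_strand(revcomp(seq), min_length):
        records.append(OrfRecord(f"orf_m_{n - end}", n - end, n - start, "-"))
    records.sort(key=lambda o: (o.start, o.end, o.strand))
    return records


def filter_orfs(
    orfs: list[OrfRecord],
    repeat_regions: list[FeatureRecord] | None = None,
    max_overlap: int = 100,
    whitelist: set[str] | None = None,
) -> list[OrfRecord]:
    """Drop ORFs fully inside a repeat region, then resolve overlaps >
    ``max_overlap`` nt by keeping the longer ORF (longest-first greedy).
    An overlap of exactly ``max_overlap`` is retained.  Whitelisted names
    are exempt from both rules.  Idempotent."""
    repeat_regions = repeat_regions or []
    whitelist = whitelist or set()

    survivors = []
    for orf in orfs:
        if orf.name in whitelist:
            survivors.append(orf)
            continue
        contained = any(
            orf.start >= f.start and orf.end <= f.end for f in repeat_regions
        )
        if not contained:
            survivors.append(orf)

    kept: list[OrfRecord] = []
    for orf in sorted(survivors, key=lambda o: (-o.length, o.start, o.strand)):
        if orf.name in whitelist or all(
            orf.overlap(k) <= max_overlap for k in kept if k.name not in whitelist
        ):
            kept.append(orf)
    kept.sort(key=lambda o: (o.start, o.end, o.strand))
    return kept


# ---------------------------------------------------------------------------
# naming against a reference annotation


def _project_to_reference(
    msa: MultiAlignment, isolate: str, start: int, end: int
) -> tuple[int, int] | None:
    """Map a query interval into reference coordinates via the alignment."""
    p2c = msa.pos_to_col(isolate)
    c2p_ref = msa.col_to_pos(msa.reference_id)
    col_s, col_e = p2c[start], p2c[end - 1]
    # nearest covered reference position inward of the interval ends
    seg = c2p_ref[col_s : col_e + 1]
    covered = seg[seg >= 0]
    if covered.size == 0:
        return None
    return int(covered[0]), int(covered[-1]) + 1


def _merge_names(a: str, b: str) -> str:
    """'cp28' + 'cp29' -> 'cp28/29'; falls back to 'a/b'."""
    prefix = ""
    for ca, cb in zip(a, b):
        if ca == cb and not ca.isdigit():
            prefix += ca
        else:
            break
    if prefix and a.startswith(prefix) and b.startswith(prefix):
        return f"{a}/{b[len(prefix):]}"
    return f"{a}/{b}"


def map_orf_names(
    query_orfs: list[OrfRecord],
    reference_orfs: list[OrfRecord],
    msa: MultiAlignment,
    query_isolate: str,
    min_reciprocal: float = 0.5,
) -> list[OrfRecord]:
    """Name query ORFs after reference ORFs through the alignment.

    Returns named query records (status intact/fused/split) plus
    ``absent_in_isolate`` records (in reference coordinates) for reference
    ORFs with no qualifying query ORF.
    """
    if query_isolate not in msa.rows:
        raise ValueError(f"isolate {query_isolate!r} missing from alignment")
    ref_sorted = sorted(reference_orfs, key=lambda o: o.start)
    ref_index = {id(r): i for i, r in enumerate(ref_sorted)}

    projected: list[tuple[OrfRecord, tuple[int, int] | None]] = []
    for q in query_orfs:
        projected.append((q, _project_to_reference(msa, query_isolate, q.start, q.end)))

    def ival_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
        return max(0, min(a[1], b[1]) - max(a[0], b[0]))

    # overlaps[qi] = list of (ref orf, overlap bp)
    overlaps: list[list[tuple[OrfRecord, int]]] = []
    for q, proj in projected:
        row = []
        if proj is not None:
            for r in ref_sorted:
                ov = ival_overlap(proj, (r.start, r.end))
                if ov > 0:
                    row.append((r, ov))
        overlaps.append(row)

    named: list[OrfRecord] = []
    claimed: dict[int, list[int]] = {}  # ref idx -> query idxs qualifying
    assignment: dict[int, OrfRecord] = {}

    for qi, ((q, proj), row) in enumerate(zip(projected, overlaps)):
        if proj is None or not row:
            continue
        # fusion: one query ORF covering >= half of each of two adjacent
        # same-strand reference ORFs
        strong = [
            (r, ov) for r, ov in row
            if ov >= min_reciprocal * r.length and r.strand == q.strand
        ]
        strong.sort(key=lambda t: ref_index[id(t[0])])
        fused = None
        for (r1, _), (r2, _) in zip(strong, strong[1:]):
            if ref_index[id(r2)] - ref_index[id(r1)] == 1:
                fused = (r1, r2)
                break
        if fused is not None:
            named.append(
                replace(
                    q,
                    name=_merge_names(fused[0].name, fused[1].name),
                    status="fused",
                )
            )
            for r in fused:
                claimed.setdefault(ref_index[id(r)], []).append(qi)
            continue
        # plain naming: greatest reciprocal overlap >= half of the shorter
        best, best_ov = None, 0
        for r, ov in row:
            if ov >= min_reciprocal * min(r.length, q.length) and ov > best_ov:
                best, best_ov = r, ov
        if best is not None:
            assignment[qi] = best
            claimed.setdefault(ref_index[id(best)], []).append(qi)

    # fission: one reference ORF claimed by >= 2 query ORFs
    for ref_idx, query_idxs in claimed.items():
        r = ref_sorted[ref_idx]
        plain = [qi for qi in query_idxs if qi in assignment and assignment[qi] is r]
        if len(plain) >= 2:
            for part_idx, qi in enumerate(
                sorted(plain, key=lambda qi: projected[qi][0].start)
            ):
                q = projected[qi][0]
                suffix = chr(ord("a") + part_idx)
                named.append(replace(q, name=f"{r.name}{suffix}", status="split"))
                del assignment[qi]

    for qi, r in assignment.items():
        named.append(replace(projected[qi][0], name=r.name, status="intact"))

    for ref_idx, r in enumerate(ref_sorted):
        if ref_idx not in claimed:
            named.append(
                OrfRecord(
                    r.name, r.start, r.end, r.strand, "absent_in_isolate",
                    {"coordinates": "reference"},
                )
            )

    named.sort(key=lambda o: (o.start, o.end))
    return named


def translate_orf(genome: Genome | str, orf: OrfRecord) -> str:
    """Amino-acid sequence of the ORF (standard code, stop excluded)."""
    from Bio.Seq import Seq

    seq = genome.sequence if isinstance(genome, Genome) else genome
    nt = seq[orf.start : orf.end]
    if orf.strand == "-":
        nt = revcomp(nt)
    aa = str(Seq(nt).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise ValueError(f"ORF {orf.name!r} has an internal stop codon")
    return aa


def orfs_to_features(orfs: list[OrfRecord]) -> list[FeatureRecord]:
    return [
        FeatureRecord(
            o.name, o.start, o.end, o.strand, "ORF",
            {"status": o.status, "length_nt": o.length},
        )
        for o in orfs
    ]
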