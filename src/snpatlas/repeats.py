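"""Maximal direct/inverted repeat detection and repeat-region delineation.

Exact maximal repeats are found first (seed on shared k-mers, extend,
deduplicate per diagonal); near-identical copies are then clustered into
dispersed-repeat families by alignment identity, and the largest tandem
array of large direct repeats is delineated as the major repeat region.
Keeping the seeds exact makes the finder checkable against an independent
quadratic diagonal-scan oracle; mismatch tolerance lives entirely in the
clustering step.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .align import pairwise_global
from .io import FeatureRecord, Genome, revcomp


@dataclass
class RepeatRecord:
    """A repeat: >= 2 copy intervals (0-based half-open) of one unit."""

    kind: str  # "direct" | "inverted"
    copy_intervals: list[tuple[int, int, str]]  # (start, end, orientation)
    unit_length: int
    identity: float = 1.0
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("direct", "inverted"):
            raise ValueError(f"bad repeat kind {self.kind!r}")
        if len(self.copy_intervals) < 2:
            raise ValueError("a repeat needs >= 2 copies")
        if not 0.0 < self.identity <= 1.0:
            raise ValueError("identity must lie in (0, 1]")

    @property
    def n_copies(self) -> int:
        return len(self.copy_intervals)

    def span(self) -> tuple[int, int]:
        starts = [s for s, _, _ in self.copy_intervals]
        ends = [e for _, e, _ in self.copy_intervals]
        return min(starts), max(ends)


class NoMajorRepeatRegion(ValueError):
    """No tandem array of large direct repeats exists."""


def _maximal_match_pairs(s: str, t: str, k: int):
    """Maximal exact match pairs (i in s, j in t, length) via seed-extend."""
    if len(s) < k or len(t) < k:
        return set()
    t_kmers: dict[str, list[int]] = defaultdict(list)
    for j in range(len(t) - k + 1):
        t_kmers[t[j : j + k]].append(j)
    diagonals: dict[int, list[int]] = defaultdict(list)
    for i in range(len(s) - k + 1):
        hits = t_kmers.get(s[i : i + k])
        if hits:
            for j in hits:
                diagonals[i - j].append(i)
    out = set()
    for diag, s_positions in diagonals.items():
        s_positions.sort()
        covered_until = -1
        for i0 in s_positions:
            if i0 < covered_until:
                continue
            i, j = i0, i0 - diag
            while i > 0 and j > 0 and s[i - 1] == t[j - 1]:
                i -= 1
                j -= 1
            max_len = min(len(s) - i, len(t) - j)
            length = 0
            while length < max_len and s[i + length] == t[j + length]:
                length += 1
            covered_until = i + length
            if length >= k:
                out.add((i, j, length))
    return out


def find_maximal_repeats(
    genome: Genome | str, min_length: int = 20, kind: str = "direct"
) -> list[RepeatRecord]:
    """All maximal exact repeats >= min_length within one genome.

    ``kind="direct"`` compares the sequence to itself (self-identical pairs
    excluded, each pair reported once with the left copy first);
    ``kind="inverted"`` compares to the reverse complement (palindromic
    self-hits deduplicated, second copy reported with orientation '-').
    """
    if min_length < 4:
        raise ValueError("min_length must be >= 4")
    seq = genome.sequence if isinstance(genome, Genome) else genome
    n = len(seq)
    records: list[RepeatRecord] = []
    if kind == "direct":
        for i, j, length in _maximal_match_pairs(seq, seq, min_length):
            if i >= j:  # keep one orientation of each pair; drop self-diagonal
                continue
            records.append(
                RepeatRecord(
                    "direct",
                    [(i, i + length, "+"), (j, j + length, "+")],
                    length,
                )
            )
    elif kind == "inverted":
        rc = revcomp(seq)
        seen = set()
        for i, j, length in _maximal_match_pairs(seq, rc, min_length):
            # s[i:i+L] == rc(s)[j:j+L] == revcomp(s[n-j-L : n-j])
            j2 = n - j - length
            a, b = sorted([i, j2])
            if a == b:
                # a palindrome matching itself in place: one copy only
                continue
            key = (a, b, length)
            if key in seen:
                continue
            seen.add(key)
            records.append(
                RepeatRecord(
                    "inverted",
                    [(a, a + length, "+"), (b, b + length, "-")],
                    length,
                )
            )
    else:
        raise ValueError(f"kind must be 'direct' or 'inverted', got {kind!r}")
    records.sort(key=lambda r: r.copy_intervals[0])
    return records


def brute_force_repeats(genome: Genome | str, min_length: int = 20,
                        kind: str = "direct") -> list[RepeatRecord]:
    """Independent quadratic oracle: scan every diagonal of the (self x self
    or self x revcomp) comparison matrix for runs of matches.  Exact same
    output contract as :func:`find_maximal_repeats`; O(n^2), for small
    genomes only."""
    seq = genome.sequence if isinstance(genome, Genome) else genome
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    other = np.frombuffer(revcomp(seq).encode(), dtype=np.uint8) if kind == "inverted" else arr
    pairs = set()
    start_diag = 1 if kind == "direct" else -(n - 1)
    for d in range(start_diag, n):
        if d >= 0:
            a, b = arr[: n - d], other[d:]
            offset_i, offset_j = 0, d
        else:
            a, b = arr[-d:], other[: n + d]
            offset_i, offset_j = -d, 0
        eq = a == b
        if not eq.any():
            continue
        padded = np.concatenate(([False], eq, [False])).astype(np.int8)
        edges = np.flatnonzero(np.diff(padded))
        for run_start, run_end in zip(edges[::2], edges[1::2]):
            length = int(run_end - run_start)
            if length < min_length:
                continue
            i = int(offset_i + run_start)
            j = int(offset_j + run_start)
            pairs.add((i, j, length))
    records = []
    if kind == "direct":
        for i, j, length in pairs:
            if i >= j:
                continue
            records.append(
                RepeatRecord("direct", [(i, i + length, "+"), (j, j + length, "+")], length)
            )
    else:
        seen = set()
        for i, j, length in pairs:
            j2 = n - j - length
            a_, b_ = sorted([i, j2])
            if a_ == b_:
                continue
            key = (a_, b_, length)
            if key in seen:
                continue
            seen.add(key)
            records.append(
                RepeatRecord("inverted", [(a_, a_ + length, "+"), (b_, b_ + length, "-")], length)
            )
    records.sort(key=lambda r: r.copy_intervals[0])
    return records


# ---------------------------------------------------------------------------
# clustering into dispersed families


def _merge_pair_fragments(records: list[RepeatRecord], slack: int = 10):
    """Rejoin repeat pairs fragmented by mismatches.

    Fragments of one underlying direct repeat share the diagonal
    (second start - first start); fragments of one inverted repeat share
    the anti-diagonal (first start + second end).  Merging along these
    keeps tandem copies distinct while healing mismatch breaks."""
    direct: dict[int, list[RepeatRecord]] = defaultdict(list)
    inverted: dict[int, list[RepeatRecord]] = defaultdict(list)
    for rec in records:
        (a_start, a_end, _), (b_start, b_end, _) = rec.copy_intervals
        if rec.kind == "direct":
            direct[b_start - a_start].append(rec)
        else:
            inverted[a_start + b_end].append(rec)
    merged: list[RepeatRecord] = []
    for kind, groups in (("direct", direct), ("inverted", inverted)):
        for group in groups.values():
            group.sort(key=lambda r: r.copy_intervals[0])
            current = None
            for rec in group:
                (a_s, a_e, _), (b_s, b_e, b_o) = rec.copy_intervals
                if current is not None and a_s <= current[1] + slack:
                    current = (
                        current[0], max(current[1], a_e),
                        min(current[2], b_s), max(current[3], b_e), b_o,
                    )
                else:
                    if current is not None:
                        merged.append(_pair_record(kind, current))
                    current = (a_s, a_e, b_s, b_e, b_o)
            if current is not None:
                merged.append(_pair_record(kind, current))
    return merged


def _pair_record(kind, bounds) -> RepeatRecord:
    a_s, a_e, b_s, b_e, b_o = bounds
    return RepeatRecord(
        kind,
        [(a_s, a_e, "+"), (b_s, b_e, b_o)],
        max(a_e - a_s, b_e - b_s),
    )


def _merge_intervals(intervals, slack: int = 0):
    """Union-merge sorted (start, end, orientation) intervals.

    Substantially overlapping intervals merge (the same copy reported by
    several pair records), as do intervals separated by a small positive
    gap up to ``slack`` bp (a mismatch break between fragments of one
    copy).  Touching or slightly overlapping intervals stay separate —
    that is the juncture between adjacent tandem copies (chance extension
    can overlap them by a few bp), not a break."""
    merged = []
    for start, end, orient in sorted(intervals):
        if merged:
            p_start, p_end, _ = merged[-1]
            overlap = p_end - start
            gap = -overlap
            big_overlap = overlap > 0.5 * min(end - start, p_end - p_start)
            if big_overlap or 1 <= gap <= slack:
                merged[-1] = (p_start, max(p_end, end), merged[-1][2])
                continue
        merged.append((start, end, orient))
    return merged


def _aligned_identity(sa: str, sb: str) -> tuple[float, float]:
    ga, gb, _ = pairwise_global(sa, sb)
    both = sum(1 for x, y in zip(ga, gb) if x != "-" and y != "-")
    same = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    if both == 0:
        return 0.0, 0.0
    return same / both, both / min(len(sa), len(sb))


def _copy_identity(seq: str, a, b) -> tuple[float, float, str]:
    """Best of forward vs reverse-complement comparison of two copies.

    Returns (identity over aligned columns, aligned coverage of the shorter
    copy, relative orientation '+'/'-')."""
    sa = seq[a[0] : a[1]]
    sb = seq[b[0] : b[1]]
    fwd = _aligned_identity(sa, sb)
    rev = _aligned_identity(sa, revcomp(sb))
    if rev[0] > fwd[0]:
        return rev[0], rev[1], "-"
    return fwd[0], fwd[1], "+"


def cluster_dispersed_copies(
    repeats: list[RepeatRecord],
    genome: Genome | str,
    min_identity: float = 0.8,
    min_coverage: float = 0.8,
) -> list[RepeatRecord]:
    """Merge repeat copies into families; flag families with >= 3 copies
    spread over >= 10% of the genome as dispersed.

    Copies join a family when they share >= ``min_identity`` identity over
    >= ``min_coverage`` of the (shorter) unit, assessed by global alignment
    of the copy sequences.
    """
    seq = genome.sequence if isinstance(genome, Genome) else genome
    genome_length = len(seq)
    repeats = _merge_pair_fragments(repeats)
    intervals = {
        (start, end) for rec in repeats for start, end, _ in rec.copy_intervals
    }
    # slack covers a dropped sub-seed fragment between two mismatches
    copies = [
        (s, e)
        for s, e, _ in _merge_intervals(((s, e, "+") for s, e in intervals), slack=25)
    ]
    if not copies:
        return []

    parent = list(range(len(copies)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    identities: dict[tuple[int, int], float] = {}
    rel_orient: dict[tuple[int, int], str] = {}
    for i in range(len(copies)):
        for j in range(i + 1, len(copies)):
            len_i = copies[i][1] - copies[i][0]
            len_j = copies[j][1] - copies[j][0]
            if min(len_i, len_j) < 0.3 * max(len_i, len_j):
                continue  # grossly different sizes cannot satisfy coverage
            ident, cover, orient = _copy_identity(seq, copies[i], copies[j])
            if ident >= min_identity and cover >= min_coverage:
                parent[find(i)] = find(j)
                identities[(i, j)] = ident
                rel_orient[(i, j)] = orient

    groups: dict[int, list[int]] = defaultdict(list)
    for idx in range(len(copies)):
        groups[find(idx)].append(idx)

    families = []
    for members in groups.values():
        if len(members) < 2:
            continue
        members = sorted(members)
        # propagate orientations from the first copy through linked pairs
        orient = {members[0]: "+"}
        frontier = [members[0]]
        links = defaultdict(list)
        for (a, b), o in rel_orient.items():
            if a in members and b in members:
                links[a].append((b, o))
                links[b].append((a, o))
        while frontier:
            node = frontier.pop()
            for nbr, o in links[node]:
                if nbr not in orient:
                    flip = {"+": "-", "-": "+"}
                    orient[nbr] = orient[node] if o == "+" else flip[orient[node]]
                    frontier.append(nbr)
        ivals = [
            (copies[m][0], copies[m][1], orient.get(m, "+")) for m in members
        ]
        unit = int(np.median([e - s for s, e, _ in ivals]))
        pair_idents = [
            v for (a, b), v in identities.items() if a in members and b in members
        ]
        identity = float(min(pair_idents)) if pair_idents else 1.0
        span = max(e for _, e, _ in ivals) - min(s for s, _, _ in ivals)
        dispersed = len(ivals) >= 3 and span >= 0.1 * genome_length
        kind = "inverted" if len({o for _, _, o in ivals}) > 1 else "direct"
        families.append(
            RepeatRecord(
                kind,
                sorted(ivals),
                unit,
                identity,
                flags={"dispersed": dispersed},
            )
        )
    families.sort(key=lambda r: (-r.n_copies, r.copy_intervals[0]))
    return families


# ---------------------------------------------------------------------------
# major repeat region


def delineate_major_repeat_region(
    genome: Genome | str,
    direct_repeats: list[RepeatRecord] | None = None,
    min_unit: int = 200,
    min_seed: int = 20,
) -> FeatureRecord:
    """The contiguous span of the largest tandem array of large direct
    repeats (unit >= ``min_unit``), extended by smaller same-period matches
    so partially deleted copies stay inside the span."""
    seq = genome.sequence if isinstance(genome, Genome) else genome
    if direct_repeats is None:
        direct_repeats = find_maximal_repeats(seq, min_length=min_seed, kind="direct")

    def period(rec: RepeatRecord) -> int:
        return rec.copy_intervals[1][0] - rec.copy_intervals[0][0]

    large_tandem = [
        rec
        for rec in direct_repeats
        if rec.unit_length >= min_unit and period(rec) <= 1.25 * rec.unit_length
    ]
    if not large_tandem:
        raise NoMajorRepeatRegion(
            f"no tandem array of direct repeats with unit >= {min_unit} bp"
        )

    best_span = None
    for rec in large_tandem:
        p = period(rec)
        lo, hi = rec.span()
        # absorb same-period fragments adjacent to the array (e.g. a copy
        # truncated by a deletion)
        changed = True
        while changed:
            changed = False
            for other in direct_repeats:
                if abs(period(other) - p) > 10:
                    continue
                o_lo, o_hi = other.span()
                if o_hi < lo - p or o_lo > hi + p:
                    continue
                new_lo, new_hi = min(lo, o_lo), max(hi, o_hi)
                if (new_lo, new_hi) != (lo, hi):
                    lo, hi = new_lo, new_hi
                    changed = True
        if best_span is None or hi - lo > best_span[1] - best_span[0]:
            best_span = (lo, hi)

    lo, hi = best_span
    return FeatureRecord(
        "major_repeat_region", lo, hi, "+", "major_repeat_region",
        {"length_bp": hi - lo},
    )


def repeat_features(families: list[RepeatRecord]) -> list[FeatureRecord]:
    """Flatten families into GFF3-ready features."""
    out = []
    for fam_idx, fam in enumerate(families):
        kind = "dispersed_repeat" if fam.flags.get("dispersed") else "repeat_region"
        for copy_idx, (start, end, orient) in enumerate(fam.copy_intervals):
            out.append(
                FeatureRecord(
                    f"family{fam_idx}_copy{copy_idx}", start, end, orient, kind,
                    {"identity": round(fam.identity, 3)},
                )
            )
    return sorted(out, key=lambda f: f.start)
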