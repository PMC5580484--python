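"""Reference-anchored multiple alignment of co-linear genomes.

The isolates analysed by this package share gene order and orientation
(no translocations or inversions), which licenses a star alignment around
a chosen reference instead of a locally-collinear-block aligner: each
query is aligned pairwise to the reference by seeding on maximal unique
exact matches, chaining them co-linearly, and filling the inter-anchor
segments with an affine-gap global alignment; the pairwise alignments are
then projected into common columns, merging same-position insertions into
shared, left-aligned insertion blocks.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io import IUPAC_CODES, IUPAC_SETS, Genome

GAP = "-"

DEFAULT_SCORING = {"match": 2, "mismatch": -3, "gap_open": -5, "gap_extend": -2}
MAX_SEGMENT = 50_000


class ColinearityError(ValueError):
    """Anchoring covers too little of a genome — likely rearranged input."""


class SegmentTooLongError(ValueError):
    """An unanchored segment exceeds the quadratic-alignment guard."""


@dataclass(frozen=True)
class Anchor:
    """A maximal exact match unique in both sequences (forward strand)."""

    ref_start: int
    qry_start: int
    length: int

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.length

    @property
    def qry_end(self) -> int:
        return self.qry_start + self.length


def _count_occurrences(haystack: str, needle: str, limit: int = 2) -> int:
    """Count (possibly overlapping) occurrences, stopping early at ``limit``."""
    count = 0
    pos = haystack.find(needle)
    while pos != -1:
        count += 1
        if count >= limit:
            return count
        pos = haystack.find(needle, pos + 1)
    return count


def find_anchors(ref: Genome | str, qry: Genome | str, min_length: int = 20) -> list[Anchor]:
    """All maximal exact matches >= min_length occurring exactly once in each sequence.

    Seeds on shared ``min_length``-mers, extends each seed to a maximal
    match, deduplicates per diagonal, then enforces uniqueness of the full
    matched substring in both sequences.
    """
    if min_length < 12:
        raise ValueError("min_length must be >= 12")
    r = ref.sequence if isinstance(ref, Genome) else ref
    q = qry.sequence if isinstance(qry, Genome) else qry
    k = min_length
    if len(r) < k or len(q) < k:
        return []

    ref_kmers: dict[str, list[int]] = defaultdict(list)
    for i in range(len(r) - k + 1):
        ref_kmers[r[i : i + k]].append(i)

    # seeds grouped by diagonal (ref_start - qry_start)
    diagonals: dict[int, list[int]] = defaultdict(list)
    for j in range(len(q) - k + 1):
        hits = ref_kmers.get(q[j : j + k])
        if hits:
            for i in hits:
                diagonals[i - j].append(j)

    candidates: set[tuple[int, int, int]] = set()
    for diag, qry_positions in diagonals.items():
        qry_positions.sort()
        covered_until = -1
        for j in qry_positions:
            if j < covered_until:
                continue
            i = j + diag
            # extend left
            while i > 0 and j > 0 and r[i - 1] == q[j - 1]:
                i -= 1
                j -= 1
            # extend right (rescans the seed; cheap relative to dict build)
            max_len = min(len(r) - i, len(q) - j)
            length = 0
            while length < max_len and r[i + length] == q[j + length]:
                length += 1
            covered_until = j + length
            if length >= k:
                candidates.add((i, j, length))

    anchors = []
    for i, j, length in candidates:
        sub = r[i : i + length]
        if _count_occurrences(r, sub) == 1 and _count_occurrences(q, sub) == 1:
            anchors.append(Anchor(i, j, length))
    anchors.sort(key=lambda a: (a.ref_start, a.qry_start))
    return anchors


#: cost per bp of diagonal change between consecutive chained anchors.
#: A true indel of length L shifts the diagonal once and costs L/2 in every
#: chain that crosses it (so comparisons are unaffected), while a spurious
#: shift-and-return through a tandem repeat costs the shift twice and is
#: suppressed unless it anchors more than the period's worth of sequence.
DIAGONAL_SHIFT_COST = 0.5


def chain_anchors(anchors: list[Anchor]) -> list[Anchor]:
    """Best co-linear chain of anchors by dynamic programming.

    Successive anchors must be strictly increasing in both start and end
    coordinates of both sequences; partial overlap is permitted (anchors
    are exact matches, so the overlap is trimmed when the chain is used)
    but anchors that would reorder either sequence are excluded.  The
    objective is the trimmed anchored length minus a diagonal-shift (indel)
    cost; ties prefer the chain with the smaller total inter-anchor gap
    span (ref gap + qry gap summed)."""
    if not anchors:
        return []
    order = sorted(anchors, key=lambda a: (a.ref_start, a.qry_start))
    n = len(order)
    best_score = [float(a.length) for a in order]
    best_gap = [0] * n
    prev = [-1] * n
    for i in range(n):
        ai = order[i]
        diag_i = ai.ref_start - ai.qry_start
        for j in range(i):
            aj = order[j]
            if (
                aj.ref_start < ai.ref_start
                and aj.qry_start < ai.qry_start
                and aj.ref_end < ai.ref_end
                and aj.qry_end < ai.qry_end
            ):
                # anchored length net of the overlap that will be trimmed,
                # so overlapping anchors earn no double credit
                trim = max(aj.ref_end - ai.ref_start, aj.qry_end - ai.qry_start, 0)
                shift = abs(diag_i - (aj.ref_start - aj.qry_start))
                cand = best_score[j] + ai.length - trim - DIAGONAL_SHIFT_COST * shift
                cand_gap = (
                    best_gap[j]
                    + max(0, ai.ref_start - aj.ref_end)
                    + max(0, ai.qry_start - aj.qry_end)
                )
                if cand > best_score[i] + 1e-9 or (
                    abs(cand - best_score[i]) <= 1e-9 and cand_gap < best_gap[i]
                ):
                    best_score[i] = cand
                    best_gap[i] = cand_gap
                    prev[i] = j
    end = max(range(n), key=lambda i: (best_score[i], -best_gap[i]))
    chain = []
    while end != -1:
        chain.append(order[end])
        end = prev[end]
    return chain[::-1]


# ---------------------------------------------------------------------------
# pairwise affine-gap global alignment


def _substitution_matrix(match: int, mismatch: int):
    """IUPAC-aware scores: exact unambiguous match -> ``match``; codes whose
    base sets intersect, at least one ambiguous -> half-match (+1); else
    ``mismatch``.  Avoids penalizing documented consensus heterogeneity."""
    alphabet = IUPAC_CODES
    mat = substitution_matrices.Array(alphabet=alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if a == b and a in "ACGT":
                mat[a, b] = match
            elif IUPAC_SETS[a] & IUPAC_SETS[b]:
                mat[a, b] = 1
            else:
                mat[a, b] = mismatch
    return mat


_ALIGNER_CACHE: dict[tuple, Align.PairwiseAligner] = {}


def _get_aligner(scoring: dict) -> Align.PairwiseAligner:
    key = tuple(sorted(scoring.items()))
    if key not in _ALIGNER_CACHE:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = _substitution_matrix(
            scoring["match"], scoring["mismatch"]
        )
        # Biopython charges open_gap_score for the first gap position and
        # extend_gap_score thereafter; the package convention charges
        # gap_open once per run plus gap_extend per position.
        aligner.open_gap_score = scoring["gap_open"] + scoring["gap_extend"]
        aligner.extend_gap_score = scoring["gap_extend"]
        _ALIGNER_CACHE[key] = aligner
    return _ALIGNER_CACHE[key]


def pairwise_global(
    a: str, b: str, scoring: dict | None = None
) -> tuple[str, str, float]:
    """Optimal affine-gap global alignment of two segments.

    A gap run of length L costs ``gap_open + L * gap_extend``.  Returns the
    two gapped strings and the optimal score.
    """
    scoring = dict(DEFAULT_SCORING, **(scoring or {}))
    if len(a) > MAX_SEGMENT or len(b) > MAX_SEGMENT:
        raise SegmentTooLongError(
            f"segment lengths {len(a)}/{len(b)} exceed {MAX_SEGMENT} bp; "
            "add anchors or relax min_length"
        )
    if not a and not b:
        return "", "", 0.0
    if not a:
        return GAP * len(b), b, scoring["gap_open"] + len(b) * scoring["gap_extend"]
    if not b:
        return a, GAP * len(a), scoring["gap_open"] + len(a) * scoring["gap_extend"]
    aligner = _get_aligner(scoring)
    alignments = aligner.align(a, b)
    best = alignments[0]
    return str(best[0]), str(best[1]), float(best.score)


# ---------------------------------------------------------------------------
# reference-anchored MSA


@dataclass
class MultiAlignment:
    """Gapped, reference-anchored alignment of all isolates.

    ``rows`` maps isolate -> gapped sequence (all equal length); the
    reference row defines the coordinate frame.  Degapping any row must
    reproduce that isolate's input genome exactly.
    """

    reference_id: str
    rows: dict[str, str]
    _col_to_pos: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _pos_to_col: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError("alignment rows differ in length")
        if self.reference_id not in self.rows:
            raise ValueError(f"reference {self.reference_id!r} not among rows")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    def isolates(self) -> list[str]:
        return list(self.rows)

    def degapped(self, isolate: str) -> str:
        return self.rows[isolate].replace(GAP, "")

    def col_to_pos(self, isolate: str) -> np.ndarray:
        """Per column: 0-based genome position of this isolate, or -1 at gaps."""
        if isolate not in self._col_to_pos:
            row = np.frombuffer(self.rows[isolate].encode(), dtype=np.uint8)
            not_gap = row != ord(GAP)
            positions = np.cumsum(not_gap) - 1
            out = np.where(not_gap, positions, -1)
            self._col_to_pos[isolate] = out
        return self._col_to_pos[isolate]

    def pos_to_col(self, isolate: str) -> np.ndarray:
        """Per genome position: alignment column holding that residue."""
        if isolate not in self._pos_to_col:
            c2p = self.col_to_pos(isolate)
            self._pos_to_col[isolate] = np.flatnonzero(c2p >= 0)
        return self._pos_to_col[isolate]

    def char_matrix(self, isolates: list[str] | None = None) -> np.ndarray:
        """(n_isolates, n_columns) byte matrix of the gapped rows."""
        isolates = isolates or self.isolates()
        return np.vstack(
            [np.frombuffer(self.rows[i].encode(), dtype=np.uint8) for i in isolates]
        )


def _align_pair(ref: str, qry: str, min_anchor: int, scoring: dict | None):
    """Anchor, chain, gap-fill: one query against the reference."""
    anchors = find_anchors(ref, qry, min_anchor)
    chain = chain_anchors(anchors)
    anchored = sum(a.length for a in chain)
    if anchored < 0.5 * len(ref) or anchored < 0.5 * len(qry):
        raise ColinearityError(
            f"anchor chain covers {anchored} bp of {len(ref)}/{len(qry)} bp "
            "(<50%); genomes may be rearranged"
        )
    ref_parts: list[str] = []
    qry_parts: list[str] = []
    r_prev = q_prev = 0
    for anchor in chain:
        # trim any overlap with the previously emitted anchor; the anchor
        # is an exact match so trimming its start keeps it exact
        trim = max(r_prev - anchor.ref_start, q_prev - anchor.qry_start, 0)
        a_ref, a_qry = anchor.ref_start + trim, anchor.qry_start + trim
        seg_r = ref[r_prev:a_ref]
        seg_q = qry[q_prev:a_qry]
        if seg_r or seg_q:
            ga, gb, _ = pairwise_global(seg_r, seg_q, scoring)
            ref_parts.append(ga)
            qry_parts.append(gb)
        matched = ref[a_ref : anchor.ref_end]
        ref_parts.append(matched)
        qry_parts.append(matched)
        r_prev, q_prev = anchor.ref_end, anchor.qry_end
    seg_r, seg_q = ref[r_prev:], qry[q_prev:]
    if seg_r or seg_q:
        ga, gb, _ = pairwise_global(seg_r, seg_q, scoring)
        ref_parts.append(ga)
        qry_parts.append(gb)
    return "".join(ref_parts), "".join(qry_parts)


def _pair_to_profile(ref_len: int, gapped_ref: str, gapped_qry: str):
    """Decompose a pairwise alignment into per-reference-position pieces.

    Returns ``(sub, ins)``: ``sub[p]`` is the query character aligned to
    reference position ``p`` (or '-'), ``ins[p]`` the query string inserted
    immediately before reference position ``p`` (``p == ref_len`` collects a
    trailing insertion).
    """
    sub = [GAP] * ref_len
    ins: dict[int, list[str]] = defaultdict(list)
    p = 0
    for rc, qc in zip(gapped_ref, gapped_qry):
        if rc == GAP:
            ins[p].append(qc)
        else:
            if qc != GAP:
                sub[p] = qc
            p += 1
    return sub, {k: "".join(v) for k, v in ins.items()}


def build_reference_msa(
    reference: Genome,
    others: list[Genome],
    min_anchor: int = 20,
    scoring: dict | None = None,
) -> MultiAlignment:
    """Star alignment of co-linear genomes around ``reference``.

    Insertions relative to the reference at the same reference position are
    merged into one shared block, each isolate's insertion left-aligned and
    gap-padded.  The degapping invariant is asserted on every run.
    """
    if not others:
        raise ValueError("need at least one non-reference genome")
    ref_seq = reference.sequence
    profiles = {}
    for genome in others:
        gr, gq = _align_pair(ref_seq, genome.sequence, min_anchor, scoring)
        profiles[genome.id] = _pair_to_profile(len(ref_seq), gr, gq)

    ref_len = len(ref_seq)
    block_len = [0] * (ref_len + 1)
    for sub, ins in profiles.values():
        for p, s in ins.items():
            block_len[p] = max(block_len[p], len(s))

    rows: dict[str, list[str]] = {reference.id: []}
    for genome in others:
        rows[genome.id] = []
    for p in range(ref_len + 1):
        blk = block_len[p]
        if blk:
            rows[reference.id].append(GAP * blk)
            for genome in others:
                _, ins = profiles[genome.id]
                s = ins.get(p, "")
                rows[genome.id].append(s + GAP * (blk - len(s)))
        if p < ref_len:
            rows[reference.id].append(ref_seq[p])
            for genome in others:
                sub, _ = profiles[genome.id]
                rows[genome.id].append(sub[p])

    msa = MultiAlignment(
        reference_id=reference.id,
        rows={name: "".join(parts) for name, parts in rows.items()},
    )
    originals = {reference.id: ref_seq, **{g.id: g.sequence for g in others}}
    for name, seq in originals.items():
        if msa.degapped(name) != seq:
            raise AssertionError(
                f"degapping invariant violated for {name!r}"
            )
    return msa


def msa_from_rows(rows: dict[str, str], reference_id: str) -> MultiAlignment:
    """Wrap externally produced aligned rows (e.g. an imported alignment)."""
    return MultiAlignment(reference_id=reference_id, rows=dict(rows))
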