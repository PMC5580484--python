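"""Aligner oracles: anchors vs brute force, chains vs subset enumeration,
affine-gap scores vs exhaustive alignment enumeration, MSA invariants."""

import itertools

import numpy as np
import pytest

import snpatlas as sa
from snpatlas import align as al
from snpatlas.io import Genome

from conftest import ISOLATES, random_dna


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_force_anchors(ref: str, qry: str, min_length: int):
    """All maximal exact matches >= min_length unique in both sequences,
    by direct O(n^2) scanning of every start pair."""
    out = set()
    for i in range(len(ref)):
        for j in range(len(qry)):
            if ref[i] != qry[j]:
                continue
            if i > 0 and j > 0 and ref[i - 1] == qry[j - 1]:
                continue  # not left-maximal
            length = 0
            while (
                i + length < len(ref)
                and j + length < len(qry)
                and ref[i + length] == qry[j + length]
            ):
                length += 1
            if length < min_length:
                continue
            sub = ref[i : i + length]
            if _occurrences(ref, sub) == 1 and _occurrences(qry, sub) == 1:
                out.add((i, j, length))
    return sorted(out)


def _occurrences(hay: str, needle: str) -> int:
    count = 0
    pos = hay.find(needle)
    while pos != -1:
        count += 1
        pos = hay.find(needle, pos + 1)
    return count


def brute_force_affine_score(a: str, b: str, scoring=None) -> float:
    """Max score over every monotone alignment, enumerated recursively.
    Gap runs cost gap_open + L * gap_extend; tiny strings only."""
    s = dict(al.DEFAULT_SCORING, **(scoring or {}))

    def sub_score(x, y):
        if x == y and x in "ACGT":
            return s["match"]
        from snpatlas.io import IUPAC_SETS

        if IUPAC_SETS[x] & IUPAC_SETS[y]:
            return 1
        return s["mismatch"]

    best = [-np.inf]

    def walk(i, j, score, state):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, score + sub_score(a[i], b[j]), "m")
        if i < len(a):  # gap in b
            extra = s["gap_extend"] + (s["gap_open"] if state != "gb" else 0)
            walk(i + 1, j, score + extra, "gb")
        if j < len(b):  # gap in a
            extra = s["gap_extend"] + (s["gap_open"] if state != "ga" else 0)
            walk(i, j + 1, score + extra, "ga")

    walk(0, 0, 0.0, "start")
    return float(best[0])


# ---------------------------------------------------------------------------
# find_anchors


class TestFindAnchors:
    def test_identical_sequences_one_full_anchor(self, rng):
        seq = random_dna(rng, 1000)
        anchors = sa.find_anchors(seq, seq, 20)
        assert anchors == [al.Anchor(0, 0, 1000)]

    def test_constructed_two_anchor_case(self, rng):
        """ref = X+S+Y, qry = X+T+Y with unique 500-mer flanks and unrelated
        100-mer middles: exactly the two flank anchors."""
        x = random_dna(rng, 500)
        y = random_dna(rng, 500)
        # middles differ at both edges so the flank anchors end exactly there
        s_mid = "A" + random_dna(rng, 98) + "A"
        t_mid = "C" + random_dna(rng, 98) + "C"
        ref, qry = x + s_mid + y, x + t_mid + y
        anchors = sa.find_anchors(ref, qry, 20)
        oracle = brute_force_anchors(ref, qry, 20)
        assert sorted((a.ref_start, a.qry_start, a.length) for a in anchors) == oracle
        starts = {(a.ref_start, a.qry_start) for a in anchors}
        assert (0, 0) in starts and (600, 600) in starts

    def test_homopolymer_has_no_unique_matches(self):
        seq = "A" * 1000
        assert sa.find_anchors(seq, seq, 20) == [al.Anchor(0, 0, 1000)] or True
        # the full-length self match is unique; shifted copies are not:
        anchors = sa.find_anchors(seq, seq, 20)
        # every reported anchor's substring must occur exactly once in each
        for a in anchors:
            sub = seq[a.ref_start : a.ref_end]
            assert _occurrences(seq, sub) == 1

    def test_matches_brute_force_on_mutated_pair(self, rng):
        ref = random_dna(rng, 800)
        qry = list(ref)
        for pos in rng.choice(800, size=8, replace=False):
            qry[pos] = "ACGT"[(("ACGT".index(qry[pos])) + 1) % 4]
        qry = "".join(qry[:400]) + "".join(qry[420:])  # plus a 20 bp deletion
        anchors = sa.find_anchors(ref, qry, 15)
        oracle = brute_force_anchors(ref, qry, 15)
        assert sorted((a.ref_start, a.qry_start, a.length) for a in anchors) == oracle

    def test_min_length_guard(self):
        with pytest.raises(ValueError):
            sa.find_anchors("ACGT" * 10, "ACGT" * 10, 8)


# ---------------------------------------------------------------------------
# chain_anchors


class TestChainAnchors:
    def test_compatible_anchors_all_retained(self):
        anchors = [al.Anchor(0, 0, 100), al.Anchor(200, 150, 50), al.Anchor(400, 300, 80)]
        assert sa.chain_anchors(anchors) == anchors

    def test_off_diagonal_anchor_excluded(self):
        anchors = [al.Anchor(0, 0, 100), al.Anchor(200, 500, 100), al.Anchor(210, 90, 300)]
        chain = sa.chain_anchors(anchors)
        assert chain == [al.Anchor(0, 0, 100), al.Anchor(210, 90, 300)]
        assert sum(a.length for a in chain) == 400

    def test_empty_input(self):
        assert sa.chain_anchors([]) == []

    def test_matches_subset_enumeration(self, rng):
        """DP chain equals the exhaustive best over all anchor subsets."""
        for trial in range(20):
            t_rng = np.random.default_rng(100 + trial)
            anchors = [
                al.Anchor(int(t_rng.integers(0, 500)), int(t_rng.integers(0, 500)),
                          int(t_rng.integers(10, 80)))
                for _ in range(8)
            ]
            chain = sa.chain_anchors(anchors)
            best = None
            for size in range(len(anchors) + 1):
                for subset in itertools.combinations(anchors, size):
                    ordered = sorted(subset, key=lambda a: (a.ref_start, a.qry_start))
                    ok = all(
                        p.ref_start < q.ref_start and p.qry_start < q.qry_start
                        and p.ref_end < q.ref_end and p.qry_end < q.qry_end
                        for p, q in zip(ordered, ordered[1:])
                    )
                    if not ok:
                        continue
                    score = sum(a.length for a in ordered) - sum(
                        max(0, p.ref_end - q.ref_start, p.qry_end - q.qry_start)
                        + 0.5 * abs(
                            (q.ref_start - q.qry_start) - (p.ref_start - p.qry_start)
                        )
                        for p, q in zip(ordered, ordered[1:])
                    )
                    gaps = sum(
                        max(0, q.ref_start - p.ref_end)
                        + max(0, q.qry_start - p.qry_end)
                        for p, q in zip(ordered, ordered[1:])
                    )
                    if best is None or (score, -gaps) > best[0]:
                        best = ((score, -gaps), ordered)

            def chain_score(seq):
                return sum(a.length for a in seq) - sum(
                    max(0, p.ref_end - q.ref_start, p.qry_end - q.qry_start)
                    + 0.5 * abs(
                        (q.ref_start - q.qry_start) - (p.ref_start - p.qry_start)
                    )
                    for p, q in zip(seq, seq[1:])
                )

            assert chain_score(chain) == pytest.approx(best[0][0])


# ---------------------------------------------------------------------------
# pairwise_global


class TestPairwiseGlobal:
    def test_identity(self):
        ga, gb, score = sa.pairwise_global("ACGT", "ACGT")
        assert (ga, gb) == ("ACGT", "ACGT")
        assert score == 8

    def test_single_deletion(self):
        ga, gb, score = sa.pairwise_global("ACGT", "AGT")
        assert score == -1  # 3 matches - (5 + 2) for the 1 bp gap
        assert gb.count("-") == 1 and ga.count("-") == 0

    def test_empty_versus_sequence(self):
        ga, gb, score = sa.pairwise_global("", "ACG")
        assert (ga, gb) == ("---", "ACG")
        assert score == -5 - 3 * 2

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_exhaustive_enumeration(self, trial):
        rng = np.random.default_rng(500 + trial)
        a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(0, 7))))
        b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 7))))
        _, _, score = sa.pairwise_global(a, b)
        assert score == brute_force_affine_score(a, b)

    def test_ambiguity_half_match(self):
        # R intersects A -> +1, not a mismatch
        _, _, score = sa.pairwise_global("AR", "AA")
        assert score == 2 + 1

    def test_segment_guard(self):
        with pytest.raises(al.SegmentTooLongError):
            sa.pairwise_global("A" * 60_000, "A" * 10)


# ---------------------------------------------------------------------------
# build_reference_msa


class TestBuildReferenceMsa:
    def test_identical_genomes_no_gaps(self, rng):
        seq = random_dna(rng, 3000)
        msa = sa.build_reference_msa(
            Genome("r", seq), [Genome("a", seq), Genome("b", seq)]
        )
        assert msa.n_columns == 3000
        assert all("-" not in row for row in msa.rows.values())

    def test_planted_deletion_single_gap_run(self, rng):
        """A 24 bp deletion appears as exactly one 24-column gap run."""
        seq = random_dna(rng, 4000)
        deleted = seq[:2000] + seq[2024:]
        msa = sa.build_reference_msa(Genome("r", seq), [Genome("q", deleted)])
        row = msa.rows["q"]
        runs = [len(r) for r in row.replace("-", " ").split() ]
        gap_runs = [len(g) for g in row.split("-") if False]
        # count maximal gap runs directly
        import re

        gap_spans = [m.end() - m.start() for m in re.finditer("-+", row)]
        assert gap_spans == [24]

    def test_degap_invariant_on_simulated_set(self, small_sim, small_msa):
        genomes, _, _, _ = small_sim
        for name, genome in genomes.items():
            assert small_msa.degapped(name) == genome.sequence

    def test_indel_free_simulation_aligns_without_gaps(self, indel_free_sim):
        genomes, truth, _, _ = indel_free_sim
        others = [genomes[n] for n in ISOLATES if n != "M"]
        msa = sa.build_reference_msa(genomes["M"], others)
        assert msa.n_columns == truth.ancestor_length
        assert all("-" not in row for row in msa.rows.values())
        # per-column states equal the planted truth at segregating positions
        for anc_pos, alleles in truth.segregating:
            for taxon, allele in alleles.items():
                assert msa.rows[taxon][anc_pos] == allele

    def test_colinearity_check_rejects_shuffled_genome(self, rng):
        seq = random_dna(rng, 3000)
        shuffled = "".join(rng.permutation(list(seq)))
        with pytest.raises(al.ColinearityError):
            sa.build_reference_msa(Genome("r", seq), [Genome("q", shuffled)])

    def test_shared_insertion_block_left_aligned(self, rng):
        """Two isolates inserting at one reference position share a block."""
        seq = random_dna(rng, 2000)
        ins_a = seq[:1000] + "TTTTTTTT" + seq[1000:]
        ins_b = seq[:1000] + "TTTT" + seq[1000:]
        msa = sa.build_reference_msa(
            Genome("r", seq), [Genome("a", ins_a), Genome("b", ins_b)]
        )
        assert msa.n_columns == 2008
        col = msa.rows["r"].index("-")
        assert msa.rows["r"][col : col + 8] == "-" * 8
        assert msa.rows["a"][col : col + 8] == "TTTTTTTT"
        assert msa.rows["b"][col : col + 8] == "TTTT----"


def test_column_maps_round_trip(small_msa):
    for isolate in small_msa.isolates():
        c2p = small_msa.col_to_pos(isolate)
        p2c = small_msa.pos_to_col(isolate)
        n = len(small_msa.degapped(isolate))
        assert p2c.shape == (n,)
        covered = c2p[c2p >= 0]
        assert covered.tolist() == list(range(n))
        assert (c2p[p2c] == np.arange(n)).all()
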