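"""Synthetic genome evolution along a tree, with a complete planted truth.

The generator evolves a random ancestor along a user-supplied rooted tree
under a K2P-style substitution process (transition/transversion
distinction, base composition set by the ancestor's GC draw), Poisson
indels in three size classes, optional transposable-element insertions on
terminal branches, and planted repeat structure (dispersed ~75 bp inverted
repeat copies plus one tandem "major repeat region" of three large
repeats).  Every event is recorded in ancestral-frame coordinates so that
downstream callers (alignment, SNP map, phylogeny) can be scored against
the planted truth.

The defaults emulate the study system: 5 co-linear betabaculovirus isolate
genomes of ~121 kb, GC ~45.4%, evolved along a ladder tree with branch
lengths chosen so the expected number of segregating positions among the
five leaves is ~788, apportioned like the published per-branch SNP sets;
indels range from 1 bp to ~1 kb and two leaves receive ~0.7 kb
transposable elements.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Genome, FeatureRecord, parse_newick, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

#: study-condition ladder: expected substitution counts per branch on a
#: 120,816 bp ancestor, proportional to the published per-branch SNP sets
#: (M 2, I12 21, M+I12 38, E2 54, M+I12+E2 21, S 101, I07 356) scaled so the
#: expected segregating total is ~788.
_DEFAULT_BRANCH_EVENTS = {
    "M": 2.66, "I12": 27.91, "M+I12": 50.50, "E2": 71.77,
    "M+I12+E2": 27.91, "S": 134.23, "I07": 473.11,
}
DEFAULT_GENOME_LENGTH = 120_816
DEFAULT_GC = 0.4539


def default_tree(genome_length: int = DEFAULT_GENOME_LENGTH,
                 substitution_rate: float = 1.0) -> str:
    """Ladder-tree Newick with branch lengths in substitutions/site."""
    def b(name: str) -> str:
        return format(_DEFAULT_BRANCH_EVENTS[name] / (substitution_rate * genome_length), ".6g")
    return (
        f"((((M:{b('M')},I12:{b('I12')}):{b('M+I12')},E2:{b('E2')})"
        f":{b('M+I12+E2')},S:{b('S')}):0.0,I07:{b('I07')});"
    )


@dataclass
class TEInsertion:
    taxon: str
    length: int
    position_fraction: float


@dataclass
class EvolutionModel:
    """Rates and event-size laws for the simulator.

    substitution_rate and indel_rate are expected events per site per unit
    branch length; ti_tv_ratio is the transition:transversion odds at a
    mutating site; indel sizes are drawn from three classes (1 bp, 2-50 bp,
    51-1000 bp, uniform within a class) with the stated probabilities.
    """

    substitution_rate: float = 1.0
    ti_tv_ratio: float = 2.0
    indel_rate: float = 0.025
    indel_size_probs: tuple[float, float, float] = (0.4, 0.4, 0.2)
    indel_size_classes: tuple[tuple[int, int], ...] = ((1, 1), (2, 50), (51, 1000))
    te_insertions: list[TEInsertion] = field(
        default_factory=lambda: [
            TEInsertion("I12", 684, 0.165),
            TEInsertion("E2", 715, 0.186),
        ]
    )
    repeat_unit_length: int = 75
    repeat_copies: int = 13
    major_repeat_unit: int = 315
    major_repeat_copies: int = 3

    def __post_init__(self) -> None:
        if self.substitution_rate < 0 or self.indel_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.ti_tv_ratio <= 0:
            raise ValueError("ti_tv_ratio must be > 0")
        if abs(sum(self.indel_size_probs) - 1.0) > 1e-9:
            raise ValueError("indel size probabilities must sum to 1")

    @classmethod
    def from_dict(cls, data: dict) -> "EvolutionModel":
        data = dict(data)
        if "te_insertions" in data:
            data["te_insertions"] = [
                te if isinstance(te, TEInsertion) else TEInsertion(**te)
                for te in data["te_insertions"]
            ]
        if "indel_size_probs" in data:
            data["indel_size_probs"] = tuple(data["indel_size_probs"])
        return cls(**data)


@dataclass
class SubstitutionEvent:
    ancestral_position: int  # -1 if the site arose by insertion on this lineage
    branch: str
    from_base: str
    to_base: str


@dataclass
class IndelEvent:
    ancestral_position: int
    branch: str
    length: int
    kind: str  # "insertion" | "deletion"


@dataclass
class TruthTable:
    """Ground truth for parameter-recovery tests."""

    substitutions: list[SubstitutionEvent] = field(default_factory=list)
    indels: list[IndelEvent] = field(default_factory=list)
    te_records: list[tuple[str, int, int]] = field(default_factory=list)
    expected_snp_patterns: dict[str, int] = field(default_factory=dict)
    segregating: list[tuple[int, dict[str, str]]] = field(default_factory=list)
    leaf_anc_maps: dict[str, np.ndarray] = field(default_factory=dict)
    ancestor_length: int = 0

    def segregating_positions(self) -> list[int]:
        return [pos for pos, _ in self.segregating]

    def leaf_position_of(self, taxon: str, ancestral_position: int) -> int | None:
        """Map an ancestral coordinate to the leaf genome's coordinate."""
        amap = self.leaf_anc_maps[taxon]
        hits = np.flatnonzero(amap == ancestral_position)
        return int(hits[0]) if hits.size else None

    def events_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.substitutions:
            rows.append(
                dict(event="substitution", ancestral_position=s.ancestral_position,
                     branch=s.branch, detail=f"{s.from_base}>{s.to_base}", length=1)
            )
        for d in self.indels:
            rows.append(
                dict(event=d.kind, ancestral_position=d.ancestral_position,
                     branch=d.branch, detail="", length=d.length)
            )
        for taxon, pos, length in self.te_records:
            rows.append(
                dict(event="transposable_element", ancestral_position=pos,
                     branch=taxon, detail="", length=length)
            )
        return pd.DataFrame(
            rows, columns=["event", "ancestral_position", "branch", "detail", "length"]
        )


# ---------------------------------------------------------------------------


def generate_ancestor(length: int, gc_fraction: float, seed: int) -> Genome:
    """Random ancestor sequence with the requested base composition."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    draws = rng.choice(_BASES, size=length, p=p)
    return Genome("ancestor", draws.tobytes().decode())


def plant_repeats(
    genome: Genome, model: EvolutionModel, seed: int
) -> tuple[Genome, list[FeatureRecord]]:
    """Overwrite the genome with dispersed inverted-repeat copies and one
    tandem major repeat region; length is preserved and exact coordinates
    are returned."""
    records: list[FeatureRecord] = []
    if model.repeat_copies == 0:
        return genome, records
    n = len(genome)
    if n < model.repeat_copies * model.repeat_unit_length * 10:
        raise ValueError("genome too short to host the requested repeats")
    rng = np.random.default_rng(seed)
    seq = list(genome.sequence)

    unit = rng.choice(_BASES, size=model.repeat_unit_length).tobytes().decode()
    major_unit = rng.choice(_BASES, size=model.major_repeat_unit).tobytes().decode()
    major_len = model.major_repeat_unit * model.major_repeat_copies

    # place the major region first, then the dispersed copies, rejecting
    # overlaps; deterministic given the seed
    placements = []  # (start, length, what, orientation)
    wanted = [(major_len, "major")] + [
        (model.repeat_unit_length, "unit")
    ] * model.repeat_copies
    margin = 10
    for length, what in wanted:
        for _ in range(10_000):
            start = int(rng.integers(1, n - length - 1))
            if all(
                start + length + margin <= s or s + l + margin <= start
                for s, l, _, _ in placements
            ):
                break
        else:
            raise ValueError("genome too short to host the requested repeats")
        orientation = "+" if what == "major" or rng.random() < 0.5 else "-"
        placements.append((start, length, what, orientation))

    copy_index = 0
    for start, length, what, orientation in placements:
        if what == "major":
            seq[start : start + major_len] = major_unit * model.major_repeat_copies
            records.append(
                FeatureRecord(
                    "major_repeat_region", start, start + major_len, "+",
                    "major_repeat_region",
                    {"unit_length": model.major_repeat_unit,
                     "copies": model.major_repeat_copies},
                )
            )
        else:
            copy_index += 1
            copy = unit if orientation == "+" else revcomp(unit)
            seq[start : start + length] = copy
            records.append(
                FeatureRecord(
                    f"dispersed_repeat_{copy_index:02d}", start, start + length,
                    orientation, "dispersed_repeat", {"unit": "dispersed"},
                )
            )
    out = Genome(genome.id, "".join(seq), source="plant_repeats")
    return out, sorted(records, key=lambda f: f.start)


def _branch_name(node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    leaves = sorted(leaf.taxon.label for leaf in node.leaf_iter())
    return "+".join(leaves)


def evolve_on_tree(
    ancestor: Genome,
    tree,
    model: EvolutionModel,
    seed: int,
) -> tuple[dict[str, Genome], TruthTable]:
    """Evolve ``ancestor`` down a rooted tree with branch lengths.

    ``tree`` is a Newick string or a dendropy Tree.  Substitution and indel
    counts per branch are Poisson with mean rate x branch length x parent
    length; zero-length branches introduce no events.  Multiple hits across
    branches are allowed.  Returns one genome per leaf plus the truth table
    (events in ancestral-frame coordinates).
    """
    if isinstance(tree, str):
        tree = parse_newick(tree)
    leaves = [leaf for leaf in tree.leaf_node_iter()]
    if len(leaves) < 3:
        raise ValueError("tree must have >= 3 leaves")
    for leaf in leaves:
        if leaf.taxon is None or not leaf.taxon.label:
            raise ValueError("all leaves must be named")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("negative branch lengths are not allowed")

    rng = np.random.default_rng(seed)
    truth = TruthTable(ancestor_length=len(ancestor))
    root = tree.seed_node
    # per node: (sequence str, ancestral map int64 array; -1 = inserted material)
    state = {
        root: (ancestor.sequence, np.arange(len(ancestor), dtype=np.int64))
    }
    te_by_taxon: dict[str, list[TEInsertion]] = {}
    for te in model.te_insertions:
        te_by_taxon.setdefault(te.taxon, []).append(te)

    genomes: dict[str, Genome] = {}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent_seq, parent_map = state[node.parent_node]
        blen = node.edge.length or 0.0
        branch = _branch_name(node)
        seq, amap = _evolve_branch(
            parent_seq, parent_map, blen, branch, model, rng, truth
        )
        if node.is_leaf():
            taxon = node.taxon.label
            for te in te_by_taxon.get(taxon, []):
                seq, amap = _insert_te(seq, amap, te, rng, truth)
            genomes[taxon] = Genome(taxon, seq, source="simulated")
            truth.leaf_anc_maps[taxon] = amap
        else:
            state[node] = (seq, amap)

    _tabulate_segregating(truth, genomes)
    return genomes, truth


def _evolve_branch(parent_seq, parent_map, blen, branch, model, rng, truth):
    seq = parent_seq
    amap = parent_map
    n = len(seq)
    if blen > 0 and n > 0:
        n_sub = rng.poisson(model.substitution_rate * blen * n)
        n_sub = min(n_sub, n)
        chars = list(seq)
        if n_sub:
            positions = rng.choice(n, size=n_sub, replace=False)
            for pos in sorted(int(p) for p in positions):
                old = chars[pos]
                if old not in "ACGT":
                    continue
                if rng.random() < model.ti_tv_ratio / (model.ti_tv_ratio + 2):
                    new = _TRANSITION[old]
                else:
                    new = _TRANSVERSIONS[old][int(rng.integers(0, 2))]
                chars[pos] = new
                truth.substitutions.append(
                    SubstitutionEvent(int(amap[pos]), branch, old, new)
                )
        n_indel = rng.poisson(model.indel_rate * blen * n)
        indels = []
        for _ in range(n_indel):
            cls = int(rng.choice(3, p=np.asarray(model.indel_size_probs)))
            lo, hi = model.indel_size_classes[cls]
            length = int(rng.integers(lo, hi + 1))
            kind = "deletion" if rng.random() < 0.5 else "insertion"
            if kind == "deletion":
                # keep the genome ends intact
                if length >= len(chars) - 2:
                    continue
                pos = int(rng.integers(1, len(chars) - length - 1))
            else:
                pos = int(rng.integers(1, len(chars) - 1))
            indels.append((pos, length, kind))
        amap = np.asarray(amap)
        # apply right-to-left so earlier positions stay valid
        for pos, length, kind in sorted(indels, reverse=True):
            anc_pos = int(amap[pos]) if amap[pos] >= 0 else -1
            if kind == "deletion":
                del chars[pos : pos + length]
                amap = np.delete(amap, np.s_[pos : pos + length])
            else:
                insert = rng.choice(_BASES, size=length).tobytes().decode()
                chars[pos:pos] = insert
                amap = np.insert(amap, pos, np.full(length, -1, dtype=np.int64))
            truth.indels.append(IndelEvent(anc_pos, branch, length, kind))
        seq = "".join(chars)
    return seq, np.asarray(amap)


def _insert_te(seq, amap, te: TEInsertion, rng, truth: TruthTable):
    pos = max(1, min(len(seq) - 1, int(te.position_fraction * len(seq))))
    element = rng.choice(_BASES, size=te.length).tobytes().decode()
    anc_pos = int(amap[pos]) if amap[pos] >= 0 else -1
    truth.te_records.append((te.taxon, anc_pos, te.length))
    new_seq = seq[:pos] + element + seq[pos:]
    new_map = np.insert(amap, pos, np.full(te.length, -1, dtype=np.int64))
    return new_seq, new_map


def _tabulate_segregating(truth: TruthTable, genomes: dict[str, Genome]) -> None:
    """Alleles per ancestral position across leaves; a position segregates
    when every leaf still carries it and >= 2 alleles occur."""
    n_anc = truth.ancestor_length
    taxa = sorted(genomes)
    allele_grid = {}
    for taxon in taxa:
        amap = truth.leaf_anc_maps[taxon]
        seq = np.frombuffer(genomes[taxon].sequence.encode(), dtype=np.uint8)
        col = np.zeros(n_anc, dtype=np.uint8)  # 0 = deleted
        keep = amap >= 0
        col[amap[keep]] = seq[keep]
        allele_grid[taxon] = col
    grid = np.vstack([allele_grid[t] for t in taxa])
    covered = (grid != 0).all(axis=0)
    varying = (grid != grid[0]).any(axis=0)
    pattern_counts: Counter[str] = Counter()
    for pos in np.flatnonzero(covered & varying):
        alleles = {t: chr(grid[i, pos]) for i, t in enumerate(taxa)}
        truth.segregating.append((int(pos), alleles))
        by_allele: dict[str, list[str]] = {}
        for t, a in alleles.items():
            by_allele.setdefault(a, []).append(t)
        label = ";".join(
            "+".join(sorted(group))
            for _, group in sorted(
                by_allele.items(), key=lambda kv: (len(kv[1]), sorted(kv[1]))
            )
            if len(group) < len(taxa)
        )
        pattern_counts[label] += 1
    truth.expected_snp_patterns = dict(pattern_counts)


def simulate_isolate_set(
    seed: int,
    length: int = DEFAULT_GENOME_LENGTH,
    gc_fraction: float = DEFAULT_GC,
    model: EvolutionModel | None = None,
    tree: str | None = None,
) -> tuple[dict[str, Genome], TruthTable, list[FeatureRecord], str]:
    """Convenience driver: ancestor -> planted repeats -> evolution.

    Returns (leaf genomes, truth, planted repeat features in ancestral
    coordinates, the generating-tree Newick).
    """
    model = model or EvolutionModel()
    newick = tree or default_tree(length, model.substitution_rate)
    ancestor = generate_ancestor(length, gc_fraction, seed)
    ancestor, repeat_features = plant_repeats(ancestor, model, seed + 1)
    genomes, truth = evolve_on_tree(ancestor, newick, model, seed + 2)
    return genomes, truth, repeat_features, newick
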