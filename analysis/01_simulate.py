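#!/usr/bin/env python
"""Generate the synthetic five-isolate study set.

Evolves a ~121 kb, GC ~45.4% ancestor with 13 planted dispersed inverted
repeats and a 945 bp tandem major repeat region along the ladder tree
(basal I07 -> S -> E2 -> (M, I12)), with branch lengths scaled so the
expected number of segregating positions is ~788.  Writes the genomes,
the generating tree and the planted-truth event table under results/.
"""

import sys
from pathlib import Path

import snpatlas as sa
from snpatlas import io as sio

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1) -> None:
    OUT.mkdir(exist_ok=True)
    genomes, truth, planted, newick = sa.simulate_isolate_set(seed=seed)
    sio.write_fasta(OUT / "simulated_genomes.fasta", list(genomes.values()))
    sio.write_newick(OUT / "generating_tree.nwk", newick)
    sio.write_tsv(OUT / "truth_events.tsv", truth.events_frame())
    sio.write_gff3(OUT / "planted_repeats.gff3", "ancestor", planted)

    print(f"seed {seed}: {len(genomes)} genomes from a "
          f"{truth.ancestor_length:,} bp ancestor")
    for name, genome in sorted(genomes.items()):
        print(f"  {name:4s} {len(genome):>9,} bp  GC {genome.gc_percent:.2f}%")
    print(f"planted truth: {len(truth.substitutions)} substitutions, "
          f"{len(truth.indels)} indels, {len(truth.te_records)} TEs; "
          f"{len(truth.segregating)} segregating positions")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
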