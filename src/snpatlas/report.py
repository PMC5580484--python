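"""Genome summary statistics and the end-to-end pipeline driver.

``genome_summary`` computes the per-isolate feature grid (length, GC%,
coding/non-coding partition, ORF counts); ``run_pipeline`` executes the
stages simulate -> align -> orfs -> repeats -> snps -> tree -> stats on a
config mapping and writes every interface file plus a JSON run report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import align as _align
from . import io as _io
from . import orfs as _orfs
from . import phylogeny as _phylo
from . import repeats as _repeats
from . import simulate as _sim
from . import snps as _snps

log = logging.getLogger("snpatlas")

ALL_STAGES = ("simulate", "align", "orfs", "repeats", "snps", "tree", "stats")


@dataclass
class GenomeSummary:
    isolate: str
    genome_length: int
    coding_bp: int
    coding_percent: float
    noncoding_bp: int
    noncoding_percent: float
    gc_percent: float
    orf_count: int
    orfs_identical_to_reference: int | None = None


def genome_summary(genome: _io.Genome, orfs: list[_orfs.OrfRecord]) -> GenomeSummary:
    """Length, GC% (ambiguity codes excluded), coding bp as the union of
    ORF spans, and the retained ORF count.  coding + noncoding = length."""
    length = len(genome)
    mask = np.zeros(length, dtype=bool)
    count = 0
    for orf in orfs:
        if orf.status == "absent_in_isolate":
            continue
        mask[orf.start : orf.end] = True
        count += 1
    coding_bp = int(mask.sum())
    noncoding_bp = length - coding_bp
    return GenomeSummary(
        isolate=genome.id,
        genome_length=length,
        coding_bp=coding_bp,
        coding_percent=round(100.0 * coding_bp / length, 2),
        noncoding_bp=noncoding_bp,
        noncoding_percent=round(100.0 * noncoding_bp / length, 2),
        gc_percent=genome.gc_percent,
        orf_count=count,
    )


def identical_orf_count(
    query_orfs: list[_orfs.OrfRecord],
    reference_orfs: list[_orfs.OrfRecord],
    query_genome: _io.Genome,
    reference_genome: _io.Genome,
) -> int:
    """Number of same-named ORFs with identical amino-acid sequences
    (standard code, stop excluded).  Untranslatable ORFs are excluded with
    a warning."""
    ref_by_name = {o.name: o for o in reference_orfs if o.status != "absent_in_isolate"}
    count = 0
    for q in query_orfs:
        if q.status == "absent_in_isolate" or q.name not in ref_by_name:
            continue
        try:
            aa_q = _orfs.translate_orf(query_genome, q)
            aa_r = _orfs.translate_orf(reference_genome, ref_by_name[q.name])
        except ValueError as exc:
            log.warning("skipping untranslatable ORF: %s", exc)
            continue
        if aa_q == aa_r:
            count += 1
    return count


def summary_grid(summaries: list[GenomeSummary]) -> pd.DataFrame:
    """Feature-by-isolate grid of the genome summaries."""
    frame = pd.DataFrame([asdict(s) for s in summaries]).set_index("isolate").T
    frame.index.name = "genome_feature"
    return frame


# ---------------------------------------------------------------------------
# pipeline


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: dict) -> dict:
    """Execute the requested stages and write all interface files.

    Config keys (all optional unless a requested stage needs them):
    ``seed``, ``outdir``, ``stages``, ``fasta`` (input genomes),
    ``reference`` (isolate id), ``isolates`` (ordered, for SNP calling),
    ``topology`` (rooted Newick for SNP classification), ``model``
    (EvolutionModel fields), ``genome_length``, ``gc_fraction``, ``tree``
    (generating tree for simulation), ``import_alignment`` (aligned FASTA
    bypassing the aligner), ``min_anchor``, ``min_orf``, ``max_overlap``,
    ``min_repeat``, ``bootstrap``.

    Returns the run report (also written as JSON); a stage failure raises
    :class:`StageError` with partial outputs retained on disk.
    """
    seed = int(config.get("seed", 0))
    outdir = Path(config.get("outdir", "snpatlas_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", ALL_STAGES))
    report: dict = {"seed": seed, "stages": stages, "parameters": {}, "results": {}}

    genomes: dict[str, _io.Genome] = {}
    truth = None
    msa = None
    reference = config.get("reference")
    orfs_by_isolate: dict[str, list] = {}
    repeat_feats: list = []
    snp_records = None
    isolates = config.get("isolates")

    def _stage(name):
        log.info("stage %s (seed=%d)", name, seed)
        return time.time()

    try:
        if "simulate" in stages:
            t0 = _stage("simulate")
            model = _sim.EvolutionModel.from_dict(config.get("model", {}))
            length = int(config.get("genome_length", _sim.DEFAULT_GENOME_LENGTH))
            gc = float(config.get("gc_fraction", _sim.DEFAULT_GC))
            sims, truth, planted, newick = _sim.simulate_isolate_set(
                seed, length, gc, model, config.get("tree")
            )
            genomes.update(sims)
            _io.write_fasta(outdir / "simulated_genomes.fasta", list(sims.values()))
            _io.write_tsv(outdir / "truth_events.tsv", truth.events_frame())
            _io.write_newick(outdir / "generating_tree.nwk", newick)
            report["parameters"]["simulate"] = {
                "genome_length": length, "gc_fraction": gc, "tree": newick,
            }
            report["results"]["simulate"] = {
                "n_genomes": len(sims),
                "planted_repeats": len(planted),
                "truth_segregating_sites": len(truth.segregating),
                "seconds": round(time.time() - t0, 2),
            }
            if reference is None:
                reference = sorted(sims)[0]
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate", exc) from exc

    try:
        if config.get("fasta"):
            for path in (
                config["fasta"] if isinstance(config["fasta"], list) else [config["fasta"]]
            ):
                for g in _io.read_fasta(path):
                    genomes[g.id] = g
            if reference is None:
                reference = next(iter(genomes))
    except Exception as exc:  # noqa: BLE001
        raise StageError("load", exc) from exc

    if isolates is None:
        isolates = sorted(genomes)

    try:
        if "align" in stages and genomes:
            t0 = _stage("align")
            if config.get("import_alignment"):
                rows = _io.read_aligned_fasta(config["import_alignment"])
                msa = _align.msa_from_rows(rows, reference)
            else:
                others = [g for name, g in sorted(genomes.items()) if name != reference]
                msa = _align.build_reference_msa(
                    genomes[reference], others,
                    min_anchor=int(config.get("min_anchor", 20)),
                )
            _io.write_aligned_fasta(outdir / "alignment.fasta", msa.rows)
            report["results"]["align"] = {
                "n_columns": msa.n_columns,
                "reference": reference,
                "seconds": round(time.time() - t0, 2),
            }
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("align", exc) from exc

    try:
        if "repeats" in stages and genomes:
            t0 = _stage("repeats")
            ref_genome = genomes[reference]
            min_rep = int(config.get("min_repeat", 20))
            direct = _repeats.find_maximal_repeats(ref_genome, min_rep, "direct")
            inverted = _repeats.find_maximal_repeats(ref_genome, min_rep, "inverted")
            families = _repeats.cluster_dispersed_copies(direct + inverted, ref_genome)
            repeat_feats = _repeats.repeat_features(families)
            try:
                major = _repeats.delineate_major_repeat_region(
                    ref_genome, direct_repeats=direct
                )
                repeat_feats.append(major)
                major_len = len(major)
            except _repeats.NoMajorRepeatRegion:
                major_len = 0
            _io.write_gff3(outdir / "repeats.gff3", reference, repeat_feats)
            report["results"]["repeats"] = {
                "n_direct_pairs": len(direct),
                "n_inverted_pairs": len(inverted),
                "n_families": len(families),
                "dispersed_copies": max(
                    (f.n_copies for f in families if f.flags.get("dispersed")),
                    default=0,
                ),
                "major_repeat_region_bp": major_len,
                "seconds": round(time.time() - t0, 2),
            }
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("repeats", exc) from exc

    try:
        if "orfs" in stages and genomes:
            t0 = _stage("orfs")
            min_orf = int(config.get("min_orf", 150))
            max_ov = int(config.get("max_overlap", 100))
            repeat_regions = [
                f for f in repeat_feats
                if f.kind in ("dispersed_repeat", "major_repeat_region", "repeat_region")
            ]
            for name, genome in sorted(genomes.items()):
                found = _orfs.find_orfs(genome, min_orf)
                kept = _orfs.filter_orfs(
                    found, repeat_regions if name == reference else [], max_ov
                )
                orfs_by_isolate[name] = kept
            _io.write_gff3(
                outdir / "orfs_reference.gff3", reference,
                _orfs.orfs_to_features(orfs_by_isolate[reference]),
            )
            report["results"]["orfs"] = {
                name: len(kept) for name, kept in orfs_by_isolate.items()
            }
            report["results"]["orfs"]["seconds"] = round(time.time() - t0, 2)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("orfs", exc) from exc

    try:
        if "snps" in stages and msa is not None:
            t0 = _stage("snps")
            topology = config.get("topology")
            snp_records = _snps.call_snps(
                msa, isolates, topology=topology,
                repeat_features=repeat_feats or None,
            )
            if orfs_by_isolate.get(reference):
                _snps.annotate_regions(
                    snp_records, orfs_by_isolate[reference], len(genomes[reference])
                )
                coding, noncoding = _snps.snp_density(
                    snp_records, orfs_by_isolate[reference], len(genomes[reference])
                )
            else:
                coding = noncoding = None
            _io.write_tsv(outdir / "snps.tsv", _snps.snps_frame(snp_records, isolates))
            _io.write_vcf(
                outdir / "snps.vcf", reference, len(genomes[reference]),
                isolates, snp_records,
            )
            _io.write_tsv(
                outdir / "snp_categories.tsv", _snps.category_counts(snp_records)
            )
            ambiguous = sum(1 for r in snp_records if r.category[0] == "ambiguous")
            specific = sum(1 for r in snp_records if r.category[0] == "specific")
            report["results"]["snps"] = {
                "total": len(snp_records),
                "total_unambiguous": len(snp_records) - ambiguous,
                "ambiguous": ambiguous,
                "specific": specific,
                "coding_density": coding,
                "noncoding_density": noncoding,
                "seconds": round(time.time() - t0, 2),
            }
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("snps", exc) from exc

    try:
        if "tree" in stages and msa is not None:
            t0 = _stage("tree")
            n_reps = int(config.get("bootstrap", 1000))
            boot = _phylo.bootstrap_support(msa, isolates, n_reps=n_reps, seed=seed)
            outgroup = config.get("outgroup")
            newick = boot.tree.newick(supports=boot.supports, outgroup=outgroup)
            _io.write_newick(outdir / "me_tree.nwk", newick)
            D = _phylo.p_distance_matrix(msa, isolates)
            _io.write_phylip_matrix(outdir / "p_distances.phy", isolates, D.values)
            report["results"]["tree"] = {
                "newick": newick,
                "bootstrap_replicates": n_reps,
                "min_support": min(boot.supports.values()) if boot.supports else None,
                "seconds": round(time.time() - t0, 2),
            }
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("tree", exc) from exc

    try:
        if "stats" in stages and genomes:
            t0 = _stage("stats")
            summaries = []
            ref_orfs = orfs_by_isolate.get(reference, [])
            for name, genome in sorted(genomes.items()):
                iso_orfs = orfs_by_isolate.get(name, [])
                s = genome_summary(genome, iso_orfs)
                if name != reference and ref_orfs and iso_orfs:
                    s.orfs_identical_to_reference = identical_orf_count(
                        iso_orfs, ref_orfs, genome, genomes[reference]
                    )
                summaries.append(s)
            grid = summary_grid(summaries)
            grid.to_csv(outdir / "genome_summary.tsv", sep="\t")
            report["results"]["stats"] = {
                s.isolate: asdict(s) for s in summaries
            }
            report["results"]["stats"]["seconds"] = round(time.time() - t0, 2)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("stats", exc) from exc

    if truth is not None and snp_records is not None:
        called = {r.ref_position for r in snp_records}
        truth_positions = set()
        for anc_pos, _ in truth.segregating:
            ref_pos = truth.leaf_position_of(reference, anc_pos)
            if ref_pos is not None:
                truth_positions.add(ref_pos)
        recovered = len(called & truth_positions)
        report["results"]["truth_comparison"] = {
            "truth_segregating": len(truth_positions),
            "called": len(called),
            "recovered": recovered,
            "recall_percent": round(100.0 * recovered / len(truth_positions), 2)
            if truth_positions else None,
        }

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
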