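"""End-to-end pipeline: simulate -> build -> classify -> score.

Driven by a small YAML/dict config; every stage is seeded so that a rerun
with the same config is bit-identical. Outputs land in one directory with
a machine-readable manifest of parameters and seeds.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

from . import __version__
from .classifier import (
    NormalizationConfig,
    ThresholdTable,
    classify_reads,
    write_assignments_tsv,
    write_profile_tsv,
)
from .evaluation import score, truth_leaf_taxa
from .refdb import build_index, save_index, split_genome
from .seqio import write_fasta, write_truth_tsv
from .synthetic import make_collection, make_leaveout, simulate_reads

log = logging.getLogger("tetrabin.pipeline")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "taxonomy": {
        "n_phyla": 4,
        "classes_per_phylum": 2,
        "orders_per_class": 2,
        "families_per_order": 2,
        "genera_per_family": 2,
    },
    "genomes": {"length": 200_000, "divergence_per_rank": 0.30},
    "reads": {"n": 2000, "length": 800, "error_rate": 0.0},
    "removals": [],
    "index": {
        "k": None,
        "strand": "forward",
        "fragment_length": 1000,
        "min_fragment_length": 500,
    },
    "classify": {"tau": 0.80, "epsilon": 0.01, "a": "auto"},
}


def _merged(config: dict[str, Any] | None) -> dict[str, Any]:
    out = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in (config or {}).items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key].update(value)
        else:
            out[key] = value
    return out


def run_pipeline(config: dict[str, Any] | None, out_dir: str | Path) -> dict[str, Any]:
    """Run all stages, write artifacts under ``out_dir``, return the manifest."""
    cfg = _merged(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    log.info("stage=simulate seed=%d taxonomy=%s", seed, cfg["taxonomy"])
    collection = make_collection(
        seed=seed,
        genome_length=int(cfg["genomes"]["length"]),
        divergence_per_rank=float(cfg["genomes"]["divergence_per_rank"]),
        **cfg["taxonomy"],
    )
    removals = [tuple(r) for r in cfg["removals"]]
    if removals:
        collection = make_leaveout(collection, removals)
    reads, truth = simulate_reads(
        collection.genomes,
        n_reads=int(cfg["reads"]["n"]),
        read_length=int(cfg["reads"]["length"]),
        error_rate=float(cfg["reads"]["error_rate"]),
        seed=seed + 1,
    )
    status = {rid: collection.representation_status(gid) for rid, gid in truth.items()}
    tree = collection.taxonomy
    write_fasta(sorted(collection.genomes.items()), out_dir / "genomes.fasta")
    tree.to_lineage_tsv(out_dir / "lineage.tsv")
    write_fasta(reads, out_dir / "reads.fasta")
    write_truth_tsv(truth, tree, out_dir / "truth.tsv", representation_status=status)
    with (out_dir / "removals.tsv").open("w") as fh:
        fh.write("rank\ttaxon_id\n")
        for rank, tid in removals:
            fh.write(f"{rank}\t{tid}\n")

    log.info("stage=build n_genomes=%d removed=%d", len(collection.genomes), len(collection.excluded_genomes))
    icfg = cfg["index"]
    excluded = collection.excluded_genomes
    fragments = []
    for genome_id in sorted(collection.genomes):
        if genome_id in excluded:
            continue
        fragments.extend(
            split_genome(
                genome_id,
                collection.genomes[genome_id],
                fragment_length=int(icfg["fragment_length"]),
                min_fragment_length=int(icfg["min_fragment_length"]),
                taxon_id=tree.genome_to_taxon[genome_id],
                strand=icfg["strand"],
            )
        )
    index = build_index(
        fragments,
        tree,
        k=icfg["k"],
        seed=seed,
        strand=icfg["strand"],
        fragment_length=int(icfg["fragment_length"]),
        min_fragment_length=int(icfg["min_fragment_length"]),
    )
    save_index(index, out_dir / "index")

    log.info("stage=classify n_reads=%d k=%d", len(reads), index.k)
    ccfg = cfg["classify"]
    a = ccfg["a"]
    norm = NormalizationConfig(a=None if a in ("auto", None) else int(a))
    assignments, profile = classify_reads(
        reads,
        index,
        tree,
        thresholds=ThresholdTable.default(),
        cfg=norm,
        tau=float(ccfg["tau"]),
        epsilon=float(ccfg["epsilon"]),
    )
    write_assignments_tsv(assignments, tree, out_dir / "assignments.tsv")
    write_profile_tsv(profile, tree, out_dir / "profile.tsv")

    log.info("stage=score assigned=%d unassigned=%d too_short=%d",
             profile.n_assigned, profile.n_unassigned, profile.n_too_short)
    report = score(assignments, truth_leaf_taxa(truth, tree), tree, representation_status=status)
    report.write_tsv(out_dir / "report.tsv")
    report.write_json(out_dir / "report.json")

    manifest = {
        "version": __version__,
        "config": cfg,
        "n_fragments": index.n_fragments,
        "k": index.k,
        "n_reads": len(reads),
        "report": report.as_dict(),
        "outputs": sorted(p.name for p in out_dir.iterdir()),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
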