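"""Shared fixtures: hand-built taxonomies and seeded synthetic collections.

The expensive collections and indexes are session-scoped so the whole
suite pays for genome simulation and k-means once.
"""

from __future__ import annotations

import pytest
from hypothesis import settings

from tetrabin.refdb import build_index, split_genome

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from tetrabin.synthetic import make_collection, make_leaveout, simulate_reads
from tetrabin.taxonomy import TaxonNode, TaxonomyTree


@pytest.fixture(scope="session")
def tiny_tree() -> TaxonomyTree:
    """Two superkingdoms; one branch is rank-complete, the other skips
    family and order (genus directly under a class)."""
    nodes = {
        "root": TaxonNode("root", "root", "root", None),
        "sk1": TaxonNode("sk1", "SK-one", "superkingdom", "root"),
        "sk2": TaxonNode("sk2", "SK-two", "superkingdom", "root"),
        "p1": TaxonNode("p1", "P-one", "phylum", "sk1"),
        "c1": TaxonNode("c1", "C-one", "class", "p1"),
        "o1": TaxonNode("o1", "O-one", "order", "c1"),
        "f1": TaxonNode("f1", "F-one", "family", "o1"),
        "g1": TaxonNode("g1", "G-one", "genus", "f1"),
        "g2": TaxonNode("g2", "G-two", "genus", "f1"),
        "s1": TaxonNode("s1", "S-one", "species", "g1"),
        # sparse branch: genus g3 hangs directly under class c2 (no family/order)
        "p2": TaxonNode("p2", "P-two", "phylum", "sk2"),
        "c2": TaxonNode("c2", "C-two", "class", "p2"),
        "g3": TaxonNode("g3", "G-three", "genus", "c2"),
    }
    genome_map = {"gen1": "g1", "gen2": "g2", "gen3": "g3"}
    return TaxonomyTree(nodes=nodes, genome_to_taxon=genome_map)


def _fragments(collection, excluded=frozenset()):
    tree = collection.taxonomy
    out = []
    for gid in sorted(collection.genomes):
        if gid in excluded:
            continue
        out.extend(
            split_genome(
                gid, collection.genomes[gid], taxon_id=tree.genome_to_taxon[gid]
            )
        )
    return out


@pytest.fixture(scope="session")
def small_collection():
    """16 genera x 50 kb: 800 fragments, builds in under a second."""
    return make_collection(
        seed=11,
        n_phyla=2,
        classes_per_phylum=2,
        orders_per_class=1,
        families_per_order=2,
        genera_per_family=2,
        genome_length=50_000,
    )


@pytest.fixture(scope="session")
def small_fragments(small_collection):
    return _fragments(small_collection)


@pytest.fixture(scope="session")
def small_index(small_collection, small_fragments):
    return build_index(small_fragments, small_collection.taxonomy, seed=11)


@pytest.fixture(scope="session")
def small_index_k1(small_collection, small_fragments):
    return build_index(small_fragments, small_collection.taxonomy, k=1, seed=11)


@pytest.fixture(scope="session")
def toy_collection():
    """The default study conditions: 64 genera, one 200 kb genome each."""
    return make_collection(seed=1)


@pytest.fixture(scope="session")
def toy_index(toy_collection):
    return build_index(_fragments(toy_collection), toy_collection.taxonomy, seed=1)


@pytest.fixture(scope="session")
def toy_reads(toy_collection):
    """2,000 error-free 800 bp reads from in-database genomes."""
    return simulate_reads(toy_collection.genomes, 2000, 800, 0.0, seed=2)


@pytest.fixture(scope="session")
def leaveout_setup(toy_collection):
    """Four genera (one per phylum) removed from the reference; 500 reads
    drawn from the removed genomes only."""
    removals = [("genus", f"genus__p{i}.c0.o0.f0.g0") for i in range(4)]
    lo = make_leaveout(toy_collection, removals)
    excluded = lo.excluded_genomes
    index = build_index(
        _fragments(lo, excluded), toy_collection.taxonomy, seed=1
    )
    lo_genomes = {g: toy_collection.genomes[g] for g in excluded}
    reads, truth = simulate_reads(lo_genomes, 500, 800, 0.0, seed=3)
    return lo, index, reads, truth
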