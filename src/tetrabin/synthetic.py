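"""Synthetic genomes, taxonomies, and reads for offline pipeline runs.

Genomes are drawn from order-3 Markov chains so their 4-mer statistics are
directly controlled. A root chain is perturbed recursively down a balanced
taxonomy, so the expected compositional (Manhattan) distance between two
genomes grows with the rank of their lowest common ancestor — the
compositional signal the classifier exploits. Reads are uniform substrings
on either strand with i.i.d. substitution errors; there is no indel or
quality model, which keeps truth bookkeeping exact.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

import numpy as np

from .taxonomy import RANK_POS, TaxonNode, TaxonomyTree
from .composition import reverse_complement

DEFAULT_DIVERGENCE = 0.30
DEFAULT_GENOME_LENGTH = 200_000

#: the four read-length classes emulating common sequencing technologies
READ_LENGTH_CLASSES = (800, 400, 250, 100)

_BASES = "ACGT"


@dataclass
class CompositionModel:
    """Order-``order`` Markov chain over {A,C,G,T}.

    ``transition_weights`` has shape (4**order, 4); each row is the
    conditional next-base distribution for one context and sums to 1.
    """

    transition_weights: np.ndarray
    order: int = 3
    label: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.transition_weights, dtype=np.float64)
        if w.shape != (4**self.order, 4):
            raise ValueError(f"weights must have shape ({4**self.order}, 4)")
        if (w <= 0).any():
            raise ValueError("transition weights must be positive")
        self.transition_weights = w / w.sum(axis=1, keepdims=True)


def uniform_model(order: int = 3, label: str = "uniform") -> CompositionModel:
    return CompositionModel(
        transition_weights=np.full((4**order, 4), 0.25), order=order, label=label
    )


def stationary_tetramer_distribution(model: CompositionModel) -> np.ndarray:
    """Stationary 4-mer distribution of an order-3 chain (length-256 vector).

    Solves for the stationary distribution over 3-mer contexts and extends
    it by one transition step. Serves as the analytic oracle for what
    empirical 4-mer frequencies converge to on long simulated genomes.
    """
    if model.order != 3:
        raise ValueError("stationary 4-mer distribution implemented for order 3 only")
    n_ctx = 64
    w = model.transition_weights
    T = np.zeros((n_ctx, n_ctx))
    for ctx in range(n_ctx):
        for b in range(4):
            T[ctx, (ctx % 16) * 4 + b] += w[ctx, b]
    vals, vecs = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi) / np.abs(pi).sum()
    out = np.zeros(256)
    for ctx in range(n_ctx):
        for b in range(4):
            out[ctx * 4 + b] = pi[ctx] * w[ctx, b]
    return out


def simulate_genome(model: CompositionModel, length: int, seed: int) -> str:
    """Draw one sequence of ``length`` bases from the chain; seeded."""
    if length < model.order + 1:
        raise ValueError(f"length must be >= order+1 = {model.order + 1}")
    rng = random.Random(seed)
    order = model.order
    shift = 4 ** (order - 1)
    cum = np.cumsum(model.transition_weights, axis=1)
    rows = [(row[0], row[1], row[2]) for row in cum]
    out = []
    ctx = 0
    for _ in range(order):
        b = rng.randrange(4)
        out.append(b)
        ctx = ctx * 4 + b
    rand = rng.random
    for _ in range(length - order):
        c0, c1, c2 = rows[ctx]
        u = rand()
        b = 0 if u < c0 else 1 if u < c1 else 2 if u < c2 else 3
        out.append(b)
        ctx = (ctx % shift) * 4 + b
    return "".join(_BASES[b] for b in out)


# ------------------------------------------------------------------- taxonomy

_SHAPE_RANKS = ("phylum", "class", "order", "family", "genus")


def make_taxonomy(
    n_phyla: int = 4,
    classes_per_phylum: int = 2,
    orders_per_class: int = 2,
    families_per_order: int = 2,
    genera_per_family: int = 2,
    seed: int = 0,
) -> TaxonomyTree:
    """Balanced rank-complete toy taxonomy with deterministic path names.

    One superkingdom under the root; genus names look like
    ``p0.c0.o0.f0.g0``. The ``seed`` only fixes reproducibility of the
    (already deterministic) construction.
    """
    counts = {
        "phylum": n_phyla,
        "class": classes_per_phylum,
        "order": orders_per_class,
        "family": families_per_order,
        "genus": genera_per_family,
    }
    if any(c < 1 for c in counts.values()):
        raise ValueError("all shape counts must be >= 1")
    nodes: dict[str, TaxonNode] = {
        "root": TaxonNode("root", "root", "root", None),
        "superkingdom__sk0": TaxonNode("superkingdom__sk0", "sk0", "superkingdom", "root"),
    }
    genome_to_taxon: dict[str, str] = {}

    def grow(parent_id: str, parent_name: str, depth: int) -> None:
        rank = _SHAPE_RANKS[depth]
        letter = rank[0]
        for i in range(counts[rank]):
            name = f"{parent_name}.{letter}{i}" if parent_name else f"{letter}{i}"
            tid = f"{rank}__{name}"
            nodes[tid] = TaxonNode(tid, name, rank, parent_id)
            if rank == "genus":
                genome_to_taxon[f"{name}.genome"] = tid
            else:
                grow(tid, name, depth + 1)

    grow("superkingdom__sk0", "", 0)
    return TaxonomyTree(nodes=nodes, genome_to_taxon=genome_to_taxon)


def derive_clade_models(
    tree: TaxonomyTree,
    divergence_per_rank: float = DEFAULT_DIVERGENCE,
    seed: int = 0,
    order: int = 3,
) -> dict[str, CompositionModel]:
    """One Markov model per genus, diverging along the taxonomy.

    Starting from a near-uniform root chain, each child clade multiplies
    its parent's transition weights by lognormal noise (sigma =
    ``divergence_per_rank``) and renormalizes. Compositional distance
    between two genera therefore accumulates with the number of tree edges
    separating them, i.e. grows with the rank of their lowest common
    ancestor.
    """
    if divergence_per_rank < 0:
        raise ValueError("divergence_per_rank must be non-negative")
    rng = np.random.default_rng(seed)
    root_w = rng.dirichlet(np.full(4, 30.0), size=4**order)
    models: dict[str, np.ndarray] = {tree.root_id: root_w}
    children: dict[str, list[str]] = {}
    for node in tree.nodes.values():
        if node.parent_id is not None:
            children.setdefault(node.parent_id, []).append(node.taxon_id)
    out: dict[str, CompositionModel] = {}
    stack = [tree.root_id]
    while stack:
        tid = stack.pop()
        w = models[tid]
        for child in sorted(children.get(tid, []), reverse=True):
            if divergence_per_rank == 0:
                cw = w.copy()
            else:
                noise = np.exp(rng.normal(0.0, divergence_per_rank, size=w.shape))
                cw = w * noise
                cw /= cw.sum(axis=1, keepdims=True)
            models[child] = cw
            node = tree.nodes[child]
            if node.rank == "genus":
                out[child] = CompositionModel(
                    transition_weights=cw, order=order, label=node.name
                )
            else:
                stack.append(child)
    return out


# ----------------------------------------------------------------- collection


@dataclass
class SimulatedCollection:
    """A toy study: taxonomy, genomes, their models, and any removed clades.

    ``removed_clades`` lists (rank, taxon_id) subtrees whose genomes are
    excluded from index building while still present in the taxonomy (and
    available as read sources), emulating query sequences from organisms
    unrepresented in the reference database.
    """

    taxonomy: TaxonomyTree
    genomes: dict[str, str]
    models: dict[str, CompositionModel] = field(default_factory=dict)
    truth: dict[str, str] = field(default_factory=dict)  # read_id -> genome_id
    removed_clades: list[tuple[str, str]] = field(default_factory=list)

    @property
    def excluded_genomes(self) -> set[str]:
        removed_ids = {tid for _, tid in self.removed_clades}
        out = set()
        for genome_id, leaf in self.taxonomy.genome_to_taxon.items():
            lineage_ids = {tid for _, tid in self.taxonomy.lineage(leaf)}
            if lineage_ids & removed_ids:
                out.add(genome_id)
        return out

    def representation_status(self, genome_id: str) -> str:
        """'known', or '<rank>_unknown' at the coarsest removed rank
        covering this genome's lineage."""
        leaf = self.taxonomy.genome_to_taxon[genome_id]
        lineage_ids = {tid for _, tid in self.taxonomy.lineage(leaf)}
        worst: str | None = None
        for rank, tid in self.removed_clades:
            if tid in lineage_ids:
                if worst is None or RANK_POS[rank] > RANK_POS[worst]:
                    worst = rank
        return "known" if worst is None else f"{worst}_unknown"


def make_collection(
    seed: int = 0,
    n_phyla: int = 4,
    classes_per_phylum: int = 2,
    orders_per_class: int = 2,
    families_per_order: int = 2,
    genera_per_family: int = 2,
    genome_length: int = DEFAULT_GENOME_LENGTH,
    divergence_per_rank: float = DEFAULT_DIVERGENCE,
) -> SimulatedCollection:
    """Default toy study: 64 genera (4x2x2x2x2), one 200 kb genome each.

    Each genome is a forward-sampled half followed by its reverse
    complement. Real prokaryotic genomes carry coding sequence on both
    strands and obey Chargaff's second parity rule, so both orientations
    of a clade's composition appear among its reference fragments; a
    single-strand Markov draw would lack that property and strand-forward
    4-mer counting would then see reverse-strand reads as alien.
    """
    tree = make_taxonomy(
        n_phyla, classes_per_phylum, orders_per_class, families_per_order,
        genera_per_family, seed=seed,
    )
    models = derive_clade_models(tree, divergence_per_rank, seed=seed)
    rng = np.random.default_rng(seed)
    genomes: dict[str, str] = {}
    for genome_id in sorted(tree.genome_to_taxon):
        genus = tree.genome_to_taxon[genome_id]
        genome_seed = int(rng.integers(0, 2**31 - 1))
        half = simulate_genome(models[genus], genome_length - genome_length // 2, genome_seed)
        genomes[genome_id] = (half + reverse_complement(half))[:genome_length]
    return SimulatedCollection(taxonomy=tree, genomes=genomes, models=models)


# ---------------------------------------------------------------------- reads


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    """Independent uniform substitutions at ``error_rate`` per base."""
    if error_rate == 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(arr.size) < error_rate)
    if hit.size == 0:
        return seq
    base_idx = np.zeros(arr.size, dtype=np.int64)
    for i, b in enumerate(_BASES):
        base_idx[arr == ord(b)] = i
    new_idx = (base_idx[hit] + 1 + rng.integers(0, 3, size=hit.size)) % 4
    lut = np.frombuffer(_BASES.encode("ascii"), dtype=np.uint8)
    arr[hit] = lut[new_idx]
    return arr.tobytes().decode("ascii")


def simulate_reads(
    genomes: dict[str, str],
    n_reads: int,
    read_length: int,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Draw reads uniformly over genomes, positions, and strands.

    Returns (reads, truth) where reads are (read_id, sequence) pairs and
    truth maps read_id to the source genome. Substitution errors are
    i.i.d. per base; no indels.
    """
    if not genomes:
        raise ValueError("no genomes to sample from")
    if not (0 <= error_rate < 1):
        raise ValueError("error_rate must be in [0, 1)")
    ids = sorted(genomes)
    for gid in ids:
        if read_length > len(genomes[gid]):
            raise ValueError(
                f"read length {read_length} exceeds genome {gid} "
                f"({len(genomes[gid])} bp)"
            )
    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str]] = []
    truth: dict[str, str] = {}
    width = max(5, len(str(n_reads)))
    for i in range(n_reads):
        gid = ids[int(rng.integers(0, len(ids)))]
        genome = genomes[gid]
        pos = int(rng.integers(0, len(genome) - read_length + 1))
        seq = genome[pos : pos + read_length]
        if rng.integers(0, 2):
            seq = reverse_complement(seq)
        seq = _apply_errors(seq, error_rate, rng)
        read_id = f"read{i:0{width}d}"
        reads.append((read_id, seq))
        truth[read_id] = gid
    return reads, truth


def make_leaveout(
    collection: SimulatedCollection, removals: list[tuple[str, str]]
) -> SimulatedCollection:
    """Mark clades as absent from the reference while keeping their reads.

    ``removals`` are (rank, taxon_id) pairs that must exist in the
    taxonomy at the stated rank. Removing every genome is an error — the
    index would be empty.
    """
    for rank, tid in removals:
        node = collection.taxonomy.nodes.get(tid)
        if node is None or node.rank != rank:
            raise ValueError(f"removal ({rank}, {tid}) not found in taxonomy")
    out = replace(collection, removed_clades=list(removals))
    if len(out.excluded_genomes) >= len(collection.genomes):
        raise ValueError("removals would exclude every genome from the index")
    return out
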