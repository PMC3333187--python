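"""Reference taxonomy: rank ladder, lineages, and rank reduction.

The taxonomy is a rooted tree over the eight-rank ladder

    species < genus < family < order < class < phylum < superkingdom < root

Lineages may skip ranks (as NCBI lineages routinely do) but never invert
them. The root absorbs both "root" and "cellular organisms"-style top
nodes; assignments are never reported at root.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

RANKS = (
    "species",
    "genus",
    "family",
    "order",
    "class",
    "phylum",
    "superkingdom",
    "root",
)
RANK_POS = {r: i for i, r in enumerate(RANKS)}
#: reportable ranks, most specific first (root excluded)
LADDER = RANKS[:-1]
#: column order of the lineage TSV, least specific first
TSV_RANKS = ("superkingdom", "phylum", "class", "order", "family", "genus", "species")

ROOT_ID = "root"


def next_higher_rank(rank: str) -> str | None:
    """Successor on the ladder; ``superkingdom`` (and ``root``) map to None."""
    if rank not in RANK_POS:
        raise ValueError(f"unknown rank {rank!r}")
    if rank in ("superkingdom", "root"):
        return None
    return RANKS[RANK_POS[rank] + 1]


@dataclass(frozen=True)
class TaxonNode:
    taxon_id: str
    name: str
    rank: str
    parent_id: str | None


@dataclass
class TaxonomyTree:
    """Rooted, rank-labeled taxonomy with genome-to-leaf mapping."""

    nodes: dict[str, TaxonNode]
    genome_to_taxon: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        roots = [n for n in self.nodes.values() if n.parent_id is None]
        if len(roots) != 1 or roots[0].rank != "root":
            raise ValueError("taxonomy must have exactly one parentless root node")
        self._root_id = roots[0].taxon_id
        limit = len(self.nodes) + 1
        for node in self.nodes.values():
            if node.rank not in RANK_POS:
                raise ValueError(f"unknown rank {node.rank!r} on {node.taxon_id}")
            cur, steps = node, 0
            while cur.parent_id is not None:
                parent = self.nodes.get(cur.parent_id)
                if parent is None:
                    raise ValueError(f"{cur.taxon_id} has unknown parent {cur.parent_id}")
                if RANK_POS[parent.rank] <= RANK_POS[cur.rank]:
                    raise ValueError(
                        f"rank inversion: {cur.taxon_id} ({cur.rank}) under "
                        f"{parent.taxon_id} ({parent.rank})"
                    )
                cur = parent
                steps += 1
                if steps > limit:
                    raise ValueError("cycle detected in taxonomy")
        for genome_id, taxon_id in self.genome_to_taxon.items():
            if taxon_id not in self.nodes:
                raise ValueError(f"genome {genome_id} maps to unknown taxon {taxon_id}")

    @property
    def root_id(self) -> str:
        return self._root_id

    def node(self, taxon_id: str) -> TaxonNode:
        try:
            return self.nodes[taxon_id]
        except KeyError:
            raise KeyError(f"unknown taxon_id {taxon_id!r}") from None

    def lineage(self, taxon_id: str) -> list[tuple[str, str]]:
        """Ordered (rank, taxon_id) pairs from the node itself up to root."""
        node = self.node(taxon_id)
        out = [(node.rank, node.taxon_id)]
        while node.parent_id is not None:
            node = self.nodes[node.parent_id]
            out.append((node.rank, node.taxon_id))
        return out

    def reduce_to_rank(self, taxon_id: str, rank: str) -> str | None:
        """Ancestor (or self) at exactly ``rank``; None if the lineage skips it."""
        if rank not in RANK_POS:
            raise ValueError(f"unknown rank {rank!r}")
        for r, tid in self.lineage(taxon_id):
            if r == rank:
                return tid
            if RANK_POS[r] > RANK_POS[rank]:
                return None
        return None

    def bucket_at(self, taxon_id: str, rank: str) -> str:
        """Taxon bucket at ``rank``: the node at that rank, or — when the
        lineage skips it — the nearest present ancestor above it.

        Used for both the database representation table and the per-read
        proportions so a rank-sparse lineage is never dropped from the
        convergence count.
        """
        if rank not in RANK_POS:
            raise ValueError(f"unknown rank {rank!r}")
        target = RANK_POS[rank]
        for r, tid in self.lineage(taxon_id):
            if RANK_POS[r] >= target:
                return tid
        return self._root_id

    # ------------------------------------------------------------------ IO

    @classmethod
    def from_lineage_tsv(cls, path: str | Path) -> "TaxonomyTree":
        """Load from a flat lineage table.

        UTF-8, tab-separated, header row ``genome_id`` + the seven named
        ranks; empty fields mark skipped ranks. Taxon ids are synthesized
        as ``{rank}__{name}``, so names must be unique within a rank.
        """
        path = Path(path)
        nodes: dict[str, TaxonNode] = {
            ROOT_ID: TaxonNode(ROOT_ID, "root", "root", None)
        }
        genome_to_taxon: dict[str, str] = {}
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            if reader.fieldnames is None or "genome_id" not in reader.fieldnames:
                raise ValueError(f"{path}: missing header with genome_id column")
            for row in reader:
                parent = ROOT_ID
                leaf = ROOT_ID
                for rank in TSV_RANKS:
                    name = (row.get(rank) or "").strip()
                    if not name:
                        continue
                    tid = f"{rank}__{name}"
                    existing = nodes.get(tid)
                    if existing is None:
                        nodes[tid] = TaxonNode(tid, name, rank, parent)
                    elif existing.parent_id != parent:
                        raise ValueError(
                            f"{path}: taxon {name!r} at rank {rank} appears with "
                            "two different parents"
                        )
                    parent = tid
                    leaf = tid
                genome_to_taxon[row["genome_id"].strip()] = leaf
        return cls(nodes=nodes, genome_to_taxon=genome_to_taxon)

    def to_lineage_tsv(self, path: str | Path) -> None:
        """Write the genome lineage table (inverse of :meth:`from_lineage_tsv`)."""
        path = Path(path)
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(("genome_id",) + TSV_RANKS)
            for genome_id in sorted(self.genome_to_taxon):
                by_rank = dict(self.lineage(self.genome_to_taxon[genome_id]))
                writer.writerow(
                    [genome_id]
                    + [self.nodes[by_rank[r]].name if r in by_rank else "" for r in TSV_RANKS]
                )

    @classmethod
    def from_ncbi_dump(
        cls,
        nodes_path: str | Path,
        names_path: str | Path,
        genome_map: Mapping[str, str],
    ) -> "TaxonomyTree":
        """Load from NCBI-style nodes.dmp / names.dmp files.

        Only ranks on the eight-rank ladder are kept; nodes at other ranks
        (no rank, strain, tribe, ...) are collapsed by re-parenting their
        descendants to the nearest ladder-rank ancestor. The NCBI root and
        "cellular organisms" collapse into the single root node.
        ``genome_map`` maps genome ids to NCBI tax ids (as strings).
        """
        raw_parent: dict[str, str] = {}
        raw_rank: dict[str, str] = {}
        for fields in _iter_dmp(nodes_path):
            tax_id, parent_id, rank = fields[0], fields[1], fields[2]
            raw_parent[tax_id] = parent_id
            raw_rank[tax_id] = rank
        names: dict[str, str] = {}
        for fields in _iter_dmp(names_path):
            if len(fields) >= 4 and fields[3] == "scientific name":
                names[fields[0]] = fields[1]

        def ladder_ancestor(tax_id: str) -> str:
            seen = 0
            cur = raw_parent.get(tax_id)
            while cur is not None:
                if cur == raw_parent.get(cur):  # NCBI root points at itself
                    return ROOT_ID
                if raw_rank.get(cur) in LADDER:
                    return cur
                cur = raw_parent.get(cur)
                seen += 1
                if seen > len(raw_parent) + 1:
                    raise ValueError("cycle detected in nodes.dmp")
            return ROOT_ID

        nodes: dict[str, TaxonNode] = {
            ROOT_ID: TaxonNode(ROOT_ID, "root", "root", None)
        }
        for tax_id, rank in raw_rank.items():
            if rank in LADDER:
                nodes[tax_id] = TaxonNode(
                    tax_id, names.get(tax_id, tax_id), rank, ladder_ancestor(tax_id)
                )
        genome_to_taxon = {}
        for genome_id, tax_id in genome_map.items():
            if tax_id not in nodes:
                raise ValueError(f"genome {genome_id}: tax id {tax_id} not on the ladder")
            genome_to_taxon[genome_id] = tax_id
        return cls(nodes=nodes, genome_to_taxon=genome_to_taxon)


def _iter_dmp(path: str | Path) -> Iterable[list[str]]:
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.endswith("\t|"):
                line = line[:-2]
            yield [f.strip() for f in line.split("\t|\t")]
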