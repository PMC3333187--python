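"""Clustered reference fragment database.

Reference genomes are split into consecutive non-overlapping 1,000 bp
fragments, each summarized as a tetranucleotide frequency vector. The
fragment vectors are clustered with k-means so that, at query time, only
the members of the compositionally nearest cluster need exact distance
evaluation. The index also carries, for every rank, the percentage of
database fragments under each taxon — the representation table used to
correct database bias during classification.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .composition import N_KMERS, KmerVector, tetra_vector
from .errors import IndexFormatError, InvariantError
from .taxonomy import LADDER, TaxonomyTree

FORMAT_TAG = "tetrabin-index-1"

DEFAULT_FRAGMENT_LENGTH = 1000
DEFAULT_MIN_FRAGMENT_LENGTH = 500
MAX_AUTO_K = 2048


@dataclass
class Fragment:
    """One reference-genome window and its composition profile."""

    fragment_id: str
    genome_id: str
    start: int
    end: int
    vector: KmerVector
    taxon_id: str


def split_genome(
    genome_id: str,
    seq: str,
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
    min_fragment_length: int = DEFAULT_MIN_FRAGMENT_LENGTH,
    taxon_id: str = "",
    strand: str = "forward",
) -> list[Fragment]:
    """Split one sequence record into consecutive non-overlapping fragments.

    Windows are [0, L), [L, 2L), ...; a trailing window shorter than
    ``min_fragment_length`` is discarded, as are (rare) windows with no
    valid 4-mer window at all (e.g. runs of Ns).
    """
    if not (fragment_length >= min_fragment_length >= 4):
        raise ValueError("need fragment_length >= min_fragment_length >= 4")
    out: list[Fragment] = []
    for start in range(0, len(seq), fragment_length):
        end = min(start + fragment_length, len(seq))
        if end - start < min_fragment_length:
            break
        vec = tetra_vector(seq[start:end], strand=strand)
        if vec.n_counted == 0:
            continue
        out.append(
            Fragment(
                fragment_id=f"{genome_id}|{start}-{end}",
                genome_id=genome_id,
                start=start,
                end=end,
                vector=vec,
                taxon_id=taxon_id,
            )
        )
    return out


@dataclass
class FragmentIndex:
    """Clustered database of reference fragments.

    ``vectors`` is the (N, 256) matrix of fragment compositions,
    ``centroids`` the (k, 256) cluster means, ``membership`` the cluster
    label per fragment, and ``representation[rank][taxon_id]`` the
    percentage of all fragments bucketed under that taxon at that rank.
    """

    fragment_ids: list[str]
    genome_ids: list[str]
    starts: np.ndarray
    ends: np.ndarray
    taxon_ids: list[str]
    vectors: np.ndarray
    k: int
    centroids: np.ndarray
    membership: np.ndarray
    representation: dict[str, dict[str, float]]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.fragment_ids)
        if not (
            len(self.genome_ids) == len(self.taxon_ids) == n
            and self.vectors.shape == (n, N_KMERS)
            and self.membership.shape == (n,)
            and self.centroids.shape == (self.k, N_KMERS)
        ):
            raise InvariantError("inconsistent index array shapes")

    @property
    def n_fragments(self) -> int:
        return len(self.fragment_ids)

    def fragment(self, i: int) -> Fragment:
        return Fragment(
            fragment_id=self.fragment_ids[i],
            genome_id=self.genome_ids[i],
            start=int(self.starts[i]),
            end=int(self.ends[i]),
            vector=KmerVector(values=self.vectors[i], n_counted=int(self.ends[i] - self.starts[i])),
            taxon_id=self.taxon_ids[i],
        )

    def cluster_members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.membership == cluster)


def default_k(n_fragments: int) -> int:
    """sqrt(N) heuristic, capped, balancing centroid scan vs in-cluster scan."""
    return min(MAX_AUTO_K, max(1, math.isqrt(n_fragments)))


def build_index(
    fragments: Sequence[Fragment],
    tree: TaxonomyTree,
    k: int | None = None,
    seed: int = 0,
    strand: str = "forward",
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
    min_fragment_length: int = DEFAULT_MIN_FRAGMENT_LENGTH,
) -> FragmentIndex:
    """Cluster fragment vectors and assemble the searchable index.

    Deterministic for a fixed seed (k-means++ initialization, Lloyd
    iterations, recorded in metadata). Centroids are the coordinate-wise
    means of their members. The representation table is computed at every
    ladder rank from fragment counts, with rank-sparse lineages bucketed
    under their nearest present ancestor.
    """
    n = len(fragments)
    if n == 0:
        raise ValueError("cannot build an index from zero fragments")
    if k is None:
        k = default_k(n)
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    vectors = np.stack([f.vector.values for f in fragments])

    if k == 1:
        membership = np.zeros(n, dtype=np.intp)
    else:
        km = KMeans(
            n_clusters=k,
            init="k-means++",
            n_init=1,
            max_iter=300,
            algorithm="lloyd",
            random_state=seed,
        )
        membership = km.fit_predict(vectors).astype(np.intp)
    centroids = np.empty((k, N_KMERS))
    for c in range(k):
        members = membership == c
        if not members.any():
            raise InvariantError(f"k-means produced an empty cluster ({c})")
        centroids[c] = vectors[members].mean(axis=0)

    taxon_ids = [f.taxon_id for f in fragments]
    representation: dict[str, dict[str, float]] = {}
    for rank in LADDER:
        counts: dict[str, int] = {}
        for tid in taxon_ids:
            bucket = tree.bucket_at(tid, rank)
            counts[bucket] = counts.get(bucket, 0) + 1
        representation[rank] = {t: 100.0 * c / n for t, c in counts.items()}

    return FragmentIndex(
        fragment_ids=[f.fragment_id for f in fragments],
        genome_ids=[f.genome_id for f in fragments],
        starts=np.array([f.start for f in fragments], dtype=np.int64),
        ends=np.array([f.end for f in fragments], dtype=np.int64),
        taxon_ids=taxon_ids,
        vectors=vectors,
        k=k,
        centroids=centroids,
        membership=membership,
        representation=representation,
        metadata={
            "format": FORMAT_TAG,
            "k": int(k),
            "seed": int(seed),
            "strand": strand,
            "fragment_length": int(fragment_length),
            "min_fragment_length": int(min_fragment_length),
            "n_fragments": int(n),
        },
    )


def save_index(index: FragmentIndex, path: str | Path) -> None:
    """Persist an index as a self-describing directory.

    JSON metadata plus flat .npy arrays and a fragment provenance TSV; no
    database dependency, loadable with :func:`load_index`.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "meta.json").write_text(json.dumps(index.metadata, indent=2, sort_keys=True))
    np.save(path / "vectors.npy", index.vectors)
    np.save(path / "centroids.npy", index.centroids)
    np.save(path / "membership.npy", index.membership)
    with (path / "fragments.tsv").open("w", encoding="utf-8") as fh:
        fh.write("fragment_id\tgenome_id\tstart\tend\ttaxon_id\n")
        for i in range(index.n_fragments):
            fh.write(
                f"{index.fragment_ids[i]}\t{index.genome_ids[i]}\t"
                f"{int(index.starts[i])}\t{int(index.ends[i])}\t{index.taxon_ids[i]}\n"
            )
    (path / "representation.json").write_text(
        json.dumps(index.representation, indent=2, sort_keys=True)
    )


def load_index(path: str | Path) -> FragmentIndex:
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.is_file():
        raise IndexFormatError(f"{path}: not an index directory (meta.json missing)")
    try:
        metadata = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise IndexFormatError(f"{path}: corrupt meta.json") from exc
    if metadata.get("format") != FORMAT_TAG:
        raise IndexFormatError(
            f"{path}: unsupported index format {metadata.get('format')!r} "
            f"(expected {FORMAT_TAG!r})"
        )
    try:
        vectors = np.load(path / "vectors.npy")
        centroids = np.load(path / "centroids.npy")
        membership = np.load(path / "membership.npy")
        representation = json.loads((path / "representation.json").read_text())
        fragment_ids, genome_ids, taxon_ids = [], [], []
        starts, ends = [], []
        with (path / "fragments.tsv").open(encoding="utf-8") as fh:
            header = fh.readline()
            if not header.startswith("fragment_id\t"):
                raise IndexFormatError(f"{path}: bad fragments.tsv header")
            for line in fh:
                fid, gid, start, end, tid = line.rstrip("\n").split("\t")
                fragment_ids.append(fid)
                genome_ids.append(gid)
                starts.append(int(start))
                ends.append(int(end))
                taxon_ids.append(tid)
    except (OSError, ValueError) as exc:
        raise IndexFormatError(f"{path}: corrupt or incomplete index") from exc
    index = FragmentIndex(
        fragment_ids=fragment_ids,
        genome_ids=genome_ids,
        starts=np.array(starts, dtype=np.int64),
        ends=np.array(ends, dtype=np.int64),
        taxon_ids=taxon_ids,
        vectors=vectors,
        k=int(metadata["k"]),
        centroids=centroids,
        membership=membership.astype(np.intp),
        representation=representation,
        metadata=metadata,
    )
    if index.n_fragments != metadata.get("n_fragments"):
        raise IndexFormatError(f"{path}: fragment count mismatch against metadata")
    return index
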