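"""Per-read taxonomic classification.

For each read the classifier:

1. finds the cluster whose centroid is nearest (Manhattan distance) to the
   read's tetranucleotide vector, evaluates exact distances to that
   cluster's fragments, and retains every fragment within ~1% of the
   minimum distance (the "closest subset");
2. converts the minimum distance and read length into the most specific
   rank at which assignment may be made (the threshold table);
3. computes the taxon proportions of the closest subset at that rank and
   damps over-represented taxa with a logarithmic normalization against
   the database representation table;
4. assigns the read to the taxon whose normalized proportion crosses the
   convergence threshold, escalating to successively coarser ranks until
   convergence or, failing even at superkingdom, reporting the read as
   unassigned.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping

import numpy as np
import yaml
from scipy.spatial.distance import cdist

from .composition import KmerVector, tetra_vector
from .errors import ConfigMismatchError
from .refdb import Fragment, FragmentIndex
from .taxonomy import LADDER, RANK_POS, TaxonomyTree, next_higher_rank

DEFAULT_TAU = 0.80
DEFAULT_EPSILON = 0.01

# ----------------------------------------------------------------- thresholds

#: read-length classes, named after the sequencing technologies whose
#: nominal lengths they cover
LENGTH_CLASSES = ("sanger", "titanium_400", "standard_250", "gs20_100")

#: lower length bound per class, checked in order
_CLASS_BOUNDS = (
    (600, "sanger"),
    (300, "titanium_400"),
    (150, "standard_250"),
    (0, "gs20_100"),
)


@dataclass(frozen=True)
class ThresholdTable:
    """Distance-to-rank mapping per read-length class.

    For each class, ``cuts`` are strictly increasing distance boundaries
    and ``ranks`` (one longer) strictly coarsen: a distance d maps to
    ``ranks[i]`` where i is the number of cuts <= d, so boundary values
    resolve to the less specific rank.
    """

    classes: Mapping[str, tuple[tuple[float, ...], tuple[str, ...]]]

    def __post_init__(self) -> None:
        for name, (cuts, ranks) in self.classes.items():
            if len(ranks) != len(cuts) + 1:
                raise ValueError(f"{name}: need one more rank than cuts")
            if list(cuts) != sorted(set(cuts)):
                raise ValueError(f"{name}: cuts must strictly increase")
            pos = [RANK_POS[r] for r in ranks]
            if pos != sorted(set(pos)) or any(r not in LADDER for r in ranks):
                raise ValueError(f"{name}: ranks must strictly coarsen along the ladder")

    @staticmethod
    def default() -> "ThresholdTable":
        return ThresholdTable(
            classes={
                "sanger": ((0.28, 0.32), ("genus", "family", "class")),
                "titanium_400": ((0.35, 0.41), ("genus", "family", "class")),
                "standard_250": ((0.43, 0.51), ("genus", "family", "class")),
                "gs20_100": ((0.6,), ("genus", "family")),
            }
        )

    @staticmethod
    def class_for_length(read_length: int) -> str:
        for lower, name in _CLASS_BOUNDS:
            if read_length >= lower:
                return name
        raise ValueError("unreachable")  # pragma: no cover

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ThresholdTable":
        """Load an override table: ``{class: {cuts: [...], ranks: [...]}}``."""
        raw = yaml.safe_load(Path(path).read_text())
        classes = {}
        for name, entry in raw.items():
            if name not in LENGTH_CLASSES:
                raise ValueError(f"unknown read-length class {name!r}")
            classes[name] = (tuple(float(c) for c in entry["cuts"]), tuple(entry["ranks"]))
        missing = set(LENGTH_CLASSES) - set(classes)
        if missing:
            raise ValueError(f"threshold table missing classes: {sorted(missing)}")
        return cls(classes=classes)


def determine_level(d_min: float, read_length: int, thresholds: ThresholdTable) -> str:
    """Most specific rank permitted for a read at distance ``d_min``."""
    if d_min < 0:
        raise ValueError("d_min must be non-negative")
    cls = ThresholdTable.class_for_length(read_length)
    cuts, ranks = thresholds.classes[cls]
    return ranks[bisect.bisect_right(cuts, d_min)]


# -------------------------------------------------------------- normalization

#: per-class default damping weight: 0 for the shortest reads (their raw
#: proportions are already noisy and damping would amplify that), 2 otherwise
DEFAULT_A = {"sanger": 2, "titanium_400": 2, "standard_250": 2, "gs20_100": 0}


def _log_damp(p: np.ndarray, r: np.ndarray, a: int) -> np.ndarray:
    return p / (1.0 + a * np.log10(1.0 + r))


#: pluggable normalization forms: f(P, R, a) -> unnormalized weights
FORMULAS: dict[str, Callable[[np.ndarray, np.ndarray, int], np.ndarray]] = {
    "log_damp": _log_damp,
}


@dataclass(frozen=True)
class NormalizationConfig:
    """Database-representation damping settings.

    ``a`` is the integer damping weight; ``None`` selects the per-class
    default at classification time. ``a = 0`` makes normalization the
    identity on proportions.
    """

    a: int | None = None
    formula_id: str = "log_damp"

    def resolve(self, length_class: str) -> "NormalizationConfig":
        a = DEFAULT_A[length_class] if self.a is None else self.a
        return replace(self, a=a)


@dataclass
class TaxonProportions:
    """Taxon composition of a closest subset at one rank.

    ``P`` are raw percentages within the subset, ``R`` database
    representation percentages, ``N`` normalized percentages (None until
    :func:`normalize_proportions` runs). All percentage vectors sum to 100.
    """

    rank: str
    taxon_ids: tuple[str, ...]
    P: np.ndarray
    R: np.ndarray
    N: np.ndarray | None = None

    @property
    def entries(self) -> dict[str, tuple[float, float, float | None]]:
        return {
            t: (float(self.P[i]), float(self.R[i]), None if self.N is None else float(self.N[i]))
            for i, t in enumerate(self.taxon_ids)
        }


# ----------------------------------------------------------------- assignment


@dataclass
class Assignment:
    """Outcome of classifying one read."""

    read_id: str
    status: str  # assigned | unassigned | too_short
    taxon_id: str | None = None
    rank: str | None = None
    d_min: float | None = None
    tl: str | None = None
    subset_size: int = 0
    winning_N: float | None = None


def closest_subset(
    index: FragmentIndex, q: KmerVector, epsilon: float = DEFAULT_EPSILON
) -> tuple[float, list[Fragment]]:
    """Nearest-cluster scan and closest-subset selection.

    Picks the cluster with the nearest centroid, computes exact distances
    to its members, and retains every fragment with d <= d_min/(1-epsilon)
    — i.e. within ~1% of the closest fragment. With d_min = 0 exactly the
    zero-distance fragments are retained.
    """
    if index.n_fragments == 0:
        raise ValueError("empty index")
    if q.n_counted == 0:
        raise ValueError("query vector has no counted windows")
    if not (0 <= epsilon < 1):
        raise ValueError("epsilon must be in [0, 1)")
    qv = q.values[np.newaxis, :]
    cluster = int(np.argmin(cdist(qv, index.centroids, metric="cityblock")[0]))
    members = index.cluster_members(cluster)
    dists = cdist(qv, index.vectors[members], metric="cityblock")[0]
    d_min = float(dists.min())
    cutoff = d_min / (1.0 - epsilon)
    keep = members[dists <= cutoff]
    return d_min, [index.fragment(int(i)) for i in keep]


def proportions_at(
    fragments: list[Fragment],
    rank: str,
    tree: TaxonomyTree,
    index: FragmentIndex,
) -> TaxonProportions:
    """Taxon proportions of a fragment subset at ``rank``.

    Each fragment's leaf taxon is bucketed at the rank (rank-sparse
    lineages fall to their nearest present ancestor); R comes from the
    index representation table under the same bucketing.
    """
    if not fragments:
        raise ValueError("fragment subset must be non-empty")
    counts: dict[str, int] = {}
    for frag in fragments:
        bucket = tree.bucket_at(frag.taxon_id, rank)
        counts[bucket] = counts.get(bucket, 0) + 1
    taxa = tuple(sorted(counts))
    total = len(fragments)
    p = np.array([100.0 * counts[t] / total for t in taxa])
    r = np.array([index.representation[rank][t] for t in taxa])
    return TaxonProportions(rank=rank, taxon_ids=taxa, P=p, R=r)


def normalize_proportions(
    p: TaxonProportions, cfg: NormalizationConfig
) -> TaxonProportions:
    """Damp over-represented taxa and renormalize to 100."""
    if cfg.a is None:
        raise ValueError("NormalizationConfig.a unresolved; call cfg.resolve(length_class)")
    if cfg.a < 0:
        raise ValueError("damping weight a must be non-negative")
    if cfg.a == 0:
        # damping weight zero: normalization is the identity on proportions
        n = p.P.copy()
    else:
        formula = FORMULAS[cfg.formula_id]
        weights = formula(p.P, p.R, cfg.a)
        n = 100.0 * weights / weights.sum()
    return TaxonProportions(rank=p.rank, taxon_ids=p.taxon_ids, P=p.P, R=p.R, N=n)


#: tolerance for declaring two normalized percentages an exact tie
_TIE_EPS = 1e-9


def assign(
    read_id: str,
    q: KmerVector,
    read_length: int,
    index: FragmentIndex,
    tree: TaxonomyTree,
    thresholds: ThresholdTable | None = None,
    cfg: NormalizationConfig | None = None,
    tau: float = DEFAULT_TAU,
    epsilon: float = DEFAULT_EPSILON,
) -> Assignment:
    """Classify one read; see the module docstring for the procedure.

    Ties on the winning normalized proportion escalate to the next rank
    rather than breaking arbitrarily; convergence only at the root is
    reported as unassigned.
    """
    if thresholds is None:
        thresholds = ThresholdTable.default()
    if cfg is None:
        cfg = NormalizationConfig()
    if q.n_counted == 0:
        return Assignment(read_id=read_id, status="too_short")
    d_min, frags = closest_subset(index, q, epsilon=epsilon)
    tl = determine_level(d_min, read_length, thresholds)
    cfg = cfg.resolve(ThresholdTable.class_for_length(read_length))
    rank: str | None = tl
    while rank is not None:
        props = normalize_proportions(proportions_at(frags, rank, tree, index), cfg)
        assert props.N is not None
        best = int(np.argmax(props.N))
        best_n = float(props.N[best])
        if best_n >= 100.0 * tau - _TIE_EPS:
            tied = np.flatnonzero(props.N >= best_n - _TIE_EPS)
            winner = props.taxon_ids[best]
            if len(tied) == 1 and winner != tree.root_id:
                return Assignment(
                    read_id=read_id,
                    status="assigned",
                    taxon_id=winner,
                    rank=rank,
                    d_min=d_min,
                    tl=tl,
                    subset_size=len(frags),
                    winning_N=best_n,
                )
        rank = next_higher_rank(rank)
    return Assignment(
        read_id=read_id,
        status="unassigned",
        d_min=d_min,
        tl=tl,
        subset_size=len(frags),
    )


# ------------------------------------------------------------------ streaming


class TaxonomicProfile:
    """Cumulative per-taxon assignment counts.

    An assignment at a rank increments its taxon and every ancestor on the
    lineage up to superkingdom, so counts at coarse ranks accumulate those
    from finer ones.
    """

    def __init__(self) -> None:
        self.counts: dict[str, dict[str, int]] = {r: {} for r in LADDER}
        self.n_assigned = 0
        self.n_unassigned = 0
        self.n_too_short = 0

    def add(self, assignment: Assignment, tree: TaxonomyTree) -> None:
        if assignment.status == "too_short":
            self.n_too_short += 1
            return
        if assignment.status != "assigned":
            self.n_unassigned += 1
            return
        self.n_assigned += 1
        assert assignment.taxon_id is not None and assignment.rank is not None
        floor = RANK_POS[assignment.rank]
        for r, tid in tree.lineage(assignment.taxon_id):
            if r == "root" or RANK_POS[r] < floor:
                continue
            bucket = self.counts[r]
            bucket[tid] = bucket.get(tid, 0) + 1

    @property
    def total(self) -> int:
        return self.n_assigned + self.n_unassigned + self.n_too_short


def classify_reads(
    reads: Iterable[tuple[str, str]],
    index: FragmentIndex,
    tree: TaxonomyTree,
    thresholds: ThresholdTable | None = None,
    cfg: NormalizationConfig | None = None,
    tau: float = DEFAULT_TAU,
    epsilon: float = DEFAULT_EPSILON,
    strand: str | None = None,
) -> tuple[list[Assignment], TaxonomicProfile]:
    """Classify a stream of (read_id, sequence) pairs, order-preserving.

    The strand mode is taken from the index metadata; passing an explicit
    conflicting ``strand`` raises :class:`ConfigMismatchError` — vectors
    counted under different strand modes are not comparable.
    """
    index_strand = index.metadata.get("strand", "forward")
    if strand is not None and strand != index_strand:
        raise ConfigMismatchError(
            f"index was built with strand={index_strand!r}; cannot classify "
            f"with strand={strand!r}"
        )
    assignments: list[Assignment] = []
    profile = TaxonomicProfile()
    for read_id, seq in reads:
        q = tetra_vector(seq, strand=index_strand)
        a = assign(
            read_id,
            q,
            read_length=len(seq),
            index=index,
            tree=tree,
            thresholds=thresholds,
            cfg=cfg,
            tau=tau,
            epsilon=epsilon,
        )
        assignments.append(a)
        profile.add(a, tree)
    return assignments, profile


# ------------------------------------------------------------------ reporting

ASSIGNMENT_COLUMNS = (
    "read_id",
    "status",
    "rank",
    "taxon_name",
    "taxon_id",
    "d_min",
    "tl",
    "subset_size",
    "winning_N",
)

PROFILE_COLUMNS = (
    "rank",
    "taxon_name",
    "taxon_id",
    "cumulative_count",
    "percent_of_assigned",
)


def _fmt(x: float | None) -> str:
    return "" if x is None else f"{x:.6f}"


def assignment_rows(assignments: Iterable[Assignment], tree: TaxonomyTree) -> Iterator[list[str]]:
    for a in assignments:
        name = tree.nodes[a.taxon_id].name if a.taxon_id else ""
        yield [
            a.read_id,
            a.status,
            a.rank or "",
            name,
            a.taxon_id or "",
            _fmt(a.d_min),
            a.tl or "",
            str(a.subset_size),
            _fmt(a.winning_N),
        ]


def profile_rows(profile: TaxonomicProfile, tree: TaxonomyTree) -> Iterator[list[str]]:
    denom = max(profile.n_assigned, 1)
    for rank in reversed(LADDER):  # superkingdom first
        for tid in sorted(profile.counts[rank]):
            count = profile.counts[rank][tid]
            yield [
                rank,
                tree.nodes[tid].name,
                tid,
                str(count),
                f"{100.0 * count / denom:.4f}",
            ]


def write_assignments_tsv(
    assignments: Iterable[Assignment], tree: TaxonomyTree, path: str | Path
) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(ASSIGNMENT_COLUMNS) + "\n")
        for row in assignment_rows(assignments, tree):
            fh.write("\t".join(row) + "\n")


def write_profile_tsv(
    profile: TaxonomicProfile, tree: TaxonomyTree, path: str | Path
) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(PROFILE_COLUMNS) + "\n")
        for row in profile_rows(profile, tree):
            fh.write("\t".join(row) + "\n")
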