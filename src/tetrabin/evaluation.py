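"""Scoring of assignments against a read truth table.

An assignment is *correct* when the assigned taxon lies anywhere on the
read's true lineage (the classifier is free to stop at a coarse rank);
*wrong* when it is off-lineage; *unassigned* covers both unassigned and
too-short reads. Correct assignments split into *specific* (phylum or
below) and *non-specific* (above phylum, i.e. superkingdom).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .classifier import Assignment
from .taxonomy import RANK_POS, TaxonomyTree

_SPECIFIC_CEILING = RANK_POS["phylum"]

CATEGORIES = ("correct", "wrong", "unassigned", "specific", "non_specific")


@dataclass
class EvaluationReport:
    total: int = 0
    correct: int = 0
    wrong: int = 0
    unassigned: int = 0
    specific: int = 0
    non_specific: int = 0
    #: representation status (known / genus_unknown / ...) -> category counts
    by_status: dict[str, dict[str, int]] = field(default_factory=dict)

    def percentages(self) -> dict[str, float]:
        denom = max(self.total, 1)
        return {c: 100.0 * getattr(self, c) / denom for c in CATEGORIES}

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            **{c: getattr(self, c) for c in CATEGORIES},
            "percentages": self.percentages(),
            "by_status": self.by_status,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2, sort_keys=True))

    def write_tsv(self, path: str | Path) -> None:
        pct = self.percentages()
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("status\tcategory\tcount\tpercent\n")
            fh.write(f"all\ttotal\t{self.total}\t100.0000\n")
            for c in CATEGORIES:
                fh.write(f"all\t{c}\t{getattr(self, c)}\t{pct[c]:.4f}\n")
            for status in sorted(self.by_status):
                counts = self.by_status[status]
                for c in CATEGORIES:
                    fh.write(f"{status}\t{c}\t{counts.get(c, 0)}\t\n")


def score(
    assignments: Iterable[Assignment],
    truth: Mapping[str, str],
    tree: TaxonomyTree,
    representation_status: Mapping[str, str] | None = None,
) -> EvaluationReport:
    """Score assignments against ``truth`` (read_id -> true leaf taxon_id).

    ``representation_status`` optionally maps read_id to a label such as
    ``known`` or ``genus_unknown`` for a per-status breakdown. A read in
    ``assignments`` missing from ``truth`` is an error.
    """
    report = EvaluationReport()
    lineage_cache: dict[str, frozenset[str]] = {}
    for a in assignments:
        if a.read_id not in truth:
            raise KeyError(f"read {a.read_id!r} missing from truth table")
        leaf = truth[a.read_id]
        report.total += 1
        if a.status != "assigned":
            cat = "unassigned"
        else:
            ids = lineage_cache.get(leaf)
            if ids is None:
                ids = frozenset(tid for _, tid in tree.lineage(leaf))
                lineage_cache[leaf] = ids
            if a.taxon_id in ids:
                cat = "correct"
                assert a.rank is not None
                sub = "specific" if RANK_POS[a.rank] <= _SPECIFIC_CEILING else "non_specific"
                setattr(report, sub, getattr(report, sub) + 1)
            else:
                cat = "wrong"
        setattr(report, cat, getattr(report, cat) + 1)
        if representation_status is not None:
            status = representation_status.get(a.read_id, "known")
            counts = report.by_status.setdefault(status, {})
            counts[cat] = counts.get(cat, 0) + 1
            if cat == "correct":
                counts[sub] = counts.get(sub, 0) + 1
    return report


def truth_leaf_taxa(
    truth_genomes: Mapping[str, str], tree: TaxonomyTree
) -> dict[str, str]:
    """Convert a read->genome truth table to read->leaf-taxon."""
    return {rid: tree.genome_to_taxon[gid] for rid, gid in truth_genomes.items()}
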