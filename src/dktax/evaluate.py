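"""Accuracy scoring at a taxonomic rank.

Reads are put into one of five categories per evaluation level:

* TP — assigned to the right taxon at the evaluated level or below;
* VP (species level only) — correct at genus level but carrying no
  species-level information (e.g. an *Escherichia coli* read assigned to
  the genus *Escherichia*);
* FP — assigned outside the true lineage at the evaluated level;
* FN — unclassified (or uninformative without conflicting);
* TN — unclassified while the truth is genuinely absent from the
  database (only tallied when the database taxon set is supplied; TN is
  not used by any metric below).

Metrics:
    D-rate = (TP + FP + VP) / TOTAL
    SEN    = TP / (TP + FP + VP + FN)
    PRE    = TP / (TP + FP)
    F1     = 2 · SEN · PRE / (SEN + PRE)

TOTAL is the number of input reads, classified plus unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import UnknownTaxidError
from .taxonomy import TaxonomyTree

CATEGORIES = ("TP", "VP", "FP", "FN", "TN")


@dataclass
class EvalCounts:
    level: str
    tp: int = 0
    vp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.vp + self.fp + self.fn + self.tn

    def add(self, category: str) -> None:
        setattr(self, category.lower(), getattr(self, category.lower()) + 1)


@dataclass
class Metrics:
    d_rate: float
    sensitivity: float
    precision: float
    f1: float
    degenerate: bool = False  # a zero denominator was hit


def categorize(
    assigned_taxid: int | None,
    true_taxid: int,
    level: str,
    tree: TaxonomyTree,
    db_taxids: set[int] | None = None,
) -> str:
    """Place one read into TP/VP/FP/FN/TN at ``level`` ('genus'|'species')."""
    if true_taxid not in tree:
        raise UnknownTaxidError(f"true taxid {true_taxid} not in taxonomy")
    true_at_level = tree.ancestor_at_rank(true_taxid, level)
    if true_at_level is None:
        raise UnknownTaxidError(
            f"true taxid {true_taxid} has no ancestor at rank {level!r}"
        )
    if assigned_taxid is None:
        if db_taxids is not None and not _truth_in_db(true_taxid, db_taxids, tree):
            return "TN"
        return "FN"
    if assigned_taxid not in tree:
        raise UnknownTaxidError(f"assigned taxid {assigned_taxid} not in taxonomy")

    assigned_at_level = tree.ancestor_at_rank(assigned_taxid, level)
    if assigned_at_level is not None:
        return "TP" if assigned_at_level == true_at_level else "FP"

    # assignment sits above the evaluated level: correct-but-uninformative
    if level == "species":
        true_genus = tree.ancestor_at_rank(true_taxid, "genus")
        assigned_genus = tree.ancestor_at_rank(assigned_taxid, "genus")
        if assigned_genus is not None and assigned_genus == true_genus:
            return "VP"
        if assigned_genus is not None:
            return "FP"
    # e.g. a family-level call at genus evaluation: FP when it conflicts
    # with the truth's lineage, otherwise uninformative -> FN
    return "FN" if assigned_taxid in tree.lineage(true_taxid) else "FP"


def _truth_in_db(true_taxid: int, db_taxids: set[int], tree: TaxonomyTree) -> bool:
    return any(node in db_taxids for node in tree.lineage(true_taxid)[:-1])


def metrics(counts: EvalCounts) -> Metrics:
    """Evaluate the four printed formulas; zero denominators yield 0 and
    set the ``degenerate`` flag."""
    degenerate = False

    def ratio(num: int, den: int) -> float:
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    d_rate = ratio(counts.tp + counts.fp + counts.vp, counts.total)
    sen = ratio(counts.tp, counts.tp + counts.fp + counts.vp + counts.fn)
    pre = ratio(counts.tp, counts.tp + counts.fp)
    if sen + pre > 0:
        f1 = 2 * sen * pre / (sen + pre)
    else:
        degenerate = True
        f1 = 0.0
    return Metrics(d_rate, sen, pre, f1, degenerate)


def evaluate_assignments(
    assignments: dict[str, int | None],
    truth: dict[str, int],
    tree: TaxonomyTree,
    level: str,
    db_taxids: set[int] | None = None,
) -> tuple[EvalCounts, Metrics]:
    """Score a read_id -> assigned-taxid map (None = unclassified) against
    a read_id -> true-taxid map.  Reads missing from ``assignments`` count
    as unclassified."""
    counts = EvalCounts(level=level)
    for read_id, true_taxid in truth.items():
        assigned = assignments.get(read_id)
        counts.add(categorize(assigned, true_taxid, level, tree, db_taxids))
    return counts, metrics(counts)
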