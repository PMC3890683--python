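"""Leave-one-out molecular identification under five criteria.

Every ingroup sequence is used once as a query against all remaining
ingroup sequences (the outgroup is never a query nor a candidate match).
Similarity-based criteria work on the K2P distance matrix:

* BM (best match): the query is correct when its nearest neighbour(s)
  are all conspecific, incorrect when the tied nearest set is a single
  other species, ambiguous when the tie spans more than one species.
* BCM (best close match): as BM, but a best distance above the threshold
  is a no-match.
* ASB (all species barcodes): within the threshold, correct only when
  every conspecific outranks every allospecific; an allospecific closer
  than the furthest conspecific makes the query ambiguous; a whole other
  species closer than all conspecifics is incorrect.

Tree-based criteria work on the rooted NJ tree:

* NJT: a species whose sequences form an exclusive clade is correct (all
  its sequences); multiple placements are incorrect; singletons ambiguous.
* NJT_M: judged per sequence one node up: correct inside an exclusively
  conspecific cluster or polytomy, incorrect one node into an allospecific
  cluster (two or more allospecific leaves), ambiguous for singletons,
  single-sister cherries and mixed polytomies.

Singleton species (one ingroup sequence) can never be correct under any
criterion — they have no conspecific to match.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .distances import DistanceMatrix
from .seqio import BarcodeDataset

__all__ = [
    "CRITERIA",
    "OUTCOMES",
    "Verdict",
    "IdentificationReport",
    "UndefinedQueryError",
    "best_match",
    "best_close_match",
    "all_species_barcodes",
    "njt_classify",
    "njt_m_classify",
    "evaluate_dataset",
    "tally_percentages",
]

CRITERIA = ("NJT", "NJT_M", "BM", "BCM", "ASB")
OUTCOMES = ("correct", "ambiguous", "incorrect", "no_match")

#: Absolute tolerance within which two distances count as an exact tie.
TIE_TOL = 1e-12


class UndefinedQueryError(ValueError):
    """A query has no defined distance to any reference sequence."""


@dataclass(frozen=True)
class Verdict:
    """Outcome for one query under one criterion.

    ``best_distance``/``matched_species`` are set for similarity criteria
    only. ``unthresholded_outcome`` carries the BM outcome regardless of
    the threshold, which the confusion classification needs to split
    discarded queries into false and true negatives.
    """

    query_id: str
    criterion: str
    outcome: str
    best_distance: float | None = None
    matched_species: frozenset[str] = field(default_factory=frozenset)
    unthresholded_outcome: str | None = None

    def __post_init__(self) -> None:
        if self.criterion not in CRITERIA:
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.outcome == "no_match" and self.criterion not in ("BCM", "ASB"):
            raise ValueError(f"{self.criterion} cannot produce no_match")


def _query_distances(
    query_id: str, m: DistanceMatrix, dataset: BarcodeDataset
) -> tuple[list[str], np.ndarray, str]:
    """Defined distances from the query to every other ingroup sequence."""
    species = dataset.species_of()
    refs, dists = [], []
    for sid in dataset.specimen_ids:
        if sid == query_id or sid in dataset.outgroup_ids:
            continue
        d = m.get(query_id, sid)
        if not math.isnan(d):
            refs.append(sid)
            dists.append(d)
    if not refs:
        raise UndefinedQueryError(
            f"query {query_id!r} has no defined distance to any reference"
        )
    return refs, np.asarray(dists), species[query_id]


def _bm_outcome(tied_species: set[str], query_species: str) -> str:
    if tied_species == {query_species}:
        return "correct"
    if query_species in tied_species or len(tied_species) > 1:
        return "ambiguous"
    return "incorrect"  # a single allospecific species


def best_match(
    query_id: str,
    m: DistanceMatrix,
    dataset: BarcodeDataset,
    tie_tol: float = TIE_TOL,
) -> Verdict:
    """Best-match (BM) verdict for one query."""
    refs, dists, query_species = _query_distances(query_id, m, dataset)
    species = dataset.species_of()
    best = float(dists.min())
    tied = {species[refs[i]] for i in np.nonzero(dists <= best + tie_tol)[0]}
    outcome = _bm_outcome(tied, query_species)
    return Verdict(
        query_id=query_id,
        criterion="BM",
        outcome=outcome,
        best_distance=best,
        matched_species=frozenset(tied),
        unthresholded_outcome=outcome,
    )


def best_close_match(
    query_id: str,
    m: DistanceMatrix,
    dataset: BarcodeDataset,
    threshold: float,
    tie_tol: float = TIE_TOL,
) -> Verdict:
    """Best-close-match (BCM) verdict: BM gated by the distance threshold."""
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    bm = best_match(query_id, m, dataset, tie_tol=tie_tol)
    outcome = "no_match" if bm.best_distance > threshold else bm.outcome
    return Verdict(
        query_id=query_id,
        criterion="BCM",
        outcome=outcome,
        best_distance=bm.best_distance,
        matched_species=bm.matched_species,
        unthresholded_outcome=bm.outcome,
    )


def all_species_barcodes(
    query_id: str,
    m: DistanceMatrix,
    dataset: BarcodeDataset,
    threshold: float,
    tie_tol: float = TIE_TOL,
) -> Verdict:
    """All-species-barcodes (ASB) verdict for one query.

    Within the threshold: correct when all conspecifics strictly precede
    all allospecifics in the ranked match list; incorrect when some other
    species' sequences are all strictly closer than every conspecific;
    otherwise ambiguous. A singleton query with an in-threshold match is
    ambiguous (it has no conspecifics whose ranking could be checked).
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    refs, dists, query_species = _query_distances(query_id, m, dataset)
    species = dataset.species_of()
    best = float(dists.min())
    bm = _bm_outcome(
        {species[refs[i]] for i in np.nonzero(dists <= best + tie_tol)[0]},
        query_species,
    )
    consp = dists[[species[r] == query_species for r in refs]]
    if best > threshold:
        outcome = "no_match"
    elif consp.size == 0:
        outcome = "ambiguous"
    else:
        worst_consp = float(consp.max())
        by_species: dict[str, list[float]] = {}
        for r, d in zip(refs, dists):
            if species[r] != query_species:
                by_species.setdefault(species[r], []).append(d)
        if not by_species or all(
            min(v) > worst_consp + tie_tol for v in by_species.values()
        ):
            outcome = "correct"
        elif any(max(v) < consp.min() - tie_tol for v in by_species.values()):
            outcome = "incorrect"
        else:
            outcome = "ambiguous"
    return Verdict(
        query_id=query_id,
        criterion="ASB",
        outcome=outcome,
        best_distance=best,
        matched_species=frozenset(),
        unthresholded_outcome=bm,
    )


# -- tree-based criteria -----------------------------------------------------


def _leaf_sets(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset[str]]:
    sets: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[node] = frozenset([node.taxon.label])
        else:
            sets[node] = frozenset().union(*(sets[c] for c in node.child_nodes()))
    return sets


def _check_tree_leaves(tree: dendropy.Tree, dataset: BarcodeDataset) -> None:
    tree_leaves = {
        l.taxon.label for l in tree.leaf_node_iter() if l.taxon is not None
    }
    expected = set(dataset.specimen_ids)
    if tree_leaves != expected:
        missing = sorted(expected - tree_leaves)
        extra = sorted(tree_leaves - expected)
        raise ValueError(
            f"tree leaves do not match dataset (missing {missing}, extra {extra})"
        )


def njt_classify(tree: dendropy.Tree, dataset: BarcodeDataset) -> list[Verdict]:
    """Species-monophyly (NJT) verdicts, one per ingroup leaf.

    A species is correct when its minimal spanning clade contains no
    allospecific leaf; a species with sequences at multiple positions is
    incorrect for all its sequences; singletons are ambiguous.
    """
    _check_tree_leaves(tree, dataset)
    species = dataset.species_of()
    sets = _leaf_sets(tree)
    by_species: dict[str, set[str]] = {}
    for r in dataset.ingroup:
        by_species.setdefault(r.species, set()).add(r.specimen_id)
    outcome_of_species: dict[str, str] = {}
    for sp, members in by_species.items():
        if len(members) == 1:
            outcome_of_species[sp] = "ambiguous"
            continue
        spanning = min(
            (s for s in sets.values() if members <= s), key=len
        )
        outcome_of_species[sp] = (
            "correct" if spanning == frozenset(members) else "incorrect"
        )
    return [
        Verdict(
            query_id=r.specimen_id,
            criterion="NJT",
            outcome=outcome_of_species[r.species],
        )
        for r in dataset.ingroup
    ]


def njt_m_classify(tree: dendropy.Tree, dataset: BarcodeDataset) -> list[Verdict]:
    """Node-level (NJT_M) verdicts on a rooted, polytomy-collapsed tree.

    Judged one node up from each leaf: correct amid only conspecifics
    (two or more), incorrect one node into an allospecific cluster or
    polytomy (two or more allospecific leaves), ambiguous for singleton
    species, single-sister cherries (conspecific or allospecific) and
    mixed company.
    """
    _check_tree_leaves(tree, dataset)
    species = dataset.species_of()
    counts = dataset.species_counts()
    sets = _leaf_sets(tree)
    verdicts = []
    leaf_of = {
        l.taxon.label: l for l in tree.leaf_node_iter() if l.taxon is not None
    }
    for r in dataset.ingroup:
        if counts[r.species] == 1:
            verdicts.append(
                Verdict(r.specimen_id, "NJT_M", "ambiguous")
            )
            continue
        leaf = leaf_of[r.specimen_id]
        parent = leaf.parent_node
        neighbours = (
            sets[parent] - {r.specimen_id} if parent is not None else frozenset()
        )
        consp = {x for x in neighbours if x not in dataset.outgroup_ids
                 and species[x] == r.species}
        allo = neighbours - consp
        if not neighbours:
            outcome = "ambiguous"
        elif not allo:
            outcome = "correct" if len(consp) >= 2 else "ambiguous"
        elif not consp:
            outcome = "incorrect" if len(allo) >= 2 else "ambiguous"
        else:
            outcome = "ambiguous"
        verdicts.append(Verdict(r.specimen_id, "NJT_M", outcome))
    return verdicts


# -- dataset-level evaluation ------------------------------------------------


def tally_percentages(counts: Mapping[str, int], n_queries: int) -> dict[str, float]:
    """Percentages of all queries per outcome, rounded half-up to 2 dp."""
    if n_queries <= 0:
        raise ValueError("n_queries must be positive")
    out = {}
    for outcome in OUTCOMES:
        c = counts.get(outcome, 0)
        pct = (Decimal(100) * Decimal(c) / Decimal(n_queries)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
        out[outcome] = float(pct)
    return out


@dataclass
class IdentificationReport:
    """Per-query verdicts plus tallies for one criterion."""

    criterion: str
    verdicts: list[Verdict]
    threshold: float | None = None

    @property
    def n_queries(self) -> int:
        return len(self.verdicts)

    @property
    def tallies(self) -> dict[str, int]:
        counts = {o: 0 for o in OUTCOMES}
        for v in self.verdicts:
            counts[v.outcome] += 1
        return counts

    @property
    def percentages(self) -> dict[str, float]:
        return tally_percentages(self.tallies, self.n_queries)

    def summary_row(self) -> dict[str, object]:
        pct = self.percentages
        label = self.criterion
        if self.threshold is not None:
            label += f" (threshold {100 * self.threshold:g}%)"
        row: dict[str, object] = {"criterion": label}
        for o in OUTCOMES:
            row[o] = pct[o]
        return row

    def verdict_rows(self, dataset: BarcodeDataset) -> list[dict[str, object]]:
        species = dataset.species_of()
        return [
            {
                "query_id": v.query_id,
                "species": species.get(v.query_id, ""),
                "criterion": v.criterion,
                "outcome": v.outcome,
                "best_distance": v.best_distance,
                "matched_species": ";".join(sorted(v.matched_species)),
            }
            for v in self.verdicts
        ]


def evaluate_dataset(
    dataset: BarcodeDataset,
    criterion: str,
    m: DistanceMatrix | None = None,
    tree: dendropy.Tree | None = None,
    threshold: float | None = None,
    tie_tol: float = TIE_TOL,
    collapse_epsilon: float = 1e-9,
) -> IdentificationReport:
    """One verdict per ingroup sequence under the given criterion.

    Similarity criteria need ``m``; BCM and ASB additionally need
    ``threshold``; tree criteria need a rooted ``tree`` (NJT_M collapses
    zero-length branches itself, so an uncollapsed tree is accepted).
    """
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}; one of {CRITERIA}")
    if criterion in ("BM", "BCM", "ASB"):
        if m is None:
            raise ValueError(f"{criterion} requires a distance matrix")
        if criterion in ("BCM", "ASB") and threshold is None:
            raise ValueError(f"{criterion} requires a threshold")
        verdicts = []
        for r in dataset.ingroup:
            if criterion == "BM":
                v = best_match(r.specimen_id, m, dataset, tie_tol)
            elif criterion == "BCM":
                v = best_close_match(r.specimen_id, m, dataset, threshold, tie_tol)
            else:
                v = all_species_barcodes(r.specimen_id, m, dataset, threshold, tie_tol)
            verdicts.append(v)
        used_threshold = threshold if criterion in ("BCM", "ASB") else None
        return IdentificationReport(criterion, verdicts, used_threshold)
    # tree criteria
    if tree is None:
        raise ValueError(f"{criterion} requires a rooted tree")
    if criterion == "NJT":
        return IdentificationReport("NJT", njt_classify(tree, dataset))
    from .njtree import collapse_short_branches

    collapsed = collapse_short_branches(tree, collapse_epsilon)
    return IdentificationReport("NJT_M", njt_m_classify(collapsed, dataset))
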