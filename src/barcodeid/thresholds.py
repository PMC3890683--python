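"""Distance thresholds, confusion classification, sweeps, the ad hoc
threshold regression, dataset stripping and problem-taxon flagging.

A query's best-close-match verdict combines with its position relative
to the threshold into the standard confusion classes:

* TP — correctly identified, best distance within the threshold;
* FP — incorrectly or ambiguously identified, within the threshold;
* FN — discarded (best distance above the threshold) although the best
  match was conspecific;
* TN — discarded and the best match was not conspecific (correctly
  rejected).

Derived metrics: accuracy (TP+TN), precision (TP/(TP+FP)), overall ID
error (FP+FN) and relative ID error (FP/(TP+FP) = 1 − precision). The ad
hoc threshold is where an OLS fit of relative ID error against the
threshold reaches the accepted error level (default 5%); a non-positive
estimate marks the reference library as unreliable for molecular
identification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .distances import DistanceMatrix, intraspecific_distances
from .identify import IdentificationReport, Verdict, evaluate_dataset
from .seqio import BarcodeDataset

__all__ = [
    "ConfusionSummary",
    "PerformanceMetrics",
    "SweepRow",
    "SweepTable",
    "AdHocThreshold",
    "StripResult",
    "TaxonFlag",
    "intraspecific_percentile_threshold",
    "classify_confusion",
    "performance_metrics",
    "threshold_sweep",
    "default_sweep_grid",
    "ad_hoc_threshold",
    "strip_dataset",
    "flag_problem_taxa",
    "zero_distance_allospecific_pairs",
]


def intraspecific_percentile_threshold(
    m: DistanceMatrix,
    dataset: BarcodeDataset,
    percentile: float = 95.0,
) -> float:
    """Distance below which the given percentage of all pooled
    intraspecific pairwise distances fall.

    Uses the linear-interpolation percentile (at rank ``(n-1)·p/100``
    between order statistics). Raises when the dataset has no
    intraspecific pair (all species singletons).
    """
    values = intraspecific_distances(m, dataset)
    if values.size == 0:
        raise ValueError(
            "no intraspecific pairs: percentile threshold undefined "
            "(all species are singletons)"
        )
    return float(np.percentile(values, percentile, method="linear"))


@dataclass(frozen=True)
class ConfusionSummary:
    """TP/FP/FN/TN as proportions of all queries at one threshold."""

    TP: float
    FP: float
    FN: float
    TN: float
    threshold: float
    n_queries: int

    @property
    def discarded_fraction(self) -> float:
        return self.FN + self.TN


@dataclass(frozen=True)
class PerformanceMetrics:
    """Accuracy, precision, overall and relative identification error.

    ``precision`` and ``relative_id_error`` are None when no query falls
    within the threshold (TP+FP = 0) — absence is a value, not an error.
    """

    accuracy: float
    precision: float | None
    overall_id_error: float
    relative_id_error: float | None


def classify_confusion(
    verdicts: Sequence[Verdict], threshold: float
) -> ConfusionSummary:
    """Split BCM-style verdicts into TP/FP/FN/TN proportions.

    Every verdict must carry ``best_distance`` and the unthresholded
    best-match outcome (used to decide whether a discarded query was
    correctly rejected). Ambiguous in-threshold queries count as FP,
    which together with incorrect ones makes TP+FP exactly the
    in-threshold fraction.
    """
    n = len(verdicts)
    if n == 0:
        raise ValueError("no verdicts to classify")
    tp = fp = fn = tn = 0
    for v in verdicts:
        if v.best_distance is None or math.isnan(v.best_distance):
            raise ValueError(f"verdict for {v.query_id!r} lacks best_distance")
        bm = v.unthresholded_outcome
        if bm is None:
            raise ValueError(
                f"verdict for {v.query_id!r} lacks the unthresholded outcome"
            )
        if v.best_distance <= threshold:
            if bm == "correct":
                tp += 1
            else:
                fp += 1
        else:
            if bm == "correct":
                fn += 1
            else:
                tn += 1
    return ConfusionSummary(
        TP=tp / n, FP=fp / n, FN=fn / n, TN=tn / n,
        threshold=threshold, n_queries=n,
    )


def performance_metrics(c: ConfusionSummary) -> PerformanceMetrics:
    """The four derived metrics from a confusion summary."""
    positives = c.TP + c.FP
    precision = c.TP / positives if positives > 0 else None
    return PerformanceMetrics(
        accuracy=c.TP + c.TN,
        precision=precision,
        overall_id_error=c.FP + c.FN,
        relative_id_error=(c.FP / positives) if positives > 0 else None,
    )


@dataclass(frozen=True)
class SweepRow:
    threshold: float
    confusion: ConfusionSummary
    metrics: PerformanceMetrics

    @property
    def discarded_fraction(self) -> float:
        return self.confusion.discarded_fraction


@dataclass
class SweepTable:
    """Per-threshold confusion and metrics, thresholds strictly decreasing."""

    rows: list[SweepRow]

    def __post_init__(self) -> None:
        ts = [r.threshold for r in self.rows]
        if any(b >= a for a, b in zip(ts, ts[1:])):
            raise ValueError("sweep thresholds must be strictly decreasing")

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def to_rows(self) -> list[dict[str, object]]:
        out = []
        for r in self.rows:
            out.append(
                {
                    "threshold": r.threshold,
                    "TP": r.confusion.TP,
                    "FP": r.confusion.FP,
                    "FN": r.confusion.FN,
                    "TN": r.confusion.TN,
                    "accuracy": r.metrics.accuracy,
                    "precision": r.metrics.precision,
                    "overall_id_error": r.metrics.overall_id_error,
                    "relative_id_error": r.metrics.relative_id_error,
                    "discarded_fraction": r.discarded_fraction,
                }
            )
        return out


def default_sweep_grid(
    upper: float = 0.15, lower: float = 0.0, steps: int = 30
) -> list[float]:
    """Evenly spaced descending threshold grid (default 0.15 → 0.00, 30)."""
    return [float(t) for t in np.linspace(upper, lower, steps)]


def threshold_sweep(
    dataset: BarcodeDataset,
    m: DistanceMatrix,
    thresholds: Iterable[float] | None = None,
) -> SweepTable:
    """BCM confusion and metrics at each threshold of a descending grid.

    The leave-one-out best matches do not depend on the threshold, so
    they are computed once and re-gated per row.
    """
    grid = list(thresholds) if thresholds is not None else default_sweep_grid()
    if not grid:
        raise ValueError("threshold grid must be non-empty")
    if any(t < 0 for t in grid):
        raise ValueError("thresholds must all be >= 0")
    base = evaluate_dataset(dataset, "BM", m=m)
    rows = []
    for t in grid:
        confusion = classify_confusion(base.verdicts, t)
        rows.append(SweepRow(t, confusion, performance_metrics(confusion)))
    return SweepTable(rows)


@dataclass(frozen=True)
class AdHocThreshold:
    """OLS-inferred threshold at the accepted relative ID error.

    ``estimate`` is None for a degenerate (zero-variance) fit;
    ``reliable`` is True only for a positive estimate — a non-positive
    one means no threshold achieves the accepted error and the library
    should be treated as unreliable for identification.
    """

    estimate: float | None
    r_squared: float | None
    slope: float | None
    intercept: float | None
    max_rel_error: float
    reliable: bool | None

    def to_dict(self) -> dict[str, object]:
        return {
            "estimate": self.estimate,
            "r_squared": self.r_squared,
            "slope": self.slope,
            "intercept": self.intercept,
            "max_rel_error": self.max_rel_error,
            "reliable": self.reliable,
        }


def ad_hoc_threshold(
    sweep: SweepTable, max_rel_error: float = 0.05
) -> AdHocThreshold:
    """Infer the ad hoc threshold from a sweep by linear regression.

    Fits relative ID error against threshold by OLS over every sweep row
    where the error is defined, and solves the fitted line for
    ``max_rel_error``. Returns the estimate, the R² of the fit and the
    reliability flag (positive estimate). Zero-variance fits report an
    absent estimate.
    """
    pts = [
        (r.threshold, r.metrics.relative_id_error)
        for r in sweep
        if r.metrics.relative_id_error is not None
    ]
    if len(pts) < 2:
        raise ValueError(
            "ad hoc threshold needs >=2 sweep rows with defined relative ID error"
        )
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.allclose(y, y[0]) or np.allclose(x, x[0]):
        return AdHocThreshold(
            estimate=None, r_squared=None, slope=None, intercept=None,
            max_rel_error=max_rel_error, reliable=None,
        )
    fit = stats.linregress(x, y)
    estimate = (max_rel_error - fit.intercept) / fit.slope
    return AdHocThreshold(
        estimate=float(estimate),
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        max_rel_error=max_rel_error,
        reliable=bool(estimate > 0),
    )


# -- dataset stripping -------------------------------------------------------


@dataclass(frozen=True)
class StripResult:
    dataset: BarcodeDataset
    removed_singletons: tuple[str, ...]  # specimen ids
    removed_taxa: tuple[str, ...]  # specimen ids
    dropped_species: tuple[str, ...]


def strip_dataset(
    dataset: BarcodeDataset,
    drop_singletons: bool = False,
    drop_taxa: Sequence[str] = (),
) -> StripResult:
    """Remove singleton species and/or named species or genera.

    A singleton is a species with exactly one ingroup sequence. Each
    entry of ``drop_taxa`` may be a species or a genus (dropping a genus
    removes all its species); unknown names raise. The outgroup is never
    stripped.
    """
    species_counts = dataset.species_counts()
    all_species = set(species_counts)
    all_genera = {r.genus for r in dataset.ingroup}
    drop_species: set[str] = set()
    for name in drop_taxa:
        if name in all_species:
            drop_species.add(name)
        elif name in all_genera:
            drop_species |= {
                r.species for r in dataset.ingroup if r.genus == name
            }
        else:
            raise ValueError(f"unknown species or genus {name!r}")
    removed_taxa = tuple(
        r.specimen_id for r in dataset.ingroup if r.species in drop_species
    )
    removed_singletons = tuple(
        r.specimen_id
        for r in dataset.ingroup
        if drop_singletons
        and species_counts[r.species] == 1
        and r.species not in drop_species
    )
    removed = set(removed_taxa) | set(removed_singletons)
    keep = [sid for sid in dataset.specimen_ids if sid not in removed]
    return StripResult(
        dataset=dataset.subset(keep),
        removed_singletons=removed_singletons,
        removed_taxa=removed_taxa,
        dropped_species=tuple(sorted(drop_species)),
    )


# -- problem-taxon flagging --------------------------------------------------


def zero_distance_allospecific_pairs(
    m: DistanceMatrix, dataset: BarcodeDataset, tol: float = 1e-12
) -> list[tuple[str, str]]:
    """Unordered ingroup pairs of different species at distance zero.

    These are the shared/identical haplotypes across species boundaries
    that make a group unidentifiable by barcode similarity.
    """
    species = dataset.species_of()
    ingroup = [sid for sid in m.ids if sid not in dataset.outgroup_ids]
    out = []
    for i, a in enumerate(ingroup):
        for b in ingroup[i + 1 :]:
            if species[a] != species[b] and m.is_defined(a, b) and m.get(a, b) <= tol:
                out.append((a, b))
    return out


@dataclass(frozen=True)
class TaxonFlag:
    rank: str  # "genus" | "species"
    name: str
    fraction_not_correct: float
    n_zero_allospecific: int
    flagged: bool
    reasons: tuple[str, ...]


def flag_problem_taxa(
    reports: Sequence[IdentificationReport],
    dataset: BarcodeDataset,
    m: DistanceMatrix | None = None,
    max_not_correct: float = 0.5,
    max_zero_allospecific: int = 0,
) -> list[TaxonFlag]:
    """Flag genera and species that undermine molecular identification.

    A taxon is flagged when, pooled over the given reports, more than
    ``max_not_correct`` of its queries are not correct, or when (given a
    distance matrix) it participates in more than ``max_zero_allospecific``
    zero-distance allospecific matches. Flagged taxa are the candidates
    for alternative identification markers.
    """
    if not reports:
        raise ValueError("need at least one identification report")
    species_of = dataset.species_of()
    genus_of = {r.specimen_id: r.genus for r in dataset.records}
    not_correct: dict[tuple[str, str], int] = {}
    totals: dict[tuple[str, str], int] = {}
    for rep in reports:
        for v in rep.verdicts:
            for key in (
                ("species", species_of[v.query_id]),
                ("genus", genus_of[v.query_id]),
            ):
                totals[key] = totals.get(key, 0) + 1
                if v.outcome != "correct":
                    not_correct[key] = not_correct.get(key, 0) + 1
    zero_counts: dict[tuple[str, str], int] = {}
    if m is not None:
        for a, b in zero_distance_allospecific_pairs(m, dataset):
            for sid in (a, b):
                for key in (
                    ("species", species_of[sid]),
                    ("genus", genus_of[sid]),
                ):
                    zero_counts[key] = zero_counts.get(key, 0) + 1
    flags = []
    for key in sorted(totals):
        frac = not_correct.get(key, 0) / totals[key]
        n_zero = zero_counts.get(key, 0)
        reasons = []
        if frac > max_not_correct:
            reasons.append(
                f"{100 * frac:.1f}% of queries not correctly identified"
            )
        if m is not None and n_zero > max_zero_allospecific:
            reasons.append(f"{n_zero} zero-distance allospecific match(es)")
        flags.append(
            TaxonFlag(
                rank=key[0],
                name=key[1],
                fraction_not_correct=frac,
                n_zero_allospecific=n_zero,
                flagged=bool(reasons),
                reasons=tuple(reasons),
            )
        )
    return flags
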