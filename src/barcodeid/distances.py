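"""Pairwise Kimura 2-parameter distances and dataset-level summaries.

The K2P model corrects observed divergence separately for transitions
(purine↔purine A↔G, pyrimidine↔pyrimidine C↔T; proportion P) and
transversions (all other mismatches; proportion Q):

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Sites where either sequence carries a gap or any IUPAC ambiguity code are
excluded pairwise (pairwise deletion); only unambiguous A/C/G/T versus
A/C/G/T positions are compared, and partial-ambiguity compatibility
(e.g. R vs A) is not credited. When the log argument is non-positive the
distance is saturated/undefined; such pairs are recorded on the matrix
rather than raised, so a single bad pair does not abort a run.

Distances are proportions throughout this module; conversion to percent
happens only in the reporting layer.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .seqio import BarcodeDataset

__all__ = [
    "SitePairCounts",
    "DistanceMatrix",
    "DistanceSummary",
    "PoolSummary",
    "count_site_pairs",
    "k2p_distance",
    "k2p_from_sequences",
    "distance_matrix",
    "summarize_distances",
    "barcode_gap_overlap",
    "species_pair_mean_distances",
]

# Encoding: A=0, C=1, G=2, T=3; anything else (ambiguity codes, gaps) = 255.
# With this encoding two differing valid bases are a transition iff they
# share parity (purines A,G → 0,2; pyrimidines C,T → 1,3).
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode(sequence: str) -> np.ndarray:
    """Encode a nucleotide string to the internal uint8 representation."""
    return _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class SitePairCounts:
    """Site-pattern counts for one pair of aligned sequences."""

    n_compared: int
    n_transitions: int
    n_transversions: int

    @property
    def P(self) -> float:
        """Proportion of compared sites that are transitions."""
        return self.n_transitions / self.n_compared if self.n_compared else math.nan

    @property
    def Q(self) -> float:
        """Proportion of compared sites that are transversions."""
        return self.n_transversions / self.n_compared if self.n_compared else math.nan


def count_site_pairs(a: str | np.ndarray, b: str | np.ndarray) -> SitePairCounts:
    """Count compared/transition/transversion sites under pairwise deletion."""
    ea = encode(a) if isinstance(a, str) else a
    eb = encode(b) if isinstance(b, str) else b
    if len(ea) != len(eb):
        raise ValueError(f"unequal sequence lengths: {len(ea)} vs {len(eb)}")
    both = (ea != 255) & (eb != 255)
    diff = both & (ea != eb)
    transitions = diff & ((ea & 1) == (eb & 1))
    return SitePairCounts(
        n_compared=int(both.sum()),
        n_transitions=int(transitions.sum()),
        n_transversions=int(diff.sum() - transitions.sum()),
    )


def k2p_distance(counts: SitePairCounts) -> float:
    """K2P distance from site-pair counts; NaN when undefined.

    Undefined cases: no comparable sites, or a saturated pair where
    ``(1 - 2P - Q) <= 0`` or ``(1 - 2Q) <= 0``.
    """
    if counts.n_compared == 0:
        return math.nan
    P, Q = counts.P, counts.Q
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    return max(0.0, -0.5 * math.log(w1 * math.sqrt(w2)))


def k2p_from_sequences(a: str, b: str) -> float:
    """Convenience: K2P distance directly from two aligned sequences."""
    return k2p_distance(count_site_pairs(a, b))


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise K2P distances keyed by specimen id.

    Undefined (saturated or incomparable) pairs hold NaN in ``d`` and are
    listed in ``undefined_pairs`` as frozensets of the two ids.
    """

    ids: list[str]
    d: np.ndarray
    undefined_pairs: set[frozenset[str]]

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} != ({n}, {n})")
        self._index = {sid: i for i, sid in enumerate(self.ids)}
        if len(self._index) != n:
            raise ValueError("duplicate ids in distance matrix")

    def index(self, specimen_id: str) -> int:
        return self._index[specimen_id]

    def get(self, a: str, b: str) -> float:
        return float(self.d[self._index[a], self._index[b]])

    def is_defined(self, a: str, b: str) -> bool:
        return not math.isnan(self.get(a, b))

    def submatrix(self, keep_ids: Iterable[str]) -> "DistanceMatrix":
        keep = [i for i in self.ids if i in set(keep_ids)]
        idx = np.array([self._index[i] for i in keep], dtype=int)
        kept = set(keep)
        return DistanceMatrix(
            ids=keep,
            d=self.d[np.ix_(idx, idx)],
            undefined_pairs={p for p in self.undefined_pairs if p <= kept},
        )

    # -- export ------------------------------------------------------------

    def to_tsv(self, path: str | Path, float_precision: int = 6) -> Path:
        path = Path(path)
        lines = ["\t".join(["id", *self.ids])]
        for i, sid in enumerate(self.ids):
            cells = [
                "" if math.isnan(v) else f"{v:.{float_precision}f}"
                for v in self.d[i]
            ]
            lines.append("\t".join([sid, *cells]))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
        return path

    def to_phylip(self, path: str | Path, float_precision: int = 6) -> Path:
        """PHYLIP square-matrix format (undefined entries rendered as -1)."""
        path = Path(path)
        lines = [f"{len(self.ids)}"]
        for i, sid in enumerate(self.ids):
            cells = [
                f"{-1.0:.{float_precision}f}" if math.isnan(v) else f"{v:.{float_precision}f}"
                for v in self.d[i]
            ]
            lines.append("  ".join([f"{sid:<10}", *cells]))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
        return path


def distance_matrix(dataset: BarcodeDataset) -> DistanceMatrix:
    """All-pairs K2P distance matrix for a dataset.

    Vectorised one row at a time; undefined pairs are recorded (with a
    single warning) and the run continues.
    """
    ids = dataset.specimen_ids
    n = len(ids)
    enc = np.stack([encode(r.sequence) for r in dataset.records])
    valid = enc != 255
    parity = enc & 1
    d = np.zeros((n, n), dtype=float)
    undefined: set[frozenset[str]] = set()
    for i in range(n - 1):
        both = valid[i] & valid[i + 1 :]
        diff = both & (enc[i] != enc[i + 1 :])
        ts = diff & (parity[i] == parity[i + 1 :])
        n_comp = both.sum(axis=1).astype(float)
        n_ts = ts.sum(axis=1).astype(float)
        n_tv = diff.sum(axis=1).astype(float) - n_ts
        with np.errstate(divide="ignore", invalid="ignore"):
            P = n_ts / n_comp
            Q = n_tv / n_comp
            w1 = 1.0 - 2.0 * P - Q
            w2 = 1.0 - 2.0 * Q
            row = np.where(
                (n_comp > 0) & (w1 > 0) & (w2 > 0),
                np.maximum(-0.5 * np.log(np.abs(w1) * np.sqrt(np.abs(w2))), 0.0),
                np.nan,
            )
        d[i, i + 1 :] = row
        d[i + 1 :, i] = row
        for j in np.nonzero(np.isnan(row))[0]:
            undefined.add(frozenset((ids[i], ids[i + 1 + int(j)])))
    if undefined:
        warnings.warn(
            f"{len(undefined)} pairwise distance(s) undefined "
            "(saturated or no comparable sites); excluded from summaries",
            stacklevel=2,
        )
    return DistanceMatrix(ids=ids, d=d, undefined_pairs=undefined)


# -- summaries ---------------------------------------------------------------


@dataclass(frozen=True)
class PoolSummary:
    """Mean/min/max of one pool of pairwise distances; absent when empty."""

    mean: float
    min: float
    max: float
    n_pairs: int

    @classmethod
    def from_values(cls, values: np.ndarray) -> "PoolSummary | None":
        values = values[~np.isnan(values)]
        if values.size == 0:
            return None
        return cls(
            mean=float(values.mean()),
            min=float(values.min()),
            max=float(values.max()),
            n_pairs=int(values.size),
        )


@dataclass(frozen=True)
class DistanceSummary:
    """Dataset-level distance summaries over the standard pools.

    Pools (ingroup pairs only; outgroup comparisons reported separately):
    intraspecific (same species), interspecific (different species),
    intrageneric (different species, same genus), intergeneric (different
    genera). Each field is None when its pool is empty.
    """

    intraspecific: PoolSummary | None
    interspecific: PoolSummary | None
    intrageneric: PoolSummary | None
    intergeneric: PoolSummary | None
    outgroup: PoolSummary | None


def _pair_pools(m: DistanceMatrix, dataset: BarcodeDataset):
    """Vector of pair distances plus boolean pool masks (ingroup pairs)."""
    species = np.array([dataset.species_of()[i] for i in m.ids])
    genus_map = {r.specimen_id: r.genus for r in dataset.records}
    genus = np.array([genus_map[i] for i in m.ids])
    is_out = np.array([i in dataset.outgroup_ids for i in m.ids])
    iu, ju = np.triu_indices(len(m.ids), k=1)
    dist = m.d[iu, ju]
    ingroup_pair = ~is_out[iu] & ~is_out[ju]
    outgroup_pair = is_out[iu] ^ is_out[ju]
    same_sp = species[iu] == species[ju]
    same_gen = genus[iu] == genus[ju]
    return dist, ingroup_pair, outgroup_pair, same_sp, same_gen


def summarize_distances(m: DistanceMatrix, dataset: BarcodeDataset) -> DistanceSummary:
    """Pool all pairwise distances and summarise each pool.

    Means are simple averages over all pairwise comparisons in the pool;
    undefined pairs are excluded. Outgroup–ingroup comparisons form their
    own pool and never enter the intra/inter pools.
    """
    if len(dataset) < 2:
        raise ValueError("need at least two specimens to summarise distances")
    dist, ingroup, outgroup, same_sp, same_gen = _pair_pools(m, dataset)
    return DistanceSummary(
        intraspecific=PoolSummary.from_values(dist[ingroup & same_sp]),
        interspecific=PoolSummary.from_values(dist[ingroup & ~same_sp]),
        intrageneric=PoolSummary.from_values(dist[ingroup & ~same_sp & same_gen]),
        intergeneric=PoolSummary.from_values(dist[ingroup & ~same_gen]),
        outgroup=PoolSummary.from_values(dist[outgroup]),
    )


def intraspecific_distances(m: DistanceMatrix, dataset: BarcodeDataset) -> np.ndarray:
    """Pooled defined intraspecific distances (ingroup pairs)."""
    dist, ingroup, _, same_sp, _ = _pair_pools(m, dataset)
    values = dist[ingroup & same_sp]
    return values[~np.isnan(values)]


def barcode_gap_overlap(
    m: DistanceMatrix, dataset: BarcodeDataset
) -> tuple[float, float, float]:
    """Barcode-gap overlap: (min_inter, max_intra, overlap_fraction).

    The overlap fraction is the proportion of all defined ingroup pairwise
    comparisons with ``min_inter <= d <= max_intra``; zero when the minimum
    interspecific distance exceeds the maximum intraspecific one (a clean
    gap). Raises when either pool is empty (overlap undefined).
    """
    dist, ingroup, _, same_sp, _ = _pair_pools(m, dataset)
    intra = dist[ingroup & same_sp]
    inter = dist[ingroup & ~same_sp]
    intra = intra[~np.isnan(intra)]
    inter = inter[~np.isnan(inter)]
    if intra.size == 0 or inter.size == 0:
        raise ValueError(
            "barcode-gap overlap undefined: intraspecific and interspecific "
            "pools must both be non-empty"
        )
    min_inter = float(inter.min())
    max_intra = float(intra.max())
    if min_inter > max_intra:
        return min_inter, max_intra, 0.0
    all_pairs = dist[ingroup]
    all_pairs = all_pairs[~np.isnan(all_pairs)]
    inside = (all_pairs >= min_inter) & (all_pairs <= max_intra)
    return min_inter, max_intra, float(inside.sum() / all_pairs.size)


def species_pair_mean_distances(
    m: DistanceMatrix,
    dataset: BarcodeDataset,
    groups: Mapping[str, str] | None = None,
    percent: bool = True,
):
    """Lower-triangular table of mean cross-pair distances between species.

    ``groups`` maps specimen_id → group label and overrides the species
    label, supporting sub-species splits such as host races; unmapped
    specimens keep their species. Returns a pandas DataFrame (NaN above
    the diagonal), in percent by default as such tables are printed.
    """
    import pandas as pd

    species = dataset.species_of()
    known = set(m.ids)
    if groups:
        unknown = set(groups) - known
        if unknown:
            raise ValueError(f"group map names unknown specimens: {sorted(unknown)}")
    label = {
        sid: (groups.get(sid, species[sid]) if groups else species[sid])
        for sid in m.ids
        if sid not in dataset.outgroup_ids
    }
    names = sorted(set(label.values()))
    if len(names) < 2:
        raise ValueError("need at least two species/groups")
    members = {g: [sid for sid, lab in label.items() if lab == g] for g in names}
    table = np.full((len(names), len(names)), np.nan)
    for (ti, gi), (tj, gj) in itertools.combinations(enumerate(names), 2):
        vals = [
            m.get(a, b)
            for a in members[gi]
            for b in members[gj]
            if m.is_defined(a, b)
        ]
        if vals:
            mean = float(np.mean(vals))
            table[max(ti, tj), min(ti, tj)] = mean * 100 if percent else mean
    return pd.DataFrame(table, index=names, columns=names)
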