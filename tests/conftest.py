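"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's vectorised code paths:
distances are recounted character by character, pools are enumerated
pair by pair, and identification rules are re-evaluated from sorted
match lists. They exist so the implementation can be checked against a
second, independently written route.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from barcodeid.distances import DistanceMatrix
from barcodeid.seqio import BarcodeDataset, BarcodeRecord


def make_dataset(
    entries: list[tuple],
    outgroup_ids: tuple[str, ...] = (),
) -> BarcodeDataset:
    """Build a dataset from (id, species, sequence[, population]) tuples;
    genus is the first word of the species binomial."""
    records = []
    for e in entries:
        sid, species, seq = e[0], e[1], e[2]
        pop = e[3] if len(e) > 3 else None
        records.append(
            BarcodeRecord(
                specimen_id=sid,
                species=species,
                genus=species.split()[0],
                sequence=seq,
                population=pop,
            )
        )
    return BarcodeDataset(records=records, outgroup_ids=frozenset(outgroup_ids))


def make_matrix(
    labels: list[tuple[str, str]],
    pair_distances: dict[tuple[str, str], float],
    seq: str = "ACGT",
    outgroup_ids: tuple[str, ...] = (),
) -> tuple[DistanceMatrix, BarcodeDataset]:
    """Hand-built distance matrix plus a label-compatible dummy dataset.

    ``labels`` is a list of (specimen_id, species); sequences are dummies
    because only the labels matter when the matrix is supplied directly.
    """
    ids = [sid for sid, _ in labels]
    n = len(ids)
    d = np.zeros((n, n))
    for (a, b), v in pair_distances.items():
        i, j = ids.index(a), ids.index(b)
        d[i, j] = d[j, i] = v
    ds = make_dataset([(sid, sp, seq) for sid, sp in labels], outgroup_ids)
    return DistanceMatrix(ids=ids, d=d, undefined_pairs=set()), ds


# -- independent character-level distance oracle -----------------------------

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


def oracle_k2p(a: str, b: str) -> float:
    """Character-by-character K2P with pairwise deletion; NaN if undefined."""
    assert len(a) == len(b)
    n = ts = tv = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x == y:
            continue
        if (x in PURINES and y in PURINES) or (x in PYRIMIDINES and y in PYRIMIDINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        return math.nan
    P, Q = ts / n, tv / n
    w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        return math.nan
    return -0.5 * math.log(w1 * math.sqrt(w2))


# -- independent identification-rule oracle ----------------------------------


def oracle_similarity_verdict(
    criterion: str,
    query_id: str,
    m: DistanceMatrix,
    dataset: BarcodeDataset,
    threshold: float | None = None,
    tol: float = 1e-12,
) -> str:
    """Re-evaluate BM/BCM/ASB from an explicitly sorted match list."""
    species = dataset.species_of()
    qsp = species[query_id]
    matches = sorted(
        (m.get(query_id, sid), species[sid])
        for sid in dataset.specimen_ids
        if sid != query_id
        and sid not in dataset.outgroup_ids
        and not math.isnan(m.get(query_id, sid))
    )
    assert matches, "oracle expects at least one defined reference"
    best = matches[0][0]
    if criterion in ("BCM", "ASB") and best > threshold:
        return "no_match"
    if criterion in ("BM", "BCM"):
        tied = {sp for d, sp in matches if d <= best + tol}
        if tied == {qsp}:
            return "correct"
        if qsp in tied or len(tied) > 1:
            return "ambiguous"
        return "incorrect"
    # ASB
    consp = [d for d, sp in matches if sp == qsp]
    if not consp:
        return "ambiguous"
    worst_consp = max(consp)
    others: dict[str, list[float]] = {}
    for d, sp in matches:
        if sp != qsp:
            others.setdefault(sp, []).append(d)
    if all(min(v) > worst_consp + tol for v in others.values()):
        return "correct"
    if any(max(v) < min(consp) - tol for v in others.values()):
        return "incorrect"
    return "ambiguous"


def random_toy_case(rng: np.random.Generator):
    """A random 4-6 sequence toy dataset with a hand-made distance matrix.

    Distances are drawn from a small discrete set so exact ties occur
    often, exercising the tie rules.
    """
    n = int(rng.integers(4, 7))
    n_species = int(rng.integers(2, n + 1))
    assignment = [int(rng.integers(0, n_species)) for _ in range(n)]
    labels = [(f"q{i}", f"Genus{assignment[i] % 2} sp{assignment[i]}") for i in range(n)]
    choices = [0.0, 0.001, 0.002, 0.005, 0.01, 0.05]
    pairs = {}
    for i, j in itertools.combinations(range(n), 2):
        pairs[(f"q{i}", f"q{j}")] = float(rng.choice(choices))
    threshold = float(rng.choice([0.0, 0.0015, 0.003, 0.02, 0.1]))
    m, ds = make_matrix(labels, pairs)
    return m, ds, threshold


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
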