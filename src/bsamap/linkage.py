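"""Two-point linkage analysis for a pseudo-testcross F1.

Markers heterozygous in one parent and homozygous in the other segregate
1:1 in the F1, so each individual's call records which parental haplotype
it inherited — a backcross-like configuration.  Because the parental
coupling phase is unknown, recombinant counting minimises the recombinant
class over the two possible phase assignments.  Linkage is quantified by a
two-point LOD score (threshold 4.0 for grouping), map distances use the
Kosambi function, and marker order within a group is found by exhaustive
minimisation of the sum of adjacent recombination fractions (SARF), which
is feasible and exactly testable at the map sizes this package targets.

The sex phenotype itself can be scored as a paternally segregating marker
(``sex_as_marker``), which is how a dominant one-locus trait is placed on
a pseudo-testcross map.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .sim import FEMALE

__all__ = [
    "MarkerCalls",
    "TwoPointResult",
    "LinkageGroup",
    "est_recomb",
    "lod_two_point",
    "two_point",
    "group_markers",
    "kosambi_cm",
    "haldane_cm",
    "order_markers",
    "pairwise_linkage",
    "sex_as_marker",
]

MISSING = -1
_CALL_CODES = {"a": 0, "b": 1, "-": MISSING, ".": MISSING, "": MISSING, "na": MISSING}


def _codes(calls) -> np.ndarray:
    arr = np.asarray(calls)
    if arr.dtype.kind in "iu":
        out = arr.astype(np.int8)
        if not np.isin(out, (0, 1, MISSING)).all():
            raise ValueError("integer calls must be 0, 1 or -1 (missing)")
        return out
    out = np.empty(arr.size, dtype=np.int8)
    for i, c in enumerate(arr.ravel()):
        key = str(c).strip().lower()
        if key not in _CALL_CODES:
            raise ValueError(f"unrecognised marker call {c!r}")
        out[i] = _CALL_CODES[key]
    return out


@dataclass
class MarkerCalls:
    """Per-individual inheritance calls for one testcross marker.

    Calls are 'a'/'b' for the two paternal alleles, '-' for missing; stored
    internally as 0/1/-1.
    """

    name: str
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = _codes(self.calls)


@dataclass
class TwoPointResult:
    r_hat: float
    n_informative: int
    n_recombinant: int
    lod: float
    d_kosambi: float | None  # None when r_hat >= 0.5


@dataclass
class LinkageGroup:
    """Ordered markers with cumulative Kosambi positions in cM."""

    markers: list[str]
    positions: np.ndarray

    @property
    def length_cm(self) -> float:
        return float(self.positions[-1]) if len(self.markers) else 0.0


def est_recomb(a: MarkerCalls, b: MarkerCalls) -> tuple[float, int, int]:
    """Estimate the recombination fraction between two testcross markers.

    Counting is pairwise-complete (individuals non-missing at both).  With
    unknown coupling, the recombinant class is whichever of the
    matching/mismatching classes is smaller, i.e. k is minimised over the
    two phase assignments; hence r_hat = k/n is always <= 1/2.
    """
    ca, cb = a.calls, b.calls
    if ca.size != cb.size:
        raise ValueError("call vectors must cover the same individuals")
    ok = (ca != MISSING) & (cb != MISSING)
    n = int(ok.sum())
    if n == 0:
        raise ValueError(f"no shared informative individuals for {a.name}/{b.name}")
    mismatches = int((ca[ok] != cb[ok]).sum())
    k = min(mismatches, n - mismatches)
    return k / n, n, k


def lod_two_point(n: int, k: int) -> float:
    """Two-point LOD at the MLE r̂ = k/n against independence (r = 1/2).

    lod = k*log10(2r̂) + (n-k)*log10(2(1-r̂)); the boundary cases k = 0 and
    k = n both reduce to n*log10(2) (complete coupling/repulsion).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    if k in (0, n):
        return n * math.log10(2.0)
    r = k / n
    return k * math.log10(2 * r) + (n - k) * math.log10(2 * (1 - r))


def kosambi_cm(r: float) -> float:
    """Kosambi map distance d = 25*ln((1+2r)/(1-2r)) cM, defined for r < 1/2."""
    if not 0 <= r < 0.5:
        raise ValueError("Kosambi distance requires 0 <= r < 0.5")
    return 25.0 * math.log((1 + 2 * r) / (1 - 2 * r))


def haldane_cm(r: float) -> float:
    """Haldane map distance d = -50*ln(1-2r) cM (no interference)."""
    if not 0 <= r < 0.5:
        raise ValueError("Haldane distance requires 0 <= r < 0.5")
    return -50.0 * math.log(1 - 2 * r)


def two_point(a: MarkerCalls, b: MarkerCalls) -> TwoPointResult:
    r_hat, n, k = est_recomb(a, b)
    lod = lod_two_point(n, k)
    d = kosambi_cm(r_hat) if r_hat < 0.5 else None
    return TwoPointResult(r_hat, n, k, lod, d)


def pairwise_linkage(markers: list[MarkerCalls]) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric matrices of pairwise r̂ and LOD over a marker set."""
    m = len(markers)
    r = np.zeros((m, m))
    lod = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            r_hat, n, k = est_recomb(markers[i], markers[j])
            r[i, j] = r[j, i] = r_hat
            lod[i, j] = lod[j, i] = lod_two_point(n, k)
    return r, lod


def group_markers(lod: np.ndarray, names: list[str], threshold: float = 4.0) -> list[list[str]]:
    """Partition markers into linkage groups at a LOD threshold.

    Groups are the connected components of the graph whose edges join
    marker pairs with LOD >= threshold (single-linkage, JoinMap-style).
    """
    lod = np.asarray(lod)
    if lod.shape != (len(names), len(names)):
        raise ValueError("lod matrix shape must match the marker list")
    adj = csr_matrix((lod >= threshold).astype(np.int8))
    n_comp, labels = connected_components(adj, directed=False)
    return [[names[i] for i in np.flatnonzero(labels == c)] for c in range(n_comp)]


@lru_cache(maxsize=4)
def _all_orders(m: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(m))), dtype=np.int16)


def _sarf(orders: np.ndarray, r: np.ndarray) -> np.ndarray:
    return r[orders[:, :-1], orders[:, 1:]].sum(axis=1)


def order_markers(names: list[str], r: np.ndarray, max_exhaustive: int = 10) -> LinkageGroup:
    """Order a linkage group and assign cumulative Kosambi positions.

    For groups of up to ``max_exhaustive`` markers the order minimising the
    sum of adjacent recombination fractions (SARF) is found exhaustively;
    between the two orientations of the optimum (and among exact ties) the
    lexicographically smallest marker sequence is returned.  Larger groups
    fall back to a greedy nearest-neighbour order with a warning.
    """
    m = len(names)
    r = np.asarray(r, dtype=float)
    if r.shape != (m, m):
        raise ValueError("r matrix shape must match the marker list")
    if m < 2:
        return LinkageGroup(list(names), np.zeros(max(m, 0)))
    if m <= max_exhaustive:
        orders = _all_orders(m)
        scores = _sarf(orders, r)
        best = scores.min()
        ties = orders[scores <= best + 1e-12]
        candidates = []
        for row in ties:
            seq = tuple(names[i] for i in row)
            candidates.append(min(seq, seq[::-1]))
        seq = min(candidates)
        order = [names.index(nm) for nm in seq]
    else:
        warnings.warn(
            f"group of {m} markers exceeds the exhaustive-search limit; "
            "using a nearest-neighbour heuristic order",
            stacklevel=2,
        )
        order = _nearest_neighbour_order(r)
        seq = [names[i] for i in order]
        if list(seq) > list(seq)[::-1]:
            order = order[::-1]
    adj = [r[order[i], order[i + 1]] for i in range(m - 1)]
    positions = np.concatenate([[0.0], np.cumsum([kosambi_cm(x) for x in adj])])
    return LinkageGroup([names[i] for i in order], positions)


def _nearest_neighbour_order(r: np.ndarray) -> list[int]:
    m = r.shape[0]
    remaining = set(range(m))
    cur = 0
    order = [cur]
    remaining.remove(cur)
    while remaining:
        nxt = min(remaining, key=lambda j: r[cur, j])
        order.append(nxt)
        remaining.remove(nxt)
        cur = nxt
    return order


def sex_as_marker(phenotypes, name: str = "sex") -> MarkerCalls:
    """Score a dominant one-locus sex trait as a paternal testcross marker.

    In an FF x MF (or FF x HF) cross every female inherited the father's
    recessive F allele and every male/hermaphrodite the dominant allele, so
    the phenotype encodes the paternal haplotype: female -> 'a',
    male/hermaphrodite -> 'b'.
    """
    calls = np.array([0 if p == FEMALE else 1 for p in phenotypes], dtype=np.int8)
    return MarkerCalls(name, calls)
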