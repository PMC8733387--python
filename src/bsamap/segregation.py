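"""Expected progeny sex ratios and chi-square goodness-of-fit testing.

Under the single-locus, tri-allelic model with dominance M > H > F, the
expected phenotype ratio of any cross follows from enumerating the four
equiprobable gamete unions: FF x MF gives 1:1 female:male, HF x MF gives
2:1:1 male:hermaphrodite:female, and so on.  Observed counts are tested
against the expectation with a chi-square goodness-of-fit statistic; for
two-category (df = 1) tests the Yates continuity correction is applied by
default.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaincc

from .sim import SexGenotype, phenotype_of

__all__ = ["PhenotypeCounts", "GofResult", "expected_ratio", "chi_square_gof"]


@dataclass
class PhenotypeCounts:
    """Observed phenotype counts for one population."""

    counts: dict[str, int]
    label: str = ""

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class GofResult:
    """Chi-square goodness-of-fit outcome."""

    chi2: float
    df: int
    corrected: bool
    p_value: float


def expected_ratio(mother: SexGenotype, father: SexGenotype) -> dict[str, float]:
    """Phenotype probabilities of a cross: enumerate the 4 gamete unions.

    Each parent transmits either allele with probability 1/2, so the four
    unions are equiprobable; their phenotypes are aggregated into a map that
    sums to 1 and is symmetric in the parents.
    """
    probs: dict[str, float] = {}
    for a in mother.alleles:
        for b in father.alleles:
            ph = phenotype_of(SexGenotype((a, b)))
            probs[ph] = probs.get(ph, 0.0) + 0.25
    return probs


def _chi2_sf(x: float, df: int) -> float:
    # survival function of chi-square(df) via the regularized upper
    # incomplete gamma function Q(df/2, x/2)
    return float(gammaincc(df / 2.0, x / 2.0))


def chi_square_gof(
    counts: PhenotypeCounts | Mapping[str, int] | Sequence[int],
    expected: Mapping[str, float] | Sequence[float],
    yates: bool | None = None,
) -> GofResult:
    """Chi-square goodness of fit of observed counts to expected proportions.

    ``chi2 = sum((|O_i - E_i| - c)^2 / E_i)`` with continuity correction
    ``c = 0.5`` when ``yates`` applies; ``yates=None`` (default) enables the
    correction automatically for df = 1 (two categories) and disables it
    otherwise.  Every observed category must have positive expected
    probability, and expected proportions are renormalised to the observed
    total.
    """
    if isinstance(counts, PhenotypeCounts):
        observed_map: dict[str, int] = dict(counts.counts)
    elif isinstance(counts, Mapping):
        observed_map = dict(counts)
    else:
        observed_map = {str(i): int(c) for i, c in enumerate(counts)}
        if not isinstance(expected, Mapping):
            expected = {str(i): float(p) for i, p in enumerate(expected)}
    if isinstance(expected, Mapping):
        missing = set(observed_map) - set(expected)
        if missing:
            raise ValueError(f"no expected probability for categories {sorted(missing)}")
        probs = np.array([expected[k] for k in observed_map], dtype=float)
    else:
        probs = np.asarray(expected, dtype=float)
        if probs.size != len(observed_map):
            raise ValueError("expected proportions do not match observed categories")
    if np.any(probs <= 0):
        raise ValueError("expected probabilities must be positive")
    observed = np.array(list(observed_map.values()), dtype=float)
    total = observed.sum()
    if total == 0:
        raise ValueError("zero total count")
    probs = probs / probs.sum()
    exp_counts = probs * total
    df = observed.size - 1
    corrected = yates if yates is not None else (df == 1)
    if corrected and df != 1:
        raise ValueError("Yates correction applies to df = 1 tests only")
    c = 0.5 if corrected else 0.0
    adj = np.maximum(np.abs(observed - exp_counts) - c, 0.0)
    chi2 = float(np.sum(adj**2 / exp_counts))
    return GofResult(chi2=chi2, df=df, corrected=bool(corrected), p_value=_chi2_sf(chi2, df))
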