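"""Kimura two-parameter divergence between aligned LTRs, and clock dating.

Transitions (A<->G, C<->T) and transversions (all other mismatches) are
counted over aligned columns after pairwise deletion of any column that
contains a gap or a non-ACGT character.  With transition proportion
P and transversion proportion Q, the K2P distance is

    K = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))   [substitutions/site]

which is undefined ("saturated") when 1 - 2P - Q <= 0 or 1 - 2Q <= 0.
Because the two LTR copies accumulate substitutions independently after
insertion, the insertion age under a molecular clock with per-site,
per-year rate r is T = K / (2 r).  The default rate, 0.59e-9
substitutions/site/year, is the value reported for Cryptomeria
japonica.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .align import GAP, AlignedPair

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
_CANONICAL = _PURINES | _PYRIMIDINES

#: Default substitution rate (substitutions/site/year) for C. japonica.
DEFAULT_RATE = 0.59e-9


@dataclass(frozen=True)
class ClockConfig:
    rate: float = DEFAULT_RATE  # substitutions/site/year

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("clock rate must be > 0")


@dataclass(frozen=True)
class DivergenceEstimate:
    element_id: str
    n_sites: int
    n_transitions: int
    n_transversions: int
    saturated: bool
    K: float | None  # substitutions/site; None when saturated

    @property
    def P(self) -> float:
        return self.n_transitions / self.n_sites if self.n_sites else float("nan")

    @property
    def Q(self) -> float:
        return self.n_transversions / self.n_sites if self.n_sites else float("nan")


@dataclass(frozen=True)
class DatedElement:
    element_id: str
    K: float | None
    saturated: bool
    rate_used: float
    age_years: float | None
    age_mya: float | None


def is_transition(a: str, b: str) -> bool:
    return (a in _PURINES and b in _PURINES) or (
        a in _PYRIMIDINES and b in _PYRIMIDINES
    )


def count_site_patterns(pair: AlignedPair) -> tuple[int, int, int]:
    """(n_sites, n_transitions, n_transversions) over comparable columns.

    Columns with a gap or a non-ACGT character in either row are
    excluded (pairwise deletion).
    """
    n_sites = n_ts = n_tv = 0
    for a, b in zip(pair.aligned_left, pair.aligned_right):
        if a == GAP or b == GAP or a not in _CANONICAL or b not in _CANONICAL:
            continue
        n_sites += 1
        if a == b:
            continue
        if is_transition(a, b):
            n_ts += 1
        else:
            n_tv += 1
    return n_sites, n_ts, n_tv


def k2p_distance(
    n_sites: int, n_transitions: int, n_transversions: int
) -> tuple[float | None, bool]:
    """K2P distance from site-pattern counts; (K, saturated).

    K is None when the correction's logarithm argument is non-positive
    (saturation) or when there are no comparable sites.
    """
    if n_sites <= 0:
        return None, True
    P = n_transitions / n_sites
    Q = n_transversions / n_sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return None, True
    K = max(-0.5 * math.log(w1 * math.sqrt(w2)), 0.0)
    return K, False


def estimate_divergence(pair: AlignedPair) -> DivergenceEstimate:
    """Site-pattern counts and K2P distance for one aligned LTR pair."""
    n_sites, n_ts, n_tv = count_site_patterns(pair)
    K, saturated = k2p_distance(n_sites, n_ts, n_tv)
    return DivergenceEstimate(
        element_id=pair.element_id,
        n_sites=n_sites,
        n_transitions=n_ts,
        n_transversions=n_tv,
        saturated=saturated,
        K=K,
    )


def date_element(est: DivergenceEstimate, clock: ClockConfig | None = None) -> DatedElement:
    """Convert K2P divergence to insertion age: T = K / (2 r).

    Saturated estimates carry no age.
    """
    clock = clock or ClockConfig()
    if est.saturated or est.K is None:
        return DatedElement(est.element_id, None, True, clock.rate, None, None)
    age_years = est.K / (2.0 * clock.rate)
    return DatedElement(
        element_id=est.element_id,
        K=est.K,
        saturated=False,
        rate_used=clock.rate,
        age_years=age_years,
        age_mya=age_years / 1e6,
    )
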