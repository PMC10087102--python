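"""Gene-set overlap statistics: representation factor, exact hypergeometric
upper tail, and a permutation null with quantile summaries.

The representation factor is the observed overlap divided by the overlap
expected for independent sets, k / (n1*n2/N); values above 1 indicate more
overlap than expected. The hypergeometric tail is one-sided and includes the
observed count, P(X >= k).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.stats import hypergeom

from .errors import ConfigurationError


@dataclass(frozen=True)
class EnrichmentResult:
    N: int
    n1: int
    n2: int
    k: int
    expected: float
    representation_factor: float
    p_hypergeometric: float | None = None


@dataclass(frozen=True)
class PermutationSummary:
    reps: int
    draw_size: int
    min: float
    q1: float
    median: float
    mean: float
    q3: float
    max: float
    rng_seed: int


def _check_sizes(N: int, n1: int, n2: int, k: int) -> None:
    if N <= 0 or n1 <= 0 or n2 <= 0:
        raise ConfigurationError(
            "N/n1/n2: expectation undefined for empty universe or sets")
    if n1 > N or n2 > N or k < 0:
        raise ConfigurationError("n1/n2/k: inconsistent sizes")


def representation_factor(N: int, n1: int, n2: int, k: int) -> EnrichmentResult:
    """Observed/expected overlap, computed in exact rational arithmetic and
    converted to float only at the end."""
    _check_sizes(N, n1, n2, k)
    expected = Fraction(n1 * n2, N)
    rf = Fraction(k) / expected
    return EnrichmentResult(
        N=N, n1=n1, n2=n2, k=k,
        expected=float(expected),
        representation_factor=float(rf),
    )


def hypergeometric_tail(N: int, n1: int, n2: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, n1, n2), evaluated via the
    log-survival function for stability in the far tail."""
    _check_sizes(N, n1, n2, k)
    if k > min(n1, n2):
        warnings.warn(
            f"overlap k={k} exceeds min(n1, n2)={min(n1, n2)}: impossible "
            "observation, returning 0", stacklevel=2)
        return 0.0
    if k <= 0:
        return 1.0
    return float(np.exp(hypergeom.logsf(k - 1, N, n1, n2)))


def permutation_overlap(universe, fixed_set, draw_size: int,
                        reps: int = 1000, seed: int = 0) -> PermutationSummary:
    """Overlap of ``reps`` uniform draws (without replacement) with a fixed
    set; summarised by min/quartiles/mean/max (linear-interpolation, type-7
    quantiles)."""
    universe = list(universe)
    fixed = set(fixed_set)
    if not fixed <= set(universe):
        raise ConfigurationError("fixed_set: must be a subset of the universe")
    if draw_size > len(universe):
        raise ConfigurationError("draw_size: must be <= |universe|")
    rng = np.random.default_rng(seed)
    is_fixed = np.array([g in fixed for g in universe])
    n = len(universe)
    overlaps = np.empty(reps, dtype=int)
    for r in range(reps):
        draw = rng.choice(n, size=draw_size, replace=False)
        overlaps[r] = int(is_fixed[draw].sum())
    q1, med, q3 = np.quantile(overlaps, [0.25, 0.5, 0.75], method="linear")
    return PermutationSummary(
        reps=reps, draw_size=draw_size,
        min=float(overlaps.min()), q1=float(q1), median=float(med),
        mean=float(overlaps.mean()), q3=float(q3), max=float(overlaps.max()),
        rng_seed=seed)


def target_set_overlap(set_a, set_b, universe) -> EnrichmentResult:
    """Representation factor and hypergeometric tail for two observed sets."""
    universe = set(universe)
    a, b = set(set_a), set(set_b)
    if not (a <= universe and b <= universe):
        raise ConfigurationError("set_a/set_b: must be subsets of the universe")
    k = len(a & b)
    base = representation_factor(len(universe), len(a), len(b), k)
    p = hypergeometric_tail(len(universe), len(a), len(b), k)
    return EnrichmentResult(
        N=base.N, n1=base.n1, n2=base.n2, k=base.k, expected=base.expected,
        representation_factor=base.representation_factor, p_hypergeometric=p)
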