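"""Conformational-composition statistics for dodecameric channel particles.

With two conformational states per protomer (pore-lining ``P`` and flexible
``F``) a 12-protomer particle has 13 possible state compositions (0:12 .. 12:0)
and each hexameric hemichannel ring has 64 labellings that collapse into 14
rotational equivalence classes (binary necklaces of length 6). If protomers
switch state independently with probability ``p`` of being pore-lining, the
composition histogram is Binomial(12, p) and a necklace class with ``k``
pore-lining protomers and orbit size ``m`` has probability ``m p^k (1-p)^(6-k)``.
Departures from those references — over-represented uniform rings, say — are
the signature of nearest-neighbour coupling between protomers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .metadata import ParticleComposition, ParticleTable

__all__ = [
    "CompositionDistribution",
    "RingArrangement",
    "IndependenceTestResult",
    "StateFractionEstimate",
    "composition_distribution",
    "binomial_expectation",
    "estimate_state_fraction",
    "canonical_necklace",
    "necklace_census",
    "arrangement_distribution",
    "independence_test",
    "adjacency_coupling_stat",
    "adjacent_same_state_pairs",
]

RING_LEN = 6
N_COMPOSITION_BINS = 13  # k = 0..12 pore-lining protomers per dodecamer


@dataclass
class CompositionDistribution:
    """Histogram of particles over k = number of pore-lining protomers (0..12)."""

    counts: np.ndarray
    n_particles: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (N_COMPOSITION_BINS,):
            raise ValueError(f"expected {N_COMPOSITION_BINS} bins")
        if self.counts.sum() != self.n_particles:
            raise ValueError("counts do not sum to n_particles")

    @property
    def fractions(self) -> np.ndarray:
        return self.counts / self.n_particles


@dataclass
class RingArrangement:
    """One rotational equivalence class of a 6-ring labelling."""

    canonical: str
    orbit_size: int
    k_pln: int
    observed: int = 0
    expected: float = 0.0


@dataclass
class IndependenceTestResult:
    statistic: float
    df: int
    p_value: float
    method: str
    pooled_bins: str = ""


@dataclass
class StateFractionEstimate:
    """Fraction of protomers in the pore-lining state with a Wilson 95% CI."""

    p_hat: float
    n: int
    ci_low: float
    ci_high: float

    def covers(self, p: float) -> bool:
        return self.ci_low <= p <= self.ci_high


def composition_distribution(
    compositions: Iterable[ParticleComposition],
) -> CompositionDistribution:
    """Count particles at each of the 13 FN:PLN ratios (0:12 .. 12:0)."""
    counts = np.zeros(N_COMPOSITION_BINS, dtype=int)
    n = 0
    for comp in compositions:
        if comp.n_other or comp.n_unassigned:
            raise ValueError(
                f"particle {comp.particle_id}: non-binary states present; "
                "exclude OTHER/UNASSIGNED upstream"
            )
        counts[comp.k_pln] += 1
        n += 1
    if n == 0:
        raise ValueError("no compositions supplied")
    return CompositionDistribution(counts=counts, n_particles=n)


def binomial_expectation(p: float, n: int, N: int) -> np.ndarray:
    """Expected particle counts over k = 0..n if states are independent.

    ``expected[k] = N * C(n, k) * p^k * (1-p)^(n-k)``; the random-placement
    null for the composition histogram.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if n < 1 or N < 0:
        raise ValueError("need n >= 1 and N >= 0")
    return N * stats.binom.pmf(np.arange(n + 1), n, p)


def estimate_state_fraction(table: ParticleTable) -> StateFractionEstimate:
    """Fraction of classified protomer records in the pore-lining state."""
    counts = table.state_counts()
    n_p, n_f = counts["PLN"], counts["FN"]
    n = n_p + n_f
    if n == 0:
        raise ValueError("no records classified as PLN or FN")
    lo, hi = proportion_confint(n_p, n, alpha=0.05, method="wilson")
    return StateFractionEstimate(p_hat=n_p / n, n=n, ci_low=float(lo), ci_high=float(hi))


def canonical_necklace(states: str) -> tuple[str, int]:
    """Canonical form of a ring labelling under cyclic rotation.

    Returns the lexicographically smallest of the 6 rotations and the number
    of distinct rotations (the orbit size, a divisor of 6).
    """
    if len(states) != RING_LEN:
        raise ValueError(f"ring string must have length {RING_LEN}, got {states!r}")
    if set(states) - set("PF"):
        raise ValueError(f"ring alphabet is {{P, F}}, got {states!r}")
    rotations = {states[i:] + states[:i] for i in range(RING_LEN)}
    return min(rotations), len(rotations)


def necklace_census() -> list[RingArrangement]:
    """All rotational classes of length-6 binary rings, sorted by (k, canonical).

    There are 14 classes with multiplicities {1, 1, 3, 4, 3, 1, 1} over
    k = 0..6 pore-lining protomers (Burnside: (64 + 8 + 8 + 4)/6 = 14 with the
    cycle index of the cyclic group C6).
    """
    seen: dict[str, RingArrangement] = {}
    for bits in range(2 ** RING_LEN):
        s = "".join("P" if bits >> i & 1 else "F" for i in range(RING_LEN))
        canon, orbit = canonical_necklace(s)
        if canon not in seen:
            seen[canon] = RingArrangement(
                canonical=canon, orbit_size=orbit, k_pln=canon.count("P")
            )
    return sorted(seen.values(), key=lambda a: (a.k_pln, a.canonical))


def arrangement_distribution(
    compositions: Iterable[ParticleComposition], p: float | None = None
) -> tuple[list[RingArrangement], float]:
    """Observed vs expected-under-independence counts per ring necklace class.

    Both hemichannel rings of every particle are counted separately. When
    ``p`` is ``None`` the plug-in estimate from the same rings is used (note
    this costs one degree of freedom in a subsequent goodness-of-fit test).
    Returns the 14 classes and the ``p`` actually used.
    """
    rings: list[str] = []
    for comp in compositions:
        for ring in comp.rings:
            if len(ring) != RING_LEN:
                raise ValueError(
                    f"particle {comp.particle_id}: ring positions unset; "
                    "run expand_symmetry / group_by_particle first"
                )
            rings.append(ring)
    if not rings:
        raise ValueError("no rings supplied")
    if p is None:
        joined = "".join(rings)
        n_p, n_f = joined.count("P"), joined.count("F")
        p = n_p / (n_p + n_f)

    classes = necklace_census()
    index = {a.canonical: a for a in classes}
    for ring in rings:
        canon, _ = canonical_necklace(ring)
        index[canon].observed += 1
    n_rings = len(rings)
    for a in classes:
        a.expected = n_rings * a.orbit_size * p ** a.k_pln * (1 - p) ** (RING_LEN - a.k_pln)
    return classes, p


def _pool_sparse(observed: np.ndarray, expected: np.ndarray, min_expected: float = 5.0):
    keep = expected >= min_expected
    if keep.all():
        return observed.astype(float), expected.astype(float), "no pooling"
    pooled_o = np.append(observed[keep], observed[~keep].sum())
    pooled_e = np.append(expected[keep], expected[~keep].sum())
    note = f"pooled {int((~keep).sum())} bins with expected < {min_expected}"
    return pooled_o.astype(float), pooled_e.astype(float), note


def independence_test(
    observed: Sequence[float],
    expected: Sequence[float],
    method: str = "pearson_chi2",
    p_estimated: bool = True,
    n_replicates: int = 10_000,
    seed: int | None = None,
) -> IndependenceTestResult:
    """Goodness-of-fit of observed class counts to the independence null.

    ``pearson_chi2`` pools classes with expected count < 5 into one bin and
    uses ``df = bins - 1 - (1 if p_estimated else 0)``. ``exact_multinomial_mc``
    draws ``n_replicates`` multinomial tables from the null and reports the
    Monte-Carlo p-value of the Pearson statistic (add-one corrected).
    """
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise ValueError("observed and expected must align")
    if not np.any(expected > 0):
        raise ValueError("expected counts are all zero")
    N = observed.sum()
    if N < 1:
        raise ValueError("need at least one observation")

    obs_p, exp_p, note = _pool_sparse(observed, expected)
    # guard against empty pooled-expected cells
    exp_p = np.maximum(exp_p, 1e-300)
    statistic = float(((obs_p - exp_p) ** 2 / exp_p).sum())

    if method == "pearson_chi2":
        df = len(obs_p) - 1 - (1 if p_estimated else 0)
        if df < 1:
            raise ValueError("not enough bins after pooling for a chi-square test")
        p_value = float(stats.chi2.sf(statistic, df))
        return IndependenceTestResult(statistic, df, p_value, method, note)
    if method == "exact_multinomial_mc":
        if seed is None:
            raise ValueError("exact_multinomial_mc requires a seed")
        rng = np.random.default_rng(seed)
        probs = exp_p / exp_p.sum()
        reps = rng.multinomial(int(N), probs, size=n_replicates).astype(float)
        rep_stats = ((reps - N * probs) ** 2 / (N * probs)).sum(axis=1)
        p_value = float((1 + (rep_stats >= statistic - 1e-12).sum()) / (1 + n_replicates))
        return IndependenceTestResult(statistic, len(obs_p) - 1, p_value, method, note)
    raise ValueError(f"unknown method {method!r}")


def adjacent_same_state_pairs(ring: str) -> int:
    """Number of cyclically adjacent equal-state pairs in a 6-ring (0..6)."""
    if len(ring) != RING_LEN:
        raise ValueError("ring string must have length 6")
    return sum(ring[i] == ring[(i + 1) % RING_LEN] for i in range(RING_LEN))


def adjacency_coupling_stat(
    compositions: Iterable[ParticleComposition],
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Neighbour-coupling statistic with a within-ring permutation null.

    The statistic is the mean, over hemichannel rings, of the number of
    cyclically adjacent same-state pairs. The null shuffles states across the
    six positions within each ring (compositions fixed), so any excess is
    positional clustering, not composition. Returns (statistic, two-sided
    Monte-Carlo p-value).
    """
    import warnings

    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse p-value", stacklevel=2)
    rings = [ring for comp in compositions for ring in comp.rings]
    if not rings:
        raise ValueError("no rings supplied")
    mat = np.array([[c == "P" for c in ring] for ring in rings], dtype=np.int8)
    n = len(rings)

    def mean_pairs(m: np.ndarray) -> float:
        return float((m == np.roll(m, -1, axis=1)).sum(axis=1).mean())

    observed = mean_pairs(mat)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = np.argsort(rng.random(mat.shape), axis=1)
        null[i] = mean_pairs(np.take_along_axis(mat, perm, axis=1))
    ge = (null >= observed - 1e-12).sum()
    le = (null <= observed + 1e-12).sum()
    p_two = min(1.0, 2 * min((1 + ge) / (1 + n_perm), (1 + le) / (1 + n_perm)))
    return observed, p_two
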