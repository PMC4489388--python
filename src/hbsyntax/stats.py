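"""Enrichment statistics and the random-placement simulation null.

Every p-value, fold and z-score of the genome-wide analysis comes from
here: Fisher's exact test on 2x2 sequence-set tables, the hypergeometric
enrichment test on region counts, per-Mb element rates and their ratios,
the Mann-Whitney comparison of distance distributions, and a Monte-Carlo
null that re-places the observed numbers of motif sites uniformly at
random within the conserved-region universe and recounts gap-constrained
pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .syntax import RegionSet, GenomicInterval


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b; c, d): group1 with/without property; group2 likewise."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    def margins(self) -> tuple[int, int, int, int]:
        return self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d


@dataclass(frozen=True)
class HypergeomSpec:
    """Population N with K marked members; sample n; x marked observed."""

    N: int
    K: int
    n: int
    x: int

    def __post_init__(self) -> None:
        if not (0 <= self.x <= min(self.K, self.n) <= self.N):
            raise ValueError(f"require 0 <= x <= min(K, n) <= N, got {self}")
        if self.n > self.N or self.K > self.N:
            raise ValueError("sample and marked counts cannot exceed N")


@dataclass(frozen=True)
class EnrichmentResult:
    observed: float
    expected: float
    fold: float
    p_value: float
    method: str


@dataclass(frozen=True)
class SimulationNull:
    """Summary of a placement-simulation null distribution of pair counts."""

    n_sims: int
    counts: tuple[int, ...]
    mean: float
    sd: float
    observed: int | None
    z: float | None
    p_normal: float | None
    p_empirical: float | None
    seed: int | None


def fisher_exact(table: ContingencyTable2x2, alternative: str = "two_sided") -> float:
    """Exact conditional p for a 2x2 table.

    ``two_sided`` sums all tables (fixed margins) whose point probability
    does not exceed the observed table's; ``greater`` is the upper
    hypergeometric tail on cell a.  A zero margin makes the test undefined;
    p = 1 is returned with a warning.
    """
    alt = {"two_sided": "two-sided", "two-sided": "two-sided",
           "greater": "greater", "less": "less"}.get(alternative)
    if alt is None:
        raise ValueError(f"unknown alternative {alternative!r}")
    if 0 in table.margins():
        warnings.warn("zero margin: Fisher's exact test undefined, returning p=1",
                      stacklevel=2)
        return 1.0
    return float(sps.fisher_exact([[table.a, table.b], [table.c, table.d]],
                                  alternative=alt)[1])


def hypergeom_enrichment(spec: HypergeomSpec) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment P(X >= x), with expected = n*K/N."""
    expected = spec.n * spec.K / spec.N
    p = float(sps.hypergeom.sf(spec.x - 1, spec.N, spec.K, spec.n))
    fold = spec.x / expected if expected > 0 else float("nan")
    return EnrichmentResult(observed=spec.x, expected=expected, fold=fold,
                            p_value=p, method="hypergeometric")


def rate_per_mb(count: int, total_bp: int) -> float:
    """Elements per megabase of sequence."""
    if total_bp <= 0:
        raise ValueError("total_bp must be positive")
    return count / (total_bp / 1e6)


def fold_vs_background(obs_count: float, obs_bp: int, bg_count: float, bg_bp: int) -> float:
    """Ratio of per-Mb rates in a focal set vs a background set.

    Algebraically identical to observed/expected with
    expected = bg_count * obs_bp / bg_bp.
    """
    if bg_count <= 0:
        raise ValueError("background count must be positive")
    return rate_per_mb(obs_count, obs_bp) / rate_per_mb(bg_count, bg_bp)


def zscore_normal_p(observed: float, mean: float, sd: float) -> tuple[float, float]:
    """Standardise an observed count and return (z, one-sided upper normal p)."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    z = (observed - mean) / sd
    return z, float(sps.norm.sf(z))


def mann_whitney_u(sample_a, sample_b, alternative: str = "two_sided") -> float:
    """Mann-Whitney rank-sum p (tie-corrected; exact for small tie-free samples)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    alt = {"two_sided": "two-sided", "two-sided": "two-sided",
           "less": "less", "greater": "greater"}.get(alternative)
    if alt is None:
        raise ValueError(f"unknown alternative {alternative!r}")
    method = "exact" if (max(a.size, b.size) <= 20
                         and np.unique(np.concatenate([a, b])).size == a.size + b.size) \
        else "asymptotic"
    return float(sps.mannwhitneyu(a, b, alternative=alt, method=method).pvalue)


def quantile(values, q: float) -> float:
    """Empirical quantile, linear interpolation between order statistics.

    q=0 is the minimum, q=1 the maximum; matches numpy's default
    ("linear") convention.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must be in [0, 1]")
    return float(np.quantile(v, q))


# ---------------------------------------------------------------------------
# placement simulation null
# ---------------------------------------------------------------------------

def _placement_universe(regions: RegionSet, site_len: int):
    """Absolute start coordinates where a site of ``site_len`` fits in one region.

    Returns (cum, origins): cum[i] = number of valid starts in regions[:i+1];
    origins maps a drawn rank to an absolute coordinate on a per-chromosome
    offset line (chromosomes separated so cross-chromosome pairs are
    impossible).
    """
    chroms = sorted({iv.chrom for iv in regions})
    # lay chromosomes end-to-end with a spacer no pair can bridge
    spacer = 10 ** 6
    offset, chrom_offset = 0, {}
    for c in chroms:
        chrom_offset[c] = offset
        offset += max((iv.end for iv in regions if iv.chrom == c), default=0) + spacer
    starts, counts = [], []
    for iv in regions:
        k = len(iv) - site_len + 1
        if k > 0:
            starts.append(iv.start + chrom_offset[iv.chrom])
            counts.append(k)
    if not counts:
        raise ValueError(f"no region can host a site of length {site_len}")
    counts = np.asarray(counts, dtype=np.int64)
    starts = np.asarray(starts, dtype=np.int64)
    return np.cumsum(counts), starts, counts


def _draw_starts(rng, cum, starts, counts, n):
    r = rng.integers(0, cum[-1], size=n)
    idx = np.searchsorted(cum, r, side="right")
    prev = np.where(idx > 0, cum[idx - 1], 0)
    return starts[idx] + (r - prev)


def count_pairs_vectorised(a_starts, len_a: int, b_starts, len_b: int,
                           max_gap: int) -> int:
    """Pairs (a, b) that do not overlap and have <= max_gap intervening bases.

    Coordinates are on a single line; the caller guarantees sites from
    different chromosomes are farther apart than any admissible gap.
    """
    a = np.sort(np.asarray(a_starts, dtype=np.int64))
    b = np.sort(np.asarray(b_starts, dtype=np.int64))
    a_end = a + len_a
    # b downstream of a: 0 <= b.start - a.end <= max_gap
    down = (np.searchsorted(b, a_end + max_gap, side="right")
            - np.searchsorted(b, a_end, side="left"))
    # b upstream of a: 0 <= a.start - b.end <= max_gap
    up = (np.searchsorted(b, a - len_b, side="right")
          - np.searchsorted(b, a - len_b - max_gap, side="left"))
    return int(down.sum() + up.sum())


def placement_null(regions: RegionSet, n_a: int, len_a: int, n_b: int, len_b: int, *,
                   max_gap: int = 40, n_sims: int = 1000, seed: int | None = None,
                   observed: int | None = None) -> SimulationNull:
    """Monte-Carlo null for the gap-constrained pair count.

    Each simulation draws ``n_a`` sites of length ``len_a`` and ``n_b``
    sites of length ``len_b`` with starts uniform (with replacement) over
    all positions where the site fits entirely inside a single region, then
    counts non-overlapping pairs with gap <= ``max_gap``.  Sites may
    overlap one another, as real motif matches may.  Reproducible from
    ``seed``.
    """
    if n_sims < 2:
        raise ValueError("n_sims must be >= 2 (sd undefined otherwise)")
    rng = np.random.default_rng(seed)
    cum_a, st_a, ct_a = _placement_universe(regions, len_a)
    cum_b, st_b, ct_b = _placement_universe(regions, len_b)
    counts = np.empty(n_sims, dtype=np.int64)
    for s in range(n_sims):
        a = _draw_starts(rng, cum_a, st_a, ct_a, n_a)
        b = _draw_starts(rng, cum_b, st_b, ct_b, n_b)
        counts[s] = count_pairs_vectorised(a, len_a, b, len_b, max_gap)
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1))
    z = p_norm = p_emp = None
    if observed is not None:
        if sd > 0:
            z, p_norm = zscore_normal_p(observed, mean, sd)
        p_emp = (1 + int((counts >= observed).sum())) / (n_sims + 1)
    return SimulationNull(n_sims=n_sims, counts=tuple(int(c) for c in counts),
                          mean=mean, sd=sd, observed=observed, z=z,
                          p_normal=p_norm, p_empirical=p_emp, seed=seed)
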