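"""Unconditional exact association statistics for small case-control tables.

The centrepiece is Barnard's unconditional exact test of superiority for a
2x2 table of two independent binomials, ordered by the pooled-variance Wald
statistic

    W = (x1/n1 - x2/n2) / sqrt( p(1-p) (1/n1 + 1/n2) ),   p = (x1+x2)/(n1+n2).

The two-sided rejection region is {|W(y1, y2)| >= |W_obs|}; its probability
is maximised over the unknown common success probability pi (the nuisance
parameter) on a dense grid followed by bounded local refinement.  For small
cohorts this test is more powerful than conditional tests (Fisher) because
it does not condition on the table margins.

Also here: dominant-model genotype collapsing (carriers = heterozygotes +
minor homozygotes), carrier odds ratios, and the Pearson chi-square test of
Hardy-Weinberg equilibrium (1 df).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "CohortGenotypes",
    "ContingencyTable2x2",
    "BarnardResult",
    "HWEResult",
    "dominant_collapse",
    "wald_statistic",
    "wald_grid",
    "barnard_two_sided",
    "odds_ratio",
    "carrier_comparison",
    "hwe_chi2",
]


@dataclass(frozen=True)
class CohortGenotypes:
    """Genotype counts for one cohort at a biallelic SNP (major allele C)."""

    label: str
    n_CC: int
    n_CT: int
    n_TT: int

    def __post_init__(self):
        for name in ("n_CC", "n_CT", "n_TT"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{self.label}: {name} must be a non-negative integer")
        if self.total == 0:
            raise ValueError(f"{self.label}: empty cohort")

    @property
    def total(self) -> int:
        return self.n_CC + self.n_CT + self.n_TT

    @property
    def minor_allele_freq(self) -> float:
        return (2 * self.n_TT + self.n_CT) / (2 * self.total)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Carrier counts x out of n in two independent groups."""

    group1_label: str
    group2_label: str
    x1: int
    n1: int
    x2: int
    n2: int

    def __post_init__(self):
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("group sizes must be >= 1")
        if not (0 <= self.x1 <= self.n1 and 0 <= self.x2 <= self.n2):
            raise ValueError("carrier counts must lie in [0, n]")

    def swapped(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(
            self.group2_label, self.group1_label, self.x2, self.n2, self.x1, self.n1
        )


@dataclass(frozen=True)
class BarnardResult:
    W_obs: float
    p_two_sided: float
    pi_star: float
    grid_step: float
    alternative: str = "two-sided"


@dataclass(frozen=True)
class HWEResult:
    chi2: float
    p: float
    expected: tuple[float, float, float]  # CC, CT, TT


def dominant_collapse(c: CohortGenotypes) -> tuple[int, int]:
    """Dominant-model grouping: carriers = CT + TT, total unchanged."""
    return c.n_CT + c.n_TT, c.total


def wald_grid(n1: int, n2: int) -> np.ndarray:
    """Pooled Wald statistic for every outcome table (y1, y2).

    Shape (n1+1, n2+1).  Tables with pooled proportion 0 or 1 have zero
    pooled variance; W is defined as 0 there (they are maximally
    unsurprising under any common pi at the boundary).
    """
    y1 = np.arange(n1 + 1, dtype=float)[:, None]
    y2 = np.arange(n2 + 1, dtype=float)[None, :]
    pooled = (y1 + y2) / (n1 + n2)
    var = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = (y1 / n1 - y2 / n2) / np.sqrt(var)
    return np.where(var > 0, w, 0.0)


def wald_statistic(t: ContingencyTable2x2) -> float:
    """Standardized difference of the two binomial proportions (group1 - group2)."""
    return float(wald_grid(t.n1, t.n2)[t.x1, t.x2])


_TIE_TOL = 1e-12  # tables whose |W| equals |W_obs| up to fp noise are extreme


def _extreme_region(t: ContingencyTable2x2, alternative: str) -> np.ndarray:
    w = wald_grid(t.n1, t.n2)
    w_obs = w[t.x1, t.x2]
    if alternative == "two-sided":
        return np.abs(w) >= abs(w_obs) - _TIE_TOL
    if alternative == "less":
        return w <= w_obs + _TIE_TOL
    if alternative == "greater":
        return w >= w_obs - _TIE_TOL
    raise ValueError(f"unknown alternative {alternative!r}")


def _tail_coefficients(t: ContingencyTable2x2, extreme: np.ndarray) -> np.ndarray:
    """Collapse the extreme region onto total-success counts.

    Under a common pi, P(y1, y2) = C(n1,y1) C(n2,y2) pi^s (1-pi)^(N-s) with
    s = y1 + y2, so the tail probability is a polynomial with coefficients
    A_s = sum of binomial-coefficient products over extreme tables at each s.
    """
    n1, n2 = t.n1, t.n2
    c1 = special.comb(n1, np.arange(n1 + 1))
    c2 = special.comb(n2, np.arange(n2 + 1))
    prod = np.outer(c1, c2) * extreme
    coeffs = np.zeros(n1 + n2 + 1)
    s_index = np.add.outer(np.arange(n1 + 1), np.arange(n2 + 1))
    np.add.at(coeffs, s_index.ravel(), prod.ravel())
    return coeffs


def _tail_at(coeffs: np.ndarray, pis: np.ndarray, N: int) -> np.ndarray:
    """Evaluate the tail polynomial in log space at each nuisance value."""
    pis = np.atleast_1d(np.asarray(pis, dtype=float))
    s = np.arange(N + 1, dtype=float)
    with np.errstate(divide="ignore"):
        logpi = np.log(pis)[None, :]
        log1m = np.log1p(-pis)[None, :]
    # 0 * log(0) = 0 convention at the boundary
    terms = np.where(s[:, None] > 0, s[:, None] * logpi, 0.0) + np.where(
        (N - s)[:, None] > 0, (N - s)[:, None] * log1m, 0.0
    )
    with np.errstate(over="ignore"):
        vals = np.exp(terms)
    return coeffs @ vals


def barnard_two_sided(
    t: ContingencyTable2x2,
    grid_step: float = 1e-4,
    alternative: str = "two-sided",
) -> BarnardResult:
    """Barnard's unconditional exact test, absolute-Wald ordering.

    Enumerates all (n1+1) x (n2+1) outcome tables, forms the extreme set
    E = {|W| >= |W_obs|} (or the one-sided analogue), and maximises
    tail(pi) = sum over E of Binom(y1; n1, pi) Binom(y2; n2, pi) over a grid
    of the nuisance proportion with step ``grid_step`` on (0, 1), followed
    by golden-section refinement in the best grid cell.

    A degenerate observed table (all carriers or none across both groups)
    has W_obs = 0, the extreme set is everything and p = 1.
    """
    if not 0.0 < grid_step <= 1e-3:
        raise ValueError("grid_step must be in (0, 0.001]")
    extreme = _extreme_region(t, alternative)
    w_obs = wald_statistic(t)
    coeffs = _tail_coefficients(t, extreme)
    N = t.n1 + t.n2

    eps = 1e-8
    pis = np.arange(grid_step, 1.0, grid_step)
    pis = np.clip(pis, eps, 1.0 - eps)
    tails = _tail_at(coeffs, pis, N)
    best = int(np.argmax(tails))
    p_grid = float(tails[best])
    pi_grid = float(pis[best])

    lo = pis[best - 1] if best > 0 else eps
    hi = pis[best + 1] if best < len(pis) - 1 else 1.0 - eps
    res = optimize.minimize_scalar(
        lambda pi: -float(_tail_at(coeffs, np.array([pi]), N)[0]),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    if -res.fun > p_grid:
        p_max, pi_star = float(-res.fun), float(res.x)
    else:
        p_max, pi_star = p_grid, pi_grid
    return BarnardResult(
        W_obs=w_obs,
        p_two_sided=min(p_max, 1.0),
        pi_star=pi_star,
        grid_step=grid_step,
        alternative=alternative,
    )


def odds_ratio(t: ContingencyTable2x2, haldane: bool = False, flip: bool = False) -> float:
    """Carrier odds ratio, group2 (case/severe) versus group1 (reference).

    OR = [x2 / (n2 - x2)] / [x1 / (n1 - x1)].  ``haldane`` adds 0.5 to every
    cell (the Haldane-Anscombe correction) when a zero cell would otherwise
    make the ratio undefined; ``flip`` inverts the orientation.
    """
    cells = {
        "group1 carriers": t.x1,
        "group1 non-carriers": t.n1 - t.x1,
        "group2 carriers": t.x2,
        "group2 non-carriers": t.n2 - t.x2,
    }
    if haldane:
        a, b, c, d = (v + 0.5 for v in cells.values())
    else:
        zero = [name for name, v in cells.items() if v == 0]
        if zero:
            raise ZeroDivisionError(
                f"zero cell ({', '.join(zero)}); enable the Haldane correction"
            )
        a, b, c, d = cells.values()
    or_ = (c / d) / (a / b)
    return 1.0 / or_ if flip else or_


def carrier_comparison(
    c1: CohortGenotypes,
    c2: CohortGenotypes,
    grid_step: float = 1e-4,
    alternative: str = "two-sided",
    haldane: bool = False,
) -> dict:
    """Dominant-model comparison of two cohorts: collapse to carriers,
    run the unconditional exact test, and report the carrier odds ratio of
    group2 versus group1 (Haldane-corrected only on request).  Returns a
    flat record suitable for a report row."""
    x1, n1 = dominant_collapse(c1)
    x2, n2 = dominant_collapse(c2)
    table = ContingencyTable2x2(c1.label, c2.label, x1, n1, x2, n2)
    res = barnard_two_sided(table, grid_step=grid_step, alternative=alternative)
    try:
        or_ = odds_ratio(table, haldane=haldane)
    except ZeroDivisionError:
        or_ = float("nan")
    return {
        "group1": c1.label,
        "group2": c2.label,
        "carriers1": x1,
        "n1": n1,
        "carriers2": x2,
        "n2": n2,
        "wald": res.W_obs,
        "p_value": res.p_two_sided,
        "pi_star": res.pi_star,
        "odds_ratio": or_,
        "alternative": res.alternative,
    }


def hwe_chi2(c: CohortGenotypes) -> HWEResult:
    """Pearson chi-square test of Hardy-Weinberg equilibrium (1 df).

    Expected genotype counts at the observed minor-allele frequency q are
    n * [(1-q)^2, 2q(1-q), q^2].  A monomorphic cohort (q in {0, 1}) carries
    no information: chi2 = 0, p = 1, with a warning.
    """
    n = c.total
    q = c.minor_allele_freq
    if q in (0.0, 1.0):
        warnings.warn(f"{c.label}: monomorphic cohort, HWE test degenerate")
        exp = (n * (1 - q) ** 2, n * 2 * q * (1 - q), n * q**2)
        return HWEResult(chi2=0.0, p=1.0, expected=exp)
    exp = (n * (1 - q) ** 2, n * 2 * q * (1 - q), n * q**2)
    obs = (c.n_CC, c.n_CT, c.n_TT)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(obs, exp))
    p = float(stats.chi2.sf(chi2, df=1))
    return HWEResult(chi2=float(chi2), p=p, expected=exp)
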