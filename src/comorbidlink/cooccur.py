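"""Population-scaled 2x2 co-occurrence tables and association statistics.

The model scales a within-cohort exposure proportion up to a synthetic
population of fixed size using published marginal rates: the exposure
prevalence fixes the exposure margin, the sex-specific disease incidence
fixes the case margin, and the joint cell is the cohort proportion applied
to the case margin.  Cell allocation is deterministic rounding of
expectations by default; a seeded multinomial draw is available for a
stochastic reading of the same cell probabilities.

Association measures are the classical ones for a 2x2 table::

    OR = ad / bc          RR = (a/(a+b)) / (c/(c+d))

with Fisher's exact (conditional hypergeometric) test computed in log
space so that population sizes of 1e7 are handled without underflow.
The two-sided convention is "minlike": the sum of probabilities of all
tables, with margins fixed, whose point probability does not exceed the
observed one (relative tie tolerance 1e-7).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .cohort import ConditionalProbability

__all__ = [
    "PopulationRates",
    "ContingencyTable",
    "AssociationResult",
    "build_population_table",
    "odds_ratio",
    "relative_risk",
    "fisher_exact",
    "run_cooccurrence",
]

#: relative tolerance for point-probability ties in the minlike two-sided test
TIE_RTOL = 1e-7


@dataclass(frozen=True)
class PopulationRates:
    """Marginal rates for one stratum of the synthetic population."""

    dm_prevalence: float
    hnscc_incidence: float
    population_size: int = 10_000_000

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        for name in ("dm_prevalence", "hnscc_incidence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.dm_prevalence + self.hnscc_incidence > 1.0:
            raise ValueError("dm_prevalence + hnscc_incidence exceeds 1")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 cross-tabulation: a = both conditions, b = exposure only,
    c = disease only, d = neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def dm_margin(self) -> int:
        return self.a + self.b

    @property
    def hnscc_margin(self) -> int:
        return self.a + self.c

    @property
    def joint_probability(self) -> float:
        """P(both conditions) in the synthetic population, a / N."""
        return self.a / self.total

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class AssociationResult:
    """OR, RR and exact-test p-value for one stratum."""

    odds_ratio: float
    relative_risk: float
    p_value: float
    log10_p: float
    continuity_applied: bool = False


def build_population_table(
    rates: PopulationRates,
    p_joint_given_case: ConditionalProbability | float,
    *,
    stochastic: bool = False,
    seed: int | None = None,
) -> ContingencyTable:
    """Allocate a synthetic population of size N to the four cells.

    Margins are ``M_h = round(N * incidence)`` (cases) and
    ``M_d = round(N * prevalence)`` (exposed); the joint cell is
    ``a = round(p * M_h)`` where ``p`` is the within-cohort exposure
    proportion among cases.  With ``stochastic=True`` the four cells are
    instead a single seeded multinomial draw over the implied cell
    probabilities (margins then hold only in expectation).
    """
    p = (
        p_joint_given_case.value
        if isinstance(p_joint_given_case, ConditionalProbability)
        else float(p_joint_given_case)
    )
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"conditional probability must lie in [0, 1], got {p}")
    n = rates.population_size
    m_h = round(n * rates.hnscc_incidence)
    m_d = round(n * rates.dm_prevalence)
    a = round(p * m_h)
    c = m_h - a
    b = m_d - a
    d = n - a - b - c
    if min(a, b, c, d) < 0:
        raise ValueError(
            "inconsistent rates: parameters imply a negative cell "
            f"(a={a}, b={b}, c={c}, d={d})"
        )
    if stochastic:
        rng = np.random.default_rng(seed)
        probs = np.array([a, b, c, d], dtype=float) / n
        a, b, c, d = (int(x) for x in rng.multinomial(n, probs))
    return ContingencyTable(a, b, c, d)


def _corrected(table: ContingencyTable, continuity: bool) -> tuple[float, ...]:
    shift = 0.5 if continuity else 0.0
    return tuple(x + shift for x in table.cells())


def odds_ratio(table: ContingencyTable, continuity: bool = False) -> float:
    """Cross-product ratio ad/bc; Haldane-Anscombe 0.5 on request."""
    a, b, c, d = _corrected(table, continuity)
    if b * c == 0:
        raise ZeroDivisionError("undefined OR; enable continuity correction")
    return (a * d) / (b * c)


def relative_risk(table: ContingencyTable, continuity: bool = False) -> float:
    """Risk ratio (a/(a+b)) / (c/(c+d)); Haldane-Anscombe 0.5 on request."""
    a, b, c, d = _corrected(table, continuity)
    if a + b == 0 or c + d == 0:
        raise ZeroDivisionError("undefined RR: empty row")
    if c == 0:
        raise ZeroDivisionError("undefined RR; enable continuity correction")
    return (a / (a + b)) / (c / (c + d))


def fisher_log_pvalue(table: ContingencyTable, alternative: str = "two_sided") -> float:
    """Natural-log Fisher exact p-value, computed entirely in log space.

    Conditioning on both margins, the joint cell follows a hypergeometric
    distribution; the full support is at most ``min(margins) + 1`` wide, so
    even N = 1e7 tables enumerate a short vector of log-pmf values.
    """
    a = table.a
    n = table.total
    row1 = table.dm_margin
    col1 = table.hnscc_margin
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    logpmf = hypergeom.logpmf(support, n, row1, col1)
    obs = logpmf[a - lo]
    if alternative == "two_sided":
        mask = logpmf <= obs + np.log1p(TIE_RTOL)
    elif alternative == "greater":
        mask = support >= a
    elif alternative == "less":
        mask = support <= a
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(min(0.0, logsumexp(logpmf[mask])))


def fisher_exact(table: ContingencyTable, alternative: str = "two_sided") -> float:
    """Fisher exact p-value; may underflow to 0.0 for extreme tables
    (use :func:`fisher_log_pvalue` when the magnitude matters)."""
    return float(np.exp(fisher_log_pvalue(table, alternative)))


def run_cooccurrence(
    rates_by_sex: dict[str, PopulationRates],
    probabilities_by_sex: dict[str, ConditionalProbability | float],
) -> dict[str, tuple[ContingencyTable, AssociationResult]]:
    """Build per-stratum tables and association statistics in one pass.

    Returns a mapping ``sex -> (ContingencyTable, AssociationResult)``
    covering every stratum present in both inputs.
    """
    if set(rates_by_sex) != set(probabilities_by_sex):
        raise ValueError("rates and probabilities must cover the same strata")
    out: dict[str, tuple[ContingencyTable, AssociationResult]] = {}
    for sex in sorted(rates_by_sex):
        table = build_population_table(rates_by_sex[sex], probabilities_by_sex[sex])
        logp = fisher_log_pvalue(table)
        out[sex] = (
            table,
            AssociationResult(
                odds_ratio=odds_ratio(table),
                relative_risk=relative_risk(table),
                p_value=float(np.exp(logp)),
                log10_p=logp / np.log(10.0),
            ),
        )
    return out
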