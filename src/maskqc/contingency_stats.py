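"""Evaluation statistics over confusion counts.

False-positive rate = FP / (FP + TN) over validated negative sites;
false-negative rate = FN / (FN + TP) over validated positive sites.

Significance of a difference in false-positive counts between two
preprocessing methods is assessed with Fisher's exact test on the 2x2
table of (FP, TN) per method — computed here by direct enumeration of the
hypergeometric distribution in log-factorial space, which is exact and
overflow-safe from Sanger-panel scale (n ~ 170) up to whole-SNP-catalogue
scale (n ~ 3x10^5). Pearson's chi-square test is provided for larger
tables where every expected count is comfortable (the exact test remains
the right tool when some cell is below five).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Collection, Literal, Optional, Sequence

import numpy as np
from scipy.stats import chi2 as _chi2_dist

from .errors import DegenerateTableError, UndefinedRateError

Sidedness = Literal["greater", "less", "two_sided"]

# Relative tolerance for the R-style two-sided rule: a table is counted when
# its point probability is <= that of the observed table up to rounding noise.
_TWO_SIDED_REL_EPS = 1e-7


@dataclass(frozen=True)
class ConfusionCounts:
    """True/false positive/negative counts against a validated truth set."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def positives(self) -> int:
        """Validated-positive total (TP + FN)."""
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        """Validated-negative total (FP + TN)."""
        return self.fp + self.tn


@dataclass(frozen=True)
class Table2x2:
    """A 2x2 contingency table: row 1 = (a, b), row 2 = (c, d)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError("table cells must be non-negative")
        if sum(cells) == 0:
            raise DegenerateTableError("all-zero 2x2 table")


@dataclass(frozen=True)
class TestResult:
    statistic: Optional[float]  # chi-square statistic; None for Fisher
    p_value: float
    sidedness: Sidedness
    df: Optional[int] = None  # chi-square only

    def as_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "sidedness": self.sidedness,
            "df": self.df,
        }


def fp_rate(c: ConfusionCounts) -> float:
    """False-positive rate: FP / (FP + TN)."""
    if c.negatives == 0:
        raise UndefinedRateError("fp_rate undefined: no validated negatives")
    return c.fp / c.negatives


def fn_rate(c: ConfusionCounts) -> float:
    """False-negative rate: FN / (FN + TP)."""
    if c.positives == 0:
        raise UndefinedRateError("fn_rate undefined: no validated positives")
    return c.fn / c.positives


def _log_hypergeom_pmf_table(r1: int, r2: int, c1: int) -> tuple[int, list[float]]:
    """Log pmf of cell 'a' over its feasible range with all margins fixed.

    Returns (lo, log_pmf) where log_pmf[i] is the log probability of a = lo+i.
    """
    n = r1 + r2
    lf = math.lgamma  # lf(k+1) = log k!
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    const = lf(r1 + 1) + lf(r2 + 1) + lf(c1 + 1) + lf(n - c1 + 1) - lf(n + 1)
    out = []
    for a in range(lo, hi + 1):
        out.append(
            const
            - lf(a + 1)
            - lf(r1 - a + 1)
            - lf(c1 - a + 1)
            - lf(r2 - c1 + a + 1)
        )
    return lo, out


def fisher_exact(t: Table2x2, sidedness: Sidedness = "greater") -> TestResult:
    """Fisher's exact test on a 2x2 table by hypergeometric enumeration.

    With all margins fixed, the first cell ``a`` is hypergeometric.
    'greater' returns P(X >= a), 'less' returns P(X <= a), and 'two_sided'
    sums the probabilities of every table at most as probable as the one
    observed (the convention of R's ``fisher.test``).
    """
    if sidedness not in ("greater", "less", "two_sided"):
        raise ValueError(f"unknown sidedness: {sidedness!r}")
    r1, r2 = t.a + t.b, t.c + t.d
    c1 = t.a + t.c
    lo, log_pmf = _log_hypergeom_pmf_table(r1, r2, c1)
    pmf = [math.exp(lp) for lp in log_pmf]
    i_obs = t.a - lo
    if sidedness == "greater":
        p = sum(pmf[i_obs:])
    elif sidedness == "less":
        p = sum(pmf[: i_obs + 1])
    else:
        cutoff = pmf[i_obs] * (1.0 + _TWO_SIDED_REL_EPS)
        p = sum(x for x in pmf if x <= cutoff)
    return TestResult(statistic=None, p_value=min(p, 1.0), sidedness=sidedness)


def chi_square(
    observed: Sequence[Sequence[float]] | Sequence[float] | np.ndarray,
    yates: bool = False,
) -> TestResult:
    """Pearson's chi-square test on a rectangular table of counts.

    For an r x c table the expected counts come from the independence model
    (row margin x column margin / grand total) with df = (r-1)(c-1). A
    one-row (or 1-D) table is treated as a goodness-of-fit test against the
    uniform distribution with df = k-1. The p-value is the upper tail of
    the chi-square distribution. ``yates`` applies the continuity
    correction (|O-E| reduced by 0.5) — meaningful for 2x2 tables only.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim == 1:
        obs = obs[None, :]
    if obs.ndim != 2:
        raise ValueError("observed must be 1- or 2-dimensional")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    total = obs.sum()
    if total == 0:
        raise DegenerateTableError("empty table")
    nr, nc = obs.shape
    if nr == 1:
        expected = np.full(nc, total / nc)
        df = nc - 1
        obs = obs[0]
    else:
        row = obs.sum(axis=1)
        col = obs.sum(axis=0)
        if (row == 0).any() or (col == 0).any():
            raise DegenerateTableError("zero row or column margin")
        expected = np.outer(row, col) / total
        df = (nr - 1) * (nc - 1)
    if (expected <= 0).any():
        raise DegenerateTableError("expected count of zero under independence")
    dev = np.abs(obs - expected)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float((dev**2 / expected).sum())
    p = float(_chi2_dist.sf(stat, df))
    return TestResult(statistic=stat, p_value=max(p, np.nextafter(0, 1)),
                      sidedness="two_sided", df=df)


def confusion_from_calls(
    called: Collection[int],
    truth_pos: Collection[int],
    truth_neg: Collection[int],
) -> ConfusionCounts:
    """Score a call set against disjoint validated positive/negative site sets.

    Calls at positions outside both truth sets are ignored — the accounting
    mirrors verification panels where only assayed sites can be scored.
    """
    pos, neg, calls = set(truth_pos), set(truth_neg), set(called)
    if pos & neg:
        raise ValueError("truth_pos and truth_neg overlap")
    return ConfusionCounts(
        tp=len(calls & pos),
        fn=len(pos - calls),
        fp=len(calls & neg),
        tn=len(neg - calls),
    )


def percent(rate: float, decimals: int = 1) -> float:
    """A proportion as a percentage rounded for display (0.0698 -> 7.0)."""
    return round(rate * 100.0, decimals)


def round_p(p: float, sig: int = 2) -> float:
    """A p-value rounded to ``sig`` significant figures (0.014278 -> 0.014)."""
    if p <= 0:
        return 0.0
    return round(p, -int(math.floor(math.log10(abs(p)))) + (sig - 1))
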