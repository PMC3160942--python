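"""Population- and individual-level agreement statistics between COD methods.

Population level: cause-specific mortality fractions (CSMF), the proportion
of all deaths attributed to each cause, with a tolerance check against a
gold-standard CSMF.  Individual level: K×K cross-classification, Cohen's
kappa with a large-sample confidence interval, Fleiss' kappa for three
raters with a subject-level bootstrap interval, one-vs-rest validity metrics
(sensitivity, specificity, PPV, NPV) with exact binomial intervals, and the
simple two-of-three agreement indicator.

Indeterminate verdicts never count as agreement — not even with each other.
This is implemented by relabelling each method's indeterminates to a
method-specific sentinel before tabulation (``indeterminate_policy=
"mismatch"``, the default); ``"drop"`` removes deaths where any compared
method is indeterminate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .cohort import INDETERMINATE, CauseList
from .util import round_half_up

KAPPA_STRENGTH_BANDS = (
    (0.21, "poor"),
    (0.41, "fair"),
    (0.61, "moderate"),
    (0.81, "good"),
    (np.inf, "very good"),
)


class UndefinedKappaError(ValueError):
    """Chance agreement is 1 (both raters constant and equal): kappa undefined."""


# ---------------------------------------------------------------------------
# CSMF


@dataclass
class CSMFTable:
    """Per-category mortality fractions over a cohort, indeterminate included."""

    fractions: pd.Series
    n_total: int

    def __post_init__(self) -> None:
        if not np.isclose(self.fractions.sum(), 1.0, atol=1e-9):
            raise ValueError("CSMF fractions must sum to 1")

    def percentages(self, ndigits: int = 1) -> pd.Series:
        """Fractions as round-half-up percentages to ``ndigits`` decimals."""
        return self.fractions.map(lambda f: round_half_up(100.0 * f, ndigits))


def csmf(assignments, cause_list: CauseList) -> CSMFTable:
    """Cause-specific mortality fractions of an assignment vector."""
    s = pd.Series(list(assignments), dtype=object)
    if len(s) == 0:
        raise ValueError("cannot compute CSMF of zero deaths")
    bad = set(s) - set(cause_list.reporting_categories)
    if bad:
        raise ValueError(f"assignments outside the cause list: {sorted(bad)}")
    counts = s.value_counts().reindex(cause_list.reporting_categories, fill_value=0)
    return CSMFTable(fractions=counts / len(s), n_total=len(s))


def csmf_tolerance_check(
    csmf_method: CSMFTable, csmf_gold: CSMFTable, tolerance: float = 0.05
) -> pd.DataFrame:
    """Per-cause |method − gold| against a tolerance, in percentage points."""
    if not csmf_method.fractions.index.equals(csmf_gold.fractions.index):
        raise ValueError("CSMF tables use different category lists")
    diff_pp = 100.0 * (csmf_method.fractions - csmf_gold.fractions)
    return pd.DataFrame(
        {
            "method_pct": csmf_method.percentages(),
            "gold_pct": csmf_gold.percentages(),
            "abs_diff_pp": diff_pp.abs(),
            "within_tolerance": diff_pp.abs() <= 100.0 * tolerance + 1e-12,
        }
    )


# ---------------------------------------------------------------------------
# Cross-classification and kappa


def _apply_indeterminate_policy(
    vectors: list[pd.Series], policy: str
) -> tuple[list[pd.Series], list[str]]:
    """Relabel or drop indeterminates so they never land on a diagonal."""
    if policy == "mismatch":
        out, extra = [], []
        for i, v in enumerate(vectors):
            sentinel = f"{INDETERMINATE} ({i + 1})"
            out.append(v.where(v != INDETERMINATE, sentinel))
            extra.append(sentinel)
        return out, extra
    if policy == "drop":
        keep = ~np.logical_or.reduce([v == INDETERMINATE for v in vectors])
        return [v[keep].reset_index(drop=True) for v in vectors], []
    raise ValueError(f"unknown indeterminate policy {policy!r}")


def contingency(assign_a, assign_b, categories) -> pd.DataFrame:
    """K×K cross-classification of two methods' assignments.

    ``categories`` is the shared condensed list; indeterminate gets its own
    row and column.  Cell (i, j) counts deaths with method A = i, B = j.
    """
    a = pd.Series(list(assign_a), dtype=object)
    b = pd.Series(list(assign_b), dtype=object)
    if len(a) != len(b):
        raise ValueError("assignment vectors must be paired (equal length)")
    cats = list(categories)
    if INDETERMINATE not in cats:
        cats.append(INDETERMINATE)
    bad = (set(a) | set(b)) - set(cats)
    if bad:
        raise ValueError(f"assignments outside the category list: {sorted(bad)}")
    table = pd.crosstab(a, b).reindex(index=cats, columns=cats, fill_value=0)
    table.index.name, table.columns.name = "method_a", "method_b"
    return table


@dataclass
class AgreementResult:
    """A chance-corrected agreement coefficient with its 95% interval."""

    kappa: float
    p_a: float
    p_e: float
    ci_low: float
    ci_high: float
    strength: str
    n: int

    def __str__(self) -> str:  # matches the usual table cell format
        return f"{self.kappa:.2f} ({self.ci_low:.2f}-{self.ci_high:.2f})"


def cohen_kappa(table: pd.DataFrame) -> AgreementResult:
    """Cohen's kappa of a square contingency table.

    κ = (P_A − P_E) / (1 − P_E) with P_A the observed agreement proportion
    and P_E the chance agreement from the marginals.  The 95% CI uses the
    large-sample (Fleiss–Cohen–Everitt) standard error, truncated to [−1, 1].
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("contingency table must be square")
    if np.any(t < 0):
        raise ValueError("contingency table counts must be non-negative")
    n = t.sum()
    if n < 1:
        raise ValueError("contingency table is empty")
    p = t / n
    p_a = float(np.trace(p))
    row, col = p.sum(axis=1), p.sum(axis=0)
    p_e = float(row @ col)
    if np.isclose(p_e, 1.0, atol=1e-12):
        raise UndefinedKappaError(
            "both raters are constant and identical; kappa is undefined"
        )
    kappa = (p_a - p_e) / (1.0 - p_e)

    # asymptotic variance, Fleiss, Cohen & Everitt (1969)
    a = float(np.diag(p) @ (1.0 - (row + col) * (1.0 - kappa)) ** 2)
    cross = (col[None, :] + row[:, None]) ** 2  # (p_.j + p_i.)² for cell (i, j)
    off = p * cross
    np.fill_diagonal(off, 0.0)
    b = (1.0 - kappa) ** 2 * float(off.sum())
    c = (kappa - p_e * (1.0 - kappa)) ** 2
    var = max((a + b - c) / (n * (1.0 - p_e) ** 2), 0.0)
    se = float(np.sqrt(var))
    return AgreementResult(
        kappa=float(kappa),
        p_a=p_a,
        p_e=p_e,
        ci_low=max(kappa - 1.96 * se, -1.0),
        ci_high=min(kappa + 1.96 * se, 1.0),
        strength=kappa_strength(float(np.clip(kappa, -1.0, 1.0))),
        n=int(round(n)),
    )


def pairwise_kappa(
    assign_a,
    assign_b,
    categories,
    indeterminate_policy: str = "mismatch",
) -> AgreementResult:
    """Cohen's kappa of two assignment vectors with indeterminate handling."""
    vecs = [pd.Series(list(assign_a), dtype=object),
            pd.Series(list(assign_b), dtype=object)]
    if len(vecs[0]) != len(vecs[1]):
        raise ValueError("assignment vectors must be paired (equal length)")
    vecs, extra = _apply_indeterminate_policy(vecs, indeterminate_policy)
    cats = list(categories)
    if INDETERMINATE not in cats:
        cats.append(INDETERMINATE)
    cats += extra
    table = pd.crosstab(vecs[0], vecs[1]).reindex(index=cats, columns=cats,
                                                  fill_value=0)
    return cohen_kappa(table)


def _fleiss_counts(vectors: list[pd.Series], categories: list[str]) -> np.ndarray:
    """Subjects × categories count matrix for Fleiss' kappa."""
    idx = {c: j for j, c in enumerate(categories)}
    n, k = len(vectors[0]), len(categories)
    counts = np.zeros((n, k), dtype=np.int64)
    for v in vectors:
        for i, label in enumerate(v):
            counts[i, idx[label]] += 1
    return counts


def _fleiss_from_counts(counts: np.ndarray) -> float:
    n, _ = counts.shape
    m = int(counts[0].sum())
    p_j = counts.sum(axis=0) / (n * m)
    p_bar = ((counts.astype(float) ** 2).sum() - n * m) / (n * m * (m - 1))
    p_e = float(p_j @ p_j)
    if np.isclose(p_e, 1.0, atol=1e-12):
        raise UndefinedKappaError("all raters constant and identical")
    return (p_bar - p_e) / (1.0 - p_e)


def multirater_kappa(
    assign_1,
    assign_2,
    assign_3,
    categories,
    indeterminate_policy: str = "mismatch",
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> AgreementResult:
    """Fleiss' kappa across three raters, CI by subject-level bootstrap.

    The bootstrap resamples deaths with replacement (``n_bootstrap`` times,
    seeded) and takes the 2.5/97.5 percentiles of the resampled statistic.
    """
    vecs = [pd.Series(list(v), dtype=object) for v in (assign_1, assign_2, assign_3)]
    if len({len(v) for v in vecs}) != 1:
        raise ValueError("the three assignment vectors must have equal length")
    n = len(vecs[0])
    if n == 0:
        raise ValueError("no subjects")
    vecs, extra = _apply_indeterminate_policy(vecs, indeterminate_policy)
    cats = list(categories)
    if INDETERMINATE not in cats:
        cats.append(INDETERMINATE)
    cats += extra
    bad = set().union(*[set(v) for v in vecs]) - set(cats)
    if bad:
        raise ValueError(f"assignments outside the category list: {sorted(bad)}")

    counts = _fleiss_counts(vecs, cats)
    kappa = _fleiss_from_counts(counts)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        sample = counts[rng.integers(0, n, size=n)]
        try:
            boots[b] = _fleiss_from_counts(sample)
        except UndefinedKappaError:
            boots[b] = 1.0  # resample happened to be unanimity
    ci_low, ci_high = np.percentile(boots, [2.5, 97.5])

    m = 3
    p_bar = ((counts.astype(float) ** 2).sum() - n * m) / (n * m * (m - 1))
    p_j = counts.sum(axis=0) / (n * m)
    return AgreementResult(
        kappa=float(kappa),
        p_a=float(p_bar),
        p_e=float(p_j @ p_j),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        strength=kappa_strength(float(np.clip(kappa, -1.0, 1.0))),
        n=n,
    )


def kappa_strength(kappa: float) -> str:
    """Verbal strength-of-agreement label for a kappa value.

    poor < 0.21 ≤ fair ≤ 0.40 < moderate ≤ 0.60 < good ≤ 0.80 < very good;
    band upper bounds are inclusive.
    """
    if not (-1.0 <= kappa <= 1.0):
        raise ValueError(f"kappa must lie in [-1, 1], got {kappa}")
    for upper, label in KAPPA_STRENGTH_BANDS:
        if kappa < upper:
            return label
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# One-vs-rest validity metrics


def _pct_ci(count: int, nobs: int) -> tuple[float | None, float | None, float | None]:
    """Percentage and exact (Clopper–Pearson) 95% bounds; None when 0/0."""
    if nobs == 0:
        return None, None, None
    low, high = proportion_confint(count, nobs, alpha=0.05, method="beta")
    return 100.0 * count / nobs, 100.0 * low, 100.0 * high


@dataclass
class ValidityTable:
    """One-vs-rest 2×2 counts and the derived diagnostic metrics.

    Metrics are percentages with exact binomial 95% CIs; a metric whose
    denominator is zero is ``None`` (not applicable), never 0.
    """

    cause: str
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self):
        return _pct_ci(self.tp, self.tp + self.fn)

    @property
    def specificity(self):
        return _pct_ci(self.tn, self.tn + self.fp)

    @property
    def ppv(self):
        return _pct_ci(self.tp, self.tp + self.fp)

    @property
    def npv(self):
        return _pct_ci(self.tn, self.tn + self.fn)

    def as_row(self) -> dict:
        row: dict = {"cause": self.cause, "tp": self.tp, "fp": self.fp,
                     "tn": self.tn, "fn": self.fn}
        for name in ("sensitivity", "ppv", "specificity", "npv"):
            val, lo, hi = getattr(self, name)
            row[name] = val
            row[f"{name}_ci_low"] = lo
            row[f"{name}_ci_high"] = hi
        return row


def two_by_two(pred, gold, cause: str) -> ValidityTable:
    """Dichotomise both methods one-vs-rest on ``cause`` and tally the 2×2.

    Indeterminate predictions count as 'not this cause', so they can only be
    true negatives or false negatives.
    """
    p = np.asarray(list(pred), dtype=object)
    g = np.asarray(list(gold), dtype=object)
    if p.shape != g.shape:
        raise ValueError("prediction and gold vectors must be paired")
    pp, gp = p == cause, g == cause
    return ValidityTable(
        cause=cause,
        tp=int(np.sum(pp & gp)),
        fp=int(np.sum(pp & ~gp)),
        tn=int(np.sum(~pp & ~gp)),
        fn=int(np.sum(~pp & gp)),
    )


def agreement_indicator(c_interva: str, c_pcva: str, c_hcod: str) -> int:
    """1 when at least two of the three labels agree, else 0.

    Indeterminate never matches anything, including another indeterminate.
    """
    labels = [c_interva, c_pcva, c_hcod]
    for a, b in itertools.combinations(labels, 2):
        if a == b and a != INDETERMINATE:
            return 1
    return 0
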