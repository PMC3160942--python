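"""Probabilistic cause-of-death assignment from VA indicators.

A naive-Bayes interpreter in the InterVA tradition: for each death the
posterior over causes is

    P(cause c | indicators)  ∝  prior(c) · Π_i  L_i(c)

where L_i(c) = emit(i, c) if indicator i is present, 1 − emit(i, c) if
absent, and 1 if unknown — an unknown (null) indicator contributes nothing.
The product is accumulated in log space.  Up to three causes are reported per
death under a configurable reporting policy; if no cause clears the threshold
the death is classed indeterminate.

Priors for designated causes whose local prevalence varies strongly between
settings (classically HIV and malaria) can be scaled by a high/low flag
before assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import (
    ABSENT,
    INDETERMINATE,
    PRESENT,
    DeathRecord,
    ProbabilityMatrix,
)
from .util import round_half_up

#: default prior multipliers for the high / low local-prevalence settings
HIGH_PREVALENCE_MULTIPLIER = 5.0
LOW_PREVALENCE_MULTIPLIER = 0.2


class DegeneratePosteriorError(ValueError):
    """Every cause has zero likelihood for this indicator profile."""


@dataclass(frozen=True)
class ReportingPolicy:
    """Thresholds governing how many causes a death is assigned.

    ``top_min``: minimum normalised posterior for any cause to be reported at
    all; below it the death is indeterminate.  ``extra_frac``: a second or
    third cause is reported only if its posterior is at least ``extra_frac``
    times the top cause's (and itself clears ``top_min``).
    """

    top_min: float = 0.4
    extra_frac: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.top_min < 1.0):
            raise ValueError("top_min must lie in (0, 1)")
        if not (0.0 < self.extra_frac <= 1.0):
            raise ValueError("extra_frac must lie in (0, 1]")


@dataclass
class CODAssignment:
    """Up to three (cause, normalised likelihood) pairs, or indeterminate."""

    causes: list[tuple[str, float]]
    indeterminate: bool
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.indeterminate != (len(self.causes) == 0):
            raise ValueError("indeterminate iff the cause list is empty")
        liks = [lik for _, lik in self.causes]
        if any(b > a + 1e-12 for a, b in zip(liks, liks[1:])):
            raise ValueError("likelihoods must be non-increasing")

    @property
    def top_cause(self) -> str:
        return self.causes[0][0] if self.causes else INDETERMINATE


def apply_prevalence(
    matrix: ProbabilityMatrix,
    flags: dict[str, str],
    high_multiplier: float = HIGH_PREVALENCE_MULTIPLIER,
    low_multiplier: float = LOW_PREVALENCE_MULTIPLIER,
) -> ProbabilityMatrix:
    """Scale flagged causes' priors by the high/low multiplier and renormalise.

    ``flags`` maps cause label -> ``"high"`` or ``"low"``.  Unflagged causes
    keep their relative priors.  Returns a new matrix; the input is untouched.
    """
    if high_multiplier <= 0 or low_multiplier <= 0:
        raise ValueError("prevalence multipliers must be positive")
    priors = matrix.priors.copy()
    for cause, level in flags.items():
        if cause not in matrix.causes:
            raise ValueError(f"unknown cause in prevalence flags: {cause!r}")
        if level not in ("high", "low"):
            raise ValueError(f"prevalence flag must be 'high' or 'low', got {level!r}")
        mult = high_multiplier if level == "high" else low_multiplier
        priors[matrix.causes.index(cause)] *= mult
    priors /= priors.sum()
    return ProbabilityMatrix(matrix.causes, matrix.indicators, priors, matrix.emit)


def posterior(indicators: np.ndarray, matrix: ProbabilityMatrix) -> np.ndarray:
    """Normalised P(cause | indicators) under conditional independence.

    Accumulated in log space so long indicator vectors cannot underflow.
    Raises :class:`DegeneratePosteriorError` when the profile is impossible
    under every cause (the caller treats that death as indeterminate).
    """
    indicators = np.asarray(indicators)
    if indicators.shape != (len(matrix.indicators),):
        raise ValueError(
            f"indicator vector length {indicators.shape} does not match matrix "
            f"({len(matrix.indicators)} indicators)"
        )
    with np.errstate(divide="ignore"):
        log_scores = np.log(matrix.priors)
        log_scores += np.log(matrix.emit[indicators == PRESENT]).sum(axis=0)
        log_scores += np.log1p(-matrix.emit[indicators == ABSENT]).sum(axis=0)
    top = log_scores.max()
    if not np.isfinite(top):
        raise DegeneratePosteriorError(
            "all causes have zero likelihood for this indicator profile"
        )
    post = np.exp(log_scores - top)
    return post / post.sum()


def assign_causes(
    indicators: np.ndarray,
    matrix: ProbabilityMatrix,
    policy: ReportingPolicy = ReportingPolicy(),
) -> CODAssignment:
    """Rank causes by posterior and report up to three under the policy.

    Ties are broken by cause-list order so batch runs are reproducible.
    """
    try:
        post = posterior(indicators, matrix)
    except DegeneratePosteriorError:
        return CODAssignment([], indeterminate=True, degenerate=True)
    order = np.argsort(-post, kind="stable")
    top = post[order[0]]
    if top < policy.top_min:
        return CODAssignment([], indeterminate=True)
    causes: list[tuple[str, float]] = []
    for j in order[:3]:
        p = float(post[j])
        if p >= policy.top_min and p >= policy.extra_frac * top:
            causes.append((matrix.causes.categories[j], p))
    return CODAssignment(causes, indeterminate=False)


def resolve_comparison_cause(assignment: CODAssignment, reference_cause: str) -> str:
    """Pick the assigned cause to carry into a cross-tabulation.

    Normally the most likely cause; but when that disagrees with the
    reference (gold-standard) cause and the second or third listed cause
    matches it, the matching cause is credited instead.  Used only when
    validating against a reference, never for standalone reporting.
    """
    if assignment.indeterminate:
        return INDETERMINATE
    first = assignment.causes[0][0]
    if first == reference_cause:
        return first
    for cause, _ in assignment.causes[1:3]:
        if cause == reference_cause:
            return cause
    return first


def batch_assign(
    records: list[DeathRecord],
    matrix: ProbabilityMatrix,
    policy: ReportingPolicy = ReportingPolicy(),
) -> tuple[pd.DataFrame, dict]:
    """Assign every death and summarise the output mix.

    Returns the per-death assignment table (columns ``id, cause1, lik1, ...,
    cause3, lik3, indeterminate``) and a summary dict with counts and
    round-half-up integer percentages of single-, two-, three-cause and
    indeterminate outputs.
    """
    rows = []
    assignments: dict[str, CODAssignment] = {}
    for rec in records:
        a = assign_causes(rec.indicators, matrix, policy)
        assignments[rec.id] = a
        row: dict = {"id": rec.id}
        for i in range(3):
            cause, lik = (a.causes[i] if i < len(a.causes) else ("", np.nan))
            row[f"cause{i + 1}"] = cause
            row[f"lik{i + 1}"] = lik
        row["indeterminate"] = a.indeterminate
        rows.append(row)
    columns = ["id", "cause1", "lik1", "cause2", "lik2", "cause3", "lik3",
               "indeterminate"]
    table = pd.DataFrame(rows, columns=columns)

    n = len(records)
    counts = {
        "single_cause": sum(len(a.causes) == 1 for a in assignments.values()),
        "two_causes": sum(len(a.causes) == 2 for a in assignments.values()),
        "three_causes": sum(len(a.causes) == 3 for a in assignments.values()),
        "indeterminate": sum(a.indeterminate for a in assignments.values()),
    }
    summary = {
        "n": n,
        "counts": counts,
        "percentages": output_mix_percentages(counts),
        "assignments": assignments,
    }
    return table, summary


def output_mix_percentages(counts: dict[str, int]) -> dict[str, int]:
    """Counts -> round-half-up integer percentages (zeros when n = 0)."""
    n = sum(counts.values())
    if n == 0:
        return {k: 0 for k in counts}
    return {k: int(round_half_up(100.0 * v / n, 0)) for k, v in counts.items()}


def write_assignments(table: pd.DataFrame, path) -> None:
    """Write the per-death assignment table CSV."""
    table.to_csv(path, index=False, float_format="%.6f")
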