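"""Synthetic verbal-autopsy cohorts with known underlying causes of death.

Real validation studies compare cause-of-death (COD) assignment methods on a
cohort of deaths whose true cause is established from hospital records.  Such
case-level data are rarely shareable, so this module generates cohorts in
which the truth is known by construction: each death draws a true cause from a
specified cause-specific mortality fraction (CSMF) vector, emits binary
sign/symptom indicators conditionally on that cause (with optional flip noise
and missingness), and is then "diagnosed" by imperfect categorical raters
defined by confusion matrices — stand-ins for a hospital diagnosis and a
physician VA coder.

Indicators are ternary: present / absent / unknown.  Unknown mirrors the
"null" indicators that occur when a questionnaire does not collect an item a
probabilistic interpreter expects; downstream, unknowns contribute nothing to
the Bayes update.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: ternary indicator codes
PRESENT: int = 1
ABSENT: int = 0
UNKNOWN: int = -1

#: reserved assignment outcome: not a cause, only a possible verdict
INDETERMINATE: str = "indeterminate"

_SEX_LABELS = ("male", "female")


@dataclass(frozen=True)
class CauseList:
    """Ordered condensed list of cause-of-death categories.

    ``indeterminate`` is never a member: it is an assignment outcome, not a
    cause, and is appended only when reporting.
    """

    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.categories) == 0:
            raise ValueError("cause list must be non-empty")
        if len(set(self.categories)) != len(self.categories):
            raise ValueError("cause labels must be unique")
        if INDETERMINATE in self.categories:
            raise ValueError(f"{INDETERMINATE!r} is an outcome, not a cause")

    def __len__(self) -> int:
        return len(self.categories)

    def __iter__(self):
        return iter(self.categories)

    def __contains__(self, label: object) -> bool:
        return label in self.categories

    def index(self, label: str) -> int:
        return self.categories.index(label)

    @property
    def reporting_categories(self) -> tuple[str, ...]:
        """Categories plus the indeterminate outcome, for tabulation."""
        return self.categories + (INDETERMINATE,)


@dataclass
class ProbabilityMatrix:
    """Cause priors and per-indicator emission probabilities.

    ``emit[i, c]`` is P(indicator i present | cause c); ``priors[c]`` is the
    prior probability of cause c, summing to one.  Designated causes (HIV,
    malaria in the classical setting) may carry a high/low local-prevalence
    flag which scales their prior before renormalisation; see
    :func:`vaval.engine.apply_prevalence`.
    """

    causes: CauseList
    indicators: tuple[str, ...]
    priors: np.ndarray
    emit: np.ndarray

    def __post_init__(self) -> None:
        self.priors = np.asarray(self.priors, dtype=float)
        self.emit = np.asarray(self.emit, dtype=float)
        k, m = len(self.causes), len(self.indicators)
        if self.priors.shape != (k,):
            raise ValueError(f"priors shape {self.priors.shape} != ({k},)")
        if self.emit.shape != (m, k):
            raise ValueError(f"emit shape {self.emit.shape} != ({m}, {k})")
        if not np.isclose(self.priors.sum(), 1.0, atol=1e-9):
            raise ValueError("priors must sum to 1")
        if np.any(self.priors < 0):
            raise ValueError("priors must be non-negative")
        if np.any((self.emit < 0) | (self.emit > 1)):
            raise ValueError("emission probabilities must lie in [0, 1]")

    def to_csv(self, path) -> None:
        """Write as CSV: indicator rows by cause columns, plus a ``_prior`` row."""
        df = pd.DataFrame(self.emit, index=list(self.indicators),
                          columns=list(self.causes))
        df.loc["_prior"] = self.priors
        df = df.reindex(["_prior", *self.indicators])
        df.index.name = "indicator"
        df.to_csv(path, float_format="%.10g")

    @classmethod
    def from_csv(cls, path) -> "ProbabilityMatrix":
        df = pd.read_csv(path, index_col=0)
        if "_prior" not in df.index:
            raise ValueError(f"{path}: probability matrix CSV lacks a '_prior' row")
        priors = df.loc["_prior"].to_numpy(dtype=float)
        emit = df.drop(index="_prior")
        return cls(
            causes=CauseList(tuple(df.columns)),
            indicators=tuple(emit.index),
            priors=priors,
            emit=emit.to_numpy(dtype=float),
        )


@dataclass
class DeathRecord:
    """One death: demographics, indicator vector, and (synthetic) truth."""

    id: str
    age: float
    sex: str
    indicators: np.ndarray  # int8 vector of PRESENT / ABSENT / UNKNOWN
    true_cause: str | None = None
    assigned: dict[str, str] = field(default_factory=dict)


@dataclass
class RaterModel:
    """An imperfect categorical rater defined by a confusion matrix.

    ``confusion[i, j]`` is P(assigned = cause j | true = cause i); rows are
    stochastic.  Independently of the truth, the rater returns indeterminate
    with probability ``indeterminate_rate``.
    """

    causes: CauseList
    confusion: np.ndarray
    indeterminate_rate: float = 0.0

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion, dtype=float)
        k = len(self.causes)
        if self.confusion.shape != (k, k):
            raise ValueError(f"confusion shape {self.confusion.shape} != ({k}, {k})")
        if np.any(self.confusion < 0) or not np.allclose(
            self.confusion.sum(axis=1), 1.0, atol=1e-9
        ):
            raise ValueError("confusion rows must be non-negative and sum to 1")
        if not (0.0 <= self.indeterminate_rate < 1.0):
            raise ValueError("indeterminate_rate must lie in [0, 1)")

    @classmethod
    def uniform_error(cls, causes: CauseList, accuracy: float,
                      indeterminate_rate: float = 0.0) -> "RaterModel":
        """Diagonal ``accuracy``, errors spread uniformly over other causes."""
        k = len(causes)
        if not (0.0 <= accuracy <= 1.0):
            raise ValueError("accuracy must lie in [0, 1]")
        off = (1.0 - accuracy) / (k - 1) if k > 1 else 0.0
        conf = np.full((k, k), off)
        np.fill_diagonal(conf, accuracy if k > 1 else 1.0)
        return cls(causes, conf, indeterminate_rate)


def build_probability_matrix(
    n_causes: int,
    n_indicators: int,
    informativeness: float = 0.8,
    seed: int = 0,
    cause_labels: CauseList | None = None,
) -> ProbabilityMatrix:
    """Construct a signature-block emission matrix with uniform priors.

    Indicators are randomly partitioned into per-cause "signature" blocks.
    A signature indicator fires with probability ``0.5 + 0.5*informativeness``
    for its cause and ``0.5*(1 - informativeness)`` otherwise, so the single
    parameter sweeps from uninformative noise (0: every emission 0.5) to a
    deterministic barcode (1: signature emissions 1, background 0).
    """
    if n_causes < 2:
        raise ValueError("need at least 2 causes")
    if n_indicators < 1:
        raise ValueError("need at least 1 indicator")
    informativeness = float(informativeness)
    if not np.isfinite(informativeness) or not (0.0 <= informativeness <= 1.0):
        raise ValueError("informativeness must be finite and in [0, 1]")
    if cause_labels is not None and len(cause_labels) != n_causes:
        raise ValueError("cause_labels length must equal n_causes")

    rng = np.random.default_rng(seed)
    causes = cause_labels or CauseList(
        tuple(f"cause_{i + 1:02d}" for i in range(n_causes))
    )
    indicators = tuple(f"ind_{i + 1:03d}" for i in range(n_indicators))

    hi = 0.5 + 0.5 * informativeness
    lo = 0.5 * (1.0 - informativeness)
    emit = np.full((n_indicators, n_causes), lo)
    # disjoint random signature blocks, round-robin over a permutation
    owner = rng.permutation(n_indicators) % n_causes
    emit[np.arange(n_indicators), owner] = hi

    priors = np.full(n_causes, 1.0 / n_causes)
    return ProbabilityMatrix(causes, indicators, priors, emit)


def signature_pattern(matrix: ProbabilityMatrix, cause: str) -> np.ndarray:
    """Most likely indicator vector for ``cause`` (ties resolved as absent)."""
    j = matrix.causes.index(cause)
    return (matrix.emit[:, j] > 0.5).astype(np.int8)


def simulate_cohort(
    csmf_true,
    matrix: ProbabilityMatrix,
    n_deaths: int,
    flip_noise: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
    mean_age: float = 55.0,
    sd_age: float = 20.0,
    male_fraction: float = 0.56,
) -> list[DeathRecord]:
    """Draw a cohort of deaths with cause-conditional indicators.

    True causes are iid from ``csmf_true``; each indicator is Bernoulli from
    the emission matrix, flipped with probability ``flip_noise``, then masked
    to unknown with probability ``missing_rate``.  Ages are normal (truncated
    to the adult range 15–100) and sex is Bernoulli; demographics are used
    only as stratifiers downstream, never to generate indicators.
    """
    csmf_true = np.asarray(csmf_true, dtype=float)
    k = len(matrix.causes)
    if csmf_true.shape != (k,):
        raise ValueError(
            f"csmf_true has {csmf_true.shape[0]} entries but matrix has {k} causes"
        )
    if not np.isclose(csmf_true.sum(), 1.0, atol=1e-9) or np.any(csmf_true < 0):
        raise ValueError("csmf_true must be a probability vector")
    if not (0.0 <= flip_noise < 1.0) or not (0.0 <= missing_rate < 1.0):
        raise ValueError("flip_noise and missing_rate must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    m = len(matrix.indicators)
    truth = rng.choice(k, size=n_deaths, p=csmf_true)
    present = rng.random((n_deaths, m)) < matrix.emit.T[truth]
    flipped = present ^ (rng.random((n_deaths, m)) < flip_noise)
    values = flipped.astype(np.int8)
    values[rng.random((n_deaths, m)) < missing_rate] = UNKNOWN

    ages = np.clip(rng.normal(mean_age, sd_age, size=n_deaths), 15.0, 100.0)
    sexes = np.where(rng.random(n_deaths) < male_fraction, "male", "female")

    width = max(4, len(str(n_deaths)))
    return [
        DeathRecord(
            id=f"d{i + 1:0{width}d}",
            age=float(round(ages[i], 1)),
            sex=str(sexes[i]),
            indicators=values[i],
            true_cause=matrix.causes.categories[truth[i]],
        )
        for i in range(n_deaths)
    ]


def simulate_rater(
    records: list[DeathRecord], rater: RaterModel, seed: int = 0
) -> dict[str, str]:
    """Assign each record a cause by sampling the rater's confusion row.

    Returns a map id -> assigned label (possibly ``indeterminate``).  Records
    must carry a true cause drawn from the rater's cause list.
    """
    rng = np.random.default_rng(seed)
    k = len(rater.causes)
    out: dict[str, str] = {}
    for rec in records:
        if rec.true_cause is None:
            raise ValueError(f"record {rec.id} has no true cause")
        if rater.indeterminate_rate > 0 and rng.random() < rater.indeterminate_rate:
            out[rec.id] = INDETERMINATE
            continue
        row = rater.confusion[rater.causes.index(rec.true_cause)]
        out[rec.id] = rater.causes.categories[rng.choice(k, p=row)]
    return out


def write_cohort(records: list[DeathRecord], matrix: ProbabilityMatrix, path) -> None:
    """Write a cohort CSV in VA batch-file style.

    Header ``id,age,sex,true_cause,<indicators...>,hcod,pcva``; indicator
    cells are ``Y`` / ``N`` / empty (empty = unknown).
    """
    code = {PRESENT: "Y", ABSENT: "N", UNKNOWN: ""}
    rows = []
    for rec in records:
        row = {"id": rec.id, "age": rec.age, "sex": rec.sex,
               "true_cause": rec.true_cause or ""}
        for name, val in zip(matrix.indicators, rec.indicators):
            row[name] = code[int(val)]
        row["hcod"] = rec.assigned.get("hcod", "")
        row["pcva"] = rec.assigned.get("pcva", "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cohort(path, matrix: ProbabilityMatrix) -> list[DeathRecord]:
    """Read a cohort CSV written by :func:`write_cohort`."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in matrix.indicators if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: cohort CSV lacks indicator columns {missing[:5]}")
    decode = {"Y": PRESENT, "N": ABSENT, "": UNKNOWN}
    records = []
    for line, row in enumerate(df.to_dict(orient="records"), start=2):
        try:
            vals = np.array(
                [decode[row[c].strip()] for c in matrix.indicators], dtype=np.int8
            )
        except KeyError as exc:
            raise ValueError(
                f"{path}:{line}: bad indicator value {exc.args[0]!r} (want Y/N/empty)"
            ) from None
        assigned = {m: row[m] for m in ("hcod", "pcva") if row.get(m, "")}
        records.append(
            DeathRecord(
                id=row["id"],
                age=float(row["age"]) if row.get("age") else float("nan"),
                sex=row.get("sex", ""),
                indicators=vals,
                true_cause=row.get("true_cause") or None,
                assigned=assigned,
            )
        )
    return records
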