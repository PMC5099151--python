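"""Inter-observer agreement: IBMD scoring, bootstrap CIs, cell retention, ICC.

The information-based measure of disagreement (IBMD) compares M observers'
values for one quantity.  For an observer pair (a, b) the disagreement term is

    d(x_a, x_b) = log2(|x_a - x_b| / max(x_a, x_b) + 1),

with the 0/0 pair defined as 0 (perfect agreement on absence).  The
multi-observer IBMD is the mean of d over all M(M-1)/2 pairs.  It equals 0
iff all observers agree and approaches 1 as the relative distance between
observers grows (d -> log2(2) = 1 when one observer reports 0 and another a
positive value).

Cells of the annotation matrices are kept only when the upper bound of a
percentile-bootstrap 95% confidence interval for their IBMD lies strictly
below a threshold (0.15 in the original study): a cell enters the emotion
network only if the judges demonstrably agree on it.

The intraclass correlation coefficient (ICC) complements IBMD at the judge
level: for every pair of judges it measures absolute agreement over the
full vector of cell values via two-way ANOVA variance components.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_matrices import RaterMatrixSet, ValidationError

__all__ = [
    "DEFAULT_THRESHOLD",
    "DEFAULT_N_BOOT",
    "CellObservations",
    "CellAgreement",
    "JudgePairICC",
    "ibmd",
    "ibmd_ci",
    "filter_cells",
    "cell_observations",
    "icc_two_way",
    "judge_pair_icc",
    "agreement_report",
    "write_agreement_json",
]

#: Retention cutoff on the IBMD CI upper bound used in the original study.
DEFAULT_THRESHOLD = 0.15
DEFAULT_N_BOOT = 2000

CI_LEVEL = 95.0


@dataclass(frozen=True)
class CellObservations:
    """The M raters' final accumulated values for one directed cell."""

    emotion: str
    source: str
    target: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) < 2:
            raise ValidationError("a cell needs at least 2 observers")
        if any(v < 0 for v in self.values):
            raise ValidationError("observer values must be non-negative")
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))


@dataclass(frozen=True)
class CellAgreement:
    """IBMD point estimate, bootstrap 95% CI and retention flag for one cell."""

    emotion: str
    source: str
    target: str
    ibmd: float
    ci_low: float
    ci_high: float
    retained: bool
    n_boot: int
    seed: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.ibmd <= self.ci_high):
            raise ValidationError(
                f"CI must bracket the point estimate: "
                f"{self.ci_low} <= {self.ibmd} <= {self.ci_high} violated"
            )


def _pairwise_ibmd_terms(values: np.ndarray) -> np.ndarray:
    """Upper-triangle pair terms log2(|xa-xb|/max(xa,xb)+1); 0/0 pair -> 0."""
    v = np.asarray(values, dtype=float)
    a = v[:, None]
    b = v[None, :]
    mx = np.maximum(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(mx > 0, np.abs(a - b) / np.where(mx > 0, mx, 1.0), 0.0)
    terms = np.log2(ratio + 1.0)
    iu = np.triu_indices(len(v), k=1)
    return terms[iu]


def ibmd(values: Sequence[float]) -> float:
    """Multi-observer IBMD: mean pairwise disagreement over all observer pairs.

    Parameters
    ----------
    values
        The M >= 2 observers' non-negative values for one cell.

    Returns
    -------
    float
        0 iff all values are equal; grows toward 1 with relative distance.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValidationError("ibmd requires a flat vector of at least 2 values")
    if np.any(v < 0):
        raise ValidationError("observer values must be non-negative")
    return float(np.mean(_pairwise_ibmd_terms(v)))


def _ibmd_batch(samples: np.ndarray) -> np.ndarray:
    """IBMD of each row of a (B, M) resample matrix, vectorised."""
    a = samples[:, :, None]
    b = samples[:, None, :]
    mx = np.maximum(a, b)
    ratio = np.where(mx > 0, np.abs(a - b) / np.where(mx > 0, mx, 1.0), 0.0)
    terms = np.log2(ratio + 1.0)
    m = samples.shape[1]
    iu = np.triu_indices(m, k=1)
    return terms[:, iu[0], iu[1]].mean(axis=1)


def ibmd_ci(
    values: Sequence[float],
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile-bootstrap 95% CI for the IBMD of one cell.

    Observers are resampled with replacement ``n_boot`` times and the IBMD
    recomputed per resample; the interval is the (2.5, 97.5) percentile of
    those replicates, widened if necessary so it brackets the point estimate.
    Deterministic given ``seed``.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValidationError("ibmd_ci requires a flat vector of at least 2 values")
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    point = ibmd(v)
    rng = np.random.default_rng(seed)
    m = len(v)
    idx = rng.integers(0, m, size=(int(n_boot), m))
    stats = _ibmd_batch(v[idx])
    lo, hi = np.percentile(stats, [(100 - CI_LEVEL) / 2, 100 - (100 - CI_LEVEL) / 2])
    # percentile intervals need not contain the plug-in estimate; widen so the
    # retention rule "CI upper bound < threshold" is never laxer than the
    # point estimate itself
    return float(min(lo, point)), float(max(hi, point))


def _cell_seed(run_seed: int, emotion: str, source: str, target: str) -> int:
    """Stable per-cell bootstrap seed, independent of cell processing order."""
    key = f"{emotion}\x1f{source}\x1f{target}".encode("utf-8")
    ss = np.random.SeedSequence([int(run_seed), zlib.crc32(key)])
    return int(ss.generate_state(1)[0] % (2**31))


def cell_observations(matrix_set: RaterMatrixSet) -> list[CellObservations]:
    """All cells of a matrix set as per-cell observer vectors (zeros included)."""
    out = []
    names = matrix_set.roster.names
    for emotion in matrix_set.emotions:
        stack = matrix_set.stacked(emotion)  # (M, n, n)
        for i, s in enumerate(names):
            for j, t in enumerate(names):
                out.append(
                    CellObservations(
                        emotion=emotion,
                        source=s,
                        target=t,
                        values=tuple(stack[:, i, j]),
                    )
                )
    return out


def filter_cells(
    observations: Iterable[CellObservations],
    threshold: float = DEFAULT_THRESHOLD,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> list[CellAgreement]:
    """Score every cell and flag which survive the CI-threshold retention rule.

    A cell is retained iff the upper bound of its bootstrap 95% CI is
    *strictly* below ``threshold``.  All-zero cells score IBMD 0 and are
    retained (they simply yield no edge downstream).  Each cell's bootstrap
    uses a seed derived deterministically from ``seed`` and the cell identity,
    so results do not depend on iteration order.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    results = []
    for obs in observations:
        cseed = _cell_seed(seed, obs.emotion, obs.source, obs.target)
        v = np.asarray(obs.values)
        point = ibmd(v)
        if np.all(v == v[0]):
            # every resample of a constant vector is constant: CI collapses
            lo = hi = point
        else:
            lo, hi = ibmd_ci(v, n_boot=n_boot, seed=cseed)
        results.append(
            CellAgreement(
                emotion=obs.emotion,
                source=obs.source,
                target=obs.target,
                ibmd=point,
                ci_low=lo,
                ci_high=hi,
                retained=bool(hi < threshold),
                n_boot=int(n_boot),
                seed=cseed,
            )
        )
    return results


# ---------------------------------------------------------------------------
# ICC


@dataclass
class JudgePairICC:
    """Pairwise judge ICC matrix (symmetric, unit diagonal)."""

    raters: tuple[str, ...]
    values: np.ndarray  # (M, M), NaN where undefined
    icc_form: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.raters, columns=self.raters)


def icc_two_way(ratings: np.ndarray, icc_form: str = "ICC2") -> float:
    """Single-measure ICC of an (n_targets, k_raters) ratings matrix.

    Forms (McGraw & Wong): ``ICC1`` one-way random; ``ICC2`` two-way random,
    absolute agreement (the default — judges are exchangeable raters scoring
    the same targets); ``ICC3`` two-way mixed, consistency.
    Returns NaN (with a warning) when the variance decomposition is degenerate.
    """
    y = np.asarray(ratings, dtype=float)
    if y.ndim != 2 or y.shape[0] < 2 or y.shape[1] < 2:
        raise ValidationError("ICC needs at least 2 targets and 2 raters")
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_total = float(((y - grand) ** 2).sum())
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err, 0.0) / ((n - 1) * (k - 1))

    form = icc_form.upper().replace("(", "").replace(")", "").replace(",", "")
    if form in ("ICC1", "1"):
        msw = (ss_total - ss_rows) / (n * (k - 1))
        denom = msr + (k - 1) * msw
        num = msr - msw
    elif form in ("ICC2", "2", "A1", "ICCA1"):
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
        num = msr - mse
    elif form in ("ICC3", "3", "C1", "ICCC1"):
        denom = msr + (k - 1) * mse
        num = msr - mse
    else:
        raise ValidationError(f"unknown ICC form: {icc_form!r}")
    if denom <= 0:
        warnings.warn(
            "ICC undefined: no variance across targets for this rater pair",
            stacklevel=2,
        )
        return float("nan")
    return float(num / denom)


def judge_pair_icc(
    matrix_set: RaterMatrixSet,
    icc_form: str = "ICC2",
    emotion: str | None = None,
) -> JudgePairICC:
    """ICC for every pair of judges over the vector of all cell values.

    By default all emotions' cells are concatenated into one target vector
    per judge; pass ``emotion`` to restrict to a single emotion's matrix.
    Pairs with no variance across cells are reported as NaN with a warning.
    """
    emotions = [emotion] if emotion is not None else list(matrix_set.emotions)
    # columns: judges; rows: all cells of all requested emotions
    per_judge = {
        r: np.concatenate(
            [matrix_set.matrices[(r, e)].values.ravel() for e in emotions]
        )
        for r in matrix_set.raters
    }
    raters = matrix_set.raters
    m = len(raters)
    out = np.full((m, m), np.nan)
    np.fill_diagonal(out, 1.0)
    for i in range(m):
        for j in range(i + 1, m):
            pair = np.column_stack([per_judge[raters[i]], per_judge[raters[j]]])
            out[i, j] = out[j, i] = icc_two_way(pair, icc_form=icc_form)
    return JudgePairICC(raters=raters, values=out, icc_form=icc_form)


# ---------------------------------------------------------------------------
# Report serialization


def agreement_report(
    cells: Sequence[CellAgreement],
    threshold: float,
    n_boot: int,
    seed: int,
    icc: JudgePairICC | None = None,
) -> dict:
    """JSON-serialisable per-cell agreement report plus run metadata."""
    report = {
        "metadata": {
            "threshold": threshold,
            "n_boot": int(n_boot),
            "seed": int(seed),
            "ci_level": CI_LEVEL,
            "icc_form": icc.icc_form if icc is not None else None,
        },
        "cells": [
            {
                k: v
                for k, v in asdict(c).items()
                if k in ("emotion", "source", "target", "ibmd", "ci_low", "ci_high", "retained")
            }
            for c in cells
        ],
    }
    if icc is not None:
        report["icc"] = {
            "raters": list(icc.raters),
            "values": [
                [None if np.isnan(x) else float(x) for x in row]
                for row in icc.values
            ],
        }
    return report


def write_agreement_json(
    path: str | Path,
    cells: Sequence[CellAgreement],
    threshold: float,
    n_boot: int,
    seed: int,
    icc: JudgePairICC | None = None,
) -> None:
    Path(path).write_text(
        json.dumps(agreement_report(cells, threshold, n_boot, seed, icc), indent=2)
        + "\n",
        encoding="utf-8",
    )
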