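"""Evaluation of driver predictions: confusion metrics and p-value calibration.

Precision, sensitivity and F1 are reported on a 0-100 scale.  Calibration
compares the sorted observed p-values with the uniform expectation
``expected_i = i/n`` and summarizes the deviation as the mean absolute
log2 fold change (MLFC); a well-calibrated method has MLFC near zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "CalibrationReport",
    "confusion_at_cutoff",
    "expected_pvalues",
    "mlfc",
    "qq_table",
    "calibration_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """True/false positive and false negative counts at a q-value cutoff."""

    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        """100 * TP / (TP + FP); NaN when nothing was predicted."""
        return 100.0 * self.tp / (self.tp + self.fp) if self.tp + self.fp else math.nan

    @property
    def sensitivity(self) -> float:
        """100 * TP / (TP + FN); NaN when the truth set is empty."""
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else math.nan

    @property
    def f1(self) -> float:
        """Harmonic mean of precision and sensitivity (0-100 scale)."""
        p, s = self.precision, self.sensitivity
        if math.isnan(p) or math.isnan(s) or p + s == 0:
            return math.nan
        return 2.0 * p * s / (p + s)


def _results_frame(results) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        return results
    return pd.DataFrame(
        {"gene_id": [r.gene_id for r in results],
         "q_value": [r.q_value for r in results],
         "tested": [getattr(r, "tested", True) for r in results]}
    )


def confusion_at_cutoff(
    results,
    truth: Iterable[str],
    negatives: Iterable[str] = (),
    q_cutoff: float = 0.1,
) -> ConfusionCounts:
    """Confusion counts for predictions at ``q <= q_cutoff``.

    ``results`` is a list of :class:`~driverscan.engine.GeneResult` or a
    DataFrame with ``gene_id`` and ``q_value`` columns.  Truth genes absent
    from the tested results are excluded from the FN denominator.  When a
    ``negatives`` universe is supplied, predictions outside truth-or-negatives
    are ignored.
    """
    truth = set(truth)
    negatives = set(negatives)
    if truth & negatives:
        raise ValueError("truth and negative sets overlap")
    df = _results_frame(results)
    if "tested" in df.columns:
        df = df[df["tested"]]
    tested = set(df["gene_id"])
    predicted = set(df.loc[df["q_value"] <= q_cutoff, "gene_id"])
    if negatives:
        predicted &= truth | negatives
    truth_tested = truth & tested
    tp = len(predicted & truth_tested)
    fp = len(predicted - truth)
    fn = len(truth_tested - predicted)
    return ConfusionCounts(tp=tp, fp=fp, fn=fn)


def expected_pvalues(n: int) -> np.ndarray:
    """Uniform-expected p-values i/n for ranks i = 1..n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return np.arange(1, n + 1) / n


def _clean_sorted(observed_p) -> np.ndarray:
    obs = np.asarray(observed_p, dtype=float)
    obs = obs[~np.isnan(obs)]
    if np.any((obs <= 0) | (obs > 1)):
        raise ValueError("observed p-values must lie in (0, 1]")
    return np.sort(obs)


def mlfc(observed_p, literal: bool = False) -> float:
    """Mean absolute log2 fold change of observed vs expected p-values.

    NaN entries are discarded before ranking.  ``literal=True`` computes the
    plain mean absolute ratio |observed/expected| instead of its log, for
    comparison (that variant is 1, not 0, under perfect calibration).
    Returns NaN on an empty vector.
    """
    obs = _clean_sorted(observed_p)
    if not len(obs):
        return math.nan
    ratio = obs / expected_pvalues(len(obs))
    if literal:
        return float(np.mean(np.abs(ratio)))
    return float(np.mean(np.abs(np.log2(ratio))))


def qq_table(observed_p) -> pd.DataFrame:
    """-log10 expected vs observed p-values, smallest p first."""
    obs = _clean_sorted(observed_p)
    exp = expected_pvalues(len(obs)) if len(obs) else np.empty(0)
    return pd.DataFrame(
        {"expected_neglog10": -np.log10(exp), "observed_neglog10": -np.log10(obs)}
    )


@dataclass
class CalibrationReport:
    """Observed vs uniform-expected p-value vectors with their MLFC."""

    observed_p: np.ndarray
    expected_p: np.ndarray
    mlfc: float
    n: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"observed_p": self.observed_p, "expected_p": self.expected_p}
        )


def calibration_report(observed_p, literal: bool = False) -> CalibrationReport:
    obs = _clean_sorted(observed_p)
    return CalibrationReport(
        observed_p=obs,
        expected_p=expected_pvalues(len(obs)) if len(obs) else np.empty(0),
        mlfc=mlfc(obs, literal=literal),
        n=len(obs),
    )
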