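"""Diagnostic-accuracy statistics for 2x2 index-test vs reference tables.

Ships the three published MRI-sequence contingency tables (plain scan, DWI,
DCE; index-test call cross-tabulated against pathology for 150 patients) as
a CSV fixture, and computes sensitivity, specificity, accuracy, Cohen's
kappa and Pearson chi-square comparisons between sequences.

Display values are rounded half-up to two decimals to match the source
report's precision; unrounded values are retained for computation.

Known reporting discrepancies
-----------------------------
The kappa values printed in the source report (plain 0.469, DWI 0.547,
DCE 0.678) are not reproducible from the printed cell counts, which give
~0.364, ~0.539 and ~0.810 respectively; likewise the printed DWI accuracy
of 91.33% disagrees with the cell counts (136/150 = 90.67%).  This module
reports the formula-true values and attaches an explicit discrepancy note
to the affected summaries rather than silently matching the printed
numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable",
    "AccuracySummary",
    "DegenerateTableError",
    "sensitivity",
    "specificity",
    "accuracy",
    "cohen_kappa",
    "chi_square_compare",
    "mcnemar_test",
    "summarize",
    "load_fixture_tables",
    "KNOWN_REPORTING_DISCREPANCIES",
]


class DegenerateTableError(ValueError):
    """A margin needed by the requested statistic is empty or degenerate."""


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: index-test call (rows) vs pathological reference (cols).

    ``tp``: test positive & reference positive, ``fp``: test positive &
    reference negative, ``fn``: test negative & reference positive,
    ``tn``: test negative & reference negative.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.total == 0:
            raise DegenerateTableError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_array(self) -> np.ndarray:
        return np.array([[self.tp, self.fp], [self.fn, self.tn]], dtype=np.int64)


def round2(value: float) -> float:
    """Half-up rounding to 2 decimals (display convention)."""
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def sensitivity(t: ContingencyTable) -> float:
    """100 * TP / (TP + FN), as a percentage."""
    if t.tp + t.fn == 0:
        raise DegenerateTableError("no reference-positive cases: sensitivity undefined")
    return 100.0 * t.tp / (t.tp + t.fn)


def specificity(t: ContingencyTable) -> float:
    """100 * TN / (TN + FP), as a percentage."""
    if t.tn + t.fp == 0:
        raise DegenerateTableError("no reference-negative cases: specificity undefined")
    return 100.0 * t.tn / (t.tn + t.fp)


def accuracy(t: ContingencyTable) -> float:
    """100 * (TP + TN) / N, as a percentage."""
    return 100.0 * (t.tp + t.tn) / t.total


def cohen_kappa(t: ContingencyTable) -> float:
    """Chance-corrected agreement (po - pe) / (1 - pe) between index test
    and reference, with pe from the row/column margins."""
    n = t.total
    po = (t.tp + t.tn) / n
    pe = ((t.tp + t.fp) * (t.tp + t.fn) + (t.fn + t.tn) * (t.fp + t.tn)) / n ** 2
    if pe == 1.0:
        raise DegenerateTableError("degenerate margins (pe = 1): kappa undefined")
    return (po - pe) / (1.0 - pe)


def kappa_band(kappa: float) -> str:
    """Agreement band: >= 0.7 good, >= 0.4 acceptable, else poor."""
    if kappa >= 0.7:
        return "good"
    if kappa >= 0.4:
        return "acceptable"
    return "poor"


def _success_failure(t: ContingencyTable, statistic: str) -> tuple[int, int]:
    if statistic == "accuracy":
        return t.tp + t.tn, t.fp + t.fn
    if statistic == "sensitivity":
        return t.tp, t.fn
    if statistic == "specificity":
        return t.tn, t.fp
    raise ValueError(
        f"unknown statistic {statistic!r}; use accuracy, sensitivity or specificity"
    )


def chi_square_compare(
    a: ContingencyTable, b: ContingencyTable, statistic: str = "accuracy"
) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) comparing the
    chosen proportion between two tables.

    Builds the 2x2 success/failure table (rows = the two tables, columns =
    e.g. correct/incorrect calls) and tests homogeneity of the proportions.
    """
    sa, fa = _success_failure(a, statistic)
    sb, fb = _success_failure(b, statistic)
    table = np.array([[sa, fa], [sb, fb]], dtype=np.int64)
    if table.sum() == 0:
        raise DegenerateTableError("empty comparison table")
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        # a zero margin means a zero expected cell
        raise DegenerateTableError(
            "zero expected cell; use an exact test (e.g. Fisher) instead"
        )
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def mcnemar_test(discordant_b: int, discordant_c: int) -> tuple[float, float]:
    """McNemar chi-square (no continuity correction) from the two discordant
    counts of a paired comparison.

    Offered for completeness: the shipped fixtures are marginal tables
    without per-patient pairing, so the discordant counts must be supplied
    by the caller.
    """
    if discordant_b < 0 or discordant_c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = discordant_b + discordant_c
    if n == 0:
        raise DegenerateTableError("no discordant pairs: McNemar undefined")
    chi2 = (discordant_b - discordant_c) ** 2 / n
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# printed-report values that conflict with the printed cell counts
KNOWN_REPORTING_DISCREPANCIES: dict[str, dict[str, float]] = {
    "plain": {"printed_kappa": 0.469},
    "DWI": {"printed_kappa": 0.547, "printed_accuracy": 91.33},
    "DCE": {"printed_kappa": 0.678},
}


@dataclass(frozen=True)
class AccuracySummary:
    """Bundle of the four statistics for one table, plus the kappa band and
    any notes about known print-vs-cells discrepancies."""

    label: str
    sensitivity: float
    specificity: float
    accuracy: float
    kappa: float
    kappa_band: str
    notes: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "sensitivity": round2(self.sensitivity),
            "specificity": round2(self.specificity),
            "accuracy": round2(self.accuracy),
            "kappa": self.kappa,
            "kappa_band": self.kappa_band,
            "notes": list(self.notes),
        }


def summarize(t: ContingencyTable) -> AccuracySummary:
    """Compute all four statistics; attaches a discrepancy note when the
    published report's printed value for this table disagrees with the value
    implied by its own printed cells."""
    kappa = cohen_kappa(t)
    acc = accuracy(t)
    notes: list[str] = []
    printed = KNOWN_REPORTING_DISCREPANCIES.get(t.label, {})
    if "printed_kappa" in printed and abs(printed["printed_kappa"] - kappa) > 0.005:
        notes.append(
            f"printed kappa {printed['printed_kappa']} is not reproducible from the "
            f"printed cells (formula gives {kappa:.4f}); reporting the formula-true value"
        )
    if "printed_accuracy" in printed and abs(printed["printed_accuracy"] - acc) > 0.005:
        notes.append(
            f"printed accuracy {printed['printed_accuracy']}% disagrees with the printed "
            f"cells ({t.tp + t.tn}/{t.total} = {acc:.2f}%); reporting the cell-derived value"
        )
    return AccuracySummary(
        label=t.label,
        sensitivity=sensitivity(t),
        specificity=specificity(t),
        accuracy=acc,
        kappa=kappa,
        kappa_band=kappa_band(kappa),
        notes=tuple(notes),
    )


def load_fixture_tables(path=None) -> dict[str, ContingencyTable]:
    """Load contingency tables from a CSV with columns
    (sequence, tp, fp, fn, tn); defaults to the packaged fixtures."""
    if path is None:
        with resources.files("lowrankmr.data").joinpath("contingency_tables.csv").open() as fh:
            frame = pd.read_csv(fh)
    else:
        frame = pd.read_csv(path)
    required = {"sequence", "tp", "fp", "fn", "tn"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"fixture CSV missing columns: {sorted(missing)}")
    return {
        row.sequence: ContingencyTable(
            tp=int(row.tp), fp=int(row.fp), fn=int(row.fn), tn=int(row.tn),
            label=str(row.sequence),
        )
        for row in frame.itertuples()
    }
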