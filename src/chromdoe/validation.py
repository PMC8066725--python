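"""Method-validation statistics: precision and robustness.

Precision is expressed as the coefficient of variation (CV, percent) of
replicate measurements — repeatability from same-day replicates and
intermediate precision from multi-day replicates — judged against an
acceptability threshold (10 % per the AOAC peer-verified guideline).

Robustness compares deliberate small variations of an instrument parameter
(three levels, a few replicates each) with pairwise pooled-variance
two-tailed t-tests and summarizes the outcome as a compact letter display:
levels sharing a letter are statistically indistinguishable at the chosen
significance level.  No multiplicity correction is applied across the
pairwise tests (plain t-tests at alpha), which is reported as a caveat.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "coefficient_of_variation",
    "PrecisionReport",
    "precision_report",
    "pooled_t_test",
    "compact_letter_display",
    "RobustnessReport",
    "robustness_letters",
    "robustness_report",
]


def coefficient_of_variation(values) -> float:
    """100 * sample SD (n-1 denominator) / mean, in percent."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValidationError("need at least 2 values for a CV")
    mean = values.mean()
    if mean == 0:
        raise ValidationError("CV undefined for zero mean")
    return float(100.0 * values.std(ddof=1) / mean)


@dataclass(frozen=True)
class PrecisionReport:
    """Per compound x metric CVs with pass/fail flags."""

    table: pd.DataFrame  # columns: compound, metric, cv_repeatability, cv_intermediate, pass_*
    threshold: float

    @property
    def all_pass(self) -> bool:
        return bool(
            self.table["pass_repeatability"].all() and self.table["pass_intermediate"].all()
        )

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _grouped_cvs(frame: pd.DataFrame) -> pd.Series:
    for col in ("compound", "metric", "value"):
        if col not in frame.columns:
            raise ValidationError(f"replicate table missing column {col!r}")
    return frame.groupby(["compound", "metric"], sort=True)["value"].apply(
        coefficient_of_variation
    )


def precision_report(
    same_day: pd.DataFrame, multi_day: pd.DataFrame, threshold: float = 10.0
) -> PrecisionReport:
    """Repeatability and intermediate-precision CVs per compound and metric.

    Both inputs need columns ``compound``, ``metric``, ``value`` (a ``day``
    column may be present in ``multi_day`` and is ignored by the CV, which
    pools all replicates).  The two inputs must cover the same compound x
    metric combinations.
    """
    cv_rep = _grouped_cvs(same_day)
    cv_int = _grouped_cvs(multi_day)
    if set(cv_rep.index) != set(cv_int.index):
        raise ValidationError(
            "same-day and multi-day replicates cover different compound/metric sets"
        )
    table = pd.DataFrame(
        {"cv_repeatability": cv_rep, "cv_intermediate": cv_int.reindex(cv_rep.index)}
    ).reset_index()
    table["pass_repeatability"] = table["cv_repeatability"] < threshold
    table["pass_intermediate"] = table["cv_intermediate"] < threshold
    return PrecisionReport(table=table, threshold=threshold)


def pooled_t_test(a, b) -> float:
    """Two-tailed p of the equal-variance two-sample t-test.

    Degenerate case: zero pooled variance gives p = 1 for equal means and
    p = 0 otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("need at least 2 replicates per group")
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if sp2 == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def compact_letter_display(p_matrix: np.ndarray, alpha: float = 0.05) -> list[str]:
    """Letters from a symmetric pairwise p-value matrix.

    Letter groups are the maximal cliques of the "not significantly
    different" graph, ordered by their smallest member, so patterns like
    ``a, ab, b`` arise when a middle level bridges two extremes.
    """
    n = p_matrix.shape[0]
    compat = p_matrix >= alpha
    np.fill_diagonal(compat, True)
    cliques: list[tuple[int, ...]] = []
    for size in range(n, 0, -1):
        for combo in itertools.combinations(range(n), size):
            if all(compat[i, j] for i, j in itertools.combinations(combo, 2)):
                if not any(set(combo) <= set(c) for c in cliques):
                    cliques.append(combo)
    cliques.sort(key=lambda c: c[0])
    letters = [""] * n
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for i in clique:
            letters[i] += letter
    return letters


@dataclass(frozen=True)
class RobustnessReport:
    """Level means, pairwise p-values and letters for one measured quantity."""

    levels: list
    means: np.ndarray
    p_values: pd.DataFrame  # symmetric matrix indexed by level
    letters: list[str]
    alpha: float
    multiplicity_correction: str = "none"  # plain pairwise t-tests

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"level": self.levels, "mean": self.means, "letters": self.letters}
        )


def robustness_letters(groups: dict, alpha: float = 0.05) -> RobustnessReport:
    """Pairwise pooled t-tests across parameter levels with letter codes.

    ``groups`` maps level labels (in presentation order) to replicate
    arrays.  Levels sharing a letter do not differ significantly at
    ``alpha``.
    """
    if len(groups) < 2:
        raise ValidationError("need at least 2 levels")
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    n = len(labels)
    p = np.ones((n, n))
    for i, j in itertools.combinations(range(n), 2):
        p[i, j] = p[j, i] = pooled_t_test(arrays[i], arrays[j])
    return RobustnessReport(
        levels=labels,
        means=np.array([a.mean() for a in arrays]),
        p_values=pd.DataFrame(p, index=labels, columns=labels),
        letters=compact_letter_display(p, alpha=alpha),
        alpha=alpha,
    )


def robustness_report(
    frame: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Letter display for every (quantity, compound, parameter) row.

    ``frame`` needs columns ``quantity``, ``compound``, ``parameter``,
    ``level``, ``value``; levels are taken in order of first appearance.
    Returns one row per group per level with mean and letters.
    """
    for col in ("quantity", "compound", "parameter", "level", "value"):
        if col not in frame.columns:
            raise ValidationError(f"robustness table missing column {col!r}")
    rows = []
    for (quantity, compound, parameter), sub in frame.groupby(
        ["quantity", "compound", "parameter"], sort=True
    ):
        levels = list(dict.fromkeys(sub["level"]))
        groups = {lv: sub.loc[sub["level"] == lv, "value"].to_numpy() for lv in levels}
        rep = robustness_letters(groups, alpha=alpha)
        for lv, mean, letters in zip(rep.levels, rep.means, rep.letters):
            rows.append(
                {
                    "quantity": quantity,
                    "compound": compound,
                    "parameter": parameter,
                    "level": lv,
                    "mean": mean,
                    "letters": letters,
                }
            )
    return pd.DataFrame(rows)
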