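"""Cell-type co-occurrence (colocalization) testing on compositions.

Two cell types that belong to the same anatomical structure — e.g. the
podocytes, mesangial cells and small vessels of a glomerulus — end up in
the same tissue fragments more often than chance.  The statistic works on
deconvolved compositions: each unit is marked "present" for a type when its
fraction strictly exceeds that type's median across units, every unordered
pair is tabulated into a present/absent 2x2 table, independence is tested
with the 1-df chi-square, pairs whose association is not positive are
discarded, and the survivors are ranked by ascending p-value (reported as
-log10 P).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CompositionMatrix

__all__ = [
    "PresenceMatrix",
    "CooccurrenceResult",
    "dichotomize",
    "pair_test",
    "direction_filter",
    "all_pair_tests",
    "rank_pairs",
    "plot_top_pairs",
]

#: floor applied to chi-square p-values so -log10 P stays finite
P_FLOOR = 1e-300

#: expected-count threshold below which the large-sample chi-square
#: approximation is conventionally considered unreliable
LOW_EXPECTED = 5.0


@dataclass
class PresenceMatrix:
    """Boolean units x cell-types presence calls with the medians used."""

    unit_ids: list[str]
    cell_types: list[str]
    present: np.ndarray
    thresholds_used: np.ndarray

    def __post_init__(self) -> None:
        self.present = np.asarray(self.present, dtype=bool)
        if self.present.shape != (len(self.unit_ids), len(self.cell_types)):
            raise ValueError("present shape mismatch")

    def column(self, cell_type: str) -> np.ndarray:
        try:
            j = self.cell_types.index(cell_type)
        except ValueError:
            raise KeyError(f"unknown cell type {cell_type!r}") from None
        return self.present[:, j]

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)


@dataclass
class CooccurrenceResult:
    """One pair's 2x2 table and test outcome.

    ``table2x2`` rows are A present/absent, columns B present/absent, so
    ``table2x2[0, 0]`` counts units where both types are present.
    """

    type_a: str
    type_b: str
    table2x2: np.ndarray
    chi2_stat: float
    p_value: float
    neg_log10_p: float
    untestable: bool
    low_expected: bool
    conditional_ratio_a_given_b: float
    conditional_ratio_b_given_a: float
    marginal_ratio_a: float
    marginal_ratio_b: float
    passed_direction_filter: bool


def dichotomize(c) -> PresenceMatrix:
    """Median-split each cell-type column into present/absent.

    A unit is "present" for a type iff its fraction strictly exceeds the
    across-unit median of that type (even-length medians average the two
    central values, so a constant column yields all-absent).  Accepts a
    :class:`CompositionMatrix` or any units x types DataFrame/array of
    fractions.
    """
    if isinstance(c, CompositionMatrix):
        df = c.to_frame()
    elif isinstance(c, pd.DataFrame):
        df = c
    else:
        arr = np.asarray(c, dtype=float)
        df = pd.DataFrame(
            arr,
            index=[f"u{i}" for i in range(arr.shape[0])],
            columns=[f"t{j}" for j in range(arr.shape[1])],
        )
    if len(df) < 2:
        raise ValueError("dichotomization needs at least 2 units")
    medians = df.median(axis=0).to_numpy()
    return PresenceMatrix(
        unit_ids=list(df.index),
        cell_types=list(df.columns),
        present=df.to_numpy() > medians[None, :],
        thresholds_used=medians,
    )


def _chi2_2x2(table: np.ndarray, yates: bool) -> float:
    """Closed-form 1-df chi-square for a 2x2 table."""
    (a, b), (c, d) = table.astype(float)
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - n / 2.0)
    return float(n * diff**2 / denom)


def pair_test(
    p: PresenceMatrix,
    type_a: str,
    type_b: str,
    continuity_correction: bool = False,
) -> CooccurrenceResult:
    """Chi-square test of independence of two types' presence calls.

    A pair with a degenerate margin (a type never or always present) is
    flagged untestable with p = 1.  The Yates continuity correction is off
    by default; ``low_expected`` flags tables where the large-sample
    approximation is shaky (any expected count < 5) — such pairs are still
    reported.
    """
    if type_a == type_b:
        raise ValueError("a pair needs two distinct cell types")
    pa = p.column(type_a)
    pb = p.column(type_b)
    n = p.n_units
    n11 = int(np.sum(pa & pb))
    n10 = int(np.sum(pa & ~pb))
    n01 = int(np.sum(~pa & pb))
    n00 = n - n11 - n10 - n01
    table = np.array([[n11, n10], [n01, n00]])

    row = table.sum(axis=1)
    col = table.sum(axis=0)
    untestable = bool((row == 0).any() or (col == 0).any())
    if untestable:
        chi2, p_value = 0.0, 1.0
        low_expected = True
    else:
        chi2 = _chi2_2x2(table, yates=continuity_correction)
        p_value = max(float(stats.chi2.sf(chi2, df=1)), P_FLOOR)
        expected = np.outer(row, col) / n
        low_expected = bool((expected < LOW_EXPECTED).any())

    marg_a = (n11 + n10) / n
    marg_b = (n11 + n01) / n
    cond_a_given_b = n11 / (n11 + n01) if (n11 + n01) else 0.0
    cond_b_given_a = n11 / (n11 + n10) if (n11 + n10) else 0.0

    result = CooccurrenceResult(
        type_a=type_a,
        type_b=type_b,
        table2x2=table,
        chi2_stat=chi2,
        p_value=p_value,
        neg_log10_p=float(-np.log10(p_value)),
        untestable=untestable,
        low_expected=low_expected,
        conditional_ratio_a_given_b=cond_a_given_b,
        conditional_ratio_b_given_a=cond_b_given_a,
        marginal_ratio_a=marg_a,
        marginal_ratio_b=marg_b,
        passed_direction_filter=False,
    )
    result.passed_direction_filter = direction_filter(result)
    return result


def direction_filter(r: CooccurrenceResult, both_directions: bool = True) -> bool:
    """Keep only positively associated pairs.

    A pair passes when each type's presence probability, conditional on the
    other being present, is at least its overall presence probability.  By
    default the rule is applied symmetrically in both directions; set
    ``both_directions=False`` for the literal one-directional variant
    (A given B only).
    """
    forward = r.conditional_ratio_a_given_b >= r.marginal_ratio_a
    backward = r.conditional_ratio_b_given_a >= r.marginal_ratio_b
    return forward and backward if both_directions else forward


def all_pair_tests(
    p: PresenceMatrix, continuity_correction: bool = False
) -> list[CooccurrenceResult]:
    """Run :func:`pair_test` over every unordered cell-type pair."""
    return [
        pair_test(p, a, b, continuity_correction=continuity_correction)
        for a, b in combinations(p.cell_types, 2)
    ]


def rank_pairs(
    results: list[CooccurrenceResult],
    top_n: int = 15,
    one_directional_filter: bool = False,
) -> pd.DataFrame:
    """Rank positively associated, testable pairs by ascending p-value.

    Ties are broken by descending chi-square, then lexicographic pair name.
    A Benjamini-Hochberg q-value column over the included pairs is emitted
    as supplementary information; the ranking itself is on raw p-values.
    """
    kept = [
        r
        for r in results
        if not r.untestable
        and direction_filter(r, both_directions=not one_directional_filter)
    ]
    kept.sort(key=lambda r: (r.p_value, -r.chi2_stat, r.type_a, r.type_b))
    rows = []
    pvals = [r.p_value for r in kept]
    qvals = stats.false_discovery_control(pvals) if pvals else []
    for r, q in zip(kept, qvals):
        rows.append(
            {
                "type_a": r.type_a,
                "type_b": r.type_b,
                "n_both_present": int(r.table2x2[0, 0]),
                "chi2": r.chi2_stat,
                "p_value": r.p_value,
                "neg_log10_p": r.neg_log10_p,
                "bh_q": float(q),
                "low_expected": r.low_expected,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "type_a", "type_b", "n_both_present", "chi2", "p_value",
            "neg_log10_p", "bh_q", "low_expected",
        ],
    )
    return df.head(top_n).reset_index(drop=True)


def plot_top_pairs(ranked: pd.DataFrame, path=None):
    """Horizontal-bar chart of -log10 P for the ranked pairs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [
        f"{a} / {b}" for a, b in zip(ranked["type_a"], ranked["type_b"])
    ]
    fig, ax = plt.subplots(figsize=(6, 0.4 * max(len(ranked), 4) + 1))
    ax.barh(labels[::-1], ranked["neg_log10_p"][::-1], color="#4878a8")
    ax.set_xlabel(r"$-\log_{10}$ P")
    ax.set_title("Cell-type co-occurrence")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
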