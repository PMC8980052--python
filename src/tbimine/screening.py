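"""Per-code matched screening: McNemar tests, BY FDR, odds ratios, replication.

Each 3-character code is tested for case/reference imbalance across the
matched pairs with a matched McNemar test.  Only the discordant pairs
matter: ``b`` pairs where only the case carries the code and ``c`` pairs
where only the reference does.  Large discordant totals use the
continuity-corrected chi-square statistic ``(|b-c|-1)^2 / (b+c)``; small
totals (``b + c < 25``) fall back to the exact two-sided binomial test on
``b ~ Binomial(b+c, 1/2)``.  P-values across all codes are adjusted with
the Benjamini-Yekutieli step-up (valid under arbitrary dependence), and a
code is flagged significant when its BY q-value is below the FDR level and
its odds ratio exceeds 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PairedCodeCounts",
    "paired_counts",
    "mcnemar_test",
    "adjust_by",
    "compute_or",
    "screen_codes",
    "replicate_filter",
    "EXACT_BRANCH_THRESHOLD",
]

#: Discordant-pair total below which the exact binomial branch is used.
EXACT_BRANCH_THRESHOLD = 25


@dataclass(frozen=True)
class PairedCodeCounts:
    """2x2 cell counts of one binary code over matched pairs."""

    code: str
    n11: int  # both members of the pair carry the code
    n10: int  # case only ("b")
    n01: int  # reference only ("c")
    n00: int  # neither

    def __post_init__(self):
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("negative cell count")

    @property
    def n_pairs(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


def _mcnemar_arrays(b: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised McNemar statistic, p-value and exact-branch flag."""
    b = np.asarray(b, dtype=np.int64)
    c = np.asarray(c, dtype=np.int64)
    n = b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        statistic = np.where(n > 0, (np.abs(b - c) - 1.0) ** 2 / np.where(n > 0, n, 1), 0.0)
    p_chi2 = stats.chi2.sf(statistic, df=1)
    # exact two-sided binomial: 2 * P(X <= min(b, c)), capped at 1
    k = np.minimum(b, c)
    p_exact = np.minimum(1.0, 2.0 * stats.binom.cdf(k, n, 0.5))
    exact = n < EXACT_BRANCH_THRESHOLD
    p = np.where(exact, p_exact, p_chi2)
    p = np.where(n == 0, 1.0, p)
    return statistic, p, exact


def mcnemar_test(counts: PairedCodeCounts) -> tuple[float, float, str]:
    """Matched McNemar test on one code's discordant pairs.

    Returns ``(statistic, p_value, branch)`` where ``branch`` is one of
    ``"chi2"``, ``"exact"`` or ``"no_discordant"``.  The statistic is always
    reported in the continuity-corrected chi-square form.
    """
    b, c = counts.n10, counts.n01
    statistic, p, exact = _mcnemar_arrays(np.array([b]), np.array([c]))
    if b + c == 0:
        return 0.0, 1.0, "no_discordant"
    return float(statistic[0]), float(p[0]), "exact" if exact[0] else "chi2"


def adjust_by(p_values, method: str = "by") -> np.ndarray:
    """FDR step-up adjustment; Benjamini-Yekutieli by default, BH optional."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    sm_method = {"by": "fdr_by", "bh": "fdr_bh"}[method]
    return multipletests(p, method=sm_method)[1]


def compute_or(counts: PairedCodeCounts, method: str = "conditional") -> float:
    """Odds ratio for one code.

    ``conditional`` (default) is the matched discordant-pair ratio ``b/c``;
    ``marginal`` collapses the pairs into an unmatched case/reference 2x2
    table.  A Haldane-Anscombe +0.5 is added to the relevant cells whenever
    any of them is zero.
    """
    if method == "conditional":
        b, c = float(counts.n10), float(counts.n01)
        if b == 0 or c == 0:
            b, c = b + 0.5, c + 0.5
        return b / c
    if method == "marginal":
        a = counts.n11 + counts.n10  # exposed cases
        bb = counts.n01 + counts.n00  # unexposed cases
        cc = counts.n11 + counts.n01  # exposed references
        d = counts.n10 + counts.n00  # unexposed references
        cells = np.array([a, bb, cc, d], dtype=float)
        if np.any(cells == 0):
            cells = cells + 0.5
        a, bb, cc, d = cells
        return (a * d) / (bb * cc)
    raise ValueError(f"unknown OR method {method!r}")


def paired_counts(
    matrix_case: pd.DataFrame, matrix_ref: pd.DataFrame
) -> pd.DataFrame:
    """Vectorised 2x2 pair counts for every code column.

    Both matrices must be indexed by ``pair_id`` with identical index and
    columns; rows are aligned by pair before counting.
    """
    if list(matrix_case.columns) != list(matrix_ref.columns):
        raise ValueError("case and reference matrices have different code axes")
    if set(matrix_case.index) != set(matrix_ref.index):
        raise ValueError("case and reference matrices cover different pair ids")
    matrix_ref = matrix_ref.reindex(matrix_case.index)
    case = matrix_case.to_numpy(dtype=bool)
    ref = matrix_ref.to_numpy(dtype=bool)
    return pd.DataFrame(
        {
            "n11": (case & ref).sum(axis=0),
            "n10": (case & ~ref).sum(axis=0),
            "n01": (~case & ref).sum(axis=0),
            "n00": (~case & ~ref).sum(axis=0),
        },
        index=matrix_case.columns,
    )


def screen_codes(
    matrix_case: pd.DataFrame,
    matrix_ref: pd.DataFrame,
    alpha: float = 0.05,
    fdr_method: str = "by",
    or_method: str = "conditional",
    require_or_gt_1: bool = True,
) -> pd.DataFrame:
    """Screen every code for matched case/reference imbalance.

    Returns one row per code with cells, statistic, raw p, FDR-adjusted q,
    both odds ratios and the significance flag
    ``(q < alpha) & (OR > 1 if require_or_gt_1)``.
    """
    counts = paired_counts(matrix_case, matrix_ref)
    b = counts["n10"].to_numpy()
    c = counts["n01"].to_numpy()
    statistic, p, exact = _mcnemar_arrays(b, c)
    q = adjust_by(p, method=fdr_method)

    bf, cf = b.astype(float), c.astype(float)
    zero = (bf == 0) | (cf == 0)
    or_cond = np.where(zero, (bf + 0.5) / (cf + 0.5), bf / np.where(cf == 0, 1, cf))
    a = (counts["n11"] + counts["n10"]).to_numpy(dtype=float)
    bb = (counts["n01"] + counts["n00"]).to_numpy(dtype=float)
    cc = (counts["n11"] + counts["n01"]).to_numpy(dtype=float)
    d = (counts["n10"] + counts["n00"]).to_numpy(dtype=float)
    zero_m = (a == 0) | (bb == 0) | (cc == 0) | (d == 0)
    am, bm, cm, dm = (np.where(zero_m, x + 0.5, x) for x in (a, bb, cc, d))
    or_marg = (am * dm) / (bm * cm)

    odds_ratio = or_cond if or_method == "conditional" else or_marg
    significant = q < alpha
    if require_or_gt_1:
        significant = significant & (odds_ratio > 1)
    out = counts.copy()
    out["statistic"] = statistic
    out["branch"] = np.where(
        (b + c) == 0, "no_discordant", np.where(exact, "exact", "chi2")
    )
    out["p_raw"] = p
    out["q_by" if fdr_method == "by" else "q_bh"] = q
    out["or_conditional"] = or_cond
    out["or_marginal"] = or_marg
    out["odds_ratio"] = odds_ratio
    out["significant"] = significant
    out.index.name = "code"
    return out


def replicate_filter(
    train_records: pd.DataFrame, validation_records: pd.DataFrame
) -> list[str]:
    """Codes significant in both the training and the validation screen."""
    if set(train_records.index) != set(validation_records.index):
        raise ValueError("train and validation screens cover different code axes")
    sig_train = train_records.index[train_records["significant"]]
    sig_val = validation_records.index[validation_records["significant"]]
    return sorted(set(sig_train) & set(sig_val))
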