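"""Principal-components factor analysis of validated binary codes.

The correlation matrix of the binary code indicators (the phi matrix) is
eigendecomposed; loadings are eigenvectors scaled by the square root of
their eigenvalues, optionally varimax-rotated.  Factor definitions collect
every code whose absolute loading meets the cutoff (0.2 by default; a code
may join several factors), patients are scored 1 on a factor if they carry
any member code, and factors too rare in the reference cohort are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.multivariate.factor_rotation import rotate_factors

__all__ = [
    "FactorModel",
    "FactorDefinition",
    "fit_factor_model",
    "scree_breakpoint",
    "select_k",
    "define_factors",
    "score_factors",
    "exclude_rare_factors",
]


@dataclass
class FactorModel:
    """Fitted principal-components factor model."""

    codes: list[str]
    loadings: pd.DataFrame  # codes x k
    eigenvalues: np.ndarray  # full spectrum, nonincreasing
    k: int
    rotation: str  # "none" | "varimax"
    dropped_constant: list[str] = field(default_factory=list)

    @property
    def cumulative_variance(self) -> np.ndarray:
        """Cumulative fraction of total variance over the full spectrum."""
        return np.cumsum(self.eigenvalues) / self.eigenvalues.sum()

    @property
    def communalities(self) -> pd.Series:
        return (self.loadings**2).sum(axis=1)


@dataclass(frozen=True)
class FactorDefinition:
    """A factor as the set of codes loading on it at or above the cutoff."""

    factor_id: str
    member_codes: tuple[str, ...]
    cutoff: float
    label: str = ""


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Flip each factor so its largest-magnitude loading is positive."""
    idx = np.argmax(np.abs(loadings), axis=0)
    signs = np.sign(loadings[idx, np.arange(loadings.shape[1])])
    signs[signs == 0] = 1.0
    return loadings * signs


def fit_factor_model(
    matrix: pd.DataFrame, k: int, rotation: str = "varimax"
) -> FactorModel:
    """Principal-components factor analysis of a binary code matrix.

    Constant columns carry no correlation information and are dropped with
    a warning.  ``k`` may not exceed the rank of the correlation matrix.
    The returned eigenvalue spectrum is the full one (its sum equals the
    number of analysed codes); loadings cover the leading ``k`` factors.
    """
    if rotation not in ("none", "varimax"):
        raise ValueError(f"unknown rotation {rotation!r}")
    x = matrix.to_numpy(dtype=float)
    const = x.std(axis=0) == 0
    dropped = [c for c, f in zip(matrix.columns, const) if f]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} constant code columns: {dropped[:5]}",
                      stacklevel=2)
        matrix = matrix.loc[:, ~const]
        x = x[:, ~const]
    codes = list(matrix.columns)
    corr = np.corrcoef(x, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    rank = int((eigvals > 1e-10).sum())
    if k > rank:
        raise ValueError(f"k={k} exceeds correlation-matrix rank {rank}")
    loadings = eigvecs[:, :k] * np.sqrt(np.clip(eigvals[:k], 0, None))
    if rotation == "varimax" and k > 1:
        loadings, _ = rotate_factors(loadings, "varimax")
    loadings = _fix_signs(loadings)
    frame = pd.DataFrame(
        loadings, index=codes, columns=[f"F{i + 1}" for i in range(k)]
    )
    return FactorModel(
        codes=codes,
        loadings=frame,
        eigenvalues=np.clip(eigvals, 0, None),
        k=k,
        rotation=rotation,
        dropped_constant=dropped,
    )


def scree_breakpoint(eigenvalues: np.ndarray) -> int:
    """Elbow of the scree curve by maximum second difference.

    The breakpoint is the last component before the sharpest bend, i.e.
    ``k = argmax_j (e[j-1] - 2 e[j] + e[j+1])`` over interior positions,
    counted 1-based.
    """
    e = np.asarray(eigenvalues, dtype=float)
    if len(e) < 3:
        return max(1, len(e) - 1)
    second = e[:-2] - 2 * e[1:-1] + e[2:]
    return int(np.argmax(second)) + 1


def select_k(
    matrix_case: pd.DataFrame,
    matrix_ref: pd.DataFrame,
    k_range,
    cutoff: float = 0.2,
    rotation: str = "varimax",
) -> dict:
    """Choose the number of factors and report all four diagnostics.

    For each candidate ``k`` a model is fitted on the pooled matrix, codes
    are reduced to binary factor scores, a conditional logistic model of
    case status on the scores is fitted on the matched pairs, and the AUC
    of its linear predictor is recorded.  The chosen ``k`` maximises this
    AUC (ties break toward the smaller ``k``).  Scree breakpoint, Kaiser
    count (eigenvalues > 1) and the cumulative-variance curve are reported
    alongside.
    """
    from .association import auc_of_model, fit_conditional_logistic

    k_range = sorted(set(int(k) for k in k_range))
    if not k_range:
        raise ValueError("empty candidate range for k")
    pooled = pd.concat([matrix_case, matrix_ref], axis=0)
    aucs: dict[int, float] = {}
    spectrum = None
    for k in k_range:
        model = fit_factor_model(pooled, k, rotation=rotation)
        spectrum = model.eigenvalues
        defs, _ = define_factors(model, cutoff=cutoff)
        if not defs:
            aucs[k] = 0.5
            continue
        sc_case = score_factors(matrix_case, defs)
        sc_ref = score_factors(matrix_ref, defs)
        try:
            fit = fit_conditional_logistic(sc_case, sc_ref)
            lin_case = sc_case.to_numpy() @ fit["coefficient"].to_numpy()
            lin_ref = sc_ref.to_numpy() @ fit["coefficient"].to_numpy()
        except ValueError:
            aucs[k] = 0.5
            continue
        scores = np.concatenate([lin_case, lin_ref])
        labels = np.concatenate([np.ones(len(lin_case)), np.zeros(len(lin_ref))])
        aucs[k] = auc_of_model(scores, labels)
    best_auc = max(aucs.values())
    chosen = min(k for k, a in aucs.items() if a == best_auc)
    return {
        "chosen_k": chosen,
        "auc_by_k": aucs,
        "scree_breakpoint": scree_breakpoint(spectrum),
        "kaiser_count": int((spectrum > 1.0).sum()),
        "eigenvalues": spectrum,
        "cumulative_variance": np.cumsum(spectrum) / spectrum.sum(),
    }


def define_factors(
    model: FactorModel, cutoff: float = 0.2
) -> tuple[list[FactorDefinition], list[str]]:
    """Factor definitions from the loading matrix.

    A code joins every factor where its absolute loading is at or above the
    cutoff (multi-membership allowed).  Returns the definitions plus the
    codes meeting the cutoff on no factor.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError(f"cutoff must be in (0, 1), got {cutoff}")
    qualifies = model.loadings.abs() >= cutoff
    defs = []
    for col in model.loadings.columns:
        members = tuple(model.loadings.index[qualifies[col]])
        if members:
            defs.append(FactorDefinition(factor_id=col, member_codes=members, cutoff=cutoff))
    unassigned = sorted(model.loadings.index[~qualifies.any(axis=1)])
    return defs, unassigned


def score_factors(
    matrix: pd.DataFrame, definitions: list[FactorDefinition]
) -> pd.DataFrame:
    """Binary factor scores: 1 if the patient carries any member code."""
    cols = {}
    for d in definitions:
        present = [c for c in d.member_codes if c in matrix.columns]
        missing = set(d.member_codes) - set(present)
        if not present:
            raise ValueError(f"factor {d.factor_id}: no member code in the matrix")
        if missing:
            warnings.warn(
                f"factor {d.factor_id}: ignoring {len(missing)} codes absent "
                f"from the matrix: {sorted(missing)[:5]}",
                stacklevel=2,
            )
        cols[d.factor_id] = (matrix[present].to_numpy().sum(axis=1) > 0).astype(np.int8)
    return pd.DataFrame(cols, index=matrix.index)


def exclude_rare_factors(
    scores: pd.DataFrame, roles: pd.Series, min_ref_count: int = 6
) -> tuple[list[str], list[str]]:
    """Drop factors with fewer than ``min_ref_count`` reference carriers.

    Returns ``(retained_ids, excluded_ids)``; the roles Series must be
    aligned to the score matrix index.
    """
    roles = roles.reindex(scores.index)
    if roles.isna().any():
        raise ValueError("roles not aligned with the score matrix")
    ref_counts = scores[roles.to_numpy() == "reference"].sum(axis=0)
    retained = [f for f in scores.columns if ref_counts[f] >= min_ref_count]
    excluded = [f for f in scores.columns if ref_counts[f] < min_ref_count]
    return retained, excluded
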