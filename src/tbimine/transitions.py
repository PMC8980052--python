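"""Transition maps: correlations, Fisher z, FDR masking, Ward clustering.

Pre-injury factor scores are correlated with event-phase factor scores (or
with severity / external-cause indicators) across patients; on binary
inputs the Pearson correlation is the phi coefficient.  Each correlation
is tested through the Fisher transformation ``z = atanh(r)`` with standard
error ``1/sqrt(n-3)``; p-values are FDR-adjusted jointly over all cells of
the map (Benjamini-Yekutieli by default) and non-significant cells are set
to 0.  Rows and columns of the masked map are ordered by agglomerative
Ward clustering on correlation distance (``1 - r`` between profiles).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist, squareform

from .screening import adjust_by

__all__ = [
    "TransitionMap",
    "ClusterResult",
    "correlation_matrix",
    "fisher_significance",
    "fdr_mask",
    "ward_cluster",
    "transition_map",
    "grouped_transition_map",
    "render_heatmap",
    "compare_splits",
]


@dataclass
class ClusterResult:
    """Ward linkage over one axis of a transition map."""

    axis: str  # "rows" | "columns"
    item_ids: list[str]
    linkage_matrix: np.ndarray  # scipy (n-1, 4) merge list
    leaf_order: list[str]

    def flat_clusters(self, n_clusters: int) -> pd.Series:
        labels = fcluster(self.linkage_matrix, t=n_clusters, criterion="maxclust")
        return pd.Series(labels, index=self.item_ids, name="cluster")


@dataclass
class TransitionMap:
    """Correlations with significance and masking over a pair of score sets."""

    r: pd.DataFrame
    z: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    masked: pd.DataFrame
    n: int
    alpha: float
    row_cluster: ClusterResult | None = None
    col_cluster: ClusterResult | None = None
    undefined: pd.DataFrame | None = None  # cells from constant columns

    def ordered_masked(self) -> pd.DataFrame:
        rows = self.row_cluster.leaf_order if self.row_cluster else list(self.masked.index)
        cols = self.col_cluster.leaf_order if self.col_cluster else list(self.masked.columns)
        return self.masked.loc[rows, cols]


def correlation_matrix(
    scores_a: pd.DataFrame, scores_b: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson (phi, on binaries) correlations between two score sets.

    Both frames must share the patient axis.  Returns ``(r, undefined)``
    where ``undefined`` flags cells involving a constant column (their r is
    NaN and they are excluded from the FDR family downstream).
    """
    if not scores_a.index.equals(scores_b.index):
        if set(scores_a.index) != set(scores_b.index):
            raise ValueError("score matrices cover different patients")
        scores_b = scores_b.reindex(scores_a.index)
    a = scores_a.to_numpy(dtype=float)
    b = scores_b.to_numpy(dtype=float)
    sd_a = a.std(axis=0)
    sd_b = b.std(axis=0)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (ac.T @ bc) / len(a) / np.outer(sd_a, sd_b)
    undefined = np.isnan(r) | (np.outer(sd_a == 0, np.ones(b.shape[1], bool)))
    undefined |= np.outer(np.ones(a.shape[1], bool), sd_b == 0)
    r_frame = pd.DataFrame(r, index=scores_a.columns, columns=scores_b.columns)
    und_frame = pd.DataFrame(undefined, index=scores_a.columns, columns=scores_b.columns)
    return r_frame, und_frame


def fisher_significance(r, n: int):
    """Fisher z statistic and two-sided normal p-value for correlations.

    ``z = atanh(r)`` and ``p = 2 Phi(-|z| sqrt(n-3))``.  ``|r| = 1`` yields
    ``z = +/-inf`` and ``p = 0`` (degenerate, flagged upstream by masking).
    Requires ``n > 3``.
    """
    if n <= 3:
        raise ValueError(f"Fisher significance needs n > 3, got n={n}")
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.arctanh(np.clip(r, -1.0, 1.0))
    p = 2.0 * stats.norm.sf(np.abs(z) * np.sqrt(n - 3))
    p = np.where(np.isinf(z), 0.0, p)
    return z, p


def fdr_mask(
    r: pd.DataFrame,
    p: pd.DataFrame,
    alpha: float = 0.05,
    method: str = "by",
    undefined: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Joint FDR adjustment over all defined cells; mask the rest to 0.

    Returns ``(masked, q)``: cells with ``q > alpha`` (or undefined r) are
    set to 0 in ``masked``; undefined cells carry ``q = NaN``.
    """
    pv = p.to_numpy(dtype=float).copy()
    if undefined is not None:
        excl = undefined.to_numpy(dtype=bool)
    else:
        excl = np.isnan(r.to_numpy())
    flat = pv[~excl]
    q = np.full_like(pv, np.nan)
    if flat.size:
        q[~excl] = adjust_by(flat, method=method)
    keep = (q <= alpha) & ~excl
    masked = np.where(keep, np.nan_to_num(r.to_numpy(dtype=float)), 0.0)
    return (
        pd.DataFrame(masked, index=r.index, columns=r.columns),
        pd.DataFrame(q, index=r.index, columns=r.columns),
    )


def _profile_distance(profiles: np.ndarray) -> np.ndarray:
    """Condensed correlation distance ``1 - r`` between profile rows.

    Constant profiles have undefined correlation; their distance defaults
    to 1 (no association).
    """
    d = pdist(profiles, metric="correlation")
    return np.nan_to_num(d, nan=1.0)


def ward_cluster(matrix: pd.DataFrame, axis: str = "rows") -> ClusterResult:
    """Agglomerative Ward clustering of map rows or columns.

    Distances are ``1 - r`` between row (or column) profiles of the masked
    matrix.  scipy's Ward implementation applies the Lance-Williams update
    and breaks ties deterministically on the input order.
    """
    if axis not in ("rows", "columns"):
        raise ValueError(f"axis must be 'rows' or 'columns', got {axis!r}")
    items = list(matrix.index if axis == "rows" else matrix.columns)
    if len(items) < 2:
        raise ValueError("need at least 2 items to cluster")
    profiles = matrix.to_numpy(dtype=float)
    if axis == "columns":
        profiles = profiles.T
    z = linkage(_profile_distance(profiles), method="ward")
    order = [items[i] for i in leaves_list(z)]
    return ClusterResult(axis=axis, item_ids=items, linkage_matrix=z, leaf_order=order)


def transition_map(
    scores_a: pd.DataFrame,
    scores_b: pd.DataFrame,
    alpha: float = 0.05,
    method: str = "by",
    cluster: bool = True,
) -> TransitionMap:
    """Full correlation -> Fisher -> FDR-mask -> Ward-cluster path."""
    r, undefined = correlation_matrix(scores_a, scores_b)
    n = len(scores_a)
    z, p = fisher_significance(r.to_numpy(), n)
    z = pd.DataFrame(z, index=r.index, columns=r.columns)
    p = pd.DataFrame(p, index=r.index, columns=r.columns)
    masked, q = fdr_mask(r, p, alpha=alpha, method=method, undefined=undefined)
    tm = TransitionMap(
        r=r, z=z, p=p, q=q, masked=masked, n=n, alpha=alpha, undefined=undefined
    )
    if cluster and len(masked.index) >= 2:
        tm.row_cluster = ward_cluster(masked, "rows")
    if cluster and len(masked.columns) >= 2:
        tm.col_cluster = ward_cluster(masked, "columns")
    return tm


def grouped_transition_map(
    pre_scores: pd.DataFrame,
    labels: pd.DataFrame,
    severity_categories=("mild", "moderate", "severe", "unspecified"),
    alpha: float = 0.05,
    method: str = "by",
) -> TransitionMap:
    """Pre-injury factors against severity and cause groupings.

    Columns are one-hot severity indicators plus the (non-exclusive) cause
    indicators from the label table; categories absent from the data are
    dropped with a warning.  The same correlation / Fisher / mask / cluster
    path as the factor-factor map is applied.
    """
    import warnings

    labels = labels.reindex(pre_scores.index)
    if labels.isna().any().any():
        raise ValueError("labels not aligned with the pre-injury score matrix")
    cols = {}
    for cat in severity_categories:
        ind = (labels["severity"] == cat).astype(np.int8)
        if ind.sum() == 0:
            warnings.warn(f"severity category {cat!r} absent; column dropped", stacklevel=2)
            continue
        cols[f"severity:{cat}"] = ind
    for cat in labels.columns:
        if cat in ("severity", "missing"):
            continue
        ind = labels[cat].astype(np.int8)
        if ind.sum() == 0:
            warnings.warn(f"cause category {cat!r} absent; column dropped", stacklevel=2)
            continue
        cols[f"cause:{cat}"] = ind
    event_cols = pd.DataFrame(cols, index=pre_scores.index)
    return transition_map(pre_scores, event_cols, alpha=alpha, method=method)


def _rank_binned(masked: np.ndarray, n_bins: int = 4) -> np.ndarray:
    """Signed quantile-bin transform of nonzero cells for display."""
    out = np.zeros_like(masked, dtype=float)
    nz = masked != 0
    if nz.sum() == 0:
        return out
    mags = np.abs(masked[nz])
    edges = np.quantile(mags, np.linspace(0, 1, n_bins + 1)[1:-1])
    bins = 1 + np.searchsorted(edges, mags)
    out[nz] = np.sign(masked[nz]) * bins / n_bins
    return out


def render_heatmap(tm: TransitionMap, png_path, tsv_path, title: str = "") -> None:
    """Write the heatmap image and the exact masked values as TSV.

    Positive correlations render magenta, negative green, masked cells
    white; the colour scale is a signed rank binning of the nonzero cells.
    Row/column order follows the Ward leaf orders.  The TSV holds the exact
    masked values in the same order and round-trips bit-exactly.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = tm.ordered_masked()
    ordered.to_csv(tsv_path, sep="\t")
    display = _rank_binned(ordered.to_numpy())
    fig, ax = plt.subplots(
        figsize=(max(4, 0.3 * ordered.shape[1] + 2), max(3, 0.3 * ordered.shape[0] + 1))
    )
    im = ax.imshow(display, cmap="PiYG_r", vmin=-1, vmax=1, aspect="auto")
    ax.set_xticks(range(ordered.shape[1]))
    ax.set_xticklabels(ordered.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(ordered.shape[0]))
    ax.set_yticklabels(ordered.index, fontsize=6)
    if title:
        ax.set_title(title, fontsize=9)
    fig.colorbar(im, ax=ax, label="signed rank bin of r")
    fig.tight_layout()
    fig.savefig(png_path, dpi=150)
    plt.close(fig)


def compare_splits(maps: dict[str, TransitionMap], n_clusters: int = 4) -> pd.DataFrame:
    """Pairwise concordance of masked maps across splits.

    Reports, per split pair: the per-cell sign agreement rate, the Jaccard
    index of the significant (nonzero) cell sets, and the adjusted Rand
    index between row flat-cluster assignments.
    """
    from sklearn.metrics import adjusted_rand_score

    names = list(maps)
    axes = [(list(maps[n].masked.index), list(maps[n].masked.columns)) for n in names]
    if any(a != axes[0] for a in axes[1:]):
        raise ValueError("masked maps have mismatched axes across splits")
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a = maps[names[i]].masked.to_numpy()
            b = maps[names[j]].masked.to_numpy()
            sign_agree = float((np.sign(a) == np.sign(b)).mean())
            nz_a, nz_b = a != 0, b != 0
            union = (nz_a | nz_b).sum()
            jaccard = float((nz_a & nz_b).sum() / union) if union else 1.0
            ari = np.nan
            ca, cb = maps[names[i]].row_cluster, maps[names[j]].row_cluster
            if ca is not None and cb is not None:
                k = min(n_clusters, len(ca.item_ids))
                ari = float(
                    adjusted_rand_score(
                        ca.flat_clusters(k).to_numpy(), cb.flat_clusters(k).to_numpy()
                    )
                )
            rows.append(
                {
                    "split_a": names[i],
                    "split_b": names[j],
                    "sign_agreement": sign_agree,
                    "jaccard_significant": jaccard,
                    "cluster_ari": ari,
                }
            )
    return pd.DataFrame(rows)
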