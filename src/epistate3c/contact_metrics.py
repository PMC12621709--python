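"""Per-cell contact-distance metrics and TAD-boundary density.

The *contact score* summarizes a cell's contact-decay profile with a
Gaussian kernel over the distance-bin axis, centered at the midpoint of the
distance range, sigma = N/6 (N = number of distance bins), normalized to
sum to 1:

    K_i = exp(-((i - c)/sigma)^2 / 2) / sum_j exp(-((j - c)/sigma)^2 / 2)
    score_c = sum_i K_i * R_{i,c}

with R_{i,c} the fraction of cell c's cis contacts in distance bin i.
Because the kernel mass sits mid-profile, cells enriched in short-range
contacts score higher than long-range-enriched cells for geometric distance
binnings; cells are classified Short/Long by k-means (k = 2) in a 2-component
PCA of the profile matrix, with the higher-mean-score cluster labeled Short.

The insulation-based boundary caller is deliberately plain plumbing: a
sliding w x w diamond mean along the diagonal, with boundaries at local
minima whose depth below the flanking maxima exceeds ``min_depth``. It
exists so the single-cell pipeline can run end-to-end; it is not a
re-implementation of any published TAD caller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "geometric_edges",
    "decay_profile",
    "decay_profile_matrix",
    "ContactScore",
    "contact_score",
    "kernel_weights",
    "classify_short_long",
    "call_boundaries_insulation",
    "boundary_density",
    "adjust_boundary_density",
]


def geometric_edges(
    dmin: int = 25_000, dmax: int | None = None, factor: float = 2.0,
    chrom_lengths: dict | None = None,
) -> np.ndarray:
    """Geometric distance-bin edges, factor 2, from 25 kb to half the largest
    chromosome by default."""
    if dmax is None:
        if not chrom_lengths:
            raise ValueError("need dmax or chrom_lengths")
        dmax = max(chrom_lengths.values()) // 2
    edges = [float(dmin)]
    while edges[-1] < dmax:
        edges.append(edges[-1] * factor)
    return np.asarray(edges)


def decay_profile(
    chrom1: np.ndarray,
    pos1: np.ndarray,
    chrom2: np.ndarray,
    pos2: np.ndarray,
    edges: np.ndarray,
) -> np.ndarray:
    """Fraction of one cell's cis contacts per distance bin.

    Trans contacts and contacts below the minimum edge are excluded; the
    returned fractions sum to 1 when any contact survives (otherwise an
    all-zero profile is returned).
    """
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing with >= 2 entries")
    cis = np.asarray(chrom1) == np.asarray(chrom2)
    d = np.abs(np.asarray(pos2)[cis] - np.asarray(pos1)[cis]).astype(float)
    d = d[d >= edges[0]]
    counts, _ = np.histogram(d, bins=edges)
    total = counts.sum()
    if total == 0:
        warnings.warn("cell has zero cis contacts in range; all-zero profile")
        return np.zeros(len(edges) - 1)
    return counts / total


def decay_profile_matrix(
    contacts: pd.DataFrame, edges: np.ndarray, cells: pd.Index | None = None
) -> pd.DataFrame:
    """Cells x distance-bin fraction matrix for a whole cohort contact list."""
    edges = np.asarray(edges, dtype=float)
    cis = (contacts["chrom1"] == contacts["chrom2"]).to_numpy()
    sub = contacts.loc[cis]
    d = np.abs(sub["pos2"].to_numpy() - sub["pos1"].to_numpy()).astype(float)
    keep = (d >= edges[0]) & (d <= edges[-1])
    sub = sub.loc[keep]
    d = d[keep]
    bin_idx = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, len(edges) - 2)
    if cells is None:
        cells = pd.Index(pd.unique(contacts["cell_id"]))
    cell_codes = pd.Categorical(sub["cell_id"], categories=cells).codes
    mat = np.zeros((len(cells), len(edges) - 1))
    np.add.at(mat, (cell_codes, bin_idx), 1.0)
    totals = mat.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.where(totals > 0, mat / np.maximum(totals, 1), 0.0)
    return pd.DataFrame(mat, index=cells)


def kernel_weights(n_bins: int, sigma: float | None = None) -> np.ndarray:
    """Normalized Gaussian kernel over 1-based bin indices, center (N+1)/2,
    default sigma = N/6."""
    if n_bins < 1:
        raise ValueError("need at least one distance bin")
    if sigma is None:
        sigma = n_bins / 6.0
    i = np.arange(1, n_bins + 1, dtype=float)
    c = (n_bins + 1) / 2.0
    w = np.exp(-0.5 * ((i - c) / sigma) ** 2)
    return w / w.sum()


@dataclass
class ContactScore:
    cell_id: str
    weights: np.ndarray
    score: float


def contact_score(
    profile: np.ndarray, sigma: float | None = None, cell_id: str = ""
) -> ContactScore:
    """Gaussian-kernel weighted average of a contact-decay profile."""
    profile = np.asarray(profile, dtype=float)
    w = kernel_weights(len(profile), sigma)
    return ContactScore(cell_id=cell_id, weights=w, score=float(w @ profile))


def classify_short_long(
    profiles: pd.DataFrame,
    standardize: bool = True,
    seed: int = 0,
    sigma: float | None = None,
) -> pd.DataFrame:
    """Classify cells as Short- or Long-range enriched.

    Computes per-cell contact scores (optionally z-scored across cells),
    applies PCA (2 components) to the profile matrix, runs k-means (k = 2)
    in PC space, and labels the cluster with the higher mean contact score
    ``Short``. Returns a table with columns score, standardized_score, class.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 cells")
    X = profiles.to_numpy(dtype=float)
    w = kernel_weights(X.shape[1], sigma)
    scores = X @ w
    std_scores = scores.copy()
    if standardize:
        sd = scores.std()
        if sd > 0:
            std_scores = (scores - scores.mean()) / sd
    if np.allclose(X, X[0]):
        warnings.warn("identical profiles; all cells assigned one class (Short)")
        labels = np.zeros(len(X), dtype=int)
        cls = np.array(["Short"] * len(X))
    else:
        pcs = PCA(n_components=min(2, X.shape[1], len(X) - 1)).fit_transform(X)
        km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(pcs)
        labels = km.labels_
        mean0 = scores[labels == 0].mean()
        mean1 = scores[labels == 1].mean()
        short_cluster = 0 if mean0 >= mean1 else 1
        cls = np.where(labels == short_cluster, "Short", "Long")
    return pd.DataFrame(
        {"score": scores, "standardized_score": std_scores, "class": cls},
        index=profiles.index,
    )


def call_boundaries_insulation(
    matrix: np.ndarray, window_bins: int = 4, min_depth: float = 0.05
) -> np.ndarray:
    """Insulation-minimum boundary calls on a square contact matrix.

    Insulation at bin i is the mean of the w x w diamond crossing the
    diagonal at i; candidate boundaries are local minima whose depth below
    both flanking maxima exceeds ``min_depth`` (relative to the mean
    insulation). Edge bins within the window are never boundaries.
    """
    M = np.asarray(matrix, dtype=float)
    n = M.shape[0]
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("matrix must be square")
    w = int(window_bins)
    if w < 1 or 2 * w >= n:
        raise ValueError("window larger than matrix")
    ins = np.full(n, np.nan)
    for i in range(w, n - w):
        ins[i] = M[i - w : i, i + 1 : i + 1 + w].mean()
    scale = np.nanmean(ins)
    scale = scale if scale > 0 else 1.0
    calls = np.zeros(n, dtype=np.int8)
    valid = np.arange(w, n - w)
    for i in valid:
        left = ins[max(w, i - w) : i]
        right = ins[i + 1 : min(n - w, i + w + 1)]
        if left.size == 0 or right.size == 0:
            continue
        if ins[i] <= left.min() and ins[i] <= right.min():
            depth = min(left.max(), right.max()) - ins[i]
            if depth / scale > min_depth:
                calls[i] = 1
    # tied-minimum plateaus: keep only the first bin of each run
    for i in range(1, n):
        if calls[i] and calls[i - 1] and ins[i] == ins[i - 1]:
            calls[i] = 0
    return calls


def boundary_density(
    calls: np.ndarray,
    bins: pd.DataFrame,
    meta: pd.DataFrame,
    window: int = 1_000_000,
    sample_keys: tuple[str, ...] = ("region", "disease", "donor", "cell_type"),
) -> pd.DataFrame:
    """Per-sample, per-1-Mb-window boundary events per cell.

    ``calls`` is the binary cells x 25-kb-bin matrix (any boundary signal in
    a bin counts once per cell); each bin is assigned to the window holding
    its genomic start coordinate. Density = event count / cells in sample.
    Samples with zero cells are dropped.
    """
    meta = meta.iloc[: calls.shape[0]] if len(meta) != calls.shape[0] else meta
    win_id = bins["chrom"].astype(str) + ":" + (
        (bins["start"] // window) * window
    ).astype(str)
    win_codes, win_labels = pd.factorize(win_id)
    binary = (np.asarray(calls) > 0).astype(np.int64)
    rows = []
    for key, sub in meta.groupby(list(sample_keys), observed=True):
        cell_pos = meta.index.get_indexer(sub.index)
        n_cells = len(cell_pos)
        if n_cells == 0:
            continue
        ev = binary[cell_pos].sum(axis=0)
        win_events = np.bincount(win_codes, weights=ev, minlength=len(win_labels))
        for wi, label in enumerate(win_labels):
            rows.append(
                dict(zip(sample_keys, key))
                | {"window": label, "density": win_events[wi] / n_cells}
            )
    return pd.DataFrame(rows)


def adjust_boundary_density(
    density: pd.DataFrame,
    covariate: pd.Series,
    sample_keys: tuple[str, ...] = ("region", "disease", "donor", "cell_type"),
) -> pd.DataFrame:
    """Regress per-window boundary density on mean cis-long contact count.

    ``covariate`` maps a sample key tuple (joined with '|') to that sample's
    mean cis long-range contact count. Per window an OLS line is fit and the
    residuals returned as ``adjusted_density``; windows with fewer than 3
    samples are mean-centered with a warning.
    """
    out = density.copy()
    key = out[list(sample_keys)].astype(str).agg("|".join, axis=1)
    out["_cov"] = key.map(covariate)
    adjusted = np.full(len(out), np.nan)
    for _, idx in out.groupby("window", observed=True).groups.items():
        sub = out.loc[idx]
        y = sub["density"].to_numpy(dtype=float)
        x = sub["_cov"].to_numpy(dtype=float)
        if len(sub) < 3 or np.ptp(x) == 0:
            if len(sub) < 3:
                warnings.warn("window with <3 samples: mean-centered only")
            adjusted[out.index.get_indexer(idx)] = y - y.mean()
            continue
        X = np.column_stack([np.ones_like(x), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        adjusted[out.index.get_indexer(idx)] = y - X @ beta
    out["adjusted_density"] = adjusted
    return out.drop(columns="_cov")


def mean_cis_long_contacts(
    contacts: pd.DataFrame,
    meta: pd.DataFrame,
    anchor_gap: int = 2_500,
    sample_keys: tuple[str, ...] = ("region", "disease", "donor", "cell_type"),
) -> pd.Series:
    """Mean per-cell cis long-range contact count (anchors > 2,500 bp apart)
    per sample, keyed by the '|'-joined sample tuple."""
    cis = contacts["chrom1"] == contacts["chrom2"]
    gap = (contacts["pos2"] - contacts["pos1"]).abs() > anchor_gap
    per_cell = contacts.loc[cis & gap].groupby("cell_id", observed=True).size()
    per_cell = per_cell.reindex(meta.index, fill_value=0)
    df = meta.copy()
    df["_n"] = per_cell
    g = df.groupby(list(sample_keys), observed=True)["_n"].mean()
    g.index = ["|".join(map(str, k)) for k in g.index]
    return g
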