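"""Single-cell methylome containers, QC, bin selection and hypomethylation scores.

The central statistic is the per-bin *hypomethylation score*: given a cell's
expected methylation probability ``p`` (the mean per-bin methylation fraction
over that cell's covered bins), the score of a bin with coverage ``c`` and
methylated count ``m`` is the binomial survival probability

    score = P(X > m),   X ~ Binomial(c, p)

i.e. the likelihood of observing *more* methylated reads than seen. Scores
near 1 mark strongly hypomethylated bins; a matrix of scores is binarized at
a strict cutoff (> 0.9) for downstream clustering. The survival function is
evaluated through the regularized incomplete beta (scipy), which is stable
up to the 10^7-read coverages seen in deep cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MethylBinCounts",
    "QCThresholds",
    "qc_filter",
    "blacklist_overlap_fraction",
    "filter_bins",
    "hypo_score",
    "binarize_scores",
    "cell_global_levels",
    "global_levels",
]

CONTEXTS = ("CG", "CH", "CCC")
AUTOSOME_EXCLUDE = {"chrX", "chrY", "chrM"}


@dataclass
class MethylBinCounts:
    """Cells x genomic-bins count table per cytosine context.

    ``bins`` has columns (chrom, start, end), 0-based half-open, sorted and
    non-overlapping within each chromosome. ``data`` maps a context (CG, CH,
    CCC) to an ``(mc, cov)`` pair of integer arrays of shape
    (n_cells, n_bins), with ``mc <= cov`` elementwise.
    """

    cells: pd.Index
    bins: pd.DataFrame
    data: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cells = pd.Index(self.cells)
        for ctx, (mc, cov) in self.data.items():
            if mc.shape != (len(self.cells), len(self.bins)) or mc.shape != cov.shape:
                raise ValueError(f"context {ctx!r}: array shape mismatch")
            if np.any(mc > cov) or np.any(mc < 0):
                raise ValueError(f"context {ctx!r}: requires 0 <= mc <= cov")
        for _, sub in self.bins.groupby("chrom", sort=False):
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            if np.any(np.diff(s) <= 0) or np.any(e[:-1] > s[1:]):
                raise ValueError("bins must be sorted and non-overlapping per chromosome")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def fraction(self, context: str) -> np.ndarray:
        """Per (cell, bin) methylation fraction; NaN where coverage is 0."""
        mc, cov = self.data[context]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cov > 0, mc / np.maximum(cov, 1), np.nan)

    def subset_bins(self, idx: np.ndarray) -> "MethylBinCounts":
        return MethylBinCounts(
            cells=self.cells,
            bins=self.bins.iloc[idx].reset_index(drop=True),
            data={c: (mc[:, idx], cov[:, idx]) for c, (mc, cov) in self.data.items()},
        )

    def to_long_tsv(self, path) -> None:
        """Write the long TSV form (cell_id, chrom, bin_start, context, mc, cov)."""
        frames = []
        for ctx, (mc, cov) in self.data.items():
            ci, bi = np.nonzero(cov)
            frames.append(
                pd.DataFrame(
                    {
                        "cell_id": self.cells[ci],
                        "chrom": self.bins["chrom"].to_numpy()[bi],
                        "bin_start": self.bins["start"].to_numpy()[bi],
                        "context": ctx,
                        "mc": mc[ci, bi],
                        "cov": cov[ci, bi],
                    }
                )
            )
        pd.concat(frames).to_csv(path, sep="\t", index=False)


@dataclass
class QCThresholds:
    """Cell-level QC cutoffs. All comparisons are strict, as stated."""

    mccc_max: float = 0.05
    mch_max: float = 0.2
    mcg_min: float = 0.5
    reads_min: float = 500_000
    reads_max: float = 10_000_000
    mapping_rate_min: float = 0.5
    cis_long_min: float = 50_000
    cis_long_anchor_gap: int = 2_500

    def __post_init__(self) -> None:
        if not (0 < self.mcg_min < 1):
            raise ValueError("mcg_min must lie in (0, 1)")
        for name in ("mccc_max", "mch_max", "reads_min", "reads_max",
                     "mapping_rate_min", "cis_long_min", "cis_long_anchor_gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


_QC_METRICS = ["mccc", "mch", "mcg", "total_reads", "mapping_rate"]


def qc_filter(
    meta: pd.DataFrame,
    thresholds: QCThresholds | None = None,
    require_3c: bool = False,
) -> tuple[pd.Index, dict[str, int]]:
    """Apply cell-level QC; returns passing cell ids and per-criterion fail counts.

    A cell passes iff mCCC < 0.05, mCH < 0.2, mCG > 0.5, 0.5M <= reads <= 10M
    and mapping rate > 0.5; with ``require_3c``, additionally
    cis long-range contacts (anchors > 2,500 bp apart) strictly > 50,000.
    """
    t = thresholds or QCThresholds()
    needed = list(_QC_METRICS) + (["cis_long_contacts"] if require_3c else [])
    for col in needed:
        if col not in meta.columns:
            raise ValueError(f"QC metric column {col!r} missing from metadata")
    fails = {
        "mccc": meta["mccc"] >= t.mccc_max,
        "mch": meta["mch"] >= t.mch_max,
        "mcg": meta["mcg"] <= t.mcg_min,
        "reads": (meta["total_reads"] < t.reads_min)
        | (meta["total_reads"] > t.reads_max),
        "mapping_rate": meta["mapping_rate"] <= t.mapping_rate_min,
    }
    if require_3c:
        fails["cis_long"] = meta["cis_long_contacts"] <= t.cis_long_min
    any_fail = np.zeros(len(meta), dtype=bool)
    counts: dict[str, int] = {}
    for name, mask in fails.items():
        counts[name] = int(mask.sum())
        any_fail |= mask.to_numpy()
    return meta.index[~any_fail], counts


def blacklist_overlap_fraction(
    bins: pd.DataFrame, blacklist: pd.DataFrame
) -> np.ndarray:
    """Fraction of each bin covered by (merged) blacklist intervals."""
    frac = np.zeros(len(bins), dtype=float)
    if blacklist is None or len(blacklist) == 0:
        return frac
    for chrom, bl in blacklist.groupby("chrom", sort=False):
        sel = np.flatnonzero((bins["chrom"] == chrom).to_numpy())
        if sel.size == 0:
            continue
        iv = bl.sort_values("start")[["start", "end"]].to_numpy(dtype=float)
        # merge overlapping blacklist intervals
        merged: list[list[float]] = []
        for s, e in iv:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        starts = bins["start"].to_numpy(dtype=float)[sel]
        ends = bins["end"].to_numpy(dtype=float)[sel]
        ov = np.zeros(sel.size)
        for s, e in merged:
            ov += np.clip(np.minimum(ends, e) - np.maximum(starts, s), 0.0, None)
        frac[sel] = ov / (ends - starts)
    return frac


def filter_bins(
    counts: MethylBinCounts,
    blacklist: pd.DataFrame | None = None,
    coverage_min: float = 500,
    coverage_max: float = 3000,
    top_k: int = 20_000,
    max_blacklist_overlap: float = 0.20,
    context: str = "CG",
) -> np.ndarray:
    """Select clustering bins; returns sorted bin indices into ``counts.bins``.

    Keeps autosomal bins whose total coverage lies strictly inside
    (coverage_min, coverage_max) and whose blacklist overlap fraction is
    below ``max_blacklist_overlap``, then ranks the survivors by the variance
    of the per-cell methylation fraction and keeps the ``top_k`` most
    variable (ties broken by genomic order).
    """
    _, cov = counts.data[context]
    total_cov = cov.sum(axis=0)
    keep = (total_cov > coverage_min) & (total_cov < coverage_max)
    keep &= ~counts.bins["chrom"].isin(AUTOSOME_EXCLUDE).to_numpy()
    if blacklist is not None and len(blacklist):
        keep &= blacklist_overlap_fraction(counts.bins, blacklist) < max_blacklist_overlap
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        return idx
    frac = counts.fraction(context)[:, idx]
    with np.errstate(invalid="ignore"):
        var = np.nanvar(frac, axis=0)
    var = np.nan_to_num(var, nan=-1.0)
    if top_k < idx.size:
        order = np.argsort(-var, kind="stable")[:top_k]
        idx = np.sort(idx[order])
    else:
        if top_k > idx.size:
            import warnings

            warnings.warn(
                f"top_k={top_k} exceeds {idx.size} surviving bins; keeping all"
            )
    return idx


def binomial_hypo_sf(m, cov, p):
    """Scoring kernel: P(X > m) for X ~ Binomial(cov, p).

    Evaluated through the regularized incomplete beta (scipy's binomial
    survival function), numerically stable for coverages up to 10^7.
    Broadcasts over array inputs.
    """
    return stats.binom.sf(m, cov, p)


def hypo_score(counts: MethylBinCounts, context: str = "CG") -> np.ndarray:
    """Per (cell, bin) hypomethylation score P(X > m), X ~ Binomial(cov, p).

    ``p`` is estimated per cell as the mean methylation fraction across that
    cell's covered bins. Bins with zero coverage get NaN (no data).
    """
    mc, cov = counts.data[context]
    frac = counts.fraction(context)
    with np.errstate(invalid="ignore"):
        p_cell = np.nanmean(frac, axis=1)
    p_cell = np.nan_to_num(p_cell, nan=0.0)
    score = binomial_hypo_sf(mc, cov, p_cell[:, None])
    return np.where(cov > 0, score, np.nan)


def binarize_scores(scores: np.ndarray, cutoff: float = 0.9) -> np.ndarray:
    """1 where score > cutoff (strict), else 0; missing scores map to 0."""
    with np.errstate(invalid="ignore"):
        return (np.nan_to_num(scores, nan=0.0) > cutoff).astype(np.int8)


def cell_global_levels(
    counts: MethylBinCounts, contexts: Sequence[str] = ("CG", "CH")
) -> pd.DataFrame:
    """Per-cell global methylation level: total mc / total cov per context."""
    out = {}
    for ctx in contexts:
        mc, cov = counts.data[ctx]
        tot = cov.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[ctx] = np.where(tot > 0, mc.sum(axis=1) / np.maximum(tot, 1), np.nan)
    return pd.DataFrame(out, index=counts.cells)


def global_levels(
    counts: MethylBinCounts,
    meta: pd.DataFrame,
    group_by: Iterable[str] = ("cell_type", "donor", "region"),
    contexts: Sequence[str] = ("CG", "CH"),
) -> pd.DataFrame:
    """Median per-cell global CG/CH level per metadata group."""
    levels = cell_global_levels(counts, contexts).join(meta.loc[counts.cells])
    grouped = levels.groupby(list(group_by), observed=True)[list(contexts)].median()
    sizes = levels.groupby(list(group_by), observed=True).size()
    grouped = grouped[sizes.loc[grouped.index] > 0]
    return grouped
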