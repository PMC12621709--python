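"""Per-pixel differential-contact F-statistics between sample groups.

Group-level contact statistics are reconstructed from per-sample mean and
squared-mean matrices: each is multiplied by the number of contributing
cells and summed, giving cumulative sum and sum-of-squares matrices per
group. Per pixel the standard one-way ANOVA decomposition applies:

    SSW = sum_g [ Sx2_g - (Sx_g)^2 / N_g ]
    SST =        Sx2    - (Sx)^2    / N       (pooled accumulator)
    SSB = SST - SSW
    F   = (SSB / (g - 1)) / (SSW / (N - g))

The F transform is isolated in :func:`pixel_f_statistic` so an alternative
variance-ratio definition is a one-line swap. Pixels with SSW = 0 but
SSB > 0 get a +inf sentinel (ranked above all finite F); SST = 0 gives
F = 0 by convention. Candidate pixels are masked to the upper triangle, a
5-500-bin distance range, and at least 8 bins away from any blacklisted
bin (a +/-7-bin pad around the blacklist is excluded).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .linear_models import DesignSpec, FeatureAssociation, fit_feature_model

__all__ = [
    "GroupContactAccumulator",
    "accumulate_group",
    "pixel_f_statistic",
    "mask_pixels",
    "loop_covariate_regression",
]

MASK_NONE = "none"
MASK_BLACKLIST = "blacklist"
MASK_DISTANCE = "distance"
MASK_LOWER = "lower_triangle"


@dataclass
class GroupContactAccumulator:
    """Cumulative per-pixel statistics for one sample group."""

    label: str
    sum_x: np.ndarray
    sum_x2: np.ndarray
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("accumulator needs n >= 1 cells")
        if self.sum_x.shape != self.sum_x2.shape:
            raise ValueError("sum and sum-of-squares shapes differ")
        if np.any(self.sum_x2 < -1e-12):
            raise ValueError("sum of squares must be nonnegative")

    def combine(self, other: "GroupContactAccumulator") -> "GroupContactAccumulator":
        if self.sum_x.shape != other.sum_x.shape:
            raise ValueError("accumulator shapes differ")
        return GroupContactAccumulator(
            label=self.label,
            sum_x=self.sum_x + other.sum_x,
            sum_x2=self.sum_x2 + other.sum_x2,
            n=self.n + other.n,
        )


def accumulate_group(
    per_sample: Iterable[tuple[np.ndarray, np.ndarray, int]],
    label: str = "",
) -> GroupContactAccumulator:
    """Combine per-sample (mean matrix, squared-mean matrix, n_cells) triples.

    Sx = sum_s n_s * M_s and Sx2 = sum_s n_s * Q_s, where M_s and Q_s are the
    per-cell mean and mean-of-squares matrices of sample s.
    """
    sum_x = sum_x2 = None
    n = 0
    for M, Q, n_cells in per_sample:
        M = np.asarray(M, dtype=float)
        Q = np.asarray(Q, dtype=float)
        if M.shape != Q.shape:
            raise ValueError("mean and squared-mean matrix shapes differ")
        if n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if sum_x is None:
            sum_x = n_cells * M
            sum_x2 = n_cells * Q
        else:
            if M.shape != sum_x.shape:
                raise ValueError("matrix shapes differ across samples")
            sum_x = sum_x + n_cells * M
            sum_x2 = sum_x2 + n_cells * Q
        n += int(n_cells)
    if sum_x is None:
        raise ValueError("no samples provided")
    return GroupContactAccumulator(label=label, sum_x=sum_x, sum_x2=sum_x2, n=n)


def pixel_f_statistic(
    groups: Sequence[GroupContactAccumulator],
) -> pd.DataFrame:
    """One-way ANOVA F per upper-triangle pixel from group accumulators.

    Returns a table with columns bin1, bin2 (bin1 < bin2), F,
    ``mean_<label>`` per group, and ``mask_reason`` (initialized "none").
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    shape = groups[0].sum_x.shape
    for g in groups:
        if g.sum_x.shape != shape:
            raise ValueError("group accumulator shapes differ")
    N = sum(g.n for g in groups)
    k = len(groups)
    if N <= k:
        raise ValueError("total cells must exceed number of groups")
    ssw = np.zeros(shape)
    sx_tot = np.zeros(shape)
    sx2_tot = np.zeros(shape)
    for g in groups:
        ssw += g.sum_x2 - (g.sum_x**2) / g.n
        sx_tot += g.sum_x
        sx2_tot += g.sum_x2
    sst = sx2_tot - (sx_tot**2) / N
    ssb = sst - ssw
    # numerical floor: tiny negative SS from cancellation
    ssw = np.maximum(ssw, 0.0)
    ssb = np.maximum(ssb, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        F = (ssb / (k - 1)) / (ssw / (N - k))
    F = np.where(np.abs(sst) <= 1e-12, 0.0, F)
    F = np.where((ssw <= 1e-12) & (ssb > 1e-12), np.inf, F)

    iu, ju = np.triu_indices(shape[0], k=1)
    out = pd.DataFrame({"bin1": iu, "bin2": ju, "F": F[iu, ju]})
    for g in groups:
        out[f"mean_{g.label}"] = (g.sum_x / g.n)[iu, ju]
    out["mask_reason"] = MASK_NONE
    return out


def mask_pixels(
    stats: pd.DataFrame,
    blacklist_bins: Iterable[int] = (),
    pad: int = 7,
    dmin: int = 5,
    dmax: int = 500,
) -> pd.DataFrame:
    """Annotate mask reasons; masked pixels carry no F.

    Excludes pixels with either anchor within ``pad`` bins of a blacklisted
    bin, pixels outside the [dmin, dmax] bin-distance range, and any pixel
    with bin1 >= bin2. Idempotent and order-independent.
    """
    out = stats.copy()
    b1 = out["bin1"].to_numpy()
    b2 = out["bin2"].to_numpy()
    reason = np.array([MASK_NONE] * len(out), dtype=object)
    bl = np.asarray(sorted(set(blacklist_bins)), dtype=int)
    if bl.size:
        near1 = np.min(np.abs(b1[:, None] - bl[None, :]), axis=1) <= pad
        near2 = np.min(np.abs(b2[:, None] - bl[None, :]), axis=1) <= pad
        reason[near1 | near2] = MASK_BLACKLIST
    d = b2 - b1
    reason[(d < dmin) | (d > dmax)] = MASK_DISTANCE
    reason[b1 >= b2] = MASK_LOWER
    out["mask_reason"] = reason
    out.loc[out["mask_reason"] != MASK_NONE, "F"] = np.nan
    return out


def loop_covariate_regression(
    candidates: pd.DataFrame,
    per_sample_values: pd.DataFrame,
    meta: pd.DataFrame,
    spec: DesignSpec | None = None,
    min_donors: int = 5,
) -> FeatureAssociation:
    """Regress candidate-pixel strengths on disease + covariates per pixel.

    ``candidates`` holds unmasked pixels (bin1, bin2); ``per_sample_values``
    is pixels x samples (index "bin1|bin2") aligned with ``meta`` (one row
    per sample: donor, disease, region, age, sex). Pixels with a
    non-finite F sentinel should be excluded by the caller. Delegates to
    :func:`epistate3c.linear_models.fit_feature_model`.
    """
    keys = candidates["bin1"].astype(str) + "|" + candidates["bin2"].astype(str)
    vals = per_sample_values.loc[per_sample_values.index.intersection(keys)]
    return fit_feature_model(vals, meta, spec=spec, min_donors=min_donors)
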