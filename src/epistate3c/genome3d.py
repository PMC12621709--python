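"""Pseudo-bulk 3D-genome machinery.

Covers merging single-cell contact lists into binned per-chromosome
matrices, iterative-correction (ICE) balancing, distance-decay expected
matrices from diagonal-band means, compartment PC1 with GC-content sign
correction, saddle construction and the Stressed/Homeostatic saddle ratio,
centromere-aligned arm-scaled average O/E maps, and detection of bins with
widespread contact loss (putative deletions) near telomeres.

Conventions:

* PC1 is the leading eigenvector of the Pearson correlation matrix of the
  observed/expected map over unmasked bins, sign-flipped so that
  corr(PC1, GC) >= 0 — A compartments (GC-rich) carry positive PC1.
* The expected matrix replaces every entry of diagonal band d by that
  band's mean, so O/E of a band-constant matrix is all ones.
* Putative deletions: per 100-kb bin, the row sum of each balanced
  pseudo-bulk matrix is computed, zeros recoded to missing, and bins
  missing in at least ``min_missing`` pseudo-bulks (but not in all of
  them) are flagged, annotated with distance to the nearest telomere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "BinnedContactMatrix",
    "pseudo_bulk",
    "balance_ice",
    "expected_by_band",
    "observed_over_expected",
    "CompartmentProfile",
    "compartment_pc1",
    "saddle",
    "saddle_state_ratio",
    "centromere_aligned_average",
    "detect_putative_deletions",
]


@dataclass
class BinnedContactMatrix:
    """Symmetric nonnegative per-chromosome contact matrix at one resolution."""

    chrom: str
    resolution: int
    matrix: np.ndarray
    weights: np.ndarray | None = None  # balancing weights; NaN where masked
    n_cells: int = 0

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError("matrix must be square")
        if not np.allclose(M, M.T, atol=1e-9):
            raise ValueError("matrix must be symmetric")
        self.matrix = M

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def balanced(self) -> np.ndarray:
        """Matrix scaled by the outer product of balancing weights."""
        if self.weights is None:
            raise ValueError("matrix not balanced yet")
        w = self.weights
        return self.matrix * np.outer(w, w)

    def to_tsv(self, path) -> None:
        header = f"# chrom={self.chrom} resolution={self.resolution} n_cells={self.n_cells}\n"
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.matrix, delimiter="\t", fmt="%.6g")


def pseudo_bulk(
    contacts: pd.DataFrame,
    cells: pd.Index,
    chrom: str,
    chrom_length: int,
    resolution: int = 100_000,
) -> BinnedContactMatrix:
    """Sum binned cis contacts of a cell group into one symmetric matrix."""
    if len(cells) == 0:
        raise ValueError("empty cell group")
    sub = contacts[
        contacts["cell_id"].isin(set(cells))
        & (contacts["chrom1"] == chrom)
        & (contacts["chrom2"] == chrom)
    ]
    n_bins = int(np.ceil(chrom_length / resolution))
    M = np.zeros((n_bins, n_bins))
    if len(sub):
        b1 = np.minimum(sub["pos1"].to_numpy() // resolution, n_bins - 1).astype(int)
        b2 = np.minimum(sub["pos2"].to_numpy() // resolution, n_bins - 1).astype(int)
        lo, hi = np.minimum(b1, b2), np.maximum(b1, b2)
        np.add.at(M, (lo, hi), 1.0)
        # standard symmetric storage: M[i, j] = M[j, i] = pair count, so the
        # upper triangle (including the diagonal) carries the contact mass
        M = M + np.triu(M, k=1).T
    return BinnedContactMatrix(
        chrom=chrom, resolution=resolution, matrix=M, n_cells=len(cells)
    )


def pseudo_bulk_by_group(
    contacts: pd.DataFrame,
    membership: pd.Series,
    chrom_lengths: dict[str, int],
    resolution: int = 100_000,
) -> dict[str, dict[str, BinnedContactMatrix]]:
    """Bin cis contacts for many cell groups in one pass over the table.

    ``membership`` maps cell_id -> group label (cells absent from it are
    ignored). Returns {group: {chrom: BinnedContactMatrix}} with the same
    per-matrix content as repeated :func:`pseudo_bulk` calls.
    """
    groups = pd.unique(membership.dropna())
    gcodes = pd.Categorical(
        contacts["cell_id"].map(membership), categories=list(groups)
    ).codes
    n_cells = membership.dropna().groupby(membership.dropna()).size()
    out: dict[str, dict[str, BinnedContactMatrix]] = {str(g): {} for g in groups}
    chrom1 = contacts["chrom1"]
    chrom2 = contacts["chrom2"]
    if isinstance(chrom1.dtype, pd.CategoricalDtype) and list(
        chrom1.cat.categories
    ) == list(chrom2.cat.categories):
        codes1 = chrom1.cat.codes.to_numpy()
        cis = codes1 == chrom2.cat.codes.to_numpy()
        chrom_code = {c: i for i, c in enumerate(chrom1.cat.categories)}
    else:
        codes1 = pd.Categorical(chrom1.astype(str)).codes
        cis = chrom1.astype(str).to_numpy() == chrom2.astype(str).to_numpy()
        chrom_code = {
            c: i for i, c in enumerate(pd.Categorical(chrom1.astype(str)).categories)
        }
    pos1 = contacts["pos1"].to_numpy()
    pos2 = contacts["pos2"].to_numpy()
    for chrom, length in chrom_lengths.items():
        nb = int(np.ceil(length / resolution))
        sel = cis & (codes1 == chrom_code.get(chrom, -99)) & (gcodes >= 0)
        g = gcodes[sel].astype(np.int64)
        b1 = np.minimum(pos1[sel] // resolution, nb - 1).astype(np.int64)
        b2 = np.minimum(pos2[sel] // resolution, nb - 1).astype(np.int64)
        lo, hi = np.minimum(b1, b2), np.maximum(b1, b2)
        flat = g * (nb * nb) + lo * nb + hi
        counts = np.bincount(flat, minlength=len(groups) * nb * nb)
        for gi, group in enumerate(groups):
            upper = counts[gi * nb * nb : (gi + 1) * nb * nb].reshape(nb, nb).astype(float)
            M = upper + np.triu(upper, k=1).T
            out[str(group)][chrom] = BinnedContactMatrix(
                chrom=chrom, resolution=resolution, matrix=M,
                n_cells=int(n_cells.get(group, 0)),
            )
    return out


def balance_ice(
    matrix: BinnedContactMatrix | np.ndarray,
    tol: float = 1e-5,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative correction: returns (balanced matrix, weights).

    Multiplicative bias vector updated until its relative change drops below
    ``tol`` or ``max_iter`` iterations (warning on non-convergence). All-zero
    rows are masked (weight NaN) and excluded from the convergence test;
    unmasked row sums of the balanced matrix are equal to within 1e-3
    relative after convergence.
    """
    M = matrix.matrix if isinstance(matrix, BinnedContactMatrix) else np.asarray(matrix, float)
    if np.any(M < 0):
        raise ValueError("matrix must be nonnegative")
    n = M.shape[0]
    mask = M.sum(axis=1) > 0
    w = np.ones(n)
    converged = False
    for _ in range(max_iter):
        B = M * np.outer(w, w)
        s = B.sum(axis=1)
        target = s[mask].mean()
        if target == 0:
            break
        update = np.ones(n)
        update[mask] = np.sqrt(s[mask] / target)
        w_new = np.where(mask, w / update, w)
        rel = np.max(np.abs(update[mask] - 1.0))
        w = w_new
        if rel < tol:
            converged = True
            break
    if not converged:
        warnings.warn("ICE did not converge; returning last iterate")
    # normalize so unmasked balanced row sums are ~1
    B = M * np.outer(w, w)
    s = B.sum(axis=1)
    scale = s[mask].mean() if mask.any() else 1.0
    if scale > 0:
        w = w / np.sqrt(scale)
    weights = np.where(mask, w, np.nan)
    balanced = M * np.outer(np.nan_to_num(w, nan=0.0), np.nan_to_num(w, nan=0.0))
    balanced[~mask, :] = 0.0
    balanced[:, ~mask] = 0.0
    if isinstance(matrix, BinnedContactMatrix):
        matrix.weights = weights
    return balanced, weights


def expected_by_band(matrix: np.ndarray) -> np.ndarray:
    """Expected matrix: every entry of diagonal band d replaced by the band mean."""
    M = np.asarray(matrix, dtype=float)
    n = M.shape[0]
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("matrix must be square")
    E = np.zeros_like(M)
    for d in range(n):
        band = np.diagonal(M, offset=d)
        m = band.mean()
        idx = np.arange(n - d)
        E[idx, idx + d] = m
        E[idx + d, idx] = m
    return E


def observed_over_expected(matrix: np.ndarray) -> np.ndarray:
    """O/E map; entries with zero expected are 0."""
    E = expected_by_band(matrix)
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = np.where(E > 0, matrix / np.where(E > 0, E, 1.0), 0.0)
    return oe


@dataclass
class CompartmentProfile:
    """Per-bin compartment eigenvector with GC sign convention."""

    pc1: np.ndarray  # NaN at masked bins
    gc: np.ndarray
    sign_corrected: bool = True


def compartment_pc1(
    matrix: np.ndarray, gc: np.ndarray, min_bins: int = 4
) -> CompartmentProfile:
    """Compartment PC1 of a balanced matrix with GC sign correction.

    O/E via band means, Pearson correlation matrix of O/E columns over
    unmasked (nonzero-coverage) bins, leading eigenvector, sign flipped if
    corr(PC1, GC) < 0 so A compartments carry positive values.
    """
    M = np.asarray(matrix, dtype=float)
    gc = np.asarray(gc, dtype=float)
    mask = M.sum(axis=1) > 0
    if mask.sum() < min_bins:
        raise ValueError(f"need >= {min_bins} unmasked bins")
    sub = M[np.ix_(mask, mask)]
    oe = observed_over_expected(sub)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        C = np.corrcoef(oe, rowvar=False)
    C = np.nan_to_num(C, nan=0.0)
    vals, vecs = np.linalg.eigh(C)
    v = vecs[:, -1]
    pc1 = np.full(M.shape[0], np.nan)
    pc1[mask] = v
    gsub = gc[mask]
    if np.ptp(gsub) > 0 and np.ptp(v) > 0:
        if np.corrcoef(v, gsub)[0, 1] < 0:
            pc1 = -pc1
    return CompartmentProfile(pc1=pc1, gc=gc)


def saddle(
    matrices,
    profiles,
    n_quantiles: int = 10,
) -> np.ndarray:
    """Quantile x quantile mean-O/E saddle, pooled across chromosomes.

    ``matrices`` and ``profiles`` may be single objects or lists (one per
    chromosome). Bins are ranked by PC1 into ``n_quantiles`` equal-size
    groups (ties broken by bin order); saddle[q1, q2] is the mean cis O/E
    over all bin pairs in those groups.
    """
    if not isinstance(matrices, (list, tuple)):
        matrices = [matrices]
        profiles = [profiles]
    sums = np.zeros((n_quantiles, n_quantiles))
    counts = np.zeros((n_quantiles, n_quantiles))
    n_defined = 0
    for M, prof in zip(matrices, profiles):
        M = np.asarray(M, dtype=float)
        pc1 = prof.pc1 if isinstance(prof, CompartmentProfile) else np.asarray(prof, float)
        ok = ~np.isnan(pc1) & (M.sum(axis=1) > 0)
        n_defined += int(ok.sum())
        if ok.sum() < n_quantiles:
            continue
        sub = M[np.ix_(ok, ok)]
        oe = observed_over_expected(sub)
        order = np.argsort(pc1[ok], kind="stable")
        q = np.empty(len(order), dtype=int)
        q[order] = np.minimum(
            (np.arange(len(order)) * n_quantiles) // len(order), n_quantiles - 1
        )
        for q1 in range(n_quantiles):
            i = np.flatnonzero(q == q1)
            for q2 in range(n_quantiles):
                j = np.flatnonzero(q == q2)
                block = oe[np.ix_(i, j)]
                sums[q1, q2] += block.sum()
                counts[q1, q2] += block.size
    if n_defined < n_quantiles:
        raise ValueError("PC1 defined on fewer bins than quantiles")
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def saddle_state_ratio(stressed: np.ndarray, homeostatic: np.ndarray) -> np.ndarray:
    """Elementwise Stressed / Homeostatic saddle ratio; 0-denominators -> NaN."""
    s = np.asarray(stressed, dtype=float)
    h = np.asarray(homeostatic, dtype=float)
    if s.shape != h.shape:
        raise ValueError("saddle shapes differ")
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(h != 0, s / np.where(h != 0, h, 1.0), np.nan)


def _bilinear_resize(block: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Continuous-coordinate bilinear resize mapping corners to corners,
    edge handling = clamp."""
    block = np.asarray(block, dtype=float)
    out_r, out_c = shape
    if block.size == 0:
        return np.zeros(shape)
    r = np.linspace(0, block.shape[0] - 1, out_r) if block.shape[0] > 1 else np.zeros(out_r)
    c = np.linspace(0, block.shape[1] - 1, out_c) if block.shape[1] > 1 else np.zeros(out_c)
    rr, cc = np.meshgrid(r, c, indexing="ij")
    return ndimage.map_coordinates(
        block, [rr.ravel(), cc.ravel()], order=1, mode="nearest"
    ).reshape(shape)


def centromere_aligned_average(
    matrices: dict[str, np.ndarray],
    centromeres: dict[str, int],
    resolution: int,
    p_bins: int = 50,
    q_bins: int = 50,
    min_chrom_bins: int = 50,
) -> np.ndarray:
    """Arm-scaled, centromere-aligned average O/E map over eligible autosomes.

    Per chromosome: NaNs in the observed matrix are zeroed, the band-mean
    expected matrix is built, both are split at the centromere bin into
    p-p / p-q / q-p / q-q blocks, each block is bilinearly resized to the
    fixed arm shape, per-chromosome O/E is the resized observed over the
    resized expected (0 where expected is 0), and the O/E maps are averaged.
    Chromosomes with fewer than ``min_chrom_bins`` bins or without a
    centromere position are excluded; any NaN/Inf in the result is set to 0.
    """
    shape = (p_bins + q_bins, p_bins + q_bins)
    acc = np.zeros(shape)
    n_used = 0
    for chrom, M in matrices.items():
        if chrom not in centromeres:
            continue
        M = np.nan_to_num(np.asarray(M, dtype=float), nan=0.0)
        n = M.shape[0]
        if n < min_chrom_bins:
            continue
        cen_bin = int(np.searchsorted(np.arange(n) * resolution, centromeres[chrom], side="right")) - 1
        cen_bin = max(1, min(cen_bin, n - 1))
        E = expected_by_band(M)
        oe = np.zeros(shape)
        obs_r = np.zeros(shape)
        exp_r = np.zeros(shape)
        slices = {
            "pp": (slice(0, cen_bin), slice(0, cen_bin), slice(0, p_bins), slice(0, p_bins)),
            "pq": (slice(0, cen_bin), slice(cen_bin, n), slice(0, p_bins), slice(p_bins, None)),
            "qp": (slice(cen_bin, n), slice(0, cen_bin), slice(p_bins, None), slice(0, p_bins)),
            "qq": (slice(cen_bin, n), slice(cen_bin, n), slice(p_bins, None), slice(p_bins, None)),
        }
        for sr, sc, tr, tc in slices.values():
            tshape = (
                len(range(*tr.indices(shape[0]))),
                len(range(*tc.indices(shape[1]))),
            )
            obs_r[tr, tc] = _bilinear_resize(M[sr, sc], tshape)
            exp_r[tr, tc] = _bilinear_resize(E[sr, sc], tshape)
        with np.errstate(invalid="ignore", divide="ignore"):
            oe = np.where(exp_r > 0, obs_r / np.where(exp_r > 0, exp_r, 1.0), 0.0)
        acc += oe
        n_used += 1
    if n_used == 0:
        raise ValueError("no eligible chromosomes")
    out = acc / n_used
    return np.nan_to_num(out, nan=0.0, posinf=0.0, neginf=0.0)


@dataclass
class DeletionCall:
    chrom: str
    bin_start: int
    bin_end: int
    n_missing: int
    telomere_distance: int


def detect_putative_deletions(
    pseudo_bulks: dict[str, dict[str, np.ndarray]],
    chrom_lengths: dict[str, int],
    resolution: int = 100_000,
    min_missing: int = 10,
) -> pd.DataFrame:
    """Flag bins with widespread contact loss across pseudo-bulks.

    ``pseudo_bulks`` maps a pseudo-bulk name (State_CellType_Region) to a
    per-chromosome balanced matrix. Per bin the balanced row sum is
    computed; zeros are recoded to missing; bins missing in at least
    ``min_missing`` pseudo-bulks are selected, and rows missing in *all*
    pseudo-bulks (no data anywhere) are then dropped. Returns a table with
    per-pseudo-bulk row sums and the distance to the nearest telomere,
    min(bin_start, chrom_length - bin_end).
    """
    names = sorted(pseudo_bulks)
    if len(names) < min_missing:
        warnings.warn(
            f"only {len(names)} pseudo-bulks < min_missing={min_missing}; empty result"
        )
        return pd.DataFrame(
            columns=["chrom", "bin_start", "bin_end", "n_missing", "telomere_distance"]
        )
    frames = []
    chroms = sorted({c for pb in pseudo_bulks.values() for c in pb})
    for chrom in chroms:
        length = chrom_lengths[chrom]
        n_bins = int(np.ceil(length / resolution))
        rows = np.full((n_bins, len(names)), np.nan)
        for j, name in enumerate(names):
            M = pseudo_bulks[name].get(chrom)
            if M is None:
                continue
            rs = np.asarray(M, dtype=float).sum(axis=1)
            rs = np.where(rs == 0, np.nan, rs)
            rows[: len(rs), j] = rs
        n_missing = np.isnan(rows).sum(axis=1)
        sel = (n_missing >= min_missing) & (n_missing < len(names))
        for b in np.flatnonzero(sel):
            start = b * resolution
            end = min(start + resolution, length)
            rec = {
                "chrom": chrom,
                "bin_start": int(start),
                "bin_end": int(end),
                "n_missing": int(n_missing[b]),
                "telomere_distance": int(min(start, length - end)),
            }
            for j, name in enumerate(names):
                rec[f"rowsum_{name}"] = rows[b, j]
            frames.append(rec)
    return pd.DataFrame(
        frames,
        columns=["chrom", "bin_start", "bin_end", "n_missing", "telomere_distance"]
        + [f"rowsum_{n}" for n in names]
        if frames
        else ["chrom", "bin_start", "bin_end", "n_missing", "telomere_distance"],
    )
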