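"""Shared per-feature OLS machinery.

Every association and correction step in the package runs through the same
three primitives:

* :func:`fit_feature_model` — one ordinary-least-squares fit per feature
  (gene, genomic bin, loop pixel, subgroup ratio ...) against a design built
  from cell/sample metadata with explicit reference levels, e.g.
  ``value ~ Disease x Region + Age + Sex`` with Control/VC/Female references.
* :func:`bh_fdr` — Benjamini–Hochberg step-up q-values, applied per model
  term across features.
* :func:`batch_correct` — fit a full covariate model per feature and subtract
  only the fitted batch component, preserving all biological variation and
  the intercept.

Inference is classical OLS: coefficient standard errors from
``sigma^2 (X'X)^-1`` and two-sided t-tests on residual degrees of freedom.
Features observed in fewer than ``min_donors`` unique donors, with all values
missing, or with a rank-deficient design are flagged and excluded from FDR.
A zero-variance response is reported as all-zero coefficients with P = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DesignSpec",
    "FeatureAssociation",
    "build_design",
    "disease_region_design",
    "fit_feature_model",
    "bh_fdr",
    "batch_correct",
    "select_by_cutoffs",
]

STATUS_OK = "ok"
STATUS_MIN_DONORS = "skipped_min_donors"
STATUS_ALL_MISSING = "skipped_all_missing"
STATUS_RANK_DEFICIENT = "rank_deficient"


class DesignError(ValueError):
    """Raised for invalid design specifications (unknown reference level...)."""


@dataclass
class DesignSpec:
    """Declarative model specification with explicit reference levels.

    ``terms`` is an ordered list of ``(covariate, kind)`` pairs where kind is
    ``"categorical"``, ``"continuous"`` or ``"interaction"``. Interactions are
    written ``"A:B"`` and must reference previously declared covariates.
    Categorical covariates are one-hot encoded dropping the reference level.
    """

    response: str = "value"
    terms: Sequence[tuple[str, str]] = ()
    references: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cov, kind in self.terms:
            if kind not in ("categorical", "continuous", "interaction"):
                raise DesignError(f"unknown term kind {kind!r} for {cov!r}")
            if kind == "interaction":
                parts = cov.split(":")
                if len(parts) != 2 or not all(p in seen for p in parts):
                    raise DesignError(
                        f"interaction {cov!r} must reference previously "
                        "declared covariates"
                    )
            else:
                if kind == "categorical" and cov not in self.references:
                    raise DesignError(f"categorical term {cov!r} has no reference level")
                seen.add(cov)


def disease_region_design(
    disease: str = "disease",
    region: str = "region",
    age: str = "age",
    sex: str = "sex",
) -> DesignSpec:
    """The cohort association design: Disease x Region + Age + Sex.

    References: Control disease, VC region, Female sex — so the disease main
    effect is the AD-minus-Control contrast in VC, and the interaction terms
    test whether that contrast differs in PFC / TC.
    """
    return DesignSpec(
        response="value",
        terms=[
            (disease, "categorical"),
            (region, "categorical"),
            (f"{disease}:{region}", "interaction"),
            (age, "continuous"),
            (sex, "categorical"),
        ],
        references={disease: "Control", region: "VC", sex: "Female"},
    )


def _encode_categorical(
    series: pd.Series, covariate: str, reference: str
) -> pd.DataFrame:
    levels = pd.unique(series.dropna())
    if reference not in levels and len(levels) > 0:
        raise DesignError(
            f"reference level {reference!r} for {covariate!r} not present "
            f"in data (levels: {sorted(map(str, levels))})"
        )
    others = sorted(str(x) for x in levels if x != reference)
    out = pd.DataFrame(index=series.index)
    for lev in others:
        out[f"{covariate}[{lev}]"] = (series.astype(str) == lev).astype(float)
    return out


def build_design(meta: pd.DataFrame, spec: DesignSpec) -> pd.DataFrame:
    """Build the design matrix (with intercept) from metadata.

    Columns are named ``cov[level]`` for categorical contrasts, ``cov`` for
    continuous terms, and ``covA[a]:covB[b]`` for interaction products.
    Rows with a missing value in any covariate get all-NaN design rows so the
    caller can drop them listwise per feature.
    """
    blocks: dict[str, pd.DataFrame] = {}
    X = pd.DataFrame(index=meta.index)
    X["Intercept"] = 1.0
    needed = [c for c, k in spec.terms if k != "interaction"]
    for cov in needed:
        if cov not in meta.columns:
            raise DesignError(f"covariate {cov!r} missing from metadata")
    missing_row = meta[needed].isna().any(axis=1) if needed else pd.Series(
        False, index=meta.index
    )
    for cov, kind in spec.terms:
        if kind == "categorical":
            block = _encode_categorical(meta[cov], cov, spec.references[cov])
            blocks[cov] = block
            X = pd.concat([X, block], axis=1)
        elif kind == "continuous":
            col = pd.to_numeric(meta[cov], errors="coerce").astype(float)
            blocks[cov] = pd.DataFrame({cov: col})
            X[cov] = col
        else:  # interaction
            a, b = cov.split(":")
            for ca in blocks[a].columns:
                for cb in blocks[b].columns:
                    X[f"{ca}:{cb}"] = blocks[a][ca] * blocks[b][cb]
    if missing_row.any():
        X.loc[missing_row.values, X.columns != "Intercept"] = np.nan
        X.loc[missing_row.values, "Intercept"] = np.nan
    return X


def _ols_inference(
    X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, bool]:
    """OLS via normal equations; returns (coef, p, ok).

    ``ok`` is False when the design is rank deficient. A zero-variance
    response returns zero coefficients (except intercept) and P = 1.
    """
    n, k = X.shape
    if np.ptp(y) == 0.0:
        coef = np.zeros(k)
        coef[0] = y[0] if k else 0.0
        return coef, np.ones(k), True
    rank = np.linalg.matrix_rank(X)
    if rank < k or n <= k:
        return np.full(k, np.nan), np.full(k, np.nan), False
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    coef = xtx_inv @ (X.T @ y)
    resid = y - X @ coef
    dof = n - k
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, coef / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(tval), dof)
    p = np.where(se > 0, p, 1.0)
    return coef, p, True


@dataclass
class FeatureAssociation:
    """Per-feature model output table plus the term names fitted."""

    table: pd.DataFrame
    terms: list[str]

    def coefficients(self, term: str) -> pd.Series:
        return self.table[f"{term}_coef"]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=True, index_label="feature")


def fit_feature_model(
    values: pd.DataFrame,
    meta: pd.DataFrame,
    spec: DesignSpec | None = None,
    min_donors: int = 5,
    donor_col: str = "donor",
) -> FeatureAssociation:
    """Fit one OLS model per feature (row of ``values``) against metadata.

    ``values`` is features x observations; its columns must align with
    ``meta``'s index. Observations with missing response or covariates are
    dropped listwise per feature. Features represented by fewer than
    ``min_donors`` unique donors are flagged ``skipped_min_donors`` and carry
    no coefficients; per-term BH q-values are computed across the remaining
    features only.
    """
    if spec is None:
        spec = disease_region_design()
    if min_donors < 1:
        raise ValueError("min_donors must be >= 1")
    meta = meta.loc[values.columns]
    X_full = build_design(meta, spec)
    term_cols = [c for c in X_full.columns if c != "Intercept"]
    donors = meta[donor_col] if donor_col in meta.columns else None

    Xv = X_full.to_numpy(dtype=float)
    design_ok_row = ~np.isnan(Xv).any(axis=1)
    records: list[dict] = []
    for feat, row in values.iterrows():
        y = row.to_numpy(dtype=float)
        obs = design_ok_row & ~np.isnan(y)
        rec: dict = {"feature": feat, "n_obs": int(obs.sum())}
        if obs.sum() == 0:
            rec.update(status=STATUS_ALL_MISSING, n_donors=0)
            records.append(rec)
            continue
        n_don = int(donors[obs].nunique()) if donors is not None else int(obs.sum())
        rec["n_donors"] = n_don
        if n_don < min_donors:
            rec["status"] = STATUS_MIN_DONORS
            records.append(rec)
            continue
        coef, p, ok = _ols_inference(Xv[obs], y[obs])
        if not ok:
            rec["status"] = STATUS_RANK_DEFICIENT
            records.append(rec)
            continue
        rec["status"] = STATUS_OK
        for j, col in enumerate(X_full.columns):
            if col == "Intercept":
                rec["intercept"] = coef[j]
                continue
            rec[f"{col}_coef"] = coef[j]
            rec[f"{col}_p"] = p[j]
        records.append(rec)

    table = pd.DataFrame.from_records(records).set_index("feature")
    for col in term_cols:
        pcol, qcol = f"{col}_p", f"{col}_q"
        if pcol not in table.columns:
            table[f"{col}_coef"] = np.nan
            table[pcol] = np.nan
        table[qcol] = bh_fdr(table[pcol].to_numpy(dtype=float))
    return FeatureAssociation(table=table, terms=term_cols)


def bh_fdr(p: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values; NaN entries are propagated."""
    p = np.asarray(list(p) if not isinstance(p, np.ndarray) else p, dtype=float)
    q = np.full(p.shape, np.nan)
    valid = ~np.isnan(p)
    if valid.any():
        pv = p[valid]
        if np.any((pv < 0) | (pv > 1)):
            raise ValueError("p-values must lie in [0, 1]")
        q[valid] = multipletests(pv, method="fdr_bh")[1]
    return q


def batch_correct(
    values: pd.DataFrame,
    meta: pd.DataFrame,
    batch_covariate: str = "instrument",
    keep_covariates: Sequence[tuple[str, str]] = (
        ("age", "continuous"),
        ("sex", "categorical"),
        ("region", "categorical"),
        ("disease", "categorical"),
        ("donor", "categorical"),
    ),
    references: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Remove the fitted batch component from each feature.

    Per feature, fits ``value ~ batch + keep covariates`` (one-hot,
    drop-first) and subtracts only ``B @ beta_batch``, aligning all
    observations to the reference batch baseline while preserving the
    intercept and every biological covariate effect.
    """
    meta = meta.loc[values.columns]
    refs: dict[str, str] = {}
    terms: list[tuple[str, str]] = [(batch_covariate, "categorical")]
    refs[batch_covariate] = str(sorted(meta[batch_covariate].astype(str).unique())[0])
    for cov, kind in keep_covariates:
        if cov not in meta.columns:
            raise DesignError(f"keep covariate {cov!r} missing from metadata")
        terms.append((cov, kind))
        if kind == "categorical":
            if references and cov in references:
                refs[cov] = references[cov]
            else:
                refs[cov] = str(sorted(meta[cov].astype(str).unique())[0])
    spec = DesignSpec(terms=terms, references=refs)
    X = build_design(meta, spec)
    batch_cols = [c for c in X.columns if c.startswith(f"{batch_covariate}[")]
    if not batch_cols:  # single batch: nothing to remove
        return values.copy()
    Xv = X.to_numpy(dtype=float)
    bidx = [X.columns.get_loc(c) for c in batch_cols]
    other = [j for j in range(Xv.shape[1]) if j not in bidx]
    # the full design is usually rank deficient (donor determines disease,
    # age, sex); a minimum-norm fit still isolates the batch component as
    # long as batch varies within the other covariates' strata
    finite = ~np.isnan(Xv).any(axis=1)
    if np.linalg.matrix_rank(Xv[finite]) == np.linalg.matrix_rank(
        Xv[finite][:, other]
    ):
        warnings.warn(
            f"batch covariate {batch_covariate!r} is confounded with the kept "
            "covariates; values left unchanged"
        )
        return values.copy()
    out = values.copy().astype(float)
    row_ok = finite
    for feat, row in values.iterrows():
        y = row.to_numpy(dtype=float)
        obs = row_ok & ~np.isnan(y)
        if obs.sum() <= 1:
            warnings.warn(f"feature {feat!r}: <=1 observation, left unchanged")
            continue
        coef, *_ = np.linalg.lstsq(Xv[obs], y[obs], rcond=None)
        bhat = Xv[obs][:, bidx] @ coef[bidx]
        vals = y.copy()
        vals[obs] = y[obs] - bhat
        out.loc[feat] = vals
    return out


def select_by_cutoffs(
    assoc: FeatureAssociation,
    p_max: float,
    coef_min_abs: float,
    term: str,
) -> set:
    """Features with ``P < p_max`` and ``|coef| > coef_min_abs`` on a term.

    Both inequalities are strict, matching the differential-gene cutoffs
    (P < 0.05, |coef| > 0.01) and the differential-PC1 cutoffs
    (P < 0.05, |beta| > 0.25).
    """
    pcol, ccol = f"{term}_p", f"{term}_coef"
    if pcol not in assoc.table.columns:
        raise KeyError(f"term {term!r} not present in association table")
    t = assoc.table
    sel = (t[pcol] < p_max) & (t[ccol].abs() > coef_min_abs)
    return set(t.index[sel.fillna(False)])
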