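"""Global-methylation cell states: instrument normalization, CG/CH subgroups,
score-threshold state labels, and the subtype-similarity clustering that
separates Homeostatic from Stressed subtypes.

The partition into three subgroups operates on per-cell global CG and CH
levels, separately for neurons and non-neurons, after mapping the second
sequencing instrument onto the first through the linear relationship
measured on shared libraries. Cluster indices are relabeled to fixed
semantics by centroid rank: the lowest-CG centroid is subgroup 0
(low CG / low CH); of the remaining two, the lower-CH centroid is subgroup 1
(high CG / low CH) and the higher-CH one subgroup 2 (high CG / high CH).

Subtype similarity clustering consumes a genes x pairwise-comparison
log2-fold-change table. Per gene a directed (antisymmetric) adjacency matrix
over subtypes is assembled, the stack is flattened and reduced by PCA
(50 components, capped at rank), each subtype is embedded as the mean of its
row of PCA-transformed contrasts, and average-linkage hierarchical
clustering of the cosine distance 1 - K cuts the subtypes into two clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .linear_models import DesignSpec, FeatureAssociation, fit_feature_model
from .synthetic_data import parse_comparison

__all__ = [
    "normalize_instruments",
    "kmeans_subgroups",
    "subgroup_ratio_association",
    "score_state_labels",
    "SubtypeEmbedding",
    "subtype_similarity_cluster",
]


def normalize_instruments(
    global_mc: pd.DataFrame,
    meta: pd.DataFrame,
    shared_libraries: pd.DataFrame | None = None,
    reference_instrument: str = "NovaSeq6000",
    instrument_col: str = "instrument",
    contexts: Sequence[str] = ("CG", "CH"),
) -> pd.DataFrame:
    """Map instrument-B global methylation levels onto the instrument-A scale.

    ``shared_libraries`` holds paired measurements of the same libraries on
    both instruments, with columns ``<ctx>_a`` and ``<ctx>_b`` per context;
    an OLS line ``a ~ b`` is fit per context and applied to every cell
    sequenced on the non-reference instrument. With fewer than two shared
    measurements, or a degenerate (zero-variance) fit, the identity map is
    used with a warning.
    """
    out = global_mc.copy().astype(float)
    instruments = meta.loc[global_mc.index, instrument_col]
    other = instruments[instruments != reference_instrument].unique()
    if len(other) == 0:
        return out
    for ctx in contexts:
        slope, intercept = 1.0, 0.0
        ok = False
        if shared_libraries is not None and len(shared_libraries) >= 2:
            x = shared_libraries[f"{ctx}_b"].to_numpy(dtype=float)
            y = shared_libraries[f"{ctx}_a"].to_numpy(dtype=float)
            if np.ptp(x) > 0:
                slope, intercept = np.polyfit(x, y, 1)
                ok = True
        if not ok:
            warnings.warn(
                f"{ctx}: no usable shared-library pairing; identity instrument map"
            )
        mask = (instruments != reference_instrument).to_numpy()
        out.loc[mask, ctx] = intercept + slope * out.loc[mask, ctx]
    return out


def kmeans_subgroups(
    levels: pd.DataFrame,
    meta: pd.DataFrame,
    neuron_cell_types: Sequence[str] = ("Exc", "Inh"),
    k: int = 3,
    seed: int = 0,
    n_init: int = 10,
) -> pd.DataFrame:
    """Partition cells into the three global CG/CH subgroups per stratum.

    Runs k-means (k = 3, ``n_init`` restarts) on normalized (CG, CH) levels
    separately for neurons and non-neurons, then relabels clusters to the
    semantic subgroups by centroid rank (see module docstring). Returns a
    table with columns CG, CH, stratum, subgroup.
    """
    meta = meta.loc[levels.index]
    is_neuron = meta["cell_type"].isin(neuron_cell_types)
    rows = []
    for stratum, mask in (("neuron", is_neuron), ("non-neuron", ~is_neuron)):
        sub = levels.loc[mask.to_numpy()]
        if len(sub) == 0:
            continue
        if len(sub) < k:
            warnings.warn(f"stratum {stratum!r} has <{k} cells; skipped")
            continue
        X = sub[["CG", "CH"]].to_numpy(dtype=float)
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
        remap = _semantic_relabel(km.cluster_centers_)
        lab = np.array([remap[c] for c in km.labels_])
        rows.append(
            pd.DataFrame(
                {
                    "CG": sub["CG"],
                    "CH": sub["CH"],
                    "stratum": stratum,
                    "subgroup": lab,
                },
                index=sub.index,
            )
        )
    if not rows:
        return pd.DataFrame(columns=["CG", "CH", "stratum", "subgroup"])
    out = pd.concat(rows)
    return out.loc[levels.index.intersection(out.index)]


def _semantic_relabel(centers: np.ndarray) -> dict[int, int]:
    """Map raw k-means cluster ids to semantic subgroups 0/1/2.

    Lowest-CG centroid -> 0; of the remaining two, lower CH -> 1, higher
    CH -> 2. Ties (impossible for distinct centroids) break by CH then CG.
    """
    order = np.lexsort((centers[:, 1], centers[:, 0]))  # by CG, then CH
    low_cg = order[0]
    rest = [i for i in range(len(centers)) if i != low_cg]
    rest.sort(key=lambda i: (centers[i, 1], centers[i, 0]))
    remap = {int(low_cg): 0}
    remap[int(rest[0])] = 1
    remap[int(rest[1])] = 2
    return remap


def subgroup_ratio_association(
    assignments: pd.DataFrame,
    meta: pd.DataFrame,
    spec: DesignSpec | None = None,
    min_donors: int = 5,
) -> FeatureAssociation:
    """Associate subgroup proportions with disease status per cell type.

    Ratios are computed per (donor, region, cell type, subgroup) as
    count / total cells in that (donor, region, cell type), then each
    (cell type, subgroup) feature is fit with
    ``ratio ~ disease x region + age + sex`` (min 5 unique donors).
    """
    df = assignments.join(meta[["donor", "region", "disease", "sex", "age", "cell_type"]])
    totals = df.groupby(["donor", "region", "cell_type"], observed=True).size()
    counts = df.groupby(
        ["donor", "region", "cell_type", "subgroup"], observed=True
    ).size()
    subgroups = sorted(df["subgroup"].unique())
    sample_meta_rows = {}
    values: dict[str, dict[tuple, float]] = {}
    for (donor, region, ct), total in totals.items():
        key = (donor, region, ct)
        sample_meta_rows[key] = {
            "donor": donor,
            "region": region,
            "cell_type": ct,
            "disease": df.loc[
                (df["donor"] == donor) & (df["region"] == region), "disease"
            ].iloc[0],
            "sex": df.loc[df["donor"] == donor, "sex"].iloc[0],
            "age": df.loc[df["donor"] == donor, "age"].iloc[0],
        }
        for g in subgroups:
            feat = f"{ct}:subgroup{g}"
            values.setdefault(feat, {})[key] = (
                counts.get((donor, region, ct, g), 0) / total
            )
    sample_meta = pd.DataFrame.from_dict(sample_meta_rows, orient="index")
    sample_meta.index = pd.Index(
        ["|".join(map(str, k)) for k in sample_meta_rows], name="sample"
    )
    vals = pd.DataFrame(
        {
            "|".join(map(str, k)): {f: values[f].get(k, np.nan) for f in values}
            for k in sample_meta_rows
        }
    )
    return fit_feature_model(vals, sample_meta, spec=spec, min_donors=min_donors)


def score_state_labels(
    stressed_score: float,
    homeostatic_score: float,
    pos: float = 2.5,
    neg: float = -2.5,
) -> str:
    """Map (stressed, homeostatic) module scores to a 3x3 state label grid.

    Each score is categorized positive (>= 2.5), negative (<= -2.5) or
    neutral; both positive -> ``DP``, both negative -> ``DN``, other
    combinations -> ``S<cat>_H<cat>``.
    """
    def cat(x: float) -> str:
        if x >= pos:
            return "pos"
        if x <= neg:
            return "neg"
        return "neu"

    s, h = cat(stressed_score), cat(homeostatic_score)
    if s == "pos" and h == "pos":
        return "DP"
    if s == "neg" and h == "neg":
        return "DN"
    return f"S{s}_H{h}"


@dataclass
class SubtypeEmbedding:
    """Subtype embeddings plus similarity/distance matrices and cluster cut."""

    subtypes: list[str]
    embedding: np.ndarray  # n_subtypes x n_components
    similarity: pd.DataFrame  # cosine K
    distance: pd.DataFrame  # 1 - K
    clusters: pd.Series  # subtype -> cluster id (1..n_clusters)

    def relabel(self, labels: Mapping[int, str]) -> pd.Series:
        """Optional hook mapping neutral cluster ids to caller-chosen names
        (e.g. Homeostatic / Stressed from per-cluster marker scores)."""
        return self.clusters.map(labels)


def subtype_similarity_cluster(
    log2fc: pd.DataFrame,
    n_components: int = 50,
    n_clusters: int = 2,
) -> SubtypeEmbedding:
    """Cluster subtypes from their pairwise differential-expression profiles.

    Steps: (1) per gene g assemble a square antisymmetric matrix A(g) over
    subtypes, filling A[i, j] with the signed log2FC of i vs j (the reverse
    direction gets the negated value; diagonal and missing entries 0);
    (2) stack over genes, flatten to (S*S) x G, mean-center genes, PCA to
    min(n_components, rank); (3) embed each subtype as the mean of its row
    of transformed contrasts; (4) cosine similarity K, distance D = 1 - K;
    (5) average-linkage hierarchical clustering of D, cut at ``n_clusters``.
    """
    parsed = []
    for col in log2fc.columns:
        ct, a, b = parse_comparison(col)
        parsed.append((col, f"{ct}:{a}", f"{ct}:{b}"))
    subtypes = sorted({s for _, a, b in parsed for s in (a, b)})
    if len(subtypes) < 2:
        raise ValueError("need at least 2 subtypes")
    by_ct: dict[str, int] = {}
    for s in subtypes:
        by_ct[s.split(":", 1)[0]] = by_ct.get(s.split(":", 1)[0], 0) + 1
    n_comparisons: dict[str, int] = {}
    for _, a, _ in parsed:
        ct = a.split(":", 1)[0]
        n_comparisons[ct] = n_comparisons.get(ct, 0) + 1
    for ct, n_sub in by_ct.items():
        if n_comparisons.get(ct, 0) < n_sub - 1:
            warnings.warn(
                f"cell type {ct!r}: fewer comparisons than subtypes-1; "
                "adjacency is sparsely filled"
            )
    S = len(subtypes)
    G = len(log2fc)
    idx = {s: i for i, s in enumerate(subtypes)}
    tensor = np.zeros((S, S, G))
    for col, a, b in parsed:
        v = log2fc[col].to_numpy(dtype=float)
        v = np.nan_to_num(v, nan=0.0)
        i, j = idx[a], idx[b]
        tensor[i, j, :] = v
        tensor[j, i, :] = -v

    flat = tensor.reshape(S * S, G)
    rank = int(np.linalg.matrix_rank(flat - flat.mean(axis=0, keepdims=True)))
    k = max(1, min(n_components, rank, S * S - 1, G))
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(flat)  # (S*S) x k, gene-axis reduced
    row_scores = scores.reshape(S, S, k)
    emb = row_scores.mean(axis=1)  # e_S: mean over the subtype's row

    norms = np.linalg.norm(emb, axis=1)
    norms = np.where(norms > 0, norms, 1.0)
    K = (emb @ emb.T) / np.outer(norms, norms)
    K = np.clip((K + K.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(K, 1.0)
    D = 1.0 - K
    np.fill_diagonal(D, 0.0)
    Z = average(squareform(D, checks=False))
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    # canonical cluster numbering: order of first appearance in sorted subtypes
    seen: dict[int, int] = {}
    canon = []
    for lab in labels:
        if lab not in seen:
            seen[lab] = len(seen) + 1
        canon.append(seen[lab])
    return SubtypeEmbedding(
        subtypes=subtypes,
        embedding=emb,
        similarity=pd.DataFrame(K, index=subtypes, columns=subtypes),
        distance=pd.DataFrame(D, index=subtypes, columns=subtypes),
        clusters=pd.Series(canon, index=subtypes, name="cluster"),
    )
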