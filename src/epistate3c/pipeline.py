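"""End-to-end orchestration: simulate -> methylome -> states -> contacts ->
genome3d -> loops, driven by a strict YAML configuration.

Each stage consumes in-memory products of earlier stages and writes compact
result tables into the output directory; a manifest records parameters and
SHA-256 hashes of every output so a rerun with the same configuration is
verifiably identical. A stage failure leaves a ``<stage>.partial`` marker
next to whatever it managed to write.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import cell_states, contact_metrics, diff_loops, genome3d, linear_models, methylome
from . import synthetic_data as sd

__all__ = ["RunConfig", "load_config", "validate", "run", "ConfigError"]

log = logging.getLogger("epistate3c")

STAGES = ["simulate", "methylome", "states", "contacts", "genome3d", "loops"]


class ConfigError(ValueError):
    pass


_STAGE_DEFAULTS: dict[str, dict[str, Any]] = {
    "methylome": {
        "binarize_cutoff": 0.9,
        "coverage_min": 500,
        "coverage_max": 3000,
        "top_k": 20000,
        "p_max": 0.05,
        "coef_min_abs": 0.01,
        "min_donors": 5,
    },
    "states": {
        "k": 3,
        "n_components": 50,
        "n_clusters": 2,
        "score_pos": 2.5,
        "score_neg": -2.5,
        "min_donors": 5,
    },
    "contacts": {
        "insulation_window": 4,
        "min_depth": 0.05,
        "density_window": 1_000_000,
        "standardize": True,
    },
    "genome3d": {
        "n_quantiles": 10,
        "min_missing": 10,
        "p_bins": 50,
        "q_bins": 50,
        "min_chrom_bins": 50,
    },
    "loops": {
        "pad": 7,
        "dmin": 5,
        "dmax": 500,
        "p_max": 0.05,
        "coef_min_abs": 0.01,
        "min_donors": 5,
        "max_candidates": 200,
    },
}


@dataclass
class RunConfig:
    """Validated pipeline configuration (strict schema: unknown keys rejected)."""

    seed: int = 0
    outdir: str = "epistate3c_run"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    log_level: str = "INFO"
    write_raw: bool = False
    simulation: dict[str, Any] = field(default_factory=dict)
    methylome: dict[str, Any] = field(default_factory=dict)
    states: dict[str, Any] = field(default_factory=dict)
    contacts: dict[str, Any] = field(default_factory=dict)
    genome3d: dict[str, Any] = field(default_factory=dict)
    loops: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s in self.stages:
            if s not in STAGES:
                raise ConfigError(f"unknown stage {s!r}")
        order = [STAGES.index(s) for s in self.stages]
        if order != sorted(order):
            raise ConfigError("stages must respect the pipeline order")
        if self.stages and self.stages[0] != "simulate":
            raise ConfigError(
                "every stage's inputs must be producible: enable 'simulate' first"
            )
        sim_fields = {f.name for f in fields(sd.SimConfig)}
        for key in self.simulation:
            if key not in sim_fields:
                raise ConfigError(f"unknown simulation key {key!r}")
        for stage, defaults in _STAGE_DEFAULTS.items():
            block = getattr(self, stage)
            for key in block:
                if key not in defaults:
                    raise ConfigError(f"unknown {stage} key {key!r}")
        if "genome3d" in self.stages:
            cen = self.simulation.get("centromeres", "default")
            if cen is not None and cen != "default" and len(cen) == 0:
                raise ConfigError(
                    "genome3d stage enabled but simulation.centromeres is empty"
                )

    def stage_params(self, stage: str) -> dict[str, Any]:
        return {**_STAGE_DEFAULTS[stage], **getattr(self, stage)}

    def sim_config(self) -> sd.SimConfig:
        sim = dict(self.simulation)
        sim.setdefault("seed", self.seed)
        # YAML mappings arrive with string/list keys; coerce tuple-keyed fields
        for key in ("subgroup_proportions", "region_effect"):
            if key in sim and isinstance(sim[key], dict):
                sim[key] = {
                    (tuple(k.split("|")) if isinstance(k, str) else tuple(k)): v
                    for k, v in sim[key].items()
                }
        try:
            return sd.SimConfig(**sim)
        except sd.ConfigurationError as exc:
            raise ConfigError(str(exc)) from exc


def load_config(path) -> RunConfig:
    text = Path(path).read_text()
    if not text.strip():
        raise ConfigError(f"{path}: empty configuration file")
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: YAML parse error: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    for key in raw:
        if key not in known:
            raise ConfigError(f"unknown configuration key {key!r}")
    return RunConfig(**raw)


def validate(path) -> dict[str, Any]:
    """Schema + cross-stage dependency check without execution."""
    cfg = load_config(path)
    cfg.sim_config()
    for stage in cfg.stages:
        if stage != "simulate" and "simulate" not in cfg.stages:
            raise ConfigError(f"stage {stage!r} requires 'simulate'")
    return {"valid": True, "stages": cfg.stages, "seed": cfg.seed}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.8g")


@dataclass
class RunState:
    """In-memory products passed between stages."""

    meta: pd.DataFrame | None = None
    truth: sd.SimTruth | None = None
    counts: Any = None
    cell_levels: pd.DataFrame | None = None
    assignments: pd.DataFrame | None = None
    cell_state: pd.Series | None = None
    contacts: pd.DataFrame | None = None
    outputs: list[Path] = field(default_factory=list)


def run(config: RunConfig | str | Path) -> dict[str, Any]:
    """Execute the configured stages; returns the manifest dict.

    Raises on stage failure after writing a ``<stage>.partial`` marker;
    rerunning with an identical configuration reproduces identical output
    hashes.
    """
    if not isinstance(config, RunConfig):
        config = load_config(config)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state = RunState()
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "stages": config.stages,
        "parameters": {s: config.stage_params(s) for s in _STAGE_DEFAULTS},
        "simulation": {k: str(v) for k, v in config.simulation.items()},
        "outputs": {},
    }
    for stage in config.stages:
        t0 = time.perf_counter()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                n_out = _STAGE_FN[stage](config, state, outdir)
            except Exception:
                (outdir / f"{stage}.partial").write_text("stage failed\n")
                raise
        log.info(
            "stage=%s elapsed=%.1fs records_out=%d warnings=%d",
            stage, time.perf_counter() - t0, n_out, len(caught),
        )
    for path in state.outputs:
        manifest["outputs"][path.name] = _sha256(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config: RunConfig, state: RunState, outdir: Path) -> int:
    sim = config.sim_config()
    meta, truth = sd.simulate_cohort(sim)
    state.meta, state.truth = meta, truth
    sd.write_metadata_tsv(meta, outdir / "metadata.tsv")
    truth.to_json(outdir / "truth.json")
    state.outputs += [outdir / "metadata.tsv", outdir / "truth.json"]
    return len(meta)


def _stage_methylome(config: RunConfig, state: RunState, outdir: Path) -> int:
    sim = config.sim_config()
    p = config.stage_params("methylome")
    counts = sd.simulate_methylome(state.meta, state.truth, sim)
    state.counts = counts
    passing, fail_counts = methylome.qc_filter(state.meta, require_3c=True)
    scores = methylome.hypo_score(counts, "CG")
    binarized = methylome.binarize_scores(scores, cutoff=p["binarize_cutoff"])
    state.cell_levels = methylome.cell_global_levels(counts)
    group_levels = methylome.global_levels(counts, state.meta)
    _write_tsv(group_levels.reset_index(), outdir / "global_levels.tsv")
    _write_tsv(state.cell_levels, outdir / "cell_levels.tsv", index=True)
    summary = pd.DataFrame(
        {
            "cell_id": counts.cells,
            "qc_pass": [c in set(passing) for c in counts.cells],
            "hypo_bins": binarized.sum(axis=1),
        }
    )
    _write_tsv(summary, outdir / "methylome_summary.tsv")
    if config.write_raw:
        counts.to_long_tsv(outdir / "methyl_counts.tsv")
        state.outputs.append(outdir / "methyl_counts.tsv")

    # per-bin pseudo-bulk CG levels -> batch correction -> AD association
    frac = counts.fraction("CG")
    sample_key = state.meta["donor"] + "|" + state.meta["region"]
    samples = sorted(sample_key.unique())
    vals = np.full((counts.n_bins, len(samples)), np.nan)
    smeta_rows = {}
    for j, s in enumerate(samples):
        cells = np.flatnonzero((sample_key == s).to_numpy())
        vals[:, j] = np.nanmean(frac[cells], axis=0)
        first = state.meta.iloc[cells[0]]
        smeta_rows[s] = {
            k: first[k] for k in ("donor", "region", "disease", "sex", "age", "instrument")
        }
    smeta = pd.DataFrame.from_dict(smeta_rows, orient="index")
    values = pd.DataFrame(vals, columns=samples,
                          index=[f"bin{i}" for i in range(counts.n_bins)])
    corrected = linear_models.batch_correct(values, smeta)
    assoc = linear_models.fit_feature_model(
        corrected, smeta, min_donors=p["min_donors"]
    )
    assoc.to_tsv(outdir / "methyl_association.tsv")
    hits = linear_models.select_by_cutoffs(
        assoc, p["p_max"], p["coef_min_abs"], "disease[AD]"
    )
    (outdir / "dm_bins.txt").write_text("\n".join(sorted(hits)) + "\n")
    state.outputs += [
        outdir / "global_levels.tsv", outdir / "cell_levels.tsv",
        outdir / "methylome_summary.tsv", outdir / "methyl_association.tsv",
        outdir / "dm_bins.txt",
    ]
    return len(assoc.table)


def _stage_states(config: RunConfig, state: RunState, outdir: Path) -> int:
    sim = config.sim_config()
    p = config.stage_params("states")
    levels = state.cell_levels
    meta = state.meta
    shared = sd.simulate_shared_libraries(meta, state.truth, sim)
    normalized = cell_states.normalize_instruments(levels, meta, shared)
    assignments = cell_states.kmeans_subgroups(
        normalized, meta, neuron_cell_types=sim.neuron_cell_types,
        k=p["k"], seed=config.seed,
    )
    state.assignments = assignments
    assoc = cell_states.subgroup_ratio_association(
        assignments, meta, min_donors=p["min_donors"]
    )
    assoc.to_tsv(outdir / "subgroup_association.tsv")

    subtypes = sorted(
        f"{ct}:g{g}"
        for ct in sim.cell_types
        for g in sorted(assignments["subgroup"].unique())
    )
    planted = {s: ("Stressed" if s.endswith(":g1") else "Homeostatic") for s in subtypes}
    log2fc = sd.simulate_log2fc_tensor(subtypes, planted, sim)
    emb = cell_states.subtype_similarity_cluster(
        log2fc, n_components=p["n_components"], n_clusters=p["n_clusters"]
    )
    # marker hook: the cluster holding more subgroup-1 subtypes is Stressed
    g1 = emb.clusters[[s.endswith(":g1") for s in emb.clusters.index]]
    stressed_cluster = int(g1.mode().iloc[0]) if len(g1) else 1
    cluster_names = {
        c: ("Stressed" if c == stressed_cluster else "Homeostatic")
        for c in emb.clusters.unique()
    }
    subtype_state = emb.relabel(cluster_names)
    _write_tsv(
        subtype_state.rename("state").rename_axis("subtype").reset_index(),
        outdir / "subtype_clusters.tsv",
    )
    cell_subtype = meta.loc[assignments.index, "cell_type"] + ":g" + assignments[
        "subgroup"
    ].astype(str)
    state.cell_state = cell_subtype.map(subtype_state).rename("state")
    out = assignments.copy()
    out["state"] = state.cell_state
    _write_tsv(out, outdir / "cell_states.tsv", index=True)
    state.outputs += [
        outdir / "subgroup_association.tsv", outdir / "subtype_clusters.tsv",
        outdir / "cell_states.tsv",
    ]
    return len(out)


def _stage_contacts(config: RunConfig, state: RunState, outdir: Path) -> int:
    sim = config.sim_config()
    p = config.stage_params("contacts")
    contacts = sd.simulate_contacts(state.meta, state.truth, sim)
    state.contacts = contacts
    if config.write_raw:
        sd.write_pairs_tsv(contacts, outdir / "contacts.pairs.tsv")
        state.outputs.append(outdir / "contacts.pairs.tsv")
    edges = contact_metrics.geometric_edges(chrom_lengths=dict(sim.chrom_lengths))
    profiles = contact_metrics.decay_profile_matrix(contacts, edges, cells=state.meta.index)
    classes = contact_metrics.classify_short_long(
        profiles, standardize=p["standardize"], seed=config.seed
    )
    _write_tsv(classes, outdir / "contact_classes.tsv", index=True)

    calls, bins = sd.simulate_boundary_calls(state.truth, sim)
    density = contact_metrics.boundary_density(
        calls, bins, state.meta, window=p["density_window"]
    )
    covariate = contact_metrics.mean_cis_long_contacts(contacts, state.meta)
    adjusted = contact_metrics.adjust_boundary_density(density, covariate)
    _write_tsv(adjusted, outdir / "boundary_density.tsv")
    state.outputs += [outdir / "contact_classes.tsv", outdir / "boundary_density.tsv"]
    return len(classes)


def _pseudo_bulk_groups(state: RunState, sim: sd.SimConfig):
    """Balanced per-chromosome pseudo-bulks keyed State_CellType_Region."""
    meta = state.meta
    st = state.cell_state if state.cell_state is not None else state.truth.state
    membership = (
        st.loc[meta.index].astype(str)
        + "_" + meta["cell_type"].astype(str)
        + "_" + meta["region"].astype(str)
    )
    raw = genome3d.pseudo_bulk_by_group(
        state.contacts, membership, dict(sim.chrom_lengths), sim.bin_size_contact
    )
    return {
        name: {chrom: genome3d.balance_ice(bm)[0] for chrom, bm in per.items()}
        for name, per in raw.items()
    }


def _stage_genome3d(config: RunConfig, state: RunState, outdir: Path) -> int:
    sim = config.sim_config()
    p = config.stage_params("genome3d")
    gc = sd.gc_track(sim)
    groups = _pseudo_bulk_groups(state, sim)

    # compartments + saddles pooled across chromosomes, per state
    by_state: dict[str, tuple[list, list]] = {}
    pc1_rows = []
    for name, per_chrom in groups.items():
        lab = name.split("_", 1)[0]
        mats, profs = by_state.setdefault(lab, ([], []))
        for chrom, M in per_chrom.items():
            try:
                prof = genome3d.compartment_pc1(M, gc[chrom])
            except ValueError:
                continue
            mats.append(M)
            profs.append(prof)
            if name == sorted(groups)[0]:
                for b, v in enumerate(prof.pc1):
                    if not np.isnan(v):
                        pc1_rows.append(
                            {"chrom": chrom, "start": b * sim.bin_size_contact,
                             "end": (b + 1) * sim.bin_size_contact, "pc1": v}
                        )
    saddles = {
        lab: genome3d.saddle(mats, profs, n_quantiles=p["n_quantiles"])
        for lab, (mats, profs) in by_state.items()
        if mats
    }
    if "Stressed" in saddles and "Homeostatic" in saddles:
        ratio = genome3d.saddle_state_ratio(saddles["Stressed"], saddles["Homeostatic"])
        np.savetxt(outdir / "saddle_ratio.tsv", ratio, delimiter="\t", fmt="%.6g")
        state.outputs.append(outdir / "saddle_ratio.tsv")
    pd.DataFrame(pc1_rows).to_csv(
        outdir / "pc1.bedGraph", sep="\t", index=False, header=False,
        float_format="%.6g",
    )
    state.outputs.append(outdir / "pc1.bedGraph")

    # centromere-aligned average for one representative pseudo-bulk per state
    for lab in sorted(by_state):
        rep = sorted(n for n in groups if n.startswith(lab + "_"))[0]
        avg = genome3d.centromere_aligned_average(
            groups[rep], dict(sim.centromeres), sim.bin_size_contact,
            p_bins=p["p_bins"], q_bins=p["q_bins"],
            min_chrom_bins=p["min_chrom_bins"],
        )
        np.savetxt(outdir / f"arm_average_{lab}.tsv", avg, delimiter="\t", fmt="%.6g")
        state.outputs.append(outdir / f"arm_average_{lab}.tsv")

    calls = genome3d.detect_putative_deletions(
        groups, dict(sim.chrom_lengths), sim.bin_size_contact,
        min_missing=p["min_missing"],
    )
    _write_tsv(calls, outdir / "deletions.tsv")
    state.outputs.append(outdir / "deletions.tsv")
    return len(calls)


def _stage_loops(config: RunConfig, state: RunState, outdir: Path) -> int:
    sim = config.sim_config()
    p = config.stage_params("loops")
    meta = state.meta
    chrom = next(iter(sim.chrom_lengths))
    length = sim.chrom_lengths[chrom]
    res = sim.bin_size_contact
    n_bins = int(np.ceil(length / res))

    # per-cell binned values on one chromosome, accumulated per sample
    sub = state.contacts[
        (state.contacts["chrom1"] == chrom) & (state.contacts["chrom2"] == chrom)
    ]
    cell_codes = pd.Categorical(sub["cell_id"], categories=meta.index).codes
    b1 = np.minimum(sub["pos1"].to_numpy() // res, n_bins - 1).astype(int)
    b2 = np.minimum(sub["pos2"].to_numpy() // res, n_bins - 1).astype(int)
    lo, hi = np.minimum(b1, b2), np.maximum(b1, b2)

    sample_key = meta["donor"].astype(str) + "|" + meta["region"].astype(str)
    per_sample: dict[str, tuple[np.ndarray, np.ndarray, int]] = {}
    per_sample_mean: dict[str, np.ndarray] = {}
    for s in sorted(sample_key.unique()):
        cells = np.flatnonzero((sample_key == s).to_numpy())
        mask = np.isin(cell_codes, cells)
        counts = np.zeros((n_bins, n_bins))
        sq = np.zeros_like(counts)
        # per-cell pixel counts, folded into sum and sum-of-squares matrices
        cc = cell_codes[mask]
        ll, hh = lo[mask], hi[mask]
        flat = cc.astype(np.int64) * (n_bins * n_bins) + ll * n_bins + hh
        uniq, cnt = np.unique(flat, return_counts=True)
        ci = uniq // (n_bins * n_bins)
        rem = uniq % (n_bins * n_bins)
        pi, pj = rem // n_bins, rem % n_bins
        np.add.at(counts, (pi, pj), cnt)
        np.add.at(sq, (pi, pj), cnt.astype(float) ** 2)
        n_cells = len(cells)
        per_sample[s] = (counts / n_cells, sq / n_cells, n_cells)
        per_sample_mean[s] = counts / n_cells

    ad_samples = [s for s in per_sample if meta.loc[sample_key == s, "disease"].iloc[0] == "AD"]
    ct_samples = [s for s in per_sample if s not in ad_samples]
    acc_ad = diff_loops.accumulate_group([per_sample[s] for s in ad_samples], "AD")
    acc_ct = diff_loops.accumulate_group([per_sample[s] for s in ct_samples], "Control")
    stats = diff_loops.pixel_f_statistic([acc_ad, acc_ct])
    stats = diff_loops.mask_pixels(stats, pad=p["pad"], dmin=p["dmin"], dmax=p["dmax"])
    keep = stats[(stats["mask_reason"] == "none") & np.isfinite(stats["F"])]
    cand = keep.nlargest(p["max_candidates"], "F")

    keys = cand["bin1"].astype(str) + "|" + cand["bin2"].astype(str)
    vals = pd.DataFrame(
        {
            s: [per_sample_mean[s][i, j] for i, j in zip(cand["bin1"], cand["bin2"])]
            for s in per_sample
        },
        index=keys,
    )
    smeta = pd.DataFrame(
        {
            s: {
                k: meta.loc[sample_key == s, k].iloc[0]
                for k in ("donor", "region", "disease", "sex", "age")
            }
            for s in per_sample
        }
    ).T
    assoc = diff_loops.loop_covariate_regression(
        cand, vals, smeta, min_donors=p["min_donors"]
    )
    out = cand.copy()
    out["chrom"] = chrom
    out["start1"] = out["bin1"] * res
    out["end1"] = out["start1"] + res
    out["start2"] = out["bin2"] * res
    out["end2"] = out["start2"] + res
    akey = out["bin1"].astype(str) + "|" + out["bin2"].astype(str)
    for col in ("disease[AD]_coef", "disease[AD]_p", "disease[AD]_q"):
        out[col] = akey.map(assoc.table[col]).to_numpy()
    _write_tsv(
        out[
            ["chrom", "start1", "end1", "chrom", "start2", "end2", "F",
             "disease[AD]_coef", "disease[AD]_p", "disease[AD]_q", "mask_reason"]
        ],
        outdir / "loops.tsv",
    )
    state.outputs.append(outdir / "loops.tsv")
    return len(out)


_STAGE_FN = {
    "simulate": _stage_simulate,
    "methylome": _stage_methylome,
    "states": _stage_states,
    "contacts": _stage_contacts,
    "genome3d": _stage_genome3d,
    "loops": _stage_loops,
}
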