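"""Synthetic snm3C-like cohorts with planted ground truth.

Generates the five inputs the analysis stages consume — cell metadata,
binned methylation counts, per-cell contact lists, binary TAD-boundary
calls, and pairwise subtype log2-fold-change tables — from a single seeded
configuration, together with a :class:`SimTruth` record sufficient to score
every downstream recovery test.

The planted structure mirrors the study conditions the statistics were
designed for:

* a cohort of 11 AD and 9 control donors, each sampled in three cortical
  regions (VC, PFC, TC);
* region-opposed methylation shifts (TC hypermethylated in AD, VC
  hypomethylated, PFC intermediate);
* three global CG/CH methylation subgroups per cell class with
  region x disease dependent mixing proportions;
* an instrument batch effect acting as an affine map on methylation levels;
* two contact-decay classes (short- vs long-range enriched) with distinct
  power-law exponents, block (TAD) and checkerboard (compartment)
  enrichment of contacts;
* telomere-proximal bins with zero contacts ("deletions") confined to the
  Stressed cell subset.

All randomness flows through one seeded generator; per-cell substreams are
derived by stable hashing (CRC-32) of cell ids, so outputs are byte-identical
for identical configurations regardless of iteration order.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .methylome import MethylBinCounts

__all__ = [
    "SimConfig",
    "SimTruth",
    "ConfigurationError",
    "simulate_cohort",
    "simulate_methylome",
    "simulate_contacts",
    "simulate_boundary_calls",
    "simulate_log2fc_tensor",
    "parse_comparison",
]

INSTRUMENT_A = "NovaSeq6000"
INSTRUMENT_B = "NovaSeqX"
HOMEOSTATIC = "Homeostatic"
STRESSED = "Stressed"


class ConfigurationError(ValueError):
    """Invalid simulation configuration; the message names the field."""


def _default_chrom_lengths() -> dict[str, int]:
    return {"chr1": 20_000_000, "chr2": 20_000_000, "chr3": 20_000_000}


def _default_subgroup_proportions() -> dict[tuple[str, str], tuple[float, float, float]]:
    base = (0.30, 0.50, 0.20)
    return {
        ("VC", "Control"): base,
        ("PFC", "Control"): base,
        ("TC", "Control"): base,
        # AD shifts: subgroup 1 (high CG / low CH) gains in TC, loses in VC
        ("VC", "AD"): (0.45, 0.35, 0.20),
        ("PFC", "AD"): (0.30, 0.50, 0.20),
        ("TC", "AD"): (0.15, 0.65, 0.20),
    }


def _default_region_effect() -> dict[tuple[str, str], float]:
    return {
        ("VC", "AD"): -0.02,
        ("PFC", "AD"): 0.01,
        ("TC", "AD"): 0.02,
    }


@dataclass
class SimConfig:
    """Full parameterization of one synthetic cohort."""

    seed: int = 0
    n_ad_donors: int = 11
    n_control_donors: int = 9
    regions: Sequence[str] = ("VC", "PFC", "TC")
    cells_per_sample: int = 100
    cell_types: Sequence[str] = ("Exc", "Inh", "ODC", "ASC")
    cell_type_proportions: Sequence[float] = (0.40, 0.20, 0.25, 0.15)
    neuron_cell_types: Sequence[str] = ("Exc", "Inh")

    chrom_lengths: Mapping[str, int] = field(default_factory=_default_chrom_lengths)
    centromeres: Mapping[str, int] | None = None  # default: 40% of length

    bin_size_methyl: int = 100_000
    bin_size_contact: int = 100_000
    bin_size_boundary: int = 25_000

    subgroup_proportions: Mapping[tuple[str, str], Sequence[float]] = field(
        default_factory=_default_subgroup_proportions
    )
    region_effect: Mapping[tuple[str, str], float] = field(
        default_factory=_default_region_effect
    )

    # methylome emission
    baseline_cg: float = 0.75
    baseline_ch: float = 0.03
    baseline_ccc: float = 0.005
    subgroup_cg_offsets: Sequence[float] = (-0.08, 0.04, 0.04)
    subgroup_ch_offsets: Sequence[float] = (0.0, 0.0, 0.05)
    methyl_coverage_mean: float = 20.0
    methyl_coverage_dispersion: float = 5.0
    noise_scale: float = 0.01

    # instrument batch: measured = batch_offset + batch_slope * true, on B
    batch_offset: float = 0.02
    batch_slope: float = 0.96

    # contacts
    contacts_per_cell: int = 1500
    decay_exponents: tuple[float, float] = (1.5, 0.8)  # (Short class, Long class)
    short_fraction: float = 0.5
    min_contact_distance: int = 1_000
    trans_fraction: float = 0.05
    tad_size: int = 1_000_000
    compartment_block: int = 2_000_000
    p_tad: float = 0.35
    p_compartment: float = 0.20

    # deletions
    n_deleted_bins: int = 20
    deletion_max_telomere_distance: int = 2_000_000

    # boundary calls
    boundary_miss_rate: float = 0.10
    boundary_jitter_rate: float = 0.10
    extra_boundary_rate: float = 0.002
    stressed_extra_boundary_rate: float = 0.004

    # log2FC tensor
    n_genes: int = 200
    log2fc_delta: float = 2.0
    log2fc_noise: float = 0.1

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_ad_donors", "n_control_donors", "cells_per_sample",
                     "bin_size_methyl", "bin_size_contact", "bin_size_boundary",
                     "contacts_per_cell", "tad_size", "compartment_block"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.n_deleted_bins < 0:
            raise ConfigurationError("n_deleted_bins must be >= 0")
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ConfigurationError(f"chrom_lengths[{chrom!r}] must be positive")
        if self.centromeres is None:
            self.centromeres = {
                c: int(0.4 * l) for c, l in self.chrom_lengths.items()
            }
        for chrom, pos in self.centromeres.items():
            if chrom not in self.chrom_lengths:
                raise ConfigurationError(f"centromeres[{chrom!r}] has no chromosome")
            if not (0 < pos < self.chrom_lengths[chrom]):
                raise ConfigurationError(
                    f"centromeres[{chrom!r}] must lie inside the chromosome"
                )
        for key, props in self.subgroup_proportions.items():
            props = tuple(props)
            if len(props) != 3 or abs(sum(props) - 1.0) > 1e-9 or min(props) < 0:
                raise ConfigurationError(
                    f"subgroup_proportions[{key!r}] must be 3 nonnegative reals summing to 1"
                )
        if len(self.cell_type_proportions) != len(self.cell_types):
            raise ConfigurationError("cell_type_proportions must match cell_types")
        if abs(sum(self.cell_type_proportions) - 1.0) > 1e-9:
            raise ConfigurationError("cell_type_proportions must sum to 1")
        if not (0 <= self.trans_fraction < 1):
            raise ConfigurationError("trans_fraction must lie in [0, 1)")
        if self.p_tad + self.p_compartment > 1:
            raise ConfigurationError("p_tad + p_compartment must be <= 1")


@dataclass
class SimTruth:
    """Planted ground truth for one simulated cohort."""

    subgroup: pd.Series  # cell -> {0,1,2}
    decay_class: pd.Series  # cell -> {"Short","Long"}
    state: pd.Series  # cell -> {"Homeostatic","Stressed"}
    deleted_bins: set  # {(chrom, contact-bin index)}
    batch_offset: float
    batch_slope: float
    region_effect: dict  # {(region, disease): shift}
    boundary_positions: dict  # {chrom: array of planted boundary bin indices (25 kb)}

    def __post_init__(self) -> None:
        idx = self.subgroup.index
        if not (idx.equals(self.decay_class.index) and idx.equals(self.state.index)):
            raise ValueError("truth label mappings must cover identical cells")
        if idx.has_duplicates:
            raise ValueError("each cell must appear exactly once per label mapping")

    def to_json(self, path) -> None:
        payload = {
            "subgroup": {k: int(v) for k, v in self.subgroup.items()},
            "decay_class": dict(self.decay_class),
            "state": dict(self.state),
            "deleted_bins": sorted([c, int(b)] for c, b in self.deleted_bins),
            "batch_offset": self.batch_offset,
            "batch_slope": self.batch_slope,
            "region_effect": {f"{r}|{d}": v for (r, d), v in self.region_effect.items()},
            "boundary_positions": {
                c: [int(x) for x in v] for c, v in self.boundary_positions.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            subgroup=pd.Series(d["subgroup"]),
            decay_class=pd.Series(d["decay_class"]),
            state=pd.Series(d["state"]),
            deleted_bins={(c, int(b)) for c, b in d["deleted_bins"]},
            batch_offset=d["batch_offset"],
            batch_slope=d["batch_slope"],
            region_effect={
                tuple(k.split("|")): v for k, v in d["region_effect"].items()
            },
            boundary_positions={
                c: np.asarray(v, dtype=int) for c, v in d["boundary_positions"].items()
            },
        )


def _cell_rng(config: SimConfig, cell_id: str, stream: str) -> np.random.Generator:
    """Deterministic per-cell substream from the global seed + CRC-32 of the id."""
    key = zlib.crc32(f"{stream}:{cell_id}".encode())
    return np.random.default_rng(np.random.SeedSequence([config.seed, key]))


# ---------------------------------------------------------------------------
# cohort


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Generate the cell metadata table and the planted-truth record.

    Donors are split AD / control per the configuration, every donor appears
    in every region, and each (donor, region) sample contributes
    ``cells_per_sample`` cells. Ages, sexes, instruments, cell types,
    methylation subgroups, decay classes and QC metrics are all assigned
    reproducibly from the seed. The Stressed state is planted as
    global-methylation subgroup 1 (high CG / low CH).
    """
    config.validate()
    if config.cells_per_sample <= 0:  # validate() already raises; keep explicit
        raise ConfigurationError("cells_per_sample must be strictly positive")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC04]))

    donors = [f"AD{i + 1:02d}" for i in range(config.n_ad_donors)] + [
        f"CT{i + 1:02d}" for i in range(config.n_control_donors)
    ]
    disease = {d: ("AD" if d.startswith("AD") else "Control") for d in donors}
    ages = {d: int(rng.integers(62, 95)) for d in donors}
    sexes = {d: ("Female" if rng.random() < 0.5 else "Male") for d in donors}

    rows = []
    for donor in donors:
        for region in config.regions:
            instrument = INSTRUMENT_A if rng.random() < 0.5 else INSTRUMENT_B
            n = config.cells_per_sample
            ct = rng.choice(
                len(config.cell_types), size=n, p=np.asarray(config.cell_type_proportions)
            )
            props = np.asarray(
                config.subgroup_proportions[(region, disease[donor])], dtype=float
            )
            subgroup = rng.choice(3, size=n, p=props)
            decay = np.where(rng.random(n) < config.short_fraction, "Short", "Long")
            # plausible mapping-level QC metrics (cells designed to pass QC)
            mccc = rng.uniform(0.002, 0.012, n)
            mch = rng.uniform(0.02, 0.10, n)
            mcg = rng.uniform(0.65, 0.85, n)
            reads = rng.integers(800_000, 6_000_000, n)
            maprate = rng.uniform(0.55, 0.80, n)
            cis_long = rng.integers(60_000, 400_000, n)
            for i in range(n):
                rows.append(
                    {
                        "cell_id": f"{donor}_{region}_c{i:04d}",
                        "donor": donor,
                        "region": region,
                        "disease": disease[donor],
                        "sex": sexes[donor],
                        "age": ages[donor],
                        "instrument": instrument,
                        "cell_type": config.cell_types[ct[i]],
                        "subgroup": int(subgroup[i]),
                        "decay_class": decay[i],
                        "mccc": round(float(mccc[i]), 6),
                        "mch": round(float(mch[i]), 6),
                        "mcg": round(float(mcg[i]), 6),
                        "total_reads": int(reads[i]),
                        "mapping_rate": round(float(maprate[i]), 6),
                        "cis_long_contacts": int(cis_long[i]),
                    }
                )
    meta = pd.DataFrame(rows).set_index("cell_id")
    truth = SimTruth(
        subgroup=meta["subgroup"].copy(),
        decay_class=meta["decay_class"].copy(),
        state=meta["subgroup"].map(lambda g: STRESSED if g == 1 else HOMEOSTATIC),
        deleted_bins=_plant_deletions(config),
        batch_offset=config.batch_offset,
        batch_slope=config.batch_slope,
        region_effect=dict(config.region_effect),
        boundary_positions=_plant_boundaries(config),
    )
    meta = meta.drop(columns=["subgroup", "decay_class"])
    return meta, truth


def _plant_deletions(config: SimConfig) -> set:
    """Pick telomere-proximal contact bins to delete in Stressed cells."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xDE1]))
    candidates: list[tuple[str, int]] = []
    bs = config.bin_size_contact
    for chrom, length in config.chrom_lengths.items():
        n_bins = int(np.ceil(length / bs))
        for b in range(n_bins):
            start, end = b * bs, min((b + 1) * bs, length)
            if min(start, length - end) <= config.deletion_max_telomere_distance:
                candidates.append((chrom, b))
    k = min(config.n_deleted_bins, len(candidates))
    if k == 0:
        return set()
    idx = rng.choice(len(candidates), size=k, replace=False)
    return {candidates[i] for i in idx}


def _plant_boundaries(config: SimConfig) -> dict:
    """Planted TAD boundaries: one every tad_size, as 25-kb bin indices."""
    out = {}
    for chrom, length in config.chrom_lengths.items():
        pos = np.arange(config.tad_size, length, config.tad_size)
        out[chrom] = (pos // config.bin_size_boundary).astype(int)
    return out


# ---------------------------------------------------------------------------
# methylome


def methyl_bins(config: SimConfig) -> pd.DataFrame:
    """0-based half-open methylation bin table over all chromosomes."""
    frames = []
    for chrom, length in config.chrom_lengths.items():
        starts = np.arange(0, length, config.bin_size_methyl)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": np.minimum(starts + config.bin_size_methyl, length),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def expected_methylation_probability(
    meta: pd.DataFrame, truth: SimTruth, config: SimConfig, context: str
) -> np.ndarray:
    """Planted per-cell methylation probability before measurement noise."""
    base = {"CG": config.baseline_cg, "CH": config.baseline_ch,
            "CCC": config.baseline_ccc}[context]
    p = np.full(len(meta), base, dtype=float)
    sub = truth.subgroup.loc[meta.index].to_numpy()
    if context == "CG":
        p += np.asarray(config.subgroup_cg_offsets)[sub]
        for (region, disease), shift in config.region_effect.items():
            mask = (meta["region"] == region) & (meta["disease"] == disease)
            p[mask.to_numpy()] += shift
    elif context == "CH":
        p += np.asarray(config.subgroup_ch_offsets)[sub]
        p[meta["cell_type"].isin(config.neuron_cell_types).to_numpy()] += 0.02
    return p


def simulate_methylome(
    meta: pd.DataFrame, truth: SimTruth, config: SimConfig
) -> MethylBinCounts:
    """Emit binned (mc, cov) counts per cell per context.

    Coverage is negative-binomial (mean, dispersion from the config);
    methylated counts are binomial with probability
    baseline + subgroup offset + region x disease effect (+ per-cell and
    per-bin Gaussian jitter at ``noise_scale``), mapped through the affine
    instrument relation for instrument-B cells and clipped to [0, 1].
    With ``noise_scale = 0`` the emission is fully deterministic: constant
    coverage and expected counts, so observed fractions equal the planted
    probabilities exactly. Clipping events are counted in
    ``counts.clip_events``.
    """
    if len(meta) == 0:
        raise ConfigurationError("metadata must be nonempty")
    bins = methyl_bins(config)
    n_bins = len(bins)
    rng_bins = np.random.default_rng(np.random.SeedSequence([config.seed, 0xB145]))
    # shared per-bin baseline wiggle so bins are distinguishable
    bin_effect = (
        rng_bins.normal(0.0, 0.02, size=n_bins) if config.noise_scale > 0 else np.zeros(n_bins)
    )
    on_b = (meta["instrument"] == INSTRUMENT_B).to_numpy()

    data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    clip_events = 0
    mean = config.methyl_coverage_mean
    disp = config.methyl_coverage_dispersion
    nb_n = disp
    nb_p = disp / (disp + mean)
    for context in ("CG", "CH", "CCC"):
        p_cell = expected_methylation_probability(meta, truth, config, context)
        mc = np.empty((len(meta), n_bins), dtype=np.int32)
        cov = np.empty((len(meta), n_bins), dtype=np.int32)
        for i, cell in enumerate(meta.index):
            p = p_cell[i]
            if config.noise_scale > 0:
                rng = _cell_rng(config, cell, f"methyl:{context}")
                p = p + rng.normal(0.0, config.noise_scale) + (
                    bin_effect if context == "CG" else 0.0
                )
            if on_b[i]:
                p = config.batch_offset + config.batch_slope * p
            p = np.broadcast_to(np.atleast_1d(p), (n_bins,)).astype(float)
            clipped = np.clip(p, 0.0, 1.0)
            clip_events += int(np.sum(clipped != p))
            if config.noise_scale > 0:
                cov[i] = rng.negative_binomial(nb_n, nb_p, size=n_bins)
                mc[i] = rng.binomial(cov[i], clipped)
            else:
                cov[i] = int(round(mean))
                mc[i] = np.rint(cov[i] * clipped).astype(np.int32)
        data[context] = (mc, cov)
    counts = MethylBinCounts(cells=meta.index, bins=bins, data=data)
    counts.clip_events = clip_events  # type: ignore[attr-defined]
    return counts


# ---------------------------------------------------------------------------
# contacts


def contact_bins(config: SimConfig) -> pd.DataFrame:
    """0-based half-open contact bin table over all chromosomes."""
    frames = []
    for chrom, length in config.chrom_lengths.items():
        starts = np.arange(0, length, config.bin_size_contact)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": np.minimum(starts + config.bin_size_contact, length),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _truncated_power_law(
    rng: np.random.Generator, n: int, alpha: float, dmin: float, dmax: float
) -> np.ndarray:
    """Contact distances with density f(d) ~ d^-alpha on [dmin, dmax].

    ``alpha`` is the contact-probability decay exponent (P(s) convention);
    larger alpha concentrates contacts at short range. alpha = 1 is the
    log-uniform special case.
    """
    u = rng.random(n)
    if abs(alpha - 1.0) < 1e-12:
        return dmin * np.exp(u * np.log(dmax / dmin))
    e = 1.0 - alpha
    return (dmin**e + u * (dmax**e - dmin**e)) ** (1.0 / e)


def simulate_contacts(
    meta: pd.DataFrame, truth: SimTruth, config: SimConfig
) -> pd.DataFrame:
    """Generate one contact list for the whole cohort.

    Returns a DataFrame with columns (cell_id, chrom1, pos1, chrom2, pos2);
    exactly ``contacts_per_cell`` rows per cell (conservation). Cis distances
    follow the decay-class power law, a ``p_tad`` fraction of cis contacts is
    resampled within the anchor's TAD block and a ``p_compartment`` fraction
    within same-parity compartment blocks (checkerboard). For Stressed cells
    any contact touching a planted deleted bin is resampled until clean.

    Randomness is drawn per (donor, region) sample batch from a substream
    keyed by the stable hash of the sample id, vectorized across the
    sample's cells; cell order within a sample is deterministic, so outputs
    are byte-identical for identical configurations.
    """
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=np.int64)
    chrom_p = lengths / lengths.sum()
    bs = config.bin_size_contact
    deleted_by_chrom = {
        ci: np.array(
            sorted(b for cc, b in truth.deleted_bins if cc == chroms[ci]),
            dtype=np.int64,
        )
        for ci in range(len(chroms))
    }
    any_deleted = any(v.size for v in deleted_by_chrom.values())
    exp_short, exp_long = config.decay_exponents
    n = config.contacts_per_cell

    sample_key = meta["donor"].astype(str) + "|" + meta["region"].astype(str)
    cell_out, c1_out, p1_out, c2_out, p2_out = [], [], [], [], []
    for skey in pd.unique(sample_key):
        cells = meta.index[(sample_key == skey).to_numpy()]
        rng = _cell_rng(config, str(skey), "contacts")
        N = n * len(cells)
        row_cell = np.repeat(np.arange(len(cells)), n)
        alpha = np.where(
            truth.decay_class.loc[cells].to_numpy() == "Short", exp_short, exp_long
        )[row_cell]
        stressed_row = (truth.state.loc[cells].to_numpy() == STRESSED)[row_cell]

        is_trans = (
            rng.random(N) < config.trans_fraction
            if len(chroms) > 1
            else np.zeros(N, dtype=bool)
        )
        ci1 = rng.choice(len(chroms), size=N, p=chrom_p)
        L1 = lengths[ci1]
        pos1 = (rng.random(N) * L1).astype(np.int64)

        # cis partner: truncated power-law distance with per-row exponent
        u = rng.random(N)
        e = 1.0 - alpha
        with np.errstate(invalid="ignore"):
            d = (
                config.min_contact_distance**e
                + u * (float(lengths.max()) ** e - config.min_contact_distance**e)
            ) ** (1.0 / e)
        log_case = np.abs(alpha - 1.0) < 1e-12
        if log_case.any():
            d[log_case] = config.min_contact_distance * np.exp(
                u[log_case] * np.log(lengths.max() / config.min_contact_distance)
            )
        d = np.minimum(d.astype(np.int64), L1 - 1)
        right_ok = pos1 + d < L1
        left_ok = pos1 - d >= 0
        go_right = (right_ok & (rng.random(N) < 0.5)) | ~left_ok
        pos2 = np.clip(pos1 + np.where(go_right & right_ok, d, -d), 0, L1 - 1)

        ue = rng.random(N)
        in_tad = np.flatnonzero(ue < config.p_tad)
        in_comp = np.flatnonzero(
            (ue >= config.p_tad) & (ue < config.p_tad + config.p_compartment)
        )
        t0 = (pos1[in_tad] // config.tad_size) * config.tad_size
        t1 = np.minimum(t0 + config.tad_size, L1[in_tad])
        pos2[in_tad] = t0 + (rng.random(len(in_tad)) * (t1 - t0)).astype(np.int64)
        pos2[in_comp] = _compartment_resample_vec(
            rng, pos1[in_comp], L1[in_comp], config.compartment_block
        )

        # trans partner: uniform on a different chromosome
        ci2 = ci1.copy()
        if len(chroms) > 1:
            tr = np.flatnonzero(is_trans)
            tj = (ci1[tr] + rng.integers(1, len(chroms), size=len(tr))) % len(chroms)
            ci2[tr] = tj
            pos2[tr] = (rng.random(len(tr)) * lengths[tj]).astype(np.int64)

        if any_deleted and stressed_row.any():
            # global sorted key (chrom index, bin) for deleted bins
            nb_max = int(lengths.max() // bs + 2)
            del_keys = np.sort(
                np.concatenate(
                    [ci * nb_max + dels for ci, dels in deleted_by_chrom.items()]
                )
            )
            srows = np.flatnonzero(stressed_row)
            for _ in range(64):
                bad1 = _in_sorted(ci1[srows] * nb_max + pos1[srows] // bs, del_keys)
                bad2 = _in_sorted(ci2[srows] * nb_max + pos2[srows] // bs, del_keys)
                if not (bad1.any() or bad2.any()):
                    break
                r1 = srows[bad1]
                pos1[r1] = (rng.random(len(r1)) * lengths[ci1[r1]]).astype(np.int64)
                r2 = srows[bad2]
                pos2[r2] = (rng.random(len(r2)) * lengths[ci2[r2]]).astype(np.int64)

        cell_out.append(np.asarray(cells)[row_cell])
        c1_out.append(ci1)
        p1_out.append(pos1)
        c2_out.append(ci2)
        p2_out.append(pos2)
    chrom_cat = pd.CategoricalDtype(categories=chroms)
    return pd.DataFrame(
        {
            "cell_id": pd.Categorical(
                np.concatenate(cell_out), categories=list(meta.index)
            ),
            "chrom1": pd.Categorical.from_codes(
                np.concatenate(c1_out), dtype=chrom_cat
            ),
            "pos1": np.concatenate(p1_out),
            "chrom2": pd.Categorical.from_codes(
                np.concatenate(c2_out), dtype=chrom_cat
            ),
            "pos2": np.concatenate(p2_out),
        }
    )


def _in_sorted(values: np.ndarray, sorted_arr: np.ndarray) -> np.ndarray:
    """Membership of ``values`` in a sorted integer array via searchsorted."""
    idx = np.searchsorted(sorted_arr, values)
    idx = np.minimum(idx, len(sorted_arr) - 1)
    return sorted_arr[idx] == values


def _compartment_resample_vec(
    rng: np.random.Generator, pos1: np.ndarray, lengths: np.ndarray, block: int
) -> np.ndarray:
    """Uniform positions in a random block of the same A/B parity as pos1,
    with per-row chromosome lengths."""
    n_blocks = np.ceil(lengths / block).astype(np.int64)
    parity = (pos1 // block) % 2
    k = (rng.random(len(pos1)) * ((n_blocks + 1) // 2)).astype(np.int64)
    b = np.minimum(2 * k + parity, n_blocks - 1)
    lo = b * block
    hi = np.minimum(lo + block, lengths)
    return lo + (rng.random(len(pos1)) * (hi - lo)).astype(np.int64)


def simulate_shared_libraries(
    meta: pd.DataFrame,
    truth: SimTruth,
    config: SimConfig,
    n_libraries: int = 12,
    measurement_noise: float = 0.002,
) -> pd.DataFrame:
    """Paired global-methylation measurements of shared libraries.

    Emulates sequencing the same library on both instruments: for
    ``n_libraries`` (donor, region) samples, the library's true mean CG/CH
    level (average planted probability over its cells) is measured once on
    instrument A (identity) and once on instrument B (through the affine
    batch relation), each with small measurement noise. Columns:
    ``CG_a, CG_b, CH_a, CH_b`` — the calibration input of
    :func:`epistate3c.cell_states.normalize_instruments`.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5A1]))
    sample_key = meta["donor"].astype(str) + "|" + meta["region"].astype(str)
    samples = sorted(sample_key.unique())[:n_libraries]
    rows = []
    for s in samples:
        cells = meta.index[(sample_key == s).to_numpy()]
        rec = {}
        for ctx in ("CG", "CH"):
            p = expected_methylation_probability(meta.loc[cells], truth, config, ctx)
            true_level = float(np.mean(p))
            rec[f"{ctx}_a"] = true_level + rng.normal(0, measurement_noise)
            rec[f"{ctx}_b"] = (
                config.batch_offset
                + config.batch_slope * true_level
                + rng.normal(0, measurement_noise)
            )
        rows.append(rec)
    return pd.DataFrame(rows)


def gc_track(config: SimConfig) -> dict[str, np.ndarray]:
    """Per-contact-bin GC fraction aligned with the planted compartments.

    Even-parity compartment blocks (the "A" checkerboard phase used by the
    contact generator) are GC-rich, matching the sign convention that A
    compartments carry positive PC1. Deterministic given the seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x6C]))
    out = {}
    for chrom, length in config.chrom_lengths.items():
        starts = np.arange(0, length, config.bin_size_contact)
        parity = (starts // config.compartment_block) % 2
        out[chrom] = 0.38 + 0.08 * (parity == 0) + rng.normal(0, 0.005, len(starts))
    return out


# ---------------------------------------------------------------------------
# boundary calls


def boundary_bins(config: SimConfig) -> pd.DataFrame:
    """0-based half-open 25-kb boundary bin table over all chromosomes."""
    frames = []
    for chrom, length in config.chrom_lengths.items():
        starts = np.arange(0, length, config.bin_size_boundary)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": np.minimum(starts + config.bin_size_boundary, length),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_boundary_calls(
    truth: SimTruth, config: SimConfig
) -> tuple[np.ndarray, pd.DataFrame]:
    """Binary cells x 25-kb-bin boundary-call matrix plus the bin table.

    Each cell's calls are the planted boundary set, with each planted
    boundary dropped at ``boundary_miss_rate``, jittered by one bin at
    ``boundary_jitter_rate``, plus Bernoulli extra boundaries per bin at
    ``extra_boundary_rate`` (``stressed_extra_boundary_rate`` for Stressed
    cells). With all rates 0 every cell carries exactly the planted set.
    """
    if not truth.boundary_positions:
        raise ConfigurationError("boundary_positions: no planted boundaries")
    bins = boundary_bins(config)
    offsets = {}
    off = 0
    for chrom, length in config.chrom_lengths.items():
        offsets[chrom] = off
        off += int(np.ceil(length / config.bin_size_boundary))
    n_bins = off
    planted = np.concatenate(
        [offsets[c] + v for c, v in truth.boundary_positions.items()]
    ).astype(int)
    cells = truth.state.index
    calls = np.zeros((len(cells), n_bins), dtype=np.int8)
    for i, cell in enumerate(cells):
        rng = _cell_rng(config, cell, "boundaries")
        keep = planted.copy()
        if config.boundary_miss_rate > 0:
            keep = keep[rng.random(len(keep)) >= config.boundary_miss_rate]
        if config.boundary_jitter_rate > 0 and len(keep):
            jit = rng.random(len(keep)) < config.boundary_jitter_rate
            shift = rng.choice([-1, 1], size=len(keep))
            keep = np.clip(keep + jit * shift, 0, n_bins - 1)
        calls[i, keep.astype(int)] = 1
        rate = (
            config.stressed_extra_boundary_rate
            if truth.state.loc[cell] == STRESSED
            else config.extra_boundary_rate
        )
        if rate > 0:
            extra = rng.random(n_bins) < rate
            calls[i, extra] = 1
    return calls, bins


# ---------------------------------------------------------------------------
# log2FC tensor


def parse_comparison(name: str) -> tuple[str, str, str]:
    """Parse ``celltype:A_vs_B`` into (celltype, A, B)."""
    if ":" not in name or "_vs_" not in name:
        raise ValueError(f"comparison name {name!r} is not 'celltype:A_vs_B'")
    celltype, rest = name.split(":", 1)
    a, b = rest.split("_vs_", 1)
    if not (celltype and a and b):
        raise ValueError(f"comparison name {name!r} is not 'celltype:A_vs_B'")
    return celltype, a, b


def simulate_log2fc_tensor(
    subtypes: Sequence[str],
    planted_clusters: Mapping[str, str],
    config: SimConfig,
) -> pd.DataFrame:
    """Genes x pairwise-comparison log2FC table with planted block structure.

    ``subtypes`` are ``celltype:Subtype`` ids; ``planted_clusters`` maps each
    subtype to one of two cluster labels. Columns are ``celltype:A_vs_B`` for
    every ordered within-cell-type pair (A before B); between-cluster columns
    carry a per-gene signed effect of magnitude ``log2fc_delta`` and
    within-cluster columns are pure Gaussian noise of scale ``log2fc_noise``.
    """
    if len(subtypes) < 2:
        raise ConfigurationError("need at least 2 subtypes")
    for s in subtypes:
        if s not in planted_clusters:
            raise ConfigurationError(f"subtype {s!r} missing from planted_clusters")
    labels = sorted(set(planted_clusters[s] for s in subtypes))
    sign_of = {lab: (1.0 if i == 0 else -1.0) for i, lab in enumerate(labels)}
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x10F]))
    genes = [f"gene{i:04d}" for i in range(config.n_genes)]
    gene_sign = rng.choice([-1.0, 1.0], size=config.n_genes)

    by_ct: dict[str, list[str]] = {}
    for s in subtypes:
        ct, name = s.split(":", 1)
        by_ct.setdefault(ct, []).append(name)
    cols: dict[str, np.ndarray] = {}
    for ct, names in by_ct.items():
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a, b = names[i], names[j]
                col = f"{ct}:{a}_vs_{b}"
                if col in cols:
                    raise ConfigurationError(f"duplicate comparison name {col!r}")
                ma = sign_of[planted_clusters[f"{ct}:{a}"]]
                mb = sign_of[planted_clusters[f"{ct}:{b}"]]
                effect = 0.5 * config.log2fc_delta * (ma - mb) * gene_sign
                cols[col] = effect + rng.normal(0.0, config.log2fc_noise, config.n_genes)
    return pd.DataFrame(cols, index=genes)


# ---------------------------------------------------------------------------
# writers


def write_metadata_tsv(meta: pd.DataFrame, path) -> None:
    cols = ["donor", "region", "disease", "sex", "age", "instrument", "cell_type"]
    extra = [c for c in meta.columns if c not in cols]
    meta[cols + extra].to_csv(path, sep="\t", index=True, index_label="cell_id")


def write_pairs_tsv(contacts: pd.DataFrame, path) -> None:
    """4DN pairs-like plain TSV: readID, chr1, pos1, chr2, pos2 (+ cell_id)."""
    out = contacts.copy()
    out.insert(0, "readID", [f"r{i}" for i in range(len(out))])
    out.to_csv(path, sep="\t", index=False,
               columns=["readID", "chrom1", "pos1", "chrom2", "pos2", "cell_id"])
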