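"""Cohort generator: planted truth, determinism, conservation, moments."""

import io
import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epistate3c import synthetic_data as sd


class TestCohort:
    def test_default_cohort_is_60_samples(self):
        cfg = sd.SimConfig(seed=0, cells_per_sample=1)
        meta, truth = sd.simulate_cohort(cfg)
        samples = meta.groupby(["donor", "region"]).size()
        assert len(samples) == (11 + 9) * 3 == 60
        assert set(meta["region"]) == {"VC", "PFC", "TC"}
        assert meta.loc[meta["disease"] == "AD", "donor"].nunique() == 11
        assert meta.loc[meta["disease"] == "Control", "donor"].nunique() == 9

    def test_empty_cohort_rejected_naming_field(self):
        with pytest.raises(sd.ConfigurationError, match="cells_per_sample"):
            sd.SimConfig(cells_per_sample=0)

    def test_invalid_centromere_named(self):
        with pytest.raises(sd.ConfigurationError, match="centromeres"):
            sd.SimConfig(chrom_lengths={"chr1": 1000}, centromeres={"chr1": 2000})

    def test_metadata_byte_identical_across_runs(self, small_config):
        bufs = []
        for _ in range(2):
            meta, _ = sd.simulate_cohort(small_config)
            buf = io.StringIO()
            sd.write_metadata_tsv(meta, buf)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]

    def test_truth_labels_cover_every_cell_once(self, small_cohort):
        meta, truth = small_cohort
        assert truth.subgroup.index.equals(meta.index)
        assert not truth.state.index.has_duplicates
        assert set(truth.state) <= {"Homeostatic", "Stressed"}

    def test_truth_json_round_trip(self, small_cohort, tmp_path):
        _, truth = small_cohort
        truth.to_json(tmp_path / "truth.json")
        back = sd.SimTruth.from_json(tmp_path / "truth.json")
        assert back.deleted_bins == truth.deleted_bins
        assert back.state.sort_index().equals(truth.state.sort_index())
        assert back.batch_slope == truth.batch_slope


class TestMethylome:
    def test_no_noise_degenerate_fractions_equal_baseline(self):
        cfg = sd.SimConfig(
            seed=3, n_ad_donors=1, n_control_donors=1, cells_per_sample=4,
            noise_scale=0.0, batch_offset=0.0, batch_slope=1.0,
            region_effect={}, subgroup_cg_offsets=(0, 0, 0),
            subgroup_ch_offsets=(0, 0, 0),
        )
        meta, truth = sd.simulate_cohort(cfg)
        counts = sd.simulate_methylome(meta, truth, cfg)
        mc, cov = counts.data["CG"]
        frac = mc[cov > 0] / cov[cov > 0]
        assert np.allclose(frac, cfg.baseline_cg)

    def test_planted_tc_ad_shift_recovered_within_binomial_error(self):
        """+0.05 CG shift in TC-AD appears in the mean fraction difference
        within 3 binomial standard errors."""
        uniform = {
            (r, d): (1 / 3, 1 / 3, 1 / 3)
            for r in ("VC", "PFC", "TC") for d in ("AD", "Control")
        }
        cfg = sd.SimConfig(
            seed=4, n_ad_donors=4, n_control_donors=4, cells_per_sample=30,
            region_effect={("TC", "AD"): 0.05}, subgroup_proportions=uniform,
            subgroup_cg_offsets=(0, 0, 0), batch_offset=0.0, batch_slope=1.0,
            noise_scale=0.01,
        )
        meta, truth = sd.simulate_cohort(cfg)
        counts = sd.simulate_methylome(meta, truth, cfg)
        mc, cov = counts.data["CG"]
        frac = np.where(cov > 0, mc / np.maximum(cov, 1), np.nan)
        cell_frac = np.nanmean(frac, axis=1)
        tc = meta["region"] == "TC"
        ad = meta["disease"] == "AD"
        diff = cell_frac[(tc & ad).to_numpy()].mean() - cell_frac[
            (tc & ~ad).to_numpy()
        ].mean()
        n_cells = int((tc & ad).sum())
        # binomial moment oracle: per-cell fraction variance ~ p(1-p)/(B*cov)
        # plus the per-cell jitter variance
        p = cfg.baseline_cg
        var_cell = p * (1 - p) / (counts.n_bins * cfg.methyl_coverage_mean) + (
            cfg.noise_scale**2
        )
        se = np.sqrt(2 * var_cell / n_cells)
        assert abs(diff - 0.05) < 3 * se

    def test_subgroup_counts_within_multinomial_bounds(self):
        props = (0.2, 0.5, 0.3)
        cfg = sd.SimConfig(
            seed=9, n_ad_donors=2, n_control_donors=2, cells_per_sample=100,
            subgroup_proportions={
                (r, d): props for r in ("VC", "PFC", "TC") for d in ("AD", "Control")
            },
        )
        meta, truth = sd.simulate_cohort(cfg)
        n = len(meta)
        counts = truth.subgroup.value_counts()
        for g, p in enumerate(props):
            lo, hi = stats.binom.ppf([0.005, 0.995], n, p)
            assert lo <= counts[g] <= hi


class TestContacts:
    def test_conservation_exact_depth(self, small_config, small_cohort, small_contacts):
        meta, _ = small_cohort
        per_cell = small_contacts["cell_id"].value_counts()
        assert per_cell.min() == per_cell.max() == small_config.contacts_per_cell
        assert len(per_cell) == len(meta)

    def test_no_deletions_means_no_empty_bins(self):
        cfg = sd.SimConfig(
            seed=6, n_ad_donors=2, n_control_donors=2, cells_per_sample=40,
            n_deleted_bins=0,
        )
        meta, truth = sd.simulate_cohort(cfg)
        contacts = sd.simulate_contacts(meta, truth, cfg)
        bs = cfg.bin_size_contact
        for chrom, length in cfg.chrom_lengths.items():
            nb = int(np.ceil(length / bs))
            cis = contacts[(contacts["chrom1"] == chrom)]
            occupancy = np.bincount(
                np.minimum(cis["pos1"].to_numpy() // bs, nb - 1), minlength=nb
            )
            assert occupancy.min() > 0

    def test_planted_deletion_has_zero_stressed_coverage(
        self, small_config, small_cohort, small_contacts
    ):
        meta, truth = small_cohort
        stressed = truth.state[truth.state == "Stressed"].index
        sub = small_contacts[small_contacts["cell_id"].isin(set(stressed))]
        bs = small_config.bin_size_contact
        for chrom, b in truth.deleted_bins:
            for anchor in ("1", "2"):
                hits = sub[
                    (sub[f"chrom{anchor}"] == chrom)
                    & (sub[f"pos{anchor}"] // bs == b)
                ]
                assert len(hits) == 0

    def test_equal_exponents_smoke(self):
        cfg = sd.SimConfig(
            seed=7, n_ad_donors=1, n_control_donors=1, cells_per_sample=10,
            decay_exponents=(1.2, 1.2),
        )
        meta, truth = sd.simulate_cohort(cfg)
        contacts = sd.simulate_contacts(meta, truth, cfg)
        assert len(contacts) == len(meta) * cfg.contacts_per_cell

    def test_deterministic(self, small_config, small_cohort, small_contacts):
        meta, truth = small_cohort
        again = sd.simulate_contacts(meta, truth, small_config)
        assert small_contacts.equals(again)


class TestBoundaryCalls:
    def test_zero_rates_reproduce_planted_set(self, small_cohort):
        meta, truth = small_cohort
        cfg = sd.SimConfig(
            seed=11, n_ad_donors=3, n_control_donors=2, cells_per_sample=30,
            boundary_miss_rate=0.0, boundary_jitter_rate=0.0,
            extra_boundary_rate=0.0, stressed_extra_boundary_rate=0.0,
        )
        calls, bins = sd.simulate_boundary_calls(truth, cfg)
        assert (calls == calls[0]).all()
        expected = sum(len(v) for v in truth.boundary_positions.values())
        assert calls[0].sum() == expected

    def test_extra_rate_within_poisson_bounds(self, small_cohort):
        meta, truth = small_cohort
        rate = 0.01
        cfg = sd.SimConfig(
            seed=11, n_ad_donors=3, n_control_donors=2, cells_per_sample=30,
            boundary_miss_rate=0.0, boundary_jitter_rate=0.0,
            extra_boundary_rate=rate, stressed_extra_boundary_rate=rate,
        )
        calls, bins = sd.simulate_boundary_calls(truth, cfg)
        planted = sum(len(v) for v in truth.boundary_positions.values())
        extras = calls.sum(axis=1) - planted
        lam = rate * (calls.shape[1] - planted)
        total = extras.sum()
        n = len(extras)
        lo, hi = stats.poisson.ppf([0.001, 0.999], lam * n)
        assert lo <= total <= hi

    def test_stressed_extra_rate_raises_mean_count(self, small_cohort):
        meta, truth = small_cohort
        cfg = sd.SimConfig(
            seed=11, n_ad_donors=3, n_control_donors=2, cells_per_sample=30,
            extra_boundary_rate=0.002, stressed_extra_boundary_rate=0.02,
        )
        calls, _ = sd.simulate_boundary_calls(truth, cfg)
        per_cell = calls.sum(axis=1)
        stressed = (truth.state == "Stressed").to_numpy()
        assert per_cell[stressed].mean() > per_cell[~stressed].mean()


class TestLog2FCTensor:
    def test_column_name_round_trip(self):
        ct, a, b = sd.parse_comparison("Exc:g0_vs_g1")
        assert (ct, a, b) == ("Exc", "g0", "g1")
        with pytest.raises(ValueError):
            sd.parse_comparison("no-separator")

    def test_planted_block_structure(self):
        cfg = sd.SimConfig(seed=0, n_genes=100, log2fc_delta=2.0, log2fc_noise=0.1)
        subtypes = ["Exc:a", "Exc:b", "ODC:a", "ODC:b"]
        clusters = {"Exc:a": "X", "ODC:a": "X", "Exc:b": "Y", "ODC:b": "Y"}
        fc = sd.simulate_log2fc_tensor(subtypes, clusters, cfg)
        between = fc["Exc:a_vs_b"].abs().mean()
        assert between == pytest.approx(2.0, rel=0.1)

    def test_duplicate_and_missing_subtype_rejected(self):
        cfg = sd.SimConfig(seed=0)
        with pytest.raises(sd.ConfigurationError, match="planted_clusters"):
            sd.simulate_log2fc_tensor(["A:x", "A:y"], {"A:x": "c"}, cfg)
        with pytest.raises(sd.ConfigurationError):
            sd.simulate_log2fc_tensor(["A:x"], {"A:x": "c"}, cfg)
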