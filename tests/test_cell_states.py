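"""Instrument normalization, CG/CH subgroups, state labels, subtype clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from epistate3c import cell_states as cs
from epistate3c import synthetic_data as sd


def _levels_meta(cg, ch, instrument, cell_type="Exc"):
    idx = pd.Index([f"c{i}" for i in range(len(cg))])
    levels = pd.DataFrame({"CG": cg, "CH": ch}, index=idx)
    meta = pd.DataFrame(
        {"instrument": instrument, "cell_type": cell_type}, index=idx
    )
    return levels, meta


class TestNormalizeInstruments:
    def test_identity_relation_leaves_levels_unchanged(self):
        levels, meta = _levels_meta(
            [0.7, 0.8], [0.05, 0.06], ["NovaSeq6000", "NovaSeqX"]
        )
        shared = pd.DataFrame(
            {"CG_a": [0.7, 0.8], "CG_b": [0.7, 0.8],
             "CH_a": [0.04, 0.06], "CH_b": [0.04, 0.06]}
        )
        out = cs.normalize_instruments(levels, meta, shared)
        assert np.allclose(out.to_numpy(), levels.to_numpy(), atol=1e-10)

    def test_planted_affine_relation_inverted_exactly(self):
        """y = 0.02 + 0.96 x recovered from a noiseless two-point pairing;
        cross-instrument group means agree after normalization."""
        true = np.array([0.70, 0.80, 0.70, 0.80])
        measured = true.copy()
        measured[2:] = 0.02 + 0.96 * true[2:]
        levels, meta = _levels_meta(
            measured, [0.05] * 4,
            ["NovaSeq6000", "NovaSeq6000", "NovaSeqX", "NovaSeqX"],
        )
        shared = pd.DataFrame(
            {
                "CG_a": [0.6, 0.9], "CG_b": 0.02 + 0.96 * np.array([0.6, 0.9]),
                "CH_a": [0.04, 0.08], "CH_b": 0.02 + 0.96 * np.array([0.04, 0.08]),
            }
        )
        out = cs.normalize_instruments(levels, meta, shared)
        assert np.allclose(out["CG"].to_numpy(), true, atol=1e-10)

    def test_single_instrument_is_identity_without_pairing(self):
        levels, meta = _levels_meta([0.7, 0.75], [0.05, 0.04], ["NovaSeq6000"] * 2)
        out = cs.normalize_instruments(levels, meta, None)
        assert out.equals(levels.astype(float))

    def test_degenerate_pairing_warns_identity(self):
        levels, meta = _levels_meta([0.7, 0.75], [0.05, 0.04], ["NovaSeqX"] * 2)
        shared = pd.DataFrame(
            {"CG_a": [0.7, 0.7], "CG_b": [0.8, 0.8],
             "CH_a": [0.05, 0.05], "CH_b": [0.05, 0.05]}
        )
        with pytest.warns(UserWarning, match="identity"):
            out = cs.normalize_instruments(levels, meta, shared)
        assert np.allclose(out.to_numpy(), levels.to_numpy())


class TestKmeansSubgroups:
    def test_semantic_relabel_on_canonical_configuration(self):
        """Clouds at (0,0), (1,0), (1,1) map to subgroups 0, 1, 2."""
        rng = np.random.default_rng(0)
        centers = [(0, 0), (1, 0), (1, 1)]
        pts, lab = [], []
        for g, (cx, cy) in enumerate(centers):
            pts.append(np.column_stack([
                rng.normal(cx, 0.01, 50), rng.normal(cy, 0.01, 50)
            ]))
            lab += [g] * 50
        X = np.vstack(pts)
        levels = pd.DataFrame(X, columns=["CG", "CH"],
                              index=[f"c{i}" for i in range(len(X))])
        meta = pd.DataFrame({"cell_type": "Exc"}, index=levels.index)
        out = cs.kmeans_subgroups(levels, meta, seed=0)
        assert (out["subgroup"].to_numpy() == np.array(lab)).all()

    def test_five_sigma_mixture_recovery(self):
        """>= 99% label recovery on a 5-sigma-separated planted mixture."""
        rng = np.random.default_rng(1)
        sigma = 0.01
        centers = [(0.66, 0.04), (0.66 + 5 * sigma * 5, 0.04), (0.91, 0.04 + 25 * sigma)]
        # centers separated by >= 5 sigma in at least one axis
        centers = [(0.66, 0.04), (0.80, 0.04), (0.80, 0.10)]
        pts, lab = [], []
        for g, (cx, cy) in enumerate(centers):
            n = 400
            pts.append(np.column_stack([
                rng.normal(cx, sigma, n), rng.normal(cy, sigma, n)
            ]))
            lab += [g] * n
        X = np.vstack(pts)
        levels = pd.DataFrame(X, columns=["CG", "CH"],
                              index=[f"c{i}" for i in range(len(X))])
        meta = pd.DataFrame({"cell_type": "ODC"}, index=levels.index)
        out = cs.kmeans_subgroups(levels, meta, seed=0)
        assert (out["subgroup"].to_numpy() == np.array(lab)).mean() >= 0.99

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        levels = pd.DataFrame(
            rng.random((60, 2)), columns=["CG", "CH"],
            index=[f"c{i}" for i in range(60)],
        )
        meta = pd.DataFrame({"cell_type": "Exc"}, index=levels.index)
        a = cs.kmeans_subgroups(levels, meta, seed=7)
        b = cs.kmeans_subgroups(levels, meta, seed=7)
        assert (a["subgroup"] == b["subgroup"]).all()

    def test_small_stratum_skipped_with_warning(self):
        levels, meta = _levels_meta([0.7, 0.8], [0.05, 0.06], ["A", "A"])
        with pytest.warns(UserWarning, match="skipped"):
            out = cs.kmeans_subgroups(levels, meta, seed=0)
        assert len(out) == 0


class TestRatioAssociation:
    def _cohort(self, shift=0.15, seed=0):
        cfg = sd.SimConfig(
            seed=seed, n_ad_donors=6, n_control_donors=6, cells_per_sample=150,
            cell_types=("Exc",), cell_type_proportions=(1.0,),
            subgroup_proportions={
                (r, d): (0.3, 0.5, 0.2)
                for r in ("VC", "PFC", "TC") for d in ("AD", "Control")
            }
            | {("TC", "AD"): (0.3 - shift / 2, 0.5 + shift, 0.2 - shift / 2)},
        )
        meta, truth = sd.simulate_cohort(cfg)
        assignments = pd.DataFrame({"subgroup": truth.subgroup}, index=meta.index)
        return assignments, meta

    def test_planted_tc_shift_recovered(self):
        assignments, meta = self._cohort()
        assoc = cs.subgroup_ratio_association(assignments, meta)
        row = assoc.table.loc["Exc:subgroup1"]
        assert row["disease[AD]:region[TC]_coef"] > 0
        assert row["disease[AD]:region[TC]_p"] < 0.05

    def test_few_donors_skipped(self):
        assignments, meta = self._cohort()
        keep_donors = ["AD01", "AD02", "CT01", "CT02"]
        m = meta[meta["donor"].isin(keep_donors)]
        a = assignments.loc[m.index]
        assoc = cs.subgroup_ratio_association(a, m)
        assert (assoc.table["status"] == "skipped_min_donors").all()


class TestStateLabels:
    @pytest.mark.parametrize(
        "s,h,expected",
        [
            (3.0, 2.6, "DP"),
            (-3.0, -2.6, "DN"),
            (0.0, 0.0, "Sneu_Hneu"),
            (-3.0, 2.6, "Sneg_Hpos"),
            (2.5, 0.0, "Spos_Hneu"),
            (2.4999, 2.5, "Sneu_Hpos"),
        ],
    )
    def test_grid(self, s, h, expected):
        assert cs.score_state_labels(s, h) == expected


class TestSubtypeSimilarity:
    def _planted(self, seed=0, delta=2.0, noise=0.1):
        cfg = sd.SimConfig(seed=seed, n_genes=120, log2fc_delta=delta,
                           log2fc_noise=noise)
        subtypes = ["Exc:a", "Exc:b", "ODC:a", "ODC:b"]
        clusters = {"Exc:a": "X", "ODC:a": "X", "Exc:b": "Y", "ODC:b": "Y"}
        return sd.simulate_log2fc_tensor(subtypes, clusters, cfg), clusters

    def test_planted_two_blocks_recovered_exactly(self):
        fc, clusters = self._planted()
        emb = cs.subtype_similarity_cluster(fc)
        truth = [clusters[s] for s in emb.clusters.index]
        assert adjusted_rand_score(truth, emb.clusters) == 1.0

    def test_brute_force_partition_confirms_separation(self):
        """The returned 2-cut maximizes between-cluster distance over all
        2-partitions (brute force on 4 subtypes)."""
        fc, clusters = self._planted()
        emb = cs.subtype_similarity_cluster(fc)
        D = emb.distance.to_numpy()
        names = emb.subtypes

        def partition_score(members):
            inside = [
                D[i, j]
                for i, j in itertools.combinations(range(len(names)), 2)
                if (i in members) == (j in members)
            ]
            across = [
                D[i, j]
                for i, j in itertools.combinations(range(len(names)), 2)
                if (i in members) != (j in members)
            ]
            return np.mean(across) - np.mean(inside)

        best = max(
            (frozenset(c) for c in itertools.combinations(range(len(names)), 2)),
            key=partition_score,
        )
        ours = frozenset(
            i for i, s in enumerate(names) if emb.clusters[s] == emb.clusters[names[0]]
        )
        assert ours in (best, frozenset(range(len(names))) - best)

    def test_similarity_symmetric_unit_diagonal(self):
        fc, _ = self._planted(seed=3)
        emb = cs.subtype_similarity_cluster(fc)
        K = emb.similarity.to_numpy()
        assert np.allclose(K, K.T, atol=1e-9)
        assert np.allclose(np.diag(K), 1.0, atol=1e-9)
        assert (emb.distance.to_numpy() >= -1e-9).all()

    def test_identical_profiles_cluster_together(self):
        # two subtypes with identical log2FC columns against all peers
        genes = [f"g{i}" for i in range(30)]
        rng = np.random.default_rng(0)
        v = rng.normal(size=30)
        w = rng.normal(size=30)
        fc = pd.DataFrame(
            {
                "Exc:a_vs_b": v, "Exc:a_vs_c": w, "Exc:b_vs_c": w,
            },
            index=genes,
        )
        emb = cs.subtype_similarity_cluster(fc, n_clusters=2)
        # a vs b small contrast? identical outgoing columns for a and b
        assert emb.similarity.loc["Exc:a", "Exc:b"] > 0.99 or (
            emb.clusters["Exc:a"] == emb.clusters["Exc:b"]
        )

    def test_invariant_to_subtype_input_order(self):
        fc, _ = self._planted(seed=5)
        emb1 = cs.subtype_similarity_cluster(fc)
        perm = list(fc.columns)[::-1]
        emb2 = cs.subtype_similarity_cluster(fc[perm])
        assert emb1.subtypes == emb2.subtypes
        assert adjusted_rand_score(emb1.clusters, emb2.clusters) == 1.0
        assert np.allclose(
            emb1.similarity.to_numpy(), emb2.similarity.to_numpy(), atol=1e-9
        )

    def test_unparseable_column_rejected(self):
        fc = pd.DataFrame({"badcolumn": [1.0, 2.0]})
        with pytest.raises(ValueError):
            cs.subtype_similarity_cluster(fc)
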