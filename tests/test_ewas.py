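"""Probewise regression, probe clustering and bump hunting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylstream import (
    StoreError,
    bumphunt,
    cluster_probes,
    ewas_probewise,
    find_bumps,
    simulate_dataset,
    write_bumps_bed,
)


def two_group_design(S):
    return pd.DataFrame({"group": np.tile([0.0, 1.0], S // 2)})


class TestProbewise:
    def test_matches_dense_regression_oracle(self):
        rng = np.random.default_rng(0)
        P, S = 200, 30
        Y = rng.uniform(0, 1, (P, S))
        design = pd.DataFrame(
            {"group": rng.normal(0, 1, S), "age": rng.uniform(20, 70, S)}
        )
        res = ewas_probewise(Y, design, "group", covariates=["age"])
        X = np.column_stack(
            [np.ones(S), design["group"], design["age"]]
        )
        for i in rng.choice(P, 20, replace=False):
            beta, rss, *_ = np.linalg.lstsq(X, Y[i], rcond=None)
            sigma2 = float(rss[0]) / (S - 3)
            se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
            assert res["effect"].iloc[i] == pytest.approx(beta[1], abs=1e-10)
            assert res["se"].iloc[i] == pytest.approx(se, abs=1e-10)
            t = beta[1] / se
            assert res["p"].iloc[i] == pytest.approx(
                2 * stats.t.sf(abs(t), S - 3), abs=1e-10
            )

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(1)
        Y = rng.uniform(0.2, 0.8, (2000, 60))
        res = ewas_probewise(Y, two_group_design(60), "group")
        ks = stats.kstest(res["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_spiked_probe_attains_minimum_p(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            Y = 0.5 + rng.normal(0, 0.02, (500, 60))
            design = two_group_design(60)
            Y[77] += 0.2 * design["group"].to_numpy()
            res = ewas_probewise(Y, design, "group")
            hits += int(res["p"].idxmin() == 77)
        assert hits == 10

    def test_block_and_worker_invariance(self, small_ds, store_factory):
        store = store_factory(small_ds)
        design = store.sample_index.copy()
        design["group"] = design["group"].astype(float)
        ref = ewas_probewise(store, design, "group", rows_per_block=None)
        for rpb, nw in [(17, 1), (400, 4), (1, 1)]:
            got = ewas_probewise(
                store, design, "group", rows_per_block=rpb, n_workers=nw
            )
            pd.testing.assert_frame_equal(got, ref)

    def test_nan_samples_dropped_probewise(self):
        rng = np.random.default_rng(2)
        Y = rng.uniform(0, 1, (10, 40))
        Y[3, :5] = np.nan
        res = ewas_probewise(Y, two_group_design(40), "group")
        assert res["n"].iloc[3] == 35
        # matches dense fit on the complete samples
        ok = ~np.isnan(Y[3])
        X = np.column_stack([np.ones(40), two_group_design(40)["group"]])[ok]
        beta = np.linalg.lstsq(X, Y[3, ok], rcond=None)[0]
        assert res["effect"].iloc[3] == pytest.approx(beta[1], abs=1e-10)

    def test_collinear_design_rejected(self):
        Y = np.random.default_rng(3).uniform(0, 1, (5, 20))
        d = two_group_design(20)
        d["twice"] = 2 * d["group"]
        with pytest.raises(StoreError, match="rank-deficient"):
            ewas_probewise(Y, d, "group", covariates=["twice"])

    def test_missing_target_rejected(self):
        Y = np.zeros((3, 10))
        with pytest.raises(StoreError, match="not in design"):
            ewas_probewise(Y, pd.DataFrame(index=range(10)), "group")

    def test_fdr_monotone_in_p(self):
        rng = np.random.default_rng(4)
        Y = rng.uniform(0, 1, (300, 30))
        res = ewas_probewise(Y, two_group_design(30), "group")
        srt = res.sort_values("p")
        assert (np.diff(srt["fdr"].to_numpy()) >= -1e-12).all()
        assert srt["fdr"].between(0, 1).all()


class TestClusterProbes:
    def manifest(self, positions, chrom=None):
        n = len(positions)
        return pd.DataFrame(
            {
                "probe_id": [f"p{i}" for i in range(n)],
                "design_type": ["II"] * n,
                "channel": ["Both"] * n,
                "chromosome": chrom or ["chr1"] * n,
                "position": positions,
                "is_control": [False] * n,
            }
        )

    def test_gap_rule(self):
        cl = cluster_probes(self.manifest([100, 200, 1_000_000]), max_gap=500)
        assert cl.tolist() == [1, 1, 2]

    def test_all_singletons_when_gaps_large(self):
        cl = cluster_probes(self.manifest([100, 10_000, 20_000]), max_gap=500)
        assert cl.tolist() == [1, 2, 3]

    def test_chromosome_split(self):
        cl = cluster_probes(
            self.manifest([100, 200, 100, 200],
                          chrom=["chr1", "chr1", "chr2", "chr2"]),
            max_gap=500,
        )
        assert cl.tolist() == [1, 1, 2, 2]

    def test_matches_transitive_closure_oracle(self):
        rng = np.random.default_rng(5)
        pos = np.sort(rng.integers(1, 100_000, 120))
        man = self.manifest(pos.tolist())
        got = cluster_probes(man, max_gap=300)
        # oracle: union-find by explicit pairwise adjacency
        parent = list(range(len(pos)))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                if abs(int(pos[j]) - int(pos[i])) <= 300:
                    parent[find(j)] = find(i)
        roots = [find(i) for i in range(len(pos))]
        # same partition?
        from collections import defaultdict

        mine, theirs = defaultdict(set), defaultdict(set)
        for i, (a, b) in enumerate(zip(got.tolist(), roots)):
            mine[a].add(i)
            theirs[b].add(i)
        assert sorted(map(sorted, mine.values())) == sorted(
            map(sorted, theirs.values())
        )

    def test_missing_positions_rejected(self):
        man = self.manifest([100, 200, 300])
        man.loc[1, "position"] = 0
        with pytest.raises(StoreError, match="positions"):
            cluster_probes(man)


class TestBumphunt:
    def test_zero_effects_give_zero_bumps(self):
        ds = simulate_dataset(P=200, S=20, seed=50)
        clusters = cluster_probes(ds.manifest)
        bumps = find_bumps(
            np.zeros(200), ds.manifest, clusters, cutoff=0.1
        )
        assert len(bumps) == 0

    def test_nonpositive_cutoff_rejected(self):
        ds = simulate_dataset(P=50, S=12, seed=51)
        with pytest.raises(StoreError, match="cutoff"):
            find_bumps(np.zeros(50), ds.manifest,
                       cluster_probes(ds.manifest), cutoff=0.0)

    def test_planted_dmr_recovered_with_significance(self):
        ds = simulate_dataset(
            P=600, S=60, seed=52, dmr_spec=[{"n_probes": 8, "delta": 0.3}]
        )
        design = ds.sample_sheet.copy()
        design["group"] = design["group"].astype(float)
        bumps = bumphunt(
            ds.betas.to_numpy(), design, "group", ds.manifest,
            cutoff=0.1, n_perm=100, seed=9,
        )
        truth = set(ds.truth.dmrs[0]["probe_ids"])
        top = set(bumps.iloc[0]["probe_ids"].split(";"))
        assert len(truth.symmetric_difference(top)) <= 1
        assert bumps.iloc[0]["fwer"] < 0.05
        assert bumps.iloc[0]["area"] > 0
        assert bumps.iloc[0]["L"] >= 7

    def test_permutation_p_includes_observed(self):
        ds = simulate_dataset(P=300, S=30, seed=53,
                              dmr_spec=[{"n_probes": 8, "delta": 0.4}])
        design = ds.sample_sheet.copy()
        design["group"] = design["group"].astype(float)
        bumps = bumphunt(
            ds.betas.to_numpy(), design, "group", ds.manifest,
            cutoff=0.1, n_perm=50, seed=1,
        )
        assert (bumps["p_value"] >= 1 / 51 - 1e-12).all()
        assert bumps["p_value"].between(0, 1).all()

    def test_translation_and_chromosome_relabel_invariance(self):
        ds = simulate_dataset(P=300, S=40, seed=54,
                              dmr_spec=[{"n_probes": 5, "delta": 0.3}])
        design = ds.sample_sheet.copy()
        design["group"] = design["group"].astype(float)

        def run(man):
            return bumphunt(ds.betas.to_numpy(), design, "group", man,
                            cutoff=0.1, n_perm=20, seed=2)

        base = run(ds.manifest)
        shifted = ds.manifest.copy()
        assay = ~shifted["is_control"]
        shifted.loc[assay, "position"] = shifted.loc[assay, "position"] + 10_000
        got = run(shifted)
        np.testing.assert_array_equal(
            got["start"].to_numpy() - 10_000, base["start"].to_numpy()
        )
        np.testing.assert_allclose(got["area"], base["area"], atol=1e-12)
        relabeled = ds.manifest.copy()
        relabeled["chromosome"] = relabeled["chromosome"].str.replace(
            "chr", "contig_"
        )
        got2 = run(relabeled)
        np.testing.assert_allclose(got2["area"], base["area"], atol=1e-12)

    def test_smoothing_span_edges(self):
        from methylstream.ewas import _smooth_cluster

        x = np.array([0.0, 0.0, 1.0, 0.0, 0.0])
        sm = _smooth_cluster(x, 3)
        np.testing.assert_allclose(sm, [0, 1 / 3, 1 / 3, 1 / 3, 0])
        # shorter than span: unsmoothed
        np.testing.assert_array_equal(_smooth_cluster(np.array([1.0, 2.0]), 3),
                                      [1.0, 2.0])

    def test_bed_output_halfopen_coordinates(self, tmp_path):
        bumps = pd.DataFrame(
            {
                "chromosome": ["chr2"],
                "start": [99],
                "end": [300],
                "probe_ids": ["a;b"],
                "L": [2],
                "area": [0.6],
                "value": [0.3],
                "cluster": [1],
                "p_value": [0.01],
                "fwer": [0.01],
            }
        )
        path = tmp_path / "b.bed"
        write_bumps_bed(bumps, path)
        chrom, start, end, name, score = path.read_text().split()
        assert (chrom, start, end, name) == ("chr2", "99", "300", "bump1")
        assert float(score) == pytest.approx(20.0)
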