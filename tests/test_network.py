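import math

import numpy as np
import pandas as pd
import pytest

from temporadt.data_model import ValidationError
from temporadt.network import (
    build_network,
    detect_modules,
    eigengene,
    hormone_crosstalk,
    hub_genes,
    intramodular_connectivity,
    module_trait_association,
    select_cutoff,
)


def _tom_bruteforce(adj: np.ndarray) -> np.ndarray:
    """Double-loop reference implementation of the TOM formula."""
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    n = len(a)
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            shared += a[i, i] * 0  # diagonal excluded by construction
            num = sum(a[i, u] * a[u, j] for u in range(n)) + a[i, j]
            tom[i, j] = num / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


class TestBuildNetwork:
    def test_perfectly_correlated_pair(self):
        x = np.arange(10.0)
        expr = pd.DataFrame([x, 2 * x + 1, -x + 3], index=["a", "b", "c"])
        adj, tom = build_network(expr, beta=6)
        assert adj.loc["a", "b"] == pytest.approx(1.0)
        assert tom.loc["a", "b"] == pytest.approx(1.0)

    def test_independent_genes_near_zero_adjacency(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(0, 1, (5, 2000)))
        adj, _ = build_network(expr, beta=6)
        off = adj.to_numpy()[np.triu_indices(5, 1)]
        assert (off < 1e-3).all()

    def test_three_gene_hand_case(self):
        # a12=a13=a23=0.5, beta=1: TOM12 = (0.25+0.5)/(1+1-0.5) = 0.5
        x = np.array(
            [[1.0, 0.5, 0.5], [0.5, 1.0, 0.5], [0.5, 0.5, 1.0]]
        )
        a = x.copy()
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        tom12 = (a[0] @ a[:, 1] + a[0, 1]) / (min(k[0], k[1]) + 1 - a[0, 1])
        assert tom12 == pytest.approx(0.5)

    def test_matches_bruteforce_on_random_instance(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.normal(0, 1, (15, 30)),
                            index=[f"g{i:02d}" for i in range(15)])
        adj, tom = build_network(expr, beta=6)
        ref = _tom_bruteforce(adj.to_numpy())
        assert np.allclose(tom.to_numpy(), ref, atol=1e-12)
        t = tom.to_numpy()
        assert np.allclose(t, t.T) and (t >= 0).all() and (t <= 1 + 1e-12).all()

    def test_constant_gene_excluded(self):
        expr = pd.DataFrame(
            [[1.0, 2, 3, 4], [2.0, 4, 6, 8], [5.0, 5, 5, 5], [1, 3, 2, 4.0]],
            index=list("abcd"),
        )
        with pytest.warns(UserWarning):
            adj, _ = build_network(expr)
        assert "c" not in adj.index

    def test_minimum_size_contract(self):
        with pytest.raises(ValidationError):
            build_network(pd.DataFrame(np.eye(2)))


class TestCutoffSelection:
    def _block_tom(self):
        # two 5-gene blocks: within-TOM 0.6, cross 0.05
        t = np.full((10, 10), 0.05)
        t[:5, :5] = 0.6
        t[5:, 5:] = 0.6
        np.fill_diagonal(t, 1.0)
        return pd.DataFrame(t, index=[f"g{i}" for i in range(10)],
                            columns=[f"g{i}" for i in range(10)])

    def test_density_matches_bruteforce(self):
        tom = self._block_tom()
        tau, scan = select_cutoff(tom)
        for _, row in scan.dropna().iterrows():
            t = tom.to_numpy()
            mask = t >= row["tau"]
            np.fill_diagonal(mask, False)
            retained = mask.any(axis=1)
            n_ret = retained.sum()
            e = mask.sum() // 2
            assert row["n_edges"] == e
            if n_ret >= 2:
                assert row["density"] == pytest.approx(2 * e / (n_ret * (n_ret - 1)))

    def test_tau_between_block_levels(self):
        tau, _ = select_cutoff(self._block_tom())
        assert 0.05 < tau <= 0.6

    def test_fixed_override_honored(self):
        tau, scan = select_cutoff(self._block_tom(), fixed=0.16)
        assert tau == 0.16
        assert len(scan) == 1

    def test_boundary_density_maximal_at_smallest_tau(self):
        tom = self._block_tom()
        _, scan = select_cutoff(tom)
        first = scan.dropna().iloc[0]["density"]
        assert first == scan.dropna()["density"].max()


class TestModules:
    def test_two_planted_blocks_recovered(self):
        from temporadt.simulate import two_block_network

        expr, blocks = two_block_network(n_per_block=40, n_samples=80,
                                         noise_sd=0.3, seed=0)
        adj, tom = build_network(expr)
        tau, _ = select_cutoff(tom)
        modules = detect_modules(tom, tau)
        # ARI = 1 expected on this clean fixture
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(blocks.to_numpy(), modules.to_numpy()) == 1.0

    def test_small_network_all_unassigned(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(0, 1, (10, 20)),
                            index=[f"g{i}" for i in range(10)])
        _, tom = build_network(expr)
        modules = detect_modules(tom, tau=0.9, min_size=30)
        assert (modules == "unassigned").all()

    def test_permutation_invariance(self):
        from temporadt.simulate import two_block_network

        expr, _ = two_block_network(n_per_block=20, n_samples=60, seed=2)
        _, tom = build_network(expr)
        tau, _ = select_cutoff(tom)
        a = detect_modules(tom, tau)
        perm = tom.sample(frac=1, random_state=5).index
        b = detect_modules(tom.loc[perm, perm], tau)
        assert (a.sort_index() == b.sort_index()).all()


class TestEigengene:
    def test_identical_genes_give_common_profile(self):
        profile = np.array([1.0, 3, 2, 5, 4, 6])
        expr = pd.DataFrame([profile, profile * 2, profile + 1],
                            index=list("abc"))
        e = eigengene(expr)
        z = (profile - profile.mean()) / profile.std()
        assert np.allclose(e.to_numpy(), z, atol=1e-10)

    def test_unit_variance_contract(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(0, 1, (5, 6)))
        e = eigengene(expr)
        assert e.std(ddof=0) == pytest.approx(1.0)
        assert e.mean() == pytest.approx(0.0, abs=1e-12)

    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(8)
        expr = pd.DataFrame(rng.normal(0, 1, (5, 6)))
        e = eigengene(expr).to_numpy()
        x = expr.to_numpy()
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        _, _, vt = np.linalg.svd(z)
        ref = vt[0]
        ref = (ref - ref.mean()) / ref.std()
        assert np.allclose(e, ref, atol=1e-10) or np.allclose(e, -ref, atol=1e-10)

    def test_rank_zero_rejected(self):
        expr = pd.DataFrame([[1.0, 1, 1, 1], [2.0, 2, 2, 2]])
        with pytest.raises(ValidationError):
            eigengene(expr)


class TestModuleTraitAndHubs:
    def test_trait_equal_to_eigengene(self):
        rng = np.random.default_rng(0)
        eig = pd.DataFrame({"M1": rng.normal(0, 1, 20)})
        traits = pd.DataFrame({"osmotic": eig["M1"].to_numpy(),
                               "noise": rng.normal(0, 1, 20)})
        table = module_trait_association(eig, traits).set_index("trait")
        assert table.loc["osmotic", "r"] == pytest.approx(1.0)
        assert abs(table.loc["noise", "r"]) < 0.5

    def test_pairwise_complete_n(self):
        eig = pd.DataFrame({"M1": [1.0, 2, 3, 4, 5, 6]})
        traits = pd.DataFrame({"t": [1.0, 2, np.nan, 4, 5, 6]})
        table = module_trait_association(eig, traits)
        assert table["n"].iloc[0] == 5

    def test_hub_count_is_ceiling_rule(self):
        modules = pd.Series(["M1"] * 20 + ["M2"] * 7,
                            index=[f"g{i:02d}" for i in range(27)])
        k = pd.Series(np.arange(27.0), index=modules.index)
        hubs = hub_genes(modules, k)
        assert hubs[modules == "M1"].sum() == math.ceil(0.15 * 20)  # 3
        assert hubs[modules == "M2"].sum() == math.ceil(0.15 * 7)   # 2

    def test_connectivity_excludes_diagonal(self):
        adj = pd.DataFrame(np.full((3, 3), 0.5), index=list("abc"), columns=list("abc"))
        np.fill_diagonal(adj.to_numpy(), 1.0)
        modules = pd.Series(["M1"] * 3, index=list("abc"))
        k = intramodular_connectivity(adj, modules)
        assert np.allclose(k, 1.0)


class TestCandidates:
    def test_region_vii_hub_excluded(self, default_run):
        hubs = default_run.hubs
        in_tradeoff = hubs["region"].isin(["III", "VII"])
        assert not hubs.loc[in_tradeoff, "candidate"].any()

    def test_planted_tolerance_hub_selected(self, default_run):
        # at least one tolerance-program hub satisfying all three rules
        truth = default_run.truth
        hubs = default_run.hubs.set_index("gene")
        tol_prog = truth.genes.index[truth.genes["class"] == "tolerant_specific"]
        selected = hubs.reindex(tol_prog).dropna(subset=["candidate"])
        assert selected["candidate"].any()

    def test_candidate_rules_conjunction(self, default_run):
        hubs = default_run.hubs
        expected = (
            hubs["trait_correlated"] & hubs["tolerance_featured"] & hubs["no_tradeoff"]
        )
        assert (hubs["candidate"] == expected).all()


class TestHormoneCrosstalk:
    def test_shared_profile_diagonal_one(self):
        profiles = pd.DataFrame(
            [[1, 2, 3, 4, 5, 3]] * 2 + [[5, 4, 3, 2, 1, 3]] * 2,
            index=["a1", "a2", "b1", "b2"],
            columns=["T1", "T2", "T3", "T4", "T5", "R"],
            dtype=float,
        )
        mapping = {"a1": "ABA", "a2": "ABA", "b1": "GA", "b2": "GA"}
        out = hormone_crosstalk(profiles, mapping)
        assert out.loc["ABA", "ABA"] == pytest.approx(1.0)
        assert out.loc["ABA", "GA"] == pytest.approx(-1.0)
        assert np.isnan(out.loc["SA", "SA"])  # <2 members

    def test_mean_of_cross_pairs_oracle(self):
        rng = np.random.default_rng(0)
        profiles = pd.DataFrame(rng.normal(0, 1, (4, 6)),
                                index=["a1", "a2", "b1", "b2"])
        mapping = {"a1": "ABA", "a2": "ABA", "b1": "GA", "b2": "GA"}
        out = hormone_crosstalk(profiles, mapping)
        pccs = [
            np.corrcoef(profiles.loc[x], profiles.loc[y])[0, 1]
            for x in ("a1", "a2")
            for y in ("b1", "b2")
        ]
        assert out.loc["ABA", "GA"] == pytest.approx(np.mean(pccs), abs=1e-12)
        assert np.allclose(out.to_numpy(), out.to_numpy().T, equal_nan=True)


class TestFullPipelineModuleRecovery:
    def test_planted_programs_recovered_on_average(self):
        # generator -> DEG calling -> network, across five seeds; one seed
        # occasionally merges the growth-coupled and acclimation modules at
        # the fixed dendrogram cut, so the bar is on the mean ARI
        from sklearn.metrics import adjusted_rand_score

        from temporadt import generate
        from temporadt.degs import call_all_degs, final_deg_calls

        aris = []
        for seed in (1, 2, 3, 4, 5):
            es, truth = generate(seed=seed)
            calls = final_deg_calls(call_all_degs(es))
            drg = sorted(set(calls.loc[calls["is_drg"], "gene"]))
            d_samples = [
                s for s in es.expression.columns
                if es.samples.loc[s, "condition"] == "D"
            ]
            log_expr = np.log2(es.expression.loc[drg, d_samples] + 0.01)
            _, tom = build_network(log_expr)
            tau, _ = select_cutoff(tom)
            modules = detect_modules(tom, tau)
            planted = truth.genes["module"]
            mask = planted != ""
            found = modules.reindex(planted.index[mask])
            keep = found.notna() & (found != "unassigned")
            aris.append(
                adjusted_rand_score(planted[mask][keep], found[keep])
            )
        assert np.mean(aris) >= 0.8
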