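"""Multivariate shrinkage: pruning, prior estimation, EM, posterior, lfsr."""

import numpy as np
import pandas as pd
import pytest

from gxeqtl import mash, simgen


def _pairs(n):
    return pd.DataFrame({"gene": [f"g{i}" for i in range(n)],
                         "snp": [f"s{i}" for i in range(n)]})


def _effects(B, S=None, contexts=None):
    B = np.asarray(B, float)
    if S is None:
        S = np.ones_like(B)
    if contexts is None:
        contexts = [f"c{r}" for r in range(B.shape[1])]
    return mash.EffectMatrix(pairs=_pairs(B.shape[0]), Bhat=B,
                             Shat=np.asarray(S, float), contexts=contexts)


class TestLdPrune:
    def _panel(self, dosages, maf=None, pos=None):
        dosages = np.asarray(dosages)
        m = dosages.shape[1]
        if maf is None:
            maf = [min(dosages[:, j].mean() / 2, 1 - dosages[:, j].mean() / 2)
                   for j in range(m)]
        snps = pd.DataFrame({"snp": [f"s{j}" for j in range(m)],
                             "chrom": "chr1",
                             "pos": pos if pos is not None else np.arange(m),
                             "ref": "A", "alt": "G", "maf": maf, "gene": "g"})
        return simgen.GenotypePanel(
            donors=[f"d{i}" for i in range(dosages.shape[0])],
            snps=snps, dosages=dosages)

    def test_independent_snps_all_kept(self, rng):
        dos = rng.binomial(2, 0.5, size=(500, 20))
        panel = self._panel(dos)
        assert len(mash.ld_prune(panel)) == 20

    def test_perfect_copies_one_survives(self):
        col = np.tile([0, 1, 2, 1], 10)
        panel = self._panel(np.column_stack([col, col]), maf=[0.5, 0.5])
        assert len(mash.ld_prune(panel)) == 1

    def test_matches_exhaustive_pairwise_oracle(self):
        cfg = simgen.SimConfig(n_donors=100, n_genes=1, n_snps_per_gene=20,
                               ld_copy_prob=0.7, seed=21)
        panel = simgen.simulate_genotypes(cfg)
        kept = set(mash.ld_prune(panel, window=20, step=20))
        # oracle: exhaustive pairwise scan with the same keep rule
        D = panel.dosages.astype(float)
        maf = panel.snps["maf"].to_numpy()
        pos = panel.snps["pos"].to_numpy()
        alive = set(range(20))
        changed = True
        while changed:
            changed = False
            for a in sorted(alive):
                for b in sorted(alive):
                    if b <= a:
                        continue
                    r = np.corrcoef(D[:, a], D[:, b])[0, 1]
                    if r * r > 0.2:
                        if maf[a] > maf[b]:
                            drop = b
                        elif maf[b] > maf[a]:
                            drop = a
                        else:
                            drop = a if pos[a] > pos[b] else b
                        alive.discard(drop)
                        changed = True
                        break
                if changed:
                    break
        oracle = {panel.snp_ids[j] for j in alive}
        assert kept == oracle


class TestNullCorrelation:
    def test_independent_contexts_near_identity(self, rng):
        Z = rng.normal(size=(5000, 4))
        V = mash.estimate_null_correlation(Z)
        off = V[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 0.05)

    def test_duplicated_context_high_correlation(self, rng):
        z = rng.normal(size=(500, 1))
        Z = np.hstack([z, z + 1e-6 * rng.normal(size=(500, 1))])
        V = mash.estimate_null_correlation(Z)
        assert V[0, 1] > 0.99
        assert np.linalg.cond(V) <= 1e6 * 1.01

    def test_single_context_scalar_one(self):
        V = mash.estimate_null_correlation(np.zeros((100, 1)))
        assert V.shape == (1, 1) and V[0, 0] == 1.0

    def test_few_rows_identity_fallback(self, rng):
        Z = rng.normal(size=(10, 3)) * 10  # all rows exceed |z| < 2
        with pytest.warns(UserWarning, match="identity"):
            V = mash.estimate_null_correlation(Z)
        np.testing.assert_array_equal(V, np.eye(3))


class TestStrongSet:
    def test_unique_minimum(self):
        res = {"c1": pd.DataFrame({"gene": ["g", "g"], "snp": ["a", "b"],
                                   "p": [0.5, 0.01]}),
               "c2": pd.DataFrame({"gene": ["g", "g"], "snp": ["a", "b"],
                                   "p": [0.9, 0.4]})}
        out = mash.build_strong_set(res)
        assert out.iloc[0]["snp"] == "b"

    def test_tie_break_reproducible(self):
        res = {"c1": pd.DataFrame({"gene": ["g", "g"], "snp": ["a", "b"],
                                   "p": [0.01, 0.01]})}
        picks = {mash.build_strong_set(res, seed=4).iloc[0]["snp"]
                 for _ in range(5)}
        assert len(picks) == 1

    def test_matches_hand_scan(self, rng):
        genes = [f"g{i}" for i in range(5)]
        res = {}
        for ctx in ["c1", "c2", "c3"]:
            res[ctx] = pd.DataFrame({
                "gene": np.repeat(genes, 4),
                "snp": [f"s{j}" for j in range(4)] * 5,
                "p": rng.uniform(size=20)})
        out = mash.build_strong_set(res).set_index("gene")
        stacked = pd.concat([d.assign(c=c) for c, d in res.items()],
                            ignore_index=True)
        for g in genes:
            sub = stacked[stacked["gene"] == g]
            best = sub.loc[sub["p"].idxmin()]
            assert out.loc[g, "snp"] == best["snp"]
            assert out.loc[g, "p_min"] == best["p"]


class TestEmFit:
    def _prior(self, R, Ulist, grid=(1.0,)):
        return mash.PriorSpec(V=np.eye(R), Ulist=Ulist,
                              grid=np.array(grid, float))

    def test_null_data_recovers_null_weight(self, rng):
        B = rng.normal(size=(2000, 3))  # pure noise: Bhat ~ N(0, S V S)
        eff = _effects(B)
        prior = self._prior(3, {"identity": np.eye(3),
                                "equal": np.ones((3, 3))})
        fit = mash.fit_weights_em(eff, prior)
        assert fit.pi[0] >= 0.95

    def test_two_component_weight_recovery(self, rng):
        # 50/50 identity vs equal-effects at scale 2; n=5000
        n, R = 5000, 3
        which = rng.random(n) < 0.5
        b = np.where(which[:, None],
                     rng.normal(scale=2.0, size=(n, R)),
                     np.tile(rng.normal(scale=2.0, size=(n, 1)), (1, R)))
        B = b + rng.normal(size=(n, R))
        eff = _effects(B)
        prior = self._prior(R, {"identity": np.eye(R),
                                "equal": np.ones((R, R))}, grid=(2.0,))
        fit = mash.fit_weights_em(eff, prior)
        # weights over (null, identity, equal)
        assert fit.pi[1] == pytest.approx(0.5, abs=0.05)
        assert fit.pi[2] == pytest.approx(0.5, abs=0.05)

    def test_single_component_weight_one(self, rng):
        B = rng.normal(size=(100, 2))
        eff = _effects(B)
        prior = mash.PriorSpec(V=np.eye(2), Ulist={}, grid=np.array([1.0]))
        fit = mash.fit_weights_em(eff, prior)
        assert fit.pi[0] == pytest.approx(1.0)


class TestPosterior:
    def test_conjugate_closed_form_r1(self):
        # R=1, U=1, omega=1, V=1, betahat=2, se=1:
        # posterior mean 1.0, posterior SD sqrt(1/2)
        eff = _effects(np.array([[2.0]]), np.array([[1.0]]))
        prior = mash.PriorSpec(V=np.eye(1), Ulist={"u": np.eye(1)},
                               grid=np.array([1.0]),
                               pi=np.array([0.0, 1.0]))
        post = mash.posterior(eff, prior)
        assert post.mean[0, 0] == pytest.approx(1.0, abs=1e-10)
        assert post.sd[0, 0] == pytest.approx(np.sqrt(0.5), abs=1e-10)

    def test_all_null_weight(self):
        eff = _effects(np.array([[1.0, -1.0]]))
        prior = mash.PriorSpec(V=np.eye(2), Ulist={"u": np.eye(2)},
                               grid=np.array([1.0]),
                               pi=np.array([1.0, 0.0]))
        post = mash.posterior(eff, prior)
        np.testing.assert_allclose(post.mean, 0.0, atol=1e-12)
        np.testing.assert_allclose(post.lfsr, 1.0, atol=1e-12)

    def test_equal_effects_component_homogenizes(self):
        eff = _effects(np.array([[2.0, -0.5]]))
        prior = mash.PriorSpec(V=np.eye(2),
                               Ulist={"equal": np.ones((2, 2))},
                               grid=np.array([2.0]),
                               pi=np.array([0.0, 1.0]))
        post = mash.posterior(eff, prior)
        assert post.mean[0, 0] == pytest.approx(post.mean[0, 1], abs=1e-10)

    def test_missing_context_equals_marginalized(self, rng):
        # posterior with context 2 missing == posterior from a 2-context
        # model on the observed coordinates
        B3 = np.array([[1.0, 0.5, np.nan]])
        S3 = np.array([[1.0, 1.0, np.nan]])
        eff3 = mash.EffectMatrix(pairs=_pairs(1), Bhat=B3, Shat=S3,
                                 contexts=["a", "b", "c"])
        U3 = np.eye(3) + 0.5 * (np.ones((3, 3)) - np.eye(3))
        prior3 = mash.PriorSpec(V=np.eye(3), Ulist={"u": U3},
                                grid=np.array([1.5]),
                                pi=np.array([0.3, 0.7]))
        post3 = mash.posterior(eff3, prior3)

        eff2 = _effects(np.array([[1.0, 0.5]]))
        prior2 = mash.PriorSpec(V=np.eye(2), Ulist={"u": U3[:2, :2]},
                                grid=np.array([1.5]),
                                pi=np.array([0.3, 0.7]))
        post2 = mash.posterior(eff2, prior2)
        np.testing.assert_allclose(post3.mean[0, :2], post2.mean[0],
                                   atol=1e-10)
        np.testing.assert_allclose(post3.sd[0, :2], post2.sd[0], atol=1e-10)
        np.testing.assert_allclose(post3.lfsr[0, :2], post2.lfsr[0],
                                   atol=1e-10)

    def test_shrinkage_reduces_rmse_and_lfsr_calibrated(self, rng):
        # mixture-generated effects in 8 contexts, 500 pairs
        n, R = 500, 8
        comp = rng.choice(3, size=n, p=[0.4, 0.3, 0.3])
        b = np.zeros((n, R))
        b[comp == 1] = rng.normal(scale=1.0, size=(np.sum(comp == 1), R))
        shared = rng.normal(scale=1.0, size=(np.sum(comp == 2), 1))
        b[comp == 2] = np.tile(shared, (1, R))
        B = b + rng.normal(size=(n, R))
        eff = _effects(B)
        prior = mash.PriorSpec(V=np.eye(R),
                               Ulist={"identity": np.eye(R),
                                      "equal": np.ones((R, R))},
                               grid=np.array([0.5, 1.0, 2.0]))
        fit = mash.fit_weights_em(eff, prior)
        post = mash.posterior(eff, fit)
        rmse_post = np.sqrt(np.mean((post.mean - b) ** 2))
        rmse_mle = np.sqrt(np.mean((B - b) ** 2))
        assert rmse_post < rmse_mle
        sig = post.lfsr < 0.1
        if sig.sum() > 20:
            wrong = (np.sign(post.mean) != np.sign(b)) | (b == 0)
            rate = wrong[sig].mean()
            mc_se = np.sqrt(0.1 * 0.9 / sig.sum())
            assert rate <= 0.1 + 2 * mc_se


class TestSharing:
    def _post(self, means, lfsr):
        means = np.asarray(means, float)
        return mash.PosteriorEffects(pairs=_pairs(means.shape[0]),
                                     contexts=["c1", "c2"], mean=means,
                                     sd=np.ones_like(means),
                                     lfsr=np.asarray(lfsr, float))

    def test_shared_within_factor(self):
        post = self._post([[0.30, 0.25]], [[0.01, 0.01]])
        assert mash.sharing_by_magnitude(post, "c1", "c2")["shared"].iloc[0]

    def test_not_shared_ratio_three(self):
        post = self._post([[0.30, 0.10]], [[0.01, 0.01]])
        assert not mash.sharing_by_magnitude(post, "c1", "c2")["shared"].iloc[0]

    def test_not_shared_sign_flip(self):
        post = self._post([[0.30, -0.30]], [[0.01, 0.01]])
        assert not mash.sharing_by_magnitude(post, "c1", "c2")["shared"].iloc[0]

    def test_zero_mean_not_shared(self):
        post = self._post([[0.30, 0.0]], [[0.01, 0.01]])
        assert not mash.sharing_by_magnitude(post, "c1", "c2")["shared"].iloc[0]


class TestInfiniteSe:
    def test_infinite_se_equals_marginalized(self):
        # a context with infinite standard error carries no information and
        # must reproduce the posterior with that context missing
        B = np.array([[1.0, 0.5, 0.2]])
        S_inf = np.array([[1.0, 1.0, np.inf]])
        S_nan = np.array([[1.0, 1.0, np.nan]])
        U = np.eye(3) + 0.4 * (np.ones((3, 3)) - np.eye(3))
        prior = mash.PriorSpec(V=np.eye(3), Ulist={"u": U},
                               grid=np.array([1.2]),
                               pi=np.array([0.3, 0.7]))
        eff_inf = mash.EffectMatrix(pairs=_pairs(1), Bhat=B, Shat=S_inf,
                                    contexts=["a", "b", "c"])
        eff_nan = mash.EffectMatrix(pairs=_pairs(1),
                                    Bhat=np.where(np.isfinite(S_nan), B,
                                                  np.nan),
                                    Shat=S_nan, contexts=["a", "b", "c"])
        p1 = mash.posterior(eff_inf, prior)
        p2 = mash.posterior(eff_nan, prior)
        np.testing.assert_allclose(p1.mean, p2.mean, atol=1e-12)
        np.testing.assert_allclose(p1.sd, p2.sd, atol=1e-12)
        np.testing.assert_allclose(p1.lfsr, p2.lfsr, atol=1e-12)
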