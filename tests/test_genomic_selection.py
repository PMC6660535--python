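import numpy as np
import pandas as pd
import pytest

from ricapanel import genomic_selection as gs
from ricapanel import synthetic_data as sd
from ricapanel.core import Pedigree


class TestGrainYield:
    def test_reference_moisture_factor_is_one(self):
        assert gs.grain_yield(312.0, 3.12, 14.0) == pytest.approx(1.0)

    def test_half_factor_at_57_percent(self):
        assert gs.grain_yield(100.0, 3.12, 57.0) == pytest.approx(
            0.5 * gs.grain_yield(100.0, 3.12, 14.0)
        )

    def test_zero_weight(self):
        assert gs.grain_yield(0.0, 3.12, 14.0) == 0.0

    def test_invalid_moisture(self):
        with pytest.raises(ValueError):
            gs.grain_yield(100.0, 3.12, 100.0)


class TestHeritability:
    def test_arithmetic(self):
        vc = gs.VarianceComponents(sigma_g2=2, sigma_t2=0, sigma_rt2=0,
                                   sigma_e2=4, sigma_gy2=2, t=2, r=2)
        assert gs.heritability(vc) == pytest.approx(0.5)

    def test_no_noise_is_one(self):
        vc = gs.VarianceComponents(sigma_g2=3, sigma_t2=1, sigma_rt2=1, sigma_e2=0)
        assert gs.heritability(vc) == 1.0

    def test_monotone_in_components(self):
        lo = gs.VarianceComponents(1.0, 0, 0, 1.0, t=2, r=2)
        hi_g = gs.VarianceComponents(2.0, 0, 0, 1.0, t=2, r=2)
        hi_e = gs.VarianceComponents(1.0, 0, 0, 2.0, t=2, r=2)
        assert gs.heritability(hi_g) > gs.heritability(lo) > gs.heritability(hi_e)


@pytest.fixture(scope="module")
def program():
    panel = sd.simulate_panel(300, seed=81)
    return sd.simulate_breeding_program(
        panel, n_families=15, family_sizes=10, seed=82,
        arch=sd.TraitArchitecture(n_qtl=60, h2=0.85),
    )


class TestFitMixed:
    def test_balanced_noiseless_blue_is_plot_mean(self, small_panel):
        arch = sd.TraitArchitecture(n_qtl=10, h2=1.0, trial_var=0.0,
                                    rep_var=0.0, resid_var=0.0)
        prog = sd.simulate_breeding_program(small_panel, n_families=3, family_sizes=4,
                                            arch=arch, n_trials=2, n_reps_per_trial=1, seed=83)
        blues, _ = gs.fit_mixed(prog.plots, "fixed")
        means = prog.plots.groupby("genotype")["value"].mean()
        assert np.allclose(blues.sort_index(), means.sort_index(), atol=1e-6)

    def test_blups_shrink_toward_mean(self, program):
        blues, _ = gs.fit_mixed(program.plots, "fixed")
        blups, _ = gs.fit_mixed(program.plots, "random")
        mu = program.plots["value"].mean()
        common = blues.index.intersection(blups.index)
        slack = 0.05 * blues.std()
        assert ((blups.loc[common] - mu).abs() <= (blues.loc[common] - mu).abs() + slack).mean() > 0.95

    def test_component_recovery(self, program):
        _, vc = gs.fit_mixed(program.plots, "random")
        truth = program.variance_components
        assert vc.sigma_g2 == pytest.approx(truth["sigma_g2"], rel=0.35)
        assert vc.sigma_e2 == pytest.approx(truth["sigma_e2"], rel=0.35)
        h2 = gs.heritability(vc)
        assert h2 == pytest.approx(0.85, abs=0.1)


class TestGrm:
    def test_duplicated_samples_identical_rows(self, clean_pop_matrix):
        dose = clean_pop_matrix.dosage()
        dose2 = np.vstack([dose, dose[:1]])
        G = gs.grm(dose2)
        assert G[-1, 0] == pytest.approx(G[0, 0])
        assert np.allclose(G[-1], G[0])

    def test_psd(self, clean_pop_matrix):
        G = gs.grm(clean_pop_matrix.dosage())
        evals = np.linalg.eigvalsh(G)
        assert evals.min() > -1e-8

    def test_hwe_outbred_diagonal_near_one(self):
        # genotypes in Hardy-Weinberg proportions (outbred diploids)
        rng = np.random.default_rng(84)
        p = rng.uniform(0.2, 0.5, size=2000)
        dose = rng.binomial(2, p, size=(200, 2000)).astype(float)
        G = gs.grm(dose)
        assert np.diag(G).mean() == pytest.approx(1.0, abs=0.05)

    def test_monomorphic_only_rejected(self):
        with pytest.raises(Exception):
            gs.grm(np.zeros((5, 4)))


def kinship_oracle(ped: Pedigree) -> pd.DataFrame:
    """Independent recursive-kinship oracle: A = 2 * coancestry."""
    parents = {i: (s, d) for i, s, d in ped.entries}
    order = {ind: k for k, ind in enumerate(ped.ids)}
    memo = {}

    def f(a, b):
        if a is None or b is None:
            return 0.0
        key = (a, b) if order[a] >= order[b] else (b, a)
        if key in memo:
            return memo[key]
        x, y = key  # x is the later-born
        if x == y:
            s, d = parents[x]
            val = 0.5 * (1.0 + f(s, d))
        else:
            s, d = parents[x]
            val = 0.5 * (f(s, y) + f(d, y))
        memo[key] = val
        return val

    ids = ped.ids
    A = pd.DataFrame(0.0, index=ids, columns=ids)
    for a in ids:
        for b in ids:
            A.loc[a, b] = 2.0 * f(a, b)
    return A


class TestAMatrix:
    def test_parent_offspring_half(self):
        ped = Pedigree([("P1", None, None), ("P2", None, None), ("O", "P1", "P2")])
        A = gs.a_matrix(ped)
        assert A.loc["P1", "O"] == 0.5
        assert A.loc["O", "O"] == 1.0

    def test_full_sibs_and_inbred_offspring(self):
        ped = Pedigree([
            ("P1", None, None), ("P2", None, None),
            ("S1", "P1", "P2"), ("S2", "P1", "P2"), ("I", "S1", "S2"),
        ])
        A = gs.a_matrix(ped)
        assert A.loc["S1", "S2"] == 0.5
        assert A.loc["I", "I"] == 1.25

    def test_founders_identity(self):
        ped = Pedigree([(f"F{i}", None, None) for i in range(4)])
        assert np.allclose(gs.a_matrix(ped).to_numpy(), np.eye(4))

    def test_matches_kinship_oracle_on_random_pedigrees(self):
        rng = np.random.default_rng(85)
        for _ in range(5):
            entries = [("F1", None, None), ("F2", None, None), ("F3", None, None)]
            for i in range(5):  # 8 individuals total
                pool = [e[0] for e in entries]
                s, d = rng.choice(pool, size=2, replace=False)
                entries.append((f"X{i}", s, d))
            ped = Pedigree(entries)
            A = gs.a_matrix(ped)
            O = kinship_oracle(ped)
            assert np.allclose(A.to_numpy(), O.loc[A.index, A.columns].to_numpy(), atol=1e-12)


def reml_grid_oracle(y, K, grid):
    """Brute-force restricted likelihood over a lambda grid, evaluated with
    dense determinant formulas (no spectral shortcut)."""
    n = len(y)
    X = np.ones((n, 1))
    best = None
    for lam in grid:
        V = lam * K + np.eye(n)
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        b = np.linalg.solve(XtViX, X.T @ Vi @ y)
        r = y - X @ b
        sig = float(r @ Vi @ r) / (n - 1)
        _, ldV = np.linalg.slogdet(V)
        _, ldX = np.linalg.slogdet(XtViX)
        ll = -0.5 * ((n - 1) * np.log(sig) + ldV + ldX + (n - 1))
        if best is None or ll > best[1]:
            best = (lam, ll)
    return best[0]


class TestFitRidge:
    def test_noiseless_limit_recovers_breeding_values(self, small_panel):
        arch = sd.TraitArchitecture(n_qtl=40, h2=0.999)
        prog = sd.simulate_breeding_program(small_panel, n_families=10, family_sizes=10,
                                            arch=arch, seed=86)
        y = prog.true_breeding_values + 50.0
        G = pd.DataFrame(gs.grm(prog.genotypes.dosage()),
                         index=prog.genotypes.samples, columns=prog.genotypes.samples)
        res = gs.fit_ridge(y, G)
        r = np.corrcoef(res.gebv.loc[y.index], y)[0, 1]
        assert r > 0.99

    @pytest.mark.parametrize("seed", [80, 82, 88, 112])
    def test_matches_grid_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, m = 12, 40
        dose = rng.binomial(2, 0.4, size=(n, m)).astype(float)
        u = dose @ rng.normal(0, 0.3, m)
        y = pd.Series(u + rng.normal(0, 1.5, n), index=[f"s{i}" for i in range(n)])
        G = pd.DataFrame(gs.grm(dose), index=y.index, columns=y.index)
        res = gs.fit_ridge(y, G)
        lam_hat = res.sigma_u2 / res.sigma_e2
        grid = np.exp(np.linspace(np.log(lam_hat) - 0.1, np.log(lam_hat) + 0.1, 4001))
        lam_star = reml_grid_oracle(y.to_numpy(), G.to_numpy(), grid)
        assert np.log(lam_hat) == pytest.approx(np.log(lam_star), abs=1e-3)

    def test_permutation_equivariance(self, program):
        blues, _ = gs.fit_mixed(program.plots, "fixed")
        G = pd.DataFrame(gs.grm(program.genotypes.dosage()),
                         index=program.genotypes.samples, columns=program.genotypes.samples)
        res = gs.fit_ridge(blues, G)
        perm = list(reversed(program.genotypes.samples))
        res_p = gs.fit_ridge(blues.loc[reversed(blues.index)], G.loc[perm, perm])
        assert np.allclose(res.gebv.loc[perm], res_p.gebv.loc[perm], atol=1e-6)

    def test_agrees_with_direct_mme_solve(self):
        rng = np.random.default_rng(88)
        n, m = 20, 50
        dose = rng.binomial(2, 0.4, size=(n, m)).astype(float)
        y = pd.Series(dose @ rng.normal(0, 0.3, m) + rng.normal(0, 1, n),
                      index=[f"s{i}" for i in range(n)])
        G = pd.DataFrame(gs.grm(dose) + 1e-8 * np.eye(n), index=y.index, columns=y.index)
        res = gs.fit_ridge(y, G)
        lam = res.sigma_u2 / res.sigma_e2
        # direct mixed-model-equation solve at the REML optimum
        X = np.ones((n, 1))
        Gi = np.linalg.inv(G.to_numpy())
        C = np.block([[X.T @ X, X.T], [X, np.eye(n) + Gi / lam]])
        rhs = np.concatenate([X.T @ y.to_numpy(), y.to_numpy()])
        sol = np.linalg.solve(C, rhs)
        assert res.mu == pytest.approx(sol[0], abs=1e-5)
        assert np.allclose(res.gebv.to_numpy() - res.mu, sol[1:], atol=1e-5)


@pytest.fixture(scope="module")
def training(program):
    blues, _ = gs.fit_mixed(program.plots, "fixed")
    X = pd.DataFrame(program.genotypes.dosage(), index=program.genotypes.samples)
    return blues, X


class TestBayes:
    def test_seeded_chains_reproduce(self, training):
        y, X = training
        spec = gs.GSModelSpec("BAYES_A", iterations=300, burn_in=100, thin=5, seed=3)
        a = gs.fit_bayes(y, X, spec)
        b = gs.fit_bayes(y, X, spec)
        assert np.array_equal(a.effects, b.effects)
        assert np.array_equal(a.varE_trace, b.varE_trace)

    def test_null_simulation_shrinks_effects(self, small_panel):
        rng = np.random.default_rng(89)
        model = sd.population_model(small_panel, n_subpops=1, divergence=0.0,
                                    residual_het_rate=0.0, missing_rate=0.0, seed=90)
        gm = sd.simulate_inbreds(small_panel, model, 120)
        X = pd.DataFrame(gm.dosage(), index=gm.samples)
        y = pd.Series(rng.normal(0, 1, 120), index=gm.samples)  # pure noise
        spec = gs.GSModelSpec("BAYES_B", iterations=500, burn_in=200, thin=5, seed=4)
        res = gs.fit_bayes(y, X, spec)
        Xc = X.to_numpy() - X.to_numpy().mean(axis=0)
        ols = (Xc * (y - y.mean()).to_numpy()[:, None]).sum(axis=0) / (Xc**2).sum(axis=0)
        assert np.mean(np.abs(res.effects)) < 0.1 * np.mean(np.abs(ols))

    def test_single_marker_posterior_matches_ols(self):
        rng = np.random.default_rng(91)
        n = 400
        x = rng.binomial(2, 0.5, n).astype(float)
        beta = 0.8
        y = pd.Series(beta * x + rng.normal(0, 0.5, n), index=[f"s{i}" for i in range(n)])
        X = pd.DataFrame({"m": x}, index=y.index)
        spec = gs.GSModelSpec("BAYES_A", iterations=2000, burn_in=500, thin=5, seed=5)
        res = gs.fit_bayes(y, X, spec)
        xc = x - x.mean()
        ols = float(xc @ (y - y.mean())) / float(xc @ xc)
        se = 0.5 / np.sqrt(float(xc @ xc))
        assert res.effects[0] == pytest.approx(ols, abs=2 * se)

    def test_varE_trace_exported(self, training, tmp_path):
        y, X = training
        spec = gs.GSModelSpec("BAYES_L", iterations=300, burn_in=100, thin=5, seed=6)
        res = gs.fit_bayes(y, X, spec)
        assert len(res.varE_trace) == 40
        out = tmp_path / "varE.dat"
        res.save_trace(out)
        assert np.allclose(np.loadtxt(out), res.varE_trace, rtol=1e-6)


class TestRkhsGA:
    def test_matches_single_kernel_when_A_equals_G(self, program):
        blues, _ = gs.fit_mixed(program.plots, "fixed")
        samples = program.genotypes.samples
        G = pd.DataFrame(gs.grm(program.genotypes.dosage()), index=samples, columns=samples)
        spec = gs.GSModelSpec("RKHS_G_A", iterations=1500, burn_in=500, thin=5, seed=7)
        two = gs.fit_rkhs_g_a(blues, G, G, spec)
        one = gs.fit_ridge(blues, G)
        r = np.corrcoef(two.gebv.loc[samples], one.gebv.loc[samples])[0, 1]
        assert r > 0.98

    def test_seed_reproducibility(self, program):
        blues, _ = gs.fit_mixed(program.plots, "fixed")
        samples = program.genotypes.samples
        G = pd.DataFrame(gs.grm(program.genotypes.dosage()), index=samples, columns=samples)
        A = gs.a_matrix(program.pedigree).loc[samples, samples]
        spec = gs.GSModelSpec("RKHS_G_A", iterations=300, burn_in=100, thin=5, seed=8)
        a = gs.fit_rkhs_g_a(blues, G, A, spec)
        b = gs.fit_rkhs_g_a(blues, G, A, spec)
        assert np.allclose(a.gebv, b.gebv)


class TestStratifiedCV:
    def test_family_of_k_spreads_over_folds(self):
        fams = pd.Series({f"s{i}": "F1" for i in range(5)})
        folds = gs.stratified_cv(list(fams.index), fams, k=5, repeats=1, seed=1)[0]
        assert sorted(folds) == [0, 1, 2, 3, 4]

    def test_partition_and_balance(self, program):
        fams = program.genotypes.sample_meta["family"]
        samples = program.genotypes.samples
        for folds in gs.stratified_cv(samples, fams, k=5, repeats=3, seed=2):
            assert set(folds.index) == set(samples)
            sizes = folds.value_counts()
            assert sizes.max() - sizes.min() <= int(np.ceil(fams.nunique() / 5))

    def test_seed_determinism(self, program):
        fams = program.genotypes.sample_meta["family"]
        a = gs.stratified_cv(program.genotypes.samples, fams, k=5, repeats=2, seed=9)
        b = gs.stratified_cv(program.genotypes.samples, fams, k=5, repeats=2, seed=9)
        assert all((x == y).all() for x, y in zip(a, b))

    def test_k_larger_than_n_rejected(self):
        fams = pd.Series({"a": "F"})
        with pytest.raises(ValueError):
            gs.stratified_cv(["a"], fams, k=5)


class TestPredictiveAbility:
    def test_oracle_model_gives_r_one(self, program):
        blues, _ = gs.fit_mixed(program.plots, "fixed")
        fams = program.genotypes.sample_meta["family"]
        folds = gs.stratified_cv(list(blues.index), fams, k=5, repeats=2, seed=10)
        cv = gs.predictive_ability(blues, lambda ytr, test: blues.loc[test], folds)
        assert cv.mean_r == pytest.approx(1.0)

    def test_constant_model_errors(self, program):
        blues, _ = gs.fit_mixed(program.plots, "fixed")
        fams = program.genotypes.sample_meta["family"]
        folds = gs.stratified_cv(list(blues.index), fams, k=5, repeats=1, seed=11)
        const = lambda ytr, test: pd.Series(1.0, index=test)
        with pytest.raises(ValueError):
            gs.predictive_ability(blues, const, folds)

    def test_ridge_cv_in_expected_band(self, program):
        blues, _ = gs.fit_mixed(program.plots, "fixed")
        fams = program.genotypes.sample_meta["family"]
        folds = gs.stratified_cv(list(blues.index), fams, k=5, repeats=3, seed=12)
        fp = gs.make_fit_predict(gs.GSModelSpec("RIDGE"), gm=program.genotypes)
        cv = gs.predictive_ability(blues, fp, folds)
        assert 0.5 < cv.mean_r < 0.95
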