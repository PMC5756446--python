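import numpy as np
import pytest
from scipy import stats
from sklearn.base import clone

from fstprior import GwrFit, GwrModelSpec, WholeGenomeRegressor, fit_gwr, predict_gebv


@pytest.fixture(scope="module")
def strong_fit(rng):
    """Six SNPs, clear signal, long chain — reused by several checks."""
    n, m = 500, 6
    X = rng.integers(0, 3, (n, m)).astype(float)
    beta = np.array([1.0, -0.8, 0.5, 0.0, 0.0, 0.3])
    y = X @ beta + rng.normal(0, 0.5, n)
    est = WholeGenomeRegressor(chain_length=4000, burn_in=500, thin=2, random_state=2)
    return X, y, beta, est.fit(X, y)


# -------------------------------------------------------------- spec & API


def test_spec_validation():
    GwrModelSpec(model="bayesB", pi_zero=0.95).validate()
    for pz in (0.90, 0.95, 0.98, 0.99):  # the study's pi grid
        GwrModelSpec(model="bayesC", pi_zero=pz).validate()
    with pytest.raises(ValueError):
        GwrModelSpec(model="bayesD").validate()
    with pytest.raises(ValueError):
        GwrModelSpec(pi_zero=1.0).validate()
    with pytest.raises(ValueError):
        GwrModelSpec(chain_length=100, burn_in=100).validate()


def test_estimator_sklearn_contract(rng):
    est = WholeGenomeRegressor(model="bayesC", pi_zero=0.95)
    assert clone(est).get_params() == est.get_params()
    X = rng.integers(0, 3, (50, 8)).astype(float)
    y = rng.normal(size=50)
    fitted = clone(est).set_params(chain_length=200, burn_in=50).fit(X, y)
    assert fitted.beta_hat_.shape == (8,)
    assert np.all((fitted.include_prob_ >= 0) & (fitted.include_prob_ <= 1))
    with pytest.raises(ValueError):
        fitted.predict(rng.normal(size=(5, 9)))  # wrong design width


def test_preselect_inclusion_is_always_one(rng):
    X = rng.integers(0, 3, (80, 5)).astype(float)
    y = rng.normal(size=80)
    est = WholeGenomeRegressor(model="fst_preselect", chain_length=300, burn_in=50).fit(X, y)
    assert np.all(est.include_prob_ == 1.0)


def test_seed_determinism(rng):
    X = rng.integers(0, 3, (100, 10)).astype(float)
    y = rng.normal(size=100)
    kw = dict(model="bayesB", pi_zero=0.9, chain_length=400, burn_in=100, random_state=9)
    a = WholeGenomeRegressor(**kw).fit(X, y)
    b = WholeGenomeRegressor(**kw).fit(X, y)
    assert np.array_equal(a.beta_hat_, b.beta_hat_)
    assert np.array_equal(a.include_prob_, b.include_prob_)
    assert a.mu_hat_ == b.mu_hat_


# ------------------------------------------------------------------ predict


def test_predict_gebv_linear_form(rng):
    fit = GwrFit(
        beta_hat=np.array([2.0]), include_prob=np.ones(1), mu_hat=5.0,
        sigma2_e_hat=1.0, n_iterations_kept=1, col_center=np.zeros(1),
    )
    assert np.allclose(predict_gebv(fit, np.array([[0.0], [1.0], [2.0]])), [0.0, 2.0, 4.0])
    fit0 = GwrFit(
        beta_hat=np.zeros(4), include_prob=np.ones(4), mu_hat=0.0,
        sigma2_e_hat=1.0, n_iterations_kept=1, col_center=np.zeros(4),
    )
    assert np.all(predict_gebv(fit0, rng.integers(0, 3, (7, 4)).astype(float)) == 0.0)
    with pytest.raises(ValueError):
        predict_gebv(fit0, np.zeros((3, 5)))


def test_predict_matches_matrix_product_oracle(rng):
    beta = rng.normal(size=20)
    center = rng.uniform(0, 2, 20)
    fit = GwrFit(
        beta_hat=beta, include_prob=np.ones(20), mu_hat=0.0,
        sigma2_e_hat=1.0, n_iterations_kept=1, col_center=center,
    )
    X = rng.integers(0, 3, (50, 20)).astype(float)
    oracle = np.array([
        sum((X[i, j] - center[j]) * beta[j] for j in range(20)) for i in range(50)
    ])
    assert np.allclose(predict_gebv(fit, X), oracle)


# -------------------------------------------------------------- inference


def test_conjugate_closed_form_known_variance_limit(rng):
    """One SNP, df -> inf: posterior mean matches the ridge closed form."""
    n = 300
    x = rng.normal(0, 1, n)
    x -= x.mean()
    y = 1.0 + 0.5 * x + rng.normal(0, 0.8, n)
    s2e, s2b = 0.64, 0.25
    closed = (x @ y) / (x @ x + s2e / s2b)
    est = WholeGenomeRegressor(
        model="fst_preselect", per_locus_scale=s2b, scale_e=s2e,
        df_g=1e9, df_e=1e9, chain_length=6000, burn_in=1000, thin=2,
        center=False, random_state=3,
    ).fit(x[:, None], y)
    assert abs(est.beta_hat_[0] - closed) / abs(closed) < 0.01


def test_strong_effect_recovered_vs_ols(rng):
    """A 10-sigma SNP effect is recovered and decisively included."""
    n, m = 2000, 5
    X = rng.integers(0, 3, (n, m)).astype(float)
    beta = np.zeros(m)
    beta[2] = 10.0
    y = X @ beta + rng.normal(0, 1, n)
    Xc = np.column_stack([np.ones(n), X - X.mean(0)])
    ols = np.linalg.lstsq(Xc, y, rcond=None)[0][1:]
    est = WholeGenomeRegressor(
        model="bayesC", pi_zero=0.9, chain_length=2000, burn_in=400, random_state=0
    ).fit(X, y)
    assert abs(est.beta_hat_[2] - 10.0) / 10.0 < 0.10
    assert abs(est.beta_hat_[2] - ols[2]) < 0.05
    assert est.include_prob_[2] > 0.95


def test_exchangeability_under_column_permutation(strong_fit):
    """Permuting SNP columns permutes the posterior means (up to MC error)."""
    X, y, beta, base = strong_fit
    perm = np.array([3, 0, 5, 1, 4, 2])
    permuted = WholeGenomeRegressor(
        chain_length=4000, burn_in=500, thin=2, random_state=2
    ).fit(X[:, perm], y)
    assert np.allclose(permuted.beta_hat_, base.beta_hat_[perm], atol=0.02)


def test_shrinkage_monotone_in_pi_zero(rng):
    """BayesC posterior effects shrink as the prior exclusion mass grows."""
    n, m = 400, 100
    X = rng.integers(0, 3, (n, m)).astype(float)
    y = X @ rng.normal(0, 0.05, m) + rng.normal(0, 1, n)
    means = []
    for pz in (0.5, 0.9, 0.99):
        est = WholeGenomeRegressor(
            model="bayesC", pi_zero=pz, chain_length=1500, burn_in=300, random_state=1
        ).fit(X, y)
        means.append(np.abs(est.beta_hat_).mean())
    assert means[0] > means[1] > means[2]


def test_parameter_recovery_on_simulated_trait(rng):
    """QTL-bearing SNP panels yield positive effect correlation and
    validation accuracy reliably above zero."""
    accs, cors = [], []
    for rep in range(5):
        r = np.random.default_rng(1000 + rep)
        n, m, nq = 800, 400, 20
        X = r.binomial(2, 0.5, (n + 300, m)).astype(float)
        beta = np.zeros(m)
        qtl = r.choice(m, nq, replace=False)
        beta[qtl] = r.normal(0, 1, nq)
        g = X @ beta
        g *= np.sqrt(0.4 / g.var())
        beta *= np.sqrt(0.4 / (X @ beta).var())
        y = g + r.normal(0, np.sqrt(0.6), n + 300)
        est = WholeGenomeRegressor(
            model="fst_preselect", chain_length=800, burn_in=200, random_state=rep
        ).fit(X[:n], y[:n])
        cors.append(np.corrcoef(est.beta_hat_, beta)[0, 1])
        gebv = est.predict_gebv(X[n:])
        accs.append(np.corrcoef(gebv, g[n:])[0, 1])
    assert all(c > 0 for c in cors)
    t = stats.ttest_1samp(accs, 0.0, alternative="greater")
    assert t.pvalue < 1e-4


def test_fit_gwr_wrapper_roundtrip(rng):
    X = rng.integers(0, 3, (60, 4)).astype(float)
    y = rng.normal(size=60)
    spec = GwrModelSpec(model="bayesC", pi_zero=0.5, chain_length=300, burn_in=50, seed=4)
    fit = fit_gwr(X, y, spec)
    assert fit.beta_hat.shape == (4,)
    gebv = predict_gebv(fit, X)
    assert gebv.shape == (60,)
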