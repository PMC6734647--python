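"""Signature-model tests: likelihood oracle, sampler contracts, matching."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln

from syncrc.contexts import MutationCatalog, N_CONTEXTS
from syncrc.model import (
    COMPONENTS,
    MCMCSettings,
    Parameters,
    SignatureModelSpec,
    attribute_counts,
    cosine_similarity,
    fit_signatures,
    log_joint,
    make_model_spec,
    match_reference,
    signature_fraction_order,
)


def toy_spec(n_patients=2, tumours_per_patient=2, msi_patients=()):
    tumour_ids, patient_of, mmr_of = [], {}, {}
    for p in range(n_patients):
        pid = f"p{p}"
        for k in range(tumours_per_patient):
            t = f"p{p}-t{k}"
            tumour_ids.append(t)
            patient_of[t] = pid
            mmr_of[t] = "MSI" if p in msi_patients else "MSS"
    return make_model_spec(tumour_ids, patient_of, mmr_of)


def random_params(rng, spec):
    T = len(spec.tumour_ids)
    S = rng.dirichlet(np.ones(N_CONTEXTS), size=4)
    W = np.abs(stats.halfcauchy.rvs(scale=100, size=(4, T), random_state=rng))
    W[1, ~spec.msi_mask()] = 0.0
    # shared patient weight: broadcast the first tumour's value
    pats = {}
    for i, t in enumerate(spec.tumour_ids):
        p = spec.patient_of[t]
        pats.setdefault(p, W[0, i])
        W[0, i] = pats[p]
    return Parameters(S, W)


def oracle_log_joint(spec, catalog, params):
    """Naive independent summation using scipy distributions."""
    S, W = params.signatures, params.weights
    total = 0.0
    for i, t in enumerate(spec.tumour_ids):
        for c in range(N_CONTEXTS):
            lam = sum(W[k, i] * S[k, c] for k in range(4))
            total += stats.poisson.logpmf(catalog.counts[i, c], lam)
    seen = set()
    for i, t in enumerate(spec.tumour_ids):
        p = spec.patient_of[t]
        if p not in seen:
            seen.add(p)
            total += stats.halfcauchy.logpdf(W[0, i], scale=spec.halfcauchy_scale)
        if spec.msi_mask()[i]:
            total += stats.halfcauchy.logpdf(W[1, i], scale=spec.halfcauchy_scale)
        total += stats.halfcauchy.logpdf(W[2, i], scale=spec.halfcauchy_scale)
        total += stats.halfcauchy.logpdf(W[3, i], scale=spec.halfcauchy_scale)
    for k in range(4):
        total += gammaln(N_CONTEXTS)  # Dirichlet(1) log density on the simplex
    return total


def random_catalog(rng, spec, scale=50):
    counts = rng.poisson(scale / N_CONTEXTS, size=(len(spec.tumour_ids), N_CONTEXTS))
    return MutationCatalog(tumour_ids=list(spec.tumour_ids), counts=counts)


# -------------------------------------------------------------- log_joint ---
def test_log_joint_closed_form_single_context():
    spec = toy_spec(n_patients=1, tumours_per_patient=2)
    # drop to a single tumour via a 1-tumour spec
    spec = make_model_spec(["p0-t0"], {"p0-t0": "p0"}, {"p0-t0": "MSS"})
    n, w = 7, 12.5
    counts = np.zeros((1, N_CONTEXTS), dtype=int)
    counts[0, 10] = n
    catalog = MutationCatalog(["p0-t0"], counts)
    S = np.zeros((4, N_CONTEXTS))
    S[:, 10] = 1.0  # all mass on the observed context
    W = np.zeros((4, 1))
    W[0, 0] = w
    params = Parameters(S, W)
    expected = (
        stats.poisson.logpmf(n, w)
        + stats.halfcauchy.logpdf(w, scale=100)
        + 2 * stats.halfcauchy.logpdf(0.0, scale=100)  # ts1, ts2 at zero; MSI excluded
        + 4 * gammaln(N_CONTEXTS)
    )
    assert log_joint(spec, catalog, params) == pytest.approx(expected, abs=1e-10)


def test_log_joint_oracle_agreement(rng):
    spec = toy_spec(n_patients=3, msi_patients=(1,))
    for _ in range(10):
        catalog = random_catalog(rng, spec)
        params = random_params(rng, spec)
        assert log_joint(spec, catalog, params) == pytest.approx(
            oracle_log_joint(spec, catalog, params), abs=1e-8
        )


def test_log_joint_poisson_increment_on_doubled_count(rng):
    spec = toy_spec(n_patients=2)
    catalog = random_catalog(rng, spec)
    params = random_params(rng, spec)
    i, c = 1, 40
    n = int(catalog.counts[i, c]) + 3  # ensure nonzero
    catalog.counts[i, c] = n
    base = log_joint(spec, catalog, params)
    doubled = catalog.counts.copy()
    doubled[i, c] = 2 * n
    cat2 = MutationCatalog(list(spec.tumour_ids), doubled)
    lam = float(params.weights[:, i] @ params.signatures[:, c])
    expected_delta = stats.poisson.logpmf(2 * n, lam) - stats.poisson.logpmf(n, lam)
    assert log_joint(spec, cat2, params) - base == pytest.approx(expected_delta, abs=1e-8)


def test_log_joint_zero_rate_positive_count_is_minus_inf():
    spec = make_model_spec(["t"], {"t": "p"}, {"t": "MSS"})
    counts = np.zeros((1, N_CONTEXTS), dtype=int)
    counts[0, 5] = 2
    catalog = MutationCatalog(["t"], counts)
    S = np.zeros((4, N_CONTEXTS))
    S[:, 9] = 1.0  # no mass on context 5
    W = np.full((4, 1), 3.0)
    W[1, 0] = 0.0
    assert log_joint(spec, catalog, Parameters(S, W)) == -np.inf


def test_log_joint_out_of_support(rng):
    spec = toy_spec()
    catalog = random_catalog(rng, spec)
    params = random_params(rng, spec)
    params.weights[2, 0] = -1.0
    assert log_joint(spec, catalog, params) == -np.inf
    params = random_params(rng, spec)
    params.signatures[0] *= 2  # off the simplex
    assert log_joint(spec, catalog, params) == -np.inf


def test_msi_weight_nonzero_in_mss_is_out_of_support(rng):
    spec = toy_spec()
    catalog = random_catalog(rng, spec)
    params = random_params(rng, spec)
    params.weights[1, 0] = 5.0  # MSS tumour
    assert log_joint(spec, catalog, params) == -np.inf


# ---------------------------------------------------------------- sampler ---
@pytest.fixture(scope="module")
def small_fit():
    rng = np.random.default_rng(5)
    spec = toy_spec(n_patients=3, msi_patients=(2,))
    counts = rng.poisson(30, size=(len(spec.tumour_ids), N_CONTEXTS))
    catalog = MutationCatalog(list(spec.tumour_ids), counts)
    mcmc = MCMCSettings(n_samples=50, n_chains=2, burn_in=50, seed=99)
    return spec, catalog, fit_signatures(spec, catalog, mcmc)


def test_fit_determinism(small_fit):
    spec, catalog, fit = small_fit
    fit2 = fit_signatures(spec, catalog, MCMCSettings(n_samples=50, n_chains=2, burn_in=50, seed=99))
    np.testing.assert_array_equal(fit.signatures, fit2.signatures)
    np.testing.assert_array_equal(fit.weights, fit2.weights)
    assert fit.map_index == fit2.map_index


def test_posterior_draws_on_simplex(small_fit):
    _, _, fit = small_fit
    sums = fit.signatures.sum(axis=2)
    assert np.abs(sums - 1.0).max() < 1e-8


def test_mss_attribution_identically_zero(small_fit):
    spec, _, fit = small_fit
    mss = ~spec.msi_mask()
    assert (fit.weights[:, 1, mss] == 0).all()
    assert (fit.attributed_counts[1, mss] == 0).all()


def test_attribution_conservation(small_fit):
    spec, catalog, fit = small_fit
    totals = fit.attributed_counts.sum(axis=0)
    np.testing.assert_allclose(totals, catalog.counts.sum(axis=1), rtol=1e-10)


def test_exposure_proportions_sum_to_one(small_fit):
    _, _, fit = small_fit
    np.testing.assert_allclose(fit.exposure_proportions.sum(axis=0), 1.0, atol=1e-10)


def test_ts_label_order_by_attribution(small_fit):
    _, _, fit = small_fit
    assert fit.attributed_counts[2].sum() >= fit.attributed_counts[3].sum()


def test_zero_catalog_no_crash():
    spec = toy_spec(n_patients=2)
    catalog = MutationCatalog(list(spec.tumour_ids), np.zeros((4, N_CONTEXTS), dtype=int))
    fit = fit_signatures(spec, catalog, MCMCSettings(n_samples=40, n_chains=1, burn_in=40, seed=3))
    # prior-dominated: exposures concentrate near zero
    assert np.median(fit.weights[:, [0, 2, 3], :]) < 10.0
    assert np.isfinite(fit.log_joints).all()


def test_seed_required():
    with pytest.raises(ValueError, match="seed"):
        MCMCSettings(n_samples=10, n_chains=1, burn_in=0)


def test_catalog_spec_mismatch_errors(small_fit):
    spec, catalog, _ = small_fit
    bad = MutationCatalog(["x"], np.zeros((1, N_CONTEXTS), dtype=int))
    with pytest.raises(ValueError):
        fit_signatures(spec, bad, MCMCSettings(n_samples=5, n_chains=1, burn_in=0, seed=1))


# ------------------------------------------------------------- matching ----
def test_match_reference_exact():
    rng = np.random.default_rng(0)
    ref = {f"s{i}": rng.dirichlet(np.ones(N_CONTEXTS)) for i in range(4)}
    name, sim = match_reference(ref["s2"], ref)
    assert name == "s2" and sim == pytest.approx(1.0)


def test_match_reference_orthogonal():
    a = np.zeros(N_CONTEXTS)
    a[:10] = 0.1
    b = np.zeros(N_CONTEXTS)
    b[50:60] = 0.1
    name, sim = match_reference(a, {"only": b})
    assert sim == pytest.approx(0.0)


def test_match_reference_empty_errors():
    with pytest.raises(ValueError):
        match_reference(np.ones(N_CONTEXTS) / N_CONTEXTS, {})


def test_cosine_zero_vector():
    assert cosine_similarity(np.zeros(3), np.ones(3)) == 0.0


# ------------------------------------------------------- fraction order ----
def _fit_with_proportions(props_by_tumour):
    tumours = list(props_by_tumour)
    spec = make_model_spec(tumours, {t: "p0" for t in tumours}, {t: "MSS" for t in tumours})
    T = len(tumours)
    W = np.array([props_by_tumour[t] for t in tumours]).T
    from syncrc.model import PosteriorFit

    return PosteriorFit(
        spec=spec,
        signatures=np.zeros((1, 4, N_CONTEXTS)),
        weights=W[None],
        log_joints=np.zeros(1),
        chain_of_draw=np.zeros(1, dtype=int),
        map_index=0,
        attributed_counts=W,
        exposure_proportions=W,
    )


def test_fraction_order_same():
    fit = _fit_with_proportions({"a": [0.6, 0.0, 0.3, 0.1], "b": [0.5, 0.0, 0.4, 0.1]})
    out = signature_fraction_order(fit, "a", "b")
    assert out.same_order
    assert out.orders["a"] == ("patient", "ts1", "ts2", "MSI")


def test_fraction_order_swapped():
    fit = _fit_with_proportions({"a": [0.2, 0.0, 0.5, 0.3], "b": [0.2, 0.0, 0.3, 0.5]})
    assert not signature_fraction_order(fit, "a", "b").same_order


def test_fraction_order_tie_breaks_by_label():
    fit = _fit_with_proportions({"a": [0.4, 0.0, 0.3, 0.3], "b": [0.4, 0.0, 0.3, 0.3]})
    out = signature_fraction_order(fit, "a", "b")
    assert out.ties["a"] and out.same_order
    assert out.orders["a"] == ("patient", "ts1", "ts2", "MSI")


def test_components_constant():
    assert COMPONENTS == ("patient", "MSI", "ts1", "ts2")
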