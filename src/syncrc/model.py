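"""Bayesian four-component mutational-signature model.

Each tumour's 96-context count vector is Poisson with rate
``lambda[t, c] = sum_k w[k, t] * S[k, c]`` where the four signatures
``S`` (patient-intrinsic, MSI, and two tumour-specific components ts1/ts2)
carry flat Dirichlet priors and the exposure weights ``w`` half-Cauchy
priors. The patient component has one weight per patient shared by all of
that patient's tumours (configurable to per-tumour); the MSI weight is
fixed to zero in MSS tumours.

Inference is a data-augmentation Gibbs sampler: each count is allocated to
a component (multinomial, sampled by binomial thinning), signatures are
then conjugate Dirichlet updates, and each weight is refreshed with an
independence Metropolis step whose Gamma proposal matches the allocation
likelihood exactly, so acceptance reduces to the half-Cauchy prior ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln

from .contexts import N_CONTEXTS, MutationCatalog

COMPONENTS = ("patient", "MSI", "ts1", "ts2")
N_COMPONENTS = 4
_PATIENT, _MSI, _TS1, _TS2 = range(4)


@dataclass(frozen=True)
class SignatureModelSpec:
    """Model structure: design maps and prior hyperparameters."""

    tumour_ids: tuple[str, ...]
    patient_of: dict[str, str] = field(hash=False)
    mmr_of: dict[str, str] = field(hash=False)  # tumour -> "MSS" | "MSI"
    halfcauchy_scale: float = 100.0
    dirichlet_alpha: float = 1.0
    shared_patient_weight: bool = True
    msi_weight_in_mss: bool = False  # when True, MSS tumours also get an MSI weight

    def __post_init__(self) -> None:
        for t in self.tumour_ids:
            if t not in self.patient_of:
                raise ValueError(f"tumour {t!r} has no patient mapping")
            if self.mmr_of.get(t) not in ("MSS", "MSI"):
                raise ValueError(f"tumour {t!r} has invalid MMR status {self.mmr_of.get(t)!r}")
        if self.halfcauchy_scale <= 0 or self.dirichlet_alpha <= 0:
            raise ValueError("prior hyperparameters must be strictly positive")

    @property
    def patients(self) -> tuple[str, ...]:
        seen: list[str] = []
        for t in self.tumour_ids:
            p = self.patient_of[t]
            if p not in seen:
                seen.append(p)
        return tuple(seen)

    def msi_mask(self) -> np.ndarray:
        """Boolean per tumour: does the MSI component carry weight here?"""
        if self.msi_weight_in_mss:
            return np.ones(len(self.tumour_ids), dtype=bool)
        return np.array([self.mmr_of[t] == "MSI" for t in self.tumour_ids])


@dataclass
class Parameters:
    """One point in parameter space.

    ``signatures`` is (4, 96); ``weights`` is the expanded (4, n_tumours)
    exposure matrix (patient weights already broadcast to tumours, MSI
    column zero for MSS tumours).
    """

    signatures: np.ndarray
    weights: np.ndarray

    def copy(self) -> "Parameters":
        return Parameters(self.signatures.copy(), self.weights.copy())


def _halfcauchy_logpdf(w: np.ndarray, scale: float) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    return np.log(2.0 / (np.pi * scale)) - np.log1p((w / scale) ** 2)


def log_joint(
    spec: SignatureModelSpec,
    catalog: MutationCatalog,
    params: Parameters,
    lambda_floor: float = 0.0,
) -> float:
    """Log prior + log likelihood; ``-inf`` for out-of-support parameters
    (negative weights, signatures off the simplex, or a positive count in a
    zero-rate context when ``lambda_floor`` is 0)."""
    S = np.asarray(params.signatures, dtype=float)
    W = np.asarray(params.weights, dtype=float)
    T = len(spec.tumour_ids)
    if S.shape != (N_COMPONENTS, N_CONTEXTS) or W.shape != (N_COMPONENTS, T):
        raise ValueError("parameter shapes do not match the model spec")
    if (S < 0).any() or not np.allclose(S.sum(axis=1), 1.0, atol=1e-6):
        return -np.inf
    if (W < 0).any():
        return -np.inf
    msi = spec.msi_mask()
    if (W[_MSI, ~msi] != 0).any():
        return -np.inf

    y = catalog.counts.astype(float)  # (T, 96)
    lam = W.T @ S + lambda_floor  # (T, 96)
    if ((lam <= 0) & (y > 0)).any():
        return -np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        loglam = np.where(lam > 0, np.log(np.where(lam > 0, lam, 1.0)), 0.0)
    loglik = float(np.sum(y * loglam - lam - gammaln(y + 1.0)))

    # half-Cauchy over the free weights (patient weight counted once per
    # patient in shared mode, MSI only where active)
    lp = 0.0
    if spec.shared_patient_weight:
        pat_idx = _first_tumour_index_per_patient(spec)
        lp += float(_halfcauchy_logpdf(W[_PATIENT, pat_idx], spec.halfcauchy_scale).sum())
    else:
        lp += float(_halfcauchy_logpdf(W[_PATIENT], spec.halfcauchy_scale).sum())
    lp += float(_halfcauchy_logpdf(W[_MSI, msi], spec.halfcauchy_scale).sum())
    lp += float(_halfcauchy_logpdf(W[_TS1], spec.halfcauchy_scale).sum())
    lp += float(_halfcauchy_logpdf(W[_TS2], spec.halfcauchy_scale).sum())
    # Dirichlet(alpha) log density on each simplex row
    a = spec.dirichlet_alpha
    logS = np.where(S > 0, np.log(np.where(S > 0, S, 1.0)), 0.0)
    if a != 1.0 and (S == 0).any():
        return -np.inf
    lp += N_COMPONENTS * float(gammaln(N_CONTEXTS * a) - N_CONTEXTS * gammaln(a))
    lp += float((a - 1.0) * logS.sum())
    return lp + loglik


def _first_tumour_index_per_patient(spec: SignatureModelSpec) -> np.ndarray:
    seen: dict[str, int] = {}
    for i, t in enumerate(spec.tumour_ids):
        seen.setdefault(spec.patient_of[t], i)
    return np.array(list(seen.values()), dtype=int)


@dataclass(frozen=True)
class MCMCSettings:
    n_samples: int = 1000  # retained draws per chain
    n_chains: int = 4
    burn_in: int = 500
    thinning: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_chains, self.thinning) < 1 or self.burn_in < 0:
            raise ValueError("MCMC settings must be positive (burn_in >= 0)")
        if self.seed is None:
            raise ValueError("an explicit MCMC seed is required")


#: full-scale settings (10 chains, 10,000 samples, burn-in 500, thinning
#: 100); expensive — desk-scale defaults are in MCMCSettings.
FULL_MCMC = dict(n_samples=10_000, n_chains=10, burn_in=500, thinning=100)


@dataclass
class PosteriorFit:
    spec: SignatureModelSpec
    signatures: np.ndarray  # (n_draws, 4, 96)
    weights: np.ndarray  # (n_draws, 4, T)
    log_joints: np.ndarray  # (n_draws,)
    chain_of_draw: np.ndarray  # (n_draws,)
    map_index: int
    attributed_counts: np.ndarray  # (4, T) at the MAP draw
    exposure_proportions: np.ndarray  # (4, T): component share of total rate

    @property
    def map_parameters(self) -> Parameters:
        return Parameters(self.signatures[self.map_index], self.weights[self.map_index])

    def exposure_table(self) -> dict[str, dict[str, float]]:
        return {
            t: {comp: float(self.exposure_proportions[k, i]) for k, comp in enumerate(COMPONENTS)}
            for i, t in enumerate(self.spec.tumour_ids)
        }


def attribute_counts(
    catalog: MutationCatalog, params: Parameters, spec: SignatureModelSpec
) -> np.ndarray:
    """Expected per-component attribution of observed counts at one draw:
    ``a[k, t] = sum_c y[t, c] * w[k, t] S[k, c] / lambda[t, c]``. The
    attribution fractions sum to one per context, so the components sum
    exactly to each tumour's total observed count."""
    S, W = params.signatures, params.weights
    rates = W[:, :, None] * S[:, None, :]  # (4, T, 96)
    lam = rates.sum(axis=0)
    y = catalog.counts.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(lam > 0, rates / np.where(lam > 0, lam, 1.0), 0.0)
    return (frac * y[None, :, :]).sum(axis=2)


def _sample_allocations(
    rng: np.random.Generator, y: np.ndarray, rates: np.ndarray
) -> np.ndarray:
    """Multinomial allocation of counts ``y`` (T, 96) across the four
    components with unnormalised per-context rates ``rates`` (4, T, 96),
    via sequential binomial thinning (vectorised over tumours/contexts)."""
    remaining = y.astype(np.int64).copy()
    rem_p = rates.sum(axis=0)
    z = np.empty((N_COMPONENTS,) + y.shape, dtype=np.int64)
    for k in range(N_COMPONENTS - 1):
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(rem_p > 0, rates[k] / np.where(rem_p > 0, rem_p, 1.0), 0.0)
        z[k] = rng.binomial(remaining, np.clip(p, 0.0, 1.0))
        remaining -= z[k]
        rem_p = rem_p - rates[k]
    z[N_COMPONENTS - 1] = remaining
    return z


def _mh_weight_update(
    rng: np.random.Generator,
    w: np.ndarray,
    n_alloc: np.ndarray,
    multiplicity: np.ndarray | float,
    scale: float,
) -> np.ndarray:
    """Vectorised independence-MH step on a vector of weights. The full
    conditional is ``w^n * exp(-m w) * halfCauchy(w)``; the Gamma(n+1, m)
    proposal cancels the likelihood term, leaving the prior ratio."""
    proposal = rng.gamma(np.asarray(n_alloc, dtype=float) + 1.0, 1.0 / np.asarray(multiplicity, dtype=float))
    log_ratio = _halfcauchy_logpdf(proposal, scale) - _halfcauchy_logpdf(
        np.maximum(w, 1e-300), scale
    )
    accept = np.log(rng.uniform(size=np.shape(w))) < log_ratio
    return np.where(accept, proposal, w)


def fit_signatures(
    spec: SignatureModelSpec,
    catalog: MutationCatalog,
    mcmc: MCMCSettings,
) -> PosteriorFit:
    """Run the Gibbs sampler and return retained draws plus the MAP draw
    (the retained draw with the highest log joint). ts1/ts2 label switching
    is resolved by ordering the two tumour-specific components by total
    attributed mutations, descending, at the MAP."""
    if list(catalog.tumour_ids) != list(spec.tumour_ids):
        raise ValueError("catalog tumours do not match the model spec")
    if len(catalog.tumour_ids) == 0:
        raise ValueError("catalog is empty")
    y = catalog.counts.astype(np.int64)
    T = y.shape[0]
    msi = spec.msi_mask()
    patients = spec.patients
    pat_index = {p: i for i, p in enumerate(patients)}
    tumour_patient = np.array([pat_index[spec.patient_of[t]] for t in spec.tumour_ids])
    tumours_of_patient = [np.flatnonzero(tumour_patient == i) for i in range(len(patients))]
    first_tumour_idx = np.array([idx[0] for idx in tumours_of_patient])

    ss = np.random.SeedSequence(mcmc.seed)
    chain_seeds = ss.spawn(mcmc.n_chains)

    all_S, all_W, all_lj, all_chain = [], [], [], []
    for chain, cs in enumerate(chain_seeds):
        rng = np.random.default_rng(cs)
        S = rng.dirichlet(np.full(N_CONTEXTS, spec.dirichlet_alpha), size=N_COMPONENTS)
        mean_total = max(float(y.sum(axis=1).mean()), 1.0)
        W = np.full((N_COMPONENTS, T), mean_total / N_COMPONENTS)
        W *= rng.uniform(0.5, 1.5, size=W.shape)
        W[_MSI, ~msi] = 0.0
        if spec.shared_patient_weight:
            for idx in tumours_of_patient:
                W[_PATIENT, idx] = W[_PATIENT, idx[0]]

        patient_sizes = np.array([len(idx) for idx in tumours_of_patient], dtype=float)
        hc = spec.halfcauchy_scale
        n_iter = mcmc.burn_in + mcmc.n_samples * mcmc.thinning
        kept = 0
        for it in range(n_iter):
            # 1. allocations + sufficient statistics
            rates = W[:, :, None] * S[:, None, :]  # (4, T, 96)
            z = _sample_allocations(rng, y, rates)
            sig_counts = z.sum(axis=1)  # (4, 96)
            alloc_tot = z.sum(axis=2)  # (4, T)
            # 2. conjugate signature update
            S = np.vstack(
                [
                    rng.dirichlet(spec.dirichlet_alpha + sig_counts[k].astype(float))
                    for k in range(N_COMPONENTS)
                ]
            )
            np.clip(S, 1e-300, None, out=S)
            S /= S.sum(axis=1, keepdims=True)
            # 3. weight updates
            if spec.shared_patient_weight:
                n_pat = np.bincount(
                    tumour_patient, weights=alloc_tot[_PATIENT], minlength=len(patients)
                )
                w_pat = _mh_weight_update(
                    rng, W[_PATIENT, first_tumour_idx], n_pat, patient_sizes, hc
                )
                W[_PATIENT] = w_pat[tumour_patient]
            else:
                W[_PATIENT] = _mh_weight_update(rng, W[_PATIENT], alloc_tot[_PATIENT], 1.0, hc)
            if msi.any():
                W[_MSI, msi] = _mh_weight_update(
                    rng, W[_MSI, msi], alloc_tot[_MSI, msi], 1.0, hc
                )
            W[_TS1] = _mh_weight_update(rng, W[_TS1], alloc_tot[_TS1], 1.0, hc)
            W[_TS2] = _mh_weight_update(rng, W[_TS2], alloc_tot[_TS2], 1.0, hc)

            if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thinning == 0:
                all_S.append(S.copy())
                all_W.append(W.copy())
                all_lj.append(log_joint(spec, catalog, Parameters(S, W)))
                all_chain.append(chain)
                kept += 1
        if kept != mcmc.n_samples:  # pragma: no cover - arithmetic guard
            raise RuntimeError(f"chain {chain} retained {kept} != {mcmc.n_samples} draws")

    sig_draws = np.array(all_S)
    w_draws = np.array(all_W)
    ljs = np.array(all_lj)
    if not np.isfinite(ljs).any():
        raise RuntimeError("sampling failed: no retained draw has finite log joint")
    map_index = int(np.argmax(ljs))

    map_params = Parameters(sig_draws[map_index], w_draws[map_index])
    attributed = attribute_counts(catalog, map_params, spec)
    # resolve ts1/ts2 label switching: larger total attribution first
    if attributed[_TS2].sum() > attributed[_TS1].sum():
        order = [_PATIENT, _MSI, _TS2, _TS1]
        sig_draws = sig_draws[:, order, :]
        w_draws = w_draws[:, order, :]
        attributed = attributed[order, :]

    W_map = w_draws[map_index]
    totals = W_map.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        proportions = np.where(totals > 0, W_map / np.where(totals > 0, totals, 1.0), 0.0)
    return PosteriorFit(
        spec=spec,
        signatures=sig_draws,
        weights=w_draws,
        log_joints=ljs,
        chain_of_draw=np.array(all_chain),
        map_index=map_index,
        attributed_counts=attributed,
        exposure_proportions=proportions,
    )


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def match_reference(
    signature: np.ndarray, reference: dict[str, np.ndarray]
) -> tuple[str, float]:
    """Best-matching named reference signature by cosine similarity."""
    if not reference:
        raise ValueError("reference signature set is empty")
    best_name, best_sim = "", -1.0
    for name, row in reference.items():
        sim = cosine_similarity(signature, row)
        if sim > best_sim:
            best_name, best_sim = name, sim
    return best_name, best_sim


@dataclass
class FractionOrder:
    orders: dict[str, tuple[str, ...]]  # tumour -> components by descending share
    same_order: bool
    ties: dict[str, bool]


def signature_fraction_order(fit: PosteriorFit, tumour_a: str, tumour_b: str) -> FractionOrder:
    """Rank components by exposure proportion in each tumour of a pair.

    Ties are broken by the fixed component label order
    (patient, MSI, ts1, ts2) and flagged.
    """
    ids = list(fit.spec.tumour_ids)
    for t in (tumour_a, tumour_b):
        if t not in ids:
            raise ValueError(f"tumour {t!r} not covered by this fit")
    orders: dict[str, tuple[str, ...]] = {}
    ties: dict[str, bool] = {}
    for t in (tumour_a, tumour_b):
        props = fit.exposure_proportions[:, ids.index(t)]
        ranked = sorted(range(N_COMPONENTS), key=lambda k: (-props[k], k))
        orders[t] = tuple(COMPONENTS[k] for k in ranked)
        ties[t] = len(set(np.round(props, 12))) < N_COMPONENTS
    return FractionOrder(
        orders=orders, same_order=orders[tumour_a] == orders[tumour_b], ties=ties
    )


def make_model_spec(
    tumour_ids: list[str],
    patient_of: dict[str, str],
    mmr_of: dict[str, str],
    **kwargs,
) -> SignatureModelSpec:
    return SignatureModelSpec(
        tumour_ids=tuple(tumour_ids), patient_of=dict(patient_of), mmr_of=dict(mmr_of), **kwargs
    )
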