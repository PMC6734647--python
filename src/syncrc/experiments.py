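"""Reusable calibration/recovery experiments used by the acceptance
checks: signature parameter recovery on synthetic catalogs and variance-
component recovery for the exposure mixed model."""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .contexts import build_catalog
from .model import MCMCSettings, cosine_similarity, fit_signatures, make_model_spec
from .synthetic import SimulationConfig, simulate_cohort
from .variance import decompose_variance

#: generator settings for the recovery experiment: 10 patients, well-
#: separated truth signatures, several hundred mutations per tumour so the
#: MAP draw is tightly constrained.
RECOVERY_SIM = dict(
    n_patients=10,
    artefact_rate=0.0,
    pair_mmr_probs={"MSS-MSS": 0.5, "MSI-MSI": 0.3, "MSS-MSI": 0.2},
    burden_median_mss=1500.0,
    burden_median_msi=4000.0,
    exposure_scales={"patient": 0.35, "ts1": 0.35, "ts2": 0.30},
)

RECOVERY_MCMC = dict(n_samples=300, n_chains=4, burn_in=800)


def signature_recovery(seed: int) -> np.ndarray:
    """Simulate, fit, and return the four truth-matched MAP cosine
    similarities (optimal assignment)."""
    sim = simulate_cohort(SimulationConfig(seed=seed, **RECOVERY_SIM))
    tumours = list(sim.cohort.frame["tumour"])
    catalog = build_catalog(
        [v for t in tumours for v in sim.somatic_variants(t) if v.variant_class == "SNV"],
        tumours,
    )
    spec = make_model_spec(tumours, sim.cohort.patient_of(), sim.cohort.mmr_of())
    fit = fit_signatures(spec, catalog, MCMCSettings(seed=seed + 1000, **RECOVERY_MCMC))
    S_map = fit.map_parameters.signatures
    truth = sim.truth.signatures
    C = np.array(
        [[cosine_similarity(S_map[i], truth[j]) for j in range(4)] for i in range(4)]
    )
    rows, cols = linear_sum_assignment(-C)
    return C[rows, cols]


def variance_recovery(
    seed: int,
    n_replicates: int = 100,
    n_patients: int = 50,
    tumours_per_patient: int = 3,
) -> np.ndarray:
    """Individual-variance shares recovered from simulated exposure values
    with equal patient and tumour variance (true share 0.5)."""
    rng = np.random.default_rng(seed)
    n, k = n_patients, tumours_per_patient
    patients = np.repeat([f"p{i}" for i in range(n)], k)
    mmr = np.array(["MSI" if i < n // 5 else "MSS" for i in range(n)]).repeat(k)
    shares = np.empty(n_replicates)
    for rep in range(n_replicates):
        patient_effect = rng.normal(0.0, 1.0, n).repeat(k)
        y = 0.3 + 0.1 * (mmr == "MSI") + patient_effect + rng.normal(0.0, 1.0, n * k)
        shares[rep] = decompose_variance(y, patients, mmr).individual_share
    return shares
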