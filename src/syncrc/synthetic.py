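"""Synthetic synchronous-tumour cohort generator.

Produces paired tumours per patient with MSS/MSI statuses, mutation
catalogs drawn from a known four-component signature mixture (one
patient-intrinsic exposure shared by a patient's tumours, an MSI component
active only in MSI tumours, and two tumour-specific components), a
configurable number of exactly-shared variants per pair, read-level
evidence with FFPE-like low-fraction C>T artefacts, and per-region immune
cell densities — all with ground truth retained for testing.

Only coding non-synonymous mutations are simulated; signature-component
draws generate SNVs, while shared-variant injections and artefacts are
tracked separately from the exposure accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import LOCATIONS, CohortTable
from .contexts import CONTEXT_LABELS, N_CONTEXTS
from .records import PanelOfNormals, VariantRecord

PAIR_TYPES = ("MSS-MSS", "MSI-MSI", "MSS-MSI")

#: toy exome: gene -> (contig, start0, end0) half-open coding interval
TOY_EXOME: dict[str, tuple[str, int, int]] = {
    gene: ("chr1" if i % 2 == 0 else "chr2", 10_000 + 12_000 * (i // 2), 10_000 + 12_000 * (i // 2) + 6_000)
    for i, gene in enumerate(
        [
            "APC", "TP53", "KRAS", "BRAF", "PIK3CA", "PTEN", "SMAD4", "ACVR2A",
            "TCF7L2", "ATM", "ERBB2", "CTNNB1", "NRAS", "FBXW7", "MSH3", "MLH1",
            "TGFBR2", "AKT1", "EGFR", "CHEK2", "RPL22", "XPNPEP1", "FAM133A", "GPR98",
        ]
    )
}

CONSEQUENCE_PROBS = {"missense": 0.72, "nonsense": 0.08, "splice": 0.04, "other": 0.16}


def default_truth_signatures() -> np.ndarray:
    """Four stylised, well-separated 96-simplex rows: an ageing-like C>T
    at-CpG signature (patient), a broad C>T MSI-like signature, a
    C>A-dominated and a T>C-dominated tumour-specific signature."""
    S = np.full((4, N_CONTEXTS), 0.05 / N_CONTEXTS)
    for i, lab in enumerate(CONTEXT_LABELS):
        sub = lab[2:5]
        f3 = lab[6]
        if sub == "C>T" and f3 == "G":
            S[0, i] += 0.95 / 16
        if sub == "C>T" and f3 != "G":
            S[1, i] += 0.75 / 36
        if sub == "C>G":
            S[1, i] += 0.20 / 16
        if sub == "C>A":
            S[2, i] += 0.95 / 16
        if sub == "T>C":
            S[3, i] += 0.80 / 16
        if sub == "T>A":
            S[3, i] += 0.15 / 16
    return S / S.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int = 23
    pair_mmr_probs: dict[str, float] = field(
        default_factory=lambda: {"MSS-MSS": 18 / 23, "MSI-MSI": 3 / 23, "MSS-MSI": 2 / 23}
    )
    burden_median_mss: float = 88.5
    burden_median_msi: float = 933.0
    burden_dispersion: float = 0.4
    shared_count_range_mss: tuple[int, int] = (0, 1)
    shared_count_range_msi: tuple[int, int] = (12, 39)
    truth_signatures: np.ndarray = field(default_factory=default_truth_signatures)
    exposure_scales: dict[str, float] = field(
        default_factory=lambda: {"patient": 0.45, "ts1": 0.35, "ts2": 0.20}
    )
    artefact_rate: float = 0.05
    depth_mean: float = 37.0
    depth_dispersion: float = 8.0
    n_germline_per_patient: int = 25
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("explicit seed required")
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        probs = self.pair_mmr_probs
        if set(probs) != set(PAIR_TYPES) or any(p < 0 for p in probs.values()):
            raise ValueError(f"pair_mmr_probs must cover {PAIR_TYPES} with non-negative values")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("pair_mmr_probs must sum to 1")
        S = np.asarray(self.truth_signatures, dtype=float)
        if S.shape != (4, N_CONTEXTS) or (S < 0).any():
            raise ValueError("truth_signatures must be a non-negative 4x96 matrix")
        if not np.allclose(S.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each truth signature must sum to 1 within 1e-9")
        if not 0 <= self.artefact_rate < 1:
            raise ValueError("artefact_rate must lie in [0, 1)")
        for name in ("burden_median_mss", "burden_median_msi", "burden_dispersion",
                     "depth_mean", "depth_dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if any(v <= 0 for v in self.exposure_scales.values()):
            raise ValueError("exposure scales must be strictly positive")
        for rng_ in (self.shared_count_range_mss, self.shared_count_range_msi):
            if rng_[0] < 0 or rng_[1] < rng_[0]:
                raise ValueError(f"invalid shared-count range {rng_}")


@dataclass
class SyntheticTruth:
    exposures: dict[str, dict[str, int]]  # tumour -> component -> count
    shared_variants: dict[str, list[tuple[str, int, str, str]]]  # patient -> keys
    artefacts: dict[str, list[tuple[str, int, str, str]]]  # tumour -> artefact keys
    mmr_of: dict[str, str]
    context_tallies: dict[str, np.ndarray]  # tumour -> 96-vector incl. injections
    signatures: np.ndarray  # the 4x96 truth matrix


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    cohort: CohortTable
    variants: dict[str, list[VariantRecord]]  # tumour and normal samples
    normal_of: dict[str, str]  # patient -> normal sample id
    panel: PanelOfNormals
    germline_afs: dict[tuple[str, int, str, str], tuple[float, float, float]]
    immune_densities: pd.DataFrame
    truth: SyntheticTruth

    def somatic_variants(self, tumour: str) -> list[VariantRecord]:
        """Tumour calls minus germline-contamination echoes (records whose
        locus+alleles are also called in the patient's matched normal)."""
        patient = self.cohort.patient_of()[tumour]
        normal_keys = {v.key for v in self.variants[self.normal_of[patient]]}
        return [v for v in self.variants[tumour] if v.key not in normal_keys]


def _sample_context_variant(rng, context_idx: int, used: set, patient_genes: list[str]):
    """Create locus/alleles for a context: pyrimidine-strand triplet,
    reverse-complemented with probability 1/2."""
    lab = CONTEXT_LABELS[context_idx]
    f5, ref, alt, f3 = lab[0], lab[2], lab[4], lab[6]
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if rng.uniform() < 0.5:  # present on the purine strand
        ref, alt = comp[ref], comp[alt]
        f5, f3 = comp[f3], comp[f5]
    for _ in range(1000):
        gene = patient_genes[rng.integers(len(patient_genes))]
        contig, start, end = TOY_EXOME[gene]
        pos = int(rng.integers(start + 2, end - 1)) + 1  # 1-based, flanks inside
        if (contig, pos) not in used:
            used.add((contig, pos))
            return (contig, pos, ref, alt), f5, f3, gene
    raise RuntimeError("could not place variant without collision")


def _read_evidence(rng, cfg: SimulationConfig, vaf_mean: float = 0.40):
    r = cfg.depth_dispersion
    depth = int(rng.negative_binomial(r, r / (r + cfg.depth_mean))) + 4
    vaf = float(np.clip(rng.beta(vaf_mean * 20, (1 - vaf_mean) * 20), 0.02, 0.98))
    alt = int(np.clip(round(depth * vaf), 1, depth))
    qual = float(rng.uniform(22.0, 60.0))
    return depth, alt, qual


def _consequence(rng) -> str:
    names = list(CONSEQUENCE_PROBS)
    return names[rng.choice(len(names), p=np.array(list(CONSEQUENCE_PROBS.values())))]


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate the full synthetic cohort; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    S = np.asarray(config.truth_signatures, dtype=float)
    genes = sorted(TOY_EXOME)

    pair_types = [
        PAIR_TYPES[i]
        for i in rng.choice(
            len(PAIR_TYPES),
            size=config.n_patients,
            p=np.array([config.pair_mmr_probs[t] for t in PAIR_TYPES]),
        )
    ]

    rows = []
    variants: dict[str, list[VariantRecord]] = {}
    normal_of: dict[str, str] = {}
    exposures: dict[str, dict[str, int]] = {}
    shared_truth: dict[str, list] = {}
    artefact_truth: dict[str, list] = {}
    mmr_of: dict[str, str] = {}
    tallies: dict[str, np.ndarray] = {}
    panel_snv: dict[tuple[str, int, str], int] = {}
    germline_afs: dict = {}
    sigma = config.burden_dispersion
    scales = config.exposure_scales

    for ip in range(config.n_patients):
        patient = f"sim_{ip + 1:03d}"
        ptype = pair_types[ip]
        statuses = {
            "MSS-MSS": ["MSS", "MSS"],
            "MSI-MSI": ["MSI", "MSI"],
            "MSS-MSI": ["MSS", "MSI"] if rng.uniform() < 0.5 else ["MSI", "MSS"],
        }[ptype]
        sex = "M" if rng.uniform() < 18 / 23 else "F"
        age = int(np.clip(round(rng.normal(72, 9)), 40, 92))
        used: set = set()
        tumour_ids = [f"{patient}-{k + 1}" for k in range(2)]
        normal_id = f"{patient}-N"
        normal_of[patient] = normal_id

        # patient-intrinsic exposure rate drawn once, applied to both tumours
        w_pat = rng.lognormal(np.log(scales["patient"] * config.burden_median_mss), sigma)
        adenomas = "Yes" if rng.uniform() < 18 / 23 else "No"

        for tumour, status in zip(tumour_ids, statuses):
            mmr_of[tumour] = status
            location = LOCATIONS[rng.integers(len(LOCATIONS))]
            rows.append(
                {
                    "patient": patient,
                    "sex": sex,
                    "age": age,
                    "tumour": tumour,
                    "location": location,
                    "histology": "ac",
                    "grade": int(rng.integers(1, 4)),
                    "mmr": status,
                    "tnm": f"T{rng.integers(1, 5)}N{rng.integers(0, 3)}M0",
                    "size_cm": round(float(rng.lognormal(np.log(4.5), 0.4)), 1),
                    "adenomas": adenomas,
                }
            )
            w = {
                "patient": w_pat,
                "MSI": (
                    rng.lognormal(
                        np.log(max(config.burden_median_msi - config.burden_median_mss, 1.0)),
                        sigma,
                    )
                    if status == "MSI"
                    else 0.0
                ),
                "ts1": rng.lognormal(np.log(scales["ts1"] * config.burden_median_mss), sigma),
                "ts2": rng.lognormal(np.log(scales["ts2"] * config.burden_median_mss), sigma),
            }
            comp_counts = {k: int(rng.poisson(v)) for k, v in w.items()}
            exposures[tumour] = comp_counts
            tally = np.zeros(N_CONTEXTS, dtype=np.int64)
            recs: list[VariantRecord] = []
            for ki, comp in enumerate(("patient", "MSI", "ts1", "ts2")):
                n_k = comp_counts[comp]
                if n_k == 0:
                    continue
                ctx_draws = rng.choice(N_CONTEXTS, size=n_k, p=S[ki])
                for ctx in ctx_draws:
                    key, f5, f3, gene = _sample_context_variant(rng, int(ctx), used, genes)
                    tally[ctx] += 1
                    depth, alt, qual = _read_evidence(rng, config)
                    recs.append(
                        VariantRecord(
                            sample_id=tumour,
                            contig=key[0],
                            position=key[1],
                            ref_allele=key[2],
                            alt_allele=key[3],
                            variant_class="SNV",
                            total_depth=depth,
                            alt_depth=alt,
                            quality=qual,
                            flank5=f5,
                            flank3=f3,
                            gene=gene,
                            consequence=_consequence(rng),
                            coding=True,
                        )
                    )
            variants[tumour] = recs
            tallies[tumour] = tally
            artefact_truth[tumour] = []

        # exactly-shared variants within the pair
        lo, hi = (
            config.shared_count_range_msi
            if ptype == "MSI-MSI"
            else config.shared_count_range_mss
        )
        n_shared = int(rng.integers(lo, hi + 1))
        shared_truth[patient] = []
        for _ in range(n_shared):
            as_indel = ptype == "MSI-MSI" and rng.uniform() < 0.9
            if as_indel:
                gene = genes[rng.integers(len(genes))]
                contig, start, end = TOY_EXOME[gene]
                for _ in range(1000):
                    pos = int(rng.integers(start + 2, end - 1)) + 1
                    base = "ACGT"[rng.integers(4)]
                    ins = "ACGT"[rng.integers(4)]
                    key = (contig, pos, base, base + ins)
                    if (contig, pos) not in used:
                        used.add((contig, pos))
                        break
                f5 = f3 = None
                consequence = "frameshift"
                vclass = "indel"
                ctx = None
            else:
                ctx = int(rng.integers(N_CONTEXTS))
                key, f5, f3, gene = _sample_context_variant(rng, ctx, used, genes)
                consequence = "missense" if rng.uniform() < 0.5 else "nonsense"
                vclass = "SNV"
            shared_truth[patient].append(key)
            for tumour in tumour_ids:
                depth, alt, qual = _read_evidence(rng, config, vaf_mean=0.35)
                if vclass == "indel":
                    alt = max(alt, int(np.ceil(0.10 * depth)))  # keep VAF above the filter
                variants[tumour].append(
                    VariantRecord(
                        sample_id=tumour,
                        contig=key[0],
                        position=key[1],
                        ref_allele=key[2],
                        alt_allele=key[3],
                        variant_class=vclass,
                        total_depth=depth,
                        alt_depth=alt,
                        quality=qual,
                        flank5=f5,
                        flank3=f3,
                        gene=gene,
                        consequence=consequence,
                        coding=True,
                    )
                )
                if ctx is not None:
                    tallies[tumour][ctx] += 1

        # FFPE-like artefacts: low-fraction C>T SNVs, most with panel support
        for tumour in tumour_ids:
            n_art = int(round(config.artefact_rate * len(variants[tumour])))
            for _ in range(n_art):
                ctx_pool = [i for i, lab in enumerate(CONTEXT_LABELS) if lab[2:5] == "C>T"]
                ctx = ctx_pool[rng.integers(len(ctx_pool))]
                key, f5, f3, gene = _sample_context_variant(rng, ctx, used, genes)
                depth = int(rng.negative_binomial(8, 8 / (8 + config.depth_mean))) + 12
                vaf = float(rng.uniform(0.01, 0.095))
                alt = max(int(depth * vaf), 1)  # floor keeps realised VAF < 10%
                variants[tumour].append(
                    VariantRecord(
                        sample_id=tumour,
                        contig=key[0],
                        position=key[1],
                        ref_allele=key[2],
                        alt_allele=key[3],
                        variant_class="SNV",
                        total_depth=depth,
                        alt_depth=min(alt, depth),
                        quality=float(rng.uniform(20.0, 35.0)),
                        flank5=f5,
                        flank3=f3,
                        gene=gene,
                        consequence=_consequence(rng),
                        coding=True,
                    )
                )
                tallies[tumour][ctx] += 1
                artefact_truth[tumour].append(key)
                if rng.uniform() < 0.7:  # recurrent artefact visible in the panel
                    panel_snv[(key[0], key[1], key[3])] = int(rng.integers(3, 12))

        # germline variants: called in the normal, echoed in the tumours
        recs_n: list[VariantRecord] = []
        for _ in range(config.n_germline_per_patient):
            ctx = int(rng.integers(N_CONTEXTS))
            key, f5, f3, gene = _sample_context_variant(rng, ctx, used, genes)
            depth = int(rng.negative_binomial(8, 8 / (8 + config.depth_mean))) + 8
            het = rng.uniform() < 0.7
            vaf = rng.beta(30, 30) if het else rng.beta(60, 3)
            alt = int(np.clip(round(depth * vaf), 1, depth))
            common = rng.uniform() < 0.6
            afs = (
                (float(rng.uniform(0.01, 0.5)),) * 3
                if common
                else (0.0, float(rng.uniform(0, 0.0008)), float(rng.uniform(0, 0.008)))
            )
            germline_afs[key] = afs
            rec = VariantRecord(
                sample_id=normal_id,
                contig=key[0],
                position=key[1],
                ref_allele=key[2],
                alt_allele=key[3],
                variant_class="SNV",
                total_depth=depth,
                alt_depth=alt,
                quality=float(rng.uniform(20.0, 60.0)),
                flank5=f5,
                flank3=f3,
                gene=gene,
                consequence=_consequence(rng),
                coding=True,
            )
            recs_n.append(rec)
            for tumour in tumour_ids:  # germline contamination of tumour calls
                if rng.uniform() < 0.9:
                    depth_t, alt_t, qual_t = _read_evidence(rng, config, vaf_mean=vaf)
                    variants[tumour].append(
                        VariantRecord(
                            sample_id=tumour,
                            contig=key[0],
                            position=key[1],
                            ref_allele=key[2],
                            alt_allele=key[3],
                            variant_class="SNV",
                            total_depth=depth_t,
                            alt_depth=alt_t,
                            quality=qual_t,
                            flank5=f5,
                            flank3=f3,
                            gene=gene,
                            consequence=rec.consequence,
                            coding=True,
                        )
                    )
        variants[normal_id] = recs_n

    cohort = CohortTable(pd.DataFrame(rows))
    truth = SyntheticTruth(
        exposures=exposures,
        shared_variants=shared_truth,
        artefacts=artefact_truth,
        mmr_of=mmr_of,
        context_tallies=tallies,
        signatures=S,
    )
    immune = simulate_immune_densities(cohort, msi_shift=2.0, seed=int(rng.integers(2**31)))
    return SimulatedCohort(
        config=config,
        cohort=cohort,
        variants=variants,
        normal_of=normal_of,
        panel=PanelOfNormals(snv_support=panel_snv),
        germline_afs=germline_afs,
        immune_densities=immune,
        truth=truth,
    )


IMMUNE_BASE_MEANS = {"CD3_CT": 600.0, "CD3_IM": 700.0, "CD8_CT": 300.0, "CD8_IM": 350.0}


def simulate_immune_densities(
    cohort: CohortTable,
    msi_shift: float,
    seed: int,
    base_means: dict[str, float] | None = None,
    sigma: float = 0.6,
) -> pd.DataFrame:
    """Per-tumour CD3/CD8 densities at centre and margin (cells/mm^2).

    Log-normal draws whose mean is multiplied by ``msi_shift`` for MSI
    tumours; with ``msi_shift=1`` the two groups share one distribution.
    """
    if msi_shift <= 0:
        raise ValueError("msi_shift must be strictly positive")
    base = base_means or IMMUNE_BASE_MEANS
    rng = np.random.default_rng(seed)
    rows = []
    for _, r in cohort.frame.iterrows():
        status = r["mmr"]
        if status not in ("MSS", "MSI"):
            raise ValueError(f"tumour {r['tumour']} lacks a valid MMR status")
        shift = msi_shift if status == "MSI" else 1.0
        row = {"tumour": r["tumour"], "patient": r["patient"], "mmr": status}
        for m, mu in base.items():
            # mean of LogNormal(log(mu * shift) - sigma^2/2, sigma) is mu * shift
            row[m] = float(rng.lognormal(np.log(mu * shift) - sigma**2 / 2, sigma))
        rows.append(row)
    return pd.DataFrame(rows)
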