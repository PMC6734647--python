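"""Immune cell score (IS): four binary high/low indicators from CD3/CD8
densities at tumour centre (CT) and invasive margin (IM), summed to 0-4,
plus within-pair concordance statistics."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MEASUREMENTS = ("CD3_CT", "CD3_IM", "CD8_CT", "CD8_IM")

#: Placeholder cutoffs (cells/mm^2). The original ROC-derived values are
#: not published; any application must supply its own.
DEFAULT_CUTOFFS = {"CD3_CT": 500.0, "CD3_IM": 500.0, "CD8_CT": 250.0, "CD8_IM": 250.0}


@dataclass
class ImmunePanel:
    tumour_id: str
    patient_id: str
    densities: dict[str, float]
    cutoffs: dict[str, float]
    component_scores: dict[str, int]
    score: int  # IS, 0..4
    mmr_status: str | None = None

    def __post_init__(self) -> None:
        assert self.score == sum(self.component_scores.values())
        assert 0 <= self.score <= 4


def compute_is(
    tumour_id: str,
    patient_id: str,
    densities: dict[str, float],
    cutoffs: dict[str, float],
    mmr_status: str | None = None,
) -> ImmunePanel | None:
    """Score one tumour. A density exactly at its cutoff scores high (1).

    Returns None (with a log line) when any of the four measurements is
    missing or non-finite — such tumours are excluded from scoring.
    """
    for m in MEASUREMENTS:
        c = cutoffs.get(m)
        if c is None or not np.isfinite(c) or c <= 0:
            raise ValueError(f"cutoff for {m} must be a positive finite number")
    missing = [
        m
        for m in MEASUREMENTS
        if m not in densities or densities[m] is None or not np.isfinite(densities[m])
    ]
    if missing:
        logger.info("IS: tumour %s excluded, missing %s", tumour_id, ",".join(missing))
        return None
    for m in MEASUREMENTS:
        if densities[m] < 0:
            raise ValueError(f"negative density {m}={densities[m]} for {tumour_id}")
    scores = {m: int(densities[m] >= cutoffs[m]) for m in MEASUREMENTS}
    return ImmunePanel(
        tumour_id=tumour_id,
        patient_id=patient_id,
        densities={m: float(densities[m]) for m in MEASUREMENTS},
        cutoffs={m: float(cutoffs[m]) for m in MEASUREMENTS},
        component_scores=scores,
        score=sum(scores.values()),
        mmr_status=mmr_status,
    )


def score_table(
    densities: pd.DataFrame, cutoffs: dict[str, float]
) -> tuple[list[ImmunePanel], list[str]]:
    """Score a density table (columns: tumour, patient, the four
    measurements, optional mmr). Returns panels and excluded tumour ids."""
    panels, excluded = [], []
    for _, row in densities.iterrows():
        panel = compute_is(
            str(row["tumour"]),
            str(row["patient"]),
            {m: row.get(m, np.nan) for m in MEASUREMENTS},
            cutoffs,
            mmr_status=row.get("mmr"),
        )
        if panel is None:
            excluded.append(str(row["tumour"]))
        else:
            panels.append(panel)
    return panels, excluded


@dataclass
class PairConcordance:
    rho: float
    p_value: float
    n_pairs: int
    pair_scores: list[tuple[str, int, int]]  # (patient, IS first, IS second)
    difference_bins: dict[str, int]  # equal / diff_1 / diff_ge2 over ALL patients
    n_patients_binned: int
    excluded_multi: list[str]


def pair_is_concordance(
    panels: list[ImmunePanel], exclude_multi: bool = True
) -> PairConcordance:
    """Spearman correlation of IS across tumour pairs.

    Within each patient tumours are ordered lexicographically by id; the
    correlation uses (first, second) scores of two-tumour patients, and —
    when ``exclude_multi`` — patients with more than two scored tumours
    are excluded from the correlation. The difference table bins every
    complete patient (including multi-tumour ones, by max-min) into
    equal / differ-by-1 / differ-by->=2.
    """
    by_patient: dict[str, list[ImmunePanel]] = {}
    for p in panels:
        by_patient.setdefault(p.patient_id, []).append(p)

    pair_scores: list[tuple[str, int, int]] = []
    bins = {"equal": 0, "diff_1": 0, "diff_ge2": 0}
    n_binned = 0
    excluded_multi: list[str] = []
    for patient in sorted(by_patient):
        group = sorted(by_patient[patient], key=lambda x: x.tumour_id)
        if len(group) < 2:
            continue
        scores = [g.score for g in group]
        spread = max(scores) - min(scores)
        bins["equal" if spread == 0 else ("diff_1" if spread == 1 else "diff_ge2")] += 1
        n_binned += 1
        if len(group) > 2 and exclude_multi:
            excluded_multi.append(patient)
            continue
        pair_scores.append((patient, scores[0], scores[1]))

    if len(pair_scores) < 3:
        raise ValueError(f"need >=3 complete pairs for concordance, got {len(pair_scores)}")
    first = [s[1] for s in pair_scores]
    second = [s[2] for s in pair_scores]
    rho, p = stats.spearmanr(first, second)
    return PairConcordance(
        rho=float(rho),
        p_value=float(p),
        n_pairs=len(pair_scores),
        pair_scores=pair_scores,
        difference_bins=bins,
        n_patients_binned=n_binned,
        excluded_multi=excluded_multi,
    )


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (reporting rule)."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass
class ISDistribution:
    counts: dict[int, int]  # IS category -> n tumours
    percentages: dict[int, int]  # rounded for reporting
    fractions: dict[int, float]
    n_scored: int
    high_is_fraction_by_group: dict[str, float | None]  # IS3+IS4 share, None if empty


def is_distribution(panels: list[ImmunePanel]) -> ISDistribution:
    """Distribution of IS categories, with the high-IS (IS3 or IS4)
    fraction per MMR group; an empty group reports None, not zero."""
    if not panels:
        raise ValueError("no scored panels")
    n = len(panels)
    counts = {k: 0 for k in range(5)}
    for p in panels:
        counts[p.score] += 1
    fractions = {k: counts[k] / n for k in counts}
    percentages = {k: round_half_away(100.0 * fractions[k]) for k in counts}
    high: dict[str, float | None] = {}
    for group in ("MSS", "MSI"):
        members = [p for p in panels if p.mmr_status == group]
        high[group] = (
            sum(1 for p in members if p.score >= 3) / len(members) if members else None
        )
    return ISDistribution(
        counts=counts,
        percentages=percentages,
        fractions=fractions,
        n_scored=n,
        high_is_fraction_by_group=high,
    )


def long_format_table(panels: list[ImmunePanel]) -> pd.DataFrame:
    """Tidy long-format IS table suitable for external ordinal-GEE
    fitting (one row per tumour)."""
    return pd.DataFrame(
        [
            {
                "patient": p.patient_id,
                "tumour": p.tumour_id,
                "mmr": p.mmr_status,
                **p.densities,
                **{f"score_{m}": p.component_scores[m] for m in MEASUREMENTS},
                "IS": p.score,
            }
            for p in panels
        ]
    )
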