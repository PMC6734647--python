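"""Cohort metadata table and cohort-level summaries."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .immune import round_half_away

#: canonical colorectal segment vocabulary
LOCATIONS = (
    "caecum",
    "ascending",
    "proximal transverse",
    "splenic flexure",
    "descending",
    "sigmoid",
    "rectum",
    "rectosigmoid border",
)

#: source-table spellings mapped onto the canonical vocabulary
LOCATION_ALIASES = {
    "caecum": "caecum",
    "ascendens": "ascending",
    "transversum": "proximal transverse",
    "flexura lienalis": "splenic flexure",
    "descendens": "descending",
    "sigma": "sigmoid",
    "rectum": "rectum",
    "border of rectosigma": "rectosigmoid border",
}

COLUMNS = [
    "patient",
    "sex",
    "age",
    "tumour",
    "location",
    "histology",
    "grade",
    "mmr",
    "tnm",
    "size_cm",
    "adenomas",
]


@dataclass(frozen=True)
class SidednessRule:
    left: frozenset = frozenset(
        {"splenic flexure", "descending", "sigmoid", "rectum", "rectosigmoid border"}
    )
    right: frozenset = frozenset({"caecum", "ascending", "proximal transverse"})

    def __post_init__(self) -> None:
        if self.left & self.right:
            raise ValueError("left and right segment sets overlap")
        if self.left | self.right != set(LOCATIONS):
            raise ValueError("sidedness rule must cover the location vocabulary")

    def side(self, location: str) -> str:
        loc = LOCATION_ALIASES.get(location.strip().lower(), location.strip().lower())
        if loc in self.left:
            return "left"
        if loc in self.right:
            return "right"
        raise ValueError(f"unknown location label: {location!r}")


@dataclass
class CohortTable:
    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        f = self.frame
        bad_mmr = set(f["mmr"]) - {"MSS", "MSI"}
        if bad_mmr:
            raise ValueError(f"invalid MMR statuses: {sorted(bad_mmr)}")
        for patient, grp in f.groupby("patient"):
            if len(grp) < 2:
                raise ValueError(f"patient {patient} has fewer than 2 tumours")
            if grp["sex"].nunique() > 1 or grp["age"].nunique() > 1:
                raise ValueError(f"sex/age vary within patient {patient}")
        if f["tumour"].duplicated().any():
            raise ValueError("duplicate tumour ids")

    @classmethod
    def read_tsv(cls, path) -> "CohortTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"patient": str, "tumour": str}))

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @property
    def patients(self) -> list[str]:
        return list(dict.fromkeys(self.frame["patient"]))

    @property
    def n_tumours(self) -> int:
        return len(self.frame)

    def mmr_of(self) -> dict[str, str]:
        return dict(zip(self.frame["tumour"], self.frame["mmr"]))

    def patient_of(self) -> dict[str, str]:
        return dict(zip(self.frame["tumour"], self.frame["patient"]))


def mmr_pair_type(statuses: list[str]) -> str:
    """Pair type of a patient's MMR multiset (>=3 tumours classified by
    the same rule: homogeneous sets keep their label, mixed is MSS-MSI)."""
    s = set(statuses)
    if s == {"MSS"}:
        return "MSS-MSS"
    if s == {"MSI"}:
        return "MSI-MSI"
    return "MSS-MSI"


def summarize_cohort(table: CohortTable, rule: SidednessRule | None = None) -> dict:
    """Cohort-level summary mirroring the published cohort description."""
    rule = rule or SidednessRule()
    f = table.frame
    patients = table.patients
    n_pat, n_tum = len(patients), len(f)

    per_patient = f.groupby("patient", sort=False)
    sexes = per_patient["sex"].first()
    ages = per_patient["age"].first().astype(float)
    n_male = int((sexes == "M").sum())

    sides = f["location"].map(rule.side)
    n_left = int((sides == "left").sum())
    n_right = n_tum - n_left

    side_by_patient = pd.DataFrame({"patient": f["patient"], "side": sides}).groupby(
        "patient", sort=False
    )["side"]
    same_side = side_by_patient.nunique() == 1
    n_same = int(same_side.sum())
    shared_side = side_by_patient.first()[same_side]
    n_same_left = int((shared_side == "left").sum())

    pair_types = per_patient["mmr"].agg(lambda s: mmr_pair_type(list(s)))
    pair_type_counts = {
        k: int((pair_types == k).sum()) for k in ("MSS-MSS", "MSI-MSI", "MSS-MSI")
    }
    n_any_msi = int(per_patient["mmr"].agg(lambda s: "MSI" in set(s)).sum())

    adenoma = per_patient["adenomas"].agg(
        lambda s: any(str(v).strip().lower() == "yes" for v in s)
    )
    n_adenoma = int(adenoma.sum())

    pct = lambda k, n: round_half_away(100.0 * k / n)  # noqa: E731
    return {
        "n_patients": n_pat,
        "n_tumours": n_tum,
        "n_male": n_male,
        "male_pct": pct(n_male, n_pat),
        "median_age": float(np.median(ages)),
        "age_range": (float(ages.min()), float(ages.max())),
        "n_left": n_left,
        "left_pct": pct(n_left, n_tum),
        "n_right": n_right,
        "right_pct": pct(n_right, n_tum),
        "n_same_side": n_same,
        "same_side_pct": pct(n_same, n_pat),
        "n_same_side_left": n_same_left,
        "same_side_left_pct": pct(n_same_left, n_same) if n_same else None,
        "mmr_pair_types": pair_type_counts,
        "n_adenoma_patients": n_adenoma,
        "n_any_msi_patients": n_any_msi,
        "any_msi_pct": pct(n_any_msi, n_pat),
    }


def _iqr(values: np.ndarray) -> tuple[float, float]:
    """Quartiles by linear interpolation (numpy default, a.k.a. type 7)."""
    return (
        float(np.percentile(values, 25, method="linear")),
        float(np.percentile(values, 75, method="linear")),
    )


def burden_summary(counts: dict[str, int], table: CohortTable) -> dict:
    """Median/IQR of non-synonymous counts by MMR group plus within-pair
    absolute differences (max - min for patients with >2 tumours)."""
    f = table.frame
    missing = [t for t in f["tumour"] if t not in counts]
    if missing:
        raise ValueError(f"missing mutation counts for tumours: {missing}")
    mmr = table.mmr_of()
    by_group: dict[str, list[int]] = {"MSS": [], "MSI": []}
    for t in f["tumour"]:
        by_group[mmr[t]].append(counts[t])

    group_stats = {}
    for g, vals in by_group.items():
        if vals:
            arr = np.array(vals, dtype=float)
            group_stats[g] = {"n": len(vals), "median": float(np.median(arr)), "iqr": _iqr(arr)}
        else:
            group_stats[g] = {"n": 0, "median": None, "iqr": None}

    pair_diffs: dict[str, int] = {}
    diffs_by_type: dict[str, list[int]] = {}
    for patient, grp in f.groupby("patient", sort=False):
        vals = [counts[t] for t in grp["tumour"]]
        d = max(vals) - min(vals)
        pair_diffs[patient] = d
        diffs_by_type.setdefault(mmr_pair_type(list(grp["mmr"])), []).append(d)

    diff_stats = {}
    for ptype, ds in diffs_by_type.items():
        arr = np.array(ds, dtype=float)
        diff_stats[ptype] = {"n": len(ds), "median": float(np.median(arr)), "iqr": _iqr(arr)}
    return {"by_group": group_stats, "pair_differences": pair_diffs, "diff_by_pair_type": diff_stats}
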