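"""Somatic and germline variant filters.

Each filter is a pure function over :class:`~syncrc.records.VariantRecord`
lists; rejected records are returned alongside the first rule they failed,
so filter behaviour is fully auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .records import (
    FilterParams,
    IntervalSet,
    PanelOfNormals,
    VariantRecord,
    left_normalize,
)

logger = logging.getLogger(__name__)

# rule names, in evaluation order
RULE_MATCHED_NORMAL = "matched_normal"
RULE_PANEL_SNV = "panel_snv"
RULE_PANEL_INDEL = "panel_indel"
RULE_TARGET = "off_target"
RULE_CALLABILITY = "uncallable"
RULE_DEPTH = "low_depth"
RULE_QUALITY = "low_quality"
RULE_INDEL_VAF = "indel_low_vaf"
RULE_NONCODING = "noncoding"
RULE_AF_GLOBAL = "af_global"
RULE_AF_FIN_EXOME = "af_finnish_exome"
RULE_AF_FIN_GENOME = "af_finnish_genome"
RULE_VAF = "low_vaf"


@dataclass
class FilterResult:
    passed: list[VariantRecord]
    rejected: list[tuple[VariantRecord, str]]

    def rejection_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, rule in self.rejected:
            out[rule] = out.get(rule, 0) + 1
        return out


def _normal_key_index(
    normal_calls: list[VariantRecord], min_alt_reads: int
) -> set[tuple[str, int, str, str]]:
    keys = set()
    for n in normal_calls:
        if n.alt_depth >= min_alt_reads:
            pos, ref, alt = left_normalize(n.position, n.ref_allele, n.alt_allele)
            keys.add((n.contig, pos, ref, alt))
    return keys


def _check_same_patient(records: list[VariantRecord], patient_of) -> None:
    patients = {patient_of(r.sample_id) for r in records}
    if len(patients) > 1:
        raise ValueError(f"records span multiple patients: {sorted(patients)}")


def somatic_failure(
    v: VariantRecord,
    normal_keys: set[tuple[str, int, str, str]],
    panel: PanelOfNormals,
    target_regions: IntervalSet,
    callability_mask: IntervalSet,
    params: FilterParams,
) -> str | None:
    """First failing somatic rule for one record, or None if it passes."""
    pos, ref, alt = left_normalize(v.position, v.ref_allele, v.alt_allele)
    if (v.contig, pos, ref, alt) in normal_keys:
        return RULE_MATCHED_NORMAL
    if v.variant_class == "SNV":
        if panel.snv_reads(v.contig, pos, alt) >= params.panel_snv_max_reads:
            return RULE_PANEL_SNV
    elif v.variant_class == "indel":
        n_samples = panel.indel_samples_nearby(
            v.contig, pos, params.panel_indel_window, params.panel_indel_min_reads
        )
        if n_samples >= params.panel_indel_sample_threshold:
            return RULE_PANEL_INDEL
    else:  # pragma: no cover - VariantRecord validates the class
        raise ValueError(f"unknown variant_class {v.variant_class!r}")
    if not target_regions.contains(v.contig, pos):
        return RULE_TARGET
    if not callability_mask.contains(v.contig, pos):
        return RULE_CALLABILITY
    if v.total_depth < params.somatic_min_depth:
        return RULE_DEPTH
    if v.quality < params.somatic_min_qual:
        return RULE_QUALITY
    if v.variant_class == "indel" and v.vaf < params.indel_min_vaf:
        return RULE_INDEL_VAF
    return None


def filter_somatic(
    tumour_calls: list[VariantRecord],
    normal_calls: list[VariantRecord],
    panel: PanelOfNormals,
    target_regions: IntervalSet,
    callability_mask: IntervalSet,
    params: FilterParams | None = None,
    patient_of=None,
) -> FilterResult:
    """Apply the somatic filter chain to one tumour's calls.

    A call survives iff it has no matching (left-normalised locus+alleles)
    call in the matched normal, passes the panel-of-normals rule for its
    class, lies inside both the target regions and the callability mask,
    meets the depth/quality thresholds, and (indels only) has VAF at or
    above the indel minimum.

    ``patient_of`` maps sample_id -> patient_id; when given, tumour and
    normal calls are checked to come from a single patient.
    """
    params = params or FilterParams()
    if patient_of is not None:
        _check_same_patient(list(tumour_calls) + list(normal_calls), patient_of)
    normal_keys = _normal_key_index(normal_calls, params.normal_min_alt_reads)
    passed: list[VariantRecord] = []
    rejected: list[tuple[VariantRecord, str]] = []
    for v in tumour_calls:
        rule = somatic_failure(v, normal_keys, panel, target_regions, callability_mask, params)
        if rule is None:
            passed.append(v)
        else:
            rejected.append((v, rule))
    result = FilterResult(passed=passed, rejected=rejected)
    logger.info(
        "filter_somatic: %d in, %d passed, rejections=%s",
        len(tumour_calls),
        len(passed),
        result.rejection_counts(),
    )
    return result


def germline_failure(
    v: VariantRecord,
    afs: tuple[float, float, float],
    target_regions: IntervalSet,
    params: FilterParams,
) -> str | None:
    """First failing germline rule, or None. ``afs`` is (global, Finnish
    exome, Finnish genome) population allele frequency."""
    af_global, af_fin_ex, af_fin_ge = afs
    for name, af in (("global", af_global), ("fin_exome", af_fin_ex), ("fin_genome", af_fin_ge)):
        if af < 0:
            raise ValueError(f"negative {name} allele frequency for {v.key}: {af}")
    if not v.coding:
        return RULE_NONCODING
    if not target_regions.contains(v.contig, v.position):
        return RULE_TARGET
    if af_global > params.af_max_global:
        return RULE_AF_GLOBAL
    if af_fin_ex > params.af_max_finnish_exome:
        return RULE_AF_FIN_EXOME
    if af_fin_ge > params.af_max_finnish_genome:
        return RULE_AF_FIN_GENOME
    if v.total_depth < params.germline_min_depth:
        return RULE_DEPTH
    if v.quality < params.germline_min_qual:
        return RULE_QUALITY
    if v.vaf < params.germline_min_vaf:
        return RULE_VAF
    return None


def filter_germline(
    normal_calls: list[VariantRecord],
    af_annotations: dict[tuple[str, int, str, str], tuple[float, float, float]],
    target_regions: IntervalSet,
    params: FilterParams | None = None,
) -> FilterResult:
    """Rare-variant germline filter.

    Retained iff coding, in-target, every population AF at or below its
    threshold (absent annotation counts as AF 0), depth/quality above the
    germline minima, and VAF >= the germline minimum.
    """
    params = params or FilterParams()
    passed: list[VariantRecord] = []
    rejected: list[tuple[VariantRecord, str]] = []
    for v in normal_calls:
        afs = af_annotations.get(v.key, (0.0, 0.0, 0.0))
        rule = germline_failure(v, afs, target_regions, params)
        if rule is None:
            passed.append(v)
        else:
            rejected.append((v, rule))
    result = FilterResult(passed=passed, rejected=rejected)
    logger.info(
        "filter_germline: %d in, %d passed, rejections=%s",
        len(normal_calls),
        len(passed),
        result.rejection_counts(),
    )
    return result
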