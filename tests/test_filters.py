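"""Filter tests, including an independently written brute-force oracle."""

import numpy as np
import pytest

from syncrc.filters import (
    RULE_AF_GLOBAL,
    RULE_INDEL_VAF,
    RULE_PANEL_SNV,
    filter_germline,
    filter_somatic,
)
from syncrc.records import FilterParams, IntervalSet, PanelOfNormals, VariantRecord
from tests.conftest import mk_indel, mk_snv

EVERYTHING = IntervalSet.everything(["chr1", "chr2"])
EMPTY_PANEL = PanelOfNormals()


# ---------------------------------------------------------------- oracle ---
def oracle_somatic_keep(v, normal_calls, panel, targets, mask, p):
    """Literal re-statement of the somatic rules, written independently of
    the implementation (no left-normalisation shortcuts: applied inline)."""

    def norm(pos, ref, alt):
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt, pos = ref[1:], alt[1:], pos + 1
        return pos, ref, alt

    vpos, vref, valt = norm(v.position, v.ref_allele, v.alt_allele)
    for n in normal_calls:
        if (v.contig,) + norm(n.position, n.ref_allele, n.alt_allele) == (
            n.contig,
            vpos,
            vref,
            valt,
        ) and n.contig == v.contig:
            return False
    if v.variant_class == "SNV":
        if panel.snv_support.get((v.contig, vpos, valt), 0) >= p.panel_snv_max_reads:
            return False
    else:
        samples = set()
        for (ctg, pos), counts in panel.indel_support.items():
            if ctg == v.contig and abs(pos - vpos) <= p.panel_indel_window:
                for i, c in enumerate(counts):
                    if c > p.panel_indel_min_reads:
                        samples.add(i)
        if len(samples) >= p.panel_indel_sample_threshold:
            return False
    if not targets.contains(v.contig, vpos) or not mask.contains(v.contig, vpos):
        return False
    if v.total_depth < p.somatic_min_depth or v.quality < p.somatic_min_qual:
        return False
    if v.variant_class == "indel":
        if v.alt_depth / v.total_depth < p.indel_min_vaf:
            return False
    return True


def oracle_germline_keep(v, afs, targets, p):
    a, b, c = afs.get(v.key, (0.0, 0.0, 0.0))
    return (
        v.coding
        and targets.contains(v.contig, v.position)
        and a <= p.af_max_global
        and b <= p.af_max_finnish_exome
        and c <= p.af_max_finnish_genome
        and v.total_depth >= p.germline_min_depth
        and v.quality >= p.germline_min_qual
        and v.alt_depth / v.total_depth >= p.germline_min_vaf
    )


def random_records(rng, n, sample="t"):
    recs = []
    for i in range(n):
        is_indel = rng.uniform() < 0.3
        depth = int(rng.integers(1, 80))
        alt = int(rng.integers(0, depth + 1))
        qual = float(rng.uniform(0, 60))
        pos = int(rng.integers(1, 3000))
        contig = "chr1" if rng.uniform() < 0.5 else "chr2"
        if is_indel:
            base = "ACGT"[rng.integers(4)]
            ins = "ACGT"[rng.integers(4)]
            ref, altn = (base, base + ins) if rng.uniform() < 0.5 else (base + ins, base)
            recs.append(
                VariantRecord(
                    sample_id=sample,
                    contig=contig,
                    position=pos,
                    ref_allele=ref,
                    alt_allele=altn,
                    variant_class="indel",
                    total_depth=depth,
                    alt_depth=alt,
                    quality=qual,
                    coding=bool(rng.uniform() < 0.8),
                )
            )
        else:
            ref = "ACGT"[rng.integers(4)]
            altn = [b for b in "ACGT" if b != ref][rng.integers(3)]
            recs.append(
                VariantRecord(
                    sample_id=sample,
                    contig=contig,
                    position=pos,
                    ref_allele=ref,
                    alt_allele=altn,
                    variant_class="SNV",
                    total_depth=depth,
                    alt_depth=alt,
                    quality=qual,
                    coding=bool(rng.uniform() < 0.8),
                )
            )
    return recs


def random_panel(rng, records):
    snv = {}
    indel = {}
    for v in records:
        if rng.uniform() < 0.15:
            if v.variant_class == "SNV":
                snv[(v.contig, v.position, v.alt_allele)] = int(rng.integers(0, 8))
            else:
                shift = int(rng.integers(-150, 151))
                indel[(v.contig, max(v.position + shift, 1))] = [
                    int(rng.integers(0, 8)) for _ in range(10)
                ]
    return PanelOfNormals(snv_support=snv, indel_support=indel)


# -------------------------------------------------------------- examples ---
def test_panel_snv_boundary_rejected():
    v = mk_snv(pos=100)
    panel = PanelOfNormals(snv_support={("chr1", 100, "T"): 3})
    res = filter_somatic([v], [], panel, EVERYTHING, EVERYTHING)
    assert res.passed == []
    assert res.rejected[0][1] == RULE_PANEL_SNV


def test_depth_quality_boundary_retained():
    v = mk_snv(depth=4, alt_depth=2, qual=20.0)
    res = filter_somatic([v], [], EMPTY_PANEL, EVERYTHING, EVERYTHING)
    assert res.passed == [v]


def test_indel_vaf_boundary():
    lo = mk_indel(depth=50, alt_depth=4)
    hi = mk_indel(depth=50, alt_depth=5)
    res = filter_somatic([lo, hi], [], EMPTY_PANEL, EVERYTHING, EVERYTHING)
    assert res.passed == [hi]
    assert res.rejected[0][1] == RULE_INDEL_VAF


def test_empty_input():
    res = filter_somatic([], [], EMPTY_PANEL, EVERYTHING, EVERYTHING)
    assert res.passed == [] and res.rejected == []


def test_matched_normal_subtraction():
    t = mk_snv(sample="t1", pos=55)
    n = mk_snv(sample="nrm", pos=55)
    res = filter_somatic([t], [n], EMPTY_PANEL, EVERYTHING, EVERYTHING)
    assert res.passed == []


def test_normal_subtraction_left_normalised():
    t = mk_indel(sample="t1", pos=10, ref="A", alt="AT", alt_depth=10)
    n = VariantRecord(
        sample_id="nrm",
        contig="chr1",
        position=9,
        ref_allele="CA",
        alt_allele="CAT",
        variant_class="indel",
        total_depth=30,
        alt_depth=15,
        quality=50.0,
    )
    res = filter_somatic([t], [n], EMPTY_PANEL, EVERYTHING, EVERYTHING)
    assert res.passed == []


def test_mismatched_patient_errors():
    t = mk_snv(sample="t1")
    n = mk_snv(sample="n_other")
    with pytest.raises(ValueError, match="patients"):
        filter_somatic([t], [n], EMPTY_PANEL, EVERYTHING, EVERYTHING, patient_of=lambda s: s)


def test_germline_af_global_rejected():
    v = mk_snv(depth=30, alt_depth=15)
    res = filter_germline([v], {v.key: (0.002, 0.0, 0.0)}, EVERYTHING)
    assert res.passed == []
    assert res.rejected[0][1] == RULE_AF_GLOBAL


def test_germline_boundary_retained():
    v = mk_snv(depth=10, alt_depth=5, qual=20.0)
    res = filter_germline([v], {v.key: (0.0, 0.0, 0.0)}, EVERYTHING)
    assert res.passed == [v]


def test_germline_fin_genome_rejected():
    v = mk_snv(depth=30, alt_depth=15)
    res = filter_germline([v], {v.key: (0.0, 0.0, 0.02)}, EVERYTHING)
    assert res.passed == []


def test_germline_negative_af_errors():
    v = mk_snv()
    with pytest.raises(ValueError, match="negative"):
        filter_germline([v], {v.key: (-0.1, 0.0, 0.0)}, EVERYTHING)


# ------------------------------------------------------------ properties ---
def test_somatic_oracle_equivalence(rng):
    params = FilterParams()
    targets = IntervalSet({"chr1": [(0, 2000)], "chr2": [(500, 2500)]})
    mask = IntervalSet({"chr1": [(0, 1800)], "chr2": [(0, 3000)]})
    tumour = random_records(rng, 200, "t")
    normal = [v.with_sample("n") for v in tumour if rng.uniform() < 0.2] + random_records(
        rng, 30, "n"
    )
    panel = random_panel(rng, tumour)
    res = filter_somatic(tumour, normal, panel, targets, mask, params)
    expected = [v for v in tumour if oracle_somatic_keep(v, normal, panel, targets, mask, params)]
    assert res.passed == expected


def test_germline_oracle_equivalence(rng):
    params = FilterParams()
    targets = IntervalSet({"chr1": [(0, 2500)], "chr2": [(0, 2500)]})
    normal = random_records(rng, 200, "n")
    afs = {}
    for v in normal:
        if rng.uniform() < 0.7:
            afs[v.key] = (
                float(rng.uniform(0, 0.003)),
                float(rng.uniform(0, 0.003)),
                float(rng.uniform(0, 0.03)),
            )
    res = filter_germline(normal, afs, targets, params)
    expected = [v for v in normal if oracle_germline_keep(v, afs, targets, params)]
    assert res.passed == expected


def test_monotonicity_in_depth_and_quality(rng):
    tumour = random_records(rng, 150)
    base = filter_somatic(tumour, [], EMPTY_PANEL, EVERYTHING, EVERYTHING, FilterParams())
    for stricter in (
        FilterParams(somatic_min_depth=10),
        FilterParams(somatic_min_qual=35.0),
        FilterParams(somatic_min_depth=10, somatic_min_qual=35.0),
    ):
        res = filter_somatic(tumour, [], EMPTY_PANEL, EVERYTHING, EVERYTHING, stricter)
        assert set(v.key for v in res.passed) <= set(v.key for v in base.passed)


def test_idempotence(rng):
    params = FilterParams()
    tumour = random_records(rng, 150)
    normal = random_records(rng, 30, "n")
    panel = random_panel(rng, tumour)
    once = filter_somatic(tumour, normal, panel, EVERYTHING, EVERYTHING, params).passed
    twice = filter_somatic(once, normal, panel, EVERYTHING, EVERYTHING, params).passed
    assert once == twice


def test_rejection_annotation_first_rule():
    v = mk_snv(pos=100, depth=2, alt_depth=1, qual=5.0)  # fails depth AND quality
    panel = PanelOfNormals(snv_support={("chr1", 100, "T"): 5})  # and panel
    res = filter_somatic([v], [], panel, EVERYTHING, EVERYTHING)
    assert res.rejected[0][1] == RULE_PANEL_SNV  # panel rule evaluated first


def test_synthetic_artefacts_mostly_filtered(small_sim):
    """Panel-supported FFPE artefacts are removed by the somatic filter."""
    from syncrc.synthetic import TOY_EXOME

    intervals = {}
    for contig, start, end in TOY_EXOME.values():
        intervals.setdefault(contig, []).append((start, end))
    targets = IntervalSet(intervals)
    removed = kept = 0
    for patient in small_sim.cohort.patients:
        normal = small_sim.variants[small_sim.normal_of[patient]]
        for tumour in small_sim.cohort.frame.loc[
            small_sim.cohort.frame["patient"] == patient, "tumour"
        ]:
            res = filter_somatic(
                small_sim.variants[tumour], normal, small_sim.panel, targets, EVERYTHING
            )
            passed_keys = {v.key for v in res.passed}
            for key in small_sim.truth.artefacts[tumour]:
                if key in passed_keys:
                    kept += 1
                else:
                    removed += 1
    assert removed > kept  # the 70% panel-supported majority is caught
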