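"""Within-pair genetic overlap: exact shared mutations, known-gene
concordance, truncating-gene overlap, and pathway overlap."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .records import NON_SYNONYMOUS, TRUNCATING, VariantRecord

logger = logging.getLogger(__name__)


def _nonsyn(variants: list[VariantRecord]) -> list[VariantRecord]:
    return [v for v in variants if v.coding and v.consequence in NON_SYNONYMOUS]


def _check_patient(a: list[VariantRecord], b: list[VariantRecord], patient_of) -> None:
    if patient_of is None:
        return
    pats = {patient_of(v.sample_id) for v in a} | {patient_of(v.sample_id) for v in b}
    if len(pats) > 1:
        raise ValueError(f"tumours belong to different patients: {sorted(pats)}")


@dataclass
class PairOverlap:
    patient_id: str | None
    tumour_ids: tuple[str, str]
    shared_variants: list[tuple[str, int, str, str]]
    n_shared: int
    n_total_pair: int  # union of non-synonymous variants across the pair
    shared_fraction: float
    per_tumour_counts: dict[str, int] = field(default_factory=dict)


def shared_mutations(
    tumour_a: list[VariantRecord],
    tumour_b: list[VariantRecord],
    *,
    patient_id: str | None = None,
    patient_of=None,
    nonsynonymous_only: bool = True,
) -> PairOverlap:
    """Exact shared mutations between two tumours of one pair.

    A variant is shared iff contig, position, ref and alt all match.
    Counts and the shared fraction (shared / union) are computed over
    coding non-synonymous variants unless ``nonsynonymous_only=False``.
    """
    _check_patient(tumour_a, tumour_b, patient_of)
    va = _nonsyn(tumour_a) if nonsynonymous_only else list(tumour_a)
    vb = _nonsyn(tumour_b) if nonsynonymous_only else list(tumour_b)
    keys_a = {v.key for v in va}
    keys_b = {v.key for v in vb}
    shared = sorted(keys_a & keys_b)
    union = keys_a | keys_b
    ids = (
        va[0].sample_id if va else "tumour_a",
        vb[0].sample_id if vb else "tumour_b",
    )
    n_union = len(union)
    return PairOverlap(
        patient_id=patient_id,
        tumour_ids=ids,
        shared_variants=list(shared),
        n_shared=len(shared),
        n_total_pair=n_union,
        shared_fraction=len(shared) / n_union if n_union else 0.0,
        per_tumour_counts={ids[0]: len(keys_a), ids[1]: len(keys_b)},
    )


@dataclass
class GeneConcordance:
    gene: str
    status_a: str  # "mutated" | "wild-type"
    status_b: str
    pair_status: str  # "both" | "one" | "neither"
    exact_same_change: bool


def gene_concordance(
    tumour_a: list[VariantRecord],
    tumour_b: list[VariantRecord],
    gene_panel: list[str],
    *,
    patient_of=None,
) -> list[GeneConcordance]:
    """Mutated / wild-type status per panel gene in each tumour of a pair.

    ``exact_same_change`` is true iff the two tumours share a variant
    (identical locus+alleles) annotated to that gene.
    """
    if not gene_panel:
        raise ValueError("gene panel must not be empty")
    _check_patient(tumour_a, tumour_b, patient_of)
    va, vb = _nonsyn(tumour_a), _nonsyn(tumour_b)
    genes_a = {v.gene for v in va if v.gene}
    genes_b = {v.gene for v in vb if v.gene}
    shared_keys = {v.key for v in va} & {v.key for v in vb}
    shared_genes = {v.gene for v in va if v.key in shared_keys and v.gene}
    out = []
    for gene in gene_panel:
        in_a, in_b = gene in genes_a, gene in genes_b
        pair_status = "both" if (in_a and in_b) else ("one" if (in_a or in_b) else "neither")
        out.append(
            GeneConcordance(
                gene=gene,
                status_a="mutated" if in_a else "wild-type",
                status_b="mutated" if in_b else "wild-type",
                pair_status=pair_status,
                exact_same_change=gene in shared_genes,
            )
        )
    return out


def truncating_overlap(
    tumour_a: list[VariantRecord],
    tumour_b: list[VariantRecord],
    *,
    exclude_genes: set[str] | None = None,
    exclude_exact_shared: bool = True,
    truncating_consequences: frozenset[str] = TRUNCATING,
    patient_of=None,
) -> set[str]:
    """Genes carrying a truncating mutation in BOTH tumours of a pair.

    Excluded: genes in ``exclude_genes``, and — when
    ``exclude_exact_shared`` — genes whose only qualifying variants are the
    exact same change in both tumours. Records without a consequence
    annotation are ignored (logged).
    """
    _check_patient(tumour_a, tumour_b, patient_of)
    exclude_genes = exclude_genes or set()

    def trunc_by_gene(variants):
        n_missing = 0
        out: dict[str, set] = {}
        for v in variants:
            if v.consequence is None:
                n_missing += 1
                continue
            if v.consequence in truncating_consequences and v.gene:
                out.setdefault(v.gene, set()).add(v.key)
        if n_missing:
            logger.info("truncating_overlap: %d records without consequence ignored", n_missing)
        return out

    ta, tb = trunc_by_gene(tumour_a), trunc_by_gene(tumour_b)
    result = set()
    for gene in set(ta) & set(tb):
        if gene in exclude_genes:
            continue
        if exclude_exact_shared:
            shared = ta[gene] & tb[gene]
            # gene qualifies only if at least one tumour has a private
            # truncating variant in it
            if not (ta[gene] - shared) and not (tb[gene] - shared):
                continue
        result.add(gene)
    return result


@dataclass
class PathwayOverlap:
    status: dict[str, str]  # pathway -> "both" | "one" | "neither"
    n_overlapping: int  # pathways altered in both tumours
    genes_hit: dict[str, tuple[frozenset, frozenset]]


def pathway_overlap(
    tumour_a: list[VariantRecord],
    tumour_b: list[VariantRecord],
    pathway_gene_sets: dict[str, set[str]],
    *,
    patient_of=None,
) -> PathwayOverlap:
    """Pathway-level overlap: a pathway is altered in a tumour iff at least
    one non-synonymously mutated gene belongs to its gene set."""
    _check_patient(tumour_a, tumour_b, patient_of)
    genes_a = {v.gene for v in _nonsyn(tumour_a) if v.gene}
    genes_b = {v.gene for v in _nonsyn(tumour_b) if v.gene}
    status: dict[str, str] = {}
    genes_hit: dict[str, tuple[frozenset, frozenset]] = {}
    n_both = 0
    for pw, genes in pathway_gene_sets.items():
        hit_a = frozenset(genes_a & genes)
        hit_b = frozenset(genes_b & genes)
        if hit_a and hit_b:
            status[pw] = "both"
            n_both += 1
        elif hit_a or hit_b:
            status[pw] = "one"
        else:
            status[pw] = "neither"
        genes_hit[pw] = (hit_a, hit_b)
    return PathwayOverlap(status=status, n_overlapping=n_both, genes_hit=genes_hit)


def patient_pairs(tumour_ids: list[str]) -> list[tuple[str, str]]:
    """All unordered tumour pairs, lexicographically ordered — patients
    with three tumours yield all three pairwise comparisons."""
    ids = sorted(tumour_ids)
    return [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]
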