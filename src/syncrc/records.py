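"""Core record types shared across the pipeline: variants, filter
parameters, panel-of-normals evidence, and genomic interval sets."""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field, replace

VALID_CONSEQUENCES = frozenset(
    {"synonymous", "missense", "nonsense", "frameshift", "splice", "other"}
)
NON_SYNONYMOUS = frozenset({"missense", "nonsense", "frameshift", "splice", "other"})
TRUNCATING = frozenset({"nonsense", "frameshift", "splice"})


@dataclass(frozen=True)
class VariantRecord:
    """One called variant with read-level evidence and annotation.

    Positions are 1-based (VCF convention). ``flank5``/``flank3`` are the
    reference bases immediately up/downstream of ``position`` as carried on
    the record itself (no reference FASTA needed).
    """

    sample_id: str
    contig: str
    position: int
    ref_allele: str
    alt_allele: str
    variant_class: str  # "SNV" | "indel"
    total_depth: int
    alt_depth: int
    quality: float
    flank5: str | None = None
    flank3: str | None = None
    gene: str | None = None
    consequence: str | None = None
    coding: bool = True

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        for name, a in (("ref_allele", self.ref_allele), ("alt_allele", self.alt_allele)):
            if not a or any(b not in "ACGT" for b in a):
                raise ValueError(f"{name} must be a non-empty uppercase ACGT string: {a!r}")
        if self.variant_class not in ("SNV", "indel"):
            raise ValueError(f"unknown variant_class {self.variant_class!r}")
        is_snv = len(self.ref_allele) == 1 and len(self.alt_allele) == 1
        if (self.variant_class == "SNV") != is_snv:
            raise ValueError(
                f"variant_class {self.variant_class!r} inconsistent with alleles "
                f"{self.ref_allele}>{self.alt_allele}"
            )
        if not 0 <= self.alt_depth <= self.total_depth:
            raise ValueError(
                f"alt_depth {self.alt_depth} out of range for depth {self.total_depth}"
            )
        if self.quality < 0:
            raise ValueError("quality must be non-negative")
        if self.consequence is not None and self.consequence not in VALID_CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")

    @property
    def vaf(self) -> float:
        return self.alt_depth / self.total_depth if self.total_depth else 0.0

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity of the genomic change: (contig, pos, ref, alt)."""
        return (self.contig, self.position, self.ref_allele, self.alt_allele)

    def with_sample(self, sample_id: str) -> "VariantRecord":
        return replace(self, sample_id=sample_id)


def left_normalize(position: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim a shared allele suffix then prefix (keeping one anchor base),
    the usual VCF left-alignment-without-reference normalisation."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        position += 1
    return position, ref, alt


@dataclass
class PanelOfNormals:
    """Pooled evidence from unrelated normal samples.

    ``snv_support`` maps (contig, pos, alt) -> pooled supporting read count.
    ``indel_support`` maps (contig, pos) -> per-sample supporting read
    counts at that (left-normalised) indel locus.
    """

    snv_support: dict[tuple[str, int, str], int] = field(default_factory=dict)
    indel_support: dict[tuple[str, int], list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for n in self.snv_support.values():
            if n < 0:
                raise ValueError("panel SNV support counts must be non-negative")
        for counts in self.indel_support.values():
            if any(c < 0 for c in counts):
                raise ValueError("panel indel support counts must be non-negative")

    def snv_reads(self, contig: str, position: int, alt: str) -> int:
        return self.snv_support.get((contig, position, alt), 0)

    def indel_samples_nearby(
        self, contig: str, position: int, window: int, min_reads: int
    ) -> int:
        """Number of panel samples with > ``min_reads`` indel-supporting
        reads within ``window`` bp of ``position`` (symmetric)."""
        hits: set[int] = set()
        for (ctg, pos), counts in self.indel_support.items():
            if ctg == contig and abs(pos - position) <= window:
                hits.update(i for i, c in enumerate(counts) if c > min_reads)
        return len(hits)


@dataclass(frozen=True)
class FilterParams:
    """Thresholds for the somatic and germline filters."""

    somatic_min_depth: int = 4
    somatic_min_qual: float = 20.0
    indel_min_vaf: float = 0.10
    panel_snv_max_reads: int = 3  # exclude if pooled support >= this
    panel_indel_sample_threshold: int = 2  # samples with >3 reads
    panel_indel_min_reads: int = 3  # "more than three reads"
    panel_indel_window: int = 100  # bp
    normal_min_alt_reads: int = 0  # evidence required in the normal to subtract
    germline_min_depth: int = 10
    germline_min_qual: float = 20.0
    germline_min_vaf: float = 0.20
    af_max_global: float = 0.001
    af_max_finnish_exome: float = 0.001
    af_max_finnish_genome: float = 0.01

    def __post_init__(self) -> None:
        numeric = {
            k: getattr(self, k) for k in self.__dataclass_fields__  # type: ignore[attr-defined]
        }
        for k, v in numeric.items():
            if v < 0:
                raise ValueError(f"{k} must be non-negative, got {v}")
        for k in ("indel_min_vaf", "germline_min_vaf"):
            if not 0 <= getattr(self, k) <= 1:
                raise ValueError(f"{k} must lie in [0, 1]")


class IntervalSet:
    """Immutable set of half-open 0-based intervals per contig with
    point-containment queries (binary search on sorted, merged starts)."""

    def __init__(self, intervals: dict[str, list[tuple[int, int]]] | None = None):
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for contig, ivs in (intervals or {}).items():
            merged: list[list[int]] = []
            for s, e in sorted(ivs):
                if s >= e:
                    raise ValueError(f"empty/inverted interval [{s}, {e}) on {contig}")
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[contig] = [s for s, _ in merged]
            self._ends[contig] = [e for _, e in merged]

    def contains(self, contig: str, position_1based: int) -> bool:
        starts = self._starts.get(contig)
        if not starts:
            return False
        p = position_1based - 1
        i = bisect_right(starts, p) - 1
        return i >= 0 and p < self._ends[contig][i]

    def intervals(self) -> dict[str, list[tuple[int, int]]]:
        return {
            c: list(zip(self._starts[c], self._ends[c])) for c in sorted(self._starts)
        }

    @classmethod
    def everything(cls, contigs: list[str], length: int = 10**9) -> "IntervalSet":
        return cls({c: [(0, length)] for c in contigs})
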