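"""Trinucleotide substitution contexts and mutation catalogs.

Single-base substitutions are folded onto the pyrimidine strand and binned
into the 96 canonical classes: 6 substitution types (C>A, C>G, C>T, T>A,
T>C, T>G) x 4 five-prime flanks x 4 three-prime flanks, ordered
substitution-major then flank-lexicographic (the usual COSMIC layout).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

N_CONTEXTS = 96

#: canonical labels, e.g. ``A[C>A]A``, in index order 0..95
CONTEXT_LABELS: tuple[str, ...] = tuple(
    f"{f5}[{sub}]{f3}" for sub in SUBSTITUTIONS for f5 in BASES for f3 in BASES
)

_LABEL_TO_INDEX = {lab: i for i, lab in enumerate(CONTEXT_LABELS)}


def canonical_context(ref: str, alt: str, flank5: str, flank3: str) -> int:
    """Map an SNV with flanking bases to its canonical context index (0..95).

    Purine-reference substitutions are reverse-complemented (the whole
    triplet, swapping the flanks) so the mutated base is always C or T.

    Raises
    ------
    ValueError
        If any argument is not a single A/C/G/T base, or ref == alt.
    """
    for name, b in (("ref", ref), ("alt", alt), ("flank5", flank5), ("flank3", flank3)):
        if not (isinstance(b, str) and len(b) == 1 and b in BASES):
            raise ValueError(f"{name} must be a single ACGT base, got {b!r}")
    if ref == alt:
        raise ValueError(f"ref and alt are identical ({ref!r})")
    if ref in "AG":  # purine strand: reverse complement the triplet
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        flank5, flank3 = COMPLEMENT[flank3], COMPLEMENT[flank5]
    return _LABEL_TO_INDEX[f"{flank5}[{ref}>{alt}]{flank3}"]


def context_label(index: int) -> str:
    return CONTEXT_LABELS[index]


@dataclass
class MutationCatalog:
    """Tumours x 96 matrix of context-binned SNV counts.

    Attributes
    ----------
    tumour_ids : list of str
    counts : (n_tumours, 96) int array
    n_skipped : per-tumour number of records that could not be binned
        (indels, missing flanks).
    """

    tumour_ids: list[str]
    counts: np.ndarray
    n_skipped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.tumour_ids), N_CONTEXTS):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"({len(self.tumour_ids)}, {N_CONTEXTS})"
            )
        if (self.counts < 0).any():
            raise ValueError("catalog counts must be non-negative")

    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """96 labelled rows x one column per tumour."""
        return pd.DataFrame(
            self.counts.T, index=list(CONTEXT_LABELS), columns=self.tumour_ids
        ).rename_axis("context")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MutationCatalog":
        if list(frame.index) != list(CONTEXT_LABELS):
            frame = frame.reindex(list(CONTEXT_LABELS))
            if frame.isna().any().any():
                raise ValueError("catalog is missing canonical context rows")
        return cls(tumour_ids=[str(c) for c in frame.columns], counts=frame.to_numpy().T)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "MutationCatalog":
        return cls.from_frame(pd.read_csv(path, sep="\t", index_col=0))


def build_catalog(variants, tumour_ids: list[str] | None = None) -> MutationCatalog:
    """Bin SNV records into a :class:`MutationCatalog`.

    Indels and records without flanking bases are skipped and counted in
    ``n_skipped`` (with a log line per tumour).
    """
    by_tumour: dict[str, np.ndarray] = {}
    skipped: dict[str, int] = {}
    order: list[str] = list(tumour_ids) if tumour_ids is not None else []
    for t in order:
        by_tumour[t] = np.zeros(N_CONTEXTS, dtype=np.int64)
    for v in variants:
        sid = v.sample_id
        if sid not in by_tumour:
            if tumour_ids is not None:
                raise ValueError(f"record from unexpected tumour {sid!r}")
            by_tumour[sid] = np.zeros(N_CONTEXTS, dtype=np.int64)
            order.append(sid)
        if v.variant_class != "SNV" or v.flank5 is None or v.flank3 is None:
            skipped[sid] = skipped.get(sid, 0) + 1
            continue
        idx = canonical_context(v.ref_allele, v.alt_allele, v.flank5, v.flank3)
        by_tumour[sid][idx] += 1
    for sid, n in skipped.items():
        logger.info("catalog: skipped %d non-binnable records in %s", n, sid)
    counts = (
        np.vstack([by_tumour[t] for t in order])
        if order
        else np.zeros((0, N_CONTEXTS), dtype=np.int64)
    )
    return MutationCatalog(tumour_ids=order, counts=counts, n_skipped=skipped)
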