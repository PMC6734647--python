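"""Readers and writers for the plain-text interchange formats: a VCF v4.2
subset (one sample per file, evidence and annotation in INFO), BED interval
files, panel-of-normals and allele-frequency TSVs, and pathway gene sets."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .records import IntervalSet, PanelOfNormals, VariantRecord

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##INFO=<ID=AD,Number=1,Type=Integer,Description="Alt-supporting read depth">
##INFO=<ID=AF,Number=1,Type=Float,Description="Alt allele fraction">
##INFO=<ID=GQ,Number=1,Type=Float,Description="Caller quality score">
##INFO=<ID=FLANK5,Number=1,Type=String,Description="5-prime flanking base">
##INFO=<ID=FLANK3,Number=1,Type=String,Description="3-prime flanking base">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">
##INFO=<ID=CODING,Number=0,Type=Flag,Description="Variant is coding">
##contig=<ID=chr1>
##contig=<ID=chr2>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(records: list[VariantRecord], path) -> None:
    """Write one sample's records as a minimal VCF v4.2 (text, sorted)."""
    lines = [_VCF_HEADER]
    for v in sorted(records, key=lambda r: (r.contig, r.position, r.alt_allele)):
        info = [f"DP={v.total_depth}", f"AD={v.alt_depth}", f"AF={v.vaf:.6g}", f"GQ={v.quality:.6g}"]
        if v.flank5:
            info.append(f"FLANK5={v.flank5}")
        if v.flank3:
            info.append(f"FLANK3={v.flank3}")
        if v.gene:
            info.append(f"GENE={v.gene}")
        if v.consequence:
            info.append(f"CSQ={v.consequence}")
        if v.coding:
            info.append("CODING")
        lines.append(
            f"{v.contig}\t{v.position}\t.\t{v.ref_allele}\t{v.alt_allele}"
            f"\t{v.quality:.6g}\t.\t{';'.join(info)}\n"
        )
    Path(path).write_text("".join(lines))


def read_vcf(path, sample_id: str | None = None) -> list[VariantRecord]:
    """Read the VCF subset written by :func:`write_vcf`. ``sample_id``
    defaults to the file stem."""
    sid = sample_id if sample_id is not None else Path(path).stem
    out: list[VariantRecord] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        contig, pos, _, ref, alt, qual, _, info_str = line.split("\t")[:8]
        info: dict[str, str | bool] = {}
        for item in info_str.split(";"):
            if "=" in item:
                k, val = item.split("=", 1)
                info[k] = val
            else:
                info[item] = True
        is_snv = len(ref) == 1 and len(alt) == 1
        out.append(
            VariantRecord(
                sample_id=sid,
                contig=contig,
                position=int(pos),
                ref_allele=ref,
                alt_allele=alt,
                variant_class="SNV" if is_snv else "indel",
                total_depth=int(info.get("DP", 0)),
                alt_depth=int(info.get("AD", 0)),
                quality=float(info.get("GQ", qual if qual != "." else 0.0)),
                flank5=info.get("FLANK5"),
                flank3=info.get("FLANK3"),
                gene=info.get("GENE"),
                consequence=info.get("CSQ"),
                coding=bool(info.get("CODING", False)),
            )
        )
    return out


def read_bed(path) -> IntervalSet:
    """BED (0-based half-open) to an :class:`IntervalSet`."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        intervals.setdefault(fields[0], []).append((int(fields[1]), int(fields[2])))
    return IntervalSet(intervals)


def write_bed(intervals: IntervalSet, path) -> None:
    lines = []
    for contig, ivs in intervals.intervals().items():
        for s, e in ivs:
            lines.append(f"{contig}\t{s}\t{e}\n")
    Path(path).write_text("".join(lines))


def write_panel_tsv(panel: PanelOfNormals, path) -> None:
    lines = ["kind\tcontig\tpos\talt\tcounts\n"]
    for (contig, pos, alt), n in sorted(panel.snv_support.items()):
        lines.append(f"snv\t{contig}\t{pos}\t{alt}\t{n}\n")
    for (contig, pos), counts in sorted(panel.indel_support.items()):
        lines.append(f"indel\t{contig}\t{pos}\t.\t{','.join(map(str, counts))}\n")
    Path(path).write_text("".join(lines))


def read_panel_tsv(path) -> PanelOfNormals:
    snv: dict[tuple[str, int, str], int] = {}
    indel: dict[tuple[str, int], list[int]] = {}
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for _, r in frame.iterrows():
        if r["kind"] == "snv":
            snv[(r["contig"], int(r["pos"]), r["alt"])] = int(r["counts"])
        else:
            indel[(r["contig"], int(r["pos"]))] = [int(x) for x in r["counts"].split(",")]
    return PanelOfNormals(snv_support=snv, indel_support=indel)


def write_af_tsv(afs: dict, path) -> None:
    lines = ["contig\tpos\tref\talt\taf_global\taf_fin_exome\taf_fin_genome\n"]
    for (contig, pos, ref, alt), (a, b, c) in sorted(afs.items()):
        lines.append(f"{contig}\t{pos}\t{ref}\t{alt}\t{a:.8g}\t{b:.8g}\t{c:.8g}\n")
    Path(path).write_text("".join(lines))


def read_af_tsv(path) -> dict:
    frame = pd.read_csv(path, sep="\t")
    return {
        (r["contig"], int(r["pos"]), r["ref"], r["alt"]): (
            float(r["af_global"]),
            float(r["af_fin_exome"]),
            float(r["af_fin_genome"]),
        )
        for _, r in frame.iterrows()
    }


def read_pathways_tsv(path) -> dict[str, set[str]]:
    """Two-column TSV (pathway, gene) to pathway gene sets."""
    frame = pd.read_csv(path, sep="\t")
    out: dict[str, set[str]] = {}
    for _, r in frame.iterrows():
        out.setdefault(str(r["pathway"]), set()).add(str(r["gene"]))
    if not all(out.values()):
        raise ValueError("pathway gene sets must be non-empty")
    return out


def read_reference_tsv(path) -> dict:
    """Reference signature matrix: a ``context`` column of the 96 labels
    plus one column per named signature. Returns name -> 96-vector."""
    import numpy as np

    from .contexts import CONTEXT_LABELS

    frame = pd.read_csv(path, sep="\t").set_index("context")
    frame = frame.reindex(list(CONTEXT_LABELS))
    if frame.isna().any().any():
        raise ValueError("reference matrix is missing canonical context rows")
    return {name: np.asarray(frame[name], dtype=float) for name in frame.columns}


def data_path(name: str):
    """Path to a bundled data file (fixtures shipped with the package)."""
    return resources.files("syncrc.data").joinpath(name)
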