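"""QTL window designation, same-type merging, and gene-overlap annotation.

Each associated variant defines a window 50 kb up- and downstream of its
position (a CNV's position is its bp span; distances are measured from
the span edges).  Variants of the same type (SNP with SNP, CNV with CNV)
within 50 kb of each other merge into one QTL by single linkage; the
merged window extends 50 kb beyond the outermost members.  SNP-QTLs and
CNV-QTLs that overlap are cross-referenced as a shared region but never
re-merged, so per-type QTL counts are preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_FLANK_BP = 50_000


@dataclass(frozen=True)
class Variant:
    variant_id: str
    chrom: int
    start_bp: int  # == end_bp for a SNP
    end_bp: int
    variant_type: str  # snp | cnv

    def __post_init__(self) -> None:
        if self.start_bp is None or self.start_bp <= 0:
            raise ValueError(f"variant {self.variant_id} has no position")
        if self.end_bp < self.start_bp:
            raise ValueError(f"variant {self.variant_id} span reversed")


@dataclass
class Qtl:
    chrom: int
    start_bp: int
    end_bp: int
    members: list[Variant]
    qtl_type: str
    shared_with: list[str] = field(default_factory=list)

    @property
    def qtl_id(self) -> str:
        return f"{self.qtl_type}_qtl_{self.chrom}_{self.start_bp}"


def _merge_same_type(variants: list[Variant], flank_bp: int) -> list[Qtl]:
    out: list[Qtl] = []
    by_chrom: dict[int, list[Variant]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)
    for chrom in sorted(by_chrom):
        vs = sorted(by_chrom[chrom], key=lambda v: (v.start_bp, v.end_bp, v.variant_id))
        cluster: list[Variant] = [vs[0]]
        right = vs[0].end_bp
        for v in vs[1:]:
            # single linkage: inter-variant distance <= flank (inclusive)
            if v.start_bp - right <= flank_bp:
                cluster.append(v)
                right = max(right, v.end_bp)
            else:
                out.append(_finish(cluster, flank_bp))
                cluster, right = [v], v.end_bp
        out.append(_finish(cluster, flank_bp))
    return out


def _finish(cluster: list[Variant], flank_bp: int) -> Qtl:
    left = min(v.start_bp for v in cluster)
    right = max(v.end_bp for v in cluster)
    return Qtl(
        chrom=cluster[0].chrom,
        start_bp=max(1, left - flank_bp),
        end_bp=right + flank_bp,
        members=sorted(cluster, key=lambda v: v.start_bp),
        qtl_type=cluster[0].variant_type,
    )


def build_qtls(variants: Sequence[Variant], flank_bp: int = DEFAULT_FLANK_BP) -> list[Qtl]:
    """Merge associated variants into QTL windows, within variant type.

    Overlapping SNP- and CNV-QTLs are cross-referenced via
    ``shared_with`` without changing either type's QTL count.
    """
    snps = [v for v in variants if v.variant_type == "snp"]
    cnvs = [v for v in variants if v.variant_type == "cnv"]
    qtls = _merge_same_type(snps, flank_bp) + _merge_same_type(cnvs, flank_bp) if (snps or cnvs) else []
    for q in qtls:
        for other in qtls:
            if (
                other is not q
                and other.qtl_type != q.qtl_type
                and other.chrom == q.chrom
                and other.start_bp <= q.end_bp
                and q.start_bp <= other.end_bp
            ):
                q.shared_with.append(other.qtl_id)
    qtls.sort(key=lambda q: (q.chrom, q.start_bp, q.qtl_type))
    return qtls


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a BED (0-based half-open) or GFF3 (1-based inclusive) gene
    annotation into 1-based inclusive (chrom, start_bp, end_bp, gene)."""
    path = Path(path)
    rows = []
    if path.suffix.lower() in (".gff", ".gff3"):
        for line in path.read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            ) if len(f) > 8 else {}
            name = attrs.get("Name") or attrs.get("ID") or f[2]
            rows.append((_chrom_int(f[0]), int(f[3]), int(f[4]), name))
    else:  # BED
        for line in path.read_text().splitlines():
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
            rows.append((_chrom_int(f[0]), int(f[1]) + 1, int(f[2]), name))
    df = pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "gene"])
    if not df.sort_values(["chrom", "start_bp"]).index.equals(df.index):
        logger.warning("annotation not position-sorted; sorting internally")
        df = df.sort_values(["chrom", "start_bp"]).reset_index(drop=True)
    return df


def _chrom_int(token: str) -> int:
    token = token.removeprefix("chr")
    try:
        return int(token)
    except ValueError:
        return 0


def annotate_qtls(qtls: Sequence[Qtl], annotation: pd.DataFrame) -> dict[str, list[str]]:
    """Genes overlapping each QTL window by at least 1 bp (1-based
    inclusive intervals)."""
    out: dict[str, list[str]] = {}
    for q in qtls:
        sub = annotation[
            (annotation["chrom"] == q.chrom)
            & (annotation["start_bp"] <= q.end_bp)
            & (annotation["end_bp"] >= q.start_bp)
        ]
        out[q.qtl_id] = sorted(set(sub["gene"]))
    return out


def qtl_table(qtls: Sequence[Qtl], genes: dict[str, list[str]] | None = None) -> pd.DataFrame:
    """1-based inclusive TSV-ready QTL table with member lists."""
    return pd.DataFrame(
        {
            "qtl_id": [q.qtl_id for q in qtls],
            "type": [q.qtl_type for q in qtls],
            "chrom": [q.chrom for q in qtls],
            "start_bp": [q.start_bp for q in qtls],
            "end_bp": [q.end_bp for q in qtls],
            "n_members": [len(q.members) for q in qtls],
            "members": [",".join(v.variant_id for v in q.members) for q in qtls],
            "shared_with": [",".join(q.shared_with) for q in qtls],
            "genes": [
                ",".join(genes.get(q.qtl_id, [])) if genes else "" for q in qtls
            ],
        }
    )


def write_bed(qtls: Sequence[Qtl], path: str | Path) -> None:
    """QTL windows as BED: 0-based half-open coordinates."""
    with open(path, "w") as fh:
        for q in qtls:
            fh.write(f"{q.chrom}\t{q.start_bp - 1}\t{q.end_bp}\t{q.qtl_id}\n")
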