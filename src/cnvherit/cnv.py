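"""Dual-caller CNV consensus, locus construction and copy-class handling.

CNVs are called per animal by two independent callers from the same SNP
array; a call from each caller describes the same event when its start and
end lie within one SNP (in SNP-index space) of the other caller's
endpoints.  Calls with fewer than three array SNPs are discarded, matched
pairs are counted once, and loci carried by fewer than three animals within
a breed are dropped.

Copy classes are stored as the integer copy number: 0 double-deletion,
1 single-deletion, 2 normal, 3 single-duplication, 4 double-duplication.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .qc import SnpPanel

logger = logging.getLogger(__name__)

NORMAL = 2
DELETION_CLASSES = (0, 1)
DUPLICATION_CLASSES = (3, 4)

_RAWCNV_RE = re.compile(
    r"chr(?P<chrom>\w+):(?P<start>\d+)-(?P<end>\d+)\s+"
    r"numsnp=(?P<numsnp>\d+)\s+(?:length=[\d,]+\s+)?"
    r"(?:state\d+,)?cn=(?P<cn>\d+)\s+(?P<sample>\S+)"
)


@dataclass(frozen=True)
class CnvCall:
    """A single per-animal CNV call resolved onto the SNP map."""

    animal_id: str
    chrom: int
    start_snp_index: int
    end_snp_index: int
    start_bp: int
    end_bp: int
    copy_number: int
    caller: str
    n_snps: int

    def __post_init__(self) -> None:
        if self.end_snp_index < self.start_snp_index:
            raise ValueError("end SNP index before start")
        if self.copy_number == NORMAL:
            raise ValueError("copy number 2 is the normal state, not a CNV")
        if self.n_snps != self.end_snp_index - self.start_snp_index + 1:
            raise ValueError("n_snps inconsistent with SNP-index span")

    @property
    def is_deletion(self) -> bool:
        return self.copy_number < NORMAL


@dataclass
class CnvLocus:
    """A consensus CNV locus with per-animal copy classes.

    ``classes`` maps animal_id -> copy number for carriers only; animals
    absent from the mapping are in the normal state.  ``carriers_by_breed``
    counts animals with a non-normal class per breed.
    """

    locus_id: str
    chrom: int
    start_snp_index: int
    end_snp_index: int
    start_bp: int
    end_bp: int
    classes: dict[str, int] = field(default_factory=dict)
    carriers_by_breed: dict[str, int] = field(default_factory=dict)
    collapsed_deletions: bool = False
    collapsed_duplications: bool = False

    @property
    def carrier_count(self) -> int:
        return sum(1 for c in self.classes.values() if c != NORMAL)

    @property
    def cnv_type(self) -> str:
        has_del = any(c in DELETION_CLASSES for c in self.classes.values())
        has_dup = any(c in DUPLICATION_CLASSES for c in self.classes.values())
        if has_del and has_dup:
            return "mixed"
        return "deletion" if has_del else "duplication"

    def class_of(self, animal_id: str) -> int:
        return self.classes.get(animal_id, NORMAL)


def read_rawcnv(path: str | Path, snp_map: pd.DataFrame, caller: str | None = None) -> list[CnvCall]:
    """Parse a PennCNV-rawcnv-style text file onto the SNP map.

    Dialect per line (whitespace separated):
    ``chr<c>:<start>-<end>  numsnp=<n>  [length=<l>]  [state<k>,]cn=<cn>  <sample>``

    Spans are resolved to the SNPs of the map they cover; ``n_snps`` is
    recomputed from the map.  Records with cn=2 or with a span containing
    no mapped SNP are rejected (counted, logged).
    """
    caller = caller or Path(path).stem
    chroms = snp_map["chrom"].to_numpy()
    pos = snp_map["pos_bp"].to_numpy()
    calls: list[CnvCall] = []
    n_no_snps = 0
    n_cn2 = 0
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        m = _RAWCNV_RE.match(line.strip())
        if m is None:
            raise ValueError(f"{path}:{lineno}: malformed rawcnv record: {line!r}")
        cn = int(m["cn"])
        if cn == NORMAL:
            n_cn2 += 1
            continue
        try:
            chrom = int(m["chrom"])
        except ValueError:
            chrom = 0  # sex chromosome or unplaced; never maps to autosomal SNPs
        start_bp, end_bp = int(m["start"]), int(m["end"])
        in_span = np.flatnonzero((chroms == chrom) & (pos >= start_bp) & (pos <= end_bp))
        if in_span.size == 0:
            n_no_snps += 1
            continue
        i0, i1 = int(in_span[0]), int(in_span[-1])
        calls.append(
            CnvCall(
                animal_id=str(m["sample"]),
                chrom=chrom,
                start_snp_index=i0,
                end_snp_index=i1,
                start_bp=int(pos[i0]),
                end_bp=int(pos[i1]),
                copy_number=cn,
                caller=caller,
                n_snps=i1 - i0 + 1,
            )
        )
    if n_no_snps or n_cn2:
        logger.info(
            "%s: rejected %d records with no mapped SNPs, %d cn=2 records",
            path, n_no_snps, n_cn2,
        )
    return calls


def _spans_match(a: CnvCall, b: CnvCall, tol: int) -> bool:
    return (
        a.chrom == b.chrom
        and abs(a.start_snp_index - b.start_snp_index) <= tol
        and abs(a.end_snp_index - b.end_snp_index) <= tol
    )


def consensus_merge(
    calls_a: Sequence[CnvCall],
    calls_b: Sequence[CnvCall],
    endpoint_tolerance_snps: int = 1,
    min_snps: int = 3,
) -> list[CnvCall]:
    """Union of both callers' calls with >= min_snps SNPs, de-duplicated.

    A call from each caller for the same animal in the same direction
    (deletion vs duplication) is the same event iff both endpoints agree
    within the tolerance; matched pairs are emitted once with the
    caller-A span.  Matching is greedy in sorted-span order, each call
    used at most once.
    """
    a_ok = [c for c in calls_a if c.n_snps >= min_snps]
    b_ok = [c for c in calls_b if c.n_snps >= min_snps]
    key = lambda c: (c.animal_id, c.is_deletion)
    b_by_group: dict[tuple, list[CnvCall]] = {}
    for c in sorted(b_ok, key=lambda c: (c.chrom, c.start_snp_index, c.end_snp_index)):
        b_by_group.setdefault(key(c), []).append(c)

    merged: list[CnvCall] = []
    for c in sorted(a_ok, key=lambda c: (c.animal_id, c.chrom, c.start_snp_index, c.end_snp_index)):
        pool = b_by_group.get(key(c), [])
        match = next((i for i, d in enumerate(pool) if _spans_match(c, d, endpoint_tolerance_snps)), None)
        if match is not None:
            pool.pop(match)  # consumed: not double counted
        merged.append(c)
    for pool in b_by_group.values():
        merged.extend(pool)
    merged.sort(key=lambda c: (c.chrom, c.start_snp_index, c.end_snp_index, c.animal_id))
    return merged


def _cluster_calls(calls: list[CnvCall], tol: int) -> list[list[CnvCall]]:
    """Transitive closure of the pairwise endpoint-tolerance match."""
    n = len(calls)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    order = sorted(range(n), key=lambda i: (calls[i].chrom, calls[i].start_snp_index))
    for ii, i in enumerate(order):
        for j in order[ii + 1:]:
            if calls[j].chrom != calls[i].chrom:
                break
            if calls[j].start_snp_index - calls[i].start_snp_index > tol:
                break
            if _spans_match(calls[i], calls[j], tol):
                parent[find(i)] = find(j)
    groups: dict[int, list[CnvCall]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(calls[i])
    return list(groups.values())


def build_loci(
    calls: Sequence[CnvCall],
    animals_by_breed: Mapping[str, Iterable[str]],
    min_carriers: int = 3,
    endpoint_tolerance_snps: int = 1,
) -> list[CnvLocus]:
    """Group consensus calls into loci and apply the within-breed carrier rule.

    Calls whose spans match under the endpoint tolerance (transitive
    closure) form one locus regardless of direction, so a locus may be
    mixed.  The consensus span is the span of the member call covering the
    most SNPs (ties: smallest start).  A locus is retained iff some breed
    has at least ``min_carriers`` carriers.
    """
    breed_of = {str(a): b for b, animals in animals_by_breed.items() for a in animals}
    loci: list[CnvLocus] = []
    clusters = _cluster_calls(list(calls), endpoint_tolerance_snps)
    clusters.sort(key=lambda g: (g[0].chrom, min(c.start_snp_index for c in g)))
    for cluster in clusters:
        anchor = max(cluster, key=lambda c: (c.n_snps, -c.start_snp_index))
        best: dict[str, CnvCall] = {}
        for c in cluster:
            prev = best.get(c.animal_id)
            if prev is None:
                best[c.animal_id] = c
            elif prev.copy_number != c.copy_number:
                winner = max(prev, c, key=lambda x: (x.n_snps, -x.copy_number))
                logger.info(
                    "conflicting copy classes for %s at chr%d:%d-%d; keeping cn=%d",
                    c.animal_id, anchor.chrom, anchor.start_bp, anchor.end_bp,
                    winner.copy_number,
                )
                best[c.animal_id] = winner
        classes = {a: c.copy_number for a, c in best.items()}
        carriers_by_breed: dict[str, int] = {}
        for a in classes:
            b = breed_of.get(a, "pop")
            carriers_by_breed[b] = carriers_by_breed.get(b, 0) + 1
        if not carriers_by_breed or max(carriers_by_breed.values()) < min_carriers:
            continue
        loci.append(
            CnvLocus(
                locus_id=f"cnv_{anchor.chrom}_{anchor.start_bp}_{anchor.end_bp}",
                chrom=anchor.chrom,
                start_snp_index=anchor.start_snp_index,
                end_snp_index=anchor.end_snp_index,
                start_bp=anchor.start_bp,
                end_bp=anchor.end_bp,
                classes=classes,
                carriers_by_breed=carriers_by_breed,
            )
        )
    for i, locus in enumerate(loci):
        locus.locus_id = f"cnv{i:04d}_{locus.chrom}_{locus.start_bp}"
    return loci


def collapse_copy_classes(locus: CnvLocus, min_class_carriers: int = 5) -> CnvLocus:
    """Collapse double into single classes when no class is common enough.

    If neither deletion class (double- or single-deletion) reaches
    ``min_class_carriers`` carriers, both are merged into one deletion
    class (coded single-deletion); duplications are treated symmetrically.
    """
    counts = {k: 0 for k in (0, 1, 3, 4)}
    for c in locus.classes.values():
        if c in counts:
            counts[c] += 1
    new_classes = dict(locus.classes)
    collapsed_del = collapsed_dup = False
    if 0 < counts[0] + counts[1] and counts[0] < min_class_carriers and counts[1] < min_class_carriers:
        collapsed_del = True
        for a, c in new_classes.items():
            if c == 0:
                new_classes[a] = 1
    if 0 < counts[3] + counts[4] and counts[3] < min_class_carriers and counts[4] < min_class_carriers:
        collapsed_dup = True
        for a, c in new_classes.items():
            if c == 4:
                new_classes[a] = 3
    return replace(
        locus,
        classes=new_classes,
        collapsed_deletions=collapsed_del,
        collapsed_duplications=collapsed_dup,
    )


def locus_table(loci: Sequence[CnvLocus]) -> pd.DataFrame:
    """Summary TSV-ready table: one row per locus."""
    return pd.DataFrame(
        {
            "locus_id": [l.locus_id for l in loci],
            "chrom": [l.chrom for l in loci],
            "start_bp": [l.start_bp for l in loci],
            "end_bp": [l.end_bp for l in loci],
            "type": [l.cnv_type for l in loci],
            "carriers": [l.carrier_count for l in loci],
        }
    )


def class_matrix(loci: Sequence[CnvLocus], animal_ids: Sequence[str]) -> pd.DataFrame:
    """Animals x loci copy-class matrix (copy numbers, 2 = normal)."""
    out = pd.DataFrame(
        NORMAL,
        index=list(animal_ids),
        columns=[l.locus_id for l in loci],
        dtype=int,
    )
    for l in loci:
        for a, c in l.classes.items():
            if a in out.index:
                out.loc[a, l.locus_id] = c
    return out


def consensus_pipeline(
    path_a: str | Path,
    path_b: str | Path,
    panel: SnpPanel,
    *,
    endpoint_tolerance_snps: int = 1,
    min_snps: int = 3,
    min_carriers: int = 3,
) -> list[CnvLocus]:
    """read both callers -> consensus merge -> loci with carrier filter."""
    calls_a = read_rawcnv(path_a, panel.snp_map, caller="A")
    calls_b = read_rawcnv(path_b, panel.snp_map, caller="B")
    merged = consensus_merge(calls_a, calls_b, endpoint_tolerance_snps, min_snps)
    if panel.breed is None:
        groups = {"pop": list(panel.animal_ids)}
    else:
        groups = {
            b: list(panel.animal_ids[panel.breed == b]) for b in panel.breeds()
        }
    return build_loci(merged, groups, min_carriers, endpoint_tolerance_snps)
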