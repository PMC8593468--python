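"""Genomic relationship matrices (VanRaden method 1) and GRM PCA.

G = (M − P)(M − P)ᵀ / 2Σᵢ pᵢ(1 − pᵢ), where M holds markers coded
−1/0/+1 (homozygote / heterozygote / other homozygote) and column i of P
is 2(pᵢ − 0.5) with pᵢ the frequency of the +1-coded allele, estimated
from the observed sample.

CNV loci enter under two codings.  Procedure 1 treats each locus like a
biallelic marker on carrier dosage: double classes → −1, single classes
→ 0, normal → +1; a mixed locus is split into a deletion locus and a
duplication locus (the other direction recoded to normal).  Procedure 2
keeps one locus per CNV with deletion → −1, normal → 0, duplication →
+1.  For procedure 2 the implied allele frequency of the three-state
locus is taken as the frequency of the +1 allele after coding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cnv import CnvLocus, DELETION_CLASSES, DUPLICATION_CLASSES, NORMAL
from .qc import SnpPanel

logger = logging.getLogger(__name__)


@dataclass
class MarkerMatrix:
    """Coded marker matrix M with per-marker +1-allele frequencies."""

    animal_ids: np.ndarray
    marker_ids: list[str]
    m: np.ndarray  # (n_animals, n_markers), values in [-1, 1]
    p: np.ndarray  # frequency of the +1-coded allele per marker
    coding: str  # snp | cnv_proc1 | cnv_proc2 | combined

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        if np.isnan(self.m).any():
            raise ValueError("coded marker matrix must have no missing values")
        if self.m.shape != (len(self.animal_ids), len(self.marker_ids)):
            raise ValueError("marker matrix shape mismatch")


@dataclass
class Grm:
    animal_ids: np.ndarray
    g: np.ndarray
    denominator: float
    coding: str

    def __post_init__(self) -> None:
        asym = np.abs(self.g - self.g.T).max()
        if asym > 1e-10:
            raise ValueError(f"GRM asymmetric by {asym:.2e}")
        mean_diag = float(np.mean(np.diag(self.g)))
        if self.coding == "snp" and not (0.5 < mean_diag < 2.0):
            logger.info("SNP GRM mean diagonal %.3f departs from 1", mean_diag)

    def write(self, prefix: str | Path) -> None:
        """GCTA-style text: ``<prefix>.grm`` lower triangle (i, j, n, g_ij,
        1-based) and ``<prefix>.grm.id``."""
        prefix = Path(prefix)
        n = len(self.animal_ids)
        with open(f"{prefix}.grm", "w") as fh:
            for i in range(n):
                for j in range(i + 1):
                    fh.write(f"{i + 1}\t{j + 1}\t{n}\t{self.g[i, j]:.10g}\n")
        with open(f"{prefix}.grm.id", "w") as fh:
            for a in self.animal_ids:
                fh.write(f"{a}\t{a}\n")


def impute_missing(panel: SnpPanel) -> SnpPanel:
    """Replace missing genotypes by the within-breed per-SNP mean.

    Fractional codes are legal downstream of imputation.  A SNP entirely
    missing within some breed falls back to the overall mean; a SNP with
    no called genotype at all is an error.
    """
    geno = panel.geno.copy()
    if not np.isnan(geno).any():
        return panel
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-nan column handled below
        overall = np.nanmean(geno, axis=0)
    if np.isnan(overall).any():
        bad = panel.snp_map["snp_id"][np.isnan(overall)].tolist()
        raise ValueError(f"SNP(s) with all genotypes missing: {bad[:5]}")
    breed = panel.breed if panel.breed is not None else np.repeat("pop", panel.n_animals)
    for b in np.unique(breed):
        rows = breed == b
        block = geno[rows]
        with np.errstate(invalid="ignore"):
            means = np.nanmean(block, axis=0)
        means = np.where(np.isnan(means), overall, means)
        nan_mask = np.isnan(block)
        block[nan_mask] = np.broadcast_to(means, block.shape)[nan_mask]
        geno[rows] = block
    out = SnpPanel(panel.animal_ids, geno, panel.snp_map.copy(), panel.breed)
    return out


def code_snps(panel: SnpPanel) -> MarkerMatrix:
    """SNP dosage 0/1/2 → −1/0/+1 (centered at the heterozygote)."""
    if np.isnan(panel.geno).any():
        raise ValueError("impute missing genotypes before coding")
    m = panel.geno - 1.0
    p = (m.mean(axis=0) + 1.0) / 2.0
    return MarkerMatrix(panel.animal_ids, list(panel.snp_map["snp_id"]), m, p, "snp")


def _locus_codes(locus: CnvLocus, animal_ids: Sequence[str], table: dict[int, float]) -> np.ndarray:
    out = np.empty(len(animal_ids))
    for i, a in enumerate(animal_ids):
        c = locus.class_of(str(a))
        try:
            out[i] = table[c]
        except KeyError:
            raise ValueError(f"unknown copy class {c} for animal {a}") from None
    return out


_PROC1_TABLE = {0: -1.0, 1: 0.0, NORMAL: 1.0, 3: 0.0, 4: -1.0}


def code_cnvs_proc1(loci: Sequence[CnvLocus], animal_ids: Sequence[str]) -> MarkerMatrix:
    """Procedure 1: carrier-dosage coding, mixed loci split in two.

    double-del/double-dup → −1, single-del/single-dup → 0, normal → +1.
    A mixed locus emits a deletion locus (duplications recoded normal)
    and a duplication locus (deletions recoded normal).
    """
    cols, ids = [], []
    for locus in loci:
        if locus.cnv_type == "mixed":
            del_view = {a: (NORMAL if c in DUPLICATION_CLASSES else c) for a, c in locus.classes.items()}
            dup_view = {a: (NORMAL if c in DELETION_CLASSES else c) for a, c in locus.classes.items()}
            for tag, view in (("del", del_view), ("dup", dup_view)):
                sub = CnvLocus(
                    f"{locus.locus_id}:{tag}", locus.chrom,
                    locus.start_snp_index, locus.end_snp_index,
                    locus.start_bp, locus.end_bp, classes=view,
                )
                cols.append(_locus_codes(sub, animal_ids, _PROC1_TABLE))
                ids.append(sub.locus_id)
        else:
            cols.append(_locus_codes(locus, animal_ids, _PROC1_TABLE))
            ids.append(locus.locus_id)
    m = np.column_stack(cols) if cols else np.empty((len(animal_ids), 0))
    p = (m.mean(axis=0) + 1.0) / 2.0 if cols else np.empty(0)
    return MarkerMatrix(np.asarray(animal_ids, object), ids, m, p, "cnv_proc1")


_PROC2_TABLE = {0: -1.0, 1: -1.0, NORMAL: 0.0, 3: 1.0, 4: 1.0}


def code_cnvs_proc2(loci: Sequence[CnvLocus], animal_ids: Sequence[str]) -> MarkerMatrix:
    """Procedure 2: one locus per CNV, deletion → −1, normal → 0,
    duplication → +1."""
    cols = [_locus_codes(l, animal_ids, _PROC2_TABLE) for l in loci]
    ids = [l.locus_id for l in loci]
    m = np.column_stack(cols) if cols else np.empty((len(animal_ids), 0))
    p = (m.mean(axis=0) + 1.0) / 2.0 if cols else np.empty(0)
    return MarkerMatrix(np.asarray(animal_ids, object), ids, m, p, "cnv_proc2")


def compute_grm(markers: MarkerMatrix) -> Grm:
    """VanRaden method-1 GRM from a coded marker matrix.

    Monomorphic markers (p(1−p) = 0) are excluded from both the numerator
    and the denominator; the formula is undefined without at least one
    polymorphic marker.
    """
    het = markers.p * (1.0 - markers.p)
    poly = het > 0
    if not poly.any():
        raise ValueError("no polymorphic markers: GRM denominator is zero")
    n_dropped = int((~poly).sum())
    if n_dropped:
        logger.info("dropping %d monomorphic markers from GRM", n_dropped)
    m = markers.m[:, poly]
    p = markers.p[poly]
    denom = 2.0 * float(het[poly].sum())
    z = m - 2.0 * (p - 0.5)  # subtract P column 2(p_i - 0.5)
    g = (z @ z.T) / denom
    g = (g + g.T) / 2.0
    return Grm(markers.animal_ids, g, denom, markers.coding)


def combine_markers(snp: MarkerMatrix, cnv: MarkerMatrix) -> MarkerMatrix:
    """Column-wise concatenation; one shared denominator downstream."""
    if len(snp.animal_ids) != len(cnv.animal_ids) or (snp.animal_ids != cnv.animal_ids).any():
        raise ValueError("marker matrices index different animal sets")
    return MarkerMatrix(
        snp.animal_ids,
        list(snp.marker_ids) + list(cnv.marker_ids),
        np.hstack([snp.m, cnv.m]),
        np.concatenate([snp.p, cnv.p]),
        "combined",
    )


def grm_pca(grm: Grm, k: int) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Eigen-decomposition of G; returns (scores, percent variance, raw
    eigenvalues), components ordered by descending eigenvalue.

    Scores are eigenvector * sqrt(max(eigenvalue, 0)).  Percent variance
    uses eigenvalues floored at 0; raw eigenvalues are returned as well.
    """
    if not np.isfinite(grm.g).all():
        raise ValueError("GRM contains non-finite entries")
    n = grm.g.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}")
    evals, evecs = np.linalg.eigh(grm.g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    floored = np.maximum(evals, 0.0)
    if (evals < 0).any():
        logger.info("flooring %d negative eigenvalues for variance shares", int((evals < 0).sum()))
    pct = 100.0 * floored / floored.sum()
    scores = evecs[:, :k] * np.sqrt(floored[:k])
    df = pd.DataFrame(scores, columns=[f"PC{j + 1}" for j in range(k)])
    df.insert(0, "animal_id", grm.animal_ids)
    return df, pct[:k], evals
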