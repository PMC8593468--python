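"""Genotype and phenotype quality control.

Edits applied to a SNP panel before relationship matrices are built:
animal call-rate, SNP call-rate (computed on the retained animals),
autosome/position completeness, Mendelian-inconsistency SNP removal from
parent-progeny duos, and exclusion of animals whose deregressed proof is
backed by less than one effective record (ERC < 1).

Genotypes are held as a float array with codes {0, 1, 2} and ``nan`` for
missing.  Chromosomes are autosome integers; 0 is the sentinel for sex
chromosomes or an unrecorded position.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MAP_COLUMNS = ("snp_id", "chrom", "pos_bp", "index")


@dataclass
class SnpPanel:
    """Animals x SNPs genotype matrix plus a positional SNP map.

    Parameters
    ----------
    animal_ids : array of str
    geno : float array, shape (n_animals, n_snps), values in {0,1,2,nan}
    snp_map : DataFrame with columns snp_id, chrom, pos_bp, index;
        sorted by (chrom, pos_bp) with contiguous 0-based indices
    breed : per-animal breed labels (optional; one breed assumed if absent)
    """

    animal_ids: np.ndarray
    geno: np.ndarray
    snp_map: pd.DataFrame
    breed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        self.geno = np.asarray(self.geno, dtype=float)
        if self.geno.shape != (len(self.animal_ids), len(self.snp_map)):
            raise ValueError(
                f"genotype shape {self.geno.shape} does not match "
                f"{len(self.animal_ids)} animals x {len(self.snp_map)} SNPs"
            )
        if self.breed is not None:
            self.breed = np.asarray(self.breed, dtype=object)
            if len(self.breed) != len(self.animal_ids):
                raise ValueError("breed labels do not match animal count")
        # integer codes 0/1/2 before imputation; fractional dosages in
        # [0, 2] are legal after mean imputation
        legal = np.isnan(self.geno) | ((self.geno >= 0.0) & (self.geno <= 2.0))
        if not legal.all():
            bad = np.unique(self.geno[~legal])
            raise ValueError(f"illegal genotype codes: {bad[:5]}")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_map)

    def breeds(self) -> np.ndarray:
        if self.breed is None:
            return np.array(["pop"], dtype=object)
        return np.unique(self.breed)

    def animal_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.animal_ids)}
        try:
            return np.array([lookup[a] for a in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"animal {exc} not in panel") from exc

    def subset(self, animal_mask=None, snp_mask=None) -> "SnpPanel":
        a = np.ones(self.n_animals, bool) if animal_mask is None else np.asarray(animal_mask, bool)
        s = np.ones(self.n_snps, bool) if snp_mask is None else np.asarray(snp_mask, bool)
        new_map = self.snp_map.loc[s].reset_index(drop=True).copy()
        new_map["index"] = np.arange(len(new_map))
        return SnpPanel(
            animal_ids=self.animal_ids[a],
            geno=self.geno[np.ix_(a, s)],
            snp_map=new_map,
            breed=None if self.breed is None else self.breed[a],
        )

    # --- plain-text round trip ------------------------------------------
    def write(self, geno_path: str | Path, map_path: str | Path) -> None:
        """Write genotypes as TSV (animal_id, breed, then one column per SNP;
        missing as NA) and the SNP map as TSV."""
        df = pd.DataFrame(self.geno, columns=self.snp_map["snp_id"])
        df.insert(0, "breed", self.breed if self.breed is not None else "pop")
        df.insert(0, "animal_id", self.animal_ids)
        df.to_csv(geno_path, sep="\t", index=False, na_rep="NA")
        self.snp_map.to_csv(map_path, sep="\t", index=False)

    @classmethod
    def read(cls, geno_path: str | Path, map_path: str | Path) -> "SnpPanel":
        snp_map = pd.read_csv(map_path, sep="\t")
        missing_cols = set(MAP_COLUMNS) - set(snp_map.columns)
        if missing_cols:
            raise ValueError(f"SNP map lacks columns {sorted(missing_cols)}")
        df = pd.read_csv(geno_path, sep="\t", na_values=["NA"])
        geno = df[snp_map["snp_id"]].to_numpy(float)
        return cls(
            animal_ids=df["animal_id"].to_numpy(object),
            geno=geno,
            snp_map=snp_map,
            breed=df["breed"].to_numpy(object) if "breed" in df else None,
        )


@dataclass
class QcStage:
    name: str
    animals_before: int
    animals_after: int
    snps_before: int
    snps_after: int
    removed_animals: list = field(default_factory=list)
    removed_snps: list = field(default_factory=list)
    detail: dict = field(default_factory=dict)


@dataclass
class QcReport:
    """Ordered record of QC stages; counts reconcile at every stage."""

    stages: list[QcStage] = field(default_factory=list)

    def add(self, stage: QcStage) -> None:
        if stage.animals_before - stage.animals_after != len(stage.removed_animals):
            raise ValueError("animal counts do not reconcile")
        if stage.snps_before - stage.snps_after != len(stage.removed_snps):
            raise ValueError("SNP counts do not reconcile")
        self.stages.append(stage)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = [
            {
                "stage": s.name,
                "animals_before": s.animals_before,
                "animals_after": s.animals_after,
                "snps_before": s.snps_before,
                "snps_after": s.snps_after,
                "removed_animals": list(map(str, s.removed_animals)),
                "removed_snps": list(map(str, s.removed_snps)),
                "detail": s.detail,
            }
            for s in self.stages
        ]
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def filter_call_rate(
    panel: SnpPanel,
    animal_threshold: float = 0.95,
    snp_threshold: float = 0.95,
    report: QcReport | None = None,
) -> tuple[SnpPanel, QcReport]:
    """Remove animals with < animal_threshold of SNPs called, then SNPs with
    call rate < snp_threshold computed over the retained animals.

    Both cuts are strict "less than": an animal or SNP exactly at the
    threshold is retained.
    """
    if panel.n_animals == 0 or panel.n_snps == 0:
        raise ValueError("empty panel")
    if not (0 < animal_threshold <= 1 and 0 < snp_threshold <= 1):
        raise ValueError("thresholds must be in (0, 1]")
    report = report if report is not None else QcReport()
    called = ~np.isnan(panel.geno)

    animal_rate = called.mean(axis=1)
    keep_a = animal_rate >= animal_threshold
    mid = panel.subset(animal_mask=keep_a)
    report.add(
        QcStage(
            "animal_call_rate",
            panel.n_animals,
            mid.n_animals,
            panel.n_snps,
            panel.n_snps,
            removed_animals=list(panel.animal_ids[~keep_a]),
            detail={"threshold": animal_threshold},
        )
    )

    snp_rate = (~np.isnan(mid.geno)).mean(axis=0)
    keep_s = snp_rate >= snp_threshold
    out = mid.subset(snp_mask=keep_s)
    report.add(
        QcStage(
            "snp_call_rate",
            mid.n_animals,
            out.n_animals,
            mid.n_snps,
            out.n_snps,
            removed_snps=list(mid.snp_map["snp_id"][~keep_s]),
            detail={"threshold": snp_threshold},
        )
    )
    return out, report


def filter_positions(
    panel: SnpPanel, n_autosomes: int = 29, report: QcReport | None = None
) -> tuple[SnpPanel, QcReport]:
    """Keep only SNPs on autosomes 1..n_autosomes with a positive position."""
    report = report if report is not None else QcReport()
    chrom = panel.snp_map["chrom"].to_numpy()
    pos = panel.snp_map["pos_bp"].to_numpy()
    keep = (chrom >= 1) & (chrom <= n_autosomes) & (pos > 0) & ~pd.isna(pos)
    out = panel.subset(snp_mask=keep)
    report.add(
        QcStage(
            "positions",
            panel.n_animals,
            out.n_animals,
            panel.n_snps,
            out.n_snps,
            removed_snps=list(panel.snp_map["snp_id"][~keep]),
            detail={"n_autosomes": n_autosomes},
        )
    )
    return out, report


def mendelian_conflict_fractions(
    panel: SnpPanel, pairs: Sequence[tuple[str, str]]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP opposing-homozygote conflict fraction over parent-progeny duos.

    A duo conflicts at a SNP iff one member is coded 0 and the other 2.
    Duos with either genotype missing at the SNP do not enter that SNP's
    denominator.  Returns (conflict_fraction, n_informative); fraction is 0
    where no duo is informative.
    """
    parents = panel.animal_index([p for p, _ in pairs])
    progeny = panel.animal_index([c for _, c in pairs])
    gp = panel.geno[parents]  # (n_pairs, n_snps)
    gc = panel.geno[progeny]
    informative = ~np.isnan(gp) & ~np.isnan(gc)
    conflict = ((gp == 0) & (gc == 2)) | ((gp == 2) & (gc == 0))
    n_inf = informative.sum(axis=0)
    n_con = (conflict & informative).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_inf > 0, n_con / np.maximum(n_inf, 1), 0.0)
    return frac, n_inf


def filter_mendelian(
    panel: SnpPanel,
    pairs: Sequence[tuple[str, str]],
    max_conflict_fraction: float = 0.02,
    report: QcReport | None = None,
) -> tuple[SnpPanel, QcReport]:
    """Remove SNPs whose duo conflict fraction exceeds (strictly) the limit."""
    report = report if report is not None else QcReport()
    if len(pairs) == 0:
        logger.warning("no parent-progeny pairs supplied; Mendelian filter skipped")
        report.add(
            QcStage(
                "mendelian",
                panel.n_animals,
                panel.n_animals,
                panel.n_snps,
                panel.n_snps,
                detail={"skipped": "no pairs"},
            )
        )
        return panel, report
    frac, _ = mendelian_conflict_fractions(panel, pairs)
    keep = frac <= max_conflict_fraction
    out = panel.subset(snp_mask=keep)
    report.add(
        QcStage(
            "mendelian",
            panel.n_animals,
            out.n_animals,
            panel.n_snps,
            out.n_snps,
            removed_snps=list(panel.snp_map["snp_id"][~keep]),
            detail={"max_conflict_fraction": max_conflict_fraction, "n_pairs": len(pairs)},
        )
    )
    return out, report


def filter_erc(traits: pd.DataFrame, min_erc: float = 1.0) -> pd.DataFrame:
    """Drop trait records whose effective record contribution is < min_erc."""
    if "erc" not in traits.columns:
        raise ValueError("trait table has no 'erc' column")
    return traits.loc[traits["erc"] >= min_erc].reset_index(drop=True)


def run_qc(
    panel: SnpPanel,
    pairs: Sequence[tuple[str, str]],
    traits: pd.DataFrame | None = None,
    *,
    animal_call_rate: float = 0.95,
    snp_call_rate: float = 0.95,
    n_autosomes: int = 29,
    mendel_max: float = 0.02,
    min_erc: float = 1.0,
) -> tuple[SnpPanel, pd.DataFrame | None, QcReport]:
    """Full edit pipeline in the fixed order: animal call-rate, SNP
    call-rate, positions, Mendelian, ERC."""
    panel, report = filter_call_rate(panel, animal_call_rate, snp_call_rate)
    panel, report = filter_positions(panel, n_autosomes, report)
    kept = set(panel.animal_ids)
    usable = [(p, c) for p, c in pairs if p in kept and c in kept]
    panel, report = filter_mendelian(panel, usable, mendel_max, report)
    if traits is not None:
        traits = filter_erc(traits, min_erc)
        traits = traits[traits["animal_id"].isin(kept)].reset_index(drop=True)
    return panel, traits, report
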