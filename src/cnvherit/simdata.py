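"""Synthetic sire populations with a known SNP/CNV variance split.

The generator emulates the data a national-evaluation CNV study consumes:
multi-breed SNP allele-frequency structure (Balding-Nichols drift around
shared ancestral frequencies), CNV loci segregating at low carrier
frequency as deletions, duplications or both, true breeding values with
configurable SNP and CNV variance fractions, deregressed EBVs whose
noise variance follows sigma_g^2 (1 - r_i^2) / r_i^2 for a per-animal
reliability r_i^2, two noisy "caller" outputs whose endpoints jitter by
at most one SNP, and parent-progeny pairs with optional injected
Mendelian inconsistencies.

It does not simulate intensity signals (CNV calling is upstream of this
pipeline), multi-generation pedigrees, or sex chromosomes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cnv import CnvLocus, NORMAL
from .qc import SnpPanel

_STATE_OF_CN = {0: "state1", 1: "state2", 3: "state5", 4: "state6"}


@dataclass
class SimConfig:
    """Study conditions for one synthetic population.

    ``n_animals`` is the count per breed.  ``var_snp`` and ``var_cnv``
    are the variances of the SNP-polygenic and CNV parts of the true
    breeding value; ``var_total_genetic`` is the sigma_g^2 used as the
    denominator of downstream variance fractions and of the dEBV noise
    model.  Endpoint jitter is a symmetric +/-1-SNP shift applied
    independently to each endpoint of each caller's call.
    """

    n_animals: int = 945
    n_snps: int = 1000
    n_chrom: int = 29
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_cnv_loci: int = 40
    cnv_carrier_freq_range: tuple[float, float] = (0.01, 0.05)
    n_causal_snps: int = 50
    n_causal_cnvs: int = 5
    var_snp: float = 0.95
    var_cnv: float = 0.05
    var_total_genetic: float = 1.0
    reliability_range: tuple[float, float] = (0.5, 0.95)
    caller_endpoint_jitter_prob: float = 0.2
    mendelian_error_rate: float = 0.05
    seed: int = 0
    # generator plumbing beyond the headline conditions
    breeds: tuple[str, ...] = ("B1",)
    fst: float = 0.05
    ld_block_size: int = 1
    cnv_span_snps: tuple[int, int] = (5, 12)
    missing_rate: float = 0.01
    n_ped_pairs: int = 100
    n_tampered_snps: int = 5
    decoy_fraction: float = 0.1
    erc_range: tuple[float, float] = (1.0, 20.0)
    mixed_fraction: float = 0.1
    double_class_prob: float = 0.1
    trait: str = "carcass_weight"

    def validate(self) -> None:
        for lo, hi, name in (
            (*self.maf_range, "maf_range"),
            (*self.cnv_carrier_freq_range, "cnv_carrier_freq_range"),
            (*self.reliability_range, "reliability_range"),
            (*self.cnv_span_snps, "cnv_span_snps"),
            (*self.erc_range, "erc_range"),
        ):
            if lo > hi:
                raise ValueError(f"{name} bounds out of order")
        if not (0 < self.maf_range[0] and self.maf_range[1] <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if not (0 < self.reliability_range[0] and self.reliability_range[1] <= 1):
            raise ValueError("reliability_range must lie in (0, 1]")
        if self.var_snp + self.var_cnv > self.var_total_genetic + 1e-12:
            raise ValueError("var_snp + var_cnv must not exceed var_total_genetic")
        if min(self.var_snp, self.var_cnv, self.var_total_genetic) < 0:
            raise ValueError("variances must be non-negative")
        if self.n_causal_snps > self.n_snps:
            raise ValueError("more causal SNPs than SNPs")
        if self.n_causal_cnvs > self.n_cnv_loci:
            raise ValueError("more causal CNVs than CNV loci")
        if self.cnv_span_snps[0] < 5:
            raise ValueError("truth CNV spans must cover >= 5 SNPs so that "
                             "1-SNP endpoint jitter cannot defeat the 3-SNP filter")


@dataclass
class TruthSet:
    true_bv: np.ndarray
    causal_snp_ids: list[str]
    causal_snp_effects: np.ndarray
    causal_cnv_ids: list[str]
    causal_cnv_effects: np.ndarray
    reliability: np.ndarray
    tampered_snp_ids: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_bv": self.true_bv.tolist(),
            "causal_snp_ids": self.causal_snp_ids,
            "causal_snp_effects": self.causal_snp_effects.tolist(),
            "causal_cnv_ids": self.causal_cnv_ids,
            "causal_cnv_effects": self.causal_cnv_effects.tolist(),
            "reliability": self.reliability.tolist(),
            "tampered_snp_ids": self.tampered_snp_ids,
        }
        Path(path).write_text(json.dumps(payload))


def _scale_to_variance(x: np.ndarray, target: float) -> np.ndarray:
    """Center and rescale so the sample variance is exactly ``target``."""
    x = x - x.mean()
    v = float(x.var())
    if target == 0 or v == 0:
        return np.zeros_like(x)
    return x * np.sqrt(target / v)


def _make_snp_map(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    per = np.full(cfg.n_chrom, cfg.n_snps // cfg.n_chrom)
    per[: cfg.n_snps % cfg.n_chrom] += 1
    rows = []
    idx = 0
    for c in range(1, cfg.n_chrom + 1):
        gaps = rng.integers(1_000, 10_000, size=per[c - 1])
        pos = np.cumsum(gaps)
        for p in pos:
            rows.append((f"snp{idx:06d}", c, int(p), idx))
            idx += 1
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos_bp", "index"])


def _draw_genotypes(cfg: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    p_anc = rng.uniform(*cfg.maf_range, size=cfg.n_snps)
    n_total = cfg.n_animals * len(cfg.breeds)
    geno = np.empty((n_total, cfg.n_snps), dtype=float)
    for b_idx in range(len(cfg.breeds)):
        if len(cfg.breeds) > 1 and cfg.fst > 0:
            f = cfg.fst
            a = p_anc * (1 - f) / f
            b = (1 - p_anc) * (1 - f) / f
            p_b = np.clip(rng.beta(a, b), 1e-3, 1 - 1e-3)
        else:
            p_b = p_anc
        rows = slice(b_idx * cfg.n_animals, (b_idx + 1) * cfg.n_animals)
        if cfg.ld_block_size > 1:
            # block-copying LD: one latent draw per block, copied across the
            # block with a small per-SNP mutation probability
            g = np.empty((cfg.n_animals, cfg.n_snps))
            for start in range(0, cfg.n_snps, cfg.ld_block_size):
                stop = min(start + cfg.ld_block_size, cfg.n_snps)
                latent = rng.binomial(2, p_b[start], size=cfg.n_animals)
                for j in range(start, stop):
                    mutate = rng.random(cfg.n_animals) < 0.05
                    g[:, j] = np.where(mutate, rng.binomial(2, p_b[j], size=cfg.n_animals), latent)
        else:
            g = rng.binomial(2, p_b[None, :], size=(cfg.n_animals, cfg.n_snps)).astype(float)
        geno[rows] = g
    return geno, p_anc


def _apply_pedigree(
    geno: np.ndarray, pairs_idx: list[tuple[int, int]], p: np.ndarray, rng: np.random.Generator
) -> None:
    """Regenerate each progeny row by true inheritance from its parent:
    one allele transmitted from the parent's genotype, the other drawn
    from the population frequency."""
    for parent, child in pairs_idx:
        gp = geno[parent]
        transmitted = np.where(gp == 1, rng.integers(0, 2, size=gp.size), gp / 2)
        geno[child] = transmitted + rng.binomial(1, p)


def _place_cnv_loci(cfg: SimConfig, snp_map: pd.DataFrame, rng: np.random.Generator) -> list[tuple[int, int, int]]:
    """Non-overlapping (chrom, start_idx, end_idx) spans with a >= 5-SNP
    gap so distinct loci can never fall within the endpoint tolerance."""
    spans: list[tuple[int, int, int]] = []
    by_chrom = {c: g["index"].to_numpy() for c, g in snp_map.groupby("chrom")}
    chroms = list(by_chrom)
    attempts = 0
    while len(spans) < cfg.n_cnv_loci:
        attempts += 1
        if attempts > 200 * cfg.n_cnv_loci:
            raise ValueError("cannot place non-overlapping CNV loci; too many loci for the map")
        c = chroms[rng.integers(len(chroms))]
        idxs = by_chrom[c]
        span = int(rng.integers(cfg.cnv_span_snps[0], cfg.cnv_span_snps[1] + 1))
        if len(idxs) < span:
            continue
        s = int(idxs[rng.integers(len(idxs) - span + 1)])
        e = s + span - 1
        if all(c != c2 or e < s2 - 5 or s > e2 + 5 for c2, s2, e2 in spans):
            spans.append((c, s, e))
    spans.sort()
    return spans


def simulate_population(
    cfg: SimConfig,
) -> tuple[SnpPanel, list[CnvLocus], TruthSet, pd.DataFrame, list[tuple[str, str]]]:
    """Generate one population under the configured study conditions.

    Returns (panel, truth CNV loci, truth set, trait table, pedigree
    pairs).  Identical configs (including seed) give identical outputs.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    snp_map = _make_snp_map(cfg, rng)
    geno, p_anc = _draw_genotypes(cfg, rng)
    n_total = geno.shape[0]
    animal_ids = np.array([f"A{i:05d}" for i in range(n_total)], dtype=object)
    breed = np.repeat(list(cfg.breeds), cfg.n_animals).astype(object)

    if 2 * cfg.n_ped_pairs > n_total:
        raise ValueError("not enough animals for the requested pedigree pairs")
    pairs_idx = [(2 * i, 2 * i + 1) for i in range(cfg.n_ped_pairs)]
    _apply_pedigree(geno, pairs_idx, p_anc, rng)
    pairs = [(str(animal_ids[p]), str(animal_ids[c])) for p, c in pairs_idx]

    # --- CNV truth states ------------------------------------------------
    spans = _place_cnv_loci(cfg, snp_map, rng)
    pos = snp_map["pos_bp"].to_numpy()
    loci: list[CnvLocus] = []
    class_matrix = np.full((n_total, len(spans)), NORMAL, dtype=int)
    for l_idx, (c, s, e) in enumerate(spans):
        freq = rng.uniform(*cfg.cnv_carrier_freq_range)
        u = rng.random()
        direction = "mixed" if u < cfg.mixed_fraction else ("deletion" if u < 0.5 + cfg.mixed_fraction / 2 else "duplication")
        carriers = np.flatnonzero(rng.random(n_total) < freq)
        classes: dict[str, int] = {}
        for a in carriers:
            if direction == "mixed":
                is_del = rng.random() < 0.5
            else:
                is_del = direction == "deletion"
            double = rng.random() < cfg.double_class_prob
            cn = (0 if double else 1) if is_del else (4 if double else 3)
            class_matrix[a, l_idx] = cn
            classes[str(animal_ids[a])] = cn
        carriers_by_breed: dict[str, int] = {}
        for a in carriers:
            carriers_by_breed[str(breed[a])] = carriers_by_breed.get(str(breed[a]), 0) + 1
        loci.append(
            CnvLocus(
                locus_id=f"truth{l_idx:04d}",
                chrom=c,
                start_snp_index=s,
                end_snp_index=e,
                start_bp=int(pos[s]),
                end_bp=int(pos[e]),
                classes=classes,
                carriers_by_breed=carriers_by_breed,
            )
        )

    # --- true breeding values -------------------------------------------
    causal_snps = np.sort(rng.choice(cfg.n_snps, size=cfg.n_causal_snps, replace=False))
    snp_effects = rng.standard_normal(cfg.n_causal_snps)
    g_snp_raw = (geno[:, causal_snps] - geno[:, causal_snps].mean(axis=0)) @ snp_effects
    g_snp = _scale_to_variance(g_snp_raw, cfg.var_snp)
    scale_snp = 0.0 if g_snp_raw.std() == 0 or cfg.var_snp == 0 else np.sqrt(
        cfg.var_snp / g_snp_raw.var()
    )
    snp_effects_scaled = snp_effects * scale_snp

    carrier_counts = (class_matrix != NORMAL).sum(axis=0)
    eligible = np.flatnonzero(carrier_counts >= 3)
    pool = eligible if eligible.size >= cfg.n_causal_cnvs else np.arange(len(spans))
    causal_cnvs = np.sort(rng.choice(pool, size=cfg.n_causal_cnvs, replace=False))
    cnv_dosage = np.where(
        class_matrix[:, causal_cnvs] < NORMAL, -1.0,
        np.where(class_matrix[:, causal_cnvs] > NORMAL, 1.0, 0.0),
    )
    cnv_effects = rng.standard_normal(cfg.n_causal_cnvs) if cfg.var_cnv > 0 else np.zeros(cfg.n_causal_cnvs)
    g_cnv_raw = (cnv_dosage - cnv_dosage.mean(axis=0)) @ cnv_effects
    g_cnv = _scale_to_variance(g_cnv_raw, cfg.var_cnv)
    scale_cnv = 0.0 if g_cnv_raw.std() == 0 or cfg.var_cnv == 0 else np.sqrt(cfg.var_cnv / g_cnv_raw.var())
    cnv_effects_scaled = cnv_effects * scale_cnv

    true_bv = g_snp + g_cnv

    # --- deregressed EBVs ------------------------------------------------
    r2 = rng.uniform(*cfg.reliability_range, size=n_total)
    noise_var = cfg.var_total_genetic * (1.0 - r2) / r2
    debv = true_bv + rng.standard_normal(n_total) * np.sqrt(noise_var)
    erc = rng.uniform(*cfg.erc_range, size=n_total)
    traits = pd.DataFrame(
        {
            "animal_id": animal_ids,
            "breed": breed,
            "trait": cfg.trait,
            "debv": debv,
            "reliability": r2,
            "erc": erc,
        }
    )

    # --- missingness ------------------------------------------------------
    if cfg.missing_rate > 0:
        miss = rng.random(geno.shape) < cfg.missing_rate
        geno = geno.astype(float)
        geno[miss] = np.nan

    panel = SnpPanel(animal_ids, geno, snp_map, breed)
    truth = TruthSet(
        true_bv=true_bv,
        causal_snp_ids=[snp_map["snp_id"].iloc[i] for i in causal_snps],
        causal_snp_effects=snp_effects_scaled,
        causal_cnv_ids=[loci[i].locus_id for i in causal_cnvs],
        causal_cnv_effects=cnv_effects_scaled,
        reliability=r2,
    )
    return panel, loci, truth, traits, pairs


def _format_rawcnv(chrom: int, start_bp: int, end_bp: int, n_snps: int, cn: int, animal: str) -> str:
    length = end_bp - start_bp + 1
    return (
        f"chr{chrom}:{start_bp}-{end_bp}\tnumsnp={n_snps}\t"
        f"length={length:,}\t{_STATE_OF_CN[cn]},cn={cn}\t{animal}"
    )


def emit_caller_files(
    truth_loci: Sequence[CnvLocus],
    snp_map: pd.DataFrame,
    jitter_prob: float,
    seed: int,
    path_a: str | Path,
    path_b: str | Path,
    decoy_fraction: float = 0.1,
) -> tuple[Path, Path]:
    """Write two rawcnv-style files emulating independent callers.

    Every true per-animal call appears in both files; each endpoint of
    each caller's record is independently shifted by one SNP (direction
    uniform) with probability ``jitter_prob``, staying inside the
    chromosome.  A ``decoy_fraction`` of extra 2-SNP calls is appended to
    each file; these must be removed by the 3-SNP consensus filter.
    """
    rng = np.random.default_rng(seed)
    pos = snp_map["pos_bp"].to_numpy()
    chrom_arr = snp_map["chrom"].to_numpy()
    bounds = {c: (int(ix.min()), int(ix.max())) for c, ix in snp_map.groupby("chrom")["index"]}
    lines: dict[str, list[str]] = {"A": [], "B": []}
    n_true = 0
    for locus in truth_loci:
        lo, hi = bounds[locus.chrom]
        for animal, cn in sorted(locus.classes.items()):
            if cn == NORMAL:
                continue
            n_true += 1
            for caller in ("A", "B"):
                s, e = locus.start_snp_index, locus.end_snp_index
                if rng.random() < jitter_prob:
                    s = int(np.clip(s + rng.choice((-1, 1)), lo, hi))
                if rng.random() < jitter_prob:
                    e = int(np.clip(e + rng.choice((-1, 1)), lo, hi))
                if s > e:  # pragma: no cover - impossible for spans >= 3 SNPs
                    s, e = e, s
                lines[caller].append(
                    _format_rawcnv(locus.chrom, int(pos[s]), int(pos[e]), e - s + 1, cn, animal)
                )
    n_decoys = int(round(decoy_fraction * n_true))
    animals = sorted({a for l in truth_loci for a in l.classes})
    for caller in ("A", "B"):
        for _ in range(n_decoys):
            i = int(rng.integers(len(pos) - 1))
            if chrom_arr[i] != chrom_arr[i + 1]:
                i -= 1
            cn = int(rng.choice((1, 3)))
            animal = animals[rng.integers(len(animals))] if animals else "A00000"
            lines[caller].append(
                _format_rawcnv(int(chrom_arr[i]), int(pos[i]), int(pos[i + 1]), 2, cn, animal)
            )
    path_a, path_b = Path(path_a), Path(path_b)
    path_a.write_text("\n".join(lines["A"]) + "\n")
    path_b.write_text("\n".join(lines["B"]) + "\n")
    return path_a, path_b


def inject_mendelian_errors(
    panel: SnpPanel,
    pairs: Sequence[tuple[str, str]],
    cfg: SimConfig,
) -> tuple[SnpPanel, list[str]]:
    """Create opposing-homozygote conflicts at a recorded set of SNPs.

    For each of ``cfg.n_tampered_snps`` randomly chosen SNPs, exactly
    ``round(cfg.mendelian_error_rate * n_pairs)`` pairs are rewritten to
    parent=0 / progeny=2.  Returns the modified panel and the tampered
    SNP ids.
    """
    if len(pairs) == 0:
        raise ValueError("no parent-progeny pairs to tamper")
    rng = np.random.default_rng(cfg.seed + 1)
    geno = panel.geno.copy()
    n_conflict = int(round(cfg.mendelian_error_rate * len(pairs)))
    tampered_snps = sorted(rng.choice(panel.n_snps, size=cfg.n_tampered_snps, replace=False))
    parent_rows = panel.animal_index([p for p, _ in pairs])
    child_rows = panel.animal_index([c for _, c in pairs])
    tampered_ids: list[str] = []
    for j in tampered_snps:
        tampered_ids.append(panel.snp_map["snp_id"].iloc[j])
        if n_conflict == 0:
            continue
        chosen = rng.choice(len(pairs), size=n_conflict, replace=False)
        geno[parent_rows[chosen], j] = 0.0
        geno[child_rows[chosen], j] = 2.0
    out = SnpPanel(panel.animal_ids, geno, panel.snp_map.copy(), panel.breed)
    return out, tampered_ids


def write_population(
    out_dir: str | Path,
    cfg: SimConfig,
) -> dict[str, Path]:
    """Simulate and write every artefact the pipeline consumes.

    Files: genotypes.tsv, snp_map.tsv, caller_a.rawcnv, caller_b.rawcnv,
    traits.tsv, pedigree.tsv, truth.json, config.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel, loci, truth, traits, pairs = simulate_population(cfg)
    if cfg.mendelian_error_rate > 0 and cfg.n_tampered_snps > 0:
        panel, tampered = inject_mendelian_errors(panel, pairs, cfg)
        truth.tampered_snp_ids = tampered
    paths = {
        "genotypes": out / "genotypes.tsv",
        "snp_map": out / "snp_map.tsv",
        "caller_a": out / "caller_a.rawcnv",
        "caller_b": out / "caller_b.rawcnv",
        "traits": out / "traits.tsv",
        "pedigree": out / "pedigree.tsv",
        "truth": out / "truth.json",
        "config": out / "config.json",
    }
    panel.write(paths["genotypes"], paths["snp_map"])
    emit_caller_files(
        loci, panel.snp_map, cfg.caller_endpoint_jitter_prob, cfg.seed + 2,
        paths["caller_a"], paths["caller_b"], cfg.decoy_fraction,
    )
    traits.to_csv(paths["traits"], sep="\t", index=False)
    pd.DataFrame(pairs, columns=["parent", "progeny"]).to_csv(
        paths["pedigree"], sep="\t", index=False
    )
    truth.to_json(paths["truth"])
    paths["config"].write_text(json.dumps(asdict(cfg)))
    return paths
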