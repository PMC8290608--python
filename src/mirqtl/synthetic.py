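"""Ground-truth-labelled simulation of a milk FT-MIR GWAS dataset.

The generator emulates the structure the downstream stages assume:

* a two-generation half-sib pedigree (few sires, many dams) giving the
  numerator relationship matrix nontrivial structure;
* LD-blocked genotypes — founder haplotypes are mosaics of a small number
  of per-block haplotype states, so adjacent-marker r² is high within a
  block and decays across blocks; offspring receive block-level
  recombinant gametes;
* three founder breeds with Balding–Nichols divergent allele frequencies,
  so crossbred cows carry fractional breed and heterosis covariates;
* latent milk constituents (fat, protein, lactose, minor solids) that map
  linearly onto the wavenumber grid through Gaussian spectral signatures,
  with residual variance inflated inside designated noise regions of the
  spectrum;
* planted QTL acting on constituents either directly (coding variants,
  annotated HIGH / MODERATE / LOW_SPLICE_REGION) or through the
  expression of a cis gene (expression-mediated, annotated OTHER);
* repeated test-day records per cow with parity, days-in-milk,
  herd-by-test-day, breed and heterosis fixed effects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import (
    BREEDS,
    HET_PAIRS,
    AnnotationTable,
    ExpressionMatrix,
    GenotypeMatrix,
    PedigreeTable,
    TestDayRecord,
    VariantRecord,
    maf_from_dosages,
    write_annotations,
    write_expression,
    write_pedigree,
    write_phenotypes,
    write_vcf,
)

COMPONENT_NAMES = ("fat", "protein", "lactose", "minor")

# Gaussian signatures over the wavenumber axis for each latent constituent,
# placed on the classical mid-infrared absorption bands: triglyceride
# C=O / C-H stretches for fat, amide I/II/III for protein, carbohydrate
# C-O stretches for lactose, and citrate/phosphate bands for minor solids.
DEFAULT_SIGNATURES: dict[str, list[tuple[float, float, float]]] = {
    "fat": [(1745, 25, 1.0), (2855, 30, 0.7), (2925, 30, 0.8), (1160, 30, 0.5)],
    "protein": [(1548, 35, 0.9), (1652, 35, 1.0), (1240, 40, 0.4)],
    "lactose": [(1045, 25, 1.0), (1080, 25, 0.8), (997, 25, 0.5)],
    "minor": [(1390, 30, 0.6), (1580, 25, 0.4), (930, 35, 0.3)],
}

DEFAULT_NOISE_REGIONS = ((649.0, 970.0), (1608.0, 1682.0), (3021.0, 3849.0))


@dataclass
class PlantedQtl:
    """A causal variant planted on one latent milk constituent."""

    chrom: str
    target_pos: int
    component: int
    mechanism: str  # "coding" | "expression_mediated"
    target_pve: float  # intended share of adjusted-trait variance
    impact: str  # coding: HIGH/MODERATE/LOW_SPLICE_REGION; mediated: OTHER
    gene: str
    vid: str | None = None  # resolved against the simulated variants
    effect: float | None = None  # constituent units per alt allele
    beta_e: float | None = None  # expression units per alt allele (mediated)

    def __post_init__(self) -> None:
        if self.mechanism == "coding":
            if self.impact not in ("HIGH", "MODERATE", "LOW_SPLICE_REGION"):
                raise ValueError("coding QTL must carry a PIV impact class")
        elif self.mechanism == "expression_mediated":
            if self.impact != "OTHER":
                raise ValueError("expression-mediated QTL are annotated OTHER")
        else:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")


@dataclass
class DecoyEqtl:
    """A planted eQTL with no trait effect (for co-localization controls)."""

    chrom: str
    target_pos: int
    gene: str
    var_explained: float = 0.2
    away_from_pos: int | None = None  # keep r2 < max_r2 to the variant there
    max_r2: float = 0.3
    vid: str | None = None
    beta_e: float | None = None


def default_planted_qtl() -> list[PlantedQtl]:
    """Ten QTL over three chromosomes, all in distinct 1-Mbp bins.

    Chromosome 1 carries two fat QTL 20 Mbp apart (5% and 2.5% of trait
    variance) to exercise the iterative conditional separation.
    """
    q = PlantedQtl
    return [
        q("1", 5_000_000, 0, "coding", 0.05, "MODERATE", "GFAT1"),
        q("1", 25_000_000, 0, "coding", 0.03, "MODERATE", "GFAT2"),
        q("1", 40_000_000, 1, "expression_mediated", 0.03, "OTHER", "GPROE1"),
        q("2", 8_000_000, 1, "coding", 0.04, "HIGH", "GPRO1"),
        q("2", 30_000_000, 2, "coding", 0.05, "MODERATE", "GLAC1"),
        q("2", 45_000_000, 0, "expression_mediated", 0.03, "OTHER", "GFATE1"),
        q("3", 10_000_000, 2, "coding", 0.03, "LOW_SPLICE_REGION", "GLAC2"),
        q("3", 25_000_000, 3, "coding", 0.04, "MODERATE", "GMIN1"),
        q("3", 35_000_000, 2, "expression_mediated", 0.03, "OTHER", "GLACE1"),
        q("3", 48_000_000, 1, "coding", 0.03, "MODERATE", "GPRO2"),
    ]


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study-scale conditions."""

    seed: int = 2021
    n_animals: int = 2000  # phenotyped cows
    n_sires: int = 25
    n_dams: int | None = None  # default n_animals // 2
    n_chromosomes: int = 3
    chrom_length_bp: int = 50_000_000
    variants_per_chrom: int = 5000
    ld_block_length_bp: int = 100_000
    n_founder_states: int = 4  # haplotype states per block and breed
    crossovers_per_chrom: float = 1.5
    maf_beta_params: tuple[float, float] = (0.5, 0.5)
    breed_fst: float = 0.1
    breed_freqs: tuple[float, float, float] = (0.4, 0.3, 0.3)  # HOL, FR, JE
    n_components: int = 4
    n_wavenumbers: int = 895
    wavenumber_range: tuple[float, float] = (649.0, 3998.0)
    component_signatures: dict = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_SIGNATURES.items()}
    )
    noise_regions: tuple = DEFAULT_NOISE_REGIONS
    planted_qtl: list[PlantedQtl] = field(default_factory=default_planted_qtl)
    decoy_eqtl: list[DecoyEqtl] = field(default_factory=list)
    component_baseline: tuple = (4.4, 3.4, 4.8, 0.8)  # % fat, protein, lactose, minor
    sigma2_polygenic: float = 0.40  # per constituent, additive genetic
    polygenic_mode: str = "pedigree"  # "pedigree" (A-matrix variance) | "genomic"
    sigma2_animal: float = 0.25  # permanent environment
    sigma2_resid: float = 0.35  # per-record constituent noise
    fixed_effect_sd: dict = field(
        default_factory=lambda: {
            "parity": 0.30, "dim": 0.30, "htd": 0.50, "breed": 0.50, "het": 0.20,
        }
    )
    spectral_noise_sd: float = 0.02  # per-wavenumber residual, clean regions
    noise_region_inflation: float = 5.0  # sd multiplier inside noise regions
    records_per_animal_probs: dict = field(
        default_factory=lambda: {1: 0.15, 2: 0.35, 3: 0.30, 4: 0.20}
    )
    n_herds: int = 40
    n_test_days: int = 8
    n_instruments: int = 3
    outlier_fraction: float = 0.0  # records given gross spectral spikes
    outlier_spike_sd: float = 10.0  # spike magnitude in overall-spectrum sd units
    grm_panel_stride: int = 5
    qtl_maf_range: tuple[float, float] = (0.15, 0.45)
    # expression cohort: partially overlapping with the phenotyped cows
    n_expression_animals: int = 357
    expression_overlap: int = 62
    n_background_genes: int = 12
    expression_h2: float = 0.3
    n_decoy_piv: int = 5

    def __post_init__(self) -> None:
        if self.n_dams is None:
            self.n_dams = max(2, self.n_animals // 2)
        self.planted_qtl = [
            q if isinstance(q, PlantedQtl) else PlantedQtl(**q)
            for q in self.planted_qtl
        ]
        self.decoy_eqtl = [
            d if isinstance(d, DecoyEqtl) else DecoyEqtl(**d)
            for d in self.decoy_eqtl
        ]
        n_blocks = self.chrom_length_bp // self.ld_block_length_bp
        if self.variants_per_chrom < 2 * n_blocks:
            raise ValueError(
                "variants_per_chrom must give at least 2 variants per LD block"
            )
        lo, hi = self.wavenumber_range
        for a, b in self.noise_regions:
            if not (lo <= a <= b <= hi):
                raise ValueError(f"noise region ({a}, {b}) outside the grid")

    @property
    def wavenumber_grid(self) -> np.ndarray:
        lo, hi = self.wavenumber_range
        return np.linspace(lo, hi, self.n_wavenumbers)

    def mixing_matrix(self) -> np.ndarray:
        """(n_components, n_wavenumbers) Gaussian-peak signatures."""
        grid = self.wavenumber_grid
        m = np.zeros((self.n_components, self.n_wavenumbers))
        for k, name in enumerate(COMPONENT_NAMES[: self.n_components]):
            for centre, width, height in self.component_signatures[name]:
                m[k] += height * np.exp(-0.5 * ((grid - centre) / width) ** 2)
        return m

    def noise_mask(self) -> np.ndarray:
        grid = self.wavenumber_grid
        mask = np.zeros(self.n_wavenumbers, dtype=bool)
        for a, b in self.noise_regions:
            mask |= (grid >= a) & (grid <= b)
        return mask


@dataclass
class GroundTruth:
    """Everything the evaluator needs to score a pipeline run."""

    planted_qtl: list[PlantedQtl]
    decoy_eqtl: list[DecoyEqtl]
    mixing_matrix: np.ndarray
    composition_loadings: np.ndarray  # (3, n_components), FP/LP/PP rows
    animal_values: pd.DataFrame  # animal x constituent true genetic+PE values
    gene_effects: dict[str, dict]  # gene -> {vid, beta_e}
    expected_h2: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        blob = {
            "planted_qtl": [asdict(q) for q in self.planted_qtl],
            "decoy_eqtl": [asdict(d) for d in self.decoy_eqtl],
            "mixing_matrix": self.mixing_matrix.tolist(),
            "composition_loadings": self.composition_loadings.tolist(),
            "animal_values": self.animal_values.to_dict(orient="list"),
            "gene_effects": self.gene_effects,
            "expected_h2": self.expected_h2,
        }
        with open(path, "w") as fh:
            json.dump(blob, fh)


# ---------------------------------------------------------------------------
# Genotypes and pedigree

def _founder_breeds(cfg: SimulationConfig, rng: np.random.Generator,
                    n: int) -> np.ndarray:
    return rng.choice(len(BREEDS), size=n, p=np.asarray(cfg.breed_freqs))


def simulate_genotypes(cfg: SimulationConfig
                       ) -> tuple[GenotypeMatrix, PedigreeTable, dict]:
    """Simulate founder + offspring genotypes and the two-generation pedigree.

    Returns the genotype matrix over all animals (founders first), the
    pedigree, and a metadata dict carrying breed assignments and per-animal
    breed/heterosis covariates used by the phenotype stage.
    """
    rng = np.random.default_rng(cfg.seed)
    n_f = cfg.n_sires + cfg.n_dams
    sires = [f"S{i:04d}" for i in range(cfg.n_sires)]
    dams = [f"D{i:04d}" for i in range(cfg.n_dams)]
    cows = [f"C{i:05d}" for i in range(cfg.n_animals)]
    founders = sires + dams
    animals = founders + cows

    founder_breed = _founder_breeds(cfg, rng, n_f)
    sire_of = rng.integers(0, cfg.n_sires, size=cfg.n_animals)
    dam_of = (np.arange(cfg.n_animals) % cfg.n_dams) + cfg.n_sires

    ped_rows: list[tuple[str, str | None, str | None]] = []
    for a in founders:
        ped_rows.append((a, None, None))
    for i, c in enumerate(cows):
        ped_rows.append((c, sires[sire_of[i]], dams[dam_of[i] - cfg.n_sires]))
    pedigree = PedigreeTable(ped_rows)

    # breed proportion vectors: founders pure, cows the parental average
    bp = np.zeros((len(animals), len(BREEDS)))
    bp[np.arange(n_f), founder_breed] = 1.0
    bp[n_f:] = 0.5 * (bp[sire_of] + bp[dam_of])

    # heterosis: het_AB = sire_A * dam_B + sire_B * dam_A (AY pairs stay 0)
    het = np.zeros((len(animals), len(HET_PAIRS)))
    pair_idx = {"FRxJE": (1, 2), "FRxHOL": (1, 0), "JExHOL": (2, 0)}
    for i in range(cfg.n_animals):
        sb, db = bp[sire_of[i]], bp[dam_of[i]]
        for j, name in enumerate(HET_PAIRS):
            if name in pair_idx:
                a, b = pair_idx[name]
                het[n_f + i, j] = sb[a] * db[b] + sb[b] * db[a]

    all_dos: list[np.ndarray] = []
    variants: list[VariantRecord] = []
    vid_counter = 0
    for c in range(cfg.n_chromosomes):
        chrom = str(c + 1)
        pos = np.sort(
            rng.choice(
                np.arange(1, cfg.chrom_length_bp + 1),
                size=cfg.variants_per_chrom,
                replace=False,
            )
        )
        block = (pos - 1) // cfg.ld_block_length_bp
        n_blocks = int(block.max()) + 1
        m = len(pos)

        # Each block carries a chain of H founder haplotype states shared by
        # all breeds; a marker's alt allele occupies a contiguous run of
        # states whose length is set by its Beta-drawn target frequency, so
        # markers with the same run are perfectly correlated and nested runs
        # correlate strongly (high within-block r2). Breeds differ in how
        # often they use each state (Dirichlet-divergent frequencies), which
        # produces Fst-like allele-frequency divergence.
        H = cfg.n_founder_states
        p_anc = np.clip(rng.beta(*cfg.maf_beta_params, size=m), 0.02, 0.98)
        k_states = np.clip(np.round(p_anc * H).astype(int), 1, H - 1)
        run_start = rng.integers(0, H - k_states + 1)
        idx_h = np.arange(H)[:, None]
        states = ((idx_h >= run_start) & (idx_h < run_start + k_states)
                  ).astype(np.int8)  # (H, m)

        f = cfg.breed_fst
        alpha = np.full(H, max((1 - f) / max(f, 1e-6), 1e-3) / H)
        freqs = np.stack(
            [rng.dirichlet(alpha, size=n_blocks) for _ in BREEDS]
        )  # (breeds, n_blocks, H)
        cum = np.cumsum(freqs, axis=2)

        # founder haplotypes: pick one state per block by breed frequency
        fh = np.empty((2 * n_f, m), dtype=np.int8)
        col = np.arange(m)
        for b in range(len(BREEDS)):
            fidx = np.where(founder_breed == b)[0]
            if len(fidx) == 0:
                continue
            hidx = np.concatenate([2 * fidx, 2 * fidx + 1])
            u = rng.random((len(hidx), n_blocks))
            choice = (u[:, :, None] > cum[b][None, :, :]).sum(axis=2)
            choice = np.minimum(choice, H - 1)
            fh[hidx] = states[choice[:, block], col]

        # offspring gametes: block-level Markov recombination along the chromosome
        p_switch = min(0.5, cfg.crossovers_per_chrom / max(1, n_blocks - 1))

        def gametes(parent_idx: np.ndarray) -> np.ndarray:
            n_off = len(parent_idx)
            switches = rng.random((n_off, n_blocks)) < p_switch
            switches[:, 0] = rng.random(n_off) < 0.5
            which = np.cumsum(switches, axis=1) % 2  # (n_off, n_blocks)
            hap_row = 2 * parent_idx[:, None] + which[:, block]
            return fh[hap_row, col]

        off = gametes(sire_of) + gametes(dam_of)
        dos = np.concatenate([fh[0::2] + fh[1::2], off]).astype(np.float64)
        maf = maf_from_dosages(dos)
        for j in range(m):
            variants.append(
                VariantRecord(
                    chrom=chrom,
                    pos=int(pos[j]),
                    vid=f"sv{vid_counter + j:07d}",
                    ref="A",
                    alt="G",
                    maf=float(maf[j]),
                    allelic_r2=1.0,
                )
            )
        vid_counter += m
        all_dos.append(dos)

    genotypes = GenotypeMatrix(animals, variants, np.concatenate(all_dos, axis=1))
    meta = {
        "founders": founders,
        "cows": cows,
        "breed_props": bp,
        "het_props": het,
        "sire_of": sire_of,
        "dam_of": dam_of,
    }
    return genotypes, pedigree, meta


def _resolve_variant(genotypes: GenotypeMatrix, chrom: str, target_pos: int,
                     maf_range: tuple[float, float],
                     avoid: tuple[np.ndarray, float] | None = None,
                     breed_props: np.ndarray | None = None,
                     max_breed_r2: float = 0.1) -> int:
    """Index of the variant nearest ``target_pos`` with acceptable MAF.

    Causal variants are restricted to sites with low breed differentiation
    (dosage R2 on the breed-proportion covariates below ``max_breed_r2``),
    so the configured variance share is not silently absorbed by the
    population-structure correction. ``avoid`` = (dosage_vector, max_r2)
    additionally restricts to variants in low LD with that vector (used
    for independent-architecture controls).
    """
    chroms = genotypes.chroms
    pos = genotypes.positions
    maf = genotypes.recompute_maf()
    ok = (chroms == chrom) & (maf >= maf_range[0]) & (maf <= maf_range[1])
    idx = np.where(ok)[0]
    if len(idx) == 0:
        raise ValueError(f"no variant with MAF in {maf_range} on chrom {chrom}")
    order = idx[np.argsort(np.abs(pos[idx] - target_pos))]
    qb = None
    if breed_props is not None:
        B = np.column_stack([np.ones(len(breed_props)), breed_props])
        qb, _ = np.linalg.qr(B)
    for i in order:
        d = genotypes.dosages[:, i]
        if qb is not None:
            resid = d - qb @ (qb.T @ d)
            tss = np.sum((d - d.mean()) ** 2)
            if tss <= 0 or 1 - resid @ resid / tss > max_breed_r2:
                continue
        if avoid is not None:
            vec, max_r2 = avoid
            r = np.corrcoef(d, vec)[0, 1]
            if r * r >= max_r2:
                continue
        return int(i)
    raise ValueError(
        f"no variant near {chrom}:{target_pos} satisfying the MAF, breed-"
        "stratification and LD constraints"
    )


def _pedigree_polygenic(cfg: SimulationConfig, meta: dict, sigma2: float,
                        rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Additive polygenic values transmitted through the pedigree.

    Founders draw N(0, sigma2); offspring take the parent average plus a
    Mendelian-sampling deviation of variance sigma2/2 (no inbreeding at
    pedigree depth two). Returns (n_all_animals, size).
    """
    n_f = cfg.n_sires + cfg.n_dams
    g = np.empty((n_f + cfg.n_animals, size))
    g[:n_f] = rng.normal(0, np.sqrt(sigma2), size=(n_f, size))
    ms = rng.normal(0, np.sqrt(sigma2 / 2), size=(cfg.n_animals, size))
    g[n_f:] = 0.5 * (g[meta["sire_of"]] + g[meta["dam_of"]]) + ms
    return g


def _genomic_polygenic(genotypes: GenotypeMatrix, sigma2: float,
                       rng: np.random.Generator, size: int,
                       maf_min: float = 0.01) -> np.ndarray:
    """Polygenic values as a sum of small effects over all common markers.

    Effects are iid N(0, sigma2/m) on standardized dosages, so the expected
    genetic variance is sigma2 and the realized covariance among animals is
    the genomic relationship itself.
    """
    maf = genotypes.recompute_maf()
    keep = np.where(maf >= maf_min)[0]
    m = len(keep)
    beta = rng.normal(0, np.sqrt(sigma2 / m), size=(m, size))
    g = np.zeros((genotypes.n_animals, size))
    offset = 0
    for chunk in np.array_split(keep, max(1, m // 2000)):
        D = genotypes.dosages[:, chunk]
        p = D.mean(axis=0) / 2
        W = (D - 2 * p) / np.sqrt(2 * p * (1 - p))
        g += W @ beta[offset:offset + len(chunk)]
        offset += len(chunk)
    return g


def _mean_inverse_records(cfg: SimulationConfig) -> float:
    ks = np.array(list(cfg.records_per_animal_probs))
    ps = np.array(list(cfg.records_per_animal_probs.values()))
    return float(np.sum(ps / ks))


def simulate_phenotypes(cfg: SimulationConfig, genotypes: GenotypeMatrix,
                        pedigree: PedigreeTable, meta: dict
                        ) -> tuple[list[TestDayRecord], GroundTruth]:
    """Simulate test-day spectra and composition traits for the cows."""
    rng = np.random.default_rng(cfg.seed + 1)
    n_f = cfg.n_sires + cfg.n_dams
    cows = meta["cows"]
    k = cfg.n_components

    # resolve planted QTL to actual variants and effect sizes
    sigma2_ref = (
        cfg.sigma2_polygenic
        + cfg.sigma2_animal
        + cfg.sigma2_resid * _mean_inverse_records(cfg)
    )
    maf = genotypes.recompute_maf()
    bp = meta["breed_props"]
    for q in cfg.planted_qtl:
        j = _resolve_variant(genotypes, q.chrom, q.target_pos, cfg.qtl_maf_range,
                             breed_props=bp)
        q.vid = genotypes.variants[j].vid
        p = maf[j]
        a = np.sqrt(q.target_pve * sigma2_ref / (2 * p * (1 - p)))
        q.effect = float(a)
        if q.mechanism == "expression_mediated":
            # expression variance share var_explained through beta_e; the
            # constituent receives its effect through the gene
            q.beta_e = float(np.sqrt(0.2 / (2 * p * (1 - p))))

    for d in cfg.decoy_eqtl:
        avoid = None
        if d.away_from_pos is not None:
            ai = _resolve_variant(genotypes, d.chrom, d.away_from_pos,
                                  cfg.qtl_maf_range, breed_props=bp)
            avoid = (genotypes.dosages[:, ai], d.max_r2)
        j = _resolve_variant(genotypes, d.chrom, d.target_pos, cfg.qtl_maf_range,
                             avoid=avoid, breed_props=bp)
        d.vid = genotypes.variants[j].vid
        p = maf[j]
        d.beta_e = float(np.sqrt(d.var_explained / (2 * p * (1 - p))))

    # per-animal constituent values: planted + polygenic + permanent environment
    if cfg.polygenic_mode == "pedigree":
        poly = _pedigree_polygenic(cfg, meta, cfg.sigma2_polygenic, rng, size=k)
    elif cfg.polygenic_mode == "genomic":
        poly = _genomic_polygenic(genotypes, cfg.sigma2_polygenic, rng, size=k)
    else:
        raise ValueError(f"unknown polygenic_mode {cfg.polygenic_mode!r}")
    pe = rng.normal(0, np.sqrt(cfg.sigma2_animal), size=(len(genotypes.animals), k))
    u = poly.copy()
    for q in cfg.planted_qtl:
        d = genotypes.vid_column(q.vid)
        u[:, q.component] += q.effect * (d - d.mean())

    # fixed-effect solutions on the constituent scale
    sd = cfg.fixed_effect_sd
    parity_eff = rng.normal(0, sd["parity"], size=(5, k))
    dim_eff = rng.normal(0, sd["dim"], size=(9, k))
    breed_coef = rng.normal(0, sd["breed"], size=(len(BREEDS), k))
    het_coef = rng.normal(0, sd["het"], size=(len(HET_PAIRS), k))
    htd_eff: dict[str, np.ndarray] = {}

    mix = cfg.mixing_matrix()
    noise_sd = np.full(cfg.n_wavenumbers, cfg.spectral_noise_sd)
    noise_sd[cfg.noise_mask()] *= cfg.noise_region_inflation
    baseline = np.asarray(cfg.component_baseline[:k])
    comp_loadings = np.zeros((3, k))
    comp_loadings[0, 0] = comp_loadings[1, 2] = comp_loadings[2, 1] = 1.0

    ks_rec = np.array(list(cfg.records_per_animal_probs))
    ps_rec = np.array(list(cfg.records_per_animal_probs.values()))
    herd_of_cow = rng.integers(0, cfg.n_herds, size=cfg.n_animals)
    parity_of_cow = rng.choice(
        np.arange(1, 8), size=cfg.n_animals,
        p=[0.3, 0.25, 0.18, 0.12, 0.08, 0.05, 0.02],
    )
    records: list[TestDayRecord] = []
    spec_sd_overall = float(mix.sum(axis=0).std()) + 1e-9
    for i, cow in enumerate(cows):
        gi = n_f + i
        n_rec = int(rng.choice(ks_rec, p=ps_rec))
        herd = herd_of_cow[i]
        inst = f"I{herd % cfg.n_instruments}"
        for _ in range(n_rec):
            tday = int(rng.integers(0, cfg.n_test_days))
            htd = f"H{herd:03d}_T{tday}"
            if htd not in htd_eff:
                htd_eff[htd] = rng.normal(0, sd["htd"], size=k)
            dim = int(rng.integers(5, 306))
            parity = int(parity_of_cow[i])
            c_rec = (
                baseline
                + u[gi]
                + pe[gi]
                + parity_eff[min(parity, 5) - 1]
                + dim_eff[min(int(np.ceil(dim / 30)), 9) - 1]
                + htd_eff[htd]
                + meta["breed_props"][gi] @ breed_coef
                + meta["het_props"][gi] @ het_coef
                + rng.normal(0, np.sqrt(cfg.sigma2_resid), size=k)
            )
            spectrum = c_rec @ mix + rng.normal(0, noise_sd)
            if cfg.outlier_fraction > 0 and rng.random() < cfg.outlier_fraction:
                start = int(rng.integers(0, max(1, cfg.n_wavenumbers - 30)))
                spectrum[start:start + 30] += cfg.outlier_spike_sd * spec_sd_overall
            records.append(
                TestDayRecord(
                    animal=cow,
                    parity=parity,
                    dim=dim,
                    herd_testday=htd,
                    breed_props=meta["breed_props"][gi],
                    het_props=meta["het_props"][gi],
                    spectrum=spectrum,
                    composition=c_rec @ comp_loadings.T,
                    instrument=inst,
                )
            )

    qtl_var = {t: 0.0 for t in range(k)}
    for q in cfg.planted_qtl:
        p = maf[genotypes.index_of(q.vid)]
        qtl_var[q.component] += 2 * p * (1 - p) * q.effect**2
    expected_h2 = {}
    for t, name in enumerate(COMPONENT_NAMES[:k]):
        var_g = cfg.sigma2_polygenic + qtl_var[t]
        denom = (var_g + cfg.sigma2_animal
                 + cfg.sigma2_resid * _mean_inverse_records(cfg))
        expected_h2[name] = var_g / denom if denom > 0 else 0.0

    truth = GroundTruth(
        planted_qtl=cfg.planted_qtl,
        decoy_eqtl=cfg.decoy_eqtl,
        mixing_matrix=mix,
        composition_loadings=comp_loadings,
        animal_values=pd.DataFrame(
            u + pe, index=genotypes.animals, columns=COMPONENT_NAMES[:k]
        ),
        gene_effects={},
        expected_h2=expected_h2,
    )
    return records, truth


def simulate_expression(cfg: SimulationConfig, genotypes: GenotypeMatrix,
                        pedigree: PedigreeTable, meta: dict,
                        truth: GroundTruth | None = None) -> ExpressionMatrix:
    """Expression phenotypes for a cohort partially overlapping the cows.

    Mediating genes sit cis to their planted causal variant; expression is
    beta_e x dosage + pedigree polygenic + noise, so the trait QTL and the
    eQTL share the causal variant. Decoy genes carry an eQTL with no trait
    effect; background genes carry none.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    n_f = cfg.n_sires + cfg.n_dams
    cows, founders = meta["cows"], meta["founders"]
    n_overlap = min(cfg.expression_overlap, len(cows))
    overlap = list(rng.choice(cows, size=n_overlap, replace=False))
    n_extra = min(cfg.n_expression_animals - n_overlap, len(founders))
    extra = list(rng.choice(founders, size=max(0, n_extra), replace=False))
    cohort = overlap + extra
    cohort_idx = [genotypes.animals.index(a) for a in cohort]

    genes: list[str] = []
    rows = []
    causal: dict[str, tuple[str, float]] = {}
    for q in cfg.planted_qtl:
        if q.mechanism != "expression_mediated":
            continue
        j = genotypes.index_of(q.vid)
        v = genotypes.variants[j]
        start = max(1, v.pos - int(rng.integers(10_000, 50_000)))
        genes.append(q.gene)
        rows.append((q.gene, v.chrom, start, start + 20_000))
        causal[q.gene] = (q.vid, q.beta_e)
    for d in cfg.decoy_eqtl:
        j = genotypes.index_of(d.vid)
        v = genotypes.variants[j]
        start = max(1, v.pos - int(rng.integers(10_000, 50_000)))
        genes.append(d.gene)
        rows.append((d.gene, v.chrom, start, start + 20_000))
        causal[d.gene] = (d.vid, d.beta_e)
    for b in range(cfg.n_background_genes):
        chrom = str(int(rng.integers(1, cfg.n_chromosomes + 1)))
        start = int(rng.integers(1, cfg.chrom_length_bp - 30_000))
        name = f"BG{b:03d}"
        genes.append(name)
        rows.append((name, chrom, start, start + 20_000))

    poly = _pedigree_polygenic(cfg, meta, cfg.expression_h2, rng, size=len(genes))
    vals = np.empty((len(cohort), len(genes)))
    for gi, gene in enumerate(genes):
        e = poly[cohort_idx, gi] + rng.normal(
            0, np.sqrt(max(1e-8, 1 - cfg.expression_h2)), size=len(cohort)
        )
        if gene in causal:
            vid, beta = causal[gene]
            dose = genotypes.vid_column(vid)[cohort_idx]
            e = e + beta * (dose - dose.mean())
        vals[:, gi] = e

    if truth is not None:
        truth.gene_effects = {
            g: {"vid": v, "beta_e": b} for g, (v, b) in causal.items()
        }
    gp = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])
    return ExpressionMatrix(cohort, genes, vals, gp)


def make_annotations(cfg: SimulationConfig, genotypes: GenotypeMatrix
                     ) -> AnnotationTable:
    """Annotation fixture: planted QTL plus a few decoy PIV-class variants."""
    rng = np.random.default_rng(cfg.seed + 3)
    rows = []
    used = set()
    for q in cfg.planted_qtl:
        desc = f"c.{rng.integers(100, 3000)}A>G" if q.mechanism == "coding" else "."
        rows.append((q.vid, q.gene, q.impact, desc))
        used.add(q.vid)
    planted_pos = {
        (q.chrom, genotypes.variants[genotypes.index_of(q.vid)].pos)
        for q in cfg.planted_qtl
    }
    maf = genotypes.recompute_maf()
    candidates = [
        i for i, v in enumerate(genotypes.variants)
        if v.vid not in used and maf[i] > 0.05
        and all(v.chrom != c or abs(v.pos - p) > 2_000_000 for c, p in planted_pos)
    ]
    pick = rng.choice(candidates, size=min(cfg.n_decoy_piv, len(candidates)),
                      replace=False)
    for n, i in enumerate(pick):
        v = genotypes.variants[int(i)]
        impact = ["MODERATE", "LOW_SPLICE_REGION", "HIGH"][n % 3]
        rows.append((v.vid, f"DECOY{n:02d}", impact, f"c.{100 + n}C>T"))
    return AnnotationTable(
        pd.DataFrame(rows, columns=["vid", "gene", "impact", "description"])
    )


def simulate_dataset(cfg: SimulationConfig):
    """Run the whole generator; returns all artifacts plus ground truth."""
    genotypes, pedigree, meta = simulate_genotypes(cfg)
    records, truth = simulate_phenotypes(cfg, genotypes, pedigree, meta)
    expression = simulate_expression(cfg, genotypes, pedigree, meta, truth)
    annotations = make_annotations(cfg, genotypes)
    return genotypes, pedigree, records, expression, annotations, truth


def emit_dataset(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the complete dataset (VCF, TSVs, truth JSON) to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genotypes, pedigree, records, expression, annotations, truth = simulate_dataset(cfg)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "pedigree": outdir / "pedigree.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "annotations": outdir / "annotations.tsv",
        "expression": outdir / "expression.tsv",
        "gene_positions": outdir / "gene_positions.tsv",
        "truth": outdir / "truth.json",
    }
    write_vcf(genotypes, paths["vcf"])
    write_pedigree(pedigree, paths["pedigree"])
    write_phenotypes(records, paths["phenotypes"])
    write_annotations(annotations, paths["annotations"])
    write_expression(expression, paths["expression"], paths["gene_positions"])
    truth.to_json(paths["truth"])
    return paths
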