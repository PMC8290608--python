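"""Record- and variant-level quality filters applied before analysis."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dataio import GenotypeMatrix, TestDayRecord, maf_from_dosages

logger = logging.getLogger("mirqtl")


@dataclass
class QcReport:
    examined: int
    removed: int
    per_rule: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.removed > self.examined:
            raise ValueError("removed > examined")


def mahalanobis_spectral_filter(
    records: list[TestDayRecord],
    k_components: int = 10,
    quantile: float = 0.999,
) -> tuple[list[TestDayRecord], QcReport]:
    """Remove spectral outliers by within-instrument Mahalanobis distance.

    Per instrument, spectra are projected onto the top ``k_components``
    principal directions of the within-instrument covariance; records whose
    squared Mahalanobis distance in that subspace exceeds the chi-square(k)
    ``quantile`` are removed. Singular or deficient covariances fall back to
    fewer components (logged).
    """
    by_inst: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        by_inst.setdefault(r.instrument, []).append(i)
    drop: set[int] = set()
    for inst, idx in by_inst.items():
        spectra = np.array([records[i].spectrum for i in idx])
        n = len(idx)
        k = min(k_components, n - 1, spectra.shape[1])
        if k < 1:
            logger.warning("instrument %s: too few records for the filter", inst)
            continue
        centred = spectra - spectra.mean(axis=0)
        # principal directions of the within-instrument covariance via SVD
        _, s, vt = np.linalg.svd(centred, full_matrices=False)
        eigvals = s**2 / (n - 1)
        pos = eigvals[:k] > 1e-12 * max(eigvals[0], 1e-300)
        if not np.all(pos):
            k_eff = int(pos.sum())
            logger.warning(
                "instrument %s: covariance rank %d < %d components, reducing",
                inst, k_eff, k,
            )
            k = max(1, k_eff)
        if k < 1 or eigvals[0] <= 0:
            continue  # all spectra identical: zero distances, nothing removed
        scores = centred @ vt[:k].T
        d2 = np.sum(scores**2 / eigvals[:k], axis=1)
        if quantile >= 1.0:
            continue
        cut = stats.chi2.ppf(quantile, df=k)
        for local, i in enumerate(idx):
            if d2[local] > cut:
                drop.add(i)
    kept = [r for i, r in enumerate(records) if i not in drop]
    report = QcReport(
        examined=len(records),
        removed=len(drop),
        per_rule={"mahalanobis": len(drop)},
    )
    return kept, report


def maf_consistency_filter(
    panel_maf: np.ndarray,
    overall_maf: np.ndarray,
    minor_allele_count: np.ndarray,
) -> np.ndarray:
    """Keep/drop mask for the reference-vs-overall MAF consistency rule.

    Applied only to variants with more than 1000 minor alleles in the
    overall population: drop when |MAF_ref - MAF_overall| / MAF_ref >= 0.4.
    A zero reference MAF with an applicable count is an undefined ratio and
    is treated as failure (logged).
    """
    panel_maf = np.asarray(panel_maf, dtype=float)
    overall_maf = np.asarray(overall_maf, dtype=float)
    count = np.asarray(minor_allele_count)
    if np.any(panel_maf < 0) or np.any(panel_maf > 0.5) or np.any(overall_maf < 0) \
            or np.any(overall_maf > 0.5):
        raise ValueError("MAF values must lie in [0, 0.5]")
    if np.any(count < 0):
        raise ValueError("minor allele counts must be >= 0")
    keep = np.ones(len(panel_maf), dtype=bool)
    applicable = count > 1000
    zero_ref = applicable & (panel_maf == 0)
    if np.any(zero_ref):
        logger.warning(
            "%d variants with zero reference MAF and >1000 minor alleles dropped",
            int(zero_ref.sum()),
        )
    keep[zero_ref] = False
    ok = applicable & ~zero_ref
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.abs(panel_maf - overall_maf) / panel_maf
    keep[ok & (ratio >= 0.4)] = False
    return keep


DEFAULT_THRESHOLD_RULES = {
    "allelic_r2_min": 0.95,  # sequence-reference stage; 0.7 post-chip-imputation
    "drop_monomorphic": True,
    "call_rate_min": 0.9,
    "concordance_max_drop": 0.7,  # drop when concordance <= this
}


def threshold_filters(
    genotypes: GenotypeMatrix,
    rules: dict | None = None,
    call_rate: np.ndarray | None = None,
    concordance: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Variant threshold filters: allelic R², monomorphy, call rate, concordance.

    The allelic-R² rule removes variants whose quality is strictly below the
    stage threshold (a variant exactly at the threshold is kept); the
    concordance rule removes variants with concordance <= 0.7.
    """
    rules = {**DEFAULT_THRESHOLD_RULES, **(rules or {})}
    m = genotypes.n_variants
    keep = np.ones(m, dtype=bool)
    per_rule: dict[str, int] = {}

    r2 = np.array([v.allelic_r2 for v in genotypes.variants])
    bad = r2 < rules["allelic_r2_min"]
    per_rule["allelic_r2"] = int(bad.sum())
    keep &= ~bad

    if rules["drop_monomorphic"]:
        maf = maf_from_dosages(genotypes.dosages)
        mono = maf <= 0.0
        per_rule["monomorphic"] = int(mono.sum())
        keep &= ~mono

    if call_rate is not None:
        bad = np.asarray(call_rate) < rules["call_rate_min"]
        per_rule["call_rate"] = int(bad.sum())
        keep &= ~bad

    if concordance is not None:
        conc = np.asarray(concordance, dtype=float)
        bad = np.isfinite(conc) & (conc <= rules["concordance_max_drop"])
        per_rule["concordance"] = int(bad.sum())
        keep &= ~bad

    kept_vids = [v.vid for v, k in zip(genotypes.variants, keep) if k]
    out = genotypes.subset_variants(kept_vids)
    report = QcReport(examined=m, removed=int((~keep).sum()), per_rule=per_rule)
    return out, report
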