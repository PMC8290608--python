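"""Pedigree-covariance eQTL scan and trait-QTL / eQTL co-localization.

Gene expression is tested against dosage by generalized least squares with
animal covariance sigma2_a * A + sigma2_e * I, where A is the numerator
relationship matrix from the pedigree. Co-localization compares the
-log10 p profiles of the trait QTL and an eQTL over 1-Mbp and 0.5-Mbp
windows centred on the trait tag: a call requires the better of the two
Pearson correlations to exceed 0.7 and the tag to sit in LD r2 > 0.9 with
the top eQTL variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .candidates import ld_r2
from .conditional import QtlTag
from .dataio import ExpressionMatrix, GenotypeMatrix, PedigreeTable
from .gwas import TINY_P, bonferroni_threshold, estimate_vc, neglog10_from_chi2

logger = logging.getLogger("mirqtl")


@dataclass
class AMatrix:
    """Numerator relationship matrix in pedigree topological order."""

    animals: list[str]
    values: np.ndarray
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {a: i for i, a in enumerate(self.animals)}

    def submatrix(self, animals: list[str]) -> np.ndarray:
        idx = [self._index[a] for a in animals]
        return self.values[np.ix_(idx, idx)]


def build_a_matrix(pedigree: PedigreeTable) -> AMatrix:
    """Tabular-method recursion over the pedigree.

    a_jj = 1 + a(sire_j, dam_j)/2 and a_ij = (a(i, sire_j) + a(i, dam_j))/2,
    with unknown parents contributing zero.
    """
    order = pedigree.order
    idx = {a: i for i, a in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for j, animal in enumerate(order):
        s, d = pedigree.parents[animal]
        si = idx.get(s) if s is not None else None
        di = idx.get(d) if d is not None else None
        contrib = np.zeros(j)
        if si is not None:
            contrib += A[:j, si]
        if di is not None:
            contrib += A[:j, di]
        A[:j, j] = A[j, :j] = 0.5 * contrib
        A[j, j] = 1.0 + (0.5 * A[si, di] if si is not None and di is not None
                         else 0.0)
    return AMatrix(list(order), A)


@dataclass
class EqtlResult:
    gene: str
    vid: str
    chi2: float
    p: float
    neglog10p: float


class EqtlScanner:
    """GLS eQTL scans for one expression cohort against one genotype set."""

    def __init__(self, expression: ExpressionMatrix, genotypes: GenotypeMatrix,
                 a_matrix: AMatrix, jitter: float = 1e-8):
        self.expression = expression
        self.genotypes = genotypes.subset_animals(expression.animals)
        A = a_matrix.submatrix(expression.animals)
        vals, vecs = np.linalg.eigh(A)
        if vals.min() < -1e-6:
            raise ValueError("A matrix not positive semi-definite")
        self._eig = (np.maximum(vals, 0.0) + jitter, vecs)
        self._rot_dos = vecs.T @ self.genotypes.dosages
        self._rot_one = vecs.T @ np.ones(len(expression.animals))

    def scan_gene(self, gene: str, vids: list[str] | None = None,
                  window_bp: int = 1_000_000) -> pd.DataFrame:
        """Test each variant (default: all in the gene's 1-Mbp window).

        Returns one row per variant with the 1-df chi-square and p-value.
        """
        g = self.genotypes
        if vids is None:
            gp = self.expression.gene_positions
            row = gp[gp["gene"] == gene].iloc[0]
            centre = (int(row["start"]) + int(row["end"])) // 2
            half = window_bp // 2
            vids = [
                v.vid for v in g.variants
                if v.chrom == str(row["chrom"]) and abs(v.pos - centre) <= half
            ]
        y = self.expression.gene_column(gene)
        vals, vecs = self._eig
        s2a, s2e, _ = estimate_vc(y, np.zeros(0), eig=self._eig)
        w = s2a * vals + s2e
        omega = 1.0 / w
        ystar = vecs.T @ y
        x0 = self._rot_one
        cols = [g.index_of(v) for v in vids]
        D = self._rot_dos[:, cols]
        a11 = float(np.sum(omega * x0 * x0))
        a12 = (omega * x0) @ D
        a22 = np.einsum("i,ij,ij->j", omega, D, D)
        b1 = float(np.sum(omega * x0 * ystar))
        b2 = (omega * ystar) @ D
        det = a11 * a22 - a12**2
        maf = g.recompute_maf()
        maf_ok = np.array([maf[c] > 0 for c in cols])
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = (a11 * b2 - a12 * b1) / det
            var_slope = a11 / det
            chi2 = slope**2 / var_slope
        chi2 = np.where(maf_ok & (det > 0), chi2, np.nan)
        neglog10p = np.where(np.isnan(chi2), np.nan,
                             neglog10_from_chi2(np.nan_to_num(chi2)))
        p = np.maximum(np.power(10.0, -np.minimum(neglog10p, 323.0)), TINY_P)
        return pd.DataFrame({
            "gene": gene,
            "vid": vids,
            "chrom": [g.variants[c].chrom for c in cols],
            "pos": [g.variants[c].pos for c in cols],
            "chi2": chi2,
            "p": np.where(np.isnan(chi2), np.nan, p),
            "neglog10p": neglog10p,
        })

    def significance_threshold(self, n_tests: int, alpha: float = 0.05
                               ) -> tuple[float, float]:
        return bonferroni_threshold(alpha, 1, n_tests)


@dataclass
class ColocCall:
    trait: str
    tag: QtlTag
    gene: str
    top_eqtl_vid: str
    top_eqtl_p: float
    r2: float  # tag vs top eQTL variant
    pearson_r: float  # max over the two windows
    window_mb: float  # winning window, 0.5 or 1.0


def coloc_test(trait_results: pd.DataFrame, eqtl_results: pd.DataFrame,
               tag: QtlTag, genotypes: GenotypeMatrix,
               min_shared: int = 30) -> ColocCall | None:
    """Dual-window correlation test for one (trait tag, gene) pair.

    ``trait_results`` and ``eqtl_results`` must carry vid, pos and
    neglog10p columns; both windows are centred on the tag position.
    """
    gene = str(eqtl_results["gene"].iloc[0])
    trait_ok = trait_results[np.isfinite(trait_results["neglog10p"])]
    eqtl_ok = eqtl_results[np.isfinite(eqtl_results["neglog10p"])]

    full = eqtl_ok[np.abs(eqtl_ok["pos"] - tag.pos) <= 500_000]
    if full.empty:
        return None
    top = full.loc[full["neglog10p"].idxmax()]

    best_r, best_win = -np.inf, None
    for window_mb in (1.0, 0.5):
        half = int(window_mb * 1_000_000) // 2
        tw = trait_ok[(trait_ok["chrom"].astype(str) == tag.chrom)
                      & (np.abs(trait_ok["pos"] - tag.pos) <= half)]
        ew = eqtl_ok[np.abs(eqtl_ok["pos"] - tag.pos) <= half]
        merged = tw.merge(ew, on="vid", suffixes=("_trait", "_eqtl"))
        if len(merged) < min_shared:
            logger.info(
                "coloc %s/%s: only %d shared variants in the %.1f-Mbp window, "
                "skipped", tag.vid, gene, len(merged), window_mb,
            )
            continue
        r = float(np.corrcoef(merged["neglog10p_trait"],
                              merged["neglog10p_eqtl"])[0, 1])
        if r > best_r:
            best_r, best_win = r, window_mb
    if best_win is None or best_r <= 0.7:
        return None
    r2 = ld_r2(genotypes.vid_column(tag.vid), genotypes.vid_column(top["vid"]))
    if r2 <= 0.9:
        return None
    return ColocCall(
        trait=tag.trait, tag=tag, gene=gene,
        top_eqtl_vid=str(top["vid"]), top_eqtl_p=float(top["p"]),
        r2=r2, pearson_r=best_r, window_mb=best_win,
    )


def coloc_table(calls: list[ColocCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.tag.chrom, "pos": c.tag.pos, "tag_vid": c.tag.vid,
                "iteration": c.tag.iteration, "p": c.tag.p, "gene": c.gene,
                "top_eqtl_vid": c.top_eqtl_vid, "top_eqtl_p": c.top_eqtl_p,
                "ld_r2": c.r2, "pearson": c.pearson_r,
                "pearson_window_mb": c.window_mb, "trait": c.trait,
            }
            for c in calls
        ]
    )
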