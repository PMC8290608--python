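"""Mixed-model single-variant association with a marker-subset GRM.

The test is the standard two-stage mixed-model (EMMAX-style) Wald test:
variance components are estimated once per trait by REML under the
infinitesimal model y = 1*mu + g + e with g ~ N(0, G*sigma2_g) on the
full-panel GRM, then each variant is tested by generalized least squares
under V = sigma2_g * G_loso + sigma2_e * I, where G_loso excludes the
panel markers of the tested variant's 5-Mbp segment (leave-one-segment-out,
to avoid proximal contamination). Extreme p-values are carried as
-log10(p) computed from the chi-square survival function in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .dataio import GenotypeMatrix, maf_from_dosages

LN10 = math.log(10.0)
#: smallest positive float, used so stored p stays in (0, 1]
TINY_P = 5e-324

SegmentId = tuple[str, int]


def segment_of(chrom: str, pos: int, segment_bp: int = 5_000_000) -> SegmentId:
    return (chrom, int(pos) // segment_bp)


@dataclass
class GwasConfig:
    maf_min: float = 0.001
    alpha: float = 0.01
    n_traits: int = 898  # Bonferroni trait count; override per analysis
    segment_bp: int = 5_000_000
    collinear_r2: float = 0.99

    def __post_init__(self) -> None:
        if not 0 <= self.maf_min < 0.5:
            raise ValueError("maf_min outside [0, 0.5)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha outside (0, 1)")


@dataclass
class GrmPanel:
    """GRM from a marker subset, with the pieces needed for LOSO downdating."""

    animals: list[str]
    panel_vids: list[str]
    G: np.ndarray
    W: np.ndarray  # standardized dosage columns, (n, m)
    segments: list[SegmentId]  # per panel variant
    segment_bp: int
    _eig: tuple | None = field(default=None, repr=False)

    @property
    def m(self) -> int:
        return len(self.panel_vids)

    def segment_columns(self, seg: SegmentId) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.segments) if s == seg],
                        dtype=int)

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        if self._eig is None:
            vals, vecs = np.linalg.eigh(self.G)
            self._eig = (np.maximum(vals, 0.0), vecs)
        return self._eig


def build_grm(genotypes: GenotypeMatrix, panel_ids: list[str],
              maf_min: float = 0.001, segment_bp: int = 5_000_000) -> GrmPanel:
    """G = WW'/m with W the centred, 1/sqrt(2pq)-scaled panel dosages.

    Allele frequencies are taken from the supplied genotype matrix, i.e.
    from the analysed study population; panel variants below ``maf_min``
    are excluded from the GRM.
    """
    sub = genotypes.subset_variants(panel_ids)
    maf = maf_from_dosages(sub.dosages)
    keep = maf >= max(maf_min, 1e-12)
    if not np.any(keep):
        raise ValueError("panel is empty after the MAF filter")
    dos = sub.dosages[:, keep]
    p_alt = dos.mean(axis=0) / 2.0
    W = (dos - 2 * p_alt) / np.sqrt(2 * p_alt * (1 - p_alt))
    G = (W @ W.T) / W.shape[1]
    variants = [v for v, k in zip(sub.variants, keep) if k]
    return GrmPanel(
        animals=list(genotypes.animals),
        panel_vids=[v.vid for v in variants],
        G=G,
        W=W,
        segments=[segment_of(v.chrom, v.pos, segment_bp) for v in variants],
        segment_bp=segment_bp,
    )


def loso_grm(panel: GrmPanel, segment_id: SegmentId) -> np.ndarray:
    """GRM excluding one segment's panel markers, by rank-k downdate.

    Identical (to numerical precision) to rebuilding the GRM from the
    complement panel: G_loso = (m*G - W_s W_s') / (m - m_s).
    """
    cols = panel.segment_columns(segment_id)
    if len(cols) == 0:
        return panel.G
    if len(cols) == panel.m:
        raise ValueError("segment contains the entire panel")
    Ws = panel.W[:, cols]
    return (panel.m * panel.G - Ws @ Ws.T) / (panel.m - len(cols))


def estimate_vc(y: np.ndarray, G: np.ndarray,
                eig: tuple[np.ndarray, np.ndarray] | None = None,
                tol: float = 1e-8) -> tuple[float, float, float]:
    """REML variance components for y = 1*mu + g + e, g ~ N(0, G*sigma2_g).

    The restricted likelihood is profiled to the ratio
    delta = sigma2_e / sigma2_g on the eigenbasis of G and maximised by
    bounded scalar search. Returns (sigma2_g, sigma2_e, sigma2_t).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if eig is None:
        vals, vecs = np.linalg.eigh(G)
        vals = np.maximum(vals, 0.0)
    else:
        vals, vecs = eig
    ystar = vecs.T @ y
    xstar = vecs.T @ np.ones(n)

    def restricted_ll(log_delta: float) -> float:
        w = vals + math.exp(log_delta)
        xx = float(np.sum(xstar**2 / w))
        xy = float(np.sum(xstar * ystar / w))
        yy = float(np.sum(ystar**2 / w))
        quad = max(yy - xy * xy / xx, 1e-300)
        s2 = quad / (n - 1)
        return -0.5 * (
            (n - 1) * math.log(s2) + float(np.sum(np.log(w))) + math.log(xx)
            + (n - 1)
        )

    res = optimize.minimize_scalar(
        lambda t: -restricted_ll(t), bounds=(math.log(1e-4), math.log(1e4)),
        method="bounded", options={"xatol": tol},
    )
    delta = math.exp(res.x)
    w = vals + delta
    xx = float(np.sum(xstar**2 / w))
    xy = float(np.sum(xstar * ystar / w))
    yy = float(np.sum(ystar**2 / w))
    sigma2_g = max(yy - xy * xy / xx, 1e-300) / (n - 1)
    sigma2_e = delta * sigma2_g
    return float(sigma2_g), float(sigma2_e), float(sigma2_g + sigma2_e)


def bonferroni_threshold(alpha: float, n_traits: int, n_variants: int
                         ) -> tuple[float, float]:
    """(p threshold, -log10 threshold) treating every test as independent."""
    if alpha <= 0 or n_traits <= 0 or n_variants <= 0:
        raise ValueError("all inputs must be positive")
    p = alpha / (n_traits * n_variants)
    return p, -math.log10(p)


def neglog10_from_chi2(chi2: np.ndarray) -> np.ndarray:
    """-log10 p for 1-df chi-square statistics, computed in log space.

    Uses sf_chi2(x; 1) = 2 * sf_normal(sqrt(x)), whose log form stays
    accurate far beyond floating-point underflow of p itself.
    """
    chi2 = np.asarray(chi2, dtype=float)
    return -(math.log(2.0) + stats.norm.logsf(np.sqrt(np.maximum(chi2, 0.0)))
             ) / LN10


@dataclass
class AssociationResult:
    vid: str
    trait: str
    a: float  # allele substitution effect, trait units per alt allele
    se: float
    chi2: float
    p: float
    neglog10p: float
    pve: float  # 2pq a^2 / sigma2_t
    pge: float  # 2pq a^2 / sigma2_g
    flag: str = ""


def test_variant(y_adj: np.ndarray, dosage: np.ndarray, V: np.ndarray,
                 extra_covariates: np.ndarray | None = None,
                 sigma2_t: float | None = None, sigma2_g: float | None = None,
                 trait: str = "", vid: str = "",
                 collinear_r2: float = 0.99) -> AssociationResult:
    """GLS effect and 1-df Wald chi-square of one dosage covariate.

    V is the phenotypic covariance (sigma2_g * G_loso + sigma2_e * I) for
    the variant's segment; the model includes an intercept and any
    conditioning covariates.
    """
    y = np.asarray(y_adj, dtype=float)
    d = np.asarray(dosage, dtype=float)
    n = len(y)
    C = np.ones((n, 1))
    if extra_covariates is not None and extra_covariates.size:
        C = np.column_stack([C, extra_covariates])
    # collinearity guard on the covariate projection
    q, _ = np.linalg.qr(C)
    resid_d = d - q @ (q.T @ d)
    tss = float(np.sum((d - d.mean()) ** 2))
    if tss <= 0 or 1 - float(resid_d @ resid_d) / tss > collinear_r2:
        return AssociationResult(vid, trait, math.nan, math.nan, math.nan,
                                 math.nan, math.nan, math.nan, math.nan,
                                 flag="skipped-collinear")
    cf = linalg.cho_factor(V)
    ViC = linalg.cho_solve(cf, C)
    Vid = linalg.cho_solve(cf, d)
    Viy = linalg.cho_solve(cf, y)
    CtViC = C.T @ ViC
    sol_d = np.linalg.solve(CtViC, C.T @ Vid)
    Pd = Vid - ViC @ sol_d
    dPd = float(d @ Pd)
    dPy = float(Pd @ y)
    a = dPy / dPd
    se = math.sqrt(1.0 / dPd)
    chi2 = dPy * dPy / dPd
    neglog10p = float(neglog10_from_chi2(np.array([chi2]))[0])
    p = max(float(10.0 ** -min(neglog10p, 323.0)), TINY_P)
    p_alt = d.mean() / 2
    maf = min(p_alt, 1 - p_alt)
    pq2 = 2 * maf * (1 - maf)
    pve = pq2 * a * a / sigma2_t if sigma2_t else math.nan
    pge = pq2 * a * a / sigma2_g if sigma2_g else math.nan
    return AssociationResult(vid, trait, a, se, chi2, p, neglog10p, pve, pge)


class GwasScanner:
    """Per-trait LOSO mixed-model scan over all (or selected) chromosomes.

    The genotype matrix must already be restricted to the analysed animals,
    in the order of the adjusted-phenotype vectors handed to
    :meth:`scan_trait`; MAF is recomputed in that population.
    """

    def __init__(self, genotypes: GenotypeMatrix, panel: GrmPanel,
                 config: GwasConfig | None = None):
        if list(genotypes.animals) != list(panel.animals):
            raise ValueError("genotypes and GRM panel animals differ")
        self.genotypes = genotypes
        self.panel = panel
        self.config = config or GwasConfig()
        self.maf = genotypes.recompute_maf()
        pos = genotypes.positions
        chroms = genotypes.chroms
        self.variant_segment = [
            segment_of(c, p, self.config.segment_bp) for c, p in zip(chroms, pos)
        ]
        self._by_segment: dict[SegmentId, np.ndarray] = {}
        for i, s in enumerate(self.variant_segment):
            self._by_segment.setdefault(s, []).append(i)  # type: ignore[arg-type]
        self._by_segment = {k: np.asarray(v, dtype=int)
                            for k, v in self._by_segment.items()}

    def variance_components(self, y: np.ndarray) -> tuple[float, float, float]:
        return estimate_vc(np.asarray(y, float), self.panel.G,
                           eig=self.panel.eig())

    def scan_trait(self, y: np.ndarray, trait: str,
                   covariates: np.ndarray | None = None,
                   covariate_vids: tuple[str, ...] = (),
                   chroms: set[str] | None = None,
                   vc: tuple[float, float, float] | None = None) -> pd.DataFrame:
        """Association results for every MAF-passing variant of the trait."""
        y = np.asarray(y, dtype=float)
        n = len(y)
        if vc is None:
            vc = self.variance_components(y)
        s2g, s2e, s2t = vc
        C = np.ones((n, 1))
        if covariates is not None and covariates.size:
            C = np.column_stack([C, covariates])
        qC, _ = np.linalg.qr(C)

        frames = []
        for seg, idx in sorted(self._by_segment.items()):
            if chroms is not None and seg[0] not in chroms:
                continue
            keep = idx[(self.maf[idx] >= self.config.maf_min)
                       & (self.maf[idx] > 0)]
            keep = keep[[self.genotypes.variants[i].vid not in covariate_vids
                         for i in keep]]
            if len(keep) == 0:
                continue
            V = s2g * loso_grm(self.panel, seg) + s2e * np.eye(n)
            cf = linalg.cho_factor(V)
            ViC = linalg.cho_solve(cf, C)
            CtViC = C.T @ ViC
            D = self.genotypes.dosages[:, keep]
            ViD = linalg.cho_solve(cf, D)
            PD = ViD - ViC @ np.linalg.solve(CtViC, C.T @ ViD)
            dPd = np.einsum("ij,ij->j", D, PD)
            dPy = PD.T @ y
            # OLS collinearity of dosages with the covariate set
            proj = qC @ (qC.T @ D)
            rss = np.einsum("ij,ij->j", D - proj, D - proj)
            tss = np.einsum("ij,ij->j", D - D.mean(axis=0), D - D.mean(axis=0))
            with np.errstate(divide="ignore", invalid="ignore"):
                r2cov = 1 - rss / tss
            bad = (tss <= 0) | (r2cov > self.config.collinear_r2) | (dPd <= 0)
            a = np.where(bad, np.nan, dPy / np.where(dPd > 0, dPd, np.nan))
            se = np.sqrt(1.0 / np.where(dPd > 0, dPd, np.nan))
            chi2 = np.where(bad, np.nan, dPy**2 / np.where(dPd > 0, dPd, np.nan))
            with np.errstate(invalid="ignore"):
                neglog10p = np.where(
                    np.isnan(chi2), np.nan,
                    neglog10_from_chi2(np.nan_to_num(chi2)),
                )
            pvals = np.maximum(np.power(10.0, -np.minimum(neglog10p, 323.0)),
                               TINY_P)
            pq2 = 2 * self.maf[keep] * (1 - self.maf[keep])
            frames.append(pd.DataFrame({
                "vid": [self.genotypes.variants[i].vid for i in keep],
                "chrom": [self.genotypes.variants[i].chrom for i in keep],
                "pos": [self.genotypes.variants[i].pos for i in keep],
                "trait": trait,
                "maf": self.maf[keep],
                "a": a,
                "se": se,
                "chi2": chi2,
                "p": np.where(np.isnan(chi2), np.nan, pvals),
                "neglog10p": neglog10p,
                "pve": pq2 * a**2 / s2t,
                "pge": pq2 * a**2 / s2g,
                "flag": np.where(bad, "skipped-collinear", ""),
            }))
        if not frames:
            return pd.DataFrame(
                columns=["vid", "chrom", "pos", "trait", "maf", "a", "se",
                         "chi2", "p", "neglog10p", "pve", "pge", "flag"]
            )
        return pd.concat(frames, ignore_index=True)


def scan_variants_multi_trait(scanner: "GwasScanner", vids: list[str],
                              Y: dict[str, np.ndarray]) -> pd.DataFrame:
    """LOSO association of a fixed variant set against many traits.

    Used to build per-locus significance profiles across all wavenumber
    traits: only the requested variants are tested, so each involved
    segment's LOSO covariance is eigendecomposed once and shared by every
    trait. Returns a long table (trait, vid, chi2, neglog10p).
    """
    g = scanner.genotypes
    panel = scanner.panel
    by_seg: dict[SegmentId, list[str]] = {}
    for vid in vids:
        v = g.variants[g.index_of(vid)]
        by_seg.setdefault(segment_of(v.chrom, v.pos, scanner.config.segment_bp),
                          []).append(vid)
    vc = {t: scanner.variance_components(y) for t, y in Y.items()}
    ones = np.ones(g.n_animals)
    rows = []
    for seg, seg_vids in sorted(by_seg.items()):
        Gl = loso_grm(panel, seg)
        vals, vecs = np.linalg.eigh(Gl)
        vals = np.maximum(vals, 0.0)
        D = vecs.T @ np.column_stack([g.vid_column(v) for v in seg_vids])
        x0 = vecs.T @ ones
        for trait, y in Y.items():
            s2g, s2e, _ = vc[trait]
            omega = 1.0 / (s2g * vals + s2e)
            ystar = vecs.T @ np.asarray(y, float)
            a11 = float(np.sum(omega * x0 * x0))
            a12 = (omega * x0) @ D
            a22 = np.einsum("i,ij,ij->j", omega, D, D)
            b1 = float(np.sum(omega * x0 * ystar))
            b2 = (omega * ystar) @ D
            det = a11 * a22 - a12**2
            with np.errstate(divide="ignore", invalid="ignore"):
                slope = (a11 * b2 - a12 * b1) / det
                chi2 = slope**2 * det / a11
            nl10 = np.where(det > 0, neglog10_from_chi2(np.nan_to_num(chi2)),
                            np.nan)
            for k, vid in enumerate(seg_vids):
                rows.append({"trait": trait, "vid": vid,
                             "chi2": float(chi2[k]),
                             "neglog10p": float(nl10[k])})
    return pd.DataFrame(rows)


def count_1mb_regions(results: pd.DataFrame, neglog10_threshold: float) -> int:
    """Distinct 1-Mbp (chrom, floor(pos/1e6)) bins holding >= 1 significant hit."""
    sig = results[results["neglog10p"] > neglog10_threshold]
    bins = {(c, p // 1_000_000) for c, p in zip(sig["chrom"], sig["pos"])}
    return len(bins)
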