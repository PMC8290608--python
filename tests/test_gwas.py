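import math

import numpy as np
import pytest
from scipy import linalg, stats

from mirqtl import gwas as gw
from mirqtl.gwas import (
    GrmPanel,
    GwasConfig,
    bonferroni_threshold,
    build_grm,
    count_1mb_regions,
    estimate_vc,
    loso_grm,
    segment_of,
    test_variant as gls_variant_test,
)


# ---------------------------------------------------------------- thresholds

def test_bonferroni_threshold_published_scale():
    """At alpha 0.01 over 898 traits x 17,873,880 variants the nominal
    p-value is 6.2e-13 and its -log10 is 12.21 (printed precision)."""
    p, nl = bonferroni_threshold(0.01, 898, 17_873_880)
    assert abs(p * 1e13 - 6.2) < 0.05
    assert abs(nl - 12.21) < 0.005


def test_bonferroni_threshold_eqtl_scale():
    p, _ = bonferroni_threshold(0.05, 1, 197_338)
    assert abs(p * 1e7 - 2.53) < 0.005


def test_bonferroni_trivial():
    p, nl = bonferroni_threshold(0.05, 1, 1)
    assert p == pytest.approx(0.05)
    assert nl == pytest.approx(-math.log10(0.05))
    with pytest.raises(ValueError):
        bonferroni_threshold(0.0, 1, 1)


# ----------------------------------------------------------------------- GRM

def test_grm_identical_animals_share_row(small_dataset):
    _, (genotypes, *_rest) = small_dataset
    sub = genotypes.subset_animals(genotypes.animals[:50])
    # duplicate an animal by stacking its dosage row
    dup = type(sub)(
        animals=sub.animals + ["clone"],
        variants=sub.variants,
        dosages=np.vstack([sub.dosages, sub.dosages[0]]),
    )
    panel = build_grm(dup, dup.vids[::3])
    assert panel.G[0, -1] == pytest.approx(panel.G[0, 0], abs=1e-10)
    assert panel.G[-1, -1] == pytest.approx(panel.G[0, 0], abs=1e-10)


def test_grm_matches_definition_and_diag(default_scanner):
    panel = default_scanner.panel
    G2 = panel.W @ panel.W.T / panel.m
    assert np.max(np.abs(G2 - panel.G)) < 1e-10
    assert 0.8 < np.mean(np.diag(panel.G)) < 1.2


def test_grm_founder_offdiagonals_near_zero():
    from mirqtl.synthetic import SimulationConfig, simulate_genotypes

    cfg = SimulationConfig(seed=13, n_animals=10, n_sires=100, n_dams=100,
                           n_chromosomes=2, variants_per_chrom=2500,
                           breed_fst=0.0)
    g, _, _ = simulate_genotypes(cfg)
    founders = g.subset_animals(g.animals[:200])
    panel = build_grm(founders, founders.vids)
    off = panel.G[np.triu_indices(200, k=1)]
    assert abs(off.mean()) < 0.02


def test_loso_empty_segment_returns_grm(default_scanner):
    panel = default_scanner.panel
    same = loso_grm(panel, ("99", 0))
    assert same is panel.G


def test_loso_downdate_equals_rebuild(small_dataset):
    _, (genotypes, *_rest) = small_dataset
    study = genotypes.subset_animals(genotypes.animals[:200])
    panel = build_grm(study, study.vids[::2])
    seg = panel.segments[0]
    fast = loso_grm(panel, seg)
    keep = [v for v, s in zip(panel.panel_vids, panel.segments) if s != seg]
    slow = build_grm(study, keep).G
    assert np.max(np.abs(fast - slow)) < 1e-10


def test_loso_contributions_reconstruct_grm(small_dataset):
    _, (genotypes, *_rest) = small_dataset
    study = genotypes.subset_animals(genotypes.animals[:100])
    panel = build_grm(study, study.vids[::5])
    total = np.zeros_like(panel.G)
    for seg in sorted(set(panel.segments)):
        cols = panel.segment_columns(seg)
        total += panel.W[:, cols] @ panel.W[:, cols].T
    assert np.max(np.abs(total / panel.m - panel.G)) < 1e-10


def test_loso_whole_panel_segment_error():
    rng = np.random.default_rng(0)
    W = rng.normal(size=(20, 5))
    panel = GrmPanel(
        animals=[str(i) for i in range(20)], panel_vids=list("abcde"),
        G=W @ W.T / 5, W=W, segments=[("1", 0)] * 5, segment_bp=5_000_000,
    )
    with pytest.raises(ValueError, match="entire panel"):
        loso_grm(panel, ("1", 0))


# --------------------------------------------------------- variance components

def test_estimate_vc_recovers_planted_h2(default_scanner):
    """A trait drawn from the GRM itself with h2 = 0.4 is recovered to
    within +-0.08 at n = 2,000."""
    panel = default_scanner.panel
    n = len(panel.animals)
    rng = np.random.default_rng(21)
    vals, vecs = panel.eig()
    g = vecs @ (np.sqrt(vals) * rng.normal(size=n))
    y = math.sqrt(0.4) * g + rng.normal(0, math.sqrt(0.6), n)
    s2g, s2e, s2t = estimate_vc(y, panel.G, eig=panel.eig())
    assert abs(s2g / s2t - 0.4) < 0.08


def test_estimate_vc_pure_noise(default_scanner):
    rng = np.random.default_rng(3)
    y = rng.normal(size=len(default_scanner.panel.animals))
    s2g, _, s2t = estimate_vc(y, default_scanner.panel.G,
                              eig=default_scanner.panel.eig())
    assert s2g / s2t < 0.05


def test_estimate_vc_scale_equivariance(default_scanner):
    rng = np.random.default_rng(4)
    n = len(default_scanner.panel.animals)
    y = rng.normal(size=n)
    eig = default_scanner.panel.eig()
    a = estimate_vc(y, default_scanner.panel.G, eig=eig)
    b = estimate_vc(10 * y, default_scanner.panel.G, eig=eig)
    assert b[0] == pytest.approx(100 * a[0], rel=1e-3, abs=1e-6)
    assert b[1] == pytest.approx(100 * a[1], rel=1e-3)
    assert b[0] / b[2] == pytest.approx(a[0] / a[2], abs=1e-6)


# -------------------------------------------------------------- variant test

def _brute_force_gls(y, d, V, C):
    """Oracle: explicit full-covariance GLS by direct inversion."""
    X = np.column_stack([C, d])
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    cov = np.linalg.inv(XtViX)
    a = beta[-1]
    se = math.sqrt(cov[-1, -1])
    return a, se, (a / se) ** 2


def test_variant_orthogonal_dosage_zero_effect():
    y = np.array([1.0, -1.0, 1.0, -1.0])
    d = np.array([1.0, 1.0, 0.0, 0.0])  # orthogonal to y after centring
    res = gls_variant_test(y, d, np.eye(4))
    assert res.a == pytest.approx(0.0, abs=1e-12)


def test_variant_collinear_flagged():
    y = np.array([1.0, -1.0, 2.0])
    d = np.array([1.0, 1.0, 1.0])
    res = gls_variant_test(y, d, np.eye(3))
    assert res.flag == "skipped-collinear"


@pytest.mark.parametrize("seed", range(8))
def test_variant_matches_brute_force(seed):
    """The segment-batched GLS equals explicit full-covariance brute force
    (chi-square to 1e-6) on n = 200 problems."""
    rng = np.random.default_rng(seed)
    n = 200
    L = rng.normal(size=(n, n)) / math.sqrt(n)
    V = L @ L.T + np.eye(n)
    y = rng.normal(size=n)
    d = rng.binomial(2, 0.3, size=n).astype(float)
    C = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
    res = gls_variant_test(y, d, V, extra_covariates=C[:, 1:])
    a, se, chi2 = _brute_force_gls(y, d, V, C)
    assert res.chi2 == pytest.approx(chi2, abs=1e-6)
    assert res.a == pytest.approx(a, rel=1e-8)
    assert res.se == pytest.approx(se, rel=1e-8)


def test_scan_trait_matches_single_variant_path(default_scanner, default_adjusted):
    adjusted, _, study = default_adjusted
    y = adjusted["FP"].to_numpy()
    vc = default_scanner.variance_components(y)
    res = default_scanner.scan_trait(y, "FP", chroms={"1"}, vc=vc)
    row = res.iloc[37]
    seg = segment_of(row["chrom"], row["pos"])
    V = vc[0] * loso_grm(default_scanner.panel, seg) + vc[1] * np.eye(len(y))
    single = gls_variant_test(y, study.vid_column(row["vid"]), V,
                          sigma2_t=vc[2], sigma2_g=vc[0])
    assert single.chi2 == pytest.approx(row["chi2"], rel=1e-8)
    assert single.a == pytest.approx(row["a"], rel=1e-8)


def test_chi2_identity_and_p_range(default_scanner, default_adjusted):
    adjusted, _, _ = default_adjusted
    res = default_scanner.scan_trait(adjusted["LP"].to_numpy(), "LP",
                                     chroms={"2"})
    ok = res[res["flag"] == ""]
    np.testing.assert_allclose(ok["chi2"], (ok["a"] / ok["se"]) ** 2,
                               atol=1e-9)
    assert (ok["p"] > 0).all() and (ok["p"] <= 1).all()
    assert (ok["pve"] >= 0).all()


def test_extreme_p_in_log_space():
    nl = gw.neglog10_from_chi2(np.array([12000.0]))[0]
    assert 2600 < nl < 2610  # far beyond float underflow, finite in log space


def test_proximal_contamination_direction(default_scanner, default_adjusted, default_sim):
    """Including a causal variant's own segment in the GRM does not increase
    its chi-square relative to LOSO, on average over planted QTL."""
    cfg, _ = default_sim
    adjusted, _, study = default_adjusted
    panel = default_scanner.panel
    deltas = []
    for trait, comp in [("FP", 0), ("PP", 1), ("LP", 2)]:
        y = adjusted[trait].to_numpy()
        s2g, s2e, _ = default_scanner.variance_components(y)
        for q in cfg.planted_qtl:
            if q.component != comp:
                continue
            d = study.vid_column(q.vid)
            v = study.variants[study.index_of(q.vid)]
            seg = segment_of(v.chrom, v.pos)
            V_loso = s2g * loso_grm(panel, seg) + s2e * np.eye(len(y))
            V_full = s2g * panel.G + s2e * np.eye(len(y))
            chi_loso = gls_variant_test(y, d, V_loso).chi2
            chi_full = gls_variant_test(y, d, V_full).chi2
            deltas.append(chi_loso - chi_full)
    assert np.mean(deltas) > 0


# -------------------------------------------------------------- region count

def test_count_1mb_regions_boundaries():
    import pandas as pd

    empty = pd.DataFrame({"chrom": [], "pos": [], "neglog10p": []})
    assert count_1mb_regions(empty, 12.0) == 0
    res = pd.DataFrame({
        "chrom": ["1", "1", "2"],
        "pos": [999_999, 1_000_000, 500],
        "neglog10p": [20.0, 20.0, 1.0],
    })
    # two significant hits straddling the 1-Mbp boundary are two regions
    assert count_1mb_regions(res, 12.21) == 2
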