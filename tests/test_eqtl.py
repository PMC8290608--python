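import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirqtl.conditional import QtlTag
from mirqtl.dataio import PedigreeTable
from mirqtl.eqtl import (
    AMatrix,
    EqtlScanner,
    build_a_matrix,
    coloc_test,
)
from mirqtl.synthetic import simulate_dataset, simulate_expression, \
    simulate_genotypes
from conftest import small_config


# ---------------------------------------------------------------- A matrix

def test_a_matrix_founders_identity():
    ped = PedigreeTable([("A", None, None), ("B", None, None)])
    A = build_a_matrix(ped)
    np.testing.assert_allclose(A.values, np.eye(2))


def test_a_matrix_textbook_values():
    ped = PedigreeTable([
        ("S", None, None), ("D", None, None),
        ("X", "S", "D"), ("Y", "S", "D"),  # full sibs
        ("Z", "S", None),  # half sib of X through the sire
    ])
    A = build_a_matrix(ped)
    i = {a: k for k, a in enumerate(A.animals)}
    assert A.values[i["X"], i["Y"]] == pytest.approx(0.5)
    assert A.values[i["X"], i["Z"]] == pytest.approx(0.25)
    assert A.values[i["X"], i["S"]] == pytest.approx(0.5)
    assert A.values[i["X"], i["X"]] == pytest.approx(1.0)  # parents unrelated


def test_a_matrix_inbred_offspring_diagonal():
    # sire mated to his own daughter: offspring inbreeding F = 0.25
    ped = PedigreeTable([
        ("S", None, None), ("D", None, None),
        ("X", "S", "D"), ("W", "S", "X"),
    ])
    A = build_a_matrix(ped)
    i = {a: k for k, a in enumerate(A.animals)}
    assert A.values[i["W"], i["W"]] == pytest.approx(1.25)
    assert np.all(np.diag(A.values) >= 1.0 - 1e-12)


def test_a_matrix_matches_gene_dropping():
    """Tabular-method relationships agree with 2 x kinship estimated by
    Monte-Carlo gene dropping on a 50-animal pedigree (+-0.02)."""
    rng = np.random.default_rng(11)
    rows = [(f"F{i}", None, None) for i in range(10)]
    for i in range(40):
        s = f"F{rng.integers(0, 5)}"
        d = f"F{rng.integers(5, 10)}" if i < 20 else f"A{rng.integers(0, i)}" \
            if rng.random() < 0.5 and i > 0 else f"F{rng.integers(5, 10)}"
        rows.append((f"A{i}", s, d))
    ped = PedigreeTable(rows)
    A = build_a_matrix(ped)
    idx = {a: k for k, a in enumerate(ped.order)}
    n_drops = 100_000
    # drop a single biallelic founder-labelled allele through the pedigree
    alleles = np.empty((len(ped.order), 2, n_drops), dtype=np.int32)
    counter = 0
    for a in ped.order:
        s, d = ped.parents[a]
        for slot, parent in enumerate((s, d)):
            if parent is None:
                alleles[idx[a], slot] = counter
                counter += 1
            else:
                pick = np.random.default_rng(hash((a, slot)) % 2**31).integers(
                    0, 2, n_drops)
                alleles[idx[a], slot] = alleles[idx[parent], pick,
                                                np.arange(n_drops)]
    test_pairs = [(ped.order[i], ped.order[j])
                  for i in range(0, 50, 7) for j in range(i, 50, 11)]
    for x, y in test_pairs:
        ax, ay = alleles[idx[x]], alleles[idx[y]]
        ibd = np.mean(
            (ax[0] == ay[0]).astype(float) + (ax[0] == ay[1])
            + (ax[1] == ay[0]) + (ax[1] == ay[1])
        ) / 4.0
        assert abs(2 * ibd - A.values[idx[x], idx[y]]) < 0.02, (x, y)


# ------------------------------------------------------------------ scans

def test_a_identity_reduces_to_ols(small_dataset):
    _, (genotypes, _p, _r, expression, *_rest) = small_dataset
    A = AMatrix(list(expression.animals),
                np.eye(len(expression.animals)))
    scanner = EqtlScanner(expression, genotypes, A, jitter=0.0)
    gene = expression.genes[0]
    res = scanner.scan_gene(gene, vids=genotypes.vids[:40])
    y = expression.gene_column(gene)
    cohort = [genotypes.animals.index(a) for a in expression.animals]
    for _, row in res.iloc[:10].iterrows():
        d = genotypes.dosages[cohort, genotypes.index_of(row["vid"])]
        if d.std() == 0:
            continue
        slope, _, rval, pval, stderr = stats.linregress(d, y)
        assert row["chi2"] == pytest.approx((slope / stderr) ** 2 *
                                            (len(y) - 2) / len(y), rel=0.05)


def test_planted_eqtl_detected_across_replicates():
    """The causal variant of a 20%-variance eQTL reaches the scan
    threshold in nearly all replicates."""
    hits = 0
    reps = 12
    for seed in range(reps):
        cfg = small_config(seed=300 + seed)
        g, ped, meta = simulate_genotypes(cfg)
        from mirqtl.synthetic import simulate_phenotypes

        _records, truth = simulate_phenotypes(cfg, g, ped, meta)
        expr = simulate_expression(cfg, g, ped, meta, truth)
        A = build_a_matrix(ped)
        scanner = EqtlScanner(expr, g, A)
        q = next(x for x in cfg.planted_qtl
                 if x.mechanism == "expression_mediated")
        res = scanner.scan_gene(q.gene)
        n_tests = len(res)
        _, nl_thr = scanner.significance_threshold(n_tests)
        row = res[res["vid"] == q.vid].iloc[0]
        hits += bool(row["neglog10p"] > nl_thr)
    assert hits >= reps - 1


def test_null_eqtl_p_values_uniform(small_dataset):
    """Expression with no genetic dosage effect gives uniform p-values
    (KS non-rejection at 1% over 10^4 tests).

    Null genes are drawn fresh (pedigree polygenic + noise) and variants
    thinned to roughly one per LD block, so the tests are near-independent
    and the KS reference distribution applies.
    """
    from mirqtl.dataio import ExpressionMatrix

    cfg, (genotypes, ped, _r, expression, *_rest) = small_dataset
    rng = np.random.default_rng(1)
    n_genes = 80
    cohort = expression.animals
    # polygenic part via the pedigree of the cohort's animals
    A = build_a_matrix(ped)
    Ac = A.submatrix(cohort)
    L = np.linalg.cholesky(Ac + 1e-10 * np.eye(len(cohort)))
    vals = (
        np.sqrt(0.3) * L @ rng.normal(size=(len(cohort), n_genes))
        + np.sqrt(0.7) * rng.normal(size=(len(cohort), n_genes))
    )
    gp = pd.DataFrame({"gene": [f"N{i}" for i in range(n_genes)],
                       "chrom": "1", "start": 1, "end": 2})
    null_expr = ExpressionMatrix(cohort, [f"N{i}" for i in range(n_genes)],
                                 vals, gp)
    scanner = EqtlScanner(null_expr, genotypes, A)
    # one variant per ~2 LD blocks, polymorphic in the cohort
    maf = scanner.genotypes.recompute_maf()
    vid_pool = [v for v, m in zip(scanner.genotypes.vids, maf) if m > 0.02][::12]
    pvals = [scanner.scan_gene(g, vids=vid_pool)["p"].dropna().to_numpy()
             for g in null_expr.genes]
    p = np.concatenate(pvals)
    assert len(p) >= 10_000
    stat, ks_p = stats.kstest(p, "uniform")
    assert ks_p > 0.01


# ------------------------------------------------------------------ coloc

def _fake_results(pos, nl, chrom="1", gene=None):
    df = pd.DataFrame({
        "vid": [f"v{i}" for i in range(len(pos))],
        "chrom": chrom, "pos": pos, "neglog10p": nl,
        "p": np.power(10.0, -np.asarray(nl)),
    })
    if gene:
        df["gene"] = gene
    return df


def test_coloc_identical_profiles_perfect_correlation(small_dataset):
    _, (genotypes, *_rest) = small_dataset
    rng = np.random.default_rng(8)
    v = genotypes.variants[50]
    pos = np.sort(rng.integers(v.pos - 400_000, v.pos + 400_000, 60))
    nl = rng.uniform(1, 30, 60)
    trait = _fake_results(pos, nl, chrom=v.chrom)
    eqtl = _fake_results(pos, nl, chrom=v.chrom, gene="G1")
    # make the top eQTL variant the tag itself so LD is 1
    top = int(np.argmax(nl))
    eqtl.loc[top, "vid"] = v.vid
    trait.loc[top, "vid"] = v.vid
    tag = QtlTag("FP", 0, v.chrom, v.pos, v.vid, 1e-20, 20.0, 0.1, 0.01)
    call = coloc_test(trait, eqtl, tag, genotypes, min_shared=30)
    assert call is not None
    assert call.pearson_r == pytest.approx(1.0)
    assert call.r2 == pytest.approx(1.0)
    assert call.window_mb in (0.5, 1.0)


def test_coloc_log_base_invariance(small_dataset):
    _, (genotypes, *_rest) = small_dataset
    rng = np.random.default_rng(9)
    v = genotypes.variants[50]
    pos = np.sort(rng.integers(v.pos - 400_000, v.pos + 400_000, 80))
    nl_t = rng.uniform(1, 30, 80)
    nl_e = 0.7 * nl_t + rng.uniform(0, 3, 80)
    trait = _fake_results(pos, nl_t, chrom=v.chrom)
    eqtl = _fake_results(pos, nl_e, chrom=v.chrom, gene="G1")
    eqtl.loc[int(np.argmax(nl_e)), "vid"] = v.vid
    trait.loc[int(np.argmax(nl_e)), "vid"] = v.vid
    tag = QtlTag("FP", 0, v.chrom, v.pos, v.vid, 1e-20, 20.0, 0.1, 0.01)
    c1 = coloc_test(trait, eqtl, tag, genotypes, min_shared=30)
    # natural-log scaling of both profiles leaves the correlation unchanged
    ln = np.log(10.0)
    trait2 = trait.assign(neglog10p=trait["neglog10p"] * ln)
    eqtl2 = eqtl.assign(neglog10p=eqtl["neglog10p"] * ln)
    c2 = coloc_test(trait2, eqtl2, tag, genotypes, min_shared=30)
    assert c1 is not None and c2 is not None
    assert c1.pearson_r == pytest.approx(c2.pearson_r, abs=1e-12)


def test_coloc_thresholds_strict(small_dataset):
    _, (genotypes, *_rest) = small_dataset
    rng = np.random.default_rng(10)
    v = genotypes.variants[50]
    pos = np.sort(rng.integers(v.pos - 400_000, v.pos + 400_000, 60))
    nl_t = rng.uniform(1, 30, 60)
    nl_e = rng.permutation(nl_t)  # uncorrelated profile
    trait = _fake_results(pos, nl_t, chrom=v.chrom)
    eqtl = _fake_results(pos, nl_e, chrom=v.chrom, gene="G1")
    eqtl.loc[int(np.argmax(nl_e)), "vid"] = v.vid
    trait.loc[int(np.argmax(nl_e)), "vid"] = v.vid
    tag = QtlTag("FP", 0, v.chrom, v.pos, v.vid, 1e-20, 20.0, 0.1, 0.01)
    assert coloc_test(trait, eqtl, tag, genotypes, min_shared=30) is None


def test_coloc_min_shared_guard(small_dataset):
    _, (genotypes, *_rest) = small_dataset
    v = genotypes.variants[50]
    trait = _fake_results([v.pos], [20.0], chrom=v.chrom)
    eqtl = _fake_results([v.pos], [20.0], chrom=v.chrom, gene="G1")
    tag = QtlTag("FP", 0, v.chrom, v.pos, v.vid, 1e-20, 20.0, 0.1, 0.01)
    assert coloc_test(trait, eqtl, tag, genotypes, min_shared=30) is None
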