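import numpy as np
import pytest

from mirqtl import gwas as gw
from mirqtl.dataio import maf_from_dosages
from mirqtl.eqtl import build_a_matrix
from mirqtl.synthetic import (
    PlantedQtl,
    SimulationConfig,
    simulate_dataset,
    simulate_expression,
    simulate_genotypes,
    simulate_phenotypes,
)
from conftest import small_config


def test_fixed_seed_reproducible(small_dataset):
    cfg, (genotypes, pedigree, records, expression, *_rest) = small_dataset
    cfg2 = small_config()
    g2, p2, m2 = simulate_genotypes(cfg2)
    np.testing.assert_array_equal(genotypes.dosages, g2.dosages)
    r2, _ = simulate_phenotypes(cfg2, g2, p2, m2)
    np.testing.assert_allclose(records[0].spectrum, r2[0].spectrum)
    e2 = simulate_expression(cfg2, g2, p2, m2)
    np.testing.assert_allclose(expression.values, e2.values)


def test_ld_decays_across_blocks(default_sim):
    """Mean adjacent-marker r2 is higher within LD blocks than across them."""
    cfg, (genotypes, *_rest) = default_sim
    chrom1 = [i for i, v in enumerate(genotypes.variants) if v.chrom == "1"]
    dos = genotypes.dosages[:, chrom1]
    pos = genotypes.positions[chrom1]
    block = (pos - 1) // cfg.ld_block_length_bp
    within, across = [], []
    sd = dos.std(axis=0)
    for j in range(len(pos) - 1):
        if sd[j] == 0 or sd[j + 1] == 0:
            continue
        r2 = np.corrcoef(dos[:, j], dos[:, j + 1])[0, 1] ** 2
        (within if block[j] == block[j + 1] else across).append(r2)
    assert np.mean(within) > np.mean(across) + 0.1


def test_maf_spectrum_and_bounds(small_dataset):
    _, (genotypes, *_rest) = small_dataset
    maf = genotypes.recompute_maf()
    assert np.all(maf <= 0.5) and np.all(maf >= 0)
    assert np.all(genotypes.dosages >= 0) and np.all(genotypes.dosages <= 2)


def test_purebred_heterosis_is_zero(small_dataset):
    _, (_g, pedigree, records, *_rest) = small_dataset
    by_animal = {r.animal: r for r in records}
    found = 0
    for r in by_animal.values():
        if np.max(r.breed_props) == 1.0:  # both parents of the same breed
            np.testing.assert_array_equal(r.het_props, np.zeros(6))
            found += 1
    assert found > 0


def test_zero_noise_spectrum_equals_mixing():
    cfg = small_config(
        sigma2_polygenic=0.0, sigma2_animal=0.0, sigma2_resid=0.0,
        spectral_noise_sd=0.0, planted_qtl=[], decoy_eqtl=[],
        fixed_effect_sd={"parity": 0, "dim": 0, "htd": 0, "breed": 0, "het": 0},
        n_animals=20, n_dams=10,
    )
    g, p, m = simulate_genotypes(cfg)
    records, truth = simulate_phenotypes(cfg, g, p, m)
    base = np.asarray(cfg.component_baseline[:4])
    expected = base @ cfg.mixing_matrix()
    for r in records[:5]:
        np.testing.assert_allclose(r.spectrum, expected, atol=1e-12)


def test_noise_regions_have_larger_residual_variance(small_dataset):
    cfg, (_g, _p, records, *_rest) = small_dataset
    spectra = np.array([r.spectrum for r in records])
    mix = cfg.mixing_matrix()
    # regress out the constituent signatures; residual variance per channel
    coef, *_ = np.linalg.lstsq(
        np.column_stack([np.ones(mix.shape[1]), mix.T]).astype(float),
        spectra.T, rcond=None,
    )
    resid = spectra.T - np.column_stack([np.ones(mix.shape[1]), mix.T]) @ coef
    var = resid.var(axis=1)
    mask = cfg.noise_mask()
    assert var[mask].mean() > 2 * var[~mask].mean()


def test_coding_qtl_homozygote_contrast(default_sim):
    """Alt- vs ref-homozygote spectrum difference at the signature peak is
    close to 2a x (peak height of the affected constituent)."""
    cfg, (genotypes, _p, records, *_rest) = default_sim
    q = next(x for x in cfg.planted_qtl
             if x.mechanism == "coding" and x.component == 0)
    mix = cfg.mixing_matrix()
    peak = int(np.argmax(mix[0]))
    dose = {a: d for a, d in zip(genotypes.animals,
                                 genotypes.vid_column(q.vid))}
    alt = [r.spectrum[peak] for r in records if dose[r.animal] == 2]
    ref = [r.spectrum[peak] for r in records if dose[r.animal] == 0]
    observed = np.mean(alt) - np.mean(ref)
    expected = 2 * q.effect * mix[0, peak]
    # the peak channel also carries polygenic and record noise: allow MC error
    se = np.sqrt(np.var(alt) / len(alt) + np.var(ref) / len(ref)) * mix[0, peak]
    assert abs(observed - expected) < max(4 * se, 0.3 * abs(expected))


def test_expression_null_gene_uncorrelated(small_dataset):
    _, (genotypes, _p, _r, expression, _a, truth) = small_dataset
    cohort_idx = [genotypes.animals.index(a) for a in expression.animals]
    causal_genes = set(truth.gene_effects)
    rng = np.random.default_rng(0)
    corrs = []
    for gene in expression.genes:
        if gene in causal_genes or not gene.startswith("BG"):
            continue
        e = expression.gene_column(gene)
        j = rng.integers(0, genotypes.n_variants)
        d = genotypes.dosages[cohort_idx, j]
        if d.std() == 0:
            continue
        corrs.append(abs(np.corrcoef(e, d)[0, 1]))
    assert np.mean(corrs) < 0.1
    assert max(corrs) < 0.35


def test_mediated_qtl_signs_consistent(small_dataset):
    """Expression and trait effects at a shared causal variant agree in
    sign with the configured mediation."""
    cfg, (genotypes, _p, _r, expression, _a, truth) = small_dataset
    q = next(x for x in cfg.planted_qtl if x.mechanism == "expression_mediated")
    cohort_idx = [genotypes.animals.index(a) for a in expression.animals]
    d = genotypes.dosages[cohort_idx, genotypes.index_of(q.vid)]
    e = expression.gene_column(q.gene)
    slope = np.polyfit(d, e, 1)[0]
    assert np.sign(slope) == np.sign(q.beta_e)
    assert np.sign(q.effect * q.beta_e) == np.sign(q.effect) * np.sign(q.beta_e)


def test_planted_qtl_on_existing_variants(default_sim):
    cfg, (genotypes, *_rest) = default_sim
    vids = set(genotypes.vids)
    for q in cfg.planted_qtl:
        assert q.vid in vids
        assert q.effect is not None and q.effect > 0


def test_heritability_recovered_by_pedigree_reml(default_sim, default_adjusted):
    """A-matrix REML on adjusted composition traits recovers the configured
    heritability (mean over the three traits, +-0.05)."""
    cfg, (_g, pedigree, _r, _e, _a, truth) = default_sim
    adjusted, _vc, _study = default_adjusted
    A = build_a_matrix(pedigree)
    Ac = A.submatrix(list(adjusted["animal"]))
    eig = (lambda w_v: (np.maximum(w_v[0], 0.0), w_v[1]))(np.linalg.eigh(Ac))
    diffs = []
    for trait, comp in [("FP", "fat"), ("LP", "lactose"), ("PP", "protein")]:
        s2g, s2e, s2t = gw.estimate_vc(adjusted[trait].to_numpy(), Ac, eig=eig)
        diffs.append(s2g / s2t - truth.expected_h2[comp])
    assert abs(np.mean(diffs)) < 0.05


def test_config_validation():
    with pytest.raises(ValueError, match="2 variants per LD block"):
        SimulationConfig(variants_per_chrom=10)
    with pytest.raises(ValueError, match="noise region"):
        SimulationConfig(noise_regions=((100.0, 200.0),))
    with pytest.raises(ValueError, match="impact"):
        PlantedQtl("1", 1, 0, "coding", 0.05, "OTHER", "G")
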