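"""End-to-end orchestration: simulate -> qc -> adjust -> gwas -> condition
-> classify -> eqtl -> coloc -> profiles, with ground-truth evaluation."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import adjust as adj
from . import candidates as cand
from . import conditional as cond
from . import eqtl as eq
from . import gwas as gw
from . import profiles as prof
from . import qc
from .dataio import COMPOSITION_TRAITS, write_results
from .synthetic import SimulationConfig, simulate_dataset

logger = logging.getLogger("mirqtl")


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    alpha: float = 0.01
    maf_min: float = 0.001
    mahalanobis_k: int = 10
    mahalanobis_quantile: float = 0.999
    traits: list[str] | None = None  # default: composition + all wavenumbers
    max_iterations: int = 25
    profile_cut_k: int = 3
    eqtl_alpha: float = 0.05
    coloc_min_shared: int = 30

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        if isinstance(sim, dict):
            sim = SimulationConfig(**sim)
        return cls(simulation=sim, **d)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out


@dataclass
class PipelineRun:
    config: dict
    seed: int
    summary: dict
    tables: dict[str, pd.DataFrame]
    threshold_neglog10: float
    profiles: list
    dendrogram: prof.Dendrogram | None
    truth: object
    wavenumber_traits: list[str]
    tags_by_trait: dict[str, list]

    def manifest(self) -> dict:
        blob = json.dumps(self.config, sort_keys=True, default=str).encode()
        hashes = {}
        for name, df in self.tables.items():
            hashes[name] = hashlib.sha256(
                df.to_csv(index=False, float_format="%.10g").encode()
            ).hexdigest()
        return {
            "config_hash": hashlib.sha256(blob).hexdigest(),
            "seed": self.seed,
            "summary": self.summary,
            "table_hashes": hashes,
        }

    def write(self, outdir: str | Path) -> dict:
        man = write_results(self.tables, outdir, config=self.config, seed=self.seed)
        man["summary"] = self.summary
        if self.dendrogram is not None:
            (Path(outdir) / "profiles.nwk").write_text(self.dendrogram.to_newick())
            with open(Path(outdir) / "profiles_merges.json", "w") as fh:
                json.dump(self.dendrogram.merge_table(), fh, indent=2)
        with open(Path(outdir) / "manifest.json", "w") as fh:
            json.dump(man, fh, indent=2, sort_keys=True, default=str)
        return man


def run_pipeline(config: PipelineConfig | dict) -> PipelineRun:
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    cfg = config.simulation
    genotypes, pedigree, records, expression, annotations, truth = \
        simulate_dataset(cfg)

    records, qc_report = qc.mahalanobis_spectral_filter(
        records, config.mahalanobis_k, config.mahalanobis_quantile,
    )
    genotypes, var_report = qc.threshold_filters(genotypes)

    traits = config.traits
    n_wn = len(records[0].spectrum)
    if traits is None:
        traits = list(COMPOSITION_TRAITS) + [f"wn_{i:04d}" for i in range(n_wn)]
    adjusted, vc_table = adj.adjust_traits(records, traits)
    wn_traits = [t for t in traits if t.startswith("wn_")]

    study = genotypes.subset_animals(list(adjusted["animal"]))
    panel_ids = study.vids[:: cfg.grm_panel_stride]
    panel = gw.build_grm(study, panel_ids, maf_min=config.maf_min)
    gcfg = gw.GwasConfig(maf_min=config.maf_min, alpha=config.alpha,
                         n_traits=len(traits))
    scanner = gw.GwasScanner(study, panel, gcfg)
    n_tested = int(np.sum(scanner.maf >= config.maf_min))
    _, B = gw.bonferroni_threshold(config.alpha, len(traits), n_tested)

    tags_by_trait: dict[str, list] = {}
    base_neglog10: dict[str, pd.Series] = {}
    all_tags: list[cond.QtlTag] = []
    sig_counts = {}
    base_frames = {}
    for t in traits:
        y = adjusted[t].to_numpy()
        res = cond.run_iterative(scanner, y, t, B,
                                 max_iterations=config.max_iterations)
        tags_by_trait[t] = res.tags
        all_tags.extend(res.tags)
        ok = res.base_results[res.base_results["flag"] == ""]
        sig_counts[t] = int((ok["neglog10p"] > B).sum())
        base_neglog10[t] = res.base_results.set_index("vid")["neglog10p"]
        base_frames[t] = res.base_results

    wn_results = pd.concat([base_frames[t] for t in wn_traits]) \
        if wn_traits else pd.DataFrame(columns=["neglog10p", "chrom", "pos"])
    comp_traits = [t for t in traits if t in COMPOSITION_TRAITS]
    comp_results = pd.concat([base_frames[t] for t in comp_traits]) \
        if comp_traits else pd.DataFrame(columns=["neglog10p", "chrom", "pos"])
    wn_regions = gw.count_1mb_regions(wn_results, B) if len(wn_results) else 0
    comp_regions = gw.count_1mb_regions(comp_results, B) if len(comp_results) else 0

    calls = cand.link_candidates(all_tags, annotations, study, B)

    a_matrix = eq.build_a_matrix(pedigree)
    escanner = eq.EqtlScanner(expression, genotypes, a_matrix)
    coloc_calls: list[eq.ColocCall] = []
    for t, tags in tags_by_trait.items():
        trait_res = base_frames[t]
        for tag in tags:
            half = 500_000
            genes = expression.genes_in_window(tag.chrom, tag.pos - half,
                                               tag.pos + half)
            for gene in genes:
                eres = escanner.scan_gene(gene, window_bp=1_000_000)
                eres = eres[eres["chrom"].astype(str) == tag.chrom]
                if eres.empty:
                    continue
                call = eq.coloc_test(trait_res, eres, tag, study,
                                     min_shared=config.coloc_min_shared)
                if call is not None:
                    coloc_calls.append(call)

    # significance profiles for implicated genes, over the wavenumber traits
    genes = sorted({c.gene for c in calls} | {c.gene for c in coloc_calls})
    profiles = []
    for gene in genes:
        vid = prof.select_representative(gene, calls, coloc_calls)
        raw = np.array(
            [base_neglog10[t].get(vid, np.nan) for t in wn_traits], dtype=float
        )
        if not np.any(np.isfinite(raw) & (raw > 0)):
            continue
        profiles.append(prof.build_profile(vid, raw, label=f"{gene}:{vid}"))
    dendro = None
    n_clusters = 0
    if len(profiles) >= 2:
        D = prof.profile_distance_matrix(profiles)
        dendro = prof.complete_linkage_cluster(D, [p.label for p in profiles])
        k = min(config.profile_cut_k, len(profiles))
        n_clusters = len(set(dendro.cut(k)))

    tag_rows = pd.concat(
        [cond.ConditionalScanResult(t, tags, 0, pd.DataFrame(),
                                    pd.DataFrame(), True).tag_table()
         for t, tags in tags_by_trait.items() if tags],
        ignore_index=True,
    ) if any(tags_by_trait.values()) else pd.DataFrame()

    tables = {
        "adjusted_phenotypes": adjusted,
        "variance_components": vc_table,
        "qtl_tags": tag_rows,
        "candidate_calls": cand.candidate_table(calls),
        "coloc_calls": eq.coloc_table(coloc_calls),
        "significant_counts": pd.DataFrame(
            {"trait": list(sig_counts), "n_significant": list(sig_counts.values())}
        ),
    }
    summary = {
        "n_records_kept": len(records),
        "n_records_removed": qc_report.removed,
        "n_variants_kept": genotypes.n_variants,
        "n_variants_tested": n_tested,
        "threshold_neglog10": B,
        "significant_per_trait": sig_counts,
        "wavenumber_regions_1mb": wn_regions,
        "composition_regions_1mb": comp_regions,
        "n_tags": len(all_tags),
        "candidate_calls_by_tier": dict(
            pd.Series([c.tier for c in calls]).value_counts()
        ) if calls else {},
        "n_coloc_calls": len(coloc_calls),
        "n_profile_clusters": n_clusters,
    }
    return PipelineRun(
        config=config.to_dict(), seed=cfg.seed, summary=summary, tables=tables,
        threshold_neglog10=B, profiles=profiles, dendrogram=dendro,
        truth=truth, wavenumber_traits=wn_traits, tags_by_trait=tags_by_trait,
    )


def evaluate_against_truth(run: PipelineRun, truth=None,
                           genotypes=None) -> pd.DataFrame:
    """Planted-QTL recall/precision and candidate-gene accuracy for a run.

    A tag is a true positive when its dosage r2 with a planted causal
    variant is at least 0.8.
    """
    truth = truth or run.truth
    if genotypes is None:
        raise ValueError("pass the study genotype matrix used in the run")
    planted = {q.vid: q for q in truth.planted_qtl}
    tag_vids = {t.vid for tags in run.tags_by_trait.values() for t in tags}
    matched = set()
    tp = 0
    for tv in tag_vids:
        hit = False
        for pv in planted:
            r2 = cand.ld_r2(genotypes.vid_column(tv), genotypes.vid_column(pv))
            if r2 >= 0.8:
                matched.add(pv)
                hit = True
        tp += int(hit)
    recall = len(matched) / max(1, len(planted))
    precision = tp / max(1, len(tag_vids))
    call_genes = set(run.tables["candidate_calls"].get("gene", []))
    coding_genes = {q.gene for q in truth.planted_qtl if q.mechanism == "coding"}
    gene_acc = len(call_genes & coding_genes) / max(1, len(coding_genes))
    rows = [
        {"metric": "qtl_recall", "value": recall},
        {"metric": "tag_precision", "value": precision},
        {"metric": "candidate_gene_recall", "value": gene_acc},
        {"metric": "n_coloc_calls", "value": len(run.tables["coloc_calls"])},
    ]
    return pd.DataFrame(rows)
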