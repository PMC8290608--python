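"""Iterative conditional association: separating multiple QTL per chromosome.

Starting from the base scan, every chromosome holding a Bonferroni-
significant variant contributes its most significant variant as a tag; the
tags join one shared covariate set and the scan is rerun on the
chromosomes that retained significance, until none does. A final
confirmation scan over all chromosomes with every tag fitted checks that
no previously-significant chromosome still harbours a significant signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gwas import GwasScanner

logger = logging.getLogger("mirqtl")


@dataclass
class QtlTag:
    trait: str
    iteration: int  # 0 = selected in the base GWAS
    chrom: str
    pos: int
    vid: str
    p: float
    neglog10p: float
    a: float
    se: float


class IterationCapError(RuntimeError):
    def __init__(self, msg: str, tags: list[QtlTag]):
        super().__init__(msg)
        self.tags = tags


@dataclass
class ConditionalScanResult:
    trait: str
    tags: list[QtlTag]
    n_iterations: int
    base_results: pd.DataFrame
    confirmation: pd.DataFrame
    confirmation_ok: bool

    def tag_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": t.chrom, "pos": t.pos, "vid": t.vid,
                    "iteration": t.iteration, "p": t.p,
                    "neglog10p": t.neglog10p, "a": t.a, "se": t.se,
                    "trait": t.trait,
                }
                for t in self.tags
            ]
        )


def _top_variant(chunk: pd.DataFrame) -> pd.Series:
    """Most significant variant; ties by |chi2|, then position, then vid."""
    c = chunk.copy()
    c = c.sort_values(
        by=["neglog10p", "chi2", "pos", "vid"],
        ascending=[False, False, True, True],
        kind="mergesort",
    )
    return c.iloc[0]


def run_iterative(scanner: GwasScanner, y: np.ndarray, trait: str,
                  neglog10_threshold: float, max_iterations: int = 25
                  ) -> ConditionalScanResult:
    """The greedy conditional tagging loop for one trait."""
    y = np.asarray(y, dtype=float)
    vc = scanner.variance_components(y)
    base = scanner.scan_trait(y, trait, vc=vc)
    results = base
    tags: list[QtlTag] = []
    cov_cols: list[np.ndarray] = []
    cov_vids: list[str] = []
    active: set[str] | None = None  # None = all chromosomes (base pass)
    ever_significant: set[str] = set()
    iteration = 0
    while True:
        ok = results[results["flag"] == ""]
        sig = ok[ok["neglog10p"] > neglog10_threshold]
        sig_chroms = set(sig["chrom"])
        if active is not None and not sig_chroms <= active:
            logger.error(
                "trait %s: chromosomes gained significance during conditioning: %s",
                trait, sorted(sig_chroms - active),
            )
            raise RuntimeError(
                "monotone-termination violation: new chromosomes became "
                f"significant at iteration {iteration}"
            )
        if not sig_chroms:
            break
        ever_significant |= sig_chroms
        for chrom in sorted(sig_chroms):
            chunk = sig[sig["chrom"] == chrom]
            row = _top_variant(chunk)
            dose = scanner.genotypes.vid_column(row["vid"])
            # a tag collinear with the accumulated covariates: take next best
            taken = False
            while not taken:
                if cov_cols:
                    C = np.column_stack(cov_cols)
                    q, _ = np.linalg.qr(np.column_stack([np.ones(len(dose)), C]))
                    resid = dose - q @ (q.T @ dose)
                    tss = np.sum((dose - dose.mean()) ** 2)
                    if tss <= 0 or 1 - resid @ resid / tss > 0.99:
                        logger.warning(
                            "trait %s: tag %s collinear with covariates, "
                            "taking next best", trait, row["vid"],
                        )
                        chunk = chunk[chunk["vid"] != row["vid"]]
                        if chunk.empty:
                            break
                        row = _top_variant(chunk)
                        dose = scanner.genotypes.vid_column(row["vid"])
                        continue
                taken = True
            if not taken:
                continue
            tags.append(
                QtlTag(
                    trait=trait, iteration=iteration, chrom=str(row["chrom"]),
                    pos=int(row["pos"]), vid=str(row["vid"]),
                    p=float(row["p"]), neglog10p=float(row["neglog10p"]),
                    a=float(row["a"]), se=float(row["se"]),
                )
            )
            cov_cols.append(dose)
            cov_vids.append(str(row["vid"]))
        active = sig_chroms
        iteration += 1
        if iteration > max_iterations:
            raise IterationCapError(
                f"trait {trait}: conditional scan exceeded {max_iterations} "
                "iterations", tags,
            )
        results = scanner.scan_trait(
            y, trait,
            covariates=np.column_stack(cov_cols),
            covariate_vids=tuple(cov_vids),
            chroms=active, vc=vc,
        )

    confirmation = scanner.scan_trait(
        y, trait,
        covariates=np.column_stack(cov_cols) if cov_cols else None,
        covariate_vids=tuple(cov_vids),
        vc=vc,
    )
    conf_ok = True
    if ever_significant:
        ok = confirmation[confirmation["flag"] == ""]
        left = ok[(ok["neglog10p"] > neglog10_threshold)
                  & (ok["chrom"].isin(ever_significant))]
        conf_ok = left.empty
        if not conf_ok:
            logger.warning(
                "trait %s: %d variants remain significant after conditioning",
                trait, len(left),
            )
    return ConditionalScanResult(
        trait=trait, tags=tags, n_iterations=iteration,
        base_results=base, confirmation=confirmation,
        confirmation_ok=conf_ok,
    )
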