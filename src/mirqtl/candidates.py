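"""Link QTL tags to putative impact variants (PIV) and classify candidacy.

A PIV is a splice-region, moderate-impact or high-impact coding variant.
Tags are linked to PIVs inside a 1-Mbp window centred on the tag when the
dosage LD r2 exceeds 0.9, and each link is classified:

* HIGH_SIG  — r2 in (0.975, 1] and -log10 p > 1.5 B; or r2 in
  (0.95, 0.975] and -log10 p > 2 B; or r2 in (0.925, 0.95] and
  -log10 p > 2.5 B,
* MODERATE_SIG — otherwise r2 > 0.9 and -log10 p > B,

with B the -log10 Bonferroni threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .conditional import QtlTag
from .dataio import AnnotationTable, GenotypeMatrix

HIGH_SIG = "HIGH_SIG"
MODERATE_SIG = "MODERATE_SIG"


def ld_r2(dosages_a: np.ndarray, dosages_b: np.ndarray) -> float:
    """Squared Pearson correlation between two dosage vectors."""
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("LD r2 is undefined for a monomorphic variant")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def find_piv_links(tag: QtlTag, annotations: AnnotationTable,
                   genotypes: GenotypeMatrix, window_bp: int = 1_000_000,
                   r2_min: float = 0.9) -> list[tuple[str, float]]:
    """PIVs within the centred window in high LD with the tag.

    The window is ``window_bp`` centred on the tag (inclusive at both
    half-window edges). Returns (piv vid, r2) pairs, best LD first.
    """
    half = window_bp // 2
    tag_dose = genotypes.vid_column(tag.vid)
    out = []
    for _, row in annotations.piv_table().iterrows():
        vid = row["vid"]
        try:
            j = genotypes.index_of(vid)
        except KeyError:
            continue
        v = genotypes.variants[j]
        if v.chrom != tag.chrom or abs(v.pos - tag.pos) > half:
            continue
        dose = genotypes.dosages[:, j]
        if dose.std() == 0:
            continue
        r2 = ld_r2(tag_dose, dose)
        if r2 > r2_min:
            out.append((vid, r2))
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


def classify_tier(r2: float, neglog10p: float, B: float,
                  ld_scale: str = "r2") -> str | None:
    """Two-tier candidacy call from the LD and significance of a tag-PIV link.

    ``ld_scale`` selects whether the tier bins are read on the squared
    correlation (default, matching the R2 > 0.9 filter) or on |r|.
    """
    if not 0 <= r2 <= 1:
        raise ValueError(f"r2 {r2} outside [0, 1]")
    ld = r2 if ld_scale == "r2" else float(np.sqrt(r2))
    if 0.975 < ld <= 1 and neglog10p > 1.5 * B:
        return HIGH_SIG
    if 0.95 < ld <= 0.975 and neglog10p > 2 * B:
        return HIGH_SIG
    if 0.925 < ld <= 0.95 and neglog10p > 2.5 * B:
        return HIGH_SIG
    if ld > 0.9 and neglog10p > B:
        return MODERATE_SIG
    return None


@dataclass
class CandidateCall:
    trait: str
    tag: QtlTag
    piv_vid: str
    gene: str
    impact: str
    description: str
    r2: float
    neglog10p: float
    tier: str


def link_candidates(tags: list[QtlTag], annotations: AnnotationTable,
                    genotypes: GenotypeMatrix, B: float,
                    window_bp: int = 1_000_000,
                    ld_scale: str = "r2") -> list[CandidateCall]:
    """All tier-classified tag-PIV links for a set of QTL tags."""
    calls: list[CandidateCall] = []
    for tag in tags:
        for vid, r2 in find_piv_links(tag, annotations, genotypes, window_bp):
            tier = classify_tier(r2, tag.neglog10p, B, ld_scale=ld_scale)
            if tier is None:
                continue
            ann = annotations.lookup(vid)
            calls.append(
                CandidateCall(
                    trait=tag.trait, tag=tag, piv_vid=vid,
                    gene=str(ann["gene"]), impact=str(ann["impact"]),
                    description=str(ann["description"]), r2=r2,
                    neglog10p=tag.neglog10p, tier=tier,
                )
            )
    return calls


def candidate_table(calls: list[CandidateCall]) -> pd.DataFrame:
    """Result layout mirroring the candidate-variant report columns."""
    return pd.DataFrame(
        [
            {
                "chrom": c.tag.chrom,
                "pos": c.tag.pos,
                "tag_vid": c.tag.vid,
                "iteration": c.tag.iteration,
                "p": c.tag.p,
                "neglog10p": c.neglog10p,
                "piv_vid": c.piv_vid,
                "ld_r2": c.r2,
                "gene": c.gene,
                "impact": c.impact,
                "description": c.description,
                "tier": c.tier,
                "trait": c.trait,
            }
            for c in calls
        ]
    )
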