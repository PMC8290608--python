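"""Readers and writers for the on-disk artifacts of the pipeline.

Genotypes travel as VCF v4.2 with a per-sample ``DS`` (alternate-allele
dosage) field; everything else — pedigree, test-day phenotypes, variant
annotations, gene expression, result tables — is tab-delimited text.
Coordinates are 1-based and inclusive throughout, matching VCF.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mirqtl")

IMPACT_CLASSES = ("HIGH", "MODERATE", "LOW_SPLICE_REGION", "OTHER")
#: impact classes that make a variant a putative impact variant (PIV)
PIV_IMPACTS = ("HIGH", "MODERATE", "LOW_SPLICE_REGION")

BREEDS = ("HOL", "FR", "JE")
HET_PAIRS = ("FRxJE", "FRxHOL", "JExHOL", "FRxAY", "JExAY", "AYxHOL")
COMPOSITION_TRAITS = ("FP", "LP", "PP")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class VariantRecord:
    """One variant: position, alleles, frequency and imputation quality."""

    chrom: str
    pos: int
    vid: str
    ref: str
    alt: str
    maf: float
    allelic_r2: float = 1.0

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant {self.vid}: pos must be >= 1, got {self.pos}")
        if not 0.0 <= self.maf <= 0.5 + 1e-12:
            raise ValueError(f"variant {self.vid}: maf {self.maf} outside [0, 0.5]")
        if not 0.0 <= self.allelic_r2 <= 1.0 + 1e-12:
            raise ValueError(
                f"variant {self.vid}: allelic_r2 {self.allelic_r2} outside [0, 1]"
            )


def maf_from_dosages(dosages: np.ndarray) -> np.ndarray:
    """Minor-allele frequency per column of an animals x variants dosage matrix."""
    p_alt = np.asarray(dosages, dtype=float).mean(axis=0) / 2.0
    return np.minimum(p_alt, 1.0 - p_alt)


@dataclass
class GenotypeMatrix:
    """Animals x variants alternate-allele dosages with variant metadata."""

    animals: list[str]
    variants: list[VariantRecord]
    dosages: np.ndarray  # shape (n_animals, n_variants), values in [0, 2]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.animals) or m != len(self.variants):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.animals)} animals x {len(self.variants)} variants"
            )
        if self.dosages.size and (
            self.dosages.min() < -1e-9 or self.dosages.max() > 2 + 1e-9
        ):
            raise ValueError("dosages outside [0, 2]")
        vids = [v.vid for v in self.variants]
        if len(set(vids)) != len(vids):
            raise ValueError("variant ids are not unique")
        self._vid_index = {v: i for i, v in enumerate(vids)}
        self._animal_index = {a: i for i, a in enumerate(self.animals)}

    @property
    def n_animals(self) -> int:
        return len(self.animals)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([v.chrom for v in self.variants])

    @property
    def vids(self) -> list[str]:
        return [v.vid for v in self.variants]

    def vid_column(self, vid: str) -> np.ndarray:
        return self.dosages[:, self._vid_index[vid]]

    def index_of(self, vid: str) -> int:
        return self._vid_index[vid]

    def recompute_maf(self) -> np.ndarray:
        return maf_from_dosages(self.dosages)

    def subset_animals(self, animals: Sequence[str]) -> "GenotypeMatrix":
        """Rows restricted to ``animals`` (order preserved); MAF recomputed."""
        idx = [self._animal_index[a] for a in animals]
        dos = self.dosages[idx]
        maf = maf_from_dosages(dos)
        variants = [
            VariantRecord(v.chrom, v.pos, v.vid, v.ref, v.alt, float(m), v.allelic_r2)
            for v, m in zip(self.variants, maf)
        ]
        return GenotypeMatrix(list(animals), variants, dos)

    def subset_variants(self, vids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self._vid_index[v] for v in vids]
        return GenotypeMatrix(
            list(self.animals),
            [self.variants[i] for i in idx],
            self.dosages[:, idx],
        )


@dataclass
class PedigreeTable:
    """Rows of (animal, sire, dam); ``None`` marks an unknown parent.

    Construction validates acyclicity and stores a topological order
    (parents before offspring), which the numerator-relationship recursion
    relies on.
    """

    rows: list[tuple[str, str | None, str | None]]

    def __post_init__(self) -> None:
        seen = set()
        for a, _, _ in self.rows:
            if a in seen:
                raise ValueError(f"duplicate animal row: {a}")
            seen.add(a)
        self.parents = {a: (s, d) for a, s, d in self.rows}
        for a, (s, d) in self.parents.items():
            for p in (s, d):
                if p is not None and p not in self.parents:
                    # tolerated: parent named but never listed -> treated unknown
                    logger.debug("pedigree parent %s of %s has no own row", p, a)
        self.order = self._toposort()

    def _toposort(self) -> list[str]:
        state: dict[str, int] = {}
        order: list[str] = []

        def visit(a: str, stack: list[str]) -> None:
            if state.get(a) == 2:
                return
            if state.get(a) == 1:
                cyc = stack[stack.index(a):] + [a]
                raise ParseError(f"pedigree cycle: {' -> '.join(cyc)}")
            state[a] = 1
            stack.append(a)
            for p in self.parents.get(a, (None, None)):
                if p is not None and p in self.parents:
                    visit(p, stack)
            stack.pop()
            state[a] = 2
            order.append(a)

        for a in self.parents:
            visit(a, [])
        return order

    @property
    def animals(self) -> list[str]:
        return [a for a, _, _ in self.rows]


@dataclass
class AnnotationTable:
    """vid -> (gene, impact class, coding-change description)."""

    table: pd.DataFrame  # columns vid, gene, impact, description

    def __post_init__(self) -> None:
        bad = set(self.table["impact"]) - set(IMPACT_CLASSES)
        if bad:
            raise ValueError(f"unknown impact classes: {sorted(bad)}")
        self.table = self.table.reset_index(drop=True)
        self._by_vid = self.table.set_index("vid", drop=False)

    def lookup(self, vid: str) -> pd.Series | None:
        if vid in self._by_vid.index:
            return self._by_vid.loc[vid]
        return None

    def piv_table(self) -> pd.DataFrame:
        return self.table[self.table["impact"].isin(PIV_IMPACTS)]


@dataclass
class ExpressionMatrix:
    """Animals x genes transformed expression values plus gene coordinates."""

    animals: list[str]
    genes: list[str]
    values: np.ndarray
    gene_positions: pd.DataFrame  # columns gene, chrom, start, end

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if self.values.shape != (len(self.animals), len(self.genes)):
            raise ValueError("expression matrix shape mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene identifiers not unique")
        self._gene_index = {g: i for i, g in enumerate(self.genes)}

    def gene_column(self, gene: str) -> np.ndarray:
        return self.values[:, self._gene_index[gene]]

    def genes_in_window(self, chrom: str, lo: int, hi: int) -> list[str]:
        gp = self.gene_positions
        hit = gp[(gp["chrom"] == chrom) & (gp["end"] >= lo) & (gp["start"] <= hi)]
        return list(hit["gene"])


@dataclass
class TestDayRecord:
    """One milk-test observation: covariates, spectrum, composition traits."""

    __test__ = False  # keep pytest from collecting this dataclass

    animal: str
    parity: int  # raw parity count, >= 1; class is min(parity, 5)
    dim: int  # days in milk, >= 1
    herd_testday: str
    breed_props: np.ndarray  # (HOL, FR, JE)
    het_props: np.ndarray  # six pairs, HET_PAIRS order
    spectrum: np.ndarray
    composition: np.ndarray  # (FP, LP, PP)
    instrument: str = "I1"

    def __post_init__(self) -> None:
        self.breed_props = np.asarray(self.breed_props, dtype=float)
        self.het_props = np.asarray(self.het_props, dtype=float)
        self.spectrum = np.asarray(self.spectrum, dtype=float)
        self.composition = np.asarray(self.composition, dtype=float)
        if self.parity < 1:
            raise ValueError("parity must be >= 1")
        if self.dim < 1:
            raise ValueError("days-in-milk must be >= 1")
        if self.breed_props.sum() > 1 + 1e-9:
            raise ValueError("breed proportions sum > 1")
        if np.any((self.het_props < -1e-12) | (self.het_props > 1 + 1e-12)):
            raise ValueError("heterosis proportions outside [0, 1]")

    @property
    def parity_class(self) -> int:
        return min(self.parity, 5)

    @property
    def dim_class(self) -> int:
        # 9 intervals of 30 days from the start of lactation; overflow capped
        return min(math.ceil(self.dim / 30), 9)


# ---------------------------------------------------------------------------
# VCF

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Load a VCF into a :class:`GenotypeMatrix`.

    A per-sample ``DS`` dosage field takes precedence over hard ``GT``
    calls; MAF is recomputed from the loaded dosages. Allelic R² is taken
    from the ``AR2`` (or ``R2``) INFO key when present, else 1.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    animals = list(vcf.samples)
    if not animals:
        raise ParseError(f"{path}: VCF contains no samples")
    cols: list[np.ndarray] = []
    variants: list[VariantRecord] = []
    for i, rec in enumerate(vcf):
        ds = None
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dose = np.asarray(ds, dtype=float).reshape(len(animals))
        else:
            gts = np.asarray(rec.genotype.array())[:, :2]
            if np.any(gts < 0):
                raise ParseError(
                    f"{path}: missing genotype call at record {i + 1} "
                    f"({rec.CHROM}:{rec.POS}) and no DS field"
                )
            dose = gts.sum(axis=1).astype(float)
        if np.any(dose < -1e-9) or np.any(dose > 2 + 1e-9):
            raise ParseError(
                f"{path}: dosage outside [0,2] at record {i + 1} ({rec.CHROM}:{rec.POS})"
            )
        r2 = rec.INFO.get("AR2", rec.INFO.get("R2", 1.0))
        alt = rec.ALT[0] if rec.ALT else "."
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}"
        p_alt = dose.mean() / 2.0
        variants.append(
            VariantRecord(
                chrom=str(rec.CHROM),
                pos=int(rec.POS),
                vid=vid,
                ref=rec.REF,
                alt=alt,
                maf=float(min(p_alt, 1 - p_alt)),
                allelic_r2=float(r2),
            )
        )
        cols.append(dose)
    dosages = np.column_stack(cols) if cols else np.zeros((len(animals), 0))
    return GenotypeMatrix(animals, variants, dosages)


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF v4.2 with DS dosages (6 decimal places)."""
    path = Path(path)
    chrom_order: list[str] = []
    for v in genotypes.variants:
        if v.chrom not in chrom_order:
            chrom_order.append(v.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mirqtl\n")
        for c in chrom_order:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=AR2,Number=1,Type=Float,Description="Allelic R-squared">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt allele dosage">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.animals)
            + "\n"
        )
        for j, v in enumerate(genotypes.variants):
            ds = "\t".join(f"{d:.6g}" for d in genotypes.dosages[:, j])
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.vid}\t{v.ref}\t{v.alt}\t.\tPASS\t"
                f"AR2={v.allelic_r2:.4g}\tDS\t{ds}\n"
            )


# ---------------------------------------------------------------------------
# Delimited tables

def _spectrum_columns(n: int) -> list[str]:
    return [f"wn_{i:04d}" for i in range(n)]


def phenotypes_to_frame(records: Sequence[TestDayRecord]) -> pd.DataFrame:
    """Flatten records to the canonical phenotype TSV layout."""
    n_wn = len(records[0].spectrum)
    rows = []
    for r in records:
        row: dict[str, object] = {
            "animal": r.animal,
            "parity": r.parity,
            "dim": r.dim,
            "herd_testday": r.herd_testday,
            "instrument": r.instrument,
        }
        for b, p in zip(BREEDS, r.breed_props):
            row[f"brd_{b}"] = p
        for h, p in zip(HET_PAIRS, r.het_props):
            row[f"het_{h}"] = p
        for t, v in zip(COMPOSITION_TRAITS, r.composition):
            row[t] = v
        for c, v in zip(_spectrum_columns(n_wn), r.spectrum):
            row[c] = v
        rows.append(row)
    return pd.DataFrame(rows)


def read_phenotypes(path: str | Path, expected_spectrum_len: int | None = None
                    ) -> list[TestDayRecord]:
    """Read a test-day phenotype table (TSV or CSV) into records."""
    path = Path(path)
    sep = "," if path.suffix == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    required = (
        ["animal", "parity", "dim", "herd_testday"]
        + [f"brd_{b}" for b in BREEDS]
        + [f"het_{h}" for h in HET_PAIRS]
        + list(COMPOSITION_TRAITS)
    )
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing covariate columns {missing}")
    wn_cols = sorted(c for c in df.columns if c.startswith("wn_"))
    if expected_spectrum_len is not None and len(wn_cols) != expected_spectrum_len:
        raise ParseError(
            f"{path}: {len(wn_cols)} spectrum columns, expected {expected_spectrum_len}"
        )
    spec = df[wn_cols].to_numpy()
    if not np.issubdtype(spec.dtype, np.number):
        bad = int(np.where(~df[wn_cols].map(np.isreal))[0][0])
        raise ParseError(f"{path}: non-numeric absorbance at row {bad}")
    records = []
    for i, row in df.iterrows():
        records.append(
            TestDayRecord(
                animal=str(row["animal"]),
                parity=int(row["parity"]),
                dim=int(row["dim"]),
                herd_testday=str(row["herd_testday"]),
                breed_props=np.array([row[f"brd_{b}"] for b in BREEDS], dtype=float),
                het_props=np.array([row[f"het_{h}"] for h in HET_PAIRS], dtype=float),
                spectrum=spec[i],
                composition=np.array(
                    [row[t] for t in COMPOSITION_TRAITS], dtype=float
                ),
                instrument=str(row.get("instrument", "I1")),
            )
        )
    return records


def write_phenotypes(records: Sequence[TestDayRecord], path: str | Path) -> None:
    phenotypes_to_frame(records).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_pedigree(path: str | Path) -> PedigreeTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    rows = []
    for _, r in df.iterrows():
        sire = r["sire"] if r["sire"] not in ("", ".", "0", "NA") else None
        dam = r["dam"] if r["dam"] not in ("", ".", "0", "NA") else None
        rows.append((r["animal"], sire, dam))
    return PedigreeTable(rows)


def write_pedigree(ped: PedigreeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("animal\tsire\tdam\n")
        for a, s, d in ped.rows:
            fh.write(f"{a}\t{s or '.'}\t{d or '.'}\n")


def read_annotations(path: str | Path) -> AnnotationTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    need = {"vid", "gene", "impact", "description"}
    if not need <= set(df.columns):
        raise ParseError(f"{path}: annotation table needs columns {sorted(need)}")
    return AnnotationTable(df[["vid", "gene", "impact", "description"]])


def write_annotations(ann: AnnotationTable, path: str | Path) -> None:
    ann.table.to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path, positions_path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    gp = pd.read_csv(positions_path, sep="\t", dtype={"gene": str, "chrom": str})
    return ExpressionMatrix(
        animals=[str(a) for a in df.index],
        genes=[str(g) for g in df.columns],
        values=df.to_numpy(),
        gene_positions=gp,
    )


def write_expression(expr: ExpressionMatrix, path: str | Path,
                     positions_path: str | Path) -> None:
    pd.DataFrame(expr.values, index=expr.animals, columns=expr.genes).to_csv(
        path, sep="\t", float_format="%.10g"
    )
    expr.gene_positions.to_csv(positions_path, sep="\t", index=False)


def write_results(tables: dict[str, pd.DataFrame], outdir: str | Path,
                  config: dict | None = None, seed: int | None = None) -> dict:
    """Write result tables as TSVs plus a machine-readable run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "tables": {}, "config_hash": None}
    if config is not None:
        blob = json.dumps(config, sort_keys=True, default=str).encode()
        manifest["config_hash"] = hashlib.sha256(blob).hexdigest()
    import mirqtl

    manifest["version"] = mirqtl.__version__
    for name, df in tables.items():
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.10g")
        manifest["tables"][name] = {
            "path": p.name,
            "columns": list(df.columns),
            "n_rows": int(len(df)),
            "sha256": hashlib.sha256(p.read_bytes()).hexdigest(),
        }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
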