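"""Repeated-measures pre-adjustment of test-day phenotypes.

Each trait (wavenumber absorbance or predicted composition) is fitted with

    y = mu + parity + dim-class + herd-by-test-day + breed + heterosis
        + animal + error,

where the animal effect is iid N(0, sigma2_anml) — no pedigree covariance —
and the error iid N(0, sigma2_e). The adjusted phenotype for an animal is
the prediction of its random effect plus the mean of its predicted errors,
which is identically the mean of (y - x'beta) over its records.

Variance components are estimated by REML with the restricted likelihood
profiled down to the single ratio lambda = sigma2_anml / sigma2_e and
maximised by bounded scalar search; the grouped structure of the animal
effect makes each likelihood evaluation closed-form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .dataio import BREEDS, HET_PAIRS, COMPOSITION_TRAITS, TestDayRecord

REML_TOL = 1e-8


class IdentifiabilityError(ValueError):
    pass


@dataclass
class DesignMatrices:
    """Fixed-effect design plus the record-to-animal incidence."""

    X: np.ndarray  # (n_records, p)
    columns: list[str]
    animals: list[str]  # unique animal ids, fit order
    animal_idx: np.ndarray  # per record, index into animals
    _agg: dict = field(default_factory=dict, repr=False)

    def aggregates(self) -> dict:
        """Cache the lambda-independent sufficient statistics."""
        if self._agg:
            return self._agg
        order = np.argsort(self.animal_idx, kind="stable")
        Xs = self.X[order]
        aidx = self.animal_idx[order]
        starts = np.searchsorted(aidx, np.arange(len(self.animals)))
        counts = np.diff(np.append(starts, len(aidx)))
        S = np.add.reduceat(Xs, starts, axis=0)  # per-animal column sums
        group_G = {}
        for n in np.unique(counts):
            rows = S[counts == n]
            group_G[int(n)] = rows.T @ rows
        self._agg = {
            "order": order, "starts": starts, "counts": counts, "S": S,
            "XtX": self.X.T @ self.X, "group_G": group_G,
        }
        return self._agg


def dim_class(dim: int) -> int:
    """30-day days-in-milk interval, 1-based, capped at class 9."""
    return min(math.ceil(dim / 30), 9)


def parity_class(parity: int) -> int:
    return min(parity, 5)


def encode_design(records: list[TestDayRecord]) -> DesignMatrices:
    """Build the Eq.-style fixed-effect design for a set of records.

    Parity (5 classes), DIM class (9) and herd-by-test-day are one-hot with
    the first observed level dropped; breed proportions enter as continuous
    covariates with the first breed absorbed into the intercept; heterosis
    proportions enter as continuous covariates. All-zero columns (e.g.
    heterosis pairs absent from the data) are dropped.
    """
    n = len(records)
    animals: list[str] = []
    amap: dict[str, int] = {}
    aidx = np.empty(n, dtype=np.int64)
    for i, r in enumerate(records):
        if r.animal not in amap:
            amap[r.animal] = len(animals)
            animals.append(r.animal)
        aidx[i] = amap[r.animal]

    def levels(vals):
        out = []
        for v in vals:
            if v not in out:
                out.append(v)
        return out

    par = [parity_class(r.parity) for r in records]
    dimc = [dim_class(r.dim) for r in records]
    htd = [r.herd_testday for r in records]
    par_lv, dim_lv, htd_lv = sorted(set(par)), sorted(set(dimc)), levels(htd)

    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    for lv in par_lv[1:]:
        cols.append(np.array([1.0 if p == lv else 0.0 for p in par]))
        names.append(f"parity_{lv}")
    for lv in dim_lv[1:]:
        cols.append(np.array([1.0 if d == lv else 0.0 for d in dimc]))
        names.append(f"dim_{lv}")
    for lv in htd_lv[1:]:
        cols.append(np.array([1.0 if h == lv else 0.0 for h in htd]))
        names.append(f"htd_{lv}")
    for bi, b in enumerate(BREEDS[1:], start=1):
        cols.append(np.array([r.breed_props[bi] for r in records]))
        names.append(f"brd_{b}")
    for hi, h in enumerate(HET_PAIRS):
        cols.append(np.array([r.het_props[hi] for r in records]))
        names.append(f"het_{h}")

    X = np.column_stack(cols)
    keep = np.abs(X).sum(axis=0) > 0
    return DesignMatrices(
        X=X[:, keep],
        columns=[c for c, k in zip(names, keep) if k],
        animals=animals,
        animal_idx=aidx,
    )


def intercept_only_design(animal_ids: list[str]) -> DesignMatrices:
    """Minimal design (grand mean only) for simulation and oracle work."""
    animals = []
    amap: dict[str, int] = {}
    aidx = np.empty(len(animal_ids), dtype=np.int64)
    for i, a in enumerate(animal_ids):
        if a not in amap:
            amap[a] = len(animals)
            animals.append(a)
        aidx[i] = amap[a]
    return DesignMatrices(
        X=np.ones((len(animal_ids), 1)), columns=["intercept"],
        animals=animals, animal_idx=aidx,
    )


@dataclass
class RepeatedMeasuresFit:
    beta: np.ndarray
    columns: list[str]
    sigma2_anml: float
    sigma2_e: float
    animals: list[str]
    animal_effects: np.ndarray  # BLUP of the animal effect, per animal
    residuals: np.ndarray  # per record, original order
    loglik: float
    converged: bool
    boundary: bool  # sigma2_anml pinned at 0
    degenerate: bool  # y essentially constant
    design: DesignMatrices
    y: np.ndarray  # the trait vector the model was fitted to

    def records_per_animal(self) -> np.ndarray:
        return np.bincount(
            self.design.animal_idx, minlength=len(self.animals)
        ).astype(float)


def _profile_restricted_loglik(lam: float, agg: dict, yterms: dict,
                               n: int) -> tuple[float, dict]:
    counts = agg["counts"]
    w = {int(k): lam / (1 + lam * k) for k in agg["group_G"]}
    XtViX = agg["XtX"].copy()
    XtViy = yterms["Xty"].copy()
    ytViy = yterms["yty"]
    logdetV0 = 0.0
    for k, G in agg["group_G"].items():
        XtViX -= w[k] * G
        XtViy -= w[k] * yterms["group_a"][k]
        ytViy -= w[k] * yterms["group_t2"][k]
        logdetV0 += int((counts == k).sum()) * math.log1p(lam * k)
    evals, evecs = np.linalg.eigh(XtViX)
    tol = max(evals.max(), 1.0) * 1e-12
    pos = evals > tol
    rank = int(pos.sum())
    coef = evecs[:, pos] @ ((evecs[:, pos].T @ XtViy) / evals[pos])
    quad = ytViy - coef @ XtViy
    quad = max(quad, 1e-300)
    df = n - rank
    sigma2_e = quad / df
    ll = -0.5 * (
        df * math.log(sigma2_e) + logdetV0 + float(np.sum(np.log(evals[pos]))) + df
    )
    return ll, {"beta": coef, "sigma2_e": sigma2_e, "rank": rank}


def _profile_score(lam: float, agg: dict, yterms: dict, n: int) -> float:
    """Closed-form d lR / d lambda of the profiled restricted likelihood.

    Root-finding on this analytic score pins the REML ratio to machine
    precision, where a derivative-free search stalls at its noise floor.
    """
    counts = agg["counts"]
    XtViX = agg["XtX"].copy()
    XtViy = yterms["Xty"].copy()
    ytViy = yterms["yty"]
    dM = np.zeros_like(XtViX)
    db = np.zeros_like(XtViy)
    dc = 0.0
    dlogdetV0 = 0.0
    for k, G in agg["group_G"].items():
        w = lam / (1 + lam * k)
        wp = 1.0 / (1 + lam * k) ** 2
        XtViX -= w * G
        XtViy -= w * yterms["group_a"][k]
        ytViy -= w * yterms["group_t2"][k]
        dM -= wp * G
        db -= wp * yterms["group_a"][k]
        dc -= wp * yterms["group_t2"][k]
        cnt = int((counts == k).sum())
        dlogdetV0 += cnt * k / (1 + lam * k)
    evals, evecs = np.linalg.eigh(XtViX)
    tol = max(evals.max(), 1.0) * 1e-12
    pos = evals > tol
    rank = int(pos.sum())
    Up = evecs[:, pos]
    Minv_b = Up @ ((Up.T @ XtViy) / evals[pos])
    quad = max(ytViy - Minv_b @ XtViy, 1e-300)
    df = n - rank
    # d logdet(M) = tr(M^-1 dM)
    dlogdetM = float(np.sum(((Up.T @ dM @ Up) / evals[pos])[
        np.diag_indices(rank)]))
    dquad = dc - 2 * Minv_b @ db + Minv_b @ dM @ Minv_b
    return -0.5 * (df * dquad / quad + dlogdetV0 + dlogdetM)


def reml_fit(design: DesignMatrices, y: np.ndarray) -> RepeatedMeasuresFit:
    """REML fit of the two-variance-component repeated-measures model."""
    y_orig = np.asarray(y, dtype=float)
    n = len(y_orig)
    agg = design.aggregates()
    counts = agg["counts"]
    if int((counts >= 2).sum()) < 2:
        raise IdentifiabilityError(
            "sigma2_anml requires at least 2 animals with at least 2 records"
        )
    degenerate = float(np.var(y_orig)) < 1e-12

    # centring y keeps the sufficient statistics well conditioned and makes
    # the fit exactly invariant to adding a constant to every record
    has_intercept = design.columns and design.columns[0] == "intercept"
    ybar = float(y_orig.mean()) if has_intercept else 0.0
    y = y_orig - ybar

    order = agg["order"]
    ys = y[order]
    t = np.add.reduceat(ys, agg["starts"])  # per-animal sums of y
    S = agg["S"]
    yterms = {
        "Xty": design.X.T @ y,
        "yty": float(y @ y),
        "group_a": {k: S[counts == k].T @ t[counts == k]
                    for k in agg["group_G"]},
        "group_t2": {k: float(np.sum(t[counts == k] ** 2))
                     for k in agg["group_G"]},
    }

    # locate a sign change of the analytic score on a log-spaced grid, then
    # pin the root by Brent's method; no sign change means a boundary optimum
    thetas = np.linspace(math.log(1e-8), math.log(1e4), 28)
    scores = [_profile_score(math.exp(t), agg, yterms, n) for t in thetas]
    bracket = None
    for i in range(len(thetas) - 1):
        if scores[i] > 0 >= scores[i + 1]:
            bracket = (thetas[i], thetas[i + 1])
            break
    converged = True
    if bracket is None:
        lam_hat = 0.0 if scores[0] <= 0 else math.exp(thetas[-1])
        converged = scores[0] <= 0  # a ratio at the upper bound is suspect
    else:
        theta_hat = optimize.brentq(
            lambda t: _profile_score(math.exp(t), agg, yterms, n),
            *bracket, xtol=1e-12, rtol=8.9e-16,
        )
        lam_hat = math.exp(theta_hat)
    ll_hat, parts = _profile_restricted_loglik(max(lam_hat, 1e-300), agg,
                                               yterms, n)
    ll0, parts0 = _profile_restricted_loglik(1e-300, agg, yterms, n)
    boundary = False
    if lam_hat == 0.0 or ll0 >= ll_hat:
        lam_hat, ll_hat, parts = 0.0, ll0, parts0
        boundary = True

    beta = parts["beta"].copy()
    sigma2_e = parts["sigma2_e"]
    sigma2_anml = lam_hat * sigma2_e
    if has_intercept:
        beta[0] += ybar

    r = y_orig - design.X @ beta
    rs = r[order]
    s_r = np.add.reduceat(rs, agg["starts"])
    ahat = lam_hat * s_r / (1 + lam_hat * counts)
    resid = r - ahat[design.animal_idx]
    return RepeatedMeasuresFit(
        beta=beta,
        columns=design.columns,
        sigma2_anml=float(sigma2_anml),
        sigma2_e=float(sigma2_e),
        animals=design.animals,
        animal_effects=ahat,
        residuals=resid,
        loglik=float(ll_hat),
        converged=bool(converged),
        boundary=boundary,
        degenerate=degenerate,
        design=design,
        y=y_orig,
    )


def adjust(fit: RepeatedMeasuresFit) -> pd.DataFrame:
    """Adjusted phenotypes: BLUP of the animal effect + mean residual.

    The same quantity is recomputed directly as mean_j(y_ij - x_ij' beta)
    per animal; the two computations are asserted to agree to 1e-9.
    """
    design = fit.design
    aidx = design.animal_idx
    n_animals = len(fit.animals)
    n_rec = fit.records_per_animal()
    mean_resid = np.bincount(aidx, weights=fit.residuals, minlength=n_animals) / n_rec
    adjusted = fit.animal_effects + mean_resid

    r = fit.y - design.X @ fit.beta
    direct = np.bincount(aidx, weights=r, minlength=n_animals) / n_rec
    if np.max(np.abs(direct - adjusted)) > 1e-9:
        raise AssertionError(
            "adjusted-phenotype identity violated: "
            f"max diff {np.max(np.abs(direct - adjusted)):.3g}"
        )
    return pd.DataFrame(
        {
            "animal": fit.animals,
            "adjusted": adjusted,
            "n_records": n_rec.astype(int),
        }
    )


def adjust_traits(records: list[TestDayRecord],
                  traits: list[str] | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit and adjust every requested trait; one row per animal.

    ``traits`` may mix composition names (FP, LP, PP) and spectrum columns
    (``wn_0000`` style); default is all composition traits plus every
    wavenumber. Returns (adjusted wide table, variance-component table).
    """
    design = encode_design(records)
    n_wn = len(records[0].spectrum)
    if traits is None:
        traits = list(COMPOSITION_TRAITS) + [f"wn_{i:04d}" for i in range(n_wn)]
    out = {"animal": design.animals}
    vc_rows = []
    for t in traits:
        if t in COMPOSITION_TRAITS:
            j = COMPOSITION_TRAITS.index(t)
            y = np.array([r.composition[j] for r in records])
        elif t.startswith("wn_"):
            j = int(t[3:])
            y = np.array([r.spectrum[j] for r in records])
        else:
            raise KeyError(f"unknown trait {t!r}")
        fit = reml_fit(design, y)
        table = adjust(fit)
        out[t] = table["adjusted"].to_numpy()
        vc_rows.append(
            {
                "trait": t,
                "sigma2_anml": fit.sigma2_anml,
                "sigma2_e": fit.sigma2_e,
                "boundary": fit.boundary,
                "degenerate": fit.degenerate,
            }
        )
    return pd.DataFrame(out), pd.DataFrame(vc_rows)
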