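"""Least-squares genome scans on line-origin predictors.

Single-locus scans regress the trait on additive/dominance coefficients
derived from origin probabilities; two-locus scans test the 4-df epistasis
block; genome-wide significance comes from permutation of trait values
(maximum-statistic distribution, empirical type-7 quantiles).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .cross_data import CrossData
from .line_origin import OriginProbTable

F_CAP = 1e12  # sentinel for perfect fits (RSS1 == 0)
_RANK_TOL = 1e-9


# ---------------------------------------------------------------------------
# predictors
# ---------------------------------------------------------------------------


@dataclass
class ChromPredictors:
    positions: np.ndarray
    a: np.ndarray               # (n, P) additive coefficient (F2) or x (BC)
    d: Optional[np.ndarray]     # (n, P) dominance coefficient; None for BC


@dataclass
class GeneticPredictors:
    individuals: list[str]
    cross_type: str
    chromosomes: dict[str, ChromPredictors]
    kinds: dict[str, str]

    def at(self, chromosome: str, position: float) -> tuple[np.ndarray, Optional[np.ndarray]]:
        cp = self.chromosomes[chromosome]
        i = int(np.argmin(np.abs(cp.positions - position)))
        if abs(cp.positions[i] - position) > 1e-6:
            raise KeyError(f"position {position} not on predictor grid")
        return cp.a[:, i], None if cp.d is None else cp.d[:, i]


def genetic_predictors(probs: OriginProbTable, cross: Optional[CrossData] = None) -> GeneticPredictors:
    """Map origin probabilities to regression coefficients.

    F2: a = P(AA) - P(BB), d = P(AB) + P(BA).
    BC: x = P(heterozygous line-origin) - P(homozygous), relative to the
    backcross line of each individual.
    """
    kinds = {}
    if cross is not None:
        kinds = {c.name: c.kind for c in cross.gmap.chromosomes}
    chroms: dict[str, ChromPredictors] = {}
    for name, cp in probs.chromosomes.items():
        if probs.cross_type == "F2":
            a = cp.probs[:, :, 0] - cp.probs[:, :, 3]
            d = cp.probs[:, :, 1] + cp.probs[:, :, 2]
        elif probs.cross_type == "BC":
            if probs.bc_lines is None:
                raise ValueError("BC probability table lacks backcross-line labels")
            # state index of the backcross line per individual
            same = np.array([0 if ln == "A" else 1 for ln in probs.bc_lines])
            p_hom = np.take_along_axis(cp.probs, same[:, None, None], axis=2)[:, :, 0]
            a = (1.0 - p_hom) - p_hom
            d = None
        else:
            raise ValueError(f"unknown cross type {probs.cross_type}")
        chroms[name] = ChromPredictors(positions=cp.positions, a=a, d=d)
    return GeneticPredictors(individuals=list(probs.individuals), cross_type=probs.cross_type,
                             chromosomes=chroms, kinds=kinds)


# ---------------------------------------------------------------------------
# design helpers
# ---------------------------------------------------------------------------


def build_design(cross: CrossData, trait: str, covariates: Sequence[str],
                 ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Trait vector and null (intercept + covariates) design for ``ids`` with
    complete data; listwise deletion of missing trait/covariate values."""
    ph = cross.phenotypes
    if trait not in ph.columns:
        raise KeyError(f"unknown trait {trait!r}")
    cols = [trait] + list(covariates)
    sub = ph.loc[[i for i in ids if i in ph.index], cols].dropna()
    kept = [str(i) for i in sub.index]
    y = sub[trait].to_numpy(dtype=float)
    parts = [np.ones((len(sub), 1))]
    for c in covariates:
        col = sub[c]
        if pd.api.types.is_numeric_dtype(col):
            parts.append(col.to_numpy(dtype=float)[:, None])
        else:  # categorical fixed effect -> dummy coding, first level dropped
            dummies = pd.get_dummies(col, drop_first=True)
            parts.append(dummies.to_numpy(dtype=float))
    X0 = np.hstack(parts)
    return y, X0, kept


def _qr_rss(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, int]:
    """Residual sums of squares of Y's columns after projecting on X; rank-aware."""
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    keep = diag > _RANK_TOL * max(diag.max(), 1.0)
    rank = int(keep.sum())
    if rank < X.shape[1]:
        # re-orthogonalize on the independent columns only
        q, _ = np.linalg.qr(X[:, _independent_columns(X)])
    qty = q.T @ Y
    rss = np.einsum("ij,ij->j", Y, Y) - np.einsum("ij,ij->j", qty, qty)
    return np.maximum(rss, 0.0), rank


def _independent_columns(X: np.ndarray) -> list[int]:
    cols: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, cols + [j]]
        if np.linalg.matrix_rank(cand, tol=_RANK_TOL * max(1.0, np.abs(X).max())) > len(cols):
            cols.append(j)
    return cols


# ---------------------------------------------------------------------------
# single-locus scan
# ---------------------------------------------------------------------------


@dataclass
class ScanProfile:
    """Per-position F statistics and effect estimates of a genome scan."""

    table: pd.DataFrame
    trait: str
    covariates: tuple[str, ...]
    individuals: list[str]

    def argmax(self) -> tuple[str, float, float]:
        row = self.table.loc[self.table["F"].idxmax()]
        return str(row["chromosome"]), float(row["position"]), float(row["F"])


def _position_ids(cross: CrossData, predictors: GeneticPredictors, chrom: str,
                  analyzed: list[str]) -> list[str]:
    if predictors.kinds.get(chrom) == "sex":
        return cross.homogametic_ids(analyzed)
    return analyzed


def scan_one(cross: CrossData, predictors: GeneticPredictors, trait: str,
             covariates: Sequence[str] = ()) -> ScanProfile:
    """Single-locus least-squares scan over the predictor grid.

    At each position fits ``y = mu + covariates + a*alpha + d*delta + e`` and
    reports the F statistic against the covariates-only null (q = 2 for F2,
    1 for BC).  Sex-chromosome positions use homogametic individuals only.
    Rank-deficient positions drop collinear columns with df adjustment
    (flag column); perfect fits are capped at ``F_CAP``.
    """
    y_all, X0_all, ids = build_design(cross, trait, covariates, predictors.individuals)
    rows_all = {iid: predictors.individuals.index(iid) for iid in ids}
    records = []
    for chrom, cp in predictors.chromosomes.items():
        sub_ids = _position_ids(cross, predictors, chrom, ids)
        sel = np.array([ids.index(i) for i in sub_ids], dtype=int)
        y = y_all[sel]
        X0 = X0_all[sel]
        rows = np.array([rows_all[i] for i in sub_ids], dtype=int)
        if len(sub_ids) == 0:
            continue
        rss0, rank0 = _qr_rss(X0, y[:, None])
        for pi, pos in enumerate(cp.positions):
            a = cp.a[rows, pi]
            cols = [a[:, None]]
            if cp.d is not None:
                cols.append(cp.d[rows, pi][:, None])
            X1 = np.hstack([X0] + cols)
            rec = _fit_position(y, X0, X1, rss0[0], rank0, cp.d is not None)
            rec.update(chromosome=chrom, position=float(pos))
            records.append(rec)
    cols_order = ["chromosome", "position", "F", "df1", "df2", "alpha", "se_alpha",
                  "delta", "se_delta", "resid_var", "flag"]
    return ScanProfile(table=pd.DataFrame.from_records(records)[cols_order],
                       trait=trait, covariates=tuple(covariates), individuals=ids)


def _fit_position(y: np.ndarray, X0: np.ndarray, X1: np.ndarray, rss0: float,
                  rank0: int, has_d: bool) -> dict:
    n = len(y)
    keep = _independent_columns(X1)
    Xk = X1[:, keep]
    beta, _, _, _ = np.linalg.lstsq(Xk, y, rcond=None)
    resid = y - Xk @ beta
    rss1 = float(resid @ resid)
    rank1 = Xk.shape[1]
    q = rank1 - rank0
    df2 = n - rank1
    flag = ""
    if rank1 < X1.shape[1]:
        flag = "columns_dropped"
    p_extra = X1.shape[1] - X0.shape[1]
    # positions of the genetic columns inside the kept set
    est = {"alpha": np.nan, "se_alpha": np.nan, "delta": np.nan, "se_delta": np.nan}
    resid_var = rss1 / df2 if df2 > 0 else np.nan
    if df2 > 0 and rss1 > 0:
        xtx_inv = np.linalg.pinv(Xk.T @ Xk)
        se = np.sqrt(np.maximum(np.diag(xtx_inv), 0.0) * resid_var)
    else:
        se = np.full(rank1, np.nan)
    names = (["alpha", "delta"] if has_d else ["alpha"])
    for off, nm in enumerate(names):
        j_full = X0.shape[1] + off
        if j_full in keep:
            j = keep.index(j_full)
            est[nm] = float(beta[j])
            est["se_" + nm] = float(se[j])
    tss = float(y @ y)
    if q <= 0 or df2 <= 0:
        F = 0.0
        flag = flag or "no_test"
    elif rss1 <= 1e-12 * max(tss, 1.0):
        F = F_CAP
        flag = "perfect_fit"
    else:
        F = ((rss0 - rss1) / q) / (rss1 / df2)
        F = max(F, 0.0)
    return {"F": F, "df1": q, "df2": df2, "resid_var": resid_var, "flag": flag, **est}


# ---------------------------------------------------------------------------
# two-locus epistasis scan
# ---------------------------------------------------------------------------


@dataclass
class EpistasisScan:
    table: pd.DataFrame
    trait: str
    covariates: tuple[str, ...]
    pair_step_cM: float

    def argmax(self) -> pd.Series:
        return self.table.loc[self.table["F"].idxmax()]


def _pair_grid(positions: np.ndarray, pair_step: float) -> np.ndarray:
    """Indices of grid positions closest to multiples of the pair step."""
    targets = np.arange(0.0, positions[-1] + pair_step / 2, pair_step)
    idx = np.unique([int(np.argmin(np.abs(positions - t))) for t in targets])
    return idx


def scan_two_epistasis(cross: CrossData, predictors: GeneticPredictors, trait: str,
                       covariates: Sequence[str] = (), pair_step_cM: float = 5.0,
                       min_sep_cM: float = 20.0) -> EpistasisScan:
    """Two-locus scan testing the epistasis block (aa, ad, da, dd) with a 4-df
    F test against the two-locus additive+dominance model (1 df for BC).

    Pairs closer than ``min_sep_cM`` on the same chromosome are excluded
    (collinearity guard).
    """
    y, X0, ids = build_design(cross, trait, covariates, predictors.individuals)
    rows = np.array([predictors.individuals.index(i) for i in ids], dtype=int)
    loci = []
    for chrom, cp in predictors.chromosomes.items():
        if predictors.kinds.get(chrom) == "sex":
            continue  # pair scan on autosomes
        for pi in _pair_grid(cp.positions, pair_step_cM):
            a = cp.a[rows, pi]
            d = cp.d[rows, pi] if cp.d is not None else None
            loci.append((chrom, float(cp.positions[pi]), a, d))
    records = []
    for i in range(len(loci)):
        c1, p1, a1, d1 = loci[i]
        for j in range(i + 1, len(loci)):
            c2, p2, a2, d2 = loci[j]
            if c1 == c2 and abs(p1 - p2) < min_sep_cM:
                continue
            main = [a1[:, None]] + ([d1[:, None]] if d1 is not None else []) \
                 + [a2[:, None]] + ([d2[:, None]] if d2 is not None else [])
            Xm = np.hstack([X0] + main)
            if d1 is not None:
                inter = np.column_stack([a1 * a2, a1 * d2, d1 * a2, d1 * d2])
                inames = ["aa", "ad", "da", "dd"]
            else:
                inter = (a1 * a2)[:, None]
                inames = ["aa"]
            Xf = np.hstack([Xm, inter])
            rec = _epistasis_fit(y, Xm, Xf, inames)
            rec.update(chrom1=c1, pos1=p1, chrom2=c2, pos2=p2)
            records.append(rec)
    cols = ["chrom1", "pos1", "chrom2", "pos2", "F", "df1", "df2", "aa", "ad", "da", "dd", "flag"]
    table = pd.DataFrame.from_records(records)
    for c in cols:
        if c not in table.columns:
            table[c] = np.nan
    return EpistasisScan(table=table[cols], trait=trait, covariates=tuple(covariates),
                         pair_step_cM=pair_step_cM)


def _epistasis_fit(y: np.ndarray, Xm: np.ndarray, Xf: np.ndarray,
                   inames: list[str]) -> dict:
    n = len(y)
    rss0, rank0 = _qr_rss(Xm, y[:, None])
    keep = _independent_columns(Xf)
    Xk = Xf[:, keep]
    beta, _, _, _ = np.linalg.lstsq(Xk, y, rcond=None)
    resid = y - Xk @ beta
    rss1 = float(resid @ resid)
    rank1 = Xk.shape[1]
    q = rank1 - rank0
    df2 = n - rank1
    est = {nm: np.nan for nm in ("aa", "ad", "da", "dd")}
    for off, nm in enumerate(inames):
        j_full = Xm.shape[1] + off
        if j_full in keep:
            est[nm] = float(beta[keep.index(j_full)])
    flag = "columns_dropped" if rank1 < Xf.shape[1] else ""
    if q <= 0 or df2 <= 0:
        F = 0.0
        flag = flag or "no_test"
    elif rss1 <= 1e-12 * max(float(y @ y), 1.0):
        F = F_CAP
        flag = "perfect_fit"
    else:
        F = max(((rss0[0] - rss1) / q) / (rss1 / df2), 0.0)
    return {"F": F, "df1": q, "df2": df2, "flag": flag, **est}


# ---------------------------------------------------------------------------
# permutation thresholds
# ---------------------------------------------------------------------------


@dataclass
class PermutationDistribution:
    max_stats: np.ndarray
    thresholds: dict[float, float]
    n_perm: int
    seed: int

    def threshold(self, q: float) -> float:
        return self.thresholds[q]


def max_stat_scan_one(cross: CrossData, predictors: GeneticPredictors, trait: str,
                      covariates: Sequence[str] = (),
                      Y: Optional[np.ndarray] = None) -> np.ndarray:
    """Genome-wide maximum scan_one F statistic for each column of ``Y``
    (defaults to the observed trait).  Vectorized over permutations."""
    y, X0, ids = build_design(cross, trait, covariates, predictors.individuals)
    if Y is None:
        Y = y[:, None]
    rows_all = {iid: predictors.individuals.index(iid) for iid in ids}
    best = np.zeros(Y.shape[1])
    for chrom, cp in predictors.chromosomes.items():
        sub_ids = _position_ids(cross, predictors, chrom, ids)
        sel = np.array([ids.index(i) for i in sub_ids], dtype=int)
        if len(sel) == 0:
            continue
        Ys = Y[sel]
        X0s = X0[sel]
        rows = np.array([rows_all[i] for i in sub_ids], dtype=int)
        rss0, rank0 = _qr_rss(X0s, Ys)
        n = len(sel)
        for pi in range(len(cp.positions)):
            cols = [cp.a[rows, pi][:, None]]
            if cp.d is not None:
                cols.append(cp.d[rows, pi][:, None])
            X1 = np.hstack([X0s] + cols)
            rss1, rank1 = _qr_rss(X1, Ys)
            q = rank1 - rank0
            df2 = n - rank1
            if q <= 0 or df2 <= 0:
                continue
            with np.errstate(divide="ignore", invalid="ignore"):
                F = ((rss0 - rss1) / q) / (rss1 / df2)
            F = np.where(rss1 <= 1e-12 * np.maximum(np.einsum("ij,ij->j", Ys, Ys), 1.0),
                         F_CAP, F)
            best = np.maximum(best, np.nan_to_num(F, nan=0.0))
    return best


def permutation_thresholds(cross: CrossData, predictors: GeneticPredictors, trait: str,
                           covariates: Sequence[str] = (), n_perm: int = 1000,
                           quantiles: Sequence[float] = (0.95, 0.99), seed: int = 0,
                           max_stat_fn: Optional[Callable[[np.ndarray], np.ndarray]] = None,
                           ) -> PermutationDistribution:
    """Churchill-Doerge genome-wide thresholds by trait permutation.

    Trait values are permuted across the analyzed individuals (predictors
    fixed); the genome-wide maximum statistic is recorded per permutation and
    thresholds are empirical type-7 quantiles.  Deterministic given ``seed``.
    ``max_stat_fn`` may replace the default single-locus scan (it receives the
    permuted trait matrix, one permutation per column).
    """
    for q in quantiles:
        if not 0.0 < q < 1.0:
            raise ValueError(f"quantile {q} outside (0, 1)")
    y, _, _ = build_design(cross, trait, covariates, predictors.individuals)
    rng = np.random.default_rng(seed)
    Y = np.column_stack([rng.permutation(y) for _ in range(n_perm)])
    if max_stat_fn is None:
        stats = max_stat_scan_one(cross, predictors, trait, covariates, Y=Y)
    else:
        stats = np.asarray(max_stat_fn(Y), dtype=float)
    thresholds = {float(q): float(np.quantile(stats, q)) for q in quantiles}
    return PermutationDistribution(max_stats=stats, thresholds=thresholds,
                                   n_perm=n_perm, seed=seed)


def plot_profile(profile: ScanProfile, path: str,
                 thresholds: Optional[dict[float, float]] = None) -> None:
    """Write a genome-scan profile plot (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    offset = 0.0
    for chrom, grp in profile.table.groupby("chromosome", sort=False):
        ax.plot(grp["position"] + offset, grp["F"], label=str(chrom))
        offset += grp["position"].max() + 5.0
    if thresholds:
        for q, thr in thresholds.items():
            ax.axhline(thr, ls="--", lw=0.8, color="grey")
    ax.set_xlabel("position (cM)")
    ax.set_ylabel("F")
    ax.set_title(f"{profile.trait} scan")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
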