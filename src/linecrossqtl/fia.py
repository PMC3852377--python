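"""Flexible intercross analysis: Monte-Carlo IBD matrices, a one-component
variance model, a score-statistic genome scan with permutation thresholds,
and the fixed-vs-segregating comparison.

The locus IBD matrix is estimated by sampling, per Monte-Carlo iteration,
(i) each offspring's line-origin state at the position from its HMM
posterior, (ii) each F1 homolog's F0-grandparental segregation indicator from
a 2-state Haldane chain conditioned on F0/F1 marker genotypes, then
propagating unique founder-homolog labels and counting allele-pair sharing.
Indicator draws are shared across siblings within an iteration, which is what
creates the IBD correlation the variance model exploits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import orth
from scipy.optimize import minimize_scalar

from .cross_data import GEN_F1, CrossData
from .line_origin import (
    LineFreqs,
    OriginProbTable,
    _block_marginals,
    _build_blocks,
    _grid_positions,
    _line_parents,
    _merge_loci,
    _transmission_dist,
    estimate_line_freqs,
    infer_f1_homolog_dists,
    line_origin_probs,
)
from .ls_scan import PermutationDistribution, build_design
from .sim_cross import TruthRecord, haldane_r


# ---------------------------------------------------------------------------
# Monte-Carlo IBD matrices
# ---------------------------------------------------------------------------


@dataclass
class IBDMatrix:
    """Locus-specific additive relationship matrix (diagonal 1 + F)."""

    matrix: np.ndarray          # (n, n), PSD after repair
    raw: np.ndarray             # pre-repair Monte-Carlo average
    mc_se: np.ndarray           # entry-wise Monte-Carlo standard errors
    individuals: list[str]
    chromosome: str
    position: float
    n_samples: int
    seed: int


def _marginals_at(cross: CrossData, chromosome: str, position: float,
                  error_rate: float) -> tuple[list[str], np.ndarray, LineFreqs, object]:
    """HMM posterior state marginals for all offspring at one position."""
    chrom = cross.gmap.chromosome(chromosome)
    if not (-1e-9 <= position <= chrom.length + 1e-9):
        raise ValueError(f"position {position} off chromosome {chromosome}")
    if chrom.kind == "sex":
        raise NotImplementedError("IBD matrices on the sex chromosome are not supported")
    freqs = estimate_line_freqs(cross)
    hd = infer_f1_homolog_dists(cross, freqs)
    ids = cross.offspring_ids
    loci, _, marker_at = _merge_loci(chrom, np.array([float(position)]))
    pos_idx = int(np.searchsorted(loci, round(float(position), 9)))
    S = 4 if cross.cross_type == "F2" else 2
    marg = np.empty((len(ids), S))
    blocks = _build_blocks(cross, freqs, hd, chrom, ids, loci, marker_at, error_rate)
    for blk in blocks:
        m = _block_marginals(blk, loci)
        marg[blk.idx] = m[:, pos_idx, :]
    return ids, marg, freqs, hd


def _indicator_marginal(loci: np.ndarray, em: np.ndarray, pos_idx: int) -> float:
    """P(indicator = homolog 1 at the query locus) of a 2-state Haldane chain."""
    L = len(loci)
    a = np.full(2, 0.5) * em[0]
    a /= a.sum()
    alphas = [a]
    for t in range(1, L):
        r = haldane_r(loci[t] - loci[t - 1])
        T = np.array([[1 - r, r], [r, 1 - r]])
        a = (a @ T) * em[t]
        s = a.sum()
        a = a / s if s > 0 else np.full(2, 0.5)
        alphas.append(a)
    b = np.ones(2)
    for t in range(L - 1, pos_idx, -1):
        r = haldane_r(loci[t] - loci[t - 1])
        T = np.array([[1 - r, r], [r, 1 - r]])
        b = T @ (em[t] * b)
        m = b.max()
        if m > 0:
            b = b / m
    p = alphas[pos_idx] * b
    s = p.sum()
    return float(p[1] / s) if s > 0 else 0.5


def _f1_indicator_probs(cross: CrossData, freqs: LineFreqs, chromosome: str,
                        position: float, error_rate: float) -> dict[tuple[str, str], float]:
    """For every F1 and line, P(its line homolog descends from the F0 parent's
    second recorded allele) at the position."""
    chrom = cross.gmap.chromosome(chromosome)
    loci, _, marker_at = _merge_loci(chrom, np.array([float(position)]))
    pos_idx = int(np.searchsorted(loci, round(float(position), 9)))
    out: dict[tuple[str, str], float] = {}
    for f1 in cross.f1_ids:
        parents = _line_parents(cross, f1)
        for line in ("A", "B"):
            other = "B" if line == "A" else "A"
            p0 = parents[line]
            em = np.ones((len(loci), 2))
            for li, marker in marker_at.items():
                g0 = cross.genotype(p0, marker) if p0 is not None else None
                gf1 = cross.genotype(f1, marker)
                if g0 is None or gf1 is None or g0[0] == g0[1]:
                    continue
                t_other = _transmission_dist(cross, freqs, parents[other], marker, other)
                u = freqs.universe[marker]
                e = np.zeros(2)
                for k in (0, 1):
                    for yi, y in enumerate(u):
                        pair = (g0[k], int(y)) if g0[k] <= y else (int(y), g0[k])
                        if pair == gf1:
                            e[k] += t_other[yi]
                g_count = len(u) * (len(u) + 1) / 2.0
                em[li] = (1.0 - error_rate) * e + error_rate / g_count
            out[(f1, line)] = _indicator_marginal(loci, em, pos_idx)
    return out


def mcibd_matrix(cross: CrossData, chromosome: str, position: float,
                 n_samples: int = 200, seed: int = 0,
                 ids: Optional[Sequence[str]] = None,
                 error_rate: float = 0.001) -> IBDMatrix:
    """Monte-Carlo estimate of the locus IBD matrix.

    Pi_ij is half the expected number of IBD pairs among the four allele
    pairs of individuals i and j; founders are assumed unrelated and
    non-inbred (globally unique homolog labels).  The returned matrix is
    symmetrized and eigenvalue-clipped to be PSD; the raw average and
    entry-wise MC standard errors are kept for diagnostics.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    all_ids, marg, freqs, hd = _marginals_at(cross, chromosome, position, error_rate)
    if ids is None:
        ids = all_ids
    ids = list(ids)
    rows = [all_ids.index(i) for i in ids]
    n = len(ids)
    rng = np.random.default_rng(seed)

    ind_probs = _f1_indicator_probs(cross, freqs, chromosome, position, error_rate)

    # founder homolog labels keyed by (founder id, recorded allele slot)
    founder_ids = cross.founder_ids
    lab = {}
    for k, fid in enumerate(founder_ids):
        lab[(fid, 0)] = 2 * k
        lab[(fid, 1)] = 2 * k + 1
    K = 2 * len(founder_ids)

    # per analyzed offspring: the F1 parent(s) and, for BC, the F0 parent
    is_f2 = cross.cross_type == "F2"
    parent_info = []
    for iid in ids:
        ind = cross.individual(iid)
        if is_f2:
            parent_info.append((ind.sire, ind.dam))
        else:
            f1p, f0p = ind.sire, ind.dam
            if f1p is None or cross.individual(f1p).generation != GEN_F1:
                f1p, f0p = ind.dam, ind.sire
            parent_info.append((f1p, f0p))

    # sample indicators: for every (F1, line) a (n_samples,) 0/1 array
    f1_lines = sorted({(p, ln) for pi in parent_info for p in (pi if is_f2 else pi[:1])
                       if p is not None for ln in ("A", "B")})
    ind_draws = {key: (rng.random(n_samples) < ind_probs.get(key, 0.5)).astype(int)
                 for key in f1_lines}

    # per-offspring state draws from the posterior marginal at the position
    pm = marg[rows]
    cum = np.cumsum(pm, axis=1)
    u = rng.random((n, n_samples)) * cum[:, -1:]
    state = (u[:, :, None] > cum[:, None, :]).sum(axis=2)   # (n, n_samples)

    # BC: indicator for the F0 parent's own meiosis, per offspring
    bc_draws = None
    if not is_f2:
        bc_draws = np.zeros((n, n_samples), dtype=int)
        chrom = cross.gmap.chromosome(chromosome)
        loci, _, marker_at = _merge_loci(chrom, np.array([float(position)]))
        pos_idx = int(np.searchsorted(loci, round(float(position), 9)))
        for oi, iid in enumerate(ids):
            f1p, f0p = parent_info[oi]
            em = np.ones((len(loci), 2))
            for li, marker in marker_at.items():
                g0 = cross.genotype(f0p, marker) if f0p is not None else None
                go = cross.genotype(iid, marker)
                if g0 is None or go is None or g0[0] == g0[1]:
                    continue
                u_m = freqs.universe[marker]
                hrow = hd.dists.get(f1p, {}).get(marker)
                t_f1 = hrow.mean(axis=0) if hrow is not None else np.full(len(u_m), 1 / len(u_m))
                e = np.zeros(2)
                for k in (0, 1):
                    for yi, y in enumerate(u_m):
                        pair = (g0[k], int(y)) if g0[k] <= y else (int(y), g0[k])
                        if pair == go:
                            e[k] += t_f1[yi]
                g_count = len(u_m) * (len(u_m) + 1) / 2.0
                em[li] = (1.0 - error_rate) * e + error_rate / g_count
            p1 = _indicator_marginal(loci, em, pos_idx)
            bc_draws[oi] = (rng.random(n_samples) < p1).astype(int)

    # resolve founder-homolog labels (vectorized over offspring and samples);
    # label index K is a dummy slot for unresolvable gametes
    def f0_of(f1_id: Optional[str], line: str) -> Optional[str]:
        if f1_id is None:
            return None
        return _line_parents(cross, f1_id)[line]

    def base_and_draws(parent: Optional[str]) -> tuple[np.ndarray, np.ndarray]:
        """Per line: label base of the grandparental F0, and indicator draws."""
        bases = np.full(2, K, dtype=int)
        draws = np.zeros((2, n_samples), dtype=int)
        for gi, line in enumerate("AB"):
            f0 = f0_of(parent, line)
            if f0 is not None:
                bases[gi] = lab[(f0, 0)]
                draws[gi] = ind_draws[(parent, line)]
        return bases, draws

    label_pat = np.full((n, n_samples), K, dtype=int)
    label_mat = np.full((n, n_samples), K, dtype=int)
    for oi, iid in enumerate(ids):
        if is_f2:
            sp, sm = state[oi] // 2, state[oi] % 2
            for labels, parent, g in ((label_pat, parent_info[oi][0], sp),
                                      (label_mat, parent_info[oi][1], sm)):
                bases, draws = base_and_draws(parent)
                cand = bases[:, None] + np.where(bases[:, None] < K, draws, 0)
                labels[oi] = np.take_along_axis(cand, g[None, :], axis=0)[0]
        else:
            f1p, f0p = parent_info[oi]
            bases, draws = base_and_draws(f1p)
            cand = bases[:, None] + np.where(bases[:, None] < K, draws, 0)
            label_pat[oi] = np.take_along_axis(cand, state[oi][None, :], axis=0)[0]
            if f0p is not None:
                label_mat[oi] = lab[(f0p, 0)] + bc_draws[oi]

    acc = np.zeros((n, n))
    acc2 = np.zeros((n, n))
    o_idx = np.arange(n)
    chunk = max(1, int(2_000_000 // (n * n) + 1))
    for s0 in range(0, n_samples, chunk):
        s1 = min(s0 + chunk, n_samples)
        ns = s1 - s0
        A = np.zeros((ns, n, K + 1))
        for labels in (label_pat, label_mat):
            flat = ((np.arange(ns)[:, None] * n + o_idx[None, :]) * (K + 1)
                    + labels[:, s0:s1].T)
            A += np.bincount(flat.ravel(), minlength=ns * n * (K + 1)) \
                .reshape(ns, n, K + 1)
        A[:, :, K] = 0.0
        Pi_s = 0.5 * np.einsum("sik,sjk->sij", A, A)
        acc += Pi_s.sum(axis=0)
        acc2 += (Pi_s ** 2).sum(axis=0)
    raw = acc / n_samples
    var = np.maximum(acc2 / n_samples - raw ** 2, 0.0)
    mc_se = np.sqrt(var / n_samples)
    mat = psd_repair(0.5 * (raw + raw.T))
    return IBDMatrix(matrix=mat, raw=raw, mc_se=mc_se, individuals=ids,
                     chromosome=chromosome, position=float(position),
                     n_samples=n_samples, seed=seed)


def psd_repair(mat: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues at zero (matrix stays symmetric)."""
    w, v = np.linalg.eigh(0.5 * (mat + mat.T))
    if w.min() >= 0:
        return 0.5 * (mat + mat.T)
    w = np.clip(w, 0.0, None)
    return (v * w) @ v.T


def ibd_from_truth(truth: TruthRecord, ids: Sequence[str], chromosome: str,
                   position: float) -> np.ndarray:
    """Realized IBD matrix from simulator founder-homolog labels (truth mode)."""
    labels = np.array([truth.labels_at(iid, chromosome, position) for iid in ids])
    uniq = np.unique(labels)
    A = np.zeros((len(ids), len(uniq)))
    for k, u in enumerate(uniq):
        A[:, k] = (labels == u).sum(axis=1)
    return 0.5 * (A @ A.T)


def line_cross_ibd(probs: OriginProbTable, chromosome: str, position: float,
                   ids: Optional[Sequence[str]] = None) -> np.ndarray:
    """IBD matrix under the fixation assumption (all line-A founder alleles
    mutually IBD, likewise line-B), from origin probabilities."""
    p = probs.probs_at(chromosome, position)
    if ids is not None:
        rows = [probs.individuals.index(i) for i in ids]
        p = p[rows]
    if probs.cross_type == "F2":
        pa_pat = p[:, 0] + p[:, 1]
        pa_mat = p[:, 0] + p[:, 2]
    else:
        pa_pat = p[:, 0]
        pa_mat = np.array([1.0 if ln == "A" else 0.0
                           for ln in (probs.bc_lines if ids is None else
                                      [probs.bc_lines[probs.individuals.index(i)] for i in ids])])
    sA = pa_pat + pa_mat
    sB = 2.0 - sA
    Pi = 0.5 * (np.outer(sA, sA) + np.outer(sB, sB))
    diag = 1.0 + pa_pat * pa_mat + (1 - pa_pat) * (1 - pa_mat)
    np.fill_diagonal(Pi, diag)
    return Pi


# ---------------------------------------------------------------------------
# variance components (REML) and the score statistic
# ---------------------------------------------------------------------------


@dataclass
class VcFit:
    sigma2_g: float
    sigma2_e: float
    loglik: float
    lam: float
    boundary: bool = False


def _reml_negloglik(lam: float, d: np.ndarray, yt: np.ndarray, Xt: np.ndarray) -> float:
    n, p = Xt.shape
    w = 1.0 + lam * d
    Xw = Xt / w[:, None]
    A = Xt.T @ Xw
    b = Xw.T @ yt
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.inf
    r = yt - Xt @ beta
    quad = float(r @ (r / w))
    if quad <= 0:
        return np.inf
    s2 = quad / (n - p)
    sign, logdet_a = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf
    ll = -0.5 * ((n - p) * (np.log(2 * np.pi * s2) + 1.0) + np.log(w).sum() + logdet_a)
    return -ll


def fit_variance_components(y: np.ndarray, X: np.ndarray, Pi: np.ndarray,
                            lam_max: float = 1e4, tol: float = 1e-6) -> VcFit:
    """REML fit of ``y = X b + g + e`` with ``g ~ N(0, s2_g Pi)``.

    One-dimensional search over lambda = s2_g / s2_e on the spectral
    decomposition of Pi, with the lambda = 0 boundary allowed.  When Pi is a
    multiple of the identity the ratio is unidentifiable and the boundary fit
    is returned flagged.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than fixed effects")
    d, U = np.linalg.eigh(0.5 * (Pi + Pi.T))
    if d.min() < -1e-8:
        raise ValueError("Pi is not PSD; run psd_repair first")
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X

    def nll(lam: float) -> float:
        return _reml_negloglik(lam, d, yt, Xt)

    if np.ptp(d) < 1e-10:
        lam, boundary = 0.0, True
    else:
        grid = np.concatenate([[0.0], np.logspace(-4, np.log10(lam_max), 45)])
        vals = np.array([nll(g) for g in grid])
        k = int(np.argmin(vals))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, len(grid) - 1)]
        if hi > lo:
            res = minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                                  options={"xatol": tol})
            lam = float(res.x) if res.fun <= vals[k] else float(grid[k])
        else:
            lam = float(grid[k])
        if nll(0.0) <= nll(lam) + 1e-12:
            lam = 0.0
        boundary = lam <= tol
        if boundary:
            lam = 0.0 if nll(0.0) <= nll(lam) else lam

    w = 1.0 + lam * d
    Xw = Xt / w[:, None]
    beta = np.linalg.solve(Xt.T @ Xw, Xw.T @ yt)
    r = yt - Xt @ beta
    s2e = float(r @ (r / w)) / (n - p)
    return VcFit(sigma2_g=lam * s2e, sigma2_e=s2e, loglik=-nll(lam), lam=lam,
                 boundary=boundary)


def fia_score(y: np.ndarray, X: np.ndarray, Pi: np.ndarray) -> float:
    """Standardized quadratic-form score statistic for genetic variance.

    ``U = (r' Pi r / s2 - tr(Q Pi)) / sqrt(2 tr((Q Pi)^2))`` with null
    residuals ``r = Q y``, ``Q = I - P_X`` and ``s2 = r'r/(n-p)``.
    Significance is assessed by permutation only.
    """
    return float(fia_score_matrix(np.asarray(y, float)[:, None], X, Pi)[0])


def fia_score_matrix(Y: np.ndarray, X: np.ndarray, Pi: np.ndarray) -> np.ndarray:
    """Score statistic for each column of Y (vectorized for permutations)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    q_mat = orth(X)  # rank-revealing: collinear columns do not inflate p
    p = q_mat.shape[1]
    R = Y - q_mat @ (q_mat.T @ Y)
    QPi = Pi - q_mat @ (q_mat.T @ Pi)
    QPiQ = QPi - (QPi @ q_mat) @ q_mat.T
    tr1 = float(np.trace(QPi))
    tr2 = float(np.sum(QPiQ * QPiQ.T))
    s2 = np.einsum("ij,ij->j", R, R) / (n - p)
    num = np.einsum("ij,ij->j", R, Pi @ R) / np.maximum(s2, 1e-300) - tr1
    den = np.sqrt(max(2.0 * tr2, 1e-300))
    return num / den


# ---------------------------------------------------------------------------
# genome scan and fixed-vs-segregating comparison
# ---------------------------------------------------------------------------


@dataclass
class FiaResult:
    table: pd.DataFrame
    perm: Optional[PermutationDistribution]
    trait: str
    n_samples: int
    seed: int

    def argmax(self) -> tuple[str, float, float]:
        row = self.table.loc[self.table["score"].idxmax()]
        return str(row["chromosome"]), float(row["position"]), float(row["score"])


def segregation_lr(y: np.ndarray, X: np.ndarray, Pi_full: np.ndarray,
                   Pi_lc: np.ndarray) -> float:
    """2 * (REML loglik with the full MC IBD matrix - with the line-cross
    fixation matrix); positive values favor within-line segregation."""
    if np.allclose(Pi_full, Pi_lc):
        return 0.0
    full = fit_variance_components(y, X, psd_repair(Pi_full))
    lc = fit_variance_components(y, X, psd_repair(Pi_lc))
    return 2.0 * (full.loglik - lc.loglik)


def fia_scan(cross: CrossData, trait: str, covariates: Sequence[str] = (),
             step_cM: float = 10.0, n_samples: int = 200, n_perm: int = 1000,
             seed: int = 0, quantiles: Sequence[float] = (0.95,),
             chromosomes: Optional[Sequence[str]] = None,
             fit_reml: bool = False, seg_lr: bool = False,
             error_rate: float = 0.001) -> FiaResult:
    """Score-statistic genome scan on Monte-Carlo IBD matrices.

    Per grid position: MCIBD matrix, score statistic, optional REML variance
    components and fixed-vs-segregating log-likelihood ratio.  Genome-wide
    permutation thresholds permute the trait and record the maximum score.
    """
    y, X, ids = build_design(cross, trait, covariates, cross.offspring_ids)
    rng = np.random.default_rng(seed)
    Y = np.column_stack([y] + [rng.permutation(y) for _ in range(n_perm)]) \
        if n_perm > 0 else y[:, None]
    probs = None
    if seg_lr:
        probs = line_origin_probs(cross, step_cM=step_cM, error_rate=error_rate,
                                  validate=False)
    chrom_names = list(chromosomes) if chromosomes is not None else \
        [c.name for c in cross.gmap.chromosomes if c.kind != "sex"]
    records = []
    perm_max = np.full(n_perm, -np.inf) if n_perm > 0 else None
    for ci, name in enumerate(chrom_names):
        chrom = cross.gmap.chromosome(name)
        grid = _grid_positions(chrom, step_cM)
        for pos in grid:
            ibd = mcibd_matrix(cross, name, float(pos), n_samples=n_samples,
                               seed=seed + 7919 * ci + int(round(pos * 1000)),
                               ids=ids, error_rate=error_rate)
            scores = fia_score_matrix(Y, X, ibd.matrix)
            rec = {"chromosome": name, "position": float(pos), "score": float(scores[0]),
                   "sigma2_g": np.nan, "sigma2_e": np.nan, "loglik_full": np.nan,
                   "loglik_lc": np.nan, "seg_lr": np.nan}
            if fit_reml or seg_lr:
                fit = fit_variance_components(y, X, ibd.matrix)
                rec.update(sigma2_g=fit.sigma2_g, sigma2_e=fit.sigma2_e,
                           loglik_full=fit.loglik)
            if seg_lr:
                Pi_lc = psd_repair(line_cross_ibd(probs, name, float(pos), ids=ids))
                lc = fit_variance_components(y, X, Pi_lc)
                rec.update(loglik_lc=lc.loglik,
                           seg_lr=2.0 * (rec["loglik_full"] - lc.loglik))
            records.append(rec)
            if n_perm > 0:
                perm_max = np.maximum(perm_max, scores[1:])
    perm = None
    if n_perm > 0:
        thresholds = {float(q): float(np.quantile(perm_max, q)) for q in quantiles}
        perm = PermutationDistribution(max_stats=perm_max, thresholds=thresholds,
                                       n_perm=n_perm, seed=seed)
    return FiaResult(table=pd.DataFrame.from_records(records), perm=perm, trait=trait,
                     n_samples=n_samples, seed=seed)
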