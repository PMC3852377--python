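"""Posterior founder-line-origin probabilities by HMM, and path sampling.

For each mapping-generation individual (F2 or BC) the hidden state at a locus
is the ordered pair of founder-line origins of its two gametes (4 ordered
states AA/AB/BA/BB for F2; 2 states for the F1-parent gamete in a BC).  The
two gamete chains are independent 2-state Markov chains with switch
probability given by the Haldane map function; emissions at markers condition
on the transmitting parents' per-homolog allele distributions, which are in
turn inferred from F0 genotypes and line allele frequencies.

Grid positions are silent states (no emission) inserted between markers, so
posteriors are available at user-defined regular intervals including both
chromosome ends.  All computations use per-step rescaling for numerical
stability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cross_data import (
    GEN_F0_A,
    GEN_F0_B,
    GEN_F1,
    SEX_MALE,
    ChromosomeMap,
    CrossData,
    Finding,
    assert_valid,
)
from .sim_cross import haldane_r

F2_STATES = ("AA", "AB", "BA", "BB")
BC_STATES = ("A", "B")

_LINE_IDX = {"A": 0, "B": 1}


# ---------------------------------------------------------------------------
# line allele frequencies and F1 homolog distributions
# ---------------------------------------------------------------------------


@dataclass
class LineFreqs:
    """Per-marker allele universe and per-line allele frequencies.

    Frequencies are counting estimates over F0 genotypes with pseudocount 0.5
    per observed allele, so no observed allele ever has frequency zero.
    Markers with no F0 data in a line fall back to the pooled-F0 frequencies,
    and to uniform when no F0 is genotyped at all.
    """

    universe: dict[str, np.ndarray]          # marker -> sorted allele codes
    freq: dict[str, dict[str, np.ndarray]]   # marker -> line -> frequency vector

    def allele_index(self, marker: str, allele: int) -> int:
        u = self.universe[marker]
        i = int(np.searchsorted(u, allele))
        if i >= len(u) or u[i] != allele:
            raise KeyError(f"allele {allele} not in universe of {marker}")
        return i


def estimate_line_freqs(cross: CrossData) -> LineFreqs:
    universe: dict[str, np.ndarray] = {}
    freq: dict[str, dict[str, np.ndarray]] = {}
    founders = {"A": cross.founders_of_line("A"), "B": cross.founders_of_line("B")}
    for marker in cross.gmap.marker_names:
        cols = [marker + "_1", marker + "_2"]
        vals = cross.genotypes[cols].to_numpy().ravel()
        obs = np.unique(vals[vals > 0])
        if len(obs) == 0:
            obs = np.array([1])
        universe[marker] = obs
        k = len(obs)

        def counts_for(ids: list[str]) -> np.ndarray:
            if not ids:
                return np.zeros(k)
            sub = cross.genotypes.loc[[i for i in ids if i in cross.genotypes.index], cols]
            v = sub.to_numpy().ravel() if len(sub) else np.array([])
            v = v[v > 0]
            return np.array([(v == a).sum() for a in obs], dtype=float)

        pooled = counts_for(founders["A"] + founders["B"])
        freq[marker] = {}
        for line in ("A", "B"):
            c = counts_for(founders[line])
            if c.sum() == 0:
                c = pooled
            if c.sum() == 0:
                freq[marker][line] = np.full(k, 1.0 / k)
            else:
                c = c + 0.5
                freq[marker][line] = c / c.sum()
    return LineFreqs(universe=universe, freq=freq)


@dataclass
class F1HomologDist:
    """Per F1 individual and marker: allele distributions on the line-A- and
    line-B-derived homologs (rows 0 and 1 of a (2, n_alleles) array)."""

    dists: dict[str, dict[str, np.ndarray]]
    findings: list[Finding] = field(default_factory=list)


def _transmission_dist(cross: CrossData, freqs: LineFreqs, parent_id: Optional[str],
                       marker: str, fallback_line: str) -> np.ndarray:
    """Allele distribution transmitted by a parent at a marker.

    Genotyped parent -> half/half over its two alleles; otherwise the line
    allele frequencies of ``fallback_line``.
    """
    u = freqs.universe[marker]
    g = cross.genotype(parent_id, marker) if parent_id is not None else None
    if g is None:
        return freqs.freq[marker][fallback_line]
    t = np.zeros(len(u))
    for a in g:
        t[freqs.allele_index(marker, a)] += 0.5
    return t


def _line_parents(cross: CrossData, f1_id: str) -> dict[str, Optional[str]]:
    ind = cross.individual(f1_id)
    out: dict[str, Optional[str]] = {"A": None, "B": None}
    for p in (ind.sire, ind.dam):
        if p is None or not cross.has_individual(p):
            continue
        gen = cross.individual(p).generation
        if gen == GEN_F0_A:
            out["A"] = p
        elif gen == GEN_F0_B:
            out["B"] = p
    return out


def infer_f1_homolog_dists(cross: CrossData, freqs: LineFreqs) -> F1HomologDist:
    """Infer the allele distribution on each F1 homolog at every marker.

    Fully informative parental genotypes give point masses; otherwise Bayes
    over the phase assignments consistent with the observed F1 genotype, with
    line allele frequencies as the prior for ungenotyped parents.  A
    non-Mendelian F1 genotype yields a finding and the marker is treated as
    missing for that F1.
    """
    marker_kind = {m: c.kind for c in cross.gmap.chromosomes for m in c.markers}
    findings: list[Finding] = []
    dists: dict[str, dict[str, np.ndarray]] = {}
    for f1 in cross.f1_ids:
        parents = _line_parents(cross, f1)
        ind = cross.individual(f1)
        per_marker: dict[str, np.ndarray] = {}
        for marker in cross.gmap.marker_names:
            u = freqs.universe[marker]
            k = len(u)
            is_sex = marker_kind[marker] == "sex"
            if is_sex and ind.sex == cross.heterogametic_sex:
                # single sex-chromosome homolog, inherited from the
                # homogametic-transmitting side (dam for XY males, sire for ZW females)
                src = ind.dam if cross.heterogametic_sex == SEX_MALE else ind.sire
                src_line = "A"
                if src is not None and cross.has_individual(src):
                    src_line = cross.individual(src).line or "A"
                t = _transmission_dist(cross, freqs, src, marker, src_line)
                g = cross.genotype(f1, marker)
                if g is not None:
                    cond = np.zeros(k)
                    cond[freqs.allele_index(marker, g[0])] = 1.0
                    if (cond * t).sum() > 0:
                        t = cond
                    else:
                        findings.append(Finding("warning",
                                                f"{f1}: hemizygous genotype at {marker} conflicts "
                                                "with parent", f"{f1}:{marker}"))
                h = np.full((2, k), 1.0 / k)
                h[_LINE_IDX[src_line]] = t
                per_marker[marker] = h
                continue

            ta = _transmission_dist(cross, freqs, parents["A"], marker, "A")
            tb = _transmission_dist(cross, freqs, parents["B"], marker, "B")
            joint = np.outer(ta, tb)
            g = cross.genotype(f1, marker)
            if g is not None:
                i = freqs.allele_index(marker, g[0])
                j = freqs.allele_index(marker, g[1])
                mask = np.zeros((k, k))
                mask[i, j] = 1.0
                mask[j, i] = 1.0
                cond = joint * mask
                if cond.sum() <= 0.0:
                    findings.append(Finding(
                        "warning", f"{f1}: genotype at {marker} incompatible with both parents "
                        "(non-Mendelian); marker treated as missing", f"{f1}:{marker}"))
                else:
                    joint = cond
            tot = joint.sum()
            h = np.vstack([joint.sum(axis=1) / tot, joint.sum(axis=0) / tot])
            per_marker[marker] = h
        dists[f1] = per_marker
    return F1HomologDist(dists=dists, findings=findings)


# ---------------------------------------------------------------------------
# chain construction (shared by forward-backward, sampler, and brute force)
# ---------------------------------------------------------------------------


@dataclass
class _Block:
    """Offspring sharing parents, hence prior/transitions/emission tables."""

    ids: list[str]
    idx: np.ndarray            # row indices into the processed-individual list
    prior: np.ndarray          # (S,)
    free: tuple[bool, ...]     # per gamete chain: does it recombine?
    em: np.ndarray             # (n, L, S) emission, ones at silent loci

    def transition(self, d_cM: float) -> np.ndarray:
        r = haldane_r(d_cM)
        R = np.array([[1 - r, r], [r, 1 - r]])
        eye = np.eye(2)
        mats = [R if f else eye for f in self.free]
        T = mats[0]
        for m in mats[1:]:
            T = np.kron(T, m)
        return T


def _pair_emission(e4: np.ndarray, gi: np.ndarray, gj: np.ndarray,
                   missing: np.ndarray, n_states: int, n_alleles: int,
                   error_rate: float) -> np.ndarray:
    """Emission vectors for observed unordered pairs given a per-state joint
    allele table ``e4`` of shape (S, A, A)."""
    n = len(gi)
    out = np.ones((n, n_states))
    obs = ~missing
    if obs.any():
        i, j = gi[obs], gj[obs]
        e = e4[:, i, j] + np.where(i != j, e4[:, j, i], 0.0)
        g_count = n_alleles * (n_alleles + 1) / 2.0
        out[obs] = ((1.0 - error_rate) * e + error_rate / g_count).T
    return out


def _build_blocks(cross: CrossData, freqs: LineFreqs, hd: F1HomologDist,
                  chrom: ChromosomeMap, ids: list[str], loci_pos: np.ndarray,
                  marker_at: dict[int, str], error_rate: float) -> list[_Block]:
    """Group processed individuals by parents and build per-block HMM terms.

    ``loci_pos`` is the merged sorted locus grid; ``marker_at`` maps locus
    index -> marker name for the marker loci.
    """
    is_sex = chrom.kind == "sex"
    n_states = 4 if cross.cross_type == "F2" else 2
    L = len(loci_pos)

    groups: dict[tuple, list[int]] = {}
    for row, iid in enumerate(ids):
        ind = cross.individual(iid)
        groups.setdefault((ind.sire, ind.dam), []).append(row)

    # genotype index arrays per marker locus for all processed individuals
    gidx: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for li, marker in marker_at.items():
        u = freqs.universe[marker]
        gi = np.zeros(len(ids), dtype=int)
        gj = np.zeros(len(ids), dtype=int)
        miss = np.zeros(len(ids), dtype=bool)
        for row, iid in enumerate(ids):
            g = cross.genotype(iid, marker)
            if g is None:
                miss[row] = True
            else:
                try:
                    gi[row] = freqs.allele_index(marker, g[0])
                    gj[row] = freqs.allele_index(marker, g[1])
                except KeyError:
                    miss[row] = True
        gidx[li] = (gi, gj, miss)

    blocks: list[_Block] = []
    for (sire, dam), rows in groups.items():
        rows_arr = np.array(rows)
        if cross.cross_type == "F2":
            prior_p, prior_m = np.full(2, 0.5), np.full(2, 0.5)
            free_p = free_m = True
            if is_sex:
                het_parent, het_is_sire = (sire, True) if cross.heterogametic_sex == SEX_MALE \
                    else (dam, False)
                src = None
                if het_parent is not None and cross.has_individual(het_parent):
                    hp = cross.individual(het_parent)
                    src = hp.dam if cross.heterogametic_sex == SEX_MALE else hp.sire
                line = "A"
                if src is not None and cross.has_individual(src):
                    line = cross.individual(src).line or "A"
                fixed = np.zeros(2)
                fixed[_LINE_IDX[line]] = 1.0
                if het_is_sire:
                    prior_p, free_p = fixed, False
                else:
                    prior_m, free_m = fixed, False
            prior = np.kron(prior_p, prior_m)
            free = (free_p, free_m)
            em = np.ones((len(rows), L, n_states))
            for li, marker in marker_at.items():
                pf = hd.dists.get(sire, {}).get(marker)
                pm = hd.dists.get(dam, {}).get(marker)
                k = len(freqs.universe[marker])
                if pf is None:
                    pf = np.full((2, k), 1.0 / k)
                if pm is None:
                    pm = np.full((2, k), 1.0 / k)
                # state (sp, sm) -> joint allele table
                e4 = np.einsum("si,tj->stij", pf, pm).reshape(n_states, k, k)
                gi, gj, miss = gidx[li]
                em[:, li, :] = _pair_emission(e4, gi[rows_arr], gj[rows_arr], miss[rows_arr],
                                              n_states, k, error_rate)
        else:  # BC
            f1_parent, f0_parent = (sire, dam)
            if f1_parent is None or cross.individual(f1_parent).generation != GEN_F1:
                f1_parent, f0_parent = dam, sire
            if f1_parent is None or cross.individual(f1_parent).generation != GEN_F1:
                raise ValueError(f"BC offspring of ({sire}, {dam}) lack an F1 parent")
            f0_line = "A"
            if f0_parent is not None and cross.has_individual(f0_parent):
                f0_line = cross.individual(f0_parent).line or "A"
            free_c = True
            prior = np.full(2, 0.5)
            if is_sex and cross.individual(f1_parent).sex == cross.heterogametic_sex:
                hp = cross.individual(f1_parent)
                src = hp.dam if cross.heterogametic_sex == SEX_MALE else hp.sire
                line = cross.individual(src).line if src and cross.has_individual(src) else "A"
                prior = np.zeros(2)
                prior[_LINE_IDX[line or "A"]] = 1.0
                free_c = False
            free = (free_c,)
            em = np.ones((len(rows), L, n_states))
            for li, marker in marker_at.items():
                k = len(freqs.universe[marker])
                pf1 = hd.dists.get(f1_parent, {}).get(marker)
                if pf1 is None:
                    pf1 = np.full((2, k), 1.0 / k)
                t0 = _transmission_dist(cross, freqs, f0_parent, marker, f0_line)
                e4 = np.einsum("si,j->sij", pf1, t0)
                gi, gj, miss = gidx[li]
                em[:, li, :] = _pair_emission(e4, gi[rows_arr], gj[rows_arr], miss[rows_arr],
                                              n_states, k, error_rate)
        blocks.append(_Block(ids=[ids[r] for r in rows], idx=rows_arr, prior=prior,
                             free=free, em=em))
    return blocks


def _merge_loci(chrom: ChromosomeMap, grid: np.ndarray) -> tuple[np.ndarray, np.ndarray, dict[int, str]]:
    """Merge grid and marker positions; return (loci, grid locus indices, marker map)."""
    loci = np.unique(np.round(np.concatenate([grid, chrom.positions]), 9))
    grid_idx = np.searchsorted(loci, np.round(grid, 9))
    marker_at: dict[int, str] = {}
    for m, p in zip(chrom.markers, chrom.positions):
        marker_at[int(np.searchsorted(loci, round(float(p), 9)))] = m
    return loci, grid_idx, marker_at


def _grid_positions(chrom: ChromosomeMap, step_cM: float) -> np.ndarray:
    if step_cM <= 0:
        raise ValueError("step_cM must be > 0")
    end = chrom.length
    g = np.arange(0.0, end, step_cM)
    return np.unique(np.round(np.append(g, end), 9))


def _normalize_rows(a: np.ndarray, fallback: np.ndarray) -> np.ndarray:
    s = a.sum(axis=1, keepdims=True)
    bad = (s <= 0.0).ravel()
    if bad.any():
        a[bad] = fallback
        s = a.sum(axis=1, keepdims=True)
    return a / s


def _block_forward(block: _Block, loci_pos: np.ndarray) -> list[np.ndarray]:
    """Scaled forward variables per locus, each (n, S)."""
    em = block.em
    a = _normalize_rows(block.prior[None, :] * em[:, 0, :], block.prior)
    alphas = [a]
    for t in range(1, len(loci_pos)):
        T = block.transition(loci_pos[t] - loci_pos[t - 1])
        a = _normalize_rows((a @ T) * em[:, t, :], block.prior)
        alphas.append(a)
    return alphas


def _block_marginals(block: _Block, loci_pos: np.ndarray) -> np.ndarray:
    """Forward-backward posterior marginals, shape (n, L, S)."""
    alphas = _block_forward(block, loci_pos)
    L = len(loci_pos)
    n, _, S = block.em.shape
    out = np.empty((n, L, S))
    b = np.ones((n, S))
    out[:, L - 1, :] = _normalize_rows(alphas[-1] * b, block.prior)
    for t in range(L - 2, -1, -1):
        T = block.transition(loci_pos[t + 1] - loci_pos[t])
        b = (block.em[:, t + 1, :] * b) @ T.T
        b = b / np.maximum(b.max(axis=1, keepdims=True), 1e-300)
        out[:, t, :] = _normalize_rows(alphas[t] * b, block.prior)
    return out


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


@dataclass
class ChromOriginProbs:
    positions: np.ndarray      # grid positions (cM)
    probs: np.ndarray          # (n_individuals, n_positions, n_states); NaN if unprocessed


@dataclass
class OriginProbTable:
    """Posterior line-origin probabilities on a regular grid."""

    individuals: list[str]
    states: tuple[str, ...]
    cross_type: str
    step_cM: float
    error_rate: float
    chromosomes: dict[str, ChromOriginProbs]
    bc_lines: Optional[np.ndarray] = None   # per individual, BC only

    def probs_at(self, chromosome: str, position: float) -> np.ndarray:
        cp = self.chromosomes[chromosome]
        i = int(np.argmin(np.abs(cp.positions - position)))
        if abs(cp.positions[i] - position) > 1e-6:
            raise KeyError(f"position {position} not on grid of chromosome {chromosome}")
        return cp.probs[:, i, :]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, cp in self.chromosomes.items():
            for pi, pos in enumerate(cp.positions):
                for ii, iid in enumerate(self.individuals):
                    rows.append((iid, chrom, float(pos), *cp.probs[ii, pi, :]))
        cols = ["individual", "chromosome", "position"] + [f"p_{s}" for s in self.states]
        return pd.DataFrame(rows, columns=cols)


def _bc_lines(cross: CrossData, ids: list[str]) -> np.ndarray:
    lines = []
    for iid in ids:
        ind = cross.individual(iid)
        line = "A"
        for p in (ind.sire, ind.dam):
            if p is not None and cross.has_individual(p):
                pi = cross.individual(p)
                if pi.generation in (GEN_F0_A, GEN_F0_B):
                    line = pi.line or ("A" if pi.generation == GEN_F0_A else "B")
        lines.append(line)
    return np.array(lines)


def line_origin_probs(cross: CrossData, step_cM: float = 1.0, error_rate: float = 0.001,
                      chromosomes: Optional[Sequence[str]] = None,
                      validate: bool = True) -> OriginProbTable:
    """Forward-backward posterior origin probabilities at regular grid positions.

    Heterogametic-sex individuals get NaN entries on the sex chromosome; all
    probability vectors elsewhere sum to one.
    """
    if step_cM <= 0:
        raise ValueError("step_cM must be > 0")
    if cross.cross_type not in ("F2", "BC"):
        raise ValueError(f"unknown cross type {cross.cross_type}")
    if validate:
        assert_valid(cross)
    freqs = estimate_line_freqs(cross)
    hd = infer_f1_homolog_dists(cross, freqs)
    ids = cross.offspring_ids
    states = F2_STATES if cross.cross_type == "F2" else BC_STATES
    S = len(states)

    chrom_names = list(chromosomes) if chromosomes is not None else cross.gmap.names
    out: dict[str, ChromOriginProbs] = {}
    for name in chrom_names:
        chrom = cross.gmap.chromosome(name)
        grid = _grid_positions(chrom, step_cM)
        loci, grid_idx, marker_at = _merge_loci(chrom, grid)
        probs = np.full((len(ids), len(grid), S), np.nan)
        proc = ids if chrom.kind != "sex" else cross.homogametic_ids(ids)
        proc_rows = [ids.index(i) for i in proc]
        if proc:
            blocks = _build_blocks(cross, freqs, hd, chrom, proc, loci, marker_at, error_rate)
            for blk in blocks:
                marg = _block_marginals(blk, loci)
                for bi, row in enumerate(blk.idx):
                    probs[proc_rows[row], :, :] = marg[bi, grid_idx, :]
        out[name] = ChromOriginProbs(positions=grid, probs=probs)
    return OriginProbTable(
        individuals=ids, states=states, cross_type=cross.cross_type, step_cM=step_cM,
        error_rate=error_rate, chromosomes=out,
        bc_lines=_bc_lines(cross, ids) if cross.cross_type == "BC" else None,
    )


@dataclass
class SampledPaths:
    """Joint origin paths sampled from the exact posterior (FFBS)."""

    individuals: list[str]
    states: tuple[str, ...]
    positions: np.ndarray           # loci where states were sampled
    samples: np.ndarray             # (n_individuals, n_samples, n_loci) state indices, -1 unprocessed

    def states_at(self, position: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.positions - position)))
        if abs(self.positions[i] - position) > 1e-6:
            raise KeyError(f"position {position} not among sampled loci")
        return self.samples[:, :, i]


def sample_origin_paths(cross: CrossData, n_samples: int, rng: np.random.Generator,
                        chromosome: Optional[str] = None,
                        extra_positions: Sequence[float] = (),
                        error_rate: float = 0.001,
                        validate: bool = True) -> SampledPaths:
    """Sample joint origin paths at marker loci (plus ``extra_positions``)
    by forward filtering-backward sampling from the exact posterior."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if validate:
        assert_valid(cross)
    chrom = cross.gmap.chromosome(chromosome if chromosome is not None
                                  else cross.gmap.names[0])
    freqs = estimate_line_freqs(cross)
    hd = infer_f1_homolog_dists(cross, freqs)
    ids = cross.offspring_ids
    states = F2_STATES if cross.cross_type == "F2" else BC_STATES
    S = len(states)

    extra = np.asarray(list(extra_positions), dtype=float)
    loci, _, marker_at = _merge_loci(chrom, np.unique(np.round(extra, 9)) if len(extra)
                                     else np.array([chrom.positions[0]]))
    L = len(loci)
    samples = np.full((len(ids), n_samples, L), -1, dtype=np.int8)
    proc = ids if chrom.kind != "sex" else cross.homogametic_ids(ids)
    proc_rows = {iid: ids.index(iid) for iid in proc}
    if proc:
        blocks = _build_blocks(cross, freqs, hd, chrom, proc, loci, marker_at, error_rate)
        for blk in blocks:
            alphas = _block_forward(blk, loci)
            n = len(blk.ids)
            smp = np.empty((n, n_samples, L), dtype=np.int8)
            # last locus
            p = np.repeat(alphas[-1], n_samples, axis=0)           # (n*K, S)
            smp[:, :, L - 1] = _sample_rows(p, rng).reshape(n, n_samples)
            for t in range(L - 2, -1, -1):
                T = blk.transition(loci[t + 1] - loci[t])
                nxt = smp[:, :, t + 1].reshape(-1)
                p = np.repeat(alphas[t], n_samples, axis=0) * T.T[nxt]  # (n*K, S)
                smp[:, :, t] = _sample_rows(p, rng).reshape(n, n_samples)
            for bi, iid in enumerate(blk.ids):
                samples[proc_rows[iid], :, :] = smp[bi]
    return SampledPaths(individuals=ids, states=states, positions=loci, samples=samples)


def _sample_rows(p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one categorical sample per row of an unnormalized probability matrix."""
    c = np.cumsum(p, axis=1)
    tot = c[:, -1:]
    u = rng.random((p.shape[0], 1)) * tot
    return (u > c).sum(axis=1).astype(np.int8)


def brute_force_origin_posterior(cross: CrossData, individual: str, chromosome: str,
                                 step_cM: Optional[float] = None,
                                 error_rate: float = 0.001,
                                 max_markers: int = 6) -> tuple[np.ndarray, np.ndarray]:
    """Exact posterior marginals by exhaustive enumeration of origin sequences.

    Enumerates every ordered origin sequence over the merged locus grid using
    the same transition/emission terms as the forward-backward recursion; a
    test oracle, bounded to small instances.  Returns (loci positions,
    marginals of shape (L, S)).
    """
    chrom = cross.gmap.chromosome(chromosome)
    if len(chrom.markers) > max_markers:
        raise ValueError(f"too many markers for enumeration (> {max_markers})")
    freqs = estimate_line_freqs(cross)
    hd = infer_f1_homolog_dists(cross, freqs)
    if step_cM is not None:
        grid = _grid_positions(chrom, step_cM)
    else:
        grid = np.array([float(chrom.positions[0])])
    loci, _, marker_at = _merge_loci(chrom, grid)
    S = 4 if cross.cross_type == "F2" else 2
    L = len(loci)
    if S ** L > 2_000_000:
        raise ValueError("instance too large for exhaustive enumeration")
    blocks = _build_blocks(cross, freqs, hd, chrom, [individual], loci, marker_at, error_rate)
    blk = blocks[0]

    seqs = np.indices((S,) * L).reshape(L, -1).T        # (S^L, L)
    p = blk.prior[seqs[:, 0]] * blk.em[0, 0, seqs[:, 0]]
    for t in range(1, L):
        T = blk.transition(loci[t] - loci[t - 1])
        p = p * T[seqs[:, t - 1], seqs[:, t]] * blk.em[0, t, seqs[:, t]]
    tot = p.sum()
    marg = np.empty((L, S))
    for t in range(L):
        marg[t] = np.bincount(seqs[:, t], weights=p, minlength=S) / tot
    return loci, marg
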