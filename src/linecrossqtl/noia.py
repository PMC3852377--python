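"""Orthogonal genetic-effect estimation and change of reference population.

The design matrix depends on the genotype frequencies of the reference
population, which makes additive and dominance effect estimates orthogonal at
those frequencies and lets effects be translated between reference
populations by an exact linear map.  Multi-locus genotype-phenotype maps are
Kronecker products of per-locus designs (linkage equilibrium assumed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product
from typing import Optional, Sequence

import numpy as np

from .cross_data import CrossData
from .line_origin import OriginProbTable
from .ls_scan import build_design

GENOTYPES = ("11", "12", "22")   # 2, 1, 0 copies of the line-A (QTL) allele
SCALES = ("mean", "a", "d")


@dataclass(frozen=True)
class GenotypeFrequencies:
    p11: float
    p12: float
    p22: float

    def __post_init__(self) -> None:
        p = np.array([self.p11, self.p12, self.p22])
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValueError("genotype frequencies must lie in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"genotype frequencies sum to {p.sum()}, not 1")

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.p11, self.p12, self.p22])


F2_FREQS = GenotypeFrequencies(0.25, 0.5, 0.25)


@dataclass
class NoiaDesign:
    """3xL design S; rows index genotypes (11, 12, 22), columns the scales.

    ``degenerate`` is True when fewer than three genotype classes are present
    so the dominance scale does not exist and the design is 3x2.
    """

    S: np.ndarray
    freqs: GenotypeFrequencies
    degenerate: bool = False

    @property
    def scales(self) -> tuple[str, ...]:
        return SCALES[:2] if self.degenerate else SCALES


def noia_design(freqs: GenotypeFrequencies) -> NoiaDesign:
    """Statistical-formulation design for arbitrary genotype frequencies.

    Additive scale: (-p12 - 2 p22, 1 - p12 - 2 p22, 2 - p12 - 2 p22).
    Dominance scale: (-2 p12 p22, 4 p11 p22, -2 p11 p12) / D with
    D = p11 + p22 - (p11 - p22)^2; dropped when D = 0.
    """
    p11, p12, p22 = freqs.p11, freqs.p12, freqs.p22
    shift = -p12 - 2.0 * p22
    add = np.array([shift, 1.0 + shift, 2.0 + shift])
    D = p11 + p22 - (p11 - p22) ** 2
    if abs(D) < 1e-12:
        S = np.column_stack([np.ones(3), add])
        return NoiaDesign(S=S, freqs=freqs, degenerate=True)
    dom = np.array([-2.0 * p12 * p22, 4.0 * p11 * p22, -2.0 * p11 * p12]) / D
    S = np.column_stack([np.ones(3), add, dom])
    return NoiaDesign(S=S, freqs=freqs)


@dataclass
class NoiaEffects:
    """Effect estimates on the NOIA scales of a reference population.

    ``effects`` is ordered (R, alpha[, delta]) for one locus, or by the
    Kronecker product of per-locus scales for multi-locus maps.
    """

    effects: np.ndarray
    se: Optional[np.ndarray]
    design: NoiaDesign
    labels: tuple[str, ...] = ("R", "a", "d")

    @property
    def genotypic_values(self) -> np.ndarray:
        return self.design.S @ self.effects


def _genotype_probs(probs: OriginProbTable, chromosome: str, position: float) -> np.ndarray:
    """Per-individual (p11, p12, p22), collapsing the ordered heterozygotes."""
    if probs.cross_type != "F2":
        raise ValueError("NOIA genotype probabilities require an F2 table")
    p = probs.probs_at(chromosome, position)
    return np.column_stack([p[:, 0], p[:, 1] + p[:, 2], p[:, 3]])


def estimate_effects_noia(cross: CrossData, probs: OriginProbTable, chromosome: str,
                          position: float, trait: str, covariates: Sequence[str] = (),
                          reference: GenotypeFrequencies | str = "sample") -> NoiaEffects:
    """Least-squares NOIA effects at one grid position.

    Per-individual genotype probabilities give expected values of the design
    scales; the reference population defaults to the sample's mean genotype
    probabilities (``"sample"``); ``"f2"`` or explicit frequencies may be
    given instead.
    """
    y, X0, ids = build_design(cross, trait, covariates, probs.individuals)
    rows = np.array([probs.individuals.index(i) for i in ids])
    gp = _genotype_probs(probs, chromosome, position)[rows]
    if isinstance(reference, str):
        if reference == "sample":
            m = gp.mean(axis=0)
            ref = GenotypeFrequencies(*(m / m.sum()))
        elif reference == "f2":
            ref = F2_FREQS
        else:
            raise ValueError(f"unknown reference {reference!r}")
    else:
        ref = reference
    design = noia_design(ref)
    Z = gp @ design.S[:, 1:]          # expected additive (and dominance) scales
    X = np.hstack([X0, Z])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    if df > 0:
        s2 = float(resid @ resid) / df
        se_full = np.sqrt(np.maximum(np.diag(np.linalg.pinv(X.T @ X)), 0.0) * s2)
    else:
        se_full = np.full(X.shape[1], np.nan)
    k = Z.shape[1]
    eff = np.concatenate([[beta[0]], beta[-k:]])
    se = np.concatenate([[se_full[0]], se_full[-k:]])
    labels = ("R", "a") if design.degenerate else ("R", "a", "d")
    return NoiaEffects(effects=eff, se=se, design=design, labels=labels)


def transform_reference(effects: NoiaEffects, to_freqs: GenotypeFrequencies) -> NoiaEffects:
    """Translate effects to another reference population: E2 = S2^-1 S1 E1.

    Genotypic values are preserved exactly (S2 E2 = S1 E1).
    """
    d2 = noia_design(to_freqs)
    if effects.design.degenerate or d2.degenerate:
        raise ValueError("change of reference requires non-degenerate designs")
    e2 = np.linalg.solve(d2.S, effects.design.S @ effects.effects)
    return NoiaEffects(effects=e2, se=None, design=d2, labels=effects.labels)


def multilocus_gp_map(designs: Sequence[NoiaDesign], effects: np.ndarray,
                      min_sep_warn: Optional[float] = None) -> tuple[np.ndarray, list[str]]:
    """Genotypic values over multi-locus genotypes from a Kronecker design.

    ``effects`` is ordered by the Kronecker product of per-locus scales
    (slowest first): for two loci the 9 labels are mm, ma, md, am, aa, ad,
    dm, da, dd, so ``aa`` is additive-by-additive epistasis.  At most 4 loci;
    per-locus frequencies are assumed independent (linkage equilibrium).
    """
    if len(designs) > 4:
        raise ValueError("multilocus maps limited to 4 loci")
    if any(d.degenerate for d in designs):
        raise ValueError("multilocus maps require non-degenerate designs")
    S = designs[0].S
    for d in designs[1:]:
        S = np.kron(S, d.S)
    effects = np.asarray(effects, dtype=float)
    if effects.shape[0] != S.shape[1]:
        raise ValueError(f"expected {S.shape[1]} effects, got {effects.shape[0]}")
    labels = ["".join(t) for t in product(*(["m", "a", "d"][: d.S.shape[1]] for d in designs))]
    return S @ effects, labels


def product_frequencies(designs: Sequence[NoiaDesign]) -> np.ndarray:
    """Joint genotype frequencies under linkage equilibrium (Kronecker order)."""
    p = designs[0].freqs.vector
    for d in designs[1:]:
        p = np.kron(p, d.freqs.vector)
    return p


def check_linked(cross: CrossData, positions: Sequence[tuple[str, float]],
                 min_sep_cM: float = 50.0) -> None:
    """Warn when chosen loci are close on one chromosome (LE assumption)."""
    for i in range(len(positions)):
        for j in range(i + 1, len(positions)):
            (c1, p1), (c2, p2) = positions[i], positions[j]
            if c1 == c2 and abs(p1 - p2) < min_sep_cM:
                warnings.warn(
                    f"loci {c1}:{p1} and {c2}:{p2} are {abs(p1 - p2):g} cM apart; "
                    "the multilocus map assumes linkage equilibrium", stacklevel=2)
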