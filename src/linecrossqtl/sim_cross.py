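"""Simulate two-line crosses (F0 -> F1 -> F2 or BC) with known truth.

Crossovers are placed as a Poisson process with rate 1 per 100 cM (Haldane,
no interference).  Founder homologs carry globally unique integer labels so
exact identity-by-descent and line origin are recoverable at any position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cross_data import (
    GEN_BC,
    GEN_F0_A,
    GEN_F0_B,
    GEN_F1,
    GEN_F2,
    SEX_FEMALE,
    SEX_MALE,
    ChromosomeMap,
    CrossData,
    GeneticMap,
    Individual,
)


def haldane_r(d: float | np.ndarray) -> float | np.ndarray:
    """Haldane map function: recombination fraction for a distance in cM."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if r.ndim == 0 else r


@dataclass
class QtlSpec:
    """A biallelic QTL with optional within-line segregation and epistasis.

    ``f_a``/``f_b`` are the frequencies of the increasing allele among line-A
    and line-B founder homologs; the classical fixed-lines case is
    ``f_a=1, f_b=0``.  ``epistasis`` optionally holds ``(partner_index,
    (aa, ad, da, dd))`` referring to another QTL in the config list.
    """

    chromosome: str
    position: float
    a: float = 0.0
    d: float = 0.0
    f_a: float = 1.0
    f_b: float = 0.0
    epistasis: Optional[tuple[int, tuple[float, float, float, float]]] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_a <= 1.0 and 0.0 <= self.f_b <= 1.0):
            raise ValueError("QTL allele frequencies must lie in [0, 1]")


@dataclass
class SimConfig:
    seed: int = 0
    chromosomes: list[tuple[str, float, int, str]] = field(
        default_factory=lambda: [("1", 100.0, 11, "autosome")]
    )  # (name, length cM, marker count, kind)
    founders_per_line: int = 2
    n_f1: int = 2
    n_offspring: int = 100
    cross_type: str = "F2"
    bc_line: str = "A"
    qtl: list[QtlSpec] = field(default_factory=list)
    mu: float = 0.0
    residual_sd: float = 1.0
    sex_effect: float = 0.0
    # per-line allele frequencies, applied to every marker; keys are allele codes
    allele_freqs: dict[str, dict[int, float]] = field(
        default_factory=lambda: {"A": {1: 1.0}, "B": {2: 1.0}}
    )
    obs_error: float = 0.0  # fraction of genotypes replaced by a uniform draw
    # every founder homolog carries its own unique allele (its label) at every
    # marker, making descent fully marker-determined; used by IBD truth tests
    unique_founder_alleles: bool = False

    def __post_init__(self) -> None:
        for name, length, n_mark, kind in self.chromosomes:
            if n_mark < 2:
                raise ValueError(f"chromosome {name}: need >= 2 markers")
        for line, freqs in self.allele_freqs.items():
            tot = sum(freqs.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"line {line}: allele frequencies sum to {tot}, not 1")
        if self.cross_type not in ("F2", "BC"):
            raise ValueError(f"unknown cross_type {self.cross_type}")
        if self.founders_per_line < 1:
            raise ValueError("founders_per_line must be >= 1")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")


@dataclass
class Gamete:
    """A chromosome mosaic: founder-homolog label per segment.

    ``breaks`` are interior breakpoints (ascending); segment i covers
    [breaks[i-1], breaks[i]) with label ``labels[i]``.
    """

    breaks: np.ndarray  # len k-1 interior breakpoints
    labels: np.ndarray  # len k founder-homolog labels

    def label_at(self, pos: float | np.ndarray):
        idx = np.searchsorted(self.breaks, pos, side="right")
        out = self.labels[idx]
        return int(out) if np.ndim(pos) == 0 else out


@dataclass
class TruthRecord:
    """Phased descent truth for a simulated cross."""

    label_line: dict[int, str]                       # founder homolog label -> line
    label_founder: dict[int, str]                    # label -> founder id
    founder_alleles: dict[int, dict[str, np.ndarray]]  # label -> chrom -> marker alleles
    founder_qtl: dict[int, np.ndarray]               # label -> 0/1 increasing-allele per QTL
    gametes: dict[str, dict[str, tuple[Gamete, Gamete]]]  # id -> chrom -> (paternal, maternal)
    qtl: list[QtlSpec]
    genetic_values: dict[str, float]
    phenotypes: dict[str, float]

    def labels_at(self, iid: str, chrom: str, pos: float) -> tuple[int, int]:
        pat, mat = self.gametes[iid][chrom]
        return pat.label_at(pos), mat.label_at(pos)

    def origin_state(self, iid: str, chrom: str, pos: float) -> tuple[str, str]:
        lp, lm = self.labels_at(iid, chrom, pos)
        return self.label_line[lp], self.label_line[lm]

    def qtl_dose(self, iid: str, q: int) -> int:
        """Count of the increasing allele at QTL index q (0, 1, or 2)."""
        spec = self.qtl[q]
        lp, lm = self.labels_at(iid, spec.chromosome, spec.position)
        return int(self.founder_qtl[lp][q] + self.founder_qtl[lm][q])


def meiosis(gametes: tuple[Gamete, Gamete], length_cM: float,
            rng: np.random.Generator) -> tuple[Gamete, np.ndarray]:
    """One meiosis on a chromosome: Poisson crossovers, fair starting homolog.

    Returns the recombinant gamete and the crossover positions.
    """
    if length_cM < 0:
        raise ValueError("chromosome length must be >= 0")
    n_xo = rng.poisson(length_cM / 100.0) if length_cM > 0 else 0
    xo = np.sort(rng.uniform(0.0, length_cM, size=n_xo))
    start = int(rng.integers(2))
    if n_xo == 0:
        g = gametes[start]
        return Gamete(g.breaks.copy(), g.labels.copy()), xo

    # merge parental breakpoints with crossover switch points
    all_breaks = np.unique(np.concatenate([gametes[0].breaks, gametes[1].breaks, xo]))
    # label of each segment comes from the active homolog at the segment start
    seg_starts = np.concatenate([[0.0], all_breaks])
    active = (start + np.searchsorted(xo, seg_starts, side="right")) % 2
    labels = np.empty(len(seg_starts), dtype=np.int64)
    for h in (0, 1):
        sel = active == h
        if sel.any():
            labels[sel] = gametes[h].label_at(seg_starts[sel])
    # compress runs of identical labels
    keep = np.concatenate([[True], labels[1:] != labels[:-1]])
    return Gamete(all_breaks[keep[1:]], labels[keep]), xo


def _draw_alleles(freqs: dict[int, float], size: int, rng: np.random.Generator) -> np.ndarray:
    codes = np.array(sorted(freqs), dtype=int)
    p = np.array([freqs[c] for c in codes], dtype=float)
    return codes[rng.choice(len(codes), size=size, p=p)]


def simulate_cross(config: SimConfig) -> tuple[CrossData, TruthRecord]:
    """Simulate a two-line cross; deterministic given ``config.seed``.

    Returns the observable :class:`CrossData` plus the full descent truth.
    Phenotypes (trait ``y``) are assigned to the mapping generation only:
    ``y = mu + sum of QTL effects (+ epistasis) (+ sex effect) + N(0, sd^2)``.
    """
    rng = np.random.default_rng(config.seed)
    gmap = GeneticMap([
        ChromosomeMap(name, kind, [f"c{name}m{i + 1}" for i in range(n_mark)],
                      np.linspace(0.0, length, n_mark))
        for name, length, n_mark, kind in config.chromosomes
    ])
    chrom_len = {name: length for name, length, _, _ in config.chromosomes}

    pedigree: list[Individual] = []
    gametes: dict[str, dict[str, tuple[Gamete, Gamete]]] = {}
    label_line: dict[int, str] = {}
    label_founder: dict[int, str] = {}
    founder_alleles: dict[int, dict[str, np.ndarray]] = {}
    founder_qtl: dict[int, np.ndarray] = {}

    next_label = 1

    def add_founder(line: str, idx: int) -> str:
        nonlocal next_label
        iid = f"{line}{idx + 1}"
        sex = SEX_MALE if idx % 2 == 0 else SEX_FEMALE
        gen = GEN_F0_A if line == "A" else GEN_F0_B
        pedigree.append(Individual(id=iid, sex=sex, generation=gen, line=line))
        labs = (next_label, next_label + 1)
        next_label += 2
        gametes[iid] = {}
        for lab in labs:
            label_line[lab] = line
            label_founder[lab] = iid
            founder_alleles[lab] = {}
            for chrom in gmap.chromosomes:
                if config.unique_founder_alleles:
                    founder_alleles[lab][chrom.name] = np.full(len(chrom.markers), lab)
                else:
                    founder_alleles[lab][chrom.name] = _draw_alleles(
                        config.allele_freqs[line], len(chrom.markers), rng)
            founder_qtl[lab] = np.array(
                [rng.random() < (q.f_a if line == "A" else q.f_b) for q in config.qtl],
                dtype=int)
        for chrom in gmap.chromosomes:
            pat = Gamete(np.array([]), np.array([labs[0]], dtype=np.int64))
            mat = Gamete(np.array([]), np.array([labs[1]], dtype=np.int64))
            if chrom.kind == "sex" and sex == SEX_MALE:
                # XY male: single X (maternal side), Y is a placeholder
                pat = Gamete(np.array([]), np.array([-1], dtype=np.int64))
            gametes[iid][chrom.name] = (pat, mat)
        return iid

    founders = {"A": [add_founder("A", i) for i in range(config.founders_per_line)],
                "B": [add_founder("B", i) for i in range(config.founders_per_line)]}

    males = {ln: [f for f in founders[ln] if _sex_of(pedigree, f) == SEX_MALE] or founders[ln]
             for ln in "AB"}
    females = {ln: [f for f in founders[ln] if _sex_of(pedigree, f) == SEX_FEMALE] or founders[ln]
               for ln in "AB"}

    def mate(sire: str, dam: str, iid: str, sex: str, gen: str) -> None:
        pedigree.append(Individual(id=iid, sire=sire, dam=dam, sex=sex, generation=gen))
        gametes[iid] = {}
        for chrom in gmap.chromosomes:
            if chrom.kind == "sex":
                # XY system (male heterogametic): daughters get the sire's X
                # intact, sons get the Y placeholder; the dam's X recombines.
                if sex == SEX_FEMALE:
                    x = gametes[sire][chrom.name][1]
                    pat = Gamete(x.breaks.copy(), x.labels.copy())
                else:
                    pat = Gamete(np.array([]), np.array([-1], dtype=np.int64))
            else:
                pat, _ = meiosis(gametes[sire][chrom.name], chrom_len[chrom.name], rng)
            mat, _ = meiosis(gametes[dam][chrom.name], chrom_len[chrom.name], rng)
            gametes[iid][chrom.name] = (pat, mat)

    f1s: list[str] = []
    for i in range(config.n_f1):
        sire = males["A"][i % len(males["A"])]
        dam = females["B"][i % len(females["B"])]
        sex = SEX_MALE if i % 2 == 0 else SEX_FEMALE
        iid = f"F1_{i + 1}"
        mate(sire, dam, iid, sex, GEN_F1)
        f1s.append(iid)

    f1_males = [f for f in f1s if _sex_of(pedigree, f) == SEX_MALE]
    f1_females = [f for f in f1s if _sex_of(pedigree, f) == SEX_FEMALE]

    offspring: list[str] = []
    for i in range(config.n_offspring):
        iid = f"O{i + 1}"
        sex = SEX_FEMALE if i % 2 == 0 else SEX_MALE
        if config.cross_type == "F2":
            if not f1_males or not f1_females:
                raise ValueError("F2 cross needs at least one F1 of each sex")
            mate(f1_males[i % len(f1_males)], f1_females[i % len(f1_females)], iid, sex, GEN_F2)
        else:
            bc = config.bc_line
            if f1_males:
                mate(f1_males[i % len(f1_males)], females[bc][i % len(females[bc])], iid, sex, GEN_BC)
            else:
                mate(males[bc][i % len(males[bc])], f1_females[i % len(f1_females)], iid, sex, GEN_BC)
        offspring.append(iid)

    # observed genotypes for everyone
    markers = gmap.marker_names
    cols = [f"{m}_{k}" for m in markers for k in (1, 2)]
    rows = {}
    allele_universe = sorted({c for ln in "AB" for c in config.allele_freqs[ln]})
    for ind in pedigree:
        vals = []
        for chrom in gmap.chromosomes:
            pat, mat = gametes[ind.id][chrom.name]
            lp = pat.label_at(chrom.positions)
            lm = mat.label_at(chrom.positions)
            for j in range(len(chrom.markers)):
                l1, l2 = int(lp[j]), int(lm[j])
                if l1 < 0 and l2 < 0:
                    vals.extend((0, 0))
                    continue
                # hemizygous sex-chromosome genotypes are recorded (a, a)
                a1 = int(founder_alleles[l1 if l1 >= 0 else l2][chrom.name][j])
                a2 = int(founder_alleles[l2 if l2 >= 0 else l1][chrom.name][j])
                if config.obs_error > 0 and rng.random() < config.obs_error:
                    a1 = int(allele_universe[rng.integers(len(allele_universe))])
                    a2 = int(allele_universe[rng.integers(len(allele_universe))])
                vals.extend((a1, a2) if a1 <= a2 else (a2, a1))
        rows[ind.id] = vals
    geno = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    geno.index.name = "id"

    label_line[-1] = "?"  # sex-chromosome placeholder (Y/W)
    truth = TruthRecord(label_line=label_line, label_founder=label_founder,
                        founder_alleles=founder_alleles, founder_qtl=founder_qtl,
                        gametes=gametes, qtl=config.qtl, genetic_values={}, phenotypes={})

    # phenotypes for the mapping generation
    pheno_rows = {}
    for iid in offspring:
        g = config.mu
        doses = [truth.qtl_dose(iid, q) for q in range(len(config.qtl))]
        xa = [dose - 1 for dose in doses]           # -1/0/+1
        xd = [1 if dose == 1 else 0 for dose in doses]
        for q, spec in enumerate(config.qtl):
            g += spec.a * xa[q] + spec.d * xd[q]
            if spec.epistasis is not None:
                partner, (aa, ad, da, dd) = spec.epistasis
                g += (aa * xa[q] * xa[partner] + ad * xa[q] * xd[partner]
                      + da * xd[q] * xa[partner] + dd * xd[q] * xd[partner])
        sexv = 1.0 if _sex_of(pedigree, iid) == SEX_MALE else 0.0
        g += config.sex_effect * sexv
        truth.genetic_values[iid] = g
        y = g + (rng.normal(0.0, config.residual_sd) if config.residual_sd > 0 else 0.0)
        truth.phenotypes[iid] = y
        pheno_rows[iid] = {"y": y, "sex": sexv}
    pheno = pd.DataFrame.from_dict(pheno_rows, orient="index")
    if not pheno_rows:
        pheno = pd.DataFrame(columns=["y", "sex"])
    pheno = pheno.reindex([i.id for i in pedigree])
    pheno.index.name = "id"

    cross = CrossData(
        pedigree=pedigree, phenotypes=pheno, genotypes=geno, gmap=gmap,
        cross_type=config.cross_type,
        heterogametic_sex=SEX_MALE,
        sex_chromosome=gmap.sex_chromosome,
    )
    return cross, truth


def _sex_of(pedigree: list[Individual], iid: str) -> str:
    for ind in pedigree:
        if ind.id == iid:
            return ind.sex
    raise KeyError(iid)


def true_predictors(truth: TruthRecord, cross: CrossData, chromosome: str,
                    position: float) -> pd.DataFrame:
    """True (a, d) codes for every mapping-generation individual at a position.

    a = +1/0/-1 and d = 0/1 from the true ordered origin state (AA/het/BB);
    the oracle the least-squares scan's predictors should converge to as
    markers become dense and informative.
    """
    chrom = cross.gmap.chromosome(chromosome)
    if not (0.0 <= position <= chrom.length + 1e-9):
        raise ValueError(f"position {position} outside chromosome {chromosome}")
    rows = {}
    for iid in cross.offspring_ids:
        sp, sm = truth.origin_state(iid, chromosome, position)
        a = (sp == "A") + (sm == "A") - 1
        d = 1 if sp != sm else 0
        rows[iid] = {"a": float(a), "d": float(d)}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "id"
    return out
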