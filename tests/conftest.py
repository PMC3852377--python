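import numpy as np
import pandas as pd
import pytest

from linecrossqtl import cross_data as cd
from linecrossqtl import sim_cross as sc


@pytest.fixture(scope="session")
def std_cross():
    """A mid-size fully informative F2 cross with one additive QTL."""
    cfg = sc.SimConfig(seed=101, chromosomes=[("1", 100.0, 21, "autosome")],
                       n_offspring=200, qtl=[sc.QtlSpec("1", 50.0, a=0.8)],
                       residual_sd=1.0)
    return sc.simulate_cross(cfg)


@pytest.fixture(scope="session")
def partial_cross():
    """A small cross with shared alleles between lines (partially informative)."""
    cfg = sc.SimConfig(seed=7, chromosomes=[("1", 12.0, 4, "autosome")], n_offspring=8,
                       allele_freqs={"A": {1: 0.7, 2: 0.3}, "B": {1: 0.2, 2: 0.5, 3: 0.3}},
                       residual_sd=1.0)
    return sc.simulate_cross(cfg)


def build_toy_cross(n_families: int = 1, offspring_per_family: int = 2,
                    n_markers: int = 2, genotyped: bool = False) -> cd.CrossData:
    """Hand-built F2 cross with ``n_families`` disjoint founder quartets.

    With ``genotyped=False`` every genotype is missing, which makes every HMM
    posterior uniform — handy for exact enumeration oracles.
    """
    pedigree = []
    oid = 0
    for f in range(n_families):
        a, b = f"A{2 * f + 1}", f"B{2 * f + 1}"
        pedigree.append(cd.Individual(a, sex="male", generation=cd.GEN_F0_A, line="A"))
        pedigree.append(cd.Individual(b, sex="female", generation=cd.GEN_F0_B, line="B"))
        s, d = f"F1s{f}", f"F1d{f}"
        pedigree.append(cd.Individual(s, sire=a, dam=b, sex="male", generation=cd.GEN_F1))
        pedigree.append(cd.Individual(d, sire=a, dam=b, sex="female", generation=cd.GEN_F1))
        for _ in range(offspring_per_family):
            oid += 1
            pedigree.append(cd.Individual(f"O{oid}", sire=s, dam=d,
                                          sex="female" if oid % 2 else "male",
                                          generation=cd.GEN_F2))
    markers = [f"m{j + 1}" for j in range(n_markers)]
    positions = np.linspace(0.0, 10.0 * (n_markers - 1), n_markers)
    gmap = cd.GeneticMap([cd.ChromosomeMap("1", "autosome", markers, positions)])
    ids = [i.id for i in pedigree]
    cols = [f"{m}_{k}" for m in markers for k in (1, 2)]
    geno = pd.DataFrame(0, index=pd.Index(ids, name="id"), columns=cols)
    if genotyped:
        for ind in pedigree:
            for m in markers:
                al = 1 if (ind.line == "A" or ind.generation == cd.GEN_F0_A) else 2
                if ind.generation in (cd.GEN_F0_A, cd.GEN_F0_B):
                    geno.loc[ind.id, [f"{m}_1", f"{m}_2"]] = al
    pheno = pd.DataFrame({"y": np.nan}, index=pd.Index(ids, name="id"))
    return cd.CrossData(pedigree=pedigree, phenotypes=pheno, genotypes=geno, gmap=gmap)
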