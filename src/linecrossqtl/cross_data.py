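"""Canonical cross data object, tabular file dialects, and validation.

The in-memory representation bundles pedigree, phenotypes, genotypes, and a
genetic map together with cross-level attributes (cross type, heterogametic
sex, sex chromosome).  All file formats are plain-text TSV dialects documented
in the reader/writer docstrings; a simplified CRI-MAP-style ``.gen`` reader is
also provided.

Missing-data conventions: genotype allele ``0`` means missing; a missing
phenotype is an empty field or ``NA``; an unknown parent is ``0`` or empty.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

SEX_FEMALE = "female"
SEX_MALE = "male"
SEX_UNKNOWN = "unknown"

GEN_F0_A = "F0_A"
GEN_F0_B = "F0_B"
GEN_F1 = "F1"
GEN_F2 = "F2"
GEN_BC = "BC"

_FOUNDER_GENERATIONS = (GEN_F0_A, GEN_F0_B)
_OFFSPRING_GENERATIONS = (GEN_F2, GEN_BC)


class CrossDataError(ValueError):
    """Raised for malformed input files or inconsistent cross data."""


@dataclass
class Finding:
    """A structured validation finding (never an exception)."""

    severity: str  # "error" | "warning"
    message: str
    location: str = ""

    def __str__(self) -> str:  # pragma: no cover - convenience
        loc = f" [{self.location}]" if self.location else ""
        return f"{self.severity.upper()}: {self.message}{loc}"


@dataclass
class Individual:
    id: str
    sire: Optional[str] = None
    dam: Optional[str] = None
    sex: str = SEX_UNKNOWN
    generation: Optional[str] = None
    line: Optional[str] = None  # founder line label ("A"/"B"), founders only

    @property
    def is_founder(self) -> bool:
        return self.sire is None and self.dam is None


@dataclass
class ChromosomeMap:
    name: str
    kind: str  # "autosome" | "sex"
    markers: list[str]
    positions: np.ndarray  # cM, strictly increasing

    @property
    def length(self) -> float:
        return float(self.positions[-1]) if len(self.positions) else 0.0


@dataclass
class GeneticMap:
    chromosomes: list[ChromosomeMap]

    def chromosome(self, name: str) -> ChromosomeMap:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"unknown chromosome {name!r}")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def marker_names(self) -> list[str]:
        return [m for c in self.chromosomes for m in c.markers]

    @property
    def sex_chromosome(self) -> Optional[str]:
        for c in self.chromosomes:
            if c.kind == "sex":
                return c.name
        return None

    def marker_position(self, marker: str) -> tuple[str, float]:
        for c in self.chromosomes:
            if marker in c.markers:
                return c.name, float(c.positions[c.markers.index(marker)])
        raise KeyError(f"unknown marker {marker!r}")


@dataclass
class CrossData:
    """Bundle of pedigree, phenotypes, genotypes, map, and cross attributes.

    ``genotypes`` is a DataFrame indexed by individual id with two integer
    columns per marker (``<marker>_1``, ``<marker>_2``; 0 = missing).
    ``phenotypes`` is a DataFrame indexed by individual id (numeric traits and
    covariates; non-numeric columns are treated as categorical fixed effects).
    ``results`` is an appendable store for analysis outputs.
    """

    pedigree: list[Individual]
    phenotypes: pd.DataFrame
    genotypes: pd.DataFrame
    gmap: GeneticMap
    cross_type: str = "F2"  # "F2" | "BC"
    heterogametic_sex: str = SEX_MALE
    sex_chromosome: Optional[str] = None
    results: dict = field(default_factory=dict)

    # -- lookups -----------------------------------------------------------
    def __post_init__(self) -> None:
        self._by_id = {ind.id: ind for ind in self.pedigree}

    def individual(self, iid: str) -> Individual:
        return self._by_id[iid]

    def has_individual(self, iid: str) -> bool:
        return iid in self._by_id

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.pedigree]

    def ids_in_generation(self, *generations: str) -> list[str]:
        return [i.id for i in self.pedigree if i.generation in generations]

    @property
    def founder_ids(self) -> list[str]:
        return self.ids_in_generation(*_FOUNDER_GENERATIONS)

    @property
    def f1_ids(self) -> list[str]:
        return self.ids_in_generation(GEN_F1)

    @property
    def offspring_ids(self) -> list[str]:
        """Mapping-generation individuals (F2 or BC)."""
        return self.ids_in_generation(*_OFFSPRING_GENERATIONS)

    def founders_of_line(self, line: str) -> list[str]:
        gen = GEN_F0_A if line == "A" else GEN_F0_B
        return [i.id for i in self.pedigree if i.generation == gen]

    def homogametic_ids(self, ids: Iterable[str]) -> list[str]:
        homo = SEX_FEMALE if self.heterogametic_sex == SEX_MALE else SEX_MALE
        return [i for i in ids if self.individual(i).sex == homo]

    def genotype(self, iid: str, marker: str) -> Optional[tuple[int, int]]:
        """Unordered allele pair, or None if missing/ungenotyped."""
        try:
            a1 = int(self.genotypes.at[iid, marker + "_1"])
            a2 = int(self.genotypes.at[iid, marker + "_2"])
        except KeyError:
            return None
        if a1 == 0 or a2 == 0:
            return None
        return (a1, a2) if a1 <= a2 else (a2, a1)


# ---------------------------------------------------------------------------
# pedigree utilities
# ---------------------------------------------------------------------------


def toposort_pedigree(pedigree: list[Individual]) -> list[Individual]:
    """Order so every parent precedes its offspring (stable Kahn's algorithm)."""
    by_id = {ind.id: ind for ind in pedigree}
    placed: set[str] = set()
    ordered: list[Individual] = []
    pending = list(pedigree)
    while pending:
        progress = False
        rest = []
        for ind in pending:
            parents = [p for p in (ind.sire, ind.dam) if p is not None and p in by_id]
            if all(p in placed for p in parents):
                ordered.append(ind)
                placed.add(ind.id)
                progress = True
            else:
                rest.append(ind)
        if not progress:
            cyc = ", ".join(i.id for i in rest[:5])
            raise CrossDataError(f"pedigree contains a cycle or unresolvable order near: {cyc}")
        pending = rest
    return ordered


def _color_founder_lines(pedigree: list[Individual]) -> dict[str, str]:
    """Assign founders to lines A/B by 2-coloring the F1 co-parent graph."""
    by_id = {i.id: i for i in pedigree}
    founders = [i.id for i in pedigree if i.is_founder]
    adj: dict[str, set[str]] = {f: set() for f in founders}
    for ind in pedigree:
        s, d = ind.sire, ind.dam
        if s in adj and d in adj and s is not None and d is not None:
            adj[s].add(d)
            adj[d].add(s)
    color: dict[str, str] = {}
    for f in founders:
        if by_id[f].line in ("A", "B"):
            color[f] = by_id[f].line
    for start in founders:
        if start in color:
            continue
        if not adj[start]:
            continue
        color[start] = "A"
        stack = [start]
        while stack:
            u = stack.pop()
            nxt = "B" if color[u] == "A" else "A"
            for v in adj[u]:
                if v not in color:
                    color[v] = nxt
                    stack.append(v)
    # propagate consistency over colored neighbors (conflicts handled in validate)
    return color


def infer_generations(pedigree: list[Individual]) -> list[Finding]:
    """Fill missing ``generation`` labels structurally; return findings.

    No parents -> F0 (line from 2-coloring of the mating graph);
    F0_A x F0_B -> F1; F1 x F1 -> F2; F1 x F0 -> BC.  Supplied labels are kept
    and checked; conflicts yield error-severity findings.
    """
    findings: list[Finding] = []
    by_id = {i.id: i for i in pedigree}
    lines = _color_founder_lines(pedigree)
    for ind in pedigree:  # assumes topological order
        inferred: Optional[str] = None
        if ind.is_founder:
            line = lines.get(ind.id)
            if line is None:
                findings.append(
                    Finding("warning", f"founder {ind.id} line not inferable; assuming line A", ind.id)
                )
                line = "A"
            ind.line = line
            inferred = GEN_F0_A if line == "A" else GEN_F0_B
        else:
            pg = []
            for p in (ind.sire, ind.dam):
                if p is None or p not in by_id:
                    pg.append(None)
                else:
                    pg.append(by_id[p].generation)
            gens = set(pg)
            if None in gens:
                findings.append(Finding("error", f"{ind.id} has a missing or unknown parent", ind.id))
            elif gens <= {GEN_F0_A, GEN_F0_B} and len(gens) == 2:
                inferred = GEN_F1
            elif gens == {GEN_F1}:
                inferred = GEN_F2
            elif GEN_F1 in gens and (gens & {GEN_F0_A, GEN_F0_B}):
                inferred = GEN_BC
            else:
                findings.append(
                    Finding("error", f"{ind.id}: parental generations {sorted(g for g in gens if g)} "
                            "do not form a supported cross", ind.id)
                )
        if ind.generation is None:
            ind.generation = inferred
        elif inferred is not None and ind.generation != inferred:
            findings.append(
                Finding("error",
                        f"{ind.id}: supplied generation {ind.generation} conflicts with "
                        f"structurally inferred {inferred}", ind.id)
            )
    return findings


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def validate_cross(cross: CrossData) -> list[Finding]:
    """Validate a CrossData; returns structured findings, never mutates input."""
    findings: list[Finding] = []
    by_id = {i.id: i for i in cross.pedigree}

    if len(by_id) != len(cross.pedigree):
        seen: set[str] = set()
        for ind in cross.pedigree:
            if ind.id in seen:
                findings.append(Finding("error", f"duplicate individual id {ind.id}", ind.id))
            seen.add(ind.id)

    placed: set[str] = set()
    for ind in cross.pedigree:
        for role, p in (("sire", ind.sire), ("dam", ind.dam)):
            if p is None:
                continue
            if p not in by_id:
                findings.append(Finding("error", f"{ind.id}: {role} {p} not in pedigree", ind.id))
            elif p not in placed:
                findings.append(Finding("error", f"{ind.id}: {role} {p} appears after offspring", ind.id))
        placed.add(ind.id)

    for ind in cross.pedigree:
        gen = ind.generation
        parents = [p for p in (ind.sire, ind.dam) if p in by_id]
        pgens = sorted(by_id[p].generation or "?" for p in parents)
        if gen in _FOUNDER_GENERATIONS and parents:
            findings.append(Finding("error", f"founder {ind.id} has recorded parents", ind.id))
        if gen == GEN_F1 and pgens != [GEN_F0_A, GEN_F0_B]:
            findings.append(Finding("error", f"F1 {ind.id} lacks one F0_A and one F0_B parent", ind.id))
        if gen == GEN_F2 and pgens != [GEN_F1, GEN_F1]:
            findings.append(Finding("error", f"F2 {ind.id} does not have two F1 parents", ind.id))
        if gen == GEN_BC:
            if len(pgens) != 2 or GEN_F1 not in pgens or not (set(pgens) & set(_FOUNDER_GENERATIONS)):
                findings.append(Finding("error", f"BC {ind.id} lacks one F1 and one F0 parent", ind.id))

    # map
    n_sex = 0
    for chrom in cross.gmap.chromosomes:
        if chrom.kind == "sex":
            n_sex += 1
        pos = np.asarray(chrom.positions, dtype=float)
        if len(pos) and pos[0] < 0:
            findings.append(Finding("error", f"negative position on {chrom.name}", chrom.name))
        bad = np.where(np.diff(pos) <= 0)[0]
        for i in bad:
            findings.append(
                Finding("error",
                        f"marker positions not strictly increasing on {chrom.name} at "
                        f"{chrom.markers[i + 1]}", f"{chrom.name}:{chrom.markers[i + 1]}")
            )
    if n_sex > 1:
        findings.append(Finding("error", "more than one sex chromosome in map", "map"))

    if (cross.sex_chromosome is not None) != (cross.gmap.sex_chromosome is not None):
        findings.append(Finding("error", "sex_chromosome attribute inconsistent with map", "attributes"))
    elif cross.sex_chromosome is not None and cross.sex_chromosome != cross.gmap.sex_chromosome:
        findings.append(Finding("error", "sex_chromosome attribute names a different chromosome than the map",
                                "attributes"))
    if cross.cross_type not in ("F2", "BC"):
        findings.append(Finding("error", f"unknown cross_type {cross.cross_type}", "attributes"))
    if cross.heterogametic_sex not in (SEX_MALE, SEX_FEMALE):
        findings.append(Finding("error", f"unknown heterogametic_sex {cross.heterogametic_sex}", "attributes"))

    # genotypes
    mapped = set(cross.gmap.marker_names)
    geno_markers = {c[:-2] for c in cross.genotypes.columns if c.endswith(("_1", "_2"))}
    for m in sorted(geno_markers - mapped):
        findings.append(Finding("error", f"genotype marker {m} not in map", m))
    for iid in cross.genotypes.index:
        if iid not in by_id:
            findings.append(Finding("error", f"genotyped individual {iid} not in pedigree", str(iid)))
    vals = cross.genotypes.to_numpy()
    if vals.size and (vals < 0).any():
        findings.append(Finding("error", "negative allele codes in genotype table", "genotypes"))

    # phenotypes
    cols = list(cross.phenotypes.columns)
    if len(set(cols)) != len(cols):
        findings.append(Finding("error", "duplicate phenotype column names", "phenotypes"))
    for iid in cross.phenotypes.index:
        if iid not in by_id:
            findings.append(Finding("error", f"phenotyped individual {iid} not in pedigree", str(iid)))

    return findings


def assert_valid(cross: CrossData) -> None:
    """Raise CrossDataError if validate_cross reports any error-severity finding."""
    errs = [f for f in validate_cross(cross) if f.severity == "error"]
    if errs:
        raise CrossDataError("invalid cross data:\n" + "\n".join(str(e) for e in errs))


# ---------------------------------------------------------------------------
# tabular dialect IO
# ---------------------------------------------------------------------------

_PED_FILE = "pedigree.tsv"
_GENO_FILE = "genotypes.tsv"
_MAP_FILE = "map.tsv"
_PHENO_FILE = "phenotypes.tsv"
_ATTR_FILE = "attributes.txt"


def _clean_token(tok) -> Optional[str]:
    if tok is None:
        return None
    s = str(tok).strip()
    if s in ("", "0", "NA", "nan"):
        return None
    return s


def read_map(map_path: str | os.PathLike) -> GeneticMap:
    """Read the map dialect: TSV ``chromosome marker position_cM kind``."""
    try:
        df = pd.read_csv(map_path, sep="\t", dtype={"chromosome": str, "marker": str})
    except Exception as exc:
        raise CrossDataError(f"{map_path}: cannot parse map file: {exc}") from exc
    needed = {"chromosome", "marker", "position_cM", "kind"}
    if not needed <= set(df.columns):
        raise CrossDataError(f"{map_path}: map file needs columns {sorted(needed)}")
    chroms: list[ChromosomeMap] = []
    for name, grp in df.groupby("chromosome", sort=False):
        kinds = set(grp["kind"])
        if len(kinds) != 1:
            raise CrossDataError(f"{map_path}: chromosome {name} has mixed kinds {sorted(kinds)}")
        chroms.append(ChromosomeMap(str(name), kinds.pop(), list(grp["marker"]),
                                    grp["position_cM"].to_numpy(dtype=float)))
    return GeneticMap(chroms)


def _read_pedigree(path: str | os.PathLike) -> list[Individual]:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:
        raise CrossDataError(f"{path}: cannot parse pedigree file: {exc}") from exc
    for col in ("id", "sire", "dam", "sex"):
        if col not in df.columns:
            raise CrossDataError(f"{path}: pedigree file missing column {col!r}")
    peds = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        iid = str(row.id).strip()
        if not iid:
            raise CrossDataError(f"{path}:{lineno}: empty individual id")
        sex = str(row.sex).strip().lower() or SEX_UNKNOWN
        if sex not in (SEX_FEMALE, SEX_MALE, SEX_UNKNOWN):
            raise CrossDataError(f"{path}:{lineno}: bad sex code {row.sex!r}")
        peds.append(Individual(
            id=iid,
            sire=_clean_token(getattr(row, "sire")),
            dam=_clean_token(getattr(row, "dam")),
            sex=sex,
            generation=_clean_token(getattr(row, "generation", None)),
            line=_clean_token(getattr(row, "line", None)),
        ))
    return peds


def _read_attributes(path: str | os.PathLike) -> dict[str, str]:
    attrs: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise CrossDataError(f"{path}:{lineno}: expected key=value, got {line!r}")
            k, v = line.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def read_cross(
    pedigree_path: str | os.PathLike,
    genotype_path: str | os.PathLike,
    map_path: str | os.PathLike,
    phenotype_path: str | os.PathLike,
    attributes: dict[str, str] | str | os.PathLike | None = None,
) -> CrossData:
    """Read and validate a cross from the documented tabular dialects.

    ``attributes`` may be a dict or a path to a key=value text file.
    Generation labels are inferred from pedigree structure when not supplied.
    Raises CrossDataError on parse failures or error-severity findings.
    """
    if attributes is None:
        attrs: dict[str, str] = {}
    elif isinstance(attributes, dict):
        attrs = dict(attributes)
    else:
        attrs = _read_attributes(attributes)

    gmap = read_map(map_path)
    pedigree = toposort_pedigree(_read_pedigree(pedigree_path))

    try:
        geno = pd.read_csv(genotype_path, sep="\t", dtype={"id": str}).set_index("id")
    except Exception as exc:
        raise CrossDataError(f"{genotype_path}: cannot parse genotype file: {exc}") from exc
    geno = geno.astype(int)

    try:
        pheno = pd.read_csv(phenotype_path, sep="\t", dtype={"id": str},
                            na_values=["NA", ""]).set_index("id")
    except Exception as exc:
        raise CrossDataError(f"{phenotype_path}: cannot parse phenotype file: {exc}") from exc

    gen_findings = infer_generations(pedigree)

    cross = CrossData(
        pedigree=pedigree,
        phenotypes=pheno,
        genotypes=geno,
        gmap=gmap,
        cross_type=attrs.get("cross_type", "F2"),
        heterogametic_sex=attrs.get("heterogametic_sex", SEX_MALE),
        sex_chromosome=attrs.get("sex_chromosome") or gmap.sex_chromosome,
    )
    errs = [f for f in gen_findings + validate_cross(cross) if f.severity == "error"]
    if errs:
        raise CrossDataError("invalid cross data:\n" + "\n".join(str(e) for e in errs))
    return cross


def write_cross(cross: CrossData, directory: str | os.PathLike, force: bool = False) -> list[Path]:
    """Write the five tabular files; ``read_cross`` on them reproduces the object.

    Refuses to overwrite existing files unless ``force`` is True.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = [d / n for n in (_PED_FILE, _GENO_FILE, _MAP_FILE, _PHENO_FILE, _ATTR_FILE)]
    if not force:
        clash = [p for p in paths if p.exists()]
        if clash:
            raise CrossDataError(f"refusing to overwrite {clash[0]} (pass force=True)")

    ped = pd.DataFrame(
        {
            "id": [i.id for i in cross.pedigree],
            "sire": [i.sire or "0" for i in cross.pedigree],
            "dam": [i.dam or "0" for i in cross.pedigree],
            "sex": [i.sex for i in cross.pedigree],
            "generation": [i.generation or "" for i in cross.pedigree],
            "line": [i.line or "" for i in cross.pedigree],
        }
    )
    ped.to_csv(paths[0], sep="\t", index=False)
    cross.genotypes.rename_axis("id").to_csv(paths[1], sep="\t")
    rows = []
    for c in cross.gmap.chromosomes:
        for m, p in zip(c.markers, c.positions):
            rows.append((c.name, m, float(p), c.kind))
    pd.DataFrame(rows, columns=["chromosome", "marker", "position_cM", "kind"]).to_csv(
        paths[2], sep="\t", index=False)
    cross.phenotypes.rename_axis("id").to_csv(paths[3], sep="\t", na_rep="NA")
    with open(paths[4], "w") as fh:
        fh.write(f"cross_type={cross.cross_type}\n")
        fh.write(f"heterogametic_sex={cross.heterogametic_sex}\n")
        if cross.sex_chromosome:
            fh.write(f"sex_chromosome={cross.sex_chromosome}\n")
    return paths


def read_cross_dir(directory: str | os.PathLike) -> CrossData:
    """Read a cross from a directory written by :func:`write_cross`."""
    d = Path(directory)
    return read_cross(d / _PED_FILE, d / _GENO_FILE, d / _MAP_FILE, d / _PHENO_FILE,
                      d / _ATTR_FILE)


# ---------------------------------------------------------------------------
# simplified CRI-MAP-style .gen dialect
# ---------------------------------------------------------------------------

_SEX_TO_GEN = {SEX_MALE: "1", SEX_FEMALE: "0", SEX_UNKNOWN: "3"}
_GEN_TO_SEX = {"1": SEX_MALE, "0": SEX_FEMALE, "3": SEX_UNKNOWN}


def read_crimap_gen(gen_path: str | os.PathLike, map_path: str | os.PathLike,
                    attributes: dict[str, str] | None = None) -> CrossData:
    """Read the simplified CRI-MAP-style ``.gen`` dialect.

    Layout: line 1 = number of families; per family a family-name line, a
    member-count line, then per member the record ``id dam sire sex`` followed
    by one whitespace-separated allele pair per mapped locus in map order
    (``0 0`` = missing).  Whitespace and line breaks are free within a member
    record.  Family blocks are concatenated into one pedigree.
    """
    gmap = read_map(map_path)
    markers = gmap.marker_names
    n_loci = len(markers)

    with open(gen_path) as fh:
        tokens = fh.read().split()
    pos = 0

    def take(n: int, what: str, block: str) -> list[str]:
        nonlocal pos
        if pos + n > len(tokens):
            raise CrossDataError(f"{gen_path}: family {block!r}: truncated while reading {what} "
                                 f"(declared member/locus counts disagree with records)")
        out = tokens[pos:pos + n]
        pos += n
        return out

    if not tokens:
        raise CrossDataError(f"{gen_path}: empty file")
    try:
        n_fam = int(tokens[0])
    except ValueError:
        raise CrossDataError(f"{gen_path}: first token must be the family count") from None
    pos = 1

    pedigree: list[Individual] = []
    geno_rows: dict[str, list[int]] = {}
    for _ in range(n_fam):
        fam = take(1, "family name", "?")[0]
        try:
            n_mem = int(take(1, "member count", fam)[0])
        except ValueError:
            raise CrossDataError(f"{gen_path}: family {fam!r}: bad member count") from None
        for _ in range(n_mem):
            iid, dam, sire, sexcode = take(4, "member record", fam)
            if sexcode not in _GEN_TO_SEX:
                raise CrossDataError(f"{gen_path}: family {fam!r}: bad sex code {sexcode!r} for {iid}")
            alleles = take(2 * n_loci, f"genotypes of {iid}", fam)
            try:
                geno_rows[iid] = [int(a) for a in alleles]
            except ValueError:
                raise CrossDataError(f"{gen_path}: family {fam!r}: non-integer allele for {iid}") from None
            pedigree.append(Individual(id=iid, sire=_clean_token(sire), dam=_clean_token(dam),
                                       sex=_GEN_TO_SEX[sexcode]))
    if pos != len(tokens):
        raise CrossDataError(f"{gen_path}: {len(tokens) - pos} trailing tokens after last declared family "
                             "(declared member/locus counts disagree with records)")

    pedigree = toposort_pedigree(pedigree)
    gen_findings = infer_generations(pedigree)
    cols = [f"{m}_{k}" for m in markers for k in (1, 2)]
    geno = pd.DataFrame.from_dict(geno_rows, orient="index", columns=cols)
    geno = geno.loc[[i.id for i in pedigree]]
    geno.index.name = "id"
    pheno = pd.DataFrame(index=pd.Index([i.id for i in pedigree], name="id"))

    attrs = dict(attributes or {})
    cross = CrossData(
        pedigree=pedigree, phenotypes=pheno, genotypes=geno, gmap=gmap,
        cross_type=attrs.get("cross_type", "F2"),
        heterogametic_sex=attrs.get("heterogametic_sex", SEX_MALE),
        sex_chromosome=attrs.get("sex_chromosome") or gmap.sex_chromosome,
    )
    errs = [f for f in gen_findings + validate_cross(cross) if f.severity == "error"]
    if errs:
        raise CrossDataError("invalid cross data:\n" + "\n".join(str(e) for e in errs))
    return cross


def write_crimap_gen(cross: CrossData, gen_path: str | os.PathLike) -> None:
    """Write the genotypes of a cross in the simplified ``.gen`` dialect (one family)."""
    markers = cross.gmap.marker_names
    with open(gen_path, "w") as fh:
        fh.write("1\nfam1\n")
        fh.write(f"{len(cross.pedigree)}\n")
        for ind in cross.pedigree:
            fh.write(f"{ind.id} {ind.dam or 0} {ind.sire or 0} {_SEX_TO_GEN[ind.sex]}\n")
            pairs = []
            for m in markers:
                g = cross.genotype(ind.id, m)
                pairs.append("0 0" if g is None else f"{g[0]} {g[1]}")
            fh.write(" ".join(pairs) + "\n")


def crosses_equal(a: CrossData, b: CrossData) -> bool:
    """Field-by-field equality used by the round-trip tests."""
    if [i.__dict__ for i in a.pedigree] != [i.__dict__ for i in b.pedigree]:
        return False
    if not a.genotypes.sort_index().equals(b.genotypes.sort_index().astype(a.genotypes.dtypes.to_dict())):
        return False
    try:
        pd.testing.assert_frame_equal(a.phenotypes.sort_index(), b.phenotypes.sort_index(),
                                      check_dtype=False)
    except AssertionError:
        return False
    if a.gmap.names != b.gmap.names:
        return False
    for ca, cb in zip(a.gmap.chromosomes, b.gmap.chromosomes):
        if ca.markers != cb.markers or ca.kind != cb.kind:
            return False
        if not np.allclose(ca.positions, cb.positions):
            return False
    return (a.cross_type, a.heterogametic_sex, a.sex_chromosome) == \
           (b.cross_type, b.heterogametic_sex, b.sex_chromosome)
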