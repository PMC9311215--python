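"""Canonical data model, standard-format IO, and locus/individual filtering.

The in-memory genotype container is a dense individuals x loci matrix of
alt-allele dosages (0, 1, 2) with an explicit missing sentinel.  Loci are
unordered de-novo markers (GBS rad-tags); no genomic coordinate system is
assumed.  All downstream statistics consult the missing mask explicitly —
nothing here imputes silently.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

#: Sentinel for a missing diploid genotype call (outside {0, 1, 2}).
MISSING = -1


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix (individuals x loci) with identifiers.

    Attributes
    ----------
    genotypes : ndarray of int8, shape (n_individuals, n_loci)
        Alt-allele dosage 0/1/2; :data:`MISSING` marks a missing call.
    locus_ids : ndarray of str
        Unique opaque locus identifiers.
    tag_ids : ndarray of str
        Per-locus rad-tag (linkage group) identifier; several SNPs may share
        one tag.
    individual_ids : ndarray of str
    """

    genotypes: np.ndarray
    locus_ids: np.ndarray
    tag_ids: np.ndarray
    individual_ids: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.locus_ids = np.asarray(self.locus_ids, dtype=object)
        self.tag_ids = np.asarray(self.tag_ids, dtype=object)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (individuals x loci)")
        n_ind, n_loc = self.genotypes.shape
        if len(self.locus_ids) != n_loc or len(self.tag_ids) != n_loc:
            raise ValueError("locus_ids/tag_ids length mismatch with genotypes")
        if len(self.individual_ids) != n_ind:
            raise ValueError("individual_ids length mismatch with genotypes")
        if len(set(self.locus_ids)) != n_loc:
            raise ValueError("locus_ids must be unique")
        valid = (self.genotypes == MISSING) | (
            (self.genotypes >= 0) & (self.genotypes <= 2)
        )
        if not valid.all():
            raise ValueError("genotype entries must be 0, 1, 2 or MISSING")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.genotypes != MISSING

    def subset(self, individuals=None, loci=None) -> "GenotypeMatrix":
        """Return a copy restricted to the given index arrays (order kept)."""
        ind = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        loc = np.arange(self.n_loci) if loci is None else np.asarray(loci)
        return GenotypeMatrix(
            genotypes=self.genotypes[np.ix_(ind, loc)].copy(),
            locus_ids=self.locus_ids[loc].copy(),
            tag_ids=self.tag_ids[loc].copy(),
            individual_ids=self.individual_ids[ind].copy(),
        )

    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per locus over non-missing calls (NaN if none)."""
        called = self.called
        alt = np.where(called, self.genotypes, 0).sum(axis=0)
        tot = 2 * called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)


@dataclass
class PopulationMap:
    """Assignment of each individual to a population and a group (clade)."""

    individuals: np.ndarray
    populations: np.ndarray
    groups: np.ndarray

    def __post_init__(self) -> None:
        self.individuals = np.asarray(self.individuals, dtype=object)
        self.populations = np.asarray(self.populations, dtype=object)
        self.groups = np.asarray(self.groups, dtype=object)
        if not (len(self.individuals) == len(self.populations) == len(self.groups)):
            raise ValueError("individuals/populations/groups must be parallel arrays")
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicate individual in population map")
        # a population must sit inside exactly one group
        pop_group: dict[str, str] = {}
        for p, g in zip(self.populations, self.groups):
            if p in pop_group and pop_group[p] != g:
                raise ValueError(f"population {p!r} assigned to multiple groups")
            pop_group[p] = g
        self._pop_group = pop_group
        self._pop_of = dict(zip(self.individuals, self.populations))
        self._group_of = dict(zip(self.individuals, self.groups))

    @property
    def population_ids(self) -> list:
        seen: dict = {}
        for p in self.populations:
            seen.setdefault(p, None)
        return list(seen)

    @property
    def group_ids(self) -> list:
        seen: dict = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)

    def group_of_population(self, pop) -> str:
        return self._pop_group[pop]

    def population_of(self, individual) -> str:
        return self._pop_of[individual]

    def group_of(self, individual) -> str:
        return self._group_of[individual]

    def indices_by_population(self, g: GenotypeMatrix) -> dict:
        """Map population -> row indices into ``g`` (order of ``g`` rows)."""
        missing = [i for i in g.individual_ids if i not in self._pop_of]
        if missing:
            raise ValueError(f"individuals without population assignment: {missing[:5]}")
        out: dict = {p: [] for p in self.population_ids}
        for row, ind in enumerate(g.individual_ids):
            out[self._pop_of[ind]].append(row)
        return {p: np.asarray(ix, dtype=int) for p, ix in out.items() if len(ix)}

    def indices_by_group(self, g: GenotypeMatrix) -> dict:
        out: dict = {gr: [] for gr in self.group_ids}
        for row, ind in enumerate(g.individual_ids):
            out[self._group_of[ind]].append(row)
        return {gr: np.asarray(ix, dtype=int) for gr, ix in out.items() if len(ix)}

    def subset(self, individuals) -> "PopulationMap":
        keep = set(individuals)
        mask = np.array([i in keep for i in self.individuals])
        return PopulationMap(
            self.individuals[mask], self.populations[mask], self.groups[mask]
        )


@dataclass
class FilterConfig:
    """Locus/individual filter thresholds.

    Order of application is fixed: individual missingness, locus missingness,
    one SNP per tag, minor-allele frequency.
    """

    maf_min: float = 0.05
    indiv_missing_max: float = 0.90
    locus_missing_max: float = 0.30
    one_snp_per_tag: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("maf_min", "indiv_missing_max", "locus_missing_max"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class FilterReport:
    """Per-step removal counts from :func:`apply_filters`."""

    n_individuals_in: int
    n_loci_in: int
    individuals_removed_missing: int = 0
    loci_removed_missing: int = 0
    loci_removed_tag_thinning: int = 0
    loci_removed_maf: int = 0
    n_individuals_out: int = 0
    n_loci_out: int = 0

    def check_totals(self) -> bool:
        return (
            self.n_loci_in
            == self.n_loci_out
            + self.loci_removed_missing
            + self.loci_removed_tag_thinning
            + self.loci_removed_maf
        ) and (
            self.n_individuals_in
            == self.n_individuals_out + self.individuals_removed_missing
        )


# ---------------------------------------------------------------------------
# VCF IO
# ---------------------------------------------------------------------------

def _tag_from_record(rec) -> str:
    # de-novo pipelines (Stacks) emit one rad-tag per pseudo-contig, so CHROM
    # identifies the tag; fall back to the ID prefix before a separator.
    if rec.chrom not in (None, "", "."):
        return str(rec.chrom)
    rid = rec.id or ""
    for sep in (":", "_", "|"):
        if sep in rid:
            return rid.split(sep, 1)[0]
    return rid or "tag0"


def read_vcf(path: str) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Multiallelic records are skipped (count logged).  Genotypes are encoded
    as alt-allele dosage; any missing allele marks the call missing.
    """
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read VCF at {path!r}: {exc}") from exc
    samples = list(vf.header.samples)
    rows: list[np.ndarray] = []
    locus_ids: list[str] = []
    tag_ids: list[str] = []
    n_multi = 0
    for rec in vf:
        alts = rec.alts or ()
        if len(alts) != 1:
            n_multi += 1
            continue
        dosage = np.empty(len(samples), dtype=np.int8)
        for i, s in enumerate(samples):
            gt = rec.samples[s].get("GT")
            if gt is None or any(a is None for a in gt):
                dosage[i] = MISSING
            else:
                dosage[i] = sum(int(a > 0) for a in gt)
        rows.append(dosage)
        locus_ids.append(rec.id if rec.id not in (None, ".") else f"{rec.chrom}:{rec.pos}")
        tag_ids.append(_tag_from_record(rec))
    vf.close()
    if n_multi:
        logger.info("read_vcf: skipped %d non-biallelic records", n_multi)
    if not rows:
        raise ValueError(f"no usable biallelic SNP records in {path!r}")
    return GenotypeMatrix(
        genotypes=np.stack(rows, axis=1),
        locus_ids=np.array(locus_ids, dtype=object),
        tag_ids=np.array(tag_ids, dtype=object),
        individual_ids=np.array(samples, dtype=object),
    )


def write_vcf(g: GenotypeMatrix, path: str) -> None:
    """Write the dosage matrix as a minimal VCF (REF=A, ALT=T placeholders).

    Positions are synthesised (loci are unordered de-novo markers); locus and
    tag identity round-trip through the ID and CHROM columns.
    """
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    seen = []
    seen_set = set()
    for t in g.tag_ids:
        if t not in seen_set:
            seen.append(t)
            seen_set.add(t)
    for t in seen:
        header.add_line(f"##contig=<ID={t}>")
    for s in g.individual_ids:
        header.add_sample(str(s))
    pos_in_tag: dict = {}
    with pysam.VariantFile(path, "w", header=header) as out:
        for j in range(g.n_loci):
            tag = g.tag_ids[j]
            pos_in_tag[tag] = pos_in_tag.get(tag, 0) + 1
            rec = out.new_record(
                contig=str(tag),
                start=pos_in_tag[tag] - 1,
                alleles=("A", "T"),
                id=str(g.locus_ids[j]),
            )
            for i, s in enumerate(g.individual_ids):
                d = g.genotypes[i, j]
                if d == MISSING:
                    rec.samples[str(s)]["GT"] = (None, None)
                else:
                    rec.samples[str(s)]["GT"] = ((0, 0), (0, 1), (1, 1))[d]
            out.write(rec)


# ---------------------------------------------------------------------------
# Tables: population map, environment, distances, results
# ---------------------------------------------------------------------------

def read_popmap(path: str) -> PopulationMap:
    """Read a 2-3 column TSV: individual, population[, group]."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if df.shape[1] == 2:
        df[2] = df[1]
    if df.shape[1] < 2:
        raise ValueError(f"population map {path!r} needs >=2 columns")
    # tolerate a header row
    if str(df.iloc[0, 0]).lower() in ("individual", "individual_id", "sample"):
        df = df.iloc[1:]
    return PopulationMap(
        df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), df.iloc[:, 2].to_numpy()
    )


def write_popmap(pm: PopulationMap, path: str) -> None:
    pd.DataFrame(
        {"individual": pm.individuals, "population": pm.populations, "group": pm.groups}
    ).to_csv(path, sep="\t", header=False, index=False)


def read_env_table(path: str) -> pd.DataFrame:
    """Environment CSV: first column population_id, remaining numeric."""
    df = pd.read_csv(path)
    df = df.set_index(df.columns[0])
    df.index.name = "population"
    return df.astype(float)


def read_distance_matrix(path: str) -> pd.DataFrame:
    """Square CSV of pairwise geographic distances (km) with population header."""
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1] or list(df.index) != list(df.columns):
        raise ValueError("distance matrix must be square with matching labels")
    return df.astype(float)


def write_results(table: pd.DataFrame, path: str) -> None:
    """Write a scan/candidate table as TSV (q-values at >=6 sig digits)."""
    if table is None or len(table) == 0:
        raise ValueError("refusing to write an empty results table")
    try:
        table.to_csv(path, sep="\t", index=False, float_format="%.8g")
    except OSError as exc:
        raise OSError(f"cannot write results to {path!r}: {exc}") from exc


def read_results(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def apply_filters(
    g: GenotypeMatrix, pm: PopulationMap, cfg: FilterConfig
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the standard GBS filter cascade and return (matrix, report).

    Steps, in order: (1) drop individuals with call missingness above
    ``indiv_missing_max``; (2) drop loci with missingness above
    ``locus_missing_max``; (3) keep one random SNP per rad-tag (seeded);
    (4) drop loci with minor-allele frequency below ``maf_min`` computed over
    all remaining non-missing calls pooled across populations.
    """
    report = FilterReport(n_individuals_in=g.n_individuals, n_loci_in=g.n_loci)

    # step 1: individuals
    miss_ind = 1.0 - g.called.mean(axis=1)
    keep_ind = np.flatnonzero(miss_ind <= cfg.indiv_missing_max)
    report.individuals_removed_missing = g.n_individuals - len(keep_ind)
    if len(keep_ind) == 0:
        raise ValueError("all individuals removed at the individual-missingness step")
    g = g.subset(individuals=keep_ind)

    # step 2: locus missingness (recomputed after individual removal)
    miss_loc = 1.0 - g.called.mean(axis=0)
    keep_loc = np.flatnonzero(miss_loc <= cfg.locus_missing_max)
    report.loci_removed_missing = g.n_loci - len(keep_loc)
    if len(keep_loc) == 0:
        raise ValueError("all loci removed at the locus-missingness step")
    g = g.subset(loci=keep_loc)

    # step 3: one SNP per tag, chosen at random but reproducibly
    if cfg.one_snp_per_tag:
        rng = np.random.default_rng(cfg.seed)
        chosen = []
        tags = pd.Series(range(g.n_loci)).groupby(pd.Series(g.tag_ids), sort=True)
        for _tag, idx in tags:
            idx = idx.to_numpy()
            chosen.append(idx[rng.integers(len(idx))])
        keep_loc = np.sort(np.asarray(chosen))
        report.loci_removed_tag_thinning = g.n_loci - len(keep_loc)
        g = g.subset(loci=keep_loc)

    # step 4: MAF over pooled non-missing calls
    p = g.allele_freq()
    maf = np.minimum(p, 1.0 - p)
    keep_loc = np.flatnonzero(np.nan_to_num(maf, nan=-1.0) >= cfg.maf_min)
    report.loci_removed_maf = g.n_loci - len(keep_loc)
    if len(keep_loc) == 0:
        raise ValueError("all loci removed at the MAF step")
    g = g.subset(loci=keep_loc)

    report.n_individuals_out = g.n_individuals
    report.n_loci_out = g.n_loci
    return g, report


def drop_population_missing_loci(
    g: GenotypeMatrix, pm: PopulationMap
) -> tuple[GenotypeMatrix, dict]:
    """Remove loci with zero non-missing calls in at least one population.

    Returns the filtered matrix and a report mapping the number of
    populations a locus was absent from to the count of such loci
    (e.g. ``{1: 73, 2: 10}``).
    """
    pops = pm.indices_by_population(g)
    if len(pops) < 2:
        raise ValueError("need >=2 populations")
    n_missing_pops = np.zeros(g.n_loci, dtype=int)
    for _pop, idx in pops.items():
        n_missing_pops += ~g.called[idx].any(axis=0)
    report: dict[int, int] = {}
    for k in range(1, len(pops) + 1):
        c = int((n_missing_pops == k).sum())
        if c:
            report[k] = c
    keep = np.flatnonzero(n_missing_pops == 0)
    return g.subset(loci=keep), report
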