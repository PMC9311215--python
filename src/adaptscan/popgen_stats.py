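"""Demographic-pattern statistics: diversity, differentiation, spectra, PCA,
directional relative migration, and the migration-distance correlation.

Diversity and differentiation follow Nei's gene-diversity framework
(Hs = within-population gene diversity, Ht = overall gene diversity,
Fst = (Ht - Hs)/Ht, Fis = 1 - Ho/Hs), with multi-locus values formed as
ratios of per-locus averages.  Pairwise differentiation uses the Weir &
Cockerham (1984) variance-component estimator theta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MISSING, GenotypeMatrix, PopulationMap


# ---------------------------------------------------------------------------
# Per-population allele counting helpers
# ---------------------------------------------------------------------------

def _pop_counts(g: GenotypeMatrix, idx: np.ndarray):
    """Return (n_called_individuals, alt_allele_count, het_count) per locus."""
    sub = g.genotypes[idx]
    called = sub != MISSING
    n = called.sum(axis=0)
    alt = np.where(called, sub, 0).sum(axis=0)
    het = ((sub == 1) & called).sum(axis=0)
    return n, alt, het


@dataclass
class DiversityStats:
    """Multi-locus Nei diversity and differentiation summary."""

    ho: float   # mean observed heterozygosity
    hs: float   # mean within-population gene diversity
    ht: float   # overall gene diversity
    fst: float  # (ht - hs) / ht, ratio of per-locus averages
    fis: float  # 1 - ho / hs
    per_locus: pd.DataFrame | None = None


def diversity(g: GenotypeMatrix, pm: PopulationMap, per_locus: bool = False) -> DiversityStats:
    """Nei diversity statistics over all populations.

    Per locus and population with n called diploids and alt frequency p:
    Ho = het/n, gene diversity h = 2p(1-p) * 2n/(2n-1) (unbiased, allele-count
    correction).  Ho and Hs are unweighted means over populations; Ht is
    2*pbar*(1-pbar) from the unweighted mean of population frequencies.
    Multi-locus Fst and Fis are ratios of per-locus averages.
    """
    pops = pm.indices_by_population(g)
    if len(pops) < 2:
        raise ValueError("need >=2 populations")
    L = g.n_loci
    ho_acc = np.zeros(L)
    hs_acc = np.zeros(L)
    p_acc = np.zeros(L)
    n_pops_called = np.zeros(L)
    for pop, idx in pops.items():
        n, alt, het = _pop_counts(g, idx)
        if n.max(initial=0) < 2:
            raise ValueError(f"population {pop!r} has <2 called individuals at every locus")
        ok = n > 0
        p = np.where(ok, alt / np.maximum(2 * n, 1), np.nan)
        h = 2.0 * p * (1.0 - p) * (2 * n) / np.maximum(2 * n - 1, 1)
        ho_acc += np.where(ok, het / np.maximum(n, 1), 0.0)
        hs_acc += np.where(ok, h, 0.0)
        p_acc += np.where(ok, p, 0.0)
        n_pops_called += ok
    if (n_pops_called == 0).any():
        raise ValueError("some loci have no called individuals in any population")
    ho_l = ho_acc / n_pops_called
    hs_l = hs_acc / n_pops_called
    pbar = p_acc / n_pops_called
    ht_l = 2.0 * pbar * (1.0 - pbar)
    ho, hs, ht = ho_l.mean(), hs_l.mean(), ht_l.mean()
    fst = (ht - hs) / ht if ht > 0 else float("nan")
    fis = 1.0 - ho / hs if hs > 0 else float("nan")
    pl = None
    if per_locus:
        pl = pd.DataFrame(
            {"locus_id": g.locus_ids, "ho": ho_l, "hs": hs_l, "ht": ht_l}
        )
    return DiversityStats(float(ho), float(hs), float(ht), float(fst), float(fis), pl)


# ---------------------------------------------------------------------------
# Weir & Cockerham pairwise Fst
# ---------------------------------------------------------------------------

def pairwise_wc_fst(
    g: GenotypeMatrix, pm: PopulationMap, pop_a: str, pop_b: str
) -> tuple[pd.Series, float]:
    """Weir & Cockerham (1984) theta for one population pair.

    Returns per-locus theta (NaN where undefined: monomorphic in the pair or
    insufficient calls) and the multi-locus theta as the ratio of summed
    variance components sum(a) / sum(a+b+c).
    """
    pops = pm.indices_by_population(g)
    for p in (pop_a, pop_b):
        if p not in pops:
            raise ValueError(f"population {p!r} not present in the genotype matrix")
    n1, alt1, het1 = _pop_counts(g, pops[pop_a])
    n2, alt2, het2 = _pop_counts(g, pops[pop_b])
    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = alt1 / (2.0 * n1)
        p2 = alt2 / (2.0 * n2)
        h1 = het1 / n1
        h2 = het2 / n2
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0
        denom = a + b + c
        theta = a / denom
    usable = (n1 >= 1) & (n2 >= 1) & (nbar > 1)
    poly = usable & (pbar > 0) & (pbar < 1)
    theta = np.where(poly & (denom != 0), theta, np.nan)
    if not poly.any():
        raise ValueError(f"no shared polymorphic loci between {pop_a!r} and {pop_b!r}")
    mean_theta = float(np.nansum(np.where(poly, a, 0.0)) / np.nansum(np.where(poly, denom, 0.0)))
    return pd.Series(theta, index=pd.Index(g.locus_ids, name="locus_id")), mean_theta


# ---------------------------------------------------------------------------
# Allele frequency spectra
# ---------------------------------------------------------------------------

def population_sfs(
    g: GenotypeMatrix, pm: PopulationMap, pop: str, mode: str = "folded"
) -> pd.Series:
    """Allele frequency spectrum for one population.

    Only loci fully called in the population contribute (listwise exclusion;
    no hypergeometric projection).  Classes are alt-allele counts (unfolded,
    0..2n) or minor-allele counts (folded, 0..n) over 2n haplotypes.
    Class 0 holds monomorphic loci, excluded from the polymorphic total.
    """
    if mode not in ("folded", "unfolded"):
        raise ValueError("mode must be 'folded' or 'unfolded'")
    pops = pm.indices_by_population(g)
    if pop not in pops:
        raise ValueError(f"population {pop!r} is empty or unknown")
    sub = g.genotypes[pops[pop]]
    complete = (sub != MISSING).all(axis=0)
    sub = sub[:, complete]
    n_ind = sub.shape[0]
    n_hap = 2 * n_ind
    alt = sub.sum(axis=0)
    if mode == "folded":
        counts = np.minimum(alt, n_hap - alt)
        classes = np.arange(n_hap // 2 + 1)
    else:
        counts = alt
        classes = np.arange(n_hap + 1)
    sfs = np.bincount(counts, minlength=len(classes))[: len(classes)]
    out = pd.Series(sfs, index=pd.Index(classes, name="allele_count"), name=pop)
    out.attrs["n_haplotypes"] = n_hap
    out.attrs["n_loci"] = int(complete.sum())
    out.attrs["n_polymorphic"] = int(sfs[1:].sum()) if mode == "folded" else int(
        sfs[1:-1].sum()
    )
    return out


def joint_sfs(
    g: GenotypeMatrix, pm: PopulationMap, group_a: str, group_b: str
) -> pd.DataFrame:
    """2-D allele frequency spectrum between two groups (clades).

    Grid cell (i, j) counts loci with alt-allele count i in group A and j in
    group B, over loci fully called in both groups.
    """
    groups = pm.indices_by_group(g)
    for gr in (group_a, group_b):
        if gr not in groups:
            raise ValueError(f"group {gr!r} is empty or unknown")
    sub_a = g.genotypes[groups[group_a]]
    sub_b = g.genotypes[groups[group_b]]
    complete = (sub_a != MISSING).all(axis=0) & (sub_b != MISSING).all(axis=0)
    alt_a = sub_a[:, complete].sum(axis=0)
    alt_b = sub_b[:, complete].sum(axis=0)
    na, nb = 2 * sub_a.shape[0], 2 * sub_b.shape[0]
    grid = np.zeros((na + 1, nb + 1), dtype=int)
    np.add.at(grid, (alt_a, alt_b), 1)
    return pd.DataFrame(
        grid,
        index=pd.Index(range(na + 1), name=group_a),
        columns=pd.Index(range(nb + 1), name=group_b),
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca(g: GenotypeMatrix, n_axes: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the genotype matrix (individuals as observations).

    Missing entries are mean-imputed per locus for this operation only.
    Returns (scores, explained-variance proportions), axes ordered by
    decreasing variance.
    """
    if g.n_individuals < 2 or g.n_loci < 2:
        raise ValueError("need >=2 individuals and >=2 loci")
    X = g.genotypes.astype(float)
    called = g.called
    with np.errstate(invalid="ignore"):
        mean = np.where(called, X, np.nan)
        mean = np.nanmean(mean, axis=0)
    X = np.where(called, X, mean[None, :]) - mean[None, :]
    if not np.any(X != 0):
        raise ValueError("constant genotype matrix: PCA undefined")
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    n_axes = min(n_axes, len(s))
    var = s**2
    prop = var / var.sum()
    scores = U[:, :n_axes] * s[:n_axes]
    return scores, prop[:n_axes]


# ---------------------------------------------------------------------------
# Directional relative migration (hypothetical-pool GST method)
# ---------------------------------------------------------------------------

@dataclass
class MigrationMatrix:
    """Directional relative migration rates, normalised so max = 1."""

    rates: pd.DataFrame  # rows = source, columns = recipient; diagonal NaN

    def masked(self, min_rate: float = 0.05) -> pd.DataFrame:
        """Copy with rates below ``min_rate`` blanked (display convention)."""
        out = self.rates.copy()
        return out.where(out >= min_rate)


def _gst(p_x: np.ndarray, p_y: np.ndarray, ok: np.ndarray) -> float:
    """Multi-locus GST between two frequency vectors (ratio of averages)."""
    hx = 2 * p_x * (1 - p_x)
    hy = 2 * p_y * (1 - p_y)
    hs = (hx + hy) / 2.0
    pm_ = (p_x + p_y) / 2.0
    ht = 2 * pm_ * (1 - pm_)
    ht_m = ht[ok].mean()
    if ht_m <= 0:
        return 0.0
    return float((ht_m - hs[ok].mean()) / ht_m)


def relative_migration(
    g: GenotypeMatrix, pm: PopulationMap, min_rate: float = 0.0
) -> MigrationMatrix:
    """Directional relative migration between all population pairs.

    For each pair a hypothetical pooled population is formed from the
    unweighted mean of the pair's allele frequencies.  The differentiation of
    the *recipient* population from that pool is converted to a Wright-style
    migrant estimate Nm = ((1/GST) - 1)/4; a population receiving many
    migrants is an admixture, hence close to the pool.  All entries are
    divided by the maximum, so the strongest connection is 1.
    """
    pops = pm.indices_by_population(g)
    names = list(pops)
    if len(names) < 2:
        raise ValueError("need >=2 populations")
    freqs: dict[str, np.ndarray] = {}
    called: dict[str, np.ndarray] = {}
    for pop, idx in pops.items():
        n, alt, _ = _pop_counts(g, idx)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[pop] = np.where(n > 0, alt / np.maximum(2 * n, 1), np.nan)
        called[pop] = n > 0
    pooled = g.allele_freq()
    if not ((pooled > 0) & (pooled < 1)).any():
        raise ValueError("monomorphic data: relative migration undefined")
    eps = 1e-12
    nm = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ok = called[a] & called[b]
            if not ok.any():
                continue
            pool = (freqs[a] + freqs[b]) / 2.0
            g_a = max(_gst(freqs[a], pool, ok), eps)
            g_b = max(_gst(freqs[b], pool, ok), eps)
            # rate source->recipient from the recipient's GST against the pool
            nm.loc[b, a] = ((1.0 / g_a) - 1.0) / 4.0
            nm.loc[a, b] = ((1.0 / g_b) - 1.0) / 4.0
    mx = np.nanmax(nm.to_numpy())
    if not np.isfinite(mx) or mx <= 0:
        raise ValueError("no defined migration estimates")
    rates = nm / mx
    if min_rate > 0:
        rates = rates.where(rates >= min_rate)
    return MigrationMatrix(rates=rates)


def migration_distance_correlation(
    m: MigrationMatrix, d: pd.DataFrame
) -> tuple[float, float]:
    """Pearson correlation of directional migration with geographic distance.

    Uses all defined off-diagonal ordered pairs; two-tailed p from the t
    distribution.  (A plain correlation test, not a Mantel permutation.)
    """
    if list(m.rates.index) != list(d.index) or list(m.rates.columns) != list(d.columns):
        raise ValueError("migration and distance matrices must share population order")
    r_vals, d_vals = [], []
    for a in m.rates.index:
        for b in m.rates.columns:
            if a == b:
                continue
            rv = m.rates.loc[a, b]
            if np.isfinite(rv):
                r_vals.append(rv)
                d_vals.append(d.loc[a, b])
    if len(r_vals) < 3:
        raise ValueError("need >=3 ordered pairs for a correlation test")
    res = stats.pearsonr(r_vals, d_vals)
    return float(res.statistic), float(res.pvalue)
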