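"""Genotype-environment association via redundancy analysis (RDA).

Environment tables are pandas DataFrames indexed by population with numeric
variable columns; a ``provenance`` entry in ``DataFrame.attrs`` marks each
variable "real" or "random".  Environmental values have per-population
resolution and are broadcast to individuals through the population map.

The association statistic projects each locus's RDA loading vector onto the
environmental direction of each constrained axis: for locus j and variable v,

    score(j, v) = sum_k loading(j, k) * corr(v, site scores on axis k)

over the constrained axes with positive eigenvalue.  Scores are standardised
per variable to z, giving two-tailed normal p-values and per-variable Storey
q-values.  With a single fitted variable this reduces to the plain
genotype-environment correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MISSING, GenotypeMatrix, PopulationMap
from .outlier_scan import storey_q


def _provenance(env: pd.DataFrame) -> dict:
    return dict(env.attrs.get("provenance", {v: "real" for v in env.columns}))


# ---------------------------------------------------------------------------
# Environment preprocessing
# ---------------------------------------------------------------------------

def preprocess_env(
    env: pd.DataFrame, r2_max: float = 0.7, priority: list | None = None
) -> tuple[pd.DataFrame, list]:
    """Centre/scale variables and greedily prune collinear ones.

    Variables are mean-centred and scaled to unit variance (sample sd).
    Walking ``priority`` (default: column order), a variable is kept iff its
    squared correlation with every already-kept variable is <= ``r2_max``
    (inclusive threshold).  Returns (preprocessed table, dropped variables).
    """
    if len(env) < 2:
        raise ValueError("need >=2 populations")
    for v in env.columns:
        if env[v].std(ddof=1) == 0:
            raise ValueError(f"constant environmental variable: {v!r}")
    scaled = (env - env.mean()) / env.std(ddof=1)
    if priority is None:
        priority = list(env.columns)
    unknown = [v for v in priority if v not in env.columns]
    if unknown:
        raise ValueError(f"priority names unknown variables: {unknown}")
    kept: list = []
    dropped: list = []
    tol = 1e-12
    for v in priority:
        r2 = [np.corrcoef(scaled[v], scaled[u])[0, 1] ** 2 for u in kept]
        if all(x <= r2_max + tol for x in r2):
            kept.append(v)
        else:
            dropped.append(v)
    out = scaled[kept].copy()
    prov = _provenance(env)
    out.attrs["provenance"] = {v: prov.get(v, "real") for v in kept}
    return out, dropped


def make_random_env(
    populations, count: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Random environmental variables: iid standard normal per population.

    One value per population (mirroring real variables' resolution), named
    ranvar_001... These are *not* subjected to collinearity pruning.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(seed)
    populations = list(populations)
    names = [f"ranvar_{i + 1:03d}" for i in range(count)]
    df = pd.DataFrame(
        rng.standard_normal((len(populations), count)),
        index=pd.Index(populations, name="population"),
        columns=names,
    )
    df.attrs["provenance"] = {v: "random" for v in names}
    return df


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def impute_modal(g: GenotypeMatrix, pm: PopulationMap) -> GenotypeMatrix:
    """Impute missing genotypes with the modal genotype within the clade.

    Ties break toward the lower dosage code.  A group with zero calls at a
    locus that still has missing entries is an error (such loci should have
    been removed by ``drop_population_missing_loci``).
    """
    out = g.genotypes.copy()
    for group, rows in pm.indices_by_group(g).items():
        sub = out[rows]
        miss = sub == MISSING
        if not miss.any():
            continue
        counts = np.stack([(sub == d).sum(axis=0) for d in (0, 1, 2)])  # (3, L)
        no_calls = counts.sum(axis=0) == 0
        bad = no_calls & miss.any(axis=0)
        if bad.any():
            which = g.locus_ids[np.flatnonzero(bad)[:5]]
            raise ValueError(
                f"group {group!r} has zero calls at loci {list(which)}; run "
                "drop_population_missing_loci before imputation"
            )
        mode = counts.argmax(axis=0).astype(np.int8)  # argmax ties -> lower code
        sub = np.where(miss, mode[None, :], sub)
        out[rows] = sub
    return GenotypeMatrix(out, g.locus_ids, g.tag_ids, g.individual_ids)


# ---------------------------------------------------------------------------
# RDA machinery
# ---------------------------------------------------------------------------

def _design(env: pd.DataFrame, pm: PopulationMap, g: GenotypeMatrix) -> np.ndarray:
    """Broadcast population-level env rows to individuals, column-centred."""
    missing_pops = [
        p for p in {pm.population_of(i) for i in g.individual_ids}
        if p not in env.index
    ]
    if missing_pops:
        raise ValueError(f"populations missing from environment table: {missing_pops}")
    X = np.stack([env.loc[pm.population_of(i)].to_numpy() for i in g.individual_ids])
    return X - X.mean(axis=0)


def _centered_genotypes(g: GenotypeMatrix) -> np.ndarray:
    if (g.genotypes == MISSING).any():
        raise ValueError("genotype matrix contains missing calls: impute first")
    Y = g.genotypes.astype(float)
    return Y - Y.mean(axis=0)


@dataclass
class RdaModel:
    """Fitted constrained ordination."""

    site_scores: np.ndarray   # (n_individuals, n_axes)
    loadings: np.ndarray      # (n_loci, n_axes), unit-variance scaled
    eigenvalues: np.ndarray   # constrained eigenvalues
    X: np.ndarray             # centred individual-level design


def fit_rda(g_imputed: GenotypeMatrix, env: pd.DataFrame, pm: PopulationMap) -> RdaModel:
    """Least-squares RDA: SVD of the fitted values of Y ~ X.

    Retains every constrained axis with a positive eigenvalue (relative to
    the leading one).  SNP loadings are scaled to unit variance per axis.
    """
    X = _design(env, pm, g_imputed)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient environmental design")
    Y = _centered_genotypes(g_imputed)
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    fitted = X @ B
    U, s, Vt = np.linalg.svd(fitted, full_matrices=False)
    if s[0] <= 0:
        raise ValueError("zero constrained variance")
    keep = s > 1e-9 * s[0]
    keep[X.shape[1]:] = False  # at most rank(X) constrained axes
    U, s, V = U[:, keep], s[keep], Vt[keep].T
    loadings = V / V.std(axis=0, ddof=0)[None, :]
    n = Y.shape[0]
    return RdaModel(
        site_scores=U * s[None, :],
        loadings=loadings,
        eigenvalues=s**2 / (n - 1),
        X=X,
    )


def rda_full_model_test(
    g_imputed: GenotypeMatrix,
    env: pd.DataFrame,
    pm: PopulationMap,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation ANOVA of the RDA full model.

    pseudo-F = (SS_fit/df_model)/(SS_resid/df_resid); the permutation
    distribution shuffles individuals' environment rows, so the minimum
    attainable p is 1/(n_perm + 1).
    """
    X = _design(env, pm, g_imputed)
    v = X.shape[1]
    if len(env) < v + 2:
        raise ValueError("need n_populations >= n_variables + 2")
    if np.linalg.matrix_rank(X) < v:
        raise ValueError("rank-deficient environmental design")
    Y = _centered_genotypes(g_imputed)
    n = Y.shape[0]
    ss_tot = float((Y**2).sum())
    df_resid = n - v - 1

    def fit_ss(Xc: np.ndarray) -> float:
        Q, _ = np.linalg.qr(Xc - Xc.mean(axis=0))
        return float(((Q.T @ Y) ** 2).sum())

    ss_fit = fit_ss(X)
    f_obs = (ss_fit / v) / ((ss_tot - ss_fit) / df_resid)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        ss_p = fit_ss(X[perm])
        f_p = (ss_p / v) / ((ss_tot - ss_p) / df_resid)
        if f_p >= f_obs:
            n_ge += 1
    p = (1 + n_ge) / (n_perm + 1)
    return float(f_obs), float(p)


def rda_associations(
    g_imputed: GenotypeMatrix,
    env: pd.DataFrame,
    pm: PopulationMap,
    method: str = "rda",
) -> pd.DataFrame:
    """Per locus x variable association table from a multivariate RDA.

    Returns a long GeaTable with columns locus_id, variable, score, z,
    p_value, q_value, method; q-values are computed per variable.
    """
    model = fit_rda(g_imputed, env, pm)
    axes = model.site_scores
    # correlation of each env variable with each constrained axis
    Xs = model.X / np.maximum(model.X.std(axis=0, ddof=0), 1e-12)[None, :]
    A = axes - axes.mean(axis=0)
    A = A / np.maximum(A.std(axis=0, ddof=0), 1e-12)[None, :]
    corr = Xs.T @ A / Xs.shape[0]              # (n_vars, n_axes)
    raw = model.loadings @ corr.T              # (n_loci, n_vars)
    frames = []
    for vi, var in enumerate(env.columns):
        s = raw[:, vi]
        sd = s.std(ddof=0)
        if sd <= 0:
            raise ValueError(f"degenerate score distribution for {var!r}")
        z = (s - s.mean()) / sd
        p = 2.0 * stats.norm.sf(np.abs(z))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            q = storey_q(p)
        frames.append(
            pd.DataFrame(
                {
                    "locus_id": g_imputed.locus_ids,
                    "variable": var,
                    "score": s,
                    "z": z,
                    "p_value": p,
                    "q_value": q,
                    "method": method,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def univariate_associations(
    g_imputed: GenotypeMatrix,
    env: pd.DataFrame,
    pm: PopulationMap,
    method: str = "rda",
) -> pd.DataFrame:
    """One univariate RDA per variable (used for the random-variable null).

    Random variables are mutually uncorrelated only in expectation, so each
    is tested alone, exactly as a univariate constrained ordination.
    """
    frames = []
    for var in env.columns:
        frames.append(
            rda_associations(g_imputed, env[[var]], pm, method=method)
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# External adapter and broad-sense combination
# ---------------------------------------------------------------------------

def ingest_external_gea(
    path: str, method: str, variables=None
) -> pd.DataFrame:
    """Read an external per-locus-per-variable q-value TSV as a GeaTable.

    Expected columns: locus_id, variable, q_value.  Unknown variables (when
    ``variables`` is given) raise a warning; malformed q-values are fatal;
    incomplete locus x variable coverage is reported via a warning.
    """
    df = pd.read_csv(path, sep="\t")
    need = {"locus_id", "variable", "q_value"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path!r} must have columns {sorted(need)}")
    q = df["q_value"].astype(float)
    if q.isna().any() or ((q < 0) | (q > 1)).any():
        raise ValueError(f"{path!r} contains q-values outside [0, 1]")
    if variables is not None:
        unknown = sorted(set(df["variable"]) - set(variables))
        if unknown:
            warnings.warn(f"unknown variables in {path!r}: {unknown}", stacklevel=2)
            df = df[df["variable"].isin(set(variables))]
    grid = df.pivot_table(index="locus_id", columns="variable", values="q_value")
    if grid.isna().any().any():
        n = int(grid.isna().sum().sum())
        warnings.warn(f"{n} locus x variable pairs missing in {path!r}", stacklevel=2)
    out = df[["locus_id", "variable"]].copy()
    out["score"] = np.nan
    out["z"] = np.nan
    out["p_value"] = np.nan
    out["q_value"] = df["q_value"].astype(float).to_numpy()
    out["method"] = method
    return out.reset_index(drop=True)


def broad_sense_combine(
    gea: pd.DataFrame, anchor: str, env: pd.DataFrame, r2_min: float = 0.7
) -> pd.DataFrame:
    """Combine q-values of all anchor-correlated variables per locus.

    The correlated set is {v : r^2(v, anchor) > r2_min} plus the anchor
    itself; per locus the combined q is the geometric mean over the set,
    giving significance to the anchor "in the broad sense".
    """
    if anchor not in env.columns:
        raise ValueError(f"anchor {anchor!r} not in environment table")
    corr_set = [anchor]
    for v in env.columns:
        if v == anchor:
            continue
        r2 = np.corrcoef(env[v], env[anchor])[0, 1] ** 2
        if r2 > r2_min:
            corr_set.append(v)
    sub = gea[gea["variable"].isin(corr_set)]
    grid = sub.pivot_table(index="locus_id", columns="variable", values="q_value")
    logq = np.log(np.maximum(grid.to_numpy(), np.finfo(float).tiny))
    combined = np.exp(logq.mean(axis=1))
    combined[np.any(grid.to_numpy() == 0.0, axis=1)] = 0.0
    out = pd.DataFrame(
        {"locus_id": grid.index.to_numpy(), "q_combined_broad": combined}
    )
    out.attrs["variables"] = corr_set
    return out
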