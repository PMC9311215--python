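"""Genome scan for outliers: PCA-based Mahalanobis scan with genomic-inflation
correction, Storey q-values, an adapter for external q-value tables, and the
post-hoc heterozygosity / per-population-missingness checks.

The scan regresses each standardised genotype column on the leading principal
axes of population structure; the per-locus vector of regression z-scores is
converted to a squared Mahalanobis distance under a robust covariance
estimate, rescaled by the genomic inflation factor (median D^2 over the null
chi-square median), and referred to the upper tail of chi^2_k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline
from sklearn.covariance import MinCovDet

from .io_formats import GenotypeMatrix, PopulationMap


@dataclass
class GifReport:
    """Number of retained axes and the genomic inflation factor lambda."""

    k: int
    lam: float


# ---------------------------------------------------------------------------
# Genotype standardisation and axis choice
# ---------------------------------------------------------------------------

def _scaled_matrix(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Binomially standardised genotypes: (x - 2p)/sqrt(2p(1-p)), missing -> 0.

    Returns (X, polymorphic mask); monomorphic loci cannot be standardised
    and are excluded from the scan.
    """
    p = g.allele_freq()
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    sd = np.sqrt(2.0 * p * (1.0 - p))
    X = g.genotypes.astype(float)
    X = np.where(g.called, X, 2.0 * p[None, :])  # mean imputation
    with np.errstate(invalid="ignore", divide="ignore"):
        X = (X - 2.0 * p[None, :]) / sd[None, :]
    X[:, ~poly] = 0.0
    return X, poly


def choose_k(g: GenotypeMatrix, max_k: int = 20) -> tuple[int, pd.DataFrame]:
    """Pick the number of structure axes by the largest scree drop.

    An automated stand-in for visual scree inspection: k is the axis index
    just before the largest decrease in explained-variance proportion.  A
    flat scree (max drop < 0.01) falls back to k = 1 with a warning.  The
    caller may always override k.
    """
    if max_k >= g.n_individuals:
        raise ValueError("max_k must be smaller than the number of individuals")
    X, poly = _scaled_matrix(g)
    if not poly.any():
        raise ValueError("no polymorphic loci: scree undefined")
    s = np.linalg.svd(X - X.mean(axis=0), compute_uv=False)
    var = s**2
    if var.sum() <= 0:
        raise ValueError("degenerate variance: scree undefined")
    prop = (var / var.sum())[:max_k]
    scree = pd.DataFrame({"axis": np.arange(1, len(prop) + 1), "proportion": prop})
    drops = -np.diff(prop)
    if len(drops) == 0 or drops.max() < 0.01:
        warnings.warn("flat scree: defaulting to k=1", stacklevel=2)
        return 1, scree
    return int(np.argmax(drops)) + 1, scree


# ---------------------------------------------------------------------------
# The scan
# ---------------------------------------------------------------------------

def pcadapt_scan(
    g: GenotypeMatrix, k: int, seed: int = 0, method: str = "pca_mahalanobis"
) -> tuple[pd.DataFrame, GifReport]:
    """PCA-based Mahalanobis outlier scan with genomic-inflation correction.

    Parameters
    ----------
    g : GenotypeMatrix
    k : number of principal axes of structure to regress on (>= 1).
    seed : seed for the robust covariance estimator.
    method : label written to the output table.

    Returns a ScanTable (locus_id, statistic, p_value, q_value, method) over
    polymorphic loci, and a :class:`GifReport`.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= g.n_individuals:
        raise ValueError("k must be smaller than the number of individuals")
    X, poly = _scaled_matrix(g)
    if not poly.any():
        raise ValueError("no polymorphic loci to scan")
    Xp = X[:, poly]
    n = Xp.shape[0]
    U, s, _ = np.linalg.svd(Xp, full_matrices=False)
    Uk = U[:, :k]
    # regression of each column on the orthonormal axes: beta = Uk' x
    beta = Uk.T @ Xp                       # (k, L)
    ss_tot = (Xp**2).sum(axis=0)
    ss_res = np.maximum(ss_tot - (beta**2).sum(axis=0), 0.0)
    sigma = np.sqrt(ss_res / max(n - k, 1))
    sigma = np.maximum(sigma, 1e-12)
    Z = (beta / sigma[None, :]).T          # (L, k)

    loc, cov = _robust_location_cov(Z, k, seed)
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        warnings.warn("singular z covariance: falling back to diagonal", stacklevel=2)
        cov_inv = np.diag(1.0 / np.maximum(np.diag(cov), 1e-12))
    diff = Z - loc[None, :]
    d2 = np.einsum("ij,jk,ik->i", diff, cov_inv, diff)

    lam = float(np.median(d2) / stats.chi2.ppf(0.5, df=k))
    if not np.isfinite(lam) or lam <= 0:
        lam = 1.0
    p = stats.chi2.sf(d2 / lam, df=k)
    q = storey_q(p)
    table = pd.DataFrame(
        {
            "locus_id": g.locus_ids[poly],
            "statistic": d2,
            "p_value": p,
            "q_value": q,
            "method": method,
        }
    )
    return table, GifReport(k=k, lam=lam)


def _robust_location_cov(Z: np.ndarray, k: int, seed: int):
    """MCD-style robust location/scatter, with documented fallbacks."""
    L = Z.shape[0]
    if L >= 10 * k and L > k + 1:
        try:
            mcd = MinCovDet(random_state=seed).fit(Z)
            return mcd.location_, mcd.covariance_
        except (ValueError, np.linalg.LinAlgError):
            warnings.warn("robust covariance failed: using sample covariance",
                          stacklevel=3)
    loc = Z.mean(axis=0)
    cov = np.cov(Z, rowvar=False)
    cov = np.atleast_2d(cov)
    return loc, cov


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

def storey_q(p, pi0: float | None = None) -> np.ndarray:
    """Storey-Tibshirani q-values with the smoother pi0 estimate.

    With too few p-values for the smoother (or if it fails), pi0 falls back
    to 1, which reduces to Benjamini-Hochberg step-up values.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        pi0 = _pi0_smoother(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _pi0_smoother(p: np.ndarray) -> float:
    m = p.size
    if m < 100:
        warnings.warn("too few p-values for pi0 smoothing: using pi0=1",
                      stacklevel=3)
        return 1.0
    lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_l = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
    try:
        spline = UnivariateSpline(lambdas, pi0_l, k=3)
        pi0 = float(spline(lambdas[-1]))
    except Exception:
        pi0 = float(pi0_l[-1])
    if not np.isfinite(pi0) or pi0 <= 0:
        warnings.warn("pi0 estimate degenerate: using pi0=1", stacklevel=3)
        return 1.0
    return min(pi0, 1.0)


# ---------------------------------------------------------------------------
# External q-value adapter and post-hoc candidate checks
# ---------------------------------------------------------------------------

def ingest_external_scan(
    path: str, method: str, locus_ids
) -> pd.DataFrame:
    """Read an externally produced per-locus q-value TSV as a ScanTable.

    Expected columns: ``locus_id``, ``q_value`` (optional ``method``).  Loci
    not present in ``locus_ids`` are dropped with a warning; less than 50%
    overlap is a fatal error.  q-values outside [0, 1] are a parse error.
    """
    df = pd.read_csv(path, sep="\t")
    if "locus_id" not in df.columns or "q_value" not in df.columns:
        raise ValueError(f"{path!r} must have locus_id and q_value columns")
    q = df["q_value"].astype(float)
    if q.isna().any() or ((q < 0) | (q > 1)).any():
        raise ValueError(f"{path!r} contains q-values outside [0, 1]")
    known = set(locus_ids)
    mask = df["locus_id"].isin(known)
    n_unknown = int((~mask).sum())
    if n_unknown:
        warnings.warn(f"{n_unknown} loci in {path!r} not in the active matrix",
                      stacklevel=2)
    df = df[mask].copy()
    if len(df) < 0.5 * len(known):
        raise ValueError(
            f"{path!r}: only {len(df)} of {len(known)} active loci covered (<50%)"
        )
    out = pd.DataFrame(
        {
            "locus_id": df["locus_id"].to_numpy(),
            "statistic": np.nan,
            "p_value": np.nan,
            "q_value": df["q_value"].astype(float).to_numpy(),
            "method": method,
        }
    )
    return out


@dataclass
class SuspectReport:
    """Outcome of post-hoc candidate checks."""

    flagged_high_het: list
    removed_missing: list
    retained: pd.DataFrame


def flag_suspect_outliers(
    g: GenotypeMatrix,
    pm: PopulationMap,
    candidates: pd.DataFrame,
    ho_max: float = 0.5,
) -> SuspectReport:
    """Flag candidates with pooled observed heterozygosity above ``ho_max``
    and remove candidates completely missing in at least one population."""
    idx_of = {l: j for j, l in enumerate(g.locus_ids)}
    missing_ids = [l for l in candidates["locus_id"] if l not in idx_of]
    if missing_ids:
        raise ValueError(f"candidate loci absent from matrix: {missing_ids[:5]}")
    cols = np.array([idx_of[l] for l in candidates["locus_id"]])
    sub = g.genotypes[:, cols]
    called = g.called[:, cols]
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = ((sub == 1) & called).sum(axis=0) / np.maximum(called.sum(axis=0), 1)
    flagged = list(candidates["locus_id"].to_numpy()[ho > ho_max])
    pops = pm.indices_by_population(g)
    absent = np.zeros(len(cols), dtype=bool)
    for _pop, rows in pops.items():
        absent |= ~called[rows].any(axis=0)
    removed = list(candidates["locus_id"].to_numpy()[absent])
    retained = candidates[~absent].copy()
    retained["high_het_flag"] = ho[~absent] > ho_max
    return SuspectReport(flagged, removed, retained)
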