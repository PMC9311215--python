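"""Geometric-mean combination of q-values across methods, the random-variable
exclusion rule, and confidence classification.

The combined q-value of two methods is sqrt(q_a * q_b) — the arithmetic mean
on the log scale.  Since min(q_a, q_b) <= sqrt(q_a*q_b) <= max(q_a, q_b),
the significant set of the combination always sits between the intersection
and the union of the two methods' significant sets, trading power against
false positives.  A GEA-significant locus is "high-confidence" only if it is
also significant with fewer than ``random_hit_max`` of the ``n_random``
randomly generated environmental variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

NOT_SIGNIFICANT = "not-significant"
LOW_CONFIDENCE = "low-confidence"
HIGH_CONFIDENCE = "high-confidence"


@dataclass
class CombineConfig:
    """Significance threshold and random-variable exclusion rule."""

    alpha: float = 0.05
    random_hit_max: int = 5
    n_random: int = 100

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 <= self.random_hit_max <= self.n_random):
            raise ValueError("random_hit_max must be in [0, n_random]")


def combine_q(q_a, q_b):
    """Geometric mean of two q-values (vectorised): sqrt(q_a * q_b).

    Strong support from one method (a small q) can outweigh no support from
    the other; exact zeros combine to zero.
    """
    q_a = np.asarray(q_a, dtype=float)
    q_b = np.asarray(q_b, dtype=float)
    for name, q in (("q_a", q_a), ("q_b", q_b)):
        if np.any((q < 0) | (q > 1)) or np.any(~np.isfinite(q)):
            raise ValueError(f"{name} must lie in [0, 1]")
    out = np.sqrt(q_a * q_b)
    if out.ndim == 0:
        return float(out)
    return out


def classify_gso(
    scan_a: pd.DataFrame, scan_b: pd.DataFrame, cfg: CombineConfig | None = None
) -> pd.DataFrame:
    """Combine two per-locus ScanTables and classify outlier candidates.

    Loci are outer-joined; a locus absent from one method receives q = 1
    there (with a warning), so the geometric mean then demands strong support
    from the other method.  The returned CandidateSet has per-locus q_a, q_b,
    q_combined plus union/intersection membership at alpha.  Significant loci
    are labelled low-confidence: no random-variable control exists on the
    outlier-scan track, so high-confidence is unreachable here.
    """
    cfg = cfg or CombineConfig()
    a = scan_a.set_index("locus_id")["q_value"]
    b = scan_b.set_index("locus_id")["q_value"]
    if len(set(a.index) & set(b.index)) == 0:
        raise ValueError("disjoint locus sets between the two scans")
    all_loci = a.index.union(b.index)
    n_fill = int(len(all_loci) - len(a.index)) + int(len(all_loci) - len(b.index))
    if n_fill:
        warnings.warn(
            f"{n_fill} method-absent loci assigned q=1 before combination",
            stacklevel=2,
        )
    qa = a.reindex(all_loci, fill_value=1.0).to_numpy()
    qb = b.reindex(all_loci, fill_value=1.0).to_numpy()
    qc = combine_q(qa, qb)
    sig = qc < cfg.alpha
    out = pd.DataFrame(
        {
            "locus_id": all_loci.to_numpy(),
            "q_a": qa,
            "q_b": qb,
            "q_combined": qc,
            "in_union": (qa < cfg.alpha) | (qb < cfg.alpha),
            "in_intersection": (qa < cfg.alpha) & (qb < cfg.alpha),
            "significant": sig,
            "class": np.where(sig, LOW_CONFIDENCE, NOT_SIGNIFICANT),
        }
    )
    return out


def combine_gea_tables(
    gea_a: pd.DataFrame, gea_b: pd.DataFrame, fill: float = 1.0
) -> pd.DataFrame:
    """Combine two GeaTables per locus x variable by the geometric mean.

    Pairs present in only one table receive q = ``fill`` on the other side.
    Returns columns locus_id, variable, q_a, q_b, q_combined.
    """
    ga = gea_a.set_index(["locus_id", "variable"])["q_value"]
    gb = gea_b.set_index(["locus_id", "variable"])["q_value"]
    idx = ga.index.union(gb.index)
    qa = ga.reindex(idx, fill_value=fill).to_numpy()
    qb = gb.reindex(idx, fill_value=fill).to_numpy()
    out = idx.to_frame(index=False)
    out["q_a"] = qa
    out["q_b"] = qb
    out["q_combined"] = combine_q(qa, qb)
    return out


def random_hit_counts(
    random_combined: pd.DataFrame, cfg: CombineConfig | None = None
) -> pd.Series:
    """Count, per locus, random variables with combined q below alpha.

    ``random_combined`` must hold a ``q_combined`` column over a complete
    locus x random-variable grid covering ``cfg.n_random`` variables.
    """
    cfg = cfg or CombineConfig()
    per_locus_vars = random_combined.groupby("locus_id")["variable"].nunique()
    if (per_locus_vars != cfg.n_random).any():
        bad = per_locus_vars[per_locus_vars != cfg.n_random]
        raise ValueError(
            f"incomplete random-variable coverage for {len(bad)} loci "
            f"(expected {cfg.n_random} each)"
        )
    hits = (
        random_combined.assign(hit=random_combined["q_combined"] < cfg.alpha)
        .groupby("locus_id")["hit"]
        .sum()
        .astype(int)
    )
    hits.name = "n_random_hits"
    return hits


def classify_gea(
    real_combined: pd.DataFrame,
    hits: pd.Series,
    cfg: CombineConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify GEA candidates with the random-variable exclusion rule.

    A locus x variable pair is significant iff combined q < alpha.  A
    significant locus is high-confidence iff its random-hit count is below
    ``random_hit_max`` ("fewer than five of one hundred"), else
    low-confidence.  The hit rule applies per locus, not per pair.

    Returns (candidate table, per-variable summary).  The summary follows
    the layout: associations per variable, loci excluded by the random rule,
    combined-significant count, final high-confidence count.
    """
    cfg = cfg or CombineConfig()
    out = real_combined.copy()
    out["n_random_hits"] = (
        out["locus_id"].map(hits).fillna(0).astype(int)
    )
    sig = out["q_combined"] < cfg.alpha
    high = sig & (out["n_random_hits"] < cfg.random_hit_max)
    out["class"] = np.select(
        [high, sig], [HIGH_CONFIDENCE, LOW_CONFIDENCE], default=NOT_SIGNIFICANT
    )
    rows = []
    for var, grp in out.groupby("variable"):
        s = grp["q_combined"] < cfg.alpha
        rows.append(
            {
                "variable": var,
                "n_significant": int(s.sum()),
                "n_random_excluded": int(
                    (s & (grp["n_random_hits"] >= cfg.random_hit_max)).sum()
                ),
                "n_high_confidence": int((grp["class"] == HIGH_CONFIDENCE).sum()),
            }
        )
    summary = pd.DataFrame(rows)
    return out, summary
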