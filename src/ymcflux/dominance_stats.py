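"""Metabolic-dominance statistics.

"Metabolic dominance" of a gene is the Pearson correlation between its
histone-mark promoter-enrichment time series and the production-flux series
of the mark's cosubstrate (acetyl-CoA for H3K9Ac, SAM for H3K4me3).  A
permutation null is built by independently shuffling both series per gene;
critical dominance values are the least extreme thresholds at which fewer
than a stated fraction (default 10%) of genes beyond the threshold are
expected under the null.  Chromatin-accessibility association regresses
per-time-point ATAC promoter enrichment on dominance across genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .epigenome import EnrichmentMatrix

__all__ = [
    "CriticalValue",
    "DominanceResult",
    "metabolic_dominance",
    "shuffle_null",
    "critical_value",
    "select_correlated_genes",
    "atac_association",
    "dominance_analysis",
]


@dataclass
class CriticalValue:
    tail: str  # "positive" | "negative"
    threshold: Optional[float]  # None if not attained
    null_count: int = 0
    observed_count: int = 0

    @property
    def attained(self) -> bool:
        return self.threshold is not None


@dataclass
class DominanceResult:
    """Observed per-gene dominance, its permutation null and critical values."""

    r: pd.Series  # per-gene Pearson r (NaN where undefined)
    null: np.ndarray  # null correlations, genes x reps flattened
    positive: CriticalValue
    negative: CriticalValue
    seed: Optional[int] = None

    @property
    def defined(self) -> pd.Series:
        return self.r.notna()


def _rowwise_pearson(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each row of X against y; NaN for zero-variance rows."""
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / (sx * sy)
    r[(sx == 0)] = np.nan
    if sy == 0:
        r[:] = np.nan
    return np.clip(r, -1.0, 1.0)


def metabolic_dominance(marks: EnrichmentMatrix, flux: np.ndarray) -> pd.Series:
    """Per-gene Pearson correlation between mark enrichment and flux.

    Genes with a zero-variance enrichment series get NaN (undefined) and
    are excluded from downstream counts.
    """
    flux = np.asarray(flux, dtype=float)
    if marks.values.shape[1] != len(flux):
        raise ValueError(
            f"marks have {marks.values.shape[1]} time points but the flux "
            f"series has {len(flux)}"
        )
    if len(flux) < 3:
        raise ValueError("at least 3 time points are required")
    r = _rowwise_pearson(marks.values.to_numpy(dtype=float), flux)
    return pd.Series(r, index=marks.values.index, name="dominance")


def shuffle_null(
    marks: EnrichmentMatrix,
    flux: np.ndarray,
    reps_per_gene: int = 1,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Permutation null: per gene and rep, independently shuffle both the
    enrichment and the flux series and record their Pearson correlation."""
    flux = np.asarray(flux, dtype=float)
    X = marks.values.to_numpy(dtype=float)
    n_genes, n_t = X.shape
    if n_t != len(flux):
        raise ValueError("marks/flux time-point mismatch")
    if n_t < 3:
        raise ValueError("at least 3 time points are required")
    rng = np.random.default_rng(seed)
    out = np.empty(n_genes * reps_per_gene)
    k = 0
    for rep in range(reps_per_gene):
        for i in range(n_genes):
            xs = rng.permutation(X[i])
            ys = rng.permutation(flux)
            out[k] = _rowwise_pearson(xs[np.newaxis, :], ys)[0]
            k += 1
    return out


def critical_value(
    observed: Sequence[float],
    null: Sequence[float],
    max_random_fraction: float = 0.10,
    tail: str = "positive",
    min_observed: int = 10,
) -> CriticalValue:
    """Least extreme dominance threshold with < ``max_random_fraction``
    random-to-observed ratio beyond it.

    Candidates are the observed values in the requested tail; at each
    candidate c the ratio (#null at or beyond c) / (#observed at or beyond
    c) is evaluated and the least extreme qualifying c is returned, with
    both counts.  ``threshold=None`` when no candidate qualifies.

    The ratio is an estimate of the false-discovery fraction; a candidate
    only qualifies when at least ``min_observed`` observed genes lie beyond
    it, so a threshold is never declared on the strength of one or two
    extreme genes whose null count is vacuously zero.
    """
    obs = np.asarray([x for x in observed if np.isfinite(x)], dtype=float)
    nul = np.asarray([x for x in null if np.isfinite(x)], dtype=float)
    if obs.size == 0 or nul.size == 0:
        raise ValueError("observed and null sets must be non-empty")
    if tail not in ("positive", "negative"):
        raise ValueError("tail must be 'positive' or 'negative'")
    sign = 1.0 if tail == "positive" else -1.0
    o = np.sort(sign * obs)  # ascending in extremeness direction
    nu = np.sort(sign * nul)
    # candidates scanned from least extreme upward
    for c in o:
        n_obs = o.size - np.searchsorted(o, c, side="left")
        n_null = nu.size - np.searchsorted(nu, c, side="left")
        if n_obs >= max(1, min_observed) and n_null / n_obs < max_random_fraction:
            return CriticalValue(tail, float(sign * c), int(n_null), int(n_obs))
    return CriticalValue(tail, None)


def select_correlated_genes(r: pd.Series, cutoff: float = 0.7) -> List[str]:
    """Genes with dominance >= cutoff (inclusive), sorted by descending r."""
    kept = r[r >= cutoff].sort_values(ascending=False)
    return list(kept.index)


def atac_association(
    dominance: pd.Series, atac: EnrichmentMatrix
) -> pd.DataFrame:
    """Per-ATAC-time-point regression of promoter accessibility on dominance.

    Over the genes shared between the dominance vector and the ATAC matrix,
    returns per time point the Pearson r, -log10 of the two-sided p-value
    (t-distribution approximation) and the least-squares slope.  Constant
    columns yield NaN with a warning.
    """
    dom = dominance.dropna()
    shared = dom.index.intersection(atac.values.index)
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} genes shared between dominance and ATAC; need >= 3"
        )
    x = dom.loc[shared].to_numpy(dtype=float)
    rows = {}
    for col in atac.values.columns:
        y = atac.values.loc[shared, col].to_numpy(dtype=float)
        if np.std(y) == 0 or np.std(x) == 0:
            warnings.warn(
                f"zero-variance series at ATAC time point {col!r}; association undefined",
                stacklevel=2,
            )
            rows[col] = (np.nan, np.nan, np.nan)
            continue
        res = stats.linregress(x, y)
        p = res.pvalue
        rows[col] = (
            float(res.rvalue),
            float(-np.log10(p)) if p > 0 else np.inf,
            float(res.slope),
        )
    return pd.DataFrame(rows, index=["pearson_r", "neg_log10_p", "slope"]).T


def dominance_analysis(
    marks: EnrichmentMatrix,
    flux: np.ndarray,
    max_random_fraction: float = 0.10,
    reps_per_gene: int = 1,
    seed: Optional[int] = None,
) -> DominanceResult:
    """Observed dominance + shuffled null + both one-tailed critical values."""
    r = metabolic_dominance(marks, flux)
    null = shuffle_null(marks, flux, reps_per_gene=reps_per_gene, seed=seed)
    obs = r.dropna().to_numpy()
    pos = critical_value(obs, null, max_random_fraction, "positive")
    neg = critical_value(obs, null, max_random_fraction, "negative")
    return DominanceResult(r=r, null=null, positive=pos, negative=neg, seed=seed)
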