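"""F_ST-bin enrichment of target-site SNPs over a background SNP set.

The enrichment score of bin b is E_b = (t_b / T) / (g_b / G): the fraction
of target-site SNPs falling in the bin divided by the fraction of background
SNPs in the same bin.  The null distribution comes from repeatedly drawing
|targets|-sized random samples from the background; significance of the
extreme-F_ST bin is an upper hypergeometric tail probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .errors import ConfigError, DataError

#: default bin edges; the last bin is the extreme-differentiation bin (>= 0.5)
DEFAULT_EDGES = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 1.0)

_EPS = 1e-9


def bin_fst(values, edges=DEFAULT_EDGES) -> np.ndarray:
    """Assign F_ST values to half-open bins [e_i, e_{i+1}), last bin closed.

    Small negative estimator values clamp into bin 0; values above 1 are an
    error.  Returns integer bin indices.
    """
    values = np.asarray(values, dtype=float)
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or (np.diff(edges) <= 0).any():
        raise ConfigError("bin edges must be strictly increasing")
    if not (edges[0] == 0.0 and edges[-1] == 1.0):
        raise ConfigError("bin edges must cover [0, 1]")
    if np.nanmax(values, initial=0.0) > 1.0 + _EPS:
        raise DataError("F_ST value above 1")
    if np.nanmin(values, initial=0.0) < -_EPS - 0.5:
        raise DataError("F_ST value below plausible estimator range")
    clipped = np.clip(values, 0.0, 1.0)
    idx = np.digitize(clipped, edges[1:-1], right=False)
    return idx.astype(int)


def _bin_fractions(values, edges) -> tuple[np.ndarray, int]:
    idx = bin_fst(values, edges)
    counts = np.bincount(idx, minlength=len(edges) - 1).astype(float)
    return counts, len(values)


@dataclass
class EnrichmentResult:
    edges: tuple[float, ...]
    target_counts: np.ndarray
    background_counts: np.ndarray
    scores: np.ndarray  # E_b per bin; NaN where background empty
    null_mean: np.ndarray | None = None
    null_sd: np.ndarray | None = None
    null_low: np.ndarray | None = None
    null_high: np.ndarray | None = None
    top_bin_p: float | None = None

    def to_frame(self) -> pd.DataFrame:
        n_bins = len(self.edges) - 1
        df = pd.DataFrame(
            {
                "bin_low": self.edges[:-1],
                "bin_high": self.edges[1:],
                "target_count": self.target_counts.astype(int),
                "background_count": self.background_counts.astype(int),
                "enrichment": self.scores,
            }
        )
        for name in ("null_mean", "null_sd", "null_low", "null_high"):
            value = getattr(self, name)
            df[name] = value if value is not None else [np.nan] * n_bins
        df["top_bin_p"] = [np.nan] * (n_bins - 1) + [
            self.top_bin_p if self.top_bin_p is not None else np.nan
        ]
        return df


def enrichment_scores(target_fst, background_fst, edges=DEFAULT_EDGES) -> EnrichmentResult:
    """Per-bin enrichment scores E_b of targets over background."""
    target_fst = np.asarray(target_fst, dtype=float)
    background_fst = np.asarray(background_fst, dtype=float)
    if target_fst.size == 0:
        raise DataError("empty target set")
    if background_fst.size == 0:
        raise DataError("empty background set")
    t_counts, t_total = _bin_fractions(target_fst, edges)
    g_counts, g_total = _bin_fractions(background_fst, edges)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = (t_counts / t_total) / (g_counts / g_total)
    scores[g_counts == 0] = np.nan
    return EnrichmentResult(
        edges=tuple(edges),
        target_counts=t_counts,
        background_counts=g_counts,
        scores=scores,
    )


def bootstrap_null(
    background_fst,
    n_draw: int,
    n_reps: int,
    edges=DEFAULT_EDGES,
    seed: int | np.random.Generator = 0,
    replace: bool = False,
) -> dict[str, np.ndarray]:
    """Null distribution of per-bin enrichment scores under random sampling.

    Each replicate draws ``n_draw`` SNPs from the background (without
    replacement by default) and scores them against the full background.
    Returns per-bin mean, SD (ddof=1) and the 2.5/97.5 percentile interval.
    """
    if n_reps < 2:
        raise ConfigError("n_reps must be >= 2")
    background_fst = np.asarray(background_fst, dtype=float)
    if not replace and n_draw > background_fst.size:
        raise DataError("n_draw exceeds background size for sampling without replacement")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g_counts, g_total = _bin_fractions(background_fst, edges)
    g_frac = g_counts / g_total
    bins = bin_fst(background_fst, edges)
    n_bins = len(edges) - 1
    scores = np.empty((n_reps, n_bins))
    for r in range(n_reps):
        draw = rng.choice(bins, size=n_draw, replace=replace)
        t_counts = np.bincount(draw, minlength=n_bins).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            scores[r] = (t_counts / n_draw) / g_frac
    return {
        "mean": scores.mean(axis=0),
        "sd": scores.std(axis=0, ddof=1),
        "low": np.percentile(scores, 2.5, axis=0),
        "high": np.percentile(scores, 97.5, axis=0),
        "scores": scores,
    }


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n), in log space.

    N = background population size, K = target-site SNPs in it, n = SNPs in
    the extreme bin, k = target-site SNPs observed in that bin.
    """
    if not (0 <= k <= n <= N and 0 <= K <= N and k <= K):
        raise DataError(f"inconsistent hypergeometric counts N={N} K={K} n={n} k={k}")
    if k == 0:
        return 1.0
    upper = min(n, K)
    support = np.arange(k, upper + 1)
    if support.size == 0:
        return 0.0
    log_pmf = stats.hypergeom.logpmf(support, N, K, n)
    return float(min(1.0, np.exp(logsumexp(log_pmf))))


def analyze(
    target_fst,
    background_fst,
    edges=DEFAULT_EDGES,
    n_reps: int = 1000,
    seed: int | np.random.Generator = 0,
    replace: bool = False,
) -> EnrichmentResult:
    """Full enrichment analysis: scores + bootstrap null + top-bin tail P.

    The hypergeometric population is the background (which, by default
    convention, includes the target SNPs as a subset).
    """
    result = enrichment_scores(target_fst, background_fst, edges)
    null = bootstrap_null(
        background_fst, len(np.atleast_1d(target_fst)), n_reps, edges, seed, replace
    )
    result.null_mean = null["mean"]
    result.null_sd = null["sd"]
    result.null_low = null["low"]
    result.null_high = null["high"]
    result.top_bin_p = hypergeom_tail(
        N=int(result.background_counts.sum()),
        K=int(result.target_counts.sum()),
        n=int(result.background_counts[-1]),
        k=int(result.target_counts[-1]),
    )
    return result


def candidate_filter(
    calls: pd.DataFrame, fst_by_snp: dict[str, float] | pd.Series, threshold: float = 0.5
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Candidate SNPs: allele-dependent site call and F_ST >= threshold.

    Returns the filtered call rows plus a summary with SNP-level and
    gene-level deduplicated counts.
    """
    if isinstance(fst_by_snp, pd.Series):
        fst_by_snp = fst_by_snp.to_dict()
    dep = calls[calls["verdict"].isin(["disrupting", "creating"])].copy()
    dep["fst"] = dep["snp_id"].map(fst_by_snp)
    kept = dep[dep["fst"] >= threshold].reset_index(drop=True)
    summary = {
        "n_calls": len(kept),
        "n_snps": kept["snp_id"].nunique(),
        "n_genes": kept["gene_id"].nunique() if "gene_id" in kept else kept["snp_id"].nunique(),
    }
    return kept, summary
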