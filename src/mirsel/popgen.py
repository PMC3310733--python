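"""Population-genetic selection statistics computed from first principles.

Implements per-SNP Weir-Cockerham F_ST, the unfolded site frequency
spectrum, Fay-Wu's H (theta_pi - theta_H, unnormalized), EHH decay curves
with trapezoidal integration (iHH), iHS with derived-frequency-bin
standardization, and a composite-likelihood-ratio sweep scan against a
panel-wide background SFS.

The CLR sweep model: at a candidate sweep position, each of the n sampled
lineages at a linked SNP escapes the sweep independently with probability
``p_e = 1 - exp(-alpha * d)`` (d = physical distance).  Escaped lineages
retain their pre-sweep alleles (pre-sweep derived counts follow the
background SFS); non-escaped lineages all copy the allelic state of the
single sweeping haplotype.  Observations are conditioned on remaining
polymorphic.  The neutral submodel is the p_e -> 1 limit (alpha -> inf),
at which the composite likelihood reduces exactly to the background SFS,
so CLR >= 0 with equality when no alpha improves on neutrality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .io_formats import HaplotypePanel

EHH_CUTOFF = 0.05
MIN_MAF = 0.05
N_IHS_BINS = 20


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------


def fst_per_snp(derived_counts, sample_sizes) -> float:
    """Weir-Cockerham (1984) theta-hat from per-population allele counts.

    ``derived_counts[i]`` derived alleles observed among ``sample_sizes[i]``
    chromosomes in population i (haploid / allele-count form of the ANOVA
    estimator; multi-population).  Returns NaN when the locus is monomorphic
    across all populations (estimator undefined).  Small negative estimates
    are returned as-is; flooring, if wanted, is a reporting concern.
    """
    counts = np.asarray(derived_counts, dtype=float)
    sizes = np.asarray(sample_sizes, dtype=float)
    if counts.shape != sizes.shape or counts.ndim != 1:
        raise DataError("derived_counts and sample_sizes must be 1-D and aligned")
    if len(sizes) < 2:
        raise DataError("F_ST needs >= 2 populations")
    if (sizes < 2).any():
        raise DataError("F_ST needs >= 2 chromosomes per population")
    return float(fst_many(counts[None, :], sizes)[0])


def fst_many(derived_counts, sample_sizes) -> np.ndarray:
    """Vectorized :func:`fst_per_snp` over an (n_snps, n_pops) count matrix."""
    counts = np.asarray(derived_counts, dtype=float)
    sizes = np.asarray(sample_sizes, dtype=float)
    r = sizes.size
    n_tot = sizes.sum()
    p = counts / sizes
    p_bar = counts.sum(axis=1) / n_tot
    msp = (sizes * (p - p_bar[:, None]) ** 2).sum(axis=1) / (r - 1)
    msg = (sizes * p * (1.0 - p)).sum(axis=1) / (sizes - 1.0).sum()
    n_c = (n_tot - (sizes**2).sum() / n_tot) / (r - 1)
    denom = msp + (n_c - 1.0) * msg
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = (msp - msg) / denom
    theta[denom == 0.0] = np.nan  # monomorphic across all populations
    return theta


def fst_multilocus(derived_counts, sample_sizes) -> float:
    """Multi-locus Weir-Cockerham estimate: ratio of summed variance
    components over loci (the recommended combination for an average F_ST;
    the mean of per-locus ratios is biased low for few populations)."""
    counts = np.asarray(derived_counts, dtype=float)
    sizes = np.asarray(sample_sizes, dtype=float)
    r = sizes.size
    n_tot = sizes.sum()
    p = counts / sizes
    p_bar = counts.sum(axis=1) / n_tot
    msp = (sizes * (p - p_bar[:, None]) ** 2).sum(axis=1) / (r - 1)
    msg = (sizes * p * (1.0 - p)).sum(axis=1) / (sizes - 1.0).sum()
    n_c = (n_tot - (sizes**2).sum() / n_tot) / (r - 1)
    return float((msp - msg).sum() / (msp + (n_c - 1.0) * msg).sum())


def panel_fst(panel: HaplotypePanel) -> pd.DataFrame:
    """Per-SNP Weir-Cockerham F_ST over all panel populations."""
    pops = panel.populations
    if len(pops) < 2:
        raise DataError("panel F_ST needs >= 2 populations")
    rows = [panel.rows_for_population(p) for p in pops]
    counts = np.column_stack([panel.haplotypes[r].sum(axis=0) for r in rows])
    sizes = np.array([len(r) for r in rows], dtype=float)
    theta = fst_many(counts, sizes)
    return pd.DataFrame(
        {
            "snp_id": panel.snp_ids,
            "chrom": [s.chrom for s in panel.snps],
            "pos": panel.positions,
            "fst": theta,
            "undefined": np.isnan(theta),
        }
    )


# ---------------------------------------------------------------------------
# SFS and Fay-Wu H
# ---------------------------------------------------------------------------


@dataclass
class WindowStats:
    chrom: str
    start: int
    end: int
    n_chromosomes: int
    sfs: np.ndarray  # S_i indexed 0..n, only 1..n-1 populated
    no_polarized: bool = False

    @property
    def n_segregating(self) -> int:
        return int(self.sfs[1:-1].sum())


def unfolded_sfs(
    panel: HaplotypePanel,
    population: str | None = None,
    window: tuple[int, int] | None = None,
    chrom: str | None = None,
) -> WindowStats:
    """Unfolded SFS (derived-allele counts) for polarized SNPs in a window.

    ``window`` is a half-open [start, end) interval on physical positions.
    """
    rows = panel.rows_for_population(population)
    n = len(rows)
    mask = panel.polarized_mask.copy()
    chroms = np.asarray([s.chrom for s in panel.snps])
    if chrom is not None:
        mask &= chroms == chrom
    pos = panel.positions
    if window is not None:
        mask &= (pos >= window[0]) & (pos < window[1])
    counts = panel.haplotypes[np.ix_(rows, np.flatnonzero(mask))].sum(axis=0)
    counts = counts[(counts > 0) & (counts < n)]  # segregating in this sample
    sfs = np.bincount(counts, minlength=n + 1).astype(np.int64)
    used_chrom = chrom if chrom is not None else (chroms[0] if len(chroms) else ".")
    start, end = window if window is not None else (int(pos.min()), int(pos.max()) + 1)
    return WindowStats(
        chrom=str(used_chrom),
        start=start,
        end=end,
        n_chromosomes=n,
        sfs=sfs,
        no_polarized=bool(sfs.sum() == 0),
    )


def fay_wu_h(window: WindowStats) -> tuple[float, float, float]:
    """Fay-Wu H = theta_pi - theta_H from the unfolded SFS.

    theta_pi = sum_i S_i * 2 i (n - i) / (n (n - 1))
    theta_H  = sum_i S_i * 2 i^2 / (n (n - 1))

    Returns (H, theta_pi, theta_H); H = 0 when no segregating sites.
    """
    n = window.n_chromosomes
    if n < 2:
        raise DataError("Fay-Wu H needs >= 2 chromosomes")
    i = np.arange(1, n)
    s_i = window.sfs[1:n].astype(float)
    denom = n * (n - 1)
    theta_pi = float((s_i * 2.0 * i * (n - i)).sum() / denom)
    theta_h = float((s_i * 2.0 * i * i).sum() / denom)
    return theta_pi - theta_h, theta_pi, theta_h


def h_scan(
    panel: HaplotypePanel,
    population: str | None = None,
    window_size: int = 50_000,
    step: int = 10_000,
) -> pd.DataFrame:
    """Sliding-window Fay-Wu H along the panel (one chromosome at a time)."""
    frames = []
    chroms = list(dict.fromkeys(s.chrom for s in panel.snps))
    for chrom in chroms:
        pos = panel.positions[[i for i, s in enumerate(panel.snps) if s.chrom == chrom]]
        lo, hi = int(pos.min()), int(pos.max())
        starts = np.arange(lo, max(hi - window_size, lo) + 1, step, dtype=np.int64)
        rows = []
        for start in starts:
            win = unfolded_sfs(
                panel, population, window=(int(start), int(start + window_size)), chrom=chrom
            )
            h, theta_pi, theta_h = fay_wu_h(win)
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(start),
                    "end": int(start + window_size),
                    "n_segregating": win.n_segregating,
                    "theta_pi": theta_pi,
                    "theta_H": theta_h,
                    "fay_wu_H": h,
                }
            )
        frames.append(pd.DataFrame(rows))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# EHH / iHS
# ---------------------------------------------------------------------------


@dataclass
class EhhCurve:
    snp_id: str
    core_allele: str  # "ancestral" or "derived"
    n_carriers: int
    left: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    right: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    ihh: float = 0.0

    def grid(self) -> np.ndarray:
        """Full curve as (signed distance, EHH) rows, left arm negated."""
        left = np.column_stack([-self.left[:, 0][::-1], self.left[:, 1][::-1]])
        centre = np.array([[0.0, 1.0]])
        return np.vstack([left, centre, self.right])


def _ehh_arm(hap: np.ndarray, ehh_out: list, stop_below: float | None = None) -> int:
    """Accumulate EHH at each column of ``hap`` (carriers x ordered SNPs).

    With ``stop_below`` set, stops after the first value under it (the walk
    past that point never contributes to the truncated integral).  Returns
    the number of columns consumed.
    """
    c = hap.shape[0]
    pairs = c * (c - 1) / 2.0
    ids = np.zeros(c, dtype=np.int64)
    for k in range(hap.shape[1]):
        _, ids = np.unique(ids * 2 + hap[:, k], return_inverse=True)
        counts = np.bincount(ids)
        value = float((counts * (counts - 1) / 2.0).sum() / pairs)
        ehh_out.append(value)
        if stop_below is not None and value < stop_below:
            return k + 1
    return hap.shape[1]


def ehh(
    panel: HaplotypePanel,
    core_snp: str | int,
    core_allele: str = "derived",
    population: str | None = None,
    max_distance: int = 1_000_000,
    cutoff: float = EHH_CUTOFF,
    truncate_at_cutoff: bool = False,
) -> EhhCurve:
    """EHH decay curve around a core SNP for carriers of one core allele.

    EHH at a SNP boundary is the fraction of carrier pairs identical over all
    SNPs from the core out to that boundary.  ``ihh`` is the trapezoidal
    integral over physical distance of both arms, truncated after the first
    point where EHH drops below ``cutoff`` (or at ``max_distance``).  With
    ``truncate_at_cutoff`` the curve itself stops there too (cheaper; the
    integral is unchanged).
    """
    j = core_snp if isinstance(core_snp, int) else panel.snp_index(core_snp)
    snp = panel.snps[j]
    rows = panel.rows_for_population(population)
    allele_code = 1 if core_allele == "derived" else 0
    carriers = rows[panel.haplotypes[rows, j] == allele_code]
    if len(carriers) < 2:
        raise DataError(
            f"{snp.snp_id}: fewer than 2 carriers of the {core_allele} allele"
        )
    pos = panel.positions
    chrom_mask = np.asarray([s.chrom == snp.chrom for s in panel.snps])
    core_pos = pos[j]

    def arm(indices: np.ndarray) -> np.ndarray:
        sel = indices[np.abs(pos[indices] - core_pos) <= max_distance]
        if sel.size == 0:
            return np.empty((0, 2))
        values: list[float] = []
        used = _ehh_arm(
            panel.haplotypes[np.ix_(carriers, sel)],
            values,
            stop_below=cutoff if truncate_at_cutoff else None,
        )
        return np.column_stack([np.abs(pos[sel[:used]] - core_pos).astype(float), values])

    right = arm(np.flatnonzero(chrom_mask & (pos > core_pos)))
    left = arm(np.flatnonzero(chrom_mask & (pos < core_pos))[::-1])
    # both arms are built walking core-outward, i.e. ascending by distance
    curve = EhhCurve(
        snp_id=snp.snp_id,
        core_allele=core_allele,
        n_carriers=len(carriers),
        left=left,
        right=right,
    )
    curve.ihh = _integrate_arm(right, cutoff) + _integrate_arm(left, cutoff)
    return curve


def _integrate_arm(arm: np.ndarray, cutoff: float) -> float:
    """Trapezoid integral of one EHH arm from the core (EHH=1 at distance 0),
    truncated after the first point below ``cutoff``."""
    total = 0.0
    prev_d, prev_e = 0.0, 1.0
    for d, e in arm:
        total += 0.5 * (prev_e + e) * (d - prev_d)
        prev_d, prev_e = d, e
        if e < cutoff:
            break
    return total


@dataclass
class IhsScore:
    snp_id: str
    derived_freq: float
    ihh_ancestral: float
    ihh_derived: float
    unstandardized: float
    standardized: float = np.nan


def ihs_scan(
    panel: HaplotypePanel,
    population: str | None = None,
    min_maf: float = MIN_MAF,
    max_distance: int = 1_000_000,
    cutoff: float = EHH_CUTOFF,
    n_bins: int = N_IHS_BINS,
    freq_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Unstandardized and bin-standardized iHS for every eligible panel SNP.

    Eligible: polarized, derived frequency within [min_maf, 1-min_maf] and
    >= 2 carriers of each allele.  Standardization subtracts the mean and
    divides by the SD of unstandardized scores within each of ``n_bins``
    equal-width derived-frequency bins.  SNPs with a zero iHH on either
    allele are flagged undefined.  ``freq_range`` optionally restricts the
    scan to a derived-frequency band; when the band is a union of whole bins
    the standardized scores inside it are unchanged.
    """
    rows = panel.rows_for_population(population)
    n = len(rows)
    freqs = panel.haplotypes[rows].mean(axis=0)
    records = []
    for j, snp in enumerate(panel.snps):
        f = freqs[j]
        if not snp.polarized or f < min_maf or f > 1 - min_maf:
            continue
        if freq_range is not None and not freq_range[0] <= f < freq_range[1]:
            continue
        if f * n < 2 or (1 - f) * n < 2:
            continue
        ihh = {}
        for allele in ("ancestral", "derived"):
            ihh[allele] = ehh(
                panel,
                j,
                allele,
                population,
                max_distance=max_distance,
                cutoff=cutoff,
                truncate_at_cutoff=True,
            ).ihh
        if ihh["derived"] == 0.0 or ihh["ancestral"] == 0.0:
            uns = np.nan
        else:
            uns = float(np.log(ihh["ancestral"] / ihh["derived"]))
        records.append(
            {
                "snp_id": snp.snp_id,
                "pos": snp.pos,
                "derived_freq": float(f),
                "ihh_ancestral": ihh["ancestral"],
                "ihh_derived": ihh["derived"],
                "unstandardized": uns,
            }
        )
    df = pd.DataFrame(
        records,
        columns=[
            "snp_id",
            "pos",
            "derived_freq",
            "ihh_ancestral",
            "ihh_derived",
            "unstandardized",
        ],
    )
    return standardize_ihs(df, n_bins=n_bins)


def standardize_ihs(df: pd.DataFrame, n_bins: int = N_IHS_BINS) -> pd.DataFrame:
    """Standardize unstandardized iHS within equal-width derived-frequency bins."""
    df = df.copy()
    if df.empty:
        df["bin"] = pd.Series(dtype=int)
        df["ihs"] = pd.Series(dtype=float)
        return df
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    df["bin"] = np.clip(np.digitize(df["derived_freq"], edges) - 1, 0, n_bins - 1)
    ihs = np.full(len(df), np.nan)
    for _, idx in df.groupby("bin").groups.items():
        values = df.loc[idx, "unstandardized"].to_numpy()
        ok = np.isfinite(values)
        if ok.sum() >= 2:
            mu = values[ok].mean()
            sd = values[ok].std(ddof=0)
            if sd > 0:
                ihs[df.index.get_indexer(idx)] = (values - mu) / sd
    df["ihs"] = ihs
    return df


# ---------------------------------------------------------------------------
# CLR sweep scan
# ---------------------------------------------------------------------------

# sweep-intensity grid: lower bound keeps the escape probability from being
# near-uniformly small across a whole region (which would let the sweep model
# soak up global SFS misfit instead of a localized signal)
DEFAULT_ALPHA_GRID = tuple(np.geomspace(2e-6, 1e-2, 10)) + (np.inf,)


def background_sfs(panel: HaplotypePanel, population: str | None = None) -> np.ndarray:
    """Normalized unfolded SFS (q_1..q_{n-1}) over all polarized panel SNPs."""
    stats_ = unfolded_sfs(panel, population)
    n = stats_.n_chromosomes
    counts = stats_.sfs[1:n].astype(float)
    if counts.sum() == 0:
        raise DataError("empty background SFS: no polarized segregating sites")
    return counts / counts.sum()


def _sweep_mixture_matrix(q: np.ndarray, n: int) -> np.ndarray:
    """A[e, k]: probability of post-sweep derived count k given e escaped
    lineages, mixed over the background SFS q (q[i-1] = P(pre-sweep count i)).

    Pre-sweep count i assigns alleles hypergeometrically to the e escapees;
    the n-e swept lineages copy one random pre-sweep lineage (derived with
    probability i/n).  Row e = n reproduces q exactly (neutral limit).
    """
    i = np.arange(1, n)  # pre-sweep derived counts
    k = np.arange(0, n + 1)
    a = np.zeros((n + 1, n + 1))
    for e in range(n + 1):
        # h[i_idx, k] = P(j = k escaped-derived | i, e)
        h = stats.hypergeom.pmf(k[None, :], n, i[:, None], e)
        swept = n - e
        # sweeping haplotype ancestral: k = j
        contrib = (1.0 - i / n)[:, None] * h
        # sweeping haplotype derived: k = j + (n - e)
        shifted = np.zeros_like(h)
        if swept <= n:
            shifted[:, swept:] = h[:, : n + 1 - swept]
        contrib += (i / n)[:, None] * shifted
        a[e] = q @ contrib
    return a


@dataclass
class ClrResult:
    position: int
    clr: float
    alpha_hat: float


def clr_scan(
    panel: HaplotypePanel,
    population: str | None = None,
    grid_positions: np.ndarray | None = None,
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID,
    background: np.ndarray | None = None,
    chrom: str | None = None,
) -> pd.DataFrame:
    """Composite-likelihood-ratio sweep scan over a grid of positions.

    CLR = 2 (ln CL_sweep(alpha_hat) - ln CL_background), maximized over the
    (log-spaced) ``alpha_grid``; the grid always includes the neutral limit
    so CLR >= 0 everywhere.
    """
    rows = panel.rows_for_population(population)
    n = len(rows)
    chroms = [s.chrom for s in panel.snps]
    use_chrom = chrom if chrom is not None else chroms[0]
    mask = panel.polarized_mask & np.asarray([c == use_chrom for c in chroms])
    counts_all = panel.haplotypes[rows].sum(axis=0)
    mask &= (counts_all >= 1) & (counts_all <= n - 1)
    cols = np.flatnonzero(mask)
    if cols.size == 0:
        raise DataError("no polarized polymorphic SNPs for CLR scan")
    k_obs = counts_all[cols].astype(int)
    pos = panel.positions[cols].astype(float)

    if background is None:
        background = background_sfs(panel, population)
    q = np.asarray(background, dtype=float)
    if q.size != n - 1 or q.sum() <= 0:
        raise DataError("background SFS must have n-1 entries and positive mass")
    q = q / q.sum()

    if grid_positions is None:
        grid_positions = np.linspace(pos.min(), pos.max(), 50)
    alpha_grid = tuple(alpha_grid)
    if not any(np.isinf(a) for a in alpha_grid):
        alpha_grid = alpha_grid + (np.inf,)

    a_mat = _sweep_mixture_matrix(q, n)  # (n+1 escapes, n+1 counts)
    e_vals = np.arange(n + 1, dtype=float)
    from scipy.special import gammaln

    log_comb = gammaln(n + 1) - gammaln(e_vals + 1) - gammaln(n - e_vals + 1)
    tiny = 1e-300
    ln_bg = float(np.log(np.maximum(q[k_obs - 1], tiny)).sum())

    def binom_rows(p_e: np.ndarray) -> np.ndarray:
        """Binomial pmf rows over e = 0..n for each escape probability."""
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = np.log(p_e)[:, None]
            lq = np.log1p(-p_e)[:, None]
            logb = log_comb[None, :] + e_vals[None, :] * lp + (n - e_vals)[None, :] * lq
        b = np.exp(np.nan_to_num(logb, nan=-np.inf, neginf=-np.inf))
        b[p_e == 0.0] = 0.0
        b[p_e == 0.0, 0] = 1.0
        b[p_e == 1.0] = 0.0
        b[p_e == 1.0, n] = 1.0
        return b

    results = []
    for g in np.asarray(grid_positions, dtype=float):
        d = np.abs(pos - g)
        best_ll, best_alpha = -np.inf, np.inf
        for alpha in alpha_grid:
            if np.isinf(alpha):
                ll = ln_bg
            else:
                p_e = -np.expm1(-alpha * d)  # 1 - exp(-alpha d)
                b = binom_rows(p_e)  # (S, n+1)
                p_all = b @ a_mat  # (S, n+1): full count distribution
                p_poly = 1.0 - p_all[:, 0] - p_all[:, n]
                p_k = p_all[np.arange(len(k_obs)), k_obs]
                ll = float(
                    np.log(np.maximum(p_k, tiny)).sum()
                    - np.log(np.maximum(p_poly, tiny)).sum()
                )
            if ll > best_ll:
                best_ll, best_alpha = ll, alpha
        results.append(
            ClrResult(position=int(round(g)), clr=2.0 * (best_ll - ln_bg), alpha_hat=best_alpha)
        )
    return pd.DataFrame(
        {
            "position": [r.position for r in results],
            "clr": [r.clr for r in results],
            "alpha_hat": [r.alpha_hat for r in results],
        }
    )


# ---------------------------------------------------------------------------
# empirical thresholds
# ---------------------------------------------------------------------------


def genome_percentile_threshold(values, quantile: float) -> float:
    """Empirical quantile (linear interpolation) of a panel-wide statistic,
    e.g. the 5% extreme line drawn for Fay-Wu H."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 20:
        raise DataError("need >= 20 values for an empirical threshold")
    return float(np.quantile(values, quantile))
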