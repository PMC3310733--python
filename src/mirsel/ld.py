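"""Pairwise linkage disequilibrium and the hitchhiking-control filter.

Haplotype frequencies are obtained by direct counting on the phased panel
(no EM).  Conventions: D = p_AB - p_A p_B; D' = D / D_max with
D_max = min(p_A p_b, p_a p_B) for D > 0 and min(p_A p_B, p_a p_b) for
D < 0; r^2 = D^2 / (p_A p_a p_B p_b); LOD is the base-10 log of the
multinomial likelihood ratio of the observed haplotype frequencies against
linkage equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .io_formats import HaplotypePanel


@dataclass
class LdStats:
    snp_i: str
    snp_j: str
    haplotype_counts: np.ndarray  # 2x2: [allele_i][allele_j]
    d: float
    d_prime: float
    r2: float
    lod: float


def _ld_from_columns(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, float, float, float]:
    n = len(x)
    counts = np.zeros((2, 2))
    for a in (0, 1):
        for b in (0, 1):
            counts[a, b] = np.count_nonzero((x == a) & (y == b))
    p_a = x.mean()
    p_b = y.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise DataError("LD undefined for a monomorphic SNP")
    p_ab = counts[1, 1] / n
    d = p_ab - p_a * p_b
    if d > 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    elif d < 0:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    else:
        d_max = 1.0
    d_prime = d / d_max if d_max > 0 else 0.0
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    # multinomial likelihood ratio: observed haplotype freqs vs independence
    marg_a = np.array([1 - p_a, p_a])
    marg_b = np.array([1 - p_b, p_b])
    lod = 0.0
    for a in (0, 1):
        for b in (0, 1):
            c = counts[a, b]
            if c > 0:
                obs = c / n
                exp = marg_a[a] * marg_b[b]
                lod += c * (np.log10(obs) - np.log10(exp))
    return counts, float(d), float(d_prime), float(r2), float(max(0.0, lod))


def ld_pair(
    panel: HaplotypePanel,
    snp_i: str | int,
    snp_j: str | int,
    population: str | None = None,
) -> LdStats:
    """LD statistics between two SNPs by direct haplotype counting."""
    i = snp_i if isinstance(snp_i, int) else panel.snp_index(snp_i)
    j = snp_j if isinstance(snp_j, int) else panel.snp_index(snp_j)
    rows = panel.rows_for_population(population)
    counts, d, d_prime, r2, lod = _ld_from_columns(
        panel.haplotypes[rows, i].astype(int), panel.haplotypes[rows, j].astype(int)
    )
    return LdStats(
        snp_i=panel.snps[i].snp_id,
        snp_j=panel.snps[j].snp_id,
        haplotype_counts=counts,
        d=d,
        d_prime=d_prime,
        r2=r2,
        lod=lod,
    )


def hitchhike_filter(
    target_snps: list[str],
    panel: HaplotypePanel,
    functional_snps: list[str] | None = None,
    window_bp: int = 500_000,
    r2_threshold: float = 0.5,
    population: str | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Exclude targets linked to annotated functional variants.

    A target SNP is excluded iff some functional SNP on the same chromosome
    lies within +/- ``window_bp`` and has r^2 >= ``r2_threshold`` with it.
    r^2 is evaluated within populations (pooled-panel r^2 is inflated by
    population structure alone); with ``population=None`` every panel
    population is checked and any hit excludes the target.  Returns
    (retained targets, exclusion log with the triggering pair).
    """
    if functional_snps is None:
        functional_snps = [s.snp_id for s in panel.snps if s.functional_flag]
    by_id = {s.snp_id: s for s in panel.snps}
    pops = [population] if population is not None else panel.populations
    pop_rows = {p: panel.rows_for_population(p) for p in pops}
    retained: list[str] = []
    log_rows = []
    for target in target_snps:
        t = by_id[target]
        trigger = None
        for func in functional_snps:
            if func == target:
                continue
            f = by_id[func]
            if f.chrom != t.chrom or abs(f.pos - t.pos) > window_bp:
                continue
            ti, fi = panel.snp_index(target), panel.snp_index(func)
            for pop, rows in pop_rows.items():
                x = panel.haplotypes[rows, ti].astype(int)
                y = panel.haplotypes[rows, fi].astype(int)
                if x.min() == x.max() or y.min() == y.max():
                    continue
                _, _, _, r2, _ = _ld_from_columns(x, y)
                if r2 >= r2_threshold:
                    trigger = (func, abs(f.pos - t.pos), r2, pop)
                    break
            if trigger is not None:
                break
        if trigger is None:
            retained.append(target)
        else:
            log_rows.append(
                {
                    "target_snp": target,
                    "functional_snp": trigger[0],
                    "distance_bp": trigger[1],
                    "r2": trigger[2],
                    "population": trigger[3],
                }
            )
    log = pd.DataFrame(
        log_rows, columns=["target_snp", "functional_snp", "distance_bp", "r2", "population"]
    )
    return retained, log


def region_ld_profile(
    panel: HaplotypePanel,
    focal_snp: str,
    region: tuple[int, int] | None = None,
    populations: list[str] | None = None,
) -> pd.DataFrame:
    """r^2 of every region SNP with the focal SNP, per population.

    SNPs monomorphic in a population get NaN (missing, not 0).
    """
    focal_idx = panel.snp_index(focal_snp)
    focal_chrom = panel.snps[focal_idx].chrom
    if populations is None:
        populations = panel.populations
    records = []
    for j, snp in enumerate(panel.snps):
        if snp.chrom != focal_chrom:
            continue
        if region is not None and not region[0] <= snp.pos < region[1]:
            continue
        row: dict = {"snp_id": snp.snp_id, "pos": snp.pos}
        for pop in populations:
            rows = panel.rows_for_population(pop)
            x = panel.haplotypes[rows, focal_idx].astype(int)
            y = panel.haplotypes[rows, j].astype(int)
            if x.min() == x.max() or y.min() == y.max():
                row[f"r2_{pop}"] = np.nan
            else:
                row[f"r2_{pop}"] = _ld_from_columns(x, y)[3]
        records.append(row)
    return pd.DataFrame(records)
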