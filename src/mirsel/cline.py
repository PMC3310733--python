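"""Latitude-allele-frequency clines and genome-wide empirical extremeness.

Pearson correlation between the derived allele frequency and the absolute
latitude of the populations sampled, with metadata-driven population
exclusions applied first.  Significance is assessed empirically: the
fraction of genome-wide SNPs whose correlation is at least as extreme as
the focal SNP's (two-sided on |R| by default), optionally restricted to
SNPs above an F_ST threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .io_formats import PopulationMeta


@dataclass
class ClineResult:
    snp_id: str
    pearson_r: float
    n_populations: int
    percentile: float | None = None
    restricted_percentile: float | None = None


def latitude_correlation(
    freqs: dict[str, float] | pd.Series, populations: list[PopulationMeta]
) -> tuple[float, int]:
    """Pearson R of derived frequency vs absolute latitude.

    Populations flagged ``excluded`` in the metadata are dropped before the
    correlation; needs >= 3 retained populations with variable latitude and
    frequency (else a :class:`DataError` flags the SNP undefined).
    Returns (R, number of populations used).
    """
    if isinstance(freqs, pd.Series):
        freqs = freqs.to_dict()
    used = [p for p in populations if not p.excluded and p.population_id in freqs]
    if len(used) < 3:
        raise DataError("latitude correlation needs >= 3 non-excluded populations")
    lat = np.array([p.absolute_latitude for p in used], dtype=float)
    f = np.array([freqs[p.population_id] for p in used], dtype=float)
    if np.ptp(lat) == 0.0:
        raise DataError("zero variance in latitude")
    if np.ptp(f) == 0.0:
        raise DataError("zero variance in allele frequency")
    r = np.corrcoef(lat, f)[0, 1]
    return float(r), len(used)


def correlations_table(
    freq_table: pd.DataFrame, populations: list[PopulationMeta]
) -> pd.DataFrame:
    """Per-SNP latitude correlations for a snp x population frequency table."""
    used = [p for p in populations if not p.excluded and p.population_id in freq_table.columns]
    if len(used) < 3:
        raise DataError("latitude correlation needs >= 3 non-excluded populations")
    lat = np.array([p.absolute_latitude for p in used], dtype=float)
    if np.ptp(lat) == 0.0:
        raise DataError("zero variance in latitude")
    values = freq_table[[p.population_id for p in used]].to_numpy(dtype=float)
    lat_c = lat - lat.mean()
    v_c = values - values.mean(axis=1, keepdims=True)
    denom = np.sqrt((v_c**2).sum(axis=1) * (lat_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (v_c @ lat_c) / denom
    r[denom == 0.0] = np.nan  # constant frequency: undefined, flagged
    return pd.DataFrame(
        {
            "snp_id": freq_table.index,
            "pearson_r": r,
            "n_populations": len(used),
            "undefined": np.isnan(r),
        }
    ).reset_index(drop=True)


def genome_percentile(focal_r: float, all_r, two_sided: bool = True) -> float:
    """Fraction of genome-wide SNPs at least as extreme as the focal SNP.

    ``all_r`` is the genome-wide correlation distribution (the focal SNP is
    conventionally part of it, so the most extreme SNP scores 1/N).
    """
    all_r = np.asarray(all_r, dtype=float)
    all_r = all_r[np.isfinite(all_r)]
    if all_r.size == 0:
        raise DataError("empty genome-wide correlation set")
    if two_sided:
        return float(np.count_nonzero(np.abs(all_r) >= abs(focal_r)) / all_r.size)
    if focal_r < 0:
        return float(np.count_nonzero(all_r <= focal_r) / all_r.size)
    return float(np.count_nonzero(all_r >= focal_r) / all_r.size)


def cline_analysis(
    freq_table: pd.DataFrame,
    populations: list[PopulationMeta],
    fst_by_snp: dict[str, float] | None = None,
    fst_threshold: float = 0.5,
    two_sided: bool = True,
) -> pd.DataFrame:
    """Correlations plus genome-wide (and high-F_ST-restricted) percentiles."""
    table = correlations_table(freq_table, populations)
    all_r = table["pearson_r"].to_numpy()
    table["percentile"] = [
        genome_percentile(r, all_r, two_sided) if np.isfinite(r) else np.nan
        for r in all_r
    ]
    if fst_by_snp is not None:
        high = table["snp_id"].map(fst_by_snp).to_numpy() >= fst_threshold
        high_r = all_r[high & np.isfinite(all_r)]
        table["restricted_percentile"] = [
            genome_percentile(r, high_r, two_sided)
            if np.isfinite(r) and h and high_r.size
            else np.nan
            for r, h in zip(all_r, high)
        ]
    return table
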