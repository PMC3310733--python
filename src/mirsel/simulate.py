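"""Ground-truth-annotated synthetic inputs.

Population structure follows the Balding-Nichols model: an ancestral
frequency p is drawn per SNP (uniform on [0.05, 0.95] by default) and each
population's frequency is Beta-distributed with mean p and variance
F * p * (1 - p), so the mean Weir-Cockerham F_ST over many SNPs calibrates
to the drift parameter.  Haplotypes are built by a copying-style latent
chain: each haplotype carries a latent uniform value that is redrawn with
probability ``recombination_rate_per_bp * distance`` between adjacent SNPs
and thresholded against the population frequency at each SNP.  This keeps
the per-SNP marginal frequencies exact while giving distance-decaying LD
and haplotype homozygosity.

Sweeps are injected structurally: carriers of the sweeping allele are
topped up to the requested final frequency and the converted haplotypes
copy a single donor haplotype within a homogenization radius, creating
extended homozygosity and an excess of high-frequency derived alleles.

Truth tables are always returned separately from the input artifacts handed
to the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .io_formats import (
    DNA_BASES,
    HaplotypePanel,
    MirnaFamily,
    PopulationMeta,
    SnpRecord,
    UtrSequence,
    revcomp,
    rna_to_dna,
)
from . import target_scan

ANCESTRAL_FREQ_RANGE = (0.05, 0.95)


@dataclass
class SimConfig:
    n_populations: int = 2
    samples_per_population: int = 50
    n_snps: int = 1000
    drift_F: float = 0.1
    recombination_rate_per_bp: float = 1e-6
    region_length_bp: int = 1_000_000
    rng_seed: int = 0
    chrom: str = "1"

    def validate(self) -> None:
        if not 0.0 < self.drift_F < 1.0:
            raise ConfigError("drift_F must be in (0, 1)")
        for name in ("n_populations", "samples_per_population", "n_snps", "region_length_bp"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.recombination_rate_per_bp < 0:
            raise ConfigError("recombination_rate_per_bp must be >= 0")


@dataclass
class SweepSpec:
    sweep_pos: int
    target_population: str
    final_derived_freq: float = 1.0
    homogenization_radius_bp: int = 100_000

    def validate(self, region_length: int | None = None) -> None:
        if not 0.0 < self.final_derived_freq <= 1.0:
            raise ConfigError("final_derived_freq must be in (0, 1]")
        if region_length is not None and not 0 <= self.sweep_pos <= region_length:
            raise ConfigError("sweep_pos outside region")


@dataclass
class SitePlantSpec:
    """What to plant: ``fraction_allele_disrupting`` is the fraction of
    planted sites where one allele breaks the match (allele-dependent);
    the remainder are planted clear of the SNP's 15-nt window, so they
    yield no allele-dependent call."""

    n_planted_sites: int = 10
    site_type_mix: dict[str, float] = field(
        default_factory=lambda: {"8mer": 0.25, "7mer-m8": 0.25, "7mer-A1": 0.25, "6mer": 0.25}
    )
    fraction_allele_disrupting: float = 1.0
    gc_content: float = 0.5
    utr_length: int = 120

    def validate(self) -> None:
        if abs(sum(self.site_type_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("site_type_mix fractions must sum to 1")
        unknown = set(self.site_type_mix) - set(target_scan.SITE_PRIORITY)
        if unknown:
            raise ConfigError(f"unknown site types {sorted(unknown)}")
        if not 0.0 <= self.fraction_allele_disrupting <= 1.0:
            raise ConfigError("fraction_allele_disrupting must be in [0, 1]")


def _population_frequencies(p: np.ndarray, drift_f: float, n_pops: int, rng) -> np.ndarray:
    """Balding-Nichols per-population frequencies: Beta with mean p and
    variance drift_f * p * (1 - p)."""
    scale = (1.0 - drift_f) / drift_f
    a = p * scale
    b = (1.0 - p) * scale
    return rng.beta(a[None, :], b[None, :], size=(n_pops, p.size))


def _copying_chain(
    freqs: np.ndarray, positions: np.ndarray, n_haps: int, rate: float, rng
) -> np.ndarray:
    """Latent-uniform copying chain yielding 0/1 haplotypes with exact
    per-SNP marginals ``freqs`` and LD decaying with distance."""
    n_snps = freqs.size
    switch = np.minimum(1.0, rate * np.diff(positions))
    u = rng.random((n_haps, n_snps))
    latent = np.empty((n_haps, n_snps))
    latent[:, 0] = u[:, 0]
    switch_draw = rng.random((n_haps, n_snps - 1)) < switch[None, :]
    for j in range(1, n_snps):
        latent[:, j] = np.where(switch_draw[:, j - 1], u[:, j], latent[:, j - 1])
    return (latent < freqs[None, :]).astype(np.int8)


def simulate_panel(config: SimConfig) -> tuple[HaplotypePanel, pd.DataFrame]:
    """Simulate a multi-population phased panel; returns (panel, truth table).

    Monomorphic columns (after sampling) are dropped.  The truth table
    records ancestral and realized per-population frequencies per SNP.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    n_pops = config.n_populations
    n_haps_per_pop = 2 * config.samples_per_population

    positions = np.sort(
        rng.choice(np.arange(1, config.region_length_bp + 1), size=config.n_snps, replace=False)
        if config.region_length_bp >= config.n_snps
        else np.arange(1, config.n_snps + 1)
    )
    lo, hi = ANCESTRAL_FREQ_RANGE
    p_anc = rng.uniform(lo, hi, size=config.n_snps)
    pop_freqs = _population_frequencies(p_anc, config.drift_F, n_pops, rng)

    blocks = [
        _copying_chain(
            pop_freqs[k], positions, n_haps_per_pop, config.recombination_rate_per_bp, rng
        )
        for k in range(n_pops)
    ]
    matrix = np.vstack(blocks)

    # drop columns monomorphic across the whole panel
    col_sums = matrix.sum(axis=0)
    keep = (col_sums > 0) & (col_sums < matrix.shape[0])
    matrix = matrix[:, keep]
    positions = positions[keep]
    p_anc = p_anc[keep]
    pop_freqs = pop_freqs[:, keep]

    base_pairs = rng.integers(0, 4, size=(2, positions.size))
    # ensure ref != alt
    clash = base_pairs[0] == base_pairs[1]
    base_pairs[1, clash] = (base_pairs[1, clash] + 1 + rng.integers(0, 3, clash.sum())) % 4

    pops = [f"pop{k + 1}" for k in range(n_pops)]
    snps = []
    width = len(str(positions.size))
    for j, pos in enumerate(positions):
        ref = DNA_BASES[base_pairs[0, j]]
        alt = DNA_BASES[base_pairs[1, j]]
        snps.append(
            SnpRecord(
                snp_id=f"snp{j:0{width}d}",
                chrom=config.chrom,
                pos=int(pos),
                ref_allele=ref,
                alt_allele=alt,
                ancestral_allele=ref,  # ancestral == REF in simulation
            )
        )
    samples = [f"{pop}_s{i:03d}" for pop in pops for i in range(config.samples_per_population)]
    panel = HaplotypePanel(
        haplotypes=matrix,
        snps=snps,
        haplotype_samples=[s for s in samples for _ in range(2)],
        sample_to_population={s: s.rsplit("_", 1)[0] for s in samples},
    )
    truth = pd.DataFrame(
        {
            "snp_id": panel.snp_ids,
            "pos": positions,
            "ancestral_freq": p_anc,
            **{f"freq_{pop}": pop_freqs[k] for k, pop in enumerate(pops)},
        }
    )
    return panel, truth


def inject_sweep(
    panel: HaplotypePanel, spec: SweepSpec, rng_seed: int = 0
) -> tuple[HaplotypePanel, pd.DataFrame]:
    """Raise the derived allele at ``sweep_pos`` to the target frequency in
    one population by copying a donor haplotype within the homogenization
    radius.  Returns a new panel and a truth table of converted rows."""
    spec.validate()
    rng = np.random.default_rng(rng_seed)
    positions = panel.positions
    hits = np.flatnonzero(positions == spec.sweep_pos)
    if hits.size == 0:
        raise DataError(f"sweep position {spec.sweep_pos} is not a SNP column")
    j = int(hits[0])
    rows = panel.rows_for_population(spec.target_population)
    matrix = panel.haplotypes.copy()

    carriers = rows[matrix[rows, j] == 1]
    target_count = int(round(spec.final_derived_freq * len(rows)))
    if target_count < len(carriers):
        raise DataError(
            f"final_derived_freq {spec.final_derived_freq} below the current "
            f"derived frequency {len(carriers) / len(rows):.3f}"
        )
    if len(carriers) == 0:
        seed_row = int(rng.choice(rows))
        matrix[seed_row, j] = 1
        carriers = np.array([seed_row])
    donor = int(rng.choice(carriers))
    non_carriers = rows[matrix[rows, j] == 0]
    n_convert = target_count - len(carriers)
    converted = np.sort(rng.choice(non_carriers, size=n_convert, replace=False))
    # every final carrier descends from the single sweeping haplotype, so all
    # carriers (original and converted) are homogenized within the radius
    homogenized = np.sort(np.setdiff1d(carriers, [donor]))

    near = np.abs(positions - spec.sweep_pos) <= spec.homogenization_radius_bp
    near &= np.asarray([s.chrom == panel.snps[j].chrom for s in panel.snps])
    donor_block = matrix[donor, near]
    for group in (converted, homogenized):
        if group.size:
            matrix[np.ix_(group, np.flatnonzero(near))] = donor_block
    matrix[converted, j] = 1  # always convert the focal allele, even radius 0

    swept = HaplotypePanel(
        haplotypes=matrix,
        snps=panel.snps,
        haplotype_samples=panel.haplotype_samples,
        sample_to_population=panel.sample_to_population,
    )
    truth = pd.DataFrame(
        {
            "haplotype_row": np.concatenate([[donor], converted, homogenized]),
            "role": ["donor"]
            + ["converted"] * len(converted)
            + ["homogenized"] * len(homogenized),
        }
    )
    truth.attrs["sweep_pos"] = spec.sweep_pos
    truth.attrs["snp_id"] = panel.snps[j].snp_id
    return swept, truth


# ---------------------------------------------------------------------------
# planted miRNA sites
# ---------------------------------------------------------------------------


def _random_sequence(length: int, gc: float, rng) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(DNA_BASES[i] for i in rng.choice(4, size=length, p=probs))


def _site_motif(seed: str, site_type: str) -> str:
    heptamer = revcomp(rna_to_dna(seed))
    hexamer = revcomp(rna_to_dna(seed[:6]))
    return {
        "8mer": heptamer + "A",
        "7mer-m8": heptamer,
        "7mer-A1": hexamer + "A",
        "6mer": hexamer,
    }[site_type]


def plant_utr_sites(
    panel: HaplotypePanel,
    families: list[MirnaFamily],
    spec: SitePlantSpec,
    rng_seed: int = 0,
    snp_ids: list[str] | None = None,
) -> tuple[list[UtrSequence], pd.DataFrame]:
    """Build synthetic UTRs with planted seed sites at panel SNPs.

    One UTR (one transcript of one gene) is produced per planted site.  For
    allele-dependent sites one allele completes a seed match of the
    requested type at the SNP offset while the other breaks it; for the
    remainder (1 - fraction_allele_disrupting) the site is planted clear of
    the SNP's 15-nt window.  Rejection sampling guarantees that the scanner
    recovers exactly the planted calls (and no accidental allele-dependent
    call for any provided family) within the window.

    The UTR sequence always carries the REF base at the SNP offset; when the
    intact allele is ALT the planted motif is completed only by substitution.
    """
    spec.validate()
    if not families:
        raise DataError("no miRNA families to plant")
    rng = np.random.default_rng(rng_seed)
    by_id = {s.snp_id: s for s in panel.snps}
    if snp_ids is None:
        snp_ids = list(rng.choice(panel.snp_ids, size=spec.n_planted_sites, replace=False))
    elif len(snp_ids) != spec.n_planted_sites:
        raise DataError("snp_ids length must equal n_planted_sites")

    types = list(spec.site_type_mix)
    type_probs = np.array([spec.site_type_mix[t] for t in types])

    utrs: list[UtrSequence] = []
    truth_rows = []
    for idx, snp_id in enumerate(snp_ids):
        snp = by_id[snp_id]
        allele_dependent = rng.random() < spec.fraction_allele_disrupting
        # for allele-dependent sites, either allele may be the intact one:
        # REF intact -> the ALT allele disrupts; ALT intact -> ALT creates
        ref_intact = bool(rng.integers(0, 2))
        intact_base = snp.ref_allele if ref_intact else snp.alt_allele
        utr = None
        family = families[0]
        site_type = types[0]
        for _ in range(2000):
            family = families[int(rng.integers(0, len(families)))]
            site_type = types[int(rng.choice(len(types), p=type_probs))]
            motif = _site_motif(family.seed, site_type)
            core_len = 7 if site_type in ("8mer", "7mer-m8") else 6
            length = spec.utr_length
            seq = list(_random_sequence(length, spec.gc_content, rng))
            offset = int(rng.integers(7, length - 8))  # keep full window inside
            if allele_dependent:
                # SNP must fall on a core-match base equal to the intact allele
                spots = [p for p in range(core_len) if motif[p] == intact_base]
                if not spots:
                    continue
                snp_in_motif = spots[int(rng.integers(0, len(spots)))]
                site_start = offset - snp_in_motif
            else:
                # site planted clear of the SNP's 15-nt window
                left_room = offset - 7 - len(motif)
                right_start = offset + 8
                right_room = length - right_start - len(motif)
                choices = []
                if left_room >= 0:
                    choices.append(int(rng.integers(0, left_room + 1)))
                if right_room >= 0:
                    choices.append(right_start + int(rng.integers(0, right_room + 1)))
                if not choices:
                    continue
                site_start = choices[int(rng.integers(0, len(choices)))]
            if site_start < 0 or site_start + len(motif) > length:
                continue
            seq[site_start : site_start + len(motif)] = motif
            # the stored sequence always carries the REF base at the SNP offset
            seq[offset] = snp.ref_allele
            candidate = "".join(seq)
            window_start = offset - 7
            ref_win = candidate[window_start : offset + 8]
            alt_win = ref_win[:7] + snp.alt_allele + ref_win[8:]
            if allele_dependent:
                intact_win = ref_win if ref_intact else alt_win
                broken_win = alt_win if ref_intact else ref_win
                hit_intact = target_scan.classify_site(intact_win, family.seed, allow_6mer=True)
                hit_broken = target_scan.classify_site(broken_win, family.seed, allow_6mer=True)
                if hit_intact is None or hit_intact[0] != site_type or hit_broken is not None:
                    continue
            else:
                # neither allele window may contain a site for this family
                if target_scan.classify_site(ref_win, family.seed, allow_6mer=True) is not None:
                    continue
                if target_scan.classify_site(alt_win, family.seed, allow_6mer=True) is not None:
                    continue
            # no accidental allele-dependent call for any other family
            clean = True
            for other in families:
                if other.family_id == family.family_id:
                    continue
                r = target_scan.classify_site(ref_win, other.seed, allow_6mer=True)
                a = target_scan.classify_site(alt_win, other.seed, allow_6mer=True)
                if (r is None) != (a is None):
                    clean = False
                    break
            if not clean:
                continue
            utr = UtrSequence(
                transcript_id=f"tx{idx:04d}",
                gene_id=f"gene{idx:04d}",
                chrom=snp.chrom,
                strand="+",
                genomic_start=0,
                sequence=candidate,
                snp_offsets={snp_id: offset},
            )
            break
        if utr is None:
            raise DataError(
                f"could not place a {site_type} site for family {family.family_id} "
                f"at SNP {snp_id} without accidental matches"
            )
        utrs.append(utr)
        if allele_dependent:
            verdict = "disrupting" if ref_intact else "creating"
            intact = "ref" if ref_intact else "alt"
        else:
            verdict = "none"
            intact = "both"
        truth_rows.append(
            {
                "snp_id": snp_id,
                "transcript_id": utr.transcript_id,
                "gene_id": utr.gene_id,
                "family_id": family.family_id,
                "site_type": site_type,
                "intact_allele": intact,
                "verdict": verdict,
                "site_start": site_start,
                "offset": utr.snp_offsets[snp_id],
            }
        )
    truth = pd.DataFrame(truth_rows)
    return utrs, truth


# ---------------------------------------------------------------------------
# latitude clines
# ---------------------------------------------------------------------------


def plant_latitude_cline(
    populations: list[PopulationMeta],
    cline_slope: float,
    n_cline_snps: int,
    n_null_snps: int,
    noise_sd: float = 0.05,
    null_drift_F: float = 0.05,
    rng_seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-population derived-frequency table with planted latitude clines.

    Cline SNPs: frequency = clip(a + slope * |latitude| + noise, 0, 1) with a
    random intercept keeping mid-range frequencies.  Null SNPs: Balding-
    Nichols frequencies independent of latitude.  Returns (frequency table
    indexed by snp_id with one column per population, truth table).
    """
    if len(populations) < 3:
        raise DataError("need >= 3 populations for a latitude cline")
    if len({p.absolute_latitude for p in populations}) < 4 and n_cline_snps > 0:
        if len({p.absolute_latitude for p in populations}) < 3:
            raise DataError("populations must have distinct latitudes")
    rng = np.random.default_rng(rng_seed)
    lats = np.array([p.absolute_latitude for p in populations])
    pop_ids = [p.population_id for p in populations]

    rows = {}
    truth_rows = []
    mid = float(np.mean(lats))
    for i in range(n_cline_snps):
        a = rng.uniform(0.4, 0.6) - cline_slope * mid
        freqs = a + cline_slope * lats + rng.normal(0.0, noise_sd, size=lats.size)
        rows[f"cline{i:05d}"] = np.clip(freqs, 0.0, 1.0)
        truth_rows.append({"snp_id": f"cline{i:05d}", "is_cline": True, "slope": cline_slope})
    lo, hi = ANCESTRAL_FREQ_RANGE
    p_null = rng.uniform(lo, hi, size=n_null_snps)
    null_freqs = _population_frequencies(p_null, null_drift_F, lats.size, rng)
    for i in range(n_null_snps):
        rows[f"null{i:05d}"] = null_freqs[:, i]
        truth_rows.append({"snp_id": f"null{i:05d}", "is_cline": False, "slope": 0.0})

    table = pd.DataFrame.from_dict(rows, orient="index", columns=pop_ids)
    table.index.name = "snp_id"
    return table, pd.DataFrame(truth_rows)
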