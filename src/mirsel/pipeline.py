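"""End-to-end orchestration: simulate-or-load -> scan -> stats -> enrich ->
filter -> cline -> report.

The pipeline is a pure function of (inputs, seed): one global seed fans out
to per-stage child seeds through :class:`numpy.random.SeedSequence`, every
filter stage logs its in/out counts, and all outputs are plain text written
deterministically (byte-identical across reruns).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cline as cline_mod
from . import enrichment as enrich_mod
from . import ld as ld_mod
from . import popgen, simulate, target_scan
from .errors import ConfigError, DataError
from .io_formats import (
    HaplotypePanel,
    MirnaFamily,
    PopulationMeta,
    UtrSequence,
    read_mirna_families,
    read_population_meta,
    read_utrs,
    read_vcf,
    utr_snp_table,
    write_results_tables,
    write_tsv,
    write_utr_fasta,
    write_vcf,
)

PROFILES = ("null", "enriched", "sweep", "cline", "full")


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run."""

    input_dir: str | None = None
    profile: str | None = "full"
    seed: int = 0
    out_dir: str = "mirsel_out"
    allow_6mer: bool = False
    score_threshold: float = target_scan.DEFAULT_SCORE_THRESHOLD
    fst_edges: tuple[float, ...] = enrich_mod.DEFAULT_EDGES
    candidate_fst_threshold: float = 0.5
    bootstrap_reps: int = 1000
    bootstrap_replace: bool = False
    ld_window_bp: int = 500_000
    ld_r2_threshold: float = 0.5
    h_window_bp: int = 50_000
    h_step_bp: int = 10_000
    ihs_bins: int = 10
    clr_grid_points: int = 40
    cline_two_sided: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.profile is not None and self.profile not in PROFILES:
            raise ConfigError(f"unknown profile {self.profile!r}; choose from {PROFILES}")
        if self.input_dir is None and self.profile is None:
            raise ConfigError("either input_dir or profile must be set")
        if not 0.0 <= self.candidate_fst_threshold <= 1.01:
            raise ConfigError("candidate_fst_threshold out of range")
        if self.bootstrap_reps < 2:
            raise ConfigError("bootstrap_reps must be >= 2")
        if not 0.0 <= self.ld_r2_threshold <= 1.0:
            raise ConfigError("ld_r2_threshold out of range")

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["fst_edges"] = list(self.fst_edges)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class Dataset:
    """All pipeline inputs plus (separately emitted) ground truth."""

    panel: HaplotypePanel
    utrs: list[UtrSequence]
    families: list[MirnaFamily]
    cline_populations: list[PopulationMeta]
    cline_freqs: pd.DataFrame | None
    truth: dict[str, pd.DataFrame] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# dataset construction
# ---------------------------------------------------------------------------

_FIXTURE_FAMILIES = [
    ("famA", "UAAUGCU", "mir-a1"),
    ("famB", "GGAGUGU", "mir-b1"),
    ("famC", "ACACACC", "mir-c1"),
    ("famD", "ACACUGC", "mir-d1"),
    ("famE", "UGGCUUA", "mir-e1"),
]


def _force_high_fst(
    panel: HaplotypePanel, columns: list[int], rng, high: float = 0.95, low: float = 0.05
) -> None:
    """Redraw selected columns with extreme per-population frequencies so
    they land in the top F_ST bin (pop1 high, the rest low)."""
    for j in columns:
        for k, pop in enumerate(panel.populations):
            rows = panel.rows_for_population(pop)
            freq = high if k == 0 else low
            panel.haplotypes[rows, j] = (rng.random(len(rows)) < freq).astype(np.int8)
        col = panel.haplotypes[:, j]
        if col.min() == col.max():  # keep the column polymorphic
            panel.haplotypes[rng.integers(0, panel.n_haplotypes), j] = 1 - col[0]


def make_dataset(profile: str, seed: int = 0) -> Dataset:
    """Build an in-memory synthetic dataset for a named profile.

    Profiles: ``null`` (no planted signal), ``enriched`` (planted sites
    only), ``sweep`` (injected sweep), ``cline`` (latitude clines), ``full``
    (all signal types, incl. one decoy candidate linked to a functional SNP).
    """
    if profile not in PROFILES:
        raise ConfigError(f"unknown profile {profile!r}; choose from {PROFILES}")
    seeds = np.random.SeedSequence(seed).spawn(6)
    rng = np.random.default_rng(seeds[0])
    families = [MirnaFamily(f, s, [m]) for f, s, m in _FIXTURE_FAMILIES]

    sim = simulate.SimConfig(
        n_populations=3,
        samples_per_population=30,
        n_snps=600,
        drift_F=0.2,
        recombination_rate_per_bp=2e-6,
        region_length_bp=2_000_000,
        rng_seed=int(seeds[1].generate_state(1)[0] % (2**31)),
    )
    panel, panel_truth = simulate.simulate_panel(sim)
    truth: dict[str, pd.DataFrame] = {"panel": panel_truth}

    n_sites = 12
    forced: list[int] = []
    site_snp_ids: list[str] | None = None
    if profile in ("enriched", "full"):
        pos = panel.positions
        first_half = np.flatnonzero(pos < 600_000)
        forced = list(rng.choice(first_half, size=5, replace=False))
        _force_high_fst(panel, forced, rng)
        background_cols = np.flatnonzero(pos >= 600_000)
        low_sites = rng.choice(background_cols, size=n_sites - 5, replace=False)
        site_cols = forced + list(low_sites)
        site_snp_ids = [panel.snps[j].snp_id for j in site_cols]

    sweep_truth = None
    if profile in ("sweep", "full"):
        pos = panel.positions
        mid = np.flatnonzero(np.abs(pos - 1_500_000) < 200_000)
        sweep_col = int(mid[len(mid) // 2])
        spec = simulate.SweepSpec(
            sweep_pos=int(pos[sweep_col]),
            target_population=panel.populations[0],
            final_derived_freq=0.95,
            homogenization_radius_bp=150_000,
        )
        panel, sweep_truth = simulate.inject_sweep(
            panel, spec, rng_seed=int(seeds[2].generate_state(1)[0] % (2**31))
        )
        truth["sweep"] = sweep_truth.assign(
            sweep_pos=spec.sweep_pos, snp_id=sweep_truth.attrs["snp_id"]
        )

    utrs: list[UtrSequence] = []
    if profile in ("null", "enriched", "sweep", "full"):
        if profile == "full":
            # the default pipeline scan runs without 6mers; plant only
            # site types the main scan accepts so recovery is exact
            plant = simulate.SitePlantSpec(
                n_planted_sites=n_sites,
                site_type_mix={"8mer": 0.4, "7mer-m8": 0.3, "7mer-A1": 0.3},
            )
        else:
            plant = simulate.SitePlantSpec(n_planted_sites=n_sites)
        utrs, site_truth = simulate.plant_utr_sites(
            panel,
            families,
            plant,
            rng_seed=int(seeds[3].generate_state(1)[0] % (2**31)),
            snp_ids=site_snp_ids,
        )
        truth["sites"] = site_truth

    # functional annotation: flag two unlinked far SNPs plus one decoy that
    # shadows the last forced high-F_ST site (full profile only)
    if profile == "full":
        pos = panel.positions
        far = np.flatnonzero(pos > 1_800_000)
        func_cols = list(rng.choice(far, size=2, replace=False))
        decoy_col = forced[-1]
        shadow_candidates = np.flatnonzero(
            (np.abs(pos - pos[decoy_col]) < 50_000) & (np.arange(len(pos)) != decoy_col)
        )
        shadow_col = int(shadow_candidates[0])
        panel.haplotypes[:, shadow_col] = panel.haplotypes[:, decoy_col]  # r^2 = 1
        func_cols.append(shadow_col)
        for j in func_cols:
            panel.snps[j].functional_flag = True

    cline_pops: list[PopulationMeta] = []
    cline_freqs = None
    if profile in ("cline", "full"):
        lats = np.linspace(1.0, 64.0, 12)
        cline_pops = [
            PopulationMeta(f"geo{i:02d}", 20, float(lat)) for i, lat in enumerate(lats)
        ]
        cline_pops.append(PopulationMeta("geo_excl", 20, 30.0, excluded=True, exclusion_reason="recent migrants"))
        cline_freqs, cline_truth = simulate.plant_latitude_cline(
            cline_pops,
            cline_slope=-0.012,
            n_cline_snps=3,
            n_null_snps=1500,
            noise_sd=0.04,
            rng_seed=int(seeds[4].generate_state(1)[0] % (2**31)),
        )
        truth["cline"] = cline_truth

    dataset = Dataset(
        panel=panel,
        utrs=utrs,
        families=families,
        cline_populations=cline_pops,
        cline_freqs=cline_freqs,
        truth=truth,
    )
    if profile in ("enriched", "full") and "sites" in truth:
        dataset.truth["expected_candidates"] = _expected_candidates(dataset, forced)
    return dataset


def _expected_candidates(dataset: Dataset, forced_cols: list[int]) -> pd.DataFrame:
    """Truth-side application of the candidate rule: planted allele-dependent
    site, F_ST >= 0.5, not LD-linked to a functional SNP."""
    panel = dataset.panel
    fst = popgen.panel_fst(panel).set_index("snp_id")["fst"]
    functional = [s.snp_id for s in panel.snps if s.functional_flag]
    rows = []
    for rec in dataset.truth["sites"].itertuples(index=False):
        if fst.get(rec.snp_id, 0.0) < 0.5:
            continue
        retained, _ = ld_mod.hitchhike_filter([rec.snp_id], panel, functional)
        rows.append({"snp_id": rec.snp_id, "expected": bool(retained)})
    return pd.DataFrame(rows, columns=["snp_id", "expected"])


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------


def make_fixture(profile: str, seed: int, out_dir: str | Path) -> Path:
    """Write a synthetic dataset (inputs + separate truth/) to ``out_dir``."""
    dataset = make_dataset(profile, seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    panel = dataset.panel

    write_vcf(panel, out_dir / "panel.vcf")
    samples = pd.DataFrame(
        {
            "sample_id": list(dict.fromkeys(panel.haplotype_samples)),
        }
    )
    samples["population_id"] = samples["sample_id"].map(panel.sample_to_population)
    write_tsv(samples, out_dir / "samples.tsv")

    annotation = pd.DataFrame(
        {
            "snp_id": panel.snp_ids,
            "chrom": [s.chrom for s in panel.snps],
            "pos": panel.positions,
            "ref": [s.ref_allele for s in panel.snps],
            "alt": [s.alt_allele for s in panel.snps],
            "ancestral": [s.ancestral_allele or "." for s in panel.snps],
            "functional_flag": [int(s.functional_flag) for s in panel.snps],
        }
    )
    write_tsv(annotation, out_dir / "snp_annotation.tsv")

    families = pd.DataFrame(
        [
            {"family_id": f.family_id, "seed": f.seed, "members": ",".join(f.member_mirnas)}
            for f in dataset.families
        ]
    )
    write_tsv(families, out_dir / "families.tsv")

    if dataset.utrs:
        write_utr_fasta(dataset.utrs, out_dir / "utrs.fasta")
        write_tsv(utr_snp_table(dataset.utrs, panel), out_dir / "utr_snps.tsv")

    if dataset.cline_populations:
        meta = pd.DataFrame(
            [
                {
                    "population_id": p.population_id,
                    "n_samples": p.n_samples,
                    "absolute_latitude": p.absolute_latitude,
                    "excluded": int(p.excluded),
                    "reason": p.exclusion_reason,
                }
                for p in dataset.cline_populations
            ]
        )
        write_tsv(meta, out_dir / "cline_populations.tsv")
        write_tsv(dataset.cline_freqs.reset_index(), out_dir / "cline_freqs.tsv")

    truth_dir = out_dir / "truth"
    for name, table in dataset.truth.items():
        write_tsv(table, truth_dir / f"{name}.tsv")
    return out_dir


def load_dataset(input_dir: str | Path) -> Dataset:
    """Load a fixture directory back into a :class:`Dataset` (truth not read)."""
    input_dir = Path(input_dir)
    samples = pd.read_csv(input_dir / "samples.tsv", sep="\t")
    pop_map = dict(zip(samples["sample_id"], samples["population_id"]))
    panel = read_vcf(input_dir / "panel.vcf", pop_map)

    annotation = pd.read_csv(input_dir / "snp_annotation.tsv", sep="\t", dtype={"snp_id": str})
    flags = dict(zip(annotation["snp_id"], annotation["functional_flag"]))
    for snp in panel.snps:
        snp.functional_flag = bool(flags.get(snp.snp_id, 0))

    families = read_mirna_families(input_dir / "families.tsv")

    utrs: list[UtrSequence] = []
    if (input_dir / "utrs.fasta").exists():
        snp_table = pd.read_csv(input_dir / "utr_snps.tsv", sep="\t", dtype={"snp_id": str})
        utrs = read_utrs(input_dir / "utrs.fasta", snp_table)
        alleles = {
            str(r.snp_id): (str(r.ref), str(r.alt)) for r in snp_table.itertuples(index=False)
        }
        for utr in utrs:
            target_scan.attach_alt_bases(utr, alleles)

    cline_pops: list[PopulationMeta] = []
    cline_freqs = None
    if (input_dir / "cline_populations.tsv").exists():
        cline_pops = read_population_meta(input_dir / "cline_populations.tsv")
        cline_freqs = pd.read_csv(
            input_dir / "cline_freqs.tsv", sep="\t", index_col="snp_id"
        )
    return Dataset(
        panel=panel,
        utrs=utrs,
        families=families,
        cline_populations=cline_pops,
        cline_freqs=cline_freqs,
    )


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns a summary dict and writes all tables.

    Stage order: target scan -> per-SNP F_ST -> bin enrichment with bootstrap
    null and top-bin hypergeometric tail -> candidate F_ST filter ->
    hitchhiking LD filter -> per-candidate selection statistics (windowed
    Fay-Wu H, iHS, regional CLR max) -> latitude clines -> candidate report.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    log: dict = {"seed": config.seed, "stages": {}}

    if config.input_dir is not None:
        dataset = load_dataset(config.input_dir)
    else:
        dataset = make_dataset(config.profile, config.seed)
        for utr in dataset.utrs:
            target_scan.attach_alt_bases(
                utr,
                {s.snp_id: (s.ref_allele, s.alt_allele) for s in dataset.panel.snps},
            )
    panel = dataset.panel
    log["stages"]["load"] = {"n_snps": panel.n_snps, "n_haplotypes": panel.n_haplotypes}

    # --- allele-aware target scan -----------------------------------------
    windows = []
    for utr in dataset.utrs:
        windows.extend(target_scan.build_windows(utr))
    calls = target_scan.scan_alleles(
        windows, dataset.families, allow_6mer=config.allow_6mer,
        score_threshold=config.score_threshold,
    )
    calls_df = target_scan.calls_to_frame(calls)
    counts = target_scan.count_polymorphic_sites(calls)
    log["stages"]["scan"] = counts

    # --- F_ST and enrichment ----------------------------------------------
    fst_df = popgen.panel_fst(panel)
    fst_by_snp = fst_df.set_index("snp_id")["fst"]
    target_snps = sorted(
        set(calls_df.loc[calls_df["verdict"].isin(["disrupting", "creating"]), "snp_id"])
    )
    background_fst = fst_by_snp.dropna().to_numpy()
    tables: dict[str, pd.DataFrame] = {"fst": fst_df, "calls": calls_df}
    if target_snps:
        target_fst = fst_by_snp[target_snps].dropna().to_numpy()
        enr = enrich_mod.analyze(
            target_fst,
            background_fst,
            edges=config.fst_edges,
            n_reps=config.bootstrap_reps,
            seed=np.random.default_rng(seeds[0]),
            replace=config.bootstrap_replace,
        )
        tables["enrichment"] = enr.to_frame()
        log["stages"]["enrichment"] = {
            "top_bin_enrichment": float(enr.scores[-1]) if np.isfinite(enr.scores[-1]) else None,
            "top_bin_p": enr.top_bin_p,
        }

    # --- candidate selection ----------------------------------------------
    candidates, cand_summary = enrich_mod.candidate_filter(
        calls_df, fst_by_snp, config.candidate_fst_threshold
    )
    cand_snps = sorted(candidates["snp_id"].unique())
    retained, excl_log = ld_mod.hitchhike_filter(
        cand_snps,
        panel,
        window_bp=config.ld_window_bp,
        r2_threshold=config.ld_r2_threshold,
    )
    tables["ld_exclusions"] = excl_log
    log["stages"]["candidates"] = {
        **cand_summary,
        "n_after_fst": len(cand_snps),
        "n_after_ld": len(retained),
        "n_excluded_ld": len(cand_snps) - len(retained),
    }

    # --- per-candidate selection statistics -------------------------------
    report_rows = []
    pop_stats_cache: dict[str, dict] = {}
    for snp_id in retained:
        snp = panel.snps[panel.snp_index(snp_id)]
        freqs = panel.per_population_derived_freq(snp_id)
        target_pop = max(freqs, key=lambda p: freqs[p])
        if target_pop not in pop_stats_cache:
            ihs_df = popgen.ihs_scan(
                panel, target_pop, max_distance=300_000, n_bins=config.ihs_bins
            )
            h_df = popgen.h_scan(
                panel, target_pop, window_size=config.h_window_bp, step=config.h_step_bp
            )
            h_thresh = popgen.genome_percentile_threshold(h_df["fay_wu_H"], 0.05)
            clr_df = popgen.clr_scan(
                panel,
                target_pop,
                grid_positions=np.linspace(
                    panel.positions.min(), panel.positions.max(), config.clr_grid_points
                ),
            )
            pop_stats_cache[target_pop] = {
                "ihs": ihs_df.set_index("snp_id"),
                "h": h_df,
                "h_thresh": h_thresh,
                "clr": clr_df,
            }
        cache = pop_stats_cache[target_pop]
        half = config.h_window_bp // 2
        win = popgen.unfolded_sfs(
            panel, target_pop, window=(snp.pos - half, snp.pos + half), chrom=snp.chrom
        )
        h_local, _, _ = popgen.fay_wu_h(win)
        ihs_val = (
            float(cache["ihs"].loc[snp_id, "ihs"]) if snp_id in cache["ihs"].index else np.nan
        )
        clr = cache["clr"]
        near = clr[np.abs(clr["position"] - snp.pos) <= 150_000]
        clr_max = float(near["clr"].max()) if len(near) else np.nan
        for rec in candidates[candidates["snp_id"] == snp_id].itertuples(index=False):
            report_rows.append(
                {
                    "snp_id": snp_id,
                    "gene_id": rec.gene_id,
                    "family_id": rec.family_id,
                    "verdict": rec.verdict,
                    **{f"freq_{p}": freqs[p] for p in panel.populations},
                    "fst": float(fst_by_snp[snp_id]),
                    "target_population": target_pop,
                    "fay_wu_H": h_local,
                    "h_5pct_threshold": cache["h_thresh"],
                    "ihs": ihs_val,
                    "max_regional_clr": clr_max,
                    "ld_filter": "pass",
                }
            )
    report = pd.DataFrame(report_rows).sort_values(["snp_id", "family_id"]).reset_index(
        drop=True
    ) if report_rows else pd.DataFrame(
        columns=["snp_id", "gene_id", "family_id", "verdict", "fst"]
    )
    tables["candidate_report"] = report

    # --- latitude clines ---------------------------------------------------
    if dataset.cline_freqs is not None:
        tables["cline"] = cline_mod.cline_analysis(
            dataset.cline_freqs,
            dataset.cline_populations,
            two_sided=config.cline_two_sided,
        )
        log["stages"]["cline"] = {"n_snps": len(tables["cline"])}

    paths = write_results_tables(tables, out_dir)
    config.to_yaml(out_dir / "config.yaml")
    log["outputs"] = {k: Path(v).name for k, v in sorted(paths.items())}
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return log
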