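"""Readers and writers for the external file formats.

Conventions established here and assumed everywhere else:

* internal coordinates are 0-based half-open; VCF stays 1-based at the
  boundary; BED output is 0-based half-open;
* haplotype matrices are coded 0/1 relative to the ancestral allele when the
  ancestral state is resolvable (``AA`` INFO tag), otherwise relative to REF
  with the record flagged unpolarized;
* UTR sequences are stored as DNA (T alphabet) in mRNA sense orientation
  (minus-strand records are reverse-complemented at load time); miRNA seeds
  are stored as RNA (U alphabet) and mapped at the comparison layer.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .errors import DataError

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_BASES = "ACGT"
RNA_BASES = "ACGU"

#: match length on the mRNA for each accepted site class
SITE_LENGTHS = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def rna_to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def dna_to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SnpRecord:
    """A biallelic SNP with optional ancestral polarization.

    ``pos`` is 1-based, as in VCF.  ``ancestral_allele`` is ``None`` when the
    ancestral state could not be resolved; such SNPs are retained but are
    excluded from statistics that require polarization (Fay-Wu H, iHS,
    latitude clines).
    """

    snp_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    ancestral_allele: str | None = None
    functional_flag: bool = False

    def __post_init__(self) -> None:
        if self.ancestral_allele is not None and self.ancestral_allele not in (
            self.ref_allele,
            self.alt_allele,
        ):
            raise DataError(
                f"{self.snp_id}: ancestral allele {self.ancestral_allele!r} is "
                f"neither REF ({self.ref_allele}) nor ALT ({self.alt_allele})"
            )

    @property
    def polarized(self) -> bool:
        return self.ancestral_allele is not None

    @property
    def derived_allele(self) -> str | None:
        if self.ancestral_allele is None:
            return None
        return (
            self.alt_allele
            if self.ancestral_allele == self.ref_allele
            else self.ref_allele
        )


@dataclass
class HaplotypePanel:
    """Phased haplotypes over ordered biallelic SNPs for >= 1 populations.

    Rows are phased haplotypes (two consecutive rows per diploid sample),
    columns are SNPs ordered by (chrom, pos).  Entries are 0/1: 1 means the
    derived allele for polarized SNPs, the ALT allele otherwise.
    """

    haplotypes: np.ndarray
    snps: list[SnpRecord]
    haplotype_samples: list[str]
    sample_to_population: dict[str, str]
    skipped_records: int = 0

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2:
            raise DataError("haplotype matrix must be 2-dimensional")
        if self.haplotypes.shape != (len(self.haplotype_samples), len(self.snps)):
            raise DataError(
                f"haplotype matrix shape {self.haplotypes.shape} does not match "
                f"{len(self.haplotype_samples)} haplotypes x {len(self.snps)} SNPs"
            )
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise DataError("haplotype matrix entries must be 0/1")
        keys = [(s.chrom, s.pos) for s in self.snps]
        if any(b <= a for a, b in zip(keys, keys[1:])):
            raise DataError("SNP columns must be strictly increasing by (chrom, pos)")
        missing = [s for s in self.haplotype_samples if s not in self.sample_to_population]
        if missing:
            raise DataError(f"samples missing from population map: {sorted(set(missing))}")

    # -- basic accessors ----------------------------------------------------

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.haplotype_samples:
            seen.setdefault(self.sample_to_population[s], None)
        return list(seen)

    @property
    def positions(self) -> np.ndarray:
        return np.asarray([s.pos for s in self.snps], dtype=np.int64)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    @property
    def polarized_mask(self) -> np.ndarray:
        return np.asarray([s.polarized for s in self.snps], dtype=bool)

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise DataError(f"SNP {snp_id!r} not in panel") from None

    def rows_for_population(self, population: str | None) -> np.ndarray:
        if population is None:
            return np.arange(self.n_haplotypes)
        rows = np.asarray(
            [
                i
                for i, s in enumerate(self.haplotype_samples)
                if self.sample_to_population[s] == population
            ],
            dtype=np.intp,
        )
        if rows.size == 0:
            raise DataError(f"population {population!r} has no haplotypes in panel")
        return rows

    def derived_counts(self, population: str | None = None) -> np.ndarray:
        return self.haplotypes[self.rows_for_population(population)].sum(axis=0)

    def derived_freqs(self, population: str | None = None) -> np.ndarray:
        rows = self.rows_for_population(population)
        return self.haplotypes[rows].mean(axis=0)

    def per_population_derived_freq(self, snp_id: str) -> dict[str, float]:
        j = self.snp_index(snp_id)
        return {
            pop: float(self.haplotypes[self.rows_for_population(pop), j].mean())
            for pop in self.populations
        }


@dataclass
class UtrSequence:
    """A 3'UTR in mRNA sense orientation with SNPs mapped to 0-based offsets."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    genomic_start: int
    sequence: str
    snp_offsets: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        for snp_id, off in self.snp_offsets.items():
            if not 0 <= off < len(self.sequence):
                raise DataError(
                    f"{self.transcript_id}: offset {off} of SNP {snp_id} outside sequence"
                )


@dataclass
class MirnaFamily:
    """A miRNA family keyed by its shared 7-base seed (miRNA positions 2-8)."""

    family_id: str
    seed: str
    member_mirnas: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.seed = self.seed.upper()
        if len(self.seed) != 7:
            raise DataError(
                f"family {self.family_id}: seed {self.seed!r} must be 7 bases"
            )
        bad = set(self.seed) - set(RNA_BASES)
        if bad:
            raise DataError(
                f"family {self.family_id}: seed contains non-RNA characters {sorted(bad)}"
            )


@dataclass
class PopulationMeta:
    """Sampling-location metadata for one population."""

    population_id: str
    n_samples: int
    absolute_latitude: float
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.absolute_latitude <= 90.0:
            raise DataError(
                f"{self.population_id}: absolute latitude must be in [0, 90]"
            )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_vcf(path: str | os.PathLike, population_map: dict[str, str]) -> HaplotypePanel:
    """Load phased diploid genotypes from a VCF into a :class:`HaplotypePanel`.

    Only biallelic SNP records are kept; others are skipped and counted in
    ``panel.skipped_records``.  When the ``AA`` INFO tag names the ALT allele
    the column coding is flipped so that 1 always means the derived allele.
    Unphased genotypes and samples absent from ``population_map`` are errors.
    """
    skipped = 0
    snps: list[SnpRecord] = []
    columns: list[np.ndarray] = []
    with pysam.VariantFile(os.fspath(path)) as vcf:
        samples = list(vcf.header.samples)
        absent = [s for s in samples if s not in population_map]
        if absent:
            raise DataError(f"samples not in population map: {absent}")
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            if (
                rec.alts is None
                or len(rec.alts) != 1
                or len(rec.ref) != 1
                or len(rec.alts[0]) != 1
                or rec.ref not in DNA_BASES
                or rec.alts[0] not in DNA_BASES
            ):
                skipped += 1
                continue
            ref, alt = rec.ref, rec.alts[0]
            aa = rec.info.get("AA")
            if isinstance(aa, (tuple, list)):
                aa = aa[0]
            aa = None if aa in (None, ".", "N", "n") else str(aa).upper()
            ancestral = aa if aa in (ref, alt) else None
            alleles = np.empty(2 * len(samples), dtype=np.int8)
            for i, sample in enumerate(samples):
                call = rec.samples[sample]
                gt = call["GT"]
                if len(gt) != 2 or any(a is None for a in gt):
                    raise DataError(
                        f"record {rec.id or rec.pos} sample {sample}: genotype must "
                        "be diploid and called"
                    )
                if not call.phased:
                    raise DataError(
                        f"record {rec.id or rec.pos} sample {sample}: unphased genotype"
                    )
                alleles[2 * i : 2 * i + 2] = gt
            if ancestral == alt:
                alleles = 1 - alleles  # flip so 1 = derived
            snps.append(
                SnpRecord(
                    snp_id=rec.id or f"{rec.chrom}:{rec.pos}",
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=ref,
                    alt_allele=alt,
                    ancestral_allele=ancestral,
                )
            )
            columns.append(alleles)
    if not snps:
        raise DataError(f"no usable biallelic SNP records in {path}")
    order = sorted(range(len(snps)), key=lambda i: (snps[i].chrom, snps[i].pos))
    matrix = np.column_stack([columns[i] for i in order])
    hap_samples = [s for s in samples for _ in range(2)]
    if skipped:
        logger.info("read_vcf: skipped %d non-biallelic/non-SNP records", skipped)
    return HaplotypePanel(
        haplotypes=matrix,
        snps=[snps[i] for i in order],
        haplotype_samples=hap_samples,
        sample_to_population={s: population_map[s] for s in samples},
        skipped_records=skipped,
    )


def read_mirna_families(path: str | os.PathLike) -> list[MirnaFamily]:
    """Read the miRNA family table (TSV: family_id, seed, members)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"family_id", "seed", "members"}
    if not required.issubset(df.columns):
        raise DataError(f"family table must have columns {sorted(required)}")
    families: list[MirnaFamily] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        if row.family_id in seen:
            raise DataError(f"duplicate family id {row.family_id!r}")
        seen.add(row.family_id)
        members = (
            [m.strip() for m in str(row.members).split(",") if m.strip()]
            if pd.notna(row.members)
            else []
        )
        families.append(MirnaFamily(row.family_id, str(row.seed), members))
    return families


def _parse_fasta_header(description: str) -> dict[str, str]:
    parts = description.split()
    attrs = {"transcript_id": parts[0]}
    for token in parts[1:]:
        if "=" in token:
            key, value = token.split("=", 1)
            attrs[key] = value
    return attrs


def read_utrs(
    fasta_path: str | os.PathLike,
    snp_table: str | os.PathLike | pd.DataFrame,
) -> list[UtrSequence]:
    """Load 3'UTR sequences and map SNPs to sense-strand offsets.

    FASTA headers carry ``gene=``, ``chrom=``, ``strand=`` and ``start=``
    attributes.  When a gene has several transcripts only the longest is
    retained.  The SNP table (``snp_id``, ``transcript_id``, ``offset``,
    ``ref``, ``alt``) gives plus-strand offsets into each record; offsets are
    converted to sense space for minus-strand records.  SNPs whose REF base
    does not match the sequence are dropped with a logged count.
    """
    from Bio import SeqIO

    if not isinstance(snp_table, pd.DataFrame):
        snp_table = pd.read_csv(snp_table, sep="\t", dtype={"snp_id": str})

    records = list(SeqIO.parse(os.fspath(fasta_path), "fasta"))
    if not records:
        raise DataError(f"empty FASTA: {fasta_path}")

    utrs: dict[str, UtrSequence] = {}
    for rec in records:
        attrs = _parse_fasta_header(rec.description)
        strand = attrs.get("strand", "+")
        seq = str(rec.seq).upper()
        if strand == "-":
            seq = revcomp(seq)
        utrs[attrs["transcript_id"]] = UtrSequence(
            transcript_id=attrs["transcript_id"],
            gene_id=attrs.get("gene", attrs["transcript_id"]),
            chrom=attrs.get("chrom", "."),
            strand=strand,
            genomic_start=int(attrs.get("start", 0)),
            sequence=seq,
        )

    # keep the longest transcript per gene
    best: dict[str, UtrSequence] = {}
    for utr in utrs.values():
        held = best.get(utr.gene_id)
        if held is None or len(utr.sequence) > len(held.sequence):
            best[utr.gene_id] = utr
    kept = {u.transcript_id: u for u in best.values()}

    dropped = 0
    for row in snp_table.itertuples(index=False):
        utr = kept.get(row.transcript_id)
        if utr is None:
            continue
        off = int(row.offset)
        if not 0 <= off < len(utr.sequence):
            raise DataError(
                f"SNP {row.snp_id}: offset {off} outside {row.transcript_id}"
            )
        if utr.strand == "-":
            sense_off = len(utr.sequence) - 1 - off
            expected = revcomp(str(row.ref))
        else:
            sense_off = off
            expected = str(row.ref).upper()
        if utr.sequence[sense_off] != expected:
            dropped += 1
            continue
        utr.snp_offsets[str(row.snp_id)] = sense_off
    if dropped:
        logger.info("read_utrs: dropped %d SNPs with REF/sequence mismatch", dropped)
    out = sorted(kept.values(), key=lambda u: u.transcript_id)
    for u in out:
        u.dropped_snps = dropped  # type: ignore[attr-defined]
    return out


def read_population_meta(path: str | os.PathLike) -> list[PopulationMeta]:
    """Read population metadata (TSV: population_id, n_samples, absolute_latitude,
    excluded, reason)."""
    df = pd.read_csv(path, sep="\t")
    metas = []
    for row in df.itertuples(index=False):
        metas.append(
            PopulationMeta(
                population_id=str(row.population_id),
                n_samples=int(row.n_samples),
                absolute_latitude=float(row.absolute_latitude),
                excluded=bool(getattr(row, "excluded", False)),
                exclusion_reason=str(getattr(row, "reason", "") or ""),
            )
        )
    return metas


def read_snp_annotation(path: str | os.PathLike) -> pd.DataFrame:
    """Read the SNP annotation table (snp_id, pos, ancestral, functional_flag)."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
    if "snp_id" not in df.columns:
        raise DataError("SNP annotation table must have a snp_id column")
    return df


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_FLOAT_FORMAT = "%.10g"


def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT, lineterminator="\n")
    return path


def write_calls_bed(calls: pd.DataFrame, path: str | os.PathLike) -> Path:
    """Write accepted site calls as BED (0-based half-open, transcript space)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for row in calls.itertuples(index=False):
            site_type = row.site_type_ref if row.site_type_ref != "none" else row.site_type_alt
            length = SITE_LENGTHS.get(site_type)
            if length is None:
                continue
            start = int(row.site_start)
            fh.write(
                f"{row.transcript_id}\t{start}\t{start + length}\t"
                f"{row.snp_id}|{row.family_id}|{row.verdict}\n"
            )
    return path


def write_results_tables(results: dict[str, pd.DataFrame], out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write each result table as ``<name>.tsv`` under ``out_dir``.

    A table named ``calls`` additionally produces ``calls.bed``.  Output is
    byte-identical across runs for identical inputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name in sorted(results):
        paths[name] = write_tsv(results[name], out_dir / f"{name}.tsv")
        if name == "calls" and len(results[name]):
            paths["calls_bed"] = write_calls_bed(results[name], out_dir / "calls.bed")
    return paths


def write_vcf(panel: HaplotypePanel, path: str | os.PathLike) -> Path:
    """Write a panel back to an uncompressed VCF 4.2 text file.

    Genotypes are emitted in REF/ALT coding (the inverse of the load-time
    polarization), so a write/read round trip reproduces the panel.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    samples = list(dict.fromkeys(panel.haplotype_samples))
    chroms = list(dict.fromkeys(s.chrom for s in panel.snps))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\t"
            + "\t".join(["FORMAT"] + samples)
            + "\n"
        )
        for j, snp in enumerate(panel.snps):
            column = panel.haplotypes[:, j]
            if snp.ancestral_allele == snp.alt_allele:
                column = 1 - column  # back to REF/ALT coding
            info = f"AA={snp.ancestral_allele}" if snp.polarized else "."
            gts = "\t".join(
                f"{column[2 * i]}|{column[2 * i + 1]}" for i in range(len(samples))
            )
            fh.write(
                f"{snp.chrom}\t{snp.pos}\t{snp.snp_id}\t{snp.ref_allele}\t"
                f"{snp.alt_allele}\t.\t.\t{info}\tGT\t{gts}\n"
            )
    return path


def write_utr_fasta(utrs: list[UtrSequence], path: str | os.PathLike) -> Path:
    """Write UTRs as FASTA with attribute-bearing headers (plus-strand sequence)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for utr in utrs:
            seq = utr.sequence if utr.strand == "+" else revcomp(utr.sequence)
            fh.write(
                f">{utr.transcript_id} gene={utr.gene_id} chrom={utr.chrom} "
                f"strand={utr.strand} start={utr.genomic_start}\n{seq}\n"
            )
    return path


def utr_snp_table(utrs: list[UtrSequence], panel: HaplotypePanel) -> pd.DataFrame:
    """Build the SNP-mapping table (plus-strand offsets) that pairs with
    :func:`write_utr_fasta` output."""
    by_id = {s.snp_id: s for s in panel.snps}
    rows = []
    for utr in utrs:
        for snp_id, sense_off in sorted(utr.snp_offsets.items(), key=lambda kv: kv[1]):
            snp = by_id[snp_id]
            off = sense_off if utr.strand == "+" else len(utr.sequence) - 1 - sense_off
            rows.append(
                {
                    "snp_id": snp_id,
                    "transcript_id": utr.transcript_id,
                    "offset": off,
                    "ref": snp.ref_allele,
                    "alt": snp.alt_allele,
                }
            )
    return pd.DataFrame(rows, columns=["snp_id", "transcript_id", "offset", "ref", "alt"])
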