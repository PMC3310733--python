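"""Allele-aware miRNA seed-site detection at SNPs.

For every SNP mapped into a 3'UTR a 15-nt window centred on the SNP is built
in both allele versions, each version is classified against every miRNA
family seed, and SNPs where exactly one allele carries an accepted site are
called site-disrupting (REF intact) or site-creating (ALT intact).

Site classes on the mRNA (sense strand, DNA alphabet), for a seed holding
miRNA positions 2-8:

==========  ================================================================
class       definition
==========  ================================================================
8mer        reverse complement of seed positions 2-8 followed by an A
7mer-m8     reverse complement of seed positions 2-8
7mer-A1     reverse complement of seed positions 2-7 followed by an A
6mer        reverse complement of seed positions 2-7 (only with allow_6mer)
==========  ================================================================

The highest class wins; ties break to the leftmost occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import DataError
from .io_formats import MirnaFamily, UtrSequence, revcomp, rna_to_dna

WINDOW_FLANK = 7  # 15-nt window: SNP offset -7 .. +7

SITE_PRIORITY = ["8mer", "7mer-m8", "7mer-A1", "6mer"]

DEFAULT_SCORE_THRESHOLD = -0.2


@dataclass
class PolymorphicWindow:
    """Both allele versions of the 15-nt window centred at a SNP."""

    snp_id: str
    transcript_id: str
    gene_id: str
    window_seq_ref: str
    window_seq_alt: str
    center: int  # offset of the SNP within the (possibly truncated) window
    window_start: int  # offset of the window start within the UTR
    truncated_left: bool = False
    truncated_right: bool = False

    def __post_init__(self) -> None:
        if len(self.window_seq_ref) != len(self.window_seq_alt):
            raise DataError(f"{self.snp_id}: allele windows differ in length")
        diffs = [
            i
            for i, (a, b) in enumerate(zip(self.window_seq_ref, self.window_seq_alt))
            if a != b
        ]
        if diffs != [self.center]:
            raise DataError(
                f"{self.snp_id}: allele windows must differ exactly at the centre"
            )


@dataclass
class TargetSiteCall:
    snp_id: str
    family_id: str
    transcript_id: str
    gene_id: str
    site_type_ref: str
    site_type_alt: str
    verdict: str  # disrupting | creating | both-intact | none
    site_start: int  # 0-based offset of the site within the UTR
    context_score: float | None = None


def classify_site(
    sequence: str, seed: str, allow_6mer: bool = False
) -> tuple[str, int] | None:
    """Best site class for ``seed`` in ``sequence`` (sense-strand mRNA).

    Returns ``(site_type, offset)`` with the offset of the match start in
    ``sequence``, or ``None`` when no accepted class occurs.
    """
    if len(seed) != 7:
        raise DataError(f"seed must be 7 bases, got {seed!r}")
    seq = rna_to_dna(sequence)
    heptamer = revcomp(rna_to_dna(seed))  # pairs miRNA positions 2-8
    hexamer = revcomp(rna_to_dna(seed[:6]))  # pairs miRNA positions 2-7

    candidates: list[tuple[str, str]] = [
        ("8mer", heptamer + "A"),
        ("7mer-m8", heptamer),
        ("7mer-A1", hexamer + "A"),
    ]
    if allow_6mer:
        candidates.append(("6mer", hexamer))
    for site_type, motif in candidates:
        idx = seq.find(motif)
        if idx >= 0:
            return site_type, idx
    return None


def build_windows(utr: UtrSequence, snp_ids: list[str] | None = None) -> list[PolymorphicWindow]:
    """15-nt polymorphic windows for the SNPs mapped into ``utr``.

    Windows at UTR edges are truncated and flagged.  The REF window is cut
    from the stored sequence; the ALT window substitutes the (strand-adjusted)
    alternate base at the centre.  Requires the alternate base, which is taken
    from ``utr.snp_alt_bases`` when present, else from the ``snp_alleles``
    mapping attached by the caller.
    """
    alt_bases: dict[str, str] = getattr(utr, "snp_alt_bases", {})
    windows = []
    items = sorted(utr.snp_offsets.items(), key=lambda kv: (kv[1], kv[0]))
    for snp_id, off in items:
        if snp_ids is not None and snp_id not in snp_ids:
            continue
        if not 0 <= off < len(utr.sequence):
            raise DataError(f"SNP {snp_id} offset {off} outside {utr.transcript_id}")
        start = max(0, off - WINDOW_FLANK)
        end = min(len(utr.sequence), off + WINDOW_FLANK + 1)
        ref_window = utr.sequence[start:end]
        alt_base = alt_bases.get(snp_id)
        if alt_base is None:
            raise DataError(f"no alternate base recorded for SNP {snp_id}")
        center = off - start
        alt_window = ref_window[:center] + alt_base + ref_window[center + 1 :]
        windows.append(
            PolymorphicWindow(
                snp_id=snp_id,
                transcript_id=utr.transcript_id,
                gene_id=utr.gene_id,
                window_seq_ref=ref_window,
                window_seq_alt=alt_window,
                center=center,
                window_start=start,
                truncated_left=off - WINDOW_FLANK < 0,
                truncated_right=off + WINDOW_FLANK + 1 > len(utr.sequence),
            )
        )
    return windows


def attach_alt_bases(utr: UtrSequence, snp_alleles: dict[str, tuple[str, str]]) -> None:
    """Record strand-adjusted ALT bases on ``utr`` for window construction.

    ``snp_alleles`` maps snp_id -> (ref, alt) in plus-strand terms; minus
    strand UTRs store the complement.
    """
    alt_bases = {}
    for snp_id in utr.snp_offsets:
        ref, alt = snp_alleles[snp_id]
        alt_bases[snp_id] = alt if utr.strand == "+" else revcomp(alt)
    utr.snp_alt_bases = alt_bases  # type: ignore[attr-defined]


def scan_alleles(
    windows: list[PolymorphicWindow],
    families: list[MirnaFamily],
    allow_6mer: bool = False,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    context_scores: dict[tuple[str, str], float] | None = None,
) -> list[TargetSiteCall]:
    """Classify both alleles of every window against every family.

    Verdicts: ``disrupting`` when only the REF allele carries an accepted
    site, ``creating`` when only ALT does, ``both-intact`` when both alleles
    carry a site (the SNP does not break the match), ``none`` otherwise;
    ``none`` results are not emitted.  When ``context_scores`` maps
    ``(snp_id, family_id)`` to a score, calls scoring above
    ``score_threshold`` are dropped (scores are consumed, never computed).
    """
    calls: list[TargetSiteCall] = []
    for window in windows:
        for family in families:
            hit_ref = classify_site(window.window_seq_ref, family.seed, allow_6mer)
            hit_alt = classify_site(window.window_seq_alt, family.seed, allow_6mer)
            if hit_ref is None and hit_alt is None:
                continue
            if hit_ref is not None and hit_alt is not None:
                verdict = "both-intact"
                site_off = hit_ref[1]
            elif hit_ref is not None:
                verdict = "disrupting"
                site_off = hit_ref[1]
            else:
                verdict = "creating"
                site_off = hit_alt[1]
            score = None
            if context_scores is not None:
                score = context_scores.get((window.snp_id, family.family_id))
                if score is not None and score > score_threshold:
                    continue
            calls.append(
                TargetSiteCall(
                    snp_id=window.snp_id,
                    family_id=family.family_id,
                    transcript_id=window.transcript_id,
                    gene_id=window.gene_id,
                    site_type_ref=hit_ref[0] if hit_ref else "none",
                    site_type_alt=hit_alt[0] if hit_alt else "none",
                    verdict=verdict,
                    site_start=window.window_start + site_off,
                    context_score=score,
                )
            )
    return calls


def calls_to_frame(calls: list[TargetSiteCall]) -> pd.DataFrame:
    columns = [
        "snp_id",
        "family_id",
        "transcript_id",
        "gene_id",
        "site_type_ref",
        "site_type_alt",
        "verdict",
        "site_start",
        "context_score",
    ]
    return pd.DataFrame(
        [{c: getattr(call, c) for c in columns} for call in calls], columns=columns
    )


def count_polymorphic_sites(calls: list[TargetSiteCall]) -> dict:
    """Summary counts of allele-dependent site calls.

    SNP-level counts deduplicate SNPs hit by several families; call-level
    counts keep every (SNP, family) pair.
    """
    allele_dep = [c for c in calls if c.verdict in ("disrupting", "creating")]
    by_type: dict[str, int] = {t: 0 for t in SITE_PRIORITY}
    for call in allele_dep:
        site_type = call.site_type_ref if call.verdict == "disrupting" else call.site_type_alt
        by_type[site_type] += 1
    return {
        "n_calls": len(allele_dep),
        "n_snps": len({c.snp_id for c in allele_dep}),
        "n_disrupting": sum(c.verdict == "disrupting" for c in allele_dep),
        "n_creating": sum(c.verdict == "creating" for c in allele_dep),
        "n_both_intact": sum(c.verdict == "both-intact" for c in calls),
        "calls_by_site_type": by_type,
    }
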