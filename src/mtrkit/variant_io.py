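"""Population and clinical variant ingestion.

Reads gnomAD-style population VCFs and ClinVar-style clinical variant
files (VCF or TSV), applies the inclusion filters (release-quality
``FILTER = PASS`` records, single-nucleotide substitutions only), projects
each variant onto transcript coordinates, classifies its coding
consequence by re-translation, and tallies observed missense/synonymous
counts per CDS nucleotide.

Allele frequency is deliberately ignored: a qualifying allele counts once
whether it was seen in one genome or a million, because the constraint
ratio is built on presence/absence of variation, not on its frequency.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .transcript_model import (
    BASES,
    CODON_TO_AA,
    STOP_SYMBOL,
    Transcript,
    complement,
)

logger = logging.getLogger(__name__)


class Consequence(str, enum.Enum):
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    STOP = "stop"
    OTHER = "other"


class ClinicalClass(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    BENIGN = "benign"
    VUS = "vus"
    NONE = "none"
    EXCLUDED = "excluded"


class InvalidVariantError(ValueError):
    """ALT equals REF, or the variant is otherwise self-inconsistent."""


class VcfFormatError(ValueError):
    """Population/clinical VCF could not be parsed."""


@dataclass(frozen=True)
class VariantRecord:
    """One single-nucleotide substitution projected onto a transcript."""

    gene_id: str
    cds_pos: int  # 0-based CDS nucleotide index
    ref_base: str
    alt_base: str
    consequence: Consequence
    protein_pos: int  # 1-based residue index
    aa_ref: str
    aa_alt: str
    clinical_class: ClinicalClass = ClinicalClass.NONE
    passed_filter: bool = True


@dataclass
class ObservedSiteTally:
    cds_pos: int
    n_obs_missense: int
    n_obs_synonymous: int


def classify_variant(t: Transcript, cds_pos: int, alt_base: str) -> Consequence:
    """Consequence of substituting ``alt_base`` at ``cds_pos``.

    The mutated codon is re-translated and compared with the reference:
    stop gained or lost -> stop; identical amino acid -> synonymous;
    otherwise missense.
    """
    if not 0 <= cds_pos < len(t.cds):
        raise IndexError(f"{t.gene_id}: CDS position {cds_pos} out of range")
    ref_base = t.cds[cds_pos]
    if alt_base == ref_base:
        raise InvalidVariantError(f"ALT equals REF ({ref_base}) at CDS pos {cds_pos}")
    if alt_base not in BASES:
        raise InvalidVariantError(f"non-ACGT ALT base {alt_base!r}")
    codon_idx, offset = divmod(cds_pos, 3)
    codon = t.cds[3 * codon_idx : 3 * codon_idx + 3]
    mutant = codon[:offset] + alt_base + codon[offset + 1 :]
    ref_aa = CODON_TO_AA[codon]
    alt_aa = CODON_TO_AA[mutant]
    if ref_aa == STOP_SYMBOL or alt_aa == STOP_SYMBOL:
        return Consequence.STOP
    if ref_aa == alt_aa:
        return Consequence.SYNONYMOUS
    return Consequence.MISSENSE


def _amino_acids(t: Transcript, cds_pos: int, alt_base: str) -> tuple[str, str]:
    codon_idx, offset = divmod(cds_pos, 3)
    codon = t.cds[3 * codon_idx : 3 * codon_idx + 3]
    mutant = codon[:offset] + alt_base + codon[offset + 1 :]
    return CODON_TO_AA[codon], CODON_TO_AA[mutant]


def make_record(
    t: Transcript,
    cds_pos: int,
    alt_base: str,
    clinical_class: ClinicalClass = ClinicalClass.NONE,
    passed_filter: bool = True,
) -> VariantRecord:
    """Build a fully classified :class:`VariantRecord` for one substitution."""
    consequence = classify_variant(t, cds_pos, alt_base)
    aa_ref, aa_alt = _amino_acids(t, cds_pos, alt_base)
    return VariantRecord(
        gene_id=t.gene_id,
        cds_pos=cds_pos,
        ref_base=t.cds[cds_pos],
        alt_base=alt_base,
        consequence=consequence,
        protein_pos=cds_pos // 3 + 1,
        aa_ref=aa_ref,
        aa_alt=aa_alt,
        clinical_class=clinical_class,
        passed_filter=passed_filter,
    )


# ----------------------------------------------------------------------
# clinical-significance parsing
# ----------------------------------------------------------------------
_PATHOGENIC = {"pathogenic", "likely_pathogenic", "pathogenic/likely_pathogenic"}
_BENIGN = {"benign", "likely_benign", "benign/likely_benign"}
_VUS = {"uncertain_significance"}


def parse_clinical_class(raw_significance: Optional[str]) -> ClinicalClass:
    """Map a ClinVar-style significance string onto the three analysed classes.

    Anything outside pathogenic(/likely), benign(/likely) and VUS —
    conflicting records, drug response, absent values — is excluded from
    enrichment rather than forced into a class.
    """
    if raw_significance is None:
        return ClinicalClass.EXCLUDED
    key = raw_significance.strip().lower().replace(" ", "_")
    if key in _PATHOGENIC:
        return ClinicalClass.PATHOGENIC
    if key in _BENIGN:
        return ClinicalClass.BENIGN
    if key in _VUS:
        return ClinicalClass.VUS
    if key:
        logger.debug("unrecognised clinical significance %r -> excluded", raw_significance)
    return ClinicalClass.EXCLUDED


# ----------------------------------------------------------------------
# VCF readers
# ----------------------------------------------------------------------
def _iter_vcf(path: str):
    from cyvcf2 import VCF

    try:
        return VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise VcfFormatError(f"cannot read VCF {path}: {exc}") from exc


def _locate(
    transcripts: Mapping[str, Transcript],
    chrom: str,
    pos1: int,
    coords: str,
) -> Optional[tuple[Transcript, int, bool]]:
    """Resolve a VCF (CHROM, POS) to (transcript, cds_pos, needs_complement)."""
    if coords == "cds":
        t = transcripts.get(chrom)
        if t is None:
            return None
        cds_pos = pos1 - 1
        if not 0 <= cds_pos < t.n_coding_nt:
            return None
        return t, cds_pos, False
    # genomic coordinates: scan exon maps (gene sets here are small)
    for t in transcripts.values():
        if t.exon_map is None:
            continue
        cds_pos = t.genomic_to_cds(chrom, pos1 - 1)
        if cds_pos is not None and cds_pos < t.n_coding_nt:
            return t, cds_pos, t.strand == "-"
    return None


def read_population_vcf(
    path: str,
    transcripts: Mapping[str, Transcript],
    coords: str = "cds",
) -> list[VariantRecord]:
    """Read a population VCF keeping PASS single-nucleotide substitutions.

    ``coords="cds"`` treats CHROM as gene_id and POS as 1-based CDS
    position; ``coords="genomic"`` projects through exon maps with
    strand-aware complementation.  Multi-allelic records are decomposed
    into one record per ALT.  Counts in/out of every filter are logged.
    """
    if coords not in ("cds", "genomic"):
        raise ValueError(f"coords must be 'cds' or 'genomic', got {coords!r}")
    counts = {"records": 0, "non_pass": 0, "non_snv": 0, "outside_cds": 0,
              "ref_mismatch": 0, "kept": 0}
    out: list[VariantRecord] = []
    for v in _iter_vcf(path):
        counts["records"] += 1
        if v.FILTER is not None:  # cyvcf2: None == PASS
            counts["non_pass"] += 1
            continue
        for alt in v.ALT:
            if len(v.REF) != 1 or len(alt) != 1 or alt not in BASES:
                counts["non_snv"] += 1
                continue
            hit = _locate(transcripts, v.CHROM, v.POS, coords)
            if hit is None:
                counts["outside_cds"] += 1
                continue
            t, cds_pos, flip = hit
            ref_base = complement(v.REF) if flip else v.REF
            alt_base = complement(alt) if flip else alt
            if t.cds[cds_pos] != ref_base:
                counts["ref_mismatch"] += 1
                logger.warning(
                    "%s: REF %s does not match CDS base %s at CDS pos %d; dropped",
                    t.gene_id, ref_base, t.cds[cds_pos], cds_pos,
                )
                continue
            out.append(make_record(t, cds_pos, alt_base))
            counts["kept"] += 1
    logger.info("population VCF %s: %s", path, counts)
    return out


def read_clinical_vcf(
    path: str,
    transcripts: Mapping[str, Transcript],
    coords: str = "cds",
    clnsig_key: str = "CLNSIG",
) -> list[VariantRecord]:
    """Read a clinical VCF; the significance INFO tag is configurable.

    Clinical catalogs are kept separate from the population catalog: their
    records carry a clinical class and never feed the MTR observed counts.
    Unlike the population reader, non-PASS records are retained (clinical
    archives use FILTER differently), but non-SNVs are still excluded.
    """
    records: list[VariantRecord] = []
    n_dropped = 0
    for v in _iter_vcf(path):
        raw = v.INFO.get(clnsig_key)
        clin = parse_clinical_class(raw if raw is None else str(raw))
        for alt in v.ALT:
            if len(v.REF) != 1 or len(alt) != 1 or alt not in BASES:
                n_dropped += 1
                continue
            hit = _locate(transcripts, v.CHROM, v.POS, coords)
            if hit is None:
                n_dropped += 1
                continue
            t, cds_pos, flip = hit
            alt_base = complement(alt) if flip else alt
            if t.cds[cds_pos] == alt_base:
                n_dropped += 1
                continue
            records.append(make_record(t, cds_pos, alt_base, clinical_class=clin))
    logger.info("clinical VCF %s: kept %d, dropped %d", path, len(records), n_dropped)
    return records


def read_clinical_tsv(
    path: str, transcripts: Mapping[str, Transcript]
) -> list[VariantRecord]:
    """Read protein-level clinical variants from a TSV.

    Columns: gene_id, protein_pos, aa_ref, aa_alt, clinical_significance.
    Each row is mapped back to a concrete SNV in the codon (any single
    substitution producing the stated amino-acid change); rows whose
    stated aa_ref disagrees with the transcript, or whose change is not
    reachable by one nucleotide substitution, are dropped with a warning —
    this protects against transcript-version drift.
    """
    import csv

    records: list[VariantRecord] = []
    n_dropped = 0
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            t = transcripts.get(row["gene_id"])
            if t is None:
                n_dropped += 1
                continue
            ppos = int(row["protein_pos"])
            aa_ref, aa_alt = row["aa_ref"], row["aa_alt"]
            if not 1 <= ppos <= len(t.protein) or t.protein[ppos - 1] != aa_ref:
                n_dropped += 1
                logger.warning(
                    "%s p.%s%d%s: aa_ref disagrees with transcript; dropped",
                    row["gene_id"], aa_ref, ppos, aa_alt,
                )
                continue
            snv = _snv_for_aa_change(t, ppos, aa_alt)
            if snv is None:
                n_dropped += 1
                logger.warning(
                    "%s p.%s%d%s: not reachable by one substitution; dropped",
                    row["gene_id"], aa_ref, ppos, aa_alt,
                )
                continue
            cds_pos, alt_base = snv
            clin = parse_clinical_class(row.get("clinical_significance"))
            records.append(make_record(t, cds_pos, alt_base, clinical_class=clin))
    logger.info("clinical TSV %s: kept %d, dropped %d", path, len(records), n_dropped)
    return records


def _snv_for_aa_change(
    t: Transcript, protein_pos: int, aa_alt: str
) -> Optional[tuple[int, str]]:
    codon_start = 3 * (protein_pos - 1)
    codon = t.cds[codon_start : codon_start + 3]
    for offset in range(3):
        for alt in BASES:
            if alt == codon[offset]:
                continue
            mutant = codon[:offset] + alt + codon[offset + 1 :]
            if CODON_TO_AA[mutant] == aa_alt:
                return codon_start + offset, alt
    return None


# ----------------------------------------------------------------------
# observed tallies
# ----------------------------------------------------------------------
@dataclass
class ObservedTallies:
    """Per-CDS-position observed missense/synonymous counts for one gene."""

    gene_id: str
    n_missense: np.ndarray  # int array, len = coding nt
    n_synonymous: np.ndarray


def tally_observed(
    records: Iterable[VariantRecord], transcript: Transcript
) -> ObservedTallies:
    """Count PASS missense/synonymous SNVs per CDS position.

    Distinct ALT alleles at one site each count once; duplicate records of
    the same (position, ALT) are collapsed.  Stop and other consequences
    are excluded.
    """
    n = transcript.n_coding_nt
    mis = np.zeros(n, dtype=np.int64)
    syn = np.zeros(n, dtype=np.int64)
    seen: set[tuple[int, str]] = set()
    for r in records:
        if r.gene_id != transcript.gene_id or not r.passed_filter:
            continue
        if r.consequence not in (Consequence.MISSENSE, Consequence.SYNONYMOUS):
            continue
        key = (r.cds_pos, r.alt_base)
        if key in seen:
            continue
        seen.add(key)
        if r.consequence is Consequence.MISSENSE:
            mis[r.cds_pos] += 1
        else:
            syn[r.cds_pos] += 1
    return ObservedTallies(transcript.gene_id, mis, syn)


def tally_observed_sites(
    records: Iterable[VariantRecord], transcript: Transcript
) -> list[ObservedSiteTally]:
    """Row-per-position view of :func:`tally_observed`."""
    t = tally_observed(records, transcript)
    return [
        ObservedSiteTally(i, int(t.n_missense[i]), int(t.n_synonymous[i]))
        for i in range(len(t.n_missense))
    ]
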