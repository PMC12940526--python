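"""Coding transcripts and exhaustive single-nucleotide mutagenesis.

A :class:`Transcript` couples a gene's coding sequence (CDS) with its
protein translation and an optional exon map for genome-to-CDS coordinate
projection.  The module enumerates every possible single-nucleotide
substitution in the CDS and classifies each as missense, synonymous or
stop-affecting; the per-site counts of *possible* changes are the expected
side of the missense tolerance ratio.

Coordinate conventions: CDS nucleotide positions are 0-based throughout
the library; protein positions are 1-based in every output table, matching
the convention of variant nomenclature (e.g. Pro70His).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

BASES = "ACGT"
STOP_SYMBOL = "*"

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    CODON_TO_AA[_stop] = STOP_SYMBOL
STOP_CODONS = tuple(sorted(_STANDARD_TABLE.stop_codons))
SENSE_CODONS = tuple(sorted(c for c in CODON_TO_AA if CODON_TO_AA[c] != STOP_SYMBOL))

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class InvalidSequenceError(ValueError):
    """CDS contains a character outside the A/C/G/T alphabet."""


class FrameError(ValueError):
    """CDS length is not a multiple of three."""


class InternalStopError(ValueError):
    """CDS contains a stop codon before its final codon."""


def complement(base: str) -> str:
    return _COMPLEMENT[base]


def translate_cds(cds: str) -> str:
    """Translate a CDS with the standard genetic code.

    A terminal stop codon, when present, is dropped from the returned
    protein.  An internal stop raises :class:`InternalStopError` so that
    broken gene models are flagged rather than silently truncated.
    """
    cds = cds.upper()
    bad = set(cds) - set(BASES)
    if bad:
        raise InvalidSequenceError(f"non-ACGT characters in CDS: {sorted(bad)}")
    if len(cds) % 3 != 0:
        raise FrameError(f"CDS length {len(cds)} is not a multiple of 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    aas = [CODON_TO_AA[c] for c in codons]
    if STOP_SYMBOL in aas[:-1]:
        pos = aas.index(STOP_SYMBOL)
        raise InternalStopError(f"internal stop codon at codon {pos + 1}")
    if aas and aas[-1] == STOP_SYMBOL:
        aas = aas[:-1]
    return "".join(aas)


@dataclass(frozen=True)
class Exon:
    """One exon interval of an exon map, 0-based half-open genomic coords."""

    chrom: str
    start: int
    end: int
    strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.end <= self.start:
            raise ValueError("exon end must exceed start (half-open coords)")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Transcript:
    """A canonical coding transcript and its protein translation.

    ``exon_map``, when present, lists exons in transcription order (5'→3'
    of the mRNA); together they must cover exactly ``len(cds)`` genomic
    bases without overlap.
    """

    gene_id: str
    cds: str
    protein: str = field(default="")
    exon_map: Optional[tuple[Exon, ...]] = None

    def __post_init__(self) -> None:
        self.cds = self.cds.upper()
        expected = translate_cds(self.cds)
        if not self.protein:
            self.protein = expected
        elif self.protein != expected:
            raise ValueError(
                f"{self.gene_id}: supplied protein disagrees with CDS translation"
            )
        if self.exon_map is not None:
            self.exon_map = tuple(self.exon_map)
            span = sum(len(e) for e in self.exon_map)
            if span != len(self.cds):
                raise ValueError(
                    f"{self.gene_id}: exon map covers {span} bases, CDS is {len(self.cds)}"
                )

    @property
    def has_terminal_stop(self) -> bool:
        return len(self.cds) == 3 * len(self.protein) + 3

    @property
    def n_coding_nt(self) -> int:
        """CDS length excluding the terminal stop codon, if any."""
        return 3 * len(self.protein)

    # ------------------------------------------------------------------
    # genome <-> CDS projection
    # ------------------------------------------------------------------
    def cds_to_genomic(self, cds_pos: int) -> tuple[str, int]:
        """Map a 0-based CDS position to (chrom, 0-based genomic position)."""
        if self.exon_map is None:
            raise ValueError(f"{self.gene_id}: no exon map")
        if not 0 <= cds_pos < len(self.cds):
            raise IndexError(cds_pos)
        offset = cds_pos
        for exon in self.exon_map:
            if offset < len(exon):
                if exon.strand == "+":
                    return exon.chrom, exon.start + offset
                return exon.chrom, exon.end - 1 - offset
            offset -= len(exon)
        raise AssertionError("unreachable: exon map shorter than CDS")

    def genomic_to_cds(self, chrom: str, gpos: int) -> Optional[int]:
        """Map a 0-based genomic position into the CDS; None if outside."""
        if self.exon_map is None:
            raise ValueError(f"{self.gene_id}: no exon map")
        offset = 0
        for exon in self.exon_map:
            if exon.chrom == chrom and exon.start <= gpos < exon.end:
                if exon.strand == "+":
                    return offset + (gpos - exon.start)
                return offset + (exon.end - 1 - gpos)
            offset += len(exon)
        return None

    @property
    def strand(self) -> Optional[str]:
        if self.exon_map is None:
            return None
        return self.exon_map[0].strand


@dataclass(frozen=True)
class PossibleSiteTally:
    """Counts of possible SNV consequences at one CDS nucleotide.

    The three alternative bases at a site partition into missense,
    synonymous and stop-affecting (gain or loss) changes, so the counts
    always sum to 3.
    """

    cds_pos: int
    n_possible_missense: int
    n_possible_synonymous: int
    n_possible_stop: int


@lru_cache(maxsize=None)
def codon_change_counts(codon: str) -> tuple[tuple[int, int, int], ...]:
    """Per-offset (missense, synonymous, stop) counts of the 9 mutant codons.

    Cached per codon: enumeration over a transcript reduces to table
    lookups.  Stop-affecting means the mutant or the reference codon is a
    stop (gain or loss).
    """
    ref_aa = CODON_TO_AA[codon]
    out = []
    for offset in range(3):
        mis = syn = stop = 0
        for alt in BASES:
            if alt == codon[offset]:
                continue
            mutant = codon[:offset] + alt + codon[offset + 1 :]
            alt_aa = CODON_TO_AA[mutant]
            if alt_aa == STOP_SYMBOL or ref_aa == STOP_SYMBOL:
                stop += 1
            elif alt_aa == ref_aa:
                syn += 1
            else:
                mis += 1
        out.append((mis, syn, stop))
    return tuple(out)


def enumerate_possible_snvs(t: Transcript) -> list[PossibleSiteTally]:
    """One tally per coding nucleotide; the terminal stop codon is skipped.

    The terminal stop encodes no residue, so neither its sites nor
    stop-loss changes there enter any window.
    """
    tallies: list[PossibleSiteTally] = []
    for codon_idx in range(len(t.protein)):
        codon = t.cds[3 * codon_idx : 3 * codon_idx + 3]
        for offset, (mis, syn, stop) in enumerate(codon_change_counts(codon)):
            tallies.append(
                PossibleSiteTally(3 * codon_idx + offset, mis, syn, stop)
            )
    return tallies


def tallies_to_arrays(
    tallies: Sequence[PossibleSiteTally],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(missense, synonymous, stop) count arrays indexed by CDS position."""
    n = len(tallies)
    mis = np.zeros(n, dtype=np.int64)
    syn = np.zeros(n, dtype=np.int64)
    stp = np.zeros(n, dtype=np.int64)
    for t in tallies:
        mis[t.cds_pos] = t.n_possible_missense
        syn[t.cds_pos] = t.n_possible_synonymous
        stp[t.cds_pos] = t.n_possible_stop
    return mis, syn, stp


def expected_proportion(
    tallies: Sequence[PossibleSiteTally], window: tuple[int, int]
) -> float:
    """Possible-missense fraction over a CDS window, 0-based half-open.

    Stop-class changes are excluded from numerator and denominator: the
    ratio contrasts missense against synonymous only.
    """
    start, end = window
    if not (0 <= start < end <= len(tallies)):
        raise ValueError(f"window {window} outside CDS of {len(tallies)} sites")
    mis = sum(t.n_possible_missense for t in tallies[start:end])
    syn = sum(t.n_possible_synonymous for t in tallies[start:end])
    denom = mis + syn
    # every sense codon admits >= 1 non-stop change, so a non-empty window
    # cannot have a zero denominator
    assert denom > 0, "empty missense+synonymous denominator in coding window"
    return mis / denom


# ----------------------------------------------------------------------
# FASTA / exon-map readers
# ----------------------------------------------------------------------
def read_cds_fasta(path: str) -> dict[str, Transcript]:
    """Read CDS records (id = gene_id); invalid gene models are skipped.

    Genes whose CDS fails validation (frame, alphabet, internal stop) are
    logged and excluded from the returned mapping rather than aborting the
    run.
    """
    from Bio import SeqIO

    transcripts: dict[str, Transcript] = {}
    n_bad = 0
    with open(path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            try:
                transcripts[record.id] = Transcript(record.id, str(record.seq))
            except (InvalidSequenceError, FrameError, InternalStopError) as exc:
                n_bad += 1
                logger.warning("skipping gene %s: %s", record.id, exc)
    logger.info("read %d transcripts (%d rejected) from %s", len(transcripts), n_bad, path)
    return transcripts


def write_cds_fasta(transcripts: Iterable[Transcript], path: str) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.gene_id}\n")
            for i in range(0, len(t.cds), 60):
                fh.write(t.cds[i : i + 60] + "\n")


def read_exon_map_bed(path: str) -> dict[str, tuple[Exon, ...]]:
    """BED (0-based half-open): chrom, start, end, gene_id, score, strand.

    Exons of minus-strand genes are returned in transcription order
    (descending genomic coordinate).
    """
    per_gene: dict[str, list[Exon]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end, gene = fields[0], int(fields[1]), int(fields[2]), fields[3]
            strand = fields[5] if len(fields) > 5 else "+"
            per_gene.setdefault(gene, []).append(Exon(chrom, start, end, strand))
    return {g: _transcription_order(exons) for g, exons in per_gene.items()}


def read_exon_map_gff3(path: str) -> dict[str, tuple[Exon, ...]]:
    """GFF3 CDS features (1-based inclusive), gene from ID=/Parent= attribute."""
    per_gene: dict[str, list[Exon]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9 or fields[2].upper() != "CDS":
                continue
            chrom, start, end, strand = fields[0], int(fields[3]), int(fields[4]), fields[6]
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            gene = attrs.get("Parent") or attrs.get("ID") or attrs.get("gene_id")
            if gene is None:
                continue
            # normalize to 0-based half-open
            per_gene.setdefault(gene, []).append(Exon(chrom, start - 1, end, strand))
    return {g: _transcription_order(exons) for g, exons in per_gene.items()}


def _transcription_order(exons: list[Exon]) -> tuple[Exon, ...]:
    strand = exons[0].strand
    return tuple(sorted(exons, key=lambda e: e.start, reverse=(strand == "-")))
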