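"""Variant reading, filtering, classification and tallying."""

import numpy as np
import pytest

from mtrkit.transcript_model import BASES, Exon, Transcript, enumerate_possible_snvs
from mtrkit.variant_io import (
    ClinicalClass,
    Consequence,
    InvalidVariantError,
    classify_variant,
    make_record,
    parse_clinical_class,
    read_clinical_tsv,
    read_population_vcf,
    tally_observed,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FILTER=<ID=AC0,Description="x">\n'
    "##contig=<ID=g1,length=33>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


@pytest.fixture
def transcript():
    # M A G L F K P R S T *
    return Transcript("g1", "ATGGCCGGATTATTTAAACCTCGATCAACGTAA")


class TestClassify:
    @pytest.mark.parametrize(
        "cds,pos,alt,expected",
        [
            ("GGGTAA", 2, "A", Consequence.SYNONYMOUS),  # GGG->GGA
            ("TTATAA", 1, "A", Consequence.STOP),  # TTA->TAA
            ("ATGTAA", 0, "G", Consequence.MISSENSE),  # ATG->GTG
        ],
    )
    def test_consequence_by_retranslation(self, cds, pos, alt, expected):
        assert classify_variant(Transcript("x", cds), pos, alt) is expected

    def test_alt_equals_ref_rejected(self, transcript):
        with pytest.raises(InvalidVariantError):
            classify_variant(transcript, 0, "A")

    def test_agrees_with_enumeration(self, random_transcript):
        """Cross-module oracle: per-position class counts from classify_variant
        must equal the enumerated possible-SNV tallies."""
        t = random_transcript
        tallies = enumerate_possible_snvs(t)
        for pos in range(t.n_coding_nt):
            counts = {c: 0 for c in Consequence}
            for alt in BASES:
                if alt == t.cds[pos]:
                    continue
                counts[classify_variant(t, pos, alt)] += 1
            assert counts[Consequence.MISSENSE] == tallies[pos].n_possible_missense
            assert counts[Consequence.SYNONYMOUS] == tallies[pos].n_possible_synonymous
            assert counts[Consequence.STOP] == tallies[pos].n_possible_stop


class TestClinicalClassParsing:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("Pathogenic", ClinicalClass.PATHOGENIC),
            ("Likely_pathogenic", ClinicalClass.PATHOGENIC),
            ("Pathogenic/Likely_pathogenic", ClinicalClass.PATHOGENIC),
            ("Benign", ClinicalClass.BENIGN),
            ("Likely_benign", ClinicalClass.BENIGN),
            ("Uncertain_significance", ClinicalClass.VUS),
            ("uncertain significance", ClinicalClass.VUS),
            ("Conflicting_classifications_of_pathogenicity", ClinicalClass.EXCLUDED),
            ("drug_response", ClinicalClass.EXCLUDED),
            (None, ClinicalClass.EXCLUDED),
        ],
    )
    def test_mapping(self, raw, expected):
        assert parse_clinical_class(raw) is expected


class TestPopulationVcf:
    def _read(self, tmp_path, body, transcripts):
        path = tmp_path / "pop.vcf"
        path.write_text(VCF_HEADER + body)
        return read_population_vcf(str(path), transcripts)

    def test_filters_and_decomposition(self, tmp_path, transcript):
        body = (
            "g1\t3\t.\tG\tA\t.\tAC0\t.\n"  # non-PASS: excluded
            "g1\t4\t.\tG\tGT\t.\tPASS\t.\n"  # insertion: excluded
            "g1\t3\t.\tG\tA,C\t.\tPASS\t.\n"  # multi-allelic: two records
            "g1\t1\t.\tA\tG\t.\tPASS\t.\n"  # ATG->GTG missense
        )
        records = self._read(tmp_path, body, {"g1": transcript})
        assert len(records) == 3
        missense = [r for r in records if r.cds_pos == 0]
        assert missense[0].consequence is Consequence.MISSENSE
        assert missense[0].aa_ref == "M" and missense[0].aa_alt == "V"

    def test_ref_mismatch_dropped(self, tmp_path, transcript):
        records = self._read(tmp_path, "g1\t1\t.\tC\tG\t.\tPASS\t.\n", {"g1": transcript})
        assert records == []

    def test_unknown_contig_dropped(self, tmp_path, transcript):
        records = self._read(tmp_path, "gX\t1\t.\tA\tG\t.\tPASS\t.\n", {"g1": transcript})
        assert records == []

    def test_minus_strand_genomic_projection(self, tmp_path):
        # CDS ATGGCC maps to the reverse complement on the genome
        t = Transcript("gm", "ATGGCC", exon_map=(Exon("chr2", 100, 106, "-"),))
        # CDS pos 0 ('A') sits at genomic 105 as 'T'; ALT C on genome = G on CDS
        path = tmp_path / "pop.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=chr2>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr2\t106\t.\tT\tC\t.\tPASS\t.\n"
        )
        records = read_population_vcf(str(path), {"gm": t}, coords="genomic")
        assert len(records) == 1
        assert records[0].cds_pos == 0
        assert records[0].alt_base == "G"
        assert records[0].consequence is Consequence.MISSENSE


class TestClinicalTsv:
    def test_round_trip_and_drift_protection(self, tmp_path, transcript):
        rows = [
            "gene_id\tprotein_pos\taa_ref\taa_alt\tclinical_significance",
            "g1\t2\tA\tV\tPathogenic",  # GCC -> GTC reachable
            "g1\t2\tQ\tV\tPathogenic",  # aa_ref disagrees: dropped
            "g1\t2\tA\tW\tBenign",  # A->W needs >1 substitution: dropped
        ]
        path = tmp_path / "clin.tsv"
        path.write_text("\n".join(rows) + "\n")
        records = read_clinical_tsv(str(path), {"g1": transcript})
        assert len(records) == 1
        r = records[0]
        assert r.clinical_class is ClinicalClass.PATHOGENIC
        assert r.protein_pos == 2 and r.aa_alt == "V"
        assert r.consequence is Consequence.MISSENSE


class TestTally:
    def test_distinct_alts_each_count(self, transcript):
        records = [
            make_record(transcript, 0, "G"),
            make_record(transcript, 0, "C"),
            make_record(transcript, 0, "G"),  # duplicate allele: once
        ]
        tallies = tally_observed(records, transcript)
        assert tallies.n_missense[0] == 2

    def test_conservation(self, random_transcript, rng):
        """Sum of tallies equals the number of retained mis/syn records."""
        t = random_transcript
        records = []
        seen = set()
        for _ in range(200):
            pos = int(rng.integers(t.n_coding_nt))
            alt = "ACGT"[int(rng.integers(4))]
            if alt == t.cds[pos] or (pos, alt) in seen:
                continue
            seen.add((pos, alt))
            records.append(make_record(t, pos, alt))
        tallies = tally_observed(records, t)
        kept = sum(
            r.consequence in (Consequence.MISSENSE, Consequence.SYNONYMOUS)
            for r in records
        )
        assert tallies.n_missense.sum() + tallies.n_synonymous.sum() == kept

    def test_non_pass_excluded(self, transcript):
        records = [make_record(transcript, 0, "G", passed_filter=False)]
        tallies = tally_observed(records, transcript)
        assert tallies.n_missense.sum() == 0

    def test_no_variants_zero_tallies(self, transcript):
        tallies = tally_observed([], transcript)
        assert len(tallies.n_missense) == transcript.n_coding_nt
        assert not tallies.n_missense.any() and not tallies.n_synonymous.any()
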