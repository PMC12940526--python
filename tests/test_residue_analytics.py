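"""Composition enrichment, biophysical descriptors and segment patterning."""

import math

import numpy as np
import pandas as pd
import pytest

from mtrkit.residue_analytics import (
    aromatic_spacing,
    biophysical_summary,
    composition_enrichment,
    delta_contrast,
    extract_segments,
)


def residue_frame(genes):
    """Rows from compact per-gene strings: (aa_seq, state_seq, class_seq).

    State letters: O/D/T/M; class letters: I/T (Tolerant)/U (Unclassified).
    """
    state_map = {"O": "order", "D": "disorder", "T": "structural_transition",
                 "M": "missing_residues"}
    class_map = {"I": "Intolerant", "T": "Tolerant", "U": "Unclassified"}
    rows = []
    for gene, (aa, states, classes) in genes.items():
        for i, (a, s, c) in enumerate(zip(aa, states, classes)):
            rows.append(
                {"gene_id": gene, "protein_pos": i + 1, "aa": a,
                 "state": state_map[s], "constraint_class": class_map[c]}
            )
    return pd.DataFrame(rows)


class TestCompositionEnrichment:
    def test_balanced_table_zero_log_or(self):
        df = residue_frame(
            {"g": ("AG" * 10 + "AG" * 10, "O" * 40, "I" * 20 + "T" * 20)}
        )
        out = composition_enrichment(df)
        row = out[(out["state"] == "order") & (out["aa"] == "A")].iloc[0]
        assert row["log2_or"] == pytest.approx(0.0)
        assert row["p"] == pytest.approx(1.0)

    def test_haldane_anscombe_zero_cell(self):
        # A absent among 10 Intolerant, 5 of 10 Tolerant: (0,10;5,5)
        aa = "G" * 10 + "A" * 5 + "G" * 5
        df = residue_frame({"g": (aa, "O" * 20, "I" * 10 + "T" * 10)})
        out = composition_enrichment(df)
        row = out[(out["state"] == "order") & (out["aa"] == "A")].iloc[0]
        assert row["log2_or"] == pytest.approx(math.log2(0.5 / 10.5), abs=1e-9)

    def test_state_without_intolerant_residues_is_na(self):
        df = residue_frame({"g": ("ACDEF", "TTTTT", "TTTTT")})
        out = composition_enrichment(df)
        assert out["log2_or"].isna().all()

    def test_antisymmetric_under_class_swap(self):
        rng = np.random.default_rng(5)
        aa = "".join(rng.choice(list("ACDEFGHIKL"), 60))
        classes = "".join(rng.choice(list("IT"), 60))
        swapped = classes.translate(str.maketrans("IT", "TI"))
        a = composition_enrichment(residue_frame({"g": (aa, "O" * 60, classes)}))
        b = composition_enrichment(residue_frame({"g": (aa, "O" * 60, swapped)}))
        assert np.allclose(a["log2_or"], -b["log2_or"])


class TestBiophysics:
    @pytest.mark.parametrize(
        "seq,charge,aromatic",
        [("AAA", 0.0, 0.0), ("KRD", 1 / 3, 0.0), ("FYW", 0.0, 1.0)],
    )
    def test_charge_and_aromatic_fraction(self, seq, charge, aromatic):
        c, _, a = biophysical_summary(seq)
        assert c == pytest.approx(charge)
        assert a == pytest.approx(aromatic)

    def test_kyte_doolittle_isoleucine(self):
        _, kd, _ = biophysical_summary("III")
        assert kd == pytest.approx(4.5)

    def test_histidine_charge_configurable(self):
        assert biophysical_summary("H")[0] == 0.0
        assert biophysical_summary("H", his_charge=0.1)[0] == pytest.approx(0.1)

    def test_empty_sequence_is_na(self):
        assert all(np.isnan(v) for v in biophysical_summary(""))

    @pytest.mark.parametrize(
        "seq,expected", [("FAAF", 3.0), ("AFAFA", 2.0), ("AAAA", float("nan"))]
    )
    def test_aromatic_spacing(self, seq, expected):
        got = aromatic_spacing(seq)
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(expected)


def brute_force_segments(df):
    """Position-by-position scan oracle."""
    segments = []
    for gene, sub in df.sort_values(["gene_id", "protein_pos"]).groupby("gene_id"):
        current = None
        for row in sub.itertuples(index=False):
            if row.constraint_class == "Unclassified":
                current = None
                continue
            key = (gene, row.state, row.constraint_class)
            if (
                current is not None
                and current["key"] == key
                and row.protein_pos == current["end"] + 1
            ):
                current["end"] = row.protein_pos
                current["len"] += 1
            else:
                current = {"key": key, "start": row.protein_pos,
                           "end": row.protein_pos, "len": 1}
                segments.append(current)
    return [(s["key"][0], s["key"][1], s["key"][2], s["start"], s["end"], s["len"])
            for s in segments]


class TestSegments:
    def test_state_change_splits(self):
        df = residue_frame({"g": ("AAAAAA", "DDDDOO", "TTTTTT")})
        segs = extract_segments(df)
        assert segs["length"].tolist() == [4, 2]
        assert segs["state"].tolist() == ["disorder", "order"]

    def test_class_change_splits(self):
        df = residue_frame({"g": ("AAAA", "DDDD", "IITT")})
        segs = extract_segments(df)
        assert segs["length"].tolist() == [2, 2]

    def test_unclassified_breaks_runs(self):
        df = residue_frame({"g": ("AAAAA", "DDDDD", "TTUTT")})
        segs = extract_segments(df)
        assert segs["length"].tolist() == [2, 2]
        assert len(segs) == 2

    def test_matches_scan_oracle_on_random_inputs(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 60))
            aa = "".join(rng.choice(list("AFKD"), n))
            states = "".join(rng.choice(list("ODTM"), n))
            classes = "".join(rng.choice(list("ITU"), n))
            df = residue_frame({"g1": (aa, states, classes)})
            got = [
                (r.gene_id, r.state, r.constraint_class, r.start, r.end, r.length)
                for r in extract_segments(df).itertuples(index=False)
            ]
            assert got == brute_force_segments(df)

    def test_lengths_conserve_residue_counts(self, rng):
        n = 300
        aa = "".join(rng.choice(list("AFKD"), n))
        states = "".join(rng.choice(list("OD"), n))
        classes = "".join(rng.choice(list("IT"), n))
        df = residue_frame({"g": (aa, states, classes)})
        segs = extract_segments(df)
        for (state, cls), sub in segs.groupby(["state", "constraint_class"]):
            n_residues = (
                (df["state"] == state) & (df["constraint_class"] == cls)
            ).sum()
            assert sub["length"].sum() == n_residues


class TestDeltaContrast:
    def test_identical_distributions_zero_delta(self):
        df = residue_frame({"g": ("KAKA" * 5, "O" * 20, "IITT" * 5)})
        segs = extract_segments(df)
        out = delta_contrast(df, segs)
        charge = out[(out["state"] == "order") & (out["property"] == "charge")].iloc[0]
        assert charge["delta"] == pytest.approx(0.0)

    def test_planted_charge_difference(self):
        df = residue_frame({"g": ("K" * 10 + "A" * 10, "O" * 20, "I" * 10 + "T" * 10)})
        out = delta_contrast(df, extract_segments(df))
        charge = out[(out["state"] == "order") & (out["property"] == "charge")].iloc[0]
        assert charge["delta"] == pytest.approx(1.0)
        assert charge["p"] < 0.05

    def test_empty_class_is_na(self):
        df = residue_frame({"g": ("AAAA", "OOOO", "TTTT")})
        out = delta_contrast(df, extract_segments(df))
        assert out["delta"].isna().all()
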