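"""Residue- and segment-level composition and patterning analytics.

Joins structural states with MTR constraint classes into one row per
residue, then asks which amino acids are over- or under-represented among
Intolerant versus Tolerant positions within each structural state, what
the biophysical texture (side-chain charge, Kyte–Doolittle hydropathy,
aromatic content) of each class looks like, and how residues organise
into contiguous same-state/same-class segments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .mtr_engine import INTOLERANT, TOLERANT, UNCLASSIFIED, MTRProfile
from .stat_battery import bh_fdr, fisher_ha, mann_whitney
from .structure_states import State

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AROMATIC = frozenset("FYW")

# side-chain charge at neutral pH; histidine 0 by default (configurable)
def charge_map(his_charge: float = 0.0) -> dict[str, float]:
    charges = dict.fromkeys(AMINO_ACIDS, 0.0)
    charges.update({"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0, "H": his_charge})
    return charges


def build_residue_table(
    profiles: Sequence[MTRProfile],
    states_by_gene: Mapping[str, Sequence[State]],
) -> pd.DataFrame:
    """One row per residue: gene, position, aa, state, mtr, class."""
    frames = []
    for prof in profiles:
        states = states_by_gene.get(prof.gene_id)
        if states is None:
            raise KeyError(f"no structural states for gene {prof.gene_id}")
        if len(states) != len(prof.protein):
            raise ValueError(
                f"{prof.gene_id}: {len(states)} states for protein of "
                f"length {len(prof.protein)}"
            )
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": prof.gene_id,
                    "protein_pos": np.arange(1, len(prof.protein) + 1),
                    "aa": list(prof.protein),
                    "state": [s.value for s in states],
                    "mtr": prof.mtr,
                    "p": prof.p_binomial,
                    "q": prof.q_fdr,
                    "constraint_class": prof.constraint_class,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ----------------------------------------------------------------------
# composition enrichment
# ----------------------------------------------------------------------
def composition_enrichment(records: pd.DataFrame) -> pd.DataFrame:
    """Per (state, amino acid): Intolerant-vs-Tolerant log2 OR, p and q.

    For each structural state a 2x2 table contrasts the amino acid against
    all others across the Intolerant and Tolerant classes; Unclassified
    residues are excluded.  Haldane–Anscombe stabilises zero cells and
    Benjamini–Hochberg runs within each state (one 20-test family per
    state, mirroring a per-state heatmap).  A state with no Intolerant
    residues yields NA rows: the contrast is undefined there.
    """
    df = records[records["constraint_class"].isin((INTOLERANT, TOLERANT))]
    rows = []
    for state in sorted(records["state"].unique()):
        sub = df[df["state"] == state]
        intol = sub[sub["constraint_class"] == INTOLERANT]
        tol = sub[sub["constraint_class"] == TOLERANT]
        if len(intol) == 0 or len(tol) == 0:
            logger.info(
                "state %s has no %s residues; composition rows set to NA",
                state, INTOLERANT if len(intol) == 0 else TOLERANT,
            )
            for aa in AMINO_ACIDS:
                rows.append(
                    {"state": state, "aa": aa, "log2_or": np.nan,
                     "p": np.nan, "q": np.nan}
                )
            continue
        intol_counts = intol["aa"].value_counts()
        tol_counts = tol["aa"].value_counts()
        n_i, n_t = len(intol), len(tol)
        ps, l2 = [], []
        for aa in AMINO_ACIDS:
            a = int(intol_counts.get(aa, 0))
            c = int(tol_counts.get(aa, 0))
            log2_or, p = fisher_ha([[a, n_i - a], [c, n_t - c]])
            l2.append(log2_or)
            ps.append(p)
        qs = bh_fdr(ps)
        for aa, log2_or, p, q in zip(AMINO_ACIDS, l2, ps, qs):
            rows.append({"state": state, "aa": aa, "log2_or": log2_or,
                         "p": p, "q": q})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# biophysical descriptors
# ----------------------------------------------------------------------
def biophysical_summary(
    sequence: str, his_charge: float = 0.0
) -> tuple[float, float, float]:
    """(mean side-chain charge, mean Kyte–Doolittle hydropathy, aromatic fraction)."""
    if not sequence:
        return float("nan"), float("nan"), float("nan")
    charges = charge_map(his_charge)
    mean_charge = sum(charges[aa] for aa in sequence) / len(sequence)
    mean_kd = sum(KYTE_DOOLITTLE[aa] for aa in sequence) / len(sequence)
    aromatic_frac = sum(aa in AROMATIC for aa in sequence) / len(sequence)
    return mean_charge, mean_kd, aromatic_frac


def aromatic_spacing(sequence: str) -> float:
    """Mean distance between consecutive aromatic (F/Y/W) residues.

    Positions are segment-local (1-based); NaN with fewer than two
    aromatics, where spacing is undefined.
    """
    positions = [i + 1 for i, aa in enumerate(sequence) if aa in AROMATIC]
    if len(positions) < 2:
        return float("nan")
    gaps = np.diff(positions)
    return float(gaps.mean())


# ----------------------------------------------------------------------
# segments
# ----------------------------------------------------------------------
@dataclass
class Segment:
    """A maximal run of same-gene/state/class consecutive residues."""

    gene_id: str
    state: str
    constraint_class: str
    start: int  # 1-based inclusive
    end: int
    length: int
    sequence: str
    mean_charge: float
    mean_hydropathy: float
    aromatic_fraction: float
    aromatic_spacing: float


def extract_segments(
    records: pd.DataFrame, his_charge: float = 0.0
) -> pd.DataFrame:
    """Maximal same-(gene, state, class) runs of consecutive residues.

    Unclassified residues carry no constraint information: they break runs
    and are not emitted as segments themselves.
    """
    df = records.sort_values(["gene_id", "protein_pos"])
    segments: list[Segment] = []
    run: list[tuple[int, str]] = []
    key: Optional[tuple[str, str, str]] = None

    def flush() -> None:
        if not run or key is None:
            return
        gene, state, cls = key
        seq = "".join(aa for _, aa in run)
        charge, kdm, arom = biophysical_summary(seq, his_charge)
        segments.append(
            Segment(gene, state, cls, run[0][0], run[-1][0], len(run), seq,
                    charge, kdm, arom, aromatic_spacing(seq))
        )

    for row in df.itertuples(index=False):
        cls = row.constraint_class
        if cls == UNCLASSIFIED:
            flush()
            run, key = [], None
            continue
        row_key = (row.gene_id, row.state, cls)
        contiguous = (
            key == row_key and run and row.protein_pos == run[-1][0] + 1
        )
        if not contiguous:
            flush()
            run, key = [], row_key
        run.append((row.protein_pos, row.aa))
    flush()

    return pd.DataFrame(
        [
            {
                "gene_id": s.gene_id,
                "state": s.state,
                "constraint_class": s.constraint_class,
                "start": s.start,
                "end": s.end,
                "length": s.length,
                "mean_charge": s.mean_charge,
                "mean_hydropathy": s.mean_hydropathy,
                "aromatic_fraction": s.aromatic_fraction,
                "aromatic_spacing": s.aromatic_spacing,
            }
            for s in segments
        ],
        columns=[
            "gene_id", "state", "constraint_class", "start", "end", "length",
            "mean_charge", "mean_hydropathy", "aromatic_fraction",
            "aromatic_spacing",
        ],
    )


# ----------------------------------------------------------------------
# Intolerant - Tolerant contrasts
# ----------------------------------------------------------------------
_RESIDUE_PROPERTIES = ("charge", "hydropathy", "aromatic_fraction")
_SEGMENT_PROPERTIES = ("segment_length", "aromatic_spacing")


def delta_contrast(
    records: pd.DataFrame,
    segments: pd.DataFrame,
    his_charge: float = 0.0,
) -> pd.DataFrame:
    """Δ = mean(Intolerant) − mean(Tolerant) per property per state.

    Residue-level properties (per-residue charge, hydropathy, aromatic
    indicator) and segment-level ones (length, aromatic spacing) are each
    compared with a two-sided Mann–Whitney U test.  States where either
    class is empty yield NA with a warning.
    """
    charges = charge_map(his_charge)
    rows = []
    for state in sorted(records["state"].unique()):
        sub = records[records["state"] == state]
        by_class = {
            cls: sub[sub["constraint_class"] == cls] for cls in (INTOLERANT, TOLERANT)
        }
        seg_sub = segments[segments["state"] == state] if len(segments) else segments
        for prop in _RESIDUE_PROPERTIES + _SEGMENT_PROPERTIES:
            if prop in _RESIDUE_PROPERTIES:
                def values(df: pd.DataFrame) -> np.ndarray:
                    if prop == "charge":
                        return df["aa"].map(charges).to_numpy(dtype=float)
                    if prop == "hydropathy":
                        return df["aa"].map(KYTE_DOOLITTLE).to_numpy(dtype=float)
                    return df["aa"].isin(AROMATIC).to_numpy(dtype=float)

                a = values(by_class[INTOLERANT])
                b = values(by_class[TOLERANT])
            else:
                col = "length" if prop == "segment_length" else "aromatic_spacing"
                def seg_values(cls: str) -> np.ndarray:
                    if len(seg_sub) == 0:
                        return np.array([])
                    v = seg_sub.loc[
                        seg_sub["constraint_class"] == cls, col
                    ].to_numpy(dtype=float)
                    return v[~np.isnan(v)]

                a = seg_values(INTOLERANT)
                b = seg_values(TOLERANT)
            if len(a) == 0 or len(b) == 0:
                logger.warning(
                    "delta_contrast: state %s property %s has an empty class; NA",
                    state, prop,
                )
                rows.append({"state": state, "property": prop,
                             "delta": np.nan, "p": np.nan,
                             "n_intolerant": len(a), "n_tolerant": len(b)})
                continue
            _, p = mann_whitney(a, b)
            rows.append(
                {"state": state, "property": prop,
                 "delta": float(a.mean() - b.mean()), "p": p,
                 "n_intolerant": len(a), "n_tolerant": len(b)}
            )
    return pd.DataFrame(rows)
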