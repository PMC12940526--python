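"""Per-residue structural states from curated and predicted annotations.

Disorder-region annotations arrive from heterogeneous sources: manually
curated disorder and structural-transition regions (DisProt-style),
consensus disorder predictions (MobiDB-style) and residues missing from
experimental structures (PDB-derived).  This module consolidates them
into exactly one of four mutually exclusive states per residue: order,
disorder, structural transition, missing residues.  Proteins with no
annotation at all are ordered-only by construction.

Overlaps are resolved by a configurable precedence; the default places
the most specific curated evidence first:

    structural transition > curated disorder > predicted disorder
    > missing residues > order (the unannotated background)
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd


class State(str, enum.Enum):
    ORDER = "order"
    DISORDER = "disorder"
    TRANSITION = "structural_transition"
    MISSING = "missing_residues"


class Source(str, enum.Enum):
    CURATED = "curated"
    PREDICTED = "predicted"
    DERIVED_PDB = "derived_pdb"


class AnnotationError(ValueError):
    pass


# layer key: (state label, source or None meaning any source)
DEFAULT_PRECEDENCE: tuple[tuple[State, Optional[Source]], ...] = (
    (State.TRANSITION, None),
    (State.DISORDER, Source.CURATED),
    (State.DISORDER, Source.PREDICTED),
    (State.MISSING, None),
)

_VALID_LABEL_SOURCE = {
    (State.DISORDER, Source.CURATED),
    (State.DISORDER, Source.PREDICTED),
    (State.TRANSITION, Source.CURATED),
    (State.MISSING, Source.DERIVED_PDB),
}


@dataclass(frozen=True)
class RegionAnnotation:
    """One annotated protein region, 1-based inclusive coordinates."""

    gene_id: str
    start: int
    end: int
    label: State
    source: Source
    term: Optional[str] = None  # optional GO/IDPO-style function term

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise AnnotationError(
                f"{self.gene_id}: bad region {self.start}-{self.end}"
            )
        if (self.label, self.source) not in _VALID_LABEL_SOURCE:
            raise AnnotationError(
                f"{self.gene_id}: label {self.label.value} cannot come from "
                f"source {self.source.value}"
            )


def assign_states(
    protein_length: int,
    annotations: Iterable[RegionAnnotation],
    precedence: Sequence[tuple[State, Optional[Source]]] = DEFAULT_PRECEDENCE,
) -> list[State]:
    """Paint one state per residue, resolving overlaps by precedence.

    Painting proceeds from the lowest-precedence layer up, so the result
    is independent of the order of the input annotation list.
    """
    annotations = list(annotations)
    for a in annotations:
        if a.end > protein_length:
            raise AnnotationError(
                f"{a.gene_id}: region {a.start}-{a.end} exceeds protein "
                f"length {protein_length}"
            )
    states = np.array([State.ORDER] * protein_length, dtype=object)
    for label, source in reversed(precedence):
        for a in annotations:
            if a.label is not label:
                continue
            if source is not None and a.source is not source:
                continue
            states[a.start - 1 : a.end] = label
    return list(states)


def state_composition(states_by_gene: Mapping[str, Sequence[State]]) -> pd.DataFrame:
    """Residue counts and fractions per state over a gene set."""
    counts = {s: 0 for s in State}
    for states in states_by_gene.values():
        for s in states:
            counts[s] += 1
    total = sum(counts.values())
    rows = [
        {
            "state": s.value,
            "n_residues": counts[s],
            "fraction": counts[s] / total if total else float("nan"),
        }
        for s in State
    ]
    return pd.DataFrame(rows)


_OVERLAP_COLUMNS = (
    "curated_disorder",
    "predicted_disorder",
    "structural_transition",
    "missing_residues",
)


def annotation_overlap_summary(
    annotations: Iterable[RegionAnnotation],
) -> tuple[pd.DataFrame, pd.Series]:
    """Gene x annotation-type presence matrix plus exact-combination counts.

    The presence matrix is the input of an UpSet-style plot; the counts
    Series is keyed by the boolean combination tuple and partitions the
    gene set (each gene contributes to exactly one combination).
    """
    presence: dict[str, dict[str, bool]] = {}
    for a in annotations:
        row = presence.setdefault(
            a.gene_id, {c: False for c in _OVERLAP_COLUMNS}
        )
        if a.label is State.DISORDER and a.source is Source.CURATED:
            row["curated_disorder"] = True
        elif a.label is State.DISORDER and a.source is Source.PREDICTED:
            row["predicted_disorder"] = True
        elif a.label is State.TRANSITION:
            row["structural_transition"] = True
        elif a.label is State.MISSING:
            row["missing_residues"] = True
    matrix = pd.DataFrame.from_dict(presence, orient="index").reindex(
        columns=list(_OVERLAP_COLUMNS)
    )
    matrix.index.name = "gene_id"
    matrix = matrix.sort_index()
    if matrix.empty:
        return matrix, pd.Series(dtype=int)
    combos = matrix.groupby(list(_OVERLAP_COLUMNS)).size()
    return matrix, combos


def term_gene_counts(annotations: Iterable[RegionAnnotation]) -> pd.DataFrame:
    """Function-term -> number of genes carrying at least one such region."""
    genes_per_term: dict[str, set[str]] = {}
    for a in annotations:
        if a.term:
            genes_per_term.setdefault(a.term, set()).add(a.gene_id)
    rows = [
        {"term": term, "n_genes": len(genes)}
        for term, genes in sorted(genes_per_term.items())
    ]
    return pd.DataFrame(rows, columns=["term", "n_genes"])


# ----------------------------------------------------------------------
# readers / writers
# ----------------------------------------------------------------------
def read_annotation_tsv(path: str) -> list[RegionAnnotation]:
    """TSV columns: gene_id, start, end, label, source, term (optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            RegionAnnotation(
                gene_id=row.gene_id,
                start=int(row.start),
                end=int(row.end),
                label=State(row.label),
                source=Source(row.source),
                term=getattr(row, "term", "") or None,
            )
        )
    return out


def write_annotation_tsv(annotations: Iterable[RegionAnnotation], path: str) -> None:
    rows = [
        {
            "gene_id": a.gene_id,
            "start": a.start,
            "end": a.end,
            "label": a.label.value,
            "source": a.source.value,
            "term": a.term or "",
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=["gene_id", "start", "end", "label", "source", "term"]).to_csv(
        path, sep="\t", index=False
    )


def read_disprot_json(
    path: str,
    field_map: Optional[Mapping[str, str]] = None,
) -> list[RegionAnnotation]:
    """DisProt-style JSON region list.

    Expects ``{"regions": [{"acc": ..., "start": ..., "end": ...,
    "label": ..., "source": ..., "term": ...}, ...]}``; ``field_map``
    renames non-default keys (e.g. ``{"acc": "uniprot_id"}``).
    """
    field_map = dict(field_map or {})
    with open(path) as fh:
        payload = json.load(fh)
    regions = payload["regions"] if isinstance(payload, dict) else payload
    out = []
    for region in regions:
        get = lambda key: region[field_map.get(key, key)]  # noqa: E731
        out.append(
            RegionAnnotation(
                gene_id=str(get("acc")),
                start=int(get("start")),
                end=int(get("end")),
                label=State(get("label")),
                source=Source(get("source")),
                term=region.get(field_map.get("term", "term")),
            )
        )
    return out
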