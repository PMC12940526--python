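"""End-to-end orchestration: inputs -> per-residue profiles -> statistics.

The pipeline reads a CDS FASTA, a population VCF, a structural-annotation
TSV and an optional clinical variant file, computes per-residue MTR
profiles with a global FDR family, joins states with constraint classes,
and writes the full set of result tables as plain TSV with fixed column
order and ``NA`` missing markers, so outputs are byte-stable under
identical inputs and config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .mtr_engine import (
    DEFAULT_MTR_THRESHOLD,
    DEFAULT_WINDOW,
    MTRProfile,
    apply_global_fdr,
    profile,
)
from .residue_analytics import (
    build_residue_table,
    composition_enrichment,
    delta_contrast,
    extract_segments,
)
from .stat_battery import clinvar_state_enrichment, descriptive, kruskal_dunn
from .structure_states import (
    RegionAnnotation,
    State,
    assign_states,
    read_annotation_tsv,
    state_composition,
)
from .transcript_model import Transcript, read_cds_fasta
from .variant_io import (
    ClinicalClass,
    VariantRecord,
    read_clinical_tsv,
    read_clinical_vcf,
    read_population_vcf,
    tally_observed,
)

logger = logging.getLogger(__name__)

STATE_ORDER = (State.ORDER, State.DISORDER, State.MISSING, State.TRANSITION)

_FLOAT_FORMAT = "%.10g"


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    cds_fasta: str
    population_vcf: str
    annotations_tsv: Optional[str] = None
    clinical_path: Optional[str] = None  # TSV or VCF by extension
    out_dir: str = "mtrkit_out"
    window_size: int = DEFAULT_WINDOW
    mtr_threshold: float = DEFAULT_MTR_THRESHOLD
    fdr_alpha: float = 0.05
    fdr_family: str = "global"  # or "per_gene"
    vcf_coords: str = "cds"  # or "genomic"
    clnsig_key: str = "CLNSIG"
    his_charge: float = 0.0
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.window_size < 1 or self.window_size % 2 == 0:
            raise ValueError("window_size must be a positive odd integer")
        if self.mtr_threshold <= 0:
            raise ValueError("mtr_threshold must be positive")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must lie in (0, 1)")
        if self.fdr_family not in ("global", "per_gene"):
            raise ValueError("fdr_family must be 'global' or 'per_gene'")

    @classmethod
    def from_file(cls, path: str, **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh)  # YAML superset parses JSON too
        payload.update(overrides)
        return cls(**payload)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    residue_table: pd.DataFrame
    profiles: dict[str, MTRProfile]
    state_summary: pd.DataFrame
    composition: pd.DataFrame
    segments: pd.DataFrame
    delta: pd.DataFrame
    enrichment: Optional[pd.DataFrame]
    state_counts: pd.DataFrame
    output_files: dict[str, str] = field(default_factory=dict)


def _check_gene_join(
    name: str, gene_ids: Sequence[str], transcripts: Mapping[str, Transcript]
) -> None:
    missing = sorted(set(gene_ids) - set(transcripts))
    if missing:
        raise PipelineError(f"{name}: unknown gene_id(s) {missing}")


def compute_profiles(
    transcripts: Mapping[str, Transcript],
    population: Sequence[VariantRecord],
    window_size: int = DEFAULT_WINDOW,
    mtr_threshold: float = DEFAULT_MTR_THRESHOLD,
    fdr_family: str = "global",
) -> dict[str, MTRProfile]:
    by_gene: dict[str, list[VariantRecord]] = {g: [] for g in transcripts}
    for r in population:
        if r.gene_id in by_gene:
            by_gene[r.gene_id].append(r)
    profiles = {}
    for gene_id, t in transcripts.items():
        observed = tally_observed(by_gene[gene_id], t)
        profiles[gene_id] = profile(
            t, observed, window_size=window_size, mtr_threshold=mtr_threshold
        )
    if fdr_family == "global":
        apply_global_fdr(profiles.values())
    return profiles


def summarize_states(
    residue_table: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-state MTR descriptives with Dunn compact letters.

    States are compared on their defined per-residue MTR values with a
    Kruskal–Wallis test and FDR-corrected Dunn post hoc pairwise tests;
    groups sharing a letter are not significantly different at ``alpha``.
    """
    present = [
        s.value
        for s in STATE_ORDER
        if (residue_table["state"] == s.value).any()
    ]
    groups, labels = [], []
    for state in present:
        vals = residue_table.loc[
            residue_table["state"] == state, "mtr"
        ].dropna().to_numpy()
        if len(vals) > 0:
            groups.append(vals)
            labels.append(state)
    letters: dict[str, str] = {}
    if len(groups) >= 2:
        letters = kruskal_dunn(groups, labels, alpha=alpha).letters
    elif len(groups) == 1:
        letters = {labels[0]: "a"}
    rows = []
    for state, vals in zip(labels, groups):
        d = descriptive(vals)
        rows.append(
            {
                "state": state,
                "n": d.n,
                "mean": d.mean,
                "stddev": d.stddev,
                "skewness": d.skewness,
                "kurtosis": d.kurtosis,
                "dunn_letter": letters.get(state, ""),
            }
        )
    for state in present:
        if state not in labels:
            rows.append({"state": state, "n": 0, "mean": np.nan, "stddev": np.nan,
                         "skewness": np.nan, "kurtosis": np.nan, "dunn_letter": ""})
    return pd.DataFrame(
        rows, columns=["state", "n", "mean", "stddev", "skewness", "kurtosis",
                       "dunn_letter"]
    )


def _clinical_with_states(
    clinical: Sequence[VariantRecord],
    states_by_gene: Mapping[str, Sequence[State]],
) -> pd.DataFrame:
    rows = []
    for r in clinical:
        states = states_by_gene.get(r.gene_id)
        if states is None or not 1 <= r.protein_pos <= len(states):
            continue
        rows.append(
            {
                "gene_id": r.gene_id,
                "protein_pos": r.protein_pos,
                "state": states[r.protein_pos - 1].value,
                "clinical_class": r.clinical_class.value,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "protein_pos", "state", "clinical_class"]
    )


def _write(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format=_FLOAT_FORMAT)


def run(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write every output table.

    Raises :class:`PipelineError` on unresolvable gene joins; an empty
    variant set completes with all-NA MTR and a prominent warning.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    os.makedirs(config.out_dir, exist_ok=True)

    transcripts = read_cds_fasta(config.cds_fasta)
    if not transcripts:
        raise PipelineError(f"no valid transcripts in {config.cds_fasta}")

    population = read_population_vcf(
        config.population_vcf, transcripts, coords=config.vcf_coords
    )
    if not population:
        logger.warning(
            "EMPTY VARIANT SET: no qualifying population variants; "
            "all MTR values will be NA"
        )

    annotations: list[RegionAnnotation] = []
    if config.annotations_tsv:
        annotations = read_annotation_tsv(config.annotations_tsv)
        _check_gene_join("annotations", [a.gene_id for a in annotations], transcripts)
    per_gene_ann: dict[str, list[RegionAnnotation]] = {}
    for a in annotations:
        per_gene_ann.setdefault(a.gene_id, []).append(a)
    states_by_gene = {
        g: assign_states(len(t.protein), per_gene_ann.get(g, []))
        for g, t in transcripts.items()
    }

    profiles = compute_profiles(
        transcripts,
        population,
        window_size=config.window_size,
        mtr_threshold=config.mtr_threshold,
        fdr_family=config.fdr_family,
    )
    ordered_profiles = [profiles[g] for g in sorted(profiles)]
    residue_table = build_residue_table(ordered_profiles, states_by_gene)
    # attach window counts for per-gene track rendering
    residue_table["obs_missense"] = np.concatenate(
        [p.obs_missense for p in ordered_profiles]
    )
    residue_table["obs_synonymous"] = np.concatenate(
        [p.obs_synonymous for p in ordered_profiles]
    )
    residue_table["exp_missense"] = np.concatenate(
        [p.exp_missense for p in ordered_profiles]
    )
    residue_table["exp_synonymous"] = np.concatenate(
        [p.exp_synonymous for p in ordered_profiles]
    )

    state_summary = summarize_states(residue_table, alpha=config.fdr_alpha)
    composition = composition_enrichment(residue_table)
    segments = extract_segments(residue_table, his_charge=config.his_charge)
    delta = delta_contrast(residue_table, segments, his_charge=config.his_charge)
    state_counts = state_composition(states_by_gene)

    enrichment = None
    if config.clinical_path:
        if config.clinical_path.endswith((".vcf", ".vcf.gz")):
            clinical = read_clinical_vcf(
                config.clinical_path, transcripts,
                coords=config.vcf_coords, clnsig_key=config.clnsig_key,
            )
        else:
            clinical = read_clinical_tsv(config.clinical_path, transcripts)
        clin_df = _clinical_with_states(clinical, states_by_gene)
        present_states = [
            s.value for s in STATE_ORDER if (clin_df["state"] == s.value).any()
        ]
        enrichment = clinvar_state_enrichment(clin_df, states=present_states)

    result = RunResult(
        residue_table=residue_table,
        profiles=profiles,
        state_summary=state_summary,
        composition=composition,
        segments=segments,
        delta=delta,
        enrichment=enrichment,
        state_counts=state_counts,
    )

    out = config.out_dir
    files = {
        "profiles": os.path.join(out, "profiles.tsv"),
        "state_summary": os.path.join(out, "state_summary.tsv"),
        "state_composition": os.path.join(out, "state_composition.tsv"),
        "composition_enrichment": os.path.join(out, "composition_enrichment.tsv"),
        "composition_log2or_matrix": os.path.join(out, "composition_log2or_matrix.tsv"),
        "segments": os.path.join(out, "segments.tsv"),
        "delta_contrast": os.path.join(out, "delta_contrast.tsv"),
        "manifest": os.path.join(out, "manifest.json"),
    }
    profile_cols = [
        "gene_id", "protein_pos", "aa", "state", "obs_missense", "obs_synonymous",
        "exp_missense", "exp_synonymous", "mtr", "p", "q", "constraint_class",
    ]
    _write(residue_table[profile_cols], files["profiles"])
    _write(state_summary, files["state_summary"])
    _write(state_counts, files["state_composition"])
    _write(composition, files["composition_enrichment"])
    matrix = composition.pivot(index="state", columns="aa", values="log2_or")
    matrix.to_csv(files["composition_log2or_matrix"], sep="\t", na_rep="NA",
                  float_format=_FLOAT_FORMAT)
    _write(segments, files["segments"])
    _write(delta, files["delta_contrast"])
    if enrichment is not None:
        files["clinvar_enrichment"] = os.path.join(out, "clinvar_enrichment.tsv")
        _write(enrichment, files["clinvar_enrichment"])
    manifest = {
        "tool": "mtrkit",
        "version": __version__,
        "config_hash": config.config_hash(),
        "n_genes": len(transcripts),
        "n_population_records": len(population),
        "files": {k: os.path.basename(v) for k, v in files.items() if k != "manifest"},
    }
    with open(files["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    result.output_files = files
    return result
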