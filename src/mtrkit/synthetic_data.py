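"""Synthetic study bundles with known planted structure.

Emulates the statistical shape of the real inputs — population variant
catalogs, disorder annotations and clinically labelled variants for a set
of coding transcripts — so that every pipeline stage is testable without
any database download and parameter recovery can be scored against a
written truth table.

The observation model is deliberately minimal: every possible SNV of a
transcript is observed independently with probability ``p_obs``
(presence/absence, no allele-frequency spectrum, matching how the MTR
consumes variants), and purifying selection is emulated by thinning
missense emission inside depletion regions by a retention factor δ while
synonymous sites stay untouched as the neutral yardstick.  Under this
model the expected MTR of a fully depleted window is an explicit function
of δ alone.

Default parameters mirror the study conditions the pipeline is meant for:
state proportions follow the residue composition of a disorder-annotated
neurodevelopmental gene set (roughly 69% order, 25% disorder, 6% missing,
<1% transition), and clinical labels plant the reported direction of
pathogenic enrichment (positive in order, negative in disorder).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import os
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .structure_states import RegionAnnotation, Source, State
from .transcript_model import (
    BASES,
    CODON_TO_AA,
    SENSE_CODONS,
    STOP_CODONS,
    STOP_SYMBOL,
    Transcript,
    write_cds_fasta,
)
from .variant_io import ClinicalClass, VariantRecord, make_record

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class DepletionRegion:
    """Missense thinning of one residue interval (1-based inclusive)."""

    gene_index: int
    start_res: int
    end_res: int
    delta: float  # missense retention factor in [0, 1]


@dataclass
class SyntheticConfig:
    n_genes: int = 50
    protein_length: tuple[int, int] = (500, 500)  # uniform inclusive bounds
    state_layout: tuple[tuple[State, float], ...] = (
        (State.ORDER, 0.685),
        (State.DISORDER, 0.250),
        (State.MISSING, 0.063),
        (State.TRANSITION, 0.002),
    )
    p_obs: float = 0.15
    nonpass_fraction: float = 0.05
    depletion_regions: tuple[DepletionRegion, ...] = ()
    clinical_targets: tuple[tuple[State, str, float], ...] = (
        (State.ORDER, "pathogenic", 2.0),
        (State.DISORDER, "pathogenic", -2.0),
    )
    clinical_base_probs: tuple[tuple[str, float], ...] = (
        ("pathogenic", 0.30),
        ("benign", 0.30),
        ("vus", 0.40),
    )
    n_clinical_variants: int = 10_000
    codon_weights: Optional[Mapping[str, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        fractions = [f for _, f in self.state_layout]
        if abs(sum(fractions) - 1.0) > 1e-9 or any(f < 0 for f in fractions):
            raise ConfigError("state_layout fractions must be >= 0 and sum to 1")
        if not 0.0 <= self.p_obs <= 1.0:
            raise ConfigError("p_obs must lie in [0, 1]")
        if not 0.0 <= self.nonpass_fraction < 1.0:
            raise ConfigError("nonpass_fraction must lie in [0, 1)")
        for r in self.depletion_regions:
            if not 0.0 <= r.delta <= 1.0:
                raise ConfigError("depletion delta must lie in [0, 1]")
        base = dict(self.clinical_base_probs)
        if abs(sum(base.values()) - 1.0) > 1e-9:
            raise ConfigError("clinical_base_probs must sum to 1")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _rng(cfg: SyntheticConfig, stage: int) -> np.random.Generator:
    # independent, reproducible stream per generator stage
    return np.random.default_rng([cfg.seed, stage])


# ----------------------------------------------------------------------
# transcripts
# ----------------------------------------------------------------------
def generate_transcripts(
    cfg: SyntheticConfig, rng: Optional[np.random.Generator] = None
) -> list[Transcript]:
    """Random CDSs with no internal stop and a terminal stop codon.

    Codon composition is uniform over the 61 sense codons unless
    ``codon_weights`` biases it (e.g. toward a disorder-like S/P/E/K/Q/G
    enrichment for composition tests).
    """
    rng = rng if rng is not None else _rng(cfg, 0)
    if cfg.codon_weights is None:
        weights = np.full(len(SENSE_CODONS), 1 / len(SENSE_CODONS))
    else:
        weights = np.array([cfg.codon_weights.get(c, 1.0) for c in SENSE_CODONS])
        weights = weights / weights.sum()
    lo, hi = cfg.protein_length
    transcripts = []
    for i in range(cfg.n_genes):
        n_res = int(rng.integers(lo, hi + 1))
        codons = rng.choice(len(SENSE_CODONS), size=n_res, p=weights)
        stop = STOP_CODONS[int(rng.integers(len(STOP_CODONS)))]
        cds = "".join(SENSE_CODONS[k] for k in codons) + stop
        transcripts.append(Transcript(f"gene{i + 1:04d}", cds))
    return transcripts


# ----------------------------------------------------------------------
# population variants
# ----------------------------------------------------------------------
def _codon_alts(codon: str) -> list[tuple[int, str, str]]:
    """(offset, alt base, consequence) for the 9 mutants of a sense codon."""
    ref_aa = CODON_TO_AA[codon]
    out = []
    for offset in range(3):
        for alt in BASES:
            if alt == codon[offset]:
                continue
            mutant = codon[:offset] + alt + codon[offset + 1 :]
            alt_aa = CODON_TO_AA[mutant]
            if alt_aa == STOP_SYMBOL:
                cls = "stop"
            elif alt_aa == ref_aa:
                cls = "synonymous"
            else:
                cls = "missense"
            out.append((offset, alt, cls))
    return out


_CODON_ALTS = {c: _codon_alts(c) for c in SENSE_CODONS}


def generate_population_variants(
    cfg: SyntheticConfig,
    transcripts: Sequence[Transcript],
    rng: Optional[np.random.Generator] = None,
) -> list[VariantRecord]:
    """Bernoulli-observe every possible SNV; thin missense in depletion regions.

    A ``nonpass_fraction`` of emitted records is flagged non-PASS (class-
    independent, so the null MTR is unaffected) to exercise the release-
    quality filter downstream.
    """
    rng = rng if rng is not None else _rng(cfg, 1)
    depletion: dict[int, list[DepletionRegion]] = {}
    for r in cfg.depletion_regions:
        depletion.setdefault(r.gene_index, []).append(r)

    records: list[VariantRecord] = []
    for gi, t in enumerate(transcripts):
        regions = depletion.get(gi, [])
        for codon_idx in range(len(t.protein)):
            codon = t.cds[3 * codon_idx : 3 * codon_idx + 3]
            res = codon_idx + 1
            delta = 1.0
            for r in regions:
                if r.start_res <= res <= r.end_res:
                    delta = min(delta, r.delta)
            for offset, alt, cls in _CODON_ALTS[codon]:
                p = cfg.p_obs * (delta if cls == "missense" else 1.0)
                if rng.random() >= p:
                    continue
                passed = rng.random() >= cfg.nonpass_fraction
                records.append(
                    make_record(t, 3 * codon_idx + offset, alt, passed_filter=passed)
                )
    return records


def write_population_vcf(
    records: Sequence[VariantRecord],
    transcripts: Sequence[Transcript],
    path: str,
) -> None:
    """Minimal VCF 4.2 in CDS coordinates (CHROM = gene_id, POS = cds_pos+1)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FILTER=<ID=AC0,Description="Allele count zero after QC">\n')
        for t in transcripts:
            fh.write(f"##contig=<ID={t.gene_id},length={len(t.cds)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        ordered = sorted(records, key=lambda r: (r.gene_id, r.cds_pos, r.alt_base))
        for r in ordered:
            filt = "PASS" if r.passed_filter else "AC0"
            fh.write(
                f"{r.gene_id}\t{r.cds_pos + 1}\t.\t{r.ref_base}\t{r.alt_base}"
                f"\t.\t{filt}\t.\n"
            )


# ----------------------------------------------------------------------
# structural annotations
# ----------------------------------------------------------------------
_DISORDER_TERMS = ("flexible linker/spacer", "protein binding", "molecular adaptor activity")


def generate_annotations(
    cfg: SyntheticConfig,
    transcripts: Sequence[Transcript],
    rng: Optional[np.random.Generator] = None,
) -> list[RegionAnnotation]:
    """Per-gene region annotations realising the configured state fractions.

    Proteins are tiled with blocks of 5-25 residues whose state is drawn
    from the layout fractions, so aggregate per-state fractions converge
    to the targets.  A fraction of curated disorder blocks also carries an
    inner predicted-disorder region to exercise the precedence rules; the
    inner region never extends past the block, leaving state fractions
    unchanged.
    """
    rng = rng if rng is not None else _rng(cfg, 2)
    states = [s for s, _ in cfg.state_layout]
    fractions = np.array([f for _, f in cfg.state_layout])
    out: list[RegionAnnotation] = []
    for t in transcripts:
        n = len(t.protein)
        pos = 1
        while pos <= n:
            length = int(rng.integers(5, 26))
            end = min(pos + length - 1, n)
            state = states[int(rng.choice(len(states), p=fractions))]
            if state is State.DISORDER:
                curated = rng.random() < 0.6
                source = Source.CURATED if curated else Source.PREDICTED
                term = (
                    _DISORDER_TERMS[int(rng.integers(len(_DISORDER_TERMS)))]
                    if curated and rng.random() < 0.5
                    else None
                )
                out.append(RegionAnnotation(t.gene_id, pos, end, State.DISORDER, source, term))
                if curated and end - pos >= 3 and rng.random() < 0.2:
                    # overlapping predicted region inside the curated block
                    inner_lo = pos + 1
                    inner_hi = end - 1
                    out.append(
                        RegionAnnotation(
                            t.gene_id, inner_lo, inner_hi, State.DISORDER, Source.PREDICTED
                        )
                    )
            elif state is State.TRANSITION:
                out.append(
                    RegionAnnotation(t.gene_id, pos, end, State.TRANSITION, Source.CURATED)
                )
            elif state is State.MISSING:
                out.append(
                    RegionAnnotation(t.gene_id, pos, end, State.MISSING, Source.DERIVED_PDB)
                )
            pos = end + 1
    return out


# ----------------------------------------------------------------------
# clinical labels
# ----------------------------------------------------------------------
_RAW_SIGNIFICANCE = {
    "pathogenic": "Pathogenic",
    "benign": "Benign",
    "vus": "Uncertain_significance",
}


def solve_state_class_probs(
    targets: Sequence[tuple[State, str, float]],
    base_probs: Mapping[str, float],
    state_weights: Mapping[State, float],
) -> pd.DataFrame:
    """Per-state class probabilities realising target state-vs-rest log2 ORs.

    For each targeted state s the class-c probability p_s solves
    odds(p_s) = 2^t · odds(P(c | not s)), where P(c | not s) mixes the
    other states by their residue weights — the targeted cells are coupled
    through that mixture, so the system is solved jointly.  Untargeted
    states keep the base probability; the remaining classes within each
    state share the leftover mass in base proportions.  Targets that force
    probabilities outside (0, 1) raise :class:`ConfigError`.
    """
    classes = list(base_probs)
    states = [s for s in State if state_weights.get(s, 0.0) > 0]
    target_classes = {c for _, c, _ in targets}
    if len(target_classes) > 1:
        raise ConfigError("targets must all address the same clinical class")
    probs = pd.DataFrame(
        {c: [base_probs[c]] * len(states) for c in classes},
        index=[s.value for s in states],
    )
    if not targets:
        return probs

    tclass = next(iter(target_classes))
    tmap = {s: t for s, _, t in targets}
    for s in tmap:
        if s not in states:
            raise ConfigError(f"target on state {s.value} with zero residue weight")
    unknown_states = [s for s in states if s in tmap]
    w = np.array([state_weights[s] for s in states])
    w = w / w.sum()
    base_c = base_probs[tclass]

    def _expit(y: np.ndarray) -> np.ndarray:
        # clamp away from {0, 1} so odds stay finite during iteration
        return np.clip(1.0 / (1.0 + np.exp(-np.clip(y, -500, 500))), 1e-12, 1 - 1e-12)

    def residuals(y: np.ndarray) -> np.ndarray:
        # unknowns in logit space so iterates stay inside (0, 1)
        p = np.array([base_c] * len(states))
        for val, s in zip(_expit(y), unknown_states):
            p[states.index(s)] = val
        res = []
        for s in unknown_states:
            i = states.index(s)
            mask = np.ones(len(states), bool)
            mask[i] = False
            p_rest = float((w[mask] * p[mask]).sum() / w[mask].sum())
            res.append(
                math.log2(p[i] / (1 - p[i])) - math.log2(p_rest / (1 - p_rest))
                - tmap[s]
            )
        return np.array(res)

    y0 = np.full(len(unknown_states), math.log(base_c / (1 - base_c)))
    sol = optimize.root(residuals, x0=y0)
    solved = _expit(sol.x)
    if not sol.success or np.any(solved < 1e-6) or np.any(solved > 1 - 1e-6):
        raise ConfigError(f"infeasible clinical odds-ratio targets: {tmap}")
    for val, s in zip(solved, unknown_states):
        probs.loc[s.value, tclass] = val
    # rescale the other classes to keep rows summing to 1
    other = [c for c in classes if c != tclass]
    other_base = sum(base_probs[c] for c in other)
    for s in unknown_states:
        leftover = 1 - probs.loc[s.value, tclass]
        for c in other:
            probs.loc[s.value, c] = base_probs[c] * leftover / other_base
    return probs


def implied_log2_or(
    probs: pd.DataFrame, state_weights: Mapping[State, float]
) -> pd.DataFrame:
    """State-vs-rest log2 OR implied by a class-probability table."""
    states = [s for s in State if s.value in probs.index]
    w = np.array([state_weights[s] for s in states])
    w = w / w.sum()
    rows = []
    for i, s in enumerate(states):
        mask = np.ones(len(states), bool)
        mask[i] = False
        for c in probs.columns:
            p_in = probs.loc[s.value, c]
            p_rest = float(
                (w[mask] * probs[c].to_numpy()[mask]).sum() / w[mask].sum()
            )
            rows.append(
                {
                    "state": s.value,
                    "clinical_class": c,
                    "prob_in_state": p_in,
                    "log2_or": math.log2(p_in / (1 - p_in))
                    - math.log2(p_rest / (1 - p_rest)),
                }
            )
    return pd.DataFrame(rows)


def generate_clinical_labels(
    cfg: SyntheticConfig,
    transcripts: Sequence[Transcript],
    states_by_gene: Mapping[str, Sequence[State]],
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(clinical variant table, planted truth table).

    Missense positions are sampled uniformly over all residues; each
    draws a concrete single-nucleotide amino-acid change in its codon and
    a class from the state's solved probabilities.  The truth table holds
    the planted probabilities and the log2 ORs they imply.
    """
    rng = rng if rng is not None else _rng(cfg, 3)
    genes, positions, res_states = [], [], []
    for t in transcripts:
        st = states_by_gene[t.gene_id]
        genes.extend([t.gene_id] * len(st))
        positions.extend(range(1, len(st) + 1))
        res_states.extend(st)
    total = len(positions)
    counts = pd.Series([s.value for s in res_states]).value_counts()
    weights = {s: counts.get(s.value, 0) / total for s in State}
    weights = {s: wgt for s, wgt in weights.items() if wgt > 0}

    base = dict(cfg.clinical_base_probs)
    probs = solve_state_class_probs(list(cfg.clinical_targets), base, weights)
    truth = implied_log2_or(probs, weights)
    planted = {(s.value, c): t for s, c, t in cfg.clinical_targets}
    truth["target_log2_or"] = [
        planted.get((row.state, row.clinical_class), np.nan)
        for row in truth.itertuples(index=False)
    ]

    tmap = {t.gene_id: t for t in transcripts}
    classes = list(probs.columns)
    rows = []
    for _ in range(cfg.n_clinical_variants):
        i = int(rng.integers(total))
        gene, pos, state = genes[i], positions[i], res_states[i]
        t = tmap[gene]
        codon = t.cds[3 * (pos - 1) : 3 * pos]
        missense = [(o, alt, CODON_TO_AA[codon[:o] + alt + codon[o + 1 :]])
                    for o, alt, cls in _CODON_ALTS[codon] if cls == "missense"]
        o, alt, aa_alt = missense[int(rng.integers(len(missense)))]
        p = probs.loc[state.value].to_numpy(dtype=float)
        cls = classes[int(rng.choice(len(classes), p=p / p.sum()))]
        rows.append(
            {
                "gene_id": gene,
                "protein_pos": pos,
                "aa_ref": t.protein[pos - 1],
                "aa_alt": aa_alt,
                "clinical_significance": _RAW_SIGNIFICANCE[cls],
            }
        )
    columns = ["gene_id", "protein_pos", "aa_ref", "aa_alt", "clinical_significance"]
    return pd.DataFrame(rows, columns=columns), truth


# ----------------------------------------------------------------------
# bundle
# ----------------------------------------------------------------------
def generate_bundle(cfg: SyntheticConfig, out_dir: str) -> dict[str, str]:
    """Write a complete synthetic study bundle and its manifest.

    Every output is a pure function of the config (seed included); the
    manifest records the config hash so runs can be tied to their inputs.
    """
    from .structure_states import assign_states, write_annotation_tsv

    os.makedirs(out_dir, exist_ok=True)
    transcripts = generate_transcripts(cfg)
    variants = generate_population_variants(cfg, transcripts)
    annotations = generate_annotations(cfg, transcripts)
    per_gene_annotations: dict[str, list[RegionAnnotation]] = {}
    for a in annotations:
        per_gene_annotations.setdefault(a.gene_id, []).append(a)
    states_by_gene = {
        t.gene_id: assign_states(len(t.protein), per_gene_annotations.get(t.gene_id, []))
        for t in transcripts
    }
    clinical, truth = generate_clinical_labels(cfg, transcripts, states_by_gene)

    paths = {
        "cds_fasta": os.path.join(out_dir, "cds.fasta"),
        "population_vcf": os.path.join(out_dir, "population.vcf"),
        "annotations_tsv": os.path.join(out_dir, "annotations.tsv"),
        "clinical_tsv": os.path.join(out_dir, "clinical.tsv"),
        "truth_clinical_tsv": os.path.join(out_dir, "truth_clinical.tsv"),
        "truth_depletion_tsv": os.path.join(out_dir, "truth_depletion.tsv"),
        "manifest_json": os.path.join(out_dir, "manifest.json"),
    }
    write_cds_fasta(transcripts, paths["cds_fasta"])
    write_population_vcf(variants, transcripts, paths["population_vcf"])
    write_annotation_tsv(annotations, paths["annotations_tsv"])
    clinical.to_csv(paths["clinical_tsv"], sep="\t", index=False)
    truth.to_csv(paths["truth_clinical_tsv"], sep="\t", index=False, na_rep="NA",
                 float_format="%.10g")
    pd.DataFrame(
        [
            {
                "gene_id": transcripts[r.gene_index].gene_id,
                "start_res": r.start_res,
                "end_res": r.end_res,
                "delta": r.delta,
            }
            for r in cfg.depletion_regions
        ],
        columns=["gene_id", "start_res", "end_res", "delta"],
    ).to_csv(paths["truth_depletion_tsv"], sep="\t", index=False)
    manifest = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "n_genes": cfg.n_genes,
        "files": {k: os.path.basename(v) for k, v in paths.items() if k != "manifest_json"},
    }
    with open(paths["manifest_json"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("synthetic bundle written to %s (%d genes, %d variants, %d clinical)",
                out_dir, len(transcripts), len(variants), len(clinical))
    return paths
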