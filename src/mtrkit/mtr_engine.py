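"""Missense tolerance ratio over a sliding residue window.

For each residue a window of 31 codons (truncated at the termini) pools
observed and possible missense/synonymous counts.  The MTR is the ratio
of the observed missense proportion O_m/(O_m+O_s) to the possible-SNV
("expected") missense proportion E_m/(E_m+E_s); values below 1 indicate
depletion of missense variation, i.e. purifying selection acting on the
window.  Significance of depletion is assessed with a one-sided exact
binomial test (observed missense count against the expected proportion),
corrected across residues by Benjamini–Hochberg.

Residues whose window holds no observed variant at all get a missing MTR
rather than a pseudo-counted score: no data is not evidence of tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .transcript_model import (
    PossibleSiteTally,
    Transcript,
    enumerate_possible_snvs,
    tallies_to_arrays,
)
from .variant_io import ObservedTallies

DEFAULT_WINDOW = 31
DEFAULT_MTR_THRESHOLD = 0.4

INTOLERANT = "Intolerant"
TOLERANT = "Tolerant"
UNCLASSIFIED = "Unclassified"


class ConfigError(ValueError):
    pass


@dataclass
class WindowCounts:
    """Aggregated counts for one residue-centred window."""

    gene_id: str
    center_residue: int  # 1-based
    window_start_res: int  # 1-based inclusive
    window_end_res: int
    obs_missense: int
    obs_synonymous: int
    exp_missense: int
    exp_synonymous: int


@dataclass
class MTRProfile:
    """Per-residue MTR, test results and constraint class for one gene."""

    gene_id: str
    protein: str
    mtr: np.ndarray  # float, NaN where missing
    p_binomial: np.ndarray  # float, NaN where missing
    q_fdr: np.ndarray
    constraint_class: list[str]
    obs_missense: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    obs_synonymous: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    exp_missense: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    exp_synonymous: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))

    def __len__(self) -> int:
        return len(self.protein)


def window_bounds(residue: int, n_residues: int, window_size: int) -> tuple[int, int]:
    """1-based inclusive window around ``residue``, truncated at termini."""
    half = window_size // 2
    return max(1, residue - half), min(n_residues, residue + half)


def _window_sums(per_codon: np.ndarray, window_size: int) -> np.ndarray:
    """Sliding-window sums over a per-codon count vector via prefix sums."""
    n = len(per_codon)
    cs = np.concatenate([[0], np.cumsum(per_codon)])
    idx = np.arange(1, n + 1)
    half = window_size // 2
    lo = np.maximum(idx - half, 1)
    hi = np.minimum(idx + half, n)
    return cs[hi] - cs[lo - 1]


def _per_codon(per_nt: np.ndarray) -> np.ndarray:
    return per_nt.reshape(-1, 3).sum(axis=1)


def build_windows(
    t: Transcript,
    observed: ObservedTallies,
    possible: Sequence[PossibleSiteTally],
    window_size: int = DEFAULT_WINDOW,
) -> list[WindowCounts]:
    """One :class:`WindowCounts` per residue of the protein."""
    if window_size < 1 or window_size % 2 == 0:
        raise ConfigError(f"window_size must be a positive odd integer, got {window_size}")
    n = len(t.protein)
    pos_mis, pos_syn, _ = tallies_to_arrays(possible)
    om = _window_sums(_per_codon(observed.n_missense), window_size)
    os_ = _window_sums(_per_codon(observed.n_synonymous), window_size)
    em = _window_sums(_per_codon(pos_mis), window_size)
    es = _window_sums(_per_codon(pos_syn), window_size)
    out = []
    for i in range(n):
        lo, hi = window_bounds(i + 1, n, window_size)
        out.append(
            WindowCounts(t.gene_id, i + 1, lo, hi,
                         int(om[i]), int(os_[i]), int(em[i]), int(es[i]))
        )
    return out


def mtr(w: WindowCounts) -> float:
    """Observed/expected missense-proportion ratio; NaN when no variants."""
    n_obs = w.obs_missense + w.obs_synonymous
    if n_obs == 0:
        return float("nan")
    obs_prop = w.obs_missense / n_obs
    exp_prop = w.exp_missense / (w.exp_missense + w.exp_synonymous)
    return obs_prop / exp_prop


def intolerance_test(w: WindowCounts) -> float:
    """One-sided exact binomial p for missense depletion in the window.

    P(X <= O_m) for X ~ Binomial(O_m + O_s, E_m/(E_m+E_s)); one-sided in
    the depletion direction because only intolerant windows are sought.
    """
    n_obs = w.obs_missense + w.obs_synonymous
    if n_obs == 0:
        return float("nan")
    p_exp = w.exp_missense / (w.exp_missense + w.exp_synonymous)
    return float(stats.binom.cdf(w.obs_missense, n_obs, p_exp))


def classify_mtr(value: float, threshold: float = DEFAULT_MTR_THRESHOLD) -> str:
    """Intolerant below the threshold, Tolerant at or above, else Unclassified."""
    if np.isnan(value):
        return UNCLASSIFIED
    return INTOLERANT if value < threshold else TOLERANT


def profile(
    t: Transcript,
    observed: ObservedTallies,
    possible: Optional[Sequence[PossibleSiteTally]] = None,
    window_size: int = DEFAULT_WINDOW,
    mtr_threshold: float = DEFAULT_MTR_THRESHOLD,
) -> MTRProfile:
    """Full per-residue profile for one gene.

    q-values are Benjamini–Hochberg over this gene's defined residues;
    :func:`apply_global_fdr` re-derives them over a whole gene set when the
    analysis treats all residues as one family (the default in the
    pipeline).
    """
    if window_size < 1 or window_size % 2 == 0:
        raise ConfigError(f"window_size must be a positive odd integer, got {window_size}")
    if possible is None:
        possible = enumerate_possible_snvs(t)
    pos_mis, pos_syn, _ = tallies_to_arrays(possible)
    om = _window_sums(_per_codon(observed.n_missense), window_size)
    os_ = _window_sums(_per_codon(observed.n_synonymous), window_size)
    em = _window_sums(_per_codon(pos_mis), window_size)
    es = _window_sums(_per_codon(pos_syn), window_size)

    n_obs = om + os_
    p_exp = em / (em + es)
    with np.errstate(invalid="ignore", divide="ignore"):
        mtr_arr = np.where(n_obs > 0, (om / np.maximum(n_obs, 1)) / p_exp, np.nan)
    p_arr = np.full(len(om), np.nan)
    defined = n_obs > 0
    p_arr[defined] = stats.binom.cdf(om[defined], n_obs[defined], p_exp[defined])

    q_arr = np.full(len(om), np.nan)
    if defined.any():
        q_arr[defined] = bh_adjust(p_arr[defined])

    classes = [classify_mtr(v, mtr_threshold) for v in mtr_arr]
    return MTRProfile(
        gene_id=t.gene_id,
        protein=t.protein,
        mtr=mtr_arr,
        p_binomial=p_arr,
        q_fdr=q_arr,
        constraint_class=classes,
        obs_missense=om,
        obs_synonymous=os_,
        exp_missense=em,
        exp_synonymous=es,
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, input order preserved."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def apply_global_fdr(profiles: Iterable[MTRProfile]) -> None:
    """Recompute q-values with all defined residues of all genes as one family.

    Mutates the profiles in place.  Each p-value belongs to exactly one
    family per run.
    """
    profiles = list(profiles)
    ps, owners = [], []
    for prof in profiles:
        defined = ~np.isnan(prof.p_binomial)
        idx = np.flatnonzero(defined)
        ps.append(prof.p_binomial[idx])
        owners.append((prof, idx))
    flat = np.concatenate(ps) if ps else np.array([])
    if flat.size == 0:
        return
    q = bh_adjust(flat)
    start = 0
    for prof, idx in owners:
        prof.q_fdr[:] = np.nan
        prof.q_fdr[idx] = q[start : start + len(idx)]
        start += len(idx)
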