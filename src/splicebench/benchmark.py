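"""Evaluation outputs: precision/recall curves, misassignment tables, features.

All benchmarking is at PSM level against an answer key mapping each spectrum
to its true peptide and true category (non-spliced, cis-spliced, or trapping —
the deliberately unidentifiable third of the constructed datasets).  A PSM is
*correct* when its sequence equals the true peptide after I/L collapsing AND
its assigned splice category equals the true category.  Precision is correct
over assigned, recall is correct over true, and the true FDR is 1 - precision
by definition.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParamData import kd as _KYTE_DOOLITTLE

from .engine_sim import (
    FdrPoint,
    PSM,
    SearchParams,
    Spectrum,
    estimate_fdr,
    theoretical_fragments,
    _match_stats,
)
from .ground_truth import TRAPPING
from .proteome import collapse_peptide
from .splice_mapper import CIS, NONSPLICED, TRANS

BENCH_CATEGORIES = (NONSPLICED, CIS)
TRUE_CATEGORIES = (NONSPLICED, CIS, TRAPPING)
ASSIGNED_CATEGORIES = (NONSPLICED, CIS, TRANS)


@dataclasses.dataclass(frozen=True)
class PrPoint:
    threshold: float
    precision: float
    recall: float
    n_assigned: int
    n_correct: int
    category: str

    @property
    def fdr_true(self) -> float:
        return 1.0 - self.precision


@dataclasses.dataclass(frozen=True)
class SpectrumFeatures:
    ion_coverage: float
    snr: float  # +inf when every peak matches
    peptide_length: int
    hydrophobicity: float  # mean Kyte-Doolittle hydropathy


AnswerKey = Mapping[str, tuple[str, str]]  # spectrum_id -> (peptide, true category)


def _require_key(psms: Sequence[PSM], answer_key: AnswerKey) -> None:
    missing = {p.spectrum_id for p in psms if p.spectrum_id not in answer_key}
    if missing:
        raise KeyError(f"spectra missing from answer key: {sorted(missing)[:5]}")


def _is_correct(psm: PSM, answer_key: AnswerKey) -> bool:
    if psm.is_decoy:
        return False
    true_pep, true_cat = answer_key[psm.spectrum_id]
    return (
        psm.assigned_category == true_cat
        and collapse_peptide(psm.peptide) == collapse_peptide(true_pep)
    )


def precision_recall(
    psms: Sequence[PSM],
    answer_key: AnswerKey,
    thresholds: Sequence[float],
    categories: Sequence[str] = BENCH_CATEGORIES,
) -> dict[str, list[PrPoint]]:
    """Per-category PR curves over a threshold grid.

    Points with zero assigned PSMs (undefined precision) are dropped.  The
    recall denominator of a category is the number of spectra whose true
    category it is.
    """
    _require_key(psms, answer_key)
    n_true = {
        cat: sum(1 for _pep, c in answer_key.values() if c == cat) for cat in categories
    }
    curves: dict[str, list[PrPoint]] = {cat: [] for cat in categories}
    for cat in categories:
        cat_psms = [p for p in psms if p.assigned_category == cat]
        for th in thresholds:
            assigned = [p for p in cat_psms if p.score >= th]
            if not assigned:
                continue
            correct = sum(1 for p in assigned if _is_correct(p, answer_key))
            recall = correct / n_true[cat] if n_true[cat] else 0.0
            curves[cat].append(
                PrPoint(th, correct / len(assigned), recall, len(assigned), correct, cat)
            )
    return curves


def misassignment_table(
    psms: Sequence[PSM], answer_key: AnswerKey, threshold: float
) -> pd.DataFrame:
    """Cross-table of true category (rows) by assigned category (columns).

    Counts target PSMs at or above the threshold; the TRAPPING row is the
    misassignment count of unidentifiable spectra.
    """
    _require_key(psms, answer_key)
    table = pd.DataFrame(
        0, index=list(TRUE_CATEGORIES), columns=list(ASSIGNED_CATEGORIES)
    )
    for p in psms:
        if p.is_decoy or p.score < threshold or p.assigned_category is None:
            continue
        true_cat = answer_key[p.spectrum_id][1]
        if true_cat in table.index and p.assigned_category in table.columns:
            table.loc[true_cat, p.assigned_category] += 1
    return table


def fdr_psm_curve(
    psms: Sequence[PSM], thresholds: Sequence[float]
) -> list[tuple[float, int, float]]:
    """(threshold, number of assigned target PSMs, estimated FDR %) per threshold."""
    out = []
    for th in thresholds:
        pt: FdrPoint = estimate_fdr(psms, th)
        out.append((th, pt.n_target, pt.fdr_percent))
    return out


def spectrum_features(
    spectrum: Spectrum, peptide: str, params: SearchParams = SearchParams()
) -> SpectrumFeatures:
    """Ion coverage, signal-to-noise, peptide length and hydropathy.

    Ion coverage is the fraction of the 2(n-1) theoretical singly-charged b/y
    ions with a peak within the fragment tolerance.  SNR is the median
    intensity of fragment-matched peaks over the median intensity of the
    remaining peaks (+inf if nothing is unmatched).
    """
    if not peptide:
        raise ValueError("empty peptide")
    frags = theoretical_fragments(peptide)
    m, _ = _match_stats(spectrum.mz, frags, params.fragment_tol_da)
    coverage = m / len(frags)
    # classify peaks as matched/unmatched for the SNR
    if len(spectrum.mz):
        idx = np.searchsorted(frags, spectrum.mz)
        left = np.clip(idx - 1, 0, len(frags) - 1)
        right = np.clip(idx, 0, len(frags) - 1)
        dist = np.minimum(
            np.abs(frags[left] - spectrum.mz), np.abs(frags[right] - spectrum.mz)
        )
        matched_mask = dist <= params.fragment_tol_da
        matched = spectrum.intensity[matched_mask]
        unmatched = spectrum.intensity[~matched_mask]
    else:
        matched = unmatched = np.empty(0)
    if len(matched) == 0:
        snr = 0.0
    elif len(unmatched) == 0:
        snr = math.inf
    else:
        snr = float(np.median(matched) / np.median(unmatched))
    hydro = float(np.mean([_KYTE_DOOLITTLE[a] for a in peptide]))
    return SpectrumFeatures(coverage, snr, len(peptide), hydro)


def plot_pr_curves(
    curves: Mapping[str, Sequence[PrPoint]], path, title: Optional[str] = None
) -> None:
    """Render per-category precision/recall curves to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for cat, pts in curves.items():
        if not pts:
            continue
        ordered = sorted(pts, key=lambda p: p.recall)
        ax.plot(
            [p.recall for p in ordered],
            [p.precision for p in ordered],
            marker="o",
            label=cat,
        )
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.set_xlim(0, 1.02)
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def pr_curves_to_frame(curves: Mapping[str, Sequence[PrPoint]]) -> pd.DataFrame:
    rows = [
        (p.category, p.threshold, p.precision, p.recall, p.n_assigned, p.n_correct)
        for pts in curves.values()
        for p in pts
    ]
    return pd.DataFrame(
        rows,
        columns=["category", "threshold", "precision", "recall", "n_assigned", "n_correct"],
    )
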