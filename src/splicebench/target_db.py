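"""Spliced-peptide target-database generation: the AP and MBS workflows.

Both workflows start from de novo candidate tables (top-k candidates per MS2
spectrum with an Average Local Confidence score, ALC, and per-residue local
confidence scores, LCS) and keep candidates that the splice mapper can explain
as spliced peptides:

* **AP**: drop candidates at or below an ALC cutoff derived from the ALC
  distribution of doubly-confirmed non-spliced identifications; per spectrum,
  discard everything if any surviving candidate is non-spliced, otherwise keep
  the single highest-ALC cis candidate, else the single highest-ALC trans
  candidate.  Retained candidates are concatenated into in-silico proteins.
* **MBS**: keep every candidate whose minimum per-residue LCS reaches 80 and
  that maps as cis-spliced (intervening <= 25) without a non-spliced
  explanation; retained candidates become one database entry each.

The resulting target database is the reference proteome plus the retained
candidate entries (``SPLICED_`` accession prefix) and is what the final
database search engine runs against.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .ground_truth import GroundTruthBundle
from .proteome import Proteome, ProteinEntry, SubstringIndex
from .splice_mapper import CIS, NONSPLICED, TRANS, MapperParams, categorize

SPLICED_TAG = "SPLICED_"
AP = "AP"
MBS = "MBS"


@dataclasses.dataclass(frozen=True)
class DeNovoCandidate:
    """One de novo sequence proposal for one spectrum."""

    spectrum_id: str
    rank: int
    sequence: str
    alc: float
    lcs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.lcs) != len(self.sequence):
            raise ValueError(
                f"{self.spectrum_id} rank {self.rank}: LCS length "
                f"{len(self.lcs)} != sequence length {len(self.sequence)}"
            )
        if abs(self.alc - float(np.mean(self.lcs))) > 0.51:
            raise ValueError(
                f"{self.spectrum_id} rank {self.rank}: ALC {self.alc} is not the "
                f"mean of the LCS values ({np.mean(self.lcs):.2f})"
            )

    @property
    def min_lcs(self) -> float:
        return min(self.lcs)


@dataclasses.dataclass(frozen=True)
class RetainedCandidate:
    candidate: DeNovoCandidate
    category: str  # CIS or TRANS


@dataclasses.dataclass
class TargetDatabase:
    """Reference proteome plus retained spliced-peptide candidate entries."""

    reference: Proteome
    spliced_entries: list[ProteinEntry]
    provenance: dict[str, RetainedCandidate]  # spectrum_id -> retained candidate
    mode: str = AP

    def full_proteome(self) -> Proteome:
        return Proteome(
            list(self.reference.entries) + list(self.spliced_entries),
            il_collapsed=self.reference.il_collapsed,
        )

    def candidate_sequences(self) -> list[str]:
        """Unique retained candidate sequences, first-retention order."""
        seen: dict[str, None] = {}
        for rc in self.provenance.values():
            seen.setdefault(rc.candidate.sequence, None)
        return list(seen)


@dataclasses.dataclass(frozen=True)
class TargetDbFeatures:
    """Figure-of-merit counts of a target database against a ground truth."""

    n_candidates: int
    n_true_candidates: int
    n_true_total: int

    @property
    def precision_potential(self) -> float:
        return self.n_true_candidates / self.n_candidates if self.n_candidates else 0.0

    @property
    def recall_potential(self) -> float:
        return self.n_true_candidates / self.n_true_total if self.n_true_total else 0.0


def group_by_spectrum(
    candidates: Iterable[DeNovoCandidate],
) -> dict[str, list[DeNovoCandidate]]:
    """Candidates per spectrum, ordered by rank."""
    groups: dict[str, list[DeNovoCandidate]] = {}
    for c in candidates:
        groups.setdefault(c.spectrum_id, []).append(c)
    for sid in groups:
        groups[sid].sort(key=lambda c: c.rank)
    return groups


def compute_alc_cutoff(
    candidates: Iterable[DeNovoCandidate],
    confident_nonspliced: Mapping[str, str],
    quantile: float = 0.05,
) -> float:
    """ALC cutoff from doubly-confirmed non-spliced identifications.

    The cutoff is the given lower quantile (lower order statistic) of the ALC
    values of rank-1 de novo candidates whose sequence equals the confident
    database-search assignment of the same spectrum.
    """
    if not 0 <= quantile <= 1:
        raise ValueError("quantile must be in [0, 1]")
    agreeing = [
        c.alc
        for c in candidates
        if c.rank == 1 and confident_nonspliced.get(c.spectrum_id) == c.sequence
    ]
    if not agreeing:
        raise ValueError(
            "no spectrum has an agreeing rank-1 de novo and confident database "
            "identification; supply a manual ALC cutoff"
        )
    return float(np.quantile(np.asarray(agreeing), quantile, method="lower"))


def ap_select_candidates(
    candidates: Iterable[DeNovoCandidate],
    index: SubstringIndex,
    alc_cutoff: float,
    params: MapperParams = MapperParams(),
    excluded_spectra: Optional[set[str]] = None,
) -> dict[str, RetainedCandidate]:
    """AP retention: at most one spliced candidate (cis or trans) per spectrum."""
    excluded = excluded_spectra or set()
    retained: dict[str, RetainedCandidate] = {}
    cat_cache: dict[str, str] = {}
    for sid, group in group_by_spectrum(candidates).items():
        if sid in excluded:
            continue
        survivors = [c for c in group if c.alc > alc_cutoff]
        if not survivors:
            continue
        by_cat: dict[str, list[DeNovoCandidate]] = {}
        for c in survivors:
            if c.sequence not in cat_cache:
                cat_cache[c.sequence] = categorize(c.sequence, index, params)
            by_cat.setdefault(cat_cache[c.sequence], []).append(c)
        if NONSPLICED in by_cat:
            continue  # potential non-spliced peptide: discard the spectrum
        for cat in (CIS, TRANS):
            if cat in by_cat:
                best = max(by_cat[cat], key=lambda c: (c.alc, -c.rank))
                retained[sid] = RetainedCandidate(best, cat)
                break
    return retained


def mbs_select_candidates(
    candidates: Iterable[DeNovoCandidate],
    index: SubstringIndex,
    lcs_min: float = 80.0,
    params: MapperParams = MapperParams(),
    excluded_spectra: Optional[set[str]] = None,
) -> dict[str, list[RetainedCandidate]]:
    """MBS retention: every clean cis candidate (min LCS >= lcs_min) survives."""
    excluded = excluded_spectra or set()
    retained: dict[str, list[RetainedCandidate]] = {}
    cat_cache: dict[str, str] = {}
    for sid, group in group_by_spectrum(candidates).items():
        if sid in excluded:
            continue
        for c in group:
            if c.min_lcs < lcs_min:
                continue
            if c.sequence not in cat_cache:
                cat_cache[c.sequence] = categorize(c.sequence, index, params)
            if cat_cache[c.sequence] == CIS:
                retained.setdefault(sid, []).append(RetainedCandidate(c, CIS))
    return retained


def build_target_db(
    retained: Mapping[str, RetainedCandidate] | Mapping[str, Sequence[RetainedCandidate]],
    reference: Proteome,
    mode: str = AP,
    chunk_size: int = 25,
) -> TargetDatabase:
    """Append retained candidates to the reference proteome.

    AP mode concatenates ``chunk_size`` unique candidate sequences per
    in-silico protein entry; MBS mode writes one entry per unique candidate.
    Input order (spectrum order of retention) is preserved.
    """
    if mode not in (AP, MBS):
        raise ValueError("mode must be 'AP' or 'MBS'")
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    provenance: dict[str, RetainedCandidate] = {}
    ordered_unique: dict[str, None] = {}
    for sid, val in retained.items():
        rcs = [val] if isinstance(val, RetainedCandidate) else list(val)
        for rc in rcs:
            if reference.il_collapsed and "I" in rc.candidate.sequence:
                raise ValueError(
                    f"candidate {rc.candidate.sequence!r} is not I/L-collapsed"
                )
            provenance.setdefault(sid, rc)
            ordered_unique.setdefault(rc.candidate.sequence, None)
    sequences = list(ordered_unique)
    entries: list[ProteinEntry] = []
    if mode == AP:
        for k in range(0, len(sequences), chunk_size):
            chunk = sequences[k : k + chunk_size]
            entries.append(
                ProteinEntry(f"{SPLICED_TAG}AP_{k // chunk_size + 1}", "".join(chunk))
            )
    else:
        for k, seq in enumerate(sequences, start=1):
            entries.append(ProteinEntry(f"{SPLICED_TAG}MBS_{k}", seq))
    return TargetDatabase(reference, entries, provenance, mode)


def target_db_features(
    db: TargetDatabase, truth: GroundTruthBundle
) -> TargetDbFeatures:
    """Candidate counts and precision/recall potential against the ground truth."""
    candidates = set(db.candidate_sequences())
    true_cis = {p for p, cat in truth.labels.items() if cat == CIS}
    return TargetDbFeatures(
        n_candidates=len(candidates),
        n_true_candidates=len(candidates & true_cis),
        n_true_total=len(true_cis),
    )


# ---------------------------------------------------------------------------
# de novo candidate table I/O
# ---------------------------------------------------------------------------


def write_denovo_table(candidates: Sequence[DeNovoCandidate], path) -> None:
    """Delimited table: spectrum_id, rank, sequence, alc, lcs (semicolon-joined)."""
    pd.DataFrame(
        [
            (c.spectrum_id, c.rank, c.sequence, round(c.alc, 2), ";".join(f"{v:.1f}" for v in c.lcs))
            for c in candidates
        ],
        columns=["spectrum_id", "rank", "sequence", "alc", "lcs"],
    ).to_csv(path, sep="\t", index=False)


def read_denovo_table(path) -> list[DeNovoCandidate]:
    df = pd.read_csv(path, sep="\t", dtype={"spectrum_id": str})
    out = []
    for row in df.itertuples(index=False):
        lcs = tuple(float(x) for x in str(row.lcs).split(";"))
        out.append(
            DeNovoCandidate(str(row.spectrum_id), int(row.rank), row.sequence, float(row.alc), lcs)
        )
    return out
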