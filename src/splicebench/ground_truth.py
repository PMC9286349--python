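"""Constructed ground-truth reference databases for benchmarking.

Real HLA-I peptides are (almost all) plain substrings of the proteome.  To
measure how well a search strategy identifies cis-spliced peptides one needs a
database in which the true category of every test peptide is *known*.  The
builder takes a proteome and a list of target peptides and rewrites the
database so that each target is identifiable only as its assigned category:

* every natural occurrence of every target is *elided* (replaced by random
  residues of the same length),
* one third of the targets is re-planted whole at a protein terminus
  (non-spliced), one third as ``reactant1 + random intervening + reactant2``
  at one terminus (cis-spliced), and one third split across the termini of two
  distinct proteins (*trapping* peptides: identifiable at best as
  trans-spliced, i.e. unidentifiable to a cis-only method),
* after every plant the builder verifies that no target drifted to a better
  category than intended, rolling the offending plant back and re-sampling its
  host/terminus/split/intervening sequence when it did.

The resulting bundle carries the constructed database, the intended label of
every target, the planting records and a verification report.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .proteome import (
    COLLAPSED_AA,
    Proteome,
    ProteinEntry,
    build_index,
    collapse_il,
    collapse_peptide,
)
from .splice_mapper import (
    CIS,
    NONE,
    NONSPLICED,
    TRANS,
    MapperParams,
    categorize,
)

TRAPPING = "TRAPPING"
INTENT_CATEGORIES = (NONSPLICED, CIS, TRAPPING)


@dataclasses.dataclass(frozen=True)
class GroundTruthParams:
    """Knobs of the constructed-database builder.

    max_intervening: longest intervening sequence of a planted cis target and
        of the verification mapper (residues, default 25).
    seed: all randomness (partition, elision, plants) derives from it; a fixed
        seed makes the output byte-reproducible.
    category_weights: proportions of non-spliced / cis / trapping targets.
    max_retries: per-target budget for plant re-sampling and elision redraws.
    """

    max_intervening: int = 25
    seed: int = 0
    category_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    max_retries: int = 100

    def __post_init__(self) -> None:
        if abs(sum(self.category_weights) - 1.0) > 1e-9:
            raise ValueError("category_weights must sum to 1")
        if self.max_retries < 1:
            raise ValueError("max_retries must be >= 1")

    def mapper_params(self) -> MapperParams:
        return MapperParams(max_intervening=self.max_intervening)


@dataclasses.dataclass(frozen=True)
class PlantRecord:
    """How one target was inserted into the constructed database."""

    peptide: str
    intended_category: str
    host_accessions: tuple[str, ...]
    termini: tuple[str, ...]  # 'C' or 'N' per host
    split_point: Optional[int] = None
    intervening_seq: Optional[str] = None


@dataclasses.dataclass
class VerificationRow:
    peptide: str
    intended: str
    observed: str
    ok: bool


@dataclasses.dataclass
class VerificationReport:
    rows: list[VerificationRow]

    @property
    def n_mismatches(self) -> int:
        return sum(not r.ok for r in self.rows)

    @property
    def ok(self) -> bool:
        return self.n_mismatches == 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.peptide, r.intended, r.observed, r.ok) for r in self.rows],
            columns=["peptide", "intended", "observed", "ok"],
        )


@dataclasses.dataclass
class GroundTruthBundle:
    constructed_db: Proteome
    labels: dict[str, str]  # peptide -> intended category
    plants: list[PlantRecord]
    verification_report: VerificationReport


# ---------------------------------------------------------------------------
# primitive scans on raw sequence lists (used during mutation, before the
# final proteome/index exist)
# ---------------------------------------------------------------------------


def _contains_any(seqs: Sequence[str], query: str) -> bool:
    return any(query in s for s in seqs)


def _partner_near(seq: str, a_start: int, a_end: int, partner: str, maxiv: int) -> bool:
    """Partner occurrence with 0 <= gap <= maxiv on either side of the anchor."""
    plen = len(partner)
    hi = min(a_end + maxiv, len(seq) - plen)
    if hi >= a_end and seq.find(partner, a_end, hi + plen) != -1:
        return True
    hi = a_start - plen
    lo = max(a_start - maxiv - plen, 0)
    if hi >= lo and seq.find(partner, lo, hi + plen) != -1:
        return True
    return False


def _cis_site_in_protein(seq: str, peptide: str, maxiv: int) -> Optional[tuple[int, int]]:
    """Span of the longer reactant of some cis explanation of *peptide* in *seq*."""
    n = len(peptide)
    for s in range(1, n):
        left, right = peptide[:s], peptide[s:]
        anchor, partner = (left, right) if len(left) >= len(right) else (right, left)
        pos = seq.find(anchor)
        while pos != -1:
            if _partner_near(seq, pos, pos + len(anchor), partner, maxiv):
                return (pos, pos + len(anchor))
            pos = seq.find(anchor, pos + 1)
    return None


def _cis_in_protein(seq: str, peptide: str, maxiv: int) -> bool:
    return _cis_site_in_protein(seq, peptide, maxiv) is not None


def _random_residues(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(COLLAPSED_AA), size=n))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def partition_targets(
    peptides: Sequence[str], params: GroundTruthParams
) -> tuple[list[str], list[str], list[str]]:
    """Seeded random partition into (non-spliced, cis, trapping) target lists."""
    peps = [collapse_peptide(p) for p in peptides]
    if len(set(peps)) != len(peps):
        dup = sorted({p for p in peps if peps.count(p) > 1})
        raise ValueError(f"duplicate peptides after I/L collapse: {dup}")
    rng = np.random.default_rng(params.seed)
    order = rng.permutation(len(peps))
    shuffled = [peps[i] for i in order]
    n = len(peps)
    base = [int(np.floor(w * n)) for w in params.category_weights]
    # hand remainders to the largest fractional parts, ties by category order
    rema = [(w * n - b, -i) for i, (w, b) in enumerate(zip(params.category_weights, base))]
    for _, negi in sorted(rema, reverse=True)[: n - sum(base)]:
        base[-negi] += 1
    b = base[0] + base[1]
    return shuffled[: base[0]], shuffled[base[0] : b], shuffled[b:]


def elide_targets(
    proteome: Proteome, peptides: Sequence[str], params: GroundTruthParams
) -> Proteome:
    """Remove every occurrence of every target by length-preserving random replacement."""
    if not proteome.il_collapsed:
        raise ValueError("elide_targets requires an I/L-collapsed proteome")
    peps = [collapse_peptide(p) for p in peptides]
    rng = np.random.default_rng(params.seed)
    seqs = [e.sequence for e in proteome]
    _elide_in_place(seqs, peps, rng, params.max_retries)
    entries = [
        ProteinEntry(acc, seq) for acc, seq in zip(proteome.accessions, seqs)
    ]
    return Proteome(entries, il_collapsed=True)


def _elide_in_place(
    seqs: list[str],
    targets: Sequence[str],
    rng: np.random.Generator,
    max_retries: int,
    only: Optional[Sequence[int]] = None,
) -> None:
    """Replace target occurrences in ``seqs`` (in place), redrawing on re-creation."""
    indices = range(len(seqs)) if only is None else only
    for i in indices:
        budget = max_retries + sum(seqs[i].count(t) for t in targets)
        while True:
            hit = _first_target_hit(seqs[i], targets)
            if hit is None:
                break
            t, pos = hit
            if budget <= 0:
                raise RuntimeError(
                    f"elision retry budget exhausted while removing {t!r}"
                )
            budget -= 1
            seqs[i] = seqs[i][:pos] + _random_residues(rng, len(t)) + seqs[i][pos + len(t) :]


def _first_target_hit(seq: str, targets: Sequence[str]) -> Optional[tuple[str, int]]:
    best: Optional[tuple[str, int]] = None
    for t in targets:
        pos = seq.find(t)
        if pos != -1 and (best is None or pos < best[1]):
            best = (t, pos)
    return best


def plant_target(
    proteome: Proteome,
    peptide: str,
    category: str,
    params: GroundTruthParams,
    rng: Optional[np.random.Generator] = None,
) -> tuple[Proteome, PlantRecord]:
    """Append one target to the proteome according to its intended category.

    Standalone operation: no verification is performed here (that is
    :func:`build_ground_truth`'s job).
    """
    if category not in INTENT_CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    if category == TRAPPING and len(proteome) < 2:
        raise ValueError("TRAPPING plants require at least 2 proteins")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    seqs = [e.sequence for e in proteome]
    record, _ = _plant_in_place(seqs, proteome.accessions, peptide, category, params, rng)
    entries = [ProteinEntry(a, s) for a, s in zip(proteome.accessions, seqs)]
    return Proteome(entries, il_collapsed=proteome.il_collapsed), record


def _append(seqs: list[str], i: int, block: str, terminus: str) -> None:
    seqs[i] = seqs[i] + block if terminus == "C" else block + seqs[i]


def _plant_in_place(
    seqs: list[str],
    accessions: Sequence[str],
    peptide: str,
    category: str,
    params: GroundTruthParams,
    rng: np.random.Generator,
) -> tuple[PlantRecord, list[tuple[int, str]]]:
    """Apply one plant; return its record and undo list of (index, old_sequence)."""
    n_prot = len(seqs)
    if category == NONSPLICED:
        i = int(rng.integers(n_prot))
        term = "C" if rng.random() < 0.5 else "N"
        undo = [(i, seqs[i])]
        _append(seqs, i, peptide, term)
        return PlantRecord(peptide, category, (accessions[i],), (term,)), undo
    if len(peptide) < 2:
        raise ValueError("spliced plants need peptides of length >= 2")
    split = int(rng.integers(1, len(peptide)))
    r1, r2 = peptide[:split], peptide[split:]
    if category == CIS:
        ivlen = int(rng.integers(1, params.max_intervening + 1))
        iv = _random_residues(rng, ivlen)
        i = int(rng.integers(n_prot))
        term = "C" if rng.random() < 0.5 else "N"
        undo = [(i, seqs[i])]
        _append(seqs, i, r1 + iv + r2, term)
        return (
            PlantRecord(peptide, category, (accessions[i],), (term,), split, iv),
            undo,
        )
    # TRAPPING: reactants on two distinct proteins
    i, j = (int(k) for k in rng.choice(n_prot, size=2, replace=False))
    ti = "C" if rng.random() < 0.5 else "N"
    tj = "C" if rng.random() < 0.5 else "N"
    undo = [(i, seqs[i]), (j, seqs[j])]
    _append(seqs, i, r1, ti)
    _append(seqs, j, r2, tj)
    return (
        PlantRecord(peptide, category, (accessions[i], accessions[j]), (ti, tj), split),
        undo,
    )


def build_ground_truth(
    proteome: Proteome, peptides: Sequence[str], params: GroundTruthParams
) -> GroundTruthBundle:
    """collapse -> partition -> elide -> plant-with-verification pipeline."""
    if not proteome.il_collapsed:
        proteome = collapse_il(proteome)
    peps = [collapse_peptide(p) for p in peptides]
    rng = np.random.default_rng(params.seed)
    ns_targets, cis_targets, trap_targets = partition_targets(peps, params)
    intent = {p: NONSPLICED for p in ns_targets}
    intent.update({p: CIS for p in cis_targets})
    intent.update({p: TRAPPING for p in trap_targets})
    _repair_nested_intents(intent, peps)
    trap_targets = [p for p in peps if intent[p] == TRAPPING]

    seqs = [e.sequence for e in proteome]
    accessions = proteome.accessions
    _elide_in_place(seqs, peps, rng, params.max_retries)
    _scrub_natural_cis(seqs, trap_targets, peps, params, rng)

    maxiv = params.max_intervening
    plant_order = [peps[i] for i in rng.permutation(len(peps))] if peps else []
    plants: list[PlantRecord] = []
    planted: set[str] = set()
    for pep in plant_order:
        cat = intent[pep]
        record = None
        for _attempt in range(params.max_retries):
            rec, undo = _plant_in_place(seqs, accessions, pep, cat, params, rng)
            touched = sorted({i for i, _ in undo})
            if _plant_is_consistent(seqs, pep, cat, touched, intent, planted, maxiv):
                record = rec
                break
            for i, old in undo:
                seqs[i] = old
        if record is None:
            raise RuntimeError(
                f"could not plant {pep!r} as {cat} within {params.max_retries} retries"
            )
        plants.append(record)
        planted.add(pep)

    entries = [ProteinEntry(a, s) for a, s in zip(accessions, seqs)]
    constructed = Proteome(entries, il_collapsed=True)
    labels = {rec.peptide: rec.intended_category for rec in plants}
    bundle = GroundTruthBundle(constructed, labels, plants, VerificationReport([]))
    bundle.verification_report = verify_categories(bundle, params.mapper_params())
    if not bundle.verification_report.ok:
        bad = [r for r in bundle.verification_report.rows if not r.ok]
        raise RuntimeError(f"post-build verification failed: {bad}")
    return bundle


def _repair_nested_intents(intent: dict[str, str], peps: Sequence[str]) -> None:
    """Make category assignments consistent for nested targets.

    Immunopeptidomes contain length variants, so one target may be a substring
    of another.  Planting a NONSPLICED container then necessarily implants the
    containee whole, and a CIS container's reactant block necessarily hands a
    cut containee a cis explanation — no plant re-sampling can repair either.
    Constraints: a NONSPLICED container forces its containees NONSPLICED; a
    CIS container forbids TRAPPING containees.  Violations are repaired by
    swapping categories with a donor target that sits in no containment pair,
    keeping the per-category counts unchanged.
    """
    pairs = [
        (c, e) for c in peps for e in peps if c != e and e in c
    ]  # (container, containee)
    if not pairs:
        return
    involved = {p for ce in pairs for p in ce}
    for _ in range(10 * len(pairs) + 10):
        violation = None
        for c, e in pairs:
            if intent[c] == NONSPLICED and intent[e] != NONSPLICED:
                violation = (e, NONSPLICED)
                break
            if intent[c] == CIS and intent[e] == TRAPPING:
                violation = (e, CIS)
                break
        if violation is None:
            return
        e, need = violation
        donor = next(
            (d for d in peps if d not in involved and intent[d] == need), None
        )
        if donor is None:
            raise RuntimeError(
                f"cannot repair nested-target categories: no free donor of {need} "
                f"for {e!r}"
            )
        intent[donor], intent[e] = intent[e], need
    raise RuntimeError("nested-target category repair did not converge")


def _scrub_natural_cis(
    seqs: list[str],
    trap_targets: Sequence[str],
    all_targets: Sequence[str],
    params: GroundTruthParams,
    rng: np.random.Generator,
) -> None:
    """Destroy pre-existing cis explanations of trapping targets.

    Elision only removes whole-target substrings; a trapping target may still
    have a coincidental cis explanation in the natural text, which no plant
    re-sampling could repair.  Replace the longer reactant occurrence of each
    offending explanation with random residues (length preserving), re-eliding
    as needed, until a full pass is clean.
    """
    for _ in range(params.max_retries):
        dirty = False
        for t in trap_targets:
            for i, seq in enumerate(seqs):
                site = _cis_site_in_protein(seq, t, params.max_intervening)
                while site is not None:
                    dirty = True
                    a, b = site
                    seqs[i] = seqs[i][:a] + _random_residues(rng, b - a) + seqs[i][b:]
                    _elide_in_place(seqs, all_targets, rng, params.max_retries, only=[i])
                    seq = seqs[i]
                    site = _cis_site_in_protein(seq, t, params.max_intervening)
        if not dirty:
            return
    raise RuntimeError("could not scrub pre-existing cis explanations of trapping targets")


def _plant_is_consistent(
    seqs: list[str],
    planted_pep: str,
    planted_cat: str,
    touched: Sequence[int],
    intent: dict[str, str],
    already_planted: set[str],
    maxiv: int,
) -> bool:
    """Check the just-applied plant against every target's intended category.

    Appending text can only *promote* a peptide in the hierarchy, and any new
    explanation must involve a touched protein, so checks are local: substring
    and cis probes in the modified proteins for all cis/trapping targets, plus
    global checks for the peptide just planted.
    """
    if planted_cat in (CIS, TRAPPING):
        if _contains_any(seqs, planted_pep):
            return False
    if planted_cat == TRAPPING:
        if any(_cis_in_protein(s, planted_pep, maxiv) for s in seqs):
            return False
    for pep, cat in intent.items():
        if pep == planted_pep or cat == NONSPLICED:
            continue
        for i in touched:
            if pep in seqs[i]:
                return False
            if cat == TRAPPING and _cis_in_protein(seqs[i], pep, maxiv):
                return False
    return True


def verify_categories(
    bundle: GroundTruthBundle, params: MapperParams = MapperParams()
) -> VerificationReport:
    """Re-classify every labelled peptide against the constructed database."""
    rows: list[VerificationRow] = []
    if not bundle.labels:
        return VerificationReport(rows)
    index = build_index(bundle.constructed_db)
    for rec in bundle.plants:
        pep = rec.peptide
        observed = categorize(pep, index, params)
        intended = bundle.labels[pep]
        if intended == TRAPPING:
            ok = observed in (TRANS, NONE)
        else:
            ok = observed == intended
        rows.append(VerificationRow(pep, intended, observed, ok))
    return VerificationReport(rows)


def write_labels_tsv(bundle: GroundTruthBundle, path) -> None:
    """Labels table: peptide, intended category, host(s), split point, intervening."""
    rows = []
    for rec in bundle.plants:
        rows.append(
            (
                rec.peptide,
                rec.intended_category,
                ";".join(rec.host_accessions),
                ";".join(rec.termini),
                "" if rec.split_point is None else rec.split_point,
                rec.intervening_seq or "",
            )
        )
    pd.DataFrame(
        rows,
        columns=[
            "peptide",
            "intended_category",
            "host_accessions",
            "termini",
            "split_point",
            "intervening_seq",
        ],
    ).to_csv(path, sep="\t", index=False)
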