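"""A pluggable stand-in database search engine and target-decoy FDR estimation.

Commercial engines (Mascot, PEAKS DB) are the identification step of the AP
and MBS workflows in the original studies; the benchmark machinery itself only
needs *a* monotone PSM score.  The stand-in scores a peptide against a
spectrum by counting matched b/y fragment peaks and converting the count into
the upper tail of a hypergeometric null (random peaks hitting fragment-sized
m/z bins), reported as -log10 of that tail probability.

The search digests the target database (plus its reversed-sequence decoy,
searched concatenated) into unspecific 8-15-mer substrings, keeps candidates
whose mass matches the precursor within a ppm tolerance, and retains the best
scoring candidate per spectrum.  The FDR at a score threshold is the classic
estimate ``100 * 2D / (T + D)`` from target and decoy counts.

Externally produced PSM tables can be fed to the same estimator/benchmark code
through :func:`read_psm_tsv`, so real engine output is benchmarked identically.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf
from pyteomics.mass import std_aa_mass
from scipy.stats import hypergeom

from .proteome import CANONICAL_AA, Proteome, build_index, make_decoy
from .splice_mapper import NONE, MapperParams, categorize

PROTON = 1.00727646677
WATER = 18.0105646837

#: monoisotopic residue masses for the 20 canonical amino acids
AA_MONO = {aa: std_aa_mass[aa] for aa in CANONICAL_AA}

_MASS_LUT = np.zeros(128)
for _aa, _m in AA_MONO.items():
    _MASS_LUT[ord(_aa)] = _m

_SCORE_CAP = 400.0  # finite stand-in for a vanishing tail probability


def _residue_masses(seq: str) -> np.ndarray:
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    masses = _MASS_LUT[codes]
    if np.any(masses == 0.0):
        bad = sorted(set(seq) - set(AA_MONO))
        raise ValueError(f"unknown residue(s) {bad} in {seq!r}")
    return masses


def peptide_mass(seq: str) -> float:
    """Neutral monoisotopic peptide mass."""
    return float(_residue_masses(seq).sum()) + WATER


def _fragments_raw(peptide: str, charge: int = 1) -> np.ndarray:
    """b- then y-series m/z, unsorted (scoring does not need order)."""
    if len(peptide) < 2:
        raise ValueError("need a peptide of length >= 2")
    if charge < 1:
        raise ValueError("fragment charge must be >= 1")
    masses = _residue_masses(peptide)
    prefix = np.cumsum(masses)[:-1]  # b fragment neutral residue sums
    suffix = np.cumsum(masses[::-1])[:-1]
    b = (prefix + charge * PROTON) / charge
    y = (suffix + WATER + charge * PROTON) / charge
    return np.concatenate([b, y])


def theoretical_fragments(peptide: str, charge: int = 1) -> np.ndarray:
    """Sorted m/z of all b- and y-ions at the given fragment charge (default 1+)."""
    return np.sort(_fragments_raw(peptide, charge))


@dataclasses.dataclass
class Spectrum:
    """One MS2 spectrum: precursor m/z + charge and a sorted peak list."""

    spectrum_id: str
    precursor_mz: float
    charge: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        if not 1 <= self.charge <= 4:
            raise ValueError(f"charge must be in 1..4, got {self.charge}")
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if len(self.mz) and np.any(self.intensity <= 0):
            raise ValueError("intensities must be positive")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))

    def precursor_mass(self) -> float:
        """Neutral mass implied by precursor m/z and charge."""
        return self.precursor_mz * self.charge - self.charge * PROTON


@dataclasses.dataclass(frozen=True)
class SearchParams:
    precursor_tol_ppm: float = 5.0
    fragment_tol_da: float = 0.02
    peptide_len_range: tuple[int, int] = (8, 15)

    def __post_init__(self) -> None:
        if self.precursor_tol_ppm <= 0 or self.fragment_tol_da <= 0:
            raise ValueError("tolerances must be positive")


@dataclasses.dataclass(frozen=True)
class PSM:
    spectrum_id: str
    peptide: str
    score: float
    is_decoy: bool
    assigned_category: Optional[str] = None
    accession: Optional[str] = None


@dataclasses.dataclass(frozen=True)
class FdrPoint:
    threshold: float
    n_target: int
    n_decoy: int
    fdr_percent: float
    undefined: bool = False  # True when T + D == 0


@dataclasses.dataclass(frozen=True)
class ThresholdPick:
    threshold: float
    satisfied: bool


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def _pad_peaks(peak_mz: np.ndarray) -> np.ndarray:
    """Sorted peak m/z with sentinels, so neighbour lookup needs no clipping."""
    return np.concatenate([[-1e12], peak_mz, [1e12]])


def _match_stats(
    peak_mz: np.ndarray, fragments: np.ndarray, tol: float
) -> tuple[int, float]:
    """(number of matched theoretical ions, summed |m/z error| of matches)."""
    if len(peak_mz) == 0:
        return 0, 0.0
    return _match_stats_padded(_pad_peaks(peak_mz), fragments, tol)


def _match_stats_padded(
    padded_mz: np.ndarray, fragments: np.ndarray, tol: float
) -> tuple[int, float]:
    idx = padded_mz.searchsorted(fragments)
    dist = np.minimum(fragments - padded_mz[idx - 1], padded_mz[idx] - fragments)
    matched = dist <= tol
    m = int(np.count_nonzero(matched))
    return m, (float(dist[matched].sum()) if m else 0.0)


_logsf_cache: dict[tuple[int, int, int, int], float] = {}


def _tail_score(m: int, n_bins: int, n_peaks: int, n_frag: int) -> float:
    """-log10 P(X >= m), X ~ Hypergeom(n_bins, n_peaks, n_frag); memoized."""
    key = (m, n_bins, n_peaks, n_frag)
    score = _logsf_cache.get(key)
    if score is None:
        logsf = hypergeom.logsf(m - 1, n_bins, n_peaks, n_frag)
        score = -logsf / math.log(10)
        if not math.isfinite(score):
            score = _SCORE_CAP
        score = min(float(score), _SCORE_CAP)
        if len(_logsf_cache) > 500_000:
            _logsf_cache.clear()
        _logsf_cache[key] = score
    return score


def score_psm(
    spectrum: Spectrum, peptide: str, params: SearchParams = SearchParams()
) -> float:
    """-log10 hypergeometric tail probability of the shared-peak count."""
    score, _ = _score_with_error(spectrum, peptide, params)
    return score


def _spectrum_bins(spectrum: Spectrum, params: SearchParams) -> int:
    if len(spectrum.mz) == 0:
        return 1
    return int(round((spectrum.mz[-1] - spectrum.mz[0]) / (2 * params.fragment_tol_da)))


def _score_with_error(
    spectrum: Spectrum, peptide: str, params: SearchParams
) -> tuple[float, float]:
    if len(spectrum.mz) == 0:
        return 0.0, 0.0
    return _score_padded(
        _pad_peaks(spectrum.mz),
        len(spectrum.mz),
        _spectrum_bins(spectrum, params),
        peptide,
        params,
    )


def _score_padded(
    padded_mz: np.ndarray, n_peaks: int, span_bins: int, peptide: str, params: SearchParams
) -> tuple[float, float]:
    frags = _fragments_raw(peptide)
    m, err = _match_stats_padded(padded_mz, frags, params.fragment_tol_da)
    if m == 0:
        return 0.0, 0.0
    n_frag = len(frags)
    n_bins = max(span_bins, n_peaks, n_frag, 1)
    return _tail_score(m, n_bins, n_peaks, n_frag), err


# ---------------------------------------------------------------------------
# candidate generation: unspecific digest with a precomputed mass index
# ---------------------------------------------------------------------------


class _MassIndex:
    """All substrings with admissible length of all entries, sorted by mass."""

    def __init__(self, entries: Sequence[tuple[str, str, bool]], len_range: tuple[int, int]):
        # entries: (accession, sequence, is_decoy) in search order
        self.entries = list(entries)
        lmin, lmax = len_range
        masses, entry_idx, starts, lengths = [], [], [], []
        for ei, (_acc, seq, _dec) in enumerate(self.entries):
            res = _residue_masses(seq)
            cum = np.concatenate([[0.0], np.cumsum(res)])
            for L in range(lmin, min(lmax, len(seq)) + 1):
                m = cum[L:] - cum[:-L] + WATER
                masses.append(m)
                starts.append(np.arange(len(m), dtype=np.int32))
                entry_idx.append(np.full(len(m), ei, dtype=np.int32))
                lengths.append(np.full(len(m), L, dtype=np.int16))
        if masses:
            mass_all = np.concatenate(masses)
            order = np.argsort(mass_all, kind="stable")
            self.mass = mass_all[order]
            self.entry_idx = np.concatenate(entry_idx)[order]
            self.start = np.concatenate(starts)[order]
            self.length = np.concatenate(lengths)[order]
        else:
            self.mass = np.empty(0)
            self.entry_idx = np.empty(0, dtype=np.int32)
            self.start = np.empty(0, dtype=np.int32)
            self.length = np.empty(0, dtype=np.int16)

    def candidates(self, neutral_mass: float, tol_ppm: float):
        """Yield (sequence, accession, is_decoy, rank) for mass-matching substrings."""
        tol = neutral_mass * tol_ppm * 1e-6
        lo = np.searchsorted(self.mass, neutral_mass - tol, side="left")
        hi = np.searchsorted(self.mass, neutral_mass + tol, side="right")
        for k in range(lo, hi):
            ei = int(self.entry_idx[k])
            s = int(self.start[k])
            L = int(self.length[k])
            acc, seq, dec = self.entries[ei]
            yield seq[s : s + L], acc, dec, (ei, s)


def search(
    spectra: Sequence[Spectrum],
    db: Union[Proteome, "TargetDatabaseLike"],
    params: SearchParams = SearchParams(),
    mapper_params: MapperParams = MapperParams(),
) -> list[PSM]:
    """Concatenated target+decoy search; best PSM per spectrum.

    ``db`` is either a plain :class:`Proteome` or a target database exposing
    ``full_proteome()`` and ``reference`` (see :mod:`splicebench.target_db`).
    The decoy is generated here by whole-protein reversal.  Target winners are
    assigned a splice category against the *reference* part of the database.

    Ties are broken by (smaller summed |m/z error| of matched peaks, target
    over decoy, lexicographic peptide, first accession in entry order).
    """
    if hasattr(db, "full_proteome"):
        target = db.full_proteome()
        reference = db.reference
    else:
        target = db
        reference = db
    if len(target) == 0:
        raise ValueError("empty database")
    decoy = make_decoy(target)
    entries = [(e.accession, e.sequence, False) for e in target]
    entries += [(e.accession, e.sequence, True) for e in decoy]
    index = _MassIndex(entries, params.peptide_len_range)
    ref_index = build_index(reference)
    category_cache: dict[str, Optional[str]] = {}

    psms: list[PSM] = []
    for spec in spectra:
        padded = _pad_peaks(spec.mz) if len(spec.mz) else None
        n_peaks = len(spec.mz)
        span_bins = _spectrum_bins(spec, params)
        best = None  # (score, err, is_decoy, peptide, rank, accession)
        seen: set[tuple[str, bool]] = set()
        for pep, acc, dec, rank in index.candidates(
            spec.precursor_mass(), params.precursor_tol_ppm
        ):
            key = (pep, dec)
            if key in seen:
                continue
            seen.add(key)
            if padded is None:
                score, err = 0.0, 0.0
            else:
                score, err = _score_padded(padded, n_peaks, span_bins, pep, params)
            cand = (-score, err, dec, pep, rank, acc)
            if best is None or cand < best:
                best = cand
        if best is None:
            continue
        neg_score, _err, dec, pep, _rank, acc = best
        category = None
        if not dec:
            if pep not in category_cache:
                cat = categorize(pep, ref_index, mapper_params)
                category_cache[pep] = None if cat == NONE else cat
            category = category_cache[pep]
        psms.append(PSM(spec.spectrum_id, pep, -neg_score, dec, category, acc))
    return psms


# ---------------------------------------------------------------------------
# FDR estimation
# ---------------------------------------------------------------------------


def estimate_fdr(psms: Sequence[PSM], threshold: float) -> FdrPoint:
    """Target-decoy FDR at a score threshold: 100 * 2D / (T + D)."""
    t = sum(1 for p in psms if not p.is_decoy and p.score >= threshold)
    d = sum(1 for p in psms if p.is_decoy and p.score >= threshold)
    if t + d == 0:
        return FdrPoint(threshold, 0, 0, 0.0, undefined=True)
    return FdrPoint(threshold, t, d, 100.0 * 2 * d / (t + d))


def threshold_sweep(psms: Sequence[PSM], thresholds: Sequence[float]) -> list[FdrPoint]:
    """One FdrPoint per threshold (thresholds must be sorted ascending)."""
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    return [estimate_fdr(psms, th) for th in thresholds]


def pick_threshold_at_fdr(
    sweep: Sequence[FdrPoint], target_fdr_percent: float
) -> ThresholdPick:
    """Loosest threshold whose estimated FDR is at or below the target."""
    if not sweep:
        raise ValueError("empty sweep")
    ok = [pt for pt in sweep if pt.fdr_percent <= target_fdr_percent and not pt.undefined]
    if ok:
        return ThresholdPick(min(pt.threshold for pt in ok), True)
    strictest = max(pt.threshold for pt in sweep)
    warnings.warn(
        f"no threshold reaches {target_fdr_percent}% FDR; returning strictest "
        f"({strictest})"
    )
    return ThresholdPick(strictest, False)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_mgf(spectra: Sequence[Spectrum], path) -> None:
    """Write spectra as MGF; TITLE carries the spectrum id."""
    records = []
    for s in spectra:
        records.append(
            {
                "m/z array": s.mz,
                "intensity array": s.intensity,
                "params": {
                    "title": s.spectrum_id,
                    "pepmass": s.precursor_mz,
                    "charge": s.charge,
                },
            }
        )
    _mgf.write(records, str(path), file_mode="w")


def read_mzml(path) -> list[Spectrum]:
    """Read MS2 spectra from an mzML file (minimal, read-only).

    Supports the common binary encodings (32/64-bit floats, no compression
    or zlib).  The spectrum id attribute carries the spectrum_id; MS1
    spectra and spectra without a selected precursor ion are skipped.  A
    missing charge state defaults to 2.
    """
    import base64
    import zlib

    from lxml import etree

    ns = "{http://psi.hupo.org/ms/mzml}"

    def cv(elem, accession):
        for p in elem.iter(ns + "cvParam"):
            if p.get("accession") == accession:
                return p.get("value", "")
        return None

    def decode_array(bda):
        raw = base64.b64decode(bda.findtext(ns + "binary", "").strip())
        if cv(bda, "MS:1000574") is not None:  # zlib compression
            raw = zlib.decompress(raw)
        dtype = np.float32 if cv(bda, "MS:1000521") is not None else np.float64
        return np.frombuffer(raw, dtype=np.dtype(dtype).newbyteorder("<")).astype(float)

    out: list[Spectrum] = []
    for _event, spec in etree.iterparse(str(path), tag=ns + "spectrum"):
        try:
            ms_level = cv(spec, "MS:1000511")
            if ms_level is not None and int(ms_level) != 2:
                continue
            ions = spec.iter(ns + "selectedIon")
            ion = next(ions, None)
            if ion is None:
                continue
            mz_arr = inten_arr = None
            for bda in spec.iter(ns + "binaryDataArray"):
                if cv(bda, "MS:1000514") is not None:
                    mz_arr = decode_array(bda)
                elif cv(bda, "MS:1000515") is not None:
                    inten_arr = decode_array(bda)
            if mz_arr is None or inten_arr is None:
                continue
            charge = cv(ion, "MS:1000041")
            out.append(
                Spectrum(
                    spectrum_id=str(spec.get("id", f"index={spec.get('index')}")),
                    precursor_mz=float(cv(ion, "MS:1000744")),
                    charge=int(charge) if charge else 2,
                    mz=mz_arr,
                    intensity=inten_arr,
                )
            )
        finally:
            spec.clear()
    return out


def read_mgf(path) -> list[Spectrum]:
    out = []
    with _mgf.MGF(str(path)) as reader:
        for rec in reader:
            params = rec["params"]
            charge = int(params["charge"][0])
            pepmass = params["pepmass"]
            out.append(
                Spectrum(
                    spectrum_id=str(params["title"]),
                    precursor_mz=float(pepmass[0] if isinstance(pepmass, tuple) else pepmass),
                    charge=charge,
                    mz=rec["m/z array"],
                    intensity=rec["intensity array"],
                )
            )
    return out


def write_psm_tsv(psms: Sequence[PSM], path) -> None:
    pd.DataFrame(
        [
            (p.spectrum_id, p.peptide, p.score, p.is_decoy, p.assigned_category or "", p.accession or "")
            for p in psms
        ],
        columns=["spectrum_id", "peptide", "score", "is_decoy", "category", "accession"],
    ).to_csv(path, sep="\t", index=False)


def read_psm_tsv(path) -> list[PSM]:
    df = pd.read_csv(path, sep="\t", dtype={"spectrum_id": str}, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            PSM(
                spectrum_id=str(row.spectrum_id),
                peptide=row.peptide,
                score=float(row.score),
                is_decoy=bool(row.is_decoy) if not isinstance(row.is_decoy, str) else row.is_decoy == "True",
                assigned_category=row.category or None,
                accession=row.accession or None,
            )
        )
    return out
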