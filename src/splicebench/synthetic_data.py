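"""Seeded generators: proteomes, peptide sets, MS2 spectra, de novo tables.

The generators emulate the statistical structure the benchmark assumes about
an HLA class I immunopeptidomics experiment: a proteome, an immunopeptidome of
8-15-mer peptides drawn from it, one b/y-ion MS2 spectrum per peptide (with
detection dropout, m/z jitter and noise peaks), and per-spectrum top-k de novo
candidate lists whose error modes mimic de novo sequencing: residue
substitutions, adjacent swaps and isobaric replacements, with depressed local
confidence at the erroneous residues.

Everything is driven by numpy Generators spawned from one top-level seed, so a
fixed seed reproduces every byte of output.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from .engine_sim import AA_MONO, PROTON, Spectrum, peptide_mass, theoretical_fragments
from .ground_truth import (
    GroundTruthBundle,
    GroundTruthParams,
    TRAPPING,
    build_ground_truth,
)
from .proteome import COLLAPSED_AA, Proteome, ProteinEntry
from .splice_mapper import CIS, NONSPLICED
from .target_db import DeNovoCandidate


@dataclasses.dataclass(frozen=True)
class SpectrumModel:
    """Peak-level model of a simulated MS2 spectrum.

    fragment_detect_prob: probability each theoretical singly-charged b/y ion
        yields a peak.  noise_peaks_mean: Poisson mean of uniformly placed
        noise peaks.  Intensities are log-normal; signal sits about an order
        of magnitude above noise.  mz_jitter_sd: Gaussian m/z error (Da) on
        signal peaks.  charges/charge_probs: precursor charge distribution.
    """

    fragment_detect_prob: float = 0.85
    noise_peaks_mean: float = 20.0
    noise_mz_range: tuple[float, float] = (100.0, 1500.0)
    signal_lognorm: tuple[float, float] = (6.9, 0.6)  # (mu, sigma) of log intensity
    noise_lognorm: tuple[float, float] = (4.6, 0.8)
    mz_jitter_sd: float = 0.004
    charges: tuple[int, ...] = (1, 2, 3)
    charge_probs: tuple[float, ...] = (0.25, 0.6, 0.15)

    def __post_init__(self) -> None:
        if not 0 <= self.fragment_detect_prob <= 1:
            raise ValueError("fragment_detect_prob must be in [0, 1]")
        if self.mz_jitter_sd < 0:
            raise ValueError("mz_jitter_sd must be >= 0")


@dataclasses.dataclass(frozen=True)
class DeNovoErrorModel:
    """Error model of the simulated de novo sequencer.

    p_correct_rank1: probability the true sequence appears (as rank 1);
    substitution_kinds: weights over the three corruption operators;
    alc_signal / alc_error: normal (mean, sd) of per-residue local confidence
    at correct and erroneous residues; with lcs_error_localization the
    erroneous residues of a corrupted candidate get the depressed scores.
    spectrum_quality_sd spreads the signal mean per spectrum: real ALC
    distributions span tens of points because spectra differ in quality, and
    that spread is what puts a distribution-derived ALC cutoff well below the
    candidates of good spectra.
    """

    p_correct_rank1: float = 0.7
    # order: (single residue substitution, adjacent-pair swap, isobaric replacement).
    # Swaps and isobaric replacements dominate because de novo candidate lists are
    # precursor-mass-constrained: mass-preserving rearrangements are the typical
    # error mode, while plain substitutions shift the precursor mass.
    substitution_kinds: tuple[float, float, float] = (0.2, 0.4, 0.4)
    alc_signal: tuple[float, float] = (92.0, 4.0)
    alc_error: tuple[float, float] = (55.0, 12.0)
    spectrum_quality_sd: float = 6.0
    # De novo errors concentrate at peptide termini, where b1/y1-level fragment
    # evidence is usually absent; error positions are drawn with a geometric
    # decay inward from a random terminus (0 < p <= 1; smaller = flatter).
    terminal_error_bias: float = 0.45
    # A de novo engine only proposes sequences whose mass matches the measured
    # precursor; corrupted candidates violating this tolerance are re-drawn.
    # The bound is the instrument's precursor accuracy, shared with the search.
    max_candidate_ppm: float = 5.0
    # Corrupted candidates carry 1 + Poisson(n_extra_ops_mean) operators:
    # lower-rank candidates of real top-k lists are rarely one edit away.
    n_extra_ops_mean: float = 0.5
    lcs_error_localization: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.p_correct_rank1 <= 1:
            raise ValueError("p_correct_rank1 must be in [0, 1]")
        if min(self.substitution_kinds) < 0 or sum(self.substitution_kinds) <= 0:
            raise ValueError("substitution_kinds must be non-negative, not all zero")


def isobaric_replacements(tol_da: float = 0.02) -> list[tuple[str, str]]:
    """(source, replacement) pairs of near-isobaric residue blocks.

    Generated from the monoisotopic residue mass table over the I-free
    alphabet: single residues versus residue pairs within ``tol_da``
    (e.g. N<->GG, Q<->AG/GA), in both directions.
    """
    singles = {a: AA_MONO[a] for a in COLLAPSED_AA}
    out: list[tuple[str, str]] = []
    for a, ma in singles.items():
        for b1 in COLLAPSED_AA:
            for b2 in COLLAPSED_AA:
                if abs(ma - singles[b1] - singles[b2]) <= tol_da:
                    out.append((a, b1 + b2))
                    out.append((b1 + b2, a))
    for a, ma in singles.items():
        for b, mb in singles.items():
            if a != b and abs(ma - mb) <= tol_da:
                out.append((a, b))
    return sorted(set(out))


_ISOBARIC = isobaric_replacements()


def sample_proteome(
    n_proteins: int,
    length_range: tuple[int, int] = (150, 350),
    seed: int | np.random.Generator = 0,
) -> Proteome:
    """Random proteome: i.i.d. uniform residues over the 19-letter (I-free) alphabet."""
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    alphabet = list(COLLAPSED_AA)
    entries = []
    for i in range(n_proteins):
        n = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(rng.choice(alphabet, size=n))
        entries.append(ProteinEntry(f"SYN{i + 1:05d}", seq))
    return Proteome(entries, il_collapsed=True)


def sample_peptides(
    proteome: Proteome,
    n: int,
    length_range: tuple[int, int] = (8, 15),
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """n unique substrings, positions uniform, lengths uniform in length_range."""
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    seqs = [e.sequence for e in proteome]
    weights = np.array([len(s) for s in seqs], dtype=float)
    weights /= weights.sum()
    out: dict[str, None] = {}
    attempts = 0
    while len(out) < n:
        if attempts > 100 * max(n, 1) + 1000:
            raise RuntimeError(f"could not sample {n} unique peptides")
        attempts += 1
        i = int(rng.choice(len(seqs), p=weights))
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        if len(seqs[i]) < L:
            continue
        start = int(rng.integers(0, len(seqs[i]) - L + 1))
        out.setdefault(seqs[i][start : start + L], None)
    return list(out)


def simulate_spectrum(
    peptide: str,
    model: SpectrumModel = SpectrumModel(),
    seed: int | np.random.Generator = 0,
    spectrum_id: Optional[str] = None,
) -> Spectrum:
    """One MS2 spectrum of *peptide* under the peak-level model."""
    if len(peptide) < 2:
        raise ValueError("need a peptide of length >= 2")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    frags = theoretical_fragments(peptide)
    keep = rng.random(len(frags)) < model.fragment_detect_prob
    sig_mz = frags[keep]
    if model.mz_jitter_sd > 0:
        sig_mz = sig_mz + rng.normal(0.0, model.mz_jitter_sd, size=len(sig_mz))
    mu_s, sd_s = model.signal_lognorm
    sig_int = rng.lognormal(mu_s, sd_s, size=len(sig_mz))
    n_noise = int(rng.poisson(model.noise_peaks_mean))
    lo, hi = model.noise_mz_range
    noise_mz = rng.uniform(lo, hi, size=n_noise)
    mu_n, sd_n = model.noise_lognorm
    noise_int = rng.lognormal(mu_n, sd_n, size=n_noise)
    charge = int(rng.choice(model.charges, p=model.charge_probs))
    mass = peptide_mass(peptide)
    return Spectrum(
        spectrum_id=spectrum_id or f"synthetic|{peptide}",
        precursor_mz=(mass + charge * PROTON) / charge,
        charge=charge,
        mz=np.concatenate([sig_mz, noise_mz]),
        intensity=np.concatenate([sig_int, noise_int]),
    )


def _terminal_weights(positions: Sequence[int], n: int, p: float) -> np.ndarray:
    """Geometric-decay-from-nearest-terminus weights over candidate positions."""
    q = 1.0 - min(max(p, 1e-6), 1.0 - 1e-6)
    w = np.array([q ** min(i, n - 1 - i) for i in positions], dtype=float)
    return w / w.sum()


def _corrupt(peptide: str, model: DeNovoErrorModel, rng: np.random.Generator) -> tuple[str, set[int]]:
    """Apply one corruption operator; return (sequence, erroneous positions)."""
    kinds = np.asarray(model.substitution_kinds, dtype=float)
    kind = int(rng.choice(3, p=kinds / kinds.sum()))
    n = len(peptide)
    bias = model.terminal_error_bias
    if kind == 0:  # single residue substitution
        return _corrupt_substitute(peptide, rng, bias)
    if kind == 1:  # adjacent-pair swap
        swappable = [i for i in range(n - 1) if peptide[i] != peptide[i + 1]]
        if not swappable:
            return _corrupt_substitute(peptide, rng, bias)
        i = int(rng.choice(swappable, p=_terminal_weights(swappable, n - 1, bias)))
        new = peptide[:i] + peptide[i + 1] + peptide[i] + peptide[i + 2 :]
        return new, {i, i + 1}
    # isobaric replacement at an applicable site
    sites = []
    for src, dst in _ISOBARIC:
        pos = peptide.find(src)
        while pos != -1:
            sites.append((pos, src, dst))
            pos = peptide.find(src, pos + 1)
    if not sites:
        return _corrupt_substitute(peptide, rng, bias)
    w = _terminal_weights([s[0] for s in sites], n, bias)
    pos, src, dst = sites[int(rng.choice(len(sites), p=w))]
    new = peptide[:pos] + dst + peptide[pos + len(src) :]
    return new, set(range(pos, pos + len(dst)))


def _corrupt_substitute(
    peptide: str, rng: np.random.Generator, bias: float
) -> tuple[str, set[int]]:
    n = len(peptide)
    pos = int(rng.choice(n, p=_terminal_weights(range(n), n, bias)))
    alphabet = [a for a in COLLAPSED_AA if a != peptide[pos]]
    return peptide[:pos] + str(rng.choice(alphabet)) + peptide[pos + 1 :], {pos}


def _lcs_draw(
    n: int,
    error_pos: set[int],
    model: DeNovoErrorModel,
    rng: np.random.Generator,
    quality_shift: float = 0.0,
) -> np.ndarray:
    mu_s, sd_s = model.alc_signal
    lcs = rng.normal(mu_s + quality_shift, sd_s, size=n)
    if model.lcs_error_localization and error_pos:
        mu_e, sd_e = model.alc_error
        for p in error_pos:
            if p < n:
                lcs[p] = rng.normal(mu_e, sd_e)
    return np.clip(lcs, 0.0, 100.0)


def simulate_denovo(
    true_peptide: str,
    spectrum: Spectrum,
    model: DeNovoErrorModel = DeNovoErrorModel(),
    k: int = 5,
    seed: int | np.random.Generator = 0,
) -> list[DeNovoCandidate]:
    """Top-k candidate list for one spectrum, ranked by ALC descending."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    include_true = rng.random() < model.p_correct_rank1
    quality = float(rng.normal(0.0, model.spectrum_quality_sd))

    entries: list[tuple[str, np.ndarray]] = []  # (sequence, lcs)
    if include_true:
        entries.append(
            (true_peptide, _lcs_draw(len(true_peptide), set(), model, rng, quality))
        )
    seen = {true_peptide} if include_true else set()
    true_mass = peptide_mass(true_peptide)
    while len(entries) < k:
        for _ in range(40):
            n_ops = 1 + int(rng.poisson(model.n_extra_ops_mean))
            seq, errs = true_peptide, set()
            for _op in range(n_ops):
                # error positions from earlier ops may drift by +-1 when an
                # isobaric op changes the length; exact tracking is immaterial
                # for the confidence model, so positions are simply unioned
                seq, new_errs = _corrupt(seq, model, rng)
                errs = errs | new_errs
            if seq in seen or seq == true_peptide or len(seq) < 2:
                continue
            dppm = abs(peptide_mass(seq) - true_mass) / true_mass * 1e6
            if dppm <= model.max_candidate_ppm:
                break
        seen.add(seq)
        entries.append((seq, _lcs_draw(len(seq), errs, model, rng, quality)))

    if include_true:
        # the true sequence is rank 1 by contract: cap corrupted ALCs below it
        true_alc = float(entries[0][1].mean())
        for i in range(1, len(entries)):
            seq, lcs = entries[i]
            alc = float(lcs.mean())
            if alc >= true_alc:
                scale = max(true_alc - 0.1, 0.0) / alc if alc > 0 else 0.0
                entries[i] = (seq, lcs * scale)
        head, tail = entries[:1], entries[1:]
    else:
        head, tail = [], entries
    tail.sort(key=lambda e: -float(e[1].mean()))
    ranked = head + tail
    return [
        DeNovoCandidate(
            spectrum_id=spectrum.spectrum_id,
            rank=r,
            sequence=seq,
            alc=float(lcs.mean()),
            lcs=tuple(np.round(lcs, 1)),
        )
        for r, (seq, lcs) in enumerate(ranked, start=1)
    ]


# ---------------------------------------------------------------------------
# end-to-end benchmark fixture
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class BenchmarkConfig:
    """Sizes and models of one synthetic benchmark dataset.

    The defaults are a desk-scale rendition of the constructed ground-truth
    design: equal thirds of non-spliced, cis-spliced and trapping 8-15-mers,
    one MS2 spectrum per peptide, top-5 de novo candidates per spectrum.  The
    proteome is kept large enough (about half a million residues) that short
    splice reactants co-occur by chance at appreciable rates, as they do
    against a full eukaryotic proteome; far smaller databases abolish the
    coincidental cis explanations whose handling the benchmark measures.
    """

    n_proteins: int = 2000
    protein_length_range: tuple[int, int] = (150, 350)
    n_peptides: int = 300
    peptide_length_range: tuple[int, int] = (8, 15)
    k_denovo: int = 5
    max_intervening: int = 25
    max_retries: int = 100
    spectrum_model: SpectrumModel = SpectrumModel()
    denovo_model: DeNovoErrorModel = DeNovoErrorModel()


@dataclasses.dataclass
class BenchmarkDataset:
    """Everything one benchmark run consumes, plus the answer key."""

    config: BenchmarkConfig
    seed: int
    bundle: GroundTruthBundle
    spectra: list[Spectrum]
    denovo: list[DeNovoCandidate]
    answer_key: dict[str, tuple[str, str]]  # spectrum_id -> (peptide, true category)


def build_benchmark_dataset(
    config: BenchmarkConfig = BenchmarkConfig(), seed: int = 0
) -> BenchmarkDataset:
    """proteome -> peptides -> constructed db -> spectra -> de novo tables."""
    ss = np.random.SeedSequence(seed)
    rng_prot, rng_pep, rng_spec, rng_dn = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    proteome = sample_proteome(config.n_proteins, config.protein_length_range, rng_prot)
    peptides = sample_peptides(
        proteome, config.n_peptides, config.peptide_length_range, rng_pep
    )
    gt_params = GroundTruthParams(
        max_intervening=config.max_intervening,
        seed=int(ss.generate_state(1)[0] % (2**31)),
        max_retries=config.max_retries,
    )
    bundle = build_ground_truth(proteome, peptides, gt_params)

    spectra: list[Spectrum] = []
    denovo: list[DeNovoCandidate] = []
    answer_key: dict[str, tuple[str, str]] = {}
    for i, rec in enumerate(bundle.plants, start=1):
        sid = f"spec_{i:05d}"
        spec = simulate_spectrum(rec.peptide, config.spectrum_model, rng_spec, sid)
        spectra.append(spec)
        denovo.extend(
            simulate_denovo(rec.peptide, spec, config.denovo_model, config.k_denovo, rng_dn)
        )
        answer_key[sid] = (rec.peptide, rec.intended_category)
    return BenchmarkDataset(config, seed, bundle, spectra, denovo, answer_key)


def write_answer_key(answer_key: dict[str, tuple[str, str]], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [(sid, pep, cat) for sid, (pep, cat) in answer_key.items()],
        columns=["spectrum_id", "peptide", "true_category"],
    ).to_csv(path, sep="\t", index=False)


def read_answer_key(path) -> dict[str, tuple[str, str]]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"spectrum_id": str})
    return {
        str(r.spectrum_id): (r.peptide, r.true_category) for r in df.itertuples(index=False)
    }
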