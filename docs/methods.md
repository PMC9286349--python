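# Methods

This note documents the models behind `splicebench`, the parameters that
matter, and the design choices made where the design was genuinely open.

## Splice mapping

A peptide is explained against a proteome by cutting it at every admissible
splice site (`min_reactant_len = 1`, so a 9-mer has 8 splits, `[1+8]` …
`[8+1]`) and looking up every exact occurrence pair of the two reactants.
Pairs on one protein whose intervening gap lies in `[0, max_intervening]`
(default 25 residues) are cis explanations — *normal* order when the
peptide-N-terminal reactant is upstream in the protein, *reverse* otherwise;
pairs on two proteins are trans explanations; a whole-peptide occurrence is a
non-spliced explanation. Competing explanations resolve by the hierarchy
**non-spliced > cis > trans > none**.

Open choices, resolved as follows:

* *Overlapping reactant occurrences* (negative intervening length) are not
  explanations by default; `allow_overlap=True` admits them. Biochemically a
  single protein molecule cannot contribute the same residues to both
  reactants, so the default excludes overlap.
* *Reverse-order intervening length* is measured symmetrically to normal
  order (gap between the upstream occurrence's end and the downstream
  occurrence's start) and shares the same cap.
* *Same-protein pairs beyond the cap* ("long-range cis") explain nothing by
  default; the switch `long_cis_as_trans=True` counts them as trans instead.
  Published workflow descriptions only discuss the two-protein case, so the
  package does not guess and exposes the switch.
* Coordinates are 0-based half-open throughout.

All sequence comparison happens in I/L-collapsed space (every isoleucine
rewritten to leucine), because mass spectrometry cannot distinguish the two
residues; mixing collapse states raises an error.

Two implementations exist: `classify` enumerates the complete explanation
set; `categorize` answers only the winning category, short-circuiting by
scanning the rarer (longer) reactant's occurrences and probing the partner in
the admissible window. The two are property-tested to agree, and both are
tested against an independent brute-force enumerator.

## Constructed ground-truth databases

Targets (an input peptide list) are randomly partitioned into equal thirds —
non-spliced, cis-spliced, and *trapping* (unidentifiable; these model the
pool of unconventional peptides a cis-aware search cannot encode, and are
realised as trans-spliced plants). The builder then:

1. collapses I/L in the reference database and the targets;
2. **elides** every occurrence of every target by replacing it with random
   residues of equal length (uniform over the 19-letter collapsed alphabet),
   redrawing when a replacement re-creates a target;
3. **scrubs** pre-existing cis explanations of trapping targets: elision only
   removes whole-target substrings, so a trapping target can retain a
   coincidental cis explanation in the natural text that no amount of plant
   re-sampling could remove; the longer reactant occurrence of each offending
   explanation is replaced the same way, to a fixpoint;
4. **repairs nested-target categories**: immunopeptidomes contain length
   variants, so one target may be a substring of another. A non-spliced
   container forces its containees non-spliced (planting it whole implants
   them), and a cis container cannot host a trapping containee (its planted
   `reactant1 + intervening + reactant2` block hands any containee cut by the
   splice site a cis explanation). Violations are repaired by deterministic
   category swaps with targets outside any containment pair, preserving the
   per-category counts;
5. **plants** each target in seeded random order: non-spliced targets are
   appended whole to a random terminus of a random protein; cis targets as
   one contiguous block `reactant1 + intervening + reactant2` (split point
   uniform over the peptide, intervening length uniform on
   `[1, max_intervening]`, residues uniform) at one terminus; trapping
   targets as two reactants on the termini of two distinct proteins. After
   every plant, the builder verifies that no target (planted or pending)
   drifted to a better category than intended — appends can only promote a
   peptide, and any new explanation must involve a touched protein, so the
   checks are local — and rolls the plant back for re-sampling on conflict
   (budget `max_retries = 100` per target).

The finished bundle is re-verified globally: every non-spliced target must
classify non-spliced, every cis target cis, and every trapping target trans
or none. Elision and scrubbing never change protein lengths, so the final
residue count equals the collapsed original plus the planted material.

## Synthetic data

The generators emulate the statistical structure of a mono-allelic HLA-I
immunopeptidome experiment, not its biochemistry:

* **Proteome** — i.i.d. uniform residues over the 19-letter collapsed
  alphabet. Default benchmark size is 2000 proteins of 150–350 residues
  (~0.5 M residues). The size matters: coincidental co-occurrence of short
  splice reactants is what makes wrong-but-cis-explainable candidates
  possible, as against a full eukaryotic proteome; far smaller databases
  abolish that phenomenon and would make the misassignment analysis vacuous.
  Uniform composition is the simplest null; a frequency-table hook would be
  the natural extension.
* **Peptides** — unique 8–15-mer substrings, positions uniform. Default 300
  per dataset, a desk-scale rendition of the 1246–1655-peptide constructed
  datasets the benchmark design mimics; one MS2 spectrum per peptide.
* **Spectra** — each theoretical singly-charged b/y ion is detected with
  probability 0.85, jittered by N(0, 0.004 Da); Poisson(20) uniform noise
  peaks; log-normal intensities with signal about an order of magnitude
  above noise; precursor charge in {1,2,3} with probabilities
  (0.25, 0.6, 0.15).
* **De novo candidates** — top-5 per spectrum. With probability 0.7 the true
  sequence is rank 1. Erroneous candidates apply 1 + Poisson(0.5) corruption
  operators — residue substitution (weight 0.2), adjacent-pair swap (0.4),
  isobaric replacement (0.4; table generated from the residue masses within
  0.02 Da, e.g. N↔GG, Q↔AG/GA) — with error positions drawn with geometric
  decay from a random terminus, and are redrawn until their mass matches the
  true precursor within 5 ppm. These three properties (mass-preserving
  rearrangements dominate, errors concentrate at termini where b1/y1-level
  evidence is missing, candidates never contradict the measured precursor)
  are the defining features of real de novo candidate lists and are exactly
  what lets erroneous candidates acquire coincidental cis explanations.
  Per-residue local confidence (LCS) is N(92, 4) at correct residues and
  N(55, 12) at erroneous ones, clipped to [0, 100]; ALC is the LCS mean. A
  per-spectrum quality offset N(0, 6) spreads the ALC distribution, as
  spectrum quality does in real data — without it a distribution-derived ALC
  cutoff would sit implausibly tight above every erroneous candidate.

What the generator does **not** model: real intensity patterns, retention
time, co-elution/chimeric spectra, post-translational modifications, charge
envelopes, empirical amino-acid composition, or engine-specific scoring.
Passing benchmarks on this data therefore demonstrates the correctness and
the qualitative behaviour of the workflows, not engine performance on real
immunopeptidomes.

## Candidate selection (AP and MBS)

Both workflows first exclude spectra confidently assigned to non-spliced
peptides by a reference-only search at 1% estimated FDR (the same exclusion
list serves both, which keeps the comparison like-for-like). Then:

* **AP**: the ALC cutoff is a configurable lower quantile (default 5%,
  lower order statistic) of the ALC values of rank-1 candidates that agree
  with the confident database identification of their spectrum. Candidates
  at or below the cutoff are dropped (the filter is strict `>`); per
  spectrum, any surviving non-spliced candidate discards the spectrum,
  otherwise the single highest-ALC cis candidate is retained, else the
  single highest-ALC trans candidate. Retained sequences are concatenated
  into in-silico proteins, 25 per entry (configurable; chunking bounds the
  scope of junction artefacts, which remain detectable via provenance).
* **MBS**: every candidate with min per-residue LCS ≥ 80 that classifies
  cis (intervening ≤ 25) and not non-spliced is retained, several per
  spectrum allowed, one database entry per unique sequence.

Duplicate retained sequences are collapsed in first-retention order; the
database feature counts (candidates, true cis candidates among them, true
cis total — the precision/recall *potential* of a target database) use
unique sequences.

## Search engine stand-in and FDR

The built-in engine exists because the benchmark machinery only requires *a*
monotone PSM score, and the engines the workflows historically used are
commercial. It digests target plus reversed-protein decoy ("searched
simultaneously") into unspecific 8–15-mer substrings, prefilters by
precursor mass (5 ppm) with a sorted mass index, and scores a candidate as
`-log10 P(X ≥ m)` where `m` of the `2(n−1)` theoretical singly-charged b/y
ions find a peak within 0.02 Da and X is hypergeometric over an m/z-bin
model (bins of twice the fragment tolerance across the spectrum's span).
Scores are capped at 400 where the tail underflows. The best candidate per
spectrum wins; ties resolve by smaller summed |m/z error| of matched peaks,
then target over decoy, lexicographic peptide, first accession. The
continuous mass-error criterion matters: the count-based score is discrete,
and a target-first rule alone would systematically depress decoy counts and
bias the FDR estimate downward — with it, the decoy estimate is unbiased on
a null experiment to within Monte-Carlo error.

FDR at a score threshold is `100·2D/(T+D)` over assigned target (T) and
decoy (D) PSMs; `T+D = 0` yields 0% with an `undefined` flag. Threshold
selection takes the loosest grid point at or below the target FDR, falling
back to the strictest with a warning. Preset grids for imported engine
results (PEAKS-style −log10P 5–100, Mascot-style peptide-expect values) are
provided; imported PSM tables run through the identical estimator and
benchmark code.

## Benchmarking

A PSM is *correct* when its sequence equals the answer-key peptide after I/L
collapse **and** its assigned category equals the true category (sequence
identity alone is also computable; the conjunction is the default because a
cis identification with the right letters but the wrong origin class is an
incorrect scientific claim). Precision is correct/assigned, recall is
correct/true, per category over a threshold grid; zero-assigned points are
dropped rather than scored 0 or 1. The misassignment table cross-tabulates
true category (non-spliced / cis / trapping) against assigned category at a
threshold, typically the 1% FDR pick. Spectrum features: ion coverage =
matched theoretical ions / 2(n−1); signal-to-noise = median matched peak
intensity / median unmatched peak intensity (+∞ flag when everything
matches); hydrophobicity = mean Kyte–Doolittle residue value (configurable
at the code level by swapping the table).

## Numerical and reproducibility choices

All randomness flows from numpy Generators spawned from one seed; identical
seeds give byte-identical FASTA/MGF/TSV outputs. Quantiles use the lower
order statistic. The substring index rejects matches spanning protein
boundaries by construction (sentinel-joined text). ALC values are validated
to equal the LCS mean within 0.51 to absorb rounding in exported tables.
Degenerate inputs are errors, not silent defaults: empty FASTA, duplicate
accessions, non-canonical residues (with an opt-in drop mode), mixed I/L
collapse states, trapping plants on single-protein databases.

## Known limitations

* Desk-scale misassignment counts are small. At ~0.5 M database residues
  and 100 trapping spectra per dataset, the number of trapping spectra
  misassigned to cis-spliced peptides per run is of order one, and the
  false-PSM floor implied by a 1% FDR filter contributes comparably many
  non-spliced misassignments; the contrast between the two (clear at full
  proteome scale, where coincidental cis explanations are far more abundant)
  is therefore noisy in any single desk-scale run, while the precision,
  recall and database-size contrasts between AP and MBS are stable.
* The full-enumeration mapper (`classify`) can return very large trans
  explanation sets for short reactants on large proteomes; pipelines use the
  category-only fast path. 
* The AP in-silico concatenation can create junction peptides spanning two
  candidates; chunking bounds, but does not eliminate, this artefact.
* `pick_threshold_at_fdr` at small PSM counts is granular: one decoy more
  or less moves the estimate by ~1 percentage point, so picked thresholds
  vary between seeds.
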