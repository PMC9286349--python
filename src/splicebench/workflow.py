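"""End-to-end AP/MBS runs: first-pass search, candidate selection, final search,
FDR filtering and benchmarking, with a manifest for reproducibility.

The two workflows share the two-round structure: search the reference database
first, exclude spectra confidently assigned to non-spliced peptides, feed the
rest's de novo candidates into the method-specific selection, append the
retained candidates to the reference, search again, and filter by the
target-decoy FDR estimate.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .benchmark import (
    PrPoint,
    misassignment_table,
    pr_curves_to_frame,
    precision_recall,
)
from .engine_sim import (
    FdrPoint,
    PSM,
    SearchParams,
    Spectrum,
    ThresholdPick,
    pick_threshold_at_fdr,
    read_mgf,
    read_psm_tsv,
    search,
    threshold_sweep,
    write_mgf,
    write_psm_tsv,
)
from .ground_truth import GroundTruthBundle
from .proteome import Proteome, read_fasta, write_fasta
from .splice_mapper import MapperParams, NONSPLICED
from .synthetic_data import (
    BenchmarkConfig,
    BenchmarkDataset,
    build_benchmark_dataset,
    read_answer_key,
    write_answer_key,
)
from .target_db import (
    AP,
    MBS,
    TargetDatabase,
    TargetDbFeatures,
    ap_select_candidates,
    build_target_db,
    compute_alc_cutoff,
    mbs_select_candidates,
    read_denovo_table,
    target_db_features,
    write_denovo_table,
)
from .proteome import build_index

#: default score grid for the built-in engine (-log10 tail probability units)
DEFAULT_THRESHOLDS: tuple[float, ...] = (
    0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0, 12.0, 15.0, 20.0, 30.0, 50.0, 100.0,
)
#: preset grids for imported engine results
PEAKS_LOG10P_GRID: tuple[float, ...] = tuple(float(x) for x in range(5, 101, 5))
MASCOT_PEP_EXPECT_GRID: tuple[float, ...] = (
    0.0, 0.05, 0.1, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0,
)


@dataclasses.dataclass
class WorkflowResult:
    workflow: str
    target_db: TargetDatabase
    psms: list[PSM]
    sweep: list[FdrPoint]
    pick: ThresholdPick
    alc_cutoff: Optional[float]
    excluded_spectra: set[str]
    curves: Optional[dict[str, list[PrPoint]]] = None
    misassignment: Optional[pd.DataFrame] = None
    features: Optional[TargetDbFeatures] = None


def run_method(
    workflow: str,
    reference: Proteome,
    spectra: Sequence[Spectrum],
    denovo,
    answer_key=None,
    bundle: Optional[GroundTruthBundle] = None,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    first_pass_fdr: float = 1.0,
    final_fdr: float = 1.0,
    search_params: SearchParams = SearchParams(),
    mapper_params: MapperParams = MapperParams(),
    alc_quantile: float = 0.05,
    lcs_min: float = 80.0,
    chunk_size: int = 25,
    final_psms: Optional[Sequence[PSM]] = None,
    first_pass_psms: Optional[Sequence[PSM]] = None,
) -> WorkflowResult:
    """One AP or MBS run against a reference database.

    ``final_psms`` replaces the built-in final search with an imported PSM
    table (external engine output); everything downstream is identical.
    ``first_pass_psms`` lets callers reuse one reference-only search when
    running both workflows on the same dataset.
    """
    if workflow not in (AP, MBS):
        raise ValueError("workflow must be 'AP' or 'MBS'")

    # first pass: reference-only search, exclude confident non-spliced spectra
    first = (
        list(first_pass_psms)
        if first_pass_psms is not None
        else search(spectra, reference, search_params, mapper_params)
    )
    first_sweep = threshold_sweep(first, list(thresholds))
    first_pick = pick_threshold_at_fdr(first_sweep, first_pass_fdr)
    confident = {
        p.spectrum_id: p.peptide
        for p in first
        if not p.is_decoy
        and p.score >= first_pick.threshold
        and p.assigned_category == NONSPLICED
    }
    excluded = set(confident)

    ref_index = build_index(reference)
    alc_cutoff: Optional[float] = None
    if workflow == AP:
        alc_cutoff = compute_alc_cutoff(denovo, confident, alc_quantile)
        retained = ap_select_candidates(
            denovo, ref_index, alc_cutoff, mapper_params, excluded_spectra=excluded
        )
    else:
        retained = mbs_select_candidates(
            denovo, ref_index, lcs_min, mapper_params, excluded_spectra=excluded
        )
    db = build_target_db(retained, reference, mode=workflow, chunk_size=chunk_size)

    psms = (
        list(final_psms)
        if final_psms is not None
        else search(spectra, db, search_params, mapper_params)
    )
    sweep = threshold_sweep(psms, list(thresholds))
    pick = pick_threshold_at_fdr(sweep, final_fdr)

    result = WorkflowResult(
        workflow, db, psms, sweep, pick, alc_cutoff, excluded
    )
    if answer_key is not None:
        result.curves = precision_recall(psms, answer_key, list(thresholds))
        result.misassignment = misassignment_table(psms, answer_key, pick.threshold)
    if bundle is not None:
        result.features = target_db_features(db, bundle)
    return result


# ---------------------------------------------------------------------------
# config-driven runs (CLI `splicebench run`)
# ---------------------------------------------------------------------------

_CONFIG_DEFAULTS = {
    "workflow": "AP",
    "engine": "builtin",
    "seed": "0",
    "proteome": "",
    "spectra": "",
    "denovo": "",
    "answer_key": "",
    "psms": "",
    "out_dir": "run",
    "first_pass_fdr": "1.0",
    "final_fdr": "1.0",
    "alc_quantile": "0.05",
    "lcs_min": "80",
    "max_intervening": "25",
    "n_proteins": "300",
    "n_peptides": "150",
}


@dataclasses.dataclass
class RunConfig:
    """Flat key-value run configuration; empty paths mean 'simulate instead'."""

    values: dict[str, str]

    @classmethod
    def from_file(cls, path: Optional[str] = None, overrides: Optional[dict] = None) -> "RunConfig":
        values = dict(_CONFIG_DEFAULTS)
        if path:
            for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                k, v = (s.strip() for s in line.split("=", 1))
                if k not in values:
                    raise ValueError(f"{path}:{lineno}: unknown key {k!r}")
                values[k] = v
        for k, v in (overrides or {}).items():
            if v is not None:
                values[k] = str(v)
        for key in ("proteome", "spectra", "denovo", "answer_key", "psms"):
            if values[key] and not Path(values[key]).exists():
                raise FileNotFoundError(f"config path {key} = {values[key]!r} does not exist")
        return cls(values)

    def __getitem__(self, key: str) -> str:
        return self.values[key]


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_workflow(config: RunConfig) -> Path:
    """Execute a full configured run; returns the run directory."""
    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    workflow = config["workflow"].upper()
    mapper_params = MapperParams(max_intervening=int(config["max_intervening"]))

    inputs: dict[str, str] = {}
    bundle = None
    answer_key = None
    if config["proteome"]:
        reference = read_fasta(config["proteome"])
        spectra = read_mgf(config["spectra"])
        denovo = read_denovo_table(config["denovo"])
        for key in ("proteome", "spectra", "denovo"):
            inputs[key] = _digest(Path(config[key]))
        if config["answer_key"]:
            answer_key = read_answer_key(config["answer_key"])
            inputs["answer_key"] = _digest(Path(config["answer_key"]))
    else:
        ds = build_benchmark_dataset(
            BenchmarkConfig(
                n_proteins=int(config["n_proteins"]),
                n_peptides=int(config["n_peptides"]),
                max_intervening=int(config["max_intervening"]),
            ),
            seed=seed,
        )
        reference = ds.bundle.constructed_db
        spectra, denovo, answer_key, bundle = ds.spectra, ds.denovo, ds.answer_key, ds.bundle
        write_fasta(reference, out / "constructed_db.fasta")
        write_mgf(spectra, out / "spectra.mgf")
        write_denovo_table(denovo, out / "denovo.tsv")
        write_answer_key(answer_key, out / "answer_key.tsv")

    final_psms = read_psm_tsv(config["psms"]) if config["psms"] else None
    if config["psms"]:
        inputs["psms"] = _digest(Path(config["psms"]))

    result = run_method(
        workflow,
        reference,
        spectra,
        denovo,
        answer_key=answer_key,
        bundle=bundle,
        first_pass_fdr=float(config["first_pass_fdr"]),
        final_fdr=float(config["final_fdr"]),
        mapper_params=mapper_params,
        alc_quantile=float(config["alc_quantile"]),
        lcs_min=float(config["lcs_min"]),
        final_psms=final_psms,
    )

    write_fasta(result.target_db.full_proteome(), out / "target_db.fasta")
    write_psm_tsv(result.psms, out / "psms.tsv")
    pd.DataFrame(
        [(p.threshold, p.n_target, p.n_decoy, p.fdr_percent) for p in result.sweep],
        columns=["threshold", "n_target", "n_decoy", "fdr_percent"],
    ).to_csv(out / "fdr_sweep.tsv", sep="\t", index=False)
    if result.curves is not None:
        pr_curves_to_frame(result.curves).to_csv(out / "pr_curves.tsv", sep="\t", index=False)
    if result.misassignment is not None:
        result.misassignment.to_csv(out / "misassignment.tsv", sep="\t")

    manifest = {
        "splicebench_version": __version__,
        "workflow": workflow,
        "engine": config["engine"],
        "seed": seed,
        "parameters": dict(config.values),
        "input_digests": inputs,
        "picked_threshold": result.pick.threshold,
        "fdr_target_satisfied": result.pick.satisfied,
        "alc_cutoff": result.alc_cutoff,
        "n_excluded_first_pass": len(result.excluded_spectra),
        "n_psms": len(result.psms),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
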