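"""Stage orchestration: design -> fit -> metrics -> lineshape.

Each enabled stage reads its inputs, writes per-stage TSV/JSON outputs
under the configured output directory, and records its status in a run
manifest (config hash, seed, package and library versions, outputs).
The same config over the same inputs produces byte-identical numeric
outputs — nothing time- or host-dependent is written.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import scipy

from . import __version__
from .config import PipelineConfig
from .dnpmetrics import derive_sensitivity, rank_conditions
from .ensembleshift import (
    Spectrum1D,
    compare_distribution_to_lineshape,
    detect_bimodality,
    linewidth_measures,
    shift_histogram,
)
from .errors import DataError, NumericalError
from .io import (
    read_curve,
    read_fasta,
    read_sample_table,
    read_shift_table,
    read_spectrum,
    write_fit_results,
    write_pairs_tsv,
    write_sample_table,
)
from .relaxfit import fit_echo_decay, fit_saturation_recovery
from .seqdesign import RegionMap, find_unique_pairs


def _infer_atom(shifts: np.ndarray) -> str | None:
    """Guess the atom type of a site from its chemical-shift range."""
    mean = float(np.mean(shifts))
    if 40.0 <= mean <= 75.0:
        return "CA"
    if 160.0 <= mean <= 190.0:
        return "CO"
    return None


def _stage_design(config: PipelineConfig, outdir: Path) -> list[str]:
    if config.input_fasta is None:
        raise DataError("design stage enabled but no input_fasta configured")
    records = read_fasta(config.input_fasta)
    opts = config.seqdesign
    regions = RegionMap([tuple(r) for r in opts.regions]) if opts.regions else None
    outputs = []
    for rec in records:
        seq = rec.as_protein() if opts.translate else rec.sequence
        pairs = find_unique_pairs(seq, exclude_residues=opts.exclude_residues,
                                  regions=regions)
        out = outdir / f"pairs_{rec.id}.tsv"
        write_pairs_tsv(out, pairs)
        outputs.append(out.name)
    return outputs


def _stage_fit(config: PipelineConfig, outdir: Path) -> list[str]:
    if not config.input_curves:
        raise DataError("fit stage enabled but no input_curves configured")
    results = {}
    for path in config.input_curves:
        curve = read_curve(path)
        if curve.kind == "saturation_recovery":
            res = fit_saturation_recovery(curve)
        else:
            j_mod = bool((curve.ground_truth or {}).get("j_modulated"))
            res = fit_echo_decay(
                curve, J_fixed_hz=config.relaxfit.j_fixed_hz if j_mod else None
            )
        if not res.converged:
            raise NumericalError(f"fit did not converge for {path}: {res.message}")
        results[Path(path).stem] = res
    out = outdir / "fit_results.json"
    write_fit_results(out, results)
    return [out.name]


def _stage_metrics(config: PipelineConfig, outdir: Path) -> list[str]:
    if config.input_sample_table is None:
        raise DataError("metrics stage enabled but no input_sample_table configured")
    records = [derive_sensitivity(r) for r in read_sample_table(config.input_sample_table)]
    derived_out = outdir / "samples_derived.tsv"
    write_sample_table(derived_out, records, derived=True)
    ranked = rank_conditions(records, criterion=config.dnpmetrics.rank_criterion)
    ranking = {
        "criterion": config.dnpmetrics.rank_criterion,
        "note": "T2_weighted is a heuristic score, not a measured quantity",
        "order": [
            {"rank": i + 1, "sample": r.label,
             "sensitivity_per_sqrt_s": round(r.sensitivity, 4)}
            for i, r in enumerate(ranked)
        ],
    }
    rank_out = outdir / "ranking.json"
    rank_out.write_text(json.dumps(ranking, indent=2) + "\n")
    return [derived_out.name, rank_out.name]


def _stage_lineshape(config: PipelineConfig, outdir: Path) -> list[str]:
    if config.input_shift_table is None and not config.input_spectra:
        raise DataError("lineshape stage enabled but no shift table or spectra configured")
    opts = config.ensembleshift
    report: dict = {"sites": {}, "spectra": {}}
    spectra: dict[str, Spectrum1D] = {}
    for path in config.input_spectra:
        spec = read_spectrum(path)
        key = spec.site or Path(path).stem
        spectra[key] = spec
        fwhm, ipw, centroid = linewidth_measures(spec)
        report["spectra"][key] = {
            "fwhm_ppm": fwhm, "width_10_90_ppm": ipw, "centroid_ppm": centroid,
        }
    if config.input_shift_table is not None:
        ensemble = read_shift_table(config.input_shift_table)
        for site in ensemble.sites:
            hist = shift_histogram(ensemble, site, bin_width=opts.bin_width_ppm)
            modes = detect_bimodality(
                ensemble.shifts[site], separation_factor=opts.separation_factor
            )
            entry: dict = {
                "n_frames": int(ensemble.n_frames),
                "histogram_mean_ppm": hist.mean(),
                "width_10_90_ppm": hist.percentile_width(),
                "n_modes": modes.n_modes,
                "mode_means_ppm": modes.means,
                "atom_type": _infer_atom(ensemble.shifts[site]),
            }
            if site in spectra:
                overlap, width_ratio = compare_distribution_to_lineshape(
                    hist, spectra[site]
                )
                entry["overlap_with_experiment"] = overlap
                entry["experiment_over_ensemble_width"] = width_ratio
            report["sites"][site] = entry
    out = outdir / "lineshape.json"
    out.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return [out.name]


_STAGES = {
    "design": _stage_design,
    "fit": _stage_fit,
    "metrics": _stage_metrics,
    "lineshape": _stage_lineshape,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; return the manifest dict.

    On a stage failure, the manifest still records every stage's status
    (partial completion) before the exception propagates.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_sha256": hashlib.sha256(config.canonical().encode()).hexdigest(),
        "seed": config.seed,
        "versions": {
            "dnpmas": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
        },
        "stages": {},
    }
    failure: Exception | None = None
    for stage in config.stages:
        if failure is not None:
            manifest["stages"][stage] = {"status": "skipped", "outputs": []}
            continue
        try:
            outputs = _STAGES[stage](config, outdir)
            manifest["stages"][stage] = {"status": "ok", "outputs": outputs}
        except (DataError, NumericalError) as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc),
                                         "outputs": []}
            failure = exc
    manifest["manifest_sha256"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    if failure is not None:
        raise failure
    return manifest
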