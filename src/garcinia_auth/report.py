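"""End-to-end report runner: fixtures arm, qNMR arm, barcode arm.

Each arm runs and reports independently; a failure in one is recorded in
the run log and does not silence the others.  Only a fixture-integrity
failure is considered fatal, because every downstream table claim rests on
the embedded values.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .barcode import assign_query, distance_matrix, distance_summaries
from .errors import FixtureIntegrityError
from .qnmr import quantify_spectrum
from .seqsim import LibrarySpec, simulate_queries, simulate_reference_library
from .spectra import SpectrumSimConfig, build_signature_library, simulate_spectrum
from .study import (load_fixtures, summarize_fruit_contents,
                    verify_label_calculations, verify_row_totals)

__all__ = ["ReportConfig", "run_report"]


@dataclass
class ReportConfig:
    """What to run and under which study conditions."""

    seed: int = 0
    out_dir: str | Path = "report_out"
    run_fixtures: bool = True
    run_qnmr: bool = True
    run_barcode: bool = True
    # qNMR arm: synthetic recovery study conditions
    n_recovery_spectra: int = 20
    n_replicates: int = 3
    fraction_range: tuple[float, float] = (0.02, 0.25)
    noise_rel: float = 0.01  # noise SD as a fraction of the reference peak height
    # barcode arm
    library_spec: LibrarySpec = field(default_factory=LibrarySpec)
    n_queries: int = 200


def _recovery_study(config: ReportConfig) -> pd.DataFrame:
    """Simulate samples at known fractions and re-measure them.

    Each sample is measured as replicate spectra (triplicate by default,
    the standard qNMR protocol) whose mass fractions are averaged by
    :func:`~garcinia_auth.qnmr.quantify_spectrum`.
    """
    library = build_signature_library()
    ir = library.internal_reference
    # reference peak height: area/(pi*fwhm/2) with area = 2H of 1 mg maleic
    ir_area = ir.mass_mg / ir.mw * ir.n_protons
    ir_height = 2.0 * ir_area / (np.pi * ir.fwhm_hz / 400.0)
    rng = np.random.default_rng(config.seed)
    lo, hi = config.fraction_range
    rows = []
    for i in range(config.n_recovery_spectra):
        f_hca = float(rng.uniform(lo, hi))
        f_lac = float(rng.uniform(lo, hi))
        replicates = []
        for _ in range(config.n_replicates):
            cfg = SpectrumSimConfig(
                concentrations={"hca": 10.0 * f_hca,
                                "hca_lactone": 10.0 * f_lac},
                noise_sd=config.noise_rel * ir_height,
                sugar_background=False,
                seed=int(rng.integers(2 ** 31)))
            replicates.append(simulate_spectrum(cfg, library))
        results = {r.analyte: r
                   for r in quantify_spectrum(replicates, library)}
        rows.append({
            "spectrum": i, "true_hca": f_hca, "true_lactone": f_lac,
            "measured_hca": results["hca"].mass_fraction,
            "measured_lactone": results["hca_lactone"].mass_fraction,
            "abs_err_hca": abs(results["hca"].mass_fraction - f_hca),
            "abs_err_lactone": abs(results["hca_lactone"].mass_fraction - f_lac),
        })
    return pd.DataFrame(rows)


def _barcode_study(config: ReportConfig) -> dict:
    spec = LibrarySpec(**{**config.library_spec.__dict__,
                          "seed": config.library_spec.seed or config.seed})
    library = simulate_reference_library(spec)
    queries, truths = simulate_queries(library, config.n_queries,
                                       seed=config.seed + 1)
    correct = 0
    assignments = []
    for query, true_species in zip(queries, truths):
        res = assign_query(query, library.records)
        assignments.append({"query": query.id, "true": true_species,
                            "assigned": res.assigned_species,
                            "nearest_distance": res.nearest_distance,
                            "clade_support": res.clade_support})
        if res.assigned_species == true_species:
            correct += 1
    matrix = distance_matrix(library.records)
    summary = distance_summaries(matrix, marker=spec.marker)
    return {
        "accuracy": correct / len(queries),
        "assignments": pd.DataFrame(assignments),
        "summary": summary,
    }


def run_report(config: ReportConfig) -> dict:
    """Run the configured arms; write CSV/JSON artifacts and a run log."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed, "version": __version__,
                 "python": platform.python_version(), "arms": {}}
    outputs: dict = {}

    if config.run_fixtures:
        fruits, supplements = load_fixtures()  # integrity failure propagates
        report = summarize_fruit_contents(fruits)
        report.per_species.to_csv(out_dir / "fruit_summary.csv", index=False)
        totals = verify_row_totals(fruits, tolerance=0.05)
        totals.to_csv(out_dir / "row_total_flags.csv", index=False)
        labels = verify_label_calculations(supplements)
        labels.to_csv(out_dir / "label_checks.csv", index=False)
        outputs["fixtures"] = {"summary": report.per_species,
                               "row_total_flags": totals,
                               "label_checks": labels}
        log["arms"]["fixtures"] = {"status": "ok",
                                   "n_fruit": len(fruits),
                                   "n_supplements": len(supplements),
                                   "n_row_total_flags": int(len(totals))}

    if config.run_qnmr:
        try:
            recovery = _recovery_study(config)
            recovery.to_csv(out_dir / "nmr_recovery.csv", index=False)
            mae = float(recovery[["abs_err_hca", "abs_err_lactone"]]
                        .to_numpy().mean())
            outputs["qnmr"] = {"recovery": recovery, "mae": mae}
            log["arms"]["qnmr"] = {"status": "ok", "mean_abs_error": mae,
                                   "n_spectra": config.n_recovery_spectra}
        except Exception as exc:  # independent-arm policy
            log["arms"]["qnmr"] = {"status": "failed", "error": str(exc)}

    if config.run_barcode:
        try:
            barcode = _barcode_study(config)
            barcode["assignments"].to_csv(out_dir / "assignments.csv",
                                          index=False)
            outputs["barcode"] = barcode
            log["arms"]["barcode"] = {
                "status": "ok", "accuracy": barcode["accuracy"],
                "intra_mean": barcode["summary"].intra_mean,
                "inter_mean": barcode["summary"].inter_mean,
                "suitable": barcode["summary"].suitable,
                "n_queries": config.n_queries}
        except Exception as exc:
            log["arms"]["barcode"] = {"status": "failed", "error": str(exc)}

    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2,
                                                     default=str) + "\n")
    outputs["log"] = log
    return outputs
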