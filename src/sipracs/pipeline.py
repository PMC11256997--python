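"""End-to-end orchestration: SIP gradient → REF calling → Raman screen →
cultivation design, mirroring the experimental workflow's order."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as sio
from .consortium import AnnotationSet, design_ratios, recommend_medium
from .enrichment import CallingParams, aggregate_window_abundance, call_active_degraders
from .gradient import WindowParams, fit_bd_vs_fraction, identify_windows
from .raman import RamanParams, build_sorting_manifest, classify_cells
from .simdata import (
    soil_gradient_config,
    screening_census_config,
    write_fixture,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "DEMO_ANNOTATIONS"]

logger = logging.getLogger(__name__)

#: Synthetic stand-in annotation labels used when no annotation file is given;
#: mirrors the gene content that drives every medium rule.
DEMO_ANNOTATIONS = [
    "thiamine biosynthesis protein ThiC (vitamin B1)",
    "riboflavin synthase (vitamin B2)",
    "cobalamin biosynthesis protein CbiB (vitamin B12)",
    "lipoic acid synthetase LipA",
    "zinc ABC transporter substrate-binding protein ZnuA",
    "cobalt transport protein CbiQ",
    "molybdate ABC transporter permease ModB",
    "aminoglycoside 3'-phosphotransferase APH(3')",
    "L-lactate dehydrogenase LldD",
]


@dataclass
class PipelineConfig:
    """Inputs, parameters and output destination for one pipeline run.

    When the three input paths are None the default synthetic soil-community experiment
    is generated under ``out_dir/fixture`` from ``seed``.
    """

    out_dir: Path
    seed: int = 0
    asv_table_path: Path | None = None
    fractions_path: Path | None = None
    spectra_path: Path | None = None
    annotations_path: Path | None = None
    calling: CallingParams = field(default_factory=CallingParams)
    window_params: WindowParams = field(default_factory=WindowParams)
    raman_params: RamanParams = field(default_factory=RamanParams)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        for name in ("asv_table_path", "fractions_path", "spectra_path", "annotations_path"):
            p = getattr(self, name)
            if p is not None:
                p = Path(p)
                setattr(self, name, p)
                if not p.exists():
                    raise FileNotFoundError(f"{name} does not exist: {p}")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - propagate with stage name
                raise PipelineError(name, exc) from exc
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write every artifact; returns the report dict.

    Outputs under ``config.out_dir``: windows.json, ref_calls.tsv,
    label_calls.tsv, sorting_manifest.txt, medium.json, ratios.json,
    report.json and report.md.  The report body is deterministic for a given
    seed and inputs.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    # --- inputs -----------------------------------------------------------
    @_stage("inputs")
    def load_inputs():
        simulated = config.asv_table_path is None
        if simulated:
            fixture_dir = out / "fixture"
            write_fixture(
                soil_gradient_config(config.seed),
                screening_census_config(config.seed),
                fixture_dir,
            )
            table = sio.read_asv_table(fixture_dir / "asv_table.tsv")
            runs = sio.read_fractions_csv(fixture_dir / "fractions.csv")
            spectra = sio.read_spectra(fixture_dir / "spectra.csv")
        else:
            if config.fractions_path is None or config.spectra_path is None:
                raise ValueError("asv_table_path given but fractions/spectra paths missing")
            table = sio.read_asv_table(config.asv_table_path)
            runs = sio.read_fractions_csv(config.fractions_path)
            spectra = sio.read_spectra(config.spectra_path)
        if not table.asv_ids or not spectra:
            raise ValueError("empty inputs: no ASVs or no spectra")
        return table, runs, spectra, simulated

    table, runs, spectra, simulated = load_inputs()

    # --- gradient windows -------------------------------------------------
    @_stage("windows")
    def windows_stage():
        fits = {t: fit_bd_vs_fraction(r) for t, r in runs.items()}
        win = identify_windows(runs["12C"], runs["13C"], config.window_params)
        sio.write_windows_json(win, out / "windows.json")
        return fits, win

    fits, windows = windows_stage()

    # --- REF calling ------------------------------------------------------
    @_stage("ref")
    def ref_stage():
        aggregates = aggregate_window_abundance(table, windows, runs)
        records = call_active_degraders(table, aggregates, config.calling)
        sio.write_ref_calls(records, out / "ref_calls.tsv")
        return records

    records = ref_stage()
    active = [r for r in records if r.active]

    # --- Raman screen -----------------------------------------------------
    @_stage("raman")
    def raman_stage():
        calls = classify_cells(spectra, config.raman_params)
        sio.write_label_calls(calls, out / "label_calls.tsv")
        manifest = build_sorting_manifest(calls)
        sio.write_sorting_manifest(manifest, out / "sorting_manifest.txt")
        return calls, manifest

    label_calls, manifest = raman_stage()

    # --- cultivation design -----------------------------------------------
    @_stage("cultivation")
    def cultivation_stage():
        if config.annotations_path is not None:
            ann = sio.read_annotations(config.annotations_path)
            ann_source = "file"
        else:
            ann = AnnotationSet(bin_id="synthetic-demo", labels=list(DEMO_ANNOTATIONS))
            ann_source = "synthetic-demo"
        recipe = recommend_medium(ann)
        sio.write_medium_json(recipe, out / "medium.json")

        if len(active) >= 2:
            a, b = active[0], active[1]  # already sorted by REF descending
            design = design_ratios(
                a.a13_heavy, b.a13_heavy, strain_a=a.asv_id, strain_b=b.asv_id
            )
        else:
            design = None
        if design is not None:
            sio.write_ratios_json(design, out / "ratios.json")
        return recipe, design, ann_source

    recipe, design, ann_source = cultivation_stage()

    # --- report -----------------------------------------------------------
    @_stage("report")
    def report_stage():
        report = {
            "seed": config.seed,
            "inputs": "simulated" if simulated else "files",
            "parameters": {
                "calling": {
                    "top_n": config.calling.top_n,
                    "threshold": config.calling.threshold,
                    "pseudocount": config.calling.pseudocount,
                },
                "windows": {
                    "bd_split": config.window_params.bd_split,
                    "ratio_min": config.window_params.ratio_min,
                    "min_copy_frac": config.window_params.min_copy_frac,
                    "light_rel_height": config.window_params.light_rel_height,
                },
                "raman": {
                    "als_lam": config.raman_params.als_lam,
                    "als_p": config.raman_params.als_p,
                    "snr_k": config.raman_params.snr_k,
                },
            },
            "bd_fits": {
                t: {"slope": f.slope, "intercept": f.intercept, "r": f.r,
                    "degenerate": f.degenerate}
                for t, f in fits.items()
            },
            "windows": windows.to_dict(),
            "n_asvs": len(table.asv_ids),
            "n_active_asvs": len(active),
            "active_asvs": [
                {"asv_id": r.asv_id, "ref": r.ref, "rank": r.rank} for r in active
            ],
            "n_cells": len(label_calls),
            "n_labelled_cells": manifest["n_labelled"],
            "medium": {
                "annotation_source": ann_source,
                "base": recipe.base,
                "supplements": [
                    {"component": s.component, "amount": s.amount, "unit": s.unit,
                     "rule": s.rule}
                    for s in recipe.supplements
                ],
            },
            "ratio_design": (
                None
                if design is None
                else {
                    "strain_a": design.strain_a,
                    "strain_b": design.strain_b,
                    "recommended_ratio": design.recommended_ratio,
                    "log_ratio": design.log_ratio,
                }
            ),
        }
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2)
        (out / "report.md").write_text(_report_markdown(report), encoding="utf-8")
        return report

    return report_stage()


def _report_markdown(report: dict) -> str:
    lines = [
        "# SIP–RACS pipeline report",
        "",
        f"- seed: {report['seed']} (inputs: {report['inputs']})",
        f"- windows: light {report['windows']['light']}, heavy {report['windows']['heavy']}"
        f" (fallback: {report['windows']['fallback']})",
        f"- ASVs: {report['n_asvs']}, active degraders: {report['n_active_asvs']}",
    ]
    for a in report["active_asvs"]:
        lines.append(f"    - {a['asv_id']}: REF = {a['ref']:.3g} (rank {a['rank']})")
    lines.append(
        f"- cells screened: {report['n_cells']}, called ¹³C-labelled: "
        f"{report['n_labelled_cells']}"
    )
    supplements = report["medium"]["supplements"]
    lines.append(f"- medium: {report['medium']['base']} + {len(supplements)} supplements")
    for s in supplements:
        lines.append(f"    - {s['component']}: {s['amount']} {s['unit']} ({s['rule']})")
    rd = report["ratio_design"]
    if rd:
        lines.append(
            f"- consortium ratio {rd['strain_a']}:{rd['strain_b']} = "
            f"{rd['recommended_ratio']} (log2 abundance ratio {rd['log_ratio']:.3f})"
        )
    return "\n".join(lines) + "\n"
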