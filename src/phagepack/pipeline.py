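"""Orchestration of the analysis stages into a single study report.

``run_study`` executes every stage whose input is available -- lattice
geometry and packing from config alone; shell detection from a radial
profile; composition and substitution from a peak-area table; ladder and
core decomposition from an MS peak set; the genome mass model from config
constants or a FASTA -- and wires the cross-stage dependencies (an
estimated substitution fraction feeds the mass model, which joins the
packing result in the density report).  Stages with missing inputs are
marked skipped and do not affect the others.  Report rendering is
deterministic: identical config and inputs give byte-identical JSON.
"""

from __future__ import annotations

import hashlib
import html as _html
import importlib.resources
import json
import logging
import time
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .capsid_geometry import (
    CapsidLattice,
    packing_density,
    subunit_count,
)
from .genome_mass_model import (
    base_composition,
    mass_model,
    modified_density_report,
    read_fasta,
)
from .ms_ladder import MsPeakSet, detect_ladders, find_core, modification_mass_summary
from .nucleoside_composition import (
    composition_from_areas,
    pairing_check,
    read_areas,
    substitution_fraction,
)
from .radial_layers import RadialProfile, detect_shells, spacing_report

log = logging.getLogger("phagepack")

RENDER_FORMATS = ("json", "text", "html")


def load_preset(name: str = "yera41_paper") -> dict:
    """Load a shipped named configuration preset."""
    ref = importlib.resources.files("phagepack") / "presets" / f"{name}.yaml"
    with ref.open() as fh:
        return yaml.safe_load(fh)


def load_config(path=None) -> dict:
    """Load a YAML/JSON config file, or the default preset when ``path`` is None."""
    if path is None:
        return load_preset()
    with open(path) as fh:
        return yaml.safe_load(fh)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _skipped(what: str) -> dict:
    return {"status": f"skipped: missing {what}"}


def run_study(
    config: dict | None = None,
    inputs: dict[str, Any] | None = None,
    seed: int = 0,
) -> dict:
    """Run all available stages and assemble the study report.

    ``inputs`` may provide ``profile`` (RadialProfile or path), ``areas``
    (DataFrame or path), ``peaks`` (MsPeakSet or path) and ``fasta`` (path).
    Every stage is optional; config-only stages always run.
    """
    config = config if config is not None else load_preset()
    inputs = inputs or {}
    report: dict[str, Any] = {}
    t0 = time.perf_counter()

    # --- geometry -------------------------------------------------------
    geo = config.get("geometry", {})
    lattice = CapsidLattice.from_hk(int(geo.get("h", 4)), int(geo.get("k", 2)))
    report["geometry"] = {
        "h": lattice.h,
        "k": lattice.k,
        "t_number": lattice.t_number,
        "handedness": lattice.handedness.value,
        "subunits": subunit_count(lattice),
    }
    log.info("geometry stage done (%.3fs)", time.perf_counter() - t0)

    # --- packing --------------------------------------------------------
    packing_rows = []
    packings = {}
    for capsid, params in config.get("capsids", {}).items():
        for copies in params.get("copies", [1]):
            res = packing_density(
                params["genome_length_bp"], copies, params["internal_volume_nm3"]
            )
            packings[(capsid, copies)] = res
            packing_rows.append(
                {
                    "capsid": capsid,
                    "copies": copies,
                    "density_bp_per_nm3": round(res.density, 2),
                    "spacing_nm": round(res.spacing_equivalent, 2),
                }
            )
    report["packing"] = {"table": packing_rows} if packing_rows else _skipped("capsid config")

    # --- shells ---------------------------------------------------------
    profile = inputs.get("profile")
    if profile is None:
        report["shells"] = _skipped("radial profile")
    else:
        if not isinstance(profile, RadialProfile):
            profile = RadialProfile.from_file(profile)
        sh_cfg = config.get("shells", {})
        shells = detect_shells(
            profile,
            min_prominence=sh_cfg.get("min_prominence", 0.1),
            min_separation=sh_cfg.get("min_separation_A", 15.0),
        )
        stage = {
            "shell_radii_A": [round(x, 2) for x in shells.shell_radii],
            "labels": shells.shell_labels,
            "spacings_A": [round(x, 2) for x in shells.spacings],
        }
        if shells.warning:
            stage["warning"] = shells.warning
        if len(shells.shell_radii) >= 2:
            tbl = spacing_report(shells, config.get("rise_per_bp_nm", 0.34))
            stage["spacing_table"] = json.loads(tbl.round(3).to_json(orient="records"))
        report["shells"] = stage

    # --- composition + substitution ------------------------------------
    comp_cfg = config.get("composition", {})
    expected_t = comp_cfg.get("expected_t_percent", 34.0)
    fasta = inputs.get("fasta")
    genome_comp = None
    if fasta is not None:
        genome_comp = base_composition(read_fasta(fasta))
        expected_t = genome_comp.T_percent
        report["genome"] = {
            "length_bp": genome_comp.length,
            "T_percent": round(genome_comp.T_percent, 2),
            "AT_bp": genome_comp.AT_bp,
        }
    areas = inputs.get("areas")
    if areas is None:
        report["composition"] = _skipped("peak-area table")
        observed_t = comp_cfg.get("observed_t_percent")
    else:
        if not isinstance(areas, pd.DataFrame):
            areas = read_areas(areas)
        comp = composition_from_areas(areas)
        report["composition"] = {
            "percent": {n: round(p, 1) for n, p in comp.percent.items()},
            "class_totals": {c: round(t, 1) for c, t in comp.class_totals.items()},
            "pairing_flags": pairing_check(
                comp, comp_cfg.get("pairing_tolerance", 0.25)
            ),
        }
        observed_t = comp.percent["T"]
    if observed_t is None:
        report["substitution"] = _skipped("observed T percentage")
        est_fraction = None
    else:
        est = substitution_fraction(expected_t, observed_t)
        # the mass model consumes the whole-percent figure the estimate reports
        est_fraction = est.percent_modified / 100.0
        report["substitution"] = {
            "expected_T_percent": round(est.expected_T_percent, 2),
            "observed_T_percent": round(est.observed_T_percent, 2),
            "fraction_modified": round(est.fraction_modified, 4),
            "percent_modified": est.percent_modified,
        }

    # --- MS ladder ------------------------------------------------------
    peaks = inputs.get("peaks")
    if peaks is None:
        report["ms"] = _skipped("MS peak set")
    else:
        if not isinstance(peaks, MsPeakSet):
            peaks = MsPeakSet.from_json(peaks)
        ms_cfg = config.get("ms", {})
        tol = ms_cfg.get("tolerance", peaks.tolerance)
        ladders = detect_ladders(peaks, ms_cfg.get("min_ladder_length", 2), tol)
        decomp = find_core(peaks, tol)
        stage: dict[str, Any] = {
            "ladders": [
                {
                    "members": [round(m, 3) for m in lad.members],
                    "residue_mass": round(lad.residue_mass, 3),
                    "length": lad.length,
                }
                for lad in ladders
            ],
            "core_status": decomp.status,
        }
        if decomp.status == "ok" and ladders:
            stage["summary"] = {
                k: (round(v, 3) if isinstance(v, float) else v)
                for k, v in modification_mass_summary(decomp, ladders[0], tol).items()
            }
        report["ms"] = stage

    # --- mass model + density report -----------------------------------
    mm_cfg = config.get("mass_model", {})
    if mm_cfg:
        length = genome_comp.length if genome_comp else mm_cfg.get("genome_length_bp")
        at_bp = genome_comp.AT_bp if genome_comp else mm_cfg.get("at_bp")
        fraction = (
            est_fraction
            if est_fraction is not None
            else mm_cfg.get("substitution_fraction", 0.0)
        )
        mm = mass_model(
            length,
            at_bp,
            fraction,
            mm_cfg.get("bp_mass_da", 618.0),
            mm_cfg.get("mod_mass_da", 1044.0),
        )
        report["mass_model"] = mm.summary()
        density_stage = {}
        for (capsid, copies), res in packings.items():
            rep = modified_density_report(
                mm, res, config.get("reference_density_bp_nm3")
            )
            density_stage[f"{capsid}/x{copies}"] = {
                k: (round(v, 3) if isinstance(v, float) else v)
                for k, v in rep.items()
            }
        report["density_report"] = density_stage if density_stage else _skipped(
            "capsid config"
        )
    else:
        report["mass_model"] = _skipped("mass-model config")
        report["density_report"] = _skipped("mass-model config")

    report["provenance"] = {
        "package": "phagepack",
        "version": __version__,
        "seed": seed,
        "config_name": config.get("name", "custom"),
        "config_sha256": _config_hash(config),
        "inputs": sorted(
            k for k, v in inputs.items() if v is not None
        ),
        "units": {
            "density": "bp/nm^3",
            "spacing": "A (profile) / nm (packing)",
            "mass": "Da",
            "percent": "%",
        },
    }
    log.info("study complete (%.3fs)", time.perf_counter() - t0)
    return report


def _text_report(report: dict) -> str:
    lines = ["# phagepack study report", ""]
    geo = report.get("geometry", {})
    if "t_number" in geo:
        lines += [
            f"Lattice (h={geo['h']}, k={geo['k']}): T = {geo['t_number']}, "
            f"{geo['handedness']}, {geo['subunits']} subunits",
            "",
        ]
    pk = report.get("packing", {})
    if "table" in pk:
        lines.append("Packing density (bp/nm^3) and equivalent spacing (nm):")
        for row in pk["table"]:
            lines.append(
                f"  {row['capsid']} x{row['copies']}: "
                f"{row['density_bp_per_nm3']} bp/nm^3, {row['spacing_nm']} nm"
            )
        lines.append("")
    comp = report.get("composition", {})
    if "percent" in comp:
        lines.append("Nucleoside composition (% within class):")
        lines.append("  nucleoside  percent")
        for n, p in comp["percent"].items():
            lines.append(f"  {n:<10}  {p}")
        for c, t in comp["class_totals"].items():
            lines.append(f"  Total ({c})  {t}")
        if comp.get("pairing_flags"):
            lines.append(f"  flags: {', '.join(comp['pairing_flags'])}")
        lines.append("")
    sub = report.get("substitution", {})
    if "percent_modified" in sub:
        lines.append(
            f"Thymidine substitution: expected T {sub['expected_T_percent']}%, "
            f"observed {sub['observed_T_percent']}% -> {sub['percent_modified']}% modified"
        )
        lines.append("")
    ms = report.get("ms", {})
    if ms.get("summary"):
        s = ms["summary"]
        lines.append(
            f"MS decomposition: core {s['core_mass_da']} Da (spacer "
            f"{s['spacer_mass_da']} Da), residue {s['residue_mass_da']} Da "
            f"(>= {s['min_residue_count']} residues), "
            f"+{s['per_base_addition_da']} Da per modified base"
        )
        lines.append("")
    mm = report.get("mass_model", {})
    if "unmodified_mass_MDa" in mm:
        lines.append(
            f"Mass model: {mm['length_bp']} bp, {mm['AT_bp']} A:T pairs, "
            f"{mm['substitution_percent']}% substituted -> "
            f"{mm['unmodified_mass_MDa']} MDa unmodified + {mm['added_mass_MDa']} MDa "
            f"added ({mm['relative_increase_percent']}% increase)"
        )
        lines.append("")
    for stage, payload in report.items():
        if isinstance(payload, dict) and str(payload.get("status", "")).startswith(
            "skipped"
        ):
            lines.append(f"[{stage}] {payload['status']}")
    prov = report.get("provenance", {})
    lines += [
        "",
        f"provenance: {prov.get('package')} {prov.get('version')} | "
        f"config {prov.get('config_name')} ({prov.get('config_sha256')}) | "
        f"seed {prov.get('seed')}",
    ]
    return "\n".join(lines) + "\n"


def render_report(report: dict, fmt: str = "json") -> str:
    """Render a study report as JSON, plain text or self-contained HTML.

    JSON rendering is canonical (sorted keys) and round-trips losslessly.
    """
    if fmt == "json":
        return json.dumps(report, sort_keys=True, indent=2) + "\n"
    if fmt == "text":
        return _text_report(report)
    if fmt == "html":
        body = _html.escape(_text_report(report))
        return (
            "<!DOCTYPE html><html><head><meta charset='utf-8'>"
            "<title>phagepack report</title></head>"
            f"<body><pre>{body}</pre></body></html>\n"
        )
    raise ValueError(f"unknown format {fmt!r}; supported: {', '.join(RENDER_FORMATS)}")
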