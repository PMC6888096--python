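"""Configuration-driven analysis runs producing a structured report.

A config (JSON file or dict) names the input CSVs per measurement plus the
surfactant/solvent descriptors; the runner executes every stage whose input
is present, chains derived quantities (tail geometry → CPP, CMC → virial
fit → hydration budget), and emits a machine-readable report with units and
fit diagnostics, plus a small human-readable summary table.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

from . import conductimetry, fluorimetry, tensiometry, viscometry
from .io import (
    BUNDLED_SURFACTANTS,
    MicelleKitError,
    ResponseKind,
    SolventSpec,
    SurfactantSpec,
    TailChemistry,
    logger,
    read_titration,
)
from .packing import fluorocarbon_tail, TailGeometry
from .viscometry import HydrationScenario

REQUIRED_KEYS = ("surfactant", "inputs")


class ConfigError(MicelleKitError):
    """The run configuration is missing required keys or malformed."""


def _surfactant_from_config(cfg: dict) -> SurfactantSpec:
    s = cfg["surfactant"]
    if isinstance(s, str):
        try:
            return BUNDLED_SURFACTANTS[s.lower()]
        except KeyError:
            raise ConfigError(
                f"unknown surfactant {s!r}; bundled: {sorted(BUNDLED_SURFACTANTS)}"
            ) from None
    return SurfactantSpec(
        name=s["name"],
        tail_carbons=int(s["tail_carbons"]),
        tail_chemistry=TailChemistry(s.get("tail_chemistry", "fluorocarbon")),
        molecular_volume=float(s["molecular_volume"]),
        ion_valences=tuple(s.get("ion_valences", (-1, 1))),
    )


def _solvent_from_config(cfg: dict) -> SolventSpec:
    s = cfg.get("solvent", {})
    if isinstance(s, SolventSpec):
        return s
    return SolventSpec(
        cosolvent_name=s.get("cosolvent_name", "urea"),
        cosolvent_molarity=float(s.get("cosolvent_molarity", 0.0)),
        cosolvent_molecular_volume=float(s.get("cosolvent_molecular_volume", 0.075)),
        water_molecular_volume=float(s.get("water_molecular_volume", 0.030)),
    )


def _tail(spec: SurfactantSpec, cfg: dict) -> TailGeometry | None:
    t = cfg.get("tail", {})
    if "volume" in t and "length" in t:
        return TailGeometry(volume=float(t["volume"]), length=float(t["length"]),
                            carbons=spec.tail_carbons)
    if spec.tail_chemistry is TailChemistry.FLUOROCARBON:
        return fluorocarbon_tail(spec.tail_carbons)
    # hydrocarbon tails need explicit user geometry
    return None


def run_report(config: dict | str | Path) -> dict[str, Any]:
    """Run every configured stage and assemble the report.

    Missing stage inputs mark that section ``{"status": "absent"}``; a stage
    that fails is flagged with its error message and the run continues.
    """
    if not isinstance(config, dict):
        config = json.loads(Path(config).read_text())
    missing = [k for k in REQUIRED_KEYS if k not in config]
    if missing:
        raise ConfigError(f"config missing required keys: {missing} "
                          f"(required: {list(REQUIRED_KEYS)})")

    spec = _surfactant_from_config(config)
    solvent = _solvent_from_config(config)
    tail = _tail(spec, config)
    inputs: dict = config["inputs"]
    temps: dict = config.get("temperature_c", {})
    report: dict[str, Any] = {
        "surfactant": {
            "name": spec.name,
            "tail_carbons": spec.tail_carbons,
            "molecular_volume_nm3": spec.molecular_volume,
        },
        "solvent": {
            "cosolvent": solvent.cosolvent_name,
            "cosolvent_molarity_M": solvent.cosolvent_molarity,
        },
        "stages": {},
    }
    stages = report["stages"]

    def run_stage(name, fn):
        if name not in inputs:
            stages[name] = {"status": "absent"}
            return None
        try:
            result = fn()
            stages[name] = {"status": "ok", **result}
            return result
        except MicelleKitError as exc:
            logger.warning("stage %s failed: %s", name, exc)
            stages[name] = {"status": "failed", "error": str(exc)}
            return None

    # --- conductivity ---
    def _conduct():
        series = read_titration(inputs["conductivity"], ResponseKind.CONDUCTIVITY,
                                temps.get("conductivity", 24.0))
        fit = conductimetry.fit_two_segments(series)
        return {
            "cmc_mM": fit.cmc, "alpha": fit.alpha,
            "s1_uS_cm_mM": fit.s1, "s2_uS_cm_mM": fit.s2,
            "rss": fit.rss, "n_below": fit.n_below, "n_above": fit.n_above,
            "flags": list(fit.flags),
        }

    conduct = run_stage("conductivity", _conduct)

    # --- surface tension ---
    def _tension():
        series = read_titration(inputs["tension"], ResponseKind.SURFACE_TENSION,
                                temps.get("tension", 24.0))
        res = tensiometry.analyze_tension(
            series, n_prefactor=config.get("n_prefactor", spec.default_n_prefactor),
            tail=tail,
        )
        out = {
            "slope_mN_m_decade": res.slope,
            "gamma_max_mol_cm2": res.gamma_max,
            "a_min_A2": res.a_min,
            "cmc_tension_mM": res.cmc_tension,
            "plateau_gamma_mN_m": res.plateau_gamma,
            "n_prefactor": res.n_prefactor,
            "flags": list(res.flags),
        }
        if res.packing is not None:
            out["cpp"] = res.packing.cpp
            out["cpp_display"] = res.packing.cpp_display
            out["shape_class"] = res.packing.shape_class.value
            out["shape_boundary"] = res.packing.boundary
        return out

    tension = run_stage("tension", _tension)

    # --- fluorescence ---
    def _fluor():
        series = read_titration(inputs["fluorescence"], ResponseKind.I1I3,
                                temps.get("fluorescence", 22.0))
        fit = fluorimetry.cmc_from_ratio_curve(series)
        return {"cmc_fluor_mM": fit.cmc, "flags": list(fit.flags)}

    run_stage("fluorescence", _fluor)

    # --- viscosity ---
    def _visc():
        series = read_titration(inputs["viscosity"], ResponseKind.RELATIVE_VISCOSITY,
                                temps.get("viscosity", 20.0))
        cmc = config.get("cmc_mM")
        cmc_source = "user"
        if cmc is None and conduct is not None:
            cmc, cmc_source = conduct["cmc_mM"], "conductivity"
        if cmc is None and tension is not None and tension.get("cmc_tension_mM"):
            cmc, cmc_source = tension["cmc_tension_mM"], "tension"
        if cmc is None:
            raise ConfigError("viscosity stage needs a CMC (user, conductivity or tension)")
        nu = float(config.get("nu", viscometry.NU_SPHERE))
        fit = viscometry.fit_virial(series, cmc_mM=float(cmc), nu=nu)
        out = {
            "p1": fit.p1, "p2": fit.p2, "k1": fit.k1, "nu": fit.nu,
            "v_shyd_nm3": fit.v_shyd, "cmc_used_mM": fit.c1_mM,
            "cmc_source": cmc_source, "rss": fit.rss, "flags": list(fit.flags),
        }
        if fit.v_shyd >= spec.molecular_volume:
            ref = config.get("reference_water_volume_nm3")
            budget = viscometry.hydration_budget(
                fit.v_shyd, spec, solvent, v_water_total_reference=ref,
                scenario=HydrationScenario.DIRECT,
            )
            out["hydration"] = {
                "v_water_total_nm3": budget.v_water_total,
                "n_water": budget.n_water,
                "v_cosolvent_total_nm3": budget.v_cosolvent_total,
                "n_cosolvent": budget.n_cosolvent,
                "flags": list(budget.flags),
            }
        return out

    run_stage("viscosity", _visc)
    return report


def format_summary(report: dict) -> str:
    """Human-readable summary table (CMC and α per technique)."""
    rows = [("stage", "CMC (mM)", "alpha", "notes")]
    s = report["stages"]

    def fmt(x, nd=2):
        return "-" if x is None else f"{x:.{nd}f}"

    if s.get("conductivity", {}).get("status") == "ok":
        c = s["conductivity"]
        rows.append(("conductivity", fmt(c["cmc_mM"]), fmt(c["alpha"]),
                     ",".join(c["flags"]) or ""))
    else:
        rows.append(("conductivity", "-", "-", s.get("conductivity", {}).get("status", "absent")))
    if s.get("tension", {}).get("status") == "ok":
        t = s["tension"]
        note = f"Amin={t['a_min_A2']:.1f} A^2"
        if "cpp" in t:
            note += f", CPP={t['cpp_display']:.2f} ({t['shape_class']})"
        rows.append(("tension", fmt(t.get("cmc_tension_mM")), "-", note))
    else:
        rows.append(("tension", "-", "-", s.get("tension", {}).get("status", "absent")))
    if s.get("fluorescence", {}).get("status") == "ok":
        rows.append(("fluorescence", fmt(s["fluorescence"]["cmc_fluor_mM"]), "-", ""))
    else:
        rows.append(("fluorescence", "-", "-", s.get("fluorescence", {}).get("status", "absent")))
    if s.get("viscosity", {}).get("status") == "ok":
        v = s["viscosity"]
        note = f"Vshyd={v['v_shyd_nm3']:.3f} nm^3 (nu={v['nu']})"
        rows.append(("viscosity", fmt(v["cmc_used_mM"]), "-", note))
    else:
        rows.append(("viscosity", "-", "-", s.get("viscosity", {}).get("status", "absent")))

    widths = [max(len(r[i]) for r in rows) for i in range(4)]
    lines = ["  ".join(cell.ljust(w) for cell, w in zip(r, widths)).rstrip() for r in rows]
    lines.insert(1, "  ".join("-" * w for w in widths))
    return "\n".join(lines)
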