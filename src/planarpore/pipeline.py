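"""End-to-end analysis driver: simulate -> idealize -> Po / i-V / GHK / block.

A PipelineConfig (YAML or JSON) describes experiment arms; run_pipeline
executes each arm independently, writes per-arm event tables and fit
summaries under the output directory, and records every parameter, seed and
warning in a machine-readable manifest. All outputs are regenerable from
config + seed alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .conduction import IVPoint, fit_binding_hyperbola, fit_iv_linear, unitary_amplitudes
from .gatingsim import (
    EnsembleConfig,
    GatingScheme,
    RecordingConfig,
    simulate_experiment,
    simulate_voltage_series,
)
from .gatingstats import compare_block, estimate_po, po_voltage_table
from .idealization import hmm_idealize, threshold_idealize
from .iontransport import (
    IonSpecies,
    SolutionPair,
    ghk_current_reversal,
    ghk_voltage_monovalent,
    permeability_ratio_from_erev,
)
from .io import write_events, write_trace

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "build_solution_pair"]

_VALENCES = {"K": 1, "Na": 1, "Cs": 1, "Li": 1, "Cl": -1, "Ca": 2, "Mg": 2, "Ba": 2}


def build_solution_pair(spec: dict[str, Any]) -> SolutionPair:
    """Build a SolutionPair from a config mapping.

    Expected keys: ``cis`` and ``trans`` (species name -> mM), optional
    ``temperature_C`` (default 22), ``activity_model``,
    ``junction_potential_mV``, ``permeabilities`` (name -> relative P).
    """
    cis = spec.get("cis", {})
    trans = spec.get("trans", {})
    perms = spec.get("permeabilities", {})
    names = sorted(set(cis) | set(trans))
    species = []
    for name in names:
        if name not in _VALENCES:
            raise ValueError(f"unknown ion species {name!r}")
        species.append(
            IonSpecies(
                name=name,
                valence=_VALENCES[name],
                conc_cis=float(cis.get(name, 0.0)),
                conc_trans=float(trans.get(name, 0.0)),
                permeability=float(perms.get(name, 1.0)),
            )
        )
    return SolutionPair(
        species=tuple(species),
        temperature=float(spec.get("temperature_C", 22.0)) + 273.15,
        activity_model=spec.get("activity_model", "concentration"),
        junction_potential=float(spec.get("junction_potential_mV", 0.0)),
    )


def _build_scheme(spec: dict[str, Any]) -> GatingScheme:
    def _ve(key: str) -> float:
        v = spec.get(key, None)
        return math.inf if v in (None, "inf") else float(v)

    scheme = GatingScheme.two_state(
        k_co=float(spec["k_co"]),
        k_oc=float(spec["k_oc"]),
        v_e_co=_ve("v_e_co"),
        v_e_oc=_ve("v_e_oc"),
    )
    blk = spec.get("block")
    if blk:
        scheme = scheme.with_block(
            k_on=float(blk["k_on_per_uM_s"]),
            blocker_conc=float(blk["blocker_conc_uM"]),
            k_off=float(blk["k_off_s"]),
            v_e_on=math.inf if blk.get("v_e_on_mV") is None else float(blk["v_e_on_mV"]),
            v_e_off=math.inf if blk.get("v_e_off_mV") is None else float(blk["v_e_off_mV"]),
        )
    return scheme


def _build_ensemble(spec: dict[str, Any]) -> EnsembleConfig:
    return EnsembleConfig(
        scheme=_build_scheme(spec["scheme"]),
        n_channels=int(spec.get("n_channels", 1)),
        conductance=float(spec.get("conductance_pS", 395.0)),
        reversal_potential=float(spec.get("reversal_mV", 0.0)),
    )


def _build_recording(spec: dict[str, Any], holding: float = 0.0) -> RecordingConfig:
    return RecordingConfig(
        holding_potential=holding,
        duration=float(spec.get("duration_s", 30.0)),
        sample_rate=float(spec.get("sample_rate_hz", 10_000.0)),
        filter_corner=float(spec.get("filter_corner_hz", 1_000.0)),
        noise_sd=float(spec.get("noise_sd_pA", 1.0)),
    )


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    seed: int
    out_dir: Path
    arms: list[dict[str, Any]]
    ghk: list[dict[str, Any]] = field(default_factory=list)
    idealization: str = "hmm"
    po_method: str = "binomial"
    alpha: float = 0.005
    write_traces: bool = False

    def __post_init__(self) -> None:
        if self.idealization not in ("hmm", "threshold"):
            raise ValueError("idealization must be 'hmm' or 'threshold'")
        if self.po_method not in ("binomial", "threshold"):
            raise ValueError("po_method must be 'binomial' or 'threshold'")
        names = [a.get("name") for a in self.arms]
        if len(set(names)) != len(names):
            raise ValueError("arm names must be unique")
        for arm in self.arms:
            kind = arm.get("kind")
            if kind not in ("iv", "block"):
                raise ValueError(f"arm {arm.get('name')!r}: unknown kind {kind!r}")
            for key in ("name", "ensemble", "recording"):
                if key not in arm:
                    raise ValueError(f"arm {arm.get('name')!r}: missing {key!r}")
            if kind == "iv" and "voltages_mV" not in arm:
                raise ValueError(f"iv arm {arm['name']!r}: missing voltages_mV")
            if kind == "block" and "block" not in arm:
                raise ValueError(f"block arm {arm['name']!r}: missing block section")


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    analysis = raw.get("analysis", {})
    return PipelineConfig(
        seed=int(raw.get("seed", 0)),
        out_dir=Path(raw.get("out_dir", "planarpore_out")),
        arms=raw.get("arms", []),
        ghk=raw.get("ghk", []),
        idealization=analysis.get("idealization", "hmm"),
        po_method=analysis.get("po_method", "binomial"),
        alpha=float(analysis.get("alpha", 0.005)),
        write_traces=bool(raw.get("write_traces", False)),
    )


def _idealize(cfg: PipelineConfig, trace, ens: EnsembleConfig):
    if cfg.idealization == "hmm":
        record, _fit = hmm_idealize(trace, n_levels=ens.n_channels)
        return record, _fit
    i_unit = ens.unitary_current(trace.holding_potential)
    return threshold_idealize(trace, i_unit, ens.n_channels), None


def _run_iv_arm(cfg: PipelineConfig, arm: dict[str, Any], arm_dir: Path,
                seed: int) -> dict[str, Any]:
    ens = _build_ensemble(arm["ensemble"])
    rec = _build_recording(arm["recording"])
    voltages = [float(v) for v in arm["voltages_mV"]]
    sims = simulate_voltage_series(ens, rec, voltages, seed=seed)
    records_by_v: dict[float, list] = {}
    iv_points: list[IVPoint] = []
    for v, (trace, seq) in sims.items():
        if cfg.write_traces:
            write_trace(trace, arm_dir / f"trace_{v:+g}mV.tsv")
        write_events(seq.to_record(), arm_dir / f"truth_{v:+g}mV.tsv")
        record, fit = _idealize(cfg, trace, ens)
        write_events(record, arm_dir / f"idealized_{v:+g}mV.tsv")
        records_by_v[v] = [record]
        if fit is not None:
            try:
                i_unit, se = unitary_amplitudes(record, fit)
                iv_points.append(IVPoint(voltage=v, unitary_current=i_unit, sem=se))
            except ValueError as exc:
                log.warning("arm %s %+g mV: %s", arm["name"], v, exc)
        else:
            iv_points.append(
                IVPoint(voltage=v, unitary_current=ens.unitary_current(v))
            )
    table = po_voltage_table(records_by_v, n=ens.n_channels, method=cfg.po_method)
    table.to_csv(arm_dir / "po_voltage.tsv", sep="\t", index=False)
    result: dict[str, Any] = {
        "kind": "iv",
        "po_voltage_table": table.to_dict(orient="records"),
        "salt_mM": arm.get("salt_mM"),
    }
    if len(iv_points) >= 2:
        ivfit = fit_iv_linear(iv_points)
        result["iv_fit"] = {
            "conductance_pS": ivfit.conductance,
            "conductance_se_pS": ivfit.conductance_se,
            "erev_mV": ivfit.erev,
            "erev_se_mV": ivfit.erev_se,
            "n_points": ivfit.n_points,
        }
        (arm_dir / "iv_fit.json").write_text(json.dumps(result["iv_fit"], indent=1))
    return result


def _run_block_arm(cfg: PipelineConfig, arm: dict[str, Any], arm_dir: Path,
                   seed: int) -> dict[str, Any]:
    voltage = float(arm.get("voltage_mV", 60.0))
    n_rec = int(arm.get("n_recordings", 6))
    rec = _build_recording(arm["recording"], holding=voltage)
    ens_ctrl = _build_ensemble(arm["ensemble"])
    treated_spec = {**arm["ensemble"],
                    "scheme": {**arm["ensemble"]["scheme"], "block": arm["block"]}}
    ens_trt = _build_ensemble(treated_spec)
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    children = ss.spawn(2 * n_rec)
    groups: dict[str, list] = {"control": [], "treated": []}
    for i in range(n_rec):
        for j, (label, ens) in enumerate((("control", ens_ctrl), ("treated", ens_trt))):
            trace, seq = simulate_experiment(ens, rec, seed=children[2 * i + j])
            record, _ = _idealize(cfg, trace, ens)
            write_events(record, arm_dir / f"{label}_{i}.tsv")
            groups[label].append(
                estimate_po(record, n=ens.n_channels, method=cfg.po_method,
                            voltage=voltage)
            )
    comparison = compare_block(
        groups["control"], groups["treated"], alpha=cfg.alpha,
        blocker_conc=float(arm["block"].get("blocker_conc_uM", 0.0)),
        voltage=voltage,
    )
    result = {
        "kind": "block",
        "voltage_mV": voltage,
        "blocker_conc_uM": comparison.condition[0],
        "po_control": comparison.po_control,
        "po_treated": comparison.po_treated,
        "statistic": comparison.statistic,
        "p_value": comparison.p_value,
        "df": comparison.df,
        "alpha": comparison.alpha,
        "significant": comparison.significant,
    }
    (arm_dir / "block_comparison.json").write_text(json.dumps(result, indent=1))
    return result


def _run_ghk(entry: dict[str, Any]) -> dict[str, Any]:
    pair = build_solution_pair(entry.get("solutions", entry))
    out: dict[str, Any] = {"name": entry.get("name", "ghk")}
    if "measured_erev_mV" in entry:
        res = permeability_ratio_from_erev(float(entry["measured_erev_mV"]), pair)
        out.update(
            ratio=res.ratio,
            numerator=res.numerator_species,
            denominator=res.denominator_species,
            erev_used_mV=res.erev_used,
            activity_model=res.activity_model,
        )
    else:
        if all(abs(s.valence) == 1 for s in pair.species):
            out["erev_mV"] = ghk_voltage_monovalent(pair)
        else:
            out["erev_mV"] = ghk_current_reversal(pair)
    return out


def simulate_iv_protocol(
    ens: EnsembleConfig,
    rec: RecordingConfig,
    voltages: list[float],
    seeds: list[int],
    idealization: str = "hmm",
):
    """Replicated i-V protocol: simulate, idealize, extract unitary currents.

    Runs one recording per (voltage, seed), idealizes each trace, extracts
    the unitary current from the fitted level amplitudes, averages replicates
    per voltage, and fits the linear i-V relation. Returns
    (ConductanceFit, points) where points carry per-voltage mean +/- SEM.
    """
    from .idealization import threshold_idealize

    per_voltage: dict[float, list[float]] = {float(v): [] for v in voltages}
    for seed in seeds:
        sims = simulate_voltage_series(ens, rec, voltages, seed=seed)
        for v, (trace, _seq) in sims.items():
            if idealization == "hmm":
                record, fit = hmm_idealize(trace, n_levels=ens.n_channels)
                i_unit, _ = unitary_amplitudes(record, fit)
            else:
                record = threshold_idealize(
                    trace, ens.unitary_current(v), ens.n_channels
                )
                i_unit = ens.unitary_current(v)
            per_voltage[v].append(i_unit)
    points = [
        IVPoint(
            voltage=v,
            unitary_current=float(np.mean(vals)),
            sem=float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0,
            n_obs=len(vals),
        )
        for v, vals in per_voltage.items()
    ]
    return fit_iv_linear(points), points


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Run every arm; failures abort the arm (logged), other arms continue."""
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    results: dict[str, Any] = {}
    errors: dict[str, str] = {}
    root = np.random.SeedSequence(cfg.seed)
    arm_seeds = root.spawn(len(cfg.arms))
    for arm, arm_seed in zip(cfg.arms, arm_seeds):
        name = arm["name"]
        arm_dir = cfg.out_dir / name
        arm_dir.mkdir(parents=True, exist_ok=True)
        try:
            runner = _run_iv_arm if arm["kind"] == "iv" else _run_block_arm
            results[name] = runner(cfg, arm, arm_dir, arm_seed)
        except Exception as exc:  # arm isolation: other arms continue
            log.error("arm %s failed: %s", name, exc)
            errors[name] = f"{type(exc).__name__}: {exc}"
            log.debug("%s", traceback.format_exc())
    # conductance saturation across iv arms that declare a salt concentration
    sat_points = [
        (float(r["salt_mM"]), r["iv_fit"]["conductance_pS"])
        for r in results.values()
        if r.get("kind") == "iv" and r.get("salt_mM") and "iv_fit" in r
    ]
    if len(sat_points) >= 3:
        sat = fit_binding_hyperbola(sat_points)
        results["saturation"] = {
            "g_max_pS": sat.g_max, "k_a_mM": sat.k_a, "converged": sat.converged,
            "points": sat_points,
        }
        (cfg.out_dir / "saturation.json").write_text(
            json.dumps(results["saturation"], indent=1)
        )
    ghk_results = []
    for entry in cfg.ghk:
        try:
            ghk_results.append(_run_ghk(entry))
        except Exception as exc:
            errors[entry.get("name", "ghk")] = f"{type(exc).__name__}: {exc}"
    if ghk_results:
        results["ghk"] = ghk_results
        (cfg.out_dir / "ghk.json").write_text(json.dumps(ghk_results, indent=1))
    manifest = {
        "planarpore_version": __version__,
        "seed": cfg.seed,
        "config": {
            **{f.name: str(getattr(cfg, f.name)) if f.name == "out_dir"
               else getattr(cfg, f.name) for f in dataclasses.fields(cfg)},
        },
        "errors": errors,
    }
    (cfg.out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    results["errors"] = errors
    return results
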