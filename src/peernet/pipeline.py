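"""End-to-end orchestration: simulate or load billing data, build networks,
compute metrics and exposures, fit the participation models, write tables.

Every run is driven by a :class:`RunConfig` (constructible from a YAML file)
and produces a manifest recording the seed, input hashes, stage outcomes and
artifact paths.  In simulate mode the same configuration and seed reproduce
every numeric output bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import exposure as exposure_mod
from . import metrics as metrics_mod
from . import models as models_mod
from . import network as network_mod
from .exceptions import ConfigurationError
from .models import ModelSpec
from .simulate import SimConfig, simulate_study

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (simulate xor load)."""

    sim: SimConfig | None = None
    billing_path: str | None = None
    physicians_path: str | None = None
    hospitals_path: str | None = None
    physician_window: tuple[str, str] | None = None
    hospital_window: tuple[str, str] = ("2020-03-01", "2021-05-31")
    a_low: float = 0.0
    binarize_mode: str = "strict"
    cutoffs: tuple[int, ...] = metrics_mod.DEFAULT_CUTOFFS
    across_transform: str = "ln1p-percent"
    interaction_var: str = "shannon"
    include_within: bool = True
    alpha: float = 0.05
    outdir: str = "results/run"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        simulate_mode = self.sim is not None
        load_mode = self.billing_path is not None
        if simulate_mode == load_mode:
            raise ConfigurationError(
                "exactly one of a simulation config or input paths must be set"
            )
        if load_mode and (self.physicians_path is None or self.hospitals_path is None):
            raise ConfigurationError(
                "load mode requires billing_path, physicians_path and hospitals_path"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "sim" in raw and raw["sim"] is not None:
            sim_raw = dict(raw["sim"])
            if "beta" in sim_raw and sim_raw["beta"] is not None:
                from .simulate import Coefficients

                sim_raw["beta"] = Coefficients(**sim_raw["beta"])
            for key in ("physicians_per_hospital", "patients_per_hospital",
                        "encounters_per_patient", "date_window"):
                if key in sim_raw:
                    sim_raw[key] = tuple(sim_raw[key])
            raw["sim"] = SimConfig(**sim_raw)
        for key in ("physician_window", "hospital_window", "cutoffs"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _hash_file(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def render_fit_table(fit: models_mod.ModelFit) -> pd.DataFrame:
    """Result-table formatting: OR to 2 decimals, CI as "(lo, hi)", p-values
    below 0.01 printed as "<0.01"."""
    rows = []
    for term, row in fit.table.iterrows():
        if term == "const":
            continue
        rows.append(
            {
                "term": term,
                "OR": f"{row['odds_ratio']:.2f}",
                "95% CI": f"({row['ci_low']:.2f}, {row['ci_high']:.2f})",
                "p": format_p(row["p"]),
            }
        )
    out = pd.DataFrame(rows, columns=["term", "OR", "95% CI", "p"])
    return out


def format_p(p: float) -> str:
    if np.isnan(p):
        return ""
    return "<0.01" if p < 0.01 else f"{p:.2f}"


def render_tables(fits: dict[str, models_mod.ModelFit]) -> dict[str, pd.DataFrame]:
    """Format a collection of named fits as printable result tables."""
    return {name: render_fit_table(fit) for name, fit in fits.items()}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest.

    Artifacts: physician network (GraphML + edge list), hospital network,
    metric table, exposure table, univariate report, model tables, threshold
    sweep, manifest.  A stage failure is recorded in the manifest and later
    stages that depend on it are skipped; partial outputs are retained.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "artifacts": {}, "inputs": {}}
    state: dict = {}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            fn()
            manifest["stages"][name] = {
                "status": "ok",
                "seconds": round(time.perf_counter() - t0, 3),
            }
        except Exception as exc:  # noqa: BLE001 - manifest records any failure
            logger.exception("stage %s failed", name)
            manifest["stages"][name] = {
                "status": "error",
                "error": f"{type(exc).__name__}: {exc}",
                "seconds": round(time.perf_counter() - t0, 3),
            }

    def load_inputs():
        if config.sim is not None:
            study = simulate_study(config.sim)
            study.write(outdir / "data")
            state["billing"] = study.billing
            state["physicians"] = study.physicians
            state["hospitals"] = study.hospitals
            manifest["inputs"]["mode"] = "simulate"
            manifest["inputs"]["sim_seed"] = config.sim.seed
        else:
            window = (
                network_mod.Window(*config.physician_window)
                if config.physician_window
                else None
            )
            state["billing"] = network_mod.read_billing(config.billing_path, window)
            state["physicians"] = pd.read_csv(config.physicians_path)
            state["hospitals"] = pd.read_csv(config.hospitals_path)
            manifest["inputs"]["mode"] = "load"
            for key in ("billing_path", "physicians_path", "hospitals_path"):
                manifest["inputs"][key] = {
                    "path": getattr(config, key),
                    "sha256": _hash_file(getattr(config, key)),
                }

    def build_networks():
        billing = state["billing"]
        Z = network_mod.build_encounter_matrix(billing)
        A = network_mod.project_shared_patients(Z)
        B = network_mod.binarize(A, config.a_low, mode=config.binarize_mode)
        attr = network_mod.attribute_physicians(billing)
        hospital_net = network_mod.build_hospital_network(
            billing, network_mod.Window(*config.hospital_window)
        )
        state.update(A=A, B=B, attr=attr, hospital_net=hospital_net)
        network_mod.write_graphml(A.physicians, A.weights, outdir / "physician_network.graphml")
        network_mod.write_edge_list(A.physicians, A.weights, outdir / "physician_network_edges.csv")
        network_mod.write_edge_list(
            hospital_net.hospitals, hospital_net.edges, outdir / "hospital_network_edges.csv"
        )
        manifest["artifacts"]["physician_network"] = "physician_network.graphml"
        manifest["artifacts"]["physician_edges"] = "physician_network_edges.csv"
        manifest["artifacts"]["hospital_edges"] = "hospital_network_edges.csv"

    def compute_metrics():
        table = metrics_mod.metric_table(state["B"], state["attr"])
        sub = metrics_mod.subnetwork_density(state["B"], state["attr"])
        table.to_csv(outdir / "metrics.csv")
        sub.per_hospital.to_csv(outdir / "subnetwork_density.csv")
        state["metrics"] = table
        manifest["artifacts"]["metrics"] = "metrics.csv"
        manifest["artifacts"]["subnetwork_density"] = "subnetwork_density.csv"
        manifest["network_density"] = metrics_mod.density(state["B"])
        manifest["subnetwork_density_summary"] = sub.summary()

    def compute_exposures():
        phys = state["physicians"].set_index("physician_id")
        steps = state["hospitals"].set_index("hospital_id")["step"]
        y = phys["participated"].astype(float)
        table = exposure_mod.build_exposure_table(
            state["B"], state["attr"], y, steps, transform=config.across_transform
        )
        table.to_csv(outdir / "exposures.csv")
        state["exposures"] = table
        manifest["artifacts"]["exposures"] = "exposures.csv"

    def model_frame():
        phys = state["physicians"].set_index("physician_id")
        frame = models_mod.covariate_frame(phys.loc[state["exposures"].index])
        frame["participated"] = phys.loc[state["exposures"].index, "participated"].astype(float)
        frame["primary_hospital"] = pd.Series(
            state["attr"].primary, index=state["attr"].physicians
        ).reindex(state["exposures"].index)
        for col in state["exposures"].columns:
            frame[col] = state["exposures"][col]
        frame["n_hospitals"] = frame["n_nonprimary"] + 1
        state["frame"] = frame

    def univariate():
        frame = state["frame"].join(
            state["physicians"].set_index("physician_id")[["sex"]]
        )
        frame["age_raw"] = state["physicians"].set_index("physician_id")["age"]
        report = models_mod.univariate_tests(
            frame,
            outcome="participated",
            continuous=(
                "age_raw", "n_hospitals", "years_org", "shannon",
                "degree_within", "degree_across", "wy_wi", "wy_ac",
            ),
            categorical=("sex",),
        )
        report.to_csv(outdir / "univariate.csv", index=False)
        manifest["artifacts"]["univariate"] = "univariate.csv"
        rate = metrics_mod.participation_percentage(
            int(state["frame"]["participated"].sum()), len(state["frame"])
        )
        manifest["participation_rate_pct"] = rate

    def fit_models():
        frame = state["frame"]
        modifier = config.interaction_var
        terms = ["age", "age_observed", "years_org", "shannon"]
        if config.include_within:
            terms.append("wy_wi")
        terms.append("wy_ac_t")
        fixed = ModelSpec(
            outcome="participated",
            terms=tuple(terms),
            interactions=(("wy_ac_t", modifier),),
        )
        mixed_terms = tuple(t for t in terms if t != "wy_wi")
        mixed = ModelSpec(
            outcome="participated",
            terms=mixed_terms,
            interactions=(("wy_ac_t", modifier),),
            random_intercept="primary_hospital",
        )
        fits = {
            "fixed_effects": models_mod.fit(fixed, frame),
            "random_effects": models_mod.fit(mixed, frame),
        }
        for name, table in render_tables(fits).items():
            table.to_csv(outdir / f"model_{name}.csv", index=False)
            manifest["artifacts"][f"model_{name}"] = f"model_{name}.csv"
        manifest["tau_random_intercept"] = fits["random_effects"].tau
        state["fits"] = fits

    def sweep():
        report = metrics_mod.threshold_sweep(
            state["A"], state["attr"], cutoffs=config.cutoffs, mode=config.binarize_mode
        )
        report.to_csv(outdir / "threshold_sweep.csv", index=False)
        manifest["artifacts"]["threshold_sweep"] = "threshold_sweep.csv"

    stage("load_inputs", load_inputs)
    if "billing" in state:
        stage("build_networks", build_networks)
    if "B" in state:
        stage("metrics", compute_metrics)
        stage("exposures", compute_exposures)
    if "exposures" in state:
        stage("model_frame", model_frame)
    if "frame" in state:
        stage("univariate", univariate)
        stage("fit_models", fit_models)
    if "A" in state:
        stage("threshold_sweep", sweep)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
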