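"""Config-driven end-to-end pipeline and report bundle.

A single YAML config seeds a complete run: synthetic trajectory generation
(ground-truth Markov chain with distance emissions), featurization, TICA,
k-means microstates, reversible MSM, Chapman-Kolmogorov validation, PCCA++
macrostates with stationary free energies, MFPT matrix, coarse transition
network, and the distance-based event/population analyses. Outputs are TSV
tables, a JSON manifest recording config and seeds, and basic figures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis, macrostates, msm, synthetic, tica
from .featurization import FeatureMatrix
from .trajectory import write_manifest

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "generator": {
        "kind": "markov_chain",
        "n_replicas": 15,
        "replica_length_ns": 5000.0,
        "lag_step_ns": 1.0,
        "emission_sd_nm": 0.35,
        "start_unbound": True,
        "seed": 2023,
    },
    "tica": {"lag_ns": 5.0, "kinetic_variance": 0.95},
    "msm": {"n_microstates": 250, "lag_ns": 5.0, "cluster_seed": 0},
    "macrostates": {"n_macrostates": 6, "temperature_K": 310.0},
    "ck": {"factors": [1, 2, 3, 4, 5]},
    "events": {"bound_threshold_nm": 6.0, "unbound_threshold_nm": 7.0,
               "bin_width_nm": 0.1},
}


@dataclass
class PipelineResult:
    """In-memory handles to every stage output plus the report directory."""

    config: dict
    features: FeatureMatrix
    tica_model: tica.TICAModel
    discretization: msm.Discretization
    msm_model: msm.MSMModel
    macro_model: macrostates.MacrostateModel
    mfpt_ns: np.ndarray
    network: pd.DataFrame
    ck: msm.CKResult
    events: analysis.EventSeries
    populations: analysis.PopulationResult
    protocol: dict
    output_dir: Path | None = None


def load_config(path: str | Path | dict | None) -> dict:
    """Merge a YAML config file (or dict) over the package defaults."""
    cfg = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    if path is None:
        return cfg
    user = path if isinstance(path, dict) else yaml.safe_load(Path(path).read_text())
    for section, values in (user or {}).items():
        if section not in cfg:
            raise ValueError(f"unknown config section '{section}'")
        cfg[section].update(values)
    return cfg


def _generate(cfg: dict) -> tuple[FeatureMatrix, list[np.ndarray], synthetic.GroundTruthChain, dict]:
    g = cfg["generator"]
    if g["kind"] != "markov_chain":
        raise ValueError(f"unsupported generator kind '{g['kind']}'")
    chain = synthetic.association_chain(
        emission_sd=g["emission_sd_nm"], lag_step=g["lag_step_ns"])
    n_steps = int(round(g["replica_length_ns"] / g["lag_step_ns"]))
    labels = synthetic.simulate_markov_chain(
        chain, n_steps=n_steps, n_replicas=g["n_replicas"], seed=g["seed"],
        start_unbound=g.get("start_unbound", True))
    features = synthetic.emit_distance_trajectories(labels, chain, seed=g["seed"] + 1)
    protocol = {
        "n_replicas": g["n_replicas"],
        "replica_length_ns": g["replica_length_ns"],
        "frame_interval_ns": g["lag_step_ns"],
        "total_time_ns": g["n_replicas"] * n_steps * g["lag_step_ns"],
        "total_time_us": g["n_replicas"] * n_steps * g["lag_step_ns"] / 1e3,
    }
    return features, labels, chain, protocol


def run_pipeline(config: str | Path | dict | None = None,
                 output_dir: str | Path | None = None,
                 features: FeatureMatrix | None = None) -> PipelineResult:
    """Execute the full analysis; optionally write the report bundle.

    ``features`` may be supplied directly (bypassing the synthetic
    generator) for externally loaded trajectories.
    """
    cfg = load_config(config)
    stage = "generate"
    try:
        if features is None:
            features, _, _, protocol = _generate(cfg)
        else:
            g = cfg["generator"]
            lengths = [X.shape[0] * features.frame_interval
                       for X in features.replicas]
            protocol = {
                "n_replicas": features.n_replicas,
                "replica_length_ns": lengths,
                "frame_interval_ns": features.frame_interval,
                "total_time_ns": float(sum(lengths)),
                "total_time_us": float(sum(lengths)) / 1e3,
            }

        stage = "tica"
        tica_model = tica.fit_tica(features, lag=cfg["tica"]["lag_ns"],
                                   variance_cutoff=cfg["tica"]["kinetic_variance"])
        projected = tica.project(tica_model, features)

        stage = "clustering"
        disc = msm.cluster_microstates(projected, k=cfg["msm"]["n_microstates"],
                                       seed=cfg["msm"]["cluster_seed"])

        stage = "msm"
        model = msm.estimate_msm(disc.labels, lag=cfg["msm"]["lag_ns"],
                                 frame_interval=features.frame_interval,
                                 n_states=disc.n_states)

        stage = "pcca"
        macro = macrostates.pcca_plus(model, cfg["macrostates"]["n_macrostates"],
                                      temperature=cfg["macrostates"]["temperature_K"])

        stage = "ck_test"
        active_sets = [model.active_set[s] for s in macro.crisp_sets()]
        ck = msm.ck_test(model, disc.labels, active_sets, cfg["ck"]["factors"],
                         features.frame_interval)

        stage = "kinetics"
        M = macrostates.mfpt_matrix(model, macro)
        network = macrostates.coarse_transition_network(model, macro)

        stage = "events"
        # monomer-scale proxy distance: mean of the four inter-domain distances
        monomer_proxy = [X.mean(axis=1) for X in features.replicas]
        events = analysis.detect_association_events(
            monomer_proxy, features.frame_interval,
            bound_thr=cfg["events"]["bound_threshold_nm"],
            unbound_thr=cfg["events"]["unbound_threshold_nm"])
        pops = analysis.population_fractions(
            monomer_proxy,
            bound_thr=cfg["events"]["bound_threshold_nm"],
            unbound_thr=cfg["events"]["unbound_threshold_nm"],
            bin_width=cfg["events"]["bin_width_nm"])
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    result = PipelineResult(
        config=cfg, features=features, tica_model=tica_model,
        discretization=disc, msm_model=model, macro_model=macro, mfpt_ns=M,
        network=network, ck=ck, events=events, populations=pops,
        protocol=protocol,
    )
    if output_dir is not None:
        result.output_dir = write_report(result, output_dir)
    return result


def write_report(result: PipelineResult, output_dir: str | Path) -> Path:
    """Write the TSV tables, manifest and figures of a finished run."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    n_macro = result.macro_model.n_macrostates
    free_energy = pd.DataFrame({
        "macrostate": np.arange(n_macro),
        "stationary_weight": result.macro_model.stationary_weights,
        "free_energy_kj_mol": result.macro_model.free_energies_kj_mol,
        "relative_free_energy_kj_mol": result.macro_model.relative_free_energies(),
    })
    free_energy.to_csv(out / "free_energies.tsv", sep="\t", index=False)

    mfpt_df = pd.DataFrame(result.mfpt_ns,
                           index=[f"macro_{i}" for i in range(n_macro)],
                           columns=[f"macro_{i}" for i in range(n_macro)])
    mfpt_df.to_csv(out / "mfpt_ns.tsv", sep="\t")

    result.network.to_csv(out / "coarse_network.tsv", sep="\t", index=False)

    ck_rows = []
    for i, k in enumerate(result.ck.factors):
        for m in range(result.ck.predicted.shape[1]):
            ck_rows.append({"factor": k, "macrostate": m,
                            "predicted": result.ck.predicted[i, m],
                            "estimated": result.ck.estimated[i, m],
                            "band": result.ck.error[i, m]})
    pd.DataFrame(ck_rows).to_csv(out / "ck_test.tsv", sep="\t", index=False)

    pops = result.populations
    pd.DataFrame({
        "bin_left_nm": pops.bin_edges[:-1],
        "bin_right_nm": pops.bin_edges[1:],
        "density": pops.density,
    }).to_csv(out / "distance_histogram.tsv", sep="\t", index=False)

    summary = dict(result.protocol)
    summary.update({
        "n_binding_events": result.events.n_binding,
        "n_unbinding_events": result.events.n_unbinding,
        "bound_fraction": pops.bound_fraction,
        "unbound_fraction": pops.unbound_fraction,
        "tica_components_kept": result.tica_model.n_components_kept,
        "n_microstates": result.discretization.n_states,
        "active_set_size": result.msm_model.n_states,
        "msm_lag_ns": result.msm_model.lag_ns,
        "ck_max_deviation": result.ck.max_deviation(),
    })
    write_manifest(out / "manifest.json", config=result.config, summary=summary)

    _write_figures(result, out)
    return out


def _write_figures(result: PipelineResult, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    pops = result.populations
    centers = 0.5 * (pops.bin_edges[:-1] + pops.bin_edges[1:])
    ax.fill_between(centers, pops.density, alpha=0.6)
    ax.axvline(result.config["events"]["bound_threshold_nm"], ls="--", c="k")
    ax.axvline(result.config["events"]["unbound_threshold_nm"], ls="--", c="k")
    ax.set_xlabel("inter-monomer distance (nm)")
    ax.set_ylabel("density")
    fig.tight_layout()
    fig.savefig(out / "distance_populations.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4.2, 3.6))
    im = ax.imshow(np.where(result.mfpt_ns > 0, result.mfpt_ns, np.nan))
    ax.set_xlabel("target macrostate")
    ax.set_ylabel("source macrostate")
    fig.colorbar(im, ax=ax, label="MFPT (ns)")
    fig.tight_layout()
    fig.savefig(out / "mfpt_matrix.png", dpi=120)
    plt.close(fig)
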