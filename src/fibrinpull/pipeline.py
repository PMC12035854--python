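"""End-to-end orchestration: synthesize -> (simulate) -> analyze -> fit ->
report, with one global seed propagated deterministically to every stage.

Every stage writes its inputs/outputs as delimited text under the output
directory, so any stage can be rerun in isolation from the persisted
files.  All thresholds carry the established defaults (500/200 pN, 30 nm,
100 nm, 0.1 pN EM tolerance) and are configurable from a YAML file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import em, fx, pulling, sop, synthetic

log = logging.getLogger("fibrinpull")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Stage toggles, sizes and thresholds for one pipeline run."""

    seed: int = 0
    out_dir: str = "pipeline_out"
    n_events: int = 5000
    run_simulation: bool = False  # toy two-strand pull + transition stats
    init_perturbation: float = 0.0  # multiplicative mean perturbation for EM init
    em_tol: float = 0.1  # pN
    em_max_iter: int = 500
    rules: fx.SelectionRules = field(default_factory=fx.SelectionRules)
    sim_n_residues: int = 24
    sim_speed: float = 1e6  # um/s (desk-scale; see docs/methods.md)
    sim_max_extension: float = 10.0  # nm

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        rules = fx.SelectionRules(**raw.pop("rules", {}))
        return cls(rules=rules, **raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 (stable across processes)."""
    import zlib

    return int(
        np.random.SeedSequence([seed, zlib.crc32(stage.encode())]).generate_state(1)[0]
        % (2**31)
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages and return (and persist) the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}

    # --- stage: synthetic events -------------------------------------
    comps = synthetic.default_components()
    events = synthetic.sample_mixture(comps, config.n_events, seed=_stage_seed(config.seed, "synth"))
    synthetic.write_events(events, out / "events.tsv")
    log.info("synth: %d events written", len(events))
    report["n_events"] = int(len(events))
    report["summary"] = fx.summarize(events)

    # --- stage: EM fit ------------------------------------------------
    truth = em.model_from_components(comps)
    init = em.model_from_components(comps)
    if config.init_perturbation:
        factor = 1.0 + config.init_perturbation
        init.mu_f = init.mu_f * factor
        init.mu_x = init.mu_x * factor
    fitted, resp = em.fit(events, init, tol=config.em_tol, max_iter=config.em_max_iter)
    fitted = em.match_components(fitted, truth)
    fitted.save(out / "model.json")
    classified = em.classify(events, fitted)
    classified.to_csv(out / "events_classified.tsv", sep="\t", index=False)
    log.info("fit-em: converged=%s in %d iterations", fitted.converged, fitted.n_iter)
    report["em"] = {
        "converged": fitted.converged,
        "n_iter": fitted.n_iter,
        "priors": fitted.priors.tolist(),
        "prior_sum": float(fitted.priors.sum()),
        "mu_f": fitted.mu_f.tolist(),
        "mu_x": fitted.mu_x.tolist(),
        "sd_f": fitted.sd_f.tolist(),
        "loglik": fitted.loglik_trace[-1],
    }

    # --- stage: L1 diagnostics ---------------------------------------
    grid = np.linspace(0.5, 250.0, 500)
    delta_f = float(grid[1] - grid[0])
    model_comp = em.component_force_densities(fitted, grid)
    kde_comp = np.vstack(
        [
            fx.kde(events.loc[events.true_type == t, "force_pN"].to_numpy(), grid)
            for t in sorted(events.true_type.unique())
        ]
    )
    weights = events.true_type.value_counts(normalize=True).sort_index().to_numpy()
    l1_types = em.l1_per_type(model_comp, kde_comp, fitted.priors, weights, delta_f)
    combined_model = em.combined_force_density(fitted, grid)
    combined_kde = fx.kde(events["force_pN"].to_numpy(), grid)
    report["l1"] = {
        "per_type": l1_types.tolist(),
        "combined": em.l1_norm(combined_model, combined_kde, delta_f),
    }

    # --- stage: toy pulling simulation -------------------------------
    if config.run_simulation:
        report["simulation"] = _toy_simulation(config, out)

    (out / "report.json").write_text(json.dumps(report, indent=1))
    return report


def _toy_simulation(config: PipelineConfig, out: Path) -> dict:
    """Transverse pull of a two-strand toy oligomer with per-strand
    transition telemetry (study-1-like geometry scaled to desk size)."""
    st = synthetic.make_toy_chain(config.sim_n_residues, "two_strand")
    topo = sop.build_topology(st)
    n_a = config.sim_n_residues // 2
    n = config.sim_n_residues
    # hold both ends of both strands, pull the middle of the assembly
    constrained = frozenset({0, n_a - 1, n_a, n - 1})
    mid = frozenset({n_a // 2, n_a + (n - n_a) // 2})
    protocol = pulling.PullProtocol(
        constrained=constrained, pulled=mid, direction="transverse",
        speed=config.sim_speed,
    )
    sim = pulling.SimConfig(
        max_extension=config.sim_max_extension,
        output_stride=500,
        seed=_stage_seed(config.seed, "simulate"),
    )
    traj = pulling.run_pull(st, topo, protocol, sim)
    synthetic.write_curve(traj.fx_curve(), out / "sim_curve.tsv")
    regions = [
        pulling.RegionDef(1, "A", ((1, n_a),)),
        pulling.RegionDef(2, "B", ((1, n - n_a),)),
    ]
    rep = pulling.classify_transitions(traj, regions)
    return {
        "n_frames": traj.n_frames,
        "max_force_pN": float(traj.force_pN.max()),
        "n_transitions": len(rep.events),
        "single_fraction": rep.single_fraction,
        "mixed_fraction": rep.mixed_fraction,
        "alternation_score": rep.alternation_score,
    }
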