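"""End-to-end orchestration of the economic evaluation.

One user seed governs every stochastic stage through named substreams, so a
full 32,000-draw run is bit-reproducible from its manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import benefit_model, cost_model, decision_analysis, effectiveness_model, inference
from .parameters import ParameterSet, load_params
from .synthetic_trial import TrialDesign, simulate_trial, write_panel

__all__ = ["RunManifest", "run_pipeline", "stage_seeds", "build_econ_draws"]

STAGES = ("trial", "inference", "cost", "epi")


def stage_seeds(seed: int) -> dict[str, int]:
    """Named integer substream seeds (< 2^31) derived from the user seed."""
    ss = np.random.SeedSequence(seed)
    states = ss.generate_state(len(STAGES)) % (2**31)
    return {name: int(s) for name, s in zip(STAGES, states)}


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    mode: str
    n_samples: int
    outdir: str
    outputs: dict[str, str] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def _config_hash(params: ParameterSet) -> str:
    canon = yaml.safe_dump(params.raw, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def build_econ_draws(
    params: ParameterSet,
    posterior: inference.PosteriorDraws,
    seeds: dict[str, int],
    cost_mode: str = "calibrated",
) -> tuple[decision_analysis.EconDraws, effectiveness_model.DalyDraws, dict]:
    """Cost, DALY and per-scenario benefit draws aligned to the posterior."""
    c = params.constants
    if cost_mode == "calibrated":
        mean_total = params.published_total_usd
    elif cost_mode == "schedule":
        schedule = cost_model.build_schedule(params.cost_accounts, c)
        mean_total = cost_model.total_discounted_cost(schedule, c.discount_rate)
    else:
        raise ValueError(f"unknown cost mode '{cost_mode}'")
    cost = cost_model.sample_costs(mean_total, params.cost_cv, posterior.S, seed=seeds["cost"])

    epi = effectiveness_model.sample_epi_draws(params, posterior, seed=seeds["epi"])
    dalys = effectiveness_model.total_dalys_averted(posterior, params, epi=epi)
    benefits = benefit_model.run_ssa(posterior, params, epi=epi)
    econ = decision_analysis.EconDraws(
        cost=cost,
        dalys_averted=dalys.total,
        benefit={k: v.total for k, v in benefits.items()},
    )
    return econ, dalys, benefits


def run_pipeline(
    config: str | Path | None = None,
    mode: str = "reconstructed",
    seed: int = 0,
    outdir: str | Path = "chveval_run",
    n_samples: int | None = None,
    cost_mode: str = "calibrated",
    design: TrialDesign | None = None,
    glmm_kwargs: dict | None = None,
) -> RunManifest:
    """Execute simulate/infer (or reconstruct) -> cost -> effectiveness ->
    benefit -> decision stages, writing draw-level CSVs, summary tables and a
    manifest under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = load_params(config)
    S = n_samples or params.constants.n_samples
    seeds = stage_seeds(seed)

    manifest = RunManifest(
        config_hash=_config_hash(params),
        seed=seed,
        mode=mode,
        n_samples=S,
        outdir=str(outdir),
        provenance=dict(params.provenance),
    )

    def _stage(name):
        t0 = time.perf_counter()

        def done(**outputs):
            manifest.timings[name] = round(time.perf_counter() - t0, 3)
            manifest.outputs.update({k: str(v) for k, v in outputs.items()})

        return done

    try:
        done = _stage("posterior")
        if mode == "synthetic":
            design = design or TrialDesign(seed=seeds["trial"])
            panel = simulate_trial(design)
            panel_path = outdir / "trial_panel.csv"
            write_panel(panel, panel_path)
            posterior = inference.fit_glmm(
                panel, seed=seeds["inference"], **(glmm_kwargs or {})
            )
            # the economic model consumes exactly S aligned draws
            rng = np.random.default_rng(seeds["inference"])
            idx = rng.integers(0, posterior.S, S)
            posterior = inference.PosteriorDraws(
                posterior.rr_diarrhoea[idx], posterior.rr_fever[idx],
                source="mcmc", diagnostics=posterior.diagnostics,
            )
            manifest.diagnostics = {
                d: vars(g) for d, g in (posterior.diagnostics or {}).items()
            }
            manifest.outputs["trial_panel"] = str(panel_path)
        elif mode == "reconstructed":
            posterior = inference.reconstruct_from_params(params, S=S, seed=seeds["inference"])
        else:
            raise ValueError(f"unknown mode '{mode}'")
        post_path = outdir / "posterior_draws.csv"
        posterior.to_csv(post_path)
        done(posterior_draws=post_path)

        done = _stage("economic")
        econ, dalys, benefits = build_econ_draws(params, posterior, seeds, cost_mode=cost_mode)
        econ_path = outdir / "econ_draws.csv"
        frame = econ.to_frame()
        dal = dalys.to_frame().drop(columns="sample_id")
        frame = frame.join(dal.drop(columns=[c for c in dal.columns if c == "dalys"]))
        frame.to_csv(econ_path, index=False)
        benefit_path = outdir / "benefit_draws.csv"
        import pandas as pd

        pd.concat([b.to_frame() for b in benefits.values()]).to_csv(benefit_path, index=False)
        done(econ_draws=econ_path, benefit_draws=benefit_path)

        done = _stage("decision")
        summary = summarize_run(econ, params)
        summary_path = outdir / "decision_summary.json"
        with open(summary_path, "w") as fh:
            json.dump(summary, fh, indent=2)
        done(decision_summary=summary_path)
    except Exception as exc:  # abort with the failing stage named
        pending = set(("posterior", "economic", "decision")) - set(manifest.timings)
        stage = min(pending, key=("posterior", "economic", "decision").index) if pending else "?"
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest_path = outdir / "manifest.json"
    manifest.outputs["manifest"] = str(manifest_path)
    manifest.save(manifest_path)
    return manifest


def summarize_run(econ: decision_analysis.EconDraws, params: ParameterSet) -> dict:
    """ICER/CEAC/CBR/NPVB summary dictionary for a full set of draws."""
    c = params.constants
    icer = decision_analysis.icer_draws(econ, epsilon=c.icer_effect_epsilon)
    lambdas = [m * c.gdp_per_capita_usd for m in params.ceac_thresholds_gdp_multiples]
    curve = decision_analysis.ceac(econ, lambdas)
    out = {
        "icer": {
            "mean": icer.mean,
            "median": icer.median,
            "ci_lower": icer.ci_lower,
            "ci_upper": icer.ci_upper,
            "n_excluded": icer.n_excluded,
        },
        "ceac": {f"{m:g}x_gdp": curve[m * c.gdp_per_capita_usd] for m in params.ceac_thresholds_gdp_multiples},
        "cba": {},
    }
    for sid in econ.benefit:
        s = decision_analysis.cbr_npvb(econ, sid)
        out["cba"][sid] = {
            "cbr_mean": s.cbr_mean,
            "cbr_median": s.cbr_median,
            "npvb_median": s.npvb_median,
            "npvb_mean": s.npvb_mean,
            "p_cbr_gt_1": s.p_cbr_gt[1.0],
            "p_cbr_gt_3": s.p_cbr_gt[3.0],
        }
    return out
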