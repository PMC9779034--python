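"""End-to-end orchestration: simulate -> SMR -> correlation screen ->
factor analysis -> spatial model -> report.

A single YAML config drives the run; every numeric default lives in
:func:`default_config`.  Each stage writes its artifact eagerly and the
MANIFEST records seeds, package versions and per-stage completion, so a
failed run keeps its partial artifacts and two runs with the same config
and seed produce identical tables.
"""

from __future__ import annotations

import json
import traceback
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._rng import substream
from .befa import (
    BefaConfig,
    active_factors,
    allocation_summary,
    befa_fit,
    factor_scores,
    standardize,
)
from .bym import BymPriors, bym_fit, relative_risk_summary, summarize_coefficients
from .diagnostics import ChainSet, effective_sample_size, gelman_rubin, write_choropleth_geojson
from .graph import (
    AreaGraph,
    build_adjacency_from_edgelist,
    build_adjacency_from_geojson,
    component_report,
    read_edgelist_csv,
    write_edgelist_csv,
)
from .smr import AreaData, correlation_matrix, expected_counts, plot_correlation_heatmap, smr
from .synthetic import default_study_graph, simulate_default_study

__all__ = [
    "default_config",
    "run_pipeline",
    "PipelineResult",
    "synthetic_regions_geojson",
]

EXIT_OK = 0
EXIT_VALIDATION = 1
EXIT_RUNTIME = 2


def default_config() -> dict:
    """The documented configuration schema with every numeric default.

    The MCMC protocol follows the study design: 10,000 iterations with
    the first 4,000 discarded as warm-up, for both samplers.
    """
    return {
        "seed": 1,
        "output_dir": "arealrisk_run",
        "mode": "synthetic",  # or "csv"
        "synthetic": {
            "alpha0": 0.0,
            "beta": [0.5, -0.3],
            "sigma_u": 0.3,
            "sigma_v": 0.1,
            "base_rate": 0.01,
        },
        "inputs": {  # csv mode only
            "area_csv": None,
            "adjacency_csv": None,
            "geojson": None,
            "id_property": "id",
            "contiguity": "queen",
        },
        "correlation": {"method": "pearson"},
        "befa": {
            "K_max": 3,
            "n_iter": 10_000,
            "n_warmup": 4_000,
            "loading_prior_sd": 1.0,
            "min_dedicated": 2,
            "retention_threshold": 0.5,
        },
        "bym": {
            "n_iter": 10_000,
            "n_warmup": 4_000,
            "n_chains": 3,
            "thin": 1,
            "tau_u_prior": [0.5, 0.0005],
            "tau_v_prior": [0.5, 0.0005],
            "extra_covariates": [],
        },
        "report": {"rhat_max": 1.05, "ess_min": 400.0},
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _validate(cfg: dict) -> None:
    if cfg["mode"] not in ("synthetic", "csv"):
        raise ConfigError(f"unknown mode '{cfg['mode']}'")
    for stage in ("befa", "bym"):
        s = cfg[stage]
        if not (0 <= int(s["n_warmup"]) < int(s["n_iter"])):
            raise ConfigError(
                f"{stage}: need 0 <= n_warmup < n_iter "
                f"(got {s['n_warmup']} / {s['n_iter']})"
            )
    if cfg["mode"] == "csv" and not cfg["inputs"].get("area_csv"):
        raise ConfigError("csv mode needs inputs.area_csv")
    if cfg["mode"] == "csv" and not (
        cfg["inputs"].get("adjacency_csv") or cfg["inputs"].get("geojson")
    ):
        raise ConfigError("csv mode needs inputs.adjacency_csv or inputs.geojson")


class ConfigError(ValueError):
    pass


def synthetic_regions_geojson(graph: AreaGraph | None = None) -> dict:
    """Polygon layout whose queen contiguity reproduces the default graph.

    Grid areas are unit squares; the two attached areas are triangles
    touching only their designated neighbour's edge; the island sits
    apart from everything.
    """
    graph = graph or default_study_graph()
    features = []
    for k, aid in enumerate(graph.area_ids):
        if k < 30:
            r, c = divmod(k, 6)
            coords = [[c, r], [c + 1, r], [c + 1, r + 1], [c, r + 1], [c, r]]
        elif aid == "A30":
            coords = [[6, 4.25], [7, 4.5], [6, 4.75], [6, 4.25]]
        elif aid == "A31":
            coords = [[6, 0.25], [7, 0.5], [6, 0.75], [6, 0.25]]
        else:  # island
            coords = [[8, 2], [9, 2], [9, 3], [8, 3], [8, 2]]
        features.append(
            {
                "type": "Feature",
                "properties": {"id": aid},
                "geometry": {"type": "Polygon", "coordinates": [coords]},
            }
        )
    return {"type": "FeatureCollection", "features": features}


@dataclass
class PipelineResult:
    exit_code: int
    artifact_dir: Path
    manifest: dict


def run_pipeline(config, output_dir=None) -> PipelineResult:
    """Run all stages; returns the exit code, artifact dir and manifest.

    ``config`` may be a YAML path or a (possibly partial) dict merged over
    :func:`default_config`.  Exit codes: 0 ok, 1 config validation error,
    2 runtime failure (partial artifacts retained, MANIFEST marks the
    failed stage).
    """
    if isinstance(config, (str, Path)):
        user_cfg = yaml.safe_load(Path(config).read_text()) or {}
    else:
        user_cfg = dict(config or {})
    cfg = _merge(default_config(), user_cfg)
    out = Path(output_dir or cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)

    manifest = {
        "seed": cfg.get("seed"),
        "versions": {
            "arealrisk": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "config": cfg,
        "protocol": {
            "bym_n_iter": int(cfg["bym"]["n_iter"]),
            "bym_n_warmup": int(cfg["bym"]["n_warmup"]),
            "bym_n_chains": int(cfg["bym"]["n_chains"]),
            "befa_n_iter": int(cfg["befa"]["n_iter"]),
            "befa_n_warmup": int(cfg["befa"]["n_warmup"]),
        },
        "stages": {},
    }

    def _finish(code):
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2, default=str))
        return PipelineResult(code, out, manifest)

    try:
        _validate(cfg)
    except ConfigError as err:
        manifest["error"] = str(err)
        return _finish(EXIT_VALIDATION)

    seed = int(cfg["seed"])
    stage = "simulate"
    try:
        # ---- stage 1: inputs -------------------------------------------
        regions = None
        if cfg["mode"] == "synthetic":
            syn = cfg["synthetic"]
            study = simulate_default_study(
                seed,
                alpha0=float(syn["alpha0"]),
                beta=tuple(syn["beta"]),
                sigma_u=float(syn["sigma_u"]),
                sigma_v=float(syn["sigma_v"]),
                base_rate=float(syn["base_rate"]),
            )
            graph = study.graph
            data = study.to_area_data()
            data.to_csv(out / "area_data.csv")
            write_edgelist_csv(graph, out / "adjacency.csv")
            truth = {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in study.truth.items()
            }
            (out / "truth.json").write_text(json.dumps(truth, indent=2))
            regions = synthetic_regions_geojson(graph)
            (out / "regions.geojson").write_text(json.dumps(regions))
        else:
            inp = cfg["inputs"]
            data = AreaData.from_csv(inp["area_csv"])
            if inp.get("geojson"):
                regions = json.loads(Path(inp["geojson"]).read_text())
                graph = build_adjacency_from_geojson(
                    regions,
                    id_property=inp.get("id_property", "id"),
                    rule=inp.get("contiguity", "queen"),
                )
            else:
                pairs = read_edgelist_csv(inp["adjacency_csv"])
                graph = build_adjacency_from_edgelist(data.area_ids, pairs)
            if list(graph.area_ids) != list(data.area_ids):
                order = [graph.index_of(a) for a in data.area_ids]
                if sorted(order) != list(range(graph.n_areas)):
                    raise ValueError("graph and area table ids do not match")
        (out / "components.txt").write_text(component_report(graph))
        manifest["stages"][stage] = "ok"

        # ---- stage 2: SMR ----------------------------------------------
        stage = "smr"
        data = expected_counts(data)
        ratios = smr(data)
        pd.DataFrame(
            {
                "area_id": data.area_ids,
                "observed": data.y,
                "expected": data.e,
                "smr": ratios,
            }
        ).to_csv(out / "smr.csv", index=False)
        manifest["stages"][stage] = "ok"

        # ---- stage 3: correlation screen -------------------------------
        stage = "correlate"
        if data.X is not None:
            corr = correlation_matrix(
                data.X, data.covariate_names, method=cfg["correlation"]["method"]
            )
            corr.to_csv(out / "correlation.csv")
            plot_correlation_heatmap(corr, out / "correlation_heatmap.png")
            manifest["stages"][stage] = "ok"
        else:
            manifest["stages"][stage] = "skipped (no covariates)"

        # ---- stage 4: factor analysis ----------------------------------
        stage = "befa"
        scores = None
        score_names: list[str] = []
        if data.X is not None:
            bcfg = cfg["befa"]
            befa_config = BefaConfig(
                K_max=int(bcfg["K_max"]),
                n_iter=int(bcfg["n_iter"]),
                n_warmup=int(bcfg["n_warmup"]),
                loading_prior_sd=float(bcfg["loading_prior_sd"]),
                min_dedicated=int(bcfg["min_dedicated"]),
                retention_threshold=float(bcfg["retention_threshold"]),
                seed=int(substream(seed, "befa").integers(2**31)),
            )
            Xstd = standardize(data.X, data.covariate_names)
            post_befa = befa_fit(Xstd, befa_config)
            summ = allocation_summary(post_befa, data.covariate_names)
            summ.to_csv(out / "befa_summary.csv", index=False)
            act = active_factors(post_befa)
            if act:
                scores = factor_scores(post_befa)
                score_names = [f"factor_{k}" for k in act]
                sc_df = pd.DataFrame(scores, columns=score_names)
                sc_df.insert(0, "area_id", data.area_ids)
                sc_df.to_csv(out / "factor_scores.csv", index=False)
            else:
                pd.DataFrame({"area_id": data.area_ids}).to_csv(
                    out / "factor_scores.csv", index=False
                )
            manifest["befa_active_factors"] = act
            manifest["stages"][stage] = "ok"
        else:
            manifest["stages"][stage] = "skipped (no covariates)"

        # ---- stage 5: spatial model ------------------------------------
        stage = "bym"
        mcfg = cfg["bym"]
        design_cols = []
        design_names = []
        if scores is not None:
            design_cols.append(scores)
            design_names += score_names
        for name in mcfg.get("extra_covariates", []):
            j = data.covariate_names.index(name)
            col = standardize(data.X[:, [j]], [name])
            design_cols.append(col)
            design_names.append(name)
        Xcov = np.column_stack(design_cols) if design_cols else None
        priors = BymPriors(
            tau_u_prior=tuple(mcfg["tau_u_prior"]),
            tau_v_prior=tuple(mcfg["tau_v_prior"]),
        )
        post = bym_fit(
            data,
            Xcov,
            graph,
            priors,
            n_iter=int(mcfg["n_iter"]),
            n_warmup=int(mcfg["n_warmup"]),
            n_chains=int(mcfg["n_chains"]),
            seed=int(substream(seed, "bym").integers(2**31)),
            thin=int(mcfg["thin"]),
            coef_names=design_names,
        )
        summarize_coefficients(post).to_csv(out / "coefficients.csv", index=False)
        rr = relative_risk_summary(post)
        rr.to_csv(out / "relative_risk.csv", index=False)
        np.savez_compressed(
            out / "draws.npz",
            alpha0=post.alpha0_draws,
            beta=post.beta_draws,
            u=post.u_draws,
            v=post.v_draws,
            tau_u=post.tau_u_draws,
            tau_v=post.tau_v_draws,
            theta=post.theta_draws,
            coef_names=np.array(post.coef_names, dtype=object),
            area_ids=np.array(post.area_ids, dtype=object),
        )
        manifest["protocol"]["bym_n_iter_run"] = post.n_iter
        manifest["protocol"]["bym_n_warmup_run"] = post.n_warmup
        manifest["protocol"]["bym_draws_kept_per_chain"] = post.n_draws_per_chain
        manifest["stages"][stage] = "ok"

        # ---- stage 6: report -------------------------------------------
        stage = "report"
        chains = ChainSet.from_bym(post, include_taus=True)
        rhat = gelman_rubin(chains)
        ess = effective_sample_size(chains)
        diag = pd.DataFrame({"rhat": rhat, "ess": ess["ess"]})
        diag.index.name = "parameter"
        diag.to_csv(out / "diagnostics.csv")
        gates = cfg["report"]
        manifest["convergence"] = {
            "max_rhat": float(rhat.max()),
            "min_ess": float(ess["ess"].min()),
            "rhat_ok": bool(rhat.max() < float(gates["rhat_max"])),
            "ess_ok": bool(ess["ess"].min() > float(gates["ess_min"])),
        }
        if regions is not None:
            ch = write_choropleth_geojson(
                regions, dict(zip(data.area_ids, ratios)), "smr"
            )
            ch = write_choropleth_geojson(
                ch, dict(zip(rr["area_id"], rr["theta_mean"])), "theta_mean"
            )
            (out / "choropleth.geojson").write_text(json.dumps(ch))
        else:
            manifest["choropleth"] = "skipped (no polygons supplied)"
        manifest["stages"][stage] = "ok"
    except ConfigError as err:
        manifest["stages"][stage] = "failed"
        manifest["error"] = str(err)
        return _finish(EXIT_VALIDATION)
    except Exception as err:  # noqa: BLE001 - boundary: report and exit nonzero
        manifest["stages"][stage] = "failed"
        manifest["error"] = f"{type(err).__name__}: {err}"
        manifest["traceback"] = traceback.format_exc()
        return _finish(EXIT_RUNTIME)

    return _finish(EXIT_OK)
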