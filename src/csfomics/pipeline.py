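"""End-to-end orchestration: simulate -> screen -> validate -> search -> report.

Stage order mirrors the analysis flow of a prognostic CSF biomarker
study: clinical chemistry first, then metabolomics, then proteomics
(with elastic-net prefiltering), then the combined multi-omics panel
search over the block-wise shortlists.  Every artifact is stamped with
the configuration hash and master seed; re-running with the same
configuration reproduces all numeric outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diagnostics
from .cohort import CohortConfig, EXAMPLE_METABOLITE_EFFECTS, generate_cohort
from .ensemble import EnsembleConfig, validate_model
from .errors import ConfigError, PipelineError
from .io import read_matrix, write_matrix, write_report
from .oplsda import fit_oplsda, vip
from .panels import best_by_size, panels_frame, search_panels, stopping_check
from .selection import ElasticNetConfig, make_selector

logger = logging.getLogger(__name__)

STAGES = ("simulate", "screen", "validate", "shortlist", "search", "report")


@dataclass
class RunConfig:
    """Master configuration for a pipeline run (seed is mandatory)."""

    seed: int
    outdir: str = "csfomics_run"
    matrix_path: str | None = None     # load instead of simulate
    block_path: str | None = None
    cohort: CohortConfig | None = None
    n_iter: int = 1000
    n_perm: int = 1000
    n_orth: int = 1
    test_fraction: float = 0.10
    elastic_net: ElasticNetConfig = field(default_factory=ElasticNetConfig)
    shortlist_cap: int = 20
    k_min: int = 1
    k_max: int = 6
    search_budget: int = 20000
    search_n_iter: int = 100
    final_n_iter: int = 1000
    stop_margin: float = 0.01

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "seed" not in doc:
            raise ConfigError("config must set a master seed")
        if "cohort" in doc and doc["cohort"] is not None:
            doc["cohort"] = CohortConfig(**doc["cohort"])
        if "elastic_net" in doc and doc["elastic_net"] is not None:
            en = doc["elastic_net"]
            if "alpha_grid" in en:
                en["alpha_grid"] = tuple(en["alpha_grid"])
            doc["elastic_net"] = ElasticNetConfig(**en)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def canonical(self) -> str:
        doc = dataclasses.asdict(self)
        return json.dumps(doc, sort_keys=True, default=str)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def _stage_log(outdir: Path, record: dict) -> None:
    with open(outdir / "stages.jsonl", "a") as fh:
        fh.write(json.dumps(record, default=str) + "\n")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns the run report as a dict.

    A stage failure writes a machine-readable ``error.json`` (partial
    outputs are retained) and raises :class:`PipelineError`.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "stages.jsonl").write_text("")
    stamp = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
    (outdir / "run.json").write_text(json.dumps(stamp, indent=2))
    seeds = np.random.SeedSequence(cfg.seed).spawn(8)
    child = [int(s.generate_state(1)[0] % 2**31) for s in seeds]

    current = "simulate"
    try:
        # -- stage 1: simulate or load --------------------------------------
        t0 = time.time()
        if cfg.matrix_path is not None:
            matrix = read_matrix(cfg.matrix_path, block_path=cfg.block_path)
        else:
            cohort_cfg = cfg.cohort or CohortConfig(
                metabolite_effects=dict(EXAMPLE_METABOLITE_EFFECTS),
                seed=child[0],
            )
            cohort, matrix = generate_cohort(cohort_cfg)
            cohort.to_csv(outdir / "cohort.csv")
        write_matrix(matrix, outdir / "matrix.csv", outdir / "blocks.tsv")
        _stage_log(outdir, {"stage": "simulate", "seed": child[0],
                            "n_samples": matrix.n_samples,
                            "n_features": matrix.n_features,
                            "elapsed_s": time.time() - t0})

        # -- stage 2: univariate screen per block ---------------------------
        current = "screen"
        t0 = time.time()
        screens = []
        for block in ("chemistry", "metabolite", "protein"):
            view = matrix.block_view(block)
            if view.n_features == 0:
                continue
            types = {
                c: ("categorical" if c == "ocgb" else "continuous")
                for c in view.values.columns
            }
            tbl = diagnostics.univariate_screen(view.values, view.y(), types)
            tbl.insert(0, "block", block)
            screens.append(tbl)
        screen_table = pd.concat(screens)
        screen_table.to_csv(outdir / "screen.csv")
        _stage_log(outdir, {"stage": "screen", "n_tested": len(screen_table),
                            "elapsed_s": time.time() - t0})

        # -- stage 3: per-block ensemble validation -------------------------
        current = "validate"
        t0 = time.time()
        block_results = {}
        for i, block in enumerate(("chemistry", "metabolite", "protein")):
            view = matrix.block_view(block)
            if view.n_features == 0:
                continue
            selector = None
            if block == "protein" and view.n_features > cfg.shortlist_cap:
                selector = make_selector(cfg.elastic_net)
            # with a per-iteration selector, empty selections are a valid
            # outcome (weak or permuted signal): relax the skip cap so the
            # permuted-label ensemble can run; skips stay logged and counted
            ecfg = EnsembleConfig(
                n_iter=cfg.n_iter, n_perm=cfg.n_perm, seed=child[1] + i,
                n_orth=cfg.n_orth, test_fraction=cfg.test_fraction,
                selector=selector, compute_importance=(selector is None),
                max_skip_fraction=1.0 if selector is not None else 0.05,
            )
            res = validate_model(view.values, view.y(), ecfg)
            res.to_json(outdir / f"ensemble_{block}.json")
            res.iterations_frame().to_csv(
                outdir / f"ensemble_{block}_iterations.csv", index=False
            )
            block_results[block] = res
        _stage_log(outdir, {
            "stage": "validate",
            "ks_p": {b: r.ks_p for b, r in block_results.items()},
            "elapsed_s": time.time() - t0,
        })

        # -- stage 4: shortlist ---------------------------------------------
        current = "shortlist"
        t0 = time.time()
        per_block_cap = max(1, cfg.shortlist_cap // max(1, len(block_results)))
        shortlist: list[str] = []
        for block, res in block_results.items():
            view = matrix.block_view(block)
            if res.importance is not None and len(res.importance):
                ranked = list(res.importance.index)
            else:
                # high-dimensional blocks: rank by selection frequency,
                # then by VIP of a whole-block fit
                freq: dict[str, int] = {}
                for sel in res.selected_sets:
                    for f in sel:
                        freq[f] = freq.get(f, 0) + 1
                if freq:
                    ranked = sorted(freq, key=lambda f: -freq[f])
                else:
                    model = fit_oplsda(view.values, view.y(), n_orth=cfg.n_orth,
                                       compute_q2=False)
                    ranked = list(vip(model).sort_values("vip", ascending=False).index)
            shortlist.extend(ranked[:per_block_cap])
        shortlist = list(dict.fromkeys(shortlist))[: cfg.shortlist_cap]
        (outdir / "shortlist.txt").write_text("\n".join(shortlist) + "\n")
        _stage_log(outdir, {"stage": "shortlist", "n": len(shortlist),
                            "elapsed_s": time.time() - t0})

        # -- stage 5: panel search ------------------------------------------
        current = "search"
        t0 = time.time()
        search_cfg = EnsembleConfig(
            n_iter=cfg.search_n_iter, n_perm=1, seed=child[2],
            n_orth=cfg.n_orth, test_fraction=cfg.test_fraction,
            compute_q2=False,
        )
        results = search_panels(
            matrix.values, matrix.y(), shortlist,
            k_min=cfg.k_min, k_max=cfg.k_max, cfg=search_cfg,
            budget=cfg.search_budget,
        )
        panels_frame(results).to_csv(outdir / "panels.csv", index=False)
        by_k = best_by_size(results)
        k_sel = stopping_check(by_k, margin=cfg.stop_margin)
        final_panel = by_k[k_sel]
        final_cfg = EnsembleConfig(
            n_iter=cfg.final_n_iter, n_perm=cfg.n_perm, seed=child[3],
            n_orth=cfg.n_orth, test_fraction=cfg.test_fraction,
        )
        final_res = validate_model(
            matrix.values[list(final_panel.features)], matrix.y(), final_cfg
        )
        from math import comb

        total_combos = sum(
            comb(len(shortlist), k) for k in range(cfg.k_min, min(cfg.k_max, len(shortlist)) + 1)
        )
        final_doc = {
            "panel": list(final_panel.features),
            "selected_size": k_sel,
            "search_mode": "exhaustive" if total_combos <= cfg.search_budget else "beam",
            **final_res.summary(),
            **stamp,
        }
        (outdir / "panel_final.json").write_text(
            json.dumps(final_doc, indent=2, default=float)
        )
        _stage_log(outdir, {"stage": "search", "selected": final_doc["panel"],
                            "elapsed_s": time.time() - t0})

        # -- stage 6: report -------------------------------------------------
        current = "report"
        t0 = time.time()
        rows = []
        for feat in shortlist:
            roc = diagnostics.roc_curve(matrix.values[feat].to_numpy(), matrix.y())
            rows.append(
                {
                    "marker": feat, "auc": roc.auc, "ci_low": roc.ci95[0],
                    "ci_high": roc.ci95[1], "acc": roc.acc, "sens": roc.sens,
                    "spec": roc.spec, "ppv": roc.ppv, "npv": roc.npv,
                    "threshold": roc.threshold, "odds_ratio": roc.odds_ratio,
                    "p_value": roc.p_auc,
                }
            )
        rows.append(
            {
                "marker": "panel:" + "+".join(final_panel.features),
                "auc": final_res.pooled_auc(),
                "acc": final_res.mean_accuracy,
                "sens": float(np.nanmean(final_res.sensitivities)),
                "spec": float(np.nanmean(final_res.specificities)),
                "p_value": final_res.ks_p,
            }
        )
        write_report(rows, outdir / "report.csv", outdir / "report.tsv")
        _stage_log(outdir, {"stage": "report", "elapsed_s": time.time() - t0})

        return {
            "outdir": str(outdir),
            "panel": list(final_panel.features),
            "panel_auc": final_res.pooled_auc(),
            "panel_accuracy": final_res.mean_accuracy,
            "ks_p_blocks": {b: r.ks_p for b, r in block_results.items()},
            "panel_ks_p": final_res.ks_p,
            **stamp,
        }
    except Exception as exc:  # stage failure: machine-readable record
        record = {"stage": current, "error": type(exc).__name__, "message": str(exc)}
        (outdir / "error.json").write_text(json.dumps(record, indent=2))
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {current!r} failed: {exc}") from exc
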