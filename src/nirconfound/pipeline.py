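"""End-to-end run orchestration and publication-style CSV artifacts.

``run_all`` executes simulate (when no input tables are given), preprocess,
Workflow A, partitioning, Workflow B step 1 and the Monte Carlo step, writing
every tabular output as CSV into one artifact directory together with the
resolved configuration, an ``algorithms.lock`` parameter dump, a structured
log with all per-stage seeds and sample counts, and a MANIFEST recording
completion state.  Every random draw traces to the single root seed, so two
runs with the same config produce byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import algorithms as zoo
from .io import read_inventory, write_inventory
from .monte_carlo import MCConfig, run_mc
from .simulate import EffectModel, GeneratorConfig, generate_dataset
from .spectra import (
    CONSTITUENTS,
    Inventory,
    PreprocessParams,
    average_replicates,
    preprocess_inventory,
)
from .workflow_a import run_workflow_a
from .workflow_b import DEFAULT_N_PAIRS, run_step1

__all__ = ["RunConfig", "run_all", "group_mean_spectra"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "workflow_a", "partition", "workflow_b", "monte_carlo")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    root_seed: int = 0
    output_dir: str = "nirconfound_run"
    spectra_path: str | None = None
    metadata_path: str | None = None
    window_length: int = 13
    poly_order: int = 2
    derivative_order: int = 1
    algorithms: tuple[str, ...] = zoo.ALGORITHM_NAMES
    k_folds: int = 10
    mc_iterations: int = 100
    mc_algorithm: str = "SVM"
    n_pairs: int | None = DEFAULT_N_PAIRS
    constituents: tuple[str, ...] = CONSTITUENTS

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["algorithms"] = list(self.algorithms)
        d["constituents"] = list(self.constituents)
        return d


def _stage_seed(root_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence(entropy=root_seed, spawn_key=(STAGES.index(stage),))
    return int(ss.generate_state(1)[0] % (2**31))


def group_mean_spectra(preprocessed: Inventory) -> pd.DataFrame:
    """Mean preprocessed (derivative) spectrum per reporting group.

    Groups mirror the standard presentation: maturity (Day 7 / Day 28 /
    controls) and presence/absence of each constituent among test samples.
    """
    means = {"wavelength_nm": np.round(preprocessed.grid.values, 1)}

    def mean_of(samples):
        if not samples:
            return np.full(len(preprocessed.grid), np.nan)
        return np.mean([average_replicates(s).intensities for s in samples], axis=0)

    tests = [s for s in preprocessed.samples if not s.is_control]
    means["day7"] = mean_of([s for s in tests if s.day == 7])
    means["day28"] = mean_of([s for s in tests if s.day == 28])
    means["controls"] = mean_of([s for s in preprocessed.samples if s.is_control])
    for c in CONSTITUENTS:
        means[f"{c}_yes"] = mean_of([s for s in tests if s.flag(c)])
        means[f"{c}_no"] = mean_of([s for s in tests if not s.flag(c)])
    return pd.DataFrame(means)


def run_all(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns the MANIFEST dict.

    Any stage failure leaves the artifacts written so far plus a MANIFEST
    noting which stages completed, then re-raises.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root_logger = logging.getLogger("nirconfound")
    root_logger.addHandler(handler)
    root_logger.setLevel(logging.INFO)

    manifest: dict = {"stages_done": [], "config": cfg.to_dict(), "artifacts": []}

    def emit(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out / name, index=False)
        manifest["artifacts"].append(name)

    try:
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
        manifest["artifacts"].append("config.yaml")

        # -- simulate (or load) -------------------------------------------
        if cfg.spectra_path and cfg.metadata_path:
            inv = read_inventory(cfg.spectra_path, cfg.metadata_path)
            log.info("loaded inventory: %d samples, %d spectra", len(inv), inv.n_spectra())
        else:
            gen = GeneratorConfig(seed=_stage_seed(cfg.root_seed, "simulate"))
            inv = generate_dataset(gen, EffectModel())
            write_inventory(inv, out / "spectra.csv", out / "metadata.csv")
            manifest["artifacts"] += ["spectra.csv", "metadata.csv"]
            log.info("simulated inventory: %d samples, %d spectra (generator seed %d)",
                     len(inv), inv.n_spectra(), gen.seed)
        manifest["stages_done"].append("simulate")

        # -- preprocess ----------------------------------------------------
        params = PreprocessParams(cfg.window_length, cfg.poly_order, cfg.derivative_order)
        pre = preprocess_inventory(inv, params)
        emit(group_mean_spectra(pre), "group_mean_spectra.csv")
        (out / "algorithms.lock").write_text(
            zoo.algorithm_lock_report(seed=cfg.root_seed, names=cfg.algorithms)
        )
        manifest["artifacts"].append("algorithms.lock")
        manifest["stages_done"].append("preprocess")
        log.info("preprocessing done: window %d, poly %d, derivative %d",
                 params.window_length, params.poly_order, params.derivative_order)

        # -- workflow A ----------------------------------------------------
        wa_seed = _stage_seed(cfg.root_seed, "workflow_a")
        table3 = run_workflow_a(pre, constituents=cfg.constituents,
                                algorithm_names=cfg.algorithms,
                                k=cfg.k_folds, seed=wa_seed)
        emit(table3[["constituent", "algorithm", "AUC", "F1"]], "table3_style.csv")
        emit(table3, "confusion_matrices.csv")
        manifest["stages_done"].append("workflow_a")
        log.info("workflow A done (seed %d): %d model evaluations", wa_seed, len(table3))

        # -- workflow B (partition + step 1) -------------------------------
        wb_seed = _stage_seed(cfg.root_seed, "workflow_b")
        comparison = run_step1(pre, constituents=cfg.constituents,
                               algorithm_names=cfg.algorithms,
                               seed=wb_seed, n_pairs=cfg.n_pairs)
        membership_rows = []
        for constituent, part in comparison.partitions.items():
            roles = [
                ("uncontrolled_train", part.uncontrolled_train_ids),
                ("controlled_train", part.controlled_train_ids),
                ("test", part.test_ids),
            ]
            assigned = set()
            for role, ids in roles:
                for sid in ids:
                    membership_rows.append(
                        {"sample_id": sid, "constituent": constituent, "role": role}
                    )
                    assigned.add(sid)
            for s in pre.samples:
                if s.sample_id not in assigned:
                    membership_rows.append(
                        {"sample_id": s.sample_id, "constituent": constituent,
                         "role": "excluded"}
                    )
            log.info("partition %s: uncontrolled %d, controlled %d, test %d samples",
                     constituent, len(part.uncontrolled_train_ids),
                     len(part.controlled_train_ids), len(part.test_ids))
        emit(pd.DataFrame(membership_rows).sort_values(
            ["constituent", "role", "sample_id"]).reset_index(drop=True),
            "membership.csv")
        manifest["stages_done"].append("partition")

        table4 = comparison.to_frame()
        summary_rows = []
        for constituent in cfg.constituents:
            summary_rows.append({
                "constituent": constituent,
                "F1_mean_difference": comparison.mean_difference(constituent, "F1"),
                "F1_p_value": comparison.f1_tests[constituent].p_value,
                "AUC_mean_difference": comparison.mean_difference(constituent, "AUC"),
                "AUC_p_value": comparison.auc_tests[constituent].p_value,
            })
        emit(table4, "table4_style.csv")
        emit(pd.DataFrame(summary_rows), "table4_summary.csv")
        manifest["stages_done"].append("workflow_b")
        log.info("workflow B step 1 done (seed %d)", wb_seed)

        # -- Monte Carlo ---------------------------------------------------
        mc_seed = _stage_seed(cfg.root_seed, "monte_carlo")
        fig4_rows, mc_summary = [], []
        from .monte_carlo import clean_inventory

        cleaned = clean_inventory(pre)
        for constituent in cfg.constituents:
            res = run_mc(cleaned, MCConfig(constituent=constituent,
                                           n_iterations=cfg.mc_iterations,
                                           algorithm=cfg.mc_algorithm,
                                           root_seed=mc_seed),
                         precleaned=True)
            for row in res.table.itertuples(index=False):
                for arm in ("controlled", "uncontrolled"):
                    fig4_rows.append({
                        "iteration": row.iteration,
                        "constituent": constituent,
                        "arm": arm,
                        "F1": getattr(row, f"F1_{arm}"),
                    })
            mc_summary.append({
                "constituent": constituent,
                "mean_delta_F1": res.t_test.mean_difference,
                "ci95_low": res.t_test.ci95_low,
                "ci95_high": res.t_test.ci95_high,
                "p_value": res.t_test.p_value,
                "n_iterations": cfg.mc_iterations,
            })
            log.info("MC %s: mean dF1 %.3f (CI %.3f..%.3f, p %.2g)",
                     constituent, res.t_test.mean_difference,
                     res.t_test.ci95_low, res.t_test.ci95_high, res.t_test.p_value)
        emit(pd.DataFrame(fig4_rows), "fig4_style.csv")
        emit(pd.DataFrame(mc_summary), "mc_summary.csv")
        manifest["stages_done"].append("monte_carlo")
        manifest["status"] = "complete"
    except Exception as exc:
        manifest["status"] = f"failed: {type(exc).__name__}: {exc}"
        raise
    finally:
        with open(out / "MANIFEST.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        root_logger.removeHandler(handler)
        handler.close()
    return manifest
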