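"""End-to-end pipeline runner with a file-backed configuration.

``run_pipeline`` drives simulate/load -> construct -> metrics -> community
-> stats -> classify and writes a deterministic directory layout::

    out/
      cohort/          matrices, lengths, nodes.csv, cohort.csv, spec JSON
      networks/        fractionally scaled + pruned matrices
      metrics/         global_metrics.csv, nodal_<metric>.csv
      partitions/      partitions.csv, hubs.csv, hub_prevalence.csv
      stats/           global_comparisons.csv, nodal_comparisons.csv, ...
      classification/  classification.json, feature_projection.csv
      report.json      stage summaries + manifest (config hash, seeds)

Re-running with the same config reproduces report.json byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectome import write_matrix
from .simulate import CohortSpec, generate_cohort, write_cohort
from .study import ConnectomeStudy

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    mode: str = "simulate"            # simulate | load
    input_dir: str | None = None      # cohort directory when mode == "load"
    out_dir: str = "neonet_run"
    cohort: dict = field(default_factory=dict)   # CohortSpec overrides
    prune_fraction: float = 0.05
    sparsities: list[float] = field(default_factory=lambda: [0.10, 0.15, 0.20, 0.25])
    run_binary: bool = False
    partition: str = "consensus"
    n_reps: int = 150
    tau: float = 0.5
    gamma: float = 1.0
    n_null: int = 0
    q_level: float = 0.05
    cv_schemes: list[str] = field(default_factory=lambda: ["loo", "5fold", "3fold"])
    cv_repeats: int = 10
    n_perm: int = 0
    include_motion: bool = False
    seed: int = 0

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls(**yaml.safe_load(text))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text())

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), ndigits)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and return the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- cohort -------------------------------------------------------------
    cohort_dir = out / "cohort"
    if config.mode == "simulate":
        spec = CohortSpec(**{"seed": config.seed, **config.cohort})
        connectomes, records = generate_cohort(spec)
        write_cohort(cohort_dir, connectomes, records, spec=spec)
        study = ConnectomeStudy(connectomes, records,
                                prune_fraction=config.prune_fraction,
                                include_motion=config.include_motion)
    elif config.mode == "load":
        if not config.input_dir or not Path(config.input_dir).exists():
            raise FileNotFoundError(f"input cohort directory {config.input_dir!r} not found")
        study = ConnectomeStudy.from_directory(config.input_dir,
                                               prune_fraction=config.prune_fraction,
                                               include_motion=config.include_motion)
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    # --- fit ----------------------------------------------------------------
    results = study.fit(seed=config.seed, partition=config.partition,
                        n_reps=config.n_reps, tau=config.tau, gamma=config.gamma,
                        n_null=config.n_null, q_level=config.q_level,
                        cv_schemes=tuple(config.cv_schemes),
                        cv_repeats=config.cv_repeats, n_perm=config.n_perm)

    # --- networks -----------------------------------------------------------
    net_dir = out / "networks"
    net_dir.mkdir(exist_ok=True)
    for sid, W in study._prepared().items():
        write_matrix(net_dir / f"{sid}.tsv", W)

    # --- metrics ------------------------------------------------------------
    met_dir = out / "metrics"
    met_dir.mkdir(exist_ok=True)
    results.global_table.to_csv(met_dir / "global_metrics.csv", index=False)
    for m, tbl in results.nodal.items():
        tbl.to_csv(met_dir / f"nodal_{m}.csv")

    # --- partitions / hubs --------------------------------------------------
    part_dir = out / "partitions"
    part_dir.mkdir(exist_ok=True)
    pd.DataFrame(results.partitions).T.to_csv(part_dir / "partitions.csv")
    pd.DataFrame({sid: h for sid, h in results.hub_classes.items()}).T.to_csv(
        part_dir / "hubs.csv")
    results.hub_prevalence.to_csv(part_dir / "hub_prevalence.csv", index=False)
    results.hub_counts.to_csv(part_dir / "hub_counts.csv", index=False)

    # --- stats --------------------------------------------------------------
    stats_dir = out / "stats"
    stats_dir.mkdir(exist_ok=True)
    results.global_comparisons.to_csv(stats_dir / "global_comparisons.csv", index=False)
    results.nodal_comparisons.to_csv(stats_dir / "nodal_comparisons.csv", index=False)
    results.hub_count_comparisons.to_csv(stats_dir / "hub_count_comparisons.csv", index=False)
    results.asymmetry.to_csv(stats_dir / "asymmetry.csv", index=False)
    results.fa_correlations.to_csv(stats_dir / "fa_correlations.csv", index=False)
    if config.run_binary:
        study.binary_comparisons(tuple(config.sparsities), q_level=config.q_level) \
            .to_csv(stats_dir / "binary_comparisons.csv", index=False)

    # --- classification -----------------------------------------------------
    cls_dir = out / "classification"
    cls_dir.mkdir(exist_ok=True)
    cls_summary = {}
    for scheme, rep in results.classification.items():
        cls_summary[scheme] = {
            "accuracy": rep.accuracy, "sensitivity": rep.sensitivity,
            "specificity": rep.specificity, "auc": rep.auc,
            "ci_low": rep.ci_low, "ci_high": rep.ci_high,
            "significant": rep.significant,
        }
    (cls_dir / "classification.json").write_text(json.dumps(_round_floats(cls_summary), indent=2))
    if results.feature_projection is not None:
        results.feature_projection.to_csv(cls_dir / "feature_projection.csv", index=False)

    # --- report -------------------------------------------------------------
    report = {
        "manifest": {
            "neonet_version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "n_subjects": len(study.connectomes),
        },
        "group_means": _round_floats(
            results.global_table.groupby("group")
            [[c for c in ("clustering", "path_length", "modularity", "density",
                          "small_worldness") if c in results.global_table.columns]]
            .mean().to_dict()),
        "global_comparisons": _round_floats(
            results.global_comparisons.to_dict(orient="records")),
        "n_significant_nodes": {
            f"{c} | {m}": int(s) for (c, m), s in
            results.nodal_comparisons.groupby(["contrast", "metric"])["significant"].sum().items()
        },
        "fa_correlations": _round_floats(results.fa_correlations.to_dict(orient="records")),
        "classification": _round_floats(cls_summary),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    (out / "config.yaml").write_text(config.to_yaml())
    return out
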