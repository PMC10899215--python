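"""End-to-end orchestration: configuration, seeded runs, fixtures, manifest.

A run executes simulate → resample → regress → static networks (activation
surfaces, VUS) → dynamic network (pooled and per-dose transition tables) →
pruning, writing tidy CSV/JSON artifacts plus a manifest recording the
stage, seed and checksum of every file.  All randomness flows from named
per-stage seeds derived from a single master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dbn, gbn, prune, regress, resample, simulate
from .errors import QAOPError
from .graph import AOPGraph, canonical_graph, mini_graph

log = logging.getLogger("qaopnet")

STAGE_NAMES = ("simulate", "resample", "regress", "gbn", "dbn", "prune")


def stage_seed(master: int, stage: str) -> int:
    """Stable per-stage seed below 2^31 derived from the master seed."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Everything a full run needs; all fields have study defaults."""

    design: simulate.StudyDesign = field(default_factory=simulate.StudyDesign)
    donor_table: list[simulate.DonorProfile] = field(
        default_factory=simulate.default_donor_table
    )
    graph: AOPGraph = field(default_factory=canonical_graph)
    delta: float = gbn.DELTA_DEFAULT
    epsilon: float | None = None      # dose half-window; default 5% of range
    n_logic_samples: int = 100_000
    n_sims_pooled: int = 100_000
    n_sims_dose: int = 10_000
    out_dir: Path = Path("qaopnet_run")
    master_seed: int = 0
    run_regressions: bool = False     # pairwise LMM table is slow; opt in

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw = {}
        if "design" in raw:
            d = dict(raw["design"])
            if "doses" in d:
                d["doses"] = tuple(float(x) for x in d["doses"])
            kw["design"] = simulate.StudyDesign(**d)
        if "donor_table" in raw:
            kw["donor_table"] = [
                simulate.DonorProfile(int(r["donor_id"]),
                                      r.get("onset_exposure"),
                                      r.get("severity", "none"))
                for r in raw["donor_table"]
            ]
        if "graph_path" in raw:
            from .graph import load_graph
            kw["graph"] = load_graph(raw["graph_path"])
        for key in ("delta", "epsilon", "n_logic_samples", "n_sims_pooled",
                    "n_sims_dose", "master_seed", "run_regressions"):
            if key in raw:
                kw[key] = raw[key]
        if "out_dir" in raw:
            kw["out_dir"] = Path(raw["out_dir"])
        return cls(**kw)

    def resolved_epsilon(self) -> float:
        if self.epsilon is not None:
            return float(self.epsilon)
        return 0.05 * (max(self.design.doses) - min(self.design.doses))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class Manifest:
    def __init__(self, out_dir: Path, master_seed: int):
        self.out_dir = out_dir
        self.entries: list[dict] = []
        self.master_seed = master_seed

    def add(self, stage: str, path: Path, seed: int) -> None:
        self.entries.append({
            "stage": stage,
            "file": str(path.relative_to(self.out_dir)),
            "seed": seed,
            "sha256": _checksum(path),
        })

    def save(self) -> Path:
        path = self.out_dir / "manifest.json"
        payload = {"master_seed": self.master_seed, "artifacts": self.entries}
        path.write_text(json.dumps(payload, indent=1))
        return path


def run_pipeline_core(
    config: RunConfig,
) -> tuple[simulate.PrimaryDataset, resample.ReplicateDataset]:
    """simulate + resample, the shared front of every analysis."""
    design = config.design.with_seed(stage_seed(config.master_seed, "simulate"))
    primary = simulate.generate_primary(design, config.donor_table, config.graph)
    replicates = resample.simulate_replicates(
        primary, seed=stage_seed(config.master_seed, "resample")
    )
    return primary, replicates


def run_all(config: RunConfig) -> dict:
    """Full pipeline; returns the manifest payload."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(out, config.master_seed)
    eps = config.resolved_epsilon()
    E = config.design.n_exposures

    try:
        primary, replicates = run_pipeline_core(config)
    except QAOPError:
        log.exception("stage simulate/resample failed")
        raise

    seed_sim = stage_seed(config.master_seed, "simulate")
    p = out / "primary.csv"
    primary.to_csv(p)
    manifest.add("simulate", p, seed_sim)
    p = out / "replicates.csv"
    replicates.replicates.to_csv(p, index=False)
    manifest.add("resample", p, stage_seed(config.master_seed, "resample"))
    p = out / "replicate_means.csv"
    replicates.means.to_csv(p, index=False)
    manifest.add("resample", p, stage_seed(config.master_seed, "resample"))

    # dose-response (and optionally pairwise) R2 tables
    seed_reg = stage_seed(config.master_seed, "regress")
    dose_r2 = regress.r2_table(replicates, "dose")
    p = out / "dose_r2.csv"
    dose_r2.to_csv(p, index=False)
    manifest.add("regress", p, seed_reg)
    if config.run_regressions:
        for mode in ("rr-lmm", "rr-poly"):
            tab = regress.r2_table(replicates, mode)
            p = out / f"{mode.replace('-', '_')}_r2.csv"
            tab.to_csv(p, index=False)
            manifest.add("regress", p, seed_reg)

    # static networks per exposure with activation surfaces and VUS
    seed_gbn = stage_seed(config.master_seed, "gbn")
    delta_grid, dose_grid = gbn.default_grids(
        (min(config.design.doses), max(config.design.doses)),
        config.design.doses,
    )
    vus_rows, r2_rows = [], []
    for e in range(1, E + 1):
        model = gbn.fit_gbn(replicates, e, config.graph)
        p = out / f"gbn_e{e}.json"
        model.save(p)
        manifest.add("gbn", p, seed_gbn)
        samples = gbn.logic_sample(model, config.n_logic_samples, seed_gbn + e)
        for v in config.graph.biology_nodes:
            if not v.startswith(("KE", "AO")):
                continue
            surf = gbn.probability_surface(
                samples, v, e, delta_grid, dose_grid, eps
            )
            vus_rows.append({"node": v, "exposure": e, "vus": surf.vus})
        r2_rows.extend(
            {"node": v, "exposure": e, "r2": r}
            for v, r in model.node_r2.items()
        )
    p = out / "gbn_r2.csv"
    pd.DataFrame(r2_rows).to_csv(p, index=False)
    manifest.add("gbn", p, seed_gbn)
    p = out / "vus.csv"
    pd.DataFrame(vus_rows).to_csv(p, index=False)
    manifest.add("gbn", p, seed_gbn)

    # dynamic network: pooled and dose-specific transition tables
    seed_dbn = stage_seed(config.master_seed, "dbn")
    model = dbn.fit_dbn(replicates, config.graph)
    p = out / "dbn_pooled.json"
    model.save(p)
    manifest.add("dbn", p, seed_dbn)
    pooled = dbn.transition_table(
        model, replicates, config.delta, config.n_sims_pooled, seed_dbn
    )
    p = out / "transitions_pooled.csv"
    pooled.to_csv(p, index=False)
    manifest.add("dbn", p, seed_dbn)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", dbn.SmallSampleWarning)
        per_dose = dbn.dose_specific_transitions(
            replicates, config.graph, config.delta, config.n_sims_dose,
            seed_dbn + 1,
        )
    p = out / "transitions_per_dose.csv"
    per_dose.to_csv(p, index=False)
    manifest.add("dbn", p, seed_dbn + 1)

    # pruning and recomputation
    seed_pr = stage_seed(config.master_seed, "prune")
    pruned = prune.lasso_prune(replicates, config.graph)
    p = out / "pruning_report.csv"
    pruned.report().to_csv(p, index=False)
    manifest.add("prune", p, seed_pr)
    ptab = prune.pruned_transitions(
        pruned, replicates, config.delta, config.n_sims_pooled, seed_pr
    )
    p = out / "transitions_pruned.csv"
    ptab.to_csv(p, index=False)
    manifest.add("prune", p, seed_pr)

    path = manifest.save()
    log.info("run complete: %s artifacts in %s", len(manifest.entries), out)
    return json.loads(path.read_text())


def make_fixtures(scale: str = "tiny", seed: int = 0):
    """Deterministic fixture bundles for tests and demos.

    ``tiny``: 2 donors × 2 doses × 3 exposures on a 5-biology-node chain
    (fast enough for unit tests); ``default``: the full study layout.
    Returns (primary, replicates).
    """
    if scale == "tiny":
        design = simulate.StudyDesign(
            doses=(0.0, 100.0), n_donors=2, n_exposures=3, n_replicates=3,
            kappa=50, seed=seed,
        )
        donors = [
            simulate.DonorProfile(1, 2, "severe"),
            simulate.DonorProfile(2, None, "none"),
        ]
        graph = mini_graph()
    elif scale == "default":
        design = simulate.StudyDesign(seed=seed)
        donors = simulate.default_donor_table()
        graph = canonical_graph()
    else:
        raise ValueError(f"unknown scale {scale!r}")
    primary = simulate.generate_primary(design, donors, graph)
    replicates = resample.simulate_replicates(primary)
    return primary, replicates
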