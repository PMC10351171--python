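"""Validation metrics and end-to-end scenario orchestration.

``run_experiment`` drives the whole pipeline — simulate, assemble panels,
profile the dimensionality of the genotyped cohort, select nested
discovery/training sets, scan, predict — over a grid of scenarios and
replicates, with per-stage child seeds derived from one master seed.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import spawn_rng
from .dimensionality import (
    build_grm_centered_scan,
    eigen_profile_from_genotypes,
    make_selection_sets,
)
from .gwas import assoc_scan, classify_hits, reml_null, total_var_explained
from .panels import augment_panel, build_chip_panel, build_sequence_panel
from .predict import run_prediction_scenario
from .simpop import SimConfig, simulate

logger = logging.getLogger("genodim")

__all__ = [
    "accuracy",
    "dispersion_b1",
    "accuracy_gain_pct",
    "ScenarioSpec",
    "MetricTable",
    "run_experiment",
    "aggregate_metrics",
]


class MetricError(ValueError):
    pass


def accuracy(tbv: np.ndarray, gebv: np.ndarray) -> float:
    """Pearson correlation between true and estimated breeding values."""
    tbv = np.asarray(tbv, dtype=float)
    gebv = np.asarray(gebv, dtype=float)
    if len(tbv) < 3:
        raise MetricError("need at least 3 test animals")
    if tbv.std() == 0 or gebv.std() == 0:
        raise MetricError("zero variance: accuracy undefined")
    return float(np.corrcoef(tbv, gebv)[0, 1])


def dispersion_b1(tbv: np.ndarray, gebv: np.ndarray) -> float:
    """Slope of TBV regressed on GEBV; < 1 flags inflation, > 1 deflation."""
    tbv = np.asarray(tbv, dtype=float)
    gebv = np.asarray(gebv, dtype=float)
    v = gebv.var()
    if v == 0:
        raise MetricError("zero GEBV variance: dispersion undefined")
    return float(np.cov(tbv, gebv, ddof=0)[0, 1] / v)


def accuracy_gain_pct(acc_with: float, acc_base: float) -> float:
    """Relative accuracy gain in percent over a baseline panel."""
    if acc_base <= 0:
        raise MetricError("baseline accuracy must be positive")
    return 100.0 * (acc_with - acc_base) / acc_base


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the experiment grid."""

    name: str
    config: SimConfig
    eigx_levels: tuple[float, ...] = (50, 90, 98)
    topv: tuple[int, ...] = ()
    include_sig: bool = True
    models: tuple[str, ...] = ("ssgblup", "pblup")
    scheme: str = "distinct"
    alpha: float = 0.05
    # scenarios sharing a seed_group get identical per-replicate simulation
    # streams, pairing comparisons that differ only in trait parameters
    seed_group: str | None = None


@dataclass
class MetricTable:
    """Long-format per-replicate metrics; aggregation is recomputable."""

    table: pd.DataFrame

    def aggregate(self) -> pd.DataFrame:
        return aggregate_metrics(self.table)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MetricTable":
        return cls(pd.read_csv(path, sep="\t"))


def aggregate_metrics(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and SE (sd / sqrt(n_replicates)) over replicates."""
    keys = ["scenario", "eigx", "panel", "model"]
    metrics = ["accuracy", "b1", "pct_var_total", "n_sig_qtn", "n_sig_snp"]
    grouped = table.groupby(keys, dropna=False)[metrics]
    mean = grouped.mean().add_suffix("_mean")
    n = grouped.count()
    se = (grouped.std(ddof=1) / np.sqrt(n)).add_suffix("_se")
    out = pd.concat([mean, se, n["accuracy"].rename("n_replicates")], axis=1)
    return out.reset_index()


def _replicate_rows(spec: ScenarioSpec, rep: int, master_seed: int) -> list[dict]:
    """Run one replicate of one scenario; returns long-format metric rows."""
    child = spawn_rng(master_seed, spec.seed_group or spec.name, rep, "seed")
    rep_seed = int(child.integers(0, 2**63 - 1))
    sim = simulate(spec.config, seed=rep_seed)
    cfg = sim.config
    gmap = sim.genome_map
    pop = sim.population

    seq_panel = build_sequence_panel(gmap)
    chip = build_chip_panel(gmap, step=cfg.chip_step)

    genotyped = pop.pedigree.loc[pop.pedigree["genotyped"], ["id", "generation"]]
    snp_idx = np.flatnonzero(gmap.snp_mask)
    geno_snp = pop.genotypes(ids=genotyped["id"].to_numpy(), loci=snp_idx)
    profile = eigen_profile_from_genotypes(geno_snp)

    sets = make_selection_sets(
        genotyped,
        profile,
        spec.eigx_levels,
        scheme=spec.scheme,
        rng=spawn_rng(master_seed, spec.seed_group or spec.name, rep, "sets"),
    )
    test_ids = next(s.ids for s in sets if s.role == "test")
    tbv_test = sim.tbv_of(test_ids)
    by_role = {
        (s.role, s.eigx_label): s.ids for s in sets if s.role != "test"
    }
    labels = [f"EIG{x:g}" for x in spec.eigx_levels] + ["ALL"]

    seq_loci = seq_panel.indices_in(gmap)
    rows: list[dict] = []
    for label in labels:
        disc_ids = by_role[("discovery", label)]
        train_ids = by_role[("training", label)]
        logger.info(
            "%s rep %d %s: discovery=%d training=%d",
            spec.name, rep, label, len(disc_ids), len(train_ids),
        )

        y = sim.phenotypes.phenotypes_of(disc_ids)
        Xd = pop.genotypes(ids=disc_ids, loci=seq_loci)
        grm_scan = build_grm_centered_scan(Xd)
        vc = reml_null(y, grm_scan)
        assoc = assoc_scan(
            y,
            Xd,
            grm_scan,
            vc,
            genome_map=gmap,
            locus_ids=gmap.locus_ids[seq_loci],
            alpha=spec.alpha,
        )
        hits = classify_hits(assoc)
        disc_freqs = Xd.mean(axis=0) / 2.0
        qtn_in_seq = np.isin(gmap.locus_ids[seq_loci], sim.architecture.qtn_ids)
        pct_var = total_var_explained(
            assoc,
            sim.architecture,
            disc_freqs[qtn_in_seq],
            freq_locus_ids=gmap.locus_ids[seq_loci][qtn_in_seq],
        )

        panels = [chip]
        for v in spec.topv:
            panels.append(augment_panel(chip, assoc, "TOP", v=v, genome_map=gmap))
        if spec.include_sig:
            panels.append(augment_panel(chip, assoc, "SIG", genome_map=gmap))

        base = {
            "scenario": spec.name,
            "replicate": rep,
            "eigx": label,
            "n_discovery": len(disc_ids),
            "n_training": len(train_ids),
            "pct_var_total": pct_var,
            "n_sig_qtn": hits.n_significant_qtn,
            "n_sig_snp": hits.n_significant_snp,
        }
        for model in spec.models:
            model_panels = panels if model == "ssgblup" else [chip]
            for panel in model_panels:
                res = run_prediction_scenario(
                    pop,
                    sim.phenotypes,
                    panel,
                    train_ids,
                    test_ids,
                    sigma_u2=cfg.sigma_u2,
                    sigma_e2=cfg.phenotypic_variance - cfg.sigma_u2,
                    model=model,
                    training_label=label,
                )
                gebv = res.gebv_of(test_ids)
                rows.append(
                    base
                    | {
                        "panel": panel.label if model == "ssgblup" else "PED",
                        "model": model,
                        "accuracy": accuracy(tbv_test, gebv),
                        "b1": dispersion_b1(tbv_test, gebv),
                    }
                )
    return rows


def run_experiment(
    specs,
    n_replicates: int,
    seed: int,
    out_dir: str | None = None,
) -> MetricTable:
    """Run every (scenario, replicate) cell; failures abort that replicate
    only and are recorded, aggregation proceeds over completed cells."""
    all_rows: list[dict] = []
    failures: list[dict] = []
    for spec in specs:
        for rep in range(n_replicates):
            try:
                all_rows.extend(_replicate_rows(spec, rep, seed))
            except Exception as exc:  # noqa: BLE001 - recorded, not swallowed silently
                logger.warning("scenario %s replicate %d failed: %s", spec.name, rep, exc)
                failures.append(
                    {"scenario": spec.name, "replicate": rep, "error": str(exc)}
                )
    table = MetricTable(pd.DataFrame(all_rows))
    if failures:
        logger.warning("%d replicate(s) failed", len(failures))
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        table.to_tsv(os.path.join(out_dir, "metrics_replicates.tsv"))
        table.aggregate().to_csv(
            os.path.join(out_dir, "metrics_aggregate.tsv"), sep="\t", index=False
        )
        manifest = {
            "seed": seed,
            "n_replicates": n_replicates,
            "scenarios": [s.name for s in specs],
            "failures": failures,
        }
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
    return table
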