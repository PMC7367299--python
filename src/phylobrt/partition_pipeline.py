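"""End-to-end analysis orchestration and the trait-vs-phylogeny partition.

The headline quantity of the analysis is a two-level deviance
decomposition:

* the boosted model explains ``total_pct`` percent of the deviance in the
  response (cross-validated, relative to the null model);
* relative influence (VI) scores, which sum to 100 over all predictors,
  are summed within the two predictor groups — species traits and
  phylogenetic eigenvectors — giving each group's share *of the model
  deviance*;
* multiplying ``total_pct`` by each group's fraction gives the group's
  share *of the response deviance*, and the two absolute shares sum back
  to ``total_pct``.

:func:`run_pipeline` composes the whole analysis — consensus tree,
patristic distances, principal coordinates, eigenvector selection, model
frame, boosted fit, influence scores, partition, partial dependence and
interaction screen — from a single config, either on user-supplied files
or on a simulated dataset, and writes a machine-readable report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import brt_engine, eigenspace, phylo_trees, synthetic_data, trait_table
from .brt_engine import BRTConfig
from .synthetic_data import SimConfig

__all__ = [
    "DeviancePartition",
    "AnalysisReport",
    "PipelineConfig",
    "PipelineStageError",
    "partition_vi",
    "absolute_deviance_shares",
    "run_pipeline",
]

GROUPS = ("trait", "phylogeny")


class PipelineStageError(RuntimeError):
    """An analysis stage failed; the message names the stage."""


@dataclass
class DeviancePartition:
    """Total percent deviance explained and its trait/phylogeny split."""

    total_pct: float
    group_vi_pct: dict
    group_abs_pct: dict

    def rounded(self, ndigits: int = 1) -> dict:
        return {
            "total_pct": round(self.total_pct, ndigits),
            "group_vi_pct": {
                g: round(v, ndigits) for g, v in self.group_vi_pct.items()
            },
            "group_abs_pct": {
                g: round(v, ndigits) for g, v in self.group_abs_pct.items()
            },
        }


def partition_vi(vi: pd.Series, groups: Mapping) -> dict:
    """Sum VI scores within predictor groups.

    ``groups`` maps every VI column to ``"trait"`` or ``"phylogeny"``;
    because VI scores sum to 100, so do the group sums.
    """
    out = {g: 0.0 for g in GROUPS}
    for col, score in vi.items():
        if col not in groups:
            raise ValueError(f"column {col!r} has no group tag")
        g = groups[col]
        if g not in out:
            raise ValueError(f"column {col!r} has unknown group {g!r}")
        out[g] += float(score)
    return out


def absolute_deviance_shares(total_pct: float, group_vi_pct: Mapping) -> dict:
    """Convert group shares of model deviance into shares of response deviance.

    Each group's absolute share is ``total_pct * group_vi_pct / 100``; the
    shares sum to ``total_pct``. (E.g. with a model explaining 73.8% of
    the response deviance and groups at 74.0/26.0 of the model deviance,
    the absolute shares are 54.6% and 19.2%.)
    """
    if not 0 <= total_pct <= 100:
        raise ValueError("total_pct must be in [0, 100]")
    total_group = sum(group_vi_pct.values())
    if abs(total_group - 100.0) > 1e-6:
        raise ValueError(f"group VI percentages must sum to 100, got {total_group}")
    return {g: total_pct * v / 100.0 for g, v in group_vi_pct.items()}


@dataclass
class AnalysisReport:
    """Full machine-readable output of one pipeline run."""

    partition: DeviancePartition
    vi_table: pd.Series
    chart_data: pd.Series
    pd_curves: dict
    interactions: list
    provenance: dict
    training_pct: float
    n_eigenvectors: int
    cum_fraction: float
    cv_deviance: float
    null_deviance: float
    selected_n_trees: int
    model_warnings: list

    def to_dict(self) -> dict:
        return {
            "partition": {
                "total_pct": self.partition.total_pct,
                "group_vi_pct": dict(self.partition.group_vi_pct),
                "group_abs_pct": dict(self.partition.group_abs_pct),
                "rounded": self.partition.rounded(),
            },
            "training_pct": self.training_pct,
            "vi_table": {k: float(v) for k, v in self.vi_table.items()},
            "chart_data": {k: float(v) for k, v in self.chart_data.items()},
            "pd_curves": {
                name: df.to_dict(orient="list")
                for name, df in self.pd_curves.items()
            },
            "interactions": [
                {"pair": list(pair), "strength": float(s)}
                for pair, s in self.interactions
            ],
            "n_eigenvectors": self.n_eigenvectors,
            "cum_fraction": self.cum_fraction,
            "cv_deviance": self.cv_deviance,
            "null_deviance": self.null_deviance,
            "selected_n_trees": self.selected_n_trees,
            "model_warnings": list(self.model_warnings),
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


@dataclass
class PipelineConfig:
    """One run's inputs, thresholds and hyperparameters.

    Either the four input paths are given (Newick tree set, trait CSV +
    schema YAML, species->subtype CSV, subtype->EC50 CSV), or
    ``simulate`` holds a :class:`SimConfig` and the inputs are generated.
    """

    trees_path: str | None = None
    traits_path: str | None = None
    schema_path: str | None = None
    subtypes_path: str | None = None
    ec50_path: str | None = None
    simulate: SimConfig | None = None
    consensus_threshold: float = 0.5
    eigen_threshold: float = 0.99
    response_transform: str = "zscore_log10"
    brt: BRTConfig = field(default_factory=BRTConfig)
    vi_cutoff: float = 0.5
    n_pd_curves: int = 6
    n_interaction_predictors: int = 5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "brt" in raw:
            raw["brt"] = BRTConfig(**raw["brt"])
        if "simulate" in raw:
            sim = raw["simulate"]
            raw["simulate"] = SimConfig(**sim) if isinstance(sim, dict) else sim
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(f"stage {name!r}: {exc}") from exc
            return False

    return _Ctx()


def _digest(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _two_column_csv(path, key, value) -> dict:
    df = pd.read_csv(path)
    return dict(zip(df[key], df[value]))


def run_pipeline(
    config: PipelineConfig | str | Path, out_dir=None
) -> AnalysisReport:
    """Execute the full analysis and (optionally) write its outputs.

    Stages: read/simulate trees -> majority-rule consensus -> patristic
    distances -> PCoA -> eigenvector selection -> model frame -> boosted
    fit -> VI scores -> deviance partition -> partial dependence ->
    interaction screen. Deterministic given the config (all randomness is
    governed by the seeds inside it).

    When ``out_dir`` is given, writes ``report.json``, ``vi.csv``,
    ``consensus.nwk``, ``eigenvectors.csv`` and one ``pd_<column>.csv``
    per curve.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)

    provenance: dict = {"config": _jsonable(config.to_dict())}

    with _stage("inputs"):
        if config.simulate is not None:
            sim = synthetic_data.simulate_dataset(config.simulate)
            trees = sim.trees
            traits = sim.traits
            subtype_by_species = sim.subtype_by_species
            ec50_by_subtype = sim.ec50_by_subtype
            provenance["inputs"] = {
                "source": "simulated",
                "traits_digest": _digest(traits.data.to_csv()),
            }
        else:
            required = {
                "trees_path": config.trees_path,
                "traits_path": config.traits_path,
                "schema_path": config.schema_path,
                "subtypes_path": config.subtypes_path,
                "ec50_path": config.ec50_path,
            }
            missing = [k for k, v in required.items() if v is None]
            if missing:
                raise ValueError(
                    f"missing input paths {missing} and no simulate block"
                )
            trees = phylo_trees.read_newick_trees(config.trees_path)
            traits = trait_table.TraitTable.read_csv(
                config.traits_path, config.schema_path
            )
            subtype_by_species = _two_column_csv(
                config.subtypes_path, "species", "subtype"
            )
            ec50_by_subtype = _two_column_csv(
                config.ec50_path, "subtype", "ec50"
            )
            provenance["inputs"] = {
                "source": "files",
                **{
                    k: _digest(Path(v).read_text())
                    for k, v in required.items()
                },
            }

    with _stage("consensus"):
        consensus = phylo_trees.majority_rule_consensus(
            trees, threshold=config.consensus_threshold
        )
    with _stage("distances"):
        D = phylo_trees.patristic_distance_matrix(consensus)
    with _stage("pcoa"):
        basis = eigenspace.pcoa(D)
        coords = eigenspace.select_eigenvectors(
            basis, cum_threshold=config.eigen_threshold
        )
    with _stage("response"):
        response = trait_table.build_response(
            subtype_by_species,
            ec50_by_subtype,
            transform=config.response_transform,
        )
    with _stage("frame"):
        traits_aligned = trait_table.TraitTable(
            data=traits.data.loc[response.species], schema=traits.schema
        )
        frame = trait_table.build_model_frame(traits_aligned, coords)
    with _stage("fit"):
        model = brt_engine.fit_brt(frame, response, config.brt)
    with _stage("importance"):
        vi = brt_engine.variable_importance(model).sort_values(
            ascending=False, kind="stable"
        )
        total_pct = brt_engine.percent_deviance_explained(model, mode="cv")
        training_pct = brt_engine.percent_deviance_explained(
            model, mode="training"
        )
    with _stage("partition"):
        group_vi = partition_vi(vi, frame.group_map)
        shares = absolute_deviance_shares(max(0.0, total_pct), group_vi)
        partition = DeviancePartition(
            total_pct=total_pct, group_vi_pct=group_vi, group_abs_pct=shares
        )
    with _stage("partial_dependence"):
        top = list(vi.index[: config.n_pd_curves])
        pd_curves = {
            name: brt_engine.partial_dependence(model, name) for name in top
        }
    with _stage("interactions"):
        screen_cols = list(vi.index[: config.n_interaction_predictors])
        interactions = []
        for a in range(len(screen_cols)):
            for b in range(a + 1, len(screen_cols)):
                s = brt_engine.interaction_strength(
                    model, screen_cols[a], screen_cols[b]
                )
                interactions.append(((screen_cols[a], screen_cols[b]), s))
        interactions.sort(key=lambda kv: (-kv[1], kv[0]))

    chart = vi[vi >= config.vi_cutoff]
    report = AnalysisReport(
        partition=partition,
        vi_table=vi,
        chart_data=chart,
        pd_curves=pd_curves,
        interactions=interactions,
        provenance=provenance,
        training_pct=training_pct,
        n_eigenvectors=coords.k,
        cum_fraction=coords.cum_fraction,
        cv_deviance=model.cv_deviance,
        null_deviance=model.null_deviance,
        selected_n_trees=model.selected_n_trees,
        model_warnings=model.warnings_,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json())
        vi.rename("vi").to_csv(out / "vi.csv", index_label="predictor")
        phylo_trees.write_newick(consensus, out / "consensus.nwk")
        coords.to_csv(out / "eigenvectors.csv")
        for name, curve in pd_curves.items():
            curve.to_csv(out / f"pd_{name}.csv", index=False)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
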