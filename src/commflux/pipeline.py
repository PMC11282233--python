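"""End-to-end two-condition community comparison.

One pipeline run mirrors the full analysis: per-member QC, optional member
FBA and biomass-sensitivity scans, community assembly, per-condition FBA and
FVA, flux-space comparison, exchange accounting, cross-feeding inference,
and a manifest capturing every parameter so the bundle is auditable and a
re-run is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .community import (
    add_community_biomass,
    apply_condition,
    merge_models,
    read_abundances,
)
from .exchange import (
    compare_conditions,
    cross_feeding_edges,
    edges_to_graph,
    species_exchange_fluxes,
)
from .fba import optimize, parsimonious_fluxes
from .fva import aggregate_by_subsystem, compare_flux_spaces, flux_variability
from .model import apply_media, read_media, read_model
from .qc import qc_report
from .sensitivity import sensitivity_scan

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("commflux.pipeline")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """Everything one comparison run needs, resolvable up front."""

    members: dict[str, str]                  # tag -> model path
    media: str                               # media TSV (shared by conditions)
    abundances: str                          # abundance TSV
    conditions: tuple[str, str]              # exactly two, compared A -> B
    outdir: str = "results"
    gamma: float = 1.0                       # FVA fraction of optimum
    delta: float = 0.20                      # sensitivity perturbation
    run_member_analyses: bool = True
    parsimonious: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        doc["conditions"] = tuple(doc["conditions"])
        return cls(**doc)

    def validate(self) -> None:
        if len(self.conditions) != 2:
            raise ValueError(
                f"exactly 2 conditions are compared, got {len(self.conditions)}"
            )
        if len(self.members) < 2:
            raise ValueError("a community needs at least 2 members")
        missing = [p for p in [self.media, self.abundances, *self.members.values()]
                   if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"config paths not found: {missing}")


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return out
        inner.__name__ = fn.__name__
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute every stage and write the report bundle; returns artifact paths.

    The run is deterministic for a fixed config (one LP backend, stable
    orderings); a failed stage aborts with its name and leaves a manifest
    recording how far the run got.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    manifest: dict = {
        "version": __version__,
        "config": {
            "members": config.members, "media": config.media,
            "abundances": config.abundances, "conditions": list(config.conditions),
            "gamma": config.gamma, "delta": config.delta, "seed": config.seed,
            "parsimonious": config.parsimonious,
            "cross_feeding_attribution": "proportional",
        },
        "stages_completed": [],
        "failed_stage": None,
    }

    def _write_manifest():
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")

    def _save(key: str, frame, name: str):
        path = outdir / name
        frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
        artifacts[key] = path

    try:
        members = {tag: read_model(path) for tag, path in config.members.items()}
        media = read_media(config.media)
        profiles = read_abundances(config.abundances)
        for cond in config.conditions:
            if cond not in profiles:
                raise PipelineError(
                    f"stage 'load' failed: condition {cond!r} not in abundance table"
                )
        manifest["stages_completed"].append("load")

        tags = sorted(members)
        if config.run_member_analyses:
            for tag in tags:
                report = _stage(f"qc[{tag}]")(qc_report)(
                    members[tag], _member_media(media, members[tag])
                )
                path = outdir / f"qc_{tag}.tsv"
                report.to_tsv(path)
                artifacts[f"qc_{tag}"] = path

                constrained = apply_media(members[tag],
                                          _member_media(media, members[tag]))
                state = _stage(f"fba[{tag}]")(
                    parsimonious_fluxes if config.parsimonious else optimize
                )(constrained)
                if state.optimal and state.objective_value > 0:
                    scan = _stage(f"sensitivity[{tag}]")(sensitivity_scan)(
                        constrained, config.delta
                    )
                    _save(f"sensitivity_{tag}", scan.to_frame(),
                          f"sensitivity_{tag}.tsv")
            manifest["stages_completed"].append("member_analyses")

        base_community = _stage("merge")(merge_models)(
            [members[t] for t in tags], tags
        )
        cond_a, cond_b = config.conditions
        community_a = add_community_biomass(base_community, profiles[cond_a])
        community_b = apply_condition(community_a, profiles[cond_b])
        manifest["stages_completed"].append("community_build")

        solve = parsimonious_fluxes if config.parsimonious else optimize
        states, ranges = {}, {}
        for cond, community in ((cond_a, community_a), (cond_b, community_b)):
            constrained = apply_media(community, media)
            state = _stage(f"fba[{cond}]")(solve)(constrained)
            if not state.optimal:
                raise PipelineError(f"stage 'fba[{cond}]' failed: status {state.status}")
            states[cond] = (constrained, state)
            ranges[cond] = _stage(f"fva[{cond}]")(flux_variability)(
                constrained, fraction_of_optimum=config.gamma
            )
            _save(f"fluxes_{cond}",
                  _flux_frame(state), f"fluxes_{cond}.tsv")
            _save(f"fva_{cond}", ranges[cond].to_frame(), f"fva_{cond}.tsv")
        manifest["growth"] = {
            cond: states[cond][1].objective_value for cond in config.conditions
        }
        manifest["stages_completed"].append("condition_solve")

        comparison = _stage("compare_fva")(compare_flux_spaces)(
            ranges[cond_a], ranges[cond_b]
        )
        _save("flux_space_comparison", comparison.table, "flux_space_comparison.tsv")
        _save("flux_space_by_subsystem",
              aggregate_by_subsystem(comparison, states[cond_a][0]),
              "flux_space_by_subsystem.tsv")
        manifest["flux_space"] = {
            "fraction_decreased": comparison.fraction_decreased,
            "fraction_increased": comparison.fraction_increased,
        }
        manifest["stages_completed"].append("compare_fva")

        report = _stage("compare_exchanges")(compare_conditions)(
            states[cond_a][0], states[cond_a][1],
            states[cond_b][0], states[cond_b][1],
        )
        _save("exchange_comparison", report, "exchange_comparison.tsv")
        for cond in config.conditions:
            table = species_exchange_fluxes(states[cond][0], states[cond][1])
            edges = cross_feeding_edges(table)
            _save(f"exchanges_{cond}", table, f"exchanges_{cond}.tsv")
            frame = _edges_frame(edges)
            _save(f"cross_feeding_{cond}", frame, f"cross_feeding_{cond}.tsv")
            graph_path = outdir / f"cross_feeding_{cond}.graphml"
            import networkx as nx
            nx.write_graphml(edges_to_graph(edges), graph_path)
            artifacts[f"cross_feeding_graph_{cond}"] = graph_path
        manifest["stages_completed"].append("exchange_analysis")
    except PipelineError as exc:
        manifest["failed_stage"] = str(exc)
        _write_manifest()
        raise

    _write_manifest()
    artifacts["manifest"] = outdir / "manifest.json"
    return artifacts


def _member_media(media, model):
    """Restrict a media table to exchanges the member model actually has.

    Community media are keyed by community exchange ids (EX_<met>_e0); a
    member model keeps its own EX_<met> ids, so match on the base id.
    """
    from .model import Media
    member_ex = {r.id for r in model.exchanges}
    limits = {}
    for ex_id, rate in media.uptake_limits.items():
        base = ex_id.removesuffix("_e0")
        if ex_id in member_ex:
            limits[ex_id] = rate
        elif base in member_ex:
            limits[base] = rate
    return Media(f"{media.name}|{model.id}", limits)


def _flux_frame(state):
    import pandas as pd
    return pd.DataFrame(
        sorted(state.fluxes.items()), columns=["reaction_id", "flux"]
    )


def _edges_frame(edges):
    import pandas as pd
    return pd.DataFrame(
        [(e.producer, e.consumer, e.metabolite, e.flux) for e in edges],
        columns=["producer", "consumer", "metabolite", "flux"],
    )
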