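"""Generators for toy species models, community scenarios, and broken fixtures.

The generated models emulate the roles curated gut-microbe reconstructions
play in a community analysis — a glucose fermenter secreting acetate, an
acetate consumer producing butyrate, and so on — at a size (under ~30
reactions) where every optimum has a closed form or is checkable by an
independent LP solver. Stoichiometry is integer and media limits are round
numbers on purpose: verification is analytic, not a regression snapshot.

ATP here is an energy-accounting token, not a mass-balanced species;
generated metabolites carry no chemical formulas, so balance checks return
"indeterminate" rather than false findings. Structure is never random —
seeded randomness only perturbs abundance profiles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .community import AbundanceProfile, write_abundances
from .model import (
    DEFAULT_BOUND,
    Media,
    MetabolicModel,
    Metabolite,
    Reaction,
    write_media,
    write_model,
)

__all__ = [
    "Conversion",
    "SpeciesSpec",
    "CommunityScenario",
    "make_species",
    "toy_model_a",
    "toy_model_b",
    "make_scenario",
    "make_broken_fixtures",
]


@dataclass
class Conversion:
    """One internal reaction: inputs -> outputs (+ ATP), all cytosolic."""

    id: str
    inputs: dict[str, float]   # base metabolite id -> consumed amount (> 0)
    outputs: dict[str, float]  # base metabolite id -> produced amount (> 0)
    atp_yield: float = 0.0


@dataclass
class SpeciesSpec:
    """Blueprint of a toy species: what it eats, converts, secretes."""

    model_id: str
    uptakes: dict[str, float]            # base metabolite -> max uptake rate
    conversions: list[Conversion]
    biomass_atp_cost: float = 1.0
    secretions: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if self.biomass_atp_cost <= 0:
            raise ValueError(f"{self.model_id}: biomass ATP cost must be > 0")
        declared = set(self.uptakes) | set(self.secretions)
        for conv in self.conversions:
            declared |= set(conv.inputs) | set(conv.outputs)
        missing = []
        for conv in self.conversions:
            for met in conv.inputs:
                if met not in set(self.uptakes) and not any(
                    met in c.outputs for c in self.conversions
                ):
                    missing.append(f"{conv.id} input {met} has no source")
        if missing:
            raise ValueError(f"{self.model_id}: inconsistent spec: " + "; ".join(missing))


def make_species(spec: SpeciesSpec) -> MetabolicModel:
    """Build a species model from its blueprint.

    Layout per exchanged base metabolite X: extracellular ``X_e`` with
    exchange ``EX_X`` and transport ``T_X`` (irreversible inward for
    uptakes, outward for secretions, reversible if both); every conversion
    runs on cytosolic ``X_c`` species; biomass consumes
    ``biomass_atp_cost`` units of ``atp_c``.

    For a species with a single linear pathway the FBA optimum is analytic:
    growth = uptake * ATP yield / ATP cost.
    """
    spec.validate()
    model = MetabolicModel(spec.model_id,
                           compartments={"c": "cytosol", "e": "extracellular"})

    cytosolic: set[str] = {"atp"}
    for conv in spec.conversions:
        cytosolic |= set(conv.inputs) | set(conv.outputs)
    cytosolic |= set(spec.uptakes) | set(spec.secretions)
    for base in sorted(cytosolic):
        model.add_metabolite(Metabolite(f"{base}_c", base, "c"))

    for base in sorted(set(spec.uptakes) | set(spec.secretions)):
        model.add_metabolite(Metabolite(f"{base}_e", base, "e"))
        inward = base in spec.uptakes
        outward = base in spec.secretions
        model.add_reaction(Reaction(
            f"EX_{base}", {f"{base}_e": -1.0},
            -spec.uptakes.get(base, 0.0), DEFAULT_BOUND,
            name=f"{base} exchange",
        ))
        if inward and outward:
            stoich, lb = {f"{base}_e": -1.0, f"{base}_c": 1.0}, -DEFAULT_BOUND
        elif inward:
            stoich, lb = {f"{base}_e": -1.0, f"{base}_c": 1.0}, 0.0
        else:
            stoich, lb = {f"{base}_c": -1.0, f"{base}_e": 1.0}, 0.0
        model.add_reaction(Reaction(
            f"T_{base}", stoich, lb, DEFAULT_BOUND, name=f"{base} transport",
        ))

    for conv in spec.conversions:
        stoich: dict[str, float] = {}
        for met, n in conv.inputs.items():
            stoich[f"{met}_c"] = stoich.get(f"{met}_c", 0.0) - n
        for met, n in conv.outputs.items():
            stoich[f"{met}_c"] = stoich.get(f"{met}_c", 0.0) + n
        if conv.atp_yield:
            stoich["atp_c"] = stoich.get("atp_c", 0.0) + conv.atp_yield
        model.add_reaction(Reaction(
            conv.id, stoich, 0.0, DEFAULT_BOUND, subsystem="central metabolism",
        ))

    model.add_reaction(Reaction(
        "BIOMASS", {"atp_c": -spec.biomass_atp_cost}, 0.0, DEFAULT_BOUND,
        name="biomass", subsystem="biomass",
    ))
    model.objective_id = "BIOMASS"
    model.validate()
    return model


def toy_model_a() -> MetabolicModel:
    """Glucose fermenter: takes up glucose, secretes acetate.

    6 reactions, 5 metabolites. Under glucose uptake 10 the optimum is
    forced: FERM yields 2 ATP and 2 acetate per glucose, biomass costs
    2 ATP, so growth = 10 with acetate secretion 20.
    """
    return make_species(SpeciesSpec(
        model_id="ToyA",
        uptakes={"glc": 10.0},
        conversions=[Conversion("FERM", {"glc": 1.0}, {"ac": 2.0}, atp_yield=2.0)],
        biomass_atp_cost=2.0,
        secretions=["ac"],
    ))


def toy_model_b() -> MetabolicModel:
    """Acetate consumer, butyrate producer (5 reactions, 4 metabolites).

    Condenses two extracellular acetate into one cytosolic butyrate plus one
    ATP; biomass costs 1 ATP, so growth = acetate uptake / 2.
    """
    model = MetabolicModel("ToyB", compartments={"c": "cytosol", "e": "extracellular"})
    for met in [Metabolite("ac_e", "acetate", "e"),
                Metabolite("but_c", "butyrate", "c"),
                Metabolite("but_e", "butyrate", "e"),
                Metabolite("atp_c", "atp", "c")]:
        model.add_metabolite(met)
    model.add_reaction(Reaction("EX_ac", {"ac_e": -1.0}, -10.0, DEFAULT_BOUND))
    model.add_reaction(Reaction("EX_but", {"but_e": -1.0}, 0.0, DEFAULT_BOUND))
    model.add_reaction(Reaction(
        "BUTS", {"ac_e": -2.0, "but_c": 1.0, "atp_c": 1.0}, 0.0, DEFAULT_BOUND,
        name="butyrate synthesis from acetate", subsystem="SCFA metabolism",
    ))
    model.add_reaction(Reaction("T_but", {"but_c": -1.0, "but_e": 1.0},
                                0.0, DEFAULT_BOUND))
    model.add_reaction(Reaction("BIOMASS", {"atp_c": -1.0}, 0.0, DEFAULT_BOUND,
                                subsystem="biomass"))
    model.objective_id = "BIOMASS"
    model.validate()
    return model


@dataclass
class CommunityScenario:
    """A fully specified toy community with known ground truth."""

    specs: list[SpeciesSpec]
    models: list[MetabolicModel]
    tags: list[str]
    designed_edges: list[tuple[str, str, str]]  # (producer, consumer, e0 met id)
    media: Media                                 # community-exchange keyed
    profiles: dict[str, AbundanceProfile]
    seed: int

    def materialize(self, outdir: str | Path) -> dict[str, Path]:
        """Write models (JSON), media and abundance TSVs; return the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for model, tag in zip(self.models, self.tags):
            p = outdir / f"{tag}.json"
            write_model(model, p, "json")
            paths[f"model_{tag}"] = p
        paths["media"] = outdir / "media.tsv"
        write_media(self.media, paths["media"])
        paths["abundances"] = outdir / "abundances.tsv"
        write_abundances(self.profiles, paths["abundances"])
        paths["ground_truth"] = outdir / "designed_edges.json"
        paths["ground_truth"].write_text(
            json.dumps([list(e) for e in self.designed_edges], indent=1) + "\n"
        )
        return paths


def make_scenario(
    n_species: int = 2,
    cross_feeding_graph: list[tuple[int, int, str]] | None = None,
    seed: int = 0,
    uptake_rate: float = 10.0,
    abundance_noise: float = 0.1,
    perturbed_species: int | None = None,
    perturbation_factor: float = 0.5,
) -> CommunityScenario:
    """Deterministic toy community with a designed cross-feeding graph.

    ``cross_feeding_graph`` lists transfers as (producer index, consumer
    index, metabolite base id); the default is a chain s0 -> s1 -> ... where
    each species ferments what the previous one secretes. Source species
    (no incoming transfer) take up their own primary substrate, which the
    media supplies at ``uptake_rate``.

    Two abundance profiles are generated: "healthy" is uniform with a
    seeded +/- ``abundance_noise`` relative jitter, and "disease" rescales
    one species (the last by default — the terminal fermenter, emulating the
    depleted downstream producer seen in dysbiosis) by
    ``perturbation_factor``. Everything is a pure function of the arguments;
    the same seed reproduces byte-identical files.
    """
    if n_species < 2:
        raise ValueError("a community scenario needs n_species >= 2")
    if cross_feeding_graph is None:
        cross_feeding_graph = [
            (i, i + 1, f"m{i}") for i in range(n_species - 1)
        ]
    graph = nx.MultiDiGraph()
    graph.add_nodes_from(range(n_species))
    for producer, consumer, met in cross_feeding_graph:
        graph.add_edge(producer, consumer, metabolite=met)
    if not nx.is_directed_acyclic_graph(graph):
        raise ValueError("cross-feeding graph must be acyclic over metabolite transfers")

    tags = [f"s{i}" for i in range(n_species)]
    specs: list[SpeciesSpec] = []
    media_limits: dict[str, float] = {}
    for i in range(n_species):
        incoming = [d["metabolite"] for _, _, d in graph.in_edges(i, data=True)]
        outgoing = [d["metabolite"] for _, _, d in graph.out_edges(i, data=True)]
        uptakes: dict[str, float] = {}
        if incoming:
            for met in incoming:
                uptakes[met] = DEFAULT_BOUND  # fed by partners, not the media
        else:
            primary = f"sub{i}"
            uptakes[primary] = uptake_rate
            media_limits[f"EX_{primary}_e0"] = uptake_rate
        products = outgoing or [f"waste{i}"]
        inputs = {met: 1.0 for met in uptakes}
        # byproduct yield 2 per substrate: the community-biomass coupling fixes
        # member growth in exact abundance ratio, so a consumer can demand up
        # to twice its supplier's growth-coupled output before the transfer
        # becomes limiting; the surplus leaves through the community exchange
        outputs = {met: 2.0 for met in products}
        specs.append(SpeciesSpec(
            model_id=f"Species{i}",
            uptakes=uptakes,
            conversions=[Conversion(f"CONV{i}", inputs, outputs, atp_yield=1.0)],
            biomass_atp_cost=1.0,
            secretions=products,
        ))
    models = [make_species(s) for s in specs]
    designed_edges = sorted(
        (tags[p], tags[c], f"{d['metabolite']}_e0")
        for p, c, d in graph.edges(data=True)
    )

    rng = np.random.default_rng(seed)
    base = 1.0 / n_species
    healthy = {
        tag: round(base * (1.0 + abundance_noise * rng.uniform(-1.0, 1.0)), 6)
        for tag in tags
    }
    disease = dict(healthy)
    target = tags[perturbed_species if perturbed_species is not None else n_species - 1]
    disease[target] = round(disease[target] * perturbation_factor, 6)
    profiles = {
        "healthy": AbundanceProfile("healthy", healthy),
        "disease": AbundanceProfile("disease", disease),
    }
    return CommunityScenario(
        specs=specs, models=models, tags=tags, designed_edges=designed_edges,
        media=Media("scenario", media_limits), profiles=profiles, seed=seed,
    )


def make_broken_fixtures() -> dict[str, MetabolicModel]:
    """Small models each triggering exactly one curation finding.

    * ``tic``: a clean fermenter plus a two-reaction loop that carries
      arbitrary flux with all uptakes closed (both flagged unbound).
    * ``imbalanced``: a fermentation dropping one carbon-2 unit
      (element imbalance C: -2, H: -4, O: -2).
    * ``dead_end``: a declared metabolite never referenced (orphan).
    * ``blocked``: a ribose branch whose nutrient the media never supplies.
    * ``degenerate``: two parallel identical transports; the FBA optimum is
      unique but the flux split is not — pFBA total flux is.
    """
    fixtures: dict[str, MetabolicModel] = {}

    tic = toy_model_a()
    tic.id = "BrokenTIC"
    tic.add_metabolite(Metabolite("x1_c", "loop species 1", "c"))
    tic.add_metabolite(Metabolite("x2_c", "loop species 2", "c"))
    tic.add_reaction(Reaction("LOOPF", {"x1_c": -1.0, "x2_c": 1.0}, 0.0, DEFAULT_BOUND))
    tic.add_reaction(Reaction("LOOPR", {"x2_c": -1.0, "x1_c": 1.0}, 0.0, DEFAULT_BOUND))
    fixtures["tic"] = tic

    imb = MetabolicModel("BrokenImbalance",
                         compartments={"c": "cytosol", "e": "extracellular"})
    glc = {"C": 6, "H": 12, "O": 6}
    ac = {"C": 2, "H": 4, "O": 2}
    for met in [Metabolite("glc_e", "glucose", "e", dict(glc), 0),
                Metabolite("glc_c", "glucose", "c", dict(glc), 0),
                Metabolite("ac_c", "acetate", "c", dict(ac), 0),
                Metabolite("ac_e", "acetate", "e", dict(ac), 0)]:
        imb.add_metabolite(met)
    imb.add_reaction(Reaction("EX_glc", {"glc_e": -1.0}, -10.0, DEFAULT_BOUND))
    imb.add_reaction(Reaction("T_glc", {"glc_e": -1.0, "glc_c": 1.0}, 0.0, DEFAULT_BOUND))
    # drops a C2H4O2 unit: products sum to C4H8O4 against C6H12O6
    imb.add_reaction(Reaction("BADFERM", {"glc_c": -1.0, "ac_c": 2.0}, 0.0, DEFAULT_BOUND))
    imb.add_reaction(Reaction("T_ac", {"ac_c": -1.0, "ac_e": 1.0}, 0.0, DEFAULT_BOUND))
    imb.add_reaction(Reaction("EX_ac", {"ac_e": -1.0}, 0.0, DEFAULT_BOUND))
    imb.add_reaction(Reaction("BIOMASS", {"ac_c": -1.0}, 0.0, DEFAULT_BOUND))
    imb.objective_id = "BIOMASS"
    fixtures["imbalanced"] = imb

    dead = toy_model_a()
    dead.id = "BrokenDeadEnd"
    dead.add_metabolite(Metabolite("unused_c", "never referenced", "c"))
    fixtures["dead_end"] = dead

    blocked = toy_model_a()
    blocked.id = "BrokenBlocked"
    blocked.add_metabolite(Metabolite("rib_e", "ribose", "e"))
    blocked.add_metabolite(Metabolite("rib_c", "ribose", "c"))
    blocked.add_reaction(Reaction("EX_rib", {"rib_e": -1.0}, 0.0, DEFAULT_BOUND))
    blocked.add_reaction(Reaction("T_rib", {"rib_e": -1.0, "rib_c": 1.0},
                                  0.0, DEFAULT_BOUND))
    blocked.add_reaction(Reaction("RIBUSE", {"rib_c": -1.0, "atp_c": 1.0},
                                  0.0, DEFAULT_BOUND))
    fixtures["blocked"] = blocked

    degen = MetabolicModel("BrokenDegenerate",
                           compartments={"c": "cytosol", "e": "extracellular"})
    for met in [Metabolite("s_e", "substrate", "e"),
                Metabolite("s_c", "substrate", "c"),
                Metabolite("atp_c", "atp", "c")]:
        degen.add_metabolite(met)
    degen.add_reaction(Reaction("EX_s", {"s_e": -1.0}, -10.0, DEFAULT_BOUND))
    degen.add_reaction(Reaction("T1", {"s_e": -1.0, "s_c": 1.0}, 0.0, DEFAULT_BOUND))
    degen.add_reaction(Reaction("T2", {"s_e": -1.0, "s_c": 1.0}, 0.0, DEFAULT_BOUND))
    degen.add_reaction(Reaction("USE", {"s_c": -1.0, "atp_c": 1.0}, 0.0, DEFAULT_BOUND))
    degen.add_reaction(Reaction("BIOMASS", {"atp_c": -1.0}, 0.0, DEFAULT_BOUND))
    degen.objective_id = "BIOMASS"
    fixtures["degenerate"] = degen

    return fixtures
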