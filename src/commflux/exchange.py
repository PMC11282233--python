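"""Per-species exchange accounting and cross-feeding network inference.

In a merged community every species touches the shared extracellular pool
only through its own transport reactions, so a species' net production or
consumption of each pooled metabolite is read directly off an optimal flux
distribution. A metabolite with at least one net producer and one net
consumer carries a cross-feeding edge: the producer's secretion is the
consumer's substrate. Comparing the same accounting between two conditions
(two abundance weightings) yields the percent-change report on uptake,
secretion and inter-species transfer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .community import SHARED_COMPARTMENT, CommunityModel
from .fba import FluxState

__all__ = [
    "CrossFeedingEdge",
    "species_exchange_fluxes",
    "cross_feeding_edges",
    "edges_to_graph",
    "percent_change",
    "compare_conditions",
]

DEFAULT_TOL = 1e-6


@dataclass(frozen=True)
class CrossFeedingEdge:
    """Directed transfer of one pooled metabolite between two members."""

    producer: str
    consumer: str
    metabolite: str
    flux: float  # lower bound on the transferred amount, mmol/gDW/h


def species_exchange_fluxes(
    community: CommunityModel, state: FluxState, tol: float = DEFAULT_TOL
) -> pd.DataFrame:
    """Net flux of every member into/out of each shared-pool metabolite.

    Columns: species, metabolite, flux, role. Positive flux = net secretion
    into the pool, negative = net consumption; |flux| <= tol is "inactive".
    Metabolites untouched by every member are omitted. Member biomass
    species are pseudo-metabolites and excluded.

    By mass balance, the per-metabolite sum over species equals the flux of
    that metabolite's community exchange reaction.
    """
    missing = set(community.reactions) - set(state.fluxes)
    if missing or not state.optimal:
        raise ValueError(
            "flux state does not match the community model"
            + (f" (missing {sorted(missing)[:3]}...)" if missing else "")
        )
    biomass_mets = set(community.biomass_metabolites.values())
    pool_mets = [
        m for m in community.metabolite_ids()
        if community.metabolites[m].compartment == SHARED_COMPARTMENT
        and m not in biomass_mets
    ]
    rows = []
    for tag in community.member_tags:
        net: dict[str, float] = {m: 0.0 for m in pool_mets}
        for rxn in community.member_reactions(tag):
            v = state.fluxes[rxn.id]
            for met_id, coeff in rxn.stoichiometry.items():
                if met_id in net:
                    net[met_id] += coeff * v
        for met_id in pool_mets:
            flux = net[met_id]
            role = ("producer" if flux > tol
                    else "consumer" if flux < -tol else "inactive")
            rows.append((tag, met_id, flux, role))
    table = pd.DataFrame(rows, columns=["species", "metabolite", "flux", "role"])
    active = set(table.loc[table["role"] != "inactive", "metabolite"])
    return table[table["metabolite"].isin(active)].reset_index(drop=True)


def cross_feeding_edges(
    table: pd.DataFrame, tol: float = DEFAULT_TOL
) -> list[CrossFeedingEdge]:
    """Producer -> consumer edges through the shared pool.

    For each metabolite with at least one producer and one consumer, the
    transferable amount is min(total produced, total consumed) — the rest
    leaves or enters through the community exchange — apportioned among
    producer/consumer pairs proportionally to their shares.
    """
    edges: list[CrossFeedingEdge] = []
    for met_id, group in table.groupby("metabolite", sort=True):
        producers = group[group["flux"] > tol]
        consumers = group[group["flux"] < -tol]
        if producers.empty or consumers.empty:
            continue
        total_p = float(producers["flux"].sum())
        total_c = float(-consumers["flux"].sum())
        transferred = min(total_p, total_c)
        for _, p in producers.iterrows():
            for _, c in consumers.iterrows():
                flux = transferred * (p["flux"] / total_p) * (-c["flux"] / total_c)
                if flux > tol:
                    edges.append(CrossFeedingEdge(
                        str(p["species"]), str(c["species"]), str(met_id), flux,
                    ))
    return sorted(edges, key=lambda e: (e.metabolite, e.producer, e.consumer))


def edges_to_graph(edges: list[CrossFeedingEdge]) -> nx.MultiDiGraph:
    """Cross-feeding network as a directed multigraph (GraphML-exportable)."""
    graph = nx.MultiDiGraph()
    for edge in edges:
        graph.add_edge(edge.producer, edge.consumer,
                       key=edge.metabolite, metabolite=edge.metabolite,
                       flux=edge.flux)
    return graph


def percent_change(
    flux_a: float, flux_b: float, magnitudes: bool = False
) -> float | None:
    """100 * (B - A) / |A|, or None when A = 0 (undefined, not an error).

    With ``magnitudes`` the comparison is on |A| and |B| — the natural scale
    for uptake rates, where a drop from -9.3 to -5.6 is a reduction.
    """
    if magnitudes:
        flux_a, flux_b = abs(flux_a), abs(flux_b)
    if flux_a == 0.0:
        return None
    return 100.0 * (flux_b - flux_a) / abs(flux_a)


def _classify(pct: float | None, tol: float) -> str:
    if pct is None or math.isnan(pct):
        return "undefined"
    if pct < -tol:
        return "decreased"
    if pct > tol:
        return "increased"
    return "unchanged"


def compare_conditions(
    community_a: CommunityModel,
    state_a: FluxState,
    community_b: CommunityModel,
    state_b: FluxState,
    tol: float = DEFAULT_TOL,
    pct_tol: float = 1e-4,
) -> pd.DataFrame:
    """Condition A vs condition B exchange report.

    One row per (species, metabolite) pair and per community exchange, with
    fluxes under both conditions, the percent change relative to A, and a
    class in {decreased, increased, unchanged, undefined}. Metabolites
    exchanged in only one condition appear with flux 0 in the other and are
    classed "undefined" when A's flux is 0.
    """
    if community_a.member_tags != community_b.member_tags:
        raise ValueError(
            f"member tags differ: {community_a.member_tags} vs {community_b.member_tags}"
        )
    table_a = species_exchange_fluxes(community_a, state_a, tol)
    table_b = species_exchange_fluxes(community_b, state_b, tol)
    merged = table_a.merge(
        table_b, on=["species", "metabolite"], how="outer",
        suffixes=("_a", "_b"),
    ).fillna({"flux_a": 0.0, "flux_b": 0.0})

    rows = []
    for _, row in merged.iterrows():
        pct = percent_change(row["flux_a"], row["flux_b"])
        rows.append(("species", row["species"], row["metabolite"],
                     row["flux_a"], row["flux_b"],
                     float("nan") if pct is None else pct,
                     _classify(pct, pct_tol)))

    ex_ids = sorted(
        {r.id for r in community_a.exchanges} | {r.id for r in community_b.exchanges}
    )
    for rid in ex_ids:
        fa = state_a.fluxes.get(rid, 0.0)
        fb = state_b.fluxes.get(rid, 0.0)
        pct = percent_change(fa, fb)
        rows.append(("community", "", rid.removeprefix("EX_"), fa, fb,
                     float("nan") if pct is None else pct,
                     _classify(pct, pct_tol)))

    return pd.DataFrame(
        rows,
        columns=["scope", "species", "metabolite", "flux_a", "flux_b",
                 "pct_change", "class"],
    )
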