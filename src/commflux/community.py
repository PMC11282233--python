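"""Compartmentalized merging of species models into a community model.

Every member model keeps its own namespace (all internal metabolite,
reaction and compartment ids get a ``_tag`` suffix) while extracellular
metabolites are pooled into one shared compartment ``e0``. Member exchange
reactions are dropped and replaced by a single community exchange per shared
metabolite, so species interact only through the common pool — one species'
secretion is another's substrate.

Growth is coupled through an abundance-weighted community biomass: each
member's biomass reaction is rewritten to produce a member biomass species
``biomass_<tag>``, and the community objective

    community biomass:  sum_k a_k * biomass_k  ->  (drain)

consumes them in proportion to the relative abundances a_k of the member
species in the condition of interest (e.g. healthy vs disease metagenomic
profiles). Maximizing its flux under a shared media yields the community
growth rate and a condition-specific flux distribution. The members compete
freely for the shared pool; there is no per-member uptake scaling and no
growth-rate coupling constraint beyond the weighted objective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

from .model import (
    DEFAULT_BOUND,
    EXTRACELLULAR_IDS,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
)

__all__ = [
    "AbundanceProfile",
    "CommunityModel",
    "tag_namespace",
    "merge_models",
    "add_community_biomass",
    "apply_condition",
    "read_abundances",
    "write_abundances",
]

SHARED_COMPARTMENT = "e0"
COMMUNITY_BIOMASS_ID = "CBIOMASS"


@dataclass
class AbundanceProfile:
    """Relative abundances of the member species under one condition."""

    condition: str
    abundances: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for tag, a in self.abundances.items():
            if not (math.isfinite(a) and a >= 0):
                raise ModelValidationError(
                    f"abundance for {tag!r} must be finite and >= 0, got {a}"
                )
        if not any(a > 0 for a in self.abundances.values()):
            raise ModelValidationError(
                f"profile {self.condition!r}: all abundances are zero"
            )

    def normalized(self) -> "AbundanceProfile":
        total = sum(self.abundances.values())
        return AbundanceProfile(
            self.condition, {t: a / total for t, a in self.abundances.items()}
        )


class CommunityModel(MetabolicModel):
    """A merged multi-species model with a shared extracellular pool."""

    def __init__(self, id: str, **kwargs):
        super().__init__(id, **kwargs)
        self.member_tags: list[str] = []
        self.member_model_ids: dict[str, str] = {}
        self.biomass_metabolites: dict[str, str] = {}
        self.community_biomass_id: str | None = None
        self.condition: str | None = None

    def copy(self) -> "CommunityModel":
        out = CommunityModel(self.id, compartments=dict(self.compartments),
                             objective_id=self.objective_id)
        out.metabolites = {k: v.copy() for k, v in self.metabolites.items()}
        out.reactions = {k: v.copy() for k, v in self.reactions.items()}
        out.member_tags = list(self.member_tags)
        out.member_model_ids = dict(self.member_model_ids)
        out.biomass_metabolites = dict(self.biomass_metabolites)
        out.community_biomass_id = self.community_biomass_id
        out.condition = self.condition
        return out

    def member_reactions(self, tag: str) -> list[Reaction]:
        suffix = f"_{tag}"
        return [r for r in self.reactions.values() if r.id.endswith(suffix)]


def _shared_id(met: Metabolite) -> str:
    """Rename an extracellular metabolite into the shared e0 namespace."""
    base = met.id
    suffix = f"_{met.compartment}"
    if base.endswith(suffix):
        base = base[: -len(suffix)]
    return f"{base}_{SHARED_COMPARTMENT}"


def tag_namespace(model: MetabolicModel, tag: str) -> MetabolicModel:
    """Suffix every internal id with ``_tag``; pool extracellular species in e0.

    Member exchange reactions are removed (community exchanges are created at
    merge time); transport reactions that touched the member's extracellular
    species are rewired to the shared e0 species.
    """
    if not tag or any(sep in tag for sep in "_:/ \t"):
        raise ValueError(f"tag must be non-empty without separators, got {tag!r}")

    out = MetabolicModel(f"{model.id}_{tag}")
    rename: dict[str, str] = {}
    for met_id in model.metabolite_ids():
        met = model.metabolites[met_id]
        if met.compartment in EXTRACELLULAR_IDS:
            new_id, new_comp = _shared_id(met), SHARED_COMPARTMENT
        else:
            new_id, new_comp = f"{met.id}_{tag}", f"{met.compartment}_{tag}"
        if new_id in rename.values():
            raise ModelValidationError(
                f"id collision after tagging: {new_id!r} (from {met.id!r})"
            )
        rename[met.id] = new_id
        out.add_metabolite(Metabolite(new_id, met.name, new_comp,
                                      dict(met.formula), met.charge))
    out.compartments[SHARED_COMPARTMENT] = "shared extracellular"

    for rxn_id in model.reaction_ids():
        rxn = model.reactions[rxn_id]
        if rxn.is_exchange:
            continue
        new = rxn.copy()
        new.id = f"{rxn.id}_{tag}"
        new.stoichiometry = {rename[m]: c for m, c in rxn.stoichiometry.items()}
        if new.id in out.reactions:
            raise ModelValidationError(f"id collision after tagging: {new.id!r}")
        out.add_reaction(new)

    if model.objective_id is not None and not model.reactions[model.objective_id].is_exchange:
        out.objective_id = f"{model.objective_id}_{tag}"
    return out


def merge_models(
    models: list[MetabolicModel], tags: list[str]
) -> CommunityModel:
    """Union of tagged member models plus community exchanges.

    Each member's biomass reaction is rewritten to produce one unit of a
    member biomass species ``biomass_<tag>`` in e0. Every other e0 metabolite
    gets exactly one community exchange reaction with fully open bounds
    (media constraints come later via :func:`~commflux.model.apply_media`).
    Biomass species get no exchange: the community biomass reaction added by
    :func:`add_community_biomass` is their only drain. No community objective
    is set yet.
    """
    if len(models) != len(tags):
        raise ValueError("need exactly one tag per model")
    if len(models) < 2:
        raise ValueError("a community needs at least 2 member models")
    if len(set(tags)) != len(tags):
        raise ValueError(f"tags must be distinct, got {tags}")

    community = CommunityModel("community_" + "_".join(tags))
    community.member_tags = list(tags)
    for model, tag in zip(models, tags):
        if model.objective_id is None:
            raise ModelValidationError(f"member {model.id} has no biomass objective")
        tagged = tag_namespace(model, tag)
        community.member_model_ids[tag] = model.id
        for met_id in tagged.metabolite_ids():
            if met_id not in community.metabolites:
                community.add_metabolite(tagged.metabolites[met_id].copy())
        community.compartments.update(tagged.compartments)
        for rxn_id in tagged.reaction_ids():
            if rxn_id in community.reactions:
                raise ModelValidationError(
                    f"reaction id collision while merging: {rxn_id!r}"
                )
            community.add_reaction(tagged.reactions[rxn_id].copy())

        # materialize member growth as a biomass species drained by CBIOMASS
        biomass_met = f"biomass_{tag}"
        community.add_metabolite(
            Metabolite(biomass_met, f"biomass of member {tag}", SHARED_COMPARTMENT)
        )
        community.biomass_metabolites[tag] = biomass_met
        community.reactions[tagged.objective_id].stoichiometry[biomass_met] = 1.0

    for met_id in community.metabolite_ids():
        met = community.metabolites[met_id]
        if met.compartment != SHARED_COMPARTMENT or met_id in community.biomass_metabolites.values():
            continue
        community.add_reaction(Reaction(
            f"EX_{met_id}", {met_id: -1.0}, -DEFAULT_BOUND, DEFAULT_BOUND,
            name=f"community exchange of {met_id}",
        ))
    community.refresh_exchange_flags()
    return community


def add_community_biomass(
    community: CommunityModel,
    profile: AbundanceProfile,
    normalize: bool = False,
) -> CommunityModel:
    """Add (or replace) the abundance-weighted community biomass objective.

    The reaction consumes a_k units of each member biomass species per unit
    of community growth; members absent from the profile contribute with
    a_k = 0 (their biomass species keeps no drain). With ``normalize`` the
    abundances are first rescaled to sum to 1.
    """
    profile.validate()
    unknown = sorted(set(profile.abundances) - set(community.member_tags))
    if unknown:
        raise ModelValidationError(
            "profile names unknown member tags: " + ", ".join(unknown)
        )
    if normalize:
        profile = profile.normalized()

    out = community.copy()
    if out.community_biomass_id and out.community_biomass_id in out.reactions:
        out.remove_reaction(out.community_biomass_id)
    stoich = {
        out.biomass_metabolites[tag]: -profile.abundances[tag]
        for tag in out.member_tags
        if profile.abundances.get(tag, 0.0) > 0.0
    }
    out.add_reaction(Reaction(
        COMMUNITY_BIOMASS_ID, stoich, 0.0, DEFAULT_BOUND,
        name=f"community biomass ({profile.condition})",
    ))
    out.community_biomass_id = COMMUNITY_BIOMASS_ID
    out.objective_id = COMMUNITY_BIOMASS_ID
    out.condition = profile.condition
    return out


def apply_condition(
    community: CommunityModel, profile: AbundanceProfile, normalize: bool = False
) -> CommunityModel:
    """Re-weight an existing community biomass for a new condition.

    Only the community biomass coefficients change; everything else —
    members, exchanges, bounds — is untouched, so two conditions differ in
    exactly one reaction.
    """
    if community.community_biomass_id is None:
        raise ModelValidationError(
            "community has no community biomass yet; call add_community_biomass"
        )
    return add_community_biomass(community, profile, normalize=normalize)


# ---------------------------------------------------------------------------
# Abundance table I/O: TSV with columns species_tag, condition, abundance.

def read_abundances(path: str | Path) -> dict[str, AbundanceProfile]:
    path = Path(path)
    profiles: dict[str, dict[str, float]] = {}
    lines = [ln for ln in path.read_text().splitlines()
             if ln.strip() and not ln.lstrip().startswith("#")]
    start = 1 if lines and lines[0].lower().startswith("species_tag") else 0
    for lineno, line in enumerate(lines[start:], start=start + 1):
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 3:
            raise ModelValidationError(
                f"{path}:{lineno}: expected 3 columns (species_tag, condition, abundance)"
            )
        tag, condition, value = parts
        profiles.setdefault(condition, {})[tag] = float(value)
    return {
        cond: AbundanceProfile(cond, abund) for cond, abund in profiles.items()
    }


def write_abundances(profiles: dict[str, AbundanceProfile], path: str | Path) -> None:
    rows = ["species_tag\tcondition\tabundance"]
    for cond in sorted(profiles):
        for tag in sorted(profiles[cond].abundances):
            rows.append(f"{tag}\t{cond}\t{profiles[cond].abundances[tag]:g}")
    Path(path).write_text("\n".join(rows) + "\n")
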