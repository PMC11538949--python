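"""Declarative definition of the reduced hepatic reaction network.

A model file (YAML or JSON) lists metabolites, reactions and regulator links.
Metabolites carry a role:

``plasma``
    Clamped boundary species (plasma nutrient concentrations set by the
    simulation protocol).
``internal``
    Balanced species whose concentrations are solved to steady state.
``store``
    Intracellular depots (glycogen, TAG) clamped at a configured fill level;
    their net synthesis flux is reported rather than integrated.

The shipped default model ``hepatocore`` is a reduced, lumped network of
central hepatic metabolism: glucose transport and phosphorylation, glycolysis
and gluconeogenesis lumps, glycogen turnover, fructose/galactose/glycerol
entry, fatty acid uptake, β-oxidation with malonyl-CoA inhibition, de novo
lipogenesis, TAG synthesis/lipolysis against a clamped droplet pool, VLDL
export, ketogenesis, a TCA + oxidative-phosphorylation lump, the urea cycle
with N-acetylglutamate-type activation, glutamine/glutamate exchange, and a
two-step ethanol oxidation lump.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .ratelaws import PHOSPHO_KINDS, RATE_LAW_KINDS

__all__ = [
    "Metabolite",
    "Modulator",
    "Reaction",
    "ModelDefinition",
    "ModelValidationError",
    "load_model_definition",
    "default_model",
]


class ModelValidationError(ValueError):
    """Raised when a model definition violates structural invariants."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    role: str  # plasma | internal | store
    unit: str = "mM"
    default: float = 0.1  # initial guess (internal) or clamp level (plasma default)
    level: float | None = None  # clamped fill level for stores


@dataclass(frozen=True)
class Modulator:
    metabolite: str
    kind: str  # activation | inhibition
    k: float
    n: float = 1.0


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: Mapping[str, float]
    rate_law: str
    vmax_ref: float
    params: Mapping[str, float] = field(default_factory=dict)
    phospho: str = "none"
    modulators: tuple[Modulator, ...] = ()
    substrate: str | None = None  # reversible_mm / ghk_transport only
    product: str | None = None

    def substrate_kms(self) -> list[tuple[str, float]]:
        """(metabolite, Km) pairs for the irreversible-MM core.

        A single-substrate reaction may give a bare ``km``; multi-substrate
        reactions give ``km_<metabolite>`` entries.
        """
        subs = sorted(m for m, c in self.stoichiometry.items() if c < 0)
        if len(subs) == 1 and "km" in self.params:
            return [(subs[0], self.params["km"])]
        return [(m, self.params[f"km_{m}"]) for m in subs]

    def rate_species(self) -> list[str]:
        """All metabolites the rate law itself evaluates."""
        if self.rate_law in ("reversible_mm", "ghk_transport"):
            out = [self.substrate, self.product]
        else:
            out = [m for m, _ in self.substrate_kms()]
        out.extend(m.metabolite for m in self.modulators)
        return out


@dataclass
class ModelDefinition:
    """Validated reaction network: metabolites, reactions, regulator links."""

    name: str
    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]

    # -- introspection -------------------------------------------------
    @property
    def internal_ids(self) -> list[str]:
        return [m.id for m in self.metabolites.values() if m.role == "internal"]

    @property
    def plasma_ids(self) -> list[str]:
        return [m.id for m in self.metabolites.values() if m.role == "plasma"]

    @property
    def store_ids(self) -> list[str]:
        return [m.id for m in self.metabolites.values() if m.role == "store"]

    def reference_vmax(self) -> dict[str, float]:
        return {r.id: r.vmax_ref for r in self.reactions.values()}

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        if not self.reactions:
            raise ModelValidationError("model has no reactions")
        for met in self.metabolites.values():
            if met.role not in ("plasma", "internal", "store"):
                raise ModelValidationError(f"metabolite {met.id}: unknown role {met.role!r}")
            if met.role == "store" and (met.level is None or met.level <= 0):
                raise ModelValidationError(f"store {met.id} needs a positive clamp level")

        produced: dict[str, int] = {m: 0 for m in self.internal_ids}
        consumed: dict[str, int] = {m: 0 for m in self.internal_ids}
        for rxn in self.reactions.values():
            if rxn.rate_law not in RATE_LAW_KINDS:
                raise ModelValidationError(f"reaction {rxn.id}: unknown rate law {rxn.rate_law!r}")
            if rxn.phospho not in PHOSPHO_KINDS:
                raise ModelValidationError(f"reaction {rxn.id}: unknown phospho kind {rxn.phospho!r}")
            if not rxn.vmax_ref > 0:
                raise ModelValidationError(f"reaction {rxn.id}: vmax_ref must be positive")
            for key, val in rxn.params.items():
                if key.startswith(("km", "keq", "k_")) and not val > 0:
                    raise ModelValidationError(f"reaction {rxn.id}: parameter {key} must be positive")
            for met in rxn.stoichiometry:
                if met not in self.metabolites:
                    raise ModelValidationError(f"reaction {rxn.id}: dangling metabolite {met!r}")
            if rxn.rate_law in ("reversible_mm", "ghk_transport"):
                if rxn.substrate not in self.metabolites or rxn.product not in self.metabolites:
                    raise ModelValidationError(
                        f"reaction {rxn.id}: {rxn.rate_law} needs valid substrate/product"
                    )
            else:
                try:
                    kms = rxn.substrate_kms()
                except KeyError as exc:
                    raise ModelValidationError(f"reaction {rxn.id}: missing Km parameter {exc}") from exc
                for _, km in kms:
                    if not km > 0:
                        raise ModelValidationError(f"reaction {rxn.id}: Km must be positive")
            for mod in rxn.modulators:
                if mod.metabolite not in self.metabolites:
                    raise ModelValidationError(f"reaction {rxn.id}: dangling modulator {mod.metabolite!r}")
                if mod.kind not in ("activation", "inhibition"):
                    raise ModelValidationError(f"reaction {rxn.id}: modulator kind {mod.kind!r}")
                if not (mod.k > 0 and mod.n > 0):
                    raise ModelValidationError(f"reaction {rxn.id}: modulator K and n must be positive")
            for met, coef in rxn.stoichiometry.items():
                if met in produced:
                    reversible = rxn.rate_law in ("reversible_mm", "ghk_transport")
                    if coef > 0 or reversible:
                        produced[met] += 1
                    if coef < 0 or reversible:
                        consumed[met] += 1

        for met in self.internal_ids:
            if produced[met] == 0:
                raise ModelValidationError(f"internal metabolite {met} has no producer")
            if consumed[met] == 0:
                raise ModelValidationError(f"internal metabolite {met} has no consumer")

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "metabolites": [
                {
                    "id": m.id,
                    "role": m.role,
                    "unit": m.unit,
                    "default": m.default,
                    **({"level": m.level} if m.level is not None else {}),
                }
                for m in self.metabolites.values()
            ],
            "reactions": [
                {
                    "id": r.id,
                    "stoichiometry": dict(r.stoichiometry),
                    "rate_law": r.rate_law,
                    "vmax_ref": r.vmax_ref,
                    "params": dict(r.params),
                    "phospho": r.phospho,
                    **({"substrate": r.substrate} if r.substrate else {}),
                    **({"product": r.product} if r.product else {}),
                    **(
                        {
                            "modulators": [
                                {"metabolite": m.metabolite, "kind": m.kind, "k": m.k, "n": m.n}
                                for m in r.modulators
                            ]
                        }
                        if r.modulators
                        else {}
                    ),
                }
                for r in self.reactions.values()
            ],
        }

    def save(self, path: str | Path) -> None:
        path = Path(path)
        payload = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(payload, indent=2))
        else:
            path.write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ModelDefinition":
        mets = {
            d["id"]: Metabolite(
                id=d["id"],
                role=d["role"],
                unit=d.get("unit", "mM"),
                default=float(d.get("default", 0.1)),
                level=float(d["level"]) if "level" in d else None,
            )
            for d in payload["metabolites"]
        }
        rxns = {}
        for d in payload["reactions"]:
            mods = tuple(
                Modulator(metabolite=m["metabolite"], kind=m["kind"], k=float(m["k"]), n=float(m.get("n", 1.0)))
                for m in d.get("modulators", [])
            )
            rxns[d["id"]] = Reaction(
                id=d["id"],
                stoichiometry={k: float(v) for k, v in d["stoichiometry"].items()},
                rate_law=d["rate_law"],
                vmax_ref=float(d["vmax_ref"]),
                params={k: float(v) for k, v in d.get("params", {}).items()},
                phospho=d.get("phospho", "none"),
                modulators=mods,
                substrate=d.get("substrate"),
                product=d.get("product"),
            )
        model = cls(name=payload.get("name", "model"), metabolites=mets, reactions=rxns)
        model.validate()
        return model


def load_model_definition(path: str | Path) -> ModelDefinition:
    """Load and validate a model definition from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return ModelDefinition.from_dict(payload)


def default_model() -> ModelDefinition:
    """The shipped control-calibrated reduced model (``hepatocore``)."""
    ref = resources.files("hepaflux.data").joinpath("hepatocore.yaml")
    payload = yaml.safe_load(ref.read_text())
    return ModelDefinition.from_dict(payload)
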