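"""Deterministic toy community fixtures.

Three hand-built networks (5-20 reactions each) with engineered, analytically
checkable behaviour, standing in for genome-scale models so that every stage
of the pipeline is testable offline:

``toy_a`` (overflow producer)
    Grows on glucose with an obligate acetate overflow wired into its biomass
    stoichiometry (20 mmol acetate dumped per gDW of biomass).  A shared
    membrane-capacity constraint (15 mmol/gDW/h across its importers) caps
    growth and, together with a deliberately flux-expensive acetate-salvage
    pathway, makes secretion the parsimonious choice while glucose lasts.
    Once glucose is gone it re-assimilates extracellular acetate (net 20 mmol
    acetate per gDW).  Can synthesise product P1 from internal glucose.

``toy_b`` (acetate specialist)
    Cannot consume glucose at all; grows only on acetate (20 mmol/gDW) and
    can synthesise product P2.  On a glucose-only medium its monoculture
    growth is exactly zero, so any growth in co-culture with ``toy_a`` is
    attributable to acetate cross-feeding.

``toy_c`` (glucose competitor and acetate waster)
    Competes for glucose with the same yield and capacity as ``toy_a`` but
    secretes nothing.  It also imports acetate at full membrane capacity yet
    assimilates it at a uselessly poor yield (100 mmol acetate per mmol of
    internal hexose), so in co-culture with ``toy_a`` it both halves the
    glucose and squanders the acetate that ``toy_a`` would otherwise salvage
    — depressing ``toy_a`` well below half of its monoculture biomass while
    itself landing near half of its own (an antagonistic interaction).

The toy stoichiometries are caricatures: reactions are not elementally
balanced and "biomass" consumes hexose units directly.  Formulas are attached
to the pool metabolites only so that molar-mass-based unit conversions
(g/L vs mmol/L) can be exercised.

Everything here is generated from literal constants, so output files are
byte-identical across runs for any seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

from .environments import Medium, write_medium
from .model_io import MetabolicModel, Metabolite, Reaction, write_model

__all__ = [
    "GLYCEROL_MOLAR_MASS",
    "P1_EXCHANGE",
    "P2_EXCHANGE",
    "ToyCommunity",
    "generate_toy_community",
    "toy_a",
    "toy_b",
    "toy_c",
    "toy_glycerol_consumer",
]

#: Product exchange reaction ids tracked in toy screens.
P1_EXCHANGE = "EX_p1_e"
P2_EXCHANGE = "EX_p2_e"

#: Glycerol molar mass (g/mol), used by fed-batch feed specifications.
GLYCEROL_MOLAR_MASS = 92.09

# Engineered stoichiometric constants (mmol per gDW unless noted).
GLC_PER_BIOMASS = 40.0      # hexose demand of one biomass unit
AC_OVERFLOW = 20.0          # obligate acetate overflow per biomass unit (toy_a)
AC_PER_BIOMASS_B = 20.0     # acetate demand of one toy_b biomass unit
CAPACITY = 15.0             # shared importer capacity (mmol/gDW/h)
AC_WASTE_RATIO = 100.0      # toy_c: acetate per internal hexose (wasteful)


def _met(met_id: str, formula: str = "") -> Metabolite:
    compartment = met_id.rsplit("_", 1)[-1]
    return Metabolite(met_id, compartment=compartment, formula=formula)


def toy_a(carbon: str = "glc__D") -> MetabolicModel:
    """Overflow producer; ``carbon`` picks the substrate (default glucose)."""
    c_e, c_c = f"{carbon}_e", f"{carbon}_c"
    formula = {"glc__D": "C6H12O6", "glyc": "C3H8O3"}.get(carbon, "")
    suffix = "" if carbon == "glc__D" else f"_{carbon}"
    return MetabolicModel(
        model_id=f"toy_a{suffix}",
        metabolites=[
            _met(c_e, formula),
            _met("ac_e", "C2H4O2"),
            _met("p1_e", "C3H8O2"),
            _met(c_c, formula),
            _met("cap_c"),
            _met("ac_x_c"),
            _met("ac_y_c"),
            _met("ac_z_c"),
            _met("p1_c", "C3H8O2"),
        ],
        reactions=[
            Reaction(f"EX_{c_e}", {c_e: -1}, -1000, 1000),
            Reaction("EX_ac_e", {"ac_e": -1}, -1000, 1000),
            Reaction(P1_EXCHANGE, {"p1_e": -1}, 0, 1000),
            Reaction("CAPGEN", {"cap_c": 1}, 0, CAPACITY),
            Reaction("CARBt", {c_e: -1, "cap_c": -1, c_c: 1}, 0, 1000),
            Reaction(
                "BIOMASS_toya",
                {c_c: -GLC_PER_BIOMASS, "ac_e": AC_OVERFLOW},
                0, 1000,
            ),
            Reaction("ACt", {"ac_e": -1, "cap_c": -1, "ac_x_c": 1}, 0, 1000),
            Reaction("ACS1", {"ac_x_c": -1, "ac_y_c": 1}, 0, 1000),
            Reaction("ACS2", {"ac_y_c": -1, "ac_z_c": 1}, 0, 1000),
            Reaction("ACOAS", {"ac_z_c": -1, c_c: 1}, 0, 1000),
            Reaction("P1S", {c_c: -1, "p1_c": 1}, 0, 1000),
            Reaction("P1t", {"p1_c": -1, "p1_e": 1}, 0, 1000),
        ],
        objective_reaction_id="BIOMASS_toya",
    )


def toy_b() -> MetabolicModel:
    """Acetate specialist; no glucose metabolism at all."""
    return MetabolicModel(
        model_id="toy_b",
        metabolites=[
            _met("ac_e", "C2H4O2"),
            _met("p2_e", "C4H8O3"),
            _met("ac_b_c"),
            _met("p2_c", "C4H8O3"),
        ],
        reactions=[
            Reaction("EX_ac_e", {"ac_e": -1}, -1000, 1000),
            Reaction(P2_EXCHANGE, {"p2_e": -1}, 0, 1000),
            Reaction("ACt_B", {"ac_e": -1, "ac_b_c": 1}, 0, 1000),
            Reaction("BIOMASS_toyb", {"ac_b_c": -AC_PER_BIOMASS_B}, 0, 1000),
            Reaction("P2S", {"ac_b_c": -1, "p2_c": 1}, 0, 1000),
            Reaction("P2t", {"p2_c": -1, "p2_e": 1}, 0, 1000),
        ],
        objective_reaction_id="BIOMASS_toyb",
    )


def toy_c() -> MetabolicModel:
    """Glucose competitor with no secretion and wasteful acetate uptake."""
    return MetabolicModel(
        model_id="toy_c",
        metabolites=[
            _met("glc__D_e", "C6H12O6"),
            _met("ac_e", "C2H4O2"),
            _met("glc__D_c", "C6H12O6"),
            _met("cap_c"),
            _met("ac_w_c"),
        ],
        reactions=[
            Reaction("EX_glc__D_e", {"glc__D_e": -1}, -1000, 1000),
            Reaction("EX_ac_e", {"ac_e": -1}, -1000, 1000),
            Reaction("CAPGEN_C", {"cap_c": 1}, 0, CAPACITY),
            Reaction("GLCt_C", {"glc__D_e": -1, "cap_c": -1, "glc__D_c": 1}, 0, 1000),
            Reaction("BIOMASS_toyc", {"glc__D_c": -GLC_PER_BIOMASS}, 0, 1000),
            Reaction("ACt_C", {"ac_e": -1, "cap_c": -1, "ac_w_c": 1}, 0, 1000),
            Reaction("ACOX_C", {"ac_w_c": -AC_WASTE_RATIO, "glc__D_c": 1}, 0, 1000),
        ],
        objective_reaction_id="BIOMASS_toyc",
    )


def toy_glycerol_consumer() -> MetabolicModel:
    """A glycerol-fed variant of ``toy_a`` for fed-batch exercises."""
    return toy_a(carbon="glyc")


#: Component lists for the fixture media (pool ids); build_environment adds
#: oxygen per regime.
MEDIA_TABLE: dict[str, list[str]] = {
    "minimal": ["glc__D_e"],
    "rich": ["glc__D_e", "ac_e"],
}


@dataclass
class ToyCommunity:
    models: dict[str, MetabolicModel]
    media: dict[str, Medium]
    media_table: dict[str, list[str]] = field(default_factory=lambda: dict(MEDIA_TABLE))
    seed: int = 0
    paths: dict[str, Path] = field(default_factory=dict)


class _WrittenPaths(NamedTuple):
    models: dict[str, Path]
    media: dict[str, Path]


def generate_toy_community(seed: int = 0, outdir: str | Path | None = None,
                           fmt: str = "json") -> ToyCommunity:
    """Emit the toy models and fixture media, optionally writing them to disk.

    The fixture is fully determined by constants, so output is byte-identical
    across calls regardless of ``seed`` (recorded for provenance only).
    """
    models = {m.model_id: m for m in (toy_a(), toy_b(), toy_c())}
    media = {
        "minimal": Medium(
            "toy_minimal", {"glc__D_e": 10.0}, oxygen_regime="anaerobic"
        ),
        "rich": Medium(
            "toy_rich", {"glc__D_e": 10.0, "ac_e": 10.0}, oxygen_regime="anaerobic"
        ),
    }
    community = ToyCommunity(models=models, media=media, seed=seed)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ext = "json" if fmt == "json" else "xml"
        for model_id, model in models.items():
            path = outdir / f"{model_id}.{ext}"
            write_model(model, path, format=fmt)
            community.paths[model_id] = path
        for name, medium in media.items():
            path = outdir / f"medium_{name}.tsv"
            write_medium(medium, path)
            community.paths[f"medium_{name}"] = path
    return community
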