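"""Growth environments: media composition and oxygen regimes.

Screens are parameterised by four canonical environments — the cross of
{rich, minimal} media with {aerobic, anaerobic} oxygen regimes.  A medium is
a named mapping from shared (pool) metabolite identifiers to initial
extracellular concentrations in mmol/L.  By convention every listed medium
component starts at 10 mmol/L unless explicitly overridden; aerobic
environments additionally carry 10 mmol/L oxygen while anaerobic ones carry
none.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "AEROBIC",
    "ANAEROBIC",
    "DEFAULT_COMPONENT_CONC",
    "OXYGEN_ID",
    "EnvironmentSpec",
    "Medium",
    "build_environment",
    "load_medium",
    "swap_carbon_source",
    "write_medium",
]

OXYGEN_ID = "o2_e"
AEROBIC = "aerobic"
ANAEROBIC = "anaerobic"
RICHNESS_LEVELS = ("rich", "minimal")
OXYGEN_REGIMES = (AEROBIC, ANAEROBIC)

#: Default initial concentration of every medium component (mmol/L).
DEFAULT_COMPONENT_CONC = 10.0

#: Default primary carbon source swapped out by carbon-source scans.
PRIMARY_CARBON_ID = "glc__D_e"


class ConfigError(ValueError):
    """Raised for invalid environment or medium configuration."""


@dataclass(frozen=True)
class EnvironmentSpec:
    """One of the four canonical screening environments."""

    richness: str
    oxygen_regime: str

    def __post_init__(self) -> None:
        if self.richness not in RICHNESS_LEVELS:
            raise ConfigError(
                f"unknown richness {self.richness!r}; expected one of {RICHNESS_LEVELS}"
            )
        if self.oxygen_regime not in OXYGEN_REGIMES:
            raise ConfigError(
                f"unknown oxygen regime {self.oxygen_regime!r}; "
                f"expected one of {OXYGEN_REGIMES}"
            )

    @property
    def name(self) -> str:
        return f"{self.oxygen_regime}_{self.richness}"

    @classmethod
    def from_name(cls, name: str) -> "EnvironmentSpec":
        try:
            oxygen, richness = name.split("_")
        except ValueError:
            raise ConfigError(f"cannot parse environment name {name!r}") from None
        return cls(richness=richness, oxygen_regime=oxygen)

    @classmethod
    def all(cls) -> tuple["EnvironmentSpec", ...]:
        return tuple(
            cls(richness=r, oxygen_regime=o)
            for o in OXYGEN_REGIMES
            for r in RICHNESS_LEVELS
        )


@dataclass
class Medium:
    """Extracellular metabolite pool composition (mmol/L) plus oxygen regime."""

    name: str
    concentrations: dict[str, float] = field(default_factory=dict)
    oxygen_regime: str = AEROBIC

    def __post_init__(self) -> None:
        for met, conc in self.concentrations.items():
            if conc < 0:
                raise ConfigError(f"negative concentration for {met}: {conc}")
        if self.oxygen_regime not in OXYGEN_REGIMES:
            raise ConfigError(f"unknown oxygen regime {self.oxygen_regime!r}")
        if self.oxygen_regime == ANAEROBIC and self.concentrations.get(OXYGEN_ID, 0.0):
            raise ConfigError("anaerobic medium must not contain oxygen")

    def get(self, met_id: str) -> float:
        return self.concentrations.get(met_id, 0.0)

    def copy(self, name: str | None = None) -> "Medium":
        return Medium(
            name=name or self.name,
            concentrations=dict(self.concentrations),
            oxygen_regime=self.oxygen_regime,
        )


def build_environment(
    spec: EnvironmentSpec,
    media_table: Mapping[str, Iterable[str]],
    overrides: Mapping[str, float] | None = None,
) -> Medium:
    """Construct the medium for one canonical environment.

    ``media_table`` maps each richness level to its list of component pool
    ids.  Every listed component starts at 10 mmol/L unless overridden;
    aerobic environments add 10 mmol/L oxygen, anaerobic ones exclude it.
    """
    try:
        components = list(media_table[spec.richness])
    except KeyError:
        raise ConfigError(
            f"media table lacks components for richness {spec.richness!r}"
        ) from None
    if not components:
        raise ConfigError(f"empty component list for richness {spec.richness!r}")
    overrides = dict(overrides or {})
    conc = {
        met: float(overrides.get(met, DEFAULT_COMPONENT_CONC))
        for met in sorted(set(components))
        if met != OXYGEN_ID
    }
    if spec.oxygen_regime == AEROBIC:
        conc[OXYGEN_ID] = float(overrides.get(OXYGEN_ID, DEFAULT_COMPONENT_CONC))
    return Medium(name=spec.name, concentrations=conc, oxygen_regime=spec.oxygen_regime)


def swap_carbon_source(
    medium: Medium,
    carbon_id: str,
    primary_carbon_id: str = PRIMARY_CARBON_ID,
    concentration: float = DEFAULT_COMPONENT_CONC,
) -> Medium:
    """Replace the primary carbon source with ``carbon_id`` at 10 mmol/L.

    All other components are conserved exactly.  Swapping to the primary
    carbon itself is the identity.
    """
    if primary_carbon_id not in medium.concentrations:
        raise ConfigError(
            f"medium {medium.name!r} lacks primary carbon source {primary_carbon_id!r}"
        )
    if carbon_id == primary_carbon_id:
        return medium.copy()
    conc = dict(medium.concentrations)
    del conc[primary_carbon_id]
    conc[carbon_id] = float(concentration)
    return Medium(
        name=f"{medium.name}__{carbon_id}",
        concentrations=conc,
        oxygen_regime=medium.oxygen_regime,
    )


def load_medium(path: str | Path, name: str | None = None,
                oxygen_regime: str = AEROBIC) -> Medium:
    """Read a medium from a TSV with columns metabolite_id, concentration_mmol_per_L."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t", comment="#")
    required = {"metabolite_id", "concentration_mmol_per_L"}
    if not required.issubset(table.columns):
        raise ConfigError(
            f"medium file {path} must have columns {sorted(required)}; "
            f"found {list(table.columns)}"
        )
    conc = {
        str(row.metabolite_id): float(row.concentration_mmol_per_L)
        for row in table.itertuples()
    }
    if conc.get(OXYGEN_ID, 0.0) > 0:
        oxygen_regime = AEROBIC
    return Medium(name=name or path.stem, concentrations=conc,
                  oxygen_regime=oxygen_regime)


def write_medium(medium: Medium, path: str | Path) -> None:
    path = Path(path)
    rows = sorted(medium.concentrations.items())
    table = pd.DataFrame(rows, columns=["metabolite_id", "concentration_mmol_per_L"])
    table.to_csv(path, sep="\t", index=False)


def anaerobic_variant(medium: Medium, name: str | None = None) -> Medium:
    """Return a copy of ``medium`` with oxygen removed."""
    conc = {k: v for k, v in medium.concentrations.items() if k != OXYGEN_ID}
    return Medium(
        name=name or f"{medium.name}_anaerobic",
        concentrations=conc,
        oxygen_regime=ANAEROBIC,
    )
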