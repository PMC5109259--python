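"""Exposure scenarios: media/land-use combinations, receptors and routes.

The default regional study covers seven scenarios along a drinking-water
supply waterway: four surface-soil land uses — riverbank vegetable plots
(RVS), riverbank green spaces (RGS), private vegetable plots (PVS) and
public green spaces (PGS) — plus groundwater (predicted by leaching from
the 0-100 cm soil profile), surface water, and river sediments.

Receptors are the most sensitive population for each scenario: farmers for
vegetable plots, residents with regular outdoor activity for green spaces,
residents drinking the supply water, and swimmers for the river water and
sediments.  Routes per scenario follow those behaviours: soil scenarios get
ingestion + dermal + inhalation (vegetable-plot soils additionally vegetable
ingestion); groundwater is ingestion-only; surface water is ingestion +
dermal; sediment is ingestion + dermal.

The total hazard quotient (THQ) of a scenario is the sum of HQs over its
routes and the eight metals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exposure import (
    METALS,
    ExposureContext,
    MetalProperties,
    conc_groundwater,
    hq_dermal_solid,
    hq_dermal_water,
    hq_ingestion,
    hq_inhalation,
    hq_vegetable,
)
from .params import CorrelationSpec, ParameterSpec, SampleMatrix, sample_parameters

__all__ = [
    "ROUTES",
    "ScenarioDefinition",
    "ScenarioResult",
    "total_hq",
    "build_default_study",
    "default_correlations",
    "metal_uncertainty_specs",
    "run_scenario",
]

ROUTES = ("ingestion", "dermal", "inhalation", "vegetable", "groundwater_ingestion")

_VEGETABLE_SCENARIOS = ("RVS", "PVS")

#: SampleMatrix column name -> ExposureContext field.
_CTX_BINDINGS = {
    "IR_s": "ir_s",
    "IR_sd": "ir_sd",
    "IR_w": "ir_w",
    "IR_v": "ir_v",
    "IR_a": "ir_a",
    "EF_ia": "ef_ia",
    "EF_oa": "ef_oa",
    "EF_sw": "ef_sw",
    "ET_sw": "et_sw",
    "ED": "ed",
    "BW": "bw",
    "SA_o": "sa_o",
    "SA_sw": "sa_sw",
    "AF_sa": "af_sa",
    "AF_sd": "af_sd",
    "theta_v": "theta_v",
    "theta_w": "theta_w",
    "rho_b": "rho_b",
    "DF": "df",
    "PEF": "pef",
}


@dataclass(frozen=True)
class ScenarioDefinition:
    """A medium/land-use with its receptor, routes and concentration source.

    ``conc_stratum`` names the concentration-summary stratum bound to the
    scenario; for the groundwater scenario it is the 0-100 cm soil profile
    from which groundwater concentrations are derived by leaching.
    """

    name: str
    medium: str  # soil | water | sediment
    receptor: str
    routes: frozenset
    conc_stratum: str

    def __post_init__(self) -> None:
        if self.medium not in ("soil", "water", "sediment"):
            raise ValueError(f"scenario {self.name!r}: unknown medium {self.medium!r}")
        unknown = set(self.routes) - set(ROUTES)
        if unknown:
            raise ValueError(f"scenario {self.name!r}: unknown routes {sorted(unknown)}")
        if "vegetable" in self.routes and not (
            self.medium == "soil" and self.name in _VEGETABLE_SCENARIOS
        ):
            raise ValueError(
                f"scenario {self.name!r}: vegetable route is restricted to "
                f"vegetable-plot soil scenarios {_VEGETABLE_SCENARIOS}"
            )
        if "groundwater_ingestion" in self.routes and self.routes != frozenset(
            {"groundwater_ingestion"}
        ):
            raise ValueError(
                f"scenario {self.name!r}: groundwater ingestion is a standalone scenario route"
            )


@dataclass
class ScenarioResult:
    """Monte Carlo output of one scenario run."""

    scenario: ScenarioDefinition
    samples: SampleMatrix
    hq: dict  # route -> metal -> ndarray of per-iteration HQs
    thq: np.ndarray
    thq_by_metal: dict

    @property
    def route_totals(self) -> dict:
        """Per-route HQ summed over metals, per iteration."""
        return {
            route: np.sum(list(by_metal.values()), axis=0)
            for route, by_metal in self.hq.items()
        }


def total_hq(per_route_hq: Mapping[str, Mapping[str, np.ndarray]]):
    """Sum HQs over routes and metals; additive by definition.

    Returns ``(thq, thq_by_metal)`` where ``thq`` is the per-iteration total
    and ``thq_by_metal`` maps each metal to its summed contribution across
    routes.  All sample vectors must share the iteration count.
    """
    lengths = {
        np.asarray(v).shape[0]
        for by_metal in per_route_hq.values()
        for v in by_metal.values()
    }
    if len(lengths) > 1:
        raise ValueError(f"mismatched iteration counts across HQ vectors: {sorted(lengths)}")
    (n,) = lengths or (0,)
    thq = np.zeros(n)
    by_metal: dict[str, np.ndarray] = {}
    for by_metal_route in per_route_hq.values():
        for metal, hq in by_metal_route.items():
            hq = np.asarray(hq, dtype=float)
            thq = thq + hq
            by_metal[metal] = by_metal.get(metal, 0.0) + hq
    return thq, by_metal


def build_default_study() -> list[ScenarioDefinition]:
    """The seven default scenarios of the regional study."""
    soil = ("ingestion", "dermal", "inhalation")
    return [
        ScenarioDefinition(
            "RVS", "soil", "farmers working riverbank vegetable plots",
            frozenset(soil + ("vegetable",)), "RVS",
        ),
        ScenarioDefinition(
            "RGS", "soil", "residents with outdoor activity on riverbank green space",
            frozenset(soil), "RGS",
        ),
        ScenarioDefinition(
            "PVS", "soil", "farmers working private vegetable plots",
            frozenset(soil + ("vegetable",)), "PVS",
        ),
        ScenarioDefinition(
            "PGS", "soil", "residents with outdoor activity on public green space",
            frozenset(soil), "PGS",
        ),
        ScenarioDefinition(
            "groundwater", "water", "residents drinking groundwater",
            frozenset({"groundwater_ingestion"}), "profile_0_100",
        ),
        ScenarioDefinition(
            "surface_water", "water", "residents drinking and swimming in river water",
            frozenset({"ingestion", "dermal"}), "surface_water",
        ),
        ScenarioDefinition(
            "sediment", "sediment", "residents swimming in the river",
            frozenset({"ingestion", "dermal"}), "sediment",
        ),
    ]


def default_correlations(
    metals: Sequence[str] = METALS,
    bw_sa: float = 0.7,
    puf_kd: float = -0.7,
) -> CorrelationSpec:
    """Default dependence structure: body weight rises with skin surface
    area; plant uptake falls with soil sorption strength (per metal).

    Both skin-area parameters are driven by body size, so they also carry
    the implied mutual correlation ``bw_sa**2`` — without it the declared
    structure would not be positive semi-definite.
    """
    pairs = [
        ("BW", "SA_o", bw_sa),
        ("BW", "SA_sw", bw_sa),
        ("SA_o", "SA_sw", bw_sa * bw_sa),
    ]
    pairs += [(f"PUF_{m}", f"Kd_{m}", puf_kd) for m in metals]
    return CorrelationSpec.from_pairs(pairs)


def metal_uncertainty_specs(
    props: Mapping[str, MetalProperties],
    kind: str,
    cv: float | None = None,
) -> list[ParameterSpec]:
    """Lognormal specs for per-metal transfer factors around their central
    values: ``kind`` is ``"Kd"`` (L/kg, default CV 0.75 — soil sorption
    varies widely between sites) or ``"PUF"`` (unitless, default CV 0.6)."""
    if kind == "Kd":
        cv = 0.75 if cv is None else cv
        lo_f, hi_f, units = 0.1, 10.0, "L/kg"
    elif kind == "PUF":
        cv = 0.6 if cv is None else cv
        lo_f, hi_f, units = 0.1, 5.0, "unitless"
    else:
        raise ValueError(f"kind must be 'Kd' or 'PUF', got {kind!r}")
    specs = []
    for metal, p in props.items():
        centre = p.kd if kind == "Kd" else p.puf
        specs.append(
            ParameterSpec(
                name=f"{kind}_{metal}",
                family="lognormal",
                mean=centre,
                sd=cv * centre,
                minimum=lo_f * centre,
                maximum=hi_f * centre,
                units=units,
            )
        )
    return specs


def _context_from_samples(samples: SampleMatrix) -> ExposureContext:
    kwargs = {
        ctx_name: samples[col]
        for col, ctx_name in _CTX_BINDINGS.items()
        if col in samples
    }
    return ExposureContext(**kwargs)


def run_scenario(
    scenario: ScenarioDefinition,
    conc_specs: Mapping[str, ParameterSpec],
    exposure_specs: Sequence[ParameterSpec],
    props: Mapping[str, MetalProperties],
    n_iterations: int = 10_000,
    seed: int = 0,
    correlations: CorrelationSpec | None = None,
) -> ScenarioResult:
    """Monte Carlo run of one scenario.

    ``conc_specs`` maps metal -> concentration ParameterSpec for the
    scenario's stratum (column names ``C_<metal>``); ``exposure_specs`` is
    the shared exposure-parameter table.  Per-metal Kd and PUF uncertainty
    specs are added automatically when a route needs them, and the declared
    rank correlations (defaults from :func:`default_correlations`) are
    induced across the joint draw.
    """
    if correlations is None:
        correlations = default_correlations(list(conc_specs))

    specs = list(exposure_specs)
    specs += [
        ParameterSpec(
            name=f"C_{metal}",
            family=spec.family,
            mean=spec.mean,
            sd=spec.sd,
            minimum=spec.minimum,
            maximum=spec.maximum,
            mode=spec.mode,
            units=spec.units,
        )
        for metal, spec in conc_specs.items()
    ]
    needs_transfer = bool(
        {"vegetable", "groundwater_ingestion"} & set(scenario.routes)
    )
    if needs_transfer:
        used = {m: props[m] for m in conc_specs}
        specs += metal_uncertainty_specs(used, "Kd")
        specs += metal_uncertainty_specs(used, "PUF")

    samples = sample_parameters(specs, n_iterations, seed, correlations)
    ctx = _context_from_samples(samples)

    hq: dict[str, dict[str, np.ndarray]] = {}
    for route in sorted(scenario.routes):
        hq[route] = {}
        for metal in conc_specs:
            conc = samples[f"C_{metal}"]
            p = props[metal]
            if route == "ingestion":
                medium = {
                    "soil": "soil", "sediment": "sediment", "water": "surface_water"
                }[scenario.medium]
                values = hq_ingestion(conc, ctx, p, medium)
            elif route == "dermal":
                if scenario.medium == "water":
                    values = hq_dermal_water(conc, ctx, p)
                else:
                    values = hq_dermal_solid(conc, ctx, p, scenario.medium)
            elif route == "inhalation":
                values = hq_inhalation(conc, ctx, p)
            elif route == "vegetable":
                values = hq_vegetable(conc, ctx, p, puf=samples[f"PUF_{metal}"])
            elif route == "groundwater_ingestion":
                c_gw = conc_groundwater(
                    conc, samples[f"Kd_{metal}"], ctx.theta_w, ctx.rho_b, ctx.df
                )
                values = hq_ingestion(c_gw, ctx, p, "groundwater")
            else:  # pragma: no cover - guarded by ScenarioDefinition
                raise ValueError(f"unhandled route {route!r}")
            hq[route][metal] = values

    thq, by_metal = total_hq(hq)
    return ScenarioResult(scenario, samples, hq, thq, by_metal)
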