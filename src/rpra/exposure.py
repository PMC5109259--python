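"""Multi-route hazard-quotient models for heavy-metal exposure.

A hazard quotient (HQ) is the chronic daily intake of a metal through one
exposure route divided by the route-specific chronic reference dose (RfD);
HQ > 1 flags a potential non-carcinogenic health risk.  The routes covered:

* incidental ingestion of soil or sediment particles, and ingestion of
  surface water or groundwater;
* ingestion of vegetables grown on contaminated soil (soil-to-plant transfer
  via the plant uptake factor, PUF, on a dry-weight basis);
* dermal contact with soil/sediment (adherence x absorption) and with water
  (permeability constant K_p over an exposure event);
* inhalation of resuspended dust (particulate emission factor, PEF) and,
  for elemental mercury only, vapour (volatilization factor, VF).

Groundwater concentrations are not measured but predicted from the 0-100 cm
soil profile by equilibrium partitioning with a dilution factor:
``C_gw = 1000 * C_ts / ((K_d + theta_w / rho_b) * DF)`` (ug/L from mg/kg).

All functions are vectorized over Monte Carlo iterations: any argument may
be a scalar or an array of per-iteration values, and the result follows
numpy broadcasting.  Unit conversions are explicit constants, never folded
silently into parameter values.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dataclass_fields
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "METALS",
    "UF_SOLID",
    "UF_WATER",
    "MetalProperties",
    "ExposureContext",
    "hq_ingestion",
    "conc_groundwater",
    "hq_vegetable",
    "hq_dermal_solid",
    "hq_dermal_water",
    "hq_inhalation",
    "load_metal_properties",
]

#: The eight metals surveyed in the study area.
METALS = ("As", "Hg", "Cd", "Zn", "Pb", "Cu", "Cr", "Ni")

#: Unit transfer factor for solids: mg intake per (mg/kg x mg ingested).
UF_SOLID = 1e-6
#: Unit transfer factor for waters: mg per ug, with intake rates in L/d.
UF_WATER = 1e-3

#: cm^2 per m^2 — skin surface areas are declared in m^2.
_CM2_PER_M2 = 1e4
#: mg/cm^3 per ug/L: 1 ug/L = 1e-3 mg / 1e3 cm^3.
_MG_CM3_PER_UG_L = 1e-6

_SOLID_MEDIA = ("soil", "sediment")
_WATER_MEDIA = ("surface_water", "groundwater")


@dataclass(frozen=True)
class MetalProperties:
    """Toxicity and transfer constants for one metal.

    Reference doses in mg/kg/d per route; ``kd`` (L/kg) and ``puf``
    (unitless, dry-weight) are the central values used to build uncertain
    parameter specs; ``kp`` (cm/h) dermal permeability from water; ``abs_f``
    (unitless) dermal absorption fraction from solids; ``vf`` (m^3/kg)
    volatilization factor, present only for elemental Hg.
    """

    metal: str
    rfd_oral: float
    rfd_dermal: float
    rfd_inhalation: float
    kd: float
    puf: float
    kp: float
    abs_f: float
    vf: float | None = None

    def __post_init__(self) -> None:
        if self.metal not in METALS:
            raise ValueError(f"unknown metal {self.metal!r}; expected one of {METALS}")
        for fname in ("rfd_oral", "rfd_dermal", "rfd_inhalation"):
            if getattr(self, fname) <= 0:
                raise ValueError(f"{self.metal}: {fname} must be > 0")


@dataclass(frozen=True)
class ExposureContext:
    """Per-iteration receptor and site parameters shared across routes.

    Each field is a scalar or an array of Monte Carlo draws (broadcastable).
    Intake rates: ``ir_s``/``ir_sd`` mg/d (soil/sediment), ``ir_w`` L/d,
    ``ir_v`` kg/d fresh weight, ``ir_a`` m^3/d.  Exposure frequencies in
    d/yr for indoor (``ef_ia``) and outdoor (``ef_oa``) activity and
    events/yr for swimming (``ef_sw``, with ``et_sw`` h/event).  ``ed``
    exposure duration (yr), ``bw`` body weight (kg), ``at`` averaging time
    (d, defaults to ed*365).  Skin areas ``sa_o``/``sa_sw`` (m^2), adherence
    ``af_sa``/``af_sd`` (mg/cm^2), vegetable water content ``theta_v``,
    water-filled porosity ``theta_w`` (L/L), bulk density ``rho_b`` (g/cm^3),
    dilution factor ``df``, particulate emission factor ``pef`` (m^3/kg).
    """

    ed: float | np.ndarray
    bw: float | np.ndarray
    at: float | np.ndarray | None = None
    ir_s: float | np.ndarray | None = None
    ir_sd: float | np.ndarray | None = None
    ir_w: float | np.ndarray | None = None
    ir_v: float | np.ndarray | None = None
    ir_a: float | np.ndarray | None = None
    ef_ia: float | np.ndarray | None = None
    ef_oa: float | np.ndarray | None = None
    ef_sw: float | np.ndarray | None = None
    et_sw: float | np.ndarray | None = None
    sa_o: float | np.ndarray | None = None
    sa_sw: float | np.ndarray | None = None
    af_sa: float | np.ndarray | None = None
    af_sd: float | np.ndarray | None = None
    theta_v: float | np.ndarray | None = None
    theta_w: float | np.ndarray | None = None
    rho_b: float | np.ndarray | None = None
    df: float | np.ndarray | None = None
    pef: float | np.ndarray | None = None

    def __post_init__(self) -> None:
        for f in dataclass_fields(self):
            v = getattr(self, f.name)
            if v is None:
                continue
            arr = np.asarray(v, dtype=float)
            if np.any(arr <= 0) and f.name not in ("theta_v",):
                raise ValueError(f"exposure parameter {f.name!r} must be strictly positive")
        if self.at is None:
            object.__setattr__(self, "at", np.asarray(self.ed, dtype=float) * 365.0)
        if np.any(np.asarray(self.at) < np.asarray(self.ed) * 365.0 - 1e-9):
            raise ValueError("averaging time at must be >= ed * 365 d")

    def require(self, *names: str):
        """Return the named fields, raising if any is unbound."""
        out = []
        for name in names:
            v = getattr(self, name)
            if v is None:
                raise ValueError(f"exposure parameter {name!r} is required but unbound")
            out.append(np.asarray(v, dtype=float))
        return out


def _ingestion_bindings(ctx: ExposureContext, medium: str):
    if medium == "soil":
        ir, ef = ctx.require("ir_s", "ef_oa")
        uf = UF_SOLID
    elif medium == "sediment":
        ir, ef = ctx.require("ir_sd", "ef_sw")
        uf = UF_SOLID
    elif medium in _WATER_MEDIA:
        ir, ef = ctx.require("ir_w", "ef_ia")
        uf = UF_WATER
    else:
        raise ValueError(
            f"unknown medium {medium!r}; expected one of "
            f"{_SOLID_MEDIA + _WATER_MEDIA}"
        )
    return ir, ef, uf


def hq_ingestion(conc, ctx: ExposureContext, props: MetalProperties, medium: str):
    """HQ for ingestion of soil/sediment particles or of water.

    ``HQ = C * IR * EF * ED * UF / (BW * AT * RfD_oral)`` with the unit
    factor UF = 1e-6 for solids (conc in mg/kg, IR in mg/d) and 1e-3 for
    waters (conc in ug/L, IR in L/d).
    """
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be nonnegative")
    ir, ef, uf = _ingestion_bindings(ctx, medium)
    (ed, bw, at) = ctx.require("ed", "bw", "at")
    return conc * ir * ef * ed * uf / (bw * at * props.rfd_oral)


def conc_groundwater(c_ts, kd, theta_w, rho_b, df):
    """Predicted groundwater concentration (ug/L) from profile soil (mg/kg).

    Equilibrium soil-water partitioning with dilution during transport:
    ``C_gw = 1000 * C_ts / ((K_d + theta_w / rho_b) * DF)``.
    Monotone increasing in ``c_ts``; decreasing in ``kd`` and ``df``.
    """
    c_ts, kd, theta_w, rho_b, df = map(np.asarray, (c_ts, kd, theta_w, rho_b, df))
    denom = (kd + theta_w / rho_b) * df
    if np.any(denom <= 0):
        raise ValueError("kd + theta_w/rho_b and df must be strictly positive")
    return 1000.0 * c_ts / denom


def hq_vegetable(c_as, ctx: ExposureContext, props: MetalProperties, puf=None):
    """HQ for ingestion of vegetables grown on agricultural soil.

    ``HQ = C_as * PUF * IR_v * (1 - theta_v) * EF * ED / (BW * AT * RfD_oral)``.
    ``IR_v`` is fresh-weight intake; the ``(1 - theta_v)`` factor converts it
    to dry mass, on which PUF is defined.  ``puf`` may be a per-iteration
    array (the sampled, K_d-correlated uptake factor); defaults to the
    metal's central value.
    """
    c_as = np.asarray(c_as, dtype=float)
    (ir_v, theta_v, ef, ed, bw, at) = ctx.require(
        "ir_v", "theta_v", "ef_ia", "ed", "bw", "at"
    )
    if np.any(theta_v < 0) or np.any(theta_v >= 1):
        raise ValueError("vegetable water content theta_v must lie in [0, 1)")
    puf = props.puf if puf is None else np.asarray(puf, dtype=float)
    return c_as * puf * ir_v * (1.0 - theta_v) * ef * ed / (bw * at * props.rfd_oral)


def hq_dermal_solid(conc, ctx: ExposureContext, props: MetalProperties, medium: str = "soil"):
    """HQ for dermal contact with soil or sediment particles.

    ``HQ = C * (SA * 1e4) * AF * ABS * EF * ED * 1e-6 / (BW * AT * RfD_dermal)``
    with SA in m^2 (converted to cm^2) and AF in mg/cm^2.  Soil contact uses
    the outdoor-activity skin area/adherence and EF_oa; sediment contact the
    swimming values and EF_sw.
    """
    if props.rfd_dermal is None or props.rfd_dermal <= 0:
        raise ValueError(f"{props.metal}: dermal route enabled but rfd_dermal missing")
    conc = np.asarray(conc, dtype=float)
    if medium == "soil":
        sa, af, ef = ctx.require("sa_o", "af_sa", "ef_oa")
    elif medium == "sediment":
        sa, af, ef = ctx.require("sa_sw", "af_sd", "ef_sw")
    else:
        raise ValueError(f"dermal solid contact medium must be soil or sediment, got {medium!r}")
    (ed, bw, at) = ctx.require("ed", "bw", "at")
    return (
        conc * (sa * _CM2_PER_M2) * af * props.abs_f * ef * ed * UF_SOLID
        / (bw * at * props.rfd_dermal)
    )


def hq_dermal_water(conc, ctx: ExposureContext, props: MetalProperties):
    """HQ for dermal contact with water during swimming.

    Absorbed dose per event is ``C[mg/cm^3] * K_p[cm/h] * SA[cm^2] * ET[h]``;
    with C in ug/L the conversion is 1 ug/L = 1e-6 mg/cm^3.  Annualized over
    EF_sw events/yr:

    ``HQ = C * 1e-6 * Kp * (SA * 1e4) * ET * EF_sw * ED / (BW * AT * RfD_dermal)``
    """
    if props.kp is None or props.kp <= 0:
        raise ValueError(f"{props.metal}: dermal water route enabled but kp missing")
    conc = np.asarray(conc, dtype=float)
    (sa, et, ef_sw, ed, bw, at) = ctx.require("sa_sw", "et_sw", "ef_sw", "ed", "bw", "at")
    dose = (
        conc * _MG_CM3_PER_UG_L * props.kp * (sa * _CM2_PER_M2) * et * ef_sw * ed
        / (bw * at)
    )
    return dose / props.rfd_dermal


def hq_inhalation(conc, ctx: ExposureContext, props: MetalProperties):
    """HQ for inhalation of resuspended soil dust and (Hg only) vapour.

    Air concentration combines the particulate and volatile pathways
    additively: ``C_air = C_soil * (1/PEF + 1/VF)``, the 1/VF term dropping
    out for metals without a volatilization factor.

    ``HQ = C * IR_a * EF * ED * (1/PEF + 1/VF) / (BW * AT * RfD_inhalation)``
    """
    conc = np.asarray(conc, dtype=float)
    (ir_a, ef, pef, ed, bw, at) = ctx.require("ir_a", "ef_oa", "pef", "ed", "bw", "at")
    inv_vf = 0.0 if props.vf is None else 1.0 / props.vf
    return (
        conc * ir_a * ef * ed * (1.0 / pef + inv_vf)
        / (bw * at * props.rfd_inhalation)
    )


def load_metal_properties(path=None) -> dict[str, MetalProperties]:
    """Load the per-metal property table (CSV: metal, rfd_oral, rfd_dermal,
    rfd_inhalation, kd, puf, kp, abs, vf).

    Without ``path``, loads the bundled defaults: a literature-assembled
    stand-in (USEPA IRIS/RAGS reference doses and absorption factors;
    partition and plant-uptake factors within published ranges for
    near-neutral alluvial soils).
    """
    if path is None:
        path = resources.files("rpra.data") / "metal_properties_default.csv"
    df = pd.read_csv(path, comment="#")
    props = {}
    for row in df.itertuples(index=False):
        props[str(row.metal)] = MetalProperties(
            metal=str(row.metal),
            rfd_oral=float(row.rfd_oral),
            rfd_dermal=float(row.rfd_dermal),
            rfd_inhalation=float(row.rfd_inhalation),
            kd=float(row.kd),
            puf=float(row.puf),
            kp=float(row.kp),
            abs_f=float(getattr(row, "abs")),
            vf=None if pd.isna(row.vf) else float(row.vf),
        )
    return props
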