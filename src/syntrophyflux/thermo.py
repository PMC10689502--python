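"""Thermodynamics of interspecies electron transfer during syntrophic
acetate oxidation.

Gibbs free energies of the guilds' net catabolic reactions are computed from
standard formation energies (packaged compilation, chemical convention at
298.15 K) with

* temperature adjustment by Gibbs-Helmholtz using formation enthalpies,
  ``dG(T) = dH - T * (dH - dG_298) / 298.15``, applied species-wise;
* in-situ adjustment ``dG = dG0(T) + R T ln Q`` with molar activities for
  aqueous species, partial pressures (atm) for gases, activity 1 for water,
  and the proton activity ``10**-pH``.

The "standard transformed" free energy at pH 7 is obtained by evaluating the
in-situ expression with every activity at 1 except the proton; for the
community conversion acetate- + H+ -> CH4(g) + CO2(g) this yields about
-35.7 kJ/mol at 298.15 K.  Note that Gibbs-Helmholtz adjustment of the same
transformed quantity to 328.15 K gives about -41 kJ/mol: the headline
"standard conditions" figure for this conversion is a 298.15 K quantity and
is reported as such (see docs/methods.md).

Guild energetics are evaluated on the common 1-mol-acetate basis so that the
per-guild free energies add up exactly to the community total (interspecies
H2/formate terms cancel).  Each guild's dG per mol ATP is affine in
ln(P_H2); sweeping the H2 partial pressure reproduces the classic syntrophy
niche diagram, and the feasibility window is the P_H2 interval over which
the required members all clear the ATP phosphorylation potential
(default -32.1 kJ/mol ATP).
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

R_KJ = 8.314462618e-3  # kJ/mol/K
T_REF = 298.15

#: ATP phosphorylation potential used as the default feasibility threshold,
#: kJ/mol ATP (measured in cells performing acetogenesis from H2 + CO2)
ATP_PHOSPHORYLATION_POTENTIAL = -32.1

#: map from community-model extracellular species to thermo table ids
MODEL_SPECIES = {
    "ac": "acetate",
    "for": "formate",
    "co2": "co2",
    "ch4": "ch4",
    "h2": "h2",
    "h2o": "h2o",
    "h": "h",
}

__all__ = [
    "ThermoTable",
    "Conditions",
    "GuildEnergetics",
    "load_thermo_table",
    "delta_g_standard",
    "delta_g_insitu",
    "guild_energetics",
    "dg_per_atp",
    "h2_sweep",
    "feasibility_interval",
    "feasibility_window",
    "syntrophy_window",
    "ATP_PHOSPHORYLATION_POTENTIAL",
]


class ThermoTable:
    """Standard formation energies/enthalpies keyed by species id."""

    def __init__(self, frame: pd.DataFrame):
        required = {"species_id", "phase", "dGf0_kj_mol", "dHf0_kj_mol"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"thermo table missing column(s) {sorted(missing)}")
        self._df = frame.set_index("species_id")

    def __contains__(self, species: str) -> bool:
        return species in self._df.index

    def phase(self, species: str) -> str:
        return str(self._row(species)["phase"])

    def _row(self, species: str):
        if species not in self._df.index:
            raise KeyError(f"species {species!r} not in thermo table")
        return self._df.loc[species]

    def dgf(self, species: str, temperature: float = T_REF) -> float:
        """Formation energy at ``temperature`` via Gibbs-Helmholtz."""
        row = self._row(species)
        dg, dh = float(row["dGf0_kj_mol"]), float(row["dHf0_kj_mol"])
        if temperature == T_REF:
            return dg
        return dh - temperature * (dh - dg) / T_REF


def load_thermo_table(path=None) -> ThermoTable:
    """Load the packaged formation-energy table, or one from ``path``."""
    if path is None:
        path = importlib.resources.files("syntrophyflux") / "data" / "thermo_table.tsv"
    return ThermoTable(pd.read_csv(path, sep="\t", comment="#"))


@dataclass
class Conditions:
    """In-situ activities: molar for aqueous species, atm for gases.

    Defaults reflect environmentally relevant digester conditions: 50 mM
    acetate, 7.5 uM formate, 0.5 atm CH4 and CO2, pH 7; the H2 partial
    pressure is the swept variable.
    """

    temperature: float = 328.15
    ph: float = 7.0
    concentrations: dict[str, float] = field(
        default_factory=lambda: {
            "acetate": 0.05,
            "formate": 7.5e-6,
            "ch4": 0.5,
            "co2": 0.5,
            "h2": 1e-4,
        }
    )

    def activity(self, species: str) -> float:
        if species == "h2o":
            return 1.0
        if species == "h":
            return 10.0 ** (-self.ph)
        if species not in self.concentrations:
            raise KeyError(f"no in-situ concentration for species {species!r}")
        a = self.concentrations[species]
        if a <= 0:
            raise ValueError(f"activity of {species!r} must be positive, got {a}")
        return a

    def with_h2(self, p_h2: float) -> "Conditions":
        conc = dict(self.concentrations)
        conc["h2"] = p_h2
        return Conditions(self.temperature, self.ph, conc)


def delta_g_standard(
    stoichiometry: dict[str, float],
    table: ThermoTable,
    temperature: float = T_REF,
) -> float:
    """Standard (chemical-convention) reaction free energy at ``temperature``.

    ``stoichiometry`` maps thermo species ids to signed coefficients
    (negative = consumed).  Missing species raise, naming the offender.
    """
    return sum(
        coeff * table.dgf(sp, temperature) for sp, coeff in stoichiometry.items()
    )


def delta_g_insitu(
    stoichiometry: dict[str, float],
    table: ThermoTable,
    cond: Conditions,
) -> float:
    """Reaction free energy under in-situ conditions: dG0(T) + RT ln Q."""
    dg0 = delta_g_standard(stoichiometry, table, cond.temperature)
    ln_q = sum(
        coeff * math.log(cond.activity(sp)) for sp, coeff in stoichiometry.items()
    )
    return dg0 + R_KJ * cond.temperature * ln_q


@dataclass
class GuildEnergetics:
    """Energetic summary of one guild's net catabolism (1-mol-acetate basis)."""

    guild: str
    net_reaction: dict[str, float]  # thermo species ids -> coefficients
    dg: float  # kJ per mol acetate basis
    atp: float  # mol ATP per mol acetate basis
    dg_per_atp: float  # kJ per mol ATP


def _to_thermo_species(net: dict[str, float]) -> dict[str, float]:
    out = {}
    for short, coeff in net.items():
        if short not in MODEL_SPECIES:
            raise KeyError(f"no thermodynamic mapping for model species {short!r}")
        out[MODEL_SPECIES[short]] = coeff
    return out


def dg_per_atp(dg: float, atp: float) -> float:
    """Free energy yield per mol ATP; undefined (raises) at zero ATP."""
    if atp <= 0:
        raise ValueError(f"ATP yield must be positive, got {atp}")
    return dg / atp


def guild_energetics(
    yield_summary: dict,
    table: ThermoTable,
    cond: Conditions,
) -> dict[str, GuildEnergetics]:
    """Per-guild in-situ energetics from a :func:`community_yield` summary."""
    out = {}
    for guild, net in yield_summary["net_stoichiometry"].items():
        stoich = _to_thermo_species(net)
        dg = delta_g_insitu(stoich, table, cond)
        atp = yield_summary["atp_per_guild"][guild]
        out[guild] = GuildEnergetics(
            guild=guild,
            net_reaction=stoich,
            dg=dg,
            atp=atp,
            dg_per_atp=dg_per_atp(dg, atp),
        )
    return out


def h2_sweep(
    yield_summary: dict,
    table: ThermoTable,
    cond: Conditions,
    p_h2_grid: np.ndarray | None = None,
    scenario: str = "",
) -> pd.DataFrame:
    """Per-guild dG/ATP curves over an H2 partial-pressure grid.

    Default grid: 200 log-spaced points over 1e-6..1 atm.  Returns a tidy
    frame (scenario, guild, p_h2_atm, dg_kj, dg_per_atp_kj).  Each curve is
    affine in ln(P_H2) with slope sign equal to the guild's net H2
    stoichiometry.
    """
    if p_h2_grid is None:
        p_h2_grid = np.logspace(-6, 0, 200)
    p_h2_grid = np.asarray(p_h2_grid, dtype=float)
    if p_h2_grid.size == 0:
        raise ValueError("empty H2 partial-pressure grid")
    rows = []
    for guild, net in yield_summary["net_stoichiometry"].items():
        stoich = _to_thermo_species(net)
        atp = yield_summary["atp_per_guild"][guild]
        # affine form: dG(p) = dG(p0) + n_H2 * R T ln(p/p0)
        p0 = cond.activity("h2")
        dg0 = delta_g_insitu(stoich, table, cond)
        n_h2 = stoich.get("h2", 0.0)
        for p in p_h2_grid:
            dg = dg0 + n_h2 * R_KJ * cond.temperature * math.log(p / p0)
            rows.append((scenario, guild, p, dg, dg_per_atp(dg, atp)))
    return pd.DataFrame(
        rows, columns=["scenario", "guild", "p_h2_atm", "dg_kj", "dg_per_atp_kj"]
    )


def _curve_from_sweep(sweep: pd.DataFrame, guild: str):
    """Interpolable monotone curve dG/ATP(p) for one guild from a sweep frame."""
    sub = sweep[sweep["guild"] == guild].sort_values("p_h2_atm")
    if sub.empty:
        raise KeyError(f"guild {guild!r} not in sweep")
    logp = np.log(sub["p_h2_atm"].to_numpy())
    vals = sub["dg_per_atp_kj"].to_numpy()
    diffs = np.diff(vals)
    if not ((diffs >= -1e-9).all() or (diffs <= 1e-9).all()):
        raise ValueError(f"curve for guild {guild!r} is not monotone in P_H2")
    return lambda p: float(np.interp(math.log(p), logp, vals))


def feasibility_interval(
    curve,
    threshold: float = ATP_PHOSPHORYLATION_POTENTIAL,
    p_range: tuple[float, float] = (1e-6, 1.0),
    rtol: float = 0.01,
) -> tuple[float, float] | None:
    """P_H2 interval where a monotone dG/ATP curve is at or below threshold.

    Endpoints located by bisection in log space to ``rtol`` relative
    precision; returns None for an empty interval.
    """
    lo, hi = p_range
    if not lo < hi:
        raise ValueError("invalid P_H2 range")
    f_lo, f_hi = curve(lo) <= threshold, curve(hi) <= threshold
    if f_lo and f_hi:
        return (lo, hi)
    if not f_lo and not f_hi:
        return None

    def bisect(a, b, feasible_at_a):
        # returns boundary pressure between feasible and infeasible side
        while b / a > 1.0 + rtol:
            mid = math.sqrt(a * b)
            if (curve(mid) <= threshold) == feasible_at_a:
                a = mid
            else:
                b = mid
        return math.sqrt(a * b)

    boundary = bisect(lo, hi, f_lo)
    return (lo, boundary) if f_lo else (boundary, hi)


def feasibility_window(
    sweep: pd.DataFrame,
    guilds: list[str] | None = None,
    threshold: float = ATP_PHOSPHORYLATION_POTENTIAL,
    rtol: float = 0.01,
) -> tuple[float, float] | None:
    """P_H2 interval where every listed guild clears the threshold.

    ``guilds`` defaults to all guilds in the sweep.  Returns the
    intersection of the per-guild feasibility intervals (None if empty).
    """
    if guilds is None:
        guilds = list(sweep["guild"].unique())
    p_range = (float(sweep["p_h2_atm"].min()), float(sweep["p_h2_atm"].max()))
    lo, hi = p_range
    for g in guilds:
        iv = feasibility_interval(
            _curve_from_sweep(sweep, g), threshold, p_range, rtol
        )
        if iv is None:
            return None
        lo, hi = max(lo, iv[0]), min(hi, iv[1])
    return (lo, hi) if lo < hi else None


def syntrophy_window(
    sweep: pd.DataFrame,
    producer: str = "saob",
    consumers: tuple[str, ...] = ("m1", "m2"),
    threshold: float = ATP_PHOSPHORYLATION_POTENTIAL,
    rtol: float = 0.01,
) -> tuple[float, float] | None:
    """P_H2 range where the producer plus at least one consumer are feasible.

    The electron-accepting partners are interchangeable for sustaining the
    oxidation, so the community window is the producer interval intersected
    with the union of the consumer intervals.
    """
    p_range = (float(sweep["p_h2_atm"].min()), float(sweep["p_h2_atm"].max()))
    prod = feasibility_interval(
        _curve_from_sweep(sweep, producer), threshold, p_range, rtol
    )
    if prod is None:
        return None
    pieces = []
    for g in consumers:
        if g not in set(sweep["guild"]):
            continue
        iv = feasibility_interval(
            _curve_from_sweep(sweep, g), threshold, p_range, rtol
        )
        if iv is not None:
            pieces.append(iv)
    if not pieces:
        return None
    union = (min(p[0] for p in pieces), max(p[1] for p in pieces))
    lo, hi = max(prod[0], union[0]), min(prod[1], union[1])
    return (lo, hi) if lo < hi else None
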