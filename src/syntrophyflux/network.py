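"""Guild-compartmentalized stoichiometric models of syntrophic communities.

The community is represented as a single stoichiometric matrix spanning the
intracellular space of each guild (here ``saob``, ``m1``, ``m2``) plus the
shared extracellular space (``e``).  Metabolite identifiers carry their
compartment in brackets (``ac[e]``, ``atp[saob]``).  Interspecies transfer is
mediated only by transport reactions into the extracellular compartment, so
cross-feeding of H2 and formate is an explicit model feature rather than an
accounting convention.

Conventions:

* every guild has one ATP sink reaction named ``ATPM_<guild>`` (ATP + H2O ->
  ADP + Pi + H+).  Its flux is the guild's net catabolic ATP yield and the
  default community objective is the summed sink flux;
* ion-motive force is carried by a massless, chargeless pseudo-metabolite
  ``imf[<guild>]`` whose stoichiometric coefficients encode ions translocated
  per turnover (in ATP-equivalent units when the ATP synthase consumes one
  ``imf`` per ATP);
* exchange reactions (guild tag ``exchange``) and transporters (``transport``
  tag unused here; transporters belong to their guild) follow the usual FBA
  sign convention: negative flux = uptake into the system.

Mass and charge balance is enforced for every non-exchange reaction at load
time; the checker parses chemical formulas that may include carrier-moiety
tokens (``Fd``, ``Th``, ``Mh`` ...) treated as conserved pseudo-elements.
"""

from __future__ import annotations

import importlib.resources
import re
from copy import deepcopy
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "Metabolite",
    "Reaction",
    "CommunityModel",
    "parse_formula",
    "parse_equation",
    "load_model",
    "PACKAGED_MODELS",
]

COMPARTMENTS = ("saob", "m1", "m2", "e")
_COMPARTMENT_ALIASES = {"extracellular": "e"}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]*)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula into element -> count.

    Carrier moieties (ferredoxin core ``Fd``, F420 ``Fo``, ...) are written as
    capitalized tokens and behave as conserved pseudo-elements.  An empty
    formula denotes a massless pseudo-species (e.g. ion-motive force).
    """
    if not formula:
        return {}
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
    return counts


@dataclass(frozen=True)
class Metabolite:
    """A metabolite in one compartment of the community model."""

    met_id: str  # full id including compartment, e.g. "ac[e]"
    compartment: str
    formula: str = ""
    charge: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        comp = _COMPARTMENT_ALIASES.get(self.compartment, self.compartment)
        object.__setattr__(self, "compartment", comp)
        if comp not in COMPARTMENTS:
            raise ValueError(
                f"unknown compartment {self.compartment!r} for {self.met_id!r}; "
                f"expected one of {COMPARTMENTS}"
            )
        parse_formula(self.formula)  # validate eagerly

    @property
    def elements(self) -> dict[str, int]:
        return parse_formula(self.formula)


@dataclass
class Reaction:
    """A reaction with stoichiometry over full metabolite ids.

    ``guild`` is a guild compartment tag or ``"exchange"``; exchange reactions
    are exempt from balance checking.  Bounds are in mol per mol acetate.
    """

    rxn_id: str
    guild: str
    stoichiometry: dict[str, float]
    lower_bound: float
    upper_bound: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ValueError(f"{self.rxn_id}: lower bound exceeds upper bound")
        if not self.stoichiometry:
            raise ValueError(f"{self.rxn_id}: empty stoichiometry")

    def atp_coefficient(self, guild: str) -> float:
        """Signed stoichiometric coefficient of ATP in this guild's compartment."""
        return self.stoichiometry.get(f"atp[{guild}]", 0.0)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def equation(self) -> str:
        """Human-readable equation string, '1 a[x] + 2 b[y] -> c[z]' style."""
        lhs, rhs = [], []
        for met, coeff in self.stoichiometry.items():
            term = f"{abs(coeff):.12g} {met}"
            (lhs if coeff < 0 else rhs).append(term)
        arrow = "<->" if self.reversible else "->"
        return f"{' + '.join(lhs)} {arrow} {' + '.join(rhs)}"


_EQ_ARROW = re.compile(r"<->|<=>|-->|->|=>")


def parse_equation(equation: str) -> tuple[dict[str, float], bool]:
    """Parse '1 ac[e] + 1 atp[saob] -> 1 acp[saob] + ...' into stoichiometry.

    Returns ``(stoichiometry, reversible_arrow)``.
    """
    m = _EQ_ARROW.search(equation)
    if m is None:
        raise ValueError(f"no reaction arrow in equation {equation!r}")
    reversible = m.group(0) in ("<->", "<=>")
    sides = (equation[: m.start()], equation[m.end() :])
    stoich: dict[str, float] = {}
    for sign, side in zip((-1.0, 1.0), sides):
        side = side.strip()
        if not side:
            continue
        for term in side.split("+"):
            term = term.strip()
            if not term:
                continue
            parts = term.split()
            if len(parts) == 1:
                coeff, met = 1.0, parts[0]
            elif len(parts) == 2:
                coeff, met = float(parts[0]), parts[1]
            else:
                raise ValueError(f"cannot parse term {term!r} in {equation!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coeff
    return {k: v for k, v in stoich.items() if v != 0.0}, reversible


class CommunityModel:
    """Stoichiometric model over guild compartments plus extracellular space."""

    def __init__(
        self,
        name: str = "community",
        metabolites: dict[str, Metabolite] | None = None,
        reactions: dict[str, Reaction] | None = None,
        proteome_shares: dict[str, float] | None = None,
    ) -> None:
        self.name = name
        self.metabolites: dict[str, Metabolite] = dict(metabolites or {})
        self.reactions: dict[str, Reaction] = dict(reactions or {})
        #: normalized guild -> ATP-yield share; None = unconstrained
        self.proteome_shares: dict[str, float] | None = (
            dict(proteome_shares) if proteome_shares else None
        )

    # -- construction -------------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> None:
        if met.met_id in self.metabolites:
            raise ValueError(f"duplicate metabolite {met.met_id!r}")
        self.metabolites[met.met_id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.rxn_id in self.reactions:
            raise ValueError(f"duplicate reaction {rxn.rxn_id!r}")
        for met in rxn.stoichiometry:
            if met not in self.metabolites:
                raise KeyError(f"{rxn.rxn_id}: unknown metabolite {met!r}")
        self.reactions[rxn.rxn_id] = rxn

    def copy(self) -> "CommunityModel":
        return deepcopy(self)

    # -- structure ----------------------------------------------------------

    @property
    def guilds(self) -> list[str]:
        """Guild compartments present, in canonical order."""
        present = {m.compartment for m in self.metabolites.values()}
        return [g for g in COMPARTMENTS if g != "e" and g in present]

    @property
    def atp_sinks(self) -> dict[str, str]:
        """Guild -> id of its ATP sink reaction (``ATPM_<guild>``)."""
        out = {}
        for g in self.guilds:
            rid = f"ATPM_{g}"
            if rid in self.reactions:
                out[g] = rid
        return out

    def default_objective(self) -> dict[str, float]:
        """Total community ATP yield: unit weight on every guild ATP sink."""
        sinks = self.atp_sinks
        if not sinks:
            raise ValueError("model has no ATP sink reactions (ATPM_<guild>)")
        return {rid: 1.0 for rid in sinks.values()}

    def stoichiometric_matrix(self):
        """Dense S (metabolites x reactions) with index lists."""
        import numpy as np

        met_ids = list(self.metabolites)
        rxn_ids = list(self.reactions)
        met_pos = {m: i for i, m in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(rxn_ids)))
        for j, rid in enumerate(rxn_ids):
            for met, coeff in self.reactions[rid].stoichiometry.items():
                S[met_pos[met], j] = coeff
        return S, met_ids, rxn_ids

    # -- validation ---------------------------------------------------------

    def check_mass_balance(self, tol: float = 1e-9) -> None:
        """Verify element and charge conservation of every non-exchange reaction.

        Raises ValueError naming the first unbalanced reaction and its element
        deltas.
        """
        for rxn in self.reactions.values():
            if rxn.guild == "exchange":
                continue
            deltas: dict[str, float] = {}
            charge = 0.0
            for met_id, coeff in rxn.stoichiometry.items():
                met = self.metabolites[met_id]
                for elem, n in met.elements.items():
                    deltas[elem] = deltas.get(elem, 0.0) + coeff * n
                charge += coeff * met.charge
            bad = {e: d for e, d in deltas.items() if abs(d) > tol}
            if abs(charge) > tol:
                bad["charge"] = charge
            if bad:
                raise ValueError(
                    f"reaction {rxn.rxn_id!r} is not balanced: "
                    + ", ".join(f"{e}: {d:+g}" for e, d in sorted(bad.items()))
                )

    def summary(self) -> dict:
        return {
            "name": self.name,
            "n_reactions": len(self.reactions),
            "n_metabolites": len(self.metabolites),
            "guilds": self.guilds,
            "proteome_shares": self.proteome_shares,
        }

    # -- scenario editing ----------------------------------------------------

    def drop_guild(self, guild: str) -> "CommunityModel":
        """Remove a guild's compartment, reactions and proteome share.

        Remaining shares are renormalized.  The returned model may be
        infeasible for the acetate-fed objective (e.g. after removing the sole
        acetate consumer); that is surfaced as a solver status, not here.
        """
        if guild not in self.guilds:
            raise KeyError(f"guild {guild!r} not in model (has {self.guilds})")
        out = self.copy()
        out.name = f"{self.name}-minus-{guild}"
        out.metabolites = {
            k: v for k, v in out.metabolites.items() if v.compartment != guild
        }
        out.reactions = {
            k: r
            for k, r in out.reactions.items()
            if r.guild != guild
            and all(m in out.metabolites for m in r.stoichiometry)
        }
        if out.proteome_shares:
            rest = {g: s for g, s in out.proteome_shares.items() if g != guild}
            total = sum(rest.values())
            if total <= 0:
                out.proteome_shares = None
            else:
                out.proteome_shares = {g: s / total for g, s in rest.items()}
        return out

    # -- serialization -------------------------------------------------------

    def to_tsvs(self, directory) -> None:
        """Write metabolites.tsv and reactions.tsv into ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        mets = pd.DataFrame(
            [
                {
                    "met_id": m.met_id,
                    "compartment": m.compartment,
                    "formula": m.formula,
                    "charge": m.charge,
                    "name": m.name,
                }
                for m in self.metabolites.values()
            ]
        )
        rxns = pd.DataFrame(
            [
                {
                    "rxn_id": r.rxn_id,
                    "guild": r.guild,
                    "equation": r.equation(),
                    "lb": r.lower_bound,
                    "ub": r.upper_bound,
                    "atp_coeff": r.atp_coefficient(r.guild)
                    if r.guild in COMPARTMENTS
                    else 0.0,
                    "name": r.name,
                }
                for r in self.reactions.values()
            ]
        )
        mets.to_csv(directory / "metabolites.tsv", sep="\t", index=False)
        rxns.to_csv(directory / "reactions.tsv", sep="\t", index=False)
        if self.proteome_shares:
            shares = pd.DataFrame(
                sorted(self.proteome_shares.items()), columns=["guild", "share"]
            )
            shares.to_csv(directory / "proteome_shares.tsv", sep="\t", index=False)

    @classmethod
    def from_tsvs(cls, directory, name: str | None = None) -> "CommunityModel":
        """Load a model from metabolites.tsv + reactions.tsv in ``directory``."""
        directory = Path(directory)
        mets = pd.read_csv(directory / "metabolites.tsv", sep="\t", comment="#")
        rxns = pd.read_csv(directory / "reactions.tsv", sep="\t", comment="#")
        model = cls(name=name or directory.name)
        for row in mets.itertuples(index=False):
            model.add_metabolite(
                Metabolite(
                    met_id=str(row.met_id),
                    compartment=str(row.compartment),
                    formula="" if pd.isna(row.formula) else str(row.formula),
                    charge=int(row.charge),
                    name="" if pd.isna(getattr(row, "name", "")) else str(row.name),
                )
            )
        for row in rxns.itertuples(index=False):
            stoich, _ = parse_equation(str(row.equation))
            model.add_reaction(
                Reaction(
                    rxn_id=str(row.rxn_id),
                    guild=str(row.guild),
                    stoichiometry=stoich,
                    lower_bound=float(row.lb),
                    upper_bound=float(row.ub),
                    name="" if pd.isna(getattr(row, "name", "")) else str(row.name),
                )
            )
        shares_path = directory / "proteome_shares.tsv"
        if shares_path.exists():
            shares = pd.read_csv(shares_path, sep="\t", comment="#")
            total = shares["share"].sum()
            model.proteome_shares = {
                str(r.guild): float(r.share) / total
                for r in shares.itertuples(index=False)
            }
        model.check_mass_balance()
        return model


#: names of models shipped with the package
PACKAGED_MODELS = ("community",)


def load_model(source) -> CommunityModel:
    """Load a model from a packaged fixture name or a directory of TSVs.

    ``load_model("community")`` returns the calibrated three-guild model;
    any other string/Path is treated as a directory containing
    ``metabolites.tsv`` and ``reactions.tsv``.
    """
    if isinstance(source, str) and source in PACKAGED_MODELS:
        root = importlib.resources.files("syntrophyflux") / "data" / source
        return CommunityModel.from_tsvs(root, name=source)
    return CommunityModel.from_tsvs(source)
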