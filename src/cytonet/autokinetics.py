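"""Kinetic-law injection and a minimal deterministic integrator.

Reactome models ship without kinetics; these routines attach uniform rate
laws so a network can at least be integrated for qualitative inspection:

* mass action:        v = k_f * prod_i [R_i]^s_i over the reactants
                      (empty product -> v = k_f, a constant source)
* Michaelis-Menten:   v = v_max * [S] / (k_m + [S]) with S the first listed
                      reactant; zero-reactant reactions are skipped.

Modifiers are ignored by both laws.  Units are dimensionless throughout.
The integrator is fixed-step classical RK4 on d[X]/dt = sum_r (s_out - s_in)
* v_r, which suffices as a sanity harness for the injected laws.
"""

from __future__ import annotations

import ast
import copy
import logging
import math

import pandas as pd

from .sbml_io import KineticLaw, PathwayModel, ReactionNode

logger = logging.getLogger(__name__)

MASS_ACTION = "mass_action"
MICHAELIS_MENTEN = "michaelis_menten"


class IntegrationError(ArithmeticError):
    """The trajectory left the finite domain; message reports the time point."""


class RateParams:
    """Uniform kinetic constants (all strictly positive, default 1.0).

    k_f   mass-action rate constant, 1/(time * concentration^(order-1))
    v_max Michaelis-Menten limiting rate, concentration/time
    k_m   Michaelis constant, concentration
    """

    def __init__(self, k_f: float = 1.0, v_max: float = 1.0, k_m: float = 1.0):
        if min(k_f, v_max, k_m) <= 0:
            raise ValueError("kinetic parameters must be strictly positive")
        self.k_f = k_f
        self.v_max = v_max
        self.k_m = k_m


def _params_for(reaction_id: str, params: RateParams,
                overrides: dict[str, RateParams] | None) -> RateParams:
    if overrides and reaction_id in overrides:
        return overrides[reaction_id]
    return params


def _mass_action_law(rxn: ReactionNode, p: RateParams) -> KineticLaw:
    factors = []
    for ref in rxn.reactants:
        exponent = ref.stoichiometry
        if exponent == int(exponent):
            exponent = int(exponent)
        factors.append(ref.species_id if exponent == 1
                       else f"{ref.species_id}**{exponent}")
    expression = " * ".join(["k_f", *factors])
    return KineticLaw(MASS_ACTION, expression, {"k_f": p.k_f})


def add_mass_action(model: PathwayModel, params: RateParams | None = None,
                    overwrite: bool = False,
                    overrides: dict[str, RateParams] | None = None) -> PathwayModel:
    """Attach a mass-action law to every reaction; returns a new model."""
    params = params or RateParams()
    out = copy.deepcopy(model)
    skipped = 0
    for rxn in out.reactions:
        if rxn.kinetic_law is not None and not overwrite:
            skipped += 1
            continue
        rxn.kinetic_law = _mass_action_law(rxn, _params_for(rxn.reaction_id,
                                                            params, overrides))
    if skipped:
        logger.warning("mass action: kept %d existing kinetic law(s); "
                       "pass overwrite=True to replace", skipped)
    return out


def add_michaelis_menten(model: PathwayModel, params: RateParams | None = None,
                         overwrite: bool = False,
                         overrides: dict[str, RateParams] | None = None
                         ) -> PathwayModel:
    """Attach a Michaelis-Menten law (first listed reactant as substrate).

    Reactions with no reactants are left without a law and reported through a
    logged warning; :func:`reactions_without_law` recovers the list.
    """
    params = params or RateParams()
    out = copy.deepcopy(model)
    skipped_existing = 0
    skipped_no_substrate: list[str] = []
    for rxn in out.reactions:
        if rxn.kinetic_law is not None and not overwrite:
            skipped_existing += 1
            continue
        if not rxn.reactants:
            skipped_no_substrate.append(rxn.reaction_id)
            continue
        p = _params_for(rxn.reaction_id, params, overrides)
        substrate = rxn.reactants[0].species_id
        rxn.kinetic_law = KineticLaw(
            MICHAELIS_MENTEN,
            f"v_max * {substrate} / (k_m + {substrate})",
            {"v_max": p.v_max, "k_m": p.k_m},
        )
    if skipped_existing:
        logger.warning("michaelis-menten: kept %d existing kinetic law(s)",
                       skipped_existing)
    if skipped_no_substrate:
        logger.warning("michaelis-menten: skipped %d zero-reactant reaction(s): %s",
                       len(skipped_no_substrate), ", ".join(skipped_no_substrate))
    return out


def reactions_without_law(model: PathwayModel) -> list[str]:
    return [r.reaction_id for r in model.reactions if r.kinetic_law is None]


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

_ALLOWED_AST = (
    ast.Expression, ast.BinOp, ast.UnaryOp, ast.Name, ast.Constant,
    ast.Add, ast.Sub, ast.Mult, ast.Div, ast.Pow, ast.USub, ast.Load,
)


def _compile_rate(law: KineticLaw, reaction_id: str):
    tree = ast.parse(law.expression, mode="eval")
    for node in ast.walk(tree):
        if not isinstance(node, _ALLOWED_AST):
            raise ValueError(
                f"reaction {reaction_id!r}: rate expression uses unsupported "
                f"construct {type(node).__name__}"
            )
    return compile(tree, f"<rate:{reaction_id}>", "eval")


def evaluate_rate(law: KineticLaw, concentrations: dict[str, float]) -> float:
    """Evaluate a rate law at the given species concentrations."""
    code = _compile_rate(law, "<adhoc>")
    env = dict(law.parameters)
    env.update(concentrations)
    return float(eval(code, {"__builtins__": {}}, env))


def simulate_mass_action(model: PathwayModel, t_end: float,
                         dt: float = 1e-3) -> pd.DataFrame:
    """Integrate the kinetically parameterized network with fixed-step RK4.

    Every reaction must carry a law; species without an initial amount start
    at 1.0.  Returns a DataFrame with a ``time`` column plus one column per
    species, deterministic for fixed inputs.
    """
    missing = reactions_without_law(model)
    if missing:
        raise ValueError(f"reactions lack kinetic laws: {', '.join(missing)}")
    if dt <= 0 or t_end < 0:
        raise ValueError("require dt > 0 and t_end >= 0")

    species_ids = list(model.species)
    index = {sid: i for i, sid in enumerate(species_ids)}
    compiled = []
    for rxn in model.reactions:
        net: dict[int, float] = {}
        for ref in rxn.reactants:
            net[index[ref.species_id]] = net.get(index[ref.species_id], 0.0) - ref.stoichiometry
        for ref in rxn.products:
            net[index[ref.species_id]] = net.get(index[ref.species_id], 0.0) + ref.stoichiometry
        compiled.append((
            _compile_rate(rxn.kinetic_law, rxn.reaction_id),
            dict(rxn.kinetic_law.parameters),
            net,
        ))

    def derivative(state: list[float]) -> list[float]:
        env = {sid: state[i] for sid, i in index.items()}
        deriv = [0.0] * len(state)
        for code, params, net in compiled:
            scope = dict(params)
            scope.update(env)
            rate = eval(code, {"__builtins__": {}}, scope)
            for i, coeff in net.items():
                deriv[i] += coeff * rate
        return deriv

    state = [
        model.species[sid].initial_amount if model.species[sid].initial_amount
        is not None else 1.0
        for sid in species_ids
    ]
    n_steps = int(round(t_end / dt))
    times = [0.0]
    rows = [list(state)]
    for step in range(n_steps):
        k1 = derivative(state)
        k2 = derivative([s + 0.5 * dt * k for s, k in zip(state, k1)])
        k3 = derivative([s + 0.5 * dt * k for s, k in zip(state, k2)])
        k4 = derivative([s + dt * k for s, k in zip(state, k3)])
        state = [
            s + dt / 6.0 * (a + 2 * b + 2 * c + d)
            for s, a, b, c, d in zip(state, k1, k2, k3, k4)
        ]
        t = (step + 1) * dt
        if not all(math.isfinite(x) for x in state):
            raise IntegrationError(f"non-finite state at t={t:.6g}")
        times.append(t)
        rows.append(list(state))

    frame = pd.DataFrame(rows, columns=species_ids)
    frame.insert(0, "time", times)
    return frame
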