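"""Behavioural rules of the motile cells.

LTin (initiator) cells perform an unbiased random walk; first contact with an
undifferentiated LTo triggers that cell's differentiation.  LTi (inducer)
cells walk with a chemokine-gradient bias that strengthens with local
concentration; their contacts with an already-differentiated LTo mature its
expression.  Near a differentiated LTo, both motile kinds may arrest
(adhesion); arrest is permanent — the model has no detachment — so arrested
cells are the material of the emergent aggregates.

These are the single-cell reference semantics.  The engine applies the same
rules to all cells of a step at once (synchronous LTo updates), which is
equivalent because an LTo's state never changes mid-step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

from .environment import Environment

LTIN = 0
LTI = 1


class CellState(Enum):
    MIGRATING = "migrating"
    ARRESTED = "arrested"


@dataclass
class MotileCell:
    kind: int  # LTIN or LTI
    position: np.ndarray  # (2,) um
    radius: float  # um
    state: CellState = CellState.MIGRATING
    entry_time: float = 0.0  # hours since E14.5


@dataclass(frozen=True)
class ContactEvent:
    """A motile cell overlapping an LTo this step."""

    lto_index: int
    cell_kind: int


def adhesion_arrest_probability(expression: float, d: float, r_adh: float) -> float:
    """Per-step arrest probability near a differentiated LTo.

    ``expression * max(0, 1 - d / r_adh)``: proportional to the adhesion-factor
    output of the LTo and decaying linearly with distance to zero at the
    adhesion radius.
    """
    if not 0.0 <= expression <= 1.0:
        raise ValueError(f"expression must be in [0, 1], got {expression}")
    if d < 0:
        raise ValueError("distance must be non-negative")
    if r_adh <= 0:
        raise ValueError("adhesion radius must be positive")
    return expression * max(0.0, 1.0 - d / r_adh)


def handle_contact(
    env: Environment,
    lto_index: int,
    cell_kind: int,
    *,
    l0: float,
    dl: float,
) -> None:
    """Apply one contact event to an LTo, in place.

    * LTin on an undifferentiated LTo: differentiation, expression starts
      at the base level ``l0``.
    * LTi on a differentiated LTo: one more inducer contact, expression
      increments by ``dl`` and saturates at 1.
    * LTi on an undifferentiated LTo, or LTin on a differentiated one:
      no effect — only initiator cells start the programme, and further
      initiator contacts add nothing.
    """
    diff = env.lto_differentiated[lto_index]
    if cell_kind == LTIN and not diff:
        env.lto_differentiated[lto_index] = True
        env.lto_expression[lto_index] = l0
    elif cell_kind == LTI and diff:
        env.lto_lti_contacts[lto_index] += 1
        env.lto_expression[lto_index] = min(
            1.0, env.lto_expression[lto_index] + dl
        )


def _contacts_and_arrest(
    cell: MotileCell,
    env: Environment,
    rng: np.random.Generator,
    r_adh: float,
) -> tuple[MotileCell, list[ContactEvent]]:
    """Collect overlap events at the cell's position, then test arrest."""
    events: list[ContactEvent] = []
    if env.n_lto == 0:
        return cell, events
    d = env.distance(cell.position, env.lto_xy)
    touching = np.nonzero(d <= cell.radius + env.lto_radius)[0]
    for i in touching:
        events.append(ContactEvent(lto_index=int(i), cell_kind=cell.kind))
    diff = np.nonzero(env.lto_differentiated)[0]
    if len(diff) > 0:
        nearest = diff[np.argmin(d[diff])]
        p = adhesion_arrest_probability(
            float(env.lto_expression[nearest]), float(d[nearest]), r_adh
        )
        if rng.random() < p:
            cell = replace(cell, state=CellState.ARRESTED)
    return cell, events


def step_ltin(
    cell: MotileCell,
    env: Environment,
    rng: np.random.Generator,
    *,
    speed: float,
    dt: float,
    r_adh: float,
) -> tuple[MotileCell, list[ContactEvent]]:
    """One time step of an LTin cell: unbiased random walk, then contact/arrest.

    ``speed`` in um/min, ``dt`` in minutes.  An arrested cell is inert and
    returned unchanged with no events.
    """
    if cell.kind != LTIN:
        raise ValueError("step_ltin requires an LTin cell")
    if cell.state is CellState.ARRESTED:
        return cell, []
    theta = rng.random() * 2.0 * math.pi
    step = speed * dt * np.array([math.cos(theta), math.sin(theta)])
    cell = replace(cell, position=env.wrap(cell.position + step))
    return _contacts_and_arrest(cell, env, rng, r_adh)


def step_lti(
    cell: MotileCell,
    env: Environment,
    rng: np.random.Generator,
    *,
    speed: float,
    dt: float,
    r_adh: float,
) -> tuple[MotileCell, list[ContactEvent]]:
    """One time step of an LTi cell: chemokine-biased walk, then contact/arrest.

    The step direction blends a uniform random unit vector ``u`` with the
    unit chemokine gradient ``g``: ``normalise((1 - b) u + b g)`` where the
    bias ``b = min(1, chemokine level at the cell)``.  In a flat field the
    walk is unbiased; in a saturated field the cell climbs the gradient
    deterministically.  If the blend cancels to (numerically) zero the random
    direction is used, keeping the step length exact.
    """
    if cell.kind != LTI:
        raise ValueError("step_lti requires an LTi cell")
    if cell.state is CellState.ARRESTED:
        return cell, []
    theta = rng.random() * 2.0 * math.pi
    u = np.array([math.cos(theta), math.sin(theta)])
    b = min(1.0, float(env.chemokine_level(cell.position)))
    direction = u
    if b > 0.0:
        grad = env.chemokine_gradient(cell.position)
        norm = float(np.linalg.norm(grad))
        ghat = grad / norm if norm > 1e-12 else np.zeros(2)
        blend = (1.0 - b) * u + b * ghat
        bnorm = float(np.linalg.norm(blend))
        direction = blend / bnorm if bnorm > 1e-9 else u
    step = speed * dt * direction
    cell = replace(cell, position=env.wrap(cell.position + step))
    return _contacts_and_arrest(cell, env, rng, r_adh)
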