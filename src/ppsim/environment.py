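"""The spatial domain: a flattened strip of embryonic gut surface.

The gut tube is modelled as a 2-D rectangle, periodic along the long (gut)
axis — the tube seam — and reflective on the short (circumferential) axis.
Stationary LTo stromal cells sit on the epithelium; once differentiated they
express adhesion factors and, past an expression threshold, a chemoattractant
sensed by LTi cells.  The chemokine field is an instantaneous radial kernel
(linear decay to zero at ``r_chem``) summed over qualifying sources, rather
than a diffusion PDE: given the LTo states it is deterministic and cheap to
recompute every step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SimConfig


class PlacementError(RuntimeError):
    """Raised when non-overlapping LTo placement fails.

    Attributes ``attempts`` (rejection samples used) and ``placed`` (cells
    successfully placed before giving up).
    """

    def __init__(self, message: str, attempts: int, placed: int):
        super().__init__(message)
        self.attempts = attempts
        self.placed = placed


@dataclass
class LToCell:
    """View of a single stromal (organiser) cell."""

    position: np.ndarray
    radius: float
    differentiated: bool
    expression: float
    lti_contacts: int


@dataclass
class Environment:
    """The bounded 2-D domain with its stromal cells and chemokine field.

    LTo state is stored as flat arrays (one entry per cell) because the
    simulation engine updates all cells per step; :attr:`lto_cells` exposes
    the same state as objects for inspection.
    """

    width: float
    height: float
    lto_xy: np.ndarray  # (n, 2) float
    lto_radius: float
    lto_differentiated: np.ndarray  # (n,) bool
    lto_expression: np.ndarray  # (n,) float in [0, 1]
    lto_lti_contacts: np.ndarray  # (n,) int
    r_chem: float = 150.0
    chemokine_threshold: float = 0.3
    fd_step: float = 1.0
    motile_cells: list = field(default_factory=list)

    @property
    def n_lto(self) -> int:
        return len(self.lto_xy)

    @property
    def lto_cells(self) -> list[LToCell]:
        return [
            LToCell(
                position=self.lto_xy[i].copy(),
                radius=self.lto_radius,
                differentiated=bool(self.lto_differentiated[i]),
                expression=float(self.lto_expression[i]),
                lti_contacts=int(self.lto_lti_contacts[i]),
            )
            for i in range(self.n_lto)
        ]

    # -- geometry -----------------------------------------------------------

    def wrap(self, p: np.ndarray) -> np.ndarray:
        """Map arbitrary coordinates into the domain.

        x is wrapped modulo the width (periodic seam); y is reflected at 0
        and ``height`` (mirror boundary).  Accepts a single point ``(2,)`` or
        an array ``(m, 2)``.
        """
        p = np.asarray(p, dtype=float)
        out = p.copy()
        out[..., 0] = np.mod(out[..., 0], self.width)
        # reflect y with a triangle wave of period 2*height
        y = np.mod(out[..., 1], 2.0 * self.height)
        out[..., 1] = np.where(y > self.height, 2.0 * self.height - y, y)
        return out

    def delta(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Shortest displacement b -> a under the periodic/reflective topology.

        Both inputs must already lie inside the domain.  The y component is a
        plain difference (the mirror boundary does not shorten paths between
        interior points); the x component is the minimal periodic image.
        """
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        d = a - b
        dx = d[..., 0]
        dx = dx - self.width * np.round(dx / self.width)
        out = np.stack([dx, d[..., 1]], axis=-1)
        return out

    def distance(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        # component form (no intermediate (..., 2) arrays); valid for points
        # already inside the domain, where |dx| < width
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        dx = np.abs(a[..., 0] - b[..., 0])
        dx = np.minimum(dx, self.width - dx)
        dy = a[..., 1] - b[..., 1]
        return np.sqrt(dx * dx + dy * dy)

    # -- chemokine field ----------------------------------------------------

    def _source_mask(self) -> np.ndarray:
        return self.lto_differentiated & (
            self.lto_expression >= self.chemokine_threshold
        )

    def chemokine_level(self, p: np.ndarray) -> np.ndarray | float:
        """Total chemoattractant concentration at point(s) ``p``.

        Sum over differentiated LTo with expression above the threshold of
        ``expression * max(0, 1 - d / r_chem)`` with ``d`` the wrapped
        distance to the source centre.
        """
        p = np.asarray(p, dtype=float)
        single = p.ndim == 1
        pts = np.atleast_2d(p)
        mask = self._source_mask()
        if not mask.any():
            out = np.zeros(len(pts))
            return float(out[0]) if single else out
        src = self.lto_xy[mask]
        expr = self.lto_expression[mask]
        dx = np.abs(pts[:, 0, None] - src[None, :, 0])
        dx = np.minimum(dx, self.width - dx)
        dy = pts[:, 1, None] - src[None, :, 1]
        d = np.sqrt(dx * dx + dy * dy)
        contrib = expr[None, :] * np.clip(1.0 - d / self.r_chem, 0.0, None)
        out = contrib.sum(axis=1)
        return float(out[0]) if single else out

    def chemokine_gradient(self, p: np.ndarray) -> np.ndarray:
        """Central finite-difference gradient of the chemokine field.

        Step ``fd_step`` (config).  Evaluation points outside the domain are
        wrapped first, so the gradient respects the domain topology.
        """
        p = np.asarray(p, dtype=float)
        single = p.ndim == 1
        pts = np.atleast_2d(p)
        h = self.fd_step
        offsets = np.array(
            [[h, 0.0], [-h, 0.0], [0.0, h], [0.0, -h]]
        )  # (4, 2)
        probe = self.wrap(pts[:, None, :] + offsets[None, :, :])  # (m, 4, 2)
        levels = self.chemokine_level(probe.reshape(-1, 2)).reshape(len(pts), 4)
        gx = (levels[:, 0] - levels[:, 1]) / (2.0 * h)
        gy = (levels[:, 2] - levels[:, 3]) / (2.0 * h)
        grad = np.stack([gx, gy], axis=-1)
        return grad[0] if single else grad


def create_environment(
    config: SimConfig, rng: np.random.Generator
) -> Environment:
    """Place the configured number of LTo cells uniformly without overlap.

    Rejection sampling; candidate centres that come within two LTo radii
    (wrapped distance) of an accepted centre are rejected.  After
    ``max_attempts`` total draws a :class:`PlacementError` is raised
    reporting the attempt count — this is how an infeasible packing
    (requested area beyond what non-overlapping discs can fill) surfaces.
    """
    env_cfg = config.environment
    n = env_cfg.lto_count
    radius = env_cfg.lto_radius_um
    width, height = env_cfg.width_um, env_cfg.height_um

    env = Environment(
        width=width,
        height=height,
        lto_xy=np.empty((n, 2)),
        lto_radius=radius,
        lto_differentiated=np.zeros(n, dtype=bool),
        lto_expression=np.zeros(n),
        lto_lti_contacts=np.zeros(n, dtype=np.int64),
        r_chem=config.chemokine.r_chem_um,
        chemokine_threshold=config.chemokine.threshold,
        fd_step=config.chemokine.fd_step_um,
    )
    if n == 0:
        return env

    max_attempts = 1000 + 200 * n
    placed = 0
    attempts = 0
    min_sep = 2.0 * radius
    while placed < n:
        if attempts >= max_attempts:
            raise PlacementError(
                f"could not place {n} non-overlapping LTo cells of radius "
                f"{radius} um in a {width} x {height} um domain "
                f"({placed} placed after {attempts} attempts)",
                attempts=attempts,
                placed=placed,
            )
        candidate = rng.random(2) * (width, height)
        attempts += 1
        if placed > 0:
            d = env.distance(candidate, env.lto_xy[:placed])
            if np.any(d <= min_sep):
                continue
        env.lto_xy[placed] = candidate
        placed += 1
    return env
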