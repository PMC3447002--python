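"""Probabilistic chemotaxis on the lattice.

A cell experiencing a chemotactic attraction vector C biases its jump
probabilities toward C while retaining its random-walk character. The
chemotaxis-only distribution weights each Moore jump by
``cos²(theta) / |u|`` (zero for jumps directed against the attraction) and
is mixed with the base-walk distribution with weight
``alpha = min(1, |C|)``; at ``|C| >= 1`` motion is fully chemotactic.

Attraction from discrete exit portals is approximated by a bounded
inverse-square distance law ``g(r) = min(1, K_E / r²)`` per portal, where
``K_E`` is the cell's chemotactic susceptibility, with multiple portals
(or any other sources) combined by vector addition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lattice import (
    JUMP_LENGTHS_2D,
    JUMP_LENGTHS_3D,
    MOORE_2D,
    MOORE_3D,
    UNIT_2D,
    UNIT_3D,
)
from .motility import DEFAULT_MOTILITY, MotilityParams, simulate_free_walk

__all__ = [
    "ChemoAttraction",
    "chemo_only_probabilities",
    "portal_attraction",
    "combined_jump_probabilities",
    "chemotaxis_index",
    "ci_sweep",
    "INFLUENCE_CUTOFF",
]

#: Per-portal influence below which the attraction is dropped (< 1% bias).
INFLUENCE_CUTOFF = 0.01


@dataclass(frozen=True)
class ChemoAttraction:
    """Net chemotactic attraction acting on one cell."""

    C: np.ndarray

    @property
    def strength(self) -> float:
        return float(np.linalg.norm(self.C))

    @property
    def direction(self) -> np.ndarray:
        s = self.strength
        if s == 0:
            raise ValueError("direction undefined for zero attraction")
        return self.C / s

    @property
    def alpha(self) -> float:
        """Fractional chemotactic influence, min(1, |C|)."""
        return min(1.0, self.strength)


def chemo_only_probabilities(v, dim: int = 3) -> np.ndarray:
    """Chemotaxis-only jump distribution toward unit vector ``v``.

    Returns a length ``N_J + 1`` vector (index 0, the no-jump slot, is 0;
    ``N_J`` = 26 in 3D, 8 in 2D) with
    ``p_c(i) ∝ cos²(theta_i) / |u(i)|`` for ``cos(theta_i) >= 0`` and 0 for
    jumps directed counter to the attraction.
    """
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("attraction direction undefined: |v| = 0")
    v = v / norm
    if dim == 3:
        unit, lengths = UNIT_3D, JUMP_LENGTHS_3D
    elif dim == 2:
        unit, lengths = UNIT_2D, JUMP_LENGTHS_2D
    else:
        raise ValueError(f"dim must be 2 or 3, got {dim}")
    cos = unit @ v
    w = np.where(cos >= 0, cos**2 / lengths, 0.0)
    p = np.zeros(w.size + 1)
    p[1:] = w / w.sum()
    return p


def portal_attraction(
    pos,
    portal_coords: np.ndarray,
    k_e: float,
    cutoff: float = INFLUENCE_CUTOFF,
) -> ChemoAttraction:
    """Net attraction toward exit portals, bounded inverse-square per portal.

    Each portal at distance r contributes ``min(1, K_E / r²)`` along the
    unit offset toward it; portals with influence below ``cutoff`` are
    ignored, and a portal exactly at the cell's site contributes nothing
    (its direction is undefined).
    """
    if k_e < 0:
        raise ValueError(f"K_E must be >= 0, got {k_e}")
    pos = np.asarray(pos, dtype=float)
    portals = np.atleast_2d(np.asarray(portal_coords, dtype=float))
    if k_e == 0 or portals.size == 0:
        return ChemoAttraction(np.zeros(pos.size))
    offsets = portals - pos[None, :]
    r = np.linalg.norm(offsets, axis=1)
    g = np.zeros_like(r)
    nz = r > 0
    g[nz] = np.minimum(1.0, k_e / r[nz] ** 2)
    g[g < cutoff] = 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        units = np.where(nz[:, None], offsets / np.where(nz, r, 1.0)[:, None], 0.0)
    return ChemoAttraction((g[:, None] * units).sum(axis=0))


def combined_jump_probabilities(
    p: np.ndarray,
    p_c: np.ndarray,
    alpha: float,
    blocked=(),
) -> np.ndarray:
    """Mix base-walk and chemotaxis-only distributions, respecting crowding.

    For unblocked jump directions
    ``p*(i) = (1 - alpha) p(i) + alpha p_c(i)``; probability mass of
    blocked directions is transferred to the no-jump slot (a blocked
    attempt is a failed move), so the result always sums to 1.
    """
    p = np.asarray(p, dtype=float)
    p_c = np.asarray(p_c, dtype=float)
    if p.shape != p_c.shape:
        raise ValueError("p and p_c must have identical shapes")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if abs(p.sum() - 1.0) > 1e-9 or abs(p_c[1:].sum() - 1.0) > 1e-9 or p_c[0] != 0:
        raise ValueError("p must sum to 1 and p_c must be a jump-only distribution")
    blocked = np.asarray(sorted(set(int(b) for b in blocked)), dtype=np.int64)
    if blocked.size and (blocked.min() < 1 or blocked.max() >= p.size):
        raise ValueError("blocked indices must be jump indices >= 1")
    star = (1.0 - alpha) * p + alpha * p_c
    star[0] = (1.0 - alpha) * p[0]
    if blocked.size:
        star[0] += star[blocked].sum()
        star[blocked] = 0.0
    return star


def chemotaxis_index(
    strength: float,
    n_steps: int = 10,
    n_traj: int = 1000,
    mode: str = "directional",
    motility: MotilityParams = DEFAULT_MOTILITY,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Chemotaxis index of free-space trajectories under uniform attraction.

    A spatially invariant attraction of the given strength acts along +x.
    The standard (McCutcheon) index is straight-line distance over path
    length; the directional variant projects the displacement onto the
    attraction axis so that the index vanishes as the strength goes to 0.
    No-jump steps contribute nothing to the path length; the rare
    trajectories that never move (no defined index) are excluded.

    Returns (mean CI, standard deviation over trajectories).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if mode not in ("standard", "directional"):
        raise ValueError(f"mode must be 'standard' or 'directional', got {mode!r}")
    if rng is None:
        rng = np.random.default_rng(0)
    attraction = np.array([float(strength), 0.0, 0.0])
    disp, jump_len = simulate_free_walk(
        motility, n_traj, n_steps, rng,
        attraction=attraction if strength > 0 else None,
    )
    path = jump_len.sum(axis=1)
    net = disp.sum(axis=1)
    ok = path > 0
    if mode == "standard":
        ci = np.linalg.norm(net[ok], axis=1) / path[ok]
    else:
        ci = net[ok, 0] / path[ok]
    return float(ci.mean()), float(ci.std(ddof=1))


def ci_sweep(
    strengths,
    n_steps: int = 10,
    n_traj: int = 1000,
    mode: str = "directional",
    motility: MotilityParams = DEFAULT_MOTILITY,
    rng: np.random.Generator | None = None,
    path=None,
) -> pd.DataFrame:
    """Chemotaxis index across attraction strengths; optional text export."""
    if rng is None:
        rng = np.random.default_rng(0)
    rows = []
    for s in strengths:
        ci, sd = chemotaxis_index(s, n_steps, n_traj, mode, motility, rng)
        rows.append({"strength": s, "mode": mode, "n_steps": n_steps,
                     "ci": ci, "sd": sd})
    frame = pd.DataFrame(rows)
    if path is not None:
        frame.to_csv(path, sep="\t", index=False)
    return frame
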