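"""Persistent random walk of T cells on the lattice.

Cells move in 15 s steps. At each step a cell stays put with probability
``p0`` or jumps to one of its 26 Moore neighbours with probability
proportional to ``exp(kappa * cos(phi)) / |u|``, where ``phi`` is the angle
between the jump vector ``u`` and the cell's persistence direction. The
persistence direction is a slowly relaxing *heading*: after an executed
jump it switches to the jump direction only with probability
``p_reorient``. This separates short-window straightness (which sets the
apparent chemotaxis index of unbiased trajectories) from long-time
diffusion (the motility coefficient), both of which have been measured by
intravital microscopy: mean speed 8-16 µm/min, motility coefficient
50-100 µm²/min.

Default parameters are calibrated (see :func:`calibrate_motility`) to a
speed of 15 µm/min and a motility coefficient of 55 µm²/min on the 6.3 µm
lattice.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .lattice import (
    DEFAULT_GRID_SPACING,
    DT_MIN,
    JUMP_LENGTHS_3D,
    MOORE_3D,
    UNIT_3D,
)

__all__ = [
    "MotilityParams",
    "DEFAULT_MOTILITY",
    "base_jump_probabilities",
    "base_probability_table",
    "stationary_mean_jump_length",
    "simulate_free_walk",
    "measure_motility",
    "calibrate_motility",
    "export_trajectories",
    "CalibrationError",
]


@dataclass(frozen=True)
class MotilityParams:
    """Parameters of the persistent random walk.

    Attributes
    ----------
    p0:
        Probability of no jump in one 15 s step, in [0, 1).
    kappa:
        Directional-persistence weight (>= 0); 0 gives an isotropic walk.
    p_reorient:
        Probability that an executed jump resets the heading.
    dt_min, grid_spacing:
        Time step (minutes) and lattice spacing (µm).
    target_speed, target_cm:
        The calibration targets these parameters were derived from,
        µm/min and µm²/min.
    """

    p0: float
    kappa: float
    p_reorient: float = 0.2
    dt_min: float = DT_MIN
    grid_spacing: float = DEFAULT_GRID_SPACING
    target_speed: float = 15.0
    target_cm: float = 55.0

    def __post_init__(self):
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError(f"p0 must be in [0, 1], got {self.p0}")
        if self.kappa < 0:
            raise ValueError(f"kappa must be >= 0, got {self.kappa}")
        if not 0.0 < self.p_reorient <= 1.0:
            raise ValueError(f"p_reorient must be in (0, 1], got {self.p_reorient}")


def base_jump_probabilities(prev_dir, params: MotilityParams) -> np.ndarray:
    """Jump distribution of the base walk given a persistence direction.

    Returns a probability vector of length 27 — index 0 is "no jump",
    indices 1..26 correspond to ``MOORE_3D`` — with ``p[0] = p0`` and
    ``p[i] ∝ (1 - p0) * exp(kappa * cos(phi_i)) / |u(i)|``. With
    ``prev_dir=None`` the walk is isotropic (kappa treated as 0).
    """
    p = np.empty(27)
    p[0] = params.p0
    if prev_dir is None:
        w = 1.0 / JUMP_LENGTHS_3D
    else:
        d = np.asarray(prev_dir, dtype=float)
        norm = np.linalg.norm(d)
        if norm == 0:
            raise ValueError("prev_dir must be a nonzero vector or None")
        cos = UNIT_3D @ (d / norm)
        w = np.exp(params.kappa * cos) / JUMP_LENGTHS_3D
    p[1:] = (1.0 - params.p0) * w / w.sum()
    return p


def base_probability_table(params: MotilityParams) -> np.ndarray:
    """(27, 27) table of jump distributions, one row per heading state.

    Row 0 is the isotropic (no-heading) distribution; row s (1..26) is the
    distribution for heading ``MOORE_3D[s-1]``.
    """
    tab = np.empty((27, 27))
    tab[0] = base_jump_probabilities(None, params)
    for s in range(26):
        tab[s + 1] = base_jump_probabilities(MOORE_3D[s], params)
    return tab


def stationary_mean_jump_length(kappa: float) -> float:
    """Mean executed-jump length (lattice units) at heading stationarity.

    The heading follows a Markov chain over the 26 directions whose
    transition matrix is the conditional jump distribution; its stationary
    distribution weights the per-heading conditional mean jump length.
    """
    params = MotilityParams(p0=0.0, kappa=kappa)
    tab = base_probability_table(params)
    P = tab[1:, 1:]
    P /= P.sum(axis=1, keepdims=True)
    evals, evecs = np.linalg.eig(P.T)
    pi = np.real(evecs[:, np.argmax(np.real(evals))])
    pi = np.abs(pi)
    pi /= pi.sum()
    return float(pi @ (P @ JUMP_LENGTHS_3D))


def simulate_free_walk(
    params: MotilityParams,
    n_traj: int,
    n_steps: int,
    rng: np.random.Generator,
    attraction: np.ndarray | None = None,
):
    """Simulate unconstrained (crowding-free) walks; vectorized.

    Parameters
    ----------
    attraction:
        Optional spatially uniform chemotactic attraction 3-vector C. With
        probability ``alpha = min(1, |C|)`` a step is drawn from the
        chemotaxis-only distribution toward C instead of the base walk.

    Returns
    -------
    disp : (n_traj, n_steps, 3) per-step displacement vectors (lattice units)
    jump_len : (n_traj, n_steps) per-step jump lengths (0 for no-jump steps)
    """
    # local import: chemotaxis depends on this module's parameter types
    from .chemotaxis import chemo_only_probabilities

    cum = base_probability_table(params).cumsum(axis=1)
    alpha = 0.0
    cum_c = None
    if attraction is not None:
        c = np.asarray(attraction, dtype=float)
        strength = np.linalg.norm(c)
        alpha = min(1.0, strength)
        if alpha > 0:
            cum_c = chemo_only_probabilities(c / strength, dim=3)[1:].cumsum()

    state = np.zeros(n_traj, dtype=np.int64)
    disp = np.zeros((n_traj, n_steps, 3))
    jump_len = np.zeros((n_traj, n_steps))
    for t in range(n_steps):
        idx = np.empty(n_traj, dtype=np.int64)
        r_pick = rng.random(n_traj)
        if alpha > 0:
            use_c = rng.random(n_traj) < alpha
            idx[use_c] = np.searchsorted(cum_c, r_pick[use_c]) + 1
            base = ~use_c
        else:
            base = np.ones(n_traj, dtype=bool)
        rows = cum[state[base]]
        idx[base] = (rows < r_pick[base, None]).sum(axis=1)
        moved = idx > 0
        disp[moved, t] = MOORE_3D[idx[moved] - 1]
        jump_len[moved, t] = JUMP_LENGTHS_3D[idx[moved] - 1]
        reorient = moved & (rng.random(n_traj) < params.p_reorient)
        state[reorient] = idx[reorient]
    return disp, jump_len


class InsufficientDataError(ValueError):
    """Trajectories too few or too short for a motility estimate."""


class CalibrationError(RuntimeError):
    """Motility calibration could not reach the requested targets."""


def measure_motility(
    positions: np.ndarray,
    grid_spacing: float = DEFAULT_GRID_SPACING,
    dt_min: float = DT_MIN,
    min_traj: int = 100,
    min_duration_min: float = 60.0,
) -> tuple[float, float]:
    """Mean speed (µm/min) and motility coefficient Cm (µm²/min).

    ``positions`` is an (n_traj, n_steps + 1, 3) array of lattice
    coordinates sampled every ``dt_min``. Speed is total path length over
    total time; Cm is the asymptotic slope of the mean squared displacement
    versus lag, fitted over the tail half of the lag range and divided by 6
    (three dimensions).
    """
    positions = np.asarray(positions, dtype=float)
    n_traj, n_pts = positions.shape[:2]
    n_steps = n_pts - 1
    if n_traj < min_traj or n_steps * dt_min < min_duration_min:
        raise InsufficientDataError(
            f"need >= {min_traj} trajectories of >= {min_duration_min} min; "
            f"got {n_traj} x {n_steps * dt_min:.0f} min"
        )
    steps = np.diff(positions, axis=1)
    path = np.linalg.norm(steps, axis=2).sum()
    speed = path / (n_traj * n_steps * dt_min) * grid_spacing

    rel = positions - positions[:, :1, :]
    msd = np.einsum("ijk,ijk->ij", rel, rel).mean(axis=0)[1:]  # lag 1..n
    lags = np.arange(1, n_steps + 1)
    tail = slice(n_steps // 2, n_steps)
    A = np.vstack([lags[tail], np.ones(lags[tail].size)]).T
    slope = np.linalg.lstsq(A, msd[tail], rcond=None)[0][0]
    cm = slope * grid_spacing**2 / dt_min / 6.0
    return float(speed), float(cm)


def _positions_from_disp(disp: np.ndarray) -> np.ndarray:
    n_traj = disp.shape[0]
    return np.concatenate(
        [np.zeros((n_traj, 1, 3)), disp.cumsum(axis=1)], axis=1
    )


def calibrate_motility(
    target_speed: float,
    target_cm: float,
    grid_spacing: float = DEFAULT_GRID_SPACING,
    rng: np.random.Generator | None = None,
    p_reorient: float = 0.2,
    n_traj: int = 1000,
    n_steps: int = 480,
    kappa_bracket: tuple[float, float] = (0.0, 4.0),
    tol_cm: float = 0.02,
) -> MotilityParams:
    """Find (p0, kappa) reproducing the target speed and Cm.

    ``p0`` follows from the speed target in closed form (the mean executed
    jump length at heading stationarity depends only on kappa); kappa is
    then bisected on the simulated motility coefficient, which is monotone
    increasing in kappa at fixed speed and ``p_reorient``.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if target_speed == 0:
        return MotilityParams(
            p0=1.0, kappa=0.0, p_reorient=p_reorient,
            grid_spacing=grid_spacing, target_speed=0.0, target_cm=target_cm,
        )

    def p0_for(kappa: float) -> float:
        ebar = stationary_mean_jump_length(kappa)
        p0 = 1.0 - target_speed * DT_MIN / grid_spacing / ebar
        if not 0.0 <= p0 < 1.0:
            raise CalibrationError(
                f"target speed {target_speed} µm/min unreachable: the lattice "
                f"ballistic limit is {ebar * grid_spacing / DT_MIN:.1f} µm/min"
            )
        return p0

    # ballistic bound on Cm over the measurement window
    t_total = n_steps * DT_MIN
    if target_cm > target_speed**2 * t_total / 6.0:
        raise CalibrationError(
            f"target Cm {target_cm} exceeds the ballistic bound "
            f"{target_speed ** 2 * t_total / 6.0:.0f} µm²/min for this window"
        )

    def measured_cm(kappa: float, seed_rng) -> float:
        params = MotilityParams(
            p0=p0_for(kappa), kappa=kappa, p_reorient=p_reorient,
            grid_spacing=grid_spacing,
            target_speed=target_speed, target_cm=target_cm,
        )
        disp, _ = simulate_free_walk(params, n_traj, n_steps, seed_rng)
        _, cm = measure_motility(_positions_from_disp(disp), grid_spacing)
        return cm

    lo, hi = kappa_bracket
    seeds = rng.integers(0, 2**31, size=64)
    cm_lo = measured_cm(lo, np.random.default_rng(seeds[0]))
    cm_hi = measured_cm(hi, np.random.default_rng(seeds[1]))
    if not cm_lo <= target_cm <= cm_hi:
        raise CalibrationError(
            f"target Cm {target_cm} outside achievable range "
            f"[{cm_lo:.0f}, {cm_hi:.0f}] µm²/min at speed {target_speed}, "
            f"p_reorient {p_reorient}"
        )
    k = 2
    while hi - lo > 1e-3 and k < 60:
        mid = 0.5 * (lo + hi)
        cm_mid = measured_cm(mid, np.random.default_rng(seeds[k]))
        k += 1
        if abs(cm_mid - target_cm) / target_cm < tol_cm:
            lo = hi = mid
            break
        if cm_mid < target_cm:
            lo = mid
        else:
            hi = mid
    kappa = 0.5 * (lo + hi)
    return MotilityParams(
        p0=p0_for(kappa), kappa=kappa, p_reorient=p_reorient,
        grid_spacing=grid_spacing,
        target_speed=target_speed, target_cm=target_cm,
    )


#: Calibrated defaults: speed 15 µm/min, Cm 55 µm²/min on the 6.3 µm lattice.
#: Regenerate with ``calibrate_motility(15.0, 55.0)`` (see scripts/recalibrate.py).
DEFAULT_MOTILITY = MotilityParams(p0=0.5626, kappa=0.875, p_reorient=0.2)


def export_trajectories(
    disp: np.ndarray, path, dt_min: float = DT_MIN
) -> pd.DataFrame:
    """Write trajectories as delimited text (cell_id, t_min, x, y, z)."""
    pos = _positions_from_disp(np.asarray(disp, dtype=float))
    n_traj, n_pts = pos.shape[:2]
    frame = pd.DataFrame(
        {
            "cell_id": np.repeat(np.arange(n_traj), n_pts),
            "t_min": np.tile(np.arange(n_pts) * dt_min, n_traj),
            "x": pos[:, :, 0].ravel(),
            "y": pos[:, :, 1].ravel(),
            "z": pos[:, :, 2].ravel(),
        }
    )
    if path is not None:
        frame.to_csv(path, sep="\t", index=False)
    return frame
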