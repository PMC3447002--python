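"""Cell ingress, discrete exit portals, and egress calibration.

T cells enter at random sites within a sphere of radius 0.7 R (the HEV
region) and leave through discrete exit portals placed near the blob
boundary, excluding a cap (x/R > 0.6) representing the interface with a
B cell follicle. A cell anywhere in the 27-site Moore neighbourhood of a
portal departs with probability P_E per 15 s step (fixed at 0.02).

The number of portals needed to sustain a given residence time follows an
empirically calibrated, nearly linear power law in the population size,
scaled inversely with P_E and reduced by a factor beta(K_E) when cells are
chemotactically attracted to the portals:

    N_E = round( max(beta(K_E), 0.5) * (0.02 / P_E) * a * N**b / T_res )

``calibrate_exit_constants`` and ``calibrate_beta`` regenerate the
constants by bisecting portal counts against steady-state runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .lattice import DT_MIN, LatticeBlob

logger = logging.getLogger(__name__)

__all__ = [
    "TraffickingParams",
    "PortalSet",
    "TransitLog",
    "beta_reduction",
    "required_exit_count",
    "is_exit_candidate",
    "exit_candidate_flat",
    "place_portals",
    "update_portals",
    "ingress_step",
    "egress_step",
    "calibrate_exit_constants",
    "calibrate_beta",
    "CalibrationError",
]

#: Reference egress probability at which the exit power law was calibrated.
REFERENCE_P_E = 0.02

# Steady-state exit power law N_E * T_res = a * N**b (T_res in minutes),
# calibrated at P_E = 0.02, T_res = 12 h over N = 2k-20k
# (regenerate with scripts/recalibrate.py).
CALIBRATED_POWER_A = 0.5655
CALIBRATED_POWER_B = 0.9809


@dataclass(frozen=True)
class TraffickingParams:
    """Trafficking parameters (times in minutes, distances in lattice units)."""

    p_e: float = 0.02                 # egress probability per 15 s step
    t_res: float = 720.0              # residence time, min
    entry_fraction: float = 0.7       # entry-sphere radius / R
    cap_threshold: float = 0.6        # x/R above which no portals
    power_a: float = CALIBRATED_POWER_A
    power_b: float = CALIBRATED_POWER_B
    beta_coeffs: tuple = (0.0231, -0.2159, 0.9997)
    beta_floor: float = 0.5
    min_separation: float = 4.0       # lattice units between portals

    def __post_init__(self):
        if not 0.0 < self.p_e <= 1.0:
            raise ValueError(f"p_e must be in (0, 1], got {self.p_e}")
        if not 0.0 < self.entry_fraction < 1.0:
            raise ValueError(f"entry_fraction must be in (0, 1), got {self.entry_fraction}")
        if self.t_res <= 0:
            raise ValueError("t_res must be positive")


class CalibrationError(RuntimeError):
    """A steady-state calibration failed to converge."""


def beta_reduction(k_e: float, coeffs=(0.0231, -0.2159, 0.9997), floor: float = 0.5) -> float:
    """Exit-count reduction factor beta(K_E), clamped below at 0.5.

    Quadratic fit from steady-state recalibration with all cells
    chemotactic; beyond K_E of about 4 the portal neighbourhoods are fully
    double-occupied and the factor saturates at the floor. The quadratic is
    evaluated at most up to its vertex so the saturation persists for
    arbitrarily large susceptibility.
    """
    c2, c1, c0 = coeffs
    if c2 > 0:
        k_e = min(k_e, -c1 / (2.0 * c2))
    return max(float(c2 * k_e**2 + c1 * k_e + c0), floor)


def required_exit_count(
    n: int,
    t_res: float | None = None,
    p_e: float | None = None,
    k_e: float = 0.0,
    params: TraffickingParams = TraffickingParams(),
) -> int:
    """Number of exit portals maintaining steady state for N cells."""
    if n < 1:
        raise ValueError("n must be >= 1")
    t_res = params.t_res if t_res is None else t_res
    p_e = params.p_e if p_e is None else p_e
    if not np.isfinite(params.power_a) or not np.isfinite(params.power_b):
        raise CalibrationError(
            "exit power-law constants missing; run calibrate_exit_constants"
        )
    beta = beta_reduction(k_e, params.beta_coeffs, params.beta_floor)
    n_e = beta * (REFERENCE_P_E / p_e) * params.power_a * float(n) ** params.power_b / t_res
    return int(round(n_e))


def mean_field_exit_count(n: int, t_res: float, p_e: float) -> float:
    """First-order estimate: egress flux = N_E * 27 sites * 1 cell * P_E per step."""
    return n * DT_MIN / (t_res * 27.0 * p_e)


# ----------------------------------------------------------------------
# exit-candidate geometry
# ----------------------------------------------------------------------
def _neighbour_offsets(blob: LatticeBlob, reach: int) -> np.ndarray:
    L = blob.L
    r = np.arange(-reach, reach + 1)
    dx, dy, dz = np.meshgrid(r, r, r, indexing="ij")
    return (dx.ravel() * L * L + dy.ravel() * L + dz.ravel()).astype(np.int64)


def is_exit_candidate(site, blob: LatticeBlob, cap_threshold: float = 0.6) -> bool:
    """True iff ``site`` qualifies as an exit-portal location.

    All 27 Moore sites must be inside the blob, at least one of them must
    itself have a neighbour outside (jointly: the 3³ block is inside but
    the 5³ block is not), and the site must lie outside the follicular cap
    (x / R <= cap_threshold).
    """
    site = np.asarray(site, dtype=np.int64)
    flat = blob.flat_index(site)
    if blob.state[flat] != 1:
        return False
    if site[0] > cap_threshold * blob.radius:
        return False
    inner = blob.state[flat + _neighbour_offsets(blob, 1)]
    if not np.all(inner == 1):
        return False
    outer = blob.state[flat + _neighbour_offsets(blob, 2)]
    return bool(np.any(outer == 0))


def exit_candidate_flat(blob: LatticeBlob, cap_threshold: float = 0.6) -> np.ndarray:
    """Flat indices of all exit-candidate sites (vectorized morphology)."""
    L = blob.L
    grid = blob.state.reshape(L, L, L).astype(bool)
    inside3 = ndimage.binary_erosion(grid, structure=np.ones((3, 3, 3), bool))
    inside5 = ndimage.binary_erosion(grid, structure=np.ones((5, 5, 5), bool))
    cand = inside3 & ~inside5
    x = np.arange(L) - blob.center
    cand &= (x <= cap_threshold * blob.radius)[:, None, None]
    return np.flatnonzero(cand.ravel())


# ----------------------------------------------------------------------
# portal set
# ----------------------------------------------------------------------
@dataclass
class PortalSet:
    """Exit portal sites in order of addition (most recent last)."""

    flat: list = field(default_factory=list)   # flat site indices
    coords: list = field(default_factory=list)  # centred (x, y, z) tuples

    def __len__(self) -> int:
        return len(self.flat)

    def coords_array(self) -> np.ndarray:
        return np.array(self.coords, dtype=float).reshape(len(self.flat), 3)

    def add(self, blob: LatticeBlob, flat: int) -> None:
        self.flat.append(int(flat))
        self.coords.append(tuple(int(c) for c in blob.coords(flat)))

    def pop_newest(self) -> None:
        self.flat.pop()
        self.coords.pop()

    def neighborhood_mask(self, blob: LatticeBlob) -> np.ndarray:
        """Flat boolean mask of all sites in any portal's Moore block."""
        mask = np.zeros(blob.state.size, dtype=bool)
        offs = _neighbour_offsets(blob, 1)
        for f in self.flat:
            mask[f + offs] = True
        return mask


def _separated(candidate_xyz: np.ndarray, accepted: np.ndarray, min_sep: float) -> bool:
    if accepted.size == 0:
        return True
    d2 = np.sum((accepted - candidate_xyz[None, :]) ** 2, axis=1)
    return bool(d2.min() >= min_sep**2)


def place_portals(
    blob: LatticeBlob,
    n_portals: int,
    params: TraffickingParams = TraffickingParams(),
    rng: np.random.Generator | None = None,
    candidates: np.ndarray | None = None,
) -> PortalSet:
    """Sample portal sites uniformly among exit candidates (dart throwing).

    Each portal gets up to 100 random draws to satisfy the pairwise
    ``min_separation``; after that the candidate farthest from the
    existing portals is accepted and the relaxation is logged.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if candidates is None:
        candidates = exit_candidate_flat(blob, params.cap_threshold)
    portals = PortalSet()
    if n_portals == 0:
        return portals
    if candidates.size < n_portals:
        raise CalibrationError(
            f"cannot place {n_portals} portals: only {candidates.size} candidate sites"
        )
    cand_xyz = blob.coords(candidates).astype(float)
    for _ in range(n_portals):
        accepted = portals.coords_array()
        placed = False
        for _try in range(100):
            k = int(rng.integers(0, candidates.size))
            if candidates[k] in portals.flat:
                continue
            if _separated(cand_xyz[k], accepted, params.min_separation):
                portals.add(blob, candidates[k])
                placed = True
                break
        if not placed:
            free = ~np.isin(candidates, portals.flat)
            if not free.any():
                raise CalibrationError("no free candidate sites left for portals")
            d2 = np.full(candidates.size, np.inf)
            if accepted.size:
                for m in np.flatnonzero(free):
                    d2[m] = np.sum((accepted - cand_xyz[m]) ** 2, axis=1).min()
            else:
                d2[free] = 0.0
            k = int(np.argmax(np.where(free, d2, -np.inf)))
            logger.info("portal separation relaxed: best available spacing %.2f",
                        float(np.sqrt(d2[k])))
            portals.add(blob, candidates[k])
    return portals


def update_portals(
    blob: LatticeBlob,
    portals: PortalSet,
    n: int,
    params: TraffickingParams = TraffickingParams(),
    rng: np.random.Generator | None = None,
    k_e: float = 0.0,
    target_count: int | None = None,
) -> bool:
    """Keep portals valid and matched in number to the current population.

    Portals no longer satisfying the exit-candidate predicate (the blob
    boundary moved) are relocated to the nearest valid candidate site;
    the count is re-matched to :func:`required_exit_count` by adding
    portals at random candidates or removing the most recently added.
    Returns True if anything changed.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if target_count is None:
        target_count = required_exit_count(n, k_e=k_e, params=params)
    invalid = [
        idx for idx, site in enumerate(portals.coords)
        if not is_exit_candidate(site, blob, params.cap_threshold)
    ]
    changed = bool(invalid) or len(portals) != target_count
    if not changed:
        return False
    candidates = exit_candidate_flat(blob, params.cap_threshold)
    if candidates.size < target_count:
        # a sharply contracted blob may not host the requested portals
        logger.warning(
            "portal count clamped to %d candidate sites (wanted %d, N=%d)",
            candidates.size, target_count, n,
        )
        target_count = candidates.size
    cand_xyz = blob.coords(candidates).astype(float)
    while len(portals) > target_count:
        portals.pop_newest()
    invalid = [
        idx for idx, site in enumerate(portals.coords)
        if not is_exit_candidate(site, blob, params.cap_threshold)
    ]
    for idx in invalid:
        free = ~np.isin(candidates, portals.flat)
        if not free.any():
            raise CalibrationError("no candidate sites available for relocation")
        old = np.asarray(portals.coords[idx], dtype=float)
        d2 = np.sum((cand_xyz - old[None, :]) ** 2, axis=1)
        k = int(np.argmin(np.where(free, d2, np.inf)))
        portals.flat[idx] = int(candidates[k])
        portals.coords[idx] = tuple(int(c) for c in blob.coords(candidates[k]))
    while len(portals) < target_count:
        accepted = portals.coords_array()
        free_idx = np.flatnonzero(~np.isin(candidates, portals.flat))
        if free_idx.size == 0:
            logger.warning("no free candidate sites to add portals (N=%d)", n)
            break
        placed = False
        for _try in range(100):
            k = int(free_idx[rng.integers(0, free_idx.size)])
            if _separated(cand_xyz[k], accepted, params.min_separation):
                portals.add(blob, candidates[k])
                placed = True
                break
        if not placed:
            d2 = np.array(
                [np.sum((accepted - cand_xyz[m]) ** 2, axis=1).min()
                 for m in free_idx]
            ) if accepted.size else np.zeros(free_idx.size)
            k = int(free_idx[np.argmax(d2)])
            logger.info("portal separation relaxed on addition")
            portals.add(blob, candidates[k])
    return True


# ----------------------------------------------------------------------
# transit log
# ----------------------------------------------------------------------
@dataclass
class TransitLog:
    """Entry/exit timestamps of cells trafficking through the blob."""

    cell_id: list = field(default_factory=list)
    entry_min: list = field(default_factory=list)
    exit_min: list = field(default_factory=list)
    tagged: list = field(default_factory=list)

    def record_exits(self, ids, entries, t_exit_min, tagged) -> None:
        self.cell_id.extend(int(i) for i in ids)
        self.entry_min.extend(float(e) for e in entries)
        self.exit_min.extend(float(t_exit_min) for _ in ids)
        self.tagged.extend(bool(g) for g in tagged)

    def record_open(self, ids, entries, tagged) -> None:
        """Cells still resident at the end of a run (open records)."""
        self.cell_id.extend(int(i) for i in ids)
        self.entry_min.extend(float(e) for e in entries)
        self.exit_min.extend(np.nan for _ in ids)
        self.tagged.extend(bool(g) for g in tagged)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "entry_min": self.entry_min,
                "exit_min": self.exit_min,
                "tagged": self.tagged,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
# per-step ingress / egress
# ----------------------------------------------------------------------
def ingress_step(
    blob: LatticeBlob,
    cells,
    f_in: float,
    rng: np.random.Generator,
    t_min: float,
    entry_fraction: float = 0.7,
    dt: float = DT_MIN,
    k_e: float = 0.0,
    tagged: bool = False,
    n_pending: int = 0,
    max_tries: int = 50,
) -> tuple[int, int]:
    """Poisson arrivals placed uniformly in the entry sphere (r <= 0.7 R).

    Each successful arrival opens one boundary site. An arrival that fails
    ``max_tries`` placement draws (all drawn sites full) is deferred to the
    next step. Returns (number placed, number deferred).
    """
    if f_in < 0:
        raise ValueError("influx rate must be >= 0")
    n_new = int(rng.poisson(f_in * dt)) + n_pending
    placed = 0
    deferred = 0
    for _ in range(n_new):
        r_entry = entry_fraction * blob.radius
        n_inner = int(np.searchsorted(blob.r_sorted, r_entry, side="right"))
        n_inner = max(1, n_inner)
        site = -1
        for _try in range(max_tries):
            rank = int(rng.integers(0, n_inner))
            f = blob.order[rank]
            if blob.state[f] == 1 and blob.occupancy[f] < 2:
                site = int(f)
                break
        if site < 0:
            deferred += 1
            logger.debug("arrival deferred at t=%.1f min: entry sphere crowded", t_min)
            continue
        blob.add_boundary_site()
        blob.occupancy[site] += 1
        cells.add(np.array([site]), k_e=k_e, tagged=tagged, entry_time=t_min)
        placed += 1
    return placed, deferred


def egress_step(
    blob: LatticeBlob,
    cells,
    near_mask: np.ndarray,
    p_e: float,
    rng: np.random.Generator,
    t_min: float,
    log: TransitLog | None = None,
):
    """Probabilistic egress of cells within any portal Moore neighbourhood.

    Each such cell departs with probability ``p_e`` (applied once per step
    regardless of how many neighbourhoods overlap it). Departing cells are
    removed, one boundary site is closed per departure, and exit times are
    recorded. Returns the removed subset.
    """
    if cells.n == 0:
        return cells.remove(np.zeros(0, dtype=bool))
    near = near_mask[cells.position]
    leave = near & (rng.random(cells.n) < p_e)
    departed = cells.remove(leave)
    for pos in departed.position:
        blob.occupancy[pos] -= 1
        blob.remove_boundary_site()
    if log is not None and departed.n:
        log.record_exits(departed.cell_id, departed.entry_time, t_min, departed.tagged)
    return departed


# ----------------------------------------------------------------------
# calibration experiments
# ----------------------------------------------------------------------
def _steady_state_error(
    n: int,
    n_portals: int,
    p_e: float,
    t_res: float,
    days: float,
    seed: int,
    k_e: float = 0.0,
) -> float:
    """Relative population drift rate per day under a fixed portal count.

    With the portal count held fixed the egress flux is nearly independent
    of the population (the blob shrinks with it, keeping the density at
    one cell per site), so an imbalance drifts the population linearly:
    the drift rate is proportional to the portal surplus/deficit and is
    the right quantity to interpolate between integer counts. Runs that
    leave the abort band early still yield the rate.
    """
    from .engine import SimulationConfig, run_simulation

    config = SimulationConfig(
        n0=n,
        t_res_min=t_res,
        p_e=p_e,
        duration_days=days,
        seed=seed,
        k_e_global=k_e,
        portal_count=n_portals,
        record_every=20,
        abort_band=(0.8, 1.25),
        headroom=1.6,
    )
    res = run_simulation(config)
    series = res.population
    elapsed_min = float(series.t_min.iloc[-1])
    if elapsed_min < days * 1440.0 - 1.0:
        return float(res.cells.n / n - 1.0) / (elapsed_min / 1440.0)
    last_day = series[series.t_min >= (days - 1.0) * 1440.0]
    return float(last_day.n.mean() / n - 1.0) / (days - 0.5)


def calibrate_exit_constants(
    p_e: float = 0.02,
    t_res: float = 720.0,
    n_values=(2000, 3500, 6000, 10000, 15000, 25000),
    tolerance: float = 0.025,
    days: float = 5.0,
    rng: np.random.Generator | None = None,
    max_iter: int = 12,
    n_refine_seeds: int = 3,
) -> tuple[float, float, pd.DataFrame]:
    """Fit the steady-state exit power law N_E * T_res = a * N**b.

    For each population size the integer portal count is bisected until a
    constant-influx run (influx N/T_res, no chemotaxis) holds the final-day
    mean population within ``tolerance`` of N; when the integer bracket
    collapses, the fractional portal count is interpolated from the
    bracketing deviations (portal counts are discrete, so exact balance
    generally falls between integers at small N), averaging each endpoint
    over ``n_refine_seeds`` independent runs to suppress the stochastic
    drift of individual realizations. Returns (a, b, table of per-N
    results with residuals).
    """
    if max(n_values) / min(n_values) < 10:
        raise ValueError("n_values must span at least one order of magnitude")
    if rng is None:
        rng = np.random.default_rng(0)
    rows = []
    for n in n_values:
        seeds = [int(s) for s in rng.integers(0, 2**31, size=n_refine_seeds)]
        guess = mean_field_exit_count(n, t_res, p_e)
        lo = max(1, int(np.floor(guess / 2)))
        hi = max(lo + 1, int(np.ceil(guess * 2)))
        cache: dict[tuple[int, int], float] = {}

        def err(k: int, seed: int) -> float:
            if (k, seed) not in cache:
                cache[(k, seed)] = _steady_state_error(n, k, p_e, t_res, days, seed)
            return cache[(k, seed)]

        it = 0
        while err(lo, seeds[0]) < 0 and lo > 1 and it < max_iter:
            lo = max(1, lo // 2)
            it += 1
        while err(hi, seeds[0]) > 0 and it < max_iter:
            hi *= 2
            it += 1
        if err(lo, seeds[0]) < 0 or err(hi, seeds[0]) > 0:
            raise CalibrationError(
                f"no bracketing portal counts for N={n}: "
                f"err({lo})={err(lo, seeds[0]):.3f}, "
                f"err({hi})={err(hi, seeds[0]):.3f}"
            )
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if err(mid, seeds[0]) > 0:
                lo = mid
            else:
                hi = mid
        def mean_err(k: int) -> float:
            return float(np.mean([err(k, s) for s in seeds]))

        # a count whose residual drift would stay within `tolerance` over the
        # run is already steady; otherwise re-bracket around zero drift
        # (seed-averaging can move a marginal endpoint across it)
        rate_tol = tolerance / (days - 0.5)
        e_lo, e_hi = mean_err(lo), mean_err(hi)
        if min(abs(e_lo), abs(e_hi)) <= rate_tol:
            n_e_star = float(lo if abs(e_lo) <= abs(e_hi) else hi)
            rows.append({"n": n, "n_e": n_e_star, "err_lo": e_lo, "err_hi": e_hi})
            logger.info("calibrated N=%d -> N_E = %.2f", n, n_e_star)
            continue
        it = 0
        while e_lo <= 0 and lo > 1 and it < max_iter:
            hi, e_hi = lo, e_lo
            lo -= 1
            e_lo = mean_err(lo)
            it += 1
        while e_hi >= 0 and it < max_iter:
            lo, e_lo = hi, e_hi
            hi += 1
            e_hi = mean_err(hi)
            it += 1
        if not e_lo > 0 > e_hi:
            raise CalibrationError(
                f"bisection did not converge for N={n}: "
                f"drift({lo})={e_lo:.3f}/d, drift({hi})={e_hi:.3f}/d"
            )
        n_e_star = lo + e_lo / (e_lo - e_hi) * (hi - lo)
        rows.append({"n": n, "n_e": n_e_star, "err_lo": e_lo, "err_hi": e_hi})
        logger.info("calibrated N=%d -> N_E = %.2f", n, n_e_star)
    table = pd.DataFrame(rows)
    logx = np.log(table.n.to_numpy(dtype=float))
    logy = np.log(table.n_e.to_numpy(dtype=float) * t_res)
    b, log_a = np.polyfit(logx, logy, 1)
    table["fit_n_e"] = np.exp(log_a) * table.n**b / t_res
    table["residual"] = table.n_e - table.fit_n_e
    return float(np.exp(log_a)), float(b), table


def calibrate_beta(
    k_e_values=(0.0, 1.0, 2.0, 3.0, 4.0, 5.0),
    n: int = 5000,
    p_e: float = 0.02,
    t_res: float = 720.0,
    days: float = 4.0,
    tolerance: float = 0.04,
    params: TraffickingParams | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Exit-count reduction factor beta(K_E) with all cells chemotactic.

    For each susceptibility the multiplier of the no-chemotaxis exit count
    is bisected until steady state; values are clamped at 0.5 and a
    quadratic is fitted. Returns (quadratic coefficients highest first,
    table).
    """
    if params is None:
        params = TraffickingParams(p_e=p_e, t_res=t_res)
    if rng is None:
        rng = np.random.default_rng(0)
    base_count = (
        (REFERENCE_P_E / p_e) * params.power_a * float(n) ** params.power_b / t_res
    )
    rows = []
    for k_e in k_e_values:
        seed = int(rng.integers(0, 2**31))
        cache: dict[int, float] = {}

        def err_mult(mult: float) -> float:
            k = max(1, int(round(mult * base_count)))
            if k not in cache:
                cache[k] = _steady_state_error(n, k, p_e, t_res, days, seed, k_e=k_e)
            return cache[k]

        lo, hi = 0.3, 1.2
        rate_tol = tolerance / max(days - 0.5, 1.0)
        if err_mult(hi) > 0:
            beta = hi
        elif err_mult(lo) < 0:
            beta = lo
        else:
            while (hi - lo) * base_count > 1.0:
                mid = 0.5 * (lo + hi)
                e = err_mult(mid)
                if abs(e) <= rate_tol:
                    lo = hi = mid
                    break
                if e > 0:
                    lo = mid
                else:
                    hi = mid
            beta = 0.5 * (lo + hi)
        rows.append({"k_e": k_e, "beta": max(beta, params.beta_floor), "seed": seed})
        logger.info("calibrated beta(K_E=%.1f) = %.3f", k_e, rows[-1]["beta"])
    table = pd.DataFrame(rows)
    coeffs = np.polyfit(table.k_e, table.beta, 2)
    return coeffs, table
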