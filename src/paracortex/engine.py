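"""Simulation orchestration: the per-step loop, scenarios and statistics.

Each 15 s step performs, in order: (1) vascular/influx update,
(2) ingress, (3) motility + chemotaxis moves over all cells in freshly
shuffled order, (4) forced resolution of shared sites, (5) egress,
(6) blob and portal bookkeeping, (7) recording. A configuration plus a
seed reproduces a run bit-identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import _kernels
from .chemotaxis import INFLUENCE_CUTOFF
from .inflammation import (
    InflammationParams,
    InflammationSchedule,
    equilibrium_state,
    influx_rate,
    step_vascular,
)
from .lattice import (
    DT_MIN,
    JUMP_LENGTHS_3D,
    LatticeBlob,
    UNIT_3D,
    CellPopulation,
    build_blob,
)
from .motility import DEFAULT_MOTILITY, MotilityParams, base_probability_table
from .trafficking import (
    PortalSet,
    TraffickingParams,
    TransitLog,
    egress_step,
    ingress_step,
    is_exit_candidate,
    place_portals,
    required_exit_count,
    update_portals,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SimulationResults",
    "run_simulation",
    "transit_statistics",
    "single_portal_scenario",
    "tagged_subset_experiment",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Complete, serializable description of one simulation run."""

    n0: int = 10_000
    t_res_min: float = 720.0
    p_e: float = 0.02
    duration_days: float = 1.0
    seed: int = 0

    # chemotaxis
    k_e_global: float = 0.0        # susceptibility of untagged cells
    portal_beta_k_e: float | None = None  # K_E used in the exit-count law
    # tagging of entering cells (subset experiments)
    tag_fraction: float = 0.0
    tag_window_h: tuple = (0.0, 48.0)
    tag_k_e: float = 0.0
    # tagging of initially resident cells (single-portal scenario)
    initial_tag_count: int = 0
    initial_tag_radius: float = 7.0
    initial_tag_k_e: float = 0.0

    # inflammation
    inflammation_level: float = 0.0
    inflammation_hold_days: float = 3.5
    inflammation_ramp_hours: float = 24.0

    # portals
    portal_count: int | None = None          # fixed count (None = automatic)
    portal_positions: tuple | None = None    # fixed sites (disables maintenance)
    influx_per_min: float | None = None      # overrides V * N0 / T_res

    entry_fraction: float = 0.7
    cap_threshold: float = 0.6
    min_separation: float = 4.0
    motility: MotilityParams = DEFAULT_MOTILITY
    inflammation_params: InflammationParams = InflammationParams()
    headroom: float | None = None
    record_every: int = 4      # steps between time-series records
    check_every: int = 960     # steps between full invariant audits
    # stop early once the population leaves (lo*N0, hi*N0): calibration
    # probes only need the sign of the imbalance
    abort_band: tuple | None = None

    def trafficking_params(self) -> TraffickingParams:
        return TraffickingParams(
            p_e=self.p_e,
            t_res=self.t_res_min,
            entry_fraction=self.entry_fraction,
            cap_threshold=self.cap_threshold,
            min_separation=self.min_separation,
        )

    def schedule(self) -> InflammationSchedule:
        return InflammationSchedule(
            level=self.inflammation_level,
            hold_days=self.inflammation_hold_days,
            ramp_hours=self.inflammation_ramp_hours,
        )

    def to_yaml(self, path=None) -> str:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
            if k not in ("motility", "inflammation_params")
        }
        data["motility"] = dict(self.motility.__dict__)
        data["inflammation_params"] = dict(self.inflammation_params.__dict__)
        text = yaml.safe_dump(data, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        motility = data.pop("motility", None)
        inflam = data.pop("inflammation_params", None)
        for key in ("tag_window_h", "portal_positions", "abort_band"):
            if data.get(key) is not None:
                data[key] = tuple(
                    tuple(x) if isinstance(x, list) else x for x in data[key]
                )
        config = cls(**data)
        if motility:
            config = replace(config, motility=MotilityParams(**motility))
        if inflam:
            config = replace(config, inflammation_params=InflammationParams(**inflam))
        return config


@dataclass
class SimulationResults:
    """Outputs of one run: time series, transit log and final state."""

    config: SimulationConfig
    population: pd.DataFrame
    transit_log: TransitLog
    blob: LatticeBlob
    cells: CellPopulation
    portals: PortalSet
    total_entries: int
    total_exits: int
    stuck_events: int
    cell_steps: int

    def save(self, prefix) -> None:
        """Write the delimited-text outputs under a path prefix."""
        self.population.to_csv(f"{prefix}_population.tsv", sep="\t", index=False)
        self.transit_log.to_csv(f"{prefix}_transit.tsv")


def _portal_attraction_arrays(
    blob: LatticeBlob,
    cells: CellPopulation,
    portal_xyz: np.ndarray,
    alpha: np.ndarray,
    vx: np.ndarray,
    vy: np.ndarray,
    vz: np.ndarray,
) -> None:
    """Fill per-cell alpha and attraction direction from portal distances."""
    alpha[:] = 0.0
    chemo = np.flatnonzero(cells.k_e > 0)
    if chemo.size == 0 or portal_xyz.shape[0] == 0:
        return
    xyz = blob.coords(cells.position[chemo]).astype(float)
    off = portal_xyz[None, :, :] - xyz[:, None, :]       # (n, P, 3)
    r2 = np.einsum("npk,npk->np", off, off)
    with np.errstate(divide="ignore"):
        g = np.minimum(1.0, cells.k_e[chemo, None] / r2)
    g[r2 == 0] = 0.0                                     # cell on a portal site
    g[g < INFLUENCE_CUTOFF] = 0.0
    r = np.sqrt(np.where(r2 > 0, r2, 1.0))
    c = np.einsum("np,npk->nk", g / r, off)
    s = np.linalg.norm(c, axis=1)
    act = s > 0
    idx = chemo[act]
    alpha[idx] = np.minimum(1.0, s[act])
    unit = c[act] / s[act, None]
    vx[idx], vy[idx], vz[idx] = unit[:, 0], unit[:, 1], unit[:, 2]


def run_simulation(config: SimulationConfig) -> SimulationResults:
    """Run the agent-based trafficking simulation described by ``config``."""
    rng = np.random.default_rng(config.seed)
    params = config.trafficking_params()
    schedule = config.schedule()
    inflamed = config.inflammation_level > 0
    headroom = config.headroom
    if headroom is None:
        headroom = 12.0 if inflamed else 2.0

    blob = build_blob(config.n0, headroom=headroom)
    cells = CellPopulation()
    sites = blob.order[: config.n0]
    cells.add(sites, k_e=config.k_e_global, tagged=False, entry_time=0.0)
    blob.occupancy[sites] = 1

    if config.initial_tag_count > 0:
        r = np.linalg.norm(blob.coords(cells.position).astype(float), axis=1)
        pool = np.flatnonzero(r <= config.initial_tag_radius)
        chosen = rng.choice(pool, size=min(config.initial_tag_count, pool.size),
                            replace=False)
        cells.tagged[chosen] = True
        cells.k_e[chosen] = config.initial_tag_k_e

    beta_k_e = (
        config.portal_beta_k_e
        if config.portal_beta_k_e is not None
        else config.k_e_global
    )
    fixed_positions = config.portal_positions is not None
    portals = PortalSet()
    if fixed_positions:
        for site in config.portal_positions:
            portals.add(blob, blob.flat_index(np.asarray(site, dtype=np.int64)))
    else:
        count = (
            config.portal_count
            if config.portal_count is not None
            else required_exit_count(config.n0, k_e=beta_k_e, params=params)
        )
        portals = place_portals(blob, count, params, rng)
    near_mask = portals.neighborhood_mask(blob)
    portal_xyz = portals.coords_array()

    vascular = equilibrium_state(config.n0, config.inflammation_params)
    log = TransitLog()

    tab = base_probability_table(config.motility)
    cum_base = tab.cumsum(axis=1)
    off_flat = blob.jump_offsets
    jlen = JUMP_LENGTHS_3D
    ux, uy, uz = UNIT_3D[:, 0].copy(), UNIT_3D[:, 1].copy(), UNIT_3D[:, 2].copy()

    n_steps = int(round(config.duration_days * 1440.0 / DT_MIN))
    tag_lo, tag_hi = (h * 60.0 for h in config.tag_window_h)
    any_chemo = (
        config.k_e_global > 0
        or config.initial_tag_k_e > 0
        or (config.tag_fraction > 0 and config.tag_k_e > 0)
    )

    records = []
    total_entries = total_exits = stuck_events = 0
    pending_arrivals = 0
    cell_steps = 0

    def record(step, t_min, f_in, a_now, extra_entries=0):
        records.append(
            (t_min, cells.n, vascular.v, a_now, f_in, len(portals),
             total_entries, total_exits, stuck_events)
        )

    record(0, 0.0, influx_rate(1.0, config.n0, config.t_res_min), schedule(0.0))

    alpha = np.zeros(0)
    for step in range(n_steps):
        t_min = step * DT_MIN
        n_before = cells.n

        # (1) vascular / influx
        a_now = schedule(t_min)
        if inflamed:
            vascular = step_vascular(
                replace_a(vascular, a_now), cells.n, config.n0,
                config.inflammation_params, DT_MIN,
            )
        if config.influx_per_min is not None:
            f_in = config.influx_per_min
        else:
            f_in = influx_rate(vascular.v, config.n0, config.t_res_min)

        # (2) ingress
        tag_now = config.tag_fraction > 0 and tag_lo <= t_min < tag_hi
        placed = deferred = 0
        if f_in > 0 or pending_arrivals:
            if tag_now:
                n_arr = int(rng.poisson(f_in * DT_MIN)) + pending_arrivals
                placed = deferred = 0
                for _ in range(n_arr):
                    tag = bool(rng.random() < config.tag_fraction)
                    p1, d1 = ingress_step(
                        blob, cells, 0.0, rng, t_min,
                        entry_fraction=config.entry_fraction,
                        k_e=config.tag_k_e if tag else config.k_e_global,
                        tagged=tag, n_pending=1,
                    )
                    placed += p1
                    deferred += d1
            else:
                placed, deferred = ingress_step(
                    blob, cells, f_in, rng, t_min,
                    entry_fraction=config.entry_fraction,
                    k_e=config.k_e_global, tagged=False,
                    n_pending=pending_arrivals,
                )
        pending_arrivals = deferred
        total_entries += placed

        n = cells.n
        if alpha.size != n:
            alpha = np.zeros(n)
            vx = np.zeros(n)
            vy = np.zeros(n)
            vz = np.zeros(n)

        # (3) moves in shuffled order
        if any_chemo:
            _portal_attraction_arrays(blob, cells, portal_xyz, alpha, vx, vy, vz)
        perm = rng.permutation(n)
        _kernels.move_kernel(
            perm, cells.position, cells.heading, alpha, vx, vy, vz,
            blob.state, blob.occupancy, cum_base, off_flat, jlen, ux, uy, uz,
            config.motility.p_reorient,
            rng.random(n), rng.random(n), rng.random(n),
        )

        # (4) forced resolution of shared sites
        if any_chemo:
            _portal_attraction_arrays(blob, cells, portal_xyz, alpha, vx, vy, vz)
        perm = rng.permutation(n)
        stuck_events += int(
            _kernels.resolve_kernel(
                perm, cells.position, cells.heading, alpha, vx, vy, vz,
                blob.state, blob.occupancy, tab, off_flat, jlen, ux, uy, uz,
                config.motility.p_reorient,
                rng.random(n), rng.random(n),
            )
        )
        cell_steps += n

        # (5) egress
        blob.retry_pending_removals()
        departed = egress_step(
            blob, cells, near_mask, config.p_e, rng, t_min + DT_MIN, log
        )
        total_exits += departed.n

        # (6) portal bookkeeping
        if not fixed_positions:
            target = (
                config.portal_count
                if config.portal_count is not None
                else required_exit_count(cells.n, k_e=beta_k_e, params=params)
            )
            needs_update = len(portals) != target or any(
                not is_exit_candidate(c, blob, config.cap_threshold)
                for c in portals.coords
            )
            if needs_update:
                update_portals(
                    blob, portals, cells.n, params, rng,
                    k_e=beta_k_e, target_count=target,
                )
                near_mask = portals.neighborhood_mask(blob)
                portal_xyz = portals.coords_array()

        # conservation audit
        if cells.n != n_before + placed - departed.n:
            raise RuntimeError(
                f"cell conservation violated at step {step}: "
                f"{n_before} + {placed} - {departed.n} != {cells.n}"
            )
        if (step + 1) % config.check_every == 0:
            blob.check_invariants(cells.n)

        # (7) recording
        if (step + 1) % config.record_every == 0:
            record(step + 1, t_min + DT_MIN, f_in, a_now)

        if config.abort_band is not None:
            lo, hi = config.abort_band
            if not lo * config.n0 <= cells.n <= hi * config.n0:
                logger.info(
                    "run aborted at t=%.1f min: population %d left the "
                    "(%.2f, %.2f) x N0 band", t_min, cells.n, lo, hi,
                )
                break

    blob.check_invariants(cells.n)
    log.record_open(cells.cell_id, cells.entry_time, cells.tagged)

    population = pd.DataFrame(
        records,
        columns=["t_min", "n", "v", "a", "f_in", "n_portals",
                 "entries", "exits", "stuck"],
    )
    return SimulationResults(
        config=config,
        population=population,
        transit_log=log,
        blob=blob,
        cells=cells,
        portals=portals,
        total_entries=total_entries,
        total_exits=total_exits,
        stuck_events=stuck_events,
        cell_steps=cell_steps,
    )


def replace_a(state, a_now):
    """Vascular state with the inflammation signal updated."""
    state.a = float(a_now)
    return state


class InsufficientRecordsError(ValueError):
    """Too few closed transit records for reliable statistics."""


def transit_statistics(
    log: TransitLog,
    burn_in_h: float = 24.0,
    bin_h: float = 1.0,
    min_records: int = 1000,
    tagged_only: bool = False,
    entry_cutoff_h: float | None = None,
) -> tuple[float, pd.DataFrame]:
    """Mean transit time (minutes) and 1 h-binned distribution.

    Only closed records of cells that entered after the burn-in are used;
    open records are excluded (their count is reported in the histogram
    frame's attrs). ``entry_cutoff_h`` additionally excludes cells that
    entered late in the run: without it the mean is biased low, because
    long transits of late entrants are right-censored at the end of the
    simulation. Leave a margin of several residence times.
    """
    frame = log.to_frame()
    if tagged_only:
        frame = frame[frame.tagged]
    after = frame[frame.entry_min >= burn_in_h * 60.0]
    if entry_cutoff_h is not None:
        after = after[after.entry_min <= entry_cutoff_h * 60.0]
    closed = after.dropna(subset=["exit_min"])
    if len(closed) < min_records:
        raise InsufficientRecordsError(
            f"only {len(closed)} closed records after burn-in (need {min_records})"
        )
    transit = (closed.exit_min - closed.entry_min).to_numpy()
    mean_min = float(transit.mean())
    # one spare bin so a transit on the last edge stays in its own bin
    # (np.histogram treats the final bin as right-inclusive)
    edges_h = np.arange(
        0.0, np.ceil(transit.max() / 60.0 / bin_h) * bin_h + 2 * bin_h, bin_h
    )
    counts, _ = np.histogram(transit / 60.0, bins=edges_h)
    hist = pd.DataFrame(
        {"bin_left_h": edges_h[:-1], "probability": counts / counts.sum()}
    )
    hist.attrs["open_records"] = int(len(after) - len(closed))
    return mean_min, hist


def single_portal_scenario(
    k_e: float,
    n_tagged: int = 100,
    tag_radius: float = 7.0,
    duration_h: float = 6.0,
    n0: int = 10_000,
    p_e: float = 0.02,
    seed: int = 0,
    **overrides,
) -> pd.DataFrame:
    """Retention of tagged cells near a single central exit portal.

    A blob of ``n0`` cells has one exit portal at its centre; ``n_tagged``
    cells initially within ``tag_radius`` of the portal are tagged and
    given chemotactic susceptibility ``k_e`` (all other cells are
    non-chemotactic). Influx balances the expected egress of the single
    portal. Returns the tagged-cells-remaining curve (t_min, n_tagged).
    """
    influx = 27.0 * p_e / DT_MIN  # one portal, ~1 cell per neighbourhood site
    config = SimulationConfig(
        n0=n0,
        p_e=p_e,
        duration_days=duration_h / 24.0,
        seed=seed,
        portal_positions=((0, 0, 0),),
        influx_per_min=influx,
        initial_tag_count=n_tagged,
        initial_tag_radius=tag_radius,
        initial_tag_k_e=k_e,
        record_every=overrides.pop("record_every", 4),
        **overrides,
    )
    res = run_simulation(config)
    frame = res.transit_log.to_frame()
    tagged = frame[frame.tagged]
    t_grid = np.arange(0.0, duration_h * 60.0 + 1.0, 1.0)
    exits = tagged.exit_min.dropna().to_numpy()
    start = len(tagged)
    remaining = [start - int((exits <= t).sum()) for t in t_grid]
    return pd.DataFrame({"t_min": t_grid, "tagged_remaining": remaining})


def tagged_subset_experiment(
    k_e_subset: float,
    fraction: float = 0.1,
    window_h: float = 48.0,
    n0: int = 50_000,
    t_res_min: float = 720.0,
    duration_days: float = 10.0,
    seed: int = 0,
    burn_in_h: float = 24.0,
    **overrides,
) -> tuple[float, pd.DataFrame, SimulationResults]:
    """Residence time of a chemotactic subset in a steady-state blob.

    A fraction of the cells entering during the first ``window_h`` hours
    is tagged and given susceptibility ``k_e_subset``; all other cells are
    non-chemotactic. Returns (mean tagged transit time in minutes, tagged
    transit histogram, full results).
    """
    min_records = overrides.pop("min_records", 200)
    config = SimulationConfig(
        n0=n0,
        t_res_min=t_res_min,
        duration_days=duration_days,
        seed=seed,
        tag_fraction=fraction,
        tag_window_h=(0.0, window_h),
        tag_k_e=k_e_subset,
        **overrides,
    )
    res = run_simulation(config)
    mean_min, hist = transit_statistics(
        res.transit_log, burn_in_h=burn_in_h, tagged_only=True,
        min_records=min_records,
    )
    return mean_min, hist, res
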