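"""Spherical lattice domain ("blob") and cell bookkeeping.

The paracortical T zone is represented as a roughly spherical set of
AVAILABLE sites on a cubic lattice. The number of available sites always
equals the number of cells present; ingress or division opens a boundary
site, egress or death closes one. Crowding is handled by allowing at most
two cells per site, with double occupancy permitted for a single time step
(the "passing" rule).

Coordinates are integer lattice indices with the blob centre at the origin;
distances are in lattice units unless micrometres are stated explicitly.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default time step, minutes (15 s).
DT_MIN = 0.25

# The 26 Moore jump vectors in 3D, lexicographic order over {-1,0,1}^3
# excluding the null vector. Index i of a jump distribution refers to
# MOORE_3D[i-1]; index 0 is "no jump".
MOORE_3D = np.array(
    [v for v in itertools.product((-1, 0, 1), repeat=3) if v != (0, 0, 0)],
    dtype=np.int64,
)
JUMP_LENGTHS_3D = np.linalg.norm(MOORE_3D.astype(float), axis=1)
UNIT_3D = MOORE_3D / JUMP_LENGTHS_3D[:, None]

# The 8 Moore jump vectors in 2D, counter-clockwise starting at +x.
# This ordering matches the conventional numbering of neighbour sites
# 1..8 used for the 2D worked example.
MOORE_2D = np.array(
    [(1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1)],
    dtype=np.int64,
)
JUMP_LENGTHS_2D = np.linalg.norm(MOORE_2D.astype(float), axis=1)
UNIT_2D = MOORE_2D / JUMP_LENGTHS_2D[:, None]


def grid_spacing_from_occupancy(volume_fraction: float, cell_volume: float) -> float:
    """Lattice grid spacing (µm) from the cell volume fraction.

    With cells of volume ``cell_volume`` µm³ filling a fraction
    ``volume_fraction`` of the tissue, one lattice site per cell implies a
    site volume of ``cell_volume / volume_fraction`` and hence a spacing of
    its cube root. The default tissue occupancy of 60% with a 150 µm³
    T cell gives the standard spacing of 6.3 µm.
    """
    if not 0.0 < volume_fraction <= 1.0:
        raise ValueError(f"volume_fraction must be in (0, 1], got {volume_fraction}")
    if cell_volume <= 0:
        raise ValueError(f"cell_volume must be positive, got {cell_volume}")
    return float((cell_volume / volume_fraction) ** (1.0 / 3.0))


#: Standard grid spacing, µm (60% occupancy, 150 µm³ cells).
DEFAULT_GRID_SPACING = grid_spacing_from_occupancy(0.6, 150.0)


def moore_neighborhood(site) -> np.ndarray:
    """The 27-site block centred on ``site`` (the site itself included)."""
    site = np.asarray(site, dtype=np.int64)
    offsets = np.array(
        list(itertools.product((-1, 0, 1), repeat=3)), dtype=np.int64
    )
    return site[None, :] + offsets


def nominal_radius(n_sites: int) -> float:
    """Radius of the sphere whose volume is ``n_sites`` unit cells."""
    return float((3.0 * n_sites / (4.0 * np.pi)) ** (1.0 / 3.0))


class BlobFullError(RuntimeError):
    """The blob cannot grow further within its allocated bounding box."""


class LatticeBlob:
    """Spherical blob of available lattice sites with occupancy tracking.

    Sites are kept in a cubic bounding box of side ``L``; internally all
    site references are flat indices into arrays of length ``L**3``. The
    available set is (approximately) the prefix of a fixed ordering of all
    box sites by (squared distance from centre, then lexicographic x, y, z),
    which makes blob construction and growth deterministic and keeps the
    region maximally spherical.

    Parameters
    ----------
    n_cells:
        Initial number of cells; exactly this many sites are made available.
    grid_spacing:
        Physical lattice spacing in µm (metadata for unit conversions).
    headroom:
        Factor by which the *population* may grow before the bounding box
        is exhausted (the radius headroom is its cube root).
    """

    def __init__(
        self,
        n_cells: int,
        grid_spacing: float = DEFAULT_GRID_SPACING,
        headroom: float = 12.0,
    ):
        if n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        self.grid_spacing = float(grid_spacing)
        r_max = nominal_radius(int(np.ceil(n_cells * headroom)))
        half = int(np.ceil(r_max)) + 3  # two outside shells + margin
        self.L = 2 * half + 1
        self.center = half  # array offset of the origin

        L = self.L
        ax = np.arange(L) - half
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
        x, y, z = x.ravel(), y.ravel(), z.ravel()
        r2 = x * x + y * y + z * z
        self.order = np.lexsort((z, y, x, r2)).astype(np.int64)
        self.rank = np.empty(L**3, dtype=np.int64)
        self.rank[self.order] = np.arange(L**3)
        self.r_sorted = np.sqrt(r2[self.order].astype(float))

        # keep a 3-site margin so Moore lookups and moves never leave the box
        self.max_sites = int(np.searchsorted(self.r_sorted, half - 3.0, side="right"))
        if self.max_sites < n_cells:
            raise ValueError("bounding box too small for n_cells")

        self.state = np.zeros(L**3, dtype=np.uint8)  # 0 OUTSIDE, 1 AVAILABLE
        self.occupancy = np.zeros(L**3, dtype=np.uint8)
        self.state[self.order[:n_cells]] = 1
        self.n_available = n_cells
        self._next_out = n_cells  # smallest rank that may be OUTSIDE
        self._max_avail = n_cells - 1  # largest rank that may be AVAILABLE
        self.pending_removals = 0
        self.crowded_removal_events = 0

        # flat-index offsets of the 26 Moore jumps
        self.jump_offsets = (
            MOORE_3D[:, 0] * L * L + MOORE_3D[:, 1] * L + MOORE_3D[:, 2]
        ).astype(np.int64)

    # ------------------------------------------------------------------
    # coordinate helpers
    # ------------------------------------------------------------------
    def flat_index(self, coords) -> np.ndarray:
        """Flat index of centred lattice coordinates (vectorized)."""
        c = np.asarray(coords, dtype=np.int64) + self.center
        if c.ndim == 1:
            return int((c[0] * self.L + c[1]) * self.L + c[2])
        return (c[..., 0] * self.L + c[..., 1]) * self.L + c[..., 2]

    def coords(self, flat) -> np.ndarray:
        """Centred coordinates of flat indices (vectorized)."""
        flat = np.asarray(flat, dtype=np.int64)
        x, rem = np.divmod(flat, self.L * self.L)
        y, z = np.divmod(rem, self.L)
        return np.stack([x, y, z], axis=-1) - self.center

    @property
    def radius(self) -> float:
        """Nominal radius R of the current blob, lattice units."""
        return nominal_radius(self.n_available)

    # ------------------------------------------------------------------
    # growth / contraction
    # ------------------------------------------------------------------
    def add_boundary_site(self) -> int:
        """Open the OUTSIDE site nearest the nominal surface; return it.

        The site with the lowest rank (closest to the centre, deterministic
        lexicographic tie-break) among OUTSIDE sites is chosen, which is
        adjacent to the blob surface for any compact blob.
        """
        p = self._next_out
        order = self.order
        n = self.max_sites
        while p < n and self.state[order[p]] == 1:
            p += 1
        if p >= n:
            raise BlobFullError(
                "bounding box exhausted; rebuild the blob with more headroom"
            )
        site = order[p]
        self.state[site] = 1
        self.n_available += 1
        self._next_out = p + 1
        self._max_avail = max(self._max_avail, p)
        return int(site)

    def remove_boundary_site(self) -> int | None:
        """Close the farthest unoccupied AVAILABLE site; return it.

        If every candidate boundary site is occupied the removal is
        deferred (``pending_removals`` is incremented) and ``None`` is
        returned; callers retry on a later step.
        """
        order = self.order
        p = self._max_avail
        while p >= 0 and self.state[order[p]] == 0:
            p -= 1
        self._max_avail = p
        q = p
        while q >= 0 and (self.state[order[q]] == 0 or self.occupancy[order[q]] > 0):
            q -= 1
        if q < 0:
            self.pending_removals += 1
            self.crowded_removal_events += 1
            logger.debug("boundary removal deferred: all boundary sites occupied")
            return None
        site = order[q]
        self.state[site] = 0
        self.n_available -= 1
        self._next_out = min(self._next_out, q)
        return int(site)

    def retry_pending_removals(self) -> int:
        """Attempt deferred boundary removals; return how many succeeded."""
        done = 0
        while self.pending_removals > 0:
            self.pending_removals -= 1
            if self.remove_boundary_site() is None:
                # remove_boundary_site re-incremented pending_removals
                break
            done += 1
        return done

    # ------------------------------------------------------------------
    # queries and export
    # ------------------------------------------------------------------
    def available_flat(self) -> np.ndarray:
        """Flat indices of all AVAILABLE sites."""
        return np.flatnonzero(self.state == 1)

    def snapshot(self) -> pd.DataFrame:
        """One row per non-OUTSIDE or occupied site: x, y, z, state, occupancy."""
        flat = self.available_flat()
        xyz = self.coords(flat)
        return pd.DataFrame(
            {
                "x": xyz[:, 0],
                "y": xyz[:, 1],
                "z": xyz[:, 2],
                "state": "AVAILABLE",
                "occupancy": self.occupancy[flat].astype(int),
            }
        )

    def check_invariants(self, n_cells: int) -> None:
        """Raise AssertionError if site/cell accounting is violated."""
        occ_total = int(self.occupancy.sum())
        assert occ_total == n_cells, (occ_total, n_cells)
        assert self.n_available + self.pending_removals == n_cells, (
            self.n_available,
            self.pending_removals,
            n_cells,
        )
        assert int((self.state == 1).sum()) == self.n_available
        assert self.occupancy.max(initial=0) <= 2
        assert not np.any((self.state == 0) & (self.occupancy > 0))


def build_blob(
    n_cells: int,
    grid_spacing: float = DEFAULT_GRID_SPACING,
    headroom: float = 12.0,
) -> LatticeBlob:
    """Construct a spherical blob with exactly ``n_cells`` available sites."""
    return LatticeBlob(n_cells, grid_spacing=grid_spacing, headroom=headroom)


# ----------------------------------------------------------------------
# cell population (structure-of-arrays)
# ----------------------------------------------------------------------
@dataclass
class CellPopulation:
    """T cell agents stored as parallel arrays.

    ``heading`` encodes the persistence direction as a jump index in 1..26
    (0 meaning "no heading yet": a freshly entered cell moves isotropically).
    """

    position: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    heading: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    k_e: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.float64))
    tagged: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    entry_time: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.float64))
    cell_id: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    _next_id: int = 0

    @property
    def n(self) -> int:
        return self.position.size

    def add(self, positions, k_e=0.0, tagged=False, entry_time=0.0) -> np.ndarray:
        """Append cells at flat positions; returns their ids."""
        positions = np.asarray(positions, dtype=np.int64)
        m = positions.size
        ids = np.arange(self._next_id, self._next_id + m, dtype=np.int64)
        self._next_id += m
        self.position = np.concatenate([self.position, positions])
        self.heading = np.concatenate([self.heading, np.zeros(m, dtype=np.int64)])
        self.k_e = np.concatenate([self.k_e, np.broadcast_to(np.asarray(k_e, float), (m,))])
        self.tagged = np.concatenate([self.tagged, np.broadcast_to(np.asarray(tagged, bool), (m,))])
        self.entry_time = np.concatenate(
            [self.entry_time, np.broadcast_to(np.asarray(entry_time, float), (m,))]
        )
        self.cell_id = np.concatenate([self.cell_id, ids])
        return ids

    def remove(self, mask: np.ndarray) -> "CellPopulation":
        """Remove cells where ``mask`` is True; returns the removed subset."""
        gone = CellPopulation(
            self.position[mask],
            self.heading[mask],
            self.k_e[mask],
            self.tagged[mask],
            self.entry_time[mask],
            self.cell_id[mask],
        )
        keep = ~mask
        self.position = self.position[keep]
        self.heading = self.heading[keep]
        self.k_e = self.k_e[keep]
        self.tagged = self.tagged[keep]
        self.entry_time = self.entry_time[keep]
        self.cell_id = self.cell_id[keep]
        return gone


def resolve_double_occupancy(
    blob: LatticeBlob,
    cells: CellPopulation,
    base_probs: np.ndarray,
    rng: np.random.Generator,
    alpha: np.ndarray | None = None,
    v: np.ndarray | None = None,
    order: np.ndarray | None = None,
    p_reorient: float = 1.0,
) -> int:
    """Force a move attempt for every cell sharing a site (reference version).

    Each cell standing on a doubly occupied site redraws a jump from its
    distribution renormalized over admissible destinations (no-jump
    excluded); if no destination is admissible it stays put and the event
    is counted. Cells are processed in the given (or a random) order, so a
    cell whose partner has already vacated the site is skipped. Returns the
    number of stuck cells.

    This pure-NumPy implementation defines the contract; the simulation
    engine runs a compiled kernel with identical semantics.
    """
    n = cells.n
    if order is None:
        order = rng.permutation(n)
    state, occ = blob.state, blob.occupancy
    offs = blob.jump_offsets
    stuck = 0
    for i in order:
        pos = cells.position[i]
        if occ[pos] < 2:
            continue
        dests = pos + offs
        admissible = (state[dests] == 1) & (occ[dests] < 2)
        w = base_probs[cells.heading[i], 1:].copy()
        if alpha is not None and alpha[i] > 0:
            cos = UNIT_3D @ v[i]
            pc = np.where(cos >= 0, cos**2 / JUMP_LENGTHS_3D, 0.0)
            pc = pc / pc.sum()
            w = (1 - alpha[i]) * w + alpha[i] * pc
        w[~admissible] = 0.0
        tot = w.sum()
        if tot <= 0.0:
            stuck += 1
            continue
        j = rng.choice(26, p=w / tot)
        dest = dests[j]
        occ[pos] -= 1
        occ[dest] += 1
        cells.position[i] = dest
        if rng.random() < p_reorient:
            cells.heading[i] = j + 1
    return stuck
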