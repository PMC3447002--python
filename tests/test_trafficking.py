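"""Exit portals, ingress/egress mechanics and the exit-count law."""

import numpy as np
import pytest

from paracortex.lattice import CellPopulation, build_blob
from paracortex.trafficking import (
    PortalSet,
    TraffickingParams,
    TransitLog,
    beta_reduction,
    egress_step,
    exit_candidate_flat,
    ingress_step,
    is_exit_candidate,
    mean_field_exit_count,
    place_portals,
    required_exit_count,
    update_portals,
    CalibrationError,
)


class TestBetaReduction:
    def test_no_chemotaxis_near_unity(self):
        assert beta_reduction(0.0) == pytest.approx(0.9997)

    def test_high_susceptibility_clamps_to_half(self):
        assert beta_reduction(5.0) == 0.5
        assert beta_reduction(10.0) == 0.5

    def test_monotone_nonincreasing_on_range(self):
        vals = [beta_reduction(k) for k in np.linspace(0, 4, 41)]
        assert np.all(np.diff(vals) <= 1e-12)


class TestRequiredExitCount:
    def test_pe_inverse_scaling(self):
        base = required_exit_count(100_000, p_e=0.02)
        assert required_exit_count(100_000, p_e=0.01) == pytest.approx(2 * base, abs=1)
        assert required_exit_count(100_000, p_e=0.005) == pytest.approx(4 * base, abs=1)

    def test_nearly_linear_in_n(self):
        n1 = required_exit_count(10_000)
        n2 = required_exit_count(20_000)
        assert n2 == pytest.approx(2 * n1, abs=1)

    def test_chemotaxis_reduces_count(self):
        assert required_exit_count(100_000, k_e=5.0) == pytest.approx(
            0.5 * required_exit_count(100_000, k_e=0.0), abs=1
        )

    def test_missing_constants(self):
        params = TraffickingParams(power_a=float("nan"))
        with pytest.raises(CalibrationError):
            required_exit_count(1000, params=params)

    def test_mean_field_guess(self):
        # N = 1e5, T_res = 12 h, P_E = 0.02 -> ~64 portals
        assert mean_field_exit_count(1e5, 720.0, 0.02) == pytest.approx(64.3, abs=0.2)


class TestExitCandidates:
    def setup_method(self):
        self.blob = build_blob(10_000)

    def test_center_not_candidate(self):
        assert not is_exit_candidate((0, 0, 0), self.blob)

    def test_cap_excluded(self):
        cand = exit_candidate_flat(self.blob, cap_threshold=0.6)
        xyz = self.blob.coords(cand)
        assert np.all(xyz[:, 0] <= 0.6 * self.blob.radius)
        # without the cap, candidates at high x exist
        cand_all = exit_candidate_flat(self.blob, cap_threshold=10.0)
        assert len(cand_all) > len(cand)
        xyz_all = self.blob.coords(cand_all)
        assert xyz_all[:, 0].max() > 0.6 * self.blob.radius

    def test_boundary_layer_site_at_low_x(self):
        # one layer inside the boundary at x ~ 0 qualifies
        cand = exit_candidate_flat(self.blob)
        xyz = self.blob.coords(cand)
        low_x = np.abs(xyz[:, 0]) <= 1
        assert low_x.any()
        r = np.linalg.norm(xyz[low_x].astype(float), axis=1)
        assert np.all(r > self.blob.radius - 4)

    def test_predicate_agrees_with_morphology(self):
        """Direct per-site predicate vs the vectorized erosion route."""
        cand = set(exit_candidate_flat(self.blob))
        rng = np.random.default_rng(0)
        sample = rng.choice(self.blob.available_flat(), size=300, replace=False)
        for flat in sample:
            site = self.blob.coords(int(flat))
            assert is_exit_candidate(site, self.blob) == (int(flat) in cand)


class TestPlacePortals:
    def setup_method(self):
        self.blob = build_blob(10_000)
        self.params = TraffickingParams()

    def test_zero_portals(self):
        assert len(place_portals(self.blob, 0, self.params)) == 0

    def test_all_satisfy_predicate_and_separation(self):
        rng = np.random.default_rng(1)
        portals = place_portals(self.blob, 8, self.params, rng)
        assert len(portals) == 8
        for site in portals.coords:
            assert is_exit_candidate(site, self.blob)
        xyz = portals.coords_array()
        d = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= self.params.min_separation

    def test_reproducible_under_seed(self):
        p1 = place_portals(self.blob, 5, self.params, np.random.default_rng(7))
        p2 = place_portals(self.blob, 5, self.params, np.random.default_rng(7))
        assert p1.flat == p2.flat

    def test_infeasible_count(self):
        with pytest.raises(CalibrationError):
            place_portals(self.blob, 10_000, self.params)


class TestUpdatePortals:
    def test_unchanged_when_target_matches(self):
        blob = build_blob(5000)
        rng = np.random.default_rng(2)
        portals = place_portals(blob, 3, rng=rng)
        changed = update_portals(blob, portals, 5000, rng=rng, target_count=3)
        assert not changed

    def test_relocation_after_shrink(self):
        blob = build_blob(5000)
        rng = np.random.default_rng(3)
        portals = place_portals(blob, 3, rng=rng)
        # contract the blob by several shells so portals fall outside
        for _ in range(1500):
            assert blob.remove_boundary_site() is not None
        update_portals(blob, portals, 3500, rng=rng, target_count=3)
        for site in portals.coords:
            assert is_exit_candidate(site, blob)

    def test_count_tracks_target(self):
        blob = build_blob(5000)
        rng = np.random.default_rng(4)
        portals = place_portals(blob, 2, rng=rng)
        update_portals(blob, portals, 5000, rng=rng, target_count=6)
        assert len(portals) == 6
        update_portals(blob, portals, 5000, rng=rng, target_count=4)
        assert len(portals) == 4


class TestIngress:
    def test_zero_influx(self):
        blob = build_blob(1000)
        cells = CellPopulation()
        placed, deferred = ingress_step(blob, cells, 0.0, np.random.default_rng(0), 0.0)
        assert placed == 0 and deferred == 0 and cells.n == 0

    def test_placement_inside_entry_sphere(self):
        blob = build_blob(8000)
        cells = CellPopulation()
        rng = np.random.default_rng(5)
        for t in range(200):
            ingress_step(blob, cells, 40.0, rng, float(t), entry_fraction=0.7)
        assert cells.n > 1500
        r = np.linalg.norm(blob.coords(cells.position).astype(float), axis=1)
        assert np.all(r <= 0.7 * blob.radius + 1e-9)
        # one boundary site opened per arrival, occupancy tracks placements
        assert blob.n_available == 8000 + cells.n
        assert int(blob.occupancy.sum()) == cells.n

    def test_mean_arrival_rate(self):
        blob = build_blob(5000)
        cells = CellPopulation()
        rng = np.random.default_rng(6)
        f_in = 138.9  # N0=1e5 at T_res=12 h -> 34.7 per 15 s step
        total = 0
        for t in range(100):
            placed, _ = ingress_step(blob, cells, f_in, rng, float(t))
            total += placed
        assert total / 100 == pytest.approx(34.7, rel=0.1)


class TestEgress:
    def _crowded_portal(self):
        blob = build_blob(5000)
        portals = PortalSet()
        site = exit_candidate_flat(blob)[0]
        portals.add(blob, site)
        near = portals.neighborhood_mask(blob)
        cells = CellPopulation()
        near_sites = np.flatnonzero(near)
        cells.add(near_sites)  # one cell on each of the 27 sites
        blob.occupancy[near_sites] = 1
        return blob, cells, near

    def test_zero_probability_no_egress(self):
        blob, cells, near = self._crowded_portal()
        log = TransitLog()
        departed = egress_step(blob, cells, near, 0.0, np.random.default_rng(0), 10.0, log)
        assert departed.n == 0 and cells.n == 27

    def test_expected_departures_from_full_neighborhood(self):
        """27 cells at P_E = 0.02 -> 0.54 expected departures per step."""
        rng = np.random.default_rng(8)
        blob, _, near = self._crowded_portal()
        near_sites = np.flatnonzero(near)
        saved = (
            blob.state.copy(), blob.occupancy.copy(), blob.n_available,
            blob._next_out, blob._max_avail,
        )
        total = 0
        n_rep = 2000
        for _ in range(n_rep):
            blob.state[:], blob.occupancy[:] = saved[0], saved[1]
            blob.n_available, blob._next_out, blob._max_avail = saved[2:]
            cells = CellPopulation()
            cells.add(near_sites)
            departed = egress_step(blob, cells, near, 0.02, rng, 0.0)
            total += departed.n
        mean = total / n_rep
        sd = np.sqrt(27 * 0.02 * 0.98 / n_rep)
        assert mean == pytest.approx(0.54, abs=4 * sd)

    def test_cells_outside_neighborhood_never_depart(self):
        blob = build_blob(5000)
        portals = PortalSet()
        portals.add(blob, exit_candidate_flat(blob)[0])
        near = portals.neighborhood_mask(blob)
        cells = CellPopulation()
        far = blob.flat_index((0, 0, 0))
        cells.add(np.array([far]))
        blob.occupancy[far] = 1
        rng = np.random.default_rng(9)
        for _ in range(500):
            departed = egress_step(blob, cells, near, 1.0, rng, 0.0)
            assert departed.n == 0
        assert cells.n == 1


class TestTransitLog:
    def test_roundtrip(self, tmp_path):
        log = TransitLog()
        log.record_exits([1, 2], [0.0, 5.0], 100.0, [True, False])
        log.record_open([3], [50.0], [False])
        frame = log.to_frame()
        assert len(frame) == 3
        assert frame.exit_min.isna().sum() == 1
        assert (frame.exit_min >= frame.entry_min).sum() == 2
        path = tmp_path / "transit.tsv"
        log.to_csv(path)
        assert path.read_text().startswith("cell_id\tentry_min")
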