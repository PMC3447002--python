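"""Lattice geometry, blob growth bookkeeping and the passing rule."""

import numpy as np
import pytest
from scipy import stats

from paracortex.lattice import (
    CellPopulation,
    LatticeBlob,
    build_blob,
    grid_spacing_from_occupancy,
    moore_neighborhood,
    resolve_double_occupancy,
)
from paracortex.motility import MotilityParams, base_probability_table


class TestGridSpacing:
    @pytest.mark.parametrize(
        "fraction,volume,expected",
        [(0.6, 150.0, 6.30), (1.0, 1000.0, 10.0), (0.5, 4.0, 2.0)],
    )
    def test_examples(self, fraction, volume, expected):
        assert grid_spacing_from_occupancy(fraction, volume) == pytest.approx(
            expected, abs=0.005
        )

    @pytest.mark.parametrize("fraction,volume", [(0.0, 100.0), (-0.1, 1.0), (0.6, 0.0), (1.2, 1.0)])
    def test_invalid_inputs(self, fraction, volume):
        with pytest.raises(ValueError):
            grid_spacing_from_occupancy(fraction, volume)


class TestMooreNeighborhood:
    def test_origin_block(self):
        nb = moore_neighborhood((0, 0, 0))
        assert nb.shape == (27, 3)
        assert set(map(tuple, nb)) == {
            (i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
        }

    def test_contains_site_and_distance_classes(self):
        site = (3, -2, 5)
        nb = moore_neighborhood(site)
        assert tuple(site) in set(map(tuple, nb))
        d = np.linalg.norm(nb - np.asarray(site), axis=1)
        counts = {1.0: 6, np.sqrt(2): 12, np.sqrt(3): 8}
        for dist, n in counts.items():
            assert np.sum(np.isclose(d, dist)) == n


class TestBuildBlob:
    def test_radius_10k(self):
        blob = build_blob(10_000)
        assert 13.3 <= blob.radius <= 13.6  # ~13.5 site radius
        assert blob.n_available == 10_000

    def test_single_site(self):
        blob = build_blob(1)
        assert blob.n_available == 1
        assert blob.state[blob.flat_index((0, 0, 0))] == 1
        assert blob.radius == pytest.approx(0.62, abs=0.01)

    def test_large_blob_radius(self):
        blob = build_blob(100_000, headroom=1.3)
        assert blob.radius == pytest.approx((3e5 / (4 * np.pi)) ** (1 / 3), rel=1e-9)

    def test_deterministic(self):
        b1, b2 = build_blob(500), build_blob(500)
        assert np.array_equal(b1.available_flat(), b2.available_flat())

    def test_sphericity(self):
        # available sites are exactly the n nearest the centre
        blob = build_blob(3000)
        flat = blob.available_flat()
        r = np.linalg.norm(blob.coords(flat).astype(float), axis=1)
        outside = np.flatnonzero(blob.state == 0)
        r_out = np.linalg.norm(blob.coords(outside).astype(float), axis=1)
        assert r.max() <= r_out.min() + 1e-9 or np.isclose(r.max(), r_out.min())


class TestBoundaryBookkeeping:
    def test_add_then_remove_restores(self):
        blob = build_blob(1000)
        before = set(blob.available_flat())
        blob.add_boundary_site()
        removed = blob.remove_boundary_site()
        assert removed is not None
        assert set(blob.available_flat()) == before

    def test_sequential_adds_grow_radius(self):
        blob = build_blob(10_000)
        for _ in range(100):
            blob.add_boundary_site()
        assert blob.radius == pytest.approx(
            (10_100 / 10_000) ** (1 / 3) * (3 * 10_000 / (4 * np.pi)) ** (1 / 3),
            rel=1e-9,
        )

    def test_removal_deferred_when_all_occupied(self):
        blob = build_blob(27)
        flat = blob.available_flat()
        blob.occupancy[flat] = 1
        assert blob.remove_boundary_site() is None
        assert blob.pending_removals == 1
        blob.occupancy[flat[-1]] = 0
        assert blob.retry_pending_removals() == 1
        assert blob.pending_removals == 0

    def test_accounting_invariants_after_churn(self):
        blob = build_blob(500)
        rng = np.random.default_rng(0)
        n = 500
        blob.occupancy[blob.available_flat()] = 1
        for _ in range(200):
            if rng.random() < 0.5:
                site = blob.add_boundary_site()
                blob.occupancy[site] = 1
                n += 1
            else:
                # free an occupied boundary site first so removal succeeds
                flat = blob.available_flat()
                occ_sites = flat[blob.occupancy[flat] > 0]
                victim = occ_sites[
                    np.argmax(np.linalg.norm(blob.coords(occ_sites), axis=1))
                ]
                blob.occupancy[victim] -= 1
                n -= 1
                assert blob.remove_boundary_site() is not None
        blob.check_invariants(n)


class TestPassingRule:
    def _shared_site_setup(self, n=2000):
        blob = build_blob(n)
        cells = CellPopulation()
        center = blob.flat_index((0, 0, 0))
        cells.add(np.array([center, center]))
        blob.occupancy[center] = 2
        return blob, cells

    def test_shared_site_resolved_in_one_pass(self):
        blob, cells = self._shared_site_setup()
        tab = base_probability_table(MotilityParams(p0=0.5, kappa=1.0))
        stuck = resolve_double_occupancy(
            blob, cells, tab, np.random.default_rng(1)
        )
        assert stuck == 0
        assert blob.occupancy[cells.position[0]] == 1
        assert blob.occupancy[cells.position[1]] == 1
        assert cells.position[0] != cells.position[1]

    def test_fully_crowded_cell_stays(self):
        blob, cells = self._shared_site_setup()
        center = blob.flat_index((0, 0, 0))
        # fill the whole neighbourhood to capacity
        for off in blob.jump_offsets:
            blob.occupancy[center + off] = 2
        tab = base_probability_table(MotilityParams(p0=0.5, kappa=1.0))
        stuck = resolve_double_occupancy(blob, cells, tab, np.random.default_rng(1))
        assert stuck == 2
        assert blob.occupancy[center] == 2

    def test_isolated_cell_noop(self):
        blob = build_blob(100)
        cells = CellPopulation()
        site = blob.flat_index((0, 0, 0))
        cells.add(np.array([site]))
        blob.occupancy[site] = 1
        tab = base_probability_table(MotilityParams(p0=0.5, kappa=1.0))
        assert resolve_double_occupancy(blob, cells, tab, np.random.default_rng(0)) == 0
        assert cells.position[0] == site

    def test_forced_move_distribution_matches_renormalized_base(self):
        """The forced jump follows the no-jump-excluded base distribution."""
        params = MotilityParams(p0=0.6, kappa=0.0)
        tab = base_probability_table(params)
        expected = tab[0, 1:] / tab[0, 1:].sum()
        rng = np.random.default_rng(7)
        counts = np.zeros(26)
        blob = build_blob(2000)
        center = blob.flat_index((0, 0, 0))
        for _ in range(4000):
            cells = CellPopulation()
            cells.add(np.array([center, center]))
            occ_backup = blob.occupancy.copy()
            blob.occupancy[center] = 2
            resolve_double_occupancy(blob, cells, tab, rng, order=np.array([0]))
            j = int(np.argmin(np.abs(blob.jump_offsets - (cells.position[0] - center))))
            counts[j] += 1
            blob.occupancy[:] = occ_backup
        chi2 = stats.chisquare(counts, expected * counts.sum())
        assert chi2.pvalue > 0.001


class TestCellPopulation:
    def test_add_remove_roundtrip(self):
        cells = CellPopulation()
        ids = cells.add(np.arange(5), k_e=1.5, tagged=True, entry_time=3.0)
        assert cells.n == 5
        assert np.array_equal(ids, np.arange(5))
        gone = cells.remove(np.array([True, False, True, False, False]))
        assert gone.n == 2 and cells.n == 3
        assert np.array_equal(gone.cell_id, [0, 2])
        assert np.all(gone.k_e == 1.5) and np.all(gone.tagged)

    def test_snapshot_export(self, tmp_path):
        blob = build_blob(50)
        frame = blob.snapshot()
        assert list(frame.columns) == ["x", "y", "z", "state", "occupancy"]
        assert len(frame) == 50
        path = tmp_path / "blob.tsv"
        frame.to_csv(path, sep="\t", index=False)
        assert path.read_text().startswith("x\ty\tz")
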