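"""Network construction: degrees, distances, delays, masks, serialization."""

import io

import numpy as np
import pytest
from scipy.stats import norm

from wcresonance import (
    ConnectivityConfig,
    LatticeSpec,
    SubnetworkMask,
    add_long_range_connections,
    apply_lateral_inhibition,
    assign_delays,
    build_local_connections,
    build_network,
    load_network,
    save_network,
    subnetwork_connectivity_stats,
    torus_distance,
)
from wcresonance.connectivity import Network


class TestTorusDistance:
    @pytest.mark.parametrize(
        "a,b,side,expected",
        [
            ((0, 0), (49, 0), 50, 1.0),  # wrap adjacency
            ((0, 0), (3, 4), 50, 5.0),
            ((0, 0), (25, 25), 50, 25 * np.sqrt(2)),  # farthest point
        ],
    )
    def test_values(self, a, b, side, expected):
        assert torus_distance(a, b, side) == pytest.approx(expected)

    def test_symmetry_vectorized(self, rng):
        a = rng.integers(0, 30, size=(100, 2))
        b = rng.integers(0, 30, size=(100, 2))
        assert np.allclose(
            torus_distance(a, b, 30), torus_distance(b, a, 30)
        )

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            torus_distance((0, 0), (50, 0), 50)


class TestLocalConnections:
    def test_zero_degree_empty(self, rng):
        spec = LatticeSpec(side=10)
        cfg = ConnectivityConfig(k_exc=0)
        edges = build_local_connections(spec, cfg, "exc", rng)
        assert len(edges) == 0

    def test_exact_degree_and_cutoff(self, rng):
        spec = LatticeSpec(side=50)
        cfg = ConnectivityConfig()
        edges = build_local_connections(spec, cfg, "exc", rng)
        deg = np.bincount(edges.src, minlength=spec.n_units)
        assert np.all(deg == cfg.k_exc)
        coords = spec.coords()
        dist = torus_distance(coords[edges.src], coords[edges.dst], spec.side)
        assert dist.max() <= cfg.cutoff / spec.spacing  # 14 lattice steps
        assert not np.any(edges.src == edges.dst)
        assert np.all(edges.weight == cfg.ce_strength)

    def test_offset_distribution_matches_rounded_gaussian(self, rng):
        """Accepted offsets follow the site-rounded truncated Gaussian.

        Oracle: exact probability mass of each integer offset under
        round-to-nearest-site Gaussian sampling, truncated at the cutoff;
        compared on radial annuli of the empirical distribution.
        """
        spec = LatticeSpec(side=60)
        cfg = ConnectivityConfig(k_exc=9)
        edges = build_local_connections(spec, cfg, "exc", rng)
        coords = spec.coords()
        # first accepted target per unit: free of the (mild) duplicate-
        # rejection depletion, so it follows the rounded Gaussian exactly
        first = slice(0, None, cfg.k_exc)
        radii = torus_distance(
            coords[edges.src[first]], coords[edges.dst[first]], spec.side
        )

        sigma = cfg.sigma_local / spec.spacing
        cut = cfg.cutoff / spec.spacing
        r = int(np.floor(cut))
        ii, jj = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1))
        cell = lambda i: norm.cdf((i + 0.5) / sigma) - norm.cdf((i - 0.5) / sigma)
        mass = cell(ii) * cell(jj)
        rad = np.hypot(ii, jj)
        ok = (rad > 0) & (rad <= cut)
        mass = np.where(ok, mass, 0.0)
        mass /= mass.sum()

        # half-integer edges: no integer-site radius sqrt(n) can fall on one
        bins = [0.5, 2.5, 4.5, 6.5, 8.5, 10.5, 14.5]
        expected = np.array(
            [mass[(rad >= lo) & (rad < hi)].sum() for lo, hi in zip(bins, bins[1:])]
        )
        observed = np.histogram(radii, bins=bins)[0] / len(radii)
        assert np.all(np.abs(observed - expected) < 0.02)

    def test_degree_exceeding_cutoff_sites_rejected(self, rng):
        spec = LatticeSpec(side=30, spacing=400.0)  # cutoff 700/400 -> r=1.75
        cfg = ConnectivityConfig(k_exc=9, sigma_local=250.0, cutoff=700.0)
        with pytest.raises(ValueError):
            build_local_connections(spec, cfg, "exc", rng)


class TestLongRange:
    def test_count_and_reach(self, rng):
        spec = LatticeSpec(side=50)
        cfg = ConnectivityConfig(seed=3)
        net = build_network(spec, cfg, delay_per_step=10.0)
        # 2500 units x 5 local exc edges x 25% -> 3125 long-range edges
        assert len(net.exc) == 2500 * 5 + 3125
        coords = spec.coords()
        lr = slice(2500 * 5, None)
        dist = torus_distance(
            coords[net.exc.src[lr]], coords[net.exc.dst[lr]], spec.side
        )
        assert dist.min() > cfg.cutoff / spec.spacing

    def test_small_lattice_cannot_host_long_range(self, rng):
        # a 10x10 torus has no pair farther apart than the 700 um cutoff
        spec = LatticeSpec(side=10)
        with pytest.raises(ValueError, match="long-range"):
            build_network(spec, ConnectivityConfig(seed=1), 10.0)

    def test_zero_fraction_unchanged(self, rng):
        spec = LatticeSpec(side=10)
        cfg = ConnectivityConfig(long_range_fraction=0.0)
        exc = build_local_connections(spec, cfg, "exc", rng)
        net = Network(spec, exc, exc.copy())
        n_before = len(net.exc)
        add_long_range_connections(net, cfg, rng)
        assert len(net.exc) == n_before


class TestDelays:
    def test_proportional_to_distance(self, tiny_network):
        spec = tiny_network.spec
        coords = spec.coords()
        for edges in (tiny_network.exc, tiny_network.inh):
            dist = torus_distance(coords[edges.src], coords[edges.dst], spec.side)
            assert np.array_equal(
                edges.delay_steps, np.floor(3.0 * dist + 0.5).astype(int)
            )

    def test_zero_rate_gives_zero_delays(self, rng):
        spec = LatticeSpec(side=30)
        net = build_network(spec, ConnectivityConfig(seed=5), delay_per_step=0.0)
        assert np.all(net.exc.delay_steps == 0)
        assert np.all(net.inh.delay_steps == 0)

    def test_round_half_away_from_zero(self, rng):
        # distance 5 at 0.1 steps/unit -> 0.5 -> rounds to 1, not banker's 0
        spec = LatticeSpec(side=20)
        exc = build_local_connections(
            spec, ConnectivityConfig(k_exc=3), "exc", rng
        )
        net = Network(spec, exc, exc.copy())
        assign_delays(net, 0.1)
        coords = spec.coords()
        dist = torus_distance(coords[net.exc.src], coords[net.exc.dst], spec.side)
        at_half = np.isclose(0.1 * dist, 0.5)
        if at_half.any():
            assert np.all(net.exc.delay_steps[at_half] == 1)


class TestLateralInhibition:
    def test_full_mask_is_identity(self, medium_network):
        net = medium_network.copy()
        before = (net.exc.weight.copy(), net.inh.weight.copy())
        apply_lateral_inhibition(net, SubnetworkMask.full(net.spec))
        assert np.array_equal(net.exc.weight, before[0])
        assert np.array_equal(net.inh.weight, before[1])

    def test_boundary_edge_census(self, medium_network):
        net = medium_network.copy()
        mask = SubnetworkMask.centred_square(net.spec, 10)
        m = mask.member
        exc_cross = int((m[net.exc.src] & ~m[net.exc.dst]).sum())
        inh_cross = int((m[net.inh.src] & ~m[net.inh.dst]).sum())
        apply_lateral_inhibition(net, mask)
        assert int((net.exc.weight == 0).sum()) == exc_cross
        assert int((net.inh.weight == 1.0).sum()) == inh_cross
        # outward excitation fully silenced
        assert net.exc.weight[m[net.exc.src] & ~m[net.exc.dst]].sum() == 0.0


class TestSubnetworkStats:
    def test_full_lattice_edge_conservation(self, medium_network):
        deg, _ = subnetwork_connectivity_stats(
            medium_network, SubnetworkMask.full(medium_network.spec)
        )
        total = len(medium_network.exc) + len(medium_network.inh)
        assert deg == pytest.approx(total / medium_network.n_units)
        # k_exc * (1 + fraction) + k_inh
        assert deg == pytest.approx(5 * 1.25 + 5)

    def test_single_unit_has_no_internal_edges(self, medium_network):
        mask = SubnetworkMask.centred_square(medium_network.spec, 1)
        deg, delay = subnetwork_connectivity_stats(medium_network, mask)
        assert deg == 0.0
        assert np.isnan(delay)

    def test_monotone_in_mask_side(self, medium_network):
        sides = [2, 6, 10, 20, 30]
        degs, delays = [], []
        for s in sides:
            d, dl = subnetwork_connectivity_stats(
                medium_network, SubnetworkMask.centred_square(medium_network.spec, s)
            )
            degs.append(d)
            delays.append(dl)
        assert np.all(np.diff(degs) >= 0)
        assert np.all(np.diff(np.nan_to_num(delays)) >= 0)


class TestReproducibilityAndIO:
    def test_fixed_seed_bit_identical(self):
        spec = LatticeSpec(side=30)
        a = build_network(spec, ConnectivityConfig(seed=42), 10.0)
        b = build_network(spec, ConnectivityConfig(seed=42), 10.0)
        for ea, eb in [(a.exc, b.exc), (a.inh, b.inh)]:
            assert np.array_equal(ea.src, eb.src)
            assert np.array_equal(ea.dst, eb.dst)
            assert np.array_equal(ea.weight, eb.weight)
            assert np.array_equal(ea.delay_steps, eb.delay_steps)

    def test_roundtrip_exact(self, tiny_network):
        buf = io.StringIO()
        save_network(tiny_network, buf)
        buf.seek(0)
        loaded = load_network(buf)
        assert loaded.spec == tiny_network.spec
        for ea, eb in [(tiny_network.exc, loaded.exc), (tiny_network.inh, loaded.inh)]:
            assert np.array_equal(ea.src, eb.src)
            assert np.array_equal(ea.dst, eb.dst)
            assert np.array_equal(ea.weight, eb.weight)
            assert np.array_equal(ea.delay_steps, eb.delay_steps)
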