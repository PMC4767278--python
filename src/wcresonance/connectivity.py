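"""Lattice network construction for the cortical-sheet model.

Units sit on a two-dimensional square lattice with periodic boundary
conditions (a torus), one unit per ~50 um minicolumn.  Each unit makes a
fixed number of *local* excitatory and inhibitory out-connections whose
targets are drawn from an isotropic Gaussian fall-off (SD 250 um, hard
cut-off 700 um), plus sparse *long-range* excitatory connections drawn
uniformly beyond the local cut-off.  Every edge carries an integer
transmission delay proportional to the torus (Euclidean, wrap-around)
distance between its endpoints.  Units are grouped into 10x10
"macrocolumns" that share a common noise source during simulation.

Edges are stored as flat arrays (source, target, weight, delay) — the
non-zero entries of the connectivity matrices CE (onto E populations) and
CI (onto I populations).  Excitatory edges connect E->E; inhibitory edges
connect the E population of the source to the I population of the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LatticeSpec",
    "ConnectivityConfig",
    "EdgeSet",
    "Network",
    "SubnetworkMask",
    "torus_distance",
    "build_local_connections",
    "add_long_range_connections",
    "assign_delays",
    "apply_lateral_inhibition",
    "subnetwork_connectivity_stats",
    "build_network",
    "save_network",
    "load_network",
]


@dataclass(frozen=True)
class LatticeSpec:
    """Geometry of the periodic lattice.

    ``side`` units per side, ``spacing`` micrometres between neighbouring
    units, macrocolumns of ``macrocolumn_side`` x ``macrocolumn_side``
    units (truncated at the lattice edge when it does not divide evenly).
    """

    side: int
    spacing: float = 50.0
    macrocolumn_side: int = 10
    periodic: bool = True

    def __post_init__(self) -> None:
        if self.side < 2:
            raise ValueError("lattice side must be >= 2")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.macrocolumn_side < 1:
            raise ValueError("macrocolumn side must be >= 1")

    @property
    def n_units(self) -> int:
        return self.side * self.side

    def unit_index(self, x, y):
        """Flat index of unit at lattice coordinates (x, y)."""
        return np.asarray(x) * self.side + np.asarray(y)

    def coords(self):
        """(n_units, 2) integer lattice coordinates in flat-index order."""
        xs, ys = np.divmod(np.arange(self.n_units), self.side)
        return np.column_stack([xs, ys])

    def macrocolumn_labels(self) -> np.ndarray:
        """Macrocolumn id per unit (row-major over macrocolumn blocks)."""
        xs, ys = np.divmod(np.arange(self.n_units), self.side)
        n_blocks = -(-self.side // self.macrocolumn_side)  # ceil
        return (xs // self.macrocolumn_side) * n_blocks + ys // self.macrocolumn_side


@dataclass(frozen=True)
class ConnectivityConfig:
    """Parameters of the random connectivity generator.

    ``sigma_local`` is the Gaussian SD of local connection offsets and
    ``cutoff`` the hard maximum reach, both in micrometres.  ``k_exc`` and
    ``k_inh`` are the exact local out-degrees per unit.  Long-range
    excitatory edges are added as ``long_range_fraction`` times the local
    excitatory edge count.  ``ce_strength`` / ``ci_strength`` are the
    entries written into CE / CI for generated edges.
    """

    sigma_local: float = 250.0
    cutoff: float = 700.0
    k_exc: int = 5
    k_inh: int = 5
    long_range_fraction: float = 0.25
    ce_strength: float = 0.15
    ci_strength: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.long_range_fraction <= 1.0:
            raise ValueError("long_range_fraction must be in [0, 1]")
        if self.cutoff < self.sigma_local:
            raise ValueError("cutoff must be >= sigma_local")
        if self.ce_strength < 0 or self.ci_strength < 0:
            raise ValueError("connection strengths must be non-negative")
        if self.k_exc < 0 or self.k_inh < 0:
            raise ValueError("out-degrees must be non-negative")


@dataclass
class EdgeSet:
    """Directed weighted edges with integer transmission delays."""

    src: np.ndarray  # int32 flat unit indices
    dst: np.ndarray
    weight: np.ndarray  # float64
    delay_steps: np.ndarray  # int32, integration steps

    @classmethod
    def empty(cls) -> "EdgeSet":
        return cls(
            np.empty(0, np.int32),
            np.empty(0, np.int32),
            np.empty(0, float),
            np.empty(0, np.int32),
        )

    def __len__(self) -> int:
        return len(self.src)

    def copy(self) -> "EdgeSet":
        return EdgeSet(
            self.src.copy(), self.dst.copy(), self.weight.copy(), self.delay_steps.copy()
        )


@dataclass
class Network:
    """A built lattice network: geometry plus excitatory/inhibitory edges."""

    spec: LatticeSpec
    exc: EdgeSet
    inh: EdgeSet
    macrocolumn_of: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.macrocolumn_of is None:
            self.macrocolumn_of = self.spec.macrocolumn_labels()

    @property
    def n_units(self) -> int:
        return self.spec.n_units

    def copy(self) -> "Network":
        return Network(self.spec, self.exc.copy(), self.inh.copy(), self.macrocolumn_of.copy())


@dataclass(frozen=True)
class SubnetworkMask:
    """Boolean membership mask over lattice units."""

    member: np.ndarray  # bool, length n_units

    def __post_init__(self) -> None:
        if not np.any(self.member):
            raise ValueError("mask must be non-empty")

    @classmethod
    def centred_square(cls, spec: LatticeSpec, side: int) -> "SubnetworkMask":
        """Centrally located ``side`` x ``side`` square of units."""
        if not 1 <= side <= spec.side:
            raise ValueError("mask side out of range")
        start = (spec.side - side) // 2
        member = np.zeros(spec.n_units, dtype=bool)
        xs, ys = np.divmod(np.arange(spec.n_units), spec.side)
        inside = (
            (xs >= start) & (xs < start + side) & (ys >= start) & (ys < start + side)
        )
        member[inside] = True
        return cls(member)

    @classmethod
    def full(cls, spec: LatticeSpec) -> "SubnetworkMask":
        return cls(np.ones(spec.n_units, dtype=bool))

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.member)

    @property
    def n_members(self) -> int:
        return int(self.member.sum())


def torus_distance(a, b, side: int):
    """Euclidean distance with per-axis wrap-around on a ``side``-periodic
    lattice.  ``a`` and ``b`` are coordinate pairs (or arrays of them) with
    components in ``[0, side)``; distance is in lattice steps.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a < 0) or np.any(a >= side) or np.any(b < 0) or np.any(b >= side):
        raise ValueError("coordinates out of range [0, side)")
    d = np.abs(a - b)
    d = np.minimum(d, side - d)
    dist = np.sqrt((d * d).sum(axis=-1))
    if dist.ndim == 0:
        return float(dist)
    return dist


def _sites_within_cutoff(cutoff_steps: float) -> int:
    """Number of integer offsets (dx, dy) != (0, 0) with radius <= cutoff."""
    r = int(np.floor(cutoff_steps))
    dx, dy = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1))
    inside = dx * dx + dy * dy <= cutoff_steps * cutoff_steps
    return int(inside.sum()) - 1


def build_local_connections(
    spec: LatticeSpec,
    cfg: ConnectivityConfig,
    kind: str,
    rng: np.random.Generator,
) -> EdgeSet:
    """Draw exactly-k local out-edges per unit with Gaussian fall-off.

    For every unit, offsets are drawn from an isotropic 2-D Gaussian with
    SD ``sigma_local/spacing`` lattice steps and rounded to the nearest
    lattice site.  Draws landing on the unit itself, duplicating an already
    accepted target, or farther than ``cutoff/spacing`` steps are rejected
    and redrawn, so the realized out-degree is exactly ``k_exc`` (for
    ``kind='exc'``) or ``k_inh`` (``'inh'``).
    """
    if kind not in ("exc", "inh"):
        raise ValueError("kind must be 'exc' or 'inh'")
    k = cfg.k_exc if kind == "exc" else cfg.k_inh
    strength = cfg.ce_strength if kind == "exc" else cfg.ci_strength
    if k == 0:
        return EdgeSet.empty()
    sigma_steps = cfg.sigma_local / spec.spacing
    cutoff_steps = cfg.cutoff / spec.spacing
    n_sites = _sites_within_cutoff(cutoff_steps)
    if k > n_sites:
        raise ValueError(
            f"requested out-degree {k} exceeds {n_sites} sites within cutoff"
        )
    side = spec.side
    n = spec.n_units
    src = np.repeat(np.arange(n, dtype=np.int32), k)
    dst = np.empty(n * k, dtype=np.int32)
    xs, ys = np.divmod(np.arange(n), side)
    chunk = max(4 * k, 16)
    for u in range(n):
        accepted: list[int] = []
        seen: set[int] = set()
        while len(accepted) < k:
            off = np.rint(rng.normal(0.0, sigma_steps, size=(chunk, 2))).astype(int)
            radius2 = (off * off).sum(axis=1)
            ok = (radius2 > 0) & (radius2 <= cutoff_steps * cutoff_steps)
            for dx, dy in off[ok]:
                tgt = ((xs[u] + dx) % side) * side + ((ys[u] + dy) % side)
                if tgt == u or tgt in seen:
                    continue  # wrap-around can fold an offset onto self/dup
                seen.add(tgt)
                accepted.append(tgt)
                if len(accepted) == k:
                    break
        dst[u * k : (u + 1) * k] = accepted
    weight = np.full(n * k, strength, dtype=float)
    delay = np.zeros(n * k, dtype=np.int32)
    return EdgeSet(src, dst, weight, delay)


def add_long_range_connections(
    network: Network,
    cfg: ConnectivityConfig,
    rng: np.random.Generator,
    n_edges: int | None = None,
) -> Network:
    """Add sparse uniform long-range excitatory edges (in place).

    The number added is ``round(long_range_fraction * len(local exc
    edges))`` unless ``n_edges`` overrides it (the degree-scan protocols
    hold the long-range count fixed while the local degree varies).
    Source and target are drawn uniformly over units; self-edges,
    duplicates and targets within the local cutoff radius of the source
    are rejected, so "long-range" is well defined.
    """
    if n_edges is None:
        n_edges = int(round(cfg.long_range_fraction * len(network.exc)))
    if n_edges == 0:
        return network
    spec = network.spec
    cutoff_steps = cfg.cutoff / spec.spacing
    # wrapped offsets reachable beyond the cutoff bound the edge budget
    off = np.arange(spec.side)
    wrapped = np.minimum(off, spec.side - off)
    d2 = wrapped[:, None] ** 2 + wrapped[None, :] ** 2
    n_far = int((d2 > cutoff_steps**2).sum())
    if n_edges > 0.8 * n_far * spec.n_units:
        raise ValueError(
            "lattice too small: not enough site pairs beyond the local "
            "cutoff to place the requested long-range connections"
        )
    coords = spec.coords()
    accepted_src: list[int] = []
    accepted_dst: list[int] = []
    seen: set[tuple[int, int]] = set()
    while len(accepted_src) < n_edges:
        m = 2 * (n_edges - len(accepted_src)) + 16
        s = rng.integers(0, spec.n_units, size=m)
        t = rng.integers(0, spec.n_units, size=m)
        dist = torus_distance(coords[s], coords[t], spec.side)
        ok = (s != t) & (dist > cutoff_steps)
        for si, ti in zip(s[ok], t[ok]):
            key = (int(si), int(ti))
            if key in seen:
                continue
            seen.add(key)
            accepted_src.append(int(si))
            accepted_dst.append(int(ti))
            if len(accepted_src) == n_edges:
                break
    exc = network.exc
    network.exc = EdgeSet(
        np.concatenate([exc.src, np.asarray(accepted_src, np.int32)]),
        np.concatenate([exc.dst, np.asarray(accepted_dst, np.int32)]),
        np.concatenate([exc.weight, np.full(n_edges, cfg.ce_strength)]),
        np.concatenate([exc.delay_steps, np.zeros(n_edges, np.int32)]),
    )
    return network


def assign_delays(network: Network, delay_per_step: float) -> Network:
    """Set every edge delay to ``round(delay_per_step * torus distance)``.

    ``delay_per_step`` is in integration steps per lattice step; rounding
    is half-away-from-zero.  ``delay_per_step = 0`` gives instantaneous
    transmission on every edge.
    """
    if delay_per_step < 0:
        raise ValueError("delay_per_step must be non-negative")
    coords = network.spec.coords()
    for edges in (network.exc, network.inh):
        if len(edges) == 0:
            continue
        dist = torus_distance(coords[edges.src], coords[edges.dst], network.spec.side)
        edges.delay_steps = np.floor(delay_per_step * dist + 0.5).astype(np.int32)
    return network


def apply_lateral_inhibition(network: Network, mask: SubnetworkMask) -> Network:
    """Suppress the surround of an activated patch (in place).

    Every existing excitatory edge from inside the mask to outside gets
    weight 0; every existing inhibitory edge with the same orientation gets
    weight 1 (maximal CI entry).  No new edges are created and edges in any
    other orientation are untouched.
    """
    m = mask.member
    exc_cross = m[network.exc.src] & ~m[network.exc.dst]
    inh_cross = m[network.inh.src] & ~m[network.inh.dst]
    network.exc.weight[exc_cross] = 0.0
    network.inh.weight[inh_cross] = 1.0
    return network


def subnetwork_connectivity_stats(network: Network, mask: SubnetworkMask):
    """Mean node degree and mean transmission delay inside a sub-network.

    Only edges with **both** endpoints inside the mask count.  Mean degree
    is the internal edge count (excitatory plus inhibitory) divided by the
    number of member units; mean delay is averaged over those edges (NaN
    when the sub-network contains no internal edges).
    """
    m = mask.member
    if not np.any(m):
        raise ValueError("empty mask")
    n_members = int(m.sum())
    count = 0
    delay_sum = 0.0
    for edges in (network.exc, network.inh):
        inside = m[edges.src] & m[edges.dst]
        count += int(inside.sum())
        delay_sum += float(edges.delay_steps[inside].sum())
    mean_degree = count / n_members
    mean_delay = delay_sum / count if count else float("nan")
    return mean_degree, mean_delay


def build_network(
    spec: LatticeSpec,
    cfg: ConnectivityConfig,
    delay_per_step: float = 10.0,
    n_long_range: int | None = None,
) -> Network:
    """Build a complete network: local edges, long-range edges, delays.

    All randomness comes from a generator seeded with ``cfg.seed``, so a
    fixed configuration reproduces the network bit-for-bit.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    exc = build_local_connections(spec, cfg, "exc", rng)
    inh = build_local_connections(spec, cfg, "inh", rng)
    net = Network(spec, exc, inh)
    add_long_range_connections(net, cfg, rng, n_edges=n_long_range)
    assign_delays(net, delay_per_step)
    return net


# ---------------------------------------------------------------------------
# Plain-text serialization: one edge per line, header with the lattice spec.


def save_network(network: Network, path_or_buf) -> None:
    """Write a network as a documented edge-list text file.

    Header lines carry the lattice spec; each edge line is
    ``src_x src_y dst_x dst_y kind weight delay_steps``.  Weights use
    17 significant digits so the file round-trips bit-exactly.
    """
    spec = network.spec
    own = isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__")
    fh = open(path_or_buf, "w") if own else path_or_buf
    try:
        fh.write(
            f"# wcresonance network side={spec.side} spacing={spec.spacing!r} "
            f"macrocolumn_side={spec.macrocolumn_side}\n"
        )
        fh.write("# src_x src_y dst_x dst_y kind weight delay_steps\n")
        side = spec.side
        for kind, edges in (("exc", network.exc), ("inh", network.inh)):
            for s, d, w, dl in zip(edges.src, edges.dst, edges.weight, edges.delay_steps):
                fh.write(
                    f"{s // side} {s % side} {d // side} {d % side} "
                    f"{kind} {w:.17g} {dl}\n"
                )
    finally:
        if own:
            fh.close()


def load_network(path_or_buf) -> Network:
    """Read a network written by :func:`save_network`."""
    own = isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__")
    fh = open(path_or_buf) if own else path_or_buf
    try:
        header = fh.readline()
        if "wcresonance network" not in header:
            raise ValueError("not a wcresonance network file")
        fields = dict(
            tok.split("=") for tok in header.split() if "=" in tok
        )
        spec = LatticeSpec(
            side=int(fields["side"]),
            spacing=float(fields["spacing"]),
            macrocolumn_side=int(fields["macrocolumn_side"]),
        )
        data: dict[str, list] = {"exc": [], "inh": []}
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            sx, sy, dx, dy, kind, w, dl = line.split()
            data[kind].append(
                (
                    int(sx) * spec.side + int(sy),
                    int(dx) * spec.side + int(dy),
                    float(w),
                    int(dl),
                )
            )
    finally:
        if own:
            fh.close()

    def to_edges(rows) -> EdgeSet:
        if not rows:
            return EdgeSet.empty()
        arr = np.array(rows, dtype=object)
        return EdgeSet(
            np.array([r[0] for r in rows], np.int32),
            np.array([r[1] for r in rows], np.int32),
            np.array([r[2] for r in rows], float),
            np.array([r[3] for r in rows], np.int32),
        )

    return Network(spec, to_edges(data["exc"]), to_edges(data["inh"]))
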