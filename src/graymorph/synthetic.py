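"""Synthetic brain-cell generator with exact ground truth.

Builds SWC reconstructions whose morphology is known by construction — a
spherical soma with N primary projections, branching to a set depth, with
log-normal branch lengths, sinusoidal radius beading, optional taper,
planar-sinusoid undulation, Watson-distributed projection orientations,
optional Z-axis compression (depth-of-field artifact), optional explicit
dendritic spines, and an optional axonal subtree.  Every generated cell is
paired with a :class:`GroundTruth` holding the true feature values, so
each pipeline stage can be validated by parameter recovery without any
external data.

Randomness is a single stream per cell consumed in a documented, fixed
order (projection direction; then per branch depth-first: length,
undulation azimuth, beading phase, bifurcation plane; then spines; then
the axon), so enabling a later feature never perturbs earlier draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .swc import CellReconstruction, SwcNode, SOMA, AXON, BASAL_DENDRITE

__all__ = [
    "SyntheticCellSpec",
    "GroundTruth",
    "generate_cell",
    "generate_population",
    "z_compress",
    "sample_watson",
]


@dataclass
class SyntheticCellSpec:
    """Generator parameters; defaults emulate a typical cortical neuron.

    Lengths in µm, angles in rad.  ``branching_depth`` is the number of
    consecutive bifurcations per projection, so the branch order reaches
    ``branching_depth + 1``.
    """

    soma_radius: float = 5.0
    n_projections: int = 7
    branching_depth: int = 2
    branch_length_median: float = 54.0
    branch_length_sigma: float = 0.35     # lognormal sigma (dimensionless)
    base_radius: float = 0.6
    taper_rate: float = 0.45              # fractional radius loss per branch
    beading_amplitude: float = 0.12       # µm, sinusoidal radius modulation
    beading_wavelength: float = 10.0
    undulation_amplitude: float = 3.0     # µm, planar sinusoid about the chord
    undulation_wavelength: float = 30.0
    orientation_kappa: float | None = 2.0 # Watson concentration; None = isotropic
    orientation_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    bifurcation_angle: float = math.radians(60.0)
    node_spacing: float = 2.0
    z_compression: float = 1.0
    spine_density: float = 0.0            # spines per µm of branch path
    spine_neck_radius: float = 0.06
    spine_neck_length: float = 1.0
    spine_head_radius: float = 0.25
    with_axon: bool = False

    def __post_init__(self) -> None:
        if self.branch_length_median < 2 * self.node_spacing:
            raise ValueError("branch length below twice the node spacing")
        if not 0 < self.z_compression <= 1:
            raise ValueError("z_compression must be in (0, 1]")
        for name in ("soma_radius", "base_radius", "node_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GroundTruth:
    """True feature values implied by the generated geometry."""

    soma_radius: float
    n_projections: int
    expected_BO: int
    branch_lengths: list[float] = field(default_factory=list)
    branch_mean_radii: list[float] = field(default_factory=list)
    branch_tau: list[float] = field(default_factory=list)
    branch_muOD: list[float] = field(default_factory=list)
    beading_cv: float = 0.0               # a / (r sqrt(2)); beading only, no taper
    bifurcation_angle: float = math.nan
    orientation_kappa: float | None = None
    projection_directions: list[tuple[float, float, float]] = field(
        default_factory=list
    )
    n_spines: int = 0
    n_axon_nodes: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Watson sampling


def sample_watson(
    rng: np.random.Generator,
    kappa: float,
    axis: np.ndarray,
    n: int,
) -> np.ndarray:
    """Draw axial unit vectors from a bipolar Watson distribution.

    Sampling is by numerical inverse-CDF on t = cos(theta) with density
    proportional to exp(kappa t²); kappa = 0 reduces to the uniform sphere.
    """
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    grid = np.linspace(-1.0, 1.0, 4001)
    logw = kappa * grid**2
    w = np.exp(logw - logw.max())
    cdf = np.concatenate([[0.0], np.cumsum((w[1:] + w[:-1]) * 0.5)])
    cdf /= cdf[-1]
    t = np.interp(rng.random(n), cdf, grid)
    phi = rng.random(n) * 2.0 * math.pi
    # orthonormal frame around the axis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    s = np.sqrt(np.clip(1.0 - t**2, 0.0, None))
    return (
        t[:, None] * axis
        + (s * np.cos(phi))[:, None] * e1
        + (s * np.sin(phi))[:, None] * e2
    )


# ---------------------------------------------------------------------------
# branch path construction


def _perp_frame(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(d @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2


def _undulated_path(
    start: np.ndarray,
    direction: np.ndarray,
    L: float,
    amplitude: float,
    wavelength: float,
    azimuth: float,
    spacing: float,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Unit-arc-length sampled sinusoidal path of total arc length L.

    Returns (points, end_tangent, true_tau, true_muOD) where the truths
    are evaluated on the continuous curve, not the sampled polyline.
    """
    d = direction / np.linalg.norm(direction)
    if amplitude <= 0:
        n = max(2, int(math.ceil(L / spacing)) + 1)
        s = np.linspace(0.0, L, n)
        pts = start + s[:, None] * d
        return pts, d, 1.0, 0.0
    e1, e2 = _perp_frame(d)
    perp = math.cos(azimuth) * e1 + math.sin(azimuth) * e2
    k = 2.0 * math.pi / wavelength

    # dense parametrisation; arc length of x(t) = start + t d + A sin(kt) perp
    t_grid = np.linspace(0.0, L, 4000)
    speed = np.sqrt(1.0 + (amplitude * k * np.cos(k * t_grid)) ** 2)
    arc = np.concatenate(
        [[0.0], np.cumsum((speed[1:] + speed[:-1]) * 0.5 * np.diff(t_grid))]
    )
    n = max(2, int(math.ceil(L / spacing)) + 1)
    s_nodes = np.linspace(0.0, L, n)
    t_nodes = np.interp(s_nodes, arc, t_grid)
    pts = (
        start
        + t_nodes[:, None] * d
        + (amplitude * np.sin(k * t_nodes))[:, None] * perp
    )
    T = t_nodes[-1]
    tangent = d + amplitude * k * math.cos(k * T) * perp
    tangent /= np.linalg.norm(tangent)

    # continuous-curve ground truths
    chord_vec = T * d + amplitude * math.sin(k * T) * perp
    tau = float(np.linalg.norm(chord_vec) / L)
    chord_hat = chord_vec / np.linalg.norm(chord_vec)
    tang = d[None, :] + (amplitude * k * np.cos(k * t_grid))[:, None] * perp
    tang /= np.linalg.norm(tang, axis=1)[:, None]
    ang = np.arccos(np.clip(tang @ chord_hat, -1.0, 1.0))
    mu_od = float(np.trapezoid(ang * speed, t_grid) / arc[-1])
    return pts, tangent, tau, mu_od


# ---------------------------------------------------------------------------
# cell assembly


class _Builder:
    def __init__(self) -> None:
        self.nodes: dict[int, SwcNode] = {}
        self.order: list[int] = []
        self._next = 1

    def add(self, tcode, xyz, radius, parent) -> int:
        nid = self._next
        self._next += 1
        self.nodes[nid] = SwcNode(
            nid, tcode, float(xyz[0]), float(xyz[1]), float(xyz[2]),
            float(radius), parent,
        )
        self.order.append(nid)
        return nid


def _grow_branch(
    b: _Builder,
    spec: SyntheticCellSpec,
    gt: GroundTruth,
    rng: np.random.Generator,
    start: np.ndarray,
    direction: np.ndarray,
    parent_id: int,
    r_start: float,
    depth_left: int,
) -> None:
    mu = math.log(spec.branch_length_median)
    L = float(np.exp(rng.normal(mu, spec.branch_length_sigma)))
    L = max(L, 2.0 * spec.node_spacing)
    azimuth = rng.random() * 2.0 * math.pi
    bead_phase = rng.random() * 2.0 * math.pi

    pts, end_tangent, tau, mu_od = _undulated_path(
        start, direction, L,
        spec.undulation_amplitude, spec.undulation_wavelength,
        azimuth, spec.node_spacing,
    )
    n = len(pts)
    s = np.linspace(0.0, L, n)
    radii = r_start * (1.0 - spec.taper_rate * s / L)
    radii = radii + spec.beading_amplitude * np.sin(
        2.0 * math.pi * s / spec.beading_wavelength + bead_phase
    )
    radii = np.clip(radii, 0.05, None)

    pid = parent_id
    node_ids = []
    for i in range(1, n):  # pts[0] coincides with the parent node
        pid = b.add(BASAL_DENDRITE, pts[i], radii[i], pid)
        node_ids.append(pid)

    gt.branch_lengths.append(L)
    gt.branch_mean_radii.append(float(np.mean(radii)))
    gt.branch_tau.append(tau)
    gt.branch_muOD.append(mu_od)

    if depth_left > 0:
        plane_az = rng.random() * 2.0 * math.pi
        e1, e2 = _perp_frame(end_tangent)
        perp = math.cos(plane_az) * e1 + math.sin(plane_az) * e2
        half = spec.bifurcation_angle / 2.0
        for sign in (+1.0, -1.0):
            d_new = math.cos(half) * end_tangent + sign * math.sin(half) * perp
            _grow_branch(
                b, spec, gt, rng, pts[-1], d_new, pid,
                float(radii[-1]), depth_left - 1,
            )


def _add_spines(
    b: _Builder, spec: SyntheticCellSpec, gt: GroundTruth,
    rng: np.random.Generator,
) -> None:
    """Explicit spines: neck + head nodes on interior dendritic nodes."""
    if spec.spine_density <= 0:
        return
    children: dict[int, list[int]] = {nid: [] for nid in b.nodes}
    for nid in b.order:
        n = b.nodes[nid]
        if n.parent_id is not None:
            children[n.parent_id].append(nid)
    interval = 1.0 / spec.spine_density
    # walk dendritic nodes in creation order, dropping a spine whenever the
    # accumulated path exceeds the next multiple of the spacing interval
    acc = 0.0
    next_at = interval
    for nid in list(b.order):
        n = b.nodes[nid]
        if n.type_code != BASAL_DENDRITE or n.parent_id is None:
            continue
        parent = b.nodes[n.parent_id]
        if parent.type_code != BASAL_DENDRITE:
            continue
        acc += float(np.linalg.norm(n.xyz - parent.xyz))
        if acc < next_at:
            continue
        # attach only where the dendrite clearly continues (>= 3 further
        # edges), so the continuing tail can never look spine-like itself
        tail, depth = nid, 0
        while children.get(tail) and depth < 3:
            tail = children[tail][0]
            depth += 1
        if depth < 3:
            continue
        next_at += interval
        seg = n.xyz - parent.xyz
        seg /= np.linalg.norm(seg)
        e1, e2 = _perp_frame(seg)
        az = rng.random() * 2.0 * math.pi
        out = math.cos(az) * e1 + math.sin(az) * e2
        neck = b.add(
            BASAL_DENDRITE, n.xyz + out * spec.spine_neck_length,
            spec.spine_neck_radius, nid,
        )
        b.add(
            BASAL_DENDRITE,
            n.xyz + out * (spec.spine_neck_length + 2 * spec.spine_head_radius),
            spec.spine_head_radius, neck,
        )
        gt.n_spines += 1


def generate_cell(
    spec: SyntheticCellSpec, seed: int | np.random.SeedSequence
) -> tuple[CellReconstruction, GroundTruth]:
    """Generate one cell; deterministic given (spec, seed)."""
    rng = np.random.default_rng(seed)
    b = _Builder()
    gt = GroundTruth(
        soma_radius=spec.soma_radius,
        n_projections=spec.n_projections,
        expected_BO=spec.branching_depth + 1,
        beading_cv=(
            spec.beading_amplitude / (spec.base_radius * math.sqrt(2.0))
            if spec.beading_amplitude > 0 else 0.0
        ),
        bifurcation_angle=(
            spec.bifurcation_angle if spec.branching_depth > 0 else math.nan
        ),
        orientation_kappa=spec.orientation_kappa,
    )

    root = b.add(SOMA, np.zeros(3), spec.soma_radius, None)

    if spec.orientation_kappa is None:
        dirs = sample_watson(rng, 0.0, np.array([0.0, 0.0, 1.0]),
                             spec.n_projections)
    else:
        dirs = sample_watson(
            rng, spec.orientation_kappa,
            np.asarray(spec.orientation_axis, float), spec.n_projections,
        )
    gt.projection_directions = [tuple(map(float, d)) for d in dirs]

    # first projection node sits just outside the soma threshold so the
    # entry stub created by the soma split has negligible length
    offset = 0.01
    for d in dirs:
        first_xyz = d * (spec.soma_radius + offset)
        first = b.add(BASAL_DENDRITE, first_xyz, spec.base_radius, root)
        _grow_branch(
            b, spec, gt, rng, first_xyz, d, first,
            spec.base_radius, spec.branching_depth,
        )

    _add_spines(b, spec, gt, rng)

    if spec.with_axon:
        d = sample_watson(rng, 0.0, np.array([0.0, 0.0, 1.0]), 1)[0]
        pid = root
        xyz = d * (spec.soma_radius + offset)
        for i in range(30):
            pid = b.add(AXON, xyz, 0.4, pid)
            xyz = xyz + d * spec.node_spacing
        gt.n_axon_nodes = 30

    cell = CellReconstruction(
        nodes=b.nodes, root_id=root,
        metadata={"node_order": b.order, "synthetic": True},
    )
    if spec.z_compression < 1.0:
        cell = z_compress(cell, spec.z_compression)
    return cell, gt


def generate_population(
    spec: SyntheticCellSpec, n: int, seed: int
) -> list[tuple[CellReconstruction, GroundTruth]]:
    """n independent cells with per-cell seeds derived from the master seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [generate_cell(spec, child) for child in children]


def z_compress(cell: CellReconstruction, factor: float) -> CellReconstruction:
    """Scale all z-coordinates by ``factor`` (radii untouched).

    Emulates the depth-of-field artifact of optical reconstructions, which
    flattens cells along the axis perpendicular to the acquisition plane.
    """
    if not 0 < factor <= 1:
        raise ValueError("compression factor must be in (0, 1]")
    out = cell.copy()
    for node in out.nodes.values():
        node.z *= factor
    return out
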