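"""Skeletal-motion data model, kinematic differentiation, and joint energy.

A motion record is a uniformly sampled tensor of joint positions,
``T frames x J joints x D coordinates`` (meters, seconds). From it the
package derives velocity, acceleration and jerk by finite differences, and
the per-joint mechanical energy

    E_t^j = 1/2 m_j ||v_t^j||^2 + m_j g h_t^j,

the composite signal on which the anomaly scoring in :mod:`motionsentry.biomech`
operates. The skeleton is an undirected anatomical graph whose symmetric
degree-normalized adjacency D^{-1/2} A D^{-1/2} drives the graph encoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GRAVITY = 9.81  # m/s^2
DEFAULT_TOTAL_MASS = 70.0  # kg, split uniformly across joints unless overridden
DEFAULT_FRAME_RATE = 25.0  # Hz; 2-3 s of motion = 50-75 frames
_DT_TOL = 1e-9


@dataclass
class MotionSequence:
    """Uniformly sampled joint positions with skeleton metadata."""

    times: np.ndarray  # (T,) seconds, strictly increasing, uniform
    positions: np.ndarray  # (T, J, D) meters
    joint_names: list[str]
    vertical_axis: int = -1

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3:
            raise ValueError("positions must be a T x J x D array")
        T, J, D = self.positions.shape
        if self.times.shape != (T,):
            raise ValueError("times length must match the number of frames")
        if T < 1:
            raise ValueError("a sequence needs at least one frame")
        if len(self.joint_names) != J:
            raise ValueError("joint_names length must match the joint axis")
        if self.vertical_axis < 0:
            self.vertical_axis += D
        if not 0 <= self.vertical_axis < D:
            raise ValueError(f"vertical_axis out of range for D={D}")
        if T > 1:
            dts = np.diff(self.times)
            dt = dts[0]
            bad = np.nonzero(np.abs(dts - dt) > _DT_TOL)[0]
            if dt <= 0:
                raise ValueError("times must be strictly increasing")
            if bad.size:
                raise ValueError(
                    f"non-uniform sampling at frame {bad[0] + 1}: "
                    f"dt={dts[bad[0]]:.6g} vs {dt:.6g}"
                )
        if not np.isfinite(self.positions).all():
            raise ValueError("positions contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_joints(self) -> int:
        return self.positions.shape[1]

    @property
    def n_dims(self) -> int:
        return self.positions.shape[2]

    @property
    def dt(self) -> float:
        if self.n_frames < 2:
            return 1.0 / DEFAULT_FRAME_RATE
        return float(self.times[1] - self.times[0])

    @property
    def frame_rate(self) -> float:
        return 1.0 / self.dt

    def heights(self) -> np.ndarray:
        """Vertical coordinate of every joint, (T, J)."""
        return self.positions[:, :, self.vertical_axis]


@dataclass
class KinematicFeatures:
    """Velocity, acceleration, jerk — all (T, J, D), zero-filled leading frames."""

    velocity: np.ndarray
    acceleration: np.ndarray
    jerk: np.ndarray


@dataclass
class SkeletonGraph:
    """Joints, anatomical edges, normalized adjacency, per-joint masses."""

    n_joints: int
    edges: list[tuple[int, int]]
    adjacency: np.ndarray  # (J, J) binary symmetric, zero diagonal
    normalized_adjacency: np.ndarray  # (J, J)
    masses: np.ndarray  # (J,) kg, all > 0
    joint_names: list[str] = field(default_factory=list)
    self_loops: bool = True
    sensor_map: dict = field(default_factory=dict)

    @property
    def degree(self) -> np.ndarray:
        return np.diag(self.adjacency.sum(axis=1))

    def neighborhoods(self) -> np.ndarray:
        """(J, J) boolean mask; N_i = graph neighbors of i plus i itself."""
        return (self.adjacency + np.eye(self.n_joints)) > 0


@dataclass
class EnergyProfile:
    """Per-joint mechanical energy and the heights used for its potential term."""

    energy: np.ndarray  # (T, J) joules
    heights: np.ndarray  # (T, J) meters above the ground reference
    gravity: float = GRAVITY


def compute_kinematics(seq: MotionSequence) -> KinematicFeatures:
    """First, second and third finite differences of the joint positions.

    The backward difference v_t = (x_t - x_{t-1}) / dt is defined from the
    second frame on; the undefined leading frame of each derivative order is
    zero-filled so every tensor keeps length T.
    """
    dt = seq.dt

    def diff(x: np.ndarray) -> np.ndarray:
        out = np.zeros_like(x)
        if x.shape[0] > 1:
            out[1:] = (x[1:] - x[:-1]) / dt
        return out

    v = diff(seq.positions)
    a = diff(v)
    jk = diff(a)
    return KinematicFeatures(velocity=v, acceleration=a, jerk=jk)


def composite_features(
    seq: MotionSequence, kin: KinematicFeatures, include_jerk: bool = False
) -> np.ndarray:
    """Per-joint concatenation [x, v, a] (or [x, v, a, jerk]), (T, J, 3D or 4D)."""
    parts = [seq.positions, kin.velocity, kin.acceleration]
    if include_jerk:
        parts.append(kin.jerk)
    shapes = {p.shape for p in parts}
    if len(shapes) != 1:
        raise ValueError(f"kinematic tensors disagree in shape: {sorted(shapes)}")
    return np.concatenate(parts, axis=2)


def build_graph(
    edges,
    n_joints: int,
    masses=None,
    self_loops: bool = True,
    joint_names=None,
    sensor_map=None,
) -> SkeletonGraph:
    """Build a skeleton graph with symmetric degree-normalized adjacency.

    With ``self_loops`` (default) the normalization is applied to A + I, the
    standard renormalization that keeps each joint's own features in the
    aggregation and leaves every degree positive. ``self_loops=False`` gives
    the bare D^{-1/2} A D^{-1/2}; it rejects isolated joints, whose degree
    would be zero.
    """
    A = np.zeros((n_joints, n_joints))
    edge_list: list[tuple[int, int]] = []
    for i, j in edges:
        i, j = int(i), int(j)
        if not (0 <= i < n_joints and 0 <= j < n_joints):
            raise ValueError(f"edge ({i}, {j}) out of range for J={n_joints}")
        if i == j:
            raise ValueError(f"self-edge ({i}, {i}) not allowed; use self_loops")
        if A[i, j] == 0:
            edge_list.append((min(i, j), max(i, j)))
        A[i, j] = A[j, i] = 1.0

    A_norm_src = A + np.eye(n_joints) if self_loops else A
    deg = A_norm_src.sum(axis=1)
    if np.any(deg == 0):
        bad = int(np.nonzero(deg == 0)[0][0])
        raise ValueError(
            f"joint {bad} is isolated; its degree is 0 and D^(-1/2) is undefined "
            "(enable self_loops or connect it)"
        )
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    A_hat = A_norm_src * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]

    if masses is None:
        masses = np.full(n_joints, DEFAULT_TOTAL_MASS / n_joints)
    masses = np.asarray(masses, dtype=float)
    if masses.shape != (n_joints,):
        raise ValueError("masses must have one entry per joint")
    if np.any(masses <= 0):
        raise ValueError("all joint masses must be positive")

    return SkeletonGraph(
        n_joints=n_joints,
        edges=edge_list,
        adjacency=A,
        normalized_adjacency=A_hat,
        masses=masses,
        joint_names=list(joint_names) if joint_names else [],
        self_loops=self_loops,
        sensor_map=dict(sensor_map) if sensor_map else {},
    )


def total_energy(
    kin: KinematicFeatures,
    seq: MotionSequence,
    graph: SkeletonGraph,
    gravity: float = GRAVITY,
    ground: float | None = None,
    baseline_window: int = 50,
) -> EnergyProfile:
    """Per-joint mechanical energy, kinetic + gravitational potential.

    Heights are referenced so the lowest vertical coordinate observed over the
    leading ``baseline_window`` frames sits at 0 (guaranteeing nonnegative
    energy during normal motion); pass ``ground`` to pin a fixed plane instead.
    """
    if np.any(graph.masses <= 0):
        raise ValueError("all joint masses must be positive")
    if graph.n_joints != seq.n_joints:
        raise ValueError("skeleton and sequence disagree on joint count")
    raw_h = seq.heights()
    if ground is None:
        w = min(seq.n_frames, baseline_window)
        ground = float(raw_h[:w].min())
    h = raw_h - ground
    speed_sq = np.sum(kin.velocity**2, axis=2)  # (T, J)
    m = graph.masses[None, :]
    energy = 0.5 * m * speed_sq + m * gravity * h
    return EnergyProfile(energy=energy, heights=h, gravity=gravity)
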