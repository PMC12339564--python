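"""Seeded synthetic motion: skeletons, gait, injuries, sensor modalities.

The generator is the test substrate for the whole pipeline. It produces
treadmill-style periodic walking on a human-like 15-joint skeleton: each
joint oscillates around its rest pose at the gait frequency (~1 Hz) with a
second-harmonic vertical bob, left and right limbs in phase opposition,
plus additive Gaussian capture noise. An injury is a transient mechanical
event at one joint — a raised-cosine vertical displacement excursion whose
peak velocity is the injury magnitude — so the per-joint energy signal
responds by construction through both its kinetic and potential terms.

Three co-registered sensor streams with modality-specific degradations are
derived from each sequence: vision (noisy positions with occlusion
dropouts), IMU (accelerations with bias drift), and a plantar-pressure
proxy (smoothed vertical foot loading, broadcast to joints by body side).

All randomness flows from a single corpus seed through
``numpy.random.SeedSequence.spawn``, so corpora are reproducible and
per-sequence generation is order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .motion import (
    DEFAULT_FRAME_RATE,
    MotionSequence,
    SkeletonGraph,
    build_graph,
    compute_kinematics,
)
from .fusion import ModalityBundle

# Canonical 15-joint body tree; each joint's parent precedes it, so any
# prefix of the list is itself a connected tree.
_JOINTS = [
    ("pelvis", None, (0.0, 0.0, 1.00)),
    ("spine", "pelvis", (0.0, 0.0, 1.25)),
    ("head", "spine", (0.0, 0.0, 1.60)),
    ("l_shoulder", "spine", (-0.20, 0.0, 1.45)),
    ("r_shoulder", "spine", (0.20, 0.0, 1.45)),
    ("l_hip", "pelvis", (-0.10, 0.0, 0.95)),
    ("r_hip", "pelvis", (0.10, 0.0, 0.95)),
    ("l_elbow", "l_shoulder", (-0.25, 0.0, 1.15)),
    ("r_elbow", "r_shoulder", (0.25, 0.0, 1.15)),
    ("l_knee", "l_hip", (-0.10, 0.0, 0.50)),
    ("r_knee", "r_hip", (0.10, 0.0, 0.50)),
    ("l_wrist", "l_elbow", (-0.28, 0.0, 0.90)),
    ("r_wrist", "r_elbow", (0.28, 0.0, 0.90)),
    ("l_ankle", "l_knee", (-0.10, 0.0, 0.10)),
    ("r_ankle", "r_knee", (0.10, 0.0, 0.10)),
]


@dataclass
class SyntheticSpec:
    """Study conditions for corpus generation."""

    n_sequences: int = 200
    n_frames: int = 50
    n_joints: int = 15
    dt: float = 1.0 / DEFAULT_FRAME_RATE  # 0.04 s = 25 Hz
    noise_sd: float = 0.005  # m, pose-capture noise
    injury_rate: float = 0.5
    injury_magnitude: float = 2.5  # m/s peak-velocity scale of the excursion
    injury_duration: int = 8  # frames
    gait_frequency: float = 1.0  # Hz
    seed: int = 0

    def __post_init__(self):
        if self.n_sequences < 1 or self.n_frames < 1 or self.n_joints < 2:
            raise ValueError("corpus dimensions must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0.0 <= self.injury_rate <= 1.0:
            raise ValueError("injury_rate must lie in [0, 1]")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


@dataclass
class InjuryAnnotation:
    joint: int
    onset: int
    duration: int
    magnitude: float


@dataclass
class DegradationConfig:
    """Modality-specific degradations for the simulated sensors."""

    vision_noise_sd: float = 0.01  # m
    occlusion_rate: float = 0.05  # per-frame probability of a masked frame
    imu_noise_sd: float = 0.5  # m/s^2
    imu_drift: float = 0.2  # m/s^2 bias accumulated per second
    pressure_noise_sd: float = 0.05  # body-weight fraction
    pressure_smooth: int = 3  # frames of box smoothing


@dataclass
class LabeledCorpus:
    """Sequences with sensor bundles, binary labels, and injury annotations."""

    sequences: list[MotionSequence]
    bundles: list[ModalityBundle]
    labels: np.ndarray  # (n,) in {0, 1}
    annotations: list[InjuryAnnotation | None]
    skeleton: SkeletonGraph
    spec: SyntheticSpec = None

    def __post_init__(self):
        for y, ann in zip(self.labels, self.annotations):
            if bool(y) != (ann is not None):
                raise ValueError("annotations must be present exactly when y = 1")


def make_skeleton(n_joints: int = 15, masses=None) -> SkeletonGraph:
    """Human-like body tree (pelvis root, spine/head, two arms, two legs).

    For ``n_joints < 15`` the leading prefix of the canonical joint list is
    used (parents always precede children, so the result stays a connected
    tree with n_joints - 1 edges). Uniform masses by default.
    """
    if not 2 <= n_joints <= len(_JOINTS):
        raise ValueError(f"n_joints must be in [2, {len(_JOINTS)}]")
    names = [j[0] for j in _JOINTS[:n_joints]]
    index = {n: i for i, n in enumerate(names)}
    edges = [
        (index[parent], index[name])
        for name, parent, _ in _JOINTS[:n_joints]
        if parent is not None
    ]
    left = [i for i, n in enumerate(names) if n.startswith("l_")]
    right = [i for i, n in enumerate(names) if n.startswith("r_")]
    sensor_map = {"pressure": {"left": left or [0], "right": right or [0]}}
    graph = build_graph(
        edges, n_joints, masses=masses, joint_names=names, sensor_map=sensor_map
    )
    assert nx.is_connected(nx.Graph(graph.edges))  # tree by construction
    return graph


def rest_pose(n_joints: int = 15) -> np.ndarray:
    return np.array([j[2] for j in _JOINTS[:n_joints]])


# Joint-specific gait amplitudes (meters): distal limb joints swing most.
_SWING = {
    "pelvis": 0.02,
    "spine": 0.02,
    "head": 0.02,
    "l_shoulder": 0.04,
    "r_shoulder": 0.04,
    "l_elbow": 0.10,
    "r_elbow": 0.10,
    "l_wrist": 0.15,
    "r_wrist": 0.15,
    "l_hip": 0.04,
    "r_hip": 0.04,
    "l_knee": 0.10,
    "r_knee": 0.10,
    "l_ankle": 0.15,
    "r_ankle": 0.15,
}
_BOB = 0.03  # m, second-harmonic vertical bob


def simulate_normal_motion(
    spec: SyntheticSpec, seed: int | None = None, amplitude_scale: float = 1.0
) -> MotionSequence:
    """Periodic gait-like motion with additive Gaussian capture noise.

    Forward (y) swing at the gait frequency with left/right phase opposition,
    a 2x-frequency vertical bob, and iid positional noise of sd ``noise_sd``.
    With ``noise_sd = 0`` the signal is exactly periodic at the gait period.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    names = [j[0] for j in _JOINTS[: spec.n_joints]]
    T, J = spec.n_frames, spec.n_joints
    t = np.arange(T) * spec.dt
    pose = rest_pose(J)
    pos = np.tile(pose[None, :, :], (T, 1, 1)).astype(float)
    w = 2 * np.pi * spec.gait_frequency
    for j, name in enumerate(names):
        phase = np.pi if name.startswith("r_") else 0.0
        amp = amplitude_scale * _SWING.get(name, 0.05)
        pos[:, j, 1] += amp * np.sin(w * t + phase)  # forward swing
        pos[:, j, 2] += amplitude_scale * _BOB * np.sin(2 * w * t + phase)
    if spec.noise_sd > 0:
        pos += rng.normal(0.0, spec.noise_sd, size=pos.shape)
    return MotionSequence(
        times=t, positions=pos, joint_names=names, vertical_axis=2
    )


def inject_injury(
    seq: MotionSequence,
    joint: int,
    onset: int,
    duration: int,
    magnitude: float,
    seed: int = 0,
) -> tuple[MotionSequence, InjuryAnnotation]:
    """Add a transient vertical excursion at one joint.

    The excursion is a raised-cosine displacement bump over
    ``[onset, onset + duration)`` scaled so its peak velocity is
    ``magnitude`` (m/s); it returns smoothly to zero, leaving every other
    joint and every frame outside the window untouched. ``magnitude = 0``
    reproduces the input exactly.
    """
    T = seq.n_frames
    if not 0 <= joint < seq.n_joints:
        raise ValueError("injury joint out of range")
    if not (0 <= onset and onset + duration <= T):
        raise ValueError("injury window must lie inside the sequence")
    if duration < 2:
        raise ValueError("injury duration must span at least 2 frames")
    pos = seq.positions.copy()
    dur_s = duration * seq.dt
    amp = magnitude * dur_s / np.pi  # sin^2 bump: peak |velocity| = amp*pi/dur_s
    tau = np.arange(duration) / duration
    bump = amp * np.sin(np.pi * tau) ** 2
    pos[onset : onset + duration, joint, seq.vertical_axis] += bump
    out = MotionSequence(
        times=seq.times.copy(),
        positions=pos,
        joint_names=list(seq.joint_names),
        vertical_axis=seq.vertical_axis,
    )
    return out, InjuryAnnotation(
        joint=joint, onset=onset, duration=duration, magnitude=magnitude
    )


def simulate_modalities(
    seq: MotionSequence,
    graph: SkeletonGraph,
    config: DegradationConfig | None = None,
    seed: int = 0,
) -> ModalityBundle:
    """Derive vision, IMU, and plantar-pressure streams from a motion record.

    vision: positions + Gaussian noise, with occluded frames (held at the
    last observed value, mask recorded); imu: per-joint accelerations +
    noise + a linear bias drift ramp; pressure: smoothed vertical-force
    proxy from foot loading, broadcast to joints by body side.
    """
    config = config or DegradationConfig()
    rng = np.random.default_rng(seed)
    T, J = seq.n_frames, seq.n_joints
    kin = compute_kinematics(seq)

    vision = seq.positions.copy()
    if config.vision_noise_sd > 0:
        vision += rng.normal(0.0, config.vision_noise_sd, size=vision.shape)
    occluded = rng.random(T) < config.occlusion_rate
    occluded[0] = False  # keep a defined first frame
    for t in range(1, T):
        if occluded[t]:
            vision[t] = vision[t - 1]  # hold last observed pose

    imu = kin.acceleration.copy()
    drift = config.imu_drift * seq.times  # bias ramp, m/s^2 accumulated per second
    imu = imu + drift[:, None, None]
    if config.imu_noise_sd > 0:
        imu += rng.normal(0.0, config.imu_noise_sd, size=imu.shape)

    # Vertical-force proxy per foot: weight share + m*a_z of that side's
    # joints, normalized by body weight, box-smoothed.
    g = 9.81
    total_mass = graph.masses.sum()
    side_map = graph.sensor_map.get(
        "pressure", {"left": list(range(J)), "right": list(range(J))}
    )
    a_z = kin.acceleration[:, :, seq.vertical_axis]
    pressure = np.zeros((T, J, 1))
    for side, joints in side_map.items():
        joints = [j for j in joints if j < J]
        if not joints:
            continue
        m_side = graph.masses[joints]
        force = np.sum(m_side[None, :] * (g + a_z[:, joints]), axis=1)
        force = force / (total_mass * g)
        k = max(1, config.pressure_smooth)
        kernel = np.ones(k) / k
        force = np.convolve(force, kernel, mode="same")
        if config.pressure_noise_sd > 0:
            force = force + rng.normal(0.0, config.pressure_noise_sd, size=T)
        for j in joints:
            pressure[:, j, 0] = force

    mask = np.ones((T,), dtype=bool)
    mask[occluded] = False
    return ModalityBundle(
        features={"vision": vision, "imu": imu, "pressure": pressure},
        masks={"vision": mask},
        static_coefficients={"vision": 1.0, "imu": 1.0, "pressure": 1.0},
    )


def make_corpus(
    spec: SyntheticSpec, degradation: DegradationConfig | None = None
) -> LabeledCorpus:
    """Generate ``n_sequences`` labeled sequences, fully determined by the seed.

    Exactly ``round(injury_rate * n)`` sequences are injured, at positions
    drawn by the corpus seed; injured joint and onset are uniform. Every
    sequence derives its own child seed from the corpus seed via
    ``SeedSequence.spawn``.
    """
    n = spec.n_sequences
    master = np.random.SeedSequence(spec.seed)
    corpus_rng = np.random.default_rng(master)
    children = master.spawn(n)
    n_injured = int(round(spec.injury_rate * n))
    injured = np.zeros(n, dtype=bool)
    injured[corpus_rng.permutation(n)[:n_injured]] = True

    graph = make_skeleton(spec.n_joints)
    sequences, bundles, annotations = [], [], []
    for i in range(n):
        child = np.random.default_rng(children[i])
        seq_seed = int(child.integers(0, 2**31 - 1))
        seq = simulate_normal_motion(spec, seed=seq_seed)
        ann = None
        if injured[i]:
            joint = int(child.integers(0, spec.n_joints))
            max_onset = spec.n_frames - spec.injury_duration
            onset = int(child.integers(1, max(2, max_onset)))
            seq, ann = inject_injury(
                seq, joint, onset, spec.injury_duration, spec.injury_magnitude
            )
        bundle = simulate_modalities(
            seq, graph, config=degradation, seed=seq_seed + 1
        )
        sequences.append(seq)
        bundles.append(bundle)
        annotations.append(ann)
    return LabeledCorpus(
        sequences=sequences,
        bundles=bundles,
        labels=injured.astype(int),
        annotations=annotations,
        skeleton=graph,
        spec=spec,
    )
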