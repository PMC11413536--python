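"""Locomotor-performance evaluation behind a pluggable backend contract.

An individual is placed on a flat, hard, featureless plane; after a
fixed number of time steps (501 by default) performance is the planar
Euclidean distance between the start and end positions of the body
reference point (centroid of segment centers).  Nonviable individuals
score zero without a trial.

Two backends satisfy the contract:

* ``SurrogateBackend`` -- a pure, deterministic function of the
  morphology, used for testing and desk-scale experiments.  It is
  strictly increasing in the number of complete sensor-to-motorized-
  joint circuits and in segment count, each up to a saturation, plus a
  small deterministic jitter derived from a hash of the morphology
  (always smaller than one circuit's contribution, so monotonicity is
  preserved).
* ``PhysicsBackend`` -- an adapter that builds the body in an external
  rigid-body engine (pybullet), activates touch sensors on ground
  contact, and drives motorized joints through the sensorimotor
  circuit.  The engine is an implementation detail; the adapter imports
  it lazily and raises a clear error when it is not installed.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass

import numpy as np

from .development import Morphology, ViabilityReport, count_driven_joints

__all__ = [
    "BehaviorTrialConfig",
    "Performance",
    "SurrogateBackend",
    "PhysicsBackend",
    "get_backend",
    "evaluate",
]

DEFAULT_TIME_STEPS = 501


@dataclass(frozen=True)
class BehaviorTrialConfig:
    """Trial protocol: duration in engine steps on a flat, hard plane."""

    time_steps: int = DEFAULT_TIME_STEPS
    backend: str = "surrogate"

    def __post_init__(self) -> None:
        if self.time_steps < 1:
            raise ValueError("time_steps must be >= 1")
        if self.backend not in ("surrogate", "physics"):
            raise ValueError(f"unknown backend {self.backend!r}")


@dataclass(frozen=True)
class Performance:
    """Planar start-to-end displacement; zero for nonviable individuals."""

    displacement: float
    failed: bool = False

    def __post_init__(self) -> None:
        if self.displacement < 0:
            raise ValueError("displacement must be non-negative")


class SurrogateBackend:
    """Deterministic stand-in trial for testing and scaled-down runs.

    displacement = CIRCUIT_GAIN * min(circuits, CIRCUIT_SAT)
                 + SEGMENT_GAIN * min(segments, SEGMENT_SAT)
                 + jitter(morphology) * JITTER_SCALE

    ``circuits`` counts motorized joints actually driven by a sensor
    through the wiring graph.  The jitter term is a CRC32 hash of the
    canonical morphology serialisation mapped to [0, 1); its scale is
    well below SEGMENT_GAIN so the function stays strictly monotone in
    both structural terms below saturation.  Referentially transparent:
    identical morphologies always score identically.
    """

    CIRCUIT_GAIN = 1.0
    SEGMENT_GAIN = 0.25
    CIRCUIT_SAT = 8
    SEGMENT_SAT = 12
    JITTER_SCALE = 0.05

    def run_trial(
        self,
        morph: Morphology,
        cfg: BehaviorTrialConfig,
        rng: np.random.Generator | None = None,
    ) -> float:
        circuits = count_driven_joints(morph)
        drive = min(circuits, self.CIRCUIT_SAT)
        prop = min(len(morph.segments), self.SEGMENT_SAT)
        # time scaling: displacement accrues linearly with trial length
        scale = cfg.time_steps / DEFAULT_TIME_STEPS
        payload = json.dumps(morph.to_dict(), sort_keys=True).encode()
        jitter = (zlib.crc32(payload) % 2**16) / 2**16
        return scale * (
            self.CIRCUIT_GAIN * drive
            + self.SEGMENT_GAIN * prop
            + self.JITTER_SCALE * jitter
        )


class PhysicsBackend:
    """Rigid-body engine adapter (pybullet); optional dependency.

    Builds each segment as a sphere, couples them with motorized hinge
    joints, activates touch sensors on plane contact, and switches the
    motors of sensor-driven joints to a fixed-amplitude oscillation (the
    engine's control law here is a documented stand-in).  Returns the
    planar displacement of the centroid of segment centers.
    """

    def __init__(self, gravity: float = -9.81, amplitude: float = 0.5,
                 frequency: float = 0.1):
        try:
            import pybullet  # noqa: F401
        except ImportError as exc:  # pragma: no cover - optional extra
            raise RuntimeError(
                "the physics backend requires the optional 'pybullet' "
                "dependency (pip install ecesim[physics]); use the "
                "surrogate backend otherwise"
            ) from exc
        self.gravity = gravity
        self.amplitude = amplitude
        self.frequency = frequency

    def run_trial(
        self,
        morph: Morphology,
        cfg: BehaviorTrialConfig,
        rng: np.random.Generator | None = None,
    ) -> float:  # pragma: no cover - requires the optional engine
        import pybullet as pb

        client = pb.connect(pb.DIRECT)
        try:
            pb.setGravity(0, 0, self.gravity, physicsClientId=client)
            pb.createCollisionShape(pb.GEOM_PLANE, physicsClientId=client)
            body = self._build_body(pb, client, morph)
            driven = _driven_joint_set(morph)
            start = self._centroid(pb, client, body)
            for step in range(cfg.time_steps):
                contact = bool(pb.getContactPoints(bodyA=body,
                                                   physicsClientId=client))
                for j in driven:
                    target = (
                        self.amplitude * np.sin(2 * np.pi * self.frequency * step)
                        if contact else 0.0
                    )
                    pb.setJointMotorControl2(
                        body, j, pb.POSITION_CONTROL, targetPosition=target,
                        physicsClientId=client,
                    )
                pb.stepSimulation(physicsClientId=client)
            end = self._centroid(pb, client, body)
            return float(np.hypot(end[0] - start[0], end[1] - start[1]))
        finally:
            pb.disconnect(client)

    @staticmethod
    def _build_body(pb, client, morph: Morphology):
        # multibody: root sphere plus hinge-linked child spheres along the tree
        radii = [s.radius for s in morph.segments]
        col = [pb.createCollisionShape(pb.GEOM_SPHERE, radius=r,
                                       physicsClientId=client) for r in radii]
        parents, axes, positions = [], [], []
        order = sorted(morph.joints, key=lambda j: j.child)
        for j in order:
            parents.append(j.parent)
            axes.append([0, 1, 0])
            offset = radii[j.parent] + radii[j.child]
            positions.append([offset, 0, 0])
        return pb.createMultiBody(
            baseMass=1.0,
            baseCollisionShapeIndex=col[0],
            basePosition=[0, 0, max(radii) + 0.1],
            linkMasses=[1.0] * len(order),
            linkCollisionShapeIndices=[col[j.child] for j in order],
            linkVisualShapeIndices=[-1] * len(order),
            linkPositions=positions,
            linkOrientations=[[0, 0, 0, 1]] * len(order),
            linkInertialFramePositions=[[0, 0, 0]] * len(order),
            linkInertialFrameOrientations=[[0, 0, 0, 1]] * len(order),
            linkParentIndices=[p + 1 for p in parents],
            linkJointTypes=[pb.JOINT_REVOLUTE] * len(order),
            linkJointAxis=axes,
            physicsClientId=client,
        )

    @staticmethod
    def _centroid(pb, client, body) -> np.ndarray:
        pos, _ = pb.getBasePositionAndOrientation(body, physicsClientId=client)
        pts = [np.asarray(pos)]
        for li in range(pb.getNumJoints(body, physicsClientId=client)):
            state = pb.getLinkState(body, li, physicsClientId=client)
            pts.append(np.asarray(state[0]))
        return np.mean(pts, axis=0)


def _driven_joint_set(morph: Morphology) -> set[int]:
    from .development import _driven_joints

    return _driven_joints(morph)


def get_backend(name: str):
    """Backend factory for the ``--backend {surrogate,physics}`` flag."""
    if name == "surrogate":
        return SurrogateBackend()
    if name == "physics":
        return PhysicsBackend()
    raise ValueError(f"unknown backend {name!r}")


def evaluate(
    morph: Morphology,
    report: ViabilityReport,
    cfg: BehaviorTrialConfig,
    rng: np.random.Generator | None = None,
    backend=None,
) -> Performance:
    """Run one behavior trial; nonviable individuals score 0 without one.

    A backend construction/trial failure yields displacement 0 with the
    ``failed`` flag set, mirroring individuals that could not move or be
    assembled.
    """
    if not report.viable:
        return Performance(0.0)
    if backend is None:
        backend = get_backend(cfg.backend)
    try:
        return Performance(float(backend.run_trial(morph, cfg, rng)))
    except RuntimeError:
        raise  # missing optional dependency: configuration error, not a trial
    except Exception:
        return Performance(0.0, failed=True)
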