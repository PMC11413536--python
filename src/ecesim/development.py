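"""The three-stage genotype-to-phenotype map.

Development runs in three stages:

1. *Transcription*: each gene yields one transcript carrying at most one
   protopart (the gene's expressed part codon) and its regulatory
   elements.  Transcription errors -- per-base point substitutions at
   rate tau -- strike the copied codons before classification, so an
   error may convert one type of transcript into another.  This is the
   model's only source of developmental randomness; the genome itself is
   never modified.
2. *Early development*: each protopart develops into a finished part;
   regulatory elements of the same transcript set categorical attributes
   (features) or increment numeric attributes (magnitudes).  Finished
   parts wait in per-kind pools in transcription order.
3. *Late development*: the body is assembled from the pools -- first the
   mechanical morphology (spherical segments connected by joints,
   elongating and branching into a tree), then the sensorimotor
   morphology (sensors and neurons on open mounts, then wires joining
   open connectors).

A developed individual is viable only if it has at least two segments,
at least one joint, at least one sensor, and a sensorimotor circuit: a
path from some sensor through wires (directly or via neurons) to a
motorized joint.  Nonviable individuals are assigned zero fitness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .code_table import Category, CodeTable, CodonRole, PartKind
from .genome import Gene, Genome, _substitute, parse_genes

__all__ = [
    "Transcript",
    "Part",
    "PartPool",
    "DevelopmentConfig",
    "Segment",
    "Joint",
    "Accessory",
    "Wire",
    "Morphology",
    "ViabilityReason",
    "ViabilityReport",
    "transcribe",
    "develop_parts",
    "assemble_mechanical",
    "assemble_sensorimotor",
    "check_viability",
    "develop",
]


@dataclass(frozen=True)
class Transcript:
    """Product of one gene: at most one protopart plus regulatory elements."""

    protopart: PartKind | None
    regulatory: tuple[CodonRole, ...]
    source_gene: int


@dataclass
class Part:
    """A finished part awaiting assembly; attributes depend on the kind."""

    kind: PartKind
    attributes: dict = field(default_factory=dict)


@dataclass
class PartPool:
    """Finished parts grouped by kind, in transcription order."""

    segments: list[Part] = field(default_factory=list)
    joints: list[Part] = field(default_factory=list)
    sensors: list[Part] = field(default_factory=list)
    neurons: list[Part] = field(default_factory=list)
    wires: list[Part] = field(default_factory=list)

    def add(self, part: Part) -> None:
        {
            PartKind.SEGMENT: self.segments,
            PartKind.JOINT: self.joints,
            PartKind.SENSOR: self.sensors,
            PartKind.NEURON: self.neurons,
            PartKind.WIRE: self.wires,
        }[part.kind].append(part)

    def counts(self) -> dict[PartKind, int]:
        return {
            PartKind.SEGMENT: len(self.segments),
            PartKind.JOINT: len(self.joints),
            PartKind.SENSOR: len(self.sensors),
            PartKind.NEURON: len(self.neurons),
            PartKind.WIRE: len(self.wires),
        }


@dataclass(frozen=True)
class DevelopmentConfig:
    """Tunable defaults for early development.

    segment_radius
        Default sphere radius, arbitrary length units.
    segment_joint_mounts / segment_accessory_mounts
        Mounts available on a fresh segment for joints and for
        sensors/neurons respectively.
    neuron_connectors
        Wire endpoints a fresh neuron offers.
    radius_increment
        Radius added per unit of a ``size`` magnitude level.
    neurons_before_sensors
        Placement order during sensorimotor assembly.
    """

    segment_radius: float = 1.0
    segment_joint_mounts: int = 2
    segment_accessory_mounts: int = 2
    neuron_connectors: int = 2
    radius_increment: float = 0.25
    neurons_before_sensors: bool = True


def transcribe(
    genes: list[Gene],
    tau: float,
    table: CodeTable,
    rng: np.random.Generator,
) -> list[Transcript]:
    """Copy each gene body with per-base error rate ``tau`` and re-classify.

    Errors use the same three-alternative substitution as germline
    mutation.  Codons mutated into START/STOP yield a null element.
    With ``tau`` = 0 the mapping is deterministic.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"transcription error rate must lie in [0, 1], got {tau}")
    transcripts: list[Transcript] = []
    for g_i, gene in enumerate(genes):
        copied = _substitute(gene.body.reshape(-1), tau, rng).reshape(-1, 3)
        idx = copied.astype(np.int64) @ np.array([16, 4, 1])
        protopart: PartKind | None = None
        regulatory: list[CodonRole] = []
        for ci in idx:
            role = table.role(int(ci))
            if role.category is Category.PART:
                if protopart is None:
                    protopart = role.part_kind
                # surplus part codons are not expressed
            elif role.category in (Category.FEATURE, Category.MAGNITUDE):
                regulatory.append(role)
            # START/STOP arising from an error: null element, no effect
        transcripts.append(Transcript(protopart, tuple(regulatory), g_i))
    return transcripts


def _fresh_part(kind: PartKind, cfg: DevelopmentConfig) -> Part:
    if kind is PartKind.SEGMENT:
        attrs = {
            "radius": cfg.segment_radius,
            "joint_mounts": cfg.segment_joint_mounts,
            "accessory_mounts": cfg.segment_accessory_mounts,
        }
    elif kind is PartKind.JOINT:
        attrs = {"motorized": True}  # all joints are motorized hinges
    elif kind is PartKind.SENSOR:
        attrs = {"output_channel": 1}
    elif kind is PartKind.NEURON:
        attrs = {"connectors": cfg.neuron_connectors}
    else:  # WIRE
        attrs = {"connection_class": "any"}
    return Part(kind, attrs)


def _apply_regulator(part: Part, role: CodonRole) -> None:
    """Regulatory effects; elements that do not apply to the kind are inert."""
    kind = part.kind
    if role.category is Category.FEATURE:
        fk = role.feature_kind
        if fk == "joint" and kind is PartKind.SEGMENT:
            part.attributes["joint_mounts"] += 1
        elif fk in ("sphere-sensor-x", "sphere-sensor-z") and kind is PartKind.SEGMENT:
            part.attributes["accessory_mounts"] += 1
        elif fk == "wire-connections":
            if kind is PartKind.WIRE:
                part.attributes["connection_class"] = "direct"
            elif kind is PartKind.NEURON:
                part.attributes["connectors"] += 1
        elif fk is not None and fk.startswith("sensor-output") and kind is PartKind.SENSOR:
            part.attributes["output_channel"] = int(fk.rsplit("-", 1)[1])
    elif role.category is Category.MAGNITUDE:
        attr, lvl = role.magnitude_attr, role.magnitude_level
        if attr == "size" and kind is PartKind.SEGMENT:
            part.attributes["radius"] += 0.25 * lvl
        elif attr == "mounts" and kind is PartKind.SEGMENT:
            part.attributes["accessory_mounts"] += lvl
        elif attr == "connectors" and kind is PartKind.NEURON:
            part.attributes["connectors"] += lvl


def develop_parts(
    transcripts: list[Transcript], cfg: DevelopmentConfig | None = None
) -> PartPool:
    """Early development: each protopart becomes a finished part.

    Regulatory elements of the same transcript modify that part's
    attributes; regulatory-only transcripts yield no part.
    """
    cfg = cfg or DevelopmentConfig()
    pool = PartPool()
    for t in transcripts:
        if t.protopart is None:
            continue
        part = _fresh_part(t.protopart, cfg)
        for role in t.regulatory:
            _apply_regulator(part, role)
        pool.add(part)
    return pool


# ---------------------------------------------------------------------------
# late development: assembly
# ---------------------------------------------------------------------------


@dataclass
class Segment:
    index: int
    radius: float
    joint_mounts: int       # total mounts for joints
    accessory_mounts: int   # total mounts for sensors/neurons
    open_joint_mounts: int = 0
    open_accessory_mounts: int = 0


@dataclass
class Joint:
    index: int
    parent: int   # segment index
    child: int    # segment index
    motorized: bool = True


@dataclass
class Accessory:
    """A sensor or neuron placed on a segment's accessory mount."""

    index: int
    kind: PartKind
    segment: int
    attributes: dict = field(default_factory=dict)


@dataclass
class Wire:
    index: int
    src_kind: PartKind      # SENSOR or NEURON
    src_index: int
    dst_kind: PartKind      # NEURON or JOINT
    dst_index: int


@dataclass
class Morphology:
    """Assembled body: a segment/joint tree plus the sensorimotor graph."""

    segments: list[Segment] = field(default_factory=list)
    joints: list[Joint] = field(default_factory=list)
    sensors: list[Accessory] = field(default_factory=list)
    neurons: list[Accessory] = field(default_factory=list)
    wires: list[Wire] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "segments": [
                {"index": s.index, "radius": s.radius,
                 "joint_mounts": s.joint_mounts,
                 "accessory_mounts": s.accessory_mounts}
                for s in self.segments
            ],
            "joints": [
                {"index": j.index, "parent": j.parent, "child": j.child,
                 "motorized": j.motorized}
                for j in self.joints
            ],
            "sensors": [
                {"index": a.index, "segment": a.segment,
                 "attributes": a.attributes}
                for a in self.sensors
            ],
            "neurons": [
                {"index": a.index, "segment": a.segment,
                 "attributes": a.attributes}
                for a in self.neurons
            ],
            "wires": [
                {"index": w.index,
                 "src": [w.src_kind.value, w.src_index],
                 "dst": [w.dst_kind.value, w.dst_index]}
                for w in self.wires
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Morphology":
        m = cls()
        for s in d["segments"]:
            m.segments.append(Segment(s["index"], s["radius"],
                                      s["joint_mounts"], s["accessory_mounts"]))
        for j in d["joints"]:
            m.joints.append(Joint(j["index"], j["parent"], j["child"],
                                  j["motorized"]))
        for a in d["sensors"]:
            m.sensors.append(Accessory(a["index"], PartKind.SENSOR,
                                       a["segment"], dict(a["attributes"])))
        for a in d["neurons"]:
            m.neurons.append(Accessory(a["index"], PartKind.NEURON,
                                       a["segment"], dict(a["attributes"])))
        for w in d["wires"]:
            m.wires.append(Wire(w["index"], PartKind(w["src"][0]), w["src"][1],
                                PartKind(w["dst"][0]), w["dst"][1]))
        return m


def assemble_mechanical(pool: PartPool) -> Morphology:
    """Build the segment/joint tree by alternating elongation and branching.

    Segments and joints are consumed in pool order.  The first segment
    seeds branch 0; each new segment is joined to the *active* segment
    (the one most recently placed) when it has an open joint mount --
    elongation.  Otherwise the placed segments are scanned from the
    original segment in order of connection and the new branch starts at
    the first open joint mount.  A joint occupies one mount on each of
    the two segments it couples.  Construction stops when segments,
    joints, or open mounts run out.  The joint graph is always a tree.
    """
    morph = Morphology()
    if not pool.segments:
        return morph

    def place(part: Part, index: int) -> Segment:
        seg = Segment(
            index=index,
            radius=part.attributes["radius"],
            joint_mounts=part.attributes["joint_mounts"],
            accessory_mounts=part.attributes["accessory_mounts"],
        )
        seg.open_joint_mounts = seg.joint_mounts
        seg.open_accessory_mounts = seg.accessory_mounts
        return seg

    morph.segments.append(place(pool.segments[0], 0))
    active = 0
    next_seg = 1
    next_joint = 0
    while next_seg < len(pool.segments) and next_joint < len(pool.joints):
        child_part = pool.segments[next_seg]
        if child_part.attributes["joint_mounts"] < 1:
            # a mountless segment can never be coupled; skip it
            next_seg += 1
            continue
        if morph.segments[active].open_joint_mounts > 0:
            parent = active
        else:
            # branch: first open joint mount, scanning in order of connection
            parent = next(
                (s.index for s in morph.segments if s.open_joint_mounts > 0),
                None,
            )
            if parent is None:
                break  # no open joint mounts remain
        child = place(child_part, len(morph.segments))
        morph.segments[parent].open_joint_mounts -= 1
        child.open_joint_mounts -= 1  # the joint claims a mount on both ends
        morph.segments.append(child)
        jp = pool.joints[next_joint]
        morph.joints.append(
            Joint(next_joint, parent, child.index, jp.attributes["motorized"])
        )
        active = child.index
        next_seg += 1
        next_joint += 1
    return morph


def assemble_sensorimotor(
    pool: PartPool, morph: Morphology, cfg: DevelopmentConfig | None = None
) -> Morphology:
    """Populate the body with sensors, neurons, and wires (in place).

    Neurons then sensors (pool order) fill open accessory mounts scanned
    in segment-connection order until parts or mounts are depleted.
    Wires are then attached in pool order: each takes the first open,
    class-compatible endpoint pair, scanning endpoint classes in the
    order sensor->joint, sensor->neuron, neuron->neuron, neuron->joint
    and components in placement order.  Stops when wires or open
    connectors are exhausted.
    """
    cfg = cfg or DevelopmentConfig()
    first, second = (
        (pool.neurons, PartKind.NEURON), (pool.sensors, PartKind.SENSOR)
    )
    if not cfg.neurons_before_sensors:
        first, second = second, first
    for parts, kind in (first, second):
        for part in parts:
            seg = next(
                (s for s in morph.segments if s.open_accessory_mounts > 0), None
            )
            if seg is None:
                break
            seg.open_accessory_mounts -= 1
            acc = Accessory(
                index=len(morph.sensors if kind is PartKind.SENSOR else morph.neurons),
                kind=kind,
                segment=seg.index,
                attributes=dict(part.attributes),
            )
            (morph.sensors if kind is PartKind.SENSOR else morph.neurons).append(acc)

    # open connector bookkeeping: sensors offer one output, joints accept one
    # drive input, neurons share their connector budget between in and out
    sensor_out = [1] * len(morph.sensors)
    joint_in = [1 if j.motorized else 0 for j in morph.joints]
    neuron_free = [n.attributes.get("connectors", cfg.neuron_connectors)
                   for n in morph.neurons]

    def first_free(avail: list[int]) -> int | None:
        return next((i for i, a in enumerate(avail) if a > 0), None)

    for w_i, wire in enumerate(pool.wires):
        direct_only = wire.attributes.get("connection_class") == "direct"
        placed: Wire | None = None
        # sensor -> joint
        s, j = first_free(sensor_out), first_free(joint_in)
        if s is not None and j is not None:
            sensor_out[s] -= 1
            joint_in[j] -= 1
            placed = Wire(len(morph.wires), PartKind.SENSOR, s, PartKind.JOINT, j)
        elif not direct_only:
            # sensor -> neuron
            s, n = first_free(sensor_out), first_free(neuron_free)
            if s is not None and n is not None:
                sensor_out[s] -= 1
                neuron_free[n] -= 1
                placed = Wire(len(morph.wires), PartKind.SENSOR, s, PartKind.NEURON, n)
            else:
                # neuron -> neuron (two distinct neurons)
                n1 = first_free(neuron_free)
                n2 = (
                    next((i for i, a in enumerate(neuron_free)
                          if a > 0 and i != n1), None)
                    if n1 is not None else None
                )
                if n1 is not None and n2 is not None:
                    neuron_free[n1] -= 1
                    neuron_free[n2] -= 1
                    placed = Wire(len(morph.wires), PartKind.NEURON, n1,
                                  PartKind.NEURON, n2)
                else:
                    # neuron -> joint
                    n, j = first_free(neuron_free), first_free(joint_in)
                    if n is not None and j is not None:
                        neuron_free[n] -= 1
                        joint_in[j] -= 1
                        placed = Wire(len(morph.wires), PartKind.NEURON, n,
                                      PartKind.JOINT, j)
        if placed is None:
            if first_free(sensor_out) is None and first_free(neuron_free) is None:
                break  # no open connectors anywhere; stop wiring
            continue  # this wire cannot attach, try the next
        morph.wires.append(placed)
    return morph


class ViabilityReason(str, Enum):
    TOO_FEW_SEGMENTS = "TOO_FEW_SEGMENTS"
    NO_JOINTS = "NO_JOINTS"
    NO_SENSORS = "NO_SENSORS"
    NO_CIRCUIT = "NO_CIRCUIT"


@dataclass(frozen=True)
class ViabilityReport:
    reasons: tuple[ViabilityReason, ...]

    @property
    def viable(self) -> bool:
        return not self.reasons


def check_viability(morph: Morphology) -> ViabilityReport:
    """Apply the four immobility conditions.

    Nonviable if: fewer than two segments; no joints; no sensors; or no
    path from any sensor through wires (directly or via neurons) to a
    motorized joint.
    """
    reasons: list[ViabilityReason] = []
    if len(morph.segments) < 2:
        reasons.append(ViabilityReason.TOO_FEW_SEGMENTS)
    if not morph.joints:
        reasons.append(ViabilityReason.NO_JOINTS)
    if not morph.sensors:
        reasons.append(ViabilityReason.NO_SENSORS)
    if not _has_circuit(morph):
        reasons.append(ViabilityReason.NO_CIRCUIT)
    return ViabilityReport(tuple(reasons))


def count_driven_joints(morph: Morphology) -> int:
    """Motorized joints reachable from some sensor through the wiring graph."""
    return len(_driven_joints(morph))


def _driven_joints(morph: Morphology) -> set[int]:
    # BFS over the directed wiring graph: sensor -> {neuron, joint},
    # neuron -> {neuron, joint}; neuron-neuron wires conduct both ways.
    neuron_out: dict[int, list[tuple[PartKind, int]]] = {}
    frontier: list[tuple[PartKind, int]] = []
    driven: set[int] = set()
    for w in morph.wires:
        if w.src_kind is PartKind.SENSOR:
            frontier.append((w.dst_kind, w.dst_index))
        else:
            neuron_out.setdefault(w.src_index, []).append((w.dst_kind, w.dst_index))
            if w.dst_kind is PartKind.NEURON:
                neuron_out.setdefault(w.dst_index, []).append(
                    (PartKind.NEURON, w.src_index)
                )
    seen_neurons: set[int] = set()
    while frontier:
        kind, idx = frontier.pop()
        if kind is PartKind.JOINT:
            if idx < len(morph.joints) and morph.joints[idx].motorized:
                driven.add(idx)
        elif idx not in seen_neurons:
            seen_neurons.add(idx)
            frontier.extend(neuron_out.get(idx, ()))
    return driven


def _has_circuit(morph: Morphology) -> bool:
    return bool(_driven_joints(morph))


def develop(
    genome: Genome,
    tau: float,
    table: CodeTable,
    rng: np.random.Generator,
    cfg: DevelopmentConfig | None = None,
) -> tuple[Morphology, ViabilityReport]:
    """Full genotype-to-phenotype map; pure function of the genome at tau=0."""
    genes = parse_genes(genome, table)
    transcripts = transcribe(genes, tau, table, rng)
    pool = develop_parts(transcripts, cfg)
    morph = assemble_mechanical(pool)
    morph = assemble_sensorimotor(pool, morph, cfg)
    return morph, check_viability(morph)
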