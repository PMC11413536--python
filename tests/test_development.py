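"""Development: transcription errors, part growth, assembly, viability."""

import numpy as np
import pytest

from ecesim import (
    DevelopmentConfig,
    Morphology,
    Part,
    PartKind,
    PartPool,
    assemble_mechanical,
    assemble_sensorimotor,
    check_viability,
    develop,
    develop_parts,
    parse_genes,
    random_genome,
    transcribe,
)
from ecesim.code_table import codon_index
from ecesim.development import ViabilityReason


def seg(joint_mounts=2, accessory_mounts=2, radius=1.0) -> Part:
    return Part(PartKind.SEGMENT, {
        "radius": radius, "joint_mounts": joint_mounts,
        "accessory_mounts": accessory_mounts,
    })


def joint() -> Part:
    return Part(PartKind.JOINT, {"motorized": True})


def sensor() -> Part:
    return Part(PartKind.SENSOR, {"output_channel": 1})


def neuron(connectors=2) -> Part:
    return Part(PartKind.NEURON, {"connectors": connectors})


def wire(cls="any") -> Part:
    return Part(PartKind.WIRE, {"connection_class": cls})


def pool_of(segments=(), joints=(), sensors=(), neurons=(), wires=()) -> PartPool:
    p = PartPool()
    p.segments = list(segments)
    p.joints = list(joints)
    p.sensors = list(sensors)
    p.neurons = list(neurons)
    p.wires = list(wires)
    return p


class TestTranscribe:
    def test_zero_error_matches_gene_exactly(self, toy_genome, table, rng):
        genes = parse_genes(toy_genome, table)
        transcripts = transcribe(genes, 0.0, table, rng)
        assert [t.protopart for t in transcripts] == [
            g.expressed_part for g in genes
        ]
        for t, g in zip(transcripts, genes):
            assert len(t.regulatory) == len(g.regulatory_offsets)

    def test_sensor_codon_single_error_neighbourhood(self, table):
        # one forced base change moves the sensor codon (100) into exactly
        # the published nine-codon neighbourhood
        neighbours = set()
        for pos in range(3):
            for shift in (1, 2, 3):
                digits = [1, 0, 0]
                digits[pos] = (digits[pos] + shift) % 4
                neighbours.add(codon_index(*digits))
        expected = {
            codon_index(0, 0, 0), codon_index(2, 0, 0), codon_index(3, 0, 0),
            codon_index(1, 1, 0), codon_index(1, 2, 0), codon_index(1, 3, 0),
            codon_index(1, 0, 1), codon_index(1, 0, 2), codon_index(1, 0, 3),
        }
        assert neighbours == expected

    def test_error_rate_one_changes_all_bases(self, table):
        # tau = 1 on a 10-codon gene: every one of its 30 copied bases
        # differs (forced by the three-alternative substitution)
        from ecesim import Genome
        from ecesim.genome import _substitute

        g = Genome.from_string("333" + "000" * 10 + "332")
        gene = parse_genes(g, table)[0]
        flat = gene.body.reshape(-1)
        out = _substitute(flat, 1.0, np.random.default_rng(0))
        assert np.all(out != flat)

    def test_per_base_error_rate_is_binomial(self, table):
        # copied gene bases flip independently at rate tau: binomial check
        from ecesim import Genome
        from ecesim.genome import _substitute

        g = Genome.from_string("333" + "000" * 10 + "332")
        gene = parse_genes(g, table)[0]
        flat = gene.body.reshape(-1)
        tau, reps, n_bases = 0.1, 1_000, 30
        changed = sum(
            int(np.count_nonzero(
                _substitute(flat, tau, np.random.default_rng(i)) != flat))
            for i in range(reps)
        )
        mean = changed / reps
        se = np.sqrt(n_bases * tau * (1 - tau) / reps)
        assert abs(mean - n_bases * tau) < 3 * se

    def test_invalid_rate_rejected(self, toy_genome, table, rng):
        genes = parse_genes(toy_genome, table)
        with pytest.raises(ValueError):
            transcribe(genes, 1.5, table, rng)

    def test_genome_never_modified(self, toy_genome, table, rng):
        before = toy_genome.bases.copy()
        genes = parse_genes(toy_genome, table)
        transcribe(genes, 1.0, table, rng)
        assert np.array_equal(toy_genome.bases, before)


class TestDevelopParts:
    def test_default_segment(self, table, rng):
        from ecesim import Transcript

        pool = develop_parts([Transcript(PartKind.SEGMENT, (), 0)])
        s = pool.segments[0]
        assert s.attributes == {
            "radius": 1.0, "joint_mounts": 2, "accessory_mounts": 2,
        }

    def test_features_and_magnitudes_modify_their_part(self, table):
        from ecesim import Transcript

        roles = (
            table.role((3, 0, 0)),   # joint feature: +1 joint mount
            table.role((1, 1, 0)),   # sphere-sensor-x: +1 accessory mount
            table.role((0, 3, 1)),   # size magnitude level 2: radius += 0.5
        )
        pool = develop_parts([Transcript(PartKind.SEGMENT, roles, 0)])
        s = pool.segments[0]
        assert s.attributes["joint_mounts"] == 3
        assert s.attributes["accessory_mounts"] == 3
        assert s.attributes["radius"] == pytest.approx(1.5)

    def test_sensor_output_channel_feature(self, table):
        from ecesim import Transcript

        pool = develop_parts(
            [Transcript(PartKind.SENSOR, (table.role((1, 0, 3)),), 0)]
        )
        assert pool.sensors[0].attributes["output_channel"] == 3

    def test_regulatory_only_transcript_yields_no_part(self, table):
        from ecesim import Transcript

        pool = develop_parts([Transcript(None, (table.role((3, 0, 0)),), 0)])
        assert sum(pool.counts().values()) == 0

    def test_pool_counts_equal_transcript_counts(self, table, random_genomes, rng):
        for g in random_genomes:
            genes = parse_genes(g, table)
            ts = transcribe(genes, 0.0, table, rng)
            pool = develop_parts(ts)
            expected = {k: 0 for k in PartKind}
            for t in ts:
                if t.protopart is not None:
                    expected[t.protopart] += 1
            assert pool.counts() == expected


class TestAssembleMechanical:
    def test_serial_chain(self):
        pool = pool_of(segments=[seg() for _ in range(4)],
                       joints=[joint() for _ in range(3)])
        m = assemble_mechanical(pool)
        assert len(m.segments) == 4
        assert len(m.joints) == 3
        assert [(j.parent, j.child) for j in m.joints] == [(0, 1), (1, 2), (2, 3)]

    def test_no_joints_places_single_segment(self):
        m = assemble_mechanical(pool_of(segments=[seg(), seg(), seg()]))
        assert len(m.segments) == 1 and not m.joints

    def test_empty_pool_gives_empty_morphology(self):
        m = assemble_mechanical(pool_of())
        assert not m.segments and not m.joints

    def test_branching_matches_hand_trace(self):
        # root with 2 joint mounts, all others with 1 (consumed when
        # attached): hand-traced star of 3 segments on the root, then stop
        pool = pool_of(
            segments=[seg(2)] + [seg(1) for _ in range(4)],
            joints=[joint() for _ in range(4)],
        )
        m = assemble_mechanical(pool)
        assert [(j.parent, j.child) for j in m.joints] == [(0, 1), (0, 2)]
        assert len(m.segments) == 3  # no open joint mounts remain

    def test_mixed_elongation_and_branching_hand_trace(self):
        # mounts [2,1,2,1,1]: trace gives edges (0,1) elongate, (0,2)
        # branch, (2,3) elongate, then no open mounts
        pool = pool_of(
            segments=[seg(2), seg(1), seg(2), seg(1), seg(1)],
            joints=[joint() for _ in range(4)],
        )
        m = assemble_mechanical(pool)
        assert [(j.parent, j.child) for j in m.joints] == [(0, 1), (0, 2), (2, 3)]

    def test_tree_invariant_on_random_genomes(self, table, random_genomes, rng):
        for g in random_genomes:
            morph, _ = develop(g, 0.0, table, rng)
            if morph.segments:
                assert len(morph.joints) == len(morph.segments) - 1

    def test_joint_graph_is_a_tree(self, table, random_genomes, rng):
        import networkx as nx

        for g in random_genomes[:30]:
            morph, _ = develop(g, 0.0, table, rng)
            if len(morph.segments) < 2:
                continue
            G = nx.Graph((j.parent, j.child) for j in morph.joints)
            G.add_nodes_from(s.index for s in morph.segments)
            assert nx.is_tree(G)


class TestAssembleSensorimotor:
    def test_single_circuit(self):
        pool = pool_of(
            segments=[seg(), seg()], joints=[joint()],
            sensors=[sensor()], wires=[wire()],
        )
        m = assemble_mechanical(pool)
        m = assemble_sensorimotor(pool, m)
        assert len(m.sensors) == 1
        assert len(m.wires) == 1
        w = m.wires[0]
        assert (w.src_kind, w.dst_kind) == (PartKind.SENSOR, PartKind.JOINT)

    def test_depleted_sensor_pool(self):
        pool = pool_of(segments=[seg(), seg()], joints=[joint()],
                       wires=[wire()])
        m = assemble_sensorimotor(pool, assemble_mechanical(pool))
        assert not m.sensors

    def test_neurons_placed_before_sensors(self):
        pool = pool_of(
            segments=[seg(2, accessory_mounts=1), seg(2, accessory_mounts=0)],
            joints=[joint()], sensors=[sensor()], neurons=[neuron()],
        )
        m = assemble_sensorimotor(pool, assemble_mechanical(pool))
        # one open mount: the neuron takes it, the sensor goes unplaced
        assert len(m.neurons) == 1 and len(m.sensors) == 0

    def test_wiring_respects_connector_budget(self, table, rng):
        # exhaustive slot audit over 50 random pools
        for i in range(50):
            r = np.random.default_rng(i)
            pool = pool_of(
                segments=[seg(int(r.integers(0, 4)), int(r.integers(0, 4)))
                          for _ in range(int(r.integers(1, 8)))],
                joints=[joint() for _ in range(int(r.integers(0, 8)))],
                sensors=[sensor() for _ in range(int(r.integers(0, 5)))],
                neurons=[neuron(int(r.integers(1, 4)))
                         for _ in range(int(r.integers(0, 5)))],
                wires=[wire("direct" if r.random() < 0.3 else "any")
                       for _ in range(int(r.integers(0, 10)))],
            )
            m = assemble_sensorimotor(pool, assemble_mechanical(pool))
            # audit endpoint usage against capacities
            sensor_use = [0] * len(m.sensors)
            joint_use = [0] * len(m.joints)
            neuron_use = [0] * len(m.neurons)
            for w in m.wires:
                if w.src_kind is PartKind.SENSOR:
                    sensor_use[w.src_index] += 1
                else:
                    neuron_use[w.src_index] += 1
                if w.dst_kind is PartKind.JOINT:
                    joint_use[w.dst_index] += 1
                else:
                    neuron_use[w.dst_index] += 1
            assert all(u <= 1 for u in sensor_use)
            assert all(u <= 1 for u in joint_use)
            assert all(
                u <= m.neurons[i].attributes["connectors"]
                for i, u in enumerate(neuron_use)
            )
            assert len(m.wires) <= len(pool.wires)


class TestViability:
    def make_viable(self) -> Morphology:
        pool = pool_of(segments=[seg(), seg()], joints=[joint()],
                       sensors=[sensor()], wires=[wire()])
        return assemble_sensorimotor(pool, assemble_mechanical(pool))

    def test_minimal_viable_individual(self):
        report = check_viability(self.make_viable())
        assert report.viable and report.reasons == ()

    def test_single_segment_nonviable(self):
        m = assemble_mechanical(pool_of(segments=[seg()]))
        report = check_viability(m)
        assert not report.viable
        assert ViabilityReason.TOO_FEW_SEGMENTS in report.reasons

    def test_removing_only_sensor_breaks_viability(self):
        m = self.make_viable()
        m.sensors.clear()
        m.wires.clear()
        report = check_viability(m)
        assert ViabilityReason.NO_SENSORS in report.reasons

    def test_sensor_wired_to_isolated_neuron_has_no_circuit(self):
        from ecesim.development import Accessory, Wire

        pool = pool_of(segments=[seg(), seg()], joints=[joint()])
        m = assemble_mechanical(pool)
        m.sensors.append(Accessory(0, PartKind.SENSOR, 0, {"output_channel": 1}))
        m.neurons.append(Accessory(0, PartKind.NEURON, 0, {"connectors": 2}))
        m.wires.append(Wire(0, PartKind.SENSOR, 0, PartKind.NEURON, 0))
        report = check_viability(m)
        assert ViabilityReason.NO_CIRCUIT in report.reasons

    def test_circuit_detection_matches_reachability_oracle(self, table, rng):
        import networkx as nx

        from ecesim.development import _has_circuit

        for i in range(200):
            g = random_genome(600, np.random.default_rng(i))
            morph, _ = develop(g, 0.0, table, rng)
            # oracle: directed reachability sensor -> ... -> motorized joint
            G = nx.DiGraph()
            for w in morph.wires:
                u = (w.src_kind.value, w.src_index)
                v = (w.dst_kind.value, w.dst_index)
                G.add_edge(u, v)
                if w.src_kind is PartKind.NEURON and w.dst_kind is PartKind.NEURON:
                    G.add_edge(v, u)
            reachable = False
            for s in range(len(morph.sensors)):
                src = ("SENSOR", s)
                if src not in G:
                    continue
                for node in nx.descendants(G, src):
                    if node[0] == "JOINT" and morph.joints[node[1]].motorized:
                        reachable = True
            assert _has_circuit(morph) == reachable


class TestDevelop:
    def test_deterministic_at_zero_error(self, table, rng):
        g = random_genome(1800, rng)
        m1, r1 = develop(g, 0.0, table, np.random.default_rng(1))
        m2, r2 = develop(g, 0.0, table, np.random.default_rng(2))
        assert m1.to_dict() == m2.to_dict()
        assert r1 == r2

    def test_errors_can_alter_phenotype(self, table):
        g = random_genome(18_000, np.random.default_rng(3))
        m0, _ = develop(g, 0.0, table, np.random.default_rng(0))
        diffs = sum(
            develop(g, 0.005, table, np.random.default_rng(i))[0].to_dict()
            != m0.to_dict()
            for i in range(5)
        )
        assert diffs > 0

    def test_all_stop_codon_genome_is_nonviable(self, table, rng):
        from ecesim import Genome

        g = Genome.from_string("332" * 20)
        morph, report = develop(g, 0.0, table, rng)
        assert not morph.segments
        assert not report.viable

    def test_morphology_json_round_trip(self, table, rng):
        g = random_genome(1800, rng)
        morph, _ = develop(g, 0.0, table, rng)
        again = Morphology.from_dict(morph.to_dict())
        assert again.to_dict() == morph.to_dict()
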