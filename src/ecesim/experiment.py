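"""Factorial experiment orchestration: designs, founders, runs, fixtures.

The full design varies the germline mutation rate mu and the
transcription error rate tau from 0 to 0.0050 in increments of 0.0005
(11 levels each, 121 conditions).  Nine founder populations of 60
uniform-random genomes are each evolved under every condition for 100
generations: 1,089 cells, a possible 6,534,000 individuals.  The same
founder genome set is reused across all conditions of a founder, so the
121 runs of one founder start genetically identical (and, for tau > 0,
phenotypically different).

A scaled-down profile (2 founders, a 3x3 {0, 0.0025, 0.0050}^2 grid,
N=30, G=25, surrogate backend) ships for desk-scale replication.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import BehaviorTrialConfig
from .code_table import CodeTable
from .evolution import (
    DEFAULT_GENERATIONS,
    DEFAULT_POPULATION_SIZE,
    ReproductionSchedule,
    run_evolution,
)
from .genome import DEFAULT_GENOME_LENGTH, Genome, random_genome

__all__ = [
    "FactorialDesign",
    "RunManifest",
    "default_rate_levels",
    "make_founder_populations",
    "run_factorial",
    "load_cell_log",
    "merge_logs",
    "make_fixture",
]


def default_rate_levels() -> list[float]:
    """0 to 0.0050 in increments of 0.0005: 11 levels."""
    return [round(0.0005 * i, 4) for i in range(11)]


@dataclass(frozen=True)
class FactorialDesign:
    """A full factorial mu x tau design over replicate founder populations."""

    mu_levels: tuple[float, ...] = tuple(default_rate_levels())
    tau_levels: tuple[float, ...] = tuple(default_rate_levels())
    n_founders: int = 9
    population_size: int = DEFAULT_POPULATION_SIZE
    generations: int = DEFAULT_GENERATIONS
    genome_length: int = DEFAULT_GENOME_LENGTH
    backend: str = "surrogate"

    def __post_init__(self) -> None:
        for r in (*self.mu_levels, *self.tau_levels):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate level {r} outside [0, 1]")
        if self.n_founders < 1:
            raise ValueError("need at least one founder population")

    @property
    def n_conditions(self) -> int:
        return len(self.mu_levels) * len(self.tau_levels)

    @property
    def n_cells(self) -> int:
        return self.n_founders * self.n_conditions

    @property
    def total_possible_individuals(self) -> int:
        """Founders x conditions x N x G (generations after generation 0)."""
        return self.n_cells * self.population_size * self.generations

    @classmethod
    def scaled_profile(cls) -> "FactorialDesign":
        """Desk-scale replication profile (surrogate backend)."""
        return cls(
            mu_levels=(0.0, 0.0025, 0.0050),
            tau_levels=(0.0, 0.0025, 0.0050),
            n_founders=2,
            population_size=30,
            generations=25,
            backend="surrogate",
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FactorialDesign":
        d = json.loads(text)
        d["mu_levels"] = tuple(d["mu_levels"])
        d["tau_levels"] = tuple(d["tau_levels"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "FactorialDesign":
        return cls.from_json(Path(path).read_text())


def make_founder_populations(
    design: FactorialDesign, rng: np.random.Generator
) -> list[list[Genome]]:
    """One uniform-random genome set per founder population.

    Each set holds ``population_size`` genomes of ``genome_length``
    i.i.d. uniform bases; the identical set is reused across all
    conditions of that founder.
    """
    return [
        [random_genome(design.genome_length, rng)
         for _ in range(design.population_size)]
        for _ in range(design.n_founders)
    ]


@dataclass
class RunManifest:
    """Per-cell bookkeeping enabling resumable factorial runs."""

    cells: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.cells, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(cells=json.loads(text))

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        return cls.from_json(path.read_text())

    def save(self, path: Path) -> None:
        path.write_text(self.to_json())

    def done(self) -> set[tuple[int, float, float]]:
        return {
            (c["founder_id"], c["mu"], c["tau"])
            for c in self.cells
            if c["status"] == "done"
        }


def _cell_filename(founder_id: int, mu: float, tau: float) -> str:
    return f"cell_f{founder_id}_mu{mu:.4f}_tau{tau:.4f}.csv"


def run_factorial(
    design: FactorialDesign,
    seed: int,
    out_dir: str | Path,
    table: CodeTable | None = None,
    include_genomes: bool = False,
) -> RunManifest:
    """Run every founder x condition cell, writing one log CSV per cell.

    Resumable: cells recorded as done in an existing manifest are
    skipped.  Seeding is hierarchical -- one master seed stream per
    (founder, mu, tau) cell -- so cells are independent and
    reproducible, and a partial failure in one cell is recorded without
    stopping the sweep.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = table or CodeTable.default()
    manifest_path = out_dir / "manifest.json"
    manifest = (
        RunManifest.load(manifest_path) if manifest_path.exists() else RunManifest()
    )
    done = manifest.done()

    master = np.random.SeedSequence(seed)
    founder_ss, *_ = master.spawn(1)
    founders = make_founder_populations(
        design, np.random.default_rng(founder_ss)
    )
    schedule = ReproductionSchedule.for_size(design.population_size)
    trial_cfg = BehaviorTrialConfig(backend=design.backend)

    cell_seeds = master.spawn(design.n_cells)
    cell_i = 0
    for founder_id in range(design.n_founders):
        for mu in design.mu_levels:
            for tau in design.tau_levels:
                ss = cell_seeds[cell_i]
                cell_i += 1
                key = (founder_id, mu, tau)
                fname = _cell_filename(founder_id, mu, tau)
                if key in done:
                    continue
                entry = {
                    "founder_id": founder_id, "mu": mu, "tau": tau,
                    "spawn_key": [int(k) for k in ss.spawn_key],
                    "log": fname, "status": "running",
                }
                try:
                    log, _ = run_evolution(
                        founders[founder_id], mu, tau, design.generations,
                        ss, table=table, founder_id=founder_id,
                        schedule=schedule, trial_cfg=trial_cfg,
                        include_genomes=include_genomes,
                    )
                    log.to_csv(out_dir / fname, index=False)
                    entry["status"] = "done"
                except Exception as exc:  # record, continue the sweep
                    entry["status"] = f"failed: {exc}"
                manifest.cells.append(entry)
                manifest.save(manifest_path)
    return manifest


def load_cell_log(out_dir: str | Path, founder_id: int, mu: float, tau: float
                  ) -> pd.DataFrame:
    return pd.read_csv(
        Path(out_dir) / _cell_filename(founder_id, mu, tau),
        keep_default_na=False,
        dtype={"reasons": str, "genome": str},
    )


def merge_logs(out_dir: str | Path) -> pd.DataFrame:
    """Concatenate all done cells of a manifest into one tidy frame."""
    out_dir = Path(out_dir)
    manifest = RunManifest.load(out_dir / "manifest.json")
    frames = [
        pd.read_csv(out_dir / c["log"], keep_default_na=False,
                    dtype={"reasons": str, "genome": str})
        for c in manifest.cells
        if c["status"] == "done"
    ]
    if not frames:
        raise ValueError("manifest has no completed cells")
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# deterministic fixtures for tests and examples
# ---------------------------------------------------------------------------

def _toy_genome_string(table: CodeTable) -> str:
    """A 30-codon strand realising a small multi-gene structure.

    Contains three genes: one expressing a segment with regulators, one
    regulatory-only gene (features/magnitudes but no part codon), and
    one with three part codons of which only the first (a sensor) is
    expressed; plus leading/trailing intergenic codons.
    """
    start, stop = "333", "332"
    codons = (
        ["012", "211"]                                        # intergenic
        + [start, "000", "300", "110", "030", stop]           # gene 1: segment
        + ["123"]                                             # intergenic
        + [start, "310", "320", "031", stop]                  # gene 2: regulatory-only
        + [start, "100", "000", "200", "101", stop]           # gene 3: sensor (+2 surplus parts)
        + ["222", "111", "013", "231", "302", "210",
           "121", "033", "213", "301"]                        # intergenic tail
    )
    assert len(codons) == 30
    return "".join(codons)


def make_fixture(kind: str, seed: int, table: CodeTable | None = None):
    """Small deterministic inputs used throughout the test suite.

    kinds: ``toy_genome`` (the 30-codon strand above), ``toy_pool``
    (the developed part pool of that strand), ``toy_population`` (a
    tiny evaluated population of random genomes).
    """
    from .development import DevelopmentConfig, develop_parts, develop
    from .evolution import Population, _develop_and_evaluate
    from .behavior import BehaviorTrialConfig
    from .genome import parse_genes

    table = table or CodeTable.default()
    rng = np.random.default_rng(seed)
    if kind == "toy_genome":
        return Genome.from_string(_toy_genome_string(table))
    if kind == "toy_pool":
        genome = Genome.from_string(_toy_genome_string(table))
        genes = parse_genes(genome, table)
        from .development import transcribe

        return develop_parts(transcribe(genes, 0.0, table, rng))
    if kind == "toy_population":
        from .behavior import get_backend

        founders = [random_genome(300, rng) for _ in range(4)]
        cfg = DevelopmentConfig()
        trial = BehaviorTrialConfig()
        backend = get_backend("surrogate")
        inds = [
            _develop_and_evaluate(g, 0.0, table, rng, cfg, trial, backend, -1, i)
            for i, g in enumerate(founders)
        ]
        return Population(individuals=inds, generation=0, mu=0.0, tau=0.0)
    raise ValueError(f"unknown fixture kind {kind!r}")
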