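"""Population statistics: complexity, variance measures, selection gradients.

Morphological complexity is counted at one structural level:

* *mechanical* complexity -- the number of body segments (joints are
  deliberately excluded: for any assembled tree j = s - 1, so the two
  are not independent);
* *sensorimotor* complexity -- sensors + neurons + wires;
* *total* complexity -- the sum of the two.

Genetic variance of a population is the total Hamming distance over all
unordered pairs of genomes.  Phenotypic variance is the median absolute
deviation (unscaled by default; the 1.4826 normal-consistency factor is
opt-in to avoid silent mismatches between statistics environments).

Selection gradients follow the classical multivariate regression of
fitness on traits: fitness = A + B1 * mechanical + B2 * sensorimotor,
with B the unstandardized ordinary-least-squares coefficients, fitted
per (founder, mu, tau, generation) group.  Total complexity is excluded
from the model because it is the sum of the other two.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .development import Morphology
from .genome import Genome

__all__ = [
    "ComplexityTriple",
    "GradientRecord",
    "complexity",
    "genetic_variance",
    "phenotypic_variance",
    "selection_gradients",
    "gradients_to_frame",
    "landscape_paths",
]

MAD_NORMAL_CONSISTENCY = 1.4826


@dataclass(frozen=True)
class ComplexityTriple:
    mechanical: int
    sensorimotor: int

    @property
    def total(self) -> int:
        return self.mechanical + self.sensorimotor


def complexity(morph: Morphology) -> ComplexityTriple:
    """Count-based complexity of an assembled morphology."""
    return ComplexityTriple(
        mechanical=len(morph.segments),
        sensorimotor=len(morph.sensors) + len(morph.neurons) + len(morph.wires),
    )


def _genome_matrix(genomes: Iterable) -> np.ndarray:
    rows = []
    for g in genomes:
        bases = g.bases if isinstance(g, Genome) else np.asarray(g, dtype=np.uint8)
        rows.append(bases)
    if not rows:
        raise ValueError("need at least one genome")
    lengths = {r.size for r in rows}
    if len(lengths) > 1:
        raise ValueError("genomes must all have equal length")
    return np.stack(rows)


def genetic_variance(genomes: Iterable) -> int:
    """Total Hamming distance over all unordered pairs of genomes.

    Accepts ``Genome`` objects, base arrays, or a ``Population`` (via
    its individuals).  Computed per locus from base counts:
    mismatching pairs at a locus = C(n,2) - sum_b C(count_b, 2).
    """
    if hasattr(genomes, "individuals"):
        genomes = [ind.genome for ind in genomes.individuals]
    mat = _genome_matrix(genomes)
    n, L = mat.shape
    if n == 1 or L == 0:
        return 0
    total_pairs = n * (n - 1) // 2
    mismatches = 0
    for b in range(4):
        cnt = (mat == b).sum(axis=0).astype(np.int64)
        mismatches -= int((cnt * (cnt - 1) // 2).sum())
    mismatches += L * total_pairs
    return mismatches


def phenotypic_variance(values: Sequence[float], scale: float = 1.0) -> float:
    """Median absolute deviation of ``values``; unscaled by default.

    Pass ``scale=MAD_NORMAL_CONSISTENCY`` for the normal-consistent
    estimator.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("phenotypic variance of an empty sample is undefined")
    return float(scale * np.median(np.abs(arr - np.median(arr))))


@dataclass(frozen=True)
class GradientRecord:
    """Per-group selection-gradient fit.

    ``intercept`` is A and ``beta_mech``/``beta_senso`` the
    unstandardized coefficients B1/B2; ``ok`` is False (with NaN
    coefficients) for groups with too few individuals or a
    rank-deficient design (e.g. constant predictors).
    """

    founder_id: int
    mu: float
    tau: float
    generation: int
    intercept: float
    beta_mech: float
    beta_senso: float
    n: int
    ok: bool


_GROUP_KEYS = ["founder_id", "mu", "tau", "generation"]


def _fit_group(fitness: np.ndarray, mech: np.ndarray, senso: np.ndarray):
    n = fitness.size
    if n < 3:
        return None
    X = np.column_stack([np.ones(n), mech, senso])
    if np.linalg.matrix_rank(X) < 3:
        return None
    coef, *_ = np.linalg.lstsq(X, fitness, rcond=None)
    return coef


def selection_gradients(
    log: pd.DataFrame, group_keys: Sequence[str] = tuple(_GROUP_KEYS)
) -> list[GradientRecord]:
    """OLS selection gradients per (founder, mu, tau, generation) group."""
    records: list[GradientRecord] = []
    for keys, grp in log.groupby(list(group_keys), sort=True):
        coef = _fit_group(
            grp["fitness"].to_numpy(float),
            grp["mech_complexity"].to_numpy(float),
            grp["senso_complexity"].to_numpy(float),
        )
        kd = dict(zip(group_keys, keys))
        base = dict(
            founder_id=int(kd.get("founder_id", -1)),
            mu=float(kd.get("mu", np.nan)),
            tau=float(kd.get("tau", np.nan)),
            generation=int(kd.get("generation", -1)),
            n=len(grp),
        )
        if coef is None:
            records.append(GradientRecord(
                **base, intercept=np.nan, beta_mech=np.nan,
                beta_senso=np.nan, ok=False,
            ))
        else:
            records.append(GradientRecord(
                **base, intercept=float(coef[0]), beta_mech=float(coef[1]),
                beta_senso=float(coef[2]), ok=True,
            ))
    return records


def gradients_to_frame(records: list[GradientRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def landscape_paths(log: pd.DataFrame) -> pd.DataFrame:
    """Adaptive-landscape paths: per-run, per-generation population means.

    One row per (founder_id, mu, tau, generation), generation-ordered,
    with mean fitness and mean complexity of each type -- ready for
    path plotting with time parameterized along the path.
    """
    agg = (
        log.groupby(_GROUP_KEYS, sort=True)
        .agg(
            mean_fitness=("fitness", "mean"),
            mean_mech_complexity=("mech_complexity", "mean"),
            mean_senso_complexity=("senso_complexity", "mean"),
            mean_total_complexity=("total_complexity", "mean"),
            n=("fitness", "size"),
        )
        .reset_index()
        .sort_values(_GROUP_KEYS, kind="stable")
        .reset_index(drop=True)
    )
    return agg
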