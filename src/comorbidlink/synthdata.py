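"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

The study data these generators emulate are not public: the clinical
cohort (an all-case head-and-neck cancer series with strong male
predominance and a diabetic subgroup per sex) and the per-gene literature
polarity counts both live behind institutional or proprietary walls.
Each generator is a pure function of its spec, which carries a mandatory
seed — same spec, same bytes, every time.

Defaults mirror the emulated study: a 728-patient cohort (692 male),
sex-specific diabetes proportions 127/692 and 5/36, ages truncated-normal
with mean 61.1, SD 10.4 on the observed range [14, 91].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import truncnorm

from .cohort import PatientRecord
from .litstats import AbmObservation
from .netanalysis import DirectedGeneNetwork
from .overlap import GeneSet

__all__ = [
    "CohortSpec",
    "LiteratureSpec",
    "NetworkSpec",
    "generate_cohort",
    "generate_literature",
    "generate_network",
    "generate_gene_sets",
]

AGE_RANGE = (14, 91)  # observed cohort age range


@dataclass(frozen=True)
class CohortSpec:
    """All-case cohort: fixed per-sex sizes, binomial diabetes status,
    truncated-normal ages."""

    n_patients: int = 728
    sex_proportion_male: float = 692 / 728
    dm_prob_male: float = 127 / 692
    dm_prob_female: float = 5 / 36
    age_mean: float = 61.1
    age_sd: float = 10.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("sex_proportion_male", "dm_prob_male", "dm_prob_female"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.age_sd <= 0:
            raise ValueError("age_sd must be positive")


@dataclass(frozen=True)
class LiteratureSpec:
    """Gene panel with a planted fraction of true associations.

    Null genes draw n_pos ~ Binomial(n_total, p_null); true genes use
    p_true > p_null.  n_total is uniform on [n_total_min, n_total_max].
    """

    n_genes: int = 1000
    frac_true: float = 0.1
    p_null: float = 0.5
    p_true: float = 0.9
    n_total_min: int = 5
    n_total_max: int = 50
    disease: str = "disease"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0.0 <= self.frac_true <= 1.0:
            raise ValueError("frac_true must lie in [0, 1]")
        if not 0.0 < self.p_null < self.p_true <= 1.0:
            raise ValueError("require 0 < p_null < p_true <= 1")
        if not 1 <= self.n_total_min <= self.n_total_max:
            raise ValueError("invalid n_total range")


@dataclass(frozen=True)
class NetworkSpec:
    """Directed random network at the scale of a small hub-gene module."""

    n_nodes: int = 9
    model: str = "fixed_edge_count"  # or "erdos_renyi"
    m_edges: int = 29
    edge_prob: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if self.model not in ("fixed_edge_count", "erdos_renyi"):
            raise ValueError(f"unknown model {self.model!r}")
        max_edges = self.n_nodes * (self.n_nodes - 1)
        if self.model == "fixed_edge_count" and not 0 <= self.m_edges <= max_edges:
            raise ValueError(f"m_edges must lie in [0, {max_edges}]")
        if not 0.0 <= self.edge_prob <= 1.0:
            raise ValueError("edge_prob must lie in [0, 1]")


def generate_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Draw a reproducible all-case cohort.

    Sex counts are deterministic (round of the male proportion); diabetes
    status is Bernoulli per patient with the sex-specific probability;
    ages are truncated-normal on the observed range.
    """
    rng = np.random.default_rng(spec.seed)
    n_male = round(spec.n_patients * spec.sex_proportion_male)
    sexes = ["male"] * n_male + ["female"] * (spec.n_patients - n_male)
    lo = (AGE_RANGE[0] - spec.age_mean) / spec.age_sd
    hi = (AGE_RANGE[1] - spec.age_mean) / spec.age_sd
    ages = truncnorm.rvs(
        lo, hi, loc=spec.age_mean, scale=spec.age_sd,
        size=spec.n_patients, random_state=rng,
    )
    dm_prob = {"male": spec.dm_prob_male, "female": spec.dm_prob_female}
    records = []
    for i, (sex, age) in enumerate(zip(sexes, ages)):
        records.append(
            PatientRecord(
                patient_id=f"P{i + 1:05d}",
                sex=sex,
                age=int(round(age)),
                dm_status=bool(rng.random() < dm_prob[sex]),
                t_stage=int(rng.integers(1, 5)),
                n_stage=int(rng.integers(0, 4)),
                m_stage=int(rng.random() < 0.01),
            )
        )
    return records


def generate_literature(
    spec: LiteratureSpec,
) -> tuple[list[AbmObservation], dict[str, bool]]:
    """Draw a gene panel of polarity counts plus ground-truth labels.

    Returns ``(observations, truth)`` where ``truth[gene]`` is True for
    planted associations — the labels allow type-I and power assessment
    of the downstream binomial scoring.
    """
    rng = np.random.default_rng(spec.seed)
    n_true = round(spec.n_genes * spec.frac_true)
    observations, truth = [], {}
    for i in range(spec.n_genes):
        gene = f"G{i + 1:06d}"
        is_true = i < n_true
        p = spec.p_true if is_true else spec.p_null
        n_total = int(rng.integers(spec.n_total_min, spec.n_total_max + 1))
        n_pos = int(rng.binomial(n_total, p))
        pos_refs = n_pos
        neg_refs = n_total - n_pos
        observations.append(
            AbmObservation(
                gene=gene,
                disease=spec.disease,
                n_pos=n_pos,
                n_total=n_total,
                p_null=spec.p_null,
                pos_refs=pos_refs,
                neg_refs=neg_refs,
            )
        )
        truth[gene] = is_true
    return observations, truth


def generate_network(spec: NetworkSpec) -> DirectedGeneNetwork:
    """Draw a random simple directed network (no self-loops).

    ``fixed_edge_count`` samples exactly m distinct ordered pairs
    uniformly; ``erdos_renyi`` includes each ordered pair independently
    with ``edge_prob``.
    """
    rng = np.random.default_rng(spec.seed)
    names = [f"G{i + 1:03d}" for i in range(spec.n_nodes)]
    pairs = [
        (names[i], names[j])
        for i in range(spec.n_nodes)
        for j in range(spec.n_nodes)
        if i != j
    ]
    if spec.model == "fixed_edge_count":
        idx = rng.choice(len(pairs), size=spec.m_edges, replace=False)
        chosen = [pairs[i] for i in sorted(idx)]
    else:
        chosen = [p for p in pairs if rng.random() < spec.edge_prob]
    signs = ["+", "-"]
    edges = [(s, t, signs[int(rng.integers(0, 2))]) for s, t in chosen]
    return DirectedGeneNetwork.from_edges(edges, extra_nodes=names)


def generate_gene_sets(
    universe_size: int,
    size_a: int,
    size_b: int,
    forced_overlap: int | None = None,
    seed: int = 0,
    labels: tuple[str, str] = ("set_a", "set_b"),
) -> tuple[GeneSet, GeneSet]:
    """Draw two gene sets from a finite universe, optionally with an
    exact intersection size."""
    if max(size_a, size_b) > universe_size:
        raise ValueError("set size exceeds universe")
    rng = np.random.default_rng(seed)
    universe = np.array([f"G{i + 1:06d}" for i in range(universe_size)])
    if forced_overlap is None:
        a = rng.choice(universe, size=size_a, replace=False)
        b = rng.choice(universe, size=size_b, replace=False)
    else:
        if forced_overlap > min(size_a, size_b):
            raise ValueError("forced_overlap exceeds a set size")
        if size_a + size_b - forced_overlap > universe_size:
            raise ValueError("universe too small for requested sizes and overlap")
        perm = rng.permutation(universe)
        shared = perm[:forced_overlap]
        only_a = perm[forced_overlap : size_a]
        only_b = perm[size_a : size_a + size_b - forced_overlap]
        a = np.concatenate([shared, only_a])
        b = np.concatenate([shared, only_b])
    return (
        GeneSet.from_iterable(labels[0], a),
        GeneSet.from_iterable(labels[1], b),
    )
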