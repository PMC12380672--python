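"""Binomial scoring of literature-derived gene-disease associations.

Each gene-disease pair comes with a count of positive-polarity findings
``n_pos`` out of ``n_total`` polarity-adjusted observations.  Under the
null of no association, polarity is at chance level ``p_null`` (0.5 by
default — a choice, not a law; see docs/methods.md), and the association
p-value is the upper binomial tail P(X >= n_pos).  Benjamini-Hochberg
q-values are computed within each disease separately, and pairs passing
the q-threshold form the significant association set.

Regulation sign (does the disease up- or down-regulate the gene, on
balance of the literature) is a simple majority vote of positive vs
negative reference counts; ties are "mixed".
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

__all__ = [
    "AbmObservation",
    "GeneDiseaseAssociation",
    "RegulationCounts",
    "abm_pvalue",
    "bh_fdr",
    "score_associations",
    "classify_sign",
    "read_observations",
    "write_associations",
]


@dataclass(frozen=True)
class AbmObservation:
    """Polarity counts for one gene-disease pair plus the null proportion."""

    gene: str
    disease: str
    n_pos: int
    n_total: int
    p_null: float = 0.5
    pos_refs: int | None = None
    neg_refs: int | None = None

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        if not 0 <= self.n_pos <= self.n_total:
            raise ValueError("n_pos must lie in [0, n_total]")
        if not 0.0 < self.p_null < 1.0:
            raise ValueError("p_null must lie in (0, 1)")


@dataclass(frozen=True)
class RegulationCounts:
    pos_refs: int
    neg_refs: int

    def __post_init__(self) -> None:
        if self.pos_refs < 0 or self.neg_refs < 0:
            raise ValueError("reference counts must be non-negative")


@dataclass(frozen=True)
class GeneDiseaseAssociation:
    """Scored pair: raw p, within-disease q, supporting references, sign."""

    gene: str
    disease: str
    p_value: float
    q_value: float
    n_refs: int
    sign: str | None = None  # "positive" | "negative" | "mixed" | None

    def is_significant(self, q_threshold: float = 0.01) -> bool:
        return self.q_value <= q_threshold


def abm_pvalue(obs: AbmObservation) -> float:
    """Upper-tail binomial probability P(X >= n_pos | n_total, p_null).

    Uses the binomial survival function, which is numerically stable for
    small tails (never the naive ``1 - cdf``).
    """
    return float(binom.sf(obs.n_pos - 1, obs.n_total, obs.p_null))


def bh_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min_{j >= i} p_(j) * m / j on the ascending sort, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def classify_sign(counts: RegulationCounts) -> str:
    """Majority polarity: positive, negative, or mixed on a tie."""
    if counts.pos_refs + counts.neg_refs == 0:
        raise ValueError("no polarity evidence")
    if counts.pos_refs > counts.neg_refs:
        return "positive"
    if counts.neg_refs > counts.pos_refs:
        return "negative"
    return "mixed"


def score_associations(
    observations: Iterable[AbmObservation],
    q_threshold: float = 0.01,
) -> list[GeneDiseaseAssociation]:
    """Score every observation; q-values computed within each disease.

    All rows are returned (filtering is a view, not destruction): use
    ``[a for a in result if a.is_significant(q)]`` for the retained set.
    Output is ordered by (disease, gene); duplicate (gene, disease) keys
    are an error.
    """
    obs = list(observations)
    keys = [(o.gene, o.disease) for o in obs]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValueError(f"duplicate (gene, disease) observations: {dupes}")

    results: list[GeneDiseaseAssociation] = []
    by_disease: dict[str, list[AbmObservation]] = {}
    for o in obs:
        by_disease.setdefault(o.disease, []).append(o)
    for disease in sorted(by_disease):
        group = sorted(by_disease[disease], key=lambda o: o.gene)
        p = np.array([abm_pvalue(o) for o in group])
        q = bh_fdr(p)
        for o, pv, qv in zip(group, p, q):
            sign = None
            if o.pos_refs is not None and o.neg_refs is not None:
                if o.pos_refs + o.neg_refs > 0:
                    sign = classify_sign(RegulationCounts(o.pos_refs, o.neg_refs))
            results.append(
                GeneDiseaseAssociation(
                    gene=o.gene,
                    disease=disease,
                    p_value=float(pv),
                    q_value=float(qv),
                    n_refs=o.n_total,
                    sign=sign,
                )
            )
    return results


def read_observations(
    path: str | Path, p_null: float = 0.5
) -> list[AbmObservation]:
    """Read a TSV with columns gene, disease, n_pos, n_total
    (optional pos_refs, neg_refs)."""
    frame = pd.read_csv(path, sep="\t")
    required = {"gene", "disease", "n_pos", "n_total"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"missing column(s) {sorted(missing)} in {path}")
    has_refs = {"pos_refs", "neg_refs"} <= set(frame.columns)
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            AbmObservation(
                gene=str(row.gene),
                disease=str(row.disease),
                n_pos=int(row.n_pos),
                n_total=int(row.n_total),
                p_null=p_null,
                pos_refs=int(row.pos_refs) if has_refs else None,
                neg_refs=int(row.neg_refs) if has_refs else None,
            )
        )
    return out


def write_associations(
    associations: Sequence[GeneDiseaseAssociation], path: str | Path
) -> None:
    """Write scored associations as TSV (gene, disease, p, q, n_refs, sign)."""
    pd.DataFrame(
        [
            {
                "gene": a.gene,
                "disease": a.disease,
                "p_value": a.p_value,
                "q_value": a.q_value,
                "n_refs": a.n_refs,
                "sign": a.sign or "",
            }
            for a in associations
        ]
    ).to_csv(path, sep="\t", index=False)
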