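"""Signed disease -> gene -> disease path assembly.

Given two sets of significant signed regulatory edges — one per disease —
a cross-disease path exists for every gene regulated (with polarity
evidence) by both.  Each path records the sign on each side and whether
the two agree (concordant).  Paths are hypothesis-generating: they mark
genes whose literature-supported regulation is shared between the
diseases, not causal mediation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

from .litstats import GeneDiseaseAssociation

__all__ = [
    "RegulatoryEdge",
    "CrossDiseasePath",
    "assemble_paths",
    "pathway_report",
    "edges_from_associations",
]

_SIGNS = ("positive", "negative")


@dataclass(frozen=True)
class RegulatoryEdge:
    """A significant signed disease -> gene regulation claim."""

    disease: str
    gene: str
    sign: str  # "positive" | "negative"
    n_refs: int
    q_value: float

    def __post_init__(self) -> None:
        if self.sign not in _SIGNS:
            raise ValueError(f"sign must be one of {_SIGNS}, got {self.sign!r}")
        if self.n_refs < 1:
            raise ValueError("n_refs must be >= 1")
        if not 0.0 <= self.q_value <= 1.0:
            raise ValueError("q_value must lie in [0, 1]")


@dataclass(frozen=True)
class CrossDiseasePath:
    """source disease -> gene -> target disease with per-side signs."""

    source_disease: str
    gene: str
    target_disease: str
    source_sign: str
    target_sign: str

    @property
    def concordant(self) -> bool:
        return self.source_sign == self.target_sign


def _index(edges: Iterable[RegulatoryEdge]) -> dict[str, RegulatoryEdge]:
    out: dict[str, RegulatoryEdge] = {}
    for e in edges:
        if e.gene in out:
            raise ValueError(
                f"duplicate edge for ({e.disease!r}, {e.gene!r})"
            )
        out[e.gene] = e
    return out


def assemble_paths(
    edges_source: Iterable[RegulatoryEdge],
    edges_target: Iterable[RegulatoryEdge],
) -> list[CrossDiseasePath]:
    """One path per gene present in both edge sets, gene-alphabetical.

    Pure function of the two edge sets; no gene appears in the output
    unless it carries a signed edge on both sides.
    """
    src = _index(edges_source)
    tgt = _index(edges_target)
    paths = []
    for gene in sorted(set(src) & set(tgt)):
        paths.append(
            CrossDiseasePath(
                source_disease=src[gene].disease,
                gene=gene,
                target_disease=tgt[gene].disease,
                source_sign=src[gene].sign,
                target_sign=tgt[gene].sign,
            )
        )
    return paths


def edges_from_associations(
    associations: Sequence[GeneDiseaseAssociation],
    disease: str,
    q_threshold: float = 0.01,
) -> tuple[list[RegulatoryEdge], list[str]]:
    """Convert scored associations for one disease into signed edges.

    Returns ``(edges, unsigned_genes)``: genes passing the q-threshold but
    with no polarity majority (no refs, or a tie) go in the side list —
    they are candidates without directional evidence, never path members.
    """
    edges, unsigned = [], []
    for a in associations:
        if a.disease != disease or not a.is_significant(q_threshold):
            continue
        if a.sign in _SIGNS:
            edges.append(
                RegulatoryEdge(
                    disease=disease,
                    gene=a.gene,
                    sign=a.sign,
                    n_refs=max(a.n_refs, 1),
                    q_value=a.q_value,
                )
            )
        else:
            unsigned.append(a.gene)
    return edges, sorted(unsigned)


_DOT_COLORS = {"positive": "green", "negative": "red"}


def pathway_report(paths: Sequence[CrossDiseasePath], fmt: str = "json") -> str:
    """Serialize paths as json, tsv or dot (signs colored green/red).

    Every format carries a hypothesis-generating disclaimer; the dot
    export draws two edges per path (disease->gene, gene->disease).
    """
    if fmt == "json":
        return json.dumps(
            {
                "note": "hypothesis-generating associations, not causal evidence",
                "paths": [
                    {
                        "source_disease": p.source_disease,
                        "gene": p.gene,
                        "target_disease": p.target_disease,
                        "source_sign": p.source_sign,
                        "target_sign": p.target_sign,
                        "concordant": p.concordant,
                    }
                    for p in paths
                ],
            },
            indent=2,
        )
    if fmt == "tsv":
        lines = [
            "# hypothesis-generating associations, not causal evidence",
            "source_disease\tgene\ttarget_disease\tsource_sign\ttarget_sign\tconcordant",
        ]
        lines += [
            f"{p.source_disease}\t{p.gene}\t{p.target_disease}\t"
            f"{p.source_sign}\t{p.target_sign}\t{str(p.concordant).lower()}"
            for p in paths
        ]
        return "\n".join(lines) + "\n"
    if fmt == "dot":
        lines = [
            "digraph cross_disease_paths {",
            '  label="hypothesis-generating associations, not causal evidence";',
        ]
        for p in paths:
            lines.append(
                f'  "{p.source_disease}" -> "{p.gene}" '
                f'[color={_DOT_COLORS[p.source_sign]}];'
            )
            lines.append(
                f'  "{p.gene}" -> "{p.target_disease}" '
                f'[color={_DOT_COLORS[p.target_sign]}];'
            )
        lines.append("}")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {fmt!r} (expected json, tsv or dot)")
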