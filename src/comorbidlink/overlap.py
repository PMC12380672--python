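"""Cross-disease gene-set overlap enrichment against a finite universe.

Two disease gene lists drawn from the same universe of tested genes are
cross-tabulated (a = shared, b/c = private to each list, d = in neither)
and the overlap is scored with Fisher's exact test — one-sided (greater)
by default, since the question is enrichment.  The universe size is a
required, explicit parameter: substituting |A ∪ B| silently changes d and
with it the odds ratio.

Extremely enriched overlaps underflow double precision; results carry the
exact log10 p alongside, and the display string falls back to a
"< 4.95e-319" style bound, the floor convention used in literature-mining
association tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .cooccur import ContingencyTable, fisher_log_pvalue, odds_ratio

__all__ = ["GeneSet", "OverlapResult", "overlap_fisher", "venn_counts",
           "read_gene_list", "read_gmt"]

#: smallest p displayed exactly; smaller values print as "< 4.95e-319"
P_DISPLAY_FLOOR = 4.95e-319


@dataclass(frozen=True)
class GeneSet:
    """A labelled set of gene symbols, case-normalized to uppercase."""

    label: str
    members: frozenset[str]

    @classmethod
    def from_iterable(cls, label: str, genes: Iterable[str]) -> "GeneSet":
        return cls(label, frozenset(str(g).strip().upper() for g in genes if str(g).strip()))

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class OverlapResult:
    """One overlap-enrichment row: sizes, OR, and exact p (with log10)."""

    size_a: int
    size_b: int
    overlap: int
    universe_size: int
    odds_ratio: float
    p_value: float
    log10_p: float

    @property
    def p_display(self) -> str:
        if np.power(10.0, self.log10_p) < P_DISPLAY_FLOOR or self.p_value == 0.0:
            return f"< {P_DISPLAY_FLOOR:.3g}"
        return f"{self.p_value:.3g}"


def _resolve_counts(
    set_a: GeneSet | int,
    set_b: GeneSet | int,
    universe_size: int,
    overlap: int | None,
    universe: GeneSet | None,
) -> tuple[int, int, int]:
    if isinstance(set_a, GeneSet) and isinstance(set_b, GeneSet):
        if universe is not None:
            for label, s in ((set_a.label, set_a), (set_b.label, set_b)):
                outside = sorted(s.members - universe.members)
                if outside:
                    raise ValueError(
                        f"genes in {label!r} outside the declared universe: {outside[:10]}"
                    )
        return len(set_a), len(set_b), len(set_a.members & set_b.members)
    if overlap is None:
        raise ValueError("overlap count required when passing sizes instead of sets")
    return int(set_a), int(set_b), int(overlap)


def overlap_fisher(
    set_a: GeneSet | int,
    set_b: GeneSet | int,
    universe_size: int,
    *,
    overlap: int | None = None,
    universe: GeneSet | None = None,
    alternative: str = "greater",
) -> OverlapResult:
    """Fisher enrichment test of two gene sets in a finite universe.

    Accepts either explicit :class:`GeneSet` members (overlap computed,
    and membership validated against ``universe`` when given) or
    pre-tabulated counts via integer sizes plus ``overlap=``.

    The 2x2 table is (a=overlap, b=only-A, c=only-B, d=rest of universe);
    OR = ad/bc; p is the one-sided (greater) hypergeometric tail unless
    ``alternative`` says otherwise.
    """
    size_a, size_b, n_overlap = _resolve_counts(
        set_a, set_b, universe_size, overlap, universe
    )
    if n_overlap > min(size_a, size_b):
        raise ValueError("overlap exceeds a set size")
    if max(size_a, size_b) > universe_size:
        raise ValueError("set size exceeds universe size")
    d = universe_size - size_a - size_b + n_overlap
    if d < 0:
        raise ValueError("universe too small for the given sizes and overlap")
    table = ContingencyTable(n_overlap, size_a - n_overlap, size_b - n_overlap, d)
    logp = fisher_log_pvalue(table, alternative=alternative)
    return OverlapResult(
        size_a=size_a,
        size_b=size_b,
        overlap=n_overlap,
        universe_size=universe_size,
        odds_ratio=odds_ratio(table, continuity=False)
        if table.b * table.c > 0
        else float("inf"),
        p_value=float(np.exp(logp)),
        log10_p=logp / np.log(10.0),
    )


def venn_counts(set_a: GeneSet, set_b: GeneSet) -> tuple[int, int, int]:
    """Two-set Venn partition: (only in A, only in B, in both)."""
    both = len(set_a.members & set_b.members)
    return len(set_a) - both, len(set_b) - both, both


def read_gene_list(path: str | Path, label: str | None = None) -> GeneSet:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    path = Path(path)
    genes = [
        line.strip()
        for line in path.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return GeneSet.from_iterable(label or path.stem, genes)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """GMT format: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets.append(GeneSet.from_iterable(fields[0], fields[2:]))
    return sets
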