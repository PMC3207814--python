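"""Gene-set over-representation against the assigned-contig background.

One-sided hypergeometric upper-tail test per term, optionally in the
conservative EASE variant (one success removed from the overlap before
testing), with Benjamini-Hochberg adjustment across terms.  Gene ids are
opaque strings; term membership is intersected with the background before
testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom


class EnrichError(ValueError):
    pass


@dataclass(frozen=True)
class GeneSet:
    term: str
    name: str
    genes: frozenset[str]

    def __post_init__(self):
        if not self.genes:
            raise EnrichError(f"gene set {self.term!r} has no members")


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet] = field(default_factory=dict)

    def add(self, term: str, name: str, genes: Iterable[str]) -> None:
        if term in self.sets:
            raise EnrichError(f"duplicate term id {term!r}")
        self.sets[term] = GeneSet(term, name, frozenset(genes))

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    @classmethod
    def read_gmt(cls, path) -> "GeneSetCollection":
        """GMT format: term <tab> description <tab> member genes..."""
        coll = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    raise EnrichError(f"{path}:{lineno}: GMT line needs >=3 columns")
                coll.add(parts[0], parts[1], [g for g in parts[2:] if g])
        return coll

    def write_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for gs in self.sets.values():
                fh.write("\t".join([gs.term, gs.name, *sorted(gs.genes)]) + "\n")


def hypergeom_p(overlap: int, background: int, term_bg: int, n_hits: int,
                ease: bool = False) -> float:
    """Upper-tail P(X >= overlap) for drawing *n_hits* genes from a
    background of size *background* containing *term_bg* term members.

    With ``ease=True`` one success is removed from the overlap first
    (DAVID's EASE score), making single-gene overlaps never significant.
    """
    if overlap == 0:
        return 1.0
    k = overlap - 1 if ease else overlap
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, background, term_bg, n_hits))


def enrich(
    hit_genes: Iterable[str],
    background_genes: Iterable[str],
    sets: GeneSetCollection,
    ease: bool = True,
) -> pd.DataFrame:
    """Per-term over-representation of *hit_genes* within *background_genes*.

    Returns a DataFrame sorted by p-value with columns term, name, overlap,
    term_background, n_hits, n_background, p_value, p_bh.
    """
    hits = set(hit_genes)
    background = set(background_genes)
    offenders = hits - background
    if offenders:
        raise EnrichError(
            f"hit genes outside the background: {sorted(offenders)[:10]}"
        )
    n_bg = len(background)
    n_hits = len(hits)
    rows = []
    for gs in sets:
        members = gs.genes & background
        overlap = len(gs.genes & hits)
        p = hypergeom_p(overlap, n_bg, len(members), n_hits, ease=ease)
        rows.append(
            {
                "term": gs.term,
                "name": gs.name,
                "overlap": overlap,
                "term_background": len(members),
                "n_hits": n_hits,
                "n_background": n_bg,
                "p_value": p,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["term", "name", "overlap", "term_background", "n_hits",
                 "n_background", "p_value"],
    )
    if len(df):
        df["p_bh"] = bh_adjust(df["p_value"].to_numpy())
        df = df.sort_values(["p_value", "term"], kind="mergesort").reset_index(drop=True)
    else:
        df["p_bh"] = []
    return df


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise EnrichError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.clip(adjusted, 0.0, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out
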