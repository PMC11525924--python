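"""Pathway over-representation analysis of miRNA target genes.

For each pathway a 2x2 contingency table is formed over a fixed background
gene universe:

    a = |pathway ∩ targets|      b = |pathway \\ targets|
    c = |targets \\ pathway|      d = |background \\ (pathway ∪ targets)|

and tested with Fisher's exact test (one-sided over-representation by
default; enrichment analyses conventionally test the greater tail).
P-values are adjusted across the whole database with the
Benjamini-Hochberg step-up procedure and flagged at an FDR threshold
(0.05 by default). Pathways with zero possible overlap still enter the BH
family, keeping the family size fixed at |db|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import InvalidInputError, NamespaceError

log = logging.getLogger(__name__)

DEFAULT_FDR = 0.05


@dataclass
class PathwayDB:
    """Gene-set database over a fixed background universe."""

    pathways: dict            # pathway id -> frozenset of gene ids
    background: frozenset     # gene universe

    def __post_init__(self) -> None:
        if not self.pathways:
            raise InvalidInputError("pathway database is empty")
        for pid, genes in self.pathways.items():
            if not genes:
                raise InvalidInputError(f"pathway {pid!r} has an empty gene set")
            stray = set(genes) - self.background
            if stray:
                raise NamespaceError(
                    f"pathway {pid!r} gene {sorted(stray)[0]!r} outside background")

    def __len__(self) -> int:
        return len(self.pathways)


@dataclass
class TargetMap:
    """miRNA id -> target gene-id set (sets may be empty)."""

    targets: dict

    def union_targets(self, mirna_ids) -> frozenset:
        out = set()
        for mid in mirna_ids:
            out |= set(self.targets.get(mid, ()))
        return frozenset(out)


def contingency_table(pathway_genes, target_genes, background) -> tuple[int, int, int, int]:
    """(a, b, c, d) counts over the background universe."""
    pw, tg, bg = set(pathway_genes), set(target_genes), set(background)
    for name, s in (("pathway", pw), ("target", tg)):
        stray = s - bg
        if stray:
            raise NamespaceError(f"{name} gene {sorted(stray)[0]!r} outside background")
    a = len(pw & tg)
    b = len(pw - tg)
    c = len(tg - pw)
    d = len(bg) - a - b - c
    return a, b, c, d


def fisher_exact_p(table, sided: str = "greater") -> float:
    """Fisher's exact p for a 2x2 table.

    ``greater`` is the over-representation tail P(X >= a) under the
    hypergeometric null with the observed margins; ``two_sided`` sums the
    point probabilities <= the observed one (the standard two-sided rule).
    """
    a, b, c, d = (int(v) for v in table)
    if min(a, b, c, d) < 0:
        raise InvalidInputError("contingency counts must be nonnegative")
    N = a + b + c + d
    K = a + b          # pathway margin
    n = a + c          # target margin
    if sided == "greater":
        return float(min(1.0, hypergeom.sf(a - 1, N, K, n)))
    if sided == "two_sided":
        lo, hi = max(0, K + n - N), min(K, n)
        support = np.arange(lo, hi + 1)
        pmf = hypergeom.pmf(support, N, K, n)
        p_obs = hypergeom.pmf(a, N, K, n)
        return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))
    raise InvalidInputError(f"unknown sidedness {sided!r}")


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH step-up adjusted p-values, returned in input order and clipped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise InvalidInputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_pathways(target_genes, db: PathwayDB, fdr: float = DEFAULT_FDR,
                    sided: str = "greater") -> pd.DataFrame:
    """Over-representation table: one row per pathway.

    Target genes outside the background are dropped with a logged warning.
    Columns: a, b, c, d, overlap, p, p_adj, significant.
    """
    targets = set(target_genes)
    stray = targets - db.background
    if stray:
        log.warning("dropping %d target gene(s) outside the background (e.g. %r)",
                    len(stray), sorted(stray)[0])
        targets -= stray
    rows = {}
    for pid in sorted(db.pathways):
        a, b, c, d = contingency_table(db.pathways[pid], targets, db.background)
        rows[pid] = {"a": a, "b": b, "c": c, "d": d, "overlap": a,
                     "p": fisher_exact_p((a, b, c, d), sided=sided)}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "pathway_id"
    out["p_adj"] = benjamini_hochberg(out["p"].to_numpy())
    out["significant"] = out["p_adj"] < fdr
    return out


def top_overlap_pathways(tables: dict[str, pd.DataFrame], k: int = 10) -> pd.DataFrame:
    """Rank pathways by summed target-overlap count across groups.

    ``tables`` maps a group name (e.g. up / down / ns) to its enrichment
    table; all tables must cover the same pathways. Returns the top ``k``
    pathways (all if k exceeds the database size) with per-group overlap
    counts and significance flags.
    """
    if not tables:
        raise InvalidInputError("no enrichment tables given")
    groups = sorted(tables)
    index = tables[groups[0]].index
    for g in groups[1:]:
        if not tables[g].index.equals(index):
            raise InvalidInputError("enrichment tables cover different pathway sets")
    out = pd.DataFrame(index=index.copy())
    for g in groups:
        out[f"overlap_{g}"] = tables[g]["overlap"]
        out[f"significant_{g}"] = tables[g]["significant"]
    out["total_overlap"] = sum(tables[g]["overlap"] for g in groups)
    # total overlap descending; ties broken by pathway id ascending
    out = out.sort_index(kind="stable").sort_values(
        "total_overlap", ascending=False, kind="stable")
    return out.head(min(k, len(out)))
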