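"""Gene-set over-representation, pathway annotation, and target prioritization.

Over-representation of the selected gene list in user-supplied GMT collections
is tested with the hypergeometric upper tail (conditioning on the measured
gene universe) and Benjamini-Hochberg adjusted across sets. Genes can also be
annotated against a single-assignment nine-category pathway map, and joined
against a local drug-gene interaction table with exclusion filters to produce
a prioritized target list.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import PATHWAY_CATEGORIES

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "hypergeom_enrich",
    "bh_adjust",
    "annotate_categories",
    "prioritize_targets",
]


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions; symbols uppercase-normalized."""

    sets: dict[str, set[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def add(self, name: str, members: Iterable[str], description: str = "") -> None:
        members = {str(m).upper() for m in members if str(m).strip()}
        if not members:
            raise ValueError(f"gene set {name!r} is empty")
        self.sets[name] = members
        self.descriptions[name] = description


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (set name, description, tab-separated members)."""
    coll = GeneSetCollection()
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields, "
                             f"got {len(fields)}")
        name, desc, *members = fields
        coll.add(name, members, desc)
    if not coll.sets:
        warnings.warn(f"GMT file {path} contains no gene sets", stacklevel=2)
    return coll


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserved)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrich(query: Iterable[str], collection: GeneSetCollection,
                     universe: Iterable[str]) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each collection set.

    With N universe genes, K set members (after intersecting with the
    universe), n query genes and k overlaps, the upper-tail p-value is
    P(X >= k) for X ~ Hypergeometric(N, K, n). Returns one row per set with
    BH-adjusted q-values, sorted by p.
    """
    universe = {str(g).upper() for g in universe}
    if not universe:
        raise ValueError("empty gene universe")
    query = {str(g).upper() for g in query}
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:5]}")

    N, n = len(universe), len(query)
    rows = []
    for name in collection:
        members = collection[name] & universe
        if not members:
            continue
        K = len(members)
        overlap = sorted(query & members)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, n, N, min(p, 1.0), ";".join(overlap)))
    out = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p", "overlap"])
    if not out.empty:
        out["q"] = bh_adjust(out["p"])
        out = out.sort_values(["p", "set"]).reset_index(drop=True)
    else:
        out["q"] = []
    return out


def annotate_categories(genes: Iterable[str], category_map: Mapping[str, str],
                        categories: Sequence[str] = PATHWAY_CATEGORIES
                        ) -> tuple[pd.DataFrame, pd.Series]:
    """Assign each gene its single pathway category, or "unannotated".

    ``category_map`` maps gene symbol -> one of the allowed categories; a gene
    mapped to an unknown category violates the single-assignment scheme and
    raises. Returns the per-gene table and the per-category counts (annotated
    categories only).
    """
    allowed = set(categories)
    bad = {g: c for g, c in category_map.items() if c not in allowed}
    if bad:
        g, c = next(iter(bad.items()))
        raise ValueError(f"gene {g!r} mapped to unknown category {c!r}")

    genes = [str(g).upper() for g in genes]
    cmap = {str(g).upper(): c for g, c in category_map.items()}
    if len(cmap) != len(category_map):
        dupes = pd.Series([str(g).upper() for g in category_map]).value_counts()
        dup = dupes[dupes > 1].index[0]
        raise ValueError(f"gene {dup!r} assigned to more than one category")
    labels = [cmap.get(g, "unannotated") for g in genes]
    table = pd.DataFrame({"gene": genes, "category": labels})
    counts = table.loc[table["category"] != "unannotated", "category"].value_counts()
    counts = counts.reindex([c for c in categories if c in counts.index])
    return table, counts


def validate_category_frame(frame: pd.DataFrame) -> dict[str, str]:
    """Turn a (gene, category) table into a map, enforcing single assignment."""
    if not {"gene", "category"}.issubset(frame.columns):
        raise ValueError("category table needs columns 'gene' and 'category'")
    per_gene = frame.groupby(frame["gene"].str.upper())["category"].nunique()
    multi = per_gene[per_gene > 1]
    if len(multi):
        raise ValueError(f"gene {multi.index[0]!r} assigned to more than one category")
    return dict(zip(frame["gene"].str.upper(), frame["category"]))


def prioritize_targets(selected_genes: Sequence[str],
                       interactions: pd.DataFrame,
                       exclusions: GeneSetCollection | None = None) -> pd.DataFrame:
    """Join selected genes against a drug-gene interaction table and filter.

    ``selected_genes`` is ordered by association rank (best first).
    ``interactions`` needs columns gene, drug, source. Genes without any
    interaction are dropped; genes belonging to an exclusion set (e.g. BCR
    signaling members, or targets already in clinical trials) are kept in the
    table but flagged ``excluded`` with the set name as reason. Retained genes
    get a priority rank in association order.
    """
    required = {"gene", "drug", "source"}
    if not required.issubset(interactions.columns):
        missing = sorted(required - set(interactions.columns))
        raise ValueError(f"interaction table missing column(s): {missing}")
    if interactions[["gene", "drug"]].isna().any().any():
        raise ValueError("interaction table contains empty gene/drug cells")

    inter = interactions.copy()
    inter["gene"] = inter["gene"].astype(str).str.upper()
    by_gene = inter.groupby("gene")

    rows = []
    rank = 0
    for pos, gene in enumerate([str(g).upper() for g in selected_genes], start=1):
        if gene not in by_gene.groups:
            continue
        sub = by_gene.get_group(gene)
        drugs = ";".join(sorted(set(sub["drug"].astype(str))))
        sources = ";".join(sorted(set(sub["source"].astype(str))))
        reason = ""
        if exclusions is not None:
            hits = sorted(name for name in exclusions if gene in exclusions[name])
            reason = ";".join(hits)
        excluded = bool(reason)
        if not excluded:
            rank += 1
        rows.append((gene, pos, drugs, sources, excluded, reason,
                     rank if not excluded else np.nan))
    return pd.DataFrame(rows, columns=[
        "gene", "association_rank", "drugs", "sources",
        "excluded", "exclusion_reason", "priority_rank",
    ])
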