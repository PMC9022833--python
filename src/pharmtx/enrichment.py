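"""Gene-set over-representation of replicated genes.

For each substance the replicated genes are tested against every supplied
gene set with a one-sided (upper tail) hypergeometric test, using the full
set of analysed genes as the background universe. Sets are intersected with
the universe before testing; q-values are BH across all sets within a
substance; significant sets sharing an identical hit-gene list are collapsed
to the one with the highest odds ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ValidationError
from .diffexpr import bh_adjust

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "overrepresentation_test",
    "enrich_substance",
    "deduplicate_pathways",
]


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional source-ontology tag per set."""

    sets: dict[str, set[str]]
    ontology: dict[str, str] = field(default_factory=dict)
    description: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path, ontology: str = "") -> GeneSetCollection:
    """Parse a GMT file: one set per line, tab-delimited name, description, genes."""
    sets: dict[str, set[str]] = {}
    desc: dict[str, str] = {}
    onto: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{lineno}: GMT line has < 3 fields")
            name = parts[0]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = {g for g in parts[2:] if g}
            if not genes:
                raise ValidationError(f"{path}:{lineno}: set {name!r} has no genes")
            sets[name] = genes
            desc[name] = parts[1]
            onto[name] = ontology
    return GeneSetCollection(sets=sets, ontology=onto, description=desc)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection.sets:
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{collection.description.get(name, '')}\t{genes}\n")


def overrepresentation_test(
    hits: set[str],
    path_genes: set[str],
    background: set[str],
) -> tuple[int, float, float]:
    """Upper-tail hypergeometric test of a gene set against a hit list.

    Returns (overlap k, odds ratio, p) where p = P(X >= k) for
    X ~ Hypergeom(N = |background|, K = |set ∩ background|, n = |hits|) and
    the odds ratio comes from the 2x2 table (k, n-k, K-k, N-K-n+k) with a
    +0.5 Haldane-Anscombe correction when any cell is zero.
    """
    if not hits <= background:
        raise ValidationError("hit genes must be a subset of the background universe")
    path_in_bg = path_genes & background
    n_bg = len(background)
    n_set = len(path_in_bg)
    n_hits = len(hits)
    k = len(hits & path_in_bg)
    p = float(stats.hypergeom.sf(k - 1, n_bg, n_set, n_hits))
    a, b = k, n_hits - k
    c, d = n_set - k, n_bg - n_set - n_hits + k
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    return k, float(odds), p


def enrich_substance(
    hits: set[str],
    collection: GeneSetCollection,
    background: set[str],
    substance: str = "",
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Test every set for over-representation of one substance's hit genes.

    Sets disjoint from the background are skipped. q-values are BH across all
    tested sets jointly (one family per substance, across ontologies).
    Returns a frame with one row per tested set.
    """
    if not hits:
        return pd.DataFrame(
            columns=["substance", "set", "ontology", "k", "K", "n", "N",
                     "odds_ratio", "p", "q", "significant", "hit_genes"]
        )
    rows = []
    for name in sorted(collection.sets):
        path_in_bg = collection.sets[name] & background
        if not path_in_bg:
            continue
        k, odds, p = overrepresentation_test(hits, collection.sets[name], background)
        rows.append(
            {
                "substance": substance,
                "set": name,
                "ontology": collection.ontology.get(name, ""),
                "k": k,
                "K": len(path_in_bg),
                "n": len(hits),
                "N": len(background),
                "odds_ratio": odds,
                "p": p,
                "hit_genes": ",".join(sorted(hits & path_in_bg)),
            }
        )
    result = pd.DataFrame(rows)
    if result.empty:
        result["q"] = []
        result["significant"] = []
        return result
    result["q"] = bh_adjust(result["p"].to_numpy())
    result["significant"] = result["q"] <= fdr
    return result


def deduplicate_pathways(result: pd.DataFrame) -> pd.DataFrame:
    """Collapse significant sets that are enriched by the identical hit-gene list.

    Within each substance, among significant sets sharing the same hit genes
    only the set with the highest odds ratio is kept (ties: smaller p, then
    lexicographic set name). Non-significant rows pass through unchanged.
    """
    if result.empty:
        return result
    sig = result[result["significant"]].copy()
    rest = result[~result["significant"]]
    if sig.empty:
        return result
    sig = sig.sort_values(
        by=["substance", "hit_genes", "odds_ratio", "p", "set"],
        ascending=[True, True, False, True, True],
        kind="stable",
    )
    deduped = sig.drop_duplicates(subset=["substance", "hit_genes"], keep="first")
    out = pd.concat([deduped, rest], ignore_index=True)
    return out.sort_values(by=["substance", "q", "set"], kind="stable").reset_index(
        drop=True
    )
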