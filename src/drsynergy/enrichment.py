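"""Signature interpretation: volcano tables and pathway over-representation.

Over-representation uses the one-sided hypergeometric upper tail
P(X >= k | N, K, n) against the universe of measured genes (those present in
the signature table), with Benjamini-Hochberg adjustment across pathways.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .signature_engine import SignatureTable

log = logging.getLogger(__name__)

#: -log10 value substituted for p = 0 (smallest positive double underflows there)
MAX_MINUS_LOG10_P = float(-np.log10(np.nextafter(0, 1)))


@dataclass
class GeneSetCollection:
    """Named gene sets intersected with a declared universe of measured genes."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValidationError("universe must be non-empty")
        for name, members in self.sets.items():
            if not members <= self.universe:
                raise ValidationError(f"gene set {name!r} has members outside the universe")
            if not members:
                raise ValidationError(f"gene set {name!r} is empty after intersection")


def make_collection(
    raw_sets: dict[str, set[str]], universe, descriptions: dict[str, str] | None = None
) -> GeneSetCollection:
    """Intersect raw sets with the universe, dropping emptied sets."""
    universe = frozenset(universe)
    kept, desc = {}, {}
    for name, members in raw_sets.items():
        inter = frozenset(members) & universe
        if inter:
            kept[name] = inter
            desc[name] = (descriptions or {}).get(name, "")
        else:
            log.info("gene set %s empty after universe intersection; dropped", name)
    return GeneSetCollection(sets=kept, descriptions=desc, universe=universe)


def read_gmt(path: str | Path, universe) -> GeneSetCollection:
    """Read a GMT file (set name TAB description TAB member genes...)."""
    raw, desc = {}, {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(f"{path}: line {lineno}: expected name, description, >=1 gene")
        raw[parts[0]] = set(g for g in parts[2:] if g)
        desc[parts[0]] = parts[1]
    return make_collection(raw, universe, desc)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, collection.descriptions.get(name, "")] + sorted(members))
        for name, members in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def volcano_table(sig: SignatureTable) -> pd.DataFrame:
    """Per-gene (gene, delta, minus_log10_p, direction) rows for volcano displays.

    p = 0 (possible for degenerate genes) maps to the maximum representable
    -log10 and is flagged in ``p_underflow``.
    """
    t = sig.table
    underflow = t["p_value"] == 0
    with np.errstate(divide="ignore"):
        mlp = -np.log10(t["p_value"].to_numpy())
    mlp = np.where(underflow, MAX_MINUS_LOG10_P, mlp)
    return pd.DataFrame(
        {
            "gene": t["gene"],
            "delta": t["delta"],
            "minus_log10_p": mlp,
            "direction": t["direction"],
            "p_underflow": underflow.to_numpy(),
        }
    )


def enrich(query, collection: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric over-representation of the query in each gene set.

    Query genes outside the universe are dropped and counted. Returns one row
    per pathway, sorted by p-value, with BH q-values across pathways.
    """
    query = set(query)
    outside = query - collection.universe
    query &= collection.universe
    if outside:
        log.warning("%d query genes outside the universe were dropped", len(outside))
    if not query:
        log.warning("empty query after universe intersection; no enrichment computed")
        return pd.DataFrame(
            columns=["pathway", "description", "k", "K", "n", "N", "p_value", "q_value", "overlap_genes"]
        )

    N = len(collection.universe)
    n = len(query)
    rows = []
    for name, members in collection.sets.items():
        overlap = sorted(query & members)
        k, K = len(overlap), len(members)
        # upper tail P(X >= k); survival function is P(X > k-1)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"pathway": name, "description": collection.descriptions.get(name, ""),
             "k": k, "K": K, "n": n, "N": N, "p_value": min(p, 1.0),
             "overlap_genes": ",".join(overlap)}
        )
    result = pd.DataFrame(rows)
    result["q_value"] = multipletests(result["p_value"], method="fdr_bh")[1]
    result = result.sort_values(["p_value", "pathway"], kind="mergesort").reset_index(drop=True)
    result.attrs["dropped_outside_universe"] = len(outside)
    return result[
        ["pathway", "description", "k", "K", "n", "N", "p_value", "q_value", "overlap_genes"]
    ]
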