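"""Exhaustive drug-pair screens: score all C(n,2) pairs per cell line, rank top-k.

Rankings are deterministic: scores sort descending, ties break by
lexicographic (drug_a, drug_b) order, and drugs lacking a representation
under the feature regime are excluded with a logged ledger rather than
silently dropped.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import pandas as pd

from . import synergy_models
from .errors import ValidationError
from .feature_assembly import FeatureSpec, PairDataset, build_pair_dataset
from .synergy_models import FittedModel

log = logging.getLogger(__name__)


@dataclass
class RankedScreen:
    """Ranked predicted-synergy table for one cell line."""

    cell_line: str
    table: pd.DataFrame = field(repr=False)  # rank, drug_a, drug_b, pred_score
    provenance: dict = field(default_factory=dict)


def rank_pairs(
    drugs,
    cell_lines,
    model: FittedModel,
    drug_features: pd.DataFrame,
    spec: FeatureSpec,
    cell_context: pd.DataFrame | None = None,
    top_k: int | None = None,
) -> dict[str, RankedScreen]:
    """Score every unordered drug pair in every cell line and rank descending.

    Returns one :class:`RankedScreen` per cell line; ``top_k=None`` keeps all
    pairs. Input drug order is irrelevant — pairs are canonicalized to
    lexicographic order before assembly.
    """
    if top_k is not None and top_k < 1:
        raise ValidationError(f"top_k must be >= 1, got {top_k}")
    drugs = sorted(set(drugs))
    excluded = [d for d in drugs if d not in drug_features.index]
    if excluded:
        log.warning("drugs without a representation excluded from screen: %s", excluded)
    usable = [d for d in drugs if d not in excluded]
    if len(usable) < 2:
        raise ValidationError("need at least 2 representable drugs to enumerate pairs")

    pairs = list(itertools.combinations(usable, 2))
    screens: dict[str, RankedScreen] = {}
    for cell in cell_lines:
        candidates = pd.DataFrame(
            {
                "drug_a": [a for a, _ in pairs],
                "drug_b": [b for _, b in pairs],
                "cell_line": cell,
                "score": 0.0,  # placeholder label; only features are used
            }
        )
        dataset: PairDataset = build_pair_dataset(drug_features, candidates, spec, cell_context)
        preds = synergy_models.predict(model, dataset)
        table = dataset.keys.assign(pred_score=preds)
        table = table.sort_values(
            ["pred_score", "drug_a", "drug_b"], ascending=[False, True, True], kind="mergesort"
        ).reset_index(drop=True)
        if top_k is not None:
            table = table.head(top_k)
        table.insert(0, "rank", range(1, len(table) + 1))
        screens[cell] = RankedScreen(
            cell_line=cell,
            table=table[["rank", "drug_a", "drug_b", "pred_score"]],
            provenance={
                "regime": spec.regime,
                "model": model.spec.algorithm,
                "n_pairs_scored": len(pairs),
                "excluded_drugs": excluded,
                "top_k": top_k,
            },
        )
    return screens


def write_screen(screen: RankedScreen, path) -> None:
    """Tables 'Rank, Drug A, Drug B, Pred-Score' layout as TSV."""
    out = screen.table.rename(
        columns={"rank": "Rank", "drug_a": "Drug A", "drug_b": "Drug B", "pred_score": "Pred-Score"}
    )
    out.to_csv(path, sep="\t", index=False)
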