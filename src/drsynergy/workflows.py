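"""Glue: cohort -> per-drug signatures -> regime-specific pair datasets.

These helpers chain the module-level operations exactly as the analysis
drivers do, so tests, the command-line interface and scripts share one path.
Signatures are computed once from the expression/IC50 cohort, which is
disjoint from the synergy labels being predicted, so this is not target
leakage.
"""

from __future__ import annotations

import logging
from typing import Mapping

import pandas as pd

from .containers import ExpressionMatrix
from .errors import InsufficientDataError
from .feature_assembly import (
    FeatureSpec,
    PairDataset,
    basal_expression,
    build_pair_dataset,
    signature_matrix,
    significant_gene_union,
)
from .signature_engine import (
    SignatureParams,
    SignatureTable,
    TREATED_COMPARTMENT,
    compute_drs,
    compute_ds,
    label_sensitivity,
    select_condition,
)
from .synthetic_data import CANONICAL_DOSE, CANONICAL_TIME, SyntheticCohort

log = logging.getLogger(__name__)


def cohort_signatures(
    cohort: SyntheticCohort,
    kind: str = "DRS",
    params: SignatureParams | None = None,
    compartment: str = TREATED_COMPARTMENT,
    dose: str = CANONICAL_DOSE,
    time: str = CANONICAL_TIME,
) -> dict[str, SignatureTable]:
    """One DS or DRS signature per drug at the canonical condition.

    Drugs for which the signature cannot be computed (e.g. too few cell lines
    on one side of the median split) are skipped with a log entry.
    """
    expr: ExpressionMatrix = select_condition(cohort.expression, dose, time)
    signatures: dict[str, SignatureTable] = {}
    for drug in cohort.drugs:
        try:
            if kind == "DS":
                signatures[drug] = compute_ds(expr, drug, params)
            else:
                labeling = label_sensitivity(cohort.ic50, drug)
                signatures[drug] = compute_drs(expr, labeling, drug, params, compartment)
        except InsufficientDataError as exc:
            log.warning("skipping %s signature for %s: %s", kind, drug, exc)
    return signatures


def regime_dataset(
    cohort: SyntheticCohort,
    regime: str,
    signatures: Mapping[str, SignatureTable] | None = None,
    gene_subset=None,
    include_cell_context: bool = True,
    context_genes=None,
    delta_threshold: float = 0.0,
    q_threshold: float = 0.05,
) -> PairDataset:
    """Assemble the cohort's pair dataset under one feature regime.

    For DS/DRS the gene subset defaults to the union of genes significant for
    any drug at (delta_threshold, q_threshold); cellular context (basal
    expression) is appended by default for every regime so the comparison
    across regimes differs only in the drug representation. ``context_genes``
    restricts the context rows (pass the DS/DRS gene subset to give the
    structure regime the identical cellular features).
    """
    context = basal_expression(cohort.expression) if include_cell_context else None
    if regime == "structure":
        if context is not None and context_genes is not None:
            context = context.loc[list(context_genes)]
        spec = FeatureSpec(regime="structure", include_cell_context=include_cell_context)
        return build_pair_dataset(cohort.fingerprints, cohort.synergy, spec, context)
    if signatures is None:
        signatures = cohort_signatures(cohort, kind=regime)
    if gene_subset is None:
        gene_subset = significant_gene_union(signatures, delta_threshold, q_threshold)
    features = signature_matrix(signatures, gene_subset)
    spec = FeatureSpec(
        regime=regime,
        gene_subset=tuple(gene_subset),
        include_cell_context=include_cell_context,
    )
    return build_pair_dataset(features, cohort.synergy, spec, context)
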