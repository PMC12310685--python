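"""Symmetric per-(drugA, drugB, cell line) feature rows under three regimes.

A drug is represented either by its fingerprint bits ("structure" regime) or
by its signature delta vector over a gene subset ("DS" / "DRS" regimes). Two
drug vectors f(A), f(B) are combined order-invariantly, by default as
[f(A) + f(B), |f(A) - f(B)|]; optionally the cell line's basal (control)
expression over the same gene subset is appended as cellular context.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .errors import EmptyDatasetError, ValidationError
from .signature_engine import SignatureTable, call_significant

REGIMES = ("structure", "DS", "DRS")
SUM_ABSDIFF = "sum_absdiff"
SORTED_CONCAT = "sorted_concat"

KEY_COLUMNS = ("drug_a", "drug_b", "cell_line")


@dataclass(frozen=True)
class FeatureSpec:
    """How pair feature rows are assembled.

    ``gene_subset=None`` means all genes in the signature tables (ignored for
    the structure regime). ``standardize`` z-scores each feature over the
    assembled table — use it only for standalone datasets; cross-validation
    refits standardization on each training split instead.
    """

    regime: str
    gene_subset: tuple[str, ...] | None = None
    symmetrization: str = SUM_ABSDIFF
    include_cell_context: bool = False
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValidationError(f"unknown regime {self.regime!r}; expected one of {REGIMES}")
        if self.symmetrization not in (SUM_ABSDIFF, SORTED_CONCAT):
            raise ValidationError(f"unknown symmetrization {self.symmetrization!r}")
        if self.gene_subset is not None and len(self.gene_subset) == 0:
            raise ValidationError("gene_subset must be non-empty when given")


@dataclass
class PairDataset:
    """Assembled feature rows with synergy labels and provenance."""

    keys: pd.DataFrame = field(repr=False)  # drug_a, drug_b, cell_line
    X: pd.DataFrame = field(repr=False)  # one column per feature name
    y: pd.Series = field(repr=False)  # synergy score
    spec: FeatureSpec = field(default_factory=lambda: FeatureSpec("structure"))
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.keys) == len(self.X) == len(self.y)):
            raise ValidationError("keys, X and y must have equal row counts")
        if self.X.isna().any().any():
            raise ValidationError("missing feature values in pair dataset")

    @property
    def n_rows(self) -> int:
        return len(self.X)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def subset(self, idx) -> "PairDataset":
        idx = np.asarray(idx)
        return PairDataset(
            keys=self.keys.iloc[idx].reset_index(drop=True),
            X=self.X.iloc[idx].reset_index(drop=True),
            y=self.y.iloc[idx].reset_index(drop=True),
            spec=self.spec,
            provenance=dict(self.provenance),
        )


def signature_matrix(
    signatures: Mapping[str, SignatureTable], gene_subset=None
) -> pd.DataFrame:
    """Stack per-drug signature deltas into a drugs x genes matrix."""
    rows = {}
    for drug, sig in signatures.items():
        rows[drug] = sig.table.set_index("gene")["delta"]
    mat = pd.DataFrame(rows).T
    mat.index.name = "drug"
    if gene_subset is not None:
        missing = [g for g in gene_subset if g not in mat.columns]
        if missing:
            raise ValidationError(f"gene_subset genes absent from signatures: {missing[:5]}...")
        mat = mat.loc[:, list(gene_subset)]
    return mat


def significant_gene_union(
    signatures: Mapping[str, SignatureTable],
    delta_threshold: float = 0.0,
    q_threshold: float = 0.05,
) -> list[str]:
    """Union over drugs of genes called up or down; sorted for determinism."""
    genes: set[str] = set()
    for sig in signatures.values():
        up, down = call_significant(sig, delta_threshold, q_threshold)
        genes |= up | down
    return sorted(genes)


def basal_expression(expr: ExpressionMatrix) -> pd.DataFrame:
    """Genes x cell lines basal matrix: mean over each line's control samples."""
    controls = expr.control_samples()
    groups = controls.groupby("cell_line").groups
    cols = {cell: expr.values[list(ids)].mean(axis=1) for cell, ids in groups.items()}
    return pd.DataFrame(cols)


def _symmetrize(fa: np.ndarray, fb: np.ndarray, order: np.ndarray, spec: FeatureSpec, names):
    if spec.symmetrization == SUM_ABSDIFF:
        feats = np.hstack([fa + fb, np.abs(fa - fb)])
        cols = [f"sum:{c}" for c in names] + [f"absdiff:{c}" for c in names]
    else:  # sorted_concat: concatenate in lexicographic drug-id order
        first = np.where(order[:, None], fa, fb)
        second = np.where(order[:, None], fb, fa)
        feats = np.hstack([first, second])
        cols = [f"first:{c}" for c in names] + [f"second:{c}" for c in names]
    return feats, cols


def build_pair_dataset(
    drug_features: pd.DataFrame,
    synergy: pd.DataFrame,
    spec: FeatureSpec,
    cell_context: pd.DataFrame | None = None,
) -> PairDataset:
    """Join synergy rows to symmetrized drug-pair features.

    ``drug_features`` is drugs x columns (fingerprint bits or signature
    deltas); rows of ``synergy`` whose drugs (or, with cell context, cell
    lines) lack a representation are dropped and counted in the provenance.
    """
    missing_cols = set(KEY_COLUMNS + ("score",)) - set(synergy.columns)
    if missing_cols:
        raise ValidationError(f"synergy table missing columns: {sorted(missing_cols)}")
    if spec.regime != "structure" and spec.gene_subset is not None:
        drug_features = drug_features.loc[:, list(spec.gene_subset)]
    if spec.include_cell_context and cell_context is None:
        raise ValidationError("include_cell_context requires a cell_context matrix")

    known_drugs = set(drug_features.index)
    ok_drug = synergy["drug_a"].isin(known_drugs) & synergy["drug_b"].isin(known_drugs)
    dropped_missing_drug = int((~ok_drug).sum())
    keep = ok_drug
    dropped_missing_cell = 0
    if spec.include_cell_context:
        ok_cell = synergy["cell_line"].isin(set(cell_context.columns))
        dropped_missing_cell = int((ok_drug & ~ok_cell).sum())
        keep = ok_drug & ok_cell
    rows = synergy.loc[keep].reset_index(drop=True)
    if rows.empty:
        raise EmptyDatasetError(
            "no synergy rows survived assembly "
            f"(dropped_missing_drug={dropped_missing_drug}, dropped_missing_cell={dropped_missing_cell})"
        )

    fa = drug_features.loc[rows["drug_a"]].to_numpy(dtype=float)
    fb = drug_features.loc[rows["drug_b"]].to_numpy(dtype=float)
    order = (rows["drug_a"] <= rows["drug_b"]).to_numpy()
    feats, cols = _symmetrize(fa, fb, order, spec, drug_features.columns)
    if spec.include_cell_context:
        ctx = cell_context
        if spec.regime != "structure" and spec.gene_subset is not None:
            ctx = ctx.loc[list(spec.gene_subset)]
        feats = np.hstack([feats, ctx.loc[:, rows["cell_line"]].to_numpy().T])
        cols = cols + [f"ctx:{g}" for g in ctx.index]
    if not np.all(np.isfinite(feats)):
        raise ValidationError("non-finite values in assembled features")

    X = pd.DataFrame(feats, columns=cols)
    provenance = {
        "spec": asdict(replace(spec, gene_subset=list(spec.gene_subset) if spec.gene_subset else None)),
        "dropped_missing_drug": dropped_missing_drug,
        "dropped_missing_cell": dropped_missing_cell,
        "n_rows": int(len(rows)),
    }
    if spec.standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0).replace(0.0, 1.0)
        X = (X - mu) / sd
        provenance["standardized"] = True
    return PairDataset(
        keys=rows[list(KEY_COLUMNS)].copy(),
        X=X,
        y=rows["score"].rename("score"),
        spec=spec,
        provenance=provenance,
    )


def write_pair_dataset(dataset: PairDataset, path: str | Path) -> None:
    """TSV with key columns + features + score, plus a JSON provenance sidecar."""
    path = Path(path)
    out = pd.concat([dataset.keys, dataset.X, dataset.y], axis=1)
    out.to_csv(path, sep="\t", index=False)
    path.with_suffix(path.suffix + ".provenance.json").write_text(
        json.dumps(dataset.provenance, indent=2)
    )


def read_pair_dataset(path: str | Path) -> PairDataset:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    provenance = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    spec_dict = provenance.get("spec", {})
    if spec_dict.get("gene_subset") is not None:
        spec_dict = {**spec_dict, "gene_subset": tuple(spec_dict["gene_subset"])}
    spec = FeatureSpec(**spec_dict) if spec_dict else FeatureSpec("structure")
    feature_cols = [c for c in frame.columns if c not in KEY_COLUMNS + ("score",)]
    return PairDataset(
        keys=frame[list(KEY_COLUMNS)],
        X=frame[feature_cols],
        y=frame["score"],
        spec=spec,
        provenance=provenance,
    )
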