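"""Sensitivity labeling and differential-expression signatures.

Two per-drug, per-gene signatures are supported:

* **DS** (drug signature): mean expression in drug-treated samples minus
  mean expression in untreated controls — the drug-induced response.
* **DRS** (drug resistance signature): mean expression in resistant cell
  lines minus mean in sensitive cell lines, where resistance is the per-drug
  median split of IC50s (IC50 >= median => resistant).

Both use a two-sided Welch t-test per gene and Benjamini-Hochberg step-up
adjustment across genes; "up"/"down" calls require both an effect-size and an
adjusted-p threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CONTROL, TREATED, ExpressionMatrix, IC50Table
from .errors import EmptySelectionError, InsufficientDataError, ValidationError

log = logging.getLogger(__name__)

SENSITIVE = "sensitive"
RESISTANT = "resistant"

#: DRS expression compartments
TREATED_COMPARTMENT = "treated"
BASELINE_COMPARTMENT = "baseline"


@dataclass(frozen=True)
class SignatureParams:
    """Thresholds and conventions for signature computation.

    delta_threshold / q_threshold gate the per-gene "up"/"down" direction
    calls. ``flip_sign`` negates deltas and t-statistics, for callers who want
    the opposite orientation of the printed convention.
    """

    delta_threshold: float = 0.0
    q_threshold: float = 0.05
    flip_sign: bool = False

    def validate(self) -> None:
        if self.delta_threshold < 0:
            raise ValidationError(f"delta_threshold must be >= 0, got {self.delta_threshold}")
        if not (0 < self.q_threshold <= 1):
            raise ValidationError(f"q_threshold must be in (0, 1], got {self.q_threshold}")


@dataclass
class SensitivityLabeling:
    """Per-drug sensitive/resistant partition from the median-IC50 split."""

    drug: str
    status: pd.Series  # cell line -> SENSITIVE / RESISTANT
    threshold: float

    @property
    def sensitive(self) -> list[str]:
        return list(self.status.index[self.status == SENSITIVE])

    @property
    def resistant(self) -> list[str]:
        return list(self.status.index[self.status == RESISTANT])


@dataclass
class SignatureTable:
    """Per-gene differential scores with test statistics and direction calls."""

    drug: str
    kind: str  # "DS" or "DRS"
    table: pd.DataFrame = field(repr=False)  # gene, delta, t_stat, p_value, q_value, direction, degenerate
    n_group_a: int = 0  # treated / resistant
    n_group_b: int = 0  # control / sensitive
    params: SignatureParams = field(default_factory=SignatureParams)

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])


def label_sensitivity(ic50: IC50Table, drug: str) -> SensitivityLabeling:
    """Median split of one drug's IC50s: IC50 < median => sensitive, else resistant.

    The median is taken over that drug's cell lines only; with an even count
    it is the midpoint of the two central order statistics, and ties at the
    median are labeled resistant.
    """
    values = ic50.for_drug(drug)
    if len(values) < 2:
        raise InsufficientDataError(
            f"drug {drug!r} has {len(values)} IC50 value(s); need >= 2 to take a median split"
        )
    threshold = float(np.median(values.to_numpy()))
    status = pd.Series(
        np.where(values.to_numpy() < threshold, SENSITIVE, RESISTANT),
        index=values.index,
        name="status",
    )
    return SensitivityLabeling(drug=drug, status=status, threshold=threshold)


def select_condition(expr: ExpressionMatrix, dose: str, time: str) -> ExpressionMatrix:
    """Keep treated samples at the given (dose, time) plus all control samples."""
    meta = expr.samples
    is_treated = meta["condition"] == TREATED
    keep_treated = is_treated & (meta["dose"] == dose) & (meta["time"] == time)
    if not keep_treated.any():
        raise EmptySelectionError(f"no treated samples match dose={dose!r}, time={time!r}")
    dropped = int(is_treated.sum() - keep_treated.sum())
    keep = keep_treated | (meta["condition"] == CONTROL)
    log.info(
        "condition filter (dose=%s, time=%s): kept %d treated, dropped %d treated, kept %d controls",
        dose, time, int(keep_treated.sum()), dropped, int((meta["condition"] == CONTROL).sum()),
    )
    return expr.select_samples(meta.index[keep])


def _welch_table(
    group_a: np.ndarray, group_b: np.ndarray, genes, params: SignatureParams
) -> pd.DataFrame:
    """Per-gene delta = mean(a) - mean(b), Welch t, BH q, direction calls.

    Genes where both groups have zero within-group variance are flagged
    degenerate: p = 0 if the means differ, 1 otherwise.
    """
    delta = group_a.mean(axis=1) - group_b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant-gene cancellation noise
        t_stat, p_value = stats.ttest_ind(group_a, group_b, axis=1, equal_var=False)
    var_a = group_a.var(axis=1, ddof=1)
    var_b = group_b.var(axis=1, ddof=1)
    degenerate = (var_a == 0) & (var_b == 0)
    if degenerate.any():
        p_value = np.where(degenerate, np.where(delta != 0, 0.0, 1.0), p_value)
        degen_t = np.where(delta > 0, np.inf, np.where(delta < 0, -np.inf, 0.0))
        t_stat = np.where(degenerate, degen_t, t_stat)
    if params.flip_sign:
        delta, t_stat = -delta, -t_stat
    q_value = multipletests(p_value, method="fdr_bh")[1]
    direction = np.where(
        (delta > 0) & (delta >= params.delta_threshold) & (q_value <= params.q_threshold),
        "up",
        np.where(
            (delta < 0) & (-delta >= params.delta_threshold) & (q_value <= params.q_threshold),
            "down",
            "ns",
        ),
    )
    return pd.DataFrame(
        {
            "gene": list(genes),
            "delta": delta,
            "t_stat": t_stat,
            "p_value": p_value,
            "q_value": q_value,
            "direction": direction,
            "degenerate": degenerate,
        }
    )


def compute_ds(
    expr: ExpressionMatrix, drug: str, params: SignatureParams | None = None
) -> SignatureTable:
    """Drug signature: per-gene mean(treated) - mean(control) with Welch test + BH."""
    params = params or SignatureParams()
    params.validate()
    treated_ids = list(expr.treated_samples(drug).index)
    control_ids = list(expr.control_samples().index)
    if len(treated_ids) < 2 or len(control_ids) < 2:
        raise InsufficientDataError(
            f"DS for {drug!r} needs >= 2 treated and >= 2 control samples; "
            f"got {len(treated_ids)} treated, {len(control_ids)} control"
        )
    table = _welch_table(
        expr.values[treated_ids].to_numpy(),
        expr.values[control_ids].to_numpy(),
        expr.values.index,
        params,
    )
    return SignatureTable(
        drug=drug, kind="DS", table=table,
        n_group_a=len(treated_ids), n_group_b=len(control_ids), params=params,
    )


def compute_drs(
    expr: ExpressionMatrix,
    labeling: SensitivityLabeling,
    drug: str,
    params: SignatureParams | None = None,
    compartment: str = TREATED_COMPARTMENT,
) -> SignatureTable:
    """Drug resistance signature: per-gene mean(resistant) - mean(sensitive).

    ``compartment`` selects which expression profiles represent a cell line:
    its drug-treated sample (default) or its untreated baseline.
    """
    params = params or SignatureParams()
    params.validate()
    if compartment == TREATED_COMPARTMENT:
        pool = expr.treated_samples(drug)
    elif compartment == BASELINE_COMPARTMENT:
        pool = expr.control_samples()
    else:
        raise ValidationError(f"unknown compartment {compartment!r}")
    by_cell = pool.groupby("cell_line").groups
    res_ids = [s for c in labeling.resistant for s in by_cell.get(c, [])]
    sens_ids = [s for c in labeling.sensitive for s in by_cell.get(c, [])]
    if len(res_ids) < 2 or len(sens_ids) < 2:
        raise InsufficientDataError(
            f"DRS for {drug!r} needs >= 2 resistant and >= 2 sensitive cell lines with "
            f"{compartment} expression; got {len(res_ids)} resistant, {len(sens_ids)} sensitive"
        )
    table = _welch_table(
        expr.values[res_ids].to_numpy(),
        expr.values[sens_ids].to_numpy(),
        expr.values.index,
        params,
    )
    return SignatureTable(
        drug=drug, kind="DRS", table=table,
        n_group_a=len(res_ids), n_group_b=len(sens_ids), params=params,
    )


def call_significant(
    sig: SignatureTable, delta_threshold: float, q_threshold: float
) -> tuple[set[str], set[str]]:
    """Partition genes into (up, down) sets at the given thresholds.

    up: delta >= +delta_threshold (strictly positive) and q <= q_threshold;
    down: mirrored. Genes with delta == 0 are never called.
    """
    SignatureParams(delta_threshold=delta_threshold, q_threshold=q_threshold).validate()
    t = sig.table
    passes_q = t["q_value"] <= q_threshold
    up = set(t.loc[(t["delta"] > 0) & (t["delta"] >= delta_threshold) & passes_q, "gene"])
    down = set(t.loc[(t["delta"] < 0) & (-t["delta"] >= delta_threshold) & passes_q, "gene"])
    return up, down


# ---------------------------------------------------------------------------
# TSV round trip, one file per (drug, kind)
# ---------------------------------------------------------------------------

def write_signature(sig: SignatureTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# drug={sig.drug}\tkind={sig.kind}\tn_group_a={sig.n_group_a}\tn_group_b={sig.n_group_b}\n")
        sig.table.to_csv(fh, sep="\t", index=False)


def read_signature(path) -> SignatureTable:
    with open(path) as fh:
        header = fh.readline().lstrip("# ").strip()
        meta = dict(item.split("=", 1) for item in header.split("\t"))
        table = pd.read_csv(fh, sep="\t")
    return SignatureTable(
        drug=meta["drug"], kind=meta["kind"], table=table,
        n_group_a=int(meta["n_group_a"]), n_group_b=int(meta["n_group_b"]),
    )
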