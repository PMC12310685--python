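"""Seeded synthetic cohorts with planted resistance programs.

The generator emulates the statistical structure the signature pipeline
assumes: a panel of cell lines whose latent "resistance program" activities
drive (i) baseline expression of the program's genes, (ii) each drug's
log-IC50 (high activity => resistant), and (iii) pairwise synergy, which is
awarded only to drug pairs targeting *different* programs and scales with the
combined program activity of the cell line. Fingerprint bits are pure
Bernoulli noise so the structure feature regime is an informative negative
control. Everything is a deterministic function of the config and its seed.

Generative model, in order:

1. program activities  a[p, c] ~ N(0, 1) per program p and cell line c;
2. baseline expression x[g, c] = m[g] + resistance_effect * a[p(g), c]
   (for genes planted in a program) + N(0, noise_sd), with gene means
   m[g] ~ N(0, 1); baseline columns are the cohort's control samples;
3. each drug d targets one program p(d) (round-robin);
   log IC50[d, c] = a[p(d), c] + N(0, ic50_noise_sd), exported as
   IC50 = exp(log IC50) so values are positive concentrations;
4. treated sample (d, c) = baseline[:, c] + perturbation_effect on p(d)'s
   genes + fresh N(0, noise_sd), stamped dose="10uM", time="24h";
5. synergy s(d1, d2, c) = synergy_base
   + synergy_effect * 1[p(d1) != p(d2)] * z(a[p(d1), c] + a[p(d2), c])
   + N(0, synergy_noise_sd), where z standardizes across cell lines;
6. fingerprints[d, b] ~ Bernoulli(0.5), independent of everything above.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CONTROL, SAMPLE_FIELDS, TREATED, ExpressionMatrix, IC50Table
from .errors import CohortParseError, ValidationError

#: canonical treatment condition stamped on treated samples
CANONICAL_DOSE = "10uM"
CANONICAL_TIME = "24h"

_COUNT_FIELDS = (
    "n_genes",
    "n_cell_lines",
    "n_drugs",
    "n_programs",
    "genes_per_program",
    "n_fingerprint_bits",
)
_SD_FIELDS = ("noise_sd", "ic50_noise_sd", "synergy_noise_sd")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generative model; defaults define the reference cohort.

    Effects are expressed in units of the expression noise SD. The defaults
    plant four 25-gene resistance programs in a 1000-gene, 80-cell-line panel
    with a resistance shift of 1.5 SD, a 1 SD treatment perturbation, and a
    synergy bonus of 10 score units (on top of a baseline of 5, with 2 units
    of label noise) for complementary-program pairs.
    """

    n_genes: int = 1000
    n_cell_lines: int = 80
    n_drugs: int = 10
    n_programs: int = 4
    genes_per_program: int = 25
    resistance_effect: float = 1.5
    perturbation_effect: float = 1.0
    noise_sd: float = 1.0
    ic50_noise_sd: float = 0.3
    synergy_base: float = 5.0
    synergy_effect: float = 10.0
    synergy_noise_sd: float = 2.0
    n_fingerprint_bits: int = 64
    seed: int = 0

    def validate(self) -> None:
        for name in _COUNT_FIELDS:
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_programs * self.genes_per_program > self.n_genes:
            raise ValidationError(
                "n_programs * genes_per_program "
                f"({self.n_programs * self.genes_per_program}) exceeds n_genes ({self.n_genes})"
            )
        for name in _SD_FIELDS:
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass
class CohortTruth:
    """Ground truth of one simulated cohort."""

    program_genes: dict[str, list[str]]
    drug_program: dict[str, str]
    activities: pd.DataFrame  # programs x cell lines

    @property
    def planted_genes(self) -> set[str]:
        return set(itertools.chain.from_iterable(self.program_genes.values()))


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    ic50: IC50Table
    fingerprints: pd.DataFrame  # drugs x bits
    synergy: pd.DataFrame  # drug_a, drug_b, cell_line, score
    truth: CohortTruth
    config: SimulationConfig

    @property
    def drugs(self) -> list[str]:
        return list(self.fingerprints.index)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.truth.activities.columns)


def simulate_cohort(config: SimulationConfig | None = None) -> SyntheticCohort:
    """Draw one cohort from the generative model described in the module docstring."""
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    cells = [f"CL{j:03d}" for j in range(config.n_cell_lines)]
    drugs = [f"D{k:02d}" for k in range(config.n_drugs)]
    programs = [f"P{m}" for m in range(config.n_programs)]
    G, C, D, P = config.n_genes, config.n_cell_lines, config.n_drugs, config.n_programs

    # (1) latent per-cell-line program activities
    activities = rng.standard_normal((P, C))

    # (2) baseline expression; the first P*genes_per_program genes are planted blockwise
    gene_means = rng.normal(0.0, 1.0, G)
    program_of_gene = np.full(G, -1)
    for p in range(P):
        lo, hi = p * config.genes_per_program, (p + 1) * config.genes_per_program
        program_of_gene[lo:hi] = p
    planted = program_of_gene >= 0
    shift = np.zeros((G, C))
    shift[planted] = config.resistance_effect * activities[program_of_gene[planted]]
    baseline = gene_means[:, None] + shift + rng.normal(0.0, config.noise_sd, (G, C))

    # (3) drug -> program assignment and log-IC50s
    drug_program_idx = np.arange(D) % P
    log_ic50 = activities[drug_program_idx] + rng.normal(0.0, config.ic50_noise_sd, (D, C))
    ic50_rows = pd.DataFrame(
        {
            "drug": np.repeat(drugs, C),
            "cell_line": np.tile(cells, D),
            "ic50": np.exp(log_ic50).ravel(),
        }
    )

    # (4) one treated sample per (drug, cell line) at the canonical condition
    blocks = [baseline]
    sample_ids = [f"{c}.ctrl" for c in cells]
    meta_rows = [("", c, CONTROL, "", "") for c in cells]
    for k, d in enumerate(drugs):
        bump = np.where(program_of_gene == drug_program_idx[k], config.perturbation_effect, 0.0)
        treated = baseline + bump[:, None] + rng.normal(0.0, config.noise_sd, (G, C))
        blocks.append(treated)
        sample_ids += [f"{d}.{c}.trt" for c in cells]
        meta_rows += [(d, c, TREATED, CANONICAL_DOSE, CANONICAL_TIME) for c in cells]
    values = pd.DataFrame(np.hstack(blocks), index=pd.Index(genes, name="gene"), columns=sample_ids)
    samples = pd.DataFrame(meta_rows, index=pd.Index(sample_ids, name="sample_id"), columns=list(SAMPLE_FIELDS))
    expression = ExpressionMatrix(values=values, samples=samples)

    # (5) synergy for every unordered drug pair, every cell line
    syn_rows = []
    for da, db in itertools.combinations(drugs, 2):
        pa, pb = drug_program_idx[drugs.index(da)], drug_program_idx[drugs.index(db)]
        if pa != pb:
            combined = activities[pa] + activities[pb]
            sd = combined.std()
            z = (combined - combined.mean()) / sd if sd > 0 else np.zeros(C)
            signal = config.synergy_effect * z
        else:
            signal = np.zeros(C)
        score = config.synergy_base + signal + rng.normal(0.0, config.synergy_noise_sd, C)
        syn_rows.append(pd.DataFrame({"drug_a": da, "drug_b": db, "cell_line": cells, "score": score}))
    synergy = pd.concat(syn_rows, ignore_index=True)

    # (6) fingerprints: pure noise, no synergy signal
    fingerprints = pd.DataFrame(
        rng.integers(0, 2, (D, config.n_fingerprint_bits)),
        index=pd.Index(drugs, name="drug"),
        columns=[f"bit{b:03d}" for b in range(config.n_fingerprint_bits)],
    )

    truth = CohortTruth(
        program_genes={
            programs[p]: [genes[i] for i in np.flatnonzero(program_of_gene == p)] for p in range(P)
        },
        drug_program={d: programs[drug_program_idx[k]] for k, d in enumerate(drugs)},
        activities=pd.DataFrame(activities, index=pd.Index(programs, name="program"), columns=cells),
    )
    return SyntheticCohort(
        expression=expression,
        ic50=IC50Table(ic50_rows),
        fingerprints=fingerprints,
        synergy=synergy,
        truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# on-disk round trip (tab-separated tables + JSON manifest)
# ---------------------------------------------------------------------------

_FILES = {
    "expression": "expression.tsv",
    "samples": "samples.tsv",
    "ic50": "ic50.tsv",
    "fingerprints": "fingerprints.tsv",
    "synergy": "synergy.tsv",
    "truth_program_genes": "truth_program_genes.tsv",
    "truth_drug_programs": "truth_drug_programs.tsv",
    "truth_activities": "truth_activities.tsv",
}
MANIFEST = "manifest.json"


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict:
    """Write every cohort table as TSV plus a JSON manifest; returns the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    tables = {
        "expression": cohort.expression.values,
        "samples": cohort.expression.samples,
        "ic50": cohort.ic50.table,
        "fingerprints": cohort.fingerprints,
        "synergy": cohort.synergy,
        "truth_program_genes": pd.DataFrame(
            [(p, g) for p, gs in cohort.truth.program_genes.items() for g in gs],
            columns=["program", "gene"],
        ),
        "truth_drug_programs": pd.DataFrame(
            sorted(cohort.truth.drug_program.items()), columns=["drug", "program"]
        ),
        "truth_activities": cohort.truth.activities,
    }
    manifest: dict = {"format_version": 1, "seed": cohort.config.seed, "config": asdict(cohort.config), "files": {}}
    indexed = {"expression", "samples", "fingerprints", "truth_activities"}
    for name, frame in tables.items():
        path = directory / _FILES[name]
        frame.to_csv(path, sep="\t", index=name in indexed)
        manifest["files"][name] = {"path": _FILES[name], "rows": int(frame.shape[0])}
    (directory / MANIFEST).write_text(json.dumps(manifest, indent=2))
    return manifest


def _read_table(directory: Path, manifest: dict, name: str, **kwargs) -> pd.DataFrame:
    entry = manifest["files"].get(name)
    if entry is None:
        raise CohortParseError(f"manifest does not list table {name!r}")
    path = directory / entry["path"]
    if not path.exists():
        raise CohortParseError(f"{path}: file listed in manifest is missing")
    try:
        frame = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[], **kwargs)
    except Exception as exc:  # pragma: no cover - message formatting only
        raise CohortParseError(f"{path}: {exc}") from exc
    if frame.shape[0] != entry["rows"]:
        raise CohortParseError(
            f"{path}: expected {entry['rows']} rows per manifest, found {frame.shape[0]} (truncated or edited?)"
        )
    return frame


def read_cohort(directory: str | Path) -> SyntheticCohort:
    """Read a cohort written by :func:`write_cohort`; inverse up to float repr."""
    directory = Path(directory)
    manifest_path = directory / MANIFEST
    if not manifest_path.exists():
        raise CohortParseError(f"{manifest_path}: manifest not found")
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise CohortParseError(f"{manifest_path}: line {exc.lineno}: {exc.msg}") from exc

    config = SimulationConfig(**manifest["config"])
    expr = _read_table(directory, manifest, "expression", index_col=0)
    samples = _read_table(directory, manifest, "samples", index_col=0, dtype=str)
    ic50 = _read_table(directory, manifest, "ic50")
    if not {"drug", "cell_line", "ic50"} <= set(ic50.columns):
        raise CohortParseError(f"{directory / _FILES['ic50']}: missing required columns")
    fingerprints = _read_table(directory, manifest, "fingerprints", index_col=0)
    synergy = _read_table(directory, manifest, "synergy")
    prog_genes = _read_table(directory, manifest, "truth_program_genes")
    drug_prog = _read_table(directory, manifest, "truth_drug_programs")
    acts = _read_table(directory, manifest, "truth_activities", index_col=0)

    truth = CohortTruth(
        program_genes={p: list(sub["gene"]) for p, sub in prog_genes.groupby("program", sort=True)},
        drug_program=dict(zip(drug_prog["drug"], drug_prog["program"])),
        activities=acts,
    )
    return SyntheticCohort(
        expression=ExpressionMatrix(values=expr, samples=samples),
        ic50=IC50Table(ic50),
        fingerprints=fingerprints,
        synergy=synergy,
        truth=truth,
        config=config,
    )
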