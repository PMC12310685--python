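#!/usr/bin/env python
"""Simulate the reference cohort and write its tables for inspection.

The cohort: 1000 genes, 80 cell lines, 10 drugs over 4 planted resistance
programs (25 genes each), with synergy generated from resistance-program
complementarity and pure-noise fingerprints. Tables are written under
scratch/cohort/ (they are large); a small summary is printed.
"""

from pathlib import Path

from drsynergy import SimulationConfig, simulate_cohort, write_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    config = SimulationConfig(seed=1)
    cohort = simulate_cohort(config)
    out = ROOT / "scratch" / "cohort"
    manifest = write_cohort(cohort, out)

    print(f"cohort written to {out} ({len(manifest['files'])} tables)")
    print(f"expression: {cohort.expression.values.shape[0]} genes x "
          f"{cohort.expression.values.shape[1]} samples")
    print(f"synergy rows: {len(cohort.synergy)} "
          f"(score mean {cohort.synergy['score'].mean():.2f}, "
          f"sd {cohort.synergy['score'].std():.2f})")
    print("drug -> program:", cohort.truth.drug_program)


if __name__ == "__main__":
    main()
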