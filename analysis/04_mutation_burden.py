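"""Filter somatic SNVs and tier adjacent-normal mutation burden.

Runs the coverage / tumor-VAF / Fisher / blood-absence cascade per patient,
classifies burden from the fraction of detected variants with adjacent
VAF > 1%, and scores RNA-level expression of tumor mutations.
"""

from pathlib import Path

import pandas as pd

from fieldscape.io_formats import read_variants
from fieldscape.mutations import burden_table

COHORT = Path("scratch/cohort")
OUT = Path("results")


def main() -> None:
    variants = read_variants(COHORT / "variants.tsv")
    calls = burden_table(variants)
    OUT.mkdir(exist_ok=True)
    calls.to_csv(OUT / "mutation_burden.tsv", sep="\t", float_format="%.6g")
    print(f"burden classes: {calls['category'].value_counts().to_dict()}")
    print(f"RNA-positive samples (>=2 expressed mutant loci): "
          f"{int(calls['rna_positive'].sum())} of {len(calls)}")
    mod_high = calls["category"].isin(["moderate", "high"]).mean()
    print(f"moderate-or-high burden prevalence: {mod_high:.2f}")


if __name__ == "__main__":
    main()
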