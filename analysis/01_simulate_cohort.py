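"""Generate the working synthetic cohort: 100 tumor/blood/adjacent triplets.

Writes every pipeline input (beta matrices, SEG files, variant pileups,
expression counts, clinical table) plus the ground-truth table. Raw cohort
files are large, so they go under scratch/; downstream steps read from there.
"""

from pathlib import Path

from fieldscape.simulate import SimConfig, simulate_cohort

COHORT_DIR = Path("scratch/cohort")
SEED = 20240901


def main() -> None:
    config = SimConfig(n_patients=100, seed=SEED)
    paths = simulate_cohort(config, COHORT_DIR)
    occult = (config.occult_fractions >= 0.4).sum()
    field = config.field_effect_flags.sum()
    contaminated = (config.cn_contamination > 0).sum()
    print(f"wrote {len(paths)} files to {COHORT_DIR}")
    print(f"ground truth: {occult} occult-tumor patients, {field} field-effect, "
          f"{contaminated} CN-contaminated, adjacent VAF scale "
          f"{config.adjacent_vaf_scale}")


if __name__ == "__main__":
    main()
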