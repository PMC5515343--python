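"""Synthetic tumor/blood/adjacent-normal cohorts with known ground truth.

The generator emulates the signals the analysis stages look for:

* adjacent methylation as a per-patient mixture f*tumor + (1-f)*normal
  plus Gaussian probe noise (field effects instead shift a sparse 10%
  probe subset toward tumor);
* adjacent copy-number segments copied from tumor segments with
  probability = contamination, attenuated in amplitude; blood carries
  only optional germline CNVs injected into all three profiles;
* adjacent variant allele fractions as down-scaled tumor VAFs (tumor
  VAF uniform on [0.13, 0.60]; adjacent typically <5%) with binomial
  read counts at Poisson depths;
* two expression subtypes (active/inactive) shifting 10% of features on
  the log2 scale, miR labels agreeing with mRNA labels at a configurable
  concordance, and exponential survival with a subtype log-hazard and
  administrative censoring.

A single master seed spawns per-patient substreams, so a cohort is
byte-reproducible and extensible without perturbing existing patients.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from fieldscape.io_formats import (
    AGE_DECADES,
    ClinicalRecord,
    MatrixTable,
    SegRecord,
    STAGES,
    T_SIZES,
    TUMOR_SUBTYPES,
    write_clinical,
    write_matrix,
    write_seg,
    write_variants,
)

CHROM_LENGTH = 100_000_000  # simplified genome: 22 autosomes x 100 Mb
N_CHROMS = 22


@dataclass
class SimConfig:
    """Cohort-level simulation parameters (the study conditions)."""

    n_patients: int = 100
    seed: int = 0

    # methylation
    n_probes: int = 2000
    occult_fractions: Sequence[float] | None = None  # per patient, in [0,1]
    field_effect_flags: Sequence[bool] | None = None
    probe_noise_sd: float = 0.03
    field_offset: float = 0.3  # sparse shift toward tumor for field effects
    field_probe_fraction: float = 0.10

    # copy number
    n_segments: int = 8
    cn_contamination: Sequence[float] | None = None  # per patient, in [0,1]
    cn_attenuation: float = 0.8
    seg_length_range: tuple[int, int] = (150_000, 1_000_000)
    n_germline_cnvs: int = 0

    # somatic variants
    n_somatic_snvs: int = 40
    adjacent_vaf_scale: float = 0.03
    vaf_scales: Sequence[float] | None = None  # per patient; None -> mixture
    depth_mean: int = 200
    rna_depth_mean: int = 50
    blood_error_rate: float = 0.001

    # expression + survival
    n_mrna_features: int = 1000
    n_mir_features: int = 400
    subtype_effect_log2: float = 1.0
    affected_feature_fraction: float = 0.10
    p_active: float = 0.5
    mir_concordance: float = 0.90
    survival_log_hr: float = float(np.log(3.0))
    baseline_hazard: float = 0.05  # events per year in the inactive subtype
    censor_time: float = 10.0

    def __post_init__(self) -> None:
        for name in ("n_patients", "n_probes", "n_segments", "n_somatic_snvs",
                     "n_mrna_features", "n_mir_features", "depth_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("adjacent_vaf_scale", "p_active", "mir_concordance",
                     "cn_attenuation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.occult_fractions is None:
            # default cohort mix mirrors the observed methylation tiers:
            # ~15% occult (f>=0.4), ~36% field effect, remainder normal
            rng = np.random.default_rng(np.random.SeedSequence([self.seed, 9151]))
            n = self.n_patients
            fractions = np.zeros(n)
            flags = np.zeros(n, dtype=bool)
            roles = rng.choice(3, size=n, p=[0.15, 0.36, 0.49])
            fractions[roles == 0] = rng.uniform(0.4, 0.9, size=int((roles == 0).sum()))
            flags[roles == 1] = True
            self.occult_fractions = fractions
            if self.field_effect_flags is None:
                self.field_effect_flags = flags
        if self.field_effect_flags is None:
            self.field_effect_flags = np.zeros(self.n_patients, dtype=bool)
        if self.cn_contamination is None:
            rng = np.random.default_rng(np.random.SeedSequence([self.seed, 9152]))
            self.cn_contamination = np.where(
                rng.random(self.n_patients) < 0.10, 1.0, 0.0
            )
        if self.vaf_scales is None:
            # burden spectrum: most patients carry no detectable tumor DNA in
            # the adjacent tissue, a minority low / moderate / high levels
            rng = np.random.default_rng(np.random.SeedSequence([self.seed, 9153]))
            self.vaf_scales = rng.choice(
                [0.0, 0.005, self.adjacent_vaf_scale, 0.08],
                size=self.n_patients,
                p=[0.68, 0.08, 0.14, 0.10],
            )
        self.vaf_scales = np.asarray(self.vaf_scales, dtype=float)
        if len(self.vaf_scales) != self.n_patients:
            raise ValueError("vaf_scales must have length n_patients")
        self.occult_fractions = np.asarray(self.occult_fractions, dtype=float)
        self.field_effect_flags = np.asarray(self.field_effect_flags, dtype=bool)
        self.cn_contamination = np.asarray(self.cn_contamination, dtype=float)
        for arr_name in ("occult_fractions", "cn_contamination"):
            arr = getattr(self, arr_name)
            if len(arr) != self.n_patients:
                raise ValueError(f"{arr_name} must have length n_patients")
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"{arr_name} entries must lie in [0, 1]")

    def patient_rng(self, patient: int, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, int(patient), int(stream)])
        )

    def cohort_rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, 777, stream]))

    def patient_ids(self) -> list[str]:
        return [f"P{i:04d}" for i in range(self.n_patients)]


# ---------------------------------------------------------------------------
# methylation


def probe_architecture(config: SimConfig) -> dict[str, np.ndarray]:
    """Cohort-shared probe layout: baseline betas and hyper/hypo blocks.

    At differential probes the normal baseline is nearly flat while the
    tumor gain varies probe-to-probe, so the occult regression slope of an
    f-mixture recovers f (shared baseline variation would otherwise pull
    every sample's slope toward 1).
    """
    rng = config.cohort_rng(1)
    n = config.n_probes
    n_diff = max(550, int(0.3 * n) // 2)
    if 2 * n_diff > n:
        raise ValueError("n_probes too small for the differential probe blocks")
    hyper = np.arange(n_diff)
    hypo = np.arange(n_diff, 2 * n_diff)
    baseline = rng.uniform(0.3, 0.6, size=n)
    baseline[hyper] = rng.uniform(0.05, 0.15, size=n_diff)
    baseline[hypo] = rng.uniform(0.85, 0.95, size=n_diff)
    gain = rng.uniform(0.25, 0.8, size=n_diff)
    loss = rng.uniform(0.25, 0.8, size=n_diff)
    tumor_mean = baseline.copy()
    tumor_mean[hyper] += gain
    tumor_mean[hypo] -= loss
    return {
        "baseline": baseline,
        "tumor_mean": np.clip(tumor_mean, 0.0, 1.0),
        "hyper": hyper,
        "hypo": hypo,
    }


def simulate_methylation_triplet(
    config: SimConfig, patient: int, arch: dict[str, np.ndarray] | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (tumor, normal, adjacent) beta vectors for one patient."""
    if arch is None:
        arch = probe_architecture(config)
    rng = config.patient_rng(patient, 1)
    sd = config.probe_noise_sd
    n = config.n_probes
    tumor = arch["tumor_mean"] + rng.normal(0.0, sd, size=n)
    normal = arch["baseline"] + rng.normal(0.0, sd, size=n)
    tumor = np.clip(tumor, 0.0, 1.0)
    normal = np.clip(normal, 0.0, 1.0)
    f = float(config.occult_fractions[patient])
    if config.field_effect_flags[patient]:
        adjacent = normal.copy()
        n_field = int(round(config.field_probe_fraction * n))
        idx = rng.choice(n, size=n_field, replace=False)
        adjacent[idx] += np.sign(tumor[idx] - normal[idx]) * config.field_offset
    else:
        adjacent = f * tumor + (1.0 - f) * normal
    adjacent = np.clip(adjacent + rng.normal(0.0, sd, size=n), 0.0, 1.0)
    return tumor, normal, adjacent


def methylation_matrices(config: SimConfig) -> tuple[MatrixTable, MatrixTable, MatrixTable]:
    """Cohort beta matrices (tumor, normal, adjacent), probes x patients."""
    arch = probe_architecture(config)
    ids = config.patient_ids()
    cols = {"tumor": [], "normal": [], "adjacent": []}
    for i in range(config.n_patients):
        t, n, a = simulate_methylation_triplet(config, i, arch)
        cols["tumor"].append(t)
        cols["normal"].append(n)
        cols["adjacent"].append(a)
    probes = [f"cg{j:07d}" for j in range(config.n_probes)]

    def table(key: str) -> MatrixTable:
        df = pd.DataFrame(np.column_stack(cols[key]), index=probes, columns=ids)
        return MatrixTable(values=df, value_kind="beta")

    return table("tumor"), table("normal"), table("adjacent")


# ---------------------------------------------------------------------------
# copy number


def simulate_segments(
    config: SimConfig, patient: int
) -> tuple[list[SegRecord], list[SegRecord], list[SegRecord]]:
    """Return (tumor, blood, adjacent) segment profiles for one patient."""
    rng = config.patient_rng(patient, 2)
    pid = config.patient_ids()[patient]
    lo, hi = config.seg_length_range
    tumor: list[SegRecord] = []
    blood: list[SegRecord] = []
    adjacent: list[SegRecord] = []
    contamination = float(config.cn_contamination[patient])
    for _ in range(config.n_segments):
        chrom = str(rng.integers(1, N_CHROMS + 1))
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, CHROM_LENGTH - length))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        log2 = sign * rng.uniform(0.2, 1.0)
        tumor.append(SegRecord(f"{pid}-T", chrom, start, start + length, log2))
        if rng.random() < contamination:
            adjacent.append(
                SegRecord(
                    f"{pid}-A", chrom, start, start + length,
                    log2 * config.cn_attenuation,
                )
            )
    for _ in range(config.n_germline_cnvs):
        chrom = str(rng.integers(1, N_CHROMS + 1))
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, CHROM_LENGTH - length))
        log2 = rng.choice([-0.5, 0.5])
        for profile, suffix in ((tumor, "T"), (blood, "B"), (adjacent, "A")):
            profile.append(
                SegRecord(f"{pid}-{suffix}", chrom, start, start + length, float(log2))
            )
    for profile in (tumor, blood, adjacent):
        profile.sort(key=lambda r: (r.chrom, r.start))
    return tumor, blood, adjacent


# ---------------------------------------------------------------------------
# somatic variants


def simulate_variants(config: SimConfig, patient: int) -> pd.DataFrame:
    """Triplet pileups for one patient's somatic SNVs (see VARIANT_COLUMNS)."""
    rng = config.patient_rng(patient, 3)
    pid = config.patient_ids()[patient]
    m = config.n_somatic_snvs
    tumor_vaf = rng.uniform(0.13, 0.60, size=m)
    adj_vaf = np.clip(tumor_vaf * float(config.vaf_scales[patient]), 0.0, 1.0)
    bases = np.array(list("ACGT"))
    rows = []
    for i in range(m):
        t_depth = max(1, int(rng.poisson(config.depth_mean)))
        b_depth = max(1, int(rng.poisson(config.depth_mean)))
        n_depth = max(1, int(rng.poisson(config.depth_mean)))
        rna_depth = int(rng.poisson(config.rna_depth_mean))
        t_alt = int(rng.binomial(t_depth, tumor_vaf[i]))
        b_alt = int(rng.binomial(b_depth, config.blood_error_rate))
        n_alt = int(rng.binomial(n_depth, adj_vaf[i]))
        rna_alt = int(rng.binomial(rna_depth, adj_vaf[i])) if rna_depth else 0
        ref, alt = rng.choice(4, size=2, replace=False)
        rows.append(
            {
                "patient": pid,
                "chrom": str(rng.integers(1, N_CHROMS + 1)),
                "pos": int(rng.integers(1, CHROM_LENGTH)),
                "ref": bases[ref],
                "alt": bases[alt],
                "t_ref": t_depth - t_alt, "t_alt": t_alt,
                "b_ref": b_depth - b_alt, "b_alt": b_alt,
                "n_ref": n_depth - n_alt, "n_alt": n_alt,
                "rna_ref": rna_depth - rna_alt, "rna_alt": rna_alt,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression + survival


def simulate_expression_and_survival(
    config: SimConfig,
) -> tuple[MatrixTable, MatrixTable, pd.DataFrame, list[ClinicalRecord]]:
    """Return (mRNA counts, miR counts, truth table, clinical records).

    Truth table columns: mrna_subtype, mir_subtype (active/inactive).
    """
    rng = config.cohort_rng(2)
    n = config.n_patients
    ids = config.patient_ids()
    active = rng.random(n) < config.p_active
    mir_active = np.where(
        rng.random(n) < config.mir_concordance, active, ~active
    )

    def counts(n_features: int, labels: np.ndarray, tag: str) -> MatrixTable:
        base_log2 = rng.uniform(3.0, 9.0, size=n_features)
        n_affected = int(round(config.affected_feature_fraction * n_features))
        affected = rng.choice(n_features, size=n_affected, replace=False)
        shift = np.zeros(n_features)
        shift[affected] = config.subtype_effect_log2 * np.where(
            rng.random(n_affected) < 0.5, 1.0, -1.0
        )
        log2_mean = base_log2[:, None] + shift[:, None] * labels[None, :]
        noise = rng.normal(0.0, 0.25, size=(n_features, n))
        lam = np.exp2(log2_mean + noise)
        vals = rng.poisson(lam).astype(float)
        feats = [f"{tag}{j:05d}" for j in range(n_features)]
        return MatrixTable(
            values=pd.DataFrame(vals, index=feats, columns=ids), value_kind="count"
        )

    mrna = counts(config.n_mrna_features, active.astype(float), "gene")
    mir = counts(config.n_mir_features, mir_active.astype(float), "mir")

    rate = config.baseline_hazard * np.exp(config.survival_log_hr * active)
    times = rng.exponential(1.0 / rate)
    event = times <= config.censor_time
    obs_time = np.minimum(times, config.censor_time)

    records = []
    for i, pid in enumerate(ids):
        records.append(
            ClinicalRecord(
                patient_id=pid,
                er_status="positive" if rng.random() < 0.7 else "negative",
                age_decade=AGE_DECADES[int(rng.integers(0, len(AGE_DECADES)))],
                stage=STAGES[int(rng.integers(0, len(STAGES)))],
                t_size=T_SIZES[int(rng.integers(0, len(T_SIZES)))],
                node_status="positive" if rng.random() < 0.4 else "negative",
                tumor_subtype=TUMOR_SUBTYPES[int(rng.integers(0, 4))],
                time_years=float(obs_time[i]),
                event=bool(event[i]),
            )
        )
    truth = pd.DataFrame(
        {
            "patient_id": ids,
            "mrna_subtype": np.where(active, "active", "inactive"),
            "mir_subtype": np.where(mir_active, "active", "inactive"),
        }
    ).set_index("patient_id")
    return mrna, mir, truth, records


# ---------------------------------------------------------------------------
# cohort writer


def simulate_cohort(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate one full cohort and write every pipeline input plus truth.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    tumor_m, normal_m, adj_m = methylation_matrices(config)
    for name, table in (
        ("methylation_tumor", tumor_m),
        ("methylation_normal", normal_m),
        ("methylation_adjacent", adj_m),
    ):
        paths[name] = out / f"{name}.tsv"
        write_matrix(table, paths[name])

    tumor_segs: list[SegRecord] = []
    blood_segs: list[SegRecord] = []
    adj_segs: list[SegRecord] = []
    variant_frames = []
    for i in range(config.n_patients):
        t, b, a = simulate_segments(config, i)
        tumor_segs += t
        blood_segs += b
        adj_segs += a
        variant_frames.append(simulate_variants(config, i))
    for name, recs in (
        ("segments_tumor", tumor_segs),
        ("segments_blood", blood_segs),
        ("segments_adjacent", adj_segs),
    ):
        paths[name] = out / f"{name}.seg"
        write_seg(recs, paths[name])
    paths["variants"] = out / "variants.tsv"
    write_variants(pd.concat(variant_frames, ignore_index=True), paths["variants"])

    mrna, mir, truth, clinical = simulate_expression_and_survival(config)
    paths["mrna_counts"] = out / "mrna_counts.tsv"
    write_matrix(mrna, paths["mrna_counts"])
    paths["mir_counts"] = out / "mir_counts.tsv"
    write_matrix(mir, paths["mir_counts"])
    paths["clinical"] = out / "clinical.tsv"
    write_clinical(clinical, paths["clinical"])

    truth_full = truth.copy()
    truth_full["occult_fraction"] = np.asarray(config.occult_fractions)
    truth_full["field_effect"] = np.asarray(config.field_effect_flags).astype(int)
    truth_full["cn_contamination"] = np.asarray(config.cn_contamination)
    truth_full["adjacent_vaf_scale"] = np.asarray(config.vaf_scales)
    paths["truth"] = out / "truth.tsv"
    truth_full.to_csv(paths["truth"], sep="\t", float_format="%.6f")
    return paths
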