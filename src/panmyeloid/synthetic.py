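"""Synthetic cohort and variant-table generator with planted ground truth.

The generator emulates the statistical structure the analysis assumes:

* an eight-diagnosis cohort (default sizes AML 388, CML 27, MDS 209,
  MDS/MPN 36, MPN 70, ALL 321, CLL 52, MM 89; total 1,192);
* gene-mutation carriage driven by planted aberration clusters, each with
  a per-disease prevalence row, arranged in an axis gradient (one block
  enriched in AML-ish patients, another in MDS/MPN-ish patients);
* karyotype flags with their own planted clusters (favorable/adverse AML
  lesions, the CML translocation, an ALL lesion);
* phenotype features that are linear in the cluster mutation loads plus
  Gaussian noise, on top of diagnosis-specific baselines;
* a logistic complete-remission model (age, ELN class, high-load
  indicator) and exponential overall survival per enhanced risk group
  with administrative censoring;
* missing values injected at a configurable rate.

Every planted quantity is recorded in :class:`GroundTruth` so downstream
stages can be tested against known parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cohort import MutationEvent, PatientRecord
from .risk import eln_enhanced, eln_from_record
from .schema import DIAGNOSES, FeatureSchema, default_schema
from .variant_filter import FilterThresholds, Locus, VariantCall

DEFAULT_SIZES: dict[str, int] = {
    "AML": 388, "CML": 27, "MDS": 209, "MDS/MPN": 36, "MPN": 70,
    "ALL": 321, "CLL": 52, "MM": 89,
}

# planted gene clusters: axis gradient from "R" (AML-enriched) to "L"
# (MPN/MDS-enriched), plus a lymphoid cluster for the outgroup
DEFAULT_GENE_CLUSTERS: dict[str, tuple[str, ...]] = {
    "R": ("FLT3-ITD", "NPM1", "KIT", "NRAS", "WT1"),
    "MR": ("TET2", "DNMT3A", "IDH2", "KRAS", "CSF3R"),
    "ML": ("ASXL1", "SRSF2", "U2AF1", "SF3B1", "EZH2"),
    "L": ("JAK2", "CALR", "MPL", "SETBP1", "ETNK1"),
    "LY": ("NOTCH1", "IKZF1", "PAX5", "MYD88", "ATM"),
}

_MYELOID_THETA = {
    #          AML    MDS   MDS/MPN  MPN
    "R":  {"AML": 0.45, "MDS": 0.08, "MDS/MPN": 0.06, "MPN": 0.04},
    "MR": {"AML": 0.30, "MDS": 0.18, "MDS/MPN": 0.12, "MPN": 0.08},
    "ML": {"AML": 0.08, "MDS": 0.30, "MDS/MPN": 0.25, "MPN": 0.12},
    "L":  {"AML": 0.03, "MDS": 0.08, "MDS/MPN": 0.20, "MPN": 0.55},
    "LY": {"AML": 0.02, "MDS": 0.02, "MDS/MPN": 0.02, "MPN": 0.02},
}
_LYMPHOID_BASE = {"R": 0.02, "MR": 0.02, "ML": 0.02, "L": 0.01, "LY": 0.30}

DEFAULT_GENE_THETA: dict[str, dict[str, float]] = {
    name: {
        **{d: _LYMPHOID_BASE[name] for d in ("ALL", "CLL", "MM", "CML")},
        **_MYELOID_THETA[name],
    }
    for name in DEFAULT_GENE_CLUSTERS
}

DEFAULT_KARYOTYPE_CLUSTERS: dict[str, tuple[str, ...]] = {
    "K_fav": ("t(8;21)", "inv(16)"),
    "K_adv": ("complex", "-7", "del(5q)", "abn(17p)"),
    "K_cml": ("t(9;22)",),
    "K_all": ("t(12;21)",),
}

DEFAULT_KARYOTYPE_THETA: dict[str, dict[str, float]] = {
    "K_fav": {**{d: 0.01 for d in DIAGNOSES}, "AML": 0.12},
    "K_adv": {**{d: 0.01 for d in DIAGNOSES}, "AML": 0.08, "MDS": 0.12},
    "K_cml": {**{d: 0.0 for d in DIAGNOSES}, "CML": 0.90, "ALL": 0.03},
    "K_all": {**{d: 0.0 for d in DIAGNOSES}, "ALL": 0.20},
}

#: phenotype features linear in cluster loads (feature -> cluster -> coef)
DEFAULT_PHENO_COEFFICIENTS: dict[str, dict[str, float]] = {
    "bm_blast_pct": {"R": 3.0, "MR": 1.0},
    "pb_blast_pct": {"R": 2.5},
    "wbc": {"R": 2.0, "MR": 0.5},
    "plt": {"R": -2.0, "L": 2.0},
    "bm_orthochromatic_erythroblast_pct": {"ML": 2.0},
    "bm_erythroid_pct": {"ML": 1.5},
    "neut_pct": {"L": 1.5},
    "pb_lymph_pct": {"LY": 2.0},
}

DEFAULT_PEDIATRIC_FRACTION = {
    "AML": 0.17, "MDS": 0.05, "MDS/MPN": 0.10, "MPN": 0.05,
    "CML": 0.10, "ALL": 0.60, "CLL": 0.0, "MM": 0.0,
}


@dataclass(frozen=True)
class SyntheticConfig:
    sizes: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_SIZES))
    gene_clusters: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_GENE_CLUSTERS)
    )
    gene_theta: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_GENE_THETA.items()}
    )
    karyotype_clusters: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_KARYOTYPE_CLUSTERS)
    )
    karyotype_theta: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_KARYOTYPE_THETA.items()
        }
    )
    pheno_coefficients: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_PHENO_COEFFICIENTS.items()
        }
    )
    pheno_noise_sd: float = 1.0
    class_separation: float = 3.0
    pediatric_fraction: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PEDIATRIC_FRACTION)
    )
    #: logistic CR model: intercept + age + ELN ordinal + high R+MR load
    cr_intercept: float = 1.0
    cr_age_coef: float = -0.3  # per standardized decade over 50
    cr_eln_coef: float = -0.8  # per ELN class step
    cr_highload_logodds: float = math.log(0.25)  # planted OR for load > 2
    #: MDS-EB CR model: high L+ML load effect
    mdseb_cr_intercept: float = -1.0
    mdseb_highload_logodds: float = math.log(4.0)
    #: exponential OS hazards (per day) for enhanced groups 1..3
    os_hazards: tuple[float, float, float] = (0.5 / 1000, 1.0 / 1000, 2.0 / 1000)
    os_horizon_days: float = 1095.0
    m3_fraction: float = 0.10  # of AML
    mdseb_fraction: float = 0.30  # of MDS
    missing_rate: float = 0.05
    #: within-cluster spectrum gradient: genes in a cluster interpolate
    #: this far toward the adjacent cluster's anchor, making the gene
    #: order along the axis identifiable (0 = identical spectra)
    within_cluster_gradient: float = 0.3

    def validate(self) -> None:
        if any(v < 0 for v in self.sizes.values()):
            raise ValueError("cohort sizes must be >= 0")
        for name, row in self.gene_theta.items():
            if any(not 0.0 <= p <= 1.0 for p in row.values()):
                raise ValueError(f"gene cluster {name}: prevalence outside [0, 1]")
        for name, row in self.karyotype_theta.items():
            if any(not 0.0 <= p <= 1.0 for p in row.values()):
                raise ValueError(f"karyotype cluster {name}: prevalence outside [0, 1]")
        if self.pheno_noise_sd <= 0:
            raise ValueError("phenotype noise sd must be > 0")
        if any(h <= 0 for h in self.os_hazards):
            raise ValueError("hazards must be > 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing rate must be in [0, 1)")


#: clusters participating in the left-to-right axis gradient
GRADIENT_ORDER = ("L", "ML", "MR", "R")


def gene_level_theta(config: "SyntheticConfig") -> dict[str, dict[str, float]]:
    """Per-gene prevalence vectors with a within-cluster gradient.

    Genes of a gradient cluster interpolate between their own anchor and
    the adjacent cluster's anchor (up to ``within_cluster_gradient``), so
    that the planted gene order along the axis is identifiable; clusters
    outside the gradient (e.g. the lymphoid cluster) use their anchor
    unchanged.
    """
    ordered = [c for c in GRADIENT_ORDER if c in config.gene_clusters]
    theta: dict[str, dict[str, float]] = {}
    for name, genes in config.gene_clusters.items():
        anchor = config.gene_theta[name]
        if name not in ordered or config.within_cluster_gradient <= 0:
            for v in genes:
                theta[v] = dict(anchor)
            continue
        ci = ordered.index(name)
        n = len(genes)
        offsets = np.linspace(-config.within_cluster_gradient,
                              config.within_cluster_gradient, n) if n > 1 else [0.0]
        for v, w in zip(genes, offsets):
            neighbour = ordered[ci - 1] if w < 0 and ci > 0 else (
                ordered[ci + 1] if w > 0 and ci < len(ordered) - 1 else name
            )
            other = config.gene_theta[neighbour]
            theta[v] = {
                d: (1.0 - abs(w)) * anchor.get(d, 0.0)
                + abs(w) * other.get(d, 0.0)
                for d in set(anchor) | set(other)
            }
    return theta


@dataclass
class GroundTruth:
    gene_cluster_of: dict[str, str]
    karyotype_cluster_of: dict[str, str]
    gene_theta: dict[str, dict[str, float]]
    gene_theta_by_variable: dict[str, dict[str, float]]
    pheno_coefficients: dict[str, dict[str, float]]
    pheno_noise_sd: float
    cr_highload_logodds: float
    os_hazards: tuple[float, float, float]
    cluster_loads: dict[str, dict[str, int]]  # patient -> cluster -> load
    axis_score: dict[str, float]  # planted left-right score per patient
    enhanced_group: dict[str, int]


_AXIS_OFFSET = {"AML": 2.0, "MDS": -1.0, "MDS/MPN": 0.0, "MPN": -2.0}

def _baselines(schema: FeatureSchema) -> dict[str, np.ndarray]:
    """Diagnosis-specific phenotype baselines.

    Fixed design constants drawn from a dedicated generator, shared
    across run seeds so that bootstrap replicates of the same design
    agree on what each diagnosis "looks like".
    """
    rng = np.random.default_rng(20220426)
    mat = rng.normal(size=(len(DIAGNOSES), len(schema.continuous)))
    return {d: mat[j] for j, d in enumerate(DIAGNOSES)}


def generate_cohort(
    config: SyntheticConfig = SyntheticConfig(),
    seed: int = 0,
    schema: FeatureSchema | None = None,
) -> tuple[list[PatientRecord], GroundTruth]:
    """Generate a cohort with planted clusters, phenotypes and outcomes."""
    config.validate()
    schema = schema or default_schema()
    rng = np.random.default_rng(seed)

    var_cluster = {
        v: name for name, genes in config.gene_clusters.items() for v in genes
    }
    theta_by_var = gene_level_theta(config)
    kary_cluster = {
        f: name for name, flags in config.karyotype_clusters.items() for f in flags
    }
    baselines = _baselines(schema)
    cont_names = schema.continuous

    records: list[PatientRecord] = []
    truth_loads: dict[str, dict[str, int]] = {}
    axis_score: dict[str, float] = {}
    enhanced: dict[str, int] = {}

    pid_counter = 0
    for diagnosis in DIAGNOSES:
        for _ in range(int(config.sizes.get(diagnosis, 0))):
            pid = f"P{pid_counter:05d}"
            pid_counter += 1

            # --- age: pediatric/adult mixture
            pediatric = rng.random() < config.pediatric_fraction.get(diagnosis, 0.0)
            if pediatric:
                age = float(rng.uniform(1.0, 16.0))
            else:
                age = float(np.clip(rng.normal(55.0, 15.0), 17.0, 95.0))

            # --- gene mutation events from planted clusters
            events: list[MutationEvent] = []
            loads = {name: 0 for name in config.gene_clusters}
            for name, genes in config.gene_clusters.items():
                for v in genes:
                    theta = theta_by_var[v].get(diagnosis, 0.0)
                    if rng.random() < theta:
                        vaf = float(np.clip(rng.beta(8, 12), 0.021, 0.449))
                        ar = None
                        if v == "FLT3-ITD":
                            ar = "high" if rng.random() < 0.5 else "low"
                        events.append(
                            MutationEvent(pid, v, vaf=vaf, flt3_ar_class=ar)
                        )
                        loads[name] += 1
            # background CEBPA in AML (favorable when biallelic); enforce
            # the at-most-one-of-sm/dm invariant by construction
            if diagnosis == "AML":
                u = rng.random()
                if u < 0.08:
                    events.append(MutationEvent(pid, "CEBPA-dm", vaf=0.4))
                elif u < 0.14:
                    events.append(MutationEvent(pid, "CEBPA-sm", vaf=0.4))

            # --- karyotype flags
            flags = {k: 0 for k in schema.karyotype}
            for name, kflags in config.karyotype_clusters.items():
                theta = config.karyotype_theta[name].get(diagnosis, 0.0)
                for f in kflags:
                    if f in flags and rng.random() < theta:
                        flags[f] = 1

            m3 = 0
            if diagnosis == "AML" and rng.random() < config.m3_fraction:
                m3 = 1
                if rng.random() < 33 / 39:
                    flags["t(15;17)"] = 1

            # --- phenotype features
            base = baselines[diagnosis] * config.class_separation
            values = base + rng.normal(0.0, config.pheno_noise_sd, size=len(cont_names))
            name_to_idx = {n: i for i, n in enumerate(cont_names)}
            for feat, coefs in config.pheno_coefficients.items():
                if feat in name_to_idx:
                    values[name_to_idx[feat]] += sum(
                        c * loads.get(cl, 0) for cl, c in coefs.items()
                    )
            values[name_to_idx["age"]] = age  # age is real, not synthetic noise

            cbc = {}
            smear = {}
            for n in schema.cbc:
                v = float(values[name_to_idx[n]])
                cbc[n] = None if rng.random() < config.missing_rate else v
            for n in schema.smear:
                v = float(values[name_to_idx[n]])
                smear[n] = None if rng.random() < config.missing_rate else v

            mdseb = int(diagnosis == "MDS" and rng.random() < config.mdseb_fraction)
            rec = PatientRecord(
                patient_id=pid,
                diagnosis=diagnosis,
                age=age,
                karyotype_flags=flags,
                cbc=cbc,
                smear=smear,
                mutation_events=events,
                m3_flag=m3,
                mdseb_flag=mdseb,
                mrc_flag=int(diagnosis == "AML" and rng.random() < 0.04),
                secondary_type_flag=0,
            )
            rec.secondary_type_flag = int(
                diagnosis == "AML"
                and not rec.mrc_flag
                and any(
                    e.gene in ("SRSF2", "SF3B1", "U2AF1", "ZRSR2", "ASXL1",
                               "EZH2", "BCOR", "STAG2")
                    for e in events
                )
            )
            rec.eln_class = eln_from_record(rec)

            # --- outcomes
            load_rmr = loads.get("R", 0) + loads.get("MR", 0)
            load_lml = loads.get("L", 0) + loads.get("ML", 0)
            eln_ord = {"Favorable": 0, "Intermediate": 1, "Adverse": 2}[rec.eln_class]
            group = eln_enhanced(rec.eln_class, load_rmr)
            enhanced[pid] = group
            if diagnosis == "AML":
                logit = (
                    config.cr_intercept
                    + config.cr_age_coef * (age - 50.0) / 10.0
                    + config.cr_eln_coef * eln_ord
                    + config.cr_highload_logodds * (load_rmr > 2)
                )
                cr = int(rng.random() < 1.0 / (1.0 + math.exp(-logit)))
                rec.cr = cr
                rec.mrd = (
                    float(rng.uniform(0.0, 0.00099)) if cr
                    else float(rng.uniform(0.0011, 0.05))
                )
            elif mdseb:
                logit = (
                    config.mdseb_cr_intercept
                    + config.mdseb_highload_logodds * (load_lml > 2)
                )
                cr = int(rng.random() < 1.0 / (1.0 + math.exp(-logit)))
                rec.cr = cr
                pre = float(rng.uniform(6.0, 19.0))
                rec.blasts_pretreatment = pre
                if cr:
                    rec.blasts_posttreatment = float(
                        rng.uniform(0.2, min(5.0, pre * 0.5))
                    )
                else:
                    rec.blasts_posttreatment = float(rng.uniform(pre * 0.6, pre))
            if diagnosis in ("AML", "MDS"):
                hazard = config.os_hazards[group - 1]
                t = float(rng.exponential(1.0 / hazard))
                rec.os_time = min(t, config.os_horizon_days)
                rec.os_event = int(t <= config.os_horizon_days)

            truth_loads[pid] = loads
            axis_score[pid] = (
                _AXIS_OFFSET.get(diagnosis, 0.0)
                + loads.get("R", 0) + loads.get("MR", 0)
                - loads.get("ML", 0) - loads.get("L", 0)
            )
            records.append(rec)

    truth = GroundTruth(
        gene_cluster_of=var_cluster,
        karyotype_cluster_of=kary_cluster,
        gene_theta={k: dict(v) for k, v in config.gene_theta.items()},
        gene_theta_by_variable=theta_by_var,
        pheno_coefficients={
            k: dict(v) for k, v in config.pheno_coefficients.items()
        },
        pheno_noise_sd=config.pheno_noise_sd,
        cr_highload_logodds=config.cr_highload_logodds,
        os_hazards=config.os_hazards,
        cluster_loads=truth_loads,
        axis_score=axis_score,
        enhanced_group=enhanced,
    )
    return records, truth


def scaled_config(scale: float, **overrides) -> SyntheticConfig:
    """The default study design with cohort sizes scaled down.

    Sizes are rounded but kept >= 5 per disease so stratified procedures
    stay well-defined.
    """
    sizes = {d: max(5, int(round(n * scale))) for d, n in DEFAULT_SIZES.items()}
    return SyntheticConfig(sizes=sizes, **overrides)


# ---------------------------------------------------------------------------
# raw variant table with planted filter decisions


def generate_variant_table(
    seed: int = 0,
    n_random: int = 60,
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[list[VariantCall], list[tuple[bool, str, bool]], frozenset[Locus]]:
    """Raw calls planted on each side of every filter threshold.

    Returns the calls, the expected ``(kept, reason, rescued)`` label per
    call (assigned by construction, not by running the filter), and the
    panel of normals used for the step-4 cases.
    """
    rng = np.random.default_rng(seed)
    calls: list[VariantCall] = []
    labels: list[tuple[bool, str, bool]] = []
    pon_locus = Locus("7", 101_000, "A", "T")
    pon = frozenset({pon_locus})

    def base(i: int, **kw) -> VariantCall:
        defaults = dict(
            patient_id=f"V{i:04d}",
            gene="TET2",
            locus=Locus("4", 106_000 + i, "C", "T"),
            q_score=40.0,
            depth=200,
            vaf=0.30,
            consequence="missense",
            cosmic_haem_count=0,
            lab_prevalence=0.01,
            pop_freqs={"gnomad": 0.0001},
        )
        defaults.update(kw)
        return VariantCall(**defaults)

    planted: list[tuple[dict, tuple[bool, str, bool]]] = [
        # step 1 boundary: Q 19 fails, Q 20 passes
        (dict(q_score=19.0), (False, "step1", False)),
        (dict(q_score=20.0), (True, "pass", False)),
        # step 2 boundary: depth 29 fails, 30 passes
        (dict(depth=29), (False, "step2", False)),
        (dict(depth=30), (True, "pass", False)),
        # step 3 boundaries: strict < 0.02 and > 0.45
        (dict(vaf=0.019), (False, "step3", False)),
        (dict(vaf=0.02), (True, "pass", False)),
        (dict(vaf=0.45), (True, "pass", False)),
        (dict(vaf=0.46), (False, "step3", False)),
        # step 4: panel-of-normals hit, with and without rescue
        (dict(locus=pon_locus), (False, "step4", False)),
        (dict(locus=pon_locus, cosmic_haem_count=2), (True, "pass", True)),
        # step 5 boundary: COSMIC 1 does not rescue, 2 does
        (dict(vaf=0.46, cosmic_haem_count=1), (False, "step3", False)),
        (dict(vaf=0.46, cosmic_haem_count=2), (True, "pass", True)),
        # rescued call still subject to step 8
        (
            dict(vaf=0.46, cosmic_haem_count=2, pop_freqs={"exac": 0.02}),
            (False, "step8", True),
        ),
        # step 6 boundary: strict > 0.10
        (dict(lab_prevalence=0.11), (False, "step6", False)),
        (dict(lab_prevalence=0.10), (True, "pass", False)),
        # step 7: silent consequences
        (dict(consequence="synonymous"), (False, "step7", False)),
        (dict(consequence="intronic"), (False, "step7", False)),
        # step 8 boundary: strict > 0.01 in any database
        (dict(pop_freqs={"gnomad": 0.011}), (False, "step8", False)),
        (dict(pop_freqs={"gnomad": 0.009, "exac": 0.009}), (True, "pass", False)),
        (dict(pop_freqs={"gnomad": 0.009, "exac": 0.02}), (False, "step8", False)),
    ]
    for i, (kw, label) in enumerate(planted):
        calls.append(base(i, **kw))
        labels.append(label)

    # random clean calls planted to pass every step
    for i in range(n_random):
        calls.append(
            base(
                1000 + i,
                q_score=float(rng.uniform(25, 60)),
                depth=int(rng.integers(60, 500)),
                vaf=float(rng.uniform(0.05, 0.40)),
                lab_prevalence=float(rng.uniform(0.0, 0.09)),
                pop_freqs={"gnomad": float(rng.uniform(0.0, 0.009))},
            )
        )
        labels.append((True, "pass", False))
    return calls, labels, pon
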