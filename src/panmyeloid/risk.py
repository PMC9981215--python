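"""Axis-derived gene groups, mutation loads and risk stratification.

Consensus aberration clusters ordered along the Pan-Myeloid Axis are
simplified into four gene groups -- ``L``, ``ML``, ``MR`` and ``R`` (left
to right, "MDS-ish" to "AML-ish") -- with a minimum myeloid mutation-rate
filter for the middle and right groups.  Per-patient mutation loads over
group unions drive two schemes:

* **2017 ELN enhanced** for AML: the 2017 European LeukemiaNet genetic
  risk class crossed with the R+MR mutation load at threshold > 2 gives
  three groups (1 best to 3 worst).
* **MDS-EB stratification**: L+ML load > 2 marks the high stratum.

Outcome evaluation covers AUROC, multivariate logistic regression with
Wald tests, Fisher exact tests, Kaplan-Meier curves with Greenwood
standard errors, Harrell's concordance and pairwise Cox comparisons.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .cohort import PatientRecord
from .panels import variable_to_gene
from .phenogenetics import cluster_load

logger = logging.getLogger(__name__)

GROUPS = ("L", "ML", "MR", "R")
ELN_CLASSES = ("Favorable", "Intermediate", "Adverse")


# ---------------------------------------------------------------------------
# gene groups along the axis


@dataclass
class AxisGeneGroups:
    """Partition of panel genes into L / ML / MR / R / other."""

    mapping: dict[str, str]  # gene (or gene variable) -> group
    rate_threshold: float = 0.01
    source_clusters: dict[str, str] = field(default_factory=dict)

    def genes(self, *groups: str) -> frozenset[str]:
        return frozenset(g for g, grp in self.mapping.items() if grp in groups)

    @property
    def sizes(self) -> dict[str, int]:
        out = {g: 0 for g in (*GROUPS, "other")}
        for grp in self.mapping.values():
            out[grp] += 1
        return out


def assign_axis_groups(
    clusters: Mapping[str, Sequence[str]],
    axis_order: Sequence[str],
    myeloid_rates: Mapping[str, float],
    blocks: Mapping[str, Sequence[str]] | None = None,
    rate_threshold: float = 0.01,
) -> AxisGeneGroups:
    """Simplify ordered clusters into the four axis gene groups.

    ``axis_order`` lists cluster ids left to right along the axis.  When
    ``blocks`` is not given, the leftmost cluster becomes ``L`` and the
    remaining clusters are split into three contiguous blocks (ML, MR, R).
    Genes in the L block keep their group regardless of mutation rate;
    genes in the ML/MR/R blocks additionally require a myeloid mutation
    rate above ``rate_threshold``, otherwise they fall into ``other``.
    """
    axis_order = list(axis_order)
    if set(axis_order) != set(clusters):
        raise ValueError("axis_order must list each cluster exactly once")
    if blocks is None:
        if len(axis_order) < 4:
            raise ValueError("need >= 4 clusters for a default block split")
        rest = axis_order[1:]
        chunks = np.array_split(np.array(rest, dtype=object), 3)
        blocks = {
            "L": [axis_order[0]],
            "ML": list(chunks[0]),
            "MR": list(chunks[1]),
            "R": list(chunks[2]),
        }
    mapping: dict[str, str] = {}
    source: dict[str, str] = {}
    for group in GROUPS:
        for cluster_id in blocks.get(group, []):
            for gene in clusters[cluster_id]:
                if gene not in myeloid_rates:
                    raise KeyError(f"gene {gene!r} absent from myeloid spectra")
                if group != "L" and myeloid_rates[gene] <= rate_threshold:
                    mapping[gene] = "other"
                else:
                    mapping[gene] = group
                source[gene] = str(cluster_id)
    # clusters not placed in any block
    for cluster_id, genes in clusters.items():
        for gene in genes:
            if gene not in mapping:
                mapping[gene] = "other"
                source[gene] = str(cluster_id)
    return AxisGeneGroups(
        mapping=mapping, rate_threshold=rate_threshold, source_clusters=source
    )


def mutation_load(
    patient: PatientRecord,
    groups: AxisGeneGroups,
    which: str = "R+MR",
    gene_level: bool = False,
) -> int:
    """Mutation-event count over the union of the named gene groups.

    ``which`` is ``"R+MR"``, ``"L+ML"`` or ``"other"``.  Genes already
    counted by the ELN class are counted again here: the two dimensions
    of the enhanced scheme are deliberately independent.
    """
    parts = {"R+MR": ("R", "MR"), "L+ML": ("L", "ML"), "other": ("other",)}
    try:
        genes = groups.genes(*parts[which])
    except KeyError:
        raise ValueError(f"unknown load selector {which!r}") from None
    return cluster_load(patient, genes, gene_level=gene_level)


# ---------------------------------------------------------------------------
# 2017 ELN classification


def _load_eln_rules() -> dict:
    ref = resources.files("panmyeloid").joinpath("data/eln2017_rules.yaml")
    return yaml.safe_load(ref.read_text())


_ELN_RULES = _load_eln_rules()


def eln2017_classify(
    karyotype_flags: Mapping[str, int],
    mutated_genes: set[str] | frozenset[str],
    flt3_itd_class: str | None = None,
    cebpa_class: str = "none",
    rules: dict | None = None,
) -> str:
    """2017 ELN genetic risk class (Favorable / Intermediate / Adverse).

    ``mutated_genes`` holds parent gene symbols of surviving somatic
    mutations; ``flt3_itd_class`` is ``"high"`` / ``"low"`` / ``None``;
    ``cebpa_class`` is ``"none"`` / ``"sm"`` / ``"dm"``.  Precedence is
    adverse > favorable > intermediate, except that RUNX1/ASXL1 do not
    count as adverse when a favorable subtype co-occurs.
    """
    r = rules or _ELN_RULES
    flag = lambda name: bool(karyotype_flags.get(name, 0))

    npm1 = "NPM1" in mutated_genes
    itd_high = flt3_itd_class == "high"

    favorable = (
        any(flag(k) for k in r["favorable_cytogenetics"])
        or (npm1 and not itd_high)
        or cebpa_class == "dm"
    )
    adverse_markers = [k for k in r["adverse_cytogenetics"] if flag(k)]
    adverse_markers += [g for g in r["adverse_genes_always"] if g in mutated_genes]
    if not favorable:
        adverse_markers += [
            g for g in r["adverse_genes_unless_favorable"] if g in mutated_genes
        ]
    if itd_high and not npm1:
        adverse_markers.append("FLT3-ITD-high")

    if adverse_markers:
        if favorable:
            logger.info(
                "favorable and adverse markers co-occur (%s); adverse takes "
                "precedence", adverse_markers,
            )
        return "Adverse"
    if favorable:
        return "Favorable"
    return "Intermediate"


def eln_from_record(patient: PatientRecord, rules: dict | None = None) -> str:
    """ELN class of a patient record from its flags and mutation events."""
    genes = {variable_to_gene(e.gene_variable) for e in patient.mutation_events}
    itd_class = None
    for e in patient.mutation_events:
        if e.gene_variable == "FLT3-ITD" and e.flt3_ar_class is not None:
            itd_class = e.flt3_ar_class
    cebpa = "none"
    if patient.carries("CEBPA-dm"):
        cebpa = "dm"
    elif patient.carries("CEBPA-sm"):
        cebpa = "sm"
    return eln2017_classify(
        patient.karyotype_flags, genes, itd_class, cebpa, rules=rules
    )


# ---------------------------------------------------------------------------
# the enhanced schemes


def eln_enhanced(eln_class: str, load_rmr: int, threshold: int = 2) -> int:
    """Three-group "2017 ELN enhanced" class.

    Group 1: Favorable with R+MR load <= threshold.  Group 2: Favorable
    with high load, or Intermediate with low load.  Group 3: Intermediate
    with high load, or Adverse.
    """
    if eln_class not in ELN_CLASSES:
        raise ValueError(f"unknown ELN class {eln_class!r}")
    high = load_rmr > threshold
    if eln_class == "Favorable":
        return 2 if high else 1
    if eln_class == "Intermediate":
        return 3 if high else 2
    return 3


def mdseb_stratify(load_lml: int, threshold: int = 2) -> str:
    """MDS-EB stratum from the L+ML mutation load: > threshold is High."""
    return "High" if load_lml > threshold else "Low"


@dataclass
class RiskAssignment:
    patient_id: str
    eln_class: str | None = None
    load_rmr: int = 0
    load_lml: int = 0
    enhanced_group: int | None = None
    mdseb_stratum: str | None = None


def assign_risk(
    patient: PatientRecord,
    groups: AxisGeneGroups,
    threshold: int = 2,
    use_recorded_eln: bool = True,
) -> RiskAssignment:
    """Full risk assignment for one patient."""
    eln = patient.eln_class if (use_recorded_eln and patient.eln_class) else (
        eln_from_record(patient)
    )
    load_rmr = mutation_load(patient, groups, "R+MR")
    load_lml = mutation_load(patient, groups, "L+ML")
    return RiskAssignment(
        patient_id=patient.patient_id,
        eln_class=eln,
        load_rmr=load_rmr,
        load_lml=load_lml,
        enhanced_group=eln_enhanced(eln, load_rmr, threshold),
        mdseb_stratum=mdseb_stratify(load_lml, threshold),
    )


# ---------------------------------------------------------------------------
# outcome definitions and patient subsets


def cr_flag(patient: PatientRecord) -> int | None:
    """Complete-remission flag under the disease-specific definition.

    AML: measurable residual disease below 0.1% by flow cytometry.
    MDS-EB: post-treatment marrow blasts <= 5% *and* a relative decrease
    of >= 50% over pretreatment.  Returns ``None`` when the outcome is
    not evaluable.
    """
    if patient.diagnosis == "AML":
        if patient.mrd is None:
            return patient.cr
        return int(patient.mrd < 0.001)
    if patient.mdseb_flag:
        pre, post = patient.blasts_pretreatment, patient.blasts_posttreatment
        if pre is None or post is None or pre <= 0:
            return patient.cr
        return int(post <= 5.0 and (pre - post) / pre >= 0.5)
    return patient.cr


def aml_analysis_subset(
    cohort: Sequence[PatientRecord],
    adult_cutoff: float = 16.0,
    exclude_mrc: bool = False,
    exclude_secondary_type: bool = False,
) -> list[PatientRecord]:
    """Adult de novo non-M3 AML treated with standard induction.

    Optional further exclusion of AML-MRC and "secondary-type" cases
    (the latter defined by mutations in SRSF2/SF3B1/U2AF1/ZRSR2/ASXL1/
    EZH2/BCOR/STAG2) yields the "bona fide" subset.
    """
    out = []
    for r in cohort:
        if r.diagnosis != "AML" or r.age <= adult_cutoff:
            continue
        if r.m3_flag or not r.denovo_flag or not r.standard_induction_flag:
            continue
        if exclude_mrc and r.mrc_flag:
            continue
        if exclude_secondary_type and r.secondary_type_flag:
            continue
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# outcome evaluation


@dataclass
class BinaryOutcomeEval:
    auroc: float
    logistic: pd.DataFrame | None = None  # coef, se, z, p per covariate
    fisher: dict[str, float] = field(default_factory=dict)
    separation_flagged: bool = False


def evaluate_binary(
    scores: Sequence[float],
    outcomes: Sequence[int],
    covariates: pd.DataFrame | None = None,
) -> BinaryOutcomeEval:
    """AUROC of an ordinal score plus multivariate logistic regression.

    ``scores`` rank patients (e.g. the enhanced group index); higher
    scores are taken to predict *failure*, so the AUROC reported is for
    predicting CR with the score negated.  The logistic model regresses
    the outcome on the supplied covariates and reports two-sided Wald
    p-values; on perfect separation the fit falls back to an L2-penalized
    solution and is flagged.
    """
    import statsmodels.api as sm

    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=int)
    if len(np.unique(outcomes)) < 2:
        raise ValueError("need both outcome classes present")
    from sklearn.metrics import roc_auc_score

    auroc = float(roc_auc_score(outcomes, -scores))
    logistic = None
    flagged = False
    if covariates is not None:
        Xd = sm.add_constant(covariates.astype(float), has_constant="add")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(outcomes, Xd).fit(disp=0)
            if not np.all(np.isfinite(fit.bse)):
                raise np.linalg.LinAlgError("non-finite standard errors")
            logistic = pd.DataFrame(
                {"coef": fit.params, "se": fit.bse, "z": fit.tvalues, "p": fit.pvalues}
            )
        except Exception:  # perfect separation or singular design
            flagged = True
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(outcomes, Xd).fit_regularized(
                    alpha=1.0, L1_wt=0.0, disp=0
                )
            logistic = pd.DataFrame(
                {"coef": fit.params, "se": np.nan, "z": np.nan, "p": np.nan}
            )
    return BinaryOutcomeEval(auroc=auroc, logistic=logistic, separation_flagged=flagged)


def fisher_exact_2x2(table: np.ndarray | Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 contingency table."""
    return float(stats.fisher_exact(np.asarray(table), alternative="two-sided")[1])


def group_cr_tables(
    groups: Sequence[int], outcomes: Sequence[int]
) -> dict[str, float]:
    """Pairwise Fisher exact p-values for group-vs-CR 2x2 tables."""
    groups = np.asarray(groups)
    outcomes = np.asarray(outcomes)
    levels = sorted(set(groups.tolist()))
    out = {}
    for a_idx in range(len(levels)):
        for b_idx in range(a_idx + 1, len(levels)):
            a, b = levels[a_idx], levels[b_idx]
            table = [
                [int(((groups == g) & (outcomes == 1)).sum()),
                 int(((groups == g) & (outcomes == 0)).sum())]
                for g in (a, b)
            ]
            out[f"{a}_vs_{b}"] = fisher_exact_2x2(table)
    return out


def _concordance(times: np.ndarray, events: np.ndarray, risk: np.ndarray) -> float:
    """Concordance of a risk score over score-discriminating pairs.

    A pair (i, j) is comparable when the shorter observed time carries an
    event; it is concordant when the higher risk score got the shorter
    survival.  Pairs with tied risk scores are excluded rather than
    counted as half-concordant, so a score that perfectly separates two
    groups with non-overlapping survival reaches exactly 1.
    """
    order = np.argsort(times, kind="stable")
    t, e, r = times[order], events[order], risk[order]
    concordant = discordant = 0
    n = len(t)
    for i in range(n):
        if not e[i]:
            continue
        later = (t > t[i]) | ((t == t[i]) & (e == 0))
        concordant += int(np.sum(later & (r < r[i])))
        discordant += int(np.sum(later & (r > r[i])))
    if concordant + discordant == 0:
        return float("nan")
    return concordant / (concordant + discordant)


@dataclass
class SurvivalEval:
    concordance: float
    km_curves: pd.DataFrame  # group, time, survival, greenwood_se
    pairwise_cox_p: dict[str, float] = field(default_factory=dict)


def evaluate_survival(
    groups: Sequence[int],
    os_time: Sequence[float],
    os_event: Sequence[int],
) -> SurvivalEval:
    """Concordance, Kaplan-Meier curves and pairwise Cox comparisons.

    Concordance is Harrell's C of the ordinal group score (higher group
    predicting shorter survival).  Kaplan-Meier standard errors use the
    Greenwood formula.  Each pair of groups is compared by the two-sided
    Wald test of a univariate Cox model on the group indicator; pairs
    where either group has no events are skipped with a warning.
    """
    from lifelines import CoxPHFitter, KaplanMeierFitter

    groups = np.asarray(groups)
    os_time = np.asarray(os_time, dtype=float)
    os_event = np.asarray(os_event, dtype=int)
    levels = sorted(set(groups.tolist()))
    if sum(os_event[groups == g].sum() > 0 for g in levels) < 2:
        raise ValueError("need >= 2 groups with observed events")

    concordance = _concordance(os_time, os_event, groups.astype(float))

    rows = []
    for g in levels:
        mask = groups == g
        kmf = KaplanMeierFitter().fit(os_time[mask], os_event[mask])
        table = kmf.event_table
        # Greenwood: Var(S) = S^2 * cumsum(d / (n (n - d)))
        at_risk = table["at_risk"].to_numpy(dtype=float)
        observed = table["observed"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(
                at_risk > observed, observed / (at_risk * (at_risk - observed)), 0.0
            )
        greenwood = np.sqrt(np.cumsum(terms))
        surv = kmf.survival_function_["KM_estimate"].to_numpy()
        for t, s, se in zip(table.index.to_numpy(), surv, surv * greenwood):
            rows.append({"group": g, "time": float(t), "survival": float(s),
                         "greenwood_se": float(se)})
    km = pd.DataFrame(rows)

    pairwise = {}
    for a_idx in range(len(levels)):
        for b_idx in range(a_idx + 1, len(levels)):
            a, b = levels[a_idx], levels[b_idx]
            mask = (groups == a) | (groups == b)
            if os_event[groups == a].sum() == 0 or os_event[groups == b].sum() == 0:
                warnings.warn(
                    f"group {a} or {b} has no events; Cox comparison skipped",
                    stacklevel=2,
                )
                continue
            df = pd.DataFrame(
                {
                    "time": os_time[mask],
                    "event": os_event[mask],
                    "upper": (groups[mask] == b).astype(float),
                }
            )
            with warnings.catch_warnings():
                # near-separated groups trip lifelines convergence warnings
                warnings.simplefilter("ignore")
                cph = CoxPHFitter().fit(df, duration_col="time", event_col="event")
            pairwise[f"{a}_vs_{b}"] = float(cph.summary.loc["upper", "p"])
    return SurvivalEval(
        concordance=concordance, km_curves=km, pairwise_cox_p=pairwise
    )
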