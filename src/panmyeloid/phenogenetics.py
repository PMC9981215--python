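"""Descriptive and correlational phenogenetic statistics.

Prevalence spectra per disease, pediatric/adult contingency comparisons,
per-patient cluster mutation loads, Pearson correlations between cluster
loads and phenotype features, and rank-sum comparisons between blocks of
correlation coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import PatientRecord
from .panels import variable_to_gene
from .schema import DIAGNOSES


@dataclass
class SpectraTable:
    """Per-disease aberration rates with their underlying counts."""

    rates: pd.DataFrame  # aberration x disease, values m/n
    carriers: pd.DataFrame  # m_ij
    totals: pd.Series  # n_j

    def ranked(self, disease: str) -> pd.Series:
        """Rates for one disease in descending order, ties by name."""
        r = self.rates[disease]
        return r.iloc[
            sorted(range(len(r)), key=lambda i: (-r.iloc[i], r.index[i]))
        ]


def mutation_spectra(
    cohort: Sequence[PatientRecord],
    variables: Sequence[str],
    diseases: Sequence[str] = DIAGNOSES,
) -> SpectraTable:
    """Observed carrier rate of each aberration in each disease.

    Rates are exact count ratios m/n.  Diseases with no patients are
    excluded with a warning.
    """
    kept = []
    for d in diseases:
        if any(r.diagnosis == d for r in cohort):
            kept.append(d)
        else:
            warnings.warn(f"disease {d!r} has no patients; excluded", stacklevel=2)
    totals = pd.Series(
        {d: sum(r.diagnosis == d for r in cohort) for d in kept}, name="n"
    )
    carriers = pd.DataFrame(0, index=list(variables), columns=kept)
    for r in cohort:
        if r.diagnosis not in carriers.columns:
            continue
        carried = r.gene_variables
        for v in variables:
            if (v in r.karyotype_flags and r.karyotype_flags[v]) or v in carried:
                carriers.loc[v, r.diagnosis] += 1
    rates = carriers / totals
    return SpectraTable(rates=rates, carriers=carriers, totals=totals)


def age_stratified_compare(
    cohort: Sequence[PatientRecord],
    disease: str,
    variables: Sequence[str],
    cutoff: float = 16.0,
    continuity_correction: bool = False,
) -> pd.DataFrame:
    """Pediatric (age <= cutoff) vs adult carrier-rate comparison.

    One two-sided chi-square p-value per aberration from the 2x2
    stratum x carrier table, uncorrected for multiple testing.  A table
    with an all-zero margin (e.g. nobody carries the aberration) yields a
    missing p-value.
    """
    patients = [r for r in cohort if r.diagnosis == disease]
    pediatric = [r for r in patients if r.age <= cutoff]
    adult = [r for r in patients if r.age > cutoff]
    if not pediatric:
        raise ValueError(f"empty pediatric stratum for {disease}")
    if not adult:
        raise ValueError(f"empty adult stratum for {disease}")

    rows = []
    for v in variables:
        def carries(r: PatientRecord) -> bool:
            return bool(
                (v in r.karyotype_flags and r.karyotype_flags[v])
                or v in r.gene_variables
            )

        a = sum(carries(r) for r in pediatric)
        b = len(pediatric) - a
        c = sum(carries(r) for r in adult)
        d = len(adult) - c
        table = np.array([[a, b], [c, d]])
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            chi2, p = np.nan, np.nan
        else:
            chi2, p, _, _ = stats.chi2_contingency(
                table, correction=continuity_correction
            )
        rows.append(
            {
                "aberration": v,
                "pediatric_carriers": a,
                "pediatric_n": len(pediatric),
                "adult_carriers": c,
                "adult_n": len(adult),
                "chi2": chi2,
                "p": p,
            }
        )
    return pd.DataFrame(rows).set_index("aberration")


# ---------------------------------------------------------------------------
# cluster loads and correlations


def cluster_load(
    patient: PatientRecord,
    cluster_genes: set[str] | frozenset[str],
    gene_level: bool = False,
) -> int:
    """Number of mutation events whose gene lies in the cluster.

    Variant-level by default (two variants of one gene count twice);
    ``gene_level=True`` counts distinct mutated genes instead.
    """
    genes = [variable_to_gene(e.gene_variable) for e in patient.mutation_events]
    hits = [
        g for g, e in zip(genes, patient.mutation_events)
        if g in cluster_genes or e.gene_variable in cluster_genes
    ]
    return len(set(hits)) if gene_level else len(hits)


def load_matrix(
    cohort: Sequence[PatientRecord],
    clusters: Mapping[str, set[str]],
    gene_level: bool = False,
) -> pd.DataFrame:
    """Per-patient mutation load for each cluster."""
    return pd.DataFrame(
        {
            name: [cluster_load(r, genes, gene_level) for r in cohort]
            for name, genes in clusters.items()
        },
        index=[r.patient_id for r in cohort],
    )


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame  # feature x cluster Pearson r
    n: pd.DataFrame  # sample size per cell


def _pearson_frame(x: pd.DataFrame, y: pd.DataFrame) -> CorrelationMatrix:
    r = pd.DataFrame(np.nan, index=x.columns, columns=y.columns)
    n = pd.DataFrame(0, index=x.columns, columns=y.columns)
    for fx in x.columns:
        for fy in y.columns:
            a = x[fx].to_numpy(dtype=float)
            b = y[fy].to_numpy(dtype=float)
            mask = np.isfinite(a) & np.isfinite(b)
            n.loc[fx, fy] = int(mask.sum())
            if mask.sum() < 3 or np.std(a[mask]) == 0 or np.std(b[mask]) == 0:
                continue  # r stays missing
            r.loc[fx, fy] = stats.pearsonr(a[mask], b[mask]).statistic
    return CorrelationMatrix(r=r, n=n)


def pheno_gene_correlation(
    cohort: Sequence[PatientRecord],
    clusters: Mapping[str, set[str]],
    features: pd.DataFrame,
    diseases: Sequence[str] | None = None,
    gene_level: bool = False,
) -> CorrelationMatrix:
    """Pearson r between per-patient cluster loads and phenotype features.

    ``features`` is a patient x feature frame indexed by patient_id (may
    contain NaN for missing measurements).  ``diseases`` restricts the
    patient set (e.g. AML only).
    """
    if diseases is not None:
        cohort = [r for r in cohort if r.diagnosis in diseases]
    if len(cohort) < 3:
        raise ValueError("need >= 3 patients for correlation analysis")
    loads = load_matrix(cohort, clusters, gene_level)
    feats = features.loc[loads.index]
    return _pearson_frame(feats, loads)


def cluster_cluster_correlation(
    cohort: Sequence[PatientRecord],
    gene_clusters: Mapping[str, set[str]],
    karyotype_clusters: Mapping[str, Sequence[str]],
    gene_level: bool = False,
) -> CorrelationMatrix:
    """Pearson r between gene-cluster loads and karyotype-cluster loads.

    Karyotype loads count set flags in the cluster; gene loads count
    mutation events.  Computed over per-patient loads across the whole
    cohort.
    """
    gene_loads = load_matrix(cohort, gene_clusters, gene_level)
    kary_loads = pd.DataFrame(
        {
            name: [
                sum(r.karyotype_flags.get(f, 0) for f in flags) for r in cohort
            ]
            for name, flags in karyotype_clusters.items()
        },
        index=[r.patient_id for r in cohort],
    )
    return _pearson_frame(gene_loads, kary_loads)


def block_compare(
    matrix: CorrelationMatrix | pd.DataFrame,
    block_a: Sequence[tuple[str, str]],
    block_b: Sequence[tuple[str, str]],
) -> float:
    """Two-sided Wilcoxon rank-sum p between two blocks of r values.

    Blocks are disjoint lists of (row, column) cells of the correlation
    matrix; the exact null distribution is used for small samples without
    ties.
    """
    r = matrix.r if isinstance(matrix, CorrelationMatrix) else matrix
    if set(block_a) & set(block_b):
        raise ValueError("blocks must be disjoint")
    va = [r.loc[cell] for cell in block_a]
    vb = [r.loc[cell] for cell in block_b]
    va = [v for v in va if np.isfinite(v)]
    vb = [v for v in vb if np.isfinite(v)]
    if len(va) < 2 or len(vb) < 2:
        raise ValueError("each block needs >= 2 finite correlation values")
    return float(
        stats.mannwhitneyu(va, vb, alternative="two-sided", method="auto").pvalue
    )
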