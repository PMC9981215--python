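"""Feature schema for the phenogenetic cohort.

A patient is described by five blocks of variables:

* gene-mutation indicators (one per *gene variable*, i.e. panel genes with
  CEBPA split into single/double-mutant and FLT3 split into ITD/TKD/Other),
* binary karyotype-abnormality indicators,
* age in years,
* complete-blood-count (CBC) measurements,
* peripheral-blood / bone-marrow smear measurements.

With the default 171-gene panel this yields 174 + 72 + 1 + 36 + 56 = 339
features.  The CBC and smear blocks are configurable because laboratories
report different variable sets; the block structure itself is fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DIAGNOSES: tuple[str, ...] = (
    "ALL", "AML", "CLL", "CML", "MDS", "MDS/MPN", "MM", "MPN",
)
#: the four diagnoses forming the myeloid continuum
MYELOID_DIAGNOSES: tuple[str, ...] = ("AML", "MDS", "MDS/MPN", "MPN")

# Karyotype abnormalities tracked as binary flags.  The leading entries are
# the lesions used by the 2017 ELN and IPSS-R schemes; the remainder are
# recurrent abnormalities of haematologic neoplasms.
KARYOTYPE_FLAGS: tuple[str, ...] = (
    "t(8;21)",
    "inv(16)",
    "t(15;17)",
    "t(9;11)",
    "t(v;11q23)",
    "t(6;9)",
    "t(9;22)",
    "inv(3)",
    "t(12;21)",
    "-5",
    "del(5q)",
    "-7",
    "del(7q)",
    "-17",
    "abn(17p)",
    "complex",
    "monosomal",
    "+8",
    "del(20q)",
    "del(9q)",
    "-18",
    "+21",
    "-X",
    "-Y",
    "+1",
    "+11",
    "-20",
    "+13",
    "+22",
    "del(11q)",
    "+19",
    "-6",
    "add(12p)",
    "del(12p)",
    "+4",
    "+6",
    "+10",
    "+14",
    "+15",
    "del(6q)",
    "del(13q)",
    "del(16q)",
    "i(17q)",
    "del(3p)",
    "t(1;19)",
    "t(4;11)",
    "t(8;14)",
    "t(11;14)",
    "t(14;16)",
    "t(14;20)",
    "del(1p)",
    "+1q",
    "del(4q)",
    "t(5;12)",
    "del(9p)",
    "+9",
    "t(10;11)",
    "+12",
    "i(12p)",
    "add(14q)",
    "-15",
    "add(16p)",
    "-16",
    "+17",
    "add(18q)",
    "-19",
    "+20",
    "del(21q)",
    "-21",
    "-22",
    "+X",
    "idic(X)(q13)",
)

CBC_FEATURES: tuple[str, ...] = (
    "wbc", "rbc", "hgb", "hct", "mcv", "mch", "mchc", "rdw_cv", "rdw_sd",
    "plt", "mpv", "pct", "pdw", "p_lcr", "ipf",
    "neut_abs", "lymph_abs", "mono_abs", "eos_abs", "baso_abs",
    "neut_pct", "lymph_pct", "mono_pct", "eos_pct", "baso_pct",
    "ret_abs", "ret_pct", "irf", "nrbc_abs", "nrbc_pct",
    "esr", "crp", "ldh", "ferritin", "uric_acid", "b2m",
)

SMEAR_FEATURES: tuple[str, ...] = (
    # peripheral blood differential
    "pb_blast_pct", "pb_promyelocyte_pct", "pb_myelocyte_pct",
    "pb_metamyelocyte_pct", "pb_band_neut_pct", "pb_seg_neut_pct",
    "pb_neut_pct", "pb_lymph_pct", "pb_atypical_lymph_pct", "pb_mono_pct",
    "pb_promonocyte_pct", "pb_eos_pct", "pb_baso_pct",
    "pb_basophilic_myelocyte_pct", "pb_nrbc_pct", "pb_plasma_cell_pct",
    "pb_smudge_cell_pct", "pb_prolymphocyte_pct",
    # bone marrow granulocytic series
    "bm_blast_pct", "bm_promyelocyte_pct", "bm_myelocyte_pct",
    "bm_metamyelocyte_pct", "bm_band_neut_pct", "bm_seg_neut_pct",
    "bm_eos_pct", "bm_baso_pct", "bm_granulocytic_pct",
    # bone marrow erythroid series
    "bm_proerythroblast_pct", "bm_basophilic_erythroblast_pct",
    "bm_polychromatic_erythroblast_pct", "bm_orthochromatic_erythroblast_pct",
    "bm_erythroid_pct", "bm_granulo_erythro_ratio",
    # bone marrow lymphoid / monocytic / other
    "bm_lymph_pct", "bm_atypical_lymph_pct", "bm_prolymphocyte_pct",
    "bm_mono_pct", "bm_promonocyte_pct", "bm_plasma_cell_pct",
    "bm_proplasmacyte_pct", "bm_reticulum_cell_pct", "bm_mast_cell_pct",
    "bm_megakaryocyte_count", "bm_granular_megakaryocyte_count",
    "bm_platelet_forming_megakaryocyte_count", "bm_naked_megakaryocyte_count",
    "bm_cellularity_grade", "bm_auer_rod_flag", "bm_ringed_sideroblast_pct",
    "bm_dysgranulopoiesis_pct", "bm_dyserythropoiesis_pct",
    "bm_dysmegakaryopoiesis_pct", "bm_micromegakaryocyte_count",
    "bm_promyelocyte_abnormal_pct", "bm_blast_equivalent_pct",
    "bm_mitotic_figure_count",
)

assert len(KARYOTYPE_FLAGS) == 72
assert len(CBC_FEATURES) == 36
assert len(SMEAR_FEATURES) == 56


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature layout: genes, karyotype, age, CBC, smear."""

    gene_variables: tuple[str, ...]
    karyotype: tuple[str, ...] = KARYOTYPE_FLAGS
    cbc: tuple[str, ...] = CBC_FEATURES
    smear: tuple[str, ...] = SMEAR_FEATURES

    def __post_init__(self) -> None:
        for block_name in ("gene_variables", "karyotype", "cbc", "smear"):
            block = getattr(self, block_name)
            if len(set(block)) != len(block):
                raise ValueError(f"duplicate names in schema block {block_name!r}")
            if not block:
                raise ValueError(f"empty schema block {block_name!r}")
        # block sizes must add up to the advertised total
        assert self.size == (len(self.gene_variables) + len(self.karyotype)
                             + 1 + len(self.cbc) + len(self.smear))

    @property
    def size(self) -> int:
        return (len(self.gene_variables) + len(self.karyotype) + 1
                + len(self.cbc) + len(self.smear))

    @property
    def names(self) -> tuple[str, ...]:
        """Full feature order: genes, karyotype, age, CBC, smear."""
        return (self.gene_variables + self.karyotype + ("age",)
                + self.cbc + self.smear)

    @property
    def continuous(self) -> tuple[str, ...]:
        """Names of non-indicator features (age, CBC, smear)."""
        return ("age",) + self.cbc + self.smear

    @property
    def indicator_count(self) -> int:
        return len(self.gene_variables) + len(self.karyotype)


def default_schema() -> FeatureSchema:
    """The 339-feature schema induced by the default 171-gene panel."""
    from .panels import default_panel, expand_gene_variables

    schema = FeatureSchema(gene_variables=tuple(expand_gene_variables(default_panel())))
    assert schema.size == 339
    return schema
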