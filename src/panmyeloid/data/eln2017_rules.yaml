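# 2017 European LeukemiaNet genetic-risk lesions for AML.
# Cytogenetic labels refer to karyotype-flag names in the feature schema.
# Precedence at classification time: adverse > favorable > intermediate;
# RUNX1 and ASXL1 mutations are not counted as adverse when a favorable
# cytogenetic or molecular subtype is present.
favorable_cytogenetics:
  - "t(8;21)"
  - "inv(16)"
intermediate_cytogenetics:
  - "t(9;11)"
adverse_cytogenetics:
  - "t(6;9)"
  - "t(v;11q23)"
  - "t(9;22)"
  - "inv(3)"
  - "-5"
  - "del(5q)"
  - "-7"
  - "-17"
  - "abn(17p)"
  - "complex"
  - "monosomal"
adverse_genes_always:
  - "TP53"
adverse_genes_unless_favorable:
  - "RUNX1"
  - "ASXL1"
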