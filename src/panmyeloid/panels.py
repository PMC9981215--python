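"""Gene panels and the gene-variable expansion.

Mutation status is recorded per *gene variable* rather than per gene:
CEBPA is split into singly- vs doubly-mutated (``CEBPA-sm`` / ``CEBPA-dm``)
because biallelic CEBPA mutation is prognostically distinct, and FLT3 is
split into ``FLT3-ITD`` / ``FLT3-TKD`` / ``FLT3-Other`` because internal
tandem duplications and tyrosine-kinase-domain point mutations behave
differently.  A 171-gene panel therefore yields 174 gene variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

CEBPA_VARIABLES = ("CEBPA-sm", "CEBPA-dm")
FLT3_VARIABLES = ("FLT3-ITD", "FLT3-TKD", "FLT3-Other")


@dataclass(frozen=True)
class GenePanel:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene panel {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


def load_panel(path: str | Path, name: str | None = None) -> GenePanel:
    """Read a panel from a plain-text file, one symbol per line.

    Blank lines and ``#`` comments are ignored; symbols are deduplicated
    while preserving validity (duplicates are an error).
    """
    path = Path(path)
    symbols: list[str] = []
    for raw in path.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            symbols.append(line)
    if len(set(symbols)) != len(symbols):
        dupes = sorted({s for s in symbols if symbols.count(s) > 1})
        raise ValueError(f"duplicate gene symbols in {path}: {dupes}")
    return GenePanel(name=name or path.stem, genes=frozenset(symbols))


def default_panel() -> GenePanel:
    """The package's synthetic 171-gene default panel."""
    ref = resources.files("panmyeloid").joinpath("data/panel171_synthetic.txt")
    with resources.as_file(ref) as path:
        panel = load_panel(path, name="panel171")
    assert len(panel) == 171
    return panel


def expand_gene_variables(panel: GenePanel) -> list[str]:
    """Expand a gene panel into the ordered gene-variable list.

    CEBPA maps to 2 variables and FLT3 to 3, so ``len(out) == len(panel)
    - 2 + 5`` when both genes are present.  Genes are emitted in sorted
    order with the expansions in place of the parent symbol.  If CEBPA or
    FLT3 is absent the symbol passes through unchanged with a warning.
    """
    for required in ("CEBPA", "FLT3"):
        if required not in panel.genes:
            warnings.warn(
                f"panel {panel.name!r} lacks {required}; passing symbols "
                "through without expansion",
                stacklevel=2,
            )
    out: list[str] = []
    for gene in sorted(panel.genes):
        if gene == "CEBPA":
            out.extend(CEBPA_VARIABLES)
        elif gene == "FLT3":
            out.extend(FLT3_VARIABLES)
        else:
            out.append(gene)
    return out


def panel_overlap(a: GenePanel, b: GenePanel) -> float:
    """Jaccard overlap |a ∩ b| / |a ∪ b| between two panels."""
    if not a.genes or not b.genes:
        raise ValueError("panel overlap is undefined for empty panels")
    return len(a.genes & b.genes) / len(a.genes | b.genes)


def variable_to_gene(variable: str) -> str:
    """Parent gene symbol of a gene variable (``FLT3-ITD`` -> ``FLT3``)."""
    if variable in CEBPA_VARIABLES:
        return "CEBPA"
    if variable in FLT3_VARIABLES:
        return "FLT3"
    return variable
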