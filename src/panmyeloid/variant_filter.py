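"""Heuristic somatic-mutation identification from annotated variant calls.

Tumour-only panel sequencing has no matched germline sample, so somatic
calls are identified by an eight-step filter over call quality, allele
fraction, a panel of normals, database annotations and laboratory
recurrence:

1. reject calls with base-call quality Q < 20;
2. reject calls with total depth < 30 at the locus;
3. reject calls with VAF < 0.02 or > 0.45 (germline-like or noise);
4. reject calls seen in healthy-donor samples (panel of normals);
5. *rescue* step-3/4 rejections recorded >= 2 times in COSMIC with
   haematopoietic/lymphoid tissue provenance;
6. reject calls recurring in > 10% of the laboratory's previous runs;
7. reject synonymous and intronic consequences;
8. reject calls with > 1% frequency in any population database.

Rescued calls remain subject to steps 6-8.  Each decision carries the
first failing step as its reason code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

CONSEQUENCES = (
    "synonymous", "intronic", "missense", "nonsense", "frameshift",
    "splice", "other",
)
#: consequences rejected at step 7
SILENT_CONSEQUENCES = frozenset({"synonymous", "intronic"})


@dataclass(frozen=True)
class Locus:
    chrom: str
    position: int  # 1-based
    ref: str
    alt: str


@dataclass
class VariantCall:
    patient_id: str
    gene: str
    locus: Locus
    q_score: float
    depth: int
    vaf: float
    consequence: str
    cosmic_haem_count: int = 0
    lab_prevalence: float | None = None
    pop_freqs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"VAF must lie in [0, 1], got {self.vaf}")
        if self.depth < 0:
            raise ValueError(f"depth must be >= 0, got {self.depth}")
        if self.cosmic_haem_count < 0:
            raise ValueError("cosmic_haem_count must be >= 0")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")


@dataclass(frozen=True)
class FilterThresholds:
    min_q: float = 20.0
    min_depth: int = 30
    min_vaf: float = 0.02
    max_vaf: float = 0.45
    rescue_cosmic_count: int = 2
    max_lab_prevalence: float = 0.10
    max_pop_freq: float = 0.01


@dataclass
class FilterDecision:
    call: VariantCall
    kept: bool
    reason: str  # "pass" or first failing "stepN"
    rescued: bool = False

    def __post_init__(self) -> None:
        # rescue only reinstates VAF / panel-of-normals rejections
        if self.rescued and not self.kept and self.reason not in (
            "step6", "step7", "step8",
        ):
            raise ValueError("a rescued call can only fail at steps 6-8")


def apply_somatic_filter(
    calls: Iterable[VariantCall],
    panel_of_normals: frozenset[Locus] | set[Locus] = frozenset(),
    thresholds: FilterThresholds = FilterThresholds(),
    lab_prevalence_available: bool = True,
) -> list[FilterDecision]:
    """Run the eight-step somatic filter over annotated calls.

    ``lab_prevalence_available=False`` skips step 6 (the laboratory
    recurrence list is site-specific and not always portable); a warning
    is logged once.
    """
    if not lab_prevalence_available:
        logger.warning("laboratory prevalence table absent; step 6 skipped")
    decisions = []
    for call in calls:
        decisions.append(
            _decide(call, panel_of_normals, thresholds, lab_prevalence_available)
        )
    return decisions


def _decide(
    call: VariantCall,
    pon: frozenset[Locus] | set[Locus],
    th: FilterThresholds,
    lab_available: bool,
) -> FilterDecision:
    # steps 1-2 are hard rejections, never rescued
    if call.q_score < th.min_q:
        return FilterDecision(call, kept=False, reason="step1")
    if call.depth < th.min_depth:
        return FilterDecision(call, kept=False, reason="step2")

    rescued = False
    soft_reason: str | None = None
    if call.vaf < th.min_vaf or call.vaf > th.max_vaf:
        soft_reason = "step3"
    elif call.locus in pon:
        soft_reason = "step4"
    if soft_reason is not None:
        if call.cosmic_haem_count >= th.rescue_cosmic_count:
            rescued = True  # step 5, continue with steps 6-8
        else:
            return FilterDecision(call, kept=False, reason=soft_reason)

    if (
        lab_available
        and call.lab_prevalence is not None
        and call.lab_prevalence > th.max_lab_prevalence
    ):
        return FilterDecision(call, kept=False, reason="step6", rescued=rescued)
    if call.consequence in SILENT_CONSEQUENCES:
        return FilterDecision(call, kept=False, reason="step7", rescued=rescued)
    if any(freq > th.max_pop_freq for freq in call.pop_freqs.values()):
        return FilterDecision(call, kept=False, reason="step8", rescued=rescued)
    return FilterDecision(call, kept=True, reason="pass", rescued=rescued)


# ---------------------------------------------------------------------------
# per-patient variant-class rules


def classify_cebpa(n_variants: int) -> str:
    """CEBPA class from the count of surviving CEBPA variants.

    0 -> ``none``; 1 -> ``sm`` (singly mutated); >= 2 -> ``dm`` (doubly
    mutated, treated as biallelic).
    """
    if n_variants < 0:
        raise ValueError("variant count must be >= 0")
    if n_variants == 0:
        return "none"
    return "sm" if n_variants == 1 else "dm"


def classify_flt3(kind: str, allele_ratio: float | None = None) -> str:
    """FLT3 variant class.

    ITD calls carry an allele ratio (ITD signal over wild-type signal);
    AR >= 0.5 is ``ITD-high``, below is ``ITD-low``.  TKD point mutations
    are ``TKD``; anything else is ``Other``.
    """
    if kind == "ITD":
        if allele_ratio is None:
            raise ValueError("FLT3-ITD requires an allele ratio")
        if allele_ratio < 0:
            raise ValueError("allele ratio must be >= 0")
        return "ITD-high" if allele_ratio >= 0.5 else "ITD-low"
    if kind == "TKD":
        return "TKD"
    return "Other"


# ---------------------------------------------------------------------------
# TSV I/O

_COLUMNS = [
    "patient_id", "gene", "chrom", "position", "ref", "alt", "q_score",
    "depth", "vaf", "consequence", "cosmic_haem_count", "lab_prevalence",
]


def load_calls(path: str | Path) -> list[VariantCall]:
    """Read variant calls from TSV; ``pop_freq_*`` columns become pop_freqs."""
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "chrom": str})
    pop_cols = [c for c in df.columns if c.startswith("pop_freq_")]
    calls = []
    for _, row in df.iterrows():
        calls.append(
            VariantCall(
                patient_id=str(row["patient_id"]),
                gene=str(row["gene"]),
                locus=Locus(
                    chrom=str(row["chrom"]),
                    position=int(row["position"]),
                    ref=str(row["ref"]),
                    alt=str(row["alt"]),
                ),
                q_score=float(row["q_score"]),
                depth=int(row["depth"]),
                vaf=float(row["vaf"]),
                consequence=str(row["consequence"]),
                cosmic_haem_count=int(row.get("cosmic_haem_count", 0)),
                lab_prevalence=(
                    None if pd.isna(row.get("lab_prevalence"))
                    else float(row["lab_prevalence"])
                ),
                pop_freqs={
                    c.removeprefix("pop_freq_"): float(row[c])
                    for c in pop_cols
                    if not pd.isna(row[c])
                },
            )
        )
    return calls


def write_decisions(
    decisions: Sequence[FilterDecision], path: str | Path
) -> None:
    rows = []
    for d in decisions:
        c = d.call
        rows.append(
            {
                "patient_id": c.patient_id,
                "gene": c.gene,
                "chrom": c.locus.chrom,
                "position": c.locus.position,
                "ref": c.locus.ref,
                "alt": c.locus.alt,
                "vaf": c.vaf,
                "kept": int(d.kept),
                "reason": d.reason,
                "rescued": int(d.rescued),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_calls(calls: Sequence[VariantCall], path: str | Path) -> None:
    """Write raw calls to TSV in the layout :func:`load_calls` reads."""
    pop_dbs = sorted({db for c in calls for db in c.pop_freqs})
    rows = []
    for c in calls:
        row = {
            "patient_id": c.patient_id,
            "gene": c.gene,
            "chrom": c.locus.chrom,
            "position": c.locus.position,
            "ref": c.locus.ref,
            "alt": c.locus.alt,
            "q_score": c.q_score,
            "depth": c.depth,
            "vaf": c.vaf,
            "consequence": c.consequence,
            "cosmic_haem_count": c.cosmic_haem_count,
            "lab_prevalence": c.lab_prevalence,
        }
        for db in pop_dbs:
            row[f"pop_freq_{db}"] = c.pop_freqs.get(db)
        rows.append(row)
    pd.DataFrame(rows, columns=_COLUMNS + [f"pop_freq_{db}" for db in pop_dbs]).to_csv(
        path, sep="\t", index=False
    )


def load_panel_of_normals(path: str | Path) -> frozenset[Locus]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return frozenset(
        Locus(str(r["chrom"]), int(r["position"]), str(r["ref"]), str(r["alt"]))
        for _, r in df.iterrows()
    )
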