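"""cDNA-tier expression calls: silencing versus loss-driven absence.

The central methodological point of a paired genomic/cDNA CAPS design is that
a missing transcript band is only *silencing* when the genomic tier proves
the homeolog is still physically present. A cDNA-only absence over a genomic
loss is ``absent_due_to_genomic_loss`` — the gene is not silenced, it is
gone. cDNA data without a genomic call can therefore never produce a
silencing call.

A separate, optional readout quantifies relative homeolog expression from
measured band intensities (paternal/maternal ratio with a dominance
threshold), mirroring densitometric comparison of homeologous bands.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping

from .digest import DiagnosticAssay, GelBandSet
from .genotyping import Genotype, GenotypeCall, ObservedPattern, Tier

__all__ = [
    "Expression",
    "ExpressionCall",
    "Dominance",
    "ExpressionRatio",
    "call_expression",
    "expression_ratio",
]


class Expression(str, enum.Enum):
    BOTH_EXPRESSED = "both_expressed"
    SILENCED_MATERNAL = "silenced_maternal"
    SILENCED_PATERNAL = "silenced_paternal"
    ABSENT_DUE_TO_GENOMIC_LOSS = "absent_due_to_genomic_loss"
    UNSCORABLE = "unscorable"


@dataclass(frozen=True)
class ExpressionCall:
    value: Expression
    matched_maternal: GelBandSet
    matched_paternal: GelBandSet


def call_expression(
    genomic_call: GenotypeCall, cdna_obs: ObservedPattern, assay: DiagnosticAssay
) -> ExpressionCall:
    """Classify a cDNA lane in the light of the same individual's genomic call.

    Silencing of parent X requires an additive genomic call, zero X-diagnostic
    cDNA matches and >=1 match for the other parent. Over a genomic loss of X,
    a missing X transcript is loss-driven absence, never silencing. Genomic
    unscorable/ambiguous calls propagate to unscorable.
    """
    if cdna_obs.tier is not Tier.CDNA:
        raise ValueError(f"call_expression requires a cdna-tier pattern, got {cdna_obs.tier.value}")
    tol = assay.gel.comigration_rel_tol
    matched_mat = GelBandSet(
        tuple(b for b in assay.maternal_diagnostic.bands if cdna_obs.bands.contains(b, tol))
    )
    matched_pat = GelBandSet(
        tuple(b for b in assay.paternal_diagnostic.bands if cdna_obs.bands.contains(b, tol))
    )
    g = genomic_call.value
    if g in (Genotype.UNSCORABLE, Genotype.AMBIGUOUS_POLYMORPHISM):
        value = Expression.UNSCORABLE
    elif g is Genotype.ADDITIVE:
        if matched_mat and matched_pat:
            value = Expression.BOTH_EXPRESSED
        elif matched_pat:
            value = Expression.SILENCED_MATERNAL
        elif matched_mat:
            value = Expression.SILENCED_PATERNAL
        else:
            value = Expression.UNSCORABLE
    elif g is Genotype.LOSS_MATERNAL:
        # maternal homeolog physically absent: its transcript absence is not silencing
        value = Expression.ABSENT_DUE_TO_GENOMIC_LOSS if not matched_mat else Expression.UNSCORABLE
    else:  # LOSS_PATERNAL
        value = Expression.ABSENT_DUE_TO_GENOMIC_LOSS if not matched_pat else Expression.UNSCORABLE
    return ExpressionCall(value=value, matched_maternal=matched_mat, matched_paternal=matched_pat)


class Dominance(str, enum.Enum):
    BALANCED = "balanced"
    PATERNAL_DOMINANT = "paternal_dominant"
    MATERNAL_DOMINANT = "maternal_dominant"
    EXCLUSIVE_PATERNAL = "exclusive_paternal"
    EXCLUSIVE_MATERNAL = "exclusive_maternal"
    UNSCORABLE = "unscorable"


@dataclass(frozen=True)
class ExpressionRatio:
    """Relative homeolog band intensity: paternal/maternal with a dominance label."""

    paternal_intensity: float
    maternal_intensity: float
    ratio: float | None
    dominance: Dominance


def expression_ratio(
    intensities: Mapping[int, float],
    assay: DiagnosticAssay,
    dominance_threshold: float = 2.0,
) -> ExpressionRatio:
    """Per-parent intensity sums over matched diagnostic bands, and the ratio.

    A parent's intensity is the sum over its diagnostic bands that were
    measured (matched by the co-migration comparator). Scale-invariant:
    multiplying all intensities by c > 0 changes neither ratio nor dominance.
    ``dominance_threshold`` (> 1) sets how skewed the ratio must be before a
    parent is called dominant.
    """
    if dominance_threshold <= 1:
        raise ValueError("dominance_threshold must be > 1")
    tol = assay.gel.comigration_rel_tol

    def parent_sum(diag: GelBandSet) -> tuple[float, bool]:
        total, measured = 0.0, False
        for band, value in intensities.items():
            if diag.contains(band, tol):
                total += value
                measured = True
        return total, measured

    pat, pat_measured = parent_sum(assay.paternal_diagnostic)
    mat, mat_measured = parent_sum(assay.maternal_diagnostic)
    if not (pat_measured or mat_measured):
        return ExpressionRatio(0.0, 0.0, None, Dominance.UNSCORABLE)
    if mat == 0 and pat == 0:
        return ExpressionRatio(pat, mat, None, Dominance.UNSCORABLE)
    if mat == 0:
        return ExpressionRatio(pat, mat, None, Dominance.EXCLUSIVE_PATERNAL)
    if pat == 0:
        return ExpressionRatio(pat, mat, 0.0, Dominance.EXCLUSIVE_MATERNAL)
    ratio = pat / mat
    if ratio >= dominance_threshold:
        dom = Dominance.PATERNAL_DOMINANT
    elif ratio <= 1.0 / dominance_threshold:
        dom = Dominance.MATERNAL_DOMINANT
    else:
        dom = Dominance.BALANCED
    return ExpressionRatio(pat, mat, ratio, dom)
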