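"""End-to-end study analysis: design → genotype → expression → summary.

Ties the stages together over in-memory objects; the CLI and the synthetic
dataset both feed this entry point. The stage order mirrors the wet-lab
workflow: pick a diagnostic enzyme per locus, screen the diploid parents for
within-parent polymorphism (which excludes a locus), call each polyploid/F1
individual's genotype from its genomic lane, then contrast cDNA lanes with
the genomic calls to separate silencing from loss-driven absence, and tally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .digest import DEFAULT_ENZYME_PANEL, DiagnosticAssay, GelConfig, RestrictionEnzyme, design_assays
from .expression import Expression, ExpressionCall, call_expression
from .genotyping import (
    GenotypeCall,
    LocusGenotypeSummary,
    ObservedPattern,
    Tier,
    call_genotype,
    detect_parental_polymorphism,
    summarize_locus,
)
from .sequence_model import IndividualRecord, LocusAlleles, Role
from .stats import StudySummary, build_study_summary

__all__ = ["StudyResult", "run_study"]


@dataclass
class StudyResult:
    """Everything the pipeline produced for one study."""

    assays: dict[str, DiagnosticAssay]
    informative_loci: list[str]
    uninformative_loci: list[str]
    polymorphic_loci: set[str]
    locus_summaries: list[LocusGenotypeSummary]
    genotype_calls: dict[tuple[str, str], GenotypeCall]
    expression_calls: dict[tuple[str, str], ExpressionCall]
    silenced_by_individual: dict[str, set[str]]
    genes_with_silencing: int
    summary: StudySummary


def run_study(
    alleles: Sequence[LocusAlleles],
    observations: Sequence[ObservedPattern],
    individuals: Sequence[IndividualRecord],
    panel: Sequence[RestrictionEnzyme] = DEFAULT_ENZYME_PANEL,
    gel: GelConfig = GelConfig(),
    decimals: int = 1,
) -> StudyResult:
    """Run the full classification pipeline over one study's inputs.

    Observations must cover the genomic tier for every scored individual ×
    locus; cDNA-tier lanes are optional and add expression calls. Loci with no
    informative enzyme are carried but not scored. Raises on observations
    naming unknown loci or individuals.
    """
    role_of = {i.individual_id: i.role for i in individuals}
    known_loci = {la.locus_id for la in alleles}
    bad_inds = sorted({o.individual_id for o in observations if o.individual_id not in role_of})
    bad_loci = sorted({o.locus_id for o in observations if o.locus_id not in known_loci})
    if bad_inds or bad_loci:
        raise ValueError(
            f"observations reference unknown individuals {bad_inds} / loci {bad_loci}"
        )

    assays: dict[str, DiagnosticAssay] = {}
    for la in alleles:
        ranked = design_assays(la, panel, gel)
        if ranked:
            assays[la.locus_id] = ranked[0]
    informative = [lid for lid, a in assays.items() if a.informative]
    uninformative = [la.locus_id for la in alleles if la.locus_id not in informative]

    by_key: dict[tuple[str, str, Tier], ObservedPattern] = {}
    for o in observations:
        by_key[(o.individual_id, o.locus_id, o.tier)] = o

    # within-parent polymorphism screen over the diploid parents, per locus per parent
    polymorphic: set[str] = set()
    for lid in informative:
        for parent_role in (Role.MATERNAL_PARENT, Role.PATERNAL_PARENT):
            lanes = [
                o
                for o in observations
                if o.locus_id == lid
                and o.tier is Tier.GENOMIC
                and role_of[o.individual_id] is parent_role
            ]
            if lanes and detect_parental_polymorphism(lanes, gel.comigration_rel_tol)[0]:
                polymorphic.add(lid)
                break

    cohort = [i for i in individuals if i.role in (Role.POLYPLOID, Role.F1_HYBRID)]
    genotype_calls: dict[tuple[str, str], GenotypeCall] = {}
    locus_summaries: list[LocusGenotypeSummary] = []
    for lid in informative:
        assay = assays[lid]
        calls: dict[str, GenotypeCall] = {}
        for ind in cohort:
            obs = by_key.get((ind.individual_id, lid, Tier.GENOMIC))
            if obs is None:
                continue
            calls[ind.individual_id] = call_genotype(obs, assay)
        if not calls:
            continue
        summary = summarize_locus(lid, calls, polymorphic_parent=lid in polymorphic)
        locus_summaries.append(summary)
        for ind_id, c in summary.calls.items():
            genotype_calls[(ind_id, lid)] = c

    expression_calls: dict[tuple[str, str], ExpressionCall] = {}
    silenced_by_individual: dict[str, set[str]] = {}
    silenced_loci: set[str] = set()
    for (ind_id, lid), gcall in genotype_calls.items():
        cdna = by_key.get((ind_id, lid, Tier.CDNA))
        if cdna is None:
            continue
        ecall = call_expression(gcall, cdna, assays[lid])
        expression_calls[(ind_id, lid)] = ecall
        if ecall.value in (Expression.SILENCED_MATERNAL, Expression.SILENCED_PATERNAL):
            silenced_by_individual.setdefault(ind_id, set()).add(lid)
            silenced_loci.add(lid)

    summary = build_study_summary(
        locus_summaries,
        individuals,
        silenced_by_individual,
        genes_with_silencing=len(silenced_loci),
        decimals=decimals,
    )
    return StudyResult(
        assays=assays,
        informative_loci=informative,
        uninformative_loci=uninformative,
        polymorphic_loci=polymorphic,
        locus_summaries=locus_summaries,
        genotype_calls=genotype_calls,
        expression_calls=expression_calls,
        silenced_by_individual=silenced_by_individual,
        genes_with_silencing=len(silenced_loci),
        summary=summary,
    )
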