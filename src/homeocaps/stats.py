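"""Study-level tallies: gene status, per-parent loss percentages, per-population breakdowns.

Conventions: loci excluded for within-parent polymorphism contribute nothing
to any tally; "homeologs assayed" is 2 × the number of informative
(non-excluded) genes, since every surveyed gene carries one maternal and one
paternal homeolog; printed percentages are round-half-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

from .sequence_model import IndividualRecord

__all__ = [
    "percent",
    "tally_gene_status",
    "HomeologLossTally",
    "tally_by_parent",
    "per_population_breakdown",
    "StudySummary",
    "build_study_summary",
]


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """``100 * numerator / denominator`` rounded half-up to ``decimals`` places.

    Half-up (not banker's) rounding matches how gel-study tallies are
    conventionally printed, e.g. 11/58 -> 18.97 at two decimals.
    """
    if denominator <= 0:
        raise ValueError("percent requires a positive denominator")
    quantum = Decimal(1).scaleb(-decimals)
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


def tally_gene_status(summaries: Sequence["LocusGenotypeSummary"]) -> tuple[int, int, int]:
    """Partition surveyed genes into (additive_all, loss_detected, excluded) counts."""
    from .genotyping import GeneStatus

    seen: set[str] = set()
    additive = loss = excluded = 0
    for s in summaries:
        if s.locus_id in seen:
            raise ValueError(f"duplicate locus_id {s.locus_id!r} in gene-status tally")
        seen.add(s.locus_id)
        if s.gene_status is GeneStatus.EXCLUDED_PARENTAL_POLYMORPHISM:
            excluded += 1
        elif s.gene_status is GeneStatus.LOSS_DETECTED:
            loss += 1
        else:
            additive += 1
    return additive, loss, excluded


@dataclass(frozen=True)
class HomeologLossTally:
    """Per-parent homeolog-loss counts over 2 × informative genes."""

    informative_gene_count: int
    genes_with_maternal_loss: int
    genes_with_paternal_loss: int
    individuals_with_loss: int
    individuals_with_silencing: int
    decimals: int = 1

    @property
    def homeologs_assayed(self) -> int:
        return 2 * self.informative_gene_count

    @property
    def maternal_loss_percent(self) -> float:
        return percent(self.genes_with_maternal_loss, self.homeologs_assayed, self.decimals)

    @property
    def paternal_loss_percent(self) -> float:
        return percent(self.genes_with_paternal_loss, self.homeologs_assayed, self.decimals)

    def combined_loss_percent(self, decimals: int = 2) -> float:
        return percent(
            self.genes_with_maternal_loss + self.genes_with_paternal_loss,
            self.homeologs_assayed,
            decimals,
        )


def tally_by_parent(
    summaries: Sequence["LocusGenotypeSummary"],
    silenced_by_individual: Mapping[str, set[str]] | None = None,
    decimals: int = 1,
) -> HomeologLossTally:
    """Count homeolog losses per parent over the informative (non-excluded) genes.

    Gene-level: a parent's homeolog counts as lost at a gene if >=1 individual
    lost it there. Individual-level: individuals with >=1 loss event and (via
    ``silenced_by_individual``, a map individual_id -> set of silenced locus
    ids) with >=1 silencing event; events deduplicate by (individual, locus).
    """
    from .genotyping import GeneStatus, Genotype

    informative = [s for s in summaries if s.gene_status is not GeneStatus.EXCLUDED_PARENTAL_POLYMORPHISM]
    mat = sum("maternal" in s.lost_parent_set for s in informative)
    pat = sum("paternal" in s.lost_parent_set for s in informative)
    individuals_with_loss: set[str] = set()
    for s in informative:
        for ind, call in s.calls.items():
            if call.value in (Genotype.LOSS_MATERNAL, Genotype.LOSS_PATERNAL):
                individuals_with_loss.add(ind)
    n_silenced = sum(1 for loci in (silenced_by_individual or {}).values() if loci)
    return HomeologLossTally(
        informative_gene_count=len(informative),
        genes_with_maternal_loss=mat,
        genes_with_paternal_loss=pat,
        individuals_with_loss=len(individuals_with_loss),
        individuals_with_silencing=n_silenced,
        decimals=decimals,
    )


def per_population_breakdown(
    summaries: Sequence["LocusGenotypeSummary"],
    individuals: Sequence[IndividualRecord],
    silenced_by_individual: Mapping[str, set[str]] | None = None,
) -> dict[str, tuple[int, int]]:
    """Per population: (distinct loci with >=1 loss call, distinct loci with >=1 silencing).

    A locus lost in two populations counts once in each; within a population
    it counts once however many individuals lost it.
    """
    from .genotyping import GeneStatus, Genotype

    pop_of = {i.individual_id: i.population_id for i in individuals}
    loss_loci: dict[str, set[str]] = {p: set() for p in {i.population_id for i in individuals}}
    sil_loci: dict[str, set[str]] = {p: set() for p in loss_loci}
    for s in summaries:
        if s.gene_status is GeneStatus.EXCLUDED_PARENTAL_POLYMORPHISM:
            continue
        for ind, call in s.calls.items():
            if ind not in pop_of:
                raise ValueError(f"call references unknown individual {ind!r}")
            if call.value in (Genotype.LOSS_MATERNAL, Genotype.LOSS_PATERNAL):
                loss_loci[pop_of[ind]].add(s.locus_id)
    for ind, loci in (silenced_by_individual or {}).items():
        if ind not in pop_of:
            raise ValueError(f"silencing record references unknown individual {ind!r}")
        sil_loci[pop_of[ind]].update(loci)
    return {p: (len(loss_loci[p]), len(sil_loci[p])) for p in sorted(loss_loci)}


@dataclass(frozen=True)
class StudySummary:
    """Top-level study report: gene-status partition, loss tally, population breakdown."""

    genes_additive: int
    genes_with_loss: int
    genes_excluded: int
    genes_with_silencing: int
    loss_tally: HomeologLossTally
    per_population: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def genes_surveyed(self) -> int:
        return self.genes_additive + self.genes_with_loss + self.genes_excluded

    def to_dict(self) -> dict:
        t = self.loss_tally
        return {
            "genes_surveyed": self.genes_surveyed,
            "genes_additive": self.genes_additive,
            "genes_with_loss": self.genes_with_loss,
            "genes_excluded": self.genes_excluded,
            "genes_with_silencing": self.genes_with_silencing,
            "informative_genes": t.informative_gene_count,
            "homeologs_assayed": t.homeologs_assayed,
            "genes_with_maternal_loss": t.genes_with_maternal_loss,
            "genes_with_paternal_loss": t.genes_with_paternal_loss,
            "maternal_loss_percent": t.maternal_loss_percent,
            "paternal_loss_percent": t.paternal_loss_percent,
            "combined_loss_percent": t.combined_loss_percent(),
            "silencing_percent": percent(self.genes_with_silencing, self.genes_surveyed, 1)
            if self.genes_surveyed
            else 0.0,
            "individuals_with_loss": t.individuals_with_loss,
            "individuals_with_silencing": t.individuals_with_silencing,
            "per_population": {p: {"loss_loci": l, "silencing_loci": s} for p, (l, s) in self.per_population.items()},
        }


def build_study_summary(
    summaries: Sequence["LocusGenotypeSummary"],
    individuals: Sequence[IndividualRecord],
    silenced_by_individual: Mapping[str, set[str]] | None = None,
    genes_with_silencing: int = 0,
    decimals: int = 1,
) -> StudySummary:
    """Assemble the full study summary from locus summaries and silencing records."""
    additive, loss, excluded = tally_gene_status(summaries)
    tally = tally_by_parent(summaries, silenced_by_individual, decimals=decimals)
    breakdown = per_population_breakdown(summaries, individuals, silenced_by_individual)
    return StudySummary(
        genes_additive=additive,
        genes_with_loss=loss,
        genes_excluded=excluded,
        genes_with_silencing=genes_with_silencing,
        loss_tally=tally,
        per_population=breakdown,
    )
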