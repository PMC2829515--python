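"""Genomic-tier CAPS genotype calls and locus-level summaries.

Each polyploid (or F1 hybrid) individual is classified at each locus from its
observed genomic band pattern against the locus's diagnostic assay:

* ``additive`` — at least one diagnostic band of each parent matched;
* ``loss_maternal`` / ``loss_paternal`` — one parent's diagnostic bands all
  absent while the other parent's are present (putative homeolog loss);
* ``unscorable`` — empty lane, or a lane matching neither parent's
  diagnostics (a tetraploid lacking both homeologs would not amplify, so a
  double loss is never called);
* ``ambiguous_polymorphism`` — the locus shows within-parent polymorphism in
  a diploid parent, which makes loss indistinguishable from segregating
  presence/absence; such loci are excluded from loss tallies.

Matching uses at-least-one-diagnostic-band semantics: shared (non-diagnostic)
fragments carry no parent information, and partial lane dropout should not
flip a call.

A putative loss can be confirmed by sequencing the surviving amplicon(s):
recovery of only one parental haplotype confirms loss, recovery of both means
the gel difference was a restriction-site polymorphism, not a loss.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .digest import DiagnosticAssay, GelBandSet, band_sets_equal
from .sequence_model import LocusAlleles, NucleotideSequence

__all__ = [
    "Tier",
    "ObservedPattern",
    "Genotype",
    "GenotypeCall",
    "SequencingResult",
    "SequencingEvidence",
    "GeneStatus",
    "LocusGenotypeSummary",
    "call_genotype",
    "detect_parental_polymorphism",
    "confirm_loss",
    "summarize_locus",
    "read_observations",
    "write_observations",
    "write_genotype_report",
]


class Tier(str, enum.Enum):
    GENOMIC = "genomic"
    CDNA = "cdna"


@dataclass(frozen=True)
class ObservedPattern:
    """One lane: an individual × locus × tier band pattern, optionally with intensities."""

    individual_id: str
    locus_id: str
    tier: Tier
    bands: GelBandSet
    intensities: Mapping[int, float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "tier", Tier(self.tier))
        if self.intensities is not None:
            if any(v < 0 for v in self.intensities.values()):
                raise ValueError(
                    f"{self.individual_id}/{self.locus_id}: intensities must be nonnegative"
                )


class Genotype(str, enum.Enum):
    ADDITIVE = "additive"
    LOSS_MATERNAL = "loss_maternal"
    LOSS_PATERNAL = "loss_paternal"
    AMBIGUOUS_POLYMORPHISM = "ambiguous_polymorphism"
    UNSCORABLE = "unscorable"


@dataclass(frozen=True)
class GenotypeCall:
    """A genotype label plus the diagnostic bands that support it."""

    value: Genotype
    matched_maternal: GelBandSet = field(default_factory=GelBandSet)
    matched_paternal: GelBandSet = field(default_factory=GelBandSet)


class SequencingResult(str, enum.Enum):
    CONFIRMED_LOSS = "confirmed_loss"
    RESTRICTION_SITE_POLYMORPHISM = "restriction_site_polymorphism"
    INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class SequencingEvidence:
    """Which parental haplotypes were recovered by sequencing, and the verdict."""

    recovered_haplotypes: frozenset[str]
    result: SequencingResult
    flags: tuple[str, ...] = ()


class GeneStatus(str, enum.Enum):
    ADDITIVE_ALL = "additive_all"
    LOSS_DETECTED = "loss_detected"
    EXCLUDED_PARENTAL_POLYMORPHISM = "excluded_parental_polymorphism"


@dataclass(frozen=True)
class LocusGenotypeSummary:
    """Locus-level digest of the per-individual genotype calls."""

    locus_id: str
    calls: Mapping[str, GenotypeCall]
    gene_status: GeneStatus
    lost_parent_set: frozenset[str]


def call_genotype(obs: ObservedPattern, assay: DiagnosticAssay) -> GenotypeCall:
    """Classify one genomic lane against the locus's diagnostic assay.

    Observed bands are matched to each parent's diagnostic bands via the
    co-migration comparator; presence of >=1 matched band per parent decides
    the call. An empty lane (failed amplification) is unscorable.
    """
    if obs.tier is not Tier.GENOMIC:
        raise ValueError(f"call_genotype requires a genomic-tier pattern, got {obs.tier.value}")
    if not assay.informative:
        raise ValueError(f"assay for locus {assay.locus_id!r} is not informative")
    tol = assay.gel.comigration_rel_tol
    matched_mat = GelBandSet(
        tuple(b for b in assay.maternal_diagnostic.bands if obs.bands.contains(b, tol))
    )
    matched_pat = GelBandSet(
        tuple(b for b in assay.paternal_diagnostic.bands if obs.bands.contains(b, tol))
    )
    if matched_mat and matched_pat:
        value = Genotype.ADDITIVE
    elif matched_pat:
        value = Genotype.LOSS_MATERNAL
    elif matched_mat:
        value = Genotype.LOSS_PATERNAL
    else:
        value = Genotype.UNSCORABLE
    return GenotypeCall(value=value, matched_maternal=matched_mat, matched_paternal=matched_pat)


def detect_parental_polymorphism(
    parent_patterns: Sequence[ObservedPattern], rel_tol: float = 0.05
) -> tuple[bool, int]:
    """Group one parent species' lanes at one locus into band-pattern classes.

    Returns ``(polymorphic, n_classes)``: polymorphic iff the sampled parent
    individuals fall into more than one class under the co-migration
    comparator. Any polymorphism excludes the locus from loss tallies.
    """
    if not parent_patterns:
        raise ValueError("detect_parental_polymorphism requires >=1 pattern")
    loci = {p.locus_id for p in parent_patterns}
    if len(loci) > 1:
        raise ValueError(f"patterns span multiple loci: {sorted(loci)}")
    classes: list[GelBandSet] = []
    for p in parent_patterns:
        if not any(band_sets_equal(p.bands, rep, rel_tol) for rep in classes):
            classes.append(p.bands)
    return len(classes) > 1, len(classes)


def _positional_identity(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / len(a)


def confirm_loss(
    recovered: Sequence[NucleotideSequence],
    alleles: LocusAlleles,
    min_identity: float = 0.95,
) -> SequencingEvidence:
    """Sequencing test separating true homeolog loss from restriction-site polymorphism.

    Each recovered amplicon is assigned to the parental allele with greater
    positional identity over the shared coordinate frame, provided identity
    >= ``min_identity``; equidistant sequences are never assigned. Exactly one
    parental haplotype recovered confirms loss; both recovered means the gel
    difference was a lost restriction site; none assignable is inconclusive.
    """
    recovered_parents: set[str] = set()
    flags: list[str] = []
    mat = alleles.maternal_allele.residues
    pat = alleles.paternal_allele.residues
    for seq in recovered:
        if len(seq) != len(mat) or len(seq) != len(pat):
            flags.append(f"{seq.seq_id}: length-incompatible comparison frame")
            continue
        id_mat = _positional_identity(seq.residues, mat)
        id_pat = _positional_identity(seq.residues, pat)
        if id_mat == id_pat:
            flags.append(f"{seq.seq_id}: equidistant from both alleles")
            continue
        best, best_id = ("maternal", id_mat) if id_mat > id_pat else ("paternal", id_pat)
        if best_id < min_identity:
            flags.append(f"{seq.seq_id}: best identity {best_id:.3f} below threshold")
            continue
        recovered_parents.add(best)
    if len(recovered_parents) == 1:
        result = SequencingResult.CONFIRMED_LOSS
    elif len(recovered_parents) == 2:
        result = SequencingResult.RESTRICTION_SITE_POLYMORPHISM
    else:
        result = SequencingResult.INCONCLUSIVE
    return SequencingEvidence(
        recovered_haplotypes=frozenset(recovered_parents), result=result, flags=tuple(flags)
    )


def summarize_locus(
    locus_id: str,
    calls: Mapping[str, GenotypeCall],
    polymorphic_parent: bool = False,
) -> LocusGenotypeSummary:
    """Collapse per-individual calls into a locus status.

    Within-parent polymorphism overrides everything (the locus is excluded);
    otherwise the locus carries ``loss_detected`` iff any individual shows a
    loss, and ``lost_parent_set`` accumulates the parents lost in >=1
    individual.
    """
    if not calls:
        raise ValueError(f"locus {locus_id!r}: no calls to summarize")
    if polymorphic_parent:
        excluded_calls = {
            ind: GenotypeCall(
                Genotype.AMBIGUOUS_POLYMORPHISM, c.matched_maternal, c.matched_paternal
            )
            for ind, c in calls.items()
        }
        return LocusGenotypeSummary(
            locus_id=locus_id,
            calls=excluded_calls,
            gene_status=GeneStatus.EXCLUDED_PARENTAL_POLYMORPHISM,
            lost_parent_set=frozenset(),
        )
    lost = set()
    for c in calls.values():
        if c.value is Genotype.LOSS_MATERNAL:
            lost.add("maternal")
        elif c.value is Genotype.LOSS_PATERNAL:
            lost.add("paternal")
    status = GeneStatus.LOSS_DETECTED if lost else GeneStatus.ADDITIVE_ALL
    return LocusGenotypeSummary(
        locus_id=locus_id, calls=dict(calls), gene_status=status, lost_parent_set=frozenset(lost)
    )


def _parse_bands(cell: str) -> GelBandSet:
    cell = str(cell).strip()
    if cell in ("", "-", "nan"):
        return GelBandSet()
    return GelBandSet(tuple(int(x) for x in cell.split(",")))


def _parse_intensities(cell: str) -> dict[int, float] | None:
    cell = str(cell).strip()
    if cell in ("", "-", "nan"):
        return None
    out: dict[int, float] = {}
    for item in cell.split(";"):
        band, _, value = item.partition("=")
        out[int(band)] = float(value)
    return out


def read_observations(path: str | Path) -> list[ObservedPattern]:
    """Read the observed-pattern TSV (individual_id, locus_id, tier, bands[, intensities])."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    missing = {"individual_id", "locus_id", "tier", "bands"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: observations table missing columns {sorted(missing)}")
    has_int = "intensities" in df.columns
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ObservedPattern(
                individual_id=row.individual_id,
                locus_id=row.locus_id,
                tier=Tier(row.tier),
                bands=_parse_bands(row.bands),
                intensities=_parse_intensities(row.intensities) if has_int else None,
            )
        )
    return out


def write_observations(patterns: Iterable[ObservedPattern], path: str | Path) -> None:
    rows = []
    for p in patterns:
        rows.append(
            {
                "individual_id": p.individual_id,
                "locus_id": p.locus_id,
                "tier": p.tier.value,
                "bands": ",".join(str(b) for b in p.bands.bands),
                "intensities": ";".join(f"{k}={v}" for k, v in p.intensities.items())
                if p.intensities
                else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_genotype_report(
    summaries: Sequence[LocusGenotypeSummary], path: str | Path
) -> pd.DataFrame:
    """Per individual × locus genotype report TSV, with the locus-level status."""
    rows = []
    for s in summaries:
        for ind, call in sorted(s.calls.items()):
            rows.append(
                {
                    "individual_id": ind,
                    "locus_id": s.locus_id,
                    "call": call.value.value,
                    "matched_maternal": ",".join(str(b) for b in call.matched_maternal.bands),
                    "matched_paternal": ",".join(str(b) for b in call.matched_paternal.bands),
                    "gene_status": s.gene_status.value,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
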