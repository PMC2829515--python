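"""In-silico restriction digestion and diagnostic-assay design.

A CAPS assay distinguishes the two parental alleles of a locus when some
restriction enzyme cuts them differently, so that each parent shows at least
one gel band the other lacks (a *diagnostic* band). This module scans IUPAC
recognition sites over both strands of a linear amplicon, predicts fragment
lengths, models agarose-gel visibility (minimum detectable size, co-migration
of similar lengths), and selects informative enzymes for a locus.

Substrate sequences must be concrete (A/C/G/T only): degenerate bases in an
amplicon would make "does the enzyme cut?" ill-defined. Enzyme sites may be
degenerate (e.g. HinfI's GANTC).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .sequence_model import (
    AlphabetError,
    IUPAC_SETS,
    LocusAlleles,
    NucleotideSequence,
    iupac_match,
    reverse_complement,
)

__all__ = [
    "RestrictionEnzyme",
    "GelConfig",
    "GelBandSet",
    "DigestPattern",
    "DiagnosticAssay",
    "DEFAULT_ENZYME_PANEL",
    "find_cut_sites",
    "digest",
    "to_band_set",
    "merge_comigrating",
    "bands_match",
    "band_sets_equal",
    "design_assays",
    "predict_polyploid_bands",
    "read_enzyme_panel",
    "write_enzyme_panel",
    "write_assay_report",
]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme: IUPAC recognition site and top-strand cut offset.

    ``cut_offset`` is measured in bp from the 5' end of the site on the strand
    where the site is read; only fragment lengths are observable on a gel, so
    no overhang bookkeeping is kept.
    """

    name: str
    site: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not (4 <= len(self.site) <= 8):
            raise ValueError(f"enzyme {self.name!r}: site length must be 4-8, got {len(self.site)}")
        for ch in self.site.upper():
            if ch not in IUPAC_SETS:
                raise AlphabetError(f"enzyme {self.name!r}: illegal site character {ch!r}")
        object.__setattr__(self, "site", self.site.upper())
        if not (0 <= self.cut_offset <= len(self.site)):
            raise ValueError(
                f"enzyme {self.name!r}: cut_offset {self.cut_offset} outside [0, {len(self.site)}]"
            )


# A generic panel of common enzymes (REBASE-style minimal fields): frequent
# 4-cutters plus standard 6-cutters, enough to make most diverged allele
# pairs scorable.
DEFAULT_ENZYME_PANEL: tuple[RestrictionEnzyme, ...] = (
    RestrictionEnzyme("AluI", "AGCT", 2),
    RestrictionEnzyme("BamHI", "GGATCC", 1),
    RestrictionEnzyme("DraI", "TTTAAA", 3),
    RestrictionEnzyme("EcoRI", "GAATTC", 1),
    RestrictionEnzyme("EcoRV", "GATATC", 3),
    RestrictionEnzyme("HaeIII", "GGCC", 2),
    RestrictionEnzyme("HindIII", "AAGCTT", 1),
    RestrictionEnzyme("HinfI", "GANTC", 1),
    RestrictionEnzyme("MseI", "TTAA", 1),
    RestrictionEnzyme("PstI", "CTGCAG", 5),
    RestrictionEnzyme("RsaI", "GTAC", 2),
    RestrictionEnzyme("TaqI", "TCGA", 1),
)


@dataclass(frozen=True)
class GelConfig:
    """Agarose-gel observability model.

    ``min_detectable_bp`` drops fragments that run off the gel;
    ``comigration_rel_tol`` is the relative size difference under which two
    bands are indistinguishable (resolution scales with fragment size).
    """

    min_detectable_bp: int = 50
    comigration_rel_tol: float = 0.05

    def __post_init__(self) -> None:
        if self.min_detectable_bp < 1:
            raise ValueError("min_detectable_bp must be >= 1")
        if not (0 <= self.comigration_rel_tol < 1):
            raise ValueError("comigration_rel_tol must be in [0, 1)")


def bands_match(a: float, b: float, rel_tol: float) -> bool:
    """Co-migration comparator: bands equal iff within ``rel_tol`` of the larger."""
    return abs(a - b) <= rel_tol * max(a, b)


@dataclass(frozen=True)
class GelBandSet:
    """Visible bands on a lane: descending-sorted representative lengths."""

    bands: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "bands", tuple(sorted(self.bands, reverse=True)))

    def __len__(self) -> int:
        return len(self.bands)

    def __bool__(self) -> bool:
        return bool(self.bands)

    def contains(self, band: float, rel_tol: float) -> bool:
        return any(bands_match(band, b, rel_tol) for b in self.bands)


@dataclass(frozen=True)
class DigestPattern:
    """Multiset of fragment lengths from a complete digest of a linear amplicon."""

    fragment_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "fragment_lengths", tuple(sorted(self.fragment_lengths, reverse=True)))
        if any(f <= 0 for f in self.fragment_lengths):
            raise ValueError("fragment lengths must be positive")


@dataclass(frozen=True)
class DiagnosticAssay:
    """One enzyme applied to one locus, with the parent-diagnostic bands.

    Informative iff both parents retain at least one band the other lacks
    (under the co-migration comparator), i.e. every individual's parent-of-
    origin content is readable from the lane.
    """

    locus_id: str
    enzyme: RestrictionEnzyme
    maternal_bands: GelBandSet
    paternal_bands: GelBandSet
    maternal_diagnostic: GelBandSet
    paternal_diagnostic: GelBandSet
    gel: GelConfig = field(default_factory=GelConfig)

    @property
    def informative(self) -> bool:
        return bool(self.maternal_diagnostic) and bool(self.paternal_diagnostic)


def _check_substrate(seq: NucleotideSequence) -> None:
    if not seq.is_concrete:
        raise AlphabetError(
            f"sequence {seq.seq_id!r}: digestion substrate must be concrete A/C/G/T "
            "(degenerate bases make cut sites ill-defined)"
        )


def _scan_one_strand(residues: str, site: str) -> list[int]:
    m = len(site)
    hits = []
    for start in range(len(residues) - m + 1):
        if all(iupac_match(site[j], residues[start + j]) for j in range(m)):
            hits.append(start)
    return hits


def find_cut_sites(
    seq: NucleotideSequence, enzyme: RestrictionEnzyme, both_strands: bool = True
) -> list[int]:
    """Between-base cut positions of ``enzyme`` on a linear sequence.

    With ``both_strands`` (default), sites on the reverse complement are
    mapped back to top-strand coordinates and deduplicated (palindromic
    sites dedupe naturally). Cuts at position 0 or at sequence length would
    produce gel-invisible zero-length fragments and are discarded.
    """
    _check_substrate(seq)
    length = len(seq)
    m = len(enzyme.site)
    top = set(_scan_one_strand(seq.residues, enzyme.site))
    cuts = {s + enzyme.cut_offset for s in top}
    if both_strands:
        rc = reverse_complement(seq.residues)
        for start in _scan_one_strand(rc, enzyme.site):
            s = length - start - m  # top-strand start of the duplex site window
            if s not in top:  # palindromic / degenerate-symmetric sites dedupe here
                cuts.add(s + m - enzyme.cut_offset)
    return sorted(p for p in cuts if 0 < p < length)


def digest(
    seq: NucleotideSequence, enzyme: RestrictionEnzyme, both_strands: bool = True
) -> DigestPattern:
    """Fragment lengths from a complete digest; lengths sum to the sequence length."""
    cuts = find_cut_sites(seq, enzyme, both_strands=both_strands)
    bounds = [0, *cuts, len(seq)]
    return DigestPattern(tuple(b - a for a, b in zip(bounds, bounds[1:])))


def merge_comigrating(lengths: Sequence[float], rel_tol: float) -> list[int]:
    """Greedy largest-first clustering of band lengths that co-migrate.

    Each cluster is represented by its largest member; a length joins the
    current cluster iff it is within ``rel_tol`` of that largest member.
    """
    reps: list[int] = []
    for x in sorted(lengths, reverse=True):
        if reps and reps[-1] - x <= rel_tol * reps[-1]:
            continue
        reps.append(int(round(x)))
    return reps


def to_band_set(pattern: DigestPattern | Sequence[float], gel: GelConfig) -> GelBandSet:
    """Gel-visible bands: drop undetectable fragments, merge co-migrating ones."""
    lengths = pattern.fragment_lengths if isinstance(pattern, DigestPattern) else pattern
    visible = [f for f in lengths if f >= gel.min_detectable_bp]
    return GelBandSet(tuple(merge_comigrating(visible, gel.comigration_rel_tol)))


def _diagnostic(own: GelBandSet, other: GelBandSet, rel_tol: float) -> GelBandSet:
    return GelBandSet(tuple(b for b in own.bands if not other.contains(b, rel_tol)))


def design_assays(
    alleles: LocusAlleles,
    panel: Sequence[RestrictionEnzyme] = DEFAULT_ENZYME_PANEL,
    gel: GelConfig = GelConfig(),
    both_strands: bool = True,
) -> list[DiagnosticAssay]:
    """Digest both parental alleles with every enzyme and rank the assays.

    Returns one :class:`DiagnosticAssay` per enzyme, informative-first, ties
    broken by enzyme name. Diagnostic bands are computed by set difference
    under the co-migration comparator.
    """
    assays = []
    for enzyme in panel:
        mat = to_band_set(digest(alleles.maternal_allele, enzyme, both_strands), gel)
        pat = to_band_set(digest(alleles.paternal_allele, enzyme, both_strands), gel)
        assays.append(
            DiagnosticAssay(
                locus_id=alleles.locus_id,
                enzyme=enzyme,
                maternal_bands=mat,
                paternal_bands=pat,
                maternal_diagnostic=_diagnostic(mat, pat, gel.comigration_rel_tol),
                paternal_diagnostic=_diagnostic(pat, mat, gel.comigration_rel_tol),
                gel=gel,
            )
        )
    return sorted(assays, key=lambda a: (not a.informative, a.enzyme.name))


def band_sets_equal(a: GelBandSet, b: GelBandSet, rel_tol: float) -> bool:
    """Two lanes look identical iff their bands pair up under the comparator."""
    if len(a) != len(b):
        return False
    return all(bands_match(x, y, rel_tol) for x, y in zip(a.bands, b.bands))


GENOTYPE_STATES = ("additive", "maternal_only", "paternal_only")


def predict_polyploid_bands(assay: DiagnosticAssay, state: str) -> GelBandSet:
    """Expected lane of a polyploid in a given genotype state.

    ``additive`` merges the union of both parental band sets through the
    co-migration comparator; ``maternal_only`` / ``paternal_only`` return the
    corresponding parent's bands.
    """
    if state == "additive":
        merged = merge_comigrating(
            list(assay.maternal_bands.bands) + list(assay.paternal_bands.bands),
            assay.gel.comigration_rel_tol,
        )
        return GelBandSet(tuple(merged))
    if state == "maternal_only":
        return assay.maternal_bands
    if state == "paternal_only":
        return assay.paternal_bands
    raise ValueError(f"unknown genotype state {state!r}; expected one of {GENOTYPE_STATES}")


def read_enzyme_panel(path: str | Path) -> list[RestrictionEnzyme]:
    """Read an enzyme panel TSV with columns name, site, cut_offset."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"name", "site", "cut_offset"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: enzyme panel missing columns {sorted(missing)}")
    panel = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        if row.name in seen:
            raise ValueError(f"{path}: duplicate enzyme name {row.name!r}")
        seen.add(row.name)
        panel.append(RestrictionEnzyme(str(row.name), str(row.site), int(row.cut_offset)))
    return panel


def write_enzyme_panel(panel: Iterable[RestrictionEnzyme], path: str | Path) -> None:
    pd.DataFrame(
        [{"name": e.name, "site": e.site, "cut_offset": e.cut_offset} for e in panel]
    ).to_csv(path, sep="\t", index=False)


def _join_bands(bs: GelBandSet) -> str:
    return ",".join(str(b) for b in bs.bands)


def write_assay_report(assays: Iterable[DiagnosticAssay], path: str | Path) -> pd.DataFrame:
    """Assay report TSV: one row per locus × enzyme with band lists and informative flag."""
    df = pd.DataFrame(
        [
            {
                "locus_id": a.locus_id,
                "enzyme": a.enzyme.name,
                "maternal_bands": _join_bands(a.maternal_bands),
                "paternal_bands": _join_bands(a.paternal_bands),
                "maternal_diagnostic": _join_bands(a.maternal_diagnostic),
                "paternal_diagnostic": _join_bands(a.paternal_diagnostic),
                "informative": int(a.informative),
            }
            for a in assays
        ]
    )
    df.to_csv(path, sep="\t", index=False)
    return df
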