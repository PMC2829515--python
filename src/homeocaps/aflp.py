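"""cDNA-AFLP fragment scoring: presence/absence classification and summaries.

Transcript fingerprints over individuals of the two diploid parent species
and the allopolyploid are scored fragment by fragment: a fragment present in
every individual is *monomorphic*; anything else is *polymorphic*, subdivided
by where it appears — *novel* (polyploids only), *maternal_origin* (shared by
polyploids and maternal parents, absent from all paternal parents),
*paternal_origin* (symmetric), or *other* (everything else, e.g. fragments
absent from all polyploids). The subdivision partitions the polymorphic
fragments so counts always sum to the total.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .sequence_model import IndividualRecord, Role
from .stats import percent

__all__ = [
    "FragmentInfo",
    "FragmentMatrix",
    "MajorClass",
    "PolymorphicSubtype",
    "FragmentClass",
    "AFLPSummary",
    "classify_fragment",
    "summarize_matrix",
    "read_matrix",
    "write_matrix",
]


class MajorClass(str, enum.Enum):
    MONOMORPHIC = "monomorphic"
    POLYMORPHIC = "polymorphic"


class PolymorphicSubtype(str, enum.Enum):
    NOVEL = "novel"
    MATERNAL_ORIGIN = "maternal_origin"
    PATERNAL_ORIGIN = "paternal_origin"
    OTHER = "other"


@dataclass(frozen=True)
class FragmentClass:
    major: MajorClass
    subtype: PolymorphicSubtype | None = None

    def __post_init__(self) -> None:
        if self.major is MajorClass.MONOMORPHIC and self.subtype is not None:
            raise ValueError("monomorphic fragments carry no subtype")
        if self.major is MajorClass.POLYMORPHIC and self.subtype is None:
            raise ValueError("polymorphic fragments require a subtype")


@dataclass(frozen=True)
class FragmentInfo:
    fragment_id: str
    primer_pair: str = ""
    approx_size: int = 0


@dataclass
class FragmentMatrix:
    """Complete presence/absence grid: fragments × individuals of three roles."""

    fragments: list[FragmentInfo]
    individuals: list[IndividualRecord]
    presence: np.ndarray  # bool, shape (n_fragments, n_individuals)

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (len(self.fragments), len(self.individuals)):
            raise ValueError(
                f"presence grid shape {self.presence.shape} does not match "
                f"{len(self.fragments)} fragments x {len(self.individuals)} individuals"
            )
        roles = {i.role for i in self.individuals}
        needed = {Role.MATERNAL_PARENT, Role.PATERNAL_PARENT, Role.POLYPLOID}
        if not needed <= roles:
            raise ValueError(f"matrix must span roles {sorted(r.value for r in needed)}")

    @property
    def roles(self) -> list[Role]:
        return [i.role for i in self.individuals]


def classify_fragment(
    row: Sequence[bool], roles: Sequence[Role], require_all_polyploids: bool = False
) -> FragmentClass:
    """Score one fragment's presence vector against the individual roles.

    ``require_all_polyploids`` switches the shared-origin quantifier from
    "present in >=1 polyploid" (default) to "present in all polyploids".
    """
    row = np.asarray(row, dtype=bool)
    if len(row) != len(roles):
        raise ValueError("presence vector and role vector lengths differ")
    role_arr = np.asarray([Role(r).value for r in roles])
    for needed in (Role.MATERNAL_PARENT, Role.PATERNAL_PARENT, Role.POLYPLOID):
        if needed.value not in role_arr:
            raise ValueError(f"role {needed.value} missing from dataset")
    if row.all():
        return FragmentClass(MajorClass.MONOMORPHIC)
    in_poly = row[role_arr == Role.POLYPLOID.value]
    in_mat = row[role_arr == Role.MATERNAL_PARENT.value]
    in_pat = row[role_arr == Role.PATERNAL_PARENT.value]
    poly_hit = in_poly.all() if require_all_polyploids else in_poly.any()
    if poly_hit and not in_mat.any() and not in_pat.any():
        return FragmentClass(MajorClass.POLYMORPHIC, PolymorphicSubtype.NOVEL)
    if poly_hit and in_mat.any() and not in_pat.any():
        return FragmentClass(MajorClass.POLYMORPHIC, PolymorphicSubtype.MATERNAL_ORIGIN)
    if poly_hit and in_pat.any() and not in_mat.any():
        return FragmentClass(MajorClass.POLYMORPHIC, PolymorphicSubtype.PATERNAL_ORIGIN)
    return FragmentClass(MajorClass.POLYMORPHIC, PolymorphicSubtype.OTHER)


@dataclass(frozen=True)
class AFLPSummary:
    """Table-style tallies: per-class counts and percentages of the total."""

    total_fragments: int
    counts: dict[str, int]
    percentages: dict[str, float]
    decimals: int = 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": list(self.counts),
                "count": list(self.counts.values()),
                "percent": [self.percentages[k] for k in self.counts],
            }
        )


_CLASS_KEYS = ("monomorphic", "polymorphic", "novel", "maternal_origin", "paternal_origin", "other")


def summarize_matrix(
    m: FragmentMatrix, decimals: int = 1, require_all_polyploids: bool = False
) -> AFLPSummary:
    """Classify every fragment and tally counts and percentages of the total.

    Percentages are round-half-up to ``decimals`` places for display; counts
    are exact. ``novel + maternal_origin + paternal_origin + other ==
    polymorphic`` and ``monomorphic + polymorphic == total``.
    """
    if len(m.fragments) == 0:
        raise ValueError("cannot summarize an empty fragment matrix")
    counts = {k: 0 for k in _CLASS_KEYS}
    roles = m.roles
    for row in m.presence:
        fc = classify_fragment(row, roles, require_all_polyploids=require_all_polyploids)
        if fc.major is MajorClass.MONOMORPHIC:
            counts["monomorphic"] += 1
        else:
            counts["polymorphic"] += 1
            counts[fc.subtype.value] += 1
    total = len(m.fragments)
    percentages = {k: percent(v, total, decimals) for k, v in counts.items()}
    return AFLPSummary(total_fragments=total, counts=counts, percentages=percentages, decimals=decimals)


def read_matrix(path: str | Path, individuals: Sequence[IndividualRecord]) -> FragmentMatrix:
    """Read the fragment-matrix TSV.

    Layout: columns ``fragment_id``, ``primer_pair``, ``approx_size`` then one
    0/1 column per individual_id. Every individual column must be declared in
    the individuals table; cells must be exactly 0 or 1.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    meta_cols = ["fragment_id", "primer_pair", "approx_size"]
    missing = set(meta_cols) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: matrix missing columns {sorted(missing)}")
    ind_cols = [c for c in df.columns if c not in meta_cols]
    by_id = {i.individual_id: i for i in individuals}
    unknown = [c for c in ind_cols if c not in by_id]
    if unknown:
        raise ValueError(f"{path}: individuals not in individuals table: {unknown}")
    cells = df[ind_cols]
    bad = ~cells.isin(["0", "1"])
    if bad.any().any():
        r, c = next(zip(*np.nonzero(bad.values)))
        raise ValueError(
            f"{path}: non-binary cell {cells.iloc[r, c]!r} at fragment "
            f"{df['fragment_id'].iloc[r]!r}, individual {ind_cols[c]!r}"
        )
    fragments = [
        FragmentInfo(str(fid), str(pp), int(sz))
        for fid, pp, sz in zip(df["fragment_id"], df["primer_pair"], df["approx_size"])
    ]
    presence = cells.astype(int).to_numpy(dtype=bool)
    return FragmentMatrix(fragments=fragments, individuals=[by_id[c] for c in ind_cols], presence=presence)


def write_matrix(m: FragmentMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "fragment_id": [f.fragment_id for f in m.fragments],
            "primer_pair": [f.primer_pair for f in m.fragments],
            "approx_size": [f.approx_size for f in m.fragments],
        }
    )
    for j, ind in enumerate(m.individuals):
        df[ind.individual_id] = m.presence[:, j].astype(int)
    df.to_csv(path, sep="\t", index=False)
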