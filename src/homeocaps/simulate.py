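"""Ground-truthed synthetic allopolyploid CAPS/AFLP studies.

The generator emulates the design of a natural-allopolyploid resynthesis
survey: two diverged parental haplotypes per locus, a cohort of allotetraploid
individuals sampled from several populations that may each have lost one
parental homeolog per locus (with a paternal-biased loss rate) or silenced a
retained homeolog, F1 hybrids with zero loss and zero silencing, occasional
within-parent presence/absence polymorphism that renders a locus unscorable,
and noisy gel observations (band dropout and multiplicative size jitter).

Randomness uses one root seed with per-component substreams (alleles,
polymorphism, losses, silencing, noise, AFLP), so changing the noise settings
never perturbs the genotype truth.

Deterministic fixture builders (`fixture_from_counts` and friends) construct
datasets whose classification by the real pipeline reproduces requested
tallies exactly; they are used to replay printed study tables end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .aflp import FragmentInfo, FragmentMatrix
from .digest import (
    DEFAULT_ENZYME_PANEL,
    DiagnosticAssay,
    GelBandSet,
    GelConfig,
    RestrictionEnzyme,
    design_assays,
    merge_comigrating,
    predict_polyploid_bands,
    write_enzyme_panel,
)
from .genotyping import ObservedPattern, Tier, write_observations
from .sequence_model import (
    IndividualRecord,
    LocusAlleles,
    NucleotideSequence,
    Role,
    write_fasta,
    write_individuals,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticDataset",
    "simulate_parental_alleles",
    "simulate_cohort",
    "simulate_aflp_matrix",
    "fixture_from_counts",
    "aflp_fixture_from_counts",
    "caps_fixture_from_counts",
]

_BASES = np.array(list("ACGT"))

# population names follow the study's sampling sites
_DEFAULT_POPULATIONS = (
    "Pullman-1", "Pullman-2", "Palouse", "Oakesdale", "Rosalia", "Tekoa", "Arizona",
)

_STREAMS = {"alleles": 0, "polymorphism": 1, "losses": 2, "silencing": 3, "noise": 4, "aflp": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],)))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror the surveyed design: 30 loci assayed over 40 allotetraploid
    individuals from seven populations, ten sampled individuals of each diploid
    parent, mildly paternal-biased per-individual per-locus loss probabilities,
    rare conditional silencing, and occasional within-parent polymorphism.
    """

    seed: int = 0
    n_loci: int = 30
    locus_length: int = 600
    divergence: float = 0.03
    n_polyploids: int = 40
    n_maternal_parents: int = 10
    n_paternal_parents: int = 10
    n_f1: int = 0
    populations: tuple[str, ...] = _DEFAULT_POPULATIONS
    loss_prob_paternal: float = 0.005
    loss_prob_maternal: float = 0.003
    silencing_prob: float = 0.001
    parental_polymorphism_prob: float = 0.03
    band_dropout_prob: float = 0.01
    size_jitter_rel: float = 0.01
    enzyme_panel: tuple[RestrictionEnzyme, ...] = DEFAULT_ENZYME_PANEL
    gel: GelConfig = field(default_factory=GelConfig)

    def __post_init__(self) -> None:
        for name in (
            "divergence",
            "loss_prob_paternal",
            "loss_prob_maternal",
            "silencing_prob",
            "parental_polymorphism_prob",
            "band_dropout_prob",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.size_jitter_rel < 0:
            raise ValueError("size_jitter_rel must be >= 0")
        if self.n_loci < 0 or self.locus_length < 1:
            raise ValueError("n_loci must be >= 0 and locus_length >= 1")


@dataclass
class GroundTruth:
    """True per (individual, locus) genotype state and silenced retained homeologs."""

    genotype_state: dict[tuple[str, str], str] = field(default_factory=dict)
    silenced: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)

    def retained_parents(self, key: tuple[str, str]) -> frozenset[str]:
        state = self.genotype_state[key]
        return {
            "additive": frozenset({"maternal", "paternal"}),
            "maternal_only": frozenset({"maternal"}),
            "paternal_only": frozenset({"paternal"}),
        }[state]

    def expressed_parents(self, key: tuple[str, str]) -> frozenset[str]:
        return self.retained_parents(key) - self.silenced.get(key, frozenset())


@dataclass
class SyntheticDataset:
    """A complete simulated study bound to its ground truth."""

    config: SimulationConfig
    alleles: list[LocusAlleles]
    assays: dict[str, DiagnosticAssay]
    individuals: list[IndividualRecord]
    observations: list[ObservedPattern]
    truth: GroundTruth
    polymorphic_loci: frozenset[str] = frozenset()
    suppressed_double_losses: tuple[tuple[str, str], ...] = ()

    @property
    def informative_loci(self) -> list[str]:
        return [lid for lid, a in self.assays.items() if a.informative]

    def write(self, outdir: str | Path) -> None:
        """Emit the dataset in the same FASTA/TSV formats the pipeline consumes."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        seqs = []
        for la in self.alleles:
            seqs.extend([la.maternal_allele, la.paternal_allele])
        write_fasta(seqs, outdir / "alleles.fasta")
        write_individuals(self.individuals, outdir / "individuals.tsv")
        write_observations(self.observations, outdir / "observations.tsv")
        write_enzyme_panel(self.config.enzyme_panel, outdir / "enzymes.tsv")
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write("individual_id\tlocus_id\tgenotype_state\tsilenced_parents\n")
            for (ind, locus), state in sorted(self.truth.genotype_state.items()):
                silenced = ",".join(sorted(self.truth.silenced.get((ind, locus), ())))
                fh.write(f"{ind}\t{locus}\t{state}\t{silenced}\n")


def simulate_parental_alleles(cfg: SimulationConfig) -> list[LocusAlleles]:
    """Draw diverged parental allele pairs.

    The maternal allele is uniform over A/C/G/T; the paternal allele applies
    an independent per-site substitution at rate ``cfg.divergence``, choosing
    uniformly among the three alternative bases. Alleles are equal length, so
    downstream positional comparison needs no alignment.
    """
    rng = _rng(cfg.seed, "alleles")
    out = []
    for i in range(cfg.n_loci):
        locus_id = f"L{i + 1:03d}"
        mat_idx = rng.integers(0, 4, size=cfg.locus_length)
        mat = "".join(_BASES[mat_idx])
        sub = rng.random(cfg.locus_length) < cfg.divergence
        shift = rng.integers(1, 4, size=cfg.locus_length)
        pat_idx = np.where(sub, (mat_idx + shift) % 4, mat_idx)
        pat = "".join(_BASES[pat_idx])
        out.append(
            LocusAlleles(
                locus_id=locus_id,
                maternal_allele=NucleotideSequence(
                    f"{locus_id}_mat", mat, Role.MATERNAL_PARENT, "T. porrifolius"
                ),
                paternal_allele=NucleotideSequence(
                    f"{locus_id}_pat", pat, Role.PATERNAL_PARENT, "T. dubius"
                ),
            )
        )
    return out


def _make_individuals(cfg: SimulationConfig) -> list[IndividualRecord]:
    inds = []
    pops = cfg.populations or ("pop-1",)
    for i in range(cfg.n_polyploids):
        inds.append(
            IndividualRecord(f"tm-{i + 1:03d}", pops[i % len(pops)], Role.POLYPLOID, "T. mirus")
        )
    for i in range(cfg.n_f1):
        inds.append(IndividualRecord(f"f1-{i + 1:03d}", "F1-cross", Role.F1_HYBRID, "F1 hybrid"))
    for i in range(cfg.n_maternal_parents):
        inds.append(
            IndividualRecord(
                f"tpo-{i + 1:03d}", pops[i % len(pops)], Role.MATERNAL_PARENT, "T. porrifolius"
            )
        )
    for i in range(cfg.n_paternal_parents):
        inds.append(
            IndividualRecord(
                f"tdu-{i + 1:03d}", pops[i % len(pops)], Role.PATERNAL_PARENT, "T. dubius"
            )
        )
    return inds


def _apply_noise(
    bands: GelBandSet, rng: np.random.Generator, cfg: SimulationConfig
) -> GelBandSet:
    """Band dropout + multiplicative size jitter, then re-filter/merge on the gel."""
    jittered = []
    for b in bands.bands:
        if rng.random() < cfg.band_dropout_prob:
            continue
        if cfg.size_jitter_rel > 0:
            b = b * rng.uniform(1 - cfg.size_jitter_rel, 1 + cfg.size_jitter_rel)
        jittered.append(b)
    visible = [b for b in jittered if b >= cfg.gel.min_detectable_bp]
    return GelBandSet(tuple(merge_comigrating(visible, cfg.gel.comigration_rel_tol)))


def _merged_union(assay: DiagnosticAssay, parents: frozenset[str]) -> GelBandSet:
    lengths: list[int] = []
    if "maternal" in parents:
        lengths += list(assay.maternal_bands.bands)
    if "paternal" in parents:
        lengths += list(assay.paternal_bands.bands)
    return GelBandSet(tuple(merge_comigrating(lengths, assay.gel.comigration_rel_tol)))


def simulate_cohort(
    cfg: SimulationConfig, alleles: Sequence[LocusAlleles] | None = None
) -> SyntheticDataset:
    """Simulate the full study: truth, assays and noisy band observations.

    Per polyploid individual × locus the paternal homeolog is dropped with
    ``loss_prob_paternal`` and the maternal with ``loss_prob_maternal``; if
    both fire the (later-drawn) maternal event is suppressed and logged, since
    an individual lacking both homeologs would not amplify at all. Silencing
    is drawn per retained homeolog. F1 hybrids never lose or silence. Parent
    lanes are emitted noise-free (they are the reference patterns); polyploid
    and F1 lanes pass through the dropout/jitter noise model. cDNA lanes show
    only retained-and-expressed homeologs.
    """
    if alleles is None:
        alleles = simulate_parental_alleles(cfg)
    assays: dict[str, DiagnosticAssay] = {}
    for la in alleles:
        ranked = design_assays(la, cfg.enzyme_panel, cfg.gel)
        if ranked:
            assays[la.locus_id] = ranked[0]
    individuals = _make_individuals(cfg)
    poly_rng = _rng(cfg.seed, "polymorphism")
    loss_rng = _rng(cfg.seed, "losses")
    sil_rng = _rng(cfg.seed, "silencing")
    noise_rng = _rng(cfg.seed, "noise")

    polymorphic = set()
    poly_parent_extra: dict[str, set[str]] = {}
    paternal_parents = [i for i in individuals if i.role is Role.PATERNAL_PARENT]
    for la in alleles:
        if poly_rng.random() < cfg.parental_polymorphism_prob and paternal_parents:
            polymorphic.add(la.locus_id)
            # >=1 (but never all) paternal-parent individuals carry an extra
            # maternal-type amplicon, so the two pattern classes are observable
            k = 1 + int(poly_rng.integers(0, max(1, len(paternal_parents) - 1)))
            chosen = poly_rng.choice(len(paternal_parents), size=min(k, len(paternal_parents)), replace=False)
            poly_parent_extra[la.locus_id] = {paternal_parents[j].individual_id for j in chosen}

    truth = GroundTruth()
    suppressed: list[tuple[str, str]] = []
    cohort = [i for i in individuals if i.role in (Role.POLYPLOID, Role.F1_HYBRID)]
    for ind in cohort:
        is_f1 = ind.role is Role.F1_HYBRID
        for la in alleles:
            key = (ind.individual_id, la.locus_id)
            lose_pat = (not is_f1) and loss_rng.random() < cfg.loss_prob_paternal
            lose_mat = (not is_f1) and loss_rng.random() < cfg.loss_prob_maternal
            if lose_pat and lose_mat:
                lose_mat = False
                suppressed.append(key)
            state = "maternal_only" if lose_pat else ("paternal_only" if lose_mat else "additive")
            truth.genotype_state[key] = state
            retained = truth.retained_parents(key)
            silenced = frozenset(
                p for p in sorted(retained) if (not is_f1) and sil_rng.random() < cfg.silencing_prob
            )
            truth.silenced[key] = silenced

    observations: list[ObservedPattern] = []
    for la in alleles:
        assay = assays.get(la.locus_id)
        if assay is None:
            continue
        extra = poly_parent_extra.get(la.locus_id, set())
        for ind in individuals:
            if ind.role is Role.MATERNAL_PARENT:
                observations.append(
                    ObservedPattern(ind.individual_id, la.locus_id, Tier.GENOMIC, assay.maternal_bands)
                )
            elif ind.role is Role.PATERNAL_PARENT:
                bands = (
                    _merged_union(assay, frozenset({"maternal", "paternal"}))
                    if ind.individual_id in extra
                    else assay.paternal_bands
                )
                observations.append(
                    ObservedPattern(ind.individual_id, la.locus_id, Tier.GENOMIC, bands)
                )
            else:
                key = (ind.individual_id, la.locus_id)
                genomic = predict_polyploid_bands(assay, truth.genotype_state[key])
                cdna = _merged_union(assay, truth.expressed_parents(key))
                observations.append(
                    ObservedPattern(
                        ind.individual_id, la.locus_id, Tier.GENOMIC,
                        _apply_noise(genomic, noise_rng, cfg),
                    )
                )
                observations.append(
                    ObservedPattern(
                        ind.individual_id, la.locus_id, Tier.CDNA,
                        _apply_noise(cdna, noise_rng, cfg),
                    )
                )
    return SyntheticDataset(
        config=cfg,
        alleles=list(alleles),
        assays=assays,
        individuals=individuals,
        observations=observations,
        truth=truth,
        polymorphic_loci=frozenset(polymorphic),
        suppressed_double_losses=tuple(suppressed),
    )


# ---------------------------------------------------------------------------
# AFLP simulation
# ---------------------------------------------------------------------------

DEFAULT_AFLP_CLASS_FREQS = {
    "monomorphic": 0.35,
    "novel": 0.004,
    "maternal_origin": 0.05,
    "paternal_origin": 0.035,
    "other": 0.561,
}


def _aflp_individuals(n_polyploid: int, n_maternal: int, n_paternal: int) -> list[IndividualRecord]:
    inds = [
        IndividualRecord(f"tm-{i + 1:03d}", "Pullman-1", Role.POLYPLOID, "T. mirus")
        for i in range(n_polyploid)
    ]
    inds += [
        IndividualRecord(f"tpo-{i + 1:03d}", "Pullman-1", Role.MATERNAL_PARENT, "T. porrifolius")
        for i in range(n_maternal)
    ]
    inds += [
        IndividualRecord(f"tdu-{i + 1:03d}", "Pullman-1", Role.PATERNAL_PARENT, "T. dubius")
        for i in range(n_paternal)
    ]
    return inds


def simulate_aflp_matrix(
    n_fragments: int = 1440,
    class_freqs: dict[str, float] | None = None,
    n_polyploid: int = 20,
    n_maternal: int = 20,
    n_paternal: int = 16,
    seed: int = 0,
) -> FragmentMatrix:
    """Draw a presence/absence fragment matrix from configured class frequencies.

    Each fragment's class is sampled, then a presence row consistent with that
    class is filled in (random nonempty subsets of the relevant roles).
    """
    freqs = dict(DEFAULT_AFLP_CLASS_FREQS if class_freqs is None else class_freqs)
    total = sum(freqs.values())
    if total <= 0:
        raise ValueError("class frequencies must sum to a positive value")
    keys = sorted(freqs)
    p = np.array([freqs[k] / total for k in keys])
    rng = _rng(seed, "aflp")
    individuals = _aflp_individuals(n_polyploid, n_maternal, n_paternal)
    n = len(individuals)
    poly = slice(0, n_polyploid)
    mat = slice(n_polyploid, n_polyploid + n_maternal)
    pat = slice(n_polyploid + n_maternal, n)
    rows = np.zeros((n_fragments, n), dtype=bool)
    classes = rng.choice(len(keys), size=n_fragments, p=p)

    def nonempty_subset(size: int) -> np.ndarray:
        mask = rng.random(size) < 0.5
        if not mask.any():
            mask[int(rng.integers(0, size))] = True
        return mask

    for i, ci in enumerate(classes):
        cls = keys[ci]
        if cls == "monomorphic":
            rows[i, :] = True
        elif cls == "novel":
            rows[i, poly] = nonempty_subset(n_polyploid)
        elif cls == "maternal_origin":
            rows[i, poly] = nonempty_subset(n_polyploid)
            rows[i, mat] = nonempty_subset(n_maternal)
        elif cls == "paternal_origin":
            rows[i, poly] = nonempty_subset(n_polyploid)
            rows[i, pat] = nonempty_subset(n_paternal)
        elif cls == "other":
            # parents-only fragment: absent from every polyploid
            rows[i, mat] = nonempty_subset(n_maternal)
            rows[i, pat] = nonempty_subset(n_paternal)
        else:
            raise ValueError(f"unknown AFLP class {cls!r}")
    fragments = [FragmentInfo(f"frag-{i + 1:05d}", "E-AA/M-CTT", 100 + (i % 400)) for i in range(n_fragments)]
    return FragmentMatrix(fragments=fragments, individuals=individuals, presence=rows)


# ---------------------------------------------------------------------------
# Deterministic fixtures from named tallies
# ---------------------------------------------------------------------------


def aflp_fixture_from_counts(
    total: int,
    monomorphic: int,
    novel: int = 0,
    maternal: int = 0,
    paternal: int = 0,
    n_polyploid: int = 5,
    n_maternal: int = 5,
    n_paternal: int = 5,
) -> FragmentMatrix:
    """Deterministic fragment matrix reproducing the requested class counts.

    Remaining (total − named) fragments are "other" polymorphic rows present
    only in the parent individuals, so the classifier's partition reproduces
    the requested tallies exactly.
    """
    named = monomorphic + novel + maternal + paternal
    if named > total:
        raise ValueError(
            f"inconsistent tallies: monomorphic+novel+maternal+paternal = {named} > total = {total}"
        )
    if min(total, monomorphic, novel, maternal, paternal) < 0:
        raise ValueError("tallies must be nonnegative")
    individuals = _aflp_individuals(n_polyploid, n_maternal, n_paternal)
    n = len(individuals)
    rows = np.zeros((total, n), dtype=bool)
    poly = slice(0, n_polyploid)
    mat = slice(n_polyploid, n_polyploid + n_maternal)
    pat = slice(n_polyploid + n_maternal, n)
    i = 0
    for _ in range(monomorphic):
        rows[i, :] = True
        i += 1
    for _ in range(novel):
        rows[i, poly] = True
        i += 1
    for _ in range(maternal):
        rows[i, poly] = True
        rows[i, mat] = True
        i += 1
    for _ in range(paternal):
        rows[i, poly] = True
        rows[i, pat] = True
        i += 1
    while i < total:
        rows[i, mat] = True
        rows[i, pat] = True
        i += 1
    fragments = [FragmentInfo(f"frag-{k + 1:05d}", "E-AA/M-CTT", 250) for k in range(total)]
    return FragmentMatrix(fragments=fragments, individuals=individuals, presence=rows)


def _fixture_alleles(locus_id: str) -> LocusAlleles:
    """A 200-bp allele pair whose only difference destroys the paternal EcoRI site.

    Maternal digests to {139, 61}; paternal stays {200}: both parents carry
    diagnostic bands, so a single-enzyme EcoRI assay is informative.
    """
    backbone = "AC" * 100
    mat = backbone[:60] + "GAATTC" + backbone[66:]
    pat = backbone[:60] + "GACTTC" + backbone[66:]
    return LocusAlleles(
        locus_id=locus_id,
        maternal_allele=NucleotideSequence(f"{locus_id}_mat", mat, Role.MATERNAL_PARENT, "T. porrifolius"),
        paternal_allele=NucleotideSequence(f"{locus_id}_pat", pat, Role.PATERNAL_PARENT, "T. dubius"),
    )


def caps_fixture_from_counts(
    genes: int = 30,
    loss_genes: int = 9,
    excluded_genes: int = 1,
    paternal_loss_genes: int = 7,
    maternal_loss_genes: int = 4,
    silenced_genes: int = 2,
    n_polyploids: int = 10,
    n_maternal: int = 5,
    n_paternal: int = 5,
) -> SyntheticDataset:
    """Deterministic CAPS study reproducing requested gene-level tallies.

    Loss genes are split so that per-parent gene counts come out exactly:
    ``both = paternal + maternal − loss_genes`` genes lose each homeolog in a
    different individual, the rest lose only one parent. One polyploid
    individual is silenced (maternal homeolog) at each of the first
    ``silenced_genes`` additive genes. Excluded genes show two band-pattern
    classes among the paternal-parent individuals.
    """
    both = paternal_loss_genes + maternal_loss_genes - loss_genes
    paternal_only = paternal_loss_genes - both
    maternal_only = maternal_loss_genes - both
    if min(both, paternal_only, maternal_only) < 0:
        raise ValueError(
            "inconsistent tallies: paternal_loss_genes + maternal_loss_genes must lie in "
            f"[loss_genes, 2*loss_genes]; got {paternal_loss_genes}+{maternal_loss_genes} "
            f"vs loss_genes={loss_genes}"
        )
    if loss_genes + excluded_genes > genes:
        raise ValueError(
            f"inconsistent tallies: loss_genes + excluded_genes = {loss_genes + excluded_genes} > genes = {genes}"
        )
    additive_genes = genes - loss_genes - excluded_genes
    if silenced_genes > additive_genes:
        raise ValueError(
            f"inconsistent tallies: silenced_genes = {silenced_genes} > additive genes = {additive_genes}"
        )
    if n_polyploids < 2:
        raise ValueError("need >=2 polyploid individuals to place both-parent losses")

    cfg = SimulationConfig(
        n_loci=genes,
        n_polyploids=n_polyploids,
        n_maternal_parents=n_maternal,
        n_paternal_parents=n_paternal,
        enzyme_panel=(RestrictionEnzyme("EcoRI", "GAATTC", 1),),
        loss_prob_paternal=0.0,
        loss_prob_maternal=0.0,
        silencing_prob=0.0,
        parental_polymorphism_prob=0.0,
        band_dropout_prob=0.0,
        size_jitter_rel=0.0,
        locus_length=200,
    )
    alleles = [_fixture_alleles(f"L{i + 1:03d}") for i in range(genes)]
    assays = {la.locus_id: design_assays(la, cfg.enzyme_panel, cfg.gel)[0] for la in alleles}
    individuals = _make_individuals(cfg)
    polyploids = [i for i in individuals if i.role is Role.POLYPLOID]
    paternal_parents = [i for i in individuals if i.role is Role.PATERNAL_PARENT]

    # per-locus plan: list of (individual, lost parent); silencing plan per locus
    plan: dict[str, list[tuple[str, str]]] = {}
    silenced_plan: dict[str, str] = {}
    polymorphic: set[str] = set()
    idx = 0
    for _ in range(both):
        lid = alleles[idx].locus_id
        plan[lid] = [(polyploids[0].individual_id, "paternal"), (polyploids[1].individual_id, "maternal")]
        idx += 1
    for _ in range(paternal_only):
        plan[alleles[idx].locus_id] = [(polyploids[0].individual_id, "paternal")]
        idx += 1
    for _ in range(maternal_only):
        plan[alleles[idx].locus_id] = [(polyploids[0].individual_id, "maternal")]
        idx += 1
    for _ in range(excluded_genes):
        polymorphic.add(alleles[idx].locus_id)
        idx += 1
    for _ in range(silenced_genes):
        silenced_plan[alleles[idx].locus_id] = polyploids[0].individual_id
        idx += 1

    truth = GroundTruth()
    observations: list[ObservedPattern] = []
    for la in alleles:
        assay = assays[la.locus_id]
        lost_here = dict(plan.get(la.locus_id, []))
        for ind in individuals:
            if ind.role is Role.MATERNAL_PARENT:
                observations.append(
                    ObservedPattern(ind.individual_id, la.locus_id, Tier.GENOMIC, assay.maternal_bands)
                )
                continue
            if ind.role is Role.PATERNAL_PARENT:
                extra = la.locus_id in polymorphic and ind.individual_id == paternal_parents[0].individual_id
                bands = (
                    _merged_union(assay, frozenset({"maternal", "paternal"}))
                    if extra
                    else assay.paternal_bands
                )
                observations.append(
                    ObservedPattern(ind.individual_id, la.locus_id, Tier.GENOMIC, bands)
                )
                continue
            key = (ind.individual_id, la.locus_id)
            lost = lost_here.get(ind.individual_id)
            state = {"paternal": "maternal_only", "maternal": "paternal_only", None: "additive"}[lost]
            truth.genotype_state[key] = state
            silenced = (
                frozenset({"maternal"})
                if silenced_plan.get(la.locus_id) == ind.individual_id
                else frozenset()
            )
            truth.silenced[key] = silenced
            genomic = predict_polyploid_bands(assay, state)
            cdna = _merged_union(assay, truth.expressed_parents(key))
            observations.append(ObservedPattern(ind.individual_id, la.locus_id, Tier.GENOMIC, genomic))
            observations.append(ObservedPattern(ind.individual_id, la.locus_id, Tier.CDNA, cdna))

    return SyntheticDataset(
        config=cfg,
        alleles=alleles,
        assays=assays,
        individuals=individuals,
        observations=observations,
        truth=truth,
        polymorphic_loci=frozenset(polymorphic),
    )


def fixture_from_counts(**tallies) -> FragmentMatrix | SyntheticDataset:
    """Dispatch on tally names: fragment counts build an AFLP matrix, gene counts a CAPS study."""
    if "total" in tallies:
        return aflp_fixture_from_counts(**tallies)
    if "genes" in tallies:
        return caps_fixture_from_counts(**tallies)
    raise ValueError("tallies must include either 'total' (AFLP) or 'genes' (CAPS)")
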