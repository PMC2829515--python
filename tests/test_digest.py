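import pytest
from hypothesis import given
from hypothesis import strategies as st

from homeocaps.sequence_model import (
    AlphabetError,
    IUPAC_SETS,
    LocusAlleles,
    NucleotideSequence,
    Role,
    reverse_complement,
)
from homeocaps.digest import (
    DEFAULT_ENZYME_PANEL,
    DigestPattern,
    GelBandSet,
    GelConfig,
    RestrictionEnzyme,
    bands_match,
    design_assays,
    digest,
    find_cut_sites,
    predict_polyploid_bands,
    to_band_set,
)

ECORI = RestrictionEnzyme("EcoRI", "GAATTC", 1)
HINFI = RestrictionEnzyme("HinfI", "GANTC", 1)


def seq(residues, seq_id="s", role=Role.POLYPLOID):
    return NucleotideSequence(seq_id, residues, role)


def brute_force_cut_sites(residues: str, enzyme: RestrictionEnzyme, both_strands: bool = True):
    """Independent oracle: check every window character by character.

    A duplex site exists at window start s if the window matches the site on
    the top strand, or (both_strands) the window's reverse complement matches
    the site read 5'->3' on the bottom strand. Top-strand hits cut at
    s + offset; bottom-only hits at s + len(site) - offset.
    """
    m = len(enzyme.site)
    cuts = set()
    for s in range(len(residues) - m + 1):
        window = residues[s : s + m]
        top = all(window[j] in IUPAC_SETS[enzyme.site[j]] for j in range(m))
        if top:
            cuts.add(s + enzyme.cut_offset)
        elif both_strands:
            rc_window = reverse_complement(window)
            if all(rc_window[j] in IUPAC_SETS[enzyme.site[j]] for j in range(m)):
                cuts.add(s + m - enzyme.cut_offset)
    return sorted(c for c in cuts if 0 < c < len(residues))


class TestFindCutSites:
    def test_ecori_example(self):
        assert find_cut_sites(seq("AAGAATTCAA"), ECORI) == [3]

    def test_no_site(self):
        assert find_cut_sites(seq("AAAAAAAA"), ECORI) == []

    def test_degenerate_site(self):
        assert find_cut_sites(seq("GGGACTCGG"), HINFI) == [3]

    def test_bottom_strand_only_site(self):
        # GGATG is the reverse complement of CATCC; site CATCC with offset 1
        enz = RestrictionEnzyme("FauI-like", "CATCC", 1)
        s = seq("AAAGGATGAAA")
        # bottom-strand site at top window [3, 8); cut at 3 + 5 - 1 = 7
        assert find_cut_sites(s, enz) == [7]
        assert find_cut_sites(s, enz, both_strands=False) == []

    def test_boundary_cuts_discarded(self):
        # site at the very start with offset 0 would cut at position 0
        enz = RestrictionEnzyme("blunt0", "GAATTC", 0)
        assert find_cut_sites(seq("GAATTCAA"), enz, both_strands=False) == []

    def test_degenerate_substrate_rejected(self):
        with pytest.raises(AlphabetError, match="concrete"):
            find_cut_sites(seq("GANTTC"), ECORI)


@st.composite
def random_enzyme(draw):
    site = draw(st.text(alphabet="ACGTRYN", min_size=4, max_size=6))
    offset = draw(st.integers(0, len(site)))
    return RestrictionEnzyme("rand", site, offset)


class TestDigest:
    def test_single_cut(self):
        assert digest(seq("AAGAATTCAA"), ECORI).fragment_lengths == (7, 3)

    def test_uncut_identity(self):
        assert digest(seq("A" * 200), ECORI).fragment_lengths == (200,)

    def test_two_cuts_interval_arithmetic(self):
        # HinfI top-strand sites in a constructed 10-mer are at 2 and 5
        s = seq("AAGAGTCTCA")  # GAGTC at 2, cut 3; ...
        cuts = find_cut_sites(s, HINFI)
        frags = digest(s, HINFI).fragment_lengths
        assert sum(frags) == 10
        assert len(frags) == len(cuts) + 1

    @given(
        st.text(alphabet="ACGT", min_size=1, max_size=500),
        random_enzyme(),
        st.booleans(),
    )
    def test_conservation_and_oracle_equivalence(self, residues, enzyme, both):
        s = seq(residues)
        cuts = find_cut_sites(s, enzyme, both_strands=both)
        assert cuts == brute_force_cut_sites(residues, enzyme, both_strands=both)
        frags = digest(s, enzyme, both_strands=both).fragment_lengths
        assert sum(frags) == len(residues)
        assert len(frags) == len(cuts) + 1


class TestGelBands:
    def test_small_fragments_dropped(self, gel):
        assert to_band_set(DigestPattern((300, 200, 30)), gel).bands == (300, 200)

    def test_comigration_merge(self, gel):
        assert to_band_set(DigestPattern((205, 200)), gel).bands == (205,)

    def test_singleton(self, gel):
        assert to_band_set(DigestPattern((500,)), gel).bands == (500,)

    def test_all_filtered_is_legal(self, gel):
        assert to_band_set(DigestPattern((20, 10)), gel).bands == ()

    @given(st.lists(st.integers(1, 2000), min_size=0, max_size=30), st.integers(1, 300))
    def test_raising_detection_floor_never_adds_bands(self, lengths, floor):
        lo = to_band_set(lengths, GelConfig(min_detectable_bp=floor))
        hi = to_band_set(lengths, GelConfig(min_detectable_bp=floor + 50))
        assert set(hi.bands) <= set(lo.bands)

    def test_bands_match_relative_tolerance(self):
        assert bands_match(205, 200, 0.05)
        assert not bands_match(300, 200, 0.05)


def make_locus(mat_residues, pat_residues, locus_id="L1"):
    return LocusAlleles(
        locus_id,
        NucleotideSequence(f"{locus_id}_m", mat_residues, Role.MATERNAL_PARENT),
        NucleotideSequence(f"{locus_id}_p", pat_residues, Role.PATERNAL_PARENT),
    )


@pytest.fixture
def snp_locus():
    """200-bp locus; the paternal allele's single substitution destroys the only EcoRI site."""
    backbone = "AC" * 100
    mat = backbone[:118] + "GAATTC" + backbone[124:]
    pat = backbone[:118] + "GACTTC" + backbone[124:]
    return make_locus(mat, pat)


class TestDesignAssays:
    def test_site_destroying_snp_is_informative(self, snp_locus, gel):
        assays = design_assays(snp_locus, [ECORI], gel)
        (a,) = assays
        assert a.informative
        assert a.maternal_bands.bands == (119, 81)
        assert a.paternal_bands.bands == (200,)
        assert a.maternal_diagnostic.bands == (119, 81)
        assert a.paternal_diagnostic.bands == (200,)

    def test_identical_alleles_never_informative(self, gel):
        locus = make_locus("ACGT" * 100, "ACGT" * 100)
        assert not any(a.informative for a in design_assays(locus, DEFAULT_ENZYME_PANEL, gel))

    def test_shared_band_after_filtering_uninformative(self):
        # parents differ only in sub-threshold fragments (49 vs 45 bp) and in
        # large fragments that co-migrate (151 vs 155): nothing diagnostic remains
        gel = GelConfig(min_detectable_bp=60)
        backbone = "AC" * 100
        mat = backbone[:48] + "GAATTC" + backbone[54:]
        pat = backbone[:44] + "GAATTC" + backbone[50:]
        locus = make_locus(mat, pat)
        (a,) = design_assays(locus, [ECORI], gel)
        assert a.maternal_bands.bands == (151,)
        assert a.paternal_bands.bands == (155,)
        assert not a.informative

    def test_empty_panel(self, snp_locus, gel):
        assert design_assays(snp_locus, [], gel) == []

    def test_informative_sorted_first(self, snp_locus, gel):
        assays = design_assays(snp_locus, DEFAULT_ENZYME_PANEL, gel)
        flags = [a.informative for a in assays]
        assert flags == sorted(flags, reverse=True)


class TestPredictPolyploidBands:
    def test_additive_union(self, simple_assay):
        assert predict_polyploid_bands(simple_assay, "additive").bands == (200, 120, 80)

    def test_paternal_only(self, simple_assay):
        assert predict_polyploid_bands(simple_assay, "paternal_only").bands == (200,)

    def test_additive_union_merges_comigrating(self, gel):
        from homeocaps.digest import DiagnosticAssay

        assay = DiagnosticAssay(
            "L1", ECORI, GelBandSet((200,)), GelBandSet((205,)),
            GelBandSet((200,)), GelBandSet((205,)), gel,
        )
        assert predict_polyploid_bands(assay, "additive").bands == (205,)

    def test_unknown_state_rejected(self, simple_assay):
        with pytest.raises(ValueError, match="unknown genotype state"):
            predict_polyploid_bands(simple_assay, "triploid")

    def test_additive_superset_of_each_parent(self, simple_assay):
        union = predict_polyploid_bands(simple_assay, "additive")
        tol = simple_assay.gel.comigration_rel_tol
        for parent_bands in (simple_assay.maternal_bands, simple_assay.paternal_bands):
            assert all(union.contains(b, tol) for b in parent_bands.bands)
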