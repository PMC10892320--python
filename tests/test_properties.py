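"""Property-group site calling, region detection, sequons, hydropathy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gamoscan.codec import AMINO_ACIDS, SequenceRecord
from gamoscan.properties import (
    PropertyScheme,
    RegionParams,
    SequonSet,
    SiteClassification,
    call_cross_boundary_sites,
    classify_column,
    detect_regions,
    hydropathy_profile,
    kyte_doolittle_scale,
    scan_sequons,
)

from tests.conftest import make_msa

SCHEME = PropertyScheme.miyata()


class TestPropertyScheme:
    def test_six_groups_cover_all_amino_acids(self):
        assert SCHEME.n_groups == 6
        assert set(SCHEME.group_of) == set(AMINO_ACIDS)


class TestClassifyColumn:
    def test_uniform_column_not_flagged(self):
        msa = make_msa({"x_1": "M", "y_1": "M", "z_1": "M"})
        site = classify_column(msa, 0)
        assert not site.cross_boundary_flag

    def test_position135_pattern_flagged(self):
        # the observed four-species pattern A / Y / V / P at one column
        msa = make_msa(
            {"undulans_1": "A", "japonicum_1": "Y", "americanum_1": "V",
             "musculus_1": "P"}
        )
        site = classify_column(msa, 0)
        assert site.cross_boundary_flag
        groups = set(site.group_by_species.values())
        assert len(groups) >= 2

    def test_within_group_difference_not_flagged(self):
        # I and L share the aliphatic group; a species swap between them is
        # not a property change
        msa = make_msa({"x_1": "I", "y_1": "L"})
        assert not classify_column(msa, 0).cross_boundary_flag
        # forced by the group table: same holds for every within-group pair
        by_group = {}
        for aa, g in SCHEME.group_of.items():
            by_group.setdefault(g, []).append(aa)
        for g, aas in by_group.items():
            if len(aas) < 2:
                continue
            msa = make_msa({"x_1": aas[0], "y_1": aas[1]})
            assert not classify_column(msa, 0).cross_boundary_flag

    def test_duplicating_strain_does_not_change_flag(self):
        msa = make_msa({"x_1": "A", "y_1": "Y"})
        dup = make_msa({"x_1": "A", "x_2": "A", "y_1": "Y"})
        assert (
            classify_column(msa, 0).cross_boundary_flag
            == classify_column(dup, 0).cross_boundary_flag
        )

    def test_within_species_heterogeneity_ambiguous_under_strict(self):
        msa = make_msa({"x_1": "A", "x_2": "Y", "y_1": "A"})
        site = classify_column(msa, 0, majority_fraction=1.0)
        assert site.group_by_species["x"] == -1  # AMBIGUOUS
        assert not site.cross_boundary_flag
        relaxed = classify_column(msa, 0, majority_fraction=0.5)
        assert relaxed.group_by_species["x"] != -1

    def test_all_gap_column(self):
        msa = make_msa({"x_1": "-M", "y_1": "-M"})
        site = classify_column(msa, 0)
        assert site.reason == "all-gap" and not site.cross_boundary_flag


class TestCallSites:
    def test_identical_two_species_no_flags(self):
        msa = make_msa({"x_1": "MKWV", "y_1": "MKWV"})
        sites = call_cross_boundary_sites(msa)
        assert not any(s.cross_boundary_flag for s in sites)

    def test_single_species_raises(self):
        msa = make_msa({"x_1": "MK", "x_2": "MK"})
        with pytest.raises(ValueError, match="2 species"):
            call_cross_boundary_sites(msa)

    def test_row_order_invariance(self):
        rows = {"x_1": "AKWV", "y_1": "YKWV", "z_1": "VKWV"}
        flags = [s.cross_boundary_flag for s in call_cross_boundary_sites(make_msa(rows))]
        rev = dict(reversed(list(rows.items())))
        flags_rev = [s.cross_boundary_flag for s in call_cross_boundary_sites(make_msa(rev))]
        assert flags == flags_rev

    def test_species_removal_monotone(self):
        # dropping a species can never create a new flagged column
        rows = {"x_1": "AYIVA", "y_1": "YYIAA", "z_1": "VYIPG"}
        full = call_cross_boundary_sites(make_msa(rows))
        reduced = call_cross_boundary_sites(
            make_msa({k: v for k, v in rows.items() if not k.startswith("z")})
        )
        for s_full, s_red in zip(full, reduced):
            assert not (s_red.cross_boundary_flag and not s_full.cross_boundary_flag)


def _mk_sites(flags, start_ref=1):
    return [
        SiteClassification(column=i, ref_position=start_ref + i,
                           residues_by_species={}, group_by_species={},
                           cross_boundary_flag=bool(f))
        for i, f in enumerate(flags)
    ]


class TestDetectRegions:
    def test_no_flags_single_conserved_region(self):
        regions = detect_regions(_mk_sites([0] * 60))
        assert len(regions) == 1
        r = regions[0]
        assert (r.kind, r.start, r.end) == ("conserved", 1, 60)

    def test_mid_density_yields_nothing(self):
        # alternating flags: window density 0.5 sits between both thresholds
        regions = detect_regions(_mk_sites([1, 0] * 30),
                                 RegionParams(window=10, mutable_min_density=0.6,
                                              conserved_max_density=0.05))
        assert regions == []

    def test_planted_block_recovered(self):
        flags = [0] * 100 + [1] * 20 + [0] * 100
        regions = detect_regions(_mk_sites(flags))
        mutable = [r for r in regions if r.kind == "mutable"]
        assert len(mutable) == 1
        assert abs(mutable[0].start - 101) <= 5 and abs(mutable[0].end - 120) <= 5

    def test_regions_disjoint_and_sorted(self, rng):
        flags = (rng.random(400) < 0.25).astype(int)
        regions = detect_regions(_mk_sites(list(flags)))
        for kind in ("conserved", "mutable"):
            rs = [r for r in regions if r.kind == kind]
            for a, b in zip(rs, rs[1:]):
                assert a.end < b.start

    def test_window_longer_than_alignment_raises(self):
        with pytest.raises(ValueError):
            detect_regions(_mk_sites([0] * 5), RegionParams(window=10))


def _sequon_oracle(seq: str, exclude_p: bool = True) -> list[int]:
    out = []
    for i in range(len(seq) - 2):
        tri = seq[i : i + 3]
        if tri[0] == "N" and tri[2] in "ST" and not (exclude_p and tri[1] == "P"):
            out.append(i + 1)
    return out


class TestScanSequons:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("MNVSK", [2]),
            ("MNPSK", []),  # X != P rule
            ("", []),
            ("N", []),
            ("NVSNIT", [1, 4]),
        ],
    )
    def test_examples(self, seq, expected):
        assert scan_sequons(seq).sites == expected

    def test_proline_rule_toggle(self):
        assert scan_sequons("MNPSK", exclude_proline_x=False).sites == [2]

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.text(alphabet=AMINO_ACIDS, min_size=0, max_size=60))
    def test_matches_bruteforce_3mer_oracle(self, seq):
        assert scan_sequons(seq).sites == _sequon_oracle(seq)

    def test_gapped_input_raises(self):
        with pytest.raises(ValueError):
            scan_sequons("MN-SK")

    def test_sites_strictly_increasing_enforced(self):
        with pytest.raises(ValueError):
            SequonSet(sequence_id="x", sites=[5, 5])


class TestHydropathy:
    def test_constant_sequences(self):
        scale = kyte_doolittle_scale()
        poly_i = hydropathy_profile("I" * 21, window=9)
        assert np.allclose(poly_i.values, scale["I"])
        poly_r = hydropathy_profile("R" * 21, window=9)
        assert np.allclose(poly_r.values, scale["R"])
        assert (poly_i.values > poly_r.values).all()

    def test_moving_average_oracle(self):
        seq = "MKWVTFISLLFAGHE"
        scale = kyte_doolittle_scale()
        prof = hydropathy_profile(seq, window=5)
        assert len(prof.values) == 11
        for i in range(11):
            want = np.mean([scale[c] for c in seq[i : i + 5]])
            assert prof.values[i] == pytest.approx(want)

    def test_even_window_raises(self):
        with pytest.raises(ValueError):
            hydropathy_profile("MKWVTFISLL", window=4)

    def test_unknown_residue_excluded(self):
        prof = hydropathy_profile("IIXII", window=5)
        scale = kyte_doolittle_scale()
        assert prof.values[0] == pytest.approx(scale["I"])
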