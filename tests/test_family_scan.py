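"""Half-sex filter, association scan and inheritance classification."""

import numpy as np
import pytest

from sexscan.family_scan import (classify_inheritance, filter_half_sex_rule,
                                 site_association)
from sexscan.records import MISSING
from sexscan.simdata import FamilyDesign, simulate_family

from conftest import make_matrix


def family_frame(n_sons=15, n_daus=14):
    sexes = (["female", "male"]
             + ["male"] * n_sons + ["female"] * n_daus)
    roles = ["dam", "sire"] + ["offspring"] * (n_sons + n_daus)
    return sexes, roles


class TestHalfSexRule:
    def _matrix_with_called(self, called_males, called_females):
        """One site; control how many of 15 males / 14 females are called."""
        sexes, roles = family_frame()
        site = []
        m = f = 0
        for sex, role in zip(sexes, roles):
            if role != "offspring":
                site.append([0, 1])
            elif sex == "male":
                site.append([0, 1] if m < called_males else [MISSING, MISSING])
                m += 1
            else:
                site.append([0, 0] if f < called_females else [MISSING, MISSING])
                f += 1
        return make_matrix([site], sexes, roles)

    def test_boundary_case_retained(self):
        gm = self._matrix_with_called(8, 7)  # ceil(15/2)=8, ceil(14/2)=7
        assert filter_half_sex_rule(gm).n_sites == 1

    def test_below_half_removed(self):
        assert filter_half_sex_rule(self._matrix_with_called(7, 14)).n_sites == 0
        assert filter_half_sex_rule(self._matrix_with_called(15, 6)).n_sites == 0

    def test_fully_called_matrix_unchanged(self, clean_xy_family):
        _, gm = clean_xy_family
        assert filter_half_sex_rule(gm).n_sites == gm.n_sites

    def test_no_offspring_is_error(self):
        gm = make_matrix([[[0, 1], [0, 0]]], ["female", "male"], ["dam", "sire"])
        with pytest.raises(ValueError, match="offspring"):
            filter_half_sex_rule(gm)


class TestAssociation:
    def test_identical_counts_give_p_one_theta_nonpositive(self):
        sexes, roles = family_frame(5, 5)
        site = [[0, 1]] * 12  # parents + everyone heterozygous
        gm = make_matrix([site], sexes, roles)
        out = site_association(gm)
        assert out.loc[0, "fet_p"] == 1.0
        assert np.isnan(out.loc[0, "fst"]) or out.loc[0, "fst"] <= 0

    def test_fixed_difference(self):
        """Males all alt/alt, females all ref/ref: theta = 1 and p equals
        the exact enumeration value 1/C(58,30)."""
        from math import comb

        sexes, roles = family_frame()
        site = ([[0, 1], [0, 1]]
                + [[1, 1]] * 15 + [[0, 0]] * 14)
        gm = make_matrix([site], sexes, roles)
        out = site_association(gm)
        assert out.loc[0, "fst"] == pytest.approx(1.0)
        assert out.loc[0, "fet_p"] == pytest.approx(1 / comb(58, 30), rel=1e-9)
        assert bool(out.loc[0, "significant"])

    def test_monomorphic_site_reported_missing(self):
        sexes, roles = family_frame(5, 5)
        site = [[0, 0]] * 12
        gm = make_matrix([site], sexes, roles)
        out = site_association(gm)
        assert out.loc[0, "fet_p"] == 1.0
        assert np.isnan(out.loc[0, "fst"])

    def test_parents_excluded_from_counts(self):
        """Flipping parental genotypes must not change the test."""
        sexes, roles = family_frame(6, 6)
        base = [[0, 1], [0, 1]] + [[0, 1]] * 6 + [[0, 0]] * 6
        flipped = [[1, 1], [0, 0]] + [[0, 1]] * 6 + [[0, 0]] * 6
        p1 = site_association(make_matrix([base], sexes, roles)).loc[0, "fet_p"]
        p2 = site_association(make_matrix([flipped], sexes, roles)).loc[0, "fet_p"]
        assert p1 == p2


class TestInheritance:
    def test_one_discordant_of_28_is_3_6_percent(self):
        """A site where 27 of 28 offspring match the sex-predicted genotype
        shows 1/28 = 3.6% discordance."""
        sexes, roles = family_frame(14, 14)
        # sire het, dam hom; one son carries the maternal-type genotype
        site = ([[0, 0], [0, 1]]
                + [[0, 1]] * 13 + [[0, 0]]   # 14 sons, one discordant
                + [[0, 0]] * 14)             # 14 daughters all concordant
        gm = make_matrix([site], sexes, roles)
        assoc = site_association(gm, alpha=1.1)  # rank every site as candidate
        rep = classify_inheritance(gm, assoc, alpha=1.1)
        conc = rep.site_table.loc[rep.site_table["model"] == "XY",
                                  "concordance"].iloc[0]
        assert conc == pytest.approx(27 / 28)
        assert 1 - conc == pytest.approx(0.036, abs=5e-4)

    def test_error_free_xy_family_classified_xy(self, clean_xy_family):
        design, gm = clean_xy_family
        assoc = site_association(gm)
        rep = classify_inheritance(gm, assoc)
        assert rep.model == "XY"
        assert rep.xy_concordance == 1.0
        sd_rows = rep.site_table[(rep.site_table["model"] == "XY")
                                 & (rep.site_table["pos"] == design.sd_position)]
        assert len(sd_rows) == 1 and sd_rows["concordance"].iloc[0] == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_zw_family_classified_zw(self, seed):
        d = FamilyDesign(system="ZW", n_sites=400,
                         genotyping_error=0.0, missing_rate=0.0)
        gm = simulate_family(d, seed=seed)
        rep = classify_inheritance(gm, site_association(gm))
        assert rep.model == "ZW"
        assert rep.zw_concordance == 1.0
        # no XY-informative significant sites exist in a ZW family
        assert np.isnan(rep.xy_concordance)

    def test_breakpoints_at_label_switches(self):
        """An offspring that switches from paternal to maternal labels between
        two informative sites gets exactly that breakpoint interval."""
        sexes, roles = family_frame(2, 2)
        # two informative sites; son i2 is paternal at site 1, maternal at 2
        s1 = [[0, 0], [0, 1], [0, 1], [0, 1], [0, 0], [0, 0]]
        s2 = [[0, 0], [0, 1], [0, 0], [0, 1], [0, 0], [0, 0]]
        gm = make_matrix([s1, s2], sexes, roles, pos=[1000, 2000])
        rep = classify_inheritance(gm, site_association(gm, alpha=1.1),
                                   alpha=1.1, decision_threshold=0.5)
        assert rep.breakpoints["i2"] == [(1000, 2000)]
        assert all(not v for k, v in rep.breakpoints.items() if k != "i2")

    def test_no_informative_sites_inconclusive(self):
        sexes, roles = family_frame(3, 3)
        site = [[0, 1], [0, 1]] + [[0, 1]] * 6  # both parents het: uninformative
        gm = make_matrix([site], sexes, roles)
        rep = classify_inheritance(gm, site_association(gm, alpha=1.1), alpha=1.1)
        assert rep.model == "inconclusive"
        assert rep.explanation

    def test_concordance_monotone_in_concordant_offspring(self):
        """Adding a concordant son never decreases the site concordance."""
        prev = -1.0
        for extra in range(4):
            sexes, roles = family_frame(4 + extra, 4)
            site = ([[0, 0], [0, 1]]
                    + [[0, 1]] * (3 + extra) + [[0, 0]]
                    + [[0, 0]] * 4)
            gm = make_matrix([site], sexes, roles)
            rep = classify_inheritance(gm, site_association(gm, alpha=1.1),
                                       alpha=1.1, decision_threshold=0.0)
            conc = rep.site_table["concordance"].iloc[0]
            assert conc >= prev
            prev = conc


class TestSdLocalization:
    def test_peak_concordance_brackets_sd_locus(self):
        """Across seeded runs the maximal-concordance site falls inside the
        diverged window around the SD position."""
        hits = runs = 0
        for seed in range(25):
            d = FamilyDesign(n_sites=400, genotyping_error=0.0,
                             missing_rate=0.1)
            gm = filter_half_sex_rule(simulate_family(d, seed=seed))
            rep = classify_inheritance(gm, site_association(gm))
            xy = rep.site_table[rep.site_table["model"] == "XY"]
            best = xy.loc[xy["concordance"].idxmax()]
            peak_sites = xy[xy["concordance"] == best["concordance"]]
            runs += 1
            if (np.abs(peak_sites["pos"] - d.sd_position)
                    <= d.sd_divergence_bp).any():
                hits += 1
        assert hits / runs >= 0.95
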