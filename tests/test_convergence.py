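"""Convergent-substitution screen: detection, filters, annotation."""

import pandas as pd
import pytest

from codonsel import (
    GroupSpec,
    classify_property_change,
    conservative_site_filter,
    detect_shared_substitutions,
    filter_background_shared,
    screen_gene_set,
)
from codonsel.convergence import annotate_domains, ungapped_position

IN3 = ["in1", "in2", "in3"]
ON4 = ["on1", "on2", "on3", "on4"]
GROUPS = GroupSpec(in_list=frozenset(IN3), on_list=frozenset(ON4))


def _aln(in_col, on_cols, length=10, at=5):
    """Build a protein alignment with one interesting column at `at`."""
    base = "A" * length
    aln = {}
    for t, res in zip(IN3, [in_col] * 3):
        aln[t] = base[: at - 1] + res + base[at:]
    for t, res in zip(ON4, on_cols):
        aln[t] = base[: at - 1] + res + base[at:]
    return aln


class TestDetect:
    def test_unanimous_in_absent_in_on_is_called(self):
        sites = detect_shared_substitutions(_aln("S", "GGGG"), GROUPS, "g")
        assert len(sites) == 1
        s = sites[0]
        assert (s.position, s.in_residue) == (5, "S")
        assert s.on_residues == ["G", "G", "G", "G"]

    def test_non_unanimous_in_not_called(self):
        aln = _aln("G", "SSSS")
        aln["in3"] = aln["in3"][:4] + "S" + aln["in3"][5:]
        assert detect_shared_substitutions(aln, GROUPS) == []

    def test_in_residue_present_in_on_not_called_when_strict(self):
        sites = detect_shared_substitutions(_aln("S", "SGGG"), GROUPS)
        assert sites == []

    def test_relaxed_mode_calls_against_consensus(self):
        sites = detect_shared_substitutions(
            _aln("S", "SGGG"), GROUPS, require_absent_in_background=False
        )
        assert len(sites) == 1  # consensus G != S, one ON taxon shares S

    def test_gap_in_in_list_skips_column(self):
        aln = _aln("S", "GGGG")
        aln["in1"] = aln["in1"][:4] + "-" + aln["in1"][5:]
        assert detect_shared_substitutions(aln, GROUPS) == []

    def test_missing_group_taxon_is_error(self):
        aln = _aln("S", "GGGG")
        del aln["on4"]
        with pytest.raises(ValueError, match="on4"):
            detect_shared_substitutions(aln, GROUPS)

    def test_invariant_to_taxon_order_and_all_gap_taxon(self):
        aln = _aln("S", "GGGG")
        reordered = {t: aln[t] for t in reversed(list(aln))}
        reordered["extra"] = "-" * 10
        a = detect_shared_substitutions(aln, GROUPS)
        b = detect_shared_substitutions(reordered, GROUPS)
        assert [(s.position, s.in_residue) for s in a] == [
            (s.position, s.in_residue) for s in b
        ]


class TestBackgroundSharedFilter:
    def test_clean_input_unchanged(self):
        sites = {"g": detect_shared_substitutions(_aln("S", "GGGG"), GROUPS, "g")}
        assert filter_background_shared(sites, GROUPS) == sites

    def test_gene_with_background_sharing_removed(self):
        sites = {
            "g": detect_shared_substitutions(
                _aln("S", "SGGG"), GROUPS, "g", require_absent_in_background=False
            )
        }
        assert filter_background_shared(sites, GROUPS) == {}

    def test_empty_input_empty_output(self):
        assert filter_background_shared({}, GROUPS) == {}


class TestConservativeFilter:
    def test_uniform_background_is_conservative(self):
        aln = _aln("G", "SSSS")
        sites = detect_shared_substitutions(aln, GROUPS)
        kept = conservative_site_filter(sites, aln, GROUPS)
        assert len(kept) == 1 and kept[0].conservative

    def test_identity_fraction_threshold_arithmetic(self):
        # background S,S,S,T: fraction 0.75 fails at 1.0, passes at 0.7
        aln = _aln("G", "SSST")
        sites = detect_shared_substitutions(aln, GROUPS)
        assert conservative_site_filter(list(sites), aln, GROUPS, 1.0) == []
        kept = conservative_site_filter(list(sites), aln, GROUPS, 0.7)
        assert len(kept) == 1
        assert kept[0].conservation_fraction == pytest.approx(0.75)

    def test_property_class_mode_admits_basic_kr_background(self):
        # Lys/Arg background, both basic, replaced by Gln in the foreground
        aln = _aln("Q", "KKRR")
        sites = detect_shared_substitutions(aln, GROUPS)
        assert conservative_site_filter(list(sites), aln, GROUPS, 1.0, "identity") == []
        kept = conservative_site_filter(list(sites), aln, GROUPS, 1.0, "property")
        assert len(kept) == 1
        assert kept[0].conservation_mode == "property"

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            conservative_site_filter([], {}, GROUPS, mode="bogus")


class TestDomains:
    def _site(self, pos):
        sites = detect_shared_substitutions(_aln("S", "GGGG", length=100, at=pos),
                                            GROUPS, "g")
        return sites

    def test_position_inside_interval(self):
        sites = annotate_domains(
            self._site(71),
            pd.DataFrame([("g", "dom", 50, 120)],
                         columns=["protein_id", "domain_name", "start", "end"]),
        )
        assert sites[0].in_domain and sites[0].domain_name == "dom"

    def test_boundary_exclusive_below_start(self):
        sites = annotate_domains(
            self._site(71),
            pd.DataFrame([("g", "dom", 72, 120)],
                         columns=["protein_id", "domain_name", "start", "end"]),
        )
        assert not sites[0].in_domain

    def test_empty_table_all_false(self):
        sites = annotate_domains(
            self._site(10),
            pd.DataFrame(columns=["protein_id", "domain_name", "start", "end"]),
        )
        assert sites[0].in_domain is False

    def test_out_of_bounds_interval_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            sites = annotate_domains(
                self._site(99),
                pd.DataFrame([("g", "dom", 90, 400)],
                             columns=["protein_id", "domain_name", "start", "end"]),
                protein_lengths={"g": 100},
            )
        assert sites[0].in_domain

    def test_ungapped_position_maps_through_gaps(self):
        assert ungapped_position("MA--KV", 5) == 3
        assert ungapped_position("MA--KV", 3) is None


class TestPropertyChange:
    def test_ser_to_gly_is_hydrophilic_to_hydrophobic(self):
        ch = classify_property_change("S", "G")
        assert ch.label == "hydrophilic→hydrophobic"
        assert not ch.no_change

    def test_lys_arg_to_gln_is_basic_to_neutral(self):
        ch = classify_property_change({"K", "R"}, "Q")
        assert ch.label == "basic→neutral"

    def test_same_residue_flagged_no_change(self):
        ch = classify_property_change("A", "A")
        assert (ch.from_class, ch.to_class) == ("hydrophobic", "hydrophobic")
        assert ch.no_change

    def test_mixed_class_sources_rejected(self):
        with pytest.raises(ValueError, match="several"):
            classify_property_change({"K", "S"}, "G")

    def test_unknown_letter_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            classify_property_change("B", "G")


class TestFullScreen:
    def test_stage_counts_monotone_and_planted_recovery(self):
        alns = {
            "clean": _aln("G", "SSSS", length=80, at=40),
            "shared": _aln("S", "SGGG", length=80, at=40),
            "nonconserved": _aln("G", "STNC", length=80, at=40),
            "null": {t: "A" * 80 for t in IN3 + ON4},
        }
        domains = pd.DataFrame(
            [("clean", "dom", 30, 50)],
            columns=["protein_id", "domain_name", "start", "end"],
        )
        sites, counts = screen_gene_set(alns, GROUPS, domain_table=domains)
        assert counts["detected"] >= counts["after_background_filter"]
        assert counts["after_background_filter"] >= counts["after_ccs"]
        assert list(sites) == ["clean"]
        (site,) = sites["clean"]
        assert site.position == 40
        assert site.in_domain
        assert site.property_change.label == "hydrophilic→hydrophobic"
        assert counts == {
            "detected": 3,
            "after_background_filter": 2,
            "after_ccs": 1,
            "in_domain": 1,
        }

    def test_group_spec_validation(self):
        with pytest.raises(ValueError, match="both groups"):
            GroupSpec(in_list=frozenset({"x"}), on_list=frozenset({"x", "y"}))
        with pytest.raises(ValueError, match="nonempty"):
            GroupSpec(in_list=frozenset(), on_list=frozenset({"y"}))
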