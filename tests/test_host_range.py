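"""Registry loading, the two-Type-I-sites cleavage rule, and concordance."""

import pytest

import phagerm as pm
from phagerm.host_range import (
    CCProfile,
    RegistryError,
    SUSCEPTIBLE_FRACTION,
    Verdict,
)

from conftest import make_site


class TestRegistry:
    def test_shipped_registry_cc30(self, registry):
        (cc30,) = [p for p in registry.profiles if p.clonal_complex == "CC30"]
        assert cc30.systems == ("CC30-1", "CC30-2")
        assert registry.site("CC30-1").notation == "GWAG-5-GATG"
        assert registry.site("CC30-2").notation == "GA-7-TCG"
        assert (cc30.infected, cc30.tested) == (8, 8)

    def test_shipped_registry_nt_rows_have_no_empirical_data(self, registry):
        (cc51,) = [p for p in registry.profiles if p.clonal_complex == "CC51"]
        assert cc51.infected is None and cc51.empirical_fraction is None

    def test_impossible_it_ratio_rejected(self):
        with pytest.raises(RegistryError):
            CCProfile("CCX", ("a",), infected=5, tested=4)

    def test_empty_systems_rejected(self):
        with pytest.raises(RegistryError):
            CCProfile("CCX", ())

    def test_duplicate_site_names_rejected(self, tmp_path):
        bad = tmp_path / "reg.yaml"
        bad.write_text(
            "sites:\n"
            "  - {name: A, notation: GATC, rm_type: TypeII}\n"
            "  - {name: A, notation: GGNCC, rm_type: TypeII}\n"
        )
        with pytest.raises(RegistryError, match="duplicate"):
            pm.load_registry(bad)

    def test_unknown_profile_system_rejected(self, tmp_path):
        bad = tmp_path / "reg.yaml"
        bad.write_text(
            "sites:\n"
            "  - {name: A, notation: GATC, rm_type: TypeII}\n"
            "profiles:\n"
            "  - {clonal_complex: CCX, systems: [missing], i_t: 1/2}\n"
        )
        with pytest.raises(RegistryError, match="missing"):
            pm.load_registry(bad)

    def test_type_ii_partition(self, registry):
        assert {s.name for s in registry.type_ii_sites} == {"Sau3A", "Sau96I"}
        assert all(s.rm_type is pm.RMType.TYPE_I
                   for s in registry.sites if s.name not in {"Sau3A", "Sau96I"})


class TestVerdict:
    def test_zero_sites_predicts_escape(self, registry):
        (cc30,) = [p for p in registry.profiles if p.clonal_complex == "CC30"]
        genome = pm.GenomeRecord("empty", "AT" * 200)
        v = pm.predict_cc_susceptibility(genome, cc30, registry)
        assert v.verdict is Verdict.ESCAPE
        assert v.per_system_counts == {"CC30-1": 0, "CC30-2": 0}
        assert v.empirical_fraction == 1.0 and v.concordant is True

    def test_single_type_i_site_still_escape(self, registry):
        """One site cannot support the two-enzyme collision needed to cleave."""
        (cc22,) = [p for p in registry.profiles if p.clonal_complex == "CC22"]
        genome, _ = pm.plant_sites(
            pm.PlantSpec(2000, registry.site("CC22-1"), 1, seed=1)
        )
        v = pm.predict_cc_susceptibility(genome, cc22, registry)
        assert v.verdict is Verdict.ESCAPE

    def test_five_sites_predicts_restriction_yet_empirically_infected(self, registry):
        """The CC22 paradox: 5 recognition sites but 4/4 strains infected."""
        (cc22,) = [p for p in registry.profiles if p.clonal_complex == "CC22"]
        genome, _ = pm.plant_sites(
            pm.PlantSpec(2000, registry.site("CC22-1"), 5, seed=1)
        )
        v = pm.predict_cc_susceptibility(genome, cc22, registry)
        assert v.verdict is Verdict.RESTRICTION_LIMITED
        assert v.empirical_fraction == 1.0
        assert v.concordant is False

    def test_type_ii_excluded_by_default_included_on_flag(self, registry):
        (cc30,) = [p for p in registry.profiles if p.clonal_complex == "CC30"]
        controlled = [registry.site(n) for n in ("Sau3A", "Sau96I", "CC30-1", "CC30-2")]
        genome, _ = pm.plant_profile(2000, {"Sau3A": 2}, controlled, seed=2)
        default = pm.predict_cc_susceptibility(genome, cc30, registry)
        strict = pm.predict_cc_susceptibility(genome, cc30, registry, include_type_ii=True)
        assert default.verdict is Verdict.ESCAPE
        assert default.type_ii_counts["Sau3A"] == 2
        assert strict.verdict is Verdict.RESTRICTION_LIMITED

    def test_precomputed_counts_bypass_scanning(self, registry):
        genome = pm.GenomeRecord("unused", "A" * 50)
        counts = {s.name: 0 for s in registry.sites}
        counts["CC22-1"] = 5
        verdicts = pm.predict_all(genome, registry, counts=counts)
        by_cc = {v.clonal_complex: v for v in verdicts}
        assert by_cc["CC22"].verdict is Verdict.RESTRICTION_LIMITED
        assert by_cc["CC45"].verdict is Verdict.ESCAPE

    def test_monotonicity_adding_high_count_system(self, registry):
        """A system with >= 2 sites can only flip escape -> limited."""
        genome = pm.GenomeRecord("unused", "A" * 50)
        counts = {s.name: 0 for s in registry.sites}
        counts["CC30-2"] = 2
        base = CCProfile("CCX", ("CC30-1",))
        extended = CCProfile("CCX", ("CC30-1", "CC30-2"))
        v1 = pm.predict_cc_susceptibility(genome, base, registry, counts=counts)
        v2 = pm.predict_cc_susceptibility(genome, extended, registry, counts=counts)
        assert v1.verdict is Verdict.ESCAPE
        assert v2.verdict is Verdict.RESTRICTION_LIMITED

    def test_unknown_system_name_errors(self, registry):
        genome = pm.GenomeRecord("g", "A" * 50)
        with pytest.raises(RegistryError, match="nope"):
            pm.predict_cc_susceptibility(genome, CCProfile("CCX", ("nope",)), registry)


class TestConcordance:
    def _verdict(self, cc, verdict, fraction):
        concordant = None
        if fraction is not None:
            concordant = (verdict is Verdict.ESCAPE) == (fraction >= SUSCEPTIBLE_FRACTION)
        return pm.SusceptibilityVerdict(
            clonal_complex=cc, per_system_counts={}, type_ii_counts={},
            verdict=verdict, empirical_fraction=fraction, concordant=concordant,
        )

    def test_all_concordant(self):
        rep = pm.concordance_report([
            self._verdict("CC30", Verdict.ESCAPE, 1.0),
            self._verdict("CC45", Verdict.ESCAPE, 1.0),
        ])
        assert rep.agreement_fraction == 1.0
        assert rep.discordant == ()

    def test_cc22_alone_discordant(self):
        rep = pm.concordance_report([self._verdict("CC22", Verdict.RESTRICTION_LIMITED, 1.0)])
        assert rep.agreement_fraction == 0.0
        assert rep.discordant == ("CC22",)

    def test_mixed_set(self):
        rep = pm.concordance_report([
            self._verdict("CC30", Verdict.ESCAPE, 1.0),
            self._verdict("CC45", Verdict.ESCAPE, 0.9),
            self._verdict("CC97", Verdict.ESCAPE, 0.0),
            self._verdict("CC22", Verdict.RESTRICTION_LIMITED, 0.2),
            self._verdict("CC51", Verdict.ESCAPE, None),
        ])
        assert rep.agreement_fraction == pytest.approx(0.75)
        assert rep.discordant == ("CC97",)
        assert rep.untested == ("CC51",)
        assert rep.n_with_data == 4

    def test_no_empirical_data_errors(self):
        with pytest.raises(ValueError):
            pm.concordance_report([self._verdict("CC51", Verdict.ESCAPE, None)])
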