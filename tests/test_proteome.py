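"""Proteome database assembly and distribution analyses."""

import numpy as np
import pytest

from sdvrc.proteome import (
    SEC_PARTNER_MASS_DA,
    LinkageError,
    MassDistribution,
    ProteinRecord,
    assemble_species,
    build_dc_table,
    dc_distribution_density,
    dcyto_from_mass,
    fit_lognormal_mass,
    synth_proteome,
)
from sdvrc.radii import mass_from_radius, radius_from_mass


def cyto(acc, mass, subunits=()):
    return ProteinRecord(accession=acc, chain_mass=mass, subunits=list(subunits))


class TestAssembleSpecies:
    def test_monomer_passes_through(self):
        (sp,) = assemble_species([cyto("A", 30_000)])
        assert (sp.form, sp.M_total) == ("monomer", 30_000)

    def test_homotetramer_mass_and_radius(self):
        # a chain whose monomer radius is 3.2 nm assembles into a tetramer
        # of radius 3.2 * 4**0.392 ~ 5.5 nm (cf. the lactose repressor)
        chain_mass = mass_from_radius(3.2, "protein")
        (sp,) = assemble_species([cyto("LACI", chain_mass, [("LACI", 4)])])
        assert sp.form == "oligomer"
        assert sp.M_total == pytest.approx(4 * chain_mass)
        assert 5.45 <= radius_from_mass(sp.M_total, "protein") <= 5.65

    def test_hetero_oligomer_sums_referenced_chains(self):
        records = [
            cyto("A", 10_000, [("A", 2), ("B", 1)]),
            cyto("B", 25_000),
        ]
        species = assemble_species(records)
        forms = {s.accession: s for s in species}
        assert forms["A"].M_total == pytest.approx(45_000)
        assert forms["B"].form == "monomer"

    def test_tat_substrate_diffuses_as_single_chain(self):
        rec = ProteinRecord(
            accession="M", chain_mass=30_000, localization="membrane", pathway="TAT"
        )
        (sp,) = assemble_species([rec])
        assert (sp.form, sp.M_total) == ("tat_monomer", 30_000)

    @pytest.mark.parametrize("partner", ["SecB", "Tig"])
    def test_sec_substrate_adds_one_chaperone_chain(self, partner):
        rec = ProteinRecord(
            accession="M", chain_mass=20_000, localization="membrane",
            pathway="Sec", sec_partner=partner,
        )
        (sp,) = assemble_species([rec])
        assert sp.form == "sec_complex"
        assert sp.M_total == pytest.approx(20_000 + SEC_PARTNER_MASS_DA[partner])

    def test_unresolved_subunit_fails_loudly(self):
        with pytest.raises(LinkageError):
            assemble_species([cyto("A", 10_000, [("GHOST", 2)])])

    def test_sec_without_partner_is_invalid(self):
        with pytest.raises(ValueError):
            ProteinRecord(
                accession="M", chain_mass=20_000, localization="membrane", pathway="Sec"
            )

    def test_pathway_localization_consistency(self):
        with pytest.raises(ValueError):
            ProteinRecord(accession="A", chain_mass=1e4, pathway="TAT")

    def test_mass_conservation(self, rng):
        records = synth_proteome(500, seed=7)
        species = assemble_species(records)
        total = sum(s.M_total for s in species)
        by_acc = {r.accession: r for r in records}
        expected = 0.0
        for r in records:
            if r.pathway == "Sec":
                expected += r.chain_mass + SEC_PARTNER_MASS_DA[r.sec_partner]
            elif r.subunits:
                expected += sum(k * by_acc[c].chain_mass for c, k in r.subunits)
            else:
                expected += r.chain_mass
        assert total == pytest.approx(expected)

    def test_monomer_forms_expand_the_record_count(self):
        records = [cyto("A", 10_000, [("A", 4)]), cyto("B", 20_000)]
        assert len(assemble_species(records)) == 2
        expanded = assemble_species(records, include_monomer_forms=True)
        assert len(expanded) == 3
        assert sum(1 for s in expanded if s.form == "monomer") == 2


class TestBuildDcTable:
    def test_empty_input_gives_empty_table(self, ref_cal):
        assert build_dc_table([], ref_cal.params) == []

    @pytest.mark.parametrize(
        "radius,expected", [(8.5, 0.5), (2.1, 19.71)]
    )
    def test_reference_molecules(self, ref_cal, env, radius, expected):
        # RNA polymerase holoenzyme and the TrpR monomer
        from sdvrc.proteome import Species

        sp = Species("X", "monomer", mass_from_radius(radius, "protein"))
        (rec,) = build_dc_table([sp], ref_cal.params, env)
        assert rec.r_p == pytest.approx(radius, rel=1e-9)
        assert rec.Dcyto == pytest.approx(expected, rel=0.1)

    def test_rows_satisfy_model_invariants(self, ref_cal, env):
        records = synth_proteome(300, seed=3)
        table = build_dc_table(assemble_species(records), ref_cal.params, env)
        assert len(table) == 300
        for rec in table:
            assert rec.Dcyto < rec.D0
            assert rec.r_p == pytest.approx(radius_from_mass(rec.M_total, "protein"))
        ordered = sorted(table, key=lambda r: r.M_total)
        dcs = [r.Dcyto for r in ordered]
        assert all(a > b for a, b in zip(dcs, dcs[1:]))


class TestLognormalMass:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(42)
        dist = MassDistribution(sigma=0.8, M_mean=30.0 * np.exp(0.8**2 / 2))
        masses_da = dist.sample(10_000, rng) * 1000.0
        est = fit_lognormal_mass(masses_da)
        assert est.sigma == pytest.approx(0.8, abs=0.02)
        assert est.median_kda == pytest.approx(30.0, rel=0.05)

    def test_degenerate_masses_rejected(self):
        with pytest.raises(ValueError):
            fit_lognormal_mass([5e4] * 100)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            fit_lognormal_mass([1e4, -2.0])

    def test_density_is_normalized_and_unimodal(self):
        dist = MassDistribution(sigma=0.8, M_mean=40.0)
        m = np.geomspace(1e-3, 1e4, 20_000)
        pdf = dist.pdf(m)
        assert np.all(pdf >= 0)
        assert np.trapezoid(pdf, m) == pytest.approx(1.0, abs=1e-3)
        peak = np.argmax(pdf)
        assert np.all(np.diff(pdf[: peak + 1]) >= 0)
        assert np.all(np.diff(pdf[peak:]) <= 0)


class TestDcDistribution:
    dist = MassDistribution(sigma=0.8, M_mean=40.0)

    def test_mass_to_dc_map_is_strictly_decreasing(self, ref_cal, env):
        m = np.geomspace(1e3, 1e9, 200)
        d = dcyto_from_mass(m, ref_cal.params, env)
        assert np.all(np.diff(d) < 0)

    def test_density_normalizes_over_attainable_range(self, ref_cal, env):
        grid = np.geomspace(1e-3, 2e3, 5000)
        dens = dc_distribution_density(self.dist, ref_cal.params, env, grid)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_matches_monte_carlo_histogram(self, ref_cal, env):
        """Total-variation distance to a 1e5-sample histogram below 0.02."""
        rng = np.random.default_rng(2024)
        masses_da = self.dist.sample(100_000, rng) * 1000.0
        samples = dcyto_from_mass(masses_da, ref_cal.params, env)
        edges = np.geomspace(samples.min() * 0.99, samples.max() * 1.01, 51)
        counts, _ = np.histogram(samples, bins=edges)
        p_mc = counts / counts.sum()
        fine = np.geomspace(edges[0], edges[-1], 20_000)
        dens = dc_distribution_density(self.dist, ref_cal.params, env, fine)
        cdf = np.concatenate([[0.0], np.cumsum(np.diff(fine) * (dens[1:] + dens[:-1]) / 2)])
        p_model = np.diff(np.interp(edges, fine, cdf))
        p_model /= p_model.sum()
        tv = 0.5 * np.abs(p_mc - p_model).sum()
        assert tv < 0.02

    def test_grid_outside_attainable_range_rejected(self, ref_cal, env):
        with pytest.raises(ValueError):
            dc_distribution_density(self.dist, ref_cal.params, env, np.array([1e9]))


class TestSynthProteome:
    def test_deterministic_given_seed(self):
        a = synth_proteome(200, seed=11)
        b = synth_proteome(200, seed=11)
        assert a == b

    def test_different_seed_differs(self):
        assert synth_proteome(50, seed=1) != synth_proteome(50, seed=2)

    def test_requested_fractions_are_met(self):
        records = synth_proteome(1000, oligomer_fraction=0.45, membrane_fraction=0.30, seed=5)
        n_olig = sum(1 for r in records if r.subunits)
        n_mem = sum(1 for r in records if r.localization == "membrane")
        assert 420 <= n_olig <= 480
        assert 270 <= n_mem <= 330

    def test_closure_mass_distribution_recovered(self):
        dist = MassDistribution(sigma=0.8, M_mean=40.0)
        records = synth_proteome(5000, dist=dist, seed=9)
        est = fit_lognormal_mass([r.chain_mass for r in records])
        assert est.sigma == pytest.approx(dist.sigma, rel=0.05)
        assert est.M_mean == pytest.approx(dist.M_mean, rel=0.05)

    def test_validation(self):
        with pytest.raises(ValueError):
            synth_proteome(0)
        with pytest.raises(ValueError):
            synth_proteome(10, oligomer_fraction=1.2)
        with pytest.raises(ValueError):
            synth_proteome(10, oligomer_fraction=0.9, membrane_fraction=0.5)
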