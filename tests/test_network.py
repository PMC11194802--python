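"""Exchange-network assembly: canonical barriers, CSV IO, edges, consistency."""

import math

import pytest

from grekin import (
    CONSTANTS,
    build_network,
    canonical_barriers,
    detailed_balance_check,
    load_barrier_table,
    write_barrier_table,
)
from grekin.network import (
    CLOSED_STATES,
    GLY_STATES,
    BarrierRecord,
    GlyState,
    abstraction_product,
    addition_product,
)


def records_by_key(records):
    return {(r.step_kind, r.site, r.isotope, r.gly_source): r for r in records}


class TestCanonicalBarriers:
    @pytest.mark.parametrize("form,key,expected", [
        ("ES", ("addition", "re", "H", "GlyH_rad"), 40.4),
        ("ES", ("addition", "si", "H", "GlyD_rad"), 61.0),
        ("ES", ("abstraction", "S", "H", "R-GlyHD"), 95.6),
        ("EP", ("addition", "si", "D", "GlyH_rad"), 67.8),
        ("APO", ("abstraction", "S", "D", "S-GlyDH"), 2.4),
        ("APO", ("addition", "re", "D", "GlyH_rad"), 109.8),
    ])
    def test_published_values(self, form, key, expected):
        assert records_by_key(canonical_barriers(form))[key].barrier == expected

    @pytest.mark.parametrize("form", ["ES", "EP", "APO"])
    def test_sixteen_unique_records(self, form):
        records = canonical_barriers(form)
        assert len(records) == 16
        assert len({r.key for r in records}) == 16
        assert sum(r.step_kind == "addition" for r in records) == 8

    def test_unknown_form(self):
        with pytest.raises(ValueError, match="unknown enzyme form"):
            canonical_barriers("EX")


class TestGlyStates:
    def test_occupant_invariants(self):
        for state in GLY_STATES.values():
            n = sum(o is not None for o in (state.proS_occupant, state.proR_occupant))
            assert n == (1 if state.kind == "radical" else 2)

    def test_monodeuterated_labels(self):
        assert GLY_STATES["R-GlyHD"].proS_occupant == "H"
        assert GLY_STATES["R-GlyHD"].proR_occupant == "D"
        assert GLY_STATES["S-GlyDH"].proS_occupant == "D"
        assert GLY_STATES["S-GlyDH"].proR_occupant == "H"

    def test_invalid_state_rejected(self):
        with pytest.raises(ValueError):
            GlyState("bad", "radical", "H", "D")


class TestBarrierCsv:
    def test_round_trip(self, tmp_path, es_records):
        path = tmp_path / "barriers.csv"
        write_barrier_table(es_records, path)
        assert load_barrier_table(path) == es_records

    def test_duplicate_key_named(self, tmp_path, es_records):
        path = tmp_path / "dup.csv"
        write_barrier_table(list(es_records) + [es_records[0]], path)
        with pytest.raises(ValueError, match="duplicate record"):
            load_barrier_table(path)

    def test_non_numeric_barrier_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "enzyme_form,step_kind,site,isotope,gly_source,barrier_kj_mol\n"
            "ES,addition,re,H,GlyH_rad,abc\n"
        )
        with pytest.raises(ValueError, match="row 2"):
            load_barrier_table(path)

    def test_missing_column(self, tmp_path):
        path = tmp_path / "cols.csv"
        path.write_text("enzyme_form,step_kind,site\nES,addition,re\n")
        with pytest.raises(ValueError, match="missing column"):
            load_barrier_table(path)


class TestBuildNetwork:
    def test_pure_d2o_weights(self, es_records):
        net = build_network(es_records, solvent_fD=1.0)
        for e in net.edges:
            if e.record.step_kind == "addition" and e.record.isotope == "H":
                assert e.rate == 0.0
        d_re = next(
            e for e in net.edges
            if e.record.key[1:] == ("addition", "re", "D", "GlyH_rad")
        )
        assert d_re.rate == pytest.approx(2.3e5, rel=0.05)
        assert d_re.to_state == "R-GlyHD"

    def test_partial_deuteration_scales_linearly(self, es_records):
        full = build_network(es_records, solvent_fD=1.0)
        part = build_network(es_records, solvent_fD=0.4)
        for e_full, e_part in zip(full.edges, part.edges):
            if e_full.record.step_kind == "addition":
                if e_full.record.isotope == "D":
                    assert e_part.rate == pytest.approx(0.4 * e_full.rate)
            else:
                assert e_part.rate == e_full.rate

    def test_solvent_weight_pairs_sum_to_one(self, es_records):
        from grekin import eyring_rate

        net = build_network(es_records, solvent_fD=0.3)
        additions = {
            e.record.key[1:]: e for e in net.edges
            if e.record.step_kind == "addition"
        }
        for site in ("re", "si"):
            for src in ("GlyH_rad", "GlyD_rad"):
                weights = [
                    additions[("addition", site, iso, src)].rate
                    / eyring_rate(additions[("addition", site, iso, src)].record.barrier)
                    for iso in ("H", "D")
                ]
                assert sum(weights) == pytest.approx(1.0, rel=1e-9)

    def test_apo_pros_penalty_suppresses_si_additions(self):
        records = canonical_barriers("APO")
        plain = build_network(records, solvent_fD=1.0)
        pen = build_network(records, solvent_fD=1.0, apo_proS_penalty=86.8)
        factor = math.exp(-86.8e3 / (CONSTANTS.R * CONSTANTS.T_default))
        for e0, e1 in zip(plain.edges, pen.edges):
            if e0.record.step_kind == "addition" and e0.record.site == "si":
                assert e1.rate == pytest.approx(e0.rate * factor, rel=1e-9)
            else:
                assert e1.rate == e0.rate

    def test_incomplete_set_lists_missing(self, es_records):
        with pytest.raises(ValueError, match="missing steps"):
            build_network(es_records[:-1])

    def test_stoichiometric_consistency(self, es_records):
        # every closed state loses each occupant exactly once via abstraction
        net = build_network(es_records, solvent_fD=0.5)
        for label in CLOSED_STATES:
            state = GLY_STATES[label]
            removals = sorted(
                (e.record.site, e.record.isotope)
                for e in net.edges
                if e.record.step_kind == "abstraction" and e.from_state == label
            )
            assert len(removals) == 2
            occupants = sorted([state.proS_occupant, state.proR_occupant])
            assert sorted(iso for _, iso in removals) == occupants

    def test_product_maps_consistent(self):
        # abstractions leave the radical carrying the untouched occupant
        for (site, iso, src), product in [
            (("R", "D", "R-GlyHD"), "GlyH_rad"),
            (("S", "H", "R-GlyHD"), "GlyD_rad"),
            (("R", "H", "S-GlyDH"), "GlyD_rad"),
            (("S", "D", "S-GlyDH"), "GlyH_rad"),
        ]:
            assert abstraction_product(site, iso, src) == product
        assert addition_product("si", "D", "GlyH_rad") == "S-GlyDH"
        with pytest.raises(KeyError):
            addition_product("re", "D", "GlyH2")

    def test_rates_decrease_with_barrier(self, es_records):
        bumped = [
            BarrierRecord(r.enzyme_form, r.step_kind, r.site, r.isotope,
                          r.gly_source, r.barrier + 1.0)
            for r in es_records
        ]
        base = build_network(es_records, solvent_fD=0.5)
        high = build_network(bumped, solvent_fD=0.5)
        for e0, e1 in zip(base.edges, high.edges):
            if e0.rate > 0:
                assert e1.rate < e0.rate


ES_INTERMEDIATE_ENERGIES = {
    ("re", "H", "GlyH_rad"): -31.7,
    ("re", "D", "GlyH_rad"): -34.2,
    ("re", "H", "GlyD_rad"): -32.6,
    ("re", "D", "GlyD_rad"): -35.2,
    ("si", "H", "GlyH_rad"): -33.7,
    ("si", "D", "GlyH_rad"): -36.2,
    ("si", "H", "GlyD_rad"): -34.6,
    ("si", "D", "GlyD_rad"): -37.2,
}


class TestDetailedBalance:
    def test_es_residuals_small(self, es_records):
        out = detailed_balance_check(es_records, ES_INTERMEDIATE_ENERGIES)
        assert len(out) == 8
        res, flagged = out[("re", "H", "GlyH_rad")]
        assert res == pytest.approx(0.1, abs=1e-9)
        assert not any(flag for _, flag in out.values())

    def test_symmetric_table_zero_residuals(self):
        records = []
        for site, rsite, iso, src, closed in [
            ("re", "R", "H", "GlyH_rad", "GlyH2"),
            ("si", "S", "H", "GlyH_rad", "GlyH2"),
        ]:
            records.append(BarrierRecord("ES", "addition", site, iso, src, 50.0))
            records.append(BarrierRecord("ES", "abstraction", rsite, iso, closed, 70.0))
        energies = {("re", "H", "GlyH_rad"): -20.0, ("si", "H", "GlyH_rad"): -20.0}
        out = detailed_balance_check(records, energies)
        assert all(res == pytest.approx(0.0) for res, _ in out.values())

    def test_perturbed_reverse_flags_exactly_one(self, es_records):
        bumped = [
            BarrierRecord(r.enzyme_form, r.step_kind, r.site, r.isotope,
                          r.gly_source,
                          r.barrier + (1.0 if r.key[1:] ==
                                       ("abstraction", "R", "D", "R-GlyHD") else 0.0))
            for r in es_records
        ]
        out = detailed_balance_check(bumped, ES_INTERMEDIATE_ENERGIES)
        flags = [k for k, (_, flag) in out.items() if flag]
        assert flags == [("re", "D", "GlyH_rad")]

    def test_missing_energy_rejected(self, es_records):
        with pytest.raises(ValueError, match="no intermediate energy"):
            detailed_balance_check(es_records, {})
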