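"""Parameter store: stack lookups, loop-table extrapolation, statistics."""

import itertools

import numpy as np
import pytest

from pzfold.alphabet import BASES, DNA_PZ, canonical_stack_key
from pzfold.parameters import (
    BIG,
    ParameterSet,
    load_parameter_set,
    read_stack_table,
    table_statistics,
    write_stack_table,
)

PZSET = frozenset("PZ")


class TestStackLookups:
    @pytest.mark.parametrize("top,bottom,value", [
        ("ZP", "PZ", -3.35),
        ("GZ", "ZG", 1.70),
        ("CP", "GZ", -2.77),
        ("PG", "ZZ", -2.47),
        ("PZ", "ZP", -1.57),
        ("GC", "CG", -2.24),
    ])
    def test_values(self, params_pz, top, bottom, value):
        assert params_pz.stack_dG37(tuple(top), tuple(bottom)) == pytest.approx(value)

    def test_rotational_equivalence(self, params_pz):
        for top, bottom in [("PP", "ZZ"), ("AA", "TT"), ("CP", "GZ")]:
            rot = (tuple(reversed(bottom)), tuple(reversed(top)))
            assert (params_pz.stack_dG37(tuple(top), tuple(bottom))
                    == params_pz.stack_dG37(*rot))

    def test_gt_column_rejected_in_dna_pz(self, params_pz):
        with pytest.raises(ValueError, match="not an allowed pair"):
            params_pz.stack_dG37(("G", "T"), ("T", "A"))

    def test_counts(self, params_pz):
        pz = gz = 0
        for key in params_pz.stacks:
            pairs = [frozenset((key[0][c], key[1][c])) for c in (0, 1)]
            if frozenset("GZ") in pairs:
                gz += 1
            elif PZSET in pairs:
                pz += 1
        assert pz == 11 and gz == 15

    def test_enthalpy_consistency_where_present(self, params_pz):
        for key, p in params_pz.stacks.items():
            if p.dH is not None and p.dS is not None:
                assert p.dG37 == pytest.approx(p.dH - 310.15 * p.dS / 1000, abs=0.15)

    def test_gz_stacks_have_no_enthalpy(self, params_pz):
        with pytest.raises(ValueError, match="enthalpy"):
            params_pz.stack_dH(("G", "Z"), ("Z", "G"))


class TestLoopExtrapolation:
    def test_measured_terminal_mismatches(self, params_pz):
        lt = params_pz.loops
        assert lt.tm(("T", "A"), ("Z", "Z")) == pytest.approx(-0.91)
        assert lt.tm(("G", "C"), ("Z", "Z")) == pytest.approx(-0.76)
        assert lt.tm(("T", "A"), ("P", "P")) == pytest.approx(-0.51)

    def test_unmeasured_pp_zz_defaults(self, params_pz):
        lt = params_pz.loops
        assert lt.tm(("C", "G"), ("P", "P")) == pytest.approx(-0.5)
        assert lt.tm(("A", "T"), ("Z", "Z")) == pytest.approx(-0.8)

    def test_mismatches_on_pz_closings_default(self, params_pz):
        lt = params_pz.loops
        assert lt.tm(("P", "Z"), ("P", "A")) == pytest.approx(-0.2)
        assert lt.tm(("Z", "G"), ("A", "C")) == pytest.approx(-0.2)
        assert lt.tm(("G", "Z"), ("T", "Z")) == pytest.approx(-0.2)

    def test_dangle_rules(self, params_pz):
        lt = params_pz.loops
        # canonical dangles on P-Z terminal pairs: -0.1 both sides
        for side in ("5p", "3p"):
            for d in "ACGT":
                assert lt.dangling(side, ("P", "Z"), d) == pytest.approx(-0.1)
                assert lt.dangling(side, ("Z", "P"), d) == pytest.approx(-0.1)
        # unmeasured P/Z dangles use the measured means
        assert lt.dangling("3p", ("G", "C"), "P") == pytest.approx(0.1)
        assert lt.dangling("5p", ("G", "C"), "P") == pytest.approx(-0.5)
        assert lt.dangling("3p", ("G", "C"), "Z") == pytest.approx(-0.1)
        assert lt.dangling("5p", ("G", "C"), "Z") == pytest.approx(-0.7)
        # measured entries beat the rule defaults
        assert lt.dangling("5p", ("A", "T"), "Z") == pytest.approx(-0.8)
        assert lt.dangling("5p", ("C", "G"), "P") == pytest.approx(-0.37)

    def test_int11_pz_stabilizer(self, params_pz):
        lt = params_pz.loops
        got = lt.int11_value(("G", "C"), ("P", "C"), ("G", "C"))
        canon = lt.int11_value(("G", "C"), ("A", "C"), ("G", "C"))
        assert got == pytest.approx(canon - 0.6)

    def test_int_tables_stabilizer_property(self, params_pz):
        """Every 1x1/2x2 entry equals its remapped canonical source - 0.6k."""
        lt = params_pz.loops
        rng = np.random.default_rng(0)
        remap = {"P": "G", "Z": "C"}
        wcf = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
        closings = [(x, y) for x in BASES for y in BASES if DNA_PZ.can_pair(x, y)]

        def remap_mm(a, b):
            a2, b2 = remap.get(a, a), remap.get(b, b)
            if (a2, b2) in wcf:
                a2 = "A" if a2 in "AGP" else "C"
                b2 = "A" if b2 in "AGP" else "C"
            return a2, b2

        def remap_cl(x, y):
            table = {("P", "Z"): ("G", "C"), ("Z", "P"): ("C", "G"),
                     ("G", "Z"): ("A", "T"), ("Z", "G"): ("T", "A")}
            return table.get((x, y), (x, y))

        for _ in range(300):
            c1 = closings[rng.integers(len(closings))]
            c2 = closings[rng.integers(len(closings))]
            a, b = (BASES[rng.integers(6)] for _ in range(2))
            k = int(a in "PZ" or b in "PZ")
            got = lt.int11_value(c1, (a, b), c2)
            src = lt.int11_value(remap_cl(*c1), remap_mm(a, b), remap_cl(*c2))
            assert got == pytest.approx(src - 0.6 * k, abs=1e-12)

    def test_completeness_no_missing_entries(self, params_pz):
        """Exhaustive legal loop queries all resolve to finite values."""
        lt = params_pz.loops
        closings = [(x, y) for x in BASES for y in BASES if DNA_PZ.can_pair(x, y)]
        for (x, y) in closings:
            for d in BASES:
                lt.dangling("5p", (x, y), d)
                lt.dangling("3p", (x, y), d)
            for a, b in itertools.product(BASES, repeat=2):
                lt.tm((x, y), (a, b))
        for c1, c2 in itertools.product(closings, repeat=2):
            for a, b in itertools.product(BASES, repeat=2):
                lt.int11_value(c1, (a, b), c2)
        assert np.all(lt.hairpin_len[3:] < BIG / 2)
        assert np.all(lt.bulge_len[1:31] < BIG / 2)
        assert np.all(lt.internal_len[3:31] < BIG / 2)

    def test_disallowed_closing_rejected(self, params_pz):
        with pytest.raises(KeyError, match="not an allowed closing pair"):
            params_pz.loops.tm(("G", "T"), ("A", "A"))


class TestTableStatistics:
    def test_aggregates(self, params_pz):
        st = table_statistics(params_pz)
        assert st["mean_ddG_per_PZ_substitution"] == pytest.approx(-0.2, abs=0.05)
        assert st["mean_XP_YZ"] == pytest.approx(-2.34, abs=0.005)
        assert st["mean_XZ_YP"] == pytest.approx(-1.78, abs=0.005)
        assert st["pz_min"] == pytest.approx(-3.35)
        assert st["gz_min"] == pytest.approx(-2.47)
        assert st["gz_max"] == pytest.approx(1.70)
        assert st["n_pz_stacks"] == 11 and st["n_gz_stacks"] == 15


class TestRoundTrip:
    def test_stack_table_round_trip_bit_identical(self, params_pz, tmp_path):
        path = tmp_path / "stacks.txt"
        write_stack_table(params_pz.stacks, path)
        back = read_stack_table(path)
        assert set(back) == set(params_pz.stacks)
        for key, p in params_pz.stacks.items():
            q = back[key]
            assert q.dG37 == p.dG37 and q.dH == p.dH and q.dS == p.dS

    def test_loading_is_deterministic(self, params_pz):
        again = load_parameter_set("DNA-PZ")
        assert np.array_equal(again.loops.int22, params_pz.loops.int22)
        assert np.array_equal(again.stack_dG, params_pz.stack_dG)
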