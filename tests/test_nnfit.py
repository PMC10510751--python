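"""Stack-parameter regression: recovery, OLS oracle, end-penalty test."""

import numpy as np
import pytest
from scipy.optimize import minimize

from pzfold.duplex import DuplexSpec, duplex_dG37
from pzfold.fixtures import gen_duplex_dataset
from pzfold.nnfit import (
    END_PENALTY_TERM,
    FitStage,
    MeltSummary,
    StackRegression,
    end_penalty_report,
    residual_stability,
)

PZ = frozenset("PZ")
GZ = frozenset("GZ")


def pz_truth(params, shift=0.0):
    """Planted values for the 11 P-Z (non-G-Z) stacks."""
    out = {}
    for key, p in params.stacks.items():
        pairs = [frozenset((key[0][c], key[1][c])) for c in (0, 1)]
        if PZ in pairs and GZ not in pairs:
            out[key] = p.dG37 + shift
    return out


class TestResidualStability:
    def test_all_fixed_duplex(self, params_pz):
        d = DuplexSpec.self_duplex("GACGTC")
        s = MeltSummary(d, dG37_exp=duplex_dG37(d, params_pz), id="x")
        assert residual_stability(s, params_pz) == pytest.approx(0.0)

    def test_planted_free_stack_value_recovered(self, params_pz):
        # one P-Z stack inside canonical flanks; the residual is its value
        d = DuplexSpec.from_strings("GACPGC", "GCZGTC")
        free_key = params_pz.stack_key(("C", "P"), ("G", "Z"))
        pred = duplex_dG37(d, params_pz)
        s = MeltSummary(d, dG37_exp=pred, id="x")
        r = residual_stability(s, params_pz)
        # two free stacks straddle the P-Z pair: CP/GZ and PG/ZC
        other = params_pz.stack_key(("P", "G"), ("Z", "C"))
        assert r == pytest.approx(params_pz.stacks[free_key].dG37
                                  + params_pz.stacks[other].dG37)


class TestFitStage:
    def test_exact_recovery_noise_free(self, params_pz):
        truth = pz_truth(params_pz, shift=0.37)
        data = gen_duplex_dataset(40, truth, 0.0, seed=5, params=params_pz)
        res = StackRegression(data, FitStage("pz"), params_pz).fit()
        for key, v in truth.items():
            name = StackRegression._term_name(key)
            assert res.estimates[name] == pytest.approx(v, abs=1e-9)
        assert res.design_matrix_rank == len(truth)

    def test_ols_equals_brute_force_minimization(self, params_pz):
        """Normal-equation OLS equals direct minimization of the objective."""
        truth = pz_truth(params_pz)
        small = {k: truth[k] for k in list(truth)[:4]}
        data = gen_duplex_dataset(14, small, 0.25, seed=8, params=params_pz)
        model = StackRegression(data, FitStage("pz"), params_pz)
        res = model.fit()
        tab = model.design_matrix()
        y = tab.pop("__y__").to_numpy()
        X = tab.to_numpy()

        def sse(beta):
            return float(np.sum((y - X @ beta) ** 2))

        direct = minimize(sse, np.zeros(X.shape[1]), method="Nelder-Mead",
                          options={"xatol": 1e-10, "fatol": 1e-14,
                                   "maxiter": 20000})
        assert np.allclose(res.estimates.to_numpy(), direct.x, atol=1e-5)

    def test_refit_with_on_model_duplex_unchanged(self, params_pz):
        truth = pz_truth(params_pz)
        data = gen_duplex_dataset(30, truth, 0.2, seed=9, params=params_pz)
        model = StackRegression(data, FitStage("pz"), params_pz)
        res = model.fit()
        # append a duplex lying exactly on the fitted model: y = fixed part
        # + fitted values of its free stacks
        from pzfold.nnfit import _fixed_prediction, _stack_keys

        d = DuplexSpec.from_strings("GACPGC", "GCZGTC")
        fitted = dict(zip(model.columns, res.estimates))
        y = _fixed_prediction(d, params_pz, FitStage("pz"))
        for k in _stack_keys(d, params_pz):
            name = StackRegression._term_name(k)
            if name in fitted:
                y += fitted[name]
        data2 = data + [MeltSummary(d, dG37_exp=y, id="onmodel")]
        res2 = StackRegression(data2, FitStage("pz"), params_pz).fit()
        assert np.allclose(res.estimates.to_numpy(),
                           res2.estimates.to_numpy(), atol=1e-9)

    def test_coverage_with_noise(self, params_pz):
        """95% CIs cover planted truth at the expected rate (reduced reps;
        the acceptance suite runs the full 200)."""
        truth = pz_truth(params_pz)
        names = {k: StackRegression._term_name(k) for k in truth}
        hits = total = 0
        for rep in range(30):
            data = gen_duplex_dataset(40, truth, 0.3, seed=100 + rep,
                                      params=params_pz)
            res = StackRegression(data, FitStage("pz"), params_pz).fit()
            ci = res.conf_int()
            for k, v in truth.items():
                total += 1
                hits += ci.loc[names[k], "lower"] <= v <= ci.loc[names[k], "upper"]
        assert hits / total >= 0.9

    def test_rank_deficiency_reported(self, params_pz):
        # no duplex has a terminal P-Z pair, so the end-penalty column is all
        # zeros and the term is unidentifiable
        tops = ["GACPGC", "AACPGC", "GACPGG", "TACPGC"]
        from pzfold.fixtures import _complement_strand

        data = [MeltSummary(
            DuplexSpec.from_strings(t, _complement_strand(t)),
            dG37_exp=-5.0, id=f"d{k}") for k, t in enumerate(tops)]
        with pytest.raises(ValueError, match="terminal_PZ"):
            StackRegression(
                data, FitStage("pz", include_end_penalty=True),
                params_pz).fit()


class TestEndPenalty:
    def test_zero_penalty_smaller_than_stderr(self, params_pz):
        truth = pz_truth(params_pz)
        data = gen_duplex_dataset(60, truth, 0.2, seed=21, params=params_pz,
                                  end_penalty=0.0)
        rep = end_penalty_report(data, params_pz)
        assert abs(rep["penalty_estimate"]) < rep["penalty_stderr"] * 2

    def test_planted_penalty_recovered(self, params_pz):
        truth = pz_truth(params_pz)
        data = gen_duplex_dataset(60, truth, 0.1, seed=22, params=params_pz,
                                  end_penalty=0.35)
        rep = end_penalty_report(data, params_pz)
        assert rep["penalty_estimate"] == pytest.approx(
            0.35, abs=3 * rep["penalty_stderr"])

    def test_planted_outlier_tops_residuals_and_exclusion_restores(
            self, params_pz):
        truth = pz_truth(params_pz)
        data = gen_duplex_dataset(50, truth, 0.05, seed=23, params=params_pz)
        # shift one terminal-P-Z duplex by +2 kcal/mol
        shifted = None
        out = []
        for s in data:
            if shifted is None and str(s.duplex.top)[0] in "PZ":
                shifted = s.id
                out.append(MeltSummary(s.duplex, s.dG37_exp + 2.0, id=s.id))
            else:
                out.append(s)
        assert shifted is not None
        rep = end_penalty_report(out, params_pz)
        assert rep["largest_residual_with"][0] == shifted
        model = StackRegression(
            data, FitStage("pz", include_end_penalty=True), params_pz)
        res_excl = model.fit()
        # excluding nothing reproduces fit bit-for-bit
        res_again = model.fit(())
        assert np.array_equal(res_excl.estimates.to_numpy(),
                              res_again.estimates.to_numpy())
        # excluding the outlier restores a near-zero penalty
        model_out = StackRegression(
            out, FitStage("pz", include_end_penalty=True), params_pz)
        res_clean = model_out.fit(exclude_ids=(shifted,))
        assert abs(res_clean.estimates[END_PENALTY_TERM]) < 0.2

    def test_unknown_exclusion_id(self, params_pz):
        truth = pz_truth(params_pz)
        data = gen_duplex_dataset(30, truth, 0.1, seed=4, params=params_pz)
        with pytest.raises(ValueError, match="not in the data"):
            StackRegression(data, FitStage("pz"), params_pz).fit(("nope",))


class TestEnthalpyEntropyStages:
    def test_dh_ds_consistency_at_37C(self, params_pz):
        """dG = dH - T dS holds across the three stages on shared synthetic
        data generated from a consistent parameter set."""
        rng = np.random.default_rng(31)
        truth_g = pz_truth(params_pz)
        truth_h = {k: v * 25.0 for k, v in truth_g.items()}  # arbitrary dH
        truth_s = {k: (truth_h[k] - truth_g[k]) * 1000.0 / 310.15
                   for k in truth_g}
        data_g = gen_duplex_dataset(40, truth_g, 0.0, seed=31, params=params_pz)
        data = []
        for s in data_g:
            d = s.duplex
            from pzfold.nnfit import _fixed_prediction, _stack_keys

            keys = [k for k in _stack_keys(d, params_pz) if k in truth_g]
            dH = (_fixed_prediction(d, params_pz, FitStage("dh-pz"))
                  + sum(truth_h[k] for k in keys))
            dS = (_fixed_prediction(d, params_pz, FitStage("ds-pz"))
                  + sum(truth_s[k] for k in keys))
            data.append(MeltSummary(d, s.dG37_exp, dH_exp=dH, dS_exp=dS,
                                    id=s.id))
        res_h = StackRegression(data, FitStage("dh-pz"), params_pz).fit()
        res_s = StackRegression(data, FitStage("ds-pz"), params_pz).fit()
        res_g = StackRegression(data, FitStage("pz"), params_pz).fit()
        implied = res_h.estimates - 310.15 * res_s.estimates / 1000.0
        assert np.allclose(implied.to_numpy(), res_g.estimates.to_numpy(),
                           atol=1e-6)


class TestGZStage:
    def test_gz_recovery_with_fixed_pz(self, params_pz):
        """G-Z stacks are fit holding canonical and P-Z values fixed."""
        from pzfold.nnfit import _fixed_prediction, _stack_keys

        rng = np.random.default_rng(41)
        gz_keys = [k for k in params_pz.stacks
                   if GZ in [frozenset((k[0][c], k[1][c])) for c in (0, 1)]]
        truth = {k: params_pz.stacks[k].dG37 + 0.2 for k in gz_keys}
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        flanks = [("GC", "AT"), ("CG", "GC"), ("TA", "CG")]
        data = []
        for i, key in enumerate(truth):
            for rep, (L, R) in enumerate(flanks):
                top = L + "".join(key[0]) + R
                bottom3 = ("".join(comp[b] for b in L) + "".join(key[1])
                           + "".join(comp[b] for b in R))
                d = DuplexSpec.from_strings(top, bottom3[::-1])
                fixed = _fixed_prediction(d, params_pz, FitStage("gz"))
                free = sum(truth[k2] for k2 in _stack_keys(d, params_pz)
                           if k2 in truth)
                data.append(MeltSummary(
                    d, fixed + free + 0.05 * rng.standard_normal(),
                    id=f"gz{i}_{rep}"))
        # terminal G-Z pairs give duplexes with a single free stack, breaking
        # the parity dependency of interior-only embeddings
        for j, (top, bottom3) in enumerate([
                ("CGAG", "GCTZ"), ("ATCG", "TAGZ"),
                ("ATGG", "TACZ"), ("ATGZ", "TACG")]):
            d = DuplexSpec.from_strings(top, bottom3[::-1])
            fixed = _fixed_prediction(d, params_pz, FitStage("gz"))
            free = sum(truth[k2] for k2 in _stack_keys(d, params_pz)
                       if k2 in truth)
            data.append(MeltSummary(
                d, fixed + free + 0.05 * rng.standard_normal(),
                id=f"gzt{j}"))
        res = StackRegression(data, FitStage("gz"), params_pz).fit()
        for key, v in truth.items():
            name = StackRegression._term_name(key)
            assert res.estimates[name] == pytest.approx(v, abs=0.25)
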