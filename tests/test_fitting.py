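import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pgpkinetics.errors import InvalidInputError
from pgpkinetics.fitting import (
    BindingScenario,
    DoseResponseDataset,
    FitResult,
    default_grid,
    grid_search_kd,
    predict_accumulation,
    rmse,
)
from pgpkinetics.pgp_model import (
    ATP_CYT,
    PGP_OFFSET,
    SUB_MEM,
    TKI_CYT,
    TKI_MEM,
    KineticParameters,
    build_network,
    n_variables,
)
from pgpkinetics.simulate import SolverSettings, integrate
from pgpkinetics.thermo import DrugParams

DOSES = tuple(np.logspace(-8, -4, 7))


@pytest.fixture(scope="module")
def template_dataset():
    return DoseResponseDataset(
        tki="nilotinib", doses=np.array(DOSES), readouts=np.zeros(len(DOSES))
    )


@pytest.fixture(scope="module")
def nilotinib_curve(template_dataset):
    return predict_accumulation(2e-9, template_dataset)


class TestRmse:
    def test_identical_vectors(self):
        assert rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_value(self):
        assert rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(3.5355339059327378)

    def test_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            rmse([1.0], [1.0, 2.0])

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            rmse([], [])

    @given(
        st.lists(st.floats(-10, 10), min_size=1, max_size=30),
        st.integers(0, 10**6),
    )
    def test_matches_reference_formula(self, values, seed):
        rng = np.random.default_rng(seed)
        p = np.asarray(values)
        o = p + rng.normal(size=p.size)
        expected = math.sqrt(sum((a - b) ** 2 for a, b in zip(p, o)) / p.size)
        assert rmse(p, o) == pytest.approx(expected, rel=1e-12)


class TestDataset:
    def test_zero_doses_rejected(self):
        with pytest.raises(InvalidInputError):
            DoseResponseDataset(tki="x", doses=np.array([]), readouts=np.array([]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            DoseResponseDataset(
                tki="x", doses=np.array([1e-6, 1e-5]), readouts=np.array([0.5])
            )

    def test_csv_round_trip(self, tmp_path):
        ds = DoseResponseDataset(
            tki="imatinib", doses=np.array([1e-7, 1e-6]), readouts=np.array([0.1, 0.9])
        )
        path = tmp_path / "ds.csv"
        ds.to_csv(path)
        back = DoseResponseDataset.from_csv(path, tki="imatinib")
        assert np.allclose(back.doses, ds.doses)
        assert np.allclose(back.readouts, ds.readouts)


class TestPredictAccumulation:
    def test_sbd_blind_tki_with_infinite_kd_is_flat(self):
        # no SBD binding + candidate Kd_nbd = inf leaves the pump untouched
        drugs = {"phantom": DrugParams("phantom", None, 100.0, math.inf)}
        ds = DoseResponseDataset(
            tki="phantom", doses=np.array(DOSES), readouts=np.zeros(len(DOSES))
        )
        curve = predict_accumulation(math.inf, ds, drugs=drugs)
        assert np.allclose(curve, curve[0], rtol=1e-6)
        assert curve[0] < 0.1  # pump active: accumulation far below passive

    def test_monotone_in_dose(self, nilotinib_curve):
        assert np.all(np.diff(nilotinib_curve) >= -1e-9)

    def test_stronger_binding_gives_more_accumulation(self, template_dataset, nilotinib_curve):
        weaker = predict_accumulation(2e-7, template_dataset)
        assert np.all(nilotinib_curve >= weaker - 1e-9)

    def test_normalized_to_unity_ceiling(self, nilotinib_curve):
        assert np.all(nilotinib_curve <= 1.0 + 1e-6)


class TestNoncompetitiveOccupancy:
    def test_stationary_lattice_matches_product_isotherm(self):
        # oracle: with k_cat = 0 and clamped ligand pools, the 12-state
        # lattice factorizes into three independent binding isotherms
        p = KineticParameters(Kd_P=1e-6, Kd_N=5e-7, Kd_A=1e-5, Kd_I=2e-9, k_cat=0.0)
        extra = [SUB_MEM, TKI_MEM, TKI_CYT]
        net = build_network(p, noncompetitive=True, extra_clamped=extra)
        n = n_variables(noncompetitive=True)
        y0 = np.zeros(n)
        sub_mem, tki_mem, atp, tki_cyt = 2e-6, 1e-7, 1e-5, 5e-9
        y0[SUB_MEM], y0[TKI_MEM], y0[ATP_CYT], y0[TKI_CYT] = sub_mem, tki_mem, atp, tki_cyt
        total = 1e-6
        y0[PGP_OFFSET] = total
        sol = integrate(net, y0, (0.0, 1e5), SolverSettings())
        frac = sol.y[PGP_OFFSET:, -1] / total

        p_sub = (sub_mem / p.Kd_P) / (1 + sub_mem / p.Kd_P)  # own sub-site
        p_tki = (tki_mem / p.Kd_N) / (1 + tki_mem / p.Kd_N)
        z_nbd = 1 + atp / p.Kd_A + tki_cyt / p.Kd_I
        p_nbd = [1 / z_nbd, (atp / p.Kd_A) / z_nbd, (tki_cyt / p.Kd_I) / z_nbd]
        expected = []
        for s_sub, s_tki in ((0, 0), (1, 0), (0, 1), (1, 1)):
            w = (p_sub if s_sub else 1 - p_sub) * (p_tki if s_tki else 1 - p_tki)
            expected += [w * q for q in p_nbd]
        assert np.allclose(frac, expected, atol=1e-6)


class TestGridSearch:
    def test_empty_grid_rejected(self, template_dataset):
        with pytest.raises(InvalidInputError):
            grid_search_kd(template_dataset, grid=[])

    def test_best_minimizes_grid_error(self, nilotinib_curve, template_dataset):
        ds = DoseResponseDataset(
            tki="nilotinib",
            doses=template_dataset.doses,
            readouts=nilotinib_curve,
            ground_truth_Kd=2e-9,
        )
        fit = grid_search_kd(ds, grid=np.logspace(-10, -7, 13))
        errs = [e for _, e in fit.grid]
        best_err = dict(fit.grid)[fit.best_Kd]
        assert best_err == min(errs)
        kds = [k for k, _ in fit.grid]
        assert kds == sorted(kds)

    def test_noiseless_recovery_at_nearest_grid_point(self, nilotinib_curve, template_dataset):
        ds = DoseResponseDataset(
            tki="nilotinib", doses=template_dataset.doses, readouts=nilotinib_curve
        )
        grid = np.logspace(-10, -7, 13)  # 4 points per decade
        fit = grid_search_kd(ds, grid=grid)
        nearest = grid[np.argmin(np.abs(np.log10(grid) - np.log10(2e-9)))]
        assert fit.best_Kd == pytest.approx(nearest)

    def test_tie_breaks_to_smaller_kd(self):
        ds = DoseResponseDataset(
            tki="nilotinib", doses=np.array([1e-6]), readouts=np.array([0.5])
        )
        preds = {1e-9: np.array([0.7]), 1e-8: np.array([0.7]), 1e-7: np.array([0.2])}
        fit = grid_search_kd(ds, grid=list(preds), predictions=preds)
        assert fit.best_Kd == 1e-9 and fit.tied

    def test_result_json(self, tmp_path):
        fr = FitResult(1e-9, [(1e-9, 0.0), (1e-8, 0.5)], BindingScenario.NONCOMPETITIVE)
        path = tmp_path / "fit.json"
        fr.to_json(path)
        import json

        payload = json.loads(path.read_text())
        assert payload["best_Kd_M"] == 1e-9
        assert len(payload["grid"]) == 2


class TestDefaultGrid:
    def test_span_and_density(self):
        g = default_grid()
        assert g[0] == pytest.approx(1e-10) and g[-1] == pytest.approx(1e-4)
        # 13 points per decade over 6 decades
        assert len(g) == 6 * 13 + 1
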