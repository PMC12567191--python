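import numpy as np
import pandas as pd
import pytest

from tgmo import (
    TruthParams,
    generate_oacd,
    make_screen_scenario,
    map_to_concentrations,
    simulate_bliss,
    simulate_linear,
    stepwise_fit,
    build_model_matrix,
)


def _two_drug_truth(psi=0.0, noise_sd=0.0):
    k = 2
    drugs = ["d1", "d2"]
    psi_mat = np.array([[0.0, psi], [psi, 0.0]])
    hill = {
        line: {d: (1.0, 1.0) for d in drugs}
        for line in ("cancer", "normal")
    }
    return TruthParams(
        drugs=drugs,
        cancer_lines=["cancer"],
        normal_line="normal",
        hill=hill,
        psi={"cancer": psi_mat, "normal": np.zeros((2, 2))},
        noise_sd=noise_sd,
    )


class TestExpectedViability:
    def test_vehicle_identity(self):
        truth = _two_drug_truth()
        assert truth.expected_viability("cancer", {"d1": 0.0, "d2": 0.0}) == 1.0

    def test_bliss_product_of_two_agents(self):
        # each drug alone at 80% viability: dose = IC50/4 with h=1
        truth = _two_drug_truth(psi=0.0)
        v = truth.expected_viability("cancer", {"d1": 0.25, "d2": 0.25})
        assert 100 * v == pytest.approx(64.0, abs=1e-12)

    def test_synergy_lowers_viability_below_bliss(self):
        base = _two_drug_truth(psi=0.0)
        syn = _two_drug_truth(psi=-2.0)
        conc = {"d1": 0.25, "d2": 0.25}
        v_base = base.expected_viability("cancer", conc)
        v_syn = syn.expected_viability("cancer", conc)
        assert v_syn < v_base
        # direct evaluation of the closed form
        assert v_syn == pytest.approx(0.64 * np.exp(-2.0 * 0.2 * 0.2), abs=1e-12)

    def test_antagonism_raises_viability(self):
        ant = _two_drug_truth(psi=2.0)
        v = ant.expected_viability("cancer", {"d1": 0.25, "d2": 0.25})
        assert v > 0.64

    def test_unknown_drug_rejected(self):
        truth = _two_drug_truth()
        with pytest.raises(KeyError):
            truth.expected_viability("cancer", {"ghost": 1.0})

    def test_monotone_when_psi_row_nonpositive(self):
        truth = _two_drug_truth(psi=-1.5)
        grid = np.linspace(0, 2.0, 15)
        prev = np.inf
        for c in grid:
            v = truth.expected_viability("cancer", {"d1": c, "d2": 0.4})
            assert v <= prev + 1e-12
            prev = v


class TestSimulateBliss:
    @pytest.fixture()
    def setup(self):
        truth = _two_drug_truth(psi=-1.0, noise_sd=0.0)
        design = generate_oacd(["d1", "d2"], seed=0)
        conc = pd.DataFrame(
            {
                "d1": 0.25 * design.runs[:, 0] / 2.0,
                "d2": 0.25 * design.runs[:, 1] / 2.0,
            },
            index=pd.Index(design.run_ids, name="run_id"),
        )
        return truth, design, conc

    def test_noise_free_runs_are_pure_functions(self, setup):
        truth, design, conc = setup
        a = simulate_bliss(truth, design, conc, replicates=2, seed=1)
        b = simulate_bliss(truth, design, conc, replicates=2, seed=99)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_vehicle_run_reads_exactly_100(self, setup):
        truth, design, conc = setup
        ds = simulate_bliss(truth, design, conc, replicates=3, seed=0)
        vehicle = ds.records[ds.records["run_id"] == design.vehicle_run_id]
        assert np.allclose(vehicle["viability_pct"], 100.0)

    def test_seeded_runs_bit_reproducible(self, setup):
        truth, design, conc = setup
        truth.noise_sd = 5.0
        a = simulate_bliss(truth, design, conc, replicates=3, seed=42)
        b = simulate_bliss(truth, design, conc, replicates=3, seed=42)
        pd.testing.assert_frame_equal(a.records, b.records)
        c = simulate_bliss(truth, design, conc, replicates=3, seed=43)
        assert not a.records["viability_pct"].equals(c.records["viability_pct"])

    def test_values_truncated_at_zero_not_at_100(self):
        truth = _two_drug_truth(psi=0.0, noise_sd=40.0)
        design = generate_oacd(["d1", "d2"], seed=0)
        conc = pd.DataFrame(
            np.zeros((design.n_runs, 2)),
            columns=["d1", "d2"],
            index=pd.Index(design.run_ids, name="run_id"),
        )
        ds = simulate_bliss(truth, design, conc, replicates=30, seed=7)
        v = ds.records["viability_pct"]
        assert (v >= 0).all()
        assert (v > 100).any()

    def test_unknown_concentration_column_rejected(self, setup):
        truth, design, conc = setup
        bad = conc.rename(columns={"d2": "ghost"})
        with pytest.raises(KeyError):
            simulate_bliss(truth, design, bad, replicates=1, seed=0)


class TestSimulateLinear:
    def test_intercept_only_truth_is_constant(self, k3_design):
        truth = _two_drug_truth()
        truth = TruthParams(
            drugs=list(k3_design.drug_order),
            cancer_lines=["cancer"],
            normal_line="normal",
            hill={
                line: {d: (1.0, 1.0) for d in k3_design.drug_order}
                for line in ("cancer", "normal")
            },
            psi={"cancer": np.zeros((3, 3)), "normal": np.zeros((3, 3))},
            noise_sd=0.0,
            linear_truth_beta={("intercept", ()): 100.0},
        )
        y = simulate_linear(truth, k3_design, replicates=2, seed=0)
        assert np.allclose(y, 100.0)

    def test_noiseless_truth_recovered_by_stepwise(self, k3_design):
        beta = {
            ("intercept", ()): 100.0,
            ("linear", (1,)): -12.0,
            ("interaction", (0, 2)): -6.0,
        }
        truth = TruthParams(
            drugs=list(k3_design.drug_order),
            cancer_lines=["cancer"],
            normal_line="normal",
            hill={
                line: {d: (1.0, 1.0) for d in k3_design.drug_order}
                for line in ("cancer", "normal")
            },
            psi={"cancer": np.zeros((3, 3)), "normal": np.zeros((3, 3))},
            noise_sd=0.0,
            linear_truth_beta=beta,
        )
        y = simulate_linear(truth, k3_design, replicates=3, seed=0)
        X, space = build_model_matrix(k3_design, replicates=3)
        model = stepwise_fit(X, y, space)
        assert set(model.term_keys) == set(beta)
        for term in model.terms:
            assert term.beta == pytest.approx(beta[term.key], abs=1e-8)

    def test_beta_for_absent_drug_rejected(self, k3_design):
        truth = TruthParams(
            drugs=list(k3_design.drug_order),
            cancer_lines=["cancer"],
            normal_line="normal",
            hill={
                line: {d: (1.0, 1.0) for d in k3_design.drug_order}
                for line in ("cancer", "normal")
            },
            psi={"cancer": np.zeros((3, 3)), "normal": np.zeros((3, 3))},
            noise_sd=0.0,
            linear_truth_beta={("linear", (7,)): 1.0},
        )
        with pytest.raises(ValueError, match="absent drug"):
            simulate_linear(truth, k3_design, replicates=1, seed=0)


class TestPaperScenario:
    def test_planted_roles_by_construction(self):
        truth = make_screen_scenario(seed=0)
        assert len(truth.drugs) == 10
        assert len(truth.roles["round1_detrimental"]) == 3
        i, j = (truth.drugs.index(d) for d in truth.roles["synergy_pair"])
        for line in truth.cancer_lines:
            assert truth.psi[line][i, j] < 0
        assert truth.psi[truth.normal_line][i, j] == 0.0

    def test_osimertinib_toxic_to_normal_line_alone(self):
        from tgmo import CLINICAL_DOSES_UM

        truth = make_screen_scenario(seed=0)
        dose = CLINICAL_DOSES_UM["osimertinib"]
        v = truth.monotherapy_viability(truth.normal_line, "osimertinib", dose)
        assert 100 * float(v) == pytest.approx(65.0, abs=1e-9)
        for drug in set(truth.drugs) - {"osimertinib"}:
            v = truth.monotherapy_viability(
                truth.normal_line, drug, CLINICAL_DOSES_UM[drug]
            )
            assert 100 * float(v) > 99.0

    def test_deterministic_given_seed(self):
        a = make_screen_scenario(seed=5)
        b = make_screen_scenario(seed=5)
        assert a.drugs == b.drugs
        for line in a.lines:
            assert np.array_equal(a.psi[line], b.psi[line])

    def test_invalid_psi_rejected(self):
        truth = _two_drug_truth()
        with pytest.raises(ValueError, match="symmetric"):
            TruthParams(
                drugs=truth.drugs,
                cancer_lines=truth.cancer_lines,
                normal_line=truth.normal_line,
                hill=truth.hill,
                psi={"cancer": np.array([[0.0, 1.0], [2.0, 0.0]]),
                     "normal": np.zeros((2, 2))},
            )
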