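import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from trichoproj.calibration import (
    AVOGADRO,
    CultureTable,
    EffectParameters,
    cells_per_ml,
    derive_effect_parameters,
    dna_p_quota,
    ethylene_to_n2,
    normalized_rate,
    paired_t_test,
    percent_change,
    rna_p_quota,
    stoichiometric_ratio,
    synthetic_culture_table,
)
from trichoproj.errors import (
    ConfigurationError,
    DegenerateVarianceError,
    DomainError,
    PairingError,
)

positive = st.floats(min_value=1e-6, max_value=1e6, allow_nan=False)


class TestPercentChange:
    def test_printed_stoichiometry_declines(self):
        # POC:POP 332:1 -> 202:1 and PON:POP 48:1 -> 31:1
        assert round(percent_change(332, 202), 1) == -39.2
        assert round(percent_change(48, 31)) == -35

    def test_identity_and_domain(self):
        assert percent_change(5.0, 5.0) == 0.0
        with pytest.raises(DomainError):
            percent_change(0.0, 1.0)

    @given(a=positive, b=positive, k=positive)
    def test_rescaling_invariance_and_sign_flip(self, a, b, k):
        assert percent_change(k * a, k * b) == pytest.approx(
            percent_change(a, b), rel=1e-9, abs=1e-9
        )
        assert math.copysign(1, percent_change(a, b)) == -math.copysign(
            1, percent_change(b, a)
        ) or percent_change(a, b) == 0


class TestRatesAndRatios:
    def test_normalized_rate(self):
        assert normalized_rate(10, 5) == 2
        assert normalized_rate(0, 5) == 0
        with pytest.raises(DomainError):
            normalized_rate(1, 0)

    def test_triplicate_means_match_loop_oracle(self):
        rng = np.random.default_rng(11)
        rates = rng.uniform(0.5, 3.0, size=3)
        quotas = rng.uniform(100, 900, size=3)
        vectorized = np.mean([normalized_rate(r, q) for r, q in zip(rates, quotas)])
        acc = 0.0
        for i in range(3):  # brute-force loop oracle
            acc += rates[i] / quotas[i]
        assert vectorized == pytest.approx(acc / 3, rel=1e-12)

    def test_stoichiometric_ratio(self):
        assert stoichiometric_ratio(48, 1) == 48
        assert stoichiometric_ratio(7.5, 7.5) == 1
        assert stoichiometric_ratio(202, 1) / stoichiometric_ratio(332, 1) == (
            pytest.approx(1 + percent_change(332, 202) / 100, rel=1e-12)
        )
        with pytest.raises(DomainError):
            stoichiometric_ratio(-1, 2)


class TestEffectParameters:
    def test_defaults_match_calibration_constants(self):
        p = EffectParameters()
        assert p.h0 == pytest.approx(10**-8.01)
        assert p.h1 == pytest.approx(10**-7.81)
        assert (p.oa, p.oap_c, p.oap_n) == (-0.184, -0.392, -0.101)

    def test_invalid_anchors_rejected(self):
        with pytest.raises(ConfigurationError):
            EffectParameters(h0=1e-8, h1=1e-9)
        with pytest.raises(ConfigurationError):
            EffectParameters(oa=-1.5)

    def test_derivation_from_printed_treatment_means(self):
        # Treatment means engineered to give POC:POP of 332 and 202.
        rows = []
        for rep, (amb_poc, acid_poc) in enumerate([(300, 180), (364, 224)], 1):
            rows.append(dict(treatment="ambient", replicate=rep, poc=amb_poc,
                             pop=1.0, pon=48.0, n2_fix_per_cell=1.0,
                             c_fix_per_cell=10.0))
            rows.append(dict(treatment="acidified", replicate=rep, poc=acid_poc,
                             pop=1.0, pon=31.0, n2_fix_per_cell=0.55,
                             c_fix_per_cell=9.0))
        table = CultureTable(pd.DataFrame(rows))
        params = derive_effect_parameters(table)
        assert params.oap_c == pytest.approx((202 - 332) / 332, rel=1e-12)
        assert round(100 * params.oap_c, 1) == -39.2

    def test_identical_treatments_give_zero_effects(self):
        table = synthetic_culture_table(effect={})
        params = derive_effect_parameters(table)
        assert params.oap_c == 0 and params.oap_n == 0

    def test_random_table_matches_loop_oracle(self):
        table = synthetic_culture_table(
            n_replicates=5, seed=2, noise_cv=0.2,
            effect={"poc": 0.8, "pop": 1.3, "n2_fix_per_cell": 0.7},
        )
        params = derive_effect_parameters(table)
        # Brute-force oracle straight off the raw rows.
        sums = {("ambient", c): 0.0 for c in ("poc", "pop", "n2_fix_per_cell")}
        sums.update({("acidified", c): 0.0 for c in ("poc", "pop", "n2_fix_per_cell")})
        counts = {"ambient": 0, "acidified": 0}
        for _, row in table.data.iterrows():
            counts[row.treatment] += 1
            for c in ("poc", "pop", "n2_fix_per_cell"):
                sums[(row.treatment, c)] += row[c]
        mean = lambda t, c: sums[(t, c)] / counts[t]
        exp_c = (mean("acidified", "poc") / mean("acidified", "pop")) / (
            mean("ambient", "poc") / mean("ambient", "pop")
        ) - 1
        exp_n = (
            mean("acidified", "n2_fix_per_cell") / mean("acidified", "poc")
        ) / (mean("ambient", "n2_fix_per_cell") / mean("ambient", "poc")) - 1
        assert params.oap_c == pytest.approx(exp_c, rel=1e-12)
        assert params.oap_n == pytest.approx(exp_n, rel=1e-12)

    def test_parameter_recovery_exact_without_noise(self):
        effect = {"poc": 0.78, "pop": 1.28, "n2_fix_per_cell": 0.70}
        table = synthetic_culture_table(effect=effect, noise_cv=0.0)
        params = derive_effect_parameters(table)
        assert params.oap_c == pytest.approx(0.78 / 1.28 - 1, rel=1e-12)
        assert params.oap_n == pytest.approx(0.70 / 0.78 - 1, rel=1e-12)

    def test_parameter_recovery_within_noise_tolerance(self):
        effect = {"poc": 0.78, "pop": 1.28, "n2_fix_per_cell": 0.70}
        table = synthetic_culture_table(
            n_replicates=400, seed=5, effect=effect, noise_cv=0.05
        )
        params = derive_effect_parameters(table)
        assert params.oap_c == pytest.approx(0.78 / 1.28 - 1, abs=0.02)
        assert params.oap_n == pytest.approx(0.70 / 0.78 - 1, abs=0.02)

    def test_unpaired_replicates_rejected(self):
        df = synthetic_culture_table().data
        df = df[~((df.treatment == "acidified") & (df.replicate == 1))]
        with pytest.raises(PairingError):
            CultureTable(df)

    def test_csv_round_trip(self, tmp_path):
        table = synthetic_culture_table(seed=9, noise_cv=0.1, effect={"poc": 0.8})
        path = tmp_path / "culture.csv"
        table.to_csv(path)
        back = CultureTable.from_csv(path)
        pd.testing.assert_frame_equal(back.data, table.data)


class TestPairedT:
    def test_symmetric_differences_give_zero_t(self):
        t, p = paired_t_test([(1, 2), (2, 1), (3, 4), (4, 3)])
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_against_textbook_formula_oracle(self):
        pairs = [(1, 2), (2, 4), (3, 5), (4, 7)]
        t, p = paired_t_test(pairs)
        d = np.array([b - a for a, b in pairs], dtype=float)
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        from scipy.stats import t as tdist

        p_oracle = 2 * tdist.sf(abs(t_oracle), df=len(d) - 1)
        assert t == pytest.approx(t_oracle, rel=1e-12)
        assert p == pytest.approx(p_oracle, rel=1e-12)

    def test_one_tailed_is_half_two_tailed(self):
        pairs = [(1.0, 0.8), (1.2, 0.9), (0.9, 0.85), (1.1, 0.7)]
        _, p2 = paired_t_test(pairs, tails=2)
        _, p1 = paired_t_test(pairs, tails=1)
        assert p1 == pytest.approx(p2 / 2, rel=1e-12)

    def test_low_power_case_not_significant(self):
        _, p = paired_t_test([(10.0, 10.2), (12.0, 11.5), (11.0, 11.1)])
        assert p > 0.05

    def test_degenerate_and_domain_errors(self):
        with pytest.raises(DegenerateVarianceError):
            paired_t_test([(1, 2), (3, 4), (5, 6)])
        with pytest.raises(DomainError):
            paired_t_test([(1, 2)])


class TestQuotasAndConversions:
    def test_cells_per_ml_examples(self):
        lengths = [100.0] * 20
        counts = [20] * 20
        assert cells_per_ml(1e6, lengths, counts) == pytest.approx(2e5)
        assert cells_per_ml(100.0, [100.0], [10]) == pytest.approx(10.0)

    def test_cells_per_ml_loop_oracle(self):
        rng = np.random.default_rng(3)
        lengths = rng.uniform(50, 400, size=20)
        counts = rng.integers(5, 60, size=20)
        total = 7.3e5
        got = cells_per_ml(total, lengths, counts)
        sum_len = sum_cells = 0.0
        for L, c in zip(lengths, counts):
            sum_len += L
            sum_cells += c
        assert got == pytest.approx(total / (sum_len / sum_cells), rel=1e-12)

    def test_cells_per_ml_zero_cells_rejected(self):
        with pytest.raises(DomainError):
            cells_per_ml(1e6, [100.0], [0])

    def test_dna_p_quota_genome_arithmetic(self):
        # 7,750,108 bp x 100 copies x 2 P per bp = 1.5500216e9 atoms
        got = dna_p_quota(7_750_108, 100)
        atoms = 2 * 7_750_108 * 100
        assert atoms == 1_550_021_600
        assert got == pytest.approx(atoms / AVOGADRO * 1e15, rel=1e-12)
        assert got == pytest.approx(2.574, abs=5e-4)

    def test_dna_p_quota_edge_cases(self):
        assert dna_p_quota(1, 1) == pytest.approx(2 / AVOGADRO * 1e15, rel=1e-12)
        with pytest.raises(DomainError):
            dna_p_quota(7_750_108, 0)

    def test_rna_p_quota(self):
        assert rna_p_quota(1000.0) == pytest.approx(3.120, abs=5e-4)
        assert rna_p_quota(0.0) == 0.0
        assert rna_p_quota(320.5) == pytest.approx(1.0, rel=1e-12)
        with pytest.raises(DomainError):
            rna_p_quota(-1.0)

    def test_ethylene_conversion(self):
        assert ethylene_to_n2(8.0) == 2.0
        assert ethylene_to_n2(0.0) == 0.0
        assert ethylene_to_n2(1.0) == 0.25
        with pytest.raises(DomainError):
            ethylene_to_n2(-0.1)
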