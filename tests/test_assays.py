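"""Pigment equations, DPPH, standard curves, and LSD letter display."""

import itertools

import numpy as np
import pytest
from scipy import stats

from drykin import (
    anova_lsd_letters,
    dpph_inhibition,
    pigments,
    standard_curve_quantify,
)
from drykin.simulate import generate_assay_table


class TestPigments:
    def test_zero_absorbance(self):
        p = pigments(0.0, 0.0, 0.0)
        assert (p.chl_a, p.chl_b, p.carotenoids) == (0.0, 0.0, 0.0)
        assert not p.any_negative

    def test_plug_in_example(self):
        p = pigments(1.0, 0.0, 0.1)
        assert p.chl_a == pytest.approx(12.25)
        assert p.chl_b == pytest.approx(-4.91)
        assert p.carotenoids == pytest.approx(2.0787, abs=5e-5)
        assert p.any_negative

    def test_linearity(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.uniform(0, 2, 3)
            y = rng.uniform(0, 2, 3)
            c = rng.uniform(0.1, 5)
            px, py = pigments(*x), pigments(*y)
            psum = pigments(*(x + y))
            pscaled = pigments(*(c * x))
            for attr in ("chl_a", "chl_b", "carotenoids"):
                assert getattr(psum, attr) == pytest.approx(
                    getattr(px, attr) + getattr(py, attr), abs=1e-12)
                assert getattr(pscaled, attr) == pytest.approx(
                    c * getattr(px, attr), abs=1e-12)

    def test_negative_absorbance_rejected(self):
        with pytest.raises(ValueError):
            pigments(-0.1, 0.0, 0.0)


class TestDpph:
    @pytest.mark.parametrize("a_test,a_control,expected", [
        (0.5, 0.5, 0.0),
        (0.0, 0.5, 100.0),
        (0.25, 0.5, 50.0),
    ])
    def test_examples(self, a_test, a_control, expected):
        assert dpph_inhibition(a_test, a_control) == pytest.approx(expected)

    def test_strictly_decreasing_in_test_absorbance(self):
        vals = [dpph_inhibition(a, 0.8) for a in np.linspace(0, 1.2, 50)]
        assert np.all(np.diff(vals) < 0)

    def test_pro_oxidant_reading_allowed(self):
        assert dpph_inhibition(0.6, 0.5) < 0

    def test_control_must_be_positive(self):
        with pytest.raises(ValueError):
            dpph_inhibition(0.2, 0.0)


class TestStandardCurve:
    def test_perfect_line(self):
        cal = [(0.0, 0.0), (0.5, 1.0), (1.0, 2.0)]
        value, info = standard_curve_quantify(cal, sample_abs=1.0)
        assert info["raw_concentration"] == pytest.approx(0.5)
        assert not info["extrapolated"]
        assert value == pytest.approx(0.5)  # default scaling 100/100 g

    def test_zero_slope_rejected(self):
        cal = [(0.0, 1.0), (0.5, 1.0), (1.0, 1.0)]
        with pytest.raises(ValueError):
            standard_curve_quantify(cal, 1.0)

    def test_extrapolation_flagged(self):
        cal = [(0.0, 0.0), (0.5, 1.0), (1.0, 2.0)]
        _, info = standard_curve_quantify(cal, sample_abs=5.0)
        assert info["extrapolated"]

    def test_noisy_recovery_within_two_percent(self):
        rng = np.random.default_rng(21)
        conc = np.linspace(0.1, 1.0, 8)
        slope, intercept = 1.8, 0.05
        for spiked in (0.3, 0.6, 0.9):
            absorb = slope * conc + intercept + rng.normal(0, 0.005, conc.size)
            _, info = standard_curve_quantify(
                list(zip(conc, absorb)), slope * spiked + intercept)
            assert info["raw_concentration"] == pytest.approx(spiked, rel=0.02)


class TestLsdLetters:
    def test_identical_groups_share_single_letter(self):
        table = anova_lsd_letters({"A": [1.0, 1.1, 0.9],
                                   "B": [1.0, 1.1, 0.9],
                                   "C": [1.0, 1.1, 0.9]})
        assert set(table.letters.values()) == {"a"}

    def test_widely_separated_groups_all_distinct(self):
        table = anova_lsd_letters({"low": [0, 0, 0.01],
                                   "mid": [10, 10, 10.01],
                                   "high": [20, 20, 20.01]})
        letters = table.letters
        assert len({letters[g] for g in letters}) == 3
        assert letters["high"] == "a"  # highest mean gets 'a'
        assert letters["low"] == "c"

    def test_degenerate_zero_variance_distinct_means(self):
        table = anova_lsd_letters({"A": [1.0, 1.0], "B": [2.0, 2.0]})
        assert not table.share_letter("A", "B")

    def test_protected_gate_blocks_pairwise_tests(self):
        groups = {"A": [1.00, 1.02, 0.98], "B": [1.01, 0.99, 1.03],
                  "C": [1.02, 1.00, 0.97]}
        table = anova_lsd_letters(groups, protected=True)
        assert table.p_value > 0.05
        assert set(table.letters.values()) == {"a"}

    def test_order_invariance(self):
        rng = np.random.default_rng(8)
        groups = {f"g{i}": rng.normal(i * 0.5, 0.3, 4) for i in range(5)}
        t1 = anova_lsd_letters(groups)
        t2 = anova_lsd_letters(dict(reversed(list(groups.items()))))
        for a, b in itertools.combinations(groups, 2):
            assert t1.share_letter(a, b) == t2.share_letter(a, b)

    def test_validation(self):
        with pytest.raises(ValueError):
            anova_lsd_letters({"A": [1, 2]})
        with pytest.raises(ValueError):
            anova_lsd_letters({"A": [1, 2], "B": [3]})

    def _oracle_decisions(self, groups, alpha=0.05):
        """Brute-force all-pairs protected LSD, written independently."""
        names = list(groups)
        data = [np.asarray(groups[n], float) for n in names]
        k = len(names)
        ntot = sum(len(d) for d in data)
        grand = np.concatenate(data).mean()
        ssb = sum(len(d) * (d.mean() - grand) ** 2 for d in data)
        ssw = sum(((d - d.mean()) ** 2).sum() for d in data)
        dfe = ntot - k
        mse = ssw / dfe
        F = (ssb / (k - 1)) / mse
        if stats.f.sf(F, k - 1, dfe) > alpha:
            return set()
        tcrit = stats.t.ppf(1 - alpha / 2, dfe)
        out = set()
        for i in range(k):
            for j in range(i + 1, k):
                lsd = tcrit * np.sqrt(mse * (1 / len(data[i]) + 1 / len(data[j])))
                if abs(data[i].mean() - data[j].mean()) > lsd:
                    out.add(frozenset((names[i], names[j])))
        return out

    def test_letter_sharing_matches_allpairs_oracle(self):
        rng = np.random.default_rng(99)
        for rep in range(50):
            k = int(rng.integers(3, 7))
            n = int(rng.integers(3, 6))
            means = rng.uniform(0, 4, k)
            sd = rng.uniform(0.05, 1.0)
            groups = generate_assay_table(k, n, means, sd, seed=rep)
            table = anova_lsd_letters(groups)
            sig = self._oracle_decisions(groups)
            for a, b in itertools.combinations(groups, 2):
                expected_diff = frozenset((a, b)) in sig
                assert table.share_letter(a, b) == (not expected_diff), \
                    (rep, a, b)
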