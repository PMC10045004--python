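"""Phytochemical assay arithmetic and group statistics for dried produce.

Covers the spectrophotometric work-up that typically accompanies a
drying study of green plant material:

* chlorophyll a / b and total carotenoids from acetone-extract
  absorbances at 663.6, 646.6 and 470.0 nm (the linear equations of
  Lichtenthaler's tradition);
* DPPH radical-scavenging percent inhibition;
* quantification against an external standard curve (gallic-acid or
  quercetin equivalents for total phenolics / flavonoids);
* one-way ANOVA with Fisher's LSD pairwise tests and a compact-letter
  display, the standard way such tables annotate which drying
  conditions differ at p <= alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PigmentResult",
    "pigments",
    "dpph_inhibition",
    "StandardCurve",
    "standard_curve_quantify",
    "AssayTable",
    "anova_lsd_letters",
]


@dataclass(frozen=True)
class PigmentResult:
    """Pigment concentrations in ug/mL of extract."""

    chl_a: float
    chl_b: float
    carotenoids: float

    @property
    def any_negative(self) -> bool:
        """The linear forms can return negative values for some spectra."""
        return self.chl_a < 0 or self.chl_b < 0 or self.carotenoids < 0


def pigments(a663_6: float, a646_6: float, a470: float) -> PigmentResult:
    """Chlorophyll a, b and total carotenoids (ug/mL) from absorbances.

    chl_a = 12.25 A663.6 - 2.25 A646.6
    chl_b = 20.31 A646.6 - 4.91 A663.6
    carotenoids = (1000 A470 - 2.27 chl_a - 81.4 chl_b) / 227

    The map is linear, so outputs scale with the absorbances; negative
    outputs are possible and flagged on the result, not raised.
    """
    if a663_6 < 0 or a646_6 < 0 or a470 < 0:
        raise ValueError("absorbances must be non-negative")
    chl_a = 12.25 * a663_6 - 2.25 * a646_6
    chl_b = 20.31 * a646_6 - 4.91 * a663_6
    caro = (1000.0 * a470 - 2.27 * chl_a - 81.4 * chl_b) / 227.0
    return PigmentResult(chl_a=chl_a, chl_b=chl_b, carotenoids=caro)


def dpph_inhibition(a_test: float, a_control: float) -> float:
    """DPPH percent inhibition ``(1 - A_test / A_control) * 100``.

    Negative values (pro-oxidant readings) are allowed and returned
    as-is.
    """
    if a_control <= 0:
        raise ValueError("control absorbance must be positive")
    if a_test < 0:
        raise ValueError("test absorbance must be non-negative")
    return (1.0 - a_test / a_control) * 100.0


@dataclass(frozen=True)
class StandardCurve:
    slope: float
    intercept: float
    conc_min: float
    conc_max: float

    def invert(self, absorbance: float) -> float:
        return (absorbance - self.intercept) / self.slope


def standard_curve_quantify(calibration: Sequence[tuple[float, float]],
                            sample_abs: float,
                            dilution_factor: float = 1.0,
                            basis_mass_g: float = 100.0,
                            ) -> tuple[float, dict]:
    """Quantify an analyte against an external calibration line.

    Parameters
    ----------
    calibration : sequence of (concentration, absorbance)
        At least 3 points; the fitted line must have positive slope.
    sample_abs : float
        Measured absorbance of the (possibly diluted) sample.
    dilution_factor, basis_mass_g : float
        Scale the back-calculated concentration to analyte per 100 g of
        dry weight: ``conc * dilution_factor * 100 / basis_mass_g``.

    Returns
    -------
    (value, info)
        ``info['extrapolated']`` flags samples outside the calibration
        concentration range.
    """
    cal = np.asarray(calibration, dtype=float)
    if cal.ndim != 2 or cal.shape[0] < 3 or cal.shape[1] != 2:
        raise ValueError("need >= 3 (concentration, absorbance) pairs")
    conc, absb = cal[:, 0], cal[:, 1]
    if np.ptp(conc) == 0:
        raise ValueError("singular calibration: identical concentrations")
    slope, intercept = np.polyfit(conc, absb, 1)
    if slope <= 1e-12:  # flat or inverted calibration
        raise ValueError(f"calibration slope must be positive (got {slope:.3g})")
    curve = StandardCurve(float(slope), float(intercept),
                          float(conc.min()), float(conc.max()))
    raw = curve.invert(sample_abs)
    value = raw * dilution_factor * 100.0 / basis_mass_g
    info = {
        "curve": curve,
        "raw_concentration": raw,
        "extrapolated": bool(raw < curve.conc_min or raw > curve.conc_max),
    }
    return value, info


# --------------------------------------------------------------------------
# one-way ANOVA + Fisher's LSD + compact-letter display

@dataclass
class AssayTable:
    """Per-condition assay replicates with LSD letter annotation."""

    conditions: list[str]
    replicates: dict[str, np.ndarray]
    means: dict[str, float]
    sds: dict[str, float]
    letters: dict[str, str]
    f_statistic: float
    p_value: float
    mse: float
    df_error: int
    alpha: float
    significant_pairs: frozenset[frozenset] = field(default_factory=frozenset)

    def share_letter(self, g1: str, g2: str) -> bool:
        return bool(set(self.letters[g1]) & set(self.letters[g2]))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "condition": c,
                "n": len(self.replicates[c]),
                "mean": self.means[c],
                "sd": self.sds[c],
                "letters": self.letters[c],
                "annotated": f"{self.means[c]:.2f} ± {self.sds[c]:.2f} {self.letters[c]}",
            }
            for c in self.conditions
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        head = (f"One-way ANOVA: F = {self.f_statistic:.4g}, "
                f"p = {self.p_value:.4g}, MSE = {self.mse:.4g}, "
                f"alpha = {self.alpha}")
        return head + "\n" + self.to_frame().to_string(index=False)


def _lsd_decisions(groups: dict[str, np.ndarray], alpha: float,
                   protected: bool) -> tuple[set, float, float, float, int]:
    """All-pairs LSD significance decisions from the pooled ANOVA error.

    Returns (significant_pairs, F, p, MSE, df_error).  With zero pooled
    error and distinct group means (degenerate MSE) every distinct-mean
    pair is declared different.
    """
    names = list(groups)
    k = len(names)
    n_total = sum(len(v) for v in groups.values())
    grand = np.concatenate(list(groups.values())).mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(float(np.sum((v - v.mean()) ** 2)) for v in groups.values())
    df_b, df_e = k - 1, n_total - k
    mse = ss_within / df_e
    if mse == 0.0:
        f_stat = np.inf if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
        sig = {
            frozenset((a, b))
            for i, a in enumerate(names) for b in names[i + 1:]
            if groups[a].mean() != groups[b].mean()
        }
        return sig, f_stat, p, mse, df_e
    f_stat = (ss_between / df_b) / mse
    p = float(stats.f.sf(f_stat, df_b, df_e))
    if protected and p > alpha:
        return set(), f_stat, p, mse, df_e
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df_e)
    sig = set()
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            lsd = tcrit * np.sqrt(mse * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
            if abs(groups[a].mean() - groups[b].mean()) > lsd:
                sig.add(frozenset((a, b)))
    return sig, f_stat, p, mse, df_e


def _compact_letter_display(names_by_mean_desc: list[str],
                            significant: set) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups not significantly different share at least one letter;
    significantly different groups share none.  Letters are assigned in
    descending-mean order, so 'a' marks the highest-mean grouping.
    """
    columns: list[set] = [set(names_by_mean_desc)]
    for pair in sorted(significant, key=lambda p: sorted(p)):
        g1, g2 = sorted(pair)
        new_cols: list[set] = []
        for col in columns:
            if g1 in col and g2 in col:
                new_cols.append(col - {g1})
                new_cols.append(col - {g2})
            else:
                new_cols.append(col)
        # absorb: drop any column contained in another
        columns = [
            c for i, c in enumerate(new_cols)
            if c and not any(i != j and c < d or (c == d and i > j)
                             for j, d in enumerate(new_cols))
        ]
    rank = {n: i for i, n in enumerate(names_by_mean_desc)}
    columns.sort(key=lambda c: min(rank[n] for n in c))
    letters = {n: "" for n in names_by_mean_desc}
    for idx, col in enumerate(columns):
        letter = chr(ord("a") + idx)
        for n in col:
            letters[n] += letter
    return {n: "".join(sorted(s)) for n, s in letters.items()}


def anova_lsd_letters(groups: Mapping[str, Sequence[float]],
                      alpha: float = 0.05,
                      protected: bool = True) -> AssayTable:
    """One-way ANOVA with LSD pairwise tests and letter annotation.

    Parameters
    ----------
    groups : mapping condition -> replicate values
        At least 2 conditions with at least 2 replicates each.
    alpha : float
        Significance level of both the omnibus F test and the pairwise
        LSD comparisons.
    protected : bool
        Fisher's protected LSD (default): pairwise tests are only run
        when the omnibus F is significant at ``alpha``; otherwise every
        pair is declared not different.  Set False for unprotected
        all-pairs testing.

    Returns
    -------
    AssayTable
        Letter sharing encodes the pairwise decisions: conditions that
        are *not* significantly different share at least one letter.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 conditions")
    arrs = {str(kk): np.asarray(v, dtype=float) for kk, v in groups.items()}
    for name, v in arrs.items():
        if v.size < 2:
            raise ValueError(f"condition {name!r} needs >= 2 replicates")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite replicate in {name!r}")
    sig, f_stat, p, mse, df_e = _lsd_decisions(arrs, alpha, protected)
    means = {n: float(v.mean()) for n, v in arrs.items()}
    sds = {n: float(v.std(ddof=1)) for n, v in arrs.items()}
    order = sorted(arrs, key=lambda n: -means[n])
    letters = _compact_letter_display(order, sig)
    return AssayTable(
        conditions=list(arrs),
        replicates=arrs,
        means=means,
        sds=sds,
        letters=letters,
        f_statistic=float(f_stat),
        p_value=float(p),
        mse=float(mse),
        df_error=int(df_e),
        alpha=alpha,
        significant_pairs=frozenset(sig),
    )
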