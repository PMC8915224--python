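"""Adiposity cutoff derivation, FFR classification, and diagnostics.

The cutoff chain: nBFV cutoffs are midpoints of adjacent fat-category
medians (overweight cutoff = (median_normal + median_overweight)/2,
obese cutoff = (median_overweight + median_obese)/2), then mapped onto
the FFR scale through the fitted ln-ln regression
ln(FFR) = a + b*ln(nBFV), and onto the %BF scale through the linear
%BF-on-nBFV regression.

Classification by FFR uses half-open intervals: obese when
FFR >= obese cutoff, overweight when overweight cutoff <= FFR < obese
cutoff, otherwise not overweight (FFR alone cannot separate normal from
underweight).  Diagnostic performance against the visual fat category is
a 2x2 table with exact (Clopper-Pearson) binomial confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from ._util import round_half_away

FFR_CLASSES = ("not_overweight", "overweight", "obese")


@dataclass(frozen=True)
class RegressionFit:
    """A simple linear fit, possibly on log-transformed axes."""

    intercept: float
    slope: float
    r: float = float("nan")
    r2: float = float("nan")
    p: float = float("nan")
    transform: str = "none"  # none | ln_ln | ln_y

    def __post_init__(self) -> None:
        if self.transform not in ("none", "ln_ln", "ln_y"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if not math.isnan(self.r) and abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| must not exceed 1")

    def predict(self, x: float) -> float:
        """Evaluate on the response's natural scale."""
        if self.transform == "none":
            return self.intercept + self.slope * x
        if x <= 0:
            raise ValueError("ln transform requires positive input")
        eta = self.intercept + self.slope * math.log(x)
        return math.exp(eta)  # ln_ln and ln_y both exponentiate back


# Published reference coefficients (fixed external inputs to the chain).
FFR_ON_NBFV_FIT = RegressionFit(
    intercept=-1.459, slope=1.356, r=0.897, r2=0.805, transform="ln_ln"
)
PBF_ON_NBFV_FIT = RegressionFit(
    intercept=10.697, slope=3.655, r=0.974, r2=0.949, transform="none"
)
PUBLISHED_NBFV_CUTOFFS = (4.180, 7.322)  # (overweight, obese)
PUBLISHED_FFR_CUTOFFS = (1.6, 3.5)


@dataclass(frozen=True)
class CutoffSet:
    """Lower cutoffs for overweight and obesity on each scale."""

    nbfv_overweight: float
    nbfv_obese: float
    ffr_overweight: float
    ffr_obese: float
    pbf_overweight: float = float("nan")
    pbf_obese: float = float("nan")

    def __post_init__(self) -> None:
        pairs = [
            (self.nbfv_overweight, self.nbfv_obese),
            (self.ffr_overweight, self.ffr_obese),
        ]
        if not math.isnan(self.pbf_overweight):
            pairs.append((self.pbf_overweight, self.pbf_obese))
        for ow, ob in pairs:
            if not ow < ob:
                raise ValueError(
                    "overweight cutoff must be below obese cutoff on every scale"
                )


FIXED_PUBLISHED_CUTOFFS = CutoffSet(
    nbfv_overweight=PUBLISHED_NBFV_CUTOFFS[0],
    nbfv_obese=PUBLISHED_NBFV_CUTOFFS[1],
    ffr_overweight=PUBLISHED_FFR_CUTOFFS[0],
    ffr_obese=PUBLISHED_FFR_CUTOFFS[1],
    pbf_overweight=PBF_ON_NBFV_FIT.predict(PUBLISHED_NBFV_CUTOFFS[0]),
    pbf_obese=PBF_ON_NBFV_FIT.predict(PUBLISHED_NBFV_CUTOFFS[1]),
)


@dataclass(frozen=True)
class DiagnosticPerformance:
    """2x2 confusion counts with optional exact binomial CIs."""

    tp: int
    fp: int
    fn: int
    tn: int
    sens_ci: tuple[float, float] | None = None
    spec_ci: tuple[float, float] | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


def median_of(values: Sequence[float]) -> float:
    """Sample median; even length averages the two central order stats."""
    return float(np.median(np.asarray(values, dtype=float)))


def derive_nbfv_cutoffs(
    nbfv_by_fc: Mapping[str, Sequence[float]],
) -> tuple[float, float]:
    """Median-midpoint rule on the normal/overweight/obese categories."""
    for fc in ("normal", "overweight", "obese"):
        if fc not in nbfv_by_fc or len(nbfv_by_fc[fc]) == 0:
            raise ValueError(f"fat category {fc!r} is empty; cutoffs undefined")
    m_norm = median_of(nbfv_by_fc["normal"])
    m_over = median_of(nbfv_by_fc["overweight"])
    m_obese = median_of(nbfv_by_fc["obese"])
    return (m_norm + m_over) / 2.0, (m_over + m_obese) / 2.0


def chain_cutoff_through_regression(
    nbfv_cutoff: float, fit: RegressionFit
) -> float:
    """Map an nBFV cutoff onto the fit's response scale (full precision).

    Use round_half_away(value, 1) for the 1-decimal reported form.
    """
    if fit.transform != "none" and nbfv_cutoff <= 0:
        raise ValueError("nBFV cutoff must be positive under a ln transform")
    return fit.predict(nbfv_cutoff)


def derive_cutoff_set(
    nbfv_by_fc: Mapping[str, Sequence[float]],
    ffr_fit: RegressionFit = FFR_ON_NBFV_FIT,
    pbf_fit: RegressionFit = PBF_ON_NBFV_FIT,
) -> CutoffSet:
    """Full chain: category medians -> nBFV cutoffs -> FFR and %BF cutoffs."""
    nbfv_ow, nbfv_ob = derive_nbfv_cutoffs(nbfv_by_fc)
    return CutoffSet(
        nbfv_overweight=nbfv_ow,
        nbfv_obese=nbfv_ob,
        ffr_overweight=chain_cutoff_through_regression(nbfv_ow, ffr_fit),
        ffr_obese=chain_cutoff_through_regression(nbfv_ob, ffr_fit),
        pbf_overweight=chain_cutoff_through_regression(nbfv_ow, pbf_fit),
        pbf_obese=chain_cutoff_through_regression(nbfv_ob, pbf_fit),
    )


def classify_by_ffr(ffr: float, cutoffs: CutoffSet) -> str:
    """Half-open bands: [overweight, obese) is overweight, >= obese is obese."""
    if ffr < 0:
        raise ValueError("FFR must be non-negative")
    if ffr >= cutoffs.ffr_obese:
        return "obese"
    if ffr >= cutoffs.ffr_overweight:
        return "overweight"
    return "not_overweight"


def confusion_table(records: pd.DataFrame, condition: str) -> DiagnosticPerformance:
    """Tally the 2x2 table of FFR class against visual fat category.

    condition="obesity": disease-positive iff visual_fc == "obese",
    test-positive iff ffr_class == "obese".  condition="overweight":
    disease-positive iff visual_fc == "overweight", test-positive iff
    ffr_class == "overweight" (i.e. FFR within the overweight band);
    both obese and not-overweight FFRs count as test-negative.
    """
    if condition == "obesity":
        disease = records["visual_fc"] == "obese"
        test = records["ffr_class"] == "obese"
    elif condition == "overweight":
        disease = records["visual_fc"] == "overweight"
        test = records["ffr_class"] == "overweight"
    else:
        raise ValueError(f"unknown condition {condition!r}")
    if records["visual_fc"].isna().any() or records["ffr_class"].isna().any():
        raise ValueError("every record needs both visual_fc and ffr_class")
    return DiagnosticPerformance(
        tp=int((disease & test).sum()),
        fp=int((~disease & test).sum()),
        fn=int((disease & ~test).sum()),
        tn=int((~disease & ~test).sum()),
    )


def exact_binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Two-sided Clopper-Pearson interval for k successes in n trials."""
    if not 0 <= k <= n or n == 0:
        raise ValueError("need 0 <= k <= n with n > 0")
    lo, hi = proportion_confint(k, n, alpha=1 - level, method="beta")
    # statsmodels returns NaN at the degenerate edges; the exact interval
    # has lower bound 0 at k=0 and upper bound 1 at k=n.
    lo = 0.0 if k == 0 else float(lo)
    hi = 1.0 if k == n else float(hi)
    return lo, hi


def sens_spec_with_ci(
    counts: DiagnosticPerformance, level: float = 0.95
) -> DiagnosticPerformance:
    """Attach exact binomial CIs to the sensitivity and specificity."""
    if counts.tp + counts.fn == 0 or counts.tn + counts.fp == 0:
        raise ValueError("both disease margins must be non-empty")
    return replace(
        counts,
        sens_ci=exact_binomial_ci(counts.tp, counts.tp + counts.fn, level),
        spec_ci=exact_binomial_ci(counts.tn, counts.tn + counts.fp, level),
    )


def band_label(value: float) -> str:
    """Qualitative band for a sensitivity/specificity proportion.

    <0.5 low; [0.5, 0.7) moderate; [0.7, 0.9) high; [0.9, 1] very high.
    """
    if not 0.0 <= value <= 1.0:
        raise ValueError("proportion must lie in [0, 1]")
    if value < 0.5:
        return "low"
    if value < 0.7:
        return "moderate"
    if value < 0.9:
        return "high"
    return "very_high"


def performance_report(perf: DiagnosticPerformance) -> dict:
    """Printed-precision summary (2 decimals, half-away rounding)."""
    return {
        "tp": perf.tp,
        "fp": perf.fp,
        "fn": perf.fn,
        "tn": perf.tn,
        "sensitivity": round_half_away(perf.sensitivity, 2),
        "specificity": round_half_away(perf.specificity, 2),
        "sens_ci": [round_half_away(v, 2) for v in perf.sens_ci]
        if perf.sens_ci
        else None,
        "spec_ci": [round_half_away(v, 2) for v in perf.spec_ci]
        if perf.spec_ci
        else None,
        "sensitivity_band": band_label(perf.sensitivity),
        "specificity_band": band_label(perf.specificity),
    }
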