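"""Agreement statistics and noninferiority decisions.

The acceptance machinery for method comparison: intraclass correlation
ICC(2,1) (two-way random effects, absolute agreement, single measures —
the variant sensitive to systematic offsets between methods), Bland-Altman
bias with a parametric 95% CI and limits of agreement, margin-based
noninferiority verdicts (ICC > 0.75 and bias not below the preset margin:
-1 uV for voltage, -0.5 dB for oscillatory peak power, -0.03 for
coherence), unweighted Cohen's kappa for sleep-stage agreement against a
0.60 substantial-agreement margin, and the exact paired sign test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .core import Hypnogram, SLEEP_STAGES

__all__ = [
    "PairedMeasurements",
    "AgreementResult",
    "NoninferiorityDecision",
    "KappaResult",
    "DEFAULT_MARGINS",
    "ICC_THRESHOLD",
    "KAPPA_MARGIN",
    "icc",
    "bland_altman",
    "noninferiority",
    "cohens_kappa",
    "paired_sign_test",
]

#: Preset noninferiority margins per measurement unit.
DEFAULT_MARGINS = {"uV": -1.0, "dB": -0.5, "coherence": -0.03}
ICC_THRESHOLD = 0.75
KAPPA_MARGIN = 0.60


@dataclass
class PairedMeasurements:
    """One row per unit (participant x contact pair, or x seizure)."""

    units: list[str]
    value_subscalp: np.ndarray
    value_scalp: np.ndarray
    measure_units: str  # "uV" | "dB" | "coherence"

    def __post_init__(self) -> None:
        self.value_subscalp = np.asarray(self.value_subscalp, float)
        self.value_scalp = np.asarray(self.value_scalp, float)
        n = len(self.units)
        if not (len(self.value_subscalp) == len(self.value_scalp) == n):
            raise ValueError("units and value arrays must have equal length")
        if n < 3:
            raise ValueError("paired agreement needs at least 3 units")
        if not (np.isfinite(self.value_subscalp).all()
                and np.isfinite(self.value_scalp).all()):
            raise ValueError("paired measurements must be finite")

    @property
    def n(self) -> int:
        return len(self.units)

    @property
    def differences(self) -> np.ndarray:
        return self.value_subscalp - self.value_scalp


@dataclass
class AgreementResult:
    icc: float
    icc_ci: tuple[float, float]
    bias: float
    bias_ci: tuple[float, float]
    limits_of_agreement: tuple[float, float]
    n: int
    measure_units: str
    icc_variant: str = "ICC(2,1) absolute agreement, single measures"


@dataclass
class NoninferiorityDecision:
    margin: float
    margin_units: str
    icc_pass: bool
    bias_pass: bool
    rule_version: str = "ci_lower"  # or "point"

    @property
    def overall(self) -> bool:
        return self.icc_pass and self.bias_pass


@dataclass
class KappaResult:
    kappa: float
    observed_agreement: float
    expected_agreement: float
    n_epochs: int
    passes_margin: bool = field(init=False)

    def __post_init__(self) -> None:
        self.passes_margin = self.kappa > KAPPA_MARGIN


def icc(pairs: PairedMeasurements) -> tuple[float, tuple[float, float]]:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    Point estimate and 95% CI from the standard two-way ANOVA decomposition
    over units x methods (computed via pingouin's ICC table, row ICC(A,1)).
    """
    if pairs.n < 5:
        raise ValueError("ICC with a meaningful CI needs at least 5 units")
    total_var = np.var(np.r_[pairs.value_subscalp, pairs.value_scalp])
    if total_var == 0:
        raise ValueError("ICC undefined: zero total variance across measurements")
    if np.allclose(pairs.differences, 0.0):
        return 1.0, (1.0, 1.0)  # perfect agreement: the F interval degenerates
    df = pd.DataFrame(
        {
            "unit": np.r_[pairs.units, pairs.units],
            "method": ["subscalp"] * pairs.n + ["scalp"] * pairs.n,
            "value": np.r_[pairs.value_subscalp, pairs.value_scalp],
        }
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        table = pg.intraclass_corr(df, targets="unit", raters="method",
                                   ratings="value")
    row = table[table["Type"] == "ICC2"] if "ICC2" in set(table["Type"]) else \
        table[table["Type"] == "ICC(A,1)"]
    row = row.iloc[0]
    lo, hi = row["CI95"] if "CI95" in table.columns else row["CI95%"]
    point = float(row["ICC"])
    # the table's CI is rounded to 2 decimals; keep lower <= point <= upper
    return point, (min(float(lo), point), max(float(hi), point))


def bland_altman(
    pairs: PairedMeasurements, ci_level: float = 0.95
) -> AgreementResult:
    """Bland-Altman agreement: bias (subscalp - scalp), t-interval CI, LoA."""
    d = pairs.differences
    n = pairs.n
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    sem = sd / np.sqrt(n)
    tcrit = stats.t.ppf(0.5 + ci_level / 2, n - 1)
    ci = (bias - tcrit * sem, bias + tcrit * sem)
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)
    icc_val, icc_ci = icc(pairs)
    return AgreementResult(
        icc=icc_val,
        icc_ci=icc_ci,
        bias=bias,
        bias_ci=ci,
        limits_of_agreement=loa,
        n=n,
        measure_units=pairs.measure_units,
    )


def noninferiority(
    agreement: AgreementResult,
    margin: float,
    margin_units: Optional[str] = None,
    rule_version: str = "ci_lower",
) -> NoninferiorityDecision:
    """Margin-based noninferiority verdict.

    ``icc_pass`` iff the ICC point estimate exceeds 0.75.  ``bias_pass``
    under the default conservative rule iff the lower bound of the bias 95%
    CI is at or above the margin; ``rule_version="point"`` compares the bias
    point estimate instead (the permissive reading of a mean-vs-margin rule).
    """
    if margin_units is None:
        margin_units = agreement.measure_units
    if margin_units != agreement.measure_units:
        raise ValueError(
            f"margin units {margin_units!r} do not match measurement units "
            f"{agreement.measure_units!r}"
        )
    if rule_version not in ("ci_lower", "point"):
        raise ValueError("rule_version must be 'ci_lower' or 'point'")
    icc_pass = agreement.icc > ICC_THRESHOLD
    ref = agreement.bias_ci[0] if rule_version == "ci_lower" else agreement.bias
    bias_pass = ref >= margin
    return NoninferiorityDecision(
        margin=margin,
        margin_units=margin_units,
        icc_pass=bool(icc_pass),
        bias_pass=bool(bias_pass),
        rule_version=rule_version,
    )


def cohens_kappa(stages_a: Hypnogram | Sequence[str],
                 stages_b: Hypnogram | Sequence[str]) -> KappaResult:
    """Unweighted Cohen's kappa over the 5-stage confusion table."""
    a = list(stages_a.stages) if isinstance(stages_a, Hypnogram) else list(stages_a)
    b = list(stages_b.stages) if isinstance(stages_b, Hypnogram) else list(stages_b)
    if len(a) != len(b):
        raise ValueError(
            f"hypnograms differ in length ({len(a)} vs {len(b)} epochs)"
        )
    if (
        isinstance(stages_a, Hypnogram)
        and isinstance(stages_b, Hypnogram)
        and stages_a.epoch_length != stages_b.epoch_length
    ):
        raise ValueError("hypnograms are not on the same epoch grid")
    n = len(a)
    if n == 0:
        raise ValueError("empty hypnograms")
    labels = list(SLEEP_STAGES)
    idx = {s: i for i, s in enumerate(labels)}
    confusion = np.zeros((len(labels), len(labels)))
    for sa, sb in zip(a, b):
        confusion[idx[sa], idx[sb]] += 1
    po = float(np.trace(confusion) / n)
    pe = float((confusion.sum(axis=1) * confusion.sum(axis=0)).sum() / n**2)
    kappa = 1.0 if pe == 1.0 else (po - pe) / (1 - pe)
    return KappaResult(kappa=float(kappa), observed_agreement=po,
                       expected_agreement=pe, n_epochs=n)


def paired_sign_test(values_a: Sequence[float],
                     values_b: Sequence[float]) -> float:
    """Exact two-sided binomial sign test on nonzero paired differences.

    Ties are dropped; if every pair is tied the test is vacuous (p = 1).
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if len(a) < 5:
        raise ValueError("sign test needs at least 5 pairs")
    d = a - b
    nonzero = d[d != 0]
    if len(nonzero) == 0:
        return 1.0
    n_pos = int((nonzero > 0).sum())
    return float(stats.binomtest(n_pos, len(nonzero), 0.5).pvalue)
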