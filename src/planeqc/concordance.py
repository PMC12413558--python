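"""Agreement statistics: Cohen's kappa, exact McNemar, t-based CIs.

These implement the validation machinery used to compare a rater (the model,
or a human examiner) against the expert examiner's gold standard on paired
binary verdicts, endpoint by endpoint (the plane plus each organ).

Cohen's kappa is the chance-corrected agreement (po − pe)/(1 − pe).  Its
standard error uses the Fleiss–Cohen–Everitt asymptotic variance for the
confidence interval and the null-hypothesis variance for the test of
kappa = 0.  Agreement bands: kappa ≤ 0.20 poor, (0.20, 0.40] weak,
(0.40, 0.60] moderate, (0.60, 0.80] good, > 0.80 very good.

The McNemar test is the exact binomial version on the discordant pair counts
(b, c): p = min(1, 2·P(X ≤ min(b, c))) with X ~ Binomial(b + c, ½); a
chi-square variant with continuity correction is available behind a flag.

When both raters rate every item identically in a single category, chance
agreement pe = 1 and kappa is undefined; this is reported as a distinct
"not estimable" state (printed "—"), never coerced to a number.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError
from .organs import ORGAN_NAMES

#: Endpoints of a concordance table: the plane plus the eight organs.
ENDPOINTS: tuple[str, ...] = ("plane",) + ORGAN_NAMES

AGREEMENT_BANDS = (
    (0.20, "poor"),
    (0.40, "weak"),
    (0.60, "moderate"),
    (0.80, "good"),
    (1.00, "very good"),
)


class UndefinedKappaError(ValueError):
    """Both raters are constant in the same category: kappa is not estimable."""


@dataclasses.dataclass(frozen=True)
class PairedRatings2x2:
    """Paired binary ratings: a = both correct, b = reference correct only,
    c = rater correct only, d = both incorrect."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("cell counts must be non-negative")
        if self.n < 1:
            raise ValidationError("need at least one paired rating")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_vectors(cls, reference: Sequence[int], rater: Sequence[int]) -> "PairedRatings2x2":
        ref = np.asarray(reference, dtype=int)
        rat = np.asarray(rater, dtype=int)
        if ref.shape != rat.shape:
            raise ValidationError("verdict vectors must have equal length")
        if not (np.isin(ref, (0, 1)).all() and np.isin(rat, (0, 1)).all()):
            raise ValidationError("verdicts must be binary (0/1)")
        return cls(
            a=int(np.sum((ref == 1) & (rat == 1))),
            b=int(np.sum((ref == 1) & (rat == 0))),
            c=int(np.sum((ref == 0) & (rat == 1))),
            d=int(np.sum((ref == 0) & (rat == 0))),
        )


@dataclasses.dataclass(frozen=True)
class KappaResult:
    kappa: float
    se: float
    ci95: tuple[float, float]
    p: float
    category: str


def categorize_kappa(kappa: float) -> str:
    """Agreement band for a kappa value in [−1, 1]."""
    if not -1.0 <= kappa <= 1.0:
        raise ValidationError(f"kappa must lie in [-1, 1], got {kappa}")
    for upper, name in AGREEMENT_BANDS:
        if kappa <= upper + 1e-12:
            return name
    raise AssertionError("unreachable")


def cohen_kappa(t: PairedRatings2x2) -> KappaResult:
    """Cohen's kappa with Fleiss–Cohen–Everitt SE, 95% CI, and p for kappa=0.

    Raises :class:`UndefinedKappaError` when chance agreement pe = 1 (both
    raters constant in the same category).
    """
    n = t.n
    # Joint and marginal proportions; rows = reference, columns = rater.
    p = np.array([[t.a, t.b], [t.c, t.d]], dtype=float) / n
    row = p.sum(axis=1)  # reference marginals (correct, incorrect)
    col = p.sum(axis=0)  # rater marginals
    po = p[0, 0] + p[1, 1]
    pe = row[0] * col[0] + row[1] * col[1]
    if 1.0 - pe < 1e-12:
        raise UndefinedKappaError(
            "both raters are constant; chance agreement is 1 and kappa undefined"
        )
    kappa = (po - pe) / (1.0 - pe)

    # Fleiss, Cohen & Everitt asymptotic variance (CI around the estimate).
    diag = np.array([p[0, 0], p[1, 1]])
    marg_sum = np.array([row[0] + col[0], row[1] + col[1]])
    term1 = float(np.sum(diag * ((1 - pe) - marg_sum * (1 - po)) ** 2))
    # off-diagonal: cell (i,j), i != j, weighted by (col_i + row_j)^2
    term2 = (1 - po) ** 2 * (
        p[0, 1] * (col[0] + row[1]) ** 2 + p[1, 0] * (col[1] + row[0]) ** 2
    )
    term3 = (po * pe - 2 * pe + po) ** 2
    var = (term1 + term2 - term3) / (n * (1 - pe) ** 4)
    se = math.sqrt(max(var, 0.0))

    # Null-hypothesis variance for the test of kappa = 0.
    var0 = (
        pe + pe**2 - float(np.sum(row * col * (row + col)))
    ) / (n * (1 - pe) ** 2)
    se0 = math.sqrt(max(var0, 0.0))
    if se0 > 0:
        z = kappa / se0
        p_value = 2.0 * stats.norm.sf(abs(z))
    else:
        p_value = 1.0

    lo = max(-1.0, kappa - 1.959963984540054 * se)
    hi = min(1.0, kappa + 1.959963984540054 * se)
    return KappaResult(
        kappa=float(kappa),
        se=float(se),
        ci95=(float(lo), float(hi)),
        p=float(p_value),
        category=categorize_kappa(float(np.clip(kappa, -1.0, 1.0))),
    )


def mcnemar_exact(t: PairedRatings2x2, method: str = "exact") -> float:
    """McNemar p-value on the discordant pairs.

    ``exact``: two-sided binomial, p = min(1, 2·P(X ≤ min(b, c))) with
    X ~ Binomial(b + c, ½); no discordant pairs → p = 1.  ``chi2``:
    chi-square with continuity correction.
    """
    b, c = t.b, t.c
    m = b + c
    if method == "exact":
        if m == 0:
            return 1.0
        p = 2.0 * float(stats.binom.cdf(min(b, c), m, 0.5))
        return min(1.0, p)
    if method == "chi2":
        if m == 0:
            return 1.0
        chi2 = (abs(b - c) - 1.0) ** 2 / m
        return float(stats.chi2.sf(chi2, df=1))
    raise ValidationError(f"unknown McNemar method {method!r}")


def mean_ci_t(
    n: int, mean: float, sd: float, level: float = 0.95
) -> tuple[float, float]:
    """t-based confidence interval for a mean from summary statistics.

    mean ± t(1 − α/2, n − 1) · sd/√n.
    """
    if n < 2:
        raise ValidationError("need n >= 2 for a t interval")
    if sd < 0:
        raise ValidationError("sd must be non-negative")
    tcrit = float(stats.t.ppf(0.5 + level / 2.0, df=n - 1))
    half = tcrit * sd / math.sqrt(n)
    return (mean - half, mean + half)


def _verdict_frame(verdicts: pd.DataFrame) -> pd.DataFrame:
    expected = {"patient_id", "endpoint", "verdict"}
    if not expected.issubset(verdicts.columns):
        raise ValidationError(f"verdict table needs columns {sorted(expected)}")
    return verdicts


def concordance_table(reference: pd.DataFrame, rater: pd.DataFrame) -> pd.DataFrame:
    """Per-endpoint agreement table of a rater against the reference.

    Both inputs are long tables (patient_id, endpoint, verdict) covering the
    plane and the eight organs.  The output has one row per endpoint with the
    rater's correct count and percentage, the exact McNemar p, and kappa with
    SE, 95% CI, p and agreement band; endpoints where kappa is not estimable
    carry missing values.
    """
    reference = _verdict_frame(reference)
    rater = _verdict_frame(rater)
    merged = reference.merge(
        rater, on=["patient_id", "endpoint"], suffixes=("_ref", "_rater"), how="outer",
        indicator=True,
    )
    if (merged["_merge"] != "both").any():
        raise ValidationError("reference and rater verdicts do not cover the same items")
    rows = []
    for endpoint in ENDPOINTS:
        sub = merged[merged["endpoint"] == endpoint]
        if sub.empty:
            raise ValidationError(f"no verdicts for endpoint {endpoint!r}")
        t = PairedRatings2x2.from_vectors(
            sub["verdict_ref"].to_numpy(), sub["verdict_rater"].to_numpy()
        )
        n_correct = int(sub["verdict_rater"].sum())
        row = {
            "endpoint": endpoint,
            "n": t.n,
            "rater_correct": n_correct,
            "rater_correct_pct": 100.0 * n_correct / t.n,
            "mcnemar_p": np.nan,
            "kappa": np.nan,
            "kappa_se": np.nan,
            "kappa_ci_low": np.nan,
            "kappa_ci_high": np.nan,
            "kappa_p": np.nan,
            "agreement": None,
        }
        try:
            res = cohen_kappa(t)
        except UndefinedKappaError:
            rows.append(row)  # printed as "—" cells: constant ratings
            continue
        row.update(
            mcnemar_p=mcnemar_exact(t),
            kappa=res.kappa,
            kappa_se=res.se,
            kappa_ci_low=res.ci95[0],
            kappa_ci_high=res.ci95[1],
            kappa_p=res.p,
            agreement=res.category,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def verdicts_to_frame(verdicts) -> pd.DataFrame:
    """Long (patient_id, endpoint, verdict) table from VideoVerdict objects."""
    rows = []
    for v in verdicts:
        rows.append({"patient_id": v.patient_id, "endpoint": "plane",
                     "verdict": int(v.plane_correct)})
        for organ, verdict in v.organ_verdict.items():
            rows.append({"patient_id": v.patient_id, "endpoint": organ.value,
                         "verdict": int(verdict)})
    return pd.DataFrame(rows)


def labels_to_frame(labels) -> pd.DataFrame:
    """Long verdict table of the ground-truth labels (plane derived as AND)."""
    df = labels.validate().organ_correct
    organ_rows = df.rename(columns={"organ": "endpoint", "organ_correct": "verdict"})
    plane = labels.plane_correct().reset_index()
    plane.columns = ["patient_id", "verdict"]
    plane["endpoint"] = "plane"
    return pd.concat(
        [plane[["patient_id", "endpoint", "verdict"]], organ_rows], ignore_index=True
    )
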