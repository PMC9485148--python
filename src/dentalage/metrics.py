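"""Evaluation metrics and statistical comparisons for age-estimation methods.

The central object is :class:`PairedAges` — per-subject chronological age
(CA) and estimated dental age (DA).  The age deviation AD = DA − CA is the
signed error (positive = overestimation); everything else derives from it:
MAE with optional age caps, per-age-group MAE, MSE/RMSE/R², a paired
t-test of DA against CA, and Cohen's kappa for rater agreement on stages.

All standard deviations use the n−1 denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .staging import AgeBin, Sex, Stage, standard_bins


class MetricError(ValueError):
    pass


@dataclass
class PairedAges:
    """Aligned per-subject chronological and dental ages."""

    subject_ids: list[str]
    ca: np.ndarray
    da: np.ndarray
    sex: list[Sex]

    def __post_init__(self):
        self.ca = np.asarray(self.ca, dtype=float)
        self.da = np.asarray(self.da, dtype=float)
        n = len(self.subject_ids)
        if not (len(self.ca) == len(self.da) == len(self.sex) == n):
            raise MetricError("PairedAges fields must have equal lengths")
        if n and not (np.isfinite(self.ca).all() and np.isfinite(self.da).all()):
            raise MetricError("ages must be finite")

    def __len__(self) -> int:
        return len(self.subject_ids)

    @property
    def ad(self) -> np.ndarray:
        """Age deviation AD = DA − CA (positive = overestimation)."""
        return self.da - self.ca

    def subset(self, mask: np.ndarray) -> "PairedAges":
        idx = np.flatnonzero(mask)
        return PairedAges(
            [self.subject_ids[i] for i in idx],
            self.ca[idx],
            self.da[idx],
            [self.sex[i] for i in idx],
        )


def age_deviation(pair: PairedAges) -> tuple[np.ndarray, float, float]:
    """Per-subject AD plus its mean and (n−1) standard deviation."""
    if len(pair) == 0:
        raise MetricError("empty paired ages")
    ad = pair.ad
    sd = float(ad.std(ddof=1)) if len(ad) > 1 else 0.0
    return ad, float(ad.mean()), sd


def mae(pair: PairedAges, age_cap: float | None = None) -> float:
    """Mean absolute AD; with ``age_cap`` only subjects with CA < cap count."""
    ad = pair.ad
    if age_cap is not None:
        keep = pair.ca < age_cap
        if not keep.any():
            raise MetricError(f"no subjects with CA < {age_cap}")
        ad = ad[keep]
    if ad.size == 0:
        raise MetricError("empty paired ages")
    return float(np.abs(ad).mean())


def regression_metrics(pair: PairedAges) -> dict[str, float]:
    """MSE, RMSE, MAE and R² of DA against CA.

    R² = 1 − Σ AD² / Σ (CA − mean CA)², the coefficient of determination of
    the predictions against the truth.
    """
    if len(pair) < 2:
        raise MetricError("regression metrics need at least 2 subjects")
    ad = pair.ad
    mse = float(np.mean(ad**2))
    ss_tot = float(np.sum((pair.ca - pair.ca.mean()) ** 2))
    if ss_tot == 0.0:
        raise MetricError("R² undefined: chronological age has zero variance")
    return {
        "MSE": mse,
        "RMSE": float(np.sqrt(mse)),
        "MAE": float(np.abs(ad).mean()),
        "R2": 1.0 - float(np.sum(ad**2)) / ss_tot,
    }


def paired_t_test(pair: PairedAges) -> tuple[float, float]:
    """Paired t-test of DA vs CA: t = mean(AD)/(sd(AD)/√n), df = n−1."""
    n = len(pair)
    if n < 2:
        raise MetricError("paired t-test needs at least 2 subjects")
    ad = pair.ad
    sd = ad.std(ddof=1)
    if sd == 0.0:
        raise MetricError("paired t-test degenerate: AD has zero variance")
    t = float(ad.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return t, p


def significance_tier(p: float) -> str:
    """The three conventional significance levels, plus 'ns'."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def cohens_kappa(
    ratings_a: Sequence, ratings_b: Sequence, weighted: bool = False
) -> float:
    """Chance-corrected agreement between two categorical rating sequences.

    Unweighted by default: κ = (p_o − p_e)/(1 − p_e).  ``weighted=True``
    applies linear weights over the ordinal stage distance.
    """
    if len(ratings_a) != len(ratings_b):
        raise MetricError("rating sequences must have equal lengths")
    if len(ratings_a) == 0:
        raise MetricError("empty rating sequences")
    cats = sorted({*ratings_a, *ratings_b}, key=_category_key)
    k = len(cats)
    index = {c: i for i, c in enumerate(cats)}
    table = np.zeros((k, k))
    for a, b in zip(ratings_a, ratings_b):
        table[index[a], index[b]] += 1
    n = table.sum()
    pa = table.sum(axis=1) / n
    pb = table.sum(axis=0) / n
    if weighted:
        ii, jj = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
        w = np.abs(ii - jj) / max(k - 1, 1)  # disagreement weights
        observed = float((w * table / n).sum())
        expected = float((w * np.outer(pa, pb)).sum())
        if expected == 0.0:
            raise MetricError("kappa degenerate: expected disagreement is zero")
        return 1.0 - observed / expected
    po = float(np.trace(table) / n)
    pe = float(np.dot(pa, pb))
    if pe == 1.0:
        raise MetricError("kappa degenerate: chance agreement is 1")
    return (po - pe) / (1.0 - pe)


def _category_key(c):
    return int(c) if isinstance(c, (int, np.integer, Stage)) else str(c)


def per_group_mae(pair: PairedAges, bins: list[AgeBin] | None = None) -> dict[AgeBin, float]:
    """MAE per age bin; bins with no subjects are omitted (not reported as 0)."""
    if bins is None:
        bins = standard_bins()
    out: dict[AgeBin, float] = {}
    for b in bins:
        keep = (pair.ca >= b.lower) & (pair.ca < b.upper)
        if keep.any():
            out[b] = float(np.abs(pair.ad[keep]).mean())
    return out


# ---------------------------------------------------------------------------
# Report builders
# ---------------------------------------------------------------------------

def method_comparison_row(method: str, sex: Sex, pair: PairedAges) -> dict:
    """One row of the score-model comparison report.

    Columns: mean(sd) of CA, DA and AD, paired-t p-value with significance
    tier, and MAE under the <18 and <16 caps.
    """
    _, ad_mean, ad_sd = age_deviation(pair)
    _, p = paired_t_test(pair)
    return {
        "method": method,
        "sex": sex.value,
        "n": len(pair),
        "CA_mean": float(pair.ca.mean()),
        "CA_sd": float(pair.ca.std(ddof=1)),
        "DA_mean": float(pair.da.mean()),
        "DA_sd": float(pair.da.std(ddof=1)),
        "AD_mean": ad_mean,
        "AD_sd": ad_sd,
        "p_value": p,
        "significance": significance_tier(p),
        "MAE_under_18": mae(pair, age_cap=18.0),
        "MAE_under_16": mae(pair, age_cap=16.0),
    }


def learner_metrics_row(learner: str, sex: Sex, split: str, pair: PairedAges) -> dict:
    """One row of the learner comparison report (per learner, sex, split)."""
    rm = regression_metrics(pair)
    return {
        "learner": learner,
        "sex": sex.value,
        "split": split,
        "n": len(pair),
        **rm,
    }


def build_report(rows: list[dict]) -> pd.DataFrame:
    """Assemble report rows into a stable, reproducible DataFrame."""
    return pd.DataFrame(rows)
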