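"""Evaluation metrics and correlation comparisons.

Metrics follow the field's conventions for stability predictors: Pearson
correlation (PCC) between predicted and experimental ddG, mean squared error
and mean absolute error in kcal/mol, and Fisher's z test for comparing two
correlation coefficients from independent samples.

Sign convention: ddG = dG(mutant) - dG(wild-type), positive = destabilizing.
Deep-mutational-scan stability scores run the other way (higher = more
stable), so correlating predicted ddG with such scores flips the sign of the
predictions by default; the applied orientation is recorded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats


@dataclass
class EvalReport:
    """Summary of one prediction-vs-observation comparison."""

    n: int
    pcc: float
    mse: float
    mae: float
    sign_applied: int = 1

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _check_pair(x, y, min_n=2):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} observations, got {len(x)}")
    return x, y


def pearson(x, y) -> float:
    """Pearson product-moment correlation; errors on zero variance."""
    x, y = _check_pair(x, y)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def mse(pred, obs) -> float:
    """Mean squared error."""
    pred, obs = _check_pair(pred, obs, min_n=1)
    return float(np.mean((pred - obs) ** 2))


def mae(pred, obs) -> float:
    """Mean absolute error."""
    pred, obs = _check_pair(pred, obs, min_n=1)
    return float(np.mean(np.abs(pred - obs)))


def fisher_z_test(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Compare two Pearson correlations from independent samples.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), with a
    two-sided p-value from the standard normal. Requires |r| < 1 and n > 3.
    """
    for r, n in ((r1, n1), (r2, n2)):
        if abs(r) >= 1:
            raise ValueError(f"|r| must be < 1, got {r}")
        if n <= 3:
            raise ValueError(f"sample size must exceed 3, got {n}")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def stability_score_correlation(
    pred_ddg, scores, destabilizing_positive: bool = True
) -> tuple[float, int]:
    """Correlate predicted ddG with deep-mutational-scan stability scores.

    Under the destabilizing-positive ddG convention the predictions are
    negated before correlating, so that stabilizing predictions align with
    higher scores. Returns (correlation, sign applied to predictions).
    """
    sign = -1 if destabilizing_positive else 1
    pred_ddg, scores = _check_pair(pred_ddg, scores)
    return pearson(sign * pred_ddg, scores), sign


def evaluate(pred, obs, target_kind: str = "ddg") -> EvalReport:
    """Full metric panel for predictions against observations.

    For ``stability_score`` targets the PCC is orientation-adjusted (see
    :func:`stability_score_correlation`); MSE/MAE are computed on the raw
    predictions and are then only meaningful as relative numbers.
    """
    pred, obs = _check_pair(pred, obs)
    if target_kind == "stability_score":
        r, sign = stability_score_correlation(pred, obs)
    else:
        r, sign = pearson(pred, obs), 1
    return EvalReport(
        n=len(pred), pcc=r, mse=mse(pred, obs), mae=mae(pred, obs), sign_applied=sign
    )
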