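"""The reversal coefficient: total-least-squares on paired log2 fold changes.

Given two contrasts sharing a gene namespace — a *disease* contrast
(disease vs. control) and a *treatment* contrast (treated vs. disease) —
each gene contributes a point (x, y) of log2 fold changes.  If treatment
undoes a fraction rho of each disease effect, the points scatter around the
line y = -rho * x, so the slope of a total-least-squares (orthogonal) fit is
an estimate of -rho: the reversal coefficient.  Pearson correlation gives a
scale-free companion measure, and genes significantly changed in opposite
directions in the two contrasts are classified as reversed.

TLS rather than ordinary least squares because both coordinates are
estimates with comparable error; OLS would attenuate the slope.  TLS is also
insensitive to an added isotropic cloud of null genes, since adding a
multiple of the identity to the 2x2 scatter matrix leaves its eigenvectors
unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ValidationError

__all__ = ["ReversalReport", "paired_fc", "tls_fit", "pearson_r",
           "classify_opposite", "reversal_report", "CLASS_LABELS"]

CLASS_LABELS = ("reversed_significant", "concordant_significant",
                "disease_only", "treatment_only", "neither")

UNIVERSES = ("union_significant", "intersection_tested", "all_tested")


@dataclass(frozen=True)
class ReversalReport:
    """Summary of one disease/treatment reversal analysis."""

    n_genes: int
    pearson_r: float
    pearson_p: float
    tls_slope: float
    tls_intercept: float
    slope_ci: tuple[float, float]
    n_bootstrap: int
    seed: int
    universe: str
    alpha: float
    classes: pd.Series = field(repr=False)  # per-gene class label

    @property
    def class_counts(self) -> pd.Series:
        return self.classes.value_counts().reindex(CLASS_LABELS, fill_value=0)


def paired_fc(disease: pd.DataFrame, treatment: pd.DataFrame,
              universe: str = "union_significant", alpha: float = 0.05) -> pd.DataFrame:
    """Inner-join two contrast tables into paired fold changes.

    Returns a frame indexed by gene with columns x, y (disease and treatment
    log2FC) and q_x, q_y.  ``universe`` selects which genes enter:
    ``union_significant`` (q < alpha in at least one contrast, the default),
    ``intersection_tested`` (every gene tested in both), or ``all_tested``
    (alias of intersection_tested; kept for symmetry with single-table use).
    """
    if universe not in UNIVERSES:
        raise ValidationError(f"unknown universe {universe!r}; expected one of {UNIVERSES}")
    shared = disease.index.intersection(treatment.index)
    if len(shared) == 0:
        raise ValidationError("contrast tables share no genes")
    out = pd.DataFrame(
        {
            "x": disease.loc[shared, "log2fc"],
            "y": treatment.loc[shared, "log2fc"],
            "q_x": disease.loc[shared, "qvalue"],
            "q_y": treatment.loc[shared, "qvalue"],
        }
    )
    if universe == "union_significant":
        out = out[(out["q_x"] < alpha) | (out["q_y"] < alpha)]
    if len(out) == 0:
        raise ValidationError("no genes pass the universe rule")
    return out


def tls_fit(x, y) -> tuple[float, float]:
    """Total-least-squares line through (x, y): returns (slope, intercept).

    Closed form from the centered second moments S_xx, S_yy, S_xy:
    b = (S_yy - S_xx + sqrt((S_yy - S_xx)^2 + 4 S_xy^2)) / (2 S_xy),
    the slope of the principal axis of the scatter.  Degenerate cases with
    S_xy = 0: b = 0 when S_xx > S_yy (horizontal principal axis), an error
    when S_yy > S_xx (the TLS line is vertical and has no finite slope), and
    b = 0 by convention when S_xx = S_yy.  Intercept a = mean(y) - b*mean(x).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValidationError("TLS fit needs at least 3 points")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    sxy = float(xc @ yc)
    if sxx == 0.0 and sxy == 0.0:
        raise ValidationError("x values are all identical; TLS slope undefined")
    if sxy == 0.0:
        if syy > sxx:
            raise ValidationError("vertical TLS line: S_yy > S_xx with S_xy = 0")
        b = 0.0
    else:
        b = (syy - sxx + math.sqrt((syy - sxx) ** 2 + 4.0 * sxy ** 2)) / (2.0 * sxy)
    a = float(y.mean() - b * x.mean())
    return b, a


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided t-based p (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValidationError("Pearson correlation needs at least 3 points")
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("zero variance in x or y")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def classify_opposite(paired: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Classify each paired gene by significance pattern and sign agreement.

    reversed_significant: both q < alpha and opposite signs;
    concordant_significant: both q < alpha, same sign; disease_only /
    treatment_only: exactly one significant; neither otherwise.  A zero fold
    change has sign 0 and can never be reversed_significant.
    """
    for col in ("q_x", "q_y"):
        if col not in paired.columns or paired[col].isna().any():
            raise ValidationError("q-values required for both contrasts")
    sig_x = paired["q_x"].to_numpy() < alpha
    sig_y = paired["q_y"].to_numpy() < alpha
    sprod = np.sign(paired["x"].to_numpy()) * np.sign(paired["y"].to_numpy())
    labels = np.where(
        sig_x & sig_y,
        np.where(sprod < 0, "reversed_significant", "concordant_significant"),
        np.where(sig_x, "disease_only", np.where(sig_y, "treatment_only", "neither")),
    )
    return pd.Series(labels, index=paired.index, name="reversal_class")


def reversal_report(disease: pd.DataFrame, treatment: pd.DataFrame,
                    universe: str = "union_significant", alpha: float = 0.05,
                    n_bootstrap: int = 1000, seed: int = 0) -> ReversalReport:
    """Full reversal analysis: pairing, TLS fit, Pearson r, classification.

    The slope CI is a percentile bootstrap over gene pairs resampled with
    replacement (``n_bootstrap`` resamples; degenerate resamples where the
    TLS slope is undefined are skipped).
    """
    paired = paired_fc(disease, treatment, universe=universe, alpha=alpha)
    x = paired["x"].to_numpy()
    y = paired["y"].to_numpy()
    b, a = tls_fit(x, y)
    r, p = pearson_r(x, y)
    classes = classify_opposite(paired, alpha=alpha)

    rng = np.random.default_rng(seed)
    boots = []
    n = len(paired)
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        try:
            bb, _ = tls_fit(x[idx], y[idx])
        except ValidationError:
            continue
        boots.append(bb)
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
        # percentile CIs from few resamples can exclude the point estimate
        ci = (min(float(lo), b), max(float(hi), b))
    else:
        ci = (b, b)

    return ReversalReport(
        n_genes=n, pearson_r=r, pearson_p=p, tls_slope=b, tls_intercept=a,
        slope_ci=ci, n_bootstrap=n_bootstrap, seed=seed, universe=universe,
        alpha=alpha, classes=classes,
    )
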