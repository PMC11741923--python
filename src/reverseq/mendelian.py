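"""Two-sample Mendelian randomization: Wald ratios, IVW, multi-pair scan.

Each genetic instrument j gives an exposure effect (beta_exp, se_exp) — an
eQTL effect on gene or signature expression — and an outcome effect
(beta_out, se_out) on a trait from an independent sample.  The per-
instrument causal estimate is the Wald ratio beta_out / beta_exp; the
fixed-effect inverse-variance-weighted (IVW) estimate combines ratios with
weights 1/se_ratio^2, with Cochran's Q for heterogeneity.  A scan over
exposure-outcome pairs applies BH adjustment across the pairs' p-values.

First-order ratio SEs (se_out / |beta_exp|) are the default; the
delta-method option adds the exposure-noise term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ValidationError
from .diffexpr import bh_adjust

__all__ = ["MREstimate", "wald_ratio", "ivw", "mr_scan"]

REQUIRED_COLS = ("beta_exp", "se_exp", "beta_out", "se_out")


@dataclass(frozen=True)
class MREstimate:
    """IVW causal-effect estimate (trait units per expression unit)."""

    theta: float
    se: float
    z: float
    pvalue: float
    n_instruments: int
    q_stat: float
    q_pvalue: float
    ratios: pd.DataFrame = field(repr=False)  # per-instrument ratio and se


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float,
               se_method: str = "first_order") -> tuple[float, float]:
    """Per-instrument causal estimate beta_out / beta_exp and its SE.

    ``first_order``: se_out / |beta_exp|.  ``delta``: adds the exposure
    noise term, sqrt(se_out^2 / beta_exp^2 + beta_out^2 * se_exp^2 /
    beta_exp^4).
    """
    if beta_exp == 0:
        raise ValidationError("beta_exp = 0: null instrument has no Wald ratio")
    if se_exp <= 0 or se_out <= 0:
        raise ValidationError("standard errors must be positive")
    ratio = beta_out / beta_exp
    if se_method == "first_order":
        se = se_out / abs(beta_exp)
    elif se_method == "delta":
        se = math.sqrt(se_out ** 2 / beta_exp ** 2
                       + beta_out ** 2 * se_exp ** 2 / beta_exp ** 4)
    else:
        raise ValidationError(f"unknown se_method {se_method!r}")
    return ratio, se


def _validate_instruments(instruments: pd.DataFrame) -> pd.DataFrame:
    for c in REQUIRED_COLS:
        if c not in instruments.columns:
            raise ValidationError(f"instrument table missing column {c!r}")
    if instruments.index.duplicated().any():
        raise ValidationError("duplicate variant identifiers in instrument table")
    if ((instruments["se_exp"] <= 0) | (instruments["se_out"] <= 0)).any():
        raise ValidationError("instrument SEs must be positive")
    return instruments


def ivw(instruments: pd.DataFrame, se_method: str = "first_order",
        random_effects: bool = False) -> MREstimate:
    """Fixed-effect IVW estimate over an instrument table.

    Instruments with beta_exp = 0 are dropped (at least one valid instrument
    is required).  With a single instrument the estimate equals that
    instrument's Wald ratio.  ``random_effects`` applies multiplicative
    random-effects scaling of the SE by sqrt(max(1, Q / (J - 1))).
    """
    tab = _validate_instruments(instruments)
    valid = tab[tab["beta_exp"] != 0]
    if len(valid) == 0:
        raise ValidationError("no valid instruments (all beta_exp are zero)")
    ratios, ses = zip(*(
        wald_ratio(r.beta_exp, r.se_exp, r.beta_out, r.se_out, se_method=se_method)
        for r in valid.itertuples()))
    r = np.asarray(ratios)
    se = np.asarray(ses)
    w = 1.0 / se ** 2
    theta = float((w * r).sum() / w.sum())
    theta_se = float(1.0 / math.sqrt(w.sum()))
    q = float((w * (r - theta) ** 2).sum())
    dof = len(valid) - 1
    q_p = float(sps.chi2.sf(q, dof)) if dof > 0 else float("nan")
    if random_effects and dof > 0:
        theta_se *= math.sqrt(max(1.0, q / dof))
    z = theta / theta_se
    p = 2.0 * float(sps.norm.sf(abs(z)))
    ratio_tab = pd.DataFrame({"ratio": r, "se": se}, index=valid.index.copy())
    return MREstimate(theta=theta, se=theta_se, z=z, pvalue=p,
                      n_instruments=len(valid), q_stat=q, q_pvalue=q_p,
                      ratios=ratio_tab)


def mr_scan(pairs: Sequence[tuple[str, str, pd.DataFrame]],
            se_method: str = "first_order") -> pd.DataFrame:
    """IVW over a list of (exposure, outcome, instrument table) pairs.

    Returns a frame sorted by (exposure, outcome) with the IVW estimate per
    pair and BH q-values across the scan; pairs whose estimation fails are
    kept as rows with missing statistics and excluded from the BH m.
    """
    if len(pairs) == 0:
        raise ValidationError("mr_scan needs at least one exposure-outcome pair")
    rows = []
    for exposure, outcome, tab in pairs:
        try:
            est = ivw(tab, se_method=se_method)
            rows.append({"exposure": exposure, "outcome": outcome,
                         "n_instruments": est.n_instruments, "theta": est.theta,
                         "se": est.se, "z": est.z, "pvalue": est.pvalue,
                         "q_stat": est.q_stat, "q_pvalue": est.q_pvalue,
                         "error": ""})
        except ValidationError as exc:
            rows.append({"exposure": exposure, "outcome": outcome,
                         "n_instruments": 0, "theta": np.nan, "se": np.nan,
                         "z": np.nan, "pvalue": np.nan, "q_stat": np.nan,
                         "q_pvalue": np.nan, "error": str(exc)})
    out = pd.DataFrame(rows).sort_values(["exposure", "outcome"], kind="mergesort")
    out = out.reset_index(drop=True)
    out["qvalue"] = bh_adjust(out["pvalue"].to_numpy())
    return out
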