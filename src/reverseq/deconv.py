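"""Bulk cell-type deconvolution by non-negative least squares.

Each bulk expression profile is modeled as a non-negative combination of
cell-type reference profiles: minimize ||S^T w - b||^2 subject to w >= 0,
where S is the cell-type x gene signature matrix.  Both bulk and signature
are counts-per-million normalized on the linear scale before fitting (NNLS
assumes additivity of linear expression), and the fitted weights are
renormalized to proportions.  Group differences in proportions are assessed
per cell type with one-way ANOVA and Tukey HSD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import nnls

from .core import SampleDesign, ValidationError

__all__ = ["align_genes", "nnls_proportions", "group_compare", "cpm"]

MIN_SHARED_GENES = 10


def cpm(x: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million column normalization (columns = samples/profiles)."""
    tot = x.sum(axis=0)
    tot = tot.replace(0, np.nan)
    return (x / tot) * 1e6


def align_genes(bulk: pd.DataFrame, signature: pd.DataFrame,
                ) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Restrict bulk (genes x samples) and signature (cell types x genes)
    to their shared genes, in a common order; returns the overlap fraction
    relative to the signature's genes."""
    shared = [g for g in signature.columns if g in set(bulk.index)]
    if len(shared) < MIN_SHARED_GENES:
        raise ValidationError(
            f"only {len(shared)} genes shared between bulk and signature "
            f"(need >= {MIN_SHARED_GENES})")
    frac = len(shared) / signature.shape[1]
    return bulk.loc[shared], signature[shared], frac


@dataclass(frozen=True)
class DeconvResult:
    proportions: pd.DataFrame  # samples x cell types, rows on the simplex
    residuals: pd.Series       # per-sample residual norm of the NNLS fit


def nnls_proportions(bulk: pd.DataFrame, signature: pd.DataFrame,
                     normalize: bool = True) -> DeconvResult:
    """Estimate per-sample cell-type proportions by NNLS.

    ``bulk`` is genes x samples (non-negative, linear scale), ``signature``
    cell types x genes.  With ``normalize`` both sides are CPM-scaled
    first.  All-zero bulk profiles (and fits collapsing to all-zero
    weights) fall back to uniform proportions with a warning.
    """
    if signature.shape[0] < 2:
        raise ValidationError("signature needs >= 2 cell types")
    if (signature.to_numpy() < 0).any() or (bulk.to_numpy() < 0).any():
        raise ValidationError("bulk and signature must be non-negative")
    if (signature.sum(axis=1) == 0).any():
        raise ValidationError("signature has an all-zero cell-type row")
    b_al, s_al, _ = align_genes(bulk, signature)
    B = cpm(b_al).to_numpy() if normalize else b_al.to_numpy(dtype=float)
    S = cpm(s_al.T).to_numpy().T if normalize else s_al.to_numpy(dtype=float)

    import logging
    props = np.empty((bulk.shape[1], signature.shape[0]))
    resid = np.empty(bulk.shape[1])
    A = S.T  # genes x cell types
    for j in range(bulk.shape[1]):
        b = B[:, j]
        if not np.isfinite(b).all() or b.sum() == 0:
            logging.getLogger("reverseq").warning(
                "sample %r has an all-zero profile; uniform proportions returned",
                bulk.columns[j])
            props[j] = 1.0 / signature.shape[0]
            resid[j] = np.linalg.norm(np.nan_to_num(b))
            continue
        w, r = nnls(A, b)
        if w.sum() == 0:
            logging.getLogger("reverseq").warning(
                "NNLS weights all zero for sample %r; uniform proportions returned",
                bulk.columns[j])
            props[j] = 1.0 / signature.shape[0]
        else:
            props[j] = w / w.sum()
        resid[j] = r
    return DeconvResult(
        proportions=pd.DataFrame(props, index=bulk.columns, columns=signature.index),
        residuals=pd.Series(resid, index=bulk.columns, name="residual"),
    )


def group_compare(result: DeconvResult, design: SampleDesign) -> pd.DataFrame:
    """One-way ANOVA plus Tukey HSD on proportions per cell type.

    Returns a long frame with per-cell-type F and p plus one row per Tukey
    pairwise comparison; cell types with a degenerate group layout are
    skipped.  Requires >= 2 arms with >= 3 samples each.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    arms = design.table.loc[result.proportions.index, "arm"]
    groups = [g for g, cnt in arms.value_counts().items() if cnt >= 3]
    if len(groups) < 2:
        raise ValidationError("need >= 2 arms with >= 3 samples for group comparison")
    keep = arms.isin(groups)
    rows = []
    for ct in result.proportions.columns:
        vals = result.proportions.loc[keep, ct]
        by_group = [vals[arms[keep] == g].to_numpy() for g in groups]
        if any(len(v) < 2 for v in by_group):
            continue
        if all(np.ptp(v) == 0 for v in by_group) and len({v[0] for v in by_group}) == 1:
            rows.append({"cell_type": ct, "comparison": "anova", "statistic": 0.0,
                         "pvalue": 1.0})
            continue
        f, p = sps.f_oneway(*by_group)
        rows.append({"cell_type": ct, "comparison": "anova", "statistic": float(f),
                     "pvalue": float(p)})
        tk = pairwise_tukeyhsd(vals.to_numpy(), arms[keep].to_numpy())
        for (g1, g2), diff, p_adj in zip(
                zip(tk.groupsunique[tk._multicomp.pairindices[0]],
                    tk.groupsunique[tk._multicomp.pairindices[1]]),
                tk.meandiffs, tk.pvalues):
            rows.append({"cell_type": ct, "comparison": f"{g2} vs {g1}",
                         "statistic": float(diff), "pvalue": float(p_adj)})
    return pd.DataFrame(rows)
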