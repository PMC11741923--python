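"""Preranked gene-set enrichment: weighted KS enrichment score, NES,
gene-label permutation p-values and FDR.

Genes are ranked by a signed score derived from a contrast table (default
sign(log2FC) * -log10 p).  For a set S, the running sum increments at hits
by |score|^p / sum_hits |score|^p and decrements at misses by
1 / (N - |S|); the enrichment score ES is the maximum deviation from zero
(signed), and the leading edge is the members at or before the extremum.
The null is random membership of the same size (gene-label permutation),
NES = ES / mean |null ES| of matching sign, and FDR q compares the
sign-matched observed and null NES pools, as in the canonical preranked
procedure.  Results are deterministic for a fixed seed.

A thin over-representation helper (one-sided hypergeometric + BH) is
provided for annotating Venn cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import GeneSet, ValidationError
from .diffexpr import bh_adjust

__all__ = ["rank_genes", "es_score", "preranked_gsea", "hypergeom_overrep"]

MAX_ABS_SCORE = 308.0  # cap for -log10 p when p underflows to 0


def rank_genes(contrast: pd.DataFrame, metric: str = "signed_logp") -> pd.Series:
    """Ranking score per gene, sorted descending.

    ``signed_logp`` = sign(log2FC) * -log10(p), capped at +/-308;
    ``log2fc`` uses the fold change directly.  Ties are broken by gene id
    (lexicographic) so the ordering is deterministic.
    """
    if metric == "signed_logp":
        p = contrast["pvalue"].to_numpy(dtype=float)
        with np.errstate(divide="ignore"):
            mag = np.minimum(-np.log10(p), MAX_ABS_SCORE)
        score = np.sign(contrast["log2fc"].to_numpy()) * mag
    elif metric == "log2fc":
        score = contrast["log2fc"].to_numpy(dtype=float)
    else:
        raise ValidationError(f"unknown ranking metric {metric!r}")
    s = pd.Series(score, index=contrast.index, name="score").dropna()
    if not np.isfinite(s.to_numpy()).all():
        raise ValidationError("non-finite ranking scores")
    # descending by score, ascending by gene id on ties
    order = sorted(s.index, key=lambda g: (-s[g], g))
    return s.loc[order]


def _es_core(scores: np.ndarray, hit_mask: np.ndarray, p: float = 1.0,
              ) -> tuple[float, np.ndarray, int]:
    """Running-sum ES for a boolean hit mask over a descending score array."""
    n = scores.size
    n_hits = int(hit_mask.sum())
    if n_hits == 0 or n_hits == n:
        raise ValidationError("gene set must hit a strict subset of the ranked list")
    w = np.abs(scores) ** p
    hit_w = np.where(hit_mask, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        hit_w = hit_mask.astype(float)  # all member scores are 0: equal weights
        denom = hit_w.sum()
    step = hit_w / denom - (~hit_mask) / (n - n_hits)
    running = np.cumsum(step)
    i_max = int(np.argmax(np.abs(running)))
    es = float(running[i_max])
    return es, running, i_max


@dataclass(frozen=True)
class ESResult:
    es: float
    running: np.ndarray
    leading_edge: tuple[str, ...]


def es_score(ranked: pd.Series, gene_set: GeneSet, p: float = 1.0) -> ESResult:
    """Enrichment score of ``gene_set`` against a descending ranked list.

    Returns the signed maximum deviation of the weighted KS running sum,
    the running profile, and the leading edge: for positive ES the members
    at or before the extremum, for negative ES the members at or after it.
    """
    genes = ranked.index.to_numpy()
    hit = np.isin(genes, list(gene_set.members))
    if not hit.any():
        raise ValidationError(f"gene set {gene_set.name!r} has no overlap with the ranked list")
    es, running, i_max = _es_core(ranked.to_numpy(dtype=float), hit, p=p)
    if es >= 0:
        le = genes[: i_max + 1][hit[: i_max + 1]]
    else:
        le = genes[i_max:][hit[i_max:]]
    return ESResult(es=es, running=running, leading_edge=tuple(le))


def preranked_gsea(ranked: pd.Series, sets: Sequence[GeneSet], n_perm: int = 1000,
                   seed: int = 0, min_size: int = 5, max_size: int = 500,
                   weight: float = 1.0) -> pd.DataFrame:
    """Permutation GSEA over a collection of gene sets.

    Sets are filtered to [min_size, max_size] members after intersection
    with the ranked list.  Per set: ES; NES = ES / mean(|null ES| of the
    matching sign); nominal p = fraction of sign-matched null ES at least as
    extreme; FDR q from the pooled sign-matched null and observed NES
    distributions.  Returns a frame indexed by set name.
    """
    import logging
    if n_perm < 100:
        logging.getLogger("reverseq").warning(
            "n_perm=%d < 100: permutation q-values will be unstable", n_perm)
    scores = ranked.to_numpy(dtype=float)
    genes = ranked.index.to_numpy()
    n = genes.size
    gene_pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    kept: list[tuple[GeneSet, np.ndarray]] = []
    for gs in sets:
        idx = np.array(sorted(gene_pos[g] for g in gs.members if g in gene_pos), dtype=int)
        if min_size <= idx.size <= max_size and idx.size < n:
            kept.append((gs, idx))
        else:
            logging.getLogger("reverseq").warning(
                "gene set %r skipped (overlap %d outside [%d, %d])",
                gs.name, idx.size, min_size, max_size)
    if not kept:
        raise ValidationError("no gene sets pass the size filter")

    # permutation nulls are shared across sets of the same size
    null_by_size: dict[int, np.ndarray] = {}
    for _, idx in kept:
        k = idx.size
        if k in null_by_size:
            continue
        null = np.empty(n_perm)
        for b in range(n_perm):
            perm_idx = rng.choice(n, size=k, replace=False)
            mask = np.zeros(n, dtype=bool)
            mask[perm_idx] = True
            null[b], _, _ = _es_core(scores, mask, p=weight)
        null_by_size[k] = null

    rows = []
    norm_obs, norm_null = [], []
    for gs, idx in kept:
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        es, running, i_max = _es_core(scores, mask, p=weight)
        null = null_by_size[idx.size]
        same = null[null >= 0] if es >= 0 else null[null < 0]
        if same.size == 0:
            nes, p_nom = np.nan, np.nan
        else:
            mean_abs = np.abs(same).mean()
            nes = es / mean_abs if mean_abs > 0 else np.nan
            p_nom = float((np.abs(same) >= abs(es)).mean())
        pos_null = null[null >= 0]
        neg_null = null[null < 0]
        nn = np.concatenate([
            pos_null / (np.abs(pos_null).mean() if pos_null.size else 1.0),
            neg_null / (np.abs(neg_null).mean() if neg_null.size else 1.0),
        ])
        norm_null.append(nn)
        norm_obs.append(nes)
        if es >= 0:
            le = genes[: i_max + 1][mask[: i_max + 1]]
        else:
            le = genes[i_max:][mask[i_max:]]
        rows.append({"set": gs.name, "size": int(idx.size), "es": es, "nes": nes,
                     "pvalue": p_nom, "leading_edge": ",".join(le)})

    out = pd.DataFrame(rows).set_index("set")
    all_null = np.concatenate(norm_null)
    obs = np.asarray(norm_obs, dtype=float)
    qvals = np.full(obs.size, np.nan)
    for i, nes in enumerate(obs):
        if np.isnan(nes):
            continue
        if nes >= 0:
            null_frac = (all_null >= nes).mean() / max((all_null >= 0).mean(), 1e-12)
            obs_frac = (obs[~np.isnan(obs)] >= nes).mean() / max(
                (obs[~np.isnan(obs)] >= 0).mean(), 1e-12)
        else:
            null_frac = (all_null <= nes).mean() / max((all_null < 0).mean(), 1e-12)
            obs_frac = (obs[~np.isnan(obs)] <= nes).mean() / max(
                (obs[~np.isnan(obs)] < 0).mean(), 1e-12)
        qvals[i] = min(null_frac / max(obs_frac, 1e-12), 1.0)
    out["qvalue"] = qvals
    out.attrs["n_perm"] = n_perm
    out.attrs["seed"] = seed
    return out


def hypergeom_overrep(selected: Iterable[str], universe: Iterable[str],
                      sets: Sequence[GeneSet]) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``selected`` in each set."""
    uni = set(universe)
    sel = set(selected) & uni
    rows = []
    for gs in sets:
        members = gs.members & uni
        k = len(sel & members)
        p = sps.hypergeom.sf(k - 1, len(uni), len(members), len(sel)) if members else np.nan
        rows.append({"set": gs.name, "overlap": k, "set_size": len(members),
                     "pvalue": float(p) if p == p else np.nan})
    out = pd.DataFrame(rows).set_index("set")
    out["qvalue"] = bh_adjust(out["pvalue"].to_numpy())
    return out
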