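"""Time-course consistency signatures, PC1 scoring, phenotype correlation.

A gene responds "consistently" to a perturbation when it is significantly
changed in the same direction at every exposure time.  Partitioning the
per-timepoint significant sets by their exact pattern of timepoints (the
Venn cells) identifies such genes; intersecting the all-timepoints cell with
a curated reference set derives a tissue-specific sub-signature (the
construction behind a hepatocyte-restricted interferon-related DNA damage
signature).  Samples are then scored by the first principal component of the
signature genes' standardized log expression, and scores (or member genes)
are correlated against numeric phenotypes with BH adjustment across the
whole entity x phenotype table.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import GeneSet, PhenotypeTable, ValidationError
from .diffexpr import bh_adjust

__all__ = ["VennPartition", "SignatureScores", "consistent_deg_sets",
           "derive_signature", "pc1_score", "correlate_phenotypes"]


@dataclass(frozen=True)
class VennPartition:
    """Partition of direction-consistent significant genes by timepoint pattern.

    ``cells`` maps each non-empty combination of timepoints (as a sorted
    tuple) to the genes significant in the stated direction at exactly those
    timepoints.  Cells are therefore pairwise disjoint, and their union is
    the set of genes significant at >= 1 timepoint in that direction.
    """

    direction: str  # "up" or "down"
    timepoints: tuple[float, ...]
    cells: Mapping[tuple[float, ...], frozenset[str]]
    alpha: float

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for key, genes in self.cells.items():
            if seen & set(genes):
                raise ValidationError("Venn cells are not disjoint")
            seen |= set(genes)

    def cell(self, *timepoints: float) -> frozenset[str]:
        """Genes significant at exactly these timepoints (and no others)."""
        key = tuple(sorted(timepoints))
        return self.cells.get(key, frozenset())

    @property
    def all_timepoints(self) -> frozenset[str]:
        return self.cell(*self.timepoints)

    @property
    def union(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.cells.values():
            out |= genes
        return frozenset(out)


def consistent_deg_sets(contrasts: Mapping[float, pd.DataFrame],
                        alpha: float = 0.05, direction: str = "down") -> VennPartition:
    """Partition genes by their per-timepoint significance pattern.

    ``contrasts`` maps timepoint -> contrast table (with ``log2fc`` and
    ``qvalue``).  A gene is significant-in-direction at t iff q_t < alpha
    and sign(log2FC_t) matches ``direction``.  Gene namespaces must agree
    across timepoints (same tested universe).
    """
    if direction not in ("up", "down"):
        raise ValidationError("direction must be 'up' or 'down'")
    if len(contrasts) < 2:
        raise ValidationError("need contrasts at >= 2 timepoints")
    tps = tuple(sorted(contrasts))
    base = set(contrasts[tps[0]].index)
    for t in tps[1:]:
        if set(contrasts[t].index) != base:
            raise ValidationError(
                "contrast tables have mismatched gene namespaces across timepoints")
    want = 1.0 if direction == "up" else -1.0
    sig_at: dict[float, set[str]] = {}
    for t in tps:
        tab = contrasts[t]
        mask = (tab["qvalue"] < alpha) & (np.sign(tab["log2fc"]) == want)
        sig_at[t] = set(tab.index[mask])

    cells: dict[tuple[float, ...], frozenset[str]] = {}
    for k in range(1, len(tps) + 1):
        for combo in combinations(tps, k):
            genes = set.intersection(*(sig_at[t] for t in combo))
            for t in tps:
                if t not in combo:
                    genes -= sig_at[t]
            cells[tuple(sorted(combo))] = frozenset(genes)
    return VennPartition(direction=direction, timepoints=tps, cells=cells, alpha=alpha)


def derive_signature(partition: VennPartition, reference: GeneSet,
                     cell: str = "all_timepoints", name: str | None = None) -> GeneSet | None:
    """Intersect a Venn cell with a reference gene set.

    ``cell`` is ``"all_timepoints"`` or a comma-separated list of timepoints
    (e.g. ``"12,24"``).  An empty intersection returns ``None`` with a
    logged warning (an empty GeneSet is invalid by construction).  Enlarging
    the reference can only enlarge the result.
    """
    if cell == "all_timepoints":
        members = partition.all_timepoints
    else:
        try:
            tps = tuple(sorted(float(t) for t in cell.split(",")))
        except ValueError:
            raise ValidationError(f"unknown cell label {cell!r}") from None
        if any(t not in partition.timepoints for t in tps):
            raise ValidationError(f"unknown cell label {cell!r}: timepoints not in partition")
        members = partition.cell(*tps)
    hit = frozenset(reference.members) & members
    if not hit:
        import logging
        logging.getLogger("reverseq").warning(
            "signature derivation: reference %r does not intersect cell %r", reference.name, cell)
        return None
    label = name or f"{reference.name}_{partition.direction}_{cell}"
    return GeneSet(name=label,
                   description=f"{len(hit)}/{len(reference)} of {reference.name} "
                               f"{partition.direction} at cell {cell}",
                   members=hit)


@dataclass(frozen=True)
class SignatureScores:
    scores: pd.Series          # per-sample PC1 score
    variance_fraction: float   # lambda_1 / sum(lambda)
    loadings: pd.Series        # per-gene PC1 loading


def pc1_score(expr: pd.DataFrame, standardize: bool = True) -> SignatureScores:
    """Score samples by PC1 of signature-member expression.

    ``expr`` is genes x samples (log-scale normalized expression restricted
    to signature members).  Genes are z-scored by default; PC1 of the
    sample x gene matrix is returned with its fraction of variance.  The
    sign of PC1 is fixed so that scores correlate non-negatively with the
    per-sample mean of member z-scores (PCA sign is otherwise arbitrary).
    """
    if expr.shape[1] < 3:
        raise ValidationError("PC1 scoring needs >= 3 samples")
    X = expr.to_numpy(dtype=float).T  # samples x genes
    sd = X.std(axis=0, ddof=1)
    usable = sd > 0
    if usable.sum() < 2:
        raise ValidationError("need >= 2 signature members with nonzero variance")
    X = X[:, usable]
    Xc = X - X.mean(axis=0)
    if standardize:
        Xc = Xc / sd[usable]
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    scores = u[:, 0] * s[0]
    loadings = vt[0]
    var_frac = float(s[0] ** 2 / (s ** 2).sum())
    mean_z = Xc.mean(axis=1)
    if mean_z.std() > 0 and np.corrcoef(scores, mean_z)[0, 1] < 0:
        scores, loadings = -scores, -loadings
    load = pd.Series(0.0, index=expr.index, name="pc1_loading")
    load[expr.index[usable]] = loadings
    return SignatureScores(
        scores=pd.Series(scores, index=expr.columns, name="pc1_score"),
        variance_fraction=var_frac,
        loadings=load,
    )


def correlate_phenotypes(entities: pd.DataFrame, phenotypes: PhenotypeTable,
                         method: str = "pearson", min_pairs: int = 3) -> pd.DataFrame:
    """Correlate each entity (score or gene) with each phenotype.

    ``entities`` is samples x entities.  Returns a long frame with columns
    entity, phenotype, n, r, pvalue, qvalue; BH is applied across the whole
    table.  Pairs with fewer than ``min_pairs`` non-missing observations are
    kept as rows with missing statistics and excluded from the BH m.
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError("method must be 'pearson' or 'spearman'")
    shared = entities.index.intersection(phenotypes.table.index)
    if len(shared) < min_pairs:
        raise ValidationError("fewer than 3 shared samples")
    E = entities.loc[shared]
    P = phenotypes.table.loc[shared]
    rows = []
    for e in E.columns:
        for ph in P.columns:
            pair = pd.concat([E[e], P[ph]], axis=1).dropna()
            if len(pair) < min_pairs or pair.iloc[:, 0].std() == 0 or pair.iloc[:, 1].std() == 0:
                rows.append((e, ph, len(pair), np.nan, np.nan))
                continue
            if method == "pearson":
                r, p = sps.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
            else:
                r, p = sps.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
            rows.append((e, ph, len(pair), float(r), float(p)))
    out = pd.DataFrame(rows, columns=["entity", "phenotype", "n", "r", "pvalue"])
    out["qvalue"] = bh_adjust(out["pvalue"].to_numpy())
    return out
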