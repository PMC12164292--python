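"""Differential-abundance screen over digit-tip TPM matrices.

Each digit group is contrasted against the pooled remaining digits with a
two-sided Welch t-test on log2(TPM + pseudocount); p-values from all
gene x contrast tests are jointly Benjamini-Hochberg adjusted, and a gene
is a candidate when its best contrast passes the adjusted-p, |L2FC| and
between-group TPM-difference cutoffs.  This is a deliberately minimal
reconstruction of the screen's filtering logic, not of any particular
differential-expression tool-chain.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TpmMatrix",
    "ScreenThresholds",
    "DegenerateVarianceWarning",
    "contrast_stats",
    "bh_adjust",
    "screen",
]

_LABEL_RE = re.compile(r"^digit([IVX]+)_rep(\d+)$")


class DegenerateVarianceWarning(UserWarning):
    """Both contrast groups had zero variance; p reported as 1."""


@dataclass(frozen=True)
class ScreenThresholds:
    """Candidate cutoffs: adjusted p, |log2 fold change|, TPM difference."""

    alpha: float = 0.05
    min_l2fc: float = 1.0
    min_tpm_diff: float = 25.0
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if min(self.alpha, self.min_l2fc, self.min_tpm_diff, self.pseudocount) <= 0:
            raise ValueError("all screen thresholds must be positive")


class TpmMatrix:
    """A genes x samples TPM table whose columns encode (digit, replicate).

    Column labels follow ``digit<ROMAN>_rep<k>``, e.g. ``digitI_rep1``.
    """

    def __init__(self, frame: pd.DataFrame):
        if (frame.to_numpy() < 0).any():
            raise ValueError("TPM values must be non-negative")
        groups: dict[str, list[str]] = {}
        for col in frame.columns:
            m = _LABEL_RE.match(str(col))
            if not m:
                raise ValueError(f"bad sample label {col!r}; expected digit<ROMAN>_rep<k>")
            groups.setdefault(m.group(1), []).append(col)
        small = [g for g, cols in groups.items() if len(cols) < 2]
        if len(groups) < 2 or small:
            raise ValueError(
                f"need >= 2 digit groups with >= 2 replicates each "
                f"(groups: { {g: len(c) for g, c in groups.items()} })"
            )
        self.frame = frame
        self.groups = {g: list(cols) for g, cols in sorted(groups.items())}

    @property
    def genes(self) -> pd.Index:
        return self.frame.index

    def group_values(self, group: str) -> pd.DataFrame:
        return self.frame[self.groups[group]]

    def rest_values(self, group: str) -> pd.DataFrame:
        rest = [c for g, cols in self.groups.items() if g != group for c in cols]
        return self.frame[rest]

    @classmethod
    def from_tsv(cls, path: "str | Path") -> "TpmMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path: "str | Path") -> None:
        self.frame.to_csv(path, sep="\t")


def _welch_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized two-sided Welch t p-values over gene rows."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    return np.asarray(res.pvalue)


def contrast_stats(
    matrix: TpmMatrix,
    gene: str,
    group: str,
    pseudocount: float = 1.0,
) -> tuple[float, float]:
    """(l2fc, p) of one gene for one digit-vs-rest contrast.

    l2fc = log2((mean_group + pc) / (mean_rest + pc)); p is a two-sided
    Welch t-test on log2(TPM + pc).  When both groups are degenerate
    (zero variance) the test is undefined and p is reported as 1 with a
    :class:`DegenerateVarianceWarning`.
    """
    g = matrix.group_values(group).loc[gene].to_numpy(dtype=float)
    r = matrix.rest_values(group).loc[gene].to_numpy(dtype=float)
    l2fc = float(np.log2((g.mean() + pseudocount) / (r.mean() + pseudocount)))
    lg, lr = np.log2(g + pseudocount), np.log2(r + pseudocount)
    if np.var(lg) == 0 and np.var(lr) == 0:
        warnings.warn(
            f"{gene} digit{group}: zero variance in both groups, p undefined (reported 1)",
            DegenerateVarianceWarning,
            stacklevel=2,
        )
        return l2fc, 1.0
    p = float(_welch_p(lg[None, :], lr[None, :])[0])
    return l2fc, p


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    q_(i) = min_{j >= i} (m * p_(j) / j), clipped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adjusted, 0.0, 1.0)
    return out


def screen(matrix: TpmMatrix, thresholds: Optional[ScreenThresholds] = None) -> pd.DataFrame:
    """Run the digit-vs-rest screen over every gene.

    Returns one row per gene: ``best_group`` (contrast with the smallest
    raw p), ``l2fc``, ``p``, ``p_adj`` (BH over all gene x contrast tests
    jointly), ``max_tpm_diff`` (largest pairwise difference of group mean
    TPM) and the boolean ``candidate``.  Invariant to gene row order and
    to sample column order within groups.
    """
    th = thresholds or ScreenThresholds()
    genes = matrix.genes
    groups = list(matrix.groups)
    n_genes = len(genes)

    group_means = np.column_stack(
        [matrix.group_values(g).to_numpy(dtype=float).mean(axis=1) for g in groups]
    )
    max_diff = group_means.max(axis=1) - group_means.min(axis=1)

    l2fc = np.empty((n_genes, len(groups)))
    pval = np.empty((n_genes, len(groups)))
    for j, g in enumerate(groups):
        a = matrix.group_values(g).to_numpy(dtype=float)
        b = matrix.rest_values(g).to_numpy(dtype=float)
        l2fc[:, j] = np.log2((a.mean(axis=1) + th.pseudocount) / (b.mean(axis=1) + th.pseudocount))
        la, lb = np.log2(a + th.pseudocount), np.log2(b + th.pseudocount)
        p = _welch_p(la, lb)
        degenerate = (np.var(la, axis=1) == 0) & (np.var(lb, axis=1) == 0)
        p[degenerate] = 1.0  # test undefined without any within-group spread
        pval[:, j] = p

    p_adj = bh_adjust(pval.ravel()).reshape(pval.shape)
    best = np.argmin(pval, axis=1)
    rows = np.arange(n_genes)
    best_l2fc = l2fc[rows, best]
    best_p = pval[rows, best]
    best_padj = p_adj[rows, best]
    candidate = (
        (best_padj < th.alpha)
        & (np.abs(best_l2fc) >= th.min_l2fc)
        & (max_diff > th.min_tpm_diff)
    )
    return pd.DataFrame(
        {
            "best_group": [groups[j] for j in best],
            "l2fc": best_l2fc,
            "p": best_p,
            "p_adj": best_padj,
            "max_tpm_diff": max_diff,
            "candidate": candidate,
        },
        index=genes,
    )
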