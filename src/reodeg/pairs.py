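"""Stable within-sample relative expression orderings (REOs).

For a gene pair (Gi, Gj) let ``s`` be the number of samples in which Gi is
strictly above Gj out of ``n_eff`` untied samples.  Under the chance
hypothesis each ordering occurs with probability ``p0`` (0.5 by default), so
the upper-tail binomial probability P(X >= s) measures how surprising the
majority ordering is.  Pairs whose Benjamini-Hochberg q-value falls at or
below the FDR threshold form the phenotype's stable-pair background.

Exactly tied values support neither ordering: they are excluded from both
``s`` and ``n_eff``, and a pair split 50/50 is never called stable.

Pair enumeration streams over gene blocks so the full G(G-1)/2 scan of a
large matrix never materializes an O(G^2 * S) temporary; the per-pair
p-value takes at most (S+1)^2 distinct values, which lets the BH step run on
a tiny histogram instead of the full pair list.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import stats

from .io import validate_expression_matrix

__all__ = [
    "binomial_reo_pvalue",
    "pair_support_counts",
    "identify_stable_pairs",
    "StablePairSet",
    "grouped_bh",
]


def binomial_reo_pvalue(s: int, n: int, p0: float = 0.5) -> float:
    """Exact upper-tail binomial probability P(X >= s) for X ~ Bin(n, p0)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= s <= n:
        raise ValueError(f"s={s} outside [0, n={n}]")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie strictly between 0 and 1")
    return float(stats.binom.sf(s - 1, n, p0))


def grouped_bh(p: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values for a family given as (distinct p, multiplicity).

    Equivalent to running BH on the expanded vector: every copy of a distinct
    p-value shares the q-value of its highest rank.
    """
    p = np.asarray(p, dtype=float)
    counts = np.asarray(counts, dtype=np.int64)
    order = np.argsort(p, kind="mergesort")
    p_sorted = p[order]
    ranks = np.cumsum(counts[order])
    m = ranks[-1]
    q = p_sorted * m / ranks
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty_like(q)
    out[order] = q
    return out


@dataclass
class StablePairSet:
    """Directed stable pairs of one phenotype plus the test metadata.

    ``pairs`` columns: winner, loser (gene ids; winner above loser), s,
    n_eff, p, q.  ``n_tested`` is the BH family size (pairs with
    n_eff > 0), needed to reinterpret the q-values later.
    """

    pairs: pd.DataFrame
    gene_ids: list[str]
    phenotype: str = ""
    fdr: float = 0.05
    p0: float = 0.5
    n_tested: int = 0
    n_samples: int = 0

    def __len__(self) -> int:
        return len(self.pairs)

    def to_tsv(self, path: str | Path, compress: bool = True) -> None:
        path = Path(path)
        opener = gzip.open if compress else open
        with opener(path, "wt") as fh:
            fh.write(f"# phenotype={self.phenotype} fdr={self.fdr} "
                     f"n_tested={self.n_tested} n_samples={self.n_samples}\n")
            self.pairs.to_csv(fh, sep="\t", index=False)


def _block_size_for(n_genes: int, n_samples: int, requested: int | None) -> int:
    if requested is not None:
        return max(1, requested)
    # cap the boolean comparison temporary near ~200 MB
    budget = 2 * 10**8
    return int(np.clip(budget // max(1, n_genes * n_samples), 16, 1024))


def _iter_pair_blocks(
    X: np.ndarray, block_size: int
) -> Iterator[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]:
    """Yield (global row idx, gt, lt, upper-triangle mask) per gene block.

    gt[r, j] counts samples where gene row r is strictly above gene j.
    """
    n_genes = X.shape[0]
    all_j = np.arange(n_genes)
    for i0 in range(0, n_genes, block_size):
        i1 = min(i0 + block_size, n_genes)
        block = X[i0:i1]
        gt = (block[:, None, :] > X[None, :, :]).sum(axis=2, dtype=np.int32)
        lt = (block[:, None, :] < X[None, :, :]).sum(axis=2, dtype=np.int32)
        rows = np.arange(i0, i1)
        upper = all_j[None, :] > rows[:, None]
        yield rows, gt, lt, upper


def pair_support_counts(matrix: pd.DataFrame, block_size: int | None = None) -> pd.DataFrame:
    """Exact per-direction ordering counts for every unordered gene pair.

    Returns one row per pair (G(G-1)/2 rows) with columns gene_i, gene_j,
    s_ij (samples with gene_i > gene_j), s_ji, n_eff.  Genes are taken in
    lexicographic id order, so gene_i < gene_j.
    """
    matrix = validate_expression_matrix(matrix)
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    if matrix.shape[1] < 1:
        raise ValueError("need at least 1 sample")
    matrix = matrix.reindex(sorted(matrix.index))
    X = matrix.to_numpy(dtype=float)
    ids = np.asarray(matrix.index)
    bs = _block_size_for(*X.shape, requested=block_size)
    frames = []
    for rows, gt, lt, upper in _iter_pair_blocks(X, bs):
        r, j = np.nonzero(upper)
        frames.append(
            pd.DataFrame(
                {
                    "gene_i": ids[rows[r]],
                    "gene_j": ids[j],
                    "s_ij": gt[r, j],
                    "s_ji": lt[r, j],
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out["n_eff"] = out["s_ij"] + out["s_ji"]
    return out


def identify_stable_pairs(
    matrix: pd.DataFrame,
    fdr: float = 0.05,
    p0: float = 0.5,
    phenotype: str = "",
    block_size: int | None = None,
) -> StablePairSet:
    """Find gene pairs whose majority REO is significant after BH correction.

    For each pair the test statistic is the majority count s = max(s_ij,
    s_ji) with an upper-tail binomial p-value; the BH family is every pair
    with at least one untied sample.  Pairs with q <= ``fdr`` are returned in
    their majority direction; exact 50/50 splits are never stable.
    """
    matrix = validate_expression_matrix(matrix)
    if not 0.0 < fdr <= 1.0:
        raise ValueError("fdr must lie in (0, 1]")
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    n_samples = matrix.shape[1]
    if n_samples < 3:
        warnings.warn(
            f"only {n_samples} samples: stable-pair calls will have little power",
            stacklevel=2,
        )
    matrix = matrix.reindex(sorted(matrix.index))
    X = matrix.to_numpy(dtype=float)
    ids = np.asarray(matrix.index)
    n_genes = X.shape[0]
    bs = _block_size_for(n_genes, n_samples, block_size)

    # p-value lookup over the (majority s, n_eff) grid
    S = n_samples
    s_grid, n_grid = np.meshgrid(np.arange(S + 1), np.arange(S + 1), indexing="ij")
    with np.errstate(invalid="ignore"):
        p_table = stats.binom.sf(s_grid - 1, np.maximum(n_grid, 1), p0)
    p_table[:, 0] = 1.0  # n_eff == 0: untestable

    # pass 1: histogram of (majority s, n_eff) across all pairs
    hist = np.zeros((S + 1) * (S + 1), dtype=np.int64)
    for rows, gt, lt, upper in _iter_pair_blocks(X, bs):
        smaj = np.maximum(gt, lt)[upper]
        neff = (gt + lt)[upper]
        hist += np.bincount(smaj * (S + 1) + neff, minlength=(S + 1) * (S + 1))
    hist2d = hist.reshape(S + 1, S + 1)
    testable = hist2d.copy()
    testable[:, 0] = 0
    n_tested = int(testable.sum())
    if n_tested == 0:
        raise ValueError("no gene pair has an untied sample; nothing to test")

    # exact BH over the histogram of distinct p-values
    q_table = np.ones_like(p_table)
    idx = np.nonzero(testable)
    q_table[idx] = grouped_bh(p_table[idx], testable[idx])

    # pass 2: collect pairs passing the threshold in their majority direction
    win_parts, lose_parts, s_parts, n_parts = [], [], [], []
    for rows, gt, lt, upper in _iter_pair_blocks(X, bs):
        smaj = np.maximum(gt, lt)
        neff = gt + lt
        keep = upper & (gt != lt) & (neff > 0) & (q_table[smaj, neff] <= fdr)
        r, j = np.nonzero(keep)
        gi = rows[r]
        i_wins = gt[r, j] > lt[r, j]
        win_parts.append(np.where(i_wins, gi, j))
        lose_parts.append(np.where(i_wins, j, gi))
        s_parts.append(smaj[r, j])
        n_parts.append(neff[r, j])
    winner = np.concatenate(win_parts) if win_parts else np.array([], dtype=int)
    loser = np.concatenate(lose_parts) if lose_parts else np.array([], dtype=int)
    s = np.concatenate(s_parts) if s_parts else np.array([], dtype=int)
    n_eff = np.concatenate(n_parts) if n_parts else np.array([], dtype=int)
    pairs = pd.DataFrame(
        {
            "winner": ids[winner],
            "loser": ids[loser],
            "s": s.astype(np.int64),
            "n_eff": n_eff.astype(np.int64),
            "p": p_table[s, n_eff] if len(s) else np.array([], dtype=float),
            "q": q_table[s, n_eff] if len(s) else np.array([], dtype=float),
        }
    )
    return StablePairSet(
        pairs=pairs,
        gene_ids=ids.tolist(),
        phenotype=phenotype,
        fdr=fdr,
        p0=p0,
        n_tested=n_tested,
        n_samples=n_samples,
    )
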