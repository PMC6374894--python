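"""The RankCompV2 differential-expression caller.

The caller compares two phenotypes only through within-sample orderings.
Gene pairs stable in *both* phenotypes are intersected; a pair whose stable
direction flips between phenotypes is a reversal.  For each gene G the
overlap pairs involving G define a 2x2 contingency table:

              G > partner   G < partner
    normal        a              b
    disease       c              d

with a + b = c + d (each pair contributes one vote per phenotype).  A
two-sided Fisher exact test asks whether the G-above fraction differs
between phenotypes.  Because candidate DEGs distort their partners'
tables, pairs whose partner is a current candidate are excluded and the
tests repeated until the number of candidates is stable across two
successive iterations.

The model/results split mirrors the statsmodels convention: build a
:class:`RankCompV2` from the two cohort matrices, call :meth:`~RankCompV2.fit`,
and read the DEG table and diagnostics off the returned
:class:`RankCompResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .io import validate_expression_matrix
from .pairs import StablePairSet, identify_stable_pairs

__all__ = [
    "fisher_exact_two_sided",
    "overlap_pairs",
    "gene_table",
    "OverlapPairs",
    "RankCompV2",
    "RankCompResults",
    "call_degs",
]


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sums the hypergeometric probabilities of every table with the same
    margins whose point probability is at most that of the observed table
    (relative tolerance 1e-7).  The all-zero table carries no evidence and
    returns 1.0.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        return 1.0
    r1, c1 = a + b, a + c
    lo = max(0, r1 - (n - c1))
    hi = min(r1, c1)
    x = np.arange(lo, hi + 1)
    # hypergeometric pmf over the whole support via log-gamma (fast and
    # accurate to ~1e-13 relative, well inside the 1e-7 comparison tolerance)
    logc = gammaln(np.array([c1 + 1, n - c1 + 1, n + 1, r1 + 1, n - r1 + 1]))
    log_pmf = (
        logc[0] - gammaln(x + 1) - gammaln(c1 - x + 1)
        + logc[1] - gammaln(r1 - x + 1) - gammaln(n - c1 - r1 + x + 1)
        - (logc[2] - logc[3] - logc[4])
    )
    pmf = np.exp(log_pmf)
    p_obs = pmf[a - lo]
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + 1e-7)].sum()))


@dataclass
class OverlapPairs:
    """Pairs stable in both phenotypes, with per-phenotype directions.

    ``gene_ids`` is the lexicographically sorted shared universe; ``i`` and
    ``j`` index into it with i < j.  Direction +1 means gene i above gene j.
    """

    gene_ids: np.ndarray
    i: np.ndarray
    j: np.ndarray
    dir_normal: np.ndarray
    dir_disease: np.ndarray

    @property
    def reversed_flags(self) -> np.ndarray:
        return self.dir_normal != self.dir_disease

    @property
    def n_reversed(self) -> int:
        return int(self.reversed_flags.sum())

    def __len__(self) -> int:
        return len(self.i)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_i": self.gene_ids[self.i],
                "gene_j": self.gene_ids[self.j],
                "dir_normal": self.dir_normal,
                "dir_disease": self.dir_disease,
                "reversed": self.reversed_flags,
            }
        )


def _pair_keys(pairs: pd.DataFrame, index: pd.Index, n: int) -> tuple[np.ndarray, np.ndarray]:
    wi = index.get_indexer(pairs["winner"])
    lo = index.get_indexer(pairs["loser"])
    if (wi < 0).any() or (lo < 0).any():
        raise ValueError("stable pair sets are not drawn from the same gene universe")
    i = np.minimum(wi, lo)
    j = np.maximum(wi, lo)
    direction = np.where(wi < lo, 1, -1)
    return i.astype(np.int64) * n + j, direction


def overlap_pairs(normal: StablePairSet, disease: StablePairSet) -> OverlapPairs:
    """Intersect two stable-pair sets on unordered pairs, keeping both directions."""
    universe = sorted(set(normal.gene_ids) | set(disease.gene_ids))
    index = pd.Index(universe)
    n = len(universe)
    keys_n, dir_n = _pair_keys(normal.pairs, index, n)
    keys_d, dir_d = _pair_keys(disease.pairs, index, n)
    common, idx_n, idx_d = np.intersect1d(keys_n, keys_d, assume_unique=True, return_indices=True)
    if len(common) == 0:
        raise ValueError("phenotypes share no stable background")
    return OverlapPairs(
        gene_ids=np.asarray(universe),
        i=(common // n).astype(np.int64),
        j=(common % n).astype(np.int64),
        dir_normal=dir_n[idx_n],
        dir_disease=dir_d[idx_d],
    )


def gene_table(
    gene: str, overlaps: OverlapPairs, excluded: frozenset[str] | set[str] = frozenset()
) -> tuple[int, int, int, int]:
    """Contingency table (a, b, c, d) for one gene over non-excluded partners.

    Reference implementation used for inspection and testing; the fitter
    computes all tables at once with bincounts.
    """
    if gene in excluded:
        raise ValueError(f"gene {gene!r} is in the excluded set")
    ids = overlaps.gene_ids
    a = b = c = d = 0
    for i, j, dn, dd in zip(overlaps.i, overlaps.j, overlaps.dir_normal, overlaps.dir_disease):
        gi, gj = ids[i], ids[j]
        if gene == gi:
            partner, g_above_n, g_above_d = gj, dn > 0, dd > 0
        elif gene == gj:
            partner, g_above_n, g_above_d = gi, dn < 0, dd < 0
        else:
            continue
        if partner in excluded:
            continue
        a += g_above_n
        b += not g_above_n
        c += g_above_d
        d += not g_above_d
    return a, b, c, d


@dataclass
class RankCompResults:
    """Fit output: the DEG table plus run diagnostics.

    ``degs`` columns: gene, direction (up/down), p, q, a, b, c, d,
    n_iterations.  ``iteration_counts`` records the candidate count at each
    iteration, including the final stabilizing one.
    """

    degs: pd.DataFrame
    converged: bool
    iteration_counts: list[int]
    n_stable_normal: int
    n_stable_disease: int
    n_overlap: int
    n_reversed: int
    n_genes: int
    params: dict
    warnings: list[str] = field(default_factory=list)

    @property
    def n_iterations(self) -> int:
        return len(self.iteration_counts)

    def summary(self) -> str:
        up = int((self.degs["direction"] == "up").sum())
        down = int((self.degs["direction"] == "down").sum())
        lines = [
            "RankCompV2 results",
            "==================",
            f"genes tested          {self.n_genes}",
            f"stable pairs (normal) {self.n_stable_normal}",
            f"stable pairs (disease){self.n_stable_disease:>7}",
            f"overlap pairs         {self.n_overlap}",
            f"reversal pairs        {self.n_reversed}",
            f"iterations            {self.n_iterations}"
            + ("" if self.converged else "  (NOT converged)"),
            f"DEGs                  {len(self.degs)} ({up} up, {down} down)",
            f"stable-pair FDR       {self.params['stable_fdr']}",
            f"DEG FDR               {self.params['deg_fdr']}",
        ]
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)

    def to_run_log(self) -> dict:
        return {
            "converged": self.converged,
            "iteration_counts": self.iteration_counts,
            "n_stable_normal": self.n_stable_normal,
            "n_stable_disease": self.n_stable_disease,
            "n_overlap": self.n_overlap,
            "n_reversed": self.n_reversed,
            "n_genes": self.n_genes,
            "n_degs": int(len(self.degs)),
            "params": self.params,
            "warnings": self.warnings,
        }


class RankCompV2:
    """REO-reversal differential-expression model for two cohorts.

    Parameters
    ----------
    normal, disease
        Gene x sample matrices over the same gene universe.  Any within-
        sample monotone normalization (raw counts, RPKM, log2) gives
        identical results.
    stable_fdr
        BH threshold for the per-phenotype stable-pair background.
    deg_fdr
        BH threshold for the per-gene Fisher tests.
    max_iter
        Safety cap on the partner-exclusion iteration.
    """

    def __init__(
        self,
        normal: pd.DataFrame,
        disease: pd.DataFrame,
        *,
        stable_fdr: float = 0.05,
        deg_fdr: float = 0.05,
        p0: float = 0.5,
        max_iter: int = 100,
        block_size: int | None = None,
    ) -> None:
        normal = validate_expression_matrix(normal, "normal")
        disease = validate_expression_matrix(disease, "disease")
        if set(normal.index) != set(disease.index):
            raise ValueError("normal and disease matrices must share the gene universe")
        self.normal = normal
        self.disease = disease
        self.stable_fdr = stable_fdr
        self.deg_fdr = deg_fdr
        self.p0 = p0
        self.max_iter = max_iter
        self.block_size = block_size
        self._fisher_cache: dict[tuple[int, int, int, int], float] = {}

    # -- internals ---------------------------------------------------------

    def _fisher(self, table: tuple[int, int, int, int]) -> float:
        p = self._fisher_cache.get(table)
        if p is None:
            p = fisher_exact_two_sided(*table)
            self._fisher_cache[table] = p
        return p

    def _iteration_tests(
        self,
        g: np.ndarray,
        partner: np.ndarray,
        g_above_n: np.ndarray,
        g_above_d: np.ndarray,
        excluded: np.ndarray,
        n_genes: int,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """One sweep of contingency tables + Fisher p-values for every gene."""
        use = ~excluded[partner]
        a = np.bincount(g[use & g_above_n], minlength=n_genes)
        b = np.bincount(g[use & ~g_above_n], minlength=n_genes)
        c = np.bincount(g[use & g_above_d], minlength=n_genes)
        tables = np.stack([a, b, c, a + b - c], axis=1)
        p = np.ones(n_genes)
        # a == c means no net reversal: the observed table is modal, p = 1
        need = ((a + b) > 0) & (a != c)
        if need.any():
            uniq, inverse = np.unique(tables[need], axis=0, return_inverse=True)
            p_uniq = np.array([self._fisher(tuple(int(x) for x in t)) for t in uniq])
            p[need] = p_uniq[inverse]
        return tables, p, (a + b) > 0

    # -- fitting -----------------------------------------------------------

    def fit(self) -> RankCompResults:
        warnings_log: list[str] = []
        for name, mat in (("normal", self.normal), ("disease", self.disease)):
            if mat.shape[1] < 3:
                warnings_log.append(f"{name} cohort has fewer than 3 samples")

        stable_n = identify_stable_pairs(
            self.normal, fdr=self.stable_fdr, p0=self.p0,
            phenotype="normal", block_size=self.block_size,
        )
        stable_d = identify_stable_pairs(
            self.disease, fdr=self.stable_fdr, p0=self.p0,
            phenotype="disease", block_size=self.block_size,
        )
        overlaps = overlap_pairs(stable_n, stable_d)

        ids = overlaps.gene_ids
        n_genes = len(ids)
        # expand each pair into two gene-centric rows
        g = np.concatenate([overlaps.i, overlaps.j])
        partner = np.concatenate([overlaps.j, overlaps.i])
        g_above_n = np.concatenate([overlaps.dir_normal > 0, overlaps.dir_normal < 0])
        g_above_d = np.concatenate([overlaps.dir_disease > 0, overlaps.dir_disease < 0])

        excluded = np.zeros(n_genes, dtype=bool)
        prev_candidates: np.ndarray | None = None
        prev2_candidates: np.ndarray | None = None
        iteration_counts: list[int] = []
        converged = False
        oscillating = False
        tables = np.zeros((n_genes, 4), dtype=np.int64)
        p = np.ones(n_genes)
        q = np.ones(n_genes)
        candidates = np.zeros(n_genes, dtype=bool)

        prev_state: tuple | None = None
        for _ in range(self.max_iter):
            tables, p, tested = self._iteration_tests(
                g, partner, g_above_n, g_above_d, excluded, n_genes
            )
            q = np.ones(n_genes)
            if tested.any():
                q[tested] = multipletests(p[tested], method="fdr_bh")[1]
            candidates = tested & (q <= self.deg_fdr) & (tables[:, 0] != tables[:, 2])
            iteration_counts.append(int(candidates.sum()))
            if prev_candidates is not None and candidates.sum() == prev_candidates.sum():
                converged = True
                if not np.array_equal(candidates, prev_candidates):
                    warnings_log.append(
                        "DEG count stabilized but membership differs between the "
                        "last two iterations"
                    )
                break
            if prev2_candidates is not None and np.array_equal(candidates, prev2_candidates):
                # The exclusion map has entered a period-2 cycle: the DEG count
                # alternates forever between two self-consistent states.  Stop
                # and report the smaller (more conservative) of the two.
                oscillating = True
                warnings_log.append(
                    "candidate set oscillates between two states; reporting the "
                    "smaller one"
                )
                if prev_state is not None and prev_candidates.sum() < candidates.sum():
                    tables, p, q, candidates = prev_state
                break
            prev2_candidates = prev_candidates
            prev_candidates = candidates
            prev_state = (tables, p, q, candidates)
            excluded = candidates
        if not converged and not oscillating:
            warnings_log.append(f"not converged after {self.max_iter} iterations")

        a, b, c, d = tables.T
        sel = np.nonzero(candidates)[0]
        direction = np.where(c[sel] > a[sel], "up", "down")
        degs = pd.DataFrame(
            {
                "gene": ids[sel],
                "direction": direction,
                "p": p[sel],
                "q": q[sel],
                "a": a[sel],
                "b": b[sel],
                "c": c[sel],
                "d": d[sel],
                "n_iterations": len(iteration_counts),
            }
        )
        degs = degs.sort_values(["q", "p", "gene"], kind="mergesort").reset_index(drop=True)
        return RankCompResults(
            degs=degs,
            converged=converged,
            iteration_counts=iteration_counts,
            n_stable_normal=len(stable_n),
            n_stable_disease=len(stable_d),
            n_overlap=len(overlaps),
            n_reversed=overlaps.n_reversed,
            n_genes=n_genes,
            params={
                "stable_fdr": self.stable_fdr,
                "deg_fdr": self.deg_fdr,
                "p0": self.p0,
                "max_iter": self.max_iter,
            },
            warnings=warnings_log,
        )


def call_degs(
    normal: pd.DataFrame,
    disease: pd.DataFrame,
    stable_fdr: float = 0.05,
    deg_fdr: float = 0.05,
    p0: float = 0.5,
    max_iter: int = 100,
    block_size: int | None = None,
) -> RankCompResults:
    """Convenience wrapper: build a :class:`RankCompV2` model and fit it."""
    return RankCompV2(
        normal,
        disease,
        stable_fdr=stable_fdr,
        deg_fdr=deg_fdr,
        p0=p0,
        max_iter=max_iter,
        block_size=block_size,
    ).fit()
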