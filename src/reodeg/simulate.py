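"""Synthetic RNA-seq cohorts and spike-in fold-change designs.

The generator emulates a normal-tissue RNA-seq cohort: each gene draws a
mean once (log-normal across genes) and every sample draws a negative-
binomial count around that mean.  Shared gene means induce the stable
within-cohort ordering structure that rank-based calling relies on.

Disease cohorts are made by multiplying selected genes' counts by a fold
change (the per-cell transcript number N changes), then rescaling every
disease count by a single transcriptome-size factor so both cohorts carry
the same grand total - the sequencing analogue of extracting equal RNA
amounts S from cells with unequal per-cell totals T: with n = S/T cells
contributing, the measured signal M = r * N * S/T is proportional to the
concentration N/T, not to N itself.  The factor (baseline total / modified
total) is the quantity the size-factor model predicts to shrink as the
spiked-in up-mass grows.

Uniform rescaling is strictly monotone within each sample, so every
within-sample ordering - and therefore every rank-based result - is
identical before and after rescaling, while count-based callers see all
totals shifted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import validate_expression_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "BaselineParams",
    "SimulationTruth",
    "generate_baseline",
    "assign_fc_groups",
    "apply_fc",
    "rescale_to_common_total",
    "make_null_split",
]

FOUR_GROUP_UP_FCS = (2.0, 3.0, 4.0, 5.0)


@dataclass(frozen=True)
class BaselineParams:
    """Conditions for the synthetic normal cohort.

    ``mean_log`` / ``sigma_log`` parameterize the log-normal distribution of
    per-gene means on the natural-log scale (sigma_log = 1.5 corresponds to
    an SD of about 2.2 on the log2 scale, a typical bulk RNA-seq spread).
    ``dispersion`` is the NB dispersion (variance = mu + dispersion * mu^2;
    0.10 gives a biological CV of ~0.32, typical for human tissue cohorts).
    """

    n_genes: int = 13000
    n_samples: int = 27
    seed: int = 0
    mean_log: float = 4.0
    sigma_log: float = 1.5
    dispersion: float = 0.1

    def __post_init__(self) -> None:
        if self.n_genes < 2 or self.n_samples < 1:
            raise ValueError("need at least 2 genes and 1 sample")
        if self.sigma_log <= 0 or self.dispersion <= 0:
            raise ValueError("sigma_log and dispersion must be positive")


@dataclass
class SimulationTruth:
    """Per-gene true fold change plus the design metadata.

    fc == 1 marks non-DEGs; fc > 1 up-regulation and fc < 1 down-regulation
    of the per-cell transcript number.
    """

    fc: pd.Series
    n_up: int
    n_down: int
    scheme: str
    seed: int

    @property
    def up_genes(self) -> pd.Index:
        return self.fc.index[self.fc > 1.0]

    @property
    def down_genes(self) -> pd.Index:
        return self.fc.index[self.fc < 1.0]

    @property
    def deg_genes(self) -> pd.Index:
        return self.fc.index[self.fc != 1.0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.fc.index, "fc": self.fc.to_numpy()})


def generate_baseline(params: BaselineParams) -> pd.DataFrame:
    """Draw an integer NB count matrix; same seed, same matrix."""
    rng = np.random.default_rng(params.seed)
    mu = rng.lognormal(params.mean_log, params.sigma_log, params.n_genes)
    r = 1.0 / params.dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p[:, None], size=(params.n_genes, params.n_samples))
    width = len(str(params.n_genes))
    genes = [f"G{i:0{width}d}" for i in range(params.n_genes)]
    samples = [f"S{j:02d}" for j in range(params.n_samples)]
    return pd.DataFrame(counts, index=genes, columns=samples)


def _parse_scheme(scheme) -> tuple[str, float | None]:
    if isinstance(scheme, (tuple, list)) and len(scheme) == 2 and scheme[0] == "uniform":
        return "uniform", float(scheme[1])
    if isinstance(scheme, str):
        if scheme == "four_group":
            return "four_group", None
        if scheme.startswith("uniform:"):
            return "uniform", float(scheme.split(":", 1)[1])
    raise ValueError(f"unknown FC scheme {scheme!r}; expected 'four_group' or 'uniform:FC'")


def _split_round_robin(items: np.ndarray, n_groups: int) -> list[np.ndarray]:
    base, rem = divmod(len(items), n_groups)
    if rem:
        logger.info("group size %d not divisible by %d; distributing remainder round-robin",
                    len(items), n_groups)
    sizes = [base + (1 if k < rem else 0) for k in range(n_groups)]
    bounds = np.cumsum([0, *sizes])
    return [items[bounds[k]:bounds[k + 1]] for k in range(n_groups)]


def assign_fc_groups(gene_ids, n_up: int, n_down: int, scheme="four_group",
                     seed: int = 0) -> SimulationTruth:
    """Select DEGs without replacement and assign their true fold changes.

    ``four_group`` splits the up-regulated genes into four equal groups with
    FC 2, 3, 4 and 5 and the down-regulated genes with the reciprocals;
    ``uniform:FC`` gives every up gene FC and every down gene 1/FC.
    """
    gene_ids = pd.Index(gene_ids)
    if n_up < 0 or n_down < 0:
        raise ValueError("n_up and n_down must be non-negative")
    if n_up + n_down > len(gene_ids):
        raise ValueError("cannot select more DEGs than genes")
    kind, uniform_fc = _parse_scheme(scheme)
    rng = np.random.default_rng(seed)
    selected = rng.choice(len(gene_ids), size=n_up + n_down, replace=False)
    ups, downs = selected[:n_up], selected[n_up:]
    fc = pd.Series(1.0, index=gene_ids, name="fc")
    if kind == "four_group":
        for group, level in zip(_split_round_robin(ups, 4), FOUR_GROUP_UP_FCS):
            fc.iloc[group] = level
        for group, level in zip(_split_round_robin(downs, 4), FOUR_GROUP_UP_FCS):
            fc.iloc[group] = 1.0 / level
        scheme_label = "four_group"
    else:
        if uniform_fc is None or uniform_fc <= 1.0:
            raise ValueError("uniform scheme needs an FC level > 1")
        fc.iloc[ups] = uniform_fc
        fc.iloc[downs] = 1.0 / uniform_fc
        scheme_label = f"uniform:{uniform_fc:g}"
    return SimulationTruth(fc=fc, n_up=n_up, n_down=n_down, scheme=scheme_label, seed=seed)


def apply_fc(baseline: pd.DataFrame, truth: SimulationTruth) -> pd.DataFrame:
    """Multiply each gene's counts by its true fold change (pre-rescaling)."""
    baseline = validate_expression_matrix(baseline, "baseline")
    missing = baseline.index.difference(truth.fc.index)
    if len(missing):
        raise ValueError(f"truth does not cover gene(s): {missing.tolist()[:5]}")
    return baseline.mul(truth.fc.reindex(baseline.index), axis=0)


def rescale_to_common_total(
    baseline: pd.DataFrame,
    modified: pd.DataFrame,
    rounding: str = "none",
) -> tuple[pd.DataFrame, float]:
    """Scale the modified cohort so both cohorts share one grand total.

    factor = (baseline grand total) / (modified grand total); every modified
    count is multiplied by it.  ``rounding='nearest'`` re-rounds to integers
    for consumers that require them; the default keeps exact reals.
    """
    baseline = validate_expression_matrix(baseline, "baseline")
    modified = validate_expression_matrix(modified, "modified")
    if baseline.size == 0 or modified.size == 0:
        raise ValueError("matrices must be non-empty")
    total_mod = float(modified.to_numpy().sum())
    if total_mod == 0:
        raise ValueError("modified matrix has zero grand total")
    factor = float(baseline.to_numpy().sum()) / total_mod
    rescaled = modified * factor
    if rounding == "nearest":
        rescaled = pd.DataFrame(
            np.rint(rescaled.to_numpy()), index=rescaled.index, columns=rescaled.columns
        )
    elif rounding != "none":
        raise ValueError("rounding must be 'none' or 'nearest'")
    return rescaled, factor


def make_null_split(normal: pd.DataFrame, seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded partition of one cohort into two disjoint near-equal halves."""
    normal = validate_expression_matrix(normal, "normal")
    n = normal.shape[1]
    if n < 6:
        raise ValueError("null split needs at least 6 samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    size_a = math.ceil(n / 2)
    in_a = np.zeros(n, dtype=bool)
    in_a[perm[:size_a]] = True
    return normal.loc[:, in_a], normal.loc[:, ~in_a]
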