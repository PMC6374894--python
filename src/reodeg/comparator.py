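"""Bridge to a count-based DEG caller (Bioconductor edgeR) for contrast runs.

edgeR is invoked as an external Rscript subprocess - TMM normalization,
common/tagwise dispersion, exact test, BH FDR - and its DEG list is
normalized into the package's directed-DEG schema.  The tool is optional:
callers must treat :class:`ComparatorUnavailableError` as "comparator
cells missing", not as a pipeline failure.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ComparatorUnavailableError", "comparator_available", "run_edger"]


class ComparatorUnavailableError(RuntimeError):
    """Raised when Rscript or the edgeR package cannot be used."""


_EDGER_SCRIPT = r"""
suppressMessages(library(edgeR))
args <- commandArgs(trailingOnly = TRUE)
counts_path <- args[1]
n_first <- as.integer(args[2])
out_path <- args[3]
x <- read.delim(counts_path, row.names = 1, check.names = FALSE)
grp <- factor(c(rep("N", n_first), rep("D", ncol(x) - n_first)), levels = c("N", "D"))
y <- DGEList(counts = as.matrix(x), group = grp)
y <- calcNormFactors(y)           # TMM
y <- estimateDisp(y)
et <- exactTest(y)
tt <- topTags(et, n = Inf)$table
out <- data.frame(gene = rownames(tt), logFC = tt$logFC,
                  PValue = tt$PValue, FDR = tt$FDR)
write.table(out, out_path, sep = "\t", quote = FALSE, row.names = FALSE)
"""


@lru_cache(maxsize=1)
def comparator_available() -> bool:
    """True when Rscript is on PATH and can load edgeR."""
    if shutil.which("Rscript") is None:
        return False
    try:
        proc = subprocess.run(
            ["Rscript", "--vanilla", "-e", "suppressMessages(library(edgeR))"],
            capture_output=True,
            timeout=120,
        )
    except (OSError, subprocess.TimeoutExpired):
        return False
    return proc.returncode == 0


def run_edger(
    normal: pd.DataFrame,
    disease: pd.DataFrame,
    fdr: float = 0.05,
    rounding: str = "nearest",
) -> pd.DataFrame:
    """Run edgeR on the two cohorts and return its DEGs (FDR < ``fdr``).

    Counts are re-rounded to integers by default since edgeR expects them.
    Output columns: gene, direction, p, q - the same schema the rank-based
    caller emits.
    """
    if not comparator_available():
        raise ComparatorUnavailableError(
            "comparator unavailable: Rscript with the edgeR package is required"
        )
    if list(normal.index) != list(disease.index):
        disease = disease.reindex(normal.index)
        if disease.isna().any().any():
            raise ValueError("normal and disease matrices must share the gene universe")
    combined = pd.concat([normal, disease], axis=1)
    combined.columns = [f"N{i}" for i in range(normal.shape[1])] + [
        f"D{i}" for i in range(disease.shape[1])
    ]
    if rounding == "nearest":
        combined = pd.DataFrame(
            np.rint(combined.to_numpy()).astype(np.int64),
            index=combined.index, columns=combined.columns,
        )
    elif rounding != "none":
        raise ValueError("rounding must be 'none' or 'nearest'")
    with tempfile.TemporaryDirectory(prefix="reodeg_edger_") as tmp:
        tmp = Path(tmp)
        counts_path = tmp / "counts.tsv"
        out_path = tmp / "edger.tsv"
        script_path = tmp / "run_edger.R"
        combined.to_csv(counts_path, sep="\t")
        script_path.write_text(_EDGER_SCRIPT)
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(script_path), str(counts_path),
             str(normal.shape[1]), str(out_path)],
            capture_output=True,
            text=True,
        )
        if proc.returncode != 0 or not out_path.exists():
            raise ComparatorUnavailableError(
                f"edgeR run failed (exit {proc.returncode}): {proc.stderr[-2000:]}"
            )
        table = pd.read_csv(out_path, sep="\t", dtype={"gene": str})
    hits = table[table["FDR"] < fdr].copy()
    hits["direction"] = np.where(hits["logFC"] > 0, "up", "down")
    hits = hits.rename(columns={"PValue": "p", "FDR": "q"})
    hits = hits.sort_values(["q", "p", "gene"], kind="mergesort").reset_index(drop=True)
    return hits[["gene", "direction", "p", "q"]]
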