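"""Relative qPCR expression by the 2^-ddCq method.

Per (tissue, specimen): technical-replicate Cq values are averaged per gene,
dCq = Cq_target - Cq_reference, ddCq = dCq - dCq of the calibrator tissue in
the same specimen, fold = 2^-ddCq.  Pairwise tissue comparisons use
two-tailed paired Student's t-tests on per-specimen ddCq (the log2 scale,
where replicate noise is closest to Gaussian), Bonferroni-adjusted over the
number of comparisons performed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import PairingError, StructureError

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("tissue", "specimen", "replicate", "gene", "cq")


def read_cq_table(source) -> pd.DataFrame:
    """Read a Cq TSV with columns tissue, specimen, replicate, gene, cq."""
    df = pd.read_csv(source, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise StructureError(f"Cq table missing columns: {missing}")
    return df


def validate_cq_table(
    df: pd.DataFrame, target_gene: str = "target", reference_gene: str = "reference"
) -> None:
    if (df["cq"] <= 0).any():
        raise StructureError("Cq values must be positive")
    genes = set(df["gene"])
    for gene in (target_gene, reference_gene):
        if gene not in genes:
            raise StructureError(f"gene {gene!r} absent from table")
    counts = df.groupby(["tissue", "specimen"])["gene"].nunique()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise PairingError(f"(tissue, specimen) missing a gene: {bad}")


@dataclass
class RelativeExpression:
    calibrator: str
    per_sample: pd.DataFrame  # tissue, specimen, dcq, ddcq, fold
    summary: pd.DataFrame  # tissue, mean_fold, sd_fold, fold_of_means
    tests: pd.DataFrame | None = None


def ddcq(
    table: pd.DataFrame,
    calibrator_tissue: str,
    target_gene: str = "target",
    reference_gene: str = "reference",
) -> RelativeExpression:
    """Per-specimen 2^-ddCq folds and per-tissue summaries.

    The summary reports both the mean of per-specimen folds (with SD) and
    the fold of mean ddCq (``fold_of_means``), since the two summaries of
    the same data differ on the linear scale.
    """
    validate_cq_table(table, target_gene, reference_gene)
    mean_cq = (
        table.groupby(["tissue", "specimen", "gene"])["cq"].mean().unstack("gene")
    )
    dcq = (mean_cq[target_gene] - mean_cq[reference_gene]).rename("dcq").reset_index()
    calib = dcq[dcq["tissue"] == calibrator_tissue].set_index("specimen")["dcq"]
    specimens = set(dcq["specimen"])
    missing = specimens - set(calib.index)
    if missing:
        raise PairingError(
            f"calibrator tissue {calibrator_tissue!r} missing for specimens {sorted(missing)}"
        )
    dcq["ddcq"] = dcq["dcq"] - dcq["specimen"].map(calib)
    dcq["fold"] = 2.0 ** (-dcq["ddcq"])
    summary = (
        dcq.groupby("tissue")
        .agg(
            mean_fold=("fold", "mean"),
            sd_fold=("fold", lambda x: x.std(ddof=1) if len(x) > 1 else 0.0),
            mean_ddcq=("ddcq", "mean"),
            n_specimens=("specimen", "nunique"),
        )
        .reset_index()
    )
    summary["fold_of_means"] = 2.0 ** (-summary["mean_ddcq"])
    return RelativeExpression(
        calibrator=calibrator_tissue, per_sample=dcq, summary=summary
    )


def pairwise_tests(
    rel: RelativeExpression,
    comparisons: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Two-tailed paired t-tests on per-specimen ddCq, Bonferroni-adjusted.

    ``comparisons`` defaults to all tissue pairs.  Bonferroni m equals the
    number of comparisons performed; degenerate pairs (all per-specimen
    differences exactly zero) are flagged and reported with p = 1.
    """
    wide = rel.per_sample.pivot(index="specimen", columns="tissue", values="ddcq")
    if comparisons is None:
        comparisons = list(itertools.combinations(sorted(wide.columns), 2))
    m = len(comparisons)
    rows = []
    for a, b in comparisons:
        if a not in wide.columns or b not in wide.columns:
            raise PairingError(f"tissue pair ({a}, {b}) absent from data")
        paired = wide[[a, b]].dropna()
        if len(paired) < 2:
            raise PairingError(f"fewer than 2 paired specimens for ({a}, {b})")
        diffs = paired[a] - paired[b]
        undefined = bool(np.allclose(diffs, 0.0))
        if undefined:
            log.info("pair (%s, %s): all differences zero; p set to 1", a, b)
            t_stat, p_raw = np.nan, 1.0
        else:
            t_stat, p_raw = stats.ttest_rel(paired[a], paired[b])
        rows.append(
            {
                "tissue_a": a,
                "tissue_b": b,
                "n": len(paired),
                "t": t_stat,
                "p_raw": p_raw,
                "p_adj": min(1.0, m * p_raw),
                "undefined": undefined,
            }
        )
    tests = pd.DataFrame(rows)
    rel.tests = tests
    return tests
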