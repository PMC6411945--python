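"""Summary statistics and qPCR fold-change computation.

Conventions follow common practice for cell-biology quantification:
values are reported as mean ± SEM (sample sd over sqrt(n)), two-sample
comparisons default to Welch's unequal-variance t-test (two-sided) with
a Mann-Whitney U alternative, and relative qPCR expression uses the
2^-ddCt method normalized to a reference gene and a control condition.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats as sps

CONDITIONS = ("control", "treated")


def summarize(values) -> tuple[float, float, int]:
    """Mean, SEM and n of a sample.

    SEM uses the n-1 sample standard deviation; for a single value the
    SEM is NaN (undefined, not zero).
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("empty sample")
    mean = float(vals.mean())
    if vals.size == 1:
        return mean, float("nan"), 1
    sem = float(vals.std(ddof=1) / math.sqrt(vals.size))
    return mean, sem, int(vals.size)


def ttest_two_tailed(a, b) -> tuple[float, float]:
    """Welch's two-sided t-test.

    Uses the Welch-Satterthwaite degrees of freedom.  If both samples
    have zero variance, equal means give (0, 1) by convention and
    unequal means (inf with the sign of the difference, 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    diff = a.mean() - b.mean()
    if va == 0 and vb == 0:
        if diff == 0:
            return 0.0, 1.0
        return math.copysign(math.inf, diff), 0.0
    se2 = va / a.size + vb / b.size
    t = diff / math.sqrt(se2)
    df = se2**2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return float(t), min(p, 1.0)


def mann_whitney_two_tailed(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (rank-sum) test, the non-parametric
    alternative to the t-test."""
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# qPCR


REQUIRED_CT_COLUMNS = {"gene", "condition", "replicate", "ct", "is_reference"}


def validate_ct_table(table: pd.DataFrame) -> tuple[str, list[str]]:
    """Check a Ct table and return (reference_gene, target_genes).

    The table needs columns ``gene, condition, replicate, ct,
    is_reference``; exactly one gene flagged as reference; conditions
    only 'control'/'treated'; and every gene present in both conditions.
    """
    missing = REQUIRED_CT_COLUMNS - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns {sorted(missing)}")
    bad = set(table["condition"].unique()) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown conditions {sorted(bad)}; use control/treated")
    ref_genes = sorted(table.loc[table["is_reference"].astype(bool), "gene"].unique())
    if len(ref_genes) != 1:
        raise ValueError(f"exactly one reference gene required, got {ref_genes}")
    ref = ref_genes[0]
    targets = sorted(g for g in table["gene"].unique() if g != ref)
    for gene in [ref, *targets]:
        conds = set(table.loc[table["gene"] == gene, "condition"].unique())
        if conds != set(CONDITIONS):
            raise ValueError(f"gene {gene!r} missing condition(s) {set(CONDITIONS) - conds}")
    return ref, targets


def ddct_fold_change(table: pd.DataFrame, per_replicate: bool = False) -> pd.DataFrame:
    """Relative expression fold changes by the 2^-ddCt method.

    For each target gene g: dCt(condition) = mean Ct_g - mean Ct_ref
    within the condition; ddCt = dCt(treated) - dCt(control); fold =
    2^-ddCt, i.e. expression in the treated condition relative to
    control after normalization to the reference gene.  The result is
    invariant to adding a constant to every Ct (a machine offset).

    With ``per_replicate=True``, replicates are paired by index within
    each condition: dCt_r = Ct_g,r - Ct_ref,r, each treated replicate
    yields fold_r = 2^-(dCt_r - mean control dCt), and the output adds
    per-gene SEM over replicate folds.
    """
    ref, targets = validate_ct_table(table)
    mean_ct = table.groupby(["gene", "condition"])["ct"].mean()
    rows = []
    for gene in targets:
        dct_control = mean_ct[(gene, "control")] - mean_ct[(ref, "control")]
        dct_treated = mean_ct[(gene, "treated")] - mean_ct[(ref, "treated")]
        ddct = dct_treated - dct_control
        row = {"gene": gene, "ddct": float(ddct), "fold_change": float(2.0**-ddct)}
        if per_replicate:
            folds = _replicate_folds(table, ref, gene)
            _, sem, n = summarize(folds)
            row.update(fold_sem=sem, n_replicates=n)
        rows.append(row)
    return pd.DataFrame(rows)


def _replicate_folds(table: pd.DataFrame, ref: str, gene: str) -> np.ndarray:
    def dct_by_rep(condition: str) -> pd.Series:
        sub = table[table["condition"] == condition]
        g = sub[sub["gene"] == gene].set_index("replicate")["ct"]
        r = sub[sub["gene"] == ref].set_index("replicate")["ct"]
        common = g.index.intersection(r.index)
        if len(common) == 0:
            raise ValueError(
                f"gene {gene!r}: no replicate indices shared with reference "
                f"in {condition}"
            )
        return (g.loc[common] - r.loc[common]).sort_index()

    dct_c = dct_by_rep("control")
    dct_t = dct_by_rep("treated")
    return np.asarray(2.0 ** -(dct_t.values - dct_c.values.mean()))
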