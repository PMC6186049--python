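"""Relative qPCR quantification by the 2^-ddCt method.

Each replicate Ct of the target gene is normalized against the mean
reference-gene Ct of its condition (dCt); the fold change between two
conditions is 2^-(mean dCt_treatment - mean dCt_baseline), with a
two-sample t-test on the replicate dCt values for significance
(Welch by default; pooled-variance optional).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def _condition_delta_ct(
    ct: pd.DataFrame, gene: str, reference: str, condition: str,
    paired: bool = False,
) -> np.ndarray:
    sub = ct[ct["condition"] == condition]
    ref = sub.loc[sub["gene"] == reference]
    if ref.empty:
        raise ValueError(
            f"reference gene {reference!r} missing in condition {condition!r}"
        )
    target = sub.loc[sub["gene"] == gene]
    if len(target) < 3:
        raise ValueError(
            f"gene {gene!r} has {len(target)} replicates in {condition!r}; need >= 3"
        )
    if paired:
        # normalize each replicate against the reference run on the same plate
        ref_by_rep = ref.set_index("replicate")["ct"]
        missing = set(target["replicate"]) - set(ref_by_rep.index)
        if missing:
            raise ValueError(
                f"paired mode: reference lacks replicates {sorted(missing)} "
                f"in condition {condition!r}"
            )
        return (
            target["ct"].to_numpy(float)
            - ref_by_rep.loc[target["replicate"]].to_numpy(float)
        )
    return target["ct"].to_numpy(float) - float(ref["ct"].mean())


def fold_change(
    ct: pd.DataFrame,
    gene: str,
    reference: str,
    baseline: str,
    treatment: str,
    welch: bool = True,
    paired: bool = False,
) -> tuple[float, float]:
    """Fold change (treatment vs baseline) and t-test p for one gene.

    ``ct`` has columns gene, condition, replicate, ct.  Returns
    (2^-ddCt, two-sided p on the replicate dCt sets).  ``paired`` switches
    from per-condition mean reference normalization to per-replicate
    (same-plate) pairing.
    """
    d_base = _condition_delta_ct(ct, gene, reference, baseline, paired)
    d_trt = _condition_delta_ct(ct, gene, reference, treatment, paired)
    ddct = d_trt.mean() - d_base.mean()
    fold = float(2.0 ** (-ddct))
    if np.allclose(d_trt, d_trt.mean()) and np.allclose(d_base, d_base.mean()):
        p = 1.0 if np.isclose(ddct, 0.0) else 0.0
    else:
        p = float(
            stats.ttest_ind(d_trt, d_base, equal_var=not welch).pvalue
        )
    return fold, p


def fold_change_table(
    ct: pd.DataFrame,
    reference: str,
    baseline: str,
    treatment: str,
    welch: bool = True,
) -> pd.DataFrame:
    """Fold change and p for every non-reference gene in the table."""
    genes = [g for g in ct["gene"].unique() if g != reference]
    rows = []
    for g in genes:
        fold, p = fold_change(ct, g, reference, baseline, treatment, welch)
        rows.append({"gene": g, "fold_change": fold, "p": p})
    return pd.DataFrame(rows)
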