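"""qPCR relative quantification by the 2^-ddCt method and concordance of
qPCR fold changes with RNA-seq fold changes.

ddCt = (Ct_target - Ct_reference) in the test condition minus the same
difference in the control condition; relative expression is 2^-ddCt with
the amplification efficiency fixed at 2 (the model's assumption). Replicate
Ct values are averaged on the Ct scale before differencing.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class QpcrError(ValueError):
    """Raised for non-finite Ct values or insufficient shared genes."""


def _ct_mean(value) -> float:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 0 or not np.isfinite(arr).all():
        raise QpcrError("Ct values must be finite and non-empty")
    return float(arr.mean())


def ddct_ratio(ct_target_test, ct_ref_test, ct_target_ctrl, ct_ref_ctrl) -> float:
    """Relative expression 2^-ddCt of test over control.

    Each argument is a scalar Ct or a sequence of replicate Cts (averaged on
    the Ct scale first). ddCt = (Ct_tgt,test - Ct_ref,test) -
    (Ct_tgt,ctrl - Ct_ref,ctrl).
    """
    d_test = _ct_mean(ct_target_test) - _ct_mean(ct_ref_test)
    d_ctrl = _ct_mean(ct_target_ctrl) - _ct_mean(ct_ref_ctrl)
    return 2.0 ** -(d_test - d_ctrl)


def relative_expression(
    ct_table: pd.DataFrame, test_sample: str, control_sample: str
) -> pd.DataFrame:
    """2^-ddCt per target gene from a long-format Ct table.

    ``ct_table`` columns: sample_id, gene_id, ct, is_reference. Each of the
    two conditions must carry at least one reference-gene record. Returns a
    DataFrame indexed by gene id with ``ratio`` and ``log2_ratio``.
    """
    required = {"sample_id", "gene_id", "ct", "is_reference"}
    missing = required - set(ct_table.columns)
    if missing:
        raise QpcrError(f"Ct table missing columns: {sorted(missing)}")
    rows = {}
    for sample in (test_sample, control_sample):
        sub = ct_table[ct_table["sample_id"] == sample]
        if sub.empty:
            raise QpcrError(f"no Ct records for sample {sample!r}")
        if not sub["is_reference"].any():
            raise QpcrError(f"sample {sample!r} has no reference-gene record")
    test = ct_table[ct_table["sample_id"] == test_sample]
    ctrl = ct_table[ct_table["sample_id"] == control_sample]
    ref_test = test.loc[test["is_reference"], "ct"]
    ref_ctrl = ctrl.loc[ctrl["is_reference"], "ct"]
    targets = sorted(set(test.loc[~test["is_reference"], "gene_id"]) & set(ctrl.loc[~ctrl["is_reference"], "gene_id"]))
    for gene in targets:
        ratio = ddct_ratio(
            test.loc[(test["gene_id"] == gene) & ~test["is_reference"], "ct"],
            ref_test,
            ctrl.loc[(ctrl["gene_id"] == gene) & ~ctrl["is_reference"], "ct"],
            ref_ctrl,
        )
        rows[gene] = {"ratio": ratio, "log2_ratio": math.log2(ratio)}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene_id"
    return out


def concordance(
    qpcr_log2: Mapping[str, float], rnaseq_log2fc: Mapping[str, float], zero_tol: float = 1e-9
) -> tuple[float, float]:
    """(sign agreement, Spearman rank correlation) over shared genes.

    Sign agreement is the fraction of shared genes whose fold-change signs
    match; values within ``zero_tol`` of zero agree with anything. Requires
    at least 3 shared genes.
    """
    shared = sorted(set(qpcr_log2) & set(rnaseq_log2fc))
    if len(shared) < 3:
        raise QpcrError(f"need >= 3 shared genes, found {len(shared)}")
    x = np.array([qpcr_log2[g] for g in shared], dtype=float)
    y = np.array([rnaseq_log2fc[g] for g in shared], dtype=float)
    near_zero = (np.abs(x) <= zero_tol) | (np.abs(y) <= zero_tol)
    agree = near_zero | (np.sign(x) == np.sign(y))
    rho = stats.spearmanr(x, y).statistic
    return float(agree.mean()), float(rho)
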