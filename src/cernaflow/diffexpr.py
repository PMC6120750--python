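"""Two-group differential expression for array intensities and miRNA counts.

The statistical contract mirrors the standard microarray workflow: quantile
normalization across samples, a two-sided equal-variance Student's t test on
log2 values, fold change from linear-scale group means, Benjamini-Hochberg
FDR across all transcripts of a class, and a strict "fold change > 2 and
p < 0.05" filter. FDR is reported alongside the raw p so either filtering
rule can be reproduced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError
from .model import ExpressionMatrix


@dataclass(frozen=True)
class DEConfig:
    """Thresholds and transform options for the differential-expression call.

    fc_threshold is on the linear fold-change scale (strict '>'),
    p_threshold on the raw two-sided p (strict '<'). With ``count_data``
    the log transform becomes log2(value + pseudo_count).
    """

    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    test: str = "student_t"
    log_transform: bool = True
    count_data: bool = False
    pseudo_count: float = 1.0

    def __post_init__(self) -> None:
        if self.fc_threshold <= 1:
            raise ConfigurationError("fc_threshold must be > 1")
        if not 0 < self.p_threshold < 1:
            raise ConfigurationError("p_threshold must be in (0, 1)")
        if self.test != "student_t":
            raise ConfigurationError(f"unsupported test {self.test!r}")


@dataclass(frozen=True)
class DERecord:
    transcript_id: str
    mean_case: float
    mean_control: float
    fold_change: float
    log2fc: float
    p_value: float
    fdr: float
    direction: str  # up | down | unchanged
    passes_filter: bool
    degenerate: bool = False


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def quantile_normalize(matrix):
    """Quantile-normalize columns so every sample shares one distribution.

    Each rank is replaced by the across-sample mean of that rank's order
    statistics; tied values within a column receive the mean of the tied
    ranks' target values. Accepts and returns either an ExpressionMatrix or
    a plain DataFrame.
    """
    is_em = isinstance(matrix, ExpressionMatrix)
    df = matrix.values if is_em else matrix
    arr = df.to_numpy(dtype=float)
    n, m = arr.shape
    if m < 2:
        raise ConfigurationError("quantile normalization needs >= 2 samples")
    target = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(m):
        col = arr[:, j]
        order = np.argsort(col, kind="stable")
        sorted_vals = col[order]
        assigned = np.empty(n)
        i = 0
        while i < n:
            k = i
            while k + 1 < n and sorted_vals[k + 1] == sorted_vals[i]:
                k += 1
            assigned[i:k + 1] = target[i:k + 1].mean()  # tie rule
            i = k + 1
        out[order, j] = assigned
    result = pd.DataFrame(out, index=df.index, columns=df.columns)
    if is_em:
        return ExpressionMatrix(values=result, group_of=dict(matrix.group_of),
                                transcript_class=dict(matrix.transcript_class))
    return result


def differential_expression(matrix: ExpressionMatrix,
                            config: DEConfig = DEConfig()) -> list[DERecord]:
    """Per-transcript two-group Student's t with FC/p filter and BH FDR."""
    case = matrix.samples_in_group("case")
    control = matrix.samples_in_group("control")
    if len(case) < 2 or len(control) < 2:
        raise ConfigurationError(
            f"both groups need >= 2 samples (case={len(case)}, control={len(control)})"
        )
    lin = matrix.values
    if config.log_transform:
        pseudo = config.pseudo_count if config.count_data else 0.0
        with np.errstate(divide="ignore"):
            work = np.log2(lin.to_numpy(dtype=float) + pseudo)
    else:
        work = lin.to_numpy(dtype=float)

    cols = list(lin.columns)
    ci = [cols.index(s) for s in case]
    ki = [cols.index(s) for s in control]
    a, b = work[:, ci], work[:, ki]

    mean_case = lin.iloc[:, ci].mean(axis=1).to_numpy()
    mean_control = lin.iloc[:, ki].mean(axis=1).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mean_control > 0, mean_case / np.where(mean_control > 0,
                                                             mean_control, 1.0),
                      np.inf)
        fc = np.where((mean_control == 0) & (mean_case == 0), 1.0, fc)
        log2fc = np.log2(fc)

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-identical rows (tiny within-group variance) are legitimate
        # here; degenerate cases are handled by the conventions below
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    zero_var = (var_a == 0) & (var_b == 0)
    equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
    degenerate = zero_var & ~equal_means
    p = np.where(zero_var & equal_means, 1.0, p)
    p = np.where(degenerate, np.finfo(float).tiny, p)
    p = np.clip(np.nan_to_num(p, nan=1.0), np.finfo(float).tiny, 1.0)

    fdr = bh_fdr(p)
    records = []
    for i, tid in enumerate(lin.index):
        fc_i, p_i = float(fc[i]), float(p[i])
        direction = "up" if fc_i > 1 else ("down" if fc_i < 1 else "unchanged")
        effect = max(fc_i, 1.0 / fc_i) if fc_i > 0 else np.inf
        passes = (p_i < config.p_threshold) and (effect > config.fc_threshold)
        records.append(DERecord(
            transcript_id=str(tid),
            mean_case=float(mean_case[i]),
            mean_control=float(mean_control[i]),
            fold_change=fc_i,
            log2fc=float(log2fc[i]),
            p_value=p_i,
            fdr=float(fdr[i]),
            direction=direction,
            passes_filter=bool(passes),
            degenerate=bool(degenerate[i]),
        ))
    return records


def de_records_to_frame(records) -> pd.DataFrame:
    cols = ["transcript_id", "mean_case", "mean_control", "fold_change",
            "log2fc", "p_value", "fdr", "direction", "passes_filter"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records],
                        columns=cols)


def hierarchical_order(values: pd.DataFrame, transcripts=None):
    """Average-linkage leaf ordering of transcripts under 1 - PCC distance.

    Rows are sorted lexicographically by id before clustering so ties break
    deterministically. Constant rows have undefined PCC; their distance to
    every other row is defined as 1 (with a warning). Returns
    ``(leaf_ids, linkage_matrix)``.
    """
    if transcripts is not None:
        values = values.loc[[t for t in transcripts if t in values.index]]
    values = values.sort_index(kind="stable")
    n = len(values)
    if n < 2:
        raise ConfigurationError("hierarchical ordering needs >= 2 transcripts")
    arr = values.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant row(s): PCC undefined, distance set to 1",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(arr)
    dist = 1.0 - corr
    dist[constant, :] = 1.0
    dist[:, constant] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, 2.0)
    condensed = dist[np.triu_indices(n, k=1)]
    z = linkage(condensed, method="average")
    order = leaves_list(z)
    return [str(values.index[i]) for i in order], z


def relative_expression_ddct(ct_target_case: float, ct_ref_case: float,
                             ct_target_control: float,
                             ct_ref_control: float) -> float:
    """qPCR relative expression 2^-ddCt (reference-gene normalized)."""
    ddct = (ct_target_case - ct_ref_case) - (ct_target_control - ct_ref_control)
    return float(2.0 ** (-ddct))
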