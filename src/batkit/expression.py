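"""Expression quantification: DE screen on counts and 2^-ddCt qPCR.

The differential-expression screen contrasts in vitro poor/non-responders
against better responders with a per-gene Welch two-sample t-test on
log2-CPM — a deliberately simple stand-in for a mean-variance-modeled linear
fit: it exercises the thresholds (|log2FC| > 2, p < 0.05), the
Benjamini-Hochberg adjustment and the group contrast, not the moderated
variance machinery, so gene counts at the thresholds will differ from a
moderated analysis of the same data.

The qPCR layer implements 2^-ddCt with a triple housekeeping reference
(B2M, GAPDH, RNA18SN5): the internal control is the geometric mean of the
reference quantities in linear space, i.e. the arithmetic mean of their Ct
values. Ct values above the censoring limit (default 40) are negative wells
and propagate as missing, never as zero expression.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_REFERENCE_GENES = ("B2M", "GAPDH", "RNA18SN5")
LOG2FC_THRESHOLD = 2.0
ALPHA = 0.05


class ExpressionError(ValueError):
    pass


def log_cpm(matrix: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million: log2((count + pc) / (libsize + 1) * 1e6).

    ``matrix`` is genes x samples; the library size is the per-sample column
    sum. The pseudocount keeps zero counts finite.
    """
    counts = matrix.to_numpy(dtype=float)
    if (counts < 0).any():
        raise ExpressionError("count matrix has negative entries")
    lib = counts.sum(axis=0)
    cpm = (counts + pseudocount) / (lib + 1.0)[None, :] * 1e6
    return pd.DataFrame(np.log2(cpm), index=matrix.index, columns=matrix.columns)


def benjamini_hochberg(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    p_adj(i) = min_{j: rank(j) >= rank(i)} p(j) * m / rank(j), capped at 1;
    NaN inputs propagate as NaN and do not count toward m.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def de_screen(
    matrix: pd.DataFrame,
    groups: Mapping[str, str],
    log2fc_threshold: float = LOG2FC_THRESHOLD,
    alpha: float = ALPHA,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Differential-expression screen, poor/non-responders vs better.

    Parameters
    ----------
    matrix
        Genes x samples count matrix.
    groups
        Sample id -> ``"better"`` or ``"poor_non"``; other samples ignored.

    Returns a per-gene table with log2FC (mean poor_non - mean better on
    log2-CPM), Welch p, BH-adjusted p, and the significance call
    (|log2FC| > threshold AND raw p < alpha), sorted by p.
    """
    better = [s for s, g in groups.items() if g == "better" and s in matrix.columns]
    poor = [s for s, g in groups.items() if g == "poor_non" and s in matrix.columns]
    if len(better) < 2 or len(poor) < 2:
        raise ExpressionError(
            f"need >= 2 samples per group, got {len(better)} better / "
            f"{len(poor)} poor_non"
        )
    lc = log_cpm(matrix[better + poor], pseudocount=pseudocount)
    x = lc[poor].to_numpy()
    y = lc[better].to_numpy()
    log2fc = x.mean(axis=1) - y.mean(axis=1)
    # Welch handles unequal group variances; constant genes yield NaN p.
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(x, y, axis=1, equal_var=False)
    p = np.where(log2fc == 0.0, np.where(np.isnan(p), 1.0, p), p)
    p_adj = benjamini_hochberg(p)
    res = pd.DataFrame({
        "gene": matrix.index,
        "log2fc": log2fc,
        "p": p,
        "p_adj": p_adj,
    })
    res["significant"] = (np.abs(res["log2fc"]) > log2fc_threshold) & (res["p"] < alpha)
    return res.sort_values("p", kind="mergesort").reset_index(drop=True)


def ddct_expression(
    ct: pd.DataFrame,
    target_genes: Sequence[str] | None = None,
    reference_genes: Sequence[str] = DEFAULT_REFERENCE_GENES,
    calibrator: str | None = None,
) -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method.

    Parameters
    ----------
    ct
        Long-format table with columns sample_id, gene, ct, censored.
    calibrator
        Sample id whose dCt anchors ddCt. When None, the per-gene mean dCt
        across all samples is the calibrator, so expression values are
        relative to the cohort average.

    Per sample, the reference Ct is the arithmetic mean of the reference-gene
    Cts (geometric-mean normalization in linear space); samples with any
    censored or missing reference gene are excluded with a warning. Censored
    target wells yield NaN expression.
    """
    required = {"sample_id", "gene", "ct", "censored"}
    if not required.issubset(ct.columns):
        raise ExpressionError(f"Ct table needs columns {sorted(required)}")
    work = ct.copy()
    work.loc[work["censored"].astype(bool), "ct"] = np.nan
    wide = work.pivot_table(index="sample_id", columns="gene", values="ct",
                            aggfunc="mean", dropna=False)

    missing_refs = [g for g in reference_genes if g not in wide.columns]
    if missing_refs:
        raise ExpressionError(f"reference genes absent from Ct table: {missing_refs}")
    ref_ok = wide[list(reference_genes)].notna().all(axis=1)
    dropped = list(wide.index[~ref_ok])
    if dropped:
        logger.warning("samples dropped (censored/missing reference gene): %s",
                       dropped)
    wide = wide[ref_ok]
    if wide.empty:
        raise ExpressionError("no sample has a complete reference-gene set")

    if target_genes is None:
        target_genes = [g for g in wide.columns if g not in reference_genes]
    ref_ct = wide[list(reference_genes)].mean(axis=1)
    dct = wide[list(target_genes)].sub(ref_ct, axis=0)

    if calibrator is not None:
        if calibrator not in dct.index:
            raise ExpressionError(f"calibrator sample {calibrator!r} not available")
        cal = dct.loc[calibrator]
        if cal.isna().any():
            raise ExpressionError(
                f"calibrator sample {calibrator!r} has censored target Cts"
            )
    else:
        cal = dct.mean(axis=0, skipna=True)
    ddct = dct.sub(cal, axis=1)
    return 2.0 ** (-ddct)
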