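"""Differential protein expression between control and heat groups.

Group means of the biological-replicate values give the fold change
(reported both as log2 and in the signed linear convention: ratios >= 1
positive, ratios < 1 as the negative reciprocal, so 1.342-fold down is
-1.342). The linear fold-change cutoff is derived from a maximum-
likelihood normal fit to the log2 ratios of all quantified proteins:
cutoff = 2^sigma rounded down to one decimal, which pairs a log2 s.d. of
0.4 with the 1.3 cutoff of the reference analysis. Significance comes
from a two-sided Student's t-test on log2 biological values (pooled
variance by default, Welch selectable); classification uses strict
inequalities (p < alpha and |signed FC| > cutoff) with no multiple-
testing correction by default, matching the reference thresholds; a
Benjamini-Hochberg option is available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simdata import StudyDesign

logger = logging.getLogger("swathlite")


def signed_fold_change(ratio) -> np.ndarray:
    """Linear ratio in the signed convention: r if r >= 1 else -1/r."""
    r = np.asarray(ratio, dtype=float)
    return np.where(r >= 1.0, r, -1.0 / r)


def group_fold_change(bio_values: pd.DataFrame, design: StudyDesign) -> pd.DataFrame:
    """Per-protein group means and fold changes (second group vs first).

    Returns columns control_mean, heat_mean (named after the design's
    groups), log2_fc and signed_fc; proteins with a non-positive or
    missing group mean get missing fold changes.
    """
    ctrl_g, heat_g = design.groups
    ctrl_cols = [c for c in bio_values.columns if c.startswith(f"{ctrl_g}_b")]
    heat_cols = [c for c in bio_values.columns if c.startswith(f"{heat_g}_b")]
    ctrl = bio_values[ctrl_cols].mean(axis=1, skipna=True)
    heat = bio_values[heat_cols].mean(axis=1, skipna=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where((ctrl > 0) & (heat > 0), heat / ctrl, np.nan)
    out = pd.DataFrame({
        f"{ctrl_g}_mean": ctrl,
        f"{heat_g}_mean": heat,
        "log2_fc": np.log2(ratio),
        "signed_fc": signed_fold_change(ratio),
    }, index=bio_values.index)
    out.loc[~np.isfinite(ratio), ["log2_fc", "signed_fc"]] = np.nan
    return out


@dataclass(frozen=True)
class CutoffFit:
    """Normal fit to the log2 ratio distribution and the derived cutoff."""

    mu: float
    sigma: float
    linear_cutoff: float
    n: int
    overridden: bool = False


def linear_cutoff_from_sigma(sigma: float) -> float:
    """2^sigma rounded down to one decimal (log2 s.d. 0.4 -> 1.3)."""
    return math.floor(2.0 ** sigma * 10.0) / 10.0


def derive_cutoff(log2_ratios, override: float | None = None,
                  min_n: int = 30) -> CutoffFit:
    """Fit Normal(mu, sigma) to the log2 ratios by maximum likelihood and
    derive the linear fold-change cutoff as 2^sigma rounded down to one
    decimal. ``override`` pins the cutoff (e.g. at 1.3) while still
    reporting the fit."""
    x = np.asarray(log2_ratios, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} finite log2 ratios, got {len(x)}")
    mu, sigma = stats.norm.fit(x)  # MLE: mean and population (ddof=0) s.d.
    if sigma == 0:
        raise ValueError("degenerate (zero-variance) log2 ratio distribution")
    if override is not None:
        return CutoffFit(float(mu), float(sigma), float(override), len(x), True)
    return CutoffFit(float(mu), float(sigma), linear_cutoff_from_sigma(sigma), len(x))


def t_test(control, heat, log2: bool = True, equal_var: bool = True) -> float:
    """Two-sided two-sample t-test p-value (pooled variance by default).

    Values are log2-transformed first unless ``log2=False``. Degenerate
    zero-variance input yields p = 1 for equal means and p = 0 (with a
    warning) for unequal means.
    """
    a = np.asarray(control, float)
    b = np.asarray(heat, float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        return np.nan
    if log2:
        a, b = np.log2(a), np.log2(b)
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 1.0
        logger.warning("zero variance with unequal means: p-value set to 0")
        return 0.0
    return float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)


def t_test_matrix(bio_values: pd.DataFrame, design: StudyDesign,
                  log2: bool = True, equal_var: bool = True) -> pd.Series:
    """Vectorized row-wise t-test over a protein x biological-sample matrix."""
    ctrl_g, heat_g = design.groups
    a = bio_values[[c for c in bio_values.columns if c.startswith(f"{ctrl_g}_b")]].to_numpy(float)
    b = bio_values[[c for c in bio_values.columns if c.startswith(f"{heat_g}_b")]].to_numpy(float)
    if log2:
        with np.errstate(divide="ignore", invalid="ignore"):
            a, b = np.log2(a), np.log2(b)
    import warnings
    with warnings.catch_warnings():
        # constant rows (zero spread) are handled explicitly below
        warnings.filterwarnings("ignore", message="Precision loss occurred")
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var, nan_policy="omit")
    p = np.asarray(res.pvalue, float)
    # degenerate rows: zero variance in both groups
    both_const = (np.nanvar(a, axis=1) == 0) & (np.nanvar(b, axis=1) == 0)
    if both_const.any():
        eq = np.nanmean(a, axis=1) == np.nanmean(b, axis=1)
        p[both_const & eq] = 1.0
        p[both_const & ~eq] = 0.0
    return pd.Series(p, index=bio_values.index, name="p_value")


@dataclass
class DiffResult:
    """Per-protein differential expression table plus the analysis-level
    fitted null and thresholds.

    ``table`` columns: the two group means, log2_fc, signed_fc, p_value
    and class in {up, down, ns}.
    """

    table: pd.DataFrame
    cutoff: CutoffFit
    alpha: float

    @property
    def counts(self) -> dict[str, int]:
        c = self.table["class"].value_counts()
        up, down = int(c.get("up", 0)), int(c.get("down", 0))
        return {"total": up + down, "up": up, "down": down}


def classify(fc: pd.DataFrame, pvalues: pd.Series, alpha: float = 0.01,
             cutoff: float = 1.3, adjust: str | None = None) -> pd.DataFrame:
    """Assign up/down/ns classes with strict thresholds.

    A protein is up-regulated iff p < ``alpha`` and signed FC > +``cutoff``,
    down-regulated iff p < ``alpha`` and signed FC < -``cutoff``; everything
    else (including a signed FC of exactly +/-cutoff) is ns.
    ``adjust='bh'`` applies Benjamini-Hochberg to the p-values first
    (off by default).
    """
    p = pvalues.reindex(fc.index)
    if adjust == "bh":
        mask = p.notna()
        adj = p.copy()
        adj[mask] = stats.false_discovery_control(p[mask], method="bh")
        p = adj
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    sfc = fc["signed_fc"]
    cls = np.full(len(fc), "ns", dtype=object)
    sig = (p < alpha).to_numpy()
    cls[sig & (sfc > cutoff).to_numpy()] = "up"
    cls[sig & (sfc < -cutoff).to_numpy()] = "down"
    out = fc.copy()
    out["p_value"] = p
    out["class"] = cls
    return out


def differential_expression(
    bio_values: pd.DataFrame,
    design: StudyDesign,
    alpha: float = 0.01,
    cutoff: float | str = "auto",
    log2_test: bool = True,
    equal_var: bool = True,
    adjust: str | None = None,
) -> DiffResult:
    """Full differential analysis of a protein x biological-sample matrix.

    ``cutoff='auto'`` derives the fold-change threshold from the normal
    fit to the log2 ratios; a number pins it (the reference value is 1.3).
    """
    fc = group_fold_change(bio_values, design)
    fit = derive_cutoff(fc["log2_fc"],
                        override=None if cutoff == "auto" else float(cutoff))
    p = t_test_matrix(bio_values, design, log2=log2_test, equal_var=equal_var)
    table = classify(fc, p, alpha=alpha, cutoff=fit.linear_cutoff, adjust=adjust)
    return DiffResult(table=table, cutoff=fit, alpha=alpha)


def export_views(result: DiffResult, bio_values: pd.DataFrame
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Volcano table (log2 FC, -log10 p, class) and heat-map matrix.

    The heat map is restricted to differential proteins and shows the
    log10 biological-sample intensities across the six samples.
    """
    t = result.table
    with np.errstate(divide="ignore"):
        volcano = pd.DataFrame({
            "log2_fc": t["log2_fc"],
            "neg_log10_p": -np.log10(t["p_value"]),
            "class": t["class"],
        }, index=t.index)
    diff_idx = t.index[t["class"] != "ns"]
    with np.errstate(divide="ignore", invalid="ignore"):
        heatmap = np.log10(bio_values.loc[diff_idx])
    return volcano, heatmap


def write_diff_table(result: DiffResult, path) -> None:
    result.table.to_csv(path, sep="\t", index_label="protein")
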