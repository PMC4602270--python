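"""Replicate-reproducibility filter cascade.

Reproduces the quality gates of the reference workflow: a technical
coefficient-of-variation filter (CV <= 25% across the three injections of
each biological sample), a completeness filter (quantified in every
biological replicate of both groups), a biological CV filter per group,
and pairwise R-squared reporting between biological replicates.

The final quantified set is the union of the two groups' biological-CV
pass sets intersected with the completeness set — a final count that
exceeds both per-group pass counts, as this workflow's summary tables
report, is only possible under a union.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diaquant import QuantTable
from .simdata import StudyDesign

logger = logging.getLogger("swathlite")


def compute_cv(values) -> float:
    """Coefficient of variation: sample (n-1) standard deviation over mean.

    Missing (NaN) when fewer than two finite values remain or the mean is
    not positive.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 2:
        return np.nan
    m = v.mean()
    if m <= 0:
        return np.nan
    return float(v.std(ddof=1) / m)


def _cv_frame(data: pd.DataFrame, groups_of_cols: dict[str, list[str]]) -> pd.DataFrame:
    """Per-protein CV over each named column group (vectorized)."""
    out = {}
    for name, cols in groups_of_cols.items():
        sub = data[cols].to_numpy(float)
        finite = np.isfinite(sub)
        n = finite.sum(axis=1)
        mean = np.where(n > 0,
                        np.where(finite, sub, 0.0).sum(axis=1) / np.maximum(n, 1),
                        np.nan)
        sd = np.full(len(sub), np.nan)
        ok = n >= 2
        if ok.any():
            with np.errstate(invalid="ignore"):
                sd[ok] = np.nanstd(sub[ok], axis=1, ddof=1)
        cv = np.where(ok & (mean > 0), sd / mean, np.nan)
        out[name] = cv
    return pd.DataFrame(out, index=data.index)


@dataclass
class TechnicalStage:
    """Technical-replicate CV filter output.

    ``bio_values``: protein x biological-sample matrix (mean of that
    sample's technical injections). ``cv``: the matching technical CVs.
    ``passed``: boolean CV <= max_cv. ``percent_passed``: per-sample pass
    percentage among proteins with a computable CV.
    """

    bio_values: pd.DataFrame
    cv: pd.DataFrame
    passed: pd.DataFrame
    percent_passed: pd.Series


def technical_stage(quant: QuantTable, design: StudyDesign,
                    max_cv: float = 0.25) -> TechnicalStage:
    """Per biological sample: technical CV over its injections, the
    biological-sample value as their mean, and the CV <= ``max_cv`` pass
    flags with per-sample pass percentages."""
    if quant.level != "protein":
        raise ValueError("technical_stage expects a protein-level table")
    data = quant.data
    sample_cols: dict[str, list[str]] = {}
    for g in design.groups:
        for b in range(1, design.bio_replicates + 1):
            cols = [c for c in quant.runs_of(g, b) if c in data.columns]
            sid = f"{g}_b{b}"
            if len(cols) < 2:
                logger.warning("biological sample %s has %d technical run(s); "
                               "technical CV stage skipped for it", sid, len(cols))
                if cols:
                    sample_cols[sid] = cols
                continue
            sample_cols[sid] = cols

    bio_values = pd.DataFrame(
        {sid: data[cols].mean(axis=1, skipna=True) for sid, cols in sample_cols.items()}
    )
    cv = _cv_frame(data, {s: c for s, c in sample_cols.items() if len(c) >= 2})
    passed = cv <= max_cv
    denom = cv.notna().sum(axis=0)
    percent = 100.0 * passed.sum(axis=0) / denom.replace(0, np.nan)
    return TechnicalStage(bio_values=bio_values, cv=cv, passed=passed,
                          percent_passed=percent)


def completeness_stage(bio_values: pd.DataFrame, design: StudyDesign,
                       mode: str = "all_bio",
                       run_data: pd.DataFrame | None = None) -> pd.Index:
    """Proteins quantified in every biological replicate of both groups.

    ``mode='all_bio'`` (default) requires a non-missing biological value in
    all biological samples; ``mode='all_runs'`` additionally requires every
    individual injection to be non-missing (pass ``run_data``), the
    stricter of the two common readings of replicate completeness.
    """
    if mode == "all_bio":
        keep = bio_values.notna().all(axis=1)
        return bio_values.index[keep]
    if mode == "all_runs":
        if run_data is None:
            raise ValueError("mode='all_runs' requires the protein x run matrix")
        keep = run_data.notna().all(axis=1)
        return run_data.index[keep]
    raise ValueError(f"unknown completeness mode {mode!r}")


@dataclass
class BiologicalStage:
    """Biological-replicate CV filter output per group plus the final set."""

    cv: pd.DataFrame                 # protein x group
    passed: pd.DataFrame             # protein x group (CV <= max_cv)
    percent_passed: pd.Series        # per group, among the completeness set
    final_proteins: pd.Index         # union of group pass sets


def biological_stage(bio_values: pd.DataFrame, design: StudyDesign,
                     complete: pd.Index, max_cv: float = 0.25) -> BiologicalStage:
    """Per group, CV across the biological replicates of the completeness
    set; the final quantified set is the union of the group pass sets."""
    sub = bio_values.loc[complete]
    groups_of_cols = {
        g: [f"{g}_b{b}" for b in range(1, design.bio_replicates + 1)
            if f"{g}_b{b}" in sub.columns]
        for g in design.groups
    }
    cv = _cv_frame(sub, groups_of_cols)
    passed = cv <= max_cv
    percent = 100.0 * passed.sum(axis=0) / max(len(sub), 1)
    final = sub.index[passed.any(axis=1)]
    return BiologicalStage(cv=cv, passed=passed, percent_passed=percent,
                           final_proteins=final)


def replicate_r2(bio_values: pd.DataFrame, design: StudyDesign,
                 log10: bool = True, min_shared: int = 3
                 ) -> tuple[pd.DataFrame, pd.Series]:
    """Pairwise squared Pearson correlation between biological replicates.

    Computed over proteins present in both members of each pair, on log10
    intensities by default (matching the display convention of the
    reference analysis). Returns the full symmetric matrix and the
    per-group minimum off-diagonal value.
    """
    cols = list(bio_values.columns)
    mat = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for a, b in itertools.combinations(cols, 2):
        pair = bio_values[[a, b]].dropna()
        pair = pair[(pair > 0).all(axis=1)] if log10 else pair
        if len(pair) < min_shared:
            logger.warning("replicates %s/%s share only %d protein(s); R2 missing",
                           a, b, len(pair))
            r2 = np.nan
        else:
            x = np.log10(pair[a]) if log10 else pair[a]
            y = np.log10(pair[b]) if log10 else pair[b]
            r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
        mat.loc[a, b] = mat.loc[b, a] = r2
    group_min = {}
    for g in design.groups:
        gcols = [c for c in cols if c.startswith(f"{g}_b")]
        vals = [mat.loc[a, b] for a, b in itertools.combinations(gcols, 2)]
        finite = [v for v in vals if np.isfinite(v)]
        group_min[g] = float(min(finite)) if finite else np.nan
    return mat, pd.Series(group_min, name="min_r2")


@dataclass
class QcResult:
    """Full output of the reproducibility cascade.

    Pass sets are nested: ``final_proteins`` is a subset of
    ``complete_proteins`` which is a subset of ``quantified_proteins``.
    """

    technical: TechnicalStage
    complete_proteins: pd.Index
    biological: BiologicalStage
    r2_matrix: pd.DataFrame
    min_r2: pd.Series
    quantified_proteins: pd.Index
    max_cv: float = 0.25

    @property
    def final_proteins(self) -> pd.Index:
        return self.biological.final_proteins

    def summary(self) -> pd.DataFrame:
        """Stage-count summary: per-stage protein counts and pass
        percentages, one row per gate."""
        rows = [
            ("proteins quantified (any run)", len(self.quantified_proteins), ""),
            ("quantified in all biological samples", len(self.complete_proteins), ""),
        ]
        for sid, pct in self.technical.percent_passed.items():
            n = int(self.technical.passed[sid].sum())
            rows.append((f"technical CV <= {self.max_cv:.0%} [{sid}]", n, f"{pct:.1f}%"))
        for g, pct in self.biological.percent_passed.items():
            n = int(self.biological.passed[g].sum())
            rows.append((f"biological CV <= {self.max_cv:.0%} [{g}]", n, f"{pct:.1f}%"))
        rows.append(("final quantified set", len(self.final_proteins), ""))
        return pd.DataFrame(rows, columns=["stage", "n_proteins", "percent"])


def run_qc(quant: QuantTable, design: StudyDesign, max_cv: float = 0.25,
           completeness_mode: str = "all_bio", r2_log10: bool = True) -> QcResult:
    """Run the full cascade on a protein-level quant table."""
    quantified = quant.data.index[quant.data.notna().any(axis=1)]
    tech = technical_stage(quant, design, max_cv=max_cv)
    complete = completeness_stage(tech.bio_values, design, mode=completeness_mode,
                                  run_data=quant.data)
    complete = complete.intersection(quantified)
    bio = biological_stage(tech.bio_values, design, complete, max_cv=max_cv)
    r2, min_r2 = replicate_r2(tech.bio_values.loc[complete], design, log10=r2_log10)
    return QcResult(technical=tech, complete_proteins=complete, biological=bio,
                    r2_matrix=r2, min_r2=min_r2, quantified_proteins=quantified,
                    max_cv=max_cv)


def write_qc_report(qc: QcResult, path) -> None:
    """Per-protein stage flags and CVs as TSV."""
    tech_cv = qc.technical.cv.add_prefix("tech_cv_")
    bio_cv = qc.biological.cv.add_prefix("bio_cv_").reindex(tech_cv.index)
    flags = pd.DataFrame({
        "complete": tech_cv.index.isin(qc.complete_proteins),
        "final": tech_cv.index.isin(qc.final_proteins),
    }, index=tech_cv.index)
    pd.concat([tech_cv, bio_cv, flags], axis=1).to_csv(path, sep="\t",
                                                       index_label="protein")
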