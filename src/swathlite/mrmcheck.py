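"""Scheduled-MRM assay design, quantification and SWATH concordance.

Assays are derived from the reference spectral library: the five most
intense library fragments per peptide become the Q1/Q3 ion pairs, with
declustering potential and collision energy computed from linear
QTRAP-style equations in precursor m/z (coefficients configurable per
charge), and the acquisition scheduled in a window around the library
retention time. MRM traces are integrated with the same peak integrator
as the DIA path and rolled up by summation, and per-protein fold changes
from the two platforms are compared by direction agreement and Spearman
rank correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diaquant import QuantTable, _integrate
from .simdata import StudyDesign
from .speclib import SpectralLibrary

logger = logging.getLogger("swathlite")

#: Default linear voltage equations, value = slope * precursor_mz + intercept,
#: keyed by precursor charge (QTRAP-style defaults).
DEFAULT_CE_COEF: dict[int, tuple[float, float]] = {
    2: (0.044, 5.5), 3: (0.044, 5.5), 4: (0.044, 5.5),
}
DEFAULT_DP_COEF: dict[int, tuple[float, float]] = {
    2: (0.0729, 31.7), 3: (0.0729, 31.7), 4: (0.0729, 31.7),
}

ASSAY_COLUMNS = ["protein", "peptide", "q1", "charge", "q3",
                 "fragment_rel_intensity", "rt_center", "rt_halfwidth", "dp", "ce"]


def collision_energy(precursor_mz: float, charge: int,
                     coef: dict[int, tuple[float, float]] = DEFAULT_CE_COEF) -> float:
    slope, intercept = coef[charge]
    return slope * precursor_mz + intercept


def declustering_potential(precursor_mz: float, charge: int,
                           coef: dict[int, tuple[float, float]] = DEFAULT_DP_COEF) -> float:
    slope, intercept = coef[charge]
    return slope * precursor_mz + intercept


@dataclass
class AssaySet:
    """Designed MRM assays plus the targets that could not be designed."""

    assays: pd.DataFrame
    undesignable: list[str] = field(default_factory=list)


def design_assays(
    library: SpectralLibrary,
    targets: list[str],
    n_transitions: int = 5,
    ce_coef: dict[int, tuple[float, float]] | None = None,
    dp_coef: dict[int, tuple[float, float]] | None = None,
    rt_halfwidth: float = 2.5,
) -> AssaySet:
    """Design scheduled MRM assays for target protein accessions.

    Per peptide the top ``n_transitions`` library fragments by relative
    intensity become Q1/Q3 pairs; CE and DP are deterministic linear
    functions of precursor m/z given the per-charge coefficients; the
    acquisition window is the library RT +/- ``rt_halfwidth`` minutes.
    Targets absent from the library are reported as undesignable, not
    raised.
    """
    ce_coef = ce_coef or DEFAULT_CE_COEF
    dp_coef = dp_coef or DEFAULT_DP_COEF
    ent = library.entries
    present = set(ent["protein_accession"])
    undesignable = [t for t in targets if t not in present]
    if undesignable:
        logger.warning("%d target(s) absent from library: %s",
                       len(undesignable), undesignable[:5])
    sub = ent[ent["protein_accession"].isin(set(targets) - set(undesignable))]
    sub = (sub.sort_values(["peptide", "fragment_rel_intensity"],
                           ascending=[True, False], kind="mergesort")
           .groupby("peptide", sort=False).head(n_transitions))
    assays = pd.DataFrame({
        "protein": sub["protein_accession"],
        "peptide": sub["peptide"],
        "q1": sub["precursor_mz"],
        "charge": sub["charge"],
        "q3": sub["fragment_mz"],
        "fragment_rel_intensity": sub["fragment_rel_intensity"],
        "rt_center": sub["ref_rt_min"],
        "rt_halfwidth": rt_halfwidth,
        "dp": [declustering_potential(m, z, dp_coef)
               for m, z in zip(sub["precursor_mz"], sub["charge"])],
        "ce": [collision_energy(m, z, ce_coef)
               for m, z in zip(sub["precursor_mz"], sub["charge"])],
    }).reset_index(drop=True)
    return AssaySet(assays=assays, undesignable=undesignable)


def quantify_mrm(
    traces: pd.DataFrame,
    assays: pd.DataFrame,
    design: StudyDesign | None = None,
    baseline_quantile: float = 0.05,
    min_points: int = 3,
    mz_decimals: int = 4,
) -> QuantTable:
    """Integrate MRM traces and roll up to protein intensities per run.

    ``traces`` columns: run_id, q1, q3, rt_min, intensity; traces are
    matched to assay transitions on rounded (q1, q3). Unmatched traces are
    ignored with a warning. Transition areas come from the shared peak
    integrator; peptide value = sum of its transition areas, protein value
    = sum of its peptide values.
    """
    key = lambda df: list(zip(df["q1"].round(mz_decimals), df["q3"].round(mz_decimals)))
    assay_keys = dict(zip(key(assays), assays.index))
    tr = traces.copy()
    tr["_k"] = key(tr)
    unmatched = ~tr["_k"].isin(assay_keys)
    if unmatched.any():
        logger.warning("%d trace point(s) with no matching assay transition ignored",
                       int(unmatched.sum()))
        tr = tr[~unmatched]

    rows = []
    for (run_id, k), g in tr.groupby(["run_id", "_k"], sort=False):
        a = assays.loc[assay_keys[k]]
        g = g.sort_values("rt_min")
        area = _integrate(g["rt_min"].to_numpy(float), g["intensity"].to_numpy(float),
                          baseline_quantile, min_points)
        rows.append((a["protein"], a["peptide"], a["q3"], run_id, area))
    long = pd.DataFrame(rows, columns=["protein", "peptide", "q3", "run_id", "area"])
    tmat = long.pivot_table(index=["protein", "peptide", "q3"], columns="run_id",
                            values="area", aggfunc="first")
    pep = tmat.groupby(level=["protein", "peptide"], sort=False).sum(min_count=1)
    prot = pep.groupby(level="protein", sort=False).sum(min_count=1)
    prot.columns.name = None

    if design is not None:
        annot = design.run_table()
        annot["run_id"] = "mrm_" + annot["run_id"]
    else:
        parts = [(c, *c.replace("mrm_", "").rsplit("_", 2)) for c in prot.columns]
        annot = pd.DataFrame(
            [(c, g, int(b[1:]), int(t[1:])) for c, g, b, t in parts],
            columns=["run_id", "group", "bio_rep", "tech_rep"],
        )
    annot = annot[annot["run_id"].isin(prot.columns)].reset_index(drop=True)
    return QuantTable(level="protein", data=prot, annotations=annot)


@dataclass
class ConcordanceReport:
    """Cross-platform agreement of SWATH and MRM fold changes.

    ``table`` holds the per-protein side-by-side signed fold changes and
    agreement flags, computed only over proteins quantified by both
    platforms; ``agreement`` is the fraction with the same fold-change
    direction and ``spearman_rho`` the rank correlation of signed fold
    changes.
    """

    table: pd.DataFrame
    agreement: float
    spearman_rho: float


def concordance(swath_fc: pd.DataFrame, mrm_fc: pd.DataFrame,
                targets: list[str] | None = None) -> ConcordanceReport:
    """Compare per-protein fold-change direction between platforms.

    Inputs are tables with ``log2_fc`` and ``signed_fc`` columns indexed
    by protein (e.g. ``DiffResult.table`` from each platform). Raises if
    the platforms share no quantified target.
    """
    shared = swath_fc.index.intersection(mrm_fc.index)
    if targets is not None:
        shared = shared.intersection(pd.Index(targets))
    both = pd.DataFrame({
        "swath_log2_fc": swath_fc.loc[shared, "log2_fc"],
        "swath_signed_fc": swath_fc.loc[shared, "signed_fc"],
        "mrm_log2_fc": mrm_fc.loc[shared, "log2_fc"],
        "mrm_signed_fc": mrm_fc.loc[shared, "signed_fc"],
    }).dropna()
    if both.empty:
        raise ValueError("no protein quantified by both platforms")
    both["direction_agrees"] = (
        np.sign(both["swath_log2_fc"]) == np.sign(both["mrm_log2_fc"])
    )
    agreement = float(both["direction_agrees"].mean())
    if len(both) > 1 and both["swath_signed_fc"].nunique() > 1:
        rho = float(stats.spearmanr(both["swath_signed_fc"],
                                    both["mrm_signed_fc"]).statistic)
    else:
        rho = np.nan
    return ConcordanceReport(table=both, agreement=agreement, spearman_rho=rho)


def write_assays(assay_set: AssaySet, path) -> None:
    assay_set.assays[ASSAY_COLUMNS].to_csv(path, sep="\t", index=False)
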