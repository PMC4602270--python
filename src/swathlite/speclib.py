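"""Reference spectral library construction with target-decoy FDR control.

Merges identification tables from multiple IDA acquisitions (the reference
study combined three survey mass ranges: low, high and full), estimates
peptide-level q-values against reversed-sequence decoys, and builds the
extraction library: confident (q <= 0.01) peptides only, shared peptides
excluded, at most six fragments per peptide ranked by relative intensity,
reference retention time as the score-weighted mean across source runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("swathlite")

#: Columns of the library TSV dialect, one row per transition.
LIBRARY_COLUMNS = [
    "protein_accession", "peptide", "modified_peptide", "precursor_mz",
    "charge", "fragment_mz", "fragment_rel_intensity", "ref_rt_min",
    "score", "q_value", "is_decoy",
]

_ID_COLUMNS = ["run_id", "protein", "peptide", "precursor_mz",
               "charge", "rt_min", "score", "is_decoy"]


@dataclass
class SpectralLibrary:
    """Filtered reference library driving targeted extraction.

    ``entries`` is a long table (one row per retained transition) in the
    library TSV dialect; after building it contains no decoys and no
    shared peptides, with at most ``max_fragments`` fragments per peptide
    sorted by descending relative intensity.
    """

    entries: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def peptides(self) -> pd.DataFrame:
        """One row per peptide with precursor and reference RT."""
        return (self.entries
                .drop_duplicates(["peptide", "charge"])
                [["protein_accession", "peptide", "precursor_mz",
                  "charge", "ref_rt_min", "score", "q_value"]]
                .reset_index(drop=True))

    @property
    def n_proteins(self) -> int:
        return self.entries["protein_accession"].nunique()

    @property
    def n_peptides(self) -> int:
        return self.entries["peptide"].nunique()


def merge_ida_runs(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate identification tables from several acquisitions.

    Rows are concatenated with provenance run ids kept; the per-peptide
    best score is attached as ``best_score`` so downstream FDR control can
    operate on the combined evidence, mirroring a joint database search of
    all runs.
    """
    if not tables:
        raise ValueError("need at least one identification table")
    for t in tables:
        missing = [c for c in _ID_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"identification table missing column(s): {', '.join(missing)}")
    merged = pd.concat(tables, ignore_index=True)
    merged["best_score"] = merged.groupby("peptide")["score"].transform("max")
    return merged


def compute_qvalues(scores: np.ndarray, is_decoy: np.ndarray) -> np.ndarray:
    """Peptide-level q-values from a target-decoy score competition.

    At score threshold s the FDR estimate is (#decoys >= s) / (#targets
    >= s); a peptide's q-value is the minimum FDR over all thresholds that
    admit it. Score ties between target and decoy are broken by counting
    the decoy first (conservative). Returns q-values aligned with the
    target entries (NaN for decoy positions).
    """
    scores = np.asarray(scores, dtype=float)
    is_decoy = np.asarray(is_decoy, dtype=bool)
    n_targets = int((~is_decoy).sum())
    if n_targets == 0:
        raise ValueError("no target entries: cannot estimate FDR")
    if is_decoy.sum() == 0:
        q = np.full(len(scores), np.nan)
        q[~is_decoy] = 0.0
        return q
    # sort by descending score; at ties decoys come first
    order = np.lexsort((~is_decoy, -scores))
    sorted_decoy = is_decoy[order]
    cum_decoys = np.cumsum(sorted_decoy)
    cum_targets = np.cumsum(~sorted_decoy)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(cum_targets > 0, cum_decoys / cum_targets, np.inf)
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.full(len(scores), np.nan)
    q[order[~sorted_decoy]] = q_sorted[~sorted_decoy]
    return q


def peptide_summary(merged: pd.DataFrame) -> pd.DataFrame:
    """Per-peptide evidence summary of a merged identification table.

    Keeps the best score, the score-weighted mean retention time across
    source runs, the provenance run ids, the set size of distinct target
    proteins the peptide maps to, and the decoy flag.
    """
    def wmean_rt(g: pd.DataFrame) -> float:
        w = np.clip(g["score"].to_numpy(float), 1e-9, None)
        return float(np.average(g["rt_min"].to_numpy(float), weights=w))

    grp = merged.groupby("peptide", sort=False)
    out = grp.agg(
        protein=("protein", "first"),
        precursor_mz=("precursor_mz", "first"),
        charge=("charge", "first"),
        score=("score", "max"),
        is_decoy=("is_decoy", "any"),
        n_proteins=("protein", "nunique"),
        source_runs=("run_id", lambda s: ",".join(dict.fromkeys(s))),
    )
    out["ref_rt_min"] = grp.apply(wmean_rt, include_groups=False)
    return out.reset_index()


def build_library(
    ids: pd.DataFrame,
    fragments: pd.DataFrame | None = None,
    max_fragments: int = 6,
    min_confidence: float = 0.99,
) -> SpectralLibrary:
    """Build the reference spectral library from identifications.

    Applies the confidence gate (q-value <= 1 - ``min_confidence``, i.e.
    1% FDR at the default ">99% peptide confidence"), removes decoys,
    excludes peptides shared by more than one protein, and retains the
    ``max_fragments`` most intense fragments per peptide. ``fragments``
    supplies the fragment catalogue (columns peptide, fragment_mz and a
    relative-intensity column); if the input already carries fragment rows
    in the library dialect it may be omitted.

    Rebuilding from an already-filtered library (which contains no decoys)
    keeps the recorded q-values, since the decoy evidence needed to
    re-estimate them is gone after filtering; this makes library building
    idempotent.
    """
    if "run_id" not in ids.columns and "fragment_rel_intensity" in ids.columns:
        # library-dialect input: peptide rows + fragment rows combined
        return _rebuild_from_entries(ids, max_fragments, min_confidence)

    merged = ids if "best_score" in ids.columns else merge_ida_runs([ids])
    summary = peptide_summary(merged)
    if (~summary["is_decoy"]).sum() == 0:
        raise ValueError("no target peptides in identification table")
    summary["q_value"] = compute_qvalues(
        summary["score"].to_numpy(), summary["is_decoy"].to_numpy()
    )

    q_max = 1.0 - min_confidence
    kept = summary[~summary["is_decoy"] & (summary["q_value"] <= q_max)].copy()
    n_shared = int((kept["n_proteins"] > 1).sum())
    if n_shared:
        logger.info("excluding %d shared peptide(s)", n_shared)
    kept = kept[kept["n_proteins"] == 1]

    if fragments is None:
        raise ValueError("a fragment catalogue is required to build a library")
    icol = "fragment_rel_intensity" if "fragment_rel_intensity" in fragments.columns else "ion_frac"
    frags = fragments.drop_duplicates(["peptide", "fragment_mz"])[
        ["peptide", "fragment_mz", icol]
    ].rename(columns={icol: "fragment_rel_intensity"})

    entries = kept.merge(frags, on="peptide", how="left")
    orphans = entries["fragment_mz"].isna()
    if orphans.any():
        logger.warning("dropping %d peptide(s) without fragments",
                       entries.loc[orphans, "peptide"].nunique())
        entries = entries[~orphans]
    entries = (entries
               .sort_values(["peptide", "fragment_rel_intensity"],
                            ascending=[True, False], kind="mergesort")
               .groupby("peptide", sort=False)
               .head(max_fragments))

    lib = pd.DataFrame({
        "protein_accession": entries["protein"],
        "peptide": entries["peptide"],
        "modified_peptide": entries["peptide"],
        "precursor_mz": entries["precursor_mz"],
        "charge": entries["charge"],
        "fragment_mz": entries["fragment_mz"],
        "fragment_rel_intensity": entries["fragment_rel_intensity"],
        "ref_rt_min": entries["ref_rt_min"],
        "score": entries["score"],
        "q_value": entries["q_value"],
        "is_decoy": False,
    }).sort_values(["protein_accession", "peptide", "fragment_rel_intensity"],
                   ascending=[True, True, False], kind="mergesort").reset_index(drop=True)
    meta = {"fdr_threshold": q_max, "max_fragments": max_fragments,
            "source_runs": sorted(set(merged["run_id"]))}
    return SpectralLibrary(entries=lib, metadata=meta)


def _rebuild_from_entries(entries: pd.DataFrame, max_fragments: int,
                          min_confidence: float) -> SpectralLibrary:
    e = entries.copy()
    if e["is_decoy"].any():
        raise ValueError("library-dialect rebuild expects no decoy rows")
    q_max = 1.0 - min_confidence
    e = e[e["q_value"] <= q_max]
    shared = e.groupby("peptide")["protein_accession"].transform("nunique") > 1
    e = e[~shared]
    e = (e.sort_values(["peptide", "fragment_rel_intensity"],
                       ascending=[True, False], kind="mergesort")
         .groupby("peptide", sort=False).head(max_fragments))
    e = e.sort_values(["protein_accession", "peptide", "fragment_rel_intensity"],
                      ascending=[True, True, False], kind="mergesort").reset_index(drop=True)
    return SpectralLibrary(entries=e[LIBRARY_COLUMNS],
                           metadata={"fdr_threshold": q_max,
                                     "max_fragments": max_fragments,
                                     "source_runs": []})


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_library(library: SpectralLibrary | pd.DataFrame, path) -> None:
    entries = library.entries if isinstance(library, SpectralLibrary) else library
    entries[LIBRARY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_library(path) -> SpectralLibrary:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in LIBRARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"library file missing column(s): {', '.join(missing)}")
    return SpectralLibrary(entries=df)
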