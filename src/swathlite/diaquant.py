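"""Library-driven targeted extraction from DIA runs and intensity roll-up.

The quantification path mirrors a PeakView-style targeted analysis: each
library precursor is assigned to its isolation window, fragment-ion XICs
are extracted at 50 ppm within a 20-minute retention-time window (after a
linear RT alignment against library anchors), peaks are integrated by
trapezoid over the contiguous region above a baseline quantile, runs are
total-area normalized, and intensities are rolled up by summation:
six transitions -> peptide, six peptides -> protein.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simdata import AcquisitionScheme, DiaRun
from .speclib import SpectralLibrary

logger = logging.getLogger("swathlite")


# ---------------------------------------------------------------------------
# Window assignment
# ---------------------------------------------------------------------------

def assign_window(precursor_mz: float, scheme: AcquisitionScheme) -> int | None:
    """Isolation-window index for a precursor m/z.

    Windows are half-open [low, high): a boundary value belongs to the
    upper window. With overlapping windows the one whose center is nearest
    wins. Returns None for an unscheduled precursor (outside every
    window) rather than raising.
    """
    idx = scheme.assign(np.array([precursor_mz]))[0]
    return None if idx < 0 else int(idx)


# ---------------------------------------------------------------------------
# XIC extraction
# ---------------------------------------------------------------------------

@dataclass
class Xic:
    """Extracted ion chromatogram: per-cycle summed intensity of all raw
    points within ``tol_ppm`` of ``target_mz`` in one isolation window."""

    run_id: str
    target_mz: float
    tol_ppm: float
    rt_min: np.ndarray
    intensity: np.ndarray

    def __len__(self) -> int:
        return len(self.rt_min)


class RunIndex:
    """Per-window m/z-sorted view of one run's scan table for fast XICs."""

    def __init__(self, run: DiaRun):
        self.run_id = run.run_id
        self._groups: dict = {}
        scans = run.scans
        lows = scans["window_low"].to_numpy()
        for low in np.unique(lows):
            sub = scans[lows == low]
            order = np.argsort(sub["mz"].to_numpy(), kind="mergesort")
            self._groups[round(float(low), 6)] = (
                sub["mz"].to_numpy()[order],
                sub["rt_min"].to_numpy()[order],
                sub["intensity"].to_numpy()[order],
            )

    def xic(self, window_low: float, target_mz: float, tol_ppm: float,
            rt_lo: float = -np.inf, rt_hi: float = np.inf
            ) -> tuple[np.ndarray, np.ndarray]:
        """(rt, per-cycle summed intensity) arrays, sorted by RT."""
        key = round(float(window_low), 6)
        grp = self._groups.get(key)
        if grp is None:
            return np.empty(0), np.empty(0)
        mz, rt, inten = grp
        half = target_mz * tol_ppm * 1e-6
        i0 = np.searchsorted(mz, target_mz - half, side="left")
        i1 = np.searchsorted(mz, target_mz + half, side="right")
        if i1 <= i0:
            return np.empty(0), np.empty(0)
        rt_sel = rt[i0:i1]
        in_rt = (rt_sel >= rt_lo) & (rt_sel <= rt_hi)
        rt_sel = rt_sel[in_rt]
        if rt_sel.size == 0:
            return np.empty(0), np.empty(0)
        int_sel = inten[i0:i1][in_rt]
        uniq, inv = np.unique(rt_sel, return_inverse=True)
        summed = np.bincount(inv, weights=int_sel)
        return uniq, summed


def extract_xic(
    run: DiaRun,
    target_mz: float,
    window_low: float,
    rt_center: float,
    rt_halfwidth: float = 10.0,
    tol_ppm: float = 50.0,
    _index: RunIndex | None = None,
) -> Xic:
    """Extract the XIC of one transition from a DIA run.

    All raw points of the isolation window starting at ``window_low``
    whose m/z lies within ``tol_ppm`` of ``target_mz`` and whose RT lies
    within ``rt_center +/- rt_halfwidth`` are summed per cycle. The
    default halfwidth of 10 minutes gives the 20-minute full extraction
    window of the reference workflow. An empty XIC is a valid result and
    propagates as a missing value downstream.
    """
    idx = _index or RunIndex(run)
    rt, inten = idx.xic(window_low, target_mz, tol_ppm,
                        rt_center - rt_halfwidth, rt_center + rt_halfwidth)
    return Xic(run.run_id, target_mz, tol_ppm, rt, inten)


# ---------------------------------------------------------------------------
# Peak integration
# ---------------------------------------------------------------------------

def _integrate(rt: np.ndarray, inten: np.ndarray,
               baseline_quantile: float, min_points: int) -> float:
    if len(rt) < min_points or not np.any(inten > 0):
        return np.nan
    baseline = np.quantile(inten, baseline_quantile)
    above = inten >= baseline
    apex = int(np.argmax(inten))
    lo = apex
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = apex
    while hi < len(inten) - 1 and above[hi + 1]:
        hi += 1
    if hi - lo + 1 < 2:
        return np.nan
    return float(np.trapezoid(inten[lo:hi + 1], rt[lo:hi + 1]))


def integrate_peak(xic: Xic, baseline_quantile: float = 0.05,
                   min_points: int = 3) -> float:
    """Trapezoidal area (intensity x min) of the main chromatographic peak.

    The baseline is a configurable quantile of the XIC (default the 5th
    percentile); the integrated region is the largest contiguous stretch
    of points at or above baseline that contains the maximum point.
    Returns NaN (missing) for traces with fewer than ``min_points`` points
    or no positive signal.
    """
    return _integrate(np.asarray(xic.rt_min, float),
                      np.asarray(xic.intensity, float),
                      baseline_quantile, min_points)


# ---------------------------------------------------------------------------
# RT alignment
# ---------------------------------------------------------------------------

@dataclass
class RtAlignment:
    """Monotone linear mapping from library RT to observed RT."""

    slope: float = 1.0
    intercept: float = 0.0
    n_anchors: int = 0
    residual_sd: float = np.nan
    identity: bool = True

    def map(self, rt):
        if self.identity:
            return np.asarray(rt, float)
        return self.slope * np.asarray(rt, float) + self.intercept


def align_rt(
    run: DiaRun | RunIndex,
    library: SpectralLibrary,
    scheme: AcquisitionScheme,
    n_anchors: int = 30,
    tol_ppm: float = 50.0,
    residual_gate_min: float = 1.5,
) -> RtAlignment:
    """Fit observed-vs-library retention time by ordinary least squares.

    Anchors are high-confidence library peptides spread over the RT range;
    each anchor's most intense fragment is extracted over the whole run
    and its apex RT recorded. Falls back to the identity mapping (with a
    warning) when fewer than two anchors yield a peak or when the fit
    residual s.d. exceeds ``residual_gate_min`` minutes.
    """
    idx = run if isinstance(run, RunIndex) else RunIndex(run)
    pep = library.peptides
    ent = library.entries
    top_frag = (ent.sort_values("fragment_rel_intensity", ascending=False)
                .drop_duplicates(["peptide", "charge"]))
    top_frag = top_frag.merge(pep[["peptide", "charge"]], on=["peptide", "charge"])
    cand = top_frag.sort_values("score", ascending=False).head(n_anchors * 4)
    cand = cand.sort_values("ref_rt_min")
    step = max(1, len(cand) // n_anchors)
    cand = cand.iloc[::step].head(n_anchors)

    win = scheme.assign(cand["precursor_mz"].to_numpy())
    lib_rt, obs_rt = [], []
    for (_, row), w in zip(cand.iterrows(), win):
        if w < 0:
            continue
        rt, inten = idx.xic(scheme.windows[w][0], row["fragment_mz"], tol_ppm)
        if len(rt) == 0 or inten.max() <= 0:
            continue
        lib_rt.append(row["ref_rt_min"])
        obs_rt.append(rt[int(np.argmax(inten))])
    if len(lib_rt) < 2:
        logger.warning("run %s: fewer than 2 RT anchors; using identity mapping",
                       idx.run_id)
        return RtAlignment(n_anchors=len(lib_rt))
    x, y = np.asarray(lib_rt), np.asarray(obs_rt)
    slope, intercept = np.polyfit(x, y, 1)
    resid_sd = float(np.std(y - (slope * x + intercept), ddof=1))
    if resid_sd > residual_gate_min:
        logger.warning("run %s: RT fit residual s.d. %.2f min exceeds gate; "
                       "using identity mapping", idx.run_id, resid_sd)
        return RtAlignment(n_anchors=len(x), residual_sd=resid_sd)
    return RtAlignment(float(slope), float(intercept), len(x), resid_sd, identity=False)


# ---------------------------------------------------------------------------
# Quant tables
# ---------------------------------------------------------------------------

@dataclass
class QuantTable:
    """Intensity matrix at one roll-up level.

    ``data`` is features x runs with NaN marking missing values (never a
    silent zero); ``annotations`` maps run ids to (group, bio_rep,
    tech_rep). The feature index is (protein, peptide, fragment_mz) at
    transition level, (protein, peptide) at peptide level and the protein
    accession at protein level.
    """

    level: str
    data: pd.DataFrame
    annotations: pd.DataFrame

    def runs_of(self, group: str, bio_rep: int) -> list[str]:
        a = self.annotations
        return list(a.loc[(a["group"] == group) & (a["bio_rep"] == bio_rep), "run_id"])


def quantify_study(
    library: SpectralLibrary,
    runs: list[DiaRun],
    scheme: AcquisitionScheme,
    tol_ppm: float = 50.0,
    rt_halfwidth: float = 10.0,
    align: bool = True,
    baseline_quantile: float = 0.05,
    min_points: int = 3,
) -> QuantTable:
    """Targeted extraction of every library transition from every run.

    Returns the transition-level quant table of integrated peak areas;
    unscheduled precursors (outside the window scheme) are dropped with a
    warning.
    """
    ent = library.entries
    pep = library.peptides.copy()
    win = scheme.assign(pep["precursor_mz"].to_numpy())
    if (win < 0).any():
        bad = pep.loc[win < 0, "peptide"].tolist()
        logger.warning("%d precursor(s) outside the window scheme dropped: %s",
                       len(bad), bad[:5])
    pep["win"] = win
    pep = pep[pep["win"] >= 0]
    trans = ent.merge(pep[["peptide", "charge", "win"]], on=["peptide", "charge"])
    t_low = np.array([scheme.windows[w][0] for w in trans["win"]])
    t_fmz = trans["fragment_mz"].to_numpy()
    t_rt = trans["ref_rt_min"].to_numpy()

    cols = {}
    annot_rows = []
    for run in runs:
        idx = RunIndex(run)
        mapping = align_rt(idx, library, scheme, tol_ppm=tol_ppm) if align else RtAlignment()
        pred_rt = mapping.map(t_rt)
        areas = np.empty(len(trans))
        for i in range(len(trans)):
            rt, inten = idx.xic(t_low[i], t_fmz[i], tol_ppm,
                                pred_rt[i] - rt_halfwidth, pred_rt[i] + rt_halfwidth)
            areas[i] = _integrate(rt, inten, baseline_quantile, min_points)
        cols[run.run_id] = areas
        annot_rows.append((run.run_id, run.group, run.bio_rep, run.tech_rep))

    index = pd.MultiIndex.from_arrays(
        [trans["protein_accession"], trans["peptide"], trans["fragment_mz"]],
        names=["protein", "peptide", "fragment_mz"],
    )
    data = pd.DataFrame(cols, index=index)
    annotations = pd.DataFrame(annot_rows, columns=["run_id", "group", "bio_rep", "tech_rep"])
    return QuantTable(level="transition", data=data, annotations=annotations)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize(quant: QuantTable, method: str = "total"
              ) -> tuple[QuantTable, pd.Series]:
    """Scale runs onto a common intensity footing.

    ``total`` (the default, matching total-area scaling): each run is
    multiplied so its summed area equals the across-run median of summed
    areas. ``median-ratio``: each run is divided by the median ratio of
    its values to the per-feature across-run median. Returns the scaled
    table and the per-run multipliers.
    """
    data = quant.data
    all_missing = data.isna().all(axis=0)
    if all_missing.any():
        raise ValueError(
            f"run(s) with no quantified values: {', '.join(data.columns[all_missing])}"
        )
    if method == "total":
        totals = data.sum(axis=0, skipna=True)
        factors = totals.median() / totals
    elif method == "median-ratio":
        ref = data.median(axis=1, skipna=True)
        ratios = data.div(ref, axis=0)
        factors = 1.0 / ratios.median(axis=0, skipna=True)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    logger.info("normalization factors: %s",
                ", ".join(f"{r}={f:.4g}" for r, f in factors.items()))
    return QuantTable(quant.level, data.mul(factors, axis=1), quant.annotations), factors


# ---------------------------------------------------------------------------
# Roll-up
# ---------------------------------------------------------------------------

def rollup(
    quant: QuantTable,
    library: SpectralLibrary,
    max_transitions: int = 6,
    max_peptides: int = 6,
) -> tuple[QuantTable, QuantTable]:
    """Summation roll-up: transitions -> peptide -> protein.

    The library defines what is retained: the ``max_transitions`` most
    intense fragments per peptide (by library relative intensity) and the
    ``max_peptides`` strongest peptides per protein (by summed library
    fragment intensity). A peptide or protein is missing in a run only if
    all of its retained constituents are missing there.
    """
    if quant.level != "transition":
        raise ValueError("rollup expects a transition-level table")
    ent = library.entries
    retained_t = (ent.sort_values(["peptide", "fragment_rel_intensity"],
                                  ascending=[True, False], kind="mergesort")
                  .groupby("peptide", sort=False).head(max_transitions))
    keys = set(zip(retained_t["peptide"], retained_t["fragment_mz"]))

    data = quant.data
    in_lib = [(p, f) in keys for _, p, f in data.index]
    dropped = len(data) - sum(in_lib)
    if dropped:
        logger.warning("%d transition(s) not retained by the library ignored", dropped)
    tdata = data[np.asarray(in_lib)]

    pep_data = tdata.groupby(level=["protein", "peptide"], sort=False).sum(min_count=1)
    pep_table = QuantTable("peptide", pep_data, quant.annotations)

    pep_rank = (retained_t.groupby(["protein_accession", "peptide"], sort=False)
                ["fragment_rel_intensity"].sum()
                .rename("lib_intensity").reset_index())
    top_pep = (pep_rank.sort_values(["protein_accession", "lib_intensity"],
                                    ascending=[True, False], kind="mergesort")
               .groupby("protein_accession", sort=False).head(max_peptides))
    keep_pep = set(zip(top_pep["protein_accession"], top_pep["peptide"]))
    mask = [(pr, pe) in keep_pep for pr, pe in pep_data.index]
    prot_data = (pep_data[np.asarray(mask)]
                 .groupby(level="protein", sort=False).sum(min_count=1))
    prot_table = QuantTable("protein", prot_data, quant.annotations)
    return pep_table, prot_table


# ---------------------------------------------------------------------------
# IO: quant tables, mzML
# ---------------------------------------------------------------------------

def write_quant_table(quant: QuantTable, path) -> None:
    """TSV with a run-annotation header block (# level / # run lines)."""
    with open(path, "w") as fh:
        fh.write(f"# level\t{quant.level}\n")
        for _, r in quant.annotations.iterrows():
            fh.write(f"# run\t{r.run_id}\t{r.group}\t{r.bio_rep}\t{r.tech_rep}\n")
        quant.data.to_csv(fh, sep="\t")


def read_quant_table(path) -> QuantTable:
    level, annot = None, []
    with open(path) as fh:
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            parts = line[1:].strip().split("\t")
            if parts[0] == "level":
                level = parts[1]
            elif parts[0] == "run":
                annot.append((parts[1], parts[2], int(parts[3]), int(parts[4])))
        n_index = {"transition": 3, "peptide": 2, "protein": 1}[level]
        data = pd.read_csv(fh, sep="\t", index_col=list(range(n_index)))
    annotations = pd.DataFrame(annot, columns=["run_id", "group", "bio_rep", "tech_rep"])
    return QuantTable(level=level, data=data, annotations=annotations)


def write_mzml(run: DiaRun, path) -> None:
    """Minimal mzML export of a DIA run: one MS2 spectrum per (window,
    cycle) with uncompressed 64-bit m/z and intensity arrays."""
    import base64
    from lxml import etree

    NS = "http://psi.hupo.org/ms/mzml"
    root = etree.Element(f"{{{NS}}}mzML", nsmap={None: NS}, version="1.1.0")
    specs = run.scans.groupby(["window_low", "window_high", "rt_min"], sort=True)
    run_el = etree.SubElement(root, f"{{{NS}}}run", id=run.run_id)
    slist = etree.SubElement(run_el, f"{{{NS}}}spectrumList", count=str(specs.ngroups))

    def cv(parent, accession, name, value="", unit=None):
        attrs = {"cvRef": "MS", "accession": accession, "name": name, "value": str(value)}
        if unit:
            attrs.update({"unitCvRef": "UO", "unitAccession": unit[0], "unitName": unit[1]})
        etree.SubElement(parent, f"{{{NS}}}cvParam", **attrs)

    def encode(arr):
        return base64.b64encode(np.asarray(arr, "<f8").tobytes()).decode()

    for i, ((wlo, whi, rt), g) in enumerate(specs):
        sp = etree.SubElement(slist, f"{{{NS}}}spectrum", index=str(i),
                              id=f"scan={i + 1}", defaultArrayLength=str(len(g)))
        cv(sp, "MS:1000511", "ms level", 2)
        scan_list = etree.SubElement(sp, f"{{{NS}}}scanList", count="1")
        scan = etree.SubElement(scan_list, f"{{{NS}}}scan")
        cv(scan, "MS:1000016", "scan start time", rt, ("UO:0000031", "minute"))
        pre_list = etree.SubElement(sp, f"{{{NS}}}precursorList", count="1")
        pre = etree.SubElement(pre_list, f"{{{NS}}}precursor")
        iso = etree.SubElement(pre, f"{{{NS}}}isolationWindow")
        center = (wlo + whi) / 2.0
        cv(iso, "MS:1000827", "isolation window target m/z", center)
        cv(iso, "MS:1000828", "isolation window lower offset", center - wlo)
        cv(iso, "MS:1000829", "isolation window upper offset", whi - center)
        bal = etree.SubElement(sp, f"{{{NS}}}binaryDataArrayList", count="2")
        for acc, name, vals in (("MS:1000514", "m/z array", g["mz"]),
                                ("MS:1000515", "intensity array", g["intensity"])):
            enc = encode(vals)
            bda = etree.SubElement(bal, f"{{{NS}}}binaryDataArray",
                                   encodedLength=str(len(enc)))
            cv(bda, "MS:1000523", "64-bit float")
            cv(bda, "MS:1000576", "no compression")
            cv(bda, acc, name)
            etree.SubElement(bda, f"{{{NS}}}binary").text = enc
    etree.ElementTree(root).write(str(path), xml_declaration=True,
                                  encoding="utf-8", pretty_print=True)


def read_mzml(path, run_id: str | None = None, group: str = "",
              bio_rep: int = 0, tech_rep: int = 0) -> DiaRun:
    """Read a DIA run from mzML into the tabular scan representation.

    Supports the subset this package writes and standard DIA exports:
    MS2 spectra with an isolation window, minute- or second-unit scan
    start times, and uncompressed or zlib-compressed 32/64-bit float
    binary arrays.
    """
    import base64
    import zlib as _zlib
    from lxml import etree

    def params(el):
        out = {}
        for cv in el.iter("{*}cvParam"):
            out[cv.get("name")] = cv
        return out

    rows = []
    for _, sp in etree.iterparse(str(path), tag="{*}spectrum"):
        p = params(sp)
        if "ms level" in p and p["ms level"].get("value") not in ("2", 2):
            sp.clear()
            continue
        scan = sp.find(".//{*}scan")
        sparams = params(scan) if scan is not None else {}
        if "scan start time" not in sparams:
            sp.clear()
            continue
        cv = sparams["scan start time"]
        rt = float(cv.get("value"))
        if cv.get("unitName") == "second":
            rt /= 60.0
        iso = sp.find(".//{*}isolationWindow")
        if iso is None:
            sp.clear()
            continue
        ip = {k: float(v.get("value")) for k, v in params(iso).items()}
        center = ip["isolation window target m/z"]
        lo = center - ip.get("isolation window lower offset", 0.0)
        hi = center + ip.get("isolation window upper offset", 0.0)
        arrays = {}
        for bda in sp.iter("{*}binaryDataArray"):
            bp = params(bda)
            raw = base64.b64decode(bda.findtext("{*}binary") or "")
            if "zlib compression" in bp:
                raw = _zlib.decompress(raw)
            dtype = "<f4" if "32-bit float" in bp else "<f8"
            vals = np.frombuffer(raw, dtype=dtype)
            if "m/z array" in bp:
                arrays["mz"] = vals
            elif "intensity array" in bp:
                arrays["intensity"] = vals
        if "mz" in arrays and "intensity" in arrays:
            for m, it in zip(arrays["mz"], arrays["intensity"]):
                rows.append((lo, hi, rt, m, it))
        sp.clear()
    scans = pd.DataFrame(rows, columns=["window_low", "window_high",
                                        "rt_min", "mz", "intensity"])
    return DiaRun(run_id or str(path), group, bio_rep, tech_rep, scans)
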