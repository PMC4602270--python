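"""Ground-truthed synthetic SWATH-MS study generator.

Emulates the acquisition design of a two-group broiler liver heat-stress
study: two groups (control 26 °C, heat 32 °C), nine animals per group pooled
three-at-a-time into three biological replicates, three technical injections
each (18 DIA runs), variable- or equal-width SWATH isolation windows over
m/z 350–1,250, IDA-style identification tables acquired over three MS mass
ranges, and scheduled MRM traces for validation targets.

Every stochastic quantity is drawn from a named substream of a single seed,
and every intermediate (animal, pool, run) value is recorded so downstream
stages can be checked against exact ground truth.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("swathlite")

# ---------------------------------------------------------------------------
# Masses and peptide chemistry
# ---------------------------------------------------------------------------

#: Monoisotopic residue masses (Da), standard 20 amino acids.
RESIDUE_MONO: dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

WATER = 18.0105646863
PROTON = 1.00727646688

#: IDA survey-scan mass ranges used to build the reference library:
#: a low range, a high range and the full range.
DEFAULT_IDA_RANGES: tuple[tuple[float, float], ...] = (
    (350.0, 750.0), (745.0, 1250.0), (350.0, 1250.0),
)


def peptide_mass(sequence: str) -> float:
    """Monoisotopic neutral mass of an unmodified peptide."""
    try:
        return sum(RESIDUE_MONO[aa] for aa in sequence) + WATER
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"unknown residue {exc.args[0]!r} in {sequence!r}") from None


def precursor_mz(sequence: str, charge: int) -> float:
    """m/z of the [M + zH]^z+ precursor ion."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (peptide_mass(sequence) + charge * PROTON) / charge


def fragment_mz(sequence: str, ion: str) -> float:
    """m/z of a singly charged b- or y-ion, e.g. ``"y4"`` or ``"b3"``."""
    kind, num = ion[0], int(ion[1:])
    if not 1 <= num < len(sequence):
        raise ValueError(f"ion {ion} out of range for length-{len(sequence)} peptide")
    if kind == "y":
        return sum(RESIDUE_MONO[aa] for aa in sequence[-num:]) + WATER + PROTON
    if kind == "b":
        return sum(RESIDUE_MONO[aa] for aa in sequence[:num]) + PROTON
    raise ValueError(f"unsupported ion series {kind!r}")


def reverse_decoy(sequence: str) -> str:
    """Decoy sequence: reverse the peptide keeping the C-terminal residue."""
    return sequence[:-1][::-1] + sequence[-1]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Named deterministic substream of a master seed (stage-name hashed)."""
    return np.random.default_rng([int(seed) % 2**31, zlib.crc32(stage.encode())])


# ---------------------------------------------------------------------------
# Study design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyDesign:
    """Two-group pooled-replicate design.

    Animals are pooled ``pool_size`` at a time into biological replicates;
    each biological replicate is injected ``tech_replicates`` times.
    ``animals_per_group`` must equal ``pool_size * bio_replicates``.
    """

    groups: tuple[str, str] = ("control", "heat")
    animals_per_group: int = 9
    pool_size: int = 3
    bio_replicates: int = 3
    tech_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.animals_per_group != self.pool_size * self.bio_replicates:
            raise ValueError(
                "animals_per_group must equal pool_size * bio_replicates "
                f"({self.animals_per_group} != {self.pool_size} * {self.bio_replicates})"
            )
        if min(self.pool_size, self.bio_replicates, self.tech_replicates) < 1:
            raise ValueError("replicate counts must be positive")

    @property
    def n_runs(self) -> int:
        return len(self.groups) * self.bio_replicates * self.tech_replicates

    def bio_sample_ids(self) -> list[str]:
        return [f"{g}_b{b + 1}" for g in self.groups for b in range(self.bio_replicates)]

    def run_table(self) -> pd.DataFrame:
        """One row per injection: run_id, group, bio_rep, tech_rep."""
        rows = [
            (f"{g}_b{b + 1}_t{t + 1}", g, b + 1, t + 1)
            for g in self.groups
            for b in range(self.bio_replicates)
            for t in range(self.tech_replicates)
        ]
        return pd.DataFrame(rows, columns=["run_id", "group", "bio_rep", "tech_rep"])


# ---------------------------------------------------------------------------
# Acquisition scheme
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionScheme:
    """SWATH or IDA duty cycle.

    In SWATH mode the cycle is one survey scan plus one MS/MS event per
    isolation window; in IDA mode it is one survey scan plus ``top_n``
    candidate MS/MS events.
    """

    mode: str = "swath"
    survey_scan_s: float = 0.05
    windows: tuple[tuple[float, float], ...] = ()
    accumulation_s: float = 0.05
    # IDA-only parameters
    top_n: int = 40
    msms_accumulation_s: float = 0.05
    min_intensity_cps: float = 150.0
    charge_range: tuple[int, int] = (2, 4)

    def __post_init__(self) -> None:
        if self.mode not in ("swath", "ida"):
            raise ValueError(f"unknown acquisition mode {self.mode!r}")
        if self.survey_scan_s < 0 or self.accumulation_s < 0:
            raise ValueError("scan times must be non-negative")
        if self.mode == "swath":
            ws = self.windows
            if any(hi <= lo for lo, hi in ws):
                raise ValueError("each window must satisfy low < high")
            for (lo1, hi1), (lo2, hi2) in zip(ws, ws[1:]):
                if lo2 > hi1:
                    raise ValueError(
                        f"gap in window scheme between {hi1} and {lo2} Th"
                    )

    @classmethod
    def default_swath(
        cls,
        mz_range: tuple[float, float] = (350.0, 1250.0),
        n_windows: int = 60,
        survey_scan_s: float = 0.05,
        accumulation_s: float = 0.05,
    ) -> "AcquisitionScheme":
        """Equal-width isolation windows over the precursor range."""
        edges = np.linspace(mz_range[0], mz_range[1], n_windows + 1)
        windows = tuple((float(lo), float(hi)) for lo, hi in zip(edges, edges[1:]))
        return cls(mode="swath", survey_scan_s=survey_scan_s,
                   windows=windows, accumulation_s=accumulation_s)

    @classmethod
    def reference_ida(cls) -> "AcquisitionScheme":
        """TripleTOF-style IDA method: 0.25 s survey, top-40 MS/MS at
        0.05 s each, 150 cps precursor threshold, charges +2..+4."""
        return cls(mode="ida", survey_scan_s=0.25, top_n=40,
                   msms_accumulation_s=0.05, min_intensity_cps=150.0,
                   charge_range=(2, 4))

    @property
    def mz_range(self) -> tuple[float, float]:
        if not self.windows:
            raise ValueError("scheme has no isolation windows")
        return (self.windows[0][0], self.windows[-1][1])

    def assign(self, mz: np.ndarray) -> np.ndarray:
        """Vectorized isolation-window index per precursor m/z.

        Windows are half-open ``[low, high)``; a boundary m/z belongs to the
        upper window. Where windows overlap the one with the nearest center
        wins. Unscheduled precursors get index -1.
        """
        mz = np.asarray(mz, dtype=float)
        lows = np.array([w[0] for w in self.windows])
        highs = np.array([w[1] for w in self.windows])
        centers = (lows + highs) / 2.0
        inside = (mz[:, None] >= lows) & (mz[:, None] < highs)
        dist = np.abs(mz[:, None] - centers)
        dist[~inside] = np.inf
        idx = np.argmin(dist, axis=1)
        idx[~inside.any(axis=1)] = -1
        return idx


def cycle_time(scheme: AcquisitionScheme) -> float:
    """Duty-cycle length in seconds: survey scan plus all scheduled
    MS/MS accumulation events of one cycle."""
    if scheme.mode == "ida":
        return scheme.survey_scan_s + scheme.top_n * scheme.msms_accumulation_s
    if not scheme.windows:
        raise ValueError("SWATH scheme requires at least one isolation window")
    return scheme.survey_scan_s + len(scheme.windows) * scheme.accumulation_s


# ---------------------------------------------------------------------------
# Proteome
# ---------------------------------------------------------------------------

@dataclass
class Proteome:
    """In-silico proteome: tryptic-like peptides with y-ion fragments.

    ``peptides`` has one row per (protein, peptide) with precursor charge,
    m/z, the peptide's share of its protein's signal and a reference
    retention time; ``fragments`` has one row per transition with the
    fragment m/z and its ionization fraction of the peptide signal.
    Peptide shares sum to 1 within each protein and ionization fractions
    sum to 1 within each peptide, so that summation roll-up over all
    transitions reconstructs the protein abundance exactly.
    """

    peptides: pd.DataFrame
    fragments: pd.DataFrame
    gradient_min: float = 60.0

    @property
    def accessions(self) -> list[str]:
        return list(dict.fromkeys(self.peptides["protein"]))


_INTERNAL_RESIDUES = "GASPVTLNDQEMHFYW"  # no K/R/C/I: tryptic interior
_TERMINAL_RESIDUES = "KR"


def _random_peptide(rng: np.random.Generator) -> str:
    length = int(rng.integers(7, 17))
    body = "".join(rng.choice(list(_INTERNAL_RESIDUES), size=length - 1))
    return body + _TERMINAL_RESIDUES[int(rng.integers(0, 2))]


def _choose_charge(mass: float, rng: np.random.Generator) -> int | None:
    # keep the precursor inside the default 350-1250 window range
    candidates = [z for z in (2, 3, 4) if 360.0 <= (mass + z * PROTON) / z <= 1240.0]
    if not candidates:
        return None
    weights = np.array([0.7, 0.25, 0.05][: len(candidates)])
    return int(rng.choice(candidates, p=weights / weights.sum()))


def generate_proteome(
    n_proteins: int,
    peptides_per_protein: int = 5,
    seed: int = 0,
    n_fragments: int = 6,
    shared_peptide_fraction: float = 0.0,
    gradient_min: float = 60.0,
    scheme: AcquisitionScheme | None = None,
    min_fragment_spacing_ppm: float = 150.0,
) -> Proteome:
    """Generate a synthetic proteome with ground-truth signal partitioning.

    Peptide sequences are random tryptic-like strings (C-terminal K/R),
    unique across proteins unless ``shared_peptide_fraction`` > 0, in which
    case that fraction of peptides is additionally attached to a second
    protein. Each peptide's quantification fragments are selected from its
    y-ion series against a per-window occupancy list so that fragments of
    peptides co-isolated in the same SWATH window stay at least
    ``min_fragment_spacing_ppm`` apart: extracted chromatograms are
    interference-free by construction (chimeric spectra are out of scope
    for this generator). A peptide may end up with fewer than
    ``n_fragments`` fragments when its window is locally crowded.
    """
    if n_proteins < 1 or peptides_per_protein < 1:
        raise ValueError("n_proteins and peptides_per_protein must be >= 1")
    rng = stage_rng(seed, "proteome")
    scheme = scheme or AcquisitionScheme.default_swath()

    n_pep = n_proteins * peptides_per_protein
    seen: set[str] = set()

    def draw_unique() -> tuple[str, int, float]:
        for _ in range(1000):
            s = _random_peptide(rng)
            if s in seen or reverse_decoy(s) in seen:
                continue
            z = _choose_charge(peptide_mass(s), rng)
            if z is None:  # precursor outside the schedulable m/z range
                continue
            seen.add(s)
            return s, z, (peptide_mass(s) + z * PROTON) / z
        raise RuntimeError("could not draw a unique peptide sequence")

    drawn = [draw_unique() for _ in range(n_pep)]
    sequences = [d[0] for d in drawn]
    charges = [d[1] for d in drawn]
    mzs = [d[2] for d in drawn]
    proteins = [f"SYNP{p:05d}" for p in range(n_proteins) for _ in range(peptides_per_protein)]

    # fragment selection with per-window spacing: y-ions are accepted in a
    # random order only if they clear the ppm guard against every fragment
    # already scheduled in the same isolation window
    import bisect

    tol = min_fragment_spacing_ppm * 1e-6
    occupancy: dict[int, list[float]] = {}

    def select_fragments(seq: str, window: int) -> list[tuple[int, float]]:
        occupied = occupancy.setdefault(window, [])
        ks = np.arange(3, len(seq))
        chosen: list[tuple[int, float]] = []
        inserted: list[float] = []
        for j in rng.permutation(len(ks)):
            k = int(ks[j])
            fm = fragment_mz(seq, f"y{k}")
            pos = bisect.bisect_left(occupied, fm)
            left_ok = pos == 0 or (fm - occupied[pos - 1]) / fm > tol
            right_ok = pos == len(occupied) or (occupied[pos] - fm) / fm > tol
            if left_ok and right_ok:
                bisect.insort(occupied, fm)
                inserted.append(fm)
                chosen.append((k, fm))
                if len(chosen) == n_fragments:
                    break
        if not chosen:
            for fm in inserted:
                occupied.remove(fm)
        return sorted(chosen)

    scheme_windows = scheme.assign(np.asarray(mzs))
    frag_ions: list[tuple[list[str], list[float]]] = []
    for i, seq in enumerate(sequences):
        chosen = select_fragments(seq, int(scheme_windows[i]))
        # crowded window + short peptide: redraw the sequence until at
        # least one interference-free fragment exists
        for _ in range(200):
            if chosen:
                break
            seen.discard(sequences[i])
            sequences[i], charges[i], mzs[i] = draw_unique()
            seq = sequences[i]
            w = int(scheme.assign(np.asarray(mzs[i : i + 1]))[0])
            chosen = select_fragments(seq, w)
        if not chosen:  # pragma: no cover - needs an absurdly crowded scheme
            raise RuntimeError("could not place interference-free fragments")
        frag_ions.append(([f"y{k}" for k, _ in chosen], [fm for _, fm in chosen]))

    ref_rt = rng.uniform(0.08 * gradient_min, 0.92 * gradient_min, size=n_pep)
    shares = np.concatenate([
        rng.dirichlet(np.full(peptides_per_protein, 2.0)) for _ in range(n_proteins)
    ])

    pep_df = pd.DataFrame({
        "protein": proteins,
        "peptide": sequences,
        "charge": charges,
        "precursor_mz": mzs,
        "pep_share": shares,
        "ref_rt_min": ref_rt,
    })

    frag_rows = []
    for (ions, fmzs), seq in zip(frag_ions, sequences):
        frac = rng.dirichlet(np.full(len(ions), 2.0))
        frag_rows.append(pd.DataFrame({"peptide": seq, "ion": ions,
                                       "fragment_mz": fmzs, "ion_frac": frac}))
    frag_df = pd.concat(frag_rows, ignore_index=True)
    frag_df = pep_df[["protein", "peptide"]].merge(frag_df, on="peptide")

    if shared_peptide_fraction > 0:
        n_shared = int(round(shared_peptide_fraction * n_pep))
        idx = rng.choice(n_pep, size=n_shared, replace=False)
        extra = pep_df.iloc[idx].copy()
        hosts = rng.integers(0, n_proteins, size=n_shared)
        extra["protein"] = [f"SYNP{h:05d}" for h in hosts]
        extra = extra[extra["protein"] != pep_df.iloc[idx]["protein"].values]
        pep_df = pd.concat([pep_df, extra], ignore_index=True)
        extra_frags = frag_df.drop(columns="protein").drop_duplicates(
            ["peptide", "ion"]).merge(extra[["protein", "peptide"]], on="peptide")
        extra_frags = extra_frags[frag_df.columns]
        frag_df = pd.concat([frag_df, extra_frags], ignore_index=True)

    return Proteome(peptides=pep_df, fragments=frag_df, gradient_min=gradient_min)


# ---------------------------------------------------------------------------
# Ground truth and noise
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """True per-protein abundances and effects plus the signal partitioning.

    ``proteins`` columns: protein, baseline, log2_effect (heat vs control,
    exactly 0 for null proteins), is_de. The proteome carries the
    per-peptide shares and per-transition ionization fractions.
    """

    proteins: pd.DataFrame
    proteome: Proteome
    de_fraction: float = 0.0


def generate_ground_truth(
    proteome: Proteome,
    de_fraction: float = 0.1,
    effect_log2: float = 1.0,
    down_fraction: float = 0.8,
    baseline_log10_range: tuple[float, float] = (4.0, 7.0),
    seed: int = 0,
) -> GroundTruth:
    """Assign log-uniform baselines and signed heat/control log2 effects.

    A ``de_fraction`` of proteins receive a +/- ``effect_log2`` effect, with
    ``down_fraction`` of those down-regulated (the heat-stress study found
    roughly four down-regulated proteins for every up-regulated one); null
    proteins have an effect of exactly zero.
    """
    if not 0 <= de_fraction <= 1:
        raise ValueError("de_fraction must be in [0, 1]")
    rng = stage_rng(seed, "truth")
    accs = proteome.accessions
    n = len(accs)
    lo, hi = baseline_log10_range
    baseline = 10.0 ** rng.uniform(lo, hi, size=n)
    n_de = int(round(de_fraction * n))
    effect = np.zeros(n)
    if n_de:
        de_idx = rng.choice(n, size=n_de, replace=False)
        signs = np.where(rng.random(n_de) < down_fraction, -1.0, 1.0)
        effect[de_idx] = signs * effect_log2
    df = pd.DataFrame({
        "protein": accs,
        "baseline": baseline,
        "log2_effect": effect,
        "is_de": effect != 0.0,
    })
    return GroundTruth(proteins=df, proteome=proteome, de_fraction=de_fraction)


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative noise and acquisition-imperfection model.

    ``animal_cv`` is the biological coefficient of variation applied per
    animal before pooling; ``tech_cv`` the lognormal CV applied per protein
    per injection (its 0.10 default keeps well over 85% of proteins under
    the 25% technical-CV gate, matching the reproducibility the reference
    study reports); ``mz_ppm_error`` the mass-error s.d. in ppm;
    ``rt_jitter`` the retention-time s.d. in minutes; ``missing_prob`` a
    per-transition per-run dropout probability.
    """

    animal_cv: float = 0.15
    tech_cv: float = 0.10
    mz_ppm_error: float = 5.0
    rt_jitter: float = 0.1
    missing_prob: float = 0.02

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"noise field {f.name} must be >= 0")

    @staticmethod
    def noiseless() -> "NoiseModel":
        return NoiseModel(0.0, 0.0, 0.0, 0.0, 0.0)


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    s = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(0.0, s, size) - s * s / 2.0)


@dataclass
class AbundanceRecord:
    """Every intermediate abundance of a simulated study.

    ``animals``: protein x animal matrix; ``pools``: protein x biological
    sample (equal-amount pooling = arithmetic mean of the pool's animals);
    ``runs``: protein x injection after technical noise.
    """

    animals: pd.DataFrame
    pools: pd.DataFrame
    runs: pd.DataFrame
    design: StudyDesign


def simulate_abundances(
    design: StudyDesign,
    truth: GroundTruth,
    noise: NoiseModel,
    seed: int | None = None,
) -> AbundanceRecord:
    """Draw animal, pool and per-injection protein abundances.

    Group mean = baseline x 2^log2_effect (heat) or baseline (control);
    animals get mean-preserving lognormal biological noise; pools are the
    arithmetic mean of their animals; each injection multiplies the pool
    value by lognormal technical noise.
    """
    seed = design.seed if seed is None else seed
    rng = stage_rng(seed, "abundance")
    prot = truth.proteins
    n = len(prot)
    base = prot["baseline"].to_numpy()
    eff = prot["log2_effect"].to_numpy()

    animal_cols, animal_vals = [], []
    pool_cols, pool_vals = [], []
    run_cols, run_vals = [], []
    for g in design.groups:
        gmean = base * (2.0 ** eff if g == design.groups[1] else 1.0)
        for b in range(design.bio_replicates):
            pool_members = []
            for a in range(design.pool_size):
                v = gmean * _lognormal_factor(rng, noise.animal_cv, n)
                animal_cols.append(f"{g}_b{b + 1}_a{a + 1}")
                animal_vals.append(v)
                pool_members.append(v)
            pool = np.mean(pool_members, axis=0)
            pool_cols.append(f"{g}_b{b + 1}")
            pool_vals.append(pool)
            for t in range(design.tech_replicates):
                run_cols.append(f"{g}_b{b + 1}_t{t + 1}")
                run_vals.append(pool * _lognormal_factor(rng, noise.tech_cv, n))

    idx = pd.Index(prot["protein"], name="protein")
    return AbundanceRecord(
        animals=pd.DataFrame(np.column_stack(animal_vals), index=idx, columns=animal_cols),
        pools=pd.DataFrame(np.column_stack(pool_vals), index=idx, columns=pool_cols),
        runs=pd.DataFrame(np.column_stack(run_vals), index=idx, columns=run_cols),
        design=design,
    )


# ---------------------------------------------------------------------------
# DIA run synthesis
# ---------------------------------------------------------------------------

@dataclass
class DiaRun:
    """One DIA injection: study labels plus the spectral map.

    ``scans`` columns: window_low, window_high, rt_min, mz, intensity —
    one row per (isolation window, cycle, fragment m/z) point.
    """

    run_id: str
    group: str
    bio_rep: int
    tech_rep: int
    scans: pd.DataFrame


@dataclass
class SimulatedStudy:
    """Bundle returned by :func:`simulate_study`."""

    library: pd.DataFrame
    runs: list[DiaRun]
    truth_record: AbundanceRecord
    truth: GroundTruth
    design: StudyDesign
    scheme: AcquisitionScheme


def synthetic_library(proteome: Proteome, score: float = 10.0) -> pd.DataFrame:
    """Ideal spectral library of the proteome, in the library TSV dialect
    (one row per transition; relative fragment intensity = ionization
    fraction)."""
    lib = proteome.fragments.merge(
        proteome.peptides, on=["protein", "peptide"], validate="many_to_one"
    )
    return pd.DataFrame({
        "protein_accession": lib["protein"],
        "peptide": lib["peptide"],
        "modified_peptide": lib["peptide"],
        "precursor_mz": lib["precursor_mz"],
        "charge": lib["charge"],
        "fragment_mz": lib["fragment_mz"],
        "fragment_rel_intensity": lib["ion_frac"],
        "ref_rt_min": lib["ref_rt_min"],
        "score": score,
        "q_value": 0.0,
        "is_decoy": False,
    })


def simulate_study(
    design: StudyDesign,
    truth: GroundTruth,
    noise: NoiseModel,
    scheme: AcquisitionScheme | None = None,
    seed: int | None = None,
    peak_sigma_min: float = 0.5,
    run_rt_shifts: Sequence[float] | None = None,
    peak_halfspan_sigmas: float = 3.0,
) -> SimulatedStudy:
    """Simulate the full 18-injection SWATH study.

    Per run, every library transition produces a Gaussian elution peak
    (s.d. ``peak_sigma_min``) centered at the peptide's reference RT plus
    any per-run shift and jitter, snapped to the instrument's cycle grid;
    the transition amplitude is protein abundance x peptide share x
    ionization fraction; recorded m/z carries a per-transition ppm error
    and transitions drop out independently with ``missing_prob``.
    """
    scheme = scheme or AcquisitionScheme.default_swath()
    if scheme.mode != "swath":
        raise ValueError("simulate_study requires a SWATH scheme")
    seed = design.seed if seed is None else seed
    proteome = truth.proteome
    record = simulate_abundances(design, truth, noise, seed=seed)

    lib = synthetic_library(proteome)
    pep = proteome.peptides
    win_idx = scheme.assign(pep["precursor_mz"].to_numpy())
    if (win_idx < 0).any():
        raise ValueError("proteome contains precursors outside the window scheme")
    lows = np.array([w[0] for w in scheme.windows])
    highs = np.array([w[1] for w in scheme.windows])

    # transition-level static arrays
    trans = proteome.fragments.merge(
        pep.assign(win=win_idx), on=["protein", "peptide"], validate="many_to_one"
    )
    t_amp_frac = (trans["pep_share"] * trans["ion_frac"]).to_numpy()
    t_prot = trans["protein"].to_numpy()
    t_fmz = trans["fragment_mz"].to_numpy()
    t_win = trans["win"].to_numpy()
    t_rt = trans["ref_rt_min"].to_numpy()

    dt = cycle_time(scheme) / 60.0  # minutes per cycle
    k_half = int(np.floor(peak_halfspan_sigmas * peak_sigma_min / dt))
    offsets = np.arange(-k_half, k_half + 1) * dt
    shape = np.exp(-(offsets ** 2) / (2.0 * peak_sigma_min ** 2))

    run_tbl = design.run_table()
    shifts = np.zeros(len(run_tbl)) if run_rt_shifts is None else np.asarray(run_rt_shifts, float)
    if len(shifts) != len(run_tbl):
        raise ValueError("run_rt_shifts must have one entry per run")

    prot_index = {p: i for i, p in enumerate(record.runs.index)}
    prot_rows = np.array([prot_index[p] for p in t_prot])
    run_values = record.runs.to_numpy()

    runs: list[DiaRun] = []
    n_t = len(trans)
    pep_key = trans.groupby(["peptide", "charge"], sort=False).ngroup().to_numpy()
    n_pep_groups = pep_key.max() + 1
    for r, row in run_tbl.iterrows():
        rng = stage_rng(seed, f"dia:{row.run_id}")
        # per-peptide RT jitter, shared by that peptide's transitions
        pep_jit = rng.normal(0.0, noise.rt_jitter, n_pep_groups) if noise.rt_jitter else np.zeros(n_pep_groups)
        rt_obs = t_rt + shifts[r] + pep_jit[pep_key]
        rt_obs = np.round(rt_obs / dt) * dt  # snap to cycle grid
        mz_obs = t_fmz * (1.0 + rng.normal(0.0, noise.mz_ppm_error, n_t) * 1e-6) \
            if noise.mz_ppm_error else t_fmz.copy()
        keep = rng.random(n_t) >= noise.missing_prob if noise.missing_prob else np.ones(n_t, bool)
        amp = run_values[prot_rows, r] * t_amp_frac

        kp = np.flatnonzero(keep)
        times = rt_obs[kp, None] + offsets[None, :]
        inten = amp[kp, None] * shape[None, :]
        ok = (times >= 0.0) & (times <= proteome.gradient_min)
        scans = pd.DataFrame({
            "window_low": np.repeat(lows[t_win[kp]], ok.sum(axis=1)),
            "window_high": np.repeat(highs[t_win[kp]], ok.sum(axis=1)),
            "rt_min": times[ok],
            "mz": np.repeat(mz_obs[kp], ok.sum(axis=1)),
            "intensity": inten[ok],
        })
        runs.append(DiaRun(row.run_id, row.group, int(row.bio_rep), int(row.tech_rep), scans))

    return SimulatedStudy(library=lib, runs=runs, truth_record=record,
                          truth=truth, design=design, scheme=scheme)


# ---------------------------------------------------------------------------
# IDA identification tables
# ---------------------------------------------------------------------------

def simulate_ida_identifications(
    proteome: Proteome,
    mass_ranges: Iterable[tuple[float, float]] = DEFAULT_IDA_RANGES,
    seed: int = 0,
    target_score: tuple[float, float] = (4.0, 1.0),
    decoy_score: tuple[float, float] = (0.0, 1.0),
    false_target_fraction: float = 0.0,
    rt_jitter: float = 0.1,
) -> pd.DataFrame:
    """Simulate database-search identification tables from IDA runs.

    One run per survey mass range; a peptide is observable in a run only if
    its precursor m/z lies in that run's range. Target and reversed-decoy
    scores come from a two-component Gaussian model; an optional
    ``false_target_fraction`` of target peptides scores like a decoy and is
    flagged in the hidden ``is_false`` column for calibration checks.
    """
    ranges = [tuple(r) for r in mass_ranges]
    if not ranges or any(hi <= lo for lo, hi in ranges):
        raise ValueError("each mass range must satisfy low < high")
    rng = stage_rng(seed, "ida")
    pep = proteome.peptides.drop_duplicates("peptide")
    n = len(pep)
    is_false = rng.random(n) < false_target_fraction

    frames = []
    for i, (lo, hi) in enumerate(ranges):
        run_id = f"ida_{i + 1}"
        obs = (pep["precursor_mz"].to_numpy() >= lo) & (pep["precursor_mz"].to_numpy() < hi)
        sub = pep.loc[obs]
        sub_false = is_false[obs]
        tmu, tsd = target_score
        dmu, dsd = decoy_score
        t_scores = np.where(
            sub_false,
            rng.normal(dmu, dsd, len(sub)),
            rng.normal(tmu, tsd, len(sub)),
        )
        d_scores = rng.normal(dmu, dsd, len(sub))
        rt = sub["ref_rt_min"].to_numpy() + rng.normal(0.0, rt_jitter, len(sub))
        target = pd.DataFrame({
            "run_id": run_id,
            "protein": sub["protein"].to_numpy(),
            "peptide": sub["peptide"].to_numpy(),
            "modified_peptide": sub["peptide"].to_numpy(),
            "precursor_mz": sub["precursor_mz"].to_numpy(),
            "charge": sub["charge"].to_numpy(),
            "rt_min": rt,
            "score": t_scores,
            "is_decoy": False,
            "is_false": sub_false,
        })
        decoy = target.copy()
        decoy["protein"] = "DECOY_" + decoy["protein"]
        decoy["peptide"] = [reverse_decoy(s) for s in decoy["peptide"]]
        decoy["modified_peptide"] = decoy["peptide"]
        decoy["score"] = d_scores
        decoy["is_decoy"] = True
        decoy["is_false"] = False
        frames.extend([target, decoy])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# MRM traces
# ---------------------------------------------------------------------------

def simulate_mrm_traces(
    assays: pd.DataFrame,
    design: StudyDesign,
    truth: GroundTruth,
    noise: NoiseModel,
    seed: int = 0,
    pools: pd.DataFrame | None = None,
    dwell_s: float = 2.0,
    peak_sigma_min: float = 0.5,
) -> pd.DataFrame:
    """Simulate scheduled-MRM chromatograms for designed assays.

    Re-injects the study's biological samples (pass ``pools`` from the SWATH
    study's truth record to reuse them; otherwise fresh biological draws are
    made) with fresh technical noise. Output columns: run_id, q1, q3,
    rt_min, intensity.
    """
    rng = stage_rng(seed, "mrm")
    if pools is None:
        pools = simulate_abundances(design, truth, noise, seed=seed + 1).pools
    prot = truth.proteins.set_index("protein")
    shares = truth.proteome.peptides.set_index("peptide")["pep_share"]

    a = assays.merge(
        truth.proteome.fragments[["peptide", "fragment_mz", "ion_frac"]],
        left_on=["peptide", "q3"], right_on=["peptide", "fragment_mz"], how="left",
    )
    if a["ion_frac"].isna().any():
        missing = a.loc[a["ion_frac"].isna(), "peptide"].unique()
        raise ValueError(f"assay transitions not in ground truth for peptides: {missing[:5]}")
    frac = (a["peptide"].map(shares) * a["ion_frac"]).to_numpy()
    dt = dwell_s / 60.0

    frames = []
    for g in design.groups:
        for b in range(design.bio_replicates):
            pool = pools[f"{g}_b{b + 1}"]
            for t in range(design.tech_replicates):
                run_id = f"mrm_{g}_b{b + 1}_t{t + 1}"
                r = stage_rng(seed, f"mrmrun:{run_id}")
                tech = pool * _lognormal_factor(r, noise.tech_cv, len(pool))
                amp = tech.reindex(a["protein"]).to_numpy() * frac
                for i, row in enumerate(a.itertuples()):
                    center = row.rt_center + (r.normal(0.0, noise.rt_jitter) if noise.rt_jitter else 0.0)
                    center = np.round(center / dt) * dt
                    lo = row.rt_center - row.rt_halfwidth
                    hi = row.rt_center + row.rt_halfwidth
                    times = np.arange(np.ceil(lo / dt), np.floor(hi / dt) + 1) * dt
                    inten = amp[i] * np.exp(-((times - center) ** 2) / (2 * peak_sigma_min ** 2))
                    frames.append(pd.DataFrame({
                        "run_id": run_id, "q1": row.q1, "q3": row.q3,
                        "rt_min": times, "intensity": inten,
                    }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Fixture IO (plain TSV)
# ---------------------------------------------------------------------------

def write_scan_table(runs: Iterable[DiaRun], path) -> None:
    """Write DIA runs as one long TSV scan table (run_id + scan columns)."""
    frames = [r.scans.assign(run_id=r.run_id)[
        ["run_id", "window_low", "window_high", "rt_min", "mz", "intensity"]
    ] for r in runs]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_scan_table(path, run_table: pd.DataFrame | None = None) -> list[DiaRun]:
    """Read a long TSV scan table back into DiaRun objects.

    Run annotations are parsed from run ids of the form group_bN_tM unless
    an explicit run table is given.
    """
    df = pd.read_csv(path, sep="\t")
    runs = []
    for run_id, scans in df.groupby("run_id", sort=False):
        if run_table is not None:
            meta = run_table.set_index("run_id").loc[run_id]
            group, bio, tech = meta["group"], int(meta["bio_rep"]), int(meta["tech_rep"])
        else:
            group, b, t = run_id.rsplit("_", 2)
            bio, tech = int(b[1:]), int(t[1:])
        runs.append(DiaRun(run_id, group, bio, tech,
                           scans.drop(columns="run_id").reset_index(drop=True)))
    return runs


def write_ground_truth(truth: GroundTruth, path) -> None:
    truth.proteins.to_csv(path, sep="\t", index=False)


def read_ground_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
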