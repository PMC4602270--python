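# Methods

`swathlite` implements a library-driven SWATH/DIA label-free quantification
workflow — spectral-library construction under target-decoy FDR control,
targeted chromatogram extraction with summation roll-up, a replicate-CV
quality cascade, fold-change/t-test differential calling, and scheduled-MRM
cross-validation — together with a synthetic-study generator that produces
all of its inputs with known ground truth. This note records the models,
the defaults and why they were chosen, and what the synthetic data do and
do not establish about behaviour on real measurements.

## Study design emulated by the generator

The simulator reproduces a two-group, pooled-replicate animal study:

* two groups (control at 26 °C, heat-stressed at 32 °C), 9 animals per
  group;
* animals pooled 3-at-a-time in equal amounts into 3 biological
  replicates per group — pooling is the arithmetic mean of the pooled
  animals' abundances, since equal-mass mixing of equal-concentration
  lysates averages abundance;
* 3 technical injections per biological replicate, giving 18 DIA runs;
* DIA acquisition over sequential precursor isolation windows covering
  m/z 350–1,250 (60 equal-width windows by default; the window list is
  fully configurable, including variable widths and overlaps);
* IDA (data-dependent) acquisition for library building in three survey
  mass ranges — m/z 350–750, 745–1,250 and 350–1,250 — with a 0.25 s
  survey scan, top-40 precursor selection at 0.05 s per MS/MS event
  (2.25 s duty cycle), a 150 cps precursor intensity floor and charges
  +2 to +4.

### Abundance model

Each protein has a log-uniform baseline abundance (default span
10⁴–10⁷ counts). A configurable fraction of proteins (default 10%)
carries a heat-vs-control effect of ±1 log2 unit, 80% of them
down-regulated (heat-stress liver studies find down-regulation dominating
roughly four to one); null proteins have an effect of exactly zero, so
ground-truth false-positive accounting is unambiguous.

Noise enters multiplicatively and mean-preservingly
(`exp(N(0, s) − s²/2)` with `s² = ln(1+CV²)`):

| parameter | default | role |
|---|---|---|
| `animal_cv` | 0.15 | biological variation per animal, applied **before** pooling so pooling demonstrably reduces variance |
| `tech_cv` | 0.10 | per-protein, per-injection technical noise; at this level ≳97% of null proteins pass the 25% technical-CV gate, the scale of reproducibility the workflow is designed around |
| `mz_ppm_error` | 5 ppm | per-transition recorded-mass error s.d. |
| `rt_jitter` | 0.1 min | per-peptide, per-run retention-time jitter |
| `missing_prob` | 0.02 | per-transition, per-run dropout |

### Signal model

Transition-level signal is `protein abundance × peptide share ×
ionization fraction`; peptide shares are Dirichlet-distributed within a
protein and sum to one, ionization fractions sum to one within a
peptide. Summation roll-up over all retained transitions therefore
reconstructs the protein abundance exactly, which is what makes the
noiseless oracle-equivalence test exact rather than approximate.

Elution peaks are Gaussian with configurable s.d. (default 0.5 min; the
shape of real peaks is not modelled beyond this). Peak centers are
snapped to the instrument's cycle-time grid — a physically faithful
quantization, and the reason a fitted RT alignment on jitter-free data is
identity only to within one cycle (~0.06 min), not to machine precision.

Fragments are y-ions selected per peptide against a per-window occupancy
list so that co-isolated fragments stay ≥150 ppm apart. Extraction at
50 ppm is therefore interference-free *by construction*. This is a
deliberate idealization: real DIA data contain chimeric windows, and
neither interference removal nor peak-group scoring is in scope. Passing
the oracle tests shows the extraction/roll-up arithmetic is exact, not
that the pipeline is robust to interference.

Other idealizations: no isotope envelopes, no charge-state coelution, no
intensity-dependent (shot) noise, dropout independent of abundance.
Consequently the synthetic CV cascade behaves homogeneously across the
abundance range, whereas real low-abundance proteins fail CV gates more
often.

## Library construction

The three IDA identification tables are concatenated (provenance kept)
and reduced to per-peptide evidence: best score, score-weighted mean
retention time across runs. Decoys are reversed sequences keeping the
C-terminal residue — the standard tryptic decoy construction. The FDR
estimate at score threshold *s* is `#decoys ≥ s / #targets ≥ s`, with
target/decoy score ties counted decoy-first (conservative); the q-value
is the minimum estimate over admitting thresholds. FDR is controlled at
the **peptide** level; ">99% peptide confidence" is operationalized as
q ≤ 0.01, the standard open equivalent of a vendor confidence score.
Protein-level FDR is not separately controlled.

The library keeps confident peptides only, excludes peptides mapping to
more than one protein, stores at most six fragments per peptide ranked by
relative intensity, and is idempotent under rebuilding: a rebuild from an
already-filtered (decoy-free) library keeps the recorded q-values, since
the decoy evidence needed to re-estimate them no longer exists.

## Targeted extraction and roll-up

* **Window assignment** — half-open `[low, high)` intervals; a boundary
  m/z belongs to the upper window; overlapping windows are resolved to
  the nearest window center; out-of-range precursors are reported as
  unscheduled, never raised.
* **XIC** — all points in the assigned window within 50 ppm of the
  fragment m/z, summed per cycle, over a 20-minute full-width RT window
  (half-width 10 min) centered on the aligned library RT. The 20 minutes
  are read as full width; a half-width reading would be configured as
  `rt_halfwidth=20`.
* **RT alignment** — ordinary least squares of observed anchor apexes
  against library RT (anchors: high-confidence library peptides spread
  over the gradient). Falls back to identity, with a warning, below two
  usable anchors or when the residual s.d. exceeds a gate (default
  1.5 min). Linear is the simplest monotone model and exact for the
  simulator's constant shifts.
* **Peak integration** — baseline is a quantile of the XIC (default the
  5th percentile); the integrated region is the largest contiguous
  stretch at or above baseline containing the maximum; the area is the
  trapezoid over that region; traces with <3 points or no positive
  signal are missing. The algorithm is this package's own definition —
  vendor integrators are proprietary — and is deliberately simple and
  configurable.
* **Normalization** — default is total-area scaling (each run scaled so
  its summed transition area equals the across-run median), the common
  default of targeted-extraction software; a median-ratio alternative is
  selectable. Note that with asymmetric regulation (mostly-down effects)
  total-area scaling transfers a small group-level bias into fold
  changes; this is a property of the method, not a defect of the
  implementation, and is one reason the statistical acceptance checks
  run on abundance matrices where no normalization applies.
* **Roll-up** — summation: the six most intense library fragments per
  peptide, the six library-strongest peptides (by summed fragment
  intensity — the library's only intensity information) per protein.
  A peptide or protein is missing in a run only when all of its retained
  constituents are missing; missing is always NaN, never silent zero.

## Quality cascade

CV is the sample (n−1) standard deviation over the mean, undefined for
fewer than two values or a non-positive mean. Stages:

1. **Technical** — per biological sample, CV over its 3 injections must
   be ≤ 0.25; the biological-sample value is the mean of its technical
   replicates.
2. **Completeness** — a non-missing biological value in all 6 biological
   samples (`all_bio`, default) or in all 18 injections (`all_runs`,
   selectable; the stricter reading).
3. **Biological** — per group, CV over the 3 biological values ≤ 0.25.
   The final quantified set is the **union** of the two groups' pass
   sets: a final count can exceed both per-group counts only under a
   union, which is what reference workflows of this design report.

Pairwise replicate agreement is squared Pearson correlation on log10
intensities (raw-scale selectable), over proteins present in both
replicates; pass sets are nested by construction (final ⊆ complete ⊆
quantified).

## Differential expression

Group means of biological values give the fold change; the signed
convention reports ratios ≥1 as positive and ratios <1 as the negative
reciprocal. The fold-change cutoff comes from a maximum-likelihood
normal fit to the log2 ratios of all quantified proteins:
`cutoff = 2^σ` rounded **down** to one decimal, pairing σ = 0.4 with
cutoff 1.3. (A 1.96σ two-sided 95% construction would give ≈1.72 for the
same σ; the implemented rule is the one that reproduces the 0.4 ↔ 1.3
pairing, and the discrepancy between the two constructions is noted here
rather than resolved.) An override pins the cutoff.

Significance is a two-sided Student's t-test on log2 biological values
(pooled variance; Welch selectable) — the log scale matches the
normality assumption implicit in fitting a normal to log2 ratios.
Classification uses strict inequalities (p < 0.01, |signed FC| > cutoff)
and **no multiple-testing correction**, matching the thresholds this
workflow historically uses; Benjamini–Hochberg is available but off by
default, and the realized FDR of the called set under the default
simulation (10% spiked effects) is verified to stay ≤10% in the test
suite. Degenerate zero-variance tests return p = 1 (equal means) or
p = 0 with a warning (unequal means).

## MRM validation

Assays take the five most intense library fragments per peptide as Q1/Q3
pairs. Collision energy and declustering potential are linear in
precursor m/z with per-charge configurable coefficients (defaults
CE = 0.044·m/z + 5.5, DP = 0.0729·m/z + 31.7, widely used
triple-quadrupole values); scheduling windows default to ±2.5 min around
the library RT. MRM traces are integrated by the same integrator as the
DIA path and rolled up by summation (consistent with the SWATH roll-up;
averaging would only change a per-protein constant). Concordance is the
fraction of targets with the same fold-change direction on both
platforms plus the Spearman rank correlation of signed fold changes,
computed only over proteins quantified by both.

## Determinism and problem sizes

A single seed drives every stochastic stage through stage-name-hashed
substreams (`np.random.default_rng([seed, crc32(stage)])`), so reruns
are byte-identical and stages can be re-executed in isolation. The
default desk-scale study is 500 proteins × 5 peptides — a deliberate
stand-in for a multi-thousand-protein tissue proteome that keeps a full
end-to-end run (simulation, extraction of ~13,000 transitions × 18 runs,
QC, differential calling, MRM) in the minutes range. The statistical
checks (type-I error, effect recovery, cascade properties) run on the
abundance layer directly, which is the model they concern; the full
extraction layer is exercised by the noiseless oracle-equivalence and
cross-platform concordance checks.

## Known limitations

* No peak-group scoring against library fragment patterns and no
  interference handling; the generator avoids interference by design.
* Identification is simulated (two-component score model + reversed
  decoys); no spectrum-to-peptide search is performed.
* The q-value/confidence equivalence is peptide-level only.
* Total-area normalization assumes most of the signal is unregulated.
* mzML support covers MS2 spectra with isolation windows and
  uncompressed or zlib 32/64-bit float arrays — the subset the package
  writes and standard DIA exports use.
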