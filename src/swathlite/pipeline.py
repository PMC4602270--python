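"""End-to-end orchestration of the SWATH quantification workflow.

Runs simulate -> build-library -> quantify -> qc -> diff -> mrm with a
single seed governing all stochastic stages through stage-name-hashed
substreams, writes every stage table as TSV, and produces a run summary
(library sizes, per-stage pass counts and percentages, differential
counts, cross-platform agreement). Every number in the summary is
recomputable from the stage output files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import diaquant, diffexpr, mrmcheck, qcfilter, simdata, speclib

logger = logging.getLogger("swathlite")


@dataclass
class PipelineConfig:
    """Flat key-value configuration of the pipeline.

    Unknown keys are rejected on load; the resolved copy (defaults filled
    in) is written alongside the outputs for provenance.
    """

    out_dir: str = "swathlite_out"
    seed: int = 0

    # study design / simulation
    n_proteins: int = 500
    peptides_per_protein: int = 5
    de_fraction: float = 0.1
    effect_log2: float = 1.0
    down_fraction: float = 0.8
    animal_cv: float = 0.15
    tech_cv: float = 0.10
    mz_ppm_error: float = 5.0
    rt_jitter: float = 0.1
    missing_prob: float = 0.02

    # acquisition
    n_windows: int = 60
    mz_low: float = 350.0
    mz_high: float = 1250.0

    # library
    fdr: float = 0.01
    max_fragments: int = 6
    false_target_fraction: float = 0.02

    # extraction
    ppm: float = 50.0
    rt_window: float = 20.0        # full width, minutes
    align: bool = True

    # qc
    max_cv: float = 0.25
    completeness_mode: str = "all_bio"

    # differential expression
    alpha: float = 0.01
    cutoff: str | float = "auto"

    # mrm
    n_mrm_targets: int = 26
    mrm_transitions: int = 5

    # stage toggles / output detail
    enable_qc: bool = True
    enable_mrm: bool = True
    write_runs: bool = False

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**raw)

    def resolved(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    """In-memory handles to every stage output of one pipeline run."""

    config: PipelineConfig
    library: speclib.SpectralLibrary
    study: simdata.SimulatedStudy
    protein_quant: diaquant.QuantTable
    qc: qcfilter.QcResult | None
    diff: diffexpr.DiffResult
    concordance: mrmcheck.ConcordanceReport | None
    summary: pd.DataFrame


def _stage(name: str):
    logger.info("stage: %s", name)


def run_pipeline(config: PipelineConfig, out_dir=None) -> PipelineResult:
    """Execute the configured stages and write the output bundle.

    A stage failure aborts the run with the stage name attached to the
    exception. Rerunning with the same config and seed reproduces the
    outputs byte for byte.
    """
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "resolved_config.yaml").write_text(
        yaml.safe_dump(config.resolved(), sort_keys=True))
    seed = config.seed

    stage = "simulate"
    try:
        design = simdata.StudyDesign(seed=seed)
        scheme = simdata.AcquisitionScheme.default_swath(
            (config.mz_low, config.mz_high), config.n_windows)
        _stage(stage)
        proteome = simdata.generate_proteome(
            config.n_proteins, config.peptides_per_protein, seed=seed, scheme=scheme)
        truth = simdata.generate_ground_truth(
            proteome, de_fraction=config.de_fraction, effect_log2=config.effect_log2,
            down_fraction=config.down_fraction, seed=seed)
        noise = simdata.NoiseModel(
            animal_cv=config.animal_cv, tech_cv=config.tech_cv,
            mz_ppm_error=config.mz_ppm_error, rt_jitter=config.rt_jitter,
            missing_prob=config.missing_prob)
        study = simdata.simulate_study(design, truth, noise, scheme, seed=seed)
        simdata.write_ground_truth(truth, out / "ground_truth.tsv")
        if config.write_runs:
            simdata.write_scan_table(study.runs, out / "dia_scans.tsv")

        stage = "build-library"
        _stage(stage)
        ids = simdata.simulate_ida_identifications(
            proteome, seed=seed, false_target_fraction=config.false_target_fraction)
        merged = speclib.merge_ida_runs(
            [g for _, g in ids.groupby("run_id", sort=False)])
        library = speclib.build_library(
            merged, fragments=proteome.fragments,
            max_fragments=config.max_fragments, min_confidence=1.0 - config.fdr)
        speclib.write_library(library, out / "library.tsv")

        stage = "quantify"
        _stage(stage)
        tquant = diaquant.quantify_study(
            library, study.runs, scheme, tol_ppm=config.ppm,
            rt_halfwidth=config.rt_window / 2.0, align=config.align)
        tquant, factors = diaquant.normalize(tquant)
        pep_quant, prot_quant = diaquant.rollup(tquant, library)
        for q, name in ((tquant, "transition"), (pep_quant, "peptide"),
                        (prot_quant, "protein")):
            diaquant.write_quant_table(q, out / f"quant_{name}.tsv")

        stage = "qc"
        if config.enable_qc:
            _stage(stage)
            qc = qcfilter.run_qc(prot_quant, design, max_cv=config.max_cv,
                                 completeness_mode=config.completeness_mode)
            qcfilter.write_qc_report(qc, out / "qc_report.tsv")
            qc.summary().to_csv(out / "qc_summary.tsv", sep="\t", index=False)
            bio_values = qc.technical.bio_values.loc[qc.final_proteins]
        else:
            logger.info("CV cascade skipped (qc disabled); differential stage "
                        "receives the completeness set")
            qc = None
            tech = qcfilter.technical_stage(prot_quant, design, max_cv=config.max_cv)
            complete = qcfilter.completeness_stage(
                tech.bio_values, design, mode=config.completeness_mode,
                run_data=prot_quant.data)
            bio_values = tech.bio_values.loc[complete]

        stage = "diff"
        _stage(stage)
        diff = diffexpr.differential_expression(
            bio_values, design, alpha=config.alpha, cutoff=config.cutoff)
        diffexpr.write_diff_table(diff, out / "diff_table.tsv")
        volcano, heatmap = diffexpr.export_views(diff, bio_values)
        volcano.to_csv(out / "volcano.tsv", sep="\t", index_label="protein")
        heatmap.to_csv(out / "heatmap.tsv", sep="\t", index_label="protein")

        stage = "mrm"
        conc = None
        if config.enable_mrm:
            _stage(stage)
            de = diff.table[diff.table["class"] != "ns"]
            ranked = de.reindex(de["signed_fc"].abs()
                                .sort_values(ascending=False).index)
            targets = list(ranked.index[:config.n_mrm_targets])
            if len(targets) < config.n_mrm_targets:
                extra = (diff.table.drop(index=targets)["signed_fc"].abs()
                         .sort_values(ascending=False)
                         .index[:config.n_mrm_targets - len(targets)])
                targets += list(extra)
            assay_set = mrmcheck.design_assays(
                library, targets, n_transitions=config.mrm_transitions)
            mrmcheck.write_assays(assay_set, out / "mrm_assays.tsv")
            traces = simdata.simulate_mrm_traces(
                assay_set.assays, design, truth, noise, seed=seed,
                pools=study.truth_record.pools)
            mrm_quant = mrmcheck.quantify_mrm(traces, assay_set.assays, design)
            mrm_tech = qcfilter.technical_stage(mrm_quant, design, max_cv=config.max_cv)
            mrm_fc = diffexpr.group_fold_change(mrm_tech.bio_values, design)
            conc = mrmcheck.concordance(diff.table, mrm_fc, targets)
            conc.table.to_csv(out / "concordance.tsv", sep="\t",
                              index_label="protein")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary = _summary(library, prot_quant, qc, diff, conc)
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    (out / "summary.json").write_text(json.dumps(
        dict(zip(summary["metric"], summary["value"])), indent=2, default=str) + "\n")
    return PipelineResult(config=config, library=library, study=study,
                          protein_quant=prot_quant, qc=qc, diff=diff,
                          concordance=conc, summary=summary)


def _summary(library, prot_quant, qc, diff, conc) -> pd.DataFrame:
    rows = [
        ("library_proteins", library.n_proteins),
        ("library_peptides", library.n_peptides),
        ("quantified_proteins", int(prot_quant.data.notna().any(axis=1).sum())),
    ]
    if qc is not None:
        rows.append(("complete_proteins", len(qc.complete_proteins)))
        for sid, pct in qc.technical.percent_passed.items():
            rows.append((f"technical_cv_pass_pct_{sid}", round(float(pct), 1)))
        for g, pct in qc.biological.percent_passed.items():
            rows.append((f"biological_cv_pass_pct_{g}", round(float(pct), 1)))
        for g, r2 in qc.min_r2.items():
            rows.append((f"min_r2_{g}", round(float(r2), 4)))
        rows.append(("final_quantified_proteins", len(qc.final_proteins)))
    c = diff.counts
    rows += [
        ("fc_cutoff_sigma_log2", round(diff.cutoff.sigma, 4)),
        ("fc_cutoff_linear", diff.cutoff.linear_cutoff),
        ("differential_total", c["total"]),
        ("differential_up", c["up"]),
        ("differential_down", c["down"]),
    ]
    if conc is not None:
        rows += [
            ("mrm_targets", len(conc.table)),
            ("mrm_direction_agreement", round(conc.agreement, 4)),
            ("mrm_spearman_rho", round(conc.spearman_rho, 4)),
        ]
    return pd.DataFrame(rows, columns=["metric", "value"])
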