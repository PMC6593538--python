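"""End-to-end orchestration: pool -> truth -> agreement -> Bland-Altman -> MRMC.

``run_pipeline`` executes every analysis stage in order on a marks table
plus an adjudication table, writes the stage CSVs, and renders a markdown
report mirroring the layout of the modeled study's printed tables: a count
table with integer-percent shares of the pool, pairwise kappa tables with
Landis-Koch categories, Bland-Altman summaries per scanner, and the
reader-averaged accuracy table with Holm significance flags.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import agreement, blandaltman, io, mrmc, pooling
from .errors import MFStudyError
from .model import MarkMatrix, StudyDesign, TruthSet

logger = logging.getLogger("mfstudy")


@dataclass
class PipelineConfig:
    marks_path: str
    adjudication_path: str | None
    design_path: str | None
    out_dir: str
    pooling: pooling.PoolingConfig = field(default_factory=pooling.PoolingConfig)
    consensus_threshold: int = 4
    reference_modality: str | None = None  # default: the design's reference
    alpha: float = 0.05
    auto_wins: bool = False
    make_plots: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise MFStudyError("alpha must be in (0, 1)")


@dataclass
class PipelineResult:
    design: StudyDesign
    matrix: MarkMatrix
    truth: TruthSet
    multiplicity: pooling.MultiplicityHistogram
    auto_true: set[str]
    counts: blandaltman.CountTable
    ba_results: list[blandaltman.BAResult]
    inter_kappa: pd.DataFrame
    intra_kappa: pd.DataFrame
    mrmc_result: mrmc.MRMCResult
    aucs: mrmc.AUCMatrix
    warnings_log: list[str]
    report_path: Path


def _stage(name: str):
    """Wrap a stage so failures carry the stage name."""

    def deco(fn):
        def run(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except MFStudyError as exc:
                raise MFStudyError(f"[stage {name}] {exc}") from exc

        return run

    return deco


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    caught: list[str] = []

    design = io.read_design(config.design_path) if config.design_path else None
    marks = _stage("read-marks")(io.read_marks)(config.marks_path, design)
    logger.info("read %d marks", len(marks))

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")

        candidates, matrix = _stage("pool")(pooling.pool_marks)(
            marks, config.pooling, design
        )
        if design is None:
            design = StudyDesign(
                readers=matrix.readers,
                modalities=matrix.modalities,
                reference_modality=config.reference_modality or matrix.modalities[-1],
                slides=list(dict.fromkeys(matrix.candidate_slides)),
                rois=[],
            )
        reference = config.reference_modality or design.reference_modality
        logger.info("pooled %d candidates", len(candidates))
        io.write_candidates(candidates, out / "candidates.csv")

        hist = _stage("truth")(pooling.reference_multiplicity)(matrix, design)
        auto = _stage("truth")(pooling.auto_consensus_truth)(
            matrix, design, config.consensus_threshold
        )
        panel = (
            io.read_adjudication(config.adjudication_path)
            if config.adjudication_path
            else {}
        )
        truth = _stage("truth")(pooling.merge_adjudication)(
            auto, panel, candidates, auto_wins=config.auto_wins
        )
        io.write_truth(truth, out / "truth.csv")
        logger.info(
            "truth: %d auto-consensus, %d true of %d candidates",
            len(auto),
            truth.n_true,
            len(candidates),
        )

        inter = pd.concat(
            [agreement.inter_observer_matrix(matrix, m) for m in matrix.modalities],
            ignore_index=True,
        )
        intra = pd.concat(
            [agreement.intra_observer_matrix(matrix, r) for r in matrix.readers],
            ignore_index=True,
        )
        io.write_table(inter, out / "kappa_inter.csv")
        io.write_table(intra, out / "kappa_intra.csv")

        counts = _stage("blandaltman")(blandaltman.per_slide_counts)(matrix, design)
        io.write_table(counts, out / "counts.csv")
        ba_results = []
        for m in matrix.modalities:
            if m == reference:
                continue
            diffs = blandaltman.log_count_differences(counts, m, reference)
            res = _stage("blandaltman")(blandaltman.ba_summary)(diffs)
            ba_results.append(res)
            if config.make_plots:
                blandaltman.plot_bland_altman(diffs, res, out / f"blandaltman_{m}.png")
        if ba_results:
            io.write_table(
                pd.concat([r.to_frame() for r in ba_results], ignore_index=True),
                out / "blandaltman.csv",
            )

        aucs = _stage("mrmc")(mrmc.auc_matrix)(matrix, truth)
        cov = _stage("mrmc")(mrmc.jackknife_cov)(matrix, truth)
        result = _stage("mrmc")(mrmc.reader_averaged_analysis)(
            aucs, cov, reference, config.alpha
        )
        io.write_table(result, out / "mrmc.csv")

        caught.extend(str(w.message) for w in wlist)
    for msg in caught:
        logger.warning("%s", msg)

    report_path = out / "report.md"
    report_path.write_text(
        render_report(design, matrix, hist, auto, truth, counts, inter, intra, ba_results, aucs, result),
        encoding="utf-8",
    )
    return PipelineResult(
        design=design,
        matrix=matrix,
        truth=truth,
        multiplicity=hist,
        auto_true=auto,
        counts=counts,
        ba_results=ba_results,
        inter_kappa=inter,
        intra_kappa=intra,
        mrmc_result=result,
        aucs=aucs,
        warnings_log=caught,
        report_path=report_path,
    )


def _md_table(header: list[str], rows: list[list[str]]) -> str:
    lines = ["| " + " | ".join(header) + " |", "|" + "---|" * len(header)]
    lines += ["| " + " | ".join(str(c) for c in row) + " |" for row in rows]
    return "\n".join(lines)


def render_report(
    design: StudyDesign,
    matrix: MarkMatrix,
    hist: pooling.MultiplicityHistogram,
    auto: set[str],
    truth: TruthSet,
    counts: blandaltman.CountTable,
    inter: pd.DataFrame,
    intra: pd.DataFrame,
    ba_results: list[blandaltman.BAResult],
    aucs: mrmc.AUCMatrix,
    result: mrmc.MRMCResult,
) -> str:
    pool = matrix.n_candidates
    parts = ["# Mitotic-figure reader study report", ""]

    parts += ["## Candidate pool and ground truth", ""]
    parts.append(
        f"Pooled candidates: **{pool}** across {len(design.slides)} slides. "
        f"Reference modality: **{result.reference}**."
    )
    mult = ", ".join(
        f"{int(c)} by {k} reader(s)"
        for k, c in enumerate(hist.counts_by_multiplicity)
        if k >= 1 and c > 0
    )
    parts.append(
        f"\nReference-modality multiplicity: {mult}; "
        f"{hist.n_reference_only_missed} candidates seen only off-reference."
    )
    parts.append(
        f"\nAuto-consensus (threshold rule on the reference modality): "
        f"**{len(auto)}** candidates; final adjudicated truth: **{truth.n_true}** "
        f"true and {truth.n_false} false mitotic figures."
    )

    parts += ["", "## Candidate counts per reader and modality", ""]
    rows = []
    for i, r in enumerate(counts.readers):
        row = [r]
        for m in counts.modalities:
            total = int(counts.per_reader_totals(m)[i])
            row.append(io.fmt_count_share(total, pool))
        rows.append(row)
    parts.append(_md_table(["Reader"] + list(counts.modalities), rows))

    parts += ["", "## Inter-observer agreement (kappa per reader pair)", ""]
    pairs = list(dict.fromkeys(zip(inter["reader_a"], inter["reader_b"])))
    rows = []
    for ra, rb in pairs:
        sub = inter[(inter["reader_a"] == ra) & (inter["reader_b"] == rb)]
        by_mod = dict(zip(sub["modality"], sub["kappa"]))
        rows.append([f"{ra} vs {rb}"] + [io.fmt3(by_mod[m]) for m in matrix.modalities])
    parts.append(_md_table(["Pair"] + list(matrix.modalities), rows))

    parts += ["", "## Intra-observer agreement (kappa per modality pair)", ""]
    pairs = list(dict.fromkeys(zip(intra["modality_a"], intra["modality_b"])))
    rows = []
    for ma, mb in pairs:
        sub = intra[(intra["modality_a"] == ma) & (intra["modality_b"] == mb)]
        by_reader = dict(zip(sub["reader"], sub["kappa"]))
        rows.append([f"{ma} vs {mb}"] + [io.fmt3(by_reader[r]) for r in matrix.readers])
    parts.append(_md_table(["Pair"] + list(matrix.readers), rows))

    if ba_results:
        parts += ["", "## Bland-Altman log10-count comparison vs reference", ""]
        rows = [
            [
                r.modality,
                io.fmt3(r.b),
                io.fmt3(r.sd_diff),
                f"({io.fmt3(r.la_low)}, {io.fmt3(r.la_high)})",
                f"({io.fmt3(r.ci_low)}, {io.fmt3(r.ci_high)})",
                io.fmt3(r.ratio_b),
            ]
            for r in ba_results
        ]
        parts.append(
            _md_table(
                ["Modality", "b", "SD(diff)", "Limits of agreement", "95% CI for b", "Count ratio 10^b"],
                rows,
            )
        )

    parts += ["", "## Accuracy (average of sensitivity and specificity)", ""]
    rows = []
    for i, r in enumerate(aucs.readers):
        rows.append([r] + [io.fmt3(v) for v in aucs.auc[i]])
    summary = result.modality_summary.set_index("modality")
    comp = result.comparisons.set_index("modality") if len(result.comparisons) else None
    avg_row = ["Average"] + [io.fmt3(summary.loc[m, "avg_auc"]) for m in aucs.modalities]
    se_row = ["SE"] + [io.fmt3(summary.loc[m, "se"]) for m in aucs.modalities]
    ci_row = ["95% CI"] + [
        f"({io.fmt3(summary.loc[m, 'ci_low'])}, {io.fmt3(summary.loc[m, 'ci_high'])})"
        for m in aucs.modalities
    ]
    p_row = ["p-value vs reference"]
    for m in aucs.modalities:
        if comp is not None and m in comp.index:
            star = "*" if bool(comp.loc[m, "holm_reject"]) else ""
            p_row.append(f"{io.fmt3(comp.loc[m, 'p_value'])}{star}")
        else:
            p_row.append("—")
    rows += [avg_row, se_row, ci_row, p_row]
    parts.append(_md_table(["Reader"] + list(aucs.modalities), rows))
    parts.append(
        f"\n`*` significant after the sequentially rejective Bonferroni (Holm) "
        f"procedure at alpha = {result.alpha}."
    )
    parts.append("")
    return "\n".join(parts)
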