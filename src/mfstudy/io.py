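"""Tabular input/output for the pipeline.

All tables are UTF-8, comma-separated CSV with a mandatory header and "."
decimal separator; floats are written at full (repr) precision so that
``read(write(x)) == x`` exactly.  Display-rounded companion columns follow
the conventions of the study's printed tables: three decimals for kappa and
accuracy values, integer percent (half-up) for shares of the candidate pool.
"""

from __future__ import annotations

import decimal
from pathlib import Path

import pandas as pd
import yaml

from .errors import FormatError, ValidationError
from .model import ROI, Candidate, Mark, StudyDesign, TruthSet

MARK_COLUMNS = ["reader_id", "modality_id", "slide_id", "roi_id", "x_um", "y_um"]
CANDIDATE_COLUMNS = [
    "candidate_id",
    "slide_id",
    "roi_id",
    "centroid_x_um",
    "centroid_y_um",
    "n_marks",
]
TRUTH_COLUMNS = ["candidate_id", "label", "provenance"]
ADJUDICATION_COLUMNS = ["candidate_id", "label"]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


# ---------------------------------------------------------------------------
# display rounding


def round_half_up(x: float, decimals: int) -> float:
    """Decimal half-up rounding (0.5 always rounds away from zero)."""
    q = decimal.Decimal(1).scaleb(-decimals)
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def fmt3(x: float) -> str:
    """Kappa/accuracy display convention: three decimals, half-up."""
    return f"{round_half_up(x, 3):.3f}"


def pct_share(numerator: int, denominator: int) -> int:
    """Integer percent share of the candidate pool, rounded half-up."""
    if denominator <= 0:
        raise ValidationError("percentage share requires a positive denominator")
    return int(round_half_up(100.0 * numerator / denominator, 0))


def fmt_count_share(count: int, pool_size: int) -> str:
    """Printed-table style, e.g. 66 of 155 -> ``"66 (43%)"``."""
    return f"{count} ({pct_share(count, pool_size)}%)"


# ---------------------------------------------------------------------------
# marks


def read_marks(path, design: StudyDesign | None = None) -> list[Mark]:
    """Read a marks CSV; validate against a design when one is supplied.

    Row numbers in error messages are 1-based data rows (header excluded).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, MARK_COLUMNS, path)
    marks = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        mark = Mark(
            reader_id=str(row.reader_id),
            modality_id=str(row.modality_id),
            slide_id=str(row.slide_id),
            roi_id=str(row.roi_id),
            x_um=float(row.x_um),
            y_um=float(row.y_um),
        )
        if design is not None:
            mark.validate(design, row=i)
        marks.append(mark)
    return marks


def write_marks(marks: list[Mark], path) -> None:
    df = pd.DataFrame([vars(m) for m in marks], columns=MARK_COLUMNS)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# candidates / truth / adjudication


def write_candidates(candidates: list[Candidate], path) -> None:
    rows = [
        {
            "candidate_id": c.candidate_id,
            "slide_id": c.slide_id,
            "roi_id": c.roi_id,
            "centroid_x_um": c.centroid_x_um,
            "centroid_y_um": c.centroid_y_um,
            "n_marks": c.n_marks,
        }
        for c in candidates
    ]
    pd.DataFrame(rows, columns=CANDIDATE_COLUMNS).to_csv(path, index=False)


def read_candidates(path) -> list[Candidate]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, CANDIDATE_COLUMNS, path)
    return [
        Candidate(
            candidate_id=str(r.candidate_id),
            slide_id=str(r.slide_id),
            roi_id=str(r.roi_id),
            centroid_x_um=float(r.centroid_x_um),
            centroid_y_um=float(r.centroid_y_um),
        )
        for r in df.itertuples(index=False)
    ]


_BOOL = {"true": True, "false": False, "1": True, "0": False}


def _parse_label(raw, path, row: int) -> bool:
    key = str(raw).strip().lower()
    if key not in _BOOL:
        raise FormatError(f"{path}: row {row}: label must be true/false, got {raw!r}")
    return _BOOL[key]


def write_truth(truth: TruthSet, path) -> None:
    rows = [
        {"candidate_id": c, "label": str(truth.labels[c]).lower(), "provenance": truth.provenance[c]}
        for c in truth.labels
    ]
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, index=False)


def read_truth(path) -> TruthSet:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, TRUTH_COLUMNS, path)
    labels, provenance = {}, {}
    for i, r in enumerate(df.itertuples(index=False), start=1):
        cid = str(r.candidate_id)
        labels[cid] = _parse_label(r.label, path, i)
        provenance[cid] = str(r.provenance)
    return TruthSet(labels=labels, provenance=provenance)


def read_adjudication(path) -> dict[str, bool]:
    """Panel adjudication CSV: candidate_id,label(true|false)[,note]."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ADJUDICATION_COLUMNS, path)
    return {
        str(r.candidate_id): _parse_label(r.label, path, i)
        for i, r in enumerate(df.itertuples(index=False), start=1)
    }


def write_adjudication(labels: dict[str, bool], path) -> None:
    rows = [{"candidate_id": c, "label": str(v).lower(), "note": ""} for c, v in labels.items()]
    pd.DataFrame(rows, columns=ADJUDICATION_COLUMNS + ["note"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# study design YAML


def design_to_dict(design: StudyDesign) -> dict:
    return {
        "readers": list(design.readers),
        "modalities": list(design.modalities),
        "reference_modality": design.reference_modality,
        "slides": list(design.slides),
        "rois": [
            {
                "roi_id": r.roi_id,
                "slide_id": r.slide_id,
                "x_origin_um": r.x_origin_um,
                "y_origin_um": r.y_origin_um,
                "width_um": r.width_um,
                "height_um": r.height_um,
            }
            for r in design.rois
        ],
    }


def write_design(design: StudyDesign, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(design_to_dict(design), fh, sort_keys=False)


def read_design(path) -> StudyDesign:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    for key in ("readers", "modalities", "reference_modality", "slides"):
        if key not in raw:
            raise FormatError(f"{path}: missing design key {key!r}")
    rois = [ROI(**r) for r in raw.get("rois", [])]
    return StudyDesign(
        readers=[str(r) for r in raw["readers"]],
        modalities=[str(m) for m in raw["modalities"]],
        reference_modality=str(raw["reference_modality"]),
        slides=[str(s) for s in raw["slides"]],
        rois=rois,
    )


# ---------------------------------------------------------------------------
# generic result tables


def write_table(obj, path) -> None:
    """Serialize any pipeline result that exposes ``to_frame()`` (or is a frame).

    Column order is deterministic; float columns keep full precision, and
    display columns (if the result defines them) carry the printed-table
    rounding.
    """
    if isinstance(obj, pd.DataFrame):
        frame = obj
    elif hasattr(obj, "to_frame"):
        frame = obj.to_frame()
    else:
        raise FormatError(f"cannot serialize object of type {type(obj).__name__}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
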