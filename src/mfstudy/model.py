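"""Domain types for a multi-reader, multi-modality point-mark reader study.

The study design is a set of readers who each examine the same rectangular
regions of interest (ROIs) under several viewing modalities (whole-slide
scanners plus a reference brightfield microscope) and drop point marks on
every cell they call a mitotic figure.  All coordinates are micrometers in a
per-slide frame (x rightward, y downward).  ROI rectangles are half-open,
``[x0, x0+w) x [y0, y0+h)``, so a mark on a shared edge belongs to exactly
one ROI.

Identifiers are opaque strings.  The ordering of readers, modalities and
candidates is the order of first appearance (or the order given by a
:class:`StudyDesign`) and is fixed thereafter, so that matrix indices are
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

DEFAULT_ROI_SIZE_UM = 200.0

AUTO_CONSENSUS = "auto_consensus"
PANEL = "panel"


@dataclass(frozen=True)
class ROI:
    """A rectangular region of interest on one slide (micrometer units)."""

    roi_id: str
    slide_id: str
    x_origin_um: float
    y_origin_um: float
    width_um: float = DEFAULT_ROI_SIZE_UM
    height_um: float = DEFAULT_ROI_SIZE_UM

    def __post_init__(self) -> None:
        if self.width_um <= 0 or self.height_um <= 0:
            raise ValidationError(
                f"ROI {self.roi_id!r}: width/height must be > 0, "
                f"got {self.width_um} x {self.height_um}"
            )

    def contains(self, x_um: float, y_um: float) -> bool:
        """Half-open containment: the left/top edges are inside, right/bottom are not."""
        return (
            self.x_origin_um <= x_um < self.x_origin_um + self.width_um
            and self.y_origin_um <= y_um < self.y_origin_um + self.height_um
        )


@dataclass
class StudyDesign:
    """Readers, modalities (with a designated reference), slides and ROIs."""

    readers: list[str]
    modalities: list[str]
    reference_modality: str
    slides: list[str]
    rois: list[ROI] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.reference_modality not in self.modalities:
            raise ValidationError(
                f"reference modality {self.reference_modality!r} not among "
                f"modalities {self.modalities}"
            )
        slide_set = set(self.slides)
        for roi in self.rois:
            if roi.slide_id not in slide_set:
                raise ValidationError(
                    f"ROI {roi.roi_id!r} references unknown slide {roi.slide_id!r}"
                )
        ids = [r.roi_id for r in self.rois]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate ROI identifiers in design")
        self._roi_by_id = {r.roi_id: r for r in self.rois}

    def roi(self, roi_id: str) -> ROI:
        try:
            return self._roi_by_id[roi_id]
        except KeyError:
            raise ValidationError(f"unknown ROI {roi_id!r}") from None

    @property
    def n_readers(self) -> int:
        return len(self.readers)

    @property
    def n_modalities(self) -> int:
        return len(self.modalities)


@dataclass(frozen=True)
class Mark:
    """One reader's point annotation of a candidate mitotic figure in one modality."""

    reader_id: str
    modality_id: str
    slide_id: str
    roi_id: str
    x_um: float
    y_um: float

    def validate(self, design: StudyDesign, row: int | None = None) -> None:
        """Check all identifiers resolve and the position lies inside the named ROI."""
        where = "" if row is None else f" (row {row})"
        if self.reader_id not in design.readers:
            raise ValidationError(f"unknown reader {self.reader_id!r}{where}")
        if self.modality_id not in design.modalities:
            raise ValidationError(f"unknown modality {self.modality_id!r}{where}")
        if self.slide_id not in design.slides:
            raise ValidationError(f"unknown slide {self.slide_id!r}{where}")
        roi = design.roi(self.roi_id)
        if roi.slide_id != self.slide_id:
            raise ValidationError(
                f"mark names slide {self.slide_id!r} but ROI {self.roi_id!r} "
                f"is on slide {roi.slide_id!r}{where}"
            )
        if not roi.contains(self.x_um, self.y_um):
            raise ValidationError(
                f"mark at ({self.x_um}, {self.y_um}) outside ROI "
                f"{self.roi_id!r}{where}"
            )


@dataclass
class Candidate:
    """A pooled candidate lesion: marks within matching distance of each other.

    The centroid is the arithmetic mean of the member-mark positions.  All
    member marks share one slide and one ROI, and no (reader, modality) pair
    contributes more than one member.
    """

    candidate_id: str
    slide_id: str
    roi_id: str
    centroid_x_um: float
    centroid_y_um: float
    member_marks: list[Mark] = field(default_factory=list)

    @property
    def n_marks(self) -> int:
        return len(self.member_marks)


class MarkMatrix:
    """Binary detection tensor indexed (reader, modality, candidate).

    Entry 1 means the reader marked the candidate as mitotic in that
    modality.  Every candidate column has at least one 1: a candidate exists
    only because someone marked it.
    """

    def __init__(
        self,
        readers: list[str],
        modalities: list[str],
        candidates: list[Candidate],
        marks: np.ndarray,
    ) -> None:
        marks = np.asarray(marks, dtype=np.int8)
        if marks.shape != (len(readers), len(modalities), len(candidates)):
            raise ValidationError(
                f"mark array shape {marks.shape} does not match "
                f"({len(readers)}, {len(modalities)}, {len(candidates)})"
            )
        if not np.isin(marks, (0, 1)).all():
            raise ValidationError("mark matrix entries must be 0 or 1")
        if candidates and (marks.sum(axis=(0, 1)) == 0).any():
            bad = [
                candidates[i].candidate_id
                for i in np.nonzero(marks.sum(axis=(0, 1)) == 0)[0]
            ]
            raise ValidationError(f"candidates with no marks at all: {bad}")
        self.readers = list(readers)
        self.modalities = list(modalities)
        self.candidates = list(candidates)
        self.marks = marks
        self._reader_index = {r: i for i, r in enumerate(self.readers)}
        self._modality_index = {m: i for i, m in enumerate(self.modalities)}

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)

    @property
    def candidate_ids(self) -> list[str]:
        return [c.candidate_id for c in self.candidates]

    @property
    def candidate_slides(self) -> list[str]:
        return [c.slide_id for c in self.candidates]

    def reader_index(self, reader_id: str) -> int:
        try:
            return self._reader_index[reader_id]
        except KeyError:
            raise ValidationError(f"unknown reader {reader_id!r}") from None

    def modality_index(self, modality_id: str) -> int:
        try:
            return self._modality_index[modality_id]
        except KeyError:
            raise ValidationError(f"unknown modality {modality_id!r}") from None

    def vector(self, reader_id: str, modality_id: str) -> np.ndarray:
        """One reader's binary determinations over the whole pool in one modality."""
        return self.marks[self.reader_index(reader_id), self.modality_index(modality_id)]

    def modality_slice(self, modality_id: str) -> np.ndarray:
        """(reader, candidate) binary array for one modality."""
        return self.marks[:, self.modality_index(modality_id), :]


@dataclass
class TruthSet:
    """Per-candidate true/false mitotic-figure labels with provenance.

    Provenance is ``auto_consensus`` for candidates accepted by the
    reference-modality multiplicity rule and ``panel`` for candidates
    adjudicated by the truthing panel.
    """

    labels: dict[str, bool]
    provenance: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.labels) != set(self.provenance):
            raise ValidationError("truth labels and provenance cover different candidates")
        bad = sorted(set(self.provenance.values()) - {AUTO_CONSENSUS, PANEL})
        if bad:
            raise ValidationError(f"unknown provenance tags: {bad}")

    @property
    def n_true(self) -> int:
        return sum(self.labels.values())

    @property
    def n_false(self) -> int:
        return len(self.labels) - self.n_true

    def label_vector(self, candidate_ids: list[str]) -> np.ndarray:
        """Boolean labels aligned to a candidate ordering."""
        try:
            return np.array([self.labels[c] for c in candidate_ids], dtype=bool)
        except KeyError as exc:
            raise ValidationError(f"candidate {exc.args[0]!r} has no truth label") from None
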