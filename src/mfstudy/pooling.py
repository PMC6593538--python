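"""Candidate pooling and ground-truth derivation.

Point marks from all readers and modalities are collapsed into a shared
candidate pool by single-linkage agglomeration within each ROI: two marks
belong to the same candidate iff a chain of pairwise distances no larger
than the match radius connects them.  The default radius (10 um) is twice
the registration accuracy of the stage/WSI co-registration platform that
presents the ROIs, so marks of the same cell from different modalities
land within one cluster.

Ground truth then combines an automatic consensus rule on the reference
modality (a candidate marked by at least ``threshold`` of the readers under
the microscope is accepted as a true mitotic figure) with a truthing-panel
adjudication table covering every remaining candidate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    IncompleteTruthError,
    PoolingAmbiguityError,
    TruthConflictError,
    ValidationError,
)
from .model import (
    AUTO_CONSENSUS,
    PANEL,
    Candidate,
    Mark,
    MarkMatrix,
    StudyDesign,
    TruthSet,
)


@dataclass(frozen=True)
class PoolingConfig:
    """Distance threshold (um) for treating two marks as the same candidate."""

    match_radius_um: float = 10.0

    def __post_init__(self) -> None:
        if self.match_radius_um <= 0:
            raise ValidationError("match_radius_um must be > 0")


@dataclass
class MultiplicityHistogram:
    """Reference-modality detection multiplicity of the candidate pool.

    ``counts_by_multiplicity[k]`` is the number of candidates marked by
    exactly k readers in the reference modality; the k=0 bucket holds
    candidates seen only on the non-reference modalities.
    """

    counts_by_multiplicity: np.ndarray

    @property
    def n_reference_detected(self) -> int:
        return int(self.counts_by_multiplicity[1:].sum())

    @property
    def n_reference_only_missed(self) -> int:
        return int(self.counts_by_multiplicity[0])


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _cluster_roi(marks: list[Mark], radius: float) -> list[list[Mark]]:
    """Single-linkage connected components of the <=radius graph in one ROI."""
    n = len(marks)
    xy = np.array([[m.x_um, m.y_um] for m in marks])
    uf = _UnionFind(n)
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
    for i, j in zip(*np.nonzero(np.triu(d2 <= radius * radius, k=1))):
        uf.union(int(i), int(j))
    groups: dict[int, list[Mark]] = {}
    for i, m in enumerate(marks):
        groups.setdefault(uf.find(i), []).append(m)
    return list(groups.values())


def pool_marks(
    marks: list[Mark],
    config: PoolingConfig | None = None,
    design: StudyDesign | None = None,
) -> tuple[list[Candidate], MarkMatrix]:
    """Pool marks into candidates and build the binary detection tensor.

    Candidates never span ROIs.  They are ordered by (slide, ROI, centroid
    y, centroid x) and assigned sequential identifiers, so pooling is
    invariant to the input order of the marks.  Reader and modality axes
    follow the design when given, else the order of first appearance.

    Raises
    ------
    PoolingAmbiguityError
        If two marks of the same (reader, modality) pair join one cluster —
        a reader cannot mark one cell twice.
    """
    config = config or PoolingConfig()
    if design is not None:
        readers, modalities = list(design.readers), list(design.modalities)
    else:
        readers = list(dict.fromkeys(m.reader_id for m in marks))
        modalities = list(dict.fromkeys(m.modality_id for m in marks))

    by_roi: dict[tuple[str, str], list[Mark]] = {}
    for m in marks:
        by_roi.setdefault((m.slide_id, m.roi_id), []).append(m)

    clusters: list[tuple[str, str, float, float, list[Mark]]] = []
    for (slide_id, roi_id), roi_marks in by_roi.items():
        for group in _cluster_roi(roi_marks, config.match_radius_um):
            seen: dict[tuple[str, str], Mark] = {}
            for m in group:
                key = (m.reader_id, m.modality_id)
                if key in seen:
                    raise PoolingAmbiguityError(
                        f"reader {m.reader_id!r} marked one candidate twice in "
                        f"modality {m.modality_id!r} within ROI {roi_id!r}: "
                        f"{seen[key]} and {m}"
                    )
                seen[key] = m
            cx = float(np.mean([m.x_um for m in group]))
            cy = float(np.mean([m.y_um for m in group]))
            clusters.append((slide_id, roi_id, cy, cx, group))

    clusters.sort(key=lambda c: (c[0], c[1], c[2], c[3]))
    width = max(4, len(str(len(clusters))))
    candidates = [
        Candidate(
            candidate_id=f"C{i:0{width}d}",
            slide_id=slide_id,
            roi_id=roi_id,
            centroid_x_um=cx,
            centroid_y_um=cy,
            member_marks=group,
        )
        for i, (slide_id, roi_id, cy, cx, group) in enumerate(clusters, start=1)
    ]

    r_idx = {r: i for i, r in enumerate(readers)}
    m_idx = {m: i for i, m in enumerate(modalities)}
    arr = np.zeros((len(readers), len(modalities), len(candidates)), dtype=np.int8)
    for c, cand in enumerate(candidates):
        for mark in cand.member_marks:
            arr[r_idx[mark.reader_id], m_idx[mark.modality_id], c] = 1
    return candidates, MarkMatrix(readers, modalities, candidates, arr)


def reference_multiplicity(
    matrix: MarkMatrix, design: StudyDesign
) -> MultiplicityHistogram:
    """Histogram of per-candidate reader multiplicity in the reference modality."""
    ref = matrix.modality_slice(design.reference_modality)  # (reader, candidate)
    k = ref.sum(axis=0)
    counts = np.bincount(k, minlength=len(matrix.readers) + 1)
    return MultiplicityHistogram(counts_by_multiplicity=counts)


def auto_consensus_truth(
    matrix: MarkMatrix, design: StudyDesign, threshold: int = 4
) -> set[str]:
    """Candidates auto-accepted as true: reference multiplicity >= threshold.

    The consensus rule is inclusive (>=): in the study this package models,
    at-least-4-of-5 microscope readers accepted a candidate without panel
    review.  The threshold is a parameter, so a strict all-readers rule is
    ``threshold = n_readers``.
    """
    if not 1 <= threshold <= len(matrix.readers):
        raise ValidationError(
            f"threshold must be in [1, {len(matrix.readers)}], got {threshold}"
        )
    ref = matrix.modality_slice(design.reference_modality)
    k = ref.sum(axis=0)
    return {cid for cid, kk in zip(matrix.candidate_ids, k) if kk >= threshold}


def merge_adjudication(
    auto: set[str],
    panel: dict[str, bool],
    pool: list[Candidate],
    auto_wins: bool = False,
) -> TruthSet:
    """Combine the auto-consensus set with the panel's adjudication table.

    Auto-consensus candidates are true with provenance ``auto_consensus``;
    every other pooled candidate takes the panel's label with provenance
    ``panel``.

    Raises
    ------
    IncompleteTruthError
        If a pooled candidate is in neither source.
    TruthConflictError
        If the panel labels an auto-true candidate false and ``auto_wins``
        is not set.
    """
    labels: dict[str, bool] = {}
    provenance: dict[str, str] = {}
    missing = []
    for cand in pool:
        cid = cand.candidate_id
        if cid in auto:
            if cid in panel and panel[cid] is False and not auto_wins:
                raise TruthConflictError(
                    f"panel labels auto-consensus candidate {cid!r} false; "
                    "set auto_wins to let the consensus rule prevail"
                )
            labels[cid] = True
            provenance[cid] = AUTO_CONSENSUS
        elif cid in panel:
            labels[cid] = bool(panel[cid])
            provenance[cid] = PANEL
        else:
            missing.append(cid)
    if missing:
        raise IncompleteTruthError(
            f"candidates with no truth from either source: {missing}"
        )
    unknown = sorted(auto - {c.candidate_id for c in pool})
    if unknown:
        raise ValidationError(f"auto-consensus candidates not in the pool: {unknown}")
    return TruthSet(labels=labels, provenance=provenance)
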