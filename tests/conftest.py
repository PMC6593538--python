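import numpy as np
import pytest

from mfstudy.model import ROI, Candidate, MarkMatrix, StudyDesign

MODALITIES = ["scannerA", "scannerB", "scannerC", "scannerD", "microscope"]
READERS = ["R1", "R2", "R3", "R4", "R5"]


def make_matrix(arr, readers=None, modalities=None, slides=None):
    """Wrap a (reader, modality, candidate) binary array in a MarkMatrix.

    Candidates get synthetic IDs and are spread round-robin over ``slides``
    (default 4 slides) so slide-clustered estimators have clusters to use.
    """
    arr = np.asarray(arr, dtype=np.int8)
    r, m, c = arr.shape
    readers = readers or [f"R{i + 1}" for i in range(r)]
    modalities = modalities or MODALITIES[:m]
    slides = slides or [f"S{i + 1}" for i in range(min(4, max(1, c)))]
    candidates = [
        Candidate(
            candidate_id=f"C{i + 1:04d}",
            slide_id=slides[i % len(slides)],
            roi_id=f"{slides[i % len(slides)]}-ROI1",
            centroid_x_um=float(i),
            centroid_y_um=0.0,
        )
        for i in range(c)
    ]
    return MarkMatrix(readers, modalities, candidates, arr)


@pytest.fixture
def small_design():
    rois = [
        ROI(f"S{s}-ROI{i}", f"S{s}", 600.0 * (i - 1), 0.0, 200.0, 200.0)
        for s in (1, 2)
        for i in (1, 2)
    ]
    return StudyDesign(
        readers=READERS,
        modalities=MODALITIES,
        reference_modality="microscope",
        slides=["S1", "S2"],
        rois=rois,
    )


@pytest.fixture
def study_shaped_matrix():
    """A 155-candidate pool realizing the modeled study's microscope multiplicities.

    Candidate groups of sizes 28, 13, 17, 8, 29 are marked under the
    microscope by exactly 1..5 readers respectively; 60 more candidates are
    marked only on a scanner.
    """
    groups = [(28, 1), (13, 2), (17, 3), (8, 4), (29, 5)]
    n = sum(g for g, _ in groups) + 60
    arr = np.zeros((5, 5, n), dtype=np.int8)
    mic = MODALITIES.index("microscope")
    scan = MODALITIES.index("scannerA")
    c = 0
    for size, k in groups:
        for _ in range(size):
            for r in range(k):
                arr[r, mic, c] = 1
            c += 1
    for i in range(60):
        arr[i % 5, scan, c] = 1
        c += 1
    return make_matrix(arr)
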