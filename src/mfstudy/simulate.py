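"""Synthetic multi-reader, multi-modality reader studies with known truth.

The generator emulates the structure of the mitotic-figure validation study
this package is built around: a handful of slides, each carrying a grid of
200 x 200 um ROIs; true mitotic figures and false (distractor) candidates
scattered in the ROIs at Poisson rates; five readers examining every ROI in
every modality (four scanners and a reference microscope) and dropping a
point mark, with small spatial jitter, on each candidate they call mitotic.

Detection is a Bernoulli draw with probability
``logistic(mu + tau_m + rho_r + eta_s + delta_c)`` where mu is the baseline
log-odds (``mu_se`` for true candidates, ``mu_fp`` for false ones), tau_m a
per-modality shift on the detection scale (the reference is pinned at 0),
and rho_r, eta_s, delta_c Gaussian reader, slide and candidate effects.
The additive structure induces exactly the two correlations the analysis
stage claims to handle: same-reader correlation across candidates and
within-slide correlation across readers.

Every random component draws from its own deterministic substream of the
single integer seed, so adding a modality or reader does not perturb the
draws of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .errors import ConfigError, ValidationError
from .model import ROI, Candidate, Mark, MarkMatrix, StudyDesign, TruthSet

_ROI_SPACING_FACTOR = 3  # ROI origins 3 widths apart: ROIs never touch


def default_modality_effects() -> dict[str, float]:
    """Four scanners harder to read than the microscope (effect 0).

    The negative detection-scale shifts are calibrated so the expected
    whole-study mark count of each scanner, relative to the microscope,
    matches the 16-37% per-reader count deficits the modeled study
    observed (ratios ~0.82, 0.84, 0.63, 0.79 for scanners A-D).
    """
    return {
        "scannerA": -0.53,
        "scannerB": -0.47,
        "scannerC": -1.12,
        "scannerD": -0.61,
        "microscope": 0.0,
    }


@dataclass
class SimConfig:
    """Generative parameters for a synthetic reader study.

    Defaults mirror the modeled study's shape: 5 readers x 5 modalities x
    4 slides x 10 ROIs per slide, with Poisson candidate rates chosen so a
    study realizes ~74 true and ~80 false candidates.
    """

    n_slides: int = 4
    rois_per_slide: int = 10
    roi_size_um: float = 200.0
    n_readers: int = 5
    modality_effects: dict[str, float] = field(default_factory=default_modality_effects)
    reference_modality: str = "microscope"
    mean_true_per_roi: float = 1.85  # ~74 true over 40 ROIs
    mean_false_per_roi: float = 2.0  # ~80 distractors over 40 ROIs
    mu_se: float = 1.1  # baseline log-odds of marking a true MF
    mu_fp: float = -1.7  # baseline log-odds of marking a distractor
    sigma_reader: float = 0.3
    sigma_slide: float = 0.2
    sigma_candidate: float = 0.8
    jitter_sd_um: float = 2.0
    min_candidate_spacing_um: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slides < 1 or self.rois_per_slide < 1 or self.n_readers < 1:
            raise ValidationError("study dimensions must be positive")
        if self.roi_size_um <= 0:
            raise ValidationError("roi_size_um must be > 0")
        for name in ("mean_true_per_roi", "mean_false_per_roi"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in (
            "sigma_reader",
            "sigma_slide",
            "sigma_candidate",
            "jitter_sd_um",
            "min_candidate_spacing_um",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.reference_modality not in self.modality_effects:
            raise ValidationError(
                f"reference modality {self.reference_modality!r} missing from effects"
            )
        if self.modality_effects[self.reference_modality] != 0.0:
            raise ValidationError("the reference modality's effect must be 0")

    @property
    def modalities(self) -> list[str]:
        return list(self.modality_effects)

    @property
    def readers(self) -> list[str]:
        return [f"R{i}" for i in range(1, self.n_readers + 1)]

    @property
    def total_sigma(self) -> float:
        return float(
            np.sqrt(self.sigma_reader**2 + self.sigma_slide**2 + self.sigma_candidate**2)
        )


@dataclass
class SimTruthBundle:
    """A realized synthetic study with its exactly-known ground truth."""

    design: StudyDesign
    marks: list[Mark]
    candidates: list[Candidate]  # all generated candidates, marked or not
    truth: TruthSet  # labels for all generated candidates
    mark_array: np.ndarray  # (reader, modality, candidate) over `candidates`
    config: SimConfig

    def marked_matrix(self) -> tuple[MarkMatrix, TruthSet]:
        """Restrict to candidates someone marked: the observable pool.

        This mirrors what a real study can see — a candidate exists only
        because a reader marked it — and is the universe every downstream
        estimator runs on.
        """
        keep = self.mark_array.sum(axis=(0, 1)) > 0
        kept = [c for c, k in zip(self.candidates, keep) if k]
        matrix = MarkMatrix(
            readers=self.design.readers,
            modalities=self.design.modalities,
            candidates=kept,
            marks=self.mark_array[:, :, keep],
        )
        ids = {c.candidate_id for c in kept}
        truth = TruthSet(
            labels={c: v for c, v in self.truth.labels.items() if c in ids},
            provenance={c: v for c, v in self.truth.provenance.items() if c in ids},
        )
        return matrix, truth


def _rng(seed: int, *keys) -> np.random.Generator:
    """Deterministic substream: seed plus CRC32-hashed component keys."""
    entropy = [int(seed) & 0x7FFFFFFF] + [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def make_design(config: SimConfig) -> StudyDesign:
    """Lay out slides and an evenly spaced ROI grid per slide."""
    w = config.roi_size_um
    slides = [f"S{i}" for i in range(1, config.n_slides + 1)]
    rois = []
    per_row = 5
    for s in slides:
        for i in range(config.rois_per_slide):
            rois.append(
                ROI(
                    roi_id=f"{s}-ROI{i + 1}",
                    slide_id=s,
                    x_origin_um=(i % per_row) * _ROI_SPACING_FACTOR * w,
                    y_origin_um=(i // per_row) * _ROI_SPACING_FACTOR * w,
                    width_um=w,
                    height_um=w,
                )
            )
    return StudyDesign(
        readers=config.readers,
        modalities=config.modalities,
        reference_modality=config.reference_modality,
        slides=slides,
        rois=rois,
    )


def _place_candidates(
    roi: ROI, n: int, min_dist: float, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Uniform placement with a minimum pairwise distance (rejection sampling)."""
    placed: list[tuple[float, float]] = []
    attempts_per = 200
    for _ in range(n):
        for _attempt in range(attempts_per):
            x = roi.x_origin_um + rng.uniform(0, roi.width_um)
            y = roi.y_origin_um + rng.uniform(0, roi.height_um)
            if all((x - px) ** 2 + (y - py) ** 2 >= min_dist**2 for px, py in placed):
                placed.append((x, y))
                break
        else:
            raise ConfigError(
                f"could not place {n} candidates in ROI {roi.roi_id!r} with "
                f"minimum spacing {min_dist} um; reduce the rates or jitter"
            )
    return placed


def simulate_study(config: SimConfig, with_marks: bool = True) -> SimTruthBundle:
    """Generate one synthetic reader study, fully reproducible from the seed.

    ``with_marks=False`` skips materializing the jittered point-mark list
    (the detection tensor and truth are unaffected); replicated simulation
    studies that only need the tensor use it to stay cheap.
    """
    design = make_design(config)
    # Spacing must dominate both the jitter (3 sigma) and any plausible
    # pooling radius, so distinct candidates stay distinct after pooling.
    min_dist = max(3.0 * config.jitter_sd_um, config.min_candidate_spacing_um)

    # --- candidates -------------------------------------------------------
    candidates: list[Candidate] = []
    labels: list[bool] = []
    deltas: list[float] = []
    for roi in design.rois:
        counts_rng = _rng(config.seed, "counts", roi.roi_id)
        n_true = int(counts_rng.poisson(config.mean_true_per_roi))
        n_false = int(counts_rng.poisson(config.mean_false_per_roi))
        place_rng = _rng(config.seed, "placement", roi.roi_id)
        points = _place_candidates(roi, n_true + n_false, min_dist, place_rng)
        effect_rng = _rng(config.seed, "candidate-effect", roi.roi_id)
        for i, (x, y) in enumerate(points):
            candidates.append(
                Candidate(
                    candidate_id="",  # assigned after the global sort
                    slide_id=roi.slide_id,
                    roi_id=roi.roi_id,
                    centroid_x_um=x,
                    centroid_y_um=y,
                )
            )
            labels.append(i < n_true)
            deltas.append(float(effect_rng.normal(0.0, config.sigma_candidate)))

    order = sorted(
        range(len(candidates)),
        key=lambda i: (
            candidates[i].slide_id,
            candidates[i].roi_id,
            candidates[i].centroid_y_um,
            candidates[i].centroid_x_um,
        ),
    )
    candidates = [candidates[i] for i in order]
    labels = [labels[i] for i in order]
    deltas = np.array([deltas[i] for i in order])
    width = max(4, len(str(len(candidates))))
    for i, c in enumerate(candidates, start=1):
        c.candidate_id = f"T{i:0{width}d}"

    # --- random effects ---------------------------------------------------
    rho = {
        r: float(_rng(config.seed, "reader-effect", r).normal(0.0, config.sigma_reader))
        for r in design.readers
    }
    eta = {
        s: float(_rng(config.seed, "slide-effect", s).normal(0.0, config.sigma_slide))
        for s in design.slides
    }
    label_arr = np.array(labels, dtype=bool)
    mu = np.where(label_arr, config.mu_se, config.mu_fp)
    slide_eff = np.array([eta[c.slide_id] for c in candidates])

    # --- marks ------------------------------------------------------------
    n_c = len(candidates)
    mark_array = np.zeros((config.n_readers, len(config.modalities), n_c), dtype=np.int8)
    marks: list[Mark] = []
    for mi, (modality, tau) in enumerate(config.modality_effects.items()):
        for ri, reader in enumerate(design.readers):
            stream = _rng(config.seed, "marks", modality, reader)
            p = expit(mu + tau + rho[reader] + slide_eff + deltas)
            hits = stream.uniform(size=n_c) < p
            jitter = stream.normal(0.0, config.jitter_sd_um, size=(n_c, 2))
            mark_array[ri, mi, hits] = 1
            if not with_marks:
                continue
            for ci in np.nonzero(hits)[0]:
                cand = candidates[ci]
                roi = design.roi(cand.roi_id)
                eps = 1e-6
                x = float(
                    np.clip(
                        cand.centroid_x_um + jitter[ci, 0],
                        roi.x_origin_um,
                        roi.x_origin_um + roi.width_um - eps,
                    )
                )
                y = float(
                    np.clip(
                        cand.centroid_y_um + jitter[ci, 1],
                        roi.y_origin_um,
                        roi.y_origin_um + roi.height_um - eps,
                    )
                )
                marks.append(
                    Mark(
                        reader_id=reader,
                        modality_id=modality,
                        slide_id=cand.slide_id,
                        roi_id=cand.roi_id,
                        x_um=x,
                        y_um=y,
                    )
                )

    truth = TruthSet(
        labels={c.candidate_id: bool(v) for c, v in zip(candidates, labels)},
        provenance={c.candidate_id: "panel" for c in candidates},
    )
    return SimTruthBundle(
        design=design,
        marks=marks,
        candidates=candidates,
        truth=truth,
        mark_array=mark_array,
        config=config,
    )


def adjudication_for_pool(bundle: SimTruthBundle, pool: list[Candidate]) -> dict[str, bool]:
    """Label pooled candidates with the generator's truth by nearest centroid.

    Pooling assigns its own canonical candidate IDs, so an adjudication
    table for a pooled synthetic study must be re-keyed: each pooled
    candidate takes the label of the nearest generated candidate in its
    ROI.  Raises if a pooled centroid is not clearly attributable (farther
    than half the minimum candidate spacing from every generated centroid).
    """
    by_roi: dict[str, list[tuple[float, float, bool]]] = {}
    for cand, label in zip(bundle.candidates, (bundle.truth.labels[c.candidate_id] for c in bundle.candidates)):
        by_roi.setdefault(cand.roi_id, []).append(
            (cand.centroid_x_um, cand.centroid_y_um, bool(label))
        )
    max_dist = max(bundle.config.min_candidate_spacing_um, 3.0 * bundle.config.jitter_sd_um) / 2.0
    labels: dict[str, bool] = {}
    for cand in pool:
        options = by_roi.get(cand.roi_id, [])
        if not options:
            raise ValidationError(f"pooled candidate {cand.candidate_id!r} in unknown ROI")
        d2 = [(cand.centroid_x_um - x) ** 2 + (cand.centroid_y_um - y) ** 2 for x, y, _ in options]
        best = int(np.argmin(d2))
        if d2[best] > max_dist**2:
            raise ValidationError(
                f"pooled candidate {cand.candidate_id!r} is {np.sqrt(d2[best]):.1f} um "
                "from the nearest generated candidate; cannot attribute a label"
            )
        labels[cand.candidate_id] = options[best][2]
    return labels


# ---------------------------------------------------------------------------
# designed (expected) operating characteristics


def _gauss_hermite_expect_logistic(mu: float, sigma: float, n_nodes: int = 80) -> float:
    """E[logistic(mu + sigma * Z)], Z ~ N(0,1), by Gauss-Hermite quadrature."""
    if sigma == 0:
        return float(expit(mu))
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    # hermegauss integrates against exp(-z^2/2); normalize by sqrt(2*pi)
    return float(np.sum(weights * expit(mu + sigma * nodes)) / np.sqrt(2.0 * np.pi))


def designed_se(config: SimConfig, modality: str) -> float:
    """Expected per-candidate sensitivity under the generative model."""
    tau = config.modality_effects[modality]
    return _gauss_hermite_expect_logistic(config.mu_se + tau, config.total_sigma)


def designed_fp(config: SimConfig, modality: str) -> float:
    """Expected per-candidate false-positive fraction."""
    tau = config.modality_effects[modality]
    return _gauss_hermite_expect_logistic(config.mu_fp + tau, config.total_sigma)


def designed_auc(config: SimConfig, modality: str) -> float:
    """Expected accuracy (Se+Sp)/2 the estimation pipeline should recover.

    Integrates the logistic detection probability over the Gaussian reader,
    slide and candidate effects (their sum is a single Gaussian) with
    Gauss-Hermite quadrature.
    """
    return (designed_se(config, modality) + 1.0 - designed_fp(config, modality)) / 2.0
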