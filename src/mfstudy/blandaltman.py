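"""Bland-Altman comparison of per-slide mitotic counts on the log10 scale.

For each reader and slide we count every candidate the reader marked in a
modality, then compare a scanner against the reference microscope through
the difference of log10 counts.  The log transform stabilizes the variance
of count differences as a function of the mean, and differences of logs map
back to count ratios: a mean difference b corresponds to a ratio 10^b of
scanner to microscope counts.

Limits of agreement are the mean difference +/- twice the standard
deviation of the individual log-count differences.  The standard deviation
(and the confidence interval on the mean difference) come from a two-way
random-effects moment decomposition of the reader-by-slide difference
matrix, so that both reader-to-reader variation and the correlation induced
by all readers counting the same slides are represented — a multi-reader
multi-case treatment of the uncertainty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError
from .model import MarkMatrix, StudyDesign

LA_MULTIPLIER = 2.0  # limits of agreement use exactly twice the SD
Z_95 = 1.959963984540054  # normal 97.5% quantile, for the CI on the mean


@dataclass
class CountTable:
    """Marked-candidate counts indexed (reader, modality, slide)."""

    counts: np.ndarray
    readers: list[str]
    modalities: list[str]
    slides: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        expected = (len(self.readers), len(self.modalities), len(self.slides))
        if self.counts.shape != expected:
            raise ValidationError(
                f"count array shape {self.counts.shape} does not match {expected}"
            )
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")

    def per_reader_totals(self, modality: str) -> np.ndarray:
        """Whole-study count per reader for one modality (sums over slides)."""
        m = self.modalities.index(modality)
        return self.counts[:, m, :].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "reader_id": r,
                "modality_id": m,
                "slide_id": s,
                "count": int(self.counts[i, j, k]),
            }
            for i, r in enumerate(self.readers)
            for j, m in enumerate(self.modalities)
            for k, s in enumerate(self.slides)
        ]
        return pd.DataFrame(rows)


@dataclass
class LogCountDiffs:
    """Per-(reader, slide) log10-count differences of one modality vs reference."""

    d: np.ndarray  # (reader, slide) log10 differences
    mean_log: np.ndarray  # (reader, slide) pair averages, for plotting
    readers: list[str]
    slides: list[str]
    modality: str
    reference: str


@dataclass
class BAResult:
    """Bland-Altman summary of one scanner-vs-reference comparison."""

    modality: str
    reference: str
    b: float  # mean log10-count difference (scanner - reference)
    sd_diff: float  # SD of individual log-count differences
    la_low: float
    la_high: float
    ci_low: float  # 95% MRMC CI on b
    ci_high: float
    variance_components: dict = field(default_factory=dict)

    @property
    def ratio_b(self) -> float:
        return float(10.0**self.b)

    @property
    def ratio_la_low(self) -> float:
        return float(10.0**self.la_low)

    @property
    def ratio_la_high(self) -> float:
        return float(10.0**self.la_high)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "modality": self.modality,
                    "reference": self.reference,
                    "b": self.b,
                    "sd_diff": self.sd_diff,
                    "la_low": self.la_low,
                    "la_high": self.la_high,
                    "ci_low": self.ci_low,
                    "ci_high": self.ci_high,
                    "ratio_b": self.ratio_b,
                    "ratio_la_low": self.ratio_la_low,
                    "ratio_la_high": self.ratio_la_high,
                }
            ]
        )


def per_slide_counts(matrix: MarkMatrix, design: StudyDesign | None = None) -> CountTable:
    """Count marked candidates per (reader, modality, slide)."""
    slides = (
        list(design.slides)
        if design is not None
        else list(dict.fromkeys(matrix.candidate_slides))
    )
    slide_idx = {s: i for i, s in enumerate(slides)}
    counts = np.zeros((len(matrix.readers), len(matrix.modalities), len(slides)), dtype=int)
    for c, slide in enumerate(matrix.candidate_slides):
        try:
            k = slide_idx[slide]
        except KeyError:
            raise ValidationError(f"candidate on slide {slide!r} not in design") from None
        counts[:, :, k] += matrix.marks[:, :, c]
    return CountTable(counts=counts, readers=matrix.readers, modalities=matrix.modalities, slides=slides)


def log_count_differences(
    counts: CountTable,
    modality: str,
    reference: str,
    zero_offset: float = 0.5,
) -> LogCountDiffs:
    """log10 count differences (modality - reference) per reader and slide.

    Zero counts are replaced by ``zero_offset`` (default 0.5, the standard
    continuity correction) before taking logs; affected cells are reported
    in a warning.  Also returns the per-pair average log count, the x-axis
    of a Bland-Altman plot.
    """
    for m in (modality, reference):
        if m not in counts.modalities:
            raise ValidationError(f"modality {m!r} not in count table")
    i = counts.modalities.index(modality)
    j = counts.modalities.index(reference)
    a = counts.counts[:, i, :].astype(float)
    b = counts.counts[:, j, :].astype(float)
    zero_cells = [
        (counts.readers[r], counts.slides[s])
        for r, s in zip(*np.nonzero((a == 0) | (b == 0)))
    ]
    if zero_cells:
        warnings.warn(
            f"zero counts replaced by {zero_offset} before log10 in cells "
            f"(reader, slide): {zero_cells}",
            stacklevel=2,
        )
    a = np.where(a == 0, zero_offset, a)
    b = np.where(b == 0, zero_offset, b)
    d = np.log10(a) - np.log10(b)
    mean_log = 0.5 * (np.log10(a) + np.log10(b))
    return LogCountDiffs(
        d=d,
        mean_log=mean_log,
        readers=list(counts.readers),
        slides=list(counts.slides),
        modality=modality,
        reference=reference,
    )


def _two_way_components(d: np.ndarray) -> tuple[float, float, float]:
    """Moment (ANOVA) estimates of reader, slide and residual variance.

    Two-way crossed layout without replication: sigma^2_res = MSE,
    sigma^2_reader = (MSR - MSE)/S, sigma^2_slide = (MSC - MSE)/R, each
    truncated at zero when the moment estimate is negative.
    """
    r, s = d.shape
    grand = d.mean()
    row_means = d.mean(axis=1)
    col_means = d.mean(axis=0)
    msr = s * ((row_means - grand) ** 2).sum() / (r - 1)
    msc = r * ((col_means - grand) ** 2).sum() / (s - 1)
    resid = d - row_means[:, None] - col_means[None, :] + grand
    mse = (resid**2).sum() / ((r - 1) * (s - 1))
    var_reader = max((msr - mse) / s, 0.0)
    var_slide = max((msc - mse) / r, 0.0)
    return float(var_reader), float(var_slide), float(mse)


def ba_summary(diffs: LogCountDiffs) -> BAResult:
    """Bland-Altman summary with MRMC-aware uncertainty.

    With at least two readers and two slides the SD of an individual
    difference is sqrt(sigma^2_reader + sigma^2_slide + sigma^2_res) from
    the two-way decomposition, and the variance of the mean difference is
    sigma^2_reader/R + sigma^2_slide/S + sigma^2_res/(R*S).  With a single
    reader (or slide) the estimate degrades, with a warning, to the naive
    single-rater Bland-Altman formulas.
    """
    d = np.asarray(diffs.d, dtype=float)
    r, s = d.shape
    if d.size < 2:
        raise InsufficientDataError("Bland-Altman summary needs at least 2 differences")
    b = float(d.mean())
    if r >= 2 and s >= 2:
        var_reader, var_slide, var_res = _two_way_components(d)
        sd_diff = float(np.sqrt(var_reader + var_slide + var_res))
        var_mean = var_reader / r + var_slide / s + var_res / (r * s)
        components = {"reader": var_reader, "slide": var_slide, "residual": var_res}
    else:
        warnings.warn(
            "fewer than 2 readers or 2 slides: using naive (single-rater) "
            "Bland-Altman variance",
            stacklevel=2,
        )
        sd_diff = float(d.std(ddof=1))
        var_mean = sd_diff**2 / d.size
        components = {"naive": sd_diff**2}
    half = Z_95 * float(np.sqrt(var_mean))
    return BAResult(
        modality=diffs.modality,
        reference=diffs.reference,
        b=b,
        sd_diff=sd_diff,
        la_low=b - LA_MULTIPLIER * sd_diff,
        la_high=b + LA_MULTIPLIER * sd_diff,
        ci_low=b - half,
        ci_high=b + half,
        variance_components=components,
    )


def plot_bland_altman(diffs: LogCountDiffs, result: BAResult, path) -> None:
    """Scatter of log-count differences vs pair means with b, CI and LA lines.

    One symbol per reader; dotted line at b, dashed lines at the 95% CI for
    b, solid lines at the limits of agreement.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for i, reader in enumerate(diffs.readers):
        ax.scatter(diffs.mean_log[i], diffs.d[i], label=reader, marker="osv^D*"[i % 6])
    ax.axhline(result.b, linestyle=":", color="k")
    for y in (result.ci_low, result.ci_high):
        ax.axhline(y, linestyle="--", color="gray")
    for y in (result.la_low, result.la_high):
        ax.axhline(y, linestyle="-", color="gray")
    ax.set_xlabel("mean log10 count")
    ax.set_ylabel(f"log10({diffs.modality}) - log10({diffs.reference})")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
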