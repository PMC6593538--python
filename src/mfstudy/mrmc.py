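"""Reader-averaged accuracy analysis with clustered (within-slide) variance.

Accuracy of one reader in one modality is the average of sensitivity and
specificity against the adjudicated truth over the pooled candidates.  For
binary determinations this equals the area under the one-threshold ROC
curve and is proportional to Youden's index J = Se + Sp - 1.

Uncertainty treats both readers and cases as random.  The covariance of the
full set of reader-by-modality accuracies is estimated with a
delete-one-slide jackknife, so candidates on the same slide may be
arbitrarily correlated.  Reader-averaged modality accuracies, their
confidence intervals, and scanner-vs-reference z-tests follow from that
covariance; the family of reference comparisons is controlled with the
Holm (sequentially rejective Bonferroni) step-down procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    DegenerateJackknifeError,
    DegenerateTruthError,
    InsufficientDataError,
    ValidationError,
)
from .io import fmt3
from .model import MarkMatrix, TruthSet

VAR_FLOOR = 1e-12


@dataclass(frozen=True)
class SeSp:
    """Sensitivity/specificity of one reader-modality mark vector."""

    sensitivity: float
    specificity: float
    n_true: int
    n_false: int
    tp: int
    fp: int


@dataclass
class AUCMatrix:
    """Accuracies (Se+Sp)/2 indexed (reader, modality)."""

    auc: np.ndarray
    readers: list[str]
    modalities: list[str]

    def reader_average(self, modality: str) -> float:
        return float(self.auc[:, self.modalities.index(modality)].mean())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.auc, index=self.readers, columns=self.modalities)
        df.index.name = "reader_id"
        return df.reset_index()


@dataclass
class CovMatrix:
    """Covariance of all reader-by-modality accuracy estimates.

    Rows/columns are ordered reader-major: cell (r, m) maps to flat index
    r * n_modalities + m.
    """

    cov: np.ndarray
    readers: list[str]
    modalities: list[str]

    def cell_index(self, reader: str, modality: str) -> int:
        return self.readers.index(reader) * len(self.modalities) + self.modalities.index(modality)

    def block(self, modality_a: str, modality_b: str) -> np.ndarray:
        """(reader, reader) covariance block between two modality columns."""
        ia = [self.cell_index(r, modality_a) for r in self.readers]
        ib = [self.cell_index(r, modality_b) for r in self.readers]
        return self.cov[np.ix_(ia, ib)]


@dataclass
class MRMCResult:
    """Reader-averaged modality accuracies and reference comparisons."""

    modality_summary: pd.DataFrame  # modality, avg_auc, se, ci_low, ci_high
    comparisons: pd.DataFrame  # modality, delta, se, z, p, holm_reject
    reference: str
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        merged = self.modality_summary.merge(
            self.comparisons[["modality", "delta_vs_reference", "p_value", "holm_reject"]],
            on="modality",
            how="left",
        )
        merged["avg_auc_display"] = merged["avg_auc"].map(fmt3)
        return merged


def sens_spec(marks: np.ndarray, truth: TruthSet, candidate_ids: list[str]) -> SeSp:
    """Se and Sp of one binary determination vector against the truth labels.

    Sensitivity is the fraction of true mitotic figures the reader marked;
    specificity is one minus the fraction of false candidates marked.
    """
    marks = np.asarray(marks).astype(bool)
    if marks.shape != (len(candidate_ids),):
        raise ValidationError("mark vector and candidate list lengths differ")
    labels = truth.label_vector(candidate_ids)
    n_true = int(labels.sum())
    n_false = int((~labels).sum())
    if n_true == 0 or n_false == 0:
        raise DegenerateTruthError(
            f"truth set needs both classes: n_true={n_true}, n_false={n_false}"
        )
    tp = int(np.sum(marks & labels))
    fp = int(np.sum(marks & ~labels))
    return SeSp(
        sensitivity=tp / n_true,
        specificity=1.0 - fp / n_false,
        n_true=n_true,
        n_false=n_false,
        tp=tp,
        fp=fp,
    )


def binary_auc(s: SeSp) -> float:
    """Average of sensitivity and specificity (one-threshold ROC area)."""
    return (s.sensitivity + s.specificity) / 2.0


def auc_matrix(matrix: MarkMatrix, truth: TruthSet) -> AUCMatrix:
    """One accuracy per (reader, modality) cell."""
    ids = matrix.candidate_ids
    auc = np.array(
        [
            [binary_auc(sens_spec(matrix.marks[r, m], truth, ids)) for m in range(len(matrix.modalities))]
            for r in range(len(matrix.readers))
        ]
    )
    return AUCMatrix(auc=auc, readers=matrix.readers, modalities=matrix.modalities)


def _auc_without_slide(matrix: MarkMatrix, truth: TruthSet, keep: np.ndarray) -> np.ndarray:
    labels = truth.label_vector(matrix.candidate_ids)[keep]
    n_true = int(labels.sum())
    n_false = int((~labels).sum())
    sub = matrix.marks[:, :, keep].astype(bool)
    tp = (sub & labels).sum(axis=2)
    fp = (sub & ~labels).sum(axis=2)
    se = tp / n_true
    sp = 1.0 - fp / n_false
    return (se + sp) / 2.0


def jackknife_cov(matrix: MarkMatrix, truth: TruthSet) -> CovMatrix:
    """Delete-one-slide jackknife covariance of all accuracy cells.

    Slides are the resampling clusters, so within-slide correlation between
    candidates (shared tissue, shared ROIs) propagates into the covariance.
    For G slide groups with leave-one-out estimates theta_(g),
    Cov(i, j) = (G-1)/G * sum_g (theta_i,(g) - mean_i)(theta_j,(g) - mean_j).
    """
    slides = list(dict.fromkeys(matrix.candidate_slides))
    if len(slides) < 2:
        raise InsufficientDataError("jackknife needs at least 2 slide clusters")
    slide_arr = np.array(matrix.candidate_slides)
    labels = truth.label_vector(matrix.candidate_ids)
    thetas = []
    for g in slides:
        keep = slide_arr != g
        kept_labels = labels[keep]
        if kept_labels.sum() == 0 or (~kept_labels).sum() == 0:
            raise DegenerateJackknifeError(
                f"deleting slide {g!r} leaves no true or no false candidates"
            )
        thetas.append(_auc_without_slide(matrix, truth, keep).ravel())
    theta = np.array(thetas)  # (G, R*M), reader-major flattening
    centered = theta - theta.mean(axis=0)
    g = len(slides)
    cov = (g - 1) / g * centered.T @ centered
    return CovMatrix(cov=cov, readers=matrix.readers, modalities=matrix.modalities)


def holm_adjust(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Holm step-down rejection flags, returned in input order.

    Sort ascending and reject while p_(i) <= alpha / (m - i + 1); the first
    failure retains that and every later hypothesis.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=alpha, method="holm")
    return reject


def reader_averaged_analysis(
    aucs: AUCMatrix,
    cov: CovMatrix,
    reference: str,
    alpha: float = 0.05,
) -> MRMCResult:
    """Reader-averaged accuracy per modality and z-tests against the reference.

    The modality average is the plain mean over readers; its variance is the
    mean of the corresponding (reader, reader) covariance block.  For each
    non-reference modality the difference of reader averages is tested with
    a two-sided normal z-test whose variance carries both modality blocks
    and their cross-covariance; the family is Holm-adjusted at ``alpha``.
    """
    if reference not in aucs.modalities:
        raise ValidationError(f"reference modality {reference!r} not present")
    if aucs.readers != cov.readers or aucs.modalities != cov.modalities:
        raise ValidationError("AUC matrix and covariance matrix are not conformable")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    r = len(aucs.readers)

    summary_rows = []
    for m in aucs.modalities:
        avg = aucs.reader_average(m)
        var = float(cov.block(m, m).sum()) / r**2
        se = float(np.sqrt(max(var, 0.0)))
        summary_rows.append(
            {
                "modality": m,
                "avg_auc": avg,
                "se": se,
                "ci_low": avg - stats.norm.ppf(0.975) * se,
                "ci_high": avg + stats.norm.ppf(0.975) * se,
            }
        )
    summary = pd.DataFrame(summary_rows)

    comp_rows = []
    for m in aucs.modalities:
        if m == reference:
            continue
        delta = aucs.reader_average(m) - aucs.reader_average(reference)
        var = (
            cov.block(m, m).sum()
            + cov.block(reference, reference).sum()
            - 2.0 * cov.block(m, reference).sum()
        ) / r**2
        if var <= 0:
            warnings.warn(
                f"non-positive variance for {m!r} vs {reference!r}; "
                f"truncated to {VAR_FLOOR}",
                stacklevel=2,
            )
            var = VAR_FLOOR
        se = float(np.sqrt(var))
        z = delta / se
        p = float(2.0 * stats.norm.sf(abs(z)))
        comp_rows.append(
            {
                "modality": m,
                "delta_vs_reference": float(delta),
                "se_delta": se,
                "z": float(z),
                "p_value": p,
            }
        )
    comparisons = pd.DataFrame(comp_rows)
    if len(comparisons):
        comparisons["holm_reject"] = holm_adjust(comparisons["p_value"].to_numpy(), alpha)
    else:
        comparisons["holm_reject"] = pd.Series(dtype=bool)
    return MRMCResult(
        modality_summary=summary, comparisons=comparisons, reference=reference, alpha=alpha
    )
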