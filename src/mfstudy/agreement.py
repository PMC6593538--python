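"""Cohen's kappa agreement over the pooled candidate set.

The negation universe for every 2x2 table is the full pooled candidate set:
a candidate a rater never marked counts as that rater's negative
determination.  Without a finite universe of candidates the chance-expected
agreement, and hence kappa, would be undefined.

Inter-observer agreement compares reader pairs within one modality;
intra-observer agreement compares modality pairs within one reader.  Kappa
values are binned into the conventional Landis-Koch categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError
from .io import fmt3
from .model import MarkMatrix

LANDIS_KOCH_BINS = (
    (-np.inf, 0.0, "poor"),
    (0.0, 0.2, "slight"),
    (0.2, 0.4, "fair"),
    (0.4, 0.6, "moderate"),
    (0.6, 0.8, "substantial"),
    (0.8, np.inf, "almost perfect"),
)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cross-tabulated binary determinations of two raters over the pool."""

    n11: int  # both positive
    n10: int  # first positive only
    n01: int  # second positive only
    n00: int  # both negative

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValidationError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    observed_agreement: float
    expected_agreement: float
    category: str
    table: ContingencyTable2x2


def two_by_two(a: np.ndarray, b: np.ndarray) -> ContingencyTable2x2:
    """Cross-tabulate two binary determination vectors over the whole pool."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError(
            f"determination vectors must be 1-D and equal length, got {a.shape} vs {b.shape}"
        )
    return ContingencyTable2x2(
        n11=int(np.sum(a & b)),
        n10=int(np.sum(a & ~b)),
        n01=int(np.sum(~a & b)),
        n00=int(np.sum(~a & ~b)),
    )


def landis_koch(kappa: float) -> str:
    """Agreement category per the conventional half-open kappa bins."""
    if kappa > 1:
        raise ValidationError(f"kappa cannot exceed 1, got {kappa}")
    for lo, hi, label in LANDIS_KOCH_BINS:
        if lo <= kappa < hi:
            return label
    return "almost perfect"  # kappa == +inf unreachable; kappa == 1 falls here


def cohen_kappa(t: ContingencyTable2x2) -> KappaResult:
    """Cohen's kappa for one 2x2 table.

    p_o = (n11+n00)/N and p_e = [(n11+n10)(n11+n01) + (n01+n00)(n10+n00)]/N^2;
    kappa = (p_o - p_e)/(1 - p_e).  When both raters are unanimous with the
    same label, p_e = 1 and the ratio is indeterminate; agreement is then
    perfect, so kappa is defined as 1 (with a warning) rather than NaN.
    """
    n = t.total
    if n == 0:
        raise InsufficientDataError("empty contingency table")
    p_o = (t.n11 + t.n00) / n
    p_e = ((t.n11 + t.n10) * (t.n11 + t.n01) + (t.n01 + t.n00) * (t.n10 + t.n00)) / n**2
    if p_e >= 1.0 - 1e-15:
        warnings.warn(
            "both raters unanimous: chance agreement is 1; kappa defined as 1",
            stacklevel=2,
        )
        kappa = 1.0
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return KappaResult(
        kappa=float(kappa),
        observed_agreement=float(p_o),
        expected_agreement=float(p_e),
        category=landis_koch(float(kappa)),
        table=t,
    )


def _pair_frame(results: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(results)
    df["kappa_display"] = df["kappa"].map(fmt3)
    return df


def inter_observer_matrix(matrix: MarkMatrix, modality: str) -> pd.DataFrame:
    """Pairwise reader kappas within one modality, over the full pool.

    Returns one row per unordered reader pair with the kappa, its category
    and the underlying 2x2 counts.
    """
    if len(matrix.readers) < 2:
        raise InsufficientDataError("inter-observer agreement needs at least 2 readers")
    rows = []
    for i, ra in enumerate(matrix.readers):
        for rb in matrix.readers[i + 1 :]:
            res = cohen_kappa(two_by_two(matrix.vector(ra, modality), matrix.vector(rb, modality)))
            rows.append(
                {
                    "modality": modality,
                    "reader_a": ra,
                    "reader_b": rb,
                    "kappa": res.kappa,
                    "category": res.category,
                    "n11": res.table.n11,
                    "n10": res.table.n10,
                    "n01": res.table.n01,
                    "n00": res.table.n00,
                }
            )
    return _pair_frame(rows)


def intra_observer_matrix(matrix: MarkMatrix, reader: str) -> pd.DataFrame:
    """Pairwise modality kappas for one reader, over the full pool."""
    if len(matrix.modalities) < 2:
        raise InsufficientDataError("intra-observer agreement needs at least 2 modalities")
    rows = []
    for i, ma in enumerate(matrix.modalities):
        for mb in matrix.modalities[i + 1 :]:
            res = cohen_kappa(two_by_two(matrix.vector(reader, ma), matrix.vector(reader, mb)))
            rows.append(
                {
                    "reader": reader,
                    "modality_a": ma,
                    "modality_b": mb,
                    "kappa": res.kappa,
                    "category": res.category,
                    "n11": res.table.n11,
                    "n10": res.table.n10,
                    "n01": res.table.n01,
                    "n00": res.table.n00,
                }
            )
    return _pair_frame(rows)


def kappa_range(*tables) -> tuple[float, float]:
    """(min, max) kappa over any mix of pair tables, KappaResults and floats."""
    values: list[float] = []
    for t in tables:
        if isinstance(t, pd.DataFrame):
            values.extend(float(v) for v in t["kappa"])
        elif isinstance(t, KappaResult):
            values.append(t.kappa)
        elif np.isscalar(t):
            values.append(float(t))
        else:
            values.extend(float(v) for v in t)
    if not values:
        raise InsufficientDataError("kappa_range needs at least one kappa value")
    return min(values), max(values)
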