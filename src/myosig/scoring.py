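"""Count normalization and per-observation signature scoring.

A signature score is the plain sum of log-normalized expression over the
signature's genes — not a mean — so the score scale grows with signature
size.  Scores are therefore only comparable within one dataset, and the
published analyses always report them after subtracting a control-group
average (:func:`center_scores`).

Two normalization conventions are provided:

* ``bulk_median_of_ratios`` — DESeq2-style size factors (median over genes of
  the ratio to the per-gene geometric mean across samples) followed by
  ``log2(x + 1)``;
* ``sc_library_size`` — per-10k library-size scaling followed by ``log1p``,
  the common single-cell convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix, GeneSignature, LOG_NORMALIZED, NORMALIZED, RAW_COUNTS

__all__ = [
    "ScoreTable",
    "size_factors_median_of_ratios",
    "log_normalize",
    "linear_normalize",
    "score_signature",
    "score_signatures",
    "center_scores",
]

logger = logging.getLogger(__name__)

#: default coverage below which a warning is logged; analyses proceed anyway
DEFAULT_COVERAGE_WARN = 0.75


@dataclass
class ScoreTable:
    """Per-observation signature scores with coverage metadata."""

    signature: str
    scores: pd.Series  # index = obs ids
    coverage: float
    genes_used: tuple[str, ...]
    centering_reference: dict | None = None  # {"control_ids": [...], "subtracted_mean": float}
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.coverage <= 1:
            raise ValueError(f"coverage must lie in (0, 1], got {self.coverage}")

    @property
    def obs_ids(self) -> list[str]:
        return list(self.scores.index)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "sample_id": self.scores.index,
                "signature": self.signature,
                "score": self.scores.to_numpy(),
                "coverage": self.coverage,
            }
        )
        if self.centering_reference is not None:
            df["centered"] = True
        return df


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, anchored so normalization is exactly
    scale invariant per sample.

    The ratio step runs on composition-normalized counts (each sample
    divided by its mean count per gene, ``N_j / G``): the per-gene reference
    is the geometric mean of these compositions over samples, taken over the
    genes nonzero in every sample, and the median ratio to that reference is
    the sample's composition factor.  The size factor re-attaches the
    library scale, ``sf_j = (N_j / G) * median_ratio_j``.

    Because the reference depends only on compositions, multiplying one
    sample's counts by a constant multiplies exactly that sample's size
    factor by the same constant and leaves every normalized value in the
    matrix untouched.  The factors agree with the classical DESeq2
    construction up to the dataset-wide constant ``geomean(N) / G`` (the
    medians are homogeneous, so the proportionality is exact).
    """
    arr = counts.to_numpy(dtype=float)
    n_genes = arr.shape[0]
    totals = arr.sum(axis=0)
    if (totals == 0).any():
        bad = counts.columns[np.where(totals == 0)[0][0]]
        raise ValueError(f"sample {bad!r} has zero total counts")
    comp = arr * (n_genes / totals)
    with np.errstate(divide="ignore"):
        log_comp = np.log(comp)
    finite = np.isfinite(log_comp).all(axis=1)
    if not finite.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; "
            "median-of-ratios is undefined (consider sc_library_size mode)"
        )
    log_ref = log_comp[finite].mean(axis=1)
    median_ratio = np.exp(np.median(log_comp[finite] - log_ref[:, None], axis=0))
    sf = (totals / n_genes) * median_ratio
    return pd.Series(sf, index=counts.columns, name="size_factor")


def linear_normalize(m: CountMatrix, mode: str = "sc_library_size", scale: float = 1e4) -> CountMatrix:
    """Linear (non-log) normalized expression; used for fold-change means."""
    if m.layer != RAW_COUNTS:
        raise ValueError(f"expected raw counts, got layer {m.layer!r}")
    arr = m.values.to_numpy(dtype=float)
    if mode == "sc_library_size":
        totals = arr.sum(axis=0)
        if (totals == 0).any():
            bad = m.values.columns[np.where(totals == 0)[0][0]]
            raise ValueError(f"observation {bad!r} has zero total counts")
        norm = arr / totals * scale
    elif mode == "bulk_median_of_ratios":
        sf = size_factors_median_of_ratios(m.values).to_numpy()
        norm = arr / sf
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return CountMatrix(pd.DataFrame(norm, index=m.values.index, columns=m.values.columns), layer=NORMALIZED)


def log_normalize(m: CountMatrix, mode: str = "bulk_median_of_ratios", log_base: float | None = None) -> CountMatrix:
    """Log-normalize raw counts.

    ``bulk_median_of_ratios``: value = log2(count / size_factor + 1)
    (base configurable via ``log_base``).
    ``sc_library_size``: value = ln(count / library_size × 10,000 + 1).
    """
    if m.layer != RAW_COUNTS:
        raise ValueError(f"expected raw counts, got layer {m.layer!r}")
    lin = linear_normalize(m, mode=mode)
    arr = lin.values.to_numpy()
    if mode == "bulk_median_of_ratios":
        base = 2.0 if log_base is None else log_base
        out = np.log1p(arr) / np.log(base)
    else:
        base = np.e if log_base is None else log_base
        out = np.log1p(arr) / np.log(base)
    return CountMatrix(pd.DataFrame(out, index=m.values.index, columns=m.values.columns), layer=LOG_NORMALIZED)


def score_signature(
    m: CountMatrix,
    sig: GeneSignature,
    coverage_warn: float = DEFAULT_COVERAGE_WARN,
) -> ScoreTable:
    """Sum of log-normalized expression over the signature's genes, per observation.

    Genes absent from the matrix are excluded from the signature for this
    analysis; the retained fraction is recorded as ``coverage`` and a warning
    is logged when it falls below ``coverage_warn``.
    """
    if m.layer != LOG_NORMALIZED:
        raise ValueError(f"expected log-normalized matrix, got layer {m.layer!r}")
    present = [g for g in sig.genes if g in m.values.index]
    if not present:
        raise ValueError(f"no gene of signature {sig.name!r} is present in the matrix")
    coverage = len(present) / len(sig.genes)
    if coverage < coverage_warn:
        logger.warning(
            "signature %r coverage %.2f below %.2f (%d/%d genes present)",
            sig.name, coverage, coverage_warn, len(present), len(sig.genes),
        )
    scores = m.values.loc[present].sum(axis=0)
    scores.name = sig.name
    return ScoreTable(signature=sig.name, scores=scores, coverage=coverage, genes_used=tuple(present))


def score_signatures(m: CountMatrix, sigs: Sequence[GeneSignature], **kw) -> list[ScoreTable]:
    return [score_signature(m, s, **kw) for s in sigs]


def center_scores(s: ScoreTable, control_ids: Sequence[str]) -> ScoreTable:
    """Subtract the arithmetic mean of the control observations' scores."""
    control_ids = list(control_ids)
    if not control_ids:
        raise ValueError("control_ids must be non-empty")
    missing = [c for c in control_ids if c not in s.scores.index]
    if missing:
        raise KeyError(f"control ids not found in score table: {missing}")
    mean = float(s.scores.loc[control_ids].mean())
    return ScoreTable(
        signature=s.signature,
        scores=s.scores - mean,
        coverage=s.coverage,
        genes_used=s.genes_used,
        centering_reference={"control_ids": control_ids, "subtracted_mean": mean},
        meta=dict(s.meta),
    )
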