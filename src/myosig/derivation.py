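"""Derivation of cluster-restricted gene signatures from clustered counts.

The procedure mirrors the marker-filter-plus-grid-search recipe used to
derive the packaged myogenic signatures: candidate markers are genes that
(i) are differentially expressed between the target population and all other
cells, (ii) show a fold-change increase in mean normalized expression in the
target above a threshold, and (iii) are detected (raw count > 0) in less
than a threshold fraction of all other cells globally and of the cells in
any single other cluster.  A grid over the three thresholds (by default
3 × 3 × 3 = 27 combinations) yields one candidate gene list each; lists
below a minimum size are discarded, and the winner is the list whose score
best separates the target population in an independent validation dataset
by ROC AUC.

All threshold comparisons are strict (``>`` fold change, ``<`` detection),
matching the published filter wording.

The grid search is exposed both as plain functions and as the
:class:`SignatureDerivation` model whose :meth:`~SignatureDerivation.fit`
returns a :class:`SignatureDerivationResults` with the candidate table and
the selected signature.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .evaluation import auc as _auc
from .io import CountMatrix, ClusterAnnotation, GeneSignature, RAW_COUNTS
from .scoring import linear_normalize, log_normalize, score_signature

__all__ = [
    "SelectionThresholds",
    "SelectionGrid",
    "MarkerStats",
    "CandidateResult",
    "PUBLISHED_GRID",
    "detection_fraction",
    "compute_marker_stats",
    "apply_thresholds",
    "enumerate_grid",
    "select_signature",
    "SignatureDerivation",
    "SignatureDerivationResults",
]


@dataclass(frozen=True, order=True)
class SelectionThresholds:
    """One point of the selection grid.

    min_fold_change
        genes must exceed this ratio of mean normalized expression
        (target vs all other cells).
    max_global_detection
        genes must be detected in less than this fraction of all
        non-target cells.
    max_cluster_detection
        genes must be detected in less than this fraction of cells within
        every single non-target cluster.
    """

    min_fold_change: float
    max_global_detection: float
    max_cluster_detection: float

    def __post_init__(self) -> None:
        if not self.min_fold_change > 1:
            raise ValueError("min_fold_change must be > 1")
        for f, what in (
            (self.max_global_detection, "max_global_detection"),
            (self.max_cluster_detection, "max_cluster_detection"),
        ):
            if not 0 < f < 1:
                raise ValueError(f"{what} must lie in (0, 1), got {f}")


@dataclass(frozen=True)
class SelectionGrid:
    fold_change_values: tuple[float, ...]
    global_detection_values: tuple[float, ...]
    cluster_detection_values: tuple[float, ...]

    def __post_init__(self) -> None:
        for name in ("fold_change_values", "global_detection_values", "cluster_detection_values"):
            vals = tuple(getattr(self, name))
            object.__setattr__(self, name, vals)
            if not vals:
                raise ValueError(f"{name} must be non-empty")
            if list(vals) != sorted(set(vals)):
                raise ValueError(f"{name} must be strictly sorted ascending")
        # validate every combination through SelectionThresholds
        SelectionThresholds(
            self.fold_change_values[0],
            self.global_detection_values[0],
            self.cluster_detection_values[0],
        )
        SelectionThresholds(
            self.fold_change_values[-1],
            self.global_detection_values[-1],
            self.cluster_detection_values[-1],
        )


#: the published 27-point grid: fold change 1.5/1.75/2.0, global detection
#: 5/10/15 %, per-cluster detection 20/30/40 %
PUBLISHED_GRID = SelectionGrid(
    fold_change_values=(1.5, 1.75, 2.0),
    global_detection_values=(0.05, 0.10, 0.15),
    cluster_detection_values=(0.20, 0.30, 0.40),
)

#: the published headline thresholds (>1.5-fold, <10 % global, <30 % per cluster)
PUBLISHED_THRESHOLDS = SelectionThresholds(1.5, 0.10, 0.30)


@dataclass
class MarkerStats:
    """Per-gene marker statistics for one target population.

    ``table`` columns: mean_target, mean_rest, fold_change, detect_target,
    detect_global_other, detect_max_other_cluster, de_pvalue, de_qvalue.
    """

    table: pd.DataFrame
    target_clusters: frozenset[str]
    pseudocount: float

    def __post_init__(self) -> None:
        req = {
            "mean_target", "mean_rest", "fold_change", "detect_target",
            "detect_global_other", "detect_max_other_cluster", "de_qvalue",
        }
        missing = req - set(self.table.columns)
        if missing:
            raise ValueError(f"marker-stats table missing columns: {sorted(missing)}")


@dataclass
class CandidateResult:
    thresholds: SelectionThresholds
    genes: tuple[str, ...]
    passed_min_size: bool
    validation_auc: float | None = None


def detection_fraction(m: CountMatrix, obs_subset: Sequence[str]) -> pd.Series:
    """Fraction of observations in the subset with a nonzero raw count, per gene."""
    obs_subset = list(obs_subset)
    if not obs_subset:
        raise ValueError("obs_subset must be non-empty")
    sub = m.subset_obs(obs_subset)
    frac = (sub.values.to_numpy() > 0).mean(axis=1)
    return pd.Series(frac, index=m.values.index, name="detection_fraction")


def compute_marker_stats(
    m: CountMatrix,
    ann: ClusterAnnotation,
    pseudocount: float = 0.01,
    de_prefilter: bool = True,
    de_adjust: str = "bonferroni",
) -> MarkerStats:
    """Per-gene fold change, detection fractions and DE q-values, target vs rest.

    Counts are library-size normalized internally (linear per-10k scaling);
    fold change is the ratio of linear normalized means with ``pseudocount``
    added to numerator and denominator.  Detection uses raw counts.  The DE
    prefilter is a two-sided Wilcoxon rank-sum on normalized expression;
    adjusted p-values use Bonferroni by default (the single-cell marker-test
    convention, family-wise) — pass ``de_adjust='fdr_bh'`` for
    Benjamini–Hochberg, or ``de_prefilter=False`` to skip the test
    (q-values are then reported as 0, disabling the filter).
    """
    if m.layer != RAW_COUNTS:
        raise ValueError(f"expected raw counts, got layer {m.layer!r}")
    ann.check_matches(m)
    if not ann.target_clusters:
        raise ValueError("annotation designates no target clusters")
    tmask = ann.target_mask()
    if tmask.all():
        raise ValueError("target population covers every observation; no 'other' cells")
    other_clusters = [c for c in ann.clusters if c not in ann.target_clusters]
    if not other_clusters:
        raise ValueError("single-cluster annotation: no non-target cluster to compare against")

    raw = m.values.to_numpy()
    norm = linear_normalize(m).values.to_numpy()

    mean_target = norm[:, tmask].mean(axis=1)
    mean_rest = norm[:, ~tmask].mean(axis=1)
    fold_change = (mean_target + pseudocount) / (mean_rest + pseudocount)

    detected = raw > 0
    detect_target = detected[:, tmask].mean(axis=1)
    detect_global_other = detected[:, ~tmask].mean(axis=1)
    labels = ann.labels.to_numpy()
    per_cluster = np.column_stack(
        [detected[:, labels == c].mean(axis=1) for c in other_clusters]
    )
    detect_max_other_cluster = per_cluster.max(axis=1)

    if de_prefilter:
        res = scipy.stats.mannwhitneyu(
            norm[:, tmask], norm[:, ~tmask], axis=1, alternative="two-sided"
        )
        pvals = np.asarray(res.pvalue, dtype=float)
        if de_adjust not in ("bonferroni", "fdr_bh"):
            raise ValueError(f"unknown de_adjust {de_adjust!r}")
        qvals = multipletests(pvals, method=de_adjust)[1]
    else:
        pvals = np.zeros(m.n_genes)
        qvals = np.zeros(m.n_genes)

    table = pd.DataFrame(
        {
            "mean_target": mean_target,
            "mean_rest": mean_rest,
            "fold_change": fold_change,
            "detect_target": detect_target,
            "detect_global_other": detect_global_other,
            "detect_max_other_cluster": detect_max_other_cluster,
            "de_pvalue": pvals,
            "de_qvalue": qvals,
        },
        index=m.values.index,
    )
    return MarkerStats(table=table, target_clusters=ann.target_clusters, pseudocount=pseudocount)


def apply_thresholds(
    stats: MarkerStats, t: SelectionThresholds, de_alpha: float = 0.05
) -> tuple[str, ...]:
    """Genes passing every filter, ordered by descending fold change.

    All comparisons are strict: fold change must exceed ``min_fold_change``
    and detection fractions must fall below their maxima.
    """
    tab = stats.table
    keep = (
        (tab["de_qvalue"] < de_alpha)
        & (tab["fold_change"] > t.min_fold_change)
        & (tab["detect_global_other"] < t.max_global_detection)
        & (tab["detect_max_other_cluster"] < t.max_cluster_detection)
    )
    sel = tab.loc[keep].sort_values("fold_change", ascending=False, kind="mergesort")
    return tuple(sel.index)


def enumerate_grid(g: SelectionGrid) -> list[SelectionThresholds]:
    """Cartesian product of the grid, fold change outermost, cluster detection innermost."""
    return [
        SelectionThresholds(fc, gd, cd)
        for fc, gd, cd in itertools.product(
            g.fold_change_values, g.global_detection_values, g.cluster_detection_values
        )
    ]


def _candidate_sort_key(c: CandidateResult):
    # maximal AUC (rounded so float noise cannot split a genuine tie),
    # then fewer genes, then lexicographically first gene list
    return (-round(c.validation_auc, 12), len(c.genes), c.genes)


def select_signature(
    candidates: Sequence[CandidateResult],
    validation: CountMatrix,
    validation_labels: Sequence[bool],
    min_size: int = 10,
    name: str = "signature",
    species: str = "human",
) -> tuple[GeneSignature, list[CandidateResult]]:
    """Pick the candidate list that best separates the validation labels by AUC.

    Candidates smaller than ``min_size`` are discarded.  The validation
    matrix may be raw (it is then log-normalized with the single-cell
    convention) or already log-normalized.  Ties on AUC are broken by
    smaller gene count, then lexicographic gene order.  Returns the winning
    signature (provenance records the winning thresholds) plus all evaluated
    candidates with their AUCs filled in.
    """
    if validation.layer == RAW_COUNTS:
        validation = log_normalize(validation, mode="sc_library_size")
    labels = np.asarray(validation_labels)
    eligible: list[CandidateResult] = []
    evaluated: list[CandidateResult] = []
    for c in candidates:
        passed = len(c.genes) >= min_size
        c = CandidateResult(c.thresholds, tuple(c.genes), passed, c.validation_auc)
        if passed and c.genes:
            sig = GeneSignature(name="candidate", genes=c.genes, species=species)
            try:
                st = score_signature(validation, sig.intersect(validation.gene_ids))
            except ValueError:
                evaluated.append(c)
                continue
            c.validation_auc = _auc(st.scores.to_numpy(), labels)
            eligible.append(c)
        evaluated.append(c)
    if not eligible:
        raise ValueError(
            f"no candidate gene list reached the minimum size of {min_size}; "
            "relax the selection grid (smaller fold change, larger detection maxima)"
        )
    best = min(eligible, key=_candidate_sort_key)
    sig = GeneSignature(
        name=name,
        genes=best.genes,
        species=species,
        provenance={
            "min_fold_change": best.thresholds.min_fold_change,
            "max_global_detection": best.thresholds.max_global_detection,
            "max_cluster_detection": best.thresholds.max_cluster_detection,
            "validation_auc": best.validation_auc,
            "min_size": min_size,
        },
    )
    return sig, evaluated


# ---------------------------------------------------------------------------
# model / results surface


class SignatureDerivation:
    """Grid-search signature derivation as a fit-to-data model.

    Parameters
    ----------
    counts, annotation
        Clustered raw single-cell counts (the derivation dataset) and the
        cluster annotation designating the target population.
    grid
        Selection-threshold grid; defaults to the published 27-point grid.
    min_size
        Minimum candidate size carried forward (default 10).
    thresholds
        If given, skip the grid search and apply this fixed threshold
        combination (the mode used for the myoblast/myocyte and myonuclear
        signatures, which reused the satellite-optimal thresholds).
    pseudocount, de_alpha, de_prefilter
        Fold-change pseudocount and DE-prefilter settings passed through to
        :func:`compute_marker_stats` / :func:`apply_thresholds`.
    """

    def __init__(
        self,
        counts: CountMatrix,
        annotation: ClusterAnnotation,
        grid: SelectionGrid = PUBLISHED_GRID,
        min_size: int = 10,
        thresholds: SelectionThresholds | None = None,
        pseudocount: float = 0.01,
        de_alpha: float = 0.05,
        de_prefilter: bool = True,
        de_adjust: str = "bonferroni",
    ) -> None:
        annotation.check_matches(counts)
        self.counts = counts
        self.annotation = annotation
        self.grid = grid
        self.min_size = min_size
        self.thresholds = thresholds
        self.pseudocount = pseudocount
        self.de_alpha = de_alpha
        self.de_prefilter = de_prefilter
        self.de_adjust = de_adjust
        self._stats: MarkerStats | None = None

    @property
    def marker_stats(self) -> MarkerStats:
        if self._stats is None:
            self._stats = compute_marker_stats(
                self.counts, self.annotation,
                pseudocount=self.pseudocount, de_prefilter=self.de_prefilter,
                de_adjust=self.de_adjust,
            )
        return self._stats

    def candidates(self) -> list[CandidateResult]:
        points = [self.thresholds] if self.thresholds is not None else enumerate_grid(self.grid)
        out = []
        for t in points:
            genes = apply_thresholds(self.marker_stats, t, de_alpha=self.de_alpha)
            out.append(CandidateResult(t, genes, len(genes) >= self.min_size))
        return out

    def fit(
        self,
        validation_counts: CountMatrix,
        validation_labels: Sequence[bool],
        name: str = "signature",
        species: str = "human",
    ) -> "SignatureDerivationResults":
        sig, evaluated = select_signature(
            self.candidates(), validation_counts, validation_labels,
            min_size=self.min_size, name=name, species=species,
        )
        return SignatureDerivationResults(model=self, signature=sig, candidates=evaluated)


@dataclass
class SignatureDerivationResults:
    """Fitted derivation: the selected signature plus the full candidate table."""

    model: SignatureDerivation
    signature: GeneSignature
    candidates: list[CandidateResult] = field(repr=False)

    def candidates_frame(self) -> pd.DataFrame:
        rows = [
            {
                "min_fold_change": c.thresholds.min_fold_change,
                "max_global_detection": c.thresholds.max_global_detection,
                "max_cluster_detection": c.thresholds.max_cluster_detection,
                "n_genes": len(c.genes),
                "passed_min_size": c.passed_min_size,
                "validation_auc": c.validation_auc,
            }
            for c in self.candidates
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        prov = self.signature.provenance or {}
        df = self.candidates_frame()
        lines = [
            "Signature derivation results",
            "=" * 60,
            f"Target clusters:      {sorted(self.model.annotation.target_clusters)}",
            f"Grid points:          {len(self.candidates)}",
            f"Candidates >= {self.model.min_size} genes: "
            f"{int(df['passed_min_size'].sum())}",
            f"Selected signature:   {self.signature.name} "
            f"({len(self.signature.genes)} genes)",
            f"Winning thresholds:   fold change > {prov.get('min_fold_change')}, "
            f"global detection < {prov.get('max_global_detection')}, "
            f"cluster detection < {prov.get('max_cluster_detection')}",
            f"Validation AUC:       {prov.get('validation_auc'):.4f}"
            if prov.get("validation_auc") is not None else "Validation AUC:       n/a",
            "-" * 60,
            "Genes (by descending fold change):",
            ", ".join(self.signature.genes),
        ]
        return "\n".join(lines)
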