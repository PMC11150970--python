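"""Score–phenotype association and the random-gene-set resampling null.

The central question: does a curated signature's score track an external
per-sample measurement (e.g., PAX7+ satellite cells per myofiber counted
histologically) better than size-matched random gene sets drawn from the
same expression matrix?  The observed statistic is the Spearman correlation
of the signature score with the measurement; the null distribution is the
same statistic over ``n_resamples`` random gene sets of equal size, and the
empirical p-value uses the add-one estimator (k+1)/(n+1), so the smallest
attainable p with 1000 resamples is 1/1001 — reported as p < 0.001 when no
random set out-performs the signature.

Also houses the group-comparison dispatch used in the published figures:
Wilcoxon (signed-rank when paired, rank-sum otherwise) for two groups, and
one-way ANOVA with Tukey's post-hoc — or Kruskal–Wallis with Dunn's
post-hoc when per-group normality fails — for three or more.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io import CountMatrix, GeneSignature, LOG_NORMALIZED
from .scoring import ScoreTable, score_signature

__all__ = [
    "ResamplingResult",
    "spearman",
    "resampling_null",
    "RandomSetNull",
    "group_compare",
    "significance_stars",
]


def significance_stars(p: float) -> str:
    for cut, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")):
        if p < cut:
            return stars
    return "ns"


# ---------------------------------------------------------------------------
# Spearman correlation


def spearman(x, y, seed: int = 0, n_mc: int = 20_000) -> tuple[float, float]:
    """Spearman rank correlation with a small-sample permutation p-value.

    rho is the Pearson correlation of mid-ranks (average ranks on ties).
    The two-sided p-value uses the t-approximation for n > 10; for n <= 10
    it enumerates all rank permutations when feasible (n <= 7) and falls
    back to seeded Monte-Carlo otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D vectors")
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector: Spearman rho is undefined")
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n > 10:
        p = float(scipy.stats.spearmanr(x, y).pvalue)
        return rho, p
    # permutation p-value on |rho|
    def _rho(perm_ry: np.ndarray) -> float:
        return float(np.corrcoef(rx, perm_ry)[0, 1])

    obs = abs(rho)
    tol = 1e-12
    if n <= 7:
        perms = itertools.permutations(ry)
        count = total = 0
        for perm in perms:
            total += 1
            if abs(_rho(np.array(perm))) >= obs - tol:
                count += 1
        return rho, count / total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_mc):
        if abs(_rho(rng.permutation(ry))) >= obs - tol:
            count += 1
    return rho, (count + 1) / (n_mc + 1)


# ---------------------------------------------------------------------------
# resampling null


@dataclass
class ResamplingResult:
    """Observed Spearman rho against a random-gene-set null distribution."""

    observed_stat: float
    null_stats: np.ndarray
    n_resamples: int
    empirical_p: float
    seed: int
    gene_universe_size: int
    signature: str = ""
    alternative: str = "greater"

    def __post_init__(self) -> None:
        if len(self.null_stats) != self.n_resamples:
            raise ValueError("null_stats length must equal n_resamples")

    def summary(self) -> str:
        thresh = 1 / (self.n_resamples + 1)
        p_str = f"p < {math.ceil(thresh * 1000) / 1000:g}" if self.empirical_p <= thresh else f"p = {self.empirical_p:.4g}"
        return "\n".join(
            [
                "Random-gene-set resampling null",
                "=" * 50,
                f"Signature:          {self.signature or 'n/a'}",
                f"Observed Spearman:  {self.observed_stat:.4f}",
                f"Resamples:          {self.n_resamples} sets "
                f"(universe of {self.gene_universe_size} genes, seed {self.seed})",
                f"Null rho range:     [{self.null_stats.min():.4f}, {self.null_stats.max():.4f}]",
                f"Sets out-performing the signature: "
                f"{int((self.null_stats >= self.observed_stat).sum())}",
                f"Empirical p:        {self.empirical_p:.6f} ({p_str})",
            ]
        )


def resampling_null(
    m: CountMatrix,
    signature: GeneSignature,
    external,
    sig_size: int | None = None,
    n_resamples: int = 1000,
    seed: int = 0,
    universe: list[str] | None = None,
    alternative: str = "greater",
) -> ResamplingResult:
    """Compare a signature's score–measurement correlation with random sets.

    For each resample, ``sig_size`` genes (default: the signature's size)
    are drawn uniformly without replacement from ``universe`` (default:
    genes with nonzero expression in at least one sample), scored, and
    correlated with ``external``.  ``alternative='greater'`` counts null
    rho >= observed rho (the one-sided "out-performed" reading);
    ``'two-sided'`` compares |rho|.
    """
    if m.layer != LOG_NORMALIZED:
        raise ValueError(f"expected log-normalized matrix, got layer {m.layer!r}")
    external = np.asarray(external, dtype=float)
    if external.size != m.n_obs:
        raise ValueError("external measurements must have one value per observation")
    if universe is None:
        nonzero = (m.values.to_numpy() > 0).any(axis=1)
        universe = list(m.values.index[nonzero])
    if sig_size is None:
        sig_size = len(signature.intersect(m.gene_ids).genes)
    if len(universe) < sig_size:
        raise ValueError(
            f"gene universe ({len(universe)}) smaller than signature size ({sig_size})"
        )

    if np.ptp(external) == 0:
        raise ValueError("constant external measurement: Spearman rho is undefined")

    def _rho(v: np.ndarray) -> float:
        if np.ptp(v) == 0:
            return 0.0  # constant random-set score carries no association
        return float(np.corrcoef(scipy.stats.rankdata(v), ext_ranks)[0, 1])

    ext_ranks = scipy.stats.rankdata(external)
    obs_scores = score_signature(m, signature.intersect(m.gene_ids)).scores.to_numpy()
    observed = _rho(obs_scores)

    rng = np.random.default_rng(seed)
    arr = m.values.loc[universe].to_numpy()
    null = np.empty(n_resamples)
    for i in range(n_resamples):
        idx = rng.choice(len(universe), size=sig_size, replace=False)
        null[i] = _rho(arr[idx].sum(axis=0))

    if alternative == "greater":
        k = int((null >= observed).sum())
    elif alternative == "two-sided":
        k = int((np.abs(null) >= abs(observed)).sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    emp_p = (k + 1) / (n_resamples + 1)
    return ResamplingResult(
        observed_stat=observed,
        null_stats=null,
        n_resamples=n_resamples,
        empirical_p=emp_p,
        seed=seed,
        gene_universe_size=len(universe),
        signature=signature.name,
        alternative=alternative,
    )


class RandomSetNull:
    """Model-style wrapper around :func:`resampling_null`.

    ``RandomSetNull(matrix, signature, external).fit(seed=...)`` returns a
    :class:`ResamplingResult`.
    """

    def __init__(
        self,
        m: CountMatrix,
        signature: GeneSignature,
        external,
        n_resamples: int = 1000,
        universe: list[str] | None = None,
        alternative: str = "greater",
    ) -> None:
        self.m = m
        self.signature = signature
        self.external = external
        self.n_resamples = n_resamples
        self.universe = universe
        self.alternative = alternative

    def fit(self, seed: int = 0) -> ResamplingResult:
        return resampling_null(
            self.m, self.signature, self.external,
            n_resamples=self.n_resamples, seed=seed,
            universe=self.universe, alternative=self.alternative,
        )


# ---------------------------------------------------------------------------
# group comparisons


def _dunn_posthoc(values: list[np.ndarray], names: list[str]) -> list[dict]:
    """Dunn's z-tests on pooled mid-ranks with tie correction (unadjusted p)."""
    pooled = np.concatenate(values)
    n_total = pooled.size
    ranks = scipy.stats.rankdata(pooled)
    # tie correction term
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12 - tie_term
    mean_ranks, sizes = [], []
    start = 0
    for v in values:
        mean_ranks.append(ranks[start:start + v.size].mean())
        sizes.append(v.size)
        start += v.size
    rows = []
    for i, j in itertools.combinations(range(len(values)), 2):
        se = math.sqrt(var_base * (1 / sizes[i] + 1 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2 * scipy.stats.norm.sf(abs(z))
        rows.append(
            {"comparison": f"{names[i]} vs {names[j]}", "method": "Dunn",
             "statistic": z, "pvalue": p}
        )
    return rows


def group_compare(
    scores: ScoreTable | pd.Series,
    groups: pd.Series,
    design: str = "two_group_unpaired",
    normality_ok: bool | None = None,
    pairs: pd.Series | None = None,
) -> pd.DataFrame:
    """Dispatch the group-comparison tests used in the published figures.

    ``two_group_unpaired`` → Wilcoxon rank-sum; ``two_group_paired`` →
    Wilcoxon signed-rank on pairs matched via ``pairs`` (a sample → pair-id
    map); ``multi_group`` → one-way ANOVA with Tukey's post-hoc when each
    group passes Shapiro–Wilk normality (or ``normality_ok=True``), else
    Kruskal–Wallis with Dunn's post-hoc.  Returns one row per comparison
    with statistic, p-value and significance stars (0.05/0.01/0.001/0.0001).
    """
    s = scores.scores if isinstance(scores, ScoreTable) else scores
    groups = groups.reindex(s.index)
    if groups.isna().any():
        raise ValueError("every observation needs a group label")
    names = list(pd.unique(groups))
    values = [s[groups == g].to_numpy(dtype=float) for g in names]
    if any(v.size < 2 for v in values):
        raise ValueError("each group needs at least 2 observations")

    rows: list[dict] = []
    if design == "two_group_unpaired":
        if len(names) != 2:
            raise ValueError(f"two-group design but {len(names)} groups found")
        res = scipy.stats.mannwhitneyu(values[0], values[1], alternative="two-sided")
        rows.append({"comparison": f"{names[0]} vs {names[1]}",
                     "method": "Wilcoxon rank-sum", "statistic": float(res.statistic),
                     "pvalue": float(res.pvalue)})
    elif design == "two_group_paired":
        if len(names) != 2:
            raise ValueError(f"two-group design but {len(names)} groups found")
        if pairs is None:
            raise ValueError("paired design requires a pairs series (sample -> pair id)")
        pairs = pairs.reindex(s.index)
        a = s[groups == names[0]]
        b = s[groups == names[1]]
        pa = pairs[a.index]
        pb = pairs[b.index]
        common = pa[pa.isin(pb.values)]
        unpaired = sorted(
            set(a.index[~pa.isin(pb.values)]) | set(b.index[~pb.isin(pa.values)])
        )
        if unpaired:
            raise ValueError(f"samples without a complete pair: {unpaired}")
        order = common.sort_values().index
        b_by_pair = pd.Series(b.to_numpy(), index=pb.to_numpy())
        x = a.loc[order].to_numpy(dtype=float)
        y = b_by_pair.loc[common.loc[order].to_numpy()].to_numpy(dtype=float)
        res = scipy.stats.wilcoxon(x, y)
        rows.append({"comparison": f"{names[0]} vs {names[1]} (paired)",
                     "method": "Wilcoxon signed-rank", "statistic": float(res.statistic),
                     "pvalue": float(res.pvalue)})
    elif design == "multi_group":
        if len(names) < 3:
            raise ValueError("multi_group design needs at least 3 groups")
        if normality_ok is None:
            normality_ok = all(scipy.stats.shapiro(v).pvalue >= 0.05 for v in values)
        if normality_ok:
            f = scipy.stats.f_oneway(*values)
            rows.append({"comparison": "omnibus", "method": "one-way ANOVA",
                         "statistic": float(f.statistic), "pvalue": float(f.pvalue)})
            tk = pairwise_tukeyhsd(s.to_numpy(dtype=float), groups.to_numpy())
            for (g1, g2), p, stat in zip(
                itertools.combinations(tk.groupsunique, 2), tk.pvalues, tk.meandiffs
            ):
                rows.append({"comparison": f"{g1} vs {g2}", "method": "Tukey HSD",
                             "statistic": float(stat), "pvalue": float(p)})
        else:
            kw = scipy.stats.kruskal(*values)
            rows.append({"comparison": "omnibus", "method": "Kruskal-Wallis",
                         "statistic": float(kw.statistic), "pvalue": float(kw.pvalue)})
            rows.extend(_dunn_posthoc(values, names))
    else:
        raise ValueError(f"unknown design {design!r}")

    report = pd.DataFrame(rows)
    report["stars"] = report["pvalue"].map(significance_stars)
    return report
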