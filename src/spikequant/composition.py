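"""Relative-vs-absolute downstream analyses.

The same community table can be analysed on two bases: per-sample read
proportions (relative) or spike-calibrated 16S copies per gram
(absolute).  Because relative abundances are constrained to sum to one,
a change in total load reshuffles every proportion; the functions here
make that contrast measurable: top-N genus rankings with rank-shift
reporting, per-genus rank-sum differential abundance on either basis,
alpha diversity (Shannon, Chao1), Bray-Curtis dissimilarities, classical
PCoA, and a permutation PERMANOVA.

Spike rows are always excluded before any of these analyses.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .containers import AbsoluteAbundanceMatrix, CountMatrix
from .stats import wilcoxon_rank_sum


# ---------------------------------------------------------------------------
# bases
# ---------------------------------------------------------------------------

def relative_abundance(cm: CountMatrix) -> pd.DataFrame:
    """Per-sample proportions of the endogenous taxa (spike rows excluded)."""
    endo = cm.endogenous().astype(float)
    totals = endo.sum(axis=0)
    empty = totals.index[totals == 0].tolist()
    if empty:
        raise ValueError(f"samples with no endogenous reads: {empty}")
    return endo / totals


def absolute_values(aam: AbsoluteAbundanceMatrix, drop_flagged: bool = True) -> pd.DataFrame:
    """Copies-per-gram table, optionally restricted to QC-passing samples."""
    if drop_flagged:
        return aam.values[aam.passing_samples()]
    return aam.values


# ---------------------------------------------------------------------------
# rankings
# ---------------------------------------------------------------------------

@dataclass
class RankReport:
    """Top-N taxa by summed values over a set of samples."""

    basis: str  # "relative" | "absolute"
    scope: str  # "pooled" or a group label
    table: pd.DataFrame  # columns: rank, taxon, aggregate
    truncated: bool = False


def top_n(
    values: pd.DataFrame,
    n: int,
    basis: str = "relative",
    scope: str = "pooled",
    samples: list[str] | None = None,
) -> RankReport:
    """Rank taxa by their summed values over ``samples``.

    Ties break deterministically: by value descending, then taxon label.
    ``n`` larger than the number of taxa truncates with a flag.
    """
    if samples is not None:
        values = values[samples]
    sums = values.sum(axis=1)
    truncated = n > len(sums)
    order = sorted(sums.items(), key=lambda kv: (-kv[1], kv[0]))[: min(n, len(sums))]
    table = pd.DataFrame(
        {
            "rank": np.arange(1, len(order) + 1),
            "taxon": [t for t, _ in order],
            "aggregate": [v for _, v in order],
        }
    )
    return RankReport(basis=basis, scope=scope, table=table, truncated=truncated)


def rank_shift(relative: RankReport, absolute: RankReport) -> pd.DataFrame:
    """Tabulate how taxa move between the two bases' top-N lists.

    One row per taxon appearing in either list, with its rank under each
    basis (NaN when outside that basis' top N) and flags for taxa that
    entered or left the top N when switching from relative to absolute.
    """
    rel = dict(zip(relative.table["taxon"], relative.table["rank"]))
    ab = dict(zip(absolute.table["taxon"], absolute.table["rank"]))
    taxa = sorted(set(rel) | set(ab), key=lambda t: (rel.get(t, np.inf), ab.get(t, np.inf), t))
    return pd.DataFrame(
        {
            "taxon": taxa,
            "rank_relative": [rel.get(t, np.nan) for t in taxa],
            "rank_absolute": [ab.get(t, np.nan) for t in taxa],
            "entered_top_n": [t not in rel for t in taxa],
            "left_top_n": [t not in ab for t in taxa],
        }
    )


# ---------------------------------------------------------------------------
# differential abundance
# ---------------------------------------------------------------------------

def diff_abundance(
    values: pd.DataFrame,
    groups: pd.Series,
    basis: str = "relative",
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Per-taxon two-group rank-sum test on the given basis.

    ``groups`` maps sample id to one of exactly two group labels.
    Significance stars follow the unadjusted P < 0.05 / 0.01 / 0.001
    convention; Benjamini-Hochberg adjusted values are added on request.
    """
    groups = groups.reindex(values.columns)
    if groups.isna().any():
        missing = groups.index[groups.isna()].tolist()
        raise ValueError(f"samples without group labels: {missing}")
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"diff_abundance needs exactly 2 groups, got {labels}")
    a_cols = groups.index[groups == labels[0]]
    b_cols = groups.index[groups == labels[1]]
    if len(a_cols) < 3 or len(b_cols) < 3:
        raise ValueError("each group needs n >= 3 samples")
    rows = []
    for taxon in values.index:
        a = values.loc[taxon, a_cols].to_numpy(dtype=float)
        b = values.loc[taxon, b_cols].to_numpy(dtype=float)
        u, p = wilcoxon_rank_sum(a, b)
        med_a, med_b = np.median(a), np.median(b)
        direction = labels[0] if med_a > med_b else labels[1] if med_b > med_a else "none"
        rows.append(
            {
                "taxon": taxon,
                "basis": basis,
                "statistic": u,
                "p_value": p,
                "higher_in": direction,
                "stars": _stars(p),
            }
        )
    out = pd.DataFrame(rows)
    if bh_correction:
        from statsmodels.stats.multitest import multipletests

        out["p_bh"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def shannon(counts) -> float:
    """Shannon diversity in nats: ``-sum(p_i * ln(p_i))`` over nonzero taxa.

    Invariant under per-sample scaling, so relative and absolute bases
    give the same value for a given sample.
    """
    x = np.asarray(counts, dtype=float)
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValueError("Shannon undefined for an all-zero sample")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from singleton/doubleton counts.

    Requires raw integer read counts — the estimator is meaningless on
    scaled (copies-per-gram) values.  The bias-corrected form
    ``S_obs + F1*(F1-1) / (2*(F2+1))`` is the default and is defined even
    without doubletons; the classic form ``S_obs + F1^2 / (2*F2)`` is
    available but undefined at F2 = 0.
    """
    x = np.asarray(counts, dtype=float)
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    if not np.array_equal(x, np.rint(x)):
        raise ValueError("Chao1 requires integer counts (raw reads, not scaled values)")
    s_obs = int(np.count_nonzero(x))
    f1 = int(np.count_nonzero(x == 1))
    f2 = int(np.count_nonzero(x == 2))
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        raise ValueError("classic Chao1 undefined without doubletons (F2 = 0)")
    return s_obs + f1**2 / (2.0 * f2)


def alpha_diversity(cm: CountMatrix) -> pd.DataFrame:
    """Per-sample Shannon (nats) and bias-corrected Chao1 on raw
    spike-excluded reads."""
    endo = cm.endogenous()
    rows = {
        s: {"shannon": shannon(endo[s]), "chao1": chao1(endo[s])}
        for s in endo.columns
    }
    return pd.DataFrame(rows).T.rename_axis("sample_id")


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def bray_curtis(values: pd.DataFrame) -> pd.DataFrame:
    """Sample-by-sample Bray-Curtis dissimilarity matrix.

    ``d(u, v) = sum|u_i - v_i| / sum(u_i + v_i)``; input columns are
    samples.  Undefined when two all-zero samples meet.
    """
    if (values.to_numpy() < 0).any():
        raise ValueError("Bray-Curtis requires non-negative values")
    zero = values.columns[(values.sum(axis=0) == 0)].tolist()
    if len(zero) >= 2:
        raise ValueError(f"Bray-Curtis undefined between all-zero samples: {zero}")
    d = squareform(pdist(values.T.to_numpy(), metric="braycurtis"))
    return pd.DataFrame(d, index=values.columns, columns=values.columns)


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray  # per retained (positive) axis
    negative_eigenvalues: np.ndarray


def pcoa(distance: pd.DataFrame, include_negative_in_denominator: bool = False) -> PcoaResult:
    """Classical scaling (principal coordinates) of a distance matrix.

    Double-centres the squared distances, eigendecomposes the Gram
    matrix, and returns coordinates on the positive-eigenvalue axes.
    Negative eigenvalues (non-Euclidean input) are reported; by default
    they are excluded from the explained-variance denominator.
    """
    d = np.asarray(distance, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals).max(), 1.0) * 1e-12
    positive = eigvals > tol
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    denom = (
        np.abs(eigvals).sum() if include_negative_in_denominator else eigvals[positive].sum()
    )
    proportion = eigvals[positive] / denom if denom > 0 else eigvals[positive] * 0.0
    index = distance.index if isinstance(distance, pd.DataFrame) else pd.RangeIndex(n)
    return PcoaResult(
        coordinates=pd.DataFrame(
            coords, index=index, columns=[f"PC{i + 1}" for i in range(coords.shape[1])]
        ),
        eigenvalues=eigvals,
        proportion_explained=proportion,
        negative_eigenvalues=eigvals[eigvals < -tol],
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    method: str  # "permutation" | "exhaustive"
    permuted_f: np.ndarray  # the null F distribution actually used


def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> float:
    """Pseudo-F from squared distances and group labels.

    ``SS_total = sum_{i<j} d2_ij / N``; ``SS_within`` sums, per group,
    the within-group squared distances over the group size; the F ratio
    uses k-1 and N-k degrees of freedom.
    """
    n = len(labels)
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    uniq = np.unique(labels)
    for g in uniq:
        idx = np.flatnonzero(labels == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    k = len(uniq)
    ss_among = ss_total - ss_within
    return (ss_among / (k - 1)) / (ss_within / (n - k))


def _distinct_assignments(labels: np.ndarray):
    """All distinct placements of the label multiset over positions."""
    n = len(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    def rec(positions: tuple[int, ...], remaining: list[tuple[str, int]]):
        if len(remaining) == 1:
            out = np.empty(n, dtype=object)
            base = yield_state.copy()
            for p in positions:
                base[p] = remaining[0][0]
            yield base
            return
        label, cnt = remaining[0]
        for chosen in itertools.combinations(positions, cnt):
            for p in chosen:
                yield_state[p] = label
            rest = tuple(p for p in positions if p not in chosen)
            yield from rec(rest, remaining[1:])
    yield_state = np.empty(n, dtype=object)
    yield from rec(tuple(range(n)), list(zip(uniq, counts)))


def permanova(
    distance: pd.DataFrame,
    groups: pd.Series,
    n_permutations: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    The observed pseudo-F is compared with the distribution obtained by
    permuting group labels; ``P = (1 + #{F_perm >= F_obs}) / (1 + n_perm)``.
    With ``exhaustive=True`` every distinct label assignment is
    enumerated and the P value is the exact tail proportion (the observed
    assignment is one of them).
    """
    d = np.asarray(distance, dtype=float)
    if isinstance(distance, pd.DataFrame):
        labels = groups.reindex(distance.index)
        if labels.isna().any():
            raise ValueError("every sample in the distance matrix needs a group label")
        labels = labels.to_numpy()
    else:
        labels = np.asarray(groups)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs >= 2 groups")
    if counts.min() < 2:
        small = uniq[counts < 2].tolist()
        raise ValueError(f"groups of size 1 not allowed: {small}")
    d2 = d**2
    f_obs = _pseudo_f(d2, labels)

    if exhaustive:
        dist = np.array([_pseudo_f(d2, a) for a in _distinct_assignments(labels)])
        p = np.count_nonzero(dist >= f_obs - 1e-12) / len(dist)
        return PermanovaResult(
            pseudo_f=f_obs,
            p_value=float(p),
            n_permutations=len(dist),
            method="exhaustive",
            permuted_f=dist,
        )
    rng = np.random.default_rng(seed)
    perms = np.empty(n_permutations)
    for i in range(n_permutations):
        perms[i] = _pseudo_f(d2, rng.permutation(labels))
    p = (1 + np.count_nonzero(perms >= f_obs - 1e-12)) / (1 + n_permutations)
    return PermanovaResult(
        pseudo_f=f_obs,
        p_value=float(p),
        n_permutations=n_permutations,
        method="permutation",
        permuted_f=perms,
    )
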