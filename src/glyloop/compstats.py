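"""Amino-acid composition vectors and group comparisons.

Composition is expressed as the percentage of each of the 20 standard
residues among the *known* residues of a sequence, so records of very
different lengths (and different unknown loads) stay comparable.  Group
comparisons follow the classical recipes: one-way fixed-effects ANOVA per
residue, Welch's two-sample t-test, and PCA via singular value
decomposition of the (column-centered) percentage matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .records import STANDARD_RESIDUES, ProteinRecord

RESIDUE_INDEX = {aa: i for i, aa in enumerate(STANDARD_RESIDUES)}


@dataclass(frozen=True)
class CompositionVector:
    """Percent composition over the 20 standard residues (X excluded)."""

    id: str
    percents: tuple[float, ...]  # aligned with STANDARD_RESIDUES
    n_known: int
    n_unknown: int

    def __getitem__(self, residue: str) -> float:
        return self.percents[RESIDUE_INDEX[residue]]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.percents, dtype=float)


@dataclass(frozen=True)
class StatResult:
    statistic: float
    df: tuple[float, float]
    p_value: float
    group_means: tuple[float, ...]
    group_sizes: tuple[int, ...]


@dataclass(frozen=True)
class PCAResult:
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # features x components
    variance_proportions: np.ndarray


class UnknownFractionError(ValueError):
    """Raised when a record carries too many unknown residues to profile."""


def composition_vector(
    record: ProteinRecord, max_unknown_fraction: float = 0.10
) -> CompositionVector:
    """Percent composition of a record over known residues.

    Records whose unknown fraction exceeds ``max_unknown_fraction`` are
    rejected, mirroring the <10% unknown filter applied before composition
    analysis.
    """
    seq = record.residues
    n_unknown = seq.count("X")
    n_known = len(seq) - n_unknown
    frac = n_unknown / len(seq)
    if n_known == 0 or frac > max_unknown_fraction:
        raise UnknownFractionError(
            f"record {record.id!r}: unknown fraction {frac:.3f} exceeds "
            f"threshold {max_unknown_fraction:.3f}"
        )
    counts = np.zeros(len(STANDARD_RESIDUES))
    for ch in seq:
        if ch != "X":
            counts[RESIDUE_INDEX[ch]] += 1
    percents = 100.0 * counts / n_known
    return CompositionVector(
        id=record.id,
        percents=tuple(percents.tolist()),
        n_known=n_known,
        n_unknown=n_unknown,
    )


def residue_anova(
    groups: list[list[CompositionVector]], residue: str
) -> StatResult:
    """One-way fixed-effects ANOVA on one residue's percentages across groups."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    samples = [np.array([v[residue] for v in g], dtype=float) for g in groups]
    if any(len(s) < 2 for s in samples):
        raise ValueError("each group needs at least two members")
    k = len(samples)
    ns = np.array([len(s) for s in samples])
    n_total = int(ns.sum())
    means = np.array([s.mean() for s in samples])
    grand = np.concatenate(samples).mean()
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((s - m) ** 2).sum() for s, m in zip(samples, means)))
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0.0:
        f = 0.0 if ss_between == 0.0 else np.inf
        p = 1.0 if ss_between == 0.0 else 0.0
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(f, df_b, df_w))
    return StatResult(
        statistic=float(f),
        df=(float(df_b), float(df_w)),
        p_value=p,
        group_means=tuple(means.tolist()),
        group_sizes=tuple(int(n) for n in ns),
    )


def welch_t_test(a, b) -> StatResult:
    """Two-sided Welch t-test with Welch-Satterthwaite degrees of freedom."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    if va == 0.0 and vb == 0.0:
        equal = a.mean() == b.mean()
        sign = np.sign(a.mean() - b.mean())
        return StatResult(
            statistic=0.0 if equal else float(sign * np.inf),
            df=(float(na + nb - 2), float(na + nb - 2)),
            p_value=1.0 if equal else 0.0,
            group_means=(float(a.mean()), float(b.mean())),
            group_sizes=(na, nb),
        )
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / (va**2 / (na**2 * (na - 1)) + vb**2 / (nb**2 * (nb - 1)))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return StatResult(
        statistic=float(t),
        df=(float(df), float(df)),
        p_value=p,
        group_means=(float(a.mean()), float(b.mean())),
        group_sizes=(na, nb),
    )


def bonferroni(results: dict[str, StatResult]) -> dict[str, float]:
    """Bonferroni-adjusted p-values for a family of per-residue tests."""
    m = len(results)
    return {k: min(1.0, r.p_value * m) for k, r in results.items()}


def pca_svd(matrix, center: bool = True, scale: bool = False) -> PCAResult:
    """PCA by singular value decomposition of the (centered) data matrix.

    Scores are U*S, loadings the right singular vectors, and each
    component's variance proportion is s_i^2 / sum_j s_j^2.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two samples")
    if np.isnan(x).any():
        raise ValueError("matrix contains missing values")
    if center:
        x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = x / sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total = float((s**2).sum())
    if total == 0.0:
        raise ValueError("matrix is constant; variance proportions undefined")
    return PCAResult(
        scores=u * s,
        loadings=vt.T,
        variance_proportions=s**2 / total,
    )
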