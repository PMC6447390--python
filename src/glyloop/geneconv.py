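"""Candidate gene-conversion fragments between aligned paralogs.

A homogenized (converted) tract between two diverged paralogs shows up as an
unusually long run of agreement over otherwise polymorphic alignment
columns.  We score each polymorphic column +1 where the pair agrees and
-penalty where it differs, take the maximal-sum contiguous segment as the
candidate fragment, and calibrate it with a column-permutation null that
uses the all-pairs maximum score (family-wise control across pairs).

This is a deliberately simple stand-in for the global-fragment statistic of
dedicated gene-conversion software; scoring constants and corrections of
such tools are not reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
import warnings

import numpy as np


@dataclass(frozen=True)
class AlignedGroup:
    """A gapped nucleotide alignment: equal-length rows over {A,C,G,T,N,-}."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least two rows")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in number")
        L = len(self.rows[0])
        if any(len(r) != L for r in self.rows):
            raise ValueError("alignment rows differ in length")
        allowed = set("ACGTN-")
        for rid, row in zip(self.ids, self.rows):
            bad = set(row.upper()) - allowed
            if bad:
                raise ValueError(f"row {rid!r}: illegal characters {sorted(bad)}")
        object.__setattr__(self, "rows", tuple(r.upper() for r in self.rows))

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def row(self, rid: str) -> str:
        return self.rows[self.ids.index(rid)]


@dataclass(frozen=True)
class ConversionFragment:
    pair: tuple[str, str]
    start: int  # alignment column, half-open
    end: int
    n_poly_sites: int
    score: float
    p_value: float | None = None

    @property
    def nt_length(self) -> int:
        return self.end - self.start


def polymorphic_columns(group: AlignedGroup) -> list[int]:
    """Alignment columns with >= 2 distinct bases; N or gap anywhere excludes."""
    cols = []
    for j in range(group.length):
        column = {row[j] for row in group.rows}
        if "N" in column or "-" in column:
            continue
        if len(column) >= 2:
            cols.append(j)
    return cols


def informative_columns(group: AlignedGroup) -> list[int]:
    """Columns the fragment statistic scans.

    With three or more rows these are the group's polymorphic columns: a
    pair agreeing where other rows vary is the conversion signal, and
    monomorphic columns carry no information about any pair.  With exactly
    two rows every column is polymorphic precisely where the pair differs,
    so restricting to polymorphic columns would leave nothing but
    mismatches; there the scan uses every gap- and N-free column, and a
    homogenized tract shows up as an unbroken run of agreement.
    """
    if len(group.rows) > 2:
        return polymorphic_columns(group)
    cols = []
    for j in range(group.length):
        column = {row[j] for row in group.rows}
        if "N" in column or "-" in column:
            continue
        cols.append(j)
    return cols


def _best_segment(scores: np.ndarray) -> tuple[int, int, float]:
    """Maximal-sum contiguous segment over ``scores`` (non-empty).

    Returns (first, last, sum) as indices into ``scores``.  Ties break
    toward the shortest segment, then the smallest start, so a clean run
    of agreements is preferred over the same run padded with
    penalty-cancelling flanks.
    """
    prefix = np.concatenate([[0.0], np.cumsum(scores)])
    best_sum = -np.inf
    best = (0, 0)
    min_val = prefix[0]
    min_idx = 0
    for j in range(1, len(prefix)):
        cand = prefix[j] - min_val
        length = (j - 1) - min_idx
        if cand > best_sum or (cand == best_sum and length < best[1] - best[0]):
            best_sum = cand
            best = (min_idx, j - 1)
        # '<=' keeps the latest minimum, yielding the shortest segment
        # ending at each j
        if prefix[j] <= min_val:
            min_val = prefix[j]
            min_idx = j
    return best[0], best[1], float(best_sum)


def pair_fragment_scan(
    group: AlignedGroup,
    pair: tuple[str, str],
    mismatch_penalty: float = 2.0,
    cols: list[int] | None = None,
) -> ConversionFragment | None:
    """Best-scoring homogenized fragment between two rows, or None.

    Over the informative columns (see :func:`informative_columns`) the pair
    scores +1 on agreement and -``mismatch_penalty`` on disagreement; the
    fragment is the maximal-sum contiguous segment, reported in alignment
    coordinates spanning its first through last scanned column.
    ``n_poly_sites`` counts the group's polymorphic columns inside the
    fragment.
    """
    if cols is None:
        cols = informative_columns(group)
    if not cols:
        return None
    poly = set(polymorphic_columns(group))
    r1, r2 = group.row(pair[0]), group.row(pair[1])
    agree = np.array([r1[j] == r2[j] for j in cols])
    scores = np.where(agree, 1.0, -float(mismatch_penalty))
    i, j, s = _best_segment(scores)
    start, end = cols[i], cols[j] + 1
    return ConversionFragment(
        pair=(pair[0], pair[1]),
        start=start,
        end=end,
        n_poly_sites=sum(1 for c in cols[i : j + 1] if c in poly),
        score=s,
    )


def permutation_test(
    group: AlignedGroup,
    n_permutations: int = 10000,
    seed: int = 0,
    mismatch_penalty: float = 2.0,
) -> list[ConversionFragment]:
    """Fragment scan for every pair with permutation p-values.

    The null shuffles the order of the scanned columns (one permutation
    shared by all rows), rescans, and records the per-permutation maximum
    score over all pairs; p = (1 + #{null >= observed}) / (1 + B).
    """
    if n_permutations < 100:
        warnings.warn(
            f"n_permutations={n_permutations} is low; p-values will be coarse",
            stacklevel=2,
        )
    cols = informative_columns(group)
    pairs = list(combinations(group.ids, 2))
    observed = [pair_fragment_scan(group, p, mismatch_penalty, cols) for p in pairs]
    if not cols:
        return [f for f in observed if f is not None]

    agree = np.array(
        [[group.row(a)[j] == group.row(b)[j] for j in cols] for a, b in pairs]
    )  # pairs x m
    score_mat = np.where(agree, 1.0, -float(mismatch_penalty))
    rng = np.random.default_rng(seed)
    m = len(cols)
    null_max = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = rng.permutation(m)
        null_max[b] = _max_over_rows(score_mat[:, perm])
    out = []
    for frag in observed:
        exceed = int((null_max >= frag.score).sum())
        p = (1 + exceed) / (1 + n_permutations)
        out.append(
            ConversionFragment(
                pair=frag.pair,
                start=frag.start,
                end=frag.end,
                n_poly_sites=frag.n_poly_sites,
                score=frag.score,
                p_value=p,
            )
        )
    return out


def _max_over_rows(score_mat: np.ndarray) -> float:
    """Max over rows of the maximal-sum contiguous segment (vectorized)."""
    prefix = np.concatenate(
        [np.zeros((score_mat.shape[0], 1)), np.cumsum(score_mat, axis=1)], axis=1
    )
    running_min = np.minimum.accumulate(prefix[:, :-1], axis=1)
    best = (prefix[:, 1:] - running_min).max(axis=1)
    return float(best.max())
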