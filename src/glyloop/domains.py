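"""Domain partitioning and glycine-loop detection.

A glycine loop is a glycine/serine-rich stretch anchored ("indexed") on its
left by an aromatic or aliphatic residue, written ``x(y)_n`` where ``x`` is
the index residue and ``n`` the number of loop residues.  Index residues may
occur as dimers or trimers; such a run collapses to a single boundary and
loop size counts only the residues strictly between boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import ProteinRecord

AROMATIC = frozenset("FYW")
ALIPHATIC = frozenset("AVLIM")
DEFAULT_INDEX = AROMATIC | ALIPHATIC
DEFAULT_LOOP_ALPHABET = frozenset("GSCK")


@dataclass(frozen=True)
class DomainPartition:
    """Half-open tiling of a record into N-terminal, central and C-terminal spans."""

    a: int  # central start; n_term = [0, a)
    b: int  # central end; c_term = [b, length)
    length: int

    def __post_init__(self) -> None:
        if not (0 <= self.a <= self.b <= self.length):
            raise ValueError(
                f"spans must satisfy 0 <= {self.a} <= {self.b} <= {self.length}"
            )

    @property
    def n_term(self) -> tuple[int, int]:
        return (0, self.a)

    @property
    def central(self) -> tuple[int, int]:
        return (self.a, self.b)

    @property
    def c_term(self) -> tuple[int, int]:
        return (self.b, self.length)


@dataclass(frozen=True)
class LoopConfig:
    """Parameters of the ``x(y)_n`` loop grammar.

    ``index_residues`` are the anchoring aromatic/aliphatic residues (x);
    ``loop_alphabet`` are the residues a loop may contain (y).  Q, P and any
    other residue outside both sets terminate loops (spacers).  When
    ``exclude_loops_with_X`` is true (default) an unknown residue also
    terminates, so no reported loop ever contains X; when false, X extends a
    loop and is counted in its size.
    """

    index_residues: frozenset[str] = DEFAULT_INDEX
    loop_alphabet: frozenset[str] = DEFAULT_LOOP_ALPHABET
    min_loop_len: int = 2
    min_gs_fraction: float = 0.6
    exclude_loops_with_X: bool = True

    def __post_init__(self) -> None:
        if self.index_residues & self.loop_alphabet:
            raise ValueError("index_residues and loop_alphabet must be disjoint")
        if "P" in self.index_residues or "Q" in self.index_residues:
            raise ValueError("P and Q are spacer residues, never index residues")
        if self.min_loop_len < 1:
            raise ValueError("min_loop_len must be >= 1")
        if not 0.0 <= self.min_gs_fraction <= 1.0:
            raise ValueError("min_gs_fraction must be in [0, 1]")


@dataclass(frozen=True)
class GlyLoop:
    """One detected loop: residues [start, end) with their left anchor."""

    start: int
    end: int
    left_index_pos: int
    right_boundary_kind: str  # "index" | "terminator" | "sequence_end"
    gs_fraction: float

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class LoopProfile:
    total_loops: int
    largest: int | None
    smallest: int | None
    mean_size: float | None


def partition_domains(
    record: ProteinRecord,
    spans: tuple[tuple[int, int], tuple[int, int], tuple[int, int]] | None = None,
    window: int = 10,
    gs_threshold: float = 0.5,
) -> DomainPartition:
    """Partition a record into N-terminal / central / C-terminal spans.

    With explicit ``spans`` the given tiling is validated and returned.
    Otherwise the central repeat domain is located automatically as the
    longest contiguous run of residues covered by length-``window`` windows
    whose G+S+X fraction is at least ``gs_threshold``.
    """
    L = len(record)
    if spans is not None:
        (s0, e0), (s1, e1), (s2, e2) = spans
        if s0 != 0 or e0 != s1 or e1 != s2 or e2 != L:
            raise ValueError("explicit spans must tile the sequence without gaps or overlap")
        return DomainPartition(a=s1, b=e1, length=L)

    seq = record.residues
    if L < window:
        return DomainPartition(a=L, b=L, length=L)
    rich = set("GSX")
    counts = [1 if c in rich else 0 for c in seq]
    covered = [False] * L
    run = sum(counts[:window])
    for i in range(L - window + 1):
        if i > 0:
            run += counts[i + window - 1] - counts[i - 1]
        if run / window >= gs_threshold:
            for j in range(i, i + window):
                covered[j] = True
    # collect covered intervals, bridging uncovered gaps shorter than one
    # window (index runs and Q/P spacers between loops)
    intervals: list[list[int]] = []
    i = 0
    while i < L:
        if covered[i]:
            j = i
            while j < L and covered[j]:
                j += 1
            if intervals and i - intervals[-1][1] < window:
                intervals[-1][1] = j
            else:
                intervals.append([i, j])
            i = j
        else:
            i += 1
    best_start, best_len = L, 0
    for s, e in intervals:
        if e - s > best_len:
            best_start, best_len = s, e - s
    if best_len == 0:
        return DomainPartition(a=L, b=L, length=L)
    return DomainPartition(a=best_start, b=best_start + best_len, length=L)


def detect_gly_loops(segment: str, config: LoopConfig | None = None) -> list[GlyLoop]:
    """Detect ``x(y)_n`` loops in a residue segment, left to right.

    A maximal run of index residues opens a candidate loop immediately to its
    right; the candidate extends through consecutive loop-alphabet residues
    and closes at the first residue outside that alphabet (or at segment
    end).  It is reported iff it meets the minimum length, the minimum G+S
    fraction, and the X-exclusion rule.  Reported loops never overlap and
    are ordered by start.
    """
    if config is None:
        config = LoopConfig()
    segment = segment.upper()
    loops: list[GlyLoop] = []
    n = len(segment)
    i = 0
    while i < n:
        if segment[i] not in config.index_residues:
            i += 1
            continue
        # maximal index run
        run_start = i
        while i < n and segment[i] in config.index_residues:
            i += 1
        start = i
        while i < n and _extends(segment[i], config):
            i += 1
        end = i
        size = end - start
        if size == 0:
            # empty candidate; rescan from the closing residue (it may be an
            # index residue only if the run above was maximal, so it is not)
            continue
        if i >= n:
            kind = "sequence_end"
        elif segment[i] in config.index_residues:
            kind = "index"
        else:
            kind = "terminator"
        body = segment[start:end]
        gs = sum(1 for c in body if c in "GS") / size
        ok = size >= config.min_loop_len and gs >= config.min_gs_fraction
        if ok and config.exclude_loops_with_X and "X" in body:
            ok = False
        if ok:
            loops.append(
                GlyLoop(
                    start=start,
                    end=end,
                    left_index_pos=run_start,
                    right_boundary_kind=kind,
                    gs_fraction=gs,
                )
            )
        # do not advance past the closing residue: an index residue there
        # both terminates this loop and anchors the next one
    return loops


def _extends(ch: str, config: LoopConfig) -> bool:
    if ch in config.loop_alphabet:
        return True
    return ch == "X" and not config.exclude_loops_with_X


def loop_profile(loops: list[GlyLoop]) -> LoopProfile:
    """Summarize loop sizes: count, extrema and 2-decimal mean."""
    if not loops:
        return LoopProfile(total_loops=0, largest=None, smallest=None, mean_size=None)
    sizes = [lp.size for lp in loops]
    return LoopProfile(
        total_loops=len(sizes),
        largest=max(sizes),
        smallest=min(sizes),
        mean_size=round(sum(sizes) / len(sizes), 2),
    )


def xy_annotation(loop: GlyLoop, segment: str) -> str:
    """Render a loop as ``x(y)_n``, e.g. ``Y(y)_5``."""
    if not (0 <= loop.left_index_pos < len(segment) and loop.end <= len(segment)):
        raise ValueError("loop lies outside the segment")
    return f"{segment[loop.left_index_pos]}(y)_{loop.size}"
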