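"""Synthetic loricrin-like sequences with known ground truth.

Generated proteins follow the tripartite architecture of the real genes:
a conserved N-terminal template, a central quasi-repeat domain of glycine
loops anchored on aromatic/aliphatic index runs and separated by Gln/Pro
spacers, and a conserved C-terminal template.  The generator records every
planted loop, the central span and spacer positions so detection, quality
classification and the conversion scan can all be checked against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .domains import LoopConfig
from .geneconv import AlignedGroup
from .records import GeneLabel, ProteinRecord

# K/Q-rich termini, deliberately poor in G and S so the windowed domain
# heuristic separates them cleanly from the repeat domain.
NTERM_TEMPLATE = "MPYQKKQPQTPKEVAQNAFDPHQVQVQKP"
CTERM_TEMPLATE = "QPKHQEVQQKHLEDPKAQNKDPKYPQWKKQ"

# residues a planted loop may contain, in weight-vector order
LOOP_RESIDUES = "GSCK"

_BACK_TABLE: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _BACK_TABLE.setdefault(aa, []).append(codon)


class IndexStyle(str, Enum):
    """Which paralog's repeat flavour to emulate."""

    LOR1_LIKE = "LOR1_like"  # isoleucine runs, HQSQGP-style spacers
    LOR2_LIKE = "LOR2_like"  # methionine runs
    LOR3_LIKE = "LOR3_like"  # tyrosine/isoleucine runs


_STYLE_INDEX = {
    IndexStyle.LOR1_LIKE: "I",
    IndexStyle.LOR2_LIKE: "M",
    IndexStyle.LOR3_LIKE: "YI",
}
_STYLE_SPACER = {
    IndexStyle.LOR1_LIKE: "HQSQGP",
    IndexStyle.LOR2_LIKE: "QPQ",
    IndexStyle.LOR3_LIKE: "HQP",
}
_STYLE_LABEL = {
    IndexStyle.LOR1_LIKE: GeneLabel.LOR1,
    IndexStyle.LOR2_LIKE: GeneLabel.LOR2,
    IndexStyle.LOR3_LIKE: GeneLabel.LOR3,
}


@dataclass(frozen=True)
class GeneratorParams:
    n_loops: int = 10
    loop_size_sampler: tuple = ("uniform", 4, 12)  # or ("fixed", [sizes...])
    index_style: IndexStyle = IndexStyle.LOR3_LIKE
    terminus_templates: tuple[str, str] = (NTERM_TEMPLATE, CTERM_TEMPLATE)
    loop_alphabet_weights: tuple[float, float, float, float] = (0.6, 0.25, 0.1, 0.05)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loops < 0:
            raise ValueError("n_loops must be >= 0")
        w = np.asarray(self.loop_alphabet_weights, dtype=float)
        if (w < 0).any() or w.sum() == 0:
            raise ValueError("weights must be nonnegative and not all zero")
        kind = self.loop_size_sampler[0]
        if kind == "uniform":
            lo, hi = self.loop_size_sampler[1:]
            if lo < 1 or hi < lo:
                raise ValueError("uniform sampler needs 1 <= lo <= hi")
        elif kind == "fixed":
            if any(s < 1 for s in self.loop_size_sampler[1]):
                raise ValueError("loop sizes must be >= 1")
        else:
            raise ValueError(f"unknown sampler kind {kind!r}")


@dataclass
class SyntheticTruth:
    planted_loops: list[tuple[int, int, int]]  # (start, end, size), record coords
    central_span: tuple[int, int]
    spacer_positions: list[int] = field(default_factory=list)
    planted_tract: tuple[int, int] | None = None
    params: GeneratorParams | None = None
    seed: int = 0


def _sample_size(sampler: tuple, i: int, rng: np.random.Generator) -> int:
    if sampler[0] == "uniform":
        return int(rng.integers(sampler[1], sampler[2] + 1))
    sizes = sampler[1]
    return int(sizes[i % len(sizes)])


def _sample_loop(
    size: int, weights, rng: np.random.Generator, min_gs_fraction: float
) -> str:
    """Draw loop residues from {G,S,C,K}; force the G+S floor so every
    planted loop is detectable under the default grammar."""
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    chars = list(rng.choice(list(LOOP_RESIDUES), size=size, p=w))
    need = int(np.ceil(min_gs_fraction * size))
    gs_pos = [i for i, c in enumerate(chars) if c in "GS"]
    non_gs = [i for i, c in enumerate(chars) if c not in "GS"]
    rng.shuffle(non_gs)
    while len(gs_pos) < need and non_gs:
        i = non_gs.pop()
        chars[i] = "G"
        gs_pos.append(i)
    return "".join(chars)


def generate_loricrin_protein(
    params: GeneratorParams, record_id: str = "sim", species_code: str = "SYNTH"
) -> tuple[ProteinRecord, SyntheticTruth]:
    """Generate one loricrin-like protein plus its ground truth.

    Layout: N-terminus, then for each loop an index run, the loop and a
    spacer, a closing index run, then the C-terminus.  Deterministic for a
    given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    index_pool = _STYLE_INDEX[params.index_style]
    spacer = _STYLE_SPACER[params.index_style]
    nterm, cterm = params.terminus_templates

    parts: list[str] = [nterm]
    pos = len(nterm)
    central_start = pos
    loops: list[tuple[int, int, int]] = []
    spacer_positions: list[int] = []
    cfg = LoopConfig()
    for i in range(params.n_loops):
        run_len = int(rng.integers(1, 4))
        run = rng.choice(list(index_pool)) * run_len
        parts.append(run)
        pos += run_len
        size = _sample_size(params.loop_size_sampler, i, rng)
        loop = _sample_loop(size, params.loop_alphabet_weights, rng, cfg.min_gs_fraction)
        loops.append((pos, pos + size, size))
        parts.append(loop)
        pos += size
        # a spacer after every loop except the last (closed by the final run)
        if i < params.n_loops - 1 and rng.random() < 0.7:
            parts.append(spacer)
            spacer_positions.extend(range(pos, pos + len(spacer)))
            pos += len(spacer)
    if params.n_loops > 0:
        closing = rng.choice(list(index_pool)) * int(rng.integers(1, 4))
        parts.append(closing)
        pos += len(closing)
    central_end = pos
    parts.append(cterm)
    sequence = "".join(parts)

    record = ProteinRecord(
        id=record_id,
        residues=sequence,
        species_code=species_code,
        gene_label=_STYLE_LABEL[params.index_style],
    )
    truth = SyntheticTruth(
        planted_loops=loops,
        central_span=(central_start, central_end),
        spacer_positions=spacer_positions,
        params=params,
        seed=params.seed,
    )
    return record, truth


def degrade_with_unknowns(
    record: ProteinRecord,
    target_fraction: float,
    placement: str = "central_only",
    seed: int = 0,
    truth: SyntheticTruth | None = None,
) -> ProteinRecord:
    """Replace residues with X in contiguous runs until the placement region
    reaches ``target_fraction`` unknowns (within 1/region-length).

    ``placement``: ``anywhere``, ``central_only`` or ``spacers_only``; the
    latter two need ``truth`` for the region coordinates.
    """
    if not 0.0 <= target_fraction < 1.0:
        raise ValueError("target_fraction must be in [0, 1)")
    if placement == "anywhere":
        region = list(range(len(record)))
    elif placement == "central_only":
        if truth is None:
            raise ValueError("central_only placement needs truth")
        a, b = truth.central_span
        region = list(range(a, b))
    elif placement == "spacers_only":
        if truth is None:
            raise ValueError("spacers_only placement needs truth")
        region = list(truth.spacer_positions)
    else:
        raise ValueError(f"unknown placement {placement!r}")
    if target_fraction == 0.0:
        return record
    if not region:
        raise ValueError("placement region is empty; achievable fraction 0.0")
    target_count = round(target_fraction * len(region))
    if target_count == 0:
        return record

    rng = np.random.default_rng(seed)
    chars = list(record.residues)
    masked: set[int] = set()
    guard = 0
    while len(masked) < target_count:
        guard += 1
        if guard > 10000:
            raise ValueError(
                f"region too short to reach target; achievable fraction "
                f"{len(masked) / len(region):.3f}"
            )
        run_len = int(rng.integers(2, 9))
        start = int(rng.integers(0, len(region)))
        for k in range(start, min(start + run_len, len(region))):
            masked.add(region[k])
            if len(masked) >= target_count:
                break
    for i in masked:
        chars[i] = "X"
    return ProteinRecord(
        id=record.id,
        residues="".join(chars),
        species_code=record.species_code,
        gene_label=record.gene_label,
        source_note=record.source_note,
    )


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Back-translate with uniform synonymous codon choice; X becomes NNN."""
    codons = []
    for aa in protein:
        if aa == "X":
            codons.append("NNN")
        else:
            options = _BACK_TABLE[aa]
            codons.append(options[int(rng.integers(0, len(options)))])
    return "".join(codons)


def generate_duplicate_pair(
    protein_params: GeneratorParams,
    divergence: float = 0.2,
    tract: tuple[float, int] | None = None,
    seed: int = 0,
) -> tuple[AlignedGroup, SyntheticTruth]:
    """A duplicate gene pair: one CDS copied, diverged, optionally homogenized.

    One generated protein is back-translated; the copy receives i.i.d.
    substitutions (uniform over the three alternative bases) at per-site
    probability ``divergence``.  If ``tract`` = (start_fraction,
    length_columns) is given, that window of the diverged copy is overwritten
    with the original's bases, planting a perfectly homogenized conversion
    tract.  Rows are gapless, so alignment columns equal CDS positions.
    """
    if not 0.0 <= divergence < 0.75:
        raise ValueError("divergence must be in [0, 0.75)")
    rng = np.random.default_rng(seed)
    protein, truth = generate_loricrin_protein(protein_params, record_id="dup")
    cds = back_translate(protein.residues, rng)
    n = len(cds)

    bases = "ACGT"
    copy = list(cds)
    hits = rng.random(n) < divergence
    for i in np.nonzero(hits)[0]:
        if copy[i] == "N":
            continue
        alternatives = [b for b in bases if b != copy[i]]
        copy[i] = alternatives[int(rng.integers(0, 3))]

    planted = None
    if tract is not None:
        start_fraction, length = tract
        start = int(start_fraction * n)
        if start + length > n:
            raise ValueError("tract extends beyond the sequence")
        copy[start : start + length] = cds[start : start + length]
        planted = (start, start + length)

    group = AlignedGroup(ids=("copy1", "copy2"), rows=(cds, "".join(copy)))
    truth.planted_tract = planted
    truth.seed = seed
    return group, truth
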