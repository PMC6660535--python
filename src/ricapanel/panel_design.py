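"""Panel SNP selection: call-rate/MAF filters, physical gap filling, and
marker-spacing statistics in kb and cM.

Genetic distance is a deterministic linear transform of physical distance
using a single genome-wide constant (default 244 kb per cM); no regional
recombination-rate variation is modelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import GENOME_LENGTH_BP, RICE_CHROM_LENGTHS, MarkerRecord


@dataclass(frozen=True)
class CandidateSNP:
    """A candidate marker with its reference-dataset quality statistics."""

    marker_id: str
    chrom: str
    pos_bp: int
    alleles: tuple[str, str]
    reference_call_rate: float
    reference_maf: float
    resource: str = "C6AIR"

    def __post_init__(self) -> None:
        if not (0 <= self.reference_call_rate <= 1):
            raise ValueError("reference_call_rate must lie in [0, 1]")
        if not (0 <= self.reference_maf <= 0.5):
            raise ValueError("reference_maf must lie in [0, 0.5]")

    def to_marker(self) -> MarkerRecord:
        return MarkerRecord(
            marker_id=self.marker_id,
            chrom=self.chrom,
            pos_bp=self.pos_bp,
            alleles=self.alleles,
            source=self.resource,
        )


@dataclass(frozen=True)
class MapConstants:
    """Physical-to-genetic map constants for the rice genome."""

    kb_per_cM: float = 244.0
    genome_length_bp: int = GENOME_LENGTH_BP
    chrom_lengths: dict[str, int] = field(default_factory=lambda: dict(RICE_CHROM_LENGTHS))

    def bp_to_cM(self, bp: float | np.ndarray) -> float | np.ndarray:
        return bp / (self.kb_per_cM * 1000.0)


def filter_candidates(
    cands: Sequence[CandidateSNP],
    min_call_rate: float = 0.95,
    min_maf: float = 0.4,
) -> list[CandidateSNP]:
    """Keep candidates with call rate strictly above ``min_call_rate`` and
    MAF at or above ``min_maf`` (strict vs. inclusive boundaries mirror the
    ">95% call rate, MAF >= 0.4" selection rule)."""
    return [
        c
        for c in cands
        if c.reference_call_rate > min_call_rate and c.reference_maf >= min_maf
    ]


def _gaps_with_ends(
    positions: dict[str, list[int]], consts: MapConstants
) -> list[tuple[str, int, int]]:
    """All current gaps: (chrom, start, end), chromosome ends included as
    gaps from position 1 and to the chromosome length."""
    out = []
    for chrom, length in consts.chrom_lengths.items():
        pos = sorted(positions.get(chrom, []))
        bounds = [1] + pos + [length]
        for a, b in zip(bounds[:-1], bounds[1:]):
            if b > a:
                out.append((chrom, a, b))
    return out


def fill_gaps(
    selected: Sequence[MarkerRecord],
    pool: Sequence[CandidateSNP],
    n_to_add: int,
    consts: MapConstants | None = None,
) -> list[MarkerRecord]:
    """Greedy physical gap filling.

    Repeats ``n_to_add`` times: locate the largest remaining gap (chromosome
    ends count as gaps), then add the pool candidate closest to that gap's
    midpoint, breaking ties toward the lower coordinate.  Stops early when
    no candidate lies strictly inside any gap.
    """
    consts = consts or MapConstants()
    result = list(selected)
    taken = {(m.chrom, m.pos_bp) for m in result}
    avail = [c for c in pool if (c.chrom, c.pos_bp) not in taken]
    if not avail:
        warnings.warn("gap-filling pool is empty; panel returned unchanged", stacklevel=2)
        return result

    positions: dict[str, list[int]] = {}
    for m in result:
        positions.setdefault(m.chrom, []).append(m.pos_bp)

    for _ in range(n_to_add):
        gaps = sorted(
            _gaps_with_ends(positions, consts),
            key=lambda g: (-(g[2] - g[1]), g[0], g[1]),
        )
        placed = False
        for chrom, start, end in gaps:
            inside = [c for c in avail if c.chrom == chrom and start < c.pos_bp < end]
            if not inside:
                continue
            mid = (start + end) / 2.0
            best = min(inside, key=lambda c: (abs(c.pos_bp - mid), c.pos_bp))
            result.append(best.to_marker())
            positions.setdefault(chrom, []).append(best.pos_bp)
            avail.remove(best)
            placed = True
            break
        if not placed:
            break
    return sorted(result, key=lambda m: (m.chrom, m.pos_bp))


@dataclass
class SpacingStats:
    """Adjacent-marker spacing summary for a panel."""

    n_markers: int
    mean_gap_bp: float
    median_gap_bp: float
    mean_gap_cM: float
    sd_gap_cM: float
    per_chrom_gaps_bp: dict[str, np.ndarray]
    largest_gaps: list[tuple[str, int, int]]
    uniform_spacing_bp: float
    uniform_spacing_cM: float


def spacing_stats(
    panel: Sequence[MarkerRecord], consts: MapConstants | None = None, n_largest: int = 10
) -> SpacingStats:
    """Spacing statistics over gaps between adjacent markers within
    chromosomes; single-marker chromosomes contribute no gaps."""
    consts = consts or MapConstants()
    by_chrom: dict[str, list[int]] = {}
    for m in panel:
        by_chrom.setdefault(m.chrom, []).append(m.pos_bp)

    per_chrom: dict[str, np.ndarray] = {}
    intervals: list[tuple[str, int, int]] = []
    for chrom, pos in by_chrom.items():
        pos = sorted(pos)
        if len(pos) < 2:
            continue
        per_chrom[chrom] = np.diff(pos).astype(float)
        intervals.extend((chrom, a, b) for a, b in zip(pos[:-1], pos[1:]))

    if not per_chrom:
        raise ValueError("need at least two markers on one chromosome")
    gaps = np.concatenate(list(per_chrom.values()))
    gaps_cm = np.asarray(consts.bp_to_cM(gaps))
    uniform = consts.genome_length_bp / len(panel)
    largest = sorted(intervals, key=lambda iv: -(iv[2] - iv[1]))[:n_largest]
    return SpacingStats(
        n_markers=len(panel),
        mean_gap_bp=float(gaps.mean()),
        median_gap_bp=float(np.median(gaps)),
        mean_gap_cM=float(gaps_cm.mean()),
        sd_gap_cM=float(gaps_cm.std(ddof=1)) if len(gaps_cm) > 1 else 0.0,
        per_chrom_gaps_bp=per_chrom,
        largest_gaps=largest,
        uniform_spacing_bp=float(uniform),
        uniform_spacing_cM=float(consts.bp_to_cM(uniform)),
    )
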