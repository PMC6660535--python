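"""Predicted-F1 construction and hybrid genotype validation.

A predicted F1 profile combines the haplotypes of two homozygous parents:
heterozygous wherever the parents carry different homozygotes, homozygous
where they agree, and undefined (missing) wherever either parent is
heterozygous or missing.  Empirical F1 calls are scored against this
prediction by exact-match percentage over mutually called loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix


def _first_alleles(row: np.ndarray) -> np.ndarray:
    return row.view("U1").reshape(-1, 2)[:, 0]


def _het_mask(row: np.ndarray) -> np.ndarray:
    chars = row.view("U1").reshape(-1, 2)
    return (row != MISSING) & (chars[:, 0] != chars[:, 1])


def predict_f1(parent1: np.ndarray, parent2: np.ndarray) -> np.ndarray:
    """Predicted F1 genotype row from two parental rows.

    Loci where either parent is heterozygous or missing are set missing;
    the function is symmetric in its parents.
    """
    p1 = np.asarray(parent1, dtype="U2")
    p2 = np.asarray(parent2, dtype="U2")
    usable = ~(_het_mask(p1) | _het_mask(p2) | (p1 == MISSING) | (p2 == MISSING))
    out = np.full(p1.shape, MISSING, dtype="U2")
    same = usable & (p1 == p2)
    out[same] = p1[same]
    diff = usable & (p1 != p2)
    a1 = _first_alleles(p1)
    a2 = _first_alleles(p2)
    hets = np.array([x + y if x <= y else y + x for x, y in zip(a1, a2)], dtype="U2")
    out[diff] = hets[diff]
    return out


def f1_concordance(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Percent exact-match over loci called in both rows; NaN if none."""
    p = np.asarray(predicted, dtype="U2")
    o = np.asarray(observed, dtype="U2")
    comparable = (p != MISSING) & (o != MISSING)
    n = int(comparable.sum())
    if n == 0:
        return float("nan")
    return 100.0 * float((p[comparable] == o[comparable]).sum()) / n


def count_polymorphic(parent1: np.ndarray, parent2: np.ndarray) -> int:
    """Loci where both parents are non-missing homozygotes with different
    alleles — the markers that segregate in the cross."""
    p1 = np.asarray(parent1, dtype="U2")
    p2 = np.asarray(parent2, dtype="U2")
    usable = ~(_het_mask(p1) | _het_mask(p2) | (p1 == MISSING) | (p2 == MISSING))
    return int((usable & (p1 != p2)).sum())


@dataclass
class CrossResult:
    """Validation summary for one bi-parental cross."""

    cross_id: str
    parent1: str
    parent2: str
    n_polymorphic: int
    per_f1_similarity: pd.Series
    mean_similarity: float


def validate_cross(
    gm: GenotypeMatrix,
    cross_id: str,
    parent1: str,
    parent2: str,
    f1_samples: list[str],
) -> CrossResult:
    """Score every F1 of one cross against the predicted-F1 profile.

    Per-cross similarity is the macro-average over the cross's F1 plants.
    """
    p1 = gm.sample_row(parent1)
    p2 = gm.sample_row(parent2)
    predicted = predict_f1(p1, p2)
    sims = pd.Series(
        {f1: f1_concordance(predicted, gm.sample_row(f1)) for f1 in f1_samples},
        name="similarity",
    )
    return CrossResult(
        cross_id=cross_id,
        parent1=parent1,
        parent2=parent2,
        n_polymorphic=count_polymorphic(p1, p2),
        per_f1_similarity=sims,
        mean_similarity=float(sims.mean()),
    )


def validate_crosses(gm: GenotypeMatrix, manifest: pd.DataFrame) -> list[CrossResult]:
    """Apply :func:`validate_cross` to a cross manifest.

    ``manifest`` needs columns cross_id, parent1, parent2, f1_sample_ids
    (the last a ';'-separated list).
    """
    results = []
    for row in manifest.itertuples(index=False):
        f1s = [s for s in str(row.f1_sample_ids).split(";") if s]
        results.append(validate_cross(gm, row.cross_id, row.parent1, row.parent2, f1s))
    return results
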