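"""Canonical synthetic study scenarios.

Each function builds a complete synthetic dataset with the structure of one
stage of an amplicon-panel validation study on rice breeding germplasm:
a ~1000-SNP panel, a diverse *indica* accession set with realistic
call-rate/heterozygosity artifacts, an F1 validation trial, a mixed
*O. sativa* diversity panel, and a multi-family elite breeding program with
field-trial phenotypes.  The default parameters are fixed study conditions
(marker counts, sample sizes, error rates, heritabilities), not tuning
knobs; analyses downstream consume these datasets unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import synthetic_data as sd
from .core import MISSING, GenotypeMatrix, concat_samples

#: per-call missing probability of a healthy assay marker (mean ~3%)
GOOD_MISSING_RANGE = (0.005, 0.06)
#: per-call missing probability of a failed assay marker (call rate << 75%)
BAD_MISSING_RANGE = (0.30, 0.95)
#: residual heterozygous-miscall rate of inbred material
RESIDUAL_HET_RATE = 0.007
#: heterozygosity of a paralog-afflicted marker
PARALOG_HET_RATE = 0.15
#: per-locus genotyping error rate between independent runs
PER_LOCUS_ERROR = 0.01


def panel_1k(seed: int = 0, n_markers: int = 995) -> sd.Panel:
    """The uniformly spaced 995-SNP panel with a high-MAF *indica* spectrum
    (MAF uniform on [0.2, 0.5]: median 0.35, quartiles ~0.28/0.43)."""
    return sd.simulate_panel(n_markers, maf_target=(0.2, 0.5), seed=seed)


def _corrupt_per_marker(
    gm: GenotypeMatrix,
    het_rates: np.ndarray,
    missing_rates: np.ndarray,
    rng: np.random.Generator,
) -> GenotypeMatrix:
    calls = gm.calls.copy()
    het = np.array([mk.ref + mk.alt for mk in gm.markers], dtype="U2")
    to_het = (np.random.default_rng(rng.integers(2**31)).random(calls.shape)
              < het_rates[None, :]) & (calls != MISSING)
    calls = np.where(to_het, np.broadcast_to(het, calls.shape), calls)
    to_miss = rng.random(calls.shape) < missing_rates[None, :]
    calls = np.where(to_miss, MISSING, calls)
    return GenotypeMatrix(markers=gm.markers, samples=gm.samples, calls=calls,
                          sample_meta=gm.sample_meta)


@dataclass
class AssayArtifacts:
    """Indices of markers given failure-mode artifacts."""

    low_cr_markers: np.ndarray
    high_het_markers: np.ndarray


def indica_diversity_panel(
    seed: int = 0,
    n_lines: int = 431,
    n_bad_cr: int = 97,
    n_high_het: int = 5,
) -> tuple[GenotypeMatrix, sd.Panel, AssayArtifacts]:
    """431 *indica* lines on the 995-SNP panel with assay artifacts.

    Lines are inbreds drawn at the panel's *indica* allele frequencies.
    ``n_bad_cr`` markers get failure-mode missingness (call rate below the
    75% filter) and ``n_high_het`` markers get paralog-like heterozygosity;
    healthy markers carry ~3% missingness and the inbred residual het rate.
    """
    panel = panel_1k(seed)
    rng = np.random.default_rng(seed + 1)
    model = sd.PopulationModel(
        subpop_allele_freqs=panel.freq_alt,
        divergence=0.0,
        residual_het_rate=0.0,
        missing_rate=0.0,
        seed=seed + 2,
        subpop_names=("indica",),
    )
    gm = sd.simulate_inbreds(panel, model, n_lines)
    m = gm.n_markers
    bad = rng.choice(m, size=n_bad_cr + n_high_het, replace=False)
    low_cr, high_het = bad[:n_bad_cr], bad[n_bad_cr:]
    het_rates = np.full(m, RESIDUAL_HET_RATE)
    het_rates[high_het] = PARALOG_HET_RATE
    missing_rates = rng.uniform(*GOOD_MISSING_RANGE, size=m)
    missing_rates[low_cr] = rng.uniform(*BAD_MISSING_RANGE, size=n_bad_cr)
    gm = _corrupt_per_marker(gm, het_rates, missing_rates, rng)
    return gm, panel, AssayArtifacts(low_cr_markers=low_cr, high_het_markers=high_het)


#: the six validation crosses: (name, subpop of parent 1, subpop of parent 2,
#: number of F1 plants) — 57 F1s in total
F1_CROSSES = (
    ("cross1", "indica", "japonica", 8),
    ("cross2", "japonica", "indica", 14),
    ("cross3", "indica", "indica", 19),
    ("cross4", "indica", "japonica", 4),
    ("cross5", "japonica", "indica", 10),
    ("cross6", "japonica", "japonica", 2),
)


def f1_trial(seed: int = 0) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Parents plus 57 observed F1 plants from six bi-parental crosses.

    Parents are clean consensus-quality inbreds from diverged *indica* and
    *japonica* pools; observed F1 genotypes carry the per-locus genotyping
    error rate and light missingness.  Returns the combined matrix and a
    cross manifest (cross_id, parent1, parent2, f1_sample_ids).
    """
    panel = panel_1k(seed)
    model = sd.population_model(
        panel, n_subpops=2, divergence=0.4, seed=seed + 3,
        residual_het_rate=0.0, missing_rate=0.0,
        subpop_names=("indica", "japonica"),
    )
    rng = np.random.default_rng(seed + 4)
    n_parents = {"indica": 0, "japonica": 0}
    for _, a, b, _n in F1_CROSSES:
        n_parents[a] += 1
        n_parents[b] += 1
    pool = sd.simulate_inbreds(panel, model, [n_parents["indica"], n_parents["japonica"]])
    cursor = {"indica": 0, "japonica": 0}
    names = {s: i for i, s in enumerate(pool.samples)}
    offset = {"indica": 0, "japonica": n_parents["indica"]}

    pieces = [pool]
    manifest_rows = []
    for cross_id, pa, pb, n_f1 in F1_CROSSES:
        ia = offset[pa] + cursor[pa]
        cursor[pa] += 1
        ib = offset[pb] + cursor[pb]
        cursor[pb] += 1
        p1, p2 = pool.samples[ia], pool.samples[ib]
        f1 = sd.simulate_cross(panel, pool.calls[ia], pool.calls[ib],
                               n_f1=n_f1, seed=int(rng.integers(2**31)), name=cross_id)
        observed = sd.simulate_replicates(f1, 1, PER_LOCUS_ERROR,
                                          seed=int(rng.integers(2**31)))
        miss = np.random.default_rng(rng.integers(2**31)).random(observed.calls.shape) < 0.02
        observed.calls[miss] = MISSING
        observed.sample_meta["replicate_group"] = None
        pieces.append(observed)
        manifest_rows.append(
            {
                "cross_id": cross_id,
                "parent1": p1,
                "parent2": p2,
                "f1_sample_ids": ";".join(observed.samples),
            }
        )
    return concat_samples(pieces), pd.DataFrame(manifest_rows)


def osativa_panel(seed: int = 0) -> GenotypeMatrix:
    """283 diverse *O. sativa* accessions: *indica*-dominated with
    *japonica* and *aus* groups at the deep-divergence default."""
    panel = panel_1k(seed)
    model = sd.population_model(
        panel, n_subpops=3, divergence=0.4, seed=seed + 5,
        residual_het_rate=RESIDUAL_HET_RATE, missing_rate=0.03,
        subpop_names=("indica", "japonica", "aus"),
    )
    return sd.simulate_inbreds(panel, model, [195, 60, 28])


def gs_program(seed: int = 0, h2: float = 0.85, trait: str = "FLW") -> sd.BreedingProgram:
    """353 elite lines from 30 bi-parental families (average size ~12) with
    three partially replicated yield trials (replication 1.2).

    The default heritability 0.85 matches a flowering-time-like trait.
    """
    panel = panel_1k(seed)
    rng = np.random.default_rng(seed + 6)
    sizes = np.clip(rng.poisson(12, size=30), 1, 36)
    while sizes.sum() != 353:
        j = rng.integers(30)
        if sizes.sum() > 353 and sizes[j] > 1:
            sizes[j] -= 1
        elif sizes.sum() < 353 and sizes[j] < 36:
            sizes[j] += 1
    arch = sd.TraitArchitecture(n_qtl=200, h2=h2, trial_var=1.0, rep_var=0.25)
    return sd.simulate_breeding_program(
        panel, n_families=30, family_sizes=list(sizes), arch=arch,
        n_trials=3, n_reps_per_trial=1.2, seed=seed + 7, trait=trait,
    )
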