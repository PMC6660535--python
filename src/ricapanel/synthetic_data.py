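"""Synthetic rice genotype, pedigree and phenotype generators.

The generators emulate the statistical structure of amplicon-panel data on
*indica*/*japonica*/*aus* breeding germplasm: ~1000 biallelic SNPs spread
over 12 chromosomes, subpopulation allele-frequency divergence following a
Balding–Nichols Beta model, inbred lines with a small residual
heterozygosity from miscalls, per-call missingness, replicated genotyping
runs with a per-locus error rate, bi-parental crosses, and an additive
polygenic trait observed in multi-trial field plots.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    NUCLEOTIDES,
    RICE_CHROM_LENGTHS,
    GenotypeError,
    GenotypeMatrix,
    MarkerRecord,
    Pedigree,
    hom_call,
)


class Panel(list):
    """A list of MarkerRecord that also carries the simulated alt-allele
    frequencies (``freq_alt``) used to seed population models."""

    freq_alt: np.ndarray | None = None


def simulate_panel(
    n_markers: int,
    genome_model: dict[str, int] | None = None,
    maf_target: tuple[float, float] = (0.2, 0.5),
    seed: int = 0,
) -> Panel:
    """Simulate a uniformly spaced (with jitter) marker panel.

    Markers are allotted to chromosomes proportionally to physical length,
    placed on an even grid within each chromosome and jittered by up to 30%
    of the local spacing.  Each marker's minor allele frequency is drawn
    uniformly inside ``maf_target`` and recorded on the returned panel.
    """
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    lo, hi = maf_target
    if not (0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_target must lie inside (0, 0.5], got {maf_target}")
    genome = dict(genome_model or RICE_CHROM_LENGTHS)
    rng = np.random.default_rng(seed)

    chroms = list(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    # largest-remainder apportionment, at least one marker per chromosome
    # while the marker budget allows
    quota = n_markers * lengths / lengths.sum()
    counts = np.floor(quota).astype(int)
    if n_markers >= len(chroms):
        counts = np.maximum(counts, 1)
    while counts.sum() > n_markers:
        counts[np.argmax(counts - quota)] -= 1
    order = np.argsort(-(quota - counts))
    i = 0
    while counts.sum() < n_markers:
        counts[order[i % len(chroms)]] += 1
        i += 1

    records: list[MarkerRecord] = []
    for c, k in zip(chroms, counts):
        if k == 0:
            continue
        spacing = genome[c] / k
        centers = (np.arange(k) + 0.5) * spacing
        jitter = rng.uniform(-0.3, 0.3, size=k) * spacing
        pos = np.clip(np.round(centers + jitter), 1, genome[c]).astype(int)
        pos = np.sort(pos)
        # resolve collisions deterministically
        for idx in range(1, k):
            if pos[idx] <= pos[idx - 1]:
                pos[idx] = pos[idx - 1] + 1
        for p in pos:
            a, b = rng.choice(len(NUCLEOTIDES), size=2, replace=False)
            records.append(
                MarkerRecord(
                    marker_id=f"{c}:{int(p)}",
                    chrom=c,
                    pos_bp=int(p),
                    alleles=(NUCLEOTIDES[a], NUCLEOTIDES[b]),
                    source="C6AIR",
                )
            )
    panel = Panel(sorted(records, key=lambda m: (m.chrom, m.pos_bp)))
    maf = rng.uniform(lo, hi, size=len(panel))
    flip = rng.random(len(panel)) < 0.5
    panel.freq_alt = np.where(flip, maf, 1.0 - maf)
    return panel


@dataclass
class PopulationModel:
    """Subpopulation allele-frequency model for inbred line simulation.

    ``subpop_allele_freqs`` has shape (n_subpops, n_markers) and stores the
    alternate-allele frequency per subpopulation.  ``divergence`` is the
    Fst-like parameter of the Balding–Nichols Beta draw that produced them.
    """

    subpop_allele_freqs: np.ndarray
    divergence: float = 0.0
    residual_het_rate: float = 0.007
    missing_rate: float = 0.05
    seed: int = 0
    subpop_names: tuple[str, ...] | None = None
    ld_block_size: int = 1
    ld_fidelity: float = 0.95

    def __post_init__(self) -> None:
        self.subpop_allele_freqs = np.atleast_2d(np.asarray(self.subpop_allele_freqs, dtype=float))
        f = self.subpop_allele_freqs
        if np.any((f < 0) | (f > 1)):
            raise ValueError("allele frequencies must lie in [0, 1]")
        for name, rate in (("divergence", self.divergence),
                           ("residual_het_rate", self.residual_het_rate),
                           ("missing_rate", self.missing_rate)):
            if not (0 <= rate < 1):
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.subpop_names is None:
            self.subpop_names = tuple(f"pop{i+1}" for i in range(self.n_subpops))
        if len(self.subpop_names) != self.n_subpops:
            raise ValueError("subpop_names length must equal n_subpops")

    @property
    def n_subpops(self) -> int:
        return self.subpop_allele_freqs.shape[0]

    @property
    def n_markers(self) -> int:
        return self.subpop_allele_freqs.shape[1]


def population_model(
    panel: Sequence[MarkerRecord],
    n_subpops: int = 3,
    divergence: float = 0.4,
    residual_het_rate: float = 0.007,
    missing_rate: float = 0.05,
    seed: int = 0,
    subpop_names: tuple[str, ...] | None = None,
    ancestral_freq: np.ndarray | None = None,
    maf_range: tuple[float, float] = (0.2, 0.5),
    ld_block_size: int = 1,
    ld_fidelity: float = 0.95,
) -> PopulationModel:
    """Draw a PopulationModel for a panel via the Balding–Nichols model.

    Ancestral alternate-allele frequencies come from the panel's simulated
    frequencies when available, otherwise a fresh uniform-MAF draw; each
    subpopulation's frequencies are Beta(p(1-F)/F, (1-p)(1-F)/F) draws
    around the ancestral p with F = ``divergence``.  The default divergence
    of 0.4 reflects the deep *indica*/*japonica* split.
    """
    rng = np.random.default_rng(seed)
    m = len(panel)
    if ancestral_freq is not None:
        p = np.asarray(ancestral_freq, dtype=float)
    elif getattr(panel, "freq_alt", None) is not None:
        p = np.asarray(panel.freq_alt, dtype=float)
    else:
        maf = rng.uniform(*maf_range, size=m)
        flip = rng.random(m) < 0.5
        p = np.where(flip, maf, 1.0 - maf)
    p = np.clip(p, 1e-6, 1 - 1e-6)
    if divergence <= 0:
        freqs = np.tile(p, (n_subpops, 1))
    else:
        c = (1.0 - divergence) / divergence
        freqs = rng.beta(p * c, (1.0 - p) * c, size=(n_subpops, m))
    return PopulationModel(
        subpop_allele_freqs=freqs,
        divergence=divergence,
        residual_het_rate=residual_het_rate,
        missing_rate=missing_rate,
        seed=seed,
        subpop_names=subpop_names,
        ld_block_size=ld_block_size,
        ld_fidelity=ld_fidelity,
    )


def _calls_from_alt_indicator(markers: Sequence[MarkerRecord], alt: np.ndarray) -> np.ndarray:
    """Map a boolean (n, m) alt-allele indicator to homozygous call strings."""
    ref_calls = np.array([hom_call(mk.ref) for mk in markers], dtype="U2")
    alt_calls = np.array([hom_call(mk.alt) for mk in markers], dtype="U2")
    return np.where(alt, alt_calls[None, :], ref_calls[None, :])


def _corrupt(
    calls: np.ndarray,
    markers: Sequence[MarkerRecord],
    residual_het_rate: float,
    missing_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    out = calls.copy()
    if residual_het_rate > 0:
        het = np.array([mk.ref + mk.alt for mk in markers], dtype="U2")
        mask = (rng.random(out.shape) < residual_het_rate) & (out != MISSING)
        out = np.where(mask, np.broadcast_to(het, out.shape), out)
    if missing_rate > 0:
        out = np.where(rng.random(out.shape) < missing_rate, MISSING, out)
    return out


def simulate_inbreds(
    panel: Sequence[MarkerRecord],
    pop_model: PopulationModel,
    n_per_subpop: int | Sequence[int],
    seed: int | None = None,
) -> GenotypeMatrix:
    """Simulate inbred lines: homozygous draws from subpopulation frequencies
    corrupted by residual heterozygosity and missingness.

    With ``ld_block_size > 1`` consecutive markers share a latent haplotype
    indicator copied with probability ``ld_fidelity``, producing
    within-block r² of about ``ld_fidelity**4``.
    """
    m = len(panel)
    if pop_model.n_markers != m:
        raise ValueError("population model and panel have different marker counts")
    if isinstance(n_per_subpop, int):
        n_per_subpop = [n_per_subpop] * pop_model.n_subpops
    if len(n_per_subpop) != pop_model.n_subpops:
        raise ValueError("n_per_subpop length must equal n_subpops")
    rng = np.random.default_rng(pop_model.seed if seed is None else seed)

    blocks = np.arange(m) // max(1, pop_model.ld_block_size)
    rows: list[np.ndarray] = []
    names: list[str] = []
    subpops: list[str] = []
    for k, (name, n_k) in enumerate(zip(pop_model.subpop_names, n_per_subpop)):
        q = pop_model.subpop_allele_freqs[k]
        if pop_model.ld_block_size > 1:
            # one representative frequency per block keeps within-block LD clean
            q_block = q[np.searchsorted(blocks, np.unique(blocks))]
            latent = rng.random((n_k, len(q_block))) < q_block
            z = latent[:, blocks]
            copy = rng.random((n_k, m)) < pop_model.ld_fidelity
            indep = rng.random((n_k, m)) < q[None, :]
            alt = np.where(copy, z, indep)
        else:
            alt = rng.random((n_k, m)) < q[None, :]
        rows.append(alt)
        names.extend(f"{name}-{i+1:04d}" for i in range(n_k))
        subpops.extend([name] * n_k)

    alt_all = np.vstack(rows) if rows else np.zeros((0, m), dtype=bool)
    calls = _calls_from_alt_indicator(panel, alt_all)
    calls = _corrupt(calls, panel, pop_model.residual_het_rate, pop_model.missing_rate, rng)
    meta = pd.DataFrame({"accession": names, "subpop": subpops}, index=names)
    return GenotypeMatrix(markers=list(panel), samples=names, calls=calls, sample_meta=meta)


def simulate_replicates(
    truth: GenotypeMatrix,
    n_reps: int,
    per_locus_error: float,
    seed: int = 0,
) -> GenotypeMatrix:
    """Replicate every accession ``n_reps`` times with per-locus call errors.

    Each replicate call is independently replaced by one of the other two
    possible genotypes at the marker with probability ``per_locus_error``;
    missing calls stay missing.  The replicate group in the metadata is the
    source accession.
    """
    if not (0 <= per_locus_error < 1):
        raise ValueError("per_locus_error must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    m = truth.n_markers
    genos = np.stack(
        [
            np.array([hom_call(mk.ref) for mk in truth.markers], dtype="U2"),
            np.array([mk.ref + mk.alt for mk in truth.markers], dtype="U2"),
            np.array([hom_call(mk.alt) for mk in truth.markers], dtype="U2"),
        ]
    )  # (3, m)

    all_calls = []
    names: list[str] = []
    groups: list[str] = []
    for i, acc in enumerate(truth.samples):
        base = truth.calls[i]
        for r in range(n_reps):
            rep = base.copy()
            err = (rng.random(m) < per_locus_error) & (rep != MISSING)
            idx = np.nonzero(err)[0]
            for j in idx:
                options = [g for g in genos[:, j] if g != rep[j]]
                rep[j] = options[rng.integers(len(options))]
            all_calls.append(rep)
            names.append(f"{acc}_rep{r+1}")
            groups.append(acc)
    meta = pd.DataFrame({"accession": groups, "replicate_group": groups}, index=names)
    if "subpop" in truth.sample_meta.columns:
        meta["subpop"] = [truth.sample_meta.loc[g, "subpop"] for g in groups]
    return GenotypeMatrix(
        markers=list(truth.markers),
        samples=names,
        calls=np.vstack(all_calls) if all_calls else np.zeros((0, m), dtype="U2"),
        sample_meta=meta,
    )


def simulate_cross(
    markers: Sequence[MarkerRecord],
    parent1: np.ndarray,
    parent2: np.ndarray,
    n_f1: int = 1,
    f2: bool = False,
    seed: int = 0,
    name: str = "cross",
) -> GenotypeMatrix:
    """Simulate F1 (or F2) progeny of two fully homozygous parents.

    F1s are heterozygous wherever the parents carry different homozygotes,
    homozygous where they agree, and missing where either parent is missing.
    With ``f2=True`` each marker segregates independently 1:2:1 (markers are
    treated as unlinked).
    """
    p1 = np.asarray(parent1, dtype="U2")
    p2 = np.asarray(parent2, dtype="U2")
    for p, tag in ((p1, "parent1"), (p2, "parent2")):
        het = (p != MISSING) & (p.view("U1").reshape(-1, 2)[:, 0] != p.view("U1").reshape(-1, 2)[:, 1])
        if het.any():
            raise GenotypeError(f"{tag} is heterozygous at {int(het.sum())} markers; parents must be homozygous")
    rng = np.random.default_rng(seed)
    m = len(markers)
    missing = (p1 == MISSING) | (p2 == MISSING)
    same = (p1 == p2) & ~missing
    diff = ~same & ~missing

    f1_row = np.full(m, MISSING, dtype="U2")
    f1_row[same] = p1[same]
    het_calls = np.array(
        [min(a, b) + max(a, b) for a, b in zip(p1.view("U1").reshape(-1, 2)[:, 0], p2.view("U1").reshape(-1, 2)[:, 0])],
        dtype="U2",
    )
    f1_row[diff] = het_calls[diff]

    rows = []
    names = []
    if not f2:
        for i in range(n_f1):
            rows.append(f1_row.copy())
            names.append(f"{name}-F1-{i+1:03d}")
    else:
        for i in range(n_f1):
            row = f1_row.copy()
            seg = rng.integers(0, 4, size=m)  # two independent gametes
            at_diff = np.nonzero(diff)[0]
            for j in at_diff:
                draw = seg[j]
                if draw == 0:
                    row[j] = p1[j]
                elif draw == 3:
                    row[j] = p2[j]
                else:
                    row[j] = het_calls[j]
            rows.append(row)
            names.append(f"{name}-F2-{i+1:03d}")
    meta = pd.DataFrame({"accession": names, "family": [name] * len(names)}, index=names)
    return GenotypeMatrix(markers=list(markers), samples=names, calls=np.array(rows, dtype="U2"), sample_meta=meta)


@dataclass
class TraitArchitecture:
    """Additive trait architecture for breeding-program simulation.

    With ``resid_var=None`` the plot residual variance is derived from the
    target accession-mean heritability ``h2`` given the trial structure, so
    the realized components are consistent with ``h2`` by construction.
    """

    n_qtl: int = 100
    effect_distribution: str = "gaussian"  # or "scaled-t"
    h2: float = 0.85
    trial_var: float = 1.0
    rep_var: float = 0.25
    resid_var: float | None = None
    mu: float = 100.0

    def __post_init__(self) -> None:
        if not (0 < self.h2 <= 1):
            raise ValueError("h2 must lie in (0, 1]")
        if self.effect_distribution not in ("gaussian", "scaled-t"):
            raise ValueError("effect_distribution must be 'gaussian' or 'scaled-t'")
        for name in ("trial_var", "rep_var"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class BreedingProgram:
    """A simulated multi-family breeding dataset with its generating truth."""

    genotypes: GenotypeMatrix
    pedigree: Pedigree
    plots: pd.DataFrame
    true_effects: np.ndarray
    true_breeding_values: pd.Series
    mu: float
    variance_components: dict[str, float]


def simulate_breeding_program(
    panel: Sequence[MarkerRecord],
    n_families: int = 30,
    family_sizes: int | Sequence[int] = 12,
    arch: TraitArchitecture | None = None,
    n_trials: int = 3,
    n_reps_per_trial: float = 1.2,
    n_founders: int = 20,
    founder_freq: np.ndarray | None = None,
    seed: int = 0,
    trait: str = "FLW",
) -> BreedingProgram:
    """Simulate an elite bi-parental breeding program with field trials.

    Families are crosses between founders drawn from one elite pool; family
    members are recombinant inbred lines (independent homozygous draws from
    the two parental alleles per marker).  True breeding values are sums of
    additive marker effects scaled to unit genetic variance; plot phenotypes
    follow mu + g_i + t_j + r(t)_jk + e_ijk.  Fractional
    ``n_reps_per_trial`` (e.g. 1.2) yields a p-rep layout where the
    fractional part of the genotypes get a second plot per trial.
    """
    arch = arch or TraitArchitecture()
    rng = np.random.default_rng(seed)
    m = len(panel)

    if founder_freq is None:
        if getattr(panel, "freq_alt", None) is not None:
            founder_freq = np.asarray(panel.freq_alt, dtype=float)
        else:
            maf = rng.uniform(0.2, 0.5, size=m)
            founder_freq = np.where(rng.random(m) < 0.5, maf, 1 - maf)

    founder_alt = rng.random((n_founders, m)) < founder_freq[None, :]
    founder_names = [f"FND-{i+1:03d}" for i in range(n_founders)]

    if isinstance(family_sizes, int):
        sizes = [family_sizes] * n_families
    else:
        sizes = list(family_sizes)
        if len(sizes) != n_families:
            raise ValueError("family_sizes length must equal n_families")

    ped_entries: list[tuple[str, str | None, str | None]] = [(f, None, None) for f in founder_names]
    alt_rows = []
    names: list[str] = []
    fams: list[str] = []
    for f in range(n_families):
        i1, i2 = rng.choice(n_founders, size=2, replace=False)
        fam = f"FAM-{f+1:02d}"
        for k in range(sizes[f]):
            pick = rng.random(m) < 0.5
            alt_rows.append(np.where(pick, founder_alt[i1], founder_alt[i2]))
            line = f"{fam}-{k+1:03d}"
            names.append(line)
            fams.append(fam)
            ped_entries.append((line, founder_names[i1], founder_names[i2]))

    alt = np.vstack(alt_rows)
    calls = _calls_from_alt_indicator(panel, alt)
    meta = pd.DataFrame({"accession": names, "family": fams}, index=names)
    gm = GenotypeMatrix(markers=list(panel), samples=names, calls=calls, sample_meta=meta)
    ped = Pedigree(entries=ped_entries)

    # additive architecture on dosage scale, genetic variance standardized to 1
    qtl = rng.choice(m, size=min(arch.n_qtl, m), replace=False)
    beta = np.zeros(m)
    if arch.effect_distribution == "gaussian":
        beta[qtl] = rng.normal(0, 1, size=len(qtl))
    else:
        beta[qtl] = rng.standard_t(df=4, size=len(qtl))
    dosage = 2.0 * alt
    tbv = dosage @ beta
    sd = tbv.std()
    if sd > 0:
        beta /= sd
        tbv /= sd
    tbv = tbv - tbv.mean()
    sigma_g2 = float(np.var(tbv))

    t = n_trials
    r = n_reps_per_trial
    if arch.resid_var is None:
        resid_var = sigma_g2 * (1.0 / arch.h2 - 1.0) * t * r
    else:
        resid_var = arch.resid_var

    n = len(names)
    n_rep_blocks = 2
    trial_eff = rng.normal(0, np.sqrt(arch.trial_var), size=t)
    rep_eff = rng.normal(0, np.sqrt(arch.rep_var), size=(t, n_rep_blocks))
    frac = r - int(r)
    rows = []
    for j in range(t):
        extra = rng.choice(n, size=int(round(frac * n)), replace=False)
        for i in range(n):
            n_plots = int(r) + (1 if i in set(extra) else 0)
            for k in range(n_plots):
                block = k % n_rep_blocks
                y = (
                    arch.mu
                    + tbv[i]
                    + trial_eff[j]
                    + rep_eff[j, block]
                    + rng.normal(0, np.sqrt(resid_var))
                )
                rows.append(
                    {
                        "genotype": names[i],
                        "trial": f"T{j+1}",
                        "rep": f"T{j+1}R{block+1}",
                        "trait": trait,
                        "value": y,
                    }
                )
    plots = pd.DataFrame(rows)
    return BreedingProgram(
        genotypes=gm,
        pedigree=ped,
        plots=plots,
        true_effects=beta,
        true_breeding_values=pd.Series(tbv, index=names),
        mu=arch.mu,
        variance_components={
            "sigma_g2": sigma_g2,
            "sigma_t2": arch.trial_var,
            "sigma_r2": arch.rep_var,
            "sigma_e2": resid_var,
        },
    )
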