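"""Per-marker QC statistics, filtering, replicate repeatability,
cross-platform concordance, consensus genotypes, and LD-kNN imputation.

Filter boundaries are inclusive exactly as commonly printed for amplicon
panels: a marker fails with MAF <= 0.01, heterozygosity >= 10%, or call
rate <= 75%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeError, GenotypeMatrix, hom_call

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
AMBIGUOUS_PAIRS = {("A", "T"), ("C", "G")}


# ---------------------------------------------------------------------------
# marker-level QC
# ---------------------------------------------------------------------------

def marker_qc(
    gm: GenotypeMatrix,
    max_maf_fail: float = 0.01,
    min_het_fail: float = 0.10,
    max_cr_fail: float = 0.75,
) -> pd.DataFrame:
    """Call rate, heterozygosity and MAF per marker, with pass/fail flags.

    Returns a DataFrame indexed like the marker list with columns
    ``marker_id, call_rate, het, maf, pass, fail_reasons``.  A marker with
    zero called samples has call rate 0, undefined (NaN) het/maf, and fails
    LOW_CR only.
    """
    if gm.n_samples < 1:
        raise GenotypeError("need at least one sample")
    called = ~gm.missing_mask()
    n_called = called.sum(axis=0).astype(float)
    cr = n_called / gm.n_samples

    het = gm.het_mask()
    n_het = het.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        het_frac = np.where(n_called > 0, n_het / n_called, np.nan)

    dose = gm.dosage()
    alt_count = np.nansum(dose, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.where(n_called > 0, alt_count / (2.0 * n_called), np.nan)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)

    rows = []
    for j, m in enumerate(gm.markers):
        reasons = []
        if cr[j] <= max_cr_fail:
            reasons.append("LOW_CR")
        if n_called[j] > 0:
            if het_frac[j] >= min_het_fail:
                reasons.append("HIGH_HET")
            if maf[j] <= max_maf_fail:
                reasons.append("LOW_MAF")
        rows.append(
            {
                "marker_id": m.marker_id,
                "call_rate": cr[j],
                "het": het_frac[j],
                "maf": maf[j],
                "pass": not reasons,
                "fail_reasons": ",".join(reasons),
            }
        )
    return pd.DataFrame(rows)


def filter_markers(gm: GenotypeMatrix, qc: pd.DataFrame | None = None, **qc_kwargs) -> GenotypeMatrix:
    """Restrict the matrix to markers passing QC; idempotent."""
    if qc is None:
        qc = marker_qc(gm, **qc_kwargs)
    if len(qc) != gm.n_markers:
        raise GenotypeError("QC table is not aligned to the marker list")
    keep = np.nonzero(qc["pass"].to_numpy())[0]
    if len(keep) == 0:
        warnings.warn("all markers failed QC; returning an empty matrix", stacklevel=2)
    dropped = qc.loc[~qc["pass"], "fail_reasons"]
    if len(dropped):
        counts = (
            dropped.str.split(",").explode().value_counts().to_dict()
        )
        warnings.warn(f"removed {len(dropped)} markers; reason counts {counts}", stacklevel=2)
    return gm.subset_markers(keep)


# ---------------------------------------------------------------------------
# consensus and repeatability
# ---------------------------------------------------------------------------

def consensus_genotype(replicate_calls: np.ndarray) -> np.ndarray:
    """Strict-majority consensus across replicate rows of one accession.

    Per locus the most frequent non-missing call wins if it is a strict
    majority winner (no tie); ties and all-missing loci yield missing.
    """
    reps = np.asarray(replicate_calls, dtype="U2")
    if reps.ndim == 1:
        reps = reps[None, :]
    n_rep, m = reps.shape
    out = np.full(m, MISSING, dtype="U2")
    for j in range(m):
        col = reps[:, j]
        col = col[col != MISSING]
        if len(col) == 0:
            continue
        vals, counts = np.unique(col, return_counts=True)
        top = counts.max()
        winners = vals[counts == top]
        if len(winners) == 1:
            out[j] = winners[0]
    return out


@dataclass
class RepeatabilityResult:
    """Replicate-consistency summary: R = 100 - mean per-locus error."""

    per_locus_m: np.ndarray
    per_locus_n: np.ndarray
    per_accession_R: pd.Series
    mean_e_l: float  # fraction, not percent
    R: float  # percent

    @property
    def per_locus_e(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.per_locus_n > 0, self.per_locus_m / self.per_locus_n, np.nan)


def repeatability(gm: GenotypeMatrix, min_reps: int = 4, drop_hets: bool = False) -> RepeatabilityResult:
    """Genotype repeatability across independent replicates of accessions.

    Replicates are grouped by the ``replicate_group`` metadata column; only
    accessions with at least ``min_reps`` replicates enter.  Each replicate
    call is compared to the accession's strict-majority consensus; any
    allelic mismatch between two non-missing calls counts toward m_l, every
    non-missing comparison toward n_l.  With ``drop_hets`` heterozygous
    replicate calls are set missing before consensus and comparison.
    """
    groups = gm.sample_meta["replicate_group"]
    if groups.isna().all():
        raise GenotypeError("no replicate_group metadata present")
    m = gm.n_markers
    m_l = np.zeros(m)
    n_l = np.zeros(m)
    per_acc: dict[str, float] = {}
    n_used = 0
    sidx = gm.sample_index()
    for acc, members in groups.groupby(groups).groups.items():
        if len(members) < min_reps:
            continue
        n_used += 1
        rows = gm.calls[[sidx[s] for s in members], :].copy()
        if drop_hets:
            first = rows.view("U1").reshape(len(members), m, 2)
            rows[(rows != MISSING) & (first[:, :, 0] != first[:, :, 1])] = MISSING
        ref = consensus_genotype(rows)
        comparable = (rows != MISSING) & (ref != MISSING)[None, :]
        mismatch = comparable & (rows != ref[None, :])
        m_l += mismatch.sum(axis=0)
        n_l += comparable.sum(axis=0)
        acc_n = comparable.sum()
        per_acc[str(acc)] = float(100.0 * (1.0 - mismatch.sum() / acc_n)) if acc_n else np.nan
    if n_used == 0:
        raise GenotypeError(f"no accession has >= {min_reps} replicates")
    with np.errstate(invalid="ignore", divide="ignore"):
        e_l = np.where(n_l > 0, m_l / n_l, np.nan)
    mean_e = float(np.nanmean(e_l))
    return RepeatabilityResult(
        per_locus_m=m_l,
        per_locus_n=n_l,
        per_accession_R=pd.Series(per_acc, name="R"),
        mean_e_l=mean_e,
        R=100.0 * (1.0 - mean_e),
    )


# ---------------------------------------------------------------------------
# cross-platform concordance
# ---------------------------------------------------------------------------

def _complement_call(call: str) -> str:
    if call == MISSING:
        return call
    a, b = COMPLEMENT[call[0]], COMPLEMENT[call[1]]
    return a + b if a <= b else b + a


@dataclass
class ConcordanceResult:
    """Exact-match genotype concordance between two platforms."""

    n_overlap_markers: int
    n_compared_calls: int
    n_matches: int
    concordance: float  # percent
    per_sample: pd.DataFrame
    excluded_markers: list[str]


def concordance(
    gm_a: GenotypeMatrix,
    gm_b: GenotypeMatrix,
    sample_map: Sequence[tuple[str, str]],
) -> ConcordanceResult:
    """Concordance of canonical calls at markers shared by (chrom, pos).

    Calls missing on either side are excluded from the comparison.  When the
    two platforms report different allele pairs at a shared marker, platform
    B is complement-reconciled if that makes the pairs agree (opposite-strand
    reporting); markers that stay incompatible — which includes all
    strand-ambiguous A/T and C/G disagreements — are flagged and excluded.
    """
    if not sample_map:
        raise GenotypeError("need at least one mapped sample pair")
    pos_a = {(m.chrom, m.pos_bp): j for j, m in enumerate(gm_a.markers)}
    shared: list[tuple[int, int, bool]] = []  # (ja, jb, flip_b)
    excluded: list[str] = []
    for jb, mb in enumerate(gm_b.markers):
        ja = pos_a.get((mb.chrom, mb.pos_bp))
        if ja is None:
            continue
        ma = gm_a.markers[ja]
        if ma.alleles == mb.alleles:
            shared.append((ja, jb, False))
        else:
            flipped = tuple(sorted(COMPLEMENT[x] for x in mb.alleles))
            if flipped == ma.alleles:
                shared.append((ja, jb, True))
            else:
                excluded.append(ma.marker_id)
    if not shared and not excluded:
        raise GenotypeError("no markers shared by (chrom, pos)")
    if not shared:
        raise GenotypeError("all shared markers have irreconcilable allele pairs")

    aidx = gm_a.sample_index()
    bidx = gm_b.sample_index()
    rows = []
    total_cmp = 0
    total_match = 0
    for sa, sb in sample_map:
        ca = gm_a.calls[aidx[sa]]
        cb = gm_b.calls[bidx[sb]]
        n_cmp = 0
        n_match = 0
        for ja, jb, flip in shared:
            a, b = ca[ja], cb[jb]
            if a == MISSING or b == MISSING:
                continue
            if flip:
                b = _complement_call(b)
            n_cmp += 1
            n_match += a == b
        rows.append(
            {
                "sample_a": sa,
                "sample_b": sb,
                "n_compared": n_cmp,
                "n_matches": n_match,
                "concordance": 100.0 * n_match / n_cmp if n_cmp else np.nan,
            }
        )
        total_cmp += n_cmp
        total_match += n_match
    return ConcordanceResult(
        n_overlap_markers=len(shared),
        n_compared_calls=total_cmp,
        n_matches=total_match,
        concordance=100.0 * total_match / total_cmp if total_cmp else np.nan,
        per_sample=pd.DataFrame(rows),
        excluded_markers=excluded,
    )


# ---------------------------------------------------------------------------
# LD-kNN imputation
# ---------------------------------------------------------------------------

def _pairwise_complete_r2(dose: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between marker columns using
    pairwise-complete observations, computed with masked cross-products."""
    mask = ~np.isnan(dose)
    z = np.where(mask, dose, 0.0)
    m = mask.astype(float)
    n = m.T @ m
    s_xy = z.T @ z
    s_x = z.T @ m  # s_x[j, k] = sum of x_j over rows complete in (j, k)
    s_xx = (z * z).T @ m
    with np.errstate(invalid="ignore", divide="ignore"):
        ex = s_x / n
        ey = s_x.T / n
        cov = s_xy / n - ex * ey
        vx = s_xx / n - ex**2
        vy = s_xx.T / n - ey**2
        r2 = cov**2 / (vx * vy)
    r2[~np.isfinite(r2)] = 0.0
    np.fill_diagonal(r2, 0.0)
    return r2


def impute_ld_knn(
    gm: GenotypeMatrix,
    l_sites: int = 30,
    k_neighbors: int = 30,
    eps: float = 1e-6,
) -> GenotypeMatrix:
    """LD-kNN genotype imputation.

    For each missing call at (sample s, marker j): the ``l_sites`` markers
    most correlated (r²) with j define a local context; the distance from s
    to every other sample is the mean absolute dosage difference over those
    sites (missing pairs skipped, samples sharing no observed site
    excluded); the imputed dosage is the 1/(d+eps)-weighted mean dosage of
    the ``k_neighbors`` nearest neighbours called at j, rounded to {0,1,2}
    with rounding ties resolved to the single nearest neighbour's genotype.
    Non-missing calls are never altered; unfillable calls stay missing.
    """
    if gm.n_markers < 2 or gm.n_samples < 2:
        raise GenotypeError("LD-kNN imputation needs at least 2 samples and 2 markers")
    dose = gm.dosage()
    n, m = dose.shape
    r2 = _pairwise_complete_r2(dose)
    out = gm.calls.copy()
    geno_strings = np.stack(
        [
            np.array([hom_call(mk.ref) for mk in gm.markers], dtype="U2"),
            np.array([mk.ref + mk.alt for mk in gm.markers], dtype="U2"),
            np.array([hom_call(mk.alt) for mk in gm.markers], dtype="U2"),
        ]
    )
    l_sites = min(l_sites, m - 1)
    for j in range(m):
        miss = np.nonzero(np.isnan(dose[:, j]))[0]
        if len(miss) == 0:
            continue
        sites = np.argsort(-r2[:, j], kind="stable")[:l_sites]
        A = dose[np.ix_(miss, sites)]  # (a, l)
        B = dose[:, sites]  # (n, l)
        diff = np.abs(A[:, None, :] - B[None, :, :])
        valid = ~np.isnan(diff)
        cnt = valid.sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.where(cnt > 0, np.nansum(diff, axis=2) / cnt, np.inf)
        donor_ok = ~np.isnan(dose[:, j])
        for a, s in enumerate(miss):
            d = dist[a].copy()
            d[s] = np.inf
            d[~donor_ok] = np.inf
            order = np.argsort(d, kind="stable")
            order = order[np.isfinite(d[order])][:k_neighbors]
            if len(order) == 0:
                continue
            w = 1.0 / (d[order] + eps)
            vals = dose[order, j]
            wmean = float(np.sum(w * vals) / np.sum(w))
            lo = int(np.floor(wmean))
            if abs(wmean - lo - 0.5) < 1e-12:  # exact rounding tie
                pred = int(vals[0])
            else:
                pred = int(np.clip(round(wmean), 0, 2))
            out[s, j] = geno_strings[pred, j]
    return GenotypeMatrix(
        markers=list(gm.markers),
        samples=list(gm.samples),
        calls=out,
        sample_meta=gm.sample_meta,
    )


def impute_mode(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Column-mode imputation: each missing call takes its marker's most
    frequent non-missing genotype (lowest dosage wins ties).  Serves as the
    simple baseline LD-kNN is judged against."""
    out = gm.calls.copy()
    for j in range(gm.n_markers):
        col = out[:, j]
        called = col[col != MISSING]
        if len(called) == 0:
            continue
        vals, counts = np.unique(called, return_counts=True)
        mode = vals[np.argmax(counts)]
        col[col == MISSING] = mode
    return GenotypeMatrix(
        markers=list(gm.markers), samples=list(gm.samples), calls=out, sample_meta=gm.sample_meta
    )
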