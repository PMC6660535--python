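"""Trait-marker diagnostics for marker-assisted selection.

A :class:`TraitMarkerDef` maps genotypes at one SNP (single mode) or an
ordered multi-SNP haplotype to favorable/unfavorable status or a trait
class (e.g. high/intermediate/low amylose).  The packaged definition file
covers the 21 diagnostic SNPs across 11 genes/QTLs carried on the 1k-RiCA
amplicon panel.

Diagnostic quality is scored with three breeding-oriented rates:

Utility
    percentage of an assessed breeding pool NOT carrying the favorable
    (donor) allele — i.e. the share of the pool the marker can be used on.
FPR
    percentage of known recipients not showing the unfavorable allele
    (incorrectly classified as carrying the target allele).
FNR
    percentage of known donors not showing the favorable allele.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeError, GenotypeMatrix

UNKNOWN = "unknown"
FAVORABLE = "favorable"
UNFAVORABLE = "unfavorable"


@dataclass
class TraitMarkerDef:
    """Allele/haplotype -> trait-class rules for one gene or QTL."""

    trait: str
    gene_label: str
    marker_ids: list[str]
    use_mode: str  # "single" | "haplotype"
    favorable: list[str] = field(default_factory=list)
    unfavorable: list[str] = field(default_factory=list)
    class_map: dict[str, str] = field(default_factory=dict)
    note: str | None = None

    def __post_init__(self) -> None:
        if self.use_mode not in ("single", "haplotype"):
            raise ValueError(f"use_mode must be single|haplotype, got {self.use_mode}")
        if self.use_mode == "single" and len(self.marker_ids) != 1:
            raise ValueError("single mode requires exactly one marker")
        overlap = set(self.favorable) & set(self.unfavorable)
        if overlap:
            raise ValueError(f"haplotypes listed as both favorable and unfavorable: {overlap}")

    def classify(self, haplotype: str) -> str:
        """Class of a fully determined allele string across the def's markers."""
        if self.class_map:
            return self.class_map.get(haplotype, UNKNOWN)
        if haplotype in self.favorable:
            return FAVORABLE
        if haplotype in self.unfavorable:
            return UNFAVORABLE
        return UNKNOWN


class TraitDefinitionError(GenotypeError):
    """A trait-marker definition cannot be applied to the genotype matrix."""


def load_trait_marker_defs(path: str | Path | None = None) -> list[TraitMarkerDef]:
    """Load trait-marker definitions from CSV (default: the packaged panel).

    Rows are grouped by (trait, gene); the first row of each haplotype group
    carries the favorable/unfavorable haplotypes and/or class map.
    """
    if path is None:
        source = resources.files("ricapanel") / "data" / "trait_marker_defs.csv"
        df = pd.read_csv(source, dtype=str, keep_default_na=False)  # type: ignore[arg-type]
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    defs = []
    for (trait, gene), grp in df.groupby(["trait", "gene"], sort=False):
        head = grp.iloc[0]
        class_map = json.loads(head["class_map"]) if head["class_map"] else {}
        mode = head["mode"]
        if mode == "single":
            for _, row in grp.iterrows():
                defs.append(
                    TraitMarkerDef(
                        trait=trait,
                        gene_label=gene,
                        marker_ids=[row["marker_id"]],
                        use_mode="single",
                        favorable=[row["positive_allele"]],
                        unfavorable=[row["negative_allele"]],
                        note=row["note"] or None,
                    )
                )
        else:
            defs.append(
                TraitMarkerDef(
                    trait=trait,
                    gene_label=gene,
                    marker_ids=list(grp["marker_id"]),
                    use_mode="haplotype",
                    favorable=[h for h in head["favorable_haplotypes"].split("/") if h],
                    unfavorable=[h for h in head["unfavorable_haplotypes"].split("/") if h],
                    class_map=class_map,
                    note=head["note"] or None,
                )
            )
    return defs


def _locate_markers(gm: GenotypeMatrix, defn: TraitMarkerDef) -> list[int]:
    by_id = gm.marker_index()
    by_pos = {(m.chrom, m.pos_bp): j for j, m in enumerate(gm.markers)}
    cols = []
    missing = []
    for mid in defn.marker_ids:
        if mid in by_id:
            cols.append(by_id[mid])
            continue
        if ":" in mid:
            chrom, _, pos = mid.partition(":")
            key = (chrom, int(pos)) if pos.isdigit() else None
            if key in by_pos:
                cols.append(by_pos[key])
                continue
        missing.append(mid)
    if missing:
        raise TraitDefinitionError(
            f"{defn.gene_label}: markers absent from the genotype matrix: {missing}"
        )
    return cols


def _allele_options(call: str, marker_alleles: tuple[str, str]) -> list[str]:
    """Possible single-allele completions of one call for haplotype building."""
    if call == MISSING:
        return list(marker_alleles)
    if call[0] == call[1]:
        return [call[0]]
    return [call[0], call[1]]


def call_trait(gm: GenotypeMatrix, defn: TraitMarkerDef) -> pd.DataFrame:
    """Per-sample trait call for one definition.

    Returns a DataFrame indexed by sample with columns ``status`` (favorable
    / unfavorable / a class label / unknown) and ``het_carrier`` (single
    mode: the sample is heterozygous but carries the favorable allele).  In
    haplotype mode a call with missing or heterozygous components is
    classified only if every completion maps to one class.
    """
    cols = _locate_markers(gm, defn)
    statuses: list[str] = []
    het_carrier: list[bool] = []
    if defn.use_mode == "single":
        j = cols[0]
        fav = defn.favorable[0]
        unfav = defn.unfavorable[0]
        for i in range(gm.n_samples):
            call = gm.calls[i, j]
            if call == MISSING:
                statuses.append(UNKNOWN)
                het_carrier.append(False)
            elif call[0] == call[1]:
                a = call[0]
                statuses.append(FAVORABLE if a == fav else UNFAVORABLE if a == unfav else UNKNOWN)
                het_carrier.append(False)
            else:
                carries = fav in call
                statuses.append(FAVORABLE if carries else UNFAVORABLE)
                het_carrier.append(carries)
    else:
        markers = [gm.markers[j] for j in cols]
        for i in range(gm.n_samples):
            options = [_allele_options(gm.calls[i, j], mk.alleles) for j, mk in zip(cols, markers)]
            completions: list[str] = [""]
            for opts in options:
                completions = [c + a for c in completions for a in opts]
            classes = {defn.classify(c) for c in completions}
            statuses.append(classes.pop() if len(classes) == 1 else UNKNOWN)
            het_carrier.append(False)
    return pd.DataFrame({"status": statuses, "het_carrier": het_carrier}, index=list(gm.samples))


def utility(status: "pd.Series | Sequence[str]") -> float:
    """Percent of assessed cultivars NOT carrying the favorable allele.

    Unknown calls are excluded from numerator and denominator (utility
    measures pool composition, not marker performance).
    """
    s = pd.Series(status)
    assessed = s[s != UNKNOWN]
    if len(assessed) == 0:
        return float("nan")
    return 100.0 * float((assessed != FAVORABLE).sum()) / len(assessed)


def fpr_fnr(
    status: "pd.Series",
    donors: Iterable[str],
    recipients: Iterable[str],
) -> tuple[float, float]:
    """False positive and false negative rates on known donor/recipient sets.

    FPR = % of recipients without the unfavorable allele; FNR = % of donors
    without the favorable allele.  Unknown calls stay in the totals — a
    marker that cannot classify a known donor or recipient has failed on it.
    """
    donors = list(donors)
    recipients = list(recipients)
    if not donors:
        raise ValueError("donor set is empty")
    if not recipients:
        raise ValueError("recipient set is empty")
    overlap = set(donors) & set(recipients)
    if overlap:
        raise ValueError(f"donor and recipient sets overlap: {sorted(overlap)}")
    fpr = 100.0 * sum(status.loc[r] != UNFAVORABLE for r in recipients) / len(recipients)
    fnr = 100.0 * sum(status.loc[d] != FAVORABLE for d in donors) / len(donors)
    return fpr, fnr


@dataclass
class TraitMarkerQC:
    """Utility/FPR/FNR with the counts each ratio was computed from."""

    utility: float
    fpr: float | None
    fnr: float | None
    n_assessed: int
    n_without_favorable: int
    n_donors: int | None = None
    n_recipients: int | None = None


def evaluate_trait_marker(
    gm: GenotypeMatrix,
    defn: TraitMarkerDef,
    donors: Sequence[str] | None = None,
    recipients: Sequence[str] | None = None,
) -> TraitMarkerQC:
    """Full QC evaluation of one trait-marker definition on a panel."""
    calls = call_trait(gm, defn)
    s = calls["status"]
    assessed = s[s != UNKNOWN]
    util = utility(s)
    fpr = fnr = None
    if donors is not None and recipients is not None:
        fpr, fnr = fpr_fnr(s, donors, recipients)
    return TraitMarkerQC(
        utility=util,
        fpr=fpr,
        fnr=fnr,
        n_assessed=len(assessed),
        n_without_favorable=int((assessed != FAVORABLE).sum()),
        n_donors=len(donors) if donors is not None else None,
        n_recipients=len(recipients) if recipients is not None else None,
    )
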