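"""HapMap-format genotype I/O plus pedigree and phenotype table readers.

Two genotype dialects are supported:

``two-letter``
    each call is a two-character allele pair ("AG"); missing is "NN",
    with "N"/"--"/"NA" also accepted on input.
``iupac``
    single-letter calls: A/C/G/T for homozygotes, the IUPAC ambiguity
    codes R,Y,S,W,K,M for heterozygotes, "N" (or "-") for missing.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    GenotypeError,
    GenotypeMatrix,
    MarkerRecord,
    Pedigree,
    canonical_call,
)

HAPMAP_COLUMNS = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panel", "QCcode",
]

IUPAC_HET = {"R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC"}
HET_IUPAC = {v: k for k, v in IUPAC_HET.items()}

_MISSING_TOKENS = {"NN", "N", "--", "-", "NA", "", "??"}


class HapmapFormatError(GenotypeError):
    """Malformed HapMap file."""


class DuplicateMarkerError(GenotypeError):
    """Two markers share a (chrom, pos) coordinate."""


def _normalize_chrom(raw: str) -> str:
    s = str(raw).strip().lower()
    if s.startswith("chr"):
        s = s[3:]
    if not s.isdigit():
        raise HapmapFormatError(f"unparseable chromosome {raw!r}")
    return f"chr{int(s):02d}"


def _decode_call(token: str, dialect: str) -> str:
    t = token.strip().upper()
    if t in _MISSING_TOKENS:
        return MISSING
    if dialect == "two-letter":
        if len(t) != 2:
            raise HapmapFormatError(f"bad two-letter call {token!r}")
        return canonical_call(t[0], t[1])
    if dialect == "iupac":
        if len(t) == 2:  # tolerate two-letter calls in IUPAC files
            return canonical_call(t[0], t[1])
        if t in IUPAC_HET:
            pair = IUPAC_HET[t]
            return canonical_call(pair[0], pair[1])
        if t in "ACGT":
            return t + t
        raise HapmapFormatError(f"bad IUPAC call {token!r}")
    raise ValueError(f"unknown dialect {dialect!r}")


def _encode_call(call: str, dialect: str) -> str:
    if dialect == "two-letter":
        return call
    if dialect == "iupac":
        if call == MISSING:
            return "N"
        if call[0] == call[1]:
            return call[0]
        return HET_IUPAC[call]
    raise ValueError(f"unknown dialect {dialect!r}")


def _parse_alleles(field: str, observed: set[str]) -> tuple[str, str]:
    tokens = [t for t in str(field).replace("/", " ").split() if t in "ACGT" and t]
    if len(tokens) >= 2 and tokens[0] != tokens[1]:
        return (tokens[0], tokens[1])
    # fall back on the alleles actually observed in the calls
    obs = sorted(observed)
    if len(obs) == 2:
        return (obs[0], obs[1])
    if len(obs) == 1 and tokens and tokens[0] != obs[0]:
        return tuple(sorted((obs[0], tokens[0])))  # type: ignore[return-value]
    raise HapmapFormatError(
        f"cannot determine the biallelic allele pair from {field!r} / observed {obs}"
    )


def read_hapmap(path: str | Path, dialect: str = "two-letter") -> GenotypeMatrix:
    """Read a HapMap tab-delimited genotype table into a GenotypeMatrix.

    The result is sorted by (chrom, pos).  Calls whose alleles fall outside
    the marker's declared pair trigger a warning; the full violation report
    stays available through :meth:`GenotypeMatrix.validate_alleles`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    header = list(df.columns[: len(HAPMAP_COLUMNS)])
    if [h.lower() for h in header] != [h.lower() for h in HAPMAP_COLUMNS]:
        raise HapmapFormatError(
            f"expected the 11 standard HapMap columns {HAPMAP_COLUMNS}, got {header}"
        )
    samples = list(df.columns[len(HAPMAP_COLUMNS):])

    markers: list[MarkerRecord] = []
    calls = np.full((len(samples), len(df)), MISSING, dtype="U2")
    seen: dict[tuple[str, int], list[str]] = {}
    for j, row in enumerate(df.itertuples(index=False)):
        chrom = _normalize_chrom(row[2])
        try:
            pos = int(row[3])
        except ValueError as exc:
            raise HapmapFormatError(f"non-integer position {row[3]!r}") from exc
        decoded = [_decode_call(df.iat[j, len(HAPMAP_COLUMNS) + i], dialect)
                   for i in range(len(samples))]
        observed = {a for c in decoded if c != MISSING for a in c}
        alleles = _parse_alleles(row[1], observed)
        rec = MarkerRecord(
            marker_id=str(row[0]),
            chrom=chrom,
            pos_bp=pos,
            alleles=alleles,
            source=str(row[6]) if str(row[6]) not in ("", "NA") else "C6AIR",
            gene_label=str(row[9]) if str(row[9]) not in ("", "NA") else None,
        )
        seen.setdefault((chrom, pos), []).append(rec.marker_id)
        markers.append(rec)
        calls[:, j] = decoded

    dupes = {k: v for k, v in seen.items() if len(v) > 1}
    if dupes:
        listing = "; ".join(f"{c}:{p} -> {ids}" for (c, p), ids in dupes.items())
        raise DuplicateMarkerError(f"duplicate marker positions: {listing}")

    gm = GenotypeMatrix(markers=markers, samples=samples, calls=calls)
    violations = gm.validate_alleles()
    if len(violations):
        warnings.warn(
            f"{len(violations)} calls carry alleles outside the declared pair "
            "(see GenotypeMatrix.validate_alleles())",
            stacklevel=2,
        )
    return gm


def write_hapmap(gm: GenotypeMatrix, path: str | Path, dialect: str = "two-letter") -> None:
    """Write a GenotypeMatrix as tab-delimited HapMap text.

    Output is deterministic: markers in (chrom, pos) order, sample columns in
    matrix order, missing rendered "NN" (two-letter) or "N" (IUPAC).
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(HAPMAP_COLUMNS + list(gm.samples)) + "\n")
        for j, m in enumerate(gm.markers):
            fixed = [
                m.marker_id,
                f"{m.alleles[0]}/{m.alleles[1]}",
                m.chrom,
                str(m.pos_bp),
                "+",
                "MSU7",
                m.source,
                "NA",
                "NA",
                m.gene_label or "NA",
                "NA",
            ]
            row = [_encode_call(c, dialect) for c in gm.calls[:, j]]
            fh.write("\t".join(fixed + row) + "\n")


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a pedigree CSV (id,sire,dam) into topological order.

    Parents referenced but never listed are auto-added as founders with a
    warning; cycles raise :class:`~ricapanel.core.PedigreeError`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = [c.lower() for c in df.columns]
    if cols[:3] != ["id", "sire", "dam"]:
        raise HapmapFormatError(f"pedigree CSV must have columns id,sire,dam; got {list(df.columns)}")
    entries = [(r[0], r[1] or None, r[2] or None) for r in df.itertuples(index=False)]
    listed = {i for i, _, _ in entries}
    unknown = sorted(
        {p for _, s, d in entries for p in (s, d) if p not in (None, "", "0", "-", "NA") and p not in listed}
    )
    if unknown:
        warnings.warn(f"parents not listed as individuals, added as founders: {unknown}", stacklevel=2)
    return Pedigree(entries=entries)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    pd.DataFrame(ped.entries, columns=["id", "sire", "dam"]).fillna("").to_csv(path, index=False)


PHENOTYPE_COLUMNS = ["genotype", "trial", "rep", "trait", "value"]


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a plot-level phenotype CSV.

    Required columns: genotype, trial, rep, trait, value.  Optional columns
    weight_g, area_m2, mc carry the raw grain-yield inputs.
    """
    df = pd.read_csv(path)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise HapmapFormatError(f"phenotype CSV missing columns {missing}")
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    return df


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def export_workbook_sheets(xlsx_path: str | Path, out_dir: str | Path) -> list[Path]:
    """Thin spreadsheet adapter: dump every sheet of a workbook to
    tab-delimited text so the HapMap parser can read it.

    Returns the written paths (one ``<sheet>.txt`` per sheet).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sheets = pd.read_excel(xlsx_path, sheet_name=None, dtype=str)
    written = []
    for name, df in sheets.items():
        safe = "".join(c if c.isalnum() or c in "-_" else "_" for c in str(name))
        path = out_dir / f"{safe}.txt"
        df.to_csv(path, sep="\t", index=False)
        written.append(path)
    return written
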