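"""Core genotype containers shared by every analysis stage.

Genotype calls are unordered diploid nucleotide pairs stored canonically as
two-character strings with the alleles in alphabetical order ("AG", never
"GA"); a missing call is "NN".  A :class:`GenotypeMatrix` holds a samples x
markers grid of such calls together with an ordered marker map and optional
per-sample metadata (accession, subpopulation, replicate group, family).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

NUCLEOTIDES = ("A", "C", "G", "T")
MISSING = "NN"

#: MSU7 Nipponbare chromosome sizes (bp); they sum to 373,245,519 bp.
RICE_CHROM_LENGTHS: dict[str, int] = {
    "chr01": 43270923,
    "chr02": 35937250,
    "chr03": 36413819,
    "chr04": 35502694,
    "chr05": 29958434,
    "chr06": 31248787,
    "chr07": 29697621,
    "chr08": 28443022,
    "chr09": 23012720,
    "chr10": 23207287,
    "chr11": 29021106,
    "chr12": 27531856,
}

CHROMOSOMES = tuple(RICE_CHROM_LENGTHS)

GENOME_LENGTH_BP = sum(RICE_CHROM_LENGTHS.values())


class GenotypeError(ValueError):
    """Raised for malformed genotype data."""


def canonical_call(allele_a: str, allele_b: str) -> str:
    """Return the canonical (alphabetically ordered) two-letter call.

    Either both alleles are nucleotides or both are missing ("N").
    """
    a, b = allele_a.upper(), allele_b.upper()
    if a == "N" or b == "N":
        if a != b:
            raise GenotypeError(f"half-missing call {a}{b!r}")
        return MISSING
    if a not in NUCLEOTIDES or b not in NUCLEOTIDES:
        raise GenotypeError(f"invalid alleles {a}{b!r}")
    return a + b if a <= b else b + a


def is_missing(call: str) -> bool:
    return call == MISSING


def is_het(call: str) -> bool:
    return call != MISSING and call[0] != call[1]


def is_hom(call: str) -> bool:
    return call != MISSING and call[0] == call[1]


@dataclass(frozen=True)
class MarkerRecord:
    """One panel SNP with its genomic coordinates and provenance tag."""

    marker_id: str
    chrom: str
    pos_bp: int
    alleles: tuple[str, str]
    source: str = "C6AIR"
    gene_label: str | None = None

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise GenotypeError(f"{self.marker_id}: position must be >= 1")
        a, b = self.alleles
        if a == b:
            raise GenotypeError(f"{self.marker_id}: alleles must be distinct")
        if a > b:
            object.__setattr__(self, "alleles", (b, a))

    @property
    def ref(self) -> str:
        return self.alleles[0]

    @property
    def alt(self) -> str:
        """Alphabetically-second allele; the one counted by dosage coding."""
        return self.alleles[1]


def parse_marker_id(marker_id: str) -> tuple[str, int] | None:
    """Parse ids of the form ``chrNN:pos`` into (chrom, pos); else None."""
    if ":" not in marker_id:
        return None
    chrom, _, pos = marker_id.partition(":")
    if chrom.startswith("chr") and pos.isdigit():
        return chrom, int(pos)
    return None


def _sorted_marker_order(markers: Sequence[MarkerRecord]) -> list[int]:
    return sorted(range(len(markers)), key=lambda i: (markers[i].chrom, markers[i].pos_bp))


META_COLUMNS = ("accession", "subpop", "replicate_group", "family")


def _normalize_meta(samples: Sequence[str], sample_meta: pd.DataFrame | None) -> pd.DataFrame:
    if sample_meta is None:
        sample_meta = pd.DataFrame(index=list(samples))
    else:
        sample_meta = sample_meta.copy()
        missing = [s for s in samples if s not in sample_meta.index]
        if missing:
            sample_meta = pd.concat(
                [sample_meta, pd.DataFrame(index=missing)]
            )
        sample_meta = sample_meta.loc[list(samples)]
    for col in META_COLUMNS:
        if col not in sample_meta.columns:
            sample_meta[col] = None
    return sample_meta


@dataclass
class GenotypeMatrix:
    """samples x markers grid of canonical diploid calls plus metadata.

    ``calls[i, j]`` is the call of sample ``i`` at marker ``j``.  Markers are
    kept sorted by (chrom, pos_bp); construction re-sorts if needed.
    """

    markers: list[MarkerRecord]
    samples: list[str]
    calls: np.ndarray
    sample_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype="U2")
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise GenotypeError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        order = _sorted_marker_order(self.markers)
        if order != list(range(len(self.markers))):
            self.markers = [self.markers[i] for i in order]
            self.calls = self.calls[:, order]
        seen: dict[tuple[str, int], str] = {}
        for m in self.markers:
            key = (m.chrom, m.pos_bp)
            if key in seen:
                raise GenotypeError(
                    f"duplicate marker position {key}: {seen[key]} / {m.marker_id}"
                )
            seen[key] = m.marker_id
        self.sample_meta = _normalize_meta(self.samples, self.sample_meta)

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_samples, self.n_markers)

    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    def marker_index(self) -> dict[str, int]:
        return {m.marker_id: j for j, m in enumerate(self.markers)}

    def sample_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.samples)}

    # -- masks ----------------------------------------------------------
    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def het_mask(self) -> np.ndarray:
        first = self.calls.view("U1").reshape(self.n_samples, self.n_markers, 2)
        return (self.calls != MISSING) & (first[:, :, 0] != first[:, :, 1])

    # -- numeric coding --------------------------------------------------
    def dosage(self) -> np.ndarray:
        """Alternate-allele counts (0/1/2) as float; missing -> NaN.

        The counted allele is each marker's alphabetically-second allele.
        """
        out = np.full(self.shape, np.nan)
        chars = self.calls.view("U1").reshape(self.n_samples, self.n_markers, 2)
        alts = np.array([m.alt for m in self.markers])
        called = self.calls != MISSING
        dose = (chars[:, :, 0] == alts).astype(float) + (chars[:, :, 1] == alts)
        out[called] = dose[called]
        return out

    def validate_alleles(self) -> pd.DataFrame:
        """Report calls with alleles outside the marker's declared pair.

        Violations are reported, never silently dropped.
        """
        rows = []
        for j, m in enumerate(self.markers):
            ok = set(m.alleles)
            col = self.calls[:, j]
            for i in np.nonzero(col != MISSING)[0]:
                call = col[i]
                bad = {call[0], call[1]} - ok
                if bad:
                    rows.append(
                        {
                            "sample": self.samples[i],
                            "marker_id": m.marker_id,
                            "call": call,
                            "unexpected_alleles": "".join(sorted(bad)),
                        }
                    )
        return pd.DataFrame(rows, columns=["sample", "marker_id", "call", "unexpected_alleles"])

    # -- subsetting ------------------------------------------------------
    def subset_markers(self, keep: Iterable[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(list(keep), dtype=int)
        return GenotypeMatrix(
            markers=[self.markers[j] for j in idx],
            samples=list(self.samples),
            calls=self.calls[:, idx].copy(),
            sample_meta=self.sample_meta,
        )

    def subset_samples(self, names: Sequence[str]) -> "GenotypeMatrix":
        sidx = self.sample_index()
        idx = np.array([sidx[s] for s in names], dtype=int)
        return GenotypeMatrix(
            markers=list(self.markers),
            samples=list(names),
            calls=self.calls[idx, :].copy(),
            sample_meta=self.sample_meta.loc[list(names)],
        )

    def sample_row(self, name: str) -> np.ndarray:
        return self.calls[self.sample_index()[name], :]

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            markers=list(self.markers),
            samples=list(self.samples),
            calls=self.calls.copy(),
            sample_meta=self.sample_meta.copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.markers == other.markers
            and self.samples == other.samples
            and bool(np.array_equal(self.calls, other.calls))
        )


class PedigreeError(ValueError):
    """Raised for invalid pedigrees (cycles, bad structure)."""


@dataclass
class Pedigree:
    """Topologically ordered pedigree: parents always precede offspring.

    ``entries`` are (individual, sire, dam) with ``None`` for unknown
    parents (founders).
    """

    entries: list[tuple[str, str | None, str | None]]

    def __post_init__(self) -> None:
        self.entries = [
            (str(i), None if s in (None, "", "0", "-", "NA") else str(s),
             None if d in (None, "", "0", "-", "NA") else str(d))
            for i, s, d in self.entries
        ]
        self.entries = _toposort(self.entries)

    @property
    def ids(self) -> list[str]:
        return [e[0] for e in self.entries]

    def parents(self, individual: str) -> tuple[str | None, str | None]:
        for i, s, d in self.entries:
            if i == individual:
                return s, d
        raise KeyError(individual)

    def __len__(self) -> int:
        return len(self.entries)


def _toposort(
    entries: list[tuple[str, str | None, str | None]]
) -> list[tuple[str, str | None, str | None]]:
    by_id = {i: (i, s, d) for i, s, d in entries}
    if len(by_id) != len(entries):
        dupes = [i for i, _, _ in entries if sum(1 for j, _, _ in entries if j == i) > 1]
        raise PedigreeError(f"duplicate individuals: {sorted(set(dupes))}")
    # Unknown parents become founders (with a warning left to the caller).
    auto = []
    for i, s, d in entries:
        for p in (s, d):
            if p is not None and p not in by_id and p not in auto:
                auto.append(p)
    for p in auto:
        by_id[p] = (p, None, None)

    order: list[tuple[str, str | None, str | None]] = []
    state: dict[str, int] = {}  # 0 visiting, 1 done

    def visit(node: str, chain: list[str]) -> None:
        st = state.get(node)
        if st == 1:
            return
        if st == 0:
            cycle = chain[chain.index(node):] + [node]
            raise PedigreeError(f"pedigree cycle: {' -> '.join(cycle)}")
        state[node] = 0
        _, s, d = by_id[node]
        for p in (s, d):
            if p is not None:
                visit(p, chain + [node])
        state[node] = 1
        order.append(by_id[node])

    for i in by_id:
        visit(i, [])
    return order


def hom_call(allele: str) -> str:
    return allele + allele


def het_call(a: str, b: str) -> str:
    return canonical_call(a, b)


def concat_samples(matrices: Sequence[GenotypeMatrix]) -> GenotypeMatrix:
    """Stack matrices that share an identical marker map."""
    first = matrices[0]
    for gm in matrices[1:]:
        if gm.markers != first.markers:
            raise GenotypeError("marker maps differ; cannot concatenate")
    return GenotypeMatrix(
        markers=list(first.markers),
        samples=[s for gm in matrices for s in gm.samples],
        calls=np.vstack([gm.calls for gm in matrices]),
        sample_meta=pd.concat([gm.sample_meta for gm in matrices]),
    )
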