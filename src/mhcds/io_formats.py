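"""Readers, writers and validated in-memory containers for every external
representation the pipeline touches.

The central objects are:

* :class:`AlleleCatalog` — an aligned set of coding-exon allele sequences
  (the adaptive marker; one aligned 270-bp reference frame, 3-bp indels
  represented as shared gap columns).
* :class:`MhcGenotypeMatrix` — binary individual × allele presence/absence
  calls with population labels.  Because several loci co-amplify, allele
  copies cannot be assigned to a locus of origin, hence the 0/1 encoding.
* :class:`MsatGenotypeTable` — diploid microsatellite calls (the neutral
  marker), unordered integer allele pairs per locus.
* :class:`PopulationTable` / :class:`ClimateTable` — per-population metadata
  and bioclimatic covariates.
* :class:`SiteList` — 1-based codon positions (antigen-binding sites or
  positively selected sites) in the reference frame.
* :class:`LabeledSymMatrix` — a labelled symmetric population × population
  matrix (differentiation, kilometres, covariate distances).

Validation is total: malformed input raises :class:`FormatError`,
:class:`AlignmentError` or :class:`ValidationError` with the offending
record named, never a silent coercion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "FormatError",
    "AlignmentError",
    "ValidationError",
    "AlleleCatalog",
    "MhcGenotypeMatrix",
    "MsatGenotypeTable",
    "PopulationTable",
    "ClimateTable",
    "SiteList",
    "LabeledSymMatrix",
    "read_allele_fasta",
    "write_allele_fasta",
    "read_mhc_genotypes",
    "write_mhc_genotypes",
    "read_msat_genotypes",
    "write_msat_genotypes",
    "read_population_table",
    "write_population_table",
    "read_climate_table",
    "write_climate_table",
    "read_site_list",
    "write_site_list",
    "read_sym_matrix",
    "write_sym_matrix",
    "write_report",
]

VALID_CHARS = frozenset("ACGT-")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class FormatError(ValueError):
    """Input not in the expected file format."""


class AlignmentError(ValueError):
    """Sequences do not share the declared aligned frame."""


class ValidationError(ValueError):
    """Well-formed input violating a domain invariant."""


# ---------------------------------------------------------------------------
# AlleleCatalog


@dataclass
class AlleleCatalog:
    """Aligned coding allele sequences keyed by allele id.

    All sequences share one aligned length; gaps ("-") mark the 3-bp indel
    regions in non-carriers (or carriers of a deletion).  The declared
    reading frame starts at ``frame_offset`` (0 by default) and no sequence
    may contain an internal stop codon once its gaps are removed.
    """

    records: dict[str, str]
    frame_offset: int = 0
    reference_length: int = 270

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.records:
            raise ValidationError("empty allele catalog")
        lengths = {len(s) for s in self.records.values()}
        if len(lengths) != 1:
            raise AlignmentError(
                f"unequal aligned lengths in catalog: {sorted(lengths)}"
            )
        for allele_id, seq in self.records.items():
            bad = set(seq) - VALID_CHARS
            if bad:
                raise FormatError(
                    f"allele {allele_id!r}: invalid characters {sorted(bad)}"
                )
            ungapped = seq.replace("-", "")
            if len(ungapped) % 3 != 0:
                raise AlignmentError(
                    f"allele {allele_id!r}: ungapped length {len(ungapped)} "
                    "not a multiple of 3"
                )
            for i in range(0, len(ungapped) - 3, 3):  # internal codons only
                if ungapped[i : i + 3] in STOP_CODONS:
                    raise ValidationError(
                        f"allele {allele_id!r}: internal stop codon at "
                        f"ungapped codon {i // 3 + 1}"
                    )

    @property
    def aligned_length(self) -> int:
        return len(next(iter(self.records.values())))

    @property
    def allele_ids(self) -> list[str]:
        return list(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, allele_ids: Sequence[str]) -> "AlleleCatalog":
        missing = [a for a in allele_ids if a not in self.records]
        if missing:
            raise KeyError(f"alleles not in catalog: {missing}")
        return AlleleCatalog(
            {a: self.records[a] for a in allele_ids},
            frame_offset=self.frame_offset,
            reference_length=self.reference_length,
        )

    def codon_array(self) -> np.ndarray:
        """(n_alleles, n_codons) array of 3-letter codon strings ('---' for gaps)."""
        n_codons = self.aligned_length // 3
        out = np.empty((len(self.records), n_codons), dtype="U3")
        for i, seq in enumerate(self.records.values()):
            for k in range(n_codons):
                out[i, k] = seq[3 * k : 3 * k + 3]
        return out

    def indel_census(self) -> dict[str, list[str]]:
        """Alleles carrying gaps, keyed by the gap column span they carry."""
        by_span: dict[str, list[str]] = {}
        for allele_id, seq in self.records.items():
            cols = [i + 1 for i, c in enumerate(seq) if c == "-"]
            if cols:
                span = f"{cols[0]}-{cols[-1]}"
                by_span.setdefault(span, []).append(allele_id)
        return by_span


def read_allele_fasta(path: str | Path, reference_length: int = 270) -> AlleleCatalog:
    """Read an aligned allele FASTA into a validated :class:`AlleleCatalog`.

    Ids are FASTA headers up to the first whitespace; description text is
    ignored.  Sequences are upper-cased before validation.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValidationError(f"duplicate allele id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return AlleleCatalog(records, reference_length=reference_length)


def write_allele_fasta(catalog: AlleleCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        for allele_id, seq in catalog.records.items():
            fh.write(f">{allele_id}\n{seq}\n")


# ---------------------------------------------------------------------------
# MhcGenotypeMatrix


@dataclass
class MhcGenotypeMatrix:
    """Binary individual × allele presence/absence matrix with population labels."""

    individuals: list[str]
    alleles: list[str]
    presence: np.ndarray  # (n_individuals, n_alleles) of {0,1}
    population_of: dict[str, str]

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=np.int8)
        self.validate()

    def validate(self) -> None:
        n, m = self.presence.shape
        if n != len(self.individuals) or m != len(self.alleles):
            raise ValidationError("presence matrix shape mismatch")
        if len(set(self.individuals)) != n:
            raise ValidationError("duplicate individual ids")
        if not set(np.unique(self.presence)) <= {0, 1}:
            raise ValidationError("presence matrix must be binary")
        row_sums = self.presence.sum(axis=1)
        if (row_sums < 1).any():
            bad = self.individuals[int(np.argmin(row_sums))]
            raise ValidationError(f"individual {bad!r} carries no allele")
        col_sums = self.presence.sum(axis=0)
        if (col_sums < 1).any():
            bad = self.alleles[int(np.argmin(col_sums))]
            raise ValidationError(f"allele {bad!r} has no carrier")
        missing = [i for i in self.individuals if i not in self.population_of]
        if missing:
            raise ValidationError(f"individuals without population: {missing}")

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(self.population_of[ind], None)
        return list(seen)

    def rows_for(self, population: str) -> np.ndarray:
        idx = [
            i
            for i, ind in enumerate(self.individuals)
            if self.population_of[ind] == population
        ]
        return self.presence[idx]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.presence, index=self.individuals, columns=self.alleles)
        df.insert(0, "population", [self.population_of[i] for i in self.individuals])
        df.index.name = "individual"
        return df


def read_mhc_genotypes(
    path: str | Path, catalog: AlleleCatalog, sep: str = "\t"
) -> MhcGenotypeMatrix:
    """Read a 0/1 genotype table (individual, population, one column per allele)."""
    df = pd.read_csv(path, sep=sep, dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise FormatError("expected individual, population and allele columns")
    ind_col, pop_col = df.columns[:2]
    allele_cols = list(df.columns[2:])
    unknown = [a for a in allele_cols if a not in catalog.records]
    if unknown:
        raise ValidationError(f"alleles not in catalog: {unknown}")
    if df[ind_col].duplicated().any():
        dup = df[ind_col][df[ind_col].duplicated()].iloc[0]
        raise ValidationError(f"duplicate individual id {dup!r}")
    presence = df[allele_cols].to_numpy()
    if not np.isin(presence, (0, 1)).all():
        raise FormatError("presence entries must be 0 or 1")
    return MhcGenotypeMatrix(
        individuals=df[ind_col].tolist(),
        alleles=allele_cols,
        presence=presence.astype(np.int8),
        population_of=dict(zip(df[ind_col], df[pop_col])),
    )


def write_mhc_genotypes(geno: MhcGenotypeMatrix, path: str | Path, sep: str = "\t") -> None:
    geno.to_frame().to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# MsatGenotypeTable

MISSING_SENTINEL = 0


@dataclass
class MsatGenotypeTable:
    """Diploid microsatellite genotypes: per individual × locus an unordered
    pair of positive integer allele labels, 0 marking a missing call."""

    individuals: list[str]
    loci: list[str]
    calls: np.ndarray  # (n_individuals, n_loci, 2) ints; 0 = missing
    population_of: dict[str, str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        n, L, two = self.calls.shape
        if two != 2 or n != len(self.individuals) or L != len(self.loci):
            raise ValidationError("calls array shape mismatch")
        if len(set(self.individuals)) != n:
            raise ValidationError("duplicate individual ids")
        if (self.calls < 0).any():
            raise FormatError("allele labels must be non-negative integers")
        # missing is all-or-nothing per genotype
        miss = self.calls == MISSING_SENTINEL
        if (miss[..., 0] != miss[..., 1]).any():
            raise ValidationError("half-missing genotype (one allele 0)")
        missing_pop = [i for i in self.individuals if i not in self.population_of]
        if missing_pop:
            raise ValidationError(f"individuals without population: {missing_pop}")

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(self.population_of[ind], None)
        return list(seen)

    def n_missing(self) -> int:
        return int((self.calls[..., 0] == MISSING_SENTINEL).sum())

    def calls_for(self, population: str) -> np.ndarray:
        idx = [
            i
            for i, ind in enumerate(self.individuals)
            if self.population_of[ind] == population
        ]
        return self.calls[idx]

    def allele_inventory(self) -> dict[str, np.ndarray]:
        """Sorted observed allele labels per locus (missing excluded)."""
        out = {}
        for j, locus in enumerate(self.loci):
            vals = self.calls[:, j, :].ravel()
            out[locus] = np.unique(vals[vals != MISSING_SENTINEL])
        return out

    def to_frame(self) -> pd.DataFrame:
        data = {"population": [self.population_of[i] for i in self.individuals]}
        for j, locus in enumerate(self.loci):
            data[f"{locus}_1"] = self.calls[:, j, 0]
            data[f"{locus}_2"] = self.calls[:, j, 1]
        df = pd.DataFrame(data, index=self.individuals)
        df.index.name = "individual"
        return df


def read_msat_genotypes(path: str | Path, sep: str = "\t") -> MsatGenotypeTable:
    """Read a diploid genotype table: individual, population, then two columns
    per locus named ``<locus>_1`` / ``<locus>_2`` (0 = missing)."""
    df = pd.read_csv(path, sep=sep, dtype={0: str, 1: str})
    ind_col, pop_col = df.columns[:2]
    locus_cols = list(df.columns[2:])
    if len(locus_cols) % 2 != 0:
        raise FormatError("odd number of allele columns (need 2 per locus)")
    loci = []
    for k in range(0, len(locus_cols), 2):
        a, b = locus_cols[k], locus_cols[k + 1]
        stem = a[:-2] if a.endswith("_1") else a
        loci.append(stem)
    raw = df[locus_cols].to_numpy()
    try:
        raw = raw.astype(np.int64)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-integer allele label: {exc}") from exc
    if (raw < 0).any():
        raise FormatError("negative allele label")
    calls = raw.reshape(len(df), len(loci), 2)
    return MsatGenotypeTable(
        individuals=df[ind_col].tolist(),
        loci=loci,
        calls=calls,
        population_of=dict(zip(df[ind_col], df[pop_col])),
    )


def write_msat_genotypes(tab: MsatGenotypeTable, path: str | Path, sep: str = "\t") -> None:
    tab.to_frame().to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# PopulationTable / ClimateTable


@dataclass
class PopulationTable:
    """Per-population metadata: lineage membership, coordinates (decimal
    degrees, WGS84) and sample size."""

    frame: pd.DataFrame  # index population_id; columns lineage, latitude, longitude, n

    def __post_init__(self) -> None:
        req = {"lineage", "latitude", "longitude", "n"}
        missing = req - set(self.frame.columns)
        if missing:
            raise FormatError(f"population table missing columns: {sorted(missing)}")
        if self.frame.index.duplicated().any():
            raise ValidationError("duplicate population ids")
        lat = self.frame["latitude"].to_numpy(float)
        lon = self.frame["longitude"].to_numpy(float)
        if (np.abs(lat) > 90).any() or (np.abs(lon) > 180).any():
            raise ValidationError("coordinates out of range")
        if (self.frame["n"].to_numpy() <= 0).any():
            raise ValidationError("population sample size must be positive")

    @property
    def population_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def lineage_of(self) -> dict[str, str]:
        return self.frame["lineage"].to_dict()

    def coords(self) -> np.ndarray:
        return self.frame[["latitude", "longitude"]].to_numpy(float)


def read_population_table(path: str | Path, sep: str = "\t") -> PopulationTable:
    df = pd.read_csv(path, sep=sep, index_col=0)
    return PopulationTable(df)


def write_population_table(tab: PopulationTable, path: str | Path, sep: str = "\t") -> None:
    tab.frame.to_csv(path, sep=sep, index_label="population")


@dataclass
class ClimateTable:
    """One row per population of numeric bioclimatic covariates."""

    frame: pd.DataFrame  # index population_id, numeric columns

    def __post_init__(self) -> None:
        if self.frame.index.duplicated().any():
            raise ValidationError("duplicate population ids in climate table")
        if self.frame.isna().any().any():
            bad = self.frame.columns[self.frame.isna().any()].tolist()
            raise ValidationError(f"missing climate values in {bad}")

    @property
    def variables(self) -> list[str]:
        return list(self.frame.columns)


def read_climate_table(path: str | Path, sep: str = "\t") -> ClimateTable:
    return ClimateTable(pd.read_csv(path, sep=sep, index_col=0))


def write_climate_table(tab: ClimateTable, path: str | Path, sep: str = "\t") -> None:
    tab.frame.to_csv(path, sep=sep, index_label="population")


# ---------------------------------------------------------------------------
# SiteList


@dataclass
class SiteList:
    """1-based codon positions in the reference frame, with a class label
    ("ABS", "non-ABS" or "PSS")."""

    positions: list[int]
    label: str
    n_codons: int = 90

    def __post_init__(self) -> None:
        if len(set(self.positions)) != len(self.positions):
            raise ValidationError(f"duplicate positions in {self.label} site list")
        for p in self.positions:
            if not 1 <= p <= self.n_codons:
                raise ValidationError(
                    f"{self.label} position {p} outside 1..{self.n_codons}"
                )
        self.positions = sorted(self.positions)

    def mask(self) -> np.ndarray:
        m = np.zeros(self.n_codons, dtype=bool)
        m[[p - 1 for p in self.positions]] = True
        return m

    def complement(self, label: str = "non-ABS") -> "SiteList":
        keep = sorted(set(range(1, self.n_codons + 1)) - set(self.positions))
        return SiteList(keep, label, self.n_codons)


def read_site_list(path: str | Path, label: str, n_codons: int = 90) -> SiteList:
    positions = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            try:
                positions.append(int(line))
            except ValueError as exc:
                raise FormatError(f"non-integer site position {line!r}") from exc
    return SiteList(positions, label, n_codons)


def write_site_list(sites: SiteList, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in sites.positions:
            fh.write(f"{p}\n")


# ---------------------------------------------------------------------------
# LabeledSymMatrix


@dataclass
class LabeledSymMatrix:
    """A symmetric population × population matrix with ordered labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12, equal_nan=True):
            raise ValidationError("matrix not symmetric")

    def triangle(self) -> np.ndarray:
        """Lower-triangle (row-major, i>j) entries as a flat vector."""
        iu = np.tril_indices(len(self.labels), k=-1)
        return self.values[iu]

    def reorder(self, labels: Sequence[str]) -> "LabeledSymMatrix":
        idx = [self.labels.index(l) for l in labels]
        return LabeledSymMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def read_sym_matrix(path: str | Path, sep: str = "\t") -> LabeledSymMatrix:
    df = pd.read_csv(path, sep=sep, index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError("matrix row and column labels differ")
    return LabeledSymMatrix(list(df.index), df.to_numpy(float))


def write_sym_matrix(mat: LabeledSymMatrix, path: str | Path, sep: str = "\t") -> None:
    mat.to_frame().to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# Reports


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, LabeledSymMatrix):
        return {"labels": obj.labels, "values": obj.values.tolist()}
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="split"))
    return obj


def write_report(results: Mapping[str, object], path: str | Path) -> Path:
    """Write a machine-readable JSON summary of pipeline results.

    The JSON is deterministic for a fixed results object (sorted keys, no
    timestamps); run timestamps belong in the side-channel log, not here.
    Stages that did not run should appear with the value
    ``{"status": "skipped"}`` so the key census is stable across configs.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(dict(results)), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
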