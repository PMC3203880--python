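"""Input/output and the shared data model.

Three containers flow through every analysis stage:

* :class:`Alignment` — one aligned locus (e.g. a 783 bp mitochondrial ND2
  fragment) for *n* samples;
* :class:`SampleTable` — per-sample metadata: sampling site, population
  label and planar x/y coordinates in kilometres;
* :class:`PairwiseMatrix` — a labelled symmetric matrix (geographic
  distances, p-distances, Phi_ST, ...).

Sequences are stored uppercased with ``U`` mapped to ``T``; gaps (``-``) and
IUPAC ambiguity codes are retained losslessly — each statistic decides how to
treat them (see :mod:`fragpop.sumstats`).  Coordinates are required to be
pre-projected planar kilometres; no geodesy is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.spatial.distance import cdist

from .errors import (
    AlignmentError,
    DegenerateInputError,
    FormatError,
    ValidationError,
)

#: Characters considered unambiguous nucleotide states everywhere.
CANONICAL_BASES = frozenset("ACGT")

#: Full storage alphabet: canonical bases, gap, and IUPAC ambiguity codes.
STORAGE_ALPHABET = frozenset("ACGTRYSWKMBDHVN-")

_SAMPLE_COLUMNS = ("sample_id", "site_id", "population", "x", "y")


@dataclass(frozen=True)
class Alignment:
    """An aligned set of equal-length sequences for one locus."""

    locus_name: str
    ids: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs differ in length")
        if len(self.ids) == 0:
            raise AlignmentError("empty alignment")
        if len(set(self.ids)) != len(self.ids):
            raise FormatError("duplicate sequence ids in alignment")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise AlignmentError(
                f"ragged alignment: sequence lengths {sorted(lengths)}"
            )
        if self.length == 0:
            raise AlignmentError("zero-length alignment")
        bad = set("".join(self.seqs)) - STORAGE_ALPHABET
        if bad:
            raise FormatError(f"illegal sequence characters: {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def to_array(self) -> np.ndarray:
        """Return the alignment as an (n, L) array of single characters."""
        return np.frombuffer(
            "".join(self.seqs).encode("ascii"), dtype="S1"
        ).reshape(self.n, self.length)

    def subset(self, ids: Iterable[str]) -> "Alignment":
        """Row-subset by sample id, preserving the requested order."""
        wanted = list(ids)
        index = {s: i for i, s in enumerate(self.ids)}
        missing = [s for s in wanted if s not in index]
        if missing:
            raise ValidationError(f"ids not in alignment: {missing[:5]}")
        return Alignment(
            self.locus_name,
            tuple(wanted),
            tuple(self.seqs[index[s]] for s in wanted),
        )


def _normalise_seq(raw: str) -> str:
    return raw.upper().replace("U", "T")


def read_alignment(path: str | Path, locus_name: str) -> Alignment:
    """Read an aligned FASTA file.

    Sequences are uppercased and ``U`` is mapped to ``T``.  Record order is
    preserved.  Raises :class:`FormatError` for empty files or duplicate ids
    and :class:`AlignmentError` for ragged lengths.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise FormatError(f"{path}: need >=2 FASTA records, got {len(records)}")
    ids = tuple(r.id for r in records)
    seqs = tuple(_normalise_seq(str(r.seq)) for r in records)
    return Alignment(locus_name=locus_name, ids=ids, seqs=seqs)


def write_alignment(aln: Alignment, path: str | Path, wrap: int = 70) -> None:
    """Write FASTA wrapped at ``wrap`` columns (bit-stable output)."""
    records = [
        SeqRecord(Seq(s), id=i, description="") for i, s in zip(aln.ids, aln.seqs)
    ]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=wrap)
    writer.write_file(records)


@dataclass
class SampleTable:
    """Per-sample site, population and planar-km coordinates.

    The optional boolean ``transplanted`` column marks individuals flagged as
    recent human-mediated transfers ("secondary contact"); analyses may
    exclude them (the reporting baseline) or keep them.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _SAMPLE_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"sample table missing columns: {missing}")
        df = self.df.copy()
        for col in ("sample_id", "site_id", "population"):
            df[col] = df[col].astype(str)
        for col in ("x", "y"):
            try:
                df[col] = pd.to_numeric(df[col], errors="raise")
            except (ValueError, TypeError) as exc:
                raise FormatError(f"non-numeric coordinate in '{col}'") from exc
            if not np.all(np.isfinite(df[col].to_numpy(dtype=float))):
                raise FormatError(f"non-finite coordinate in '{col}'")
        if "transplanted" not in df.columns:
            df["transplanted"] = False
        df["transplanted"] = df["transplanted"].astype(bool)
        if df["sample_id"].duplicated().any():
            raise FormatError("duplicate sample_id in sample table")
        # each site must have exactly one coordinate pair
        per_site = df.groupby("site_id")[["x", "y"]].nunique()
        if (per_site > 1).any().any():
            raise FormatError("a site_id maps to more than one coordinate")
        if df["population"].nunique() < 1:
            raise FormatError("no populations in sample table")
        self.df = df.reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def populations(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.df["population"]))

    @property
    def sites(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.df["site_id"]))

    def ids_in(self, population: str, exclude_transplanted: bool = False) -> list[str]:
        sel = self.df["population"] == population
        if exclude_transplanted:
            sel &= ~self.df["transplanted"]
        return list(self.df.loc[sel, "sample_id"])

    def site_coords(self) -> pd.DataFrame:
        """One row per site: site_id, x, y (km)."""
        return (
            self.df.drop_duplicates("site_id")[["site_id", "x", "y"]]
            .set_index("site_id")
            .sort_index()
        )

    def site_of(self) -> dict[str, str]:
        return dict(zip(self.df["sample_id"], self.df["site_id"]))

    def population_of(self) -> dict[str, str]:
        return dict(zip(self.df["sample_id"], self.df["population"]))

    def site_population_map(self) -> dict[str, str]:
        """site_id -> population (a site belongs to exactly one population)."""
        grouped = self.df.groupby("site_id")["population"].nunique()
        if (grouped > 1).any():
            raise ValidationError("a site_id spans more than one population")
        return dict(
            self.df.drop_duplicates("site_id")[["site_id", "population"]].values
        )

    def validate_against(self, aln: Alignment) -> None:
        """Require a 1:1 match between table sample_ids and alignment ids."""
        table_ids = set(self.df["sample_id"])
        aln_ids = set(aln.ids)
        if table_ids != aln_ids:
            extra = sorted(table_ids - aln_ids)[:5]
            missing = sorted(aln_ids - table_ids)[:5]
            raise ValidationError(
                f"sample table / alignment id mismatch "
                f"(extra in table: {extra}, missing: {missing})"
            )


def read_sample_table(path: str | Path) -> SampleTable:
    """Read the tab-separated sample metadata file."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty sample table") from exc
    if "transplanted" in df.columns:
        mapped = df["transplanted"].map(
            {"True": True, "False": False, "true": True, "false": False,
             "1": True, "0": False}
        )
        if mapped.isna().any():
            raise FormatError("transplanted column must be boolean")
        df["transplanted"] = mapped
    return SampleTable(df)


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


@dataclass
class PairwiseMatrix:
    """A labelled symmetric non-negative matrix with zero diagonal.

    Small negative entries are tolerated only when ``allow_negative`` is set
    (Phi_ST estimates can dip below zero); they are flagged via
    :attr:`has_negative`.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    allow_negative: bool = False
    has_negative: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if v.shape != (k, k):
            raise ValidationError(f"matrix shape {v.shape} != ({k}, {k})")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValidationError("matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValidationError("matrix diagonal not zero")
        if (v < 0).any():
            if not self.allow_negative:
                raise ValidationError("negative entries in distance matrix")
            self.has_negative = True
        self.values = v

    def condensed(self) -> np.ndarray:
        """Upper-triangle (off-diagonal) entries, row-major."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def reorder(self, labels: Sequence[str]) -> "PairwiseMatrix":
        idx = [self.labels.index(l) for l in labels]
        return PairwiseMatrix(
            tuple(labels), self.values[np.ix_(idx, idx)], self.allow_negative
        )


def euclidean_site_distances(
    table: SampleTable, level: str = "site"
) -> PairwiseMatrix:
    """Pairwise Euclidean distances (km) between sites or population centroids.

    At ``level='population'`` each population is represented by the centroid
    of its distinct sampling sites.
    """
    if level == "site":
        coords = table.site_coords()
        labels = tuple(coords.index)
        xy = coords[["x", "y"]].to_numpy(dtype=float)
    elif level == "population":
        sites = table.df.drop_duplicates("site_id")
        cent = sites.groupby("population")[["x", "y"]].mean().sort_index()
        labels = tuple(cent.index)
        xy = cent.to_numpy(dtype=float)
    else:
        raise ValueError(f"level must be 'site' or 'population', got {level!r}")
    if len(labels) < 2:
        raise DegenerateInputError(f"need >=2 {level}s for a distance matrix")
    return PairwiseMatrix(labels, cdist(xy, xy))


def write_pairwise_matrix(m: PairwiseMatrix, path: str | Path) -> None:
    m.to_dataframe().to_csv(path, sep="\t")


def read_pairwise_matrix(path: str | Path, allow_negative: bool = False) -> PairwiseMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return PairwiseMatrix(tuple(df.index.astype(str)), df.to_numpy(dtype=float),
                          allow_negative)
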