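"""Validated containers and delimited-text I/O for the pipeline's inputs.

Matrices are genes x samples with unique string identifiers on both axes.
Sample metadata carries the four design fields (strain, genotype, age in
months, tissue class) from which the treatment-group label is derived.
Gene sets use the Broad GMT dialect. Delimiters are auto-detected between
tab and comma, ties broken toward tab; gene identifiers are case-sensitive
and never normalized implicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STRAINS = ("Tg2576", "TgCRND8", "other")
GENOTYPES = ("WT", "TG")
TISSUE_CLASSES = ("whole_cortex", "plaque_niche", "non_plaque")
SPECIES = ("mouse", "human", "generic")
DIRECTIONS = ("up", "down", "unsigned")

SAMPLE_COLUMNS = ("sample_id", "strain", "genotype", "age_months", "tissue_class")


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


def _duplicates(ids: Iterable[str]) -> list[str]:
    idx = pd.Index(list(ids))
    return idx[idx.duplicated()].unique().tolist()


def _sniff_delimiter(path: Path) -> str:
    """Pick tab or comma from the header line; ties (incl. 0-0) go to tab."""
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            return "\t" if line.count("\t") >= line.count(",") else ","
    raise ValidationError(f"{path}: file is empty")


def format_age(age_months: float) -> str:
    """Render an age without a spurious trailing '.0' (6.0 -> '6', 1.5 -> '1.5')."""
    return format(float(age_months), "g")


def group_label(strain: str, genotype: str, age_months: float, tissue_class: str) -> str:
    """Derive the treatment-group label, e.g. 'TgCRND8:TG:6:plaque_niche'.

    A treatment group is the finest design cell: strain x genotype x age x
    tissue. The derivation is a pure function of the four fields.
    """
    return f"{strain}:{genotype}:{format_age(age_months)}:{tissue_class}"


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def _validate_axes(data: pd.DataFrame) -> None:
    for axis, what in ((data.index, "gene ids"), (data.columns, "sample ids")):
        dupes = _duplicates(axis)
        if dupes:
            raise ValidationError(f"duplicate {what}: {dupes}")


@dataclass
class CountMatrix:
    """Non-negative integer gene x sample counts (genes are rows)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _validate_axes(self.data)
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or not np.all(values == np.floor(values)):
                bad = np.argwhere(~(np.isfinite(values) & (values == np.floor(values))))
                g, s = bad[0]
                raise ValidationError(
                    f"non-integer count at gene {self.data.index[g]!r}, "
                    f"sample {self.data.columns[s]!r}: {values[g, s]!r}"
                )
            self.data = self.data.astype(np.int64)
            values = self.data.to_numpy()
        if (values < 0).any():
            bad = np.argwhere(values < 0)
            g, s = bad[0]
            raise ValidationError(
                f"negative count at gene {self.data.index[g]!r}, "
                f"sample {self.data.columns[s]!r}: {values[g, s]}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class AbundanceMatrix:
    """Non-negative real gene x sample abundances in FPKM-like units."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _validate_axes(self.data)
        self.data = self.data.astype(float)
        values = self.data.to_numpy()
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))
            g, s = bad[0]
            raise ValidationError(
                f"non-finite abundance at gene {self.data.index[g]!r}, "
                f"sample {self.data.columns[s]!r}"
            )
        if (values < 0).any():
            bad = np.argwhere(values < 0)
            g, s = bad[0]
            raise ValidationError(
                f"negative abundance at gene {self.data.index[g]!r}, "
                f"sample {self.data.columns[s]!r}: {values[g, s]}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def read_matrix(path: str | Path, kind: str = "counts") -> CountMatrix | AbundanceMatrix:
    """Read a delimited gene x sample matrix.

    Parameters
    ----------
    path
        Tab- or comma-delimited text; header row of sample ids, first column
        of gene ids. Lines starting with ``#`` are ignored.
    kind
        ``"counts"`` (integers required) or ``"abundance"`` (non-negative
        reals).
    """
    path = Path(path)
    if kind not in ("counts", "abundance"):
        raise ValueError(f"kind must be 'counts' or 'abundance', got {kind!r}")
    sep = _sniff_delimiter(path)
    frame = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    if kind == "counts":
        return CountMatrix(frame)
    return AbundanceMatrix(frame)


def write_matrix(matrix: CountMatrix | AbundanceMatrix | pd.DataFrame,
                 path: str | Path, comment: str | None = None) -> None:
    """Write a matrix as TSV, optionally preceded by a ``#`` comment line."""
    frame = matrix.data if hasattr(matrix, "data") else matrix
    path = Path(path)
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        frame.to_csv(fh, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

@dataclass
class SampleTable:
    """Per-sample design metadata defining treatment groups.

    The underlying frame is indexed by ``sample_id`` and carries ``strain``,
    ``genotype``, ``age_months``, ``tissue_class`` and the derived
    ``group_label``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        frame = self.data
        if frame.index.name != "sample_id":
            if "sample_id" in frame.columns:
                frame = frame.set_index("sample_id")
            else:
                frame = frame.rename_axis("sample_id")
        frame.index = frame.index.astype(str)
        dupes = _duplicates(frame.index)
        if dupes:
            raise ValidationError(f"duplicate sample ids: {dupes}")
        missing = [c for c in SAMPLE_COLUMNS[1:] if c not in frame.columns]
        if missing:
            raise ValidationError(f"sample table missing columns: {missing}")
        for col, allowed in (("strain", STRAINS), ("genotype", GENOTYPES),
                             ("tissue_class", TISSUE_CLASSES)):
            bad = sorted(set(frame[col]) - set(allowed))
            if bad:
                raise ValidationError(
                    f"unknown {col} value(s) {bad}; allowed: {list(allowed)}"
                )
        frame["age_months"] = frame["age_months"].astype(float)
        if (frame["age_months"] <= 0).any():
            offenders = frame.index[frame["age_months"] <= 0].tolist()
            raise ValidationError(f"age_months must be > 0; offenders: {offenders}")
        frame["group_label"] = [
            group_label(r.strain, r.genotype, r.age_months, r.tissue_class)
            for r in frame.itertuples()
        ]
        self.data = frame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def group_labels(self) -> pd.Series:
        return self.data["group_label"]

    def groups(self) -> dict[str, list[str]]:
        """Map group label -> ordered member sample ids."""
        out: dict[str, list[str]] = {}
        for sample, label in self.data["group_label"].items():
            out.setdefault(label, []).append(sample)
        return out

    def samples_in_group(self, label: str) -> list[str]:
        members = [s for s, g in self.data["group_label"].items() if g == label]
        if not members:
            raise ValidationError(
                f"group {label!r} not present; known groups: {sorted(set(self.data['group_label']))}"
            )
        return members

    def require_samples(self, sample_ids: Sequence[str]) -> None:
        """Fail if any matrix sample lacks a metadata row (join-time check)."""
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise ValidationError(f"samples missing from sample table: {missing}")


def read_sample_table(path: str | Path) -> SampleTable:
    """Read delimited sample metadata with the five required columns."""
    path = Path(path)
    sep = _sniff_delimiter(path)
    frame = pd.read_csv(path, sep=sep, comment="#", dtype={"sample_id": str})
    missing = [c for c in SAMPLE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    return SampleTable(frame)


def write_sample_table(table: SampleTable, path: str | Path,
                       comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        table.data.to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers with a species tag.

    Members may be empty at construction time (e.g. the result of a strict
    threshold filter); analysis entry points that require a non-empty set
    validate at the point of use.
    """

    name: str
    members: frozenset = field(default_factory=frozenset)
    species: str = "generic"
    direction: str = "unsigned"
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if self.species not in SPECIES:
            raise ValidationError(f"unknown species {self.species!r}; allowed: {list(SPECIES)}")
        if self.direction not in DIRECTIONS:
            raise ValidationError(f"unknown direction {self.direction!r}; allowed: {list(DIRECTIONS)}")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def restrict(self, background: Iterable[str]) -> "GeneSet":
        return GeneSet(self.name, self.members & frozenset(background),
                       self.species, self.direction, self.description)


@dataclass
class GeneSetCollection:
    """An ordered, name-unique list of gene sets."""

    name: str
    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        dupes = _duplicates(s.name for s in self.sets)
        if dupes:
            raise ValidationError(f"duplicate set names in collection: {dupes}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


def read_gmt(path: str | Path, species: str = "generic") -> GeneSetCollection:
    """Read a GMT file: one set per line as name, description, members.

    Duplicate members within a line are collapsed with a logged warning;
    a line with fewer than three tab-separated fields is a parse error.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields, got {len(fields)}"
                )
            name, description, *members = fields
            members = [m for m in members if m]
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                logger.warning("%s:%d: set %s had %d duplicate member(s); collapsed",
                               path, lineno, name, len(members) - len(unique))
            sets.append(GeneSet(name, frozenset(unique), species=species,
                                description=description))
    return GeneSetCollection(path.stem, sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection in GMT format, members in sorted order."""
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description or "na", *sorted(s.members)]) + "\n")


def read_gene_list(path: str | Path, name: str | None = None,
                   species: str = "generic") -> GeneSet:
    """Read a one-identifier-per-line gene list into a GeneSet."""
    path = Path(path)
    members = [line.strip() for line in open(path)
               if line.strip() and not line.startswith("#")]
    return GeneSet(name or path.stem, frozenset(members), species=species)


def write_gene_list(gene_set: GeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(gene_set.members):
            fh.write(gene + "\n")


# ---------------------------------------------------------------------------
# ortholog maps
# ---------------------------------------------------------------------------

@dataclass
class OrthologMap:
    """Pairs of (source_id, target_id) between two species.

    Many-to-many entries are permitted; exact duplicate pairs are collapsed.
    """

    pairs: pd.DataFrame
    source_species: str = "human"
    target_species: str = "mouse"

    def __post_init__(self) -> None:
        frame = self.pairs
        if list(frame.columns[:2]) != ["source_id", "target_id"]:
            frame = frame.iloc[:, :2].set_axis(["source_id", "target_id"], axis=1)
        n_before = len(frame)
        frame = frame.drop_duplicates(ignore_index=True).astype(str)
        if len(frame) < n_before:
            logger.warning("ortholog map: collapsed %d duplicate pair(s)",
                           n_before - len(frame))
        for sp in (self.source_species, self.target_species):
            if sp not in SPECIES:
                raise ValidationError(f"unknown species {sp!r}; allowed: {list(SPECIES)}")
        self.pairs = frame

    def targets_of(self, source_id: str) -> list[str]:
        hit = self.pairs.loc[self.pairs["source_id"] == source_id, "target_id"]
        return hit.tolist()

    def as_dict(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for row in self.pairs.itertuples():
            out.setdefault(row.source_id, []).append(row.target_id)
        return out


def read_ortholog_map(path: str | Path, source_species: str = "human",
                      target_species: str = "mouse") -> OrthologMap:
    """Read a two-column delimited source->target identifier map."""
    path = Path(path)
    sep = _sniff_delimiter(path)
    frame = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    if frame.shape[1] < 2:
        raise ValidationError(f"{path}: ortholog map needs two columns")
    return OrthologMap(frame, source_species, target_species)


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    omap.pairs.to_csv(path, sep="\t", index=False)
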