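"""Shared data model: expression tables, library metadata, homology maps,
interaction tables.

The pipeline's cross-species unit of analysis is the *homology group* — a
cluster of sequence-similar transcripts that stands in for a gene across
species whose references were assembled independently.  Transcript-level
tables carry per-library TPM abundances; library metadata records which
species, individual and tissue each library came from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Allowed tissue labels for an RNA library.
TISSUES = ("ovary", "head", "carcass", "whole")

META_COLUMNS = ("species", "individual", "tissue")


@dataclass(frozen=True)
class LibraryMeta:
    """Metadata for a single RNA library.

    Parameters
    ----------
    library_id :
        Unique identifier of the library within a dataset.
    species :
        Four-letter species code (matched case-insensitively against tree
        tip labels).
    individual :
        Identifier of the replicate individual the library was dissected
        from; tissues from the same individual share this value.
    tissue :
        One of :data:`TISSUES`.
    """

    library_id: str
    species: str
    individual: str
    tissue: str

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(
                f"unknown tissue label {self.tissue!r} for library "
                f"{self.library_id!r}; expected one of {TISSUES}"
            )


class ExpressionTable:
    """Transcripts x libraries abundance matrix with library metadata.

    ``values`` is a DataFrame indexed by transcript id with one column per
    library id; ``meta`` is indexed by library id with columns
    ``species, individual, tissue``.  Values are non-negative (TPM or a
    monotone transform thereof; see :mod:`exprphylo.normalization`).
    """

    def __init__(
        self,
        values: pd.DataFrame,
        meta: pd.DataFrame,
        *,
        unit: str = "TPM",
        log_applied: bool = False,
        allow_negative: bool = False,
    ) -> None:
        values = values.astype(float)
        meta = meta.copy()
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate transcript ids: {dups[:5]}")
        if values.columns.has_duplicates:
            raise ValueError("duplicate library ids in expression table")
        if not allow_negative and np.nanmin(values.to_numpy()) < 0:
            raise ValueError("expression values must be non-negative")
        missing = [c for c in values.columns if c not in meta.index]
        if missing:
            raise ValueError(f"libraries without metadata: {missing[:5]}")
        for col in META_COLUMNS:
            if col not in meta.columns:
                raise ValueError(f"metadata missing required column {col!r}")
        bad = meta.loc[~meta["tissue"].isin(TISSUES)]
        if len(bad):
            lib, lab = bad.index[0], bad["tissue"].iloc[0]
            raise ValueError(
                f"unknown tissue label {lab!r} for library {lib!r}; "
                f"expected one of {TISSUES}"
            )
        # species codes are matched case-insensitively downstream
        meta["species"] = meta["species"].str.lower()
        self.values = values
        self.meta = meta.loc[values.columns, list(META_COLUMNS)]
        self.unit = unit
        self.log_applied = log_applied

    # -- convenience accessors -------------------------------------------

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def library_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def libraries(self) -> list[LibraryMeta]:
        return [
            LibraryMeta(lib, row["species"], row["individual"], row["tissue"])
            for lib, row in self.meta.iterrows()
        ]

    @property
    def species(self) -> list[str]:
        return sorted(self.meta["species"].unique())

    def libraries_for(self, species: str | None = None, tissue: str | None = None) -> list[str]:
        """Library ids matching the given species and/or tissue."""
        sel = pd.Series(True, index=self.meta.index)
        if species is not None:
            sel &= self.meta["species"] == species.lower()
        if tissue is not None:
            sel &= self.meta["tissue"] == tissue
        return list(self.meta.index[sel])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionTable):
            return NotImplemented
        return (
            self.values.equals(other.values)
            and self.meta.equals(other.meta)
            and self.unit == other.unit
            and self.log_applied == other.log_applied
        )

    def __repr__(self) -> str:
        n_t, n_l = self.values.shape
        return f"<ExpressionTable {n_t} transcripts x {n_l} libraries [{self.unit}]>"


@dataclass
class HomologyMap:
    """Transcript -> homology group and transcript -> parent-gene annotation.

    ``group_of`` maps each transcript id to its homology-group id;
    ``symbols_of_group`` maps a group to the (possibly empty) set of
    reference gene symbols annotated to it; ``parent_gene`` optionally maps
    a transcript to a single reference parent-gene symbol.
    """

    group_of: dict[str, str]
    symbols_of_group: dict[str, frozenset[str]] = field(default_factory=dict)
    parent_gene: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        groups = set(self.group_of.values())
        for g in self.symbols_of_group:
            if g not in groups:
                raise ValueError(f"homology group {g!r} has no member transcripts")
        # every group present in group_of gets a symbol set (possibly empty)
        for g in groups:
            self.symbols_of_group.setdefault(g, frozenset())

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.group_of.values()))

    def members(self, group: str) -> list[str]:
        return sorted(t for t, g in self.group_of.items() if g == group)

    def group_of_symbol(self) -> dict[str, set[str]]:
        """Reverse map: reference gene symbol -> set of homology groups."""
        rev: dict[str, set[str]] = {}
        for g, syms in self.symbols_of_group.items():
            for s in syms:
                rev.setdefault(s, set()).add(g)
        return rev


#: Allowed interaction classes.
INTERACTION_CLASSES = ("physical", "enhancement", "suppression")


@dataclass(frozen=True)
class Interaction:
    gene_a: str
    gene_b: str
    interaction_class: str


class InteractionTable:
    """Deduplicated unordered gene pairs with an interaction class."""

    def __init__(self, rows: Iterable[tuple[str, str, str]]) -> None:
        seen: set[tuple[str, str, str]] = set()
        entries: list[Interaction] = []
        n_self = 0
        for a, b, cls in rows:
            if cls not in INTERACTION_CLASSES:
                raise ValueError(
                    f"unknown interaction class {cls!r}; "
                    f"expected one of {INTERACTION_CLASSES}"
                )
            if a == b:
                n_self += 1
                continue
            key = (min(a, b), max(a, b), cls)
            if key in seen:
                continue
            seen.add(key)
            entries.append(Interaction(key[0], key[1], cls))
        if n_self:
            logger.warning("dropped %d self-pair interaction rows", n_self)
        self.entries = entries

    def pairs(self, interaction_class: str | None = None) -> list[tuple[str, str]]:
        return [
            (e.gene_a, e.gene_b)
            for e in self.entries
            if interaction_class is None or e.interaction_class == interaction_class
        ]

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.gene_a, e.gene_b, e.interaction_class) for e in self.entries],
            columns=["gene_a", "gene_b", "class"],
        )


def metadata_from_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a raw metadata frame (columns library_id, species,
    individual, tissue) and return it indexed by library_id."""
    required = ["library_id", *META_COLUMNS]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"metadata missing required column {col!r}")
    if df["library_id"].duplicated().any():
        raise ValueError("duplicate library_id in metadata")
    bad = df.loc[~df["tissue"].isin(TISSUES)]
    if len(bad):
        row = bad.iloc[0]
        raise ValueError(
            f"unknown tissue label {row['tissue']!r} for library "
            f"{row['library_id']!r}; expected one of {TISSUES}"
        )
    return df.set_index("library_id")[list(META_COLUMNS)]
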