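"""Core data containers shared across the pipeline.

The design is a classical *daughter design*: sires are genotyped, their
crossbred daughters are phenotyped, and the unit of association is the
sire's mean of its daughters' adjusted records ("sire performance").
These containers carry the three inputs of that design — sire genotypes,
a pedigree, and daughter phenotype records — plus the per-sire means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN_PARENT = "0"

#: Condition labels used for per-condition sire means and scans.
CONDITION_ALL = "ALL"
DIET_CONDITIONS = ("HE", "LE")
AGE_CONDITIONS = ("AGE50", "AGE70")

#: Columns of the long-format phenotype table.
PHENO_COLUMNS = [
    "record_id", "sire", "hatch", "diet", "age", "battery", "column",
    "floor", "operator", "W", "R", "trait", "value",
]


class PipelineError(RuntimeError):
    """Raised when a pipeline stage cannot proceed (e.g. empty data)."""


@dataclass
class GenotypeMatrix:
    """Sires x markers minor-allele dosage matrix with a marker map.

    Parameters
    ----------
    sire_ids
        Ordered individual identifiers (rows).
    dosages
        Float array of shape ``(n_sires, n_markers)`` with entries in
        ``{0, 1, 2}`` counting copies of the minor allele; ``NaN`` marks a
        missing call.
    markers
        Marker map with columns ``marker`` (id), ``chrom`` (opaque label)
        and ``pos`` (1-based bp), one row per dosage column.  Positions
        must be strictly increasing within a chromosome.
    """

    sire_ids: list[str]
    dosages: np.ndarray
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        self.sire_ids = [str(s) for s in self.sire_ids]
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D array")
        if self.dosages.shape[0] != len(self.sire_ids):
            raise ValueError("row count does not match number of sire ids")
        if self.dosages.shape[1] != len(self.markers):
            raise ValueError("marker map length does not match column count")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosage entries must be 0, 1, 2 or NaN")
        m = self.markers
        for col in ("marker", "chrom", "pos"):
            if col not in m.columns:
                raise ValueError(f"marker map is missing column {col!r}")
        for chrom, grp in m.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

    @property
    def n_sires(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def call_rate_markers(self) -> np.ndarray:
        """Fraction of non-missing calls per marker."""
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def call_rate_individuals(self) -> np.ndarray:
        """Fraction of non-missing calls per individual."""
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per marker from non-missing dosages.

        Dosages count the minor allele as determined at load time; if a
        subset of individuals makes a frequency exceed 0.5 the folded
        frequency ``min(f, 1-f)`` is returned.
        """
        with np.errstate(invalid="ignore"):
            f = np.nanmean(self.dosages, axis=0) / 2.0
        f = np.where(np.isnan(f), 0.0, f)
        return np.minimum(f, 1.0 - f)

    def subset(self, *, rows: np.ndarray | None = None,
               cols: np.ndarray | None = None) -> "GenotypeMatrix":
        """Return a copy restricted to the given row/column index arrays."""
        rows = np.arange(self.n_sires) if rows is None else np.asarray(rows)
        cols = np.arange(self.n_markers) if cols is None else np.asarray(cols)
        return GenotypeMatrix(
            sire_ids=[self.sire_ids[i] for i in rows],
            dosages=self.dosages[np.ix_(rows, cols)],
            markers=self.markers.iloc[cols].reset_index(drop=True),
        )


@dataclass
class Pedigree:
    """Pedigree rows (individual, sire, dam); ``"0"`` marks an unknown parent."""

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["id", "sire", "dam"])
    )

    def __post_init__(self) -> None:
        t = self.table
        for col in ("id", "sire", "dam"):
            if col not in t.columns:
                raise ValueError(f"pedigree is missing column {col!r}")
        self.table = t.astype({"id": str, "sire": str, "dam": str}).reset_index(drop=True)
        if self.table["id"].duplicated().any():
            dup = self.table.loc[self.table["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate individual id {dup!r}")
        self.topological_order()  # raises on cycles

    @property
    def ids(self) -> list[str]:
        return list(self.table["id"])

    def parents(self) -> dict[str, tuple[str, str]]:
        return {
            r.id: (r.sire, r.dam)
            for r in self.table.itertuples(index=False)
        }

    def topological_order(self) -> list[str]:
        """Return ids with every parent before its offspring.

        Raises ``ValueError`` if the pedigree contains a cycle (an
        individual that is its own ancestor).
        """
        parents = self.parents()
        known = set(parents)
        order: list[str] = []
        placed: set[str] = set()
        remaining = list(parents)
        while remaining:
            progress = False
            nxt = []
            for ind in remaining:
                s, d = parents[ind]
                if (s not in known or s in placed) and (d not in known or d in placed):
                    order.append(ind)
                    placed.add(ind)
                    progress = True
                else:
                    nxt.append(ind)
            if not progress:
                raise ValueError(f"pedigree contains a cycle involving {nxt[:5]}")
            remaining = nxt
        return order

    def ancestors_of(self, ids: list[str]) -> list[str]:
        """The given ids plus all their recorded ancestors, in pedigree order."""
        parents = self.parents()
        wanted: set[str] = set()
        stack = [str(i) for i in ids]
        while stack:
            ind = stack.pop()
            if ind in wanted or ind not in parents:
                continue
            wanted.add(ind)
            stack.extend(parents[ind])
        return [i for i in self.topological_order() if i in wanted]


def validate_phenotypes(records: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format phenotype table and normalise dtypes."""
    missing = [c for c in PHENO_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"phenotype table is missing columns {missing}")
    rec = records.copy()
    rec["sire"] = rec["sire"].astype(str)
    bad_diet = ~rec["diet"].isin(DIET_CONDITIONS)
    if bad_diet.any():
        raise ValueError(f"invalid diet labels: {sorted(rec.loc[bad_diet, 'diet'].unique())}")
    ages = rec["age"].dropna().unique()
    bad_ages = [a for a in ages if int(a) not in (50, 70)]
    if bad_ages:
        raise ValueError(f"invalid age labels: {bad_ages}")
    if not np.isfinite(rec["value"]).all():
        raise ValueError("phenotype values must be finite")
    return rec
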