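"""Shared data containers and table I/O.

Count and frequency tables are long-format pandas DataFrames (one
observation per row) so they round-trip losslessly through TSV, the
package's on-disk interchange format.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TAG_LENGTH = 25
DNA_ALPHABET = "ACGT"

#: column order of the long-format count table
COUNT_COLUMNS = ["tag", "strain_id", "generation", "condition", "run", "count"]


@dataclass
class StrainRecord:
    """One barcoded haploid strain of the combinatorial-knockout pool.

    ``knockout_mask[i]`` is True where locus *i* carries a deletion
    cassette; ``presence_vector`` is the complementary gene-presence
    encoding used by the network model (1 = gene present).
    """

    strain_id: str
    mating_type: str  # "a" or "alpha"
    plate: int
    row: int
    column: int
    up_tag: str
    dn_tag: str
    knockout_mask: np.ndarray

    def __post_init__(self) -> None:
        self.knockout_mask = np.asarray(self.knockout_mask, dtype=bool)
        if self.mating_type not in ("a", "alpha"):
            raise ValueError(f"mating_type must be 'a' or 'alpha', got {self.mating_type!r}")
        for tag in (self.up_tag, self.dn_tag):
            if len(tag) != TAG_LENGTH or set(tag) - set(DNA_ALPHABET):
                raise ValueError(f"tags must be {TAG_LENGTH} nt over ACGT, got {tag!r}")

    @property
    def presence_vector(self) -> np.ndarray:
        """0/1 gene-presence encoding (logical NOT of the knockout mask)."""
        return (~self.knockout_mask).astype(np.int8)


def presence_matrix(strains: list[StrainRecord]) -> np.ndarray:
    """Stack strain presence vectors into an (n_strains, n_loci) 0/1 array."""
    return np.stack([s.presence_vector for s in strains])


def knockout_matrix(strains: list[StrainRecord]) -> np.ndarray:
    return np.stack([s.knockout_mask.astype(np.int8) for s in strains])


def strains_to_frame(strains: list[StrainRecord]) -> pd.DataFrame:
    rows = []
    for s in strains:
        rows.append(
            {
                "strain_id": s.strain_id,
                "mating_type": s.mating_type,
                "plate": s.plate,
                "row": s.row,
                "column": s.column,
                "up_tag": s.up_tag,
                "dn_tag": s.dn_tag,
                "genotype": "".join("1" if b else "0" for b in s.knockout_mask),
            }
        )
    return pd.DataFrame(rows)


def frame_to_strains(df: pd.DataFrame) -> list[StrainRecord]:
    out = []
    for rec in df.itertuples(index=False):
        out.append(
            StrainRecord(
                strain_id=str(rec.strain_id),
                mating_type=str(rec.mating_type),
                plate=int(rec.plate),
                row=int(rec.row),
                column=int(rec.column),
                up_tag=str(rec.up_tag),
                dn_tag=str(rec.dn_tag),
                knockout_mask=np.array([c == "1" for c in str(rec.genotype)]),
            )
        )
    return out


def write_strain_table(strains: list[StrainRecord], path: str | Path) -> None:
    strains_to_frame(strains).to_csv(path, sep="\t", index=False)


def read_strain_table(path: str | Path) -> list[StrainRecord]:
    return frame_to_strains(pd.read_csv(path, sep="\t", dtype={"genotype": str}))


@dataclass
class CountMatrix:
    """Barcode counts per (tag kind, strain, timepoint, condition, run).

    ``counts`` is a long-format frame with columns ``COUNT_COLUMNS``.
    ``generation`` is in pool generations (doublings of the whole pool).
    Duplicate runs of the same sample (the t=0 double collection) are
    kept as separate rows until summed downstream.
    """

    counts: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in COUNT_COLUMNS if c not in self.counts.columns]
        if missing:
            raise ValueError(f"count table missing columns {missing}")
        if (self.counts["count"] < 0).any():
            raise ValueError("counts must be non-negative")

    def summed_over_runs(self) -> pd.DataFrame:
        """Collapse duplicate runs (summing counts), dropping the run column."""
        return (
            self.counts.groupby(["tag", "strain_id", "generation", "condition"], as_index=False)[
                "count"
            ]
            .sum()
        )

    def sample_totals(self) -> pd.DataFrame:
        """Total mapped reads per (tag, generation, condition, run) sample."""
        return self.counts.groupby(["tag", "generation", "condition", "run"], as_index=False)[
            "count"
        ].sum()

    @property
    def conditions(self) -> list[str]:
        return sorted(self.counts["condition"].unique())

    @property
    def generations(self) -> list[float]:
        return sorted(self.counts["generation"].unique())

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, metadata: dict | None = None) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"tag": str, "strain_id": str, "condition": str})
        return cls(counts=df, metadata=metadata or {})


@dataclass
class FrequencyTable:
    """Per-sample normalized strain frequencies.

    ``f`` has columns (strain_id, generation, condition, f); within every
    (generation, condition) sample the frequencies sum to 1.
    ``provenance`` records which tag kinds contributed per strain.
    """

    f: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def pivot(self, condition: str) -> pd.DataFrame:
        """strain x generation frequency matrix for one condition."""
        sub = self.f[self.f["condition"] == condition]
        return sub.pivot(index="strain_id", columns="generation", values="f")

    def to_tsv(self, path: str | Path) -> None:
        self.f.to_csv(path, sep="\t", index=False)
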