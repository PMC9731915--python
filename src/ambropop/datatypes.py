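"""Core domain containers shared by every pipeline stage.

The study design these types encode: ~20 giant ragweed populations sampled
from two regions, each population either weedy (agricultural habitat) or
wild (non-agricultural), with 2-5 plants per population and a few plants
sequenced as biological replicate pairs. Genotypes are biallelic transcript
SNPs, expression is a TPM matrix, and sequences live in per-population
transcript collections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

HABITATS = ("weedy", "wild")

MISSING = -1  # dosage code for an uncalled genotype


class ValidationError(ValueError):
    """An input violates a container invariant."""


@dataclass(frozen=True)
class SamplePanel:
    """Per-sample metadata: the grouping backbone of every analysis.

    Wraps a DataFrame with columns ``sample_id``, ``population_id``,
    ``habitat`` (weedy/wild), ``region``, ``latitude``, ``longitude`` and
    optional ``replicate_group`` (samples sharing a value are biological
    replicates of one plant; NaN/empty means unreplicated).
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "population_id", "habitat", "region",
                "latitude", "longitude")

    def __post_init__(self) -> None:
        t = self.table
        for col in self.REQUIRED:
            if col not in t.columns:
                raise ValidationError(f"panel missing column {col!r}")
        if "replicate_group" not in t.columns:
            t = t.copy()
            t["replicate_group"] = pd.NA
            object.__setattr__(self, "table", t)
        t = self.table
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample_id {dup!r}")
        bad = set(t["habitat"]) - set(HABITATS)
        if bad:
            raise ValidationError(f"habitat must be one of {HABITATS}, got {bad}")
        pop_attrs = t.groupby("population_id")[["habitat", "region"]].nunique()
        if (pop_attrs > 1).any().any():
            raise ValidationError("a population must have one habitat and one region")
        if not t["latitude"].between(-90, 90).all():
            raise ValidationError("latitude outside [-90, 90]")
        if not t["longitude"].between(-180, 180).all():
            raise ValidationError("longitude outside [-180, 180]")
        rg = t["replicate_group"].dropna()
        rg = rg[rg.astype(str) != ""]
        counts = rg.value_counts()
        if (counts < 2).any():
            raise ValidationError("replicate_group needs >= 2 samples")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def populations(self) -> list[str]:
        return list(pd.unique(self.table["population_id"]))

    def samples_of(self, population_id: str) -> list[str]:
        t = self.table
        return list(t.loc[t["population_id"] == population_id, "sample_id"])

    def habitat_of(self, population_id: str) -> str:
        t = self.table
        h = t.loc[t["population_id"] == population_id, "habitat"]
        if h.empty:
            raise KeyError(population_id)
        return h.iloc[0]

    def region_of(self, population_id: str) -> str:
        t = self.table
        r = t.loc[t["population_id"] == population_id, "region"]
        if r.empty:
            raise KeyError(population_id)
        return r.iloc[0]

    def replicate_groups(self) -> dict[str, list[str]]:
        """Map replicate_group id -> member sample ids."""
        t = self.table
        rg = t.dropna(subset=["replicate_group"])
        rg = rg[rg["replicate_group"].astype(str) != ""]
        return {g: list(sub["sample_id"]) for g, sub in rg.groupby("replicate_group")}

    def subset(self, sample_ids: Iterable[str]) -> "SamplePanel":
        keep = set(sample_ids)
        sub = self.table[self.table["sample_id"].isin(keep)].reset_index(drop=True)
        return SamplePanel(sub)

    def drop_replicate_duplicates(self) -> "SamplePanel":
        """One sample per plant: keep the first member of each replicate
        group. Replicates are repeat libraries of one plant, so keeping both
        would pseudo-replicate every downstream statistic."""
        drop: set[str] = set()
        for _, members in self.replicate_groups().items():
            drop |= set(sorted(members)[1:])
        sub = self.table[~self.table["sample_id"].isin(drop)].copy()
        sub["replicate_group"] = pd.NA
        return SamplePanel(sub.reset_index(drop=True))


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages: loci x samples, values in {0, 1, 2, MISSING}.

    ``loci`` is a DataFrame with columns chrom, pos (1-based), ref, alt;
    positions are strictly increasing within each chrom.
    """

    loci: pd.DataFrame
    samples: list[str]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        for col in ("chrom", "pos", "ref", "alt"):
            if col not in self.loci.columns:
                raise ValidationError(f"loci missing column {col!r}")
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.loci), len(self.samples)):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.loci)}, {len(self.samples)})")
        ok = np.isin(self.dosage, (0, 1, 2, MISSING))
        if not ok.all():
            raise ValidationError("dosages must be 0/1/2 or missing")
        for _, sub in self.loci.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValidationError("positions not strictly increasing within chrom")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample_ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} absent from genotype matrix") from e

    def subset_samples(self, sample_ids: Iterable[str]) -> "GenotypeMatrix":
        ids = list(sample_ids)
        idx = self.sample_index(ids)
        return GenotypeMatrix(self.loci.reset_index(drop=True), ids,
                              self.dosage[:, idx])

    def subset_loci(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(self.loci[mask].reset_index(drop=True),
                              list(self.samples), self.dosage[mask])

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (self.samples == other.samples
                and len(self.loci) == len(other.loci)
                and self.loci[["chrom", "pos", "ref", "alt"]].reset_index(drop=True)
                    .equals(other.loci[["chrom", "pos", "ref", "alt"]]
                            .reset_index(drop=True))
                and np.array_equal(self.dosage, other.dosage))


@dataclass
class ExpressionMatrix:
    """Transcripts x samples TPM values (non-negative)."""

    values: pd.DataFrame  # index = transcript_id, columns = sample_id

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            raise ValidationError("duplicate transcript_ids")
        if v.columns.duplicated().any():
            raise ValidationError("duplicate sample_ids")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("non-numeric TPM values")
        if (arr < 0).any():
            raise ValidationError("negative TPM values")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(sample_ids)])


@dataclass
class TranscriptCollection:
    """Named nucleotide sequences (one population's transcripts, or the reference)."""

    entries: dict[str, str]
    label: str = "reference"

    def __post_init__(self) -> None:
        allowed = set("ACGTN")
        clean: dict[str, str] = {}
        for name, seq in self.entries.items():
            s = seq.upper()
            if not s:
                raise ValidationError(f"empty sequence for {name!r}")
            if set(s) - allowed:
                raise ValidationError(f"non-ACGTN characters in {name!r}")
            clean[name] = s
        self.entries = clean

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __getitem__(self, name: str) -> str:
        return self.entries[name]

    def names(self) -> list[str]:
        return list(self.entries)


@dataclass
class AnnotationMap:
    """transcript_id -> set of functional term ids, plus term descriptions."""

    terms: dict[str, set[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        undescribed = set().union(*self.terms.values()) - set(self.descriptions) \
            if self.terms else set()
        if undescribed:
            raise ValidationError(
                f"terms without description: {sorted(undescribed)[:5]}")

    def of(self, transcript_id: str) -> set[str]:
        return self.terms.get(transcript_id, set())


@dataclass(frozen=True)
class PairwiseMatrix:
    """Symmetric labelled matrix (FST, km, or genetic distance)."""

    labels: tuple[str, ...]
    matrix: np.ndarray
    kind: str = "distance"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValidationError("matrix shape does not match labels")
        if not np.allclose(m, m.T, equal_nan=True):
            raise ValidationError("matrix not symmetric")
        object.__setattr__(self, "matrix", m)

    def condensed(self) -> np.ndarray:
        """Lower-triangle values in scipy condensed order."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.matrix[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.labels),
                            columns=list(self.labels))


@dataclass(frozen=True)
class ResistanceCatalog:
    """Known target-site resistance substitutions (gene, codon, wt AA, resistant AAs)."""

    table: pd.DataFrame  # columns: gene, codon, wildtype_aa, resistant_aas

    def __post_init__(self) -> None:
        for col in ("gene", "codon", "wildtype_aa", "resistant_aas"):
            if col not in self.table.columns:
                raise ValidationError(f"catalog missing column {col!r}")
        if (self.table["codon"].astype(int) < 1).any():
            raise ValidationError("codon numbers are 1-based")

    def resistant_aas(self, gene: str, codon: int) -> set[str]:
        t = self.table
        row = t[(t["gene"] == gene) & (t["codon"].astype(int) == codon)]
        out: set[str] = set()
        for aas in row["resistant_aas"]:
            out |= {a.strip() for a in str(aas).split(",") if a.strip()}
        return out
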