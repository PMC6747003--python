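"""In-memory containers for genotypes, expression traits, and QTL trios.

Conventions used throughout the package:

* genotypes are biallelic alt-allele dosages 0/1/2, stored as floats so
  missing calls can be ``NaN``;
* variant positions are 1-based (VCF convention); BED input/output is
  converted explicitly at the I/O boundary;
* expression matrices are genes x samples with ``NaN`` for missing
  quantifications.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError, ParameterError

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Dosage matrix (variants x samples) plus per-variant metadata.

    Attributes
    ----------
    variants : pd.DataFrame
        Indexed by variant_id with columns ``chrom, pos, ref, alt``;
        ``pos`` is 1-based.
    dosages : pd.DataFrame
        Same index as ``variants``; one float column per sample with
        values in {0, 1, 2, NaN}.
    """

    variants: pd.DataFrame
    dosages: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.variants.index.equals(self.dosages.index):
            raise ParameterError("variant metadata and dosages must share an index")
        if self.variants.index.has_duplicates:
            raise ParameterError("duplicate variant ids")
        if self.dosages.columns.has_duplicates:
            raise ParameterError("duplicate sample ids")
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ParameterError(f"variant table lacks columns: {missing}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants.index)

    def maf(self) -> pd.Series:
        """Per-variant minor allele frequency over non-missing samples."""
        from .qtl import compute_maf

        return self.dosages.apply(lambda row: compute_maf(row.to_numpy()), axis=1)


@dataclass
class ExpressionMatrix:
    """Gene x sample quantitative trait matrix with a scale tag."""

    values: pd.DataFrame
    scale: str = "raw"  # "raw" | "normalized"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ParameterError("duplicate gene ids")
        if self.values.columns.has_duplicates:
            raise ParameterError("duplicate sample ids")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class GeneInterval:
    """A gene body on 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ParameterError(f"{self.gene_id}: start > end")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class TrioData:
    """Aligned complete-case vectors for one candidate QTL-gene pair.

    ``S`` holds genotype class indices 0/1/2 (equal to the alt-allele
    dosage), ``R`` mRNA values, ``N`` protein values.  ``class_priors``
    are the empirical genotype-class frequencies over the analyzed
    individuals.
    """

    S: np.ndarray
    R: np.ndarray
    N: np.ndarray
    class_priors: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=int)
        self.R = np.asarray(self.R, dtype=float)
        self.N = np.asarray(self.N, dtype=float)
        if not (self.S.shape == self.R.shape == self.N.shape):
            raise ParameterError("S, R, N must be aligned vectors")
        if self.S.size < 2:
            raise DegenerateDataError("trio needs at least 2 individuals")
        if not np.isin(self.S, [0, 1, 2]).all():
            raise ParameterError("genotype classes must be 0, 1 or 2")
        if len(np.unique(self.S)) < 2:
            raise DegenerateDataError("all individuals share one genotype class")
        if self.class_priors is None:
            counts = np.bincount(self.S, minlength=3).astype(float)
            self.class_priors = counts / counts.sum()
        else:
            self.class_priors = np.asarray(self.class_priors, dtype=float)
            if self.class_priors.shape != (3,) or not np.isclose(
                self.class_priors.sum(), 1.0
            ):
                raise ParameterError("class_priors must be 3 values summing to 1")

    @property
    def n(self) -> int:
        return int(self.S.size)

    @classmethod
    def from_vectors(
        cls,
        dosages: np.ndarray,
        mrna: np.ndarray,
        protein: np.ndarray,
    ) -> "TrioData":
        """Build a complete-case trio from possibly-missing aligned vectors."""
        s = np.asarray(dosages, dtype=float)
        r = np.asarray(mrna, dtype=float)
        n = np.asarray(protein, dtype=float)
        keep = ~(np.isnan(s) | np.isnan(r) | np.isnan(n))
        if keep.sum() < 2:
            raise DegenerateDataError("fewer than 2 complete cases")
        return cls(S=s[keep].astype(int), R=r[keep], N=n[keep])
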