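"""Core in-memory containers for genotype and expression data.

Both matrices are thin dataclasses around a numpy array plus a pandas
annotation frame, oriented features x samples (SNPs x samples, probes x
samples) to match the on-disk TSV layout.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd


class ConfigurationError(ValueError):
    """A parameter combination that the pipeline cannot honour."""


class DegenerateInputError(ValueError):
    """Input on which the requested statistic is undefined (e.g. a
    constant vector for a correlation)."""


class ParseError(ValueError):
    """Malformed input file."""


class EmptyResultError(ValueError):
    """An operation whose result is undefined because the input set was
    empty (explicit signal, distinct from an empty-but-valid result)."""


@dataclass
class GenotypeMatrix:
    """Dosage matrix (SNPs x samples) with SNP metadata.

    Dosages count the declared counted allele (``allele2``) and lie in
    [0, 2]; np.nan marks a missing genotype.  ``snps`` is indexed by SNP id
    with columns ``chrom``, ``pos`` (1-based), ``allele1``, ``allele2``.
    """

    dosage: np.ndarray
    snps: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ConfigurationError("dosage must be 2-D (snps x samples)")
        if self.dosage.shape != (len(self.snps), len(self.samples)):
            raise ConfigurationError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.snps)} SNPs x {len(self.samples)} samples"
            )
        if self.snps.index.has_duplicates:
            raise ParseError("duplicated SNP ids")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosage, initial=0) < 0 or np.nanmax(self.dosage, initial=0) > 2:
                raise ConfigurationError("dosages must lie in [0, 2]")

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[1]

    @property
    def snp_ids(self) -> pd.Index:
        return self.snps.index

    def maf(self) -> np.ndarray:
        """Empirical minor-allele frequency per SNP (missing ignored)."""
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.dosage, axis=1) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosage), axis=1)

    def row(self, snp_id: str) -> np.ndarray:
        return self.dosage[self.snps.index.get_loc(snp_id)]

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.snps.index.get_indexer(snp_ids)
        if (idx < 0).any():
            missing = [s for s, i in zip(snp_ids, idx) if i < 0]
            raise KeyError(f"unknown SNP ids: {missing[:5]}")
        return GenotypeMatrix(self.dosage[idx], self.snps.iloc[idx], list(self.samples))

    def subset_samples(self, index: Sequence[int]) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.dosage[:, index], self.snps, [self.samples[i] for i in index]
        )


@dataclass
class ExpressionMatrix:
    """Expression matrix (probes x samples) with probe positions.

    ``probes`` is indexed by probe id with columns ``chrom`` and
    ``midpoint`` (1-based transcript midpoint).  The flags record the
    normalisation state so downstream stages can assert their inputs.
    """

    values: np.ndarray
    probes: pd.DataFrame
    samples: list[str]
    log2: bool = False
    quantile_normalized: bool = False
    n_pcs_removed: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probes), len(self.samples)):
            raise ConfigurationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.probes)} probes x {len(self.samples)} samples"
            )
        if self.probes.index.has_duplicates:
            raise ParseError("duplicated probe ids")

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def probe_ids(self) -> pd.Index:
        return self.probes.index

    def row(self, probe_id: str) -> np.ndarray:
        return self.values[self.probes.index.get_loc(probe_id)]

    def subset_samples(self, index: Sequence[int]) -> "ExpressionMatrix":
        index = np.asarray(index)
        return ExpressionMatrix(
            self.values[:, index],
            self.probes,
            [self.samples[i] for i in index],
            log2=self.log2,
            quantile_normalized=self.quantile_normalized,
            n_pcs_removed=self.n_pcs_removed,
        )

    def with_values(self, values: np.ndarray, **flags) -> "ExpressionMatrix":
        out = replace(self, values=values)
        for k, v in flags.items():
            setattr(out, k, v)
        return out
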