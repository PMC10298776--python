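"""Core data containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CohortGenotypes", "PeakCountTensor", "AllelicCounts"]


@dataclass
class CohortGenotypes:
    """Diploid biallelic genotypes for a cohort.

    Positions are 1-based (VCF convention); interval overlap logic converts
    to 0-based half-open internally.
    """

    chrom: np.ndarray  # str per variant
    positions: np.ndarray  # int, 1-based, strictly increasing per chrom
    ref: np.ndarray  # single-base str
    alt: np.ndarray  # single-base str
    dosage: np.ndarray  # (n_samples, n_variants) int in {0,1,2}; -1 missing
    variant_ids: np.ndarray
    sample_ids: list[str]
    # optional haplotypes, (n_samples, n_variants, 2) in {0,1}
    phase: np.ndarray | None = None
    # per-variant target minor allele frequency used by the simulator
    target_maf: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.dosage = np.asarray(self.dosage)
        valid = self.dosage[self.dosage >= 0]
        if valid.size and not np.isin(valid, [0, 1, 2]).all():
            raise ValueError("dosage entries must be in {0, 1, 2} (or -1 missing)")
        if (np.asarray(self.ref) == np.asarray(self.alt)).any():
            raise ValueError("ref and alt alleles must differ")
        for ch in np.unique(self.chrom):
            pos = self.positions[self.chrom == ch]
            if not (np.diff(pos) > 0).all():
                raise ValueError(f"positions not strictly increasing on {ch}")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def allele_frequency(self) -> np.ndarray:
        """Empirical ALT allele frequency per variant (missing excluded)."""
        d = np.ma.masked_less(self.dosage, 0)
        return np.asarray(d.mean(axis=0) / 2.0)

    def minor_allele_frequency(self) -> np.ndarray:
        af = self.allele_frequency()
        return np.minimum(af, 1.0 - af)

    def variant_index(self) -> pd.Index:
        return pd.Index(self.variant_ids)


@dataclass
class AllelicCounts:
    """Long-format allele-specific read counts at heterozygous sites.

    One row per (variant, sample) with ref/alt-supporting read counts.
    Only samples heterozygous at the variant may carry a record.
    """

    table: pd.DataFrame  # columns: variant_id, sample, ref_count, alt_count

    REQUIRED = ("variant_id", "sample", "ref_count", "alt_count")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"allelic table missing columns: {missing}")
        if (self.table[["ref_count", "alt_count"]].to_numpy() < 0).any():
            raise ValueError("allelic counts must be non-negative")

    def for_variant(self, variant_id: str) -> pd.DataFrame:
        return self.table[self.table["variant_id"] == variant_id]


@dataclass
class PeakCountTensor:
    """Per-cell-type peak fragment counts plus allelic counts.

    totals[ct] is a (n_samples, n_peaks) matrix of fragment counts;
    allelic[ct] holds ref/alt read counts at heterozygous variants;
    offsets[ct] are positive per-sample library-size factors.
    """

    peaks: pd.DataFrame  # chrom, start, end (0-based half-open), peak_id
    sample_ids: list[str]
    totals: dict[str, np.ndarray]
    allelic: dict[str, AllelicCounts]
    offsets: dict[str, np.ndarray] = field(default_factory=dict)
    covariates: np.ndarray | None = None  # (n_samples, k)

    def __post_init__(self) -> None:
        for ct, off in self.offsets.items():
            if (np.asarray(off) <= 0).any():
                raise ValueError(f"offsets for {ct} must be positive")

    @property
    def cell_types(self) -> list[str]:
        return list(self.totals)

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    def mean_depth(self, cell_type: str) -> np.ndarray:
        """Mean fragment count per sample for every peak."""
        return self.totals[cell_type].mean(axis=0)


def library_size_factors(totals: np.ndarray) -> np.ndarray:
    """Per-sample library-size factors: total counts scaled to mean 1."""
    lib = totals.sum(axis=1).astype(float)
    if (lib <= 0).any():
        lib = np.maximum(lib, 1.0)
    return lib / lib.mean()
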