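"""Out-of-core access to PLINK 1 variant-major genotype data.

A biallelic hard-call genotype takes one of four states — 0, 1, or 2 copies
of the counted allele, or missing — so PLINK's .bed format packs four samples
per byte as 2-bit pairs.  This module memory-maps that file and exposes

* decoding of the 2-bit pairs into dosage codes,
* per-variant QC statistics (minor-allele frequency, missing rate, and the
  mean dosage used for imputation),
* dense block materialization of a requested variant subset with missing
  entries mean-imputed, and
* the sparse three-register inner-product kernel
  ``x^T r = 1*sum(r[x==1]) + 2*sum(r[x==2]) + mu*sum(r[x==missing])``
  used by screening and KKT checking, which touches each requested variant's
  bytes exactly once per call.

Dosages count the BIM A1 allele: bit-pair 00 decodes to dosage 2 (two copies
of A1).  Effect signs therefore follow A1.  Missingness is carried as the
explicit reserved code ``MISSING`` (3), never NaN; imputation happens only
when a block is materialized or inside the inner-product kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import BedFormatError, TruncatedBedError, UnsupportedLayoutError

#: Reserved dosage code for a missing genotype (the 2-bit pair 01).
MISSING: int = 3

BED_MAGIC = bytes([0x6C, 0x1B])
_MODE_VARIANT_MAJOR = 0x01

# bit-pair -> dosage code, pairs read from the least significant bit upward:
# 00 -> 2 copies of A1, 01 -> missing, 10 -> heterozygote, 11 -> 0 copies.
_PAIR_TO_CODE = np.array([2, MISSING, 1, 0], dtype=np.uint8)

# dosage code -> bit-pair, inverse of the above (index by code 0,1,2,MISSING)
CODE_TO_PAIR = np.array([0b11, 0b10, 0b00, 0b01], dtype=np.uint8)


def _byte_lut() -> np.ndarray:
    """256 x 4 table mapping a packed byte to its four dosage codes."""
    b = np.arange(256, dtype=np.uint16)
    cols = [(b >> (2 * k)) & 0b11 for k in range(4)]
    return _PAIR_TO_CODE[np.stack(cols, axis=1)]


_BYTE_LUT = _byte_lut()


def decode_bed_byte(byte: int, n_remaining: int) -> list[int]:
    """Decode one packed .bed byte into ``n_remaining`` dosage codes.

    Bit-pairs are read from the least-significant end; trailing padding
    pairs (beyond ``n_remaining``) are ignored.
    """
    if not 1 <= n_remaining <= 4:
        raise ValueError("n_remaining must be in 1..4")
    return [int(c) for c in _BYTE_LUT[byte, :n_remaining]]


@dataclass(frozen=True)
class DosageBlock:
    """A dense, mean-imputed submatrix of the genotype file.

    ``matrix`` is n_samples x len(variant_indices), column order matching
    ``variant_indices``; missing entries have been replaced by each variant's
    imputation value.
    """

    variant_indices: np.ndarray
    matrix: np.ndarray


@dataclass
class GenotypeStore:
    """Memory-mapped handle over a variant-major PLINK 1 fileset."""

    bed_path: Path
    n_samples: int
    n_variants: int
    variant_meta: pd.DataFrame
    sample_ids: np.ndarray
    _mmap: np.ndarray = field(repr=False)

    @property
    def bytes_per_variant(self) -> int:
        return (self.n_samples + 3) // 4

    # -- raw code access -------------------------------------------------

    def codes(self, indices: np.ndarray, sample_indices: np.ndarray | None = None) -> np.ndarray:
        """Dosage codes in {0,1,2,MISSING} as an (n_selected, k) uint8 array."""
        indices = np.asarray(indices, dtype=np.int64)
        if indices.size and (indices.min() < 0 or indices.max() >= self.n_variants):
            raise IndexError("variant index out of range")
        if indices.size == 0:
            decoded = np.empty((0, self.n_samples), dtype=np.uint8)
        else:
            raw = self._mmap[indices]                   # (k, bytes_per_variant)
            decoded = _BYTE_LUT[raw].reshape(indices.size, -1)[:, : self.n_samples]
        decoded = decoded.T                             # (n_samples, k)
        if sample_indices is not None:
            decoded = decoded[np.asarray(sample_indices, dtype=np.int64)]
        return decoded


def open_store(bed_path, bim_path, fam_path) -> GenotypeStore:
    """Open a PLINK 1 .bed/.bim/.fam triplet without decoding the matrix.

    Raises :class:`UnsupportedLayoutError` for sample-major files,
    :class:`BedFormatError` for wrong magic bytes, and
    :class:`TruncatedBedError` when the file length disagrees with
    ``3 + n_variants * ceil(n_samples / 4)``.
    """
    bed_path, bim_path, fam_path = Path(bed_path), Path(bim_path), Path(fam_path)
    bim = pd.read_csv(
        bim_path, sep=r"\s+", header=None,
        names=["chromosome", "variant_id", "cm", "position", "allele1", "allele2"],
        dtype={"chromosome": str, "variant_id": str, "allele1": str, "allele2": str},
    )
    fam = pd.read_csv(
        fam_path, sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype={"iid": str},
    )
    n_samples, n_variants = len(fam), len(bim)

    with open(bed_path, "rb") as fh:
        header = fh.read(3)
    if len(header) < 3 or header[:2] != BED_MAGIC:
        raise BedFormatError(f"{bed_path}: not a PLINK 1 .bed file (bad magic bytes)")
    if header[2] != _MODE_VARIANT_MAJOR:
        raise UnsupportedLayoutError(
            f"{bed_path}: sample-major .bed layout (mode byte 0x00) is not supported"
        )

    bpv = (n_samples + 3) // 4
    expected = 3 + n_variants * bpv
    actual = bed_path.stat().st_size
    if actual != expected:
        raise TruncatedBedError(
            f"{bed_path}: file length {actual} != expected {expected} "
            f"(3 + {n_variants} * {bpv})"
        )

    mm = np.memmap(bed_path, dtype=np.uint8, mode="r", offset=3, shape=(n_variants, bpv))
    return GenotypeStore(
        bed_path=bed_path,
        n_samples=n_samples,
        n_variants=n_variants,
        variant_meta=bim,
        sample_ids=fam["iid"].to_numpy(),
        _mmap=mm,
    )


def variant_stats(
    store: GenotypeStore,
    indices: np.ndarray,
    sample_indices: np.ndarray | None = None,
    chunk_size: int = 1024,
) -> pd.DataFrame:
    """Per-variant (maf, missing_rate, impute_value) over non-missing entries.

    ``sample_indices`` restricts the computation to a sample subset (e.g. the
    training split, so imputation means never leak validation/test data).  A
    variant with every entry missing gets impute_value 0, maf 0, missing
    rate 1.
    """
    indices = np.asarray(indices, dtype=np.int64)
    n_sel = store.n_samples if sample_indices is None else len(sample_indices)
    out = np.empty((indices.size, 3), dtype=np.float64)
    for start in range(0, indices.size, chunk_size):
        idx = indices[start : start + chunk_size]
        codes = store.codes(idx, sample_indices)                  # (n_sel, m)
        miss = codes == MISSING
        n_miss = miss.sum(axis=0)
        n_obs = n_sel - n_miss
        dose_sum = np.where(miss, 0, codes).sum(axis=0, dtype=np.int64)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(n_obs > 0, dose_sum / np.maximum(n_obs, 1), 0.0)
        freq = mean / 2.0
        maf = np.minimum(freq, 1.0 - freq)
        maf[n_obs == 0] = 0.0
        sl = slice(start, start + idx.size)
        out[sl, 0] = maf
        out[sl, 1] = n_miss / n_sel if n_sel else 0.0
        out[sl, 2] = mean
    return pd.DataFrame(
        out, columns=["maf", "missing_rate", "impute_value"], index=indices
    )


def qc_filter(
    stats: pd.DataFrame, max_missing_rate: float = 0.10, min_maf: float = 0.001
) -> np.ndarray:
    """Indices of variants passing missing-rate <= 10% and MAF >= 0.1% (defaults)."""
    keep = (stats["missing_rate"].to_numpy() <= max_missing_rate) & (
        stats["maf"].to_numpy() >= min_maf
    )
    return np.asarray(stats.index)[keep]


def load_block(
    store: GenotypeStore,
    indices: np.ndarray,
    impute_values: np.ndarray | None = None,
    sample_indices: np.ndarray | None = None,
) -> DosageBlock:
    """Materialize a dense float matrix for the requested variants.

    Missing entries are replaced column-wise by ``impute_values`` (defaults
    to the mean dosage over the selected samples).
    """
    indices = np.asarray(indices, dtype=np.int64)
    codes = store.codes(indices, sample_indices)
    if impute_values is None:
        impute_values = variant_stats(store, indices, sample_indices)["impute_value"].to_numpy()
    impute_values = np.asarray(impute_values, dtype=np.float64)
    if impute_values.shape[0] != indices.size:
        raise ValueError("impute_values length must match indices")
    mat = codes.astype(np.float64)
    miss_rows, miss_cols = np.nonzero(codes == MISSING)
    mat[miss_rows, miss_cols] = impute_values[miss_cols]
    return DosageBlock(variant_indices=indices, matrix=mat)


def sparse_inner_products(
    store: GenotypeStore,
    R: np.ndarray,
    indices: np.ndarray,
    chunk_size: int = 512,
    impute_values: np.ndarray | None = None,
    sample_indices: np.ndarray | None = None,
) -> np.ndarray:
    """Compute ``X[:, indices]^T R`` by the SNP-optimized accumulation.

    Because a dosage column only takes the values {0, 1, 2, mu}, the dot
    product with a residual vector reduces to three masked partial sums —
    zero-dosage entries contribute nothing.  One sequential variant-major
    pass over the requested bytes serves all ``R`` columns at once; the
    result is independent of ``chunk_size`` up to float summation order.
    """
    R = np.atleast_2d(np.asarray(R, dtype=np.float64))
    if R.shape[0] == 1 and R.size > 1 and R.shape[1] != 1:
        pass  # a 1-row matrix is legitimate only when n_samples == 1
    indices = np.asarray(indices, dtype=np.int64)
    n_rows = store.n_samples if sample_indices is None else len(sample_indices)
    if R.shape[0] != n_rows:
        raise ValueError(f"R has {R.shape[0]} rows, expected {n_rows}")
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    if impute_values is None:
        impute_values = variant_stats(store, indices, sample_indices)["impute_value"].to_numpy()
    impute_values = np.asarray(impute_values, dtype=np.float64)

    out = np.empty((indices.size, R.shape[1]), dtype=np.float64)
    for start in range(0, indices.size, chunk_size):
        idx = indices[start : start + chunk_size]
        codes = store.codes(idx, sample_indices)          # (n_rows, m)
        het = (codes == 1).T.astype(np.float64)
        hom = (codes == 2).T.astype(np.float64)
        mis = (codes == MISSING).T.astype(np.float64)
        mu = impute_values[start : start + idx.size, None]
        out[start : start + idx.size] = het @ R + 2.0 * (hom @ R) + mu * (mis @ R)
    return out
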