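"""Synthetic genotype/phenotype generator with known ground truth.

Emulates the structure of a biobank SNP dataset at desk scale: biallelic
hard-call dosages in {0, 1, 2, missing} drawn as Binomial(2, MAF) with
per-variant MAF uniform on a configurable range, i.i.d. missingness, and a
sparse linear signal read out through one of three links —

* gaussian: y = Z gamma + X beta* + eps, with the noise variance set so
  that var(X beta*) / var(y) equals the requested heritability;
* binomial: y ~ Bernoulli(logistic(eta)), with eta scaled so the genetic
  share of the latent variance (var(X beta*) against the logistic variance
  pi^2/3) matches the heritability;
* cox: event times ~ Exponential(h0 * exp(eta)) with independent
  exponential censoring whose rate is tuned to the requested censored
  fraction.

Variants are independent by default; a block-autoregressive mode adds
within-block LD for exercising the grouped-selection behaviour of the
elastic net.  Everything is deterministic under the seed.  The companion
writer emits a PLINK 1 .bed/.bim/.fam triplet that round-trips bit-exactly
through :mod:`basilnet.genotype_io`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .families import SurvivalResponse
from .genotype_io import CODE_TO_PAIR, MISSING


@dataclass(frozen=True)
class SimulationSpec:
    """Generative parameters for one synthetic dataset."""

    n_samples: int
    n_variants: int
    family: str = "gaussian"
    maf_low: float = 0.05
    maf_high: float = 0.5
    missing_rate: float = 0.01
    n_causal: int = 10
    effect_sd: float = 1.0
    heritability: float = 0.5
    baseline_hazard: float = 0.1
    censoring_rate: float = 0.3
    n_covariates: int = 0
    ld_block_size: int = 1          # >1 enables block-correlated variants
    ld_rho: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_causal > self.n_variants:
            raise ValueError("n_causal cannot exceed n_variants")
        if not 0 < self.heritability < 1:
            raise ValueError("heritability must lie in (0, 1)")
        if not 0 <= self.maf_low <= self.maf_high <= 0.5:
            raise ValueError("require 0 <= maf_low <= maf_high <= 0.5")


def simulate_genotypes(spec: SimulationSpec) -> tuple[np.ndarray, np.ndarray]:
    """Dosage matrix over {0,1,2,MISSING} plus the true per-variant MAFs.

    With ld_block_size > 1, allele draws within a block follow an AR(1)
    copy process with correlation ld_rho, giving geometrically decaying LD.
    """
    rng = np.random.default_rng(spec.seed)
    mafs = rng.uniform(spec.maf_low, spec.maf_high, size=spec.n_variants)
    n, p = spec.n_samples, spec.n_variants

    if spec.ld_block_size <= 1 or spec.ld_rho == 0.0:
        dosages = rng.binomial(2, mafs[None, :], size=(n, p)).astype(np.uint8)
    else:
        # two haplotypes per sample, AR(1) allele copying within blocks
        haps = np.empty((2, n, p), dtype=np.uint8)
        for h in range(2):
            alleles = np.empty((n, p), dtype=np.uint8)
            for j in range(p):
                fresh = rng.random(n) < mafs[j]
                if j % spec.ld_block_size == 0:
                    alleles[:, j] = fresh
                else:
                    copy = rng.random(n) < spec.ld_rho
                    alleles[:, j] = np.where(copy, alleles[:, j - 1], fresh)
            haps[h] = alleles
        dosages = (haps[0] + haps[1]).astype(np.uint8)

    if spec.missing_rate > 0:
        mask = rng.random((n, p)) < spec.missing_rate
        dosages[mask] = MISSING
    return dosages, mafs


def _imputed(dosages: np.ndarray) -> np.ndarray:
    X = dosages.astype(np.float64)
    miss = dosages == MISSING
    X[miss] = np.nan
    col_means = np.nanmean(X, axis=0)
    col_means = np.where(np.isnan(col_means), 0.0, col_means)
    idx = np.nonzero(miss)
    X[idx] = col_means[idx[1]]
    return X


def simulate_phenotype(dosages: np.ndarray, spec: SimulationSpec):
    """Response (and status for cox), covariates, and the true coefficients.

    Returns (response, Z, beta_true, gamma_true); Z is None when
    n_covariates == 0.  The genetic signal is built on the mean-imputed
    dosage matrix.
    """
    rng = np.random.default_rng(spec.seed + 1)
    n, p = dosages.shape
    X = _imputed(dosages)

    beta = np.zeros(p)
    causal = rng.choice(p, size=spec.n_causal, replace=False)
    beta[causal] = rng.normal(0.0, spec.effect_sd, size=spec.n_causal)
    signal = X @ beta
    signal_var = signal.var()
    if spec.n_causal > 0 and signal_var == 0:
        raise ValueError("degenerate genetic signal; increase MAF or effect size")

    Z = None
    gamma = np.zeros(spec.n_covariates)
    cov_part = 0.0
    if spec.n_covariates > 0:
        Z = rng.normal(size=(n, spec.n_covariates))
        gamma = rng.normal(0.0, 0.5, size=spec.n_covariates)
        cov_part = Z @ gamma

    h2 = spec.heritability
    if spec.family == "gaussian":
        noise_var = signal_var * (1 - h2) / h2 if signal_var > 0 else 1.0
        y = cov_part + signal + rng.normal(0.0, np.sqrt(noise_var), size=n)
        return y, Z, beta, gamma
    if spec.family == "binomial":
        # scale eta so genetic variance is h2 of the latent total (logistic pi^2/3)
        latent_noise = np.pi**2 / 3.0
        if signal_var > 0:
            s = np.sqrt(h2 * latent_noise / ((1 - h2) * signal_var))
        else:
            s = 1.0
        beta = beta * s
        eta = cov_part + X @ beta
        y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(np.float64)
        return y, Z, beta, gamma
    if spec.family == "cox":
        eta = cov_part + signal
        eta = eta - eta.mean()
        rate = spec.baseline_hazard * np.exp(eta)
        T = rng.exponential(1.0 / rate)
        target = spec.censoring_rate

        def censored_fraction(log_c_rate):
            c = np.exp(log_c_rate)
            return np.mean(c / (c + rate)) - target

        # P(censor before event) for exponential races; solve for the rate
        lo, hi = np.log(rate.min()) - 20, np.log(rate.max()) + 20
        log_c = optimize.brentq(censored_fraction, lo, hi)
        C = rng.exponential(np.exp(-log_c), size=n)
        time = np.minimum(T, C)
        event = T <= C
        return SurvivalResponse(time=time, event=event), Z, beta, gamma
    raise ValueError(f"unknown family {spec.family!r}")


def split_indices(n: int, seed: int, fractions=(0.6, 0.2, 0.2)):
    """Seeded train/validation/test partition (defaults 60/20/20)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    return (
        np.sort(perm[:n_train]),
        np.sort(perm[n_train : n_train + n_val]),
        np.sort(perm[n_train + n_val :]),
    )


def write_plink_fixture(
    dosages: np.ndarray,
    out_prefix,
    variant_ids=None,
    sample_ids=None,
    chromosome: str = "1",
) -> tuple[Path, Path, Path]:
    """Write a dosage matrix as a PLINK 1 .bed/.bim/.fam triplet.

    Padding bit-pairs in the final byte of each variant row are written as
    00 and ignored on read.  Dosage 2 means two copies of the BIM A1 allele.
    """
    dosages = np.asarray(dosages)
    if not np.all(np.isin(dosages, [0, 1, 2, MISSING])):
        raise ValueError(f"dosages must be in {{0, 1, 2, {MISSING} (missing)}}")
    n, p = dosages.shape
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    if variant_ids is None:
        variant_ids = [f"snp{j}" for j in range(p)]
    if sample_ids is None:
        sample_ids = [f"sample{i}" for i in range(n)]

    bpv = (n + 3) // 4
    pairs = CODE_TO_PAIR[dosages.astype(np.uint8)]          # (n, p)
    padded = np.zeros((bpv * 4, p), dtype=np.uint8)         # pad pairs are 0b00
    padded[:n] = pairs
    quads = padded.reshape(bpv, 4, p)
    packed = (
        quads[:, 0] | (quads[:, 1] << 2) | (quads[:, 2] << 4) | (quads[:, 3] << 6)
    )  # (bpv, p)

    bed_path = out_prefix.with_suffix(".bed")
    with open(bed_path, "wb") as fh:
        fh.write(bytes([0x6C, 0x1B, 0x01]))
        fh.write(packed.T.astype(np.uint8).tobytes())       # variant-major rows

    bim = pd.DataFrame(
        {
            "chrom": chromosome,
            "id": variant_ids,
            "cm": 0,
            "pos": np.arange(1, p + 1),
            "a1": "A",
            "a2": "G",
        }
    )
    bim_path = out_prefix.with_suffix(".bim")
    bim.to_csv(bim_path, sep="\t", header=False, index=False)

    fam = pd.DataFrame(
        {
            "fid": sample_ids,
            "iid": sample_ids,
            "pat": 0,
            "mat": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam_path = out_prefix.with_suffix(".fam")
    fam.to_csv(fam_path, sep="\t", header=False, index=False)
    return bed_path, bim_path, fam_path


def simulate_dataset(spec: SimulationSpec, out_prefix):
    """simulate genotypes + phenotype and write the full fileset.

    Writes the PLINK triplet, a tab-delimited phenotype/covariate table
    (IID, response, status for cox, covariates), and a ground-truth
    coefficient table.  Returns the paths and in-memory arrays.
    """
    dosages, mafs = simulate_genotypes(spec)
    response, Z, beta, gamma = simulate_phenotype(dosages, spec)
    bed, bim, fam = write_plink_fixture(dosages, out_prefix)

    out_prefix = Path(out_prefix)
    iids = [f"sample{i}" for i in range(spec.n_samples)]
    tab = {"IID": iids}
    if spec.family == "cox":
        tab["time"] = response.time
        tab["status"] = response.event.astype(int)
    else:
        tab["pheno"] = response
    if Z is not None:
        for k in range(Z.shape[1]):
            tab[f"covar{k + 1}"] = Z[:, k]
    pheno_path = out_prefix.parent / (out_prefix.name + ".pheno.tsv")
    pd.DataFrame(tab).to_csv(pheno_path, sep="\t", index=False)

    truth = pd.DataFrame(
        {
            "variant_id": [f"snp{j}" for j in range(spec.n_variants)],
            "beta_true": beta,
            "maf_true": mafs,
        }
    )
    truth_path = out_prefix.parent / (out_prefix.name + ".truth.tsv")
    truth.to_csv(truth_path, sep="\t", index=False)
    return {
        "bed": bed,
        "bim": bim,
        "fam": fam,
        "pheno": pheno_path,
        "truth": truth_path,
        "dosages": dosages,
        "response": response,
        "covariates": Z,
        "beta_true": beta,
        "gamma_true": gamma,
    }
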