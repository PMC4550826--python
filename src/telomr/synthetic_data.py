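"""Synthetic two-sample GWAS summary statistics with known ground truth.

Summary estimates are drawn directly from their asymptotic sampling
distributions — the exact model both causal estimators assume — rather than
from simulated genotypes:

    x_k ~ Normal(xi_k, sigma_xk^2),   sigma_xk = sd_TL / sqrt(2 m_k (1-m_k) n_exp)
    y_k ~ Normal(beta xi_k + alpha_k, sigma_yk^2),
                sigma_yk = 1 / sqrt(2 m_k (1-m_k) * n_cases n_controls / N)

with m_k the allele frequency, n_exp the effective exposure-GWAS size, and
the outcome SE the standard per-allele logistic-regression approximation at
the given case/control split.  Exposure and outcome draws are independent
(two-sample design).  alpha_k are direct (pleiotropic) effects of the SNP
on the outcome, zero under the exclusion restriction.

Defaults put the generator on the scale of the telomere-length instrument
set: the nine active per-allele TL effects from the packaged GWAS table
(kb per long allele), TL SD 0.5 kb, and adenocarcinoma-scale outcome
counts.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DomainError
from .summary_io import (
    BASES,
    COMPLEMENT,
    InstrumentSet,
    SnpExposureAssoc,
    SnpOutcomeAssoc,
    build_instrument_set,
    telomere_instruments,
    two_sided_p,
    write_exposure_table,
    write_outcome_table,
)

#: per-allele TL effects (kb) of the nine active packaged instruments
DEFAULT_INSTRUMENT_BETAS_KB = tuple(
    r.beta_kb for r in telomere_instruments(active_only=True))
DEFAULT_SNP_IDS = tuple(
    r.snp_id for r in telomere_instruments(active_only=True))
_PACKAGED_LONG_ALLELES = {
    r.snp_id: r.long_allele for r in telomere_instruments()}


def _allele_pair(snp_id: str) -> tuple[str, str]:
    """Deterministic (long, short) allele pair for a SNP id, never
    palindromic.  Depends only on the id, so exposure and outcome tables
    generated under different seeds remain joinable."""
    bases = sorted(BASES)
    h = zlib.crc32(snp_id.encode())
    long_allele = _PACKAGED_LONG_ALLELES.get(snp_id, bases[h % 4])
    partners = [b for b in bases
                if b != long_allele and b != COMPLEMENT[long_allele]]
    return long_allele, partners[(h >> 2) % len(partners)]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative law for one synthetic two-sample MR dataset.

    ``true_beta`` is the causal log-odds of outcome per kb of TL.
    ``exposure_n`` is the effective exposure-GWAS sample size (default the
    ~37k of the largest TL GWAS feeding the instrument table).  Outcome
    counts default to the adenocarcinoma stratum scale (3718 cases /
    15871 controls).  ``flip_fraction`` of the SNPs are written with the
    outcome oriented to the short-TL allele, exercising harmonization.
    """

    true_beta: float = 0.0
    n_snps: int = 9
    instrument_betas_kb: tuple[float, ...] = DEFAULT_INSTRUMENT_BETAS_KB
    exposure_n: int = 37_000
    n_cases: int = 3_718
    n_controls: int = 15_871
    maf: tuple[float, ...] | float = 0.3
    pleiotropy: tuple[float, ...] | float = 0.0
    sd_tl_kb: float = 0.5
    flip_fraction: float = 0.5
    outcome_label: str = "synthetic"
    seed: int = 0

    def __post_init__(self):
        if self.n_snps < 1:
            raise DomainError("n_snps must be >= 1")
        # normalise scalar maf/pleiotropy to per-SNP tuples so configs that
        # describe the same generative law compare equal
        object.__setattr__(self, "instrument_betas_kb",
                           tuple(float(b) for b in
                                 np.atleast_1d(self.instrument_betas_kb)))
        object.__setattr__(self, "maf",
                           tuple(map(float, self._broadcast(self.maf))))
        object.__setattr__(self, "pleiotropy",
                           tuple(map(float, self._broadcast(self.pleiotropy))))
        if len(self.instrument_betas_kb) != self.n_snps:
            raise DomainError("instrument_betas_kb must have length n_snps")
        if len(self.maf_array()) != self.n_snps:
            raise DomainError("maf must be scalar or length n_snps")
        if len(self.pleiotropy_array()) != self.n_snps:
            raise DomainError("pleiotropy must be scalar or length n_snps")
        maf = self.maf_array()
        if np.any(maf <= 0.01) or np.any(maf > 0.5):
            raise DomainError("maf must lie in (0.01, 0.5]")
        if not 0 <= self.flip_fraction <= 1:
            raise DomainError("flip_fraction must lie in [0, 1]")
        if min(self.exposure_n, self.n_cases, self.n_controls) <= 0:
            raise DomainError("sample sizes must be positive")

    def _broadcast(self, v) -> np.ndarray:
        arr = np.atleast_1d(np.asarray(v, dtype=float))
        if arr.size == 1:
            arr = np.full(self.n_snps, arr[0])
        return arr

    def maf_array(self) -> np.ndarray:
        return self._broadcast(self.maf)

    def pleiotropy_array(self) -> np.ndarray:
        return self._broadcast(self.pleiotropy)

    @property
    def sigma_x(self) -> np.ndarray:
        m = self.maf_array()
        return self.sd_tl_kb / np.sqrt(2 * m * (1 - m) * self.exposure_n)

    @property
    def sigma_y(self) -> np.ndarray:
        m = self.maf_array()
        n_eff = self.n_cases * self.n_controls / (self.n_cases + self.n_controls)
        return 1.0 / np.sqrt(2 * m * (1 - m) * n_eff)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth stored alongside a generated dataset."""

    true_beta: float
    xi: tuple[float, ...]
    alpha: tuple[float, ...]
    expected_q_noncentrality: float

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def _q_noncentrality(xi, alpha, sigma_y) -> float:
    """Noncentrality of Q_rs induced by mean offsets alpha on the outcome:
    the squared weighted norm of alpha minus its projection on xi."""
    w = sigma_y ** -2.0
    total = float(np.sum(alpha**2 * w))
    proj = float(np.sum(xi * alpha * w) ** 2 / np.sum(xi**2 * w))
    return total - proj


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[list[SnpExposureAssoc], list[SnpOutcomeAssoc], SyntheticTruth]:
    """Draw one synthetic exposure table, outcome table and its truth.

    Deterministic in ``(config, seed)``.  Exposure betas are reported for
    the long-TL allele; a ``flip_fraction`` of outcome rows are oriented to
    the short allele (effect sign negated) so downstream harmonization has
    real work to do.  Allele pairs are never palindromic.
    """
    rng = np.random.default_rng(config.seed)
    xi = np.asarray(config.instrument_betas_kb, dtype=float)
    alpha = config.pleiotropy_array()
    sx, sy = config.sigma_x, config.sigma_y

    x_hat = rng.normal(xi, sx)
    # the long-allele convention makes observed exposure betas positive;
    # at instrument-grade z-scores a non-positive draw is ~impossible, but
    # redraw rather than emit an invalid table
    for _ in range(100):
        bad = x_hat <= 0
        if not bad.any():
            break
        x_hat[bad] = rng.normal(xi[bad], sx[bad])
    y_hat = rng.normal(config.true_beta * xi + alpha, sy)

    n_flip = int(round(config.flip_fraction * config.n_snps))
    flip = np.zeros(config.n_snps, dtype=bool)
    flip[rng.choice(config.n_snps, size=n_flip, replace=False)] = True

    if config.n_snps <= len(DEFAULT_SNP_IDS) and tuple(xi) == tuple(
            DEFAULT_INSTRUMENT_BETAS_KB[:config.n_snps]):
        snp_ids = list(DEFAULT_SNP_IDS[:config.n_snps])
    else:
        snp_ids = [f"rs9{i:06d}" for i in range(config.n_snps)]

    exposures, outcomes = [], []
    # Wald P floored at the representable limit (near-noiseless configs
    # otherwise underflow to an invalid P of exactly 0)
    wald_p = lambda b, s: max(two_sided_p(b, s), 1e-300)
    for k in range(config.n_snps):
        long_allele, short_allele = _allele_pair(snp_ids[k])
        exposures.append(SnpExposureAssoc(
            snp_id=snp_ids[k], long_allele=long_allele,
            beta_kb=float(x_hat[k]), se_kb=float(sx[k]),
            p_value=wald_p(float(x_hat[k]), float(sx[k])),
            chrom="1", locus="synthetic", source="synthetic"))
        if flip[k]:
            eff, other, beta = short_allele, long_allele, -float(y_hat[k])
        else:
            eff, other, beta = long_allele, short_allele, float(y_hat[k])
        outcomes.append(SnpOutcomeAssoc(
            snp_id=snp_ids[k], effect_allele=eff, other_allele=other,
            beta_logodds=beta, se_logodds=float(sy[k]),
            p_value=wald_p(beta, float(sy[k])),
            outcome_label=config.outcome_label,
            n_cases=config.n_cases, n_controls=config.n_controls))

    truth = SyntheticTruth(
        true_beta=config.true_beta, xi=tuple(xi), alpha=tuple(alpha),
        expected_q_noncentrality=_q_noncentrality(xi, alpha, sy))
    return exposures, outcomes, truth


def generate_instrument_set(config: SyntheticConfig) -> tuple[InstrumentSet,
                                                              SyntheticTruth]:
    """Generate a dataset and harmonize it in one step (for simulations)."""
    exposures, outcomes, truth = generate_dataset(config)
    return build_instrument_set(exposures, outcomes), truth


def inject_pleiotropy(config: SyntheticConfig, snp_index: int,
                      offset: float) -> SyntheticConfig:
    """Return a config whose ``snp_index``-th SNP gains a direct effect
    ``offset`` on the outcome log-odds; everything else is untouched."""
    if not 0 <= snp_index < config.n_snps:
        raise DomainError(f"snp_index {snp_index} out of range "
                          f"[0, {config.n_snps})")
    alpha = config.pleiotropy_array().copy()
    alpha[snp_index] += offset
    return dataclasses.replace(config, pleiotropy=tuple(alpha))


def write_dataset(config: SyntheticConfig, outdir: str | Path,
                  prefix: str = "synthetic") -> dict[str, Path]:
    """Generate and write exposure/outcome TSVs plus a truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exposures, outcomes, truth = generate_dataset(config)
    paths = {
        "exposure": outdir / f"{prefix}_exposure.tsv",
        "outcome": outdir / f"{prefix}_outcome.tsv",
        "truth": outdir / f"{prefix}_truth.json",
    }
    write_exposure_table(exposures, paths["exposure"])
    write_outcome_table(outcomes, paths["outcome"])
    truth.to_json(paths["truth"])
    return paths
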