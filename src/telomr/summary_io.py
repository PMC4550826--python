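"""Data model and I/O for GWAS summary statistics used as MR inputs.

The exposure side is a table of SNP-telomere-length associations reported in
kb of telomere per copy of the "long TL" allele; the outcome side is a table
of per-allele log odds ratios for a disease outcome.  Harmonization orients
every outcome effect to the long-TL allele, so a positive causal effect of
telomere length appears as positive outcome effects across instruments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import (
    AlleleMismatchError,
    DomainError,
    EmptyInstrumentError,
    PalindromicAlleleError,
    SummaryFormatError,
)

logger = logging.getLogger("telomr")

BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column names, in serialization order
EXPOSURE_COLUMNS = (
    "snp_id", "chrom", "locus", "long_allele",
    "beta_kb", "se_kb", "p_value", "source", "excluded_reason",
)
OUTCOME_COLUMNS = (
    "snp_id", "effect_allele", "other_allele", "beta_logodds",
    "se_logodds", "p_value", "outcome_label", "n_cases", "n_controls",
)

_EXPOSURE_REQUIRED = ("snp_id", "long_allele", "beta_kb", "p_value")
_OUTCOME_REQUIRED = ("snp_id", "effect_allele", "beta_logodds", "se_logodds")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpExposureAssoc:
    """One instrument SNP's association with telomere length.

    ``beta_kb`` is the TL effect in kb per copy of ``long_allele`` and is
    positive by the long-allele reporting convention.  ``se_kb`` may be
    absent on input; :func:`derive_se_from_p` recovers it from the P-value.
    ``excluded_reason`` marks rows that are retained for audit but excluded
    from analysis (e.g. LD with another instrument).
    """

    snp_id: str
    long_allele: str
    beta_kb: float
    p_value: float
    chrom: str = ""
    locus: str = ""
    se_kb: float | None = None
    source: str = ""
    excluded_reason: str | None = None

    def __post_init__(self):
        if self.long_allele not in BASES:
            raise DomainError(
                f"{self.snp_id}: long_allele must be one of A/C/G/T, "
                f"got {self.long_allele!r}")
        if not self.beta_kb > 0:
            raise DomainError(
                f"{self.snp_id}: beta_kb must be > 0 (long-allele "
                f"convention), got {self.beta_kb}")
        if not 0 < self.p_value <= 1:
            raise DomainError(
                f"{self.snp_id}: p_value must lie in (0, 1], got {self.p_value}")
        if self.se_kb is not None and not self.se_kb > 0:
            raise DomainError(f"{self.snp_id}: se_kb must be > 0 when present")

    @property
    def active(self) -> bool:
        return self.excluded_reason is None

    def with_derived_se(self) -> "SnpExposureAssoc":
        """Return a copy whose ``se_kb`` is filled in from the P-value."""
        if self.se_kb is not None:
            return self
        return replace(self, se_kb=derive_se_from_p(self.beta_kb, self.p_value))


@dataclass(frozen=True)
class SnpOutcomeAssoc:
    """One SNP's per-allele log-odds association with a disease outcome."""

    snp_id: str
    effect_allele: str
    beta_logodds: float
    se_logodds: float
    other_allele: str | None = None
    p_value: float | None = None
    outcome_label: str = ""
    n_cases: int | None = None
    n_controls: int | None = None

    def __post_init__(self):
        if not self.se_logodds > 0:
            raise DomainError(f"{self.snp_id}: se_logodds must be > 0")
        if self.effect_allele not in BASES:
            raise DomainError(f"{self.snp_id}: bad effect_allele "
                              f"{self.effect_allele!r}")
        if self.other_allele is not None:
            if self.other_allele not in BASES:
                raise DomainError(f"{self.snp_id}: bad other_allele "
                                  f"{self.other_allele!r}")
            if self.other_allele == self.effect_allele:
                raise DomainError(f"{self.snp_id}: effect and other allele "
                                  "must differ")
        for name in ("n_cases", "n_controls"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise DomainError(f"{self.snp_id}: {name} must be positive")


@dataclass(frozen=True)
class HarmonizedVariant:
    """Exposure + outcome effects oriented to the long-TL allele."""

    snp_id: str
    long_allele: str
    x: float            # TL effect, kb per long allele
    sigma_x: float      # SE of x, kb
    y: float            # outcome log-odds per long allele
    sigma_y: float      # SE of y
    flipped: bool = False

    def __post_init__(self):
        if not self.x > 0:
            raise DomainError(f"{self.snp_id}: x must be > 0")
        if not self.sigma_x > 0 or not self.sigma_y > 0:
            raise DomainError(f"{self.snp_id}: SEs must be > 0")


@dataclass
class InstrumentSet:
    """An ordered, duplicate-free set of harmonized instruments.

    ``excluded`` records every SNP dropped on the way here, with the reason,
    so analysis reports can audit the instrument selection.
    """

    variants: list[HarmonizedVariant]
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        ids = [v.snp_id for v in self.variants]
        if len(ids) != len(set(ids)):
            raise DomainError("duplicate snp_id in instrument set")

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    @property
    def snp_ids(self) -> list[str]:
        return [v.snp_id for v in self.variants]

    @property
    def x(self) -> np.ndarray:
        return np.array([v.x for v in self.variants])

    @property
    def sigma_x(self) -> np.ndarray:
        return np.array([v.sigma_x for v in self.variants])

    @property
    def y(self) -> np.ndarray:
        return np.array([v.y for v in self.variants])

    @property
    def sigma_y(self) -> np.ndarray:
        return np.array([v.sigma_y for v in self.variants])

    def drop(self, snp_ids: Iterable[str], reason: str) -> "InstrumentSet":
        """Return a new set without ``snp_ids``; absent ids warn and pass."""
        snp_ids = list(snp_ids)
        present = {v.snp_id for v in self.variants}
        for s in snp_ids:
            if s not in present:
                logger.warning("drop: %s not in instrument set; ignored", s)
        keep = [v for v in self.variants if v.snp_id not in snp_ids]
        dropped = [(v.snp_id, reason) for v in self.variants
                   if v.snp_id in snp_ids]
        if not keep:
            raise EmptyInstrumentError("dropping all SNPs leaves no instruments")
        for s, r in dropped:
            logger.info("excluded %s (%s)", s, r)
        return InstrumentSet(keep, self.excluded + dropped)


# ---------------------------------------------------------------------------
# SE <-> P plumbing
# ---------------------------------------------------------------------------

def derive_se_from_p(beta: float, p_value: float) -> float:
    """Standard error implied by an effect size and its two-sided P-value.

    Inverts the Wald test: ``se = |beta| / z`` with
    ``z = Phi^{-1}(1 - p/2)``.  P-values below 1e-300 are rejected rather
    than clamped — the quantile is no longer reliably representable there.
    """
    if beta == 0:
        raise DomainError("beta = 0: the Wald z-score is undefined")
    if not 0 < p_value < 1:
        raise DomainError(f"p_value must lie strictly in (0, 1), got {p_value}")
    if p_value < 1e-300:
        raise DomainError(f"p_value {p_value} below representable floor 1e-300")
    z = stats.norm.isf(p_value / 2.0)
    return abs(beta) / z


def two_sided_p(beta: float, se: float) -> float:
    """Two-sided normal P-value for beta/se."""
    if not se > 0:
        raise DomainError("se must be > 0")
    return float(2.0 * stats.norm.sf(abs(beta) / se))


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def is_palindromic(a1: str, a2: str | None) -> bool:
    return a2 is not None and COMPLEMENT.get(a1) == a2


def harmonize(
    exposure: SnpExposureAssoc,
    outcome: SnpOutcomeAssoc,
    *,
    allow_palindromic: bool = False,
) -> HarmonizedVariant:
    """Orient an outcome association to the exposure's long-TL allele.

    No strand flipping is attempted: the outcome effect allele must equal the
    long allele (kept as-is) or the other allele must (sign flipped).
    Palindromic A/T and C/G pairs are ambiguous without strand information
    and raise unless ``allow_palindromic`` is set, in which case the stated
    alleles are trusted and a warning is logged.
    """
    if exposure.snp_id != outcome.snp_id:
        raise DomainError(
            f"snp_id mismatch: {exposure.snp_id} vs {outcome.snp_id}")
    if is_palindromic(outcome.effect_allele, outcome.other_allele):
        if not allow_palindromic:
            raise PalindromicAlleleError(
                f"{exposure.snp_id}: palindromic allele pair "
                f"{outcome.effect_allele}/{outcome.other_allele}")
        logger.warning("%s: palindromic pair %s/%s accepted as stated",
                       exposure.snp_id, outcome.effect_allele,
                       outcome.other_allele)

    exposure = exposure.with_derived_se()
    if outcome.effect_allele == exposure.long_allele:
        y, flipped = outcome.beta_logodds, False
    elif outcome.other_allele == exposure.long_allele:
        y, flipped = -outcome.beta_logodds, True
    else:
        raise AlleleMismatchError(
            f"{exposure.snp_id}: neither {outcome.effect_allele} nor "
            f"{outcome.other_allele} matches long allele "
            f"{exposure.long_allele}")
    if flipped:
        logger.info("%s: outcome effect flipped to long allele %s",
                    exposure.snp_id, exposure.long_allele)
    return HarmonizedVariant(
        snp_id=exposure.snp_id,
        long_allele=exposure.long_allele,
        x=exposure.beta_kb,
        sigma_x=exposure.se_kb,
        y=y,
        sigma_y=outcome.se_logodds,
        flipped=flipped,
    )


def build_instrument_set(
    exposures: Sequence[SnpExposureAssoc],
    outcomes: Sequence[SnpOutcomeAssoc],
    *,
    exclusions: Mapping[str, str] | None = None,
    proxy_map: Mapping[str, str] | None = None,
    allow_palindromic: bool = False,
) -> InstrumentSet:
    """Join exposure and outcome tables into a harmonized instrument set.

    Proxy substitution (instrument id -> tag SNP id present in the outcome
    table) is applied before the join; the instrument keeps its exposure
    effect.  LD-marked exposure rows and user ``exclusions`` are dropped
    with audit reasons; instruments absent from the outcome table are
    dropped with reason ``missing-in-outcome`` rather than erroring.
    """
    exclusions = dict(exclusions or {})
    proxy_map = dict(proxy_map or {})
    by_id = {o.snp_id: o for o in outcomes}

    variants: list[HarmonizedVariant] = []
    dropped: list[tuple[str, str]] = []
    for exp in exposures:
        if exp.excluded_reason is not None:
            dropped.append((exp.snp_id, exp.excluded_reason))
            continue
        if exp.snp_id in exclusions:
            dropped.append((exp.snp_id, exclusions[exp.snp_id]))
            continue
        lookup_id = proxy_map.get(exp.snp_id, exp.snp_id)
        out = by_id.get(lookup_id)
        if out is None:
            dropped.append((exp.snp_id, "missing-in-outcome"))
            logger.warning("%s: not in outcome table (no usable proxy); "
                           "dropped", exp.snp_id)
            continue
        if lookup_id != exp.snp_id:
            logger.info("%s: using proxy %s from outcome table",
                        exp.snp_id, lookup_id)
            out = replace(out, snp_id=exp.snp_id)
        variants.append(
            harmonize(exp, out, allow_palindromic=allow_palindromic))
    if not variants:
        raise EmptyInstrumentError("no instruments survived the join")
    for s, r in dropped:
        logger.info("excluded %s (%s)", s, r)
    return InstrumentSet(variants, dropped)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def load_dialect(source: str | Path | Mapping[str, str] | None) -> dict:
    """Normalise a dialect (role -> column name map) from a dict or YAML/JSON
    file; ``None`` means canonical column names."""
    if source is None:
        return {}
    if isinstance(source, Mapping):
        return dict(source)
    with open(source) as fh:
        loaded = yaml.safe_load(fh)
    if not isinstance(loaded, Mapping):
        raise SummaryFormatError(f"dialect file {source} must map roles "
                                 "to column names")
    return dict(loaded)


def _read_table(path, dialect, required, kind):
    dialect = load_dialect(dialect)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed TSV
        raise SummaryFormatError(f"cannot parse {kind} table {path}: {exc}")
    rename = {col: role for role, col in dialect.items()}
    df = df.rename(columns=rename)
    for col in required:
        if col not in df.columns:
            raise SummaryFormatError(
                f"{kind} table {path} is missing required column {col!r}")
    return df


def _opt_float(v):
    return None if v is None or pd.isna(v) or v == "" else float(v)


def _opt_int(v):
    return None if v is None or pd.isna(v) or v == "" else int(float(v))


def _opt_str(v):
    return None if v is None or pd.isna(v) or v == "" else str(v)


def read_exposure_table(
    path: str | Path,
    dialect: str | Path | Mapping[str, str] | None = None,
) -> list[SnpExposureAssoc]:
    """Read a SNP -> telomere-length table into exposure records.

    Rows with a non-empty ``excluded_reason`` (LD with another instrument,
    in the packaged table) are retained and marked, not silently dropped.
    """
    df = _read_table(path, dialect, _EXPOSURE_REQUIRED, "exposure")
    records = []
    for row in df.to_dict("records"):
        records.append(SnpExposureAssoc(
            snp_id=str(row["snp_id"]),
            long_allele=str(row["long_allele"]),
            beta_kb=float(row["beta_kb"]),
            p_value=float(row["p_value"]),
            chrom=str(row.get("chrom", "") or ""),
            locus=str(row.get("locus", "") or ""),
            se_kb=_opt_float(row.get("se_kb")),
            source=str(row.get("source", "") or ""),
            excluded_reason=_opt_str(row.get("excluded_reason")),
        ))
    return records


def read_outcome_table(
    path: str | Path,
    dialect: str | Path | Mapping[str, str] | None = None,
    outcome_label: str | None = None,
) -> list[SnpOutcomeAssoc]:
    """Read a SNP -> disease log-odds table into outcome records."""
    df = _read_table(path, dialect, _OUTCOME_REQUIRED, "outcome")
    records = []
    for row in df.to_dict("records"):
        records.append(SnpOutcomeAssoc(
            snp_id=str(row["snp_id"]),
            effect_allele=str(row["effect_allele"]),
            beta_logodds=float(row["beta_logodds"]),
            se_logodds=float(row["se_logodds"]),
            other_allele=_opt_str(row.get("other_allele")),
            p_value=_opt_float(row.get("p_value")),
            outcome_label=outcome_label or str(row.get("outcome_label", "") or ""),
            n_cases=_opt_int(row.get("n_cases")),
            n_controls=_opt_int(row.get("n_controls")),
        ))
    return records


def exposure_frame(records: Sequence[SnpExposureAssoc]) -> pd.DataFrame:
    return pd.DataFrame(
        [{c: getattr(r, c) for c in EXPOSURE_COLUMNS} for r in records],
        columns=list(EXPOSURE_COLUMNS))


def outcome_frame(records: Sequence[SnpOutcomeAssoc]) -> pd.DataFrame:
    return pd.DataFrame(
        [{c: getattr(r, c) for c in OUTCOME_COLUMNS} for r in records],
        columns=list(OUTCOME_COLUMNS))


def write_exposure_table(records: Sequence[SnpExposureAssoc],
                         path: str | Path) -> None:
    exposure_frame(records).to_csv(path, sep="\t", index=False)


def write_outcome_table(records: Sequence[SnpOutcomeAssoc],
                        path: str | Path) -> None:
    outcome_frame(records).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# packaged instrument table
# ---------------------------------------------------------------------------

def packaged_instrument_path() -> Path:
    """Path of the packaged telomere-length GWAS instrument table."""
    return Path(resources.files("telomr") / "data" / "telomere_gwas_hits.tsv")


def telomere_instruments(active_only: bool = False) -> list[SnpExposureAssoc]:
    """The packaged TL instrument table (11 GWAS hits, 2 LD-excluded).

    With ``active_only`` the two LD-excluded rows are filtered, leaving the
    nine independent genome-wide-significant instruments.
    """
    records = read_exposure_table(packaged_instrument_path())
    if active_only:
        records = [r for r in records if r.active]
    return records
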