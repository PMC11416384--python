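"""GWAS summary statistics: reading, validation, instrument selection,
and allele harmonization.

The in-memory container for one trait's per-SNP association estimates is
:class:`SummaryStats`, a thin wrapper around a pandas DataFrame with the
mandatory columns ``rsid, chrom, pos, effect_allele, other_allele, eaf,
beta, se, pval, n``.  Instrument selection follows the usual two-sample MR
recipe: keep genome-wide candidates below a p-value threshold, greedily
clump by LD within a physical window, then screen out weak instruments by
F-statistic.  Harmonization aligns exposure and outcome effects onto the
exposure's effect allele, dropping palindromic (A/T, G/C) and otherwise
ambiguous records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateVariantError,
    EmptyInputError,
    EmptyInstrumentError,
    HarmonizationEmptyError,
    InvalidParameterError,
    SchemaError,
)
from .ld import LDMatrix

logger = logging.getLogger(__name__)

#: mandatory summary-statistic columns, in canonical order
COLUMNS = [
    "rsid", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

TRAIT_CLASSES = ("gut_microbiota", "immune_cell", "outcome", "other")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: per-SNP provenance flags assigned during harmonization
KEPT = "kept"
FLIPPED = "flipped_then_kept"
DROP_PALINDROMIC = "dropped_palindromic"
DROP_AMBIGUOUS = "dropped_ambiguous"
DROP_MISSING = "dropped_missing_in_outcome"


@dataclass(frozen=True)
class SnpAssociation:
    """One variant's association estimate for one trait."""

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: float

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise InvalidParameterError(f"{self.rsid}: identical alleles")
        if not self.se > 0:
            raise InvalidParameterError(f"{self.rsid}: se must be positive")
        if not 0 < self.pval <= 1:
            raise InvalidParameterError(f"{self.rsid}: pval must be in (0, 1]")


@dataclass
class SummaryStats:
    """One trait's GWAS summary statistics."""

    trait_id: str
    table: pd.DataFrame
    trait_class: str = "other"

    def __post_init__(self) -> None:
        if self.trait_class not in TRAIT_CLASSES:
            raise InvalidParameterError(f"unknown trait class {self.trait_class!r}")
        missing = [c for c in COLUMNS if c not in self.table.columns]
        if missing:
            raise SchemaError(f"{self.trait_id}: missing columns {missing}")
        if len(self.table) == 0:
            raise EmptyInputError(f"{self.trait_id}: no records")
        dup = self.table["rsid"][self.table["rsid"].duplicated()]
        if len(dup):
            raise DuplicateVariantError(
                f"{self.trait_id}: duplicated rsids {sorted(set(dup))}"
            )
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def records(self) -> Iterator[SnpAssociation]:
        for row in self.table.itertuples(index=False):
            yield SnpAssociation(
                rsid=str(row.rsid), chrom=str(row.chrom), pos=int(row.pos),
                effect_allele=str(row.effect_allele), other_allele=str(row.other_allele),
                eaf=float(row.eaf), beta=float(row.beta), se=float(row.se),
                pval=float(row.pval), n=float(row.n),
            )

    def subset(self, rsids: Sequence[str]) -> "SummaryStats":
        keep = self.table[self.table["rsid"].isin(set(rsids))]
        return SummaryStats(self.trait_id, keep.copy(), self.trait_class)


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_id: str | None = None,
    trait_class: str = "other",
) -> SummaryStats:
    """Read a tab-separated summary-statistics file.

    ``column_map`` maps canonical names to the file's column names.  Rows
    with non-finite beta/se or non-positive se are dropped with a logged
    count; alleles are upper-cased.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if len(df) == 0:
        raise EmptyInputError(f"{path}: empty summary-statistics file")
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    df = df[COLUMNS].copy()
    df["chrom"] = df["chrom"].astype(str)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    bad = ~(np.isfinite(df["beta"]) & np.isfinite(df["se"]) & (df["se"] > 0))
    if bad.any():
        logger.info("%s: dropped %d rows with invalid beta/se", path, int(bad.sum()))
        df = df[~bad]
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no valid rows after filtering")
    return SummaryStats(trait_id or path.stem, df.reset_index(drop=True), trait_class)


def write_summary_stats(stats: SummaryStats, path: str | Path) -> None:
    """Write the canonical tab-separated format (lossless round-trip)."""
    stats.table[COLUMNS].to_csv(path, sep="\t", index=False)


def f_statistic(beta, se, literal: bool = False):
    """Single-SNP instrument-strength statistic.

    Default is the conventional approximation F = (beta/se)^2; the
    ``literal`` variant beta/se^2 is available for comparison.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise InvalidParameterError("se must be strictly positive")
    out = beta / se**2 if literal else (beta / se) ** 2
    return float(out) if out.ndim == 0 else out


def select_instruments(
    stats: SummaryStats,
    ld: LDMatrix | None = None,
    p_threshold: float = 1e-5,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000.0,
    f_min: float = 10.0,
    f_literal: bool = False,
) -> SummaryStats:
    """Select approximately independent, strong instruments for a trait.

    Greedy LD clumping: candidates with ``pval < p_threshold`` are sorted by
    p-value (ties by chromosome then position); the best remaining SNP is
    kept and every other candidate on the same chromosome within
    ``window_kb`` whose squared correlation with it exceeds ``r2_threshold``
    is removed.  SNPs absent from ``ld`` are treated as independent (logged).
    Finally SNPs with F below ``f_min`` are dropped.
    """
    df = stats.table
    cand = df[df["pval"] < p_threshold].copy()
    if len(cand) == 0:
        raise EmptyInstrumentError(
            f"{stats.trait_id}: no SNP passes p < {p_threshold:g}"
        )
    if ld is not None:
        uncovered = [r for r in cand["rsid"] if r not in ld]
        if uncovered:
            logger.info(
                "%s: %d candidate SNPs absent from LD matrix, treated as independent",
                stats.trait_id, len(uncovered),
            )
    cand = cand.sort_values(
        ["pval", "chrom", "pos"], kind="mergesort"
    ).reset_index(drop=True)
    window_bp = window_kb * 1000.0

    kept_rows: list[int] = []
    alive = np.ones(len(cand), dtype=bool)
    chrom = cand["chrom"].astype(str).to_numpy()
    pos = cand["pos"].to_numpy(float)
    rsid = cand["rsid"].astype(str).to_numpy()
    for i in range(len(cand)):
        if not alive[i]:
            continue
        kept_rows.append(i)
        alive[i] = False
        if ld is None:
            continue
        near = alive & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window_bp)
        for j in np.flatnonzero(near):
            if ld.r2(rsid[i], rsid[j]) > r2_threshold:
                alive[j] = False

    kept = cand.iloc[kept_rows]
    f = f_statistic(kept["beta"].to_numpy(), kept["se"].to_numpy(), literal=f_literal)
    weak = f < f_min
    if weak.any():
        logger.info("%s: dropped %d weak instruments (F < %g)",
                    stats.trait_id, int(weak.sum()), f_min)
    kept = kept[~weak]
    if len(kept) == 0:
        raise EmptyInstrumentError(
            f"{stats.trait_id}: no instrument survives clumping and F >= {f_min:g}"
        )
    # restore genomic order for reproducible downstream arrays
    kept = kept.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return SummaryStats(stats.trait_id, kept, stats.trait_class)


@dataclass
class HarmonizedPair:
    """Allele-aligned exposure/outcome effects for one trait pair.

    ``gamma_hat``/``sigma_x`` are the SNP-to-exposure estimates, and
    ``Gamma_hat``/``sigma_y`` the SNP-to-outcome estimates, all expressed
    per copy of the exposure's effect allele.  ``provenance`` records the
    fate of every input instrument.
    """

    exposure_id: str
    outcome_id: str
    rsids: np.ndarray
    gamma_hat: np.ndarray
    sigma_x: np.ndarray
    Gamma_hat: np.ndarray
    sigma_y: np.ndarray
    provenance: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self.rsids = np.asarray(self.rsids, dtype=object)
        for name in ("gamma_hat", "sigma_x", "Gamma_hat", "sigma_y"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        lengths = {len(self.rsids), len(self.gamma_hat), len(self.sigma_x),
                   len(self.Gamma_hat), len(self.sigma_y)}
        if len(lengths) != 1:
            raise InvalidParameterError("harmonized arrays must have equal length")
        if self.n_snp < 1:
            raise HarmonizationEmptyError(
                f"{self.exposure_id}->{self.outcome_id}: no kept SNPs"
            )
        if np.any(self.sigma_x <= 0) or np.any(self.sigma_y <= 0):
            raise InvalidParameterError("standard errors must be positive")
        if self.provenance is None:
            self.provenance = pd.DataFrame(
                {"rsid": self.rsids, "status": KEPT}
            )

    @property
    def n_snp(self) -> int:
        return len(self.gamma_hat)

    def drop(self, mask: np.ndarray) -> "HarmonizedPair":
        """Return a pair restricted to SNPs where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return HarmonizedPair(
            self.exposure_id, self.outcome_id,
            self.rsids[mask], self.gamma_hat[mask], self.sigma_x[mask],
            self.Gamma_hat[mask], self.sigma_y[mask],
            provenance=self.provenance,
        )

    def counts(self) -> dict[str, int]:
        return self.provenance["status"].value_counts().to_dict()


def is_palindromic(a1: str, a2: str) -> bool:
    """A/T or G/C allele pairs are strand-ambiguous."""
    return {a1, a2} in ({"A", "T"}, {"G", "C"})


def harmonize(exposure_instruments: SummaryStats, outcome: SummaryStats) -> HarmonizedPair:
    """Align outcome effects onto the exposure's effect allele, per SNP.

    Instruments missing from the outcome are dropped (proxy lookup is not
    attempted); palindromic allele pairs in either trait are dropped; swapped
    alleles (directly or after strand complement) flip the outcome beta and
    reflect its frequency; anything else is dropped as ambiguous.
    """
    out_idx = outcome.table.set_index("rsid")
    statuses: list[tuple[str, str]] = []
    rows: list[tuple[str, float, float, float, float]] = []
    for rec in exposure_instruments.records:
        if rec.rsid not in out_idx.index:
            statuses.append((rec.rsid, DROP_MISSING))
            continue
        o = out_idx.loc[rec.rsid]
        oe, oo = str(o["effect_allele"]).upper(), str(o["other_allele"]).upper()
        ee, eo = rec.effect_allele.upper(), rec.other_allele.upper()
        if is_palindromic(ee, eo) or is_palindromic(oe, oo):
            statuses.append((rec.rsid, DROP_PALINDROMIC))
            continue
        ce, co = _COMPLEMENT.get(oe, "?"), _COMPLEMENT.get(oo, "?")
        if (oe, oo) == (ee, eo) or (ce, co) == (ee, eo):
            beta_out = float(o["beta"])
            statuses.append((rec.rsid, KEPT))
        elif (oo, oe) == (ee, eo) or (co, ce) == (ee, eo):
            beta_out = -float(o["beta"])
            statuses.append((rec.rsid, FLIPPED))
        else:
            statuses.append((rec.rsid, DROP_AMBIGUOUS))
            continue
        rows.append((rec.rsid, rec.beta, rec.se, beta_out, float(o["se"])))

    provenance = pd.DataFrame(statuses, columns=["rsid", "status"])
    if not rows:
        raise HarmonizationEmptyError(
            f"{exposure_instruments.trait_id}->{outcome.trait_id}: "
            "no SNP kept after harmonization"
        )
    rsids, gam, sx, Gam, sy = (np.array(v) for v in zip(*rows))
    return HarmonizedPair(
        exposure_id=exposure_instruments.trait_id,
        outcome_id=outcome.trait_id,
        rsids=rsids, gamma_hat=gam.astype(float), sigma_x=sx.astype(float),
        Gamma_hat=Gam.astype(float), sigma_y=sy.astype(float),
        provenance=provenance,
    )
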