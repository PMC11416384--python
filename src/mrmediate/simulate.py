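"""Synthetic three-trait GWAS summary statistics with known causal structure.

The generator emulates the statistical structure of the real study inputs
(an exposure such as a gut-microbiome feature, an immune-cell mediator, and
a disease outcome) directly on the summary-statistic scale: per-SNP true
effects, sampling noise determined by sample size and allele frequency, and
optional horizontal pleiotropy.  Causal structure is

    exposure --a--> mediator --b--> outcome,   direct effect c' on outcome,

so the total exposure-outcome effect is c = c' + a*b by construction, and a
true proportion mediated a*b/c is known exactly for every simulated study.

Two instrument sets are generated: ``n_snps`` exposure instruments (true
exposure effect gamma_j, mediator effect a*gamma_j, outcome effect
c*gamma_j plus any pleiotropic offset alpha_j) and ``n_snps_mediator``
mediator-specific instruments (mediator effect delta_k, outcome effect
b*delta_k, no exposure effect).  The second set is what makes the
mediator-to-outcome leg of two-step mediation identifiable: selecting
instruments on the mediator GWAS picks up the delta_k SNPs and recovers b.

Estimated effects are true effects plus Normal(0, se^2) noise with the
standard single-SNP standard error se = 1/sqrt(2*p*(1-p)*n) at allele
frequency p and GWAS size n.  Identical parameters (including seed) give
byte-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .errors import EmptyInputError, InvalidParameterError
from .gwas import SummaryStats
from .ld import LDMatrix

#: non-palindromic allele pairs assigned to simulated variants
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass
class TruthParams:
    """Ground-truth parameters of a simulated three-trait study.

    ``effect_a`` (exposure->mediator), ``effect_b`` (mediator->outcome) and
    ``effect_direct`` (c', outcome effect not through the mediator) define
    the mediation decomposition; ``beta_total`` (c) is derived as
    c' + a*b unless supplied, in which case it must agree exactly.
    Pleiotropy controls: a fraction ``pleio_fraction`` of exposure
    instruments receives a direct outcome offset drawn from
    Normal(pleio_mean, pleio_sd^2); pleio_mean = 0 is balanced pleiotropy.
    Default sample sizes mirror the study cohorts (microbiome GWAS n=7738,
    immune-cell GWAS n=3757, FinnGen outcome n~330k).
    """

    effect_a: float = 0.24
    effect_b: float = -0.27
    effect_direct: float = -0.90
    beta_total: float | None = None
    pleio_fraction: float = 0.0
    pleio_mean: float = 0.0
    pleio_sd: float = 0.0
    n_snps: int = 150
    n_snps_mediator: int = 150
    n_exp: int = 7738
    n_med: int = 3757
    n_out: int = 330_690
    maf_range: tuple[float, float] = (0.05, 0.5)
    mean_instrument_f: float = 30.0
    f_reference_n: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        derived = self.effect_direct + self.effect_a * self.effect_b
        if self.beta_total is None:
            self.beta_total = derived
        elif abs(self.beta_total - derived) > 1e-12:
            raise InvalidParameterError(
                "beta_total must equal effect_direct + effect_a*effect_b"
            )
        if not 0 <= self.pleio_fraction <= 1:
            raise InvalidParameterError("pleio_fraction must be in [0, 1]")
        if self.pleio_sd < 0:
            raise InvalidParameterError("pleio_sd must be non-negative")
        if min(self.n_exp, self.n_med, self.n_out) < 2:
            raise InvalidParameterError("sample sizes must be >= 2")
        if self.n_snps < 1:
            raise EmptyInputError("n_snps must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise InvalidParameterError("maf_range must lie within (0, 0.5]")
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, float) and not np.isfinite(v):
                raise InvalidParameterError(f"non-finite parameter {f.name}")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["maf_range"] = list(d["maf_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TruthParams":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["maf_range"] = tuple(d["maf_range"])
        return cls(**d)


def gwas_se(maf: np.ndarray, n: float) -> np.ndarray:
    """Standard error of a per-allele effect estimate: 1/sqrt(2p(1-p)n)."""
    maf = np.asarray(maf, dtype=float)
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def simulate_ld_blocks(
    n_snps: int,
    block_size: int,
    rho: float,
    positions_per_chrom: int = 100,
    seed: int = 0,
) -> LDMatrix:
    """Block-diagonal AR(1) LD: r_ij = rho^|i-j| within a block, 0 across.

    Variant ids follow the layout produced by :func:`variant_layout`, with
    strictly increasing positions within each chromosome.
    """
    if not 0 <= rho < 1:
        raise InvalidParameterError("rho must be in [0, 1)")
    if n_snps < 1 or block_size < 1:
        raise InvalidParameterError("n_snps and block_size must be >= 1")
    r = np.zeros((n_snps, n_snps))
    for start in range(0, n_snps, block_size):
        stop = min(start + block_size, n_snps)
        idx = np.arange(start, stop)
        r[np.ix_(idx, idx)] = rho ** np.abs(idx[:, None] - idx[None, :])
    layout = variant_layout(n_snps, positions_per_chrom)
    return LDMatrix(ids=list(layout["rsid"]), r=r)


def variant_layout(n_snps: int, positions_per_chrom: int = 100,
                   spacing_bp: int = 1_000_000) -> pd.DataFrame:
    """Deterministic rsid/chrom/pos layout shared by simulator and LD matrix."""
    i = np.arange(n_snps)
    return pd.DataFrame({
        "rsid": [f"rs{k + 1:07d}" for k in i],
        "chrom": (1 + i // positions_per_chrom).astype(str),
        "pos": 1 + (i % positions_per_chrom) * spacing_bp,
    })


def simulate_triplet_gwas(
    truth: TruthParams,
) -> tuple[SummaryStats, SummaryStats, SummaryStats, TruthParams]:
    """Simulate exposure, mediator and outcome GWAS over a shared SNP panel."""
    rng = np.random.default_rng(truth.seed)
    J = truth.n_snps
    K = truth.n_snps_mediator
    total = J + K
    layout = variant_layout(total)

    maf = rng.uniform(*truth.maf_range, size=total)
    se_exp = gwas_se(maf, truth.n_exp)
    se_med = gwas_se(maf, truth.n_med)
    se_out = gwas_se(maf, truth.n_out)

    # True per-SNP effects are physical quantities independent of how large
    # the GWAS happens to be: their scale is set so the expected single-SNP
    # F statistic is ~1 + mean_instrument_f in a reference cohort of
    # f_reference_n samples (default: the exposure GWAS size, so the
    # defaults give expected F ~ 31 at n_exp).  Larger actual cohorts then
    # yield proportionally stronger instruments, as in real data.
    n_ref = truth.f_reference_n if truth.f_reference_n is not None else truth.n_exp
    scale = np.sqrt(truth.mean_instrument_f)
    gamma = np.zeros(total)
    gamma[:J] = rng.normal(0.0, scale * gwas_se(maf[:J], n_ref))
    delta = np.zeros(total)
    if K:
        delta[J:] = rng.normal(0.0, scale * gwas_se(maf[J:], n_ref))

    alpha = np.zeros(total)
    if truth.pleio_fraction > 0:
        pleio = rng.random(J) < truth.pleio_fraction
        alpha[:J][pleio] = rng.normal(
            truth.pleio_mean, truth.pleio_sd, size=int(pleio.sum())
        )

    a, b, c = truth.effect_a, truth.effect_b, truth.beta_total
    true_exp = gamma
    true_med = a * gamma + delta
    true_out = c * gamma + b * delta + alpha

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=total)
    alleles = np.array(_ALLELE_PAIRS, dtype=object)[pair_idx]

    def one_trait(true_beta, se, n, trait_id, trait_class):
        beta_hat = true_beta + rng.normal(0.0, se)
        pval = 2.0 * sps.norm.sf(np.abs(beta_hat / se))
        table = layout.copy()
        table["effect_allele"] = alleles[:, 0]
        table["other_allele"] = alleles[:, 1]
        table["eaf"] = maf
        table["beta"] = beta_hat
        table["se"] = se
        table["pval"] = np.clip(pval, np.finfo(float).tiny, 1.0)
        table["n"] = n
        return SummaryStats(trait_id, table, trait_class)

    exposure = one_trait(true_exp, se_exp, truth.n_exp, "exposure", "gut_microbiota")
    mediator = one_trait(true_med, se_med, truth.n_med, "mediator", "immune_cell")
    outcome = one_trait(true_out, se_out, truth.n_out, "outcome", "outcome")
    return exposure, mediator, outcome, truth


def designed_instrument_pair(truth: TruthParams, leg: str = "exposure->outcome"):
    """Harmonized pair over a leg's designed instrument set.

    Bypasses p-value selection and clumping: calibration and oracle studies
    need the instrument set fixed by design rather than re-selected per
    replicate (re-selection adds winner's-curse conditioning that the
    classical sampling theory does not model).  Exposure legs use the first
    ``n_snps`` variants; the mediator->outcome leg uses the
    mediator-specific variants.
    """
    from .gwas import HarmonizedPair

    exposure, mediator, outcome, _ = simulate_triplet_gwas(truth)
    J, K = truth.n_snps, truth.n_snps_mediator
    legs = {
        "exposure->outcome": (exposure, outcome, slice(0, J)),
        "exposure->mediator": (exposure, mediator, slice(0, J)),
        "mediator->outcome": (mediator, outcome, slice(J, J + K)),
    }
    if leg not in legs:
        raise InvalidParameterError(f"unknown leg {leg!r}")
    src, dst, sl = legs[leg]
    s, d = src.table.iloc[sl], dst.table.iloc[sl]
    return HarmonizedPair(
        exposure_id=src.trait_id, outcome_id=dst.trait_id,
        rsids=s["rsid"].to_numpy(object),
        gamma_hat=s["beta"].to_numpy(float), sigma_x=s["se"].to_numpy(float),
        Gamma_hat=d["beta"].to_numpy(float), sigma_y=d["se"].to_numpy(float),
    )


@dataclass
class HarmonizationNoiseLog:
    """Which records were strand-flipped or rewritten as palindromic."""

    flipped_ids: list[str]
    palindromic_ids: list[str]


def flip_rows(table: pd.DataFrame, mask: np.ndarray) -> pd.DataFrame:
    """Swap effect/other alleles, negate beta, reflect eaf, where mask holds.

    Applying the same mask twice restores the original table.
    """
    out = table.copy()
    ea = out.loc[mask, "effect_allele"].copy()
    out.loc[mask, "effect_allele"] = out.loc[mask, "other_allele"]
    out.loc[mask, "other_allele"] = ea
    out.loc[mask, "beta"] = -out.loc[mask, "beta"]
    out.loc[mask, "eaf"] = 1.0 - out.loc[mask, "eaf"]
    return out


def inject_harmonization_noise(
    stats: SummaryStats,
    frac_flipped: float,
    frac_palindromic: float,
    seed: int = 0,
) -> tuple[SummaryStats, HarmonizationNoiseLog]:
    """Introduce the allele artifacts harmonization must handle.

    A ``frac_flipped`` fraction of records has alleles swapped with beta
    negated and eaf reflected (recoverable by harmonization); a disjoint
    ``frac_palindromic`` fraction has its allele pair rewritten to A/T or
    G/C (must be dropped).  Counts are rounded down.
    """
    if not (0 <= frac_flipped <= 1 and 0 <= frac_palindromic <= 1
            and frac_flipped + frac_palindromic <= 1):
        raise InvalidParameterError(
            "fractions must be in [0, 1] and sum to at most 1"
        )
    rng = np.random.default_rng(seed)
    n = len(stats)
    n_flip = int(frac_flipped * n)
    n_pal = int(frac_palindromic * n)
    chosen = rng.choice(n, size=n_flip + n_pal, replace=False)
    flip_idx, pal_idx = chosen[:n_flip], chosen[n_flip:]

    mask = np.zeros(n, dtype=bool)
    mask[flip_idx] = True
    table = flip_rows(stats.table, mask)
    pal_pairs = [("A", "T"), ("G", "C"), ("T", "A"), ("C", "G")]
    for i in pal_idx:
        ea, oa = pal_pairs[int(rng.integers(0, len(pal_pairs)))]
        table.iloc[int(i), table.columns.get_loc("effect_allele")] = ea
        table.iloc[int(i), table.columns.get_loc("other_allele")] = oa
    log = HarmonizationNoiseLog(
        flipped_ids=sorted(table["rsid"].iloc[flip_idx]),
        palindromic_ids=sorted(table["rsid"].iloc[pal_idx]),
    )
    return SummaryStats(stats.trait_id, table, stats.trait_class), log


def write_study(
    truth: TruthParams,
    outdir: str | Path,
    ld: LDMatrix | None = None,
) -> dict[str, Path]:
    """Write a complete synthetic study: three GWAS, LD matrix, truth sidecar."""
    from .gwas import write_summary_stats

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exposure, mediator, outcome, _ = simulate_triplet_gwas(truth)
    paths = {}
    for stats in (exposure, mediator, outcome):
        p = outdir / f"{stats.trait_id}.tsv"
        write_summary_stats(stats, p)
        paths[stats.trait_id] = p
    if ld is not None:
        paths["ld"] = outdir / "ld.tsv"
        ld.to_tsv(paths["ld"])
    paths["truth"] = outdir / "truth.yaml"
    truth.to_yaml(paths["truth"])
    return paths
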