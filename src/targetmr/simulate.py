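"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator follows the canonical linear instrumental-variable
summary-statistic model: variant j has exposure effect gamma_j, direct
(pleiotropic) outcome effect alpha_j, and total outcome effect

    Gamma_j = theta * gamma_j + alpha_j,

where theta is the causal effect of the exposure on the outcome.  The
observed effect sizes are drawn with independent noise in the exposure and
outcome samples (the two-sample design), with standard errors from the
standardized-trait closed form

    sigma_j = 1 / sqrt(2 * p_j * (1 - p_j) * n)

for effect-allele frequency p_j and the respective sample size.  Valid
variants have alpha_j = 0; invalid variants draw alpha_j from
Normal(pleiotropy_mean, pleiotropy_sd^2) — balanced when the mean is 0,
directional otherwise.  Binary outcomes reuse the same Gaussian
approximation on the log-odds scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator
from scipy import stats

from .exceptions import DataValidationError
from .io import GeneRegion, LDMatrix, SumstatRecord

# non-palindromic allele pairs only, so harmonization never needs to drop
# simulated variants under the default `infer` palindrome policy
_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))


class SimulationConfig(BaseModel):
    """Parameters of one simulated exposure-outcome summary-statistic pair.

    Defaults describe a well-powered two-sample design: 50 independent
    variants, 100k individuals per sample, a causal effect of 0.3 per SD
    of exposure, and no pleiotropy.
    """

    model_config = ConfigDict(frozen=True)

    n_variants: int = 50
    n_exposure: int = 100_000
    n_outcome: int = 100_000
    theta: float = 0.3
    invalid_fraction: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.05
    exposure_effect_range: tuple[float, float] = (0.05, 0.15)
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0
    outcome_binary: bool = False
    #: draw gamma_j with random sign (set False for all-positive effects)
    random_sign: bool = True
    #: correlation between alpha_j and gamma_j among invalid variants
    #: (0 = InSIDE satisfied by construction)
    correlated_pleiotropy: float = 0.0
    chrom: str = "1"
    id_prefix: str = "rs"
    positions: tuple[int, ...] | None = None

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if self.n_variants < 1:
            raise DataValidationError("n_variants must be >= 1")
        if self.n_exposure < 2:
            raise DataValidationError("n_exposure must be >= 2")
        if self.n_outcome < 2:
            raise DataValidationError("n_outcome must be >= 2")
        if not (0 <= self.invalid_fraction < 1):
            raise DataValidationError("invalid_fraction must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise DataValidationError("maf_range must satisfy 0 < min <= max <= 0.5")
        elo, ehi = self.exposure_effect_range
        if not (0 <= elo <= ehi):
            raise DataValidationError(
                "exposure_effect_range must satisfy 0 <= min <= max"
            )
        if self.pleiotropy_sd < 0:
            raise DataValidationError("pleiotropy_sd must be >= 0")
        if not (-1 <= self.correlated_pleiotropy <= 1):
            raise DataValidationError("correlated_pleiotropy must be in [-1, 1]")
        if self.positions is not None and len(self.positions) != self.n_variants:
            raise DataValidationError("positions must have length n_variants")
        return self


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth of one simulated pair (theta, gamma_j, alpha_j, validity)."""

    theta: float
    variant_ids: tuple[str, ...]
    gamma: np.ndarray
    alpha: np.ndarray
    valid: np.ndarray
    seed: int


def _se_closed_form(eaf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.maximum(p, 5e-324)  # keep p in (0, 1]


def _draw_instruments(rng: np.random.Generator, config: SimulationConfig):
    """Draw the variant-level quantities shared by exposure and outcomes."""
    j = config.n_variants
    eaf = rng.uniform(config.maf_range[0], config.maf_range[1], j)
    gamma = rng.uniform(*config.exposure_effect_range, j)
    if config.random_sign:
        gamma = gamma * rng.choice([-1.0, 1.0], j)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), j)
    return eaf, gamma, pair_idx


def _draw_alpha(rng: np.random.Generator, config: SimulationConfig, gamma: np.ndarray):
    """Pleiotropic outcome effects; zero for valid variants."""
    j = config.n_variants
    alpha = np.zeros(j)
    n_invalid = round(config.invalid_fraction * j)
    perm = rng.permutation(j)
    invalid_idx = perm[:n_invalid]
    if n_invalid:
        eps = rng.normal(0.0, 1.0, n_invalid)
        rho = config.correlated_pleiotropy
        if rho != 0.0 and n_invalid >= 2 and np.std(gamma[invalid_idx]) > 0:
            z_g = (gamma[invalid_idx] - gamma[invalid_idx].mean()) / gamma[
                invalid_idx
            ].std()
            eps = rho * z_g + np.sqrt(1.0 - rho**2) * eps
        alpha[invalid_idx] = config.pleiotropy_mean + config.pleiotropy_sd * eps
    return alpha


def _records(
    config: SimulationConfig,
    ids: list[str],
    pair_idx: np.ndarray,
    eaf: np.ndarray,
    beta: np.ndarray,
    se: np.ndarray,
    n: int,
    positions: np.ndarray,
) -> list[SumstatRecord]:
    p = _two_sided_p(beta, se)
    return [
        SumstatRecord(
            variant_id=ids[k],
            chrom=config.chrom,
            pos=int(positions[k]),
            effect_allele=_ALLELE_PAIRS[pair_idx[k]][0],
            other_allele=_ALLELE_PAIRS[pair_idx[k]][1],
            eaf=float(eaf[k]),
            beta=float(beta[k]),
            se=float(se[k]),
            pvalue=float(p[k]),
            n=float(n),
        )
        for k in range(config.n_variants)
    ]


def simulate_two_sample(
    config: SimulationConfig,
) -> tuple[list[SumstatRecord], list[SumstatRecord], TruthRecord]:
    """Simulate exposure and outcome summary statistics for one pair.

    Returns
    -------
    (exposure records, outcome records, truth).  Identical config (including
    seed) gives bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    j = config.n_variants
    eaf, gamma, pair_idx = _draw_instruments(rng, config)
    alpha = _draw_alpha(rng, config, gamma)
    big_gamma = config.theta * gamma + alpha

    se_x = _se_closed_form(eaf, config.n_exposure)
    se_y = _se_closed_form(eaf, config.n_outcome)
    beta_x = gamma + rng.normal(0.0, 1.0, j) * se_x
    beta_y = big_gamma + rng.normal(0.0, 1.0, j) * se_y

    ids = [f"{config.id_prefix}{k + 1}" for k in range(j)]
    if config.positions is not None:
        positions = np.asarray(config.positions)
    else:
        positions = 1 + 5000 * np.arange(j)

    exposure = _records(config, ids, pair_idx, eaf, beta_x, se_x, config.n_exposure, positions)
    outcome = _records(config, ids, pair_idx, eaf, beta_y, se_y, config.n_outcome, positions)
    truth = TruthRecord(
        theta=config.theta,
        variant_ids=tuple(ids),
        gamma=gamma,
        alpha=alpha,
        valid=(alpha == 0.0),
        seed=config.seed,
    )
    return exposure, outcome, truth


def simulate_ld_blocks(
    n_variants: int,
    block_size: int,
    within_r: float,
    seed: int = 0,
    variant_ids: tuple[str, ...] | None = None,
) -> LDMatrix:
    """Block-diagonal LD: within-block correlation ``within_r``, 0 between.

    The matrix is fully determined by its arguments; ``seed`` is accepted
    for interface uniformity and unused.  The result is symmetric positive
    semi-definite for any ``within_r`` in [0, 1).
    """
    del seed
    if block_size < 1:
        raise DataValidationError("block_size must be >= 1")
    if not (0 <= within_r < 1):
        raise DataValidationError("within_r must be in [0, 1)")
    r = np.eye(n_variants)
    for start in range(0, n_variants, block_size):
        stop = min(start + block_size, n_variants)
        r[start:stop, start:stop] = within_r
    np.fill_diagonal(r, 1.0)
    if variant_ids is None:
        variant_ids = tuple(f"rs{k + 1}" for k in range(n_variants))
    return LDMatrix(variant_ids=variant_ids, r=r)


def simulate_gene_region(
    chrom: str,
    start: int,
    end: int,
    n_variants: int,
    seed: int = 0,
    name: str = "GENE",
) -> tuple[GeneRegion, np.ndarray]:
    """Place ``n_variants`` distinct positions uniformly in [start, end)."""
    if start >= end:
        raise DataValidationError(f"start ({start}) must be < end ({end})")
    if n_variants > end - start:
        raise DataValidationError("n_variants exceeds the number of positions in the region")
    rng = np.random.default_rng(seed)
    chosen: set[int] = set()
    while len(chosen) < n_variants:
        draw = rng.integers(start, end, n_variants - len(chosen))
        chosen.update(int(x) for x in draw)
    positions = np.array(sorted(chosen))
    return GeneRegion(name=name, chrom=chrom, start=start, end=end), positions


# ---------------------------------------------------------------------------
# truth-record I/O


def write_truth(truth: TruthRecord, path: str | Path) -> None:
    """Scalar truth on a ``#``-header line, then a per-variant table."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# theta={truth.theta:.17g}\tseed={truth.seed}\n")
        fh.write("variant_id\tgamma\talpha\tvalid\n")
        for k, vid in enumerate(truth.variant_ids):
            fh.write(
                f"{vid}\t{truth.gamma[k]:.17g}\t{truth.alpha[k]:.17g}\t"
                f"{int(truth.valid[k])}\n"
            )


def read_truth(path: str | Path) -> TruthRecord:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().lstrip("#").strip()
        scalars = dict(item.split("=") for item in header.split("\t"))
        fh.readline()  # column header
        ids, gam, alp, val = [], [], [], []
        for line in fh:
            if not line.strip():
                continue
            vid, g, a, v = line.rstrip("\n").split("\t")
            ids.append(vid)
            gam.append(float(g))
            alp.append(float(a))
            val.append(bool(int(v)))
    return TruthRecord(
        theta=float(scalars["theta"]),
        variant_ids=tuple(ids),
        gamma=np.array(gam),
        alpha=np.array(alp),
        valid=np.array(val),
        seed=int(scalars["seed"]),
    )


# ---------------------------------------------------------------------------
# whole-study simulation (multiple gene regions x outcomes)


@dataclass(frozen=True)
class SimulatedStudy:
    """File locations and ground truth of a simulated drug-target study."""

    exposure_path: Path
    outcome_paths: dict[str, Path]
    regions_path: Path
    ld_path: Path
    truths: dict[tuple[str, str], TruthRecord]  # (gene, outcome) -> truth


#: gene regions loosely modelled on the three LDL-c-lowering drug targets
DEFAULT_GENES = {
    "HMGCR": ("5", 74_600_000, 74_700_000),
    "PCSK9": ("1", 55_500_000, 55_600_000),
    "NPC1L1": ("7", 44_550_000, 44_650_000),
}


def simulate_study(
    out_dir: str | Path,
    seed: int,
    thetas: dict[tuple[str, str], float],
    outcomes: dict[str, bool],
    genes: dict[str, tuple[str, int, int]] | None = None,
    n_variants_per_gene: int = 20,
    n_exposure: int = 100_000,
    n_outcome: int = 100_000,
    invalid_fraction: float = 0.0,
    pleiotropy_mean: float = 0.0,
    pleiotropy_sd: float = 0.05,
    ld_block_size: int = 4,
    ld_within_r: float = 0.7,
) -> SimulatedStudy:
    """Write a full simulated drug-target study to ``out_dir``.

    One exposure file spanning all gene regions, one outcome file per
    outcome label, a BED of regions and a block-diagonal LD matrix.  The
    exposure effects of each gene's variants are drawn once and shared
    across outcomes; ``thetas[(gene, outcome)]`` sets the causal effect of
    the exposure on that outcome through that gene's instruments.

    ``outcomes`` maps outcome label -> binary flag (log-odds scale when
    True; the flag only documents the scale — the Gaussian summary-statistic
    approximation is the same).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genes = genes or DEFAULT_GENES
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(genes) * (1 + len(outcomes)) + len(genes)))

    exposure_records: list[SumstatRecord] = []
    outcome_records: dict[str, list[SumstatRecord]] = {o: [] for o in outcomes}
    regions: list[GeneRegion] = []
    all_ids: list[str] = []
    truths: dict[tuple[str, str], TruthRecord] = {}

    for gene, (chrom, start, end) in genes.items():
        region_seed = int(next(children).generate_state(1)[0] % 2**31)
        region, positions = simulate_gene_region(
            chrom, start, end, n_variants_per_gene, seed=region_seed, name=gene
        )
        regions.append(region)
        base = SimulationConfig(
            n_variants=n_variants_per_gene,
            n_exposure=n_exposure,
            n_outcome=n_outcome,
            invalid_fraction=invalid_fraction,
            pleiotropy_mean=pleiotropy_mean,
            pleiotropy_sd=pleiotropy_sd,
            chrom=chrom,
            id_prefix=f"{gene}_rs",
            positions=tuple(int(p) for p in positions),
        )
        rng = np.random.default_rng(next(children))
        eaf, gamma, pair_idx = _draw_instruments(rng, base)
        se_x = _se_closed_form(eaf, n_exposure)
        beta_x = gamma + rng.normal(0.0, 1.0, n_variants_per_gene) * se_x
        ids = [f"{gene}_rs{k + 1}" for k in range(n_variants_per_gene)]
        all_ids.extend(ids)
        exposure_records.extend(
            _records(base, ids, pair_idx, eaf, beta_x, se_x, n_exposure, positions)
        )
        for outcome, _binary in outcomes.items():
            theta = thetas.get((gene, outcome), 0.0)
            orng = np.random.default_rng(next(children))
            alpha = _draw_alpha(orng, base, gamma)
            big_gamma = theta * gamma + alpha
            se_y = _se_closed_form(eaf, n_outcome)
            beta_y = big_gamma + orng.normal(0.0, 1.0, n_variants_per_gene) * se_y
            outcome_records[outcome].extend(
                _records(base, ids, pair_idx, eaf, beta_y, se_y, n_outcome, positions)
            )
            truths[(gene, outcome)] = TruthRecord(
                theta=theta,
                variant_ids=tuple(ids),
                gamma=gamma,
                alpha=alpha,
                valid=(alpha == 0.0),
                seed=seed,
            )

    from .io import write_ld, write_regions, write_sumstats

    exposure_path = out_dir / "exposure.tsv"
    write_sumstats(exposure_records, exposure_path)
    outcome_paths = {}
    for outcome in outcomes:
        p = out_dir / f"outcome_{outcome}.tsv"
        write_sumstats(outcome_records[outcome], p)
        outcome_paths[outcome] = p
    regions_path = out_dir / "regions.bed"
    write_regions(regions, regions_path)
    ld = simulate_ld_blocks(
        len(all_ids), ld_block_size, ld_within_r, variant_ids=tuple(all_ids)
    )
    ld_path = out_dir / "ld.tsv"
    write_ld(ld, ld_path)
    return SimulatedStudy(
        exposure_path=exposure_path,
        outcome_paths=outcome_paths,
        regions_path=regions_path,
        ld_path=ld_path,
        truths=truths,
    )
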