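"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generative model is the standard two-sample MR setup on summary scale:
each instrument j has a true standardized effect gamma_j on the exposure and
a direct (pleiotropic) effect alpha_j on the outcome, so the outcome-side
effect is theta * gamma_j + alpha_j where theta is the causal effect. The
observed estimates are

    gamma_hat_j ~ Normal(gamma_j,        se_xj^2)
    Gamma_hat_j ~ Normal(theta*gamma_j + alpha_j, se_yj^2)

with the analytic GWAS standard error se^2 = 1 / (2 * maf_j * (1-maf_j) * n)
(for binary outcomes the effective n is n * phi * (1-phi) * 4 with phi the
case fraction, and effects live on the log-odds scale). Balanced or
directional pleiotropy, InSIDE violation (alpha correlated with |gamma|),
block LD, palindromic alleles and strand/allele-swap corruptions of the
outcome file are all configurable, and every draw is reproducible from the
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .instruments import LDMatrix
from .records import COMPLEMENT, SumStatRecord, complement_allele
from .sumstats_io import Dialect, write_sumstats

__all__ = ["SimConfig", "SimTruth", "generate_study_pair", "generate_grid"]

_NONPALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]
_PALINDROMIC_PAIRS = [("A", "T"), ("G", "C")]
#: blocks are spaced beyond the clumping window; within-block spacing 1 kb
_BLOCK_SPACING_BP = 20_000_000
_N_CHROM = 22


@dataclass
class SimConfig:
    """Ground-truth configuration for one exposure/outcome study pair.

    Defaults emulate a plasma-protein exposure GWAS of ~15k participants
    instrumented by ~18 variants against a large binary disease outcome.
    """

    theta: float = 0.1  # causal effect, SD outcome (or log-odds) per SD exposure
    n_instruments: int = 18
    n_exposure: int = 14_824
    n_outcome: int = 115_803
    gamma_sd: float = 0.15  # SD of true standardized instrument effects
    pleiotropy_mean: float = 0.0  # mu_alpha: directional pleiotropy
    pleiotropy_sd: float = 0.0  # sigma_alpha: balanced pleiotropy spread
    inside_violation: bool = False  # correlate alpha with |gamma|
    inside_lambda: float = 0.1
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_null_variants: int = 0  # background variants with gamma = 0
    n_outcome_instruments: int = 0  # variants acting on the outcome only
    outcome_gamma_sd: float = 0.15
    theta_reverse: float = 0.0  # outcome -> exposure effect via outcome instruments
    prop_palindromic: float = 0.0
    prop_strand_flipped: float = 0.0
    prop_allele_swapped: float = 0.0
    ld_block_size: int = 1
    ld_within_r2: float = 0.0
    binary_outcome: bool = False
    case_fraction: float = 0.5
    min_expected_f: Optional[float] = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_instruments < 1:
            raise ValueError("need at least one instrument")
        if self.n_exposure <= 2 or self.n_outcome <= 2:
            raise ValueError("sample sizes must exceed 2")
        if self.pleiotropy_sd < 0:
            raise ValueError("pleiotropy_sd must be nonnegative")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for p in (self.prop_palindromic, self.prop_strand_flipped, self.prop_allele_swapped):
            if not (0 <= p <= 1):
                raise ValueError("corruption proportions must lie in [0, 1]")
        if not (0 < self.case_fraction < 1):
            raise ValueError("case_fraction must lie in (0, 1)")
        if self.ld_block_size < 1 or not (0 <= self.ld_within_r2 <= 1):
            raise ValueError("invalid LD block configuration")


@dataclass
class SimTruth:
    """Per-variant ground truth and the corruption flags that were applied."""

    table: pd.DataFrame  # variant_id, gamma_true, alpha_true, maf, role, flags
    theta: float

    def to_file(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _se(maf: np.ndarray, n: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _effective_n(config: SimConfig) -> float:
    if config.binary_outcome:
        phi = config.case_fraction
        return config.n_outcome * 4.0 * phi * (1.0 - phi)
    return float(config.n_outcome)


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    from scipy import stats

    z = np.abs(beta / se)
    p = 2.0 * stats.norm.sf(z)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def _draw_gamma(rng: np.random.Generator, config: SimConfig, maf: np.ndarray) -> np.ndarray:
    """True instrument effects; resampled until the expected per-variant F
    (based on the true R^2) exceeds ``min_expected_f`` when configured."""
    k = maf.size
    gamma = rng.normal(0.0, config.gamma_sd, size=k)
    if config.min_expected_f is None:
        return gamma
    for _ in range(1000):
        r2 = 2.0 * maf * (1.0 - maf) * gamma**2
        f = r2 / (1.0 - r2) * (config.n_exposure - 2.0)
        weak = f <= config.min_expected_f
        if not weak.any():
            return gamma
        gamma[weak] = rng.normal(0.0, config.gamma_sd, size=int(weak.sum()))
    raise RuntimeError(
        "could not draw instruments with expected F above the floor; "
        "increase gamma_sd or n_exposure"
    )


def generate_study_pair(
    config: SimConfig,
    outcome_noise_seed: Optional[int] = None,
) -> tuple[list[SumStatRecord], list[SumStatRecord], LDMatrix, SimTruth]:
    """Generate matched exposure and outcome summary statistics.

    Returns ``(exposure_records, outcome_records, ld, truth)``. The outcome
    file carries any configured corruptions (allele swaps, strand flips);
    the exposure file is always on the canonical orientation, and the truth
    table records exactly what was done so tests can invert it.

    ``outcome_noise_seed`` draws the outcome-side sampling noise from its
    own stream, so one exposure draw can be paired with several
    independently-noised outcome studies (as a study grid requires).
    """
    rng = np.random.default_rng(config.seed)
    rng_out = rng if outcome_noise_seed is None else np.random.default_rng(outcome_noise_seed)
    L = config.n_instruments
    n_null = config.n_null_variants
    n_oi = config.n_outcome_instruments
    total = L + n_null + n_oi

    maf = rng.uniform(*config.maf_range, size=total)
    gamma = np.zeros(total)
    alpha = np.zeros(total)
    delta = np.zeros(total)  # direct outcome effects of outcome-only instruments

    gamma[:L] = _draw_gamma(rng, config, maf[:L])
    # pleiotropy is directional with respect to the exposure-increasing
    # allele (the orientation MR-Egger tests): on the reported allele its
    # contribution is sign(gamma) * alpha_oriented
    alpha_oriented = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=L)
    if config.inside_violation:
        alpha_oriented += config.inside_lambda * np.abs(gamma[:L])
    sign = np.sign(gamma[:L])
    sign[sign == 0] = 1.0
    alpha[:L] = sign * alpha_oriented
    if n_oi:
        sl = slice(L + n_null, total)
        oc_cfg = replace(
            config,
            gamma_sd=config.outcome_gamma_sd,
            n_exposure=int(_effective_n(config)),
            seed=config.seed,
        )
        delta[sl] = _draw_gamma(rng, oc_cfg, maf[sl])

    se_x = _se(maf, config.n_exposure)
    se_y = _se(maf, _effective_n(config))
    true_x = gamma + config.theta_reverse * delta
    true_y = config.theta * gamma + alpha + delta
    beta_x = rng.normal(true_x, se_x)
    beta_y = rng_out.normal(true_y, se_y)
    p_x = _pvals(beta_x, se_x)
    p_y = _pvals(beta_y, se_y)

    # genomic layout: LD blocks are contiguous runs, spaced far beyond the
    # clumping window so the greedy step is governed by block membership
    ids = [f"rs{config.seed % 100_000:05d}{i:05d}" for i in range(total)]
    n_blocks = math.ceil(total / config.ld_block_size)
    chroms: list[str] = []
    poss: list[int] = []
    for i in range(total):
        block = i // config.ld_block_size
        within = i % config.ld_block_size
        chroms.append(str(block % _N_CHROM + 1))
        poss.append(1 + (block // _N_CHROM) * _BLOCK_SPACING_BP + within * 1000)

    palindromic = rng.random(total) < config.prop_palindromic
    strand_flip = rng.random(total) < config.prop_strand_flipped
    allele_swap = rng.random(total) < config.prop_allele_swapped
    pal_choice = rng.integers(0, len(_PALINDROMIC_PAIRS), size=total)
    nonpal_choice = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=total)

    exposure: list[SumStatRecord] = []
    outcome: list[SumStatRecord] = []
    for i in range(total):
        ea, oa = (
            _PALINDROMIC_PAIRS[pal_choice[i]]
            if palindromic[i]
            else _NONPALINDROMIC_PAIRS[nonpal_choice[i]]
        )
        base = dict(
            variant_id=ids[i],
            chrom=chroms[i],
            pos=poss[i],
        )
        exposure.append(
            SumStatRecord(
                effect_allele=ea,
                other_allele=oa,
                eaf=float(maf[i]),
                beta=float(beta_x[i]),
                se=float(se_x[i]),
                pval=float(p_x[i]),
                n=float(config.n_exposure),
                **base,
            )
        )
        out = SumStatRecord(
            effect_allele=ea,
            other_allele=oa,
            eaf=float(maf[i]),
            beta=float(beta_y[i]),
            se=float(se_y[i]),
            pval=float(p_y[i]),
            n=float(config.n_outcome),
            **base,
        )
        if strand_flip[i]:
            out = out.with_complemented_alleles()
        if allele_swap[i]:
            out = out.with_swapped_alleles()
        outcome.append(out)

    roles = ["instrument"] * L + ["null"] * n_null + ["outcome_instrument"] * n_oi
    truth = SimTruth(
        table=pd.DataFrame(
            {
                "variant_id": ids,
                "role": roles,
                "gamma_true": true_x,
                "alpha_true": alpha,
                "delta_true": delta,
                "maf": maf,
                "palindromic": palindromic,
                "strand_flipped": strand_flip,
                "allele_swapped": allele_swap,
            }
        ),
        theta=config.theta,
    )

    r2 = np.eye(total)
    if config.ld_block_size > 1 and config.ld_within_r2 > 0:
        for b in range(n_blocks):
            lo = b * config.ld_block_size
            hi = min(lo + config.ld_block_size, total)
            r2[lo:hi, lo:hi] = config.ld_within_r2
        np.fill_diagonal(r2, 1.0)
    ld = LDMatrix(ids, r2)
    return exposure, outcome, ld, truth


def generate_grid(
    exposure_configs: Sequence[SimConfig],
    exposure_labels: Sequence[str],
    outcome_labels: Sequence[str],
    out_dir: str | Path,
    theta_matrix: Optional[np.ndarray] = None,
    dialect: Optional[Dialect] = None,
) -> tuple[Path, Path]:
    """Write an exposures x outcomes synthetic study grid plus manifests.

    One summary-stat file is written per exposure and per outcome (E + O
    study files for an E x O grid); each outcome file stacks the outcome-side
    statistics of every exposure's variants, so any exposure can be analyzed
    against any outcome downstream. ``theta_matrix[i, j]`` overrides the
    causal effect of exposure i on outcome j (default: each config's theta
    for every outcome). Returns paths of the two manifest YAML files,
    consumable by :func:`mrkit.pipeline.run_direction`.
    """
    if len(exposure_configs) != len(exposure_labels):
        raise ValueError("one label per exposure config required")
    labels = list(exposure_labels) + list(outcome_labels)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate study labels")
    E, O = len(exposure_configs), len(outcome_labels)
    if theta_matrix is not None:
        theta_matrix = np.asarray(theta_matrix, dtype=float)
        if theta_matrix.shape != (E, O):
            raise ValueError(f"theta_matrix must be {E}x{O}")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dialect = dialect or Dialect()

    outcome_records: dict[str, list[SumStatRecord]] = {lab: [] for lab in outcome_labels}
    exposure_entries = []
    for i, (cfg, lab) in enumerate(zip(exposure_configs, exposure_labels)):
        for j, out_lab in enumerate(outcome_labels):
            theta_ij = float(theta_matrix[i, j]) if theta_matrix is not None else cfg.theta
            # identical exposure draw across a row; fresh outcome noise per cell
            cell_cfg = replace(cfg, theta=theta_ij, seed=(cfg.seed * 1_000 + i) % (2**31))
            noise_seed = (cfg.seed * 7_919 + i * 101 + j + 1) % (2**31)
            exp_recs, out_recs, ld, truth = generate_study_pair(cell_cfg, outcome_noise_seed=noise_seed)
            outcome_records[out_lab].extend(out_recs)
            if j == 0:
                exp_path = out_dir / f"{lab}.tsv"
                write_sumstats(exp_recs, exp_path, dialect)
                ld.to_file(out_dir / f"{lab}.ld.tsv")
                truth.to_file(out_dir / f"{lab}.truth.tsv")
                exposure_entries.append(
                    {
                        "study_id": lab,
                        "path": str(exp_path),
                        "trait_type": "continuous",
                        "ld_path": str(out_dir / f"{lab}.ld.tsv"),
                    }
                )
    outcome_entries = []
    for lab in outcome_labels:
        path = out_dir / f"{lab}.tsv"
        write_sumstats(outcome_records[lab], path, dialect)
        outcome_entries.append({"study_id": lab, "path": str(path), "trait_type": "continuous"})

    exp_manifest = out_dir / "exposures.yaml"
    out_manifest = out_dir / "outcomes.yaml"
    exp_manifest.write_text(yaml.safe_dump({"studies": exposure_entries}))
    out_manifest.write_text(yaml.safe_dump({"studies": outcome_entries}))
    return exp_manifest, out_manifest
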