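"""Synthetic multi-environment trial generator.

Emulates a durum-wheat-style design: a panel of inbred lines genotyped at
independent biallelic SNPs, phenotyped for several positively-valued
correlated traits (think days to heading, grain yield, plant height) in an
incomplete set of environments.  Phenotypes follow the additive
multi-environment model

    y_ij = baseline_t + E_i + g_j + gE_ij + e_ij

with g ~ N(0, sigma1^2 G) across lines, the interaction gE independent
across environments with within-environment covariance sigma2^2 G
(the I_I (x) G structure), and iid residuals.  Across traits the genomic
effects g share a configurable genetic correlation; gE and e are
trait-independent.  True effects are returned so recovery tests can compare
estimates against the generating values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GRM, MarkerMatrix

__all__ = [
    "SimulationConfig",
    "TrueEffects",
    "simulate_markers",
    "make_incomplete_design",
    "simulate_phenotypes",
]

# Desk-scale defaults sized so the full pipeline runs in minutes on one CPU.
# Trait scales mirror days-to-heading (days), grain yield (t/ha) and plant
# height (cm): positive baselines large relative to the noise so the
# arctan-relative-error metric is well behaved.
_DEFAULT_BASELINES = (75.0, 5.5, 95.0)
_DEFAULT_SIGMA2_G = (9.0, 0.25, 36.0)
_DEFAULT_SIGMA2_GE = (4.0, 0.12, 16.0)
_DEFAULT_SIGMA2_E = (4.0, 0.12, 25.0)
_DEFAULT_ENV_SPREAD = (5.0, 0.8, 8.0)
_DEFAULT_TRAIT_CORR = (
    (1.0, 0.5, 0.4),
    (0.5, 1.0, 0.3),
    (0.4, 0.3, 1.0),
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic trial.

    Defaults are desk scale: 100 lines x 1,000 markers x 8 environments with
    57-93 lines observed per environment.  ``paper_scale()`` returns the full
    design of 270 lines, ~14k markers and 43 environments observing 57-193
    lines each.
    """

    n_lines: int = 100
    n_markers: int = 1000
    n_envs: int = 8
    maf_range: tuple[float, float] = (0.05, 0.5)
    marker_missing_rate: float = 0.02
    lines_per_env_range: tuple[int, int] = (57, 93)
    env_effect_spread: tuple[float, ...] = _DEFAULT_ENV_SPREAD
    trait_baselines: tuple[float, ...] = _DEFAULT_BASELINES
    sigma2_g: tuple[float, ...] = _DEFAULT_SIGMA2_G
    sigma2_ge: tuple[float, ...] = _DEFAULT_SIGMA2_GE
    sigma2_e: tuple[float, ...] = _DEFAULT_SIGMA2_E
    trait_genetic_correlation: tuple[tuple[float, ...], ...] = _DEFAULT_TRAIT_CORR
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not (0.0 <= self.marker_missing_rate < 1.0):
            raise ValueError("marker_missing_rate must be in [0, 1)")
        lo, hi = self.lines_per_env_range
        if not (1 <= lo <= hi <= self.n_lines):
            raise ValueError(
                f"lines_per_env_range {self.lines_per_env_range} infeasible for "
                f"{self.n_lines} lines"
            )
        T = self.n_traits
        for name in ("env_effect_spread", "trait_baselines", "sigma2_g", "sigma2_ge", "sigma2_e"):
            if len(getattr(self, name)) != T:
                raise ValueError(f"{name} must have one value per trait ({T})")
        for name in ("sigma2_g", "sigma2_ge", "sigma2_e"):
            if any(v < 0 for v in getattr(self, name)):
                raise ValueError(f"{name} must be nonnegative")
        R = np.asarray(self.trait_genetic_correlation, dtype=float)
        if R.shape != (T, T) or not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
            raise ValueError("trait_genetic_correlation must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(R).min() <= 0:
            raise ValueError("trait_genetic_correlation must be positive definite")

    @property
    def n_traits(self) -> int:
        return len(self.trait_baselines)

    @property
    def trait_names(self) -> list[str]:
        return [f"trait{t + 1}" for t in range(self.n_traits)]

    @property
    def line_ids(self) -> list[str]:
        return [f"L{j + 1:03d}" for j in range(self.n_lines)]

    @property
    def env_ids(self) -> list[str]:
        return [f"E{i + 1}" for i in range(self.n_envs)]

    @classmethod
    def paper_scale(cls, **overrides) -> "SimulationConfig":
        """Full-design configuration: 270 lines, 14,163 markers, 43 environments."""
        kw = dict(n_lines=270, n_markers=14163, n_envs=43, lines_per_env_range=(57, 193))
        kw.update(overrides)
        return cls(**kw)


@dataclass
class TrueEffects:
    """Generating effects, kept for recovery tests.

    ``interaction_effects[i]`` is the (J x T) matrix of within-environment
    genomic deviations for environment i (defined for every line, observed
    or not).
    """

    env_effects: np.ndarray  # (I, T)
    genomic_effects: np.ndarray  # (J, T)
    interaction_effects: np.ndarray  # (I, J, T)
    line_ids: list[str]
    env_ids: list[str]
    trait_names: list[str]

    def to_csv(self, path) -> None:
        rows = []
        I, J, T = self.interaction_effects.shape
        for t, trait in enumerate(self.trait_names):
            for i, env in enumerate(self.env_ids):
                rows.append({"effect": "env", "trait": trait, "environment": env,
                             "line": "", "value": self.env_effects[i, t]})
            for j, line in enumerate(self.line_ids):
                rows.append({"effect": "genomic", "trait": trait, "environment": "",
                             "line": line, "value": self.genomic_effects[j, t]})
            for i, env in enumerate(self.env_ids):
                for j, line in enumerate(self.line_ids):
                    rows.append({"effect": "interaction", "trait": trait,
                                 "environment": env, "line": line,
                                 "value": self.interaction_effects[i, j, t]})
        pd.DataFrame(rows).to_csv(path, index=False)


def simulate_markers(config: SimulationConfig) -> MarkerMatrix:
    """Draw independent biallelic SNPs at Hardy-Weinberg dosages.

    Per-marker allele frequencies are uniform in ``maf_range``; genotypes are
    Binomial(2, f); missingness is Bernoulli(``marker_missing_rate``)
    independent of genotype.
    """
    if config.n_lines < 2 or config.n_markers < 1:
        raise ValueError("need at least 2 lines and 1 marker")
    rng = np.random.default_rng(config.seed)
    freqs = rng.uniform(*config.maf_range, size=config.n_markers)
    dosages = rng.binomial(2, freqs[None, :], size=(config.n_lines, config.n_markers)).astype(float)
    if config.marker_missing_rate > 0:
        miss = rng.random((config.n_lines, config.n_markers)) < config.marker_missing_rate
        dosages[miss] = np.nan
    marker_ids = [f"M{k + 1:05d}" for k in range(config.n_markers)]
    return MarkerMatrix(dosages, config.line_ids, marker_ids)


def make_incomplete_design(config: SimulationConfig, max_tries: int = 1000) -> list[tuple[str, str]]:
    """Observed (line, environment) cells of an incomplete trial.

    Each environment observes a uniformly drawn number of distinct lines in
    ``lines_per_env_range`` (sampled without replacement).  The design is
    redrawn until every line is observed in at least one environment.
    """
    rng = np.random.default_rng(config.seed + 1)
    lo, hi = config.lines_per_env_range
    lines = config.line_ids
    envs = config.env_ids
    for _ in range(max_tries):
        cells: list[tuple[str, str]] = []
        seen: set[str] = set()
        for env in envs:
            n_i = int(rng.integers(lo, hi + 1))
            chosen = rng.choice(config.n_lines, size=n_i, replace=False)
            for j in chosen:
                cells.append((lines[j], env))
                seen.add(lines[j])
        if len(seen) == config.n_lines:
            return cells
    raise ValueError(
        f"could not cover all {config.n_lines} lines in {max_tries} draws; "
        f"lines_per_env_range {config.lines_per_env_range} too narrow for "
        f"{config.n_envs} environments"
    )


def simulate_phenotypes(
    design: list[tuple[str, str]], grm: GRM, config: SimulationConfig
) -> tuple[pd.DataFrame, TrueEffects]:
    """Phenotypes for the observed cells, plus the generating effects.

    Returns a long-format table with columns ``line, environment, trait,
    value`` and the :class:`TrueEffects` used to generate it.
    """
    rng = np.random.default_rng(config.seed + 2)
    J, I, T = config.n_lines, config.n_envs, config.n_traits
    if grm.line_ids != config.line_ids:
        raise ValueError("GRM line ordering does not match the configuration")
    # jittered Cholesky doubles as the PSD check: a matrix that fails the
    # full jitter ladder is not a valid relationship matrix
    from .genotypes import cholesky_factor

    try:
        L = cholesky_factor(grm).lower_t  # lower triangular, L L^T ~= G
    except ValueError as exc:
        raise ValueError("GRM is not positive semi-definite") from exc

    env_effects = rng.normal(0.0, np.asarray(config.env_effect_spread), size=(I, T))

    # genomic effects: vec covariance Sigma_T (x) G, Sigma_T from per-trait
    # variances and the genetic correlation matrix
    R = np.asarray(config.trait_genetic_correlation, dtype=float)
    sd_g = np.sqrt(np.asarray(config.sigma2_g))
    Sigma_T = sd_g[:, None] * R * sd_g[None, :]
    w, V = np.linalg.eigh(Sigma_T)
    L_T = V * np.sqrt(np.clip(w, 0.0, None))  # PSD square root; exact zeros stay zero
    genomic = L @ rng.standard_normal((J, T)) @ L_T.T

    # interaction: independent across environments and traits, covariance
    # sigma2_ge[t] * G within each environment
    sd_ge = np.sqrt(np.asarray(config.sigma2_ge))
    interaction = np.einsum("jk,ikt->ijt", L, rng.standard_normal((I, J, T))) * sd_ge[None, None, :]

    line_index = {l: j for j, l in enumerate(config.line_ids)}
    env_index = {e: i for i, e in enumerate(config.env_ids)}
    baselines = np.asarray(config.trait_baselines)
    sd_e = np.sqrt(np.asarray(config.sigma2_e))

    rows = []
    for line, env in design:
        j, i = line_index[line], env_index[env]
        resid = rng.normal(0.0, sd_e)
        y = baselines + env_effects[i] + genomic[j] + interaction[i, j] + resid
        for t, trait in enumerate(config.trait_names):
            rows.append({"line": line, "environment": env, "trait": trait, "value": y[t]})
    pheno = pd.DataFrame(rows)
    effects = TrueEffects(
        env_effects, genomic, interaction, config.line_ids, config.env_ids, config.trait_names
    )
    return pheno, effects
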