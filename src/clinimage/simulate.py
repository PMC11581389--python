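"""Synthetic breast-cancer cohort generator.

The study cohort is private, so downstream stages are exercised on simulated
cohorts that emulate its published marginal summaries: continuous features are
drawn from a piecewise-linear quantile function interpolating the printed
median and quartiles (clipped to a clinically plausible domain), categorical
features from the printed level frequencies. A class-conditional signal is a
controllable knob, not an emulated quantity: the real class-conditional
distributions were never characterised.

Two signal models are provided:

* ``simulate_cohort`` applies a per-feature ``effect_size`` to positive-class
  records — an IQR-shift for continuous features and an additive
  level-probability tilt for categorical ones (infeasible tilts raise).
* ``simulate_separable_cohort`` plants a known informative feature subset with
  shift ``delta``, using exponential tilting for categorical features so
  arbitrarily large deltas stay well-defined; it returns the ground-truth set
  for recovery experiments.

Same seed implies byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import ClinicalCohort
from .schema import FeatureSchema, default_schema

__all__ = [
    "ContinuousMarginal",
    "CategoricalMarginal",
    "SimulationConfig",
    "simulate_cohort",
    "simulate_separable_cohort",
    "default_marginals",
    "ConfigError",
]


class ConfigError(ValueError):
    """Invalid simulation configuration (e.g. infeasible probability tilt)."""


@dataclass(frozen=True)
class ContinuousMarginal:
    """Continuous feature summarised by median/quartiles on a bounded domain."""

    median: float
    q1: float
    q3: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo <= self.q1 <= self.median <= self.q3 <= self.hi:
            raise ConfigError("quantiles must be ordered lo<=q1<=median<=q3<=hi")

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    def quantile(self, u: np.ndarray, shift: float = 0.0) -> np.ndarray:
        """Piecewise-linear inverse CDF through (0,lo),(.25,q1),(.5,med),(.75,q3),(1,hi).

        ``shift`` translates the whole curve (in raw units) and re-clips to the
        domain, which is how a class-conditional location shift is applied.
        """
        knots_u = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        knots_x = np.array([self.lo, self.q1, self.median, self.q3, self.hi]) + shift
        return np.clip(np.interp(u, knots_u, knots_x), self.lo, self.hi)


@dataclass(frozen=True)
class CategoricalMarginal:
    """Categorical feature with level probabilities (catalogue order)."""

    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.probs)
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ConfigError("level probabilities must be non-negative and sum to 1")

    def tilted(self, tilt: float) -> "CategoricalMarginal":
        """Additive tilt moving probability mass toward higher levels.

        The tilt direction is a zero-sum ramp over level indices scaled so
        ``tilt`` is the total mass moved; any probability leaving [0, 1]
        raises ``ConfigError``.
        """
        if tilt == 0.0:
            return self
        k = len(self.probs)
        ramp = np.arange(k) - (k - 1) / 2.0
        direction = ramp / np.abs(ramp).sum()  # sums to 0, |.|-norm 1
        p = np.asarray(self.probs) + tilt * direction
        if (p < -1e-12).any() or (p > 1 + 1e-12).any():
            raise ConfigError(f"tilt {tilt} drives a level probability outside [0, 1]")
        p = np.clip(p, 0.0, 1.0)
        return CategoricalMarginal(tuple(p / p.sum()))

    def exp_tilted(self, delta: float) -> "CategoricalMarginal":
        """Exponential tilt: p_k proportional to p_k * exp(delta * z_k), with z the
        standardised level index. Valid for any real delta."""
        k = len(self.probs)
        z = (np.arange(k) - (k - 1) / 2.0) / max(k - 1, 1)
        w = np.asarray(self.probs) * np.exp(delta * z)
        return CategoricalMarginal(tuple(w / w.sum()))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.choice(len(self.probs), size=n, p=np.asarray(self.probs))


Marginal = ContinuousMarginal | CategoricalMarginal


def _cat(*counts: float) -> CategoricalMarginal:
    """Level probabilities from published absolute counts (NA excluded)."""
    c = np.asarray(counts, dtype=float)
    return CategoricalMarginal(tuple(c / c.sum()))


def default_marginals() -> dict[str, Marginal]:
    """Published cohort marginals (696 patients; NA counts excluded from
    categorical denominators; continuous domains are package choices)."""
    return {
        "age": ContinuousMarginal(52, 45, 62, lo=25, hi=92),
        "previous_tumors": _cat(678, 18),
        "breast": _cat(348, 346),
        "histological_type": _cat(587, 56, 53),
        "intraductal_component": _cat(512, 116, 17, 16, 24),
        "multifocality": _cat(572, 124),
        "angioinvasion": _cat(441, 130, 41, 84),
        "er": ContinuousMarginal(60, 1, 90, lo=0, hi=100),
        "pgr": ContinuousMarginal(25, 0, 73, lo=0, hi=100),
        "ki67": ContinuousMarginal(20, 10, 39, lo=0, hi=100),
        "her2_neu_score": _cat(193, 155, 90, 99),
        "her2": _cat(445, 122),
        "grading": _cat(64, 309, 300),
        "diameter": _cat(23, 64, 286, 252, 16, 31),
        "lymph_node_status": _cat(361, 243, 53, 32),
        "slnb": _cat(537, 98, 48),
        "alnd": _cat(95, 587),
        "eradicated_lymph_nodes": ContinuousMarginal(18, 12, 24, lo=0, hi=45),
        "metastatic_lymph_nodes": ContinuousMarginal(0, 0, 2, lo=0, hi=30),
        "surgery": _cat(268, 428),
        "chemotherapy": _cat(227, 467),
        "chemotherapy_scheme": _cat(227, 119, 153, 3, 112, 76),
        "chemotherapy_completion": _cat(444, 242),
        "trastuzumab": _cat(600, 96),
        "trastuzumab_completion": _cat(84, 610),
        "hormone_therapy": _cat(178, 512),
        "hormone_therapy_scheme": _cat(178, 27, 4, 109, 239, 36, 28, 63),
        "hormone_therapy_completion": _cat(387, 286),
    }


@dataclass
class SimulationConfig:
    """Cohort simulation settings.

    ``n_per_class`` is (positives, negatives); defaults give the 5-year cohort
    prevalence (168 IDE / 528 controls). ``effect_size`` maps feature name to a
    class-conditional shift: IQR units for continuous features, total tilted
    probability mass for categorical ones. ``missing_rate`` places missing
    cells completely at random.
    """

    n_per_class: tuple[int, int] = (168, 528)
    marginals: dict[str, Marginal] = field(default_factory=default_marginals)
    effect_size: dict[str, float] = field(default_factory=dict)
    missing_rate: float = 0.0
    seed: int = 0
    horizon: str = "5y"
    schema: FeatureSchema = field(default_factory=default_schema)

    def __post_init__(self) -> None:
        if min(self.n_per_class) < 1:
            raise ConfigError("n_per_class entries must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must lie in [0, 1)")
        missing = [n for n in self.schema.names if n not in self.marginals]
        if missing:
            raise ConfigError(f"no marginal for features: {missing}")
        unknown = [n for n in self.effect_size if n not in self.schema.names]
        if unknown:
            raise ConfigError(f"effect_size names unknown features: {unknown}")


def _draw_feature(
    rng: np.random.Generator,
    marginal: Marginal,
    n: int,
    shift: float,
    exponential_tilt: bool,
) -> np.ndarray:
    if isinstance(marginal, ContinuousMarginal):
        return marginal.quantile(rng.random(n), shift=shift * marginal.iqr)
    if shift == 0.0:
        return marginal.sample(rng, n).astype(float)
    tilted = marginal.exp_tilted(shift) if exponential_tilt else marginal.tilted(shift)
    return tilted.sample(rng, n).astype(float)


def _simulate(
    config: SimulationConfig, exponential_tilt: bool
) -> ClinicalCohort:
    rng = np.random.default_rng(config.seed)
    n_pos, n_neg = config.n_per_class
    n = n_pos + n_neg
    labels = np.concatenate([np.ones(n_pos, int), np.zeros(n_neg, int)])
    values = np.zeros((n, config.schema.n_features))
    for j, name in enumerate(config.schema.names):
        marginal = config.marginals[name]
        shift = config.effect_size.get(name, 0.0)
        # positives first, then negatives (unshifted)
        values[:n_pos, j] = _draw_feature(rng, marginal, n_pos, shift, exponential_tilt)
        values[n_pos:, j] = _draw_feature(rng, marginal, n_neg, 0.0, exponential_tilt)
    mask = (
        rng.random(values.shape) < config.missing_rate
        if config.missing_rate > 0
        else np.zeros_like(values, dtype=bool)
    )
    return ClinicalCohort(
        values=values,
        labels=labels,
        missing_mask=mask,
        horizon=config.horizon,
        schema=config.schema,
    )


def simulate_cohort(config: SimulationConfig) -> ClinicalCohort:
    """Draw a cohort from the configured marginals with optional class signal."""
    return _simulate(config, exponential_tilt=False)


def simulate_separable_cohort(
    n_per_class: tuple[int, int],
    n_informative: int,
    delta: float,
    seed: int = 0,
    missing_rate: float = 0.0,
    horizon: str = "5y",
) -> tuple[ClinicalCohort, list[str]]:
    """Plant a class signal of size ``delta`` on a known feature subset.

    Continuous features come first in the informative set (delta is an IQR
    shift there, so rank-based recovery is calibrated); remaining slots take
    categorical features under exponential tilting. Returns the cohort and the
    ground-truth informative feature names.
    """
    schema = default_schema()
    if not 1 <= n_informative <= schema.n_features:
        raise ConfigError("n_informative must lie in [1, 28]")
    marginals = default_marginals()
    continuous = [n for n in schema.names
                  if isinstance(marginals[n], ContinuousMarginal)]
    categorical = [n for n in schema.names if n not in continuous]
    informative = (continuous + categorical)[:n_informative]
    config = SimulationConfig(
        n_per_class=n_per_class,
        effect_size={name: delta for name in informative},
        missing_rate=missing_rate,
        seed=seed,
        horizon=horizon,
    )
    return _simulate(config, exponential_tilt=True), informative
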