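"""Study design and ground-truth parameter containers.

The design mirrors a mesocosm exposure experiment: three treatments
(control, low, high), four replicate mesocosms per treatment, twelve males
per mesocosm. Two behaviours (activity, refuge use) are assayed on three
trials each; three life-history traits (body condition, coloration,
gonopodium length) and three ejaculate traits (sperm vitality, velocity,
count) are measured once per individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, ValidationError

#: Canonical trait roster, in model order.
DEFAULT_TRAITS: tuple[str, ...] = (
    "activity",
    "refuge_use",
    "body_condition",
    "coloration",
    "gonopodium_length",
    "sperm_vitality",
    "sperm_velocity",
    "sperm_count",
)

#: Flags marking the repeatedly measured behaviours.
DEFAULT_REPEATED: tuple[bool, ...] = (True, True) + (False,) * 6

DEFAULT_TREATMENTS: tuple[str, ...] = ("control", "low", "high")

#: Residual SD pinned for once-measured traits (variance 0.01).
FIXED_RESIDUAL_SD: float = 0.1


def _as_1d(x, n, name):
    arr = np.asarray(x, dtype=float)
    if arr.shape != (n,):
        raise ConfigError(f"{name} must have shape ({n},), got {arr.shape}")
    return arr


def is_psd(mat: np.ndarray, tol: float = 1e-8) -> bool:
    """True if ``mat`` is symmetric positive semi-definite within ``tol``."""
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        return False
    if not np.allclose(mat, mat.T, atol=1e-10):
        return False
    eigvals = np.linalg.eigvalsh(mat)
    return bool(eigvals.min() >= -tol * max(1.0, abs(eigvals.max())))


@dataclass(frozen=True)
class DesignConfig:
    """Sampling design of the experiment.

    Defaults reproduce the study layout: 3 treatments x 4 mesocosms x 12
    males = 144 individuals, behaviours on 3 trials each.
    """

    n_treatments: int = 3
    n_mesocosms_per_treatment: int = 4
    n_individuals_per_mesocosm: int = 12
    n_trials_behaviour: int = 3
    trait_names: tuple[str, ...] = DEFAULT_TRAITS
    repeated_flags: tuple[bool, ...] = DEFAULT_REPEATED
    seed: int = 0

    def __post_init__(self):
        for name in (
            "n_treatments",
            "n_mesocosms_per_treatment",
            "n_individuals_per_mesocosm",
            "n_trials_behaviour",
        ):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if len(self.trait_names) != len(self.repeated_flags):
            raise ConfigError("trait_names and repeated_flags lengths differ")
        if len(set(self.trait_names)) != len(self.trait_names):
            raise ConfigError("trait names must be unique")
        object.__setattr__(self, "trait_names", tuple(self.trait_names))
        object.__setattr__(self, "repeated_flags", tuple(bool(f) for f in self.repeated_flags))

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    @property
    def n_individuals(self) -> int:
        return (
            self.n_treatments
            * self.n_mesocosms_per_treatment
            * self.n_individuals_per_mesocosm
        )

    @property
    def treatment_names(self) -> tuple[str, ...]:
        if self.n_treatments == len(DEFAULT_TREATMENTS):
            return DEFAULT_TREATMENTS
        return tuple(f"treatment_{i}" for i in range(self.n_treatments))

    @property
    def repeated_traits(self) -> tuple[str, ...]:
        return tuple(t for t, f in zip(self.trait_names, self.repeated_flags) if f)

    @property
    def n_rows(self) -> int:
        """Total long-table rows: repeated traits get n_trials occasions, others one."""
        n_rep = sum(self.repeated_flags)
        n_single = self.n_traits - n_rep
        return self.n_individuals * (n_rep * self.n_trials_behaviour + n_single)


@dataclass
class ParameterSet:
    """Ground-truth (or drawn) values of every model parameter.

    All trait values are on the standardized (z-score) scale of the fitted
    model.  ``beta_treat`` uses reference coding: one row per non-reference
    treatment.  ``Sigma_B`` holds one between-individual covariance matrix
    per treatment; ``sigma_W`` one within-individual SD per treatment and
    behaviour.
    """

    mu: np.ndarray                 # (n_traits,)
    beta_treat: np.ndarray         # (n_treatments - 1, n_traits)
    gamma_trial: np.ndarray        # (n_behaviours,)
    sigma_mesocosm: np.ndarray     # (n_traits,)
    Sigma_B: np.ndarray            # (n_treatments, n_traits, n_traits)
    sigma_W: np.ndarray            # (n_treatments, n_behaviours)
    sigma_fixed: float = FIXED_RESIDUAL_SD

    def validate(self, config: DesignConfig) -> None:
        k = config.n_traits
        t = config.n_treatments
        b = sum(config.repeated_flags)
        self.mu = _as_1d(self.mu, k, "mu")
        self.gamma_trial = _as_1d(self.gamma_trial, b, "gamma_trial")
        self.sigma_mesocosm = _as_1d(self.sigma_mesocosm, k, "sigma_mesocosm")
        self.beta_treat = np.asarray(self.beta_treat, dtype=float)
        if self.beta_treat.shape != (t - 1, k):
            raise ConfigError(
                f"beta_treat must have shape ({t - 1}, {k}), got {self.beta_treat.shape}"
            )
        self.Sigma_B = np.asarray(self.Sigma_B, dtype=float)
        if self.Sigma_B.shape != (t, k, k):
            raise ConfigError(
                f"Sigma_B must have shape ({t}, {k}, {k}), got {self.Sigma_B.shape}"
            )
        self.sigma_W = np.asarray(self.sigma_W, dtype=float)
        if self.sigma_W.shape != (t, b):
            raise ConfigError(
                f"sigma_W must have shape ({t}, {b}), got {self.sigma_W.shape}"
            )
        if (self.sigma_mesocosm < 0).any() or (self.sigma_W < 0).any() or self.sigma_fixed < 0:
            raise ValidationError("all standard deviations must be >= 0")
        for i, mat in enumerate(self.Sigma_B):
            if not is_psd(mat):
                raise ValidationError(
                    f"Sigma_B for treatment '{config.treatment_names[i]}' "
                    "is not symmetric positive semi-definite"
                )

    def to_dict(self) -> dict:
        return {
            "mu": self.mu.tolist(),
            "beta_treat": self.beta_treat.tolist(),
            "gamma_trial": self.gamma_trial.tolist(),
            "sigma_mesocosm": self.sigma_mesocosm.tolist(),
            "Sigma_B": self.Sigma_B.tolist(),
            "sigma_W": self.sigma_W.tolist(),
            "sigma_fixed": float(self.sigma_fixed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        return cls(
            mu=np.asarray(d["mu"], dtype=float),
            beta_treat=np.asarray(d["beta_treat"], dtype=float),
            gamma_trial=np.asarray(d["gamma_trial"], dtype=float),
            sigma_mesocosm=np.asarray(d["sigma_mesocosm"], dtype=float),
            Sigma_B=np.asarray(d["Sigma_B"], dtype=float),
            sigma_W=np.asarray(d["sigma_W"], dtype=float),
            sigma_fixed=float(d.get("sigma_fixed", FIXED_RESIDUAL_SD)),
        )
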