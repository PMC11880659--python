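"""Derived phenotypes from raw measurements.

Covers the pre-modelling steps: scaled mass index as a body-condition
proxy (Peig & Green's standardized-major-axis formulation), proportional
body coloration, tracked-count-weighted sperm velocity, haemocytometer
sperm counts and live/dead vitality, and per-trait z-standardization of
the long table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateDataError, DomainError


@dataclass(frozen=True)
class MorphometricRecord:
    """Raw morphometrics for one male (mass g, lengths mm, areas in px² or mm²)."""

    individual_id: str
    body_mass: float
    standard_length: float
    gonopodium_length: float
    body_area: float
    orange_area: float
    black_area: float

    def __post_init__(self):
        for name in ("body_mass", "standard_length", "gonopodium_length", "body_area"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0")
        if self.orange_area < 0 or self.black_area < 0:
            raise DomainError("colour areas must be >= 0")
        if self.orange_area + self.black_area > self.body_area * (1 + 1e-9):
            raise DomainError("orange_area + black_area exceeds body_area")


@dataclass(frozen=True)
class EjaculateRecord:
    """Raw ejaculate measurements for one male.

    ``vcl_samples``: (mean curvilinear velocity in um/s, n sperm tracked)
    per recorded sample.  ``live_counts``/``dead_counts``: haemocytometer
    subsample counts (at most three subsamples).  ``dilution_factor`` and
    ``chamber_volume`` (uL) scale subsample counts to a per-ejaculate total.
    """

    individual_id: str
    vcl_samples: tuple[tuple[float, int], ...]
    live_counts: tuple[int, ...]
    dead_counts: tuple[int, ...]
    dilution_factor: float | None = None
    chamber_volume: float = 1.0

    def __post_init__(self):
        if len(self.live_counts) != len(self.dead_counts):
            raise DomainError("live and dead subsample counts must pair up")
        if len(self.live_counts) > 3:
            raise DomainError("at most three counting subsamples are supported")
        if any(c < 0 for c in self.live_counts + self.dead_counts):
            raise DomainError("counts must be >= 0")
        if any(n < 1 for _, n in self.vcl_samples):
            raise DomainError("every velocity sample must track at least one sperm")


@dataclass(frozen=True)
class SmiParams:
    """Scaled-mass-index parameters: allometric exponent and reference length (mm)."""

    beta_sma: float
    reference_length: float

    def __post_init__(self):
        if self.reference_length <= 0:
            raise DomainError("reference_length must be > 0")


def fit_sma_slope(masses, lengths) -> float:
    """Standardized-major-axis slope of ln(mass) on ln(length).

    Computed as the OLS slope divided by the Pearson correlation on the
    log-log scale.  This is the allometric exponent used by the
    scaled-mass-index body-condition proxy.
    """
    m = np.asarray(masses, dtype=float)
    l = np.asarray(lengths, dtype=float)
    if m.shape != l.shape or m.ndim != 1 or m.size < 3:
        raise DomainError("need >= 3 paired mass/length values")
    if (m <= 0).any() or (l <= 0).any():
        raise DomainError("masses and lengths must be > 0")
    x, y = np.log(l), np.log(m)
    if np.ptp(x) == 0:
        raise DegenerateDataError("all lengths equal: SMA slope undefined")
    sxx = np.sum((x - x.mean()) ** 2)
    syy = np.sum((y - y.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    if syy == 0 or sxy == 0:
        raise DegenerateDataError("mass and length are uncorrelated: SMA slope undefined")
    b_ols = sxy / sxx
    r = sxy / np.sqrt(sxx * syy)
    return float(b_ols / r)


def scaled_mass_index(mass: float, length: float, params: SmiParams) -> float:
    """Body condition M * (L0 / L)**beta — mass rescaled to the reference length."""
    if mass <= 0 or length <= 0:
        raise DomainError("mass and length must be > 0")
    return float(mass * (params.reference_length / length) ** params.beta_sma)


def coloration_proportion(record: MorphometricRecord) -> float:
    """(orange + black area) / body area, in [0, 1]."""
    if record.body_area <= 0:
        raise DomainError("body_area must be > 0")
    return float(
        min((record.orange_area + record.black_area) / record.body_area, 1.0)
    )


def sperm_vitality(record: EjaculateRecord) -> float:
    """Live fraction: sum(live) / (sum(live) + sum(dead)) over subsamples."""
    live = sum(record.live_counts)
    dead = sum(record.dead_counts)
    if live + dead == 0:
        raise DegenerateDataError("no sperm counted: vitality undefined")
    return live / (live + dead)


def sperm_count(record: EjaculateRecord) -> float:
    """Estimated total sperm per ejaculate.

    Mean subsample total (live + dead) scaled by the dilution factor and
    the chamber-volume factor.  The chamber geometry is an explicit
    parameter because extender volumes varied between males.
    """
    if not record.live_counts:
        raise DomainError("at least one counting subsample is required")
    if record.dilution_factor is None:
        raise ConfigError("dilution_factor is required to estimate total sperm count")
    totals = [lv + dd for lv, dd in zip(record.live_counts, record.dead_counts)]
    return float(np.mean(totals) * record.dilution_factor * record.chamber_volume)


def mean_vcl(record: EjaculateRecord) -> float:
    """Tracked-count-weighted mean curvilinear velocity across samples (um/s)."""
    if not record.vcl_samples:
        raise DomainError("at least one velocity sample is required")
    v = np.array([s[0] for s in record.vcl_samples], dtype=float)
    n = np.array([s[1] for s in record.vcl_samples], dtype=float)
    if n.sum() <= 0:
        raise DegenerateDataError("all tracked counts zero: velocity undefined")
    return float(np.average(v, weights=n))


@dataclass
class StandardizationParams:
    """Per-trait means/SDs enabling exact back-transformation."""

    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    occasion_offset: int = 1  # files are 1-based; the model uses trial 1 = 0

    def to_dict(self) -> dict:
        return {
            "means": dict(self.means),
            "sds": dict(self.sds),
            "occasion_offset": self.occasion_offset,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizationParams":
        return cls(dict(d["means"]), dict(d["sds"]), int(d["occasion_offset"]))


def standardize(table: pd.DataFrame) -> tuple[pd.DataFrame, StandardizationParams]:
    """Z-score each trait (pooled over treatments and trials); left-centre occasions.

    Returns the transformed copy and the parameters needed to undo it.
    Occasions 1,2,3 become 0,1,2 so the model intercept sits at trial 1.
    """
    params = StandardizationParams()
    out = table.copy()
    offset = int(out["occasion"].min())
    params.occasion_offset = offset
    out["occasion"] = out["occasion"].astype(int) - offset
    for trait, grp in table.groupby("trait", sort=False):
        vals = grp["value"].to_numpy(dtype=float)
        if np.unique(vals).size < 2:
            raise DegenerateDataError(f"trait {trait!r} has zero variance; cannot standardize")
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        params.means[trait] = mean
        params.sds[trait] = sd
        mask = out["trait"] == trait
        out.loc[mask, "value"] = (out.loc[mask, "value"] - mean) / sd
    return out, params


def unstandardize(table: pd.DataFrame, params: StandardizationParams) -> pd.DataFrame:
    """Exact inverse of :func:`standardize`."""
    out = table.copy()
    out["occasion"] = out["occasion"].astype(int) + params.occasion_offset
    for trait, mean in params.means.items():
        mask = out["trait"] == trait
        out.loc[mask, "value"] = out.loc[mask, "value"] * params.sds[trait] + mean
    return out


def derive_trait_table(
    morphometrics: pd.DataFrame,
    ejaculates: pd.DataFrame | None = None,
    smi_params: SmiParams | None = None,
) -> pd.DataFrame:
    """Wide per-individual table of the once-measured derived traits.

    If ``smi_params`` is omitted the SMA exponent is fitted to the supplied
    morphometrics and the reference length set to their mean standard
    length (the study's own procedure).
    """
    if smi_params is None:
        smi_params = SmiParams(
            beta_sma=fit_sma_slope(
                morphometrics["body_mass"], morphometrics["standard_length"]
            ),
            reference_length=float(morphometrics["standard_length"].mean()),
        )
    rows = []
    ej_by_id = {}
    if ejaculates is not None:
        for _, r in ejaculates.iterrows():
            ej_by_id[r["individual_id"]] = ejaculate_record_from_row(r)
    for _, r in morphometrics.iterrows():
        rec = MorphometricRecord(
            individual_id=r["individual_id"],
            body_mass=r["body_mass"],
            standard_length=r["standard_length"],
            gonopodium_length=r["gonopodium_length"],
            body_area=r["body_area"],
            orange_area=r["orange_area"],
            black_area=r["black_area"],
        )
        row = {
            "individual_id": rec.individual_id,
            "body_condition": scaled_mass_index(
                rec.body_mass, rec.standard_length, smi_params
            ),
            "coloration": coloration_proportion(rec),
            "gonopodium_length": rec.gonopodium_length,
        }
        ej = ej_by_id.get(rec.individual_id)
        if ej is not None:
            row["sperm_vitality"] = sperm_vitality(ej)
            row["sperm_velocity"] = mean_vcl(ej)
            row["sperm_count"] = sperm_count(ej)
        rows.append(row)
    return pd.DataFrame(rows)


def ejaculate_record_from_row(row) -> EjaculateRecord:
    """Build an :class:`EjaculateRecord` from one wide-table row.

    Expects columns ``vcl_<s>``/``n_tracked_<s>`` for velocity samples and
    ``live_<s>``/``dead_<s>`` for counting subsamples, plus
    ``dilution_factor`` and ``chamber_volume``.
    """
    vcl = []
    s = 1
    while f"vcl_{s}" in row and pd.notna(row.get(f"vcl_{s}")):
        vcl.append((float(row[f"vcl_{s}"]), int(row[f"n_tracked_{s}"])))
        s += 1
    live, dead = [], []
    s = 1
    while f"live_{s}" in row and pd.notna(row.get(f"live_{s}")):
        live.append(int(row[f"live_{s}"]))
        dead.append(int(row[f"dead_{s}"]))
        s += 1
    return EjaculateRecord(
        individual_id=str(row["individual_id"]),
        vcl_samples=tuple(vcl),
        live_counts=tuple(live),
        dead_counts=tuple(dead),
        dilution_factor=(
            float(row["dilution_factor"]) if pd.notna(row.get("dilution_factor")) else None
        ),
        chamber_volume=float(row.get("chamber_volume", 1.0)),
    )
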