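"""Synthetic labeled datasets with the per-class statistics of the real study.

Reference chemistry is drawn per class from truncated Gaussians on the
published per-class [min, max] supports, with the published class SD as the
parent scale.  Truncating N(mean, SD) to an asymmetric window shifts its
mean, so the parent location is solved numerically to make the truncated
mean equal the published class mean exactly; the resulting truncated SD is
at most the published one.  (Several published SDs are unattainable outright:
class-85 TA asks for SD 0.11 on a 0.28-wide support whose uniform limit is
0.081, so no unimodal distribution there can match both the range and the
SD.)

Spectra come from a linear forward model: each parameter contributes fixed
Gaussian absorbance bands scaled by its value, on top of a random additive
baseline (offset + slope), a random multiplicative scatter factor, and white
noise.  The model is deliberately linear in the four parameters so that
recovery by multivariate calibration is an identifiability check, not a
physics claim.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from mangonir.data import (
    LabeledDataset,
    MATURITY_CLASSES,
    PARAMETERS,
    ReferenceRecord,
    Spectrum,
    WavelengthGrid,
)

# Published per-class summary statistics: class -> parameter -> (min, max, mean, SD)
CLASS_SUMMARY: dict[int, dict[str, tuple[float, float, float, float]]] = {
    80: {
        "TA": (0.8, 2.23, 1.11, 0.31),
        "SSC": (5.9, 9.7, 8.456, 0.82),
        "firmness": (3.6, 4.4, 3.76, 0.19),
        "starch": (7.23, 10.3, 7.58, 0.75),
    },
    85: {
        "TA": (0.53, 0.81, 0.67, 0.11),
        "SSC": (9.5, 15.0, 11.26, 1.16),
        "firmness": (3.0, 3.6, 3.47, 0.09),
        "starch": (5.3, 7.19, 6.52, 0.65),
    },
    90: {
        "TA": (0.44, 0.56, 0.49, 0.03),
        "SSC": (12.3, 19.2, 16.19, 2.31),
        "firmness": (2.9, 3.8, 3.12, 0.20),
        "starch": (3.96, 4.97, 4.49, 0.21),
    },
    95: {
        "TA": (0.36, 0.46, 0.42, 0.03),
        "SSC": (18.0, 19.7, 19.15, 0.51),
        "firmness": (1.8, 2.9, 2.13, 0.32),
        "starch": (2.01, 3.26, 2.31, 0.45),
    },
    100: {
        "TA": (0.19, 0.38, 0.33, 0.05),
        "SSC": (19.5, 21.9, 20.21, 0.65),
        "firmness": (0.6, 1.9, 1.34, 0.39),
        "starch": (0.89, 1.94, 1.59, 0.36),
    },
}

#: Real per-class scan counts after removing the four invalid acquisitions.
CLASS_COUNTS: dict[int, int] = {80: 139, 85: 140, 90: 140, 95: 139, 100: 138}


@dataclass(frozen=True)
class ClassParameterModel:
    """Per-class, per-parameter (min, max, mean, SD) driving the sampler."""

    summary: dict[int, dict[str, tuple[float, float, float, float]]] = field(
        default_factory=lambda: CLASS_SUMMARY
    )

    def __post_init__(self) -> None:
        for cls, params in self.summary.items():
            for name, (lo, hi, mean, sd) in params.items():
                if not lo <= mean <= hi:
                    raise ValueError(f"{cls}/{name}: mean outside [min, max]")
                if sd <= 0:
                    raise ValueError(f"{cls}/{name}: SD must be positive")


def _truncnorm_stats(mu: float, sigma: float, lo: float, hi: float):
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
    return float(m), float(np.sqrt(v))


def _solve_mu(sigma: float, lo: float, hi: float, mean: float) -> float:
    f = lambda mu: _truncnorm_stats(mu, sigma, lo, hi)[0] - mean
    step = max(sigma, hi - lo)
    a, b = lo - step, hi + step
    for _ in range(80):
        if f(a) < 0 < f(b):
            break
        step *= 2.0
        a, b = lo - step, hi + step
    return optimize.brentq(f, a, b, xtol=1e-12)


def _match_truncnorm(lo, hi, mean, sd) -> tuple[float, float]:
    """Parent (mu, sigma) of the class truncated Gaussian.

    The parent scale is the published SD; the parent location is solved so
    that the mean of the [lo, hi]-truncated distribution equals the published
    class mean exactly (plain truncation of N(mean, SD) shifts it, e.g.
    class-80 TA would average 1.20 instead of 1.11).
    """
    return _solve_mu(sd, lo, hi, mean), sd


_MATCH_CACHE: dict[tuple[float, float, float, float], tuple[float, float]] = {}


def _matched(cell: tuple[float, float, float, float]) -> tuple[float, float]:
    if cell not in _MATCH_CACHE:
        _MATCH_CACHE[cell] = _match_truncnorm(*cell)
    return _MATCH_CACHE[cell]


def sample_parameters(
    maturity: int,
    n: int,
    model: ClassParameterModel | None = None,
    seed: int = 0,
    sample_prefix: str = "syn",
) -> list[ReferenceRecord]:
    """Draw ``n`` reference records for one maturity class.

    Parameters are drawn independently (the published summary carries no
    covariances); scan locations cycle 1-4 within consecutive synthetic fruit.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    model = model or ClassParameterModel()
    if maturity not in model.summary:
        raise ValueError(f"no summary for class {maturity}")
    rng = np.random.default_rng(seed)
    draws = {}
    for name in PARAMETERS:
        cell = model.summary[maturity][name]
        lo, hi, _, _ = cell
        mu, sigma = _matched(cell)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        draws[name] = stats.truncnorm.rvs(
            a, b, loc=mu, scale=sigma, size=n, random_state=rng
        )
    records = []
    for i in range(n):
        records.append(
            ReferenceRecord(
                sample_id=f"{sample_prefix}-{maturity}-{i // 4:03d}",
                location=i % 4 + 1,
                TA=float(draws["TA"][i]),
                SSC=float(draws["SSC"][i]),
                firmness=float(draws["firmness"][i]),
                starch=float(draws["starch"][i]),
                maturity=maturity,
            )
        )
    return records


# ---------------------------------------------------------------------------
# spectral forward model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectralForwardModel:
    """Linear band model plus baseline, scatter and noise.

    ``bands`` maps parameter -> tuple of (center nm, width nm, weight per
    unit of the parameter).  Band centers sit near real overtone regions
    (water ~1450/1940 nm, sugar/starch C-H and O-H combination bands
    1560-2330 nm) but are an identifiability device, not assigned chemistry.
    """

    grid: WavelengthGrid = field(default_factory=WavelengthGrid.default)
    bands: dict[str, tuple[tuple[float, float, float], ...]] = field(
        default_factory=lambda: {
            "TA": ((1450.0, 50.0, 0.12), (1725.0, 40.0, 0.06)),
            "SSC": ((1940.0, 50.0, 0.008), (2100.0, 60.0, 0.012)),
            "firmness": ((1680.0, 45.0, 0.07), (2270.0, 55.0, 0.04)),
            "starch": ((1560.0, 45.0, 0.03), (2330.0, 60.0, 0.02)),
        }
    )
    offset_range: tuple[float, float] = (0.30, 0.40)
    slope_range: tuple[float, float] = (-0.05, 0.05)
    scatter_range: tuple[float, float] = (0.95, 1.05)
    noise_sd: float = 0.002

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")

    @classmethod
    def noiseless(cls, **kwargs) -> "SpectralForwardModel":
        """Deterministic variant: no noise, baseline or scatter randomness."""
        fm = cls(**kwargs)
        return replace(
            fm,
            offset_range=(0.0, 0.0),
            slope_range=(0.0, 0.0),
            scatter_range=(1.0, 1.0),
            noise_sd=0.0,
        )

    def clean_signal(self, record: ReferenceRecord) -> np.ndarray:
        """Pure band contribution, linear in the four parameter values."""
        wl = self.grid.wavelengths
        signal = np.zeros_like(wl)
        for name in PARAMETERS:
            value = getattr(record, name)
            for center, width, weight in self.bands.get(name, ()):
                signal += weight * value * np.exp(-0.5 * ((wl - center) / width) ** 2)
        return signal


def generate_spectrum(
    record: ReferenceRecord,
    forward_model: SpectralForwardModel | None = None,
    seed: int = 0,
) -> Spectrum:
    """One synthetic absorbance scan for a reference record."""
    fm = forward_model or SpectralForwardModel()
    rng = np.random.default_rng(seed)
    wl = fm.grid.wavelengths
    lam = (wl - wl[0]) / (wl[-1] - wl[0])
    offset = rng.uniform(*fm.offset_range)
    slope = rng.uniform(*fm.slope_range)
    scatter = rng.uniform(*fm.scatter_range)
    values = scatter * (fm.clean_signal(record) + offset + slope * lam)
    if fm.noise_sd > 0:
        values = values + rng.normal(0.0, fm.noise_sd, size=wl.size)
    return Spectrum(sample_id=record.sample_id, location=record.location, values=values)


@dataclass(frozen=True)
class GeneratorConfig:
    """Dataset-level settings: per-class size, seed, invalid-scan injection."""

    n_per_class: int = 35
    seed: int = 0
    invalid_count: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 0 or self.invalid_count < 0:
            raise ValueError("counts must be >= 0")


def generate_dataset(
    config: GeneratorConfig | None = None,
    model: ClassParameterModel | None = None,
    forward_model: SpectralForwardModel | None = None,
    class_counts: dict[int, int] | None = None,
) -> LabeledDataset:
    """Full labeled dataset: records + matched spectra for all five classes.

    ``class_counts`` overrides the uniform ``n_per_class`` (e.g. the real
    study's 139/140/140/139/138).  ``invalid_count`` scans get a NaN injected
    so downstream validity filtering is exercised.
    """
    config = config or GeneratorConfig()
    fm = forward_model or SpectralForwardModel()
    counts = class_counts or dict.fromkeys(MATURITY_CLASSES, config.n_per_class)
    root = np.random.default_rng(config.seed)
    records: list[ReferenceRecord] = []
    spectra: list[Spectrum] = []
    for cls in MATURITY_CLASSES:
        n = counts.get(cls, 0)
        if n == 0:
            continue
        cls_seed = int(root.integers(0, 2**31 - 1))
        recs = sample_parameters(cls, n, model, seed=cls_seed)
        records.extend(recs)
        for i, rec in enumerate(recs):
            spectra.append(generate_spectrum(rec, fm, seed=cls_seed + i + 1))
    if config.invalid_count:
        idx = root.choice(len(spectra), size=config.invalid_count, replace=False)
        for i in idx:
            bad = spectra[i].values.copy()
            bad[int(root.integers(0, bad.size))] = np.nan
            spectra[i] = Spectrum(spectra[i].sample_id, spectra[i].location, bad)
    return LabeledDataset(grid=fm.grid, spectra=spectra, references=records)
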