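"""Spectral transformation operators, pipelines, and combinatorial search.

Twelve operators are available: CLIP, SNV, RNV, LSNV, MSC, EMSC, NORML,
DETREND, BASELINE, SMOOTH, SAVGOL and RESAMPLE.  A pipeline is a subset of
them (at most one instance per operator) applied in a fixed canonical order:

    CLIP -> DETREND -> BASELINE -> SNV -> RNV -> LSNV -> MSC -> EMSC
         -> NORML -> SMOOTH -> SAVGOL -> RESAMPLE

Clipping and baseline removal must precede the scatter-correction statistics;
smoothing/derivatives operate on corrected spectra; Fourier resampling runs
last because it changes the grid.  MSC/EMSC need a reference spectrum: the
mean of the *training* spectra, frozen at fit time so that held-out data never
leak into the correction.

Exhaustive search over an enumerated set of pipelines (any subset of the
operator pool crossed with each operator's parameter grid) scores every
candidate with a caller-supplied evaluator and returns the ranked results.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from mangonir.data import WavelengthGrid

OPERATOR_NAMES: tuple[str, ...] = (
    "CLIP",
    "DETREND",
    "BASELINE",
    "SNV",
    "RNV",
    "LSNV",
    "MSC",
    "EMSC",
    "NORML",
    "SMOOTH",
    "SAVGOL",
    "RESAMPLE",
)

#: Canonical application order (position in OPERATOR_NAMES).
_ORDER = {name: i for i, name in enumerate(OPERATOR_NAMES)}

_MSC_B_TOL = 1e-8


class DegenerateSpectrumError(ValueError):
    """An operator's statistics collapse on this input (e.g. constant scan)."""


class PipelineError(ValueError):
    """Invalid pipeline specification."""


# ---------------------------------------------------------------------------
# operators (x: 1-D absorbance vector)
# ---------------------------------------------------------------------------

def op_snv(x: np.ndarray) -> np.ndarray:
    """Standard normal variate: centre by the mean, scale by the sample SD."""
    x = np.asarray(x, dtype=float)
    sd = np.std(x, ddof=1)
    if sd <= 0:
        raise DegenerateSpectrumError("SNV undefined for a constant spectrum")
    return (x - np.mean(x)) / sd


def op_rnv(x: np.ndarray, iqr: tuple[float, float] = (75.0, 25.0)) -> np.ndarray:
    """Robust normal variate: centre by the median, scale by a percentile range."""
    x = np.asarray(x, dtype=float)
    hi, lo = iqr
    spread = np.percentile(x, hi) - np.percentile(x, lo)
    if spread <= 0:
        raise DegenerateSpectrumError("RNV undefined: zero inter-percentile range")
    return (x - np.median(x)) / spread


def op_lsnv(x: np.ndarray, window: int = 17) -> np.ndarray:
    """Localized SNV: standardize consecutive windows independently.

    The trailing remainder (fewer than ``window`` points) is merged into the
    last full window so every point is standardized exactly once.
    """
    x = np.asarray(x, dtype=float)
    if window < 3 or window % 2 == 0:
        raise PipelineError(f"LSNV window must be odd and >= 3, got {window}")
    if window > x.size:
        raise PipelineError("LSNV window exceeds spectrum length")
    n_windows = max(x.size // window, 1)
    out = np.empty_like(x)
    for w in range(n_windows):
        start = w * window
        stop = (w + 1) * window if w < n_windows - 1 else x.size
        out[start:stop] = op_snv(x[start:stop])
    return out


def _msc_fit(x: np.ndarray, ref: np.ndarray) -> tuple[float, float]:
    A = np.column_stack([np.ones_like(ref), ref])
    (a, b), *_ = np.linalg.lstsq(A, x, rcond=None)
    return float(a), float(b)


def op_msc(x: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Multiplicative scatter correction against a reference (training mean)."""
    x = np.asarray(x, dtype=float)
    ref = np.asarray(ref, dtype=float)
    a, b = _msc_fit(x, ref)
    if abs(b) <= _MSC_B_TOL:
        raise DegenerateSpectrumError("MSC slope ~ 0: spectrum orthogonal to reference")
    return (x - a) / b


def op_emsc(x: np.ndarray, ref: np.ndarray, wavelengths: np.ndarray) -> np.ndarray:
    """Extended MSC: also removes linear and quadratic wavelength terms."""
    x = np.asarray(x, dtype=float)
    ref = np.asarray(ref, dtype=float)
    wl = np.asarray(wavelengths, dtype=float)
    lam = 2 * (wl - wl[0]) / (wl[-1] - wl[0]) - 1  # rescale to [-1, 1]
    A = np.column_stack([np.ones_like(ref), ref, lam, lam**2])
    if np.linalg.matrix_rank(A) < 4:
        raise DegenerateSpectrumError("EMSC design matrix is rank deficient")
    coef, *_ = np.linalg.lstsq(A, x, rcond=None)
    a, b, c, d = coef
    if abs(b) <= _MSC_B_TOL:
        raise DegenerateSpectrumError("EMSC slope ~ 0: no reference component")
    return (x - a - c * lam - d * lam**2) / b


def op_norml(x: np.ndarray) -> np.ndarray:
    """Euclidean normalization to unit L2 norm."""
    x = np.asarray(x, dtype=float)
    norm = np.linalg.norm(x)
    if norm <= 0:
        raise DegenerateSpectrumError("cannot normalize the zero spectrum")
    return x / norm


def op_detrend(x: np.ndarray, wavelengths: np.ndarray, bp=(0,)) -> np.ndarray:
    """Subtract the least-squares straight line over the whole spectrum."""
    if tuple(bp) != (0,):
        raise PipelineError("only single-segment detrending (bp=[0]) is supported")
    x = np.asarray(x, dtype=float)
    wl = np.asarray(wavelengths, dtype=float)
    A = np.column_stack([np.ones_like(wl), wl])
    coef, *_ = np.linalg.lstsq(A, x, rcond=None)
    return x - A @ coef


def op_baseline(x: np.ndarray) -> np.ndarray:
    """Subtract the spectral mean (offset-only baseline removal)."""
    x = np.asarray(x, dtype=float)
    return x - np.mean(x)


def op_clip(
    x: np.ndarray, threshold: float = 10_000.0, substitute: float | None = None
) -> np.ndarray:
    """Replace values above ``threshold`` with ``substitute`` (or the threshold)."""
    x = np.asarray(x, dtype=float).copy()
    fill = threshold if substitute is None else substitute
    x[x > threshold] = fill
    return x


def op_smooth(x: np.ndarray, filter_win: int = 5, window_type: str = "hamming") -> np.ndarray:
    """Moving-window smoothing with a unit-sum taper and reflective padding."""
    if filter_win < 3 or filter_win % 2 == 0:
        raise PipelineError(f"smoothing window must be odd and >= 3, got {filter_win}")
    x = np.asarray(x, dtype=float)
    win = signal.get_window(window_type, filter_win, fftbins=False)
    win = win / win.sum()
    padded = np.pad(x, filter_win // 2, mode="reflect")
    return np.convolve(padded, win, mode="valid")


def op_savgol(
    x: np.ndarray, filter_win: int = 5, poly_order: int = 3, deriv_order: int = 1
) -> np.ndarray:
    """Savitzky-Golay smoothing / derivative (per-sample units, length kept)."""
    if filter_win % 2 == 0 or filter_win < 3:
        raise PipelineError(f"SAVGOL window must be odd and >= 3, got {filter_win}")
    if poly_order >= filter_win:
        raise PipelineError("poly_order must be < filter_win")
    if deriv_order > poly_order:
        raise PipelineError("deriv_order must be <= poly_order")
    return signal.savgol_filter(
        np.asarray(x, dtype=float), filter_win, poly_order, deriv=deriv_order, delta=1.0
    )


def op_resample(
    x: np.ndarray, ratio: float = 0.7, grid: WavelengthGrid | None = None
) -> tuple[np.ndarray, WavelengthGrid | None]:
    """Fourier resampling to ``round(N * ratio)`` evenly spaced points."""
    if not 0 < ratio <= 1:
        raise PipelineError(f"resampling ratio must be in (0, 1], got {ratio}")
    x = np.asarray(x, dtype=float)
    m = int(round(x.size * ratio))
    out = signal.resample(x, m)
    new_grid = None
    if grid is not None:
        wl = grid.wavelengths
        new_grid = WavelengthGrid(np.linspace(wl[0], wl[-1], m))
    return out, new_grid


# ---------------------------------------------------------------------------
# pipeline specification and fitting
# ---------------------------------------------------------------------------

def _freeze_params(params) -> tuple:
    """Normalize a params mapping to a hashable, sorted tuple of pairs."""
    items = params.items() if isinstance(params, dict) else params
    return tuple(
        sorted((k, tuple(v) if isinstance(v, (list, tuple)) else v) for k, v in items)
    )


@dataclass(frozen=True)
class OperatorSpec:
    """One named operator with its parameter values."""

    name: str
    params: tuple[tuple[str, object], ...] = ()

    def __post_init__(self) -> None:
        if self.name not in OPERATOR_NAMES:
            raise PipelineError(f"unknown operator {self.name!r}")
        object.__setattr__(self, "params", _freeze_params(self.params))

    @property
    def param_dict(self) -> dict:
        return dict(self.params)

    def to_json_obj(self) -> dict:
        return {"name": self.name, "params": self.param_dict}


@dataclass(frozen=True)
class PipelineSpec:
    """Ordered, deduplicated set of operators in canonical order."""

    steps: tuple[OperatorSpec, ...] = ()

    def __post_init__(self) -> None:
        steps = tuple(self.steps)
        names = [s.name for s in steps]
        if len(set(names)) != len(names):
            raise PipelineError(f"duplicate operators in pipeline: {names}")
        ordered = tuple(sorted(steps, key=lambda s: _ORDER[s.name]))
        object.__setattr__(self, "steps", ordered)

    def __len__(self) -> int:
        return len(self.steps)

    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.steps)

    def to_json(self) -> str:
        return json.dumps([s.to_json_obj() for s in self.steps])

    @classmethod
    def from_json(cls, text: str) -> "PipelineSpec":
        return cls(
            tuple(
                OperatorSpec(item["name"], item.get("params", {}))
                for item in json.loads(text)
            )
        )


@dataclass
class FittedPipeline:
    """A pipeline plus the state estimated from training spectra.

    ``reference`` maps an operator name (MSC/EMSC) to the mean training
    spectrum *at that stage* of the pipeline; ``output_grid`` is the grid after
    an optional RESAMPLE step.
    """

    spec: PipelineSpec
    input_grid: WavelengthGrid
    reference: dict[str, np.ndarray] = field(default_factory=dict)
    output_grid: WavelengthGrid | None = None

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        grid = self.input_grid
        for step in self.spec.steps:
            X, grid = _apply_step(step, X, grid, self.reference.get(step.name))
        return X


def _apply_step(
    step: OperatorSpec,
    X: np.ndarray,
    grid: WavelengthGrid,
    ref: np.ndarray | None,
) -> tuple[np.ndarray, WavelengthGrid]:
    p = step.param_dict
    name = step.name
    if name == "CLIP":
        rows = [op_clip(x, **p) for x in X]
    elif name == "DETREND":
        rows = [op_detrend(x, grid.wavelengths, **p) for x in X]
    elif name == "BASELINE":
        rows = [op_baseline(x) for x in X]
    elif name == "SNV":
        rows = [op_snv(x) for x in X]
    elif name == "RNV":
        iqr = tuple(p.get("iqr", (75.0, 25.0)))
        rows = [op_rnv(x, iqr) for x in X]
    elif name == "LSNV":
        rows = [op_lsnv(x, **p) for x in X]
    elif name == "MSC":
        rows = [op_msc(x, ref) for x in X]
    elif name == "EMSC":
        rows = [op_emsc(x, ref, grid.wavelengths) for x in X]
    elif name == "NORML":
        rows = [op_norml(x) for x in X]
    elif name == "SMOOTH":
        rows = [op_smooth(x, **p) for x in X]
    elif name == "SAVGOL":
        rows = [op_savgol(x, **p) for x in X]
    elif name == "RESAMPLE":
        ratio = p.get("resampling_ratio", p.get("ratio", 0.7))
        pairs = [op_resample(x, ratio, grid) for x in X]
        rows = [out for out, _ in pairs]
        grid = pairs[0][1]
        return np.vstack(rows), grid
    else:  # pragma: no cover - guarded by OperatorSpec
        raise PipelineError(name)
    return np.vstack(rows), grid


def fit_apply_pipeline(
    spec: PipelineSpec,
    train_X: np.ndarray,
    grid: WavelengthGrid,
    other_X: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None, FittedPipeline]:
    """Fit pipeline state on training spectra, transform train and other.

    MSC/EMSC reference spectra are the training mean at the stage where the
    operator runs, so applying the fitted pipeline to held-out spectra uses
    training statistics only.
    """
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    fitted = FittedPipeline(spec=spec, input_grid=grid)
    cur = train_X
    cur_grid = grid
    for step in spec.steps:
        ref = None
        if step.name in ("MSC", "EMSC"):
            ref = cur.mean(axis=0)
            fitted.reference[step.name] = ref
        cur, cur_grid = _apply_step(step, cur, cur_grid, ref)
    fitted.output_grid = cur_grid
    other_out = fitted.transform(other_X) if other_X is not None else None
    return cur, other_out, fitted


# ---------------------------------------------------------------------------
# enumeration and search
# ---------------------------------------------------------------------------

#: Parameter grids matching the printed operator tables; SAVGOL/SMOOTH grids
#: differ between the classification and regression searches, so callers pass
#: their own pools (these are the classification-search defaults).
DEFAULT_POOLS: dict[str, list[dict]] = {
    "CLIP": [{"threshold": 10_000.0, "substitute": None}],
    "SNV": [{}],
    "RNV": [{"iqr": (75.0, 25.0)}, {"iqr": (90.0, 10.0)}],
    "LSNV": [{"window": 17}],
    "MSC": [{}],
    "EMSC": [{}],
    "NORML": [{}],
    "DETREND": [{"bp": (0,)}],
    "BASELINE": [{}],
    "SMOOTH": [
        {"filter_win": w, "window_type": "hamming"} for w in (5, 7, 9)
    ],
    "SAVGOL": [
        {"filter_win": w, "poly_order": 3, "deriv_order": d}
        for w in (5, 7, 11, 31, 71)
        for d in (1, 2)
    ],
    "RESAMPLE": [{"resampling_ratio": 0.7}],
}


def enumerate_pipelines(
    pools: dict[str, list[dict]],
    scheme: str = "subset",
    max_steps: int | None = None,
) -> list[PipelineSpec]:
    """Enumerate candidate pipelines from per-operator parameter grids.

    ``scheme='subset'``: every subset of the pooled operator names (including
    the empty pipeline), crossed with each operator's parameter choices, at
    most one instance per operator.  ``max_steps`` optionally caps the subset
    size.  The result is deduplicated and deterministic.
    """
    if not pools:
        raise PipelineError("empty operator pool")
    if scheme != "subset":
        raise PipelineError(f"unknown enumeration scheme {scheme!r}")
    names = [n for n in OPERATOR_NAMES if n in pools]
    specs: list[PipelineSpec] = []
    seen: set = set()
    for r in range(len(names) + 1):
        if max_steps is not None and r > max_steps:
            break
        for combo in itertools.combinations(names, r):
            grids = [pools[name] for name in combo]
            for choice in itertools.product(*grids):
                steps = tuple(
                    OperatorSpec(name, params) for name, params in zip(combo, choice)
                )
                key = tuple((s.name, s.params) for s in steps)
                if key not in seen:
                    seen.add(key)
                    specs.append(PipelineSpec(steps))
    return specs


@dataclass(frozen=True)
class SearchResult:
    spec: PipelineSpec
    score: float
    rank: int


def search_best(
    pipelines: list[PipelineSpec],
    evaluator,
    direction: str = "max",
) -> list[SearchResult]:
    """Exhaustively score pipelines; return results ranked best-first.

    ``evaluator(spec) -> float`` must return a finite score.  Ties are broken
    by fewer steps, then lexicographically on the serialized spec, so the
    ranking is fully deterministic.
    """
    if direction not in ("max", "min"):
        raise PipelineError(f"direction must be 'max' or 'min', got {direction!r}")
    if not pipelines:
        raise PipelineError("no pipelines to search")
    scored = []
    failures = 0
    for spec in pipelines:
        try:
            score = float(evaluator(spec))
        except DegenerateSpectrumError:
            failures += 1
            continue
        if not np.isfinite(score):
            raise PipelineError(f"evaluator returned non-finite score for {spec}")
        scored.append((spec, score))
    if not scored:
        raise PipelineError("every pipeline failed evaluation")
    sign = -1.0 if direction == "max" else 1.0
    scored.sort(key=lambda item: (sign * item[1], len(item[0]), item[0].to_json()))
    return [
        SearchResult(spec=spec, score=score, rank=i + 1)
        for i, (spec, score) in enumerate(scored)
    ]
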