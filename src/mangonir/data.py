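"""Domain types and CSV I/O for labeled NIR spectra of mango fruit.

A scan is an absorbance vector on a shared wavelength grid (1350-2500 nm, 136
points by default), taken at one of four marked locations on a fruit.  Each
scan carries reference wet-chemistry values — total acidity (TA, %), soluble
solids content (SSC, degrees Brix), firmness (kgf) and starch (%) — plus a
five-level maturity index label (80, 85, 90, 95 or 100 percent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Admissible maturity-index labels (percent maturity).
MATURITY_CLASSES: tuple[int, ...] = (80, 85, 90, 95, 100)

#: Names of the four reference quality parameters, in canonical order.
PARAMETERS: tuple[str, ...] = ("TA", "SSC", "firmness", "starch")

#: Universe (admissible range) of each quality parameter, in its own units.
PARAMETER_UNIVERSE: dict[str, tuple[float, float]] = {
    "TA": (0.0, 2.5),
    "SSC": (4.0, 24.0),
    "firmness": (0.0, 5.0),
    "starch": (0.0, 15.0),
}

GRID_MIN_NM = 1350.0
GRID_MAX_NM = 2500.0
DEFAULT_GRID_POINTS = 136


class DataError(ValueError):
    """Malformed or inconsistent input data."""


def check_class(label: int) -> int:
    label = int(label)
    if label not in MATURITY_CLASSES:
        raise DataError(f"maturity class must be one of {MATURITY_CLASSES}, got {label}")
    return label


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength axis in nm, bounded by [1350, 2500]."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise DataError("wavelength grid must be a 1-D vector of length >= 2")
        if not np.all(np.diff(wl) > 0):
            raise DataError("wavelengths must be strictly increasing")
        if wl[0] < GRID_MIN_NM - 1e-9 or wl[-1] > GRID_MAX_NM + 1e-9:
            raise DataError(
                f"wavelengths must lie within [{GRID_MIN_NM}, {GRID_MAX_NM}] nm"
            )
        object.__setattr__(self, "wavelengths", wl)

    def __len__(self) -> int:
        return self.wavelengths.size

    @classmethod
    def default(cls, n_points: int = DEFAULT_GRID_POINTS) -> "WavelengthGrid":
        """Evenly spaced grid over the full 1350-2500 nm range."""
        return cls(np.linspace(GRID_MIN_NM, GRID_MAX_NM, n_points))


@dataclass(frozen=True)
class Spectrum:
    """One absorbance scan at a marked location (1-4) of a fruit sample."""

    sample_id: str
    location: int
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not 1 <= int(self.location) <= 4:
            raise DataError(f"location must be 1-4, got {self.location}")


@dataclass(frozen=True)
class ReferenceRecord:
    """Wet-chemistry reference values for one scan location."""

    sample_id: str
    location: int
    TA: float
    SSC: float
    firmness: float
    starch: float
    maturity: int

    def __post_init__(self) -> None:
        check_class(self.maturity)
        for name in PARAMETERS:
            value = float(getattr(self, name))
            lo, hi = PARAMETER_UNIVERSE[name]
            if not np.isfinite(value) or value < lo or value > hi:
                raise DataError(
                    f"{name}={value} outside universe [{lo}, {hi}] "
                    f"for {self.sample_id}/{self.location}"
                )

    def parameter_vector(self) -> np.ndarray:
        return np.array([self.TA, self.SSC, self.firmness, self.starch])


@dataclass
class LabeledDataset:
    """Spectra aligned row-wise with reference records and class labels.

    ``X`` is the ``(n_scans, n_wavelengths)`` absorbance matrix; row *i*
    belongs to ``spectra[i]`` and ``references[i]`` (same (sample_id,
    location) key).
    """

    grid: WavelengthGrid
    spectra: list[Spectrum]
    references: list[ReferenceRecord] = field(default_factory=list)
    labels: np.ndarray | None = None  # class labels when references are absent

    def __post_init__(self) -> None:
        for s in self.spectra:
            if s.values.size != len(self.grid):
                raise DataError(
                    f"spectrum {s.sample_id}/{s.location} has {s.values.size} "
                    f"points, grid has {len(self.grid)}"
                )
        if self.references and len(self.references) != len(self.spectra):
            raise DataError("one reference record required per spectrum")
        for s, r in zip(self.spectra, self.references):
            if (s.sample_id, s.location) != (r.sample_id, r.location):
                raise DataError(
                    f"spectrum/reference key mismatch: {s.sample_id}/{s.location}"
                    f" vs {r.sample_id}/{r.location}"
                )

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def X(self) -> np.ndarray:
        return np.vstack([s.values for s in self.spectra]) if self.spectra else (
            np.empty((0, len(self.grid)))
        )

    @property
    def classes(self) -> np.ndarray:
        if self.references:
            return np.array([r.maturity for r in self.references], dtype=int)
        if self.labels is not None:
            return np.asarray(self.labels, dtype=int)
        return np.empty(0, dtype=int)

    @property
    def parameters(self) -> pd.DataFrame:
        return pd.DataFrame(
            {name: [getattr(r, name) for r in self.references] for name in PARAMETERS}
        )

    def class_counts(self) -> dict[int, int]:
        counts = dict.fromkeys(MATURITY_CLASSES, 0)
        for r in self.references:
            counts[r.maturity] += 1
        return counts

    def subset(self, indices: np.ndarray) -> "LabeledDataset":
        idx = np.asarray(indices, dtype=int)
        return LabeledDataset(
            grid=self.grid,
            spectra=[self.spectra[i] for i in idx],
            references=[self.references[i] for i in idx] if self.references else [],
            labels=None if self.labels is None else np.asarray(self.labels)[idx],
        )


def validate_spectrum(spectrum: Spectrum, clip_threshold: float = 10_000.0) -> bool:
    """A scan is valid iff every value is finite and |value| <= clip_threshold.

    The acquisition occasionally produces unusable scans (saturated or
    dropped readings); those are excluded before modelling.
    """
    v = spectrum.values
    return bool(np.all(np.isfinite(v)) and np.all(np.abs(v) <= clip_threshold))


# ---------------------------------------------------------------------------
# CSV dialects
#
# Spectra CSV:   sample_id,location,class,<wl1>,<wl2>,...   (header row carries
#                the wavelength grid)
# Reference CSV: sample_id,location,TA,SSC,firmness,starch,class
# ---------------------------------------------------------------------------

def write_spectra_csv(path, dataset: LabeledDataset) -> None:
    wl_cols = [f"{w:.6g}" for w in dataset.grid.wavelengths]
    rows = []
    for s, r in zip(dataset.spectra, dataset.references or [None] * len(dataset)):
        label = r.maturity if r is not None else ""
        rows.append([s.sample_id, s.location, label, *s.values])
    frame = pd.DataFrame(rows, columns=["sample_id", "location", "class", *wl_cols])
    frame.to_csv(path, index=False, float_format="%.10g")


def read_spectra_csv(path) -> LabeledDataset:
    """Read a spectra CSV; wavelengths come from the header row.

    Returns a dataset whose reference list carries only the class label; use
    :func:`read_reference_csv` + :func:`attach_references` for full records.
    """
    frame = pd.read_csv(path, dtype={"sample_id": str})
    fixed = ["sample_id", "location", "class"]
    if list(frame.columns[:3]) != fixed:
        raise DataError(f"spectra CSV must start with columns {fixed}")
    try:
        wl = np.array([float(c) for c in frame.columns[3:]])
    except ValueError as exc:
        raise DataError(f"non-numeric wavelength header: {exc}") from None
    grid = WavelengthGrid(wl)
    values = frame.iloc[:, 3:].to_numpy(dtype=float)
    spectra = [
        Spectrum(str(sid), int(loc), row)
        for sid, loc, row in zip(frame["sample_id"], frame["location"], values)
    ]
    raw_labels = frame["class"]
    labels = (
        None
        if raw_labels.isna().all()
        else np.array([check_class(c) for c in raw_labels])
    )
    return LabeledDataset(grid=grid, spectra=spectra, labels=labels)


def write_reference_csv(path, records: list[ReferenceRecord]) -> None:
    frame = pd.DataFrame(
        [
            [r.sample_id, r.location, r.TA, r.SSC, r.firmness, r.starch, r.maturity]
            for r in records
        ],
        columns=["sample_id", "location", *PARAMETERS, "class"],
    )
    frame.to_csv(path, index=False, float_format="%.10g")


def read_reference_csv(path) -> list[ReferenceRecord]:
    frame = pd.read_csv(path, dtype={"sample_id": str})
    expected = ["sample_id", "location", *PARAMETERS, "class"]
    if list(frame.columns) != expected:
        raise DataError(f"reference CSV must have columns {expected}")
    return [
        ReferenceRecord(
            sample_id=str(row["sample_id"]),
            location=int(row["location"]),
            TA=float(row["TA"]),
            SSC=float(row["SSC"]),
            firmness=float(row["firmness"]),
            starch=float(row["starch"]),
            maturity=int(row["class"]),
        )
        for _, row in frame.iterrows()
    ]


def attach_references(
    dataset: LabeledDataset, records: list[ReferenceRecord]
) -> LabeledDataset:
    """Join reference records onto spectra by (sample_id, location)."""
    by_key = {(r.sample_id, r.location): r for r in records}
    refs = []
    for s in dataset.spectra:
        key = (s.sample_id, s.location)
        if key not in by_key:
            raise DataError(f"no reference record for scan {key}")
        refs.append(by_key[key])
    return LabeledDataset(grid=dataset.grid, spectra=dataset.spectra, references=refs)


def split_train_test(
    dataset: LabeledDataset,
    test_fraction: float = 0.10,
    seed: int = 0,
    stratified: bool = True,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Deterministic train/test split; stratified by maturity class.

    Per-class test counts are ``round(class_n * test_fraction)`` with
    round-half-up, which for class counts (139, 140, 140, 139, 138) at a 10%
    fraction gives 14 scans per class, 70 in total.
    """
    if not 0 <= test_fraction < 1:
        raise DataError(f"test_fraction must be in [0, 1), got {test_fraction}")
    rng = np.random.default_rng(seed)
    n = len(dataset)
    labels = dataset.classes
    test_idx: list[int] = []
    if stratified:
        for cls in MATURITY_CLASSES:
            members = np.flatnonzero(labels == cls)
            if members.size == 0:
                continue
            n_test = int(np.floor(members.size * test_fraction + 0.5))
            chosen = rng.permutation(members)[:n_test]
            test_idx.extend(chosen.tolist())
    else:
        n_test = int(np.floor(n * test_fraction + 0.5))
        test_idx = rng.permutation(n)[:n_test].tolist()
    test_mask = np.zeros(n, dtype=bool)
    test_mask[test_idx] = True
    return dataset.subset(np.flatnonzero(~test_mask)), dataset.subset(
        np.flatnonzero(test_mask)
    )
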