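"""Mamdani fuzzy inference for mango maturity grading.

The four quality parameters are fuzzified into Low / Medium / High linguistic
levels with trapezoidal membership functions whose overlapping ramps encode
expert boundaries between maturity grades.  An 81-rule base (every
combination of the four inputs' three levels) maps level tuples to one of the
five maturity indexes, each represented on the 75-100% output universe by a
symmetric triangular set peaking at its label.  Inference is classic Mamdani:
rule strength is the minimum of the antecedent degrees, each consequent
triangle is clipped at the strength of its strongest rule, the clipped sets
are combined pointwise by maximum, and the aggregate is defuzzified by its
centroid on a discretized output grid.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field

import numpy as np

from mangonir.data import MATURITY_CLASSES, PARAMETER_UNIVERSE, PARAMETERS

LEVELS = ("L", "M", "H")


@dataclass(frozen=True)
class TrapezoidMF:
    """Trapezoid with corners a <= b <= c <= d; plateau 1 on [b, c]."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if not self.a <= self.b <= self.c <= self.d:
            raise ValueError(f"corners must be ordered: {self}")

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        if self.b > self.a:
            ramp = (x - self.a) / (self.b - self.a)
            out = np.where((x >= self.a) & (x < self.b), ramp, out)
        out = np.where((x >= self.b) & (x <= self.c), 1.0, out)
        if self.d > self.c:
            ramp = (self.d - x) / (self.d - self.c)
            out = np.where((x > self.c) & (x <= self.d), ramp, out)
        return out


@dataclass(frozen=True)
class TriangleMF:
    """Triangle with corners a <= b <= c; peak 1 at b."""

    a: float
    b: float
    c: float

    def __call__(self, x) -> np.ndarray:
        return TrapezoidMF(self.a, self.b, self.b, self.c)(x)


@dataclass(frozen=True)
class LinguisticVariable:
    """One input parameter with its universe and L/M/H trapezoids."""

    name: str
    universe: tuple[float, float]
    sets: dict[str, TrapezoidMF]

    def __post_init__(self) -> None:
        if set(self.sets) != set(LEVELS):
            raise ValueError(f"{self.name}: sets must be exactly {LEVELS}")


@dataclass(frozen=True)
class OutputVariable:
    """Maturity-index output on [75, 100] with one triangle per grade."""

    universe: tuple[float, float] = (75.0, 100.0)
    sets: dict[int, TriangleMF] = None

    def __post_init__(self) -> None:
        if self.sets is None:
            object.__setattr__(
                self,
                "sets",
                {cls: TriangleMF(cls - 5.0, float(cls), cls + 5.0) for cls in MATURITY_CLASSES},
            )
        if set(self.sets) != set(MATURITY_CLASSES):
            raise ValueError("output needs one set per maturity class")


@dataclass(frozen=True)
class FISConfig:
    """Mamdani settings: min implication, max aggregation, centroid defuzz."""

    defuzz_step: float = 0.01

    def __post_init__(self) -> None:
        if self.defuzz_step <= 0:
            raise ValueError("defuzz step must be positive")


# ---------------------------------------------------------------------------
# default membership functions
#
# Input trapezoids encode the published L/M/H boundaries: the two numbers
# printed per boundary are the ramp interval (e.g. TA Low ends over
# 0.60-0.65 while Medium rises over the same span).  Starch is printed with
# touching M/H bounds; a 0.3-wide overlap is imposed there to keep every
# universe point covered, mirroring the other variables.
# ---------------------------------------------------------------------------

_INPUT_CORNERS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "TA": {
        "L": (0.0, 0.0, 0.60, 0.65),
        "M": (0.60, 0.65, 0.75, 0.80),
        "H": (0.75, 0.80, 2.5, 2.5),
    },
    "SSC": {
        "L": (4.0, 4.0, 9.2, 9.6),
        "M": (9.2, 9.6, 16.0, 16.5),
        "H": (16.0, 16.5, 24.0, 24.0),
    },
    "firmness": {
        "L": (0.0, 0.0, 1.5, 1.7),
        "M": (1.5, 1.7, 2.7, 2.9),
        "H": (2.7, 2.9, 5.0, 5.0),
    },
    "starch": {
        "L": (0.0, 0.0, 3.0, 3.5),
        "M": (3.0, 3.5, 5.3, 5.6),
        "H": (5.3, 5.6, 15.0, 15.0),
    },
}


def default_variables() -> dict[str, LinguisticVariable]:
    return {
        name: LinguisticVariable(
            name=name,
            universe=PARAMETER_UNIVERSE[name],
            sets={lvl: TrapezoidMF(*corners) for lvl, corners in per_level.items()},
        )
        for name, per_level in _INPUT_CORNERS.items()
    }


# ---------------------------------------------------------------------------
# rule base
#
# The 81 expert rules, laid out as rows = (TA level, SSC level) and columns
# = (firmness level, starch level).  Consequents are maturity indexes.
# ---------------------------------------------------------------------------

# _RULE_GRID[(ta, ssc)][(firmness, starch)] with level order H, M, L on every axis
_RULE_ROWS: dict[tuple[str, str], tuple[int, ...]] = {
    # firmness:   H  H  H   M  M  M   L  L  L
    # starch:     H  M  L   H  M  L   H  M  L
    ("H", "H"): (80, 90, 95, 80, 90, 95, 80, 90, 95),
    ("H", "M"): (80, 85, 95, 80, 85, 95, 80, 85, 95),
    ("H", "L"): (80, 80, 95, 80, 85, 95, 80, 85, 95),
    ("M", "H"): (85, 90, 95, 85, 90, 95, 85, 95, 100),
    ("M", "M"): (85, 85, 95, 85, 95, 95, 85, 85, 95),
    ("M", "L"): (80, 85, 95, 80, 85, 95, 80, 85, 95),
    ("L", "H"): (85, 90, 95, 85, 95, 95, 85, 100, 100),
    ("L", "M"): (85, 90, 95, 85, 90, 95, 85, 95, 95),
    ("L", "L"): (80, 85, 95, 80, 85, 95, 80, 85, 100),
}


@dataclass(frozen=True)
class RuleBase:
    """Total map {H,M,L}^4 -> maturity class, keyed (TA, SSC, firmness, starch)."""

    rules: dict[tuple[str, str, str, str], int]

    def __post_init__(self) -> None:
        expected = {
            (ta, ssc, f, st)
            for ta in LEVELS
            for ssc in LEVELS
            for f in LEVELS
            for st in LEVELS
        }
        if set(self.rules) != expected:
            raise ValueError(
                f"rule base must cover all {len(expected)} level combinations"
            )
        bad = {c for c in self.rules.values() if c not in MATURITY_CLASSES}
        if bad:
            raise ValueError(f"invalid consequents: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.rules)

    def to_csv(self) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(["TA", "SSC", "firmness", "starch", "consequent"])
        for key in sorted(self.rules):
            writer.writerow([*key, self.rules[key]])
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str) -> "RuleBase":
        reader = csv.DictReader(io.StringIO(text))
        rules = {
            (row["TA"], row["SSC"], row["firmness"], row["starch"]): int(
                row["consequent"]
            )
            for row in reader
        }
        return cls(rules)


def default_rule_base() -> RuleBase:
    hml = ("H", "M", "L")
    rules = {}
    for (ta, ssc), row in _RULE_ROWS.items():
        i = 0
        for f in hml:
            for st in hml:
                rules[(ta, ssc, f, st)] = row[i]
                i += 1
    return RuleBase(rules)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def fuzzify(value: float, variable: LinguisticVariable) -> dict[str, float]:
    """L/M/H membership degrees; out-of-universe values are clamped first."""
    lo, hi = variable.universe
    v = float(np.clip(value, lo, hi))
    return {lvl: float(variable.sets[lvl](v)) for lvl in LEVELS}


def rule_strengths(
    degrees: dict[str, dict[str, float]], rules: RuleBase
) -> dict[tuple[str, str, str, str], float]:
    """Strength of each rule = min of its four antecedent degrees."""
    out = {}
    for key in rules.rules:
        ta, ssc, f, st = key
        out[key] = min(
            degrees["TA"][ta],
            degrees["SSC"][ssc],
            degrees["firmness"][f],
            degrees["starch"][st],
        )
    return out


def _aggregate_on(
    grid: np.ndarray,
    strengths: dict[tuple[str, str, str, str], float],
    rules: RuleBase,
    out: OutputVariable,
) -> np.ndarray:
    clip_level = dict.fromkeys(MATURITY_CLASSES, 0.0)
    for key, s in strengths.items():
        cls = rules.rules[key]
        if s > clip_level[cls]:
            clip_level[cls] = s
    agg = np.zeros_like(grid)
    for cls, level in clip_level.items():
        if level > 0:
            agg = np.maximum(agg, np.minimum(out.sets[cls](grid), level))
    return agg


def aggregate_and_defuzzify(
    strengths: dict[tuple[str, str, str, str], float],
    out: OutputVariable | None = None,
    cfg: FISConfig | None = None,
    rules: RuleBase | None = None,
) -> float:
    """Clip, max-aggregate and take the centroid on the discretized universe."""
    out = out or OutputVariable()
    cfg = cfg or FISConfig()
    rules = rules or default_rule_base()
    if max(strengths.values(), default=0.0) <= 0:
        raise ValueError("all rule strengths are zero; nothing to defuzzify")
    lo, hi = out.universe
    grid = np.arange(lo, hi + cfg.defuzz_step / 2, cfg.defuzz_step)
    agg = _aggregate_on(grid, strengths, rules, out)
    return float(np.sum(grid * agg) / np.sum(agg))


def oracle_defuzzify(
    strengths,
    out: OutputVariable | None = None,
    rules: RuleBase | None = None,
    step: float = 0.001,
) -> float:
    """Brute-force fine-grid Riemann centroid, kept as an independent check."""
    if step > 0.001:
        raise ValueError("oracle step must be <= 0.001")
    out = out or OutputVariable()
    rules = rules or default_rule_base()
    lo, hi = out.universe
    grid = np.arange(lo, hi + step / 2, step)
    agg = _aggregate_on(grid, strengths, rules, out)
    total = agg.sum()
    if total <= 0:
        raise ValueError("all rule strengths are zero")
    return float(np.sum(grid * agg) / total)


def assign_class(crisp: float) -> int:
    """Nearest output peak; ties go to the lower maturity index."""
    if not 75.0 <= crisp <= 100.0:
        raise ValueError(f"crisp value {crisp} outside [75, 100]")
    best = min(MATURITY_CLASSES, key=lambda cls: (abs(crisp - cls), cls))
    return best


@dataclass(frozen=True)
class MamdaniGrader:
    """Bundled variables + rules + output sets, the full inference path."""

    variables: dict[str, LinguisticVariable] = field(default_factory=default_variables)
    rules: RuleBase = field(default_factory=default_rule_base)
    output: OutputVariable = field(default_factory=OutputVariable)
    config: FISConfig = field(default_factory=FISConfig)

    def infer(self, TA: float, SSC: float, firmness: float, starch: float):
        values = dict(TA=TA, SSC=SSC, firmness=firmness, starch=starch)
        degrees = {
            name: fuzzify(values[name], self.variables[name]) for name in PARAMETERS
        }
        strengths = rule_strengths(degrees, self.rules)
        crisp = aggregate_and_defuzzify(
            strengths, self.output, self.config, self.rules
        )
        return crisp, assign_class(crisp)

    def membership_json(self) -> str:
        return json.dumps(
            {
                name: {
                    lvl: [mf.a, mf.b, mf.c, mf.d]
                    for lvl, mf in var.sets.items()
                }
                for name, var in self.variables.items()
            }
        )


def default_fis() -> MamdaniGrader:
    return MamdaniGrader()


def classify_fuzzy(
    TA: float,
    SSC: float,
    firmness: float,
    starch: float,
    fis: MamdaniGrader | None = None,
) -> tuple[float, int]:
    """Crisp maturity value and class for one parameter quadruple."""
    fis = fis or default_fis()
    return fis.infer(TA, SSC, firmness, starch)
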