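"""Synthetic life tables: age- and sex-specific annual death probabilities.

The Markov cohort model needs a mortality backbone: the annual probability of
death ``qx`` for each integer age and sex, as a national all-cause life table
(e.g. the Human Mortality Database) would provide. This module generates a
synthetic stand-in from a Gompertz–Makeham hazard and reads/writes the simple
CSV exchange format ``age,sex,qx``.

The Gompertz–Makeham law models the adult all-cause hazard as an
age-independent background ``c`` plus an exponentially increasing senescent
component ``a * exp(b * age)``. The annual death probability at age ``x`` is

    qx(x) = 1 - exp(-(c + a * exp(b * x)))

which is guaranteed in [0, 1] and, for ``a, b > 0``, strictly increasing in
age — the only qualitative feature of real mortality schedules the downstream
cost-utility results depend on.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AgeRangeError, FormatError, ParameterError

SEXES = ("female", "male")

#: Default Gompertz parameters: a plausible late-life all-cause schedule for a
#: high-income country (qx ~ 1.3% at 65, ~10% at 87, ~60% at 110).
DEFAULT_GOMPERTZ = {"a": 2.7e-5, "b": 0.095, "c": 0.0}


def gompertz_makeham_qx(age: float, a: float, b: float, c: float = 0.0) -> float:
    """Annual death probability at ``age`` under a Gompertz–Makeham hazard.

    Overflow at extreme ages saturates to 1.
    """
    hazard = c + a * math.exp(min(b * age, 700.0))
    return min(1.0, 1.0 - math.exp(-hazard))


@dataclass
class LifeTable:
    """Age- and sex-indexed annual death probabilities.

    ``frame`` holds one row per (age, sex) with columns ``age``, ``sex``,
    ``qx``. Ages form a contiguous integer range per sex; every qx lies in
    [0, 1]. A non-monotone qx schedule is legal (real tables can wiggle) but
    triggers a warning at validation.
    """

    frame: pd.DataFrame
    _lookup: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._validate()
        self._lookup = {
            (int(r.age), r.sex): float(r.qx) for r in self.frame.itertuples()
        }

    def _validate(self) -> None:
        required = {"age", "sex", "qx"}
        missing = required - set(self.frame.columns)
        if missing:
            raise FormatError(f"life table missing columns: {sorted(missing)}")
        bad = self.frame[(self.frame.qx < 0) | (self.frame.qx > 1)]
        if not bad.empty:
            row = bad.iloc[0]
            raise FormatError(
                f"qx={row.qx} outside [0, 1] at age={int(row.age)} sex={row.sex}"
            )
        unknown = set(self.frame.sex.unique()) - set(SEXES)
        if unknown:
            raise FormatError(f"unknown sex labels: {sorted(unknown)}")
        for sex, grp in self.frame.groupby("sex"):
            ages = np.sort(grp.age.to_numpy())
            if len(ages) != len(set(ages)):
                raise FormatError(f"duplicate ages for sex={sex}")
            gaps = np.where(np.diff(ages) != 1)[0]
            if gaps.size:
                raise FormatError(
                    f"non-contiguous ages for sex={sex}: gap after age {int(ages[gaps[0]])}"
                )
            qx = grp.sort_values("age").qx.to_numpy()
            lo, hi = int(ages.min()), int(ages.max())
            win = qx[: max(0, min(hi, 105) - lo + 1)]
            if win.size > 1 and np.any(np.diff(win) < -1e-12):
                warnings.warn(
                    f"qx not non-decreasing in age for sex={sex}", stacklevel=3
                )

    @property
    def age_min(self) -> int:
        return int(self.frame.age.min())

    @property
    def age_max(self) -> int:
        return int(self.frame.age.max())

    def qx(self, age: int, sex: str) -> float:
        """Annual probability of death at integer ``age`` for ``sex``."""
        try:
            return self._lookup[(int(age), sex)]
        except KeyError:
            raise AgeRangeError(
                f"(age={age}, sex={sex}) not in life table "
                f"[{self.age_min}, {self.age_max}]"
            ) from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LifeTable):
            return NotImplemented
        return self._lookup == other._lookup


def generate_gompertz_life_table(
    a: float = DEFAULT_GOMPERTZ["a"],
    b: float = DEFAULT_GOMPERTZ["b"],
    c: float = DEFAULT_GOMPERTZ["c"],
    age_min: int = 65,
    age_max: int = 110,
    *,
    params_by_sex: dict[str, tuple[float, float, float]] | None = None,
) -> LifeTable:
    """Build a LifeTable from Gompertz–Makeham parameters.

    Parameters
    ----------
    a, b, c
        Baseline hazard (> 0, or 0 for the degenerate zero-hazard table),
        senescence rate (> 0) and Makeham background (>= 0). Applied to both
        sexes unless ``params_by_sex`` supplies per-sex ``(a, b, c)`` triples.
    age_min, age_max
        Inclusive integer age range; must satisfy ``age_min < age_max``.

    Notes
    -----
    ``a = 0`` with ``c = 0`` yields qx = 0 everywhere (useful for tests); any
    strictly positive ``a, b`` yields a qx schedule non-decreasing in age,
    saturating at 1.
    """
    if age_min >= age_max:
        raise ParameterError(f"age_min={age_min} must be < age_max={age_max}")
    rows = []
    for sex in SEXES:
        if params_by_sex is not None:
            sa, sb, sc = params_by_sex[sex]
        else:
            sa, sb, sc = a, b, c
        if sa < 0 or sb <= 0 or sc < 0:
            raise ParameterError(
                f"invalid Gompertz-Makeham parameters for {sex}: "
                f"a={sa} (>=0), b={sb} (>0), c={sc} (>=0)"
            )
        for age in range(age_min, age_max + 1):
            rows.append((age, sex, gompertz_makeham_qx(age, sa, sb, sc)))
    frame = pd.DataFrame(rows, columns=["age", "sex", "qx"])
    return LifeTable(frame)


def read_life_table(path) -> LifeTable:
    """Read a ``age,sex,qx`` CSV into a LifeTable.

    Raises FormatError on missing columns, out-of-range qx or non-contiguous
    ages, naming the first offending row.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    required = {"age", "sex", "qx"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    try:
        frame["age"] = frame["age"].astype(int)
        frame["qx"] = frame["qx"].astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric age/qx ({exc})") from exc
    return LifeTable(frame)


def write_life_table(table: LifeTable, path) -> None:
    """Write a LifeTable as ``age,sex,qx`` CSV (UTF-8, decimal point)."""
    table.frame.to_csv(path, index=False)
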