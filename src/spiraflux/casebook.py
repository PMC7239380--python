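"""Insect case studies: parameter registry, gain evaluation, and sweeps.

A small bundled table records flutter-phase parameters for four insects
(five spiracle cases) drawn from the experimental literature: giant Saturniid
silkworms, the desert ant *Cataglyphis bicolor* (abdominal and thoracic
spiracles), the hissing cockroach *Gromphadorhina portentosa*, and the pine
weevil *Hylobius abietis*.  For each case the flutter factor ``f``, the
respiratory gain ``G = f/p``, and the dimensionless switching rate
``s = r L^2/D`` are derived; gains are additionally rounded half-up to the
precision conventionally reported (the ``g_decimals`` column), with the
unrounded values always retained.

Sweep helpers evaluate ``f``/``G`` over flutter-rate and tracheal-length
grids and the water flutter factor over wall-transfer-rate grids; they back
the figure-generation routines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .bvp import water_flutter_factor_bvp
from .model import (
    D_OXYGEN,
    D_WATER,
    FlutterSchedule,
    WaterModel,
    durations_to_rates,
    flutter_factor,
)

__all__ = [
    "InsectCase",
    "CaseResult",
    "bundled_case_path",
    "load_cases",
    "evaluate_case",
    "evaluate_cases",
    "sweep_gain",
    "sweep_flutter_factor",
    "sweep_water_factor",
]

_CSV_COLUMNS = ["name", "L_cm", "d_open_s", "d_closed_s", "p", "r_per_s", "D_cm2_s"]


@dataclass(frozen=True)
class InsectCase:
    """Named flutter-phase parameter bundle for one insect (or spiracle).

    Either mean bout durations ``(d_open, d_closed)`` or rates ``(p, r)``
    must be given; if only durations are given, ``p`` and ``r`` are derived.
    ``g_decimals`` is the number of decimals at which the gain is
    conventionally reported for this case.
    """

    name: str
    L: float
    D: float = D_OXYGEN
    p: float | None = None
    r: float | None = None
    d_open: float | None = None
    d_closed: float | None = None
    g_decimals: int = 1
    source_note: str = ""

    def __post_init__(self) -> None:
        if not self.L > 0:
            raise ValueError(f"case {self.name!r}: L must be positive, got {self.L}")
        if not self.D > 0:
            raise ValueError(f"case {self.name!r}: D must be positive, got {self.D}")
        has_durations = self.d_open is not None and self.d_closed is not None
        has_rates = self.p is not None and self.r is not None
        if not has_durations and not has_rates:
            raise ValueError(
                f"case {self.name!r}: give either (d_open, d_closed) or (p, r)"
            )
        if has_durations:
            p, r = durations_to_rates(self.d_open, self.d_closed)
            if has_rates:
                if not (
                    math.isclose(p, self.p, rel_tol=1e-6)
                    and math.isclose(r, self.r, rel_tol=1e-6)
                ):
                    raise ValueError(
                        f"case {self.name!r}: (p, r) inconsistent with "
                        f"(d_open, d_closed); derived p={p:g}, r={r:g}"
                    )
            else:
                object.__setattr__(self, "p", p)
                object.__setattr__(self, "r", r)
        if not 0 < self.p <= 1:
            raise ValueError(
                f"case {self.name!r}: field p must be in (0, 1], got {self.p}"
            )
        if not self.r > 0:
            raise ValueError(
                f"case {self.name!r}: field r must be positive, got {self.r}"
            )

    @property
    def schedule(self) -> FlutterSchedule:
        return FlutterSchedule(p=self.p, r=self.r)


@dataclass(frozen=True)
class CaseResult:
    """Derived quantities for one case: s = r L^2/D, f, and G = f/p, plus
    the half-up rounding of G at the case's reporting precision."""

    name: str
    p: float
    r: float
    s: float
    f: float
    gain: float
    gain_printed: float
    g_decimals: int


def _round_half_up(value: float, decimals: int) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def bundled_case_path() -> Path:
    """Path of the bundled insect case table (CSV)."""
    return Path(resources.files("spiraflux.data") / "insect_cases.csv")


def load_cases(path: str | Path | None = None) -> list[InsectCase]:
    """Read insect cases from a CSV table (the bundled one by default).

    Required header: name, L_cm, d_open_s, d_closed_s, p, r_per_s, D_cm2_s;
    optional columns g_decimals and source_note.  Blank cells mark absent
    optional values.  Validation errors name the offending row and field.
    """
    path = bundled_case_path() if path is None else Path(path)
    table = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"case table {path} lacks required columns: {missing}")

    def opt(row, col):
        val = row[col]
        return None if pd.isna(val) else float(val)

    cases = []
    for idx, row in table.iterrows():
        name = str(row["name"])
        if not name or pd.isna(row["name"]):
            raise ValueError(f"case table row {idx}: field 'name' is blank")
        try:
            cases.append(
                InsectCase(
                    name=name,
                    L=float(row["L_cm"]),
                    D=float(row["D_cm2_s"]),
                    p=opt(row, "p"),
                    r=opt(row, "r_per_s"),
                    d_open=opt(row, "d_open_s"),
                    d_closed=opt(row, "d_closed_s"),
                    g_decimals=(
                        int(row["g_decimals"]) if "g_decimals" in table.columns
                        and not pd.isna(row.get("g_decimals")) else 1
                    ),
                    source_note=(
                        str(row["source_note"]) if "source_note" in table.columns
                        and not pd.isna(row.get("source_note")) else ""
                    ),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"case table row {idx} ({name!r}): {exc}") from exc
    return cases


def evaluate_case(case: InsectCase) -> CaseResult:
    """Compute s, f and the respiratory gain for one case."""
    s = case.r * case.L**2 / case.D
    f = flutter_factor(case.p, s)
    gain = f / case.p
    return CaseResult(
        name=case.name,
        p=case.p,
        r=case.r,
        s=s,
        f=f,
        gain=gain,
        gain_printed=_round_half_up(gain, case.g_decimals),
        g_decimals=case.g_decimals,
    )


def evaluate_cases(cases: list[InsectCase] | None = None) -> pd.DataFrame:
    """Evaluate a list of cases (bundled table by default) into a DataFrame."""
    if cases is None:
        cases = load_cases()
    rows = [evaluate_case(c) for c in cases]
    return pd.DataFrame(
        {
            "name": [r.name for r in rows],
            "p": [r.p for r in rows],
            "r_per_s": [r.r for r in rows],
            "s": [r.s for r in rows],
            "f": [r.f for r in rows],
            "gain": [r.gain for r in rows],
            "gain_printed": [r.gain_printed for r in rows],
        }
    )


def sweep_gain(
    p: float,
    r_values,
    L_values,
    D: float = D_OXYGEN,
) -> pd.DataFrame:
    """Respiratory gain G on an (L, r) grid at fixed open fraction p.

    Returns a DataFrame indexed by L (cm) with one column per flutter rate
    (1/s).  G is nondecreasing along both axes.
    """
    r_values = np.asarray(r_values, dtype=float)
    L_values = np.asarray(L_values, dtype=float)
    if np.any(r_values <= 0) or np.any(L_values <= 0):
        raise ValueError("r and L sweep values must be positive")
    grid = np.empty((L_values.size, r_values.size))
    for i, L in enumerate(L_values):
        for j, r in enumerate(r_values):
            grid[i, j] = flutter_factor(p, r * L**2 / D) / p
    return pd.DataFrame(grid, index=L_values, columns=r_values)


def sweep_flutter_factor(
    p_values,
    r_values,
    L: float = 1.0,
    D: float = D_OXYGEN,
) -> pd.DataFrame:
    """f(r) and G(r) curves for several open fractions at fixed L, D.

    Long-format DataFrame with columns p, r_per_s, f, gain.  Each f-curve
    rises from near p (r -> 0) toward 1.
    """
    rows = []
    for p in p_values:
        for r in np.asarray(r_values, dtype=float):
            f = flutter_factor(p, r * L**2 / D)
            rows.append((p, r, f, f / p))
    return pd.DataFrame(rows, columns=["p", "r_per_s", "f", "gain"])


def sweep_water_factor(
    cases: list[InsectCase],
    k_values,
    D_w: float = D_WATER,
    n_grid: int = 400,
) -> pd.DataFrame:
    """Water flutter factor f_w(k) for each case, via the two-mode BVP.

    Long-format DataFrame with columns case, p, k_per_s, f_w.  Each curve
    approaches the case's open fraction p as k grows.
    """
    k_values = np.asarray(k_values, dtype=float)
    if np.any(k_values <= 0):
        raise ValueError("k sweep values must be positive")
    rows = []
    for case in cases:
        for k in k_values:
            fw = water_flutter_factor_bvp(
                WaterModel(k=k, D_w=D_w), case.schedule, case.L, n_grid=n_grid
            )
            rows.append((case.name, case.p, k, fw))
    return pd.DataFrame(rows, columns=["case", "p", "k_per_s", "f_w"])
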