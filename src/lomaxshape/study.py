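"""Monte Carlo risk study: simulate Lomax samples, apply every estimator,
and tabulate mean squared errors.

The protocol, per (case, n) cell:

1. draw ``reps`` independent samples of size n from Lomax(shape, scale)
   by the inverse-CDF transform;
2. evaluate all estimators on each sample (paired design: every column
   sees the same replicates);
3. report MSE = mean of (estimate - shape)^2 across replicates, together
   with its Monte Carlo standard error.

Output mirrors the conventional presentation: one table for the five
classical estimators and one per prior with seven Bayes columns
(posterior mean, LINEX at each asymmetry a, composite LINEX at each a).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .bayes import PriorFamily, PriorSpec
from .classical import PlottingPosition
from .model import LomaxParams

__all__ = ["StudyDesign", "MSETable", "run_study", "format_tables"]

PRIOR_ORDER = (
    PriorFamily.EXTENDED_JEFFREYS,
    PriorFamily.CHI_SQUARE,
    PriorFamily.INVERTED_LEVY,
    PriorFamily.GAMMA,
)

_ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X")


def case_label(index: int) -> str:
    return _ROMAN[index] if index < len(_ROMAN) else str(index + 1)


@dataclass(frozen=True)
class StudyDesign:
    """Full configuration of the simulation study.

    Defaults are the standard design: cases I-III share scale 2 with
    shapes 1.5, 2.0, 2.5 (scale >, =, < shape); n in {20, ..., 100};
    10,000 replicates; ridge penalty 0.75; prior hyperparameters c=0.5,
    (k, d)=(0.6, 0.2); LINEX asymmetries {0.5, 1, 1.5}.
    """

    cases: Tuple[Tuple[float, float], ...] = ((2.0, 1.5), (2.0, 2.0), (2.0, 2.5))
    sample_sizes: Tuple[int, ...] = (20, 40, 60, 80, 100)
    reps: int = 10_000
    lam: float = 0.75
    c: float = 0.5
    k: float = 0.6
    d: float = 0.2
    a_values: Tuple[float, ...] = (0.5, 1.0, 1.5)
    pp: PlottingPosition = PlottingPosition.MEDIAN_RANK
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "cases", tuple((float(s), float(t)) for s, t in self.cases))
        object.__setattr__(self, "sample_sizes", tuple(int(n) for n in self.sample_sizes))
        object.__setattr__(self, "a_values", tuple(float(a) for a in self.a_values))
        object.__setattr__(self, "pp", PlottingPosition(self.pp))
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        for scale, shape in self.cases:
            LomaxParams(shape=shape, scale=scale)  # validates positivity
        if any(n < 2 for n in self.sample_sizes):
            raise ValueError("sample sizes must be >= 2")

    def prior(self, family: PriorFamily) -> PriorSpec:
        return PriorSpec(family=family, c=self.c, k=self.k, d=self.d)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "cases": [list(c) for c in self.cases],
            "sample_sizes": list(self.sample_sizes),
            "reps": self.reps,
            "lam": self.lam,
            "c": self.c,
            "k": self.k,
            "d": self.d,
            "a_values": list(self.a_values),
            "pp": self.pp.value,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "StudyDesign":
        kwargs = dict(data)
        if "cases" in kwargs:
            kwargs["cases"] = tuple(tuple(c) for c in kwargs["cases"])
        if "sample_sizes" in kwargs:
            kwargs["sample_sizes"] = tuple(kwargs["sample_sizes"])
        if "a_values" in kwargs:
            kwargs["a_values"] = tuple(kwargs["a_values"])
        return cls(**kwargs)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "StudyDesign":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    # -- column layout ----------------------------------------------------

    @property
    def classical_columns(self) -> List[str]:
        return ["MLE", "OLS", "Rid", "UMVUE", "Med"]

    def prior_columns(self, family: PriorFamily) -> List[str]:
        cols = [f"{family.value}:SELF"]
        cols += [f"{family.value}:LLF(a={a:g})" for a in self.a_values]
        cols += [f"{family.value}:CLLF(a={a:g})" for a in self.a_values]
        return cols

    @property
    def all_columns(self) -> List[str]:
        cols = list(self.classical_columns)
        for family in PRIOR_ORDER:
            cols += self.prior_columns(family)
        return cols


@dataclass(frozen=True)
class MSETable:
    """Estimator-by-(case, n) grid of Monte Carlo MSEs with standard errors."""

    mse: pd.DataFrame  # rows MultiIndex (case, n), columns = estimator ids
    se: pd.DataFrame   # same layout; SE of each MSE cell
    design: StudyDesign

    def cell(self, case: str, n: int, column: str) -> Tuple[float, float]:
        return float(self.mse.loc[(case, n), column]), float(self.se.loc[(case, n), column])

    def is_complete(self) -> bool:
        expected = pd.MultiIndex.from_product(
            [[case_label(i) for i in range(len(self.design.cases))], self.design.sample_sizes],
            names=["case", "n"],
        )
        return (
            self.mse.index.equals(expected)
            and list(self.mse.columns) == self.design.all_columns
            and not self.mse.isna().any().any()
        )

    def save(self, outdir: Union[str, Path]) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        long = self.mse.stack().rename("mse").to_frame()
        long["se"] = self.se.stack()
        long.index.set_names(["case", "n", "estimator"], inplace=True)
        long.reset_index().to_csv(outdir / "cells.csv", index=False)
        self.design.to_yaml(outdir / "design.yaml")

    @classmethod
    def load(cls, outdir: Union[str, Path]) -> "MSETable":
        outdir = Path(outdir)
        design = StudyDesign.from_yaml(outdir / "design.yaml")
        long = pd.read_csv(outdir / "cells.csv")
        mse = long.pivot_table(index=["case", "n"], columns="estimator", values="mse")
        se = long.pivot_table(index=["case", "n"], columns="estimator", values="se")
        order = pd.MultiIndex.from_product(
            [[case_label(i) for i in range(len(design.cases))], design.sample_sizes],
            names=["case", "n"],
        )
        mse = mse.reindex(index=order, columns=design.all_columns)
        se = se.reindex(index=order, columns=design.all_columns)
        mse.columns.name = None
        se.columns.name = None
        return cls(mse=mse, se=se, design=design)


def _bayes_posterior_params(
    design: StudyDesign, family: PriorFamily, n: int, T: np.ndarray
) -> Tuple[float, np.ndarray]:
    if family is PriorFamily.EXTENDED_JEFFREYS:
        return n - 2.0 * design.c + 1.0, T
    if family is PriorFamily.CHI_SQUARE:
        return n + design.k / 2.0, T + design.d / 2.0
    if family is PriorFamily.INVERTED_LEVY:
        return n + 0.5, T + design.d / 2.0
    return n + design.k, T + design.d


def _cell_estimates(
    design: StudyDesign, params: LomaxParams, n: int, rng: np.random.Generator
) -> Dict[str, np.ndarray]:
    """All estimator values on ``reps`` paired replicates of size n."""
    reps = design.reps
    scale, theta = params.scale, params.shape
    u = rng.random((reps, n))
    x = scale * ((1.0 - u) ** (-1.0 / theta) - 1.0)

    T = np.log1p(x / scale).sum(axis=1)
    if np.any(T <= 0):
        bad = int(np.argmax(T <= 0))
        raise RuntimeError(f"degenerate replicate {bad}: T = 0 (all observations zero)")

    est: Dict[str, np.ndarray] = {}
    est["MLE"] = n / T
    est["UMVUE"] = (n - 1) / T

    # probability-plot regressions: the rank response y depends on (i, n) only
    xs = np.sort(x, axis=1)
    x_star = np.log(scale + xs)
    y = np.log(1.0 - design.pp.positions(n))
    sum_x = x_star.sum(axis=1)
    sum_xx = (x_star * x_star).sum(axis=1)
    sum_xy = (x_star * y).sum(axis=1)
    sum_y = float(y.sum())
    for name, lam in (("OLS", 0.0), ("Rid", design.lam)):
        denom = (n + lam) * sum_xx - sum_x * sum_x
        if np.any(denom == 0):
            bad = int(np.argmax(denom == 0))
            raise RuntimeError(f"singular design in replicate {bad}")
        est[name] = -((n + lam) * sum_xy - sum_x * sum_y) / denom

    x_med = np.median(x, axis=1)
    if np.any(x_med <= 0):
        bad = int(np.argmax(x_med <= 0))
        raise RuntimeError(f"degenerate replicate {bad}: sample median is zero")
    est["Med"] = -np.log(0.5) / np.log1p(x_med / scale)

    for family in PRIOR_ORDER:
        A, B = _bayes_posterior_params(design, family, n, T)
        est[f"{family.value}:SELF"] = A / B
        for a in design.a_values:
            est[f"{family.value}:LLF(a={a:g})"] = (A / a) * np.log1p(a / B)
        for a in design.a_values:
            if np.any(B <= a):
                bad = int(np.argmax(B <= a))
                raise RuntimeError(
                    f"composite-LINEX estimate undefined in replicate {bad}: "
                    f"posterior rate {B[bad]:.6g} <= a = {a}"
                )
            est[f"{family.value}:CLLF(a={a:g})"] = (A / a) * np.arctanh(a / B)
    return est


def run_study(design: StudyDesign, progress: bool = False) -> MSETable:
    """Run the full simulation grid; deterministic given ``design.seed``.

    One root seed spawns an independent substream per (case, n) cell, so
    any cell can be recomputed in isolation with the same result.
    """
    labels = [case_label(i) for i in range(len(design.cases))]
    index = pd.MultiIndex.from_product([labels, design.sample_sizes], names=["case", "n"])
    columns = design.all_columns
    mse = pd.DataFrame(np.nan, index=index, columns=columns)
    se = pd.DataFrame(np.nan, index=index, columns=columns)

    root = np.random.SeedSequence(design.seed)
    streams = root.spawn(len(design.cases) * len(design.sample_sizes))
    pos = 0
    for ci, (scale, theta) in enumerate(design.cases):
        params = LomaxParams(shape=theta, scale=scale)
        for n in design.sample_sizes:
            rng = np.random.default_rng(streams[pos])
            pos += 1
            estimates = _cell_estimates(design, params, n, rng)
            for col, values in estimates.items():
                sq = (values - theta) ** 2
                mse.loc[(labels[ci], n), col] = sq.mean()
                se.loc[(labels[ci], n), col] = (
                    sq.std(ddof=1) / np.sqrt(design.reps) if design.reps > 1 else np.nan
                )
            if progress:
                print(f"case {labels[ci]} (scale={scale:g}, shape={theta:g}) "
                      f"n={n}: {design.reps} replicates done")
    return MSETable(mse=mse, se=se, design=design)


def t_estimator(design: StudyDesign, column: str):
    """Return (g, t_lower) for a T-measurable column, for the risk oracle.

    ``g(n, t)`` evaluates the column's estimator from the sufficient
    statistic alone; ``t_lower(n)`` is the left edge of its existence
    region (nonzero only for composite LINEX, where the posterior rate
    must exceed the asymmetry a).  OLS/Rid/Med depend on the full order
    statistics and have no such reduction.
    """
    if column in ("MLE", "UMVUE"):
        shift = 0 if column == "MLE" else 1
        return (lambda n, t: (n - shift) / t), (lambda n: 0.0)
    if column in ("OLS", "Rid", "Med"):
        raise ValueError(f"{column} is not a function of T alone")
    prior_name, loss_name = column.split(":", 1)
    family = PriorFamily(prior_name)

    def post(n: int, t):
        return _bayes_posterior_params(design, family, n, np.asarray(t, dtype=float))

    offset = {PriorFamily.EXTENDED_JEFFREYS: 0.0,
              PriorFamily.CHI_SQUARE: design.d / 2.0,
              PriorFamily.INVERTED_LEVY: design.d / 2.0,
              PriorFamily.GAMMA: design.d}[family]
    if loss_name == "SELF":
        return (lambda n, t: post(n, t)[0] / post(n, t)[1]), (lambda n: 0.0)
    kind, a_str = loss_name[:-1].split("(a=")
    a = float(a_str)
    if kind == "LLF":
        def g(n, t, a=a):
            A, B = post(n, t)
            return (A / a) * np.log1p(a / B)
        return g, (lambda n: 0.0)
    if kind == "CLLF":
        def g(n, t, a=a):
            A, B = post(n, t)
            return (A / a) * np.arctanh(a / B)
        return g, (lambda n, a=a, offset=offset: max(0.0, a - offset))
    raise ValueError(f"unrecognised column {column!r}")


def _table_frames(table: MSETable) -> Dict[str, pd.DataFrame]:
    """Split the grid into the classical table and one per prior."""
    design = table.design
    frames = {"classical": table.mse[design.classical_columns]}
    for family in PRIOR_ORDER:
        sub = table.mse[design.prior_columns(family)]
        sub = sub.rename(columns=lambda name: name.split(":", 1)[1])
        frames[family.value] = sub
    return frames


def format_tables(
    table: MSETable,
    outdir: Union[str, Path],
    decimals: int = 4,
) -> List[Path]:
    """Write one CSV per table (full precision) plus a Markdown report.

    Refuses an incomplete grid: every (case, n, estimator) cell must be
    present before anything is written.
    """
    if not table.is_complete():
        raise ValueError("MSE grid is incomplete; refusing to write tables")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    report = ["# Monte Carlo MSE tables", ""]
    titles = {
        "classical": "Classical estimators",
        "extended_jeffreys": "Bayes estimators, extended Jeffreys prior",
        "chi_square": "Bayes estimators, chi-square prior",
        "inverted_levy": "Bayes estimators, inverted Levy prior",
        "gamma": "Bayes estimators, gamma prior",
    }
    for key, frame in _table_frames(table).items():
        path = outdir / f"{key}.csv"
        frame.to_csv(path)
        written.append(path)
        report.append(f"## {titles[key]}")
        report.append("")
        report.append(_markdown(frame.round(decimals)))
        report.append("")
    md = outdir / "report.md"
    md.write_text("\n".join(report))
    written.append(md)
    return written


def _markdown(frame: pd.DataFrame) -> str:
    flat = frame.reset_index()
    header = "| " + " | ".join(str(c) for c in flat.columns) + " |"
    rule = "|" + "|".join("---" for _ in flat.columns) + "|"
    rows = [
        "| " + " | ".join(f"{v:.4f}" if isinstance(v, float) else str(v) for v in row) + " |"
        for row in flat.itertuples(index=False)
    ]
    return "\n".join([header, rule] + rows)
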