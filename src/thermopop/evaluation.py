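"""Simulation-based evaluation of designs and estimators, with CART summaries.

For each cell of a factorial grid (design x true activation energy x
Monte-Carlo replicate), a dataset is simulated, one or more methods are run
on the *same* data (so method comparisons are paired), and two percentage
metrics are recorded:

    R = 100 * |m(E_A) - E_A| / E_A      (relative error; accuracy = 1/R)
    P = 100 * se(E_A) / E_A             (precision, relative scale of the SE)

A classification-and-regression-tree (CART) analysis of R on the four design
factors (FRACSAMP, TIMESAMP, TEMPSAMP, REPS) then ranks which experimental
choices drive estimation error.
"""

from __future__ import annotations

import dataclasses
import itertools
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ArrheniusModel, T0_DEFAULT
from .inference import ChainConfig, EAEstimate, run_methods
from .simulate import (
    FRACSAMP_LEVELS,
    ExperimentalDesign,
    simulate_design,
)

__all__ = [
    "EA_GRID_FULL",
    "DESIGN_FACTORS",
    "EvaluationRecord",
    "RegressionTree",
    "TreeNode",
    "baseline_model",
    "design_grid",
    "full_design_grid",
    "error_metrics",
    "run_factorial",
    "cart",
]

#: activation energies spanning the plausible metabolic range (eV)
EA_GRID_FULL: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0, 1.2)

DESIGN_FACTORS = ("FRACSAMP", "TIMESAMP", "TEMPSAMP", "REPS")

#: baseline rates at T0: birth 1.5/d, density coefficient 1, death 0.5/d,
#: ceiling N = 15000 -> r(T0) = 1/d, K(T0) = 10000
_BASELINE = dict(theta01=1.5, theta02=1.0, theta03=0.5, N=15000)


def baseline_model(e_a, T0: float = T0_DEFAULT) -> ArrheniusModel:
    """The reference parameterization with the given activation energy (eV)."""
    return ArrheniusModel(e_a=e_a, T0=T0, **_BASELINE)


def design_grid(
    tempsamp=(3, 6, 11),
    reps=(1, 3, 5),
    timesamp=(5, 10, 15),
    fracsamp=FRACSAMP_LEVELS,
) -> list[ExperimentalDesign]:
    """Cartesian product of factor levels -> list of designs."""
    return [
        ExperimentalDesign.from_levels(ts, rp, tm, fs)
        for ts, rp, tm, fs in itertools.product(tempsamp, reps, timesamp, fracsamp)
    ]


def full_design_grid() -> list[ExperimentalDesign]:
    """All 81 design cells (3 levels of each of the four factors)."""
    return design_grid()


@dataclass(frozen=True)
class EvaluationRecord:
    """One (design x method x true E_A x Monte-Carlo run) result row."""

    FRACSAMP: float
    TIMESAMP: int
    TEMPSAMP: int
    REPS: int
    true_ea: float
    method: str
    mc: int
    m_ea: float = np.nan
    se_ea: float = np.nan
    R: float = np.nan
    P: float = np.nan
    status: str = "ok"

    def __post_init__(self) -> None:
        if self.status == "ok" and np.isfinite(self.R) and self.R < 0:
            raise ValueError("R must be >= 0")


def error_metrics(estimate: EAEstimate, true_ea: float) -> tuple[float, float]:
    """Relative error R and precision P of an estimate, in percent of true E_A."""
    if not true_ea > 0:
        raise ValueError("true_ea must be > 0")
    R = 100.0 * abs(estimate.mean - true_ea) / true_ea
    P = 100.0 * estimate.se / true_ea
    return R, P


def _cell_seed(master: int, i_design: int, i_ea: int, mc: int, stream: int) -> int:
    ss = np.random.SeedSequence([int(master), i_design, i_ea, mc, stream])
    return int(ss.generate_state(1, dtype=np.uint32)[0]) % (2**31)


def run_factorial(
    methods,
    designs,
    ea_grid,
    n_monte_carlo: int,
    seed: int,
    chain: ChainConfig | None = None,
    T0: float = T0_DEFAULT,
    dt: float = 0.025,
    checkpoint: str | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Sweep (designs x ea_grid x MC replicates x methods) -> records table.

    Every method in a cell sees the same simulated dataset; per-cell seeds are
    derived deterministically from ``seed``.  Individual failures are recorded
    with status "failed" and the sweep continues.  If ``checkpoint`` names a
    CSV file, completed cells are appended there and skipped on resume.
    """
    designs = list(designs)
    methods = list(methods)
    done: set[tuple] = set()
    rows: list[dict] = []
    if checkpoint and os.path.exists(checkpoint):
        prev = pd.read_csv(checkpoint)
        rows = prev.to_dict("records")
        done = {
            (r["FRACSAMP"], r["TIMESAMP"], r["TEMPSAMP"], r["REPS"],
             r["true_ea"], r["mc"], r["method"])
            for r in rows
        }
    for i_d, design in enumerate(designs):
        lv = design.levels
        for i_e, ea in enumerate(ea_grid):
            model = baseline_model(ea, T0=T0)
            for mc in range(n_monte_carlo):
                keybase = (lv["FRACSAMP"], lv["TIMESAMP"], lv["TEMPSAMP"],
                           lv["REPS"], ea, mc)
                todo = [m for m in methods if keybase + (m,) not in done]
                if not todo:
                    continue
                data_seed = _cell_seed(seed, i_d, i_e, mc, 0)
                dataset = simulate_design(model, design, data_seed)
                fit_seed = _cell_seed(seed, i_d, i_e, mc, 1)
                sub = chain or ChainConfig()
                sub = ChainConfig(sub.n_iter, sub.burn_frac, sub.n_keep,
                                  seed=fit_seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    ests = run_methods(todo, dataset, chain=sub, dt=dt)
                cell_rows = []
                for method in todo:
                    fields = dict(zip(
                        ("FRACSAMP", "TIMESAMP", "TEMPSAMP", "REPS", "true_ea", "mc"),
                        keybase,
                    ))
                    est = ests[method]
                    if isinstance(est, Exception):
                        rec = EvaluationRecord(method=method,
                                               status=f"failed: {est}", **fields)
                    else:
                        R, P = error_metrics(est, ea)
                        rec = EvaluationRecord(method=method, m_ea=est.mean,
                                               se_ea=est.se, R=R, P=P,
                                               status="ok", **fields)
                    cell_rows.append(dataclasses.asdict(rec))
                rows.extend(cell_rows)
                if checkpoint:
                    pd.DataFrame(cell_rows).to_csv(
                        checkpoint, mode="a", index=False,
                        header=not os.path.exists(checkpoint),
                    )
                if progress:
                    print(
                        f"[factorial] design {i_d + 1}/{len(designs)} "
                        f"ea={ea} mc={mc + 1}/{n_monte_carlo}",
                        flush=True,
                    )
    df = pd.DataFrame(rows)
    return df.reset_index(drop=True)


# ----------------------------------------------------------------------------
# CART
# ----------------------------------------------------------------------------

@dataclass
class TreeNode:
    """One node of a regression tree; leaves have ``var`` = None."""

    mean: float
    n: int
    var: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.var is None

    def render(self, indent: int = 0) -> str:
        pad = "  " * indent
        if self.is_leaf:
            return f"{pad}leaf: mean={self.mean:.1f}% (n={self.n})"
        lines = [f"{pad}{self.var} <= {self.threshold:g} "
                 f"(node mean={self.mean:.1f}%, n={self.n})"]
        lines.append(self.left.render(indent + 1))
        lines.append(self.right.render(indent + 1))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {"mean": self.mean, "n": self.n}
        if not self.is_leaf:
            d.update(var=self.var, threshold=self.threshold,
                     left=self.left.to_dict(), right=self.right.to_dict())
        return d


@dataclass
class RegressionTree:
    """SSE-minimizing binary regression tree of |R| on the design factors."""

    root: TreeNode
    response: str
    predictors: tuple[str, ...]
    records: int = 0
    diagnostics: dict = field(default_factory=dict)

    @property
    def first_split(self) -> str | None:
        return self.root.var

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node)
            else:
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out

    def render(self) -> str:
        return self.root.render()

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "predictors": list(self.predictors),
            "records": self.records,
            "tree": self.root.to_dict(),
        }


def cart(
    records: pd.DataFrame,
    response: str = "R",
    predictors: tuple[str, ...] = DESIGN_FACTORS,
    min_node: int = 5,
    complexity: float = 0.01,
) -> RegressionTree:
    """Greedy SSE-minimizing regression tree of |response| on design factors.

    A split is kept only if it reduces the total sum of squared errors by at
    least ``complexity`` (default 1%) of the root SSE; leaves contain at least
    ``min_node`` records.  Leaf means are in the same percent units as the
    response.
    """
    from sklearn.tree import DecisionTreeRegressor

    df = records.dropna(subset=[response])
    if len(df) < 20:
        raise ValueError(f"need >= 20 usable records, got {len(df)}")
    X = df[list(predictors)].to_numpy(dtype=float)
    y = np.abs(df[response].to_numpy(dtype=float))
    # sklearn's impurity decrease is (SSE reduction)/n_total, so a threshold of
    # complexity * Var(y) keeps exactly the splits cutting >= complexity * root SSE
    tree = DecisionTreeRegressor(
        criterion="squared_error",
        min_samples_leaf=min_node,
        min_impurity_decrease=complexity * float(np.var(y)),
        random_state=0,
    ).fit(X, y)
    t = tree.tree_

    def build(i: int) -> TreeNode:
        node = TreeNode(mean=float(t.value[i, 0, 0]), n=int(t.n_node_samples[i]))
        if t.children_left[i] != -1:
            node.var = predictors[int(t.feature[i])]
            node.threshold = float(t.threshold[i])
            node.left = build(int(t.children_left[i]))
            node.right = build(int(t.children_right[i]))
        return node

    return RegressionTree(
        root=build(0),
        response=response,
        predictors=tuple(predictors),
        records=len(df),
        diagnostics={"depth": int(tree.get_depth()),
                     "n_leaves": int(tree.get_n_leaves())},
    )
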