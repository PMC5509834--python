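"""Learning the prior kernel hyperparameter theta_0 from expert demonstrations.

Demonstration mapping sequences — (x, y, z, voltage) tables from previous
procedures in the same patient cohort — are concatenated (positions/values
pairing preserved, ordering ignored) and four candidate kernel families are
fitted by maximizing the GP log marginal likelihood from random restarts.
Families are then compared by held-out point-wise RMSE (5-fold CV over
points, seeded folds) and the winner's hyperparameters become theta_0, the
initial value the particle filter is centred on during a procedure.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.model_selection import KFold

from .gp_core import (
    KERNEL_FAMILIES,
    IllConditionedError,
    KernelSpec,
    ObservationSet,
    gp_posterior,
    lml_value_and_grad,
)
from .surfaces import dedupe_points

logger = logging.getLogger("cardiomap.prior")

#: Log-uniform random-initialization ranges, as multiples of the data scales
#: (domain diameter for l, var(y) for signal and noise variance).
INIT_RANGE_L = (0.05, 5.0)
INIT_RANGE_SF2 = (0.1, 10.0)
INIT_RANGE_NOISE = (1e-3, 0.1)

_FREE_PARAMS = {
    "linear": ("length_scale", "signal_variance", "noise_variance"),
    "squared_exponential": ("length_scale", "signal_variance", "noise_variance"),
    "matern": ("length_scale", "signal_variance", "noise_variance"),
    "rational_quadratic": ("length_scale", "signal_variance", "noise_variance", "alpha"),
}


@dataclass
class DemonstrationSet:
    """Per-case expert mapping data; each case is deduplicated and non-empty."""

    cases: dict[str, ObservationSet]

    def __post_init__(self) -> None:
        if not self.cases:
            raise ValueError("DemonstrationSet needs at least one case")
        for cid, obs in self.cases.items():
            if obs.n == 0:
                raise ValueError(f"case {cid!r} is empty")

    @property
    def case_ids(self) -> list[str]:
        return list(self.cases)

    @classmethod
    def from_csv(cls, path: str | Path, dedupe_tol: float = 1e-6) -> "DemonstrationSet":
        """Read a `case_id,x,y,z,value` table; duplicates removed per case."""
        df = pd.read_csv(path)
        required = {"case_id", "x", "y", "z", "value"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        bad = df[["x", "y", "z", "value"]].isna().any(axis=1)
        if bad.any():
            line = int(df.index[bad][0]) + 2  # header + 1-based
            raise ValueError(f"{path}: malformed row at line {line}")
        cases: dict[str, ObservationSet] = {}
        for cid, grp in df.groupby("case_id", sort=False):
            obs = ObservationSet(grp[["x", "y", "z"]].to_numpy(),
                                 grp["value"].to_numpy())
            obs, removed = dedupe_points(obs, dedupe_tol)
            if removed:
                logger.info("case %s: removed %d duplicate points", cid, removed)
            cases[str(cid)] = obs
        return cls(cases)


def concatenate_demonstrations(
    demos: DemonstrationSet, exclude: str | None = None
) -> ObservationSet:
    """Row-stack all cases (optionally leaving one out), pairing preserved."""
    keep = [cid for cid in demos.case_ids if cid != exclude]
    if not keep:
        raise ValueError("no cases remain after exclusion")
    X = np.vstack([demos.cases[cid].X for cid in keep])
    y = np.concatenate([demos.cases[cid].y for cid in keep])
    return ObservationSet(X, y)


@dataclass
class FamilyFit:
    """Outcome of fitting one kernel family."""

    family: str
    spec: KernelSpec | None
    log_marginal_likelihood: float
    cv_rmse: float
    train_rmse: float
    n_restarts: int
    n_converged: int
    failed: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["spec"] = self.spec.to_dict() if self.spec else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FamilyFit":
        d = dict(d)
        d["spec"] = KernelSpec.from_dict(d["spec"]) if d["spec"] else None
        return cls(**d)


@dataclass
class KernelFitReport:
    """Per-family fits plus the selected family."""

    fits: list[FamilyFit]
    selected_family: str
    seed: int
    n_points: int
    n_folds: int

    def best(self) -> FamilyFit:
        return next(f for f in self.fits if f.family == self.selected_family)

    def to_json(self) -> str:
        return json.dumps({
            "fits": [f.to_dict() for f in self.fits],
            "selected_family": self.selected_family,
            "seed": self.seed, "n_points": self.n_points,
            "n_folds": self.n_folds,
        }, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "KernelFitReport":
        d = json.loads(text)
        return cls(fits=[FamilyFit.from_dict(f) for f in d["fits"]],
                   selected_family=d["selected_family"], seed=d["seed"],
                   n_points=d["n_points"], n_folds=d["n_folds"])


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _random_spec(family: str, rng: np.random.Generator, diameter: float,
                 var_y: float) -> KernelSpec:
    def logu(lo, hi):
        return float(np.exp(rng.uniform(math.log(lo), math.log(hi))))

    return KernelSpec(
        family=family,
        length_scale=logu(*INIT_RANGE_L) * diameter,
        signal_variance=logu(*INIT_RANGE_SF2) * var_y,
        noise_variance=logu(*INIT_RANGE_NOISE) * var_y,
        alpha=logu(0.2, 5.0) if family == "rational_quadratic" else 1.0,
    )


def _optimize_family(family: str, obs: ObservationSet, restarts: int,
                     rng: np.random.Generator) -> tuple[KernelSpec | None, float, int]:
    diameter = max(float(np.linalg.norm(obs.X.max(0) - obs.X.min(0))), 1e-6)
    var_y = max(float(np.var(obs.y)), 1e-12)
    free = _FREE_PARAMS[family]
    # generous bounds in log domain keep the optimizer out of degenerate corners
    bounds_map = {
        "length_scale": (math.log(1e-3 * diameter), math.log(1e2 * diameter)),
        "signal_variance": (math.log(1e-4 * var_y), math.log(1e4 * var_y)),
        "noise_variance": (math.log(1e-8 * var_y), math.log(1e2 * var_y)),
        "alpha": (math.log(1e-2), math.log(1e3)),
    }
    bounds = [bounds_map[p] for p in free]

    def neg_lml(log_theta: np.ndarray):
        spec = _spec_from_log(family, free, log_theta)
        try:
            lml, grad = lml_value_and_grad(spec, obs, free)
        except (IllConditionedError, FloatingPointError):
            return 1e12, np.zeros_like(log_theta)
        if not np.isfinite(lml):
            return 1e12, np.zeros_like(log_theta)
        return -lml, -grad

    best: tuple[KernelSpec | None, float] = (None, -np.inf)
    n_conv = 0
    for _ in range(restarts):
        spec0 = _random_spec(family, rng, diameter, var_y)
        x0 = np.array([math.log(getattr(spec0, p)) for p in free])
        res = minimize(neg_lml, x0, jac=True, method="L-BFGS-B", bounds=bounds)
        if not np.isfinite(res.fun) or res.fun >= 1e12:
            continue
        n_conv += 1
        if -res.fun > best[1]:
            best = (_spec_from_log(family, free, res.x), -res.fun)
    return best[0], best[1], n_conv


def _spec_from_log(family: str, free, log_theta) -> KernelSpec:
    kwargs = {p: float(np.exp(v)) for p, v in zip(free, log_theta)}
    base = dict(family=family, length_scale=1.0, signal_variance=1.0)
    base.update(kwargs)
    return KernelSpec(**base)


def _cv_rmse(spec: KernelSpec, obs: ObservationSet, n_folds: int, seed: int) -> float:
    """Held-out RMSE of GP regression at fixed hyperparameters (seeded folds).

    Fold training values are centred (zero-mean GP) and the mean re-added.
    """
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    se = np.empty(obs.n)
    for train, test in kf.split(obs.X):
        ybar = float(obs.y[train].mean())
        sub = ObservationSet(obs.X[train], obs.y[train] - ybar)
        post = gp_posterior(spec, sub, obs.X[test])
        se[test] = (post.mean + ybar - obs.y[test]) ** 2
    return float(np.sqrt(se.mean()))


def _train_rmse(spec: KernelSpec, obs: ObservationSet) -> float:
    ybar = float(obs.y.mean())
    sub = ObservationSet(obs.X, obs.y - ybar)
    post = gp_posterior(spec, sub, obs.X)
    return float(np.sqrt(np.mean((post.mean + ybar - obs.y) ** 2)))


def fit_kernel(
    obs: ObservationSet,
    families=KERNEL_FAMILIES,
    restarts: int = 5,
    seed: int = 0,
    n_folds: int = 5,
) -> tuple[KernelSpec, KernelFitReport]:
    """Fit each family by evidence maximization, select by CV-RMSE.

    Returns the winning family's spec (theta_0) and the full per-family
    report (both held-out and training RMSE are recorded).
    """
    if obs.n < 10:
        raise ValueError("need at least 10 observations to fit a kernel prior")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    rng = np.random.default_rng(seed)
    fits: list[FamilyFit] = []
    for family in families:
        spec, lml, n_conv = _optimize_family(family, obs, restarts, rng)
        if spec is None:
            logger.warning("family %s failed on all %d restarts", family, restarts)
            fits.append(FamilyFit(family, None, -np.inf, np.inf, np.inf,
                                  restarts, 0, failed=True))
            continue
        cv = _cv_rmse(spec, obs, n_folds, seed)
        tr = _train_rmse(spec, obs)
        logger.info("family %-20s lml=%10.2f cv_rmse=%.4f", family, lml, cv)
        fits.append(FamilyFit(family, spec, lml, cv, tr, restarts, n_conv))
    ok = [f for f in fits if not f.failed]
    if not ok:
        raise RuntimeError("all kernel families failed to fit")
    winner = min(ok, key=lambda f: f.cv_rmse)
    report = KernelFitReport(fits=fits, selected_family=winner.family,
                             seed=seed, n_points=obs.n, n_folds=n_folds)
    return winner.spec, report
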