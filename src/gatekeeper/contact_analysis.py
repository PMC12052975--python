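"""Transport classification from contact features and the electronic
binding-energy relation.

Adjusted contact frequencies from many (molecule, variant, replicate)
simulations are assembled into a design matrix; an L2-regularized logistic
regression of the binary transport outcome then yields signed per-residue
coefficients: positive coefficients mark residues whose contacts promote
transport, negative ones residues whose contacts counteract it.

The fit minimizes

    mean cross-entropy + (lambda/2) * ||beta||^2     (intercept unpenalized)

by a damped Newton iteration from a zero start, so refits are bit-stable
and the label-flip symmetry (y -> 1-y negates all coefficients) holds
exactly.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd

from .pulling import ContactFrequencyTable

__all__ = [
    "DesignMatrix",
    "LogisticModel",
    "BindingEnergyComponents",
    "build_design_matrix",
    "fit_logistic",
    "residue_importance",
    "electronic_binding_energy",
    "classify_binding",
]


def residue_number(label: str) -> int:
    """Residue number parsed from a label like 'I585' (0 if none)."""
    m = re.search(r"(\d+)", label)
    return int(m.group(1)) if m else 0


def _column_order(labels) -> list:
    return sorted(labels, key=lambda s: (residue_number(s), s))


@dataclass
class DesignMatrix:
    """Rows = simulations, columns = residues, values = adjusted frequency."""

    values: pd.DataFrame  # index: (molecule, variant, replicate)
    standardized: bool = False
    column_means: np.ndarray | None = None
    column_sds: np.ndarray | None = None

    @property
    def residues(self) -> list:
        return list(self.values.columns)


@dataclass
class LogisticModel:
    """Fitted L2-regularized logistic classifier."""

    beta: pd.Series  # per-residue coefficients
    intercept: float
    lam: float
    iterations: int
    gradient_norm: float
    converged: bool
    standardized: bool = False

    def predict_proba(self, X: DesignMatrix) -> np.ndarray:
        eta = self.intercept + X.values.to_numpy() @ self.beta.to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass(frozen=True)
class BindingEnergyComponents:
    """DFT-derived electronic energies (shared units, e.g. kcal/mol)."""

    E_PL: float
    E_P: float
    E_L: float

    def __post_init__(self):
        for name in ("E_PL", "E_P", "E_L"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def build_design_matrix(tables: Sequence[ContactFrequencyTable],
                        labels: pd.DataFrame,
                        standardize: bool = True) -> Tuple[DesignMatrix, np.ndarray]:
    """Assemble the (simulations x residues) matrix and label vector.

    ``labels`` maps (molecule, variant) to transported in {0, 1}. Residue
    columns are the union over tables; residues absent from a table are
    filled with 0. With ``standardize`` each column is z-scored (population
    sd; constant columns left at 0) and the parameters stored.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 simulations")
    lab = labels.set_index(["molecule", "variant"])["transported"]
    rows = {}
    y = []
    missing = []
    for i, t in enumerate(tables):
        mol = t.metadata.get("molecule", f"mol{i}")
        var = t.metadata.get("variant", "Wt")
        rep = t.metadata.get("replicate", i)
        key = (mol, var)
        if key not in lab.index:
            missing.append(key)
            continue
        s = t.table.set_index("residue")["adjusted_frequency"]
        rows[(mol, var, rep)] = s
        y.append(int(lab.loc[key]))
    if missing:
        raise ValueError(f"unlabeled simulations: {sorted(set(missing))}")
    X = pd.DataFrame(rows).T.fillna(0.0)
    X = X[_column_order(X.columns)]
    X.index = pd.MultiIndex.from_tuples(X.index, names=["molecule", "variant", "replicate"])
    y = np.asarray(y, dtype=float)
    means = sds = None
    if standardize:
        means = X.to_numpy().mean(axis=0)
        sds = X.to_numpy().std(axis=0)  # population sd
        safe = np.where(sds > 0, sds, 1.0)
        X = (X - means) / safe
    return DesignMatrix(values=X, standardized=standardize,
                        column_means=means, column_sds=sds), y


def logistic_objective(X: np.ndarray, y: np.ndarray, beta: np.ndarray,
                       intercept: float, lam: float) -> float:
    """Mean cross-entropy plus the L2 penalty (intercept unpenalized)."""
    eta = intercept + X @ beta
    # log(1 + exp(-|eta|)) formulation for numerical stability
    ll = np.where(eta >= 0, np.log1p(np.exp(-eta)) + (1 - y) * eta,
                  np.log1p(np.exp(eta)) - y * eta)
    return float(ll.mean() + 0.5 * lam * beta @ beta)


def fit_logistic(X: DesignMatrix, y: np.ndarray, lam: float = 1.0,
                 max_iter: int = 100, tol: float = 1e-8) -> LogisticModel:
    """Damped Newton fit of the penalized logistic objective.

    The objective is non-increasing across accepted iterations (step
    halving) and iteration stops when the gradient norm drops below
    ``tol``. Non-convergence at ``max_iter`` flags the model and warns.
    """
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    A = X.values.to_numpy(dtype=float)
    n, p = A.shape
    if lam == 0:
        # perfect separation has no finite optimum without a penalty
        warnings.warn("lambda = 0: coefficients unbounded on separable data",
                      stacklevel=2)
    theta = np.zeros(p + 1)  # [intercept, beta]
    pen = np.concatenate([[0.0], np.full(p, lam)])
    ones = np.ones((n, 1))
    Z = np.hstack([ones, A])

    def grad_hess(theta):
        eta = Z @ theta
        prob = 1.0 / (1.0 + np.exp(-eta))
        g = Z.T @ (prob - y) / n + pen * theta
        w = prob * (1.0 - prob)
        H = (Z * w[:, None]).T @ Z / n + np.diag(pen)
        return g, H

    obj = logistic_objective(A, y, theta[1:], theta[0], lam)
    it = 0
    gnorm = np.inf
    for it in range(1, max_iter + 1):
        g, H = grad_hess(theta)
        gnorm = float(np.linalg.norm(g))
        if gnorm < tol:
            break
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        t = 1.0
        for _ in range(50):
            cand = theta - t * step
            cobj = logistic_objective(A, y, cand[1:], cand[0], lam)
            if cobj <= obj:
                theta = cand
                obj = cobj
                break
            t *= 0.5
        else:  # no descent step found; gradient already ~ machine precision
            break
    g, _ = grad_hess(theta)
    gnorm = float(np.linalg.norm(g))
    converged = gnorm < tol
    if not converged:
        warnings.warn(f"logistic fit did not converge (|grad| = {gnorm:.2e})",
                      stacklevel=2)
    return LogisticModel(beta=pd.Series(theta[1:], index=X.residues),
                         intercept=float(theta[0]), lam=lam, iterations=it,
                         gradient_norm=gnorm, converged=converged,
                         standardized=X.standardized)


def residue_importance(model: LogisticModel, dead_zone: float = 1e-10) -> pd.DataFrame:
    """Signed residue ranking: promote (>0) / counteract (<0) / neutral.

    Sorted by |coefficient| descending, ties broken by residue number.
    """
    beta = model.beta
    cls = np.where(beta > dead_zone, "promote",
                   np.where(beta < -dead_zone, "counteract", "neutral"))
    df = pd.DataFrame({"residue": beta.index, "coefficient": beta.to_numpy(),
                       "class": cls})
    df["_num"] = [residue_number(r) for r in df.residue]
    df = df.sort_values(by=["coefficient", "_num"],
                        key=lambda s: -s.abs() if s.name == "coefficient" else s)
    return df.drop(columns="_num").reset_index(drop=True)


def electronic_binding_energy(c: BindingEnergyComponents) -> float:
    """E_el = E_PL - (E_P + E_L): negative favors binding."""
    return c.E_PL - (c.E_P + c.E_L)


def classify_binding(e_el: float, tol: float = 0.0) -> str:
    """'binder' if E_el < 0, 'non-binder' if > 0, else 'undetermined'."""
    if e_el < -tol:
        return "binder"
    if e_el > tol:
        return "non-binder"
    return "undetermined"
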