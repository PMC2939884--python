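"""Single-QTL LOD scans.

Two models, mirroring standard intercross interval-mapping practice:

* Haley-Knott regression for the quantitative traits: at each position the
  trait is regressed on the additive dosage a = P(BB) - P(AA) and the
  dominance regressor d = P(AB), and LOD = (n/2) log10(RSS0/RSS1) against
  the covariate-only null.
* A binary (logistic) model for incidence: LOD = (l1 - l0)/ln 10 from the
  maximized log-likelihoods, with complete separation handled by a small
  fixed ridge penalty (1e-4) and a logged flag.

Sex can enter as an additive or interactive covariate; for the covariate
scans the null model always contains the covariate, so the interactive scan
dominates the additive scan position-wise (nested models).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .formats import PhenotypeTable, ScanResult
from .genoprob import GenoProbGrid

logger = logging.getLogger(__name__)

__all__ = [
    "CovariateSpec",
    "scan_hk",
    "scan_binary",
    "scan_with_sex_models",
    "encode_sex",
]

#: Fixed ridge magnitude used when logistic fits separate.
SEPARATION_RIDGE = 1e-4
#: RSS floor below which a Haley-Knott fit is treated as numerically perfect.
RSS_FLOOR = 1e-12


@dataclass(frozen=True)
class CovariateSpec:
    """A covariate and its role in the scan model."""

    name: str | None = None
    role: str = "none"  # none | additive | interactive

    def __post_init__(self) -> None:
        if self.role not in ("none", "additive", "interactive"):
            raise ValueError("role must be none, additive or interactive")
        if self.role != "none" and not self.name:
            raise ValueError("a named covariate is required for this role")

    @property
    def label(self) -> str:
        return "none" if self.role == "none" else f"{self.name}:{self.role}"


NO_COVARIATE = CovariateSpec()


def encode_sex(phenos: PhenotypeTable) -> np.ndarray:
    """Sex as 0 (F) / 1 (M), aligned with the phenotype table rows."""
    return (phenos.table["sex"].to_numpy() == "M").astype(float)


def _design(
    a: np.ndarray, d: np.ndarray, x: np.ndarray | None, role: str
) -> tuple[np.ndarray, np.ndarray]:
    """Null and alternative design matrices for one position."""
    n = a.size
    one = np.ones(n)
    if role == "none" or x is None:
        X0 = np.column_stack([one])
        X1 = np.column_stack([one, a, d])
    elif role == "additive":
        X0 = np.column_stack([one, x])
        X1 = np.column_stack([one, x, a, d])
    else:  # interactive: QTL main effects plus QTL x covariate terms
        X0 = np.column_stack([one, x])
        X1 = np.column_stack([one, x, a, d, a * x, d * x])
    return X0, X1


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def scan_hk(
    trait_values: np.ndarray,
    probs: GenoProbGrid,
    cov: CovariateSpec = NO_COVARIATE,
    covariate_values: np.ndarray | None = None,
    trait_name: str = "trait",
) -> ScanResult:
    """Haley-Knott regression scan for a quantitative trait.

    ``trait_values`` is aligned with ``probs.ids``; individuals with the
    trait undefined (NaN) are dropped rather than imputed.
    """
    y = np.asarray(trait_values, float)
    if y.size != probs.n_individuals:
        raise ValueError("trait vector does not match the probability grid")
    keep = np.isfinite(y)
    if cov.role != "none":
        if covariate_values is None:
            raise ValueError(f"covariate {cov.name!r} values are required")
        covariate_values = np.asarray(covariate_values, float)
        keep &= np.isfinite(covariate_values)
    n = int(keep.sum())
    if n < 8:
        raise ValueError(f"need >= 8 non-missing trait values, got {n}")
    y = y[keep]
    if float(np.var(y)) <= 0:
        raise ValueError("trait variance is zero")
    x = covariate_values[keep] if cov.role != "none" else None

    a_all, d_all = probs.dosage()
    a_all, d_all = a_all[keep], d_all[keep]

    lod = np.empty(probs.positions.size)
    flags: list[str] = []
    for j in range(probs.positions.size):
        X0, X1 = _design(a_all[:, j], d_all[:, j], x, cov.role)
        rss0 = _rss(X0, y)
        rss1 = _rss(X1, y)
        if rss1 < RSS_FLOOR:
            logger.warning(
                "perfect fit at position %.3f Mb; LOD capped",
                probs.positions[j],
            )
            flags.append("perfect_fit")
            rss1 = RSS_FLOOR
        lod[j] = max(0.0, (n / 2.0) * math.log10(rss0 / rss1))

    return ScanResult(
        positions=probs.positions,
        lod=lod,
        trait=trait_name,
        model="haley_knott",
        covariate=cov.label,
        n=n,
        markers=probs.markers,
        flags=tuple(sorted(set(flags))),
    )


# ---------------------------------------------------------------------------
# binary model
# ---------------------------------------------------------------------------


def _logistic_loglik(X, y, beta):
    eta = X @ beta
    # log(1+e^eta) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _fit_logistic(X, y, ridge: float = 0.0, max_iter: int = 60):
    """Newton-Raphson fit; returns (beta, converged, separated)."""
    n, k = X.shape
    beta = np.zeros(k)
    separated = False
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        grad = X.T @ (y - p) - ridge * beta
        H = (X.T * w) @ X + (ridge + 1e-10) * np.eye(k)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            separated = True
            break
        beta = beta + step
        if np.abs(step).max() < 1e-10:
            converged = True
            break
    if np.abs(beta).max() > 15.0:
        separated = True
    return beta, converged, separated


def scan_binary(
    inc_values: np.ndarray,
    probs: GenoProbGrid,
    cov: CovariateSpec = NO_COVARIATE,
    covariate_values: np.ndarray | None = None,
    trait_name: str = "INC",
) -> ScanResult:
    """Logistic-model scan for the binary incidence trait."""
    y = np.asarray(inc_values, float)
    if y.size != probs.n_individuals:
        raise ValueError("trait vector does not match the probability grid")
    keep = np.isfinite(y)
    if cov.role != "none":
        if covariate_values is None:
            raise ValueError(f"covariate {cov.name!r} values are required")
        covariate_values = np.asarray(covariate_values, float)
        keep &= np.isfinite(covariate_values)
    y = y[keep]
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("binary trait must be coded 0/1")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    n = y.size
    x = covariate_values[keep] if cov.role != "none" else None

    a_all, d_all = probs.dosage()
    a_all, d_all = a_all[keep], d_all[keep]

    lod = np.empty(probs.positions.size)
    flags: list[str] = []
    null_cache: dict[int, float] = {}
    for j in range(probs.positions.size):
        X0, X1 = _design(a_all[:, j], d_all[:, j], x, cov.role)
        key = X0.shape[1]
        if key not in null_cache:
            b0, *_ = _fit_logistic(X0, y)
            null_cache[key] = _logistic_loglik(X0, y, b0)
        ll0 = null_cache[key]
        b1, conv, sep = _fit_logistic(X1, y)
        if sep or not conv:
            logger.warning(
                "separation/non-convergence at %.3f Mb; refitting with "
                "ridge %.0e", probs.positions[j], SEPARATION_RIDGE,
            )
            flags.append("ridge")
            b1, *_ = _fit_logistic(X1, y, ridge=SEPARATION_RIDGE)
        ll1 = _logistic_loglik(X1, y, b1)
        lod[j] = max(0.0, (ll1 - ll0) / math.log(10.0))

    return ScanResult(
        positions=probs.positions,
        lod=lod,
        trait=trait_name,
        model="binary",
        covariate=cov.label,
        n=n,
        markers=probs.markers,
        flags=tuple(sorted(set(flags))),
    )


def scan_with_sex_models(
    trait_values: np.ndarray,
    probs: GenoProbGrid,
    phenos: PhenotypeTable,
    trait_name: str = "trait",
    model: str = "haley_knott",
) -> dict[str, ScanResult]:
    """Plain, additive-sex and interactive-sex scans of one trait.

    Returns a dict with keys ``plain``, ``additive`` and ``interactive``.
    With a single sex present, falls back to the plain scan (with a
    warning) for all three entries.
    """
    sex = encode_sex(phenos)
    fn = scan_hk if model == "haley_knott" else scan_binary
    plain = fn(trait_values, probs, trait_name=trait_name)
    if len(set(sex)) < 2:
        logger.warning("only one sex present; covariate scans fall back to plain")
        return {"plain": plain, "additive": plain, "interactive": plain}
    add = fn(
        trait_values, probs,
        cov=CovariateSpec("sex", "additive"), covariate_values=sex,
        trait_name=trait_name,
    )
    inter = fn(
        trait_values, probs,
        cov=CovariateSpec("sex", "interactive"), covariate_values=sex,
        trait_name=trait_name,
    )
    return {"plain": plain, "additive": add, "interactive": inter}
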