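"""Case/control separability: classical MDS + single-covariate logistic fit.

Classical (metric) multidimensional scaling — principal coordinates of the
double-centered squared Euclidean distance matrix between samples — is used
because it is deterministic and, for Euclidean distances, equals PCA scores,
so "the first principal coordinate" is well defined. Separability of the two
groups along that coordinate is then quantified by an intercept+slope
logistic regression fitted by iteratively reweighted least squares,
reporting the slope beta, odds ratio exp(beta), and a two-sided Wald p. The
covariate is standardized before the fit by default so odds ratios are
comparable across gene subsets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import CASE, CONTROL, LabeledExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class SeparabilityResult:
    gene_subset_name: str
    beta: float
    odds_ratio: float
    p_value: float
    complete_separation: bool
    coordinates: pd.DataFrame  # sample x (dim1, dim2, group)

    @property
    def abs_beta(self) -> float:
        return abs(self.beta)


def classical_mds(
    log_matrix: LabeledExpressionMatrix,
    gene_subset="all",
    n_components: int = 2,
) -> pd.DataFrame:
    """Principal coordinates of samples in (subset-restricted) gene space.

    Components are ordered by descending eigenvalue and scaled by the square
    root of the eigenvalue; each axis is oriented so the case-group mean is
    >= the control-group mean (MDS axes have arbitrary sign). If fewer
    positive eigenvalues than requested exist, the available ones are
    returned with a warning.
    """
    if len(log_matrix.samples) < 3:
        raise ValueError("MDS needs at least 3 samples")
    if isinstance(gene_subset, str) and gene_subset == "all":
        sub = log_matrix.values
    else:
        keep = [g for g in log_matrix.genes if g in frozenset(gene_subset)]
        if not keep:
            raise ValueError("gene subset shares no genes with the matrix")
        sub = log_matrix.values.loc[keep]

    x = sub.to_numpy(dtype=float).T  # samples x genes
    sq = np.sum(x**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * x @ x.T
    np.clip(d2, 0, None, out=d2)
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(evals[0], 0) * 1e-9
    n_pos = int(np.sum(evals > tol))
    if n_pos < n_components:
        warnings.warn(
            f"only {n_pos} positive eigenvalues available for {n_components} "
            "requested components",
            stacklevel=2,
        )
    k = max(min(n_components, n_pos), 0)
    coords = evecs[:, :k] * np.sqrt(evals[:k])

    samples = log_matrix.samples
    labels = np.array([log_matrix.group[s] for s in samples])
    for comp in range(k):
        case_mean = coords[labels == CASE, comp].mean() if (labels == CASE).any() else 0.0
        ctrl_mean = coords[labels == CONTROL, comp].mean() if (labels == CONTROL).any() else 0.0
        if case_mean < ctrl_mean:
            coords[:, comp] = -coords[:, comp]
    out = pd.DataFrame(
        coords,
        index=pd.Index(samples, name="sample"),
        columns=[f"dim{i + 1}" for i in range(k)],
    )
    out["group"] = labels
    return out


def logistic_fit(
    x: np.ndarray,
    labels: np.ndarray,
    standardize: bool = True,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> dict:
    """Intercept+slope logistic regression by IRLS with a Wald test.

    *labels* are 0 (control) / 1 (case). Complete separation is reported via
    the ``complete_separation`` flag (beta then reflects the diverged fit)
    instead of raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and labels must be 1-D and of equal length")
    if not np.isfinite(x).all():
        raise ValueError("x contains non-finite values")
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("labels must contain both classes (0 and 1)")
    if standardize:
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError("covariate has zero variance")
        x = (x - x.mean()) / sd

    design = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    deviance = np.inf
    separated = False
    for _ in range(max_iter):
        eta = design @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        w = mu * (1 - mu)
        z = eta + (y - mu) / w
        wx = design * w[:, None]
        try:
            beta = np.linalg.solve(design.T @ wx, design.T @ (w * z))
        except np.linalg.LinAlgError:
            separated = True
            break
        new_dev = -2.0 * float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
        if new_dev < 1e-8 or np.abs(beta).max() > 1e2:
            separated = True
            deviance = new_dev
            break
        if abs(deviance - new_dev) < tol * (abs(new_dev) + 0.1):
            deviance = new_dev
            break
        deviance = new_dev

    eta = design @ beta
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    w = mu * (1 - mu)
    info = design.T @ (design * w[:, None])
    try:
        cov = np.linalg.inv(info)
        se = float(np.sqrt(cov[1, 1]))
    except np.linalg.LinAlgError:  # pragma: no cover
        se = float("inf")
    from scipy import stats as _st

    slope = float(beta[1])
    if separated:
        p = float("nan")
    else:
        zval = slope / se if se > 0 else float("inf")
        p = float(2.0 * _st.norm.sf(abs(zval)))
    return {
        "beta": slope,
        "abs_beta": abs(slope),
        "odds_ratio": float(np.exp(slope)),
        "p_value": p,
        "se": se,
        "intercept": float(beta[0]),
        "complete_separation": separated,
        "standardized": standardize,
    }


def separability_report(
    log_matrix: LabeledExpressionMatrix,
    subsets: dict | None = None,
    standardize: bool = True,
) -> list[SeparabilityResult]:
    """MDS + logistic separability for each gene subset (always incl. "all").

    Empty subsets (no shared genes) are skipped with a logged warning.
    Standardization is uniform across subsets so |beta| and OR are
    comparable.
    """
    todo: dict = {"all": "all"}
    for name, genes in (subsets or {}).items():
        todo[name] = frozenset(genes)

    labels = np.array(
        [1.0 if log_matrix.group[s] == CASE else 0.0 for s in log_matrix.samples]
    )
    results = []
    for name, subset in todo.items():
        if subset != "all" and not (frozenset(subset) & frozenset(log_matrix.genes)):
            logger.warning("subset %r shares no genes with the matrix; skipped", name)
            continue
        coords = classical_mds(log_matrix, subset, n_components=2)
        fit = logistic_fit(coords["dim1"].to_numpy(), labels, standardize=standardize)
        results.append(
            SeparabilityResult(
                gene_subset_name=name,
                beta=fit["beta"],
                odds_ratio=fit["odds_ratio"],
                p_value=fit["p_value"],
                complete_separation=fit["complete_separation"],
                coordinates=coords,
            )
        )
    return results
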