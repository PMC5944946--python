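"""Environmental-variable analysis: sub-surface light, BoxCox, PCA, Ward.

Sampling seasons are recovered from physics and chemistry alone: each
variable is BoxCox-transformed toward normality, standardized, fed to a
correlation-matrix PCA (variables carry heterogeneous units), and the
sample scores on the first factorial plane are grouped by Ward
hierarchical clustering, three groups by default (spring bloom, summer,
winter in a temperate coastal series).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)


def par_subsurface(i0, kd, z):
    """Depth-averaged sub-surface daily light.

    ``I = I0 * (1 - exp(-kd*z)) / (kd*z)`` with ``I0`` the daily incident
    light (E m^-2 d^-1), ``kd`` the diffuse attenuation coefficient
    (m^-1) and ``z`` the sampling depth (m). The Beer-Lambert profile is
    averaged over the 0..z layer; as ``kd*z -> 0`` the water column is
    transparent and ``I -> I0``.
    """
    i0 = np.asarray(i0, dtype=float)
    kd = np.asarray(kd, dtype=float)
    z = np.asarray(z, dtype=float)
    if np.any(kd <= 0):
        raise ValueError("kd must be positive")
    if np.any(z <= 0):
        raise ValueError("z must be positive")
    if np.any(i0 < 0):
        raise ValueError("I0 must be non-negative")
    tau = kd * z
    out = i0 * (-np.expm1(-tau)) / tau
    return float(out) if out.ndim == 0 else out


@dataclass
class BoxCoxResult:
    values: np.ndarray
    lmbda: float
    shift: float = 0.0  # added to the data before transforming, if any


def boxcox_transform(x, lmbda: float | None = None, eps: float = 1e-6) -> BoxCoxResult:
    """BoxCox power transform ``(x^lambda - 1)/lambda`` (ln at lambda=0).

    ``lmbda=None`` fits lambda by maximum likelihood. Non-positive values
    get a recorded ``+eps - min`` shift first. A constant vector has no
    defined lambda; it is returned untransformed with a warning.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("expected a 1-D vector with >= 2 values")
    if np.any(~np.isfinite(x)):
        raise ValueError("non-finite values")
    shift = 0.0
    if x.min() <= 0:
        shift = eps - x.min()
        x = x + shift
        logger.info("BoxCox: shifted data by %+g to make it positive", shift)
    if np.ptp(x) == 0:
        logger.warning("BoxCox: constant vector, identity transform used")
        return BoxCoxResult(values=x - shift, lmbda=math.nan, shift=shift)
    if lmbda is None:
        y, fitted = stats.boxcox(x)
        return BoxCoxResult(values=y, lmbda=float(fitted), shift=shift)
    y = stats.boxcox(x, lmbda=lmbda)
    return BoxCoxResult(values=y, lmbda=float(lmbda), shift=shift)


@dataclass
class PcaResult:
    """Scores, loadings, explained-variance fractions and contribution%."""

    scores: pd.DataFrame        # dates x components
    loadings: pd.DataFrame      # variables x components (unit eigenvectors)
    explained: np.ndarray       # fraction of variance per component
    contributions: pd.DataFrame  # variables x components, percent, sums to 100

    def top_contributors(self, component: str = "PC1", threshold_pct: float = 10.0) -> list[str]:
        c = self.contributions[component]
        return list(c.index[c > threshold_pct])


def pca_env(
    env: pd.DataFrame,
    n_components: int | None = None,
    transform: bool = True,
) -> PcaResult:
    """Correlation-matrix PCA of an environmental table.

    Rows with any missing value are dropped (logged). Each variable is
    optionally BoxCox-transformed, then centered and scaled to unit
    variance. Contribution of variable *i* to axis *j* is
    ``100 * v_ij^2`` with ``v`` the unit eigenvector, so contributions on
    each axis sum to 100.
    """
    data = env.dropna(axis=0, how="any")
    dropped = len(env) - len(data)
    if dropped:
        logger.info("PCA: dropped %d dates with missing values", dropped)
    if data.shape[1] < 1:
        raise ValueError("need at least one variable")
    if data.shape[0] < 3:
        raise ValueError("need at least 3 complete dates for PCA")
    if transform:
        data = data.apply(lambda col: boxcox_transform(col.to_numpy()).values, axis=0)
    std = data.std(ddof=0)
    constant = std.index[std == 0].tolist()
    if constant:
        logger.warning("PCA: dropping constant variables %s", constant)
        data = data.drop(columns=constant)
        std = std.drop(index=constant)
    scaled = (data - data.mean()) / std
    k = min(scaled.shape) if n_components is None else n_components
    pca = PCA(n_components=k)
    scores = pca.fit_transform(scaled.to_numpy())
    names = [f"PC{i + 1}" for i in range(pca.n_components_)]
    vecs = pca.components_.T  # variables x components, unit columns
    return PcaResult(
        scores=pd.DataFrame(scores, index=data.index, columns=names),
        loadings=pd.DataFrame(vecs, index=data.columns, columns=names),
        explained=pca.explained_variance_ratio_,
        contributions=pd.DataFrame(100.0 * vecs**2, index=data.columns, columns=names),
    )


def ward_groups(scores: pd.DataFrame, k: int = 3) -> pd.Series:
    """Ward hierarchical clustering of PCA scores, cut to ``k`` groups.

    Uses the first two components when more are present (the first
    factorial plane). Returns integer labels 1..k indexed like ``scores``.
    """
    if k < 1 or k > len(scores):
        raise ValueError(f"k must be in [1, {len(scores)}], got {k}")
    x = scores.to_numpy(dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[1] > 2:
        x = x[:, :2]
    z = linkage(x, method="ward")
    labels = fcluster(z, t=k, criterion="maxclust")
    return pd.Series(labels, index=scores.index, name="season_group")
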