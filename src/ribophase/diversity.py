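"""Alpha-diversity indices and a permutation comparison between samples.

Indices operate on one sample's OTU count vector:

* Chao-1 richness (bias-corrected): ``S_obs + F1*(F1-1) / (2*(F2+1))``
  where ``F1``/``F2`` are the numbers of OTUs seen once/twice. The classic
  ``S_obs + F1^2/(2*F2)`` form is available but undefined when ``F2 = 0``.
* Simpson dominance ``D = sum(p_i^2)``: 1/S for S equally abundant taxa,
  1 when a single taxon holds every read.
* Shannon ``H' = -sum(p_i ln p_i)`` and Pielou-style equitability
  ``J = H'/ln(S_obs)``, undefined (NaN) for fewer than two observed OTUs.

Two samples are compared by pooling their reads and re-splitting them at
the original depths (multivariate hypergeometric, i.e. without
replacement); the two-sided p-value uses add-one smoothing.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np
import pandas as pd

from .io_tables import OtuTable


def _as_counts(counts) -> np.ndarray:
    x = np.asarray(counts)
    if x.ndim != 1:
        raise ValueError("expected a 1-D count vector")
    if x.size == 0 or x.sum() <= 0:
        raise ValueError("empty sample")
    if np.any(x < 0):
        raise ValueError("negative counts")
    return x


def observed_richness(counts) -> int:
    return int((_as_counts(counts) > 0).sum())


def chao1(counts, bias_corrected: bool = True) -> float:
    x = _as_counts(counts)
    s_obs = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        raise ValueError("classic Chao-1 undefined without doubletons")
    return s_obs + f1 * f1 / (2.0 * f2)


def shannon(counts) -> float:
    x = _as_counts(counts).astype(float)
    p = x[x > 0] / x.sum()
    return float(-(p * np.log(p)).sum())


def simpson(counts) -> float:
    x = _as_counts(counts).astype(float)
    p = x / x.sum()
    return float((p * p).sum())


def equitability(counts) -> float:
    """Shannon evenness H'/ln(S); NaN when fewer than 2 OTUs observed."""
    x = _as_counts(counts)
    s_obs = int((x > 0).sum())
    if s_obs <= 1:
        return math.nan
    return shannon(x) / math.log(s_obs)


_INDEX_FUNCS: dict[str, Callable] = {
    "s_obs": observed_richness,
    "chao1": chao1,
    "shannon": shannon,
    "simpson": simpson,
    "equitability": equitability,
}


def diversity_table(table: OtuTable) -> pd.DataFrame:
    """Per-sample diversity record: S_obs, Chao-1, Simpson, Shannon,
    equitability, and the observed/expected richness ratio."""
    rows = []
    for sample_id, row in table.counts.iterrows():
        x = row.to_numpy()
        s_obs = observed_richness(x)
        s_chao = chao1(x)
        rows.append(
            {
                "sample_id": sample_id,
                "S_obs": s_obs,
                "S_chao1": s_chao,
                "simpson_D": simpson(x),
                "shannon_H": shannon(x),
                "equitability_J": equitability(x),
                "obs_over_expected": s_obs / s_chao,
            }
        )
    out = pd.DataFrame(rows).set_index("sample_id")
    if table.molecule is not None:
        out["molecule"] = table.molecule
    if table.dates is not None:
        out["date"] = table.dates
    return out


def mean_obs_over_expected(table: OtuTable) -> pd.DataFrame:
    """Mean +/- SD of S_obs/S_chao1 per molecule dataset."""
    div = diversity_table(table)
    if "molecule" not in div.columns:
        div = div.assign(molecule="all")
    g = div.groupby("molecule")["obs_over_expected"]
    return pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1)})


def compare_diversity(
    sample_a,
    sample_b,
    index: str = "simpson",
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Permutation comparison of a diversity index between two samples.

    The null pools both samples' reads and re-splits them at the original
    depths without replacement ``n_perm`` times. Returns
    ``(delta_obs, p)`` with ``p = (1 + #{|delta_perm| >= |delta_obs|}) /
    (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    try:
        func = _INDEX_FUNCS[index]
    except KeyError as exc:
        raise ValueError(f"unknown index {index!r}; choose from {sorted(_INDEX_FUNCS)}") from exc
    a = _as_counts(sample_a).astype(np.int64)
    b = _as_counts(sample_b).astype(np.int64)
    if a.shape != b.shape:
        raise ValueError("samples must share the same OTU axis")
    delta_obs = float(func(a)) - float(func(b))
    pooled = a + b
    depth_a = int(a.sum())
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        a_perm = rng.multivariate_hypergeometric(pooled, depth_a)
        b_perm = pooled - a_perm
        d = float(func(a_perm)) - float(func(b_perm))
        if abs(d) >= abs(delta_obs) - 1e-12:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return delta_obs, p
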