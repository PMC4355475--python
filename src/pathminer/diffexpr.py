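"""Two-group differential expression with a SAM-style permutation statistic.

The per-feature statistic is the moderated d score

    d_i = (mean_case_i - mean_control_i) / (s_i + s0)

where ``s_i`` is the pooled standard error of the mean difference and the
fudge factor ``s0`` (by default the median of the per-feature pooled
standard errors) damps the statistic for features with near-zero spread.
Significance comes from group-label permutations: permuted |d*| scores are
pooled across all features into a single null distribution, per-feature
p-values are the pooled exceedance fractions, and q-values follow by
Benjamini-Hochberg.  When the number of distinct label assignments does not
exceed the requested permutation count the assignments are enumerated
exhaustively; otherwise they are sampled uniformly (with replacement) from a
seeded generator.

Probe-level arrays are collapsed to one row per gene by averaging the probe
rows that map to it; genes measured on several platforms are called DE only
when flagged on every platform.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .scoring import bh_fdr

logger = logging.getLogger(__name__)

GROUP_LABELS = ("control", "case")


@dataclass
class ExpressionDataset:
    """A two-group expression matrix (features x samples, log-scale values).

    Parameters
    ----------
    values:
        DataFrame indexed by feature (or probe) id, one column per sample.
    groups:
        Series mapping sample id -> "control" | "case"; must cover exactly
        the sample columns, and both groups must be non-empty.
    platform:
        Free-text platform tag (used when intersecting DE calls).
    probe_map:
        Optional Series mapping probe id -> feature (gene) id, for datasets
        whose rows are probes.
    """

    values: pd.DataFrame
    groups: pd.Series
    platform: str = ""
    probe_map: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if set(self.groups.index) != set(self.values.columns):
            raise ValueError("group labels must cover exactly the sample columns")
        labels = set(self.groups)
        if labels != set(GROUP_LABELS):
            raise ValueError(
                f"group label set must be exactly {set(GROUP_LABELS)}, got {labels}"
            )
        self.groups = self.groups.reindex(self.values.columns)
        self.values.index.name = "feature"

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def case_mask(self) -> np.ndarray:
        return (self.groups == "case").to_numpy()

    @property
    def n_control(self) -> int:
        return int((~self.case_mask).sum())

    @property
    def n_case(self) -> int:
        return int(self.case_mask.sum())

    def exclude_samples(self, excluded: Iterable[str]) -> "ExpressionDataset":
        """Drop listed samples (e.g. confounded subjects); ids not present are ignored."""
        excluded = set(excluded)
        keep = [s for s in self.sample_ids if s not in excluded]
        return replace(
            self, values=self.values[keep], groups=self.groups.loc[keep]
        )


def read_expression(
    values_path: str | Path,
    labels_path: str | Path,
    probe_map_path: str | Path | None = None,
    platform: str = "",
    exclude: Iterable[str] = (),
) -> ExpressionDataset:
    """Read an expression TSV (header = sample ids, first column = feature id)
    plus its ``sample<TAB>group`` label sidecar and optional probe map."""
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    labels = pd.read_csv(
        labels_path, sep="\t", header=None, names=["sample", "group"], comment="#"
    )
    groups = pd.Series(labels["group"].values, index=labels["sample"].astype(str))
    probe_map = None
    if probe_map_path is not None:
        pm = pd.read_csv(
            probe_map_path, sep="\t", header=None, names=["probe", "feature"], comment="#"
        )
        probe_map = pd.Series(pm["feature"].astype(str).values, index=pm["probe"].astype(str))
    ds = ExpressionDataset(
        values=values, groups=groups.loc[values.columns], platform=platform, probe_map=probe_map
    )
    return ds.exclude_samples(exclude) if exclude else ds


def write_expression(
    ds: ExpressionDataset,
    values_path: str | Path,
    labels_path: str | Path,
    probe_map_path: str | Path | None = None,
) -> None:
    ds.values.to_csv(values_path, sep="\t", index_label="feature")
    ds.groups.to_csv(labels_path, sep="\t", header=False)
    if probe_map_path is not None:
        if ds.probe_map is None:
            raise ValueError("dataset has no probe map to write")
        ds.probe_map.to_csv(probe_map_path, sep="\t", header=False)


def collapse_probes(
    ds: ExpressionDataset, return_report: bool = False
) -> ExpressionDataset | tuple[ExpressionDataset, dict]:
    """Average probe rows that map to the same gene.

    Probes without a mapping are dropped and counted in the report
    (``n_probes_unmapped``).  The collapsed dataset has one row per mapped
    gene, each cell the arithmetic mean of that gene's probe values for the
    sample.
    """
    if ds.probe_map is None or len(ds.probe_map) == 0:
        raise ValueError("collapse_probes requires a non-empty probe map")
    probe_map = ds.probe_map.dropna()
    mapped = ds.values.index.intersection(probe_map.index)
    n_unmapped = len(ds.values.index) - len(mapped)
    genes = probe_map.loc[mapped]
    collapsed = ds.values.loc[mapped].groupby(genes).mean()
    collapsed = collapsed.sort_index()
    report = {
        "platform": ds.platform,
        "n_probes": len(ds.values.index),
        "n_probes_unmapped": n_unmapped,
        "n_genes": len(collapsed.index),
    }
    if n_unmapped:
        logger.info(
            "platform %s: dropped %d unmapped probe(s)", ds.platform or "?", n_unmapped
        )
    out = ExpressionDataset(
        values=collapsed, groups=ds.groups, platform=ds.platform, probe_map=None
    )
    return (out, report) if return_report else out


def _pooled_se(X: np.ndarray, case: np.ndarray) -> np.ndarray:
    """Pooled standard error of the case-control mean difference, per row."""
    n1 = int((~case).sum())
    n2 = int(case.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 samples per group for variance estimation")
    ctrl, trt = X[:, ~case], X[:, case]
    ss = ((ctrl - ctrl.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (trt - trt.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    pooled_var = ss / (n1 + n2 - 2)
    return np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))


def _d_scores(X: np.ndarray, case: np.ndarray, s0: float) -> np.ndarray:
    se = _pooled_se(X, case)
    denom = se + s0
    if np.any(denom == 0):
        raise ZeroDivisionError(
            "zero pooled spread with s0=0; set a positive fudge factor s0"
        )
    diff = X[:, case].mean(axis=1) - X[:, ~case].mean(axis=1)
    return diff / denom


def default_s0(ds: ExpressionDataset) -> float:
    """Median of the per-feature pooled standard errors."""
    return float(np.median(_pooled_se(ds.values.to_numpy(float), ds.case_mask)))


def sam_d_statistic(ds: ExpressionDataset, s0: float | None = None) -> pd.Series:
    """Moderated d score per feature: (case mean - control mean) / (SE + s0).

    ``s0=None`` uses the median pooled standard error.  With ``s0=0`` a
    feature whose spread is zero in both groups raises ``ZeroDivisionError``.
    """
    if s0 is None:
        s0 = default_s0(ds)
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    d = _d_scores(ds.values.to_numpy(float), ds.case_mask, s0)
    return pd.Series(d, index=ds.values.index, name="d")


def _permutation_masks(
    n_samples: int, n_case: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Boolean (n_used x n_samples) case-assignment matrix.

    Enumerates all C(n_samples, n_case) assignments when that count does not
    exceed ``n_perm``; otherwise draws ``n_perm`` assignments uniformly with
    replacement.
    """
    total = math.comb(n_samples, n_case)
    if total <= n_perm:
        masks = np.zeros((total, n_samples), dtype=bool)
        for i, idx in enumerate(combinations(range(n_samples), n_case)):
            masks[i, list(idx)] = True
        return masks
    masks = np.zeros((n_perm, n_samples), dtype=bool)
    for i in range(n_perm):
        masks[i, rng.permutation(n_samples)[:n_case]] = True
    return masks


def permutation_test(
    ds: ExpressionDataset,
    n_perm: int = 200,
    seed: int = 0,
    s0: float | None = None,
    q_threshold: float | None = 0.01,
    p_threshold: float | None = None,
) -> pd.DataFrame:
    """Permutation DE test with pooled null distribution and BH q-values.

    Per-feature p-values pool the permuted |d*| scores of *all* features:

        p_i = (1 + #{permuted |d*| >= |d_i|}) / (1 + n_used * n_features)

    The DE call uses ``p <= p_threshold`` when ``p_threshold`` is given
    (the raw-p rule used for miRNA profiles), otherwise ``q < q_threshold``.
    Deterministic given ``seed``.

    Returns a DataFrame indexed by feature with columns d, p, q, is_de.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if q_threshold is None and p_threshold is None:
        raise ValueError("provide q_threshold or p_threshold")
    X = ds.values.to_numpy(float)
    case = ds.case_mask
    if s0 is None:
        s0 = default_s0(ds)

    d_obs = _d_scores(X, case, s0)
    rng = np.random.default_rng(seed)
    masks = _permutation_masks(X.shape[1], int(case.sum()), n_perm, rng)
    n_used = masks.shape[0]

    null_abs = np.empty((X.shape[0], n_used))
    for j in range(n_used):
        null_abs[:, j] = np.abs(_d_scores(X, masks[j], s0))
    pooled = np.sort(null_abs.ravel())

    abs_obs = np.abs(d_obs)
    n_ge = pooled.size - np.searchsorted(pooled, abs_obs, side="left")
    p = (1.0 + n_ge) / (1.0 + pooled.size)
    q = bh_fdr(p)

    if p_threshold is not None:
        is_de = p <= p_threshold
    else:
        is_de = q < q_threshold
    result = pd.DataFrame(
        {"d": d_obs, "p": p, "q": q, "is_de": is_de}, index=ds.values.index
    )
    result.index.name = "feature"
    logger.info(
        "platform %s: %d/%d features DE (%d permutations%s)",
        ds.platform or "?",
        int(is_de.sum()),
        len(result),
        n_used,
        " exhaustive" if n_used < n_perm or math.comb(X.shape[1], int(case.sum())) == n_used else "",
    )
    return result


def intersect_platforms(results: Sequence[pd.DataFrame]) -> set[str]:
    """Features flagged DE on *every* platform (the all-platforms rule)."""
    if not results:
        raise ValueError("need at least one platform result")
    de_sets = [set(res.index[res["is_de"]]) for res in results]
    return set.intersection(*de_sets)


def write_de_table(result: pd.DataFrame, path: str | Path) -> None:
    """Write the DE table TSV: ``feature  d  p  q  is_de``."""
    result.to_csv(path, sep="\t")


def read_de_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature")
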