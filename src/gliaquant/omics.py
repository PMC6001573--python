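"""Matrix-level statistics for expression and antibody-array data.

Covers below-background flag filtering, upper-quartile (75th percentile)
normalization, fold-change + moderated-t differential selection, condition
PCA with proportion-of-variance reporting, and the group-comparison tests
used throughout the downstream summaries.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError, GliaquantError


@dataclass
class AssayTable:
    """Nonnegative features x samples matrix with sample annotations.

    ``flags`` follows the well-above-background convention: 1 means the
    entry is reliably above background, 0 means too close to background.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_labels: list[str]
    conditions: list[str]
    replicates: list[int]
    flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n_feat, n_samp = self.values.shape
        if len(self.feature_ids) != n_feat:
            raise ValueError("feature_ids length does not match matrix rows")
        if not (len(self.sample_labels) == len(self.conditions) == len(self.replicates) == n_samp):
            raise ValueError("sample annotations do not match matrix columns")
        if any(lbl is None or lbl == "" for lbl in self.sample_labels):
            raise ValueError("missing sample labels")
        if self.flags is not None:
            self.flags = np.asarray(self.flags)
            if self.flags.shape != self.values.shape:
                raise ValueError("flags shape does not match values")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def columns_for(self, condition: str) -> list[int]:
        return [j for j, c in enumerate(self.conditions) if c == condition]


@dataclass
class DEGResult:
    feature_ids: list[str]
    log2_fc: np.ndarray
    p_values: np.ndarray
    selected: np.ndarray
    p_threshold: float
    fc_threshold_log2: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_ids,
                "log2FC": self.log2_fc,
                "p": self.p_values,
                "selected": self.selected,
            }
        )


@dataclass
class PCAResult:
    sample_labels: list[str]
    scores: np.ndarray          # samples x components
    pov: np.ndarray             # proportion of variance, all components
    loadings: np.ndarray        # features x components

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.sample_labels,
                "PC1": self.scores[:, 0],
                "PC2": self.scores[:, 1] if self.scores.shape[1] > 1 else 0.0,
            }
        )


# ---------------------------------------------------------------------------
# Flag filtering


def filter_flags(table: AssayTable, policy: str = "any") -> tuple[AssayTable, list[str]]:
    """Drop features too close to background; returns (table, removed ids).

    policy "any": drop a feature if flagged below background in any sample
    (strictest). "all": drop only if below background everywhere.
    "majority": drop if below background in more than half the samples.
    """
    if table.flags is None:
        raise GliaquantError("filter_flags requires a flags matrix (1 = well above background)")
    below = table.flags == 0
    if policy == "any":
        drop = below.any(axis=1)
    elif policy == "all":
        drop = below.all(axis=1)
    elif policy == "majority":
        drop = below.sum(axis=1) > table.n_samples / 2
    else:
        raise ValueError(f"unknown flag policy {policy!r}")
    keep = ~drop
    removed = [fid for fid, d in zip(table.feature_ids, drop) if d]
    filtered = AssayTable(
        values=table.values[keep],
        feature_ids=[fid for fid, k in zip(table.feature_ids, keep) if k],
        sample_labels=list(table.sample_labels),
        conditions=list(table.conditions),
        replicates=list(table.replicates),
        flags=table.flags[keep],
    )
    return filtered, removed


# ---------------------------------------------------------------------------
# Upper-quartile normalization


def normalize_75th(table: AssayTable) -> AssayTable:
    """Scale each sample so its 75th percentile equals the geometric mean of
    all samples' pre-scaling 75th percentiles.

    Percentiles use linear interpolation between order statistics so the
    operation is pinned and idempotent to 1e-9.
    """
    q = np.percentile(table.values, 75, axis=0)
    if np.any(q <= 0):
        bad = [table.sample_labels[j] for j in np.nonzero(q <= 0)[0]]
        raise GliaquantError(f"75th percentile is nonpositive for sample(s) {bad}")
    target = float(np.exp(np.mean(np.log(q))))
    scaled = table.values * (target / q)[None, :]
    return replace(table, values=scaled)


# ---------------------------------------------------------------------------
# Differential selection


def select_degs(
    table: AssayTable,
    group_a: str,
    group_b: str,
    p_threshold: float = 0.05,
    fc_threshold_log2: float = 1.0,
    shrinkage_weight: float = 0.5,
    pseudocount: float = 0.0,
) -> DEGResult:
    """Fold-change + moderated-t selection of group_a vs group_b.

    Values are log2-transformed internally. Per-feature log2FC is
    mean(log2 a) - mean(log2 b). The t statistic uses pooled per-feature
    variances shrunk toward the mean feature variance with weight
    ``shrinkage_weight`` (0 reduces to the ordinary two-sample t).
    Selected iff p < p_threshold and |log2FC| > fc_threshold_log2.
    """
    cols_a = table.columns_for(group_a)
    cols_b = table.columns_for(group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise DesignError("select_degs needs >=2 replicates per group")
    if not 0 <= shrinkage_weight <= 1:
        raise ValueError("shrinkage_weight must lie in [0, 1]")

    with np.errstate(divide="raise"):
        try:
            log_a = np.log2(table.values[:, cols_a] + pseudocount)
            log_b = np.log2(table.values[:, cols_b] + pseudocount)
        except FloatingPointError as exc:
            raise GliaquantError("zero values; supply a positive pseudocount") from exc

    na, nb = len(cols_a), len(cols_b)
    mean_a, mean_b = log_a.mean(axis=1), log_b.mean(axis=1)
    log2_fc = mean_a - mean_b

    df = na + nb - 2
    ss = log_a.var(axis=1, ddof=1) * (na - 1) + log_b.var(axis=1, ddof=1) * (nb - 1)
    s2 = ss / df
    prior = float(np.mean(s2))
    s2_mod = shrinkage_weight * prior + (1.0 - shrinkage_weight) * s2

    with np.errstate(divide="ignore", invalid="ignore"):
        t = log2_fc / np.sqrt(s2_mod * (1.0 / na + 1.0 / nb))
    t = np.where(np.isfinite(t), t, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)

    selected = (p < p_threshold) & (np.abs(log2_fc) > fc_threshold_log2)
    return DEGResult(
        feature_ids=list(table.feature_ids),
        log2_fc=log2_fc,
        p_values=p,
        selected=selected,
        p_threshold=p_threshold,
        fc_threshold_log2=fc_threshold_log2,
    )


# ---------------------------------------------------------------------------
# PCA


def pca_conditions(table: AssayTable, scale: bool = False) -> PCAResult:
    """PCA of samples with features centered (optionally unit-scaled) across
    samples. Covariance PCA by default; ``scale=True`` gives correlation PCA.

    Sign convention: each component is flipped so its largest-magnitude
    feature loading is positive, making scores reproducible.
    """
    if table.n_samples < 3:
        raise DesignError("pca_conditions needs at least 3 samples")
    x = table.values.T.astype(float)  # samples x features
    x = x - x.mean(axis=0, keepdims=True)
    if scale:
        sd = x.std(axis=0, ddof=1)
        keep = sd > 0
        x = x[:, keep] / sd[keep]
    if not np.any(np.abs(x) > 0):
        raise GliaquantError("matrix has rank 0 after centering")

    u, s, vt = np.linalg.svd(x, full_matrices=False)
    n = x.shape[0]
    var = s**2 / (n - 1)
    nz = var > var[0] * 1e-12 if var[0] > 0 else var > 0
    u, s, vt, var = u[:, nz], s[nz], vt[nz], var[nz]
    pov = var / var.sum()

    # fix signs by the largest-magnitude loading of each component
    for k in range(s.size):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] = -vt[k]
            u[:, k] = -u[:, k]

    scores = u * s
    return PCAResult(
        sample_labels=list(table.sample_labels),
        scores=scores,
        pov=pov,
        loadings=vt.T,
    )


# ---------------------------------------------------------------------------
# Group comparisons


@dataclass
class GroupComparison:
    design: str
    statistic: float
    p_value: float
    group_means: dict[str, float]
    group_sds: dict[str, float]
    group_ns: dict[str, int]
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)
    degenerate: bool = False


def compare_groups(values_by_group: dict[str, np.ndarray], design: str = "unpaired") -> GroupComparison:
    """Requested two-or-more-group test with descriptive summaries.

    design: "unpaired" | "paired" | "anova_bonferroni" | "ks".
    Bonferroni multiplies each pairwise unpaired p by the number of
    pairwise comparisons, capped at 1.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    names = list(groups)
    for k, v in groups.items():
        if v.size < 2:
            raise DesignError(f"group {k!r} has fewer than 2 observations")

    means = {k: float(v.mean()) for k, v in groups.items()}
    sds = {k: float(v.std(ddof=1)) for k, v in groups.items()}
    ns = {k: int(v.size) for k, v in groups.items()}
    degenerate = False

    if design in ("unpaired", "paired", "ks"):
        if len(names) != 2:
            raise DesignError(f"design {design!r} requires exactly 2 groups, got {len(names)}")
        a, b = groups[names[0]], groups[names[1]]
        if design == "unpaired":
            res = stats.ttest_ind(a, b)
            stat, p = float(res.statistic), float(res.pvalue)
            if not np.isfinite(stat):  # zero pooled variance
                stat, p, degenerate = 0.0, 1.0 if np.allclose(a.mean(), b.mean()) else 0.0, True
        elif design == "paired":
            if a.size != b.size:
                raise DesignError("paired design requires equal group lengths")
            d = a - b
            if np.allclose(d, d[0]):
                # constant shift: zero variance of differences, t undefined
                stat = 0.0
                p = 1.0 if np.allclose(d, 0) else 0.0
                degenerate = True
            else:
                res = stats.ttest_rel(a, b)
                stat, p = float(res.statistic), float(res.pvalue)
        else:
            res = stats.ks_2samp(a, b)
            stat, p = float(res.statistic), float(res.pvalue)
        return GroupComparison(design, stat, p, means, sds, ns, degenerate=degenerate)

    if design == "anova_bonferroni":
        if len(names) < 2:
            raise DesignError("ANOVA requires at least 2 groups")
        res = stats.f_oneway(*groups.values())
        n_comp = len(names) * (len(names) - 1) // 2
        pairwise: dict[tuple[str, str], float] = {}
        for ka, kb in itertools.combinations(names, 2):
            pr = stats.ttest_ind(groups[ka], groups[kb])
            p_adj = min(1.0, float(pr.pvalue) * n_comp) if np.isfinite(pr.pvalue) else 1.0
            pairwise[(ka, kb)] = p_adj
        stat = float(res.statistic)
        p = float(res.pvalue)
        if not np.isfinite(stat):
            stat, p, degenerate = 0.0, 1.0, True
        return GroupComparison(design, stat, p, means, sds, ns, pairwise=pairwise, degenerate=degenerate)

    raise DesignError(f"unknown design {design!r}")
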