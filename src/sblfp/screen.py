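"""Screening statistics: bias thresholds, region over-representation,
octant classification, correlations, and the standard-test dispatcher.

The screening logic selects region pairs whose preferred-vs-less-preferred
bias in bout-locked coherence (or power) change crosses mean +/- 1.5 SD of
the bias distribution, then asks which regions are over-represented among
the selected pairs (exact binomial tail against the region's share of the
pair universe).  Octant classification places each region in one of the
eight sign combinations of its bias across the three tasks.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import TASKS

#: preferred stimulus per task, fixing the bias sign convention
PREFERRED = {"SP": "social", "EsP": "isolated", "SxP": "female"}


@dataclass
class SelectionResult:
    selected: list  # unit ids that crossed the threshold
    direction: dict  # unit -> +1 / -1
    mean: float
    sd: float
    n_units: int

    @property
    def lower(self) -> float:
        return self.mean - 1.5 * self.sd

    @property
    def upper(self) -> float:
        return self.mean + 1.5 * self.sd


def threshold_bias(
    biases: pd.Series | dict, n_sd: float = 1.5
) -> SelectionResult:
    """Units whose bias strictly crosses mean +/- ``n_sd`` * SD of the bias
    distribution (ties at the boundary excluded)."""
    s = pd.Series(biases).dropna()
    if len(s) < 3:
        raise ValueError("need at least 3 units to form a threshold")
    mu, sd = float(s.mean()), float(s.std(ddof=1))
    if sd == 0:
        warnings.warn("zero SD of biases: nothing selected")
        return SelectionResult([], {}, mu, sd, len(s))
    hi, lo = mu + n_sd * sd, mu - n_sd * sd
    sel = s[(s > hi) | (s < lo)]
    return SelectionResult(
        list(sel.index), {k: (1 if v > hi else -1) for k, v in sel.items()},
        mu, sd, len(s),
    )


def region_overrepresentation(
    selected_pairs: list[tuple[str, str]],
    universe_pairs: list[tuple[str, str]],
) -> pd.DataFrame:
    """One-sided exact binomial test per region: is the region contained in
    more selected pairs than its share of the universe predicts?

    p = P(X >= k), X ~ Binomial(m, p0) with k = selected pairs containing
    the region, m = total selected pairs, p0 = its universe share.
    """
    if not universe_pairs:
        raise ValueError("empty pair universe")
    m = len(selected_pairs)
    regions = sorted({r for p in universe_pairs for r in p})
    rows = []
    for r in regions:
        n_univ = sum(r in p for p in universe_pairs)
        p0 = n_univ / len(universe_pairs)
        k = sum(r in p for p in selected_pairs)
        p = float(stats.binom.sf(k - 1, m, p0)) if m > 0 else 1.0
        rows.append(dict(region=r, k=k, m=m, p0=p0, p=min(p, 1.0)))
    return pd.DataFrame(rows)


def octant_classification(
    biases: pd.DataFrame, n_mc: int = 0, seed: int = 0
) -> tuple[pd.Series, dict]:
    """Assign each region to one of 8 sign octants across the three tasks.

    ``biases`` is regions x tasks (columns SP, EsP, SxP).  Zero bias
    tie-breaks to the positive class (logged).  Returns the per-region
    octant labels and a summary with per-octant counts plus the exact
    binomial tail probability P(X >= k_max), X ~ Binomial(n_regions, 1/8),
    of the observed maximum octant count under uniform assignment (optional
    Monte-Carlo check of the max-count distribution with ``n_mc`` draws).
    """
    missing = [t for t in TASKS if t not in biases.columns]
    if missing:
        raise ValueError(f"biases missing task column(s) {missing}")
    if (biases[list(TASKS)] == 0).any().any():
        warnings.warn("zero bias encountered; tie-broken to the positive class")
    signs = biases[list(TASKS)].apply(lambda c: np.where(c >= 0, "+", "-"))
    octants = signs.apply(lambda row: "".join(row), axis=1)
    counts = octants.value_counts()
    k_max = int(counts.iloc[0])
    n = len(octants)
    p_tail = float(stats.binom.sf(k_max - 1, n, 1 / 8))
    summary = {"counts": counts, "max_count": k_max, "binomial_tail_p": p_tail}
    if n_mc > 0:
        rng = np.random.default_rng(seed)
        draws = rng.integers(0, 8, size=(n_mc, n))
        maxima = np.array([np.bincount(d, minlength=8).max() for d in draws])
        summary["mc_p_max_ge_observed"] = float((maxima >= k_max).mean())
    return octants, summary


def correlate(x, y, method: str = "pearson"):
    """Pearson or Spearman correlation with pairwise missing removal."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 complete observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    if method == "pearson":
        r = stats.pearsonr(x, y)
    elif method == "spearman":
        r = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r.statistic), float(r.pvalue)


def bh_fdr(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejected mask, adjusted p)."""
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    rejected, adjusted, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return rejected, adjusted


@dataclass
class GroupCompareResult:
    test: str
    statistic: float
    p: float
    normal: bool
    posthoc: pd.DataFrame | None = None


def _normalish(samples: list[np.ndarray], alpha: float = 0.05) -> bool:
    for s in samples:
        if len(s) < 3:
            return False
        if len(np.unique(s)) == 1:
            return False
        if stats.shapiro(s).pvalue < alpha:
            return False
    return True


def _dunn_posthoc(groups: list[np.ndarray], labels: list[str]) -> pd.DataFrame:
    """Dunn's test: pairwise rank-sum z statistics with tie correction,
    FDR-adjusted."""
    all_vals = np.concatenate(groups)
    ranks = stats.rankdata(all_vals)
    n = len(all_vals)
    idx = np.cumsum([0] + [len(g) for g in groups])
    mean_ranks = [ranks[idx[i]:idx[i + 1]].mean() for i in range(len(groups))]
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12 * (n - 1))
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        ni, nj = len(groups[i]), len(groups[j])
        se = np.sqrt((n * (n + 1) / 12 - tie_term) * (1 / ni + 1 / nj))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        rows.append(dict(group_1=labels[i], group_2=labels[j], z=z,
                         p=2 * stats.norm.sf(abs(z))))
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_fdr(df["p"].to_numpy())[1]
    return df


def group_compare(
    samples: list, design: str, labels: list[str] | None = None
) -> GroupCompareResult:
    """Normality-screened dispatcher for the standard group comparisons.

    * ``paired_2``: paired t-test (normal differences) or Wilcoxon
      signed-rank.
    * ``unpaired_2``: t-test or Mann-Whitney U.
    * ``k_groups``: one-way ANOVA or Kruskal-Wallis, with Dunn's post-hoc
      (FDR-adjusted) after a non-parametric main effect.
    """
    groups = [np.asarray(s, dtype=float) for s in samples]
    labels = labels or [f"g{i}" for i in range(len(groups))]
    if design == "paired_2":
        if len(groups) != 2 or len(groups[0]) != len(groups[1]):
            raise ValueError("paired design needs two equal-length samples")
        d = groups[0] - groups[1]
        if len(d) < 3:
            raise ValueError("too few pairs")
        if np.allclose(d, 0):
            return GroupCompareResult("identical", 0.0, 1.0, True)
        if _normalish([d]):
            r = stats.ttest_rel(groups[0], groups[1])
            return GroupCompareResult("paired_t", float(r.statistic), float(r.pvalue), True)
        r = stats.wilcoxon(groups[0], groups[1])
        return GroupCompareResult("wilcoxon_signed_rank", float(r.statistic), float(r.pvalue), False)
    if design == "unpaired_2":
        if len(groups) != 2:
            raise ValueError("unpaired design needs two samples")
        if _normalish(groups):
            r = stats.ttest_ind(groups[0], groups[1])
            return GroupCompareResult("t", float(r.statistic), float(r.pvalue), True)
        r = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        return GroupCompareResult("mann_whitney", float(r.statistic), float(r.pvalue), False)
    if design == "k_groups":
        if len(groups) < 3:
            raise ValueError("k-group design needs at least 3 samples")
        if _normalish(groups):
            r = stats.f_oneway(*groups)
            return GroupCompareResult("anova", float(r.statistic), float(r.pvalue), True)
        r = stats.kruskal(*groups)
        posthoc = _dunn_posthoc(groups, labels) if r.pvalue < 0.05 else None
        return GroupCompareResult("kruskal_wallis", float(r.statistic), float(r.pvalue),
                                  False, posthoc)
    raise ValueError(f"unknown design {design!r}")


def pair_bias_table(
    bout_table: pd.DataFrame, preferred: dict[str, str] = PREFERRED
) -> pd.DataFrame:
    """Preferred-minus-less-preferred bias per pair x task from a long-format
    bout coherence/power table (columns subject, task, pair, stimulus,
    value), averaging sessions within subject first, then across subjects."""
    df = bout_table.dropna(subset=["value"])
    per_subj = (
        df.groupby(["task", "pair", "subject", "stimulus"])["value"].mean().reset_index()
    )
    rows = []
    for (task, pair), grp in per_subj.groupby(["task", "pair"]):
        pref = preferred[task]
        wide = grp.pivot_table(index="subject", columns="stimulus", values="value")
        others = [c for c in wide.columns if c != pref]
        if pref not in wide.columns or not others:
            continue
        bias = (wide[pref] - wide[others[0]]).mean()
        rows.append(dict(task=task, pair=pair, bias=float(bias)))
    return pd.DataFrame(rows)
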