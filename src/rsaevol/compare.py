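"""Jackknife resampling and robust per-branch rate-ratio statistics.

The data-summarising stage: delete-half jackknife replicates of alignment
columns (the same column sets applied to the amino-acid and PAA channels),
per-replicate branch-length fits collected into a :class:`BranchTable`, the
branch statistic ``ln(L) = ln(l_rsa / l_aa)``, and a robust classification
of inner branches as having accelerated, decelerated or neutral RSA
evolution.  Each branch's ln(L) sample (the 1-set) is compared against the
pooled ln(L) values of all retained inner branches of the same tree
(the 0-set, subsampled to at most ten times the 1-set size) with a two-sided
Mann-Whitney U test, Holm correction across the tree's branches, and
Cliff's delta as the effect size; near-zero branches and branches whose
ln(L) interquartile range betrays model instability are filtered first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import engine
from .io import LabeledTree, ResidueAlignment
from .revmodel import RevModel

#: Branch-length floor; shorter lengths are indistinguishable from zero.
LENGTH_FLOOR = 5e-5

#: Default classification thresholds.
DELTA_MIN_HETEROTACHY = 0.7
DELTA_MIN_PARTITION = 0.6
P_MAX = 1e-4
IQR_MAX = 6.0
IQR_PROBES = (4.0, 5.0, 6.0)
DELTA_THRESHOLDS = (0.3, 0.4, 0.5, 0.6, 0.7)
ZERO_SET_MAX_RATIO = 10


# ---------------------------------------------------------------------------
# Jackknife
# ---------------------------------------------------------------------------


def jackknife_replicates(alignment, n: int = 100, fraction: float = 0.5,
                         seed=None) -> list[np.ndarray]:
    """Delete-half jackknife column index sets.

    Each of the ``n`` replicates draws ``floor(columns * fraction)`` distinct
    columns without replacement.  ``alignment`` may be a ResidueAlignment or
    a column count.  The same index sets must be applied to both channels so
    the per-branch ratio compares like with like.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n_cols = (
        alignment if isinstance(alignment, (int, np.integer))
        else alignment.n_sites
    )
    if n_cols < 2:
        raise ValueError("alignment must have at least 2 columns")
    size = int(np.floor(n_cols * fraction))
    rng = np.random.default_rng(seed)
    return [
        np.sort(rng.choice(n_cols, size=size, replace=False))
        for _ in range(n)
    ]


# ---------------------------------------------------------------------------
# Branch table
# ---------------------------------------------------------------------------


@dataclass
class BranchTable:
    """Per-inner-branch, per-replicate lengths for both channels.

    Rows are inner-branch labels, columns are replicate indices; failed
    replicates hold NaN.  ``flagged`` lists branches with under 50%%
    successful replicates.
    """

    l_aa: pd.DataFrame
    l_rsa: pd.DataFrame
    mode: str
    flagged: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.l_aa.index.equals(self.l_rsa.index) or \
                not self.l_aa.columns.equals(self.l_rsa.columns):
            raise ValueError("l_aa and l_rsa must share branch and "
                             "replicate indices")
        for df in (self.l_aa, self.l_rsa):
            if (df.to_numpy() < 0).any():
                raise ValueError("branch lengths must be nonnegative")

    @property
    def branch_labels(self) -> list[str]:
        return list(self.l_aa.index)

    def to_tsv(self, path) -> None:
        long = pd.concat(
            {
                "l_aa": self.l_aa.stack(future_stack=True),
                "l_rsa": self.l_rsa.stack(future_stack=True),
            },
            axis=1,
        )
        long.index.names = ["branch", "replicate"]
        long = long.reset_index()
        long.insert(0, "mode", self.mode)
        long.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "BranchTable":
        long = pd.read_csv(path, sep="\t")
        mode = str(long["mode"].iloc[0])
        l_aa = long.pivot(index="branch", columns="replicate", values="l_aa")
        l_rsa = long.pivot(index="branch", columns="replicate", values="l_rsa")
        order = long["branch"].drop_duplicates().tolist()
        return cls(l_aa.loc[order], l_rsa.loc[order], mode)


def _combined_lengths(alignment, tree, model, mode, H, n_categories,
                      likelihood, warm_start=None):
    if mode == "heterotachy":
        fit = engine.fit_heterotachy(
            alignment, tree, model, H=H, warm_start=warm_start,
            _likelihood=likelihood,
        )
        return fit.combined_lengths, fit
    if mode == "partition":
        cats = engine.categorize_sites(alignment, n_categories)
        fit = engine.fit_partitioned(alignment, tree, model, cats)
        return fit.combined_lengths, fit
    raise ValueError(f"unknown engine mode {mode!r}")


def build_branch_table(aa_alignment: ResidueAlignment,
                       paa_alignment: ResidueAlignment,
                       tree: LabeledTree,
                       aa_model: RevModel, paa_model: RevModel,
                       replicates: Sequence[np.ndarray],
                       mode: str = "heterotachy", *,
                       H: int = 3, n_categories: int = 8) -> BranchTable:
    """Fit both channels per replicate and collect combined branch lengths.

    The two alignments must share taxa and column coordinates; each
    replicate's column set is applied to both.  Engine failures are recorded
    as NaN for that replicate, and branches with fewer than half their
    replicates successful are flagged.
    """
    if aa_alignment.n_sites != paa_alignment.n_sites:
        raise ValueError("channels must share column coordinates")
    if set(aa_alignment.taxon_names) != set(paa_alignment.taxon_names):
        raise ValueError("channels must share taxa")
    inner = tree.inner_branch_labels
    n_rep = len(replicates)
    arr_aa = np.full((len(inner), n_rep), np.nan)
    arr_rsa = np.full((len(inner), n_rep), np.nan)
    # replicates are exchangeable halves of the same data, so each
    # heterotachy fit warm-starts from the previous replicate's optimum
    # (the first replicate runs the cold initialisation ladder)
    warm: dict[str, "engine.HeterotachyFit"] = {}
    for j, idx in enumerate(replicates):
        for arr, tag, aln, model in (
            (arr_aa, "aa", aa_alignment, aa_model),
            (arr_rsa, "rsa", paa_alignment, paa_model),
        ):
            sub = aln.select_columns(idx)
            try:
                lik = engine.AlignmentLikelihood(sub, tree)
                lengths, fit = _combined_lengths(
                    sub, tree, model, mode, H, n_categories, lik,
                    warm_start=warm.get(tag),
                )
                if mode == "heterotachy":
                    warm[tag] = fit
                arr[:, j] = [lengths[lab] for lab in inner]
            except (engine.LikelihoodError, np.linalg.LinAlgError) as exc:
                warnings.warn(
                    f"replicate {j} failed on one channel: {exc}",
                    stacklevel=2,
                )
    ok = ~np.isnan(arr_aa) & ~np.isnan(arr_rsa)
    flagged = tuple(
        lab for i, lab in enumerate(inner) if ok[i].mean() < 0.5
    )
    cols = pd.RangeIndex(n_rep, name="replicate")
    return BranchTable(
        pd.DataFrame(arr_aa, index=pd.Index(inner, name="branch"), columns=cols),
        pd.DataFrame(arr_rsa, index=pd.Index(inner, name="branch"), columns=cols),
        mode,
        flagged,
    )


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------


def ln_ratio(l_rsa, l_aa, floor: float = LENGTH_FLOOR):
    """ln(l_rsa / l_aa) with both lengths clamped below at ``floor``.

    The floor is the meaningful minimum of a branch length; clamping both
    channels removes infinities without changing any ratio of estimable
    lengths.
    """
    a = np.maximum(np.asarray(l_rsa, dtype=float), floor)
    b = np.maximum(np.asarray(l_aa, dtype=float), floor)
    return np.log(a / b)


def filter_branches(table: BranchTable,
                    min_len: float = LENGTH_FLOOR,
                    ) -> tuple[BranchTable, tuple[str, ...]]:
    """Mark near-zero branches (median RSA-channel length below ``min_len``).

    Returns the table unchanged plus the set of filtered branch labels;
    filtered branches are excluded from statistical testing downstream.
    ``min_len=0`` retains everything.
    """
    med = table.l_rsa.median(axis=1, skipna=True)
    filtered = tuple(med.index[~(med >= min_len)])
    return table, filtered


def cliffs_delta(x, y) -> float:
    """Cliff's delta: (#{x_i > y_j} - #{x_i < y_j}) / (|x| |y|), exactly.

    This is the O(nm) definition computed directly (vectorised); any faster
    path must agree with it to the last ulp.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("cliffs_delta needs non-empty samples")
    diff = np.sign(x[:, None] - y[None, :])
    return float(diff.sum() / (x.size * y.size))


def compare_branch(branch_lnL, all_other_lnL, seed=None,
                   max_ratio: int = ZERO_SET_MAX_RATIO,
                   ) -> tuple[float, float]:
    """U-test p-value and Cliff's delta of a branch's ln(L) sample vs pool.

    The 0-set is randomly subsampled (seeded) to at most ``max_ratio`` times
    the 1-set size so the two samples stay comparable; the test is a
    two-sided Mann-Whitney U with the tie-corrected normal approximation.
    All-tied input returns ``(1.0, 0.0)``.
    """
    x = np.asarray(branch_lnL, dtype=float)
    y = np.asarray(all_other_lnL, dtype=float)
    if x.size == 0:
        raise ValueError("1-set is empty")
    cap = max_ratio * x.size
    if y.size > cap:
        rng = np.random.default_rng(seed)
        y = y[rng.choice(y.size, size=cap, replace=False)]
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0, 0.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic")
    p = float(res.pvalue)
    if not np.isfinite(p):
        p = 1.0
    return p, cliffs_delta(x, y)


def holm_adjust(p_values) -> np.ndarray:
    """Step-down Holm adjustment, input order preserved.

    Sort ascending, multiply the i-th smallest by (m - i), enforce a
    monotone nondecreasing sequence, cap at one.
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * (m - np.arange(m))
    adj = np.minimum(np.maximum.accumulate(adj), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def iqr_filter(samples: Mapping[str, np.ndarray],
               threshold: float = IQR_MAX,
               ) -> tuple[list[str], list[str], dict[str, float]]:
    """Split branches by the interquartile range of their ln(L) sample.

    Branches with Q3 - Q1 >= ``threshold`` are dropped: such spreads arise
    when a floored near-zero length is compared against a large one, i.e.
    the model is unstable on that branch under data variation.  Branches
    with fewer than 4 replicate values are unestimable and also dropped.
    Returns (kept, dropped, iqr-by-branch).
    """
    kept, dropped, iqrs = [], [], {}
    for label, vals in samples.items():
        v = np.asarray(vals, dtype=float)
        v = v[np.isfinite(v)]
        if v.size < 4:
            dropped.append(label)
            iqrs[label] = np.nan
            continue
        q1, q3 = np.percentile(v, [25, 75])
        iqrs[label] = float(q3 - q1)
        (kept if q3 - q1 < threshold else dropped).append(label)
    return kept, dropped, iqrs


# ---------------------------------------------------------------------------
# Per-branch comparison driver
# ---------------------------------------------------------------------------


@dataclass
class BranchComparison:
    """One inner branch's ln(L) sample and its test statistics."""

    branch: str
    lnL: np.ndarray
    median_lnL: float
    iqr: float
    p_value: float
    p_holm: float
    delta: float
    call: str = "neutral"
    reason: str = ""


def compare_branches(table: BranchTable, *,
                     min_len: float = LENGTH_FLOOR,
                     floor: float = LENGTH_FLOOR,
                     iqr_max: float = IQR_MAX,
                     seed=0,
                     max_ratio: int = ZERO_SET_MAX_RATIO,
                     ) -> list[BranchComparison]:
    """Full statistics pass over a branch table.

    Computes ln(L) per branch and replicate, applies the near-zero and IQR
    filters, then tests every retained branch against the pooled ln(L)
    values of all retained branches and Holm-adjusts within the tree.
    Filtered branches are returned with a reason code and p = NaN.
    """
    lnL: dict[str, np.ndarray] = {}
    for label in table.branch_labels:
        a = table.l_aa.loc[label].to_numpy()
        r = table.l_rsa.loc[label].to_numpy()
        ok = np.isfinite(a) & np.isfinite(r)
        lnL[label] = ln_ratio(r[ok], a[ok], floor)

    _, near_zero = filter_branches(table, min_len)
    testable = {k: v for k, v in lnL.items() if k not in near_zero}
    kept, iqr_dropped, iqrs = iqr_filter(testable, iqr_max)

    # the 0-set pools every retained branch of the tree, the focal branch
    # included; its self-ties anchor the comparison and keep single-dataset
    # channel offsets from saturating the effect size on small trees
    pool = (
        np.concatenate([lnL[k] for k in kept]) if kept else np.empty(0)
    )
    results: list[BranchComparison] = []
    raw_p: dict[str, float] = {}
    rng = np.random.default_rng(seed)
    for label in kept:
        sub_seed = int(rng.integers(2**31))
        p, delta = compare_branch(lnL[label], pool,
                                  seed=sub_seed, max_ratio=max_ratio)
        raw_p[label] = p
        results.append(BranchComparison(
            branch=label, lnL=lnL[label],
            median_lnL=float(np.median(lnL[label])) if lnL[label].size else np.nan,
            iqr=iqrs[label], p_value=p, p_holm=np.nan, delta=delta,
        ))
    adj = holm_adjust([raw_p[r.branch] for r in results]) if results else []
    for r, a in zip(results, adj):
        r.p_holm = float(a)
    for label in table.branch_labels:
        if label in kept:
            continue
        reason = (
            "near_zero" if label in near_zero
            else "unestimable" if len(lnL[label]) < 4
            else "iqr"
        )
        results.append(BranchComparison(
            branch=label, lnL=lnL[label],
            median_lnL=float(np.median(lnL[label])) if lnL[label].size else np.nan,
            iqr=iqrs.get(label, np.nan),
            p_value=np.nan, p_holm=np.nan, delta=np.nan,
            call="filtered", reason=reason,
        ))
    order = {lab: i for i, lab in enumerate(table.branch_labels)}
    results.sort(key=lambda r: order[r.branch])
    return results


def classify_branches(comparisons: Sequence[BranchComparison],
                      delta_min: float = DELTA_MIN_HETEROTACHY,
                      p_max: float = P_MAX,
                      partition_comparisons: Sequence[BranchComparison] | None = None,
                      partition_delta_min: float = DELTA_MIN_PARTITION,
                      ) -> dict[str, str]:
    """Accelerated / decelerated / neutral calls per inner branch.

    A branch is accelerated when delta >= ``delta_min`` with Holm-adjusted
    p below ``p_max``, decelerated for the mirrored condition, neutral
    otherwise; filtered branches keep their flag.  In consensus mode
    (``partition_comparisons`` given) a call stands only when the partition
    model, at its own ``partition_delta_min`` threshold, agrees.
    """

    def single(comp: BranchComparison, dmin: float) -> str:
        if comp.call == "filtered":
            return "filtered"
        if np.isfinite(comp.p_holm) and comp.p_holm < p_max:
            if comp.delta >= dmin:
                return "accelerated"
            if comp.delta <= -dmin:
                return "decelerated"
        return "neutral"

    calls = {c.branch: single(c, delta_min) for c in comparisons}
    if partition_comparisons is not None:
        part = {
            c.branch: single(c, partition_delta_min)
            for c in partition_comparisons
        }
        for branch, call in calls.items():
            if call in ("accelerated", "decelerated"):
                if part.get(branch) != call:
                    calls[branch] = "neutral"
    return calls


def comparisons_to_frame(comparisons: Sequence[BranchComparison],
                         calls: Mapping[str, str] | None = None,
                         ) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        rows.append({
            "branch": c.branch,
            "n": int(c.lnL.size),
            "median_lnL": c.median_lnL,
            "iqr": c.iqr,
            "p_value": c.p_value,
            "p_holm": c.p_holm,
            "delta": c.delta,
            "call": calls.get(c.branch, c.call) if calls else c.call,
            "reason": c.reason,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tree- and clade-level summaries
# ---------------------------------------------------------------------------


def tree_summary(comparisons: Sequence[BranchComparison],
                 delta_thresholds: Sequence[float] = DELTA_THRESHOLDS,
                 ) -> dict[float, int]:
    """Signed difference #(delta >= thr) - #(delta <= -thr) per threshold.

    A symmetric model produces differences centred on zero; systematic
    over- or under-calling of accelerated RSA evolution shows up as a bias.
    """
    deltas = np.array([
        c.delta for c in comparisons if np.isfinite(c.delta)
    ])
    return {
        float(t): int((deltas >= t).sum() - (deltas <= -t).sum())
        for t in delta_thresholds
    }


def family_sensitivity(lnL_values) -> tuple[float, float | None]:
    """(median, (mean - median) / median) of a family's ln(L) values.

    The median gauges the family-wide rate shift; the mean shift flags
    multimodality.  The shift is undefined (None) when the median is zero.
    """
    v = np.asarray(lnL_values, dtype=float)
    med = float(np.median(v))
    if med == 0:
        return med, None
    return med, float((v.mean() - med) / med)


@dataclass
class ChannelMoments:
    variance_aa: float
    variance_rsa: float
    skewness_aa: float
    skewness_rsa: float
    kurtosis_aa: float
    kurtosis_rsa: float
    welch_p: float
    welch_t: float


def channel_moments(branch_medians_aa, branch_medians_rsa) -> ChannelMoments:
    """Distribution moments of per-branch median lengths, per channel.

    Kurtosis is excess kurtosis; the Welch two-sample t test (unequal
    variances) compares the channels.  Descriptive only.
    """
    a = np.asarray(branch_medians_aa, dtype=float)
    r = np.asarray(branch_medians_rsa, dtype=float)
    t, p = stats.ttest_ind(r, a, equal_var=False)
    return ChannelMoments(
        variance_aa=float(np.var(a, ddof=1)),
        variance_rsa=float(np.var(r, ddof=1)),
        skewness_aa=float(stats.skew(a)),
        skewness_rsa=float(stats.skew(r)),
        kurtosis_aa=float(stats.kurtosis(a)),
        kurtosis_rsa=float(stats.kurtosis(r)),
        welch_p=float(p),
        welch_t=float(t),
    )


def heterotachy_weight_ratio(fit_rsa: "engine.HeterotachyFit",
                             fit_aa: "engine.HeterotachyFit") -> np.ndarray:
    """Elementwise RSA/AA heterotachy weight ratio, classes paired by rank.

    Both fits sort their classes by total tree length, so the ratio is
    invariant to the arbitrary class labelling.  A zero AA weight yields
    ``inf`` for that class.
    """
    if fit_rsa.n_classes != fit_aa.n_classes:
        raise ValueError("fits have different class counts")
    w_rsa = np.asarray(fit_rsa.weights, dtype=float)
    w_aa = np.asarray(fit_aa.weights, dtype=float)
    with np.errstate(divide="ignore"):
        return np.where(w_aa > 0, w_rsa / np.maximum(w_aa, 1e-300), np.inf)


@dataclass
class CladeSummary:
    """Per-clade counts of accelerated (Na) and decelerated (Nd) branches."""

    clade: str
    n_accelerated: int
    n_decelerated: int
    accelerated: dict[str, list[str]] = field(default_factory=dict)
    decelerated: dict[str, list[str]] = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    mode: str = "heterotachy"
    family_stats: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "clade": self.clade,
            "Na": self.n_accelerated,
            "Nd": self.n_decelerated,
            "accelerated": self.accelerated,
            "decelerated": self.decelerated,
            "thresholds": self.thresholds,
            "mode": self.mode,
            "family_stats": self.family_stats,
        }


def summarize_clades(calls_by_family: Mapping[str, Mapping[str, str]],
                     clade_map: Mapping[str, Sequence[str]],
                     thresholds: Mapping | None = None,
                     mode: str = "heterotachy",
                     family_stats: Mapping | None = None,
                     ) -> list[CladeSummary]:
    """Aggregate per-family branch calls over user-supplied clades.

    ``clade_map`` names each clade's inner-branch labels (replacing any
    taxonomy lookup); a clade's Na / Nd are counts of accelerated /
    decelerated branches on those labels, summed over families, with the
    contributing families listed per set.
    """
    out = []
    for clade, branches in clade_map.items():
        acc: dict[str, list[str]] = {}
        dec: dict[str, list[str]] = {}
        na = nd = 0
        for family, calls in calls_by_family.items():
            hits_a = [b for b in branches if calls.get(b) == "accelerated"]
            hits_d = [b for b in branches if calls.get(b) == "decelerated"]
            na += len(hits_a)
            nd += len(hits_d)
            if hits_a:
                acc[family] = hits_a
            if hits_d:
                dec[family] = hits_d
        out.append(CladeSummary(
            clade=clade, n_accelerated=na, n_decelerated=nd,
            accelerated=acc, decelerated=dec,
            thresholds=dict(thresholds or {}), mode=mode,
            family_stats=dict(family_stats or {}),
        ))
    return out
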