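"""Four-group differential analysis and validation statistics.

Per protein: classical one-way fixed-effects ANOVA across groups,
Tukey-Kramer studentized-range post-hoc p-values for requested pairwise
contrasts, Benjamini-Hochberg adjustment of the ANOVA p-values across
proteins, plus paired and pooled-variance two-sample t-tests for validation
cohorts.  All statistics run on available (non-missing) observations per
protein; proteins failing the minimum-n rules are skipped and reported.

ANOVA/t statistics are computed with vectorized sums-of-squares arithmetic so
matrices with thousands of proteins stay fast; Tukey p-values go through
``scipy.stats.studentized_range`` and can be switched off on hot paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import InputError, QuantMatrix, SampleMetadata

# p-value reported when a test statistic is infinite (zero variance, nonzero
# effect); flagged in the output rather than silently zeroed.
P_FLOOR = 1e-300


def _as_frame(m) -> pd.DataFrame:
    return m.to_frame() if hasattr(m, "to_frame") else pd.DataFrame(m)


@dataclass
class DifferentialTable:
    """Per-protein ANOVA + Tukey results for one data matrix.

    ``table`` columns: ``mean_<group>`` per group, ``f``, ``p``, ``p_adj``,
    and per comparison ``diff_<name>``, ``tukey_p_<name>``, ``sig_<name>``.
    The per-comparison flag requires both the BH-adjusted ANOVA p and the
    Tukey p to fall below alpha.
    """

    table: pd.DataFrame
    groups: list[str]
    comparisons: list[str]
    alpha: float
    skipped: list[str] = field(default_factory=list)
    has_tukey: bool = True

    def significant(self, comparison: str) -> list[str]:
        """Sorted proteins flagged significant for one pairwise comparison."""
        col = f"sig_{comparison}"
        if col not in self.table.columns:
            raise InputError(f"unknown comparison {comparison!r}")
        return sorted(self.table.index[self.table[col].fillna(False)])

    def significant_union(self) -> list[str]:
        """Sorted union of the per-comparison significant sets."""
        out: set[str] = set()
        for c in self.comparisons:
            out.update(self.significant(c))
        return sorted(out)


@dataclass
class PairedTestTable:
    """Per-protein paired t-test results (mean difference, t, two-tailed p)."""

    table: pd.DataFrame
    n_pairs: int
    skipped: list[str] = field(default_factory=list)

    def significant(self, alpha: float = 0.05, adjusted: bool = False) -> list[str]:
        col = "p_adj" if adjusted else "p"
        return sorted(self.table.index[self.table[col] < alpha])


def bh_adjust(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved).

    NaN entries are passed through and do not count toward m.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise InputError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    restored = np.empty(m)
    restored[order] = adj
    out[ok] = restored
    return out


def _group_indices(
    sample_ids: Sequence[str], groups: Mapping[str, str]
) -> dict[str, np.ndarray]:
    """Column indices per group label, restricted to samples with a label."""
    by_label: dict[str, list[int]] = {}
    for j, s in enumerate(sample_ids):
        if s in groups:
            by_label.setdefault(groups[s], []).append(j)
    return {g: np.array(ix, dtype=int) for g, ix in sorted(by_label.items())}


def anova_oneway(
    m, groups: Mapping[str, str]
) -> pd.DataFrame:
    """Vectorized one-way fixed-effects ANOVA per protein (missing-aware).

    Returns a frame with per-group counts and means, F and raw p.  A protein
    needs >= 2 groups with >= 2 non-missing observations each; groups below
    that threshold are excluded from that protein's test, and proteins left
    with fewer than two usable groups get NaN statistics.
    """
    frame = _as_frame(m)
    idx = _group_indices(frame.columns, groups)
    if len(idx) < 2:
        raise InputError("ANOVA needs at least two groups")
    X = frame.to_numpy(dtype=float)
    P = X.shape[0]
    labels = list(idx)
    n_g = np.empty((P, len(labels)))
    mean_g = np.empty((P, len(labels)))
    ss_within = np.zeros(P)
    for k, g in enumerate(labels):
        sub = X[:, idx[g]]
        n = np.sum(~np.isnan(sub), axis=1).astype(float)
        with np.errstate(invalid="ignore"):
            mu = np.nanmean(np.where(np.isnan(sub), np.nan, sub), axis=1)
        n_g[:, k] = n
        mean_g[:, k] = mu
    usable = n_g >= 2
    k_eff = usable.sum(axis=1)
    # zero-out unusable groups for the pooled quantities
    n_use = np.where(usable, n_g, 0.0)
    mean_use = np.where(usable, mean_g, 0.0)
    N = n_use.sum(axis=1)
    grand = np.divide(
        (n_use * mean_use).sum(axis=1), N, out=np.full(P, np.nan), where=N > 0
    )
    ss_between = (n_use * (mean_use - grand[:, None]) ** 2).sum(axis=1)
    for k, g in enumerate(labels):
        sub = X[:, idx[g]]
        dev = sub - mean_g[:, [k]]
        ssw = np.nansum(dev**2, axis=1)
        ss_within += np.where(usable[:, k], ssw, 0.0)
    df_between = k_eff - 1
    df_within = N - k_eff
    valid = (k_eff >= 2) & (df_within > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        msb = ss_between / df_between
        msw = ss_within / df_within
        F = np.where(valid, msb / msw, np.nan)
    p = np.full(P, np.nan)
    # identical constant groups: SSW == SSB == 0 -> F = 0, p = 1
    degenerate = valid & (ss_within <= 1e-300) & (ss_between <= 1e-300)
    F = np.where(degenerate, 0.0, F)
    finite = valid & np.isfinite(F)
    p[finite] = stats.f.sf(F[finite], df_between[finite], df_within[finite])
    p[valid & np.isinf(F)] = P_FLOOR
    F = np.where(valid & np.isinf(F), np.inf, F)
    out = pd.DataFrame(index=frame.index)
    for k, g in enumerate(labels):
        out[f"n_{g}"] = n_g[:, k]
        out[f"mean_{g}"] = mean_g[:, k]
    out["mse"] = np.where(valid, msw, np.nan)
    out["df_within"] = np.where(valid, df_within, np.nan)
    out["f"] = F
    out["p"] = p
    return out


def _named_comparisons(
    comparisons: Sequence[tuple],
) -> list[tuple[str, str, str]]:
    out = []
    for comp in comparisons:
        if len(comp) == 3:
            out.append(tuple(comp))
        else:
            a, b = comp
            out.append((a, b, f"{a}_vs_{b}"))
    return out


def tukey_pvalues(
    anova: pd.DataFrame,
    groups_present: Sequence[str],
    comparisons: Sequence[tuple],
) -> pd.DataFrame:
    """Tukey-Kramer studentized-range p-values for the requested contrasts.

    Uses the per-protein MSE and within-group counts produced by
    :func:`anova_oneway`; the Kramer form handles unequal group sizes.
    """
    k = len(groups_present)
    out = pd.DataFrame(index=anova.index)
    df = anova["df_within"].to_numpy()
    mse = anova["mse"].to_numpy()
    for a, b, name in _named_comparisons(comparisons):
        na = anova[f"n_{a}"].to_numpy()
        nb = anova[f"n_{b}"].to_numpy()
        diff = anova[f"mean_{a}"].to_numpy() - anova[f"mean_{b}"].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(mse / 2.0 * (1.0 / na + 1.0 / nb))
            q = np.abs(diff) / se
        valid = (na >= 2) & (nb >= 2) & np.isfinite(df) & np.isfinite(q)
        pvals = np.full(len(anova), np.nan)
        if valid.any():
            pvals[valid] = stats.studentized_range.sf(q[valid], k, df[valid])
        zero_q = (na >= 2) & (nb >= 2) & np.isfinite(df) & (se == 0) & (diff == 0)
        pvals[zero_q] = 1.0
        inf_q = (na >= 2) & (nb >= 2) & np.isfinite(df) & np.isinf(q)
        pvals[inf_q] = P_FLOOR
        out[f"diff_{name}"] = diff
        out[f"tukey_p_{name}"] = pvals
    return out


def anova_tukey(
    m,
    groups: Mapping[str, str],
    alpha: float = 0.05,
    comparisons: Sequence[tuple[str, str]] | None = None,
    adjust: str = "bh",
    tukey: bool = True,
) -> DifferentialTable:
    """One-way ANOVA + Tukey-Kramer post hoc per protein, BH across proteins.

    ``comparisons`` are (groupA, groupB) label pairs; default is every pair.
    ``adjust`` selects the across-protein adjustment of the ANOVA p-values
    ('bh', 'bonferroni', 'holm' or 'none').  The per-comparison significance
    flag requires both adjusted ANOVA p < alpha and Tukey p < alpha.
    """
    if not 0 < alpha < 1:
        raise InputError(f"alpha must be in (0, 1), got {alpha}")
    frame = _as_frame(m)
    idx = _group_indices(frame.columns, groups)
    labels = list(idx)
    for g, ix in idx.items():
        sub = frame.iloc[:, ix]
        if sub.notna().to_numpy().sum() == 0:
            raise InputError(f"group {g!r} has no observations in the matrix")
    res = anova_oneway(frame, groups)
    res["p_adj"] = adjust_pvalues(res["p"].to_numpy(), method=adjust)
    if comparisons is None:
        comparisons = [
            (labels[i], labels[j])
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]
    comparisons = _named_comparisons(comparisons)
    comp_names = [name for _, _, name in comparisons]
    if tukey:
        tk = tukey_pvalues(res, labels, comparisons)
        res = pd.concat([res, tk], axis=1)
        for name in comp_names:
            res[f"sig_{name}"] = (res["p_adj"] < alpha) & (res[f"tukey_p_{name}"] < alpha)
    skipped = sorted(res.index[res["p"].isna()])
    return DifferentialTable(
        table=res,
        groups=labels,
        comparisons=comp_names,
        alpha=alpha,
        skipped=skipped,
        has_tukey=tukey,
    )


def adjust_pvalues(p: np.ndarray, method: str = "bh") -> np.ndarray:
    """Across-protein multiple-testing adjustment ('bh', 'bonferroni', 'holm', 'none')."""
    p = np.asarray(p, dtype=float)
    if method == "bh":
        return bh_adjust(p)
    if method == "none":
        return p.copy()
    ok = ~np.isnan(p)
    out = np.full(p.shape, np.nan)
    m = int(ok.sum())
    if method == "bonferroni":
        out[ok] = np.clip(p[ok] * m, 0, 1)
        return out
    if method == "holm":
        pv = p[ok]
        order = np.argsort(pv, kind="mergesort")
        stepped = np.maximum.accumulate(pv[order] * (m - np.arange(m)))
        restored = np.empty(m)
        restored[order] = np.clip(stepped, 0, 1)
        out[ok] = restored
        return out
    raise InputError(f"unknown adjustment method {method!r}")


def fourgroup_comparisons(
    conditions: Sequence[str] = ("Ctrl", "DEN"),
    genotypes: Sequence[str] = ("WT", "KO"),
) -> list[tuple[str, str, str]]:
    """The four canonical contrasts of a condition x genotype design.

    Group labels are '<condition>-<genotype>'; contrasts are genotype within
    each condition and condition within each genotype, named
    '<levelA>_vs_<levelB>.within_<stratum>'.
    """
    c0, c1 = conditions
    g0, g1 = genotypes
    return [
        (f"{c0}-{g1}", f"{c0}-{g0}", f"{g1}_vs_{g0}.within_{c0}"),
        (f"{c1}-{g1}", f"{c1}-{g0}", f"{g1}_vs_{g0}.within_{c1}"),
        (f"{c1}-{g0}", f"{c0}-{g0}", f"{c1}_vs_{c0}.within_{g0}"),
        (f"{c1}-{g1}", f"{c0}-{g1}", f"{c1}_vs_{c0}.within_{g1}"),
    ]


def group_labels_from_metadata(
    meta: SampleMetadata,
    sample_ids: Sequence[str],
    variables: Sequence[str] = ("condition", "genotype"),
    exclude_replicates: bool = True,
) -> dict[str, str]:
    """Sample -> '<condition>-<genotype>' labels for the given samples."""
    all_labels = meta.group_labels(variables)
    reps = set(meta.replicate_sample_ids()) if exclude_replicates else set()
    return {s: all_labels[s] for s in sample_ids if s in all_labels and s not in reps}


@dataclass
class SignificanceSets:
    """Per-comparison significant protein sets and per-data-type unions."""

    per_comparison: dict[str, dict[str, list[str]]]
    union: dict[str, list[str]]


def significant_sets(
    tables: Mapping[str, DifferentialTable], alpha: float | None = None
) -> SignificanceSets:
    """Collect sorted significant sets per comparison and their union per table.

    If the tables do not share a protein universe the intersection is used.
    """
    universes = [set(t.table.index) for t in tables.values()]
    universe = set.intersection(*universes) if universes else set()
    per_comparison: dict[str, dict[str, list[str]]] = {}
    union: dict[str, list[str]] = {}
    for name, t in tables.items():
        per_comparison[name] = {
            c: sorted(set(t.significant(c)) & universe) for c in t.comparisons
        }
        union[name] = sorted(set(t.significant_union()) & universe)
    return SignificanceSets(per_comparison=per_comparison, union=union)


def set_overlap(sets: Mapping[str, Sequence[str]]) -> dict[frozenset[str], int]:
    """Cardinality of every exclusive region of the inclusion-exclusion partition.

    Keys are frozensets of set names (the region's membership pattern); the
    values sum to the size of the union.
    """
    if len(sets) < 2:
        raise InputError("set_overlap needs at least two sets")
    named = {k: set(v) for k, v in sets.items()}
    universe = set().union(*named.values())
    regions: dict[frozenset[str], int] = {}
    for el in universe:
        key = frozenset(k for k, v in named.items() if el in v)
        regions[key] = regions.get(key, 0) + 1
    return regions


def paired_ttest(m, pairs: Mapping[str, tuple[str, str]]) -> PairedTestTable:
    """Two-tailed paired t-test per protein over (case, control) sample pairs.

    Differences are case minus control; pairs with either value missing are
    dropped per protein.  Zero-variance differences: all-zero -> t = 0, p = 1;
    nonzero mean -> p floored at the numeric underflow floor and flagged.
    """
    frame = _as_frame(m)
    case_cols = [c for c, _ in pairs.values()]
    ctrl_cols = [c for _, c in pairs.values()]
    for c in case_cols + ctrl_cols:
        if c not in frame.columns:
            raise InputError(f"paired sample {c!r} not in matrix")
    diffs = frame[case_cols].to_numpy() - frame[ctrl_cols].to_numpy()
    n = np.sum(~np.isnan(diffs), axis=1).astype(float)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(np.where(np.isnan(diffs), np.nan, diffs), axis=1)
        sd = _nanstd1(diffs)
    valid = n >= 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where(valid, t, np.nan)
    zero_all = valid & (sd == 0) & (mean == 0)
    zero_var = valid & (sd == 0) & (mean != 0)
    t = np.where(zero_all, 0.0, t)
    p = np.full(len(frame), np.nan)
    finite = valid & np.isfinite(t)
    p[finite] = 2.0 * stats.t.sf(np.abs(t[finite]), n[finite] - 1)
    p[zero_var] = P_FLOOR
    with np.errstate(invalid="ignore"):
        t = np.where(zero_var, np.sign(mean) * np.inf, t)
    out = pd.DataFrame(
        {
            "n_pairs": n,
            "mean_diff": mean,
            "t": t,
            "p": p,
            "p_adj": bh_adjust(p),
            "degenerate": zero_var,
        },
        index=frame.index,
    )
    skipped = sorted(out.index[~valid])
    return PairedTestTable(table=out, n_pairs=len(pairs), skipped=skipped)


def two_sample_ttest(
    m, groups: Mapping[str, str], labels: tuple[str, str] | None = None
) -> pd.DataFrame:
    """Pooled-variance (equal-variance) two-sample t-test per protein.

    ``labels`` picks (case, control); default is the two labels sorted, with
    the second as control.  t is signed case-mean minus control-mean.
    Proteins with < 2 observations in either group get NaN (skipped).
    """
    frame = _as_frame(m)
    idx = _group_indices(frame.columns, groups)
    if labels is None:
        found = list(idx)
        if len(found) != 2:
            raise InputError(f"expected exactly two groups, found {found}")
        labels = (found[0], found[1])
    a, b = labels
    if a not in idx or b not in idx:
        raise InputError(f"group labels {labels} not present")
    Xa = frame.iloc[:, idx[a]].to_numpy()
    Xb = frame.iloc[:, idx[b]].to_numpy()
    na = np.sum(~np.isnan(Xa), axis=1).astype(float)
    nb = np.sum(~np.isnan(Xb), axis=1).astype(float)
    with np.errstate(invalid="ignore"):
        ma, mb = np.nanmean(Xa, axis=1), np.nanmean(Xb, axis=1)
        va, vb = _nanstd1(Xa) ** 2, _nanstd1(Xb) ** 2
    valid = (na >= 2) & (nb >= 2)
    df = na + nb - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        t = (ma - mb) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    t = np.where(valid, t, np.nan)
    diff = ma - mb
    zero_all = valid & (sp2 == 0) & (diff == 0)
    zero_var = valid & (sp2 == 0) & (diff != 0)
    t = np.where(zero_all, 0.0, t)
    p = np.full(len(frame), np.nan)
    finite = valid & np.isfinite(t)
    p[finite] = 2.0 * stats.t.sf(np.abs(t[finite]), df[finite])
    p[zero_var] = P_FLOOR
    with np.errstate(invalid="ignore"):
        t = np.where(zero_var, np.sign(diff) * np.inf, t)
    return pd.DataFrame(
        {
            f"n_{a}": na,
            f"n_{b}": nb,
            "mean_diff": diff,
            "t": t,
            "p": p,
            "p_adj": bh_adjust(p),
        },
        index=frame.index,
    )


def _nanstd1(x: np.ndarray) -> np.ndarray:
    """Row-wise sample standard deviation (ddof=1) ignoring NaN, without warnings."""
    n = np.sum(~np.isnan(x), axis=1).astype(float)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(x, axis=1)
        ss = np.nansum((x - mean[:, None]) ** 2, axis=1)
    out = np.full(x.shape[0], np.nan)
    ok = n >= 2
    out[ok] = np.sqrt(ss[ok] / (n[ok] - 1))
    return out
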