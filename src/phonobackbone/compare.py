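"""Group assembly and Welch ANOVA comparison of backbone survivors.

Three word groups are compared, mirroring the survivor analysis of the
backbone procedure: all words in the original network's giant component
(ORIGINAL_GC), the words in the backbone's giant component (BACKBONE_GC),
and the words that were in the original GC but fell out of the backbone GC
(GC_NOT_BACKBONE = ORIGINAL_GC minus BACKBONE_GC).  The first group
overlaps the other two by construction; the groups are nevertheless
treated as independent samples, as is conventional in this analysis.

Because the groups have very unequal sizes and variances, the omnibus test
per variable is the Welch (1951) heteroscedastic one-way ANOVA with
Satterthwaite-adjusted denominator degrees of freedom.  Post hocs default
to Games-Howell (pairwise Welch t with a studentized-range adjustment at
the pairwise Welch df), the heteroscedasticity-consistent analogue of
Tukey's HSD; plain Tukey HSD (pooled variance) is available as an option.

Network variables (degree, clustering, closeness) are always taken from
the ORIGINAL network, even for the backbone group: group membership
changes, the measured words do not.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .backbone import BackboneResult, backbone_graph
from .lexicon import Lexicon
from .metrics import decompose

__all__ = [
    "GROUPS",
    "GroupAssignment",
    "WelchAnovaResult",
    "PosthocResult",
    "GroupComparisonTable",
    "assign_groups",
    "welch_anova",
    "games_howell",
    "tukey_posthoc",
    "posthoc",
    "describe_groups",
    "TABLE_VARIABLES",
]

GROUPS = ("ORIGINAL_GC", "BACKBONE_GC", "GC_NOT_BACKBONE")

#: the variables of the standard comparison table, in report order
TABLE_VARIABLES = (
    "familiarity",
    "log_frequency",
    "length",
    "degree",
    "clustering",
    "closeness",
)


@dataclass
class GroupAssignment:
    """Per-word giant-component membership before and after sparsification."""

    table: pd.DataFrame  # word_id, in_original_gc, in_backbone_gc, group
    backbone_gc_outside_original: int  # diagnostics: backbone-GC words not in original GC

    def members(self, group: str) -> list[str]:
        t = self.table
        if group == "ORIGINAL_GC":
            mask = t["in_original_gc"]
        elif group == "BACKBONE_GC":
            mask = t["in_backbone_gc"]
        elif group == "GC_NOT_BACKBONE":
            mask = t["in_original_gc"] & ~t["in_backbone_gc"]
        else:
            raise ValueError(f"unknown group {group!r}")
        return t.loc[mask, "word_id"].tolist()


def assign_groups(original: nx.Graph, backbone: BackboneResult | nx.Graph) -> GroupAssignment:
    """Label every word by original-GC and backbone-GC membership.

    The backbone GC is the largest component of the retained-edge graph
    over all original nodes.  Backbone-GC membership is not forced to be a
    subset of the original GC; any words outside it are counted and
    reported (the identity |ORIGINAL_GC| = |BACKBONE_GC ∩ ORIGINAL_GC| +
    |GC_NOT_BACKBONE| always holds by construction).
    """
    if isinstance(backbone, BackboneResult):
        bb = backbone_graph(original, backbone)
    else:
        bb = backbone
    if set(bb.nodes) != set(original.nodes):
        raise ValueError("backbone node set does not match the original network")
    orig_gc = decompose(original).giant
    bb_gc = decompose(bb).giant
    words = sorted(original.nodes)
    df = pd.DataFrame(
        {
            "word_id": words,
            "in_original_gc": [w in orig_gc for w in words],
            "in_backbone_gc": [w in bb_gc for w in words],
        }
    )
    df["group"] = np.select(
        [df["in_backbone_gc"], df["in_original_gc"]],
        ["BACKBONE_GC", "GC_NOT_BACKBONE"],
        default="",
    )
    outside = int((df["in_backbone_gc"] & ~df["in_original_gc"]).sum())
    return GroupAssignment(table=df, backbone_gc_outside_original=outside)


@dataclass
class WelchAnovaResult:
    variable: str
    F: float
    df1: int
    df2: float
    p: float
    group_labels: tuple[str, ...]
    group_means: tuple[float, ...]
    group_sds: tuple[float, ...]
    group_ns: tuple[int, ...]


def welch_anova(samples: list[np.ndarray], labels: tuple[str, ...] | None = None,
                variable: str = "") -> WelchAnovaResult:
    """Welch's heteroscedastic one-way ANOVA for k >= 2 groups.

    With weights w_j = n_j / s_j^2 and weighted grand mean x_w:

        F   = [ sum_j w_j (x_j - x_w)^2 / (k-1) ] / [ 1 + 2(k-2)/(k^2-1) L ]
        L   = sum_j (1 - w_j / sum w)^2 / (n_j - 1)
        df2 = (k^2 - 1) / (3 L)

    and p is the upper tail of F(k-1, df2).  Missing values must be dropped
    before calling; each group needs n_j >= 2 and nonzero variance.
    """
    k = len(samples)
    if k < 2:
        raise ValueError(f"need at least 2 groups, got {k}")
    labels = labels or tuple(f"group{i}" for i in range(k))
    arrs = [np.asarray(s, dtype=float) for s in samples]
    ns = np.array([a.size for a in arrs])
    if (ns < 2).any():
        bad = labels[int(np.argmin(ns))]
        raise ValueError(f"group {bad!r} has fewer than 2 observations")
    means = np.array([a.mean() for a in arrs])
    variances = np.array([a.var(ddof=1) for a in arrs])
    if (variances == 0).any():
        bad = labels[int(np.argmin(variances))]
        raise ValueError(f"group {bad!r} has zero variance")
    w = ns / variances
    sw = w.sum()
    xw = (w * means).sum() / sw
    lam = (((1 - w / sw) ** 2) / (ns - 1)).sum()
    num = (w * (means - xw) ** 2).sum() / (k - 1)
    den = 1 + 2 * (k - 2) / (k**2 - 1) * lam
    F = num / den
    df2 = (k**2 - 1) / (3 * lam)
    p = float(stats.f.sf(F, k - 1, df2))
    return WelchAnovaResult(
        variable=variable,
        F=float(F),
        df1=k - 1,
        df2=float(df2),
        p=p,
        group_labels=tuple(labels),
        group_means=tuple(float(m) for m in means),
        group_sds=tuple(float(math.sqrt(v)) for v in variances),
        group_ns=tuple(int(n) for n in ns),
    )


@dataclass
class PosthocResult:
    pair: tuple[str, str]
    t: float
    df: float
    p_unadjusted: float
    p_adjusted: float
    method: str


def games_howell(samples: list[np.ndarray], labels: tuple[str, ...]) -> list[PosthocResult]:
    """Games-Howell pairwise comparisons.

    For each pair: Welch t with Satterthwaite df, then the adjusted p is
    the studentized-range tail at q = |t|*sqrt(2) with k groups and that
    df — Tukey's adjustment made heteroscedasticity-consistent.
    """
    k = len(samples)
    arrs = [np.asarray(s, dtype=float) for s in samples]
    out: list[PosthocResult] = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = arrs[i], arrs[j]
            va, vb = a.var(ddof=1), b.var(ddof=1)
            na, nb = a.size, b.size
            se2 = va / na + vb / nb
            t = (a.mean() - b.mean()) / math.sqrt(se2)
            df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
            p_un = float(2 * stats.t.sf(abs(t), df))
            p_adj = float(stats.studentized_range.sf(abs(t) * math.sqrt(2), k, df))
            out.append(
                PosthocResult(
                    pair=(labels[i], labels[j]),
                    t=float(t),
                    df=float(df),
                    p_unadjusted=p_un,
                    p_adjusted=min(1.0, p_adj),
                    method="games_howell",
                )
            )
    return out


def tukey_posthoc(samples: list[np.ndarray], labels: tuple[str, ...]) -> list[PosthocResult]:
    """Tukey HSD (pooled variance) pairwise comparisons via scipy."""
    arrs = [np.asarray(s, dtype=float) for s in samples]
    res = stats.tukey_hsd(*arrs)
    n_total = sum(a.size for a in arrs)
    df = n_total - len(arrs)
    out: list[PosthocResult] = []
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            stat = res.statistic[i, j]
            # scipy reports the mean difference; convert to a t on the pooled SE
            ssd = sum((a.size - 1) * a.var(ddof=1) for a in arrs)
            sp2 = ssd / df
            se = math.sqrt(sp2 * (1 / arrs[i].size + 1 / arrs[j].size))
            t = stat / se
            p_un = float(2 * stats.t.sf(abs(t), df))
            out.append(
                PosthocResult(
                    pair=(labels[i], labels[j]),
                    t=float(t),
                    df=float(df),
                    p_unadjusted=p_un,
                    p_adjusted=float(res.pvalue[i, j]),
                    method="tukey_hsd",
                )
            )
    return out


def posthoc(samples: list[np.ndarray], labels: tuple[str, ...],
            method: str = "games_howell") -> list[PosthocResult]:
    if method == "games_howell":
        return games_howell(samples, labels)
    if method == "tukey_hsd":
        return tukey_posthoc(samples, labels)
    raise ValueError(f"unknown post-hoc method {method!r}")


@dataclass
class GroupComparisonTable:
    """Per-variable group summaries, omnibus Welch tests, and post hocs."""

    summary: pd.DataFrame          # variable x (mean/sd/n per group, F, df1, df2, p)
    posthocs: pd.DataFrame         # variable, pair, t, df, p_unadjusted, p_adjusted, method
    group_sizes: dict[str, int]
    skipped: list[str] = field(default_factory=list)


def _variable_frame(lexicon: Lexicon, node_metrics: pd.DataFrame) -> pd.DataFrame:
    lex = lexicon.to_frame()[["word_id", "familiarity", "log_frequency", "length"]]
    return lex.merge(
        node_metrics[["word_id", "degree", "clustering", "closeness"]],
        on="word_id",
        how="inner",
    )


def describe_groups(
    assignment: GroupAssignment,
    lexicon: Lexicon,
    node_metrics: pd.DataFrame,
    method: str = "games_howell",
    variables: tuple[str, ...] = TABLE_VARIABLES,
) -> GroupComparisonTable:
    """Build the survivor-comparison table.

    ``node_metrics`` must come from the ORIGINAL network (per-word degree,
    clustering, closeness via :func:`phonobackbone.metrics.all_node_metrics`).
    Missing norm values are dropped per variable (listwise within variable);
    a variable entirely missing in any group is skipped with a warning.
    """
    vf = _variable_frame(lexicon, node_metrics).set_index("word_id")
    members = {g: assignment.members(g) for g in GROUPS}
    if min(len(m) for m in members.values()) < 2:
        small = [g for g, m in members.items() if len(m) < 2]
        raise ValueError(f"empty or singleton group(s): {small}; comparison not possible")
    rows = []
    ph_rows = []
    skipped: list[str] = []
    for var in variables:
        if var not in vf.columns:
            skipped.append(var)
            continue
        samples, labels = [], []
        for g in GROUPS:
            vals = vf.loc[vf.index.intersection(members[g]), var].dropna().to_numpy(dtype=float)
            samples.append(vals)
            labels.append(g)
        if any(s.size < 2 for s in samples):
            warnings.warn(f"variable {var!r} missing in a group; skipped")
            skipped.append(var)
            continue
        res = welch_anova(samples, tuple(labels), variable=var)
        row = {"variable": var, "F": res.F, "df1": res.df1, "df2": res.df2, "p": res.p}
        for g, m, sd, n in zip(res.group_labels, res.group_means, res.group_sds, res.group_ns):
            row[f"mean_{g}"] = m
            row[f"sd_{g}"] = sd
            row[f"n_{g}"] = n
        rows.append(row)
        for ph in posthoc(samples, tuple(labels), method):
            ph_rows.append(
                {
                    "variable": var,
                    "pair": " vs ".join(ph.pair),
                    "t": ph.t,
                    "df": ph.df,
                    "p_unadjusted": ph.p_unadjusted,
                    "p_adjusted": ph.p_adjusted,
                    "method": ph.method,
                }
            )
    return GroupComparisonTable(
        summary=pd.DataFrame(rows),
        posthocs=pd.DataFrame(ph_rows),
        group_sizes={g: len(m) for g, m in members.items()},
        skipped=skipped,
    )
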