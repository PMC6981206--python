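"""Interaction scoring and rewiring classification from SILAC ratio tables.

The statistical contract mirrors common quantitative-interactomics
practice: reverse-label runs are sign-flipped to a common orientation and
each run is median-centred; technical replicates are averaged into their
biological replicate before testing (the test n is the number of
biological replicates, avoiding pseudo-replication); prey enrichment over
empty-vector controls is a one-sided Welch t-test; condition-vs-condition
shifts are a two-sided one-sample t-test against zero; and significance A
is the percentile-based robust-z outlier statistic for log-ratios, applied
per bait experiment.  High-confidence interactors must jointly pass
P <= 0.05 and significance A <= 0.05; the same joint gate on the direct
condition comparison defines rewired interactions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)

STAT_COLUMNS = ["bait", "prey", "mean_log2fc", "p_value", "n_replicates"]


@dataclass
class Thresholds:
    """Joint significance gates and the frequent-flyer contaminant cutoff."""

    p_max: float = 0.05
    sig_a_max: float = 0.05
    contaminant_max_frequency: float = 0.5

    def validate(self) -> None:
        for name in ("p_max", "sig_a_max", "contaminant_max_frequency"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


def normalize_ratios(raw: pd.DataFrame, center: bool = True) -> pd.DataFrame:
    """Orient label-swapped runs and median-centre each run's ratio set.

    Reverse-orientation rows are sign-flipped to the forward convention,
    then ratios are median-centred to 0 per (bait, condition, replicate)
    MS run — each run is one experiment's ratio set — removing per-run
    global offsets (``center=False`` skips the centring and only fixes
    orientation).  The input is not modified.
    """
    missing = raw["label_orientation"].isna() | ~raw["label_orientation"].isin(
        ["forward", "reverse"]
    )
    if missing.any():
        idx = list(raw.index[missing][:10])
        raise ValueError(
            f"{int(missing.sum())} rows lack a valid label_orientation "
            f"(first offending rows: {idx})"
        )
    out = raw.copy()
    flip = out["label_orientation"] == "reverse"
    out.loc[flip, "log2_ratio"] = -out.loc[flip, "log2_ratio"]
    if center:
        med = out.groupby(["bait", "condition", "replicate_id"])[
            "log2_ratio"
        ].transform("median")
        out["log2_ratio"] = out["log2_ratio"] - med
    return out


def _collapse_technical(df: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates into their biological replicate."""
    return (
        df.groupby(["bait", "prey", "condition", "bio_rep"], as_index=False)[
            "log2_ratio"
        ].mean()
    )


def _welch_one_sided(m1, v1, n1, m2, v2, n2):
    """Vectorised one-sided Welch t-test P(group1 > group2).

    Zero pooled variance is resolved by the sign of the difference:
    identical groups give p = 0.5, a positive difference p = 0, a negative
    one p = 1 (a degenerate but noise-free-consistent convention).
    """
    se2 = v1 / n1 + v2 / n2
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = np.where(
        se2 > 0,
        stats.t.sf(np.nan_to_num(t), np.where(np.isfinite(df) & (df > 0), df, 1.0)),
        np.where(diff > 0, 0.0, np.where(diff < 0, 1.0, 0.5)),
    )
    return p


def test_enrichment(
    bait_rows: pd.DataFrame, control_rows: pd.DataFrame
) -> pd.DataFrame:
    """Per-prey enrichment of pulldown ratios over empty-vector controls.

    Preys without their own control measurements (true interactors are not
    expected in empty-vector pulldowns) are tested against the pooled
    control null distribution. Preys with fewer than two biological
    replicates in the pulldown are skipped with a warning.
    """
    bait_bio = _collapse_technical(bait_rows)
    ctrl_bio = _collapse_technical(control_rows)

    g = bait_bio.groupby(["bait", "prey"])["log2_ratio"].agg(["mean", "var", "count"])
    skipped = g[g["count"] < 2]
    if len(skipped):
        logger.warning(
            "test_enrichment: skipping %d preys with <2 biological replicates",
            len(skipped),
        )
        g = g[g["count"] >= 2]

    ctrl = ctrl_bio.groupby("prey")["log2_ratio"].agg(["mean", "var", "count"])
    pooled = ctrl_bio["log2_ratio"]
    pooled_stats = (pooled.mean(), pooled.var(ddof=1), len(pooled))

    g = g.reset_index()
    cm = g["prey"].map(ctrl["mean"])
    cv = g["prey"].map(ctrl["var"])
    cn = g["prey"].map(ctrl["count"])
    use_pooled = cn.isna() | (cn < 2)
    cm = cm.where(~use_pooled, pooled_stats[0]).to_numpy(float)
    cv = cv.where(~use_pooled, pooled_stats[1]).to_numpy(float)
    cn = cn.where(~use_pooled, pooled_stats[2]).to_numpy(float)

    p = _welch_one_sided(
        g["mean"].to_numpy(), g["var"].to_numpy(), g["count"].to_numpy(), cm, cv, cn
    )
    return pd.DataFrame(
        {
            "bait": g["bait"],
            "prey": g["prey"],
            "mean_log2fc": g["mean"].to_numpy() - cm,
            "p_value": p,
            "n_replicates": g["count"].astype(int),
        }
    )


def significance_a(log2fcs, on_degenerate: str = "raise") -> np.ndarray:
    """Percentile-based outlier significance for a vector of log2 ratios.

    For each value ``r`` a robust z-score is formed from the empirical
    15.87 / 50 / 84.13 percentiles (one-sided robust standard deviations),
    and mapped to a tail probability ``0.5 * erfc(z / sqrt(2))``.  The
    statistic is location-invariant and equals 0.5 at the median.

    ``on_degenerate`` controls behaviour when a side's spread is zero:
    ``"raise"`` (default) signals pathological data, ``"saturate"`` treats
    any off-median value on that side as an infinitely strong outlier
    (sig A -> 0), which is the sensible limit for noise-free input.
    """
    r = np.asarray(log2fcs, dtype=float)
    if r.size < 10:
        raise ValueError("significance A requires >= 10 values to estimate quantiles")
    q_lo, q50, q_hi = np.percentile(r, [15.87, 50.0, 84.13])
    up, down = q_hi - q50, q50 - q_lo
    if (up <= 0 or down <= 0) and on_degenerate == "raise":
        raise ValueError(
            "degenerate ratio spread (identical quantiles); the input has "
            "(near-)constant values — check normalization or replicate quality"
        )
    z = np.empty_like(r)
    upper = r >= q50
    with np.errstate(divide="ignore", invalid="ignore"):
        z[upper] = (r[upper] - q50) / up if up > 0 else np.where(r[upper] > q50, np.inf, 0.0)
        z[~upper] = (q50 - r[~upper]) / down if down > 0 else np.inf
    return 0.5 * special.erfc(z / np.sqrt(2.0))


def add_significance_a(
    stats_df: pd.DataFrame,
    per_bait: bool = True,
    on_degenerate: str = "raise",
    value_col: str = "mean_log2fc",
) -> pd.DataFrame:
    """Attach a ``sig_a`` column computed over per-prey mean log2 ratios.

    By default the ratio distribution is taken per bait experiment; set
    ``per_bait=False`` to pool all baits.
    """
    out = stats_df.copy()
    if per_bait:
        out["sig_a"] = (
            out.groupby("bait")[value_col]
            .transform(lambda v: significance_a(v.to_numpy(), on_degenerate))
            .astype(float)
        )
    else:
        out["sig_a"] = significance_a(out[value_col].to_numpy(), on_degenerate)
    return out


def filter_true_interactors(
    stats_df: pd.DataFrame,
    thresholds: Thresholds,
    bait_count: int,
    exclusion: set | None = None,
) -> pd.DataFrame:
    """Two-step false-positive filter on enrichment statistics.

    Step 1 retains preys passing the joint P / significance A gate; step 2
    removes "frequent flyers" retained for more than
    ``contaminant_max_frequency x bait_count`` distinct baits, plus any
    prey on a user-supplied exclusion list.  Both steps log their counts.
    """
    thresholds.validate()
    if "sig_a" not in stats_df.columns:
        raise ValueError("stats require a sig_a column; run add_significance_a first")
    step1 = stats_df[
        (stats_df["p_value"] <= thresholds.p_max)
        & (stats_df["sig_a"] <= thresholds.sig_a_max)
    ]
    logger.info(
        "filter step 1 (P<=%.3g & sigA<=%.3g): %d -> %d interactions",
        thresholds.p_max,
        thresholds.sig_a_max,
        len(stats_df),
        len(step1),
    )
    freq = step1.groupby("prey")["bait"].nunique()
    flyers = set(freq[freq > thresholds.contaminant_max_frequency * bait_count].index)
    if exclusion:
        flyers |= set(exclusion)
    step2 = step1[~step1["prey"].isin(flyers)]
    logger.info(
        "filter step 2 (frequent-flyer > %.0f%% of %d baits): removed %d preys, "
        "%d interactions retained",
        100 * thresholds.contaminant_max_frequency,
        bait_count,
        len(flyers),
        len(step2),
    )
    return step2.reset_index(drop=True)


def compare_conditions(
    hi_vs_lo: pd.DataFrame, per_bait_sig_a: bool = True
) -> pd.DataFrame:
    """Direct condition-vs-condition statistics per (bait, prey).

    A two-sided one-sample t-test of the biological-replicate log2 ratios
    against 0 gives the P value; significance A is computed over the
    per-prey mean ratios of the same bait experiment (pooled across baits
    when ``per_bait_sig_a`` is False).  Zero-variance replicate sets give
    p = 1 when the mean is 0 and p = 0 otherwise.
    """
    bio = _collapse_technical(hi_vs_lo)
    g = bio.groupby(["bait", "prey"])["log2_ratio"].agg(["mean", "var", "count"])
    small = g[g["count"] < 2]
    if len(small):
        logger.warning(
            "compare_conditions: skipping %d preys with <2 biological replicates",
            len(small),
        )
        g = g[g["count"] >= 2]
    g = g.reset_index()
    m, v, n = (g[c].to_numpy(float) for c in ("mean", "var", "count"))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / np.sqrt(v / n)
    zero_var = ~(v > 0)
    if zero_var.any() and (m[zero_var] != 0).any():
        logger.warning(
            "compare_conditions: %d zero-variance replicate sets with nonzero mean "
            "(p set to 0)",
            int((zero_var & (m != 0)).sum()),
        )
    p = np.where(
        zero_var,
        np.where(m == 0, 1.0, 0.0),
        2.0 * stats.t.sf(np.abs(np.nan_to_num(t)), n - 1),
    )
    out = pd.DataFrame(
        {
            "bait": g["bait"],
            "prey": g["prey"],
            "mean_log2fc": m,
            "p_value": p,
            "n_replicates": g["count"].astype(int),
        }
    )
    return add_significance_a(out, per_bait=per_bait_sig_a, on_degenerate="saturate")


def classify_rewiring(
    net_hi_edges,
    net_lo_edges,
    diff_stats: pd.DataFrame,
    thresholds: Thresholds,
) -> pd.DataFrame:
    """Assign a rewiring category to every edge of the condition union.

    An edge is rewired only if the direct comparison passes the joint
    P / significance A gate; otherwise it is "unchanged" even when
    detected in a single network.  Rewired edges present in one network
    only become hi_only / lo_only; those present in both are
    shared_up_hi / shared_up_lo by the sign of the hi-vs-lo fold-change.
    """
    thresholds.validate()
    hi = {tuple(e) for e in net_hi_edges}
    lo = {tuple(e) for e in net_lo_edges}
    union = hi | lo
    lookup = diff_stats.set_index(["bait", "prey"])
    covered = set(lookup.index)
    missing = sorted(union - covered)
    if missing:
        raise ValueError(
            f"{len(missing)} edges lack a condition-comparison statistic, "
            f"e.g. {missing[:5]}"
        )
    rows = []
    for bait, prey in sorted(union):
        s = lookup.loc[(bait, prey)]
        p, sa, fc = float(s["p_value"]), float(s["sig_a"]), float(s["mean_log2fc"])
        significant = p <= thresholds.p_max and sa <= thresholds.sig_a_max
        if not significant or fc == 0:
            cat = "unchanged"
        elif (bait, prey) not in lo:
            cat = "hi_only"
        elif (bait, prey) not in hi:
            cat = "lo_only"
        else:
            cat = "shared_up_hi" if fc > 0 else "shared_up_lo"
        rows.append((bait, prey, cat, p, sa, fc))
    return pd.DataFrame(
        rows,
        columns=["bait", "prey", "category", "diff_p", "diff_sig_a", "log2fc_hi_vs_lo"],
    )
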