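"""Induction-versus-selection inference from barcode count tables.

The central question: after chemotherapy, does the surviving mTORC1-high
population consist of pre-existing high clones (selection) or of the same
clones as the low population, re-equilibrated between states (induction)?
Three statistics address it:

* **shared-barcode fraction** — fraction of detected barcodes present in
  both the H and L gates.  Frozen (zero-transition) clones are mono-state,
  so selection drives this to 0; state plasticity keeps it high.
* **cumulative clone-proportion curves** — barcodes ranked by decreasing
  abundance with cumulative proportion plotted; steeper curves (higher Gini)
  mean fewer clones dominate, i.e. stronger selection.  The maximum vertical
  gap between the H and L curves measures divergent clonal structure between
  gates, benchmarked against a pooled-resampling bootstrap null.
* **within-barcode log-odds ratio** — per shared barcode, the depth- and
  pseudocount-adjusted log-odds of appearing in the H versus the L gate.
  Under induction at stationarity this distribution is symmetric and
  centred at 0.

``classify_mechanism`` combines the three into an induction / selection /
indeterminate call with bootstrap confidence intervals, using a declared,
simulation-calibrated decision rule (thresholds in ``StatsConfig``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CumulativeCurve",
    "LogOddsSummary",
    "MechanismReport",
    "StatsConfig",
    "cumulative_curve",
    "curve_steepness",
    "curve_divergence",
    "shared_barcode_fraction",
    "log_odds",
    "bootstrap_counts",
    "classify_mechanism",
    "geneset_overlap",
    "plot_curves",
]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class CumulativeCurve:
    """Barcodes ranked by decreasing proportion with cumulative sums."""

    barcodes: np.ndarray
    proportions: np.ndarray
    cumulative: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.proportions) > 1e-12):
            raise ValueError("proportions must be nonincreasing")
        if abs(self.cumulative[-1] - 1.0) > 1e-12:
            raise ValueError("cumulative curve must end at 1")


@dataclass
class LogOddsSummary:
    """Per-barcode log-odds of H- versus L-gate representation."""

    values: pd.Series
    mean: float
    median: float
    skewness: float
    sign_test_p: float
    pseudocount: float
    empty: bool = False


@dataclass
class MechanismReport:
    """Per-timepoint statistics and the aggregated mechanism call."""

    per_day: pd.DataFrame      # day, shared_fraction, divergence, null95, ...
    call: str                  # induction | selection | indeterminate
    composite_score: float     # mean of per-post-day votes (+1 induction, -1 selection)
    config: "StatsConfig"

    def to_dict(self) -> dict:
        return {
            "call": self.call,
            "composite_score": self.composite_score,
            "per_day": self.per_day.to_dict(orient="records"),
        }


@dataclass(frozen=True)
class StatsConfig:
    """Decision-rule thresholds (declared, calibrated on simulations)."""

    min_count: int = 1
    pseudocount: float = 0.5
    shared_selection_max: float = 0.05   # shared fraction below -> selection
    shared_induction_min: float = 0.2    # shared fraction needed for induction
    lor_median_selection: float = log(3.0)
    sign_test_alpha: float = 0.05
    n_boot: int = 50
    null_quantile: float = 0.95
    tiebreak_day: float = 7.0            # burden nadir gets priority


# ---------------------------------------------------------------------------
# Curves
# ---------------------------------------------------------------------------


def _as_series(counts) -> pd.Series:
    s = pd.Series(counts) if not isinstance(counts, pd.Series) else counts
    return s[s > 0]


def cumulative_curve(counts) -> CumulativeCurve:
    """Rank barcodes by decreasing proportion and accumulate.

    Ties are broken lexicographically by barcode so curves are reproducible.
    """
    s = _as_series(counts)
    if len(s) == 0:
        raise ValueError("cumulative_curve requires at least one positive count")
    df = pd.DataFrame({"barcode": s.index.astype(str), "count": s.to_numpy()})
    df = df.sort_values(["count", "barcode"], ascending=[False, True])
    prop = df["count"].to_numpy(dtype=float) / float(df["count"].sum())
    cum = np.cumsum(prop)
    cum /= cum[-1]  # shed accumulated floating error so the curve ends at 1
    return CumulativeCurve(df["barcode"].to_numpy(), prop, cum)


def curve_steepness(curve: CumulativeCurve) -> tuple[float, float]:
    """Gini coefficient and mean cumulative height (area under the curve).

    Gini is 0 for a uniform clone-size distribution and approaches
    ``(k - 1) / k`` when one of k barcodes holds all mass; steeper cumulative
    curves (higher area) correspond to higher Gini, i.e. stronger selection.
    """
    p = curve.proportions
    n = len(p)
    # mean absolute difference form, computed from the sorted proportions
    asc = p[::-1]
    i = np.arange(1, n + 1)
    gini = float(np.sum((2 * i - n - 1) * asc) / (n * np.sum(asc)))
    auc = float(curve.cumulative.mean())
    return gini, auc


def curve_divergence(curve_h: CumulativeCurve, curve_l: CumulativeCurve) -> float:
    """Maximum vertical gap between two cumulative curves.

    Curves are compared rank-by-rank; the shorter curve is continued at 1
    (all of its mass already accumulated).
    """
    k = max(len(curve_h.cumulative), len(curve_l.cumulative))
    ch = np.ones(k)
    cl = np.ones(k)
    ch[:len(curve_h.cumulative)] = curve_h.cumulative
    cl[:len(curve_l.cumulative)] = curve_l.cumulative
    return float(np.abs(ch - cl).max())


# ---------------------------------------------------------------------------
# Shared barcodes and log-odds
# ---------------------------------------------------------------------------


def shared_barcode_fraction(
    table_H, table_L, min_count: int = 1, denominator: str = "union",
):
    """Fraction of barcodes detected (count >= min_count) in both gates.

    ``denominator='union'`` returns a single symmetric fraction over all
    detected barcodes; ``'each'`` returns ``(shared/|H|, shared/|L|)``.
    """
    h = _as_series(table_H)
    l = _as_series(table_L)
    idx_h = h.index[h >= min_count].to_numpy()
    idx_l = l.index[l >= min_count].to_numpy()
    n_h, n_l = len(idx_h), len(idx_l)
    n_shared = len(np.intersect1d(idx_h, idx_l, assume_unique=True))
    n_union = n_h + n_l - n_shared
    if n_union == 0:
        raise ValueError("no barcodes detected in either gate")
    if denominator == "union":
        return n_shared / n_union
    if denominator == "each":
        return (n_shared / n_h if n_h else np.nan,
                n_shared / n_l if n_l else np.nan)
    raise ValueError("denominator must be 'union' or 'each'")


def log_odds(
    table_H, table_L,
    pseudocount: float = 0.5,
    normalize_depth: bool = True,
    min_count: int = 1,
) -> LogOddsSummary:
    """Within-barcode log-odds of H- vs L-gate representation.

    For each barcode detected in both gates,

        LOR(b) = ln[(c_H(b) + q) / (D_H + q k)] - ln[(c_L(b) + q) / (D_L + q k)]

    with q the pseudocount, D the per-gate sequencing depths and k the number
    of barcodes in the union of both gates.  Depth normalisation removes the
    asymmetry introduced by sorting different numbers of cells per gate; with
    ``normalize_depth=False`` the depth terms are dropped.  The summary
    reports mean, median, skewness and a two-sided sign test for median 0.
    An absence of shared barcodes (pure selection) yields an empty summary,
    not an error.
    """
    h = _as_series(table_H)
    l = _as_series(table_L)
    if len(h) == 0 and len(l) == 0:
        raise ValueError("both tables are empty")
    shared = h.index[h >= min_count].intersection(l.index[l >= min_count])
    if len(shared) == 0:
        return LogOddsSummary(pd.Series(dtype=float), np.nan, np.nan, np.nan,
                              np.nan, pseudocount, empty=True)
    q = pseudocount
    k = len(h.index.union(l.index))
    denom_h = float(h.sum()) + q * k if normalize_depth else 1.0
    denom_l = float(l.sum()) + q * k if normalize_depth else 1.0
    lor = (np.log((h[shared] + q) / denom_h)
           - np.log((l[shared].to_numpy() + q) / denom_l))
    nonzero = lor[np.abs(lor) > 1e-12]
    if len(nonzero) == 0:
        p = 1.0
    else:
        p = stats.binomtest(int((nonzero > 0).sum()), len(nonzero), 0.5).pvalue
    skew = float(stats.skew(lor)) if len(lor) > 2 else np.nan
    return LogOddsSummary(lor, float(lor.mean()), float(lor.median()),
                          skew, float(p), pseudocount)


def bootstrap_counts(table, n_boot: int, seed) -> list[pd.Series]:
    """Multinomial resamples of a count table at its original depth."""
    s = _as_series(table)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if n_boot < 0:
        raise ValueError("n_boot must be >= 0")
    depth = int(s.sum())
    probs = s.to_numpy(dtype=float) / s.sum()
    out = []
    for _ in range(n_boot):
        draw = rng.multinomial(depth, probs)
        out.append(pd.Series(draw, index=s.index))
    return out


# ---------------------------------------------------------------------------
# Mechanism classification
# ---------------------------------------------------------------------------


def _desc_cumsum(x: np.ndarray) -> np.ndarray:
    x = x[x > 0]
    if np.issubdtype(x.dtype, np.integer) and int(x.max()) < 1_000_000:
        bc = np.bincount(x)
        desc = np.repeat(np.arange(len(bc) - 1, 0, -1), bc[1:][::-1])
    else:
        desc = np.sort(x)[::-1]
    return desc.cumsum()


def _gap_from_counts(a: np.ndarray, b: np.ndarray) -> float:
    """Max vertical gap between rank-cumulative curves of two count vectors.

    Identity-free fast path: the cumulative curve depends only on the sorted
    positive counts (counting sort for small-integer count vectors).
    """
    ca = _desc_cumsum(a)
    cb = _desc_cumsum(b)
    ca = ca / ca[-1]
    cb = cb / cb[-1]
    k = max(len(ca), len(cb))
    fa = np.ones(k)
    fb = np.ones(k)
    fa[:len(ca)] = ca
    fb[:len(cb)] = cb
    return float(np.abs(fa - fb).max())


def _divergence_null(h: pd.Series, l: pd.Series, n_boot: int, quantile: float,
                     rng: np.random.Generator) -> float:
    """Bootstrap null for the curve divergence under a common clone structure.

    Pools both gates, then resamples gate-sized tables from the pooled
    proportions; the null divergence quantifies the rank-curve gap expected
    from sampling alone.  Resampling is Poissonized (independent Poisson
    counts with the multinomial means): the gap statistic is normalised by
    the realised total, so the two schemes agree to O(1/sqrt(depth)).
    """
    pooled = h.add(l, fill_value=0)
    probs = pooled.to_numpy(dtype=float) / pooled.sum()
    lam_h, lam_l = probs * float(h.sum()), probs * float(l.sum())
    null = np.empty(n_boot)
    chunk = 20
    for start in range(0, n_boot, chunk):
        m = min(chunk, n_boot - start)
        bh = rng.poisson(lam_h, size=(m, len(probs)))
        bl = rng.poisson(lam_l, size=(m, len(probs)))
        for j in range(m):
            null[start + j] = _gap_from_counts(bh[j], bl[j])
    return float(np.quantile(null, quantile))


def classify_mechanism(
    tables: dict[float, dict[str, pd.Series]],
    config: StatsConfig | None = None,
    seed: int = 0,
) -> MechanismReport:
    """Call induction vs selection from pre/post H- and L-gate count tables.

    ``tables`` maps timepoint day -> {'H': counts, 'L': counts}; days <= 0
    are pre-treatment.  Per post-treatment day the rule is:

    * **selection** if the shared-barcode fraction is below
      ``shared_selection_max``, or the H-vs-L curve divergence exceeds its
      bootstrap null and |median LOR| > ``lor_median_selection``;
    * **induction** if the shared fraction is at least
      ``shared_induction_min``, the divergence is within the null, and the
      sign test for LOR median 0 is not rejected;
    * **indeterminate** otherwise.

    Days are aggregated by majority vote over post-treatment days, with the
    day closest to the burden nadir (day 7) breaking ties.
    """
    config = config or StatsConfig()
    rng = np.random.default_rng(seed)

    post_days = sorted(d for d in tables if d > 0)
    pre_days = sorted(d for d in tables if d <= 0)
    if not pre_days or not post_days:
        raise ValueError("need at least one pre- and one post-treatment timepoint")

    rows = []
    votes: dict[float, str] = {}
    for day in sorted(tables):
        pair = tables[day]
        if "H" not in pair or "L" not in pair:
            import warnings
            warnings.warn(f"day {day}: missing gate, skipped", stacklevel=2)
            continue
        h, l = _as_series(pair["H"]), _as_series(pair["L"])
        shared = shared_barcode_fraction(h, l, config.min_count)
        curve_h, curve_l = cumulative_curve(h), cumulative_curve(l)
        div = curve_divergence(curve_h, curve_l)
        null95 = _divergence_null(h, l, config.n_boot, config.null_quantile, rng)
        lor = log_odds(h, l, config.pseudocount, min_count=config.min_count)
        gini_h, _ = curve_steepness(curve_h)
        gini_l, _ = curve_steepness(curve_l)

        # bootstrap CI for the shared fraction
        boot_shared = []
        for bh, bl in zip(bootstrap_counts(h, config.n_boot // 4, rng),
                          bootstrap_counts(l, config.n_boot // 4, rng)):
            boot_shared.append(shared_barcode_fraction(bh, bl, config.min_count))
        ci = (float(np.quantile(boot_shared, 0.025)),
              float(np.quantile(boot_shared, 0.975))) if boot_shared else (np.nan, np.nan)

        if lor.empty or shared < config.shared_selection_max or (
                div > null95 and abs(lor.median) > config.lor_median_selection):
            call = "selection"
        elif (shared >= config.shared_induction_min and div <= null95
              and lor.sign_test_p >= config.sign_test_alpha):
            call = "induction"
        else:
            call = "indeterminate"
        if day > 0:
            votes[day] = call
        rows.append({
            "day": day, "phase": "post" if day > 0 else "pre",
            "shared_fraction": shared, "shared_ci_low": ci[0], "shared_ci_high": ci[1],
            "divergence": div, "divergence_null95": null95,
            "gini_H": gini_h, "gini_L": gini_l,
            "lor_mean": lor.mean, "lor_median": lor.median,
            "lor_sign_p": lor.sign_test_p, "n_shared": len(lor.values),
            "call": call,
        })

    score_map = {"induction": 1.0, "selection": -1.0, "indeterminate": 0.0}
    scores = [score_map[v] for v in votes.values()]
    composite = float(np.mean(scores))
    counts = pd.Series(list(votes.values())).value_counts()
    top = counts[counts == counts.max()].index.tolist()
    if len(top) == 1:
        final = top[0]
    else:  # tie: the day nearest the burden nadir decides
        nadir_day = min(votes, key=lambda d: abs(d - config.tiebreak_day))
        final = votes[nadir_day]
    return MechanismReport(pd.DataFrame(rows), final, composite, config)


# ---------------------------------------------------------------------------
# Gene-set overlap
# ---------------------------------------------------------------------------


def geneset_overlap(k_overlap: int, size_a: int, size_b: int,
                    universe_size: int) -> float:
    """Hypergeometric tail probability P(X >= k) for a gene-set overlap.

    X counts the overlap of two gene sets of sizes ``size_a`` and ``size_b``
    drawn from a universe of ``universe_size`` genes.
    """
    if not (0 <= k_overlap <= min(size_a, size_b) <= universe_size):
        raise ValueError("require 0 <= k <= min(size_a, size_b) <= universe_size")
    if max(size_a, size_b) > universe_size:
        raise ValueError("set sizes cannot exceed the universe")
    return float(stats.hypergeom.sf(k_overlap - 1, universe_size, size_a, size_b))


def plot_curves(curves: dict[str, CumulativeCurve], path=None, title=None):
    """Publication-style cumulative clone-proportion plot.

    ``curves`` maps a label (e.g. 'day 7 H') to a CumulativeCurve; H-gate
    curves are drawn solid and L-gate curves dashed when the label says so.
    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in curves.items():
        style = "--" if label.rstrip().endswith("L") else "-"
        ranks = np.arange(1, len(curve.cumulative) + 1)
        ax.plot(ranks, curve.cumulative, style, label=label, linewidth=1.2)
    ax.set_xlabel("barcode rank (decreasing proportion)")
    ax.set_ylabel("cumulative proportion")
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
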