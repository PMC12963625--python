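"""Concordance and equivalence statistics for paired window metrics.

Given paired radar/reference window means of a respiratory metric pooled
across subjects, this module provides

* descriptive statistics per source,
* the repeated-measures correlation r_rm (ANCOVA with subject-specific
  intercepts and a common slope; df = N - k - 1 for N intervals and k
  subjects),
* a modified Bland-Altman analysis: differences (radar - reference) against
  the reference value, bias mu, limits of agreement mu +/- 1.96*sigma with
  t-based confidence bands, and the fractions of intervals inside the
  equivalence bounds and inside the limits of agreement,
* a paired TOST equivalence test against symmetric clinical bounds
  (equivalence declared iff both one-sided p < alpha, which is identical to
  the 90% CI of the mean difference lying inside the bounds), and
* Cohen's d_z with a noncentral-t confidence interval.

Intervals are pooled across subjects with df = n_intervals - 1, matching
the reference analysis this package reproduces; this treats overlapping
windows as independent and is therefore anti-conservative -- see the
methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = [
    "EquivalenceBounds",
    "DEFAULT_BOUNDS",
    "RmCorrResult",
    "ConcordanceResult",
    "TostResult",
    "descriptive_stats",
    "repeated_measures_correlation",
    "bland_altman_modified",
    "tost_paired",
    "cohens_dz",
    "run_validation",
    "METRICS",
]

METRICS = ("RR", "TI", "TE", "IE")


@dataclass(frozen=True)
class EquivalenceBounds:
    """Symmetric clinical equivalence margins (-lower, +upper)."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (self.lower < 0 < self.upper):
            raise ValueError("bounds must satisfy lower < 0 < upper")


#: Clinically motivated TOST margins per metric.
DEFAULT_BOUNDS: Mapping[str, EquivalenceBounds] = {
    "RR": EquivalenceBounds(-2.0, 2.0),   # brpm
    "TI": EquivalenceBounds(-0.3, 0.3),   # s
    "TE": EquivalenceBounds(-0.3, 0.3),   # s
    "IE": EquivalenceBounds(-0.2, 0.2),   # dimensionless
}


def descriptive_stats(values_by_source: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Min, max, mean, standard error and sample SD per source."""
    rows = {}
    for source, v in values_by_source.items():
        v = np.asarray(v, float)
        if v.size == 0:
            raise ValueError("descriptive_stats requires non-empty samples")
        sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
        rows[source] = dict(
            n=v.size,
            min=float(v.min()),
            max=float(v.max()),
            mean=float(v.mean()),
            se=sd / np.sqrt(v.size),
            sd=sd,
        )
    return pd.DataFrame(rows).T


@dataclass(frozen=True)
class RmCorrResult:
    r: float
    dof: int
    p: float


def repeated_measures_correlation(subjects, x, y) -> RmCorrResult:
    """Common within-subject correlation (rmcorr).

    Equivalent to an ANCOVA of y on x with one intercept per subject and a
    shared slope: both variables are centred within subject, the correlation
    of the centred values gives |r_rm| and the common slope gives its sign;
    df = N - k - 1, with p from the corresponding t distribution.

    Subjects whose x or y is constant contribute no within-subject
    information; if no subject varies, an error is raised.
    """
    df = pd.DataFrame({"s": np.asarray(subjects), "x": np.asarray(x, float),
                       "y": np.asarray(y, float)})
    if df.isna().any().any():
        raise ValueError("missing values are not allowed")
    counts = df.groupby("s").size()
    if (counts < 2).any():
        raise ValueError("every subject needs at least 2 paired intervals")
    if counts.size < 2:
        raise ValueError("rmcorr requires at least 2 subjects")
    cx = df.x - df.groupby("s").x.transform("mean")
    cy = df.y - df.groupby("s").y.transform("mean")
    sxx = float(cx @ cx)
    syy = float(cy @ cy)
    if sxx == 0 or syy == 0:
        raise ValueError("all subjects are constant; rmcorr undefined")
    sxy = float(cx @ cy)
    r = sxy / np.sqrt(sxx * syy)
    dof = int(len(df) - counts.size - 1)
    if dof <= 0:
        raise ValueError("not enough intervals for the requested model")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(dof / (1.0 - r**2))
        p = float(2 * sst.t.sf(abs(t), dof))
    return RmCorrResult(r=r, dof=dof, p=p)


@dataclass(frozen=True)
class ConcordanceResult:
    """Modified Bland-Altman summary for one metric."""

    n: int
    bias_mu: float
    loa_sigma: float
    loa_lower: float
    loa_upper: float
    bias_ci: tuple[float, float]
    loa_lower_ci: tuple[float, float]
    loa_upper_ci: tuple[float, float]
    fraction_within_loa: float
    fraction_within_bounds: Optional[float] = None
    r_rm: Optional[float] = None
    r_rm_p: Optional[float] = None


def bland_altman_modified(
    radar,
    reference,
    bounds: Optional[EquivalenceBounds] = None,
) -> ConcordanceResult:
    """Bias, limits of agreement and within-bounds fractions.

    Differences d = radar - reference; mu = mean(d), sigma = SD(d, ddof=1);
    LoA = mu +/- 1.96*sigma.  95% CIs: mu +/- t*sigma/sqrt(n) for the bias
    and LoA +/- t*sigma*sqrt(3/n) for each limit, t = t(0.975, n-1).
    """
    d = np.asarray(radar, float) - np.asarray(reference, float)
    n = d.size
    if n < 3:
        raise ValueError("need at least 3 intervals")
    mu = float(d.mean())
    sigma = float(d.std(ddof=1))
    loa_lo, loa_hi = mu - 1.96 * sigma, mu + 1.96 * sigma
    tcrit = sst.t.ppf(0.975, n - 1)
    half_mu = tcrit * sigma / np.sqrt(n)
    half_loa = tcrit * sigma * np.sqrt(3.0 / n)
    frac_loa = float(np.mean((d >= loa_lo) & (d <= loa_hi)))
    frac_bounds = (
        float(np.mean((d >= bounds.lower) & (d <= bounds.upper)))
        if bounds is not None
        else None
    )
    return ConcordanceResult(
        n=n,
        bias_mu=mu,
        loa_sigma=sigma,
        loa_lower=loa_lo,
        loa_upper=loa_hi,
        bias_ci=(mu - half_mu, mu + half_mu),
        loa_lower_ci=(loa_lo - half_loa, loa_lo + half_loa),
        loa_upper_ci=(loa_hi - half_loa, loa_hi + half_loa),
        fraction_within_loa=frac_loa,
        fraction_within_bounds=frac_bounds,
    )


@dataclass(frozen=True)
class TostResult:
    """Two one-sided paired equivalence test against symmetric bounds."""

    n: int
    df: int
    mean_diff: float
    sd_diff: float
    t_lower: float
    t_upper: float
    p_lower: float
    p_upper: float
    overall_p: float
    raw_effect_ci: tuple[float, float]  # 90% two-sided CI of the mean diff
    cohens_dz: float
    cohens_dz_ci: tuple[float, float]
    equivalent: bool
    alpha: float = 0.05


def cohens_dz(differences, ci: float = 0.90) -> tuple[float, float, float]:
    """Paired standardized mean difference mu/sigma with a noncentral-t CI.

    The CI inverts the noncentral t distribution of the observed statistic
    t = d_z * sqrt(n): bounds are the noncentrality parameters whose upper /
    lower tail probability at t equals (1 -/+ ci)/2, divided by sqrt(n).
    """
    d = np.asarray(differences, float)
    n = d.size
    if n < 3:
        raise ValueError("need at least 3 differences")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences: d_z undefined")
    dz = float(d.mean() / sd)
    t_obs = dz * np.sqrt(n)
    df = n - 1
    lo_q, hi_q = (1 - ci) / 2, (1 + ci) / 2

    def _cdf(nc: float) -> float:
        v = sst.nct.cdf(t_obs, df, nc)
        if np.isnan(v):
            # scipy's noncentral t is unstable at large |nc|; fall back to the
            # standard normal approximation of the noncentral t CDF
            z = (t_obs * (1 - 1 / (4 * df)) - nc) / np.sqrt(1 + t_obs**2 / (2 * df))
            v = sst.norm.cdf(z)
        return v

    def _nc_for(prob: float) -> float:
        # find nc with P(T_{df, nc} <= t_obs) = prob
        f = lambda nc: _cdf(nc) - prob
        span = 10 + abs(t_obs) * 2
        lo, hi = t_obs - span, t_obs + span
        while f(lo) < 0:
            lo -= span
        while f(hi) > 0:
            hi += span
        from scipy.optimize import brentq

        return brentq(f, lo, hi, xtol=1e-12)

    nc_lo = _nc_for(hi_q)  # lower CI bound has the larger cdf
    nc_hi = _nc_for(lo_q)
    return dz, nc_lo / np.sqrt(n), nc_hi / np.sqrt(n)


def tost_paired(
    radar,
    reference=None,
    bounds: EquivalenceBounds = DEFAULT_BOUNDS["TI"],
    alpha: float = 0.05,
) -> TostResult:
    """Paired TOST; pass differences directly or (radar, reference) arrays.

    t_lower tests H0: effect <= lower bound (rejected for large positive t);
    t_upper tests H0: effect >= upper bound (rejected for large negative t).
    Equivalence is declared iff both one-sided p < alpha, which coincides
    with the (1 - 2*alpha) CI of the mean difference lying strictly inside
    the bounds.
    """
    d = np.asarray(radar, float)
    if reference is not None:
        d = d - np.asarray(reference, float)
    n = d.size
    if n < 3:
        raise ValueError("need at least 3 paired intervals")
    df = n - 1
    mu = float(d.mean())
    sd = float(d.std(ddof=1))

    if sd == 0:
        inside = bounds.lower < mu < bounds.upper
        p = 0.0 if inside else 1.0
        t_inf = np.inf if inside else -np.inf
        return TostResult(
            n=n, df=df, mean_diff=mu, sd_diff=0.0,
            t_lower=t_inf, t_upper=-t_inf,
            p_lower=p, p_upper=p, overall_p=p,
            raw_effect_ci=(mu, mu),
            cohens_dz=np.nan, cohens_dz_ci=(np.nan, np.nan),
            equivalent=bool(inside), alpha=alpha,
        )

    se = sd / np.sqrt(n)
    t_lower = (mu - bounds.lower) / se
    t_upper = (mu - bounds.upper) / se
    p_lower = float(sst.t.sf(t_lower, df))
    p_upper = float(sst.t.cdf(t_upper, df))
    overall_p = max(p_lower, p_upper)
    tcrit = sst.t.ppf(1 - alpha, df)
    ci = (mu - tcrit * se, mu + tcrit * se)
    dz, dz_lo, dz_hi = cohens_dz(d, ci=1 - 2 * alpha)
    return TostResult(
        n=n, df=df, mean_diff=mu, sd_diff=sd,
        t_lower=float(t_lower), t_upper=float(t_upper),
        p_lower=p_lower, p_upper=p_upper, overall_p=float(overall_p),
        raw_effect_ci=ci,
        cohens_dz=dz, cohens_dz_ci=(dz_lo, dz_hi),
        equivalent=bool(p_lower < alpha and p_upper < alpha),
        alpha=alpha,
    )


# ------------------------------------------------------------------ report

@dataclass
class MetricValidation:
    metric: str
    concordance: ConcordanceResult
    tost: TostResult


def run_validation(
    paired: pd.DataFrame,
    bounds: Mapping[str, EquivalenceBounds] = DEFAULT_BOUNDS,
    alpha: float = 0.05,
    outdir=None,
    make_figures: bool = True,
) -> dict[str, MetricValidation]:
    """Full method-comparison report over the four respiratory metrics.

    ``paired`` is a long-form table with columns ``subject``, ``metric``
    (RR | TI | TE | IE), ``window_start_s``, ``radar`` and ``reference``.
    Returns per-metric results; optionally writes CSV/JSON tables and
    scatter / Bland-Altman / histogram figures under ``outdir``.
    """
    required = {"subject", "metric", "radar", "reference"}
    if not required.issubset(paired.columns):
        raise ValueError(f"paired table must have columns {sorted(required)}")
    missing = [m for m in METRICS if m not in set(paired.metric)]
    if missing:
        raise ValueError(f"paired table lacks metrics: {missing}")

    results: dict[str, MetricValidation] = {}
    for metric in METRICS:
        sub = paired[paired.metric == metric]
        conc = bland_altman_modified(
            sub.radar.to_numpy(), sub.reference.to_numpy(), bounds=bounds[metric]
        )
        try:
            rm = repeated_measures_correlation(
                sub.subject.to_numpy(), sub.reference.to_numpy(), sub.radar.to_numpy()
            )
            conc = ConcordanceResult(
                **{**vars(conc), "r_rm": rm.r, "r_rm_p": rm.p}
            )
        except ValueError:
            pass  # single-subject input: r_rm not estimable
        tost = tost_paired(
            sub.radar.to_numpy(), sub.reference.to_numpy(),
            bounds=bounds[metric], alpha=alpha,
        )
        results[metric] = MetricValidation(metric=metric, concordance=conc, tost=tost)

    if outdir is not None:
        _write_report(paired, results, outdir, make_figures=make_figures)
    return results


def _results_tables(results: dict[str, MetricValidation]):
    conc_rows, tost_rows = [], []
    for m, res in results.items():
        c, t = res.concordance, res.tost
        conc_rows.append(
            dict(metric=m, n=c.n, bias=c.bias_mu, sd_diff=c.loa_sigma,
                 loa_lower=c.loa_lower, loa_upper=c.loa_upper,
                 pct_within_bounds=(np.nan if c.fraction_within_bounds is None
                                    else 100 * c.fraction_within_bounds),
                 pct_within_loa=100 * c.fraction_within_loa,
                 r_rm=c.r_rm, r_rm_p=c.r_rm_p)
        )
        tost_rows.append(
            dict(metric=m, t_lower=t.t_lower, t_upper=t.t_upper, df=t.df,
                 p=t.overall_p, raw_effect=t.mean_diff,
                 raw_ci_lower=t.raw_effect_ci[0], raw_ci_upper=t.raw_effect_ci[1],
                 cohens_dz=t.cohens_dz, dz_ci_lower=t.cohens_dz_ci[0],
                 dz_ci_upper=t.cohens_dz_ci[1], equivalent=t.equivalent)
        )
    return pd.DataFrame(conc_rows), pd.DataFrame(tost_rows)


def _write_report(paired, results, outdir, make_figures=True) -> None:
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    conc_df, tost_df = _results_tables(results)
    desc = []
    for m in METRICS:
        sub = paired[paired.metric == m]
        t = descriptive_stats({"radar": sub.radar, "reference": sub.reference})
        t.insert(0, "metric", m)
        desc.append(t.rename_axis("source").reset_index())
    pd.concat(desc, ignore_index=True).to_csv(outdir / "metrics_summary.csv", index=False)
    conc_df.to_csv(outdir / "concordance.csv", index=False)
    tost_df.to_csv(outdir / "tost.csv", index=False)
    payload = {
        m: {"concordance": {k: v for k, v in vars(res.concordance).items()},
            "tost": {k: v for k, v in vars(res.tost).items()}}
        for m, res in results.items()
    }
    (outdir / "concordance.json").write_text(
        json.dumps(payload, indent=2, default=lambda o: list(o) if isinstance(o, tuple) else o)
    )
    if make_figures:
        _figures(paired, results, outdir)


def _figures(paired, results, outdir) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    units = {"RR": "brpm", "TI": "s", "TE": "s", "IE": "-"}
    for m in METRICS:
        sub = paired[paired.metric == m]
        res = results[m]
        fig, axes = plt.subplots(1, 3, figsize=(13, 4))

        ax = axes[0]
        for _, grp in sub.groupby("subject"):
            ax.plot(grp.reference, grp.radar, ".", ms=4, alpha=0.6)
            if grp.reference.nunique() > 1:
                b, a = np.polyfit(grp.reference, grp.radar, 1)
                xs = np.array([grp.reference.min(), grp.reference.max()])
                ax.plot(xs, b * xs + a, "-", lw=0.8, alpha=0.7)
        lims = [sub[["radar", "reference"]].min().min(), sub[["radar", "reference"]].max().max()]
        ax.plot(lims, lims, "k--", lw=1, label="identity")
        c = res.concordance
        title = f"{m}: scatter"
        if c.r_rm is not None:
            title += f" (r_rm = {c.r_rm:.2f})"
        ax.set_title(title)
        ax.set_xlabel(f"reference ({units[m]})")
        ax.set_ylabel(f"radar ({units[m]})")

        ax = axes[1]
        d = sub.radar - sub.reference
        ax.plot(sub.reference, d, ".", ms=4, alpha=0.6)
        for yv, style in ((c.bias_mu, "-"), (c.loa_lower, "--"), (c.loa_upper, "--")):
            ax.axhline(yv, color="k", ls=style, lw=1)
        ax.axhspan(*c.bias_ci, color="tab:blue", alpha=0.15)
        ax.axhspan(*c.loa_lower_ci, color="tab:orange", alpha=0.15)
        ax.axhspan(*c.loa_upper_ci, color="tab:orange", alpha=0.15)
        ax.set_title(f"{m}: Bland-Altman (mu = {c.bias_mu:.2f})")
        ax.set_xlabel(f"reference ({units[m]})")
        ax.set_ylabel(f"radar - reference ({units[m]})")

        ax = axes[2]
        ax.hist(sub.reference, bins=20, alpha=0.5, label="reference")
        ax.hist(sub.radar, bins=20, alpha=0.5, label="radar")
        ax.set_title(f"{m}: distributions")
        ax.set_xlabel(units[m])
        ax.legend()

        fig.tight_layout()
        fig.savefig(outdir / f"{m.lower()}_concordance.svg")
        plt.close(fig)
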