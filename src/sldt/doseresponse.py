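"""Fraction-of-control normalization, group statistics and EC50 estimation.

Endpoints (net dye-transfer area, total cells, viable cells) are normalized
per experiment to the mean of the matched vehicle-control group and reported
as the fraction of control (FOC; control mean ≡ 1.0). Treated groups are
compared with the control by a diagnostics-driven decision tree — one-way
ANOVA with Dunnett's many-to-one test (or a two-group t-test) when every
group passes Shapiro–Wilk normality and a Brown–Forsythe equal-variance
test, otherwise Kruskal–Wallis with Dunn's many-to-one rank test (or
Mann–Whitney U). Concentration–response data are fitted with a 4-parameter
logistic,

    f(c) = bottom + (top − bottom) / (1 + (c / EC50)^hill),

one fit per independent experiment, and the experiment-level EC50s are
summarized as a geometric mean with a t-based 95% confidence interval on the
log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "FOCRecord",
    "GroupComparison",
    "FourPLModel",
    "FourPLResults",
    "DoseResponseFit",
    "EC50Summary",
    "compute_foc",
    "compare_groups",
    "fit_4pl",
    "summarize_ec50",
]

DEGENERATE_VARIANCE = "degenerate_variance"
SMALL_GROUP = "small_group_nonparametric"
CI_UNDEFINED = "ci_undefined"


# ---------------------------------------------------------------------------
# fraction of control


@dataclass
class FOCRecord:
    """One control-normalized endpoint value."""

    endpoint: str
    raw: float
    control_mean: float
    foc: float
    experiment_id: str = ""
    concentration: float = 0.0


def compute_foc(
    values: Sequence[float],
    control_values: Sequence[float],
    endpoint: str = "GJIC",
    experiment_id: str = "",
    concentrations: Sequence[float] | None = None,
) -> list[FOCRecord]:
    """Normalize per-image values to the control-group mean.

    Each FOC is ``value / mean(control_values)``; normalizing the control
    group against itself therefore gives a group mean of exactly 1.0.
    """
    control_values = np.asarray(control_values, dtype=float)
    if control_values.size == 0:
        raise ValueError("control group is empty; normalization impossible")
    cmean = float(control_values.mean())
    if cmean <= 0:
        raise ValueError(f"control mean must be > 0 for normalization, got {cmean}")
    values = np.asarray(values, dtype=float)
    if concentrations is None:
        concentrations = np.zeros(values.size)
    return [
        FOCRecord(endpoint, float(v), cmean, float(v) / cmean, experiment_id, float(c))
        for v, c in zip(values, concentrations)
    ]


# ---------------------------------------------------------------------------
# group comparisons


@dataclass
class GroupComparison:
    """Outcome of the control-vs-treatment decision tree."""

    p_values: dict  # concentration/key -> p-value vs control
    test_used: str
    overall_p: float
    normality_p: dict
    variance_p: float
    alpha: float
    control: object
    qc_flags: set = field(default_factory=set)


def dunnett_pvalues(
    treated: Sequence[np.ndarray], control: np.ndarray, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Dunnett many-to-one p-values (multivariate-t formulation)."""
    res = stats.dunnett(
        *[np.asarray(t, float) for t in treated],
        control=np.asarray(control, float),
        random_state=rng if rng is not None else np.random.default_rng(0),
    )
    return np.asarray(res.pvalue)


def dunn_many_to_one(
    treated: Sequence[np.ndarray], control: np.ndarray, adjust: str = "bonferroni"
) -> np.ndarray:
    """Dunn's rank-based many-to-one test with tie correction.

    z_j = (R̄_j − R̄_0) / sqrt((N(N+1)/12 − T/(12(N−1))) (1/n_j + 1/n_0)),
    where T = Σ(t³ − t) over tie groups; two-sided normal p-values,
    Bonferroni-adjusted over the k comparisons by default.
    """
    groups = [np.asarray(control, float)] + [np.asarray(t, float) for t in treated]
    sizes = [g.size for g in groups]
    allv = np.concatenate(groups)
    n = allv.size
    ranks = stats.rankdata(allv)
    _, counts = np.unique(allv, return_counts=True)
    ties = float(((counts**3) - counts).sum())
    var = n * (n + 1) / 12.0 - ties / (12.0 * (n - 1))
    if var <= 0:
        return np.ones(len(treated))
    means, start = [], 0
    for sz in sizes:
        means.append(ranks[start : start + sz].mean())
        start += sz
    k = len(treated)
    pvals = np.empty(k)
    for j in range(k):
        se = math.sqrt(var * (1.0 / sizes[j + 1] + 1.0 / sizes[0]))
        z = (means[j + 1] - means[0]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        pvals[j] = min(1.0, p * k) if adjust == "bonferroni" else p
    return pvals


def compare_groups(
    groups: Mapping,
    alpha: float = 0.05,
    control=None,
    rng: np.random.Generator | None = None,
) -> GroupComparison:
    """Compare treated groups with the control by the diagnostics tree.

    ``groups`` maps concentration (or any label) to the FOC values of that
    group; the control key defaults to 0 when present, else the smallest
    key. Normality (Shapiro–Wilk per group, n ≥ 3) and homoscedasticity
    (Brown–Forsythe) at ``alpha`` select the parametric branch (ANOVA +
    Dunnett, or t-test for two groups) or the rank branch (Kruskal–Wallis +
    Dunn, or Mann–Whitney U). Groups with fewer than two observations force
    the rank branch with a QC note; fully degenerate data (all values
    identical) short-circuit to p = 1.0 with a flag.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    keys = sorted(groups)
    if control is None:
        control = 0 if 0 in groups else ("0" if "0" in groups else keys[0])
    if control not in groups:
        raise ValueError(f"control key {control!r} not among groups")
    treated_keys = [k for k in keys if k != control]
    arrays = {k: np.asarray(groups[k], dtype=float) for k in keys}
    flags: set = set()

    allv = np.concatenate(list(arrays.values()))
    if np.ptp(allv) == 0:
        flags.add(DEGENERATE_VARIANCE)
        return GroupComparison(
            {k: 1.0 for k in treated_keys}, "degenerate", 1.0,
            {k: float("nan") for k in keys}, float("nan"), alpha, control, flags,
        )

    parametric_ok = all(arrays[k].size >= 2 for k in keys)
    if not parametric_ok:
        flags.add(SMALL_GROUP)

    normality_p: dict = {}
    for k in keys:
        vals = arrays[k]
        if vals.size >= 3 and np.ptp(vals) > 0:
            with np.errstate(divide="ignore", invalid="ignore"):
                normality_p[k] = float(stats.shapiro(vals).pvalue)
        else:
            normality_p[k] = float("nan")  # too small to test; not a rejection
    normal = all(not (p == p and p <= alpha) for p in normality_p.values())  # NaN passes

    try:
        with np.errstate(divide="ignore", invalid="ignore"):
            variance_p = float(stats.levene(*arrays.values(), center="median").pvalue)
    except Exception:
        variance_p = float("nan")
    eqvar = not (variance_p == variance_p and variance_p <= alpha)

    control_vals = arrays[control]
    treated_vals = [arrays[k] for k in treated_keys]

    if parametric_ok and normal and eqvar:
        if len(keys) == 2:
            r = stats.ttest_ind(treated_vals[0], control_vals, equal_var=True)
            return GroupComparison(
                {treated_keys[0]: float(r.pvalue)}, "t-test", float(r.pvalue),
                normality_p, variance_p, alpha, control, flags,
            )
        overall = float(stats.f_oneway(*arrays.values()).pvalue)
        pvals = dunnett_pvalues(treated_vals, control_vals, rng)
        return GroupComparison(
            dict(zip(treated_keys, (float(p) for p in pvals))), "ANOVA+Dunnett",
            overall, normality_p, variance_p, alpha, control, flags,
        )

    if len(keys) == 2:
        r = stats.mannwhitneyu(treated_vals[0], control_vals, alternative="two-sided")
        return GroupComparison(
            {treated_keys[0]: float(r.pvalue)}, "Mann-Whitney", float(r.pvalue),
            normality_p, variance_p, alpha, control, flags,
        )
    overall = float(stats.kruskal(*arrays.values()).pvalue)
    pvals = dunn_many_to_one(treated_vals, control_vals)
    return GroupComparison(
        dict(zip(treated_keys, (float(p) for p in pvals))), "KW+Dunn",
        overall, normality_p, variance_p, alpha, control, flags,
    )


# ---------------------------------------------------------------------------
# 4-parameter logistic fitting


def _fourpl(c, bottom, top, log10_ec50, hill):
    return bottom + (top - bottom) / (1.0 + (c / 10.0**log10_ec50) ** hill)


@dataclass
class FourPLResults:
    """Fitted 4PL parameters for one experiment.

    ``hill > 0`` describes an inhibitor (response falls with concentration),
    ``hill < 0`` a stimulator. ``ec50`` is NaN when the fit did not converge
    (flat or non-monotone data) — never a fabricated number.
    """

    bottom: float
    top: float
    hill: float
    ec50: float
    converged: bool
    sse: float
    experiment_id: str = ""
    nobs: int = 0
    bse: dict = field(default_factory=dict)
    ec50_unit: str = ""

    @property
    def params(self) -> dict:
        return {"bottom": self.bottom, "top": self.top, "hill": self.hill, "ec50": self.ec50}

    def predict(self, c):
        return _fourpl(np.asarray(c, float), self.bottom, self.top, math.log10(self.ec50), self.hill)

    def summary(self) -> str:
        lines = [
            "4-parameter logistic concentration-response fit",
            "=" * 48,
            f"experiment: {self.experiment_id or '-'}   n obs: {self.nobs}",
            f"converged:  {self.converged}   SSE: {self.sse:.6g}",
            "-" * 48,
            f"{'param':<10}{'estimate':>14}{'std err':>14}",
        ]
        for name in ("bottom", "top", "hill", "ec50"):
            se = self.bse.get(name, float("nan"))
            lines.append(f"{name:<10}{getattr(self, name):>14.6g}{se:>14.6g}")
        if self.ec50_unit:
            lines.append(f"ec50 unit: {self.ec50_unit}")
        return "\n".join(lines)

    def plot(self, ax=None, **scatter_kw):
        """Concentration–response curve with the fitted 4PL overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.converged:
            lo, hi = self.ec50 / 1000.0, self.ec50 * 1000.0
            cgrid = np.geomspace(lo, hi, 200)
            ax.plot(cgrid, self.predict(cgrid), "-", label="4PL fit")
        ax.set_xscale("log")
        ax.set_xlabel("concentration")
        ax.set_ylabel("fraction of control")
        return ax


#: alias: the fit result doubles as the per-experiment dose-response record.
DoseResponseFit = FourPLResults


class FourPLModel:
    """4PL concentration–response model (fit one independent experiment).

    Parameters
    ----------
    concentration, response :
        Per-observation arrays; concentrations must be positive (vehicle
        controls at c = 0 anchor the top asymptote through normalization and
        are excluded from the likelihood).
    """

    def __init__(self, concentration, response, experiment_id: str = "", ec50_unit: str = ""):
        conc = np.asarray(concentration, dtype=float)
        resp = np.asarray(response, dtype=float)
        if conc.shape != resp.shape:
            raise ValueError("concentration and response must have the same length")
        keep = conc > 0
        self.concentration = conc[keep]
        self.response = resp[keep]
        if not np.all(np.isfinite(self.response)):
            raise ValueError("responses must be finite")
        if np.unique(self.concentration).size < 4:
            raise ValueError("need at least 4 distinct positive concentrations for a 4PL fit")
        self.experiment_id = experiment_id
        self.ec50_unit = ec50_unit

    @classmethod
    def from_dataframe(cls, df, conc_col="concentration", resp_col="foc", **kw):
        return cls(df[conc_col].to_numpy(), df[resp_col].to_numpy(), **kw)

    def _initial_params(self) -> tuple[float, float, float, float]:
        conc, resp = self.concentration, self.response
        uniq = np.unique(conc)
        means = np.array([resp[conc == u].mean() for u in uniq])
        top0, bottom0 = float(means.max()), float(means.min())
        # response direction: falling with concentration -> hill +1
        hill0 = 1.0 if means[0] >= means[-1] else -1.0
        half = (top0 + bottom0) / 2.0
        ec50_0 = float(uniq[np.argmin(np.abs(means - half))])
        return bottom0, top0, ec50_0, hill0

    def fit(self, anchor_top: float | None = None, min_span: float = 0.1) -> FourPLResults:
        """Least-squares 4PL fit.

        ``anchor_top`` fixes the top asymptote (e.g. at 1.0 on the FOC
        scale); by default all four parameters are free. Data whose group
        means span less than ``min_span`` are declared flat and returned
        non-converged with NaN EC50.
        """
        conc, resp = self.concentration, self.response
        uniq = np.unique(conc)
        means = np.array([resp[conc == u].mean() for u in uniq])
        bottom0, top0, ec50_0, hill0 = self._initial_params()

        def _failed(flags_sse=float("nan")):
            return FourPLResults(
                float("nan"), float("nan"), float("nan"), float("nan"),
                False, flags_sse, self.experiment_id, conc.size, {}, self.ec50_unit,
            )

        if float(means.max() - means.min()) < min_span:
            return _failed()

        try:
            if anchor_top is None:
                p0 = [bottom0, top0, math.log10(ec50_0), hill0]
                popt, pcov = optimize.curve_fit(
                    _fourpl, conc, resp, p0=p0, maxfev=20000
                )
                bottom, top, log_ec50, hill = popt
            else:
                def f(c, bottom, log10_ec50, hill):
                    return _fourpl(c, bottom, anchor_top, log10_ec50, hill)

                p0 = [bottom0, math.log10(ec50_0), hill0]
                popt, pcov = optimize.curve_fit(f, conc, resp, p0=p0, maxfev=20000)
                bottom, log_ec50, hill = popt
                top = anchor_top
        except (RuntimeError, ValueError):
            return _failed()

        ec50 = 10.0**log_ec50
        resid = resp - _fourpl(conc, bottom, top, log_ec50, hill)
        sse = float(resid @ resid)
        if not np.isfinite(ec50) or ec50 <= 0:
            return _failed(sse)
        # plausibility guard: an EC50 far outside the tested range means the
        # curve has no information about it (no plateau reached) — report
        # non-convergence rather than an extrapolated number
        if not (uniq.min() / 100.0 <= ec50 <= uniq.max() * 100.0):
            return _failed(sse)

        bse: dict = {}
        diag = np.diag(pcov)
        if np.all(np.isfinite(diag)):
            names = (
                ["bottom", "top", "log_ec50", "hill"]
                if anchor_top is None
                else ["bottom", "log_ec50", "hill"]
            )
            se = dict(zip(names, np.sqrt(diag)))
            bse = {k: float(v) for k, v in se.items() if k != "log_ec50"}
            if "log_ec50" in se:  # delta method back to the linear scale
                bse["ec50"] = float(math.log(10.0) * ec50 * se["log_ec50"])
        return FourPLResults(
            float(bottom), float(top), float(hill), float(ec50),
            True, sse, self.experiment_id, conc.size, bse, self.ec50_unit,
        )


def fit_4pl(
    concentrations,
    foc_values,
    experiment_id: str = "",
    anchor_top: float | None = None,
    ec50_unit: str = "",
) -> FourPLResults:
    """Convenience wrapper: build a :class:`FourPLModel` and fit it."""
    return FourPLModel(
        concentrations, foc_values, experiment_id=experiment_id, ec50_unit=ec50_unit
    ).fit(anchor_top=anchor_top)


# ---------------------------------------------------------------------------
# cross-experiment EC50 summary


@dataclass
class EC50Summary:
    """Geometric-mean EC50 across independent experiments with 95% CI."""

    geomean_ec50: float
    ci_low: float
    ci_high: float
    n_experiments: int
    qc_flags: set = field(default_factory=set)


def summarize_ec50(fits: Sequence) -> EC50Summary:
    """Geometric mean of converged experiment-level EC50s with a 95% CI.

    The CI is t-based on ln(EC50) with n − 1 degrees of freedom,
    exponentiated back. A single experiment yields an undefined CI (NaN,
    flagged); zero converged fits is an error.
    """
    ec50s = []
    for f in fits:
        val = f.ec50 if hasattr(f, "ec50") else float(f)
        conv = getattr(f, "converged", True)
        if conv and np.isfinite(val) and val > 0:
            ec50s.append(float(val))
    if not ec50s:
        raise ValueError("no converged EC50 estimates to summarize")
    logs = np.log(ec50s)
    n = logs.size
    geo = float(np.exp(logs.mean()))
    flags: set = set()
    if n == 1:
        flags.add(CI_UNDEFINED)
        return EC50Summary(geo, float("nan"), float("nan"), 1, flags)
    sem = logs.std(ddof=1) / math.sqrt(n)
    tcrit = stats.t.ppf(0.975, df=n - 1)
    return EC50Summary(
        geo, float(np.exp(logs.mean() - tcrit * sem)), float(np.exp(logs.mean() + tcrit * sem)),
        n, flags,
    )
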