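"""Statistics for three-zone choice-assay trials.

Each trial records how long one animal spent in the cue-side, middle and
far third of a tank during a fixed observation window, for one cue
treatment (a solvent control and three cue concentrations) at one pH.
The design is paired within animals: every animal sees all four
treatments at its assigned pH.

The response is the percentage of trial time in the cue-side third.  The
dose–response model is a linear mixed model with treatment as a 4-level
fixed factor and a random intercept per animal (REML).  The omnibus
treatment test is a Wald F with the balanced-design denominator
(n−1)(t−1) degrees of freedom, alongside a likelihood-ratio chi-squared;
post-hoc pairwise contrasts use a Tukey-style single-step adjustment via
the equicoordinate multivariate-t distribution (Holm fallback).  The
between-pH effect contrasts per-animal (high dose − control) changes with
a one-sided Welch t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .errors import InsufficientDataError, InvalidInputError, UnbalancedDesignError

__all__ = [
    "TREATMENTS",
    "DegenerateVarianceWarning",
    "zone_fractions",
    "validate_trials",
    "DoseResponseModel",
    "DoseResponseResults",
    "PairwiseComparison",
    "fit_dose_response",
    "posthoc_pairwise",
    "BetweenPhResult",
    "between_ph_effect",
    "count_preferring",
]

#: Canonical treatment levels in increasing dose order (mol/L on the filter paper).
TREATMENTS = ("control", "3e-6", "3e-5", "3e-4")

_ZONES = {"near": "t_near_s", "neutral": "t_neutral_s", "far": "t_far_s"}


class DegenerateVarianceWarning(UserWarning):
    """Random-intercept variance estimated at (or collapsed to) zero."""


def canonical_treatment(value) -> str:
    """Normalise a treatment label to one of :data:`TREATMENTS`."""
    s = str(value).strip().lower()
    if s in {"control", "ctrl", "0", "0.0", "blank"}:
        return "control"
    try:
        x = float(s)
    except ValueError:
        raise InvalidInputError(f"unrecognised treatment label {value!r}")
    for canon in TREATMENTS[1:]:
        if abs(x - float(canon)) <= 1e-3 * float(canon):
            return canon
    raise InvalidInputError(f"unrecognised treatment concentration {value!r}")


def validate_trials(df: pd.DataFrame, slack_s: float = 1.0) -> pd.DataFrame:
    """Validate and normalise a trial table.

    Requires columns crab_id, ph, treatment, t_near_s, t_neutral_s,
    t_far_s, total_s.  Times must be non-negative and sum to the total
    within ``slack_s`` (whole-second scoring slack); each animal appears
    once per treatment within one pH condition.
    """
    required = {"crab_id", "ph", "treatment", "t_near_s", "t_neutral_s", "t_far_s", "total_s"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"trial table missing columns: {sorted(missing)}")
    out = df.copy()
    out["treatment"] = out["treatment"].map(canonical_treatment)
    times = out[["t_near_s", "t_neutral_s", "t_far_s"]].to_numpy(dtype=float)
    if np.any(times < 0) or not np.all(np.isfinite(times)):
        raise InvalidInputError("zone times must be finite and non-negative")
    mismatch = np.abs(times.sum(axis=1) - out["total_s"].to_numpy(dtype=float)) > slack_s
    if mismatch.any():
        bad = out.index[mismatch].tolist()[:5]
        raise InvalidInputError(f"zone times do not sum to total_s (rows {bad}...)")
    dup = out.duplicated(subset=["crab_id", "ph", "treatment"])
    if dup.any():
        raise InvalidInputError(
            f"duplicate (crab, pH, treatment) rows: {out.loc[dup, ['crab_id', 'ph', 'treatment']].values.tolist()}"
        )
    return out


def zone_fractions(trials: pd.DataFrame) -> pd.DataFrame:
    """Augment trials with percentage of time per zone (sums to 100/trial)."""
    df = validate_trials(trials)
    total = df["total_s"].to_numpy(dtype=float)
    if np.any(total <= 0):
        raise InvalidInputError("invalid trial: zero or negative total time")
    for zone, col in _ZONES.items():
        df[f"{zone}_pct"] = 100.0 * df[col].to_numpy(dtype=float) / total
    return df


def _check_paired(df: pd.DataFrame) -> None:
    crabs = df["crab_id"].unique()
    if len(crabs) < 2:
        raise InsufficientDataError(f"need >= 2 animals, got {len(crabs)}")
    missing = []
    for crab, grp in df.groupby("crab_id"):
        for t in TREATMENTS:
            if t not in set(grp["treatment"]):
                missing.append((crab, t))
    if missing:
        raise UnbalancedDesignError(f"missing (crab, treatment) cells: {missing}")


@dataclass(frozen=True)
class PairwiseComparison:
    pair: tuple
    estimate: float  # mean(first) - mean(second), percentage points
    stderr: float
    t_value: float
    p_unadjusted: float
    p_adjusted: float


@dataclass
class DoseResponseResults:
    """Fitted dose–response summary for one pH condition."""

    ph: float | None
    zone: str
    n_crabs: int
    fixed_effects: dict  # treatment -> estimated mean % time
    effects_vs_control: dict  # treatment -> difference to control, pp
    random_intercept_sd: float
    omnibus_F: float
    omnibus_df: tuple
    omnibus_p: float
    lrt_chi2: float
    lrt_df: int
    lrt_p: float
    method: str
    comparisons: list = field(default_factory=list)
    _param_means: dict = field(default_factory=dict, repr=False)
    _cov_means: np.ndarray | None = field(default=None, repr=False)

    def summary(self) -> str:
        lines = [
            f"Dose-response fit ({self.method}), zone={self.zone}, "
            f"pH={self.ph}, n={self.n_crabs} animals",
            f"random intercept SD: {self.random_intercept_sd:.2f} % time",
            f"omnibus treatment test: F({self.omnibus_df[0]:.0f}, {self.omnibus_df[1]:.0f}) "
            f"= {self.omnibus_F:.3f}, p = {self.omnibus_p:.4f}; "
            f"LRT chi2({self.lrt_df}) = {self.lrt_chi2:.3f}, p = {self.lrt_p:.4f}",
            "treatment means (% time):",
        ]
        for t in TREATMENTS:
            lines.append(f"  {t:>8}: {self.fixed_effects[t]:6.1f}")
        for c in self.comparisons:
            lines.append(
                f"  {c.pair[0]} - {c.pair[1]}: {c.estimate:+.2f} pp, "
                f"p_adj = {c.p_adjusted:.4f}"
            )
        return "\n".join(lines)


class DoseResponseModel:
    """Random-intercept model of % zone time on the 4-level treatment factor.

    Parameters
    ----------
    trials : DataFrame
        Trial table (see :func:`validate_trials`); one pH condition.
    ph : float, optional
        Subset to this pH before fitting.
    zone : {"near", "far", "neutral"}
        Which zone's time percentage is the response (cue-side by default).
    """

    def __init__(self, trials: pd.DataFrame, ph: float | None = None, zone: str = "near"):
        if zone not in _ZONES:
            raise InvalidInputError(f"zone must be one of {sorted(_ZONES)}")
        df = zone_fractions(trials)
        if ph is not None:
            df = df[np.isclose(df["ph"].astype(float), float(ph))]
            if df.empty:
                raise InsufficientDataError(f"no trials at pH {ph}")
        elif df["ph"].nunique() > 1:
            raise InvalidInputError("trials span several pH conditions; pass ph=")
        _check_paired(df)
        self.ph = float(ph) if ph is not None else float(df["ph"].iloc[0])
        self.zone = zone
        self.data = df.assign(
            response=df[f"{zone}_pct"],
            treatment=pd.Categorical(df["treatment"], categories=list(TREATMENTS)),
        )

    # -- internals ---------------------------------------------------------
    _FORMULA = "response ~ C(treatment, Treatment(reference='control'))"

    def _design_row(self, treatment: str, params_index) -> np.ndarray:
        """Fixed-effects design row for the mean of one treatment level."""
        x = np.zeros(len(params_index))
        for i, name in enumerate(params_index):
            if name == "Intercept":
                x[i] = 1.0
            elif f"[T.{treatment}]" in name:
                x[i] = 1.0
        return x

    def fit(self) -> DoseResponseResults:
        df = self.data
        n_crabs = df["crab_id"].nunique()
        ddf = (n_crabs - 1) * (len(TREATMENTS) - 1)

        method = "mixed (REML)"
        params = cov = None
        sd_re = 0.0
        degenerate = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            try:
                mod = smf.mixedlm(self._FORMULA, df, groups=df["crab_id"])
                res = mod.fit(reml=True)
                sd_re = float(np.sqrt(max(res.cov_re.iloc[0, 0], 0.0)))
                fe_names = list(res.fe_params.index)
                params = res.fe_params
                cov = res.cov_params().loc[fe_names, fe_names]
                if res.cov_re.iloc[0, 0] < 1e-8:
                    raise _DegenerateVariance
            except (_DegenerateVariance, np.linalg.LinAlgError, ValueError):
                degenerate = True
                method = "fixed-effects paired (OLS)"
                ols = smf.ols(self._FORMULA + " + C(crab_id)", df).fit()
                keep = [n for n in ols.params.index if "crab_id" not in n]
                params = ols.params[keep]
                cov = ols.cov_params().loc[keep, keep]
                ddf = int(ols.df_resid)
                sd_re = 0.0
        if degenerate:
            warnings.warn(
                "random-intercept variance degenerate; fell back to a "
                "fixed-effects paired model",
                DegenerateVarianceWarning,
                stacklevel=2,
            )

        fe_names = list(params.index)
        b = params.to_numpy()
        V = cov.to_numpy()

        means, rows = {}, {}
        for t in TREATMENTS:
            x = self._design_row(t, fe_names)
            rows[t] = x
            means[t] = float(x @ b)
        effects = {t: means[t] - means["control"] for t in TREATMENTS[1:]}

        # Omnibus Wald F on the three treatment coefficients.
        L = np.array([rows[t] - rows["control"] for t in TREATMENTS[1:]])
        est = L @ b
        M = L @ V @ L.T
        q = L.shape[0]
        if np.ptp(df["response"].to_numpy()) < 1e-10:  # all responses identical
            F, p_F = 0.0, 1.0
        else:
            try:
                stat = float(est @ np.linalg.solve(M, est))
                F = stat / q
                p_F = float(st.f.sf(F, q, ddf))
            except np.linalg.LinAlgError:  # zero-variance contrast covariance
                F, p_F = 0.0, 1.0

        lrt_chi2, lrt_p = self._lrt(df)

        X = np.array([rows[t] for t in TREATMENTS])
        return DoseResponseResults(
            ph=self.ph,
            zone=self.zone,
            n_crabs=n_crabs,
            fixed_effects=means,
            effects_vs_control=effects,
            random_intercept_sd=sd_re,
            omnibus_F=F,
            omnibus_df=(q, ddf),
            omnibus_p=p_F,
            lrt_chi2=lrt_chi2,
            lrt_df=3,
            lrt_p=lrt_p,
            method=method,
            _param_means={t: X[i] @ b for i, t in enumerate(TREATMENTS)},
            _cov_means=X @ V @ X.T,
        )

    def _lrt(self, df: pd.DataFrame) -> tuple:
        """Likelihood-ratio omnibus (ML fits of full vs intercept-only model)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                full = smf.mixedlm(self._FORMULA, df, groups=df["crab_id"]).fit(reml=False)
                null = smf.mixedlm("response ~ 1", df, groups=df["crab_id"]).fit(reml=False)
                chi2 = max(0.0, 2.0 * (full.llf - null.llf))
                return float(chi2), float(st.chi2.sf(chi2, 3))
            except (np.linalg.LinAlgError, ValueError):
                return float("nan"), float("nan")


class _DegenerateVariance(Exception):
    pass


def fit_dose_response(trials: pd.DataFrame, ph: float | None = None, zone: str = "near"):
    """Fit the random-intercept dose–response model for one pH condition."""
    return DoseResponseModel(trials, ph=ph, zone=zone).fit()


def posthoc_pairwise(
    fit: DoseResponseResults, random_state: int = 20181101
) -> list[PairwiseComparison]:
    """All pairwise treatment contrasts with family-wise error control.

    Single-step Tukey-style adjustment: each |t| is referred to the
    equicoordinate multivariate-t distribution of the full contrast
    family (correlation from the fitted contrast covariance, df from the
    omnibus denominator).  Falls back to Holm if that distribution cannot
    be evaluated; the method used is recorded on the fit.
    """
    if fit._cov_means is None:
        raise InvalidInputError("fit carries no covariance information")
    levels = list(TREATMENTS)
    pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1 :]]
    k = len(levels)
    C = np.zeros((len(pairs), k))
    for r, (a, b) in enumerate(pairs):
        C[r, levels.index(a)], C[r, levels.index(b)] = 1.0, -1.0
    m = np.array([fit._param_means[t] for t in levels], dtype=float)
    est = C @ m
    Vc = C @ fit._cov_means @ C.T
    se = np.sqrt(np.diag(Vc))
    tvals = est / se
    ddf = fit.omnibus_df[1]
    p_raw = 2.0 * st.t.sf(np.abs(tvals), ddf)

    p_adj, method = _single_step_mvt(tvals, Vc, ddf, random_state)
    if p_adj is None:
        p_adj = _holm(p_raw)
        method = "holm"
    p_adj = np.minimum(1.0, np.maximum(p_adj, p_raw))  # adjustment never helps

    comps = [
        PairwiseComparison(
            pair=pairs[i],
            estimate=float(est[i]),
            stderr=float(se[i]),
            t_value=float(tvals[i]),
            p_unadjusted=float(p_raw[i]),
            p_adjusted=float(p_adj[i]),
        )
        for i in range(len(pairs))
    ]
    fit.comparisons = comps
    fit.method = f"{fit.method}; posthoc={method}"
    return comps


def _single_step_mvt(tvals, Vc, ddf, random_state):
    try:
        d = np.sqrt(np.diag(Vc))
        R = Vc / np.outer(d, d)
        R = (R + R.T) / 2.0 + 1e-10 * np.eye(len(d))
        mvt = st.multivariate_t(loc=np.zeros(len(d)), shape=R, df=ddf, allow_singular=True)
        out = np.empty(len(tvals))
        for i, t in enumerate(np.abs(tvals)):
            inside = mvt.cdf(
                np.full(len(d), t),
                lower_limit=np.full(len(d), -t),
                random_state=np.random.default_rng(random_state),
            )
            out[i] = 1.0 - float(inside)
        return np.clip(out, 0.0, 1.0), "tukey-single-step"
    except Exception:
        return None, None


def _holm(p_raw: np.ndarray) -> np.ndarray:
    order = np.argsort(p_raw)
    m = len(p_raw)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p_raw[idx])
        adj[idx] = min(1.0, running)
    return adj


@dataclass(frozen=True)
class BetweenPhResult:
    mean_difference_pp: float
    t_value: float
    df: float
    p_one_sided: float
    n: tuple
    deltas_low_ph: np.ndarray = field(repr=False, default=None)
    deltas_high_ph: np.ndarray = field(repr=False, default=None)


def _per_crab_delta(trials: pd.DataFrame, zone: str, treatment_high: str) -> pd.Series:
    df = zone_fractions(trials)
    wide = df.pivot_table(index="crab_id", columns="treatment", values=f"{zone}_pct")
    for t in ("control", treatment_high):
        if t not in wide.columns or wide[t].isna().any():
            missing = (
                [(c, t) for c in wide.index[wide[t].isna()]] if t in wide.columns
                else [(c, t) for c in wide.index]
            )
            raise UnbalancedDesignError(f"missing (crab, treatment) cells: {missing}")
    return wide[treatment_high] - wide["control"]


def between_ph_effect(
    trials_low_ph: pd.DataFrame,
    trials_high_ph: pd.DataFrame,
    treatment_high: str = "3e-4",
    zone: str = "near",
) -> BetweenPhResult:
    """Between-pH contrast of the per-animal high-dose attraction effect.

    Δ = (% time near cue at the highest dose) − (% time in control) per
    animal; the low-pH Δs are compared against the high-pH Δs with a
    one-sided Welch two-sample t-test (alternative: low pH > high pH).
    Returns the mean difference in percentage points and the p-value.
    """
    d_low = _per_crab_delta(trials_low_ph, zone, treatment_high).to_numpy(dtype=float)
    d_high = _per_crab_delta(trials_high_ph, zone, treatment_high).to_numpy(dtype=float)
    if len(d_low) < 2 or len(d_high) < 2:
        raise InsufficientDataError("need >= 2 animals per pH condition")
    res = st.ttest_ind(d_low, d_high, equal_var=False, alternative="greater")
    return BetweenPhResult(
        mean_difference_pp=float(d_low.mean() - d_high.mean()),
        t_value=float(res.statistic),
        df=float(res.df),
        p_one_sided=float(res.pvalue),
        n=(len(d_low), len(d_high)),
        deltas_low_ph=d_low,
        deltas_high_ph=d_high,
    )


def count_preferring(trials: pd.DataFrame, treatment_high: str = "3e-4", zone: str = "near") -> int:
    """Animals spending strictly more time near the cue at the highest dose
    than in their own control trial (ties count as non-preferring)."""
    delta = _per_crab_delta(trials, zone, treatment_high)
    return int((delta > 0).sum())
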