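"""Study statistics: measurement uncertainty, power-based sample sizing, and
repeated-measures modelling with a compound-symmetry covariance structure.

The longitudinal responses (volume change, RMS, radiographic area change —
all expressed as change from the specimen's own baseline) are modelled as

    y_ijk = mu + group_i + time_j + (group x time)_ij + b_k + e_ijk,

with a random intercept ``b_k ~ N(0, sigma_b^2)`` per specimen and residual
``e ~ N(0, sigma_e^2)``.  A random intercept with non-negative correlation is
exactly the compound-symmetry structure: equal variance and equal
within-specimen correlation at all repeated measures.  Estimation is REML via
statsmodels MixedLM; missing cells are handled by using all available rows
(no imputation).

Least-squares (LS) means are model-based cell means averaged over the other
factor at equal weights.  Pairwise group differences and within-group
time-versus-baseline effects are reported with SEs, Bonferroni-adjusted p
values and 95% confidence intervals (CIs unadjusted by default; a flag
produces Bonferroni-adjusted CIs).  Because the responses are changes from
baseline, baseline itself is not a modelled time level; each period's LS mean
is tested against zero.

Denominator degrees of freedom use a between-within split: between-specimen
contrasts (group comparisons) get ``n_specimens - n_groups`` df, and
within-specimen contrasts (time effects) get the residual within df.  This is
one of the standard mixed-model df families; no exact reproduction of any
particular software's default is claimed.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .errors import InsufficientReplicatesError, ValidationError

# ---------------------------------------------------------------------------
# measurement uncertainty
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UncertaintyRecord:
    S: float      # sample SD (n-1 denominator)
    n: int        # number of repeat measurements
    u: float      # standard uncertainty, S / sqrt(n)
    k: float      # coverage factor
    U: float      # expanded uncertainty, k * u  (~95% confidence for k = 2)


def measurement_uncertainty(values, k: float = 2.0) -> UncertaintyRecord:
    """Standard and expanded measurement uncertainty of repeated measurements.

    ``u = S / sqrt(n)`` with S the sample standard deviation; the expanded
    uncertainty ``U = k u`` gives a ~95% confidence interval for ``k = 2``.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        raise InsufficientReplicatesError(
            "at least 2 repeat measurements are required")
    if k <= 0:
        raise ValidationError("coverage factor must be positive")
    S = float(np.std(vals, ddof=1))
    u = S / math.sqrt(vals.size)
    return UncertaintyRecord(S=S, n=int(vals.size), u=u, k=float(k), U=float(k) * u)


# ---------------------------------------------------------------------------
# sample size
# ---------------------------------------------------------------------------

def power_two_sample_t(n_per_group: int, effect_size: float,
                       alpha: float = 0.05) -> float:
    """Exact power of the two-sided two-sample t test at ``n`` per group."""
    df = 2 * n_per_group - 2
    tc = st.t.ppf(1.0 - alpha / 2.0, df)
    ncp = effect_size * math.sqrt(n_per_group / 2.0)
    return float(1.0 - st.nct.cdf(tc, df, ncp) + st.nct.cdf(-tc, df, ncp))


def sample_size_two_groups(delta_pct: float, sd_pct: float,
                           alpha: float = 0.05, power: float = 0.90) -> int:
    """Smallest per-group n detecting a mean difference ``delta`` at SD ``sd``.

    Two-sided two-sample t test; the normal-approximation start
    ``n = 2 (z_{1-a/2} + z_{1-b})^2 (sd/delta)^2`` is refined by exact
    noncentral-t power evaluation until the smallest integer n with
    power >= target is found (floor n = 2).
    """
    if delta_pct <= 0 or sd_pct <= 0:
        raise ValidationError("effect and SD must be positive")
    if not (0.0 < alpha < 1.0):
        raise ValidationError("alpha must lie in (0, 1)")
    if not (alpha < power < 1.0):
        raise ValidationError("power must exceed alpha and be below 1")
    d = delta_pct / sd_pct
    z = st.norm.ppf(1.0 - alpha / 2.0) + st.norm.ppf(power)
    n = max(2, int(math.floor(2.0 * (z / d) ** 2)) - 2)
    while power_two_sample_t(n, d, alpha) < power:
        n += 1
        if n > 10_000_000:  # pragma: no cover - absurd inputs
            raise ValidationError("required sample size is unreasonably large")
    while n > 2 and power_two_sample_t(n - 1, d, alpha) >= power:
        n -= 1
    return n


def inflate_for_dropout(n: int, dropout: float) -> int:
    """Inflate a per-group n for anticipated specimen loss: ceil(n / (1 - dropout))."""
    if n < 1:
        raise ValidationError("n must be positive")
    if not (0.0 <= dropout < 1.0):
        raise ValidationError("dropout fraction must lie in [0, 1)")
    m = n / (1.0 - dropout)
    if abs(m - round(m)) < 1e-9:  # guard float noise at exact ratios
        m = round(m)
    return int(math.ceil(m))


# ---------------------------------------------------------------------------
# compound-symmetry repeated-measures model
# ---------------------------------------------------------------------------

@dataclass
class ComparisonRecord:
    label: str
    estimate: float
    se: float
    df: float
    stat: float
    p_raw: float
    p_adj: float
    ci_low: float
    ci_high: float
    family_size: int
    estimable: bool = True
    note: str = ""

    def as_dict(self):
        return {
            "effect": self.label, "estimate": self.estimate, "SE": self.se,
            "df": self.df, "t": self.stat, "p_raw": self.p_raw, "p": self.p_adj,
            "CI_low": self.ci_low, "CI_high": self.ci_high,
            "estimable": self.estimable, "note": self.note,
        }


def _levels(series: pd.Series):
    if isinstance(series.dtype, pd.CategoricalDtype):
        cats = [c for c in series.cat.categories if c in set(series)]
        return list(cats)
    return list(pd.unique(series))


class RepeatedMeasuresCS:
    """Repeated-measures model with compound-symmetry covariance.

    Fixed effects: group, time and their interaction; random intercept per
    specimen.  Build from a tidy table with one row per specimen x time.

    Examples
    --------
    >>> model = RepeatedMeasuresCS.from_dataframe(df, response="response")
    >>> res = model.fit()
    >>> res.pairwise_groups()          # Table-2-style group comparisons
    >>> res.time_effects()             # Table-3-style within-group effects
    """

    def __init__(self, data: pd.DataFrame, response: str = "response",
                 group: str = "group", time: str = "time",
                 subject: str = "specimen_id"):
        cols = [subject, group, time, response]
        for c in cols:
            if c not in data.columns:
                raise ValidationError(f"missing column {c!r}")
        df = data[cols].dropna().copy()
        self.group_levels = [str(x) for x in _levels(df[group])]
        self.time_levels = [str(x) for x in _levels(df[time])]
        if len(self.group_levels) < 2 or len(self.time_levels) < 2:
            raise ValidationError("need >= 2 groups and >= 2 time points")
        counts = df.groupby(subject).size()
        if (counts >= 2).sum() < 1:
            raise ValidationError("need >= 1 specimen with >= 2 observations")
        dup = df.groupby([subject, time]).size()
        if (dup > 1).any():
            raise ValidationError("one row per specimen x time is required")
        self.data = df
        self.names = dict(response=response, group=group, time=time, subject=subject)
        self._build_design()

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response_type: str | None = None,
                       response: str = "response", **kwargs) -> "RepeatedMeasuresCS":
        """Construct from a tidy longitudinal table; optionally filter one
        ``response_type`` (volume_mm3 / rms_mm / area_mm2)."""
        df = data
        if response_type is not None:
            if "response_type" not in df.columns:
                raise ValidationError("no response_type column to filter on")
            df = df[df["response_type"] == response_type]
            if df.empty:
                raise ValidationError(f"no rows with response_type={response_type!r}")
        return cls(df, response=response, **kwargs)

    # -- design ------------------------------------------------------------
    def _column_names(self):
        g_ref, t_ref = self.group_levels[0], self.time_levels[0]
        names = ["Intercept"]
        names += [f"group[{g}]" for g in self.group_levels[1:]]
        names += [f"time[{t}]" for t in self.time_levels[1:]]
        names += [f"group[{g}]:time[{t}]"
                  for g in self.group_levels[1:] for t in self.time_levels[1:]]
        return names

    def _row(self, g: str, t: str) -> np.ndarray:
        """Full design row for the (group, time) cell (treatment coding)."""
        gl, tl = self.group_levels, self.time_levels
        x = [1.0]
        x += [1.0 if g == gg else 0.0 for gg in gl[1:]]
        x += [1.0 if t == tt else 0.0 for tt in tl[1:]]
        x += [1.0 if (g == gg and t == tt) else 0.0
              for gg in gl[1:] for tt in tl[1:]]
        return np.asarray(x)

    def _build_design(self):
        n = self.names
        g = self.data[n["group"]].astype(str).to_numpy()
        t = self.data[n["time"]].astype(str).to_numpy()
        X = np.vstack([self._row(gi, ti) for gi, ti in zip(g, t)])
        self.column_names = self._column_names()
        # columns unsupported by the data (all-missing cells) are dropped;
        # contrasts that need them are flagged non-estimable, never silently
        kept = X.any(axis=0)
        kept[0] = True
        self._kept = kept
        self.exog = pd.DataFrame(X[:, kept],
                                 columns=[c for c, k in zip(self.column_names, kept) if k])
        self.endog = self.data[n["response"]].to_numpy(dtype=float)
        self.subjects = self.data[n["subject"]].astype(str).to_numpy()

    def fit(self, reml: bool = True) -> "RepeatedMeasuresCSResults":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mod = sm.MixedLM(self.endog, self.exog, groups=self.subjects)
            try:
                res = mod.fit(reml=reml)
            except Exception:
                res = mod.fit(reml=reml, method="lbfgs")
        return RepeatedMeasuresCSResults(self, res)


class RepeatedMeasuresCSResults:
    """Estimates, variance components, LS means and contrasts of a fitted
    compound-symmetry repeated-measures model."""

    def __init__(self, model: RepeatedMeasuresCS, mixedlm_results):
        self.model = model
        self._res = mixedlm_results
        self.fe_params = mixedlm_results.fe_params
        names = list(self.fe_params.index)
        cov = mixedlm_results.cov_params()
        self.cov_fe = np.asarray(cov.loc[names, names], dtype=float)
        self.sigma_e2 = float(mixedlm_results.scale)
        sb2 = float(np.asarray(mixedlm_results.cov_re)[0, 0])
        self.singular = sb2 < 1e-10
        self.sigma_b2 = 0.0 if self.singular else sb2
        self.reml_loglike = float(mixedlm_results.llf)
        self.converged = bool(getattr(mixedlm_results, "converged", True))
        self.n_obs = len(model.endog)
        self.n_subjects = len(np.unique(model.subjects))
        g = len(model.group_levels)
        p = int(model._kept.sum())
        self.df_between = max(self.n_subjects - g, 1)
        self.df_within = max(self.n_obs - self.n_subjects - (p - g), 1)

    # -- helpers -----------------------------------------------------------
    def _reduce(self, c_full: np.ndarray):
        """Map a full-design contrast vector onto the kept columns; returns
        (vector, estimable)."""
        kept = self.model._kept
        if np.any(np.abs(c_full[~kept]) > 1e-12):
            return None, False
        return c_full[kept], True

    def _contrast(self, c_full, label, df, family_size,
                  alpha=0.05, adjust_ci=False) -> ComparisonRecord:
        c, ok = self._reduce(np.asarray(c_full, dtype=float))
        if not ok:
            return ComparisonRecord(label, np.nan, np.nan, df, np.nan, np.nan,
                                    np.nan, np.nan, np.nan, family_size,
                                    estimable=False,
                                    note="non-estimable: empty design cells")
        est = float(c @ self.fe_params.to_numpy())
        se = float(np.sqrt(c @ self.cov_fe @ c))
        stat = est / se if se > 0 else np.inf * np.sign(est or 1.0)
        p_raw = float(2.0 * st.t.sf(abs(stat), df))
        p_adj = min(1.0, family_size * p_raw)
        a = alpha / family_size if adjust_ci else alpha
        tq = st.t.ppf(1.0 - a / 2.0, df)
        return ComparisonRecord(label, est, se, df, float(stat), p_raw, p_adj,
                                est - tq * se, est + tq * se, family_size)

    def cell_vector(self, group: str, time: str) -> np.ndarray:
        return self.model._row(str(group), str(time))

    def group_ls_vector(self, group: str) -> np.ndarray:
        """LS mean of a group: cell means averaged over time at equal weights."""
        rows = [self.cell_vector(group, t) for t in self.model.time_levels]
        return np.mean(rows, axis=0)

    def time_ls_vector(self, time: str) -> np.ndarray:
        rows = [self.cell_vector(g, time) for g in self.model.group_levels]
        return np.mean(rows, axis=0)

    # -- public tables -----------------------------------------------------
    def ls_means(self, by: str = "cell") -> pd.DataFrame:
        """LS means with SEs and unadjusted 95% CIs (by 'cell', 'group' or 'time')."""
        rows = []
        if by == "cell":
            items = [((g, t), self.cell_vector(g, t), f"{g} {t}")
                     for g in self.model.group_levels for t in self.model.time_levels]
        elif by == "group":
            items = [((g,), self.group_ls_vector(g), g) for g in self.model.group_levels]
        elif by == "time":
            items = [((t,), self.time_ls_vector(t), t) for t in self.model.time_levels]
        else:
            raise ValidationError("by must be 'cell', 'group' or 'time'")
        df = self.df_within if by != "group" else self.df_between
        for _, vec, label in items:
            rec = self._contrast(vec, label, df, family_size=1)
            rows.append(rec.as_dict())
        return pd.DataFrame(rows)

    def pairwise_groups(self, alpha: float = 0.05,
                        adjust_ci: bool = False) -> list[ComparisonRecord]:
        """All pairwise group LS-mean differences, Bonferroni-adjusted over the
        family of C(g, 2) comparisons (between-specimen df)."""
        pairs = list(itertools.combinations(self.model.group_levels, 2))
        m = len(pairs)
        return [self._contrast(self.group_ls_vector(a) - self.group_ls_vector(b),
                               f"{a} versus {b}", self.df_between, m,
                               alpha=alpha, adjust_ci=adjust_ci)
                for a, b in pairs]

    def time_effects(self, family: str = "per_group", alpha: float = 0.05,
                     adjust_ci: bool = False) -> list[ComparisonRecord]:
        """Within-group LS mean of each period, tested against zero.

        Responses are changes from baseline, so each cell mean is the effect
        of that immersion period relative to baseline.  The Bonferroni family
        is per sealer group by default (m = number of periods); ``family=
        'global'`` adjusts over all group x period tests instead.
        """
        if family not in ("per_group", "global"):
            raise ValidationError("family must be 'per_group' or 'global'")
        n_t = len(self.model.time_levels)
        m = n_t if family == "per_group" else n_t * len(self.model.group_levels)
        return [self._contrast(self.cell_vector(g, t), f"{g} {t}",
                               self.df_within, m, alpha=alpha, adjust_ci=adjust_ci)
                for g in self.model.group_levels for t in self.model.time_levels]

    def summary(self) -> str:
        lines = [
            "Repeated-measures model, compound symmetry (random intercept, REML)",
            f"  observations: {self.n_obs}   specimens: {self.n_subjects}",
            f"  groups: {', '.join(self.model.group_levels)}",
            f"  periods: {', '.join(self.model.time_levels)}",
            f"  sigma_b^2 (between-specimen): {self.sigma_b2:.6g}"
            + ("  [pinned at 0: singular fit]" if self.singular else ""),
            f"  sigma_e^2 (residual): {self.sigma_e2:.6g}",
            f"  within-specimen correlation: "
            f"{self.sigma_b2 / (self.sigma_b2 + self.sigma_e2):.4f}",
            f"  REML log-likelihood: {self.reml_loglike:.4f}",
            f"  df (between / within): {self.df_between} / {self.df_within}",
            "",
            "Group comparisons (Bonferroni-adjusted p, unadjusted 95% CI):",
        ]
        for rec in self.pairwise_groups():
            lines.append(f"  {rec.label:<22} est {rec.estimate:+.4f}  SE {rec.se:.4f}"
                         f"  p {rec.p_adj:.4f}  CI [{rec.ci_low:+.4f}, {rec.ci_high:+.4f}]")
        return "\n".join(lines)


def fit_cs_model(data: pd.DataFrame, response_type: str | None = None,
                 **kwargs) -> RepeatedMeasuresCSResults:
    """Fit the compound-symmetry repeated-measures model to a tidy table."""
    return RepeatedMeasuresCS.from_dataframe(data, response_type=response_type,
                                             **kwargs).fit()


def ls_means_and_contrasts(fit: RepeatedMeasuresCSResults,
                           family: str = "groups") -> list[ComparisonRecord]:
    """Contrast family dispatch: 'groups' (pairwise LS-mean differences) or
    'times_within_group' (each period versus baseline zero)."""
    if family == "groups":
        return fit.pairwise_groups()
    if family == "times_within_group":
        return fit.time_effects()
    raise ValidationError("family must be 'groups' or 'times_within_group'")


def comparisons_to_frame(records: list[ComparisonRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in records])


# ---------------------------------------------------------------------------
# simulation (study-condition synthetic responses)
# ---------------------------------------------------------------------------

def simulate_longitudinal(n_per_group: int, groups, times, effects=None,
                          sigma_b: float = 0.5, sigma_e: float = 1.0,
                          rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Balanced longitudinal responses with known fixed effects.

    ``effects`` maps ``(group, time) -> mean``; omitted cells default to 0.
    Specimen random intercepts are N(0, sigma_b^2), residuals N(0, sigma_e^2).
    """
    rng = rng or np.random.default_rng(0)
    effects = effects or {}
    rows = []
    sid = 0
    for g in groups:
        for _ in range(n_per_group):
            b = rng.normal(0.0, sigma_b)
            for t in times:
                mu = effects.get((g, t), 0.0)
                rows.append((f"S{sid:04d}", g, t, mu + b + rng.normal(0.0, sigma_e)))
            sid += 1
    return pd.DataFrame(rows, columns=["specimen_id", "group", "time", "response"])
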