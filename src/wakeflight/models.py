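"""Mixed-effects estimation of in-wake effects on the energy proxies.

Three analyses mirror the study design:

* **VeDBA point models** (:class:`DbaPositionModel`) — 5 Hz VeDBA is
  strongly bimodal by flap/glide, so gliding and flapping are fitted
  separately: flying position (not-in-wake reference) as fixed effect;
  bird, date and bird-in-date as random intercepts; the random slope of
  position within each grouping factor, uncorrelated with the
  intercepts.  The gliding response is log-transformed (left-skewed),
  so its position effect back-transforms as ``exp(b) - 1``; the
  flapping effect is reported relative to the intercept.
* **Heart-rate bout model** (:class:`HeartRateModel`) — bout-mean
  heart rate is right-skewed and is reverse-score square-root
  transformed, ``x = sqrt(C - hr)`` with ``C = 511.2``; fixed effects
  are position x flap proportion x duration (continuous covariates
  z-scored) with all interactions; per-bird random intercept and
  position slope (uncorrelated).  Per-bird effects combine the fixed
  slope with the bird's conditional slope and back-transform to a
  percent heart-rate difference at the bird's own intercept.
* **Paired wingbeat tests** — per-bird per-position means of effective
  wingbeat frequency (one-sided: not-in-wake > in-wake) and flapping
  frequency (two-sided), plus the derived percent gaps and skipped
  wingbeats per minute.

Mixed models are fitted by restricted maximum likelihood through
``statsmodels`` (variance-component formulation: crossed random
intercepts and slopes enter as variance components of a single
super-group); full-vs-null comparisons refit by maximum likelihood,
since REML likelihoods are not comparable across fixed-effect
structures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "HR_TRANSFORM_C",
    "hr_forward_transform",
    "hr_back_transform",
    "hr_percent_difference",
    "DbaPositionModel",
    "DbaPositionResults",
    "HeartRateModel",
    "HeartRateResults",
    "paired_wingbeat_tests",
    "derived_wingbeat_quantities",
]

#: reverse-score constant of the heart-rate transform (bpm)
HR_TRANSFORM_C = 511.2


def hr_forward_transform(hr, C: float = HR_TRANSFORM_C):
    """hr (bpm) -> x = sqrt(C - hr); requires hr < C."""
    hr = np.asarray(hr, dtype=float)
    if np.any(hr >= C):
        raise ValueError(f"heart rate at or above the transform constant C={C}")
    return np.sqrt(C - hr)


def hr_back_transform(x, C: float = HR_TRANSFORM_C):
    """x -> hr = C - x**2 (exact inverse of the forward transform)."""
    x = np.asarray(x, dtype=float)
    return C - x**2


def hr_percent_difference(intercept_x: float, slope_x: float,
                          C: float = HR_TRANSFORM_C) -> float:
    """Percent in-wake heart-rate change from transformed-scale terms.

    ``intercept_x`` is the not-in-wake estimate and ``slope_x`` the
    in-wake contrast, both on the sqrt(C - hr) scale.  Back-transform
    both states and report 100*(hr_inwake - hr_notinwake)/hr_notinwake.
    A positive transformed-scale slope therefore maps to a *decrease*
    in heart rate.
    """
    if intercept_x**2 >= C:
        raise ValueError("intercept**2 >= C: outside the transform's domain")
    hr0 = C - intercept_x**2
    hr1 = C - (intercept_x + slope_x) ** 2
    return 100.0 * (hr1 - hr0) / hr0


def _fit_mixedlm(model, reml: bool = True, maxiter: int = 500):
    """Fit a MixedLM robustly: several optimizer sequences, best REML/ML.

    The profiled (restricted) likelihood has flat ridges in the
    variance components where a single gradient method can stall, and
    gradient-free search can step into singular covariance regions.
    Each sequence is attempted independently and the best finite,
    converged fit wins.
    """
    best = None
    for methods in (["powell", "lbfgs"], ["lbfgs", "bfgs"], ["nm", "lbfgs"]):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(reml=reml, maxiter=maxiter, method=methods)
        except (np.linalg.LinAlgError, ValueError):
            continue
        if not np.isfinite(res.llf):
            continue
        if best is None or (res.converged and not best.converged) \
                or (res.converged == best.converged and res.llf > best.llf):
            best = res
    if best is None:
        raise RuntimeError("mixed-model fit failed with every optimizer")
    return best


# ---------------------------------------------------------------------------
# VeDBA point models
# ---------------------------------------------------------------------------


@dataclass
class EffectReport:
    """Estimates and uncertainty of one in-wake effect."""

    subset: str
    response: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    percent: float
    percent_ci: tuple[float, float]
    intercept: float
    converged: bool
    n_obs: int
    per_bird: pd.DataFrame | None = None
    notes: str = ""


class DbaPositionModel:
    """Linear mixed model of 5 Hz VeDBA on flying position, one subset.

    Built from a point table with columns ``bird, date, in_wake,
    vedba, flapping``; ``subset`` selects gliding or flapping samples.
    Random structure: intercepts for bird, date and bird-in-date, plus
    the position slope within each, all mutually uncorrelated (the
    slope indicator is centred within its grouping factor).
    """

    def __init__(self, data: pd.DataFrame, subset: str):
        if subset not in ("gliding", "flapping"):
            raise ValueError("subset must be 'gliding' or 'flapping'")
        self.subset = subset
        self.log_response = subset == "gliding"
        sel = data["flapping"].astype(bool)
        d = data.loc[~sel if subset == "gliding" else sel].copy()
        d = d[np.isfinite(d["vedba"]) & (d["vedba"] > 0 if self.log_response else np.isfinite(d["vedba"]))]
        d["y"] = np.log(d["vedba"]) if self.log_response else d["vedba"]
        d["pos"] = d["in_wake"].astype(float)
        d["bird_date"] = d["bird"].astype(str) + ":" + d["date"].astype(str)
        for g in ("bird", "date", "bird_date"):
            d[f"pos_c_{g}"] = d["pos"] - d.groupby(g)["pos"].transform("mean")
        # random-effect levels with a single observation cannot support
        # a variance component contribution; drop them with a warning
        for g in ("bird", "date", "bird_date"):
            counts = d[g].value_counts()
            thin = counts[counts < 2].index
            if len(thin):
                warnings.warn(f"dropping {len(thin)} level(s) of {g} with <2 observations")
                d = d[~d[g].isin(thin)]
        self.data = d.reset_index(drop=True)

    @classmethod
    def from_points(cls, points: pd.DataFrame, subset: str) -> "DbaPositionModel":
        return cls(points, subset)

    def fit(self, reml: bool = True, maxiter: int = 10000,
            backend: str = "auto") -> "DbaPositionResults":
        """Fit by REML.  ``backend``: "lme4", "statsmodels" or "auto".

        The default backend is lme4 through Rscript (bobyqa optimizer,
        ``maxiter`` function evaluations), which handles the
        six-variance-component crossed structure robustly; the
        statsmodels variance-component formulation is the fallback and
        the cross-check.
        """
        if backend == "auto":
            try:
                return self._fit_lme4(reml, maxiter)
            except (OSError, RuntimeError) as e:
                warnings.warn(f"lme4 backend unavailable ({e}); using statsmodels")
                return self._fit_statsmodels(reml, maxiter=500)
        if backend == "lme4":
            return self._fit_lme4(reml, maxiter)
        return self._fit_statsmodels(reml, maxiter=500)

    def _fit_statsmodels(self, reml: bool = True, maxiter: int = 500) -> "DbaPositionResults":
        d = self.data
        d = d.assign(_one=1)
        vc = {
            "bird": "0 + C(bird)",
            "bird_slope": "0 + C(bird):pos_c_bird",
        }
        # with a single date the date and bird-in-date components are
        # collinear with the bird component and unidentifiable
        if d["date"].nunique() >= 2:
            vc.update({
                "date": "0 + C(date)",
                "bird_date": "0 + C(bird_date)",
                "date_slope": "0 + C(date):pos_c_date",
                "bird_date_slope": "0 + C(bird_date):pos_c_bird_date",
            })
        model = smf.mixedlm("y ~ pos", d, groups=d["_one"], vc_formula=vc)
        res = _fit_mixedlm(model, reml, maxiter)
        return DbaPositionResults(self, params=res.fe_params, bse=res.bse_fe,
                                  converged=bool(res.converged),
                                  backend="statsmodels", raw=res)

    def _fit_lme4(self, reml: bool = True, maxiter: int = 10000) -> "DbaPositionResults":
        d = self.data
        multi_date = d["date"].nunique() >= 2
        re_terms = "(1|bird) + (0+pos_c_bird|bird)"
        if multi_date:
            re_terms += (" + (1|date) + (1|bird_date)"
                         " + (0+pos_c_date|date) + (0+pos_c_bird_date|bird_date)")
        out = _lme4_fit(
            d[["y", "pos", "bird", "date", "bird_date",
               "pos_c_bird", "pos_c_date", "pos_c_bird_date"]],
            formula=f"y ~ pos + {re_terms}",
            reml=reml, maxiter=maxiter,
        )
        params = pd.Series({"Intercept": out["fe"]["(Intercept)"], "pos": out["fe"]["pos"]})
        bse = pd.Series({"Intercept": out["se"]["(Intercept)"], "pos": out["se"]["pos"]})
        return DbaPositionResults(self, params=params, bse=bse,
                                  converged=bool(out["converged"]),
                                  backend="lme4", raw=out)


def _lme4_fit(data: pd.DataFrame, formula: str, reml: bool = True,
              maxiter: int = 10000) -> dict:
    """Fit an lmer model through Rscript; returns fixef/SE/varcorr."""
    import json
    import shutil
    import subprocess
    import tempfile
    from pathlib import Path

    if shutil.which("Rscript") is None:
        raise OSError("Rscript not found on PATH")
    with tempfile.TemporaryDirectory() as td:
        td = Path(td)
        data.to_csv(td / "d.csv", index=False)
        script = f"""
suppressMessages({{library(lme4); library(jsonlite)}})
d <- read.csv("{td / 'd.csv'}")
d$bird <- factor(d$bird); d$date <- factor(d$date)
if ("bird_date" %in% names(d)) d$bird_date <- factor(d$bird_date)
m <- lmer({formula}, data = d, REML = {str(reml).upper()},
          control = lmerControl(optimizer = "bobyqa",
                                optCtrl = list(maxfun = {maxiter})))
s <- summary(m)$coefficients
vc <- as.data.frame(VarCorr(m))
out <- list(fe = as.list(setNames(s[, "Estimate"], rownames(s))),
            se = as.list(setNames(s[, "Std. Error"], rownames(s))),
            vcov = as.list(setNames(vc$vcov, paste(vc$grp, vc$var1, sep = "."))),
            sigma2 = sigma(m)^2,
            converged = (m@optinfo$conv$opt == 0),
            singular = isSingular(m),
            llf = as.numeric(logLik(m)))
writeLines(toJSON(out, auto_unbox = TRUE, digits = 12), "{td / 'out.json'}")
"""
        (td / "fit.R").write_text(script)
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(td / "fit.R")],
            capture_output=True, text=True,
        )
        if proc.returncode != 0 or not (td / "out.json").exists():
            raise RuntimeError(f"lme4 fit failed: {proc.stderr.strip()[-500:]}")
        return json.loads((td / "out.json").read_text())


class DbaPositionResults:
    """REML fit of one VeDBA subset model (backend-agnostic)."""

    def __init__(self, model: DbaPositionModel, params: pd.Series, bse: pd.Series,
                 converged: bool, backend: str, raw=None):
        self.model = model
        self.params = params
        self.bse = bse
        self.converged = converged
        self.backend = backend
        self._raw = raw

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        p, s = self.params, self.bse
        return pd.DataFrame({"lower": p - z * s, "upper": p + z * s})

    def percent_effect(self) -> float:
        """In-wake effect on the response scale, percent.

        Gliding (log response): ``100*(exp(b) - 1)``; flapping (raw
        response): ``100*b/intercept``.
        """
        b = self.params["pos"]
        if self.model.log_response:
            return 100.0 * (np.exp(b) - 1.0)
        return 100.0 * b / self.params["Intercept"]

    def report(self) -> EffectReport:
        ci = self.conf_int()
        b = self.params["pos"]
        lo, hi = ci.loc["pos", "lower"], ci.loc["pos", "upper"]
        if self.model.log_response:
            pct = (100.0 * (np.exp(b) - 1.0), 100.0 * (np.exp(lo) - 1.0), 100.0 * (np.exp(hi) - 1.0))
        else:
            i0 = self.params["Intercept"]
            pct = (100.0 * b / i0, 100.0 * lo / i0, 100.0 * hi / i0)
        return EffectReport(
            subset=self.model.subset,
            response="log(vedba)" if self.model.log_response else "vedba",
            estimate=float(b),
            se=float(self.bse["pos"]),
            ci_low=float(lo),
            ci_high=float(hi),
            percent=float(pct[0]),
            percent_ci=(float(pct[1]), float(pct[2])),
            intercept=float(self.params["Intercept"]),
            converged=self.converged,
            n_obs=len(self.model.data),
            notes=f"backend {self.backend}; Wald 95% interval "
                  "(normal approximation, no Satterthwaite df)",
        )

    def summary(self) -> str:
        rep = self.report()
        lines = [
            f"VeDBA {self.model.subset} model ({rep.response}), backend {self.backend}",
            f"n = {rep.n_obs}, converged = {rep.converged}",
            f"Intercept = {rep.intercept:.4f}",
            f"in-wake effect = {rep.estimate:.4f} (se {rep.se:.4f}, "
            f"95% CI [{rep.ci_low:.4f}, {rep.ci_high:.4f}])",
            f"percent effect on response scale = {rep.percent:.2f}% "
            f"[{rep.percent_ci[0]:.2f}, {rep.percent_ci[1]:.2f}]",
        ]
        return "\n".join(lines)


def fit_dba_models(points: pd.DataFrame, reml: bool = True) -> dict[str, EffectReport]:
    """Fit both VeDBA subset models and return their effect reports."""
    out = {}
    for subset in ("gliding", "flapping"):
        out[subset] = DbaPositionModel.from_points(points, subset).fit(reml=reml).report()
    return out


# ---------------------------------------------------------------------------
# heart-rate bout model
# ---------------------------------------------------------------------------


@dataclass
class CovariateScaling:
    mean: float
    sd: float

    def apply(self, x):
        return (np.asarray(x, dtype=float) - self.mean) / self.sd


class HeartRateModel:
    """Mixed model of transformed bout-mean heart rate.

    Response ``x = sqrt(C - hr)``; fixed effects position x flap x
    duration with all interactions (flap and duration z-scored);
    per-bird random intercept and position slope, uncorrelated.
    """

    def __init__(self, bouts: pd.DataFrame, C: float = HR_TRANSFORM_C):
        self.C = C
        d = bouts.copy()
        d = d[np.isfinite(d["mean_hr"])]
        if "hr_plausible" in d:
            d = d[d["hr_plausible"].astype(bool)]
        self.n_rejected_domain = int((d["mean_hr"] >= C).sum())
        if self.n_rejected_domain:
            warnings.warn(
                f"{self.n_rejected_domain} bout(s) with heart rate >= C={C} rejected"
            )
            d = d[d["mean_hr"] < C]
        if d["bird"].nunique() < 2:
            raise ValueError("heart-rate model needs bouts from at least 2 birds")
        d["x"] = hr_forward_transform(d["mean_hr"], C)
        d["pos"] = d["in_wake"].astype(float)
        self.scaling = {
            "flap": CovariateScaling(d["flap_prop"].mean(), d["flap_prop"].std(ddof=0) or 1.0),
            "duration": CovariateScaling(d["duration"].mean(), d["duration"].std(ddof=0) or 1.0),
        }
        d["flap_z"] = self.scaling["flap"].apply(d["flap_prop"])
        d["dur_z"] = self.scaling["duration"].apply(d["duration"])
        self.data = d.reset_index(drop=True)

    @classmethod
    def from_bouts(cls, bouts: pd.DataFrame, C: float = HR_TRANSFORM_C) -> "HeartRateModel":
        return cls(bouts, C)

    _FORMULA = "x ~ pos * flap_z * dur_z"

    def fit(self, reml: bool = True, maxiter: int = 200) -> "HeartRateResults":
        d = self.data
        model = smf.mixedlm(
            self._FORMULA, d, groups=d["bird"], re_formula="1",
            vc_formula={"pos_slope": "0 + pos"},
        )
        return HeartRateResults(self, _fit_mixedlm(model, reml, maxiter), reml=reml)


class HeartRateResults:
    """Fit of the heart-rate bout model, with per-bird elaboration."""

    def __init__(self, model: HeartRateModel, res, reml: bool = True):
        self.model = model
        self._res = res
        self.reml = reml

    @property
    def converged(self) -> bool:
        return bool(self._res.converged)

    @property
    def params(self) -> pd.Series:
        return self._res.fe_params

    @property
    def bse(self) -> pd.Series:
        return self._res.bse_fe

    @property
    def scale(self) -> float:
        return float(self._res.scale)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame({"lower": self.params - z * self.bse,
                             "upper": self.params + z * self.bse})

    def fixed_effects_table(self) -> pd.DataFrame:
        ci = self.conf_int()
        t = self.params / self.bse
        # residual-df fallback for p-values (flagged in the summary)
        df = len(self.model.data) - len(self.params)
        p = 2 * stats.t.sf(np.abs(t), df)
        return pd.DataFrame({
            "estimate": self.params, "se": self.bse,
            "lower": ci["lower"], "upper": ci["upper"], "t": t, "p": p,
        })

    def _bird_effects(self, res=None) -> pd.DataFrame:
        """Per-bird combined intercept and position slope (fixed + conditional)."""
        res = res or self._res
        fe = res.fe_params
        rows = []
        for bird, re in res.random_effects.items():
            re = pd.Series(re)
            icpt = float(fe["Intercept"] + re.get("Group", 0.0))
            slope_re = float(sum(v for k, v in re.items() if k.startswith("pos_slope")))
            slope = float(fe["pos"] + slope_re)
            rows.append({"bird": bird, "intercept_x": icpt, "slope_x": slope})
        df = pd.DataFrame(rows).set_index("bird")
        df["pct_difference"] = [
            hr_percent_difference(r.intercept_x, r.slope_x, self.model.C)
            for r in df.itertuples()
        ]
        return df

    def per_bird_table(self) -> pd.DataFrame:
        """Transformed-scale per-bird intercepts/slopes and percent change."""
        return self._bird_effects()

    # -- parametric bootstrap ------------------------------------------

    def bootstrap_per_bird(self, n_boot: int = 500, seed: int = 0,
                           use_u: bool = True, alpha: float = 0.05) -> pd.DataFrame:
        """Percentile intervals of per-bird slopes and percent changes.

        Parametric bootstrap: responses are simulated from the fitted
        model and the model refitted.  With ``use_u=True`` the birds'
        conditional random effects are held fixed (only residual noise
        is redrawn), so each bird's interval is centred on its own
        estimate — the analogue of a conditional bootstrap of the
        random-effect elaboration.  With ``use_u=False`` random effects
        are redrawn from their estimated distribution.
        """
        rng = np.random.default_rng(seed)
        d = self.model.data
        X = self._res.model.exog
        fixed = X @ self.params.to_numpy()
        cond = self._conditional_part()
        sd = np.sqrt(self.scale)
        per_bird = {b: [] for b in d["bird"].unique()}
        fe_draws = []
        n_fail = 0
        for _ in range(n_boot):
            if use_u:
                mu = fixed + cond
            else:
                mu = fixed + self._draw_random_part(rng)
            y = mu + rng.normal(0.0, sd, size=len(d))
            try:
                bres = self._refit(y)
            except Exception:
                n_fail += 1
                continue
            if not bres.converged:
                n_fail += 1
                continue
            fe_draws.append(bres.fe_params["pos"])
            eff = HeartRateResults(self.model, bres, self.reml)._bird_effects(bres)
            for b in per_bird:
                if b in eff.index:
                    per_bird[b].append(
                        (eff.loc[b, "slope_x"], eff.loc[b, "pct_difference"])
                    )
        if n_boot and n_fail / n_boot > 0.2:
            warnings.warn(f"{n_fail}/{n_boot} bootstrap refits failed to converge")
        qs = (100 * alpha / 2, 100 * (1 - alpha / 2))
        est = self._bird_effects()
        rows = []
        for b, draws in per_bird.items():
            arr = np.array(draws)
            slope_ci = np.percentile(arr[:, 0], qs) if len(arr) else (np.nan, np.nan)
            pct_ci = np.percentile(arr[:, 1], qs) if len(arr) else (np.nan, np.nan)
            rows.append({
                "bird": b,
                "intercept_x": est.loc[b, "intercept_x"],
                "slope_x": est.loc[b, "slope_x"],
                "slope_lower": slope_ci[0], "slope_upper": slope_ci[1],
                "pct_difference": est.loc[b, "pct_difference"],
                "pct_lower": min(pct_ci), "pct_upper": max(pct_ci),
            })
        return pd.DataFrame(rows).set_index("bird")

    def _conditional_part(self) -> np.ndarray:
        """Z @ u_hat for every row, from the conditional random effects."""
        d = self.model.data
        out = np.zeros(len(d))
        for bird, re in self._res.random_effects.items():
            re = pd.Series(re)
            sel = (d["bird"] == bird).to_numpy()
            out[sel] += float(re.get("Group", 0.0))
            slope_re = float(sum(v for k, v in re.items() if k.startswith("pos_slope")))
            out[sel] += slope_re * d.loc[sel, "pos"].to_numpy()
        return out

    def _draw_random_part(self, rng) -> np.ndarray:
        d = self.model.data
        var_icpt = float(np.asarray(self._res.cov_re).ravel()[0]) * self.scale \
            if self._res.cov_re.size else 0.0
        # statsmodels stores cov_re and vcomp on the scale-free parameterisation
        # only when fitted via the profiled likelihood; cov_re here is already
        # on the response scale
        var_icpt = float(np.asarray(self._res.cov_re).ravel()[0])
        var_slope = float(self._res.vcomp[0]) if len(self._res.vcomp) else 0.0
        out = np.zeros(len(d))
        for bird in d["bird"].unique():
            sel = (d["bird"] == bird).to_numpy()
            out[sel] += rng.normal(0.0, np.sqrt(max(var_icpt, 0.0)))
            out[sel] += rng.normal(0.0, np.sqrt(max(var_slope, 0.0))) * d.loc[sel, "pos"].to_numpy()
        return out

    def _refit(self, y: np.ndarray):
        d = self.model.data.copy()
        d["x"] = y
        model = smf.mixedlm(
            HeartRateModel._FORMULA, d, groups=d["bird"], re_formula="1",
            vc_formula={"pos_slope": "0 + pos"},
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return model.fit(reml=self.reml, maxiter=200, method=["lbfgs", "bfgs"])

    def lrt_position(self) -> dict:
        """Full-vs-null likelihood-ratio test of flying position.

        Both models are refitted by maximum likelihood (REML
        likelihoods are not comparable across fixed-effect structures);
        the null drops every position term (main effect, all its
        interactions, and the per-bird position slope).
        """
        d = self.model.data

        full = _fit_mixedlm(
            smf.mixedlm(HeartRateModel._FORMULA, d, groups=d["bird"], re_formula="1",
                        vc_formula={"pos_slope": "0 + pos"}),
            reml=False,
        )
        null = _fit_mixedlm(
            smf.mixedlm("x ~ flap_z * dur_z", d, groups=d["bird"], re_formula="1"),
            reml=False,
        )
        chi2 = 2 * (full.llf - null.llf)
        df = (len(full.fe_params) + 1) - len(null.fe_params)  # +1: slope variance
        return {"chi2": float(chi2), "df": int(df),
                "p": float(stats.chi2.sf(max(chi2, 0.0), df))}

    def summary(self) -> str:
        lines = [
            "Heart-rate bout model (response sqrt(C - hr), C = %.1f)" % self.model.C,
            "n bouts = %d, birds = %d, REML = %s, converged = %s"
            % (len(self.model.data), self.model.data["bird"].nunique(),
               self.reml, self.converged),
            "",
            self.fixed_effects_table().to_string(float_format="%.4f"),
            "",
            "Per-bird elaboration (transformed scale and % heart-rate change):",
            self.per_bird_table().to_string(float_format="%.3f"),
            "",
            "p-values use a residual-df t approximation (flagged: no "
            "Satterthwaite df in this backend).",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# paired wingbeat tests and derived quantities
# ---------------------------------------------------------------------------


def paired_wingbeat_tests(means: pd.DataFrame) -> dict:
    """Paired t-tests of the per-bird wingbeat means by flying position.

    ``means`` has one row per bird with columns ``ewbf_not, ewbf_in,
    flapfreq_not, flapfreq_in``.  Effective wingbeat frequency uses a
    one-sided test (directed hypothesis: not-in-wake > in-wake);
    flapping frequency a two-sided test.  Identical pairs (zero
    variance of the differences) are reported with an undefined t and
    the boundary p-value.
    """
    if len(means) < 3:
        raise ValueError(f"need at least 3 paired birds, got {len(means)}")

    def _paired(a, b, alternative):
        d = np.asarray(a, float) - np.asarray(b, float)
        n = d.size
        if np.allclose(d.std(ddof=1), 0.0):
            if np.allclose(d.mean(), 0.0):
                return {"t": float("nan"), "df": n - 1,
                        "p": 0.5 if alternative != "two-sided" else 1.0,
                        "mean_diff": 0.0}
            return {"t": float("inf") * np.sign(d.mean()), "df": n - 1,
                    "p": 0.0 if d.mean() > 0 else 1.0, "mean_diff": float(d.mean())}
        t, p = stats.ttest_rel(a, b, alternative=alternative)
        return {"t": float(t), "df": n - 1, "p": float(p), "mean_diff": float(d.mean())}

    ewbf = _paired(means["ewbf_not"], means["ewbf_in"], "greater")
    ewbf["percent_diff"] = 100.0 * ewbf["mean_diff"] / means["ewbf_not"].mean()
    ff = _paired(means["flapfreq_not"], means["flapfreq_in"], "two-sided")
    ff["percent_diff"] = 100.0 * ff["mean_diff"] / means["flapfreq_not"].mean()
    return {"ewbf_one_sided": ewbf, "flapping_freq_two_sided": ff}


def derived_wingbeat_quantities(
    ewbf_not: float, ewbf_in: float, flapfreq_not: float, flapfreq_in: float
) -> dict:
    """Percent eWBF-vs-flapping-frequency gaps and skipped beats/minute.

    Per position the gap is ``100*(f_flap - f_eff)/f_flap`` — how much
    of the flapping rhythm is forgone through glide pauses; the skipped
    wingbeats per minute are ``60*(eWBF_not - eWBF_in)``.
    """
    vals = (ewbf_not, ewbf_in, flapfreq_not, flapfreq_in)
    if any((not np.isfinite(v)) or v <= 0 for v in vals):
        raise ValueError("all four frequencies must be positive and finite")
    return {
        "gap_pct_not_in_wake": 100.0 * (flapfreq_not - ewbf_not) / flapfreq_not,
        "gap_pct_in_wake": 100.0 * (flapfreq_in - ewbf_in) / flapfreq_in,
        "skipped_per_minute": 60.0 * (ewbf_not - ewbf_in),
    }
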