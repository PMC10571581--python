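"""Interfraction dose variation (IDV) uncertainty distributions.

An IDV is the signed percent difference between the delivered and the
prescribed (target) or expected (organ-at-risk) EQD2 over a brachytherapy
course.  Cohort IDVs are modeled with three candidate families — a
four-parameter (two shapes, location, scale) Beta, a generalized extreme
value (GEV), and a normal distribution — compared by residual-sum-of-squares
(RSS) scoring of their densities against the sample histogram, and tested
for goodness of fit with the Anderson-Darling statistic (standard
normal-case tables for the normal family, parametric bootstrap otherwise).

The cohort's target IDVs are left-skewed (under-dosing is more likely than
over-dosing), which the default Beta specification captures by moment
matching: its analytic mean, SD and skewness are set to the cohort values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from brachyidv.errors import (
    ConfigurationError,
    InvalidInputError,
    NoSolutionError,
)

Family = Literal["beta", "gev", "normal", "empirical"]

#: Cohort HRCTV IDV moments: mean -1.53%, SD 11.0% for the Beta fit,
#: SD 11.2% for the raw data / standard-normal comparison distribution.
COHORT_MEAN_IDV = -1.53
COHORT_SD_BETA = 11.0
COHORT_SD_RAW = 11.2
#: Default assumed skewness/concentration of the left-skewed Beta spec.
DEFAULT_BETA_SKEWNESS = -0.6
DEFAULT_BETA_CONCENTRATION = 10.0


@dataclass(frozen=True)
class IDVDistributionSpec:
    """A configured or fitted IDV uncertainty distribution (percent scale).

    ``shape_params`` is family-specific: ``(a, b)`` Beta shapes, ``(c,)``
    the GEV shape (scipy sign convention), and empty for the normal and
    empirical families.  ``location``/``scale`` follow scipy's loc/scale.
    ``mean_idv``/``sd_idv``/``skewness`` are the analytic moments of the
    distribution (sample moments for the empirical family).
    """

    family: Family
    shape_params: tuple[float, ...]
    location: float
    scale: float
    mean_idv: float
    sd_idv: float
    skewness: float
    rss: float | None = None
    ad_pvalue: float | None = None
    samples: tuple[float, ...] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gev", "normal", "empirical"):
            raise InvalidInputError(f"unknown family {self.family!r}")
        if self.family != "empirical" and self.scale <= 0:
            raise InvalidInputError("scale must be positive")
        if self.sd_idv <= 0:
            raise InvalidInputError("sd_idv must be positive")
        if self.family == "empirical" and self.samples is None:
            raise InvalidInputError("empirical spec requires samples")

    def frozen(self):
        """The scipy frozen distribution backing this spec."""
        if self.family == "beta":
            a, b = self.shape_params
            return stats.beta(a, b, loc=self.location, scale=self.scale)
        if self.family == "gev":
            (c,) = self.shape_params
            return stats.genextreme(c, loc=self.location, scale=self.scale)
        if self.family == "normal":
            return stats.norm(loc=self.location, scale=self.scale)
        raise InvalidInputError("empirical family has no parametric form")

    @property
    def support(self) -> tuple[float, float]:
        if self.family == "empirical":
            return (min(self.samples), max(self.samples))
        lo, hi = self.frozen().support()
        return (float(lo), float(hi))

    def to_json(self) -> str:
        payload = {
            "family": self.family,
            "shape_params": list(self.shape_params),
            "location": self.location,
            "scale": self.scale,
            "mean_idv": self.mean_idv,
            "sd_idv": self.sd_idv,
            "skewness": self.skewness,
            "rss": self.rss,
            "ad_pvalue": self.ad_pvalue,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "IDVDistributionSpec":
        d = json.loads(text)
        d["shape_params"] = tuple(d["shape_params"])
        return cls(**d)


def compute_idv(delivered_eqd2, reference_eqd2):
    """Signed percent difference of delivered vs prescribed/expected EQD2."""
    delivered = np.asarray(delivered_eqd2, dtype=float)
    reference = np.asarray(reference_eqd2, dtype=float)
    if np.any(reference <= 0):
        raise InvalidInputError("reference EQD2 must be positive")
    out = 100.0 * (delivered - reference) / reference
    return out if out.ndim else float(out)


def _spec_from_frozen(family: Family, shape_params, loc, scale,
                      rss=None, ad_pvalue=None) -> IDVDistributionSpec:
    spec = IDVDistributionSpec(
        family=family, shape_params=tuple(float(s) for s in shape_params),
        location=float(loc), scale=float(scale),
        mean_idv=0.0, sd_idv=1.0, skewness=0.0, rss=rss, ad_pvalue=ad_pvalue,
    )
    m, v, s = spec.frozen().stats(moments="mvs")
    return replace(spec, mean_idv=float(m), sd_idv=float(np.sqrt(v)),
                   skewness=float(s))


def _beta_skewness_at(a: float, concentration: float) -> float:
    b = concentration - a
    return (2.0 * (b - a) * math.sqrt(concentration + 1.0)
            / ((concentration + 2.0) * math.sqrt(a * b)))


def beta_from_moments(mean: float, sd: float, skewness: float,
                      concentration: float) -> IDVDistributionSpec:
    """Construct a four-parameter Beta spec by moment matching.

    Shapes ``(a, b)`` with fixed concentration ``a + b`` are solved so the
    standardized skewness hits the target; location and scale then set the
    mean and SD exactly.  Both shapes are constrained to be >= 1 (unimodal
    density with finite endpoints), which bounds the attainable |skewness|
    at a given concentration.
    """
    if sd <= 0:
        raise InvalidInputError("sd must be positive")
    if concentration <= 2:
        raise InvalidInputError("concentration must exceed 2 (shapes >= 1)")
    nu = float(concentration)
    # skewness is strictly decreasing in a on [1, nu-1]
    bound = _beta_skewness_at(1.0, nu)
    if abs(skewness) > bound:
        raise NoSolutionError(
            f"skewness {skewness} infeasible at concentration {nu}: "
            f"|skewness| <= {bound:.4f} with both shapes >= 1"
        )
    if skewness == 0.0:
        a = nu / 2.0
    elif abs(abs(skewness) - bound) < 1e-12:
        a = nu - 1.0 if skewness < 0 else 1.0
    else:
        a = brentq(lambda x: _beta_skewness_at(x, nu) - skewness,
                   1.0, nu - 1.0, xtol=1e-13)
    b = nu - a
    sd_unit = math.sqrt(a * b / (nu ** 2 * (nu + 1.0)))
    scale = sd / sd_unit
    loc = mean - scale * a / nu
    return _spec_from_frozen("beta", (a, b), loc, scale)


def default_beta_spec() -> IDVDistributionSpec:
    """The left-skewed Beta IDV spec moment-matched to the cohort target."""
    return beta_from_moments(COHORT_MEAN_IDV, COHORT_SD_BETA,
                             DEFAULT_BETA_SKEWNESS, DEFAULT_BETA_CONCENTRATION)


def snd_spec(sd: float = COHORT_SD_RAW) -> IDVDistributionSpec:
    """Standard-normal IDV spec: mean 0%, SD equal to the cohort raw IDV SD."""
    return _spec_from_frozen("normal", (), 0.0, sd)


def fit_distribution(samples, family: Family, *, standard_normal: bool = False,
                     n_bins: int = 50) -> IDVDistributionSpec:
    """Maximum-likelihood fit of one candidate family, with its RSS score.

    ``standard_normal=True`` (normal family only) fixes the mean at 0 and
    uses the sample SD, matching the comparison distribution used against
    the skewed fits.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 20:
        raise InvalidInputError("need at least 20 samples to fit")
    if np.std(x) == 0:
        raise InvalidInputError("degenerate (zero-variance) samples")
    if family == "normal":
        if standard_normal:
            loc, scale = 0.0, float(np.std(x, ddof=1))
        else:
            loc, scale = stats.norm.fit(x)
        spec = _spec_from_frozen("normal", (), loc, scale)
    elif family == "beta":
        spread = x.max() - x.min()
        best = None
        # MLE is multimodal in the 4-parameter case; multistart on the shape
        # guesses and support padding, keep the highest log-likelihood
        for pad in (0.05, 0.15, 0.4):
            loc0 = x.min() - pad * spread
            scale0 = (1.0 + 2.0 * pad) * spread
            for a0, b0 in ((2.0, 2.0), (5.0, 2.0), (2.0, 5.0)):
                try:
                    params = stats.beta.fit(x, a0, b0, loc=loc0, scale=scale0)
                except Exception:
                    continue
                ll = np.sum(stats.beta.logpdf(x, *params))
                if np.isfinite(ll) and (best is None or ll > best[0]):
                    best = (ll, params)
        if best is None:
            raise InvalidInputError("beta MLE failed for these samples")
        a, b, loc, scale = best[1]
        spec = _spec_from_frozen("beta", (a, b), loc, scale)
    elif family == "gev":
        best = None
        # default start frequently lands in a poor local optimum for
        # strongly skewed data; multistart over the shape parameter
        for c0 in (-0.5, -0.2, 0.0, 0.2, 0.5):
            try:
                params = stats.genextreme.fit(x, c0)
            except Exception:
                continue
            ll = np.sum(stats.genextreme.logpdf(x, *params))
            if np.isfinite(ll) and (best is None or ll > best[0]):
                best = (ll, params)
        if best is None:
            raise InvalidInputError("GEV MLE failed for these samples")
        c, loc, scale = best[1]
        spec = _spec_from_frozen("gev", (c,), loc, scale)
    elif family == "empirical":
        spec = IDVDistributionSpec(
            family="empirical", shape_params=(), location=0.0, scale=1.0,
            mean_idv=float(np.mean(x)), sd_idv=float(np.std(x, ddof=1)),
            skewness=float(stats.skew(x)), samples=tuple(x),
        )
        return spec
    else:
        raise InvalidInputError(f"unknown family {family!r}")
    return replace(spec, rss=rss_score(x, spec, n_bins=n_bins))


def rss_score(samples, spec: IDVDistributionSpec, n_bins: int = 50) -> float:
    """Residual sum of squares between the histogram density and the spec PDF.

    The sample histogram is density-normalized on ``n_bins`` equal-width bins
    and compared to the spec's PDF at the bin centers.
    """
    if n_bins < 5:
        raise InvalidInputError("n_bins must be >= 5")
    x = np.asarray(samples, dtype=float)
    density, edges = np.histogram(x, bins=n_bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    pdf = spec.frozen().pdf(centers)
    return float(np.sum((density - pdf) ** 2))


def _ad_statistic(x: np.ndarray, cdf) -> float:
    """Anderson-Darling A^2 of sorted data against a CDF callable."""
    n = x.size
    u = np.clip(cdf(np.sort(x)), 1e-12, 1.0 - 1e-12)
    i = np.arange(1, n + 1)
    return float(-n - np.mean((2 * i - 1) * (np.log(u) + np.log(1.0 - u[::-1]))))


def _ad_normal_pvalue(a2: float, n: int) -> float:
    """Normal-case A^2 p-value (parameters estimated), standard small-sample
    correction and piecewise exponential approximation."""
    a = a2 * (1.0 + 0.75 / n + 2.25 / n ** 2)
    if a >= 0.6:
        p = math.exp(1.2937 - 5.709 * a + 0.0186 * a * a)
    elif a >= 0.34:
        p = math.exp(0.9177 - 4.279 * a - 1.38 * a * a)
    elif a > 0.2:
        p = 1.0 - math.exp(-8.318 + 42.796 * a - 59.938 * a * a)
    else:
        p = 1.0 - math.exp(-13.436 + 101.14 * a - 223.73 * a * a)
    return min(max(p, 0.0), 1.0)


def anderson_darling(samples, spec: IDVDistributionSpec, *,
                     n_bootstrap: int = 1000, seed=None,
                     method: str = "auto",
                     standard_normal: bool = False) -> tuple[float, float]:
    """Anderson-Darling goodness-of-fit of ``samples`` against ``spec``.

    Returns ``(A2, p_value)``.  The null hypothesis is that the spec fits
    the data, so small p-values reject the spec.  For the normal family the
    p-value comes from the standard normal-case tables (``method="table"``,
    the default under ``"auto"``); for the Beta and GEV families — whose
    null distribution of A^2 has no usable tables once parameters are
    estimated — a parametric bootstrap refits the family to ``n_bootstrap``
    synthetic samples drawn from the fitted spec.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 20:
        raise InvalidInputError("need at least 20 samples")
    if method == "auto":
        method = "table" if spec.family == "normal" else "bootstrap"
    a2 = _ad_statistic(x, spec.frozen().cdf)
    if method == "table":
        if spec.family != "normal":
            raise ConfigurationError("table p-values exist only for the normal family")
        return a2, _ad_normal_pvalue(a2, x.size)
    if method != "bootstrap":
        raise ConfigurationError(f"unknown method {method!r}")
    if spec.family != "normal" and n_bootstrap < 100:
        raise ConfigurationError(
            "parametric bootstrap needs n_bootstrap >= 100 for non-normal families"
        )
    rng = np.random.default_rng(seed)
    frozen = spec.frozen()
    exceed = 0
    for _ in range(n_bootstrap):
        xb = frozen.rvs(size=x.size, random_state=rng)
        try:
            spec_b = fit_distribution(xb, spec.family,
                                      standard_normal=standard_normal)
        except (InvalidInputError, RuntimeError):
            continue  # rare degenerate bootstrap resample
        a2_b = _ad_statistic(xb, spec_b.frozen().cdf)
        if a2_b >= a2:
            exceed += 1
    p = (exceed + 1.0) / (n_bootstrap + 1.0)
    return a2, p


def sample_idv(spec: IDVDistributionSpec, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` IDVs (percent) from the spec, reproducibly under ``seed``.

    ``seed`` may be an int, a ``numpy.random.Generator``, or None.
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if spec.family == "empirical":
        return rng.choice(np.asarray(spec.samples, dtype=float), size=n, replace=True)
    return np.asarray(spec.frozen().rvs(size=n, random_state=rng), dtype=float)


def qq_points(samples, spec: IDVDistributionSpec) -> tuple[np.ndarray, np.ndarray]:
    """Quantile-quantile pairs: spec quantiles at plotting positions
    ``(i - 0.5)/n`` against the ordered samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    if x.size < 3:
        raise InvalidInputError("need at least 3 samples")
    p = (np.arange(1, x.size + 1) - 0.5) / x.size
    if spec.family == "empirical":
        theo = np.quantile(np.asarray(spec.samples, dtype=float), p)
    else:
        theo = spec.frozen().ppf(p)
    return theo, x


def write_samples_csv(samples: Sequence[float], path) -> None:
    pd.DataFrame({"idv_percent": np.asarray(samples, dtype=float)}).to_csv(
        path, index=False
    )


def read_samples_csv(path) -> np.ndarray:
    return pd.read_csv(path)["idv_percent"].to_numpy(dtype=float)
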