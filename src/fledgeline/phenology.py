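"""Hierarchical Bernoulli logistic model for the date of 50% fledging.

The probability that a brood observation is "certainly fledged" is modelled
on the logit scale as a function of z-transformed day of year and elevation,
with a date-by-elevation interaction and a random year displacement on the
date axis::

    y_i ~ Bernoulli(p_i)
    logit(p_i) = b0 + b1*elev_i + b2*(date_i + d_year[i]) +
                 b3*(date_i + d_year[i])*elev_i
    d_year ~ Normal(0, sigma)

so the whole seasonal curve slides earlier or later from year to year while
its slope (and the elevational change in slope) is shared across years.
The date at which the fledged proportion reaches 50% (t50) follows in
closed form as the root of the linear predictor:

    t50_z(elev) = -(b0 + b1*z_elev) / (b2 + b3*z_elev) - d

on the z-date scale, back-transformed to day of year.  Posteriors are
sampled with Hamiltonian Monte Carlo (4 chains of 2000 by default, second
halves retained -> 4000 draws), using a non-centered parameterization of
the year displacements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from ._hmc import sample_chains

__all__ = [
    "Standardizer",
    "Design",
    "PosteriorDraws",
    "FledglingPhenology",
    "standardize",
    "linear_predictor",
    "log_likelihood",
    "t50_z",
    "fit_posterior",
    "t50_summary",
    "elevational_delay",
    "year_deviation_summary",
    "proportion_curve",
]

#: Elevations (m) at which results are presented by default.
PRESENTATION_ELEVATIONS = (1650.0, 1850.0, 2050.0)

#: Mean elevation (m) used for per-year deviation tables.
MEAN_ELEVATION = 1743.0


@dataclass(frozen=True)
class Standardizer:
    """Sample moments used to z-transform day of year and elevation."""

    mean_doy: float
    sd_doy: float
    mean_elev: float
    sd_elev: float

    def __post_init__(self):
        if not (self.sd_doy > 0 and self.sd_elev > 0):
            raise ValueError("standardizer requires positive spread in doy and elevation")

    def z_doy(self, doy):
        return (np.asarray(doy, dtype=float) - self.mean_doy) / self.sd_doy

    def z_elev(self, elev):
        return (np.asarray(elev, dtype=float) - self.mean_elev) / self.sd_elev

    def doy_from_z(self, z):
        return self.mean_doy + self.sd_doy * np.asarray(z, dtype=float)

    def elev_from_z(self, z):
        return self.mean_elev + self.sd_elev * np.asarray(z, dtype=float)

    def to_dict(self) -> dict[str, float]:
        return {
            "mean_doy": self.mean_doy,
            "sd_doy": self.sd_doy,
            "mean_elev": self.mean_elev,
            "sd_elev": self.sd_elev,
        }


@dataclass
class Design:
    """Model-ready arrays: z-covariates, binary response, year indexing."""

    z_date: np.ndarray
    z_elev: np.ndarray
    y: np.ndarray
    year_index: np.ndarray
    years: list[int]
    standardizer: Standardizer

    @property
    def n_years(self) -> int:
        return len(self.years)


def standardize(records: pd.DataFrame) -> tuple[Design, Standardizer]:
    """Build the z-transformed design from an encoded observation table.

    ``records`` needs columns ``doy``, ``elevation_m``, ``year`` and a
    defined binary ``response``.  The z-columns have sample mean 0 and
    sample SD 1 (ddof=1); year labels are mapped to contiguous indices
    with the mapping retained on the design.
    """
    df = records.dropna(subset=["response"])
    doy = df["doy"].to_numpy(dtype=float)
    elev = df["elevation_m"].to_numpy(dtype=float)
    if len(np.unique(doy)) < 2 or len(np.unique(elev)) < 2:
        raise ValueError("need >= 2 distinct doy and elevation values to z-transform")
    std = Standardizer(
        mean_doy=float(doy.mean()),
        sd_doy=float(doy.std(ddof=1)),
        mean_elev=float(elev.mean()),
        sd_elev=float(elev.std(ddof=1)),
    )
    years = sorted(int(v) for v in df["year"].unique())
    year_to_idx = {yv: i for i, yv in enumerate(years)}
    design = Design(
        z_date=std.z_doy(doy),
        z_elev=std.z_elev(elev),
        y=df["response"].to_numpy(dtype=float),
        year_index=df["year"].map(year_to_idx).to_numpy(dtype=int),
        years=years,
        standardizer=std,
    )
    return design, std


def linear_predictor(beta, d, z_date, z_elev):
    """Logit-scale linear predictor eta; p = logistic(eta).

    ``beta`` is (b0, b1, b2, b3); ``d`` the year displacement added to the
    z-date (scalar or per-observation array).
    """
    b0, b1, b2, b3 = beta
    td = np.asarray(z_date, dtype=float) + d
    return b0 + b1 * np.asarray(z_elev, dtype=float) + (b2 + b3 * np.asarray(z_elev)) * td


def log_likelihood(beta, d_year, design: Design) -> float:
    """Bernoulli log likelihood, stable for |eta| up to ~700."""
    d = np.asarray(d_year, dtype=float)[design.year_index]
    eta = linear_predictor(beta, d, design.z_date, design.z_elev)
    # y*eta - log(1 + exp(eta)) without overflow
    return float(np.sum(design.y * eta - np.logaddexp(0.0, eta)))


def t50_z(beta, d, z_elev):
    """z-date at which the fledged proportion crosses 50%.

    Root of the linear predictor: ``-(b0 + b1*e)/(b2 + b3*e) - d``.  A zero
    denominator yields a non-finite value that is propagated, never clamped.
    """
    b0, b1, b2, b3 = beta
    z_elev = np.asarray(z_elev, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return -(b0 + b1 * z_elev) / (b2 + b3 * z_elev) - d


@dataclass
class PosteriorDraws:
    """Retained MCMC draws with chain metadata and the back-transform.

    ``table`` holds one row per retained draw with columns ``chain``,
    ``iter``, ``beta0..beta3``, ``sigma`` and one ``d_<year>`` column per
    observed year (displacements on the z-date scale).
    """

    table: pd.DataFrame
    standardizer: Standardizer
    years: list[int]
    diagnostics: pd.DataFrame
    converged: bool = True
    config: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return len(self.table)

    def betas(self) -> np.ndarray:
        return self.table[["beta0", "beta1", "beta2", "beta3"]].to_numpy()

    def d_year(self, year: int) -> np.ndarray:
        return self.table[f"d_{year}"].to_numpy()

    def t50_doy(self, elevation: float, year: int | None = None) -> np.ndarray:
        """Per-draw 50%-fledged day of year at one elevation.

        ``year=None`` is the average year (displacement fixed at 0);
        otherwise the posterior draws of that year's displacement are used.
        """
        b = self.betas()
        d = 0.0 if year is None else self.d_year(year)
        ze = self.standardizer.z_elev(elevation)
        z = t50_z((b[:, 0], b[:, 1], b[:, 2], b[:, 3]), d, ze)
        return self.standardizer.doy_from_z(z)

    def save(self, outdir) -> None:
        """Serialize draws, standardizer and config into a directory."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(outdir / "draws.csv", index=False)
        lines = [f"{k}: {v}" for k, v in self.standardizer.to_dict().items()]
        lines += [f"years: {','.join(str(y) for y in self.years)}"]
        lines += [f"converged: {self.converged}"]
        lines += [f"config.{k}: {v}" for k, v in self.config.items()]
        (outdir / "fit_meta.txt").write_text("\n".join(lines) + "\n")
        self.diagnostics.to_csv(outdir / "diagnostics.csv", index=False)

    @classmethod
    def load(cls, outdir) -> "PosteriorDraws":
        outdir = Path(outdir)
        table = pd.read_csv(outdir / "draws.csv")
        meta: dict[str, str] = {}
        for line in (outdir / "fit_meta.txt").read_text().splitlines():
            if ":" in line:
                k, v = line.split(":", 1)
                meta[k.strip()] = v.strip()
        std = Standardizer(
            mean_doy=float(meta["mean_doy"]),
            sd_doy=float(meta["sd_doy"]),
            mean_elev=float(meta["mean_elev"]),
            sd_elev=float(meta["sd_elev"]),
        )
        years = [int(v) for v in meta["years"].split(",")]
        diagnostics = pd.read_csv(outdir / "diagnostics.csv")
        config = {
            k[len("config."):]: v for k, v in meta.items() if k.startswith("config.")
        }
        return cls(
            table=table,
            standardizer=std,
            years=years,
            diagnostics=diagnostics,
            converged=meta.get("converged", "True") == "True",
            config=config,
        )


class FledglingPhenology(BaseEstimator):
    """Hierarchical Bernoulli logistic model of fledging phenology.

    Parameters
    ----------
    chains : int
        Number of independent HMC chains (default 4).
    iterations : int
        Transitions per chain; the first half is warmup and discarded, so
        the retained posterior has ``chains * iterations / 2`` draws
        (default 4 x 2000 -> 4000).
    prior_beta_sd : float
        SD of the Normal(0, .) prior on each regression coefficient
        (z-covariate scale); weakly informative by default.
    prior_sigma_sd : float
        Scale of the half-Normal prior on the between-year SD sigma
        (z-date units).
    rhat_threshold : float
        Convergence flag threshold on the largest split R-hat.
    random_state : int or None
        Seed for the sampler.

    Attributes
    ----------
    posterior_ : PosteriorDraws
        Retained draws, standardizer, and per-parameter diagnostics.
    standardizer_ : Standardizer
    years_ : list of int
    converged_ : bool
    """

    def __init__(
        self,
        chains: int = 4,
        iterations: int = 2000,
        prior_beta_sd: float = 5.0,
        prior_sigma_sd: float = 2.0,
        rhat_threshold: float = 1.05,
        random_state: int | None = None,
    ):
        self.chains = chains
        self.iterations = iterations
        self.prior_beta_sd = prior_beta_sd
        self.prior_sigma_sd = prior_sigma_sd
        self.rhat_threshold = rhat_threshold
        self.random_state = random_state

    # -- model density -----------------------------------------------------

    def _logp_grad_factory(self, design: Design):
        y = design.y
        t = design.z_date
        e = design.z_elev
        yi = design.year_index
        n_years = design.n_years
        sb2 = self.prior_beta_sd ** 2
        ss2 = self.prior_sigma_sd ** 2

        def logp_grad(theta: np.ndarray):
            b0, b1, b2, b3 = theta[:4]
            u = theta[4:4 + n_years]
            log_s = theta[-1]
            sigma = np.exp(log_s)
            d = sigma * u
            td = t + d[yi]
            slope = b2 + b3 * e
            eta = b0 + b1 * e + slope * td
            lp = np.sum(y * eta - np.logaddexp(0.0, eta))
            lp += -np.sum(theta[:4] ** 2) / (2.0 * sb2)
            lp += -0.5 * np.sum(u * u)
            lp += -(sigma * sigma) / (2.0 * ss2) + log_s  # half-normal + Jacobian

            r = y - expit(eta)
            grad = np.empty_like(theta)
            grad[0] = np.sum(r) - b0 / sb2
            grad[1] = np.sum(r * e) - b1 / sb2
            grad[2] = np.sum(r * td) - b2 / sb2
            grad[3] = np.sum(r * td * e) - b3 / sb2
            g_d = np.bincount(yi, weights=r * slope, minlength=n_years)
            grad[4:4 + n_years] = g_d * sigma - u
            grad[-1] = np.sum(g_d * d) - (sigma * sigma) / ss2 + 1.0
            return float(lp), grad

        return logp_grad

    def _initial_betas(self, design: Design) -> np.ndarray:
        """Maximum-likelihood start from a plain (non-hierarchical) GLM."""
        import statsmodels.api as sm

        X = np.column_stack(
            [
                np.ones_like(design.z_date),
                design.z_elev,
                design.z_date,
                design.z_date * design.z_elev,
            ]
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(design.y, X, family=sm.families.Binomial()).fit(maxiter=50)
            b = np.asarray(res.params, dtype=float)
            if np.all(np.isfinite(b)) and np.max(np.abs(b)) < 50:
                return b
        except Exception:
            pass
        return np.array([0.0, 0.0, 1.0, 0.0])

    # -- fitting -----------------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None):
        """Fit the model to one species' encoded observation table.

        ``X`` needs columns ``doy``, ``elevation_m``, ``year`` and, unless
        ``y`` is given separately, a binary ``response`` column.  One model
        is fitted per call; multi-species tables should be filtered first.
        """
        df = X.copy()
        if y is not None:
            df["response"] = np.asarray(y, dtype=float)
        if "response" not in df.columns:
            raise ValueError("fit needs a 'response' column or an explicit y")
        bad = ~df["response"].dropna().isin([0.0, 1.0])
        if bad.any():
            raise ValueError("responses must be binary 0/1")
        design, std = standardize(df)
        n_years = design.n_years
        dim = 5 + n_years

        logp_grad = self._logp_grad_factory(design)
        b_start = self._initial_betas(design)

        def init(rng: np.random.Generator) -> np.ndarray:
            theta = np.zeros(dim)
            theta[:4] = b_start + 0.1 * rng.normal(size=4)
            theta[4:4 + n_years] = 0.1 * rng.normal(size=n_years)
            theta[-1] = np.log(0.2) + 0.2 * rng.normal()
            return theta

        result = sample_chains(
            logp_grad, init, self.chains, self.iterations, self.random_state
        )
        kept = self.iterations - self.iterations // 2

        # assemble the draws table: d_year on the natural (z-date) scale
        draws = result.draws  # (chains, kept, dim)
        sigma = np.exp(draws[..., -1])
        d = sigma[..., None] * draws[..., 4:4 + n_years]
        posterior = {
            "beta0": draws[..., 0],
            "beta1": draws[..., 1],
            "beta2": draws[..., 2],
            "beta3": draws[..., 3],
            "sigma": sigma,
            "d_year": d,
        }
        idata = az.from_dict(
            posterior=posterior, coords={"year": design.years}, dims={"d_year": ["year"]}
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summ = az.summary(idata, kind="diagnostics")
        diagnostics = summ.reset_index().rename(columns={"index": "parameter"})

        rhat_max = float(diagnostics["r_hat"].max())
        converged = bool(rhat_max <= self.rhat_threshold)
        if not converged:
            warnings.warn(
                f"MCMC convergence flag: max R-hat {rhat_max:.3f} exceeds "
                f"{self.rhat_threshold}",
                RuntimeWarning,
                stacklevel=2,
            )

        table = pd.DataFrame(
            {
                "chain": np.repeat(np.arange(self.chains), kept),
                "iter": np.tile(np.arange(kept), self.chains),
                "beta0": draws[..., 0].ravel(),
                "beta1": draws[..., 1].ravel(),
                "beta2": draws[..., 2].ravel(),
                "beta3": draws[..., 3].ravel(),
                "sigma": sigma.ravel(),
            }
        )
        for j, yr in enumerate(design.years):
            table[f"d_{yr}"] = d[..., j].ravel()

        self.posterior_ = PosteriorDraws(
            table=table,
            standardizer=std,
            years=design.years,
            diagnostics=diagnostics,
            converged=converged,
            config={
                "chains": self.chains,
                "iterations": self.iterations,
                "prior_beta_sd": self.prior_beta_sd,
                "prior_sigma_sd": self.prior_sigma_sd,
                "seed": self.random_state,
                "accept_rate": np.round(result.accept_rate, 3).tolist(),
                "divergences": result.divergences.tolist(),
            },
        )
        self.standardizer_ = std
        self.years_ = design.years
        self.converged_ = converged
        self.rhat_max_ = rhat_max
        self.n_draws_ = len(table)
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Posterior-mean fledged probability for new (doy, elevation) rows."""
        check_is_fitted(self, "posterior_")
        post = self.posterior_
        zt = post.standardizer.z_doy(X["doy"])
        ze = post.standardizer.z_elev(X["elevation_m"])
        b = post.betas()
        eta = (
            b[:, [0]]
            + b[:, [1]] * ze[None, :]
            + (b[:, [2]] + b[:, [3]] * ze[None, :]) * zt[None, :]
        )
        p1 = expit(eta).mean(axis=0)
        return np.column_stack([1.0 - p1, p1])

    def t50(self, elevations=PRESENTATION_ELEVATIONS, mode="average", point="mean"):
        check_is_fitted(self, "posterior_")
        return t50_summary(self.posterior_, elevations, mode=mode, point=point)

    def elevational_delay(self, elev_low: float, elev_high: float, point="mean"):
        check_is_fitted(self, "posterior_")
        return elevational_delay(self.posterior_, elev_low, elev_high, point=point)

    def year_deviations(self, elevation: float = MEAN_ELEVATION, point="mean"):
        check_is_fitted(self, "posterior_")
        return year_deviation_summary(self.posterior_, elevation, point=point)


# -- posterior summaries ---------------------------------------------------


def _summarize(values: np.ndarray, point: str) -> tuple[float, float, float, int]:
    """Point + 95% quantiles with the non-finite draw policy.

    Non-finite draws (zero t50 denominator) are excluded only when they are
    at most 1% of all draws; beyond that they are kept so extreme quantiles
    propagate honestly.  The count of non-finite draws is returned either way.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    finite = np.isfinite(values)
    n_bad = int(n - finite.sum())
    if 0 < n_bad <= max(1, n // 100):
        values = values[finite]
    pt = float(np.mean(values)) if point == "mean" else float(np.median(values))
    lo, hi = np.quantile(values, [0.025, 0.975])
    return pt, float(lo), float(hi), n_bad


def t50_summary(
    draws: PosteriorDraws,
    elevations=PRESENTATION_ELEVATIONS,
    mode: str | int = "average",
    point: str = "mean",
) -> pd.DataFrame:
    """Posterior 50%-fledged dates (day of year) at chosen elevations.

    ``mode`` is ``"average"`` (year displacement 0) or a specific year
    label.  Values are never clamped to the calendar: poorly identified
    species can yield intervals far outside [1, 366].
    """
    year = None if mode == "average" else int(mode)
    rows = []
    for elev in np.atleast_1d(elevations):
        vals = draws.t50_doy(float(elev), year=year)
        pt, lo, hi, n_bad = _summarize(vals, point)
        rows.append(
            {
                "elevation_m": float(elev),
                "mode": "average" if year is None else str(year),
                "t50_doy": pt,
                "ci_low": lo,
                "ci_high": hi,
                "n_nonfinite": n_bad,
            }
        )
    return pd.DataFrame(rows)


def elevational_delay(
    draws: PosteriorDraws,
    elev_low: float = 1650.0,
    elev_high: float = 2050.0,
    point: str = "mean",
) -> dict:
    """Delay in the 50%-fledged date between two elevations, in days.

    Per-draw difference t50(high) - t50(low), summarized with 95%
    quantiles, plus the slope expressed per 100 m.
    """
    if not elev_low < elev_high:
        raise ValueError("elev_low must be below elev_high")
    diff = draws.t50_doy(elev_high) - draws.t50_doy(elev_low)
    pt, lo, hi, n_bad = _summarize(diff, point)
    span = elev_high - elev_low
    return {
        "elev_low_m": elev_low,
        "elev_high_m": elev_high,
        "delay_days": pt,
        "delay_days_per_100m": pt / span * 100.0,
        "ci_low": lo,
        "ci_high": hi,
        "n_nonfinite": n_bad,
    }


def year_deviation_summary(
    draws: PosteriorDraws,
    elevation: float = MEAN_ELEVATION,
    point: str = "mean",
) -> pd.DataFrame:
    """Per-year shift of the 50%-fledged date relative to the average year.

    Computed per draw as t50(elev, d_year) - t50(elev, 0); under the
    closed form this equals ``-sd_doy * d_year`` days.
    """
    rows = []
    for yr in draws.years:
        dev = draws.t50_doy(elevation, year=yr) - draws.t50_doy(elevation)
        pt, lo, hi, _ = _summarize(dev, point)
        rows.append(
            {"year": yr, "deviation_days": pt, "ci_low": lo, "ci_high": hi}
        )
    return pd.DataFrame(rows)


def proportion_curve(
    draws: PosteriorDraws,
    elevation: float,
    doy_grid: np.ndarray,
    mode: str | int = "average",
) -> pd.DataFrame:
    """Posterior fledged-proportion curve over a day-of-year grid.

    Returns the pointwise posterior median and 2.5/97.5% band of
    p(doy) at one elevation.
    """
    year = None if mode == "average" else int(mode)
    doy_grid = np.asarray(doy_grid, dtype=float)
    std = draws.standardizer
    zt = std.z_doy(doy_grid)
    ze = float(std.z_elev(elevation))
    b = draws.betas()
    d = 0.0 if year is None else draws.d_year(year)[:, None]
    td = zt[None, :] + d
    eta = b[:, [0]] + b[:, [1]] * ze + (b[:, [2]] + b[:, [3]] * ze) * td
    p = expit(eta)
    med = np.median(p, axis=0)
    lo, hi = np.quantile(p, [0.025, 0.975], axis=0)
    return pd.DataFrame(
        {"doy": doy_grid, "p_median": med, "p_low": lo, "p_high": hi}
    )


def fit_posterior(
    records: pd.DataFrame,
    chains: int = 4,
    iterations: int = 2000,
    seed: int | None = None,
    prior_beta_sd: float = 5.0,
    prior_sigma_sd: float = 2.0,
) -> PosteriorDraws:
    """Functional wrapper: fit the phenology model and return the draws."""
    model = FledglingPhenology(
        chains=chains,
        iterations=iterations,
        prior_beta_sd=prior_beta_sd,
        prior_sigma_sd=prior_sigma_sd,
        random_state=seed,
    )
    model.fit(records)
    return model.posterior_
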