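"""Mixed-effects comparison models, statsmodels-style (Model -> fit -> Results).

Two model families cover the statistical contracts of the analysis:

* :class:`StrategyMixedLM` — linear mixed models contrasting wintering
  strategies within calendar-season / day-phase cells, with a random
  intercept per bird and a date variance component, and Bonferroni-adjusted
  post-hoc p-values.

* :class:`EventCentredSmooth` — per-strategy smooths of a response over an
  event-centred day axis (or Julian day), fitted as a modest-rank B-spline
  regression inside a mixed model with a per-bird random intercept.
  Smoothness is controlled by the basis dimension; significance between
  strategies is read off as the maximal day ranges where the two 95%
  confidence bands do not overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.stats import norm, t as t_dist
from statsmodels.regression.mixed_linear_model import MixedLM


# ---------------------------------------------------------------------------
# strategy contrasts by cell


@dataclass
class StrategyMixedLMResults:
    """Per-cell strategy contrasts with Bonferroni-adjusted p-values."""

    table: pd.DataFrame

    def summary(self) -> str:
        cols = ["cell", "estimate", "se", "z", "p", "p_adj", "n", "converged"]
        return self.table[cols].to_string(index=False, float_format=lambda v: f"{v:.4g}")


class StrategyMixedLM:
    """Mixed model for migrant-vs-resident contrasts of f_H or T_b.

    For each cell (by default every season x day-phase combination present)
    the model ``response ~ strategy + sex`` is fitted with a random
    intercept per bird and a date variance component, and the migrant
    coefficient (resident reference) is reported.  P-values are Bonferroni
    corrected across cells.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response: str,
        cells: tuple[str, ...] = ("season", "day_phase"),
        strategy_col: str = "strategy",
        sex_col: str = "sex",
        bird_col: str = "bird_id",
        include_date_vc: bool = True,
    ) -> None:
        self.data = data
        self.response = response
        self.cells = cells
        self.strategy_col = strategy_col
        self.sex_col = sex_col
        self.bird_col = bird_col
        self.include_date_vc = include_date_vc

    def fit(self) -> StrategyMixedLMResults:
        df = self.data.copy()
        if "date" not in df.columns:
            df["date"] = pd.DatetimeIndex(df["timestamp"]).normalize()
        groups = list(df.groupby(list(self.cells), observed=True))
        rows = []
        for cell, sub in groups:
            rows.append(self._fit_cell(cell, sub))
        table = pd.DataFrame(rows)
        table["p_adj"] = np.minimum(table["p"] * len(table), 1.0)
        return StrategyMixedLMResults(table=table)

    def _fit_cell(self, cell, sub: pd.DataFrame) -> dict:
        sub = sub.copy()
        sub["_y"] = sub[self.response].astype(float)
        sub["_migrant"] = (sub[self.strategy_col] == "migrant").astype(float)
        formula = "_y ~ _migrant"
        if sub[self.sex_col].nunique() > 1:
            formula += f" + C({self.sex_col})"
        vc = None
        if self.include_date_vc and sub["date"].nunique() > 1:
            sub["_date"] = sub["date"].astype(str)
            vc = {"date": "0 + C(_date)"}

        converged = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model = MixedLM.from_formula(
                    formula,
                    data=sub,
                    groups=sub[self.bird_col],
                    re_formula="1",
                    vc_formula=vc,
                )
                res = model.fit(reml=True, maxiter=200)
                converged = bool(res.converged)
                est = float(res.params["_migrant"])
                se = float(res.bse["_migrant"])
            except Exception:
                converged = False
                est, se = np.nan, np.nan
        z = est / se if se and np.isfinite(se) and se > 0 else np.nan
        p = 2.0 * norm.sf(abs(z)) if np.isfinite(z) else np.nan
        # the contrast's uncertainty is dominated by between-bird variation,
        # so interval quantiles use a t distribution with bird-level df
        n_birds = sub[self.bird_col].nunique()
        tcrit = float(t_dist.ppf(0.975, max(n_birds - 2, 1)))
        return {
            "cell": cell if isinstance(cell, str) else "/".join(map(str, cell)),
            "term": "strategy[migrant]",
            "estimate": est,
            "se": se,
            "z": z,
            "p": p,
            "ci_low": est - tcrit * se if np.isfinite(se) else np.nan,
            "ci_high": est + tcrit * se if np.isfinite(se) else np.nan,
            "n": len(sub),
            "converged": converged,
        }


# ---------------------------------------------------------------------------
# event-centred smooths


def _bspline_basis(x: np.ndarray, knots: np.ndarray, degree: int) -> np.ndarray:
    xc = np.clip(x, knots[degree], knots[-degree - 1])
    return BSpline.design_matrix(xc, knots, degree).toarray()


def _make_knots(x: np.ndarray, df: int, degree: int) -> np.ndarray:
    n_interior = max(df - degree - 1, 0)
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.quantile(x, qs) if n_interior else np.array([])
    lo, hi = float(np.min(x)), float(np.max(x))
    return np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])


@dataclass
class _SmoothFit:
    beta: np.ndarray
    cov: np.ndarray
    knots: np.ndarray
    degree: int
    n_obs: int

    def predict(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = _bspline_basis(np.asarray(x, dtype=float), self.knots, self.degree)
        fit = X @ self.beta
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, self.cov, X), 0.0))
        return fit, se


@dataclass
class EventCentredSmoothResults:
    """Per-strategy smooths with confidence bands and non-overlap windows."""

    fits: dict[str, _SmoothFit]
    x_grid: np.ndarray
    level: float = 0.95
    _frame: pd.DataFrame | None = field(default=None, repr=False)

    def predict_frame(self) -> pd.DataFrame:
        if self._frame is None:
            z = norm.ppf(0.5 + self.level / 2.0)
            parts = []
            for strategy, fit in self.fits.items():
                mu, se = fit.predict(self.x_grid)
                parts.append(
                    pd.DataFrame(
                        {
                            "x": self.x_grid,
                            "strategy": strategy,
                            "fit": mu,
                            "lo": mu - z * se,
                            "hi": mu + z * se,
                        }
                    )
                )
            self._frame = pd.concat(parts, ignore_index=True)
        return self._frame

    def significant_windows(self) -> list[tuple[float, float]]:
        """Maximal x ranges where the two strategies' CIs do not overlap."""
        frame = self.predict_frame()
        strategies = list(self.fits)
        if len(strategies) != 2:
            raise ValueError("non-overlap windows need exactly two strategies")
        a = frame[frame["strategy"] == strategies[0]].set_index("x")
        b = frame[frame["strategy"] == strategies[1]].set_index("x")
        disjoint = (a["lo"] > b["hi"]) | (b["lo"] > a["hi"])
        windows = []
        start = None
        xs = disjoint.index.to_numpy()
        vals = disjoint.to_numpy()
        for i, (x, d) in enumerate(zip(xs, vals)):
            if d and start is None:
                start = x
            if (not d or i == len(xs) - 1) and start is not None:
                end = x if (d and i == len(xs) - 1) else xs[max(i - 1, 0)]
                windows.append((float(start), float(end)))
                start = None
        return windows

    def difference_sign(self, reference: str) -> float:
        """Sign of mean(other - reference) over the significant windows."""
        frame = self.predict_frame()
        windows = self.significant_windows()
        if not windows:
            return 0.0
        other = [s for s in self.fits if s != reference][0]
        mask = np.zeros(len(self.x_grid), dtype=bool)
        for lo, hi in windows:
            mask |= (self.x_grid >= lo) & (self.x_grid <= hi)
        ref = frame[frame["strategy"] == reference]["fit"].to_numpy()[mask]
        oth = frame[frame["strategy"] == other]["fit"].to_numpy()[mask]
        return float(np.sign(np.mean(oth - ref)))


class EventCentredSmooth:
    """Per-strategy penalized-spline-style smooth over an event-centred axis.

    Each strategy's response is modelled as a B-spline curve in ``x_col``
    (day offset from the anchor event, or Julian day for seasonal trends)
    plus a per-bird random intercept, via ``statsmodels`` MixedLM.  The
    rank of the spline basis (``spline_df``) plays the role of the
    smoothing parameter.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response: str,
        x_col: str = "day_offset",
        strategy_col: str = "strategy",
        bird_col: str = "bird_id",
        spline_df: int = 8,
        degree: int = 3,
        min_birds: int = 3,
        level: float = 0.95,
    ) -> None:
        self.data = data.dropna(subset=[response, x_col])
        self.response = response
        self.x_col = x_col
        self.strategy_col = strategy_col
        self.bird_col = bird_col
        self.spline_df = spline_df
        self.degree = degree
        self.min_birds = min_birds
        self.level = level

    def fit(self, x_grid: np.ndarray | None = None) -> EventCentredSmoothResults:
        x_all = self.data[self.x_col].to_numpy(dtype=float)
        knots = _make_knots(x_all, self.spline_df, self.degree)
        if x_grid is None:
            x_grid = np.arange(np.floor(x_all.min()), np.ceil(x_all.max()) + 1)

        fits: dict[str, _SmoothFit] = {}
        for strategy, sub in self.data.groupby(self.strategy_col, observed=True):
            n_birds = sub[self.bird_col].nunique()
            if n_birds < self.min_birds:
                raise ValueError(
                    f"strategy '{strategy}' has only {n_birds} birds "
                    f"(minimum {self.min_birds}); refusing to fit"
                )
            X = _bspline_basis(sub[self.x_col].to_numpy(dtype=float), knots, self.degree)
            y = sub[self.response].to_numpy(dtype=float)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = MixedLM(y, X, groups=sub[self.bird_col].to_numpy())
                res = model.fit(reml=True, maxiter=200)
            k = X.shape[1]
            cov = np.asarray(res.cov_params())[:k, :k]
            fits[str(strategy)] = _SmoothFit(
                beta=np.asarray(res.fe_params, dtype=float),
                cov=cov,
                knots=knots,
                degree=self.degree,
                n_obs=len(sub),
            )
        return EventCentredSmoothResults(fits=fits, x_grid=np.asarray(x_grid, dtype=float), level=self.level)
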