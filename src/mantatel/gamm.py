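"""Binomial presence GAMM: penalized IRLS with cyclic-spline smooths.

Model: logit P(detected in hour) = intercept + f_Day(doy) + f_Hour(hour)
+ f_Moon(moon) + f_CHLA(chla) + sex + maturity + b*nStations + u_animal,
with f_* penalized cubic regression splines (Day/Hour cyclic, k=7; Moon k=6;
CHLA k=7), and u_animal a ridge-penalized per-animal intercept — the standard
mixed-model-as-penalized-GLM equivalence.

Smoothing parameters (one per smooth plus one for the random-intercept ridge)
are chosen by coordinate-wise search over a log-spaced grid minimising GCV,
``n * deviance / (n - edf)^2``.  AIC is conditional: deviance + 2 * edf with
edf the trace of the influence matrix.  Model selection fits all 2^4 subsets
of the four smooths (parametric terms and the random intercept always stay)
and ranks by AIC.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import to_calendar_day
from .splines import cyclic_cubic_basis, natural_cubic_basis, quantile_knots

logger = logging.getLogger("mantatel")

SMOOTH_COVARIATES = {
    "Day": "day_of_year",
    "Hour": "hour",
    "Moon": "moon_frac",
    "CHLA": "chla",
}
SMOOTH_DEFAULT_K = {"Day": 7, "Hour": 7, "Moon": 6, "CHLA": 7}
SMOOTH_PERIOD = {"Day": 365.0, "Hour": 24.0}  # cyclic terms; others natural


def day_of_year_365(dates: pd.Series) -> np.ndarray:
    """Day of year on a fixed 365-day cycle (Feb 29 folded onto Feb 28)."""
    dt = pd.to_datetime(dates)
    doy = dt.dt.dayofyear.to_numpy().astype(float)
    leap = dt.dt.is_leap_year.to_numpy()
    doy = np.where(leap & (doy >= 60), doy - 1, doy)
    return doy


def build_hourly_table(
    detections: pd.DataFrame,
    deployments: pd.DataFrame,
    environment: pd.DataFrame,
    receivers: pd.DataFrame,
    tz_offset_hours: float = 3.0,
    post_release_hours: float = 48.0,
    window_end=None,
    max_env_gap_days: int = 7,
) -> pd.DataFrame:
    """Animal x hour binomial observations with joined covariates.

    One row per animal-hour from release + 48 h to the study end; y = 1 iff
    the animal was detected at least once in [hour, hour+1).  Covariates:
    local day-of-year, local hour, daily moon fraction and chlorophyll-a
    (forward-filled over short gaps), hourly active-receiver count, sex,
    maturity.
    """
    from .qc import retained

    det = retained(detections)
    if window_end is None:
        window_end = det["timestamp"].max()
    window_end = pd.Timestamp(window_end)
    if window_end.tzinfo is None:
        window_end = window_end.tz_localize("UTC")

    env = environment.set_index("date").sort_index()
    frames = []
    for _, dep in deployments.iterrows():
        start = (dep["release_time"] + pd.Timedelta(hours=post_release_hours)).ceil("h")
        hours = pd.date_range(start, window_end.floor("h"), freq="h", inclusive="left")
        if len(hours) == 0:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": dep["animal_id"],
                    "tag_id": dep["tag_id"],
                    "hour_start": hours,
                    "sex": dep["sex"],
                    "maturity": dep["maturity"],
                }
            )
        )
    if not frames:
        raise ValueError("no observation window: check deployments and window_end")
    table = pd.concat(frames, ignore_index=True)

    det_hours = det.assign(hour_start=det["timestamp"].dt.floor("h"))
    hit = det_hours.groupby(["tag_id", "hour_start"]).size()
    idx = pd.MultiIndex.from_frame(table[["tag_id", "hour_start"]])
    table["y"] = (hit.reindex(idx, fill_value=0).to_numpy() > 0).astype(int)

    local = table["hour_start"] + pd.Timedelta(hours=tz_offset_hours)
    table["hour"] = local.dt.hour.astype(float)
    table["date"] = local.dt.date
    table["day_of_year"] = day_of_year_365(local.dt.date.astype(str))

    env_cols = env.reindex(table["date"])
    missing = env_cols["chla"].isna()
    if missing.any():
        run = missing.groupby((~missing).cumsum()).sum().max()
        if run > max_env_gap_days * 24:
            raise ValueError("environmental covariate gap exceeds tolerance")
        env_cols = env_cols.ffill()
        logger.warning("environment series forward-filled over %d rows", int(missing.sum()))
        if env_cols["chla"].isna().any():
            raise ValueError("environment series does not cover the observation window")
    table["chla"] = env_cols["chla"].to_numpy()
    table["moon_frac"] = env_cols["moon_frac"].to_numpy()

    table["n_stations"] = _hourly_station_counts(receivers, table["hour_start"])
    return table


def _hourly_station_counts(receivers: pd.DataFrame, hours: pd.Series) -> np.ndarray:
    uniq = pd.DatetimeIndex(hours.unique()).sort_values()
    counts = np.zeros(len(uniq), dtype=float)
    for _, row in receivers.iterrows():
        a = np.searchsorted(uniq.asi8, pd.Timestamp(row["active_start"]).value, side="left")
        b = np.searchsorted(uniq.asi8, pd.Timestamp(row["active_end"]).value, side="left")
        counts[a:b] += 1.0
    lookup = pd.Series(counts, index=uniq)
    return lookup.reindex(pd.DatetimeIndex(hours)).to_numpy()


# ---------------------------------------------------------------------------
# design construction


@dataclass
class _Block:
    """A column block of the design matrix, possibly penalized."""

    name: str
    cols: slice
    penalty: np.ndarray | None = None  # in block coordinates; None = unpenalized
    lam: float = 0.0
    # for smooths: evaluation closure mapping covariate grid -> constrained basis
    evaluate: callable = None
    covariate: str = ""


def _constrain(X: np.ndarray, S: np.ndarray):
    """Absorb the sum-to-zero-over-data constraint into the basis.

    Returns (Xc, Sc, Z) with Z an orthonormal null-space basis of the column
    means, so fitted smooths are centred and do not confound the intercept.
    """
    c = X.mean(axis=0)
    norm = np.linalg.norm(c)
    if norm == 0:
        raise ValueError("degenerate smooth basis (zero column means)")
    c = c / norm
    # Householder reflector sending c to e1; Z = remaining columns
    v = c.copy()
    v[0] += np.sign(c[0]) if c[0] != 0 else 1.0
    v /= np.linalg.norm(v)
    H = np.eye(len(c)) - 2.0 * np.outer(v, v)
    Z = H[:, 1:]
    Sc = Z.T @ S @ Z
    # normalize the penalty scale so one lambda grid suits every term
    scale = np.diag(Sc).mean()
    if scale > 0:
        Sc = Sc / scale
    return X @ Z, Sc, Z


@dataclass
class GammDesign:
    X: np.ndarray
    y: np.ndarray
    blocks: list
    smooth_names: list
    animal_levels: list

    @property
    def penalized(self):
        return [b for b in self.blocks if b.penalty is not None]


def build_design(table: pd.DataFrame, smooths=("Day", "Hour", "Moon", "CHLA"), k=None) -> GammDesign:
    """Assemble the penalized design matrix for the hourly presence model."""
    k = dict(SMOOTH_DEFAULT_K, **(k or {}))
    y = table["y"].to_numpy(dtype=float)
    n = len(table)
    cols: list[np.ndarray] = [np.ones((n, 1))]
    blocks: list[_Block] = [_Block("intercept", slice(0, 1))]
    start = 1

    def add(name, mat, penalty=None, evaluate=None, covariate=""):
        nonlocal start
        cols.append(mat)
        blocks.append(
            _Block(name, slice(start, start + mat.shape[1]), penalty, evaluate=evaluate, covariate=covariate)
        )
        start += mat.shape[1]

    # parametric fixed effects (always present); zero-variance terms dropped
    for name, vec in (
        ("sex", (table["sex"] == "M").to_numpy(dtype=float)),
        ("maturity", (table["maturity"] == "mature").to_numpy(dtype=float)),
        ("n_stations", table["n_stations"].to_numpy(dtype=float)),
    ):
        if np.var(vec) == 0:
            warnings.warn(f"fixed effect {name} has zero variance; dropped")
            continue
        add(name, vec[:, None])

    smooth_names = []
    for sm in smooths:
        cov = SMOOTH_COVARIATES[sm]
        x = table[cov].to_numpy(dtype=float)
        if np.var(x) == 0:
            warnings.warn(f"smooth {sm} covariate has zero variance; term dropped")
            continue
        if sm in SMOOTH_PERIOD:
            period = SMOOTH_PERIOD[sm]
            Xs, Ss, _ = cyclic_cubic_basis(x, period, k[sm])
            Xc, Sc, Z = _constrain(Xs, Ss)

            def evaluate(grid, sm=sm, period=period, kk=k[sm], Z=Z):
                Xg, _, _ = cyclic_cubic_basis(grid, period, kk)
                return Xg @ Z

        else:
            knots = quantile_knots(x, k[sm])
            Xs, Ss = natural_cubic_basis(x, knots)
            Xc, Sc, Z = _constrain(Xs, Ss)

            def evaluate(grid, knots=knots, Z=Z):
                Xg, _ = natural_cubic_basis(grid, knots)
                return Xg @ Z

        add(f"s({sm})", Xc, penalty=Sc, evaluate=evaluate, covariate=cov)
        smooth_names.append(sm)

    # per-animal random intercept as a ridge-penalized dummy block
    levels = sorted(table["animal_id"].unique())
    if len(levels) > 1:
        codes = pd.Categorical(table["animal_id"], categories=levels).codes
        Zr = np.zeros((n, len(levels)))
        Zr[np.arange(n), codes] = 1.0
        add("animal", Zr, penalty=np.eye(len(levels)))

    X = np.concatenate(cols, axis=1)
    return GammDesign(X=X, y=y, blocks=blocks, smooth_names=smooth_names, animal_levels=levels)


# ---------------------------------------------------------------------------
# penalized IRLS


def _binomial_deviance(y, mu):
    mu = np.clip(mu, 1e-10, 1 - 1e-10)
    return -2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu))


def _assemble_penalty(design: GammDesign) -> np.ndarray:
    p = design.X.shape[1]
    S = np.zeros((p, p))
    for b in design.penalized:
        S[b.cols, b.cols] += b.lam * b.penalty
    return S


def _pirls(design: GammDesign, beta0=None, max_iter=100, tol=1e-9):
    """Penalized IRLS for the binomial/logit model.  Returns a dict of state."""
    X, y = design.X, design.y
    n, p = X.shape
    S = _assemble_penalty(design)
    if beta0 is None:
        mu = np.full(n, np.clip(y.mean(), 0.01, 0.99))
        eta = np.log(mu / (1 - mu))
        beta = np.zeros(p)
        beta[0] = eta[0]
    else:
        beta = beta0.copy()
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
    dev = _binomial_deviance(y, mu)
    pdev = dev + beta @ S @ beta  # PIRLS minimises the penalized deviance
    for it in range(max_iter):
        mu = np.clip(mu, 1e-8, 1 - 1e-8)
        w = mu * (1 - mu)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        H = X.T @ WX
        rhs = WX.T @ z
        try:
            beta_new = np.linalg.solve(H + S, rhs)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise RuntimeError("PIRLS normal equations are singular") from exc
        # step-halving on the penalized deviance for stability
        step = 1.0
        for _ in range(30):
            cand = beta + step * (beta_new - beta)
            eta_c = X @ cand
            mu_c = 1.0 / (1.0 + np.exp(-eta_c))
            dev_c = _binomial_deviance(y, mu_c)
            pdev_c = dev_c + cand @ S @ cand
            if np.isfinite(pdev_c) and pdev_c <= pdev + 1e-8 * (abs(pdev) + 1):
                break
            step /= 2.0
        beta, eta, mu, dev = cand, eta_c, mu_c, dev_c
        if abs(pdev - pdev_c) < tol * (abs(pdev_c) + 1):
            pdev = pdev_c
            break
        pdev = pdev_c
    else:
        raise RuntimeError(f"PIRLS did not converge in {max_iter} iterations (dev={dev:.3f})")

    if mu.min() < 1e-7 or mu.max() > 1 - 1e-7:
        logger.warning("fitted probabilities near 0/1: possible complete separation")
    w = np.clip(mu * (1 - mu), 1e-10, None)
    H = X.T @ (X * w[:, None])
    Hinv = np.linalg.inv(H + S)
    edf_mat = Hinv @ H
    return {
        "beta": beta,
        "mu": mu,
        "deviance": dev,
        "H": H,
        "cov": Hinv,
        "edf_diag": np.diag(edf_mat),
        "edf": float(np.trace(edf_mat)),
        "iterations": it + 1,
    }


def _gcv(fit, n):
    denom = max(n - fit["edf"], 1e-8)
    return n * fit["deviance"] / denom**2


@dataclass
class FitResult:
    """A fitted presence GAMM."""

    smooths: tuple
    beta: np.ndarray = field(repr=False)
    cov: np.ndarray = field(repr=False)
    lambdas: dict
    edf_by_term: dict
    edf: float
    deviance: float
    null_deviance: float
    aic: float
    design: GammDesign = field(repr=False, default=None)
    fitted: np.ndarray = field(repr=False, default=None)
    term_pvalues: dict = field(default_factory=dict)

    @property
    def deviance_explained(self) -> float:
        """Percent of null deviance explained."""
        return 100.0 * (1.0 - self.deviance / self.null_deviance)

    def partial_effect(self, smooth: str, grid=None, n_grid: int = 100):
        """Centred partial effect of a smooth on a covariate grid.

        Returns a DataFrame (grid value, effect, se).  Effects are centred to
        sum to zero over the observed covariate values.
        """
        block = next((b for b in self.design.blocks if b.name == f"s({smooth})"), None)
        if block is None:
            raise KeyError(f"smooth {smooth} not in model")
        if grid is None:
            if smooth not in SMOOTH_PERIOD:
                raise ValueError("grid required for non-cyclic smooths")
            grid = np.linspace(0, SMOOTH_PERIOD[smooth], n_grid)
        grid = np.asarray(grid, dtype=float)
        Xg = block.evaluate(grid)
        bet = self.beta[block.cols]
        eff = Xg @ bet
        # centre over observed covariate values
        X_obs_block = self.design.X[:, block.cols]
        eff = eff - (X_obs_block @ bet).mean()
        V = self.cov[block.cols, block.cols]
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xg, V, Xg), 0.0))
        return pd.DataFrame({"x": grid, "effect": eff, "se": se})

    def summary_text(self) -> str:
        lines = [
            f"smooths: {', '.join(self.smooths) if self.smooths else '(none)'}",
            f"AIC: {self.aic:.2f}   edf: {self.edf:.2f}",
            f"deviance explained: {self.deviance_explained:.2f}%",
            "term edf / p-values:",
        ]
        for term, edf in self.edf_by_term.items():
            p = self.term_pvalues.get(term)
            ptxt = f" p={p:.3g}" if p is not None else ""
            lam = self.lambdas.get(term)
            ltxt = f" lambda={lam:.3g}" if lam is not None else ""
            lines.append(f"  {term}: edf={edf:.2f}{ptxt}{ltxt}")
        return "\n".join(lines)


def fit_binomial_gamm(
    table: pd.DataFrame,
    smooths=("Day", "Hour", "Moon", "CHLA"),
    k=None,
    lambda_grid=(1e-2, 1.0, 1e2, 1e4, 1e6),
    sweeps: int = 2,
    max_iter: int = 100,
    fixed_lambdas: dict | None = None,
) -> FitResult:
    """Fit the hourly presence GAMM with GCV-selected smoothing parameters.

    ``fixed_lambdas`` bypasses the GCV search for named terms (mainly for
    tests, e.g. the lambda -> 0 unpenalized limit).
    """
    y = table["y"].to_numpy()
    if y.min() == y.max():
        raise ValueError("response is all 0 or all 1: model is degenerate")
    design = build_design(table, smooths=smooths, k=k)
    n = len(y)

    fixed_lambdas = fixed_lambdas or {}
    for b in design.penalized:
        b.lam = fixed_lambdas.get(b.name, 1.0)

    fit = _pirls(design, max_iter=max_iter)
    free = [b for b in design.penalized if b.name not in fixed_lambdas]
    if free:
        for _ in range(max(sweeps, 1)):
            for b in free:
                best = (np.inf, b.lam, None)
                for lam in lambda_grid:
                    b.lam = lam
                    cand = _pirls(design, beta0=fit["beta"], max_iter=max_iter)
                    score = _gcv(cand, n)
                    if score < best[0]:
                        best = (score, lam, cand)
                b.lam = best[1]
                fit = best[2]

    # null model (intercept only) for deviance explained
    mu0 = np.clip(y.mean(), 1e-10, 1 - 1e-10)
    null_dev = _binomial_deviance(y, np.full(n, mu0))

    edf_by_term = {}
    pvals = {}
    for b in design.blocks:
        if b.name == "intercept":
            continue
        edf_b = float(np.sum(fit["edf_diag"][b.cols]))
        edf_by_term[b.name] = edf_b
        bet = fit["beta"][b.cols]
        V = fit["cov"][b.cols, b.cols]
        try:
            stat = float(bet @ np.linalg.solve(V, bet))
            df = max(edf_b, 1e-3)
            pvals[b.name] = float(stats.chi2.sf(stat, df))
        except np.linalg.LinAlgError:
            pvals[b.name] = np.nan

    aic = fit["deviance"] + 2.0 * fit["edf"]
    return FitResult(
        smooths=tuple(s for s in smooths if f"s({s})" in {b.name for b in design.blocks}),
        beta=fit["beta"],
        cov=fit["cov"],
        lambdas={b.name: b.lam for b in design.penalized},
        edf_by_term=edf_by_term,
        edf=fit["edf"],
        deviance=fit["deviance"],
        null_deviance=null_dev,
        aic=aic,
        design=design,
        fitted=fit["mu"],
        term_pvalues=pvals,
    )


def enumerate_model_specs(smooths=("Day", "Hour", "Moon", "CHLA")):
    """All subsets of the optional smooths (parametric core always included)."""
    out = []
    for r in range(len(smooths) + 1):
        out.extend(itertools.combinations(smooths, r))
    return out


def enumerate_and_select(
    table: pd.DataFrame,
    smooths=("Day", "Hour", "Moon", "CHLA"),
    k=None,
    lambda_grid=(1e-2, 1.0, 1e2, 1e4, 1e6),
    sweeps: int = 1,
):
    """Fit every candidate smooth subset and rank by AIC.

    Returns (ranking DataFrame, best FitResult).  Failed fits are recorded
    with NaN AIC and the ranking proceeds over the successes.
    """
    candidates = enumerate_model_specs(smooths)
    rows = []
    fits = {}
    for cand in candidates:
        name = "+".join(cand) if cand else "(none)"
        try:
            res = fit_binomial_gamm(table, smooths=cand, k=k, lambda_grid=lambda_grid, sweeps=sweeps)
            fits[cand] = res
            rows.append(
                {
                    "smooths": name,
                    "n_smooths": len(cand),
                    "aic": res.aic,
                    "edf": res.edf,
                    "deviance_explained_pct": res.deviance_explained,
                    "error": "",
                }
            )
        except Exception as exc:  # noqa: BLE001 - ranking proceeds over successes
            logger.warning("candidate %s failed: %s", name, exc)
            rows.append(
                {
                    "smooths": name,
                    "n_smooths": len(cand),
                    "aic": np.nan,
                    "edf": np.nan,
                    "deviance_explained_pct": np.nan,
                    "error": str(exc),
                }
            )
    ranking = pd.DataFrame(rows).sort_values("aic", na_position="last").reset_index(drop=True)
    ranking["delta_aic"] = ranking["aic"] - ranking["aic"].min()
    best_name = ranking.loc[0, "smooths"]
    best_key = tuple(best_name.split("+")) if best_name != "(none)" else ()
    return ranking, fits[best_key]
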