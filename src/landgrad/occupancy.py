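"""Single-season occupancy model with AICc multimodel inference.

The model is the standard zero-inflated Bernoulli hierarchy for
detection/non-detection data: site i is occupied with probability
psi_i (logit-linear in site covariates) and, if occupied, detected on
visit j with probability p_ij (logit-linear in site and visit
covariates). With detection history y_i over J_i visits the site
likelihood is

    L_i = psi_i * prod_j p_ij^y_ij (1-p_ij)^(1-y_ij)
          + (1 - psi_i) * 1[sum_j y_ij = 0],

maximized jointly over both coefficient blocks by quasi-Newton search
with an analytic gradient. Ranking uses the small-sample corrected
AICc = -2l + 2K + 2K(K+1)/(n-K-1) with n the number of sites, and
model weights are the usual Akaike weights over converged candidates.

Entry points follow the statsmodels Model/Results convention::

    model = OccupancyModel(data, psi="city*HS+BG", p="city*date+date2+HS+BG")
    res = model.fit()
    print(res.summary())
    res.predict(newdata, kind="psi")

plus :func:`two_stage_select` (detection structure chosen against the
global occupancy structure, then occupancy structures against the best
detection), :func:`mb_gof` (parametric-bootstrap chi-square goodness
of fit on detection-history frequencies), and :func:`simulate`.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from .checklists import OccuData
from .formulas import DesignInfo, build_design, count_columns, parse_formula

__all__ = [
    "OccupancyModel",
    "OccupancyResults",
    "TwoStageSelection",
    "GofResult",
    "count_params",
    "candidate_detection_set",
    "candidate_occupancy_set",
    "selection_table",
    "two_stage_select",
    "mb_gof",
    "simulate",
]

GLOBAL_PSI = "city*(HS*BG)"
_BOUNDARY = 15.0  # |logit coefficient| beyond which a fit sits on the boundary


def _visit_frame(data: OccuData) -> pd.DataFrame:
    """Visit-level model frame: site covariates joined, date = scaled date."""
    v = data.visits[["site_id", "scaled_date", "y"]].copy()
    v = v.rename(columns={"scaled_date": "date"})
    site_cols = [c for c in data.sites.columns if c not in ("x", "y")]
    return v.merge(data.sites[site_cols], on="site_id", how="left", sort=False)


class OccupancyModel:
    """Zero-inflated Bernoulli occupancy model bound to one dataset.

    Parameters
    ----------
    data : OccuData
        Sites, detection histories, visit dates and covariates.
    psi : str
        Formula for the occupancy submodel (site covariates).
    p : str
        Formula for the detection submodel (site and visit covariates;
        ``date`` is the scaled survey date, ``date2`` its square).
    """

    def __init__(self, data: OccuData, psi: str = "1", p: str = "1", marginality: bool = True):
        self.data = data
        self.psi_formula = psi
        self.p_formula = p
        self.psi_terms = parse_formula(psi, marginality)
        self.p_terms = parse_formula(p, marginality)

        sites = data.sites.sort_values("site_id", kind="stable").reset_index(drop=True)
        visits = _visit_frame(data)
        order = {sid: i for i, sid in enumerate(sites["site_id"])}
        self._site_ids = sites["site_id"].to_numpy()
        self.X, self.psi_info = build_design(self.psi_terms, sites)
        self.V, self.p_info = build_design(self.p_terms, visits)
        self.site_index = visits["site_id"].map(order).to_numpy()
        self.y = visits["y"].to_numpy(dtype=float)
        self.n_sites = len(sites)
        self.detected_any = (
            np.bincount(self.site_index, weights=self.y, minlength=self.n_sites) > 0
        )

    # ---- likelihood machinery -------------------------------------------

    @property
    def k_psi(self) -> int:
        return self.X.shape[1]

    @property
    def k_params(self) -> int:
        return self.X.shape[1] + self.V.shape[1]

    def _site_loglik(self, beta: np.ndarray):
        kpsi = self.k_psi
        eta_psi = self.X @ beta[:kpsi]
        eta_p = self.V @ beta[kpsi:]
        log_psi = -np.logaddexp(0.0, -eta_psi)
        log_1mpsi = -np.logaddexp(0.0, eta_psi)
        log_p = -np.logaddexp(0.0, -eta_p)
        log_1mp = -np.logaddexp(0.0, eta_p)
        vis = self.y * log_p + (1.0 - self.y) * log_1mp
        cll = np.bincount(self.site_index, weights=vis, minlength=self.n_sites)
        a = log_psi + cll
        ll = np.where(self.detected_any, a, np.logaddexp(a, log_1mpsi))
        return ll, a, eta_psi, eta_p

    def loglike(self, beta: np.ndarray) -> float:
        ll, *_ = self._site_loglik(np.asarray(beta, dtype=float))
        return float(ll.sum())

    def nloglike_grad(self, beta: np.ndarray):
        """Negative log-likelihood and its analytic gradient."""
        beta = np.asarray(beta, dtype=float)
        ll, a, eta_psi, eta_p = self._site_loglik(beta)
        psi = expit(eta_psi)
        p = expit(eta_p)
        # s_i = psi_i * A_i / L_i (1 exactly for sites with a detection)
        s = np.where(self.detected_any, 1.0, np.exp(a - ll))
        w_psi = s * (1.0 - psi) - (1.0 - s) * psi
        w_p = s[self.site_index] * (self.y - p)
        grad = np.concatenate([self.X.T @ w_psi, self.V.T @ w_p])
        return -float(ll.sum()), -grad

    def _hessian(self, beta: np.ndarray) -> np.ndarray:
        """Numerical Hessian of the NLL via central differences of the gradient."""
        k = beta.size
        H = np.empty((k, k))
        step = 1e-5 * np.maximum(1.0, np.abs(beta))
        for j in range(k):
            bp, bm = beta.copy(), beta.copy()
            bp[j] += step[j]
            bm[j] -= step[j]
            _, gp = self.nloglike_grad(bp)
            _, gm = self.nloglike_grad(bm)
            H[:, j] = (gp - gm) / (2.0 * step[j])
        return 0.5 * (H + H.T)

    # ---- fitting ---------------------------------------------------------

    def fit(
        self,
        start: np.ndarray | None = None,
        restarts: int = 3,
        seed: int = 0,
        gtol: float = 1e-4,
        maxiter: int = 1000,
    ) -> "OccupancyResults":
        """Maximize the likelihood by BFGS from zero initialization.

        Convergence requires a small gradient max-norm, a
        positive-definite numerical Hessian, and no coefficient on the
        logit boundary; failures are recorded on the result, never
        raised, so a selection run over many candidates can proceed.
        """
        k = self.k_params
        rng = np.random.default_rng(seed)
        best = None
        x0 = np.zeros(k) if start is None else np.asarray(start, dtype=float)
        for attempt in range(restarts + 1):
            res = optimize.minimize(
                self.nloglike_grad,
                x0,
                jac=True,
                method="BFGS",
                options={"gtol": gtol / 10.0, "maxiter": maxiter},
            )
            if best is None or res.fun < best.fun:
                best = res
            if np.max(np.abs(res.jac)) < gtol:
                best = res if res.fun <= best.fun else best
                break
            x0 = rng.normal(scale=0.5, size=k)
        beta = best.x
        grad_norm = float(np.max(np.abs(best.jac)))
        boundary = bool(np.any(np.abs(beta) > _BOUNDARY))
        H = self._hessian(beta)
        cov = None
        pd_hessian = False
        try:
            L = np.linalg.cholesky(H)
            ident = np.eye(k)
            Linv = np.linalg.solve(L, ident)
            cov = Linv.T @ Linv
            pd_hessian = True
        except np.linalg.LinAlgError:
            pass
        converged = (grad_norm < gtol) and pd_hessian and not boundary
        llf = -best.fun
        n = self.n_sites
        if n - k - 1 > 0:
            aicc = 2.0 * best.fun + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)
        else:
            aicc = float("inf")
            converged = False
        return OccupancyResults(
            model=self,
            params=beta,
            cov_params=cov,
            llf=llf,
            aicc=aicc,
            converged=converged,
            boundary=boundary,
            grad_norm=grad_norm,
        )


@dataclass
class OccupancyResults:
    """MLE output of one occupancy model fit."""

    model: OccupancyModel
    params: np.ndarray
    cov_params: np.ndarray | None
    llf: float
    aicc: float
    converged: bool
    boundary: bool = False
    grad_norm: float = float("nan")

    @property
    def k_params(self) -> int:
        return self.model.k_params

    @property
    def param_names(self) -> list[str]:
        return [f"psi:{n}" for n in self.model.psi_info.column_names] + [
            f"p:{n}" for n in self.model.p_info.column_names
        ]

    @property
    def bse(self) -> np.ndarray:
        if self.cov_params is None:
            return np.full(self.params.size, np.nan)
        return np.sqrt(np.clip(np.diag(self.cov_params), 0.0, None))

    def params_series(self) -> pd.Series:
        return pd.Series(self.params, index=self.param_names)

    def summary(self) -> str:
        header = [
            "Single-season occupancy model (zero-inflated Bernoulli, logit links)",
            f"  psi ~ {self.model.psi_formula}    p ~ {self.model.p_formula}",
            f"  sites: {self.model.n_sites}   visits: {self.model.y.size}   K: {self.k_params}",
            f"  logLik: {self.llf:.3f}   AICc: {self.aicc:.3f}   converged: {self.converged}"
            + ("   [boundary]" if self.boundary else ""),
        ]
        tab = pd.DataFrame(
            {
                "estimate": np.round(self.params, 4),
                "se": np.round(self.bse, 4),
            },
            index=self.param_names,
        )
        return "\n".join(header) + "\n" + tab.to_string()

    def predict(self, newdata: pd.DataFrame, kind: str = "psi") -> pd.DataFrame:
        """Back-transformed predictions with delta-method 95% intervals.

        ``kind='psi'`` uses the occupancy design (site covariates),
        ``kind='p'`` the detection design (requires a ``date`` column
        holding the scaled survey date). Intervals are computed on the
        logit scale and mapped through the inverse link, so they stay
        inside (0, 1).
        """
        if kind == "psi":
            info, terms, block = self.model.psi_info, self.model.psi_terms, slice(0, self.model.k_psi)
        elif kind == "p":
            info, terms, block = self.model.p_info, self.model.p_terms, slice(self.model.k_psi, None)
        else:
            raise ValueError("kind must be 'psi' or 'p'")
        X, _ = build_design(terms, newdata.reset_index(drop=True), info=info)
        beta = self.params[block]
        eta = X @ beta
        if self.cov_params is not None:
            cov = self.cov_params[block, :][:, block]
            se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", X, cov, X), 0.0, None))
        else:
            se = np.full(eta.size, np.nan)
        lo = expit(eta - 1.96 * se)
        hi = expit(eta + 1.96 * se)
        return pd.DataFrame(
            {
                "estimate": expit(eta),
                "se_logit": se,
                "ci_low": lo,
                "ci_high": hi,
            }
        )

    def fitted_probabilities(self):
        """(psi per site, p per visit) at the MLE."""
        m = self.model
        psi = expit(m.X @ self.params[: m.k_psi])
        p = expit(m.V @ self.params[m.k_psi :])
        return psi, p

    def to_json(self) -> str:
        return json.dumps(
            {
                "psi_formula": self.model.psi_formula,
                "p_formula": self.model.p_formula,
                "params": dict(zip(self.param_names, self.params.tolist())),
                "se": dict(zip(self.param_names, self.bse.tolist())),
                "llf": self.llf,
                "K": self.k_params,
                "AICc": self.aicc,
                "converged": self.converged,
                "n_sites": self.model.n_sites,
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# parameter counting and candidate sets


def count_params(psi_formula: str, p_formula: str, n_cities: int) -> int:
    """Total design width K of a psi/p pair for a given city count.

    Treatment coding with a single intercept per submodel: the city
    factor contributes ``n_cities - 1`` columns per appearance and
    every continuous term one column.
    """
    levels = {"city": n_cities}
    return count_columns(parse_formula(psi_formula), levels) + count_columns(
        parse_formula(p_formula), levels
    )


def candidate_detection_set(config: list[str] | None = None) -> list[str]:
    """The default 26 detection structures, or a user-supplied list.

    All additive combinations of {city, date (+date2 under
    marginality), HS, BG} except the full additive model (23), plus
    three single-interaction structures carrying a city interaction.
    """
    if config is not None:
        if len(config) == 0:
            raise ValueError("empty detection candidate list")
        return [parse_formula(f).formula for f in config]
    additive = []
    for city, date, hs, bg in itertools.product(
        ("", "city"), ("", "date", "date+date2"), ("", "HS"), ("", "BG")
    ):
        parts = [t for t in (city, date, hs, bg) if t]
        additive.append("+".join(parts) if parts else "1")
    additive.remove("city+date+date2+HS+BG")
    interactions = ["city*date+date2+HS+BG", "city*date+HS+BG", "city*HS"]
    return additive + interactions


def candidate_occupancy_set(config: list[str] | None = None) -> list[str]:
    """The default 16 occupancy structures (all city-gradient combinations)."""
    if config is not None:
        if len(config) == 0:
            raise ValueError("empty occupancy candidate list")
        return [parse_formula(f).formula for f in config]
    return [
        "1",
        "HS",
        "BG",
        "HS+BG",
        "HS*BG",
        "city",
        "city+HS",
        "city+BG",
        "city+HS+BG",
        "city+HS*BG",
        "city*HS",
        "city*BG",
        "city*HS+BG",
        "city*BG+HS",
        "city*(HS+BG)",
        "city*(HS*BG)",
    ]


# ---------------------------------------------------------------------------
# model selection


def selection_table(results: dict) -> pd.DataFrame:
    """AICc ranking of labelled fits; non-converged listed, not ranked.

    Columns mirror a standard selection table: model, K, AICc, dAICc,
    weight, negLogLik, converged. Akaike weights are normalized over
    converged models only and sum to one.
    """
    rows = []
    for label, res in results.items():
        rows.append(
            {
                "model": label,
                "K": res.k_params,
                "AICc": res.aicc,
                "negLogLik": -res.llf,
                "converged": res.converged,
            }
        )
    df = pd.DataFrame(rows)
    conv = df["converged"] & np.isfinite(df["AICc"])
    if not conv.any():
        raise ValueError("no converged model to rank")
    best = df.loc[conv, "AICc"].min()
    df["dAICc"] = np.where(conv, df["AICc"] - best, np.nan)
    rel = np.where(conv, np.exp(-0.5 * df["dAICc"].fillna(np.inf)), 0.0)
    df["weight"] = rel / rel.sum()
    df = df.sort_values(
        ["converged", "AICc"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return df[["model", "K", "AICc", "dAICc", "weight", "negLogLik", "converged"]]


@dataclass
class TwoStageSelection:
    """Output of the two-stage detection-then-occupancy selection."""

    stage1: pd.DataFrame
    stage2: pd.DataFrame
    best_detection: str
    best_occupancy: str
    best_result: OccupancyResults
    stage1_results: dict = field(repr=False, default_factory=dict)
    stage2_results: dict = field(repr=False, default_factory=dict)


def two_stage_select(
    data: OccuData,
    det_set: list[str] | None = None,
    occ_set: list[str] | None = None,
    global_psi: str = GLOBAL_PSI,
    seed: int = 0,
    **fit_kw,
) -> TwoStageSelection:
    """Detection structure first, then occupancy structure.

    Stage 1 fits every detection candidate with the global (most
    complex) occupancy structure fixed; the AICc-best converged
    detection structure is carried into stage 2, where every occupancy
    candidate is fitted with it. Both stage tables are returned with
    delta-AICc and Akaike weights.
    """
    det_set = candidate_detection_set(det_set)
    occ_set = candidate_occupancy_set(occ_set)
    if global_psi not in occ_set:
        raise ValueError("global_psi must be a member of the occupancy candidate set")
    stage1_results = {}
    for p_formula in det_set:
        model = OccupancyModel(data, psi=global_psi, p=p_formula)
        stage1_results[p_formula] = model.fit(seed=seed, **fit_kw)
    stage1 = selection_table(stage1_results)
    best_det = stage1.loc[stage1["converged"], "model"].iloc[0]

    stage2_results = {}
    for psi_formula in occ_set:
        model = OccupancyModel(data, psi=psi_formula, p=best_det)
        stage2_results[psi_formula] = model.fit(seed=seed, **fit_kw)
    stage2 = selection_table(stage2_results)
    best_occ = stage2.loc[stage2["converged"], "model"].iloc[0]
    return TwoStageSelection(
        stage1, stage2, best_det, best_occ, stage2_results[best_occ],
        stage1_results, stage2_results,
    )


# ---------------------------------------------------------------------------
# simulation


def simulate(
    psi_formula: str,
    p_formula: str,
    beta: np.ndarray,
    sites: pd.DataFrame,
    visit_dates: dict | int = 4,
    seed: int = 0,
    season_start: str = "2018-04-01",
) -> OccuData:
    """Draw detection histories from known occupancy and detection models.

    ``sites`` needs a ``site_id`` column plus every covariate the
    formulas use. ``visit_dates`` is either the number of visits per
    site (scaled dates evenly spaced over 0..18) or a mapping
    site_id -> sequence of scaled dates, allowing ragged designs.
    Occupancy states z_i ~ Bernoulli(psi_i) and detections
    y_ij ~ z_i * Bernoulli(p_ij); deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    sites = sites.sort_values("site_id", kind="stable").reset_index(drop=True)
    if isinstance(visit_dates, int):
        dates = np.linspace(0.0, 18.0, visit_dates)
        plan = {sid: dates for sid in sites["site_id"]}
    else:
        plan = {sid: np.asarray(d, dtype=float) for sid, d in visit_dates.items()}
    visit_rows = []
    for sid in sites["site_id"]:
        for d in plan[sid]:
            visit_rows.append((sid, d))
    visits = pd.DataFrame(visit_rows, columns=["site_id", "date"])
    site_cols = [c for c in sites.columns if c not in ("x", "y")]
    vframe = visits.merge(sites[site_cols], on="site_id", how="left", sort=False)

    psi_terms = parse_formula(psi_formula)
    p_terms = parse_formula(p_formula)
    X, _ = build_design(psi_terms, sites)
    V, _ = build_design(p_terms, vframe)
    beta = np.asarray(beta, dtype=float)
    if beta.size != X.shape[1] + V.shape[1]:
        raise ValueError(
            f"beta has {beta.size} entries, designs need {X.shape[1] + V.shape[1]}"
        )
    psi = expit(X @ beta[: X.shape[1]])
    p = expit(V @ beta[X.shape[1] :])
    order = {sid: i for i, sid in enumerate(sites["site_id"])}
    site_idx = visits["site_id"].map(order).to_numpy()
    z = rng.random(len(sites)) < psi
    y = (rng.random(len(visits)) < p) & z[site_idx]

    start = pd.Timestamp(season_start)
    out_visits = pd.DataFrame(
        {
            "site_id": visits["site_id"],
            "date": start + pd.to_timedelta(visits["date"] * 10.0, unit="D"),
            "scaled_date": visits["date"].to_numpy(),
            "y": y.astype(int),
        }
    )
    out_sites = sites.copy()
    if "x" not in out_sites.columns:
        out_sites["x"] = 0.0
    if "y" not in out_sites.columns:
        out_sites["y"] = 0.0
    return OccuData(out_sites, out_visits, start)


# ---------------------------------------------------------------------------
# goodness of fit


@dataclass
class GofResult:
    """Parametric-bootstrap chi-square goodness of fit."""

    chi2_obs: float
    chi2_boot: np.ndarray
    p_value: float
    c_hat: float
    n_boot: int
    seed: int


def _history_chi2(res: OccupancyResults, max_j: int = 14, min_expected: float = 2.0) -> float:
    """Chi-square over detection-history frequencies, cohorted by J.

    Sites are grouped by their number of visits; within each cohort
    the observed count of every possible binary history is compared to
    its expected count under the fitted model, and sparse cells
    (expected < ``min_expected``) are pooled into one cell per cohort.
    """
    m = res.model
    psi, p = res.fitted_probabilities()
    chi2 = 0.0
    j_per_site = np.bincount(m.site_index, minlength=m.n_sites)
    for J in np.unique(j_per_site):
        if J > max_j:
            raise ValueError(
                f"cohort with {J} visits exceeds the enumeration cap ({max_j})"
            )
        in_cohort = np.flatnonzero(j_per_site == J)
        # visit-level p for cohort sites, shape (n_c, J)
        pmat = np.empty((in_cohort.size, J))
        ymat = np.empty((in_cohort.size, J))
        for r, i in enumerate(in_cohort):
            sel = np.flatnonzero(m.site_index == i)
            pmat[r] = p[sel]
            ymat[r] = m.y[sel]
        hists = np.array(list(itertools.product((0, 1), repeat=int(J))))
        # expected count of each history: sum over sites of Pr(h | x_i)
        logp = np.log(pmat)
        log1mp = np.log1p(-pmat)
        cond = np.exp(hists @ logp.T + (1 - hists) @ log1mp.T)  # (H, n_c)
        pr = psi[in_cohort][None, :] * cond
        allzero = hists.sum(axis=1) == 0
        pr[allzero] += (1.0 - psi[in_cohort])[None, :]
        expected = pr.sum(axis=1)
        codes = hists @ (1 << np.arange(int(J)))
        obs_codes = (ymat.astype(int) @ (1 << np.arange(int(J))))
        observed = np.array([(obs_codes == c).sum() for c in codes], dtype=float)
        dense = expected >= min_expected
        for o, e in zip(observed[dense], expected[dense]):
            chi2 += (o - e) ** 2 / e
        pooled_e = expected[~dense].sum()
        pooled_o = observed[~dense].sum()
        if pooled_e > 0:
            chi2 += (pooled_o - pooled_e) ** 2 / pooled_e
    return float(chi2)


def _resample_fit(res: OccupancyResults, rng: np.random.Generator) -> OccupancyResults:
    """Refit the same model to data simulated from its own MLE."""
    m = res.model
    psi, p = res.fitted_probabilities()
    z = rng.random(m.n_sites) < psi
    y = ((rng.random(m.y.size) < p) & z[m.site_index]).astype(float)
    boot = object.__new__(OccupancyModel)
    boot.__dict__.update(m.__dict__)
    boot.y = y
    boot.detected_any = np.bincount(m.site_index, weights=y, minlength=m.n_sites) > 0
    return boot.fit(restarts=1)


def mb_gof(res: OccupancyResults, n_boot: int = 100, seed: int = 0) -> GofResult:
    """MacKenzie-Bailey-style parametric bootstrap goodness of fit.

    The observed chi-square on detection-history frequencies is
    compared with its distribution over ``n_boot`` datasets simulated
    from the fitted model (each refitted before computing its
    statistic). The p-value is the share of bootstrap statistics at
    least as large as observed, and c-hat the ratio of the observed
    statistic to the bootstrap mean — the usual overdispersion
    estimate.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be at least 1")
    if not res.converged:
        warnings.warn("goodness of fit on a non-converged model", stacklevel=2)
    chi2_obs = _history_chi2(res)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        bres = _resample_fit(res, rng)
        boot[b] = _history_chi2(bres)
    p_value = float(np.mean(boot >= chi2_obs))
    mean_boot = float(boot.mean())
    c_hat = chi2_obs / mean_boot if mean_boot > 0 else float("nan")
    return GofResult(chi2_obs, boot, p_value, c_hat, n_boot, seed)
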