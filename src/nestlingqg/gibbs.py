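"""Bayesian Gaussian mixed models fitted by Gibbs sampling.

Two model forms are supported, matching common practice for cross-sex
quantitative genetics in full-sib cross-fostering designs:

* **univariate** — one trait for both sexes; sex enters as a fixed
  effect; nest-of-origin, nest-of-rearing and dyad are random effects
  with a single variance each; one residual variance.
* **bivariate** — the male and the female expression of the trait are
  treated as two response streams.  The nest-of-origin effect is a sexed
  pair of values per nest with a full 2x2 covariance matrix (variances
  V_OM, V_OF and cross-sex covariance COV_MF); rearing and dyad effects
  carry sex-specific variances but no cross-sex covariance; residual
  variances are sex-specific.  A cross-sex residual covariance is
  structurally absent because no nestling is observed in both streams.

The sampler is a systematic-scan block Gibbs: the fixed-effect block and
each random-effect term are drawn from their Gaussian full conditionals
(the levels of a term are conditionally independent given the other
terms, so each term costs O(n) per sweep), and every variance
(co)variance block from its conjugate inverse-Wishart full conditional
(inverse-gamma in the scalar case).  Variance draws are therefore
strictly positive in every retained sample, and the 2x2 origin block is
positive definite by construction.  Fixed effects carry an improper
flat prior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import yaml
from scipy.linalg import solve_triangular

__all__ = [
    "ModelSpec",
    "PriorSpec",
    "MCMCSettings",
    "RandomTerm",
    "GibbsDesign",
    "PosteriorSamples",
    "build_design",
    "run_gibbs",
    "autocorrelation",
    "write_chains",
    "read_chains",
]

_RANDOM_COLUMNS = {"origin": "origin", "rearing": "rearing", "dyad": "dyad"}


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: response trait, model form, fixed and random terms."""

    response: str
    form: str = "univariate"
    fixed: tuple = ("treatment", "year", "sex")
    random: tuple = ("origin", "rearing", "dyad")

    def __post_init__(self) -> None:
        if self.form not in ("univariate", "bivariate"):
            raise ValueError(f"unknown model form {self.form!r}")
        if self.form == "bivariate" and "sex" in self.fixed:
            raise ValueError("bivariate form models sex via response streams, not a fixed effect")
        if len(set(self.random)) != len(self.random):
            raise ValueError("random terms must be distinct")
        unknown = set(self.random) - set(_RANDOM_COLUMNS)
        if unknown:
            raise ValueError(f"unknown random terms: {sorted(unknown)}")


@dataclass(frozen=True)
class PriorSpec:
    """Inverse-Wishart prior for every variance (co)variance component.

    ``variance_scale`` is the prior scale V applied to each variance;
    ``covariance_scale`` the prior scale of the cross-sex origin
    covariance (0 for the weakly informative default); ``nu`` the degree
    of belief.  The defaults V = 1, COV = 0, nu = 1.002 are the standard
    weakly informative choice for this model class.
    """

    variance_scale: float = 1.0
    covariance_scale: float = 0.0
    nu: float = 1.002

    def __post_init__(self) -> None:
        if self.variance_scale <= 0:
            raise ValueError("variance_scale must be positive")
        if self.nu <= 0:
            raise ValueError("nu must be positive")
        if abs(self.covariance_scale) >= self.variance_scale:
            raise ValueError("prior scale matrix must be positive definite")

    @property
    def origin_scale(self) -> np.ndarray:
        v, c = self.variance_scale, self.covariance_scale
        return np.array([[v, c], [c, v]])

    def scaled(self, factor: float) -> "PriorSpec":
        """Prior with every scale multiplied by ``factor`` (sensitivity checks)."""
        return replace(
            self,
            variance_scale=self.variance_scale * factor,
            covariance_scale=self.covariance_scale * factor,
        )


@dataclass(frozen=True)
class MCMCSettings:
    """Chain length bookkeeping.  Defaults give ~2000 weakly
    autocorrelated draws on study-scale data; simulation studies use
    shorter chains (see the replicate helpers)."""

    n_iterations: int = 60_000
    burn_in: int = 10_000
    thinning: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iterations - self.burn_in + self.thinning - 1) // self.thinning


@dataclass
class RandomTerm:
    """Incidence of one random-effect term.

    ``kind`` is ``scalar`` (one variance), ``sexed`` (independent male
    and female variances, diagonal 2x2) or ``cross`` (full 2x2 with
    cross-sex covariance; used for the origin term in bivariate fits).
    """

    name: str
    kind: str
    group_idx: np.ndarray
    n_groups: int
    labels: list


@dataclass
class GibbsDesign:
    """Numeric design assembled from a tidy nestling table."""

    y: np.ndarray
    X: np.ndarray
    fixed_names: list
    sex_idx: np.ndarray  # 0 = female, 1 = male
    terms: list
    residual_by_sex: bool
    spec: ModelSpec

    @property
    def n_obs(self) -> int:
        return len(self.y)


@dataclass
class PosteriorSamples:
    """Retained MCMC draws plus what DIC evaluation needs.

    ``draws`` has one column per fixed effect and variance component and
    a ``deviance`` column (-2 x Gaussian log-likelihood conditional on
    the sampled random effects).  ``mean_fitted`` is the posterior-mean
    linear predictor (fixed + random), accumulated over retained draws.
    """

    draws: pd.DataFrame
    mean_fitted: np.ndarray
    design: GibbsDesign
    prior: PriorSpec
    settings: MCMCSettings

    @property
    def variance_columns(self) -> list:
        return [c for c in self.draws.columns if c.startswith(("V_", "COV_"))]


def _factor_dummies(
    table: pd.DataFrame, factor: str, reference: str | None
) -> tuple[list[np.ndarray], list[str]]:
    """Reference-coded dummy columns for one fixed factor."""
    values = table[factor].astype(str)
    levels = sorted(values.unique())
    if len(levels) < 2:
        warnings.warn(
            f"fixed factor {factor!r} has a single level ({levels[0]!r}); dropped",
            stacklevel=3,
        )
        return [], []
    if reference is not None and reference in levels:
        levels = [reference] + [l for l in levels if l != reference]
    cols, names = [], []
    for level in levels[1:]:
        cols.append((values == level).to_numpy().astype(float))
        names.append(f"{factor}[{level}]")
    return cols, names


def build_design(table: pd.DataFrame, spec: ModelSpec) -> GibbsDesign:
    """Assemble response, fixed-effect and random-effect incidence.

    Fixed factors are reference-coded (control treatment, first year,
    female sex).  In the bivariate form each nestling belongs to exactly
    one sex stream and the fixed part carries one intercept per stream.
    Validates sex codes and that every rearing nest lies inside the
    nestling's own dyad.
    """
    required = {spec.response, "sex"} | set(_RANDOM_COLUMNS[t] for t in spec.random)
    required |= {f for f in spec.fixed if f != "sex"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table missing columns: {sorted(missing)}")

    sex = table["sex"].astype(str)
    bad_sex = set(sex.unique()) - {"male", "female"}
    if bad_sex:
        raise ValueError(f"unknown sex codes: {sorted(bad_sex)}")
    sex_idx = (sex == "male").to_numpy().astype(np.intp)

    if {"origin", "rearing", "dyad"} <= set(table.columns):
        nest_dyad = dict(zip(table["origin"].astype(str), table["dyad"].astype(str)))
        rearing_dyads = table["rearing"].astype(str).map(nest_dyad)
        off = rearing_dyads != table["dyad"].astype(str)
        if off.any():
            bad = table.loc[off, "nestling_id"].head(3).tolist() if "nestling_id" in table else []
            raise ValueError(f"rearing nest outside the nestling's dyad (e.g. {bad})")

    y = table[spec.response].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError(f"non-finite values in response {spec.response!r}")

    cols: list[np.ndarray] = []
    names: list[str] = []
    if spec.form == "univariate":
        cols.append(np.ones(len(table)))
        names.append("(Intercept)")
    else:
        cols.append((sex_idx == 0).astype(float))
        cols.append((sex_idx == 1).astype(float))
        names.extend(["mu[female]", "mu[male]"])
    for factor in spec.fixed:
        if factor == "sex":
            c, n = _factor_dummies(table, "sex", reference="female")
        elif factor == "treatment":
            c, n = _factor_dummies(table, "treatment", reference="control")
        else:
            c, n = _factor_dummies(table, factor, reference=None)
        cols.extend(c)
        names.extend(n)
    X = np.column_stack(cols)

    terms = []
    for term in spec.random:
        col = table[_RANDOM_COLUMNS[term]].astype(str)
        labels = sorted(col.unique())
        lookup = {lab: i for i, lab in enumerate(labels)}
        gidx = col.map(lookup).to_numpy(dtype=np.intp)
        if spec.form == "bivariate":
            kind = "cross" if term == "origin" else "sexed"
        else:
            kind = "scalar"
        terms.append(
            RandomTerm(name=term, kind=kind, group_idx=gidx, n_groups=len(labels), labels=labels)
        )

    return GibbsDesign(
        y=y,
        X=X,
        fixed_names=names,
        sex_idx=sex_idx,
        terms=terms,
        residual_by_sex=(spec.form == "bivariate"),
        spec=spec,
    )


def _invgamma_draw(rng: np.random.Generator, shape: float, scale: float) -> float:
    return scale / rng.gamma(shape)


def _invwishart2_draw(rng: np.random.Generator, psi: np.ndarray, df: float) -> np.ndarray:
    """Draw a 2x2 inverse-Wishart(psi, df) matrix via Bartlett decomposition."""
    # W ~ Wishart(df, inv(psi)); return inv(W)
    det = psi[0, 0] * psi[1, 1] - psi[0, 1] ** 2
    if det <= 0 or psi[0, 0] <= 0:
        raise ValueError("inverse-Wishart scale matrix not positive definite")
    s = np.array([[psi[1, 1], -psi[0, 1]], [-psi[0, 1], psi[0, 0]]]) / det
    l11 = np.sqrt(s[0, 0])
    l21 = s[1, 0] / l11
    l22 = np.sqrt(s[1, 1] - l21**2)
    a11 = np.sqrt(rng.chisquare(df))
    a21 = rng.standard_normal()
    a22 = np.sqrt(rng.chisquare(df - 1.0))
    # T = L @ A (both lower triangular), W = T T'
    t11 = l11 * a11
    t21 = l21 * a11 + l22 * a21
    t22 = l22 * a22
    w11 = t11**2
    w21 = t11 * t21
    w22 = t21**2 + t22**2
    wdet = w11 * w22 - w21**2
    return np.array([[w22, -w21], [-w21, w11]]) / wdet


class _TermState:
    """Per-term sampler state: effects, contribution vector, variances."""

    def __init__(self, term: RandomTerm, design: GibbsDesign, prior: PriorSpec):
        self.term = term
        n = design.n_obs
        q = term.n_groups
        self.contrib = np.zeros(n)
        if term.kind == "scalar":
            self.u = np.zeros(q)
            self.var = prior.variance_scale
            self.counts = np.bincount(term.group_idx, minlength=q).astype(float)
        else:
            self.u = np.zeros((q, 2))  # columns (female, male)
            self.rows = [np.flatnonzero(design.sex_idx == s) for s in (0, 1)]
            self.gsub = [term.group_idx[r] for r in self.rows]
            self.counts = [
                np.bincount(g, minlength=q).astype(float) for g in self.gsub
            ]
            if term.kind == "sexed":
                self.var = [prior.variance_scale, prior.variance_scale]
            else:
                self.G = prior.origin_scale.copy()


def run_gibbs(
    design: GibbsDesign,
    prior: PriorSpec | None = None,
    settings: MCMCSettings | None = None,
    fix_residual: float | None = None,
) -> PosteriorSamples:
    """Systematic-scan Gibbs sampler for the mixed model.

    Each sweep draws, in order: the fixed-effect block from its joint
    Gaussian full conditional; every random-effect term level-wise (the
    levels are conditionally independent given all other terms); every
    variance component from its conjugate inverse-Wishart/inverse-gamma
    full conditional; and the per-sweep conditional deviance.  Retains
    ``(n_iterations - burn_in)/thinning`` draws; bit-reproducible for a
    given seed.

    ``fix_residual`` holds the residual variance at a known constant
    (shared-residual designs only) — used for conjugate closed-form
    validation of the fixed-effect block.
    """
    prior = prior or PriorSpec()
    settings = settings or MCMCSettings()
    if fix_residual is not None and design.residual_by_sex:
        raise ValueError("fix_residual only supported for shared-residual designs")
    rng = np.random.default_rng(settings.seed)
    n, p = design.X.shape
    y = design.y
    X = design.X
    sex_rows = [np.flatnonzero(design.sex_idx == s) for s in (0, 1)]
    nu = prior.nu
    V = prior.variance_scale

    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design is rank deficient after coding")
    XtX_by_sex = [X[r].T @ X[r] for r in sex_rows]
    XtX = XtX_by_sex[0] + XtX_by_sex[1]

    states = [_TermState(t, design, prior) for t in design.terms]
    beta = np.zeros(p)
    fixed_contrib = np.zeros(n)
    if design.residual_by_sex:
        res_var = np.array([V, V])
    else:
        res_var = float(V) if fix_residual is None else float(fix_residual)

    n_keep = settings.n_retained
    comp_names: list[str] = []
    for st in states:
        t = st.term
        if t.kind == "scalar":
            comp_names.append(f"V_{t.name}")
        elif t.kind == "sexed":
            comp_names.extend([f"V_{t.name}_F", f"V_{t.name}_M"])
        else:
            comp_names.extend([f"V_{t.name}_F", f"V_{t.name}_M", f"COV_{t.name}_MF"])
    if design.residual_by_sex:
        comp_names.extend(["V_residual_F", "V_residual_M"])
    else:
        comp_names.append("V_residual")
    out = np.empty((n_keep, p + len(comp_names) + 1))
    mean_fitted = np.zeros(n)
    kept = 0

    def row_weights():
        if design.residual_by_sex:
            w = np.empty(n)
            w[sex_rows[0]] = 1.0 / res_var[0]
            w[sex_rows[1]] = 1.0 / res_var[1]
            return w
        return np.full(n, 1.0 / res_var)

    total_random = np.zeros(n)
    for it in range(settings.n_iterations):
        # --- fixed-effect block ---
        r = y - total_random
        if design.residual_by_sex:
            A = XtX_by_sex[0] / res_var[0] + XtX_by_sex[1] / res_var[1]
            w = row_weights()
            b = X.T @ (w * r)
        else:
            A = XtX / res_var
            b = X.T @ r / res_var
        try:
            L = np.linalg.cholesky(A)
        except np.linalg.LinAlgError as exc:
            raise ValueError("fixed-effect conditional precision not positive definite") from exc
        mean = solve_triangular(L.T, solve_triangular(L, b, lower=True), lower=False)
        beta = mean + solve_triangular(L.T, rng.standard_normal(p), lower=False)
        fixed_contrib = X @ beta

        # --- random-effect terms ---
        for st in states:
            t = st.term
            q = t.n_groups
            r = y - fixed_contrib - (total_random - st.contrib)
            if t.kind == "scalar":
                bsum = np.bincount(t.group_idx, weights=r, minlength=q) / res_var
                prec = st.counts / res_var + 1.0 / st.var
                st.u = bsum / prec + rng.standard_normal(q) / np.sqrt(prec)
                new_contrib = st.u[t.group_idx]
            elif t.kind == "sexed":
                for s in (0, 1):
                    rs = r[st.rows[s]]
                    bsum = np.bincount(st.gsub[s], weights=rs, minlength=q) / res_var[s]
                    prec = st.counts[s] / res_var[s] + 1.0 / st.var[s]
                    st.u[:, s] = bsum / prec + rng.standard_normal(q) / np.sqrt(prec)
                new_contrib = st.u[t.group_idx, design.sex_idx]
            else:  # cross: 2x2 full conditional per origin nest
                G = st.G
                gdet = G[0, 0] * G[1, 1] - G[0, 1] ** 2
                if gdet <= 0:
                    raise ValueError("origin covariance left the positive-definite cone")
                ginv = np.array([[G[1, 1], -G[0, 1]], [-G[0, 1], G[0, 0]]]) / gdet
                bF = np.bincount(st.gsub[0], weights=r[st.rows[0]], minlength=q) / res_var[0]
                bM = np.bincount(st.gsub[1], weights=r[st.rows[1]], minlength=q) / res_var[1]
                pF = st.counts[0] / res_var[0] + ginv[0, 0]
                pM = st.counts[1] / res_var[1] + ginv[1, 1]
                off = ginv[0, 1]
                det = pF * pM - off**2
                mF = (pM * bF - off * bM) / det
                mM = (pF * bM - off * bF) / det
                # per-group precision Cholesky, closed form
                l11 = np.sqrt(pF)
                l21 = off / l11
                l22 = np.sqrt(pM - l21**2)
                z1 = rng.standard_normal(q)
                z2 = rng.standard_normal(q)
                e2 = z2 / l22
                e1 = (z1 - l21 * e2) / l11
                st.u[:, 0] = mF + e1
                st.u[:, 1] = mM + e2
                new_contrib = st.u[t.group_idx, design.sex_idx]
            total_random += new_contrib - st.contrib
            st.contrib = new_contrib

        # --- variance components ---
        comps: list[float] = []
        for st in states:
            t = st.term
            q = t.n_groups
            if t.kind == "scalar":
                S = float(st.u @ st.u)
                st.var = _invgamma_draw(rng, (nu + q) / 2.0, (nu * V + S) / 2.0)
                comps.append(st.var)
            elif t.kind == "sexed":
                for s in (0, 1):
                    S = float(st.u[:, s] @ st.u[:, s])
                    st.var[s] = _invgamma_draw(rng, (nu + q) / 2.0, (nu * V + S) / 2.0)
                comps.extend(st.var)
            else:
                psi = nu * prior.origin_scale + st.u.T @ st.u
                st.G = _invwishart2_draw(rng, psi, nu + q)
                comps.extend([st.G[0, 0], st.G[1, 1], st.G[0, 1]])

        resid = y - fixed_contrib - total_random
        if design.residual_by_sex:
            for s in (0, 1):
                rs = resid[sex_rows[s]]
                S = float(rs @ rs)
                res_var[s] = _invgamma_draw(rng, (nu + len(rs)) / 2.0, (nu * V + S) / 2.0)
            comps.extend([res_var[0], res_var[1]])
        else:
            if fix_residual is None:
                S = float(resid @ resid)
                res_var = _invgamma_draw(rng, (nu + n) / 2.0, (nu * V + S) / 2.0)
            comps.append(res_var)

        # --- conditional deviance ---
        if design.residual_by_sex:
            dev = 0.0
            for s in (0, 1):
                rs = resid[sex_rows[s]]
                dev += len(rs) * np.log(2 * np.pi * res_var[s]) + float(rs @ rs) / res_var[s]
        else:
            dev = n * np.log(2 * np.pi * res_var) + float(resid @ resid) / res_var

        if it >= settings.burn_in and (it - settings.burn_in) % settings.thinning == 0:
            out[kept, :p] = beta
            out[kept, p : p + len(comps)] = comps
            out[kept, -1] = dev
            mean_fitted += fixed_contrib + total_random
            kept += 1

    draws = pd.DataFrame(out[:kept], columns=design.fixed_names + comp_names + ["deviance"])
    return PosteriorSamples(
        draws=draws,
        mean_fitted=mean_fitted / max(kept, 1),
        design=design,
        prior=prior,
        settings=settings,
    )


def autocorrelation(chain: np.ndarray, max_lag: int) -> np.ndarray:
    """Sample autocorrelation of one parameter's chain for lags 0..max_lag.

    A constant chain has no defined autocorrelation; NaNs are returned
    with a warning.
    """
    x = np.asarray(chain, dtype=float)
    if len(x) <= max_lag:
        raise ValueError("chain shorter than max_lag")
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0:
        warnings.warn("constant chain: autocorrelation undefined", stacklevel=2)
        return np.full(max_lag + 1, np.nan)
    return np.array([float(xc[: len(x) - k] @ xc[k:]) / denom for k in range(max_lag + 1)])


def write_chains(samples: PosteriorSamples, chain_path, meta_path=None) -> None:
    """Write retained draws as CSV plus an optional run-metadata YAML."""
    samples.draws.to_csv(chain_path, index=False)
    if meta_path is not None:
        meta = {
            "model": {
                "response": samples.design.spec.response,
                "form": samples.design.spec.form,
                "fixed": list(samples.design.spec.fixed),
                "random": list(samples.design.spec.random),
            },
            "prior": {
                "variance_scale": samples.prior.variance_scale,
                "covariance_scale": samples.prior.covariance_scale,
                "nu": samples.prior.nu,
            },
            "mcmc": {
                "n_iterations": samples.settings.n_iterations,
                "burn_in": samples.settings.burn_in,
                "thinning": samples.settings.thinning,
                "seed": samples.settings.seed,
            },
            "n_obs": int(samples.design.n_obs),
        }
        with open(meta_path, "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=False)


def read_chains(chain_path) -> pd.DataFrame:
    """Read a posterior-chain CSV written by :func:`write_chains`."""
    return pd.read_csv(chain_path)
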