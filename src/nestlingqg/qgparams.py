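"""Genetic parameters derived from posterior variance components.

In a full-sib cross-fostering design with unrelated families the
nest-of-origin variance captures about half of the additive genetic
variance (plus a quarter of dominance and any maternal effects), so
broad-sense heritability is estimated as

    H^2 = 2 * V_O / (V_O + V_R + V_D + V_Res)

and the cross-sex genetic correlation as

    r_mf = COV_MF / sqrt(V_OM * V_OF).

Both are computed **per posterior draw** and only then summarised: the
posterior of a ratio is not the ratio of posterior summaries, which is
also why published point estimates need not equal plug-in ratios of
published component estimates.  Interval summaries are 95% highest
posterior density (HPD) intervals — the shortest contiguous interval
holding the requested mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

__all__ = [
    "heritability",
    "cross_sex_correlation",
    "hpd_interval",
    "point_summary",
    "significance_flags",
    "DerivedParameters",
    "derive_parameters",
    "component_summary",
    "table_report",
]


def _component(draws: pd.DataFrame, name: str, suffix: str) -> np.ndarray:
    col = f"{name}{suffix}"
    if col in draws.columns:
        return draws[col].to_numpy(dtype=float)
    return np.zeros(len(draws))


def heritability(draws: pd.DataFrame, sex: str | None = None) -> np.ndarray:
    """Per-draw broad-sense heritability 2*V_O / (V_O + V_R + V_D + V_Res).

    For univariate chains call with ``sex=None``; for bivariate chains
    pass ``sex='M'`` or ``'F'`` to use the sex-specific components.
    Random terms absent from the fitted model contribute zero variance.
    Accepts a plain mapping of component values as a single "draw".
    """
    if not isinstance(draws, pd.DataFrame):
        draws = pd.DataFrame([draws])
    suffix = "" if sex is None else f"_{sex.upper()}"
    v_o = _component(draws, "V_origin", suffix)
    total = (
        v_o
        + _component(draws, "V_rearing", suffix)
        + _component(draws, "V_dyad", suffix)
        + _component(draws, "V_residual", suffix)
    )
    if np.any(total <= 0):
        raise ValueError("total phenotypic variance must be positive in every draw")
    return 2.0 * v_o / total


def cross_sex_correlation(draws: pd.DataFrame) -> np.ndarray:
    """Per-draw r_mf = COV_MF / sqrt(V_OM * V_OF) from a bivariate chain."""
    if not isinstance(draws, pd.DataFrame):
        draws = pd.DataFrame([draws])
    needed = {"V_origin_M", "V_origin_F", "COV_origin_MF"}
    missing = needed - set(draws.columns)
    if missing:
        raise ValueError(f"bivariate origin components missing: {sorted(missing)}")
    vm = draws["V_origin_M"].to_numpy(dtype=float)
    vf = draws["V_origin_F"].to_numpy(dtype=float)
    if np.any(vm <= 0) or np.any(vf <= 0):
        raise ValueError("origin variances must be positive in every draw")
    return draws["COV_origin_MF"].to_numpy(dtype=float) / np.sqrt(vm * vf)


def hpd_interval(draws, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass * n)`` draws.

    The standard highest-posterior-density credibility interval for a
    unimodal posterior, computed over the sorted sample.
    """
    x = np.sort(np.asarray(draws, dtype=float))
    n = len(x)
    if n < 100:
        raise ValueError("HPD interval needs at least 100 draws")
    if not (0 < mass < 1):
        raise ValueError("mass must be in (0, 1)")
    m = int(np.ceil(mass * n))
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def point_summary(draws) -> dict:
    """Posterior mean and kernel-density mode of a chain.

    The mode is the argmax of a Gaussian KDE (Scott's bandwidth rule)
    evaluated on a fine grid over the sample range; for a (near)
    degenerate chain the mode is the common value.
    """
    x = np.asarray(draws, dtype=float)
    if len(x) == 0:
        raise ValueError("empty chain")
    mean = float(x.mean())
    if np.ptp(x) == 0:
        return {"mean": mean, "mode": float(x[0])}
    try:
        kde = gaussian_kde(x)
    except np.linalg.LinAlgError:
        return {"mean": mean, "mode": float(np.median(x))}
    pad = 0.05 * np.ptp(x)
    grid = np.linspace(x.min() - pad, x.max() + pad, 512)
    mode = float(grid[int(np.argmax(kde(grid)))])
    return {"mean": mean, "mode": mode}


def significance_flags(hpd: tuple[float, float]) -> dict:
    """Qualitative conclusions about a correlation's HPD interval.

    ``rmf_differs_from_zero`` — the interval excludes 0 (a genetic
    cross-sex association is supported); ``rmf_differs_from_unity`` —
    the interval excludes 1 (the male and female trait are not the same
    genetic character).
    """
    low, high = hpd
    return {
        "rmf_differs_from_zero": not (low <= 0.0 <= high),
        "rmf_differs_from_unity": not (low <= 1.0 <= high),
    }


@dataclass
class DerivedParameters:
    """Per-draw derived genetic parameters with their summaries.

    ``chains`` maps parameter name (e.g. ``H2``, ``H2_M``, ``r_mf``) to
    the per-draw array; ``summary`` holds mean, KDE mode and 95% HPD
    bounds per parameter.
    """

    chains: dict
    summary: pd.DataFrame

    def flags(self) -> dict:
        if "r_mf" not in self.chains:
            return {}
        row = self.summary.loc["r_mf"]
        return significance_flags((row["hpd_low"], row["hpd_high"]))


def derive_parameters(draws: pd.DataFrame, mass: float = 0.95) -> DerivedParameters:
    """Compute every derivable genetic parameter from a posterior chain.

    Univariate chains yield ``H2``; bivariate chains yield ``H2_M``,
    ``H2_F`` and ``r_mf``.  Each parameter is transformed draw-by-draw
    and then summarised (mean, KDE mode, HPD interval).
    """
    chains: dict[str, np.ndarray] = {}
    if "V_origin" in draws.columns:
        chains["H2"] = heritability(draws)
    if "V_origin_M" in draws.columns:
        chains["H2_M"] = heritability(draws, sex="M")
        chains["H2_F"] = heritability(draws, sex="F")
        chains["r_mf"] = cross_sex_correlation(draws)
    if not chains:
        raise ValueError("chain contains no origin variance components")
    rows = {}
    for name, chain in chains.items():
        low, high = hpd_interval(chain, mass=mass)
        summ = point_summary(chain)
        rows[name] = {
            "mean": summ["mean"],
            "mode": summ["mode"],
            "hpd_low": low,
            "hpd_high": high,
        }
    return DerivedParameters(chains=chains, summary=pd.DataFrame(rows).T)


def component_summary(draws: pd.DataFrame, mass: float = 0.95) -> pd.DataFrame:
    """Posterior mean, mode and HPD interval of every variance component."""
    rows = {}
    for col in draws.columns:
        if not col.startswith(("V_", "COV_")):
            continue
        chain = draws[col].to_numpy(dtype=float)
        low, high = hpd_interval(chain, mass=mass)
        summ = point_summary(chain)
        rows[col] = {
            "mean": summ["mean"],
            "mode": summ["mode"],
            "hpd_low": low,
            "hpd_high": high,
        }
    return pd.DataFrame(rows).T


def table_report(
    trait: str, univariate: pd.DataFrame | None, bivariate: pd.DataFrame | None
) -> pd.DataFrame:
    """Variance-component report for one trait.

    One row per component (posterior mean with 95% HPD bounds) with the
    derived heritability and cross-sex correlation rows interleaved, in
    the layout conventional for cross-fostering variance tables.
    """
    rows = []

    def add_block(draws: pd.DataFrame, form: str) -> None:
        comps = component_summary(draws)
        derived = derive_parameters(draws)
        for name, row in comps.iterrows():
            rows.append(
                {
                    "trait": trait,
                    "model": form,
                    "parameter": name,
                    "estimate": row["mean"],
                    "hpd_low": row["hpd_low"],
                    "hpd_high": row["hpd_high"],
                }
            )
        for name, row in derived.summary.iterrows():
            rows.append(
                {
                    "trait": trait,
                    "model": form,
                    "parameter": name,
                    "estimate": row["mean"],
                    "hpd_low": row["hpd_low"],
                    "hpd_high": row["hpd_high"],
                }
            )

    if univariate is not None:
        add_block(univariate, "univariate")
    if bivariate is not None:
        add_block(bivariate, "bivariate")
    return pd.DataFrame(rows)
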