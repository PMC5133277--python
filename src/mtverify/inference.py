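"""Contrast-coded maximal mixed-effects models for the six dependent measures.

Each measure is regressed on the three ±0.5-coded factors (plausibility,
congruency, order of presentation) with all two- and three-way interactions,
under a maximal random structure: random intercepts and *uncorrelated*
random slopes per grouping factor (participants; scene units, i.e. scene x
plausibility; counterbalancing).  A slope enters only for predictors built
entirely from factors that vary within the grouping unit — e.g. participants
get plausibility, congruency and their interaction, but not order (a
between-participants factor), while counterbalancing (2 levels) carries an
intercept only.  Singular fits are handled by pruning the smallest-variance
slope and refitting, with the reduction path logged.

Estimation is delegated to lme4 (REML for Gaussian measures, Laplace
binomial logit for accuracy) through :mod:`mtverify._lme4`; p-values use the
normal reference for the mixed-model t/z statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._lme4 import run_mixed_fits
from .contrasts import CODE_COLUMNS, COLUMN_TO_TERM, code_contrasts

#: Grouping-factor columns of the full design, in reporting order.
DEFAULT_GROUPS = ("participant_id", "scene_unit", "counterbalance")

#: Grouping factors restricted to a random intercept (no identifiable slopes).
DEFAULT_INTERCEPT_ONLY = ("counterbalance",)

_BASE_FACTORS = ("c_plaus", "c_cong", "c_order")
_TERM_FACTORS = {
    "c_plaus": {"c_plaus"},
    "c_cong": {"c_cong"},
    "c_order": {"c_order"},
    "c_pc": {"c_plaus", "c_cong"},
    "c_po": {"c_plaus", "c_order"},
    "c_co": {"c_cong", "c_order"},
    "c_pco": {"c_plaus", "c_cong", "c_order"},
}


class SeparationError(ValueError):
    """The binary response admits a perfect (separated) fit."""


def significance(stat: float, df_policy: str = "normal") -> float:
    """Two-tailed p-value for a mixed-model t (or z) statistic.

    Only the normal reference is implemented (``df_policy="normal"``); the
    policy used is recorded in every :class:`FitResult`.
    """
    if df_policy != "normal":
        raise ValueError(f"unknown df policy {df_policy!r}")
    if not np.isfinite(stat):
        raise ValueError("statistic must be finite")
    return float(2.0 * stats.norm.sf(abs(stat)))


def stars(p: float) -> str:
    """Significance stars: *** p<0.001, ** p<0.01, * p<0.05."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class FitResult:
    """Fixed effects (beta, t, p), random-structure summary and diagnostics."""

    table: pd.DataFrame
    vcomp: pd.DataFrame
    converged: bool
    singular: bool
    pruned: list[str]
    random: list[str]
    family: str
    method: str
    df_policy: str
    n_obs: int
    notes: list[str] = field(default_factory=list)

    def coef(self, term: str) -> pd.Series:
        row = self.table[self.table["term"] == term]
        if row.empty:
            raise KeyError(f"no fixed-effect term {term!r}")
        return row.iloc[0]


def scene_unit(trials: pd.DataFrame) -> pd.Series:
    """Scene grouping unit: each scene in each plausibility condition."""
    return (
        "s" + trials["scene_id"].astype(str) + "_" + trials["plausibility"].astype(str)
    )


def _ensure_codes(data: pd.DataFrame) -> pd.DataFrame:
    if all(c in data.columns for c in CODE_COLUMNS):
        out = data.copy()
    else:
        out = code_contrasts(data)
    if "scene_unit" not in out.columns and "scene_id" in out.columns:
        out["scene_unit"] = scene_unit(out)
    return out


def admissible_slopes(data: pd.DataFrame, group: str) -> list[str]:
    """Slope terms identifiable for a grouping factor.

    A base factor qualifies if it varies within at least one unit of the
    grouping factor; a slope is included for every predictor composed solely
    of qualifying factors (between-unit factors and their carriers are
    absorbed by the unit intercepts).
    """
    varying = {
        f for f in _BASE_FACTORS
        if data.groupby(group, sort=False)[f].nunique().max() > 1
    }
    return [t for t in _TERM_FACTORS if _TERM_FACTORS[t] <= varying]


def _random_spec(
    data: pd.DataFrame,
    groups: tuple[str, ...],
    intercept_only: tuple[str, ...],
) -> list[dict]:
    spec = []
    for g in groups:
        if data[g].nunique() < 2:
            raise ValueError(f"grouping factor {g!r} needs at least 2 levels")
        spec.append({"group": g, "term": "1"})
        if g not in intercept_only:
            spec.extend({"group": g, "term": t} for t in admissible_slopes(data, g))
    return spec


def _parse_fit(
    raw: dict,
    *,
    family: str,
    method: str,
    df_policy: str,
    n_obs: int,
    name_map: dict[str, str] | None = None,
    notes: list[str] | None = None,
) -> FitResult:
    if "error" in raw:
        raise RuntimeError(f"mixed-model fit failed: {raw['error']}")
    name_map = name_map or COLUMN_TO_TERM

    def aslist(val):
        # jsonlite un-boxes length-1 vectors to scalars
        if val is None:
            return []
        return [val] if isinstance(val, str) else list(val)
    rows = []
    for term, beta, se, stat in zip(raw["terms"], raw["beta"], raw["se"], raw["stat"]):
        p = significance(stat, df_policy)
        rows.append((name_map.get(term, term), beta, se, stat, p, stars(p)))
    table = pd.DataFrame(rows, columns=["term", "beta", "se", "t", "p", "stars"])
    vc = raw.get("vcomp") or []
    vcomp = pd.DataFrame(
        [(v["group"], name_map.get(v["term"], v["term"]), v["variance"]) for v in vc],
        columns=["group", "term", "variance"],
    )
    return FitResult(
        table=table,
        vcomp=vcomp,
        converged=bool(raw.get("converged", False)),
        singular=bool(raw.get("singular", False)),
        pruned=aslist(raw.get("pruned")),
        random=aslist(raw.get("random")),
        family=family,
        method=method,
        df_policy=df_policy,
        n_obs=n_obs,
        notes=list(notes or []),
    )


def fit_lmm_maximal(
    data: pd.DataFrame,
    response: str,
    *,
    groups: tuple[str, ...] = DEFAULT_GROUPS,
    intercept_only: tuple[str, ...] = DEFAULT_INTERCEPT_ONLY,
    reml: bool = True,
    prune: bool = True,
    df_policy: str = "normal",
    batch: str | None = None,
) -> FitResult | list[FitResult]:
    """Fit the maximal linear mixed model for a continuous measure.

    ``data`` needs the factor (or code) columns, the grouping columns and the
    response.  Rows with a missing response are dropped (and noted) — the
    initial-degree and latency measures are undefined for trials that never
    leave the start radius.  With ``groups=()`` the model degenerates to OLS
    on the fixed design (useful as a zero-variance reference).  ``batch``
    names a column splitting the data into independently fitted replicates,
    returning a list of results.
    """
    df = _ensure_codes(data)
    notes = []
    n_miss = int(df[response].isna().sum())
    if n_miss:
        notes.append(f"dropped {n_miss} rows with missing {response}")
        df = df[df[response].notna()]
    random = _random_spec(df, tuple(groups), tuple(intercept_only)) if groups else []
    method = ("REML" if reml else "ML") if groups else "OLS"
    raws = run_mixed_fits(
        df,
        response=response,
        fixed=list(CODE_COLUMNS),
        random=random,
        family="gaussian",
        reml=reml,
        prune=prune,
        batch=batch,
    )
    results = [
        _parse_fit(
            r, family="gaussian", method=method, df_policy=df_policy,
            n_obs=len(df), notes=notes,
        )
        for r in raws
    ]
    return results if batch else results[0]


def fit_accuracy_glmm(
    data: pd.DataFrame,
    response: str = "correct",
    *,
    groups: tuple[str, ...] = DEFAULT_GROUPS,
    random: str = "intercepts",
    prune: bool = True,
    df_policy: str = "normal",
    batch: str | None = None,
) -> FitResult | list[FitResult]:
    """Binomial-logit mixed model for response accuracy.

    ``random="intercepts"`` (default) fits random intercepts per grouping
    factor — the reduction is recorded in the result notes; ``"maximal"``
    requests uncorrelated slopes as in the Gaussian models (slower, and
    pruned on singularity).  Raises :class:`SeparationError` when the
    response is constant.
    """
    df = _ensure_codes(data)
    y = df[response].astype(float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError(f"{response} must be binary")
    if y.nunique() < 2:
        raise SeparationError(
            f"response {response!r} is constant; the logit intercept is unbounded"
        )
    df = df.copy()
    df["ybin"] = y.astype(int)
    notes = []
    if random == "maximal":
        rspec = _random_spec(df, tuple(groups), tuple(DEFAULT_INTERCEPT_ONLY))
    elif random == "intercepts":
        rspec = [{"group": g, "term": "1"} for g in groups]
        notes.append("random structure reduced to intercepts")
    else:
        raise ValueError(f"random must be 'intercepts' or 'maximal', got {random!r}")
    raws = run_mixed_fits(
        df,
        response="ybin",
        fixed=list(CODE_COLUMNS),
        random=rspec,
        family="binomial",
        prune=prune,
        batch=batch,
    )
    results = [
        _parse_fit(
            r, family="binomial-logit", method="Laplace", df_policy=df_policy,
            n_obs=len(df), notes=notes,
        )
        for r in raws
    ]
    return results if batch else results[0]


# --------------------------------------------------------------------------
# growth-curve analysis of angular trajectory profiles


@dataclass(frozen=True)
class GCASpec:
    """Growth-curve settings: time bins and orthogonal polynomial order."""

    n_bins: int = 101
    poly_order: int = 3

    def __post_init__(self):
        if self.poly_order < 1:
            raise ValueError("poly_order must be >= 1")
        if self.n_bins < self.poly_order + 1:
            raise ValueError("need more bins than polynomial terms")


def orthogonal_time_basis(n_bins: int, order: int) -> np.ndarray:
    """Orthonormal polynomial basis over the bin grid (constant excluded).

    Column k is a degree-(k+1) polynomial; columns are zero-mean and
    orthonormal over the ``n_bins`` equally spaced points, so time terms are
    mutually independent in a balanced design.
    """
    if n_bins < order + 1:
        raise ValueError("need n_bins > order")
    x = np.linspace(-1.0, 1.0, n_bins)
    V = np.vander(x, order + 1, increasing=True)
    Q, _ = np.linalg.qr(V)
    Q = Q[:, 1:]
    # sign convention: each column increasing at the right end
    signs = np.sign(Q[-1, :] - Q[-2, :])
    signs[signs == 0] = 1.0
    return Q * signs


def fit_gca(
    profiles: pd.DataFrame,
    spec: GCASpec | None = None,
    *,
    groups: tuple[str, ...] = ("participant_id",),
    reml: bool = True,
    prune: bool = True,
    df_policy: str = "normal",
) -> FitResult:
    """Growth-curve model of time-normalized movement angles.

    ``profiles`` is a long table with ``bin``, ``angle_deg``, a participant
    column and the three design factors (typically aggregated to one profile
    per participant x condition cell).  The fixed part crosses the condition
    codes with orthogonal time polynomials; participants carry a random
    intercept and uncorrelated random time slopes.
    """
    spec = spec or GCASpec()
    df = _ensure_codes(profiles)
    bins = np.sort(df["bin"].unique())
    if len(bins) != spec.n_bins:
        spec = GCASpec(n_bins=len(bins), poly_order=spec.poly_order)
    basis = orthogonal_time_basis(spec.n_bins, spec.poly_order)
    bin_index = {b: i for i, b in enumerate(bins)}
    rows = df["bin"].map(bin_index).to_numpy()

    name_map = dict(COLUMN_TO_TERM)
    ot_cols = []
    for k in range(spec.poly_order):
        col = f"ot{k + 1}"
        df[col] = basis[rows, k]
        ot_cols.append(col)
        name_map[col] = f"Time^{k + 1}"
    fixed = list(CODE_COLUMNS) + list(ot_cols)
    for ot in ot_cols:
        for code in CODE_COLUMNS:
            col = f"{ot}_{code}"
            df[col] = df[ot] * df[code]
            fixed.append(col)
            name_map[col] = f"{name_map[ot]}:{COLUMN_TO_TERM[code]}"

    random = []
    for g in groups:
        random.append({"group": g, "term": "1"})
        random.extend({"group": g, "term": ot} for ot in ot_cols)

    raws = run_mixed_fits(
        df,
        response="angle_deg",
        fixed=fixed,
        random=random,
        family="gaussian",
        reml=reml,
        prune=prune,
    )
    return _parse_fit(
        raws[0], family="gaussian", method="REML" if reml else "ML",
        df_policy=df_policy, n_obs=len(df), name_map=name_map,
    )
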