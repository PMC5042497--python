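"""Compositional analysis of habitat selection (log-ratio MANOVA).

Each radio-tracked individual contributes one *composition*: a vector of
habitat-use proportions paired with a vector of availability proportions
over the same D classes.  Two study designs are supported:

* **Type II** (second-order selection): use = habitat proportions inside the
  individual's home range; availability = proportions over the species'
  study area, taken as the convex hull around the home ranges of all
  radio-tracked individuals of that species.
* **Type III** (third-order selection): use = proportions of the radio
  locations themselves; availability = proportions inside the individual's
  home range.

With a reference habitat *r*, each individual yields the (D-1)-vector
``y_i = ln(U_i/U_r) - ln(V_i/V_r)``.  Random use implies E[y] = 0; the test
is the one-sample MANOVA with Wilks' statistic

    lambda = |sum (y - ybar)(y - ybar)'| / |sum y y'| ,

where ``-N ln lambda`` is asymptotically chi-square with D-1 degrees of
freedom.  A randomization alternative flips the sign of each individual's
y-vector (full enumeration up to N = 10, otherwise 999 seeded resamples).
Pairwise selection is summarised by the matrix of mean log-ratio
differences with paired t statistics, and habitats are ranked by the number
of positive row entries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import stats

from .homerange import HomeRange
from .io import HabitatMap, LocationSet


@dataclass
class CompositionRecord:
    """Use and availability proportions over D habitat classes for one animal."""

    individual: str
    use: np.ndarray
    avail: np.ndarray
    design: str = "III"
    habitats: list | None = None

    def __post_init__(self):
        self.use = np.asarray(self.use, dtype=float)
        self.avail = np.asarray(self.avail, dtype=float)
        for name, v in (("use", self.use), ("avail", self.avail)):
            if np.any(v < 0):
                raise ValueError(f"{name} proportions must be >= 0")
            if abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} proportions must sum to 1 "
                                 f"(got {v.sum():.12f})")
        if len(self.use) != len(self.avail):
            raise ValueError("use and avail must have equal length")

    @property
    def D(self) -> int:
        return len(self.use)


@dataclass
class SelectionTestResult:
    """Wilks' lambda test of non-random habitat use."""

    wilks_lambda: float
    chi2: float
    df: int
    p_parametric: float
    N: int
    design: str
    p_randomization: float | None = None
    n_resamples: int | None = None

    def __str__(self):
        s = (f"Type {self.design} compositional test: lambda = "
             f"{self.wilks_lambda:.3f}; chi2({self.df}) = {self.chi2:.3f}; "
             f"p = {self.p_parametric:.3f}")
        if self.p_randomization is not None:
            s += (f"; randomization p = {self.p_randomization:.3f} "
                  f"({self.n_resamples} resamples)")
        return s


@dataclass
class RankingMatrix:
    """Pairwise habitat-selection matrix with paired-t p-values and ranks."""

    habitats: list
    mean_diff: pd.DataFrame    # d_ij = mean over animals of ln(Ui/Uj)-ln(Vi/Vj)
    t_stat: pd.DataFrame
    p_value: pd.DataFrame
    ranks: pd.Series           # rank D-1 = most-selected habitat

    def to_table(self) -> pd.DataFrame:
        """Publication-style upper-triangle table 't (p)' plus a Ranking column."""
        order = self.ranks.sort_values(ascending=False).index
        out = pd.DataFrame(index=order, columns=list(order)[1:] + ["Ranking"],
                           dtype=object)
        for a, i in enumerate(order):
            for j in list(order)[1:]:
                if list(order).index(j) <= a:
                    out.loc[i, j] = ""
                else:
                    out.loc[i, j] = (f"{self.t_stat.loc[i, j]:.3f} "
                                     f"({self.p_value.loc[i, j]:.2f})")
            out.loc[i, "Ranking"] = int(self.ranks[i])
        return out


# ---------------------------------------------------------------------------
# compositions from map + geometry


def _proportions_in_home_range(hmap: HabitatMap, hr: HomeRange) -> np.ndarray:
    X, Y = hmap.cell_centers()
    inside = hr.contains_xy(X.ravel(), Y.ravel()).reshape(hmap.shape)
    inside &= hmap.grid >= 0
    if not inside.any():
        raise ValueError("home range lies entirely outside the habitat map")
    return hmap.class_proportions(mask=inside)


def study_area_polygon(home_ranges: dict) -> shapely.Polygon:
    """Convex hull around the home-range cells of all individuals of a species."""
    pts = np.vstack([hr.cell_center_coords() for hr in home_ranges.values()])
    return shapely.MultiPoint(pts).convex_hull


def composition_type2(home_ranges: dict, hmap: HabitatMap,
                      study_area: shapely.Polygon | None = None) -> list:
    """Second-order compositions: home range use vs study-area availability.

    ``home_ranges`` maps individual id -> :class:`HomeRange`.  The study
    area defaults to the convex hull around all individuals' home ranges.
    """
    if len(home_ranges) < 2:
        raise ValueError("Type II design needs >= 2 individuals")
    if study_area is None:
        study_area = study_area_polygon(home_ranges)
    X, Y = hmap.cell_centers()
    in_area = shapely.contains_xy(study_area, X.ravel(), Y.ravel()
                                  ).reshape(hmap.shape)
    in_area &= hmap.grid >= 0
    avail = hmap.class_proportions(mask=in_area)
    out = []
    for aid, hr in home_ranges.items():
        use = _proportions_in_home_range(hmap, hr)
        out.append(CompositionRecord(individual=aid, use=use, avail=avail,
                                     design="II", habitats=list(hmap.classes)))
    return out


def composition_type3(points: LocationSet, hr: HomeRange,
                      hmap: HabitatMap) -> CompositionRecord:
    """Third-order composition: location use vs home-range availability."""
    cls = hmap.class_at(points.x, points.y)
    usable = cls >= 0
    n_drop = int((~usable).sum())
    if n_drop:
        warnings.warn(f"{points.animal_id}: {n_drop} location(s) outside the "
                      "habitat map were dropped")
    if usable.sum() == 0:
        raise ValueError(f"{points.animal_id}: no usable locations on the map")
    counts = np.bincount(cls[usable], minlength=hmap.n_classes).astype(float)
    use = counts / counts.sum()
    avail = _proportions_in_home_range(hmap, hr)
    return CompositionRecord(individual=points.animal_id, use=use, avail=avail,
                             design="III", habitats=list(hmap.classes))


def zero_replace(comp: CompositionRecord,
                 value: float = 1e-4) -> CompositionRecord:
    """Replace zero proportions by ``value`` and renormalize (no-op without zeros)."""
    if value <= 0:
        raise ValueError("replacement value must be positive")

    def _fix(v):
        if not np.any(v == 0):
            return v
        w = np.where(v == 0, value, v)
        return w / w.sum()

    return CompositionRecord(individual=comp.individual, use=_fix(comp.use),
                             avail=_fix(comp.avail), design=comp.design,
                             habitats=comp.habitats)


# ---------------------------------------------------------------------------
# Wilks' lambda and ranking


def _log_ratio_matrix(comps: list, reference: int) -> np.ndarray:
    D = comps[0].D
    keep = [k for k in range(D) if k != reference]
    rows = []
    for c in comps:
        if np.any(c.use <= 0) or np.any(c.avail <= 0):
            raise ValueError(
                f"{c.individual}: zero proportions — apply zero_replace first")
        lu = np.log(c.use)
        lv = np.log(c.avail)
        d = (lu - lv)
        rows.append(d[keep] - d[reference])
    return np.asarray(rows)


def _wilks_lambda(Y: np.ndarray) -> float:
    ybar = Y.mean(axis=0)
    R = Y - ybar
    resid = R.T @ R
    total = Y.T @ Y
    s_t, ld_t = np.linalg.slogdet(total)
    s_r, ld_r = np.linalg.slogdet(resid)
    if s_t <= 0:
        raise np.linalg.LinAlgError(
            "singular total cross-product matrix: merge habitat classes or "
            "use the randomization mode")
    if s_r <= 0:
        return 0.0
    return float(np.exp(ld_r - ld_t))


def wilks_test(comps: list, reference: int | str | None = None,
               mode: str = "parametric", n_resamples: int = 999,
               seed: int | None = None) -> SelectionTestResult:
    """Overall test of non-random habitat use across individuals.

    Parameters
    ----------
    comps : list of CompositionRecord
    reference : habitat index or name, optional
        Reference class for the log-ratio transform (default: last class).
        The value of lambda does not depend on this choice.
    mode : {'parametric', 'randomization', 'both'}
    n_resamples : int
        Randomization resamples when N > 10; for N <= 10 all 2^N sign
        patterns are enumerated exactly.
    """
    D = comps[0].D
    N = len(comps)
    habitats = comps[0].habitats or [str(i) for i in range(D)]
    if isinstance(reference, str):
        reference = habitats.index(reference)
    if reference is None:
        reference = D - 1
    if mode in ("parametric", "both") and N < D - 1:
        raise ValueError(f"parametric test needs N >= D-1 = {D - 1} "
                         f"individuals, got {N}")
    Y = _log_ratio_matrix(comps, reference)
    lam = _wilks_lambda(Y)
    chi2 = -N * np.log(lam) if lam > 0 else np.inf
    df = D - 1
    p_par = float(stats.chi2.sf(chi2, df))
    result = SelectionTestResult(wilks_lambda=lam, chi2=float(chi2), df=df,
                                 p_parametric=p_par, N=N,
                                 design=comps[0].design)
    if mode in ("randomization", "both"):
        if N <= 10:
            signs = np.array(np.meshgrid(*[[1.0, -1.0]] * N)).T.reshape(-1, N)
        else:
            rng = np.random.default_rng(seed)
            signs = rng.choice([1.0, -1.0], size=(n_resamples, N))
        lams = np.array([_wilks_lambda(s[:, None] * Y) for s in signs])
        result.p_randomization = float(np.mean(lams <= lam + 1e-12))
        result.n_resamples = len(signs)
    return result


def ranking_matrix(comps: list) -> RankingMatrix:
    """Pairwise log-ratio selection matrix with paired t tests and ranks."""
    if len(comps) < 2:
        raise ValueError("need >= 2 individuals for the pairwise matrix")
    D = comps[0].D
    habitats = comps[0].habitats or [str(i) for i in range(D)]
    # per-animal centred log differences: d_ij = (lnUi-lnVi) - (lnUj-lnVj)
    diffs = []
    for c in comps:
        if np.any(c.use <= 0) or np.any(c.avail <= 0):
            raise ValueError(
                f"{c.individual}: zero proportions — apply zero_replace first")
        diffs.append(np.log(c.use) - np.log(c.avail))
    diffs = np.asarray(diffs)                     # (N, D)
    mean = pd.DataFrame(np.zeros((D, D)), index=habitats, columns=habitats)
    tstat = pd.DataFrame(np.full((D, D), np.nan), index=habitats,
                         columns=habitats)
    pval = pd.DataFrame(np.full((D, D), np.nan), index=habitats,
                        columns=habitats)
    for i in range(D):
        for j in range(D):
            if i == j:
                continue
            d = diffs[:, i] - diffs[:, j]
            mean.iloc[i, j] = d.mean()
            if np.allclose(d, d[0]):
                # zero variance across animals: degenerate pair
                tstat.iloc[i, j] = np.inf * np.sign(d[0]) if d[0] else 0.0
                pval.iloc[i, j] = np.nan
            else:
                t, p = stats.ttest_1samp(d, 0.0)
                tstat.iloc[i, j] = t
                pval.iloc[i, j] = p
    ranks = pd.Series((mean.to_numpy() > 0).sum(axis=1), index=habitats)
    return RankingMatrix(habitats=habitats, mean_diff=mean, t_stat=tstat,
                         p_value=pval, ranks=ranks)


# ---------------------------------------------------------------------------
# model-style front end


class CompositionalSelection:
    """Compositional habitat-selection model over a set of individuals.

    Construct from :class:`CompositionRecord` objects (see
    :func:`composition_type2` / :func:`composition_type3`) or from a tidy
    DataFrame, then call :meth:`fit`.
    """

    def __init__(self, comps: list, zero_replacement: float | None = None):
        if zero_replacement is not None:
            comps = [zero_replace(c, zero_replacement) for c in comps]
        self.comps = comps

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, habitats: list,
                       design: str = "III", **kw) -> "CompositionalSelection":
        """Build from a frame with columns individual, use_<h>, avail_<h>."""
        comps = []
        for _, row in df.iterrows():
            comps.append(CompositionRecord(
                individual=str(row["individual"]),
                use=np.array([row[f"use_{h}"] for h in habitats], float),
                avail=np.array([row[f"avail_{h}"] for h in habitats], float),
                design=design, habitats=list(habitats)))
        return cls(comps, **kw)

    def fit(self, mode: str = "parametric", reference=None,
            n_resamples: int = 999, seed: int | None = None
            ) -> "CompositionalResults":
        test = wilks_test(self.comps, reference=reference, mode=mode,
                          n_resamples=n_resamples, seed=seed)
        ranking = ranking_matrix(self.comps)
        return CompositionalResults(model=self, test=test, ranking=ranking)


@dataclass
class CompositionalResults:
    """Fitted compositional analysis: overall test plus pairwise ranking."""

    model: CompositionalSelection
    test: SelectionTestResult
    ranking: RankingMatrix

    @property
    def wilks_lambda(self) -> float:
        return self.test.wilks_lambda

    @property
    def pvalue(self) -> float:
        return self.test.p_parametric

    def summary(self) -> str:
        lines = [str(self.test), "",
                 "Pairwise selection (paired t, p in parentheses); higher "
                 "rank = stronger selection:",
                 self.ranking.to_table().to_string()]
        return "\n".join(lines)
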