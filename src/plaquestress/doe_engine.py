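"""Face-centred central composite design and response-surface ANOVA.

The screening campaign varies four continuous factors — wall thickness (WT),
imaging slice thickness (ST), lipid-core stiffness (LC) and fibrous-tissue
stiffness (FT) — over a face-centred CCD (coded levels -1, 0, +1; 2^k
factorial + 2k face-axial + 1 centre point), replicated for each level of
the categorical media-behaviour factor and each geometry.  Each response
(PPS, PCS) is fitted with a full quadratic response surface on coded units;
term significance comes from the partial F-test of each single-degree
term (equivalently the OLS t-test), residual normality from an omnibus
normality test, and the categorical factor is judged with a paired t-test
across the matched design points of the two media behaviours.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm


@dataclass(frozen=True)
class Factor:
    """A continuous screening factor with its physical range."""

    name: str
    low: float
    high: float
    units: str = ""

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError(f"factor {self.name}: lower limit must be below upper limit")

    def decode(self, coded: np.ndarray) -> np.ndarray:
        """Coded (-1..1) to natural units, linear with the face centre at the midpoint."""
        mid = 0.5 * (self.low + self.high)
        half = 0.5 * (self.high - self.low)
        return mid + half * np.asarray(coded)


def default_factors() -> list[Factor]:
    """The four continuous screening factors with their study ranges."""
    return [
        Factor("WT", 0.0, 0.5, "mm"),
        Factor("ST", 0.25, 1.5, "mm"),
        Factor("LC", 0.1, 50.0, "kPa"),
        Factor("FT", 2.7, 342.1, "kPa"),
    ]


def face_centred_ccd(factors: list[Factor]) -> pd.DataFrame:
    """Face-centred CCD: 2^k factorial + 2k axial (on faces) + 1 centre.

    Returns a tidy frame with run ids, point types, coded columns
    `<name>_coded` and natural-unit columns `<name>`.
    """
    names = [f.name for f in factors]
    if len(set(names)) != len(names):
        raise ValueError("duplicate factor names")
    k = len(factors)
    if k < 2:
        raise ValueError("need at least 2 factors")
    rows = []
    for combo in itertools.product([-1.0, 1.0], repeat=k):
        rows.append((combo, "factorial"))
    for j in range(k):
        for v in (-1.0, 1.0):
            axial = [0.0] * k
            axial[j] = v
            rows.append((tuple(axial), "axial"))
    rows.append((tuple([0.0] * k), "center"))
    coded = np.array([r[0] for r in rows])
    df = pd.DataFrame({
        "run": np.arange(len(rows)),
        "point_type": [r[1] for r in rows],
    })
    for j, f in enumerate(factors):
        df[f"{f.name}_coded"] = coded[:, j]
        df[f.name] = f.decode(coded[:, j])
    return df


def cross_with_categorical(
    design: pd.DataFrame,
    media_levels: tuple[str, ...] = ("isotropic", "anisotropic"),
    geometries: tuple[str, ...] = ("geometry1",),
) -> pd.DataFrame:
    """Replicate the design per media behaviour per geometry; unique run ids."""
    blocks = []
    rid = 0
    for geom in geometries:
        for mb in media_levels:
            b = design.copy()
            b["media_behaviour"] = mb
            b["geometry"] = geom
            b["block_run"] = b["run"]
            b["run"] = np.arange(rid, rid + len(b))
            rid += len(b)
            blocks.append(b)
    return pd.concat(blocks, ignore_index=True)


# --------------------------------------------------------------------------
# response-surface fitting


def quadratic_terms(names: list[str]) -> list[tuple[str, ...]]:
    """Full quadratic model terms: linear, squares, two-way interactions."""
    terms: list[tuple[str, ...]] = [(n,) for n in names]
    terms += [(n, n) for n in names]
    terms += [(a, b) for a, b in itertools.combinations(names, 2)]
    return terms


def term_label(t: tuple[str, ...]) -> str:
    if len(t) == 1:
        return t[0]
    a, b = t
    return f"{a}*{b}"


def design_matrix(df: pd.DataFrame, names: list[str], terms) -> np.ndarray:
    cols = [np.ones(len(df))]
    for t in terms:
        if len(t) == 1:
            cols.append(df[f"{t[0]}_coded"].to_numpy())
        else:
            cols.append(df[f"{t[0]}_coded"].to_numpy() * df[f"{t[1]}_coded"].to_numpy())
    return np.column_stack(cols)


@dataclass
class ResponseSurface:
    """Fitted quadratic response surface with its ANOVA summary."""

    response: str
    factor_names: list[str]
    terms: list[tuple[str, ...]]
    coefficients: np.ndarray  # intercept first, then per term
    anova: pd.DataFrame  # term, coefficient, p_value, significant, near_significant
    r_squared: float
    residuals: np.ndarray
    normality_p: float | None
    alpha: float = 0.05
    near_alpha: float = 0.1

    def predict(self, coded: np.ndarray) -> np.ndarray:
        coded = np.atleast_2d(coded)
        idx = {n: j for j, n in enumerate(self.factor_names)}
        X = [np.ones(len(coded))]
        for t in self.terms:
            if len(t) == 1:
                X.append(coded[:, idx[t[0]]])
            else:
                X.append(coded[:, idx[t[0]]] * coded[:, idx[t[1]]])
        return np.column_stack(X) @ self.coefficients

    def to_frame(self) -> pd.DataFrame:
        return self.anova.copy()


class RankDeficientDesign(ValueError):
    pass


def fit_response_surface(
    runs: pd.DataFrame,
    response: str,
    factor_names: list[str] | None = None,
    alpha: float = 0.05,
    near_alpha: float = 0.1,
    reduce: bool = False,
    alpha_out: float = 0.1,
) -> ResponseSurface:
    """Least-squares full quadratic fit on coded units with term-wise ANOVA.

    With `reduce=True` a hierarchy-preserving backward elimination removes
    terms with p > alpha_out one at a time (a square or interaction goes
    before the linear terms it involves), mirroring the reduced statistical
    models such screening studies report.
    """
    if factor_names is None:
        factor_names = [c[: -len("_coded")] for c in runs.columns if c.endswith("_coded")]
    y = runs[response].to_numpy(dtype=float)
    terms = quadratic_terms(factor_names)

    def _fit(terms_now):
        X = design_matrix(runs, factor_names, terms_now)
        if len(y) < X.shape[1]:
            raise RankDeficientDesign(
                f"{len(y)} runs cannot identify {X.shape[1]} model terms"
            )
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            labels = ["intercept"] + [term_label(t) for t in terms_now]
            raise RankDeficientDesign(f"aliased terms in design: {labels}")
        return sm.OLS(y, X).fit()

    fit = _fit(terms)
    if reduce:
        while True:
            pvals = fit.pvalues[1:]
            # only terms whose removal preserves hierarchy are candidates
            removable = []
            for j, t in enumerate(terms):
                if len(t) == 1:
                    involved = [s for s in terms if len(s) == 2 and t[0] in s]
                    if involved:
                        continue
                removable.append((pvals[j], j))
            removable = [(p, j) for p, j in removable if p > alpha_out]
            if not removable:
                break
            _, j = max(removable)
            terms = terms[:j] + terms[j + 1 :]
            if not terms:
                break
            fit = _fit(terms)

    pvals = fit.pvalues[1:]
    coeffs = fit.params
    resid = fit.resid
    normality_p = None
    if len(resid) >= 8:
        normality_p = float(scipy.stats.normaltest(resid).pvalue)
    anova = pd.DataFrame({
        "term": [term_label(t) for t in terms],
        "kind": ["square" if len(t) == 2 and t[0] == t[1]
                 else ("interaction" if len(t) == 2 else "linear") for t in terms],
        "coefficient": coeffs[1:],
        "p_value": pvals,
        "significant": pvals < alpha,
        "near_significant": pvals < near_alpha,
    })
    return ResponseSurface(
        response=response,
        factor_names=factor_names,
        terms=terms,
        coefficients=coeffs,
        anova=anova,
        r_squared=float(fit.rsquared),
        residuals=np.asarray(resid),
        normality_p=normality_p,
        alpha=alpha,
        near_alpha=near_alpha,
    )


@dataclass
class TTestResult:
    mean_difference: float
    p_value: float | None
    n: int
    degenerate: bool = False


def paired_t_test(responses_a, responses_b) -> TTestResult:
    """Two-sided paired t-test; mean difference reported as a - b [kPa]."""
    a = np.asarray(responses_a, dtype=float)
    b = np.asarray(responses_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length paired vectors with n >= 2")
    d = a - b
    if np.allclose(d, d[0]):
        return TTestResult(float(d.mean()), None, len(a), degenerate=True)
    t = scipy.stats.ttest_rel(a, b)
    return TTestResult(float(d.mean()), float(t.pvalue), len(a))


def cube_summary(model: ResponseSurface, group_by: str = "FT") -> pd.DataFrame:
    """Predicted responses at the 2^k design corners, panelled by one factor.

    Mirrors the cube plots of screening reports: corner predictions grouped
    into a low-`group_by` and a high-`group_by` panel.
    """
    names = model.factor_names
    corners = np.array(list(itertools.product([-1.0, 1.0], repeat=len(names))))
    pred = model.predict(corners)
    df = pd.DataFrame(corners, columns=names)
    df["predicted"] = pred
    df["panel"] = np.where(df[group_by] < 0, f"low {group_by}", f"high {group_by}")
    return df.sort_values(["panel"] + names).reset_index(drop=True)
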