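"""Statistical models for fitness and its components.

The centrepiece is a two-part hurdle model for the bimodal individual
fitness distribution: a logistic mixed model for whether fitness is zero
or positive (all individuals), and a Gaussian mixed model for the
magnitude of fitness when positive.  Both parts carry the same candidate
predictor set and nested random intercepts (nest within mother), and the
joint log-likelihood — the exact sum of the two parts — drives model
selection.

Model selection is all-subsets under AICc,

    AICc = -2 logLik + 2k + 2k(k+1)/(n - k - 1),

with the constraint that a covariate's linear form and its nonlinear
(threshold) form never appear in the same candidate model.  Akaike weights
w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2) quantify relative support.

Separate GLMMs handle the fitness components: binomial (survival,
recruitment), Gaussian (nestling condition and size), and zero-inflated
Poisson (number of genetic fledglings).  Paired EPO-WPO contrasts within
mixed-paternity broods (maternal half-sibs) use the Wilcoxon signed-rank
test with midranks for ties.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from wrenfit.mixedmodels import GLMMFit, fit_glmm

MAX_CANDIDATE_MODELS = 2**16
MIN_POSITIVE_ROWS = 10  # refuse the hurdle's positive part below this


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: response, family, fixed terms, random intercepts.

    ``terms`` are data column names or ``"a:b"`` products; the intercept is
    implicit.  ``groups`` are grouping columns, outermost first (a second
    factor must be nested in the first).  Continuous covariates are scaled
    to z-scores at design-matrix construction; 0/1 columns are left as
    factors.
    """

    response: str
    family: str  # binary | gaussian | zip | hurdle
    terms: tuple = ()
    groups: tuple = ()
    scale: bool = True

    def with_terms(self, terms) -> "ModelSpec":
        return replace(self, terms=tuple(terms))


def _is_binary(col: np.ndarray) -> bool:
    vals = np.unique(col[~np.isnan(col)])
    return vals.size <= 2 and np.isin(vals, (0.0, 1.0)).all()


def design_matrix(data: pd.DataFrame, spec: ModelSpec):
    """Build (y, X, names, groups) for a spec; z-scores continuous covariates."""
    y = data[spec.response].to_numpy(dtype=float)
    cols = [np.ones(len(data))]
    names = ["const"]

    def column(name: str) -> np.ndarray:
        if ":" in name:
            parts = name.split(":")
            out = np.ones(len(data))
            for p in parts:
                out = out * column(p)
            return out
        col = data[name].to_numpy(dtype=float)
        if spec.scale and not _is_binary(col):
            sd = col.std()
            if sd == 0:
                raise ValueError(f"covariate {name!r} is constant")
            col = (col - col.mean()) / sd
        return col

    for term in spec.terms:
        cols.append(column(term))
        names.append(term)
    X = np.column_stack(cols)
    groups = [(g, data[g].to_numpy()) for g in spec.groups]
    return y, X, names, groups


def fit_binary_mm(data: pd.DataFrame, spec: ModelSpec, **kw) -> GLMMFit:
    """Logistic random-intercept mixed model (ML, Laplace)."""
    y, X, names, groups = design_matrix(data, spec)
    return fit_glmm(y, X, names, groups, family="binary", **kw)


def fit_gaussian_mm(data: pd.DataFrame, spec: ModelSpec, **kw) -> GLMMFit:
    """Gaussian random-intercept mixed model, fitted by ML (not REML)."""
    y, X, names, groups = design_matrix(data, spec)
    return fit_glmm(y, X, names, groups, family="gaussian", **kw)


def fit_zip_mm(data: pd.DataFrame, spec: ModelSpec, **kw) -> GLMMFit:
    """Zero-inflated Poisson mixed model; random intercept on the count part."""
    y, X, names, groups = design_matrix(data, spec)
    fit = fit_glmm(y, X, names, groups, family="zip", **kw)
    if fit.extra.get("logit_pi", 0.0) <= -11.9:
        warnings.warn("zero-inflation estimated at the boundary (pi ~ 0)")
    return fit


@dataclass
class HurdleFit:
    """Two-part hurdle fit: zero-vs-positive and positive-magnitude parts."""

    binary: GLMMFit
    positive: GLMMFit
    n: int  # observations entering the model (all rows)
    dropped_positive_terms: tuple = ()  # unidentifiable in the positive subset

    @property
    def loglik(self) -> float:
        """Joint log-likelihood: the exact sum of the two parts."""
        return self.binary.loglik + self.positive.loglik

    @property
    def k(self) -> int:
        return self.binary.k + self.positive.k

    @property
    def converged(self) -> bool:
        return self.binary.converged and self.positive.converged

    @property
    def aicc(self) -> float:
        return aicc(self.loglik, self.k, self.n)


def fit_hurdle(data: pd.DataFrame, spec: ModelSpec, **kw) -> HurdleFit:
    """Fit the two-part hurdle model for a non-negative response with zeros.

    Part 1 models 1{response > 0} on all rows; part 2 models the response
    on the rows where it is positive, Gaussian.  Both parts receive the
    spec's full predictor set and random structure, except that a term
    constant within the positive subset (e.g. a rare threshold factor none
    of whose carriers have positive fitness) is unidentifiable there and is
    fitted in the zero part only; such terms are listed in
    ``dropped_positive_terms`` and do not count parameters in part 2.
    """
    y = data[spec.response].to_numpy(dtype=float)
    if (y < 0).any():
        raise ValueError("hurdle response must be non-negative")
    positive = y > 0
    if positive.all():
        raise ValueError("hurdle response has no zeros; part 1 is degenerate")
    if positive.sum() < MIN_POSITIVE_ROWS:
        raise ValueError(
            f"only {int(positive.sum())} positive rows; refusing the positive part"
        )
    start_binary = kw.pop("start_binary", None)
    start_positive = kw.pop("start_positive", None)
    bdata = data.copy()
    bdata["_nonzero"] = positive.astype(float)
    bspec = replace(spec, response="_nonzero", family="binary")
    bfit = fit_binary_mm(bdata, bspec, start=start_binary, **kw)
    pdata = data.loc[positive]
    keep, dropped = [], []
    for term in spec.terms:
        cols = term.split(":")
        col = np.ones(len(pdata))
        for c in cols:
            col = col * pdata[c].to_numpy(dtype=float)
        (keep if np.ptp(col) > 0 else dropped).append(term)
    pspec = replace(spec, family="gaussian", terms=tuple(keep))
    pfit = fit_gaussian_mm(pdata, pspec, start=start_positive, **kw)
    return HurdleFit(
        binary=bfit, positive=pfit, n=len(data), dropped_positive_terms=tuple(dropped)
    )


def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike's information criterion corrected for sample size."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


@dataclass
class SelectionTable:
    """Ranked AICc table over the fitted candidate set."""

    table: pd.DataFrame  # rank, terms, k, loglik, aicc, delta, weight
    fits: dict  # terms tuple -> fitted model
    failed: list = field(default_factory=list)

    @property
    def best_terms(self) -> tuple:
        return self.table.iloc[0]["terms"]

    @property
    def best(self):
        return self.fits[self.best_terms]

    def weight_of(self, term: str) -> float:
        """Summed Akaike weight of all models containing *term*."""
        has = self.table["terms"].map(lambda ts: term in ts)
        return float(self.table.loc[has, "weight"].sum())


def _admissible(subset: tuple, exclusive: list) -> bool:
    s = set(subset)
    return not any(a in s and b in s for a, b in exclusive)


def all_subset_selection(
    data: pd.DataFrame,
    base_spec: ModelSpec,
    candidate_terms,
    exclusive=(),
    ftol: float = 1e-9,
    gtol: float = 1e-4,
) -> SelectionTable:
    """Fit every admissible subset of candidate terms and rank by AICc.

    ``exclusive`` lists pairs of terms that never co-occur (a covariate's
    linear form versus its threshold form).  Terms already in
    ``base_spec.terms`` appear in every model.  Candidates that fail to
    converge are recorded in ``failed`` and excluded from the weights.
    """
    candidate_terms = list(candidate_terms)
    exclusive = list(exclusive)
    if 2 ** len(candidate_terms) > MAX_CANDIDATE_MODELS:
        raise ValueError("candidate set too large to enumerate")
    fitters = {
        "binary": fit_binary_mm,
        "gaussian": fit_gaussian_mm,
        "zip": fit_zip_mm,
        "hurdle": fit_hurdle,
    }
    fit_fn = fitters[base_spec.family]
    rows = []
    fits: dict = {}
    failed: list = []
    for r in range(len(candidate_terms) + 1):
        for subset in itertools.combinations(candidate_terms, r):
            if not _admissible(subset, exclusive):
                continue
            terms = tuple(base_spec.terms) + subset
            spec = base_spec.with_terms(terms)
            try:
                fit = fit_fn(data, spec, ftol=ftol, gtol=gtol)
            except (ValueError, np.linalg.LinAlgError) as exc:
                warnings.warn(f"candidate {terms!r} failed: {exc}")
                failed.append((terms, str(exc)))
                continue
            if not fit.converged:
                failed.append((terms, "non-convergence"))
                continue
            n = fit.n
            rows.append(
                {
                    "terms": terms,
                    "k": fit.k,
                    "loglik": fit.loglik,
                    "aicc": aicc(fit.loglik, fit.k, n),
                    "n": n,
                }
            )
            fits[terms] = fit
    if not rows:
        raise ValueError("no candidate model could be fitted")
    tab = pd.DataFrame(rows)
    # ties broken by smaller k, then lexicographic term order
    tab = tab.sort_values(
        ["aicc", "k", "terms"], key=lambda c: c.map(str) if c.name == "terms" else c
    ).reset_index(drop=True)
    tab["delta"] = tab["aicc"] - tab["aicc"].iloc[0]
    rel = np.exp(-0.5 * tab["delta"].to_numpy())
    tab["weight"] = rel / rel.sum()
    tab.insert(0, "rank", np.arange(1, len(tab) + 1))
    return SelectionTable(table=tab, fits=fits, failed=failed)


@dataclass(frozen=True)
class WilcoxonResult:
    V: float  # sum of positive-difference midranks
    p: float
    n_used: int  # pairs with nonzero difference
    method: str  # "exact" or "normal"


def wilcoxon_paired(values_a, values_b, alternative: str = "two-sided") -> WilcoxonResult:
    """Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped; ties among |differences| take midranks
    (which can make V fractional).  The p-value is exact (full enumeration
    of sign assignments via a rank-sum convolution) for n <= 25 without
    ties, else a normal approximation with tie correction and continuity
    correction.  ``alternative`` "less" tests for a shifted down relative
    to b (small V).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; test carries no information")
        return WilcoxonResult(V=0.0, p=1.0, n_used=0, method="degenerate")
    ranks = stats.rankdata(np.abs(d))
    V = float(ranks[d > 0].sum())
    has_ties = np.unique(np.abs(d)).size < n
    if n <= 25 and not has_ties:
        # distribution of V over the 2^n equiprobable sign assignments
        counts = np.zeros(n * (n + 1) // 2 + 1)
        counts[0] = 1.0
        for r in range(1, n + 1):
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[:-r]
            counts = counts + shifted
        total = counts.sum()
        v_int = int(round(V))
        p_le = counts[: v_int + 1].sum() / total
        p_ge = counts[v_int:].sum() / total
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        tie_sizes = np.unique(np.abs(d), return_counts=True)[1]
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_sizes**3 - tie_sizes).sum() / 48.0
        sd = np.sqrt(var)
        p_le = stats.norm.cdf((V - mean + 0.5) / sd)
        p_ge = stats.norm.sf((V - mean - 0.5) / sd)
        method = "normal"
    if alternative == "two-sided":
        p = min(1.0, 2.0 * min(p_le, p_ge))
    elif alternative == "less":
        p = p_le
    elif alternative == "greater":
        p = p_ge
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return WilcoxonResult(V=V, p=float(p), n_used=n, method=method)


def paired_halfsib_table(
    offspring: pd.DataFrame,
    response_cols,
    seed: int = 0,
) -> pd.DataFrame:
    """One EPO-WPO pair per mixed-paternity brood (maternal half-sibs).

    ``offspring`` needs columns ``id``, ``nest``, ``epp`` (0/1) plus the
    requested response columns.  In broods with several EPO or WPO one of
    each is chosen at random (seeded).  Broods without both kinds are
    excluded; an empty result triggers a warning.
    """
    response_cols = list(response_cols)
    rng = np.random.default_rng(seed)
    rows = []
    for nest, grp in offspring.groupby("nest", sort=True):
        epo = grp[grp["epp"].astype(bool)]
        wpo = grp[~grp["epp"].astype(bool)]
        if len(epo) == 0 or len(wpo) == 0:
            continue
        e = epo.iloc[rng.integers(len(epo))]
        w = wpo.iloc[rng.integers(len(wpo))]
        row = {"nest": nest, "epo_id": e["id"], "wpo_id": w["id"]}
        for col in response_cols:
            row[f"epo_{col}"] = e[col]
            row[f"wpo_{col}"] = w[col]
        rows.append(row)
    if not rows:
        warnings.warn("no mixed-paternity broods; paired table is empty")
        cols = ["nest", "epo_id", "wpo_id"]
        for col in response_cols:
            cols += [f"epo_{col}", f"wpo_{col}"]
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)
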