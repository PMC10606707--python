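"""Repeatability animal model: mixed model equations and AI-REML.

The litter-size model for record vector y is

    y = f d + X b + T h + Z u + W p + e

with b the parity fixed effects (first class absorbs the intercept), f the
per-sow heterozygosity percentage with slope d, h ~ N(0, I sigma2_h) the
herd-year-season effect, u ~ N(0, H sigma2_a) the additive genetic effect
with the single-step relationship structure H, p ~ N(0, I sigma2_p) the
permanent environmental sow effect, and e ~ N(0, I sigma2_e).

Variance components are estimated by average-information REML on Henderson's
mixed model equations; an optional per-sow 0/1 carrier indicator enters as
one extra fixed effect for the per-ROH scan.  All linear algebra is dense:
the systems this package builds stay around 1,000-2,000 equations, where a
dense Cholesky factorization outperforms sparse machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .genotypes import PhenotypeTable
from .relationships import RelationshipMatrix

__all__ = [
    "ModelSpec",
    "RandomTerm",
    "MMESystem",
    "VarianceComponents",
    "CovariateEstimate",
    "build_mme",
    "solve_mme",
    "ai_reml",
    "fit_het_covariate",
    "one_sided_p",
]


@dataclass
class ModelSpec:
    """What enters the model for one trait fit."""

    trait: str = "tnb"
    het_covariate: bool = False
    carrier: bool = False
    hys: bool = True
    df: float | None = None  # reference distribution for one-sided p; None = normal

    def __post_init__(self):
        self.trait = self.trait.lower()
        if self.trait not in ("tnb", "nba"):
            raise ValueError(f"trait must be TNB or NBA, got {self.trait!r}")


@dataclass
class RandomTerm:
    name: str
    Z: np.ndarray  # n_records x q incidence
    kinv: np.ndarray | None = None  # None = identity covariance among levels
    logdet_kinv: float = 0.0

    @property
    def q(self) -> int:
        return self.Z.shape[1]


@dataclass
class VarianceComponents:
    sigma2_a: float
    sigma2_p: float
    sigma2_h: float
    sigma2_e: float
    sampling_variances: dict = field(default_factory=dict)
    iterations: int = 0
    converged: bool = True
    final_update_norm: float = 0.0
    boundary: list = field(default_factory=list)

    def __post_init__(self):
        for name in ("sigma2_a", "sigma2_p", "sigma2_h", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} negative")

    def as_dict(self):
        return {
            "sigma2_a": self.sigma2_a,
            "sigma2_p": self.sigma2_p,
            "sigma2_h": self.sigma2_h,
            "sigma2_e": self.sigma2_e,
        }


@dataclass
class CovariateEstimate:
    estimate: float  # piglets per percent heterozygosity
    se: float
    p_one_sided: float


@dataclass
class MMESystem:
    C: np.ndarray
    rhs: np.ndarray
    blocks: dict  # term name -> slice into the equations
    fixed_names: list
    vc: VarianceComponents
    W: np.ndarray  # full design, records x equations order [fixed | random...]
    y: np.ndarray

    @property
    def n_records(self):
        return len(self.y)


def one_sided_p(estimate: float, se: float, direction: str = "greater",
                df: float | None = None) -> float:
    """Tail probability of estimate/se under N(0,1) or Student-t(df)."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    z = estimate / se
    dist = stats.norm if df is None else stats.t(df)
    if direction == "greater":
        return float(dist.sf(z))
    if direction == "less":
        return float(dist.cdf(z))
    raise ValueError(f"direction must be 'greater' or 'less', got {direction!r}")


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def _indicator(levels, universe=None):
    if universe is None:
        universe = list(dict.fromkeys(levels))
    index = {lv: k for k, lv in enumerate(universe)}
    Z = np.zeros((len(levels), len(universe)))
    for r, lv in enumerate(levels):
        try:
            Z[r, index[lv]] = 1.0
        except KeyError:
            raise ValueError(f"unresolvable level {lv!r} in record {r}") from None
    return Z, universe


def build_design(
    phen: PhenotypeTable,
    spec: ModelSpec,
    hinv: RelationshipMatrix,
    het: dict | None = None,
    carrier: dict | None = None,
):
    """Return (y, X, fixed_names, random_terms) for the requested model.

    ``het`` and ``carrier`` map sow id -> covariate value / 0-1 indicator;
    both are constant across a sow's records.
    """
    df = phen.records
    y = phen.trait(spec.trait)
    n = len(df)

    parities = sorted(df["parity"].unique())
    cols = [np.ones(n)]
    fixed_names = ["intercept(parity1)"] if parities and parities[0] == 1 else ["intercept"]
    for pc in parities[1:]:
        cols.append((df["parity"] == pc).to_numpy(float))
        fixed_names.append(f"parity{pc}")
    if spec.het_covariate:
        if het is None:
            raise ValueError("model includes the heterozygosity covariate but none supplied")
        f = np.array([het[s] for s in df["sow"]], dtype=float)
        if np.ptp(f) == 0:
            raise ValueError("heterozygosity covariate is constant; slope not estimable")
        cols.append(f)
        fixed_names.append("het_percent")
    if spec.carrier:
        if carrier is None:
            raise ValueError("model includes a carrier effect but no indicator supplied")
        c = np.array([carrier[s] for s in df["sow"]], dtype=float)
        if c.min() == c.max():
            raise ValueError("carrier indicator constant across phenotyped sows")
        cols.append(c)
        fixed_names.append("carrier")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"fixed-effect design rank deficient; columns {fixed_names}")

    terms = []
    if spec.hys:
        # sorted level universes keep solutions invariant to record order
        T, hys_levels = _indicator(list(df["hys"]), universe=sorted(set(df["hys"])))
        terms.append(RandomTerm("hys", T, None))
    sows = list(df["sow"])
    missing = [s for s in set(sows) if s not in hinv.ids]
    if missing:
        raise ValueError(f"phenotyped sows absent from relationship structure: {sorted(missing)[:5]}")
    Zu, _ = _indicator(sows, universe=list(hinv.ids))
    sign, logdet = np.linalg.slogdet(hinv.values)
    if sign <= 0:
        raise ValueError("H-inverse is not positive definite")
    terms.append(RandomTerm("u", Zu, hinv.values, logdet))
    Wp, sow_levels = _indicator(sows, universe=sorted(set(sows)))
    terms.append(RandomTerm("p", Wp, None))
    return y, X, fixed_names, terms


# ---------------------------------------------------------------------------
# MME assembly and solving
# ---------------------------------------------------------------------------

def _assemble(y, X, terms, variances, sigma2_e):
    if sigma2_e <= 0:
        raise ValueError("residual variance must be strictly positive")
    W = np.hstack([X] + [t.Z for t in terms])
    p = X.shape[1]
    blocks = {"fixed": slice(0, p)}
    at = p
    for t in terms:
        blocks[t.name] = slice(at, at + t.q)
        at += t.q
    C = (W.T @ W) / sigma2_e
    for t in terms:
        s2 = variances[t.name]
        if s2 <= 0:
            raise ValueError(f"variance of random term {t.name!r} must be strictly positive")
        b = blocks[t.name]
        if t.kinv is None:
            C[b, b] += np.eye(t.q) / s2
        else:
            C[b, b] += t.kinv / s2
    rhs = W.T @ y / sigma2_e
    return C, rhs, blocks, W


def build_mme(
    phen: PhenotypeTable,
    spec: ModelSpec,
    hinv: RelationshipMatrix,
    vc: VarianceComponents,
    het: dict | None = None,
    carrier: dict | None = None,
) -> MMESystem:
    """Henderson system for the repeatability model at fixed variances."""
    y, X, fixed_names, terms = build_design(phen, spec, hinv, het, carrier)
    variances = {"hys": vc.sigma2_h, "u": vc.sigma2_a, "p": vc.sigma2_p}
    terms = [t for t in terms]
    C, rhs, blocks, W = _assemble(y, X, terms, variances, vc.sigma2_e)
    return MMESystem(C, rhs, blocks, fixed_names, vc, W, y)


def solve_mme(system: MMESystem, targets=()):
    """Solve the MME; return (solution, sampling variances of targets).

    Targets are (block_name, offset) pairs; the sampling variance is the
    corresponding diagonal element of the inverse coefficient matrix (the
    coefficient matrix already carries 1/sigma2_e, so no rescaling).
    """
    try:
        factor = cho_factor(system.C)
    except np.linalg.LinAlgError as exc:
        raise ValueError("MME coefficient matrix singular; check fixed-effect columns") from exc
    sol = cho_solve(factor, system.rhs)
    variances = {}
    for block, offset in targets:
        j = system.blocks[block].start + offset
        e = np.zeros(len(sol))
        e[j] = 1.0
        variances[(block, offset)] = float(cho_solve(factor, e)[j])
    return sol, variances


# ---------------------------------------------------------------------------
# AI-REML
# ---------------------------------------------------------------------------

def reml_core(
    y,
    X,
    terms,
    init=None,
    tol: float = 1e-8,
    max_iter: int = 200,
    n_em: int = 2,
    floor_frac: float = 1e-6,
):
    """AI-REML for y = Xb + sum_i Z_i u_i + e with u_i ~ N(0, K_i s2_i).

    Starts from an equal split of the phenotypic variance (or ``init``, a
    dict of term name -> value plus 'e'), takes ``n_em`` expectation-
    maximization steps for stability, then average-information updates with
    step halving whenever a step would leave the parameter space or lower
    the restricted likelihood.  Returns a dict with estimates, sampling
    variances (inverse AI at convergence), and diagnostics.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    p = X.shape[1]
    names = [t.name for t in terms]
    vary = float(np.var(y, ddof=1))
    floor = floor_frac * vary
    if init is None:
        theta = {name: vary / (len(terms) + 1) for name in names}
        theta["e"] = vary / (len(terms) + 1)
    else:
        theta = {k: float(v) for k, v in init.items()}

    W = np.hstack([X] + [t.Z for t in terms])
    WtW = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)
    m = W.shape[1]
    blocks = {"fixed": slice(0, p)}
    at = p
    for t in terms:
        blocks[t.name] = slice(at, at + t.q)
        at += t.q

    def evaluate(th):
        """Factorize the MME at th; return the pieces REML needs."""
        se = th["e"]
        C = WtW / se
        for t in terms:
            b = blocks[t.name]
            if t.kinv is None:
                C[b, b] += np.eye(t.q) / th[t.name]
            else:
                C[b, b] += t.kinv / th[t.name]
        rhs = Wty / se
        factor = cho_factor(C)
        sol = cho_solve(factor, rhs)
        logdet_C = 2.0 * np.sum(np.log(np.diag(factor[0])))
        yPy = yty / se - float(rhs @ sol)
        logdet_G = sum(t.q * np.log(th[t.name]) - t.logdet_kinv for t in terms)
        m2ll = n * np.log(se) + logdet_G + logdet_C + yPy
        return {"C": C, "factor": factor, "sol": sol, "m2ll": m2ll, "se": se}

    state = evaluate(theta)
    iterations, converged, delta_norm = 0, False, np.inf
    AI = None
    for iterations in range(1, max_iter + 1):
        Cinv = cho_solve(state["factor"], np.eye(m))
        sol = state["sol"]
        resid = y - W @ sol
        sse = float(resid @ resid)
        Wte = Wty - WtW @ sol

        traces, quads, u_hat = {}, {}, {}
        for t in terms:
            b = blocks[t.name]
            u = sol[b]
            u_hat[t.name] = u
            Cb = Cinv[b, b]
            if t.kinv is None:
                traces[t.name] = float(np.trace(Cb))
                quads[t.name] = float(u @ u)
            else:
                traces[t.name] = float(np.sum(t.kinv * Cb.T))
                quads[t.name] = float(u @ t.kinv @ u)

        se = theta["e"]
        grad = np.empty(len(terms) + 1)
        for k, t in enumerate(terms):
            s2 = theta[t.name]
            grad[k] = -0.5 * ((t.q - traces[t.name] / s2) / s2 - quads[t.name] / s2**2)
        sum_eff = sum((t.q - traces[t.name] / theta[t.name]) for t in terms)
        grad[-1] = -0.5 * ((n - p - sum_eff) / se - sse / se**2)

        # AI matrix via f_i' P f_j with f_i = Z_i u_i / s2_i, f_e = e_hat / s2_e
        Wf = np.empty((m, len(terms) + 1))
        for k, t in enumerate(terms):
            b = blocks[t.name]
            Wf[:, k] = WtW[:, b] @ u_hat[t.name] / theta[t.name]
        Wf[:, -1] = Wte / se
        f_cols = [terms[k].Z @ u_hat[terms[k].name] / theta[terms[k].name]
                  for k in range(len(terms))] + [resid / se]
        F = np.column_stack(f_cols)
        ff = F.T @ F
        CinvWf = cho_solve(state["factor"], Wf)
        PF = ff / se - (Wf.T @ CinvWf) / se**2
        AI = 0.5 * PF
        AI = 0.5 * (AI + AI.T)

        # EM warm-up keeps early steps inside the parameter space
        if iterations <= n_em:
            new = {}
            for t in terms:
                new[t.name] = max((quads[t.name] + traces[t.name]) / t.q, floor)
            tr_wcw = se * (m - sum(traces[t.name] / theta[t.name] for t in terms))
            new["e"] = max((sse + tr_wcw) / n, floor)
        else:
            cur = np.array([theta[nm] for nm in names] + [theta["e"]])
            # active set: components pinned at the zero boundary whose
            # gradient points outward stay fixed at the floor
            active = ~((cur <= floor * (1 + 1e-9)) & (grad < 0))
            step = np.zeros_like(cur)
            Aact = AI[np.ix_(active, active)]
            try:
                step[active] = np.linalg.solve(Aact, grad[active])
            except np.linalg.LinAlgError:
                step[active] = np.linalg.lstsq(Aact, grad[active], rcond=None)[0]
            scale = 1.0
            new = None
            for _ in range(30):
                cand = cur + scale * step
                if (cand >= floor).all() or scale < 1e-6:
                    cand = np.maximum(cand, floor)
                    cand_th = dict(zip(names + ["e"], cand))
                    cand_state = evaluate(cand_th)
                    if cand_state["m2ll"] <= state["m2ll"] + 1e-10 or scale < 1e-6:
                        new = cand_th
                        break
                scale *= 0.5
            if new is None:  # pragma: no cover - exhausted halving
                new = {t.name: max((quads[t.name] + traces[t.name]) / t.q, floor) for t in terms}
                tr_wcw = se * (m - sum(traces[t.name] / theta[t.name] for t in terms))
                new["e"] = max((sse + tr_wcw) / n, floor)

        old = np.array([theta[nm] for nm in names] + [theta["e"]])
        upd = np.array([new[nm] for nm in names] + [new["e"]])
        delta = upd - old
        # components pinned at the zero boundary do not block convergence
        pinned = upd <= floor * (1 + 1e-9)
        delta[pinned] = 0.0
        delta_norm = float(np.linalg.norm(delta) / (np.linalg.norm(old) + 1e-30))
        theta = new
        state = evaluate(theta)
        if delta_norm < tol:
            converged = True
            break

    if not converged:
        raise RuntimeError(
            f"AI-REML did not converge in {max_iter} iterations "
            f"(last scaled update {delta_norm:.3e}); estimates {theta}"
        )
    boundary = [nm for nm in names + ["e"] if theta[nm] <= floor * (1 + 1e-9)]
    try:
        ai_inv = np.linalg.inv(AI)
        sampling = {nm: float(ai_inv[k, k]) for k, nm in enumerate(names + ["e"])}
    except np.linalg.LinAlgError:  # boundary-degenerate AI
        sampling = {nm: float("nan") for nm in names + ["e"]}
    return {
        "variances": theta,
        "sampling_variances": sampling,
        "iterations": iterations,
        "converged": converged,
        "final_update_norm": delta_norm,
        "boundary": boundary,
        "minus2_restricted_ll": state["m2ll"],
    }


def ai_reml(
    phen: PhenotypeTable,
    spec: ModelSpec,
    hinv: RelationshipMatrix,
    het: dict | None = None,
    init: VarianceComponents | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> VarianceComponents:
    """Estimate the four variance components of the repeatability model.

    The model used for estimation never includes a ROH carrier term:
    components are fixed before the scan.
    """
    if spec.carrier:
        raise ValueError("variance estimation precedes the scan; drop the carrier term")
    y, X, fixed_names, terms = build_design(phen, spec, hinv, het=het)
    init_map = None
    if init is not None:
        init_map = {"u": init.sigma2_a, "p": init.sigma2_p, "e": init.sigma2_e}
        if spec.hys:
            init_map["hys"] = init.sigma2_h
    res = reml_core(y, X, terms, init=init_map, tol=tol, max_iter=max_iter)
    th, sv = res["variances"], res["sampling_variances"]
    return VarianceComponents(
        sigma2_a=th["u"],
        sigma2_p=th["p"],
        sigma2_h=th.get("hys", 0.0),
        sigma2_e=th["e"],
        sampling_variances={
            "sigma2_a": sv["u"],
            "sigma2_p": sv["p"],
            "sigma2_h": sv.get("hys", float("nan")),
            "sigma2_e": sv["e"],
        },
        iterations=res["iterations"],
        converged=res["converged"],
        final_update_norm=res["final_update_norm"],
        boundary=res["boundary"],
    )


def fit_het_covariate(
    phen: PhenotypeTable,
    spec: ModelSpec,
    hinv: RelationshipMatrix,
    vc: VarianceComponents,
    het: dict,
) -> CovariateEstimate:
    """Heterozygosity slope d (piglets per percent) with one-sided p.

    The alternative is d > 0: more heterozygosity, larger litters — the
    signature of inbreeding depression.
    """
    spec = ModelSpec(trait=spec.trait, het_covariate=True, carrier=False,
                     hys=spec.hys, df=spec.df)
    system = build_mme(phen, spec, hinv, vc, het=het)
    j = system.fixed_names.index("het_percent")
    sol, var = solve_mme(system, targets=[("fixed", j)])
    d = float(sol[system.blocks["fixed"].start + j])
    se = float(np.sqrt(var[("fixed", j)]))
    return CovariateEstimate(d, se, one_sided_p(d, se, "greater", df=spec.df))
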