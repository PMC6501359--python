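"""All-subsets PGLS model selection with AICc and conditional averaging.

Every subset of the main effects (plus any interaction whose two main
effects are both present — the marginality constraint) is fitted by PGLS
with profile-ML lambda. Models are ranked by the small-sample Akaike
criterion

    AICc = -2 l + 2k + 2k(k+1)/(n - k - 1),

where k counts the regression coefficients plus one residual variance
(lambda is not counted, matching the caper/MuMIn convention the comparative
literature reports). Models within a Delta-AICc threshold (default 4) of
the best form the candidate set; Akaike weights renormalized over that set
give per-variable importances and conditional model-averaged coefficients,
with unconditional standard errors per Burnham & Anderson:

    SE_uncond = sum_m w'_m * sqrt(SE_m^2 + (beta_m - beta_bar)^2).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trees import Phylogeny, align
from .pgls import PGLSFit, pgls_fit

logger = logging.getLogger(__name__)

__all__ = [
    "aicc", "akaike_weights", "enumerate_models",
    "ModelRecord", "ModelSet", "AveragedCoefficient",
    "dredge", "split_analysis",
]


def aicc(loglik: float, k: int, n: int) -> float:
    """Corrected Akaike information criterion."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined: n - k - 1 = {n - k - 1} <= 0")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    """exp(-Delta/2) normalized; computed stably by subtracting the min."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0 or not np.any(np.isfinite(a)):
        raise ValueError("need at least one finite AICc value")
    delta = a - np.nanmin(a)
    w = np.exp(-delta / 2.0)
    w[~np.isfinite(a)] = 0.0
    return w / w.sum()


def enumerate_models(variables: list, interactions: list | None = None) -> list:
    """All subsets of main effects, with marginality-respecting interactions.

    Returns a list of ``(mains, inters)`` tuples, mains/inters in the input
    order; includes the intercept-only model ``((), ())``.
    """
    if not variables:
        raise ValueError("need at least one candidate variable")
    interactions = [tuple(t.split(":")) if isinstance(t, str) else tuple(t)
                    for t in (interactions or [])]
    for a, b in interactions:
        if a not in variables or b not in variables:
            raise ValueError(f"interaction {a}:{b} references unknown main effect")
    models = []
    for r in range(len(variables) + 1):
        for mains in itertools.combinations(variables, r):
            ok = [t for t in interactions if t[0] in mains and t[1] in mains]
            for s in range(len(ok) + 1):
                for inters in itertools.combinations(ok, s):
                    models.append((mains, inters))
    return models


def _term_names(mains, inters):
    return list(mains) + [f"{a}:{b}" for a, b in inters]


@dataclass
class ModelRecord:
    mains: tuple
    interactions: tuple
    fit: PGLSFit | None
    aicc: float
    delta: float = np.nan
    weight: float = np.nan
    in_candidate_set: bool = False
    error: str | None = None

    @property
    def label(self) -> str:
        return " + ".join(_term_names(self.mains, self.interactions)) or "(intercept)"


@dataclass
class ModelSet:
    records: list                     # ranked by AICc (failed fits last)
    delta_threshold: float
    n_species: int

    @property
    def candidates(self) -> list:
        return [r for r in self.records if r.in_candidate_set]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "model": r.label,
                "k": r.fit.k_coefficients + 1 if r.fit else np.nan,
                "AICc": r.aicc,
                "delta_AICc": r.delta,
                "weight": r.weight,
                "R2": r.fit.r_squared if r.fit else np.nan,
                "lambda": r.fit.lambda_hat if r.fit else np.nan,
                "candidate": r.in_candidate_set,
                "error": r.error or "",
            })
        return pd.DataFrame(rows)


@dataclass
class AveragedCoefficient:
    variable: str
    estimate: float
    unconditional_se: float
    importance: float


def _rank_key(rec: ModelRecord):
    k = rec.fit.k_coefficients if rec.fit else np.inf
    return (rec.aicc, k, _term_names(rec.mains, rec.interactions))


def dredge(tree: Phylogeny, traits: pd.DataFrame, response: str,
           variables: list, interactions: list | None = None,
           delta_threshold: float = 4.0,
           renormalize_importance: bool = True):
    """Fit, rank and average all marginality-respecting predictor subsets.

    ``tree``/``traits`` must already be aligned (trees.align) on the union
    of response and variables. Returns ``(ModelSet, [AveragedCoefficient])``.
    With ``renormalize_importance`` (default) averaging weights are
    renormalized within the candidate set; otherwise the full-enumeration
    weights are used directly.
    """
    models = enumerate_models(variables, interactions)
    records = []
    n = tree.n_tips
    for mains, inters in models:
        try:
            fit = pgls_fit(tree, traits, response, list(mains), list(inters))
            a = aicc(fit.loglik, fit.k_coefficients + 1, n)
            records.append(ModelRecord(mains, inters, fit, a))
        except Exception as e:  # logged, excluded from weights
            logger.warning("model %s failed: %s", _term_names(mains, inters), e)
            records.append(ModelRecord(mains, inters, None, np.inf, error=str(e)))
    if all(r.fit is None for r in records):
        raise RuntimeError("every candidate model failed to fit")

    records.sort(key=_rank_key)
    aiccs = np.array([r.aicc for r in records])
    weights = akaike_weights(aiccs)
    best = np.nanmin(aiccs)
    for r, w in zip(records, weights):
        r.delta = r.aicc - best
        r.weight = float(w)
        r.in_candidate_set = bool(np.isfinite(r.aicc) and r.delta <= delta_threshold)
    mset = ModelSet(records=records, delta_threshold=delta_threshold, n_species=n)

    cand = mset.candidates
    if renormalize_importance:
        total = sum(r.weight for r in cand)
        w_cand = {id(r): r.weight / total for r in cand}
    else:
        w_cand = {id(r): r.weight for r in cand}

    all_terms = ["intercept"] + list(variables) + \
        [f"{a}:{b}" for a, b in (tuple(t.split(":")) if isinstance(t, str) else tuple(t)
                                 for t in (interactions or []))]
    averaged = []
    for term in all_terms:
        sub = [r for r in cand if term in r.fit.terms]
        if not sub:
            continue
        imp = sum(w_cand[id(r)] for r in sub)
        wsub = np.array([w_cand[id(r)] for r in sub])
        wsub = wsub / wsub.sum()
        betas = np.array([r.fit.beta[r.fit.terms.index(term)] for r in sub])
        ses = np.array([r.fit.se[r.fit.terms.index(term)] for r in sub])
        est = float(wsub @ betas)
        se_u = float(wsub @ np.sqrt(ses ** 2 + (betas - est) ** 2))
        averaged.append(AveragedCoefficient(term, est, se_u, float(imp)))
    return mset, averaged


def averaged_frame(averaged: list) -> pd.DataFrame:
    return pd.DataFrame({
        "variable": [a.variable for a in averaged],
        "estimate": [a.estimate for a in averaged],
        "se": [a.unconditional_se for a in averaged],
        "importance": [a.importance for a in averaged],
    })


def split_analysis(tree: Phylogeny, traits: pd.DataFrame, response: str,
                   split_variable: str, variables_by_level: dict,
                   interactions_by_level: dict | None = None,
                   delta_threshold: float = 4.0):
    """Run dredge independently within each level of a binary variable.

    ``variables_by_level`` maps level (0/1) -> candidate variable list for
    that stratum (the split variable itself must not appear). Returns a dict
    level -> (ModelSet, averaged list, n_species).
    """
    interactions_by_level = interactions_by_level or {}
    levels = sorted(pd.unique(traits[split_variable]))
    if set(levels) != {0, 1}:
        raise ValueError(f"split variable {split_variable!r} must be binary 0/1, got {levels}")
    out = {}
    for level in (0, 1):
        varlist = variables_by_level[level]
        if split_variable in varlist:
            raise ValueError("split variable cannot be a candidate within its own stratum")
        sub = traits.loc[traits[split_variable] == level]
        kmax = 1 + len(varlist) + len(interactions_by_level.get(level, []))
        if len(sub) < kmax + 2:
            raise ValueError(
                f"stratum {split_variable}={level} has {len(sub)} species; "
                f"cannot support {kmax} coefficients"
            )
        subtree, subtab = align(tree, sub, [response] + list(varlist))
        logger.info("stratum %s=%d: %d species", split_variable, level, subtree.n_tips)
        mset, avg = dredge(subtree, subtab, response, list(varlist),
                           interactions_by_level.get(level), delta_threshold)
        out[level] = (mset, avg, subtree.n_tips)
    return out
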