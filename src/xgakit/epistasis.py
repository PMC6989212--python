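"""Multiplicative genetic-effects model and high-order interaction search.

Under the multiplicative null, the resistance of a multi-knockout strain
is the product of its component single-knockout resistances; writing
log-resistance effects l_i and interaction terms epsilon_J (the log-ratio
of observed to multiplicatively expected resistance for knockout subset
J), predicted resistance is

    r_hat = exp( sum_i l_i + sum_J epsilon_J + c_d + b_p )

with a per-drug offset c_d and per-plate biases b_p. The model is fit as
a GLM with Gaussian error and log link (interactions are products of
knockout indicators); per-term significance uses Wald chi-square tests,
which coincide with Type-III marginal tests for these single-degree-of-
freedom terms.

The search protocol: marginal association starts from all single-knockout
terms and eliminates the least significant until every survivor passes
p <= 0.05/16; stepwise expansion then proposes all n-way interactions
among genes in the current model (n = 2..5), discards proposals with
p > 0.05, and finally re-eliminates until every term passes p <= 0.05/k,
where k counts all 1-5-gene combinations among the marginal genes.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import mannwhitneyu

Term = tuple[int, ...]  # sorted locus indices; singletons are l terms


def expected_multiplicative(r_singles) -> float:
    """Expected combination resistance: product of single-knockout r's."""
    r = np.asarray(r_singles, dtype=float)
    if (r <= 0).any():
        raise ValueError("single-knockout resistances must be positive")
    return float(np.prod(r))


def epsilon(observed: float, expected: float) -> float:
    """Interaction term: log-ratio of observed to expected resistance."""
    if observed <= 0 or expected <= 0:
        raise ValueError("resistances must be positive")
    return float(np.log(observed / expected))


# ---------------------------------------------------------------------------
# GLM core


@dataclass
class EpistasisModel:
    """Fitted genetic-effects model for one drug."""

    drug: str
    coefficients: pd.DataFrame  # term, order, estimate, se, p, stage
    offset: float  # c_d
    plate_bias: dict = field(default_factory=dict)  # b_p
    family: str = "gaussian_log"
    thresholds: dict = field(default_factory=dict)

    @property
    def terms(self) -> list[Term]:
        return [t for t in self.coefficients["term"]]

    def interaction_terms(self) -> list[Term]:
        return [t for t in self.terms if len(t) > 1]

    def predict_log(self, masks: np.ndarray, plates=None) -> np.ndarray:
        masks = np.atleast_2d(np.asarray(masks, dtype=float))
        lp = np.full(masks.shape[0], self.offset)
        for rec in self.coefficients.itertuples(index=False):
            lp += rec.estimate * np.prod(masks[:, list(rec.term)], axis=1)
        if plates is not None and self.plate_bias:
            lp += np.array([self.plate_bias.get(p, 0.0) for p in plates])
        return lp

    def predict(self, masks, plates=None) -> np.ndarray:
        return np.exp(self.predict_log(masks, plates))


def _term_name(term: Term) -> str:
    return "k" + ":".join(str(i) for i in term)


def _build_design(
    masks: np.ndarray, terms: list[Term], plates=None
) -> tuple[pd.DataFrame, list[str]]:
    masks = np.atleast_2d(np.asarray(masks, dtype=float))
    cols = {"const": np.ones(masks.shape[0])}
    plate_cols: list[str] = []
    if plates is not None:
        levels = sorted(pd.unique(np.asarray(plates)))
        for p in levels[1:]:  # first level absorbed by the intercept
            name = f"plate_{p}"
            cols[name] = (np.asarray(plates) == p).astype(float)
            plate_cols.append(name)
    for term in terms:
        cols[_term_name(term)] = np.prod(masks[:, list(term)], axis=1)
    return pd.DataFrame(cols), plate_cols


class RankDeficientDesignError(ValueError):
    def __init__(self, aliased: list[str]):
        self.aliased = aliased
        super().__init__(f"design matrix is rank deficient; aliased terms: {aliased}")


def _check_rank(X: pd.DataFrame) -> None:
    from scipy.linalg import qr

    arr = X.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        _, R, piv = qr(arr, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(arr.shape) * np.finfo(float).eps
        aliased = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] < tol]
        aliased += [X.columns[p] for p in piv[len(diag) :]]
        raise RankDeficientDesignError(aliased)


def fit_glm(
    y: np.ndarray,
    masks: np.ndarray,
    terms: list[Term],
    plates=None,
    family: str = "gaussian_log",
    drug: str = "",
    stage: str = "fit",
) -> EpistasisModel:
    """Fit the exp-linear genetic-effects model by maximum likelihood.

    ``family='gaussian_log'`` (default) fits Gaussian error with a log
    link on the resistance scale, matching the epsilon definition on
    observed r; ``family='lognormal'`` fits OLS on log(r) instead.
    """
    y = np.asarray(y, dtype=float)
    if (y <= 0).any():
        raise ValueError("responses must be positive (apply the 1e-10 floor first)")
    terms = [tuple(sorted(t)) for t in terms]
    X, plate_cols = _build_design(masks, terms, plates)
    _check_rank(X)
    if family == "gaussian_log":
        beta0, *_ = np.linalg.lstsq(X.to_numpy(), np.log(y), rcond=None)
        res = sm.GLM(
            y, X, family=sm.families.Gaussian(sm.families.links.Log())
        ).fit(start_params=beta0, maxiter=300)
    elif family == "lognormal":
        res = sm.OLS(np.log(y), X).fit()
    else:
        raise ValueError(f"unknown family {family!r}")
    coefs = []
    for term in terms:
        name = _term_name(term)
        coefs.append(
            {
                "term": term,
                "order": len(term),
                "estimate": float(res.params[name]),
                "se": float(res.bse[name]),
                "p": float(res.pvalues[name]),
                "stage": stage,
            }
        )
    plate_bias = {
        c.removeprefix("plate_"): float(res.params[c]) for c in plate_cols
    }
    return EpistasisModel(
        drug=drug,
        coefficients=pd.DataFrame(
            coefs, columns=["term", "order", "estimate", "se", "p", "stage"]
        ),
        offset=float(res.params["const"]),
        plate_bias=plate_bias,
        family=family,
    )


# ---------------------------------------------------------------------------
# term selection


def _drop_worst(coefs: pd.DataFrame, threshold: float) -> Term | None:
    """Term to eliminate: highest p above threshold; ties broken toward the
    larger subset, then lexically (deterministic)."""
    failing = coefs[coefs["p"] > threshold]
    if failing.empty:
        return None
    pmax = failing["p"].max()
    ties = failing[failing["p"] == pmax]
    ordered = sorted(ties["term"], key=lambda t: (-len(t), t))
    return ordered[0]


def marginal_association(
    y: np.ndarray,
    masks: np.ndarray,
    plates=None,
    n_loci: int | None = None,
    alpha: float = 0.05,
    family: str = "gaussian_log",
    drug: str = "",
) -> tuple[list[int], EpistasisModel | None]:
    """Loci with reproducible single-knockout effects.

    Starts from all single-knockout terms (no interactions) and performs
    stepwise elimination of the highest-p term until every survivor passes
    the Bonferroni level alpha / n_loci.
    """
    y = np.asarray(y, dtype=float)
    masks = np.atleast_2d(np.asarray(masks))
    if n_loci is None:
        n_loci = masks.shape[1]
    if np.var(y) == 0:
        return [], None
    threshold = alpha / n_loci
    terms: list[Term] = [(i,) for i in range(masks.shape[1])]
    model = None
    while terms:
        model = fit_glm(y, masks, terms, plates, family, drug, stage="marginal")
        worst = _drop_worst(model.coefficients, threshold)
        if worst is None:
            return sorted(t[0] for t in terms), model
        terms = [t for t in terms if t != worst]
    return [], model


def n_combinations(n_genes: int, max_order: int = 5) -> int:
    """Count of all 1..max_order-gene combinations among n genes."""
    return sum(math.comb(n_genes, i) for i in range(1, min(max_order, n_genes) + 1))


def stepwise_expansion(
    y: np.ndarray,
    masks: np.ndarray,
    plates=None,
    max_order: int = 5,
    alpha: float = 0.05,
    expand_alpha: float = 0.05,
    family: str = "gaussian_log",
    drug: str = "",
) -> EpistasisModel:
    """Full interaction search: marginal -> expansion -> final elimination.

    At each order n, all n-way interactions among genes currently in the
    model are proposed; terms with p > expand_alpha are discarded in one
    pass. The final elimination threshold is alpha / k with k the number
    of all 1-5-gene combinations among the marginally associated genes.
    """
    y = np.asarray(y, dtype=float)
    masks = np.atleast_2d(np.asarray(masks))
    marginal, model = marginal_association(
        y, masks, plates, masks.shape[1], alpha, family, drug
    )
    if not marginal:
        return EpistasisModel(
            drug=drug,
            coefficients=pd.DataFrame(
                columns=["term", "order", "estimate", "se", "p", "stage"]
            ),
            offset=float(np.log(np.mean(y))),
            family=family,
            thresholds={"marginal": alpha / masks.shape[1]},
        )
    terms: list[Term] = [(i,) for i in marginal]
    for order in range(2, max_order + 1):
        genes = sorted({g for t in terms for g in t})
        if len(genes) < order:
            break
        proposals = [
            c for c in itertools.combinations(genes, order) if c not in set(terms)
        ]
        if not proposals:
            continue
        model = fit_glm(y, masks, terms + proposals, plates, family, drug, stage=f"expand{order}")
        kept = model.coefficients[model.coefficients["p"] <= expand_alpha]
        terms = [t for t in kept["term"]]
        if not terms:
            break
    k = n_combinations(len(marginal), max_order)
    threshold = alpha / k
    final = None
    while terms:
        final = fit_glm(y, masks, terms, plates, family, drug, stage="final")
        worst = _drop_worst(final.coefficients, threshold)
        if worst is None:
            break
        terms = [t for t in terms if t != worst]
    if final is None or not terms:
        final = EpistasisModel(
            drug=drug,
            coefficients=pd.DataFrame(
                columns=["term", "order", "estimate", "se", "p", "stage"]
            ),
            offset=float(np.log(np.mean(y))),
            family=family,
        )
    final.thresholds = {
        "marginal": alpha / masks.shape[1],
        "expand": expand_alpha,
        "final": threshold,
        "k": k,
        "marginal_genes": marginal,
    }
    return final


# ---------------------------------------------------------------------------
# grouped combinatorial profiles


@dataclass
class GroupProfile:
    """Five-locus (or fewer) combinatorial resistance summary.

    ``groups``: one row per focal genotype class (2^k rows) with mean
    resistance and strain count. ``edges``: every pair of groups differing
    at exactly one focal locus, with a two-sided Mann-Whitney U test and
    multiplicity-adjusted p. ``wheel``: cumulative-knockout paths (one row
    per step of each locus-order permutation) for wheel-style displays.
    """

    focal_loci: list[int]
    groups: pd.DataFrame
    edges: pd.DataFrame
    wheel: pd.DataFrame


def group_profiles(
    values: pd.Series,
    masks: pd.DataFrame,
    focal_loci: list[int],
    adjust: str = "bonferroni",
) -> GroupProfile:
    """Partition strains by focal-locus genotype and test adjacent groups.

    ``values`` holds per-strain resistance for one drug; ``masks`` the
    knockout masks (strains x loci, index-aligned with values). Strains
    are assigned to one of 2^k groups by their focal genotype, averaging
    over all other loci.
    """
    if len(focal_loci) > 5:
        raise ValueError("at most 5 focal loci")
    k = len(focal_loci)
    sub = masks.loc[values.index, :].iloc[:, focal_loci].astype(int).to_numpy()
    keys = [tuple(row) for row in sub]
    by_group: dict[tuple, np.ndarray] = {}
    for key, val in zip(keys, values.to_numpy(dtype=float)):
        by_group.setdefault(key, []).append(val)
    all_groups = list(itertools.product((0, 1), repeat=k))
    group_rows = []
    for gkey in all_groups:
        vals = np.asarray(by_group.get(gkey, []), dtype=float)
        group_rows.append(
            {
                "genotype": gkey,
                "n_knockouts": sum(gkey),
                "n_strains": len(vals),
                "mean_resistance": float(vals.mean()) if len(vals) else np.nan,
            }
        )
    groups = pd.DataFrame(group_rows)

    edge_rows = []
    for gkey in all_groups:
        for pos in range(k):
            if gkey[pos] == 1:
                continue
            other = tuple(1 if i == pos else b for i, b in enumerate(gkey))
            a = np.asarray(by_group.get(gkey, []), dtype=float)
            b = np.asarray(by_group.get(other, []), dtype=float)
            row = {
                "from": gkey,
                "to": other,
                "locus": focal_loci[pos],
                "skipped": len(a) == 0 or len(b) == 0,
            }
            if not row["skipped"]:
                stat = mannwhitneyu(a, b, alternative="two-sided")
                row.update(
                    u=float(stat.statistic),
                    p=float(stat.pvalue),
                    delta_mean=float(b.mean() - a.mean()),
                    lower_mean="to" if b.mean() < a.mean() else "from",
                )
            edge_rows.append(row)
    edges = pd.DataFrame(edge_rows)
    tested = edges[~edges["skipped"]]
    if len(tested):
        if adjust == "bonferroni":
            edges.loc[tested.index, "p_adj"] = np.minimum(tested["p"] * len(tested), 1.0)
        else:
            from statsmodels.stats.multitest import multipletests

            edges.loc[tested.index, "p_adj"] = multipletests(tested["p"], method=adjust)[1]

    means = {tuple(r.genotype): r.mean_resistance for r in groups.itertuples(index=False)}
    wheel_rows = []
    for path_id, order in enumerate(itertools.permutations(range(k))):
        state = [0] * k
        for step, pos in enumerate(order):
            state[pos] = 1
            gkey = tuple(state)
            wheel_rows.append(
                {
                    "path": path_id,
                    "step": step + 1,
                    "added_locus": focal_loci[pos],
                    "genotype": gkey,
                    "mean_resistance": means.get(gkey, np.nan),
                }
            )
    wheel = pd.DataFrame(wheel_rows)
    return GroupProfile(focal_loci=list(focal_loci), groups=groups, edges=edges, wheel=wheel)
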