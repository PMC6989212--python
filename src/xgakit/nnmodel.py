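"""Interpretable genotype -> transporter activity -> drug resistance network.

The model is a structured three-layer sigmoid network. The input layer is
the 0/1 gene-presence genotype G; the middle layer holds one "activity"
node per transporter, gated to exactly 0 when its gene is knocked out;
the output layer is normalized resistance per drug. Genotype->activity
links carry signed "influence" weights I (no self-influence), and
activity->resistance links carry non-negative "efflux" weights E, so that
activity x efflux is the clearance each transporter contributes against
each drug. L1 regularization (coefficient lambda) is applied to I and to
the activity offsets B_A, which drives extraneous influence links to zero
while leaving the efflux layer free.

Training minimizes mean squared error on normalized resistance by
mini-batch Adam with analytically derived gradients; E is kept
non-negative by projection after every step. Multiple independent runs
are merged (mean with a |Z| reproducibility filter, or median without),
and each surviving weight is then tested for predictive value by a paired
rank test on squared residuals with and without the weight.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import wilcoxon


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite during optimization."""


def sigmoid(x: np.ndarray) -> np.ndarray:
    return expit(x)


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class NetworkParams:
    """Weights of the two-layer (genotype->activity->resistance) network.

    ``influence[i, j]`` is the effect of gene i's presence on activity j;
    the diagonal is structurally zero. ``efflux[j, d] >= 0`` is transporter
    j's efflux capacity against drug d. ``always_present`` appends that many
    trailing genotype slots hard-wired to 1 (the "always-present factor"
    extension for resistance factors outside the targeted gene set).
    """

    influence: np.ndarray  # (L, L)
    efflux: np.ndarray  # (L, D)
    activity_bias: np.ndarray  # (L,)
    drug_bias: np.ndarray  # (D,)
    lam: float = 0.0
    always_present: int = 0
    locus_names: list | None = None
    drug_names: list | None = None

    def __post_init__(self) -> None:
        self.influence = np.asarray(self.influence, dtype=float)
        self.efflux = np.asarray(self.efflux, dtype=float)
        self.activity_bias = np.asarray(self.activity_bias, dtype=float)
        self.drug_bias = np.asarray(self.drug_bias, dtype=float)
        L = self.influence.shape[0]
        if self.influence.shape != (L, L) or self.efflux.shape[0] != L:
            raise ValueError("inconsistent parameter dimensions")
        if self.activity_bias.shape != (L,) or self.drug_bias.shape != (self.efflux.shape[1],):
            raise ValueError("inconsistent bias dimensions")
        self.apply_constraints()

    # -- structure ---------------------------------------------------------
    @property
    def n_slots(self) -> int:
        """Total genotype slots including always-present extras."""
        return self.influence.shape[0]

    @property
    def n_loci(self) -> int:
        """Targeted (knockout-able) loci."""
        return self.n_slots - self.always_present

    @property
    def n_drugs(self) -> int:
        return self.efflux.shape[1]

    def copy(self) -> "NetworkParams":
        return replace(
            self,
            influence=self.influence.copy(),
            efflux=self.efflux.copy(),
            activity_bias=self.activity_bias.copy(),
            drug_bias=self.drug_bias.copy(),
        )

    def arrays(self) -> dict[str, np.ndarray]:
        return {
            "influence": self.influence,
            "efflux": self.efflux,
            "activity_bias": self.activity_bias,
            "drug_bias": self.drug_bias,
        }

    def l1_names(self) -> tuple[str, ...]:
        return ("influence", "activity_bias")

    def apply_constraints(self) -> None:
        """Structural zeros (no self-influence) and E >= 0 projection."""
        np.fill_diagonal(self.influence, 0.0)
        np.clip(self.efflux, 0.0, None, out=self.efflux)

    def structural_zero(self, name: str, idx: tuple) -> bool:
        return name == "influence" and idx[0] == idx[1]

    def canonicalize(self) -> None:
        """No-op: the two-layer parameterization has no gauge freedom."""

    # -- forward / backward -------------------------------------------------
    def _extend(self, presence: np.ndarray) -> np.ndarray:
        G = np.atleast_2d(np.asarray(presence, dtype=float))
        if G.shape[1] == self.n_loci and self.always_present:
            G = np.hstack([G, np.ones((G.shape[0], self.always_present))])
        elif G.shape[1] == self.n_slots:
            G = G.copy()
            if self.always_present:
                G[:, self.n_loci :] = 1.0  # fixed slots can never be knocked out
        else:
            raise ValueError(
                f"genotype width {G.shape[1]} matches neither {self.n_loci} loci "
                f"nor {self.n_slots} slots"
            )
        return G

    def forward(self, presence: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (activities A, predicted resistances R_hat), both in [0, 1]."""
        G = self._extend(presence)
        A = sigmoid(G @ self.influence + self.activity_bias) * G
        R = sigmoid(A @ self.efflux + self.drug_bias)
        return A, R

    def predict(self, presence: np.ndarray) -> np.ndarray:
        return self.forward(presence)[1]

    def loss_grads(self, presence: np.ndarray, r: np.ndarray):
        """MSE (without the L1 term) and analytic gradients of MSE + L1."""
        G = self._extend(presence)
        ZA = G @ self.influence + self.activity_bias
        S = sigmoid(ZA)
        A = S * G
        ZR = A @ self.efflux + self.drug_bias
        R = sigmoid(ZR)
        resid = R - r
        n_obs = resid.size
        mse = float(np.mean(resid**2))

        dZR = (2.0 / n_obs) * resid * R * (1.0 - R)
        dE = A.T @ dZR
        dBd = dZR.sum(axis=0)
        dA = dZR @ self.efflux.T
        dZA = dA * G * S * (1.0 - S)
        dI = G.T @ dZA
        np.fill_diagonal(dI, 0.0)
        dBA = dZA.sum(axis=0)
        if self.lam:
            dI += self.lam * np.sign(self.influence)
            dBA += self.lam * np.sign(self.activity_bias)
        return mse, {"influence": dI, "efflux": dE, "activity_bias": dBA, "drug_bias": dBd}


@dataclass
class ThreeLayerParams:
    """Single-activity network with a hidden influence mediator.

    The genotype is restricted to ``k`` focal loci; a single activity node
    (index ``focal``) receives direct influences I1 from the other loci
    plus a weighted input from a mediator node A' which itself integrates
    indirect influences I2 from the loci. Resistance is predicted from the
    focal activity alone via non-negative efflux weights.
    """

    direct: np.ndarray  # I1, (k,), focal entry structurally 0
    indirect: np.ndarray  # I2, (k,), focal entry structurally 0
    mediator_bias: float
    mediator_weight: float  # A' -> focal activity (not regularized)
    activity_bias: float
    efflux: np.ndarray  # (D,), >= 0
    drug_bias: np.ndarray  # (D,)
    lam: float = 0.0
    focal: int = 0

    def __post_init__(self) -> None:
        self.direct = np.asarray(self.direct, dtype=float)
        self.indirect = np.asarray(self.indirect, dtype=float)
        self.efflux = np.atleast_1d(np.asarray(self.efflux, dtype=float))
        self.drug_bias = np.atleast_1d(np.asarray(self.drug_bias, dtype=float))
        self._scalars = {"mediator_bias", "mediator_weight", "activity_bias"}
        self.apply_constraints()

    @property
    def n_loci(self) -> int:
        return self.direct.shape[0]

    def copy(self) -> "ThreeLayerParams":
        return replace(
            self,
            direct=self.direct.copy(),
            indirect=self.indirect.copy(),
            efflux=self.efflux.copy(),
            drug_bias=self.drug_bias.copy(),
        )

    def arrays(self) -> dict[str, np.ndarray]:
        # scalars are exposed as 0-d-like views via 1-element arrays at update
        # time; the trainer special-cases them through get/set below.
        return {
            "direct": self.direct,
            "indirect": self.indirect,
            "efflux": self.efflux,
            "drug_bias": self.drug_bias,
            "mediator_bias": np.array([self.mediator_bias]),
            "mediator_weight": np.array([self.mediator_weight]),
            "activity_bias": np.array([self.activity_bias]),
        }

    def set_array(self, name: str, value: np.ndarray) -> None:
        if name in self._scalars:
            setattr(self, name, float(np.asarray(value).ravel()[0]))
        else:
            getattr(self, name)[...] = value

    def l1_names(self) -> tuple[str, ...]:
        return ("direct", "indirect", "mediator_bias", "activity_bias")

    def apply_constraints(self) -> None:
        self.direct[self.focal] = 0.0
        self.indirect[self.focal] = 0.0
        np.clip(self.efflux, 0.0, None, out=self.efflux)

    def structural_zero(self, name: str, idx: tuple) -> bool:
        return name in ("direct", "indirect") and idx[0] == self.focal

    def canonicalize(self) -> None:
        """Resolve the mediator sign symmetry toward mediator_weight >= 0.

        (w, I2, b2, B_A) and (-w, -I2, -b2, B_A + w) define the same
        function, since sigmoid(-x) = 1 - sigmoid(x); independent training
        runs land in either branch, which would make element-wise merging
        meaningless. Mapping every run to the w >= 0 branch fixes that.
        """
        if self.mediator_weight < 0:
            self.activity_bias += self.mediator_weight
            self.mediator_weight = -self.mediator_weight
            self.indirect[...] = -self.indirect
            self.mediator_bias = -self.mediator_bias
        self.apply_constraints()

    def _mediator(self, G: np.ndarray) -> np.ndarray:
        return sigmoid(G @ self.indirect + self.mediator_bias)

    def focal_activity(self, presence: np.ndarray, gated: bool = False) -> np.ndarray:
        G = np.atleast_2d(np.asarray(presence, dtype=float))
        z = G @ self.direct + self.mediator_weight * self._mediator(G) + self.activity_bias
        act = sigmoid(z)
        return act * G[:, self.focal] if gated else act

    def forward(self, presence: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        G = np.atleast_2d(np.asarray(presence, dtype=float))
        A = self.focal_activity(G, gated=True)
        R = sigmoid(A[:, None] * self.efflux[None, :] + self.drug_bias)
        return A, R

    def predict(self, presence: np.ndarray) -> np.ndarray:
        return self.forward(presence)[1]

    def loss_grads(self, presence: np.ndarray, r: np.ndarray):
        G = np.atleast_2d(np.asarray(presence, dtype=float))
        zp = G @ self.indirect + self.mediator_bias
        Ap = sigmoid(zp)
        z = G @ self.direct + self.mediator_weight * Ap + self.activity_bias
        S = sigmoid(z)
        gate = G[:, self.focal]
        A = S * gate
        ZR = A[:, None] * self.efflux[None, :] + self.drug_bias
        R = sigmoid(ZR)
        resid = R - np.atleast_2d(r)
        n_obs = resid.size
        mse = float(np.mean(resid**2))

        dZR = (2.0 / n_obs) * resid * R * (1.0 - R)
        dE = (dZR * A[:, None]).sum(axis=0)
        dBd = dZR.sum(axis=0)
        dA = (dZR * self.efflux[None, :]).sum(axis=1)
        dz = dA * gate * S * (1.0 - S)
        d_direct = G.T @ dz
        d_ab = dz.sum()
        d_w = float((dz * Ap).sum())
        dzp = dz * self.mediator_weight * Ap * (1.0 - Ap)
        d_indirect = G.T @ dzp
        d_mb = dzp.sum()
        d_direct[self.focal] = 0.0
        d_indirect[self.focal] = 0.0
        if self.lam:
            d_direct += self.lam * np.sign(self.direct)
            d_indirect += self.lam * np.sign(self.indirect)
            d_mb += self.lam * np.sign(self.mediator_bias)
            d_ab += self.lam * np.sign(self.activity_bias)
        return mse, {
            "direct": d_direct,
            "indirect": d_indirect,
            "efflux": dE,
            "drug_bias": dBd,
            "mediator_bias": np.array([d_mb]),
            "mediator_weight": np.array([d_w]),
            "activity_bias": np.array([d_ab]),
        }


def _set_array(params, name: str, value: np.ndarray) -> None:
    if hasattr(params, "set_array"):
        params.set_array(name, value)
    else:
        getattr(params, name)[...] = value


# ---------------------------------------------------------------------------
# construction helpers


def make_params(
    n_loci: int,
    n_drugs: int,
    rng: np.random.Generator | None = None,
    lam: float = 5e-4,
    always_present: int = 0,
    locus_names: list | None = None,
    drug_names: list | None = None,
) -> NetworkParams:
    """Fresh two-layer parameters; fan-balanced uniform init when rng given.

    Efflux weights start at |init| so the non-negativity constraint is
    satisfied from the first step.
    """
    L = n_loci + always_present
    if rng is None:
        I = np.zeros((L, L))
        E = np.zeros((L, n_drugs))
    else:
        lim_i = np.sqrt(6.0 / (2 * L))
        lim_e = np.sqrt(6.0 / (L + n_drugs))
        I = rng.uniform(-lim_i, lim_i, size=(L, L))
        E = np.abs(rng.uniform(-lim_e, lim_e, size=(L, n_drugs)))
    return NetworkParams(
        influence=I,
        efflux=E,
        activity_bias=np.zeros(L),
        drug_bias=np.zeros(n_drugs),
        lam=lam,
        always_present=always_present,
        locus_names=locus_names,
        drug_names=drug_names,
    )


def extend_always_present_factor(base: NetworkParams) -> NetworkParams:
    """Add one genotype slot fixed at 1, with its own influences, offset and
    efflux row; existing weights are preserved and the new ones start at 0."""
    L, D = base.n_slots, base.n_drugs
    I = np.zeros((L + 1, L + 1))
    I[:L, :L] = base.influence
    E = np.zeros((L + 1, D))
    E[:L] = base.efflux
    return NetworkParams(
        influence=I,
        efflux=E,
        activity_bias=np.append(base.activity_bias, 0.0),
        drug_bias=base.drug_bias.copy(),
        lam=base.lam,
        always_present=base.always_present + 1,
        locus_names=base.locus_names,
        drug_names=base.drug_names,
    )


def build_three_layer(
    n_focal: int,
    focal: int,
    n_drugs: int = 1,
    rng: np.random.Generator | None = None,
    lam: float = 1e-5,
) -> ThreeLayerParams:
    """Mediator model over ``n_focal`` loci with one focal activity node.

    Default lambda is the less restrictive 1e-5 used for mediator fits;
    merging for this architecture should use median without the Z filter.
    """
    if rng is None:
        direct = np.zeros(n_focal)
        indirect = np.zeros(n_focal)
        w = 0.0
        E = np.zeros(n_drugs)
    else:
        lim = np.sqrt(6.0 / (n_focal + 1))
        direct = rng.uniform(-lim, lim, n_focal)
        indirect = rng.uniform(-lim, lim, n_focal)
        w = rng.uniform(-lim, lim)
        E = np.abs(rng.uniform(-lim, lim, n_drugs))
    return ThreeLayerParams(
        direct=direct,
        indirect=indirect,
        mediator_bias=0.0,
        mediator_weight=w,
        activity_bias=0.0,
        efflux=E,
        drug_bias=np.zeros(n_drugs),
        lam=lam,
        focal=focal,
    )


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainConfig:
    """Optimization and regularization settings.

    Defaults follow the multi-drug protocol: Adam at learning rate 0.05,
    10,000 epochs, mini-batches of 30% of the training split, 10% held out
    for monitoring only, 10 independent runs merged with a |Z| >= 4
    reproducibility filter, and residual-based pruning at Bonferroni level
    0.05/k. Single-drug fits benefit from learning_rate=0.01.
    """

    learning_rate: float = 0.05
    epochs: int = 10000
    batch_fraction: float = 0.30
    validation_fraction: float = 0.10
    n_runs: int = 10
    z_cut: float = 4.0
    prune_alpha: float = 0.05
    prune_tolerance: float = 1e-4
    merge_mode: str = "mean_with_z"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.batch_fraction <= 1 and 0 <= self.validation_fraction < 1):
            raise ValueError("fractions must lie in (0,1)")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.merge_mode not in ("mean_with_z", "median_no_z"):
            raise ValueError(f"unknown merge_mode {self.merge_mode!r}")


def train(
    presence: np.ndarray,
    r_norm: np.ndarray,
    init,
    config: TrainConfig,
    rng: np.random.Generator | None = None,
):
    """Mini-batch Adam on MSE + L1; returns (trained params, history).

    ``rng`` drives the validation split and batch shuffling (defaults to a
    generator seeded from ``config.seed``); E is projected to >= 0 after
    every update. The validation split is monitored, never used to stop.
    """
    G = np.atleast_2d(np.asarray(presence, dtype=float))
    r = np.atleast_2d(np.asarray(r_norm, dtype=float))
    if G.shape[0] != r.shape[0] or G.shape[0] == 0:
        raise ValueError("presence and r_norm must be non-empty with equal rows")
    rng = np.random.default_rng(config.seed) if rng is None else rng

    params = init.copy()
    n = G.shape[0]
    perm = rng.permutation(n)
    n_val = int(round(config.validation_fraction * n))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Gtr, rtr = G[tr_idx], r[tr_idx]
    Gval, rval = G[val_idx], r[val_idx]
    batch = max(1, int(np.ceil(config.batch_fraction * len(tr_idx))))

    beta1, beta2, eps = 0.9, 0.999, 1e-8
    m = {k: np.zeros_like(v) for k, v in params.arrays().items()}
    v = {k: np.zeros_like(val) for k, val in params.arrays().items()}
    t = 0
    history: list[dict] = []
    log_every = max(1, config.epochs // 50)

    for epoch in range(config.epochs):
        order = rng.permutation(len(tr_idx))
        for start in range(0, len(order), batch):
            sel = order[start : start + batch]
            loss, grads = params.loss_grads(Gtr[sel], rtr[sel])
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, step {start // batch}"
                )
            t += 1
            arrs = params.arrays()
            for name, g in grads.items():
                m[name] = beta1 * m[name] + (1 - beta1) * g
                v[name] = beta2 * v[name] + (1 - beta2) * g * g
                mhat = m[name] / (1 - beta1**t)
                vhat = v[name] / (1 - beta2**t)
                new = arrs[name] - config.learning_rate * mhat / (np.sqrt(vhat) + eps)
                if params.lam and name in params.l1_names():
                    # L1 enters twice: the subgradient above supplies a
                    # constant-magnitude (Adam-normalized) pull toward zero,
                    # and this proximal soft-threshold converts the residual
                    # oscillation around zero into exact zeros
                    shrink = config.learning_rate * params.lam
                    new = np.sign(new) * np.maximum(np.abs(new) - shrink, 0.0)
                _set_array(params, name, new)
                arrs = params.arrays()
            params.apply_constraints()
        if epoch % log_every == 0 or epoch == config.epochs - 1:
            tr_mse = params.loss_grads(Gtr, rtr)[0]
            entry = {"epoch": epoch, "train_mse": tr_mse}
            if len(val_idx):
                entry["val_mse"] = float(np.mean((params.predict(Gval) - rval) ** 2))
            history.append(entry)
    return params, history


def train_runs(
    presence: np.ndarray,
    r_norm: np.ndarray,
    config: TrainConfig,
    init_factory,
) -> list:
    """``n_runs`` independent trainings; run i is seeded with seed + i."""
    runs = []
    for i in range(config.n_runs):
        rng = np.random.default_rng(config.seed + i)
        init = init_factory(rng)
        params, _ = train(presence, r_norm, init, config, rng=rng)
        runs.append(params)
    return runs


# ---------------------------------------------------------------------------
# merging / pruning / model selection


def merge_runs(run_params: list, mode: str = "mean_with_z", z_cut: float = 4.0):
    """Combine independent training runs into one parameter set.

    mean_with_z: element-wise mean, then zero every weight whose
    reproducibility score |Z| = |mean| / sd(across runs) is below ``z_cut``
    (sd == 0 with non-zero mean counts as infinitely reproducible).
    median_no_z: element-wise median, no filter.
    Returns (merged params, dict of Z arrays).
    """
    if len(run_params) < 2:
        raise ValueError("merging requires at least 2 runs")
    canon = []
    for p in run_params:
        p = p.copy()
        p.canonicalize()
        canon.append(p)
    run_params = canon
    ref = run_params[0]
    names = list(ref.arrays())
    for p in run_params[1:]:
        for n in names:
            if p.arrays()[n].shape != ref.arrays()[n].shape:
                raise ValueError("run parameter shapes differ")
    merged = ref.copy()
    zs: dict[str, np.ndarray] = {}
    for name in names:
        stack = np.stack([p.arrays()[name] for p in run_params])
        if mode == "median_no_z":
            _set_array(merged, name, np.median(stack, axis=0))
            continue
        if mode != "mean_with_z":
            raise ValueError(f"unknown merge mode {mode!r}")
        mean = stack.mean(axis=0)
        sd = stack.std(axis=0, ddof=1)
        # identical runs produce sd at rounding noise; treat as exactly zero
        sd = np.where(sd <= np.abs(mean) * 1e-12, 0.0, sd)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(sd > 0, np.abs(mean) / sd, np.where(mean != 0, np.inf, 0.0))
        mean = np.where((z < z_cut) & (sd > 0), 0.0, mean)
        zs[name] = z
        _set_array(merged, name, mean)
    merged.apply_constraints()
    return merged, zs


def nonzero_support(params) -> list[tuple[str, tuple]]:
    """Indices of all non-zero, non-structural weights."""
    out = []
    for name, arr in params.arrays().items():
        for idx in zip(*np.nonzero(np.atleast_1d(arr))):
            if not params.structural_zero(name, idx):
                out.append((name, idx))
    return out


def prune_weights(
    merged,
    presence: np.ndarray,
    r_norm: np.ndarray,
    alpha: float = 0.05,
    tolerance: float = 1e-4,
):
    """Drop weights without significant predictive value.

    For each of the k non-zero weights, squared residuals are recomputed
    with that weight set to 0; restricted to observations where this makes
    a difference beyond ``tolerance``, a paired two-sided rank test
    (Wilcoxon signed-rank; exact p for <= 25 informative pairs, normal
    approximation beyond) compares initial and reduced squared errors, and
    the weight is kept iff p < alpha / k. Weights whose removal changes no
    prediction are zeroed outright.

    Returns (pruned params, report DataFrame).
    """
    G = np.atleast_2d(np.asarray(presence, dtype=float))
    r = np.atleast_2d(np.asarray(r_norm, dtype=float))
    support = nonzero_support(merged)
    k = len(support)
    if k == 0:
        return merged.copy(), pd.DataFrame(columns=["name", "index", "p", "kept"])
    e1 = ((merged.predict(G) - r) ** 2).ravel()
    pruned = merged.copy()
    rows = []
    for name, idx in support:
        trial = merged.copy()
        arr = np.atleast_1d(trial.arrays()[name]).copy()
        arr[idx] = 0.0
        _set_array(trial, name, arr.reshape(np.atleast_1d(trial.arrays()[name]).shape))
        e2 = ((trial.predict(G) - r) ** 2).ravel()
        differs = np.abs(e1 - e2) > tolerance
        if not differs.any():
            p = 1.0
            keep = False
        else:
            n_pairs = int(differs.sum())
            method = "exact" if n_pairs <= 25 else "approx"
            try:
                p = float(wilcoxon(e1[differs], e2[differs], method=method).pvalue)
            except ValueError:  # all differences zero after internal rounding
                p = 1.0
            keep = p < alpha / k
        if not keep:
            parr = np.atleast_1d(pruned.arrays()[name]).copy()
            parr[idx] = 0.0
            _set_array(pruned, name, parr.reshape(np.atleast_1d(pruned.arrays()[name]).shape))
        rows.append({"name": name, "index": idx, "p": p, "kept": keep})
    pruned.apply_constraints()
    return pruned, pd.DataFrame(rows)


@dataclass
class FitReport:
    """Everything produced by one train/merge/prune cycle."""

    runs: list
    merged: object
    z: dict
    pruned: object
    prune_report: pd.DataFrame
    history: list
    correlation: float


def fit_network(
    presence: np.ndarray,
    r_norm: np.ndarray,
    config: TrainConfig,
    init_factory,
) -> FitReport:
    """Full stack: n_runs trainings -> merge -> residual-test pruning."""
    runs = train_runs(presence, r_norm, config, init_factory)
    merged, zs = merge_runs(runs, mode=config.merge_mode, z_cut=config.z_cut)
    pruned, report = prune_weights(
        merged, presence, r_norm, alpha=config.prune_alpha, tolerance=config.prune_tolerance
    )
    pred = pruned.predict(presence).ravel()
    obs = np.atleast_2d(np.asarray(r_norm, dtype=float)).ravel()
    corr = float(np.corrcoef(pred, obs)[0, 1]) if np.std(pred) > 0 and np.std(obs) > 0 else 0.0
    return FitReport(
        runs=runs,
        merged=merged,
        z=zs,
        pruned=pruned,
        prune_report=report,
        history=[],
        correlation=corr,
    )


def lambda_search(
    presence: np.ndarray,
    r_norm: np.ndarray,
    grid: np.ndarray,
    config: TrainConfig,
    init_factory_for,
) -> pd.DataFrame:
    """Run the full train/merge/prune stack per lambda.

    ``init_factory_for(lam)`` must return an rng->params factory with that
    regularization coefficient baked in. Selection is left to the caller;
    see :func:`flag_lambda_before_jump` for the MSE-jump heuristic.
    """
    rows = []
    for lam in np.atleast_1d(grid):
        fit = fit_network(presence, r_norm, config, init_factory_for(float(lam)))
        pred = fit.pruned.predict(presence)
        mse = float(np.mean((pred - np.atleast_2d(r_norm)) ** 2))
        rows.append(
            {
                "lam": float(lam),
                "mse": mse,
                "n_nonzero": len(nonzero_support(fit.pruned)),
            }
        )
    return pd.DataFrame(rows)


def flag_lambda_before_jump(table: pd.DataFrame, factor: float = 2.0) -> float:
    """Largest lambda before the first MSE jump exceeding ``factor``."""
    tab = table.sort_values("lam").reset_index(drop=True)
    for i in range(len(tab) - 1):
        if tab.loc[i, "mse"] > 0 and tab.loc[i + 1, "mse"] / tab.loc[i, "mse"] > factor:
            return float(tab.loc[i, "lam"])
    return float(tab["lam"].iloc[-1])


# ---------------------------------------------------------------------------
# model-derived quantities


def predicted_activity_ratio(params, genotype: np.ndarray, mode: str = "all") -> float:
    """Fold change of the focal activity in ``genotype`` relative to the
    all-present wild type.

    ``indirect_only`` zeroes direct influences into the focal activity
    (mediator path retained) in both numerator and denominator; for a
    model without a mediator the ratio is then 1 by construction.
    """
    if mode not in ("all", "indirect_only"):
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(params, ThreeLayerParams):
        p = params.copy()
        if mode == "indirect_only":
            p.direct[...] = 0.0
        wt = np.ones(p.n_loci)
        num = float(p.focal_activity(genotype)[0])
        den = float(p.focal_activity(wt)[0])
        return num / den
    raise TypeError("predicted_activity_ratio expects a ThreeLayerParams model")


def activity_ratio(params: NetworkParams, genotype: np.ndarray, locus: int) -> float:
    """Two-layer analogue: ungated activity of ``locus`` vs wild type."""
    G = params._extend(genotype)
    wt = params._extend(np.ones(params.n_loci))
    act = sigmoid(G @ params.influence + params.activity_bias)[:, locus]
    ref = sigmoid(wt @ params.influence + params.activity_bias)[:, locus]
    return float(act[0] / ref[0])


# ---------------------------------------------------------------------------
# serialization


def params_to_json(params: NetworkParams, path: str | Path, manifest: dict | None = None) -> None:
    """Weights as labeled JSON; structural zeros are implied by the format
    (the influence diagonal), pruned zeros are explicit array entries."""
    payload = {
        "model": "two_layer",
        "influence": params.influence.tolist(),
        "efflux": params.efflux.tolist(),
        "activity_bias": params.activity_bias.tolist(),
        "drug_bias": params.drug_bias.tolist(),
        "lam": params.lam,
        "always_present": params.always_present,
        "locus_names": params.locus_names,
        "drug_names": params.drug_names,
        "manifest": manifest or {},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def params_from_json(path: str | Path) -> NetworkParams:
    d = json.loads(Path(path).read_text())
    return NetworkParams(
        influence=np.array(d["influence"]),
        efflux=np.array(d["efflux"]),
        activity_bias=np.array(d["activity_bias"]),
        drug_bias=np.array(d["drug_bias"]),
        lam=d.get("lam", 0.0),
        always_present=d.get("always_present", 0),
        locus_names=d.get("locus_names"),
        drug_names=d.get("drug_names"),
    )
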