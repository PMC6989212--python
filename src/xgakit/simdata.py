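"""Synthetic combinatorial-knockout pool experiments with known truth.

Generates every input the downstream stages consume: barcoded strains with
random 16-locus knockout genotypes (1:1 segregation, optionally one weakly
linked locus pair), a ground-truth influence/efflux network, competitive
pool-growth barcode counts over timepoints measured in pool generations,
tagged sequencing reads with substitution errors, logistic plate OD curves
with a sigmoidal dose response, and qPCR Cq tables.

Conventions: timepoint tau means the whole pool has doubled tau times; a
strain's relative rate g is doublings per pool generation, so a strain
with g = 1 exactly tracks the pool. Drug effects enter multiplicatively,
g_drug = r_true * g_solvent, which is precisely the ratio the resistance
estimator inverts.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nnmodel
from .containers import (
    COUNT_COLUMNS,
    DNA_ALPHABET,
    TAG_LENGTH,
    CountMatrix,
    StrainRecord,
    presence_matrix,
)
from .fitness import PlateGrowthCurve

#: minimum pairwise Hamming distance enforced within a tag pool so the
#: two-mismatch-tolerant matcher is well-posed on simulated reads
MIN_TAG_DISTANCE = 5

PLATE_ROWS, PLATE_COLS = 8, 12


@dataclass
class LinkageSpec:
    """Locus pairs to correlate: list of (i, j, target Pearson correlation)."""

    locus_pairs: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, j, rho in self.locus_pairs:
            if not abs(rho) < 1:
                raise ValueError(f"|correlation| must be < 1, got {rho} for ({i},{j})")
            if i == j:
                raise ValueError("linked pair must reference two distinct loci")


@dataclass
class SimTruth:
    """Ground truth behind a simulated experiment.

    ``network`` is the generative twin of the fitted model: true strain
    resistance is its exact forward pass on each genotype. ``plate_bias``
    is an additive log-scale bias applied to drug resistance per
    plate-of-origin; ``noise_sd`` is log-scale phenotype noise.
    ``resistance_fn``, when set, overrides the network (used to plant
    explicit multiplicative-interaction truths for the epistasis stage).
    """

    network: nnmodel.NetworkParams
    baseline_growth: float = 1.0
    baseline_growth_sd: float = 0.05
    plate_bias: dict[int, float] = field(default_factory=dict)
    noise_sd: float = 0.03
    seed: int = 0
    resistance_fn: object = None

    def __post_init__(self) -> None:
        if self.baseline_growth <= 0:
            raise ValueError("baseline_growth must be positive")

    @property
    def n_drugs(self) -> int:
        return self.network.n_drugs

    def resistance_matrix(self, strains: list[StrainRecord]) -> np.ndarray:
        """True resistance r in (0, 1] per strain x drug."""
        G = presence_matrix(strains)
        if self.resistance_fn is not None:
            r = np.asarray(self.resistance_fn(G), dtype=float)
        else:
            r = self.network.predict(G)
        if r.ndim == 1:
            r = r[:, None]
        return np.clip(r, 1e-10, None)


# ---------------------------------------------------------------------------
# genotypes and tags


def _pair_probs(rho: float) -> np.ndarray:
    """Joint Bernoulli(0.5, 0.5) cell probabilities for (11, 10, 01, 00)."""
    p11 = 0.25 + rho / 4.0
    if not (0.0 <= p11 <= 0.5):
        raise ValueError(f"correlation {rho} unreachable for Bernoulli(0.5) marginals")
    return np.array([p11, 0.5 - p11, 0.5 - p11, p11])


def _sample_masks(n: int, n_loci: int, linkage: LinkageSpec | None, rng) -> np.ndarray:
    masks = rng.integers(0, 2, size=(n, n_loci)).astype(bool)
    if linkage is None:
        return masks
    used: set[int] = set()
    for i, j, rho in linkage.locus_pairs:
        if not (0 <= i < n_loci and 0 <= j < n_loci):
            raise ValueError(f"linked pair ({i},{j}) outside 0..{n_loci - 1}")
        if used & {i, j}:
            raise ValueError("linkage pairs must use disjoint loci")
        used |= {i, j}
        cells = rng.choice(4, size=n, p=_pair_probs(rho))
        masks[:, i] = cells <= 1  # 11 or 10
        masks[:, j] = (cells == 0) | (cells == 2)  # 11 or 01
    return masks


def _tags_to_strings(tags: np.ndarray) -> list[str]:
    lut = np.array(list(DNA_ALPHABET))
    return ["".join(row) for row in lut[tags]]


def _draw_tag_pool(n: int, rng, min_distance: int = MIN_TAG_DISTANCE) -> list[str]:
    """n unique random tags with all pairwise Hamming distances >= min_distance.

    Random 25-mers essentially never violate the bound, so this is a
    verify-and-redraw loop that usually passes on the first sweep.
    """
    tags = rng.integers(0, 4, size=(n, TAG_LENGTH), dtype=np.int8)
    for _ in range(100):
        bad = np.zeros(n, dtype=bool)
        chunk = 256
        for start in range(0, n, chunk):
            block = tags[start : start + chunk]
            # Hamming distances block x all
            d = (block[:, None, :] != tags[None, :, :]).sum(axis=2)
            rows = np.arange(start, start + block.shape[0])
            d[np.arange(block.shape[0]), rows] = TAG_LENGTH  # ignore self
            close = d < min_distance
            bad[rows] |= close.any(axis=1)
            # only redraw the later member of a close pair to make progress
            for bi, row in enumerate(rows):
                others = np.nonzero(close[bi])[0]
                if len(others) and (others < row).all():
                    pass  # keep flag
                elif len(others):
                    bad[row] = True
        if not bad.any():
            return _tags_to_strings(tags)
        tags[bad] = rng.integers(0, 4, size=(int(bad.sum()), TAG_LENGTH), dtype=np.int8)
    raise RuntimeError("could not satisfy tag distance constraint")


def simulate_population(
    n_strains: int,
    n_loci: int = 16,
    linkage: LinkageSpec | None = None,
    mating_split: float = 0.5,
    seed: int = 0,
) -> list[StrainRecord]:
    """Random haploid knockout strains with unique, well-separated tags.

    Each locus is knocked out independently with probability 0.5 (1:1
    segregation); linked pairs are drawn jointly to hit the requested
    Pearson correlation. Strains are split into mating pools by
    ``mating_split`` (fraction of MATa) and arrayed onto 96-well plates.
    """
    if n_strains < 1:
        raise ValueError("n_strains must be >= 1")
    rng = np.random.default_rng(seed)
    masks = _sample_masks(n_strains, n_loci, linkage, rng)
    n_a = int(round(mating_split * n_strains))
    mating = np.array(["a"] * n_a + ["alpha"] * (n_strains - n_a))
    rng.shuffle(mating)
    up_tags = _draw_tag_pool(n_strains, rng)
    dn_tags = _draw_tag_pool(n_strains, rng)
    strains = []
    per_plate = PLATE_ROWS * PLATE_COLS
    for idx in range(n_strains):
        plate, well = divmod(idx, per_plate)
        row, col = divmod(well, PLATE_COLS)
        strains.append(
            StrainRecord(
                strain_id=f"S{idx:05d}",
                mating_type=str(mating[idx]),
                plate=plate + 1,
                row=row + 1,
                column=col + 1,
                up_tag=up_tags[idx],
                dn_tag=dn_tags[idx],
                knockout_mask=masks[idx],
            )
        )
    return strains


# ---------------------------------------------------------------------------
# ground-truth network


def simulate_truth(
    n_loci: int = 16,
    n_drugs: int = 8,
    n_influences: int = 6,
    n_effluxes: int = 12,
    sign_constraints: dict | None = None,
    seed: int = 0,
    noise_sd: float = 0.03,
    n_plates: int = 30,
    plate_bias_sd: float = 0.0,
    drug_bias_range: tuple[float, float] = (-2.0, 0.0),
    efflux_range: tuple[float, float] = (1.5, 4.0),
    influence_range: tuple[float, float] = (0.8, 2.0),
) -> SimTruth:
    """Sparse ground-truth network with known influence/efflux support.

    Efflux positions are drawn first; influence links are targeted at
    transporters that carry at least one efflux weight so every planted
    influence is identifiable from resistance data. Default magnitudes
    give each drug a realistic dynamic range — baseline (no-transporter)
    resistance sigmoid(B_d) in ~[0.1, 0.5] and effluxer-carrying strains
    approaching 1 — rather than compressing all strains into the
    saturated top of the dose-response sigmoid.
    """
    if n_influences > n_loci * (n_loci - 1):
        raise ValueError("too many influence links requested")
    if n_effluxes > n_loci * n_drugs:
        raise ValueError("too many efflux links requested")
    rng = np.random.default_rng(seed)
    nonpositive = bool((sign_constraints or {}).get("influences_nonpositive", True))

    E = np.zeros((n_loci, n_drugs))
    flat = rng.choice(n_loci * n_drugs, size=n_effluxes, replace=False)
    E.flat[flat] = rng.uniform(*efflux_range, size=n_effluxes)

    I = np.zeros((n_loci, n_loci))
    targets = np.nonzero(E.any(axis=1))[0]
    if len(targets) == 0:
        targets = np.arange(n_loci)
    pairs = [(i, j) for j in targets for i in range(n_loci) if i != j]
    if n_influences > 0:
        chosen = rng.choice(len(pairs), size=min(n_influences, len(pairs)), replace=False)
        for c in chosen:
            i, j = pairs[c]
            mag = rng.uniform(*influence_range)
            I[i, j] = -mag if nonpositive else mag * rng.choice([-1.0, 1.0])

    network = nnmodel.NetworkParams(
        influence=I,
        efflux=E,
        activity_bias=np.zeros(n_loci),
        drug_bias=rng.uniform(*drug_bias_range, size=n_drugs),
        lam=0.0,
    )
    plate_bias = {
        p + 1: float(rng.normal(0.0, plate_bias_sd)) if plate_bias_sd > 0 else 0.0
        for p in range(n_plates)
    }
    return SimTruth(
        network=network,
        plate_bias=plate_bias,
        noise_sd=noise_sd,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# pool growth counts


def _growth_rates(
    strains: list[StrainRecord],
    truth: SimTruth,
    conditions: list[str],
    solvent: str,
    rng,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-strain relative growth g per condition, and initial frequencies."""
    n = len(strains)
    drugs = [c for c in conditions if c != solvent]
    if truth.n_drugs < len(drugs):
        raise ValueError("truth network has fewer drugs than requested conditions")
    r_true = truth.resistance_matrix(strains)[:, : len(drugs)]
    baseline = truth.baseline_growth * np.exp(
        rng.normal(0.0, truth.baseline_growth_sd, size=n)
    )
    bias = np.array([truth.plate_bias.get(s.plate, 0.0) for s in strains])
    g = np.empty((n, len(conditions)))
    for ci, cond in enumerate(conditions):
        if cond == solvent:
            g[:, ci] = baseline
        else:
            di = drugs.index(cond)
            noise = rng.normal(0.0, truth.noise_sd, size=n)
            g[:, ci] = r_true[:, di] * np.exp(bias + noise) * baseline
    f0 = np.exp(rng.normal(0.0, 0.25, size=n))
    f0 /= f0.sum()
    return g, f0


def _expected_frequencies(f0: np.ndarray, g: np.ndarray, tau: float) -> np.ndarray:
    """Strain frequencies when this condition's pool has doubled tau times.

    Each pool is grown to a fixed density per passage, so the timepoint
    label tau counts that pool's own doublings: real time T(tau) solves
    sum_s f0_s 2^(g_s T) = 2^tau, and frequencies are the exponential
    abundances at T renormalized by the pool expansion. This matches the
    estimator's convention (a strain with g equal to the pool-effective
    rate keeps a constant frequency).
    """
    from scipy.optimize import brentq

    if tau == 0:
        return f0.copy()
    g = np.maximum(g, 1e-10)

    def log2_pool(T: float) -> float:
        m = (g * T).max()
        return m + np.log2(np.sum(f0 * np.exp2(g * T - m)))

    hi = tau / max(float(g.mean()), 1e-6)
    while log2_pool(hi) < tau:
        hi *= 2.0
    T = brentq(lambda x: log2_pool(x) - tau, 0.0, hi, xtol=1e-12, rtol=1e-14)
    w = f0 * np.exp2(g * T - tau)
    return w / w.sum()  # sums to 1 up to rounding by construction


def simulate_pool_counts(
    strains: list[StrainRecord],
    truth: SimTruth,
    timepoints: tuple[float, ...] = (0, 5, 10, 15, 20),
    depth: int = 1_000_000,
    conditions: tuple[str, ...] | None = None,
    solvent: str = "DMSO",
    seed: int = 0,
    two_t0_runs: bool = True,
) -> CountMatrix:
    """Multinomial barcode counts from competitive exponential pool growth.

    Strain abundance follows A0 * 2^(g * tau); frequencies are renormalized
    so the pool as a whole doubles tau times by timepoint tau. Counts are
    drawn multinomially at ``depth`` reads per sample, independently for UP
    and DN tags; t = 0 is emitted as two runs to exercise run summing.
    """
    if not strains:
        raise ValueError("strains must be non-empty")
    if conditions is None:
        conditions = tuple(f"drug{d + 1:02d}" for d in range(truth.n_drugs)) + (solvent,)
    if not conditions:
        raise ValueError("condition list is empty")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    g, f0 = _growth_rates(strains, truth, list(conditions), solvent, rng)
    ids = [s.strain_id for s in strains]
    frames = []
    for ci, cond in enumerate(conditions):
        for tau in timepoints:
            f = _expected_frequencies(f0, g[:, ci], float(tau))
            runs = (1, 2) if (tau == 0 and two_t0_runs) else (1,)
            for run in runs:
                for tag in ("UP", "DN"):
                    counts = rng.multinomial(depth, f)
                    frames.append(
                        pd.DataFrame(
                            {
                                "tag": tag,
                                "strain_id": ids,
                                "generation": float(tau),
                                "condition": cond,
                                "run": run,
                                "count": counts,
                            }
                        )
                    )
    df = pd.concat(frames, ignore_index=True)[COUNT_COLUMNS]
    meta = {
        "timepoints": list(map(float, timepoints)),
        "conditions": list(conditions),
        "solvent": solvent,
        "depth": depth,
        "seed": seed,
    }
    return CountMatrix(counts=df, metadata=meta)


def simulate_pool_frequencies(
    strains: list[StrainRecord],
    truth: SimTruth,
    timepoints: tuple[float, ...] = (0, 5, 10, 15, 20),
    conditions: tuple[str, ...] | None = None,
    solvent: str = "DMSO",
    seed: int = 0,
) -> pd.DataFrame:
    """Noise-free expected frequencies (the depth -> infinity limit)."""
    if conditions is None:
        conditions = tuple(f"drug{d + 1:02d}" for d in range(truth.n_drugs)) + (solvent,)
    rng = np.random.default_rng(seed)
    g, f0 = _growth_rates(strains, truth, list(conditions), solvent, rng)
    ids = [s.strain_id for s in strains]
    rows = []
    for ci, cond in enumerate(conditions):
        for tau in timepoints:
            f = _expected_frequencies(f0, g[:, ci], float(tau))
            rows.append(
                pd.DataFrame(
                    {"strain_id": ids, "generation": float(tau), "condition": cond, "f": f}
                )
            )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# reads


@dataclass
class TaggedRead:
    """One paired read: sample tag + UP tag forward, sample tag + DN tag reverse."""

    fwd: str
    rev: str
    true_strain_id: str


def _mutate(seqs: np.ndarray, error_rate: float, rng) -> np.ndarray:
    if error_rate == 0:
        return seqs
    hits = rng.random(seqs.shape) < error_rate
    shift = rng.integers(1, 4, size=seqs.shape)
    return np.where(hits, (seqs + shift) % 4, seqs)


_BASE_TO_INT = {b: i for i, b in enumerate(DNA_ALPHABET)}


def _str_to_int(seq: str) -> np.ndarray:
    return np.array([_BASE_TO_INT[b] for b in seq], dtype=np.int8)


def simulate_reads(
    strains: list[StrainRecord],
    counts_per_strain,
    error_rate: float = 0.0,
    sample_tags: tuple[str, str] = ("ACGTACGT", "TGCATGCA"),
    seed: int = 0,
) -> list[TaggedRead]:
    """Tagged reads for one sample, with truth labels for scoring.

    Per-base substitutions (rate < 0.25) are applied independently to the
    strain-tag regions; sample tags are left intact so exact-match
    demultiplexing routes every read.
    """
    if not 0 <= error_rate < 0.25:
        raise ValueError("error_rate must be in [0, 0.25)")
    rng = np.random.default_rng(seed)
    if isinstance(counts_per_strain, dict):
        counts = [int(counts_per_strain.get(s.strain_id, 0)) for s in strains]
    else:
        counts = [int(c) for c in counts_per_strain]
    lut = np.array(list(DNA_ALPHABET))
    reads: list[TaggedRead] = []
    ftag, rtag = sample_tags
    for s, c in zip(strains, counts):
        if c == 0:
            continue
        up = np.tile(_str_to_int(s.up_tag), (c, 1))
        dn = np.tile(_str_to_int(s.dn_tag), (c, 1))
        up = _mutate(up, error_rate, rng)
        dn = _mutate(dn, error_rate, rng)
        for k in range(c):
            reads.append(
                TaggedRead(
                    fwd=ftag + "".join(lut[up[k]]),
                    rev=rtag + "".join(lut[dn[k]]),
                    true_strain_id=s.strain_id,
                )
            )
    return reads


def write_reads_fastq(reads: list[TaggedRead], fwd_path, rev_path) -> None:
    """Plain 4-line FASTQ with placeholder Phred-33 qualities."""
    with open(fwd_path, "w") as fh1, open(rev_path, "w") as fh2:
        for i, r in enumerate(reads):
            fh1.write(f"@read{i}/1 truth={r.true_strain_id}\n{r.fwd}\n+\n{'I' * len(r.fwd)}\n")
            fh2.write(f"@read{i}/2 truth={r.true_strain_id}\n{r.rev}\n+\n{'I' * len(r.rev)}\n")


def read_reads_fastq(fwd_path, rev_path) -> list[TaggedRead]:
    from Bio import SeqIO

    fwd = list(SeqIO.parse(str(fwd_path), "fastq"))
    rev = list(SeqIO.parse(str(rev_path), "fastq"))
    reads = []
    for f, r in zip(fwd, rev):
        truth = ""
        for tok in f.description.split():
            if tok.startswith("truth="):
                truth = tok[len("truth=") :]
        reads.append(TaggedRead(fwd=str(f.seq), rev=str(r.seq), true_strain_id=truth))
    return reads


# ---------------------------------------------------------------------------
# plate growth and qPCR fixtures


def _dose_factor(conc: float, ic50: float, steepness: float) -> float:
    """Sigmoid dose response, symmetric about ic50 in linear concentration,
    so linear interpolation at 0.5 recovers ic50 on symmetric grids.
    Concentration 0 is defined as exactly no inhibition."""
    if conc == 0:
        return 1.0
    return float(1.0 / (1.0 + np.exp(steepness * (conc - ic50))))


def simulate_plate_growth(
    ic50: float,
    hill_steepness: float = 0.5,
    conc_grid: tuple[float, ...] = (10.0, 20.0),
    od_params: dict | None = None,
    sampling_interval: float = 10.0,
    duration: float = 1440.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> dict[float, PlateGrowthCurve]:
    """Logistic OD(t) curves: solvent (key 0.0) plus one per concentration.

    Saturation OD in drug relative to solvent follows the dose response,
    crossing 0.5 at ``ic50``.
    """
    grid = list(conc_grid)
    if any(c <= 0 for c in grid) or sorted(grid) != grid:
        raise ValueError("conc_grid must be positive and sorted")
    od = {"od0": 0.0625, "plateau": 1.3, "midpoint": 600.0, "scale": 60.0}
    od.update(od_params or {})
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration + 0.5 * sampling_interval, sampling_interval)
    logistic = 1.0 / (1.0 + np.exp(-(times - od["midpoint"]) / od["scale"]))
    out: dict[float, PlateGrowthCurve] = {}
    for conc in [0.0] + grid:
        phi = _dose_factor(conc, ic50, hill_steepness)
        curve = od["od0"] + (od["plateau"] - od["od0"]) * phi * logistic
        if noise_sd > 0:
            curve = np.clip(curve + rng.normal(0.0, noise_sd, size=curve.shape), 0.0, None)
        label = "solvent" if conc == 0 else f"drug@{conc}"
        out[conc] = PlateGrowthCurve(
            times=times.copy(), od=curve, condition=label, concentration=conc
        )
    return out


def simulate_cq_table(
    fold_changes: dict[str, float],
    cq_control: float = 21.0,
    n_replicates: int = 3,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """qPCR Cq fixture: target Cq = control Cq - log2(fold) plus noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for strain, fold in fold_changes.items():
        for rep in range(n_replicates):
            rows.append(
                {
                    "strain": strain,
                    "replicate": rep + 1,
                    "cq_target": cq_control - np.log2(fold) + rng.normal(0, noise_sd),
                    "cq_control": cq_control + rng.normal(0, noise_sd),
                }
            )
    return pd.DataFrame(rows)
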