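"""Multi-ancestry case-control simulation under a liability-threshold model.

Generates genotype/phenotype data for a large "majority" European-ancestry
(EUR) cohort and a smaller data-disadvantaged population (DDP), with two
built-in forms of inequality:

* **sample-size inequality** — the DDP cohort is a fraction of the EUR one
  (defaults: 10,000 EUR vs 2,000 DDP individuals);
* **genotype–phenotype distribution shift** — per-SNP effect sizes in the
  DDP are a noisy copy of the EUR effects with correlation ``rho``, where
  ``rho`` decays with the genetic distance between the two populations.

The liability of individual *i* is

    g_i = h * s_i + sqrt(1 - h^2) * zeta_i

where ``s_i`` is the (variance-standardized) weighted genotype score
``sum_j w_j x_ij``, ``h^2`` the heritability, and ``zeta`` independent noise.
Individuals whose liability exceeds a population-specific threshold are
cases; the threshold is the empirical quantile that realizes the requested
case:control ratio.

Allele-frequency divergence between populations follows a Balding–Nichols
beta model whose spread parameter is calibrated by Monte-Carlo so that the
L1 genetic distance ``d = sum_j |F_j^EUR - F_j^DDP|`` matches a requested
target (the study conditions use d = 42.7 / 46.1 / 80.6 / 94.1 for
AMR / SAS / EAS / AFR at m = 500 SNPs).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

POPULATIONS = ("EUR", "AMR", "SAS", "EAS", "AFR")

#: printed L1 genetic distances to EUR at m=500 SNPs
GENETIC_DISTANCES = {"AMR": 42.7, "SAS": 46.1, "EAS": 80.6, "AFR": 94.1}

FREQ_MIN, FREQ_MAX = 0.05, 0.95

# standard deviation of a standard normal truncated to [-1, 1]
_TRUNC_SD = float(stats.truncnorm.std(-1.0, 1.0))


def _rng(seed: int, *tags: object) -> np.random.Generator:
    """Derive an independent, reproducible stream from a master seed.

    Tags (strings/ints) are hashed so that each pipeline stage gets its own
    stream; the same (seed, tags) pair always yields the same stream.
    """
    h = hashlib.sha256(repr((int(seed),) + tags).encode()).digest()
    return np.random.default_rng(np.frombuffer(h[:16], dtype=np.uint64))


def derive_seed(seed: int, *tags: object) -> int:
    """A deterministic child seed below 2**31, for APIs that take an int."""
    h = hashlib.sha256(repr((int(seed),) + tags).encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class FrequencyProfile:
    """Per-population minor-allele frequencies for the m simulated SNPs."""

    population_label: str
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.ndim != 1 or f.size == 0:
            raise ValueError("frequencies must be a non-empty 1-D vector")
        if np.any(f < FREQ_MIN - 1e-12) or np.any(f > FREQ_MAX + 1e-12):
            raise ValueError(
                f"frequencies outside [{FREQ_MIN}, {FREQ_MAX}] for "
                f"{self.population_label}"
            )
        object.__setattr__(self, "frequencies", f)

    @property
    def m(self) -> int:
        return self.frequencies.size


@dataclass(frozen=True)
class EffectModel:
    """EUR effect vector W and its shifted DDP counterpart W'."""

    W: np.ndarray
    W_prime: np.ndarray
    rho: float
    h2: float
    zeta_prime: np.ndarray

    def __post_init__(self) -> None:
        if not (0.0 < self.rho <= 1.0):
            raise ValueError("rho must be in (0, 1]")
        if not (0.0 <= self.h2 <= 1.0):
            raise ValueError("h2 must be in [0, 1]")
        if len(self.W) != len(self.W_prime):
            raise ValueError("W and W_prime must have equal length")


@dataclass(frozen=True)
class LiabilityConfig:
    """Heritability, case:control ratio and seed for label generation."""

    h2: float
    case_control_ratio: tuple[int, int] = (1, 1)
    seed: int = 0
    truncated_noise: bool = True  # noise support [-1,1]; False = plain normal

    @property
    def case_fraction(self) -> float:
        a, b = self.case_control_ratio
        if a <= 0 or b <= 0:
            raise ValueError("case:control ratio parts must be positive")
        return a / (a + b)


@dataclass
class MultiAncestryDataset:
    """Genotypes, labels, ancestry and split assignments for one EUR+DDP pair.

    ``g`` (latent liabilities) and ``thresholds`` are retained for testing
    and never consumed by the learning schemes.
    """

    X: np.ndarray
    y: np.ndarray
    ancestry: np.ndarray
    split: np.ndarray
    g: np.ndarray
    thresholds: dict[str, float]
    effect_model: EffectModel | None = None
    snp_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        if not (len(self.y) == len(self.ancestry) == len(self.split) == n):
            raise ValueError("row-aligned arrays have inconsistent lengths")

    @property
    def populations(self) -> list[str]:
        seen: list[str] = []
        for a in self.ancestry:
            if a not in seen:
                seen.append(a)
        return seen

    def mask(self, population: str | None = None, split: str | None = None) -> np.ndarray:
        m = np.ones(len(self.y), dtype=bool)
        if population is not None:
            m &= self.ancestry == population
        if split is not None:
            m &= self.split == split
        return m

    def subset(self, population: str | None = None, split: str | None = None):
        m = self.mask(population, split)
        return self.X[m], self.y[m]


# ---------------------------------------------------------------------------
# allele-frequency profiles


def simulate_frequency_profiles(
    m: int,
    divergence_params: dict[str, float],
    seed: int,
) -> list[FrequencyProfile]:
    """Draw an EUR frequency profile and Balding–Nichols-shifted DDP profiles.

    ``divergence_params`` maps each non-EUR population label to a divergence
    scalar c >= 0; the DDP frequency of SNP j is drawn from
    Beta(F_j(1-c)/c, (1-F_j)(1-c)/c) (mean F_j, variance c*F_j(1-F_j)),
    then clipped to the admissible band. c = 0 copies EUR exactly.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    for pop, c in divergence_params.items():
        if c < 0:
            raise ValueError(f"negative divergence for {pop}")
    rng = _rng(seed, "freq", m)
    f_eur = rng.uniform(FREQ_MIN, FREQ_MAX, size=m)
    profiles = [FrequencyProfile("EUR", f_eur)]
    for pop in sorted(divergence_params):
        c = float(divergence_params[pop])
        profiles.append(
            FrequencyProfile(pop, _diverge(f_eur, c, _rng(seed, "freq", m, pop)))
        )
    return profiles


def _diverge(f_eur: np.ndarray, c: float, rng: np.random.Generator) -> np.ndarray:
    if c == 0.0:
        return f_eur.copy()
    if c >= 1.0:
        raise ValueError("divergence scalar must be < 1 (Balding–Nichols)")
    k = (1.0 - c) / c
    f = rng.beta(f_eur * k, (1.0 - f_eur) * k)
    f = np.clip(f, FREQ_MIN, FREQ_MAX)
    if np.allclose(f, f[0]):  # degenerate draw: constant profile
        raise RuntimeError("degenerate (constant) frequency draw")
    return f


def genetic_distance(f_a: FrequencyProfile | np.ndarray, f_b: FrequencyProfile | np.ndarray) -> float:
    """L1 distance between two frequency profiles: sum_j |F_j - F'_j|."""
    a = f_a.frequencies if isinstance(f_a, FrequencyProfile) else np.asarray(f_a, float)
    b = f_b.frequencies if isinstance(f_b, FrequencyProfile) else np.asarray(f_b, float)
    if a.shape != b.shape:
        raise ValueError("frequency profiles have different lengths")
    return float(np.abs(a - b).sum())


def calibrate_divergence(
    target_distance: float,
    m: int,
    seed: int,
    n_draws: int = 20,
    tol: float = 0.02,
) -> float:
    """Find the Balding–Nichols scalar whose expected L1 distance hits a target.

    Bisection on c in (0, 1), each candidate evaluated by the Monte-Carlo mean
    distance over ``n_draws`` independent profile draws. The realized mean is
    required to be within ``tol`` (relative) of the target.
    """
    if target_distance < 0 or target_distance >= 0.9 * m:
        raise ValueError(
            f"target distance {target_distance} unattainable for m={m} "
            f"(per-SNP |dF| <= 0.9)"
        )
    if target_distance == 0:
        return 0.0

    def mean_dist(c: float) -> float:
        tot = 0.0
        for d in range(n_draws):
            rng = _rng(seed, "cal", m, d)
            f_eur = rng.uniform(FREQ_MIN, FREQ_MAX, size=m)
            tot += genetic_distance(f_eur, _diverge(f_eur, c, rng))
        return tot / n_draws

    lo, hi = 1e-6, 1.0 - 1e-6
    if mean_dist(hi) < target_distance:
        raise ValueError(f"target distance {target_distance} exceeds attainable bound")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if mean_dist(mid) < target_distance:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-10:
            break
    c = 0.5 * (lo + hi)
    realized = mean_dist(c)
    if abs(realized - target_distance) > tol * max(target_distance, 1.0):
        raise RuntimeError(
            f"calibration failed: realized {realized:.3f} vs target {target_distance}"
        )
    return c


# ---------------------------------------------------------------------------
# effects and liabilities


def rho_schedule(d0: float, dk: float, rho0: float = 0.8, r: float = 0.5) -> float:
    """Effect-size correlation as a power-law decay in genetic distance.

    rho_k = rho0 * (d0 / d_k)^r; equals rho0 at d_k = d0 and decreases in
    d_k for r > 0.
    """
    if d0 <= 0 or dk <= 0:
        raise ValueError("distances must be positive")
    if not (0.0 < rho0 <= 1.0):
        raise ValueError("rho0 must be in (0, 1]")
    return float(rho0 * (d0 / dk) ** r)


def _draw_truncnorm(m: int, rng: np.random.Generator, truncated: bool = True) -> np.ndarray:
    if truncated:
        return stats.truncnorm.rvs(-1.0, 1.0, size=m, random_state=rng)
    return rng.standard_normal(m)


def draw_effects(m: int, seed: int, truncated: bool = True) -> np.ndarray:
    """EUR per-SNP effect sizes: standard normal truncated to [-1, 1]."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return _draw_truncnorm(m, _rng(seed, "effects", m), truncated)


def correlate_effects(
    W: np.ndarray, rho: float, seed: int, truncated: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """DDP effects W' = rho*W + sqrt(1-rho^2)*zeta', returning (W', zeta').

    zeta' is drawn from the same truncated-normal family as W, so
    corr(W, W') has expectation rho.
    """
    if not (0.0 <= rho <= 1.0):
        raise ValueError("rho must be in [0, 1]")
    W = np.asarray(W, dtype=float)
    zeta = _draw_truncnorm(W.size, _rng(seed, "zeta", W.size), truncated)
    return rho * W + np.sqrt(1.0 - rho**2) * zeta, zeta


def compute_liability(
    X: np.ndarray,
    W: np.ndarray,
    h2: float,
    seed: int,
    truncated_noise: bool = True,
) -> np.ndarray:
    """Latent liabilities g = h * standardized(XW) + sqrt(1-h2) * zeta.

    The weighted genotype score is variance-standardized across individuals
    and the noise zeta is scaled to unit variance, so Var(g) ~= 1 and the
    genetic share of liability variance equals h2 exactly in expectation.
    """
    X = np.asarray(X, dtype=float)
    W = np.asarray(W, dtype=float)
    if X.shape[1] != W.size:
        raise ValueError("column count of X must equal length of W")
    if not (0.0 <= h2 <= 1.0):
        raise ValueError("h2 must be in [0, 1]")
    score = X @ W
    sd = score.std()
    if sd == 0:
        raise ValueError("zero-variance genetic component")
    score = (score - score.mean()) / sd
    zeta = _draw_truncnorm(X.shape[0], _rng(seed, "liab-noise", X.shape[0]), truncated_noise)
    if truncated_noise:
        zeta = zeta / _TRUNC_SD  # unit-variance noise
    return np.sqrt(h2) * score + np.sqrt(1.0 - h2) * zeta


def assign_labels(
    g: np.ndarray, case_control_ratio: tuple[int, int]
) -> tuple[np.ndarray, float]:
    """Threshold liabilities at the empirical quantile giving the target ratio.

    thr is the control-fraction quantile of g; y_i = 1 iff g_i > thr (strict).
    Ties at thr all fall on the control side, so the realized case count can
    undershoot the target only in the (measure-zero) presence of ties.
    """
    g = np.asarray(g, dtype=float)
    if g.size == 0:
        raise ValueError("empty liability vector")
    a, b = case_control_ratio
    if a <= 0 or b <= 0:
        raise ValueError("invalid case:control ratio")
    control_frac = b / (a + b)
    order = np.sort(g)
    k = int(round(control_frac * g.size))
    k = min(max(k, 1), g.size)  # at least one control boundary
    thr = order[k - 1]
    y = (g > thr).astype(np.int8)
    return y, float(thr)


# ---------------------------------------------------------------------------
# dataset assembly


def _stratified_split(
    y: np.ndarray,
    ancestry: np.ndarray,
    rng: np.random.Generator,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> np.ndarray:
    """80/10/10 split stratified jointly by ancestry and class label."""
    split = np.empty(len(y), dtype=object)
    for pop in np.unique(ancestry):
        for label in (0, 1):
            idx = np.flatnonzero((ancestry == pop) & (y == label))
            if idx.size < 10:
                raise ValueError(
                    f"stratum ({pop}, y={label}) has {idx.size} < 10 individuals"
                )
            idx = rng.permutation(idx)
            n_train = int(round(fractions[0] * idx.size))
            n_val = int(round(fractions[1] * idx.size))
            split[idx[:n_train]] = "train"
            split[idx[n_train : n_train + n_val]] = "validation"
            split[idx[n_train + n_val :]] = "test"
    return split.astype(str)


def draw_genotypes(
    profile: FrequencyProfile, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Independent-SNP additive dosages: X_ij ~ Binomial(2, F_j)."""
    return rng.binomial(2, profile.frequencies, size=(n, profile.m)).astype(np.int8)


def build_dataset(
    profiles: list[FrequencyProfile],
    effect_model: EffectModel,
    n_per_pop: dict[str, int],
    liability_config: LiabilityConfig,
    seed: int,
    clinical_effects: tuple[float, float] | None = None,
) -> MultiAncestryDataset:
    """Assemble an EUR + one-DDP dataset with labels, liabilities and splits.

    EUR labels use W; the DDP uses W'. Each population gets its own
    empirical threshold so both realize the configured case:control ratio.

    ``clinical_effects`` (off by default) appends one standard-normal
    continuous covariate and one centred Bernoulli(0.5) covariate as the
    last two feature columns, adding the given effect sizes to the
    liability — this exercises the clinical terms of the linear transfer
    model.
    """
    by_label = {p.population_label: p for p in profiles}
    if "EUR" not in by_label:
        raise ValueError("profiles must include EUR")
    pops = [p for p in n_per_pop if p != "EUR"]
    if len(pops) != 1:
        raise ValueError("expected exactly one DDP population alongside EUR")
    ddp = pops[0]

    blocks, labels, liabs, ancs = [], [], [], []
    thresholds: dict[str, float] = {}
    for pop, w in (("EUR", effect_model.W), (ddp, effect_model.W_prime)):
        n = int(n_per_pop[pop])
        X = draw_genotypes(by_label[pop], n, _rng(seed, "geno", pop, n))
        g = compute_liability(
            X, w, liability_config.h2, derive_seed(seed, "liab", pop),
            truncated_noise=liability_config.truncated_noise,
        )
        if clinical_effects is not None:
            b_cont, b_bin = clinical_effects
            crng = _rng(seed, "clinical", pop)
            c_cont = crng.standard_normal(n)
            c_bin = crng.binomial(1, 0.5, n).astype(float)
            g = g + b_cont * c_cont + b_bin * (c_bin - 0.5)
            X = np.column_stack([X, c_cont, c_bin])
        y, thr = assign_labels(g, liability_config.case_control_ratio)
        thresholds[pop] = thr
        blocks.append(X)
        labels.append(y)
        liabs.append(g)
        ancs.append(np.full(n, pop, dtype=object))

    X = np.vstack(blocks)
    y = np.concatenate(labels)
    g = np.concatenate(liabs)
    ancestry = np.concatenate(ancs).astype(str)
    split = _stratified_split(y, ancestry, _rng(seed, "split"))
    n_snp = len(effect_model.W)
    ids = [f"snp{j}" for j in range(n_snp)]
    if X.shape[1] == n_snp + 2:
        ids += ["cov_cont", "cov_bin"]
    return MultiAncestryDataset(
        X=X, y=y, ancestry=ancestry, split=split, g=g,
        thresholds=thresholds, effect_model=effect_model,
        snp_ids=ids,
    )


@dataclass(frozen=True)
class DatasetConfig:
    """Recipe for one synthetic dataset (an SD-table row analogue)."""

    name: str
    ddp: str
    h2: float
    r: float
    case_control_ratio: tuple[int, int] = (1, 1)
    m: int = 500
    n_eur: int = 10_000
    n_ddp: int = 2_000
    rho0: float = 0.8

    @property
    def rho(self) -> float:
        d0 = GENETIC_DISTANCES["AMR"]
        return rho_schedule(d0, GENETIC_DISTANCES[self.ddp], self.rho0, self.r)


def sd_compendium(
    case_control_ratio: tuple[int, int] = (1, 1),
    m: int = 500,
    n_eur: int = 10_000,
    n_ddp: int = 2_000,
) -> list[DatasetConfig]:
    """The 16-dataset grid: DDP x h2 in {0.5, 0.25} x r in {0.5, 1.0}.

    Rows 1-8 use r=0.5, rows 9-16 use r=1.0; within each block the four DDPs
    are crossed with the two heritabilities. Rows 9 and 13 duplicate rows 1
    and 5 because r does not change rho at d_k = d0.
    """
    star = case_control_ratio != (1, 1)
    configs = []
    i = 0
    for r in (0.5, 1.0):
        for h2 in (0.5, 0.25):
            for ddp in ("AMR", "SAS", "EAS", "AFR"):
                i += 1
                name = f"SD{i}" + ("*" if star else "")
                configs.append(
                    DatasetConfig(
                        name=name, ddp=ddp, h2=h2, r=r,
                        case_control_ratio=case_control_ratio,
                        m=m, n_eur=n_eur, n_ddp=n_ddp,
                    )
                )
    return configs


_DIVERGENCE_CACHE: dict[tuple[float, int, int], float] = {}


def generate_dataset(config: DatasetConfig, seed: int) -> MultiAncestryDataset:
    """End-to-end generation for one DatasetConfig (deterministic in seed)."""
    cal_seed = derive_seed(seed, "calibration", config.m)
    div = {}
    for pop in (config.ddp,):
        # the printed distances refer to m=500 SNPs; at other panel sizes the
        # target scales with m so the per-SNP divergence regime is unchanged
        target = GENETIC_DISTANCES[pop] * config.m / 500.0
        key = (target, config.m, cal_seed)
        if key not in _DIVERGENCE_CACHE:
            _DIVERGENCE_CACHE[key] = calibrate_divergence(target, config.m, cal_seed)
        div[pop] = _DIVERGENCE_CACHE[key]
    profiles = simulate_frequency_profiles(config.m, div, derive_seed(seed, "profiles"))
    W = draw_effects(config.m, derive_seed(seed, "W"))
    W_prime, zeta = correlate_effects(W, config.rho, derive_seed(seed, "Wp"))
    em = EffectModel(W=W, W_prime=W_prime, rho=config.rho, h2=config.h2, zeta_prime=zeta)
    lc = LiabilityConfig(h2=config.h2, case_control_ratio=config.case_control_ratio,
                         seed=derive_seed(seed, "liab"))
    return build_dataset(
        profiles, em, {"EUR": config.n_eur, config.ddp: config.n_ddp}, lc,
        derive_seed(seed, "build"),
    )
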