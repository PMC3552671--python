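"""Two-promoter Poisson model with gamma hyperpriors, fitted by PSO.

Each promoter's expected binned RPol II count is an exponential-decay
curve anchored at its TSS bin: level ``S`` at the TSS, decaying with
scale ``Kp`` (bp) toward the upstream background ``B`` and with scale
``Kt`` toward the downstream transcript level ``T``:

    promoter side:   lambda(D) = B + (S - B) * exp(-D / Kp)
    transcript side: lambda(D) = T + (S - T) * exp(-D / Kt)

For a divergent pair the observed count in each bin is the sum of two
independent Poisson contributions, one per promoter, so the expected
count is the sum of the two curves, with the side (promoter vs
transcript) of each gene determined by the bin's region label
(NEG / MID / POS).  Genome-wide, each of the five parameters is assumed
gamma-distributed across expressed genes; those gamma (shape, scale)
pairs form the hyperprior, and pair parameters are estimated by
maximizing the Poisson log-likelihood plus the gamma log-prior (a MAP
fit) with a seeded particle swarm.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from .profiles import MID, NEG, POS, BinnedProfile
from .pso import PSOConfig, pso_maximize

__all__ = [
    "SinglePromoterParams",
    "PairParams",
    "GammaFamily",
    "Hyperparams",
    "RegulatoryRegion",
    "expected_lambda_single",
    "expected_lambda_pair",
    "pair_lambda_profile",
    "log_likelihood",
    "log_prior",
    "SinglePromoterModel",
    "GammaHyperprior",
    "PairPromoterModel",
    "fit_single_promoter",
    "fit_hyperparams",
    "fit_pair_map",
    "extract_regulatory_region",
    "classify_promoters",
]

PARAM_FAMILIES = ("B", "T", "S", "Kp", "Kt")

# PairParams flat order: B1,B2,T1,T2,S1,S2,Kp1,Kp2,Kt1,Kt2
_PAIR_ORDER = [(f, g) for f in PARAM_FAMILIES for g in (1, 2)]


@dataclass(frozen=True)
class SinglePromoterParams:
    """B, T, S levels (counts/bin) and Kp, Kt decay scales (bp) of one promoter."""

    B: float
    T: float
    S: float
    Kp: float
    Kt: float

    def __post_init__(self) -> None:
        for name in PARAM_FAMILIES:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.B, self.T, self.S, self.Kp, self.Kt], dtype=float)

    @classmethod
    def from_array(cls, a) -> "SinglePromoterParams":
        b, t, s, kp, kt = map(float, a)
        return cls(B=b, T=t, S=s, Kp=kp, Kt=kt)

    @property
    def is_peaked(self) -> bool:
        """Whether the TSS level exceeds both flanking levels."""
        return self.S >= self.B and self.S >= self.T


@dataclass(frozen=True)
class PairParams:
    """Ten hidden variables of a pair: gene1 on +, gene2 on - strand."""

    gene1: SinglePromoterParams
    gene2: SinglePromoterParams

    def as_array(self) -> np.ndarray:
        """Flat order B1,B2,T1,T2,S1,S2,Kp1,Kp2,Kt1,Kt2."""
        out = np.empty(10)
        for i, (fam, g) in enumerate(_PAIR_ORDER):
            out[i] = getattr(self.gene1 if g == 1 else self.gene2, fam)
        return out

    @classmethod
    def from_array(cls, a) -> "PairParams":
        a = np.asarray(a, dtype=float)
        vals: dict[int, dict[str, float]] = {1: {}, 2: {}}
        for i, (fam, g) in enumerate(_PAIR_ORDER):
            vals[g][fam] = float(a[i])
        return cls(gene1=SinglePromoterParams(**vals[1]),
                   gene2=SinglePromoterParams(**vals[2]))

    def swapped(self) -> "PairParams":
        return PairParams(gene1=self.gene2, gene2=self.gene1)


@dataclass(frozen=True)
class GammaFamily:
    """Gamma(shape alpha, scale beta) hyperprior for one parameter family."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("gamma shape and scale must be positive")

    @property
    def mean(self) -> float:
        return self.alpha * self.beta

    def log_pdf(self, y: float) -> float:
        if y <= 0:
            raise ValueError("gamma variate must be positive")
        return (
            (self.alpha - 1) * math.log(y)
            - y / self.beta
            - math.lgamma(self.alpha)
            - self.alpha * math.log(self.beta)
        )


@dataclass(frozen=True)
class Hyperparams:
    """Gamma hyperpriors for the five parameter families."""

    B: GammaFamily
    T: GammaFamily
    S: GammaFamily
    Kp: GammaFamily
    Kt: GammaFamily

    def family(self, name: str) -> GammaFamily:
        return getattr(self, name)

    @classmethod
    def from_moments(cls, means: dict[str, float], shapes: dict[str, float] | None = None,
                     shape: float = 4.0) -> "Hyperparams":
        fams = {}
        for name in PARAM_FAMILIES:
            a = shapes[name] if shapes else shape
            fams[name] = GammaFamily(alpha=a, beta=means[name] / a)
        return cls(**fams)


# ---------------------------------------------------------------------------
# expected counts


def expected_lambda_single(p: SinglePromoterParams, D, side: str):
    """Expected count at distance ``D`` bp from the TSS bin, on one side."""
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("distance must be non-negative")
    if side == "promoter":
        if p.Kp <= 0:
            raise ValueError("Kp must be positive")
        out = p.B + (p.S - p.B) * np.exp(-D / p.Kp)
    elif side == "transcript":
        if p.Kt <= 0:
            raise ValueError("Kt must be positive")
        out = p.T + (p.S - p.T) * np.exp(-D / p.Kt)
    else:
        raise ValueError(f"unknown side {side!r}")
    return float(out) if out.ndim == 0 else out


def expected_lambda_pair(Y: PairParams, region: str, D1, D2):
    """Expected pair count: sum of the two single-promoter curves.

    The bin's region decides each gene's side: in NEG (transcript of the
    minus gene) gene1 contributes its promoter curve and gene2 its
    transcript curve; in MID both contribute promoter curves; in POS
    gene1 contributes transcript and gene2 promoter.
    """
    if region == NEG:
        return expected_lambda_single(Y.gene1, D1, "promoter") + \
            expected_lambda_single(Y.gene2, D2, "transcript")
    if region == MID:
        return expected_lambda_single(Y.gene1, D1, "promoter") + \
            expected_lambda_single(Y.gene2, D2, "promoter")
    if region == POS:
        return expected_lambda_single(Y.gene1, D1, "transcript") + \
            expected_lambda_single(Y.gene2, D2, "promoter")
    raise ValueError(f"unknown region label {region!r}")


def pair_lambda_profile(Y: PairParams, profile: BinnedProfile) -> np.ndarray:
    """Vector of expected counts for every labelled bin of a pair window."""
    if profile.region_labels is None or profile.distances is None:
        raise ValueError("profile must carry region labels and distances")
    lam = np.full(profile.n_bins, np.nan)
    d1 = profile.distances[:, 0]
    d2 = profile.distances[:, 1]
    for region in (NEG, MID, POS):
        m = profile.region_labels == region
        if m.any():
            lam[m] = expected_lambda_pair(Y, region, d1[m], d2[m])
    return lam


# ---------------------------------------------------------------------------
# likelihood and prior


def _likelihood_mask(profile: BinnedProfile, transcript_bins: int | None) -> np.ndarray:
    """Bins entering the likelihood: all MID bins plus the ``transcript_bins``
    NEG/POS bins nearest each TSS (the transcript-region truncation)."""
    labels = profile.region_labels
    if labels is None or profile.tss_bins is None:
        raise ValueError("profile must carry region labels and TSS bins")
    i_neg, i_pos = profile.tss_bins
    idx = np.arange(profile.n_bins)
    mask = labels == MID
    if transcript_bins is None:
        mask |= (labels == NEG) | (labels == POS)
    else:
        mask |= (labels == NEG) & (idx > i_neg - transcript_bins)
        mask |= (labels == POS) & (idx < i_pos + transcript_bins)
    return mask


def log_likelihood(profile: BinnedProfile, Y: PairParams,
                   transcript_bins: int | None = 50) -> float:
    """Poisson log-likelihood of a labelled pair profile under ``Y``.

    Each transcript region (NEG, POS) is truncated to the
    ``transcript_bins`` bins nearest its TSS (default 50, i.e. 1000 bp at
    20-bp bins); the MID region enters in full.
    """
    if (profile.counts < 0).any():
        raise ValueError("counts must be non-negative")
    mask = _likelihood_mask(profile, transcript_bins)
    lam = pair_lambda_profile(Y, profile)[mask]
    if np.any(lam <= 0) or np.any(~np.isfinite(lam)):
        raise ValueError("non-positive expected count under Y")
    x = profile.counts[mask].astype(float)
    return float(np.sum(x * np.log(lam) - lam - gammaln(x + 1)))


def log_prior(Y: PairParams, theta: Hyperparams) -> float:
    """Gamma log-prior of the ten pair parameters (independent families)."""
    total = 0.0
    for name in PARAM_FAMILIES:
        fam = theta.family(name)
        total += fam.log_pdf(getattr(Y.gene1, name))
        total += fam.log_pdf(getattr(Y.gene2, name))
    return total


def _single_lambda(params_arr: np.ndarray, D: np.ndarray,
                   promoter_side: np.ndarray) -> np.ndarray:
    """Expected counts for a single gene; vectorized over parameter rows.

    ``params_arr`` is (n, 5) rows of (B, T, S, Kp, Kt); returns (n, n_bins).
    """
    B, T, S, Kp, Kt = (params_arr[:, i][:, None] for i in range(5))
    D = D[None, :]
    prom = B + (S - B) * np.exp(-D / Kp)
    tran = T + (S - T) * np.exp(-D / Kt)
    return np.where(promoter_side[None, :], prom, tran)


def _single_log_likelihood_matrix(params_arr, counts, D, promoter_side,
                                  gln) -> np.ndarray:
    lam = _single_lambda(params_arr, D, promoter_side)
    return np.sum(counts[None, :] * np.log(lam) - lam - gln[None, :], axis=1)


# ---------------------------------------------------------------------------
# estimators


class SinglePromoterModel(BaseEstimator):
    """Maximum-likelihood fit of the five-parameter single-promoter curve.

    Fits (B, T, S, Kp, Kt) to a TSS-anchored profile by L-BFGS-B from a
    moment-based initializer; the achieved log-likelihood never falls
    below the initializer's.

    Parameters
    ----------
    k_bounds : (float, float)
        Box bounds for the decay scales Kp, Kt in bp (default 20-2000).
    orientation : {'+', '-'}
        '+' places the promoter side left of the TSS bin (the default for
        plus-strand-oriented profiles); '-' mirrors it.

    Attributes
    ----------
    params_ : SinglePromoterParams
    log_likelihood_ : float
    boundary_flags_ : dict  — decay scales that ended on a box wall.
    """

    def __init__(self, k_bounds=(20.0, 2000.0), orientation: str = "+",
                 maxiter: int = 300):
        self.k_bounds = k_bounds
        self.orientation = orientation
        self.maxiter = maxiter

    def fit(self, profile: BinnedProfile, tss_bin: int | None = None):
        counts = profile.counts.astype(float)
        if counts.sum() == 0:
            raise ValueError("all-zero profile: no signal to fit")
        if tss_bin is None:
            if profile.tss_bins is None:
                raise ValueError("tss_bin required")
            tss_bin = profile.tss_bins[0]
        n = counts.size
        if not 0 <= tss_bin < n:
            raise IndexError("tss_bin outside profile")

        idx = np.arange(n)
        D = np.abs(idx - tss_bin) * float(profile.bin_size)
        if self.orientation == "+":
            promoter_side = idx < tss_bin
        elif self.orientation == "-":
            promoter_side = idx > tss_bin
        else:
            raise ValueError("orientation must be '+' or '-'")
        gln = gammaln(counts + 1)

        x0 = self._moment_init(counts, tss_bin, promoter_side)
        cmax = counts.max()
        eps = 1e-2
        bounds = [
            (eps, cmax + 1.0),          # B
            (eps, cmax + 1.0),          # T
            (eps, 2.0 * cmax + 1.0),    # S
            self.k_bounds,              # Kp
            self.k_bounds,              # Kt
        ]
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])

        def nll(x):
            return -_single_log_likelihood_matrix(
                x[None, :], counts, D, promoter_side, gln)[0]

        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": self.maxiter})
        best_x, best_f = (res.x, res.fun) if res.fun <= nll(x0) else (x0, nll(x0))

        self.params_ = SinglePromoterParams.from_array(best_x)
        self.log_likelihood_ = -float(best_f)
        lo, hi = self.k_bounds
        tol = 1e-6
        self.boundary_flags_ = {
            "Kp": abs(self.params_.Kp - lo) < tol or abs(self.params_.Kp - hi) < tol,
            "Kt": abs(self.params_.Kt - lo) < tol or abs(self.params_.Kt - hi) < tol,
        }
        return self

    @staticmethod
    def _moment_init(counts: np.ndarray, tss_bin: int,
                     promoter_side: np.ndarray) -> np.ndarray:
        up = counts[promoter_side]
        down_mask = ~promoter_side.copy()
        down_mask[tss_bin] = False
        down = counts[down_mask]
        # outermost quarter of each flank approximates the asymptotic level
        q_up = up[: max(1, up.size // 4)] if up.size else np.array([counts.mean()])
        q_dn = down[-max(1, down.size // 4):] if down.size else np.array([counts.mean()])
        b0 = max(float(np.mean(q_up)), 0.1)
        t0 = max(float(np.mean(q_dn)), 0.1)
        s0 = max(float(counts[tss_bin]), b0 + 0.5, t0 + 0.5)
        return np.array([b0, t0, s0, 200.0, 200.0])


class GammaHyperprior(BaseEstimator):
    """Method-of-moments gamma fit per parameter family.

    Given single-gene fits across a cohort, estimates each family's gamma
    hyperprior as alpha = mean^2 / var, beta = var / mean.

    Attributes
    ----------
    theta_ : Hyperparams
    n_fits_ : int
    """

    def __init__(self, min_fits: int = 30):
        self.min_fits = min_fits

    def fit(self, single_fits):
        fits = list(single_fits)
        if len(fits) < self.min_fits:
            raise ValueError(
                f"need >= {self.min_fits} single-gene fits, got {len(fits)}"
            )
        fams = {}
        for name in PARAM_FAMILIES:
            vals = np.array([getattr(p, name) for p in fits], dtype=float)
            m = vals.mean()
            v = vals.var(ddof=1)
            if v <= 0:
                raise ValueError(f"degenerate (zero) variance in family {name}")
            fams[name] = GammaFamily(alpha=m * m / v, beta=v / m)
        self.theta_ = Hyperparams(**fams)
        self.n_fits_ = len(fits)
        return self


class PairPromoterModel(BaseEstimator):
    """MAP fit of the ten pair parameters by particle swarm.

    Maximizes Poisson log-likelihood (transcript regions truncated to
    ``transcript_bins`` bins) plus the gamma log-prior under ``theta``.
    The moment-based initializer is injected into the swarm, so the
    achieved log-posterior never falls below the initializer's; results
    are reproducible given ``seed``.

    Attributes
    ----------
    params_ : PairParams
    log_posterior_ : float
    """

    def __init__(self, theta: Hyperparams | None = None,
                 transcript_bins: int | None = 50,
                 k_bounds=(20.0, 2000.0),
                 pso: PSOConfig = PSOConfig(),
                 seed: int | None = None):
        self.theta = theta
        self.transcript_bins = transcript_bins
        self.k_bounds = k_bounds
        self.pso = pso
        self.seed = seed

    def fit(self, profile: BinnedProfile, seed: int | None = None):
        if self.theta is None:
            raise ValueError("a fitted Hyperparams (theta) is required")
        if seed is None:
            seed = self.seed
        if seed is None:
            raise ValueError("a seed is required for the particle swarm")

        mask = _likelihood_mask(profile, self.transcript_bins)
        labels = profile.region_labels[mask]
        counts = profile.counts[mask].astype(float)
        d1 = profile.distances[mask, 0]
        d2 = profile.distances[mask, 1]
        gln = gammaln(counts + 1)
        # per-bin side of each gene's curve (promoter vs transcript)
        g1_promoter = labels != POS
        g2_promoter = labels != NEG

        theta = self.theta
        alphas = np.empty(10)
        betas = np.empty(10)
        for i, (fam_name, _) in enumerate(_PAIR_ORDER):
            fam = theta.family(fam_name)
            alphas[i] = fam.alpha
            betas[i] = fam.beta
        prior_const = float(np.sum(-gammaln(alphas) - alphas * np.log(betas)))

        def objective(P: np.ndarray) -> np.ndarray:
            # columns in flat order B1,B2,T1,T2,S1,S2,Kp1,Kp2,Kt1,Kt2
            B1, B2, T1, T2, S1, S2, Kp1, Kp2, Kt1, Kt2 = (P[:, i][:, None]
                                                          for i in range(10))
            lam1 = np.where(
                g1_promoter[None, :],
                B1 + (S1 - B1) * np.exp(-d1[None, :] / Kp1),
                T1 + (S1 - T1) * np.exp(-d1[None, :] / Kt1),
            )
            lam2 = np.where(
                g2_promoter[None, :],
                B2 + (S2 - B2) * np.exp(-d2[None, :] / Kp2),
                T2 + (S2 - T2) * np.exp(-d2[None, :] / Kt2),
            )
            lam = lam1 + lam2
            ll = np.sum(counts[None, :] * np.log(lam) - lam - gln[None, :], axis=1)
            lp = np.sum((alphas[None, :] - 1) * np.log(P) - P / betas[None, :],
                        axis=1) + prior_const
            return ll + lp

        cmax = float(profile.counts.max())
        eps = 1e-2
        level_hi = cmax + 1.0
        bounds = (
            [(eps, level_hi)] * 2            # B1, B2
            + [(eps, level_hi)] * 2          # T1, T2
            + [(eps, 2 * cmax + 1.0)] * 2    # S1, S2
            + [self.k_bounds] * 4            # Kp1, Kp2, Kt1, Kt2
        )
        init = self._moment_init(profile)
        x, f = pso_maximize(objective, bounds, seed=seed, config=self.pso, init=init)

        self.params_ = PairParams.from_array(x)
        self.log_posterior_ = float(f)
        return self

    @staticmethod
    def _moment_init(profile: BinnedProfile) -> np.ndarray:
        labels = profile.region_labels
        counts = profile.counts.astype(float)
        i_neg, i_pos = profile.tss_bins
        neg_idx = np.flatnonzero(labels == NEG)
        pos_idx = np.flatnonzero(labels == POS)
        # outermost quarter of each transcript flank -> T levels
        t2 = float(counts[neg_idx[: max(1, neg_idx.size // 4)]].mean())
        t1 = float(counts[pos_idx[-max(1, pos_idx.size // 4):]].mean())
        mid = counts[labels == MID]
        b0 = float(np.percentile(counts, 25))
        if mid.size:
            b0 = min(b0, float(mid.min()))
        b0 = max(b0 / 2.0, 0.2)
        s1 = max(float(counts[i_pos]), b0 + 0.5, t1 + 0.5)
        s2 = max(float(counts[i_neg]), b0 + 0.5, t2 + 0.5)
        t1 = max(t1, 0.2)
        t2 = max(t2, 0.2)
        return np.array([b0, b0, t1, t2, s1, s2, 200.0, 200.0, 200.0, 200.0])


# ---------------------------------------------------------------------------
# functional wrappers


def fit_single_promoter(profile: BinnedProfile, tss_bin: int | None = None,
                        **kwargs) -> SinglePromoterParams:
    """ML fit of one promoter's parameters; see :class:`SinglePromoterModel`."""
    return SinglePromoterModel(**kwargs).fit(profile, tss_bin=tss_bin).params_


def fit_hyperparams(single_fits, min_fits: int = 30) -> Hyperparams:
    """Method-of-moments gamma hyperpriors; see :class:`GammaHyperprior`."""
    return GammaHyperprior(min_fits=min_fits).fit(single_fits).theta_


def fit_pair_map(profile: BinnedProfile, theta: Hyperparams, seed: int,
                 pso: PSOConfig = PSOConfig(), **kwargs):
    """MAP pair fit; returns (PairParams, log_posterior)."""
    m = PairPromoterModel(theta=theta, pso=pso, seed=seed, **kwargs).fit(profile)
    return m.params_, m.log_posterior_


# ---------------------------------------------------------------------------
# regulatory regions and promoter categories


@dataclass(frozen=True)
class RegulatoryRegion:
    """A promoter's regulatory interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    owner: str  # 'gene1' (+), 'gene2' (-), or 'shared'

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty regulatory region")

    def covers(self, point: int) -> bool:
        return self.start <= point < self.end

    @property
    def width(self) -> int:
        return self.end - self.start


def _decay_extent(K: float, S: float, base: float, decay_fraction: float,
                  mode: str, max_extent: float) -> float:
    g = 1.0 - decay_fraction
    if mode == "excess":
        # normalized excess (lambda - base)/(S - base) > g  =>  D < K ln(1/g)
        if S <= base:
            return 0.0
        return K * math.log(1.0 / g) if g > 0 else max_extent
    if mode == "absolute":
        # lambda > g * S
        thr = g * S
        if S <= base:
            return 0.0
        if thr <= base:
            return max_extent
        return K * math.log((S - base) / (thr - base))
    raise ValueError(f"unknown decay mode {mode!r}")


def extract_regulatory_region(
    p: SinglePromoterParams,
    tss: int,
    decay_fraction: float = 0.9,
    bin_size: int = 20,
    strand: str = "+",
    chrom: str = "chrS",
    mode: str = "excess",
    max_extent: float = 5000.0,
) -> RegulatoryRegion:
    """Interval around the TSS where the signal has decayed less than
    ``decay_fraction`` relative to the TSS-bin level.

    Under the default ``excess`` reading the boundary on the promoter side
    is the closed form D* = Kp * ln(1 / (1 - decay_fraction)) (so 90%
    decay gives Kp * ln 10), independent of absolute depth; the
    transcript side uses Kt analogously.  Boundaries are snapped outward
    to bin edges, and ``decay_fraction = 0`` returns exactly the TSS bin.
    A side with no excess over its baseline (S <= B or S <= T) gets zero
    extent, with a warning for the promoter side.
    """
    if not 0.0 <= decay_fraction < 1.0:
        raise ValueError("decay_fraction must be in [0, 1)")
    if strand not in "+-":
        raise ValueError("strand must be '+' or '-'")
    ext_p = _decay_extent(p.Kp, p.S, p.B, decay_fraction, mode, max_extent)
    ext_t = _decay_extent(p.Kt, p.S, p.T, decay_fraction, mode, max_extent)
    if p.S <= p.B:
        warnings.warn("S <= B: empty promoter-side excess", stacklevel=2)

    def snap(ext: float) -> int:
        return int(math.ceil(ext / bin_size - 1e-9)) * bin_size

    tb_start = (tss // bin_size) * bin_size
    tb_end = tb_start + bin_size
    if strand == "+":
        start = tb_start - snap(ext_p)
        end = tb_end + snap(ext_t)
    else:
        start = tb_start - snap(ext_t)
        end = tb_end + snap(ext_p)
    owner = "gene1" if strand == "+" else "gene2"
    return RegulatoryRegion(chrom=chrom, start=start, end=end, owner=owner)


def classify_promoters(tss_neg: int, tss_pos: int, shape: str, regions):
    """Four-way promoter category from shape and regulatory regions.

    Bi-peak pairs carry two regions and are *double* promoters, with the
    overlap width of the two regions reported (0 when disjoint).  Single-
    peak pairs carry one region: covering only the minus-strand TSS ->
    *left*; only the plus-strand TSS -> *right*; both -> *centre*.

    Returns (category, overlap_width); overlap_width is None for single
    shapes.
    """
    regions = list(regions)
    if shape == "bipeak":
        if len(regions) != 2:
            raise ValueError("bi-peak pairs need exactly two regulatory regions")
        r1, r2 = regions
        overlap = max(0, min(r1.end, r2.end) - max(r1.start, r2.start))
        return "double", overlap
    if shape == "single":
        if len(regions) != 1:
            raise ValueError("single-peak pairs need exactly one regulatory region")
        r = regions[0]
        cov_neg = r.covers(tss_neg)
        cov_pos = r.covers(tss_pos)
        if cov_neg and cov_pos:
            return "centre", None
        if cov_neg:
            return "left", None
        if cov_pos:
            return "right", None
        raise ValueError("single-shape regulatory region covers neither TSS")
    raise ValueError(f"unknown shape {shape!r}")
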